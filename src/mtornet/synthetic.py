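"""Ground-truth synthetic data: noisy time courses and SILAC phosphosite tables.

This module makes every pipeline stage testable without downloads.  It ships

* a calibrated ground-truth parameterization of the quadruple-input extended
  network (``truth_model``) whose qualitative behaviour matches the published
  stimulation/perturbation phenotypes (``behaviour_checklist``);
* ``generate_timecourses`` — immunoblot-like readout tables: multiplicative
  Gaussian noise (densitometry-like), >=3 replicates, the experimental time
  grid 0..120 min;
* ``generate_phospho_table`` — MaxQuant-dialect phosphosite tables emulating
  the five-experiment triple-SILAC design (0/5 min in three experiments,
  10/15 min in two, 30 min in all five as the normalization bridge, with
  per-experiment label rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .network import build_base_model, build_variant
from .simulate import CompiledModel, IntegrationError, Protocol, perturbation_scan, simulate

__all__ = [
    "TRUTH_INPUTS", "TRUTH_PARAMS", "truth_model", "SynthConfig",
    "behaviour_checklist", "generate_timecourses",
    "default_design", "generate_phospho_table",
]

# extra amino-acid inputs of the selected (best-AIC) network
TRUTH_INPUTS = frozenset({"IRS_p", "AMPK_pT172", "mTORC2_pS2481"})

# Calibrated ground-truth rate constants (1/min, arbitrary-unit pools).
# Chosen so that the behaviour checklist below passes: fast CaMKKbeta-like
# aa->AMPK activation, slower mTORC1->S6K axis, strong Akt->TSC coupling
# (wortmannin sensitivity of S6K-pT389) and an effective negative feedback
# (S6K -||- IRS) that lets mTORC1 inhibition disinhibit Akt.
TRUTH_PARAMS = {
    "k_IR_phos": 1.0,
    "k_IR_refrac": 0.2,
    "k_IR_recover": 0.05,
    "k_IRS_phos_by_IR": 1.0,
    "k_aa_IRS_p": 0.3,
    "k_IRS_dephos": 0.2,
    "k_IRS_S636_phos": 6.0,
    "k_IRS_S636_dephos": 0.5,
    "k_PI3K_PDK1_act": 1.0,
    "k_PI3K_PDK1_inact": 0.6,
    "k_PI3K_var_act": 0.3,
    "k_PI3K_var_inact": 0.5,
    "k_Akt_T308_phos": 1.0,
    "k_Akt_T308_dephos": 0.5,
    "k_Akt_S473_phos": 0.8,
    "k_Akt_S473_dephos": 0.8,
    "k_TSC_T1462_phos": 8.0,
    "k_TSC_T1462_dephos": 0.5,
    "k_TSC_S1387_phos": 0.6,
    "k_TSC_S1387_dephos": 0.5,
    "k_aa_mTORC1": 0.1,
    "k_mTORC1_inact": 2.0,
    "k_mTORC2_act": 1.0,
    "k_aa_mTORC2_pS2481": 0.08,
    "k_mTORC2_inact": 1.0,
    "k_aa_AMPK_pT172": 0.5,
    "k_AMPK_T172_phos": 0.15,
    "k_AMPK_T172_dephos": 0.5,
    "k_PRAS40_T246_phos": 1.0,
    "k_PRAS40_T246_dephos": 0.5,
    "k_PRAS40_S183_phos": 1.0,
    "k_PRAS40_S183_dephos": 0.5,
    "k_S6K_T229_phos": 0.5,
    "k_S6K_T229_dephos": 0.5,
    "k_S6K_T389_phos": 0.3,
    "k_S6K_T389_dephos": 0.6,
}

# experimental sampling grid (min)
TIME_GRID = (0.0, 1.0, 3.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0)


def truth_model(s6k_module="extended", inputs=TRUTH_INPUTS):
    """The quadruple-input ground-truth model with calibrated parameters."""
    base = build_base_model(s6k_module)
    model = build_variant(base, set(inputs))
    values = {k: v for k, v in TRUTH_PARAMS.items() if k in model.parameters}
    return model.with_params(values)


@dataclass(frozen=True)
class SynthConfig:
    """Settings of the noisy time-course generator."""

    time_grid: tuple = TIME_GRID
    n_replicates: int = 3
    noise_cv: float = 0.10
    seed: int = 0
    aa_level: float = 1.0
    insulin_level: float = 1.0
    extra_conditions: tuple = ()  # of (name, Protocol)

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")

    def conditions(self):
        conds = {
            "aa": Protocol(aa=self.aa_level, insulin=0.0),
            "aa_insulin": Protocol(aa=self.aa_level, insulin=self.insulin_level),
        }
        conds.update(dict(self.extra_conditions))
        return conds


# ---------------------------------------------------------------------------
# behaviour checklist: the qualitative phenotypes a truth fixture must show
# ---------------------------------------------------------------------------

def _peak(traj, obs):
    return float(traj.observable(obs).max())


def behaviour_checklist(model, params=None, output_step=0.25):
    """Qualitative stimulation/perturbation phenotype checks.

    Returns a list of (check name, passed, detail) tuples covering, under
    aa-only stimulation: acute AMPK activation, delayed S6K-T389, no
    saturation, and the wortmannin / shRaptor / STO-609 / shSin1 analogue
    perturbations (residual activities 10 / 25 / 50 / 40%).
    """
    aa_only = Protocol(aa=1.0, insulin=0.0, output_step=output_step)
    cm = CompiledModel(model)
    results = []

    def run(protocol):
        return simulate(model, protocol, params=params, compiled=cm)

    try:
        ctrl = run(aa_only)
        pi3k10 = run(aa_only.with_perturbation("PI3K", 0.1))
        mtorc1_25 = run(aa_only.with_perturbation("mTORC1", 0.25))
        ampk50 = run(aa_only.with_perturbation("AMPK", 0.5))
        mtorc2_40 = run(aa_only.with_perturbation("mTORC2", 0.4))
    except IntegrationError as exc:
        return [("integration", False, str(exc))]

    ampk = ctrl.observable("AMPK-pT172")
    results.append((
        "AMPK-pT172 acute (>=50% of max by t=5)",
        # an acute response requires a response: >=5% of the pool total
        ampk.max() >= 0.05 and ctrl.at("AMPK-pT172", 5.0) >= 0.5 * ampk.max(),
        f"t5={ctrl.at('AMPK-pT172', 5.0):.3f} max={ampk.max():.3f}",
    ))
    results.append((
        "p70S6K-pT389 delayed (t15 > t5)",
        ctrl.at("p70S6K-pT389", 15.0) > ctrl.at("p70S6K-pT389", 5.0),
        f"t5={ctrl.at('p70S6K-pT389', 5.0):.3f} t15={ctrl.at('p70S6K-pT389', 15.0):.3f}",
    ))
    pools = model.pools
    totals = {
        obs: sum(
            s.initial_amount
            for s in model.species
            if s.protein == next(
                sp.protein for sp in model.species
                if sp.id == model.observables[obs][0]
            )
        )
        for obs in model.observables
    }
    sat = {obs: _peak(ctrl, obs) / totals[obs] for obs in model.observables}
    worst = max(sat, key=sat.get)
    results.append((
        "no observable saturates (<=0.95 of pool total)",
        sat[worst] <= 0.95,
        f"max saturation {sat[worst]:.3f} ({worst})",
    ))

    def rel(pert, obs):
        return _peak(pert, obs) / _peak(ctrl, obs)

    results.append((
        "PI3K 10%: Akt-pT308 peak suppressed >=50%, AMPK-pT172 within 20%",
        rel(pi3k10, "Akt-pT308") <= 0.5
        and abs(rel(pi3k10, "AMPK-pT172") - 1.0) <= 0.2,
        f"pT308 ratio {rel(pi3k10, 'Akt-pT308'):.3f}, "
        f"AMPK ratio {rel(pi3k10, 'AMPK-pT172'):.3f}",
    ))
    results.append((
        "mTORC1 25%: p70S6K-pT389 suppressed >=50%, Akt-pS473 peak raised",
        # the rise must exceed solver noise to count as a feedback response
        rel(mtorc1_25, "p70S6K-pT389") <= 0.5
        and rel(mtorc1_25, "Akt-pS473") > 1.02,
        f"pT389 ratio {rel(mtorc1_25, 'p70S6K-pT389'):.3f}, "
        f"pS473 ratio {rel(mtorc1_25, 'Akt-pS473'):.3f}",
    ))
    results.append((
        "AMPK 50%: p70S6K-pT389 peak within 20%",
        abs(rel(ampk50, "p70S6K-pT389") - 1.0) <= 0.2,
        f"pT389 ratio {rel(ampk50, 'p70S6K-pT389'):.3f}",
    ))
    results.append((
        "mTORC2 40%: Akt-pS473 suppressed >=30%, pT389 and AMPK within 20%",
        rel(mtorc2_40, "Akt-pS473") <= 0.7
        and abs(rel(mtorc2_40, "p70S6K-pT389") - 1.0) <= 0.2
        and abs(rel(mtorc2_40, "AMPK-pT172") - 1.0) <= 0.2,
        f"pS473 ratio {rel(mtorc2_40, 'Akt-pS473'):.3f}, "
        f"pT389 ratio {rel(mtorc2_40, 'p70S6K-pT389'):.3f}, "
        f"AMPK ratio {rel(mtorc2_40, 'AMPK-pT172'):.3f}",
    ))
    return results


def checklist_passes(model, params=None):
    return all(ok for _, ok, _ in behaviour_checklist(model, params))


# ---------------------------------------------------------------------------
# noisy time-course generation
# ---------------------------------------------------------------------------

def generate_timecourses(truth, config: SynthConfig = None) -> Dataset:
    """Noisy readout time courses from a ground-truth model.

    y = yhat * (1 + eps), eps ~ Normal(0, CV) truncated at -0.99, independent
    per replicate and data point; deterministic given ``config.seed``.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    conditions = config.conditions()
    cm = CompiledModel(truth)
    times = np.asarray(sorted(config.time_grid), float)
    rows = []
    for cond in sorted(conditions):
        protocol = conditions[cond]
        run_proto = Protocol(
            aa=protocol.aa, insulin=protocol.insulin,
            duration=max(float(times[-1]), 1.0),
            output_step=protocol.output_step,
            perturbations=protocol.perturbations,
        )
        traj = simulate(truth, run_proto, compiled=cm)
        for obs in cm.observable_ids:
            yhat = np.interp(times, traj.time, traj.observable(obs))
            for rep in range(config.n_replicates):
                eps = np.maximum(
                    rng.normal(0.0, config.noise_cv, len(times)), -0.99
                )
                y = yhat * (1.0 + eps) if config.noise_cv > 0 else yhat.copy()
                rows.append(pd.DataFrame({
                    "observable": obs, "condition": cond, "time": times,
                    "replicate": rep + 1, "value": y,
                }))
    table = pd.concat(rows, ignore_index=True)
    return Dataset(table=table, conditions=conditions)


# ---------------------------------------------------------------------------
# triple-SILAC phosphosite tables
# ---------------------------------------------------------------------------

def default_design():
    """The five-experiment triple-SILAC layout with label rotation.

    Experiments 1-3 measure 0/5/30 min, experiments 4-5 measure 10/15/30 min;
    the 30 min channel is present in every experiment and bridges them.
    """
    from .phospho import DesignSpec

    return DesignSpec(experiments={
        "Exp1": {"L": 0, "M": 5, "H": 30},
        "Exp2": {"M": 0, "H": 5, "L": 30},
        "Exp3": {"H": 0, "L": 5, "M": 30},
        "Exp4": {"L": 10, "M": 15, "H": 30},
        "Exp5": {"M": 10, "H": 15, "L": 30},
    }, bridge_time=30)


def generate_phospho_table(
    n_sites=500,
    n_regulated=25,
    effect_log2fc=1.5,
    design=None,
    seed=0,
    noise_cv=0.15,
    missing_rate=0.02,
    contaminant_fraction=0.10,
    regulated_times=(5, 10, 15, 30),
):
    """Synthetic MaxQuant-dialect phosphosite table.

    Baseline intensities are log-normal; regulated sites are multiplied by
    2**effect_log2fc in their stimulated channels; localization probabilities
    are a mixture with a sub-0.75 contaminant fraction; intensities are
    dropped (set to 0 = missing) at ``missing_rate``.
    """
    if n_regulated > n_sites:
        raise ValueError("n_regulated cannot exceed n_sites")
    design = design or default_design()
    rng = np.random.default_rng(seed)

    base = 10.0 ** rng.normal(7.0, 0.8, n_sites)  # MaxQuant-like intensity scale
    regulated = np.zeros(n_sites, dtype=bool)
    regulated[:n_regulated] = True
    sign = np.where(rng.random(n_sites) < 0.8, 1.0, -1.0)  # mostly up-regulated

    contaminant = rng.random(n_sites) < contaminant_fraction
    loc_prob = np.where(
        contaminant,
        rng.uniform(0.30, 0.75, n_sites),
        rng.uniform(0.755, 1.0, n_sites),
    ).round(3)

    records = {
        "Proteins": [f"PROT{i:04d}" for i in range(n_sites)],
        "Positions within proteins": rng.integers(5, 900, n_sites),
        "Amino acid": rng.choice(list("STY"), n_sites, p=[0.8, 0.15, 0.05]),
        "Localization prob": loc_prob,
        "Regulated truth": regulated.astype(int),  # provenance column, ignored by readers
    }
    for exp in sorted(design.experiments):
        for channel in ("L", "M", "H"):
            t = design.experiments[exp].get(channel)
            col = f"Intensity {channel} {exp}"
            if t is None:
                records[col] = np.zeros(n_sites)
                continue
            fold = np.ones(n_sites)
            if t in regulated_times:
                fold = np.where(
                    regulated, 2.0 ** (sign * effect_log2fc), 1.0
                )
            noise = rng.lognormal(0.0, np.log1p(noise_cv), n_sites)
            vals = base * fold * noise
            vals[rng.random(n_sites) < missing_rate] = 0.0
            records[col] = vals
    return pd.DataFrame(records)
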