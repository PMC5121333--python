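"""Parameter estimation: multi-start trust-region fitting with AIC scoring.

The objective is a weighted least-squares chi-square with a 10% proportional
error model, sigma = max(0.10 * y_obs, floor), the floor being 1% of each
observable's maximum over the dataset (readouts start at 0, so a pure
proportional model would give zero-variance points).  Optimization runs in
log10-parameter space inside the bounds [1e-6, 1e4]; start points are the
current best-known values perturbed multiplicatively by 10^N(0, 0.4) per
parameter (the first start is unperturbed).  Model goodness of fit is scored
as AIC = chi2 + 2 k (Gaussian likelihood with known variances, constants
dropped).

The statsmodels-style surface is :class:`KineticModel` (model + dataset)
whose ``fit`` returns a :class:`FitResults` ensemble with estimates,
ensemble-spread uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data import Dataset
from .network import ModelSpec
from .simulate import CompiledModel, IntegrationError, Protocol, simulate

__all__ = ["FitConfig", "FitResult", "FitResults", "KineticModel",
           "chi2", "fit", "aic", "calibrate_ir"]

_FAILED_RESIDUAL = 1e6


@dataclass(frozen=True)
class FitConfig:
    """Multi-start optimizer settings."""

    n_starts: int = 100
    disturbance_sd: float = 0.4  # log10 decades around the start center
    max_iter: int = 250
    tolerance: float = 1e-5
    error_fraction: float = 0.10
    sigma_floor_fraction: float = 0.01
    seed: int = 0
    frozen: tuple = ()  # of (param id, value) pairs held fixed
    center: tuple = ()  # of (param id, value) pairs overriding start center
    perturb_first_start: bool = False  # disturb start 0 too (recovery studies)

    def frozen_map(self):
        return dict(self.frozen)

    def center_map(self):
        return dict(self.center)


@dataclass(frozen=True)
class FitResult:
    params: dict
    chi2: float
    aic: float
    n_data: int
    k_params: int
    converged: bool
    start_index: int


def aic(chi2_value, k_params):
    """Akaike information criterion: chi2 + 2 * (number of fitted parameters)."""
    if chi2_value < 0 or k_params < 0:
        raise ValueError("chi2 and k must be nonnegative")
    return chi2_value + 2.0 * k_params


class _Objective:
    """Residual evaluator shared by chi2, fit and profile likelihood."""

    def __init__(self, model: ModelSpec, dataset: Dataset, config: FitConfig):
        dataset.validate_against(model)
        self.model = model
        self.config = config
        self.compiled = CompiledModel(model)
        obs_idx = {o: i for i, o in enumerate(self.compiled.observable_ids)}
        floors = {
            o: config.sigma_floor_fraction * m
            for o, m in dataset.observable_max().items()
        }
        self.blocks = []
        for cond, sub in dataset.table.groupby("condition", sort=True):
            protocol = dataset.conditions[cond]
            times = np.sort(sub["time"].unique())
            t_index = {t: i for i, t in enumerate(times)}
            y = sub["value"].to_numpy(float)
            sigma = np.maximum(
                config.error_fraction * y,
                sub["observable"].map(floors).to_numpy(float),
            )
            self.blocks.append({
                "protocol": protocol,
                "times": times,
                "row_obs": sub["observable"].map(obs_idx).to_numpy(int),
                "row_time": sub["time"].map(t_index).to_numpy(int),
                "y": y,
                "sigma": sigma,
            })
        self.n_data = sum(len(b["y"]) for b in self.blocks)

    def residuals(self, params):
        out = []
        for b in self.blocks:
            proto = b["protocol"]
            eval_proto = Protocol(
                aa=proto.aa, insulin=proto.insulin,
                duration=float(b["times"][-1]) or proto.duration,
                output_step=proto.output_step,
                perturbations=proto.perturbations,
            )
            traj = _simulate_at(self.model, eval_proto, b["times"], params,
                                self.compiled)
            y_sim = traj[b["row_obs"], b["row_time"]]
            out.append((y_sim - b["y"]) / b["sigma"])
        return np.concatenate(out)

    def chi2(self, params):
        try:
            r = self.residuals(params)
        except IntegrationError:
            return math.inf
        return float(r @ r)


def _simulate_at(model, protocol, times, params, compiled):
    """Observable matrix evaluated exactly at the requested time points."""
    from scipy.integrate import solve_ivp

    from .simulate import ATOL, NEGATIVITY_TOL, RTOL, _param_hash

    kg = compiled.rate_constants(protocol, params)
    x0 = compiled.initial_state(protocol)
    t_end = float(times[-1]) if times[-1] > 0 else 1.0
    sol = solve_ivp(compiled.rhs(kg), (0.0, t_end), x0, method="LSODA",
                    t_eval=times, jac=compiled.jacobian(kg),
                    rtol=RTOL, atol=ATOL)
    if not sol.success or sol.y.min() < NEGATIVITY_TOL:
        raise IntegrationError(
            f"integration failed during fitting; parameter hash {_param_hash(kg)}"
        )
    return compiled.obs_matrix @ sol.y


def chi2(model, params, dataset, config: FitConfig = None):
    """Weighted chi-square of ``params`` against ``dataset``."""
    config = config or FitConfig()
    return _Objective(model, dataset, config).chi2(params)


class KineticModel:
    """A network model bound to a time-course dataset, ready to fit.

    Parameters
    ----------
    model_spec : ModelSpec
    dataset : Dataset

    Examples
    --------
    >>> km = KineticModel(model_spec, dataset)
    >>> res = km.fit(FitConfig(n_starts=20, seed=1))
    >>> print(res.summary())
    """

    def __init__(self, model_spec: ModelSpec, dataset: Dataset):
        self.model_spec = model_spec
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, model_spec, frame, conditions):
        return cls(model_spec, Dataset(table=frame, conditions=conditions))

    def loglike_chi2(self, params, config=None):
        return chi2(self.model_spec, params, self.dataset, config)

    def fit(self, config: FitConfig = None) -> "FitResults":
        config = config or FitConfig()
        obj = _Objective(self.model_spec, self.dataset, config)
        frozen = config.frozen_map()
        free = [p for p in self.model_spec.parameters if p not in frozen]
        if not free:
            raise ValueError("no free parameters to fit")
        lo = np.log10([self.model_spec.parameters[p][1] for p in free])
        hi = np.log10([self.model_spec.parameters[p][2] for p in free])
        center_map = {**self.model_spec.param_values(), **config.center_map()}
        center = np.clip(np.log10([center_map[p] for p in free]), lo, hi)
        rng = np.random.default_rng(config.seed)

        def residual_vec(x):
            params = dict(zip(free, 10.0 ** x))
            params.update(frozen)
            try:
                return obj.residuals(params)
            except IntegrationError:
                return np.full(obj.n_data, _FAILED_RESIDUAL)

        results = []
        failures = []
        for i in range(config.n_starts):
            if i == 0 and not config.perturb_first_start:
                x0 = center.copy()
            else:
                x0 = np.clip(
                    center + rng.normal(0.0, config.disturbance_sd, len(free)),
                    lo, hi,
                )
            try:
                sol = least_squares(
                    residual_vec, x0, bounds=(lo, hi), method="trf",
                    ftol=config.tolerance, xtol=config.tolerance,
                    gtol=config.tolerance,
                    max_nfev=config.max_iter * (len(free) + 1),
                )
            except Exception as exc:  # keep the multistart alive
                failures.append((i, repr(exc)))
                continue
            params = dict(zip(free, 10.0 ** sol.x))
            params.update(frozen)
            c2 = float(2.0 * sol.cost)
            if c2 >= _FAILED_RESIDUAL:  # never left the failure plateau
                failures.append((i, "integration failed at optimum"))
                continue
            results.append(FitResult(
                params=params, chi2=c2, aic=aic(c2, len(free)),
                n_data=obj.n_data, k_params=len(free),
                converged=bool(sol.status > 0), start_index=i,
            ))
        if not results:
            raise RuntimeError(f"all {config.n_starts} starts failed: {failures}")
        results.sort(key=lambda r: r.chi2)
        return FitResults(self, results, config, free, failures)


class FitResults:
    """Sorted multi-start ensemble with estimates and diagnostics."""

    def __init__(self, kinetic_model, results, config, free_params, failures=()):
        self.model = kinetic_model
        self.results = list(results)
        self.config = config
        self.free_params = list(free_params)
        self.failures = list(failures)

    def __len__(self):
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, i):
        return self.results[i]

    @property
    def best(self) -> FitResult:
        return self.results[0]

    @property
    def params(self):
        return dict(self.best.params)

    @property
    def chi2(self):
        return self.best.chi2

    @property
    def aic(self):
        return self.best.aic

    def params_frame(self, best_fraction=1.0):
        """Parameter values across the ensemble (rows = fits, best first)."""
        n = max(1, int(math.ceil(best_fraction * len(self.results))))
        return pd.DataFrame([r.params for r in self.results[:n]])

    def ensemble_sd(self, best_fraction=0.5):
        """log10 ensemble standard deviation over the best fits."""
        frame = self.params_frame(best_fraction)
        return np.log10(frame[self.free_params]).std(ddof=1).to_dict()

    def ensemble_cv(self, best_fraction=0.5):
        """Linear-scale coefficient of variation over the best fits."""
        frame = self.params_frame(best_fraction)[self.free_params]
        return (frame.std(ddof=1) / frame.mean()).to_dict()

    def summary(self):
        best = self.best
        sd = self.ensemble_sd() if len(self.results) > 2 else {}
        lines = [
            "Kinetic model fit (multi-start trust-region least squares)",
            "=" * 62,
            f"data points: {best.n_data}    fitted parameters: {best.k_params}",
            f"starts: {len(self.results)} kept / {self.config.n_starts} run"
            f"    converged best: {best.converged}",
            f"chi2: {best.chi2:.4g}    AIC (chi2 + 2k): {best.aic:.4g}",
            "-" * 62,
            f"{'parameter':<28}{'estimate':>12}{'log10 sd':>12}",
        ]
        for p in self.free_params:
            sd_txt = f"{sd[p]:.3f}" if p in sd else "--"
            lines.append(f"{p:<28}{best.params[p]:>12.4g}{sd_txt:>12}")
        frozen = self.config.frozen_map()
        if frozen:
            lines.append("-" * 62)
            for p, v in frozen.items():
                lines.append(f"{p:<28}{v:>12.4g}{'(fixed)':>12}")
        return "\n".join(lines)

    def to_json(self):
        import json

        return json.dumps({
            "chi2": self.best.chi2,
            "aic": self.best.aic,
            "n_data": self.best.n_data,
            "k_params": self.best.k_params,
            "params": self.best.params,
            "ensemble_size": len(self.results),
        }, indent=2, sort_keys=True)


def fit(model, dataset, config: FitConfig = None) -> FitResults:
    """Functional wrapper around :meth:`KineticModel.fit`."""
    return KineticModel(model, dataset).fit(config)


IR_PARAMS = ("k_IR_phos", "k_IR_refrac", "k_IR_recover")


def calibrate_ir(model, dataset, config: FitConfig = None) -> FitResults:
    """Fit the three insulin-receptor parameters alone.

    The IR module sits upstream of everything and is only excited by
    insulin-containing conditions; it is calibrated once against those
    conditions (all other parameters held at their current values) and the
    result is frozen for the network/variant fits.
    """
    config = config or FitConfig()
    insulin_conds = [c for c, p in dataset.conditions.items() if p.insulin > 0]
    if not insulin_conds:
        raise ValueError("IR calibration requires an insulin-containing condition")
    sub = Dataset(
        table=dataset.table[dataset.table["condition"].isin(insulin_conds)],
        conditions={c: dataset.conditions[c] for c in insulin_conds},
    )
    frozen = tuple(
        (p, v) for p, v in model.param_values().items() if p not in IR_PARAMS
    )
    return KineticModel(model, sub).fit(dc_replace(config, frozen=frozen))
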