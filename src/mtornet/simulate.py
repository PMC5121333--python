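"""Deterministic simulation of network models under stimulation protocols.

A :class:`Protocol` is a single simulated experiment: step stimuli for amino
acids and insulin switching on at t = 0 (cells are starved beforehand, so all
phospho-states start empty and the gates are constant over the integration
window), plus optional perturbations that scale a protein pool's total amount
at t = 0 — the in-silico counterpart of an inhibitor or knockdown.

Integration uses the stiff-capable LSODA method with an analytic Jacobian,
relative tolerance 1e-6 and absolute tolerance 1e-12.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import ModelSpec

__all__ = ["Protocol", "Trajectory", "simulate", "perturbation_scan",
           "IntegrationError", "SCAN_POOLS"]

RTOL = 1e-6
ATOL = 1e-12
NEGATIVITY_TOL = -1e-6

# perturbable pool groups; "PI3K" scales both wortmannin-sensitive variants
SCAN_POOLS = {
    "mTORC1": ("mTORC1",),
    "mTORC2": ("mTORC2",),
    "AMPK": ("AMPK",),
    "PI3K": ("PI3K_PDK1", "PI3K_var"),
}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces negative amounts."""


@dataclass(frozen=True)
class Protocol:
    """Stimulus levels, perturbations and output grid of one experiment."""

    aa: float = 1.0
    insulin: float = 0.0
    duration: float = 120.0
    output_step: float = 0.1
    perturbations: tuple = ()  # of (pool group name, residual fraction)

    def __post_init__(self):
        if not 0.0 <= self.aa <= 1.0 or not 0.0 <= self.insulin <= 1.0:
            raise ValueError("stimulus levels must be in [0, 1]")
        for pool, frac in self.perturbations:
            if pool not in SCAN_POOLS:
                raise ValueError(f"unknown perturbable pool {pool!r}; "
                                 f"one of {sorted(SCAN_POOLS)}")
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"residual fraction for {pool} must be in (0, 1]")

    def with_perturbation(self, pool, fraction):
        return Protocol(aa=self.aa, insulin=self.insulin, duration=self.duration,
                        output_step=self.output_step,
                        perturbations=self.perturbations + ((pool, fraction),))

    @property
    def time_grid(self):
        n = int(round(self.duration / self.output_step))
        return np.linspace(0.0, self.duration, n + 1)


@dataclass
class Trajectory:
    """Species and observable time courses of one simulated experiment."""

    time: np.ndarray
    species_ids: list
    amounts: np.ndarray  # species x time
    observable_ids: list
    observables: np.ndarray  # observable x time
    protocol: Protocol

    def observable(self, obs_id):
        return self.observables[self.observable_ids.index(obs_id)]

    def species(self, species_id):
        return self.amounts[self.species_ids.index(species_id)]

    def peak(self, obs_id):
        return float(self.observable(obs_id).max())

    def at(self, obs_id, t):
        return float(np.interp(t, self.time, self.observable(obs_id)))

    def to_frame(self):
        """Tidy DataFrame (kind, id, time, value)."""
        import pandas as pd

        rows = []
        for kind, ids, mat in (("species", self.species_ids, self.amounts),
                               ("observable", self.observable_ids, self.observables)):
            for i, name in enumerate(ids):
                rows.append(pd.DataFrame({
                    "kind": kind, "id": name, "time": self.time, "value": mat[i],
                }))
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, observables=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for obs in observables or self.observable_ids:
            ax.plot(self.time, self.observable(obs), label=obs)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("amount (a.u.)")
        ax.legend(fontsize="x-small", ncol=2)
        return ax


class CompiledModel:
    """Index-array compilation of a ModelSpec for fast RHS/Jacobian evaluation.

    Parameter values are supplied per call, so one compiled model serves all
    fits of the same topology.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        self.species_ids = model.species_ids
        self.index = {s: i for i, s in enumerate(self.species_ids)}
        self.n_species = len(self.species_ids)
        self.param_ids = list(model.parameters)
        self._pindex = {p: i for i, p in enumerate(self.param_ids)}
        rxns = model.reactions
        self.n_reactions = len(rxns)
        self.sub = np.array([self.index[r.substrate] for r in rxns])
        self.prod = np.array([self.index[r.product] for r in rxns])
        self.kidx = np.array([self._pindex[r.rate_param] for r in rxns])
        self.gate_kind = np.array(
            [{"none": 0, "aa": 1, "insulin": 2}[r.stimulus_gate] for r in rxns]
        )
        # catalyst incidence matrix C (reactions x species); rows of
        # catalyst-free reactions are zero and replaced by 1 via has_cat mask
        self.cat = np.zeros((self.n_reactions, self.n_species))
        self.has_cat = np.zeros(self.n_reactions, dtype=bool)
        for j, r in enumerate(rxns):
            for c in r.catalyst_pool:
                self.cat[j, self.index[c]] = 1.0
                self.has_cat[j] = True
        # stoichiometry N (species x reactions)
        self.stoich = np.zeros((self.n_species, self.n_reactions))
        for j in range(self.n_reactions):
            self.stoich[self.sub[j], j] -= 1.0
            self.stoich[self.prod[j], j] += 1.0
        # observables
        self.observable_ids = list(model.observables)
        self.obs_matrix = np.zeros((len(self.observable_ids), self.n_species))
        for i, obs in enumerate(self.observable_ids):
            for s in model.observables[obs]:
                self.obs_matrix[i, self.index[s]] = 1.0
        pools = model.pools
        self.pool_names = list(pools)
        self.pool_matrix = np.zeros((len(pools), self.n_species))
        for i, name in enumerate(self.pool_names):
            for s in pools[name]:
                self.pool_matrix[i, self.index[s]] = 1.0

    def param_vector(self, params=None):
        values = self.model.param_values()
        if params:
            values.update(params)
        try:
            return np.array([values[p] for p in self.param_ids])
        except KeyError as exc:
            raise KeyError(f"missing parameter {exc.args[0]!r}")

    def gates(self, protocol: Protocol):
        g = np.ones(self.n_reactions)
        g[self.gate_kind == 1] = protocol.aa
        g[self.gate_kind == 2] = protocol.insulin
        return g

    def rate_constants(self, protocol: Protocol, params=None):
        """Per-reaction effective constants k_r * gate_r (gates are static)."""
        return self.param_vector(params)[self.kidx] * self.gates(protocol)

    def initial_state(self, protocol: Protocol):
        x0 = np.array([s.initial_amount for s in self.model.species], float)
        for pool, frac in protocol.perturbations:
            for name in SCAN_POOLS[pool]:
                for i, s in enumerate(self.model.species):
                    if s.protein == name:
                        x0[i] *= frac
        return x0

    def rates(self, x, kg):
        catsum = self.cat @ x
        catsum[~self.has_cat] = 1.0
        return kg * catsum * x[self.sub]

    def rhs(self, kg):
        def f(t, x):
            return self.stoich @ self.rates(x, kg)
        return f

    def jacobian(self, kg):
        sub = self.sub

        def jac(t, x):
            catsum = self.cat @ x
            catsum[~self.has_cat] = 1.0
            # dv_j/dx_i = kg_j * (catsum_j * [i == sub_j] + x[sub_j] * C_ji)
            dv = (kg * x[sub])[:, None] * self.cat
            dv[np.arange(self.n_reactions), sub] += kg * catsum
            return self.stoich @ dv
        return jac


def simulate(model, protocol: Protocol = None, params=None,
             compiled: CompiledModel = None) -> Trajectory:
    """Integrate the model ODEs under a protocol and return a Trajectory.

    ``params`` optionally overrides parameter values (by id) without
    modifying ``model``; ``compiled`` allows reuse of a compiled topology.
    """
    if protocol is None:
        protocol = Protocol()
    cm = compiled if compiled is not None else CompiledModel(model)
    kg = cm.rate_constants(protocol, params)
    x0 = cm.initial_state(protocol)
    t_eval = protocol.time_grid
    sol = solve_ivp(
        cm.rhs(kg), (0.0, protocol.duration), x0, method="LSODA",
        t_eval=t_eval, jac=cm.jacobian(kg), rtol=RTOL, atol=ATOL,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed ({sol.message}); parameter hash "
            f"{_param_hash(kg)}"
        )
    amounts = sol.y
    if amounts.min() < NEGATIVITY_TOL:
        raise IntegrationError(
            f"negative amounts below tolerance (min {amounts.min():.3e}); "
            f"parameter hash {_param_hash(kg)}"
        )
    return Trajectory(
        time=sol.t,
        species_ids=list(cm.species_ids),
        amounts=amounts,
        observable_ids=list(cm.observable_ids),
        observables=cm.obs_matrix @ amounts,
        protocol=protocol,
    )


def perturbation_scan(model, base_protocol: Protocol, pool,
                      fractions=None, params=None, compiled=None):
    """Simulate graded knockdown of one pool (10%..100% residual by default).

    ``pool`` is one of mTORC1, mTORC2, PI3K (both wortmannin-sensitive PI3K
    variants jointly) or AMPK; each returned Trajectory carries the protocol
    with the corresponding residual fraction.
    """
    if pool not in SCAN_POOLS:
        raise ValueError(f"unknown perturbable pool {pool!r}; one of {sorted(SCAN_POOLS)}")
    if fractions is None:
        fractions = np.round(np.arange(1, 11) * 0.1, 10)
    cm = compiled if compiled is not None else CompiledModel(model)
    return [
        simulate(model, base_protocol.with_perturbation(pool, float(f)),
                 params=params, compiled=cm)
        for f in fractions
    ]


def _param_hash(k):
    return hashlib.sha1(np.asarray(k).tobytes()).hexdigest()[:12]
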