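"""Identifiability analysis: ensemble-correlation flags and profile likelihoods.

Two complementary diagnostics:

* ``mota_flags`` — over the best half of a multi-start ensemble, each
  parameter (in log10) is regressed on small tuples (size <= 5 including the
  target) of the other parameters by greedy forward selection; a tuple is
  flagged as functionally related (hence non-identifiable) when the
  regression r^2 exceeds 0.9 while the target varies substantially across
  the ensemble (coefficient of variation > 15%).
* ``profile_likelihood`` — one parameter is stepped over a log10 grid while
  all others are re-optimized; a parameter is identifiable when both profile
  arms cross chi2_min + 3.84 (95%, 1 df), practically non-identifiable when
  one arm stays flat below the threshold, structurally non-identifiable when
  both do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .estimate import FitConfig, KineticModel

__all__ = ["MotaConfig", "mota_flags", "profile_likelihood",
           "ProfileResult", "IdentifiabilityReport", "DCHI2_95_1DF"]

DCHI2_95_1DF = 3.84  # chi-square 95% quantile, 1 degree of freedom


@dataclass(frozen=True)
class MotaConfig:
    r2_threshold: float = 0.9
    cv_threshold: float = 0.15
    max_tuple_size: int = 5
    best_fraction: float = 0.5


def _r2(y, X):
    """r^2 of an ordinary least-squares fit of y on X (with intercept)."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    return 1.0 - np.sum(resid**2) / ss_tot


def mota_flags(ensemble, config: MotaConfig = None):
    """Flag parameter tuples that co-vary strongly across good fits.

    ``ensemble`` is a FitResults object or a DataFrame of parameter values
    (rows = fits, already sorted best first).  Returns a list of dicts with
    keys ``params`` (target first), ``r2`` and ``cv``.
    """
    config = config or MotaConfig()
    if isinstance(ensemble, pd.DataFrame):
        frame = ensemble
    else:
        frame = ensemble.params_frame()
        frame = frame[ensemble.free_params]
    if len(frame) < 10:
        raise ValueError("MOTA needs an ensemble of at least 10 fits")
    n_best = max(2, int(np.ceil(config.best_fraction * len(frame))))
    top = frame.iloc[:n_best]

    if (top.std(ddof=1) == 0).all():
        warnings.warn("degenerate ensemble (all fits identical); no flags")
        return []

    logs = np.log10(top.to_numpy(float))
    names = list(top.columns)
    cvs = (top.std(ddof=1) / top.mean()).to_dict()

    flags = []
    for ti, target in enumerate(names):
        if not np.isfinite(cvs[target]) or cvs[target] <= config.cv_threshold:
            continue  # the parameter barely moves: identifiable in practice
        y = logs[:, ti]
        if np.std(y) == 0:
            continue
        others = [j for j in range(len(names)) if j != ti]
        chosen = []
        best_r2 = 0.0
        # greedy forward selection up to max_tuple_size - 1 regressors
        while len(chosen) < config.max_tuple_size - 1:
            best_j, best_gain_r2 = None, best_r2
            for j in others:
                if j in chosen:
                    continue
                r2 = _r2(y, logs[:, chosen + [j]])
                if r2 > best_gain_r2 + 1e-12:
                    best_j, best_gain_r2 = j, r2
            if best_j is None:
                break
            chosen.append(best_j)
            best_r2 = best_gain_r2
            if best_r2 > config.r2_threshold:
                break
        if best_r2 > config.r2_threshold and chosen:
            flags.append({
                "params": tuple([target] + [names[j] for j in chosen]),
                "r2": float(best_r2),
                "cv": float(cvs[target]),
            })
    return flags


@dataclass
class ProfileResult:
    param: str
    grid: np.ndarray  # parameter values (linear scale)
    chi2: np.ndarray  # re-optimized chi2 per grid point (NaN = failed step)
    chi2_min: float
    classification: str
    threshold: float = DCHI2_95_1DF

    def to_frame(self):
        return pd.DataFrame({"value": self.grid, "chi2": self.chi2})


def profile_likelihood(model, dataset, best_params, param, n_steps=21,
                       span=2.0, fit_config: FitConfig = None) -> ProfileResult:
    """Profile the chi2 of one parameter over +-``span`` log10 decades."""
    if param not in model.parameters:
        raise KeyError(f"unknown parameter {param!r}")
    fit_config = fit_config or FitConfig()
    center = np.log10(best_params[param])
    lo, hi = (np.log10(model.parameters[param][i]) for i in (1, 2))
    grid_log = np.clip(np.linspace(center - span, center + span, n_steps), lo, hi)
    # keep the exact center on the grid so the profile nests the optimum
    grid_log[np.argmin(np.abs(grid_log - center))] = center

    km = KineticModel(model, dataset)
    chi2s = np.full(n_steps, np.nan)
    current = dict(best_params)
    for i, g in enumerate(grid_log):
        value = 10.0 ** g
        fc = dc_replace(
            fit_config,
            n_starts=1,
            frozen=tuple({**fit_config.frozen_map(), param: value}.items()),
            center=tuple({**current, param: value}.items()),
        )
        try:
            res = km.fit(fc)
            chi2s[i] = res.chi2
            current = res.params
        except RuntimeError:
            continue  # failed step recorded as missing point
    chi2_min = float(np.nanmin(chi2s))
    threshold = chi2_min + DCHI2_95_1DF
    center_idx = int(np.argmin(np.abs(grid_log - center)))
    left = chi2s[: center_idx + 1]
    right = chi2s[center_idx:]
    left_crosses = bool(np.nanmax(left) > threshold) if np.isfinite(left).any() else False
    right_crosses = bool(np.nanmax(right) > threshold) if np.isfinite(right).any() else False
    if left_crosses and right_crosses:
        cls = "identifiable"
    elif left_crosses or right_crosses:
        cls = "practically non-identifiable"
    else:
        cls = "structurally non-identifiable"
    return ProfileResult(
        param=param,
        grid=10.0 ** grid_log,
        chi2=chi2s,
        chi2_min=chi2_min,
        classification=cls,
    )


@dataclass
class IdentifiabilityReport:
    """Per-parameter classification plus the flagged co-varying tuples."""

    classes: dict  # param -> classification string
    flags: list = field(default_factory=list)
    profiles: dict = field(default_factory=dict)  # param -> ProfileResult

    def summary(self):
        lines = ["Identifiability report", "=" * 50]
        for p in sorted(self.classes):
            lines.append(f"{p:<34}{self.classes[p]}")
        if self.flags:
            lines.append("-" * 50)
            lines.append("co-varying tuples (r2 > 0.9, CV > 15%):")
            for fl in self.flags:
                lines.append(
                    f"  {' ~ '.join(fl['params'])}  r2={fl['r2']:.3f} cv={fl['cv']:.2f}"
                )
        return "\n".join(lines)

    def to_json(self):
        import json

        return json.dumps({
            "classes": self.classes,
            "flags": [
                {"params": list(f["params"]), "r2": f["r2"], "cv": f["cv"]}
                for f in self.flags
            ],
        }, indent=2, sort_keys=True)
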