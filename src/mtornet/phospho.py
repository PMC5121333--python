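"""Post-MaxQuant SILAC ratio pipeline: bridged ratios, centering, volcano filter.

Each triple-SILAC experiment measures three time points in its L/M/H
channels; the 30 min point is present in every experiment and serves as a
bridge for cross-experiment normalization.  For a stimulated time point
t in {5, 10, 15} min the pipeline forms all ordered cross-experiment
combinations

    ratio(t; i, j) = (I[t, exp_i] / I[30, exp_i]) / (I[0, exp_j] / I[30, exp_j])

over experiments i containing t and experiments j containing 0 min — nine
combinations for 5 min (3 x 3 experiments) and six for 10 and 15 min (2 x 3).
Log2 ratios are median-centered per ratio column, and sites with at least two
finite ratios at a time point are tested with a two-sided one-sample t-test
against 0.  A site is regulated at a fold-change cutoff if |mean log2 ratio|
>= log2(cutoff) and p < 0.05 (no multiple-testing correction) at one or more
time points.  Zero intensities are treated as missing; localization
probability must exceed 0.75 (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignSpec", "compute_ratios", "median_center", "localization_filter",
    "volcano_filter", "VolcanoAnalysis", "VolcanoResult",
    "read_sites_table", "LOCALIZATION_CUTOFF",
]

LOCALIZATION_CUTOFF = 0.75
STIM_TIMES = (5, 10, 15)


@dataclass(frozen=True)
class DesignSpec:
    """Channel -> time point layout of each experiment, plus the bridge."""

    experiments: dict  # experiment -> {channel: time point (min)}
    bridge_time: int = 30

    def __post_init__(self):
        for exp, channels in self.experiments.items():
            bad = set(channels) - {"L", "M", "H"}
            if bad:
                raise ValueError(f"{exp}: unknown channel(s) {sorted(bad)}")
            if self.bridge_time not in channels.values():
                raise ValueError(
                    f"{exp}: bridge time point {self.bridge_time} missing "
                    "(required for cross-experiment normalization)"
                )

    def experiments_with(self, time_point):
        return sorted(
            e for e, ch in self.experiments.items() if time_point in ch.values()
        )

    def channel_of(self, experiment, time_point):
        for ch, t in self.experiments[experiment].items():
            if t == time_point:
                return ch
        raise KeyError(f"{experiment} has no channel at {time_point} min")

    def intensity_column(self, experiment, time_point):
        return f"Intensity {self.channel_of(experiment, time_point)} {experiment}"

    def n_ratio_combinations(self, time_point):
        return len(self.experiments_with(time_point)) * len(self.experiments_with(0))


def read_sites_table(path, sep="\t"):
    """Read a MaxQuant 'Phospho (STY)Sites'-dialect table."""
    table = pd.read_csv(path, sep=sep)
    if "Localization prob" not in table.columns:
        raise ValueError("table lacks a 'Localization prob' column")
    return table


def localization_filter(table, cutoff=LOCALIZATION_CUTOFF):
    """Retain sites whose localization probability strictly exceeds the cutoff.

    The original row index is preserved so that site identity survives
    filtering.
    """
    return table[table["Localization prob"] > cutoff]


def _intensity(table, design, experiment, time_point):
    col = design.intensity_column(experiment, time_point)
    if col not in table.columns:
        raise KeyError(f"missing intensity column {col!r}")
    vals = table[col].to_numpy(float).copy()
    vals[vals <= 0] = np.nan  # zero intensity means not quantified
    return vals


def compute_ratios(table, design: DesignSpec, time_point):
    """Per-site log2 bridged-ratio matrix at one stimulated time point.

    Returns a DataFrame with one column per (experiment_t, experiment_0)
    combination; entries with any missing term are NaN.
    """
    if time_point not in STIM_TIMES:
        raise ValueError(f"time point must be one of {STIM_TIMES}")
    exps_t = design.experiments_with(time_point)
    exps_0 = design.experiments_with(0)
    cols = {}
    for ei in exps_t:
        it = _intensity(table, design, ei, time_point)
        bi = _intensity(table, design, ei, design.bridge_time)
        if np.all(np.isnan(bi)):
            warnings.warn(f"{ei}: bridge intensities all missing; combinations dropped")
            continue
        for ej in exps_0:
            i0 = _intensity(table, design, ej, 0)
            bj = _intensity(table, design, ej, design.bridge_time)
            cols[f"{ei}/{ej}"] = np.log2((it / bi) / (i0 / bj))
    return pd.DataFrame(cols, index=table.index)


def median_center(ratio_columns):
    """Subtract the per-column median (over sites) from each log2 ratio column."""
    out = ratio_columns.copy()
    for col in out.columns:
        finite = out[col].dropna()
        if finite.empty:
            warnings.warn(f"ratio column {col} is empty; left uncentered")
            continue
        out[col] = out[col] - finite.median()
    return out


def _one_sample_t(values):
    """Two-sided one-sample t-test of log2 ratios against 0.

    A zero-variance vector leaves t undefined; such a site passes the p-gate
    iff its mean differs from 0 (documented convention).
    """
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        return np.nan, np.nan, n
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        return mean, 0.0 if mean != 0 else 1.0, n
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return mean, p, n


def volcano_records(table, design, center=True, site_ids=None):
    """Long-format per-site, per-time-point test results."""
    if site_ids is None:
        site_ids = table.index.to_numpy()
    rows = []
    for t in STIM_TIMES:
        ratios = compute_ratios(table, design, t)
        if center:
            ratios = median_center(ratios)
        mat = ratios.to_numpy(float)
        for i, sid in enumerate(site_ids):
            mean, p, n = _one_sample_t(mat[i])
            rows.append({
                "site": sid, "time": t, "n_ratios": n,
                "mean_log2fc": mean, "fold_change": 2.0 ** mean if np.isfinite(mean) else np.nan,
                "p_value": p,
            })
    return pd.DataFrame(rows)


def volcano_filter(records, fc_cutoff=2.0, p_cutoff=0.05):
    """Sites regulated at >=1 time point under the fold-change/p-value gates."""
    if fc_cutoff <= 1:
        raise ValueError("fold-change cutoff must exceed 1")
    if not 0 < p_cutoff < 1:
        raise ValueError("p-value cutoff must lie in (0, 1)")
    ok = (
        (records["n_ratios"] >= 2)
        & (records["mean_log2fc"].abs() >= np.log2(fc_cutoff))
        & (records["p_value"] < p_cutoff)
    )
    return set(records.loc[ok, "site"])


@dataclass
class VolcanoResult:
    """Per-site volcano statistics and regulated flags at both cutoffs."""

    records: pd.DataFrame
    regulated_1_5: set
    regulated_2_0: set
    n_sites_tested: int
    n_sites_input: int

    def regulated(self, fc_cutoff):
        if abs(fc_cutoff - 1.5) < 1e-9:
            return self.regulated_1_5
        if abs(fc_cutoff - 2.0) < 1e-9:
            return self.regulated_2_0
        return volcano_filter(self.records, fc_cutoff)

    def summary(self):
        return "\n".join([
            "SILAC bridged-ratio volcano analysis",
            "=" * 44,
            f"sites in table:          {self.n_sites_input}",
            f"localized (prob > 0.75): {self.n_sites_tested}",
            f"regulated at 1.5x FC:    {len(self.regulated_1_5)}",
            f"regulated at 2.0x FC:    {len(self.regulated_2_0)}",
        ])

    def to_frame(self):
        rec = self.records.copy()
        rec["regulated_1.5"] = rec["site"].isin(self.regulated_1_5)
        rec["regulated_2.0"] = rec["site"].isin(self.regulated_2_0)
        return rec

    def plot(self, time_point=5, fc_cutoff=2.0, p_cutoff=0.05, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.records[self.records["time"] == time_point].dropna()
        ax.scatter(sub["mean_log2fc"], -np.log10(sub["p_value"]),
                   s=8, c="grey", alpha=0.6)
        ax.axhline(-np.log10(p_cutoff), ls="--", lw=0.8, c="k")
        for x in (np.log2(fc_cutoff), -np.log2(fc_cutoff)):
            ax.axvline(x, ls="--", lw=0.8, c="k")
        ax.set_xlabel("mean log2 ratio")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"{time_point} min vs 0 min")
        return ax


class VolcanoAnalysis:
    """Model-style wrapper: table + design in, VolcanoResult out via fit()."""

    def __init__(self, table, design: DesignSpec, site_column=None):
        self.table = table
        self.design = design
        self.site_column = site_column

    def fit(self, center=True, p_cutoff=0.05) -> VolcanoResult:
        localized = localization_filter(self.table)
        if self.site_column is not None:
            site_ids = localized[self.site_column].to_numpy()
        else:
            site_ids = localized.index.to_numpy()
        records = volcano_records(localized, self.design, center=center,
                                  site_ids=site_ids)
        return VolcanoResult(
            records=records,
            regulated_1_5=volcano_filter(records, 1.5, p_cutoff),
            regulated_2_0=volcano_filter(records, 2.0, p_cutoff),
            n_sites_tested=len(localized),
            n_sites_input=len(self.table),
        )
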