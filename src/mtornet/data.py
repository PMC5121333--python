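"""Time-course dataset container: the fitting target.

A :class:`Dataset` holds quantified readout values (observable, condition,
time, replicate, value) — the shape of densitometry-quantified immunoblot
time courses — together with the stimulation :class:`~mtornet.simulate.Protocol`
of each condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Dataset", "COLUMNS"]

COLUMNS = ["observable", "condition", "time", "replicate", "value"]


@dataclass
class Dataset:
    table: pd.DataFrame
    conditions: dict  # condition id -> Protocol

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset table lacks column(s) {missing}")
        self.table = (
            self.table[COLUMNS]
            .astype({"time": float, "replicate": int, "value": float})
            .reset_index(drop=True)
        )
        if (self.table["value"] < 0).any():
            raise ValueError("dataset contains negative readout values")
        unknown = set(self.table["condition"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"conditions without a protocol: {sorted(unknown)}")

    @property
    def n_points(self):
        return len(self.table)

    @property
    def observables(self):
        return sorted(self.table["observable"].unique())

    def validate_against(self, model):
        unknown = set(self.table["observable"]) - set(model.observables)
        if unknown:
            raise ValueError(
                f"observables not defined by the model: {sorted(unknown)}"
            )

    def observable_max(self):
        """Per-observable maximum value (basis of the sigma floor)."""
        return self.table.groupby("observable")["value"].max().to_dict()

    def to_tsv(self, path):
        # 17 significant digits: lossless float64 text round-trip
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, conditions):
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls(table=table, conditions=conditions)
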