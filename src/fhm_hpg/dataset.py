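"""Observation datasets: per-fish physiology and plasma endpoints.

The CSV schema is ``fish_id, group, scenario_id, time_hr, bw_kg, gsi_pct,
hsi_pct, e2_ng_ml, t_ng_ml, vtg_mg_ml`` with empty cells for missing
values.  Groups name the exposure class (unexposed / TB / EE2) used to
index the grouped error variances.  Missing physiology is filled with the
medians of the measured values, the same convention the calibration and
prediction machinery assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import ExposureScenario
from .parameters import Physiology

__all__ = ["GROUPS", "ENDPOINTS", "DATASET_COLUMNS", "Dataset"]

GROUPS = ("unexposed", "TB", "EE2")
ENDPOINTS = ("E2", "T", "VTG")
ENDPOINT_TO_COLUMN = {"E2": "e2_ng_ml", "T": "t_ng_ml", "VTG": "vtg_mg_ml"}
DATASET_COLUMNS = ["fish_id", "group", "scenario_id", "time_hr", "bw_kg",
                   "gsi_pct", "hsi_pct", "e2_ng_ml", "t_ng_ml", "vtg_mg_ml"]
_PHYS_COLS = ("bw_kg", "gsi_pct", "hsi_pct")


@dataclass
class Dataset:
    """Endpoint observations plus the exposure scenario of each group."""

    records: pd.DataFrame
    scenarios: dict = field(default_factory=dict)   # scenario_id -> scenario

    def __post_init__(self):
        df = self.records
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown exposure groups: {sorted(bad_groups)}")
        endpoint_cols = list(ENDPOINT_TO_COLUMN.values())
        if len(df):        # an empty dataset is allowed (prior-only runs)
            if df[endpoint_cols].isna().all(axis=1).any():
                raise ValueError("every record needs at least one endpoint")
            vals = df[endpoint_cols].to_numpy(dtype=float)
            if not np.all(np.isnan(vals) | (vals > 0)):
                raise ValueError("endpoint measurements must be positive")
        unknown = set(df["scenario_id"]) - set(self.scenarios)
        if unknown:
            raise ValueError(f"records reference unknown scenarios: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    def physiology_medians(self) -> dict:
        """Medians of the measured physiology fields."""
        med = self.records[list(_PHYS_COLS)].median(skipna=True)
        return {c: float(med[c]) for c in _PHYS_COLS}

    def fill_physiology(self) -> pd.DataFrame:
        """Records with missing BW/GSI/HSI replaced by the medians."""
        df = self.records.copy()
        med = self.physiology_medians()
        for c in _PHYS_COLS:
            fallback = med[c]
            if np.isnan(fallback):   # nothing measured at all: population medians
                fallback = {"bw_kg": 0.0016, "gsi_pct": 11.0, "hsi_pct": 3.0}[c]
            df[c] = df[c].fillna(fallback)
        return df

    def group_physiology(self, group: str) -> Physiology:
        """Median physiology of one exposure group (median fill-in)."""
        df = self.fill_physiology()
        sub = df[df["group"] == group]
        if sub.empty:
            return Physiology()
        return Physiology(body_weight=float(sub["bw_kg"].median()),
                          gsi=float(sub["gsi_pct"].median()),
                          hsi=float(sub["hsi_pct"].median()))

    def scenario_for(self, scenario_id: str) -> ExposureScenario:
        return self.scenarios[scenario_id]

    def to_csv(self, path) -> None:
        self.records[DATASET_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scenarios: dict) -> "Dataset":
        return cls(pd.read_csv(path), scenarios)
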