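"""Event-table container and CSV serialization.

A cytometry sample is a table of per-event measurements: forward-scatter
area (``fsc_area``), side-scatter height (``ssc_height``), and one or two
fluorescence areas (``fl1_area``, ``fl2_area``), all in arbitrary units,
plus sample-level metadata (inducer condition, replicate, control flag).

The on-disk format is plain CSV with the fixed header::

    sample_id,condition_atc_nM,condition_iptg_uM,replicate,is_control,
    fsc_area,ssc_height,fl1_area[,fl2_area]

Metadata columns are repeated per row so that concatenated files remain
self-describing. FCS export from an instrument should be converted to this
CSV layout (one file per sample) before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

MEASUREMENT_COLUMNS = ("fsc_area", "ssc_height", "fl1_area", "fl2_area")
METADATA_COLUMNS = (
    "sample_id",
    "condition_atc_nM",
    "condition_iptg_uM",
    "replicate",
    "is_control",
)


@dataclass
class EventTable:
    """Per-event cytometry measurements for one sample.

    Parameters
    ----------
    data
        DataFrame with columns ``fsc_area``, ``ssc_height``, ``fl1_area``
        and optionally ``fl2_area``; all finite, no missing values.
    sample_id, condition_atc_nM, condition_iptg_uM, replicate, is_control
        Sample-level metadata. ``is_control`` marks autofluorescence-only
        (no fluorescent protein) control samples.
    is_debris
        Optional per-event boolean array marking simulated debris events.
        Ground-truth bookkeeping only; never serialized.
    """

    data: pd.DataFrame
    sample_id: str = "sample"
    condition_atc_nM: float = 0.0
    condition_iptg_uM: float = 0.0
    replicate: int = 1
    is_control: bool = False
    is_debris: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("fsc_area", "ssc_height", "fl1_area") if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing required columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("event table must contain at least one event")
        meas = [c for c in MEASUREMENT_COLUMNS if c in self.data.columns]
        values = self.data[meas].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("event table contains non-finite measurements")
        if self.is_debris is not None and len(self.is_debris) != len(self.data):
            raise ValueError("is_debris length does not match event count")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def has_fl2(self) -> bool:
        return "fl2_area" in self.data.columns

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def subset(self, keep: np.ndarray) -> "EventTable":
        """Row-subset (e.g. gated events); preserves metadata."""
        keep = np.asarray(keep)
        return replace(
            self,
            data=self.data.loc[keep].reset_index(drop=True),
            is_debris=None if self.is_debris is None else self.is_debris[keep],
        )


def write_events_csv(table: EventTable, path: str | Path) -> None:
    """Write one sample to CSV with the fixed column order."""
    out = pd.DataFrame(
        {
            "sample_id": table.sample_id,
            "condition_atc_nM": table.condition_atc_nM,
            "condition_iptg_uM": table.condition_iptg_uM,
            "replicate": table.replicate,
            "is_control": table.is_control,
            "fsc_area": table.data["fsc_area"].to_numpy(),
            "ssc_height": table.data["ssc_height"].to_numpy(),
            "fl1_area": table.data["fl1_area"].to_numpy(),
        }
    )
    if table.has_fl2:
        out["fl2_area"] = table.data["fl2_area"].to_numpy()
    out.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> EventTable:
    """Read one sample from CSV written by :func:`write_events_csv`."""
    raw = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    sample_ids = raw["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError(f"{path}: expected a single sample per file, found {list(sample_ids)}")
    meas_cols = [c for c in MEASUREMENT_COLUMNS if c in raw.columns]
    first = raw.iloc[0]
    return EventTable(
        data=raw[meas_cols].reset_index(drop=True),
        sample_id=str(first["sample_id"]),
        condition_atc_nM=float(first["condition_atc_nM"]),
        condition_iptg_uM=float(first["condition_iptg_uM"]),
        replicate=int(first["replicate"]),
        is_control=bool(first["is_control"]),
    )
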