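"""Density gating on the 2D scatter histogram.

Cytometry samples contain debris and atypically sized cells. The standard
remedy is a density gate: bin events on (log FSC-area, log SSC-height),
smooth the 2D histogram, and retain the fixed fraction of events whose bins
lie nearest the histogram mode. Retaining one third of events around the
scatter mode selects typical-size cells and modestly reduces measured
fluorescence noise.

The retained count is exact: bins are admitted whole in decreasing smoothed
density until the next bin would overshoot ``round(f * n)``; inside that one
boundary bin, events are admitted in ascending row order until the count
matches. Events with non-positive scatter go to an underflow class and are
never retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from duotune.io import EventTable

__all__ = ["GateResult", "density_gate"]


@dataclass
class GateResult:
    """Outcome of a density gate: per-event retain flags plus diagnostics."""

    retain: np.ndarray  # bool, per event
    retained_fraction: float
    params: dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def n_retained(self) -> int:
        return int(self.retain.sum())


def density_gate(
    events: Union[EventTable, pd.DataFrame],
    target_fraction: float = 1.0 / 3.0,
    bins: int = 64,
    smooth_sigma: float = 1.0,
) -> GateResult:
    """Retain the ``target_fraction`` of events in the densest scatter bins.

    Binning is 64x64 by default, equal width in log10 of each scatter channel
    over the central 99.9% range of the positive values; the histogram is
    Gaussian-smoothed (sigma in bins) before ranking. Out-of-range positive
    events are clipped into the edge bins.

    A degenerate sample (all events in one bin) retains the first
    ``round(f * n)`` events and flags the result.
    """
    data = events.data if isinstance(events, EventTable) else events
    fsc = np.asarray(data["fsc_area"], dtype=float)
    ssc = np.asarray(data["ssc_height"], dtype=float)
    n = len(fsc)
    if n < 2:
        raise ValueError(f"density gate needs >= 2 events, got {n}")
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError(f"target_fraction must be in (0, 1], got {target_fraction}")
    if bins < 2:
        raise ValueError("bins must be >= 2")

    target = int(np.rint(target_fraction * n))
    params = {
        "target_fraction": target_fraction,
        "bins": bins,
        "smooth_sigma": smooth_sigma,
        "target_count": target,
    }
    retain = np.zeros(n, dtype=bool)
    if target == 0:
        return GateResult(retain=retain, retained_fraction=0.0, params=params)

    positive = (fsc > 0) & (ssc > 0)
    pos_idx = np.flatnonzero(positive)
    if len(pos_idx) <= target:
        # not enough gateable events for the requested fraction: keep all
        # positive-scatter events and flag
        retain[pos_idx] = True
        return GateResult(
            retain=retain,
            retained_fraction=retain.sum() / n,
            params=params,
            degenerate=True,
        )

    lf = np.log10(fsc[pos_idx])
    ls = np.log10(ssc[pos_idx])
    ix = _bin_index(lf, bins)
    iy = _bin_index(ls, bins)
    flat = ix * bins + iy

    hist = np.bincount(flat, minlength=bins * bins).reshape(bins, bins).astype(float)
    occupied = int((hist > 0).sum())
    if occupied == 1:
        retain[:target] = True
        return GateResult(
            retain=retain,
            retained_fraction=target / n,
            params=params,
            degenerate=True,
        )

    smoothed = gaussian_filter(hist, sigma=smooth_sigma, mode="constant").ravel()
    counts = np.bincount(flat, minlength=bins * bins)

    # bins in decreasing smoothed density; ties broken by flat index for
    # order stability
    order = np.lexsort((np.arange(bins * bins), -smoothed))
    kept = 0
    keep_bin = np.zeros(bins * bins, dtype=bool)
    boundary = -1
    for b in order:
        c = int(counts[b])
        if c == 0:
            continue
        if kept + c <= target:
            keep_bin[b] = True
            kept += c
            if kept == target:
                break
        else:
            boundary = b
            break

    retain[pos_idx[keep_bin[flat]]] = True
    if boundary >= 0 and kept < target:
        need = target - kept
        in_boundary = pos_idx[flat == boundary]  # ascending row order
        retain[in_boundary[:need]] = True

    return GateResult(retain=retain, retained_fraction=int(retain.sum()) / n, params=params)


def _bin_index(values: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = np.quantile(values, [0.0005, 0.9995])
    if hi <= lo:
        return np.zeros(len(values), dtype=np.int64)
    idx = np.floor((values - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)
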