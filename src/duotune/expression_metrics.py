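"""Sample-level expression summaries: background-subtracted mean, CV^2,
dose response, backbone comparison, and two-channel independence.

Noise is the coefficient of variation squared, CV^2 = sigma^2 / mu^2, with
mu and sigma^2 taken from the gamma fit of the gated fluorescence
distribution. The mean autofluorescence of a control strain carrying a
similar, fluorophore-free plasmid is subtracted from the fitted mean; CV^2
divides the fitted variance by the background-subtracted mean squared and
is flagged undefined when that mean is non-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from duotune.density_fit import GammaFit, fit_values
from duotune.flow_gating import GateResult
from duotune.io import EventTable

__all__ = [
    "SampleSummary",
    "DoseResponseSummary",
    "BackboneComparison",
    "CrosstalkSummary",
    "summarize_sample",
    "summaries_to_frame",
    "compute_cv2",
    "dose_response",
    "compare_backbones",
    "crosstalk",
]


@dataclass
class SampleSummary:
    """Background-subtracted mean and CV^2 for one sample/one condition."""

    sample_id: str
    condition_atc_nM: float
    condition_iptg_uM: float
    replicate: int
    mean_raw: float
    control_mean: float
    mean_bgsub: float
    variance: float
    cv2: float  # NaN when undefined
    cv2_defined: bool
    n_gated: int
    fit: Optional[GammaFit] = field(default=None, repr=False)

    @property
    def fit_converged(self) -> bool:
        return self.fit.converged if self.fit is not None else True


def compute_cv2(mean: float, variance: float) -> float:
    """CV^2 = variance / mean^2; NaN (undefined) for mean <= 0."""
    if mean <= 0:
        return math.nan
    return variance / mean**2


def summarize_sample(
    events: EventTable,
    control_mean: float,
    gate: Optional[GateResult] = None,
    n_bins: int = 48,
    column: str = "fl1_area",
) -> SampleSummary:
    """Gate -> log-bin -> gamma fit -> subtract control mean -> CV^2.

    ``gate`` must have been computed on these events; ``None`` means the
    table is already gated (all events used). ``control_mean`` is the mean
    fluorescence of the autofluorescence-only control.
    """
    if control_mean < 0:
        raise ValueError("control_mean must be >= 0")
    values = events.column(column)
    if gate is not None:
        if len(gate.retain) != events.n_events:
            raise ValueError("gate was not computed on this event table")
        values = values[gate.retain]
    fit = fit_values(values, n_bins=n_bins)
    mean_raw = fit.mu
    variance = fit.sigma2
    mean_bgsub = mean_raw - control_mean
    cv2 = compute_cv2(mean_bgsub, variance)
    return SampleSummary(
        sample_id=events.sample_id,
        condition_atc_nM=events.condition_atc_nM,
        condition_iptg_uM=events.condition_iptg_uM,
        replicate=events.replicate,
        mean_raw=mean_raw,
        control_mean=control_mean,
        mean_bgsub=mean_bgsub,
        variance=variance,
        cv2=cv2,
        cv2_defined=bool(np.isfinite(cv2)),
        n_gated=len(values),
        fit=fit,
    )


def summaries_to_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "condition_atc_nM": s.condition_atc_nM,
            "condition_iptg_uM": s.condition_iptg_uM,
            "replicate": s.replicate,
            "mean_raw": s.mean_raw,
            "control_mean": s.control_mean,
            "mean_bgsub": s.mean_bgsub,
            "variance": s.variance,
            "cv2": s.cv2,
            "cv2_defined": s.cv2_defined,
            "n_gated": s.n_gated,
            "fit_converged": s.fit_converged,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def _inducer_axis(summaries: Sequence[SampleSummary], inducer: str) -> str:
    if inducer in ("atc", "iptg"):
        return inducer
    atc = {s.condition_atc_nM for s in summaries}
    iptg = {s.condition_iptg_uM for s in summaries}
    if len(atc) > 1 and len(iptg) > 1:
        raise ValueError("both inducers vary; specify inducer='atc' or 'iptg'")
    return "atc" if len(atc) > 1 else "iptg"


def _level(s: SampleSummary, axis: str) -> float:
    return s.condition_atc_nM if axis == "atc" else s.condition_iptg_uM


@dataclass
class DoseResponseSummary:
    """Replicate-averaged (inducer, mean, CV^2) triples plus range/shape."""

    inducer_axis: str  # "atc" (nM) or "iptg" (uM)
    table: pd.DataFrame  # inducer, mean_bgsub, cv2, sem_mean, sem_cv2, n_replicates
    dynamic_range: float  # max/min mean over nonzero-inducer conditions
    monotone: bool
    zero_inducer_mean: float = math.nan  # reported separately


def dose_response(
    summaries: Sequence[SampleSummary], inducer: str = "auto"
) -> DoseResponseSummary:
    """Average replicates per inducer level and summarize the dose response.

    The zero-inducer condition is reported separately and excluded from the
    dynamic range (it sits below the tunable range on a log axis).
    """
    if len(summaries) == 0:
        raise ValueError("dose response needs at least one sample summary")
    axis = _inducer_axis(summaries, inducer)
    seen = set()
    for s in summaries:
        key = (_level(s, axis), s.replicate)
        if key in seen:
            raise ValueError(f"duplicate (inducer, replicate) pair {key}")
        seen.add(key)

    levels = sorted({_level(s, axis) for s in summaries})
    rows = []
    for lvl in levels:
        grp = [s for s in summaries if _level(s, axis) == lvl]
        means = np.array([s.mean_bgsub for s in grp])
        cv2s = np.array([s.cv2 for s in grp])
        r = len(grp)
        rows.append(
            {
                "inducer": lvl,
                "mean_bgsub": means.mean(),
                "cv2": float(np.nanmean(cv2s)),
                "sem_mean": means.std(ddof=1) / math.sqrt(r) if r > 1 else math.nan,
                "sem_cv2": float(np.nanstd(cv2s, ddof=1) / math.sqrt(r)) if r > 1 else math.nan,
                "n_replicates": r,
            }
        )
    table = pd.DataFrame(rows).sort_values("inducer").reset_index(drop=True)

    nonzero = table[table["inducer"] > 0]
    span = nonzero if len(nonzero) else table
    dynamic_range = float(span["mean_bgsub"].max() / span["mean_bgsub"].min()) if len(span) > 1 else 1.0
    zero_mean = float(table.loc[table["inducer"] == 0, "mean_bgsub"].iloc[0]) if (table["inducer"] == 0).any() else math.nan
    monotone = bool(np.all(np.diff(table["mean_bgsub"].to_numpy()) >= 0))
    return DoseResponseSummary(
        inducer_axis=axis,
        table=table,
        dynamic_range=dynamic_range,
        monotone=monotone,
        zero_inducer_mean=zero_mean,
    )


@dataclass
class BackboneComparison:
    """Percent drop in mean expression between matched conditions."""

    percent_drop: float
    sem: float
    per_condition: pd.DataFrame  # condition, mean_high, mean_low, percent_drop


def compare_backbones(
    high: Sequence[SampleSummary], low: Sequence[SampleSummary]
) -> BackboneComparison:
    """Drop = 100 * (1 - mean_low / mean_high) averaged over matched conditions.

    Conditions are matched on the (ATc, IPTG) pair after averaging
    replicates within each arm; unmatched conditions are an error.
    """
    if not high or not low:
        raise ValueError("both sample lists must be nonempty")

    def by_condition(summaries):
        out: dict[tuple[float, float], list[float]] = {}
        for s in summaries:
            out.setdefault((s.condition_atc_nM, s.condition_iptg_uM), []).append(s.mean_bgsub)
        return {k: float(np.mean(v)) for k, v in out.items()}

    mh, ml = by_condition(high), by_condition(low)
    if set(mh) != set(ml):
        raise ValueError(
            f"unmatched conditions: high-only {sorted(set(mh) - set(ml))}, "
            f"low-only {sorted(set(ml) - set(mh))}"
        )
    rows = []
    for cond in sorted(mh):
        h, lo = mh[cond], ml[cond]
        drop = 100.0 * (1.0 - lo / h) if h != 0 else math.nan
        rows.append(
            {
                "condition_atc_nM": cond[0],
                "condition_iptg_uM": cond[1],
                "mean_high": h,
                "mean_low": lo,
                "percent_drop": drop,
            }
        )
    per = pd.DataFrame(rows)
    drops = per["percent_drop"].to_numpy()
    sem = float(np.nanstd(drops, ddof=1) / math.sqrt(len(drops))) if len(drops) > 1 else math.nan
    return BackboneComparison(
        percent_drop=float(np.nanmean(drops)), sem=sem, per_condition=per
    )


@dataclass
class CrosstalkSummary:
    """Per-channel sensitivity of mean expression to the *other* inducer.

    For each channel and each level of its own inducer, the relative span
    (max - min) of the background-subtracted mean across the other
    inducer's levels, normalized by the mean at the lowest other-inducer
    level (the channel's baseline), is computed; the channel metric is the
    worst (max) such span. Doubling a channel's mean at the high level of
    the other inducer therefore scores exactly 1. Channels are independent
    when all metrics fall below tolerance.
    """

    per_channel: dict[str, float]
    tolerance: float
    independent: bool


def crosstalk(
    channel_summaries: Mapping[str, Sequence[SampleSummary]],
    own_axis: Optional[Mapping[str, str]] = None,
    tolerance: float = 0.05,
) -> CrosstalkSummary:
    """Quantify inducer independence on a complete (ATc x IPTG) grid.

    ``channel_summaries`` maps channel name -> summaries over the full
    factorial grid; ``own_axis`` maps channel name -> "atc" or "iptg" (the
    inducer that *should* drive it). Defaults to fl1->atc, fl2->iptg (the
    GFP/ATc and RFP/IPTG pairing).
    """
    if own_axis is None:
        own_axis = {"fl1": "atc", "fl2": "iptg"}
    per_channel: dict[str, float] = {}
    for name, summaries in channel_summaries.items():
        if name not in own_axis:
            raise ValueError(f"no own-inducer axis declared for channel {name!r}")
        axis = own_axis[name]
        other = "iptg" if axis == "atc" else "atc"
        own_levels = sorted({_level(s, axis) for s in summaries})
        other_levels = sorted({_level(s, other) for s in summaries})
        if len(own_levels) < 2 or len(other_levels) < 2:
            raise ValueError(f"channel {name!r}: need >= 2 levels of each inducer")
        cell_means: dict[tuple[float, float], list[float]] = {}
        for s in summaries:
            cell_means.setdefault((_level(s, axis), _level(s, other)), []).append(s.mean_bgsub)
        missing = [
            (a, b) for a in own_levels for b in other_levels if (a, b) not in cell_means
        ]
        if missing:
            raise ValueError(f"channel {name!r}: incomplete grid, missing cells {missing}")
        worst = 0.0
        for a in own_levels:
            means = np.array([np.mean(cell_means[(a, b)]) for b in other_levels])
            baseline = means[0]  # lowest other-inducer level
            span = float((means.max() - means.min()) / baseline)
            worst = max(worst, span)
        per_channel[name] = worst
    independent = all(v <= tolerance for v in per_channel.values())
    return CrosstalkSummary(
        per_channel=per_channel, tolerance=tolerance, independent=independent
    )
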