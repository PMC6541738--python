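"""Parametric model of bicistronic repressor circuits and cytometry measurement.

The circuit couples a repressor (TetR- or LacI-style) and a reporter on one
mRNA transcribed from a promoter the repressor itself represses. Inducer
(ATc for TetR, IPTG for LacI) inactivates the repressor. Two regulatory modes
are supported:

* ``autoregulated`` — the repressor is co-translated with the reporter, so
  reporter output feeds back on its own promoter. Negative feedback gives
  dosage compensation: mean expression scales sub-proportionally with
  plasmid copy number.
* ``constitutive_repressor`` — the repressor is held at a fixed level
  ``R0``; expression is then strictly proportional to copy number.

Deterministic skeleton, per cell with copy number ``N`` at inducer
concentration ``I``:

    rho(I)   = 1 / (1 + (I / Kd_I)^hill_I)          active-repressor fraction
    a(Rf)    = basal + (1 - basal) / (1 + (Rf / K_R)^hill_R)   promoter activity
    constitutive:  G_det = N * alpha * a(R0 * rho)
    autoregulated: G_det solves  G = N * alpha * a(r_ratio * G * rho)

The autoregulatory fixed point is unique because the right-hand side is
positive and non-increasing in ``G``. Stochasticity enters as a gamma burst
approximation (``G ~ Gamma(shape=G_det/burst, scale=burst)``) for intrinsic
noise and a multiplicative lognormal cell-size factor (mean 1, CV^2 =
``size_cv2``) for extrinsic noise. ``burst = 0`` selects the deterministic
limit exactly.

Measurement renders a population as a cytometry event table: fluorescence =
(reporter x maturation fraction + autofluorescence x size) with
multiplicative instrument noise; scatter channels report cell size with
their own noise; a fraction of events is replaced by small low-fluorescence
debris particles independent of the population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from duotune.io import EventTable

__all__ = [
    "CircuitParams",
    "MeasurementParams",
    "CellPopulation",
    "FixedPointError",
    "simulate_population",
    "simulate_flow_sample",
    "simulate_control_sample",
    "deterministic_reporter",
    "maturation_fraction",
    "tet_like",
    "lac_like",
]

MODES = ("autoregulated", "constitutive_repressor")


class FixedPointError(RuntimeError):
    """Raised when the autoregulatory fixed point cannot be bracketed/solved."""


def maturation_fraction(tau_min: float, chase_min: float = 60.0) -> float:
    """Fraction of fluorophores matured after a translation-inhibited chase.

    First-order maturation with time constant ``tau_min`` (minutes) during a
    chloramphenicol chase of ``chase_min`` minutes: ``1 - exp(-chase/tau)``.
    """
    if tau_min <= 0:
        return 1.0
    return 1.0 - math.exp(-chase_min / tau_min)


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of one repressor-reporter circuit on one plasmid.

    Attributes
    ----------
    mode
        ``"autoregulated"`` or ``"constitutive_repressor"``.
    alpha
        Reporter output per plasmid copy at full promoter activity
        (protein-equivalent arbitrary units).
    basal
        Basal promoter activity fraction in [0, 1] at saturating repressor.
    K_R
        Active-repressor level at half-maximal repression.
    hill_R
        Hill coefficient of repression (>= 1).
    Kd_I
        Inducer concentration at half de-repression, in the inducer's own
        units (nM for ATc-like, uM for IPTG-like).
    hill_I
        Hill coefficient of inducer binding (>= 1).
    r_ratio
        Repressor:reporter translation ratio from the bicistron (> 0).
    R0
        Constitutive repressor level; used only in constitutive mode.
    N_mean, N_disp
        Plasmid copy-number mean and dispersion (variance/mean). Copies are
        drawn as 1 + negative binomial; ``N_disp = 0`` fixes N at
        ``round(N_mean)``.
    burst
        Intrinsic burst size b: reporter ~ Gamma(G_det/b, b). ``0`` selects
        the deterministic limit.
    size_cv2
        Extrinsic cell-size CV^2 (lognormal multiplicative factor, mean 1).
    """

    mode: str = "autoregulated"
    alpha: float = 1500.0
    basal: float = 0.0
    K_R: float = 6.0
    hill_R: float = 1.0
    Kd_I: float = 40.0
    hill_I: float = 3.0
    r_ratio: float = 1.0
    R0: float = 0.0
    N_mean: float = 10.0
    N_disp: float = 1.0
    burst: float = 5.0
    size_cv2: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("alpha", "K_R", "Kd_I", "r_ratio", "R0", "size_cv2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.basal <= 1.0:
            raise ValueError(f"basal must be in [0, 1], got {self.basal}")
        if self.hill_R < 1 or self.hill_I < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.N_mean <= 0:
            raise ValueError(f"N_mean must be > 0, got {self.N_mean}")
        if self.N_disp < 0:
            raise ValueError(f"N_disp must be >= 0, got {self.N_disp}")
        if self.burst < 0:
            raise ValueError(f"burst must be >= 0 (0 = deterministic limit), got {self.burst}")
        if self.mode == "autoregulated" and self.r_ratio == 0:
            raise ValueError("r_ratio must be > 0 in autoregulated mode")


def tet_like(**overrides) -> CircuitParams:
    """Default TetR/ATc-style circuit (Kd_I in nM; strong inducer binding)."""
    base = dict(mode="autoregulated", Kd_I=10.0, hill_I=2.0)
    base.update(overrides)
    return CircuitParams(**base)


def lac_like(**overrides) -> CircuitParams:
    """Default LacI/IPTG-style circuit (Kd_I in uM, ~3.6 orders of magnitude
    weaker inducer binding than the ATc-like default in absolute terms)."""
    base = dict(mode="autoregulated", Kd_I=40.0, hill_I=3.0)
    base.update(overrides)
    return CircuitParams(**base)


# Maturation times of GFPmut2-like (5.6 min) and mScarlet-I-like (25.7 min)
# fluorophores, after a 60-min translation-inhibited chase.
_MATURATION_GFP = maturation_fraction(5.6)
_MATURATION_RFP = maturation_fraction(25.7)


@dataclass(frozen=True)
class MeasurementParams:
    """Cytometer measurement model.

    autofluorescence is in AU per unit cell size; instrument_cv is the
    multiplicative measurement noise CV; maturation fractions are per
    channel; a ``debris_fraction`` of events is replaced by small particles
    with exponential low fluorescence (scale ``debris_scale``) and reduced
    scatter, independent of the cell population.
    """

    autofluorescence: float = 100.0
    instrument_cv: float = 0.02
    maturation_fl1: float = _MATURATION_GFP
    maturation_fl2: float = _MATURATION_RFP
    debris_fraction: float = 0.02
    debris_scale: float = 50.0
    debris_size: float = 0.25
    fsc_gain: float = 1000.0
    ssc_gain: float = 800.0
    fsc_cv: float = 0.15
    ssc_cv: float = 0.25
    n_events: int = 30_000

    def __post_init__(self) -> None:
        if self.autofluorescence < 0:
            raise ValueError("autofluorescence must be >= 0")
        if self.instrument_cv < 0 or self.fsc_cv < 0 or self.ssc_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        for name in ("maturation_fl1", "maturation_fl2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.debris_fraction < 1.0:
            raise ValueError("debris_fraction must be in [0, 1)")
        if self.debris_scale < 0 or self.debris_size <= 0:
            raise ValueError("debris scale/size must be positive")
        if self.fsc_gain <= 0 or self.ssc_gain <= 0:
            raise ValueError("scatter gains must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass
class CellPopulation:
    """Ground-truth per-cell state from the circuit simulator."""

    copy_number: np.ndarray  # int, >= 1
    repressor: np.ndarray  # >= 0
    reporter: np.ndarray  # >= 0, protein-equivalent AU
    cell_size: np.ndarray  # > 0, mean ~1
    params: CircuitParams
    inducer: float
    seed: object
    reporter2: Optional[np.ndarray] = None
    params2: Optional[CircuitParams] = None
    inducer2: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.copy_number)
        arrays = [self.repressor, self.reporter, self.cell_size]
        if self.reporter2 is not None:
            arrays.append(self.reporter2)
        if any(len(a) != n for a in arrays):
            raise ValueError("per-cell arrays must have equal length")
        if n == 0:
            raise ValueError("population must contain at least one cell")
        if np.any(self.cell_size <= 0):
            raise ValueError("cell sizes must be strictly positive")
        if not np.all(np.isfinite(self.reporter)) or np.any(self.reporter < 0):
            raise ValueError("reporter must be finite and non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.copy_number)


def active_fraction(inducer: float, params: CircuitParams) -> float:
    """rho(I): fraction of repressor not inactivated by inducer."""
    if inducer < 0:
        raise ValueError("inducer concentration must be >= 0")
    if inducer == 0:
        return 1.0
    if params.Kd_I == 0:
        return 0.0
    return 1.0 / (1.0 + (inducer / params.Kd_I) ** params.hill_I)


def promoter_activity(r_free: float | np.ndarray, params: CircuitParams):
    """a(Rf): fractional promoter activity at active-repressor level Rf."""
    r_free = np.asarray(r_free, dtype=float)
    if params.K_R == 0:
        act = np.where(r_free > 0, params.basal, 1.0)
    else:
        act = params.basal + (1.0 - params.basal) / (1.0 + (r_free / params.K_R) ** params.hill_R)
    return act if act.ndim else float(act)


def deterministic_reporter(
    params: CircuitParams, inducer: float, copy_number: float | np.ndarray
) -> float | np.ndarray:
    """Mean-field reporter level G_det for given copy number(s).

    Constitutive mode evaluates the promoter activity at the fixed repressor
    level; autoregulated mode solves the scalar fixed point
    ``G = N * alpha * a(r_ratio * G * rho)`` by Brent's method on the
    bracket [0, N*alpha] (the right-hand side is non-increasing in G, so
    the root is unique).
    """
    rho = active_fraction(inducer, params)
    n_arr = np.atleast_1d(np.asarray(copy_number, dtype=float))
    if np.any(n_arr < 0):
        raise ValueError("copy number must be >= 0")

    if params.mode == "constitutive_repressor":
        g = n_arr * params.alpha * promoter_activity(params.R0 * rho, params)
    elif params.alpha == 0:
        g = np.zeros_like(n_arr)
    elif rho == 0:
        g = n_arr * params.alpha  # fully de-repressed: a(0) = 1
    else:
        g = np.empty_like(n_arr)
        cache: dict[float, float] = {}
        for i, n in enumerate(n_arr):
            if n in cache:
                g[i] = cache[n]
                continue
            g[i] = cache[n] = _solve_fixed_point(params, rho, n)
    out = np.asarray(g, dtype=float)
    return out if np.ndim(copy_number) else float(out[0])


def _solve_fixed_point(params: CircuitParams, rho: float, n: float) -> float:
    if n == 0:
        return 0.0
    top = n * params.alpha

    def residual(g: float) -> float:
        return n * params.alpha * promoter_activity(params.r_ratio * g * rho, params) - g

    # residual(0) = N*alpha >= 0 (a(0) = 1), residual(top) <= 0
    try:
        root, info = brentq(
            residual, 0.0, top, xtol=1e-12 * max(1.0, top), maxiter=200, full_output=True
        )
    except ValueError as exc:  # pragma: no cover - bracket is valid by construction
        raise FixedPointError(f"could not bracket fixed point on [0, {top}]: {exc}") from exc
    if not info.converged:
        raise FixedPointError(
            f"fixed-point iteration did not converge: {info.iterations} iterations, "
            f"last root estimate {info.root}"
        )
    return float(root)


def simulate_population(
    params: CircuitParams,
    inducer: float,
    n_cells: int,
    seed,
    params2: Optional[CircuitParams] = None,
    inducer2: float = 0.0,
) -> CellPopulation:
    """Draw a single-cell population at one inducer condition.

    All randomness flows from one generator seeded with ``seed``; draws occur
    in the fixed order copy-number, intrinsic, size(, channel-2 copy-number,
    channel-2 intrinsic), so identical inputs reproduce identical output.

    When ``params2`` is given, a second reporter (independent plasmid with
    its own copy-number draw and intrinsic noise, at inducer ``inducer2``)
    shares each cell's size factor — cell size is the extrinsic covariate
    coupling the two channels.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if inducer < 0 or inducer2 < 0:
        raise ValueError("inducer concentrations must be >= 0")
    rng = np.random.default_rng(seed)

    n1 = _draw_copy_number(rng, params, n_cells)
    g1 = _draw_intrinsic(rng, params, inducer, n1)
    if params.size_cv2 > 0:
        sigma2 = math.log1p(params.size_cv2)
        size = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n_cells)
    else:
        size = np.ones(n_cells)
    g1 = g1 * size

    if params.mode == "autoregulated":
        repressor = params.r_ratio * g1
    else:
        repressor = np.full(n_cells, float(params.R0))

    reporter2 = None
    if params2 is not None:
        n2 = _draw_copy_number(rng, params2, n_cells)
        reporter2 = _draw_intrinsic(rng, params2, inducer2, n2) * size

    return CellPopulation(
        copy_number=n1,
        repressor=repressor,
        reporter=g1,
        cell_size=size,
        params=params,
        inducer=float(inducer),
        seed=seed,
        reporter2=reporter2,
        params2=params2,
        inducer2=float(inducer2),
    )


def _draw_copy_number(rng: np.random.Generator, params: CircuitParams, n_cells: int) -> np.ndarray:
    """1 + negative binomial, targeting mean N_mean and variance N_disp*N_mean."""
    if params.N_disp == 0:
        return np.full(n_cells, max(1, round(params.N_mean)), dtype=np.int64)
    mean_m = max(params.N_mean - 1.0, 0.0)
    var_m = params.N_disp * params.N_mean
    if mean_m == 0:
        return np.ones(n_cells, dtype=np.int64)
    if var_m <= mean_m:
        extra = rng.poisson(mean_m, size=n_cells)
    else:
        r = mean_m**2 / (var_m - mean_m)
        p = r / (r + mean_m)
        extra = rng.negative_binomial(r, p, size=n_cells)
    return 1 + extra.astype(np.int64)


def _draw_intrinsic(
    rng: np.random.Generator, params: CircuitParams, inducer: float, copies: np.ndarray
) -> np.ndarray:
    g_det = np.asarray(deterministic_reporter(params, inducer, copies), dtype=float)
    if params.burst == 0:
        return g_det.copy()
    shape = g_det / params.burst
    out = np.zeros(len(copies))
    pos = shape > 0
    if np.any(pos):
        out[pos] = rng.gamma(shape[pos], scale=params.burst)
    return out


def simulate_flow_sample(
    pop: CellPopulation,
    meas: MeasurementParams,
    n_events: Optional[int] = None,
    seed=0,
    sample_id: str = "sample",
    condition_atc_nM: float = 0.0,
    condition_iptg_uM: float = 0.0,
    replicate: int = 1,
    is_control: bool = False,
) -> EventTable:
    """Render a population as a cytometry event table.

    Cells are taken in order when ``n_events <= n_cells`` and resampled with
    replacement otherwise. With maturation 1, zero autofluorescence, zero
    instrument noise and zero debris, ``fl1_area`` equals the sampled cells'
    reporter values exactly (unit gain).
    """
    if pop.n_cells == 0:
        raise ValueError("population is empty")
    n_events = int(meas.n_events if n_events is None else n_events)
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)

    if n_events <= pop.n_cells:
        idx = np.arange(n_events)
    else:
        idx = rng.integers(0, pop.n_cells, size=n_events)
    g = pop.reporter[idx]
    s = pop.cell_size[idx]
    g2 = pop.reporter2[idx] if pop.reporter2 is not None else None

    debris = rng.random(n_events) < meas.debris_fraction

    def noisy(base: np.ndarray, cv: float) -> np.ndarray:
        if cv == 0:
            return base.copy()
        return base * (1.0 + cv * rng.standard_normal(n_events))

    fl1 = noisy(g * meas.maturation_fl1 + meas.autofluorescence * s, meas.instrument_cv)
    fl2 = None
    if g2 is not None:
        fl2 = noisy(g2 * meas.maturation_fl2 + meas.autofluorescence * s, meas.instrument_cv)
    fsc = noisy(meas.fsc_gain * s, meas.fsc_cv)
    ssc = noisy(meas.ssc_gain * s, meas.ssc_cv)

    n_debris = int(debris.sum())
    if n_debris:
        ds = meas.debris_size * rng.lognormal(mean=0.0, sigma=0.5, size=n_debris)
        fl1[debris] = rng.exponential(meas.debris_scale, size=n_debris)
        if fl2 is not None:
            fl2[debris] = rng.exponential(meas.debris_scale, size=n_debris)
        fsc[debris] = meas.fsc_gain * ds * (1.0 + meas.fsc_cv * rng.standard_normal(n_debris))
        ssc[debris] = meas.ssc_gain * ds * (1.0 + meas.ssc_cv * rng.standard_normal(n_debris))

    data = pd.DataFrame({"fsc_area": fsc, "ssc_height": ssc, "fl1_area": fl1})
    if fl2 is not None:
        data["fl2_area"] = fl2
    return EventTable(
        data=data,
        sample_id=sample_id,
        condition_atc_nM=condition_atc_nM,
        condition_iptg_uM=condition_iptg_uM,
        replicate=replicate,
        is_control=is_control,
        is_debris=debris,
    )


def simulate_control_sample(
    meas: MeasurementParams,
    n_events: Optional[int] = None,
    seed=0,
    size_cv2: float = 0.1,
    sample_id: str = "control",
    replicate: int = 1,
) -> EventTable:
    """Autofluorescence-only control (no fluorescent protein encoded).

    Emulates a strain carrying an otherwise similar plasmid without a
    fluorophore: reporter forced to zero, cell-size variation ``size_cv2``.
    """
    n_events = int(meas.n_events if n_events is None else n_events)
    params = CircuitParams(
        mode="constitutive_repressor", alpha=0.0, burst=0.0, size_cv2=size_cv2, N_disp=0.0
    )
    pop = simulate_population(params, inducer=0.0, n_cells=n_events, seed=seed)
    table = simulate_flow_sample(
        pop,
        meas,
        n_events=n_events,
        seed=seed,
        sample_id=sample_id,
        replicate=replicate,
        is_control=True,
    )
    return table
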