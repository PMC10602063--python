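"""Binding-kinetics assembly and analysis: time series, steady-state
detection, dose-response linear range, intra-channel spatial profiles,
fold changes.

Rate constants (k_on/k_off/K_D) are deliberately not fitted: the assay
operates in the titration, partly mass-transport-limited regime where such
fits are biased.  The analysis is restricted to the time to approximately
reach steady state, the plateau densities, and their spatial structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .quantify import DENSITY_UNIT_UM2, DensityRecord

STEADY_STATE_WINDOW_H = 2.0
STEADY_STATE_REL_TOL = 0.05
N_SEGMENTS = 10


@dataclass
class KineticsSeries:
    """Signal density vs time for one channel, with counting errors."""

    times_h: np.ndarray
    density: np.ndarray  # signal counts per 100 um^2
    density_err: np.ndarray
    channel_id: str = "ch0"
    concentration: Optional[float] = None
    flow_ul_h: Optional[float] = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.density_err = np.asarray(self.density_err, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")


@dataclass
class SteadyState:
    reached: bool
    t_ss_h: Optional[float] = None
    plateau_density: Optional[float] = None


@dataclass
class DoseResponse:
    """Steady-state density vs concentration with its linear range."""

    concentrations: np.ndarray
    steady_density: np.ndarray
    steady_density_err: np.ndarray
    slope: float = math.nan  # density per (particles/mL)
    linear_range_max: float = math.nan


@dataclass
class SegmentProfile:
    """Along-flow density profile; segment 1 is the channel entrance."""

    edges_um: np.ndarray
    counts: np.ndarray
    density: np.ndarray  # per 100 um^2
    density_err: np.ndarray
    segment_area_um2: float


@dataclass
class FoldChange:
    ratio: Optional[float]
    ci_low: float
    ci_high: float
    one_sided: bool = False


def assemble_timeseries(records: Sequence[DensityRecord]) -> KineticsSeries:
    """Order per-timepoint density records into a series (>= 2 points,
    duplicate timestamps rejected)."""
    if len(records) < 2:
        raise ValueError("need at least two time points")
    channels = {r.channel_id for r in records}
    if len(channels) != 1:
        raise ValueError(f"mixed channels: {sorted(channels)}")
    recs = sorted(records, key=lambda r: r.timestamp_h)
    times = np.array([r.timestamp_h for r in recs])
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicate timestamps")
    return KineticsSeries(
        times,
        np.array([r.density_signal for r in recs]),
        np.array([r.density_signal_err for r in recs]),
        channel_id=recs[0].channel_id,
        concentration=recs[0].concentration,
        flow_ul_h=recs[0].flow_ul_h,
    )


def detect_steady_state(series: KineticsSeries,
                        window_h: float = STEADY_STATE_WINDOW_H,
                        rel_slope_tol: float = STEADY_STATE_REL_TOL
                        ) -> SteadyState:
    """Earliest time at which the relative density change across the
    trailing ``window_h`` drops below ``rel_slope_tol``; the plateau is the
    mean density from that time on.  Returns an explicit not-reached result
    when the criterion is never met — no extrapolation.
    """
    t, d = series.times_h, series.density
    if t[-1] - t[0] < window_h:
        raise ValueError("series shorter than the steady-state window")
    for i in range(len(t)):
        if t[i] - t[0] < window_h:
            continue
        j = int(np.searchsorted(t, t[i] - window_h, side="right") - 1)
        ref = d[i] if d[i] > 0 else 1.0
        if abs(d[i] - d[j]) / ref < rel_slope_tol:
            return SteadyState(True, float(t[i]), float(d[i:].mean()))
    return SteadyState(False)


def fit_linear_range(concentrations: Sequence[float],
                     densities: Sequence[float],
                     density_errs: Optional[Sequence[float]] = None
                     ) -> DoseResponse:
    """Zero-intercept linear fit over the largest ascending dose prefix
    whose residuals all stay within 2x the counting error.

    The line is forced through the origin because the densities are net of
    the pre-assay baseline.  Requires >= 3 doses.
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(densities, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least three doses")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(c)
    c, d = c[order], d[order]
    if density_errs is None:
        err = np.sqrt(np.maximum(d, 1.0))
    else:
        err = np.asarray(density_errs, dtype=float)[order]
    tol = 2.0 * np.where(err > 0, err, 1e-6 * max(float(np.abs(d).max()), 1.0))

    best_k, best_slope = None, math.nan
    for k in range(3, len(c) + 1):
        ck, dk, ek = c[:k], d[:k], err[:k]
        wk = 1.0 / np.where(ek > 0, ek, 1.0) ** 2
        slope = float((wk * ck * dk).sum() / (wk * ck * ck).sum())
        if np.all(np.abs(dk - slope * ck) <= tol[:k]):
            best_k, best_slope = k, slope
        else:
            break
    dr = DoseResponse(c, d, err)
    if best_k is not None:
        dr.slope = best_slope
        dr.linear_range_max = float(c[best_k - 1])
    return dr


def segment_channel_profile(locs: pd.DataFrame,
                            channel_length_um: float,
                            channel_width_um: float,
                            n_segments: int = N_SEGMENTS,
                            flow_column: str = "x_um") -> SegmentProfile:
    """Equal-length along-flow bins of the localisation positions.

    ``flow_column`` holds the along-flow coordinate with 0 at the channel
    entrance.  Segment counts conserve the channel total.
    """
    if channel_length_um <= 0 or channel_width_um <= 0:
        raise ValueError("channel geometry missing or non-positive")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if flow_column not in locs.columns:
        raise ValueError(f"localisations lack the {flow_column!r} column")
    x = locs[flow_column].to_numpy(dtype=float)
    edges = np.linspace(0.0, channel_length_um, n_segments + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                  n_segments - 1)
    counts = np.bincount(idx, minlength=n_segments)
    seg_area = channel_length_um / n_segments * channel_width_um
    units = seg_area / DENSITY_UNIT_UM2
    return SegmentProfile(edges, counts, counts / units,
                          np.sqrt(counts) / units, seg_area)


def fit_depletion_length(profile: SegmentProfile) -> float:
    """Depletion length (um) from a log-linear fit of the along-flow
    density profile; requires at least three non-empty segments."""
    centers = 0.5 * (profile.edges_um[:-1] + profile.edges_um[1:])
    good = profile.density > 0
    if good.sum() < 3:
        raise ValueError("too few non-empty segments for a depletion fit")
    slope, _ = np.polyfit(centers[good], np.log(profile.density[good]), 1)
    if slope >= 0:
        return math.inf
    return -1.0 / slope


def fold_change(a: DensityRecord, b: DensityRecord,
                n_boot: int = 2000, seed: int = 0,
                ci: float = 0.95) -> FoldChange:
    """Ratio of signal densities a/b with a Poisson-bootstrap CI.

    A zero-count denominator yields a one-sided lower bound (rule of
    three: the 95% upper bound on a mean with zero observed counts is ~3).
    """
    units_a = a.scanned_area_um2 / DENSITY_UNIT_UM2
    units_b = b.scanned_area_um2 / DENSITY_UNIT_UM2
    if b.n_signal == 0:
        lower = (a.n_signal / units_a) / (3.0 / units_b)
        return FoldChange(None, lower, math.inf, one_sided=True)
    ratio = (a.n_signal / units_a) / (b.n_signal / units_b)
    rng = np.random.default_rng(seed)
    na = rng.poisson(a.n_signal, size=n_boot)
    nb = np.maximum(rng.poisson(b.n_signal, size=n_boot), 1)
    reps = (na / units_a) / (nb / units_b)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return FoldChange(ratio, float(lo), float(hi))


def timelapse_to_series(tl, channel_id: str = "ch0") -> KineticsSeries:
    """Ground-truth cumulative counts of a synthetic binding time-lapse as
    a KineticsSeries (Poisson counting errors)."""
    counts = tl.counts_series().astype(float)
    units = tl.area_um2 / DENSITY_UNIT_UM2
    return KineticsSeries(tl.times_h, counts / units,
                          np.sqrt(counts) / units,
                          channel_id=channel_id,
                          concentration=tl.scenario.concentration,
                          flow_ul_h=tl.scenario.flow_ul_h)
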