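"""Counting statistics: contrast classification, densities per 100 um^2,
and contrast histograms.

Detection is SNR-gated upstream; here localisations are split into a
background class (substrate roughness and minute inhomogeneities, contrast
magnitude at or below the cut-off) and a signal class above it, then
normalised to counts per 100 um^2 with Poisson counting errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Background/signal contrast cut-off: localisations with contrast
#: magnitude strictly above this are counted as signal.
CONTRAST_CUTOFF = 7.5e-3

#: Density reporting unit, um^2 (counts per 10x10 um^2).
DENSITY_UNIT_UM2 = 100.0


@dataclass
class DensityRecord:
    """Per-channel counting summary in counts per 100 um^2."""

    channel_id: str
    scanned_area_um2: float
    n_background: int
    n_signal: int
    density_background: float
    density_signal: float
    density_background_err: float
    density_signal_err: float
    contrast_threshold: float
    timestamp_h: float = 0.0
    concentration: Optional[float] = None
    flow_ul_h: Optional[float] = None

    @property
    def n_total(self) -> int:
        return self.n_background + self.n_signal


def classify_contrast(locs: pd.DataFrame,
                      threshold: float = CONTRAST_CUTOFF) -> pd.DataFrame:
    """Label each localisation ``signal`` or ``background`` by contrast
    magnitude.  The boundary value itself is background (strict inequality
    for signal)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = locs.copy()
    if len(out) == 0:
        out["klass"] = pd.Series(dtype=str)
        return out
    out["klass"] = np.where(out["contrast_mag"].to_numpy() > threshold,
                            "signal", "background")
    return out


def compute_density(locs: pd.DataFrame, scanned_area_um2: float,
                    channel_id: str = "ch0",
                    threshold: float = CONTRAST_CUTOFF,
                    timestamp_h: float = 0.0,
                    concentration: Optional[float] = None,
                    flow_ul_h: Optional[float] = None) -> DensityRecord:
    """Counts per 100 um^2 for each contrast class, with sqrt(n) Poisson
    counting errors scaled identically."""
    if scanned_area_um2 <= 0:
        raise ValueError("scanned_area_um2 must be positive")
    labelled = locs if "klass" in locs.columns else classify_contrast(
        locs, threshold)
    n_sig = int((labelled.get("klass", pd.Series(dtype=str)) == "signal").sum())
    n_bg = len(labelled) - n_sig
    units = scanned_area_um2 / DENSITY_UNIT_UM2
    return DensityRecord(
        channel_id=channel_id,
        scanned_area_um2=scanned_area_um2,
        n_background=n_bg,
        n_signal=n_sig,
        density_background=n_bg / units,
        density_signal=n_sig / units,
        density_background_err=np.sqrt(n_bg) / units,
        density_signal_err=np.sqrt(n_sig) / units,
        contrast_threshold=threshold,
        timestamp_h=timestamp_h,
        concentration=concentration,
        flow_ul_h=flow_ul_h,
    )


def density_record_from_counts(n_signal: int, scanned_area_um2: float,
                               n_background: int = 0,
                               channel_id: str = "ch0",
                               timestamp_h: float = 0.0,
                               threshold: float = CONTRAST_CUTOFF,
                               concentration: Optional[float] = None,
                               flow_ul_h: Optional[float] = None
                               ) -> DensityRecord:
    """DensityRecord straight from class counts (e.g. ground-truth event
    counts of a simulated channel)."""
    if scanned_area_um2 <= 0:
        raise ValueError("scanned_area_um2 must be positive")
    units = scanned_area_um2 / DENSITY_UNIT_UM2
    return DensityRecord(
        channel_id=channel_id, scanned_area_um2=scanned_area_um2,
        n_background=n_background, n_signal=n_signal,
        density_background=n_background / units,
        density_signal=n_signal / units,
        density_background_err=np.sqrt(n_background) / units,
        density_signal_err=np.sqrt(n_signal) / units,
        contrast_threshold=threshold, timestamp_h=timestamp_h,
        concentration=concentration, flow_ul_h=flow_ul_h)


def contrast_histogram(locs: pd.DataFrame,
                       bins: Optional[Sequence[float]] = None,
                       n_bins: int = 50,
                       use_magnitude: bool = True) -> pd.DataFrame:
    """Histogram of (by default log-spaced) contrast magnitudes.

    Returns a frame with ``bin_lo``, ``bin_hi``, ``count``; counts sum to
    the number of in-range localisations.
    """
    vals = (locs["contrast_mag"] if use_magnitude
            else locs["contrast"]).to_numpy(dtype=float)
    if bins is None:
        lo = max(vals.min(), 1e-6) if len(vals) else 1e-4
        hi = vals.max() if len(vals) else 1e-1
        if hi <= lo:
            hi = lo * 10
        bins = np.logspace(np.log10(lo * (1 - 1e-9)),
                           np.log10(hi * (1 + 1e-9)), n_bins + 1)
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be strictly increasing")
    counts, edges = np.histogram(vals, bins=bins)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "count": counts})


def density_records_to_frame(records: Sequence[DensityRecord]) -> pd.DataFrame:
    """Tidy table of density records (one row per channel/time point)."""
    rows = []
    for r in records:
        rows.append({
            "channel_id": r.channel_id,
            "timestamp_h": r.timestamp_h,
            "scanned_area_um2": r.scanned_area_um2,
            "n_background": r.n_background,
            "n_signal": r.n_signal,
            "density_background_per_100um2": r.density_background,
            "density_signal_per_100um2": r.density_signal,
            "density_background_err": r.density_background_err,
            "density_signal_err": r.density_signal_err,
            "contrast_threshold": r.contrast_threshold,
            "concentration": r.concentration,
            "flow_ul_h": r.flow_ul_h,
        })
    return pd.DataFrame(rows)
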