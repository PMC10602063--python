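"""Multi-channel surface-biomarker fingerprints normalised to the isotype
control, positivity calls, and the contrast-density correlation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CONTRAST_CUTOFF, DensityRecord

POSITIVITY_K = 3.0

FINGERPRINT_COLUMNS = ["marker", "density", "density_sd", "normalized",
                       "normalized_sd", "median_contrast_mag", "n_locs",
                       "n_replicates", "positive", "flags"]


def build_fingerprint(records: Mapping[str, Sequence[DensityRecord]],
                      control_marker: str = "IgG1",
                      locs: Optional[Mapping[str, pd.DataFrame]] = None
                      ) -> pd.DataFrame:
    """Normalised biomarker profile from per-channel density records.

    ``records`` maps marker -> replicate DensityRecords; every marker's
    replicate-mean signal density is divided by the grand mean of the
    control channel's density, so the control row is 1 by construction.
    When per-marker localisation tables are given, the median contrast
    magnitude of the signal-class localisations is attached.
    """
    if control_marker not in records:
        raise ValueError(f"control channel {control_marker!r} missing")
    ctrl = [r.density_signal for r in records[control_marker]]
    ctrl_mean = float(np.mean(ctrl))
    if ctrl_mean <= 0:
        raise ValueError("control channel density is zero")
    rows = []
    for marker, reps in records.items():
        if len(reps) == 0:
            raise ValueError(f"no replicates for {marker!r}")
        dens = np.array([r.density_signal for r in reps], dtype=float)
        sd = float(dens.std(ddof=1)) if len(dens) > 1 else 0.0
        med_contrast = math.nan
        n_locs = int(sum(r.n_signal for r in reps))
        if locs is not None and marker in locs:
            tab = locs[marker]
            sig = tab[tab["contrast_mag"] > CONTRAST_CUTOFF]
            if len(sig):
                med_contrast = float(sig["contrast_mag"].median())
        rows.append({
            "marker": marker,
            "density": float(dens.mean()),
            "density_sd": sd,
            "normalized": float(dens.mean()) / ctrl_mean,
            "normalized_sd": sd / ctrl_mean,
            "median_contrast_mag": med_contrast,
            "n_locs": n_locs,
            "n_replicates": len(reps),
            "positive": False,
            "flags": "",
        })
    return pd.DataFrame(rows, columns=FINGERPRINT_COLUMNS)


def call_positive(table: pd.DataFrame, k: float = POSITIVITY_K,
                  control_marker: str = "IgG1") -> pd.DataFrame:
    """Mark markers whose normalised density exceeds 1 + k x control CV.

    The control CV comes from its replicate spread; with a single control
    replicate it falls back to the Poisson counting CV (flagged).
    """
    out = table.copy()
    ctrl = out[out["marker"] == control_marker]
    if len(ctrl) != 1:
        raise ValueError("table must contain exactly one control row")
    ctrl = ctrl.iloc[0]
    flag = ""
    if ctrl["n_replicates"] > 1 and ctrl["density"] > 0:
        cv = ctrl["density_sd"] / ctrl["density"]
    else:
        n = max(int(ctrl["n_locs"]), 1)
        cv = 1.0 / math.sqrt(n)
        flag = "poisson_control_cv"
    out["positive"] = out["normalized"] > 1.0 + k * cv
    out.loc[out["marker"] == control_marker, "positive"] = False
    if flag:
        out["flags"] = np.where(out["flags"] == "", flag,
                                out["flags"] + ";" + flag)
    return out


@dataclass
class CorrelationResult:
    rho: float
    n_markers: int
    defined: bool
    tie_flag: bool = False


def contrast_density_correlation(table: pd.DataFrame,
                                 exclude_control: bool = True,
                                 control_marker: str = "IgG1"
                                 ) -> CorrelationResult:
    """Spearman rank correlation of (median contrast magnitude, density)
    across markers with localisations.

    Background-class localisations are already excluded from the median
    contrast during fingerprint construction.  Fewer than three usable
    markers, or fully tied contrasts, give an undefined result reported as
    such.
    """
    tab = table
    if exclude_control:
        tab = tab[tab["marker"] != control_marker]
    tab = tab[(tab["n_locs"] > 0) & tab["median_contrast_mag"].notna()]
    n = len(tab)
    if n < 3:
        return CorrelationResult(math.nan, n, defined=False)
    c = tab["median_contrast_mag"].to_numpy(dtype=float)
    d = tab["density"].to_numpy(dtype=float)
    if np.allclose(c, c[0]) or np.allclose(d, d[0]):
        return CorrelationResult(0.0, n, defined=False, tie_flag=True)
    rho, _ = stats.spearmanr(c, d)
    if math.isnan(rho):
        return CorrelationResult(0.0, n, defined=False, tie_flag=True)
    return CorrelationResult(float(rho), n, defined=True)
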