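"""Single-particle localisation: two-level noise model, SNR segmentation
with a cluster rule, radial-symmetry sub-pixel centres, contrast extraction.

The detection chain mirrors how the contrast images are formed: a global
noise scale from the median absolute deviation, a local RMS noise map over
inlier pixels, an SNR image (both polarities), 8-connected candidate groups
that must concentrate at least ``min_cluster`` above-threshold pixels in
some 3x3 window, and finally closed-form radial-symmetry localisation with
signed contrast and integrated contrast per spot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .preprocess import ContrastImage, Mosaic

SNR_THRESHOLD = 4.0
MIN_CLUSTER = 3
NOISE_KERNEL = 65
INLIER_FACTOR = 2.5
ROI_HALFWIDTH = 7
MERGE_RADIUS_PX = 2.0

#: MAD -> Gaussian-equivalent sigma.
MAD_SCALE = 1.4826

_EIGHT_CONN = np.ones((3, 3), dtype=int)

LOCALISATION_COLUMNS = ["fov_id", "channel_id", "t_h", "x_px", "y_px",
                        "x_um", "y_um", "contrast", "contrast_mag",
                        "integrated_contrast", "snr", "flags"]


@dataclass
class NoiseModel:
    """Global MAD-based noise scale plus a per-pixel local RMS map."""

    sigma_global: float
    sigma_local: np.ndarray
    inlier_factor: float = INLIER_FACTOR
    kernel: int = NOISE_KERNEL


@dataclass
class Candidate:
    """One above-threshold connected group that passed the cluster rule."""

    bbox: tuple  # (r0, c0, r1, c1), exclusive upper bounds
    peak: tuple  # (row, col) of the max-SNR pixel
    peak_snr: float
    n_pixels: int


def estimate_noise(img: Union[ContrastImage, np.ndarray],
                   kernel: int = NOISE_KERNEL,
                   inlier_factor: float = INLIER_FACTOR) -> NoiseModel:
    """Two-level noise estimate of a zero-centred contrast image.

    Global scale: 1.4826 x median(|pixels - median|).  Local map: RMS of
    the pixels within a ``kernel`` x ``kernel`` reflect-padded window whose
    values fall within ``inlier_factor`` x the global scale — bright spots
    are excluded so the map tracks the background noise.  Windows with
    fewer than 10% inliers fall back to the global scale, and the map is
    floored at 0.1 x the global scale.
    """
    pix = np.asarray(img.pixels if hasattr(img, "pixels") else img,
                     dtype=np.float64)
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    med = np.median(pix)
    sigma_global = MAD_SCALE * float(np.median(np.abs(pix - med)))
    if sigma_global == 0:
        raise ValueError("constant image: noise level undefined")
    inlier = (np.abs(pix) <= inlier_factor * sigma_global).astype(np.float64)
    sq = ndimage.uniform_filter(pix * pix * inlier, size=kernel,
                                mode="reflect")
    frac = ndimage.uniform_filter(inlier, size=kernel, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        local = np.sqrt(sq / frac)
    local = np.where(frac < 0.10, sigma_global, local)
    local = np.maximum(local, 0.1 * sigma_global)
    return NoiseModel(sigma_global, local, inlier_factor, kernel)


def snr_map(img: Union[ContrastImage, np.ndarray],
            noise: NoiseModel) -> np.ndarray:
    """|pixels| / local noise — both polarities are detectable."""
    pix = np.asarray(img.pixels if hasattr(img, "pixels") else img,
                     dtype=np.float64)
    return np.abs(pix) / noise.sigma_local


def _cluster_ok(component_mask: np.ndarray, min_cluster: int) -> bool:
    """True iff some 3x3 window holds >= min_cluster pixels of this
    component."""
    sums = ndimage.convolve(component_mask.astype(np.int32),
                            np.ones((3, 3), dtype=np.int32),
                            mode="constant", cval=0)
    return bool(sums.max() >= min_cluster)


def segment_candidates(img: Union[ContrastImage, np.ndarray],
                       noise: NoiseModel,
                       snr_threshold: float = SNR_THRESHOLD,
                       min_cluster: int = MIN_CLUSTER,
                       valid_mask: Optional[np.ndarray] = None) -> list:
    """Above-threshold pixels grouped by 8-connectivity; a group survives
    iff at least one 3x3 window contains ``min_cluster`` of its pixels.
    The candidate peak is the group's max-SNR pixel (ties: smaller row,
    then smaller column)."""
    snr = snr_map(img, noise)
    mask = snr >= snr_threshold
    if valid_mask is not None:
        mask &= valid_mask
    labels, n_lab = ndimage.label(mask, structure=_EIGHT_CONN)
    if n_lab == 0:
        return []
    out = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        comp = labels[sl] == lab
        if comp.sum() < min_cluster or not _cluster_ok(comp, min_cluster):
            continue
        local_snr = np.where(comp, snr[sl], -np.inf)
        flat = int(np.argmax(local_snr))  # row-major: smallest row then col
        pr, pc = np.unravel_index(flat, local_snr.shape)
        peak = (sl[0].start + int(pr), sl[1].start + int(pc))
        out.append(Candidate(
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            peak=peak,
            peak_snr=float(snr[peak]),
            n_pixels=int(comp.sum())))
    return out


# ---------------------------------------------------------------------------
# radial symmetry centres
# ---------------------------------------------------------------------------

def radial_symmetry_center(roi: np.ndarray) -> tuple[float, float, bool]:
    """Sub-pixel centre of a radially symmetric spot (closed form).

    Intensity gradients are computed on the half-pixel midpoint lattice
    from diagonal differences of 2x2 pixel blocks and smoothed with a 3x3
    mean.  Each lattice point defines the line through it along its
    gradient; the centre is the point minimising the weighted sum of
    squared perpendicular distances to all lines (2x2 linear solve),
    weighted by squared gradient magnitude over distance to a preliminary
    gradient-weighted centroid.

    Returns ``(x, y, ok)`` in 0-based ROI pixel coordinates (x = column,
    y = row); ``ok`` is False when the normal equations are singular and
    the intensity centroid is returned instead.
    """
    I = np.asarray(roi, dtype=np.float64)
    ny, nx = I.shape
    if ny < 3 or nx < 3:
        raise ValueError("ROI must be at least 3x3")
    # midpoint-lattice coordinates relative to the ROI centre
    xm = (np.arange(nx - 1) - (nx - 2) / 2.0)[None, :]
    ym = (np.arange(ny - 1) - (ny - 2) / 2.0)[:, None]

    dIdu = I[:-1, 1:] - I[1:, :-1]
    dIdv = I[:-1, :-1] - I[1:, 1:]
    fdu = ndimage.uniform_filter(dIdu, size=3, mode="constant")
    fdv = ndimage.uniform_filter(dIdv, size=3, mode="constant")
    mag2 = fdu * fdu + fdv * fdv

    with np.errstate(divide="ignore", invalid="ignore"):
        m = -(fdv + fdu) / (fdu - fdv)
    m = np.where(np.isnan(m), 0.0, m)
    if np.any(np.isinf(m)):
        finite = m[np.isfinite(m)]
        big = 10.0 * np.abs(finite).max() if finite.size else 1.0e6
        m = np.where(np.isinf(m), np.sign(m) * max(big, 1.0e6), m)

    b = ym - m * xm
    s = mag2.sum()
    if s <= 0:
        return _intensity_centroid(I) + (False,)
    xc0 = (mag2 * xm).sum() / s
    yc0 = (mag2 * ym).sum() / s
    dist = np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2)
    w = mag2 / np.maximum(dist, 0.1)

    wm2p1 = w / (m * m + 1.0)
    sw = wm2p1.sum()
    smmw = (m * m * wm2p1).sum()
    smw = (m * wm2p1).sum()
    smbw = (m * b * wm2p1).sum()
    sbw = (b * wm2p1).sum()
    det = smw * smw - smmw * sw
    if abs(det) < 1e-24:
        return _intensity_centroid(I) + (False,)
    xc = (smbw * sw - smw * sbw) / det
    yc = (smbw * smw - smmw * sbw) / det
    return xc + (nx - 1) / 2.0, yc + (ny - 1) / 2.0, True


def _intensity_centroid(I: np.ndarray) -> tuple[float, float]:
    mag = np.abs(I - np.median(I))
    tot = mag.sum()
    if tot == 0:
        return (I.shape[1] - 1) / 2.0, (I.shape[0] - 1) / 2.0
    ys, xs = np.mgrid[0:I.shape[0], 0:I.shape[1]]
    return float((mag * xs).sum() / tot), float((mag * ys).sum() / tot)


def localize_spot(img: Union[ContrastImage, np.ndarray],
                  candidate: Candidate,
                  roi_halfwidth: int = ROI_HALFWIDTH
                  ) -> tuple[float, float, str]:
    """Radial-symmetry localisation of one candidate.

    Returns ``(x_px, y_px, flags)``; flags name an edge-clipped ROI and/or
    a centroid fallback."""
    pix = np.asarray(img.pixels if hasattr(img, "pixels") else img,
                     dtype=np.float64)
    pr, pc = candidate.peak
    r0, r1 = pr - roi_halfwidth, pr + roi_halfwidth + 1
    c0, c1 = pc - roi_halfwidth, pc + roi_halfwidth + 1
    flags = []
    if r0 < 0 or c0 < 0 or r1 > pix.shape[0] or c1 > pix.shape[1]:
        flags.append("edge_clipped")
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, pix.shape[0]), min(c1, pix.shape[1])
    roi = pix[r0:r1, c0:c1]
    x, y, ok = radial_symmetry_center(roi)
    if not ok:
        flags.append("centroid_fallback")
    return c0 + x, r0 + y, ";".join(flags)


def measure_contrast(img: Union[ContrastImage, np.ndarray],
                     position: tuple[float, float],
                     roi_halfwidth: int = ROI_HALFWIDTH,
                     noise: Optional[NoiseModel] = None
                     ) -> tuple[float, float]:
    """Signed peak contrast and integrated contrast at a position.

    Contrast: extremal-magnitude pixel within 1 px of the position.
    Integrated contrast: sum of same-signed ROI pixels exceeding
    1 x local noise in magnitude (the whole same-signed ROI when no noise
    model is given).
    """
    pix = np.asarray(img.pixels if hasattr(img, "pixels") else img,
                     dtype=np.float64)
    x, y = position
    if not (0 <= x < pix.shape[1] and 0 <= y < pix.shape[0]):
        raise ValueError("position outside image")
    r, c = int(round(y)), int(round(x))
    win = pix[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
    if np.all(win == 0):
        return 0.0, 0.0
    contrast = float(win.flat[np.argmax(np.abs(win))])
    sign = math.copysign(1.0, contrast)
    r0, r1 = max(r - roi_halfwidth, 0), min(r + roi_halfwidth + 1,
                                            pix.shape[0])
    c0, c1 = max(c - roi_halfwidth, 0), min(c + roi_halfwidth + 1,
                                            pix.shape[1])
    roi = pix[r0:r1, c0:c1]
    if noise is not None:
        floor = noise.sigma_local[r0:r1, c0:c1]
    else:
        floor = 0.0
    sel = (roi * sign > floor)
    integrated = float(roi[sel].sum())
    return contrast, integrated


# ---------------------------------------------------------------------------
# full detection
# ---------------------------------------------------------------------------

def merge_localisations(locs: pd.DataFrame,
                        radius_px: float = MERGE_RADIUS_PX) -> pd.DataFrame:
    """Collapse localisations closer than ``radius_px``, keeping the
    higher-SNR member of each close pair.  Greedy from the strongest spot;
    idempotent and order-independent for pairwise-separated sets."""
    if len(locs) <= 1:
        return locs.reset_index(drop=True)
    order = locs.sort_values("snr", ascending=False,
                             kind="mergesort").reset_index(drop=True)
    xy = order[["x_px", "y_px"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    keep = np.ones(len(order), dtype=bool)
    for i in range(len(order)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(xy[i], radius_px):
            if j != i and keep[j] and j > i:
                keep[j] = False
    return order[keep].reset_index(drop=True)


def detect_particles(img: Union[ContrastImage, Mosaic, np.ndarray],
                     snr_threshold: float = SNR_THRESHOLD,
                     min_cluster: int = MIN_CLUSTER,
                     noise_kernel: int = NOISE_KERNEL,
                     inlier_factor: float = INLIER_FACTOR,
                     roi_halfwidth: int = ROI_HALFWIDTH,
                     merge_radius_px: float = MERGE_RADIUS_PX,
                     pixel_size_um: Optional[float] = None) -> pd.DataFrame:
    """estimate noise -> segment -> localise -> measure, one row per spot.

    Accepts a contrast image, a stitched mosaic (detection restricted to
    the valid mask, near-duplicates merged keeping the higher SNR), or a
    bare zero-centred array.
    """
    valid_mask = None
    fov_id, channel_id, t_h = "fov0", "ch0", 0.0
    if isinstance(img, Mosaic):
        pix = img.pixels
        valid_mask = img.valid_mask
        channel_id, t_h = img.channel_id, img.timestamp_h
        fov_id = "mosaic"
        psz = img.pixel_size_um
    elif isinstance(img, ContrastImage):
        pix = img.pixels
        fov_id, channel_id, t_h = img.fov_id, img.channel_id, img.timestamp_h
        psz = img.pixel_size_um
    else:
        pix = np.asarray(img)
        psz = pixel_size_um if pixel_size_um is not None else 1.0
    if pixel_size_um is not None:
        psz = pixel_size_um

    noise = estimate_noise(pix, kernel=noise_kernel,
                           inlier_factor=inlier_factor)
    cands = segment_candidates(pix, noise, snr_threshold=snr_threshold,
                               min_cluster=min_cluster,
                               valid_mask=valid_mask)
    rows = []
    for cand in cands:
        x, y, flags = localize_spot(pix, cand, roi_halfwidth=roi_halfwidth)
        contrast, integrated = measure_contrast(
            pix, (x, y), roi_halfwidth=roi_halfwidth, noise=noise)
        rows.append({
            "fov_id": fov_id, "channel_id": channel_id, "t_h": t_h,
            "x_px": x, "y_px": y,
            "x_um": x * psz, "y_um": y * psz,
            "contrast": contrast, "contrast_mag": abs(contrast),
            "integrated_contrast": integrated,
            "snr": cand.peak_snr, "flags": flags,
        })
    df = pd.DataFrame(rows, columns=LOCALISATION_COLUMNS)
    if isinstance(img, Mosaic) and len(df) > 1:
        df = merge_localisations(df, radius_px=merge_radius_px)
    return df
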