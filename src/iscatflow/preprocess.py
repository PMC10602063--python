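"""Raw counts -> contrast images: normalisation, flat-field, large-feature
removal, and phase-correlation stitching of raster scans.

The processing order is fixed: normalise to the robust background level,
divide by the flat field, subtract a wide spatial median.  Each stage is
idempotent on its own output class.  Stitching is translation-only with a
first-placed-wins overlap policy so that contrast values are never blended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

#: Minimum number of source frames for a trustworthy flat field.
FLATFIELD_MIN_FRAMES = 60

#: Default spatial-median kernel (px) for large-feature removal.
MEDIAN_KERNEL = 17

#: Sample-plane pixel size (um) for the default camera/objective combination
#: (6.5 um camera pixels at 100x magnification).
DEFAULT_PIXEL_SIZE_UM = 0.065


@dataclass
class RawFrame:
    """A single camera field of view in (possibly normalised) counts."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    fov_id: str = "fov0"
    channel_id: str = "ch0"
    timestamp_h: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("RawFrame pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class FlatField:
    """Dimensionless per-pixel illumination/optics response, mean ~ 1."""

    pixels: np.ndarray
    n_source_frames: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)


@dataclass
class ContrastImage:
    """Dimensionless reflectivity-normalised image.

    ``stage`` is ``"flatfielded"`` (pixels ~ 1 + contrast) or
    ``"background_removed"`` (zero-centred contrast)."""

    pixels: np.ndarray
    stage: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    fov_id: str = "fov0"
    channel_id: str = "ch0"
    timestamp_h: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.stage not in ("flatfielded", "background_removed"):
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class OffsetEstimate:
    """Translation of one frame relative to another, in pixels (row, col)."""

    dy: float
    dx: float
    confidence: float
    low_confidence: bool = False


@dataclass
class Mosaic:
    """Stitched scan: translated frames on a common canvas."""

    pixels: np.ndarray
    offsets_px: list  # (dy, dx) per frame, canvas coordinates
    valid_mask: np.ndarray
    overlap_map: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel_id: str = "ch0"
    timestamp_h: float = 0.0
    flags: list = field(default_factory=list)

    @property
    def scanned_area_um2(self) -> float:
        return float(self.valid_mask.sum()) * self.pixel_size_um ** 2


# ---------------------------------------------------------------------------
# normalisation and flat field
# ---------------------------------------------------------------------------

def normalize_counts(frame: RawFrame, offset_counts: float = 0.0) -> RawFrame:
    """Divide a frame by its robust background level (whole-frame median).

    The median is insensitive to the sparse diffraction-limited spots, so it
    tracks the true background scale to well under a percent for spot cover
    of a few percent.
    """
    pix = frame.pixels.astype(np.float64) - offset_counts
    scale = float(np.median(pix))
    if scale <= 0:
        raise ValueError("frame has non-positive median after offset removal")
    out = RawFrame(pix / scale, frame.pixel_size_um, frame.fov_id,
                   frame.channel_id, frame.timestamp_h)
    return out


def build_flat_field(frames: Sequence[RawFrame],
                     min_frames: int = FLATFIELD_MIN_FRAMES,
                     strict: bool = True) -> FlatField:
    """Pixel-wise median of normalised frames from distinct positions.

    Any feature present in only a minority of frames (particles, defects) is
    rejected by the median; what survives is the static optical response.
    The result is renormalised to mean 1.
    """
    if len(frames) == 0:
        raise ValueError("no frames given")
    shapes = {f.pixels.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("all frames must share one shape")
    if len(frames) < min_frames:
        msg = (f"flat field built from {len(frames)} frames; "
               f"at least {min_frames} recommended")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    stack = np.stack([f.pixels for f in frames]).astype(np.float64)
    med = np.median(stack, axis=0)
    med /= med.mean()
    if np.any(med <= 0):
        raise ValueError("flat field contains non-positive pixels")
    return FlatField(med, n_source_frames=len(frames))


def flat_field_correct(frame: RawFrame, flat: FlatField) -> ContrastImage:
    """Divide a normalised frame by the flat field."""
    if frame.pixels.shape != flat.pixels.shape:
        raise ValueError("frame and flat field shapes differ")
    if np.any(flat.pixels <= 0):
        raise ValueError("flat field must be strictly positive")
    out = frame.pixels.astype(np.float64) / flat.pixels.astype(np.float64)
    return ContrastImage(out, stage="flatfielded",
                         pixel_size_um=frame.pixel_size_um,
                         fov_id=frame.fov_id, channel_id=frame.channel_id,
                         timestamp_h=frame.timestamp_h)


def remove_large_features(img: ContrastImage,
                          kernel: int = MEDIAN_KERNEL) -> ContrastImage:
    """Subtract a wide spatial median to remove low-frequency structure.

    Out-of-focus features (e.g. the top PDMS surface of the chip) vary on
    scales much larger than the PSF; a 17-px median captures them while the
    diffraction-limited spots pass through essentially unattenuated
    (peak change < 2%).  Reflect padding at the edges.
    """
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd")
    if kernel < 3 or kernel >= min(img.pixels.shape):
        raise ValueError("kernel must be >= 3 and smaller than the image")
    pix = img.pixels.astype(np.float32)
    bg = ndimage.median_filter(pix, size=kernel, mode="reflect")
    return ContrastImage(pix - bg, stage="background_removed",
                         pixel_size_um=img.pixel_size_um,
                         fov_id=img.fov_id, channel_id=img.channel_id,
                         timestamp_h=img.timestamp_h)


def preprocess_frame(frame: RawFrame, flat: FlatField,
                     kernel: int = MEDIAN_KERNEL,
                     offset_counts: float = 0.0) -> ContrastImage:
    """normalise -> flat-field -> large-feature removal, in one call."""
    return remove_large_features(
        flat_field_correct(normalize_counts(frame, offset_counts), flat),
        kernel=kernel)


# ---------------------------------------------------------------------------
# stitching
# ---------------------------------------------------------------------------

def estimate_offset(img_a: np.ndarray, img_b: np.ndarray,
                    nominal: Optional[tuple[float, float]] = None,
                    upsample_factor: int = 20,
                    confidence_floor: float = 0.05) -> OffsetEstimate:
    """Translation of ``img_b`` relative to ``img_a`` by phase correlation.

    Returns (dy, dx) such that ``img_b(r, c) ~ img_a(r - dy, c - dx)``:
    positive dy means the content of ``img_b`` sits lower.  Sub-pixel
    resolution comes from DFT upsampling of the cross-power spectrum peak.

    When a nominal stage offset is given, both images are first cropped to
    the nominally overlapping region and only the residual shift is
    estimated — raster-scan overlaps are a small fraction of the frame, so
    correlating the full frames would drown the shared content.  A
    degenerate or low-peak correlation is flagged and, when a nominal
    offset is given, replaced by it.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share one shape")
    if a.std() == 0 or b.std() == 0:
        if nominal is None:
            return OffsetEstimate(0.0, 0.0, 0.0, low_confidence=True)
        return OffsetEstimate(float(nominal[0]), float(nominal[1]), 0.0,
                              low_confidence=True)
    base = (0.0, 0.0)
    # whitened (phase) correlation is sharpest on full frames; on narrow
    # nominal-overlap crops plain cross-correlation is more robust
    normalization = "phase"
    if nominal is not None:
        ny, nx = int(round(nominal[0])), int(round(nominal[1]))
        h, w = a.shape
        rb0, rb1 = max(ny, 0), h + min(ny, 0)
        cb0, cb1 = max(nx, 0), w + min(nx, 0)
        if rb1 - rb0 >= 16 and cb1 - cb0 >= 16:
            a = a[rb0 - ny:rb1 - ny, cb0 - nx:cb1 - nx]
            b = b[rb0:rb1, cb0:cb1]
            base = (float(ny), float(nx))
            normalization = None
            if a.std() == 0 or b.std() == 0:
                return OffsetEstimate(float(nominal[0]), float(nominal[1]),
                                      0.0, low_confidence=True)
    shift, _, _ = phase_cross_correlation(
        b, a, upsample_factor=upsample_factor, normalization=normalization)
    shift = (shift[0] + base[0], shift[1] + base[1])
    # confidence: height of the normalised cross-power-spectrum peak
    # (1 for a pure translation, ~N^-1/2 for unrelated content)
    fa, fb = np.fft.fft2(a - a.mean()), np.fft.fft2(b - b.mean())
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    cross /= np.where(mag > 0, mag, 1.0)
    confidence = float(np.abs(np.fft.ifft2(cross)).max())
    if confidence < confidence_floor:
        if nominal is not None:
            return OffsetEstimate(float(nominal[0]), float(nominal[1]),
                                  confidence, low_confidence=True)
        return OffsetEstimate(float(shift[0]), float(shift[1]),
                              confidence, low_confidence=True)
    return OffsetEstimate(float(shift[0]), float(shift[1]), confidence)


def stitch_scan(images: Sequence[ContrastImage],
                layout: dict,
                loop_closure_tol_px: float = 2.0) -> Mosaic:
    """Place raster-scanned frames on a common canvas by translation.

    ``layout`` must carry ``grid`` (rows, cols) and ``nominal_step_px``
    (row step, col step); frame order is row-major.  Each frame's offset is
    estimated against its left neighbour (or top neighbour for the first
    frame of a row) and accumulated; overlap pixels keep the first-placed
    frame's values.  A loop-closure discrepancy above
    ``loop_closure_tol_px`` triggers a warning naming the frame pair.
    """
    rows, cols = layout["grid"]
    if rows * cols != len(images):
        raise ValueError("grid does not match number of frames")
    step_r, step_c = layout["nominal_step_px"]
    if len(images) == 1:
        img = images[0]
        mask = np.ones_like(img.pixels, dtype=bool)
        return Mosaic(img.pixels.copy(), [(0.0, 0.0)], mask,
                      np.zeros_like(img.pixels, dtype=np.int16),
                      pixel_size_um=img.pixel_size_um,
                      channel_id=img.channel_id, timestamp_h=img.timestamp_h)

    # accumulate canvas positions frame by frame in row-major order;
    # estimate_offset returns o_ref - o_frame, so positions subtract it
    offsets: list[tuple[float, float]] = [(0.0, 0.0)] * len(images)
    flags: list[str] = [""] * len(images)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if r == 0 and c == 0:
                continue
            if c > 0:
                ref_idx = i - 1
                step = (0.0, float(step_c))
            else:
                ref_idx = i - cols
                step = (float(step_r), 0.0)
            est = estimate_offset(images[ref_idx].pixels, images[i].pixels,
                                  nominal=(-step[0], -step[1]))
            base = offsets[ref_idx]
            if est.low_confidence:
                flags[i] = "low_confidence"
                offsets[i] = (base[0] + step[0], base[1] + step[1])
            else:
                offsets[i] = (base[0] - est.dy, base[1] - est.dx)
            # loop closure: compare the left-chain position with top-chain
            if r > 0 and c > 0:
                est_top = estimate_offset(images[i - cols].pixels,
                                          images[i].pixels,
                                          nominal=(-float(step_r), 0.0))
                top_base = offsets[i - cols]
                alt = (top_base[0] - est_top.dy, top_base[1] - est_top.dx)
                gap = np.hypot(alt[0] - offsets[i][0], alt[1] - offsets[i][1])
                if gap > loop_closure_tol_px:
                    warnings.warn(
                        f"loop closure error {gap:.2f} px at grid ({r},{c})",
                        stacklevel=2)

    # shift so the minimum offset is zero, round for placement
    arr = np.array(offsets, dtype=np.float64)
    arr -= arr.min(axis=0)
    int_off = np.rint(arr).astype(int)
    h, w = images[0].pixels.shape
    canvas_h = int(int_off[:, 0].max()) + h
    canvas_w = int(int_off[:, 1].max()) + w
    canvas = np.zeros((canvas_h, canvas_w), dtype=np.float32)
    mask = np.zeros((canvas_h, canvas_w), dtype=bool)
    overlap = np.zeros((canvas_h, canvas_w), dtype=np.int16)
    for i, img in enumerate(images):
        r0, c0 = int_off[i]
        region = (slice(r0, r0 + h), slice(c0, c0 + w))
        fresh = ~mask[region]
        canvas[region][fresh] = img.pixels[fresh]
        overlap[region] += 1
        mask[region] = True
    return Mosaic(canvas, [tuple(o) for o in arr], mask, overlap,
                  pixel_size_um=images[0].pixel_size_um,
                  channel_id=images[0].channel_id,
                  timestamp_h=images[0].timestamp_h,
                  flags=flags)
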