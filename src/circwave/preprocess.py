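"""B-scan preprocessing: normalization, retinal flattening, ROI crop, denoising.

The full chain (``datasetA`` profile) mirrors standard SD-OCT preparation:
resize to 496x512, scale intensities to [0, 1], locate the hyper-reflective
complex (HRC), shift each column so the retina lies flat, crop a 400-row
window around the HRC down to a 128x128 region of interest, and suppress
speckle with non-local means.  The ``datasetB`` profile covers data that
arrives already flattened/denoised (divide by 255, drop the first 50 columns,
resize).  A ``phantom`` profile runs the same flatten+denoise logic at the
phantoms' native 128-px resolution.

HRC localization uses a thresholded intensity-centroid with an order-2
polynomial fit across columns; this satisfies the only contract downstream
stages rely on (a flat retina after correction) without any external
graph-based machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.restoration import denoise_nl_means
from skimage.transform import resize as _sk_resize

PROFILES = ("datasetA", "datasetB", "phantom")


@dataclass
class BScan:
    image: np.ndarray
    subject_id: str = ""
    label: str = "unknown"
    provenance: list = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        if any(s == step for s, _ in self.provenance):
            raise ValueError(f"step {step!r} already applied (provenance check)")
        self.provenance.append((step, params))


@dataclass
class HrcCurve:
    """Per-column row coordinate of the hyper-reflective complex."""

    center_row: np.ndarray
    smoothed: bool = True
    coefficients: np.ndarray | None = None


def _resize(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if image.shape == tuple(shape):
        return image.astype(float, copy=True)
    down = shape[0] < image.shape[0] or shape[1] < image.shape[1]
    return _sk_resize(image, shape, order=1, anti_aliasing=down, mode="reflect")


def normalize_and_resize(image: np.ndarray,
                         target: tuple[int, int] | None = (496, 512)) -> np.ndarray:
    """Scale intensities to [0, 1] (integer inputs divided by the dtype
    maximum) and resize to ``target`` (skipped when None)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {image.shape}")
    if np.issubdtype(image.dtype, np.integer):
        out = image.astype(float) / float(np.iinfo(image.dtype).max)
    else:
        out = np.clip(image.astype(float), 0.0, 1.0)
    if target is not None:
        out = _resize(out, tuple(target))
    return np.clip(out, 0.0, 1.0)


def detect_hrc(image: np.ndarray, on_empty: str = "center") -> HrcCurve:
    """Locate the retinal profile per column.

    Pixels above an Otsu threshold contribute an intensity-weighted mean row
    per column; the raw curve is then smoothed with an order-2 least-squares
    polynomial.  Columns with no above-threshold pixel inherit the fitted
    value.  All-zero images either raise or return a flat center curve,
    depending on ``on_empty``.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if image.max() <= 0:
        if on_empty == "reject":
            raise ValueError("cannot detect HRC on an all-zero image")
        return HrcCurve(np.full(w, (h - 1) / 2.0), smoothed=True,
                        coefficients=np.array([0.0, 0.0, (h - 1) / 2.0]))
    thresh = threshold_otsu(image)
    above = image >= thresh
    weights = np.where(above, image, 0.0)
    colsum = weights.sum(axis=0)
    rows = np.arange(h)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (weights * rows).sum(axis=0) / colsum
    valid = colsum > 0
    x = np.arange(w)
    coef = np.polyfit(x[valid], raw[valid], deg=2)
    fitted = np.clip(np.polyval(coef, x), 0, h - 1)
    return HrcCurve(center_row=fitted, smoothed=True, coefficients=coef)


def flatten_retina(image: np.ndarray, curve: HrcCurve) -> np.ndarray:
    """Circularly shift each column so the HRC maps to the curve's median row."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if len(curve.center_row) != w:
        raise ValueError("curve length must equal image width")
    target = np.median(curve.center_row)
    shifts = np.round(target - curve.center_row).astype(int)
    rows = (np.arange(h)[:, None] - shifts[None, :]) % h
    return image[rows, np.arange(w)[None, :]]


def crop_roi(image: np.ndarray, hrc_row: float, half_height: int = 200,
             out_side: int = 128) -> np.ndarray:
    """Crop ``half_height`` rows above/below the HRC (zero-padded at borders),
    resize to ``out_side`` x width, center-crop the width to the 470/512
    fraction, and resize to ``out_side`` square."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    r0 = int(round(hrc_row)) - half_height
    r1 = r0 + 2 * half_height
    window = np.zeros((2 * half_height, w))
    src0, src1 = max(r0, 0), min(r1, h)
    window[src0 - r0:src1 - r0] = image[src0:src1]
    band = _resize(window, (out_side, w))
    crop_w = int(round(w * 470 / 512))
    c0 = (w - crop_w) // 2
    return np.clip(_resize(band[:, c0:c0 + crop_w], (out_side, out_side)), 0.0, 1.0)


def denoise_nlm(image: np.ndarray, h: float = 10.0, patch_size: int = 7,
                patch_distance: int = 10) -> np.ndarray:
    """Non-local means denoising; ``h`` is the filter strength on the 0-255
    scale (rescaled internally for [0, 1] images)."""
    if h <= 0:
        raise ValueError("filter strength h must be positive")
    image = np.asarray(image, dtype=float)
    out = denoise_nl_means(image, h=h / 255.0, patch_size=patch_size,
                           patch_distance=patch_distance, fast_mode=True)
    return np.clip(out, 0.0, 1.0)


def preprocess_bscan(image: np.ndarray | BScan, profile: str = "datasetA",
                     nlm_h: float = 10.0, out_side: int = 128) -> BScan:
    """Run the named preprocessing profile; returns a 128x128 BScan in [0, 1]
    with the applied steps recorded in its provenance."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    if isinstance(image, BScan):
        scan = image
        if scan.provenance:
            raise ValueError("scan has already been preprocessed (provenance non-empty)")
    else:
        scan = BScan(image=np.asarray(image))

    if profile == "datasetA":
        img = normalize_and_resize(scan.image, (496, 512))
        scan.record("normalize_and_resize", target=(496, 512))
        curve = detect_hrc(img)
        scan.record("detect_hrc", order=2)
        img = flatten_retina(img, curve)
        scan.record("flatten_retina")
        img = crop_roi(img, float(np.median(curve.center_row)), out_side=out_side)
        scan.record("crop_roi", half_height=200, out_side=out_side)
        img = denoise_nlm(img, h=nlm_h)
        scan.record("denoise_nlm", h=nlm_h)
    elif profile == "datasetB":
        img = normalize_and_resize(scan.image, None)
        scan.record("normalize", scale=255)
        img = img[:, 50:]
        scan.record("crop_columns", first=50)
        img = np.clip(_resize(img, (out_side, out_side)), 0.0, 1.0)
        scan.record("resize", side=out_side)
    else:  # phantom profile: native-resolution flatten + recenter + denoise
        img = normalize_and_resize(scan.image, None)
        scan.record("normalize", scale="dtype")
        curve = detect_hrc(img)
        scan.record("detect_hrc", order=2)
        img = flatten_retina(img, curve)
        scan.record("flatten_retina")
        # anchor the flattened HRC at the image center row (native-resolution
        # analogue of the ROI crop)
        shift = img.shape[0] // 2 - int(round(np.median(curve.center_row)))
        img = np.roll(img, shift, axis=0)
        scan.record("center_hrc", shift=shift)
        img = denoise_nlm(img, h=nlm_h)
        scan.record("denoise_nlm", h=nlm_h)
        if img.shape != (out_side, out_side):
            img = np.clip(_resize(img, (out_side, out_side)), 0.0, 1.0)
        scan.record("resize", side=out_side)
    scan.image = img
    return scan


def preprocess_phantom_pair(image: np.ndarray, mask: np.ndarray,
                            nlm_h: float = 10.0,
                            out_side: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Phantom-profile preprocessing of an image together with its lesion
    mask: the geometric steps (flatten, recenter, resize) are applied to
    both so the mask stays co-registered; denoising touches the image only."""
    img = normalize_and_resize(np.asarray(image), None)
    m = np.asarray(mask, dtype=float)
    curve = detect_hrc(img)
    img = flatten_retina(img, curve)
    m = flatten_retina(m, curve)
    shift = img.shape[0] // 2 - int(round(np.median(curve.center_row)))
    img = np.roll(img, shift, axis=0)
    m = np.roll(m, shift, axis=0)
    img = denoise_nlm(img, h=nlm_h)
    if img.shape != (out_side, out_side):
        img = np.clip(_resize(img, (out_side, out_side)), 0.0, 1.0)
        m = _resize(m, (out_side, out_side))
    return img, m > 0.5
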