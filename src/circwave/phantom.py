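"""Synthetic OCT-like phantom generator.

Emulates the three-class retinal B-scan problem (normal / DME / AMD) with
subject-level geometry so that subject-wise cross-validation, transforms,
feature extraction and interpretability experiments are all testable without
clinical data.  A phantom B-scan is a stack of horizontal tissue bands bent by
a low-order polynomial curve shared within a subject, corrupted by
multiplicative speckle.  DME scans additionally carry hypo-reflective
near-circular fluid pockets inside the band region; AMD scans carry smooth
dome-shaped upward deformations of the lowest bright band (the RPE/HRC
analogue).  Ground-truth lesion masks are recorded for every abnormal scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

CLASSES = ("normal", "DME", "AMD")

# fixed alternating band reflectivities, brightest band last (RPE/HRC analogue)
_BAND_LUT = np.array([0.55, 0.32, 0.46, 0.30, 0.50, 0.34, 0.42, 0.85])
_BACKGROUND = 0.06
_FLUID = 0.10


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a phantom dataset.

    ``speckle_level`` is the standard deviation of the multiplicative
    mean-one Gamma speckle; radius/amplitude ranges are in pixels.
    """

    n_subjects_per_class: int = 5
    scans_per_subject: int = 10
    image_size: int = 128
    classes: tuple[str, ...] = CLASSES
    n_layers: int = 8
    speckle_level: float = 0.15
    dme_blob_radius_range: tuple[float, float] = (4.0, 10.0)
    amd_bump_amplitude_range: tuple[float, float] = (6.0, 14.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1 or self.scans_per_subject < 1:
            raise ValueError("subject and scan counts must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if not 0.0 < self.speckle_level < 1.0:
            raise ValueError("speckle_level must lie in (0, 1)")
        for name in ("dme_blob_radius_range", "amd_bump_amplitude_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValueError(f"{name} must be positive and ordered (lo <= hi)")
        unknown = set(self.classes) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")


@dataclass
class PhantomScan:
    """One phantom B-scan with its ground truth."""

    image: np.ndarray            # 2-D float in [0, 1]
    subject_id: str
    label: str
    lesion_mask: np.ndarray      # bool, same shape; all-zero iff label == normal
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.lesion_mask.shape:
            raise ValueError("image and lesion_mask must share a shape")


def _subject_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Draw the geometry shared by all scans of one subject."""
    s = spec.image_size
    x = np.arange(s)
    cx = (s - 1) / 2.0
    # mild global curvature: sag of a few percent of the height
    a2 = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0]) * (0.08 * s) / cx**2
    a1 = rng.uniform(-0.02, 0.02)
    curve = a2 * (x - cx) ** 2 + a1 * (x - cx)
    curve -= curve.mean()
    top = rng.uniform(0.26, 0.34) * s
    total = rng.uniform(0.38, 0.42) * s
    fractions = rng.dirichlet(np.full(spec.n_layers, 40.0))
    thickness = np.maximum(fractions * total, 2.0)
    lut = _BAND_LUT[np.round(np.linspace(0, len(_BAND_LUT) - 1, spec.n_layers)).astype(int)]
    return {"curve": curve, "top": top, "thickness": thickness, "lut": lut,
            "poly": (a2, a1)}


def _render_layers(spec: PhantomSpec, geom: dict, slice_jitter: dict,
                   bump: np.ndarray | None):
    """Rasterize the band stack; returns (clean image, layer-index map x2).

    ``slice_jitter`` perturbs the subject geometry per scan (a B-scan is one
    slice through the volume, so position, curvature and thickness vary a
    little from slice to slice).  ``bump`` (per-column, >= 0) lifts the top
    boundary of the lowest band upward (the AMD dome).  The second layer map
    is rendered without the bump so callers can diff the two to obtain the
    lesion mask.
    """
    s = spec.image_size
    rows = np.arange(s)[:, None]
    top = (geom["top"] + slice_jitter["top"]
           + slice_jitter["curve_scale"] * geom["curve"][None, :])
    depth = rows - top                           # signed depth below the top surface
    bounds = np.concatenate(
        [[0.0], np.cumsum(geom["thickness"] * slice_jitter["thickness_scale"])])

    def layer_map(bump_cols):
        # per-column boundary rows; boundary b[i] is the top of layer i
        b = bounds[:, None] + np.zeros((1, s))
        if bump_cols is not None:
            # the dome lifts the top of the lowest bright band and pushes the
            # overlying layers upward (compressed to >= 1 px) rather than
            # being clipped by them
            b[-2] = b[-2] - bump_cols
            for i in range(b.shape[0] - 3, -1, -1):
                b[i] = np.minimum(b[i], b[i + 1] - 1.0)
        # digitize depth against per-column boundaries
        li = np.zeros((s, s), dtype=int)
        for i in range(len(bounds)):
            li += (depth >= b[i][None, :]).astype(int)
        return li  # 0 = above retina, 1..n_layers = bands, n_layers+1 = below

    li = layer_map(bump)
    li_ref = layer_map(None) if bump is not None else li
    lut_full = np.concatenate([[_BACKGROUND], geom["lut"], [_BACKGROUND + 0.02]])
    return lut_full[li], li, li_ref


def _place_dme_blobs(spec: PhantomSpec, geom: dict, rng: np.random.Generator,
                     image: np.ndarray, slice_jitter: dict) -> np.ndarray:
    """Paint 1-4 dark near-circular fluid pockets strictly inside the bands."""
    s = spec.image_size
    lo, hi = spec.dme_blob_radius_range
    n_blobs = int(rng.integers(1, 5))
    mask = np.zeros((s, s), dtype=bool)
    yy, xx = np.mgrid[0:s, 0:s]
    placed: list[tuple[float, float, float]] = []
    total = float(np.sum(geom["thickness"])) * slice_jitter["thickness_scale"]
    for _ in range(n_blobs):
        for _attempt in range(50):
            r = rng.uniform(lo, min(hi, total / 2.5))
            ratio = rng.uniform(0.8, 1.25)
            ry, rx = r, r * ratio
            cxp = rng.uniform(rx + 2, s - rx - 2)
            top_here = (geom["top"] + slice_jitter["top"]
                        + slice_jitter["curve_scale"]
                        * np.interp(cxp, np.arange(s), geom["curve"]))
            lo_row = top_here + ry + 1.5
            hi_row = top_here + total - ry - 1.5
            if hi_row <= lo_row:
                continue
            cyp = rng.uniform(lo_row, hi_row)
            if any((cxp - px) ** 2 + (cyp - py) ** 2 < (pr + max(ry, rx) + 2) ** 2
                   for px, py, pr in placed):
                continue
            ellipse = ((yy - cyp) / ry) ** 2 + ((xx - cxp) / rx) ** 2 <= 1.0
            image[ellipse] = _FLUID
            mask |= ellipse
            placed.append((cxp, cyp, max(ry, rx)))
            break
    return mask


def generate_subject(label: str, spec: PhantomSpec, subject_seed: int,
                     subject_id: str | None = None) -> list[PhantomScan]:
    """Generate all scans of one subject.

    Scans share the subject's layer geometry (curvature, thicknesses); speckle,
    small curve jitter and lesion placement vary per scan.
    """
    if label not in spec.classes:
        raise ValueError(f"unknown label {label!r}; expected one of {spec.classes}")
    root = np.random.SeedSequence(entropy=int(subject_seed))
    geom_rng = np.random.default_rng(root.spawn(1)[0])
    geom = _subject_geometry(spec, geom_rng)
    sid = subject_id if subject_id is not None else f"{label}_s{subject_seed}"
    scans = []
    for i in range(spec.scans_per_subject):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=int(subject_seed), spawn_key=(1, i)))
        # per-scan slice geometry: each B-scan is a different cut through the
        # volume, so vertical position, curvature and thickness vary mildly
        jitter = {"top": rng.uniform(-2.0, 2.0),
                  "curve_scale": rng.uniform(0.85, 1.15),
                  "thickness_scale": rng.uniform(0.95, 1.05)}
        bump = None
        if label == "AMD":
            s = spec.image_size
            x = np.arange(s)
            bump = np.zeros(s)
            for _ in range(int(rng.integers(1, 4))):
                amp = rng.uniform(*spec.amd_bump_amplitude_range)
                width = rng.uniform(0.05, 0.10) * s
                center = rng.uniform(0.15 * s, 0.85 * s)
                bump += amp * np.exp(-0.5 * ((x - center) / width) ** 2)
        clean, li, li_ref = _render_layers(spec, geom, jitter, bump)
        if label == "AMD":
            mask = li != li_ref
        else:
            mask = np.zeros_like(clean, dtype=bool)
        if label == "DME":
            mask = _place_dme_blobs(spec, geom, rng, clean, jitter)
        clean = gaussian_filter(clean, 0.8)
        k = 1.0 / spec.speckle_level**2
        speckled = clean * rng.gamma(k, 1.0 / k, clean.shape)
        image = np.clip(speckled, 0.0, 1.0)
        scans.append(PhantomScan(image=image, subject_id=sid, label=label,
                                 lesion_mask=mask,
                                 meta={"curve_poly": geom["poly"],
                                       "slice_jitter": jitter,
                                       "top": geom["top"]}))
    return scans


def generate_dataset(spec: PhantomSpec) -> tuple[pd.DataFrame, list[PhantomScan]]:
    """Generate the full phantom dataset and its manifest.

    Subject seeds are spawned deterministically from ``spec.seed``, so equal
    specs give bit-identical datasets.
    """
    scans: list[PhantomScan] = []
    rows = []
    for ci, label in enumerate(spec.classes):
        for si in range(spec.n_subjects_per_class):
            seed = int(np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(ci, si)).generate_state(1)[0] % (2**31))
            sid = f"{label}{si + 1:02d}"
            for k, scan in enumerate(generate_subject(label, spec, seed, subject_id=sid)):
                rows.append({"subject_id": sid, "label": label, "scan_index": k,
                             "index": len(scans)})
                scans.append(scan)
    manifest = pd.DataFrame(rows)
    return manifest, scans


def write_dataset(manifest: pd.DataFrame, scans: list[PhantomScan], out_dir) -> pd.DataFrame:
    """Write 8-bit PNG images + masks and a manifest CSV; returns the manifest
    with image_path/mask_path columns filled in."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    image_paths, mask_paths = [], []
    for _, row in manifest.iterrows():
        scan = scans[int(row["index"])]
        stem = f"{row.subject_id}_{int(row.scan_index):03d}"
        ip = out / "images" / f"{stem}.png"
        mp = out / "masks" / f"{stem}.png"
        iio.imwrite(ip, np.round(scan.image * 255).astype(np.uint8))
        iio.imwrite(mp, (scan.lesion_mask * 255).astype(np.uint8))
        image_paths.append(str(ip))
        mask_paths.append(str(mp))
    manifest["image_path"] = image_paths
    manifest["mask_path"] = mask_paths
    manifest.drop(columns=["index"]).to_csv(out / "manifest.csv", index=False)
    return manifest


def lesion_contrast(scan: PhantomScan, annulus_width: int = 4) -> float:
    """Mean intensity inside the lesion mask minus the mean of the surrounding
    annulus (negative for DME fluid pockets).  Undefined for empty masks."""
    from scipy.ndimage import binary_dilation

    if not scan.lesion_mask.any():
        warnings.warn("lesion_contrast on an empty mask", stacklevel=2)
        return float("nan")
    ring = binary_dilation(scan.lesion_mask, iterations=annulus_width) & ~scan.lesion_mask
    return float(scan.image[scan.lesion_mask].mean() - scan.image[ring].mean())
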