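"""Non-subsampled X-let transforms: a-trous Haar 2D-DWT, circlet filter bank,
and their channel concatenation ("CircWave").

All transforms here are *non-subsampled*: every sub-band keeps the source
resolution, so the sub-band stack is shift-equivariant and can be fed to a
CNN as co-registered channels.  Boundary handling is periodic throughout,
which makes shift-equivariance exact for the a-trous DWT and FFT-natural for
the circlet.

Haar filters are normalized as tensor products of [1/2, 1/2] and
[1/2, -1/2]; with this scaling the four level-1 sub-bands sum exactly to the
parent signal, so synthesis is the telescoping channel sum and the round trip
is exact to machine precision.

The circlet is realized as an isotropic radial filter bank: raised-cosine
(Meyer-style) windows over log2 radial frequency with dyadically spaced band
boundaries, one low-pass plus ``stages`` ring-shaped band-passes, normalized
to an amplitude partition of unity (the channel sum reproduces the image).
Ring-shaped image structure whose dominant radial frequency falls in band j
concentrates its energy in channel j, which is the property exploited for
fluid pockets ("appearing circles") in DME B-scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

Channel = tuple[str, int, str]  # (transform_name, stage, band_name)


@dataclass
class SubbandStack:
    """H x W x C stack of co-registered sub-bands with per-channel metadata."""

    data: np.ndarray
    channels: list[Channel]
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channels):
            raise ValueError("data must be H x W x C with C == len(channels)")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


# ---------------------------------------------------------------------------
# non-subsampled Haar 2D-DWT (a-trous / stationary, periodic boundary)
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, axis: int, step: int) -> np.ndarray:
    return 0.5 * (x + np.roll(x, -step, axis=axis))


def _detail(x: np.ndarray, axis: int, step: int) -> np.ndarray:
    return 0.5 * (x - np.roll(x, -step, axis=axis))


def ns_haar_dwt2(image: np.ndarray, levels: int = 2) -> SubbandStack:
    """A-trous Haar decomposition.

    Channels are ``[A_L, H_1, V_1, D_1, ..., H_L, V_L, D_L]`` (3L+1 total),
    every one at the source resolution.  H_j differences along rows (responds
    to horizontal edges), V_j along columns, D_j along both.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    a = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("image must be finite")
    details: list[np.ndarray] = []
    channels: list[Channel] = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        sr = _smooth(a, 0, step)      # smooth along rows axis
        dr = _detail(a, 0, step)
        h = _smooth(dr, 1, step)      # detail across rows, smooth across cols
        v = _detail(sr, 1, step)
        d = _detail(dr, 1, step)
        a = _smooth(sr, 1, step)
        details.extend([h, v, d])
        channels.extend([("dwt", j, "H"), ("dwt", j, "V"), ("dwt", j, "D")])
    data = np.stack([a] + details, axis=-1)
    meta = [("dwt", levels, "A")] + channels
    return SubbandStack(data=data, channels=meta, source_shape=a.shape)


def ns_haar_idwt2(stack: SubbandStack) -> np.ndarray:
    """Synthesis for :func:`ns_haar_dwt2`: the telescoping channel sum."""
    names = {c[0] for c in stack.channels}
    if names != {"dwt"}:
        raise ValueError(f"stack does not come from ns_haar_dwt2 (channels {names})")
    bands = {c[2] for c in stack.channels}
    if "A" not in bands:
        raise ValueError("stack is missing the approximation channel")
    return stack.data.sum(axis=-1)


# ---------------------------------------------------------------------------
# circlet: isotropic radial Meyer-window filter bank
# ---------------------------------------------------------------------------

@dataclass
class CircletBank:
    """Frequency-domain filters of the circlet: low-pass + ring band-passes.

    ``filters[c]`` is real and in [0, 1]; the bank sums to 1 at every
    frequency sample.  ``radii[c]`` is the characteristic radial frequency
    (cycles/pixel) of each band (0 for the low-pass).
    """

    filters: np.ndarray          # C x H x W
    radii: np.ndarray
    stages: int


def _meyer_step(rho: np.ndarray, boundary: float, width_octaves: float) -> np.ndarray:
    """Smooth raised-cosine step 0 -> 1 around ``boundary`` in log2 frequency."""
    with np.errstate(divide="ignore"):
        u = np.where(rho > 0, np.log2(np.maximum(rho, 1e-300) / boundary), -np.inf)
    u = np.clip(u / width_octaves, -1.0, 1.0)
    return np.sin(np.pi * (u + 1.0) / 4.0) ** 2


def build_circlet_bank(shape: tuple[int, int], stages: int = 6,
                       transition: float = 0.5) -> CircletBank:
    """Build the circlet filter bank for images of the given shape.

    Band boundaries are dyadic, ``nyquist / 2**(stages - j)`` for
    j = 1..stages, each with a raised-cosine transition of ``transition``
    octaves; band j is the difference of consecutive smooth steps, so the
    bank sums to exactly 1 everywhere and the DC sample belongs entirely to
    the low-pass.
    """
    if stages < 1:
        raise ValueError("stages must be >= 1")
    if min(shape) < 8:
        raise ValueError("shape must be at least 8x8 (bands degenerate below)")
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fy, fx)
    nyquist = 0.5
    # boundary j sits half an octave below the peak of band j+1, so band
    # peaks fall at nyquist * 2**(j - stages), the last one exactly at Nyquist
    boundaries = [nyquist * 2.0 ** (j - stages - 0.5) for j in range(1, stages + 1)]
    steps = [_meyer_step(rho, b, transition) for b in boundaries]
    filters = [1.0 - steps[0]]
    radii = [0.0]
    for j in range(stages):
        upper = steps[j + 1] if j + 1 < stages else np.zeros_like(rho)
        filters.append(steps[j] - upper)
        radii.append(float(nyquist * 2.0 ** (j + 1 - stages)))
    return CircletBank(filters=np.stack(filters), radii=np.asarray(radii),
                       stages=stages)


def circlet_transform(image: np.ndarray, stages: int = 6,
                      bank: CircletBank | None = None) -> SubbandStack:
    """Decompose an image with the circlet bank.

    Channels are ``[lowpass, band_1 (coarsest), ..., band_stages]``; because
    the bank is an amplitude partition of unity, the channel sum reproduces
    the image.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if bank is None:
        bank = build_circlet_bank(image.shape, stages)
    spectrum = np.fft.fft2(image)
    data = np.real(np.fft.ifft2(bank.filters * spectrum[None]))
    channels: list[Channel] = [("circlet", 0, "lowpass")]
    channels += [("circlet", j, "band") for j in range(1, bank.stages + 1)]
    return SubbandStack(data=np.moveaxis(data, 0, -1), channels=channels,
                        source_shape=image.shape)


# ---------------------------------------------------------------------------
# CircWave and helpers
# ---------------------------------------------------------------------------

def circwave(image: np.ndarray, dwt_levels: int = 2, circ_stages: int = 6) -> SubbandStack:
    """Channel-wise concatenation of the NS Haar DWT and circlet stacks
    (DWT channels first); defaults give (3*2+1) + (6+1) = 14 channels."""
    dwt = ns_haar_dwt2(image, dwt_levels)
    circ = circlet_transform(image, circ_stages)
    return SubbandStack(data=np.concatenate([dwt.data, circ.data], axis=-1),
                        channels=dwt.channels + circ.channels,
                        source_shape=dwt.source_shape)


def original_stack(image: np.ndarray) -> SubbandStack:
    """The untransformed image as a single-channel stack (baseline input)."""
    image = np.asarray(image, dtype=float)
    return SubbandStack(data=image[..., None],
                        channels=[("original", 0, "image")],
                        source_shape=image.shape)


def resize_stack(stack: SubbandStack, side: int) -> SubbandStack:
    """Bilinear per-channel resize to ``side`` x ``side``; metadata unchanged."""
    if side < 8:
        raise ValueError("side must be >= 8")
    if stack.data.shape[:2] == (side, side):
        return SubbandStack(stack.data.copy(), list(stack.channels), stack.source_shape)
    down = side < max(stack.data.shape[:2])
    data = _sk_resize(stack.data, (side, side), order=1, anti_aliasing=down,
                      mode="reflect")
    return SubbandStack(data=data, channels=list(stack.channels),
                        source_shape=stack.source_shape)


def _coarse_to_fine_order(stack: SubbandStack) -> list[int]:
    """Channel indices sorted from lowest to highest spatial frequency."""
    def rank(idx_channel):
        _, (name, stage, band) = idx_channel
        if name == "dwt":
            # approximation first, then detail levels from coarsest (large
            # stage = large a-trous step = low frequency) to finest
            return (0.0,) if band == "A" else (1.0, -stage, "HVD".index(band))
        return (0.0,) if band == "lowpass" else (1.0, stage - 10_000)
    order = sorted(enumerate(stack.channels), key=rank)
    return [i for i, _ in order]


def reconstruct_from_selection(image: np.ndarray, transform: str,
                               keep: np.ndarray, dwt_levels: int = 2,
                               circ_stages: int = 6) -> np.ndarray:
    """Forward-transform, zero the channels where ``keep`` is False, and
    sum-reconstruct; output clipped to [0, 1]."""
    if transform == "dwt":
        stack = ns_haar_dwt2(image, dwt_levels)
    elif transform == "circlet":
        stack = circlet_transform(image, circ_stages)
    else:
        raise ValueError(f"unknown transform {transform!r}; expected dwt or circlet")
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (stack.n_channels,):
        raise ValueError("keep mask length must equal the channel count")
    return np.clip(stack.data[..., keep].sum(axis=-1), 0.0, 1.0)


def reconstruct_from_half(image: np.ndarray, transform: str,
                          half: str = "lowfreq", dwt_levels: int = 2,
                          circ_stages: int = 6) -> np.ndarray:
    """Reconstruct a B-scan from half of its sub-bands.

    Channels are ranked coarse to fine; ``lowfreq`` keeps the first
    ceil(C/2), ``highfreq`` the remaining floor(C/2).  ``all``/``none`` are
    accepted for degenerate checks.
    """
    if transform == "dwt":
        stack = ns_haar_dwt2(image, dwt_levels)
    elif transform == "circlet":
        stack = circlet_transform(image, circ_stages)
    else:
        raise ValueError(f"unknown transform {transform!r}; expected dwt or circlet")
    c = stack.n_channels
    keep = np.zeros(c, dtype=bool)
    order = _coarse_to_fine_order(stack)
    n_low = int(np.ceil(c / 2))
    if half == "lowfreq":
        keep[order[:n_low]] = True
    elif half == "highfreq":
        keep[order[n_low:]] = True
    elif half == "all":
        keep[:] = True
    elif half == "none":
        pass
    else:
        raise ValueError(f"unknown half {half!r}")
    return np.clip(stack.data[..., keep].sum(axis=-1), 0.0, 1.0)


# ---------------------------------------------------------------------------
# transform registry (pluggable comparators share the SubbandStack contract)
# ---------------------------------------------------------------------------

_REGISTRY: dict = {
    "original": original_stack,
    "dwt": ns_haar_dwt2,
    "circlet": circlet_transform,
    "circwave": circwave,
}


def register_transform(name: str, fn) -> None:
    """Register an additional X-let (e.g. DTCW/shearlet comparators); ``fn``
    must map (image, **params) to a SubbandStack."""
    _REGISTRY[name] = fn


def get_transform(name: str):
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown transform {name!r}; registered: "
                         f"{sorted(_REGISTRY)}") from None


def transform_image(image: np.ndarray, name: str, side: int | None = 64,
                    **params) -> SubbandStack:
    """Apply a registered transform and optionally resize the stack."""
    stack = get_transform(name)(image, **params)
    if side is not None:
        stack = resize_stack(stack, side)
    return stack
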