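"""Stimulus generation: orientation filtering and image manipulations.

Stimuli are grayscale luminance images on a nominal [0, 1] scale, filtered in
the Fourier domain with wrapped-Gaussian orientation filters.  Orientation
labels follow the image-plane convention used throughout the face-perception
literature: 0 deg = vertical structure (vertical edges), 90 deg = horizontal
structure.  Because the Fourier energy of an oriented grating lies along the
frequency axis perpendicular to its stripes, the 90 deg filter passes energy
on the vertical frequency axis, i.e. gratings whose luminance varies along
the vertical pixel axis.

The pipeline mirrors the standard psychophysics recipe: mirror-pad to avoid
border artefacts, normalize to zero mean / unit RMS contrast, multiply the
amplitude spectrum by the orientation filter, crop, re-normalize to the
display range (mean 0.5, RMS contrast 0.12), clip, then apply negation /
inversion and blend an elliptical aperture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

WRAP_PERIOD_DEG = 180.0
#: number of wrap terms on each side; truncation error < 1e-300 for sigma=25
_WRAP_K = 3

DEFAULT_FILTER_CENTERS = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
DEFAULT_SIGMA_DEG = 25.0
DEFAULT_TARGET_MEAN = 0.5
DEFAULT_TARGET_RMS = 0.12
DEFAULT_PAD_PX = 100
DEFAULT_SHAPE = (309, 302)  # rows x cols


@dataclass(frozen=True)
class OrientationFilterSpec:
    """A wrapped-Gaussian orientation filter on the 180-deg circle."""

    center_deg: float
    sigma_deg: float = DEFAULT_SIGMA_DEG

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_deg < WRAP_PERIOD_DEG:
            raise ValueError(f"center_deg must be in [0, 180): {self.center_deg}")
        if self.sigma_deg <= 0:
            raise ValueError(f"sigma_deg must be positive: {self.sigma_deg}")


@dataclass(frozen=True)
class NoiseMaskSpec:
    """1/f noise mask matched in luminance statistics to the face stimuli."""

    diameter_px: int = 380
    spectral_exponent: float = 1.0
    target_mean: float = DEFAULT_TARGET_MEAN
    target_rms: float = DEFAULT_TARGET_RMS

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("image must be 2D with at least 2x2 pixels")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    return arr


def mirror_pad(img, pad_px: int) -> np.ndarray:
    """Pad an image by mirror reflection (edge pixel not duplicated)."""
    arr = _as_image(img)
    if pad_px < 0:
        raise ValueError("pad_px must be >= 0")
    if pad_px == 0:
        return arr.copy()
    if pad_px >= min(arr.shape):
        raise ValueError(
            f"pad_px={pad_px} exceeds image extent {arr.shape}; reflection undefined"
        )
    return np.pad(arr, pad_px, mode="reflect")


def crop_center(img, shape: tuple[int, int]) -> np.ndarray:
    """Crop the central ``shape`` region (inverse of a symmetric pad)."""
    arr = _as_image(img)
    r0 = (arr.shape[0] - shape[0]) // 2
    c0 = (arr.shape[1] - shape[1]) // 2
    if r0 < 0 or c0 < 0:
        raise ValueError("crop shape larger than image")
    return arr[r0 : r0 + shape[0], c0 : c0 + shape[1]].copy()


def normalize_image(img, target_mean: float, target_rms: float) -> np.ndarray:
    """Affinely rescale to an exact mean luminance and RMS contrast.

    RMS contrast is the population standard deviation of luminance about the
    mean.  Raises on a constant (zero-variance) image.
    """
    arr = _as_image(img)
    sd = arr.std()
    if sd == 0:
        raise ValueError("cannot normalize a zero-variance image")
    return (arr - arr.mean()) / sd * target_rms + target_mean


def wrapped_gaussian_weight(theta_deg, spec: OrientationFilterSpec, *, peak_normalized: bool = True):
    """Wrapped-Gaussian weight at orientation ``theta_deg``.

    Sum of Gaussian lobes at ``center + 180k`` for ``|k| <= 3``, optionally
    rescaled so the weight at the filter center is exactly 1.
    """
    theta = np.asarray(theta_deg, dtype=float)
    two_s2 = 2.0 * spec.sigma_deg**2
    ks = np.arange(-_WRAP_K, _WRAP_K + 1) * WRAP_PERIOD_DEG
    d = theta[..., None] - spec.center_deg + ks
    w = np.exp(-(d**2) / two_s2).sum(axis=-1)
    if peak_normalized:
        w = w / np.exp(-(ks**2) / two_s2).sum()
    return w if w.shape else float(w)


def _orientation_map_deg(shape: tuple[int, int]) -> np.ndarray:
    """Image-plane orientation (deg, mod 180) of each FFT frequency sample.

    The orientation assigned to frequency (fx, fy) is that of the image
    structure carrying energy there: atan2(fy, fx), so the vertical frequency
    axis (fx=0) maps to 90 deg = horizontal structure.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    theta = np.degrees(np.arctan2(fy, fx)) % WRAP_PERIOD_DEG
    return np.broadcast_to(theta, shape).copy()


def filter_weight_map(shape: tuple[int, int], spec: OrientationFilterSpec) -> np.ndarray:
    """Per-frequency filter weights; DC passes unmodified."""
    w = wrapped_gaussian_weight(_orientation_map_deg(shape), spec)
    w[0, 0] = 1.0
    return w


def orientation_filter(img, spec: OrientationFilterSpec) -> np.ndarray:
    """Multiply the image's amplitude spectrum by the orientation filter."""
    arr = _as_image(img)
    spectrum = np.fft.fft2(arr)
    filtered = spectrum * filter_weight_map(arr.shape, spec)
    return np.real(np.fft.ifft2(filtered))


def clipped_fraction(img, lo: float = 0.0, hi: float = 1.0) -> float:
    """Proportion of pixels outside [lo, hi]."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    arr = np.asarray(img, dtype=float)
    return float(np.mean((arr < lo) | (arr > hi)))


def negate_image(img) -> np.ndarray:
    """Reverse contrast polarity by reflecting luminance about 0.5."""
    return 1.0 - _as_image(img)


def invert_image(img) -> np.ndarray:
    """Rotate 180 deg in the picture plane (reversal of both axes)."""
    return _as_image(img)[::-1, ::-1].copy()


def make_aperture_mask(images, *, threshold: float = 0.05, ramp_px: int = 6) -> np.ndarray:
    """Elliptical aperture fitted to the average image's face region.

    Pixels of the average image deviating from the mid-grey background by more
    than ``threshold`` define the face region; the mask is the smallest
    axis-aligned ellipse covering it, with a cosine ramp of ``ramp_px`` at the
    edge (1 inside = face visible, 0 outside = background grey).
    """
    imgs = [np.asarray(im, dtype=float) for im in images]
    if not imgs:
        raise ValueError("need at least one image")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("all images must share dimensions")
    avg = np.mean(imgs, axis=0)
    dev = np.abs(avg - 0.5) > threshold
    if not dev.any():
        return np.zeros(shape)
    rows, cols = np.nonzero(dev)
    cy, cx = (rows.min() + rows.max()) / 2.0, (cols.min() + cols.max()) / 2.0
    ry = max((rows.max() - rows.min()) / 2.0, 1.0)
    rx = max((cols.max() - cols.min()) / 2.0, 1.0)
    yy, xx = np.indices(shape)
    # radial coordinate of the ellipse (1 on the boundary)
    rho = np.hypot((yy - cy) / ry, (xx - cx) / rx)
    # cosine ramp over ~ramp_px pixels at the boundary, in normalized units
    eps = ramp_px / max(rx, ry)
    mask = np.clip((1.0 + eps - rho) / (2.0 * eps), 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * mask)


def blend_aperture(img, mask, background: float = 0.5) -> np.ndarray:
    """Blend an image with the grey background through an aperture mask."""
    arr = _as_image(img)
    m = np.asarray(mask, dtype=float)
    if m.shape != arr.shape:
        raise ValueError("mask and image dimensions differ")
    return m * arr + (1.0 - m) * background


def make_noise_mask(spec: NoiseMaskSpec, seed: int) -> np.ndarray:
    """Seeded 1/f noise image normalized to the target luminance statistics."""
    rng = np.random.default_rng(seed)
    n = spec.diameter_px
    white = rng.standard_normal((n, n))
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # avoid division by zero; DC replaced below anyway
    amp = f**-spec.spectral_exponent
    amp[0, 0] = 0.0
    noise = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
    return normalize_image(noise, spec.target_mean, spec.target_rms)


# ---------------------------------------------------------------------------
# synthetic face generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentityParams:
    """Procedural face geometry, in fractions of image height/width.

    A face is a bright ellipse ("skin") on mid-grey with darker horizontal
    bands for brows, eyes, nose shadow and mouth — reproducing the vertical
    alternation of light and dark that carries the horizontal-orientation
    energy of real face images.
    """

    head_ry: float = 0.42
    head_rx: float = 0.33
    skin_tone: float = 0.72
    #: (vertical center, half height, half width, darkness) per feature band
    bands: tuple[tuple[float, float, float, float], ...] = (
        (-0.17, 0.022, 0.24, 0.30),  # brows
        (-0.09, 0.030, 0.26, 0.38),  # eyes
        (0.10, 0.020, 0.10, 0.22),  # nose shadow / nostrils
        (0.24, 0.028, 0.18, 0.34),  # mouth
    )
    jitter_scale: float = 0.012
    smooth_px: float = 2.0


def generate_synthetic_face(
    identity_params: IdentityParams,
    seed: int,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> np.ndarray:
    """Render one face-like image; deterministic given (params, seed).

    Images of the same identity share geometry and differ only by the
    per-image jitter of band positions and sizes.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.indices(shape)
    img = np.full(shape, 0.5)
    head = ((yy - cy) / (identity_params.head_ry * h)) ** 2 + (
        (xx - cx) / (identity_params.head_rx * w)
    ) ** 2 <= 1.0
    img[head] = identity_params.skin_tone
    js = identity_params.jitter_scale
    for by, bh, bw, dark in identity_params.bands:
        by = by + js * rng.standard_normal()
        bh = max(bh * (1.0 + 0.5 * js / 0.012 * rng.standard_normal() * 0.2), 0.005)
        bw = max(bw + js * rng.standard_normal(), 0.02)
        band = (
            (np.abs(yy - (cy + by * h)) <= bh * h)
            & (np.abs(xx - cx) <= bw * w)
            & head
        )
        img[band] = identity_params.skin_tone - dark
    if identity_params.smooth_px > 0:
        img = ndimage.gaussian_filter(img, identity_params.smooth_px)
    return img


def make_identity_pool(n_identities: int, seed: int) -> list[IdentityParams]:
    """Draw distinct identities by perturbing the default geometry."""
    rng = np.random.default_rng(seed)
    base = IdentityParams()
    pool = []
    for _ in range(n_identities):
        bands = tuple(
            (
                by + 0.02 * rng.standard_normal(),
                max(bh * np.exp(0.2 * rng.standard_normal()), 0.008),
                max(bw * np.exp(0.15 * rng.standard_normal()), 0.05),
                float(np.clip(dark * np.exp(0.2 * rng.standard_normal()), 0.08, 0.45)),
            )
            for by, bh, bw, dark in base.bands
        )
        pool.append(
            replace(
                base,
                head_ry=float(base.head_ry * np.exp(0.06 * rng.standard_normal())),
                head_rx=float(base.head_rx * np.exp(0.06 * rng.standard_normal())),
                skin_tone=float(np.clip(base.skin_tone + 0.04 * rng.standard_normal(), 0.6, 0.85)),
                bands=bands,
            )
        )
    return pool


# ---------------------------------------------------------------------------
# full stimulus pipeline
# ---------------------------------------------------------------------------


@dataclass
class StimulusSet:
    """All rendered stimuli plus per-image bookkeeping.

    ``images`` maps (stimulus_type, filter_label, identity, image_index) to
    the final image; ``manifest`` records the clipped-pixel fraction measured
    after the final normalization, before clipping to [0, 1].
    """

    images: dict = field(default_factory=dict)
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_stimulus_set(
    n_identities: int = 10,
    images_per_identity: int = 3,
    *,
    filter_centers=DEFAULT_FILTER_CENTERS,
    sigma_deg: float = DEFAULT_SIGMA_DEG,
    pad_px: int = DEFAULT_PAD_PX,
    target_mean: float = DEFAULT_TARGET_MEAN,
    target_rms: float = DEFAULT_TARGET_RMS,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    stimulus_types=("natural", "inverted", "negated"),
    include_fullspectrum: bool = True,
    seed: int = 0,
) -> StimulusSet:
    """Generate the full filtered stimulus set from synthetic faces.

    Per image: mirror-pad, normalize to (0, 1), orientation-filter, crop,
    normalize to (target_mean, target_rms), record the clipped fraction, clip,
    derive negated/inverted versions, and blend the elliptical aperture.
    """
    identities = make_identity_pool(n_identities, seed)
    rng = np.random.default_rng(seed + 1)
    faces = {
        (i, j): generate_synthetic_face(ident, int(rng.integers(2**31)), shape)
        for i, ident in enumerate(identities)
        for j in range(images_per_identity)
    }
    aperture = make_aperture_mask(list(faces.values()))

    labels = [f"{int(c)}" for c in filter_centers]
    specs = {lab: OrientationFilterSpec(c, sigma_deg) for lab, c in zip(labels, filter_centers)}
    if include_fullspectrum:
        labels.append("fullspectrum")

    out = StimulusSet()
    rows = []
    for (ident, idx), face in faces.items():
        padded = normalize_image(mirror_pad(face, pad_px), 0.0, 1.0)
        for lab in labels:
            if lab == "fullspectrum":
                core = crop_center(padded, shape)
            else:
                core = crop_center(orientation_filter(padded, specs[lab]), shape)
            core = normalize_image(core, target_mean, target_rms)
            frac = clipped_fraction(core, 0.0, 1.0)
            mean_equalized, rms_equalized = float(core.mean()), float(core.std())
            core = np.clip(core, 0.0, 1.0)
            variants = {
                "natural": core,
                "negated": negate_image(core),
                "inverted": invert_image(core),
            }
            for st in stimulus_types:
                out.images[(st, lab, ident, idx)] = blend_aperture(variants[st], aperture)
            rows.append(
                {
                    "identity": ident,
                    "image": idx,
                    "filter": lab,
                    "clipped_fraction": frac,
                    "mean_equalized": mean_equalized,
                    "rms_equalized": rms_equalized,
                }
            )
    out.manifest = pd.DataFrame(rows)
    return out
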