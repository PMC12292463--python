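"""Synthetic lung-perfusion phantoms with known ground truth.

The clinical data behind this kind of study are private, so every test and
demonstration in the package runs on phantoms generated here. A phantom is a
stylised coronal chest: a body ellipse of moderate intensity, two low-intensity
lung fields, and a recursive bifurcating vascular tree inside each lung whose
branches enhance strongly during the contrast bolus. The noise model is
zero-mean additive Gaussian noise that is spatially correlated in-plane
(smoothed white noise) and modulated by a smooth multiplicative gain field
(higher variance towards the image periphery, mimicking surface-coil
inhomogeneity). Rician effects are deliberately ignored: the downstream
pipeline works on background-subtracted magnitude differences where the
zero-mean additive approximation is standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .series import DynamicSeries

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "PhantomBundle",
    "generate_vessel_tree",
    "generate_phantom",
    "apply_noise",
    "fbm_surface",
]

# geometry of the stylised chest, as fractions of the grid dimensions
_LUNG_SEMIAXES = (0.42, 0.38, 0.18)  # (slice, row, col) fractions
_LUNG_OFFSET_COLS = 0.22             # lateral offset of each lung centre
_BODY_SEMIAXES = (0.49, 0.46, 0.46)
# Vessel calibre is scaled to the grid so that the major vessels stay wider
# than the pixel-shuffle stride (5), as they are at acquisition resolution
# (~1.2 mm/px, central pulmonary arteries tens of pixels across). A phantom
# whose vessels are narrower than the stride would present sub-stride delta
# structures the blind-spot scheme is not designed for.
_TRUNK_RADIUS_FRAC = 0.055           # trunk radius as fraction of min(rows, cols)
_RADIUS_RATIO = 0.75                 # child/parent branch radius
_LENGTH_RATIO = 0.75                 # child/parent branch length
_MIN_RADIUS_VOX = 0.5                # stop subdividing below this radius


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the clean phantom anatomy and its enhancement dynamics.

    ``enhancement_curve`` holds one scale factor in [0, 1] per timepoint with a
    unique maximum (the peak perfusion phase). ``lesion`` optionally carves a
    spherical perfusion deficit: ``(center_zyx, radius_vox, deficit)`` with
    deficit in [0, 1]; enhancement inside the lesion is scaled by
    ``1 - deficit``.
    """

    grid_shape: tuple[int, int, int] = (12, 64, 64)
    n_timepoints: int = 6
    vessel_levels: int = 4
    vessel_contrast: float = 100.0
    parenchyma_level: float = 20.0
    body_level: float = 60.0
    enhancement_curve: tuple[float, ...] = (0.0, 0.15, 0.6, 1.0, 0.7, 0.4)
    perfusion_fraction: float = 1.0
    lesion: tuple[tuple[int, int, int], float, float] | None = None
    #: in-plane acquisition point-spread FWHM in pixels (partial volume).
    #: MR magnitude images are band-limited: razor-edged digital cylinders are
    #: not an achievable signal, so the clean anatomy is smoothed by this PSF.
    psf_fwhm: float = 2.0

    def __post_init__(self) -> None:
        nz, ny, nx = self.grid_shape
        if ny < 16 or nx < 16 or nz < 4:
            raise ValueError("grid must have rows, cols >= 16 and >= 4 slices")
        for name in ("vessel_contrast", "parenchyma_level", "body_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vessel_levels < 1:
            raise ValueError("vessel_levels must be >= 1")
        curve = np.asarray(self.enhancement_curve, dtype=float)
        if len(curve) != self.n_timepoints:
            raise ValueError("enhancement_curve length must equal n_timepoints")
        if curve.min() < 0 or curve.max() > 1:
            raise ValueError("enhancement_curve values must lie in [0, 1]")
        if curve.max() > 0 and np.sum(curve == curve.max()) != 1:
            raise ValueError("enhancement_curve must attain its maximum exactly once")
        if self.lesion is not None:
            _, radius, deficit = self.lesion
            if radius <= 0 or not (0.0 <= deficit <= 1.0):
                raise ValueError("lesion radius must be > 0 and deficit in [0, 1]")
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Spatially correlated, variance-modulated additive Gaussian noise.

    ``correlation_fwhm`` is the FWHM (pixels) of the in-plane Gaussian kernel
    that correlates the noise; 0 means white noise. ``gain_coeffs`` = (c0, c1)
    define the radial-quadratic gain field ``c0 + c1 * (r / r_max)**2``
    measured from the in-plane centre, which must be strictly positive.
    """

    base_sigma: float = 4.0
    correlation_fwhm: float = 3.0
    gain_coeffs: tuple[float, float] = (1.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_sigma <= 0:
            raise ValueError("base_sigma must be > 0")
        if self.correlation_fwhm < 0:
            raise ValueError("correlation_fwhm must be >= 0")
        c0, c1 = self.gain_coeffs
        if c0 <= 0 or c0 + min(c1, 0.0) <= 0:
            raise ValueError("gain field must be strictly positive everywhere")

    def gain_field(self, shape_2d: tuple[int, int]) -> np.ndarray:
        ny, nx = shape_2d
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        r2max = cy**2 + cx**2
        c0, c1 = self.gain_coeffs
        return c0 + c1 * r2 / max(r2max, 1.0)


@dataclass
class PhantomBundle:
    """Clean + noisy series, lung mask and the generating parameters."""

    clean_series: DynamicSeries
    noisy_series: DynamicSeries | None
    lung_mask: np.ndarray
    enhancement: np.ndarray  # 3D per-voxel enhancement amplitude (ground truth)
    spec: PhantomSpec
    noise: NoiseSpec | None = None
    vessel_levels_map: np.ndarray | None = None
    level_voxel_counts: dict[int, int] = field(default_factory=dict)


def _lung_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the left and right lung ellipsoids."""
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    az, ay, ax = (_LUNG_SEMIAXES[0] * nz, _LUNG_SEMIAXES[1] * ny, _LUNG_SEMIAXES[2] * nx)
    cz, cy = (nz - 1) / 2.0, (ny - 1) / 2.0
    masks = []
    for side in (-1.0, 1.0):
        cx = (nx - 1) / 2.0 + side * _LUNG_OFFSET_COLS * nx
        d = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        masks.append(d <= 1.0)
    return masks[0], masks[1]


def _body_mask(shape: tuple[int, int, int]) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    az, ay, ax = (_BODY_SEMIAXES[0] * nz, _BODY_SEMIAXES[1] * ny, _BODY_SEMIAXES[2] * nx)
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    d = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    return d <= 1.0


def _rasterize_segment(levels: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                       radius: float, level: int) -> None:
    """Mark voxels within ``radius`` of segment p0-p1 with ``level`` (first wins)."""
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 1).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(levels.shape) - 1)
    if np.any(hi < lo):
        return
    zz, yy, xx = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1].astype(float)
    p = np.stack([zz, yy, xx], axis=-1)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        t = np.zeros(p.shape[:-1])
    else:
        t = np.clip((p - p0) @ d / denom, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((p - closest) ** 2, axis=-1)
    inside = dist2 <= radius**2
    sub = levels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    sub[inside & (sub == 0)] = level


def _grow_branch(levels: np.ndarray, p0: np.ndarray, direction: np.ndarray,
                 radius: float, length: float, level: int, max_level: int,
                 rng: np.random.Generator, warned: list[bool]) -> None:
    p1 = p0 + direction * length
    _rasterize_segment(levels, p0, p1, radius, level)
    if level >= max_level:
        return
    child_r = radius * _RADIUS_RATIO
    if child_r < _MIN_RADIUS_VOX:
        if not warned[0]:
            warnings.warn(
                "vessel_levels too deep for the grid: stopping at sub-voxel radii",
                stacklevel=2,
            )
            warned[0] = True
        return
    for _ in range(2):
        # jittered branching: rotate the parent direction by ~35 deg +/- 10 deg
        angle = np.deg2rad(35.0 + rng.normal(0.0, 10.0))
        # random axis perpendicular to the parent direction
        rand = rng.normal(size=3)
        axis = np.cross(direction, rand)
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            axis = np.array([1.0, 0.0, 0.0])
        else:
            axis = axis / norm
        # Rodrigues rotation
        d = (direction * np.cos(angle)
             + np.cross(axis, direction) * np.sin(angle)
             + axis * float(axis @ direction) * (1 - np.cos(angle)))
        d = d / np.linalg.norm(d)
        _grow_branch(levels, p1, d, child_r, length * _LENGTH_RATIO,
                     level + 1, max_level, rng, warned)


def generate_vessel_tree(spec: PhantomSpec, seed: int,
                         return_levels: bool = False):
    """Grow one bifurcating vascular tree per lung and rasterize it.

    Returns the binary vessel volume, or ``(binary, levels_map, counts)`` when
    ``return_levels`` is set, where ``levels_map`` labels each vessel voxel
    with the branch generation (1 = trunk) it was first drawn by and
    ``counts`` tallies voxels per generation.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.grid_shape
    levels = np.zeros(spec.grid_shape, dtype=np.int16)
    left, right = _lung_masks(spec.grid_shape)
    warned = [False]
    trunk_r = _TRUNK_RADIUS_FRAC * min(ny, nx)
    trunk_len = 0.22 * ny
    for side in (-1.0, 1.0):
        cx = (nx - 1) / 2.0 + side * _LUNG_OFFSET_COLS * nx
        start = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0 - 0.30 * ny, cx])
        direction = np.array([0.0, 1.0, 0.15 * side])
        direction = direction / np.linalg.norm(direction)
        _grow_branch(levels, start, direction, trunk_r, trunk_len,
                     1, spec.vessel_levels, rng, warned)
    # vessels live inside the lungs only
    lung = left | right
    levels[~lung] = 0
    counts = {int(k): int(np.sum(levels == k)) for k in range(1, spec.vessel_levels + 1)
              if np.any(levels == k)}
    binary = levels > 0
    if return_levels:
        return binary, levels, counts
    return binary


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomBundle:
    """Build the clean dynamic series, lung mask and enhancement ground truth.

    ``clean[t] = static anatomy + enhancement_curve[t] * enhancement`` where the
    enhancement amplitude is ``vessel_contrast`` inside vessels and
    ``perfusion_fraction * parenchyma_level`` in the remaining parenchyma,
    scaled by ``1 - deficit`` inside an optional lesion.
    """
    vessels, levels, counts = generate_vessel_tree(spec, seed, return_levels=True)
    left, right = _lung_masks(spec.grid_shape)
    lung = left | right
    body = _body_mask(spec.grid_shape)

    anatomy = np.zeros(spec.grid_shape, dtype=np.float32)
    anatomy[body & ~lung] = spec.body_level
    anatomy[lung] = spec.parenchyma_level

    enhancement = np.zeros(spec.grid_shape, dtype=np.float32)
    enhancement[lung & ~vessels] = spec.perfusion_fraction * spec.parenchyma_level
    enhancement[vessels] = spec.vessel_contrast
    if spec.lesion is not None:
        (cz, cy, cx), radius, deficit = spec.lesion
        zz, yy, xx = np.mgrid[0:spec.grid_shape[0], 0:spec.grid_shape[1], 0:spec.grid_shape[2]]
        les = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        enhancement[les] *= 1.0 - deficit

    if spec.psf_fwhm > 0:
        # in-plane partial-volume smoothing: the acquisition PSF applies to
        # static anatomy and enhancement alike (linear), so blur each once
        sigma = spec.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        anatomy = ndimage.gaussian_filter(anatomy, sigma=(0, sigma, sigma),
                                          mode="nearest").astype(np.float32)
        enhancement = ndimage.gaussian_filter(enhancement, sigma=(0, sigma, sigma),
                                              mode="nearest").astype(np.float32)

    curve = np.asarray(spec.enhancement_curve, dtype=np.float32)
    data = anatomy[None] + curve[:, None, None, None] * enhancement[None]
    clean = DynamicSeries(data, time_index_of_baseline=0)
    return PhantomBundle(
        clean_series=clean,
        noisy_series=None,
        lung_mask=lung,
        enhancement=enhancement,
        spec=spec,
        vessel_levels_map=levels,
        level_voxel_counts=counts,
    )


def _smoothing_std(sigma: float) -> float:
    """Std of unit white noise after separable 2D Gaussian smoothing (wrap mode)."""
    half = max(int(4.0 * sigma + 0.5), 1)
    impulse = np.zeros(2 * half + 1)
    impulse[half] = 1.0
    k1 = ndimage.gaussian_filter1d(impulse, sigma, mode="constant")
    return float(np.sum(k1**2))  # separable: std_2d = sum(k1d**2)


def apply_noise(clean: DynamicSeries, noise: NoiseSpec) -> DynamicSeries:
    """Add correlated, gain-modulated zero-mean Gaussian noise to a series.

    The white field is smoothed in-plane with a Gaussian of the requested FWHM
    (periodic boundaries, so the field is stationary) and rescaled to unit
    pointwise variance before multiplication by ``base_sigma * gain``, hence
    the local noise std equals ``base_sigma * gain`` everywhere. Noise is
    independent across timepoints and slices.
    """
    rng = np.random.default_rng(noise.seed)
    data = clean.data
    white = rng.standard_normal(data.shape)
    if noise.correlation_fwhm > 0:
        sigma = noise.correlation_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        field_ = ndimage.gaussian_filter(white, sigma=(0, 0, sigma, sigma), mode="wrap")
        field_ /= _smoothing_std(sigma)
    else:
        field_ = white
    gain = noise.gain_field(data.shape[2:])
    noisy = data + noise.base_sigma * gain[None, None] * field_
    return DynamicSeries(noisy.astype(np.float32),
                         voxel_spacing=clean.voxel_spacing,
                         time_index_of_baseline=clean.time_index_of_baseline)


def make_phantom_bundle(spec: PhantomSpec | None = None,
                        noise: NoiseSpec | None = None,
                        seed: int = 0) -> PhantomBundle:
    """Convenience: clean phantom + noise in one call."""
    spec = spec or PhantomSpec()
    noise = noise or NoiseSpec(seed=seed)
    bundle = generate_phantom(spec, seed=seed)
    bundle.noisy_series = apply_noise(bundle.clean_series, noise)
    bundle.noise = noise
    return bundle


def fbm_surface(shape: tuple[int, int], hurst: float, seed: int = 0) -> np.ndarray:
    """Fractional Brownian surface with Hurst exponent H, theoretical FD 3 - H.

    Exact FFT-based synthesis by circulant embedding of Stein's compactly
    supported stationary covariance: the field restricted to the output grid
    has the exact fBm increment structure at every lag, unlike naive
    power-law periodogram synthesis whose fine-scale increments come out too
    smooth (which would bias any fractal-dimension oracle built on it).
    Returned with zero mean and unit std (an affine change, FD-invariant).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = int(max(shape))
    R = 2.0
    alpha = 2.0 * hurst
    if alpha <= 1.5:
        beta, c2 = 0.0, alpha / 2.0
        c0 = 1.0 - alpha / 2.0
    else:
        beta = alpha * (2.0 - alpha) / (3.0 * R * (R * R - 1.0))
        c2 = (alpha - beta * (R - 1.0) ** 2 * (R + 2.0)) / 2.0
        c0 = beta * (R - 1.0) ** 3 + 1.0 - c2
    m = 2 * n  # simulate on [0, R) so the output grid covers [0, 1)
    t = np.arange(m) / m * R
    xx, yy = np.meshgrid(t, t, indexing="ij")
    r = np.sqrt(xx**2 + yy**2)
    rho = np.where(
        r <= 1.0, c0 - r**alpha + c2 * r**2,
        np.where(r <= R, beta * (R - r) ** 3 / np.where(r > 0, r, 1.0), 0.0),
    )
    top = np.concatenate([rho, rho[:, -2:0:-1]], axis=1)
    blk = np.concatenate([top, top[-2:0:-1, :]], axis=0)
    lam = np.sqrt(np.maximum(np.real(np.fft.fft2(blk)) / blk.size, 0.0))
    zc = rng.standard_normal(blk.shape) + 1j * rng.standard_normal(blk.shape)
    field = np.real(np.fft.fft2(lam * zc))[:n, :n]
    field -= field[0, 0]
    # linear-ramp correction restores the exact |d|^(2H) increment variance
    w1, w2 = rng.standard_normal(2)
    tn = t[:n]
    field += np.sqrt(2.0 * c2) * (tn[:, None] * w1 + tn[None, :] * w2)
    surface = field[:shape[0], :shape[1]]
    surface = surface - surface.mean()
    std = surface.std()
    if std > 0:
        surface /= std
    return surface
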