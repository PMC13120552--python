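"""Analytic forward simulation for ideal-collimator SPECT acquisitions.

This module stands in for a full Monte Carlo photon-transport simulation:
emission images are mapped to sinograms by a deterministic attenuated
parallel-beam projector (the "Ideal Collimator": each detector bin accepts
only rays perpendicular to the detector face), counting statistics are
added as independent Poisson draws per bin, and the four standardized
image/sinogram products used for benchmarking are assembled by
:func:`make_standardized_set`:

* the **Source** image -- the phantom's emissivity, the ground truth;
* the **Detector** image -- emissivity weighted by each pixel's
  angle-averaged probability that an emitted photon survives attenuation;
* the **Ideal** image/sinogram -- the infinite-statistics, blur-free limit;
  the image is a converged attenuation-aware MLEM reconstruction of the
  noise-free sinogram and serves as the evaluation reference;
* the **Realistic** image/sinogram -- detector-blurred, finite-count
  acquisition reconstructed the same way.

Scatter, septal penetration and energy response are not modeled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from . import _projector
from .phantom import MU_WATER_159KEV, ActivityImage, AttenuationMap, PhantomSpec, rasterize

__all__ = [
    "AcquisitionConfig",
    "Sinogram",
    "StandardizedSet",
    "parallel_project",
    "attenuated_project",
    "add_counting_noise",
    "make_detector_image",
    "make_standardized_set",
    "projection_matrix",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and statistics level.

    ``total_counts`` is the expected total number of detected counts over
    the whole sinogram; ``statistics_fraction`` scales it (1/8, 1/4, 1/2, 1
    are the standard levels).  ``detector_blur_sigma_mm`` is the 1-D
    Gaussian detector-response width applied along the bin axis for
    "realistic" acquisitions; the ideal collimator itself is blur-free.
    """

    n_projections: int = 128
    angular_range_deg: float = 360.0
    n_bins: int = 256
    total_counts: float = 5.0e6
    statistics_fraction: float = 1.0
    seed: int = 0
    collimator: str = "ideal"
    detector_blur_sigma_mm: float = 0.0
    bin_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_projections < 2:
            raise ValueError("need at least 2 projections")
        if self.total_counts <= 0 or self.statistics_fraction <= 0:
            raise ValueError("total_counts and statistics_fraction must be positive")
        if self.collimator not in ("ideal", "blurred"):
            raise ValueError(f"unknown collimator {self.collimator!r}")

    @property
    def angles_deg(self) -> np.ndarray:
        """Equally spaced view angles covering the angular range."""
        step = self.angular_range_deg / self.n_projections
        return np.arange(self.n_projections) * step

    @property
    def angular_step_deg(self) -> float:
        return self.angular_range_deg / self.n_projections

    @property
    def expected_counts(self) -> float:
        return self.total_counts * self.statistics_fraction


@dataclass
class Sinogram:
    """Projection data: one row per view angle, one column per detector bin.

    ``variance`` holds the per-bin counting variance sigma_i^2 (expected
    counts, floored at one count) once a statistics level has been applied;
    it is None for raw line-integral sinograms.
    """

    values: np.ndarray
    angles_deg: np.ndarray
    bin_mm: float = 1.0
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.angles_deg.size:
            raise ValueError("sinogram shape must be (n_angles, n_bins)")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite and non-negative")
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != self.values.shape:
                raise ValueError("variance shape must match values")
            if np.any(self.variance < 0):
                raise ValueError("variance must be non-negative")

    @property
    def n_projections(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizedSet:
    """The four standardized images and their sinograms."""

    source: ActivityImage
    detector: ActivityImage
    ideal_image: ActivityImage
    ideal_sinogram: Sinogram
    realistic_image: ActivityImage
    realistic_sinogram: Sinogram
    mu: AttenuationMap | None = None


# Small cache of assembled projection matrices, keyed by geometry and the
# attenuation map contents; repeated projections of the same setup (MLEM
# iterations, re-projections for chi^2) then cost one sparse matvec each.
_MATRIX_CACHE: dict = {}
_MATRIX_CACHE_MAX = 6


def _cache_key(grid_n, pixel_mm, config: AcquisitionConfig, mu: np.ndarray | None) -> tuple:
    mu_tag = None if mu is None else hashlib.sha1(np.ascontiguousarray(mu).tobytes()).hexdigest()
    return (
        grid_n,
        float(pixel_mm),
        config.n_projections,
        float(config.angular_range_deg),
        config.n_bins,
        float(config.bin_mm),
        mu_tag,
    )


def projection_matrix(
    grid_n: int,
    pixel_mm: float,
    config: AcquisitionConfig,
    mu: AttenuationMap | None = None,
):
    """The (cached) stacked sparse projection matrix for this geometry."""
    mu_arr = None if mu is None else np.asarray(mu.mu, dtype=float)
    key = _cache_key(grid_n, pixel_mm, config, mu_arr)
    if key not in _MATRIX_CACHE:
        if len(_MATRIX_CACHE) >= _MATRIX_CACHE_MAX:
            _MATRIX_CACHE.pop(next(iter(_MATRIX_CACHE)))
        _MATRIX_CACHE[key] = _projector.stack_angle_matrices(
            config.angles_deg,
            grid_n,
            config.n_bins,
            pixel_mm=pixel_mm,
            bin_mm=config.bin_mm,
            mu=mu_arr,
        )
    return _MATRIX_CACHE[key]


def parallel_project(image: ActivityImage, config: AcquisitionConfig) -> Sinogram:
    """Ideal-collimator line integrals of the emission image at every angle."""
    if config.collimator != "ideal":
        raise ValueError("parallel_project models the ideal collimator only")
    P = projection_matrix(image.grid_n, image.pixel_mm, config, mu=None)
    vals = (P @ image.values.ravel()).reshape(config.n_projections, config.n_bins)
    return Sinogram(values=vals, angles_deg=config.angles_deg, bin_mm=config.bin_mm)


def attenuated_project(
    image: ActivityImage, mu: AttenuationMap, config: AcquisitionConfig
) -> Sinogram:
    """Attenuated line integrals: emission at x is weighted by the survival
    probability exp(-integral of mu) along the ray from x to the detector."""
    if mu.mu.shape != image.values.shape:
        raise ValueError("attenuation map and image grids differ")
    P = projection_matrix(image.grid_n, image.pixel_mm, config, mu=mu)
    vals = (P @ image.values.ravel()).reshape(config.n_projections, config.n_bins)
    # Bilinear sampling can leave tiny negative round-off; clamp.
    np.clip(vals, 0.0, None, out=vals)
    return Sinogram(values=vals, angles_deg=config.angles_deg, bin_mm=config.bin_mm)


def scale_to_counts(sinogram: Sinogram, total_counts: float) -> Sinogram:
    """Rescale a sinogram so that its total equals ``total_counts`` and set
    the counting variance (expected counts, floored at 1)."""
    total = sinogram.values.sum()
    if total <= 0:
        raise ValueError("cannot scale a zero-sum sinogram to a count level")
    expected = sinogram.values * (total_counts / total)
    return Sinogram(
        values=expected,
        angles_deg=sinogram.angles_deg,
        bin_mm=sinogram.bin_mm,
        variance=np.maximum(expected, 1.0),
    )


def add_counting_noise(sinogram: Sinogram, total_counts: float, seed: int) -> Sinogram:
    """Poisson counting noise at a given expected total number of counts.

    The noise-free input is rescaled so its sum equals ``total_counts``,
    then every bin is replaced by an independent Poisson draw with that
    expectation.  The variance field carries the expected counts per bin
    (floored at one count), i.e. the counting-statistics sigma_i^2 used in
    chi^2 weighting.
    """
    expected = scale_to_counts(sinogram, total_counts)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(expected.values).astype(float)
    return Sinogram(
        values=noisy,
        angles_deg=sinogram.angles_deg,
        bin_mm=sinogram.bin_mm,
        variance=expected.variance,
    )


def blur_detector(sinogram: Sinogram, sigma_mm: float) -> Sinogram:
    """1-D Gaussian detector-response blur along the bin axis, per projection."""
    if sigma_mm <= 0:
        return sinogram
    vals = gaussian_filter1d(sinogram.values, sigma=sigma_mm / sinogram.bin_mm, axis=1, mode="constant")
    np.clip(vals, 0.0, None, out=vals)
    return Sinogram(values=vals, angles_deg=sinogram.angles_deg, bin_mm=sinogram.bin_mm)


def make_detector_image(
    source: ActivityImage, mu: AttenuationMap, config: AcquisitionConfig
) -> ActivityImage:
    """Emissivity weighted by the angle-averaged photon survival probability.

    For each acquisition angle the survival factor exp(-integral of mu from
    the pixel to the detector) is evaluated on the projector's ray-sample
    grid and interpolated back to pixel centers; the detector image is the
    source image times the mean factor over angles.
    """
    if mu.mu.shape != source.values.shape:
        raise ValueError("attenuation map and image grids differ")
    n = source.grid_n
    pitch = source.pixel_mm
    s_axis, t_axis, dt = _projector._ray_samples(n, config.n_bins, pitch, config.bin_mm)
    n_bins, n_t = s_axis.size, t_axis.size

    # Pixel centers in mm (row 0 = top).
    coords = (np.arange(n) - (n - 1) / 2.0) * pitch
    px = np.broadcast_to(coords[None, :], (n, n))
    py = np.broadcast_to(-coords[:, None], (n, n))

    p_sum = np.zeros((n, n), dtype=float)
    for th_deg in config.angles_deg:
        th = np.deg2rad(th_deg)
        cos_t, sin_t = np.cos(th), np.sin(th)
        # mu sampled on the (bin, t) ray grid of this angle.
        sx = s_axis[:, None] * cos_t - t_axis[None, :] * sin_t
        sy = s_axis[:, None] * sin_t + t_axis[None, :] * cos_t
        rr = (n - 1) / 2.0 - sy / pitch
        cc = sx / pitch + (n - 1) / 2.0
        mu_s = map_coordinates(mu.mu, [rr.ravel(), cc.ravel()], order=1, cval=0.0)
        mu_s = mu_s.reshape(n_bins, n_t)
        tail = np.cumsum(mu_s[:, ::-1], axis=1)[:, ::-1] - mu_s
        path = dt * (tail + 0.5 * mu_s)
        # Interpolate the path integral at each pixel center's (s, t).
        s_pix = px * cos_t + py * sin_t
        t_pix = -px * sin_t + py * cos_t
        bs = s_pix / config.bin_mm + (n_bins - 1) / 2.0
        bt = t_pix / dt + (n_t - 1) / 2.0
        path_pix = map_coordinates(path, [bs.ravel(), bt.ravel()], order=1, mode="nearest")
        p_sum += np.exp(-path_pix.reshape(n, n))
    p_mean = np.clip(p_sum / config.n_projections, 0.0, 1.0)
    return ActivityImage(values=source.values * p_mean, pixel_mm=source.pixel_mm)


def make_standardized_set(
    spec: PhantomSpec,
    config: AcquisitionConfig,
    recon_settings=None,
    mu_water: float = MU_WATER_159KEV,
) -> StandardizedSet:
    """Build the Source/Detector/Ideal/Realistic standardized products.

    The Ideal sinogram is the attenuated, blur-free projection of the
    source scaled to the expected count level but left noise-free (the
    infinite-statistics limit); the Ideal image is its converged
    attenuation-aware MLEM reconstruction.  The Realistic sinogram applies
    the detector blur and Poisson counting noise, and the Realistic image
    is the same reconstruction recipe applied to it.
    """
    from . import reconstruct
    from .phantom import build_attenuation_map

    if recon_settings is None:
        recon_settings = reconstruct.ReconSettings(algorithm="mlem", max_iterations=200)

    source = rasterize(spec)
    mu = build_attenuation_map(spec, mu_water=mu_water)
    detector = make_detector_image(source, mu, config)

    raw = attenuated_project(source, mu, config)
    # Reconstructions run on the count scale; dividing by the count scale
    # factor returns the images to the source's specific-activity units.
    count_scale = config.expected_counts / raw.values.sum()
    ideal_sino = scale_to_counts(raw, config.expected_counts)
    P = reconstruct.build_system_matrix(spec.grid_n, config, mu=mu, pixel_mm=spec.pixel_mm)
    ideal_res = reconstruct.mlem(ideal_sino, P, recon_settings)
    ideal_image = ActivityImage(values=ideal_res.image.values / count_scale, pixel_mm=spec.pixel_mm)

    blurred = blur_detector(raw, config.detector_blur_sigma_mm)
    realistic_sino = add_counting_noise(blurred, config.expected_counts, config.seed)
    real_res = reconstruct.mlem(realistic_sino, P, recon_settings)
    realistic_image = ActivityImage(values=real_res.image.values / count_scale, pixel_mm=spec.pixel_mm)

    return StandardizedSet(
        source=source,
        detector=detector,
        ideal_image=ideal_image,
        ideal_sinogram=ideal_sino,
        realistic_image=realistic_image,
        realistic_sinogram=realistic_sino,
        mu=mu,
    )
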