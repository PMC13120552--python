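"""Iterative reconstruction: system matrix, ART and MLEM.

Both reconstructors share one sparse system matrix P (rays x pixels) built
with exactly the same ray sampling as the forward simulator, optionally
attenuation-weighted.  ART is the classic Kaczmarz row action

    f  <-  f + relax * (S_i - <P_i, f>) / ||P_i||^2 * P_i

applied ray by ray in an angle-interleaved order, with non-negativity
enforced at the end of each full sweep.  MLEM is the multiplicative
expectation-maximization update

    f_j  <-  f_j / sens_j * sum_i P_ij * g_i / (P f)_i ,   sens_j = sum_i P_ij

which preserves non-negativity and monotonically increases the Poisson
log-likelihood of the measured counts.  Both stop when the reduced chi^2
between the re-projected estimate and the data is stationary (relative
change below a tolerance over a trailing window of iterations) or at the
iteration cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .forward_sim import AcquisitionConfig, Sinogram, projection_matrix
from .phantom import ActivityImage, AttenuationMap

__all__ = [
    "SystemMatrix",
    "ReconSettings",
    "ReconResult",
    "build_system_matrix",
    "art",
    "mlem",
    "chi2_stationary",
    "reduced_chi2",
]

log = logging.getLogger(__name__)


@dataclass
class SystemMatrix:
    """Sparse projection operator P_ij mapping image pixels to sinogram bins."""

    P: sparse.csr_matrix
    grid_n: int
    n_projections: int
    n_bins: int
    angles_deg: np.ndarray
    pixel_mm: float = 1.0
    bin_mm: float = 1.0

    @property
    def n_rays(self) -> int:
        return self.n_projections * self.n_bins

    @property
    def n_pixels(self) -> int:
        return self.grid_n * self.grid_n

    def forward(self, image: np.ndarray | ActivityImage) -> np.ndarray:
        """Image -> sinogram (n_projections x n_bins)."""
        vals = image.values if isinstance(image, ActivityImage) else np.asarray(image)
        return (self.P @ vals.ravel()).reshape(self.n_projections, self.n_bins)

    def adjoint(self, sino: np.ndarray | Sinogram) -> np.ndarray:
        """Sinogram -> image (grid_n x grid_n); the transpose operator."""
        vals = sino.values if isinstance(sino, Sinogram) else np.asarray(sino)
        return (self.P.T @ vals.ravel()).reshape(self.grid_n, self.grid_n)

    def sensitivity(self) -> np.ndarray:
        """Per-pixel sensitivity sum_i P_ij, as a grid_n x grid_n array."""
        return np.asarray(self.P.sum(axis=0)).reshape(self.grid_n, self.grid_n)


@dataclass(frozen=True)
class ReconSettings:
    """Iteration control shared by ART and MLEM."""

    algorithm: str = "mlem"
    max_iterations: int = 100
    chi2_stationarity_tol: float = 1e-3
    chi2_window: int = 3
    relaxation: float = 0.5
    init: str = "uniform"
    record_history: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in ("art", "mlem"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.chi2_stationarity_tol <= 0:
            raise ValueError("chi2 stationarity tolerance must be positive")
        if not 0 < self.relaxation <= 1:
            raise ValueError("relaxation must be in (0, 1]")


@dataclass
class ReconResult:
    """A reconstructed image plus its convergence record."""

    image: ActivityImage
    iterations_run: int
    chi2_history: list[float]
    converged: bool
    checkpoints: dict[int, np.ndarray] = field(default_factory=dict)


def build_system_matrix(
    grid_n: int,
    config: AcquisitionConfig,
    mu: AttenuationMap | None = None,
    pixel_mm: float = 1.0,
) -> SystemMatrix:
    """Assemble the sparse projection matrix for this acquisition geometry.

    The matrix uses the same pixel-driven bilinear ray sampling as the
    forward simulator, so ``forward(image)`` reproduces
    :func:`tomoeval.forward_sim.attenuated_project` to float round-off.
    ``mu=None`` gives the unattenuated operator.
    """
    if mu is not None and mu.mu.shape != (grid_n, grid_n):
        raise ValueError("attenuation map shape does not match grid_n")
    P = projection_matrix(grid_n, pixel_mm, config, mu=mu)
    return SystemMatrix(
        P=P,
        grid_n=grid_n,
        n_projections=config.n_projections,
        n_bins=config.n_bins,
        angles_deg=config.angles_deg,
        pixel_mm=pixel_mm,
        bin_mm=config.bin_mm,
    )


def reduced_chi2(model: np.ndarray, data: np.ndarray, variance: np.ndarray | None) -> float:
    """Mean over bins of (model - data)^2 / sigma^2.

    When no variance is supplied the observed counts, floored at one count,
    serve as the counting-statistics variance.
    """
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if variance is None:
        variance = np.maximum(data, 1.0)
    return float(np.mean((model - data) ** 2 / variance))


def chi2_stationary(chi2_history, tol: float, window: int) -> bool:
    """True when the reduced chi^2 has stabilized.

    The trailing ``window`` successive relative changes must all be below
    ``tol``; histories too short to provide them return False (except a
    history that is too short but already constant over what it has).
    """
    h = [float(v) for v in chi2_history]
    if len(h) < 2 or len(h) < window + 1:
        return False
    changes = []
    for prev, cur in zip(h[-(window + 1):-1], h[-window:]):
        if prev == 0.0 and cur == 0.0:
            changes.append(0.0)
        elif prev == 0.0:
            changes.append(math.inf)
        else:
            changes.append(abs(cur - prev) / abs(prev))
    return max(changes) < tol


def _interleaved_ray_order(n_projections: int, n_bins: int) -> np.ndarray:
    """Angle-interleaved processing order: angles visited with a stride
    close to the golden ratio of the angle count (to decorrelate successive
    hyperplane projections), all bins of an angle consecutively."""
    n = n_projections
    stride = max(1, round(n * 0.382))
    while math.gcd(stride, n) != 1:
        stride += 1
    angle_order = (np.arange(n) * stride) % n
    return (angle_order[:, None] * n_bins + np.arange(n_bins)[None, :]).ravel()


def art(sinogram: Sinogram, P: SystemMatrix, settings: ReconSettings | None = None) -> ReconResult:
    """Algebraic Reconstruction Technique (relaxed Kaczmarz row action)."""
    if settings is None:
        settings = ReconSettings(algorithm="art")
    if settings.algorithm != "art":
        raise ValueError("settings.algorithm must be 'art'")
    if sinogram.values.shape != (P.n_projections, P.n_bins):
        raise ValueError("sinogram shape does not match the system matrix")

    S = sinogram.values.ravel()
    csr = P.P.tocsr()
    indptr, indices, data = csr.indptr, csr.indices, csr.data
    row_norm2 = np.asarray(csr.multiply(csr).sum(axis=1)).ravel()
    order = _interleaved_ray_order(P.n_projections, P.n_bins)
    zero_rows = int(np.count_nonzero(row_norm2[order] == 0))
    if zero_rows:
        log.warning("ART: skipping %d rays with all-zero weights", zero_rows)

    f = np.zeros(P.n_pixels, dtype=float)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, settings.max_iterations + 1):
        for i in order:
            lo, hi = indptr[i], indptr[i + 1]
            if row_norm2[i] == 0.0:
                continue
            cols = indices[lo:hi]
            w = data[lo:hi]
            resid = S[i] - w @ f[cols]
            f[cols] += settings.relaxation * resid / row_norm2[i] * w
        np.clip(f, 0.0, None, out=f)
        chi2 = reduced_chi2(csr @ f, S, None if sinogram.variance is None else sinogram.variance.ravel())
        history.append(chi2)
        log.info("ART sweep %d: reduced chi2 = %.6g", it, chi2)
        if chi2_stationary(history, settings.chi2_stationarity_tol, settings.chi2_window):
            converged = True
            break
    image = ActivityImage(values=f.reshape(P.grid_n, P.grid_n), pixel_mm=P.pixel_mm)
    return ReconResult(
        image=image,
        iterations_run=it,
        chi2_history=history if settings.record_history else [],
        converged=converged,
    )


def mlem(
    sinogram: Sinogram,
    P: SystemMatrix,
    settings: ReconSettings | None = None,
    checkpoints: tuple[int, ...] = (),
    init_image: np.ndarray | None = None,
) -> ReconResult:
    """Maximum Likelihood Expectation Maximization reconstruction.

    The default initial estimate is a uniform positive image scaled so
    that its forward projection carries the same total counts as the data;
    ``init_image`` overrides it with an explicit strictly positive start.
    ``checkpoints`` requests snapshots of the estimate after the listed
    iteration numbers (returned in ``ReconResult.checkpoints``).
    """
    if settings is None:
        settings = ReconSettings(algorithm="mlem")
    if settings.algorithm != "mlem":
        raise ValueError("settings.algorithm must be 'mlem'")
    if sinogram.values.shape != (P.n_projections, P.n_bins):
        raise ValueError("sinogram shape does not match the system matrix")

    g = sinogram.values.ravel()
    var = None if sinogram.variance is None else sinogram.variance.ravel()
    csr = P.P
    sens = np.asarray(csr.sum(axis=0)).ravel()
    dead = sens <= 0
    if dead.any():
        log.warning("MLEM: %d pixels outside every ray; frozen at zero", int(dead.sum()))
    sens_safe = np.where(dead, 1.0, sens)

    if init_image is not None:
        f = np.asarray(init_image, dtype=float).ravel().copy()
        if f.size != P.n_pixels:
            raise ValueError("init_image size does not match the grid")
        if np.any(f[~dead] <= 0):
            raise ValueError("init_image must be strictly positive on live pixels")
    else:
        # Scale-matched uniform start: total forward counts equal total data.
        f = np.ones(P.n_pixels, dtype=float)
        q = csr @ f
        total_q = q.sum()
        if total_q > 0 and g.sum() > 0:
            f *= g.sum() / total_q
    f[dead] = 0.0

    history: list[float] = []
    snaps: dict[int, np.ndarray] = {}
    converged = False
    it = 0
    for it in range(1, settings.max_iterations + 1):
        q = csr @ f
        floor = 1e-12 * q.max() if q.max() > 0 else 1e-12
        ratio = g / np.maximum(q, floor)
        back = csr.T @ ratio
        f = f * back / sens_safe
        f[dead] = 0.0
        chi2 = reduced_chi2(csr @ f, g, var)
        history.append(chi2)
        log.info("MLEM iteration %d: reduced chi2 = %.6g", it, chi2)
        if it in checkpoints:
            snaps[it] = f.reshape(P.grid_n, P.grid_n).copy()
        if chi2_stationary(history, settings.chi2_stationarity_tol, settings.chi2_window) and (
            not checkpoints or it >= max(checkpoints)
        ):
            converged = True
            break
    image = ActivityImage(values=f.reshape(P.grid_n, P.grid_n), pixel_mm=P.pixel_mm)
    return ReconResult(
        image=image,
        iterations_run=it,
        chi2_history=history if settings.record_history else [],
        converged=converged,
        checkpoints=snaps,
    )
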