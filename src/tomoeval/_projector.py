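"""Parallel-beam ray sampling shared by the simulator and the reconstructor.

The projector is pixel-driven: each detector ray is sampled at equally
spaced points (step = half a pixel), each sample reads the image by
bilinear interpolation, and the line integral is the step-weighted sum of
samples.  Attenuation enters as a per-sample survival weight
exp(-integral of mu from the sample to the detector side of the ray), so
the attenuated operator stays linear in the emission image and one sparse
matrix assembly serves both the forward simulation and the system matrix
used by ART/MLEM.

Geometry: angle theta places the detector axis along u = (cos t, sin t);
rays run along v = (-sin t, cos t) with the detector at large +v.  Bin
offsets and ray parameters are in mm; image row 0 is the top (largest y).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["angle_matrix", "stack_angle_matrices", "STEP_FRACTION"]

#: Ray sampling step as a fraction of the pixel pitch.
STEP_FRACTION = 0.5


def _ray_samples(grid_n: int, n_bins: int, pixel_mm: float, bin_mm: float):
    """Bin offsets s (mm), ray sample positions t (mm) and the step dt."""
    s = (np.arange(n_bins) - (n_bins - 1) / 2.0) * bin_mm
    half_diag = grid_n * pixel_mm / np.sqrt(2.0)
    dt = STEP_FRACTION * pixel_mm
    n_t = int(np.ceil(2.0 * half_diag / dt)) + 1
    t = (np.arange(n_t) - (n_t - 1) / 2.0) * dt
    return s, t, dt


def angle_matrix(
    theta_deg: float,
    grid_n: int,
    n_bins: int,
    pixel_mm: float = 1.0,
    bin_mm: float | None = None,
    mu: np.ndarray | None = None,
) -> sparse.csr_matrix:
    """Sparse (n_bins x grid_n^2) projection matrix for one view angle.

    When ``mu`` (a grid_n x grid_n attenuation map in 1/mm) is given, each
    sample's contribution is multiplied by its attenuation survival factor
    along the remainder of the ray toward the detector.
    """
    if bin_mm is None:
        bin_mm = pixel_mm
    s, t, dt = _ray_samples(grid_n, n_bins, pixel_mm, bin_mm)
    th = np.deg2rad(theta_deg)
    cos_t, sin_t = np.cos(th), np.sin(th)

    # Sample coordinates for all (bin, t) pairs, in mm then pixel indices.
    x = s[:, None] * cos_t - t[None, :] * sin_t
    y = s[:, None] * sin_t + t[None, :] * cos_t
    col = x / pixel_mm + (grid_n - 1) / 2.0
    row = (grid_n - 1) / 2.0 - y / pixel_mm

    if mu is not None:
        mu = np.asarray(mu, dtype=float)
        if mu.shape != (grid_n, grid_n):
            raise ValueError("attenuation map shape does not match the grid")
        att_w = _attenuation_weights(mu, row, col, dt)
    else:
        att_w = None

    # Bilinear footprint of in-bounds samples.
    inb = (row > -1) & (row < grid_n) & (col > -1) & (col < grid_n)
    bins_idx, t_idx = np.nonzero(inb)
    r = row[inb]
    c = col[inb]
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    fr = r - r0
    fc = c - c0

    weight = np.full(r.shape, dt, dtype=float)
    if att_w is not None:
        weight = weight * att_w[inb]

    rows_out = []
    cols_out = []
    vals_out = []
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < grid_n) & (cc >= 0) & (cc < grid_n) & (w > 0)
        rows_out.append(bins_idx[ok])
        cols_out.append(rr[ok] * grid_n + cc[ok])
        vals_out.append((w * weight)[ok])

    mat = sparse.coo_matrix(
        (np.concatenate(vals_out), (np.concatenate(rows_out), np.concatenate(cols_out))),
        shape=(n_bins, grid_n * grid_n),
    )
    return mat.tocsr()


def _attenuation_weights(mu: np.ndarray, row: np.ndarray, col: np.ndarray, dt: float) -> np.ndarray:
    """exp(-path integral of mu from each sample to the detector (+t end)).

    mu is sampled bilinearly at the same ray sample points; the path
    integral uses a midpoint rule (half weight on the sample itself).
    """
    from scipy.ndimage import map_coordinates

    mu_s = map_coordinates(mu, [row.ravel(), col.ravel()], order=1, mode="constant", cval=0.0)
    mu_s = mu_s.reshape(row.shape)
    # Reverse cumulative sum along t (last axis): sum over t' > t, plus half
    # of the local sample.
    tail = np.cumsum(mu_s[:, ::-1], axis=1)[:, ::-1] - mu_s
    path = dt * (tail + 0.5 * mu_s)
    return np.exp(-path)


def stack_angle_matrices(
    angles_deg: np.ndarray,
    grid_n: int,
    n_bins: int,
    pixel_mm: float = 1.0,
    bin_mm: float | None = None,
    mu: np.ndarray | None = None,
) -> sparse.csr_matrix:
    """Full (n_angles*n_bins x grid_n^2) projection matrix, rays grouped by angle."""
    blocks = [
        angle_matrix(th, grid_n, n_bins, pixel_mm=pixel_mm, bin_mm=bin_mm, mu=mu)
        for th in np.asarray(angles_deg, dtype=float)
    ]
    return sparse.vstack(blocks, format="csr")
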