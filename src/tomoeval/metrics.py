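"""Residual diagnostics for reconstructed images and sinograms.

Four families of tools:

* **Global scalar metrics** (NMSE, PSNR, CC, SSIM, CNR, reduced chi^2)
  condensing the agreement of a test array X with a reference Y into
  single numbers.
* **Residual maps**: the signed/absolute difference map R = X - Y and the
  chi^2 map (X - Y)^2 / sigma^2 with counting-statistics variances, plus
  their reduced-chi^2 summary.
* **The Structure and Contrast Index (SCI)**: the product of the contrast
  and structure components of the SSIM formalism, evaluated on the
  residual map of mean-normalized inputs, with the luminance component
  discarded (it is identically zero after mean normalization).  The SCI
  quantifies whether residuals still contain organized, recoverable
  structure; it keeps discriminating between high-fidelity reconstructions
  after SSIM and CC have saturated.  Note that in fluctuation-dominated
  regimes (e.g. very noisy ART reconstructions) low SCI reflects masking
  of coherent structure by noise, not superior fidelity.
* **Intensity (gray-value) histogram analysis**: pixel-intensity
  histograms of mean-normalized arrays over shared equal-width bins,
  compared through an unweighted reduced chi^2 over bins.

Uncertainties on any metric come from delete-one jackknife resampling
(projection angles for sinogram-domain metrics, blocks of image rows for
image-domain metrics).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity

from .phantom import RoIMask

__all__ = [
    "ResidualMaps",
    "SCIComponents",
    "IntensityHistogram",
    "MetricReport",
    "normalize_mean",
    "residual_maps",
    "sci",
    "sci_from_components",
    "global_metrics",
    "intensity_histogram",
    "shared_edges",
    "histogram_chi2red",
    "jackknife",
    "jackknife_rows",
]

log = logging.getLogger(__name__)


@dataclass
class ResidualMaps:
    """Signed/absolute difference maps and the variance-weighted chi^2 map."""

    signed: np.ndarray
    absolute: np.ndarray
    chi2_map: np.ndarray
    chi2_reduced: float
    valid: np.ndarray


@dataclass(frozen=True)
class SCIComponents:
    """Luminance, contrast and structure of a residual decomposition.

    ``luminance`` is reported for completeness but excluded from the
    index: ``sci = contrast * structure`` by construction.
    """

    luminance: float
    contrast: float
    structure: float

    @property
    def sci(self) -> float:
        return sci_from_components(self.contrast, self.structure)


@dataclass
class IntensityHistogram:
    """Pixel-intensity histogram over NB equal-width bins."""

    edges: np.ndarray
    counts: np.ndarray
    nb: int


@dataclass
class MetricReport:
    """Named metric values with optional jackknife standard errors."""

    values: dict[str, float] = field(default_factory=dict)
    uncertainties: dict[str, float | None] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_dict(self) -> dict:
        return {
            "values": {k: _jsonable(v) for k, v in self.values.items()},
            "uncertainties": {k: _jsonable(v) for k, v in self.uncertainties.items()},
            "provenance": self.provenance,
        }


def _jsonable(v):
    if v is None:
        return None
    v = float(v)
    if math.isinf(v):
        return "inf" if v > 0 else "-inf"
    if math.isnan(v):
        return "nan"
    return v


def normalize_mean(X: np.ndarray) -> np.ndarray:
    """Divide an array by its mean so the output mean is exactly one."""
    X = np.asarray(X, dtype=float)
    m = X.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError("normalize_mean requires a positive finite mean")
    return X / m


def residual_maps(X: np.ndarray, Y: np.ndarray, variance: np.ndarray) -> ResidualMaps:
    """Difference maps and the counting-statistics chi^2 map of X vs Y.

    Pixels whose variance is non-positive or non-finite are excluded from
    the reduced chi^2 and set to NaN in the chi^2 map.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if X.shape != Y.shape or X.shape != variance.shape:
        raise ValueError("X, Y and variance must share one shape")
    signed = X - Y
    valid = np.isfinite(variance) & (variance > 0)
    if not valid.any():
        raise ValueError("no pixel has a valid variance")
    chi2_map = np.full(X.shape, np.nan)
    chi2_map[valid] = signed[valid] ** 2 / variance[valid]
    return ResidualMaps(
        signed=signed,
        absolute=np.abs(signed),
        chi2_map=chi2_map,
        chi2_reduced=float(np.mean(chi2_map[valid])),
        valid=valid,
    )


def sci_from_components(contrast: float, structure: float) -> float:
    """Compose the Structure and Contrast Index from its two components."""
    return float(contrast) * float(structure)


def sci(
    X: np.ndarray,
    Y: np.ndarray,
    normalize: bool = True,
    windowed: bool = False,
    stabilizer_k: tuple[float, float] = (0.01, 0.03),
) -> SCIComponents:
    """SSIM-style decomposition of the residual map R = X - Y.

    Both arrays are mean-normalized first (so the residual has exactly
    zero mean and the luminance component vanishes); the luminance,
    contrast and structure components are then evaluated between the
    residual R and the normalized reference Y.  The structure component
    uses the *magnitude* of the normalized covariance: the index measures
    how much spatially organized residual structure remains, regardless of
    whether the reconstruction over- or under-shoots where the reference
    is bright, and so decays to zero from above as reconstruction quality
    improves.  By default the components are global (whole-array)
    statistics; ``windowed=True`` averages 11-pixel Gaussian-windowed
    component maps instead.  In either case the index is the exact product
    of the reported contrast and structure.

    Stabilizer constants follow the SSIM convention C = (k * L)^2 with
    L the data range of the normalized reference and k = (0.01, 0.03).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must share one shape")
    if normalize:
        X = normalize_mean(X)
        Y = normalize_mean(Y)
    R = X - Y
    L = float(Y.max() - Y.min())
    if L == 0:
        raise ValueError("constant reference: structure component undefined")
    k1, k2 = stabilizer_k
    C1 = (k1 * L) ** 2
    C2 = (k2 * L) ** 2
    C3 = C2 / 2.0

    if not windowed:
        mu_r, mu_y = R.mean(), Y.mean()
        sd_r, sd_y = R.std(), Y.std()
        cov = float(((R - mu_r) * (Y - mu_y)).mean())
        luminance = 2 * mu_r * mu_y / (mu_r**2 + mu_y**2 + C1)
        contrast = 2 * sd_r * sd_y / (sd_r**2 + sd_y**2 + C2)
        structure = (abs(cov) + C3) / (sd_r * sd_y + C3)
    else:
        sigma = 1.5  # 11-pixel Gaussian window
        mu_r = gaussian_filter(R, sigma, truncate=3.5)
        mu_y = gaussian_filter(Y, sigma, truncate=3.5)
        var_r = np.clip(gaussian_filter(R * R, sigma, truncate=3.5) - mu_r**2, 0, None)
        var_y = np.clip(gaussian_filter(Y * Y, sigma, truncate=3.5) - mu_y**2, 0, None)
        cov = gaussian_filter(R * Y, sigma, truncate=3.5) - mu_r * mu_y
        sd_r, sd_y = np.sqrt(var_r), np.sqrt(var_y)
        luminance = float(np.mean(2 * mu_r * mu_y / (mu_r**2 + mu_y**2 + C1)))
        contrast = float(np.mean(2 * sd_r * sd_y / (var_r + var_y + C2)))
        structure = float(np.mean((np.abs(cov) + C3) / (sd_r * sd_y + C3)))
    return SCIComponents(luminance=float(luminance), contrast=float(contrast), structure=float(structure))


def _pearson(X: np.ndarray, Y: np.ndarray) -> float:
    sx, sy = X.std(), Y.std()
    if sx == 0 or sy == 0:
        raise ValueError("CC undefined for a constant input")
    return float(((X - X.mean()) * (Y - Y.mean())).mean() / (sx * sy))


def _ssim(X: np.ndarray, Y: np.ndarray) -> float:
    drange = float(Y.max() - Y.min())
    if drange == 0:
        raise ValueError("SSIM undefined for a constant reference")
    win = min(11, X.shape[0] - (X.shape[0] + 1) % 2, X.shape[1] - (X.shape[1] + 1) % 2)
    if win < 3:
        raise ValueError("SSIM needs at least a 3-pixel window")
    return float(
        structural_similarity(
            X,
            Y,
            data_range=drange,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            win_size=None if win == 11 else win,
        )
    )


def global_metrics(
    X: np.ndarray,
    Y: np.ndarray,
    variance: np.ndarray | None = None,
    signal_mask: RoIMask | np.ndarray | None = None,
    background_mask: RoIMask | np.ndarray | None = None,
    jackknife_row_block: int | None = None,
    strict: bool = True,
) -> MetricReport:
    """Standard scalar metrics of a test array X against a reference Y.

    NMSE = sum (X-Y)^2 / sum Y^2; PSNR = 10 log10(max(Y)^2 / MSE) (infinite
    for identical inputs); CC is the Pearson correlation; SSIM the
    Gaussian-windowed mean structural similarity with the reference's data
    range; CNR = (mean_signal - mean_background) / sigma_background on X
    (requires ``signal_mask``; the background defaults to the mask
    complement); the reduced chi^2 is included when a variance is given.

    With ``jackknife_row_block`` set, each metric also gets a delete-one
    jackknife standard error over blocks of that many rows (use 1 for
    sinograms: delete one projection angle at a time).  ``strict=False``
    skips metrics that are undefined for the given inputs (with a warning)
    instead of raising.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must share one shape")

    def compute(Xa: np.ndarray, Ya: np.ndarray, var: np.ndarray | None) -> dict[str, float]:
        out: dict[str, float] = {}
        mse = float(((Xa - Ya) ** 2).mean())
        ss_y = float((Ya**2).sum())
        out["nmse"] = float(((Xa - Ya) ** 2).sum() / ss_y) if ss_y > 0 else math.nan
        peak = float(np.abs(Ya).max())
        out["psnr"] = math.inf if mse == 0 else 10.0 * math.log10(peak**2 / mse)
        try:
            out["cc"] = _pearson(Xa, Ya)
        except ValueError:
            if strict:
                raise
            log.warning("skipping CC: constant input")
        try:
            out["ssim"] = _ssim(Xa, Ya)
        except ValueError:
            if strict:
                raise
            log.warning("skipping SSIM: undefined for these inputs")
        if var is not None:
            ok = np.isfinite(var) & (var > 0)
            out["chi2_reduced"] = float(np.mean((Xa - Ya)[ok] ** 2 / var[ok]))
        return out

    values = compute(X, Y, variance)
    uncertainties: dict[str, float | None] = {k: None for k in values}

    if signal_mask is not None:
        sig = signal_mask.mask if isinstance(signal_mask, RoIMask) else np.asarray(signal_mask, bool)
        if background_mask is None:
            bg = ~sig
        else:
            bg = background_mask.mask if isinstance(background_mask, RoIMask) else np.asarray(background_mask, bool)
        sd_bg = X[bg].std() if bg.any() else 0.0
        if sd_bg == 0:
            if strict:
                raise ValueError("CNR undefined: zero background standard deviation")
            log.warning("skipping CNR: zero background standard deviation")
        else:
            values["cnr"] = float((X[sig].mean() - X[bg].mean()) / sd_bg)
            uncertainties["cnr"] = None

    if jackknife_row_block is not None:
        for name in list(values):
            if name == "cnr" or not math.isfinite(values[name]):
                continue

            def stat(rows, _name=name):
                keep = np.concatenate(rows)
                var = None if variance is None else variance[keep]
                return compute(X[keep], Y[keep], var)[_name]

            blocks = _row_blocks(X.shape[0], jackknife_row_block)
            try:
                _, se = jackknife(stat, blocks)
                uncertainties[name] = se
            except ValueError:
                uncertainties[name] = None
    return MetricReport(values=values, uncertainties=uncertainties)


def shared_edges(X: np.ndarray, Y: np.ndarray, nb: int) -> np.ndarray:
    """Equal-width bin edges spanning the joint range of both arrays."""
    if nb < 2:
        raise ValueError("need at least 2 bins")
    lo = min(float(np.min(X)), float(np.min(Y)))
    hi = max(float(np.max(X)), float(np.max(Y)))
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, nb + 1)


def intensity_histogram(X: np.ndarray, nb: int = 256, edges: np.ndarray | None = None) -> IntensityHistogram:
    """Pixel-intensity histogram over NB equal-width bins.

    Pass the edges from :func:`shared_edges` to compare two arrays on a
    common binning; values are clipped into the edge range so every valid
    pixel is counted.
    """
    if nb < 2:
        raise ValueError("need at least 2 bins")
    X = np.asarray(X, dtype=float).ravel()
    X = X[np.isfinite(X)]
    if edges is None:
        counts, edges = np.histogram(X, bins=nb)
    else:
        edges = np.asarray(edges, dtype=float)
        if edges.size != nb + 1:
            raise ValueError("edges must have nb + 1 entries")
        counts, _ = np.histogram(np.clip(X, edges[0], edges[-1]), bins=edges)
    return IntensityHistogram(edges=edges, counts=counts.astype(float), nb=nb)


def histogram_chi2red(SX: IntensityHistogram, SY: IntensityHistogram) -> float:
    """Unweighted reduced chi^2 between two histograms on shared bins:
    (1/NB) * sum (SX_i - SY_i)^2, on the raw-count scale."""
    if SX.nb != SY.nb or not np.allclose(SX.edges, SY.edges):
        raise ValueError("histograms must share bin count and edges")
    return float(np.mean((SX.counts - SY.counts) ** 2))


def jackknife(stat, units) -> tuple[float, float]:
    """Delete-one jackknife standard error of a statistic.

    ``units`` is a sequence of n >= 3 data partitions; ``stat`` maps a list
    of partitions to a scalar.  Returns the full-sample value and
    SE = sqrt(((n-1)/n) * sum (theta_(i) - theta_bar)^2).
    """
    units = list(units)
    n = len(units)
    if n < 3:
        raise ValueError("jackknife needs at least 3 units")
    full = float(stat(units))
    loo = np.array([float(stat(units[:i] + units[i + 1:])) for i in range(n)])
    se = math.sqrt((n - 1) / n * float(((loo - loo.mean()) ** 2).sum()))
    return full, se


def _row_blocks(n_rows: int, block: int) -> list[np.ndarray]:
    return [np.arange(i, min(i + block, n_rows)) for i in range(0, n_rows, block)]


def jackknife_rows(stat2d, arrays: tuple[np.ndarray, ...], block: int = 16) -> tuple[float, float]:
    """Jackknife over row blocks of one or more same-shape 2-D arrays.

    ``stat2d(*subarrays)`` is evaluated with the same row blocks deleted
    from every array; ``block=1`` deletes one projection angle at a time
    (sinograms), ``block=16`` deletes 16-row image bands.
    """
    n_rows = arrays[0].shape[0]
    blocks = _row_blocks(n_rows, block)

    def stat(rows):
        keep = np.concatenate(rows)
        return stat2d(*(a[keep] for a in arrays))

    return jackknife(stat, blocks)
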