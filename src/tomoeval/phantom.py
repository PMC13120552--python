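"""Digital emission phantom: a modified Shepp-Logan activity distribution.

The phantom is a set of nine ellipses (``SRC0`` .. ``SRC8``) on a square
field of view.  ``SRC0`` is the large body/background ellipse which also
acts as the uniform attenuating medium (water, no skull); ``SRC1``/``SRC2``
are the two big side ellipses and ``SRC3``-``SRC8`` are the central ellipse
and the small hotspots.  Two variants are provided which differ only in the
background specific activity: 5 (moderate) or 20 (four times higher, the
deliberately low-contrast benchmarking configuration with activity ratio
background : side ellipses : hotspots = 20 : 5 : 10).

Geometry convention: the image center is (0, 0) mm, x grows rightward
(columns), y grows upward (rows count downward), and a pixel's value is the
specific activity sampled at its center.  Ellipse rotation angles are
counter-clockwise about the ellipse center.  Later-listed ellipses
*override* earlier ones (they replace, not add) -- this is what makes the
variant-2 side ellipses read 5 on top of a background of 20.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EllipseSpec",
    "PhantomSpec",
    "ActivityImage",
    "AttenuationMap",
    "RoIMask",
    "build_shepp_logan_spec",
    "rasterize",
    "build_attenuation_map",
    "make_rois",
    "MU_WATER_159KEV",
]

#: Linear attenuation coefficient of water at ~159 keV, in 1/mm.
MU_WATER_159KEV = 0.0146


@dataclass(frozen=True)
class EllipseSpec:
    """One emitting ellipse of the phantom.

    ``semi_axis_x_mm`` / ``semi_axis_y_mm`` are the semi-axes along x and y
    before rotation; ``angle_deg`` rotates the ellipse counter-clockwise
    about its center.  ``specific_activity`` (activity per surface a.u.)
    is the value painted into the raster.
    """

    label: str
    center_mm: tuple[float, float]
    semi_axis_x_mm: float
    semi_axis_y_mm: float
    angle_deg: float
    surface_over_pi_mm2: float
    surface_au: float
    activity_kbq: float
    specific_activity: float

    def __post_init__(self) -> None:
        if self.semi_axis_x_mm <= 0 or self.semi_axis_y_mm <= 0:
            raise ValueError(f"{self.label}: semi-axes must be positive")

    def contains(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (rotated) ellipse."""
        dx = np.asarray(x_mm, dtype=float) - self.center_mm[0]
        dy = np.asarray(y_mm, dtype=float) - self.center_mm[1]
        phi = np.deg2rad(self.angle_deg)
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        return (u / self.semi_axis_x_mm) ** 2 + (v / self.semi_axis_y_mm) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """An ordered list of ellipses plus the raster geometry.

    Order matters: rasterization paints ellipses first-to-last with
    override semantics.
    """

    ellipses: tuple[EllipseSpec, ...]
    variant: int = 1
    fov_mm: float = 256.0
    grid_n: int = 256

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.grid_n

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "fov_mm": self.fov_mm,
            "grid_n": self.grid_n,
            "ellipses": [
                {
                    "label": e.label,
                    "center_mm": list(e.center_mm),
                    "semi_axis_x_mm": e.semi_axis_x_mm,
                    "semi_axis_y_mm": e.semi_axis_y_mm,
                    "angle_deg": e.angle_deg,
                    "surface_over_pi_mm2": e.surface_over_pi_mm2,
                    "surface_au": e.surface_au,
                    "activity_kbq": e.activity_kbq,
                    "specific_activity": e.specific_activity,
                }
                for e in self.ellipses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        ellipses = tuple(
            EllipseSpec(
                label=e["label"],
                center_mm=tuple(e["center_mm"]),
                semi_axis_x_mm=e["semi_axis_x_mm"],
                semi_axis_y_mm=e["semi_axis_y_mm"],
                angle_deg=e["angle_deg"],
                surface_over_pi_mm2=e["surface_over_pi_mm2"],
                surface_au=e["surface_au"],
                activity_kbq=e["activity_kbq"],
                specific_activity=e["specific_activity"],
            )
            for e in d["ellipses"]
        )
        return cls(ellipses=ellipses, variant=d["variant"], fov_mm=d["fov_mm"], grid_n=d["grid_n"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ActivityImage:
    """2-D grid of specific activity (emissivity) values."""

    values: np.ndarray
    pixel_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ActivityImage requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ActivityImage values must be finite")
        if np.any(self.values < 0):
            raise ValueError("ActivityImage values must be non-negative")

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    def total_activity(self) -> float:
        """Integrated activity: sum of values times pixel area."""
        return float(self.values.sum() * self.pixel_mm**2)


@dataclass
class AttenuationMap:
    """2-D grid of linear attenuation coefficients mu in 1/mm."""

    mu: np.ndarray
    pixel_mm: float = 1.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.ndim != 2:
            raise ValueError("AttenuationMap requires a 2-D array")
        if np.any(self.mu < 0) or not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite and non-negative")


@dataclass
class RoIMask:
    """Binary region-of-interest mask with a label and a kind tag."""

    mask: np.ndarray
    label: str
    kind: str  # one of {"edge", "hotspot", "background"}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("RoIMask requires a 2-D array")
        if not self.mask.any():
            raise ValueError(f"RoI '{self.label}': mask has no true pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


# Phantom geometry and activities of the nine emitting regions:
# label, (cx, cy) mm, semi-x mm, semi-y mm, angle deg, surface/pi mm^2,
# surface a.u., activity kBq, specific activity (kBq per a.u.).
_SHEPP_LOGAN_ROWS = [
    ("SRC0", (0.0, 0.0), 75.0, 100.0, 0.0, 7500.00, 1200.0, 6000.0, 5.0),
    ("SRC1", (24.0, 2.0), 12.0, 34.0, -18.0, 408.00, 65.0, 325.0, 5.0),
    ("SRC2", (-24.0, 2.0), 17.0, 45.0, 18.0, 765.00, 122.0, 610.0, 5.0),
    ("SRC3", (0.0, 40.0), 23.0, 27.0, 0.0, 621.00, 100.0, 1000.0, 10.0),
    ("SRC4", (0.0, 13.0), 5.0, 5.0, 0.0, 25.00, 4.0, 40.0, 10.0),
    ("SRC5", (0.0, -11.0), 5.0, 5.0, 0.0, 25.00, 4.0, 40.0, 10.0),
    ("SRC6", (-11.0, -64.0), 5.0, 2.5, 0.0, 12.50, 2.0, 20.0, 10.0),
    ("SRC7", (0.0, -64.0), 2.5, 2.5, 0.0, 6.25, 1.0, 10.0, 10.0),
    ("SRC8", (9.0, -64.0), 2.5, 5.0, 0.0, 12.50, 2.0, 20.0, 10.0),
]

# Background (SRC0) total activity and specific activity per variant.
_VARIANT_BACKGROUND = {1: (6000.0, 5.0), 2: (24000.0, 20.0)}


def build_shepp_logan_spec(variant: int = 1, grid_n: int = 256, fov_mm: float = 256.0) -> PhantomSpec:
    """Build the 9-region modified Shepp-Logan phantom specification.

    Parameters
    ----------
    variant : {1, 2}
        Background configuration.  Variant 1 has background specific
        activity 5; variant 2 has 20 (same total geometry, four times the
        background activity), giving the low-contrast 20:5:10 ratio of
        background to side ellipses to hotspots.
    grid_n : int
        Pixels per side of the raster grid (>= 32).
    fov_mm : float
        Field-of-view width in mm; the default of 256 gives a 1 mm pixel
        pitch at the default grid.
    """
    if variant not in _VARIANT_BACKGROUND:
        raise ValueError(f"unknown phantom variant {variant!r}; expected 1 or 2")
    if grid_n < 32:
        raise ValueError("grid_n must be at least 32")
    ellipses = []
    for label, c, ax, ay, ang, s_over_pi, s_au, act, spec_act in _SHEPP_LOGAN_ROWS:
        if label == "SRC0":
            act, spec_act = _VARIANT_BACKGROUND[variant]
        ellipses.append(
            EllipseSpec(
                label=label,
                center_mm=c,
                semi_axis_x_mm=ax,
                semi_axis_y_mm=ay,
                angle_deg=ang,
                surface_over_pi_mm2=s_over_pi,
                surface_au=s_au,
                activity_kbq=act,
                specific_activity=spec_act,
            )
        )
    return PhantomSpec(ellipses=tuple(ellipses), variant=variant, fov_mm=fov_mm, grid_n=grid_n)


def pixel_centers_mm(grid_n: int, fov_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinates in mm of every pixel center, as 2-D arrays.

    Row 0 is the top of the image (largest y).
    """
    pitch = fov_mm / grid_n
    coords = (np.arange(grid_n) - (grid_n - 1) / 2.0) * pitch
    x = np.broadcast_to(coords[None, :], (grid_n, grid_n))
    y = np.broadcast_to(-coords[:, None], (grid_n, grid_n))
    return x, y


def rasterize(spec: PhantomSpec) -> ActivityImage:
    """Paint the phantom onto its pixel grid.

    Each pixel takes the specific activity of the *last* listed ellipse
    whose interior contains the pixel center (override semantics), and 0
    outside all ellipses.
    """
    x, y = pixel_centers_mm(spec.grid_n, spec.fov_mm)
    values = np.zeros((spec.grid_n, spec.grid_n), dtype=float)
    for ellipse in spec.ellipses:
        inside = ellipse.contains(x, y)
        values[inside] = ellipse.specific_activity
    return ActivityImage(values=values, pixel_mm=spec.pixel_mm)


def build_attenuation_map(spec: PhantomSpec, mu_water: float = MU_WATER_159KEV) -> AttenuationMap:
    """Uniform-water attenuation map: mu_water inside SRC0, zero outside.

    The phantom body has no skull/bone shell, so the medium is a single
    uniform water ellipse coincident with the background source SRC0.
    """
    if mu_water < 0:
        raise ValueError("mu_water must be non-negative")
    x, y = pixel_centers_mm(spec.grid_n, spec.fov_mm)
    body = spec.ellipses[0] if spec.ellipses else None
    mu = np.zeros((spec.grid_n, spec.grid_n), dtype=float)
    if body is not None and mu_water > 0:
        mu[body.contains(x, y)] = mu_water
    return AttenuationMap(mu=mu, pixel_mm=spec.pixel_mm)


# Default RoI rectangles in mm, (x_min, x_max, y_min, y_max).  The exact
# boxes are a package choice (configurable): an edge box straddling the top
# boundary of the central ellipse SRC3, a hotspot box enclosing the small
# SRC6-SRC8 cluster, and a uniform-background box inside SRC0 away from all
# sources.
_DEFAULT_ROI_BOXES = {
    "edge": (-12.0, 12.0, 57.0, 77.0),
    "hotspot": (-20.0, 18.0, -72.0, -56.0),
    "background": (30.0, 50.0, -65.0, -45.0),
}


def make_rois(
    grid_n: int = 256,
    fov_mm: float = 256.0,
    boxes_mm: dict[str, tuple[float, float, float, float]] | None = None,
) -> list[RoIMask]:
    """Build the three diagnostic RoI masks (edge, hotspot, background).

    ``boxes_mm`` may override the default rectangles; keys are the RoI
    kinds, values are (x_min, x_max, y_min, y_max) in mm.
    """
    boxes = dict(_DEFAULT_ROI_BOXES)
    if boxes_mm:
        boxes.update(boxes_mm)
    x, y = pixel_centers_mm(grid_n, fov_mm)
    rois = []
    for i, (kind, (x0, x1, y0, y1)) in enumerate(boxes.items(), start=1):
        mask = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
        if not mask.any():
            raise ValueError(
                f"grid {grid_n} with FOV {fov_mm} mm too small to place the '{kind}' RoI"
            )
        rois.append(RoIMask(mask=mask, label=f"RoI-{i}", kind=kind))
    for a in range(len(rois)):
        for b in range(a + 1, len(rois)):
            if (rois[a].mask & rois[b].mask).any():
                raise ValueError(f"RoIs '{rois[a].label}' and '{rois[b].label}' overlap")
    return rois
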