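"""Thermal scene I/O and region-of-interest temperature extraction.

A :class:`ThermalScene` holds a 2-D brightness-temperature raster (Kelvin
internally; Celsius only at user-facing interfaces) together with labelled
plant and wet/dry reference regions of interest and the emissivities used to
convert brightness to surface temperature. Rasters round-trip through plain
single-band float32 TIFF, NPY or CSV with a JSON sidecar carrying pixel size
and origin; ROIs are a JSON list of named rectangles or polygons in 0-based,
row-major pixel coordinates (rectangle bounds half-open).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import polygon as _sk_polygon

from .thermal import ReferenceTemps

__all__ = [
    "ROI",
    "ThermalScene",
    "PlantThermalRecord",
    "brightness_to_surface_temperature",
    "load_scene",
    "save_scene",
    "extract_roi_temperature",
    "extract_all",
]

DEFAULT_TRIM_FRACTION = 0.05
DEFAULT_N_MIN = 10


@dataclass(frozen=True)
class ROI:
    """A named region of interest in pixel coordinates.

    ``kind`` is "plant", "wet" or "dry"; plants carry a ``treatment`` label.
    Either ``rect`` (row0, col0, row1, col1; half-open) or ``polygon``
    (list of (row, col) vertices) defines the footprint.
    """

    name: str
    kind: str
    rect: tuple[int, int, int, int] | None = None
    polygon: tuple | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("plant", "wet", "dry"):
            raise ValueError(f"ROI {self.name!r}: unknown kind {self.kind!r}")
        if (self.rect is None) == (self.polygon is None):
            raise ValueError(f"ROI {self.name!r}: exactly one of rect/polygon required")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of this ROI on a grid of the given shape."""
        m = np.zeros(shape, dtype=bool)
        if self.rect is not None:
            r0, c0, r1, c1 = self.rect
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1] or r0 >= r1 or c0 >= c1:
                raise ValueError(
                    f"ROI {self.name!r}: rect {self.rect} outside grid {shape}"
                )
            m[r0:r1, c0:c1] = True
        else:
            verts = np.asarray(self.polygon, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise ValueError(f"ROI {self.name!r}: polygon needs >= 3 (row, col) vertices")
            if (verts < 0).any() or (verts[:, 0] > shape[0]).any() or (verts[:, 1] > shape[1]).any():
                raise ValueError(
                    f"ROI {self.name!r}: polygon vertices outside grid {shape}"
                )
            rr, cc = _sk_polygon(verts[:, 0], verts[:, 1], shape=shape)
            m[rr, cc] = True
        return m


@dataclass
class ThermalScene:
    """Brightness-temperature raster (K) with ROIs and emissivity settings."""

    grid: np.ndarray
    pixel_size: float
    rois: list[ROI] = field(default_factory=list)
    origin: tuple[float, float] = (0.0, 0.0)
    emissivity_canopy: float = 0.96
    emissivity_reference: float = 0.95

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("scene grid must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for eps in (self.emissivity_canopy, self.emissivity_reference):
            if not (0.0 < eps <= 1.0):
                raise ValueError("emissivities must lie in (0, 1]")
        for roi in self.rois:
            roi.mask(self.grid.shape)  # raises if outside grid

    @property
    def plant_rois(self) -> list[ROI]:
        return [r for r in self.rois if r.kind == "plant"]

    @property
    def reference_rois(self) -> list[ROI]:
        return [r for r in self.rois if r.kind in ("wet", "dry")]


@dataclass(frozen=True)
class PlantThermalRecord:
    """Extracted canopy temperature for one plant ROI.

    Tc in degC (emissivity-corrected, trimmed mean), n_pixels the retained
    pixel count and spread the pixel SD (K) after trimming.
    """

    plant_id: str
    treatment: str | None
    Tc: float
    n_pixels: int
    spread: float


def brightness_to_surface_temperature(Tb, emissivity: float):
    """Graybody inversion Ts = Tb / emissivity^(1/4), temperatures in Kelvin.

    Reflected sky radiance is neglected; with emissivity 1 this is the
    identity, and Ts >= Tb for any emissivity <= 1.
    """
    if not (0.0 < emissivity <= 1.0):
        raise ValueError("emissivity must lie in (0, 1]")
    out = np.asarray(Tb, dtype=float) / emissivity**0.25
    return float(out) if np.ndim(out) == 0 else out


def _roi_to_json(roi: ROI) -> dict:
    d: dict = {"name": roi.name, "kind": roi.kind}
    if roi.rect is not None:
        d["rect"] = list(roi.rect)
    else:
        d["polygon"] = [list(v) for v in roi.polygon]
    if roi.treatment is not None:
        d["treatment"] = roi.treatment
    return d


def _roi_from_json(d: dict) -> ROI:
    return ROI(
        name=d["name"],
        kind=d["kind"],
        rect=tuple(d["rect"]) if "rect" in d else None,
        polygon=tuple(tuple(v) for v in d["polygon"]) if "polygon" in d else None,
        treatment=d.get("treatment"),
    )


def save_scene(scene: ThermalScene, raster_path, roi_path) -> None:
    """Write the raster plus JSON sidecar and the ROI JSON file.

    The raster format follows the suffix: ``.tif``/``.tiff`` (single-band
    float32), ``.npy``, or ``.csv``. A ``<raster>.json`` sidecar records
    pixel size, origin, units and emissivities.
    """
    raster_path = Path(raster_path)
    suffix = raster_path.suffix.lower()
    grid32 = scene.grid.astype(np.float32)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(raster_path, grid32)
    elif suffix == ".npy":
        np.save(raster_path, grid32)
    elif suffix == ".csv":
        np.savetxt(raster_path, grid32, delimiter=",")
    else:
        raise ValueError(f"unsupported raster format {suffix!r}")
    sidecar = {
        "pixel_size_m": scene.pixel_size,
        "origin": list(scene.origin),
        "units": "K",
        "emissivity_canopy": scene.emissivity_canopy,
        "emissivity_reference": scene.emissivity_reference,
    }
    raster_path.with_suffix(raster_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )
    Path(roi_path).write_text(
        json.dumps({"rois": [_roi_to_json(r) for r in scene.rois]}, indent=1)
    )


def load_scene(raster_path, roi_path) -> ThermalScene:
    """Load a scene from a raster (+ JSON sidecar) and an ROI JSON file.

    ROIs are validated against the grid; one lying outside raises a
    ``ValueError`` naming it.
    """
    raster_path = Path(raster_path)
    suffix = raster_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        grid = tifffile.imread(raster_path)
    elif suffix == ".npy":
        grid = np.load(raster_path)
    elif suffix == ".csv":
        grid = np.loadtxt(raster_path, delimiter=",", ndmin=2)
    else:
        raise ValueError(f"unsupported raster format {suffix!r}")

    sidecar_path = raster_path.with_suffix(raster_path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"raster sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())

    roi_doc = json.loads(Path(roi_path).read_text())
    if "rois" not in roi_doc:
        raise ValueError("ROI file must contain a top-level 'rois' list")
    rois = [_roi_from_json(d) for d in roi_doc["rois"]]

    return ThermalScene(
        grid=np.asarray(grid, dtype=float),
        pixel_size=float(meta["pixel_size_m"]),
        rois=rois,
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        emissivity_canopy=float(meta.get("emissivity_canopy", 0.96)),
        emissivity_reference=float(meta.get("emissivity_reference", 0.95)),
    )


def extract_roi_temperature(
    scene: ThermalScene,
    roi: ROI,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    n_min: int = DEFAULT_N_MIN,
) -> tuple[float, int, float]:
    """Symmetric-trimmed mean temperature of one ROI.

    Applies the graybody emissivity correction appropriate to the ROI kind
    (canopy emissivity for plants, reference emissivity for wet/dry targets),
    drops ``floor(n * trim_fraction)`` pixels from each tail, and returns
    ``(mean_degC, n_retained, sd_K)``. Fewer than ``n_min`` retained pixels
    is an error: aggregates from a handful of pixels are not trustworthy.
    """
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    eps = scene.emissivity_canopy if roi.kind == "plant" else scene.emissivity_reference
    pixels = brightness_to_surface_temperature(scene.grid[roi.mask(scene.grid.shape)], eps)
    k = int(np.floor(pixels.size * trim_fraction))
    kept = np.sort(pixels)[k : pixels.size - k] if k else np.sort(pixels)
    if kept.size < n_min:
        raise ValueError(
            f"ROI {roi.name!r}: only {kept.size} pixels after trimming (n_min={n_min})"
        )
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    return float(np.mean(kept) - 273.15), int(kept.size), sd


def extract_all(
    scene: ThermalScene,
    trim_fraction: float = DEFAULT_TRIM_FRACTION,
    n_min: int = DEFAULT_N_MIN,
    model_refs: ReferenceTemps | None = None,
) -> tuple[list[PlantThermalRecord], ReferenceTemps]:
    """Extract every plant ROI plus the wet/dry reference temperatures.

    Reference temperatures are the means over the wet and dry reference ROIs.
    If either reference class is missing, ``model_refs`` (energy-balance
    reference temperatures, see
    :func:`thermetab.thermal.model_reference_temps`) is used as fallback;
    without a fallback this is a configuration error. A dry reference at or
    below the wet one triggers a degenerate-reference warning, and the pair
    is returned un-validated so callers can flag downstream indices.
    """
    records = [
        PlantThermalRecord(
            plant_id=roi.name,
            treatment=roi.treatment,
            Tc=mean,
            n_pixels=n,
            spread=sd,
        )
        for roi in scene.plant_rois
        for mean, n, sd in [extract_roi_temperature(scene, roi, trim_fraction, n_min)]
    ]

    wet = [
        extract_roi_temperature(scene, r, trim_fraction, n_min)[0]
        for r in scene.rois
        if r.kind == "wet"
    ]
    dry = [
        extract_roi_temperature(scene, r, trim_fraction, n_min)[0]
        for r in scene.rois
        if r.kind == "dry"
    ]
    if not wet or not dry:
        if model_refs is None:
            raise ValueError(
                "scene lacks wet and/or dry reference ROIs and no model-reference "
                "fallback was supplied"
            )
        return records, model_refs

    T_wet, T_dry = float(np.mean(wet)), float(np.mean(dry))
    if T_dry <= T_wet:
        warnings.warn(
            f"degenerate references: T_dry ({T_dry:.2f}) <= T_wet ({T_wet:.2f}); "
            "downstream indices are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
        return records, ReferenceTemps.unchecked(T_wet, T_dry)
    return records, ReferenceTemps(T_wet=T_wet, T_dry=T_dry)
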