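"""Coring-location geometry and Voronoi-area weighted RLD estimation.

Locations are defined relative to the focal plant (x across-row, y
along-row).  Each location is expanded under the plot's symmetry group
(reflection across the row axis, 180-degree rotation about the focal
plant), wrapped into one row-by-plant unit cell, and the periodic Voronoi
tessellation of the expanded set yields an area per location.  The
whole-plot RLD estimate is the area-weighted mean of the per-location
profiles; the unweighted mean is the conventional "unadjusted" estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from rhizocore.coring import RLDProfile

_STEM_OFFSET = 2.2  # cm: one core radius from the plant axis ("next to plant base")
_DEDUP_TOL = 1e-6


class LocationCollisionError(ValueError):
    """Two distinct locations coincide after symmetry expansion."""


@dataclass(frozen=True)
class CoringLayout:
    """Named coring locations for one species' row/plant spacing."""

    species: str
    row_spacing: float
    plant_spacing: float
    locations: Mapping[int, tuple[float, float]]

    def __post_init__(self) -> None:
        pts = list(self.locations.values())
        for i, p in enumerate(pts):
            for q in pts[i + 1 :]:
                if abs(p[0] - q[0]) < _DEDUP_TOL and abs(p[1] - q[1]) < _DEDUP_TOL:
                    raise ValueError("location coordinates must be distinct")

    @property
    def cell_area(self) -> float:
        return self.row_spacing * self.plant_spacing

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species,
                "row_spacing": self.row_spacing,
                "plant_spacing": self.plant_spacing,
                "locations": {str(k): list(v) for k, v in self.locations.items()},
            },
            indent=2,
        )


@dataclass
class VoronoiWeights:
    """Area-derived weights for a subset of coring locations."""

    subset: tuple[int, ...]
    w: dict[int, float]
    areas: dict[int, float]

    def __post_init__(self) -> None:
        total = sum(self.w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total})")
        if any(v < 0 for v in self.w.values()):
            raise ValueError("weights must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "subset": list(self.subset),
                "weights": {str(k): v for k, v in self.w.items()},
                "areas_cm2": {str(k): v for k, v in self.areas.items()},
            },
            indent=2,
        )


@dataclass
class RLDEstimate:
    """A whole-plot RLD estimate assembled from per-location core profiles."""

    profile: RLDProfile
    method: str  # voronoi | unadjusted
    subset: tuple[int, ...]
    per_location_profiles: dict[int, RLDProfile]
    weights: VoronoiWeights | None = None


def default_layout(species: str) -> CoringLayout:
    """The six standard coring locations for maize or bean.

    1: between row, next to plant base; 2: halfway between plants in a row;
    3: between row, 5 cm from plant base; 4: halfway between plants in
    neighboring rows; 5: equidistant from 4 plants in 2 rows; 6: next to
    plant, in row.
    """
    if species == "maize":
        R, P = 76.0, 23.0
    elif species == "bean":
        R, P = 76.0, 10.0
    else:
        raise ValueError(f"unknown species {species!r}")
    locations = {
        1: (_STEM_OFFSET, 0.0),
        2: (0.0, P / 2.0),
        3: (5.0, 0.0),
        4: (R / 2.0, 0.0),
        5: (R / 2.0, P / 2.0),
        6: (0.0, _STEM_OFFSET),
    }
    return CoringLayout(species=species, row_spacing=R, plant_spacing=P, locations=locations)


def _wrap(points: np.ndarray, R: float, P: float) -> np.ndarray:
    """Wrap points into the half-open cell [-R/2, R/2) x [-P/2, P/2)."""
    out = points.copy()
    out[:, 0] = (out[:, 0] + R / 2.0) % R - R / 2.0
    out[:, 1] = (out[:, 1] + P / 2.0) % P - P / 2.0
    return out


def expand_by_symmetry(layout: CoringLayout, subset: Iterable[int]) -> dict[int, np.ndarray]:
    """Images of each location under {identity, reflect across row, rotate 180, both}.

    Images are wrapped into the unit cell and de-duplicated (1e-6 cm);
    returns location_id -> array of distinct image coordinates.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    R, P = layout.row_spacing, layout.plant_spacing
    expanded: dict[int, np.ndarray] = {}
    for loc in subset:
        if loc not in layout.locations:
            raise KeyError(f"unknown location id {loc}")
        x, y = layout.locations[loc]
        images = np.array([[x, y], [-x, y], [-x, -y], [x, -y]], dtype=float)
        images = _wrap(images, R, P)
        keep: list[np.ndarray] = []
        for p in images:
            if not any(np.all(np.abs(p - q) < _DEDUP_TOL) for q in keep):
                keep.append(p)
        expanded[loc] = np.array(keep)
    return expanded


def voronoi_weights(layout: CoringLayout, subset: Iterable[int]) -> VoronoiWeights:
    """Voronoi-area weights over the periodic unit cell for a location subset.

    The expanded point set is tiled over the 8 neighboring cells so every
    Voronoi region of interest is bounded; regions are clipped to one cell
    and areas accumulated per source location, then normalized.
    """
    subset = tuple(subset)
    expanded = expand_by_symmetry(layout, subset)
    R, P = layout.row_spacing, layout.plant_spacing

    points = []
    owners = []
    for loc, imgs in expanded.items():
        for p in imgs:
            points.append(p)
            owners.append(loc)
    points = np.asarray(points)

    # distinct locations whose images collide make the weights ill-defined
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if owners[i] != owners[j] and np.all(np.abs(points[i] - points[j]) < _DEDUP_TOL):
                raise LocationCollisionError(
                    f"locations {owners[i]} and {owners[j]} coincide after symmetry expansion"
                )

    if len(points) == 1:
        loc = owners[0]
        return VoronoiWeights(subset=subset, w={loc: 1.0}, areas={loc: layout.cell_area})

    # 5x5 periodic tiling: any region touching the center cell belongs to a
    # point in the middle 3x3 tiles, and those regions are all bounded
    tiles = []
    tile_owner = []
    for ix in (-2, -1, 0, 1, 2):
        for iy in (-2, -1, 0, 1, 2):
            tiles.append(points + np.array([ix * R, iy * P]))
            tile_owner.extend(owners)
    all_points = np.vstack(tiles)

    vor = Voronoi(all_points)
    cell = box(-R / 2.0, -P / 2.0, R / 2.0, P / 2.0)
    areas = {loc: 0.0 for loc in subset}
    for idx, loc in enumerate(tile_owner):
        region = vor.regions[vor.point_region[idx]]
        if not region or -1 in region:
            continue  # unbounded outermost-tile region; cannot reach the cell
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid or poly.is_empty:
            continue
        clipped = poly.intersection(cell)
        if not clipped.is_empty:
            areas[loc] += clipped.area

    total = sum(areas.values())
    if abs(total - layout.cell_area) > 1e-3 * layout.cell_area:
        raise RuntimeError(
            f"Voronoi areas ({total:.4f}) do not tile the cell ({layout.cell_area:.4f})"
        )
    w = {loc: areas[loc] / total for loc in subset}
    # exact renormalization
    s = sum(w.values())
    w = {loc: v / s for loc, v in w.items()}
    return VoronoiWeights(subset=subset, w=w, areas=areas)


def _check_bins(profiles: Mapping[int, RLDProfile]) -> tuple[float, ...]:
    bins = None
    for p in profiles.values():
        if bins is None:
            bins = tuple(p.depth_bins)
        elif tuple(p.depth_bins) != bins:
            raise ValueError("depth bins of per-location profiles do not match")
    assert bins is not None
    return bins


def estimate_rld(cores: Mapping[int, RLDProfile], weights: VoronoiWeights) -> RLDEstimate:
    """Voronoi-weighted whole-plot RLD estimate from per-location profiles."""
    if set(cores.keys()) != set(weights.subset):
        raise ValueError(
            f"core locations {sorted(cores)} do not match weight subset {sorted(weights.subset)}"
        )
    bins = _check_bins(cores)
    est = np.zeros(len(bins) - 1)
    for loc, prof in cores.items():
        est += weights.w[loc] * prof.rld_by_bin
    profile = RLDProfile(
        rld_by_bin=est, depth_bins=bins, provenance="voronoi", n_contributing_cores=len(cores)
    )
    return RLDEstimate(
        profile=profile,
        method="voronoi",
        subset=tuple(weights.subset),
        per_location_profiles=dict(cores),
        weights=weights,
    )


def unadjusted_mean(cores: Mapping[int, RLDProfile]) -> RLDEstimate:
    """Unweighted mean of per-location profiles (the conventional estimate)."""
    if not cores:
        raise ValueError("at least one core profile is required")
    bins = _check_bins(cores)
    est = np.mean([p.rld_by_bin for p in cores.values()], axis=0)
    profile = RLDProfile(
        rld_by_bin=est, depth_bins=bins, provenance="unadjusted", n_contributing_cores=len(cores)
    )
    return RLDEstimate(
        profile=profile,
        method="unadjusted",
        subset=tuple(sorted(cores.keys())),
        per_location_profiles=dict(cores),
        weights=None,
    )
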