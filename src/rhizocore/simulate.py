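"""Stochastic geometric root-architecture simulator.

Generates plots of four maize or bean plants whose root systems differ only
in axial/basal emergence angle (shallow / intermediate / deep phenotypes).
Roots grow as 3-D polylines with per-step random tip deflection and
gravitropic curvature; first-order laterals branch off the axial roots.
Total root length per plant equals a fixed elongation budget (times a
per-replicate stochastic multiplier), so phenotypes are length-invariant by
construction and differ only in how that length is distributed with depth.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SPECIES = ("maize", "bean")
PHENOTYPES = ("shallow", "intermediate", "deep")

#: integer codes for root classes, used in the segment arrays
CLASS_TAPROOT = 0
CLASS_AXIAL = 1
CLASS_LATERAL = 2
CLASS_NAMES = {CLASS_TAPROOT: "taproot", CLASS_AXIAL: "axial", CLASS_LATERAL: "lateral"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

# Study-mode angle offsets (degrees added to the default emergence angle).
# Larger offset = deeper phenotype; the generator subtracts the offset from
# the default angle-from-vertical, so a larger offset steers roots downward.
STUDY_ANGLE_OFFSETS = {
    "bean": {"shallow": 0.0, "intermediate": 20.0, "deep": 40.0},
    "maize": {"shallow": -30.0, "intermediate": 0.0, "deep": 30.0},
}

# Root topology: default emergence angles from vertical (degrees) per whorl
# and number of roots per whorl.  Bean: taproot + 3 basal whorls; maize:
# taproot surrogate + 4 nodal whorls.  Counts and angles are calibration
# choices, tuned so the depth-profile contrasts drive the downstream
# analyses at realistic core-level noise.
_BEAN_WHORLS = ((40.0, 10, 1.0), (55.0, 10, 2.0), (70.0, 10, 3.0))  # (angle, n, emergence depth)
_MAIZE_WHORLS = ((40.0, 6, 1.0), (40.0, 6, 2.0), (40.0, 6, 3.0), (40.0, 6, 4.0))

_MIN_ANGLE = 5.0  # clamp for effective emergence angle, degrees from vertical
_MAX_ANGLE = 85.0
_BRANCH_ANGLE = 65.0  # lateral emergence angle from the parent heading
_LATERAL_GRAVITROPISM_FACTOR = 0.5
_EMERGENCE_RADIUS = {"maize": 2.0, "bean": 1.5}  # cm: root-crown ring radius

_SPECIES_DEFAULTS = {
    "maize": dict(plant_spacing=23.0, elongation_budget=3800.0, axial_fraction=0.5, tip_deflection_sd=9.0, stochastic_cv=0.12),
    "bean": dict(plant_spacing=10.0, elongation_budget=3200.0, axial_fraction=0.6, tip_deflection_sd=6.0, stochastic_cv=0.10),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters for one simulated plot.

    Distances in cm, angles in degrees, z is depth (positive downward).
    """

    species: str
    phenotype: str = "intermediate"
    angle_offset: float = 0.0
    row_spacing: float = 76.0
    plant_spacing: float = 23.0
    n_plants: int = 4
    growth_days: int = 40
    elongation_budget: float = 3800.0  # cm of root per plant (axial + lateral)
    step_length: float = 0.5
    gravitropism_rate: float = 0.4  # degrees per cm toward vertical
    branching_frequency: float = 0.2  # laterals per cm of axial root
    tip_deflection_sd: float = 8.0  # degrees per step, each bending axis
    stochastic_cv: float = 0.10
    axial_fraction: float = 0.5  # share of the budget spent on axial roots
    max_depth: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.elongation_budget < 0:
            raise ValueError("elongation_budget must be non-negative")
        for name in ("gravitropism_rate", "branching_frequency", "tip_deflection_sd", "stochastic_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.axial_fraction <= 1:
            raise ValueError("axial_fraction must be in (0, 1]")
        if self.max_depth < 60:
            raise ValueError("max_depth must be at least 60 cm")
        if self.n_plants != 4:
            raise ValueError("only 4-plant plots (2 rows x 2 plants) are supported")

    @classmethod
    def for_study(cls, species: str, phenotype: str, **overrides) -> "SimConfig":
        """Study-mode configuration: 76 cm rows, 40 days, phenotype via angle offset."""
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
        params = dict(_SPECIES_DEFAULTS[species])
        params.update(
            species=species,
            phenotype=phenotype,
            angle_offset=STUDY_ANGLE_OFFSETS[species][phenotype],
        )
        params.update(overrides)
        return cls(**params)

    def whorls(self) -> tuple[tuple[float, int, float], ...]:
        """(effective emergence angle, n roots, emergence depth) per whorl."""
        base = _BEAN_WHORLS if self.species == "bean" else _MAIZE_WHORLS
        return tuple(
            (float(np.clip(angle - self.angle_offset, _MIN_ANGLE, _MAX_ANGLE)), n, z0)
            for angle, n, z0 in base
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class RootSegment:
    """One straight piece of a root polyline; z is depth (>= 0, downward)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    length: float
    root_class: str
    plant_id: int


@dataclass
class PlotSim:
    """Raw simulation output: all root segments of one 4-plant plot.

    Segments are stored as flat numpy arrays (``starts``/``ends`` of shape
    (N, 3), x across-row, y along-row, z depth).  The plot is periodic with
    period ``domain`` = (2 * row_spacing, 2 * plant_spacing); the focal plant
    sits at the origin.
    """

    config: SimConfig
    seed: int
    starts: np.ndarray
    ends: np.ndarray
    lengths: np.ndarray
    plant_id: np.ndarray
    root_class: np.ndarray
    plant_positions: np.ndarray  # (4, 2)
    replicate_id: int = 0

    @property
    def species(self) -> str:
        return self.config.species

    @property
    def phenotype(self) -> str:
        return self.config.phenotype

    @property
    def domain(self) -> tuple[float, float]:
        return (2 * self.config.row_spacing, 2 * self.config.plant_spacing)

    @property
    def plot_area(self) -> float:
        return self.config.n_plants * self.config.row_spacing * self.config.plant_spacing

    @property
    def n_segments(self) -> int:
        return len(self.lengths)

    @property
    def total_root_length(self) -> float:
        return float(self.lengths.sum())

    def iter_segments(self) -> Iterator[RootSegment]:
        for i in range(self.n_segments):
            yield RootSegment(
                start=tuple(self.starts[i]),
                end=tuple(self.ends[i]),
                length=float(self.lengths[i]),
                root_class=CLASS_NAMES[int(self.root_class[i])],
                plant_id=int(self.plant_id[i]),
            )

    def to_csv(self, path, config_path=None) -> None:
        """Write segments to CSV; optionally the config to JSON alongside."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["plant_id", "root_class", "x0", "y0", "z0", "x1", "y1", "z1", "length_cm"])
            for i in range(self.n_segments):
                writer.writerow(
                    [int(self.plant_id[i]), CLASS_NAMES[int(self.root_class[i])]]
                    + [repr(v) for v in self.starts[i]]
                    + [repr(v) for v in self.ends[i]]
                    + [repr(float(self.lengths[i]))]
                )
        if config_path is not None:
            with open(config_path, "w") as fh:
                fh.write(self.config.to_json())


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _orthonormal_frame(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to each row of h (shape (n, 3))."""
    ref = np.zeros_like(h)
    # pick the axis least aligned with h to avoid degeneracy
    idx = np.argmin(np.abs(h), axis=1)
    ref[np.arange(len(h)), idx] = 1.0
    u = _unit(np.cross(h, ref))
    v = np.cross(h, u)  # already unit: h and u orthonormal
    return u, v


def _grow(
    starts: np.ndarray,
    headings: np.ndarray,
    total_lengths: np.ndarray,
    step: float,
    grav_rate_per_cm: np.ndarray,
    defl_sd_deg: float,
    max_depth: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow polylines for a batch of roots; returns (seg_starts, seg_ends, root_index).

    Each root takes ceil(L/step) steps (last step shorter).  Per step the
    heading is rotated toward vertical by gravitropism, deflected by a random
    bend on two axes, then advanced.  The soil surface (z=0) and the maximum
    depth act as reflecting boundaries applied to the heading before the
    step, so recorded segment lengths are exact and depths stay in range.
    """
    n = len(total_lengths)
    if n == 0 or total_lengths.max() <= 0:
        empty = np.empty((0, 3))
        return empty, empty.copy(), np.empty(0, dtype=np.intp)
    n_steps = int(math.ceil(float(total_lengths.max()) / step))
    pos = starts.astype(float).copy()
    h = _unit(headings.astype(float).copy())

    # pre-draw deflections so the stream shape depends only on (n, n_steps)
    deflections = rng.normal(0.0, math.radians(defl_sd_deg), size=(n_steps, n, 2))

    seg_starts = []
    seg_ends = []
    seg_roots = []
    root_idx = np.arange(n, dtype=np.intp)
    for k in range(n_steps):
        ds = np.clip(total_lengths - k * step, 0.0, step)
        active = ds > 1e-12
        if not active.any():
            break
        # gravitropism: rotate heading toward +z (down) by at most the
        # remaining angle
        hz = np.clip(h[:, 2], -1.0, 1.0)
        phi = np.arccos(hz)  # angle from vertical
        delta = np.minimum(np.radians(grav_rate_per_cm) * ds, phi)
        sin_phi = np.sqrt(np.maximum(1.0 - hz**2, 0.0))
        bendable = sin_phi > 1e-9
        new_phi = phi - delta
        h_xy = np.zeros_like(h)
        h_xy[bendable, :2] = h[bendable, :2] / sin_phi[bendable, None]
        h_new = h.copy()
        h_new[bendable, :2] = h_xy[bendable, :2] * np.sin(new_phi[bendable, None])
        h_new[bendable, 2] = np.cos(new_phi[bendable])
        h = h_new

        # random tip deflection on two bending axes
        if defl_sd_deg > 0:
            u, v = _orthonormal_frame(h)
            a = deflections[k, :, 0:1]
            b = deflections[k, :, 1:2]
            h = _unit(h + a * u + b * v)

        # reflecting boundaries: flip the vertical heading component before
        # stepping so z stays within [0, max_depth] and lengths are exact
        dz = h[:, 2] * ds
        going_up_out = pos[:, 2] + dz < 0.0
        going_down_out = pos[:, 2] + dz > max_depth
        h[going_up_out | going_down_out, 2] *= -1.0

        end = pos + h * ds[:, None]
        seg_starts.append(pos[active].copy())
        seg_ends.append(end[active].copy())
        seg_roots.append(root_idx[active].copy())
        pos = end

    return (
        np.concatenate(seg_starts, axis=0),
        np.concatenate(seg_ends, axis=0),
        np.concatenate(seg_roots, axis=0),
    )


def _truncated_normal(rng: np.random.Generator, mean: float, cv: float, size=None) -> np.ndarray:
    """Multiplier ~ Normal(mean, cv*mean) truncated to mean +- 3 sd (and > 0.05)."""
    sd = cv * mean
    x = rng.normal(mean, sd, size=size)
    lo = max(0.05, mean - 3 * sd)
    hi = mean + 3 * sd
    return np.clip(x, lo, hi)


def simulate_plot(config: SimConfig, seed: int | None = None, replicate_id: int = 0) -> PlotSim:
    """Simulate one plot; deterministic for a fixed config + seed."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    R, P = config.row_spacing, config.plant_spacing
    plant_positions = np.array([[0.0, 0.0], [0.0, P], [R, 0.0], [R, P]])

    # per-replicate stochastic multipliers (elongation, branching, gravitropism)
    mult_elong, mult_branch, mult_grav = _truncated_normal(rng, 1.0, config.stochastic_cv, size=3)

    budget = config.elongation_budget * float(mult_elong)  # per plant
    if budget <= 0:
        empty3 = np.empty((0, 3))
        return PlotSim(
            config=config,
            seed=seed,
            starts=empty3,
            ends=empty3.copy(),
            lengths=np.empty(0),
            plant_id=np.empty(0, dtype=np.int32),
            root_class=np.empty(0, dtype=np.int8),
            plant_positions=plant_positions,
            replicate_id=replicate_id,
        )

    whorls = config.whorls()
    n_axial_per_plant = 1 + sum(n for _, n, _ in whorls)  # taproot + whorl roots

    axial_budget = config.axial_fraction * budget
    lateral_budget = budget - axial_budget
    axial_total_plant = axial_budget  # per plant
    n_lat_per_plant = int(round(config.branching_frequency * float(mult_branch) * axial_total_plant))
    if config.branching_frequency == 0 or n_lat_per_plant == 0 or lateral_budget <= 0:
        n_lat_per_plant = 0
        axial_budget = budget
        lateral_budget = 0.0
    axial_len_per_root = axial_budget / n_axial_per_plant

    # --- axial roots of all plants, grown together -------------------------
    starts = []
    headings = []
    classes = []
    plants = []
    for pid, (px, py) in enumerate(plant_positions):
        # taproot: vertical
        starts.append([px, py, 0.5])
        headings.append([0.0, 0.0, 1.0])
        classes.append(CLASS_TAPROOT)
        plants.append(pid)
        r_em = _EMERGENCE_RADIUS[config.species]
        for angle_deg, n_roots, z0 in whorls:
            theta = math.radians(angle_deg)
            phase = rng.uniform(0.0, 2 * math.pi)
            for j in range(n_roots):
                az = phase + 2 * math.pi * j / n_roots
                starts.append([px + r_em * math.cos(az), py + r_em * math.sin(az), z0])
                headings.append(
                    [math.sin(theta) * math.cos(az), math.sin(theta) * math.sin(az), math.cos(theta)]
                )
                classes.append(CLASS_AXIAL)
                plants.append(pid)

    starts = np.asarray(starts, dtype=float)
    headings = np.asarray(headings, dtype=float)
    classes = np.asarray(classes, dtype=np.int8)
    plants = np.asarray(plants, dtype=np.int32)
    n_axial_total = len(starts)
    axial_lengths = np.full(n_axial_total, axial_len_per_root)
    grav = np.full(n_axial_total, config.gravitropism_rate * float(mult_grav))

    ax_s, ax_e, ax_root = _grow(
        starts,
        headings,
        axial_lengths,
        config.step_length,
        grav,
        config.tip_deflection_sd,
        config.max_depth,
        rng,
    )
    ax_class = classes[ax_root]
    ax_plant = plants[ax_root]

    # --- laterals ----------------------------------------------------------
    if n_lat_per_plant > 0:
        lat_len_each = lateral_budget / n_lat_per_plant  # per plant budget / count
        seg_len = np.linalg.norm(ax_e - ax_s, axis=1)
        lat_starts = []
        lat_headings = []
        lat_plants = []
        for pid in range(config.n_plants):
            mask = np.flatnonzero(ax_plant == pid)
            w = seg_len[mask]
            parents = mask[rng.choice(len(mask), size=n_lat_per_plant, p=w / w.sum())]
            u = rng.uniform(0.0, 1.0, size=n_lat_per_plant)[:, None]
            bp = ax_s[parents] + u * (ax_e[parents] - ax_s[parents])
            hp = _unit(ax_e[parents] - ax_s[parents])
            pu, pv = _orthonormal_frame(hp)
            az = rng.uniform(0.0, 2 * math.pi, size=n_lat_per_plant)[:, None]
            w_perp = np.cos(az) * pu + np.sin(az) * pv
            theta_b = math.radians(_BRANCH_ANGLE)
            lat_h = math.cos(theta_b) * hp + math.sin(theta_b) * w_perp
            lat_starts.append(bp)
            lat_headings.append(lat_h)
            lat_plants.append(np.full(n_lat_per_plant, pid, dtype=np.int32))
        lat_starts = np.concatenate(lat_starts)
        lat_headings = np.concatenate(lat_headings)
        lat_plants = np.concatenate(lat_plants)
        n_lat_total = len(lat_starts)
        lat_s, lat_e, lat_root = _grow(
            lat_starts,
            lat_headings,
            np.full(n_lat_total, lat_len_each),
            config.step_length,
            np.full(n_lat_total, config.gravitropism_rate * float(mult_grav) * _LATERAL_GRAVITROPISM_FACTOR),
            config.tip_deflection_sd,
            config.max_depth,
            rng,
        )
        all_s = np.concatenate([ax_s, lat_s])
        all_e = np.concatenate([ax_e, lat_e])
        all_class = np.concatenate([ax_class, np.full(len(lat_s), CLASS_LATERAL, dtype=np.int8)])
        all_plant = np.concatenate([ax_plant, lat_plants[lat_root]])
    else:
        all_s, all_e, all_class, all_plant = ax_s, ax_e, ax_class, ax_plant

    lengths = np.linalg.norm(all_e - all_s, axis=1)
    return PlotSim(
        config=config,
        seed=seed,
        starts=all_s,
        ends=all_e,
        lengths=lengths,
        plant_id=all_plant,
        root_class=all_class,
        plant_positions=plant_positions,
        replicate_id=replicate_id,
    )


def study_ensemble(
    config_base: SimConfig,
    n_replicates: int,
    seed_sequence: Sequence[int] | None = None,
) -> list[PlotSim]:
    """Independent seeded replicates of one configuration.

    If ``seed_sequence`` is omitted, replicate seeds are spawned
    deterministically from ``config_base.seed``.  Reusing the same
    seed_sequence across phenotypes pairs their stochastic draws, which
    keeps total root length identical across phenotypes by construction.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if seed_sequence is None:
        ss = np.random.SeedSequence(config_base.seed)
        seed_sequence = [int(s.generate_state(1)[0]) for s in ss.spawn(n_replicates)]
    seeds = list(seed_sequence)
    if len(seeds) != n_replicates:
        raise ValueError("seed_sequence length must equal n_replicates")
    if len(set(seeds)) != len(seeds):
        logger.warning("duplicate seeds in seed_sequence; replicates will not be independent")
    return [simulate_plot(config_base, seed=s, replicate_id=i) for i, s in enumerate(seeds)]
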