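"""Virtual soil coring: root length inside vertical cylindrical cores.

The intersection of a straight segment with the core (an infinite vertical
cylinder clipped to a depth slab) is solved analytically: the quadratic for
the cylinder-wall crossings gives a parameter interval, intersected with
the slab interval.  The 4-plant plot is treated as periodic in x and y, so
every coring location behaves as fully bordered; periodic images are
handled with the minimal-image convention (valid because growth steps are
much shorter than the plot domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from rhizocore.simulate import PlotSim, RootSegment

DEFAULT_DIAMETER = 4.4  # cm (44 mm core)
DEFAULT_DEPTH_BINS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)

_EPS = 1e-12


class DegenerateSimulationError(ValueError):
    """Raised when a profile is requested from a plot with zero root length."""


@dataclass(frozen=True)
class CoreSpec:
    """A vertical cylindrical core; center is (x, y) relative to the focal plant."""

    center: tuple[float, float]
    diameter: float = DEFAULT_DIAMETER
    depth_bins: tuple[float, ...] = DEFAULT_DEPTH_BINS
    location_id: int | str = "random"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("core diameter must be positive")
        bins = tuple(float(b) for b in self.depth_bins)
        if len(bins) < 2 or bins[0] != 0.0:
            raise ValueError("depth_bins must start at 0 and contain at least one bin")
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("depth_bins must be strictly increasing")
        object.__setattr__(self, "depth_bins", bins)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.depth_bins) - 1

    def bin_volume(self, bin_index: int) -> float:
        height = self.depth_bins[bin_index + 1] - self.depth_bins[bin_index]
        return math.pi * self.radius**2 * height


@dataclass
class CoreSample:
    """Root length and RLD per depth bin for one core."""

    location_id: int | str
    replicate_id: int
    species: str
    phenotype: str
    depth_bins: tuple[float, ...]
    root_length_by_bin: np.ndarray  # cm per bin
    rld_by_bin: np.ndarray  # cm / cm^3 per bin

    def __post_init__(self) -> None:
        self.root_length_by_bin = np.asarray(self.root_length_by_bin, dtype=float)
        self.rld_by_bin = np.asarray(self.rld_by_bin, dtype=float)
        if (self.root_length_by_bin < 0).any() or (self.rld_by_bin < 0).any():
            raise ValueError("root length and RLD must be non-negative")

    @property
    def total_root_length(self) -> float:
        return float(self.root_length_by_bin.sum())


@dataclass
class RLDProfile:
    """RLD by depth bin with provenance."""

    rld_by_bin: np.ndarray
    depth_bins: tuple[float, ...] = DEFAULT_DEPTH_BINS
    provenance: str = "whole_plot"  # whole_plot | unadjusted | voronoi | trench | field
    n_contributing_cores: int = 0

    def __post_init__(self) -> None:
        self.rld_by_bin = np.asarray(self.rld_by_bin, dtype=float)
        if len(self.rld_by_bin) != len(self.depth_bins) - 1:
            raise ValueError("bin count must match depth_bins - 1")
        if (self.rld_by_bin < 0).any():
            raise ValueError("RLD must be non-negative")


def _cylinder_slab_lengths(
    starts: np.ndarray,
    ends: np.ndarray,
    cx: float,
    cy: float,
    radius: float,
    z_lo: float,
    z_hi: float,
) -> np.ndarray:
    """Length of each segment inside the cylinder clipped to [z_lo, z_hi)."""
    d = ends - starts
    lengths = np.linalg.norm(d, axis=1)
    ok = lengths > _EPS

    fx = starts[:, 0] - cx
    fy = starts[:, 1] - cy
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]

    # radial interval: |f + t*d|_xy <= r  -> a t^2 + b t + c <= 0
    a = dx * dx + dy * dy
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - radius * radius

    t_lo = np.zeros(len(starts))
    t_hi = np.ones(len(starts))

    vertical = a <= _EPS
    outside_vertical = vertical & (c > 0)
    t_hi[outside_vertical] = 0.0  # vertical segment outside the radius

    nv = ~vertical & ok
    disc = b * b - 4.0 * a * c
    no_hit = nv & (disc < 0)
    t_hi[no_hit] = 0.0
    hit = nv & (disc >= 0)
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = (-b - sq) / (2.0 * a)
        r2 = (-b + sq) / (2.0 * a)
    t_lo[hit] = np.maximum(t_lo[hit], r1[hit])
    t_hi[hit] = np.minimum(t_hi[hit], r2[hit])

    # depth-slab interval
    z0 = starts[:, 2]
    flat = np.abs(dz) <= _EPS
    outside_flat = flat & ~((z0 >= z_lo) & (z0 < z_hi))
    t_hi[outside_flat] = 0.0
    sloped = ~flat
    with np.errstate(divide="ignore", invalid="ignore"):
        tz1 = (z_lo - z0) / dz
        tz2 = (z_hi - z0) / dz
    lo = np.minimum(tz1, tz2)
    hi = np.maximum(tz1, tz2)
    t_lo[sloped] = np.maximum(t_lo[sloped], lo[sloped])
    t_hi[sloped] = np.minimum(t_hi[sloped], hi[sloped])

    frac = np.clip(t_hi - t_lo, 0.0, 1.0)
    frac[~ok] = 0.0
    return frac * lengths


def _segment_arrays(segment: RootSegment) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(segment.start, dtype=float)[None, :]
    e = np.asarray(segment.end, dtype=float)[None, :]
    return s, e


def segment_cylinder_length(segment: RootSegment, spec: CoreSpec, bin_index: int) -> float:
    """Length of one segment inside the core within depth bin ``bin_index``."""
    if not 0 <= bin_index < spec.n_bins:
        raise IndexError(f"bin_index {bin_index} out of range for {spec.n_bins} bins")
    s, e = _segment_arrays(segment)
    out = _cylinder_slab_lengths(
        s,
        e,
        spec.center[0],
        spec.center[1],
        spec.radius,
        spec.depth_bins[bin_index],
        spec.depth_bins[bin_index + 1],
    )
    return float(out[0])


def _minimal_image(starts: np.ndarray, ends: np.ndarray, center: tuple[float, float], domain: tuple[float, float]):
    """Shift each segment by whole periods so its start is the nearest image."""
    Lx, Ly = domain
    shift_x = -np.round((starts[:, 0] - center[0]) / Lx) * Lx
    shift_y = -np.round((starts[:, 1] - center[1]) / Ly) * Ly
    shift = np.column_stack([shift_x, shift_y, np.zeros(len(starts))])
    return starts + shift, ends + shift


def extract_core(plot: PlotSim, spec: CoreSpec) -> CoreSample:
    """Sum segment-cylinder intersection lengths per depth bin and convert to RLD."""
    n_bins = spec.n_bins
    rl = np.zeros(n_bins)
    if plot.n_segments > 0:
        s, e = _minimal_image(plot.starts, plot.ends, spec.center, plot.domain)
        # prefilter: segments whose start is within radius + step of the axis
        margin = spec.radius + float(plot.config.step_length) + 1e-9
        r2 = (s[:, 0] - spec.center[0]) ** 2 + (s[:, 1] - spec.center[1]) ** 2
        near = r2 <= margin * margin
        s, e = s[near], e[near]
        for k in range(n_bins):
            rl[k] = _cylinder_slab_lengths(
                s, e, spec.center[0], spec.center[1], spec.radius,
                spec.depth_bins[k], spec.depth_bins[k + 1],
            ).sum()
    volumes = np.array([spec.bin_volume(k) for k in range(n_bins)])
    return CoreSample(
        location_id=spec.location_id,
        replicate_id=plot.replicate_id,
        species=plot.species,
        phenotype=plot.phenotype,
        depth_bins=spec.depth_bins,
        root_length_by_bin=rl,
        rld_by_bin=rl / volumes,
    )


def whole_plot_profile(plot: PlotSim, depth_bins: Sequence[float] = DEFAULT_DEPTH_BINS) -> RLDProfile:
    """True whole-plot RLD profile: total segment length per depth layer over layer volume."""
    if plot.n_segments == 0 or plot.total_root_length <= 0:
        raise DegenerateSimulationError("plot has no root length; cannot compute a profile")
    bins = tuple(float(b) for b in depth_bins)
    z0 = plot.starts[:, 2]
    z1 = plot.ends[:, 2]
    dz = z1 - z0
    lengths = plot.lengths
    rld = np.zeros(len(bins) - 1)
    area = plot.plot_area
    flat = np.abs(dz) <= _EPS
    for k, (lo, hi) in enumerate(zip(bins, bins[1:])):
        frac = np.zeros(len(lengths))
        inside_flat = flat & (z0 >= lo) & (z0 < hi)
        frac[inside_flat] = 1.0
        sl = ~flat
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - z0) / dz
            t2 = (hi - z0) / dz
        tlo = np.clip(np.minimum(t1, t2), 0.0, 1.0)
        thi = np.clip(np.maximum(t1, t2), 0.0, 1.0)
        frac[sl] = np.maximum(thi[sl] - tlo[sl], 0.0)
        rld[k] = float((frac * lengths).sum()) / (area * (hi - lo))
    return RLDProfile(rld_by_bin=rld, depth_bins=bins, provenance="whole_plot")


def place_random_core(
    plot: PlotSim,
    rng: np.random.Generator,
    diameter: float = DEFAULT_DIAMETER,
    depth_bins: Sequence[float] = DEFAULT_DEPTH_BINS,
) -> CoreSpec:
    """Uniform random core center over one row-by-plant unit cell around the focal plant."""
    R, P = plot.config.row_spacing, plot.config.plant_spacing
    x = rng.uniform(-R / 2.0, R / 2.0)
    y = rng.uniform(-P / 2.0, P / 2.0)
    return CoreSpec(center=(x, y), diameter=diameter, depth_bins=tuple(depth_bins), location_id="random")
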