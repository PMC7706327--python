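"""Univariate rooting-depth metrics and profile comparison.

D_p is the depth above which p% of root length is found, computed from the
cumulative sum over depth bins with linear interpolation inside the bin
that contains the p/100 fraction (mass is treated as uniform within a bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rhizocore.coring import CoreSample, RLDProfile


@dataclass(frozen=True)
class DepthMetric:
    p: float
    value: float  # cm


def _bin_masses(profile) -> tuple[np.ndarray, np.ndarray]:
    """Extract (depth breakpoints, per-bin mass) from a profile or core sample."""
    if isinstance(profile, CoreSample):
        mass = np.asarray(profile.root_length_by_bin, dtype=float)
        bins = np.asarray(profile.depth_bins, dtype=float)
    elif isinstance(profile, RLDProfile):
        bins = np.asarray(profile.depth_bins, dtype=float)
        heights = np.diff(bins)
        mass = np.asarray(profile.rld_by_bin, dtype=float) * heights
    else:  # (bins, values) pair or bare per-bin masses
        mass = np.asarray(profile, dtype=float)
        bins = 10.0 * np.arange(len(mass) + 1)
    return bins, mass


def depth_quantile(profile, p: float) -> DepthMetric:
    """Depth above which p% of root length lies (linear interpolation in-bin)."""
    if not 0 < p < 100:
        raise ValueError(f"p must be in (0, 100), got {p}")
    bins, mass = _bin_masses(profile)
    total = mass.sum()
    if total <= 0:
        raise ValueError("depth quantile undefined for an all-zero profile")
    target = (p / 100.0) * total
    cum = np.cumsum(mass)
    k = int(np.searchsorted(cum, target, side="left"))
    k = min(k, len(mass) - 1)
    below = cum[k - 1] if k > 0 else 0.0
    frac = (target - below) / mass[k]
    value = bins[k] + frac * (bins[k + 1] - bins[k])
    return DepthMetric(p=float(p), value=float(value))


def manhattan_distance(a: RLDProfile, b: RLDProfile) -> float:
    """Sum of absolute per-bin RLD differences between two profiles."""
    if tuple(a.depth_bins) != tuple(b.depth_bins):
        raise ValueError("profiles have mismatched depth bins")
    return float(np.abs(a.rld_by_bin - b.rld_by_bin).sum())
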