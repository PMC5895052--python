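"""Gel densitometry: ladder calibration, size distributions, weighted medians.

A denaturing-gel lane is quantified as a 1-D intensity profile over migration
position. A marker ladder run in parallel anchors the standard log-linear
migration model ``position = A - B * log10(size)``; the lane intensity is then
reassigned to fragment-size bins. Because radiolabel signal scales with
fragment length, the signal-weighted distribution over-represents long
fragments; dividing each bin by its size ("length correction") converts it to
a molar fragment-abundance distribution, from which the median fragment
length is read off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LaneProfile",
    "MarkerLadder",
    "GelCalibration",
    "SizeDistribution",
    "fit_calibration",
    "profile_to_sizes",
    "length_correct",
    "median_size",
    "subtract_baseline",
]


@dataclass(frozen=True)
class LaneProfile:
    """Ordered (migration position, intensity) samples for one gel lane."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        if self.positions.ndim != 1 or self.positions.size < 2:
            raise ValueError("LaneProfile requires at least 2 samples")
        if self.intensities.shape != self.positions.shape:
            raise ValueError("positions and intensities must have equal length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class MarkerLadder:
    """Size <-> position anchor points from co-electrophoresed standards.

    Anchors are stored sorted by increasing migration position; sizes must
    then be strictly decreasing (larger fragments migrate less).
    """

    sizes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if sizes.ndim != 1 or sizes.size < 2 or positions.shape != sizes.shape:
            raise ValueError("MarkerLadder requires >= 2 (size, position) anchors")
        if np.any(sizes <= 0):
            raise ValueError("marker sizes must be positive")
        order = np.argsort(positions)
        sizes, positions = sizes[order], positions[order]
        if not np.all(np.diff(positions) > 0):
            raise ValueError("marker positions must be distinct")
        if not np.all(np.diff(sizes) < 0):
            raise ValueError(
                "marker sizes must decrease strictly with migration position"
            )
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "positions", positions)

    @classmethod
    def from_anchors(cls, anchors) -> "MarkerLadder":
        """Build from an iterable of (size_nt, position) pairs."""
        arr = np.asarray(list(anchors), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("anchors must be (size, position) pairs")
        return cls(sizes=arr[:, 0], positions=arr[:, 1])


@dataclass(frozen=True)
class GelCalibration:
    """Fitted log-linear migration: position = intercept - slope * log10(size)."""

    intercept: float  # A
    slope: float  # B > 0
    size_range: tuple[float, float]  # fitted anchor size bounds (min, max)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def position_of(self, size) -> np.ndarray | float:
        size = np.asarray(size, dtype=float)
        return self.intercept - self.slope * np.log10(size)

    def size_of(self, position) -> np.ndarray | float:
        position = np.asarray(position, dtype=float)
        return 10.0 ** ((self.intercept - position) / self.slope)

    @property
    def position_range(self) -> tuple[float, float]:
        lo = float(self.position_of(self.size_range[1]))
        hi = float(self.position_of(self.size_range[0]))
        return (lo, hi)

    def in_range(self, size) -> np.ndarray:
        size = np.asarray(size, dtype=float)
        return (size >= self.size_range[0]) & (size <= self.size_range[1])


def fit_calibration(ladder: MarkerLadder) -> GelCalibration:
    """Least-squares fit of migration position against log10(fragment size).

    With exactly two anchors the fit interpolates through both. Calling
    ``size_of``/``position_of`` outside the anchor range extrapolates the
    log-linear law; :func:`profile_to_sizes` drops (and counts) such samples
    rather than trusting the extrapolation.
    """
    x = np.log10(ladder.sizes)
    m, c = np.polyfit(x, ladder.positions, 1)
    # anchors are strictly monotone, so the LS slope is strictly negative
    return GelCalibration(
        intercept=float(c),
        slope=float(-m),
        size_range=(float(ladder.sizes.min()), float(ladder.sizes.max())),
    )


@dataclass(frozen=True)
class SizeDistribution:
    """Binned fragment sizes with signal-weighted and molar fractions.

    ``signal_fraction`` is the fraction of total lane intensity per bin;
    ``molar_fraction`` is the length-corrected (per-molecule) fraction.
    ``dropped_intensity`` / ``dropped_samples`` record intensity that fell
    outside the calibration's fitted size range and was excluded.
    """

    bin_edges: np.ndarray
    signal_fraction: np.ndarray
    molar_fraction: np.ndarray | None = None
    dropped_intensity: float = 0.0
    dropped_samples: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        sig = np.asarray(self.signal_fraction, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "signal_fraction", sig)
        if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be increasing with >= 2 entries")
        if sig.shape != (edges.size - 1,):
            raise ValueError("signal_fraction must have one entry per bin")
        if np.any(sig < 0):
            raise ValueError("fractions must be nonnegative")
        if abs(sig.sum() - 1.0) > 1e-9:
            raise ValueError("signal_fraction must sum to 1")
        if self.molar_fraction is not None:
            mol = np.asarray(self.molar_fraction, dtype=float)
            object.__setattr__(self, "molar_fraction", mol)
            if mol.shape != sig.shape or np.any(mol < 0):
                raise ValueError("molar_fraction malformed")
            if abs(mol.sum() - 1.0) > 1e-9:
                raise ValueError("molar_fraction must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def subtract_baseline(profile: LaneProfile) -> LaneProfile:
    """Constant-baseline subtraction (lane minimum); off by default upstream."""
    base = float(profile.intensities.min())
    return LaneProfile(profile.positions, profile.intensities - base)


def profile_to_sizes(
    profile: LaneProfile,
    calibration: GelCalibration,
    bin_width: float = 25.0,
) -> SizeDistribution:
    """Reassign lane intensity to fragment-size bins via the calibration.

    Each profile sample's intensity goes to the size bin containing
    ``calibration.size_of(position)``; no Jacobian re-weighting is applied
    (matching the percentage-of-total-signal convention of gel quantification
    software). Samples mapping outside the fitted size range are dropped and
    counted. Raises ``ValueError`` when no retained intensity remains.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sizes = np.asarray(calibration.size_of(profile.positions), dtype=float)
    keep = calibration.in_range(sizes)
    dropped_intensity = float(profile.intensities[~keep].sum())
    dropped_samples = int(np.count_nonzero(~keep))
    sizes_kept = sizes[keep]
    weights = profile.intensities[keep]
    total = float(weights.sum())
    if total <= 0.0:
        raise ValueError("no lane intensity within the calibration range")
    n_bins = int(np.ceil(calibration.size_range[1] / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    hist, _ = np.histogram(sizes_kept, bins=edges, weights=weights)
    signal_fraction = hist / total
    dist = SizeDistribution(
        bin_edges=edges,
        signal_fraction=signal_fraction,
        dropped_intensity=dropped_intensity,
        dropped_samples=dropped_samples,
    )
    return length_correct(dist)


def length_correct(dist: SizeDistribution) -> SizeDistribution:
    """Convert the signal-weighted distribution to molar fragment abundance.

    Radiolabel signal is proportional to fragment length, so the molar
    fraction of bin *i* is ``signal_fraction_i / center_i``, renormalised.
    """
    centers = dist.bin_centers
    if np.any((centers <= 0) & (dist.signal_fraction > 0)):
        raise ValueError("cannot length-correct signal in a bin centred at <= 0 nt")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(centers > 0, dist.signal_fraction / np.where(centers > 0, centers, 1.0), 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no signal to length-correct")
    return SizeDistribution(
        bin_edges=dist.bin_edges,
        signal_fraction=dist.signal_fraction,
        molar_fraction=w / total,
        dropped_intensity=dist.dropped_intensity,
        dropped_samples=dist.dropped_samples,
    )


def median_size(dist: SizeDistribution, weighting: str = "molar") -> float:
    """Weighted median fragment size in nt.

    The cumulative chosen fraction is traced over bins in increasing size;
    the median interpolates linearly inside the bin straddling 0.5. An exact
    0.5 tie at a bin boundary resolves to that boundary (the lower edge of
    the upper bin).
    """
    if weighting == "molar":
        if dist.molar_fraction is None:
            raise ValueError("molar_fraction not populated; run length_correct first")
        w = dist.molar_fraction
    elif weighting == "signal":
        w = dist.signal_fraction
    else:
        raise ValueError("weighting must be 'molar' or 'signal'")
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5, side="left"))
    if idx >= w.size:  # numerical guard; fractions sum to 1
        idx = w.size - 1
    before = cum[idx] - w[idx]
    lo, hi = dist.bin_edges[idx], dist.bin_edges[idx + 1]
    if w[idx] <= 0:
        return float(lo)
    return float(lo + (0.5 - before) / w[idx] * (hi - lo))
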