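"""Headline statistics: rNMP incorporation frequency from median fragment
lengths, per-genome extrapolation, single-hit termination probabilities and
bypass-fidelity fractions.

The incorporation-frequency estimator compares the median product length of
an untreated reaction (``a``) with the median alkali-stable fragment length
of the same products after NaOH treatment (``b``). Since hydrolysis at each
embedded ribonucleotide adds cut sites on top of the natural product-length
attrition, the average spacing between rNMPs is

    f = a / (a/b - 1) = a*b / (a - b) = 1 / (1/b - 1/a)   [nt per rNMP]

reported in the field's convention "1 rNMP per f nt".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .densitometry import (
    LaneProfile,
    MarkerLadder,
    fit_calibration,
    median_size,
    profile_to_sizes,
    subtract_baseline,
)

__all__ = [
    "EstimateResult",
    "BandTable",
    "TerminationProfile",
    "NoFragmentationError",
    "rnmp_frequency",
    "round_to_sig",
    "expected_rnmps_per_genome",
    "termination_probability",
    "fidelity_fraction",
    "analyze_reaction",
    "AnalysisReport",
]

FULL_LENGTH_LABEL = "FULL"


class NoFragmentationError(ValueError):
    """Treated median >= untreated median: the estimator is undefined."""


def round_to_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (the reporting precision used
    for incorporation frequencies, e.g. 2311 -> 2300)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class EstimateResult:
    """Incorporation-frequency estimate from one untreated/treated lane pair."""

    a: float  # untreated median product length, nt
    b: float  # alkali-treated median fragment length, nt
    frequency: float  # nt per rNMP, unrounded
    frequency_2sf: float  # two significant figures, the reporting precision

    def to_dict(self) -> dict:
        return {
            "untreated_median_nt": self.a,
            "treated_median_nt": self.b,
            "frequency_nt_per_rnmp": self.frequency,
            "frequency_2sf": self.frequency_2sf,
        }


def rnmp_frequency(a: float, b: float) -> EstimateResult:
    """Average rNMP spacing from untreated (``a``) and treated (``b``) medians.

    Raises :class:`NoFragmentationError` when ``a <= b`` (no detectable
    rNMP-dependent fragmentation) and ``ValueError`` on nonpositive medians.
    """
    if a <= 0 or b <= 0:
        raise ValueError("median lengths must be positive")
    if a <= b:
        raise NoFragmentationError("no detectable rNMP-dependent fragmentation")
    frequency = a * b / (a - b)
    return EstimateResult(a=float(a), b=float(b), frequency=float(frequency),
                          frequency_2sf=round_to_sig(frequency, 2))


def expected_rnmps_per_genome(
    frequency: float, genome_length: float = 16_500.0, double_stranded: bool = True
) -> int:
    """Expected embedded rNMPs per genome at spacing ``frequency`` nt/rNMP.

    ``genome_length`` is in bp; a double-stranded genome carries twice its
    length in nucleotides. Rounded to the nearest integer (half up), the
    precision at which per-genome counts are quoted.
    """
    if frequency <= 0 or genome_length <= 0:
        raise ValueError("frequency and genome_length must be positive")
    nt = (2.0 if double_stranded else 1.0) * genome_length
    return int(math.floor(nt / frequency + 0.5))


@dataclass(frozen=True)
class BandTable:
    """Primer-extension band intensities per template position and timepoint.

    Positions are ordered 5'->3' with a distinguished terminal full-length
    row (labelled ``FULL`` in TSV interchange): molecules tallied there ran
    past every scored position. ``intensities`` has shape
    ``(n_positions, n_timepoints)``.
    """

    positions: list[str]
    timepoints: list[str]
    intensities: np.ndarray
    full_length_label: str = FULL_LENGTH_LABEL

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if len(self.positions) < 1:
            raise ValueError("BandTable requires at least one row")
        if arr.shape != (len(self.positions), len(self.timepoints)):
            raise ValueError("intensities must be (n_positions, n_timepoints)")
        if np.any(arr < 0):
            raise ValueError("band intensities must be nonnegative")
        if np.any(arr.sum(axis=0) <= 0):
            raise ValueError("each timepoint must have positive total intensity")

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, float, str]],
                     full_length_label: str = FULL_LENGTH_LABEL) -> "BandTable":
        """Build from long-format (position, intensity, timepoint) rows.

        Positions keep first-appearance order; the full-length row is moved
        to the end and must be present.
        """
        positions: list[str] = []
        timepoints: list[str] = []
        for pos, _, tp in records:
            if pos not in positions:
                positions.append(pos)
            if tp not in timepoints:
                timepoints.append(tp)
        if full_length_label not in positions:
            raise ValueError(f"band table lacks a '{full_length_label}' row")
        positions = [p for p in positions if p != full_length_label] + [full_length_label]
        arr = np.zeros((len(positions), len(timepoints)))
        for pos, inten, tp in records:
            arr[positions.index(pos), timepoints.index(tp)] += float(inten)
        return cls(positions=positions, timepoints=timepoints, intensities=arr,
                   full_length_label=full_length_label)


@dataclass(frozen=True)
class TerminationProfile:
    """Per-position termination probabilities, aggregated over timepoints.

    ``per_timepoint`` has shape ``(n_internal_positions, n_timepoints)``;
    ``mean``/``sd`` are the across-timepoint arithmetic mean and sample
    standard deviation (0 when a single timepoint is given). Positions past
    the last nonzero survivor pool are undefined and reported as NaN.
    ``full_length_fraction[t]`` equals the telescoping product
    ``prod(1 - T(N))`` over defined positions, exactly.
    """

    positions: list[str]
    timepoints: list[str]
    per_timepoint: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    full_length_fraction: np.ndarray


def termination_probability(bands: BandTable) -> TerminationProfile:
    """Single-hit termination probabilities from band intensities.

    At each internal template position N (5'->3'), ``T(N) = I(N) / sum of
    I(k) for k >= N`` per timepoint — the fraction of molecules that reached
    N and stopped there. The terminal full-length row is the survivor class.
    A zero denominator (no molecule reached N) marks truncated data: T is
    reported as NaN there, with a warning.
    """
    arr = bands.intensities
    n_pos = arr.shape[0]
    if n_pos < 2:
        raise ValueError("need at least one internal position besides the terminal row")
    # tail[i, t] = sum of intensities at positions >= i
    tail = np.cumsum(arr[::-1, :], axis=0)[::-1, :]
    internal = slice(0, n_pos - 1)
    denom = tail[internal, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, arr[internal, :] / np.where(denom > 0, denom, 1.0), np.nan)
    if np.isnan(t).any():
        warnings.warn(
            "zero survivor pool before the last scored position: truncated data, "
            "termination probabilities undefined past it",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(t, axis=1)
        sd = (np.nanstd(t, axis=1, ddof=1) if len(bands.timepoints) > 1
              else np.zeros(t.shape[0]))
    full_fraction = arr[-1, :] / arr.sum(axis=0)
    return TerminationProfile(
        positions=list(bands.positions[:-1]),
        timepoints=list(bands.timepoints),
        per_timepoint=t,
        mean=mean,
        sd=sd,
        full_length_fraction=full_fraction,
    )


def fidelity_fraction(base_counts: Mapping[str, float], correct_base: str) -> float:
    """Percentage of insertions opposite a lesion/rNMP that are the correct
    base, to one decimal place (the convention for bypass-fidelity tables)."""
    if not base_counts:
        raise ValueError("empty base counts")
    total = float(sum(base_counts.values()))
    if total <= 0:
        raise ValueError("total count must be positive")
    return round(100.0 * float(base_counts.get(correct_base, 0.0)) / total, 1)


@dataclass(frozen=True)
class AnalysisReport:
    """Full record of one untreated/treated lane-pair analysis."""

    estimate: EstimateResult
    weighting: str
    bin_width: float
    calibration_intercept: float
    calibration_slope: float
    calibration_size_range: tuple[float, float]
    untreated_dropped_intensity: float
    untreated_dropped_samples: int
    treated_dropped_intensity: float
    treated_dropped_samples: int
    untreated_total_intensity: float = 0.0
    treated_total_intensity: float = 0.0

    def to_dict(self) -> dict:
        d = self.estimate.to_dict()
        d.update(
            weighting=self.weighting,
            bin_width_nt=self.bin_width,
            calibration={
                "intercept": self.calibration_intercept,
                "slope": self.calibration_slope,
                "size_range_nt": list(self.calibration_size_range),
            },
            diagnostics={
                "untreated_dropped_intensity": self.untreated_dropped_intensity,
                "untreated_dropped_intensity_fraction": (
                    self.untreated_dropped_intensity / self.untreated_total_intensity
                    if self.untreated_total_intensity else 0.0
                ),
                "untreated_dropped_samples": self.untreated_dropped_samples,
                "treated_dropped_intensity": self.treated_dropped_intensity,
                "treated_dropped_intensity_fraction": (
                    self.treated_dropped_intensity / self.treated_total_intensity
                    if self.treated_total_intensity else 0.0
                ),
                "treated_dropped_samples": self.treated_dropped_samples,
            },
        )
        return d


def analyze_reaction(
    untreated: LaneProfile,
    treated: LaneProfile,
    ladder: MarkerLadder,
    bin_width: float = 25.0,
    weighting: str = "molar",
    baseline_subtract: bool = False,
) -> AnalysisReport:
    """End-to-end lane-pair analysis.

    Fits the ladder calibration, converts both lanes to size distributions,
    length-corrects, takes the weighted median of each and applies
    :func:`rnmp_frequency`. Default weighting is ``molar`` (medians on the
    length-corrected distribution); ``signal`` medians are available because
    quantification conventions differ between labs.
    """
    cal = fit_calibration(ladder)
    if baseline_subtract:
        untreated = subtract_baseline(untreated)
        treated = subtract_baseline(treated)
    dist_u = profile_to_sizes(untreated, cal, bin_width=bin_width)
    dist_t = profile_to_sizes(treated, cal, bin_width=bin_width)
    a = median_size(dist_u, weighting=weighting)
    b = median_size(dist_t, weighting=weighting)
    estimate = rnmp_frequency(a, b)
    return AnalysisReport(
        estimate=estimate,
        weighting=weighting,
        bin_width=bin_width,
        calibration_intercept=cal.intercept,
        calibration_slope=cal.slope,
        calibration_size_range=cal.size_range,
        untreated_dropped_intensity=dist_u.dropped_intensity,
        untreated_dropped_samples=dist_u.dropped_samples,
        treated_dropped_intensity=dist_t.dropped_intensity,
        treated_dropped_samples=dist_t.dropped_samples,
        untreated_total_intensity=untreated.total_intensity,
        treated_total_intensity=treated.total_intensity,
    )
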