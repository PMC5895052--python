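"""Forward simulator: strand synthesis, alkaline hydrolysis, labelling,
gel-lane rendering and single-hit primer-extension band tables.

The statistical model is deliberately the one the downstream analysis
assumes. Synthesis terminates after each nucleotide with probability
``stop_prob`` (geometric product lengths, truncated at the template length);
each position independently embeds an rNMP with probability ``rnmp_prob``
and carries a non-rNMP alkali-labile site with probability
``background_lability_prob``. Alkali cleaves immediately 3' of every marked
position, the ribonucleotide staying on the 5' fragment. Radiolabel signal
is proportional to fragment length (deterministic mode) or binomial in it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ReactionConfig
from .densitometry import GelCalibration, LaneProfile

__all__ = [
    "Strand",
    "FragmentSet",
    "synthesize_strands",
    "hydrolyze",
    "label_fragments",
    "render_lane",
    "simulate_extension_bands",
    "geometric_median_length",
    "tune_reaction",
]

_EMPTY = np.empty(0, dtype=np.int64)


@dataclass(frozen=True)
class Strand:
    """One synthesis product: length plus 0-based marked positions."""

    length: int
    rnmp_positions: np.ndarray
    labile_positions: np.ndarray

    def __post_init__(self) -> None:
        for name in ("rnmp_positions", "labile_positions"):
            pos = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, pos)
            if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] >= self.length):
                raise ValueError(f"{name} must be strictly increasing within [0, length)")
        if self.length < 1:
            raise ValueError("strand length must be >= 1")


@dataclass(frozen=True)
class FragmentSet:
    """Fragment lengths with per-fragment label signal.

    ``strand_index`` maps each fragment back to its source strand, which lets
    tests assert per-strand nucleotide conservation.
    """

    lengths: np.ndarray
    signals: np.ndarray
    strand_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=np.int64)
        signals = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "signals", signals)
        if lengths.size == 0:
            raise ValueError("FragmentSet cannot be empty")
        if np.any(lengths <= 0):
            raise ValueError("fragment lengths must be positive")
        if signals.shape != lengths.shape or np.any(signals < 0):
            raise ValueError("signals must be nonnegative, one per fragment")
        if self.strand_index is not None:
            idx = np.asarray(self.strand_index, dtype=np.int64)
            object.__setattr__(self, "strand_index", idx)
            if idx.shape != lengths.shape:
                raise ValueError("strand_index must have one entry per fragment")

    def __len__(self) -> int:
        return int(self.lengths.size)

    @property
    def total_signal(self) -> float:
        return float(self.signals.sum())

    def molar_median(self) -> float:
        """Median fragment length with every fragment counted once."""
        return float(np.median(self.lengths))


def geometric_median_length(p: float) -> int:
    """Closed-form median of a geometric length with per-nt hazard ``p``.

    ``ceil(ln 0.5 / ln(1 - p))``; e.g. p = 0.01 gives 69 nt. Used as the
    analytic oracle for simulated fragment-length medians.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("hazard must be in (0, 1)")
    return int(math.ceil(math.log(0.5) / math.log1p(-p)))


def _rng_streams(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(c) for c in ss.spawn(4))


def _geometric_lengths(rng: np.random.Generator, n: int, q: float, tmax: int) -> np.ndarray:
    """Truncated geometric product lengths via inverse transform.

    Using explicit uniforms makes length a pointwise monotone function of the
    hazard under a fixed seed, which keeps the bisection tuner stable.
    """
    if q <= 0.0:
        return np.full(n, tmax, dtype=np.int64)
    u = rng.random(n)  # in [0, 1)
    lengths = 1 + np.floor(np.log(1.0 - u) / math.log1p(-q)).astype(np.int64)
    return np.minimum(lengths, tmax)


def _bernoulli_sites(rng: np.random.Generator, total: int, p: float) -> np.ndarray:
    """Sorted 0-based positions of an iid Bernoulli(p) process on [0, total).

    Drawn via geometric gaps, so the cost scales with the number of sites,
    not with ``total``.
    """
    if p <= 0.0 or total == 0:
        return _EMPTY
    chunks: list[np.ndarray] = []
    last = -1
    batch = max(64, int(total * p * 1.3) + 16)
    while last < total:
        gaps = rng.geometric(p, size=batch)
        pos = last + np.cumsum(gaps)
        chunks.append(pos)
        last = int(pos[-1])
    sites = np.concatenate(chunks)
    return sites[sites < total]


def _split_sites(sites: np.ndarray, starts: np.ndarray) -> list[np.ndarray]:
    """Split global sorted sites into per-strand local coordinates."""
    bounds = np.searchsorted(sites, starts)
    return [
        sites[bounds[i]:bounds[i + 1]] - starts[i]
        for i in range(starts.size - 1)
    ]


def synthesize_strands(config: ReactionConfig) -> list[Strand]:
    """Simulate ``n_strands`` synthesis products under ``config``.

    Product length is geometric with hazard ``stop_prob`` truncated at
    ``template_length`` (truncated products count as full-length). rNMP and
    background-labile positions are independent per-position Bernoulli
    processes. Reproducible bit-for-bit from ``config.seed``.
    """
    rng_len, rng_rnmp, rng_bg, _ = _rng_streams(config.seed)
    lengths = _geometric_lengths(
        rng_len, config.n_strands, config.stop_prob, config.template_length
    )
    starts = np.concatenate(([0], np.cumsum(lengths)))
    total = int(starts[-1])
    # Per-position Bernoulli processes are memoryless, so drawing them on the
    # concatenation of all strands is exactly equivalent to per-strand draws.
    rnmp = _split_sites(_bernoulli_sites(rng_rnmp, total, config.rnmp_prob), starts)
    bg = _split_sites(
        _bernoulli_sites(rng_bg, total, config.background_lability_prob), starts
    )
    return [
        Strand(length=int(lengths[i]), rnmp_positions=rnmp[i], labile_positions=bg[i])
        for i in range(config.n_strands)
    ]


def hydrolyze(strands: list[Strand], treated: bool = True) -> FragmentSet:
    """Alkaline hydrolysis of a strand population.

    Treated: every rNMP and background-labile position is cleaved immediately
    3' of the marked nucleotide (which stays on the 5' fragment); a mark on a
    strand's last nucleotide changes nothing. Untreated (NaCl mock): one
    fragment per strand. Per strand, fragment lengths sum exactly to the
    strand length. Signals are initialised to fragment length (full label
    density); :func:`label_fragments` applies the configured labelling.
    """
    if not strands:
        raise ValueError("no strands to hydrolyze")
    lengths = np.fromiter((s.length for s in strands), dtype=np.int64, count=len(strands))
    if not treated:
        return FragmentSet(
            lengths=lengths,
            signals=lengths.astype(float),
            strand_index=np.arange(lengths.size, dtype=np.int64),
        )
    starts = np.concatenate(([0], np.cumsum(lengths)))
    cut_chunks = [starts]
    for i, s in enumerate(strands):
        if s.rnmp_positions.size or s.labile_positions.size:
            marked = np.union1d(s.rnmp_positions, s.labile_positions)
            cut_chunks.append(marked + starts[i] + 1)  # cleave 3' of the mark
    points = np.unique(np.concatenate(cut_chunks))
    frag_lengths = np.diff(points)
    frag_starts = points[:-1]
    strand_index = np.searchsorted(starts[1:], frag_starts, side="right")
    return FragmentSet(
        lengths=frag_lengths,
        signals=frag_lengths.astype(float),
        strand_index=strand_index.astype(np.int64),
    )


def label_fragments(fragments: FragmentSet, config: ReactionConfig) -> FragmentSet:
    """Assign radiolabel signal to each fragment.

    Deterministic mode: signal = length * label_density exactly. Binomial
    mode: signal ~ Binomial(length, label_density), seeded from the reaction
    seed on its own substream.
    """
    if config.labeling_mode == "deterministic":
        signals = fragments.lengths * config.label_density
    else:
        _, _, _, rng_label = _rng_streams(config.seed)
        signals = rng_label.binomial(fragments.lengths, config.label_density).astype(float)
    return FragmentSet(
        lengths=fragments.lengths, signals=signals, strand_index=fragments.strand_index
    )


def render_lane(
    fragments: FragmentSet,
    calibration: GelCalibration,
    resolution: float = 0.02,
    band_sigma: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> LaneProfile:
    """Render a fragment set as a densitometry lane profile.

    Each fragment contributes a Gaussian band centred at
    ``calibration.position_of(length)`` with standard deviation
    ``band_sigma`` (position units) whose integral over position equals the
    fragment's signal; bands are summed on a uniform grid of spacing
    ``resolution``. Optional additive Gaussian noise is clipped at zero.
    """
    if resolution <= 0 or band_sigma <= 0:
        raise ValueError("resolution and band_sigma must be positive")
    sizes, inverse = np.unique(fragments.lengths, return_inverse=True)
    amp = np.bincount(inverse, weights=fragments.signals, minlength=sizes.size)
    centers = np.asarray(calibration.position_of(sizes), dtype=float)
    lo = centers.min() - 6.0 * band_sigma
    hi = centers.max() + 6.0 * band_sigma
    grid = lo + resolution * np.arange(int(np.ceil((hi - lo) / resolution)) + 1)
    intensity = np.zeros_like(grid)
    norm = 1.0 / (band_sigma * math.sqrt(2.0 * math.pi))
    chunk = 512
    for i in range(0, sizes.size, chunk):
        c = centers[i:i + chunk, None]
        a = amp[i:i + chunk, None]
        z = (grid[None, :] - c) / band_sigma
        intensity += (a * np.exp(-0.5 * z * z)).sum(axis=0) * norm
    if noise_sd > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed,
                                                           spawn_key=(7,)))
        intensity = np.maximum(intensity + rng.normal(0.0, noise_sd, grid.size), 0.0)
    return LaneProfile(positions=grid, intensities=intensity)


def simulate_extension_bands(
    termination_probs,
    n_molecules: int,
    seed: int = 0,
    positions=None,
    timepoints=("t1",),
    full_length_label: str = "FULL",
):
    """Simulate single-hit primer-extension band counts.

    Each molecule walks template positions 5'->3', stopping at position *N*
    with probability ``termination_probs[N]`` given survival to *N*;
    survivors of all positions tally in the terminal full-length class. Band
    counts per timepoint are independent multinomial draws of
    ``n_molecules`` molecules over the implied stop classes.
    """
    from .estimators import BandTable  # local import to avoid a cycle

    t = np.asarray(termination_probs, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any((t < 0) | (t > 1)):
        raise ValueError("termination probabilities must lie in [0, 1]")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    surv_before = np.concatenate(([1.0], np.cumprod(1.0 - t)))
    probs = np.concatenate((t * surv_before[:-1], [surv_before[-1]]))
    if positions is None:
        positions = [f"N{i + 1}" for i in range(t.size)]
    labels = list(positions) + [full_length_label]
    rng = np.random.default_rng(seed)
    counts = np.stack(
        [rng.multinomial(n_molecules, probs) for _ in timepoints], axis=1
    ).astype(float)
    return BandTable(positions=labels, timepoints=list(timepoints), intensities=counts,
                     full_length_label=full_length_label)


def _treated_molar_median(config: ReactionConfig) -> float:
    return hydrolyze(synthesize_strands(config), treated=True).molar_median()


def tune_reaction(
    template_length: int,
    n_strands: int,
    target_untreated_median: float,
    target_treated_median: float,
    seed: int = 0,
    iterations: int = 48,
) -> ReactionConfig:
    """Find (stop_prob, rnmp_prob) reproducing target molar medians.

    Bisection against the simulator's own direct molar medians at a fixed
    seed: first ``stop_prob`` is tuned so the untreated median product length
    hits ``target_untreated_median``, then ``rnmp_prob`` so the alkali-treated
    molar median hits ``target_treated_median``. Both medians decrease
    monotonically in their hazard, so plain bisection converges to within the
    sample-median granularity.
    """
    if not 0 < target_treated_median < target_untreated_median <= template_length:
        raise ValueError("targets must satisfy 0 < treated < untreated <= template")

    def untreated_median(q: float) -> float:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        return float(np.median(_geometric_lengths(rng, n_strands, q, template_length)))

    lo, hi = 1e-9, 0.05
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if untreated_median(mid) > target_untreated_median:
            lo = mid
        else:
            hi = mid
    stop_prob = 0.5 * (lo + hi)

    def treated_median(p: float) -> float:
        cfg = ReactionConfig(
            template_length=template_length, n_strands=n_strands,
            stop_prob=stop_prob, rnmp_prob=p, seed=seed,
        )
        return _treated_molar_median(cfg)

    lo, hi = 1e-9, 0.05
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if treated_median(mid) > target_treated_median:
            lo = mid
        else:
            hi = mid
    rnmp_prob = 0.5 * (lo + hi)
    return ReactionConfig(
        template_length=template_length, n_strands=n_strands,
        stop_prob=stop_prob, rnmp_prob=rnmp_prob, seed=seed,
    )
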