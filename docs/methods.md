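# Methods

## The assay and its statistical model

A polymerase synthesises radiolabelled products on a single-stranded
template. Embedded ribonucleotides (rNMPs) are alkali-labile; NaOH cleaves
3′ of each one. Comparing the fragment-length distribution of the same
products before (`a` = median length) and after (`b` = median length)
alkaline treatment separates the natural product-length attrition from the
rNMP-dependent cleavage, giving the average inter-rNMP spacing

    f = a / (a/b − 1) = a·b / (a − b) = 1 / (1/b − 1/a)   [nt per rNMP].

The reciprocal form makes the logic explicit: `1/a` is the per-nucleotide
rate of product ends that exist without treatment, `1/b` the rate after
treatment, and the difference is attributed to rNMP cleavage. When the
per-nucleotide hazards are small, medians and means of geometric spacings
differ only by the constant ln 2, which cancels in the difference, so the
estimator applied to medians estimates the *median* spacing between
rNMP-dependent cuts; the assay's convention is to quote it as "1 rNMP per
f nt". Frequencies are reported to two significant figures and per-genome
counts `round(2·G / f)` (half up) to the nearest integer — the precision at
which such numbers are quoted; unrounded values are always retained in
reports.

`rnmp_frequency` refuses `a ≤ b` ("no detectable rNMP-dependent
fragmentation"): the estimator is undefined without a treatment-dependent
shift.

## Simulator

The generator produces data with exactly the structure the analysis
assumes, so round trips are meaningful end-to-end checks.

* **Strand lengths**: synthesis terminates after each nucleotide with
  probability `stop_prob` (`q`), giving geometric product lengths truncated
  at `template_length`; truncated products count as full length. This models
  complete replication of a circular single-stranded template as one
  full-length linear product (rolling-circle multimers are not modelled).
* **Marked sites**: each position independently carries an rNMP with
  probability `rnmp_prob` (`p_r`) and a background alkali-labile site with
  probability `background_lability_prob` (`p_bg`, e.g. ATP incorporated in
  helicase-dependent reactions). Because per-position Bernoulli processes
  are memoryless, sites are drawn once on the concatenation of all strands
  via geometric gaps (cost scales with the number of sites) and split back —
  exactly equivalent to per-strand draws.
* **Hydrolysis**: treated strands are cut immediately 3′ of every marked
  position, the marked nucleotide staying on the 5′ fragment (which fragment
  retains the ribonucleotide is a ±1 nt convention, immaterial at these
  scales); untreated (mock) strands yield one full-length fragment. Per
  strand, fragment lengths sum exactly to the strand length, and pooled
  treated fragment lengths are distributionally identical to untreated
  strands at the combined hazard `1 − (1−q)(1−p)` (tested by a two-sample
  KS test).
* **Labelling**: `deterministic` sets signal = length × `label_density`
  exactly, making the length correction exactly invertible in round-trip
  tests; `binomial` draws signal ~ Binomial(length, density) for realism.
* **Lane rendering**: each fragment adds a Gaussian band (SD `band_sigma`
  position units) centred at its calibrated migration position, with
  integral equal to its signal, on a uniform grid (`resolution` units per
  sample); optional additive Gaussian noise is clipped at zero. Bands are
  accumulated per unique fragment length, so rendering is exact Gaussian
  quadrature, not a kernel-smoothed histogram.
* **Single-hit extension bands**: molecules walk template positions 5′→3′,
  stopping at position N with the configured probability given survival;
  per-timepoint band counts are independent multinomial draws.

All randomness flows from one integer seed through named substreams
(lengths, rNMP sites, background sites, labelling, lane noise); identical
config + seed reproduces outputs bit-identically, and provenance blocks
record the config hash and seed (and deliberately no timestamp).

Defaults: 20,000 strands per reaction (enough that the sample-median error
of a 5,200-nt median is ≈1%), deterministic labelling at density 1,
noiseless rendering with `band_sigma` 0.1 and `resolution` 0.02 position
units against a three-anchor ladder (10,000/1,000/100 nt at 10/20/30
position units, i.e. one decade per 10 units).

What the generator does **not** emulate: sequence-context bias in rNMP
placement, rolling-circle multimer products, enzyme kinetics (idling,
rNTP-dependent slowdown), 2-D gel artefacts (smiling, lane bleed) and
band-intensity saturation. Passing round-trip tests therefore validates the
*analysis chain* under the assay's own idealisations, not gel physics.

## Densitometry

* **Calibration**: least-squares fit of migration position against
  log10(size); with two anchors the fit interpolates exactly. The fitted
  size range is stored; `size_of`/`position_of` extrapolate algebraically,
  but distribution building drops (and counts) intensity mapping outside the
  fitted range rather than trusting extrapolation.
* **Size distributions**: each profile sample's intensity is assigned to the
  size bin containing its calibrated size, with no Jacobian re-weighting —
  matching the percentage-of-total-signal convention of gel-quantification
  software. Default bin width 25 nt.
* **Length correction**: molar fraction ∝ signal fraction / bin centre,
  renormalised. Radiolabel signal scales with fragment length, so the raw
  signal distribution over-represents long fragments; medians default to the
  corrected (molar) weighting, with signal weighting available because
  quantification conventions differ between labs.
* **Medians**: weighted median with linear interpolation inside the bin
  straddling cumulative fraction 0.5; an exact 0.5 tie at a bin boundary
  resolves to that boundary. Baseline subtraction (lane minimum) is
  available but off by default — background handling is assumed upstream.

## Known bias of the full pipeline

On the reference conditions (direct molar medians 5,200/1,600 nt, ladder
spanning 100–10,000 nt) the end-to-end pipeline reports a spacing of
≈2,490–2,510 nt versus the exact median-pair value 2,311. The cause is
structural, not numerical: fragments shorter than the smallest ladder anchor
(≈4% of treated molecules, but <0.1% of signal) migrate out of the
calibrated range and are excluded, so the retained molar median sits at the
≈52nd percentile of the true distribution, inflating `b` by ≈6% and the
frequency by ≈8%. The same truncation affects the wet assay itself. The
report's diagnostics (dropped intensity and sample counts per lane) flag
when this matters; widening the ladder below 100 nt removes the bias, as the
round-trip tests with a 10–10,000 nt ladder show. No correction for
incomplete template replication is applied: the full-length fraction and
dropped-intensity diagnostics are reported instead, since any such
correction is a lab-specific convention.

## Termination probabilities

At internal template position N (5′→3′), `T(N) = I(N) / Σ_{k≥N} I(k)` per
timepoint — the fraction of molecules that reached N and stopped there. The
terminal full-length row is the survivor class, and the telescoping identity
`Π (1−T(N)) = full-length fraction` holds exactly per timepoint. Profiles
report the arithmetic mean ± sample SD (ddof = 1) across timepoints, the
convention for multi-timepoint single-hit assays; a single timepoint gets
SD 0. A zero survivor pool before the last scored position marks truncated
data: probabilities past it are NaN with a warning rather than an
exception, so partial tables remain analysable.

`fidelity_fraction` is a bare percentage (one decimal place) of insertions
matching the correct base; no confidence interval is attached, but the raw
counts stay available for downstream statistics.

## Design choices and limitations

* Hazard tuning (`tune_reaction`) uses plain bisection against the
  simulator's own direct molar medians at a fixed seed; strand lengths are
  drawn by inverse transform from explicit uniforms so the sample median is
  pointwise monotone in the hazard and bisection is stable. Convergence is
  to the sample-median granularity (a few nt at n = 20,000).
* TSV (tab-separated, header row, UTF-8, '.' decimal) is the canonical
  tabular dialect; JSON for configs and reports. Config files are validated
  strictly (unknown keys rejected, field-level messages).
* The CLI is a thin layer over the library: every subcommand is one library
  call plus I/O, and all error paths exit nonzero with a single
  `error: ...` line.
* Not covered: gel-image (2-D) processing — the pipeline starts from 1-D
  lane profiles; per-band deconvolution; kinetic models of polymerase
  stalling; sequence-resolved incorporation maps.
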