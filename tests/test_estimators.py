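"""Estimators: incorporation frequency, genome extrapolation, termination
probabilities, fidelity fractions and the composed lane-pair analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribogel import (
    BandTable,
    NoFragmentationError,
    ReactionConfig,
    analyze_reaction,
    expected_rnmps_per_genome,
    fidelity_fraction,
    hydrolyze,
    label_fragments,
    render_lane,
    rnmp_frequency,
    simulate_extension_bands,
    synthesize_strands,
    termination_probability,
)
from ribogel.densitometry import MarkerLadder, fit_calibration

valid_medians = st.tuples(
    st.floats(min_value=1.0, max_value=1e6),
    st.floats(min_value=0.5, max_value=0.999),
).map(lambda t: (t[0], t[0] * t[1]))  # (a, b) with 0 < b < a


class TestRnmpFrequency:
    @pytest.mark.parametrize(
        "a,b,freq,freq2sf",
        [
            (5_200, 1_600, 5_200 * 1_600 / 3_600, 2_300),  # M13, normal dNTPs
            (1_900, 860, 1_900 * 860 / 1_040, 1_600),  # minicircle, low dNTPs
        ],
    )
    def test_reported_frequencies_from_measured_median_pairs(self, a, b, freq, freq2sf):
        result = rnmp_frequency(a, b)
        assert result.frequency == pytest.approx(freq)
        assert result.frequency_2sf == freq2sf

    def test_halved_median_returns_the_untreated_median(self):
        # a/(a/b - 1) with b = a/2 is exactly a
        assert rnmp_frequency(4_242.0, 2_121.0).frequency == pytest.approx(4_242.0)

    @settings(deadline=None, derandomize=True)
    @given(valid_medians)
    def test_algebraic_identity_of_the_three_formula_forms(self, ab):
        a, b = ab
        f = rnmp_frequency(a, b).frequency
        assert f == pytest.approx(a / (a / b - 1.0), rel=1e-9)
        assert f == pytest.approx(1.0 / (1.0 / b - 1.0 / a), rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(valid_medians, st.floats(min_value=1.001, max_value=10.0))
    def test_monotonicity_and_scale_invariance(self, ab, k):
        a, b = ab
        f = rnmp_frequency(a, b).frequency
        # increasing b (toward a) increases f; increasing a decreases f
        assert rnmp_frequency(a, min(b * k, 0.9999 * a)).frequency > f
        assert rnmp_frequency(a * k, b).frequency < f
        # scaling both medians scales the frequency
        assert rnmp_frequency(k * a, k * b).frequency == pytest.approx(k * f, rel=1e-9)

    def test_undefined_when_treated_median_not_smaller(self):
        with pytest.raises(NoFragmentationError, match="no detectable"):
            rnmp_frequency(1_000.0, 1_000.0)
        with pytest.raises(ValueError):
            rnmp_frequency(-5.0, 1.0)


class TestGenomeExtrapolation:
    @pytest.mark.parametrize(
        "freq,expected",
        [(2_300, 14), (1_400, 24), (33_000, 1)],
    )
    def test_rnmps_per_double_stranded_mitochondrial_genome(self, freq, expected):
        assert expected_rnmps_per_genome(freq, 16_500, double_stranded=True) == expected

    def test_single_stranded_counts_half_the_nucleotides(self):
        assert expected_rnmps_per_genome(16_500, 16_500, double_stranded=False) == 1

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_rnmps_per_genome(0.0, 16_500)


def _table(intensities, timepoints=("t1",)):
    arr = np.atleast_2d(np.asarray(intensities, float).T).T
    n = arr.shape[0]
    labels = [f"N{i + 1}" for i in range(n - 1)] + ["FULL"]
    return BandTable(positions=labels, timepoints=list(timepoints), intensities=arr)


class TestTermination:
    def test_all_signal_at_full_length_gives_zero_termination(self):
        prof = termination_probability(_table([[0.0], [0.0], [10.0]]))
        np.testing.assert_allclose(prof.mean, [0.0, 0.0])
        np.testing.assert_allclose(prof.full_length_fraction, [1.0])

    def test_toy_band_table_and_telescoping(self):
        prof = termination_probability(_table([[1.0], [1.0], [2.0]]))
        np.testing.assert_allclose(prof.mean, [0.25, 1 / 3])
        # full-length fraction 0.5 = (1 - 0.25)(1 - 1/3)
        assert prof.full_length_fraction[0] == pytest.approx(
            np.prod(1.0 - prof.mean)
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=2, max_value=12))
    def test_telescoping_product_equals_full_length_fraction(self, seed, n_pos):
        rng = np.random.default_rng(seed)
        arr = rng.random((n_pos, 3)) * 10
        arr[-1, :] += 0.1  # nonzero survivor pool at every position
        prof = termination_probability(_table(arr, timepoints=("t1", "t2", "t3")))
        for j in range(3):
            assert np.prod(1.0 - prof.per_timepoint[:, j]) == pytest.approx(
                prof.full_length_fraction[j], rel=1e-9
            )

    def test_scale_invariance_of_termination_probabilities(self):
        arr = np.array([[3.0], [2.0], [5.0]])
        p1 = termination_probability(_table(arr))
        p2 = termination_probability(_table(arr * 123.4))
        np.testing.assert_allclose(p1.mean, p2.mean)

    def test_recovery_from_simulated_single_hit_bands(self):
        truth = np.array([0.25, 1 / 3])
        n = 100_000
        bands = simulate_extension_bands(truth, n, seed=17,
                                         timepoints=("t1", "t2", "t3"))
        prof = termination_probability(bands)
        # 3-SE band on each recovered probability, per timepoint
        reach = np.array([n, n * 0.75])  # expected molecules reaching each position
        se = np.sqrt(truth * (1 - truth) / reach)
        assert np.all(np.abs(prof.per_timepoint - truth[:, None]) < 3 * se[:, None])

    def test_mean_and_sd_aggregate_across_timepoints(self):
        arr = np.array([[1.0, 2.0, 3.0], [9.0, 8.0, 7.0]])
        prof = termination_probability(
            BandTable(positions=["N1", "FULL"], timepoints=["t1", "t2", "t3"],
                      intensities=arr)
        )
        per_tp = arr[0] / arr.sum(axis=0)
        assert prof.mean[0] == pytest.approx(per_tp.mean())
        assert prof.sd[0] == pytest.approx(per_tp.std(ddof=1))

    def test_truncated_data_yields_nan_past_last_survivor(self):
        with pytest.warns(UserWarning, match="truncated"):
            prof = termination_probability(_table([[2.0], [3.0], [0.0], [0.0]]))
        assert prof.per_timepoint[0, 0] == pytest.approx(0.4)
        assert prof.per_timepoint[1, 0] == pytest.approx(1.0)
        assert np.isnan(prof.per_timepoint[2, 0])


class TestFidelity:
    def test_only_correct_base_gives_100_percent(self):
        assert fidelity_fraction({"A": 50}, "A") == 100.0

    def test_majority_correct_base_fraction(self):
        assert fidelity_fraction({"A": 68, "C": 20, "G": 12}, "A") == 68.0

    def test_uniform_counts_give_25_percent_for_any_base(self):
        counts = {"A": 1, "C": 1, "G": 1, "T": 1}
        assert all(fidelity_fraction(counts, b) == 25.0 for b in "ACGT")

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            fidelity_fraction({}, "A")


class TestAnalyzeReaction:
    @pytest.fixture()
    def wide_ladder(self):
        # spans 10-10,000 nt so essentially no intensity is out of range
        return MarkerLadder.from_anchors([(10_000, 10.0), (10, 40.0)])

    def test_round_trip_recovers_direct_molar_medians(self, wide_ladder):
        cfg = ReactionConfig(template_length=7_300, n_strands=4_000,
                             stop_prob=1.4e-4, rnmp_prob=3e-4, seed=23)
        strands = synthesize_strands(cfg)
        cal = fit_calibration(wide_ladder)
        fu = label_fragments(hydrolyze(strands, treated=False), cfg)
        ft = label_fragments(hydrolyze(strands, treated=True), cfg)
        report = analyze_reaction(
            render_lane(fu, cal, band_sigma=0.05),
            render_lane(ft, cal, band_sigma=0.05),
            wide_ladder,
            bin_width=25.0,
        )
        assert abs(report.estimate.a - fu.molar_median()) <= 25.0
        assert abs(report.estimate.b - ft.molar_median()) <= 25.0
        direct = rnmp_frequency(fu.molar_median(), ft.molar_median()).frequency
        assert report.estimate.frequency == pytest.approx(direct, rel=0.08)

    def test_identical_lanes_raise_no_fragmentation(self, wide_ladder):
        cfg = ReactionConfig(template_length=7_300, n_strands=500,
                             stop_prob=2e-4, seed=3)
        cal = fit_calibration(wide_ladder)
        frags = label_fragments(hydrolyze(synthesize_strands(cfg), False), cfg)
        lane = render_lane(frags, cal)
        with pytest.raises(NoFragmentationError):
            analyze_reaction(lane, lane, wide_ladder)
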