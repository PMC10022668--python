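"""Descriptor analyses: rank agreement, standardization, calibration, RMs."""

import numpy as np
import pandas as pd
import pytest

from duoscale.descriptor_scaling import (
    RankingRecord,
    RelativeMagnitudeTable,
    calibrate_participants,
    check_monotonicity,
    compare_sensations,
    fit_power_law,
    geometric_mean,
    load_reference_table,
    rank_agreement,
    read_responses_tsv,
    relative_magnitudes,
    standardize_responses,
    write_responses_tsv,
)
from duoscale.exceptions import DuoscaleError
from duoscale.simulate import (
    ResponderParams,
    simulate_descriptor_experiment,
    simulate_magnitude_responses,
    simulate_rankings,
)

REF = tuple("abcdefghijkl")


class TestRankAgreement:
    def test_unanimous_reference_order_scores_100_everywhere(self):
        recs = [RankingRecord(i, "pain", REF) for i in range(5)]
        agg = rank_agreement(recs, REF)
        assert agg["pct_at_reference"].eq(100.0).all()
        assert agg["modal_rank"].tolist() == list(range(12))

    def test_half_the_sample_swapping_one_pair_halves_those_two(self):
        swapped = list(REF)
        swapped[3], swapped[4] = swapped[4], swapped[3]
        recs = [RankingRecord(i, "pain", REF) for i in range(5)] + [
            RankingRecord(5 + i, "pain", tuple(swapped)) for i in range(5)
        ]
        agg = rank_agreement(recs, REF)
        assert agg.loc["d", "pct_at_reference"] == 50.0
        assert agg.loc["e", "pct_at_reference"] == 50.0
        others = agg.drop(index=["d", "e"])
        assert others["pct_at_reference"].eq(100.0).all()

    def test_matches_independent_counting_oracle(self):
        recs = simulate_rankings(REF, swap_prob=0.3, n=20, seed=4)
        agg = rank_agreement(recs, REF)
        # brute-force tally, written independently of the implementation
        for pos, label in enumerate(REF):
            hits = sum(rec.ranking[pos] == label for rec in recs)
            assert agg.loc[label, "pct_at_reference"] == pytest.approx(100.0 * hits / 20)

    def test_non_permutation_record_rejected(self):
        recs = [RankingRecord(0, "pain", REF[:-1] + ("a",))]
        with pytest.raises(DuoscaleError, match="permutation"):
            rank_agreement(recs, REF)

    def test_empty_input_rejected(self):
        with pytest.raises(DuoscaleError):
            rank_agreement([], REF)


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 10, 100], 10.0), ([7, 7, 7], 7.0), ([2, 8], 4.0)],
    )
    def test_known_values(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize("values", [[1.0, 0.0], [2.0, -1.0], []])
    def test_nonpositive_or_empty_rejected(self, values):
        with pytest.raises(DuoscaleError):
            geometric_mean(values)


def _responses(rows):
    return pd.DataFrame(
        rows,
        columns=["participant", "stimulus_type", "stimulus_intensity", "modality",
                 "trial", "value"],
    )


class TestStandardize:
    def test_single_stimulus_block_standardizes_to_one(self):
        rows = [(0, "line", 5.0, "handgrip", t, v) for t, v in [(1, 2.0), (2, 4.0), (3, 8.0)]]
        out = standardize_responses(_responses(rows))
        assert out["std_value"].tolist() == pytest.approx([1.0])

    def test_block_product_is_one(self):
        rng = np.random.default_rng(8)
        rows = [
            (p, "line", s, m, t, float(rng.lognormal(1.0, 0.4)))
            for p in range(3)
            for m in ("handgrip", "button")
            for s in (1.0, 2.0, 4.0, 8.0)
            for t in (1, 2, 3)
        ]
        out = standardize_responses(_responses(rows))
        logsums = (
            out.assign(l=np.log(out["std_value"]))
            .groupby(["participant", "modality", "stimulus_type"])["l"]
            .sum()
        )
        assert np.allclose(logsums, 0.0, atol=1e-9)

    def test_matches_hand_computation(self):
        # participant 0, handgrip, lines 1 and 4:
        #   cell gms: gm(2,4,8)=4, gm(1,8,8)=4; grand gm = 4 -> both cells 1.0
        rows = (
            [(0, "line", 1.0, "handgrip", t, v) for t, v in [(1, 2.0), (2, 4.0), (3, 8.0)]]
            + [(0, "line", 4.0, "handgrip", t, v) for t, v in [(1, 1.0), (2, 8.0), (3, 8.0)]]
        )
        out = standardize_responses(_responses(rows)).set_index("stimulus_intensity")
        assert out.loc[1.0, "std_value"] == pytest.approx(1.0)
        assert out.loc[4.0, "std_value"] == pytest.approx(1.0)

    def test_incomplete_cells_dropped_with_warning(self, caplog):
        rows = [(0, "line", 1.0, "handgrip", t, 2.0) for t in (1, 2, 3)] + [
            (0, "line", 2.0, "handgrip", 1, 5.0)  # only one trial
        ]
        with caplog.at_level("WARNING"):
            out = standardize_responses(_responses(rows))
        assert len(out) == 1
        assert "incomplete" in caplog.text

    def test_nonpositive_values_rejected(self):
        rows = [(0, "line", 1.0, "handgrip", 1, -2.0)]
        with pytest.raises(DuoscaleError):
            standardize_responses(_responses(rows))


class TestPowerLaw:
    def test_square_root_responses_give_half_exponent(self):
        lengths = np.array([1, 2, 4, 8, 16, 32, 64], float)
        fit = fit_power_law(lengths, lengths**0.5)
        assert fit.exponent_beta == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_scale_factor_lands_in_intercept(self):
        lengths = np.array([1, 2, 4, 8, 16, 32, 64], float)
        fit = fit_power_law(lengths, 3.0 * lengths**0.7)
        assert fit.exponent_beta == pytest.approx(0.7)
        assert fit.intercept_alpha == pytest.approx(np.log(3.0))

    def test_zero_length_variance_rejected(self):
        with pytest.raises(DuoscaleError):
            fit_power_law([5, 5, 5], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(8))
    def test_noisy_exponent_recovery_within_tolerance(self, seed):
        # 7 lengths x 3 reps, lognormal noise sigma=0.1 around beta=0.6
        rng = np.random.default_rng(seed)
        lengths = np.repeat([1, 2, 4, 8, 16, 32, 64], 3).astype(float)
        resp = lengths**0.6 * np.exp(rng.normal(0.0, 0.1, lengths.size))
        fit = fit_power_law(lengths, resp)
        assert abs(fit.exponent_beta - 0.6) < 0.08


class TestRelativeMagnitudes:
    def _run(self, params, intensities=(1.0, 2.0, 4.0, 8.0), n=3, seed=0):
        rng = np.random.default_rng(seed)
        resp = pd.concat(
            [
                simulate_magnitude_responses(
                    [1, 2, 4, 8, 16, 32, 64], params, n, rng=rng
                ),
                simulate_magnitude_responses(
                    intensities, params, n,
                    stimulus_type="pain_descriptor",
                    recorded_intensity=np.arange(1, len(intensities) + 1),
                    rng=rng,
                ),
            ],
            ignore_index=True,
        )
        std = standardize_responses(resp)
        fits = calibrate_participants(std)
        labels = [f"L{i}" for i in range(1, len(intensities) + 1)]
        return relative_magnitudes(std, fits, "pain", labels=labels)

    def test_noiseless_rms_proportional_to_true_intensities(self):
        rm = self._run(ResponderParams(lognoise_sd=0.0))
        vals = rm.values_in_rank_order(labels=["L1", "L2", "L3", "L4"])
        ratios = vals / np.array([1.0, 2.0, 4.0, 8.0])
        assert np.allclose(ratios, ratios[0], rtol=1e-9)

    def test_modality_invariance_under_different_exponents(self):
        a = self._run(ResponderParams(lognoise_sd=0.0, beta_grip=1.7, beta_button=1.1))
        b = self._run(ResponderParams(lognoise_sd=0.0, beta_grip=0.5, beta_button=2.0))
        va = a.values_in_rank_order(labels=["L1", "L2", "L3", "L4"])
        vb = b.values_in_rank_order(labels=["L1", "L2", "L3", "L4"])
        assert np.allclose(va / va[0], vb / vb[0], rtol=1e-9)

    def test_nonpositive_calibration_exponent_rejected(self):
        std = pd.DataFrame(
            {
                "participant": [0, 0],
                "modality": ["handgrip", "handgrip"],
                "stimulus_type": ["pain_descriptor", "pain_descriptor"],
                "stimulus_intensity": [1.0, 2.0],
                "std_value": [0.5, 2.0],
            }
        )
        from duoscale.descriptor_scaling import CalibrationFit

        fits = {(0, "handgrip"): CalibrationFit("handgrip", -0.2, 0.0, 1.0)}
        with pytest.raises(DuoscaleError, match="non-invertible"):
            relative_magnitudes(std, fits, "pain", allow_single_modality=True)

    def test_modulus_invariance_scaling_one_participant(self):
        params = ResponderParams(lognoise_sd=0.1)
        rng = np.random.default_rng(12)
        resp = pd.concat(
            [
                simulate_magnitude_responses([1, 2, 4, 8, 16, 32, 64], params, 3, rng=rng),
                simulate_magnitude_responses(
                    [1.0, 2.0, 4.0], params, 3,
                    stimulus_type="pain_descriptor",
                    recorded_intensity=[1, 2, 3],
                    rng=rng,
                ),
            ],
            ignore_index=True,
        )
        scaled = resp.copy()
        scaled.loc[scaled["participant"] == 1, "value"] *= 7.0
        labels = ["L1", "L2", "L3"]
        rm_a = relative_magnitudes(
            standardize_responses(resp),
            calibrate_participants(standardize_responses(resp)),
            "pain", labels=labels,
        )
        rm_b = relative_magnitudes(
            standardize_responses(scaled),
            calibrate_participants(standardize_responses(scaled)),
            "pain", labels=labels,
        )
        for l in labels:
            assert rm_a.rm[l] == pytest.approx(rm_b.rm[l], rel=1e-9)


class TestReferenceTableAnalyses:
    def test_fatigue_vs_pain_paired_t_matches_published_value(self):
        res = compare_sensations(load_reference_table("fatigue"), load_reference_table("pain"))
        assert res.df == 11
        assert res.t == pytest.approx(-1.38, abs=0.01)
        assert 0.15 < res.p < 0.25

    def test_identical_tables_give_zero_t(self):
        t = load_reference_table("pain")
        res = compare_sensations(t, t)
        assert res.t == 0.0 and not res.degenerate

    def test_constant_shift_is_degenerate(self):
        t = load_reference_table("pain")
        shifted = RelativeMagnitudeTable("fatigue", {k: v + 0.5 for k, v in t.rm.items()})
        res = compare_sensations(shifted, t)
        assert res.degenerate and np.isinf(res.t)

    def test_mismatched_descriptor_sets_rejected(self):
        t = load_reference_table("pain")
        partial = RelativeMagnitudeTable("fatigue", dict(list(t.rm.items())[:6]))
        with pytest.raises(DuoscaleError):
            compare_sensations(partial, t)

    def test_reference_inversions_flagged_exactly(self):
        assert check_monotonicity(load_reference_table("pain")) == [
            ("faint", "very weak")
        ]
        assert check_monotonicity(load_reference_table("fatigue")) == [
            ("moderate", "barely strong")
        ]

    def test_strictly_increasing_table_flags_nothing(self):
        toy = RelativeMagnitudeTable("pain", {"L1": 1.0, "L2": 2.0, "L3": 3.0})
        assert check_monotonicity(toy, labels=["L1", "L2", "L3"]) == []


def test_responses_tsv_roundtrip(tmp_path):
    resp = simulate_descriptor_experiment(n_participants=2, seed=1)
    path = tmp_path / "resp.tsv"
    write_responses_tsv(resp, path)
    restored = read_responses_tsv(path)
    pd.testing.assert_frame_equal(resp, restored)
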