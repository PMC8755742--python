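"""Normalization chain: factor conventions, hand-computed toys, inversion."""

import numpy as np
import pandas as pd
import pytest

import afproteome as afp
from afproteome.datatypes import AbundanceMatrix


def _raw(df):
    return AbundanceMatrix(df, scale="raw")


class TestHybridization:
    def test_uniform_double_gives_half_factor(self):
        ref = pd.Series({"C1": 10.0, "C2": 20.0})
        df = pd.DataFrame({"C1": [20.0, 10.0], "C2": [40.0, 20.0],
                           "A1": [6.0, 7.0]}, index=["S1", "S2"])
        out, factors = afp.hybridization_normalize(_raw(df), ["C1", "C2"], ref)
        assert factors["S1"] == pytest.approx(0.5)
        assert factors["S2"] == pytest.approx(1.0)
        assert out.data.loc["S1", "A1"] == pytest.approx(3.0)
        # post-condition: per-sample median control ratio is 1
        ratios = ref / out.data[["C1", "C2"]]
        assert np.allclose(ratios.median(axis=1), 1.0)

    def test_reference_sample_is_unchanged(self):
        ref = pd.Series({"C1": 5.0})
        df = pd.DataFrame({"C1": [5.0], "A1": [9.0]}, index=["S1"])
        out, factors = afp.hybridization_normalize(_raw(df), ["C1"], ref)
        assert factors["S1"] == 1.0
        assert np.array_equal(out.values, df.to_numpy())

    def test_requires_controls(self, toy_matrix):
        with pytest.raises(afp.ValidationError, match="control"):
            afp.hybridization_normalize(toy_matrix, [], pd.Series(dtype=float))

    def test_recovers_planted_factors(self, small_sim):
        matrix, _, annotation, truth = small_sim
        _, factors = afp.hybridization_normalize(
            matrix, annotation.control_ids, truth.reference
        )
        rel = np.abs(
            factors.to_numpy() * truth.samples["hyb_factor"].to_numpy() - 1.0
        )
        assert rel.max() < 1e-6


class TestMedianNormalize:
    def test_single_sample_all_factors_one(self):
        df = pd.DataFrame({"A1": [3.0], "A2": [7.0]}, index=["S1"])
        bins = pd.Series({"A1": 1, "A2": 1})
        out, factors = afp.median_normalize(_raw(df), bins)
        assert np.allclose(factors.to_numpy(), 1.0)
        assert np.array_equal(out.values, df.to_numpy())

    def test_three_sample_toy_hand_computed(self):
        # S3 is uniformly 3x the others within the bin -> factor ~ 1/3
        base = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        df = pd.DataFrame([base, base, 3 * base], index=["S1", "S2", "S3"],
                          columns=[f"A{i}" for i in range(5)])
        bins = pd.Series(1, index=df.columns)
        out, factors = afp.median_normalize(_raw(df), bins)
        # analyte medians equal base, so S3's ratios are all exactly 1/3
        assert factors.loc["S3", 1] == pytest.approx(1 / 3)
        assert factors.loc["S1", 1] == pytest.approx(1.0)
        assert np.allclose(out.data.loc["S3"], base)

    def test_bins_corrected_independently(self):
        base = np.array([2.0, 4.0, 6.0])
        rows = {
            "S1": np.concatenate([base, base]),
            "S2": np.concatenate([base, base]),
            "S3": np.concatenate([2 * base, 5 * base]),
        }
        cols = [f"A{i}" for i in range(6)]
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = cols
        bins = pd.Series([1, 1, 1, 2, 2, 2], index=cols)
        out, factors = afp.median_normalize(_raw(df), bins)
        assert factors.loc["S3", 1] == pytest.approx(0.5)
        assert factors.loc["S3", 2] == pytest.approx(0.2)
        assert np.allclose(out.data.loc["S3"], np.concatenate([base, base]))

    def test_empty_bin_rejected(self):
        df = pd.DataFrame({"A1": [1.0, 2.0]}, index=["S1", "S2"])
        out, factors = afp.median_normalize(_raw(df), pd.Series({"A1": 1}))
        assert set(factors.columns) == {1}


class TestPlateCalibrate:
    def test_plate_matching_reference_gets_unit_factors(self):
        df = pd.DataFrame({"A1": [4.0, 4.0]}, index=["S1", "S2"])
        plates = pd.Series({"S1": "P1", "S2": "P1"})
        ref = pd.Series({"A1": 4.0})
        out, factors = afp.plate_calibrate(_raw(df), plates, ref)
        assert factors.loc["P1", "A1"] == 1.0
        assert np.array_equal(out.values, df.to_numpy())

    def test_doubled_plate_gets_half_factor(self):
        df = pd.DataFrame({"A1": [8.0, 8.0]}, index=["S1", "S2"])
        plates = pd.Series({"S1": "P1", "S2": "P1"})
        ref = pd.Series({"A1": 4.0})
        _, factors = afp.plate_calibrate(_raw(df), plates, ref)
        assert factors.loc["P1", "A1"] == pytest.approx(0.5)

    def test_recovers_planted_plate_factors(self, small_sim):
        matrix, metadata, annotation, truth = small_sim
        hyb_free, _ = afp.hybridization_normalize(
            matrix, annotation.control_ids, truth.reference
        )
        _, factors = afp.plate_calibrate(
            hyb_free,
            metadata.table["plate_id"],
            truth.reference,
            calibrators=truth.calibrators,
        )
        planted = truth.plate_factors.loc[factors.index, factors.columns]
        rel = np.abs((factors * planted).to_numpy() - 1.0)
        assert rel.max() < 1e-6


class TestLog2:
    def test_powers_of_two(self, toy_matrix):
        out = afp.log2_transform(toy_matrix)
        assert out.scale == "log2"
        assert out.data.loc["S3", "A2"] == pytest.approx(10.0)

    def test_round_trip(self, toy_matrix):
        out = afp.log2_transform(toy_matrix)
        back = 2.0 ** out.values
        assert np.abs(back - toy_matrix.values).max() < 1e-12

    def test_rejects_double_transform(self, toy_matrix):
        once = afp.log2_transform(toy_matrix)
        with pytest.raises(afp.ValidationError, match="already log2"):
            afp.log2_transform(once)

    def test_nonpositive_rejected_at_construction(self):
        with pytest.raises(afp.ValidationError, match="nonpositive"):
            AbundanceMatrix(pd.DataFrame({"A1": [0.0]}, index=["S1"]), scale="raw")


def test_chain_preserves_group_contrasts(small_sim, small_norm):
    """Scale corrections never shift group differences: estimates on the
    normalized matrix equal those on the planted log2 signal to 1e-9."""
    matrix, metadata, annotation, truth = small_sim
    norm, _ = small_norm
    is_term = (metadata.table["group"] == "term").to_numpy()
    signal = truth.log2_signal[norm.data.columns]
    diff_signal = signal[is_term].mean(axis=0) - signal[~is_term].mean(axis=0)
    diff_norm = norm.data[is_term].mean(axis=0) - norm.data[~is_term].mean(axis=0)
    assert np.abs(diff_signal - diff_norm).max() < 1e-9


def test_normalization_preserves_shape_and_ids(small_sim):
    matrix, metadata, annotation, truth = small_sim
    out, factors = afp.normalize_chain(
        matrix,
        annotation,
        control_reference=truth.reference,
        calibrator_reference=truth.reference,
        plate_ids=metadata.table["plate_id"],
        calibrators=truth.calibrators,
        log2=False,
    )
    assert out.sample_ids == matrix.sample_ids
    assert out.analyte_ids == matrix.analyte_ids
    assert (factors["hyb"] > 0).all()
    assert (factors["plate"].to_numpy() > 0).all()
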