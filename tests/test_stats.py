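"""CPM normalization, paired log2 fold changes and robust-z scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from clonescreen import (
    ConfigurationError,
    CountMatrix,
    SampleSheet,
    ValidationError,
    compute_log2fc,
    normalize_cpm,
    pair_samples,
    score_shrnas,
)
from clonescreen.stats import median_center
from conftest import make_library


def cm_from(values, samples):
    idx = pd.Index([f"sh{i}" for i in range(len(values))], name="shrna_id")
    return CountMatrix(pd.DataFrame(values, index=idx, columns=samples.sample_ids), samples)


@pytest.fixture
def one_rep_samples():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["t0_r1", "t14_r1"],
                "screen": ["S", "S"],
                "timepoint": ["t0", "t14"],
                "replicate": [1, 1],
            }
        )
    )


class TestNormalizeCpm:
    def test_basic_scaling(self, one_rep_samples):
        cm = cm_from([[10, 10], [990, 990]], one_rep_samples)
        norm = normalize_cpm(cm, pseudocount=0)
        assert norm["t0_r1"].tolist() == [10_000.0, 990_000.0]

    def test_equal_column_symmetry(self, one_rep_samples):
        k = 8
        idx = pd.Index([f"sh{i}" for i in range(k)], name="shrna_id")
        cm = CountMatrix(
            pd.DataFrame(7, index=idx, columns=one_rep_samples.sample_ids),
            one_rep_samples,
        )
        norm = normalize_cpm(cm, pseudocount=0)
        assert np.allclose(norm, 1e6 / k)

    def test_pseudocount_added_after_scaling(self, one_rep_samples):
        cm = cm_from([[0, 0], [100, 100]], one_rep_samples)
        norm = normalize_cpm(cm, pseudocount=1)
        assert norm["t0_r1"].tolist() == [1.0, 1e6 + 1.0]

    def test_zero_column_sum_names_sample(self, one_rep_samples):
        cm = cm_from([[0, 5], [0, 5]], one_rep_samples)
        with pytest.raises(ValidationError, match="t0_r1"):
            normalize_cpm(cm)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_column_sums_equal_one_million(self, seed):
        """Pre-pseudocount CPM columns sum to 1e6 (1e-6 relative)."""
        samples = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["t0_r1", "t14_r1"],
                    "screen": ["S", "S"],
                    "timepoint": ["t0", "t14"],
                    "replicate": [1, 1],
                }
            )
        )
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 1000, size=(30, 2))
        vals[0] += 1  # keep sums positive
        cm = cm_from(vals, samples)
        norm = normalize_cpm(cm, pseudocount=0)
        assert np.allclose(norm.sum(axis=0), 1e6, rtol=1e-6)


class TestLog2FC:
    def test_identity_and_halving(self, one_rep_samples):
        cm = cm_from([[100, 100], [100, 50], [100, 200]], one_rep_samples)
        # per-column CPM: t0 all equal; t14 reweighted -> use pseudocount-free
        norm = pd.DataFrame(
            {"t0_r1": [100.0, 100.0, 100.0], "t14_r1": [100.0, 50.0, 200.0]},
            index=cm.counts.index,
        )
        lfc = compute_log2fc(norm, one_rep_samples, "S")
        assert lfc["S:r1"].tolist() == [0.0, -1.0, 1.0]

    def test_full_dropout_value(self, one_rep_samples):
        """count 0 at t14 with pseudocount 1 against 1000 CPM at t0."""
        cm = cm_from([[1000, 0], [999_000, 1_000_000]], one_rep_samples)
        norm = normalize_cpm(cm, pseudocount=1)
        lfc = compute_log2fc(norm, one_rep_samples, "S")
        assert lfc["S:r1"].iloc[0] == pytest.approx(np.log2(1 / 1001), abs=1e-9)
        assert lfc["S:r1"].iloc[0] == pytest.approx(-9.967, abs=1e-3)

    def test_requires_positive_cells(self, one_rep_samples):
        norm = pd.DataFrame(
            {"t0_r1": [0.0, 1.0], "t14_r1": [1.0, 1.0]},
            index=pd.Index(["a", "b"], name="shrna_id"),
        )
        with pytest.raises(ValidationError, match="pseudocount"):
            compute_log2fc(norm, one_rep_samples, "S")

    def test_unpaired_t14_is_configuration_error(self):
        samples = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b"],
                    "screen": ["S", "S"],
                    "timepoint": ["t0", "t14"],
                    "replicate": [1, 2],
                }
            )
        )
        with pytest.raises(ConfigurationError, match="no matching t0"):
            pair_samples(samples, "S")

    def test_explicit_pairing_overrides(self):
        samples = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b"],
                    "screen": ["S", "S"],
                    "timepoint": ["t0", "t14"],
                    "replicate": [1, 2],
                }
            )
        )
        pairs = pair_samples(samples, "S", pairing={"b": "a"})
        assert pairs == [("S:r2", "a", "b")]


def lfc_frame(values_by_rep):
    idx = pd.Index([f"sh{i}" for i in range(len(next(iter(values_by_rep.values()))))],
                   name="shrna_id")
    return pd.DataFrame(values_by_rep, index=idx)


def library_for(lfc):
    rows = [(sid, "G1") for sid in lfc.index]
    df = pd.DataFrame(rows, columns=["shrna_id", "gene_symbol"])
    from conftest import make_barcode

    df["barcode"] = [make_barcode(i) for i in range(len(df))]
    from clonescreen import LibraryAnnotation

    return LibraryAnnotation(df)


class TestScoreShrnas:
    def test_at_median_z_zero_p_one(self):
        lfc = lfc_frame({"r1": [-1.0, -0.5, 0.0, 0.5, 1.0]})
        lib = library_for(lfc)
        out = score_shrnas(lfc, lib)
        mid = out.loc["sh2"]
        assert mid["z"] == 0.0
        assert mid["p"] == 1.0
        assert not mid["significant"]

    def test_one_scaled_mad_below_median(self):
        """A hairpin at median - 1.4826*MAD scores z=-1, p~0.3173."""
        lfc = lfc_frame({"r1": [-1.4826, -1.0, 0.0, 1.0, 2.0]})
        lib = library_for(lfc)
        out = score_shrnas(lfc, lib)  # median 0, MAD 1
        assert out.loc["sh0", "z"] == pytest.approx(-1.0, abs=1e-12)
        assert out.loc["sh0", "p"] == pytest.approx(0.3173, abs=2e-4)

    def test_stouffer_combination_two_replicates(self):
        """Two replicates each at z=-2 combine to z=-2.828, p~0.00468."""
        col = [-2 * 1.4826, -1.0, 0.0, 1.0, 2.0]
        lfc = lfc_frame({"r1": col, "r2": col})
        lib = library_for(lfc)
        out = score_shrnas(lfc, lib, alpha=0.05)
        assert out.loc["sh0", "z"] == pytest.approx(-2 * np.sqrt(2), abs=1e-12)
        assert out.loc["sh0", "p"] == pytest.approx(0.00468, abs=5e-5)
        assert bool(out.loc["sh0", "significant"])

    def test_zero_mad_is_error(self):
        lfc = lfc_frame({"r1": [0.0, 0.0, 0.0, 5.0]})
        lib = library_for(lfc)
        with pytest.raises(ValidationError, match="MAD"):
            score_shrnas(lfc, lib)

    def test_unknown_shrna_rejected(self, tiny_library):
        lfc = lfc_frame({"r1": [0.0, 1.0, -1.0]})
        with pytest.raises(ValidationError, match="absent"):
            score_shrnas(lfc, tiny_library)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        shift=st.floats(min_value=-5, max_value=5, allow_nan=False),
        seed=st.integers(min_value=0, max_value=999),
    )
    def test_shift_invariance(self, shift, seed):
        """Adding a constant to one replicate's log2FCs changes nothing."""
        rng = np.random.default_rng(seed)
        lfc = lfc_frame({"r1": rng.normal(size=25), "r2": rng.normal(size=25)})
        lib = library_for(lfc)
        base = score_shrnas(lfc, lib)
        shifted = lfc.copy()
        shifted["r1"] = shifted["r1"] + shift
        out = score_shrnas(shifted, lib)
        np.testing.assert_allclose(out["z"], base["z"], atol=1e-9)
        np.testing.assert_allclose(out["p"], base["p"], atol=1e-9)

    def test_sign_symmetry(self):
        """Hairpins at median +/- c*MAD get equal p-values."""
        lfc = lfc_frame({"r1": [-2.0, -1.0, 0.0, 1.0, 2.0]})
        lib = library_for(lfc)
        out = score_shrnas(lfc, lib)
        assert out.loc["sh0", "p"] == pytest.approx(out.loc["sh4", "p"], abs=1e-12)
        assert out.loc["sh1", "p"] == pytest.approx(out.loc["sh3", "p"], abs=1e-12)

    def test_null_calibration_small(self):
        """Under a homogeneous normal null the p <= alpha fraction is ~alpha."""
        rng = np.random.default_rng(123)
        n = 4000
        lfc = lfc_frame({"r1": rng.normal(size=n), "r2": rng.normal(size=n)})
        lib = library_for(lfc)
        out = score_shrnas(lfc, lib, alpha=0.05)
        frac = out["significant"].mean()
        # binomial 3-sigma band around 0.05 at n=4000
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n) + 1e-9

    def test_bh_adjustment_flag(self):
        rng = np.random.default_rng(5)
        lfc = lfc_frame({"r1": rng.normal(size=100)})
        lib = library_for(lfc)
        out = score_shrnas(lfc, lib, alpha=0.05, adjust=True)
        assert "p_adj" in out.columns
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        np.testing.assert_allclose(
            out["p_adj"], sps.false_discovery_control(out["p"], method="bh")
        )


def test_median_center_zeroes_replicate_medians():
    rng = np.random.default_rng(9)
    lfc = lfc_frame({"r1": rng.normal(2.0, 1, 51), "r2": rng.normal(-1.0, 1, 51)})
    centered = median_center(lfc)
    assert np.allclose(centered.median(axis=0), 0.0)
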