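"""Masking, size factors (with an independent DESeq2-family oracle),
log2 transform and fold-change calls."""

import numpy as np
import pandas as pd
import pytest

from lignosom.normalize import (fold_changes, mask_low_counts,
                                normalize_log2, size_factors)
from lignosom.simulate import SimConfig, simulate


def _info(samples, substrate_of):
    rows = [(s, "sp", substrate_of[s], i + 1)
            for i, s in enumerate(samples)]
    df = pd.DataFrame(rows, columns=["sample_id", "species", "substrate",
                                     "replicate"]).set_index("sample_id")
    # replicate numbering restarts within each substrate
    df["replicate"] = df.groupby("substrate").cumcount() + 1
    return df


class TestMaskLowCounts:
    def setup_method(self):
        self.samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        self.info = _info(self.samples,
                          dict(a1="maltose", a2="maltose", a3="maltose",
                               b1="avicel", b2="avicel", b3="avicel"))

    def test_condition_mean_below_threshold_is_zeroed(self):
        counts = pd.DataFrame([[4, 4, 5, 50, 60, 70]],
                              index=pd.Index(["g"], name="gene_id"),
                              columns=self.samples)
        out = mask_low_counts(counts, self.info, 5.0)
        assert out.loc["g", ["a1", "a2", "a3"]].tolist() == [0, 0, 0]
        assert out.loc["g", ["b1", "b2", "b3"]].tolist() == [50, 60, 70]

    def test_mean_exactly_at_threshold_survives(self):
        counts = pd.DataFrame([[5, 5, 5, 1, 1, 1]],
                              index=pd.Index(["g"], name="gene_id"),
                              columns=self.samples)
        out = mask_low_counts(counts, self.info, 5.0)
        assert out.loc["g", ["a1", "a2", "a3"]].tolist() == [5, 5, 5]
        assert out.loc["g", ["b1", "b2", "b3"]].tolist() == [0, 0, 0]

    def test_idempotent_and_zero_gene_stays_zero(self):
        counts = pd.DataFrame([[0] * 6, [3, 4, 5, 9, 9, 9]],
                              index=pd.Index(["z", "g"], name="gene_id"),
                              columns=self.samples)
        once = mask_low_counts(counts, self.info, 5.0)
        twice = mask_low_counts(once, self.info, 5.0)
        pd.testing.assert_frame_equal(once, twice)
        assert (once.loc["z"] == 0).all()

    def test_unknown_sample_errors(self):
        counts = pd.DataFrame([[1]], index=["g"], columns=["nope"])
        with pytest.raises(ValueError):
            mask_low_counts(counts, self.info, 5.0)


class TestSizeFactors:
    def test_identical_samples_have_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 100, 7], "s2": [10, 100, 7]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_splits_sqrt2(self):
        counts = pd.DataFrame({"A": [10, 100, 7], "B": [20, 200, 14]})
        np.testing.assert_allclose(size_factors(counts),
                                   [1 / np.sqrt(2), np.sqrt(2)],
                                   rtol=1e-12)

    def test_gene_with_zero_excluded_from_reference(self):
        base = pd.DataFrame({"A": [10, 100], "B": [10, 100]})
        with_zero = pd.concat(
            [base, pd.DataFrame({"A": [0], "B": [10 ** 6]})],
            ignore_index=True)
        np.testing.assert_allclose(size_factors(with_zero),
                                   size_factors(base))

    def test_no_reference_gene_errors(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(counts)

    def test_matches_pydeseq2_oracle(self):
        """Independent median-of-ratios oracle: DESeq2's own estimator."""
        pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.05, (300, 8)),
            index=[f"g{i}" for i in range(300)],
            columns=[f"s{j}" for j in range(8)])
        meta = pd.DataFrame({"condition": ["x"] * 4 + ["y"] * 4},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.fit_size_factors()
        expected = np.asarray(dds.obs["size_factors"], dtype=float)
        np.testing.assert_allclose(size_factors(counts), expected,
                                   rtol=1e-8)

    def test_scaling_one_sample_only_rescales_globally(self):
        """Multiplying one sample's counts by c leaves the normalized
        matrix unchanged up to a single global factor (the ratio structure
        between genes and samples is invariant)."""
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, (200, 6)) + 1,
                              columns=[f"s{j}" for j in range(6)])
        scaled = counts.copy()
        scaled["s2"] = counts["s2"] * 4
        a = counts.div(size_factors(counts), axis=1).to_numpy()
        b = scaled.div(size_factors(scaled), axis=1).to_numpy()
        ratio = b / a
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-9)

    def test_recovers_planted_library_factors(self):
        """No differential expression: estimated factors correlate with
        the planted library sizes at r > 0.99."""
        lib = tuple(np.exp(np.random.default_rng(2).normal(0, 0.4, 30)))
        cfg = SimConfig(n_species=2, n_genes_per_species=2000, n_modules=0,
                        module_size=1, batch_log2_shift=(0, 0),
                        batch_scale=(1, 1), library_size_factors=lib,
                        seed=3)
        res = simulate(cfg)
        est, truth = [], []
        offset = 0
        for sp, counts in res.counts.items():
            f = size_factors(counts)
            est.extend(f / np.exp(np.log(f).mean()))
            block = np.array(lib[offset:offset + counts.shape[1]])
            truth.extend(block / np.exp(np.log(block).mean()))
            offset += counts.shape[1]
        r = np.corrcoef(est, truth)[0, 1]
        assert r > 0.99


class TestNormalizeLog2:
    def test_hand_values(self):
        counts = pd.DataFrame({"s": [0, 7, 8]})
        factors = pd.Series({"s": 1.0})
        out = normalize_log2(counts, factors)
        np.testing.assert_allclose(out["s"], [0.0, 3.0, np.log2(9)])
        out2 = normalize_log2(pd.DataFrame({"s": [8]}),
                              pd.Series({"s": 2.0}))
        np.testing.assert_allclose(out2["s"], [np.log2(5)])

    def test_nonpositive_factor_errors(self):
        with pytest.raises(ValueError):
            normalize_log2(pd.DataFrame({"s": [1]}), pd.Series({"s": 0.0}))


class TestFoldChanges:
    def setup_method(self):
        self.samples = ["m1", "m2", "a1", "a2"]
        self.info = _info(self.samples,
                          dict(m1="maltose", m2="maltose",
                               a1="avicel", a2="avicel"))

    def _calls(self, rows):
        counts = pd.DataFrame(rows, columns=self.samples,
                              index=pd.Index(
                                  [f"g{i}" for i in range(len(rows))],
                                  name="gene_id"))
        factors = pd.Series(1.0, index=self.samples)
        return fold_changes(counts, factors, self.info)

    def test_pseudocounted_ratio_and_direction(self):
        calls = self._calls([[10, 10, 80, 80],   # 81/11 -> up
                             [50, 50, 50, 50],   # 1 -> none
                             [0, 0, 100, 100]])  # 101 -> up
        by_gene = calls.set_index("gene_id")
        assert by_gene.loc["g0", "fold_change"] == pytest.approx(81 / 11)
        assert by_gene.loc["g0", "direction"] == "up"
        assert by_gene.loc["g1", "fold_change"] == pytest.approx(1.0)
        assert by_gene.loc["g1", "direction"] == "none"
        assert by_gene.loc["g2", "fold_change"] == pytest.approx(101.0)
        assert by_gene.loc["g2", "direction"] == "up"

    def test_down_direction(self):
        calls = self._calls([[99, 99, 24, 24]])
        assert calls.loc[0, "direction"] == "down"

    def test_missing_control_errors(self):
        info = _info(self.samples, dict(m1="avicel", m2="avicel",
                                        a1="avicel", a2="avicel"))
        counts = pd.DataFrame([[1, 1, 1, 1]], columns=self.samples,
                              index=pd.Index(["g"], name="gene_id"))
        with pytest.raises(ValueError):
            fold_changes(counts, pd.Series(1.0, index=self.samples), info)
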