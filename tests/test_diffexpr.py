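"""Median-of-ratios normalization, NB Wald test, BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from vasctx.diffexpr import (
    CountMatrix,
    NormalizationError,
    adjust_bh,
    estimate_size_factors,
)
from vasctx.diffexpr import test_two_group as run_two_group
from vasctx.simulate import PlantedSignal, SimConfig, simulate_counts


def cm_from_array(arr, conditions):
    arr = np.asarray(arr)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(
        pd.DataFrame(arr, index=genes, columns=samples),
        dict(zip(samples, conditions)),
    )


class TestSizeFactors:
    def test_identical_samples_all_one(self):
        cm = cm_from_array([[5, 5], [8, 8], [100, 100]], ["a", "b"])
        np.testing.assert_allclose(estimate_size_factors(cm), 1.0)

    def test_doubled_sample_scale_equivariance(self):
        base = np.array([[5, 10], [8, 16], [100, 200]])
        cm = cm_from_array(base, ["a", "b"])
        sf = estimate_size_factors(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_hand_computed_median_of_ratios(self):
        # genes x samples: [[4, 16], [9, 1], [25, 4]]
        # geomeans: 8, 3, 10; ratios col0: (0.5, 3, 2.5) -> median 2.5
        #                    ratios col1: (2, 1/3, 0.4)  -> median 0.4
        cm = cm_from_array([[4, 16], [9, 1], [25, 4]], ["a", "b"])
        sf = estimate_size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(), [2.5, 0.4])

    def test_zero_containing_genes_excluded(self):
        cm = cm_from_array([[0, 100], [10, 10]], ["a", "b"])
        np.testing.assert_allclose(estimate_size_factors(cm).to_numpy(), [1.0, 1.0])

    def test_no_usable_gene_raises(self):
        cm = cm_from_array([[0, 5], [5, 0]], ["a", "b"])
        with pytest.raises(NormalizationError):
            estimate_size_factors(cm)

    def test_agrees_with_reference_implementation(self):
        """Median-of-ratios factors match pydeseq2 on a random matrix."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(1)
        n_genes, n_samples = 60, 8
        counts = rng.poisson(50, (n_genes, n_samples))
        samples_by_genes = pd.DataFrame(
            counts.T,
            index=[f"s{j}" for j in range(n_samples)],
            columns=[f"g{i}" for i in range(n_genes)],
        )
        meta = pd.DataFrame(
            {"condition": ["a"] * 4 + ["b"] * 4}, index=samples_by_genes.index
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=samples_by_genes, metadata=meta, design="~condition",
                quiet=True,
            )
            dds.fit_size_factors()
        theirs = dds.obs["size_factors"].to_numpy()
        ours = estimate_size_factors(
            cm_from_array(counts, meta["condition"])
        ).to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)


class TestTwoGroup:
    @staticmethod
    def _null_cm(seed=0, n_genes=300):
        cfg = SimConfig(
            n_genes=n_genes,
            timepoints=("1h",),
            n_replicates=4,
            dispersion=0.05,
            n_sets=2,
            set_size_range=(2, 5),
            seed=seed,
        )
        return simulate_counts(cfg)[0]

    def test_identical_counts_give_zero_lfc(self):
        arr = np.tile([[10], [50], [200]], (1, 6))
        cm = cm_from_array(arr, ["ref"] * 3 + ["trt"] * 3)
        de = run_two_group(cm, None, "ref", "trt")
        np.testing.assert_allclose(de["log2_fold_change"], 0.0)

    def test_swapping_groups_negates_lfc_keeps_p(self):
        cm = self._null_cm()
        sf = estimate_size_factors(cm)
        fwd = run_two_group(cm, sf, "baseline", "1h")
        rev = run_two_group(cm, sf, "1h", "baseline")
        np.testing.assert_allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-12
        )
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-9)

    def test_sample_rescaling_scales_relative_factors_keeps_lfc(self):
        """Scaling one sample by c scales its size factor by c relative to
        the others (the geometric-mean reference itself shifts by c^(1/n),
        so only factor ratios are exactly equivariant) and leaves LFCs
        invariant up to the pseudocount."""
        cm = self._null_cm(seed=3)
        scaled_counts = cm.counts.copy()
        scaled_counts.iloc[:, 0] *= 5
        cm2 = CountMatrix(scaled_counts, dict(cm.sample_condition))
        sf1 = estimate_size_factors(cm)
        sf2 = estimate_size_factors(cm2)
        rel1 = sf1 / sf1.iloc[1]
        rel2 = sf2 / sf2.iloc[1]
        assert rel2.iloc[0] / rel1.iloc[0] == pytest.approx(5.0, rel=1e-9)
        np.testing.assert_allclose(rel2.iloc[1:], rel1.iloc[1:], rtol=1e-9)
        # with a negligible pseudocount the LFCs are exactly invariant
        de1 = run_two_group(cm, sf1, "baseline", "1h", pseudocount=1e-9)
        de2 = run_two_group(cm2, sf2, "baseline", "1h", pseudocount=1e-9)
        np.testing.assert_allclose(
            de1["log2_fold_change"], de2["log2_fold_change"], atol=1e-9
        )

    def test_all_zero_genes_flagged_not_dropped(self):
        arr = np.array([[10, 12, 9, 11], [0, 0, 0, 0], [50, 55, 48, 52]])
        cm = cm_from_array(arr, ["ref", "ref", "trt", "trt"])
        de = run_two_group(cm, None, "ref", "trt")
        assert list(de.index) == ["g0", "g1", "g2"]
        row = de.loc["g1"]
        assert row["status"] == "all_zero"
        assert row["p_value"] == 1.0
        assert row["log2_fold_change"] == 0.0

    def test_unknown_condition_rejected(self):
        cm = self._null_cm()
        with pytest.raises(ValueError, match="unknown"):
            run_two_group(cm, None, "baseline", "nope")

    def test_single_replicate_rejected(self):
        arr = np.array([[10, 11, 12]])
        cm = cm_from_array(arr, ["ref", "ref", "trt"])
        with pytest.raises(ValueError, match="replicates"):
            run_two_group(cm, None, "ref", "trt")

    def test_planted_signal_power(self):
        """~200 genes planted at delta=2 (6 vs 6, alpha=0.05): >=90% detected."""
        planted = tuple(
            PlantedSignal(f"HOT{i}", "persistent", 2.0) for i in range(3)
        )
        cfg = SimConfig(
            n_genes=2000,
            timepoints=("1h",),
            n_replicates=6,
            dispersion=0.05,
            planted=planted,
            n_sets=4,
            set_size_range=(60, 80),
            seed=11,
        )
        cm, catalog, truth = simulate_counts(cfg)
        de = run_two_group(cm, estimate_size_factors(cm), "baseline", "1h")
        hot = [g for i in range(3) for g in catalog[f"HOT{i}"].genes]
        assert len(hot) >= 180
        assert (de.loc[hot, "adj_p"] < 0.05).mean() >= 0.90


class TestAdjustBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_identical_ties(self):
        np.testing.assert_allclose(adjust_bh([0.02] * 5), [0.02] * 5)

    def test_hand_computed_values(self):
        out = adjust_bh([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04 * 4 / 3, 0.5], rtol=1e-12)

    def test_permutation_equivariance_and_dominance(self, rng):
        p = rng.uniform(0.001, 1.0, size=40)
        perm = rng.permutation(40)
        np.testing.assert_allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))
        assert (adjust_bh(p) >= p - 1e-15).all()
        assert (adjust_bh(p) <= 1.0).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_bh(bad)
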