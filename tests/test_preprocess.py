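"""Volume cropping/scaling, clinical pipeline, SNP QC and Lasso selection."""

import numpy as np
import pandas as pd
import pytest

from disfc.datatypes import CLINICAL_FEATURES, GenotypeMatrix, VolumeImage
from disfc.errors import DegenerateInputError, DimensionError, SchemaError
from disfc.preprocess import (
    QCThresholds,
    crop_reduction_fraction,
    crop_volume,
    hwe_exact_pvalue,
    impute_genotypes,
    knowledge_filter,
    lasso_select,
    normalize_volume,
    preprocess_clinical,
    qc_filter_snps,
    recompute_snp_stats,
)

rng = np.random.default_rng(1)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

class TestVolumeOps:
    def test_center_crop_is_contiguous_subgrid(self):
        v = VolumeImage(rng.random((20, 22, 24)).astype(np.float32))
        out = crop_volume(v, (10, 10, 10))
        assert out.shape == (10, 10, 10)
        np.testing.assert_array_equal(
            out.intensities, v.intensities[5:15, 6:16, 7:17])

    def test_crop_to_source_shape_is_identity(self):
        v = VolumeImage(rng.random((9, 9, 9)))
        np.testing.assert_array_equal(
            crop_volume(v, (9, 9, 9)).intensities, v.intensities)

    def test_crop_larger_than_source_rejected(self):
        with pytest.raises(DimensionError):
            crop_volume(VolumeImage(np.zeros((8, 8, 8))), (9, 8, 8))

    def test_reduction_fraction_cases(self):
        assert crop_reduction_fraction((256, 256, 256), (160, 176, 200)) \
            == pytest.approx(0.6643, abs=5e-5)
        assert crop_reduction_fraction((10, 10, 10), (10, 10, 10)) == 0.0
        assert crop_reduction_fraction((10, 10, 10), (5, 10, 10)) == 0.5
        with pytest.raises(DimensionError):
            crop_reduction_fraction((0, 10, 10), (5, 5, 5))

    def test_normalize_examples(self):
        v = VolumeImage(np.array([[[2.0, 4.0, 6.0]]]))
        np.testing.assert_allclose(
            normalize_volume(v).intensities, [[[0.0, 0.5, 1.0]]])
        unit = VolumeImage(rng.random((4, 4, 4)))
        unit.intensities[0, 0, 0] = 0.0
        unit.intensities[1, 1, 1] = 1.0
        np.testing.assert_allclose(
            normalize_volume(unit).intensities, unit.intensities, atol=1e-7)
        with pytest.raises(DegenerateInputError):
            normalize_volume(VolumeImage(np.full((4, 4, 4), 3.0)))


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------

def _clin_table(n=3):
    data = {c: rng.random(n) * 10 for c in CLINICAL_FEATURES}
    data["sex"] = ["F", "M", "F"][:n]
    return pd.DataFrame(data)


class TestClinicalPipeline:
    def test_impute_then_scale(self):
        df = _clin_table()
        df["MMSE"] = [10.0, np.nan, 20.0]
        x, stats = preprocess_clinical(df)
        j = CLINICAL_FEATURES.index("MMSE")
        np.testing.assert_allclose(x[:, j], [0.0, 0.5, 1.0])
        assert x.shape == (3, 14)
        assert np.all((x >= 0) & (x <= 1)) and not np.isnan(x).any()

    def test_missing_column_named_in_error(self):
        df = _clin_table().drop(columns=["MMSE"])
        with pytest.raises(SchemaError, match="MMSE"):
            preprocess_clinical(df)

    def test_all_missing_column_rejected(self):
        df = _clin_table()
        df["FAQ"] = np.nan
        with pytest.raises(SchemaError, match="FAQ"):
            preprocess_clinical(df)

    def test_heldout_values_clipped_with_train_stats(self):
        train = _clin_table()
        train["age"] = [10.0, 15.0, 20.0]
        _, stats = preprocess_clinical(train)
        held = _clin_table()
        held["age"] = [25.0, 5.0, 15.0]
        x, _ = preprocess_clinical(held, fit_stats=stats)
        j = CLINICAL_FEATURES.index("age")
        assert x[0, j] == 1.0 and x[1, j] == 0.0 and x[2, j] == 0.5

    def test_pipeline_idempotent_on_preprocessed_data(self):
        x, _ = preprocess_clinical(_clin_table())
        again, _ = preprocess_clinical(pd.DataFrame(x, columns=CLINICAL_FEATURES))
        np.testing.assert_allclose(again, x, atol=1e-12)

    def test_fit_stats_independent_of_heldout_rows(self):
        train = _clin_table()
        _, stats = preprocess_clinical(train)
        before = (stats.means.copy(), stats.mins.copy(), stats.maxs.copy())
        for _ in range(3):
            preprocess_clinical(_clin_table(), fit_stats=stats)
        for a, b in zip(before, (stats.means, stats.mins, stats.maxs)):
            np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

from _oracles import hwe_enumeration_oracle


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_pvalue(25, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 9) == 1.0

    def test_matches_enumeration_for_all_small_triples(self):
        for n in range(1, 51):
            for n_ab in range(n + 1):
                for n_aa in range(n - n_ab + 1):
                    n_bb = n - n_ab - n_aa
                    got = hwe_exact_pvalue(n_aa, n_ab, n_bb)
                    want = hwe_enumeration_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-12), \
                        (n_aa, n_ab, n_bb)

    def test_extreme_heterozygote_deficiency(self):
        assert hwe_exact_pvalue(50, 0, 50) < 1e-10

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 2, 3)


# ---------------------------------------------------------------------------
# QC filter / imputation / knowledge filter
# ---------------------------------------------------------------------------

def _toy_gm(counts, ids=None):
    counts = np.asarray(counts, dtype=float)
    m = counts.shape[1]
    ids = ids or [f"rs{j}" for j in range(m)]
    meta = pd.DataFrame({"id": ids, "chrom": "1", "pos": np.arange(m) + 1})
    return GenotypeMatrix(counts, meta, [f"s{i}" for i in range(counts.shape[0])])


class TestQCAndImputation:
    def test_decoys_removed_clean_kept(self, tiny_cohort):
        gm = tiny_cohort.genotypes
        filtered, report = qc_filter_snps(gm)
        kept = set(filtered.snp_meta["id"])
        tags = gm.snp_meta.set_index("id")["tag"]
        for snp_id, tag in tags.items():
            if tag in ("low_maf", "low_callrate", "hwe_violating"):
                assert snp_id not in kept, f"decoy {tag} survived QC"
            else:
                assert snp_id in kept, "clean SNP lost to QC"
        assert report["n_kept"] + 3 * 4 == report["n_input"]

    def test_zero_thresholds_keep_everything(self, tiny_cohort):
        thr = QCThresholds(0.0, 0.0, 0.0)
        filtered, _ = qc_filter_snps(tiny_cohort.genotypes, thr)
        assert filtered.n_snps == tiny_cohort.genotypes.n_snps

    def test_recomputed_stats_consistent(self):
        gm = _toy_gm([[0, 1], [1, 1], [2, np.nan], [0, 0]])
        gm = recompute_snp_stats(gm)
        assert gm.snp_meta["call_rate"].iloc[1] == pytest.approx(0.75)
        assert gm.snp_meta["maf"].iloc[0] == pytest.approx(3 / 8)
        assert gm.snp_meta["maf"].iloc[1] == pytest.approx(2 / 6)

    def test_impute_mode_and_tie_break(self):
        gm = _toy_gm([[0, 0], [0, 2], [np.nan, np.nan], [2, 2]])
        out = impute_genotypes(gm)
        assert out.counts[2, 0] == 0.0  # mode of {0, 0, 2}
        assert out.counts[2, 1] == 2.0  # mode of {0, 2, 2}
        tie = impute_genotypes(_toy_gm([[0.0], [2.0], [np.nan]]))
        assert tie.counts[2, 0] == 0.0  # 0 vs 2 tie -> lower allele count

    def test_impute_without_missing_is_identity(self):
        gm = _toy_gm([[0, 1], [2, 1]])
        np.testing.assert_array_equal(impute_genotypes(gm).counts, gm.counts)

    def test_all_missing_snp_rejected(self):
        gm = _toy_gm([[np.nan, 1], [np.nan, 0]])
        with pytest.raises(DegenerateInputError):
            impute_genotypes(gm)

    def test_knowledge_filter_behaviour(self):
        gm = _toy_gm(np.zeros((3, 4)), ids=["a", "b", "c", "d"])
        full = knowledge_filter(gm, ["a", "b", "c", "d"])
        assert list(full.snp_meta["id"]) == ["a", "b", "c", "d"]
        single = knowledge_filter(gm, ["c"])
        assert single.n_snps == 1 and single.snp_meta["id"].iloc[0] == "c"
        with pytest.warns(UserWarning):
            out = knowledge_filter(gm, ["b", "zzz"])
        assert list(out.snp_meta["id"]) == ["b"]
        with pytest.raises(SchemaError):
            knowledge_filter(gm, ["x", "y"])


# ---------------------------------------------------------------------------
# Lasso-to-k selection
# ---------------------------------------------------------------------------

class TestLassoSelect:
    def test_perfect_predictor_selected_at_k1(self):
        n = 60
        y = np.tile([0, 1], n // 2)
        X = rng.normal(size=(n, 8))
        X[:, 5] = y * 2.0 - 1.0
        assert list(lasso_select(X, y, k=1)) == [5]

    def test_k_equal_m_returns_all(self):
        X = rng.normal(size=(30, 6))
        y = np.tile([0, 1], 15)
        np.testing.assert_array_equal(lasso_select(X, y, k=6), np.arange(6))

    def test_requested_size_achieved(self):
        n = 80
        y = np.tile([0, 1], n // 2)
        X = rng.normal(size=(n, 25)) + 0.3 * y[:, None] * rng.normal(size=25)
        sel = lasso_select(X, y, k=7)
        assert len(sel) == 7
        np.testing.assert_array_equal(sel, lasso_select(X, y, k=7))  # deterministic

    def test_null_selection_roughly_uniform(self):
        """With y independent of X, no column should dominate selection."""
        m, k = 15, 4
        hits = np.zeros(m)
        for seed in range(30):
            r = np.random.default_rng(seed)
            X = r.normal(size=(50, m))
            y = r.integers(0, 2, 50)
            if y.sum() in (0, 50):
                continue
            sel = lasso_select(X, y, k=k)
            assert len(sel) <= k
            hits[sel] += 1
        assert (hits > 0).sum() >= m - 3
        assert hits.max() <= 0.5 * hits.sum()

    def test_invalid_k_rejected(self):
        X = rng.normal(size=(20, 4))
        y = np.tile([0, 1], 10)
        with pytest.raises(ValueError):
            lasso_select(X, y, k=0)
        with pytest.raises(ValueError):
            lasso_select(X, y, k=5)
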