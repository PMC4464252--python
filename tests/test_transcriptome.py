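"""Normalization, differential expression, profile clustering and term
enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact
from sklearn.metrics import adjusted_rand_score

from rddmkit import transcriptome as tr
from rddmkit.transcriptome import (
    ClusterResult,
    ExpressionMatrix,
    cluster_enrichment,
    cluster_profiles,
    condition_cpm,
    de_union,
    differential_expression,
    expression_profiles,
    most_significant_term,
    normalize,
)


def matrix_from(counts: dict, conditions: dict) -> ExpressionMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    df.index.name = "gene_id"
    meta = pd.DataFrame(
        {"condition": [conditions[s] for s in df.columns],
         "replicate": list(range(1, len(df.columns) + 1))},
        index=df.columns,
    )
    return ExpressionMatrix(df, meta)


class TestNormalize:
    def test_cpm_arithmetic(self):
        mat = matrix_from({"s1": [50, 999950]}, {"s1": "normal"})
        cpm = normalize(mat)
        assert cpm.loc["g0", "s1"] == pytest.approx(50.0)

    def test_scale_invariance(self):
        a = matrix_from({"s1": [10, 90]}, {"s1": "normal"})
        b = matrix_from({"s1": [20, 180]}, {"s1": "normal"})
        pd.testing.assert_frame_equal(normalize(a), normalize(b))

    def test_all_zero_gene_stays_zero_and_empty_library_raises(self):
        mat = matrix_from({"s1": [0, 10], "s2": [0, 20]}, {"s1": "normal", "s2": "R1"})
        assert (normalize(mat).loc["g0"] == 0).all()
        empty = matrix_from({"s1": [0, 0]}, {"s1": "normal"})
        with pytest.raises(ValueError, match="library"):
            normalize(empty)


class TestDifferentialExpression:
    def test_unreplicated_exact_test_matches_fisher_oracle(self):
        """Pooled counts 100 vs 400 in libraries of 1e6: the conditioned
        exact test equals Fisher on the 2x2 split of the libraries."""
        mat = matrix_from(
            {"R2_1": [100, 999900], "FR2_1": [400, 999600]},
            {"R2_1": "R2", "FR2_1": "FR2"},
        )
        res = differential_expression(mat, "R2", "FR2")
        _, want = fisher_exact([[100, 999900], [400, 999600]])
        assert res.loc["g0", "p"] == pytest.approx(want, rel=1e-6)
        assert res.loc["g0", "log2fc"] == pytest.approx(-2.0, abs=0.01)
        assert bool(res.loc["g0", "de"])

    def test_fold_change_rule(self):
        # 1.5-fold with overwhelming p is still not DE
        mat = matrix_from(
            {"R2_1": [200_000, 800_000], "FR2_1": [300_000, 700_000]},
            {"R2_1": "R2", "FR2_1": "FR2"},
        )
        res = differential_expression(mat, "R2", "FR2")
        assert res.loc["g0", "p"] < 1e-20
        assert not bool(res.loc["g0", "de"])

    def test_p_value_rule(self):
        # 4-fold from tiny counts: fold passes, p does not
        mat = matrix_from(
            {"R2_1": [2, 999_998], "FR2_1": [8, 999_992]},
            {"R2_1": "R2", "FR2_1": "FR2"},
        )
        res = differential_expression(mat, "R2", "FR2")
        assert abs(res.loc["g0", "log2fc"]) >= 1
        assert res.loc["g0", "p"] > 0.001
        assert not bool(res.loc["g0", "de"])

    def test_reciprocal_fold_changes_identical_p(self, small_dataset):
        mat = small_dataset.expression
        ab = differential_expression(mat, "R2", "FR2", dispersion=0.1)
        ba = differential_expression(mat, "FR2", "R2", dispersion=0.1)
        assert np.allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
        assert np.allclose(ab["p"], ba["p"], atol=1e-12)

    def test_monotone_in_thresholds(self, small_dataset):
        mat = small_dataset.expression
        strict = de_union(mat, min_fc=4.0, p_thresh=1e-5, dispersion=0.1)
        loose = de_union(mat, min_fc=2.0, p_thresh=1e-3, dispersion=0.1)
        assert set(strict.index[strict["de"]]) <= set(loose.index[loose["de"]])

    def test_dispersion_estimate_recovers_generating_value(self, small_dataset):
        phi = tr.estimate_common_dispersion(small_dataset.expression)
        assert 0.05 <= phi <= 0.2  # generator uses 0.1

    def test_union_detects_planted_red_up_genes(self, small_dataset):
        de = de_union(small_dataset.expression)
        planted = small_dataset.truth.planted_genes
        calls = de.loc[planted]
        assert calls["de"].mean() >= 0.8
        assert (calls.loc[calls["de"], "log2fc"] > 0).all()


class TestProfiles:
    def test_flat_gene_has_zero_profile_and_rows_are_centered(self, small_dataset):
        prof = expression_profiles(small_dataset.expression)
        assert list(prof.columns) == list(tr.CONDITION_ORDER)
        assert np.allclose(prof.mean(axis=1), 0.0, atol=1e-12)

    def test_constant_abundance_gives_all_zero(self):
        counts = {f"{c}_1": [100, 900] for c in tr.CONDITION_ORDER}
        mat = matrix_from(counts, {f"{c}_1": c for c in tr.CONDITION_ORDER})
        prof = expression_profiles(mat)
        assert np.allclose(prof.loc["g0"], 0.0, atol=1e-12)

    def test_antisymmetric_regulation_gives_antisymmetric_profile(self):
        # 2x up under all R, 2x down under all FR, flat filler gene
        vals = {"FR5": 50, "FR2": 50, "FR1": 50, "normal": 100, "R1": 200, "R2": 200, "R5": 200}
        counts = {f"{c}_1": [vals[c], 100_000] for c in tr.CONDITION_ORDER}
        mat = matrix_from(counts, {f"{c}_1": c for c in tr.CONDITION_ORDER})
        prof = expression_profiles(mat, pseudocount=0).loc["g0"].to_numpy()
        assert np.allclose(prof + prof[::-1], 0.0, atol=0.02)
        assert prof[0] < 0 < prof[-1]

    def test_unknown_gene_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            expression_profiles(small_dataset.expression, ["no-such-gene"])


class TestClustering:
    @staticmethod
    def _two_groups(n=40, seed=0):
        rng = np.random.default_rng(seed)
        up = np.array([-2, -1.5, -1, 0, 1, 1.5, 2])
        prof = np.vstack(
            [up + rng.normal(0, 0.1, 7) for _ in range(n)]
            + [-up + rng.normal(0, 0.1, 7) for _ in range(n)]
        )
        idx = [f"g{i}" for i in range(2 * n)]
        return pd.DataFrame(prof, index=idx, columns=tr.CONDITION_ORDER)

    def test_separated_groups_partition_perfectly(self):
        prof = self._two_groups()
        res = cluster_profiles(prof, k=2, seed=0)
        labels = res.labels.to_numpy()
        assert len(set(labels[:40])) == 1
        assert len(set(labels[40:])) == 1
        assert set(labels) == {1, 2}

    def test_deterministic_and_order_invariant(self):
        prof = self._two_groups()
        a = cluster_profiles(prof, k=2, seed=7)
        b = cluster_profiles(prof.sample(frac=1.0, random_state=3), k=2, seed=7)
        assert (a.labels.sort_index() == b.labels.sort_index()).all()
        assert a.inertia == pytest.approx(b.inertia)

    def test_labels_ranked_by_cluster_size(self):
        prof = self._two_groups()
        lopsided = pd.concat([prof.iloc[:40], prof.iloc[40:50]])
        res = cluster_profiles(lopsided, k=2, seed=0)
        sizes = res.labels.value_counts()
        assert sizes.loc[1] >= sizes.loc[2]

    def test_planted_archetypes_recovered(self):
        """Sixteen well-separated archetype patterns with coordinate noise
        at one fifth of their minimum separation are recovered almost
        perfectly (adjusted Rand >= 0.9)."""
        rng = np.random.default_rng(12)
        arch = rng.normal(0, 1, size=(16, 7))
        arch -= arch.mean(axis=1, keepdims=True)
        dists = [
            np.linalg.norm(arch[i] - arch[j])
            for i in range(16) for j in range(i + 1, 16)
        ]
        sigma = min(dists) / 5
        profs, truth = [], []
        for a in range(16):
            for _ in range(25):
                profs.append(arch[a] + rng.normal(0, sigma, 7))
                truth.append(a)
        prof = pd.DataFrame(profs, index=[f"g{i}" for i in range(len(profs))])
        res = cluster_profiles(prof, k=16, seed=0)
        assert adjusted_rand_score(truth, res.labels.to_numpy()) >= 0.9

    def test_too_few_profiles_suggests_smaller_k(self):
        prof = self._two_groups(n=3)
        with pytest.raises(ValueError, match="smaller k"):
            cluster_profiles(prof, k=16)


class TestEnrichment:
    def test_fully_contained_cluster_probability(self):
        universe = [f"g{i}" for i in range(20)]
        terms = {g: {"termA"} for g in universe[:5]}
        report = cluster_enrichment(universe[:4], terms, universe)
        assert report.iloc[0]["p"] == pytest.approx(5 / 4845, abs=1e-12)
        assert most_significant_term(report) == "termA"

    def test_universal_term_is_not_significant(self):
        universe = [f"g{i}" for i in range(10)]
        terms = {g: {"everything"} for g in universe}
        report = cluster_enrichment(universe[:3], terms, universe)
        assert report.iloc[0]["p"] == pytest.approx(1.0)

    def test_unannotated_cluster_reports_nothing(self):
        universe = [f"g{i}" for i in range(10)]
        terms = {"g9": {"termA"}}
        assert cluster_enrichment(universe[:3], terms, universe).empty
        assert cluster_enrichment([], terms, universe).empty

    def test_ties_resolve_lexicographically(self):
        universe = [f"g{i}" for i in range(12)]
        terms = {g: {"zeta", "alpha"} for g in universe[:4]}
        report = cluster_enrichment(universe[:3], terms, universe)
        assert report.iloc[0]["p"] == report.iloc[1]["p"]
        assert most_significant_term(report) == "alpha"

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            cluster_enrichment(["gX"], {}, ["g0"])


def test_condition_cpm_averages_replicates(small_dataset):
    mat = small_dataset.expression
    cpm = normalize(mat)
    cols = mat.condition_samples("normal")
    pd.testing.assert_series_equal(
        condition_cpm(mat, "normal"), cpm[cols].mean(axis=1), check_names=False
    )
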