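"""Quadrant rule, core-cluster selection and the pan-cancer loop."""

import numpy as np
import pandas as pd
import pytest

from glycochol import ClusterConfig, ExpressionMatrix, GeneSetCollection
from glycochol.subtyping import (
    GeneCluster,
    MetabolicScore,
    assign_subtype,
    assign_subtypes,
    compute_metabolic_scores,
    make_gene_clusters,
    run_pan_cancer,
    select_core_clusters,
    subtype_table,
)

from .conftest import standardized_matrix


def cluster(cid, n_gly, n_chol, n_other=0):
    members = (
        [f"GLY{cid}_{i}" for i in range(n_gly)]
        + [f"CHOL{cid}_{i}" for i in range(n_chol)]
        + [f"X{cid}_{i}" for i in range(n_other)]
    )
    annotated = n_gly + n_chol
    return GeneCluster(
        cluster_id=cid,
        member_genes=members,
        frac_glycolytic=n_gly / annotated if annotated else 0.0,
        frac_cholesterogenic=n_chol / annotated if annotated else 0.0,
    )


class TestQuadrantRule:
    @pytest.mark.parametrize(
        "gly,chol,expected",
        [
            (0.0, 0.0, "quiescent"),
            (0.5, -0.2, "glycolytic"),
            (-0.1, 0.3, "cholesterogenic"),
            (0.1, 0.2, "mixed"),
            (0.0, 0.3, "cholesterogenic"),  # boundary: gly exactly 0 is low
            (0.3, 0.0, "glycolytic"),  # boundary: chol exactly 0 is low
            (-1e-12, -1e-12, "quiescent"),
        ],
    )
    def test_boundaries(self, gly, chol, expected):
        assert assign_subtype(MetabolicScore("s", gly, chol)) == expected

    def test_partition_property(self, rng):
        scores = [
            MetabolicScore(f"S{i}", float(g), float(c))
            for i, (g, c) in enumerate(rng.normal(size=(200, 2)))
        ]
        labels = assign_subtypes(scores)
        assert len(labels) == 200
        assert labels.value_counts().sum() == 200

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            MetabolicScore("s", float("nan"), 0.0)


class TestCoreSelection:
    def test_pure_chol_cluster_is_core(self):
        gly_c = cluster(1, 4, 6)  # 0.40 > 0.30
        chol_c = cluster(2, 0, 10)  # 1.00 > 0.90
        core_gly, core_chol = select_core_clusters([gly_c, chol_c])
        assert core_gly.cluster_id == 1
        assert core_chol.cluster_id == 2

    def test_gly_fraction_boundary_is_strict(self):
        at_bound = cluster(1, 3, 7)  # exactly 0.30: excluded
        above = cluster(2, 31, 69)  # 0.31: included
        chol_c = cluster(3, 0, 10)
        core_gly, _ = select_core_clusters([at_bound, above, chol_c])
        assert core_gly.cluster_id == 2
        with pytest.raises(ValueError, match="glycolytic"):
            select_core_clusters([at_bound, chol_c])

    def test_most_homogeneous_chol_candidate_wins(self):
        c95 = cluster(1, 1, 19)  # 0.95
        c100 = cluster(2, 0, 10)  # 1.00
        gly_c = cluster(3, 5, 5)
        _, core_chol = select_core_clusters([c95, c100, gly_c])
        assert core_chol.cluster_id == 2

    def test_tie_broken_by_size_then_id(self):
        small = cluster(1, 0, 8)
        large = cluster(2, 0, 20)
        gly_c = cluster(3, 5, 0)
        _, core_chol = select_core_clusters([small, large, gly_c])
        assert core_chol.cluster_id == 2
        twin = cluster(0, 0, 8)
        _, core_chol = select_core_clusters([small, twin, gly_c])
        assert core_chol.cluster_id == 0  # equal size: lowest id

    def test_missing_category_names_it(self):
        with pytest.raises(ValueError, match="cholesterogenic"):
            select_core_clusters([cluster(1, 5, 5)])

    def test_make_gene_clusters_fractions_over_annotated_only(self):
        genes = ["g1", "g2", "c1", "other"]
        labels = [0, 0, 0, 0]
        [gc] = make_gene_clusters(genes, labels, ["g1", "g2"], ["c1"])
        assert gc.frac_glycolytic == pytest.approx(2 / 3)
        assert gc.frac_cholesterogenic == pytest.approx(1 / 3)
        assert gc.homogeneity == pytest.approx(2 / 3)


class TestScores:
    def test_median_conventions(self):
        vals = np.array(
            [
                [1.0, 1.0],   # gly gene
                [2.0, 3.0],   # gly gene
                [-1.0, 1.0],  # gly gene
                [1.0, 0.0],   # chol gene
                [3.0, 0.0],   # chol gene
            ]
        )
        m = standardized_matrix(vals, genes=["g1", "g2", "g3", "c1", "c2"])
        scores = compute_metabolic_scores(m, ["g1", "g2", "g3"], ["c1", "c2"])
        assert scores[0].gly_score == 1.0  # odd count: middle value
        assert scores[0].chol_score == 2.0  # even count: mean of middle two
        assert scores[1].chol_score == 0.0  # all-zero rows give 0

    def test_gene_and_sample_order_invariance(self, rng):
        vals = rng.normal(size=(6, 5))
        genes = [f"g{i}" for i in range(4)] + ["c0", "c1"]
        m = standardized_matrix(vals, genes=genes)
        scores = compute_metabolic_scores(m, genes[:4], genes[4:])
        perm_g = rng.permutation(6)
        perm_s = rng.permutation(5)
        m2 = ExpressionMatrix(
            m.values.iloc[perm_g, perm_s], scale_tag="standardized"
        )
        scores2 = compute_metabolic_scores(m2, genes[:4], genes[4:])
        by_id = {s.sample_id: s for s in scores2}
        for s in scores:
            assert by_id[s.sample_id].gly_score == pytest.approx(s.gly_score)
            assert by_id[s.sample_id].chol_score == pytest.approx(s.chol_score)

    def test_too_few_core_genes_present_rejected(self):
        m = standardized_matrix(np.zeros((2, 3)), genes=["g1", "c1"])
        with pytest.raises(ValueError, match="glycolytic"):
            compute_metabolic_scores(m, ["g1", "g2", "g3"], ["c1"])

    def test_table_layout(self):
        scores = [MetabolicScore("a", 1.0, -1.0), MetabolicScore("b", -1.0, 1.0)]
        table = subtype_table(scores)
        assert list(table["subtype"]) == ["glycolytic", "cholesterogenic"]


def _planted_dataset(rng, n_samples, gly_members, chol_members, mix_into_gly=0):
    """Two co-expressed blocks; optionally contaminate the gly block."""
    gly = [f"G{i}" for i in range(gly_members)]
    chol = [f"C{i}" for i in range(chol_members)]
    contam = [f"C{chol_members + i}" for i in range(mix_into_gly)]
    genes = gly + contam + chol
    n_a = gly_members + mix_into_gly
    block_a = rng.normal(size=n_samples) * 2.0
    block_b = rng.normal(size=n_samples) * 2.0
    vals = np.vstack(
        [
            block_a + 0.2 * rng.normal(size=(n_a, n_samples)),
            block_b + 0.2 * rng.normal(size=(chol_members, n_samples)),
        ]
    )
    vals = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
    matrix = standardized_matrix(vals, genes=genes,
                                 samples=[f"S{j}" for j in range(n_samples)])
    sets = GeneSetCollection(
        sets={"GLY": gly, "CHOL": chol + contam},
        categories={"GLY": "glycolytic", "CHOL": "cholesterogenic"},
    )
    return matrix, sets


class TestPanCancer:
    def test_homogeneity_boundary_inclusive(self, rng):
        cfg = ClusterConfig(k=2, reps=10, seed=0)
        datasets = {
            # gly core 3/4 = 0.75 homogeneity: retained (inclusive bound)
            "at_bound": _planted_dataset(rng, 120, 3, 10, mix_into_gly=1),
            # gly core 14/19 ~ 0.737 homogeneity: omitted
            "below": _planted_dataset(rng, 120, 14, 10, mix_into_gly=5),
        }
        res = run_pan_cancer(datasets, cfg, min_samples=100)
        assert "at_bound" in res.subtype_tables
        omitted = dict(res.omissions)
        assert "below" in omitted
        assert "0.737" in omitted["below"] or "homogeneity" in omitted["below"]

    def test_small_dataset_omitted_by_floor(self, rng):
        cfg = ClusterConfig(k=2, reps=5, seed=0)
        res = run_pan_cancer(
            {"tiny": _planted_dataset(rng, 40, 5, 10)}, cfg, min_samples=100
        )
        assert res.subtype_tables == {}
        assert "screening floor" in res.omissions[0][1]

    def test_missing_core_reported_not_raised(self, rng):
        # no cholesterogenic genes at all -> no chol core, dataset omitted
        gly = [f"G{i}" for i in range(10)]
        vals = rng.normal(size=(10, 120))
        matrix = standardized_matrix(vals, genes=gly,
                                     samples=[f"S{j}" for j in range(120)])
        sets = GeneSetCollection(sets={"GLY": gly}, categories={"GLY": "glycolytic"})
        res = run_pan_cancer({"d": (matrix, sets)}, ClusterConfig(k=2, reps=5, seed=1),
                             min_samples=100)
        assert res.subtype_tables == {}
        assert "cholesterogenic" in res.omissions[0][1]

    def test_retained_dataset_recovers_block_structure(self, rng):
        cfg = ClusterConfig(k=2, reps=10, seed=2)
        matrix, sets = _planted_dataset(rng, 150, 8, 12)
        res = run_pan_cancer({"ok": (matrix, sets)}, cfg, min_samples=100)
        info = res.core_info["ok"]
        assert set(info["core_gly_genes"]) == {f"G{i}" for i in range(8)}
        assert info["core_chol_homogeneity"] == 1.0
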