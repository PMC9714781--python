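"""Normalization, DE, pooling, K-means, GSEA, phenotype and gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import clonetracer as ct
from clonetracer.expression import (
    CountMatrix,
    DEResult,
    de_test,
    enrichment_score,
    gate_clones_by_markers,
    gsea_collection,
    gsea_preranked,
    kmeans_cluster,
    marker_phenotype,
    rank_genes_for_gsea,
    select_top_de,
    size_factor_normalize,
)


def nb_matrix(n_genes=200, n_cells=40, seed=0, groups=("A", "B")):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(20), 1.0, n_genes)
    lib = rng.lognormal(0, 0.3, n_cells)
    mu = base[:, None] * lib[None, :]
    r = 1 / 0.3
    counts = rng.negative_binomial(r, r / (r + mu))
    cells = [f"c{i}" for i in range(n_cells)]
    half = n_cells // 2
    return CountMatrix.from_arrays(
        counts, [f"g{i}" for i in range(n_genes)], cells,
        {c: (groups[0] if i < half else groups[1]) for i, c in enumerate(cells)},
    )


def median_of_ratios_oracle(counts: np.ndarray) -> np.ndarray:
    """Direct re-implementation of the size-factor formula."""
    ref = counts[(counts > 0).all(axis=1)]
    geomean = np.exp(np.log(ref).mean(axis=1))
    return np.median(ref / geomean[:, None], axis=0)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up, written out longhand."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestSizeFactors:
    def test_doubled_sample_doubles_factor(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(50, size=100) + 1
        m = CountMatrix.from_arrays(np.column_stack([a, 2 * a]),
                                    [f"g{i}" for i in range(100)], ["s1", "s2"])
        sf = size_factor_normalize(m).size_factors
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_equal_samples_give_unit_factors(self):
        a = np.arange(1, 51)
        m = CountMatrix.from_arrays(np.column_stack([a, a, a]),
                                    [f"g{i}" for i in range(50)], ["s1", "s2", "s3"])
        assert np.allclose(size_factor_normalize(m).size_factors, 1.0)

    def test_matches_direct_oracle_on_random_matrix(self):
        m = nb_matrix(seed=7)
        sf = size_factor_normalize(m).size_factors.to_numpy()
        assert np.allclose(sf, median_of_ratios_oracle(m.counts.to_numpy().astype(float)))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(c=st.integers(min_value=2, max_value=8), seed=st.integers(0, 100))
    def test_scaling_one_sample_scales_its_factor_ratio(self, c, seed):
        # multiplying sample 0's counts by c multiplies sf_0 relative to
        # every other sample by exactly c (the geometric means rescale all
        # factors by the same c^(1/n))
        m = nb_matrix(n_genes=80, n_cells=6, seed=seed)
        counts2 = m.counts.copy()
        counts2.iloc[:, 0] = m.counts.iloc[:, 0] * c
        m2 = CountMatrix(counts2, m.groups)
        sf1 = size_factor_normalize(m).size_factors
        sf2 = size_factor_normalize(m2).size_factors
        assert sf2.iloc[0] / sf2.iloc[1] == pytest.approx(c * sf1.iloc[0] / sf1.iloc[1])

    def test_sparse_fallback_path(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(30, size=(100, 20))
        # every gene gets at least one zero, <=10% of cells, triggering fallback
        for g in range(100):
            counts[g, rng.integers(20)] = 0
        m = CountMatrix.from_arrays(counts, [f"g{i}" for i in range(100)],
                                    [f"c{i}" for i in range(20)])
        sf = size_factor_normalize(m).size_factors
        assert (sf > 0).all()

    def test_fallback_disabled_raises(self):
        counts = np.zeros((5, 4), dtype=int)
        counts[0, 0] = 10
        m = CountMatrix.from_arrays(counts, list("abcde"), list("wxyz"))
        with pytest.raises(ValueError):
            size_factor_normalize(m, fallback=False)


class TestDifferentialExpression:
    def test_adjusted_p_matches_bh_oracle_and_dominates_raw(self):
        m = size_factor_normalize(nb_matrix(seed=11))
        de = de_test(m, ("A", "B"))
        assert np.allclose(de.table.padj, bh_oracle(de.table.pvalue.to_numpy()))
        assert (de.table.padj >= de.table.pvalue - 1e-12).all()

    def test_planted_shift_is_most_significant(self):
        rng = np.random.default_rng(5)
        m = nb_matrix(n_genes=300, n_cells=200, seed=5)
        counts = m.counts.copy()
        b_cells = m.cells_in("B")
        counts.loc["g0", b_cells] = rng.negative_binomial(
            1 / 0.3, (1 / 0.3) / (1 / 0.3 + 20 * 32), size=len(b_cells)
        )
        m = size_factor_normalize(CountMatrix(counts, m.groups))
        de = de_test(m, ("A", "B"))
        assert de.table.padj.idxmin() == "g0"
        assert de.table.loc["g0", "log2fc"] < -3

    def test_copied_groups_yield_no_discoveries(self):
        rng = np.random.default_rng(9)
        half = rng.negative_binomial(3, 0.1, size=(150, 20))
        counts = np.hstack([half, half])
        cells = [f"c{i}" for i in range(40)]
        m = CountMatrix.from_arrays(counts, [f"g{i}" for i in range(150)], cells,
                                    {c: ("A" if i < 20 else "B") for i, c in enumerate(cells)})
        de = de_test(size_factor_normalize(m), ("A", "B"))
        assert (de.table.padj >= 0.05).all()

    def test_all_zero_genes_excluded(self):
        m = nb_matrix(seed=13)
        counts = m.counts.copy()
        counts.loc["g0"] = 0
        de = de_test(size_factor_normalize(CountMatrix(counts, m.groups)), ("A", "B"))
        assert "g0" not in de.table.index

    def test_small_groups_rejected(self):
        m = size_factor_normalize(nb_matrix(n_cells=4, seed=1))
        with pytest.raises(ValueError, match="cells"):
            de_test(m, ("A", "B"))


def fake_de(genes_up, genes_down, contrast=("x", "ctrl"), p=1e-6):
    rows = []
    for i, g in enumerate(genes_up):
        rows.append((g, 1.0, p * (i + 1), p * (i + 1)))
    for i, g in enumerate(genes_down):
        rows.append((g, -1.0, p * (i + 1), p * (i + 1)))
    table = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "padj"]).set_index("gene")
    table.insert(0, "base_mean", 10.0)
    return DEResult(table=table, contrast=contrast)


class TestTopDePooling:
    def test_disjoint_contrasts_pool_to_6k(self):
        k = 5
        results = [
            fake_de([f"u{c}{i}" for i in range(k)], [f"d{c}{i}" for i in range(k)])
            for c in range(3)
        ]
        assert len(select_top_de(results, k=k)) == 6 * k

    def test_identical_contrasts_collapse_to_2k(self):
        k = 5
        res = fake_de([f"u{i}" for i in range(k)], [f"d{i}" for i in range(k)])
        assert len(select_top_de([res, res, res], k=k)) == 2 * k

    def test_known_overlap_union_cardinality(self):
        # three diseases share a core program: exact set arithmetic
        a = fake_de(["u1", "u2", "u3"], ["d1", "d2"])
        b = fake_de(["u2", "u3", "u4"], ["d2", "d3"])
        c = fake_de(["u5"], ["d1"])
        expected = {"u1", "u2", "u3", "d1", "d2", "u4", "d3", "u5"}
        assert set(select_top_de([a, b, c], k=3)) == expected

    def test_p_cut_filters_weak_genes(self):
        res = fake_de(["strong"], [], p=1e-6)
        res.table.loc["weak"] = [10.0, 1.0, 0.5, 0.5]
        assert select_top_de([res], k=5, p_cut=0.01) == ["strong"]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_top_de([])


class TestKMeans:
    def _separated(self, seed=0):
        # opposing expression programs (not a library-size shift, which
        # normalization would erase): genes 0-14 high in group 1, 15-29 in group 2
        rng = np.random.default_rng(seed)
        a = np.vstack([rng.poisson(80, size=(15, 25)), rng.poisson(5, size=(15, 25))])
        b = np.vstack([rng.poisson(5, size=(15, 25)), rng.poisson(80, size=(15, 25))])
        counts = np.hstack([a, b])
        cells = [f"c{i}" for i in range(50)]
        return CountMatrix.from_arrays(counts, [f"g{i}" for i in range(30)], cells), [0] * 25 + [1] * 25

    def test_separated_groups_recovered(self):
        m, truth = self._separated()
        res = kmeans_cluster(size_factor_normalize(m), [f"g{i}" for i in range(30)], k=2, seed=1)
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0

    def test_k1_sse_equals_total_variance(self):
        m, _ = self._separated(seed=2)
        m = size_factor_normalize(m)
        genes = [f"g{i}" for i in range(30)]
        res = kmeans_cluster(m, genes, k=1, seed=0)
        x = m.normalized(log2=True).loc[genes].to_numpy().T
        sd = x.std(axis=0)
        sd[sd == 0] = 1
        x = (x - x.mean(axis=0)) / sd
        assert res.sse == pytest.approx(((x - x.mean(axis=0)) ** 2).sum())

    def test_same_seed_reproducible(self):
        m, _ = self._separated(seed=3)
        m = size_factor_normalize(m)
        genes = [f"g{i}" for i in range(30)]
        a = kmeans_cluster(m, genes, k=3, seed=7)
        b = kmeans_cluster(m, genes, k=3, seed=7)
        assert a.assignments.equals(b.assignments)

    def test_k_exceeding_cells_rejected(self):
        m, _ = self._separated(seed=4)
        with pytest.raises(ValueError):
            kmeans_cluster(size_factor_normalize(m), ["g0"], k=100)

    def test_absent_gene_list_rejected(self):
        m, _ = self._separated(seed=5)
        with pytest.raises(ValueError):
            kmeans_cluster(size_factor_normalize(m), ["nope"], k=2)


def brute_force_es(ranking: pd.Series, gene_set: set, p=1.0) -> float:
    """Running sum enumerated step by step (oracle)."""
    order = ranking.sort_values(ascending=False)
    nh = sum(g in gene_set for g in order.index)
    nr = sum(abs(order[g]) ** p for g in order.index if g in gene_set)
    n_miss = len(order) - nh
    best, running = 0.0, 0.0
    for g in order.index:
        if g in gene_set:
            running += abs(order[g]) ** p / nr
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    toy = pd.Series(
        {f"g{i}": s for i, s in enumerate(
            [3.2, 2.8, 2.5, 2.1, 1.9, 1.4, 1.1, 0.9, 0.7, 0.5,
             -0.4, -0.6, -0.8, -1.0, -1.3, -1.7, -2.0, -2.4, -2.9, -3.3]
        )}
    )

    def test_top5_set_matches_brute_force(self):
        gene_set = {"g0", "g1", "g2", "g3", "g4"}
        es, leading = enrichment_score(self.toy, gene_set)
        assert es > 0
        assert es == pytest.approx(brute_force_es(self.toy, gene_set))
        assert set(leading) == gene_set

    def test_bottom_set_negative_es(self):
        gene_set = {"g17", "g18", "g19"}
        es, _ = enrichment_score(self.toy, gene_set)
        assert es < 0
        assert es == pytest.approx(brute_force_es(self.toy, gene_set))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.sets(st.sampled_from([f"g{i}" for i in range(20)]), min_size=1, max_size=19))
    def test_es_matches_brute_force_on_random_sets(self, gene_set):
        es, _ = enrichment_score(self.toy, gene_set)
        assert es == pytest.approx(brute_force_es(self.toy, gene_set))

    def test_full_set_scores_zero(self):
        es, _ = enrichment_score(self.toy, set(self.toy.index))
        assert es == 0.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            gsea_preranked(self.toy, ["absent"], n_perm=100)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            gsea_preranked(self.toy, ["g0"], n_perm=10)

    def test_strong_set_has_small_p_and_positive_nes(self):
        res = gsea_preranked(self.toy, ["g0", "g1", "g2", "g3"], n_perm=500, seed=1)
        assert res.pvalue < 0.05 and res.nes > 1

    def test_permutation_p_roughly_uniform_for_random_sets(self):
        rng = np.random.default_rng(2)
        ranking = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        ps = [
            gsea_preranked(ranking, list(rng.choice(ranking.index, 10, replace=False)),
                           n_perm=200, seed=s).pvalue
            for s in range(20)
        ]
        assert 0.05 < np.mean(ps) < 0.95  # not systematically extreme
        assert max(ps) > 0.3

    def test_collection_assigns_fdr(self):
        res = gsea_collection(self.toy, {"top": ["g0", "g1", "g2"], "mixed": ["g3", "g16"]},
                              n_perm=200, seed=0)
        assert all(r.fdr_q is not None for r in res)

    def test_ranking_excludes_silent_genes(self):
        m = nb_matrix(seed=20)
        counts = m.counts.copy()
        counts.loc["g0"] = 0
        ranking = rank_genes_for_gsea(size_factor_normalize(CountMatrix(counts, m.groups)),
                                      ("A", "B"))
        assert "g0" not in ranking.index


class TestMarkerPhenotypeAndGating:
    def _cohort_matrix(self, effects, n_cells=400, seed=6, fraction=0.2):
        cfg = ct.SimulationConfig(n_cells=n_cells, clone_fraction=fraction,
                                  marker_effects=effects, seed=seed, include_heavy=False)
        cohort = ct.simulate_repertoire(
            ct.SimulationConfig(n_cells=n_cells, clone_fraction=fraction,
                                include_heavy=False, seed=seed),
            ct.build_germline_reference(seed=seed))
        return size_factor_normalize(ct.simulate_expression(cfg, cohort))

    def test_cd19_shift_sets_flag(self):
        m = self._cohort_matrix({"CD19": -5.0})
        pheno = marker_phenotype(m, reference_group="nonclone")
        assert pheno.flags.loc["clone", "cd19_negative"]
        assert not pheno.flags.loc["nonclone", "cd19_negative"]

    def test_null_effects_no_flags(self):
        m = self._cohort_matrix({})
        pheno = marker_phenotype(m, reference_group="nonclone")
        assert not pheno.flags.loc["clone"].any()

    def test_flags_recomputable_from_means(self):
        m = self._cohort_matrix({"CD19": -5.0, "HLA-DRA": -4.0})
        pheno = marker_phenotype(m, reference_group="nonclone")
        for flag, gene in pheno.flags.columns.to_series().items():
            gene = type(pheno).FLAG_MARKERS[flag]
            ref = pheno.means.loc["nonclone", gene]
            recomputed = pheno.means[gene] < ref - pheno.margin
            assert (recomputed == pheno.flags[flag]).all()

    def test_absent_marker_listed_not_fatal(self):
        m = nb_matrix(seed=30)
        m = size_factor_normalize(m)
        pheno = marker_phenotype(m, reference_group="A")
        assert set(pheno.missing) == set(ct.expression.MARKER_PANEL)

    def test_infinite_thresholds_gate_everything(self):
        m = self._cohort_matrix({"CD19": -5.0})
        gate = gate_clones_by_markers(
            m, markers=("CD19",), thresholds={"CD19": float("inf")}
        )
        assert len(gate.gated_cells) == len(m.cells)
        assert gate.recall == 1.0
        assert gate.purity == pytest.approx((m.groups == "clone").mean())

    def test_impossible_thresholds_gate_nothing(self):
        m = self._cohort_matrix({"CD19": -5.0})
        gate = gate_clones_by_markers(m, markers=("CD19",), thresholds={"CD19": -1e9})
        assert gate.gated_cells == [] and gate.purity is None

    def test_missing_marker_rejected(self):
        m = size_factor_normalize(nb_matrix(seed=31))
        with pytest.raises(ValueError, match="absent"):
            gate_clones_by_markers(m, markers=("CD19",), reference_group="A")
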