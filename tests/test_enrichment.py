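import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from senskin import (
    RankedList,
    SignedGeneSet,
    SimulationConfig,
    enrichment_score,
    gsea_phenotype,
    ora,
    rank_signal_to_noise,
    simulate_bulk,
    wilcoxon_de,
)

from conftest import make_adata


def brute_es(metric, member, weight=1.0):
    """Independent O(N) running-sum oracle for the weighted KS statistic."""
    N = len(metric)
    hits = [i for i in range(N) if member[i]]
    denom = sum(abs(metric[i]) ** weight for i in hits)
    if denom == 0:
        denom = len(hits)
        w = {i: 1.0 for i in hits}
    else:
        w = {i: abs(metric[i]) ** weight for i in hits}
    n_miss = N - len(hits)
    dec = 1.0 / n_miss if n_miss else 0.0
    run, best = 0.0, 0.0
    for i in range(N):
        run += w[i] / denom if member[i] else -dec
        if abs(run) > abs(best):
            best = run
    return best


def random_instance(rng, n_max=50):
    N = int(rng.integers(5, n_max + 1))
    metric = np.sort(rng.normal(size=N))[::-1]
    n_hit = int(rng.integers(1, N))
    member = np.zeros(N, dtype=bool)
    member[rng.choice(N, size=n_hit, replace=False)] = True
    genes = [f"g{i}" for i in range(N)]
    return RankedList(genes=genes, metric=metric), member


class TestSignalToNoise:
    def test_identical_gene_scores_zero(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0]], index=["g0"])
        rl = rank_signal_to_noise(expr, ["a"] * 3 + ["b"] * 3)
        assert rl.metric[0] == 0.0

    def test_closed_form_means_and_sds(self):
        # means 2 vs 1, both sds 0.5 (above the floors) -> s2n = 1.0
        a = np.array([1.5, 2.0, 2.5])
        b = np.array([0.5, 1.0, 1.5])
        sd = a.std()  # population sd, 0.408; floor 0.2*2=0.4 < sd
        expr = pd.DataFrame([np.concatenate([a, b])], index=["g0"])
        rl = rank_signal_to_noise(expr, ["x"] * 3 + ["y"] * 3, positive="x")
        assert rl.metric[0] == pytest.approx((2.0 - 1.0) / (2 * sd))

    def test_sd_floor_applies_to_near_constant_genes(self):
        # sd ~ 0 but mean 1 -> denominator floored at 0.2 + 0.2
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0001, 2.0, 2.0, 2.0001]], index=["g0"]
        )
        rl = rank_signal_to_noise(expr, ["a"] * 3 + ["b"] * 3, positive="b")
        assert rl.metric[0] == pytest.approx(1.0 / (0.2 * 1 + 0.2 * 2), rel=1e-3)

    def test_five_gene_toy_ranking_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(loc=[[0], [1], [2], [3], [4]], scale=1.0, size=(5, 8))
        X[2, :4] += 3.0  # strongest group difference for gene 2
        expr = pd.DataFrame(X, index=[f"g{i}" for i in range(5)])
        groups = ["a"] * 4 + ["b"] * 4
        rl = rank_signal_to_noise(expr, groups, positive="a")
        expected = {}
        for i in range(5):
            xa, xb = X[i, :4], X[i, 4:]
            sda = max(xa.std(), 0.2 * abs(xa.mean()) or 0.2)
            sdb = max(xb.std(), 0.2 * abs(xb.mean()) or 0.2)
            expected[f"g{i}"] = (xa.mean() - xb.mean()) / (sda + sdb)
        order = sorted(expected, key=expected.get, reverse=True)
        assert rl.genes == order
        np.testing.assert_allclose(rl.metric, [expected[g] for g in order])

    def test_group_swap_negates_metric(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(10, 8)))
        groups = ["a"] * 4 + ["b"] * 4
        fwd = rank_signal_to_noise(expr, groups, positive="b")
        rev = rank_signal_to_noise(expr, groups, positive="a")
        np.testing.assert_allclose(fwd.metric, -rev.metric[::-1])

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="3 samples"):
            rank_signal_to_noise(expr, ["a", "a", "b", "b"])


class TestEnrichmentScore:
    def test_single_top_gene_set_gives_one(self):
        rl = RankedList(genes=[f"g{i}" for i in range(10)],
                        metric=np.linspace(2, -2, 10))
        es, running, leading = enrichment_score(rl, ["g0"])
        assert es == pytest.approx(1.0)
        assert leading == ["g0"]

    def test_absent_set_rejected(self):
        rl = RankedList(genes=["g0", "g1"], metric=np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="no gene"):
            enrichment_score(rl, ["zz"])

    def test_scale_invariance_of_metric(self):
        rng = np.random.default_rng(2)
        rl, member = random_instance(rng, 30)
        setg = [g for g, m in zip(rl.genes, member) if m]
        es1, _, _ = enrichment_score(rl, setg)
        rl2 = RankedList(genes=rl.genes, metric=rl.metric * 7.5)
        es2, _, _ = enrichment_score(rl2, setg)
        assert es2 == pytest.approx(es1)

    def test_oracle_equivalence_500_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            rl, member = random_instance(rng)
            setg = [g for g, m in zip(rl.genes, member) if m]
            es, _, _ = enrichment_score(rl, setg)
            assert es == pytest.approx(brute_es(rl.metric, member)), (
                rl.metric, member)

    def test_matches_reference_tool_on_random_instances(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        for _ in range(10):
            rl, member = random_instance(rng, 40)
            setg = [g for g, m in zip(rl.genes, member) if m]
            if len(setg) < 2:
                continue
            es, _, _ = enrichment_score(rl, setg)
            res = gseapy.prerank(
                rnk=pd.DataFrame({"gene": rl.genes, "score": rl.metric}),
                gene_sets={"S": setg},
                permutation_num=2, min_size=1, max_size=100,
                weight=1, seed=0, outdir=None, no_plot=True,
            )
            assert es == pytest.approx(float(res.res2d["ES"].iloc[0]), abs=1e-9)

    def test_leading_edge_subset_of_hits(self):
        rng = np.random.default_rng(4)
        rl, member = random_instance(rng, 40)
        setg = [g for g, m in zip(rl.genes, member) if m]
        _, _, leading = enrichment_score(rl, setg)
        assert set(leading) <= set(setg)
        assert leading


@pytest.fixture(scope="module")
def bulk(senskin_set):
    cfg = SimulationConfig.default_bulk(n_genes=150, effect_delta=1.0, seed=9)
    return simulate_bulk(cfg, senskin_set)


class TestGseaPhenotype:
    def test_deterministic_under_seed(self, bulk, senskin_set):
        expr, groups = bulk
        a = gsea_phenotype(expr, groups, [senskin_set], n_perm=10, seed=5)
        b = gsea_phenotype(expr, groups, [senskin_set], n_perm=10, seed=5)
        assert a[0].es == b[0].es and a[0].nes == b[0].nes
        assert a[0].p_nominal == b[0].p_nominal and a[0].fdr_q == b[0].fdr_q

    def test_invariants(self, bulk, senskin_set):
        expr, groups = bulk
        (r,) = gsea_phenotype(expr, groups, [senskin_set], n_perm=50, seed=1)
        assert -1 <= r.es <= 1
        assert np.sign(r.nes) == np.sign(r.es)
        assert r.p_nominal >= 1 / (r.n_perm + 1)
        assert 0 <= r.fdr_q <= 1
        assert set(r.leading_edge) <= {g for g in senskin_set.all_genes}

    def test_injected_set_positively_enriched(self, bulk, senskin_set):
        expr, groups = bulk
        (r,) = gsea_phenotype(expr, groups, [senskin_set], n_perm=100, seed=2,
                              positive="old")
        assert r.nes > 0 and r.fdr_q < 0.25

    def test_label_swap_negates_es(self, bulk, senskin_set):
        expr, groups = bulk
        fwd = gsea_phenotype(expr, groups, [senskin_set], n_perm=10, seed=3,
                             positive="old")[0]
        rev = gsea_phenotype(expr, groups, [senskin_set], n_perm=10, seed=3,
                             positive="young")[0]
        assert fwd.es == pytest.approx(-rev.es)

    def test_too_few_permutations_rejected(self, bulk, senskin_set):
        expr, groups = bulk
        with pytest.raises(ValueError, match="n_perm"):
            gsea_phenotype(expr, groups, [senskin_set], n_perm=5)

    def test_set_absent_from_matrix_rejected(self, bulk):
        expr, groups = bulk
        ghost = SignedGeneSet("ghost", up_genes=("NOT_A_GENE",))
        with pytest.raises(ValueError, match="no gene"):
            gsea_phenotype(expr, groups, [ghost], n_perm=10, seed=0)


class TestWilcoxonDe:
    def test_identical_groups_null(self):
        cell_profile = np.linspace(0, 2, 4)[:, None] * np.ones((1, 3))
        X = np.vstack([cell_profile, cell_profile])  # group b mirrors group a
        adata = make_adata(X, conditions=["a"] * 4 + ["b"] * 4)
        de = wilcoxon_de(adata, "condition")
        assert np.allclose(de["ln_fc"], 0)
        assert not de["passes"].any()

    def test_small_group_p_matches_exact_enumeration(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        adata = make_adata(X, conditions=["a", "a", "a", "b", "b", "b"])
        de = wilcoxon_de(adata, "condition")
        assert de["p"].iloc[0] == pytest.approx(0.1)

    def test_bonferroni_is_p_times_m_capped(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 10))
        X[:20, 0] += 3.0
        adata = make_adata(X, conditions=["a"] * 20 + ["b"] * 20)
        de = wilcoxon_de(adata, "condition")
        np.testing.assert_allclose(
            de["p_bonferroni"], np.minimum(1.0, de["p"] * 10)
        )

    def test_pass_flag_requires_both_cutoffs(self):
        rng = np.random.default_rng(6)
        X = rng.normal(loc=1.0, scale=0.1, size=(30, 3))
        X[:15, 0] += 1.0   # big shift: passes
        X[:15, 1] += 0.02  # significant rank shift possible but tiny ln-fc
        adata = make_adata(np.abs(X), conditions=["a"] * 15 + ["b"] * 15)
        de = wilcoxon_de(adata, "condition", positive="a")
        by_gene = de.set_index("gene")
        assert by_gene.loc["g0", "passes"]
        assert not by_gene.loc["g1", "passes"]

    def test_seurat_convention_ln_fc(self):
        # two cells per group, known lognorm values
        X = np.log1p(np.array([[3.0], [5.0], [1.0], [1.0]]))
        adata = make_adata(X, conditions=["a", "a", "b", "b"])
        de = wilcoxon_de(adata, "condition", positive="a")
        assert de["ln_fc"].iloc[0] == pytest.approx(np.log(5.0) - np.log(2.0))
        de2 = wilcoxon_de(adata, "condition", positive="a", fc_mode="log_diff")
        assert de2["ln_fc"].iloc[0] == pytest.approx(X[:2, 0].mean() - X[2:, 0].mean())


class TestOra:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        pathway = universe[:5]
        res = ora(pathway, {"p": pathway}, universe)
        assert res[0].k_overlap == 5
        assert res[0].p == pytest.approx(1.0 / comb(20, 5))

    def test_query_equals_universe_degenerate(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora(universe, {"p": universe}, universe)
        assert res[0].p == pytest.approx(1.0)
        assert res[0].k_overlap == 10

    def test_zero_overlap_p_near_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = ora(universe[:5], {"p": universe[45:]}, universe)
        assert res[0].p > 0.5 and res[0].fdr > 0.5

    def test_query_outside_universe_dropped_with_warning(self, caplog):
        universe = ["a", "b", "c", "d"]
        with caplog.at_level("WARNING"):
            res = ora(["a", "zzz"], {"p": ["a", "b"]}, universe)
        assert res[0].n_query == 1
        assert "outside" in caplog.text

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora(["a"], {"p": ["a"]}, [])

    def test_sorted_by_p_with_bh_fdr(self):
        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(100)]
        query = universe[:20]
        pathways = {
            "enriched": universe[:15],
            "random": list(rng.choice(universe, 15, replace=False)),
            "depleted": universe[80:],
        }
        res = ora(query, pathways, universe)
        ps = [r.p for r in res]
        assert ps == sorted(ps)
        assert res[0].pathway == "enriched"
        assert all(0 <= r.fdr <= 1 for r in res)
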