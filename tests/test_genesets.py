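import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somportraits import genesets
from somportraits.genesets import GeneSet, GSZParams


def _universe(n):
    return [f"g{i:03d}" for i in range(n)]


class TestGMT:
    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("setA", frozenset({"g1", "g2", "g3"}), description="first"),
                GeneSet("setB", frozenset({"g2", "g4"}), description="second")]
        path = tmp_path / "c.gmt"
        genesets.write_gmt(sets, path)
        back = genesets.read_gmt(path)
        assert {s.name: s.genes for s in back} == {s.name: s.genes for s in sets}

    def test_duplicate_members_collapse(self, tmp_path):
        (tmp_path / "d.gmt").write_text("s\tdesc\tga\tga\tgb\n")
        back = genesets.read_gmt(tmp_path / "d.gmt")
        assert back[0].genes == frozenset({"ga", "gb"})

    def test_universe_filter_drops_empty(self, tmp_path):
        (tmp_path / "e.gmt").write_text("s1\t.\tga\tgb\ns2\t.\tzz\n")
        with pytest.warns(UserWarning, match="dropped"):
            back = genesets.read_gmt(tmp_path / "e.gmt", universe={"ga", "gb"})
        assert [s.name for s in back] == ["s1"]

    def test_malformed_line_reports_number(self, tmp_path):
        (tmp_path / "f.gmt").write_text("good\t.\tga\nbad-line\n")
        with pytest.raises(ValueError, match=":2"):
            genesets.read_gmt(tmp_path / "f.gmt")


class TestHypergeometric:
    def test_hand_enumeration_n4(self):
        # N=4, list of 2, set of 2, overlap 1: only the both-members list of
        # the C(4,2)=6 possible lists exceeds 1 -> p = 1/6
        assert genesets.hg_overrepresentation(4, 2, 2, 1) == pytest.approx(1 / 6)

    def test_maximal_overlap_gives_zero(self):
        assert genesets.hg_overrepresentation(10, 3, 5, 3) == 0.0

    def test_inclusive_tail_flag(self):
        strict = genesets.hg_overrepresentation(20, 5, 8, 2)
        incl = genesets.hg_overrepresentation(20, 5, 8, 2, inclusive=True)
        assert incl > strict
        assert incl == pytest.approx(strict + stats.hypergeom.pmf(2, 20, 8, 5))

    def test_impossible_margins_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            genesets.hg_overrepresentation(10, 3, 3, 4)

    def test_exhaustive_oracle_small_universes(self):
        # every margin with N <= 8 against explicit enumeration of all lists
        for n in range(2, 9):
            genes = list(range(n))
            for n_set in range(0, n + 1):
                member = set(genes[:n_set])
                for n_list in range(0, n + 1):
                    counts = {}
                    for lst in itertools.combinations(genes, n_list):
                        k = len(member.intersection(lst))
                        counts[k] = counts.get(k, 0) + 1
                    total = sum(counts.values())
                    for n_pos in range(max(0, n_list + n_set - n),
                                       min(n_list, n_set) + 1):
                        brute = sum(v for k, v in counts.items() if k > n_pos) / total
                        p = genesets.hg_overrepresentation(n, n_list, n_set, n_pos)
                        assert p == pytest.approx(brute, abs=1e-12)


class TestGSZ:
    def test_binary_hand_value(self):
        # N=100, list 10, set 10: mean 1, var 0.9*90/99; observed 4 -> z ~ 3.317
        z = genesets.gsz_binary(100, 10, 10, 4)
        assert z == pytest.approx(3.0 / np.sqrt(0.9 * 90 / 99))

    def test_binary_zero_at_expectation(self):
        assert genesets.gsz_binary(100, 10, 10, 1) == pytest.approx(0.0)

    def test_full_list_hand_value(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        z = genesets.gsz_full_list(s, GeneSet("x", frozenset("cd")))
        assert z == pytest.approx(1.0 / np.sqrt(1.25 / 2))

    def test_full_list_whole_universe_zero(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert genesets.gsz_full_list(s, GeneSet("x", frozenset("abc"))) == 0.0

    def test_constant_scores_rejected(self):
        s = pd.Series(1.0, index=list("abc"))
        with pytest.raises(ValueError, match="variance"):
            genesets.gsz_full_list(s, GeneSet("x", frozenset("ab")))

    def test_general_reduces_to_binary(self, rng):
        genes = _universe(60)
        for _ in range(50):
            n_list = int(rng.integers(3, 50))
            n_set = int(rng.integers(2, 30))
            lst = list(rng.choice(genes, n_list, replace=False))
            gs = GeneSet("s", frozenset(rng.choice(genes, n_set, replace=False)))
            npos = len(gs.genes.intersection(lst))
            scores = pd.Series(1.0, index=lst)
            try:
                zb = genesets.gsz_binary(60, n_list, n_set, npos)
            except ValueError:
                continue
            zg = genesets.gsz(scores, gs, 60, lam=1.0)
            assert zg == pytest.approx(zb, rel=1e-10, abs=1e-10)

    def test_general_reduces_to_full_list(self, rng):
        genes = _universe(40)
        scores = pd.Series(rng.normal(size=40), index=genes)
        for n_set in (3, 10, 25):
            gs = GeneSet("s", frozenset(rng.choice(genes, n_set, replace=False)))
            zg = genesets.gsz(scores, gs, 40, lam=1.0)
            zf = genesets.gsz_full_list(scores, gs, finite_population=True)
            assert zg == pytest.approx(zf, rel=1e-10)

    def test_short_list_approximation_close(self, rng):
        # Eq-level consistency: the simplified variance agrees within 10%
        # when list and set are both small fractions of the universe
        for _ in range(30):
            n = 2000
            n_list = int(rng.integers(5, 100))
            n_set = int(rng.integers(5, 100))
            npos = int(rng.integers(0, min(n_list, n_set)))
            z1 = genesets.gsz_binary(n, n_list, n_set, npos)
            z2 = genesets.gsz_binary(n, n_list, n_set, npos, short_list=True)
            if abs(z1) > 1e-9:
                assert abs(z2 - z1) / abs(z1) < 0.10

    def test_small_sets_penalized(self, rng):
        # the regularization targets short lists and small sets relative to
        # the universe, where the exact null SE vanishes; the SE_0 floor keeps
        # the denominator bounded, shrinking |GSZ|
        genes = _universe(10_000)
        lst = [f"g{i:05d}x" for i in range(20)]
        scores = pd.Series(rng.normal(size=20) + 1.0, index=lst)
        small = GeneSet("small", frozenset(lst[:3]))
        params = GSZParams(n_list_min=10, n_set_min=10)
        z_blend = genesets.gsz(scores, small, 10_000, params)
        z_exact = genesets.gsz(scores, small, 10_000, params, lam=1.0)
        assert abs(z_blend) < abs(z_exact)
        # lambda follows the printed size formula
        lam = 1 - min(1.0, (10 / 20) * (10 / 3))
        assert lam == 0.0  # fully floored for this tiny set
        z_floor = genesets.gsz(scores, small, 10_000, params, lam=0.0)
        assert z_blend == pytest.approx(z_floor)

    def test_incoherent_set_damped(self):
        # members with cancelling positive/negative scores score lower than a
        # coherent same-size set
        genes = _universe(100)
        scores = pd.Series(0.1, index=genes)
        up = genes[:10]
        coherent = GeneSet("coh", frozenset(up))
        scores_coh = scores.copy()
        scores_coh[up] = 2.0
        z_coh = genesets.gsz(scores_coh, coherent, 100, lam=1.0)
        scores_mix = scores.copy()
        scores_mix[up[:5]] = 2.0
        scores_mix[up[5:]] = -2.0
        z_mix = genesets.gsz(scores_mix, coherent, 100, lam=1.0)
        assert abs(z_mix) < abs(z_coh)


class TestPermutation:
    def test_add_one_floor_and_null_center(self, rng):
        genes = _universe(200)
        scores = pd.Series(rng.normal(size=200), index=genes)
        params = GSZParams(n_permutations=100, seed=3)
        gs = GeneSet("s", frozenset(genes[:20]))
        z = genesets.gsz(scores, gs, 200, params)
        p = genesets.gsz_permutation_p(z, scores, 20, genes, params)
        assert p >= 1 / 101
        p0 = genesets.gsz_permutation_p(0.0, scores, 20, genes, params)
        assert p0 > 0.9  # observed 0 is never extreme

    def test_null_pvalues_roughly_uniform(self, rng):
        genes = _universe(300)
        scores = pd.Series(rng.normal(size=300), index=genes)
        params = GSZParams(n_permutations=100, seed=9)
        pvals = []
        prng = np.random.default_rng(17)
        for _ in range(120):
            gs = GeneSet("s", frozenset(prng.choice(genes, 15, replace=False)))
            z = genesets.gsz(scores, gs, 300, params)
            pvals.append(genesets.gsz_permutation_p(z, scores, 15, genes, params,
                                                    rng=np.random.default_rng(prng.integers(2**31))))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestMaps:
    def test_confined_set_hits_single_tile(self, trained):
        asg = trained["assignment"]
        k = int(np.argmax(asg.sizes))
        members = asg.clusters[k][:3]
        pmap = genesets.metagene_overrepresentation_map(
            GeneSet("s", frozenset(members)), asg)
        assert np.nanargmin(pmap) == k
        other = np.delete(pmap, k)
        assert np.all(np.isnan(other) | (other >= pmap[k]))

    def test_map_matches_per_tile_brute_force(self, trained):
        asg = trained["assignment"]
        rng = np.random.default_rng(4)
        members = frozenset(rng.choice(asg.bmu.index, 60, replace=False))
        pmap = genesets.metagene_overrepresentation_map(GeneSet("s", members), asg)
        n = asg.n_genes
        n_set = sum(g in members for g in asg.bmu.index)
        for k in range(len(asg.clusters)):
            hits = sum(g in members for g in asg.clusters[k])
            if hits == 0:
                assert np.isnan(pmap[k])
            else:
                assert pmap[k] == pytest.approx(
                    genesets.hg_overrepresentation(n, asg.sizes[k], n_set, hits))

    def test_random_set_not_bonferroni_significant(self, trained):
        asg = trained["assignment"]
        k = len(asg.clusters)
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(40 + s)
            members = frozenset(rng.choice(asg.bmu.index, 50, replace=False))
            pmap = genesets.metagene_overrepresentation_map(GeneSet("s", members), asg)
            hits += np.nansum(pmap < 0.05 / k)
        assert hits <= 2  # expected well below one per map


class TestSpotEnrichment:
    def test_planted_set_ranks_first(self, trained):
        from somportraits import diffexpr, portraits, spots, synthetic
        truth = trained["truth"]
        asg, grid, delta = trained["assignment"], trained["grid"], trained["delta"]
        le = trained["log_expr"]
        over, _ = spots.summary_spots(portraits.summary_maps(grid), (8, 8), 0.95, asg)
        sets = synthetic.matched_gmt(truth, list(delta.index), n_decoys=3)
        scores = diffexpr.score_table(delta, le.values, le.sigma, le.n_replicates)
        name, members = next(iter(truth.modules.items()))
        spot = max(over, key=lambda s: len(set(members) & set(s.genes)))
        active = delta.columns[truth.module_group[name]]
        res = genesets.spot_enrichment(spot, sets, scores["t"][active],
                                       len(delta), list(delta.index),
                                       GSZParams(n_permutations=100, seed=1),
                                       permutation=False)
        assert res[0].set_name == name
        decoys = [r for r in res if r.set_name.startswith(name + "_decoy")]
        assert all(r.rank > 1 for r in decoys)

    def test_full_universe_spot_degenerate_hg(self):
        # a "spot" spanning the whole universe forces N_+ = N_set -> p = 0
        assert genesets.hg_overrepresentation(50, 50, 7, 7) == 0.0


class TestProfilesAndHeatmap:
    def test_profile_peaks_in_active_group(self, trained):
        truth = trained["truth"]
        delta = trained["delta"]
        name, members = next(iter(truth.modules.items()))
        gs = GeneSet(name, frozenset(members))
        prof = genesets.gene_set_profile(gs, delta,
                                         GSZParams(n_permutations=100, seed=2))
        g = truth.module_group[name]
        active = [c for i, c in enumerate(delta.columns) if i % truth.n_groups == g]
        inactive = [c for c in delta.columns if c not in active]
        assert prof.loc[active, "GSZ"].min() > prof.loc[inactive, "GSZ"].max()
        assert prof.loc[active, "GSZ"].min() > prof["threshold"].iloc[0]

    def test_profile_correlates_with_top_metagene(self, trained):
        truth = trained["truth"]
        delta, asg, grid = trained["delta"], trained["assignment"], trained["grid"]
        name, members = next(iter(truth.modules.items()))
        gs = GeneSet(name, frozenset(members))
        prof = genesets.gene_set_profile(gs, delta,
                                         GSZParams(n_permutations=100, seed=2))
        pmap = genesets.metagene_overrepresentation_map(gs, asg)
        top_tile = int(np.nanargmin(pmap))
        r = np.corrcoef(prof["GSZ"].to_numpy(), grid.weights[top_tile])[0, 1]
        assert r > 0.9  # guilt-by-association: set profile ~ metagene profile

    def test_top_three_union_deduplicated(self):
        res = {
            ("s1", "A"): [genesets.EnrichmentResult("x", "A", perm_p=0.01),
                          genesets.EnrichmentResult("y", "A", perm_p=0.02),
                          genesets.EnrichmentResult("z", "A", perm_p=0.5),
                          genesets.EnrichmentResult("w", "A", perm_p=0.9)],
            ("s2", "B"): [genesets.EnrichmentResult("x", "B", perm_p=0.03),
                          genesets.EnrichmentResult("q", "B", perm_p=0.04)],
        }
        heat = genesets.top_three_heatmap(res, ["s1", "s2"])
        assert set(heat.index) == {"x", "y", "z", "q"}  # union of top-3, dedup
        assert heat.loc["x", "s1"] == pytest.approx(2.0)
        heat2 = genesets.top_three_heatmap(res, ["s1", "s2"])
        assert list(heat.index) == list(heat2.index)  # deterministic order

    def test_empty_results_warn(self):
        with pytest.warns(UserWarning, match="empty"):
            heat = genesets.top_three_heatmap({}, ["s1"])
        assert heat.empty
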