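import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from volescape.data_io import GenotypeTable, HaplotypeAlignment
from volescape.fstats import (
    amova_phi,
    gabriel_graph,
    hudson_fst,
    linearize_fst,
    mito_nuclear_calibrate,
    pairwise_fst,
    samova_search,
    sequence_diversity,
    wc_fstats,
)
from volescape.synthetic_data import SimulationConfig, simulate_metapopulation


def table_of(pop_genos, locus_count=None):
    """pop_genos: {pop: list of per-locus genotype pair lists}."""
    ids, pops, calls = [], [], []
    for pop, genos in pop_genos.items():
        for g in genos:
            ids.append(f"s{len(ids)}")
            pops.append(pop)
            calls.append(g)
    calls = np.asarray(calls)
    L = calls.shape[1]
    return GenotypeTable(ids, np.array(pops, dtype=object), calls,
                         [f"L{j}" for j in range(L)])


def aln_of(pop_seqs):
    ids, pops, seqs = [], [], []
    for pop, ss in pop_seqs.items():
        for s in ss:
            ids.append(f"h{len(ids)}")
            pops.append(pop)
            seqs.append(list(s))
    return HaplotypeAlignment(ids, np.array(seqs), np.array(pops, dtype=object))


class TestWcFstats:
    def test_fixed_difference_theta_one(self):
        t = table_of({"p1": [[[1, 1]]] * 4, "p2": [[[2, 2]]] * 4})
        assert wc_fstats(t, n_boot=0).theta == pytest.approx(1.0)

    def test_panmictic_mean_near_zero(self):
        rng = np.random.default_rng(0)
        thetas = []
        for _ in range(30):
            calls = rng.choice(np.arange(1, 6), size=(40, 5, 2))
            t = GenotypeTable(
                [f"s{i}" for i in range(40)],
                np.array(["a"] * 20 + ["b"] * 20, dtype=object),
                calls, [f"L{j}" for j in range(5)],
            )
            thetas.append(wc_fstats(t, n_boot=0).theta)
        assert abs(np.mean(thetas)) < 0.02

    def test_matches_hand_variance_components(self, toy_two_pop):
        # full a/b/c components computed independently with plain loops
        def hand_theta(table):
            sa = sb = sc = 0.0
            for l in range(table.n_loci):
                genos = []
                for pop in table.populations:
                    g = table.calls[table.pop_indices(pop), l, :]
                    genos.append(g[g[:, 0] != 0])
                r = len(genos)
                n_i = [len(g) for g in genos]
                nbar = sum(n_i) / r
                nc = (sum(n_i) - sum(n**2 for n in n_i) / sum(n_i)) / (r - 1)
                alleles = sorted({int(a) for g in genos for a in g.ravel()})
                for al in alleles:
                    p_i = [np.mean(g == al) for g in genos]
                    h_i = [
                        np.mean((g[:, 0] != g[:, 1]) & ((g == al).any(axis=1)))
                        for g in genos
                    ]
                    pbar = sum(n * p for n, p in zip(n_i, p_i)) / sum(n_i)
                    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / (
                        (r - 1) * nbar
                    )
                    hbar = sum(n * h for n, h in zip(n_i, h_i)) / sum(n_i)
                    a = (nbar / nc) * (
                        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                        / (nbar - 1)
                    )
                    b = (nbar / (nbar - 1)) * (
                        pbar * (1 - pbar) - (r - 1) / r * s2
                        - (2 * nbar - 1) / (4 * nbar) * hbar
                    )
                    sa, sb, sc = sa + a, sb + b, sc + hbar / 2
            return sa / (sa + sb + sc)

        assert wc_fstats(toy_two_pop, n_boot=0).theta == pytest.approx(
            hand_theta(toy_two_pop), abs=1e-12
        )

    def test_requires_two_populations(self):
        t = table_of({"p1": [[[1, 2]]] * 3})
        with pytest.raises(ValueError):
            wc_fstats(t)


class TestPairwiseFst:
    def test_duplicated_population(self):
        rng = np.random.default_rng(1)
        genos = rng.choice([1, 2, 3], size=(30, 5, 2)).tolist()
        t = table_of({"a": genos, "b": genos})
        theta, lin, p = pairwise_fst(t, n_perm=99, seed=0)
        assert abs(theta.pair("a", "b")) < 0.05
        assert p.pair("a", "b") > 0.3

    def test_fixed_pair_extreme(self):
        t = table_of({"a": [[[1, 1]]] * 10, "b": [[[2, 2]]] * 10})
        theta, lin, p = pairwise_fst(t, n_perm=99, seed=1)
        assert theta.pair("a", "b") == pytest.approx(1.0)
        assert p.pair("a", "b") == pytest.approx(1 / 100)

    def test_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(2)
        t = table_of({
            "a": rng.choice([1, 2], size=(6, 2, 2)).tolist(),
            "b": rng.choice([2, 3], size=(6, 2, 2)).tolist(),
            "c": rng.choice([1, 3], size=(6, 2, 2)).tolist(),
        })
        theta, lin, _ = pairwise_fst(t, n_perm=10, seed=0)
        for x, y in itertools.combinations(["a", "b", "c"], 2):
            idx = np.concatenate([t.pop_indices(x), t.pop_indices(y)])
            expected = wc_fstats(t.subset(idx), n_boot=0).theta
            assert theta.pair(x, y) == pytest.approx(expected, abs=1e-12)
            assert lin.pair(x, y) == pytest.approx(
                expected / (1 - expected), abs=1e-12
            )


class TestLinearize:
    @pytest.mark.parametrize("f,expected", [(0.0, 0.0), (0.5, 1.0),
                                            (0.072, 0.0776)])
    def test_values(self, f, expected):
        assert linearize_fst(f) == pytest.approx(expected, abs=5e-5)

    def test_error_at_one(self):
        with pytest.raises(ValueError):
            linearize_fst(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.0, 0.9))
    def test_inverse_identity(self, f):
        lin = linearize_fst(f)
        assert lin / (1 + lin) == pytest.approx(f, abs=1e-12)


class TestMitoNuclearCalibration:
    def test_paper_value(self):
        assert mito_nuclear_calibrate(0.3682) == pytest.approx(0.1272, abs=5e-5)

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_fixed_points(self, f):
        assert mito_nuclear_calibrate(f) == f

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.001, 0.999))
    def test_shrinks_interior_and_monotone(self, f):
        assert mito_nuclear_calibrate(f) < f
        assert mito_nuclear_calibrate(f) > mito_nuclear_calibrate(f * 0.9)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mito_nuclear_calibrate(1.2)


class TestSequenceDiversity:
    def test_identical_sequences(self):
        aln = aln_of({"x": ["ACGT"] * 4})
        d = sequence_diversity(aln)
        assert (d.S, d.pi, d.H, d.k) == (0, 0.0, 0.0, 0.0)
        assert d.h == 1

    def test_one_transition(self):
        aln = aln_of({"x": ["ACGT", "ACAT"]})  # G->A purine transition
        d = sequence_diversity(aln)
        assert d.S == 1 and d.k == 1.0 and d.ts_proportion == 1.0
        assert d.H == pytest.approx(1.0)  # (2/1)*(1-0.5)

    def test_matches_exhaustive_pair_counting(self):
        seqs = ["ACGTAC", "ACGTAT", "TCGAAC", "ACGAAC"]
        aln = aln_of({"x": seqs})
        d = sequence_diversity(aln)
        pairs = list(itertools.combinations(seqs, 2))
        diffs = [sum(a != b for a, b in zip(s, t)) for s, t in pairs]
        assert d.k == pytest.approx(np.mean(diffs))
        assert d.pi == pytest.approx(np.mean([x / 6 for x in diffs]))
        assert d.S == sum(len({s[i] for s in seqs}) > 1 for i in range(6))

    def test_gap_sites_pairwise_complete(self):
        aln = aln_of({"x": ["AC-T", "ACGT", "ACAT"]})
        d = sequence_diversity(aln)
        # pair (1,2) differs at site 3; pairs with the gap compare 3 sites
        assert d.k == pytest.approx((0 + 0 + 1) / 3)


class TestHudsonFst:
    def test_identical_populations_zero(self):
        aln = aln_of({"x": ["ACGT", "ACGA"], "y": ["ACGT", "ACGA"]})
        overall, mat = hudson_fst(aln)
        assert mat.pair("x", "y") == pytest.approx(0.0)

    def test_fixed_difference_one(self):
        aln = aln_of({"x": ["AAAA", "AAAA"], "y": ["TTTT", "TTTT"]})
        overall, mat = hudson_fst(aln)
        assert mat.pair("x", "y") == pytest.approx(1.0)
        assert overall == pytest.approx(1.0)

    def test_matches_hand_count(self):
        # within x (ordered pairs incl. self): 2 of 4 pairs differ by 1 -> 0.5
        # within y: 0; between: AAAA-TTTA=3, AAAT-TTTA=4 (x2) -> mean 3.5
        aln = aln_of({"x": ["AAAA", "AAAT"], "y": ["TTTA", "TTTA"]})
        overall, mat = hudson_fst(aln)
        expected = 1 - (0.5 * (0.5 + 0)) / 3.5
        assert mat.pair("x", "y") == pytest.approx(expected)

    def test_duplication_invariance(self):
        a = aln_of({"x": ["ACGT", "ACGA"], "y": ["TCGT", "TCGA"]})
        b = aln_of({"x": ["ACGT", "ACGA"] * 2, "y": ["TCGT", "TCGA"] * 2})
        assert hudson_fst(a)[1].pair("x", "y") == pytest.approx(
            hudson_fst(b)[1].pair("x", "y")
        )

    def test_singleton_population_flagged(self):
        aln = aln_of({"x": ["ACGT"], "y": ["TCGT", "TCGA"]})
        _, mat = hudson_fst(aln)
        assert np.isnan(mat.pair("x", "y"))


class TestAmova:
    def test_fixed_difference_split_positive(self):
        t = table_of({
            "a": [[[1, 1]]] * 4, "b": [[[1, 1]]] * 4,
            "c": [[[2, 2]]] * 4, "d": [[[2, 2]]] * 4,
        })
        ct, sc, stt = amova_phi(t, {"a": 0, "b": 0, "c": 1, "d": 1})
        assert ct > 0.5

    def test_matches_hand_sums_of_squares(self):
        t = table_of({
            "a": [[[1, 1]], [[1, 2]]],
            "b": [[[1, 2]], [[2, 2]]],
            "c": [[[3, 3]], [[2, 3]]],
            "d": [[[3, 3]], [[3, 3]]],
        })
        grouping = {"a": 0, "b": 0, "c": 1, "d": 1}

        def d2(g1, g2):
            shared = 0
            b2 = list(g2)
            for x in g1:
                if x in b2:
                    b2.remove(x)
                    shared += 1
            return 2 - shared

        genos = [tuple(t.calls[i, 0]) for i in range(8)]
        pops = list(t.population)

        def ss(idx):
            return sum(
                d2(genos[i], genos[j]) for i, j in itertools.combinations(idx, 2)
            ) / len(idx)

        all_idx = list(range(8))
        ss_tot = ss(all_idx)
        pop_idx = {p: [i for i in all_idx if pops[i] == p] for p in "abcd"}
        grp_idx = {0: pop_idx["a"] + pop_idx["b"], 1: pop_idx["c"] + pop_idx["d"]}
        ssd_wp = sum(ss(v) for v in pop_idx.values())
        ssd_ap = sum(ss(v) for v in grp_idx.values()) - ssd_wp
        ssd_ag = ss_tot - sum(ss(v) for v in grp_idx.values())
        # balanced design: n = 2, n' = 4 group-size coefficient analogues
        ms_wp = ssd_wp / (8 - 4)
        ms_ap = ssd_ap / (4 - 2)
        ms_ag = ssd_ag / (2 - 1)
        sc2 = ms_wp
        sb2 = (ms_ap - sc2) / 2
        sa2 = (ms_ag - sc2 - 2 * sb2) / 4
        tot = sa2 + sb2 + sc2
        ct, sc_, stt = amova_phi(t, grouping)
        assert ct == pytest.approx(sa2 / tot, abs=1e-12)
        assert sc_ == pytest.approx(sb2 / (sb2 + sc2), abs=1e-12)
        assert stt == pytest.approx((sa2 + sb2) / tot, abs=1e-12)

    def test_random_grouping_of_panmixia_near_zero(self):
        rng = np.random.default_rng(3)
        cts = []
        for _ in range(20):
            calls = rng.choice([1, 2, 3], size=(24, 2, 2))
            t = GenotypeTable(
                [f"s{i}" for i in range(24)],
                np.repeat(["a", "b", "c", "d"], 6).astype(object),
                calls, ["L0", "L1"],
            )
            ct, _, _ = amova_phi(t, {"a": 0, "b": 0, "c": 1, "d": 1})
            cts.append(ct)
        assert abs(np.mean(cts)) < 0.03

    def test_single_group_rejected(self):
        t = table_of({"a": [[[1, 1]]] * 2, "b": [[[2, 2]]] * 2})
        with pytest.raises(ValueError):
            amova_phi(t, {"a": 0, "b": 0})


@pytest.fixture(scope="module")
def two_cluster_dataset():
    coords = np.array(
        [[0, 0], [1000, 0], [500, 800],
         [20000, 0], [21000, 0], [20500, 800]], float
    )
    M = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            if i != j and (i < 3) == (j < 3):
                M[i, j] = 0.05
        M[i, i] = 1 - M[i].sum()
    cfg = SimulationConfig(
        seed=2, n_demes=6, deme_coords=coords, deme_size=40,
        generations=250, migration="matrix", migration_matrix=M,
        n_loci=10, mu_nuc=1e-3, sample_size=12, mt_sample_size=0,
        mt_length=8, mu_mt=0,
    )
    table, _, _ = simulate_metapopulation(cfg)
    from volescape.distances import population_centroids
    return table, population_centroids(table)


class TestSamova:
    def test_recovers_planted_split(self, two_cluster_dataset):
        table, cent = two_cluster_dataset
        res = samova_search(table, cent, K=2, n_restarts=5, n_steps=300,
                            n_perm=30, seed=1)
        groups = {}
        for p, g in res.grouping.items():
            groups.setdefault(g, set()).add(p)
        assert sorted(map(sorted, groups.values())) == [
            ["deme1", "deme2", "deme3"], ["deme4", "deme5", "deme6"]
        ]
        assert res.phi_ct > 0.2

    def test_k_equals_p_singletons(self, two_cluster_dataset):
        table, cent = two_cluster_dataset
        res = samova_search(table, cent, K=6, seed=0)
        assert len(set(res.grouping.values())) == 6

    def test_beats_random_contiguous_partitions(self, two_cluster_dataset):
        table, cent = two_cluster_dataset
        res = samova_search(table, cent, K=3, n_restarts=10, n_steps=500,
                            n_perm=10, seed=5)
        rng = np.random.default_rng(9)
        adj = gabriel_graph(cent)
        pops = table.populations
        from volescape.fstats import _genotype_distance_sq, _amova_from_d2
        d2, pop_of = _genotype_distance_sq(table)
        worse = 0
        for _ in range(100):
            # random contiguous partition by region growing
            seeds = rng.choice(len(pops), size=3, replace=False)
            grouping = {pops[s]: g for g, s in enumerate(seeds)}
            while len(grouping) < len(pops):
                for p in pops:
                    if p in grouping:
                        continue
                    nbr = {grouping[q] for q in adj[p] if q in grouping}
                    if nbr:
                        grouping[p] = rng.choice(sorted(nbr))
            try:
                ct = _amova_from_d2(d2, pop_of, grouping)[0]
            except ValueError:
                continue
            worse += ct <= res.phi_ct + 1e-9
        assert worse == 100

    def test_k_out_of_range(self, two_cluster_dataset):
        table, cent = two_cluster_dataset
        with pytest.raises(ValueError):
            samova_search(table, cent, K=7, seed=0)
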