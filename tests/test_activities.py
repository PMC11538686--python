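import numpy as np
import pandas as pd
import pytest
import modulon as md

from .oracles import exact_permutation_pvalue, hypergeom_sf_bruteforce


def _activity_frame(rows, samples=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"IM{i:03d}" for i in range(rows.shape[0])],
                        columns=samples)


class TestActivityCorrelation:
    def test_perfect_and_inverted(self, rng):
        a = rng.normal(size=12)
        A = _activity_frame([a])
        X = pd.DataFrame([a, -a], index=["gpos", "gneg"], columns=A.columns)
        assert md.activity_correlation(A, "IM000", X, "gpos") == pytest.approx(1.0)
        assert md.activity_correlation(A, "IM000", X, "gneg") == pytest.approx(-1.0)

    def test_planted_member_tracks_activity(self, recovery_pipeline):
        sim = recovery_pipeline["sim"]
        est = recovery_pipeline["est"]
        X = recovery_pipeline["X"]
        truth = sim.truth
        # strongest-weight member of the first planted module
        w = truth.true_weights.iloc[:, 0]
        gene = w.abs().idxmax()
        # recovered component best matching that module
        C = np.abs(np.corrcoef(
            np.hstack([truth.true_weights.to_numpy()[:, :1],
                       est.gene_weights_.to_numpy()]).T
        ))[0, 1:]
        comp = est.gene_weights_.columns[C.argmax()]
        r = md.activity_correlation(est.activities_, comp, X, gene)
        assert abs(r) > 0.9

    def test_zero_variance_rejected(self):
        A = _activity_frame([[1.0, 1.0, 1.0]])
        X = pd.DataFrame([[0.0, 1.0, 2.0]], index=["g"], columns=A.columns)
        with pytest.raises(ValueError):
            md.activity_correlation(A, "IM000", X, "g")


class TestClusterActivities:
    def test_identical_rows_merge_at_zero(self, rng):
        a = rng.normal(size=10)
        Z, order = md.cluster_activities(_activity_frame([a, a, rng.normal(size=10)]))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_merge_at_two(self, rng):
        a = rng.normal(size=10)
        Z, order = md.cluster_activities(_activity_frame([a, -a]))
        assert Z[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_constant_row_named_in_error(self, rng):
        A = _activity_frame([rng.normal(size=6), np.full(6, 3.0)])
        with pytest.raises(ValueError, match="IM001"):
            md.cluster_activities(A)

    def test_coactivated_pair_clusters_adjacently(self):
        """Two modules sharing an activity driver sit next to each other in
        the dendrogram leaf order across seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            driver = rng.normal(size=30)
            rows = [driver + rng.normal(0, 0.1, 30),
                    driver + rng.normal(0, 0.1, 30)]
            rows += [rng.normal(size=30) for _ in range(4)]
            _, order = md.cluster_activities(_activity_frame(rows))
            pos = {name: i for i, name in enumerate(order)}
            assert abs(pos["IM000"] - pos["IM001"]) == 1


class TestDifferentialActivity:
    def test_identical_groups_null(self):
        A = _activity_frame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        delta, p = md.differential_activity(
            A, "IM000", ["s0", "s1", "s2"], ["s3", "s4", "s5"], n_perm=499, seed=0
        )
        assert delta == pytest.approx(0.0)
        assert p > 0.9

    def test_planted_condition_specific_module(self):
        """A module active in exactly one condition separates that condition
        from the rest at p <= 0.01."""
        truth = md.generate_ground_truth(300, 2, module_size_range=(8, 12), seed=0)
        design = md.generate_design(8, 3, seed=0)
        act = np.zeros((2, 8))
        act[0, 3] = 4.0          # module 0 only active in condition 3
        act[1, 1:] = np.linspace(-2, 2, 7)
        sim = md.synthesize_compendium(truth, design, seed=1, condition_activities=act)
        A = sim.truth.true_activities
        active = [s for s in A.columns if sim.design.loc[s, "condition"] == "cond03"]
        others = [s for s in A.columns if s not in active]
        delta, p = md.differential_activity(A, A.index[0], active, others,
                                            n_perm=999, seed=5)
        assert delta == pytest.approx(4.0)
        assert p <= 0.01

    def test_deterministic(self, rng):
        A = _activity_frame([rng.normal(size=12)])
        g1, g2 = list(A.columns[:6]), list(A.columns[6:])
        r1 = md.differential_activity(A, "IM000", g1, g2, n_perm=999, seed=3)
        r2 = md.differential_activity(A, "IM000", g1, g2, n_perm=999, seed=3)
        assert r1 == r2

    def test_overlapping_groups_rejected(self, rng):
        A = _activity_frame([rng.normal(size=6)])
        with pytest.raises(ValueError):
            md.differential_activity(A, "IM000", ["s0", "s1"], ["s1", "s2"])

    def test_matches_exact_enumeration(self, rng):
        """Permutation p within 3 Monte-Carlo SE of the exact enumeration
        p-value on 6-vs-6 groups."""
        for _ in range(5):
            vals = rng.normal(0, 1, 12)
            vals[:6] += rng.uniform(0, 1.5)
            A = _activity_frame([vals])
            g1, g2 = list(A.columns[:6]), list(A.columns[6:])
            n_perm = 1999
            _, p_mc = md.differential_activity(A, "IM000", g1, g2, n_perm=n_perm, seed=7)
            p_exact = exact_permutation_pvalue(vals[:6], vals[6:])
            se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(p_mc - p_exact) <= 3 * se + 1 / n_perm


class TestRegulonEnrichment:
    def test_identical_sets(self):
        members = {"a", "b", "c"}
        res = md.regulon_enrichment(members, {"R": {"a", "b", "c"}}, universe=100)
        assert res[0].precision == res[0].recall == res[0].f1 == 1.0
        assert res[0].pvalue < 1e-4

    def test_soxr_style_overlap(self):
        # 9-member iModulon, 6 of which belong to the known regulon
        members = {f"g{i}" for i in range(9)}
        regulon = {f"g{i}" for i in range(6)} | {"x1", "x2"}
        res = md.regulon_enrichment(members, {"SoxR": regulon}, universe=7000)
        assert res[0].overlap == 6
        assert res[0].precision == pytest.approx(6 / 9)
        assert res[0].recall == pytest.approx(6 / 8)

    def test_hypergeometric_matches_bruteforce(self):
        # universe 20, regulon = first 5 genes, members = 4 genes with overlap 3
        members = {"g0", "g1", "g2", "g10"}
        regulons = {"R": {f"g{i}" for i in range(5)}}
        res = md.regulon_enrichment(members, regulons, universe=20)
        expected = hypergeom_sf_bruteforce(universe=20, n_target=5, n_draw=4, obs=3)
        assert res[0].pvalue == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_monotone(self, rng):
        members = {f"g{i}" for i in range(10)}
        regulons = {
            f"R{j}": set(rng.choice([f"g{i}" for i in range(200)], size=12, replace=False))
            for j in range(8)
        }
        res = md.regulon_enrichment(members, regulons, universe=200)
        by_p = sorted(res, key=lambda r: r.pvalue)
        qs = [r.qvalue for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.qvalue >= r.pvalue - 1e-12 for r in res)

    def test_empty_members(self):
        assert md.regulon_enrichment(set(), {"R": {"a"}}, universe=10) == []


class TestTRN:
    def _imodulon(self, id_, members, regulator=None):
        return md.IModulon(id=id_, members=set(members), weights=None, threshold=0.1,
                           explained_variance=0.1, regulator=regulator)

    def test_no_assignments_gives_known_edges(self):
        known = {"R1": {"a", "b"}, "R2": {"c"}}
        trn = md.build_trn([self._imodulon("IM001", {"x", "y"})], known)
        assert len(trn) == 3
        assert set(trn["provenance"]) == {"known"}

    def test_new_edges_tagged(self):
        known = {"R1": {"a"}}
        im = self._imodulon("IM001", {"m1", "m2", "m3", "m4", "m5"}, regulator="R1")
        trn = md.build_trn([im], known)
        assert (trn["provenance"] == "imodulon").sum() == 5
        assert len(trn) == 6

    def test_planted_regulon_edges_recovered(self):
        """Assign regulators to recovered iModulons by enrichment and check
        edge precision against the planted regulatory network."""
        from modulon.preprocess import preprocess_counts

        sim = md.simulate_compendium(
            n_genes=1000, k_true=8, n_conditions=15, module_size_range=(15, 30),
            seed=1,
        )
        X, _ = preprocess_counts(sim.counts, sim.genes, sim.design)
        est = md.RobustICA(n_components=8, n_runs=15, random_state=1).fit(X)
        ims = md.build_imodulons(est.to_component_set(), X, seed=0)
        regs = sim.truth.regulon_map
        md.assign_regulators(ims, regs, universe=sim.counts.shape[0])
        trn = md.build_trn(ims, known={})
        assert len(trn) > 0
        truth_edges = {
            (reg, g)
            for i, (reg, targets) in enumerate(sorted(regs.items()))
            for g in sim.truth.module_members[i]
        }
        got = set(zip(trn["regulator"], trn["target"]))
        precision = len(got & truth_edges) / len(got)
        assert precision >= 0.9
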