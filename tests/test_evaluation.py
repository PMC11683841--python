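import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import pearsonr, spearmanr

from plevaluate import evaluation, phenotypes, relmat, simdata
from plevaluate.bayes import _fixed_design, _hstack_csc, _level_design

VAR = {"u": 0.019, "p": 0.057, "c": 0.026, "e": 0.081}


def _dense_mme_solution(rec, a_inv, ids, var):
    Wf, names = _fixed_design(rec)
    cows = sorted(rec["cow"].unique(), key=str)
    cgs = sorted(rec["cg"].unique(), key=str)
    W = _hstack_csc([Wf, _level_design(rec["cow"], ids),
                     _level_design(rec["cow"], cows),
                     _level_design(rec["cg"], cgs)])
    lam = sp.block_diag([
        sp.coo_matrix((Wf.shape[1],) * 2),
        sp.csr_matrix(a_inv) * (var["e"] / var["u"]),
        sp.identity(len(cows)) * (var["e"] / var["p"]),
        sp.identity(len(cgs)) * (var["e"] / var["c"])])
    C = (W.T @ W + lam).toarray()
    resp = "y" if "y" in rec else "success"
    x = np.linalg.solve(C, W.T @ rec[resp].to_numpy(dtype=float))
    return x, Wf.shape[1]


class TestSolver:
    def test_diagonal_toy_exact(self):
        # one record per cow, unrelated animals, single fixed level:
        # hand-checkable shrinkage system
        rec = pd.DataFrame({
            "cow": ["a", "b"], "parity": [2, 2],
            "year_season": ["2000_1", "2000_1"],
            "afc": [2.0, 2.0], "rh": [0.0, 0.0],
            "cg": ["g", "g"], "y": [1.0, -1.0]})
        a_inv = sp.identity(2, format="csr")
        res = evaluation.solve_ssgblup(rec, a_inv, ["a", "b"], VAR,
                                       tol=1e-24)
        x, nf = _dense_mme_solution(rec, a_inv, ["a", "b"], VAR)
        np.testing.assert_allclose(res.ebv.values, x[nf:nf + 2], atol=1e-10)

    def test_matches_dense_solve_20_animals(self, recovery_herd):
        rec = recovery_herd["records"].iloc[:140].copy()
        ped = relmat.truncate_pedigree(recovery_herd["pedigree"],
                                       rec["cow"].unique(), 5)
        _, a_inv, codes = relmat.compute_inbreeding_and_A_inverse(ped)
        ids = list(codes.ids)
        res = evaluation.solve_ssgblup(rec, a_inv, ids, VAR, tol=1e-24)
        x, nf = _dense_mme_solution(rec, a_inv, ids, VAR)
        np.testing.assert_allclose(res.ebv.values, x[nf:nf + len(ids)],
                                   atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_systems_match_dense(self, seed):
        # random pedigrees/records, system size <= 200 equations
        rng = np.random.default_rng(seed)
        n_cows = int(rng.integers(10, 40))
        cows = [f"c{i}" for i in range(n_cows)]
        rows = []
        for c in cows:
            for t in range(2, 2 + int(rng.integers(2, 7))):
                rows.append([c, t, f"{2000 + int(rng.integers(0, 3))}_1",
                             rng.uniform(1.5, 2.6),
                             rng.uniform(0, 1), f"g{rng.integers(0, 4)}",
                             rng.normal()])
        rec = pd.DataFrame(rows, columns=["cow", "parity", "year_season",
                                          "afc", "rh", "cg", "y"])
        a_inv = sp.identity(n_cows, format="csr")
        res = evaluation.solve_ssgblup(rec, a_inv, cows, VAR, tol=1e-24,
                                       max_iter=3000)
        x, nf = _dense_mme_solution(rec, a_inv, cows, VAR)
        np.testing.assert_allclose(res.ebv.values, x[nf:nf + n_cows],
                                   atol=1e-8)

    def test_phenotype_free_genotyped_animal_gets_information(self):
        # a record-free genotyped animal picks up parent-average plus
        # genomic deviation; checked against a dense solve
        ped = pd.DataFrame({"animal": [1, 2, 3, 4, 5, 6],
                            "sire": [0, 0, 1, 1, 1, 0],
                            "dam": [0, 0, 2, 2, 2, 0],
                            "sex": ["M", "F", "F", "F", "F", "F"],
                            "birth_date": ["1990-01-01"] * 2
                            + ["1995-01-01"] * 3 + ["1990-01-01"],
                            "herd": 1})
        rng = np.random.default_rng(0)
        rows = []
        for c in (3, 4, 6):
            for t in range(2, 6):
                rows.append([c, t, f"{1999 + int(rng.integers(0, 2))}_1",
                             2.0, 0.0, "g1", rng.normal()])
        rec = pd.DataFrame(rows, columns=["cow", "parity", "year_season",
                                          "afc", "rh", "cg", "y"])
        geno = simdata.simulate_genotypes(ped, 80, (0.2, 0.5), seed=1)
        _, a_inv, codes = relmat.compute_inbreeding_and_A_inverse(ped)
        gids = [3, 5]       # animal 5 has no records
        A22 = relmat.build_A22(codes, gids)
        G = relmat.blend_G(relmat.build_G(geno.loc[gids]).to_numpy(), A22)
        pos = codes.positions(gids)
        h_star = relmat.build_H_star(a_inv, pos, np.linalg.inv(G),
                                     np.linalg.inv(A22))
        res = evaluation.solve_ssgblup(rec, h_star, list(codes.ids), VAR,
                                       tol=1e-24)
        assert res.ebv.loc[5] != 0
        # dense oracle with the same H*
        Wf, _ = _fixed_design(rec)
        cows = sorted(rec["cow"].unique(), key=str)
        cgs = sorted(rec["cg"].unique(), key=str)
        W = _hstack_csc([Wf, _level_design(rec["cow"], list(codes.ids)),
                         _level_design(rec["cow"], cows),
                         _level_design(rec["cg"], cgs)])
        lam = sp.block_diag([
            sp.coo_matrix((Wf.shape[1],) * 2),
            h_star * (VAR["e"] / VAR["u"]),
            sp.identity(len(cows)) * (VAR["e"] / VAR["p"]),
            sp.identity(len(cgs)) * (VAR["e"] / VAR["c"])])
        C = (W.T @ W + lam).toarray()
        x = np.linalg.solve(C, W.T @ rec["y"].to_numpy())
        np.testing.assert_allclose(res.ebv.values,
                                   x[Wf.shape[1]:Wf.shape[1] + codes.n],
                                   atol=1e-8)

    def test_tolerance_clamped_with_warning(self):
        rec = pd.DataFrame({
            "cow": ["a", "b", "c"], "parity": 2, "year_season": "2000_1",
            "afc": 2.0, "rh": 0.0, "cg": "g", "y": [1.0, 0.0, -1.0]})
        with pytest.warns(UserWarning, match="clamped"):
            evaluation.solve_ssgblup(rec, sp.identity(3, format="csr"),
                                     ["a", "b", "c"], VAR, tol=1e-30)


class TestEbvRescaling:
    def test_affine_counts_fit_exactly(self):
        ebv = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        counts = 2.0 + 5.0 * ebv
        b0, b1, nc = evaluation.ebv_to_calves(ebv, counts)
        assert (b0, b1) == (pytest.approx(2.0), pytest.approx(5.0))
        pd.testing.assert_series_equal(nc, counts)

    def test_spearman_preserved_when_slope_positive(self):
        rng = np.random.default_rng(0)
        ebv = pd.Series(rng.normal(size=50))
        counts = 3 + 2 * ebv + rng.normal(0, 0.5, 50)
        _, b1, nc = evaluation.ebv_to_calves(ebv, counts)
        assert b1 > 0
        assert spearmanr(ebv, nc).statistic == pytest.approx(1.0)

    def test_positive_slope_on_genetic_signal(self, small_herd):
        # cows with more successes get larger EBV, so b1 > 0
        rec, _ = phenotypes.build_pl_dataset(small_herd.pedigree,
                                             small_herd.calvings,
                                             "2020-12-31")
        ped = relmat.truncate_pedigree(small_herd.pedigree,
                                       rec["cow"].unique(), 5)
        _, a_inv, codes = relmat.compute_inbreeding_and_A_inverse(ped)
        res = evaluation.solve_ssgblup(rec, a_inv, list(codes.ids), VAR,
                                       response="success")
        counts = evaluation.calf_counts(rec)
        _, b1, _ = evaluation.ebv_to_calves(res.ebv, counts)
        assert b1 > 0

    def test_zero_variance_rejected(self):
        ebv = pd.Series([0.5, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            evaluation.ebv_to_calves(ebv, pd.Series([1, 2],
                                                    index=["a", "b"]))


class TestEPD:
    def test_halving(self):
        nc = pd.Series([2.0, 0.0, -1.0])
        epd = evaluation.compute_epd(nc)
        assert list(epd) == [1.0, 0.0, -0.5]

    def test_ranking_preserved(self):
        nc = pd.Series(np.random.default_rng(0).normal(size=20))
        assert spearmanr(nc, evaluation.compute_epd(nc)).statistic == 1.0


class TestPrecorrect:
    def test_zero_fixed_effects_identity(self):
        counts = pd.Series([5.0, 3.0, 7.0], index=list("abc"))
        contrib = pd.Series(0.0, index=list("abc"))
        pd.testing.assert_series_equal(
            evaluation.precorrect_phenotypes(counts, contrib), counts)

    def test_constant_shift_cancels(self):
        counts = pd.Series([5.0, 3.0, 7.0], index=list("abc"))
        contrib = pd.Series(2.5, index=list("abc"))
        pd.testing.assert_series_equal(
            evaluation.precorrect_phenotypes(counts, contrib), counts)

    def test_simulated_afc_effect_removed(self):
        rng = np.random.default_rng(0)
        n = 400
        afc = rng.uniform(1.5, 2.67, n)
        base = rng.normal(5, 1, n)
        beta = 3.0
        counts = pd.Series(base + beta * afc, index=range(n))
        contrib = pd.Series(beta * afc, index=range(n))
        adj = evaluation.precorrect_phenotypes(counts, contrib)
        assert abs(pearsonr(adj, afc).statistic) < 0.1
        assert adj.mean() == pytest.approx(counts.mean())

    def test_missing_covariates_dropped(self):
        counts = pd.Series([5.0, 3.0], index=["a", "b"])
        contrib = pd.Series([1.0], index=["a"])
        adj = evaluation.precorrect_phenotypes(counts, contrib)
        assert list(adj.index) == ["a"]


class TestCompareModels:
    def test_identical_rankings(self):
        ebv = pd.Series(np.arange(200, dtype=float),
                        index=[f"a{i}" for i in range(200)])
        rho, ov = evaluation.compare_models(ebv, ebv * 2 + 1)
        assert rho == pytest.approx(1.0)
        assert ov == 100.0

    def test_reversed_rankings(self):
        ebv = pd.Series(np.arange(400, dtype=float),
                        index=[f"a{i}" for i in range(400)])
        rho, ov = evaluation.compare_models(ebv, -ebv)
        assert rho == pytest.approx(-1.0)
        assert ov == 0.0

    def test_printed_counts_give_77_percent(self):
        assert round(evaluation.overlap_percentage(9821, 12746)) == 77

    def test_mismatched_sets_error(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError, match="orphans"):
            evaluation.compare_models(a, b)


@pytest.fixture(scope="module")
def herd():
    cfg = simdata.SimConfig(n_founders_per_breed=60, n_generations=3,
                            seed=9, start_year=1990, data_end_year=2012,
                            et_rate=0.0, twin_rate=0.0,
                            liability_scale=4.0)
    return simdata.generate(cfg)


class TestForwardValidation:
    def test_self_comparison_trivial(self, herd):
        rep = evaluation.forward_validate(
            herd.pedigree, herd.calvings, VAR, 1999, [2012], 2012)
        row = rep.iloc[0]
        assert row["bias"] == pytest.approx(1.0, abs=1e-6)

    def test_correlations_rise_with_truncation_year(self, herd):
        rep = evaluation.forward_validate(
            herd.pedigree, herd.calvings, VAR, 1999,
            [1999, 2003, 2006, 2009], 2012)
        r = rep["r_precorrected"].dropna()
        assert len(r) == 4
        assert r.iloc[-1] > r.iloc[0]
        assert spearmanr(rep["truncation_year"][r.index],
                         r).statistic > 0

    def test_affine_invariance_of_correlations(self, herd):
        # Pearson correlation is invariant to the EBV -> EBV_NC map
        rep1 = evaluation.forward_validate(
            herd.pedigree, herd.calvings, VAR, 1999, [2006], 2012)
        res, rec = evaluation.run_evaluation(
            herd.pedigree, herd.calvings, "2012-12-31", VAR)
        counts = evaluation.calf_counts(rec)
        byear = pd.to_datetime(herd.pedigree.set_index("animal")
                               ["birth_date"]).dt.year
        val = [c for c in counts.index if byear.get(c) == 1999]
        # raw-EBV correlation from a manual truncated run
        cut = pd.Timestamp("2006-12-31")
        ped_t = herd.pedigree[pd.to_datetime(
            herd.pedigree["birth_date"]) <= cut].copy()
        keep = set(ped_t["animal"])
        for col in ("sire", "dam"):
            ped_t.loc[~ped_t[col].isin(keep), col] = 0
        cal_t = herd.calvings[
            (pd.to_datetime(herd.calvings["calf_birth_date"]) <= cut)
            & herd.calvings["dam"].isin(keep)]
        res_t, _ = evaluation.run_evaluation(ped_t, cal_t, cut, VAR,
                                             keep_animals=val)
        avail = [c for c in val if c in res_t.ebv.index]
        r_raw = pearsonr(res_t.ebv.loc[avail], counts.loc[avail]).statistic
        assert rep1["r_observed"].iloc[0] == pytest.approx(r_raw, abs=1e-6)


class TestPedigreeGenomicConsistency:
    def test_uninformative_genotypes_equal_pedigree_only(self, small_herd):
        rec, _ = phenotypes.build_pl_dataset(small_herd.pedigree,
                                             small_herd.calvings,
                                             "2020-12-31")
        ped = relmat.truncate_pedigree(small_herd.pedigree,
                                       rec["cow"].unique(), 5)
        mono = pd.DataFrame(
            2.0, index=list(ped["animal"][:10]), columns=["s1", "s2"])
        with pytest.warns(UserWarning):
            rel_g = relmat.build_relationships(ped, mono, use_groups=False)
        rel_p = relmat.build_relationships(ped, None, use_groups=False)
        r1 = evaluation.solve_ssgblup(rec, rel_g.h_star,
                                      list(rel_g.codes.ids), VAR,
                                      response="success", tol=1e-24)
        r2 = evaluation.solve_ssgblup(rec, rel_p.h_star,
                                      list(rel_p.codes.ids), VAR,
                                      response="success", tol=1e-24)
        pd.testing.assert_series_equal(r1.ebv.sort_index(),
                                       r2.ebv.sort_index())


class TestRRMSolver:
    def test_rrm_matches_dense_kron_oracle(self):
        rng = np.random.default_rng(3)
        cows = [f"c{i}" for i in range(12)]
        rows = []
        for c in cows:
            for t in range(2, 9):
                rows.append([c, t, f"{2000 + int(rng.integers(3))}_1",
                             rng.uniform(1.5, 2.6), rng.uniform(0, 1),
                             f"g{rng.integers(3)}", rng.normal()])
        rec = pd.DataFrame(rows, columns=["cow", "parity", "year_season",
                                          "afc", "rh", "cg", "y"])
        a_inv = sp.identity(len(cows), format="csr")
        var = {"G_u": np.array([[0.068, -0.007], [-0.007, 0.0009]]),
               "G_p": np.array([[0.185, -0.023], [-0.023, 0.0035]]),
               "G_c": np.array([[0.084, -0.010], [-0.010, 0.0031]]),
               "e": 0.059}
        res = evaluation.solve_ssgblup(rec, a_inv, cows, var, model="rrm",
                                       tol=1e-24, max_iter=5000)
        # dense oracle
        Wf, _ = _fixed_design(rec)
        t = rec["parity"].to_numpy(float)

        def pair(values, levels):
            base = _level_design(values, levels).tocoo().toarray()
            out = np.zeros((len(values), 2 * len(levels)))
            out[:, 0::2] = base
            out[:, 1::2] = base * t[:, None]
            return out

        cgs = sorted(rec["cg"].unique(), key=str)
        W = np.hstack([Wf.toarray(), pair(rec["cow"], cows),
                       pair(rec["cow"], cows), pair(rec["cg"], cgs)])
        lam = np.zeros((W.shape[1],) * 2)
        nf = Wf.shape[1]
        ve = var["e"]
        lam[nf:nf + 24, nf:nf + 24] = np.kron(
            np.eye(12), np.linalg.inv(var["G_u"])) * ve
        lam[nf + 24:nf + 48, nf + 24:nf + 48] = np.kron(
            np.eye(12), np.linalg.inv(var["G_p"])) * ve
        lam[nf + 48:, nf + 48:] = np.kron(
            np.eye(len(cgs)), np.linalg.inv(var["G_c"])) * ve
        C = W.T @ W + lam
        x = np.linalg.solve(C, W.T @ rec["y"].to_numpy())
        blk = x[nf:nf + 24].reshape(12, 2)
        np.testing.assert_allclose(res.ebv_intercept.values, blk[:, 0],
                                   atol=1e-8)
        np.testing.assert_allclose(res.ebv_slope.values, blk[:, 1],
                                   atol=1e-8)
        # EBV at parity 8 is intercept + 8 * slope
        np.testing.assert_allclose(res.ebv.values,
                                   blk[:, 0] + 8 * blk[:, 1], atol=1e-8)
        np.testing.assert_allclose(res.ebv_at(8.0).values, res.ebv.values)
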