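"""Mixed-model equations, BLUP solving, and REML."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize

import ssblend.model as model
from ssblend import pedigree as pedlib
from ssblend.model import (
    ModelSpec,
    VarianceComponents,
    build_design,
    genetic_correlations,
    heritability,
    reml,
    solve_mme,
)
from ssblend.pedigree import Pedigree, pedigree_from_frame
from ssblend.simulate import SimConfig, simulate


def unrelated_pedigree(ids):
    n = len(ids)
    return Pedigree(ids=np.array(ids, dtype=object),
                    sire=np.full(n, -1), dam=np.full(n, -1))


def vc1(vg, ve, trait="bw"):
    return VarianceComponents(genetic=[[vg]], residual=[[ve]], traits=(trait,))


class TestBuildDesign:
    def test_single_common_group_x_is_ones(self):
        ped = unrelated_pedigree(["a", "b", "c"])
        ph = pd.DataFrame({"animal": ["a", "b", "c"], "hatch_wy": ["h1"] * 3,
                           "sex": ["M"] * 3, "bw": [1.0, 2.0, 3.0]})
        d = build_design(ph, ped, ModelSpec(traits=("bw",)))
        X = d.W.toarray()[:, : d.n_fixed]
        assert d.n_fixed == 1
        assert X == pytest.approx(np.ones((3, 1)))

    def test_sex_effect_only_for_sex_traits(self):
        ped = unrelated_pedigree(["a", "b"])
        ph = pd.DataFrame({"animal": ["a", "b"], "hatch_wy": ["h1", "h1"],
                           "sex": ["F", "M"], "bw": [1.0, 2.0],
                           "fcr": [2.5, 2.6]})
        d = build_design(ph, ped, ModelSpec(traits=("bw", "fcr")))
        # bw: hatch level + one sex contrast; fcr: hatch level only
        assert [e for e, _ in d.fixed_labels["bw"]] == ["hatch_wy", "sex"]
        assert [e for e, _ in d.fixed_labels["fcr"]] == ["hatch_wy"]

    def test_missing_trait_excluded_from_pattern(self):
        ped = unrelated_pedigree(["a", "b"])
        ph = pd.DataFrame({"animal": ["a", "b"], "hatch_wy": ["h1", "h1"],
                           "sex": ["M", "M"], "bw": [1.0, 2.0],
                           "fcr": [np.nan, 2.6]})
        d = build_design(ph, ped, ModelSpec(traits=("bw", "fcr")))
        patterns = {tuple(obs) for obs in d.anim_obs}
        assert patterns == {(0,), (0, 1)}
        assert d.n_records == 3


class TestSolveMME:
    def test_matches_dense_gls_oracle(self):
        # unrelated animals, mean-only model: the MME reduce to ridge
        # regression with lambda = ve/vg; build the oracle by hand
        ped = unrelated_pedigree(["a", "b", "c"])
        y = np.array([1.0, 2.0, 4.0])
        ph = pd.DataFrame({"animal": ped.ids, "hatch_wy": ["h"] * 3,
                           "sex": ["M"] * 3, "bw": y})
        d = build_design(ph, ped, ModelSpec(traits=("bw",)))
        vg, ve = 2.0, 3.0
        fit = solve_mme(d, sp.eye(3).tocsr(), vc1(vg, ve))
        X = np.ones((3, 1))
        lam = ve / vg
        C = np.block([[X.T @ X, X.T], [X, np.eye(3) + lam * np.eye(3)]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ y, y]))
        assert fit.fixed_solutions["bw"].iloc[0] == pytest.approx(sol[0])
        assert fit.breeding_values["bw"].to_numpy() == pytest.approx(sol[1:])

    def test_unphenotyped_offspring_gets_parent_average(self):
        ped = pedigree_from_frame(pd.DataFrame({
            "animal": ["s", "d", "o"], "sire": ["0", "0", "s"],
            "dam": ["0", "0", "d"],
        }))
        ph = pd.DataFrame({"animal": ["s", "d"], "hatch_wy": ["h", "h"],
                           "sex": ["M", "F"], "bw": [3.0, 5.0]})
        fit = solve_mme(build_design(ph, ped, ModelSpec(traits=("bw",))),
                        pedlib.a_inverse(ped), vc1(1.0, 1.0))
        bv = fit.breeding_values["bw"]
        assert bv["o"] == pytest.approx(0.5 * (bv["s"] + bv["d"]))

    def test_high_heritability_limit_recovers_adjusted_phenotypes(self):
        ped = unrelated_pedigree(["a", "b", "c", "d"])
        y = np.array([1.0, -2.0, 0.5, 0.5])
        ph = pd.DataFrame({"animal": ped.ids, "hatch_wy": ["h"] * 4,
                           "sex": ["M"] * 4, "bw": y})
        d = build_design(ph, ped, ModelSpec(traits=("bw",)))
        fit = solve_mme(d, sp.eye(4).tocsr(), vc1(1.0, 1e-8))
        mu = fit.fixed_solutions["bw"].iloc[0]
        assert fit.breeding_values["bw"].to_numpy() == pytest.approx(
            y - mu, abs=1e-5
        )

    def test_pcg_agrees_with_direct(self, small_sim):
        ph = small_sim.phenotypes
        ped = small_sim.pedigree
        d = build_design(ph, ped, ModelSpec(traits=("bw",)))
        Ainv = pedlib.a_inverse(ped)
        vc = vc1(9.9, 18.4)
        direct = solve_mme(d, Ainv, vc, method="direct")
        pcg = solve_mme(d, Ainv, vc, method="pcg", tol=1e-12)
        u1 = direct.breeding_values["bw"].to_numpy()
        u2 = pcg.breeding_values["bw"].to_numpy()
        assert np.abs(u1 - u2).max() / np.abs(u1).max() < 1e-6


class TestREML:
    def _toy_design(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        sires = [f"s{i}" for i in range(8)]
        rows = {"animal": [], "sire": [], "dam": []}
        for s in sires:
            rows["animal"].append(s)
            rows["sire"].append("0")
            rows["dam"].append("0")
        for i in range(n):
            rows["animal"].append(f"x{i}")
            rows["sire"].append(sires[i % 8])
            rows["dam"].append("0")
        ped = pedigree_from_frame(pd.DataFrame(rows))
        u = np.zeros(ped.n)
        A = pedlib.a_matrix(ped)
        u = np.linalg.cholesky(A) @ rng.standard_normal(ped.n)
        ph = pd.DataFrame({
            "animal": [f"x{i}" for i in range(n)],
            "hatch_wy": ["h"] * n, "sex": ["M"] * n,
            "bw": [u[ped.index_of([f"x{i}"])[0]] + rng.normal(0, 1.2)
                   for i in range(n)],
        })
        return ped, build_design(ph, ped, ModelSpec(traits=("bw",)))

    def test_em_fixed_point_matches_likelihood_grid(self):
        """EM/AI REML lands on the maximizer of the restricted likelihood."""
        ped, d = self._toy_design()
        Ainv = pedlib.a_inverse(ped)
        vc = reml(d, Ainv, tol=1e-10)

        A = pedlib.a_matrix(ped)
        W = d.W.toarray()
        X, Z = W[:, : d.n_fixed], W[:, d.n_fixed:]
        y = d.y
        ZAZ = Z @ A @ Z.T

        def negll(theta):
            vg, ve = np.exp(theta)
            V = vg * ZAZ + ve * np.eye(len(y))
            Vi_y = np.linalg.solve(V, y)
            Vi_X = np.linalg.solve(V, X)
            XVX = X.T @ Vi_X
            beta = np.linalg.solve(XVX, X.T @ Vi_y)
            r = y - X @ beta
            return 0.5 * (np.linalg.slogdet(V)[1]
                          + np.linalg.slogdet(XVX)[1]
                          + r @ np.linalg.solve(V, r))

        res = minimize(negll, np.log([1.0, 1.0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        vg, ve = np.exp(res.x)
        assert vc.genetic[0, 0] == pytest.approx(vg, rel=1e-4)
        assert vc.residual[0, 0] == pytest.approx(ve, rel=1e-4)

    def test_em_and_ai_agree(self):
        ped, d = self._toy_design(seed=1)
        Ainv = pedlib.a_inverse(ped)
        ai = reml(d, Ainv, method="ai", tol=1e-10)
        em = reml(d, Ainv, method="em", tol=1e-10, max_iter=3000)
        # EM converges slowly near the optimum; agreement at ~1% is as
        # close as its 3000-iteration budget gets on this toy
        assert ai.genetic[0, 0] == pytest.approx(em.genetic[0, 0], rel=1e-2)
        assert ai.residual[0, 0] == pytest.approx(em.residual[0, 0], rel=1e-2)

    def test_delta_method_ses_are_finite_and_positive(self):
        ped, d = self._toy_design(seed=3)
        vc = reml(d, pedlib.a_inverse(ped))
        se = model.heritability_se(vc, "bw")
        assert 0 < se < 1.0

    def test_zero_signal_gives_near_zero_h2(self):
        cfg = SimConfig(seed=31, traits=("bw",), h2={"bw": 0.001},
                        generations=6, n_sires=12, n_dams=48,
                        offspring_per_dam=4, n_markers=10, genotyped_share=0.0)
        out = simulate(cfg)
        ph = out.phenotypes
        ped = out.pedigree.prune(ph["animal"][ph["bw"].notna()])
        d = build_design(ph, ped, ModelSpec(traits=("bw",)))
        vc = reml(d, pedlib.a_inverse(ped))
        assert heritability(vc, "bw") < 0.05

    def test_scale_invariance(self):
        ped, d = self._toy_design(seed=0)
        Ainv = pedlib.a_inverse(ped)
        vc = reml(d, Ainv, tol=1e-10)
        c = 7.0
        d2 = build_design(
            pd.DataFrame({
                "animal": ped.ids[d.rec_animal],
                "hatch_wy": ["h"] * len(d.y), "sex": ["M"] * len(d.y),
                "bw": c * d.y,
            }), ped, ModelSpec(traits=("bw",)))
        vc2 = reml(d2, Ainv, tol=1e-10)
        assert vc2.genetic[0, 0] == pytest.approx(c**2 * vc.genetic[0, 0],
                                                  rel=1e-4)
        assert vc2.residual[0, 0] == pytest.approx(c**2 * vc.residual[0, 0],
                                                   rel=1e-4)

    def test_canonical_path_matches_general_path(self, small_sim):
        """The equal-design fast path equals the generic dense path."""
        ph = small_sim.phenotypes
        ped = small_sim.pedigree.prune(ph["animal"][ph["bw"].notna()])
        d1 = build_design(ph, ped, ModelSpec(traits=("bw", "ws")))
        d2 = build_design(ph, ped, ModelSpec(traits=("bw", "ws")))
        d2._canonical_ok = False
        assert model._canonical_ok(d1)
        Ainv = pedlib.a_inverse(ped).tocsr()
        G0 = np.array([[9.0, -0.9], [-0.9, 0.2]])
        R0 = np.array([[18.0, -0.6], [-0.6, 0.55]])
        s1 = model._RemlState(d1, Ainv, G0, R0)
        s2 = model._RemlState(d2, Ainv, G0, R0)
        assert np.abs(s1.sol - s2.sol).max() < 1e-8
        t1, t2 = s1.em_matrices(), s2.em_matrices()
        assert t1[0] == pytest.approx(t2[0], abs=1e-9)
        assert t1[1] == pytest.approx(t2[1], abs=1e-9)


class TestSummaries:
    def test_heritability_values(self):
        vc = vc1(25.0, 75.0)
        assert heritability(vc, "bw") == pytest.approx(0.25)
        assert heritability(vc1(5.0, 0.0), "bw") == pytest.approx(1.0)
        assert heritability(vc1(0.0, 4.0), "bw") == pytest.approx(0.0)

    def test_genetic_correlations(self):
        vc = VarianceComponents(
            genetic=[[1.0, 0.68], [0.68, 1.0]],
            residual=np.eye(2), traits=("fcr", "rfi"))
        corr = genetic_correlations(vc)
        assert corr[0, 1] == pytest.approx(0.68)
        assert np.allclose(np.diag(corr), 1.0)
        diagonal = VarianceComponents(genetic=np.diag([2.0, 3.0]),
                                      residual=np.eye(2), traits=("a", "b"))
        assert genetic_correlations(diagonal) == pytest.approx(np.eye(2))
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)
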