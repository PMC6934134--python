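"""Synthetic population generator: structure, laws, and determinism."""

import numpy as np
import pandas as pd
import pytest

from ssblend import genomic, pedigree as pedlib
from ssblend.pedigree import UNKNOWN
from ssblend.simulate import (
    SimConfig,
    founder_frequencies,
    gene_drop,
    simulate,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)


def small_cfg(**kw):
    base = dict(seed=5, generations=4, n_sires=8, n_dams=24,
                offspring_per_dam=3, n_markers=300, genotyped_share=0.5)
    base.update(kw)
    return SimConfig(**base)


class TestPedigreeGeneration:
    def test_one_generation_founders_only(self):
        ped = simulate_pedigree(small_cfg(generations=0))
        assert ped.founders.all()

    def test_default_has_ten_generations(self):
        cfg = SimConfig(seed=1, n_markers=10)
        ped = simulate_pedigree(cfg)
        years = {c.split("-")[0] for c in ped.cohort}
        assert len(years) == 11  # founder year + 10 hatch years

    def test_same_seed_identical(self):
        a = simulate(small_cfg())
        b = simulate(small_cfg())
        assert list(a.pedigree.ids) == list(b.pedigree.ids)
        assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_truncation_selection_raises_mean_bv(self):
        random_out = simulate(small_cfg(traits=("bw",), n_markers=10))
        sel_out = simulate(small_cfg(traits=("bw",), n_markers=10,
                                     selection="truncation",
                                     selection_trait="bw"))
        gen_r = random_out.pedigree.cohort
        last = max(c for c in gen_r)
        mean_random = random_out.true_breeding_values.loc[
            random_out.pedigree.ids[gen_r == last], "bw"].mean()
        gen_s = sel_out.pedigree.cohort
        last_s = max(c for c in gen_s)
        mean_sel = sel_out.true_breeding_values.loc[
            sel_out.pedigree.ids[gen_s == last_s], "bw"].mean()
        assert mean_sel > mean_random + 1.0


class TestGeneDrop:
    def test_fixed_founder_allele(self):
        cfg = small_cfg(n_markers=5)
        rng = np.random.default_rng(0)
        ped = simulate_pedigree(cfg, rng)
        codes = gene_drop(ped, np.ones(5), rng)
        assert np.all(codes == 2)

    def test_founder_frequencies_match_law(self):
        cfg = small_cfg(n_markers=4000)
        rng = np.random.default_rng(1)
        p = founder_frequencies(cfg, rng)
        lo, hi = cfg.founder_freq_range
        assert p.mean() == pytest.approx((lo + hi) / 2, abs=0.02)

    def test_full_sib_genotype_correlation(self):
        # two founders, many full-sib offspring: correlation of centered
        # codes across markers approaches the additive relationship 0.5
        rows = {"animal": ["s", "d"], "sire": ["0", "0"], "dam": ["0", "0"]}
        for i in range(60):
            rows["animal"].append(f"o{i}")
            rows["sire"].append("s")
            rows["dam"].append("d")
        ped = pedlib.pedigree_from_frame(pd.DataFrame(rows))
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, 3000)
        codes = gene_drop(ped, p, rng)
        Z = (codes - 2 * p) / np.sqrt(2 * p * (1 - p))
        off = ped.index_of([f"o{i}" for i in range(60)])
        corr = np.corrcoef(Z[off])
        upper = corr[np.triu_indices(60, 1)]
        assert upper.mean() == pytest.approx(0.5, abs=0.03)


class TestBreedingValues:
    def test_founder_variance_matches_config(self):
        cfg = SimConfig(seed=3, traits=("bw",), generations=0, n_sires=4000,
                        n_dams=4000, n_markers=10)
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, cfg)
        var = bv["bw"].to_numpy().var()
        truth = cfg.genetic_cov()[0, 0]
        assert var == pytest.approx(truth, rel=0.05)

    def test_diagonal_truth_gives_uncorrelated_founder_bvs(self):
        cfg = SimConfig(seed=4, traits=("bw", "ws"),
                        genetic_corr={("bw", "ws"): 0.0},
                        generations=0, n_sires=2000, n_dams=2000, n_markers=10)
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, cfg)
        corr = np.corrcoef(bv["bw"], bv["ws"])[0, 1]
        assert abs(corr) < 0.05

    def test_parent_offspring_covariance_half_genetic_variance(self):
        # many independent trios: cov(parent BV, offspring BV) = sigma_g^2 / 2
        rows = {"animal": [], "sire": [], "dam": []}
        n_trio = 4000
        for i in range(n_trio):
            rows["animal"] += [f"s{i}", f"d{i}", f"o{i}"]
            rows["sire"] += ["0", "0", f"s{i}"]
            rows["dam"] += ["0", "0", f"d{i}"]
        ped = pedlib.pedigree_from_frame(pd.DataFrame(rows))
        cfg = SimConfig(seed=6, traits=("bw",), n_markers=10)
        bv = simulate_breeding_values(ped, cfg)
        s = bv.loc[[f"s{i}" for i in range(n_trio)], "bw"].to_numpy()
        o = bv.loc[[f"o{i}" for i in range(n_trio)], "bw"].to_numpy()
        cov = np.cov(s, o)[0, 1]
        truth = cfg.genetic_cov()[0, 0]
        assert cov == pytest.approx(0.5 * truth, rel=0.15)

    def test_marker_mode_founder_variance(self):
        cfg = SimConfig(seed=7, traits=("bw",), generations=0, n_sires=1500,
                        n_dams=1500, n_markers=1500, bv_mode="marker")
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, cfg)
        truth = cfg.genetic_cov()[0, 0]
        assert bv["bw"].to_numpy().var() == pytest.approx(truth, rel=0.15)


class TestPhenotypes:
    def test_residual_free_phenotypes_equal_bv_plus_mean(self):
        cfg = small_cfg(traits=("bw",), h2={"bw": 0.999},
                        hatch_sd_frac=0.0, sex_effects={"bw": 0.0})
        out = simulate(cfg)
        obs = out.phenotypes["bw"].notna()
        got = out.phenotypes.loc[obs, "bw"].to_numpy()
        want = (out.true_breeding_values.loc[
            out.phenotypes.loc[obs, "animal"], "bw"].to_numpy() + 17.50)
        assert got == pytest.approx(want, abs=0.6)

    def test_sex_limited_recording(self, small_sim):
        ph = small_sim.phenotypes.merge(
            pd.DataFrame({"animal": small_sim.pedigree.ids,
                          "is_f": small_sim.pedigree.sex == "F"}), on="animal")
        females = ph[ph["is_f"]]
        assert females[["fcr", "rfi", "bmy"]].isna().all().all()
        non_founder_males = ph[(~ph["is_f"]) & ph["bw"].notna()]
        assert non_founder_males[["fcr", "rfi", "bmy"]].notna().all().all()

    def test_walking_score_range_and_mean(self, small_sim):
        ws = small_sim.phenotypes["ws"].dropna()
        assert ws.isin([1, 2, 3, 4, 5, 6]).all()
        assert ws.mean() == pytest.approx(2.10, abs=0.3)

    def test_bw_mean_near_target(self, small_sim):
        # genetic drift from the small founder base shifts the raw mean, so
        # judge the phenotype law net of the true breeding values
        ph = small_sim.phenotypes.dropna(subset=["bw"])
        u = small_sim.true_breeding_values.loc[ph["animal"], "bw"].to_numpy()
        env = ph["bw"].to_numpy() - u
        # residual + hatch-cohort noise around the configured mean
        assert env.mean() == pytest.approx(17.50, abs=1.0)


class TestRoundTrip:
    def test_outputs_parse_and_survive_qc(self, small_sim, tmp_path):
        small_sim.write(tmp_path)
        ped = pedlib.read_pedigree(tmp_path / "pedigree.csv")
        assert ped.n == small_sim.pedigree.n
        geno = genomic.read_genotypes(tmp_path / "genotypes.tsv", dialect="tsv")
        filtered, report = genomic.qc_filter(geno)
        assert filtered.n_markers >= 0.95 * geno.n_markers
        assert (tmp_path / "truths.json").exists()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = small_cfg(genetic_corr={("fcr", "rfi"): 0.5})
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        back = SimConfig.from_yaml(path)
        assert back == cfg
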