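"""Synthetic breeding-population generator.

Generates a discrete-generation pedigree of hatch-week cohorts, gene-drops
SNP genotypes for a configurable share of animals, draws true breeding
values either from the pedigree (``u ~ N(0, A (x) R)`` via recursive
Mendelian sampling) or from marker effects, and emits multi-trait
phenotypes ``y = mean + hatch + sex + u + e`` with sex-limited recording
(feed traits and breast meat yield on males only) and a 1-6 ordinal
walking score obtained by discretizing a latent Gaussian.

Default trait means, standard deviations, heritabilities, and genetic and
residual correlations emulate a commercial turkey sire-line data set (two
feed-efficiency traits, body weight, breast meat yield, walking score)
at a desk scale of roughly 5,000 phenotyped birds over 10 generations.
Everything is deterministic given the mandatory seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

import ssblend.pedigree as pedlib
from ssblend.genomic import GenotypeMatrix
from ssblend.model import VarianceComponents
from ssblend.pedigree import UNKNOWN, Pedigree, inbreeding

logger = logging.getLogger(__name__)

#: Canonical trait order.
ALL_TRAITS = ("fcr", "rfi", "bw", "bmy", "ws")

#: Default per-trait phenotype law: mean, phenotypic SD, heritability,
#: male-only recording, additive sex effect (added for males, subtracted
#: for females), ordinal discretization.
TRAIT_DEFAULTS = {
    "fcr": {"mean": 2.58, "sd": 0.39, "h2": 0.14, "male_only": True,
            "sex_effect": 0.0, "ordinal": False},
    "rfi": {"mean": 0.0, "sd": 2.51, "h2": 0.12, "male_only": True,
            "sex_effect": 0.0, "ordinal": False},
    "bw": {"mean": 17.50, "sd": 5.32, "h2": 0.35, "male_only": False,
           "sex_effect": 2.0, "ordinal": False},
    "bmy": {"mean": 24.37, "sd": 2.33, "h2": 0.27, "male_only": True,
            "sex_effect": 0.0, "ordinal": False},
    "ws": {"mean": 2.10, "sd": 0.86, "h2": 0.24, "male_only": False,
           "sex_effect": -0.10, "ordinal": True},
}

#: Default genetic correlations (upper triangle, canonical trait order).
GENETIC_CORR_DEFAULT = {
    ("fcr", "rfi"): 0.68, ("fcr", "bw"): 0.19, ("fcr", "bmy"): -0.05,
    ("fcr", "ws"): -0.09, ("rfi", "bw"): 0.13, ("rfi", "bmy"): -0.13,
    ("rfi", "ws"): 0.08, ("bw", "bmy"): 0.16, ("bw", "ws"): -0.47,
    ("bmy", "ws"): -0.35,
}

#: Default residual correlations.
RESIDUAL_CORR_DEFAULT = {
    ("fcr", "rfi"): 0.23, ("fcr", "bw"): -0.39, ("fcr", "bmy"): -0.10,
    ("fcr", "ws"): 0.03, ("rfi", "bw"): -0.17, ("rfi", "bmy"): -0.07,
    ("rfi", "ws"): 0.05, ("bw", "bmy"): 0.19, ("bw", "ws"): -0.15,
    ("bmy", "ws"): -0.06,
}


def _corr_matrix(traits, overrides, table) -> np.ndarray:
    t = len(traits)
    C = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            key = (traits[i], traits[j])
            val = table.get(key, table.get((traits[j], traits[i]), 0.0))
            if overrides and key in overrides:
                val = overrides[key]
            elif overrides and (traits[j], traits[i]) in overrides:
                val = overrides[(traits[j], traits[i])]
            C[i, j] = C[j, i] = val
    return C


@dataclass
class SimConfig:
    """Configuration of the synthetic breeding population.

    Population structure: ``generations`` non-founder generations, each
    produced by ``n_sires`` males mated at random to ``n_dams`` females
    selected from the previous generation, ``offspring_per_dam`` offspring
    per dam (~50/50 sex ratio), cohorts split over
    ``hatch_weeks_per_generation`` hatch week-year labels per generation.

    Genetics: ``n_markers`` biallelic autosomal SNPs, founder allele
    frequencies from a uniform or beta law; true breeding values in
    ``bv_mode`` "pedigree" (exact ``A (x) R`` covariance) or "marker"
    (sum of marker effects, for single-step recovery studies).

    Trait laws default to :data:`TRAIT_DEFAULTS` /
    :data:`GENETIC_CORR_DEFAULT` / :data:`RESIDUAL_CORR_DEFAULT`; ``h2``,
    ``means``, ``sds`` and the correlation override dicts replace
    individual entries.
    """

    seed: int
    traits: tuple = ALL_TRAITS
    generations: int = 10
    n_sires: int = 25
    n_dams: int = 100
    offspring_per_dam: int = 5
    hatch_weeks_per_generation: int = 3
    first_year: int = 2009
    n_markers: int = 2000
    founder_freq_law: str = "uniform"
    founder_freq_range: tuple = (0.1, 0.9)
    founder_freq_beta: tuple = (2.0, 2.0)
    genotyped_share: float | dict = 0.4
    genotyped_sex: str | None = None
    bv_mode: str = "pedigree"
    h2: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    sex_effects: dict = field(default_factory=dict)
    genetic_corr: dict = field(default_factory=dict)
    residual_corr: dict = field(default_factory=dict)
    hatch_sd_frac: float = 0.25
    selection: str = "random"
    selection_trait: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.traits = tuple(t.lower() for t in self.traits)
        unknown = set(self.traits) - set(ALL_TRAITS)
        if unknown:
            raise ValueError(f"unknown traits: {sorted(unknown)}")
        shares = (self.genotyped_share.values()
                  if isinstance(self.genotyped_share, dict)
                  else [self.genotyped_share])
        if any(not (0.0 <= s <= 1.0) for s in shares):
            raise ValueError("genotyped_share must be in [0, 1]")
        if self.bv_mode not in ("pedigree", "marker"):
            raise ValueError(f"unknown bv_mode {self.bv_mode!r}")
        if self.selection not in ("random", "truncation"):
            raise ValueError(f"unknown selection {self.selection!r}")
        G = self.genetic_cov()
        E = self.residual_cov()
        for name, M in (("genetic", G), ("residual", E)):
            if np.any(np.linalg.eigvalsh(M) <= 0):
                raise ValueError(f"{name} covariance truth is not positive definite")

    # -- trait laws -------------------------------------------------------

    def trait_param(self, trait, key):
        override = {"h2": self.h2, "mean": self.means, "sd": self.sds,
                    "sex_effect": self.sex_effects}.get(key)
        if override and trait in override:
            return override[trait]
        return TRAIT_DEFAULTS[trait][key]

    def genetic_cov(self) -> np.ndarray:
        sd_g = np.array([
            np.sqrt(self.trait_param(t, "h2")) * self.trait_param(t, "sd")
            for t in self.traits
        ])
        C = _corr_matrix(self.traits, self.genetic_corr, GENETIC_CORR_DEFAULT)
        return C * np.outer(sd_g, sd_g)

    def residual_cov(self) -> np.ndarray:
        sd_e = np.array([
            np.sqrt(1.0 - self.trait_param(t, "h2")) * self.trait_param(t, "sd")
            for t in self.traits
        ])
        C = _corr_matrix(self.traits, self.residual_corr, RESIDUAL_CORR_DEFAULT)
        return C * np.outer(sd_e, sd_e)

    def true_vc(self) -> VarianceComponents:
        return VarianceComponents(genetic=self.genetic_cov(),
                                  residual=self.residual_cov(),
                                  traits=self.traits)

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["traits"] = list(d["traits"])
        for key in ("genetic_corr", "residual_corr"):
            d[key] = {f"{a}:{b}": v for (a, b), v in d[key].items()}
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "SimConfig":
        try:
            with open(path_or_text) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(path_or_text)
        for key in ("genetic_corr", "residual_corr"):
            if key in d and d[key]:
                d[key] = {tuple(k.split(":")): v for k, v in d[key].items()}
        for key in ("traits", "founder_freq_range", "founder_freq_beta"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimOutput:
    """Everything a simulation emits, aligned by animal ID."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix | None
    phenotypes: pd.DataFrame
    true_breeding_values: pd.DataFrame
    true_vc: VarianceComponents
    config: SimConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.write_csv(out / "pedigree.csv")
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        if self.genotypes is not None:
            self.genotypes.write_tsv(out / "genotypes.tsv")
        self.true_breeding_values.reset_index(names="animal").to_csv(
            out / "true_breeding_values.csv", index=False
        )
        with open(out / "truths.json", "w") as fh:
            json.dump(
                {
                    "traits": list(self.config.traits),
                    "genetic_cov": self.true_vc.genetic.tolist(),
                    "residual_cov": self.true_vc.residual.tolist(),
                    "h2": {
                        t: self.config.trait_param(t, "h2")
                        for t in self.config.traits
                    },
                },
                fh, indent=2,
            )
        self.config.to_yaml(out / "sim_config.yaml")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None,
                      _return_bv: bool = False):
    """Simulate a discrete-generation pedigree with hatch-week cohorts.

    Founders (generation 0) are ``n_sires`` males and ``n_dams`` females.
    Each later generation re-selects parents from the previous one and
    produces ``n_dams * offspring_per_dam`` offspring assigned to
    hatch-week cohorts within the generation's year.

    With ``cfg.selection == "truncation"`` parents are the highest
    true-breeding-value candidates for ``cfg.selection_trait``; breeding
    values (pedigree mode, exact ``A (x) R`` covariance with incremental
    inbreeding) are co-simulated and returned when ``_return_bv`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    truncation = cfg.selection == "truncation"
    t = len(cfg.traits)
    Lg = np.linalg.cholesky(cfg.genetic_cov())
    sel_idx = (cfg.traits.index(cfg.selection_trait.lower())
               if cfg.selection_trait else 0)

    n_total = cfg.n_sires + cfg.n_dams + (
        cfg.generations * cfg.n_dams * cfg.offspring_per_dam
    )
    sire = np.full(n_total, UNKNOWN, dtype=np.int64)
    dam = np.full(n_total, UNKNOWN, dtype=np.int64)
    cohort = np.full(n_total, "", dtype=object)
    sex = np.full(n_total, "", dtype=object)
    F = np.zeros(n_total)
    d_ms = np.zeros(n_total)
    U = np.zeros((n_total, t))

    n_f = cfg.n_sires + cfg.n_dams
    cohort[:n_f] = f"{cfg.first_year - 1}-00"
    sex[:cfg.n_sires] = "M"
    sex[cfg.n_sires:n_f] = "F"
    if truncation or _return_bv:
        U[:n_f] = rng.standard_normal((n_f, t)) @ Lg.T
        for i in range(n_f):
            pedlib._ml_step(i, sire, dam, F, d_ms)

    def _pick(pool, k):
        pool = np.asarray(pool)
        if truncation:
            order = np.argsort(-U[pool, sel_idx], kind="stable")
            return pool[order[: min(k, pool.size)]]
        return rng.choice(pool, size=min(k, pool.size), replace=False)

    prev_males = list(range(cfg.n_sires))
    prev_females = list(range(cfg.n_sires, n_f))
    counter = n_f
    for g in range(1, cfg.generations + 1):
        year = cfg.first_year + g - 1
        sires_g = _pick(prev_males, cfg.n_sires)
        dams_g = _pick(prev_females, cfg.n_dams)
        new_males, new_females = [], []
        sire_of_dam = rng.choice(sires_g, size=len(dams_g), replace=True)
        week_of = rng.integers(1, cfg.hatch_weeks_per_generation + 1,
                               size=len(dams_g))
        for d_pos, d_idx in enumerate(dams_g):
            for _ in range(cfg.offspring_per_dam):
                i = counter
                sire[i] = int(sire_of_dam[d_pos])
                dam[i] = int(d_idx)
                cohort[i] = f"{year}-{int(week_of[d_pos]):02d}"
                if rng.random() < 0.5:
                    sex[i] = "M"
                    new_males.append(i)
                else:
                    sex[i] = "F"
                    new_females.append(i)
                if truncation or _return_bv:
                    pedlib._ml_step(i, sire, dam, F, d_ms)
                    ms_var = 0.5 - 0.25 * (F[sire[i]] + F[dam[i]])
                    U[i] = (0.5 * (U[sire[i]] + U[dam[i]])
                            + np.sqrt(ms_var) * (rng.standard_normal(t) @ Lg.T))
                counter += 1
        prev_males, prev_females = new_males, new_females

    ped = Pedigree(
        ids=np.array([str(i + 1) for i in range(n_total)], dtype=object),
        sire=sire,
        dam=dam,
        cohort=cohort,
        sex=sex,
    )
    if _return_bv:
        bv = pd.DataFrame(U, index=pd.Index(ped.ids, name="animal"),
                          columns=list(cfg.traits))
        return ped, bv
    return ped


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def founder_frequencies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.founder_freq_law == "uniform":
        lo, hi = cfg.founder_freq_range
        return rng.uniform(lo, hi, size=cfg.n_markers)
    if cfg.founder_freq_law == "beta":
        a, b = cfg.founder_freq_beta
        return rng.beta(a, b, size=cfg.n_markers)
    raise ValueError(f"unknown founder frequency law {cfg.founder_freq_law!r}")


def gene_drop(ped: Pedigree, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Drop alleles through the pedigree; returns 0/1/2 codes for everyone.

    Founder haplotypes are Bernoulli draws at the supplied frequencies;
    each offspring inherits one allele per marker from each parent,
    with independent Mendelian segregation across markers.
    """
    n, m = ped.n, p.size
    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for h, parent in ((0, s), (1, d)):
            if parent == UNKNOWN:
                hap[i, h] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, h] = hap[parent, pick, np.arange(m)]
    return (hap[:, 0] + hap[:, 1]).astype(np.int8)


def _generation_of(ped: Pedigree, cfg: SimConfig) -> np.ndarray:
    """Generation number per animal (0 = founders) from the cohort year."""
    years = np.array([int(str(c).split("-")[0]) for c in ped.cohort])
    return np.maximum(years - cfg.first_year + 1, 0)


def _genotyped_mask(ped: Pedigree, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random per-generation genotyped subset.

    ``cfg.genotyped_share`` is one share for every generation or a mapping
    generation -> share (unlisted generations get 0).  Founders are never
    genotyped (no DNA bank for the base population).
    """
    mask = np.zeros(ped.n, dtype=bool)
    gen = _generation_of(ped, cfg)
    if isinstance(cfg.genotyped_share, dict):
        share = np.array([cfg.genotyped_share.get(int(g), 0.0) for g in gen])
    else:
        share = np.full(ped.n, cfg.genotyped_share)
    eligible = (gen > 0) & (share > 0)
    if cfg.genotyped_sex is not None:
        eligible &= ped.sex == cfg.genotyped_sex
    idx = np.flatnonzero(eligible)
    if idx.size:
        take = rng.random(idx.size) < share[idx]
        mask[idx[take]] = True
    return mask


def simulate_genotypes(ped: Pedigree, cfg: SimConfig,
                       rng: np.random.Generator | None = None,
                       return_full: bool = False):
    """Gene-drop genotypes; returns a :class:`GenotypeMatrix` of the
    genotyped subset (or also the full code matrix and frequency vector
    with ``return_full``)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = founder_frequencies(cfg, rng)
    codes = gene_drop(ped, p, rng)
    mask = _genotyped_mask(ped, cfg, rng)
    meta = pd.DataFrame({
        "marker": [f"m{j + 1}" for j in range(cfg.n_markers)],
        "chrom": [str(1 + j % 28) for j in range(cfg.n_markers)],
        "pos": np.arange(cfg.n_markers) * 1000,
    })
    gm = GenotypeMatrix(codes=codes[mask], animal_ids=ped.ids[mask],
                        marker_meta=meta)
    if return_full:
        return gm, codes, p
    return gm


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def simulate_breeding_values(ped: Pedigree, cfg: SimConfig,
                             rng: np.random.Generator | None = None,
                             codes: np.ndarray | None = None,
                             founder_p: np.ndarray | None = None) -> pd.DataFrame:
    """True breeding values per animal and trait.

    Pedigree mode draws recursively — founders ``N(0, R)``, offspring
    parent-average plus Mendelian sampling ``N(0, d_i R)`` with
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` — so ``cov(vec U) = A (x) R``
    exactly.  Marker mode (``codes`` supplied or ``cfg.bv_mode ==
    "marker"``) sums centered genotype codes times i.i.d. multivariate
    normal marker effects scaled so founder BV covariance is ``R``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    R = cfg.genetic_cov()
    t = len(cfg.traits)
    L = np.linalg.cholesky(R)

    if cfg.bv_mode == "marker" or codes is not None:
        if codes is None:
            p = founder_frequencies(cfg, rng)
            codes = gene_drop(ped, p, rng)
            founder_p = p
        denom = 2.0 * float(np.sum(founder_p * (1.0 - founder_p)))
        effects = rng.standard_normal((cfg.n_markers, t)) @ L.T / np.sqrt(denom)
        U = (codes - 2.0 * founder_p) @ effects
    else:
        F = inbreeding(ped)
        Z = rng.standard_normal((ped.n, t)) @ L.T
        U = np.zeros((ped.n, t))
        sire, dam = ped.sire, ped.dam
        for i in range(ped.n):
            s, d = sire[i], dam[i]
            if s == UNKNOWN and d == UNKNOWN:
                U[i] = Z[i]
            elif s == UNKNOWN or d == UNKNOWN:
                k = s if s != UNKNOWN else d
                U[i] = 0.5 * U[k] + np.sqrt(0.75 - 0.25 * F[k]) * Z[i]
            else:
                di = 0.5 - 0.25 * (F[s] + F[d])
                U[i] = 0.5 * (U[s] + U[d]) + np.sqrt(di) * Z[i]

    return pd.DataFrame(U, index=pd.Index(ped.ids, name="animal"),
                        columns=list(cfg.traits))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(bv: pd.DataFrame, ped: Pedigree, cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Phenotypes ``mean + hatch + sex + u + e`` with sex-limited recording.

    Founders carry no records.  Hatch week-year effects are i.i.d. normal
    per cohort with SD ``hatch_sd_frac`` times the trait's phenotypic SD;
    sex effects are added for males and subtracted for females.  The
    walking score is discretized to 1-6 by rounding the latent value.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    E = cfg.residual_cov()
    Le = np.linalg.cholesky(E)
    n, t = ped.n, len(cfg.traits)
    e = rng.standard_normal((n, t)) @ Le.T

    cohorts = pd.unique(ped.cohort)
    hatch_eff = {
        trait: dict(zip(cohorts, rng.normal(
            0.0, cfg.hatch_sd_frac * cfg.trait_param(trait, "sd"),
            size=len(cohorts))))
        for trait in cfg.traits
    }

    is_male = ped.sex == "M"
    is_founder = ped.founders
    out = pd.DataFrame({
        "animal": ped.ids,
        "hatch_wy": ped.cohort,
        "sex": ped.sex,
    })
    U = bv.loc[ped.ids].to_numpy()
    for k, trait in enumerate(cfg.traits):
        mean = cfg.trait_param(trait, "mean")
        sx = cfg.trait_param(trait, "sex_effect")
        he = np.array([hatch_eff[trait][c] for c in ped.cohort])
        y = mean + he + np.where(is_male, sx, -sx) + U[:, k] + e[:, k]
        if TRAIT_DEFAULTS[trait]["ordinal"]:
            y = np.clip(np.rint(y), 1, 6)
        y = y.astype(float)
        y[is_founder] = np.nan
        if TRAIT_DEFAULTS[trait]["male_only"]:
            y[~is_male] = np.nan
        out[trait] = y
    return out


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

def simulate(cfg: SimConfig) -> SimOutput:
    """Run the full generator: pedigree, genotypes, BVs, phenotypes."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.selection == "truncation":
        if cfg.bv_mode != "pedigree":
            raise ValueError(
                "truncation selection is only available in pedigree BV mode"
            )
        ped, bv = simulate_pedigree(cfg, rng, _return_bv=True)
        genotypes = simulate_genotypes(ped, cfg, rng)
    else:
        ped = simulate_pedigree(cfg, rng)
        genotypes, codes, p = simulate_genotypes(ped, cfg, rng, return_full=True)
        if cfg.bv_mode == "marker":
            bv = simulate_breeding_values(ped, cfg, rng, codes=codes, founder_p=p)
        else:
            bv = simulate_breeding_values(ped, cfg, rng)
    ph = simulate_phenotypes(bv, ped, cfg, rng)
    logger.info(
        "simulated %d animals (%d genotyped), %d phenotyped",
        ped.n, genotypes.n_animals,
        int(ph[list(cfg.traits)].notna().any(axis=1).sum()),
    )
    return SimOutput(
        pedigree=ped, genotypes=genotypes, phenotypes=ph,
        true_breeding_values=bv, true_vc=cfg.true_vc(), config=cfg,
    )
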