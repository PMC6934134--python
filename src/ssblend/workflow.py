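"""Configuration-driven orchestration of a model-comparison experiment.

``run_experiment`` executes the full forward-validation protocol on one
data set (read from files or simulated inline):

1. prune the pedigree to phenotyped/genotyped animals and their ancestors;
2. estimate variance components per kinship type on the full data (REML),
   or take supplied/true components;
3. fit the full pedigree model and compute adjusted phenotypes;
4. hold out the youngest cohorts (~10% of phenotyped animals);
5. re-fit every model in the grid (PBLUP and ssGBLUP at each blending
   weight) on the masked data with the *same* split;
6. tabulate per-trait accuracy and dispersion bias per model.

Re-running with the same configuration and seed reproduces every table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ssblend import genomic, pedigree as pedlib, validation
from ssblend.model import (
    ModelSpec,
    VarianceComponents,
    build_design,
    heritability,
    reml,
    solve_mme,
)
from ssblend.simulate import SimConfig, simulate
from ssblend.traits import read_phenotypes

logger = logging.getLogger(__name__)

#: The default model grid: pedigree BLUP and single-step at three blends.
DEFAULT_GRID = (
    ("A", None, None),
    ("H", 0.95, "observed"),
    ("H", 0.90, "observed"),
    ("H", 0.85, "observed"),
)


@dataclass
class RunConfig:
    """Experiment configuration.

    Either ``simulate_cfg`` (inline simulation) or the three input paths
    must be given.  ``vc_source`` is ``"reml"`` (estimate on the full
    data, once per kinship type), ``"true"`` (simulation truths; only with
    inline simulation), or a mapping ``{"A": VarianceComponents, "H":
    ...}`` supplied programmatically.
    """

    seed: int
    traits: tuple
    simulate_cfg: SimConfig | None = None
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    genotype_path: str | None = None
    marker_meta_path: str | None = None
    grid: tuple = DEFAULT_GRID
    validation_fraction: float = 0.10
    vc_source: object = "reml"
    qc: genomic.QCThresholds = field(default_factory=genomic.QCThresholds)
    reml_options: dict = field(default_factory=dict)
    solver: str = "auto"
    outdir: str | None = None

    def __post_init__(self):
        if not self.grid:
            raise ValueError("model grid must be non-empty")
        for kin, w, _ in self.grid:
            if kin == "H" and not (0.0 < w <= 1.0):
                raise ValueError(f"blending weight must be in (0, 1], got {w}")
        if self.simulate_cfg is None and (
            self.pedigree_path is None or self.phenotype_path is None
        ):
            raise ValueError("need either simulate_cfg or input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("schema_version", None)
        if "simulate" in d:
            sim = d.pop("simulate")
            sim.setdefault("seed", d.get("seed", 0))
            d["simulate_cfg"] = SimConfig(**{
                k: (tuple(v) if isinstance(v, list) else v) for k, v in sim.items()
            })
        if "grid" in d:
            d["grid"] = tuple(tuple(entry) for entry in d["grid"])
        if d.get("vc_source") is True:   # YAML reads bare `true` as boolean
            d["vc_source"] = "true"
        if "qc" in d:
            d["qc"] = genomic.QCThresholds(**d["qc"])
        d["traits"] = tuple(d["traits"])
        return cls(**d)


def _subset_vc(vc: VarianceComponents, traits) -> VarianceComponents:
    idx = [vc.traits.index(t.lower()) for t in traits]
    ix = np.ix_(idx, idx)
    return VarianceComponents(genetic=vc.genetic[ix], residual=vc.residual[ix],
                              traits=tuple(t.lower() for t in traits))


def _load_inputs(cfg: RunConfig):
    if cfg.simulate_cfg is not None:
        sim = cfg.simulate_cfg
        if sim.seed is None:
            sim = SimConfig(**{**sim.__dict__, "seed": cfg.seed})
        out = simulate(sim)
        return out.pedigree, out.phenotypes, out.genotypes, out
    ped = pedlib.read_pedigree(cfg.pedigree_path)
    ph = read_phenotypes(cfg.phenotype_path)
    geno = None
    if cfg.genotype_path is not None:
        geno = genomic.read_genotypes(
            cfg.genotype_path, dialect="tsv", marker_meta_path=cfg.marker_meta_path
        )
    return ped, ph, geno, None


def _kinship_inverse(kind, ped, geno, w, scheme, qc_thresholds, cache):
    """A^-1 or H^-1 on the pruned pedigree, with per-run caching."""
    if "Ainv" not in cache:
        cache["F"] = pedlib.inbreeding(ped)
        cache["Ainv"] = pedlib.a_inverse(ped, cache["F"])
    if kind == "A":
        return cache["Ainv"]
    if geno is None or geno.n_animals == 0:
        logger.warning("single-step requested with no genotypes; H = A")
        return cache["Ainv"]
    if "geno_qc" not in cache:
        filtered, report = genomic.qc_filter(geno, qc_thresholds)
        in_ped = np.isin(filtered.animal_ids.astype(str), ped.ids.astype(str))
        if not in_ped.all():
            filtered = genomic.GenotypeMatrix(
                codes=filtered.codes[in_ped],
                animal_ids=filtered.animal_ids[in_ped],
                marker_meta=filtered.marker_meta,
            )
        cache["geno_qc"] = filtered
        cache["qc_report"] = report
        cache["a22"] = pedlib.a_submatrix(ped, filtered.animal_ids)
        cache["gidx"] = ped.index_of(filtered.animal_ids)
    filtered = cache["geno_qc"]
    key = ("G", scheme)
    if key not in cache:
        if scheme == "scaled":
            f = genomic.fit_beta_moments(
                genomic.allele_frequencies(filtered, "observed")
            )
            cache[key] = genomic.g_matrix_scaled(filtered, f)
        else:
            f = genomic.allele_frequencies(filtered, scheme)
            cache[key] = genomic.g_matrix(filtered, f)
    gw = genomic.blend(cache[key], cache["a22"], w, scheme=scheme,
                       animal_ids=filtered.animal_ids)
    return genomic.h_inverse(cache["Ainv"], gw, cache["a22"], cache["gidx"])


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full protocol; returns a report bundle.

    The bundle maps: ``"evaluation"`` to the accuracy table (one row per
    trait and model), ``"bias"`` likewise, ``"variance_components"`` to
    the per-kinship REML fits, ``"heritability"`` to per-trait h2 per
    kinship, ``"split"`` to the realized validation split, plus logs and
    diagnostics.  All artifacts are also written under ``cfg.outdir``
    when set.
    """
    t0 = time.time()
    stage = "load"
    stage_t0 = t0
    stage_seconds = {}

    def _enter(name):
        nonlocal stage, stage_t0
        now = time.time()
        stage_seconds[stage] = round(now - stage_t0, 3)
        logger.info("stage %s done in %.2fs", stage, now - stage_t0)
        stage, stage_t0 = name, now

    try:
        ped_full, ph, geno, sim = _load_inputs(cfg)

        _enter("prune")
        used_ids = set(ph["animal"].astype(str))
        if geno is not None:
            used_ids |= set(map(str, geno.animal_ids))
        ped = ped_full.prune(sorted(used_ids, key=lambda s: (len(s), s)))

        trait_cols = list(cfg.traits)
        ph = ph[["animal", "hatch_wy", "sex"] + trait_cols]

        _enter("variance_components")
        cache = {}
        vc_by_kinship = {}
        kin_kinds = []
        for kin, w, scheme in cfg.grid:
            key = "A" if kin == "A" else f"H_{w}_{scheme}"
            kin_kinds.append((key, kin, w, scheme))
        spec_full = ModelSpec(traits=cfg.traits, kinship="A")
        design = build_design(ph, ped, spec_full)
        for key, kin, w, scheme in kin_kinds:
            if key in vc_by_kinship:
                continue
            if isinstance(cfg.vc_source, dict):
                vc_by_kinship[key] = cfg.vc_source[kin]
            elif cfg.vc_source == "true":
                if sim is None:
                    raise ValueError("vc_source='true' requires inline simulation")
                vc_by_kinship[key] = _subset_vc(sim.true_vc, cfg.traits)
            else:
                Kinv = _kinship_inverse(kin, ped, geno, w, scheme, cfg.qc, cache)
                vc_by_kinship[key] = reml(design, Kinv, **cfg.reml_options)

        _enter("full_model")
        Ainv = _kinship_inverse("A", ped, geno, None, None, cfg.qc, cache)
        full_fit = solve_mme(design, Ainv, vc_by_kinship[kin_kinds[0][0]],
                             method=cfg.solver)
        y_adj = validation.adjust_phenotypes(ph, full_fit, spec_full)

        _enter("split")
        split = validation.make_split(ph, cfg.validation_fraction)
        ph_masked = validation.mask_validation(ph, split)
        design_red = build_design(ph_masked, ped, spec_full)

        _enter("reduced_models")
        acc_rows, bias_rows, diag = [], [], {}
        for key, kin, w, scheme in kin_kinds:
            label = "PBLUP" if kin == "A" else f"ssGBLUP_{w:.2f}"
            Kinv = _kinship_inverse(kin, ped, geno, w, scheme, cfg.qc, cache)
            red_fit = solve_mme(design_red, Kinv, vc_by_kinship[key],
                                method=cfg.solver)
            table = validation.evaluate_model(y_adj, red_fit, split, cfg.traits)
            for _, row in table.iterrows():
                acc_rows.append({"trait": row["trait"], "model": label,
                                 "accuracy": row["accuracy"],
                                 "n_validation": row["n_validation"]})
                bias_rows.append({"trait": row["trait"], "model": label,
                                  "bias_slope": row["bias_slope"],
                                  "bias_se": row["bias_se"],
                                  "n_validation": row["n_validation"]})
            diag[label] = red_fit.diagnostics

        acc = pd.DataFrame(acc_rows).pivot(index="trait", columns="model",
                                           values="accuracy")
        bias = pd.DataFrame(bias_rows).pivot(index="trait", columns="model",
                                             values="bias_slope")
        h2 = {
            key: {t: heritability(vc, t) for t in cfg.traits}
            for key, vc in vc_by_kinship.items()
        }
        _enter("report")
        report = {
            "evaluation": acc,
            "bias": bias,
            "bias_long": pd.DataFrame(bias_rows),
            "accuracy_long": pd.DataFrame(acc_rows),
            "variance_components": vc_by_kinship,
            "heritability": h2,
            "split": split,
            "diagnostics": diag,
            "runtime_s": time.time() - t0,
            "stage_seconds": stage_seconds,
            "n_pedigree": ped.n,
        }
        if cfg.outdir is not None:
            _write_report(cfg, report, y_adj)
        return report
    except Exception:
        logger.error("experiment failed at stage %r", stage)
        raise


def _write_report(cfg: RunConfig, report: dict, y_adj: pd.DataFrame) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report["evaluation"].to_csv(out / "accuracy.csv")
    report["bias"].to_csv(out / "bias.csv")
    y_adj.to_csv(out / "adjusted_phenotypes.csv", index=False)
    for key, vc in report["variance_components"].items():
        vc.to_json(out / f"variance_components_{key}.json")
    split = report["split"]
    meta = {
        "validation_fraction_achieved": split.fraction_achieved,
        "split_rule": split.rule,
        "n_training": int(len(split.training_ids)),
        "n_validation": int(len(split.validation_ids)),
        "heritability": report["heritability"],
        "diagnostics": report["diagnostics"],
        "runtime_s": report["runtime_s"],
        "n_pedigree": report["n_pedigree"],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(meta, fh, indent=2)
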