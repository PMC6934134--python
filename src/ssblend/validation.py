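"""Forward-validation protocol: accuracy and dispersion bias.

Prediction ability is assessed by a forward split: records of the youngest
~10% of phenotyped animals (whole hatch-cohorts) are masked, the model is
re-fitted (the "reduced" run), and the masked animals' predictions are
compared with their phenotypes adjusted for fixed effects from the full
pedigree run:

* accuracy — Pearson correlation between adjusted phenotypes and the
  reduced-run (G)EBV;
* bias — slope of the OLS regression of adjusted phenotype on (G)EBV;
  slopes below 1 indicate inflated (over-dispersed) predictions, above 1
  deflated ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ValidationSplit:
    """A forward (youngest-cohorts) training/validation split."""

    training_ids: np.ndarray
    validation_ids: np.ndarray
    rule: str
    fraction_achieved: float

    def __post_init__(self):
        overlap = set(map(str, self.training_ids)) & set(map(str, self.validation_ids))
        if overlap:
            raise ValueError(f"training/validation overlap: {sorted(overlap)[:5]}")


def _cohort_sort_key(label: str):
    """Order hatch week-year labels chronologically.

    Labels like ``"2013-27"`` (year-week) sort correctly as strings of
    equal layout; numeric labels are compared numerically.
    """
    parts = str(label).replace("_", "-").split("-")
    try:
        return tuple(int(p) for p in parts)
    except ValueError:
        return (float("inf"),) + tuple(parts)


def make_split(ph: pd.DataFrame, fraction: float = 0.10) -> ValidationSplit:
    """Hold out whole youngest cohorts until at least ``fraction`` of
    phenotyped animals are in validation.

    Animals count as phenotyped when any trait column is non-missing.
    Splitting on whole cohorts avoids information leakage through
    contemporary-group effects estimated partly from validation records.
    """
    meta_cols = {"animal", "hatch_wy", "sex"}
    trait_cols = [c for c in ph.columns if c not in meta_cols]
    phenotyped = ph[ph[trait_cols].notna().any(axis=1)].copy()
    n = len(phenotyped)
    if n == 0:
        raise ValueError("no phenotyped animals to split")

    cohorts = sorted(phenotyped["hatch_wy"].astype(str).unique(), key=_cohort_sort_key)
    if len(cohorts) < 2:
        raise ValueError("cannot make a forward split with a single cohort")

    counts = phenotyped["hatch_wy"].astype(str).value_counts()
    held, total = [], 0
    for c in reversed(cohorts):
        held.append(c)
        total += int(counts[c])
        if total / n >= fraction:
            break
    if len(held) == len(cohorts):
        raise ValueError("validation fraction would consume every cohort")

    val_mask = phenotyped["hatch_wy"].astype(str).isin(held)
    split = ValidationSplit(
        training_ids=phenotyped.loc[~val_mask, "animal"].astype(str).to_numpy(),
        validation_ids=phenotyped.loc[val_mask, "animal"].astype(str).to_numpy(),
        rule=f"youngest cohorts {sorted(held, key=_cohort_sort_key)}",
        fraction_achieved=total / n,
    )
    logger.info("forward split: %d training, %d validation (%.1f%%)",
                len(split.training_ids), len(split.validation_ids),
                100 * split.fraction_achieved)
    return split


def mask_validation(ph: pd.DataFrame, split: ValidationSplit) -> pd.DataFrame:
    """Set all trait records of validation animals to missing.

    The reduced model is built from the returned frame, so validation
    phenotypes can never influence it.
    """
    meta_cols = {"animal", "hatch_wy", "sex"}
    trait_cols = [c for c in ph.columns if c not in meta_cols]
    out = ph.copy()
    val = set(map(str, split.validation_ids))
    mask = out["animal"].astype(str).isin(val)
    out.loc[mask, trait_cols] = np.nan
    return out


def adjust_phenotypes(ph: pd.DataFrame, full_fit, spec) -> pd.DataFrame:
    """Adjusted phenotypes ``y - x'b_hat`` using full-model fixed effects.

    Returns a frame ``animal`` plus one adjusted column per trait in
    ``spec.traits`` (NaN where the trait is missing).  Fixed-effect levels
    follow the model specification: hatch week-year for every trait, sex
    additionally where specified.
    """
    out = pd.DataFrame({"animal": ph["animal"].astype(str)})
    hw = ph["hatch_wy"].astype(str)
    sex = ph["sex"].astype(str)
    for trait in spec.traits:
        y = ph[trait].to_numpy(dtype=float)
        b = full_fit.fixed_solutions[trait]
        adj = np.full(len(ph), np.nan)
        obs = ~np.isnan(y)
        xb = np.zeros(len(ph))
        hb = b.loc["hatch_wy"]
        xb += hw.map(hb).fillna(0.0).to_numpy()
        if "sex" in b.index.get_level_values("effect"):
            sb = b.loc["sex"]
            xb += sex.map(sb).fillna(0.0).to_numpy()
        adj[obs] = y[obs] - xb[obs]
        out[trait] = adj
    return out


def accuracy(y_adj: np.ndarray, ebv: np.ndarray) -> float:
    """Pearson correlation between adjusted phenotypes and predictions.

    Returns NaN when fewer than 3 complete pairs remain or either vector
    is constant.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    ok = ~(np.isnan(y_adj) | np.isnan(ebv))
    y, x = y_adj[ok], ebv[ok]
    if y.size < 3 or np.std(y) == 0 or np.std(x) == 0:
        return float("nan")
    return float(np.corrcoef(y, x)[0, 1])


def bias_slope(y_adj: np.ndarray, ebv: np.ndarray) -> tuple[float, float]:
    """OLS slope (and its SE) of adjusted phenotype on prediction.

    A slope of 1 means unbiased dispersion; below 1 the predictions are
    inflated (too spread out), above 1 deflated.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    ok = ~(np.isnan(y_adj) | np.isnan(ebv))
    y, x = y_adj[ok], ebv[ok]
    n = y.size
    if n < 3 or np.var(x) == 0:
        return float("nan"), float("nan")
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    resid = y - y.mean() - slope * xc
    if n > 2:
        se = float(np.sqrt(np.dot(resid, resid) / (n - 2) / np.dot(xc, xc)))
    else:
        se = 0.0
    return slope, se


def evaluate_model(y_adj_table: pd.DataFrame, reduced_fit, split: ValidationSplit,
                   traits) -> pd.DataFrame:
    """Accuracy and bias per trait for one reduced-model run.

    ``y_adj_table`` comes from :func:`adjust_phenotypes` on the full data;
    only validation animals with the trait recorded enter each statistic.
    """
    bv = reduced_fit.breeding_values
    val = pd.Index(map(str, split.validation_ids))
    rows = []
    adj = y_adj_table.set_index("animal")
    for trait in traits:
        ids = val.intersection(adj.index[adj[trait].notna()])
        y = adj.loc[ids, trait].to_numpy()
        u = bv.loc[ids, trait].to_numpy()
        slope, se = bias_slope(y, u)
        rows.append(
            {
                "trait": trait,
                "accuracy": accuracy(y, u),
                "bias_slope": slope,
                "bias_se": se,
                "n_validation": int(len(ids)),
            }
        )
    return pd.DataFrame(rows)
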