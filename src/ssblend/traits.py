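"""Derived production traits: FCR, RFI and BMY.

Feed conversion ratio (FCR, kg feed / kg gain) and residual feed intake
(RFI, kg) summarize feed efficiency over a test period; breast meat yield
(BMY, %) is breast weight as a share of live slaughter weight.  Body
weight (BW, kg) and the 1-6 walking score (WS) pass through unchanged.

RFI is defined as the residual of an ordinary least-squares regression of
observed feed intake on metabolic mid-weight, body-weight gain, and hatch
week (categorical), fitted within the data set being analyzed, so RFI has
mean zero by construction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Trait names in canonical order.
TRAITS = ("fcr", "rfi", "bw", "bmy", "ws")

#: Traits recorded on males only (feed test and slaughter traits).
MALE_ONLY = ("fcr", "rfi", "bmy")

#: Exponent turning mid-test body weight into metabolic mid-weight.
METABOLIC_EXPONENT = 0.75


def compute_fcr(total_intake, weight_gain):
    """Feed conversion ratio: total feed intake / weight gain (kg/kg).

    Non-positive gain gives a missing value (NaN) with a warning; a test
    animal that lost weight has no meaningful conversion ratio.
    """
    intake = np.asarray(total_intake, dtype=float)
    gain = np.asarray(weight_gain, dtype=float)
    bad = ~(gain > 0)
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} record(s) with non-positive weight gain; "
            "FCR set to missing",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, intake / np.where(bad, 1.0, gain))
    return out if out.ndim else float(out)


def compute_rfi(intake, mid_weight_or_mmw, gain, hatch_week, *,
                is_metabolic: bool = False):
    """Residual feed intake: observed minus regression-expected intake (kg).

    Expected intake is the fit of an OLS regression of intake on metabolic
    mid-weight (mid-test body weight ** 0.75, or the metabolic weight
    directly when ``is_metabolic``), weight gain, and categorical hatch
    week, with intercept.  Aliased hatch-week levels (rank deficiency) are
    handled by lstsq's minimum-norm solution; residuals are unaffected.
    """
    intake = np.asarray(intake, dtype=float)
    mmw = np.asarray(mid_weight_or_mmw, dtype=float)
    if not is_metabolic:
        mmw = mmw ** METABOLIC_EXPONENT
    gain = np.asarray(gain, dtype=float)
    hatch = pd.Categorical([str(h) for h in np.asarray(hatch_week, dtype=object)])
    if np.isnan(intake).any() or np.isnan(mmw).any() or np.isnan(gain).any():
        raise ValueError("RFI regression covariates must be complete")

    n = intake.size
    levels = hatch.categories
    X = np.zeros((n, 2 + len(levels)))
    X[:, 0] = mmw
    X[:, 1] = gain
    X[np.arange(n), 2 + hatch.codes] = 1.0  # level dummies absorb the intercept
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "rank-deficient RFI design (aliased hatch-week levels); "
            "residuals are still well defined",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, intake, rcond=None)
    return intake - X @ beta


def compute_bmy(breast_weight, live_weight):
    """Breast meat yield: breast weight / live slaughter weight * 100 (%)."""
    breast = np.asarray(breast_weight, dtype=float)
    live = np.asarray(live_weight, dtype=float)
    if np.any(~(live > 0)):
        raise ValueError("live weight must be positive")
    if np.any(breast > live):
        warnings.warn("breast weight exceeds live weight for some records",
                      stacklevel=2)
    out = 100.0 * breast / live
    return out if out.ndim else float(out)


def derive_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive FCR, RFI and BMY from raw feed-test and slaughter records.

    ``raw`` columns: ``animal, hatch_wy, sex, intake, mid_weight, gain,
    breast_wt, live_wt`` (the last two optional/NaN for animals without
    slaughter records).  Returns a phenotype frame ``animal, hatch_wy,
    sex, fcr, rfi, bmy``.
    """
    out = raw[["animal", "hatch_wy", "sex"]].copy()
    out["fcr"] = compute_fcr(raw["intake"], raw["gain"])
    out["rfi"] = compute_rfi(raw["intake"], raw["mid_weight"], raw["gain"],
                             raw["hatch_wy"])
    if "breast_wt" in raw.columns and "live_wt" in raw.columns:
        has = raw["breast_wt"].notna() & raw["live_wt"].notna()
        bmy = np.full(len(raw), np.nan)
        if has.any():
            bmy[has.to_numpy()] = compute_bmy(raw.loc[has, "breast_wt"],
                                              raw.loc[has, "live_wt"])
        out["bmy"] = bmy
    return out


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV (``animal,hatch_wy,sex,fcr,rfi,bw,bmy,ws``).

    Empty cells are missing values.  Walking scores are validated to lie in
    1-6 when present.
    """
    df = pd.read_csv(path, dtype={"animal": str, "hatch_wy": str, "sex": str})
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("animal", "hatch_wy", "sex"):
        if col not in df.columns:
            raise ValueError(f"phenotype file missing column {col!r}")
    if "ws" in df.columns:
        ws = df["ws"].dropna()
        if len(ws) and not ws.isin([1, 2, 3, 4, 5, 6]).all():
            raise ValueError("walking score outside 1-6 encountered")
    return df
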