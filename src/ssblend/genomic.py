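"""Genotype QC, genomic relationship matrices, blending, and H-inverse.

The genomic relationship matrix is built from additive-coded genotypes
(0/1/2 copies of the second allele) as

    G = (M - P)(M - P)' / (2 * sum_j p_j (1 - p_j))

where column ``j`` of ``M`` is centered by twice the allele frequency
``p_j``.  Three allele-frequency schemes are supported: all frequencies
fixed at 0.5, frequencies observed in the genotyped sample, and observed
frequencies with a beta-distribution-based rescaling of the denominator.

For single-step evaluation ``G`` is blended with the pedigree block
``A22`` as ``Gw = w*G + (1-w)*A22`` (guaranteeing invertibility) and the
pedigree ``A``-inverse is augmented in the genotyped block by
``Gw^-1 - A22^-1`` to give the single-step ``H``-inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.stats import chi2

logger = logging.getLogger(__name__)

#: Internal missing-genotype code.
MISSING = -1


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes: animals in rows, markers in columns.

    ``codes`` holds values in {0, 1, 2} with ``-1`` for missing, stored as
    int8.  ``marker_meta`` is a DataFrame with columns ``marker, chrom,
    pos`` (``chrom`` may carry non-autosomal labels filtered during QC).
    """

    codes: np.ndarray
    animal_ids: np.ndarray
    marker_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.codes.ndim != 2:
            raise GenotypeError("codes must be 2-D (animals x markers)")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            r, c = np.argwhere(~valid)[0]
            raise GenotypeError(
                f"invalid genotype code {int(self.codes[r, c])} at "
                f"animal {self.animal_ids[r]!r}, marker column {c}"
            )
        if len(self.animal_ids) != self.codes.shape[0]:
            raise GenotypeError("animal_ids length does not match row count")
        if self.marker_meta is None:
            self.marker_meta = pd.DataFrame(
                {
                    "marker": [f"m{j}" for j in range(self.codes.shape[1])],
                    "chrom": ["1"] * self.codes.shape[1],
                    "pos": np.arange(self.codes.shape[1]),
                }
            )
        if len(self.marker_meta) != self.codes.shape[1]:
            raise GenotypeError("marker_meta length does not match column count")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.codes, columns=self.marker_meta["marker"].tolist()
        ).astype(object)
        df[df == MISSING] = "NA"
        df.insert(0, "animal_id", self.animal_ids)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class QCThresholds:
    """Marker/animal quality-control thresholds.

    Defaults follow common practice for medium-density SNP panels:
    Hardy-Weinberg exact-deviation p-value floor 1e-8, minor allele
    frequency floor 5%, call rate floor 90% for both markers and animals,
    autosomes only.
    """

    hwe_p_min: float = 1e-8
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    autosomal_only: bool = True

    def __post_init__(self):
        for name in ("hwe_p_min", "maf_min", "call_rate_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class FrequencySpec:
    """Per-marker second-allele frequencies under a named scheme.

    ``scheme`` is ``"half"`` (all 0.5), ``"observed"`` (sample means / 2)
    or ``"scaled"`` (observed frequencies plus fitted beta parameters
    ``alpha_hat, beta_hat`` used to rescale the G denominator).
    """

    scheme: str
    p: np.ndarray
    alpha_hat: float | None = None
    beta_hat: float | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.scheme not in ("half", "observed", "scaled"):
            raise ValueError(f"unknown frequency scheme {self.scheme!r}")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.alpha_hat is not None and not (self.alpha_hat > 0 and self.beta_hat > 0):
            raise ValueError("fitted beta parameters must be positive")

    @property
    def x_bar(self) -> float:
        return float(np.mean(self.p))

    @property
    def v_bar(self) -> float:
        return float(np.var(self.p))


@dataclass
class BlendedG:
    """A blended genomic relationship matrix ``Gw = w*G + (1-w)*A22``."""

    g: np.ndarray
    w: float
    scheme: str
    animal_ids: np.ndarray = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "tsv", marker_meta_path=None) -> GenotypeMatrix:
    """Read additive-coded genotypes.

    ``dialect="tsv"``: first column ``animal_id``, one column per marker,
    codes 0/1/2 with ``NA`` (or empty) for missing.
    ``dialect="plink_raw"``: PLINK ``--recode A`` export with header
    ``FID IID PAT MAT SEX PHENOTYPE <SNP>_<allele> ...``.

    An optional marker-metadata TSV (``marker, chrom, pos``) attaches
    chromosome labels used by the autosomal QC filter.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        animal_ids = df.iloc[:, 0].to_numpy(dtype=object)
        geno = df.iloc[:, 1:]
        marker_names = list(geno.columns)
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != lead:
            raise GenotypeError(
                f"not a PLINK additive .raw header: {list(df.columns[:6])}"
            )
        animal_ids = df["IID"].to_numpy(dtype=object)
        geno = df.iloc[:, 6:]
        # strip the _<counted allele> suffix PLINK appends
        marker_names = [c.rsplit("_", 1)[0] for c in geno.columns]
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    arr = geno.to_numpy(dtype=object)
    codes = np.full(arr.shape, MISSING, dtype=np.int8)
    for code in ("0", "1", "2"):
        codes[arr == code] = int(code)
    bad = ~(np.isin(arr, ("0", "1", "2", "NA", "", "nan", "-9")))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise GenotypeError(
            f"invalid genotype code {arr[r, c]!r} at row {r} "
            f"(animal {animal_ids[r]!r}), marker {marker_names[c]!r}"
        )

    meta = None
    if marker_meta_path is not None:
        meta = pd.read_csv(marker_meta_path, sep="\t", dtype={"marker": str, "chrom": str})
        meta = meta.set_index("marker").loc[marker_names].reset_index()
    else:
        meta = pd.DataFrame(
            {"marker": marker_names, "chrom": "1", "pos": np.arange(len(marker_names))}
        )
    return GenotypeMatrix(codes=codes, animal_ids=animal_ids, marker_meta=meta)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

_AUTOSOME_EXCLUDE = {"x", "y", "z", "w", "mt", "m", "xy", "0", "un"}


def _hwe_chisq_p(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    Vectorized over markers; counts are (hom first, het, hom second).
    """
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n1 + 2 * n2) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        stat = np.zeros_like(p, dtype=float)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            stat += term
    pval = chi2.sf(stat, df=1)
    # monomorphic markers: HWE test undefined, treat as passing (MAF filter
    # removes them anyway)
    pval = np.where((p <= 0) | (p >= 1), 1.0, pval)
    return pval


def qc_filter(g: GenotypeMatrix, t: QCThresholds | None = None):
    """Apply marker and animal QC; returns ``(filtered, report)``.

    Stages, in order: autosomal filter, per-marker call rate, minor allele
    frequency, Hardy-Weinberg 1-df chi-square, per-animal call rate.  The
    report DataFrame counts removals per stage; a per-marker flag table is
    attached as ``report.attrs["marker_flags"]``.
    """
    if t is None:
        t = QCThresholds()
    codes = g.codes
    n_markers = g.n_markers
    keep = np.ones(n_markers, dtype=bool)
    flags = pd.DataFrame({"marker": g.marker_meta["marker"], "removed_by": ""})

    def _flag(mask, reason):
        newly = mask & keep
        flags.loc[newly, "removed_by"] = reason
        return keep & ~mask

    stage_counts = {}

    if t.autosomal_only:
        chrom = g.marker_meta["chrom"].astype(str).str.lower().to_numpy()
        non_auto = np.isin(chrom, list(_AUTOSOME_EXCLUDE))
        stage_counts["non_autosomal"] = int((non_auto & keep).sum())
        keep = _flag(non_auto, "non_autosomal")

    obs = codes != MISSING
    call_rate = obs.mean(axis=0)
    low_cr = call_rate < t.call_rate_min
    stage_counts["marker_call_rate"] = int((low_cr & keep).sum())
    keep = _flag(low_cr, "marker_call_rate")

    with np.errstate(invalid="ignore"):
        p = np.where(obs.sum(axis=0) > 0,
                     np.where(obs, codes, 0).sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1),
                     np.nan)
    maf = np.minimum(p, 1.0 - p)
    low_maf = ~(maf >= t.maf_min)  # catches NaN too
    stage_counts["maf"] = int((low_maf & keep).sum())
    keep = _flag(low_maf, "maf")

    n0 = ((codes == 0) & obs).sum(axis=0)
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    hwe_p = _hwe_chisq_p(n0, n1, n2)
    hwe_fail = hwe_p < t.hwe_p_min
    stage_counts["hwe"] = int((hwe_fail & keep).sum())
    keep = _flag(hwe_fail, "hwe")

    if not keep.any():
        raise GenotypeError("all markers removed by QC; check thresholds and input")

    codes_kept = codes[:, keep]
    animal_cr = (codes_kept != MISSING).mean(axis=1)
    keep_animals = animal_cr >= t.call_rate_min
    stage_counts["animal_call_rate"] = int((~keep_animals).sum())

    filtered = GenotypeMatrix(
        codes=codes_kept[keep_animals],
        animal_ids=g.animal_ids[keep_animals],
        marker_meta=g.marker_meta.loc[keep].reset_index(drop=True),
    )
    report = pd.DataFrame(
        {
            "stage": list(stage_counts),
            "removed": list(stage_counts.values()),
        }
    )
    report.attrs["marker_flags"] = flags
    report.attrs["n_markers_kept"] = int(keep.sum())
    report.attrs["n_animals_kept"] = int(keep_animals.sum())
    logger.info(
        "QC: kept %d/%d markers, %d/%d animals (%s)",
        keep.sum(), n_markers, keep_animals.sum(), g.n_animals,
        ", ".join(f"{k}={v}" for k, v in stage_counts.items()),
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Allele frequencies and G construction
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix, scheme: str = "observed") -> FrequencySpec:
    """Second-allele frequencies under ``scheme`` ("half" or "observed")."""
    if scheme == "half":
        return FrequencySpec(scheme="half", p=np.full(g.n_markers, 0.5))
    if scheme != "observed":
        raise ValueError(
            f"scheme must be 'half' or 'observed' here, got {scheme!r}; "
            "use fit_beta_moments for 'scaled'"
        )
    obs = g.codes != MISSING
    counts = obs.sum(axis=0)
    if np.any(counts == 0):
        raise GenotypeError("marker with no observed genotypes; run qc_filter first")
    p = np.where(obs, g.codes, 0).sum(axis=0) / (2.0 * counts)
    if np.any((p <= 0) | (p >= 1)):
        raise GenotypeError("monomorphic marker encountered; run qc_filter first")
    return FrequencySpec(scheme="observed", p=p)


def fit_beta_moments(f: FrequencySpec) -> FrequencySpec:
    """Fit beta-distribution parameters to the frequency spectrum by moments.

    With sample mean ``x`` and variance ``v`` of the per-marker frequencies:

        alpha = x * (x(1-x)/v - 1),   beta = (1-x) * (x(1-x)/v - 1)

    Requires ``0 < v < x(1-x)`` (else the moment estimator is undefined).
    """
    x, v = f.x_bar, f.v_bar
    if not (v > 0):
        raise ValueError("frequency variance is zero; beta fit undefined")
    if v >= x * (1 - x):
        raise ValueError(
            f"frequency variance {v:.4g} >= x(1-x) = {x * (1 - x):.4g}; "
            "moment estimator undefined"
        )
    k = x * (1 - x) / v - 1.0
    return FrequencySpec(
        scheme="scaled", p=f.p, alpha_hat=x * k, beta_hat=(1 - x) * k
    )


def impute_missing(g: GenotypeMatrix, f: FrequencySpec) -> np.ndarray:
    """Mean-impute: replace missing codes at marker ``j`` by ``2 p_j``.

    Returns a float matrix (imputed values are fractional).
    """
    M = g.codes.astype(float)
    miss = g.codes == MISSING
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * f.p, M.shape)[miss]
    return M


def _centered(g: GenotypeMatrix, f: FrequencySpec) -> np.ndarray:
    if f.p.shape[0] != g.n_markers:
        raise ValueError("frequency vector length does not match marker count")
    M = impute_missing(g, f)
    return M - 2.0 * f.p


def g_matrix(g: GenotypeMatrix, f: FrequencySpec) -> np.ndarray:
    """Genomic relationship matrix ``(M-P)(M-P)' / (2 sum p_j(1-p_j))``.

    Genotype columns are centered by ``2 p_j``; with observed frequencies
    the rows of the result sum to zero.  Residual missing codes are
    mean-imputed first.
    """
    Z = _centered(g, f)
    denom = 2.0 * float(np.sum(f.p * (1.0 - f.p)))
    if denom <= 0:
        raise ValueError("zero G denominator: all markers monomorphic under f")
    G = (Z @ Z.T) / denom
    return 0.5 * (G + G.T)


def scaled_g_denominator(f: FrequencySpec, n_markers: int) -> float:
    """Denominator of the beta-rescaled G.

    Reading of the rescaling bracket: with ``p0 = alpha/(alpha+beta)``,
    ``q0 = 1 - p0``, ``s = sum_j p_j(1-p_j) / m``:

        denom = m * [ (p0 - q0)^2 + 2 * s * (alpha + beta + 2) / (alpha + beta) ]

    The source formulation is typographically ambiguous; this reading keeps
    the denominator positive, reduces sensibly at alpha = beta (where the
    (p0-q0)^2 term vanishes), and approaches the observed-frequency
    denominator for large alpha + beta.  The scaled scheme is therefore
    kept out of defaults.
    """
    if f.alpha_hat is None or f.beta_hat is None:
        raise ValueError("scaled scheme requires fitted beta parameters")
    a, b = f.alpha_hat, f.beta_hat
    p0 = a / (a + b)
    q0 = 1.0 - p0
    s = float(np.sum(f.p * (1.0 - f.p))) / n_markers
    bracket = (p0 - q0) ** 2 + 2.0 * s * (a + b + 2.0) / (a + b)
    denom = n_markers * bracket
    if denom <= 0:
        raise ValueError("non-positive scaled G denominator")
    return denom


def g_matrix_scaled(g: GenotypeMatrix, f: FrequencySpec) -> np.ndarray:
    """Beta-rescaled genomic relationship matrix (scheme ``scaled``).

    Shares the centered numerator with :func:`g_matrix`; only the scalar
    denominator differs (see :func:`scaled_g_denominator`).
    """
    Z = _centered(g, f)
    denom = scaled_g_denominator(f, g.n_markers)
    G = (Z @ Z.T) / denom
    return 0.5 * (G + G.T)


# ---------------------------------------------------------------------------
# Blending and H-inverse
# ---------------------------------------------------------------------------

def blend(gmat: np.ndarray, a22: np.ndarray, w: float, scheme: str = "observed",
          animal_ids=None) -> BlendedG:
    """Convex blend ``Gw = w*G + (1-w)*A22``.

    ``w < 1`` guarantees positive definiteness whenever ``A22`` is positive
    definite, making ``Gw`` safely invertible; it also acts as the relative
    weight of the residual polygenic effect.
    """
    gmat = np.asarray(gmat, dtype=float)
    a22 = np.asarray(a22, dtype=float)
    if gmat.shape != a22.shape:
        raise ValueError(f"G shape {gmat.shape} != A22 shape {a22.shape}")
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"blending weight must be in [0, 1], got {w}")
    return BlendedG(g=w * gmat + (1.0 - w) * a22, w=w, scheme=scheme,
                    animal_ids=animal_ids)


def _chol_inverse(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = sla.cho_factor(mat, lower=True, check_finite=False)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"{what} is not positive definite ({exc}); "
            "for a blended G, a smaller blending weight w may help"
        ) from None
    inv = sla.cho_solve((c, low), np.eye(mat.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def h_inverse(a_inv: sp.spmatrix, gw: BlendedG | np.ndarray, a22: np.ndarray,
              genotyped_idx: np.ndarray) -> sp.csr_matrix:
    """Single-step ``H^-1``: ``A^-1`` plus ``Gw^-1 - A22^-1`` in the
    genotyped block.

    ``genotyped_idx`` maps rows of ``Gw``/``A22`` to rows of ``a_inv``
    (pedigree order).  With no genotyped animals the result equals
    ``a_inv`` exactly.
    """
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    gmat = gw.g if isinstance(gw, BlendedG) else np.asarray(gw, dtype=float)
    if genotyped_idx.size == 0:
        return sp.csr_matrix(a_inv)
    if gmat.shape[0] != genotyped_idx.size or a22.shape[0] != genotyped_idx.size:
        raise ValueError("Gw/A22 dimension does not match genotyped index length")

    gw_inv = _chol_inverse(gmat, "blended G")
    a22_inv = _chol_inverse(np.asarray(a22, dtype=float), "A22")
    delta = gw_inv - a22_inv

    rows = np.repeat(genotyped_idx, genotyped_idx.size)
    cols = np.tile(genotyped_idx, genotyped_idx.size)
    aug = sp.coo_matrix((delta.ravel(), (rows, cols)), shape=a_inv.shape)
    H = (sp.csr_matrix(a_inv) + aug.tocsr()).tocsr()
    return H
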