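"""Multi-trait animal model: mixed-model equations, BLUP, and REML.

The model for trait vector ``y`` is ``y = Xb + Zu + e`` with fixed effects
``b`` (hatch week-year for every trait, plus sex for body weight and
walking score), additive genetic effects ``u ~ N(0, G0 (x) K)`` where
``K`` is the pedigree relationship matrix ``A`` or the single-step ``H``
(supplied through its sparse inverse), and residuals ``e`` with per-animal
covariance ``R0[o, o]`` restricted to the traits observed on that animal.

Variance components are estimated by REML: EM updates (always available,
guaranteed to stay in the parameter space) accelerated by average-
information (AI) Newton steps with step halving back towards EM when a
step leaves the positive-definite cone.  The traces the EM and AI
formulas need are computed exactly from a dense inverse of the coefficient
matrix, which keeps the implementation honest at the moderate problem
sizes this package targets (thousands of animals).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import lapack

logger = logging.getLogger(__name__)

#: Traits that get a sex fixed effect (recorded on both sexes).
DEFAULT_SEX_TRAITS = ("bw", "ws")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Which traits to analyze and with which kinship.

    ``kinship`` is ``"A"`` (pedigree) or ``"H"`` (single-step); ``w`` and
    ``scheme`` describe the blending weight and allele-frequency scheme
    when single-step.  Every trait gets a hatch week-year fixed effect;
    traits in ``sex_traits`` additionally get a sex effect.
    """

    traits: tuple
    kinship: str = "A"
    w: float = 0.90
    scheme: str = "observed"
    sex_traits: tuple = DEFAULT_SEX_TRAITS

    def __post_init__(self):
        self.traits = tuple(t.lower() for t in self.traits)
        if not self.traits:
            raise ValueError("trait list must be non-empty")
        if self.kinship not in ("A", "H"):
            raise ValueError(f"kinship must be 'A' or 'H', got {self.kinship!r}")

    @property
    def label(self) -> str:
        if self.kinship == "A":
            return "PBLUP"
        return f"ssGBLUP_{self.w:.2f}"


@dataclass
class VarianceComponents:
    """Genetic and residual trait covariance matrices plus fit metadata."""

    genetic: np.ndarray
    residual: np.ndarray
    traits: tuple
    se_approx: dict | None = None
    converged: bool = True
    iterations: int = 0
    param_cov: np.ndarray | None = None  # AI-inverse over vech(G0), vech(R0)

    def __post_init__(self):
        self.genetic = np.atleast_2d(np.asarray(self.genetic, dtype=float))
        self.residual = np.atleast_2d(np.asarray(self.residual, dtype=float))
        t = len(self.traits)
        if self.genetic.shape != (t, t) or self.residual.shape != (t, t):
            raise ValueError("covariance matrices must be t x t for t traits")

    def trait_index(self, trait: str) -> int:
        return self.traits.index(trait.lower())

    def to_json(self, path=None) -> str:
        payload = {
            "traits": list(self.traits),
            "genetic": self.genetic.tolist(),
            "residual": self.residual.tolist(),
            "se_approx": self.se_approx,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "VarianceComponents":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genetic=np.array(payload["genetic"]),
            residual=np.array(payload["residual"]),
            traits=tuple(payload["traits"]),
            se_approx=payload.get("se_approx"),
            converged=payload.get("converged", True),
            iterations=payload.get("iterations", 0),
        )


@dataclass
class SolutionSet:
    """BLUP solutions: fixed-effect estimates and breeding values."""

    fixed_solutions: dict
    breeding_values: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    def write_csv(self, path) -> None:
        long = self.breeding_values.reset_index(names="animal").melt(
            id_vars="animal", var_name="trait", value_name="ebv"
        )
        long.to_csv(path, index=False)


@dataclass
class Design:
    """Assembled record-level design for the multi-trait animal model."""

    W: sp.csr_matrix              # records x equations, [X | Z]
    y: np.ndarray                 # stacked observations, animal-major
    n_fixed: int
    q: int                        # number of pedigree animals
    traits: tuple
    fixed_labels: dict            # trait -> list of (effect, level) labels
    rec_animal: np.ndarray        # pedigree index per record
    rec_trait: np.ndarray         # trait index per record
    anim_rows: list               # per data-animal: record row indices
    anim_obs: list                # per data-animal: observed trait indices
    anim_ped: np.ndarray          # per data-animal: pedigree index
    animal_ids: np.ndarray        # pedigree IDs (length q)

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_eq(self) -> int:
        return self.n_fixed + self.n_traits * self.q

    def u_slice(self, t: int) -> slice:
        return slice(self.n_fixed + t * self.q, self.n_fixed + (t + 1) * self.q)


def build_design(ph: pd.DataFrame, ped, spec: ModelSpec) -> Design:
    """Build stacked incidence matrices and the observed-trait patterns.

    ``ph`` must carry ``animal, hatch_wy, sex`` plus one column per trait
    in ``spec.traits`` (NaN = missing).  Equations are ordered fixed
    effects first (trait-major), then breeding values (trait-major, all
    pedigree animals per trait), matching a ``G0 (x) K`` genetic prior.
    """
    traits = spec.traits
    ph = ph.copy()
    ph["animal"] = ph["animal"].astype(str)
    for trait in traits:
        if trait not in ph.columns:
            raise ValueError(f"phenotype table lacks trait column {trait!r}")
    # animals with no record on any analyzed trait never enter the design;
    # they may legitimately be absent from a pruned pedigree
    has_record = ph[list(traits)].notna().any(axis=1)
    ph = ph.loc[has_record].reset_index(drop=True)
    ped_idx = ped.index_of(ph["animal"])

    # per-trait fixed-effect design
    fixed_blocks = []
    fixed_labels = {}
    n_fixed = 0
    trait_fixed_info = []
    for t, trait in enumerate(traits):
        if trait not in ph.columns:
            raise ValueError(f"phenotype table lacks trait column {trait!r}")
        obs_mask = ph[trait].notna().to_numpy()
        hw = ph.loc[obs_mask, "hatch_wy"].astype(str)
        levels = sorted(hw.unique())
        labels = [("hatch_wy", lv) for lv in levels]
        cols = {lv: i for i, lv in enumerate(levels)}
        sex_col = None
        if trait in spec.sex_traits:
            sexes = sorted(ph.loc[obs_mask, "sex"].astype(str).unique())
            if len(sexes) > 1:
                # first sex level absorbed into the hatch levels (full-rank)
                for sx in sexes[1:]:
                    labels.append(("sex", sx))
                sex_col = {sx: len(cols) + i for i, sx in enumerate(sexes[1:])}
        fixed_labels[trait] = labels
        trait_fixed_info.append((obs_mask, cols, sex_col, n_fixed))
        n_fixed += len(labels)

    q = ped.n
    rows, cols_, vals = [], [], []
    y_parts, rec_animal, rec_trait = [], [], []

    # animal-major record ordering: iterate animals, then their traits
    order = np.argsort(ped_idx, kind="stable")
    row_counter = 0
    anim_rows, anim_obs, anim_ped_list = [], [], []
    obs_matrix = np.column_stack(
        [ph[t].notna().to_numpy() for t in traits]
    )
    values = np.column_stack([ph[t].to_numpy(dtype=float) for t in traits])
    hw_arr = ph["hatch_wy"].astype(str).to_numpy()
    sex_arr = ph["sex"].astype(str).to_numpy()

    for r in order:
        obs_t = np.flatnonzero(obs_matrix[r])
        if obs_t.size == 0:
            continue
        a = ped_idx[r]
        this_rows = []
        for t in obs_t:
            obs_mask, hcols, sex_col, offset = trait_fixed_info[t]
            hw = hw_arr[r]
            rows.append(row_counter)
            cols_.append(offset + hcols[hw])
            vals.append(1.0)
            if sex_col is not None:
                sx = sex_arr[r]
                if sx in sex_col:
                    rows.append(row_counter)
                    cols_.append(offset + sex_col[sx])
                    vals.append(1.0)
            rows.append(row_counter)
            cols_.append(n_fixed + t * q + a)
            vals.append(1.0)
            y_parts.append(values[r, t])
            rec_animal.append(a)
            rec_trait.append(t)
            this_rows.append(row_counter)
            row_counter += 1
        anim_rows.append(np.array(this_rows, dtype=np.int64))
        anim_obs.append(obs_t)
        anim_ped_list.append(a)

    n_eq = n_fixed + len(traits) * q
    W = sp.coo_matrix(
        (vals, (rows, cols_)), shape=(row_counter, n_eq)
    ).tocsr()
    return Design(
        W=W,
        y=np.array(y_parts, dtype=float),
        n_fixed=n_fixed,
        q=q,
        traits=traits,
        fixed_labels=fixed_labels,
        rec_animal=np.array(rec_animal, dtype=np.int64),
        rec_trait=np.array(rec_trait, dtype=np.int64),
        anim_rows=anim_rows,
        anim_obs=anim_obs,
        anim_ped=np.array(anim_ped_list, dtype=np.int64),
        animal_ids=ped.ids,
    )


# ---------------------------------------------------------------------------
# residual structure
# ---------------------------------------------------------------------------

def _pattern_groups(design: Design):
    """Group data animals by observed-trait pattern; cached on the design."""
    if not hasattr(design, "_patterns"):
        groups = {}
        for k, obs in enumerate(design.anim_obs):
            groups.setdefault(tuple(obs), []).append(k)
        design._patterns = {p: np.array(ix) for p, ix in groups.items()}
    return design._patterns


def _residual_inverse(design: Design, R0: np.ndarray) -> sp.csr_matrix:
    """Block-diagonal R^-1 over records, one ``R0[o,o]^-1`` per animal."""
    n = design.n_records
    rows, cols, vals = [], [], []
    for pattern, anim_ix in _pattern_groups(design).items():
        o = np.array(pattern)
        Rinv_blk = np.linalg.inv(R0[np.ix_(o, o)])
        m = o.size
        # record rows per animal in this pattern (all have m records)
        rr = np.stack([design.anim_rows[k] for k in anim_ix])  # (na, m)
        na = rr.shape[0]
        rows.append(np.repeat(rr, m, axis=1).ravel())
        cols.append(np.tile(rr, m).ravel())
        vals.append(np.tile(Rinv_blk.ravel(), na))
    R = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return R.tocsr()


def _assemble_mme(design: Design, kinship_inverse: sp.spmatrix,
                  G0: np.ndarray, R0: np.ndarray):
    """Coefficient matrix and right-hand side of Henderson's MME."""
    Rinv = _residual_inverse(design, R0)
    WtR = (design.W.T @ Rinv).tocsr()
    C = (WtR @ design.W).tocsr()
    G0inv = np.linalg.inv(G0)
    prior = sp.kron(sp.csr_matrix(G0inv), sp.csr_matrix(kinship_inverse))
    nf = design.n_fixed
    C = (C + sp.block_diag(
        [sp.csr_matrix((nf, nf)), prior], format="csr"
    )).tocsr()
    rhs = WtR @ design.y
    return C, rhs, Rinv


# ---------------------------------------------------------------------------
# BLUP solving
# ---------------------------------------------------------------------------

def _solution_set(design: Design, sol: np.ndarray, diagnostics: dict) -> SolutionSet:
    nf = design.n_fixed
    fixed = {}
    pos = 0
    for trait in design.traits:
        labels = design.fixed_labels[trait]
        fixed[trait] = pd.Series(
            sol[pos: pos + len(labels)],
            index=pd.MultiIndex.from_tuples(labels, names=["effect", "level"]),
        )
        pos += len(labels)
    U = sol[nf:].reshape(design.n_traits, design.q).T
    bv = pd.DataFrame(U, index=pd.Index(design.animal_ids, name="animal"),
                      columns=list(design.traits))
    return SolutionSet(fixed_solutions=fixed, breeding_values=bv,
                       diagnostics=diagnostics)


def solve_mme(design: Design, kinship_inverse: sp.spmatrix,
              vc: VarianceComponents, method: str = "auto",
              tol: float = 1e-10, max_iter: int = 5000) -> SolutionSet:
    """Solve Henderson's mixed-model equations for BLUP.

    ``method``: ``"direct"`` (sparse LU), ``"pcg"`` (Jacobi-preconditioned
    conjugate gradients), or ``"auto"`` (direct up to 20,000 equations).
    """
    G0 = vc.genetic
    R0 = vc.residual
    C, rhs, _ = _assemble_mme(design, kinship_inverse, G0, R0)
    if method == "auto":
        method = "direct" if design.n_eq <= 20000 else "pcg"
    if method == "direct":
        sol = spla.spsolve(C.tocsc(), rhs)
        iters = 0
    elif method == "pcg":
        d = C.diagonal()
        M = sp.diags(1.0 / np.where(d > 0, d, 1.0))
        count = {"n": 0}

        def _cb(_):
            count["n"] += 1

        sol, info = spla.cg(C, rhs, rtol=tol, maxiter=max_iter, M=M, callback=_cb)
        if info != 0:
            res = np.linalg.norm(C @ sol - rhs) / np.linalg.norm(rhs)
            raise ConvergenceError(
                f"PCG did not converge in {max_iter} iterations "
                f"(relative residual {res:.2e})"
            )
        iters = count["n"]
    else:
        raise ValueError(f"unknown solver method {method!r}")
    resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    return _solution_set(design, sol, {"method": method, "iterations": iters,
                                       "relative_residual": resid})


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _vech_indices(t: int):
    return [(r, s) for r in range(t) for s in range(r, t)]


def _mat_to_theta(G0, R0, t):
    ix = _vech_indices(t)
    return np.array([G0[r, s] for r, s in ix] + [R0[r, s] for r, s in ix])


def _theta_to_mat(theta, t):
    ix = _vech_indices(t)
    k = len(ix)
    G0 = np.zeros((t, t))
    R0 = np.zeros((t, t))
    for j, (r, s) in enumerate(ix):
        G0[r, s] = G0[s, r] = theta[j]
        R0[r, s] = R0[s, r] = theta[k + j]
    return G0, R0


def _is_pd(M, floor=1e-10):
    try:
        np.linalg.cholesky(M + 0.0)
    except np.linalg.LinAlgError:
        return False
    return np.all(np.diag(M) > floor)


def _canonical_ok(design: Design) -> bool:
    """True when the multi-trait MME block-diagonalizes exactly.

    Requires every data animal to have all traits recorded (one residual
    pattern) and identical per-trait fixed-effect structures, i.e. the
    incidence matrices are the same for every trait.  The coefficient
    matrix is then ``R0^-1 (x) M + G0^-1 (x) Ktilde`` and a congruence
    transform from the generalized eigendecomposition of ``(G0, R0)``
    reduces it to ``t`` independent single-trait-sized blocks.
    """
    if not hasattr(design, "_canonical_ok"):
        t = design.n_traits
        ok = t > 1
        if ok:
            full = np.arange(t)
            ok = all(np.array_equal(obs, full) for obs in design.anim_obs)
        if ok:
            labels = [design.fixed_labels[tr] for tr in design.traits]
            ok = all(lbl == labels[0] for lbl in labels[1:])
        design._canonical_ok = ok
    return design._canonical_ok


def _dense_pd_inverse(Cd: np.ndarray, what: str = "coefficient matrix"):
    """(inverse, factor) of a dense SPD matrix via LAPACK, minimal copies."""
    L, info = lapack.dpotrf(Cd, lower=1, overwrite_a=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"{what} not positive definite (info={info})")
    return L


class _RemlState:
    """One REML iteration's worth of shared computations."""

    def __init__(self, design: Design, Kinv: sp.csr_matrix, G0, R0):
        self.design = design
        self.G0, self.R0 = G0, R0
        t, q, nf = design.n_traits, design.q, design.n_fixed
        self._Cinv = None
        self._L = None
        self._Kinv = Kinv

        if _canonical_ok(design):
            rhs = self._init_canonical(Kinv, G0, R0)
        else:
            C, rhs, Rinv = _assemble_mme(design, Kinv, G0, R0)
            self.Rinv = Rinv
            Cd = C.toarray()
            self._L = _dense_pd_inverse(Cd, "MME coefficient matrix")
        sol = self.solve(rhs)
        self.sol = sol
        self.U = sol[nf:].reshape(t, q).T                      # q x t
        self.ehat = design.y - design.W @ sol
        self.estar = self.Rinv @ self.ehat

        # per-record row of estar by (data-animal, trait); -1 when absent
        self._rowmap = np.full((len(design.anim_rows), t), -1, dtype=np.int64)
        for k, (rr, obs) in enumerate(zip(design.anim_rows, design.anim_obs)):
            self._rowmap[k, obs] = rr

    def _init_canonical(self, Kinv, G0, R0) -> np.ndarray:
        """Exact block-diagonalization of the MME for equal-design traits.

        With ``C = R0^-1 (x) M + G0^-1 (x) Ktilde`` (per-trait ordering
        ``[fixed, u]``), the generalized eigendecomposition ``G0 Phi =
        R0 Phi Lam`` with ``Phi' R0 Phi = I`` gives, for ``Psi =
        inv(Phi)'``, ``(Psi (x) I)' C (Psi (x) I) = I (x) M +
        Lam^-1 (x) Ktilde``; the full inverse is re-assembled from ``t``
        single-trait-sized inverses.
        """
        d = self.design
        t, q, nf = d.n_traits, d.q, d.n_fixed
        nf1 = nf // t
        self.Rinv = _residual_inverse(d, R0)

        if not hasattr(d, "_canon_W1"):
            rows0 = np.flatnonzero(d.rec_trait == 0)
            cols = np.concatenate([np.arange(nf1),
                                   np.arange(nf + 0 * q, nf + q)])
            W1 = d.W[rows0][:, cols].tocsr()
            d._canon_W1 = W1
            d._canon_M0 = (W1.T @ W1).tocsr()
            # records of trait k, in the same animal order as trait 0
            d._canon_rows = [np.flatnonzero(d.rec_trait == k) for k in range(t)]
        W1 = d._canon_W1
        M0 = d._canon_M0

        lam, Phi = sla.eigh(G0, R0)
        Psi = np.linalg.inv(Phi).T
        n1 = nf1 + q
        Ktilde = sp.block_diag(
            [sp.csr_matrix((nf1, nf1)), sp.csr_matrix(Kinv)], format="csr"
        )
        Binvs = []
        for j in range(t):
            Bj = (M0 + (1.0 / lam[j]) * Ktilde).toarray()
            L = _dense_pd_inverse(Bj, "canonical MME block")
            inv, info = lapack.dpotri(L, lower=1, overwrite_c=1)
            if info != 0:
                raise np.linalg.LinAlgError("dpotri failed")
            Binvs.append(np.tril(inv) + np.tril(inv, -1).T)

        Cinv = np.empty((d.n_eq, d.n_eq))
        for r in range(t):
            for s in range(r, t):
                blk = np.zeros((n1, n1))
                for j in range(t):
                    blk += Psi[r, j] * Psi[s, j] * Binvs[j]
                self._scatter_block(Cinv, blk, r, s, nf1)
                if s != r:
                    self._scatter_block(Cinv, blk.T, s, r, nf1)
        self._Cinv = Cinv

        WtR = (d.W.T @ self.Rinv)
        return WtR @ d.y

    def _scatter_block(self, Cinv, blk, r, s, nf1):
        q, nf = self.design.q, self.design.n_fixed
        fr = slice(r * nf1, (r + 1) * nf1)
        fs = slice(s * nf1, (s + 1) * nf1)
        ur = self.design.u_slice(r)
        us = self.design.u_slice(s)
        Cinv[fr, fs] = blk[:nf1, :nf1]
        Cinv[fr, us] = blk[:nf1, nf1:]
        Cinv[ur, fs] = blk[nf1:, :nf1]
        Cinv[ur, us] = blk[nf1:, nf1:]

    def solve(self, B: np.ndarray) -> np.ndarray:
        if self._Cinv is not None:
            return self._Cinv @ B
        out, info = lapack.dpotrs(self._L, B, lower=1)
        return out

    def cinv(self) -> np.ndarray:
        """Dense inverse of the coefficient matrix (destroys the factor)."""
        if self._Cinv is None:
            inv, info = lapack.dpotri(self._L, lower=1, overwrite_c=1)
            if info != 0:
                raise np.linalg.LinAlgError("dpotri failed")
            inv = np.tril(inv) + np.tril(inv, -1).T
            self._Cinv = inv
            self._L = None
        return self._Cinv

    # ---- EM quantities -------------------------------------------------

    def em_matrices(self):
        """EM-update matrices: T_g / q for G0 and sum(T_i)/n for R0."""
        d = self.design
        t, q, nf = d.n_traits, d.q, d.n_fixed
        Kinv = self._Kinv
        Cinv = self.cinv()

        KU = Kinv @ self.U
        Tg = self.U.T @ KU
        Kcoo = Kinv.tocoo()
        for r in range(t):
            for s in range(r, t):
                blk = Cinv[d.u_slice(r), d.u_slice(s)]
                tr = float(Kcoo.data @ blk[Kcoo.col, Kcoo.row])
                Tg[r, s] += tr
                if s != r:
                    Tg[s, r] += tr

        R0 = self.R0
        Tr = np.zeros((t, t))
        n_anim = len(d.anim_rows)
        Wcsr = d.W
        for k in range(n_anim):
            rr = d.anim_rows[k]
            obs = d.anim_obs[k]
            m = obs.size
            # gather the nonzero columns of this animal's W rows
            idx_list, Wl_rows = [], []
            for row in rr:
                a, b = Wcsr.indptr[row], Wcsr.indptr[row + 1]
                idx_list.append(Wcsr.indices[a:b])
                Wl_rows.append(Wcsr.data[a:b])
            all_idx = np.unique(np.concatenate(idx_list))
            pos = {c: i for i, c in enumerate(all_idx)}
            Wl = np.zeros((m, all_idx.size))
            for i, (ix, vv) in enumerate(zip(idx_list, Wl_rows)):
                for c, v in zip(ix, vv):
                    Wl[i, pos[c]] = v
            Csub = Cinv[np.ix_(all_idx, all_idx)]
            e_o = self.ehat[rr]
            S = np.outer(e_o, e_o) + Wl @ Csub @ Wl.T

            if m == t:
                Tr += S
            else:
                o = obs
                mi = np.setdiff1d(np.arange(t), o)
                Roo = R0[np.ix_(o, o)]
                B = R0[np.ix_(mi, o)] @ np.linalg.inv(Roo)
                T = np.zeros((t, t))
                T[np.ix_(o, o)] = S
                BS = B @ S
                T[np.ix_(mi, o)] = BS
                T[np.ix_(o, mi)] = BS.T
                T[np.ix_(mi, mi)] = (
                    BS @ B.T + R0[np.ix_(mi, mi)] - B @ R0[np.ix_(o, mi)]
                )
                Tr += T
        return Tg / q, Tr / n_anim, q, n_anim

    # ---- AI quantities -------------------------------------------------

    def scores(self, Tg_mean, Tr_mean, q, n_anim):
        """REML score vector for vech(G0), vech(R0)."""
        t = self.design.n_traits
        G0inv = np.linalg.inv(self.G0)
        R0inv = np.linalg.inv(self.R0)
        Sg = -0.5 * (q * G0inv - G0inv @ (q * Tg_mean) @ G0inv)
        Sr = -0.5 * (n_anim * R0inv - R0inv @ (n_anim * Tr_mean) @ R0inv)
        out = []
        for M in (Sg, Sr):
            for r, s in _vech_indices(t):
                out.append(M[r, s] if r == s else 2.0 * M[r, s])
        return np.array(out)

    def ai_matrix(self):
        """Average-information matrix for vech(G0), vech(R0)."""
        d = self.design
        t, q, nf = d.n_traits, d.q, d.n_fixed
        ix = _vech_indices(t)
        n_par = 2 * len(ix)
        F = np.zeros((d.n_records, n_par))

        G0inv = np.linalg.inv(self.G0)
        # genetic parameters: f = Z (J_rs K) Z' P y = Z vec(U (J G0inv)')
        for j, (r, s) in enumerate(ix):
            J = np.zeros((t, t))
            J[r, s] = J[s, r] = 1.0
            fu = self.U @ (J @ G0inv).T          # q x t
            fvec = np.concatenate([np.zeros(nf), fu.T.ravel()])
            F[:, j] = d.W @ fvec

        # residual parameters: per record, J_rs applied to estar by trait
        est_by_trait = np.zeros((self._rowmap.shape[0], t))
        valid = self._rowmap >= 0
        est_by_trait[valid] = self.estar[self._rowmap[valid]]
        k0 = len(ix)
        for j, (r, s) in enumerate(ix):
            col = np.zeros(d.n_records)
            # records of trait r pick up estar of trait s (same animal), and
            # vice versa
            rows_r = self._rowmap[:, r]
            ok = rows_r >= 0
            col_vals = est_by_trait[ok, s]
            col[rows_r[ok]] += col_vals
            if s != r:
                rows_s = self._rowmap[:, s]
                ok = rows_s >= 0
                col[rows_s[ok]] += est_by_trait[ok, r]
            F[:, k0 + j] = col

        RF = self.Rinv @ F
        WtRF = (d.W.T @ RF)
        sol = self.solve(np.asfortranarray(WtRF))
        PF = self.Rinv @ (F - d.W @ sol)
        return 0.5 * (F.T @ PF)


def reml(design: Design, kinship_inverse: sp.spmatrix,
         start: VarianceComponents | None = None, method: str = "ai",
         max_iter: int = 500, tol: float = 1e-8,
         em_warmup: int = 3, verbose: bool = False) -> VarianceComponents:
    """Estimate genetic and residual covariances by REML.

    ``method="em"`` runs pure EM (slow, monotone, always in the parameter
    space); ``method="ai"`` (default) runs a few EM warm-up rounds and then
    AI Newton steps with step halving, falling back to EM whenever a step
    would leave the positive-definite cone.  Convergence is declared when
    the largest relative parameter change drops below ``tol``.

    Approximate standard errors come from the inverse AI matrix at the
    final estimates.
    """
    t = design.n_traits
    Kinv = sp.csr_matrix(kinship_inverse)
    if start is None:
        # split observed phenotypic variance 40/60 genetic/residual
        vp = np.array([
            np.nanvar(design.y[design.rec_trait == k]) for k in range(t)
        ])
        vp = np.where(vp > 0, vp, 1.0)
        start = VarianceComponents(
            genetic=np.diag(0.4 * vp), residual=np.diag(0.6 * vp),
            traits=design.traits,
        )
    G0 = start.genetic.copy()
    R0 = start.residual.copy()
    if not (_is_pd(G0) and _is_pd(R0)):
        raise ValueError("starting covariance matrices must be positive definite")

    scale = np.mean(np.diag(G0) + np.diag(R0))
    floor = 1e-8 * scale
    converged = False
    ai = None
    it = 0
    for it in range(1, max_iter + 1):
        state = _RemlState(design, Kinv, G0, R0)
        use_em = method == "em" or it <= em_warmup
        if use_em:
            Tg, Trm, q, n_anim = state.em_matrices()
            G0n, R0n = Tg.copy(), Trm.copy()
        else:
            ai = state.ai_matrix()
            Tg, Trm, q, n_anim = state.em_matrices()
            score = state.scores(Tg, Trm, q, n_anim)
            theta = _mat_to_theta(G0, R0, t)
            try:
                step = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(ai, score, rcond=None)[0]
            # step-halve into the PD cone
            lam = 1.0
            G0n = R0n = None
            for _ in range(30):
                cand = theta + lam * step
                Gc, Rc = _theta_to_mat(cand, t)
                if _is_pd(Gc, floor) and _is_pd(Rc, floor):
                    G0n, R0n = Gc, Rc
                    break
                lam *= 0.5
            if G0n is None:
                G0n, R0n = Tg.copy(), Trm.copy()   # EM fallback

        # boundary guard: clamp collapsing variances
        for M in (G0n, R0n):
            dg = np.diag(M).copy()
            low = dg < floor
            if low.any():
                logger.warning("variance component at boundary; clamped")
                dg[low] = floor
                M[np.diag_indices_from(M)] = dg

        rel = np.max(
            np.abs(_mat_to_theta(G0n, R0n, t) - _mat_to_theta(G0, R0, t))
            / max(scale, 1e-300)
        )
        G0, R0 = G0n, R0n
        if verbose:
            logger.info("REML iter %d (%s): rel change %.3e, h2 ~ %s",
                        it, "EM" if use_em else "AI", rel,
                        np.diag(G0) / (np.diag(G0) + np.diag(R0)))
        if rel < tol and it > em_warmup:
            converged = True
            break

    if not converged:
        logger.warning("REML did not reach tol %.1e in %d iterations", tol, max_iter)

    se = None
    cov = None
    if method == "ai":
        state = _RemlState(design, Kinv, G0, R0)
        ai = state.ai_matrix()
        try:
            cov = np.linalg.inv(ai)
            names = ([f"G[{r},{s}]" for r, s in _vech_indices(t)]
                     + [f"R[{r},{s}]" for r, s in _vech_indices(t)])
            se = {nm: float(np.sqrt(max(v, 0.0)))
                  for nm, v in zip(names, np.diag(cov))}
        except np.linalg.LinAlgError:
            se = cov = None

    return VarianceComponents(
        genetic=G0, residual=R0, traits=design.traits,
        se_approx=se, converged=converged, iterations=it, param_cov=cov,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def heritability(vc: VarianceComponents, trait: str) -> float:
    """Narrow-sense heritability: genetic / (genetic + residual) variance."""
    i = vc.trait_index(trait)
    vg, ve = vc.genetic[i, i], vc.residual[i, i]
    if vg + ve == 0:
        raise ValueError("zero total variance")
    return float(vg / (vg + ve))


def genetic_correlations(vc: VarianceComponents) -> np.ndarray:
    """Genetic correlation matrix ``R_ij / sqrt(R_ii R_jj)``."""
    d = np.sqrt(np.diag(vc.genetic))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = vc.genetic / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def _param_gradient_se(vc: VarianceComponents, grad: dict) -> float:
    """Delta-method SE from the AI parameter covariance.

    ``grad`` maps parameter names (``G[i,j]`` / ``R[i,j]``, upper
    triangle) to partial derivatives.
    """
    if vc.param_cov is None:
        raise ValueError("no AI parameter covariance available (EM-only fit?)")
    t = len(vc.traits)
    names = ([f"G[{r},{s}]" for r, s in _vech_indices(t)]
             + [f"R[{r},{s}]" for r, s in _vech_indices(t)])
    g = np.array([grad.get(nm, 0.0) for nm in names])
    var = float(g @ np.asarray(vc.param_cov) @ g)
    return float(np.sqrt(max(var, 0.0)))


def heritability_se(vc: VarianceComponents, trait: str) -> float:
    """Approximate (delta-method) standard error of a heritability."""
    i = vc.trait_index(trait)
    vg, ve = vc.genetic[i, i], vc.residual[i, i]
    tot2 = (vg + ve) ** 2
    return _param_gradient_se(vc, {
        f"G[{i},{i}]": ve / tot2,
        f"R[{i},{i}]": -vg / tot2,
    })


def genetic_correlation_se(vc: VarianceComponents, trait_a: str,
                           trait_b: str) -> float:
    """Approximate (delta-method) standard error of a genetic correlation."""
    i, j = sorted((vc.trait_index(trait_a), vc.trait_index(trait_b)))
    if i == j:
        raise ValueError("need two distinct traits")
    gii, gjj, gij = vc.genetic[i, i], vc.genetic[j, j], vc.genetic[i, j]
    denom = np.sqrt(gii * gjj)
    return _param_gradient_se(vc, {
        f"G[{i},{j}]": 1.0 / denom,
        f"G[{i},{i}]": -0.5 * gij / (gii * denom),
        f"G[{j},{j}]": -0.5 * gij / (gjj * denom),
    })
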