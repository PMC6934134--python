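"""Pedigree handling, inbreeding, and numerator relationship matrices.

The numerator relationship matrix ``A`` describes expected additive genetic
relationships among animals given a pedigree.  This module builds the pieces
a single-step evaluation needs:

* per-animal inbreeding coefficients ``F`` (``diag(A) = 1 + F``);
* the dense tabular ``A`` (and principal submatrices such as ``A22``, the
  block for genotyped animals);
* the sparse inverse ``A^-1`` via Henderson's rules with Mendelian-sampling
  variances adjusted for parental inbreeding.

Animals are renumbered internally to dense integer indices in topological
order (parents before offspring); original string identifiers are retained
on the :class:`Pedigree` and on exported ID maps.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Sentinel index used for an unknown parent.
UNKNOWN = -1

#: Strings interpreted as "parent unknown" in pedigree files.
_MISSING_CODES = {"", "0", "na", "nan", "none", ".", "-"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """A topologically sorted pedigree.

    Attributes
    ----------
    ids
        Animal identifiers, in topological order (parents precede offspring).
    sire, dam
        Integer indices into ``ids`` (``UNKNOWN`` = -1 for unknown parents).
    cohort
        Per-animal cohort label (hatch week-year), ``""`` if absent.
    sex
        Per-animal sex, ``"M"``/``"F"`` or ``""`` if absent.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    cohort: np.ndarray = field(default=None)
    sex: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.ids)
        if self.cohort is None:
            self.cohort = np.full(n, "", dtype=object)
        if self.sex is None:
            self.sex = np.full(n, "", dtype=object)
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != n:
            dup = pd.Series(self.ids).value_counts()
            raise PedigreeError(
                f"duplicate animal IDs: {list(dup.index[dup > 1])[:5]}"
            )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Map external animal IDs to internal integer indices."""
        try:
            return np.array([self._index[str(a)] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal ID not in pedigree: {exc.args[0]!r}") from None

    @property
    def founders(self) -> np.ndarray:
        """Boolean mask of animals with both parents unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        """Return the pedigree as a DataFrame with original string IDs."""
        sid = np.where(self.sire == UNKNOWN, "0", self.ids[np.clip(self.sire, 0, None)])
        did = np.where(self.dam == UNKNOWN, "0", self.ids[np.clip(self.dam, 0, None)])
        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": sid,
                "dam": did,
                "hatch_wy": self.cohort,
                "sex": self.sex,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def prune(self, keep_ids) -> "Pedigree":
        """Restrict to ``keep_ids`` and all their ancestors.

        Evaluations only need the part of the pedigree that is connected to
        phenotyped or genotyped animals; the rest contributes nothing to the
        mixed-model equations.
        """
        keep = np.zeros(self.n, dtype=bool)
        keep[self.index_of(keep_ids)] = True
        # ids are topologically sorted, so one backwards sweep reaches all
        # ancestors
        for i in range(self.n - 1, -1, -1):
            if keep[i]:
                if self.sire[i] != UNKNOWN:
                    keep[self.sire[i]] = True
                if self.dam[i] != UNKNOWN:
                    keep[self.dam[i]] = True
        idx = np.flatnonzero(keep)
        remap = np.full(self.n, UNKNOWN, dtype=np.int64)
        remap[idx] = np.arange(len(idx))

        def _remap_parent(p):
            return np.where(p[idx] == UNKNOWN, UNKNOWN, remap[np.clip(p[idx], 0, None)])

        logger.info("pedigree pruned from %d to %d animals", self.n, len(idx))
        return Pedigree(
            ids=self.ids[idx],
            sire=_remap_parent(self.sire),
            dam=_remap_parent(self.dam),
            cohort=self.cohort[idx],
            sex=self.sex[idx],
        )


def _normalize_parent(value) -> str | None:
    s = str(value).strip()
    if s.lower() in _MISSING_CODES:
        return None
    return s


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    """Build a topologically sorted :class:`Pedigree` from a DataFrame.

    Expects columns ``animal, sire, dam`` and optionally ``hatch_wy, sex``.
    Parents that never appear as animals are added as founder records.
    Raises :class:`PedigreeError` on duplicate animals or ancestry cycles.
    """
    required = {"animal", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {sorted(missing)}")

    animals = [str(a).strip() for a in df["animal"]]
    if len(set(animals)) != len(animals):
        counts = pd.Series(animals).value_counts()
        raise PedigreeError(
            f"duplicate animal IDs: {list(counts.index[counts > 1])[:5]}"
        )
    sires = [_normalize_parent(s) for s in df["sire"]]
    dams = [_normalize_parent(d) for d in df["dam"]]
    cohort = (
        [str(c) for c in df["hatch_wy"]] if "hatch_wy" in df.columns else [""] * len(animals)
    )
    sex = [str(s) for s in df["sex"]] if "sex" in df.columns else [""] * len(animals)

    known = set(animals)
    # parents never listed as animals become implicit founders
    implicit = []
    for p in sires + dams:
        if p is not None and p not in known:
            known.add(p)
            implicit.append(p)
    if implicit:
        logger.info("added %d implicit founder records for unlisted parents", len(implicit))

    all_ids = implicit + animals
    parent_of = {}
    meta = {}
    for a in implicit:
        parent_of[a] = (None, None)
        meta[a] = ("", "")
    for a, s, d, c, x in zip(animals, sires, dams, cohort, sex):
        if s == a or d == a:
            raise PedigreeError(f"animal {a!r} is listed as its own parent")
        parent_of[a] = (s, d)
        meta[a] = (c, x)

    order = _topological_order(all_ids, parent_of)
    # canonical ordering independent of input row order: generation depth
    # (longest ancestral path), ties broken by ID
    depth = {}
    for a in order:
        s, d = parent_of[a]
        depth[a] = 1 + max(
            depth.get(s, -1) if s is not None else -1,
            depth.get(d, -1) if d is not None else -1,
        )
    order = sorted(order, key=lambda a: (depth[a], str(a)))
    pos = {a: i for i, a in enumerate(order)}

    n = len(order)
    sire_idx = np.full(n, UNKNOWN, dtype=np.int64)
    dam_idx = np.full(n, UNKNOWN, dtype=np.int64)
    coh = np.full(n, "", dtype=object)
    sx = np.full(n, "", dtype=object)
    for a in order:
        i = pos[a]
        s, d = parent_of[a]
        if s is not None:
            sire_idx[i] = pos[s]
        if d is not None:
            dam_idx[i] = pos[d]
        coh[i], sx[i] = meta[a]

    if list(order) != all_ids:
        logger.warning("pedigree rows were not parent-first; sorted topologically")
    return Pedigree(
        ids=np.array(order, dtype=object), sire=sire_idx, dam=dam_idx, cohort=coh, sex=sx
    )


def _topological_order(ids, parent_of) -> list:
    """Depth-first topological sort; reports the offending chain on a cycle."""
    WHITE, GREY, BLACK = 0, 1, 2
    state = {a: WHITE for a in ids}
    order = []
    for root in ids:
        if state[root] != WHITE:
            continue
        # iterative DFS to survive deep pedigrees
        stack = [(root, False)]
        path = []
        while stack:
            node, done = stack.pop()
            if done:
                path.pop()
                state[node] = BLACK
                order.append(node)
                continue
            if state[node] == BLACK:
                continue
            if state[node] == GREY:
                chain = path[path.index(node):] + [node]
                raise PedigreeError(
                    "pedigree cycle detected: " + " -> ".join(map(str, chain))
                )
            state[node] = GREY
            path.append(node)
            stack.append((node, True))
            for p in parent_of[node]:
                if p is not None and state[p] != BLACK:
                    if state[p] == GREY:
                        chain = path[path.index(p):] + [p]
                        raise PedigreeError(
                            "pedigree cycle detected: " + " -> ".join(map(str, chain))
                        )
                    stack.append((p, False))
    return order


def read_pedigree(path, **read_csv_kwargs) -> Pedigree:
    """Read a pedigree CSV (columns ``animal,sire,dam[,hatch_wy,sex]``).

    Unknown parents may be coded ``0``, empty, ``NA`` or ``.``.  Rows may be
    in any order; the result is always topologically sorted.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **read_csv_kwargs)
    df.columns = [c.strip().lower() for c in df.columns]
    return pedigree_from_frame(df)


# ---------------------------------------------------------------------------
# Inbreeding
# ---------------------------------------------------------------------------

def inbreeding(ped: Pedigree, method: str = "auto") -> np.ndarray:
    """Per-animal inbreeding coefficients ``F``.

    ``method`` is ``"tabular"`` (dense ``A`` recursion, quadratic memory),
    ``"recursive"`` (a Meuwissen–Luo-style sparse-``L`` traversal, linear
    memory) or ``"auto"`` (tabular up to 5,000 animals, recursive above).
    The two methods agree to machine precision; the split point only trades
    memory for speed.
    """
    if method == "auto":
        method = "tabular" if ped.n <= 5000 else "recursive"
    if method == "tabular":
        return np.ascontiguousarray(np.diag(a_matrix(ped)) - 1.0)
    if method == "recursive":
        return _inbreeding_meuwissen_luo(ped)
    raise ValueError(f"unknown inbreeding method {method!r}")


def _ml_step(i: int, sire, dam, F, d) -> None:
    """One animal's inbreeding by the recursive (Meuwissen–Luo-style) rule.

    Fills ``F[i]`` and the Mendelian sampling variance ``d[i]`` given that
    both are known for all earlier (ancestral) indices.  ``A_ii`` is
    accumulated as ``sum_j L_ij^2 d_j`` with the L-row generated lazily
    over ancestors only, so memory stays linear in pedigree size.
    """
    s, p = sire[i], dam[i]
    if s == UNKNOWN and p == UNKNOWN:
        d[i] = 1.0
        F[i] = 0.0
        return
    if s == UNKNOWN or p == UNKNOWN:
        k = s if s != UNKNOWN else p
        d[i] = 0.75 - 0.25 * F[k]
    else:
        d[i] = 0.5 - 0.25 * (F[s] + F[p])
    L = {i: 1.0}
    aii = 0.0
    # process ancestors in decreasing index order (parents precede
    # offspring, so a max-heap over indices works)
    heap = [-i]
    in_heap = {i}
    while heap:
        j = -heapq.heappop(heap)
        lj = L.pop(j)
        aii += lj * lj * d[j]
        for par in (sire[j], dam[j]):
            if par != UNKNOWN:
                L[par] = L.get(par, 0.0) + 0.5 * lj
                if par not in in_heap:
                    heapq.heappush(heap, -par)
                    in_heap.add(par)
        in_heap.discard(j)
    F[i] = aii - 1.0


def _inbreeding_meuwissen_luo(ped: Pedigree) -> np.ndarray:
    n = ped.n
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        _ml_step(i, ped.sire, ped.dam, F, d)
    return F


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Memory is quadratic in pedigree size; intended for pedigrees up to a few
    tens of thousands of animals.  For subsets of large pedigrees use
    :func:`a_submatrix`, which prunes first.
    """
    n = ped.n
    if n > 30000:
        raise MemoryError(
            f"tabular A for {n} animals would need "
            f"{n * n * 8 / 1e9:.1f} GB; prune the pedigree first"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, p = sire[i], dam[i]
        if s != UNKNOWN and p != UNKNOWN:
            A[i, :i] = 0.5 * (A[s, :i] + A[p, :i])
            A[i, i] = 1.0 + 0.5 * A[s, p]
        elif s != UNKNOWN or p != UNKNOWN:
            k = s if s != UNKNOWN else p
            A[i, :i] = 0.5 * A[k, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def a_submatrix(ped: Pedigree, subset_ids) -> np.ndarray:
    """Dense block of ``A`` for ``subset_ids`` (e.g. ``A22`` for genotyped).

    The pedigree is pruned to the subset's ancestors before the tabular
    recursion, so the cost depends on ancestry size, not total pedigree size.
    Diagonals equal ``1 + F`` for each subset animal.
    """
    subset_ids = [str(a) for a in subset_ids]
    sub = ped.prune(subset_ids)
    A = a_matrix(sub)
    idx = sub.index_of(subset_ids)
    return np.ascontiguousarray(A[np.ix_(idx, idx)])


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse ``A^-1`` by Henderson's rules, accounting for inbreeding.

    Each animal contributes at most 9 entries built from the inverse of its
    Mendelian sampling variance ``d_i``:

    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one, and ``1`` for founders.
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    sire, dam = ped.sire, ped.dam

    both = (sire != UNKNOWN) & (dam != UNKNOWN)
    one = (sire != UNKNOWN) ^ (dam != UNKNOWN)
    known_one = np.where(sire != UNKNOWN, sire, dam)

    d = np.ones(n)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    d[one] = 0.75 - 0.25 * F[known_one[one]]
    alpha = 1.0 / d

    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    idx = np.arange(n)
    add(idx, idx, alpha)  # (i,i)

    for parents, weight in ((sire, 0.5), (dam, 0.5)):
        m = parents != UNKNOWN
        p = parents[m]
        a = alpha[m]
        i = idx[m]
        add(i, p, -weight * a)
        add(p, i, -weight * a)
        add(p, p, weight * weight * a)
    # cross sire-dam term
    m = both
    s, p, a, i = sire[m], dam[m], alpha[m], idx[m]
    add(s, p, 0.25 * a)
    add(p, s, 0.25 * a)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def write_id_map(path, ids) -> None:
    """Write a two-column ``index,animal`` CSV mapping matrix rows to IDs."""
    pd.DataFrame({"index": np.arange(len(ids)), "animal": ids}).to_csv(path, index=False)
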