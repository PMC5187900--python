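"""Pedigree bookkeeping and additive (numerator) relationship computation.

The animal model used throughout this package needs the additive
relationship matrix A, its sparse inverse, and per-animal inbreeding
coefficients. A is built with the tabular method,

    a_ii = 1 + 0.5 * a(sire, dam)          (unknown parents contribute 0)
    a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))   for j preceding i,

and A^-1 directly with Henderson's rules, using Mendelian-sampling
variances adjusted for parental inbreeding (d_i = 1/2 - 1/4 (F_s + F_d)).
Unknown parents are treated as unrelated, non-inbred base-population
founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

#: Sentinel for an unknown parent / litter in files and records.
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    animal: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    cohort: int = 0
    litter: str = UNKNOWN
    sex: str = "U"  # 'M', 'F' or 'U'


@dataclass
class Pedigree:
    """An ordered collection of pedigree records.

    Invariants enforced at construction: unique animal ids, every named
    parent present as an animal record, no animal its own ancestor.
    """

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.animal for r in self.records]

    def index(self) -> dict[str, int]:
        return {r.animal: i for i, r in enumerate(self.records)}

    def validate(self) -> None:
        ids = [r.animal for r in self.records]
        idset = set(ids)
        if len(idset) != len(ids):
            seen, dups = set(), []
            for a in ids:
                if a in seen:
                    dups.append(a)
                seen.add(a)
            raise PedigreeError(f"duplicate animal ids: {dups[:5]}")
        for r in self.records:
            for parent in (r.sire, r.dam):
                if parent != UNKNOWN and parent not in idset:
                    raise PedigreeError(
                        f"animal {r.animal!r} references undefined parent {parent!r}"
                    )
            if r.animal in (r.sire, r.dam):
                raise PedigreeError(f"animal {r.animal!r} is its own parent")

    def is_sorted(self) -> bool:
        pos = self.index()
        for r in self.records:
            for parent in (r.sire, r.dam):
                if parent != UNKNOWN and pos[parent] > pos[r.animal]:
                    return False
        return True

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of sire/dam positions, -1 for unknown. Requires sorted."""
        pos = self.index()
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.sire != UNKNOWN:
                out[i, 0] = pos[r.sire]
            if r.dam != UNKNOWN:
                out[i, 1] = pos[r.dam]
        return out


@dataclass
class RelationshipMatrix:
    """Additive relationships a_ij over a fixed animal order."""

    order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.order)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match order")

    def loc(self, a: str, b: str) -> float:
        pos = {x: i for i, x in enumerate(self.order)}
        return float(self.values[pos[a], pos[b]])


def _find_cycle(records: Sequence[PedigreeRecord]) -> list[str]:
    """Return one id chain forming a parent cycle (for error reporting)."""
    parents = {r.animal: [p for p in (r.sire, r.dam) if p != UNKNOWN] for r in records}
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {a: WHITE for a in parents}
    stack: list[str] = []

    def dfs(a: str) -> list[str] | None:
        color[a] = GRAY
        stack.append(a)
        for p in parents[a]:
            if color[p] == GRAY:
                return stack[stack.index(p):] + [p]
            if color[p] == WHITE:
                found = dfs(p)
                if found:
                    return found
        stack.pop()
        color[a] = BLACK
        return None

    for a in parents:
        if color[a] == WHITE:
            found = dfs(a)
            if found:
                return found
    return []


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so every parent precedes its offspring.

    An already-sorted pedigree is returned unchanged; otherwise ties
    (animals simultaneously available) break by (cohort, animal id),
    making the order deterministic. Raises :class:`PedigreeError` with the
    offending id chain if the parentage graph is cyclic.
    """
    if ped.is_sorted():
        return ped
    records = {r.animal: r for r in ped.records}
    n_parents = {a: 0 for a in records}
    children: dict[str, list[str]] = {a: [] for a in records}
    for r in ped.records:
        for p in (r.sire, r.dam):
            if p != UNKNOWN:
                n_parents[r.animal] += 1
                children[p].append(r.animal)

    import heapq

    ready = [(records[a].cohort, a) for a, k in n_parents.items() if k == 0]
    heapq.heapify(ready)
    out: list[PedigreeRecord] = []
    while ready:
        _, a = heapq.heappop(ready)
        out.append(records[a])
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                heapq.heappush(ready, (records[c].cohort, c))
    if len(out) != len(records):
        chain = _find_cycle(ped.records)
        raise PedigreeError(f"pedigree contains a parentage cycle: {' -> '.join(chain)}")
    if [r.animal for r in out] == [r.animal for r in ped.records]:
        return ped
    return Pedigree(out)


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix A by the tabular method."""
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    n = len(ped)
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return RelationshipMatrix(ped.ids, A)


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """F_i = a_ii - 1, in pedigree (sorted) order."""
    A = additive_relationship_matrix(ped)
    return np.diag(A.values) - 1.0


def a_inverse(ped: Pedigree, f: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 via Henderson's rules with inbreeding adjustment.

    The Mendelian-sampling variance of animal i is
    d_i = 1/2 - 1/4 (F_s + F_d) when both parents are known,
    3/4 - 1/4 F_p with one known parent p, and 1 for founders.
    """
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    n = len(ped)
    par = ped.parent_indices()
    if f is None:
        f = inbreeding_coefficients(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (f[s] + f[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * f[p]
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        known = [p for p in (s, d) if p >= 0]
        for p in known:
            for q in known:
                add(p, q, alpha / 4.0)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv


def gene_drop_relationships(
    ped: Pedigree,
    n_replicates: int = 100_000,
    seed: int = 0,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of additive relationships by gene dropping.

    Each founder receives two unique alleles; alleles descend by random
    Mendelian transmission. a_ij is estimated as twice the mean
    identity-by-descent probability over the four allele pairings of
    animals i and j (for i == j, as 1 + P(the two alleles of i are IBD)).

    Independent of the tabular recursion, so it serves as a cross-check.
    With ``pairs`` given (index pairs into the sorted order), returns
    (estimates, standard errors) for those pairs only; otherwise full
    (A_hat, SE) matrices.
    """
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    n = len(ped)
    par = ped.parent_indices()
    rng = np.random.default_rng(seed)
    R = n_replicates
    # allele labels per animal per replicate: (n, R) x 2 chromosomes
    pat = np.zeros((n, R), dtype=np.int32)
    mat = np.zeros((n, R), dtype=np.int32)
    next_label = 0
    for i in range(n):
        s, d = par[i]
        if s >= 0:
            pick = rng.integers(0, 2, R, dtype=np.int8).astype(bool)
            pat[i] = np.where(pick, pat[s], mat[s])
        else:
            pat[i] = next_label
            next_label += 1
        if d >= 0:
            pick = rng.integers(0, 2, R, dtype=np.int8).astype(bool)
            mat[i] = np.where(pick, pat[d], mat[d])
        else:
            mat[i] = next_label
            next_label += 1

    def estimate(i: int, j: int) -> tuple[float, float]:
        if i == j:
            ibd = 0.5 * (1.0 + (pat[i] == mat[i]))
        else:
            ibd = (
                (pat[i] == pat[j]).astype(np.float64)
                + (pat[i] == mat[j])
                + (mat[i] == pat[j])
                + (mat[i] == mat[j])
            ) / 4.0
        return 2.0 * float(ibd.mean()), 2.0 * float(ibd.std(ddof=1)) / np.sqrt(R)

    if pairs is not None:
        est = np.zeros(len(pairs))
        se = np.zeros(len(pairs))
        for k, (i, j) in enumerate(pairs):
            est[k], se[k] = estimate(i, j)
        return est, se

    A_hat = np.zeros((n, n))
    SE = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            a, s_ = estimate(i, j)
            A_hat[i, j] = A_hat[j, i] = a
            SE[i, j] = SE[j, i] = s_
    return A_hat, SE
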