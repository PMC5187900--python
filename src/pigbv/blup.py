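"""Pedigree BLUP via Henderson's mixed-model equations.

Single-trait animal model:

    y = X b + Z u + e,   u ~ N(0, A sigma2_a),  e ~ N(0, I sigma2_e)

solved from  [X'X  X'Z; Z'X  Z'Z + lambda A^-1] [b; u] = [X'y; Z'y]
with lambda = sigma2_e / sigma2_a. The multitrait model uses the
G0^-1 (x) A^-1 structure, and per-animal missing traits are handled by
inverting only the observed-trait residual block of R0 for each animal.

Fixed effects default to intercept + cohort + batch; identifiability is
restored by zeroing the first level of each factor and any remaining
linearly dependent columns (batch is nested within cohort in the
synthetic design, so nested-level columns are dropped and reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .simulate import (
    PERFORMANCE_TRAITS,
    GeneticArchitecture,
    ScenarioBundle,
)


class ModelError(ValueError):
    pass


def _solve_spd(C: sp.spmatrix, rhs: np.ndarray) -> np.ndarray:
    """Direct sparse solve of the (symmetric positive-definite) MME."""
    lu = splu(C, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))
    return lu.solve(rhs)


@dataclass
class VarianceComponents:
    """Additive (G0) and residual (R0) covariance over an ordered trait set."""

    traits: list[str]
    G0: np.ndarray
    R0: np.ndarray

    def __post_init__(self) -> None:
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        self.R0 = np.atleast_2d(np.asarray(self.R0, dtype=float))
        k = len(self.traits)
        for name, M in (("G0", self.G0), ("R0", self.R0)):
            if M.shape != (k, k):
                raise ModelError(f"{name} must be {k}x{k}")
            if not np.allclose(M, M.T, atol=1e-10):
                raise ModelError(f"{name} not symmetric")
            if np.linalg.eigvalsh(M).min() <= 0:
                raise ModelError(f"{name} not positive definite")

    @classmethod
    def from_architecture(
        cls,
        arch: GeneticArchitecture,
        traits: Sequence[str],
        polygenic_only: bool = False,
    ) -> "VarianceComponents":
        """Model (co)variances implied by the generating architecture.

        By default G0 is the *total* genetic covariance (polygenic plus
        major loci): a pedigree-only model treats unobserved major loci as
        part of the polygene. With ``polygenic_only`` the major-locus
        contribution is removed — the right animal-effect variance when
        the marker genotypes are fitted explicitly (marker-assisted BLUP).
        """
        idx = [arch.traits.index(t) for t in traits]
        full = arch.polygenic_cov() if polygenic_only else arch.total_genetic_cov()
        G = full[np.ix_(idx, idx)]
        R = arch.residual_cov()[np.ix_(idx, idx)]
        return cls(list(traits), G, R)

    def single(self, trait: str) -> tuple[float, float]:
        i = self.traits.index(trait)
        return float(self.G0[i, i]), float(self.R0[i, i])

    def subset(self, traits: Sequence[str]) -> "VarianceComponents":
        idx = [self.traits.index(t) for t in traits]
        return VarianceComponents(
            list(traits), self.G0[np.ix_(idx, idx)], self.R0[np.ix_(idx, idx)]
        )


@dataclass
class FixedDesign:
    """Fixed-effect design matrix with constraint bookkeeping."""

    matrix: np.ndarray
    columns: list[tuple[str, str]]        # (factor, level); ("intercept", "")
    dropped: list[tuple[str, str]]        # levels constrained to zero

    def solutions(self, beta: np.ndarray) -> dict[tuple[str, str], float]:
        out = {c: float(b) for c, b in zip(self.columns, beta)}
        out.update({c: 0.0 for c in self.dropped})
        return out


def build_fixed_design(
    covars: pd.DataFrame, factors: Sequence[str] = ("cohort", "batch")
) -> FixedDesign:
    """Intercept + dummy columns per factor, first level zeroed.

    Any column that is linearly dependent on preceding ones (e.g. nested
    factor levels) is additionally constrained to zero and reported in
    ``dropped``.
    """
    n = len(covars)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[tuple[str, str]] = [("intercept", "")]
    dropped: list[tuple[str, str]] = []
    for f in factors:
        if f not in covars.columns:
            continue
        levels = sorted(covars[f].astype(str).unique())
        if not levels:
            continue
        dropped.append((f, levels[0]))
        for lv in levels[1:]:
            cols.append((covars[f].astype(str) == lv).to_numpy(dtype=float))
            labels.append((f, lv))
    X = np.column_stack(cols)
    # greedy rank filter, deterministic in column order
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            dropped.append(labels[j])
    return FixedDesign(X[:, keep], [labels[j] for j in keep], dropped)


@dataclass
class BreedingValueEstimate:
    """Per-animal, per-trait EBVs plus fixed-effect solutions and labels."""

    ebv: pd.DataFrame                  # index animal, columns traits
    fixed: dict[str, dict[tuple[str, str], float]]   # trait -> solutions
    method: str = ""
    scenario: str = ""
    diagnostics: dict = field(default_factory=dict)


def _incidence(animals: Sequence[str], order: Sequence[str]) -> sp.csr_matrix:
    pos = {a: i for i, a in enumerate(order)}
    rows = np.arange(len(animals))
    cols = np.array([pos[a] for a in animals])
    return sp.csr_matrix(
        (np.ones(len(animals)), (rows, cols)), shape=(len(animals), len(order))
    )


def solve_mme_single(
    records: pd.DataFrame,
    trait: str,
    a_inv: sp.spmatrix,
    order: Sequence[str],
    sigma2_a: float,
    sigma2_e: float,
    factors: Sequence[str] = ("cohort", "batch"),
) -> BreedingValueEstimate:
    """Solve the single-trait animal model MME.

    ``records`` is indexed by animal id with the trait column and factor
    columns; rows with a missing trait value are ignored. EBVs are
    returned for every animal in ``order`` (tied in through A^-1).
    """
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ModelError("variances must be positive")
    obs = records[records[trait].notna()]
    if len(obs) == 0:
        nres = pd.DataFrame(0.0, index=list(order), columns=[trait])
        return BreedingValueEstimate(nres, {trait: {}}, diagnostics={"n_records": 0})
    missing = set(obs.index) - set(order)
    if missing:
        raise ModelError(f"phenotyped animals not in pedigree: {sorted(missing)[:5]}")
    lam = sigma2_e / sigma2_a
    design = build_fixed_design(obs, factors)
    X = sp.csr_matrix(design.matrix)
    Z = _incidence(list(obs.index), order)
    y = obs[trait].to_numpy(dtype=float)
    C = sp.bmat(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * a_inv.tocsc()],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = _solve_spd(C, rhs)
    p = X.shape[1]
    ebv = pd.DataFrame(sol[p:], index=list(order), columns=[trait])
    return BreedingValueEstimate(
        ebv,
        {trait: design.solutions(sol[:p])},
        diagnostics={"n_records": len(obs), "dropped_levels": design.dropped},
    )


def solve_mme_multi(
    records: pd.DataFrame,
    varcomp: VarianceComponents,
    a_inv: sp.spmatrix,
    order: Sequence[str],
    factors: Sequence[str] = ("cohort", "batch"),
) -> BreedingValueEstimate:
    """Multitrait MME with per-animal missing-trait patterns.

    For each data animal only the observed-trait block of R0 is inverted,
    so animals recorded for (say) BW/BF but not fatty acids still
    contribute through the genetic covariance.
    """
    traits = varcomp.traits
    k = len(traits)
    obs_any = records[records[traits].notna().any(axis=1)]
    if len(obs_any) == 0:
        raise ModelError("no records for any model trait")
    n_data = len(obs_any)
    Yn = obs_any[traits].to_numpy(dtype=float)
    Ymask = ~np.isnan(Yn)
    Y0 = np.where(Ymask, Yn, 0.0)

    # per-animal scattered inverse residual blocks, grouped by pattern
    E = np.zeros((n_data, k, k))
    patterns = {}
    for i in range(n_data):
        key = tuple(Ymask[i])
        if key not in patterns:
            o = np.flatnonzero(Ymask[i])
            Einv = np.zeros((k, k))
            if o.size:
                Einv[np.ix_(o, o)] = np.linalg.inv(varcomp.R0[np.ix_(o, o)])
            patterns[key] = Einv
        E[i] = patterns[key]

    designs = []
    for t_i, t in enumerate(traits):
        designs.append(build_fixed_design(obs_any[Ymask[:, t_i]], factors))
    # expand each trait design to all data-animal rows (zero weight elsewhere)
    Xfull = []
    for t_i, t in enumerate(traits):
        d = designs[t_i]
        Xt = np.zeros((n_data, d.matrix.shape[1]))
        Xt[Ymask[:, t_i]] = d.matrix
        Xfull.append(sp.csr_matrix(Xt))

    Z = _incidence(list(obs_any.index), order)
    n_ped = len(order)
    Ginv = np.linalg.inv(varcomp.G0)
    a_inv = a_inv.tocsc()

    def D(kk: int, ll: int) -> sp.dia_matrix:
        return sp.diags(E[:, kk, ll])

    XX = [[Xfull[kk].T @ D(kk, ll) @ Xfull[ll] for ll in range(k)] for kk in range(k)]
    XZ = [[Xfull[kk].T @ D(kk, ll) @ Z for ll in range(k)] for kk in range(k)]
    ZZ = [
        [
            Z.T @ D(kk, ll) @ Z + Ginv[kk, ll] * a_inv
            for ll in range(k)
        ]
        for kk in range(k)
    ]
    C = sp.bmat(
        [
            [XX[kk][ll] for ll in range(k)] + [XZ[kk][ll] for ll in range(k)]
            for kk in range(k)
        ]
        + [
            [XZ[ll][kk].T for ll in range(k)] + [ZZ[kk][ll] for ll in range(k)]
            for kk in range(k)
        ],
        format="csc",
    )
    rhs_parts = []
    for kk in range(k):
        r = np.zeros(Xfull[kk].shape[1])
        for ll in range(k):
            r += Xfull[kk].T @ (E[:, kk, ll] * Y0[:, ll])
        rhs_parts.append(r)
    for kk in range(k):
        r = np.zeros(n_ped)
        for ll in range(k):
            r += Z.T @ (E[:, kk, ll] * Y0[:, ll])
        rhs_parts.append(r)
    rhs = np.concatenate(rhs_parts)
    sol = _solve_spd(C, rhs)

    fixed = {}
    off = 0
    for t_i, t in enumerate(traits):
        p = Xfull[t_i].shape[1]
        fixed[t] = designs[t_i].solutions(sol[off:off + p])
        off += p
    U = sol[off:].reshape(k, n_ped).T
    ebv = pd.DataFrame(U, index=list(order), columns=traits)
    return BreedingValueEstimate(
        ebv,
        fixed,
        diagnostics={
            "n_records": int(Ymask.sum()),
            "dropped_levels": {t: d.dropped for t, d in zip(traits, designs)},
        },
    )


# ---------------------------------------------------------------------------
# Field scenarios (U/M x L/NL)
# ---------------------------------------------------------------------------

def scenario_records(
    bundle: ScenarioBundle,
    trait: str,
    use_littermates: bool,
    multitrait: bool,
) -> pd.DataFrame:
    """Assemble the training record table for one scenario.

    Quality-trait records come from the background and training-genotyped
    animals, plus the littermates of the testing set when L. BW/BF records
    (all recorded animals, testing included) are added for M. Testing-set
    quality records never enter.
    """
    ph = bundle.phenotypes
    roles = bundle.roles
    keep_quality = roles.isin(["background", "training_genotyped"])
    if use_littermates:
        keep_quality |= roles == "littermate_of_testing"
    traits = [trait] + (PERFORMANCE_TRAITS if multitrait else [])
    rec = ph[["cohort", "batch", "litter", "sex"] + traits].copy()
    rec.loc[~keep_quality, trait] = np.nan
    return rec[rec[traits].notna().any(axis=1)]


def run_blup_scenario(
    bundle: ScenarioBundle,
    trait: str,
    flags: tuple[str, str],
    varcomp: VarianceComponents,
    a_inv: sp.spmatrix,
) -> BreedingValueEstimate:
    """Method B: pedigree BLUP under one U/M x L/NL scenario."""
    uv, lit = flags
    if uv not in ("U", "M") or lit not in ("L", "NL"):
        raise ModelError(f"invalid scenario flags {flags}")
    multitrait = uv == "M"
    rec = scenario_records(bundle, trait, lit == "L", multitrait)
    if rec[trait].notna().sum() == 0 and not multitrait:
        # no usable quality records: EBVs are the prior mean 0
        est = BreedingValueEstimate(
            pd.DataFrame(0.0, index=bundle.pedigree.ids, columns=[trait]),
            {trait: {}},
        )
    elif multitrait:
        vc = varcomp.subset([trait] + PERFORMANCE_TRAITS)
        est = solve_mme_multi(rec, vc, a_inv, bundle.pedigree.ids)
        est.ebv = est.ebv[[trait]]
    else:
        s2a, s2e = varcomp.single(trait)
        est = solve_mme_single(rec, trait, a_inv, bundle.pedigree.ids, s2a, s2e)
    est.method = "BLUP"
    est.scenario = f"{uv},{lit}"
    return est
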