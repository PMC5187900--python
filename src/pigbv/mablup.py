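"""Marker-assisted BLUP: SCD/LEPR genotype classes plus a polygenic effect.

The animal-model MME is extended with one fixed three-level genotype-class
factor per major marker, so additive and dominance class effects are both
captured. The breeding value of an animal is the centered genotypic value
of its marker classes plus its polygenic EBV; ungenotyped animals carry
the expected (frequency-weighted mean, i.e. zero after centering)
genotypic value and contribute no marker-contrast information to the fit
(their design rows hold the class frequencies of the genotyped training
subset).

When a genotype class is entirely absent from the training records the
marker collapses to additive dosage regression, noted in the diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .blup import (
    BreedingValueEstimate,
    _solve_spd,
    ModelError,
    VarianceComponents,
    _incidence,
    build_fixed_design,
    scenario_records,
)
from .simulate import PERFORMANCE_TRAITS, ScenarioBundle


@dataclass
class MarkerGenotypicValues:
    """Centered genotype-class effects and per-animal genotypic values."""

    class_effects: dict[str, dict[str, np.ndarray]]  # trait -> marker -> 3 effects
    class_freqs: dict[str, np.ndarray]               # marker -> class frequencies
    values: pd.DataFrame                             # animal x trait summed values
    additive_collapsed: list[tuple[str, str]]        # (trait, marker) fallbacks


def _marker_design(
    calls: pd.Series, freqs: np.ndarray, collapse: bool
) -> np.ndarray:
    """Design columns for one marker over the given animals.

    Class coding uses dosage classes {0,1,2}. Genotyped animals get an
    indicator row; ungenotyped animals get the class-frequency row (mean
    imputation, no contrast information). With ``collapse`` a single
    centered-dosage column is returned instead.
    """
    n = len(calls)
    d = calls.to_numpy(dtype=float)
    if collapse:
        mean_dose = freqs @ np.array([0.0, 1.0, 2.0])
        col = np.where(np.isnan(d), mean_dose, d) - mean_dose
        return col[:, None]
    M = np.tile(freqs, (n, 1))
    known = ~np.isnan(d)
    M[known] = 0.0
    M[known, d[known].astype(int)] = 1.0
    # drop the first class (zeroed by constraint); frequencies rescale to
    # keep rows of ungenotyped animals at the class mean
    return M[:, 1:]


def _class_frequencies(calls: pd.Series) -> np.ndarray:
    d = calls.dropna().to_numpy(dtype=float).astype(int)
    if d.size == 0:
        return np.array([1.0, 0.0, 0.0])
    counts = np.bincount(d, minlength=3).astype(float)
    return counts / counts.sum()


def solve_mablup(
    bundle: ScenarioBundle,
    trait: str,
    flags: tuple[str, str],
    varcomp: VarianceComponents,
    a_inv: sp.spmatrix,
    marker_ids: tuple[str, ...] = ("SCD", "LEPR"),
) -> tuple[BreedingValueEstimate, MarkerGenotypicValues]:
    """Method C under one U/M x L/NL scenario.

    Returns the estimate (total EBV = marker genotypic value + polygenic
    EBV) together with the fitted genotypic values.
    """
    uv, lit = flags
    if uv not in ("U", "M") or lit not in ("NL", "L"):
        raise ModelError(f"invalid scenario flags {flags}")
    multitrait = uv == "M"
    traits = [trait] + (PERFORMANCE_TRAITS if multitrait else [])
    rec = scenario_records(bundle, trait, lit == "L", multitrait)
    order = bundle.pedigree.ids
    calls = bundle.marker_calls

    # class frequencies from the genotyped animals among training records;
    # markers with <2 observed classes carry no contrast: a 2-class marker
    # collapses to additive dosage regression, a monomorphic (or uncalled)
    # one is excluded from the design entirely
    freqs = {}
    collapse = {}
    excluded = []
    for m in marker_ids:
        train_calls = calls.loc[rec.index, m]
        freqs[m] = _class_frequencies(train_calls)
        counts = np.bincount(train_calls.dropna().astype(int), minlength=3)
        n_classes = int((counts > 0).sum())
        collapse[m] = n_classes == 2
        if n_classes < 2:
            excluded.append(m)
    active_markers = tuple(m for m in marker_ids if m not in excluded)

    vc = varcomp.subset(traits) if multitrait else varcomp
    Ginv = (
        np.linalg.inv(vc.G0) if multitrait else None
    )

    # --- assemble MME with marker fixed effects appended per trait -------
    k = len(traits)
    Yn = rec[traits].to_numpy(dtype=float)
    Ymask = ~np.isnan(Yn)
    Y0 = np.where(Ymask, Yn, 0.0)
    n_data = len(rec)
    if multitrait:
        R0 = vc.R0
        E = np.zeros((n_data, k, k))
        patterns = {}
        for i in range(n_data):
            key = tuple(Ymask[i])
            if key not in patterns:
                o = np.flatnonzero(Ymask[i])
                Einv = np.zeros((k, k))
                if o.size:
                    Einv[np.ix_(o, o)] = np.linalg.inv(R0[np.ix_(o, o)])
                patterns[key] = Einv
            E[i] = patterns[key]
    else:
        s2a, s2e = varcomp.single(trait)
        E = (Ymask[:, :1] / s2e).reshape(n_data, 1, 1)

    designs = []
    Xfull = []
    for t_i, t in enumerate(traits):
        base = build_fixed_design(rec[Ymask[:, t_i]])
        Xt = np.zeros((n_data, base.matrix.shape[1]))
        Xt[Ymask[:, t_i]] = base.matrix
        cols = [Xt]
        for m in active_markers:
            Dm = _marker_design(calls.loc[rec.index, m], freqs[m], collapse[m])
            cols.append(Dm)
        designs.append(base)
        Xfull.append(sp.csr_matrix(np.column_stack(cols)))

    Z = _incidence(list(rec.index), order)
    n_ped = len(order)
    a_inv = a_inv.tocsc()

    def D(kk, ll):
        return sp.diags(E[:, kk, ll])

    if multitrait:
        g_blocks = [[Ginv[kk, ll] * a_inv for ll in range(k)] for kk in range(k)]
    else:
        g_blocks = [[(s2e / s2a) / s2e * a_inv]]  # lambda/sigma2_e (weighted MME)

    XX = [[Xfull[kk].T @ D(kk, ll) @ Xfull[ll] for ll in range(k)] for kk in range(k)]
    XZ = [[Xfull[kk].T @ D(kk, ll) @ Z for ll in range(k)] for kk in range(k)]
    ZZ = [
        [Z.T @ D(kk, ll) @ Z + g_blocks[kk][ll] for ll in range(k)]
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
    sol = _solve_spd(C, np.concatenate(rhs_parts))

    # --- unpack: fixed, marker class effects, polygenic EBVs -------------
    fixed = {}
    class_effects: dict[str, dict[str, np.ndarray]] = {t: {} for t in traits}
    off = 0
    for t_i, t in enumerate(traits):
        p_base = designs[t_i].matrix.shape[1]
        fixed[t] = designs[t_i].solutions(sol[off:off + p_base])
        mvals = sol[off + p_base: off + Xfull[t_i].shape[1]]
        pos = 0
        for m in marker_ids:
            if m not in active_markers:
                class_effects[t][m] = np.zeros(3)
                continue
            if collapse[m]:
                beta = mvals[pos]
                pos += 1
                class_effects[t][m] = np.array([0.0, beta, 2.0 * beta])
            else:
                g = np.concatenate([[0.0], mvals[pos:pos + 2]])
                pos += 2
                class_effects[t][m] = g
        off += Xfull[t_i].shape[1]
    U = sol[off:].reshape(k, n_ped).T

    # centered genotypic values for every pedigree animal
    gv = pd.DataFrame(0.0, index=pd.Index(order, name="animal"), columns=traits)
    for m in marker_ids:
        f = freqs[m]
        d_all = calls.loc[order, m].to_numpy(dtype=float)
        known = ~np.isnan(d_all)
        for t in traits:
            g = class_effects[t][m]
            centered = g - f @ g
            vals = np.zeros(len(order))
            vals[known] = centered[d_all[known].astype(int)]
            gv[t] += vals

    poly = pd.DataFrame(U, index=gv.index, columns=traits)
    total = gv + poly
    est = BreedingValueEstimate(
        total[[trait]],
        fixed,
        method="MA-BLUP",
        scenario=f"{uv},{lit}",
        diagnostics={
            "polygenic": poly[[trait]],
            "additive_collapsed": [
                (t, m) for t in traits for m in marker_ids if collapse[m]
            ],
            "excluded_markers": excluded,
        },
    )
    mgv = MarkerGenotypicValues(
        class_effects=class_effects,
        class_freqs=freqs,
        values=gv,
        additive_collapsed=[(t, m) for t in traits for m in marker_ids if collapse[m]],
    )
    return est, mgv


def variance_explained_by_markers(
    mgv: MarkerGenotypicValues,
    calls: pd.DataFrame,
    trait: str,
    sigma2_a: float,
    marker_ids: tuple[str, ...] = ("SCD", "LEPR"),
) -> dict[str, float]:
    """q-hat per marker and jointly: Var(genotypic value) / sigma2_a.

    ``calls`` holds per-animal dosage classes (NaN = ungenotyped);
    variances are taken over the animals genotyped for the marker(s).
    """
    if sigma2_a <= 0:
        raise ModelError("additive variance must be positive for q-hat")
    out: dict[str, float] = {}
    joint = None
    for m in marker_ids:
        f = mgv.class_freqs[m]
        g = mgv.class_effects[trait][m]
        centered = g - f @ g
        d = calls[m].dropna().astype(int).to_numpy()
        vals = centered[d]
        out[m] = float(np.var(vals)) / sigma2_a
    both = calls[list(marker_ids)].dropna()
    tot = np.zeros(len(both))
    for m in marker_ids:
        g = mgv.class_effects[trait][m]
        centered = g - mgv.class_freqs[m] @ g
        tot += centered[both[m].astype(int).to_numpy()]
    out["joint"] = float(np.var(tot)) / sigma2_a if len(both) else float("nan")
    return out
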