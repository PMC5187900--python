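"""Evaluation: adjusted phenotypes, predictive correlations, accuracies.

Prediction quality is measured as the Pearson correlation between
predicted breeding values and the fixed-effect-adjusted phenotypes of the
testing animals, optionally converted to an accuracy by dividing by the
square root of the trait heritability. Results are collected into a
method x trait comparison grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    pass


#: Canonical row order of the comparison grid.
METHOD_ROW_ORDER = [
    "BayesB 36k",
    "BayesB SCD/LEPR",
    "BayesB rest_of_chip",
    "BLUP U,NL",
    "BLUP U,L",
    "BLUP M,NL",
    "BLUP M,L",
    "MA-BLUP U,NL",
    "MA-BLUP U,L",
    "MA-BLUP M,NL",
    "MA-BLUP M,L",
]


def adjust_phenotypes(
    pheno_test: pd.DataFrame,
    trait: str,
    fixed_solutions: Mapping[tuple[str, str], float],
    factors: Sequence[str] = ("cohort", "batch"),
) -> pd.Series:
    """Adjusted value = raw phenotype minus fitted fixed effects.

    ``fixed_solutions`` maps (factor, level) -> estimate as produced by the
    MME solvers (the intercept is removed too; correlations are invariant
    to it). Fixed-effect levels never seen in the base fit cannot be
    adjusted from training information; records in such a level are
    centered on the level mean within the testing set instead, which
    removes the level effect without using any training-set estimate.
    Missing phenotypes stay missing.
    """
    y = pheno_test[trait].astype(float).copy()
    known_levels = {f: {lv for (ff, lv) in fixed_solutions if ff == f} for f in factors}
    unadjusted = pd.Series(False, index=y.index)
    adj = y - fixed_solutions.get(("intercept", ""), 0.0)
    for f in factors:
        if f not in pheno_test.columns:
            continue
        lv = pheno_test[f].astype(str)
        effects = lv.map(
            lambda x: fixed_solutions.get((f, x), np.nan)
        )
        seen = lv.isin(known_levels[f])
        adj[seen] -= effects[seen].astype(float)
        unadjusted |= ~seen
    # fallback: center within unseen levels (cohorts with no training records)
    if unadjusted.any():
        for f in factors:
            if f not in pheno_test.columns:
                continue
            lv = pheno_test[f].astype(str)
            for level in lv[unadjusted & ~lv.isin(known_levels[f])].unique():
                sel = lv == level
                adj[sel] -= adj[sel].mean()
    return adj


def predictive_correlation(ebv: pd.Series, adjusted: pd.Series) -> float:
    """Pearson correlation over animals with both values present (NaN if undefined)."""
    joined = pd.concat([ebv, adjusted], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise EvaluationError("need at least 3 paired values for a correlation")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def accuracy_from_correlation(r: float, h2: float) -> float:
    """Accuracy of the EBV as a predictor of the true breeding value: r / sqrt(h2)."""
    if not 0.0 < h2 <= 1.0:
        raise EvaluationError("h2 must be in (0,1]")
    return r / np.sqrt(h2)


@dataclass
class EvaluationReport:
    """Method/scenario x trait grid of predictive correlations."""

    correlations: pd.DataFrame          # rows = method labels, cols = traits
    dispersion: pd.DataFrame | None = None   # SD over replicates, same shape
    accuracies: pd.DataFrame | None = None
    n_replicates: int = 1

    def to_json_dict(self) -> dict:
        out = {
            "n_replicates": self.n_replicates,
            "correlations": {
                row: {t: _round(v) for t, v in self.correlations.loc[row].items()}
                for row in self.correlations.index
            },
        }
        if self.dispersion is not None:
            out["sd"] = {
                row: {t: _round(v) for t, v in self.dispersion.loc[row].items()}
                for row in self.dispersion.index
            }
        if self.accuracies is not None:
            out["accuracies"] = {
                row: {t: _round(v) for t, v in self.accuracies.loc[row].items()}
                for row in self.accuracies.index
            }
        return out


def _round(v: float) -> float | None:
    return None if pd.isna(v) else round(float(v), 4)


def method_comparison_table(
    results: Sequence[tuple[str, Mapping[str, float]]],
    h2: Mapping[str, float] | None = None,
    n_replicates: int = 1,
    dispersion: Mapping[str, Mapping[str, float]] | None = None,
) -> EvaluationReport:
    """Assemble per-method trait correlations into the canonical grid.

    ``results`` holds (label, trait -> r) pairs; labels must be unique.
    Rows follow :data:`METHOD_ROW_ORDER` (unknown labels appended in input
    order), columns the union of traits in input order.
    """
    labels = [lab for lab, _ in results]
    if len(set(labels)) != len(labels):
        raise EvaluationError("duplicate method/scenario labels")
    traits: list[str] = []
    for _, r in results:
        for t in r:
            if t not in traits:
                traits.append(t)
    ordered = [l for l in METHOD_ROW_ORDER if l in labels] + [
        l for l in labels if l not in METHOD_ROW_ORDER
    ]
    grid = pd.DataFrame(np.nan, index=ordered, columns=traits)
    for lab, r in results:
        for t, v in r.items():
            grid.loc[lab, t] = v
    disp = None
    if dispersion is not None:
        disp = pd.DataFrame(np.nan, index=ordered, columns=traits)
        for lab, r in dispersion.items():
            for t, v in r.items():
                disp.loc[lab, t] = v
    acc = None
    if h2 is not None:
        acc = grid.copy()
        for t in traits:
            if t in h2:
                acc[t] = grid[t] / np.sqrt(h2[t])
    return EvaluationReport(grid, disp, acc, n_replicates)
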