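"""End-to-end pipeline: simulate -> QC -> methods A/B/C -> comparison grid.

One replicate runs the whole field comparison on a fresh synthetic
population: Bayes B on three marker subsets (whole chip, SCD/LEPR only,
rest of chip), pedigree BLUP under the four U/M x L/NL scenarios, and
marker-assisted BLUP under the same four scenarios; all eleven
predictions are scored as correlations with the adjusted phenotypes of
the testing animals. Replicates are aggregated by the arithmetic mean of
the correlations.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np

from .bayesb import BayesBConfig, fit_bayesb, predict_gebv, qc_genotypes
from .blup import VarianceComponents, run_blup_scenario, solve_mme_single
from .evaluate import (
    adjust_phenotypes,
    method_comparison_table,
    predictive_correlation,
    EvaluationReport,
)
from .io import BayesBSettings, RunConfig, write_report
from .mablup import solve_mablup
from .pedigree import a_inverse
from .simulate import ScenarioBundle, make_field_scenario

log = logging.getLogger("pigbv")

SCENARIO_FLAGS = [("U", "NL"), ("U", "L"), ("M", "NL"), ("M", "L")]


def _base_fixed_fits(bundle, a_inv, varcomp, traits):
    """Single-trait fits on the full training record set (U,L equivalent);
    their fixed-effect solutions define the adjusted phenotypes."""
    fits = {}
    for t in traits:
        from .blup import scenario_records

        rec = scenario_records(bundle, t, use_littermates=True, multitrait=False)
        s2a, s2e = varcomp.single(t)
        fits[t] = solve_mme_single(rec, t, a_inv, bundle.pedigree.ids, s2a, s2e)
    return fits


def evaluate_bundle(
    bundle: ScenarioBundle,
    traits: Sequence[str] | None = None,
    bayes: BayesBSettings | None = None,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Score all eleven method/scenario rows on one synthetic bundle.

    Returns label -> trait -> predictive correlation on the testing set.
    """
    bayes = bayes or BayesBSettings()
    arch = bundle.architecture
    traits = list(traits) if traits is not None else [
        t for t in arch.traits if t not in ("BW", "BF")
    ]
    t0 = time.perf_counter()
    Ainv = a_inverse(bundle.pedigree)
    varcomp = VarianceComponents.from_architecture(arch, arch.traits)
    base = _base_fixed_fits(bundle, Ainv, varcomp, traits)

    testing = bundle.testing_ids
    test_pheno = bundle.phenotypes.loc[testing]
    adjusted = {
        t: adjust_phenotypes(test_pheno, t, base[t].fixed[t]) for t in traits
    }
    train = bundle.training_ids
    if len(train) < 30:
        log.warning(
            "training set has only %d genotyped animals; marker-effect "
            "estimates will be unreliable", len(train)
        )
    train_pheno = bundle.phenotypes.loc[train]
    adjusted_train = {
        t: adjust_phenotypes(train_pheno, t, base[t].fixed[t]) for t in traits
    }
    log.info("bundle seed=%s: base fits in %.1fs", bundle.seed, time.perf_counter() - t0)

    results: list[tuple[str, dict[str, float]]] = []

    # ---- Method A: Bayes B on three marker subsets ----------------------
    geno_tt = bundle.genotypes.subset_animals(train + testing)
    geno_qc, qc_report = qc_genotypes(
        geno_tt, min_maf=bayes.min_maf, min_call_rate=bayes.min_call_rate
    )
    log.info(
        "QC: %d/%d markers retained", len(qc_report.retained), qc_report.n_input
    )
    subsets = {
        "BayesB 36k": (geno_qc.marker_ids, bayes.pi_chip),
        "BayesB SCD/LEPR": (geno_qc.major_marker_ids, bayes.pi_major),
        "BayesB rest_of_chip": (
            [m for m in geno_qc.marker_ids if m not in geno_qc.major_marker_ids],
            bayes.pi_chip,
        ),
    }
    rng = np.random.default_rng(seed)
    for label, (markers, pi) in subsets.items():
        sub = geno_qc.subset_markers(markers)
        sub_train = sub.subset_animals(train)
        sub_test = sub.subset_animals(testing)
        row: dict[str, float] = {}
        for t in traits:
            cfg = BayesBConfig(
                pi=pi,
                chain_length=bayes.chain_length,
                burn_in=bayes.burn_in,
                thinning=bayes.thinning,
                nu=bayes.nu,
                h2_prior=bayes.h2_prior,
                seed=int(rng.integers(2**31)),
            )
            effects = fit_bayesb(sub_train, adjusted_train[t].dropna(), cfg, trait=t)
            gebv = predict_gebv(effects, sub_test, subset="all")
            row[t] = predictive_correlation(gebv, adjusted[t])
        results.append((label, row))
        log.info("%s done (%d markers)", label, len(markers))

    # ---- Method B: pedigree BLUP ----------------------------------------
    for flags in SCENARIO_FLAGS:
        row = {}
        for t in traits:
            est = run_blup_scenario(bundle, t, flags, varcomp, Ainv)
            row[t] = predictive_correlation(est.ebv.loc[testing, t], adjusted[t])
        results.append((f"BLUP {flags[0]},{flags[1]}", row))
    log.info("BLUP scenarios done")

    # ---- Method C: marker-assisted BLUP ---------------------------------
    varcomp_poly = VarianceComponents.from_architecture(
        arch, arch.traits, polygenic_only=True
    )
    for flags in SCENARIO_FLAGS:
        row = {}
        for t in traits:
            est, _ = solve_mablup(bundle, t, flags, varcomp_poly, Ainv)
            row[t] = predictive_correlation(est.ebv.loc[testing, t], adjusted[t])
        results.append((f"MA-BLUP {flags[0]},{flags[1]}", row))
    log.info(
        "MA-BLUP scenarios done; bundle total %.1fs", time.perf_counter() - t0
    )
    return dict(results)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> EvaluationReport:
    """Run ``replicates`` independent synthetic studies and aggregate.

    Writes the Table-shaped grid (TSV + JSON) into ``config.output_dir``
    when requested; returns the aggregated report.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(config.replicates)]
    arch_h2 = dict(config.h2_override)
    per_rep: list[dict[str, dict[str, float]]] = []
    for rep, s in enumerate(child_seeds):
        log.info("replicate %d/%d seed=%d", rep + 1, config.replicates, s)
        bundle = make_field_scenario(config.scenario, seed=s)
        if arch_h2:
            for t, v in arch_h2.items():
                bundle.architecture.h2[t] = v
        per_rep.append(
            evaluate_bundle(bundle, config.traits, config.bayesb, seed=s)
        )
    labels = list(per_rep[0])
    mean_rows = []
    sd_rows = {}
    for lab in labels:
        traits = list(per_rep[0][lab])
        vals = {t: np.array([r[lab][t] for r in per_rep], dtype=float) for t in traits}
        mean_rows.append((lab, {t: float(np.nanmean(v)) for t, v in vals.items()}))
        sd_rows[lab] = {
            t: float(np.nanstd(v, ddof=1)) if len(v) > 1 else float("nan")
            for t, v in vals.items()
        }
    from .simulate import default_architecture

    h2_defaults = default_architecture().h2
    report = method_comparison_table(
        mean_rows,
        h2={t: config.h2_override.get(t, h2_defaults[t]) for t in config.traits},
        n_replicates=config.replicates,
        dispersion=sd_rows if config.replicates > 1 else None,
    )
    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(
            report,
            out / "report.tsv",
            out / "report.json",
            seed=config.seed,
            config_hash=config.config_hash(),
        )
        log.info("report written to %s", out)
    return report
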