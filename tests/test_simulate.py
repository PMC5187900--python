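"""Synthetic-population generator: structure, Mendelian rules, calibration."""

import numpy as np
import pandas as pd
import pytest

from pigbv import (
    GeneticArchitecture,
    MajorLocus,
    ScenarioConfig,
    SimulationError,
    default_architecture,
    drop_genotypes,
    make_field_scenario,
    simulate_pedigree,
    simulate_traits,
)
from pigbv.simulate import ALL_TRAITS, mask_genotypes


class TestSimulatePedigree:
    def test_zero_cohorts_gives_founders_only(self):
        p = simulate_pedigree(n_founders=10, n_cohorts=0, seed=0)
        assert len(p) == 10
        assert all(r.sire == "0" and r.dam == "0" for r in p)

    def test_single_litter_shares_parents_and_litter_id(self):
        p = simulate_pedigree(
            n_founders=4, n_cohorts=1, litters_per_cohort=1, litter_size=4, seed=0
        )
        offspring = [r for r in p if r.sire != "0"]
        assert len(offspring) == 4
        assert len({(r.sire, r.dam, r.litter) for r in offspring}) == 1

    def test_size_counting_identity(self):
        p = simulate_pedigree(
            n_founders=30, n_cohorts=4, litters_per_cohort=6, litter_size=5, seed=1
        )
        assert len(p) == 30 + 4 * 6 * 5

    def test_infeasible_mating_structure_rejected(self):
        with pytest.raises(SimulationError, match="dams"):
            simulate_pedigree(n_founders=4, n_cohorts=1, litters_per_cohort=50, seed=0)

    def test_seed_determinism(self):
        a = simulate_pedigree(seed=11, n_founders=20, n_cohorts=2, litters_per_cohort=5)
        b = simulate_pedigree(seed=11, n_founders=20, n_cohorts=2, litters_per_cohort=5)
        assert a.records == b.records


class TestDropGenotypes:
    def test_offspring_of_null_parents_is_null(self):
        p = simulate_pedigree(n_founders=20, n_cohorts=2, litters_per_cohort=5,
                              litter_size=4, seed=3)
        eps = 1e-9
        g = drop_genotypes(p, n_markers=3, allele_freqs=np.full(3, eps), seed=0)
        assert np.nanmax(g.dosages) == 0.0

    def test_near_fixed_frequency_gives_dosage_two(self):
        p = simulate_pedigree(n_founders=50, n_cohorts=0, seed=0)
        g = drop_genotypes(p, n_markers=2, allele_freqs=np.array([1 - 1e-12] * 2), seed=0)
        assert np.all(g.dosages == 2.0)

    def test_realized_founder_frequency_binomial(self):
        p = simulate_pedigree(n_founders=5000, n_cohorts=0, seed=4)
        g = drop_genotypes(p, n_markers=4, allele_freqs=np.full(4, 0.3), seed=5)
        freq = g.dosages.mean(axis=0) / 2.0
        se = np.sqrt(0.3 * 0.7 / (2 * 5000))
        assert np.all(np.abs(freq - 0.3) < 3 * se)

    def test_bad_frequency_rejected(self):
        p = simulate_pedigree(n_founders=4, n_cohorts=0, seed=0)
        with pytest.raises(SimulationError, match="frequencies"):
            drop_genotypes(p, n_markers=1, allele_freqs=np.array([1.2]), seed=0)

    def test_major_loci_flagged(self):
        p = simulate_pedigree(n_founders=10, n_cohorts=0, seed=0)
        arch = default_architecture()
        g = drop_genotypes(p, n_markers=5, major_loci=arch.major_loci, seed=0)
        assert g.major_marker_ids == ["SCD", "LEPR"]

    def test_masking_marks_missing(self):
        p = simulate_pedigree(n_founders=200, n_cohorts=0, seed=0)
        g = drop_genotypes(p, n_markers=2, seed=0)
        masked = mask_genotypes(g, g.marker_ids[0], keep_fraction=0.5, seed=1)
        frac = np.isnan(masked.dosages[:, 0]).mean()
        assert 0.35 < frac < 0.65
        assert not np.isnan(masked.dosages[:, 1]).any()


def _noiseless_architecture():
    traits = ["t1", "t2"]
    return GeneticArchitecture(
        traits=traits,
        means={"t1": 10.0, "t2": -3.0},
        h2={"t1": 1.0, "t2": 1.0},
        phenotypic_var={"t1": 2.0, "t2": 1.0},
        genetic_corr=np.eye(2),
        residual_corr=np.eye(2),
        major_loci=[],
        cohort_effect_sd_frac=0.0,
        batch_effect_sd_frac=0.0,
    )


class TestSimulateTraits:
    def test_h2_one_no_fixed_effects_phenotype_equals_tbv(self):
        p = simulate_pedigree(n_founders=30, n_cohorts=2, litters_per_cohort=6,
                              litter_size=3, seed=6)
        arch = _noiseless_architecture()
        g = drop_genotypes(p, n_markers=1, seed=0)
        pheno, tbv = simulate_traits(p, g, arch, seed=7)
        np.testing.assert_allclose(
            pheno["t1"] - 10.0, tbv.total["t1"], atol=1e-12
        )

    def test_tbv_decomposition_exact(self, default_bundle):
        tbv = default_bundle.true_bv
        np.testing.assert_allclose(
            tbv.total.to_numpy(), (tbv.major + tbv.polygenic).to_numpy(), atol=1e-12
        )

    def test_non_psd_architecture_rejected(self):
        C = np.array([[1.0, 0.99], [0.99, 1.0]])
        bad = C.copy()
        bad[0, 1] = bad[1, 0] = 1.2
        with pytest.raises(SimulationError, match="positive semi-definite"):
            GeneticArchitecture(
                traits=["a", "b"],
                means={"a": 0, "b": 0},
                h2={"a": 0.5, "b": 0.5},
                phenotypic_var={"a": 1, "b": 1},
                genetic_corr=bad,
                residual_corr=np.eye(2),
            )

    def test_default_means_match_reference_composition(self):
        arch = default_architecture()
        assert arch.means["MUFA"] == 49.51
        assert arch.means["SFA"] == 39.84
        assert arch.means["18:1"] == 45.41
        assert arch.means["PUFA"] == 10.61
        assert arch.means["18:1/18:0"] == 3.31

    def test_calibration_on_large_founder_population(self):
        """Realized h2, genetic correlations and the SCD variance fraction
        converge to the configured architecture at 10,000 founders."""
        arch = default_architecture()
        ped = simulate_pedigree(n_founders=10_000, n_cohorts=0, seed=21)
        geno = drop_genotypes(ped, n_markers=0, major_loci=arch.major_loci, seed=22)
        pheno, tbv = simulate_traits(ped, geno, arch, seed=23)

        G = tbv.total
        # anchored genetic correlations (only 18:1/18:0 carries marker
        # variance among these four pairs, diluting |r| by at most 0.012)
        for a, b, target in [
            ("IMF", "BW", 0.29), ("IMF", "BF", 0.44),
            ("18:1/18:0", "BW", -0.07), ("18:1/18:0", "BF", 0.00),
        ]:
            r = np.corrcoef(G[a], G[b])[0, 1]
            assert abs(r - target) < 0.03, (a, b, r)

        # realized heritability per trait (founder cohort, single batch level)
        for t in ALL_TRAITS:
            h2_real = G[t].var() / pheno[t].var()
            assert abs(h2_real - arch.h2[t]) < 0.03, (t, h2_real)

        # SCD fraction of the additive variance of MUFA
        j = geno.marker_ids.index("SCD")
        beta = arch.marker_effects().loc["MUFA", "SCD"]
        scd_vals = (geno.dosages[:, j] - 1.0) * beta
        q_hat = scd_vals.var() / G["MUFA"].var()
        assert abs(q_hat - 0.27) < 0.02


class TestFieldScenario:
    def test_default_role_counts(self, default_bundle):
        counts = default_bundle.roles.value_counts()
        assert counts["training_genotyped"] == 65
        assert counts["testing"] == 70
        assert counts["background"] == 936
        assert counts["littermate_of_testing"] == 196

    def test_small_scenario_role_counts(self, small_bundle, small_scenario_config):
        c = small_bundle.roles.value_counts()
        assert c["training_genotyped"] == small_scenario_config.n_training
        assert c["testing"] == small_scenario_config.n_testing

    def test_littermates_share_litter_with_testing(self, small_bundle):
        ph = small_bundle.phenotypes
        test_litters = set(ph.loc[small_bundle.testing_ids, "litter"])
        lit_litters = set(ph.loc[small_bundle.littermate_ids, "litter"])
        assert lit_litters <= test_litters

    def test_zero_littermates_constructible(self):
        cfg = ScenarioConfig(
            n_founders=40, n_cohorts=5, litters_per_cohort=10, litter_size=4,
            n_markers=10, n_training=10, n_testing=10, n_background=50,
            n_littermates=0, background_cohorts=3,
        )
        b = make_field_scenario(cfg, seed=5)
        assert (b.roles == "littermate_of_testing").sum() == 0

    def test_excessive_counts_rejected(self):
        cfg = ScenarioConfig(n_founders=10, n_cohorts=2, litters_per_cohort=2,
                             litter_size=2, n_training=50)
        with pytest.raises(SimulationError):
            make_field_scenario(cfg, seed=0)

    def test_same_seed_identical_bundles(self, small_scenario_config):
        a = make_field_scenario(small_scenario_config, seed=77)
        b = make_field_scenario(small_scenario_config, seed=77)
        assert a.pedigree.records == b.pedigree.records
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.marker_calls, b.marker_calls)

    def test_testing_quality_records_present_but_flagged(self, small_bundle):
        # testing animals keep their quality phenotypes (evaluation needs
        # them) and the scenario record assembly must exclude them
        from pigbv.blup import scenario_records

        ph = small_bundle.phenotypes
        assert ph.loc[small_bundle.testing_ids, "MUFA"].notna().all()
        rec = scenario_records(small_bundle, "MUFA", True, False)
        assert not (set(rec[rec["MUFA"].notna()].index) & set(small_bundle.testing_ids))
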