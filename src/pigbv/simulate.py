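"""Synthetic Duroc-style populations: pedigree, genotypes, correlated traits.

The generator emulates the field-data design of the genetic-evaluation
comparison: a multi-cohort pedigree with littermate structure, an unlinked
SNP chip carrying two major loci (SCD and LEPR), and multivariate
phenotypes for intramuscular fat (IMF), fatty-acid composition traits,
body weight (BW) and backfat thickness (BF).

Trait model per animal i and trait t:

    y_it = mu_t + cohort effect + batch effect + g_it + e_it
    g_it = sum_m (dosage_im - 2 p_m) beta_tm  +  u_it      (TBV)

where the major-locus substitution effect beta_tm is scaled so that
2 p (1 - p) beta^2 equals the configured fraction q_t of the additive
variance sigma2_a,t = h2_t * phenotypic variance, and the polygenic
values u follow the multivariate animal model: founders drawn from
N(0, Sigma_poly) and non-founders as parent average plus a
Mendelian-sampling deviate with variance (1/2 - 1/4 (F_s + F_d)) Sigma_poly.

``genetic_corr`` parameterises the *polygenic* correlations; shared major
loci add genetic covariance on top of it, so realized total genetic
correlations for marker-affected trait pairs include the marker term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import (
    UNKNOWN,
    Pedigree,
    PedigreeRecord,
    inbreeding_coefficients,
    sort_pedigree,
)

# Trait names used throughout (the seven reported quality traits + the two
# routinely recorded performance traits).
QUALITY_TRAITS = ["IMF", "SFA", "MUFA", "18:1", "PUFA", "18:1/18:0", "SFA/PUFA"]
PERFORMANCE_TRAITS = ["BW", "BF"]
ALL_TRAITS = QUALITY_TRAITS + PERFORMANCE_TRAITS


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genetic architecture
# ---------------------------------------------------------------------------

@dataclass
class MajorLocus:
    """A validated major locus with per-trait additive variance fractions."""

    locus_id: str
    allele_freq: float
    #: trait -> fraction of additive genetic variance explained (q_t)
    var_fraction: Mapping[str, float]
    #: trait -> sign of the substitution effect (+1/-1); default +1
    effect_sign: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise SimulationError(
                f"allele frequency of {self.locus_id} must be in (0,1)"
            )
        for t, q in self.var_fraction.items():
            if not 0.0 <= q < 1.0:
                raise SimulationError(f"variance fraction q[{t}] out of [0,1)")


@dataclass
class GeneticArchitecture:
    traits: list[str]
    means: dict[str, float]
    h2: dict[str, float]
    phenotypic_var: dict[str, float]
    genetic_corr: np.ndarray      # polygenic correlations, traits x traits
    residual_corr: np.ndarray
    major_loci: list[MajorLocus] = field(default_factory=list)
    cohort_effect_sd_frac: float = 0.25   # SD of cohort effects as fraction of sigma_p
    batch_effect_sd_frac: float = 0.15

    def __post_init__(self) -> None:
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        self.residual_corr = np.asarray(self.residual_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        k = len(self.traits)
        for name, C in (("genetic", self.genetic_corr), ("residual", self.residual_corr)):
            if C.shape != (k, k):
                raise SimulationError(f"{name} correlation matrix must be {k}x{k}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise SimulationError(f"{name} correlation matrix not symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise SimulationError(f"{name} correlation matrix diagonal must be 1")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise SimulationError(
                    f"{name} correlation matrix not positive semi-definite:\n{C}"
                )
        for t in self.traits:
            if not 0.0 < self.h2[t] <= 1.0:
                raise SimulationError(f"h2[{t}] must be in (0,1]")
            if self.phenotypic_var[t] <= 0:
                raise SimulationError(f"phenotypic_var[{t}] must be positive")
            qsum = sum(m.var_fraction.get(t, 0.0) for m in self.major_loci)
            if qsum >= 1.0:
                raise SimulationError(
                    f"major-locus variance fractions for {t} sum to {qsum} >= 1"
                )

    # -- derived quantities ---------------------------------------------
    def additive_var(self, trait: str) -> float:
        return self.h2[trait] * self.phenotypic_var[trait]

    def marker_effects(self) -> pd.DataFrame:
        """Substitution effects beta_tm (traits x loci), from 2p(1-p)b^2 = q sigma2_a."""
        out = {}
        for m in self.major_loci:
            p = m.allele_freq
            col = []
            for t in self.traits:
                q = m.var_fraction.get(t, 0.0)
                sign = m.effect_sign.get(t, 1.0)
                col.append(sign * np.sqrt(q * self.additive_var(t) / (2 * p * (1 - p))))
            out[m.locus_id] = col
        return pd.DataFrame(out, index=self.traits)

    def polygenic_cov(self) -> np.ndarray:
        """Covariance of the polygenic component: (1 - sum q_t) of sigma2_a on the diagonal."""
        sd = np.array(
            [
                np.sqrt(
                    self.additive_var(t)
                    * (1.0 - sum(m.var_fraction.get(t, 0.0) for m in self.major_loci))
                )
                for t in self.traits
            ]
        )
        return self.genetic_corr * np.outer(sd, sd)

    def total_genetic_cov(self) -> np.ndarray:
        """Polygenic covariance plus the major-locus contribution (closed form)."""
        G = self.polygenic_cov().copy()
        B = self.marker_effects().to_numpy()  # traits x loci
        for j, m in enumerate(self.major_loci):
            p = m.allele_freq
            G += 2 * p * (1 - p) * np.outer(B[:, j], B[:, j])
        return G

    def residual_cov(self) -> np.ndarray:
        sd = np.sqrt(
            [ (1.0 - self.h2[t]) * self.phenotypic_var[t] for t in self.traits ]
        )
        return self.residual_corr * np.outer(sd, sd)


def _corr_from_pairs(traits: Sequence[str], pairs: Mapping[tuple[str, str], float]) -> np.ndarray:
    k = len(traits)
    idx = {t: i for i, t in enumerate(traits)}
    C = np.eye(k)
    for (a, b), r in pairs.items():
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    return C


#: Polygenic correlations. The IMF-BW/BF and 18:1/18:0-BW/BF entries are the
#: reported field estimates; the remaining entries are plausible compositional
#: trade-offs chosen once for the default architecture.
_DEFAULT_GENETIC_PAIRS: dict[tuple[str, str], float] = {
    ("IMF", "BW"): 0.29,
    ("IMF", "BF"): 0.44,
    ("18:1/18:0", "BW"): -0.07,
    ("18:1/18:0", "BF"): 0.00,
    ("SFA", "BW"): 0.15,
    ("SFA", "BF"): 0.22,
    ("MUFA", "BW"): 0.15,
    ("MUFA", "BF"): 0.22,
    ("18:1", "BW"): 0.15,
    ("18:1", "BF"): 0.22,
    ("PUFA", "BW"): 0.19,
    ("PUFA", "BF"): 0.26,
    ("SFA/PUFA", "BW"): 0.19,
    ("SFA/PUFA", "BF"): 0.26,
    ("BW", "BF"): 0.22,
    ("MUFA", "18:1"): 0.45,
    ("MUFA", "SFA"): -0.22,
    ("SFA", "18:1"): -0.19,
    ("IMF", "MUFA"): 0.15,
    ("IMF", "PUFA"): -0.15,
    ("PUFA", "MUFA"): -0.19,
    ("PUFA", "SFA"): -0.15,
    ("SFA/PUFA", "PUFA"): -0.45,
    ("SFA/PUFA", "SFA"): 0.34,
    ("18:1/18:0", "MUFA"): 0.30,
    ("18:1/18:0", "18:1"): 0.26,
    ("18:1/18:0", "SFA"): -0.26,
}


def default_architecture() -> GeneticArchitecture:
    """The default study architecture.

    Means for the fatty-acid traits are the gluteus medius values of the
    reference Duroc line; IMF defaults to 3.5% (mid Duroc range) and
    SFA/PUFA to the ratio of the SFA and PUFA means. Heritability defaults
    to 0.55 for IMF and fatty-acid traits (middle of the reported 0.4-0.7
    range) and 0.35 for BW/BF. The SCD locus explains 27% of the additive
    variance of MUFA and 14.7% of oleic acid (18:1); LEPR adds smaller
    fractions, and IMF, PUFA and SFA/PUFA carry no major-locus variance.
    """
    traits = list(ALL_TRAITS)
    means = {
        "IMF": 3.5, "SFA": 39.84, "MUFA": 49.51, "18:1": 45.41,
        "PUFA": 10.61, "18:1/18:0": 3.31, "SFA/PUFA": 3.76,
        "BW": 105.0, "BF": 15.0,
    }
    h2 = {t: 0.55 for t in QUALITY_TRAITS} | {"BW": 0.35, "BF": 0.35}
    # Phenotypic SDs on each trait's own scale.
    psd = {
        "IMF": 0.9, "SFA": 2.4, "MUFA": 2.4, "18:1": 2.1,
        "PUFA": 2.6, "18:1/18:0": 0.45, "SFA/PUFA": 0.9,
        "BW": 10.0, "BF": 3.0,
    }
    phen_var = {t: psd[t] ** 2 for t in traits}
    genetic_corr = _corr_from_pairs(traits, _DEFAULT_GENETIC_PAIRS)
    # Residual correlations unreported in the field data: half the polygenic
    # ones (a convex blend with identity, hence PSD).
    residual_corr = 0.5 * genetic_corr + 0.5 * np.eye(len(traits))
    major = [
        MajorLocus(
            "SCD", 0.5,
            var_fraction={"MUFA": 0.27, "18:1": 0.147, "18:1/18:0": 0.25, "SFA": 0.10},
            effect_sign={"MUFA": 1, "18:1": 1, "18:1/18:0": 1, "SFA": -1},
        ),
        MajorLocus(
            "LEPR", 0.30,
            var_fraction={"MUFA": 0.05, "18:1": 0.05, "18:1/18:0": 0.05, "SFA": 0.10},
            effect_sign={"MUFA": 1, "18:1": 1, "18:1/18:0": 1, "SFA": -1},
        ),
    ]
    return GeneticArchitecture(
        traits=traits, means=means, h2=h2, phenotypic_var=phen_var,
        genetic_corr=genetic_corr, residual_corr=residual_corr, major_loci=major,
    )


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int = 80,
    n_cohorts: int = 9,
    litters_per_cohort: int = 40,
    litter_size: int = 6,
    seed: int = 0,
    start_year: int = 2002,
    litters_per_sire: int = 5,
) -> Pedigree:
    """Multi-cohort pedigree with littermate and half-sib structure.

    Founders (half male, half female) form the base population; each yearly
    cohort consists of full-sib litters, each litter from one sire and one
    dam drawn from earlier cohorts (sires reused across litters, dams used
    for one litter per year). Deterministic under a fixed seed.
    """
    if n_founders < 2 or litter_size < 1 or litters_per_cohort < 0 or n_cohorts < 0:
        raise SimulationError("pedigree sizes must be positive")
    rng = np.random.default_rng(seed)
    records: list[PedigreeRecord] = []
    males: list[str] = []
    females: list[str] = []
    for i in range(n_founders):
        sex = "M" if i % 2 == 0 else "F"
        aid = f"F{i:04d}"
        records.append(PedigreeRecord(aid, UNKNOWN, UNKNOWN, start_year - 1, UNKNOWN, sex))
        (males if sex == "M" else females).append(aid)

    for c in range(n_cohorts):
        year = start_year + c
        n_sires = max(1, -(-litters_per_cohort // litters_per_sire))  # ceil
        if len(females) < litters_per_cohort or len(males) < n_sires:
            raise SimulationError(
                f"cohort {year}: need {litters_per_cohort} dams and {n_sires} sires, "
                f"have {len(females)} females / {len(males)} males"
            )
        sires = rng.choice(males, size=n_sires, replace=False)
        dams = rng.choice(females, size=litters_per_cohort, replace=False)
        new_m: list[str] = []
        new_f: list[str] = []
        for k in range(litters_per_cohort):
            sire = sires[k % n_sires]
            dam = dams[k]
            litter = f"L{year}_{k:03d}"
            for o in range(litter_size):
                aid = f"A{year}_{k:03d}_{o}"
                sex = "M" if rng.random() < 0.5 else "F"
                records.append(PedigreeRecord(aid, str(sire), str(dam), year, litter, sex))
                (new_m if sex == "M" else new_f).append(aid)
        males.extend(new_m)
        females.extend(new_f)
    return sort_pedigree(Pedigree(records))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Animals x markers allele dosages; NaN marks a missing call."""

    animal_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray  # float, entries in {0,1,2} or NaN
    marker_meta: pd.DataFrame  # index marker_id; columns allele_freq, is_major, label

    def __post_init__(self) -> None:
        # fractional dosages are tolerated in memory (mean imputation);
        # file writers enforce {0,1,2,NA}
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise SimulationError("dosage matrix shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.animal_ids, columns=self.marker_ids)

    def subset_animals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [pos[a] for a in ids]
        return GenotypeMatrix(list(ids), self.marker_ids, self.dosages[rows], self.marker_meta)

    def subset_markers(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {m: i for i, m in enumerate(self.marker_ids)}
        cols = [pos[m] for m in ids]
        return GenotypeMatrix(
            self.animal_ids, list(ids), self.dosages[:, cols], self.marker_meta.loc[list(ids)]
        )

    @property
    def major_marker_ids(self) -> list[str]:
        return list(self.marker_meta.index[self.marker_meta["is_major"]])


def drop_genotypes(
    ped: Pedigree,
    n_markers: int = 120,
    allele_freqs: np.ndarray | None = None,
    major_loci: Sequence[MajorLocus] = (),
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop unlinked biallelic markers through the pedigree.

    Founder alleles are Bernoulli(p) per locus; offspring receive one
    random allele from each parent (free recombination). Major loci are
    appended after the chip markers and flagged in ``marker_meta``.
    """
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    rng = np.random.default_rng(seed)
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.1, 0.9, size=n_markers)
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    if allele_freqs.shape != (n_markers,):
        raise SimulationError("allele_freqs length must equal n_markers")
    if np.any((allele_freqs <= 0) | (allele_freqs >= 1)):
        raise SimulationError("allele frequencies must be in (0,1)")

    major_freqs = np.array([m.allele_freq for m in major_loci], dtype=float)
    p = np.concatenate([allele_freqs, major_freqs])
    L = p.size
    n = len(ped)
    par = ped.parent_indices()
    pat = np.zeros((n, L), dtype=np.int8)
    mat = np.zeros((n, L), dtype=np.int8)
    for i in range(n):
        s, d = par[i]
        if s >= 0:
            pick = rng.random(L) < 0.5
            pat[i] = np.where(pick, pat[s], mat[s])
        else:
            pat[i] = rng.random(L) < p
        if d >= 0:
            pick = rng.random(L) < 0.5
            mat[i] = np.where(pick, pat[d], mat[d])
        else:
            mat[i] = rng.random(L) < p
    dosages = (pat + mat).astype(float)
    marker_ids = [f"M{j:05d}" for j in range(n_markers)] + [m.locus_id for m in major_loci]
    meta = pd.DataFrame(
        {
            "allele_freq": p,
            "is_major": [False] * n_markers + [True] * len(major_loci),
            "label": ["chip"] * n_markers + [m.locus_id for m in major_loci],
        },
        index=pd.Index(marker_ids, name="marker_id"),
    )
    return GenotypeMatrix(ped.ids, marker_ids, dosages, meta)


def mask_genotypes(
    geno: GenotypeMatrix, marker_id: str, keep_fraction: float, seed: int = 0
) -> GenotypeMatrix:
    """Set a random fraction of calls at one marker to missing (NaN)."""
    rng = np.random.default_rng(seed)
    j = geno.marker_ids.index(marker_id)
    d = geno.dosages.copy()
    drop = rng.random(len(geno.animal_ids)) >= keep_fraction
    d[drop, j] = np.nan
    return GenotypeMatrix(geno.animal_ids, geno.marker_ids, d, geno.marker_meta)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

@dataclass
class TrueBreedingValues:
    """Exact decomposition total = major + polygenic, per animal per trait."""

    total: pd.DataFrame
    major: pd.DataFrame
    polygenic: pd.DataFrame


def simulate_traits(
    ped: Pedigree,
    geno: GenotypeMatrix,
    arch: GeneticArchitecture,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrueBreedingValues]:
    """Simulate complete multivariate phenotypes and true breeding values.

    Returns (phenotypes, tbv). The phenotype frame has one row per animal
    with columns cohort, batch, litter, sex and one column per trait; no
    missingness is applied here (the field-scenario builder decides which
    records exist).
    """
    if not ped.is_sorted():
        ped = sort_pedigree(ped)
    if geno.animal_ids != ped.ids:
        geno = geno.subset_animals(ped.ids)
    rng = np.random.default_rng(seed)
    traits = arch.traits
    k = len(traits)
    n = len(ped)

    # major-locus genotypic values (centered at 2p)
    B = arch.marker_effects()  # traits x loci
    major_vals = np.zeros((n, k))
    for m in arch.major_loci:
        j = geno.marker_ids.index(m.locus_id)
        centered = geno.dosages[:, j] - 2 * m.allele_freq
        major_vals += np.outer(centered, B[m.locus_id].to_numpy())

    # polygenic values through the pedigree
    Sigma = arch.polygenic_cov()
    w, V = np.linalg.eigh(Sigma)
    if w.min() < -1e-8:
        raise SimulationError(f"polygenic covariance not PSD:\n{Sigma}")
    Lchol = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    par = ped.parent_indices()
    # founder-only populations need no O(n^2) relationship pass
    F = inbreeding_coefficients(ped) if (par >= 0).any() else np.zeros(n)
    u = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            mean = 0.5 * (u[s] + u[d])
            scale = np.sqrt(0.5 - 0.25 * (F[s] + F[d]))
        elif s >= 0 or d >= 0:
            pidx = s if s >= 0 else d
            mean = 0.5 * u[pidx]
            scale = np.sqrt(0.75 - 0.25 * F[pidx])
        else:
            mean = 0.0
            scale = 1.0
        u[i] = mean + scale * (Lchol @ z[i])

    tbv_total = major_vals + u

    # fixed effects: cohort and batch (two slaughter batches per cohort,
    # assigned by litter), drawn once per level
    cohorts = np.array([r.cohort for r in ped.records])
    litters = [r.litter for r in ped.records]
    psd = np.sqrt([arch.phenotypic_var[t] for t in traits])
    cohort_levels = sorted(set(cohorts))
    cohort_eff = {
        c: rng.standard_normal(k) * arch.cohort_effect_sd_frac * psd for c in cohort_levels
    }
    def batch_of(i: int) -> str:
        # two slaughter batches per cohort, litters alternating between them
        lit = litters[i]
        half = int(lit.rsplit("_", 1)[-1]) % 2 if lit != UNKNOWN and "_" in lit else 0
        return f"B{cohorts[i]}_{half}"

    batches = [batch_of(i) for i in range(n)]
    batch_levels = sorted(set(batches))
    batch_eff = {
        b: rng.standard_normal(k) * arch.batch_effect_sd_frac * psd for b in batch_levels
    }

    # residuals
    Re = arch.residual_cov()
    wr, Vr = np.linalg.eigh(Re)
    if wr.min() < -1e-8:
        raise SimulationError(f"residual covariance not PSD:\n{Re}")
    Lr = Vr @ np.diag(np.sqrt(np.clip(wr, 0, None)))
    resid = rng.standard_normal((n, k)) @ Lr.T

    mu = np.array([arch.means[t] for t in traits])
    y = (
        mu[None, :]
        + np.array([cohort_eff[c] for c in cohorts])
        + np.array([batch_eff[b] for b in batches])
        + tbv_total
        + resid
    )

    idx = pd.Index(ped.ids, name="animal")
    pheno = pd.DataFrame(y, index=idx, columns=traits)
    pheno.insert(0, "cohort", cohorts)
    pheno.insert(1, "batch", batches)
    pheno.insert(2, "litter", litters)
    pheno.insert(3, "sex", [r.sex for r in ped.records])
    tbv = TrueBreedingValues(
        total=pd.DataFrame(tbv_total, index=idx, columns=traits),
        major=pd.DataFrame(major_vals, index=idx, columns=traits),
        polygenic=pd.DataFrame(u, index=idx, columns=traits),
    )
    return pheno, tbv


# ---------------------------------------------------------------------------
# Field scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Role counts and pedigree scale for the field-data design."""

    n_founders: int = 80
    n_cohorts: int = 9
    litters_per_cohort: int = 40
    litter_size: int = 6
    n_markers: int = 120
    n_training: int = 65
    n_testing: int = 70
    n_background: int = 936
    n_littermates: int = 196
    training_cohorts: int = 2    # first k offspring cohorts supply training pigs
    background_cohorts: int = 6  # first k offspring cohorts supply background records
    scd_call_fraction: float = 0.45   # fraction of record-bearing animals SCD-genotyped
    lepr_call_fraction: float = 0.40
    start_year: int = 2002


@dataclass
class ScenarioBundle:
    pedigree: Pedigree
    genotypes: GenotypeMatrix          # full gene-dropped matrix (all animals)
    phenotypes: pd.DataFrame           # masked per study design (NaN = no record)
    raw_phenotypes: pd.DataFrame       # complete values (evaluation ground truth)
    true_bv: TrueBreedingValues
    roles: pd.Series                   # animal -> role tag
    architecture: GeneticArchitecture
    marker_calls: pd.DataFrame         # animal x [SCD, LEPR] dosages with NaN gaps
    seed: int
    config: ScenarioConfig

    @property
    def training_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == "training_genotyped"])

    @property
    def testing_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == "testing"])

    @property
    def littermate_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == "littermate_of_testing"])

    @property
    def background_ids(self) -> list[str]:
        return list(self.roles.index[self.roles == "background"])


def make_field_scenario(
    config: ScenarioConfig | None = None,
    seed: int = 0,
    arch: GeneticArchitecture | None = None,
) -> ScenarioBundle:
    """Build the full synthetic study: pedigree, chip, phenotypes, roles.

    Role tags mirror the field design: ``training_genotyped`` pigs (early
    cohorts, chip-genotyped, complete quality records), ``testing`` pigs
    (last two cohorts, chip-genotyped; their quality records exist but are
    reserved for evaluation), ``littermate_of_testing`` records,
    ``background`` low-relationship quality records from early cohorts, and
    BW/BF recorded on essentially all non-founders.
    """
    config = config or ScenarioConfig()
    arch = arch or default_architecture()
    ss = np.random.SeedSequence(seed)
    s_ped, s_geno, s_traits, s_roles, s_scd, s_lepr = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(6)
    ]

    ped = simulate_pedigree(
        n_founders=config.n_founders,
        n_cohorts=config.n_cohorts,
        litters_per_cohort=config.litters_per_cohort,
        litter_size=config.litter_size,
        seed=s_ped,
        start_year=config.start_year,
    )
    geno = drop_genotypes(
        ped, n_markers=config.n_markers, major_loci=arch.major_loci, seed=s_geno
    )
    raw_pheno, tbv = simulate_traits(ped, geno, arch, seed=s_traits)

    rng = np.random.default_rng(s_roles)
    cohorts = raw_pheno["cohort"]
    first_year = config.start_year
    is_founder = cohorts < first_year
    offspring_years = sorted(set(cohorts[~is_founder]))
    if len(offspring_years) < 2:
        raise SimulationError("need at least two offspring cohorts for a testing split")
    train_years = offspring_years[: config.training_cohorts]
    bg_years = offspring_years[: config.background_cohorts]
    test_years = offspring_years[-2:]

    roles = pd.Series("other", index=raw_pheno.index, name="role")
    roles[is_founder] = "founder"

    train_pool = list(raw_pheno.index[cohorts.isin(train_years)])
    if len(train_pool) < config.n_training:
        raise SimulationError("not enough early-cohort animals for the training set")
    training = list(rng.choice(train_pool, size=config.n_training, replace=False))
    roles[training] = "training_genotyped"

    # one testing pig per litter in the last two cohorts, littermates kept aside
    test_frame = raw_pheno[cohorts.isin(test_years)]
    litter_groups = test_frame.groupby("litter").groups
    litter_ids = sorted(litter_groups)
    if len(litter_ids) < config.n_testing:
        raise SimulationError("not enough late-cohort litters for the testing set")
    chosen = rng.choice(litter_ids, size=config.n_testing, replace=False)
    testing = [str(rng.choice(sorted(litter_groups[l]))) for l in chosen]
    roles[testing] = "testing"
    sib_pool = [
        a for l in chosen for a in sorted(litter_groups[l]) if roles[a] == "other"
    ]
    if len(sib_pool) < config.n_littermates:
        raise SimulationError("not enough littermates of the testing set")
    litters_of_testing = list(rng.choice(sib_pool, size=config.n_littermates, replace=False))
    roles[litters_of_testing] = "littermate_of_testing"

    bg_pool = [
        a
        for a in raw_pheno.index[cohorts.isin(bg_years)]
        if roles[a] == "other"
    ]
    if len(bg_pool) < config.n_background:
        raise SimulationError("not enough animals for the background record set")
    background = list(rng.choice(bg_pool, size=config.n_background, replace=False))
    roles[background] = "background"

    # record masking: quality traits only for tagged roles; BW/BF on all non-founders
    pheno = raw_pheno.copy()
    has_quality = roles.isin(
        ["training_genotyped", "testing", "littermate_of_testing", "background"]
    )
    for t in QUALITY_TRAITS:
        pheno.loc[~has_quality, t] = np.nan
    for t in PERFORMANCE_TRAITS:
        pheno.loc[is_founder, t] = np.nan

    # SCD/LEPR single-marker genotyping with gaps, emulating partial assays
    recorded = pheno.index[has_quality | ~is_founder]
    locus_ids = [m.locus_id for m in arch.major_loci]
    calls = pd.DataFrame(np.nan, index=raw_pheno.index, columns=locus_ids)
    fracs = {"SCD": config.scd_call_fraction, "LEPR": config.lepr_call_fraction}
    for li, locus in enumerate(locus_ids):
        frac = fracs.get(locus, config.scd_call_fraction)
        r = np.random.default_rng((s_scd if li == 0 else s_lepr) + li)
        keep = r.random(len(recorded)) < frac
        kept = recorded[keep]
        j = geno.marker_ids.index(locus)
        pos = {a: i for i, a in enumerate(geno.animal_ids)}
        calls.loc[kept, locus] = [geno.dosages[pos[a], j] for a in kept]
        # chip-genotyped animals always have their major-locus calls
        for a in training + testing:
            calls.loc[a, locus] = geno.dosages[pos[a], j]

    return ScenarioBundle(
        pedigree=ped,
        genotypes=geno,
        phenotypes=pheno,
        raw_phenotypes=raw_pheno,
        true_bv=tbv,
        roles=roles,
        architecture=arch,
        marker_calls=calls,
        seed=seed,
        config=config,
    )
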