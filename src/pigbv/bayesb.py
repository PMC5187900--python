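"""Bayes B whole-genome regression: per-SNP effects with a point mass at zero.

Model for an adjusted training phenotype y:

    y_i = mu + sum_j z_ij a_j delta_j + e_i
    delta_j ~ Bernoulli(1 - pi)
    a_j | sigma2_j ~ N(0, sigma2_j),  sigma2_j ~ nu S / chi2_nu
    e_i ~ N(0, sigma2_e)

Sampling follows the classic scheme: for every locus the pair
(delta_j, sigma2_j) is proposed from its prior and accepted by a
Metropolis-Hastings step on the marginal likelihood with a_j integrated
out; conditional on inclusion, a_j and sigma2_j are Gibbs-updated, as are
mu and sigma2_e. The kernel is numba-compiled; a fixed seed gives
identical chains.

Also here: genotype quality control (MAF, call rate, monomorphic) with
mean imputation, GEBV prediction on marker subsets, and ranking of
markers by posterior explained-variance share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from numba import njit

from .simulate import GenotypeMatrix


class BayesBError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    removed_monomorphic: list[str]
    removed_low_maf: list[str]
    removed_low_call_rate: list[str]
    retained: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed_monomorphic) + len(self.removed_low_maf) + len(
            self.removed_low_call_rate
        )


def qc_genotypes(
    geno: GenotypeMatrix,
    min_maf: float = 0.05,
    min_call_rate: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate, low-MAF and monomorphic markers; impute the rest.

    Checks run in that order, each marker counted once. Remaining missing
    dosages are replaced by the marker mean. Raises if nothing survives.
    """
    D = geno.dosages
    n, m = D.shape
    call_rate = 1.0 - np.isnan(D).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(D, axis=0) / 2.0  # allele frequency per marker
    maf = np.minimum(freq, 1.0 - freq)
    low_call = call_rate < min_call_rate
    mono = ~low_call & ((maf == 0) | np.isnan(freq))
    low_maf = ~low_call & ~mono & (maf < min_maf)
    keep = ~(low_call | mono | low_maf)
    ids = np.asarray(geno.marker_ids)
    if not keep.any():
        raise BayesBError(
            f"quality control removed all {m} markers "
            f"(call-rate {low_call.sum()}, monomorphic {mono.sum()}, MAF {low_maf.sum()})"
        )
    Dk = D[:, keep].copy()
    col_mean = np.nanmean(Dk, axis=0)
    nan_r, nan_c = np.where(np.isnan(Dk))
    Dk[nan_r, nan_c] = col_mean[nan_c]
    kept_ids = [str(x) for x in ids[keep]]
    out = GenotypeMatrix(
        geno.animal_ids, kept_ids, Dk, geno.marker_meta.loc[kept_ids]
    )
    report = QCReport(
        n_input=m,
        removed_monomorphic=[str(x) for x in ids[mono]],
        removed_low_maf=[str(x) for x in ids[low_maf]],
        removed_low_call_rate=[str(x) for x in ids[low_call]],
        retained=kept_ids,
    )
    return out, report


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class BayesBConfig:
    pi: float = 0.95
    chain_length: int = 20_000
    burn_in: int = 5_000
    thinning: int = 10
    nu: float = 4.2
    scale: float | None = None       # prior scale S; derived from the data if None
    h2_prior: float = 0.5            # used to derive S when scale is None
    nu_e: float = 4.0                # residual-variance prior df
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise BayesBError("pi must be in [0,1]")
        if self.burn_in >= self.chain_length:
            raise BayesBError("burn_in must be smaller than chain_length")
        if self.nu <= 2:
            raise BayesBError("nu must exceed 2 for a finite prior mean")


@dataclass
class MarkerEffects:
    """Posterior summaries of per-SNP substitution effects."""

    table: pd.DataFrame       # index marker; effect, inclusion_prob, var_share, center
    mu: float
    sigma2_e: float
    trait: str
    config: BayesBConfig
    samples: np.ndarray = field(repr=False, default=None)  # thinned effect draws

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)


@njit(cache=True)
def _bayesb_kernel(Zt, y, pi, n_iter, burn_in, thin, nu, S, nu_e, Se, seed):
    # Zt is markers x animals (each marker's dosage vector contiguous)
    np.random.seed(seed)
    m, n = Zt.shape
    zz = np.empty(m)
    for j in range(m):
        zz[j] = np.dot(Zt[j], Zt[j])
    mu = y.mean()
    e = y - mu
    a = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    sig2 = np.full(m, S * nu / (nu - 2.0))
    sigma2_e = np.dot(e, e) / n if n > 0 else 1.0
    if sigma2_e <= 0:
        sigma2_e = 1e-8
    n_keep = (n_iter - burn_in) // thin
    samples = np.zeros((n_keep, m))
    mu_sum = 0.0
    s2e_sum = 0.0
    kept = 0
    for it in range(n_iter):
        # intercept
        e += mu
        mu = e.sum() / n + np.random.normal() * np.sqrt(sigma2_e / n)
        e -= mu
        for j in range(m):
            if zz[j] <= 0.0:
                continue
            # remove locus j from the residual
            if delta[j] == 1 and a[j] != 0.0:
                for i in range(n):
                    e[i] += Zt[j, i] * a[j]
            rhs = np.dot(Zt[j], e)

            # MH on (delta, sigma2_j), proposal = prior, a_j integrated out
            d_prop = 1 if np.random.random() < (1.0 - pi) else 0
            s2_prop = S * nu / np.random.chisquare(nu)
            if delta[j] == 0:
                ll_cur = 0.0
            else:
                v = sigma2_e + sig2[j] * zz[j]
                ll_cur = -0.5 * (
                    np.log(v / sigma2_e) - sig2[j] * rhs * rhs / (sigma2_e * v)
                )
            if d_prop == 0:
                ll_prop = 0.0
            else:
                v = sigma2_e + s2_prop * zz[j]
                ll_prop = -0.5 * (
                    np.log(v / sigma2_e) - s2_prop * rhs * rhs / (sigma2_e * v)
                )
            if np.log(np.random.random() + 1e-300) < ll_prop - ll_cur:
                delta[j] = d_prop
                sig2[j] = s2_prop
            if delta[j] == 1:
                # Gibbs for a_j | sigma2_j
                c = zz[j] + sigma2_e / sig2[j]
                a[j] = rhs / c + np.random.normal() * np.sqrt(sigma2_e / c)
                # Gibbs for sigma2_j | a_j
                sig2[j] = (nu * S + a[j] * a[j]) / np.random.chisquare(nu + 1.0)
                for i in range(n):
                    e[i] -= Zt[j, i] * a[j]
            else:
                a[j] = 0.0
        # residual variance
        sse = np.dot(e, e)
        sigma2_e = (sse + nu_e * Se) / np.random.chisquare(n + nu_e)
        if not np.isfinite(sigma2_e) or sigma2_e <= 0.0:
            return samples, mu_sum, s2e_sum, kept, -1
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            for j in range(m):
                samples[kept, j] = a[j] * delta[j]
            mu_sum += mu
            s2e_sum += sigma2_e
            kept += 1
    return samples, mu_sum, s2e_sum, kept, 0


def fit_bayesb(
    geno: GenotypeMatrix,
    y: pd.Series,
    cfg: BayesBConfig,
    trait: str = "",
) -> MarkerEffects:
    """Fit Bayes B on a training set.

    ``y`` must be complete (fixed-effect-adjusted phenotypes indexed by
    animal id); the intercept is re-fit inside the sampler. Dosages are
    centered on the training means, which are stored with the effects so
    prediction uses the same centering.
    """
    if y.isna().any():
        raise BayesBError("training phenotypes must be complete")
    geno = geno.subset_animals(list(y.index))
    D = geno.dosages
    if np.isnan(D).any():
        raise BayesBError("genotypes must be imputed (run qc_genotypes first)")
    center = D.mean(axis=0)
    Z = D - center
    yv = y.to_numpy(dtype=float)
    vary = float(np.var(yv)) if np.var(yv) > 0 else 1.0

    # prior scale: expected genetic variance h2_prior * var(y) spread over
    # the expected number of included markers
    m = Z.shape[1]
    sumvar = float((Z**2).mean(axis=0).sum())
    if cfg.scale is None:
        n_incl = max((1.0 - cfg.pi) * m, 1.0)
        per_snp = cfg.h2_prior * vary / max(sumvar / m, 1e-12) / n_incl
        S = per_snp * (cfg.nu - 2.0) / cfg.nu
    else:
        S = cfg.scale
    Se = (1.0 - cfg.h2_prior) * vary

    samples, mu_sum, s2e_sum, kept, status = _bayesb_kernel(
        np.ascontiguousarray(Z.T),
        yv,
        cfg.pi,
        cfg.chain_length,
        cfg.burn_in,
        cfg.thinning,
        cfg.nu,
        S,
        cfg.nu_e,
        Se,
        cfg.seed % (2**31),
    )
    if status != 0:
        raise BayesBError("residual variance diverged; check data scaling")
    samples = samples[:kept]
    eff = samples.mean(axis=0)
    incl = (samples != 0).mean(axis=0)
    zvar = (Z**2).mean(axis=0)
    var_per_sample = samples**2 * zvar[None, :]
    mean_var = var_per_sample.mean(axis=0)
    total = mean_var.sum()
    share = mean_var / total if total > 0 else np.zeros_like(mean_var)
    table = pd.DataFrame(
        {
            "effect": eff,
            "inclusion_prob": incl,
            "var_share": share,
            "center": center,
        },
        index=pd.Index(geno.marker_ids, name="marker"),
    )
    return MarkerEffects(
        table=table,
        mu=mu_sum / max(kept, 1),
        sigma2_e=s2e_sum / max(kept, 1),
        trait=trait,
        config=cfg,
        samples=samples,
    )


def credible_interval(
    effects: MarkerEffects, marker_id: str, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed posterior interval for one marker's effect (zeros included)."""
    j = effects.marker_ids.index(marker_id)
    lo = (1.0 - level) / 2.0
    draws = effects.samples[:, j]
    return float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo))


def predict_gebv(
    effects: MarkerEffects,
    geno: GenotypeMatrix,
    subset: str = "all",
) -> pd.Series:
    """GEBV_i = sum_j (dosage_ij - training mean_j) * effect_j over a subset.

    ``subset`` is one of 'all', 'major_only', 'rest_of_chip', resolved
    against the genotype metadata. The effects must have been *fitted* on
    the matching marker set (subsets are re-estimated, not masked); this
    function only validates coverage and sums.
    """
    ids = effects.marker_ids
    if subset == "all":
        use = ids
    elif subset == "major_only":
        use = [m for m in ids if geno.marker_meta.loc[m, "is_major"]]
    elif subset == "rest_of_chip":
        use = [m for m in ids if not geno.marker_meta.loc[m, "is_major"]]
    else:
        raise BayesBError(f"unknown subset {subset!r}")
    if not use:
        raise BayesBError(f"subset {subset!r} selects no markers")
    missing = set(use) - set(geno.marker_ids)
    if missing:
        raise BayesBError(f"markers absent from genotypes: {sorted(missing)[:5]}")
    sub = geno.subset_markers(use)
    D = sub.dosages
    if np.isnan(D).any():
        D = np.where(np.isnan(D), np.nanmean(D, axis=0), D)
    t = effects.table.loc[use]
    g = (D - t["center"].to_numpy()) @ t["effect"].to_numpy()
    return pd.Series(g, index=sub.animal_ids, name="gebv")


def rank_markers(effects: MarkerEffects, top: int | None = None) -> pd.DataFrame:
    """Markers sorted by posterior explained-variance share (stable ties by id)."""
    t = effects.table.sort_index()
    ranked = t.sort_values("var_share", ascending=False, kind="stable")
    ranked = ranked.assign(rank=np.arange(1, len(ranked) + 1))
    return ranked.head(top) if top else ranked
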