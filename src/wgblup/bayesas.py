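"""Region-wise Bayesian whole-genome regression (single- and multi-trait).

The sampler assumes SNPs within a contiguous genome region share one effect
(co)variance that differs between regions.  For two traits the effect of
SNP j (region s) on trait t is decomposed as

    beta_tj = r_t * s0_j  +  r_ts * s1_j  +  bstar_tj

where s0 and s1 are latent SNP vectors shared by the traits (standard
normal priors), r_t is a genome-wide loading carrying the average
between-trait covariance, r_ts a per-region loading carrying the region's
deviation from it, and bstar_tj a trait-specific residual SNP effect,
N(0, sigma2_bstar_t).  Priors: r_t flat; r_ts ~ N(0, sigma2_r_t) with a
flat positive prior on sigma2_r_t; flat positive prior on sigma2_bstar_t;
the 2x2 residual covariance R0 gets a Jeffreys prior by default.  The
per-SNP posterior (co)variances follow the identities

    var(beta_tj)        = r_t^2 + r_ts^2 + sigma2_bstar_t
    cov(beta_Lj, b_Hj)  = r_L r_H + r_Ls r_Hs

accumulated over post-burn-in thinned cycles; they are constant within each
region and feed the weighted-GRM construction.  The single-trait model
drops the genome-wide layer (beta_tj = r_ts s1_j + bstar_tj) and runs with
sigma2_bstar fixed at the multi-trait estimate.

All full conditionals are normal / scaled inverse chi-square / inverse
Wishart; the derivations are standard generalized-least-squares steps and
are spelled out in docs/methods.md.  The per-SNP sweeps are JIT-compiled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .grm import GenotypeMatrix, SnpCovarianceTrack

logger = logging.getLogger(__name__)

__all__ = [
    "RegionPartition",
    "McmcConfig",
    "PosteriorSummary",
    "make_regions",
    "run_multitrait_bayesas",
    "run_singletrait_bayesas",
    "derive_variance_components",
]

_VAR_FLOOR_REL = 1e-10  # relative floor keeping variance draws off exact zero


# ---------------------------------------------------------------------------
# region partitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPartition:
    """Contiguous SNP index ranges sharing one effect (co)variance."""

    mode: str
    k: int | None
    starts: np.ndarray
    ends: np.ndarray  # exclusive

    @property
    def n_regions(self) -> int:
        return len(self.starts)

    @property
    def n_snps(self) -> int:
        return int(self.ends[-1])

    @property
    def region_of(self) -> np.ndarray:
        """Region id of each SNP."""
        sizes = self.ends - self.starts
        return np.repeat(np.arange(self.n_regions), sizes)

    def sizes(self) -> np.ndarray:
        return self.ends - self.starts


def make_regions(snps_per_chrom, mode: str, k: int | None = None
                 ) -> RegionPartition:
    """Partition SNPs into regions: per_snp, fixed_k, chromosome or genome.

    ``snps_per_chrom`` is the per-chromosome SNP count (a ``GeneticMap`` is
    also accepted).  fixed_k regions never span chromosomes; the final
    region of a chromosome may be smaller than k.  A k exceeding the total
    SNP count degrades to one region per chromosome with a warning.
    """
    if hasattr(snps_per_chrom, "n_snps_per_chrom"):
        snps_per_chrom = snps_per_chrom.n_snps_per_chrom
    counts = np.asarray(snps_per_chrom, dtype=np.int64)
    total = int(counts.sum())
    offs = np.concatenate([[0], np.cumsum(counts)])

    if mode == "genome":
        starts, ends = np.array([0]), np.array([total])
    elif mode == "chromosome":
        starts, ends = offs[:-1].copy(), offs[1:].copy()
    elif mode == "per_snp":
        starts = np.arange(total)
        ends = starts + 1
    elif mode == "fixed_k":
        if k is None or k < 1:
            raise ValueError("fixed_k mode needs k >= 1")
        if k > total:
            logger.warning("region size k=%d exceeds the %d available SNPs; "
                           "using one region per chromosome", k, total)
            starts, ends = offs[:-1].copy(), offs[1:].copy()
        else:
            starts_l, ends_l = [], []
            for c in range(len(counts)):
                for s in range(offs[c], offs[c + 1], k):
                    starts_l.append(s)
                    ends_l.append(min(s + k, offs[c + 1]))
            starts, ends = np.array(starts_l), np.array(ends_l)
    else:
        raise ValueError(f"unknown region mode {mode!r}")
    return RegionPartition(mode=mode, k=k, starts=starts.astype(np.int64),
                           ends=ends.astype(np.int64))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.  Defaults: 20,000 cycles, 5,000 burn-in, thin 10,
    which stores 1,500 posterior samples."""

    n_cycles: int = 20_000
    burn_in: int = 5_000
    thinning: int = 10
    seed: int = 0
    r0_prior_df: float = 0.0      # 0 => Jeffreys prior on R0
    r0_prior_scale: np.ndarray | None = None
    residual_refresh: int = 200   # full residual recomputation interval

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_cycles:
            raise ValueError("burn_in must be smaller than n_cycles")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.n_cycles - self.burn_in) // self.thinning


@dataclass
class PosteriorSummary:
    """Posterior means from a BayesAS run.

    ``track`` holds the per-SNP (co)variances (constant within regions);
    ``beta_mean`` the posterior-mean SNP effects (traits x SNPs), which give
    EBVs for any animal as centered-genotypes @ beta_mean.
    """

    track: SnpCovarianceTrack
    R0: np.ndarray
    beta_mean: np.ndarray
    mu_mean: np.ndarray
    sigma2_r: np.ndarray
    sigma2_bstar: np.ndarray
    n_saved: int
    regions: RegionPartition
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """EBVs (n x n_traits) for centered genotype rows X."""
        return np.asarray(X) @ self.beta_mean.T

    @property
    def ebv_reference(self) -> np.ndarray | None:
        return self.diagnostics.get("ebv_reference")


# ---------------------------------------------------------------------------
# JIT kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sample2(q00, q01, q11, r0, r1, z0, z1):
    """Sample from N(Q^-1 r, Q^-1) for a 2x2 precision Q."""
    det = q00 * q11 - q01 * q01
    c00 = q11 / det
    c01 = -q01 / det
    c11 = q00 / det
    m0 = c00 * r0 + c01 * r1
    m1 = c01 * r0 + c11 * r1
    l00 = np.sqrt(c00)
    l10 = c01 / l00
    l11 = np.sqrt(max(c11 - l10 * l10, 1e-300))
    return m0 + l00 * z0, m1 + l10 * z0 + l11 * z1


@njit(cache=True)
def _mt_cycle(Xt, xx, e, mu, s0, s1, r, rts, bstar,
              sigma2_r, sigma2_bstar, W,
              starts, ends, region_of,
              z_mu, z_bstar, z_s, z_r, z_rts,
              chi_r, chi_bstar, var_floor):
    m, n = Xt.shape
    S = starts.shape[0]
    w00, w01, w11 = W[0, 0], W[0, 1], W[1, 1]

    # ---- overall means (flat prior, joint across traits)
    sL = 0.0
    sH = 0.0
    for i in range(n):
        e[0, i] += mu[0]
        e[1, i] += mu[1]
        sL += e[0, i]
        sH += e[1, i]
    m0, m1 = _sample2(n * w00, n * w01, n * w11,
                      w00 * sL + w01 * sH, w01 * sL + w11 * sH,
                      z_mu[0], z_mu[1])
    mu[0] = m0
    mu[1] = m1
    for i in range(n):
        e[0, i] -= mu[0]
        e[1, i] -= mu[1]

    # ---- trait-specific residual SNP effects, bivariate per SNP
    for j in range(m):
        xj = Xt[j]
        bL = bstar[0, j]
        bH = bstar[1, j]
        cL = 0.0
        cH = 0.0
        for i in range(n):
            e0 = e[0, i] + xj[i] * bL
            e1 = e[1, i] + xj[i] * bH
            e[0, i] = e0
            e[1, i] = e1
            cL += xj[i] * e0
            cH += xj[i] * e1
        q00 = xx[j] * w00 + 1.0 / sigma2_bstar[0]
        q01 = xx[j] * w01
        q11 = xx[j] * w11 + 1.0 / sigma2_bstar[1]
        nbL, nbH = _sample2(q00, q01, q11,
                            w00 * cL + w01 * cH, w01 * cL + w11 * cH,
                            z_bstar[j, 0], z_bstar[j, 1])
        bstar[0, j] = nbL
        bstar[1, j] = nbH
        for i in range(n):
            e[0, i] -= xj[i] * nbL
            e[1, i] -= xj[i] * nbH

    # ---- latent vectors s0, s1 jointly per SNP (N(0,1) priors)
    aL = r[0]
    aH = r[1]
    for j in range(m):
        s = region_of[j]
        bL = rts[0, s]
        bH = rts[1, s]
        xj = Xt[j]
        old0 = aL * s0[j] + bL * s1[j]
        old1 = aH * s0[j] + bH * s1[j]
        cL = 0.0
        cH = 0.0
        for i in range(n):
            e0 = e[0, i] + xj[i] * old0
            e1 = e[1, i] + xj[i] * old1
            e[0, i] = e0
            e[1, i] = e1
            cL += xj[i] * e0
            cH += xj[i] * e1
        awa = aL * aL * w00 + 2.0 * aL * aH * w01 + aH * aH * w11
        awb = aL * bL * w00 + (aL * bH + aH * bL) * w01 + aH * bH * w11
        bwb = bL * bL * w00 + 2.0 * bL * bH * w01 + bH * bH * w11
        wc0 = w00 * cL + w01 * cH
        wc1 = w01 * cL + w11 * cH
        n0, n1 = _sample2(xx[j] * awa + 1.0, xx[j] * awb, xx[j] * bwb + 1.0,
                          aL * wc0 + aH * wc1, bL * wc0 + bH * wc1,
                          z_s[j, 0], z_s[j, 1])
        s0[j] = n0
        s1[j] = n1
        new0 = aL * n0 + bL * n1
        new1 = aH * n0 + bH * n1
        for i in range(n):
            e[0, i] -= xj[i] * new0
            e[1, i] -= xj[i] * new1

    # ---- genome-wide loadings r_t (flat prior, joint)
    g0 = np.dot(s0, Xt)
    gg = 1e-12
    cL = 0.0
    cH = 0.0
    for i in range(n):
        e[0, i] += r[0] * g0[i]
        e[1, i] += r[1] * g0[i]
        gg += g0[i] * g0[i]
        cL += g0[i] * e[0, i]
        cH += g0[i] * e[1, i]
    r0n, r1n = _sample2(gg * w00, gg * w01, gg * w11,
                        w00 * cL + w01 * cH, w01 * cL + w11 * cH,
                        z_r[0], z_r[1])
    r[0] = r0n
    r[1] = r1n
    for i in range(n):
        e[0, i] -= r[0] * g0[i]
        e[1, i] -= r[1] * g0[i]

    # ---- region loadings r_ts (N(0, sigma2_r_t) prior, joint per region)
    for s in range(S):
        js, je = starts[s], ends[s]
        g1 = np.dot(s1[js:je], Xt[js:je])
        gg = 0.0
        cL = 0.0
        cH = 0.0
        for i in range(n):
            e[0, i] += rts[0, s] * g1[i]
            e[1, i] += rts[1, s] * g1[i]
            gg += g1[i] * g1[i]
            cL += g1[i] * e[0, i]
            cH += g1[i] * e[1, i]
        q00 = gg * w00 + 1.0 / sigma2_r[0]
        q01 = gg * w01
        q11 = gg * w11 + 1.0 / sigma2_r[1]
        n0, n1 = _sample2(q00, q01, q11,
                          w00 * cL + w01 * cH, w01 * cL + w11 * cH,
                          z_rts[s, 0], z_rts[s, 1])
        rts[0, s] = n0
        rts[1, s] = n1
        for i in range(n):
            e[0, i] -= rts[0, s] * g1[i]
            e[1, i] -= rts[1, s] * g1[i]

    # ---- variance components (scaled inverse chi-square)
    for t in range(2):
        ss = 0.0
        for s in range(S):
            ss += rts[t, s] * rts[t, s]
        sigma2_r[t] = max(ss / chi_r[t], var_floor)
        ss = 0.0
        for j in range(m):
            ss += bstar[t, j] * bstar[t, j]
        sigma2_bstar[t] = max(ss / chi_bstar[t], var_floor)


@njit(cache=True)
def _st_cycle(Xt, xx, e, mu_arr, s1, rts, bstar,
              sigma2_r_arr, sigma2_bstar, sigma2_e,
              starts, ends, region_of,
              z_mu, z_bstar, z_s, z_rts, chi_r, var_floor):
    m, n = Xt.shape
    S = starts.shape[0]
    inv_e = 1.0 / sigma2_e

    tot = 0.0
    for i in range(n):
        e[i] += mu_arr[0]
        tot += e[i]
    prec = n * inv_e
    mu_new = tot * inv_e / prec + z_mu / np.sqrt(prec)
    mu_arr[0] = mu_new
    for i in range(n):
        e[i] -= mu_new

    for j in range(m):
        xj = Xt[j]
        b = bstar[j]
        c = 0.0
        for i in range(n):
            ei = e[i] + xj[i] * b
            e[i] = ei
            c += xj[i] * ei
        prec = xx[j] * inv_e + 1.0 / sigma2_bstar
        nb = c * inv_e / prec + z_bstar[j] / np.sqrt(prec)
        bstar[j] = nb
        for i in range(n):
            e[i] -= xj[i] * nb

    for j in range(m):
        s = region_of[j]
        coef = rts[s]
        xj = Xt[j]
        old = coef * s1[j]
        c = 0.0
        for i in range(n):
            ei = e[i] + xj[i] * old
            e[i] = ei
            c += xj[i] * ei
        prec = xx[j] * coef * coef * inv_e + 1.0
        ns = coef * c * inv_e / prec + z_s[j] / np.sqrt(prec)
        s1[j] = ns
        new = coef * ns
        for i in range(n):
            e[i] -= xj[i] * new

    for s in range(S):
        js, je = starts[s], ends[s]
        g1 = np.dot(s1[js:je], Xt[js:je])
        gg = 0.0
        c = 0.0
        for i in range(n):
            e[i] += rts[s] * g1[i]
            gg += g1[i] * g1[i]
            c += g1[i] * e[i]
        prec = gg * inv_e + 1.0 / sigma2_r_arr[0]
        nr = c * inv_e / prec + z_rts[s] / np.sqrt(prec)
        rts[s] = nr
        for i in range(n):
            e[i] -= rts[s] * g1[i]

    ss = 0.0
    for s in range(S):
        ss += rts[s] * rts[s]
    sigma2_r_arr[0] = max(ss / chi_r, var_floor)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _check_inputs(y: np.ndarray, X: GenotypeMatrix,
                  regions: RegionPartition) -> None:
    if np.isnan(y).any():
        raise ValueError("missing phenotypes are not supported; "
                         "all reference animals need complete records")
    if y.shape[-1] != X.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    if regions.n_snps != X.n_snps:
        raise ValueError(f"region partition covers {regions.n_snps} SNPs, "
                         f"genotype matrix has {X.n_snps}")
    if np.var(y, axis=-1).min() <= 0.0:
        raise ValueError("a trait has zero phenotypic variance")


def _df_flat_positive(count: int) -> int:
    # flat positive prior => scaled-inv-chi2 with df = count - 2, which is
    # proper only beyond 2 deviates; small region counts fall back to df=count
    return count - 2 if count > 2 else max(count, 1)


def run_multitrait_bayesas(y_L: np.ndarray, y_H: np.ndarray,
                           X: GenotypeMatrix, regions: RegionPartition,
                           config: McmcConfig) -> PosteriorSummary:
    """Gibbs sampler for the two-trait region-wise model.

    Phenotypes must be pre-adjusted for all fixed effects except the overall
    mean, which the model fits.  Returns posterior means: the per-SNP
    (co)variance track (constant within regions), residual covariance R0,
    SNP effects, and chain bookkeeping.
    """
    y = np.asarray([y_L, y_H], dtype=float)
    _check_inputs(y, X, regions)
    rng = np.random.default_rng(config.seed)

    n, m = X.n_individuals, X.n_snps
    S = regions.n_regions
    Xt = np.ascontiguousarray(X.X.T)
    xx = np.einsum("ji,ji->j", Xt, Xt)
    starts, ends = regions.starts, regions.ends
    region_of = regions.region_of

    vary = y.var(axis=1)
    s2pq = max(X.sum_2pq, 1e-12)
    vinit = 0.5 * vary / s2pq          # per-SNP effect variance scale
    var_floor = float(_VAR_FLOOR_REL * vinit.min())

    mu = y.mean(axis=1).copy()
    s0 = np.zeros(m)
    s1 = np.zeros(m)
    r = np.full(2, 0.01)               # small positive start breaks the zero trap
    rts = np.full((2, S), 0.01)
    bstar = np.zeros((2, m))
    sigma2_r = vinit.copy()
    sigma2_bstar = vinit.copy()
    R0 = np.diag(0.5 * vary)
    W = np.linalg.inv(R0)
    e = y - mu[:, None]

    df_r = _df_flat_positive(S)
    df_b = _df_flat_positive(m)
    r0_df = config.r0_prior_df
    r0_scale = (np.zeros((2, 2)) if config.r0_prior_scale is None
                else np.asarray(config.r0_prior_scale, float))

    sum_var = np.zeros((2, S))
    sum_cov = np.zeros(S)
    sum_R0 = np.zeros((2, 2))
    sum_beta = np.zeros((2, m))
    sum_mu = np.zeros(2)
    sum_s2r = np.zeros(2)
    sum_s2b = np.zeros(2)
    n_saved = 0

    for cycle in range(1, config.n_cycles + 1):
        _mt_cycle(Xt, xx, e, mu, s0, s1, r, rts, bstar,
                  sigma2_r, sigma2_bstar, W, starts, ends, region_of,
                  rng.standard_normal(2), rng.standard_normal((m, 2)),
                  rng.standard_normal((m, 2)), rng.standard_normal(2),
                  rng.standard_normal((S, 2)),
                  rng.chisquare(df_r, 2), rng.chisquare(df_b, 2), var_floor)

        # residual covariance: inverse-Wishart posterior
        S_e = e @ e.T + r0_scale
        R0 = stats.invwishart.rvs(df=n + r0_df, scale=S_e, random_state=rng)
        R0 = np.atleast_2d(R0)
        W = np.linalg.inv(R0)

        if not (np.isfinite(sigma2_r).all() and np.isfinite(sigma2_bstar).all()
                and np.isfinite(R0).all()):
            raise RuntimeError(f"non-finite state at cycle {cycle}")

        if cycle % config.residual_refresh == 0:
            beta = r[:, None] * s0 + rts[:, region_of] * s1 + bstar
            e = y - mu[:, None] - beta @ Xt

        if cycle > config.burn_in and (cycle - config.burn_in) % config.thinning == 0:
            n_saved += 1
            for t in range(2):
                sum_var[t] += r[t] ** 2 + rts[t] ** 2 + sigma2_bstar[t]
            sum_cov += r[0] * r[1] + rts[0] * rts[1]
            sum_R0 += R0
            sum_beta += r[:, None] * s0 + rts[:, region_of] * s1 + bstar
            sum_mu += mu
            sum_s2r += sigma2_r
            sum_s2b += sigma2_bstar

    assert n_saved == config.n_saved
    region_var = sum_var / n_saved
    region_cov = sum_cov / n_saved
    track = SnpCovarianceTrack(
        var_L=region_var[0][region_of], var_H=region_var[1][region_of],
        cov_LH=region_cov[region_of], region_id=region_of,
        provenance=f"multitrait:{regions.mode}" + (f":{regions.k}" if regions.k else ""))
    beta_mean = sum_beta / n_saved
    summary = PosteriorSummary(
        track=track, R0=sum_R0 / n_saved, beta_mean=beta_mean,
        mu_mean=sum_mu / n_saved, sigma2_r=sum_s2r / n_saved,
        sigma2_bstar=sum_s2b / n_saved, n_saved=n_saved, regions=regions,
        diagnostics={"ebv_reference": X.X @ beta_mean.T})
    return summary


def run_singletrait_bayesas(y_t: np.ndarray, X: GenotypeMatrix,
                            regions: RegionPartition, config: McmcConfig,
                            sigma2_beta_star_fixed: float) -> PosteriorSummary:
    """Single-trait reduction: beta_tj = r_ts s1_j + bstar_tj.

    The trait-specific residual-effect variance is fixed at the value
    estimated by a multi-trait run (by convention, the run with the same
    region partition).
    """
    if sigma2_beta_star_fixed <= 0.0:
        raise ValueError("sigma2_beta_star_fixed must be positive")
    y = np.asarray(y_t, dtype=float)
    _check_inputs(y[None, :], X, regions)
    rng = np.random.default_rng(config.seed)

    n, m = X.n_individuals, X.n_snps
    S = regions.n_regions
    Xt = np.ascontiguousarray(X.X.T)
    xx = np.einsum("ji,ji->j", Xt, Xt)
    starts, ends = regions.starts, regions.ends
    region_of = regions.region_of

    vary = float(np.var(y))
    s2pq = max(X.sum_2pq, 1e-12)
    var_floor = float(_VAR_FLOOR_REL * 0.5 * vary / s2pq)

    mu = np.array([float(np.mean(y))])
    s1 = np.zeros(m)
    rts = np.full(S, 0.01)
    bstar = np.zeros(m)
    sigma2_r = np.array([0.5 * vary / s2pq])
    sigma2_e = 0.5 * vary
    e = y - mu[0]

    df_r = _df_flat_positive(S)

    sum_var = np.zeros(S)
    sum_beta = np.zeros(m)
    sum_mu = 0.0
    sum_s2r = 0.0
    sum_s2e = 0.0
    n_saved = 0

    for cycle in range(1, config.n_cycles + 1):
        _st_cycle(Xt, xx, e, mu, s1, rts, bstar,
                  sigma2_r, sigma2_beta_star_fixed, sigma2_e,
                  starts, ends, region_of,
                  float(rng.standard_normal()), rng.standard_normal(m),
                  rng.standard_normal(m), rng.standard_normal(S),
                  float(rng.chisquare(df_r)), var_floor)

        sigma2_e = float(e @ e) / rng.chisquare(n)  # Jeffreys prior
        if not (np.isfinite(sigma2_e) and np.isfinite(sigma2_r[0])):
            raise RuntimeError(f"non-finite state at cycle {cycle}")

        if cycle % config.residual_refresh == 0:
            beta = rts[region_of] * s1 + bstar
            e = y - mu[0] - beta @ Xt

        if cycle > config.burn_in and (cycle - config.burn_in) % config.thinning == 0:
            n_saved += 1
            sum_var += rts ** 2 + sigma2_beta_star_fixed
            sum_beta += rts[region_of] * s1 + bstar
            sum_mu += mu[0]
            sum_s2r += sigma2_r[0]
            sum_s2e += sigma2_e

    assert n_saved == config.n_saved
    region_var = sum_var / n_saved
    track = SnpCovarianceTrack(
        var_L=region_var[region_of], region_id=region_of,
        provenance=f"singletrait:{regions.mode}" + (f":{regions.k}" if regions.k else ""))
    beta_mean = (sum_beta / n_saved)[None, :]
    return PosteriorSummary(
        track=track, R0=np.array([[sum_s2e / n_saved]]), beta_mean=beta_mean,
        mu_mean=np.array([sum_mu / n_saved]), sigma2_r=np.array([sum_s2r / n_saved]),
        sigma2_bstar=np.array([sigma2_beta_star_fixed]), n_saved=n_saved,
        regions=regions,
        diagnostics={"ebv_reference": X.X @ beta_mean.T})


# ---------------------------------------------------------------------------
# trait-level components
# ---------------------------------------------------------------------------

def derive_variance_components(track: SnpCovarianceTrack,
                               frequencies: np.ndarray
                               ) -> tuple[float, float | None, float | None]:
    """Genomic (co)variance components from a per-SNP track.

    Under Hardy-Weinberg, sigma2_u_t = sum_j 2 p_j q_j var_tj and
    sigma_uLH = sum_j 2 p_j q_j cov_j.
    """
    p = np.asarray(frequencies, dtype=float)
    if len(p) != track.n_snps:
        raise ValueError("frequencies and track are not aligned")
    w = 2.0 * p * (1.0 - p)
    s2u_L = float(w @ track.var_L)
    if not track.is_bivariate:
        return s2u_L, None, None
    return s2u_L, float(w @ track.var_H), float(w @ track.cov_LH)
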