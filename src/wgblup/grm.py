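"""Genomic relationship matrices, unweighted and SNP-(co)variance weighted.

The unweighted matrix is G = X D X' with X the column-centered 0/1/2 dosage
matrix and D = I / sum_j 2 p_j q_j (VanRaden method 1).  The weighted
variant replaces the common diagonal by per-SNP entries proportional to
externally estimated SNP (co)variances, yielding a trait pair's triple
(G_L, G_H, G_LH): d_{L,j} = (sigma2_{bL,j} / sigma2_bL) / sum 2pq and
analogously for H and the cross matrix.  The trait-level denominators
default to the mean of the per-SNP values so the weights average one and a
uniform track reproduces the unweighted G exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "SnpCovarianceTrack",
    "GrmSet",
    "center_genotypes",
    "build_grm",
    "build_weighted_grms",
    "repair_psd",
    "write_track",
    "read_track",
    "write_grm",
    "read_grm",
]


@dataclass
class GenotypeMatrix:
    """Centered dosages plus the allele frequencies used to center them."""

    X: np.ndarray                # individuals x SNPs, centered
    frequencies: np.ndarray      # p_j per retained SNP
    snp_indices: np.ndarray      # indices into the original panel
    centered: bool = True

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    @property
    def sum_2pq(self) -> float:
        p = self.frequencies
        return float(np.sum(2.0 * p * (1.0 - p)))


@dataclass
class SnpCovarianceTrack:
    """Per-SNP effect (co)variances, constant within estimation regions."""

    var_L: np.ndarray
    var_H: np.ndarray | None = None
    cov_LH: np.ndarray | None = None
    region_id: np.ndarray | None = None
    provenance: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.var_L)

    @property
    def is_bivariate(self) -> bool:
        return self.var_H is not None and self.cov_LH is not None


@dataclass
class GrmSet:
    """Either one common G or the weighted triple (G_L, G_H, G_LH)."""

    G: np.ndarray | None = None
    G_L: np.ndarray | None = None
    G_H: np.ndarray | None = None
    G_LH: np.ndarray | None = None
    sum_2pq: float = 0.0
    trait_var_L: float | None = None
    trait_var_H: float | None = None
    trait_cov_LH: float | None = None

    @property
    def weighted(self) -> bool:
        return self.G_L is not None


# ---------------------------------------------------------------------------

def center_genotypes(dosages: np.ndarray,
                     frequencies: np.ndarray | str = "observed"
                     ) -> GenotypeMatrix:
    """Center a 0/1/2 dosage matrix to X = dosage - 2p per column.

    With ``frequencies="observed"`` each column p_j is the observed allele
    frequency, so columns sum to zero exactly.  Externally supplied
    frequencies (e.g. from a reference generation) are used as-is; columns
    then need not sum to zero.  Monomorphic SNPs (observed p in {0, 1}) are
    dropped with a warning.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim != 2:
        raise ValueError("dosages must be 2-D (individuals x SNPs)")
    obs_p = D.mean(axis=0) / 2.0
    if isinstance(frequencies, str):
        if frequencies != "observed":
            raise ValueError("frequencies must be an array or 'observed'")
        p = obs_p
    else:
        p = np.asarray(frequencies, dtype=float)
        if len(p) != D.shape[1]:
            raise ValueError("frequency vector length mismatch")

    keep = (obs_p > 0.0) & (obs_p < 1.0) & (p > 0.0) & (p < 1.0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d monomorphic SNP(s) before centering", n_drop)
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; nothing to center")
    return GenotypeMatrix(X=D[:, keep] - 2.0 * p[keep],
                          frequencies=p[keep],
                          snp_indices=np.flatnonzero(keep))


def build_grm(X: GenotypeMatrix) -> GrmSet:
    """Unweighted G = X X' / sum(2 p_j q_j)."""
    if not X.centered:
        raise ValueError("genotypes must be centered first")
    s2pq = X.sum_2pq
    if s2pq <= 0.0:
        raise ValueError("sum of 2pq is zero; no polymorphic SNPs")
    G = X.X @ X.X.T / s2pq
    G = (G + G.T) / 2.0
    return GrmSet(G=G, sum_2pq=s2pq)


def _weighted(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    G = (X * w) @ X.T
    return (G + G.T) / 2.0


def build_weighted_grms(X: GenotypeMatrix, track: SnpCovarianceTrack,
                        trait_var_L: float | None = None,
                        trait_var_H: float | None = None,
                        trait_cov_LH: float | None = None,
                        cov_tol: float = 1e-12) -> GrmSet:
    """Weighted triple G_L, G_H, G_LH from a per-SNP (co)variance track.

    The j'th diagonal entries are the per-SNP (co)variances divided by the
    trait-level values and by sum(2pq).  Trait-level denominators default to
    the per-SNP means of the track, which centers the weights at one; with
    an explicit near-zero ``trait_cov_LH`` and a non-degenerate covariance
    track this is an error (the ratio is unstable), and the caller is told
    to fall back to the mean normalization.
    """
    if not track.is_bivariate:
        raise ValueError("weighted GRMs need a bivariate track")
    if track.n_snps != X.n_snps:
        raise ValueError(f"track covers {track.n_snps} SNPs, genotype matrix "
                         f"has {X.n_snps}")
    s2pq = X.sum_2pq
    vL = float(np.mean(track.var_L)) if trait_var_L is None else float(trait_var_L)
    vH = float(np.mean(track.var_H)) if trait_var_H is None else float(trait_var_H)
    cLH = float(np.mean(track.cov_LH)) if trait_cov_LH is None else float(trait_cov_LH)
    if vL <= 0.0 or vH <= 0.0:
        raise ValueError("trait-level variances must be positive")
    if abs(cLH) < cov_tol:
        if np.any(np.abs(track.cov_LH) > cov_tol):
            raise ValueError(
                "trait-level covariance is ~0 while per-SNP covariances are "
                "not; use the default mean normalization (trait_cov_LH=None)")
        cLH = 1.0  # all-zero covariance track: G_LH is exactly zero anyway

    G_L = _weighted(X.X, track.var_L / (vL * s2pq))
    G_H = _weighted(X.X, track.var_H / (vH * s2pq))
    G_LH = _weighted(X.X, track.cov_LH / (cLH * s2pq))
    return GrmSet(G_L=G_L, G_H=G_H, G_LH=G_LH, sum_2pq=s2pq,
                  trait_var_L=vL, trait_var_H=vH, trait_cov_LH=cLH)


def repair_psd(track: SnpCovarianceTrack,
               shrink: float = 0.999) -> SnpCovarianceTrack:
    """Clip per-SNP covariances that violate |cov| <= sqrt(var_L * var_H).

    Posterior means of the per-SNP 2x2 blocks need not be PSD even when
    every sample is; clipping to ``shrink`` times the bound restores it.
    """
    if not track.is_bivariate:
        return track
    bound = shrink * np.sqrt(track.var_L * track.var_H)
    bad = np.abs(track.cov_LH) > bound
    if not bad.any():
        return track
    logger.info("PSD repair: clipping %d of %d per-SNP covariances",
                int(bad.sum()), track.n_snps)
    cov = np.where(bad, np.sign(track.cov_LH) * bound, track.cov_LH)
    return SnpCovarianceTrack(var_L=track.var_L.copy(), var_H=track.var_H.copy(),
                              cov_LH=cov, region_id=track.region_id,
                              provenance=track.provenance)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_track(track: SnpCovarianceTrack, path) -> None:
    pd.DataFrame({
        "snp_id": np.arange(track.n_snps),
        "region_id": (track.region_id if track.region_id is not None
                      else np.zeros(track.n_snps, int)),
        "var_L": track.var_L,
        "var_H": (track.var_H if track.var_H is not None
                  else np.zeros(track.n_snps)),
        "cov_LH": (track.cov_LH if track.cov_LH is not None
                   else np.zeros(track.n_snps)),
    }).to_csv(path, sep="\t", index=False)


def read_track(path) -> SnpCovarianceTrack:
    df = pd.read_csv(path, sep="\t")
    return SnpCovarianceTrack(var_L=df["var_L"].to_numpy(),
                              var_H=df["var_H"].to_numpy(),
                              cov_LH=df["cov_LH"].to_numpy(),
                              region_id=df["region_id"].to_numpy())


def write_grm(G: np.ndarray, ids: np.ndarray, path) -> None:
    pd.DataFrame(G, index=ids, columns=ids).to_csv(path, sep="\t")


def read_grm(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), df.index.to_numpy()
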