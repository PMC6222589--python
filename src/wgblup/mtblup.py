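"""Single- and multi-trait (weighted) GBLUP via covariance projection.

The model for two traits L and H over n animals is

    y = u + e,   u ~ N(0, K),   e ~ N(0, R0 (x) I)

with K = [[s2uL * G_L, suLH * G_LH], [suLH * G_LH, s2uH * G_H]] in the
weighted case, or the same structure with one common G otherwise.  Breeding
values are the BLUP u_hat = Cov(u, y') Var(y)^-1 y, evaluated both for the
phenotyped reference animals and, through the genomic covariances, for
unphenotyped test animals.  Phenotypes are centered by their mean before
solving; variance components are inputs (estimated upstream by the Bayesian
sampler), not estimated here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .grm import GrmSet

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "validate_components",
    "solve_gblup_multi",
    "solve_gblup_single",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Genomic and residual 2x2 (co)variance components."""

    s2u_L: float
    s2u_H: float
    su_LH: float
    s2e_L: float
    s2e_H: float
    se_LH: float = 0.0

    @property
    def genetic(self) -> np.ndarray:
        return np.array([[self.s2u_L, self.su_LH], [self.su_LH, self.s2u_H]])

    @property
    def residual(self) -> np.ndarray:
        return np.array([[self.s2e_L, self.se_LH], [self.se_LH, self.s2e_H]])


def validate_components(vc: VarianceComponents,
                        shrink: float = 0.999) -> VarianceComponents:
    """Ensure both 2x2 matrices are positive definite.

    Non-positive variances are an error; covariances exceeding the
    Cauchy-Schwarz bound are shrunk to ``shrink`` times it with a warning.
    """
    if min(vc.s2u_L, vc.s2u_H, vc.s2e_L, vc.s2e_H) <= 0.0:
        raise ValueError("variances must be strictly positive")
    su, se = vc.su_LH, vc.se_LH
    bound_u = shrink * np.sqrt(vc.s2u_L * vc.s2u_H)
    bound_e = shrink * np.sqrt(vc.s2e_L * vc.s2e_H)
    if abs(su) > bound_u:
        logger.warning("genetic covariance %.4g exceeds the PSD bound; "
                       "shrinking to %.4g", su, np.sign(su) * bound_u)
        su = float(np.sign(su) * bound_u)
    if abs(se) > bound_e:
        logger.warning("residual covariance %.4g exceeds the PSD bound; "
                       "shrinking to %.4g", se, np.sign(se) * bound_e)
        se = float(np.sign(se) * bound_e)
    return replace(vc, su_LH=su, se_LH=se)


def _solve_projection(K_all_ref: np.ndarray, V: np.ndarray,
                      y: np.ndarray) -> np.ndarray:
    """u_hat = K_{all,ref} V^-1 y with a jittered Cholesky fallback."""
    try:
        cho = linalg.cho_factor(V, check_finite=False)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(V)))
        logger.warning("(K+R) factorization failed; retrying with jitter %.3g",
                       jitter)
        try:
            cho = linalg.cho_factor(V + jitter * np.eye(len(V)),
                                    check_finite=False)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "(K+R) is singular even after jitter; check the variance "
                "components and GRM conditioning") from err
    return K_all_ref @ linalg.cho_solve(cho, y, check_finite=False)


def _indices(ids: np.ndarray, subset: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids)
    subset = np.asarray(subset)
    pos = {v: i for i, v in enumerate(ids)}
    missing = [v for v in subset if v not in pos]
    if missing:
        raise KeyError(f"{what} ids not present in the GRM: {missing[:5]}")
    return np.array([pos[v] for v in subset], dtype=np.int64)


def solve_gblup_multi(y_L: np.ndarray, y_H: np.ndarray, grms: GrmSet,
                      vc: VarianceComponents, ids: np.ndarray,
                      reference_ids: np.ndarray, test_ids: np.ndarray,
                      method_tag: str = "", region_tag: str = ""
                      ) -> pd.DataFrame:
    """Two-trait (w)GBLUP EBVs for reference and test animals.

    ``grms`` may hold one common G (GBLUP) or the weighted triple
    (wGBLUP).  ``ids`` orders the GRM rows; reference animals carry the
    phenotypes, test animals are predicted by covariance projection.
    """
    vc = validate_components(vc)
    ref = _indices(ids, reference_ids, "reference")
    tst = _indices(ids, test_ids, "test")
    y = np.concatenate([np.asarray(y_L, float) - np.mean(y_L),
                        np.asarray(y_H, float) - np.mean(y_H)])
    if len(y) != 2 * len(ref):
        raise ValueError("phenotype vectors must match the reference ids")

    if grms.weighted:
        G_L, G_H, G_LH = grms.G_L, grms.G_H, grms.G_LH
    else:
        G_L = G_H = G_LH = grms.G

    allidx = np.concatenate([ref, tst])
    K_ar = np.block([
        [vc.s2u_L * G_L[np.ix_(allidx, ref)], vc.su_LH * G_LH[np.ix_(allidx, ref)]],
        [vc.su_LH * G_LH[np.ix_(allidx, ref)], vc.s2u_H * G_H[np.ix_(allidx, ref)]],
    ])
    n_ref = len(ref)
    V = np.block([
        [vc.s2u_L * G_L[np.ix_(ref, ref)], vc.su_LH * G_LH[np.ix_(ref, ref)]],
        [vc.su_LH * G_LH[np.ix_(ref, ref)], vc.s2u_H * G_H[np.ix_(ref, ref)]],
    ]) + np.kron(vc.residual, np.eye(n_ref))

    u = _solve_projection(K_ar, V, y)
    n_all = len(allidx)
    ebv_L, ebv_H = u[:n_all], u[n_all:]
    out_ids = np.concatenate([np.asarray(reference_ids), np.asarray(test_ids)])
    return pd.DataFrame({
        "id": out_ids,
        "role": ["reference"] * len(ref) + ["test"] * len(tst),
        "ebv_L": ebv_L,
        "ebv_H": ebv_H,
        "method": method_tag or ("wgblup" if grms.weighted else "gblup"),
        "region": region_tag,
    })


def solve_gblup_single(y_t: np.ndarray, G: np.ndarray, s2u: float, s2e: float,
                       ids: np.ndarray, reference_ids: np.ndarray,
                       test_ids: np.ndarray, method_tag: str = "",
                       region_tag: str = "") -> pd.DataFrame:
    """Single-trait specialization: u_hat = s2u G_ar (s2u G_rr + s2e I)^-1 y."""
    if s2u <= 0.0 or s2e < 0.0:
        raise ValueError("s2u must be positive and s2e non-negative")
    ref = _indices(ids, reference_ids, "reference")
    tst = _indices(ids, test_ids, "test")
    y = np.asarray(y_t, float) - np.mean(y_t)
    if len(y) != len(ref):
        raise ValueError("phenotype vector must match the reference ids")

    allidx = np.concatenate([ref, tst])
    K_ar = s2u * G[np.ix_(allidx, ref)]
    V = s2u * G[np.ix_(ref, ref)] + s2e * np.eye(len(ref))
    u = _solve_projection(K_ar, V, y)
    out_ids = np.concatenate([np.asarray(reference_ids), np.asarray(test_ids)])
    return pd.DataFrame({
        "id": out_ids,
        "role": ["reference"] * len(ref) + ["test"] * len(tst),
        "ebv": u,
        "method": method_tag or "gblup",
        "region": region_tag,
    })
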