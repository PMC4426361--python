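"""Distance-Distance analysis: classical Mahalanobis distance, the
Stahel-Donoho robust distance via projection-pursuit outlyingness, and
chi-square-cutoff outlier classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAD_SCALE = 1.4826  # consistency factor for normal data


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-standardize (mean 0, sample SD 1, ddof=1)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (X - X.mean(axis=0)) / sd


def mahalanobis(X: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Classical Mahalanobis distance of each row from the centroid.

    The sample covariance is regularized by ridge * trace/p only if it
    is numerically singular.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    center = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        S = S + ridge * np.trace(S) / p * np.eye(p)
        Sinv = np.linalg.inv(S)
    d = X - center
    return np.sqrt(np.einsum("ij,jk,ik->i", d, Sinv, d))


@dataclass
class StahelDonohoResult:
    location: np.ndarray
    scatter: np.ndarray
    rd: np.ndarray
    outlyingness: np.ndarray
    weights: np.ndarray


def stahel_donoho(
    X: np.ndarray,
    n_directions: int | None = None,
    seed: int = 0,
) -> StahelDonohoResult:
    """Stahel-Donoho robust location/scatter and robust distances.

    Directions are the p coordinate axes plus normalized differences of
    seeded random row pairs.  Outlyingness of row i is the max over
    directions of |proj_i - median(proj)| / (1.4826 * MAD(proj));
    weights are the Huber-type min(1, (c/r)^2) with c = sqrt of the 95%
    chi-square quantile at p df.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= 2 * p:
        raise ValueError(f"need n > 2p (n={n}, p={p})")
    if n_directions is None:
        n_directions = 250 * p
    rng = np.random.default_rng(seed)
    dirs = [np.eye(p)]
    ii = rng.integers(0, n, size=n_directions)
    jj = rng.integers(0, n, size=n_directions)
    diff = X[ii] - X[jj]
    norms = np.linalg.norm(diff, axis=1)
    keep = norms > 1e-12
    dirs.append(diff[keep] / norms[keep, None])
    D = np.vstack(dirs)  # (n_dir, p)

    proj = X @ D.T  # (n, n_dir)
    med = np.median(proj, axis=0)
    mad = MAD_SCALE * np.median(np.abs(proj - med), axis=0)
    usable = mad > 1e-12
    if not np.any(usable):
        raise ValueError("all projection directions have zero MAD")
    r = np.max(np.abs(proj[:, usable] - med[usable]) / mad[usable], axis=1)

    # hard-rejection weights: points beyond the 95% chi-square
    # outlyingness radius carry no weight, so clustered outliers cannot
    # inflate the scatter (the masking effect this estimator exists to
    # avoid); the scatter is rescaled for chi-square consistency.
    c = np.sqrt(stats.chi2.ppf(0.95, p))
    w = (r <= c).astype(float)
    if w.sum() <= p:
        raise ValueError("too few points with non-zero weight")
    sw = w.sum()
    loc = (w[:, None] * X).sum(axis=0) / sw
    centered = X - loc
    scatter = (w[:, None] * centered).T @ centered / sw
    Sinv = np.linalg.pinv(scatter)
    d2 = np.einsum("ij,jk,ik->i", centered, Sinv, centered)
    consistency = np.median(d2) / stats.chi2.ppf(0.5, p)
    if consistency > 0:
        scatter = scatter * consistency
        d2 = d2 / consistency
    rd = np.sqrt(d2)
    return StahelDonohoResult(
        location=loc, scatter=scatter, rd=rd, outlyingness=r, weights=w
    )


@dataclass
class DDResult:
    md: np.ndarray
    rd: np.ndarray
    cutoff: float
    outlier_md: np.ndarray
    outlier_rd: np.ndarray
    quadrant: list[str]  # none | md_only | rd_only | both

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "md": self.md,
                "rd": self.rd,
                "outlier_md": self.outlier_md,
                "outlier_rd": self.outlier_rd,
                "quadrant": self.quadrant,
            },
            index=index,
        )


def dd_cutoff(p: int = 8, quantile: float = 0.975) -> float:
    """sqrt of the chi-square quantile at p df (4.19 for p=8, q=0.975)."""
    return float(np.sqrt(stats.chi2.ppf(quantile, p)))


def dd_classify(
    md: np.ndarray, rd: np.ndarray, p: int = 8, quantile: float = 0.975
) -> DDResult:
    md = np.asarray(md, dtype=float)
    rd = np.asarray(rd, dtype=float)
    if md.shape != rd.shape:
        raise ValueError("md and rd must have equal length")
    cutoff = dd_cutoff(p, quantile)
    out_md = md > cutoff
    out_rd = rd > cutoff
    quadrant = [
        "both" if m and r else "rd_only" if r else "md_only" if m else "none"
        for m, r in zip(out_md, out_rd)
    ]
    return DDResult(
        md=md, rd=rd, cutoff=cutoff,
        outlier_md=out_md, outlier_rd=out_rd, quadrant=quadrant,
    )
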