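"""Differential accessibility by regularized-log (rlog) fold change.

Counts are normalized by median-of-ratios size factors, per-peak
dispersions are estimated by method of moments with a 1/mean trend, and a
closed-form empirical-Bayes shrinkage produces rlog values on the log2
scale:

    beta_ij = log2(n_ij + 0.5) - mu_i,   mu_i = mean_j log2(n_ij + 0.5)
    w_ij    = (1/ln 2)^2 * (1/(n_ij + 0.5) + alpha_i)      (delta method)
    sigma^2 = (q95(|beta|) / 1.645)^2                      (matched prior)
    c_ij    = sigma^2 / (sigma^2 + w_ij)
    rlog_ij = mu_i + c_ij * beta_ij

Low counts carry large sampling variance w and are shrunk hard toward the
row mean, so fold changes from weak peaks cannot dominate.  A peak is
called *opening* for an ordered condition pair (A, B) when
rlog_B - rlog_A >= log2(1.5), *closing* when <= -log2(1.5) (ties at the
threshold are classified as differential), else *unchanged*.

No replication is assumed: samples are the conditions themselves, and the
dispersion is estimated across them as a blind design — a documented
limitation inherited from non-replicated library designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import CountMatrix

__all__ = [
    "DEFAULT_THRESHOLD",
    "DispersionFit",
    "RlogResult",
    "OverlapSummary",
    "size_factors",
    "fit_dispersion",
    "rlog_transform",
    "classify_peaks",
    "pca_samples",
    "random_split",
    "overlap_summary",
]

DEFAULT_THRESHOLD = math.log2(1.5)
LN2_SQ_INV = (1.0 / math.log(2.0)) ** 2
A0_FLOOR = 0.01
PRIOR_VAR_FLOOR = 1e-6


@dataclass
class DispersionFit:
    """Method-of-moments dispersions with an alpha(mu) = a0 + a1/mu trend."""

    alpha: np.ndarray      # raw per-peak MoM dispersion, >= 0
    a0: float
    a1: float
    trended: np.ndarray    # dispersion used downstream, > 0


@dataclass
class RlogResult:
    """Shrunken log2 accessibility per peak x sample."""

    peak_ids: list[str]
    samples: list[str]
    rlog: np.ndarray
    mu: np.ndarray
    shrinkage: np.ndarray
    prior_var: float

    def _col(self, cond: str) -> int:
        try:
            return self.samples.index(cond)
        except ValueError:
            raise KeyError(f"unknown condition label {cond!r}") from None

    def fold_change(self, pair: tuple[str, str]) -> np.ndarray:
        """rlogFC for the ordered pair (A, B): rlog_B - rlog_A."""
        a, b = pair
        return self.rlog[:, self._col(b)] - self.rlog[:, self._col(a)]


@dataclass
class OverlapSummary:
    """Cross-pair sharing of differential peak IDs, per class."""

    per_class: dict[str, tuple[int, int, int]]  # class -> (n_A, n_shared, pct)


def _as_counts(counts: CountMatrix | pd.DataFrame) -> tuple[np.ndarray,
                                                            list[str],
                                                            list[str]]:
    if isinstance(counts, pd.DataFrame):
        counts = CountMatrix.from_frame(counts)
    return counts.counts.astype(float), list(counts.peak_ids), list(counts.samples)


def size_factors(counts: CountMatrix | pd.DataFrame,
                 fallback: str = "error") -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``fallback='positive'`` computes the per-peak geometric reference over
    all peaks with at least one positive count (using only their positive
    entries) when no peak is positive in every sample.
    """
    K, _, samples = _as_counts(counts)
    if K.shape[1] < 1:
        raise ValueError("need >= 1 sample")
    all_pos = (K > 0).all(axis=1)
    if all_pos.any():
        logK = np.log(K[all_pos])
        ref = logK.mean(axis=1, keepdims=True)
        s = np.exp(np.median(logK - ref, axis=0))
    elif fallback == "positive":
        any_pos = (K > 0).any(axis=1)
        if not any_pos.any():
            raise ValueError("all counts are zero")
        with np.errstate(divide="ignore"):
            logK = np.where(K[any_pos] > 0, np.log(K[any_pos]), np.nan)
        ref = np.nanmean(logK, axis=1, keepdims=True)
        s = np.exp(np.nanmedian(logK - ref, axis=0))
    else:
        raise ValueError(
            "no peak has positive counts in every sample; simulate deeper "
            "libraries or pass fallback='positive'"
        )
    s = s / np.exp(np.mean(np.log(s)))
    return s


def fit_dispersion(counts: CountMatrix | pd.DataFrame,
                   size_factors_: np.ndarray) -> DispersionFit:
    """Method-of-moments dispersion per peak plus a 1/mean trend.

    alpha_i = max(0, (v_i - m_i) / m_i^2) on normalized counts; the trend
    (a0, a1) is least squares of the positive alphas on 1/m, with a0
    floored at 0.01 and the trended value floored to stay positive.
    """
    K, _, samples = _as_counts(counts)
    if K.shape[1] < 2:
        raise ValueError("dispersion needs >= 2 samples")
    if K.shape[0] < 10:
        import warnings

        warnings.warn("fewer than 10 peaks; dispersion trend is unstable")
    n = K / np.asarray(size_factors_)
    m = n.mean(axis=1)
    v = n.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
    alpha = np.maximum(alpha, 0.0)
    use = (alpha > 0) & (m > 0)
    if use.sum() >= 2:
        X = np.column_stack([np.ones(use.sum()), 1.0 / m[use]])
        coef, *_ = np.linalg.lstsq(X, alpha[use], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = A0_FLOOR, 0.0
    a0 = max(a0, A0_FLOOR)
    with np.errstate(divide="ignore"):
        trended = a0 + a1 / np.maximum(m, 1e-300)
    trended = np.maximum(trended, 1e-8)
    return DispersionFit(alpha, a0, a1, trended)


def rlog_transform(counts: CountMatrix | pd.DataFrame,
                   size_factors_: np.ndarray,
                   dispersion: DispersionFit,
                   prior_var: float | None = None) -> RlogResult:
    """Empirical-Bayes shrunken log2 transform (see module docstring).

    ``prior_var`` overrides the quantile-matched prior variance; pass
    ``numpy.inf`` to disable shrinkage entirely (plain log2(n + 0.5)).
    """
    K, peak_ids, samples = _as_counts(counts)
    n = K / np.asarray(size_factors_)
    logn = np.log2(n + 0.5)
    mu = logn.mean(axis=1)
    beta = logn - mu[:, None]
    w = LN2_SQ_INV * (1.0 / (n + 0.5) + dispersion.trended[:, None])
    if prior_var is None:
        finite = np.abs(beta[np.isfinite(beta)])
        sigma2 = max((np.quantile(finite, 0.95) / 1.645) ** 2,
                     PRIOR_VAR_FLOOR) if finite.size else PRIOR_VAR_FLOOR
    else:
        sigma2 = float(prior_var)
    if np.isinf(sigma2):
        c = np.ones_like(w)
    else:
        c = sigma2 / (sigma2 + w)
    rlog = mu[:, None] + c * beta
    return RlogResult(peak_ids, samples, rlog, mu, c, sigma2)


def classify_peaks(rlog: RlogResult, pair: tuple[str, str],
                   threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """Label every peak opening/closing/unchanged for the ordered pair."""
    fc = rlog.fold_change(pair)
    labels = np.where(fc >= threshold, "opening",
                      np.where(fc <= -threshold, "closing", "unchanged"))
    return pd.Series(labels, index=rlog.peak_ids, name=f"{pair[0]}:{pair[1]}")


def pca_samples(rlog: RlogResult, top_n: int = 500
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over the ``top_n`` most variable peaks.

    Returns per-sample PC coordinates and the fraction of variance per PC.
    """
    if len(rlog.samples) < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = rlog.rlog
    rowvar = X.var(axis=1)
    if top_n < X.shape[0]:
        keep = np.argsort(rowvar)[::-1][:top_n]
        X = X[keep]
    Xc = X - X.mean(axis=1, keepdims=True)
    total = (Xc ** 2).sum()
    if total == 0:
        raise ValueError("zero total variance across samples")
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    coords = U * S
    var_frac = S ** 2 / (S ** 2).sum()
    n_pc = min(len(S), len(rlog.samples))
    df = pd.DataFrame(
        coords[:, :n_pc], index=rlog.samples,
        columns=[f"PC{i + 1}" for i in range(n_pc)],
    )
    return df, var_frac[:n_pc]


def random_split(peak_ids: list[str], seed: int
                 ) -> tuple[list[str], list[str]]:
    """Assign each peak independently to one of two subgroups (p = 0.5)."""
    if len(peak_ids) < 2:
        raise ValueError("need >= 2 peaks to split")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, len(peak_ids))
    g1 = [p for p, b in zip(peak_ids, pick) if b == 0]
    g2 = [p for p, b in zip(peak_ids, pick) if b == 1]
    return g1, g2


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def overlap_summary(class_a: pd.Series, class_b: pd.Series) -> OverlapSummary:
    """Per-class sharing of differential peak IDs between two contrasts.

    Both classifications must cover the same atlas peak-ID universe.  The
    percentage is 100 * n_shared / n_A rounded half away from zero.
    """
    if set(class_a.index) != set(class_b.index):
        raise ValueError("classifications cover different peak-ID universes")
    per_class: dict[str, tuple[int, int, int]] = {}
    for klass in ("opening", "closing"):
        ids_a = set(class_a.index[class_a == klass])
        ids_b = set(class_b.index[class_b == klass])
        n_a = len(ids_a)
        n_shared = len(ids_a & ids_b)
        pct = _round_half_away(100.0 * n_shared / n_a) if n_a else 0
        per_class[klass] = (n_a, n_shared, pct)
    return OverlapSummary(per_class)
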