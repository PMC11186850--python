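"""Summary-data MR estimators with heterogeneity, pleiotropy and direction diagnostics.

All estimators consume per-variant exposure effects (b_x, se_x) and outcome
effects (b_y, se_y) expressed on a shared effect allele — either as a
:class:`~pwmr.harmonize.HarmonizedPair` or as bare arrays.  Binary-outcome
betas are log odds ratios throughout; ``odds_ratio`` is exp(beta).

Estimators
----------
wald_ratio        single-instrument ratio (first-order delta-method SE)
ivw               random-effects inverse-variance-weighted meta-analysis
ivw_correlated    generalized least squares under an LD covariance
mr_egger          weighted regression with intercept (pleiotropy test)
weighted_median   robust to <50% invalid weight
weighted_mode     kernel-mode of the ratio distribution
steiger_test      directionality by variance explained
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair
from .io import LDMatrix

__all__ = [
    "MRResult",
    "SteigerResult",
    "wald_ratio",
    "ivw",
    "ivw_correlated",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "steiger_test",
]

_Z95 = stats.norm.ppf(0.975)


class NotEstimableError(ValueError):
    """Too few variants for the requested estimator."""


@dataclass
class MRResult:
    """One estimator's causal estimate with diagnostics.

    ``beta`` is on the outcome scale per unit exposure (log odds for a binary
    outcome); ``odds_ratio`` = exp(beta) when the outcome is binary.  ``Q`` /
    ``Q_pval`` are Cochran's heterogeneity about the fitted slope;
    ``egger_intercept`` / ``intercept_pval`` are set by MR-Egger only.
    """

    method: str
    n_snps: int
    beta: float
    se: float
    pval: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    odds_ratio: float = np.nan
    Q: float = np.nan
    Q_pval: float = np.nan
    egger_intercept: float = np.nan
    intercept_pval: float = np.nan
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low) and np.isfinite(self.se):
            self.ci_low = self.beta - _Z95 * self.se
            self.ci_high = self.beta + _Z95 * self.se

    def with_or(self) -> "MRResult":
        self.odds_ratio = float(np.exp(self.beta))
        return self


def _unpack(pair, se_x=None, b_y=None, se_y=None):
    """Accept a HarmonizedPair or four arrays (b_x, se_x, b_y, se_y)."""
    if isinstance(pair, HarmonizedPair):
        return pair.b_x, pair.se_x, pair.b_y, pair.se_y, pair.outcome_type == "binary"
    b_x = np.asarray(pair, dtype=float)
    return (
        b_x,
        np.asarray(se_x, dtype=float),
        np.asarray(b_y, dtype=float),
        np.asarray(se_y, dtype=float),
        False,
    )


def _finish(res: MRResult, binary: bool) -> MRResult:
    return res.with_or() if binary else res


# ---------------------------------------------------------------------------


def wald_ratio(b_x, se_x, b_y, se_y, second_order: bool = False, binary: bool = False) -> MRResult:
    """Single-instrument causal estimate: beta = b_y / b_x.

    The default SE is the first-order delta method, se_y/|b_x| — the same
    weighting convention IVW uses.  ``second_order=True`` adds the
    exposure-side term sqrt(se_y^2/b_x^2 + b_y^2 se_x^2 / b_x^4).
    """
    b_x, se_x, b_y, se_y = (float(v) for v in (b_x, se_x, b_y, se_y))
    if b_x == 0:
        raise ZeroDivisionError("wald_ratio undefined for b_x = 0")
    beta = b_y / b_x
    if second_order:
        se = np.sqrt(se_y**2 / b_x**2 + b_y**2 * se_x**2 / b_x**4)
    else:
        se = se_y / abs(b_x)
    z = beta / se
    pval = float(2 * stats.norm.sf(abs(z)))
    res = MRResult("wald_ratio", 1, beta, float(se), pval)
    return _finish(res, binary)


def ivw(pair, se_x=None, b_y=None, se_y=None, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted meta-analysis of per-variant Wald ratios.

    Weights are the inverse variance of the variant-outcome estimate
    (w_j = 1/se_yj^2), equivalent to a zero-intercept weighted regression of
    b_y on b_x.  The random-effects SE inflates the fixed-effect SE by
    max(1, sqrt(Q/(k-1))) — multiplicative, never deflating — with Q =
    Cochran's Q about the fitted slope.
    """
    b_x, _, b_y, se_y, binary = _unpack(pair, se_x, b_y, se_y)
    k = len(b_x)
    if k < 2:
        raise NotEstimableError("ivw needs >=2 variants; use wald_ratio for a single instrument")
    w = 1.0 / se_y**2
    denom = np.sum(w * b_x**2)
    beta = float(np.sum(w * b_x * b_y) / denom)
    se_fixed = float(denom ** -0.5)
    Q = float(np.sum(w * (b_y - beta * b_x) ** 2))
    Q_pval = float(stats.chi2.sf(Q, k - 1))
    infl = max(1.0, np.sqrt(Q / (k - 1))) if random_effects else 1.0
    se = se_fixed * infl
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    method = "ivw_re" if random_effects else "ivw_fe"
    res = MRResult(method, k, beta, se, pval, Q=Q, Q_pval=Q_pval)
    return _finish(res, binary)


def ivw_correlated(
    pair,
    ld: LDMatrix | np.ndarray,
    se_x=None,
    b_y=None,
    se_y=None,
    ridge: float = 1e-3,
) -> MRResult:
    """LD-aware IVW: GLS of b_y on b_x under Omega_ij = se_yi se_yj r_ij.

    ``ld`` may be an :class:`LDMatrix` (sub-set and allele-aligned to the
    pair) or a pre-aligned correlation array.  With identity LD this reduces
    exactly to fixed-effect :func:`ivw`.  The correlation matrix is
    ridge-regularized before inversion.
    """
    b_x, _, b_y, se_y, binary = _unpack(pair, se_x, b_y, se_y)
    k = len(b_x)
    if k < 2:
        raise NotEstimableError("ivw_correlated needs >=2 variants")
    if isinstance(ld, LDMatrix):
        r = ld.submatrix(pair.variant_ids, pair.df["ea"].tolist())
    else:
        r = np.asarray(ld, dtype=float)
    r = (r + ridge * np.eye(k)) / (1.0 + ridge)
    omega = np.outer(se_y, se_y) * r
    try:
        oi_x = np.linalg.solve(omega, b_x)
        oi_y = np.linalg.solve(omega, b_y)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"LD covariance singular after regularization: {e}") from e
    denom = float(b_x @ oi_x)
    beta = float(b_x @ oi_y) / denom
    se = denom ** -0.5
    resid = b_y - beta * b_x
    Q = float(resid @ np.linalg.solve(omega, resid))
    Q_pval = float(stats.chi2.sf(Q, k - 1))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    res = MRResult("ivw_correlated", k, beta, se, pval, Q=Q, Q_pval=Q_pval)
    return _finish(res, binary)


def mr_egger(pair, se_x=None, b_y=None, se_y=None) -> MRResult:
    """MR-Egger: weighted regression of b_y on b_x *with* an intercept.

    Exposure effects are first oriented non-negative (flipping the paired
    outcome effects), the convention that makes the intercept interpretable
    as average directional pleiotropy.  Slope = causal estimate; the
    intercept test is the pleiotropy diagnostic.  SEs are inflated by
    max(1, sqrt(Q_egger/(k-2))); inference is normal-based, matching the
    other estimators (the floor already makes the intercept test mildly
    conservative; stacking a t correction on top would over-correct).
    """
    b_x, _, b_y, se_y, binary = _unpack(pair, se_x, b_y, se_y)
    k = len(b_x)
    if k < 3:
        raise NotEstimableError("mr_egger needs >=3 variants")
    s = np.where(b_x < 0, -1.0, 1.0)
    x = b_x * s
    y = b_y * s
    w = 1.0 / se_y**2
    X = np.column_stack([np.ones(k), x])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ y)
    resid = y - X @ coef
    Q = float(np.sum(w * resid**2))
    infl = max(1.0, np.sqrt(Q / (k - 2)))
    cov = np.linalg.inv(xtwx)
    se_int, se_slope = infl * np.sqrt(np.diag(cov))
    p_slope = float(2 * stats.norm.sf(abs(coef[1] / se_slope)))
    p_int = float(2 * stats.norm.sf(abs(coef[0] / se_int)))
    res = MRResult(
        "mr_egger",
        k,
        float(coef[1]),
        float(se_slope),
        p_slope,
        Q=Q,
        Q_pval=float(stats.chi2.sf(Q, k - 2)),
        egger_intercept=float(coef[0]),
        intercept_pval=p_int,
    )
    return _finish(res, binary)


def _ratio_stats(b_x, se_x, b_y, se_y):
    ratio = b_y / b_x
    var = se_y**2 / b_x**2 + b_y**2 * se_x**2 / b_x**4
    return ratio, var


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    """Weight-0.5 quantile of the ordered ratios with linear interpolation."""
    order = np.argsort(ratio)
    r = ratio[order]
    w = w[order] / np.sum(w)
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(pair, se_x=None, b_y=None, se_y=None, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median MR: consistent when valid instruments carry >50% weight.

    Weights are the inverse delta-method variance of each ratio; the SE comes
    from a seeded parametric bootstrap (resampling b_x, b_y from their
    sampling normals ``n_boot`` times).
    """
    b_x, se_x, b_y, se_y, binary = _unpack(pair, se_x, b_y, se_y)
    k = len(b_x)
    if k < 3:
        raise NotEstimableError("weighted_median needs >=3 variants")
    ratio, var = _ratio_stats(b_x, se_x, b_y, se_y)
    w = 1.0 / var
    beta = _weighted_median_point(ratio, w)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(b_x, se_x, size=(n_boot, k))
    by_b = rng.normal(b_y, se_y, size=(n_boot, k))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    est = np.empty(n_boot)
    for i in range(n_boot):
        r_i, v_i = _ratio_stats(bx_b[i], se_x, by_b[i], se_y)
        est[i] = _weighted_median_point(r_i, 1.0 / v_i)
    se = float(np.std(est, ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else (0.0 if beta else 1.0)
    res = MRResult("weighted_median", k, beta, se, pval)
    return _finish(res, binary)


def _weighted_mode_point(ratio, w, bandwidth_factor):
    w = w / np.sum(w)
    mu = np.sum(w * ratio)
    sd = np.sqrt(np.sum(w * (ratio - mu) ** 2))
    q25, q75 = np.quantile(ratio, [0.25, 0.75])  # unweighted IQR as spread guard
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        return float(ratio[np.argmax(w)])
    h = bandwidth_factor * 0.9 * spread * len(ratio) ** (-1 / 5)
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 512)
    dens = np.sum(w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2), axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    pair, se_x=None, b_y=None, se_y=None,
    bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0,
) -> MRResult:
    """Weighted-mode MR: the kernel-density argmax of the ratio distribution.

    Consistent when the largest weight cluster of instruments is valid, even
    if they are a minority.  Bandwidth is ``bandwidth_factor`` times a
    weighted Silverman rule; SE by seeded parametric bootstrap.
    """
    b_x, se_x, b_y, se_y, binary = _unpack(pair, se_x, b_y, se_y)
    k = len(b_x)
    if k < 3:
        raise NotEstimableError("weighted_mode needs >=3 variants")
    ratio, var = _ratio_stats(b_x, se_x, b_y, se_y)
    w = 1.0 / var
    beta = _weighted_mode_point(ratio, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for i in range(n_boot):
        bx_i = rng.normal(b_x, se_x)
        by_i = rng.normal(b_y, se_y)
        bx_i = np.where(bx_i == 0, np.finfo(float).tiny, bx_i)
        r_i, v_i = _ratio_stats(bx_i, se_x, by_i, se_y)
        est[i] = _weighted_mode_point(r_i, 1.0 / v_i, bandwidth_factor)
    se = float(np.std(est, ddof=1))
    pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else (0.0 if beta else 1.0)
    res = MRResult("weighted_mode", k, beta, se, pval)
    return _finish(res, binary)


# ---------------------------------------------------------------------------
# directionality


@dataclass
class SteigerResult:
    """Directionality test comparing variance explained in exposure vs outcome."""

    direction: str  # "exposure->outcome" or "outcome->exposure"
    pval: float
    r_exposure: float
    r_outcome: float
    per_snp: "np.ndarray | None" = None  # structured per-variant table (pandas)
    assessable: bool = True


def _r2_from_z(z: np.ndarray, n: int) -> np.ndarray:
    """Variance explained from a marginal z statistic: r^2 = z^2/(z^2 + n - 2).

    For a binary outcome this is the observed-scale approximation from the
    log-odds z score (labelled as such in output); no liability-scale
    conversion is attempted.
    """
    z2 = np.asarray(z, dtype=float) ** 2
    return z2 / (z2 + n - 2)


def steiger_test(pair, n_x: int | None = None, n_y: int | None = None) -> SteigerResult:
    """MR Steiger directionality test.

    Trait-level r = sqrt(sum of per-variant r^2 over the (assumed
    independent) instruments, capped at 1).  The inference compares
    Fisher-transformed correlations:
    Z = (atanh|r_x| - atanh|r_y|) / sqrt(1/(n_x-3) + 1/(n_y-3)).
    """
    if not isinstance(pair, HarmonizedPair):
        raise TypeError("steiger_test requires a HarmonizedPair (use _steiger_arrays for arrays)")
    if n_x is None:
        n_x = int(pair.df["n_exp"].median())
    if n_y is None:
        n_y = int(pair.df["n_out"].median())
    zx = pair.b_x / pair.se_x
    zy = pair.b_y / pair.se_y
    return _steiger_arrays(zx, zy, n_x, n_y, ids=pair.variant_ids)


def _steiger_arrays(zx, zy, n_x, n_y, ids=None) -> SteigerResult:
    import pandas as pd

    if n_x is None or n_y is None or min(n_x, n_y) <= 3:
        return SteigerResult("not_assessable", np.nan, np.nan, np.nan, assessable=False)
    zx = np.asarray(zx, dtype=float)
    zy = np.asarray(zy, dtype=float)
    r2x = _r2_from_z(zx, n_x)
    r2y = _r2_from_z(zy, n_y)
    rx = np.sqrt(min(1.0 - 1e-12, float(np.sum(r2x))))
    ry = np.sqrt(min(1.0 - 1e-12, float(np.sum(r2y))))
    denom = np.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))

    def _p(rxi, ryi):
        Z = (np.arctanh(rxi) - np.arctanh(ryi)) / denom
        return float(2 * stats.norm.sf(abs(Z)))

    pval = _p(rx, ry)
    direction = "exposure->outcome" if rx > ry else "outcome->exposure"
    per = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else np.arange(len(zx)),
            "r2_exposure": r2x,
            "r2_outcome": r2y,
            "direction": np.where(r2x > r2y, "exposure->outcome", "outcome->exposure"),
            "pval": [
                _p(np.sqrt(min(1 - 1e-12, a)), np.sqrt(min(1 - 1e-12, b)))
                for a, b in zip(r2x, r2y)
            ],
        }
    )
    return SteigerResult(direction, pval, rx, ry, per_snp=per)
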