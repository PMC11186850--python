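"""Generalized summary-data MR (GSMR): LD-aware GLS with iterative outlier removal.

GSMR combines per-variant Wald ratios by generalized least squares under the
LD-induced covariance, and — unlike plain IVW — propagates the exposure-side
sampling variance into each ratio's weight.  An outlier loop drops variants
whose ratio deviates from the current estimate more than chance allows
(instruments with direct, non-mediated outcome effects), then refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair
from .io import LDMatrix

__all__ = ["GsmrResult", "gsmr_fit"]


class DegenerateFitError(ValueError):
    """All variants were removed as outliers."""


@dataclass
class GsmrResult:
    """GSMR causal estimate with the removed-outlier audit."""

    beta: float
    se: float
    pval: float
    n_snps_used: int
    removed_outliers: list[tuple[str, float]] = field(default_factory=list)
    used_variant_ids: list[str] = field(default_factory=list)


def _gls_fit(b_xy: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    ones = np.ones(len(b_xy))
    Vi_b = np.linalg.solve(V, b_xy)
    Vi_1 = np.linalg.solve(V, ones)
    var_beta = 1.0 / float(ones @ Vi_1)
    beta = float(ones @ Vi_b) * var_beta
    return beta, var_beta


def gsmr_fit(
    pair: HarmonizedPair,
    ld: LDMatrix | np.ndarray | None = None,
    outlier_alpha: float = 0.01,
    ridge: float = 1e-3,
) -> GsmrResult:
    """Fit GSMR on a harmonized pair (instruments clumped at relaxed r^2 < 0.1).

    Per-variant ratio b_xy_j = b_yj/b_xj with delta-method variance
    v_j = (se_yj^2 + b_xy_j^2 se_xj^2) / b_xj^2; the joint covariance is
    V_ij = r_ij sqrt(v_i v_j).  The GLS estimate is
    beta = (1' V^-1 b_xy) / (1' V^-1 1).  Outlier loop: while any variant's
    standardized deviation from the estimate has p < ``outlier_alpha``,
    remove the worst one and refit.
    """
    if isinstance(pair, HarmonizedPair):
        b_x, se_x, b_y, se_y = pair.b_x, pair.se_x, pair.b_y, pair.se_y
        ids = pair.variant_ids
        if isinstance(ld, LDMatrix):
            r_full = ld.submatrix(ids, pair.df["ea"].tolist())
        elif ld is None:
            r_full = np.eye(len(b_x))
        else:
            r_full = np.asarray(ld, dtype=float)
    else:
        raise TypeError("gsmr_fit expects a HarmonizedPair")
    k = len(b_x)
    if k < 2:
        raise ValueError("gsmr needs >=2 variants after relaxed clumping")
    if np.any(b_x == 0):
        raise ZeroDivisionError("gsmr undefined when any b_x = 0")

    b_xy = b_y / b_x
    v = (se_y**2 + b_xy**2 * se_x**2) / b_x**2
    r_full = (r_full + ridge * np.eye(k)) / (1.0 + ridge)

    active = np.arange(k)
    removed: list[tuple[str, float]] = []
    while True:
        va = v[active]
        V = r_full[np.ix_(active, active)] * np.sqrt(np.outer(va, va))
        beta, var_beta = _gls_fit(b_xy[active], V)
        d = b_xy[active] - beta
        var_d = np.maximum(va - var_beta, 1e-12)
        z = d / np.sqrt(var_d)
        p = 2 * stats.norm.sf(np.abs(z))
        worst = int(np.argmin(p))
        if p[worst] >= outlier_alpha:
            break
        if len(active) - 1 < 2:
            raise DegenerateFitError(
                "outlier analysis removed all but one variant; GSMR fit is degenerate"
            )
        removed.append((ids[active[worst]], float(p[worst])))
        active = np.delete(active, worst)

    se = float(np.sqrt(var_beta))
    pval = float(2 * stats.norm.sf(abs(beta / se)))
    return GsmrResult(
        beta=float(beta),
        se=se,
        pval=pval,
        n_snps_used=len(active),
        removed_outliers=removed,
        used_variant_ids=[ids[i] for i in active],
    )
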