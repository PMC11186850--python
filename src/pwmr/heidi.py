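"""HEIDI: heterogeneity-in-dependent-instruments test for a cis region.

Under a single shared causal variant, the ratio estimate b_xy at every variant
in LD with the top association equals the ratio at the top variant up to
sampling noise.  HEIDI tests the joint deviation d_j = b_xy(j) - b_xy(top)
across the region: a small p-value rejects the single-shared-variant model in
favour of distinct causal variants in linkage.  A p >= 0.05 is therefore the
*passing* outcome for colocalization-style evidence (see docs/methods.md for
the interpretation note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .harmonize import harmonize_pair
from .io import LDMatrix, SummaryStats

__all__ = ["HeidiResult", "heidi_test", "quadform_pvalue"]


@dataclass
class HeidiResult:
    """HEIDI outcome: the test statistic is a sum of correlated squared z's."""

    top_snp: str
    n_snps_used: int
    T_heidi: float
    pval: float
    eligible_snp_count: int
    reason: str = ""

    @property
    def assessable(self) -> bool:
        return np.isfinite(self.pval) if self.pval is not None else False

    def passes(self, alpha: float = 0.05) -> bool:
        """Consistent with one shared causal variant iff p >= alpha."""
        return self.assessable and self.pval >= alpha


def quadform_pvalue(t: float, lambdas: np.ndarray) -> float:
    """Upper-tail probability of Q = sum lambda_i * chi^2_1 at Q = t.

    Numeric inversion of the characteristic function (Imhof's integral),
    falling back to Satterthwaite moment matching when the integration
    fails or returns an out-of-range value.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0 or t <= 0:
        return 1.0

    def theta(u):
        return 0.5 * np.sum(np.arctan(lam[:, None] * u[None, :]), axis=0) - 0.5 * t * u

    def rho(u):
        return np.prod((1.0 + (lam[:, None] * u[None, :]) ** 2) ** 0.25, axis=0)

    def integrand(u):
        u = np.atleast_1d(u)
        return np.sin(theta(u)) / (u * rho(u))

    # the envelope 1/(u*rho(u)) decays polynomially; truncate where it is
    # negligible instead of integrating an oscillatory tail to infinity
    upper = 1.0
    while upper < 1e6 and 1.0 / (upper * float(rho(np.array([upper]))[0])) > 1e-11:
        upper *= 2.0
    # integrate piecewise: segments short enough that each holds a bounded
    # number of oscillations of sin(theta(u)) ~ sin(t*u/2)
    seg = min(64.0, 100.0 * np.pi / max(1.0, t))
    edges = np.arange(0.0, upper + seg, seg)
    edges[-1] = upper
    try:
        val = 0.0
        err = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            for a, b in zip(edges[:-1], edges[1:]):
                v, e = integrate.quad(
                    lambda u: float(integrand(np.array([u]))[0]), a, b, limit=200
                )
                val += v
                err += e
        p = 0.5 + val / np.pi
        if np.isfinite(p) and -0.005 <= p <= 1.005 and err < 1e-5:
            return float(min(1.0, max(0.0, p)))
    except Exception:
        pass
    # Satterthwaite fallback: Q ~ a * chi^2_nu with matched first two moments
    a = np.sum(lam**2) / np.sum(lam)
    nu = np.sum(lam) ** 2 / np.sum(lam**2)
    return float(stats.chi2.sf(t / a, nu))


def _heidi_arrays(
    b_x: np.ndarray,
    se_x: np.ndarray,
    b_y: np.ndarray,
    se_y: np.ndarray,
    r: np.ndarray,
    top: int,
    test_idx: np.ndarray,
) -> tuple[float, float]:
    """HEIDI statistic and p for pre-selected test variants (``test_idx``
    excludes ``top``).  Delta-method covariance of d_j under LD."""
    idx = np.concatenate([[top], test_idx])
    bx, sx, by, sy = b_x[idx], se_x[idx], b_y[idx], se_y[idx]
    rr = r[np.ix_(idx, idx)]
    bxy = by / bx
    # cov of the ratio vector (exposure and outcome samples independent)
    c = rr * np.outer(sy, sy) / np.outer(bx, bx) + rr * np.outer(sx, sx) * np.outer(
        by, by
    ) / np.outer(bx**2, bx**2)
    m = len(test_idx)
    d = bxy[1:] - bxy[0]
    cov_d = c[1:, 1:] - c[1:, [0]] - c[[0], 1:] + c[0, 0]
    sd = np.sqrt(np.diag(cov_d))
    z = d / sd
    T = float(np.sum(z**2))
    corr = cov_d / np.outer(sd, sd)
    lam = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    pval = quadform_pvalue(T, lam)
    return T, pval


def heidi_test(
    region_exposure: SummaryStats,
    region_outcome: SummaryStats,
    ld: LDMatrix,
    p_include: float = 1.57e-3,
    min_snps: int = 3,
    max_snps: int = 20,
    r2_max: float = 0.9,
    r2_min: float = 0.05,
) -> HeidiResult:
    """Run the HEIDI test on a harmonized cis region.

    The top variant is the smallest exposure p-value.  Test variants must have
    exposure p <= ``p_include`` and r^2 with the top variant in
    [``r2_min``, ``r2_max``] (near-duplicates carry no information,
    near-independent variants are off-signal); at most ``max_snps`` are kept,
    strongest exposure |z| first.  With fewer than ``min_snps`` eligible the
    result is flagged not assessable.
    """
    pair = harmonize_pair(region_exposure, region_outcome, ld=ld)
    df = pair.df
    ids = pair.variant_ids
    missing = [v for v in ids if v not in ld]
    if missing:
        raise KeyError(f"variant(s) absent from LD reference: {missing[:5]}")
    r = ld.submatrix(ids, df["ea"].tolist())
    zx = pair.b_x / pair.se_x
    px = df["pval_exp"].to_numpy(dtype=float)
    order = np.lexsort((df["variant_id"].to_numpy(), px))
    top = int(order[0])
    if not np.isfinite(px[top]):
        raise ValueError("top variant has no exposure p-value")

    r2_top = r[top] ** 2
    eligible = np.nonzero(
        (np.arange(len(ids)) != top)
        & (px <= p_include)
        & (r2_top >= r2_min)
        & (r2_top <= r2_max)
    )[0]
    n_eligible = len(eligible)
    if n_eligible < min_snps:
        return HeidiResult(
            top_snp=ids[top],
            n_snps_used=n_eligible,
            T_heidi=np.nan,
            pval=np.nan,
            eligible_snp_count=n_eligible,
            reason=f"not assessable: {n_eligible} eligible test SNP(s) < {min_snps}",
        )
    if n_eligible > max_snps:
        keep = eligible[np.argsort(-np.abs(zx[eligible]), kind="mergesort")[:max_snps]]
    else:
        keep = eligible
    T, pval = _heidi_arrays(pair.b_x, pair.se_x, pair.b_y, pair.se_y, r, top, np.sort(keep))
    return HeidiResult(
        top_snp=ids[top],
        n_snps_used=len(keep),
        T_heidi=T,
        pval=pval,
        eligible_snp_count=n_eligible,
    )
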