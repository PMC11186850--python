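"""cis-pQTL instrument selection: filters, LD clumping and strength diagnostics.

Instruments for a protein are drawn from its cis window (gene body plus a
flank), kept only when genome-wide significant, common, non-palindromic at
intermediate frequency and outside the extended HLA region, then greedily
clumped to approximate pairwise independence.  Every exclusion is recorded in
an audit trail with the rule that removed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import is_palindromic
from .io import LDMatrix, SummaryStats

__all__ = [
    "GeneRegion",
    "SelectionParams",
    "InstrumentSet",
    "HetResult",
    "select_cis_instruments",
    "clump",
    "per_snp_f",
    "cross_cohort_het",
]


@dataclass(frozen=True)
class GeneRegion:
    """Gene span (1-based, inclusive) used to anchor the cis window."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class SelectionParams:
    """Instrument-selection thresholds.

    Defaults follow the standard cis-pQTL recipe: genome-wide significance,
    a 500 kb flank around the gene, MAF >= 0.01, clumping at r^2 < 0.001
    within 10 Mb, removal of the extended HLA region (chr6:29-34 Mb) and of
    palindromic variants with allele frequency in [0.4, 0.6].
    """

    p_threshold: float = 5e-8
    cis_flank_bp: int = 500_000
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_window_bp: float = 1e7
    hla_chrom: str = "6"
    hla_start: int = 29_000_000
    hla_end: int = 34_000_000
    palindromic_af_window: tuple[float, float] = (0.4, 0.6)

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0,1)")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 < self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in (0,1]")


@dataclass
class InstrumentSet:
    """Selected instruments for one protein, with per-variant F statistics and
    an audit trail recording which rule removed each rejected candidate."""

    protein_id: str
    table: pd.DataFrame
    audit: pd.DataFrame
    params: SelectionParams = field(default_factory=SelectionParams)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def empty(self) -> bool:
        return len(self.table) == 0

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def min_f(self) -> float:
        return float(self.table["F"].min()) if len(self.table) else np.nan

    def weak(self, f_min: float = 10.0) -> bool:
        """Weak-instrument gate: any instrument with F below ``f_min``."""
        return bool(len(self.table)) and bool((self.table["F"] < f_min).any())


def per_snp_f(beta: float, se: float) -> float:
    """Per-variant instrument-strength F statistic, F = (beta/se)^2.

    The z^2 approximation is the standard choice when only the marginal beta
    and SE are available; F >= 10 is the conventional weak-instrument gate.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    r2: float = 0.001,
    window_bp: float = 1e7,
) -> pd.DataFrame:
    """Greedy p-value clumping.

    Repeatedly take the smallest-p remaining candidate as an index variant and
    remove every other candidate within ``window_bp`` of it whose r^2 with it
    is >= ``r2``.  Ties on p break lexicographically on variant id, so the
    result is deterministic.  Candidates absent from the LD reference are
    treated as correlated with nothing (retained, with a warning column).
    """
    if candidates.empty:
        return candidates.copy()
    work = candidates.sort_values(["pval", "variant_id"], kind="mergesort").reset_index(drop=True)
    in_ld = work["variant_id"].map(lambda v: v in ld)
    retained_idx: list[int] = []
    alive = np.ones(len(work), dtype=bool)
    pos = work["pos"].to_numpy()
    chrom = work["chrom"].to_numpy()
    for i in range(len(work)):
        if not alive[i]:
            continue
        retained_idx.append(i)
        alive[i] = False
        if not in_ld[i]:
            continue
        vi = work.at[i, "variant_id"]
        for j in np.nonzero(alive)[0]:
            if chrom[j] != chrom[i] or abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            if not in_ld[j]:
                continue
            if ld.r2(vi, work.at[j, "variant_id"]) >= r2:
                alive[j] = False
    out = work.loc[retained_idx].reset_index(drop=True)
    out["ld_missing"] = ~in_ld[retained_idx].to_numpy()
    return out


def select_cis_instruments(
    pqtl: SummaryStats,
    region: GeneRegion,
    ld: LDMatrix,
    params: SelectionParams | None = None,
) -> InstrumentSet:
    """Select independent cis instruments for one protein.

    Filter order: cis window (gene +/- flank, inclusive), association p-value,
    MAF, palindromic-with-intermediate-AF, HLA region, then greedy clumping.
    An empty result is returned (not raised) when nothing survives; the
    pipeline treats it as "no instruments".
    """
    params = params or SelectionParams()
    df = pqtl.df
    audit: list[dict] = []

    lo, hi = region.start - params.cis_flank_bp, region.end + params.cis_flank_bp
    in_window = (df["chrom"] == region.chrom) & df["pos"].between(lo, hi)
    work = df[in_window].copy()

    def _drop(mask: pd.Series, rule: str) -> None:
        nonlocal work
        for vid in work.loc[mask, "variant_id"]:
            audit.append({"variant_id": vid, "rule": rule})
        work = work[~mask]

    _drop(~work["pval"].lt(params.p_threshold), "pval_above_threshold")
    maf = np.minimum(work["eaf"], 1 - work["eaf"])
    _drop(~(maf >= params.maf_min), "maf_below_min")
    lo_af, hi_af = params.palindromic_af_window
    pal = work.apply(lambda r: is_palindromic(r["ea"], r["oa"]), axis=1) if len(work) else pd.Series(dtype=bool)
    if len(work):
        _drop(pal & work["eaf"].between(lo_af, hi_af), "palindromic_intermediate_af")
    if len(work):
        in_hla = (work["chrom"] == params.hla_chrom) & work["pos"].between(
            params.hla_start, params.hla_end
        )
        _drop(in_hla, "hla_region")

    clumped = clump(work, ld, r2=params.clump_r2, window_bp=params.clump_window_bp)
    clumped_ids = set(clumped["variant_id"])
    for vid in work.loc[~work["variant_id"].isin(clumped_ids), "variant_id"]:
        audit.append({"variant_id": vid, "rule": "clumped"})

    table = clumped.reset_index(drop=True)
    if len(table):
        table["F"] = per_snp_f(table["beta"].to_numpy(), table["se"].to_numpy())
    else:
        table = table.assign(F=pd.Series(dtype=float))
    audit_df = pd.DataFrame(audit, columns=["variant_id", "rule"])
    return InstrumentSet(region.gene_id, table, audit_df, params)


@dataclass
class HetResult:
    """Fixed-effect meta-analysis heterogeneity across cohorts."""

    Q: float
    pval: float
    i2: float
    n_cohorts: int
    assessable: bool = True

    def passes(self, alpha: float = 0.05, i2_max: float = 0.5) -> bool:
        """Low-heterogeneity gate: p > alpha and I^2 < i2_max."""
        return self.assessable and self.pval > alpha and self.i2 < i2_max


def cross_cohort_het(betas, ses) -> HetResult:
    """Cochran's Q and I^2 for one variant's effect across K cohorts.

    Fixed-effect weights w_k = 1/se_k^2; Q = sum w_k (b_k - b_bar)^2 on
    chi^2(K-1); I^2 = max(0, (Q - (K-1))/Q).  A single cohort is flagged
    not assessable.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    b, s = b[ok], s[ok]
    k = len(b)
    if k < 2:
        return HetResult(np.nan, np.nan, np.nan, k, assessable=False)
    w = 1.0 / s**2
    bbar = np.sum(w * b) / np.sum(w)
    Q = float(np.sum(w * (b - bbar) ** 2))
    pval = float(stats.chi2.sf(Q, k - 1))
    i2 = float(max(0.0, (Q - (k - 1)) / Q)) if Q > 0 else 0.0
    return HetResult(Q, pval, i2, k)
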