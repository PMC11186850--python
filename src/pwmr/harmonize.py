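"""Allele harmonization of exposure/outcome summary statistics and LD-proxy lookup.

Two-sample MR needs both traits' effects expressed on the same effect allele.
For each variant shared by the two traits the outcome record is re-oriented to
the exposure's effect allele (negating the beta and complementing the allele
frequency when the alleles are swapped), allowing for strand flips.  Palindromic
variants (A/T, G/C) with intermediate exposure allele frequency cannot be
oriented reliably and are removed.  Exposure variants missing from the outcome
can be rescued through an LD proxy with r^2 above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COMPLEMENT, LDMatrix, SummaryStats

__all__ = ["HarmonizedPair", "ProxyAssignment", "harmonize_pair", "find_proxy", "is_palindromic"]


class EmptyHarmonizationError(ValueError):
    """No shared variants between exposure and outcome (even after proxies)."""


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T and G/C pairs read the same on both strands."""
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


@dataclass
class ProxyAssignment:
    """An outcome-present stand-in for a missing variant, with the LD sign
    needed to re-orient the proxy's effect onto the query's effect allele."""

    query_id: str
    proxy_id: str
    r: float
    r2: float


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects on a common (exposure) effect allele.

    ``df`` has one row per retained variant; ``dropped`` records removed
    variants with the rule that removed them (``palindromic_dropped``,
    ``allele_mismatch``, ``missing_from_outcome``).
    """

    df: pd.DataFrame
    dropped: pd.DataFrame
    exposure_id: str = ""
    outcome_id: str = ""
    outcome_type: str = "binary"
    exposure_type: str = "quantitative"
    notes: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    @property
    def b_x(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(dtype=float)

    @property
    def se_x(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(dtype=float)

    @property
    def b_y(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(dtype=float)

    @property
    def se_y(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(dtype=float)

    def subset(self, variant_ids) -> "HarmonizedPair":
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))].reset_index(drop=True)
        return HarmonizedPair(
            keep, self.dropped, self.exposure_id, self.outcome_id,
            self.outcome_type, self.exposure_type, list(self.notes),
        )

    def to_summary_stats(self) -> tuple[SummaryStats, SummaryStats]:
        """Re-emit the harmonized records as two SummaryStats (used for
        idempotence checks and for feeding region tools)."""
        base = self.df[["variant_id", "chrom", "pos", "ea", "oa"]].copy()
        exp = base.copy()
        exp[["eaf", "beta", "se", "pval", "n"]] = self.df[
            ["eaf_exp", "beta_exp", "se_exp", "pval_exp", "n_exp"]
        ].to_numpy()
        out = base.copy()
        out[["eaf", "beta", "se", "pval", "n"]] = self.df[
            ["eaf_out", "beta_out", "se_out", "pval_out", "n_out"]
        ].to_numpy()
        for d in (exp, out):
            d["pos"] = d["pos"].astype(int)
            d["n"] = d["n"].astype(int)
        return (
            SummaryStats(self.exposure_id, self.exposure_type, exp),
            SummaryStats(self.outcome_id, self.outcome_type, out),
        )


def find_proxy(
    variant_id: str,
    outcome: SummaryStats,
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> ProxyAssignment | None:
    """Best outcome-present proxy for ``variant_id`` with r^2 >= ``r2_min``.

    Returns the variant itself (r = 1) when it is present in the outcome.
    Returns ``None`` when no candidate reaches the threshold.  Raises
    ``KeyError`` when the query variant is absent from the LD reference.
    """
    qi = ld.index(variant_id)  # KeyError if absent
    present = [v for v in outcome.variant_ids if v in ld]
    if variant_id in set(outcome.variant_ids):
        return ProxyAssignment(variant_id, variant_id, 1.0, 1.0)
    best = None
    for v in present:
        r = float(ld.r[qi, ld.index(v)])
        r2 = r * r
        if r2 >= r2_min and (best is None or r2 > best.r2):
            best = ProxyAssignment(variant_id, v, r, r2)
    return best


def _orient_outcome_row(row_exp, row_out):
    """Classify the outcome row's allele orientation against the exposure's.

    Returns ('same'|'flip'|None).  Strand complements are accepted for
    non-palindromic variants; palindromic strand handling is the caller's job.
    """
    ea_x, oa_x = row_exp["ea"], row_exp["oa"]
    ea_y, oa_y = row_out["ea"], row_out["oa"]
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flip"
    cea, coa = COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y)
    if (cea, coa) == (ea_x, oa_x):
        return "same"
    if (cea, coa) == (oa_x, ea_x):
        return "flip"
    return None


def harmonize_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    proxy_r2: float = 0.8,
    af_window: tuple[float, float] = (0.4, 0.6),
) -> HarmonizedPair:
    """Align outcome effects to the exposure's effect alleles.

    Per shared variant: if the outcome's effect allele is the exposure's other
    allele (directly or via strand complement), the outcome beta is negated and
    its allele frequency complemented.  Palindromic variants whose *exposure*
    allele frequency falls inside ``af_window`` are removed (strand cannot be
    resolved).  Variants matching neither orientation are dropped.  Exposure
    variants absent from the outcome are resolved through :func:`find_proxy`
    when an LD reference is supplied, re-orienting the proxy effect by the
    sign of r.
    """
    out_by_id = {r["variant_id"]: r for _, r in outcome.df.iterrows()}
    kept_rows = []
    dropped_rows = []
    for _, ex in exposure.df.iterrows():
        vid = ex["variant_id"]
        proxy: ProxyAssignment | None = None
        if vid in out_by_id:
            oy = out_by_id[vid]
        elif ld is not None and vid in ld:
            proxy = find_proxy(vid, outcome, ld, r2_min=proxy_r2)
            if proxy is None:
                dropped_rows.append({"variant_id": vid, "reason": "missing_from_outcome"})
                continue
            oy = out_by_id[proxy.proxy_id]
        else:
            dropped_rows.append({"variant_id": vid, "reason": "missing_from_outcome"})
            continue

        palindromic = is_palindromic(ex["ea"], ex["oa"])
        if palindromic and proxy is None:
            eaf = ex.get("eaf", np.nan)
            if pd.notna(eaf) and af_window[0] <= eaf <= af_window[1]:
                dropped_rows.append({"variant_id": vid, "reason": "palindromic_dropped"})
                continue

        beta_y, se_y = float(oy["beta"]), float(oy["se"])
        eaf_y = float(oy["eaf"]) if pd.notna(oy.get("eaf", np.nan)) else np.nan
        flipped = False
        if proxy is None:
            orient = _orient_outcome_row(ex, oy)
            if orient is None:
                dropped_rows.append({"variant_id": vid, "reason": "allele_mismatch"})
                continue
            if orient == "flip":
                beta_y, eaf_y, flipped = -beta_y, 1.0 - eaf_y, True
        else:
            # proxy effect re-oriented onto the query's effect allele via the
            # signed LD correlation (alleles of query and proxy differ, so
            # direct allele matching does not apply)
            sign_q = ld.orientation_sign(vid, ex["ea"])
            sign_p = ld.orientation_sign(proxy.proxy_id, oy["ea"])
            s = sign_q * np.sign(proxy.r) * sign_p
            if s < 0:
                beta_y, eaf_y, flipped = -beta_y, 1.0 - eaf_y, True

        kept_rows.append(
            {
                "variant_id": vid,
                "chrom": ex["chrom"],
                "pos": int(ex["pos"]),
                "ea": ex["ea"],
                "oa": ex["oa"],
                "eaf_exp": float(ex["eaf"]) if pd.notna(ex.get("eaf", np.nan)) else np.nan,
                "beta_exp": float(ex["beta"]),
                "se_exp": float(ex["se"]),
                "pval_exp": float(ex["pval"]) if pd.notna(ex.get("pval", np.nan)) else np.nan,
                "n_exp": int(ex["n"]),
                "eaf_out": eaf_y,
                "beta_out": beta_y,
                "se_out": se_y,
                "pval_out": float(oy["pval"]) if pd.notna(oy.get("pval", np.nan)) else np.nan,
                "n_out": int(oy["n"]),
                "flipped": flipped,
                "palindromic": palindromic,
                "proxy_used": proxy is not None,
                "proxy_id": proxy.proxy_id if proxy else "",
                "proxy_r2": proxy.r2 if proxy else np.nan,
            }
        )

    if not kept_rows:
        raise EmptyHarmonizationError(
            f"no shared variants between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )
    df = pd.DataFrame(kept_rows)
    dropped = pd.DataFrame(dropped_rows, columns=["variant_id", "reason"])
    return HarmonizedPair(
        df,
        dropped,
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        outcome_type=outcome.trait_type,
        exposure_type=exposure.trait_type,
    )
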