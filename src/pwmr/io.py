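"""Reading, writing and validation of GWAS/pQTL summary statistics and LD references.

Summary statistics are held as a :class:`SummaryStats` — a thin, validated wrapper
around a :class:`pandas.DataFrame` with one row per variant and canonical column
names.  LD references are held as a :class:`LDMatrix` — a signed correlation matrix
plus the variant list and the allele orientation the signs refer to.

The TSV dialect is the common GWAS one: tab-delimited, UTF-8, header row,
``.`` for missing values.  The writer emits exactly what the reader accepts, so
round trips are lossless.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "SummaryStats",
    "LoadReport",
    "LDMatrix",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "compute_ld",
]

#: canonical column order for summary-statistics tables
REQUIRED_COLUMNS = ("variant_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")
OPTIONAL_COLUMNS = ("n_case", "n_control")

_VALID_BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigurationError(ValueError):
    """A required column could not be resolved from the input file."""


class EmptyInputError(ValueError):
    """No valid variant rows survived validation."""


@dataclass
class LoadReport:
    """Bookkeeping from a summary-statistics load: rows read, kept and dropped."""

    n_read: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SummaryStats:
    """Per-variant marginal association records for one trait.

    ``df`` carries one row per variant with the canonical columns; ``trait_type``
    is ``"quantitative"`` or ``"binary"`` (binary betas are log odds ratios).
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative|binary, got {self.trait_type!r}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant_id within trait {self.trait_id!r}: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def subset(self, variant_ids) -> "SummaryStats":
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))].reset_index(drop=True)
        return SummaryStats(self.trait_id, self.trait_type, keep, self.provenance)

    def sort(self) -> "SummaryStats":
        out = self.df.sort_values(["chrom", "pos", "variant_id"]).reset_index(drop=True)
        return SummaryStats(self.trait_id, self.trait_type, out, self.provenance)


def _is_snp_allele(a) -> bool:
    return isinstance(a, str) and len(a) == 1 and a in _VALID_BASES


def validate_records(df: pd.DataFrame, report: LoadReport | None = None) -> pd.DataFrame:
    """Drop invalid variant rows, counting each rejection by rule.

    Rules: missing beta/se/alleles; se <= 0; non-SNP (indel/multi-allelic)
    alleles; eaf outside (0, 1); pval outside (0, 1].
    """
    if report is None:
        report = LoadReport()
    report.n_read += len(df)
    mask = pd.Series(True, index=df.index)

    def _reject(bad: pd.Series, rule: str) -> None:
        bad = bad & mask
        report.dropped[rule] += int(bad.sum())
        mask[bad] = False

    _reject(df["beta"].isna() | df["se"].isna(), "missing_beta_se")
    _reject(df["ea"].isna() | df["oa"].isna(), "missing_alleles")
    _reject(~df["se"].gt(0), "nonpositive_se")
    snp = df["ea"].map(_is_snp_allele) & df["oa"].map(_is_snp_allele)
    _reject(~snp, "not_a_snp")
    _reject(df["ea"] == df["oa"], "identical_alleles")
    if "eaf" in df:
        _reject(df["eaf"].notna() & ~(df["eaf"].gt(0) & df["eaf"].lt(1)), "eaf_out_of_range")
    if "pval" in df:
        _reject(df["pval"].notna() & ~(df["pval"].gt(0) & df["pval"].le(1)), "pval_out_of_range")
    out = df[mask].reset_index(drop=True)
    report.n_kept += len(out)
    return out


def read_summary_stats(
    path,
    trait_type: str = "quantitative",
    trait_id: str | None = None,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> tuple[SummaryStats, LoadReport]:
    """Read a tab- or comma-delimited summary-statistics file.

    Parameters
    ----------
    column_map
        Maps canonical names (``variant_id``, ``chrom`` ...) to the file's
        column names where they differ.
    sep
        Field separator; autodetected (tab, then comma) when omitted.

    Returns the validated :class:`SummaryStats` plus a :class:`LoadReport`
    counting rejected rows per rule.
    """
    if sep is None:
        with open(path, "rt", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, na_values=["."], dtype={"chrom": str})
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"cannot resolve required column(s) {missing} in {path}")
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in raw.columns]
    df = raw[cols].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    for a in ("ea", "oa"):
        df[a] = df[a].str.upper()
    report = LoadReport()
    df = validate_records(df, report)
    if df.empty:
        raise EmptyInputError(f"no valid variant rows in {path}")
    tid = trait_id if trait_id is not None else str(path)
    return SummaryStats(tid, trait_type, df, provenance=f"read from {path}"), report


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write a summary-statistics TSV in the dialect :func:`read_summary_stats` reads."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in stats.df.columns]
    stats.df[cols].to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# LD reference


@dataclass
class LDMatrix:
    """Signed pairwise correlation (r) among variants, with allele orientation.

    ``alleles[i] = (effect, other)`` is the orientation the signs of row/column
    i refer to: flipping a variant's alleles flips the sign of its correlations
    with every other variant.
    """

    variant_ids: list[str]
    alleles: list[tuple[str, str]]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValueError(f"r has shape {self.r.shape}, expected ({n}, {n})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} absent from LD reference") from None

    def submatrix(self, variant_ids, effect_alleles=None) -> np.ndarray:
        """Correlation submatrix for ``variant_ids``, optionally re-oriented.

        When ``effect_alleles`` is given, any variant whose requested effect
        allele is the reference's *other* allele (directly or by strand
        complement) has the signs of its row/column flipped, so the returned
        matrix matches the caller's allele orientation.
        """
        idx = [self.index(v) for v in variant_ids]
        sub = self.r[np.ix_(idx, idx)].copy()
        if effect_alleles is not None:
            signs = np.array(
                [
                    self.orientation_sign(v, ea)
                    for v, ea in zip(variant_ids, effect_alleles)
                ]
            )
            sub = sub * np.outer(signs, signs)
            np.fill_diagonal(sub, 1.0)
        return sub

    def orientation_sign(self, variant_id: str, effect_allele: str) -> float:
        """+1 if ``effect_allele`` matches the reference effect allele, -1 if it
        matches the other allele (allowing strand complement), else an error."""
        ea, oa = self.alleles[self.index(variant_id)]
        if effect_allele in (ea, COMPLEMENT.get(ea)):
            return 1.0
        if effect_allele in (oa, COMPLEMENT.get(oa)):
            return -1.0
        raise ValueError(
            f"allele {effect_allele!r} matches neither orientation of {variant_id!r} ({ea}/{oa})"
        )

    def regularized(self, lam: float = 1e-3) -> np.ndarray:
        """Ridge-regularized correlation matrix (r + lam*I)/(1 + lam).

        Reference panels give near-singular matrices; the ridge keeps every
        inverse downstream well conditioned while preserving the unit diagonal.
        """
        n = self.r.shape[0]
        return (self.r + lam * np.eye(n)) / (1.0 + lam)

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)


def compute_ld(dosages, variant_ids=None, alleles=None) -> LDMatrix:
    """Pearson LD from a variants x samples dosage table.

    ``dosages`` may be a DataFrame (index = variant ids) or an array plus
    explicit ``variant_ids``.  Monomorphic variants (zero dosage variance) are
    excluded with a warning.  ``alleles`` defaults to ``("A", "G")`` per
    variant when the table carries no allele information (simulation use).
    """
    if isinstance(dosages, pd.DataFrame):
        variant_ids = list(dosages.index)
        mat = dosages.to_numpy(dtype=float)
    else:
        mat = np.asarray(dosages, dtype=float)
        if variant_ids is None:
            raise ValueError("variant_ids required when dosages is a bare array")
        variant_ids = list(variant_ids)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute LD")
    var = mat.var(axis=1)
    mono = var <= 0
    if mono.any():
        dropped = [v for v, m in zip(variant_ids, mono) if m]
        warnings.warn(f"excluding {len(dropped)} monomorphic variant(s): {dropped[:5]}")
        mat = mat[~mono]
        variant_ids = [v for v, m in zip(variant_ids, mono) if not m]
        if alleles is not None:
            alleles = [a for a, m in zip(alleles, mono) if not m]
    r = np.atleast_2d(np.corrcoef(mat))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if alleles is None:
        alleles = [("A", "G")] * len(variant_ids)
    return LDMatrix(variant_ids, alleles, r)


def write_ld_matrix(ld: LDMatrix, matrix_path, variants_path) -> None:
    """Write the square r matrix plus the sidecar variant/allele list."""
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        matrix_path, sep="\t", index=True, index_label="variant_id"
    )
    pd.DataFrame(
        {
            "variant_id": ld.variant_ids,
            "ea": [a for a, _ in ld.alleles],
            "oa": [b for _, b in ld.alleles],
        }
    ).to_csv(variants_path, sep="\t", index=False)


def read_ld_matrix(matrix_path, variants_path) -> LDMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sidecar = pd.read_csv(variants_path, sep="\t")
    ids = sidecar["variant_id"].tolist()
    alleles = list(zip(sidecar["ea"], sidecar["oa"]))
    r = mat.loc[ids, ids].to_numpy(dtype=float)
    return LDMatrix(ids, alleles, r)
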