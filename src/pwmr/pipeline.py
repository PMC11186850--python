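"""Discovery -> validation -> confirmation -> sensitivity -> HEIDI -> coloc -> tiers.

The pipeline runs proteome-wide two-sample MR of protein levels on disease
outcomes and grades every protein-outcome association:

* discovery MR (Wald ratio for one instrument, random-effects IVW otherwise)
  with Benjamini-Hochberg FDR across the whole discovery family;
* validation MR in an independent pQTL study (p < 0.05, same direction);
* confirmation with GSMR on relaxed-clumped (r^2 < 0.1) instruments, falling
  back to LD-aware IVW when too few variants;
* sensitivity MR excluding confounder-associated variants;
* HEIDI and Bayesian colocalization over the cis region;
* reverse MR (outcome as exposure) for directionality;
* tier classification: tier 1 = replicated, diagnostics-clean, >= 2 outcomes,
  strong colocalization (PP.H4 >= 0.80); tier 3 = weak colocalization
  (PP.H4 < 0.50) or sensitivity/confirmation failure; tier 2 otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coloc import ColocPriors, coloc_abf
from .estimators import MRResult, NotEstimableError, ivw, ivw_correlated, mr_egger, steiger_test, wald_ratio
from .gsmr import DegenerateFitError, gsmr_fit
from .harmonize import EmptyHarmonizationError, HarmonizedPair, harmonize_pair
from .heidi import HeidiResult, heidi_test
from .instruments import GeneRegion, SelectionParams, select_cis_instruments
from .io import LDMatrix, SummaryStats, read_ld_matrix, read_summary_stats

__all__ = [
    "TierCriteria",
    "AssociationRecord",
    "ProteinData",
    "StudyData",
    "bh_fdr",
    "classify_tier",
    "run_discovery_validation",
    "sensitivity_confounder_filter",
    "reverse_mr",
    "load_printed_associations",
    "classify_printed_associations",
    "run_pipeline",
    "ALL_STAGES",
]

ALL_STAGES = frozenset({"confirmation", "diagnostics", "sensitivity", "heidi", "coloc", "reverse"})


class ClassificationError(ValueError):
    """Required evidence fields are missing for tier classification."""


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TierCriteria:
    """Thresholds for the evidence grading."""

    fdr_alpha: float = 0.05
    validation_alpha: float = 0.05
    aux_alpha: float = 0.05  # heterogeneity, pleiotropy, HEIDI
    coloc_strong: float = 0.80
    coloc_moderate: float = 0.50
    min_outcomes: int = 2
    not_assessable_passes: bool = True  # het/pleiotropy only

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "validation_alpha", "aux_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1)")
        if not self.coloc_moderate < self.coloc_strong:
            raise ValueError("coloc_moderate must be < coloc_strong")


@dataclass
class AssociationRecord:
    """One protein-outcome pair with all stage results and the final tier."""

    protein: str
    outcome: str
    n_instruments: int = 0
    discovery_method: str = ""
    discovery: MRResult | None = None
    discovery_q: float = np.nan
    validation: MRResult | None = None
    confirmation: object | None = None  # GsmrResult or MRResult
    confirmation_status: str = ""  # confirmed | failed | insufficient_snps
    sensitivity: MRResult | None = None
    sensitivity_pass: bool | None = None
    sensitivity_reason: str = ""
    Q_pval: float | None = None
    egger_intercept_pval: float | None = None
    heidi: HeidiResult | None = None
    pp_h4: float = np.nan
    steiger_direction: str = ""
    steiger_pval: float = np.nan
    reverse_pval: float = np.nan
    reverse_flag: bool = False
    outcomes_associated_count: int = 0
    significant: bool = False
    suggestive: bool = False
    tier: int | None = None  # 1|2|3|None
    notes: list = field(default_factory=list)

    @property
    def heidi_pval(self) -> float | None:
        if self.heidi is None or not np.isfinite(self.heidi.pval):
            return None
        return self.heidi.pval


def _passes(p: float | None, alpha: float, none_passes: bool) -> bool:
    if p is None or (isinstance(p, float) and not np.isfinite(p)):
        return none_passes
    return p >= alpha


def classify_tier(record, criteria: TierCriteria | None = None) -> int | None:
    """Assign tier 1/2/3 (or None) to an association record.

    ``record`` may be an :class:`AssociationRecord` or any object/dict with
    the fields ``significant``, ``suggestive``, ``pp_h4``,
    ``sensitivity_pass``, ``confirmation_status``, ``heidi_pval``,
    ``Q_pval``, ``egger_intercept_pval``, ``outcomes_associated_count``.

    Rules: only discovery+validation-significant records enter the 1/2/3
    grading (suggestive-only records are graded tier 3).  Tier 3: weak
    colocalization (PP.H4 < moderate), sensitivity failure or confirmation
    failure.  Tier 1: strong colocalization, HEIDI p >= alpha, heterogeneity
    and pleiotropy clean (missing counts as clean by default), and the
    protein associated with >= ``min_outcomes`` outcomes.  Tier 2 otherwise.
    """
    criteria = criteria or TierCriteria()
    get = record.get if isinstance(record, dict) else lambda k, d=None: getattr(record, k, d)

    significant = bool(get("significant"))
    if not significant:
        return 3 if get("suggestive") else None

    missing = []
    pp_h4 = get("pp_h4")
    if pp_h4 is None or not np.isfinite(pp_h4):
        missing.append("pp_h4")
    sens = get("sensitivity_pass")
    if sens is None:
        missing.append("sensitivity_pass")
    conf = get("confirmation_status") or ""
    if conf not in ("confirmed", "failed", "insufficient_snps"):
        missing.append("confirmation_status")
    n_out = get("outcomes_associated_count")
    if not n_out or n_out < 1:
        missing.append("outcomes_associated_count")
    if missing:
        raise ClassificationError(f"cannot classify: missing field(s) {missing}")

    if pp_h4 < criteria.coloc_moderate or not sens or conf == "failed":
        return 3

    heidi_ok = _passes(get("heidi_pval"), criteria.aux_alpha, none_passes=False)
    het_ok = _passes(get("Q_pval"), criteria.aux_alpha, criteria.not_assessable_passes)
    ple_ok = _passes(get("egger_intercept_pval"), criteria.aux_alpha, criteria.not_assessable_passes)
    if (
        pp_h4 >= criteria.coloc_strong
        and heidi_ok
        and het_ok
        and ple_ok
        and n_out >= criteria.min_outcomes
    ):
        return 1
    return 2


# ---------------------------------------------------------------------------
# printed-table fixture


def _parse_printed(v: str) -> float | None:
    """Parse a printed p-value/posterior cell: 'NA' -> None, '<x' -> x/2."""
    v = str(v).strip()
    if v in ("NA", "", "nan"):
        return None
    if v.startswith("<"):
        return float(v[1:]) / 2.0
    return float(v)


def load_printed_associations() -> pd.DataFrame:
    """The packaged table of the published significant associations (22 rows)
    with metrics, audit flags and the printed tier."""
    with resources.files("pwmr").joinpath("data/table1_associations.tsv").open("rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    for col in ("p_het", "p_ple", "p_heidi", "pp_h4"):
        df[col + "_num"] = df[col].map(_parse_printed)
    return df


def classify_printed_associations(criteria: TierCriteria | None = None) -> pd.DataFrame:
    """Run the tier classifier over the printed-table fixture.

    Returns the fixture with a ``tier_assigned`` column for comparison with
    the printed ``tier`` column.
    """
    df = load_printed_associations()
    assigned = []
    for _, row in df.iterrows():
        rec = {
            "significant": True,
            "suggestive": True,
            "pp_h4": row["pp_h4_num"],
            "sensitivity_pass": row["sensitivity_pass"] == "yes",
            "confirmation_status": row["confirmation_status"],
            "heidi_pval": row["p_heidi_num"],
            "Q_pval": row["p_het_num"],
            "egger_intercept_pval": row["p_ple_num"],
            "outcomes_associated_count": int(row["n_outcomes"]),
        }
        assigned.append(classify_tier(rec, criteria))
    out = df.copy()
    out["tier_assigned"] = assigned
    return out


# ---------------------------------------------------------------------------
# study containers


@dataclass
class ProteinData:
    """Everything the pipeline needs for one protein."""

    protein_id: str
    discovery: SummaryStats
    validation: SummaryStats
    region: GeneRegion
    ld: LDMatrix


@dataclass
class StudyData:
    proteins: dict
    outcomes: dict
    confounder_snps: pd.DataFrame | None = None
    truth: dict | None = None
    #: all (GeneRegion, LDMatrix) pairs with genome-wide coverage, including
    #: outcome-only loci; defaults to the proteins' cis regions
    regions: list | None = None

    def all_regions(self) -> list:
        if self.regions is not None:
            return self.regions
        return [(p.region, p.ld) for p in self.proteins.values()]


# ---------------------------------------------------------------------------
# stage operations


def _subset_region(stats: SummaryStats, region: GeneRegion, flank_bp: int = 0) -> SummaryStats:
    """Restrict summary statistics to a cis window (region +/- flank)."""
    df = stats.df
    keep = (df["chrom"] == region.chrom) & df["pos"].between(
        region.start - flank_bp, region.end + flank_bp
    )
    return SummaryStats(stats.trait_id, stats.trait_type, df[keep].reset_index(drop=True), stats.provenance)


def _mr_estimate(pair: HarmonizedPair) -> tuple[MRResult, str]:
    """Wald ratio for a single instrument, random-effects IVW otherwise."""
    if len(pair) == 1:
        row = pair.df.iloc[0]
        res = wald_ratio(
            row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"],
            binary=pair.outcome_type == "binary",
        )
        return res, "wald_ratio"
    res = ivw(pair)
    return res, "ivw_re"


def _same_direction(a: float, b: float) -> bool:
    return np.sign(a) == np.sign(b) and a != 0


def sensitivity_confounder_filter(
    protein: ProteinData,
    outcome_stats: SummaryStats,
    confounder_snps: pd.DataFrame | None,
    discovery_beta: float,
    params: SelectionParams | None = None,
    outcome_p_max: float | None = None,
    alpha: float = 0.05,
) -> tuple[MRResult | None, bool, str]:
    """Refit the discovery MR after excluding confounder-associated variants.

    Candidates are the unclumped genome-wide-significant cis variants; any
    variant listed in ``confounder_snps`` (column ``variant_id``) is removed,
    as are variants with outcome p-value below ``outcome_p_max`` when that
    pre-filter is enabled; the remainder is clumped at the strict r^2 and the
    MR refitted.  Pass = p < alpha with the discovery direction.
    """
    params = params or SelectionParams()
    excluded = set()
    if confounder_snps is not None and len(confounder_snps):
        excluded = set(confounder_snps["variant_id"])
    base = params if params.clump_r2 <= 0.001 else SelectionParams()
    iv = select_cis_instruments(
        protein.discovery.subset(
            [v for v in protein.discovery.variant_ids if v not in excluded]
        ),
        protein.region,
        protein.ld,
        base,
    )
    if iv.empty:
        return None, False, "no instruments after confounder exclusion"
    try:
        pair = harmonize_pair(protein.discovery.subset(iv.variant_ids), outcome_stats, ld=protein.ld)
    except EmptyHarmonizationError:
        return None, False, "no instruments shared with outcome after exclusion"
    if outcome_p_max is not None:
        keep = pair.df["pval_out"] > outcome_p_max
        if not keep.any():
            return None, False, "no instruments below outcome-association pre-filter"
        pair = pair.subset(pair.df.loc[keep, "variant_id"])
    res, _ = _mr_estimate(pair)
    ok = res.pval < alpha and _same_direction(res.beta, discovery_beta)
    return res, bool(ok), "" if ok else "sensitivity estimate not significant/consistent"


def reverse_mr(
    outcome_stats: SummaryStats,
    pqtl: SummaryStats,
    regions,
    exclude: GeneRegion | None = None,
    p_threshold: float = 5e-8,
    relaxed_threshold: float = 1e-5,
    params: SelectionParams | None = None,
) -> tuple[MRResult | None, str]:
    """MR with roles swapped: does the outcome causally shift protein levels?

    Instruments are outcome-associated variants selected and clumped within
    each of ``regions`` (``(GeneRegion, LDMatrix)`` pairs — the outcome's
    genome-wide loci); the protein's own cis window (``exclude``) is skipped,
    since a shared causal variant there would mimic reverse causation under
    any true forward effect.  When no instrument reaches ``p_threshold`` the
    threshold is relaxed to ``relaxed_threshold`` (sparse outcomes).

    Returns (result, note); the note flags potential reverse causality at
    p < 0.05, or explains why the test was not assessable.
    """
    from dataclasses import replace as _replace

    params = params or SelectionParams()
    for thr, label in ((p_threshold, "primary"), (relaxed_threshold, "relaxed")):
        ids: list[str] = []
        for region, ld in regions:
            if exclude is not None and region.chrom == exclude.chrom:
                continue
            iv = select_cis_instruments(
                outcome_stats, region, ld, _replace(params, p_threshold=thr)
            )
            ids.extend(iv.variant_ids)
        if ids:
            try:
                pair = harmonize_pair(outcome_stats.subset(ids), pqtl)
            except EmptyHarmonizationError:
                continue
            res, _ = _mr_estimate(pair)
            note = f"{label} threshold {thr:g}; {len(pair)} instrument(s)"
            if res.pval < 0.05:
                note += "; potential reverse causality"
            return res, note
    return None, "not assessable: no instruments at either threshold"


def _confirmation(
    protein: ProteinData,
    outcome_stats: SummaryStats,
    discovery_beta: float,
    params: SelectionParams,
    relaxed_r2: float = 0.1,
    gsmr_min_snps: int = 5,
    outlier_alpha: float = 0.01,
):
    """GSMR on relaxed-clumped instruments; LD-aware IVW when too few SNPs."""
    from dataclasses import replace as _replace

    relaxed = _replace(params, clump_r2=relaxed_r2)
    iv = select_cis_instruments(protein.discovery, protein.region, protein.ld, relaxed)
    if len(iv) < 2:
        return None, "insufficient_snps", None
    try:
        pair = harmonize_pair(protein.discovery.subset(iv.variant_ids), outcome_stats, ld=protein.ld)
    except EmptyHarmonizationError:
        return None, "insufficient_snps", None
    if len(pair) < 2:
        return None, "insufficient_snps", None
    try:
        if len(pair) >= gsmr_min_snps:
            res = gsmr_fit(pair, protein.ld, outlier_alpha=outlier_alpha)
            beta, pval = res.beta, res.pval
        else:
            res = ivw_correlated(pair, protein.ld)
            beta, pval = res.beta, res.pval
    except (DegenerateFitError, np.linalg.LinAlgError):
        return None, "failed", pair
    status = "confirmed" if (pval < 0.05 and _same_direction(beta, discovery_beta)) else "failed"
    return res, status, pair


def run_discovery_validation(
    study: StudyData,
    params: SelectionParams | None = None,
    criteria: TierCriteria | None = None,
    stages: frozenset = ALL_STAGES,
    priors: ColocPriors | None = None,
    gsmr_min_snps: int = 5,
    seed: int = 0,
) -> list[AssociationRecord]:
    """Run the full association pipeline over every protein x outcome cell.

    FDR is applied jointly across all discovery tests.  Per-cell failures are
    recorded with reasons, never raised.  ``stages`` can drop expensive
    stages (confirmation/diagnostics/sensitivity/heidi/coloc/reverse) for
    calibration studies that only need discovery + validation.
    """
    params = params or SelectionParams()
    criteria = criteria or TierCriteria()
    priors = priors or ColocPriors()
    records: list[AssociationRecord] = []

    for pid in sorted(study.proteins):
        protein = study.proteins[pid]
        for oid in sorted(study.outcomes):
            outcome_stats = study.outcomes[oid]
            rec = AssociationRecord(protein=pid, outcome=oid)
            records.append(rec)

            iv = select_cis_instruments(protein.discovery, protein.region, protein.ld, params)
            if iv.empty:
                rec.notes.append("no discovery instruments")
                continue
            rec.n_instruments = len(iv)
            try:
                pair = harmonize_pair(
                    protein.discovery.subset(iv.variant_ids), outcome_stats, ld=protein.ld
                )
            except EmptyHarmonizationError:
                rec.notes.append("no instruments shared with outcome")
                continue
            rec.discovery, rec.discovery_method = _mr_estimate(pair)
            st = steiger_test(pair)
            rec.steiger_direction, rec.steiger_pval = st.direction, st.pval

            # validation in the second pQTL study
            iv_v = select_cis_instruments(protein.validation, protein.region, protein.ld, params)
            if not iv_v.empty:
                try:
                    pair_v = harmonize_pair(
                        protein.validation.subset(iv_v.variant_ids), outcome_stats, ld=protein.ld
                    )
                    rec.validation, _ = _mr_estimate(pair_v)
                except EmptyHarmonizationError:
                    rec.notes.append("validation instruments not shared with outcome")
            else:
                rec.notes.append("no validation instruments")

    # joint FDR across the whole discovery family
    tested = [r for r in records if r.discovery is not None]
    if tested:
        q = bh_fdr([r.discovery.pval for r in tested])
        for r, qv in zip(tested, q):
            r.discovery_q = float(qv)

    for rec in records:
        if rec.discovery is None or rec.validation is None:
            continue
        same_dir = _same_direction(rec.discovery.beta, rec.validation.beta)
        rec.significant = (
            rec.discovery_q < criteria.fdr_alpha
            and rec.validation.pval < criteria.validation_alpha
            and same_dir
        )
        rec.suggestive = (
            rec.discovery.pval < criteria.validation_alpha
            and rec.validation.pval < criteria.validation_alpha
            and same_dir
        )

    # outcomes-associated count per protein (significant or suggestive)
    counts: dict[str, int] = {}
    for rec in records:
        if rec.significant or rec.suggestive:
            counts[rec.protein] = counts.get(rec.protein, 0) + 1
    for rec in records:
        rec.outcomes_associated_count = counts.get(rec.protein, 0)

    # downstream stages only where discovery succeeded
    for rec in records:
        if rec.discovery is None:
            continue
        protein = study.proteins[rec.protein]
        outcome_stats = study.outcomes[rec.outcome]
        disc_beta = rec.discovery.beta

        if "confirmation" in stages:
            res, status, pair_r = _confirmation(
                protein, outcome_stats, disc_beta, params, gsmr_min_snps=gsmr_min_snps
            )
            rec.confirmation, rec.confirmation_status = res, status
            if "diagnostics" in stages and pair_r is not None and len(pair_r) >= 2:
                try:
                    rec.Q_pval = ivw(pair_r).Q_pval
                except NotEstimableError:
                    pass
                if len(pair_r) >= 3:
                    rec.egger_intercept_pval = mr_egger(pair_r).intercept_pval

        if "sensitivity" in stages:
            res, ok, reason = sensitivity_confounder_filter(
                protein, outcome_stats, study.confounder_snps, disc_beta, params
            )
            rec.sensitivity, rec.sensitivity_pass, rec.sensitivity_reason = res, ok, reason

        region_exp = _subset_region(protein.discovery, protein.region, params.cis_flank_bp)
        region_out = _subset_region(outcome_stats, protein.region, params.cis_flank_bp)

        if "heidi" in stages:
            try:
                rec.heidi = heidi_test(region_exp, region_out, protein.ld)
            except (KeyError, ValueError, EmptyHarmonizationError) as e:
                rec.notes.append(f"heidi not run: {e}")

        if "coloc" in stages:
            pp = []
            for expo in (region_exp, _subset_region(protein.validation, protein.region, params.cis_flank_bp)):
                try:
                    pp.append(coloc_abf(expo, region_out, priors).pp_h4)
                except ValueError:
                    pass
            if pp:
                rec.pp_h4 = float(max(pp))

        if "reverse" in stages:
            res, note = reverse_mr(
                outcome_stats, protein.discovery, study.all_regions(), exclude=protein.region
            )
            if res is not None:
                rec.reverse_pval = res.pval
                rec.reverse_flag = res.pval < 0.05
            rec.notes.append(f"reverse: {note}")

    # tiers
    for rec in records:
        if not (rec.significant or rec.suggestive):
            rec.tier = None
            continue
        try:
            rec.tier = classify_tier(rec, criteria)
        except ClassificationError as e:
            rec.tier = None
            rec.notes.append(str(e))
    return records


# ---------------------------------------------------------------------------
# tabulation and the file-driven entry point


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "protein": r.protein,
                "outcome": r.outcome,
                "n_instruments": r.n_instruments,
                "method": r.discovery_method,
                "beta_discovery": r.discovery.beta if r.discovery else np.nan,
                "se_discovery": r.discovery.se if r.discovery else np.nan,
                "or_discovery": r.discovery.odds_ratio if r.discovery else np.nan,
                "p_discovery": r.discovery.pval if r.discovery else np.nan,
                "q_discovery": r.discovery_q,
                "beta_validation": r.validation.beta if r.validation else np.nan,
                "p_validation": r.validation.pval if r.validation else np.nan,
                "confirmation_status": r.confirmation_status,
                "p_het": np.nan if r.Q_pval is None else r.Q_pval,
                "p_ple": np.nan if r.egger_intercept_pval is None else r.egger_intercept_pval,
                "p_heidi": np.nan if r.heidi_pval is None else r.heidi_pval,
                "pp_h4": r.pp_h4,
                "sensitivity_pass": "" if r.sensitivity_pass is None else str(bool(r.sensitivity_pass)),
                "steiger_direction": r.steiger_direction,
                "p_reverse": r.reverse_pval,
                "n_outcomes_associated": r.outcomes_associated_count,
                "significant": r.significant,
                "suggestive": r.suggestive,
                "tier": "" if r.tier is None else r.tier,
                "notes": "; ".join(r.notes),
            }
        )
    return pd.DataFrame(rows)


def write_records(records: list[AssociationRecord], out_dir, config_used: dict | None = None) -> Path:
    """Write associations.tsv (fixed float formatting, hence byte-stable) and
    a machine-readable JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    path = out / "associations.tsv"
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    manifest = {
        "n_records": len(records),
        "n_significant": int(sum(r.significant for r in records)),
        "n_suggestive_only": int(sum(r.suggestive and not r.significant for r in records)),
        "tiers": {
            str(t): int(sum(1 for r in records if r.tier == t)) for t in (1, 2, 3)
        },
        "config": config_used or {},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _study_from_config(cfg: dict) -> tuple[StudyData, dict]:
    if "simulate" in cfg:
        from .simulate import simulate_study

        sim = dict(cfg["simulate"])
        study = simulate_study(**sim)
        return study, sim
    proteins = {}
    for p in cfg["proteins"]:
        disc, _ = read_summary_stats(p["discovery"], trait_type="quantitative", trait_id=p["id"])
        val, _ = read_summary_stats(p["validation"], trait_type="quantitative", trait_id=p["id"])
        ld = read_ld_matrix(p["ld_matrix"], p["ld_variants"])
        g = p["gene"]
        region = GeneRegion(p["id"], str(g["chrom"]), int(g["start"]), int(g["end"]))
        proteins[p["id"]] = ProteinData(p["id"], disc, val, region, ld)
    outcomes = {}
    for o in cfg["outcomes"]:
        stats, _ = read_summary_stats(o["path"], trait_type=o.get("trait_type", "binary"), trait_id=o["id"])
        outcomes[o["id"]] = stats
    confounders = None
    if cfg.get("confounder_snps"):
        confounders = pd.read_csv(cfg["confounder_snps"], sep="\t")
    return StudyData(proteins, outcomes, confounders), {}


def run_pipeline(config, out_dir=None) -> list[AssociationRecord]:
    """Run the whole pipeline from a config mapping or YAML file path.

    The config names the input files (or a ``simulate`` block), thresholds
    (SelectionParams / TierCriteria fields), the seed and the output
    directory.  Outputs: associations.tsv + run_manifest.json.  Identical
    config and seed give byte-identical outputs.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config, "rt") as fh:
            config = yaml.safe_load(fh)
    study, sim_cfg = _study_from_config(config)
    params = SelectionParams(**config.get("selection", {}))
    criteria = TierCriteria(**config.get("criteria", {}))
    priors = ColocPriors(**config.get("coloc_priors", {}))
    seed = int(config.get("seed", 0))
    records = run_discovery_validation(
        study, params=params, criteria=criteria, priors=priors, seed=seed
    )
    out = out_dir or config.get("out_dir")
    if out:
        cfg_used = {k: v for k, v in config.items() if k != "proteins"}
        write_records(records, out, cfg_used)
    return records
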