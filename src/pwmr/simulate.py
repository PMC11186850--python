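"""Synthetic GWAS/pQTL summary statistics with known causal architecture.

The generator works on the standardized-genotype scale: a region of m variants
with LD correlation R, joint (causal) exposure effects b_x and outcome effects
b_y.  True marginal z-scores are sqrt(n) * R b (the marginal-effect identity),
and observed z-scores are drawn from MVN(true z, R) — the classical
distribution of correlated marginal association statistics.  Betas and SEs are
then re-expressed on the per-allele scale with se = 1/sqrt(n * 2 f (1-f)) so
that emitted files look like real GWAS output.  Binary outcomes use the
effective sample size n_eff = 4 / (1/n_case + 1/n_control) on the log-odds
scale.

Scenario presets cover the colocalization hypotheses (H0-H4) plus pleiotropy,
invalid instruments, reverse causation and confounding; ``paper_like`` scale
uses the study sample sizes (exposure n = 35,559; outcome 79,495 cases /
1,259,808 controls, case/control counts scaled down 40x by default for desk
runtime).  An individual-level generator (latent-Gaussian haplotypes, logistic
outcome) serves as an independent oracle for the summary-level one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import LDMatrix, SummaryStats

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_ld",
    "simulate_summary_stats",
    "simulate_individual_level",
    "summary_from_individual",
    "scenario_preset",
    "PRESET_NAMES",
]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimConfig:
    """One region's simulation parameters (seed mandatory).

    Effects are on the standardized-genotype scale: ``exposure_effects`` maps
    variant index -> joint effect on the exposure (SD units);
    ``causal_beta`` is the exposure->outcome effect (log-odds per SD
    exposure); ``direct_effects`` are variant->outcome effects bypassing the
    exposure (pleiotropy); ``outcome_effects`` are outcome-specific causal
    effects for distinct-variant scenarios; ``reverse_beta`` routes the
    outcome's genetic effects back onto the exposure (reverse causation).
    """

    n_snps: int = 40
    seed: int = 0
    ld_model: str = "ar1"  # ar1 | blocks | identity
    rho: float = 0.5
    block_sizes: tuple = ()
    block_rhos: tuple = ()
    maf_range: tuple = (0.01, 0.5)
    n_x: int = 5000
    n_case: int = 2000
    n_control: int = 20000
    exposure_effects: dict = field(default_factory=dict)
    causal_beta: float = 0.0
    direct_effects: dict = field(default_factory=dict)
    outcome_effects: dict = field(default_factory=dict)
    reverse_beta: float = 0.0
    scenario: str = "custom"
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000
    id_prefix: str = "rs"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must be in (-1, 1)")
        for d in (self.exposure_effects, self.direct_effects, self.outcome_effects):
            for i in d:
                if not (0 <= i < self.n_snps):
                    raise ValueError(f"causal index {i} outside region of {self.n_snps} variants")
        if self.scenario == "H4" and self.outcome_effects:
            raise ValueError("H4 (shared causal variant) is inconsistent with distinct outcome_effects")
        if self.scenario == "H3" and self.causal_beta != 0:
            raise ValueError("H3 (distinct variants) is inconsistent with a nonzero causal_beta")

    @property
    def n_eff_outcome(self) -> float:
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)

    def joint_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """(b_x, b_y) joint standardized effects implied by the architecture."""
        b_x = np.zeros(self.n_snps)
        for i, v in self.exposure_effects.items():
            b_x[i] += v
        b_out = np.zeros(self.n_snps)
        for i, v in self.outcome_effects.items():
            b_out[i] += v
        if self.reverse_beta != 0.0:
            # outcome -> exposure: the outcome's genetic effects leak into the
            # exposure scaled by reverse_beta
            b_x = b_x + self.reverse_beta * b_out
        b_y = self.causal_beta * b_x + b_out
        for i, v in self.direct_effects.items():
            b_y[i] += v
        return b_x, b_y


@dataclass
class SimTruth:
    """Ground truth for recovery tests: joint and marginal effects plus LD."""

    scenario: str
    b_x_joint: np.ndarray
    b_y_joint: np.ndarray
    z_x_true: np.ndarray
    z_y_true: np.ndarray
    ld: np.ndarray
    maf: np.ndarray
    causal_beta: float
    config: SimConfig


def simulate_ld(config: SimConfig) -> LDMatrix:
    """LD matrix for the configured model (PSD by construction).

    ar1: r_ij = rho^|i-j|; blocks: block-diagonal constant rho; identity.
    """
    m = config.n_snps
    if config.ld_model == "identity":
        r = np.eye(m)
    elif config.ld_model == "ar1":
        idx = np.arange(m)
        r = config.rho ** np.abs(idx[:, None] - idx[None, :])
    elif config.ld_model == "blocks":
        sizes = config.block_sizes or (m,)
        rhos = config.block_rhos or (config.rho,) * len(sizes)
        if sum(sizes) != m:
            raise ValueError(f"block sizes {sizes} do not sum to n_snps={m}")
        r = np.zeros((m, m))
        off = 0
        for s, rho in zip(sizes, rhos):
            if not (0 <= rho < 1):
                # a constant-rho block is PSD only for rho >= -1/(size-1);
                # negative within-block LD is not a realistic model anyway
                raise ValueError(f"block rho must be in [0, 1), got {rho}")
            blk = np.full((s, s), rho)
            np.fill_diagonal(blk, 1.0)
            r[off : off + s, off : off + s] = blk
            off += s
    else:
        raise ValueError(f"unknown ld_model {config.ld_model!r}")
    ids, alleles, _, _ = _variant_frame(config)
    return LDMatrix(ids, alleles, r)


def _variant_frame(config: SimConfig):
    """Deterministic variant ids, alleles, positions and MAFs for a config."""
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    ids = [f"{config.id_prefix}{config.chrom}_{i:04d}" for i in range(m)]
    alleles = [_NONPALINDROMIC_PAIRS[int(k)] for k in rng.integers(0, len(_NONPALINDROMIC_PAIRS), m)]
    pos = config.pos_start + config.pos_step * np.arange(m)
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, m)
    flip = rng.random(m) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    return ids, alleles, pos, eaf


def _draw_z(rng, z_true: np.ndarray, chol: np.ndarray) -> np.ndarray:
    return z_true + chol @ rng.standard_normal(len(z_true))


def simulate_z_scores(config: SimConfig, rng=None, chol=None, R=None):
    """Fast path: one draw of (z_x, z_y) observed marginal z-scores.

    Used by calibration loops; ``chol``/``R`` may be precomputed.
    """
    if R is None:
        R = simulate_ld(config).r
    if chol is None:
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    if rng is None:
        # offset from the variant-frame stream so frequencies and noise are independent
        rng = np.random.default_rng(config.seed + 1)
    b_x, b_y = config.joint_effects()
    z_x_true = np.sqrt(config.n_x) * (R @ b_x)
    z_y_true = np.sqrt(config.n_eff_outcome) * (R @ b_y)
    return _draw_z(rng, z_x_true, chol), _draw_z(rng, z_y_true, chol), z_x_true, z_y_true


def _stats_frame(config, ids, alleles, pos, eaf, z, n, n_case=None, n_control=None):
    f = np.asarray(eaf)
    se = 1.0 / np.sqrt(n * 2.0 * f * (1.0 - f))
    beta = z * se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": config.chrom,
            "pos": pos,
            "ea": [a for a, _ in alleles],
            "oa": [b for _, b in alleles],
            "eaf": f,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": int(round(n)) if n_case is None else int(n_case + n_control),
        }
    )
    if n_case is not None:
        df["n_case"] = int(n_case)
        df["n_control"] = int(n_control)
    return df


def simulate_summary_stats(
    config: SimConfig, rng=None
) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """One region's exposure and outcome summary statistics plus ground truth.

    Deterministic given ``config.seed`` (pass ``rng`` to drive replicate
    loops from an external seed sequence).
    """
    ld = simulate_ld(config)
    R = ld.r
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ids, alleles, pos, eaf = _variant_frame(config)
    z_x, z_y, z_x_true, z_y_true = simulate_z_scores(config, rng=rng, chol=chol, R=R)
    exp_df = _stats_frame(config, ids, alleles, pos, eaf, z_x, config.n_x)
    out_df = _stats_frame(
        config, ids, alleles, pos, eaf, z_y, config.n_eff_outcome,
        n_case=config.n_case, n_control=config.n_control,
    )
    b_x, b_y = config.joint_effects()
    exposure = SummaryStats(
        f"exposure_{config.scenario}", "quantitative", exp_df,
        provenance=f"simulated scenario={config.scenario} seed={config.seed}",
    )
    outcome = SummaryStats(
        f"outcome_{config.scenario}", "binary", out_df,
        provenance=f"simulated scenario={config.scenario} seed={config.seed}; "
        f"n_eff={config.n_eff_outcome:.0f} (4/(1/cases+1/controls))",
    )
    truth = SimTruth(config.scenario, b_x, b_y, z_x_true, z_y_true, R, np.minimum(eaf, 1 - eaf), config.causal_beta, config)
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# individual-level oracle


def simulate_individual_level(config: SimConfig, n_samples: int, rng=None):
    """Individual-level data consistent with the summary-level model.

    Haplotypes are latent standard normals with correlation R thresholded at
    the MAF quantile; dosage = sum of two haplotypes (values in {0,1,2}).
    Exposure = standardized dosages @ b_x + Gaussian noise; binary outcome
    from a logistic model with intercept set to the configured case fraction.

    Note the thresholding attenuates the latent correlation, so the realized
    dosage LD is slightly below R off the diagonal; expectation identities
    hold exactly with the *realized* LD.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    ld = simulate_ld(config)
    R = ld.r
    chol = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    ids, alleles, pos, eaf = _variant_frame(config)
    maf = np.minimum(eaf, 1 - eaf)
    thresh = stats.norm.ppf(eaf)  # carrier of the *effect* allele with prob eaf
    hap1 = (chol @ rng.standard_normal((config.n_snps, n_samples))) < thresh[:, None]
    hap2 = (chol @ rng.standard_normal((config.n_snps, n_samples))) < thresh[:, None]
    dosage = (hap1.astype(int) + hap2.astype(int)).astype(float)

    mean_d = 2.0 * eaf
    sd_d = np.sqrt(2.0 * eaf * (1.0 - eaf))
    g_std = (dosage - mean_d[:, None]) / sd_d[:, None]

    b_x, b_y = config.joint_effects()
    gvar = float(b_x @ R @ b_x)
    noise_sd = np.sqrt(max(1e-6, 1.0 - gvar))
    x = g_std.T @ b_x + noise_sd * rng.standard_normal(n_samples)

    case_frac = config.n_case / (config.n_case + config.n_control)
    alpha = np.log(case_frac / (1 - case_frac))
    eta = alpha + g_std.T @ (b_y - config.causal_beta * b_x) + config.causal_beta * x
    y = (rng.random(n_samples) < expit(eta)).astype(int)

    dosages = pd.DataFrame(dosage, index=ids)
    phenos = pd.DataFrame({"exposure": x, "outcome": y})
    return dosages, phenos


def summary_from_individual(config: SimConfig, dosages: pd.DataFrame, phenos: pd.DataFrame):
    """Per-variant marginal regressions on individual-level data.

    Exposure: OLS slope per standardized variant.  Outcome: score-test
    (linear-probability) approximation of the per-variant log-odds effect —
    adequate for the moderate effects the generator emits.
    """
    g = dosages.to_numpy(dtype=float)
    n = g.shape[1]
    x = phenos["exposure"].to_numpy(dtype=float)
    y = phenos["outcome"].to_numpy(dtype=float)
    ids, alleles, pos, _ = _variant_frame(config)
    eaf_hat = g.mean(axis=1) / 2.0
    gc = g - g.mean(axis=1, keepdims=True)
    gvar = gc.var(axis=1)
    gvar = np.where(gvar <= 0, np.nan, gvar)

    bx = (gc @ (x - x.mean())) / (n * gvar)
    resid_var = x.var() - bx**2 * gvar
    se_x = np.sqrt(np.maximum(resid_var, 1e-12) / (n * gvar))

    pbar = y.mean()
    by = (gc @ (y - pbar)) / (n * gvar) / (pbar * (1 - pbar))
    se_yv = 1.0 / np.sqrt(n * gvar * pbar * (1 - pbar))

    def _frame(beta, se):
        z = beta / se
        return pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": config.chrom,
                "pos": pos,
                "ea": [a for a, _ in alleles],
                "oa": [b for _, b in alleles],
                "eaf": eaf_hat,
                "beta": beta,
                "se": se,
                "pval": np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
                "n": n,
            }
        )

    exposure = SummaryStats("exposure_individual", "quantitative", _frame(bx, se_x))
    outcome = SummaryStats("outcome_individual", "binary", _frame(by, se_yv))
    return exposure, outcome


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = (
    "H0", "H1", "H2", "H3", "H4",
    "pleiotropy", "invalid_instruments", "reverse", "confounded",
)

#: study-condition effect sizes (standardized scale): a strong cis-pQTL
#: explains ~9% of protein variance; the causal log-odds per SD protein is
#: sized so the scaled-down outcome carries a clearly detectable signal
_CIS_EFFECT = 0.3
_CAUSAL_BETA = 0.25
_OUTCOME_EFFECT = 0.08
_IV_EFFECT = 0.15


def scenario_preset(name: str, scale: str = "small", seed: int = 0, full_scale: bool = False) -> SimConfig:
    """Fully populated SimConfig for a named causal architecture.

    ``scale="paper_like"`` uses exposure n = 35,559 and outcome counts
    79,495 / 1,259,808 divided by 40 for desk runtime (``full_scale=True``
    keeps the printed counts); ``scale="small"`` uses desk-test sizes.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if scale == "paper_like":
        n_x = 35_559
        if full_scale:
            n_case, n_control = 79_495, 1_259_808
        else:
            n_case, n_control = 79_495 // 40, 1_259_808 // 40
        n_snps = 60
    elif scale == "small":
        n_x, n_case, n_control, n_snps = 5_000, 2_000, 20_000, 40
    else:
        raise ValueError(f"unknown scale {scale!r}; choose small|paper_like")

    base = SimConfig(
        n_snps=n_snps, seed=seed, ld_model="ar1", rho=0.5,
        maf_range=(0.05, 0.5), n_x=n_x, n_case=n_case, n_control=n_control,
        scenario=name,
    )
    c = n_snps // 2
    if name == "H0":
        return base
    if name == "H1":
        return replace(base, exposure_effects={c: _CIS_EFFECT})
    if name == "H2":
        return replace(base, outcome_effects={c: _OUTCOME_EFFECT})
    if name == "H3":
        # distinct causal variants two steps apart (latent r = rho^2)
        return replace(
            base,
            exposure_effects={c: _CIS_EFFECT},
            outcome_effects={c + 2: _OUTCOME_EFFECT},
        )
    if name == "H4":
        return replace(base, exposure_effects={c: _CIS_EFFECT}, causal_beta=_CAUSAL_BETA)
    if name == "pleiotropy":
        k = 20
        return replace(
            base, n_snps=k, ld_model="identity",
            exposure_effects={i: _IV_EFFECT for i in range(k)},
            causal_beta=0.1,
            direct_effects={i: 0.05 for i in range(k)},
        )
    if name == "invalid_instruments":
        k = 20
        n_invalid = int(round(0.4 * k))
        return replace(
            base, n_snps=k, ld_model="identity",
            exposure_effects={i: _IV_EFFECT for i in range(k)},
            causal_beta=0.1,
            direct_effects={i: 0.1 for i in range(n_invalid)},
        )
    if name == "reverse":
        return replace(base, outcome_effects={c: 0.1}, reverse_beta=0.4)
    if name == "confounded":
        k = 11
        eff = {i: _IV_EFFECT for i in range(1, k)}
        eff[0] = 0.1  # confounder-acting variant: affects exposure AND outcome
        return replace(
            base, n_snps=k, ld_model="identity",
            exposure_effects=eff, causal_beta=0.1,
            direct_effects={0: 0.15},
        )
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# whole-study simulation for the pipeline


def simulate_study(
    n_proteins: int = 8,
    n_causal: int = 2,
    n_confounded: int = 0,
    n_reverse: int = 0,
    n_outcome_loci: int = 2,
    seed: int = 0,
    n_snps: int = 30,
    n_x_discovery: int = 7_213,
    n_x_validation: int = 35_559,
    n_case: int = 1_987,
    n_control: int = 31_495,
    causal_beta: float = _CAUSAL_BETA,
    cis_effect: float = _CIS_EFFECT,
    outcome_locus_effect: float = 0.1,
    reverse_gamma: float = 0.4,
    rho: float = 0.5,
    outcome_ids: tuple = ("migraine",),
):
    """A synthetic proteome study with genome-wide summary statistics.

    Layout: one cis region per protein (separate chromosomes) plus
    ``n_outcome_loci`` dedicated outcome-only loci.  Every protein's pQTL
    files cover all regions (null associations outside its own cis region),
    as real proteome-wide data do — this is what makes reverse MR and
    cross-region operations meaningful.

    Protein roles: the first ``n_causal`` proteins carry a true
    exposure->outcome effect ``causal_beta`` (log-odds per SD protein);
    ``n_confounded`` of those additionally carry a confounder-acting variant
    (strong exposure association plus a direct outcome effect, nearly
    LD-independent of the main cis signal) listed in the returned exclusion
    table; the last ``n_reverse`` proteins are *downstream* of the outcome
    liability (their levels associate with the outcome's own loci scaled by
    ``reverse_gamma``) with a null forward effect.

    Sample-size defaults mirror the study structure (discovery n = 7,213;
    validation n = 35,559; case/control counts scaled down 40x).
    """
    from .instruments import GeneRegion
    from .pipeline import ProteinData, StudyData

    if n_causal + n_reverse > n_proteins:
        raise ValueError("n_causal + n_reverse must not exceed n_proteins")
    rng = np.random.default_rng(seed)
    c = n_snps // 2
    conf_idx = max(0, c - 6)  # r = rho^6 with the main signal: clump-independent

    def _role(p):
        if p < n_causal:
            return "confounded" if p < n_confounded else "causal"
        if p >= n_proteins - n_reverse:
            return "reverse"
        return "null"

    # region registry: protein cis regions then outcome-only loci
    region_cfgs = []
    for q in range(n_proteins):
        role = _role(q)
        exposure = {c: cis_effect}
        direct = {}
        if role == "confounded":
            exposure[conf_idx] = 0.25
            direct[conf_idx] = 0.25
        region_cfgs.append(
            SimConfig(
                n_snps=n_snps, seed=seed * 1_000 + q, ld_model="ar1", rho=rho,
                maf_range=(0.05, 0.5), n_x=n_x_discovery, n_case=n_case,
                n_control=n_control, exposure_effects=exposure,
                causal_beta=causal_beta if role in ("causal", "confounded") else 0.0,
                direct_effects=direct, chrom=str(q + 1),
            )
        )
    for j in range(n_outcome_loci):
        region_cfgs.append(
            SimConfig(
                n_snps=n_snps, seed=seed * 1_000 + n_proteins + j, ld_model="ar1",
                rho=rho, maf_range=(0.05, 0.5), n_x=n_x_discovery, n_case=n_case,
                n_control=n_control, outcome_effects={c: outcome_locus_effect},
                scenario="H2", chrom=str(n_proteins + j + 1),
            )
        )

    n_eff_y = region_cfgs[0].n_eff_outcome
    proteins = {}
    all_regions = []
    outcome_frames: dict[str, list] = {oid: [] for oid in outcome_ids}
    disc_frames: dict[int, list] = {p: [] for p in range(n_proteins)}
    val_frames: dict[int, list] = {p: [] for p in range(n_proteins)}
    confounder_rows = []
    truth = {}

    for r_i, cfg in enumerate(region_cfgs):
        ld = simulate_ld(cfg)
        R = ld.r
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(n_snps))
        ids, alleles, pos, eaf = _variant_frame(cfg)
        region = GeneRegion(
            f"region_{cfg.chrom}", cfg.chrom, int(cfg.pos_start),
            int(cfg.pos_start + cfg.pos_step * (n_snps - 1)),
        )
        owner = r_i if r_i < n_proteins else None
        _, b_y = cfg.joint_effects()
        b_o_own = np.zeros(n_snps)
        for i, v in cfg.outcome_effects.items():
            b_o_own[i] = v
        # one outcome draw per region per outcome trait
        zy_true = np.sqrt(n_eff_y) * (R @ b_y)
        for oid in outcome_ids:
            zy = _draw_z(rng, zy_true, chol)
            outcome_frames[oid].append(
                _stats_frame(cfg, ids, alleles, pos, eaf, zy, n_eff_y,
                             n_case=cfg.n_case, n_control=cfg.n_control)
            )
        # per-protein exposure draws (discovery + validation)
        for p in range(n_proteins):
            if owner == p:
                b_x_p, _ = cfg.joint_effects()
            elif owner is None and _role(p) == "reverse":
                b_x_p = reverse_gamma * b_o_own
            else:
                b_x_p = np.zeros(n_snps)
            for n_x, sink in ((n_x_discovery, disc_frames), (n_x_validation, val_frames)):
                zx = _draw_z(rng, np.sqrt(n_x) * (R @ b_x_p), chol)
                sink[p].append(_stats_frame(cfg, ids, alleles, pos, eaf, zx, n_x))
        all_regions.append((region, ld))
        if owner is not None:
            role = _role(owner)
            pid = f"PROT{owner:02d}"
            truth[pid] = {
                "role": role,
                "causal_beta": cfg.causal_beta,
                "config": cfg,
            }
            if role == "confounded":
                confounder_rows.append(
                    {"variant_id": ids[conf_idx], "trait": "synthetic_confounder"}
                )

    for p in range(n_proteins):
        pid = f"PROT{p:02d}"
        region, ld = all_regions[p]
        disc = SummaryStats(
            f"{pid}_discovery", "quantitative", pd.concat(disc_frames[p], ignore_index=True),
            provenance=f"simulated study seed={seed}",
        )
        val = SummaryStats(
            f"{pid}_validation", "quantitative", pd.concat(val_frames[p], ignore_index=True),
            provenance=f"simulated study seed={seed}",
        )
        cis = GeneRegion(pid, region.chrom, region.start, region.end)
        proteins[pid] = ProteinData(pid, disc, val, cis, ld)

    outcomes = {
        oid: SummaryStats(oid, "binary", pd.concat(frames, ignore_index=True),
                          provenance=f"simulated study seed={seed}")
        for oid, frames in outcome_frames.items()
    }
    confounders = (
        pd.DataFrame(confounder_rows, columns=["variant_id", "trait"])
        if confounder_rows
        else None
    )
    return StudyData(
        proteins, outcomes, confounder_snps=confounders, truth=truth,
        regions=all_regions,
    )
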