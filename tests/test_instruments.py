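"""Instrument selection, clumping, F statistics and cross-cohort heterogeneity."""

import numpy as np
import pytest
from scipy import stats as sps

from pwmr import (
    GeneRegion,
    SelectionParams,
    clump,
    cross_cohort_het,
    per_snp_f,
    select_cis_instruments,
)
from pwmr.simulate import SimConfig, simulate_individual_level, summary_from_individual

from conftest import ld_from, make_stats


def _region(chrom="6", start=29_400_000, end=29_600_000):
    return GeneRegion("GENE", chrom, start, end)


def _pqtl(rows):
    return make_stats(rows, trait_id="protein")


IDENTITY3 = ld_from(["rs0", "rs1", "rs2"], np.eye(3))


class TestSelection:
    def test_hla_exclusion(self):
        stats = _pqtl(
            [{"variant_id": "rs0", "chrom": "6", "pos": 29_500_000, "ea": "A", "oa": "G",
              "beta": 0.5, "se": 0.05, "pval": 1e-12}]
        )
        iv = select_cis_instruments(stats, _region(), ld_from(["rs0"], [[1.0]]))
        assert iv.empty
        assert dict(zip(iv.audit["variant_id"], iv.audit["rule"]))["rs0"] == "hla_region"

    def test_cis_window_boundary_inclusive(self):
        region = GeneRegion("GENE", "2", 1_000_000, 2_000_000)
        stats = _pqtl(
            [
                {"variant_id": "rs0", "chrom": "2", "pos": 2_500_000, "ea": "A", "oa": "G",
                 "beta": 0.5, "se": 0.05, "pval": 1e-12},  # exactly end + 500kb
                {"variant_id": "rs1", "chrom": "2", "pos": 2_500_001, "ea": "A", "oa": "G",
                 "beta": 0.5, "se": 0.05, "pval": 1e-12},  # one bp outside
            ]
        )
        iv = select_cis_instruments(stats, region, ld_from(["rs0", "rs1"], np.eye(2)))
        assert iv.variant_ids == ["rs0"]

    def test_six_variant_hand_rule(self):
        """2 below p-threshold, 1 palindromic at eaf 0.45, 3 mutually correlated
        at r^2 = 0.5 -> exactly one instrument survives."""
        region = GeneRegion("GENE", "2", 1_000_000, 1_100_000)
        r = np.sqrt(0.5)
        ids = [f"rs{i}" for i in range(6)]
        ld_r = np.eye(6)
        for i in (0, 1, 2):
            for j in (0, 1, 2):
                if i != j:
                    ld_r[i, j] = r
        rows = []
        for i, vid in enumerate(ids):
            rows.append(
                {"variant_id": vid, "chrom": "2", "pos": 1_000_000 + i * 1000,
                 "ea": "A", "oa": "G", "beta": 0.5, "se": 0.05,
                 "pval": [1e-20, 1e-15, 1e-12, 0.5, 1e-3, 1e-30][i], "eaf": 0.3}
            )
        rows[3]["pval"], rows[4]["pval"] = 0.5, 1e-3  # below threshold
        rows[5].update({"ea": "A", "oa": "T", "eaf": 0.45})  # palindromic, intermediate
        iv = select_cis_instruments(_pqtl(rows), region, ld_from(ids, ld_r))
        assert iv.variant_ids == ["rs0"]
        rules = dict(zip(iv.audit["variant_id"], iv.audit["rule"]))
        assert rules["rs5"] == "palindromic_intermediate_af"
        assert rules["rs3"] == "pval_above_threshold"
        assert rules["rs1"] == rules["rs2"] == "clumped"

    def test_maf_filter_and_audit(self):
        region = GeneRegion("GENE", "2", 1_000_000, 1_100_000)
        stats = _pqtl(
            [{"variant_id": "rs0", "chrom": "2", "pos": 1_050_000, "ea": "A", "oa": "G",
              "beta": 0.5, "se": 0.05, "pval": 1e-12, "eaf": 0.995}]
        )
        iv = select_cis_instruments(stats, region, ld_from(["rs0"], [[1.0]]))
        assert iv.empty
        assert iv.audit.iloc[0]["rule"] == "maf_below_min"

    def test_filter_order_commutes(self):
        """HLA and palindromic filters remove the same set in either order."""
        region = _region()
        rows = [
            {"variant_id": "rs0", "chrom": "6", "pos": 29_500_000, "ea": "A", "oa": "T",
             "beta": 0.5, "se": 0.05, "pval": 1e-12, "eaf": 0.5},
            {"variant_id": "rs1", "chrom": "6", "pos": 28_990_000, "ea": "G", "oa": "C",
             "beta": 0.5, "se": 0.05, "pval": 1e-12, "eaf": 0.45},
            {"variant_id": "rs2", "chrom": "6", "pos": 28_980_000, "ea": "A", "oa": "G",
             "beta": 0.5, "se": 0.05, "pval": 1e-12, "eaf": 0.3},
        ]
        iv = select_cis_instruments(_pqtl(rows), region, IDENTITY3)
        assert iv.variant_ids == ["rs2"]

    def test_tightening_never_enlarges(self):
        region = GeneRegion("GENE", "2", 1_000_000, 1_100_000)
        rows = [
            {"variant_id": f"rs{i}", "chrom": "2", "pos": 1_000_000 + i * 1000,
             "ea": "A", "oa": "G", "beta": 0.3 + 0.1 * i, "se": 0.05,
             "pval": p, "eaf": 0.2 + 0.05 * i}
            for i, p in enumerate([1e-20, 1e-10, 1e-9])
        ]
        ld = ld_from([f"rs{i}" for i in range(3)], np.eye(3))
        loose = select_cis_instruments(_pqtl(rows), region, ld, SelectionParams())
        tight = select_cis_instruments(
            _pqtl(rows), region, ld, SelectionParams(p_threshold=1e-15)
        )
        assert set(tight.variant_ids) <= set(loose.variant_ids)


class TestClump:
    def _candidates(self, pvals, pos_step=1000):
        return make_stats(
            [
                {"variant_id": f"rs{i}", "chrom": "1", "pos": 1_000_000 + i * pos_step,
                 "ea": "A", "oa": "G", "beta": 0.5, "se": 0.05, "pval": p}
                for i, p in enumerate(pvals)
            ]
        ).df

    def test_below_threshold_both_retained(self):
        ld = ld_from(["rs0", "rs1"], [[1.0, np.sqrt(0.0005)], [np.sqrt(0.0005), 1.0]])
        out = clump(self._candidates([1e-10, 1e-9]), ld, r2=0.001)
        assert set(out["variant_id"]) == {"rs0", "rs1"}

    def test_greedy_keeps_smallest_p(self):
        r = np.full((3, 3), np.sqrt(0.9))
        np.fill_diagonal(r, 1.0)
        ld = ld_from(["rs0", "rs1", "rs2"], r)
        out = clump(self._candidates([1e-20, 1e-10, 1e-9]), ld, r2=0.001)
        assert out["variant_id"].tolist() == ["rs0"]

    def test_tie_breaks_lexicographically(self):
        r = np.full((2, 2), 0.99)
        np.fill_diagonal(r, 1.0)
        ld = ld_from(["rsB", "rsA"], r)
        cands = self._candidates([1e-10, 1e-10])
        cands["variant_id"] = ["rsB", "rsA"]
        out = clump(cands, ld, r2=0.001)
        assert out["variant_id"].tolist() == ["rsA"]

    def test_window_limits_removal(self):
        """Correlated variants outside the physical window are both kept."""
        r = np.full((2, 2), 0.99)
        np.fill_diagonal(r, 1.0)
        ld = ld_from(["rs0", "rs1"], r)
        out = clump(self._candidates([1e-10, 1e-9], pos_step=2_000_000), ld, r2=0.001, window_bp=1e6)
        assert len(out) == 2

    def test_missing_from_ld_retained(self):
        ld = ld_from(["rs0"], [[1.0]])
        out = clump(self._candidates([1e-10, 1e-9]), ld, r2=0.001)
        assert set(out["variant_id"]) == {"rs0", "rs1"}
        assert out.set_index("variant_id").loc["rs1", "ld_missing"]

    def test_clumped_set_is_independent(self):
        rng = np.random.default_rng(5)
        m = 12
        a = rng.normal(size=(m, m))
        cov = a @ a.T + m * np.eye(m)
        d = np.sqrt(np.diag(cov))
        r = cov / np.outer(d, d)
        ld = ld_from([f"rs{i}" for i in range(m)], r)
        cands = self._candidates(rng.uniform(1e-30, 1e-8, m))
        out = clump(cands, ld, r2=0.1)
        kept = out["variant_id"].tolist()
        for i, a_ in enumerate(kept):
            for b_ in kept[i + 1 :]:
                assert ld.r2(a_, b_) < 0.1


class TestPerSnpF:
    def test_direct_arithmetic(self):
        assert per_snp_f(0.10, 0.02) == pytest.approx(25.0)

    def test_weak_instrument_gate(self):
        region = GeneRegion("GENE", "2", 1_000_000, 1_100_000)
        stats = _pqtl(
            [{"variant_id": "rs0", "chrom": "2", "pos": 1_050_000, "ea": "A", "oa": "G",
              "beta": 0.30, "se": 0.05, "pval": 1e-9}]
        )
        iv = select_cis_instruments(stats, region, ld_from(["rs0"], [[1.0]]))
        assert iv.min_f == pytest.approx(36.0)
        assert not iv.weak(f_min=10.0)
        assert iv.weak(f_min=100.0)

    def test_matches_variance_explained_formula(self):
        """For a single causal variant, F ~ (n-2) R^2/(1-R^2) at large n."""
        cfg = SimConfig(
            n_snps=1, seed=42, ld_model="identity", n_x=20_000,
            exposure_effects={0: 0.22}, maf_range=(0.3, 0.4),
        )
        n = 20_000
        fs = []
        for rep in range(10):
            dos, phen = simulate_individual_level(cfg, n, rng=np.random.default_rng(100 + rep))
            exp, _ = summary_from_individual(cfg, dos, phen)
            fs.append(per_snp_f(exp.df["beta"][0], exp.df["se"][0]))
        r2 = 0.22**2
        expected = (n - 2) * r2 / (1 - r2)
        assert np.mean(fs) == pytest.approx(expected, rel=0.10)


class TestCrossCohortHet:
    def test_homogeneous(self):
        res = cross_cohort_het([0.2, 0.2, 0.2], [0.1, 0.1, 0.1])
        assert res.Q == pytest.approx(0.0)
        assert res.i2 == 0.0
        assert res.pval == pytest.approx(1.0)

    def test_hand_calculation(self):
        res = cross_cohort_het([0.1, 0.3], [0.1, 0.1])
        assert res.Q == pytest.approx(2.0)
        assert res.i2 == pytest.approx(0.5)
        assert res.pval == pytest.approx(sps.chi2.sf(2.0, 1), abs=1e-12)
        assert res.pval == pytest.approx(0.157, abs=5e-4)

    def test_pass_rule(self):
        assert cross_cohort_het([0.2, 0.21], [0.1, 0.1]).passes()
        # Q = 4.5 on 1 df: p = 0.034 < 0.05 and I2 = 78% > 50% -> fails both gates
        assert not cross_cohort_het([0.1, 0.4], [0.1, 0.1]).passes()

    def test_single_cohort_not_assessable(self):
        res = cross_cohort_het([0.2], [0.1])
        assert not res.assessable
        assert not res.passes()
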