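import numpy as np
import pandas as pd
import pytest

from oncotrace.simulate import (
    PloidyRegion,
    Sample,
    build_truth,
    default_config,
    expected_ratio,
    simulate_base_coverage,
    simulate_coverage,
    simulate_dna_pileups,
    simulate_het_sites,
    simulate_junctions,
    simulate_perturbation_matrix,
    simulate_rna,
    DELETION_START,
    DELETION_END,
)


PURE_SAMPLES = [
    Sample("NORM", "normal", "germline", 0.0),
    Sample("Met2", "tumor", "autopsy", 1.0),
]


class TestConfigValidation:
    def test_rejects_bad_depth(self):
        with pytest.raises(ValueError):
            default_config(seed=0, dna_depth=0)

    def test_rejects_bad_error_rate(self):
        with pytest.raises(ValueError):
            default_config(seed=0, error_rate=0.9)

    def test_rejects_bad_purity(self):
        with pytest.raises(ValueError):
            Sample("S", "tumor", "t", 1.2)

    def test_rejects_region_outside_genome(self):
        with pytest.raises(ValueError):
            default_config(
                seed=0,
                ploidy_profile=[PloidyRegion("chr1", 0, 99_000_000, 4, 2)],
            )


class TestDeterminism:
    def test_pileups_identical_for_same_seed(self):
        a = simulate_dna_pileups(default_config(seed=42))
        b = simulate_dna_pileups(default_config(seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_pileups_differ_for_other_seed(self):
        a = simulate_dna_pileups(default_config(seed=42))
        b = simulate_dna_pileups(default_config(seed=43))
        assert not a.equals(b)

    def test_other_generators_deterministic(self):
        for gen in (simulate_coverage, simulate_het_sites, simulate_junctions,
                    simulate_perturbation_matrix):
            a = gen(default_config(seed=7))
            b = gen(default_config(seed=7))
            pd.testing.assert_frame_equal(
                pd.DataFrame(a), pd.DataFrame(b)
            )

    def test_rna_deterministic(self):
        g1, s1 = simulate_rna(default_config(seed=7))
        g2, s2 = simulate_rna(default_config(seed=7))
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(s1, s2)


class TestPileups:
    def test_count_conservation(self, pileups):
        assert (pileups["ref_count"] + pileups["alt_count"] == pileups["depth"]).all()
        assert (pileups[["ref_count", "alt_count"]] >= 0).all().all()

    def test_truth_consistency_private_absent_early(self, cfg, truth, pileups):
        """Private mutations appear only in the index tumor's pileups."""
        private = truth.mutations[truth.mutations["label"] == "private"]
        for sample in ("Met1", "PT1", "PT2", "PT3", "PT4"):
            sub = pileups[pileups["sample"] == sample].merge(
                private[["chrom", "pos"]], on=["chrom", "pos"]
            )
            # error-level only: well under 5% of reads
            frac = sub["alt_count"].sum() / sub["depth"].sum()
            assert frac < 0.05

    def test_law_of_large_numbers_vaf_half(self):
        """purity=1, CN 4 with 2 mutant copies, depth 1e5 -> VAF 0.5 +- 0.01."""
        cfg = default_config(
            seed=11, dna_depth=1e5, n_background_sites=10, samples=PURE_SAMPLES
        )
        truth = build_truth(cfg)
        p = simulate_dna_pileups(cfg, truth)
        founder = truth.mutations[
            (truth.mutations["label"] == "founder") & (truth.mutations["cn"] == 4)
        ]
        sub = p[(p["sample"] == "Met2")].merge(founder[["chrom", "pos"]], on=["chrom", "pos"])
        fractions = sub["alt_count"] / sub["depth"]
        assert np.allclose(fractions, 0.5, atol=0.01)

    def test_private_in_early_is_error_binomial(self, cfg, truth, pileups):
        private = truth.mutations[truth.mutations["label"] == "private"]
        sub = pileups[pileups["sample"] == "Met1"].merge(
            private[["chrom", "pos"]], on=["chrom", "pos"]
        )
        total = sub["depth"].sum()
        # pooled alt fraction within 3 SE of the error rate
        se = np.sqrt(cfg.error_rate * (1 - cfg.error_rate) / total)
        assert abs(sub["alt_count"].sum() / total - cfg.error_rate) < 3 * se


def _pure_diploid_cfg(seed=5):
    """Mostly-diploid genome with one CN-4 region; purity 1."""
    return default_config(
        seed=seed,
        baseline_cn=(2, 1),
        ploidy_profile=[PloidyRegion("chr1", 0, 2_000_000, 4, 2)],
        chromothripsis_region=None,
        focal_deletion=None,
        samples=PURE_SAMPLES,
        n_background_sites=10,
    )


class TestCoverage:
    def test_cn4_region_ratio_near_one(self):
        """Tumor CN=4 at purity 1 on a diploid background -> ratio ~ 2x."""
        cfg = _pure_diploid_cfg()
        cov = simulate_coverage(cfg)
        t = cov[cov["sample"] == "Met2"]
        n = cov[cov["sample"] == "NORM"]
        region = (t["chrom"] == "chr1") & (t["end"] <= 2_000_000)
        ratio = np.log2(
            t[region.to_numpy()]["coverage"].mean() / n[region.to_numpy()]["coverage"].mean()
        )
        assert abs(ratio - 1.0) < 0.05

    def test_laf_quarter_for_3_to_1(self):
        cfg = default_config(
            seed=6, samples=PURE_SAMPLES, chromothripsis_region=None,
            focal_deletion=None, n_background_sites=10,
        )
        hets = simulate_het_sites(cfg)
        sub = hets[(hets["chrom"] == "chr2") & (hets["pos"] < 2_500_000)]
        laf = np.minimum(sub["a_count"], sub["b_count"]) / (
            sub["a_count"] + sub["b_count"]
        )
        assert abs(laf.mean() - 0.25) < 0.01

    def test_focal_deletion_base_coverage_drop(self):
        """CN 4 -> 2 at purity 1: in/out depth ratio drops by the planted factor."""
        cfg = default_config(seed=6, samples=PURE_SAMPLES, n_background_sites=10)
        bc = simulate_base_coverage(cfg, "chrX", 76_900_000, 76_950_000, ["Met2"])
        x = bc["Met2"]
        inside = x[DELETION_START - 76_900_000 : DELETION_END - 76_900_000]
        outside = np.concatenate(
            [x[: DELETION_START - 76_900_000], x[DELETION_END - 76_900_000 :]]
        )
        assert abs(np.log2(inside.mean() / outside.mean()) - np.log2(2 / 4)) < 0.05

    def test_region_outside_bounds_raises(self, cfg):
        with pytest.raises(ValueError):
            simulate_base_coverage(cfg, "chr1", 0, 99_000_000)

    def test_calibration_three_se(self):
        """Window coverage mean within 3 SE of the configured expectation."""
        cfg = _pure_diploid_cfg(seed=9)
        cov = simulate_coverage(cfg)
        n = cov[cov["sample"] == "NORM"]["coverage"]
        lam_per_window = cfg.dna_depth * (cfg.window_size / 1000.0)
        se = np.sqrt(lam_per_window) / (cfg.window_size / 1000.0) / np.sqrt(len(n))
        assert abs(n.mean() - cfg.dna_depth) < 3 * se


class TestJunctions:
    def test_deletion_junction_at_planted_breakpoints(self, cfg):
        jx = simulate_junctions(cfg)
        met2 = jx[jx["sample"] == "Met2"]
        dele = met2[
            (met2["pos1"] == DELETION_START) & (met2["pos2"] == DELETION_END)
        ]
        assert len(dele) == 1
        assert dele.iloc[0]["type"] == "deletion"
        assert (dele.iloc[0]["strand1"], dele.iloc[0]["strand2"]) == ("+", "-")

    def test_no_junctions_outside_planted_regions(self, cfg):
        jx = simulate_junctions(cfg)
        ct = cfg.chromothripsis_region
        outside = jx[
            ~(
                (jx["chrom1"] == ct.chrom)
                & (jx["pos1"] >= ct.start)
                & (jx["pos2"] < ct.end)
            )
            & ~((jx["pos1"] == DELETION_START) & (jx["pos2"] == DELETION_END))
        ]
        assert outside.empty

    def test_region_too_small_raises(self):
        cfg = default_config(seed=0)
        ct = cfg.chromothripsis_region
        bad = type(ct)(ct.chrom, ct.start, ct.start + 100, 1000, ct.cn_states)
        cfg2 = default_config(seed=0, chromothripsis_region=bad)
        with pytest.raises(ValueError):
            simulate_junctions(cfg2)

    def test_normal_sample_has_no_junctions(self, cfg):
        jx = simulate_junctions(cfg)
        assert "NORM" not in set(jx["sample"])


class TestRNA:
    def test_zero_fraction_gene_error_level_only(self, cfg, truth):
        _, sites = simulate_rna(cfg, truth)
        zero = sites[sites["gene"].isin(["G013", "G014", "G015"])]
        assert (zero["alt_count"] / zero["depth"].clip(lower=1) < 0.05).all()

    def test_zero_expression_zero_counts(self, cfg, truth):
        t = truth
        t.genes.loc[t.genes["gene"] == "G020", "expression"] = 0.0
        genes, sites = simulate_rna(cfg, t)
        assert (genes[genes["gene"] == "G020"]["reads"] == 0).all()
        assert (sites[sites["gene"] == "G020"]["depth"] == 0).all()

    def test_unexpressed_gene_with_fraction_warns(self, cfg):
        t = build_truth(cfg)
        t.genes.loc[t.genes["gene"] == "G001", "expression"] = 0.0
        with pytest.warns(UserWarning):
            simulate_rna(cfg, t)

    def test_fraction_recovered_at_high_depth(self):
        """Planted fraction 0.45 at ~1e4 site reads -> observed +- 0.015."""
        cfg = default_config(seed=12, rna_site_depth=500.0)
        truth = build_truth(cfg)
        _, sites = simulate_rna(cfg, truth)
        g1 = sites[(sites["gene"] == "G001") & (sites["sample"] == "Met2")]
        obs = (g1["alt_count"] / g1["depth"]).iloc[0]
        assert g1["depth"].iloc[0] >= 5000
        assert abs(obs - 0.45) < 0.015


class TestPerturbation:
    def test_no_effect_centers_dce_at_zero(self):
        cfg = default_config(seed=3, effect_size=1.0)
        m = simulate_perturbation_matrix(cfg)
        dce = (np.log2(m["mt_1h"]) - np.log2(m["mt_0h"])) - (
            np.log2(m["wt_1h"]) - np.log2(m["wt_0h"])
        )
        assert abs(dce.mean()) < 0.05

    def test_fourfold_shift_gives_dce_two(self):
        cfg = default_config(seed=3)
        m = simulate_perturbation_matrix(cfg)
        dce = (np.log2(m["mt_1h"]) - np.log2(m["mt_0h"])) - (
            np.log2(m["wt_1h"]) - np.log2(m["wt_0h"])
        )
        resp = dce[cfg.responsive_genes]
        assert abs(resp.mean() - 2.0) < 0.2

    def test_nonresponsive_dce_unbiased_at_5000_genes(self):
        cfg = default_config(seed=4, n_perturb_genes=5000)
        m = simulate_perturbation_matrix(cfg)
        dce = (np.log2(m["mt_2h"]) - np.log2(m["mt_0h"])) - (
            np.log2(m["wt_2h"]) - np.log2(m["wt_0h"])
        )
        others = dce.drop(cfg.responsive_genes)
        assert abs(others.mean()) < 0.05

    def test_strictly_positive(self):
        m = simulate_perturbation_matrix(default_config(seed=3))
        assert (m > 0).all().all()

    def test_bad_effect_size_raises(self):
        with pytest.raises(ValueError):
            simulate_perturbation_matrix(default_config(seed=3, effect_size=0.0))
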