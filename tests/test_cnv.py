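import numpy as np
import pandas as pd
import pytest

from oncotrace.cnv import (
    CopySegment,
    call_loh_and_events,
    cbs_segment,
    detect_focal_deletion,
    lesser_allele_fraction,
    segment_ratios,
    windowed_log_ratio,
)
from oncotrace.simulate import (
    Sample,
    default_config,
    deletion_target_gene,
    simulate_base_coverage,
    simulate_coverage,
    simulate_het_sites,
    DELETION_START,
    DELETION_END,
)


def _cov(values, chrom="chr1", window=1000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(len(values)) * window,
            "end": (np.arange(len(values)) + 1) * window,
            "coverage": values,
        }
    )


class TestWindowedLogRatio:
    def test_equal_coverage_gives_zero(self):
        t = _cov([100.0] * 50)
        out = windowed_log_ratio(t, t.copy())
        assert np.allclose(out["ratio"], 0.0)

    def test_doubled_window_near_one(self):
        base = [100.0] * 100
        tumor = base.copy()
        tumor[10] = 200.0
        out = windowed_log_ratio(_cov(tumor), _cov(base))
        assert out.loc[10, "ratio"] == pytest.approx(1.0, abs=0.02)

    def test_low_normal_coverage_masked(self):
        t = _cov([100.0] * 10)
        n = _cov([100.0] * 9 + [5.0])
        out = windowed_log_ratio(t, n, min_normal_cov=10)
        assert np.isnan(out.loc[9, "ratio"])
        assert np.isfinite(out.loc[:8, "ratio"]).all()

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            windowed_log_ratio(_cov([1.0] * 10), _cov([1.0] * 9))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            windowed_log_ratio(_cov([0.0] * 10), _cov([1.0] * 10))

    def test_cn4_region_mean_ratio_from_config(self):
        """Mean ratio over a planted CN-4 region matches the value computed
        by hand from the generator config (including the genome-average
        normalization that total-count scaling implies)."""
        from oncotrace.simulate import PloidyRegion

        cfg = default_config(
            seed=5,
            baseline_cn=(2, 1),
            ploidy_profile=[PloidyRegion("chr1", 0, 2_000_000, 4, 2)],
            chromothripsis_region=None,
            focal_deletion=None,
            samples=[
                Sample("NORM", "normal", "g", 0.0),
                Sample("Met2", "tumor", "a", 1.0),
            ],
            n_background_sites=10,
        )
        cov = simulate_coverage(cfg)
        t = cov[cov["sample"] == "Met2"].reset_index(drop=True)
        n = cov[cov["sample"] == "NORM"].reset_index(drop=True)
        out = windowed_log_ratio(t, n)
        region = out[(out["chrom"] == "chr1") & (out["end"] <= 2_000_000)]
        genome_bp = sum(l for _, l in cfg.genome)
        avg_content = (2_000_000 * 4 + (genome_bp - 2_000_000) * 2) / genome_bp
        expected = np.log2(4 / avg_content)
        assert region["ratio"].mean() == pytest.approx(expected, abs=0.05)
        assert region["ratio"].mean() == pytest.approx(1.0, abs=0.05)


class TestCBS:
    def test_constant_series_no_breakpoints(self):
        assert cbs_segment([1.0] * 50) == []

    def test_noiseless_step_found_exactly(self):
        x = [0.0] * 20 + [5.0] * 20
        assert cbs_segment(x, seed=1) == [20]

    def test_breaks_strictly_increasing_within_range(self):
        rng = np.random.default_rng(2)
        x = np.concatenate(
            [rng.normal(m, 0.2, 25) for m in (0.0, 1.0, 0.0, -1.0)]
        )
        breaks = cbs_segment(x, seed=2)
        assert breaks == sorted(set(breaks))
        assert all(0 < b < len(x) for b in breaks)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            cbs_segment([1.0, np.nan, 2.0])

    def test_short_series_no_breaks(self):
        assert cbs_segment([1.0]) == []
        assert cbs_segment([]) == []

    def test_noisy_three_segment_recovery(self):
        """Steps of 0.6 at sigma 0.2: both breakpoints within +-2 windows."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            x = np.concatenate(
                [
                    rng.normal(0.0, 0.2, 20),
                    rng.normal(0.6, 0.2, 20),
                    rng.normal(1.2, 0.2, 20),
                ]
            )
            breaks = cbs_segment(x, n_perm=200, seed=rep)
            ok = all(
                any(abs(b - t) <= 2 for b in breaks) for t in (20, 40)
            )
            hits += ok
        assert hits >= 9


class TestLAF:
    def _hets(self, counts, chrom="chr1"):
        return pd.DataFrame(
            [
                {"chrom": chrom, "pos": 100 * i + 1, "a_count": a, "b_count": b}
                for i, (a, b) in enumerate(counts)
            ]
        )

    def _seg(self, start=0, end=10_000, ratio=0.0):
        return CopySegment("chr1", start, end, ratio, 10)

    def test_balanced_site(self):
        seg = self._seg()
        lesser_allele_fraction(self._hets([(50, 50)]), [seg])
        assert seg.laf == pytest.approx(0.5)

    def test_three_to_one(self):
        seg = self._seg()
        lesser_allele_fraction(self._hets([(75, 25), (25, 75)]), [seg])
        assert seg.laf == pytest.approx(0.25)

    def test_total_loss_goes_to_zero(self):
        seg = self._seg()
        lesser_allele_fraction(self._hets([(100, 0)]), [seg])
        assert seg.laf == pytest.approx(0.0)

    def test_zero_depth_site_skipped(self):
        seg = self._seg()
        lesser_allele_fraction(self._hets([(0, 0), (50, 50)]), [seg])
        assert seg.laf == pytest.approx(0.5)

    def test_no_sites_leaves_none(self):
        seg = self._seg(start=90_000, end=99_000)
        lesser_allele_fraction(self._hets([(50, 50)]), [seg])
        assert seg.laf is None

    def test_laf_bounded(self):
        rng = np.random.default_rng(3)
        counts = [(int(a), int(b)) for a, b in rng.integers(0, 500, (200, 2))]
        seg = self._seg(end=100_000)
        lesser_allele_fraction(self._hets(counts), [seg])
        assert 0.0 <= seg.laf <= 0.5


class TestFlags:
    def test_copy_neutral_loh(self):
        seg = CopySegment("chr1", 0, 1000, 0.0, 1, laf=0.02)
        call_loh_and_events([seg])
        assert seg.flags == {"LOH"}

    def test_gain_without_loh(self):
        seg = CopySegment("chr1", 0, 1000, 0.9, 1, laf=0.45)
        call_loh_and_events([seg])
        assert seg.flags == {"gain"}

    def test_loss(self):
        seg = CopySegment("chr1", 0, 1000, -0.8, 1, laf=0.3)
        call_loh_and_events([seg])
        assert seg.flags == {"loss"}


class TestSelfComparison:
    def test_identity_no_signal(self, coverage):
        n = coverage[coverage["sample"] == "NORM"].reset_index(drop=True)
        out = windowed_log_ratio(n, n.copy())
        assert np.allclose(out["ratio"].dropna(), 0.0)
        segs = segment_ratios(out, n_perm=100, seed=0)
        per_chrom = {}
        for s in segs:
            per_chrom.setdefault(s.chrom, []).append(s)
        assert all(len(v) == 1 for v in per_chrom.values())
        call_loh_and_events(segs)
        assert all(not s.flags or s.flags == set() for s in segs)


class TestPurityMonotonicity:
    def test_ratio_and_laf_move_with_purity(self):
        """Lower purity pulls the gain region's ratio toward 0 and its LAF
        toward 0.5 (three purity levels, window/site means as proxies)."""
        ratios, lafs = [], []
        for purity in (1.0, 0.7, 0.4):
            cfg = default_config(
                seed=8,
                samples=[
                    Sample("NORM", "normal", "g", 0.0),
                    Sample("Met2", "tumor", "a", purity),
                ],
                chromothripsis_region=None,
                focal_deletion=None,
                n_background_sites=10,
            )
            cov = simulate_coverage(cfg)
            t = cov[cov["sample"] == "Met2"].reset_index(drop=True)
            n = cov[cov["sample"] == "NORM"].reset_index(drop=True)
            out = windowed_log_ratio(t, n)
            gain = out[(out["chrom"] == "chr2") & (out["start"] >= 2_500_000)]
            ratios.append(gain["ratio"].mean())
            hets = simulate_het_sites(cfg)
            sub = hets[(hets["chrom"] == "chr2") & (hets["pos"] < 2_500_000)]
            laf = np.minimum(sub["a_count"], sub["b_count"]) / (
                sub["a_count"] + sub["b_count"]
            )
            lafs.append(laf.mean())
        assert ratios[0] > ratios[1] > ratios[2] > 0
        assert lafs[0] < lafs[1] < lafs[2] < 0.5


FINE_REGION = (76_880_000, 76_960_000)


class TestFocalDeletion:
    def test_planted_deletion_recovered(self, cfg):
        start, end = FINE_REGION
        bc = simulate_base_coverage(cfg, "chrX", start, end, ["Met2", "NORM"])
        call = detect_focal_deletion(
            bc["Met2"], bc["NORM"], start, deletion_target_gene(),
            n_perm=300, seed=5,
        )
        assert call is not None
        assert abs(call.start - DELETION_START) <= 5
        assert abs(call.end - DELETION_END) <= 5
        assert call.exons == [10, 11, 12]
        assert round(call.length / 1000) == 16

    def test_flat_region_no_call(self, cfg):
        start, end = 10_000, 60_000
        bc = simulate_base_coverage(cfg, "chr1", start, end, ["Met2", "NORM"])
        call = detect_focal_deletion(
            bc["Met2"], bc["NORM"], start, deletion_target_gene(),
            n_perm=200, seed=5,
        )
        assert call is None

    def test_region_too_short_raises(self, cfg):
        with pytest.raises(ValueError):
            detect_focal_deletion(
                np.ones(100), np.ones(100), 0, deletion_target_gene()
            )

    def test_breakpoint_localization_replicates(self):
        """Breakpoints within +-1 fine window across seeded replicates."""
        start, end = FINE_REGION
        gene = deletion_target_gene()
        ok = 0
        reps = 10
        for rep in range(reps):
            cfg = default_config(seed=200 + rep, n_background_sites=10)
            bc = simulate_base_coverage(cfg, "chrX", start, end, ["Met2", "NORM"])
            call = detect_focal_deletion(
                bc["Met2"], bc["NORM"], start, gene, n_perm=150, seed=rep
            )
            if call is None:
                continue
            if (
                abs(call.start - DELETION_START) <= 200
                and abs(call.end - DELETION_END) <= 200
            ):
                ok += 1
        assert ok == reps
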