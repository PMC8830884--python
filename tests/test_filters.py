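"""Site, sample and auxiliary filters: thresholds, exact tests, presets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dnmkit as dk
from dnmkit.filters import (
    DepthStats,
    binomial_two_sided_p,
    config_from_dict,
    poisson_two_sided_p,
)

from conftest import make_call, make_record


# ---------------------------------------------------------------------------
# independent oracles: brute-force tail sums of the mass functions
# ---------------------------------------------------------------------------

def brute_binom_two_sided(k, n, p=0.5):
    pmf = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    return min(1.0, 2.0 * min(lower, upper))


def brute_poisson_two_sided(k, lam, tail=400):
    pmf = [math.exp(-lam)]
    for i in range(1, tail):
        pmf.append(pmf[-1] * lam / i)
    lower = sum(pmf[: k + 1])
    upper = 1.0 - sum(pmf[:k])
    return min(1.0, 2.0 * min(lower, upper))


class TestExactTests:
    def test_binomial_matches_brute_force_all_small_n(self):
        for n in range(1, 31):
            for k in range(n + 1):
                assert binomial_two_sided_p(k, n) == pytest.approx(
                    brute_binom_two_sided(k, n), abs=1e-12
                )

    def test_poisson_matches_brute_force_all_small_n(self):
        for lam in (0.5, 3.0, 10.0, 25.0):
            for k in range(31):
                assert poisson_two_sided_p(k, lam) == pytest.approx(
                    brute_poisson_two_sided(k, lam), rel=1e-9
                )

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 60), st.integers(0, 60))
    def test_binomial_symmetry(self, a, b):
        """ad = (a, b) and ad = (b, a) give identical p-values."""
        n = a + b
        if n == 0:
            return
        assert binomial_two_sided_p(a, n) == pytest.approx(
            binomial_two_sided_p(b, n), abs=1e-12
        )


# ---------------------------------------------------------------------------
# site filter
# ---------------------------------------------------------------------------

class TestSiteFilter:
    def test_qd_below_threshold_fails(self):
        rec = make_record(annotations=dk.SiteAnnotations(qd=1.5, mq=60.0))
        verdict = dk.site_filter(rec, dk.load_preset("gatk_default"))
        assert not verdict.passed
        (reason,) = verdict.reasons
        assert (reason.filter_name, reason.observed, reason.threshold) == (
            "QD", 1.5, 2.0,
        )

    def test_values_exactly_at_threshold_pass(self):
        rec = make_record(annotations=dk.SiteAnnotations(
            qd=2.0, mq=40.0, fs=60.0, sor=3.0,
            mq_rank_sum=-12.5, read_pos_rank_sum=-8.0,
        ))
        assert dk.site_filter(rec, dk.load_preset("gatk_default")).passed

    def test_missing_annotation_goes_to_not_evaluable(self):
        rec = make_record(annotations=dk.SiteAnnotations(qd=10.0))
        verdict = dk.site_filter(rec, dk.load_preset("gatk_default"))
        assert verdict.passed
        assert "MQRankSum" in verdict.not_evaluable

    def test_missing_policy_fail(self):
        config = dk.FilterConfig(
            site=dk.SiteFilterConfig(mq_min=40.0),
            missing_policy=(("site", "fail"),),
        )
        rec = make_record(annotations=dk.SiteAnnotations())
        assert not dk.site_filter(rec, config).passed

    def test_rank_sum_window_two_sided(self):
        config = dk.FilterConfig(site=dk.SiteFilterConfig(
            read_pos_rank_sum_window=(-3.0, 3.0)
        ))
        bad = make_record(annotations=dk.SiteAnnotations(read_pos_rank_sum=3.5))
        good = make_record(annotations=dk.SiteAnnotations(read_pos_rank_sum=-3.0))
        assert not dk.site_filter(bad, config).passed
        assert dk.site_filter(good, config).passed


# ---------------------------------------------------------------------------
# depth filter
# ---------------------------------------------------------------------------

class TestDepthFilter:
    def test_absolute_minimum(self):
        config = dk.FilterConfig(depth=dk.DepthFilterConfig(dp_min=10))
        assert not dk.depth_filter(make_call(gt=(0, 1), dp=9), config).passed
        assert dk.depth_filter(make_call(gt=(0, 1), dp=10), config).passed

    def test_relative_individual_maximum(self):
        config = dk.FilterConfig(depth=dk.DepthFilterConfig(
            mode="relative_individual", low_mult=0.5, high_mult=2.0,
        ))
        stats = DepthStats(mean=70.0)
        assert not dk.depth_filter(make_call(gt=(0, 1), dp=150), config, stats).passed
        assert dk.depth_filter(make_call(gt=(0, 1), dp=140), config, stats).passed
        assert not dk.depth_filter(make_call(gt=(0, 1), dp=34), config, stats).passed

    def test_sigma_rule(self):
        config = dk.FilterConfig(depth=dk.DepthFilterConfig(mode="sigma", n_sigma=3.0))
        stats = DepthStats(mean=40.0, sd=6.0)
        assert dk.depth_filter(make_call(gt=(0, 1), dp=58), config, stats).passed
        assert not dk.depth_filter(make_call(gt=(0, 1), dp=59), config, stats).passed

    def test_poisson_mode_against_oracle(self):
        config = dk.FilterConfig(depth=dk.DepthFilterConfig(
            mode="poisson", poisson_p_threshold=2e-4,
        ))
        stats = DepthStats(mean=70.0)
        assert not dk.depth_filter(make_call(gt=(0, 1), dp=140), config, stats).passed
        assert dk.depth_filter(make_call(gt=(0, 1), dp=70), config, stats).passed
        # the decision boundary agrees with the brute-force tail sum
        for dp in (30, 40, 100, 110):
            expected_fail = brute_poisson_two_sided(dp, 70.0) < 2e-4
            verdict = dk.depth_filter(make_call(gt=(0, 1), dp=dp), config, stats)
            assert verdict.passed == (not expected_fail)

    def test_missing_depth_not_evaluable(self):
        config = dk.FilterConfig(depth=dk.DepthFilterConfig(dp_min=10))
        verdict = dk.depth_filter(make_call(gt=(0, 1)), config)
        assert verdict.passed and "DP" in verdict.not_evaluable


# ---------------------------------------------------------------------------
# genotype quality
# ---------------------------------------------------------------------------

class TestGenotypeQuality:
    def test_gq_below_child_threshold(self):
        config = dk.FilterConfig(genotype_quality=dk.GenotypeQualityConfig(
            gq_min_parent=60, gq_min_child=60,
        ))
        assert not dk.genotype_quality_filter(
            make_call(gt=(0, 1), gq=55), "child", config
        ).passed

    def test_gq_at_cap_passes(self):
        config = dk.FilterConfig(genotype_quality=dk.GenotypeQualityConfig(
            gq_min_child=99,
        ))
        assert dk.genotype_quality_filter(
            make_call(gt=(0, 1), gq=99), "child", config
        ).passed

    def test_pl_gap_per_zygosity(self):
        config = dk.FilterConfig(genotype_quality=dk.GenotypeQualityConfig(
            pl_gap_min_hom=100, pl_gap_min_het=200,
        ))
        het = make_call(gt=(0, 1), pl=(120, 0, 800))
        assert not dk.genotype_quality_filter(het, "child", config).passed
        hom = make_call(gt=(0, 0), pl=(0, 120, 800))
        assert dk.genotype_quality_filter(hom, "parent", config).passed

    def test_both_sources_missing(self):
        config = dk.FilterConfig(genotype_quality=dk.GenotypeQualityConfig(
            gq_min_child=20, pl_gap_min_het=100,
        ))
        verdict = dk.genotype_quality_filter(make_call(gt=(0, 1)), "child", config)
        assert verdict.passed and set(verdict.not_evaluable) == {"GQ", "PL_gap"}


# ---------------------------------------------------------------------------
# parent allele / AB / strand
# ---------------------------------------------------------------------------

class TestParentAllele:
    @pytest.mark.parametrize("ad_max,expected", [(0, False), (1, True)])
    def test_alt_read_cap(self, ad_max, expected):
        config = dk.FilterConfig(parent_allele=dk.ParentAlleleConfig(
            parent_ad_max=ad_max,
        ))
        verdict = dk.parent_allele_filter(make_call(gt=(0, 0), ad=(30, 1)), 1, config)
        assert verdict.passed is expected

    def test_lowq_alt_reads(self):
        config = dk.FilterConfig(parent_allele=dk.ParentAlleleConfig(
            lowq_ad_alt_max=1,
        ))
        bad = make_call(gt=(0, 0), ad=(30, 0), lowq_ad_alt=2)
        assert not dk.parent_allele_filter(bad, 1, config).passed


class TestAllelicBalance:
    @pytest.mark.parametrize("ad,expected", [
        ((15, 15), 0.5), ((20, 5), 0.2), ((0, 12), 1.0),
    ])
    def test_fraction(self, ad, expected):
        assert dk.allelic_balance(make_call(gt=(0, 1), ad=ad), 1) == expected

    def test_no_informative_reads(self):
        assert dk.allelic_balance(make_call(gt=(0, 1), ad=(0, 0)), 1) is None

    def test_window_mode(self):
        config = dk.FilterConfig(ab=dk.AbConfig(mode="window", ab_min=0.3, ab_max=0.7))
        assert not dk.ab_filter(make_call(gt=(0, 1), ad=(40, 10)), 1, config).passed
        assert dk.ab_filter(make_call(gt=(0, 1), ad=(35, 15)), 1, config).passed  # exactly 0.3

    def test_binomial_mode_against_oracle(self):
        config = dk.FilterConfig(ab=dk.AbConfig(mode="binomial", p_threshold=0.05))
        assert not dk.ab_filter(make_call(gt=(0, 1), ad=(25, 5)), 1, config).passed
        assert dk.ab_filter(make_call(gt=(0, 1), ad=(16, 14)), 1, config).passed
        assert brute_binom_two_sided(5, 30) < 0.05 < brute_binom_two_sided(14, 30)


class TestStrand:
    def test_one_strand_fails_when_required(self):
        config = dk.FilterConfig(strand=dk.StrandConfig(require_both_strands=True))
        assert not dk.strand_filter(5, 0, config).passed
        assert dk.strand_filter(1, 1, config).passed

    def test_flag_unset_passes(self):
        config = dk.FilterConfig()
        assert dk.strand_filter(5, 0, config).passed

    def test_counts_unavailable(self):
        config = dk.FilterConfig(strand=dk.StrandConfig(require_both_strands=True))
        verdict = dk.strand_filter(None, None, config)
        assert verdict.passed and "strand" in verdict.not_evaluable


# ---------------------------------------------------------------------------
# cluster / exclusion
# ---------------------------------------------------------------------------

class TestClusterFilter:
    def test_four_in_window_all_removed(self):
        config = dk.FilterConfig(cluster=dk.ClusterConfig(
            window_bp=200, max_in_window=4,
        ))
        positions = [("chr1", p) for p in (100, 150, 200, 250)]
        kept, removed = dk.cluster_filter(positions, config)
        assert kept == [] and removed == [0, 1, 2, 3]

    def test_close_pair_removed(self):
        config = dk.FilterConfig(cluster=dk.ClusterConfig(pair_min_distance_bp=10))
        kept, removed = dk.cluster_filter(
            [("chr1", 100), ("chr1", 105), ("chr1", 400)], config
        )
        assert removed == [0, 1] and kept == [2]

    def test_single_candidate_kept(self):
        config = dk.FilterConfig(cluster=dk.ClusterConfig(
            window_bp=200, max_in_window=4, pair_min_distance_bp=10,
        ))
        kept, removed = dk.cluster_filter([("chr1", 100)], config)
        assert kept == [0] and removed == []

    def test_chromosomes_independent(self):
        config = dk.FilterConfig(cluster=dk.ClusterConfig(pair_min_distance_bp=10))
        kept, removed = dk.cluster_filter(
            [("chr1", 100), ("chr2", 105)], config
        )
        assert removed == []


class TestExclusionFilter:
    def test_population_snp(self):
        verdict = dk.exclusion_filter(
            "chr1", 500, 1, population_positions={("chr1", 500)},
        )
        assert not verdict.passed

    def test_mask_hit(self):
        mask = dk.RegionMask([("chr1", 490, 510)], label="LCR")
        assert not dk.exclusion_filter("chr1", 500, 1, masks=[mask]).passed

    def test_clean_candidate_passes(self):
        mask = dk.RegionMask([("chr1", 1000, 2000)], label="LCR")
        verdict = dk.exclusion_filter(
            "chr1", 500, 1,
            other_genotypes={"sib": make_call(gt=(0, 0))},
            population_positions={("chr1", 999)},
            masks=[mask],
        )
        assert verdict.passed

    def test_other_sample_carrier(self):
        verdict = dk.exclusion_filter(
            "chr1", 500, 1, other_genotypes={"sib": make_call(gt=(0, 1))},
        )
        assert not verdict.passed


# ---------------------------------------------------------------------------
# presets and config files
# ---------------------------------------------------------------------------

class TestPresets:
    def test_lb_ab_window(self):
        lb = dk.load_preset("LB")
        assert (lb.ab.mode, lb.ab.ab_min, lb.ab.ab_max) == ("window", 0.3, 0.7)
        assert lb.genotype_quality.gq_min_child == 60
        assert lb.parent_allele.parent_ad_max is None

    def test_rw_absolute_depth(self):
        rw = dk.load_preset("RW")
        assert (rw.depth.dp_min, rw.depth.dp_max) == (20, 80)
        assert rw.strand.require_both_strands
        assert rw.ab.ab_min == 0.35 and rw.ab.ab_max is None

    def test_gatk_site_set(self):
        site = dk.load_preset("gatk_default").site
        assert site.fs_max == 60.0 and site.sor_max == 3.0
        assert site.qd_min == 2.0 and site.mq_min == 40.0

    def test_sb_mixed_depth_bounds(self):
        sb = dk.load_preset("SB")
        assert sb.depth.dp_min == 10 and sb.depth.high_mult == 2.0
        assert sb.parent_allele.lowq_ad_alt_max == 1

    def test_unknown_preset_lists_available(self):
        with pytest.raises(dk.ConfigurationError, match="LB"):
            dk.load_preset("nope")

    def test_config_override_semantics(self):
        config = config_from_dict({
            "preset": "LB",
            "ab": {"ab_min": 0.2},
            "name": "LB_loose_ab",
        })
        assert config.ab.ab_min == 0.2
        assert config.ab.ab_max == 0.7  # untouched preset value
        assert config.genotype_quality.gq_min_child == 60

    def test_unknown_config_key_rejected(self):
        with pytest.raises(dk.ConfigurationError, match="unknown config keys"):
            config_from_dict({"depht": {}})

    def test_yaml_file_loading(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "preset: RW\ndepth:\n  dp_min: 25\nab:\n  ab_min: 0.4\n"
        )
        config = dk.load_config(str(path))
        assert config.depth.dp_min == 25 and config.depth.dp_max == 80
        assert config.ab.ab_min == 0.4
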