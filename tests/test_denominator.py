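"""Callable genome and false-negative-rate estimators."""

import math

import numpy as np
import pytest
from scipy import stats

import dnmkit as dk
from dnmkit.denominator import DenominatorError, fnr_ab_closed_form

from conftest import make_call, make_record


def _dp_gq_config(dp_min=10, dp_max=80, gq_min=20):
    return dk.FilterConfig(
        depth=dk.DepthFilterConfig(dp_min=dp_min, dp_max=dp_max),
        genotype_quality=dk.GenotypeQualityConfig(
            gq_min_parent=gq_min, gq_min_child=gq_min,
        ),
    )


class TestCallableCount:
    def test_hand_counted_toy_table(self, trio):
        """5 sites; exactly 3 satisfy DP in [10, 80] and GQ >= 20 for all
        members with both parents homref."""
        rows = [
            make_record(pos=1, c=(0, 0), dp=30, gq=50),        # callable
            make_record(pos=2, c=(0, 0), dp=9, gq=50),         # DP too low
            make_record(pos=3, c=(0, 0), dp=30, gq=50),        # callable
            make_record(pos=4, c=(0, 0), dp=30, gq=10),        # GQ too low
            make_record(pos=5, c=(0, 0), dp=80, gq=20),        # callable (bounds)
        ]
        result = dk.callable_genome_count(rows, trio, _dp_gq_config())
        assert result.cg_sites == 3
        assert result.method == "count_based"

    def test_non_homref_parents_never_callable(self, trio):
        rows = [make_record(pos=1, f=(0, 1), c=(0, 0), dp=30, gq=99)]
        result = dk.callable_genome_count(rows, trio, _dp_gq_config())
        assert result.cg_sites == 0

    def test_all_pass(self, trio):
        rows = [make_record(pos=p, c=(0, 0)) for p in range(1, 8)]
        result = dk.callable_genome_count(rows, trio, _dp_gq_config())
        assert result.cg_sites == result.total_sites == 7

    def test_empty_input_raises(self, trio):
        with pytest.raises(DenominatorError, match="BP-resolution"):
            dk.callable_genome_count([], trio, _dp_gq_config())

    def test_table_path_agrees_with_record_path(self, sim_moderate):
        """The vectorised table count matches a per-record recount on the
        same depth/GQ data."""
        config = _dp_gq_config(dp_min=20, dp_max=70, gq_min=40)
        table = sim_moderate.callable_table
        result = dk.callable_genome_count(table, sim_moderate.trio, config)
        manual = int((
            table.parents_called_homref
            & (table.dp >= 20).all(axis=1)
            & (table.dp <= 70).all(axis=1)
            & (table.gq >= 40).all(axis=1)
        ).sum())
        assert result.cg_sites == manual

    def test_stricter_thresholds_never_increase_cg(self, sim_moderate):
        table = sim_moderate.callable_table
        loose = dk.callable_genome_count(
            table, sim_moderate.trio, _dp_gq_config(10, 100, 20))
        strict = dk.callable_genome_count(
            table, sim_moderate.trio, _dp_gq_config(20, 60, 60))
        assert strict.cg_sites <= loose.cg_sites


class TestCallableProbabilistic:
    def _inherited(self, n, dp, gq, n_fail_gq=0):
        recs = []
        for i in range(n):
            recs.append(make_record(
                pos=10 + i, f=(0, 0), m=(1, 1), c=(0, 1),
                dp=dp, gq=(5 if i < n_fail_gq else gq),
            ))
        return recs

    def test_pass_probability_one_gives_genome_length(self, trio):
        recs = self._inherited(20, dp=30, gq=99)
        profile = np.full(1234, 30)
        result = dk.callable_genome_probabilistic(
            recs, profile, trio, dk.FilterConfig())
        assert result.cg_sites == 1234

    def test_uniform_pass_probability(self, trio):
        # 8 of 10 inherited variants pass the GQ filter -> 0.8 over 1000 sites
        recs = self._inherited(10, dp=30, gq=99, n_fail_gq=2)
        config = _dp_gq_config(gq_min=20)
        profile = np.full(1000, 30)
        result = dk.callable_genome_probabilistic(recs, profile, trio, config)
        assert result.cg_sites == pytest.approx(800.0)
        assert result.n_basis == 10

    def test_empty_bin_borrows_nearest(self, trio):
        recs = self._inherited(10, dp=30, gq=99)
        profile = np.full(100, 75)  # no inherited variant near depth 75
        result = dk.callable_genome_probabilistic(
            recs, profile, trio, dk.FilterConfig())
        assert result.cg_sites == 100
        assert result.flags

    def test_self_profile_reproduces_direct_pass_count(self, sim_moderate, lb_preset):
        """Applying the pass table to its own depth profile returns exactly
        the number of inherited variants that pass the filters directly."""
        from dnmkit.filters import ab_filter, depth_filter, genotype_quality_filter

        trio = sim_moderate.trio
        stats_ = sim_moderate.depth_stats
        inherited = sim_moderate.inherited_het_records()
        assert len(inherited) > 100
        dps = np.array([
            min(r.call(m).dp for m in trio.members) for r in inherited
        ])
        result = dk.callable_genome_probabilistic(
            inherited, dps, trio, lb_preset, depth_stats=stats_,
        )
        direct = 0
        for rec in inherited:
            ok = all(
                depth_filter(rec.call(m), lb_preset, stats_[m])
                and genotype_quality_filter(rec.call(m), role, lb_preset)
                for m, role in zip(trio.members, ("parent", "parent", "child"))
            )
            if ok:
                child = rec.call(trio.child)
                others = [a for a in child.alleles if a != 1]
                ok = bool(ab_filter(child, 1, lb_preset, others[0] if others else 0))
            direct += ok
        assert result.cg_sites == pytest.approx(direct)


class TestFnrSpikeIn:
    def test_error_free_permissive_recovers_everything(self):
        config = dk.SimulationConfig(genome_length=30_000, mu_true=0.0,
                                     sequencing_error=0.0)
        sim = dk.simulate_trio(config, 2)
        spiked = dk.inject_spikes(sim, 300, 3)
        est = dk.fnr_spike_in(spiked, dk.FilterConfig())
        assert est.value == 0.0
        assert est.n_basis == 300

    def test_ab_window_loss_matches_closed_form(self):
        """With only a (0.4, 0.6) AB window at mean depth 20 and no errors,
        spike-in FNR equals the binomial mass outside the window, averaged
        over the Poisson depth mixture."""
        config = dk.SimulationConfig(genome_length=60_000, mu_true=0.0,
                                     sequencing_error=0.0, mean_depth=20.0)
        sim = dk.simulate_trio(config, 17)
        spiked = dk.inject_spikes(sim, 800, 18)
        filt = dk.FilterConfig(ab=dk.AbConfig(mode="window", ab_min=0.4, ab_max=0.6))
        est = dk.fnr_spike_in(spiked, filt)
        expected = 0.0
        for d, w in enumerate(stats.poisson.pmf(np.arange(120), 20.0)):
            if d == 0:
                expected += w
                continue
            ks = np.arange(d + 1)
            mass = stats.binom.pmf(ks, d, 0.5)
            expected += w * mass[(ks / d < 0.4) | (ks / d > 0.6)].sum()
        se = math.sqrt(expected * (1 - expected) / 800)
        assert abs(est.value - expected) <= 3.5 * se

    def test_no_spikes_raises(self, sim_moderate):
        with pytest.raises(DenominatorError, match="no spiked"):
            dk.fnr_spike_in(sim_moderate, dk.FilterConfig())


class TestFnrAb:
    def test_arithmetic(self):
        calls = [make_call(gt=(0, 1), ad=(10, 10)) for _ in range(842)]
        calls += [make_call(gt=(0, 1), ad=(19, 1)) for _ in range(158)]
        config = dk.FilterConfig(ab=dk.AbConfig(ab_min=0.3, ab_max=0.7))
        est = dk.fnr_ab(calls, config)
        assert est.value == pytest.approx(0.158)

    def test_vacuous_window(self):
        calls = [make_call(gt=(0, 1), ad=(3, 17))]
        config = dk.FilterConfig(ab=dk.AbConfig(ab_min=0.0, ab_max=1.0))
        assert dk.fnr_ab(calls, config).value == 0.0

    def test_no_evaluable_sites_raises(self):
        config = dk.FilterConfig(ab=dk.AbConfig(ab_min=0.3, ab_max=0.7))
        with pytest.raises(DenominatorError):
            dk.fnr_ab([make_call(gt=(0, 1))], config)

    def test_closed_form_helper(self):
        config = dk.FilterConfig(ab=dk.AbConfig(ab_min=0.4, ab_max=0.6))
        est = fnr_ab_closed_form(20, config)
        # outside = k <= 7 or k >= 13 for Bin(20, 1/2)
        expected = stats.binom.cdf(7, 20, 0.5) + stats.binom.sf(12, 20, 0.5)
        assert est.value == pytest.approx(expected)


class TestFnrSiteProportion:
    def test_counts_failures(self, lb_preset):
        good = dk.SiteAnnotations(qd=20.0, mq=60.0, fs=1.0, sor=1.0,
                                  mq_rank_sum=0.0, read_pos_rank_sum=0.0)
        bad = dk.SiteAnnotations(qd=1.0, mq=60.0, fs=1.0, sor=1.0)
        recs = [make_record(pos=i + 1, annotations=good) for i in range(39)]
        recs.append(make_record(pos=40, annotations=bad))
        est = dk.fnr_site_filter_proportion(recs, lb_preset)
        assert est.value == pytest.approx(1 / 40)

    def test_tightening_never_decreases(self, sim_moderate):
        trusted = sim_moderate.inherited_het_records()
        loose = dk.FilterConfig(site=dk.SiteFilterConfig(fs_max=60.0))
        tight = dk.FilterConfig(site=dk.SiteFilterConfig(fs_max=2.0))
        assert (dk.fnr_site_filter_proportion(trusted, tight).value
                >= dk.fnr_site_filter_proportion(trusted, loose).value)

    def test_empty_set_raises(self, lb_preset):
        with pytest.raises(DenominatorError):
            dk.fnr_site_filter_proportion([], lb_preset)


class TestCombineFnr:
    def test_complement_product(self):
        a = dk.FnrEstimate(0.05, "ab_empirical")
        b = dk.FnrEstimate(0.10, "site_filter_proportion")
        assert dk.combine_fnr([a, b]).value == pytest.approx(0.145)

    def test_single_passthrough(self):
        a = dk.FnrEstimate(0.08, "spike_in")
        assert dk.combine_fnr([a], mode="single") is a

    def test_absorbing_one(self):
        a = dk.FnrEstimate(1.0, "ab_empirical")
        b = dk.FnrEstimate(0.2, "site_filter_proportion")
        assert dk.combine_fnr([a, b]).value == 1.0
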