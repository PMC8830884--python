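"""Callable-genome and false-negative-rate estimation.

The denominator of a per-generation mutation rate has two parts: the
callable genome CG (sites where a DNM would have been detected had it
occurred) and the false-negative rate FNR (the fraction of true DNMs the
filter stack would remove even at callable sites).  Three complementary FNR
estimators are provided: full-pipeline spike-in recovery, the allelic-balance
tail of true heterozygous sites, and the proportion of trusted variants
removed by site-level filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .filters import FilterConfig, DepthStats, ab_filter, site_filter
from .model import SampleCall, Trio, TrioSiteRecord
from .pipeline import run_pipeline
from .simulate import CallableTable, SimulatedTrio


@dataclass
class CallableResult:
    """Number of callable sites and how it was obtained."""

    cg_sites: float
    method: str  # count_based | probabilistic
    total_sites: int
    per_chrom: dict[str, float] = field(default_factory=dict)
    filters: Optional[FilterConfig] = None
    n_basis: int = 0  # inherited variants behind a probabilistic estimate
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.cg_sites < 0:
            raise ValueError("cg_sites must be non-negative")


@dataclass
class FnrEstimate:
    value: float
    method: str  # spike_in | ab_closed_form | ab_empirical | site_filter_proportion | combined
    n_basis: int = 0

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"FNR must lie in [0,1], got {self.value}")


class DenominatorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# callable genome
# ---------------------------------------------------------------------------

def _call_passes_depth_gq(
    call: SampleCall,
    role: str,
    config: FilterConfig,
    ind_stats: Optional[DepthStats],
    trio_stats: Optional[DepthStats],
) -> bool:
    from .filters import depth_filter, genotype_quality_filter

    return bool(
        depth_filter(call, config, ind_stats, trio_stats)
        and genotype_quality_filter(call, role, config)
    )


def callable_genome_count(
    per_site_calls: Union[CallableTable, Iterable[TrioSiteRecord]],
    trio: Trio,
    config: FilterConfig,
    depth_stats: Optional[dict[str, DepthStats]] = None,
) -> CallableResult:
    """Count sites where a DNM would have been detected (count-based CG).

    A site is callable when both parents are confidently homozygous for the
    reference allele and every trio member passes the configured depth and
    genotype-quality filters.  The input must cover non-variant sites
    (BP-resolution records or a per-site depth/GQ table).
    """
    if isinstance(per_site_calls, CallableTable):
        return _callable_from_table(per_site_calls, trio, config, depth_stats)

    records = iter(per_site_calls)
    trio_stats = None
    if depth_stats is not None:
        means = [depth_stats[i].mean for i in trio.members]
        trio_stats = DepthStats(mean=sum(means) / 3.0)
    total = 0
    per_chrom: dict[str, float] = {}
    cg = 0
    saw_nonvariant = False
    for rec in records:
        total += 1
        if not rec.alt_alleles or rec.alt_alleles == ("<NON_REF>",):
            saw_nonvariant = True
        father, mother = rec.call(trio.father), rec.call(trio.mother)
        if not (father.is_hom(0) and mother.is_hom(0)):
            continue
        ok = True
        for member, role in ((trio.father, "parent"), (trio.mother, "parent"),
                             (trio.child, "child")):
            ind = depth_stats.get(member) if depth_stats else None
            if not _call_passes_depth_gq(rec.call(member), role, config, ind, trio_stats):
                ok = False
                break
        if ok:
            cg += 1
            per_chrom[rec.chrom] = per_chrom.get(rec.chrom, 0) + 1
    if total == 0:
        raise DenominatorError(
            "no per-site records supplied; callable-genome counting needs "
            "BP-resolution input covering non-variant sites"
        )
    return CallableResult(
        cg_sites=float(cg), method="count_based", total_sites=total,
        per_chrom=per_chrom, filters=config,
    )


def _callable_from_table(
    table: CallableTable,
    trio: Trio,
    config: FilterConfig,
    depth_stats: Optional[dict[str, DepthStats]],
) -> CallableResult:
    """Vectorised count-based CG over a BP-resolution depth/GQ table."""
    c = config.depth
    g = config.genotype_quality
    dp = table.dp.astype(np.float64)
    ok = table.parents_called_homref.copy()
    members = list(trio.members)
    means = None
    if depth_stats is not None:
        means = np.array([depth_stats[m].mean for m in members])
    elif any(x is not None for x in (c.low_mult, c.high_mult, c.n_sigma,
                                     c.poisson_p_threshold)):
        means = dp.mean(axis=0)
    if c.dp_min is not None:
        ok &= (dp >= c.dp_min).all(axis=1)
    if c.dp_max is not None:
        ok &= (dp <= c.dp_max).all(axis=1)
    if c.low_mult is not None:
        ok &= (dp >= c.low_mult * means[None, :]).all(axis=1)
    if c.high_mult is not None:
        ok &= (dp <= c.high_mult * means[None, :]).all(axis=1)
    if c.n_sigma is not None:
        sds = np.array([
            (depth_stats[m].sd if depth_stats else float(dp[:, j].std()))
            for j, m in enumerate(members)
        ])
        ok &= (np.abs(dp - means[None, :]) <= c.n_sigma * sds[None, :]).all(axis=1)
    if c.poisson_p_threshold is not None:
        from scipy import stats as sps

        lo = np.zeros(3, dtype=np.int64)
        hi = np.zeros(3, dtype=np.int64)
        for j in range(3):
            lam = means[j]
            # precompute the accepted depth interval for the two-sided test
            ks = np.arange(0, int(lam * 4 + 50))
            lower = sps.poisson.cdf(ks, lam)
            upper = sps.poisson.sf(ks - 1, lam)
            p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
            accepted = ks[p >= c.poisson_p_threshold]
            lo[j], hi[j] = accepted.min(), accepted.max()
        ok &= ((table.dp >= lo[None, :]) & (table.dp <= hi[None, :])).all(axis=1)
    for j, role in enumerate(("parent", "parent", "child")):
        bound = g.gq_min(role)
        if bound is not None:
            ok &= table.gq[:, j] >= bound
    cg = int(ok.sum())
    return CallableResult(
        cg_sites=float(cg), method="count_based", total_sites=len(table),
        per_chrom={table.chrom: float(cg)}, filters=config,
    )


def callable_genome_probabilistic(
    inherited_variants: Sequence[TrioSiteRecord],
    depth_profile: np.ndarray,
    trio: Trio,
    config: FilterConfig,
    depth_stats: Optional[dict[str, DepthStats]] = None,
    bin_width: int = 5,
) -> CallableResult:
    """Probabilistic CG: sum per-site DNM-detection probabilities.

    An empirical pass-probability table is built from inherited (transmitted
    heterozygous) variants, binned by the trio's minimum depth, where "pass"
    means the child's call survives the depth, genotype-quality and
    allelic-balance filters and the parents survive depth and GQ.  The table
    is then applied to the genome's per-site trio-minimum-depth profile and
    summed.  Empty bins borrow the nearest populated bin (flagged).
    """
    if len(inherited_variants) == 0:
        raise DenominatorError("no inherited variants to build the pass table from")
    trio_stats = None
    if depth_stats is not None:
        means = [depth_stats[i].mean for i in trio.members]
        trio_stats = DepthStats(mean=sum(means) / 3.0)

    pass_count: dict[int, int] = {}
    total_count: dict[int, int] = {}
    for rec in inherited_variants:
        calls = [rec.call(m) for m in trio.members]
        if any(c.dp is None for c in calls):
            continue
        b = min(c.dp for c in calls) // bin_width
        ok = True
        for member, role, call in zip(trio.members, ("parent", "parent", "child"), calls):
            ind = depth_stats.get(member) if depth_stats else None
            if not _call_passes_depth_gq(call, role, config, ind, trio_stats):
                ok = False
                break
        if ok:
            child = calls[2]
            others = [a for a in (child.alleles or {0, 1}) if a != 1]
            ref_index = others[0] if others else 0
            if not ab_filter(child, 1, config, ref_index):
                ok = False
        total_count[b] = total_count.get(b, 0) + 1
        if ok:
            pass_count[b] = pass_count.get(b, 0) + 1

    bins = sorted(total_count)
    probs = {b: pass_count.get(b, 0) / total_count[b] for b in bins}
    flags = []
    depth_profile = np.asarray(depth_profile)
    profile_bins = depth_profile // bin_width
    cg = 0.0
    bin_arr = np.array(bins)
    for b, n in zip(*np.unique(profile_bins, return_counts=True)):
        if int(b) in probs:
            p = probs[int(b)]
        else:
            nearest = int(bin_arr[np.abs(bin_arr - int(b)).argmin()])
            p = probs[nearest]
            flags.append(f"depth bin {int(b)*bin_width}-{(int(b)+1)*bin_width-1} "
                         f"empty; borrowed bin {nearest*bin_width}")
        cg += p * int(n)
    return CallableResult(
        cg_sites=float(cg), method="probabilistic",
        total_sites=int(len(depth_profile)),
        filters=config, n_basis=sum(total_count.values()), flags=flags,
    )


# ---------------------------------------------------------------------------
# false-negative rate
# ---------------------------------------------------------------------------

def fnr_spike_in(
    spiked: SimulatedTrio,
    config: FilterConfig,
    **pipeline_kwargs,
) -> FnrEstimate:
    """FNR by full-pipeline recovery of injected DNMs.

    Runs the complete filter stack on the spiked record set and reports
    (injected - recovered) / injected over the ``kind="spike"`` entries of
    the truth ledger.
    """
    spikes = [d for d in spiked.truth.dnms if d.kind == "spike"]
    if not spikes:
        raise DenominatorError("truth ledger holds no spiked DNMs")
    result = run_pipeline(
        spiked.records, spiked.trio, config,
        depth_stats=spiked.depth_stats, **pipeline_kwargs,
    )
    recovered_pos = {c.pos for c in result.survivors}
    missed = sum(1 for s in spikes if s.pos not in recovered_pos)
    return FnrEstimate(
        value=missed / len(spikes), method="spike_in", n_basis=len(spikes),
    )


def fnr_ab(
    het_calls: Sequence[SampleCall],
    config: FilterConfig,
    alt_index: int = 1,
) -> FnrEstimate:
    """FNR from the allelic-balance tail of true heterozygous sites.

    ``het_calls`` are offspring calls at sites where heterozygosity is forced
    by the parental genotypes (one parent 0/0, the other 1/1); the estimate
    is the fraction whose allelic balance falls outside the configured AB
    filter, using the same strict-inequality convention as the filter itself.
    """
    evaluable = [c for c in het_calls if c.ad is not None and sum(c.ad[:2]) > 0]
    if not evaluable:
        raise DenominatorError("no evaluable heterozygous calls")
    outside = sum(1 for c in evaluable if not ab_filter(c, alt_index, config))
    return FnrEstimate(
        value=outside / len(evaluable), method="ab_empirical",
        n_basis=len(evaluable),
    )


def fnr_ab_closed_form(depth: int, config: FilterConfig) -> FnrEstimate:
    """Closed-form AB-tail FNR at a fixed depth.

    For window mode this is the Binomial(depth, 1/2) mass strictly outside
    the AB window; for binomial mode, the mass of outcomes whose two-sided
    exact test falls below the threshold.
    """
    from scipy import stats as sps

    from .filters import binomial_two_sided_p

    c = config.ab
    ks = np.arange(depth + 1)
    pmf = sps.binom.pmf(ks, depth, 0.5)
    if c.mode == "window":
        ab = ks / depth
        lo = -np.inf if c.ab_min is None else c.ab_min
        hi = np.inf if c.ab_max is None else c.ab_max
        outside = (ab < lo) | (ab > hi)
    else:
        outside = np.array([
            binomial_two_sided_p(int(k), depth, 0.5) < c.p_threshold for k in ks
        ])
    return FnrEstimate(
        value=float(pmf[outside].sum()), method="ab_closed_form", n_basis=depth,
    )


def fnr_site_filter_proportion(
    trusted_variants: Sequence[TrioSiteRecord], config: FilterConfig
) -> FnrEstimate:
    """FNR contribution of site-level filters: the fraction of a trusted
    variant set (e.g. transmitted heterozygous sites) they remove."""
    if not trusted_variants:
        raise DenominatorError("empty trusted variant set")
    failed = sum(1 for rec in trusted_variants if not site_filter(rec, config))
    return FnrEstimate(
        value=failed / len(trusted_variants),
        method="site_filter_proportion",
        n_basis=len(trusted_variants),
    )


def combine_fnr(
    estimates: Sequence[FnrEstimate], mode: str = "complement_product"
) -> FnrEstimate:
    """Combine independent FNR components.

    ``complement_product`` assumes independent loss mechanisms:
    combined = 1 - prod(1 - FNR_i).  ``single`` passes a lone estimate
    through unchanged.
    """
    if not estimates:
        raise DenominatorError("no estimates to combine")
    if mode == "single":
        if len(estimates) != 1:
            raise DenominatorError("mode='single' needs exactly one estimate")
        return estimates[0]
    if mode != "complement_product":
        raise DenominatorError(f"unknown combination mode {mode!r}")
    value = 1.0
    for e in estimates:
        value *= 1.0 - e.value
    return FnrEstimate(
        value=1.0 - value, method="combined",
        n_basis=sum(e.n_basis for e in estimates),
    )
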