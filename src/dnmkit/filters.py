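"""Site-, sample- and auxiliary-level hard filters for candidate de novo mutations.

Every filter is a pure predicate returning a :class:`FilterVerdict` that
records, for each failed criterion, the observed value and the threshold it
violated, and lists criteria that could not be evaluated because the
underlying annotation was absent.

Conventions
-----------
* All threshold violations are **strict** inequalities in the direction the
  threshold is written (a value exactly equal to its bound passes).  This
  mirrors how published hard-filter sets are stated (``QD < 2.0`` fails,
  ``GQ > 60`` passes).
* A filter whose input is missing never silently passes or fails: it is
  reported as not evaluable, and the configured missing-data policy decides
  whether that counts against the record (default: it does not).
* Two-sided exact test p-values (allelic-balance binomial test, Poisson depth
  test) are twice the smaller tail, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from scipy import stats

from .model import RegionMask, SampleCall, TrioSiteRecord


class ConfigurationError(ValueError):
    """Invalid or unknown filter configuration."""


# ---------------------------------------------------------------------------
# verdicts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FailureReason:
    filter_name: str
    observed: object
    threshold: object

    def __str__(self) -> str:  # compact provenance for TSV output
        return f"{self.filter_name}[{self.observed}|{self.threshold}]"


@dataclass(frozen=True)
class FilterVerdict:
    reasons: tuple[FailureReason, ...] = ()
    not_evaluable: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.reasons

    def __bool__(self) -> bool:
        return self.passed

    @staticmethod
    def merge(*verdicts: "FilterVerdict") -> "FilterVerdict":
        reasons: list[FailureReason] = []
        ne: list[str] = []
        for v in verdicts:
            reasons.extend(v.reasons)
            ne.extend(v.not_evaluable)
        return FilterVerdict(tuple(reasons), tuple(ne))


PASS = FilterVerdict()


def _fail(name: str, observed, threshold) -> FilterVerdict:
    return FilterVerdict((FailureReason(name, observed, threshold),))


def _skip(name: str) -> FilterVerdict:
    return FilterVerdict((), (name,))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

Window = tuple[Optional[float], Optional[float]]


@dataclass(frozen=True)
class SiteFilterConfig:
    """Thresholds on site-level annotations; ``None`` disables a criterion."""

    qual_min: Optional[float] = None
    qd_min: Optional[float] = None
    mq_min: Optional[float] = None
    fs_max: Optional[float] = None
    sor_max: Optional[float] = None
    mq_rank_sum_window: Optional[Window] = None
    read_pos_rank_sum_window: Optional[Window] = None
    base_q_rank_sum_window: Optional[Window] = None


@dataclass(frozen=True)
class DepthFilterConfig:
    """Read-depth filter.

    Any combination of bounds may be active simultaneously; published
    pipelines mix absolute and relative bounds (e.g. an absolute minimum with
    a maximum of twice the individual's mean depth).  ``mode`` labels the
    dominant flavour for reporting only.
    """

    mode: str = "absolute"  # absolute | relative_individual | sigma | relative_trio | poisson
    dp_min: Optional[float] = None
    dp_max: Optional[float] = None
    low_mult: Optional[float] = None
    high_mult: Optional[float] = None
    n_sigma: Optional[float] = None
    poisson_p_threshold: Optional[float] = None
    # remove sites whose two-sided Poisson p-value is *below* the threshold;
    # the opposite direction is available for sensitivity analyses.
    poisson_reject_low: bool = True
    relative_to: str = "individual"  # individual | trio, for mult/sigma bounds

    def __post_init__(self):
        for m in (self.low_mult, self.high_mult):
            if m is not None and m <= 0:
                raise ConfigurationError("depth multipliers must be positive")
        p = self.poisson_p_threshold
        if p is not None and not (0.0 < p < 1.0):
            raise ConfigurationError("poisson_p_threshold must lie in (0,1)")


@dataclass(frozen=True)
class GenotypeQualityConfig:
    """GQ thresholds per pedigree role, or PL-gap thresholds per zygosity."""

    gq_min_parent: Optional[float] = None
    gq_min_child: Optional[float] = None
    pl_gap_min_hom: Optional[float] = None
    pl_gap_min_het: Optional[float] = None

    def gq_min(self, role: str) -> Optional[float]:
        return self.gq_min_child if role == "child" else self.gq_min_parent


@dataclass(frozen=True)
class ParentAlleleConfig:
    parent_ad_max: Optional[int] = None
    lowq_ad_alt_max: Optional[int] = None


@dataclass(frozen=True)
class AbConfig:
    """Allelic-balance filter on the offspring's heterozygous call."""

    mode: str = "window"  # window | binomial
    ab_min: Optional[float] = None
    ab_max: Optional[float] = None
    p_threshold: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("window", "binomial"):
            raise ConfigurationError(f"unknown AB mode {self.mode!r}")
        if self.mode == "binomial":
            p = self.p_threshold
            if p is None or not (0.0 < p < 1.0):
                raise ConfigurationError("binomial AB mode needs p_threshold in (0,1)")
        lo, hi = self.ab_min, self.ab_max
        if lo is not None and hi is not None and lo > hi:
            raise ConfigurationError("ab_min must not exceed ab_max")


@dataclass(frozen=True)
class StrandConfig:
    require_both_strands: bool = False


@dataclass(frozen=True)
class ClusterConfig:
    window_bp: Optional[int] = None
    max_in_window: Optional[int] = None
    pair_min_distance_bp: Optional[int] = None


@dataclass(frozen=True)
class ExclusionConfig:
    use_population_snps: bool = False
    use_other_samples: bool = False
    masks: tuple[str, ...] = ()  # labels of RegionMasks to apply


#: filter families that a missing-data policy can be set for
FILTER_FAMILIES = (
    "site", "depth", "genotype_quality", "parent_allele", "ab", "strand",
)


@dataclass(frozen=True)
class FilterConfig:
    """A fully materialised filter stack.

    ``violation_mode`` selects which Mendelian-violation genotype
    configurations are admitted: ``homref_config`` (both parents 0/0, child
    0/1 — the common restriction), ``all_configs`` (additionally 1/1 x 1/1
    -> 0/1 and 0/0 x 1/1 -> 0/0 or 1/1) or ``allele_absence`` (any child
    allele carried by neither parent, which also admits multi-allelic sites).
    """

    name: str = "custom"
    site: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    depth: DepthFilterConfig = field(default_factory=DepthFilterConfig)
    genotype_quality: GenotypeQualityConfig = field(default_factory=GenotypeQualityConfig)
    parent_allele: ParentAlleleConfig = field(default_factory=ParentAlleleConfig)
    ab: AbConfig = field(default_factory=AbConfig)
    strand: StrandConfig = field(default_factory=StrandConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    violation_mode: str = "homref_config"
    # per-family policy for filters that could not be evaluated: "pass" keeps
    # the record, "fail" removes it.
    missing_policy: tuple[tuple[str, str], ...] = tuple(
        (f, "pass") for f in FILTER_FAMILIES
    )

    def __post_init__(self):
        if self.violation_mode not in ("homref_config", "all_configs", "allele_absence"):
            raise ConfigurationError(f"unknown violation_mode {self.violation_mode!r}")

    def policy(self, family: str) -> str:
        return dict(self.missing_policy).get(family, "pass")


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def binomial_two_sided_p(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value: twice the smaller tail, capped at 1."""
    if n < 0 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return min(1.0, 2.0 * min(lower, upper))


def poisson_two_sided_p(k: int, lam: float) -> float:
    """Two-sided exact Poisson p-value: twice the smaller tail, capped at 1."""
    if k < 0 or lam <= 0:
        raise ValueError("need k >= 0 and lam > 0")
    lower = stats.poisson.cdf(k, lam)
    upper = stats.poisson.sf(k - 1, lam)
    return min(1.0, 2.0 * min(lower, upper))


# ---------------------------------------------------------------------------
# statistics needed by relative depth filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthStats:
    mean: float
    sd: Optional[float] = None


def depth_stats_from_records(
    records: Iterable[TrioSiteRecord], individual_ids: Sequence[str]
) -> dict[str, DepthStats]:
    """Per-individual mean/sd of DP over a record stream (single pass)."""
    n = {i: 0 for i in individual_ids}
    s = {i: 0.0 for i in individual_ids}
    ss = {i: 0.0 for i in individual_ids}
    for rec in records:
        for i in individual_ids:
            dp = rec.call(i).dp
            if dp is not None:
                n[i] += 1
                s[i] += dp
                ss[i] += dp * dp
    out = {}
    for i in individual_ids:
        if n[i] == 0:
            raise ConfigurationError(f"no depth observations for {i!r}")
        mean = s[i] / n[i]
        var = max(0.0, ss[i] / n[i] - mean * mean)
        out[i] = DepthStats(mean=mean, sd=math.sqrt(var))
    return out


# ---------------------------------------------------------------------------
# site filter
# ---------------------------------------------------------------------------

def site_filter(record: TrioSiteRecord, config: FilterConfig) -> FilterVerdict:
    """Apply site-level annotation thresholds to one record.

    A record fails iff any *present* annotation violates its configured
    threshold; absent annotations are reported as not evaluable.
    """
    c = config.site
    a = record.annotations
    checks: list[tuple[str, Optional[float], object, object]] = []

    def low(name: str, value: Optional[float], bound: Optional[float]) -> None:
        if bound is None:
            return
        if value is None:
            checks.append((name, None, None, None))
        elif value < bound:
            checks.append((name, value, value, bound))

    def high(name: str, value: Optional[float], bound: Optional[float]) -> None:
        if bound is None:
            return
        if value is None:
            checks.append((name, None, None, None))
        elif value > bound:
            checks.append((name, value, value, bound))

    def window(name: str, value: Optional[float], win: Optional[Window]) -> None:
        if win is None:
            return
        lo, hi = win
        if value is None:
            checks.append((name, None, None, None))
        elif (lo is not None and value < lo) or (hi is not None and value > hi):
            checks.append((name, value, value, win))

    low("QUAL", a.qual, c.qual_min)
    low("QD", a.qd, c.qd_min)
    low("MQ", a.mq, c.mq_min)
    high("FS", a.fs, c.fs_max)
    high("SOR", a.sor, c.sor_max)
    window("MQRankSum", a.mq_rank_sum, c.mq_rank_sum_window)
    window("ReadPosRankSum", a.read_pos_rank_sum, c.read_pos_rank_sum_window)
    window("BaseQRankSum", a.base_q_rank_sum, c.base_q_rank_sum_window)

    reasons = []
    missing = []
    for name, value, observed, threshold in checks:
        if value is None:
            missing.append(name)
        else:
            reasons.append(FailureReason(name, observed, threshold))
    if config.policy("site") == "fail":
        reasons.extend(FailureReason(m, None, "missing") for m in missing)
        missing = []
    return FilterVerdict(tuple(reasons), tuple(missing))


# ---------------------------------------------------------------------------
# sample filters
# ---------------------------------------------------------------------------

def depth_filter(
    call: SampleCall,
    config: FilterConfig,
    individual_stats: Optional[DepthStats] = None,
    trio_stats: Optional[DepthStats] = None,
) -> FilterVerdict:
    """Depth bounds for one individual's call.

    Relative bounds use the individual's (or trio's) mean depth; the sigma
    rule uses mean +/- n_sigma * sd; the Poisson rule removes calls whose
    two-sided exact Poisson tail under lambda = mean depth is below the
    configured threshold.
    """
    c = config.depth
    dp = call.dp
    if dp is None:
        if config.policy("depth") == "fail":
            return _fail("DP", None, "missing")
        return _skip("DP")

    ref_stats = trio_stats if c.relative_to == "trio" else individual_stats
    needs_stats = any(
        x is not None for x in (c.low_mult, c.high_mult, c.n_sigma, c.poisson_p_threshold)
    )
    if needs_stats and ref_stats is None:
        raise ConfigurationError(
            "relative depth filter configured but no depth statistics supplied"
        )

    verdicts = []
    if c.dp_min is not None and dp < c.dp_min:
        verdicts.append(_fail("DP_min", dp, c.dp_min))
    if c.dp_max is not None and dp > c.dp_max:
        verdicts.append(_fail("DP_max", dp, c.dp_max))
    if c.low_mult is not None and dp < c.low_mult * ref_stats.mean:
        verdicts.append(_fail("DP_low_mult", dp, c.low_mult * ref_stats.mean))
    if c.high_mult is not None and dp > c.high_mult * ref_stats.mean:
        verdicts.append(_fail("DP_high_mult", dp, c.high_mult * ref_stats.mean))
    if c.n_sigma is not None:
        if ref_stats.sd is None:
            verdicts.append(_skip("DP_sigma"))
        elif abs(dp - ref_stats.mean) > c.n_sigma * ref_stats.sd:
            verdicts.append(_fail("DP_sigma", dp, (ref_stats.mean, c.n_sigma * ref_stats.sd)))
    if c.poisson_p_threshold is not None:
        p = poisson_two_sided_p(dp, ref_stats.mean)
        reject = p < c.poisson_p_threshold if c.poisson_reject_low else p > c.poisson_p_threshold
        if reject:
            verdicts.append(_fail("DP_poisson", p, c.poisson_p_threshold))
    return FilterVerdict.merge(*verdicts) if verdicts else PASS


def _pl_gap(pl: Sequence[int]) -> int:
    ordered = sorted(pl)
    return ordered[1] - ordered[0]


def genotype_quality_filter(
    call: SampleCall, role: str, config: FilterConfig
) -> FilterVerdict:
    """Genotype-confidence filter: GQ per role, or PL gap per zygosity.

    GQ is the Phred gap between the two most likely genotypes capped at 99;
    the PL-gap mode uses the uncapped difference and applies a stricter bound
    to heterozygous than to homozygous calls.
    """
    c = config.genotype_quality
    verdicts = []
    evaluated = False
    gq_bound = c.gq_min(role)
    if gq_bound is not None:
        if call.gq is None:
            verdicts.append(_skip("GQ"))
        else:
            evaluated = True
            if call.gq < gq_bound:
                verdicts.append(_fail("GQ", call.gq, gq_bound))
    gap_bound = c.pl_gap_min_het if call.is_het else c.pl_gap_min_hom
    if gap_bound is not None:
        if call.pl is None or len(call.pl) < 2 or call.gt is None:
            verdicts.append(_skip("PL_gap"))
        else:
            evaluated = True
            if _pl_gap(call.pl) < gap_bound:
                verdicts.append(_fail("PL_gap", _pl_gap(call.pl), gap_bound))
    merged = FilterVerdict.merge(*verdicts) if verdicts else PASS
    if (
        merged.not_evaluable
        and not evaluated
        and config.policy("genotype_quality") == "fail"
    ):
        return _fail("genotype_quality", None, "missing")
    return merged


def parent_allele_filter(
    parent_call: SampleCall, alt_index: int, config: FilterConfig
) -> FilterVerdict:
    """Purity of a parent's homozygous call: cap on alt-supporting reads."""
    c = config.parent_allele
    verdicts = []
    if c.parent_ad_max is not None:
        ad = parent_call.ad
        if ad is None or alt_index >= len(ad):
            if config.policy("parent_allele") == "fail":
                verdicts.append(_fail("parent_AD", None, "missing"))
            else:
                verdicts.append(_skip("parent_AD"))
        elif ad[alt_index] > c.parent_ad_max:
            verdicts.append(_fail("parent_AD", ad[alt_index], c.parent_ad_max))
    if c.lowq_ad_alt_max is not None and parent_call.lowq_ad_alt is not None:
        if parent_call.lowq_ad_alt > c.lowq_ad_alt_max:
            verdicts.append(_fail("lowQ_AD", parent_call.lowq_ad_alt, c.lowq_ad_alt_max))
    return FilterVerdict.merge(*verdicts) if verdicts else PASS


def allelic_balance(
    call: SampleCall, alt_index: int, ref_index: int = 0
) -> Optional[float]:
    """Fraction of reads supporting the alternative allele.

    The denominator is the sum of reads supporting the two alleles under
    consideration (reference by default).  Returns ``None`` when AD is absent
    or carries no informative reads.
    """
    ad = call.ad
    if ad is None or alt_index >= len(ad) or ref_index >= len(ad):
        return None
    total = ad[ref_index] + ad[alt_index]
    if total == 0:
        return None
    return ad[alt_index] / total


def ab_filter(
    call: SampleCall, alt_index: int, config: FilterConfig, ref_index: int = 0
) -> FilterVerdict:
    """Allelic-balance filter on a heterozygous call.

    Window mode removes calls outside (ab_min, ab_max); binomial mode removes
    calls whose two-sided exact binomial test against a true allele fraction
    of 0.5 has p-value below the threshold.
    """
    c = config.ab
    ad = call.ad
    if ad is None or alt_index >= len(ad) or ref_index >= len(ad):
        if config.policy("ab") == "fail":
            return _fail("AB", None, "missing")
        return _skip("AB")
    n_alt = ad[alt_index]
    n_total = ad[ref_index] + n_alt
    if n_total == 0:
        if config.policy("ab") == "fail":
            return _fail("AB", None, "no informative reads")
        return _skip("AB")
    if c.mode == "window":
        ab = n_alt / n_total
        if c.ab_min is not None and ab < c.ab_min:
            return _fail("AB_min", round(ab, 6), c.ab_min)
        if c.ab_max is not None and ab > c.ab_max:
            return _fail("AB_max", round(ab, 6), c.ab_max)
        return PASS
    p = binomial_two_sided_p(n_alt, n_total, 0.5)
    if p < c.p_threshold:
        return _fail("AB_binom", p, c.p_threshold)
    return PASS


def strand_filter(
    alt_forward: Optional[int], alt_reverse: Optional[int], config: FilterConfig
) -> FilterVerdict:
    """Require alt-supporting reads on both strands when configured."""
    if not config.strand.require_both_strands:
        return PASS
    if alt_forward is None or alt_reverse is None:
        if config.policy("strand") == "fail":
            return _fail("strand", None, "missing")
        return _skip("strand")
    if alt_forward == 0 or alt_reverse == 0:
        return _fail("strand", (alt_forward, alt_reverse), "alt on both strands")
    return PASS


# ---------------------------------------------------------------------------
# auxiliary filters operating across candidates / resources
# ---------------------------------------------------------------------------

def cluster_filter(
    positions: Sequence[tuple[str, int]], config: FilterConfig
) -> tuple[list[int], list[int]]:
    """Mutation-cluster filter over (chrom, pos) sorted candidates.

    Window rule: every member of any same-chromosome run of at least
    ``max_in_window`` candidates spanning at most ``window_bp`` is removed.
    Pair rule: both members of any same-chromosome pair closer than
    ``pair_min_distance_bp`` are removed.  Both rules are evaluated on the
    original candidate set in a single pass and their removals unioned.

    Returns (kept indices, removed indices) into ``positions``.
    """
    c = config.cluster
    n = len(positions)
    removed = set()
    if c.window_bp is not None and c.max_in_window is not None:
        for i in range(n):
            chrom_i, pos_i = positions[i]
            j = i
            while (
                j + 1 < n
                and positions[j + 1][0] == chrom_i
                and positions[j + 1][1] - pos_i <= c.window_bp
            ):
                j += 1
            if j - i + 1 >= c.max_in_window:
                removed.update(range(i, j + 1))
    if c.pair_min_distance_bp is not None:
        for i in range(n - 1):
            if positions[i][0] != positions[i + 1][0]:
                continue
            if positions[i + 1][1] - positions[i][1] < c.pair_min_distance_bp:
                removed.update((i, i + 1))
    kept = [i for i in range(n) if i not in removed]
    return kept, sorted(removed)


def exclusion_filter(
    chrom: str,
    pos: int,
    mutant_allele_index: int,
    other_genotypes: Optional[dict[str, SampleCall]] = None,
    population_positions: Optional[set[tuple[str, int]]] = None,
    masks: Sequence[RegionMask] = (),
    config: Optional[FilterConfig] = None,
) -> FilterVerdict:
    """Remove candidates seen elsewhere: other samples, known polymorphisms,
    or masked (low-complexity / repeat) regions."""
    use_pop = config is None or config.exclusion.use_population_snps
    use_other = config is None or config.exclusion.use_other_samples
    verdicts = []
    if use_other and other_genotypes:
        carriers = [
            i for i, call in other_genotypes.items()
            if call.gt is not None and mutant_allele_index in call.gt
        ]
        if carriers:
            verdicts.append(_fail("other_samples", carriers, "allele absent elsewhere"))
    if use_pop and population_positions and (chrom, pos) in population_positions:
        verdicts.append(_fail("population_SNP", (chrom, pos), "not a known SNP"))
    for mask in masks:
        if mask.contains(chrom, pos):
            verdicts.append(_fail(f"mask:{mask.label}", (chrom, pos), mask.label))
    return FilterVerdict.merge(*verdicts) if verdicts else PASS


def homopolymer_mask(
    reference: str, chrom: str, min_run: int = 10, bases: str = "AT"
) -> RegionMask:
    """Mask runs of >= ``min_run`` identical A or T bases in a reference
    sequence (0-based, half-open spans of each run)."""
    intervals = []
    i, n = 0, len(reference)
    while i < n:
        b = reference[i].upper()
        j = i + 1
        while j < n and reference[j].upper() == b:
            j += 1
        if b in bases and j - i >= min_run:
            intervals.append((chrom, i, j))
        i = j
    return RegionMask(intervals, label="homopolymer")


# ---------------------------------------------------------------------------
# presets (published pipelines)
# ---------------------------------------------------------------------------

_GATK_SITE = SiteFilterConfig(
    qd_min=2.0,
    mq_min=40.0,
    fs_max=60.0,
    sor_max=3.0,
    mq_rank_sum_window=(-12.5, None),
    read_pos_rank_sum_window=(-8.0, None),
)

_LB_SITE = SiteFilterConfig(
    qd_min=2.0,
    fs_max=20.0,
    mq_min=40.0,
    sor_max=3.0,
    mq_rank_sum_window=(-2.0, 4.0),
    read_pos_rank_sum_window=(-3.0, 3.0),
)

_SB_SITE = SiteFilterConfig(
    fs_max=30.0,
    mq_rank_sum_window=(-10.0, 10.0),
    read_pos_rank_sum_window=(-2.5, 2.5),
    base_q_rank_sum_window=(-13.0, 13.0),
)

_PRESETS: dict[str, FilterConfig] = {
    "gatk_default": FilterConfig(name="gatk_default", site=_GATK_SITE),
    "CV": FilterConfig(
        name="CV",
        site=_GATK_SITE,
        depth=DepthFilterConfig(mode="relative_individual", low_mult=0.5, high_mult=2.0),
        genotype_quality=GenotypeQualityConfig(gq_min_parent=40, gq_min_child=40),
        parent_allele=ParentAlleleConfig(parent_ad_max=0),
        ab=AbConfig(mode="window", ab_min=0.25, ab_max=0.75),
    ),
    "RW": FilterConfig(
        name="RW",
        site=_GATK_SITE,
        depth=DepthFilterConfig(mode="absolute", dp_min=20, dp_max=80),
        genotype_quality=GenotypeQualityConfig(gq_min_parent=20, gq_min_child=20),
        parent_allele=ParentAlleleConfig(parent_ad_max=0),
        ab=AbConfig(mode="window", ab_min=0.35),
        strand=StrandConfig(require_both_strands=True),
    ),
    "TT": FilterConfig(
        name="TT",
        site=SiteFilterConfig(),  # repeat/homopolymer masks instead of annotations
        depth=DepthFilterConfig(mode="absolute", dp_min=10),
        genotype_quality=GenotypeQualityConfig(gq_min_parent=20, gq_min_child=20),
        parent_allele=ParentAlleleConfig(parent_ad_max=0),
        ab=AbConfig(mode="window", ab_min=0.25),
        exclusion=ExclusionConfig(masks=("LCR", "repeat", "homopolymer")),
        violation_mode="allele_absence",
    ),
    "LB": FilterConfig(
        name="LB",
        site=_LB_SITE,
        depth=DepthFilterConfig(mode="relative_individual", low_mult=0.5, high_mult=2.0),
        genotype_quality=GenotypeQualityConfig(gq_min_parent=60, gq_min_child=60),
        ab=AbConfig(mode="window", ab_min=0.3, ab_max=0.7),
    ),
    "SB": FilterConfig(
        name="SB",
        site=_SB_SITE,
        depth=DepthFilterConfig(mode="relative_individual", dp_min=10, high_mult=2.0),
        genotype_quality=GenotypeQualityConfig(gq_min_parent=55, gq_min_child=55),
        parent_allele=ParentAlleleConfig(parent_ad_max=0, lowq_ad_alt_max=1),
        ab=AbConfig(mode="window", ab_min=0.3),
        strand=StrandConfig(require_both_strands=True),
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def load_preset(name: str) -> FilterConfig:
    """Return one of the named published filter stacks, fully materialised."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

def config_from_dict(data: dict) -> FilterConfig:
    """Build a FilterConfig from a nested mapping (YAML layout).

    A top-level ``preset`` key seeds the config; any explicit section then
    overrides the preset's values key by key.
    """
    data = dict(data)
    base = load_preset(data.pop("preset")) if "preset" in data else FilterConfig()
    sections = {
        "site": SiteFilterConfig,
        "depth": DepthFilterConfig,
        "genotype_quality": GenotypeQualityConfig,
        "parent_allele": ParentAlleleConfig,
        "ab": AbConfig,
        "strand": StrandConfig,
        "cluster": ClusterConfig,
        "exclusion": ExclusionConfig,
    }
    updates = {}
    for key, cls in sections.items():
        if key in data:
            section = dict(data.pop(key))
            for k in ("mq_rank_sum_window", "read_pos_rank_sum_window",
                      "base_q_rank_sum_window"):
                if k in section and section[k] is not None:
                    section[k] = tuple(section[k])
            if "masks" in section:
                section["masks"] = tuple(section["masks"])
            current = getattr(base, key)
            updates[key] = replace(current, **section)
    for key in ("name", "violation_mode"):
        if key in data:
            updates[key] = data.pop(key)
    if "missing_policy" in data:
        mp = data.pop("missing_policy")
        updates["missing_policy"] = tuple(sorted(mp.items()))
    if data:
        raise ConfigurationError(f"unknown config keys: {sorted(data)}")
    return replace(base, **updates)


def load_config(path: str) -> FilterConfig:
    """Load a filter configuration from a YAML file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
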