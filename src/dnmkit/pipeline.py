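"""Mendelian-violation detection and the candidate-DNM filter stack.

The stack is applied in a fixed order:

    violation detection -> site filter -> depth (all trio members)
    -> genotype quality (all members) -> parent allele purity (both parents)
    -> allelic balance (child) -> strand -> exclusion resources -> clusters

All per-candidate stages are pure predicates, so their order cannot change
the final candidate set, only which stage gets credited with a removal.  The
cluster rule is evaluated on the pre-filter Mendelian-violation set (its
removals are independent of the other filters' strictness, which keeps the
whole stack monotone in every threshold) and applied last.  Every stage's
in/out counts are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .filters import (
    DepthStats,
    FailureReason,
    FilterConfig,
    FilterVerdict,
    ab_filter,
    cluster_filter,
    depth_filter,
    depth_stats_from_records,
    exclusion_filter,
    genotype_quality_filter,
    parent_allele_filter,
    site_filter,
    strand_filter,
)
from .model import (
    RegionMask,
    SampleCall,
    Trio,
    TrioSiteRecord,
    ValidationOutcome,
)

#: default chromosomes excluded from calling (sex chromosomes / mito)
DEFAULT_EXCLUDED_CHROMS = frozenset(
    {"X", "Y", "chrX", "chrY", "MT", "chrM", "chrMT"}
)

STAGES = (
    "input",
    "mendelian_violation",
    "site_filter",
    "depth",
    "genotype_quality",
    "parent_allele",
    "allelic_balance",
    "strand",
    "exclusion",
    "cluster",
)


@dataclass
class CandidateDNM:
    """A Mendelian violation with full filter provenance."""

    chrom: str
    pos: int
    ref_allele: str
    mutant_allele: str
    child_id: str
    background: str  # homref | homalt | mixed | allele_absence
    mutant_allele_index: int
    child_call: SampleCall
    father_call: SampleCall
    mother_call: SampleCall
    record: Optional[TrioSiteRecord] = None
    verdicts: dict[str, FilterVerdict] = field(default_factory=dict)
    status: str = "candidate"
    validation: str = "untested"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.mutant_allele)

    @property
    def passed(self) -> bool:
        return self.status == "candidate"

    @property
    def genotype_configuration(self) -> str:
        def fmt(call: SampleCall) -> str:
            return "./." if call.gt is None else "/".join(map(str, sorted(call.gt)))

        return (
            f"{fmt(self.father_call)}x{fmt(self.mother_call)}"
            f"->{fmt(self.child_call)}"
        )


@dataclass
class StageAccounting:
    """Ordered (stage, records in, records out) counts."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.rows.append((stage, n_in, n_out))

    def as_dict(self) -> list[dict]:
        return [
            {"stage": s, "in": i, "out": o} for s, i, o in self.rows
        ]


@dataclass
class PipelineResult:
    candidates: list[CandidateDNM]  # every violation, including removed ones
    accounting: StageAccounting
    config: FilterConfig
    n_records: int = 0
    n_skipped_missing_child: int = 0
    n_skipped_indel: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_chrom: int = 0

    @property
    def survivors(self) -> list[CandidateDNM]:
        return [c for c in self.candidates if c.passed]


def _violations_for_record(
    record: TrioSiteRecord, trio: Trio, mode: str
) -> list[CandidateDNM]:
    """Mendelian violations at one site under the configured genotype model."""
    father = record.call(trio.father)
    mother = record.call(trio.mother)
    child = record.call(trio.child)
    if child.gt is None or father.gt is None or mother.gt is None:
        return []
    out: list[CandidateDNM] = []

    def make(allele_index: int, background: str) -> CandidateDNM:
        return CandidateDNM(
            chrom=record.chrom,
            pos=record.pos,
            ref_allele=record.ref_allele,
            mutant_allele=record.alleles[allele_index],
            child_id=trio.child,
            background=background,
            mutant_allele_index=allele_index,
            child_call=child,
            father_call=father,
            mother_call=mother,
            record=record,
        )

    if mode == "allele_absence":
        parental = father.alleles | mother.alleles
        for a in sorted(child.alleles - parental):
            if a == 0:
                bg = "mixed"
            elif father.is_hom(0) and mother.is_hom(0):
                bg = "homref"
            elif father.alleles == mother.alleles and not father.is_het:
                bg = "homalt" if 0 not in father.alleles else "homref"
            else:
                bg = "allele_absence"
            out.append(make(a, bg))
        return out

    # genotype-configuration modes operate on biallelic sites only
    if not record.is_biallelic:
        return []
    f, m, c = father.gt, mother.gt, child.gt
    homref, homalt, het = (0, 0), (1, 1), (0, 1)
    c_sorted = tuple(sorted(c))
    if f == homref and m == homref and c_sorted == het:
        out.append(make(1, "homref"))
    elif mode == "all_configs":
        if f == homalt and m == homalt and c_sorted == het:
            out.append(make(0, "homalt"))
        elif {f, m} == {homref, homalt} and c_sorted in (homref, homalt):
            # the child is homozygous although one parent carries only the
            # other allele: one inherited allele must have mutated
            out.append(make(0 if c_sorted == homref else 1, "mixed"))
    return out


def detect_violations(
    records: Iterable[TrioSiteRecord], trio: Trio, config: FilterConfig
) -> Iterable[CandidateDNM]:
    """Yield Mendelian violations from a record stream (no quality filters)."""
    for record in records:
        yield from _violations_for_record(record, trio, config.violation_mode)


def run_pipeline(
    records: Iterable[TrioSiteRecord],
    trio: Trio,
    config: FilterConfig,
    depth_stats: Optional[dict[str, DepthStats]] = None,
    population_positions: Optional[set[tuple[str, int]]] = None,
    masks: Sequence[RegionMask] = (),
    other_sample_ids: Sequence[str] = (),
    include_chroms: Optional[Sequence[str]] = None,
    excluded_chroms: frozenset[str] = DEFAULT_EXCLUDED_CHROMS,
) -> PipelineResult:
    """Run the full candidate-DNM filter stack for one focal trio.

    ``depth_stats`` (per-individual mean/sd depth) must be supplied when the
    config uses relative, sigma or Poisson depth bounds; otherwise it is
    computed in a prior pass over ``records`` (which is then materialised).

    Sex chromosomes are excluded by default; pass ``include_chroms`` to
    restrict calling to an explicit chromosome set instead.
    """
    c = config.depth
    needs_stats = any(
        x is not None for x in (c.low_mult, c.high_mult, c.n_sigma, c.poisson_p_threshold)
    )
    if needs_stats and depth_stats is None:
        records = list(records)
        depth_stats = depth_stats_from_records(records, trio.members)
    trio_stats = None
    if depth_stats is not None:
        means = [depth_stats[i].mean for i in trio.members]
        trio_stats = DepthStats(mean=sum(means) / 3.0)

    accounting = StageAccounting()
    result = PipelineResult([], accounting, config)

    masks = [
        m for m in masks
        if not config.exclusion.masks or m.label in config.exclusion.masks
    ]

    n_in = 0
    candidates: list[CandidateDNM] = []
    for record in records:
        n_in += 1
        if include_chroms is not None:
            if record.chrom not in include_chroms:
                result.n_skipped_chrom += 1
                continue
        elif record.chrom in excluded_chroms:
            result.n_skipped_chrom += 1
            continue
        if not record.is_snv:
            result.n_skipped_indel += 1
            continue
        if not record.is_biallelic and config.violation_mode != "allele_absence":
            result.n_skipped_multiallelic += 1
            continue
        if record.call(trio.child).gt is None:
            result.n_skipped_missing_child += 1
            continue
        candidates.extend(_violations_for_record(record, trio, config.violation_mode))
    result.n_records = n_in
    accounting.add("input", n_in, n_in)
    accounting.add("mendelian_violation", n_in, len(candidates))
    result.candidates = candidates

    # the cluster rule is defined on the pre-filter violation set, so its
    # removals do not depend on how strict the other filters are
    candidates.sort(key=lambda c: (c.chrom, c.pos))
    _, cluster_removed = cluster_filter(
        [(c.chrom, c.pos) for c in candidates], config
    )
    cluster_removed = set(cluster_removed)

    def apply_stage(stage: str, evaluate) -> None:
        alive = [c for c in candidates if c.passed]
        for cand in alive:
            verdict = evaluate(cand)
            cand.verdicts[stage] = verdict
            if not verdict.passed:
                cand.status = f"removed:{stage}"
        accounting.add(stage, len(alive), sum(1 for c in alive if c.passed))

    def eval_site(cand: CandidateDNM) -> FilterVerdict:
        return site_filter(cand.record, config)

    def eval_depth(cand: CandidateDNM) -> FilterVerdict:
        parts = []
        for member, call in (
            (trio.father, cand.father_call),
            (trio.mother, cand.mother_call),
            (trio.child, cand.child_call),
        ):
            ind = depth_stats.get(member) if depth_stats else None
            parts.append(depth_filter(call, config, ind, trio_stats))
        return FilterVerdict.merge(*parts)

    def eval_gq(cand: CandidateDNM) -> FilterVerdict:
        return FilterVerdict.merge(
            genotype_quality_filter(cand.father_call, "parent", config),
            genotype_quality_filter(cand.mother_call, "parent", config),
            genotype_quality_filter(cand.child_call, "child", config),
        )

    def eval_parent_ad(cand: CandidateDNM) -> FilterVerdict:
        return FilterVerdict.merge(
            parent_allele_filter(cand.father_call, cand.mutant_allele_index, config),
            parent_allele_filter(cand.mother_call, cand.mutant_allele_index, config),
        )

    def eval_ab(cand: CandidateDNM) -> FilterVerdict:
        # balance the mutant allele against the child's other allele (the
        # reference allele in the usual homref configuration)
        others = [a for a in cand.child_call.alleles if a != cand.mutant_allele_index]
        ref_index = others[0] if others else 0
        return ab_filter(cand.child_call, cand.mutant_allele_index, config, ref_index)

    def eval_strand(cand: CandidateDNM) -> FilterVerdict:
        return strand_filter(
            cand.child_call.alt_forward, cand.child_call.alt_reverse, config
        )

    def eval_exclusion(cand: CandidateDNM) -> FilterVerdict:
        other = {}
        if config.exclusion.use_other_samples and cand.record is not None:
            other = {
                i: cand.record.call(i)
                for i in other_sample_ids
                if i not in trio.members
            }
        return exclusion_filter(
            cand.chrom,
            cand.pos,
            cand.mutant_allele_index,
            other_genotypes=other,
            population_positions=population_positions
            if config.exclusion.use_population_snps
            else None,
            masks=masks,
            config=config,
        )

    apply_stage("site_filter", eval_site)
    apply_stage("depth", eval_depth)
    apply_stage("genotype_quality", eval_gq)
    apply_stage("parent_allele", eval_parent_ad)
    apply_stage("allelic_balance", eval_ab)
    apply_stage("strand", eval_strand)
    apply_stage("exclusion", eval_exclusion)

    alive = [c for c in candidates if c.passed]
    removed = [c for i, c in enumerate(candidates) if i in cluster_removed and c.passed]
    for cand in removed:
        cand.status = "removed:cluster"
        cand.verdicts["cluster"] = FilterVerdict(
            (FailureReason("cluster", cand.pos, "mutation cluster"),)
        )
    accounting.add("cluster", len(alive), len(alive) - len(removed))
    return result


def attach_validation(
    candidates: Sequence[CandidateDNM],
    outcomes: Iterable[ValidationOutcome],
) -> list[str]:
    """Attach experimental validation statuses to candidates in place.

    Returns warnings for outcomes that match no candidate.  Untested
    candidates keep their current status.
    """
    by_key = {c.key: c for c in candidates}
    warnings = []
    status_map = {
        "validated": "validated",
        "failed": "false_positive",
        "not_amplified": "not_amplified",
        "untested": None,
    }
    for outcome in outcomes:
        cand = by_key.get(outcome.key)
        if cand is None:
            warnings.append(
                f"validation outcome at {outcome.chrom}:{outcome.pos} "
                f"({outcome.allele}) matches no candidate; ignored"
            )
            continue
        mapped = status_map[outcome.status]
        if mapped is not None:
            cand.validation = mapped
    return warnings
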