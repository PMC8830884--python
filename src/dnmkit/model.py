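"""Core data model for trio variant records and pedigrees.

Positions follow VCF convention (1-based); region masks use BED convention
(0-based, half-open).  Genotypes are unphased multisets of allele indices:
``0/1`` and ``1|0`` are the same genotype everywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, unresolvable trio)."""


@dataclass(frozen=True)
class IndividualRecord:
    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Optional[int] = None  # 1 = male, 2 = female, None = unknown
    generation: int = 0
    age_at_conception_years: Optional[float] = None


@dataclass(frozen=True)
class Trio:
    father: str
    mother: str
    child: str

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.father, self.mother, self.child)

    @property
    def parents(self) -> tuple[str, str]:
        return (self.father, self.mother)


class Pedigree:
    """A set of individuals with parent links.

    Generation indices are computed from parent links: founders (no known
    parent in the pedigree) are generation 0, every other individual is one
    more than the deepest known parent.
    """

    def __init__(self, individuals: Iterable[IndividualRecord]):
        members = list(individuals)
        by_id = {m.id: m for m in members}
        if len(by_id) != len(members):
            raise PedigreeError("duplicate individual ids in pedigree")
        self._check_acyclic(by_id)
        generations = self._generations(by_id)
        self.individuals = [
            IndividualRecord(
                m.id, m.father_id, m.mother_id, m.sex,
                generations[m.id], m.age_at_conception_years,
            )
            for m in members
        ]
        self._by_id = {m.id: m for m in self.individuals}

    @staticmethod
    def _check_acyclic(by_id: Mapping[str, IndividualRecord]) -> None:
        # DFS colouring over parent links; a back edge means an individual
        # is its own ancestor.
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {i: WHITE for i in by_id}

        def visit(i: str) -> None:
            colour[i] = GREY
            rec = by_id[i]
            for p in (rec.father_id, rec.mother_id):
                if p is None or p not in by_id:
                    continue
                if colour[p] == GREY:
                    raise PedigreeError(f"cyclic parentage involving {p!r}")
                if colour[p] == WHITE:
                    visit(p)
            colour[i] = BLACK

        for i in by_id:
            if colour[i] == WHITE:
                visit(i)

    @staticmethod
    def _generations(by_id: Mapping[str, IndividualRecord]) -> dict[str, int]:
        memo: dict[str, int] = {}

        def depth(i: str) -> int:
            if i in memo:
                return memo[i]
            rec = by_id[i]
            parents = [p for p in (rec.father_id, rec.mother_id) if p in by_id]
            memo[i] = 0 if not parents else 1 + max(depth(p) for p in parents)
            return memo[i]

        return {i: depth(i) for i in by_id}

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __getitem__(self, individual_id: str) -> IndividualRecord:
        return self._by_id[individual_id]

    def __iter__(self):
        return iter(self.individuals)

    def trios(self) -> list[Trio]:
        """All (father, mother, child) triples with both parents present."""
        out = []
        for m in self.individuals:
            if (m.father_id in self._by_id) and (m.mother_id in self._by_id):
                out.append(Trio(m.father_id, m.mother_id, m.id))
        return out

    def trio_for_child(self, child_id: str) -> Trio:
        for t in self.trios():
            if t.child == child_id:
                return t
        raise PedigreeError(
            f"no complete trio with child {child_id!r}; "
            "both parents must be present in the pedigree"
        )


@dataclass(frozen=True)
class SampleCall:
    """One individual's call at one site.

    All fields other than the genotype are optional: a missing annotation is
    represented as ``None`` and is never coerced to zero.  ``ad`` follows the
    site's allele order (reference first).
    """

    gt: Optional[tuple[int, int]] = None
    dp: Optional[int] = None
    ad: Optional[tuple[int, ...]] = None
    gq: Optional[int] = None
    pl: Optional[tuple[int, ...]] = None
    lowq_ad_alt: Optional[int] = None
    alt_forward: Optional[int] = None  # alt-supporting reads on the forward strand
    alt_reverse: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.gt is None

    @property
    def alleles(self) -> frozenset[int]:
        return frozenset(self.gt) if self.gt is not None else frozenset()

    @property
    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]

    def is_hom(self, allele: int = 0) -> bool:
        return self.gt is not None and self.gt == (allele, allele)


@dataclass(frozen=True)
class SiteAnnotations:
    """Site-level quality annotations; any of them may be absent."""

    qual: Optional[float] = None
    qd: Optional[float] = None
    mq: Optional[float] = None
    fs: Optional[float] = None
    sor: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    base_q_rank_sum: Optional[float] = None


@dataclass(frozen=True)
class TrioSiteRecord:
    """One genomic site: alleles, site annotations and per-individual calls."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    annotations: SiteAnnotations = field(default_factory=SiteAnnotations)
    calls: Mapping[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError("empty reference allele")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + tuple(self.alt_alleles)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    def call(self, individual_id: str) -> SampleCall:
        return self.calls.get(individual_id, SampleCall())


class RegionMask:
    """A labelled set of genomic intervals (0-based, half-open).

    Intervals are merged per chromosome at construction, so membership tests
    run against sorted non-overlapping intervals.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]], label: str = ""):
        self.label = label
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        self._intervals: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged = [ivs[0]]
            for s, e in ivs[1:]:
                ls, le = merged[-1]
                if s <= le:
                    merged[-1] = (ls, max(le, e))
                else:
                    merged.append((s, e))
            self._intervals[chrom] = merged

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (c, s, e) for c, ivs in sorted(self._intervals.items()) for s, e in ivs
        ]

    def __len__(self) -> int:
        return sum(len(v) for v in self._intervals.values())

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based VCF position: tests pos-1 in [start, end)."""
        import bisect

        ivs = self._intervals.get(chrom)
        if not ivs:
            return False
        p = pos - 1
        i = bisect.bisect_right(ivs, (p, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= p < ivs[i][1]


VALIDATION_STATUSES = ("validated", "failed", "not_amplified", "untested")


@dataclass(frozen=True)
class ValidationOutcome:
    """Experimental validation result for one candidate site."""

    chrom: str
    pos: int
    allele: str
    status: str  # one of VALIDATION_STATUSES
    confirmed_genotypes: Optional[Mapping[str, str]] = None

    def __post_init__(self):
        if self.status not in VALIDATION_STATUSES:
            raise ValueError(f"unknown validation status {self.status!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.allele)
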