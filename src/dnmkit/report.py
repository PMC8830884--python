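"""Comparison statistics across call sets and the standardised run report:
set overlaps, mutation spectrum, ti/tv, transmission to a third generation,
one-at-a-time filter sweeps, and a machine-readable reporting checklist.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .denominator import (
    callable_genome_count,
    combine_fnr,
    fnr_ab,
    fnr_site_filter_proportion,
)
from .filters import (
    AbConfig,
    ClusterConfig,
    DepthFilterConfig,
    FilterConfig,
    GenotypeQualityConfig,
    ParentAlleleConfig,
    SiteFilterConfig,
    binomial_two_sided_p,
)
from .pipeline import CandidateDNM, PipelineResult, run_pipeline
from .rates import mutation_rate
from .simulate import SimulatedTrio

Key = tuple[str, int, str]  # (chrom, pos, mutant allele)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


# ---------------------------------------------------------------------------
# call-set overlaps
# ---------------------------------------------------------------------------

def overlap_counts(
    collection: Mapping[str, Iterable[Key]]
) -> list[tuple[frozenset[str], int]]:
    """Exact counts per non-empty membership pattern (upset-plot input).

    Patterns with zero count are omitted; the counts sum to the size of the
    union of all call sets.
    """
    sets = {label: set(keys) for label, keys in collection.items()}
    if len(sets) < 2:
        raise ValueError("need at least two call sets")
    union = set().union(*sets.values())
    patterns: dict[frozenset[str], int] = {}
    for key in union:
        pattern = frozenset(label for label, s in sets.items() if key in s)
        patterns[pattern] = patterns.get(pattern, 0) + 1
    return sorted(patterns.items(), key=lambda kv: (-len(kv[0]), -kv[1]))


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for A<->G and C<->T, else 'transversion'."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT alleles {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    return "transition" if (ref, alt) in _TRANSITIONS else "transversion"


def titv_ratio(candidates: Sequence[CandidateDNM]) -> Optional[float]:
    """Transition/transversion ratio; None when there are no transversions."""
    ti = tv = 0
    for c in candidates:
        kind = classify_substitution(c.ref_allele, c.mutant_allele)
        if kind == "transition":
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


def spectrum(
    candidates: Sequence[CandidateDNM],
    reference_context: Optional[Mapping[Key, str]] = None,
) -> dict:
    """Strand-collapsed six-class mutation spectrum.

    Purine-rooted changes map to their pyrimidine complement (G>A counts as
    C>T).  When 3-mer reference contexts are supplied (keyed by candidate),
    C>T events at CpG sites are sub-classified.
    """
    counts = {k: 0 for k in SPECTRUM_CLASSES}
    cpg = 0 if reference_context is not None else None
    for c in candidates:
        ref, alt = c.ref_allele.upper(), c.mutant_allele.upper()
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
        if reference_context is not None:
            ctx = reference_context.get(c.key, "").upper()
            if len(ctx) == 3:
                fwd_cpg = c.ref_allele.upper() == "C" and ctx[2] == "G"
                rev_cpg = c.ref_allele.upper() == "G" and ctx[0] == "C"
                if fwd_cpg or rev_cpg:
                    cpg += 1
    out = {"classes": counts, "total": sum(counts.values())}
    out["cpg"] = cpg if cpg is not None else "not computed"
    if cpg is not None and out["total"]:
        out["cpg_percent"] = 100.0 * cpg / out["total"]
    return out


# ---------------------------------------------------------------------------
# transmission
# ---------------------------------------------------------------------------

def transmission_summary(
    candidates: Sequence[CandidateDNM],
    third_generation_calls: Mapping[Key, object],
    definition: str = "genotype",
    min_alt_reads: int = 2,
) -> dict:
    """Transmission of candidate DNMs to a genotyped third generation.

    ``genotype``: transmitted when the grandchild is called heterozygous for
    the mutant allele; ``read_support``: when at least ``min_alt_reads``
    grandchild reads carry it.  Reports raw counts, the rate, and both the
    one-sided and two-sided exact binomial p-values against 50% (two-sided =
    doubled smaller tail).
    """
    if definition not in ("genotype", "read_support"):
        raise ValueError(f"unknown transmission definition {definition!r}")
    transmitted = 0
    total = 0
    for cand in candidates:
        call = third_generation_calls.get(cand.key)
        if call is None:
            continue
        total += 1
        mut = cand.mutant_allele_index
        if definition == "genotype":
            if call.gt is not None and mut in call.gt and call.is_het:
                transmitted += 1
        else:
            if call.ad is not None and mut < len(call.ad) and call.ad[mut] >= min_alt_reads:
                transmitted += 1
    if total == 0:
        raise ValueError("no candidates overlap the third-generation calls")
    from scipy import stats

    one_sided = float(stats.binom.cdf(min(transmitted, total - transmitted), total, 0.5))
    return {
        "transmitted": transmitted,
        "total": total,
        "rate": transmitted / total,
        "binomial_p_two_sided": binomial_two_sided_p(transmitted, total, 0.5),
        "binomial_p_one_sided": one_sided,
    }


# ---------------------------------------------------------------------------
# filter sweep
# ---------------------------------------------------------------------------

_FAMILY_SECTIONS = {
    "site": ("site", SiteFilterConfig),
    "depth": ("depth", DepthFilterConfig),
    "genotype_quality": ("genotype_quality", GenotypeQualityConfig),
    "parent_allele": ("parent_allele", ParentAlleleConfig),
    "ab": ("ab", AbConfig),
    "cluster": ("cluster", ClusterConfig),
}


@dataclass
class SweepRow:
    family: str
    setting: dict
    n_candidates: int
    n_false_positives: int
    cg_sites: float
    fnr: float
    mu: float


@dataclass
class SweepResult:
    rows: list[SweepRow] = field(default_factory=list)

    def as_dicts(self) -> list[dict]:
        return [dataclasses.asdict(r) for r in self.rows]


def _apply_setting(base: FilterConfig, family: str, setting: dict) -> FilterConfig:
    if family not in _FAMILY_SECTIONS:
        raise ValueError(f"unknown filter family {family!r}")
    attr, _ = _FAMILY_SECTIONS[family]
    section = replace(getattr(base, attr), **setting)
    return replace(base, **{attr: section})


def filter_sweep(
    sim: SimulatedTrio,
    base_config: FilterConfig,
    grid: Mapping[str, Sequence[dict]],
) -> SweepResult:
    """One-at-a-time filter sweep on simulated data.

    For each family in ``grid`` and each setting (a dict of overrides for
    that family's config section, applied to ``base_config``), the full
    pipeline is re-run; candidates, false positives against the truth
    ledger, callable genome, FNR (AB tail combined with the site-filter
    proportion) and the resulting rate are reported.
    """
    result = SweepResult()
    trio = sim.trio
    truth_pos = sim.truth.dnm_positions
    trusted = sim.inherited_het_records()
    het_calls = sim.forced_het_child_calls()
    for family, settings in grid.items():
        for setting in settings:
            if not isinstance(setting, Mapping):
                raise ValueError("each sweep setting must be a mapping of overrides")
            config = _apply_setting(base_config, family, dict(setting))
            run = run_pipeline(sim.records, trio, config, depth_stats=sim.depth_stats)
            survivors = run.survivors
            n_fp = sum(1 for c in survivors if c.pos not in truth_pos)
            cg = callable_genome_count(
                sim.callable_table, trio, config, depth_stats=sim.depth_stats
            )
            fnr_parts = []
            if het_calls:
                try:
                    fnr_parts.append(fnr_ab(het_calls, config))
                except ValueError:
                    pass
            if trusted:
                fnr_parts.append(fnr_site_filter_proportion(trusted, config))
            fnr = combine_fnr(fnr_parts) if fnr_parts else None
            mu = float("nan")
            if cg.cg_sites > 0 and (fnr is None or fnr.value < 1.0):
                est = mutation_rate(
                    len(survivors), 0.0, cg,
                    fnr if fnr is not None else 0.0,
                )
                mu = est.mu
            result.rows.append(SweepRow(
                family=family,
                setting=dict(setting),
                n_candidates=len(survivors),
                n_false_positives=n_fp,
                cg_sites=cg.cg_sites,
                fnr=fnr.value if fnr is not None else float("nan"),
                mu=mu,
            ))
    return result


# ---------------------------------------------------------------------------
# standardised report
# ---------------------------------------------------------------------------

def _ab_distribution(calls, alt_index: int = 1) -> list[float]:
    from .filters import allelic_balance

    out = []
    for c in calls:
        ab = allelic_balance(c, alt_index)
        if ab is not None:
            out.append(round(ab, 4))
    return out


def standardized_report(
    pipeline_result: PipelineResult,
    fdr=None,
    cg=None,
    fnr=None,
    rate=None,
    transmission: Optional[dict] = None,
    true_het_calls: Sequence = (),
    reference_context: Optional[Mapping] = None,
) -> dict:
    """Assemble the standardised reporting checklist as a JSON-able dict.

    Sections without data are reported as "not reported" rather than
    omitted, so downstream consumers always see the full checklist.
    """
    NOT = "not reported"
    survivors = pipeline_result.survivors
    pre_ab = [
        c for c in pipeline_result.candidates
        if c.passed or c.status in ("removed:allelic_balance", "removed:strand",
                                    "removed:exclusion", "removed:cluster")
    ]
    config = pipeline_result.config

    def fmt_section(obj) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(obj).items()
        }

    report = {
        "filters": {
            "preset": config.name,
            "violation_mode": config.violation_mode,
            "site": fmt_section(config.site),
            "depth": fmt_section(config.depth),
            "genotype_quality": fmt_section(config.genotype_quality),
            "parent_allele": fmt_section(config.parent_allele),
            "ab": fmt_section(config.ab),
            "strand": fmt_section(config.strand),
            "cluster": fmt_section(config.cluster),
            "exclusion": fmt_section(config.exclusion),
        },
        "stage_accounting": pipeline_result.accounting.as_dict(),
        "n_candidates": len(survivors),
        "fdr": {"value": fdr.value, "method": fdr.method} if fdr is not None else NOT,
        "callable_genome": (
            {"cg_sites": cg.cg_sites, "method": cg.method} if cg is not None else NOT
        ),
        "fnr": {"value": fnr.value, "method": fnr.method} if fnr is not None else NOT,
        "mutation_rate": rate.as_dict() if rate is not None else NOT,
        "titv": titv_ratio(survivors) if survivors else NOT,
        "spectrum": spectrum(survivors, reference_context) if survivors else NOT,
        "transmission": transmission if transmission is not None else NOT,
        "ab_distributions": {
            "true_heterozygous_sites": _ab_distribution(true_het_calls),
            "candidates_before_ab_filter": _ab_distribution(
                [c.child_call for c in pre_ab]
            ),
            "final_candidates": _ab_distribution([c.child_call for c in survivors]),
        },
    }
    return report
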