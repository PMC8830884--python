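"""Synthetic trio sequencing simulator with a complete truth ledger.

The simulator emulates the statistical structure a trio-based DNM pipeline
sees at the VCF level, so every downstream stage can be tested without real
sequencing data:

* parental genotypes arise from a fixed-difference background (divergence to
  the reference) plus common polymorphic sites in Hardy-Weinberg proportions
  at allele frequency 0.5, calibrated so each parent is heterozygous at the
  configured per-site rate;
* the child's genotype is drawn by Mendelian sampling, germline DNMs are
  injected per haploid transmission, and somatic (mosaic) variants are
  assigned cell fractions;
* per-individual depth is Poisson, allele-supporting read counts are binomial
  with a symmetric per-read miscall probability, and genotype likelihoods /
  PL / GQ / called genotypes follow the standard diploid read model (a read
  matches an allele of the genotype with probability 1 - e, a heterozygote is
  an even mixture);
* site annotations (QD, MQ, FS, SOR, rank sums) are drawn from stylised null
  distributions with a configurable outlier fraction -- the simulator does
  not model read mapping, so their absolute scales carry no meaning beyond
  "typical" versus "artifact-like".

Only polymorphic sites are materialised as :class:`TrioSiteRecord` (as in a
real multi-sample VCF); monomorphic background sites are summarised in a
per-site depth/GQ table used for callable-genome estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .model import (
    IndividualRecord,
    Pedigree,
    SampleCall,
    SiteAnnotations,
    Trio,
    TrioSiteRecord,
)
from .filters import DepthStats

BASES = ("A", "C", "G", "T")
_PL_CAP = 9999  # stand-in for a Phred likelihood of an impossible genotype


@dataclass(frozen=True)
class AnnotationModel:
    """Null distributions for site annotations, with an artifact fraction.

    Typical sites draw from tight, well-behaved distributions; a fraction
    ``outlier_fraction`` of sites draws from distributions chosen to violate
    common hard-filter thresholds (mimicking mapping artifacts).
    """

    outlier_fraction: float = 0.01
    qd_loc: float = 25.0
    qd_scale: float = 5.0
    mq_loc: float = 60.0
    mq_scale: float = 2.0
    fs_scale: float = 3.0
    sor_loc: float = 1.0
    sor_scale: float = 0.3
    rank_sum_scale: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated trio.

    Defaults describe a macaque-like trio sequenced to ~40x: parental
    heterozygosity of 2.5e-3 per site, 5e-3 fixed divergence to the
    reference, a per-read miscall probability of 1e-3 and a true rate of
    1e-8 mutations per site per haploid transmission.
    """

    genome_length: int = 100_000
    chrom: str = "chr1"
    heterozygosity: float = 0.0025
    divergence_to_reference: float = 0.005
    mean_depth: float | dict[str, float] = 40.0
    sequencing_error: float = 1e-3
    mu_true: float = 1e-8
    n_somatic: int = 0
    somatic_cell_fraction: tuple[float, float] = (0.1, 0.3)
    somatic_half_fraction: bool = False  # read fraction = cell fraction / 2
    n_cluster_pairs: int = 0  # extra DNM pairs placed within cluster_span
    cluster_span: int = 100
    gq_cap: int = 99
    lowq_depth_fraction: float = 0.05
    annotations: AnnotationModel = field(default_factory=AnnotationModel)
    father_id: str = "father"
    mother_id: str = "mother"
    child_id: str = "child"
    grandchild_id: str = "grandchild"

    def __post_init__(self):
        for name in ("heterozygosity", "divergence_to_reference",
                     "sequencing_error", "mu_true"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        for v in self.depths().values():
            if v <= 0:
                raise ValueError("mean depths must be positive")

    def depths(self) -> dict[str, float]:
        ids = (self.father_id, self.mother_id, self.child_id)
        if isinstance(self.mean_depth, dict):
            return {i: float(self.mean_depth[i]) for i in ids}
        return {i: float(self.mean_depth) for i in ids}

    def trio(self) -> Trio:
        return Trio(self.father_id, self.mother_id, self.child_id)

    def pedigree(self) -> Pedigree:
        return Pedigree([
            IndividualRecord(self.father_id, sex=1),
            IndividualRecord(self.mother_id, sex=2),
            IndividualRecord(self.child_id, self.father_id, self.mother_id),
        ])


@dataclass
class DnmTruth:
    pos: int
    parent_of_origin: str
    allele: str
    background: str  # homref | homalt | het_parent | ...
    kind: str = "dnm"  # dnm | spike
    transmitted: Optional[bool] = None


@dataclass
class SomaticTruth:
    pos: int
    cell_fraction: float


@dataclass
class SimTruth:
    """Ground-truth ledger for a simulated pedigree."""

    dnms: list[DnmTruth] = field(default_factory=list)
    somatic: list[SomaticTruth] = field(default_factory=list)
    forced_het_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    alt_background_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    # true (father, mother, child) allele-index genotypes at emitted sites
    true_genotypes: dict[int, tuple] = field(default_factory=dict)

    @property
    def dnm_positions(self) -> set[int]:
        return {d.pos for d in self.dnms}


@dataclass
class CallableTable:
    """Per-site depth/GQ summary over the whole simulated genome."""

    chrom: str
    positions: np.ndarray  # 1-based, length L
    dp: np.ndarray  # (L, 3) father/mother/child
    gq: np.ndarray  # (L, 3)
    parents_called_homref: np.ndarray  # (L,) bool

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SimulatedTrio:
    """Everything one simulation run produced."""

    config: SimulationConfig
    records: list[TrioSiteRecord]
    truth: SimTruth
    callable_table: CallableTable
    depth_stats: dict[str, DepthStats]

    @property
    def trio(self) -> Trio:
        return self.config.trio()

    def forced_het_child_calls(self) -> list[SampleCall]:
        """Child calls at sites where heterozygosity is forced by the parents
        (one parent 0/0, the other 1/1) -- the basis of the AB-tail FNR."""
        wanted = set(self.truth.forced_het_positions.tolist())
        child = self.config.child_id
        return [r.call(child) for r in self.records if r.pos in wanted]

    def inherited_het_records(self) -> list[TrioSiteRecord]:
        """Biallelic records where the child is truly heterozygous through
        inheritance (not a DNM): the trusted-variant set for site-filter FNR
        and probabilistic callable-genome estimation."""
        dnm_pos = self.truth.dnm_positions
        out = []
        for r in self.records:
            tg = self.truth.true_genotypes.get(r.pos)
            if tg is None or r.pos in dnm_pos or not r.is_biallelic:
                continue
            f, m, c = tg
            if sorted(c) == [0, 1] and (1 in f or 1 in m):
                out.append(r)
        return out


# ---------------------------------------------------------------------------
# read model
# ---------------------------------------------------------------------------

def _genotype_model_raw(
    dp: np.ndarray, n_alt: np.ndarray, eps: float, gq_cap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised biallelic genotype likelihoods.

    Returns (called dosage, PL array (L,3) ordered 0/0, 0/1, 1/1, GQ).
    Sites with zero depth get an uninformative PL of all zeros.
    """
    n_ref = dp - n_alt
    p = np.array([eps, 0.5, 1.0 - eps])
    log_p = np.full(3, -np.inf)
    np.log10(p, where=p > 0, out=log_p)
    log_q = np.full(3, -np.inf)
    np.log10(1.0 - p, where=(1.0 - p) > 0, out=log_q)
    # 0 * log(0) is a zero contribution, not NaN
    with np.errstate(invalid="ignore"):
        term_alt = np.where(n_alt[:, None] > 0, n_alt[:, None] * log_p[None, :], 0.0)
        term_ref = np.where(n_ref[:, None] > 0, n_ref[:, None] * log_q[None, :], 0.0)
    ll = term_alt + term_ref
    best = ll.max(axis=1)
    pl = 10.0 * (best[:, None] - ll)
    pl = np.where(np.isfinite(pl), pl, _PL_CAP)
    pl = np.minimum(np.rint(pl), _PL_CAP).astype(np.int32)
    called = np.asarray(ll.argmax(axis=1), dtype=np.int8)
    gq = np.partition(pl, 1, axis=1)[:, 1]
    gq = np.minimum(gq, gq_cap).astype(np.int32)
    zero = dp == 0
    called[zero] = 0
    pl[zero] = 0
    gq[zero] = 0
    return called, pl, gq


@lru_cache(maxsize=8)
def _genotype_lut(eps: float, gq_cap: int, max_dp: int):
    """Lookup table of (called, PL, GQ) over every (dp, n_alt) with dp <= max_dp.

    The biallelic read model depends on the reads only through (dp, n_alt),
    so results for all pairs are precomputed once; the flat index of pair
    (dp, n_alt) is dp * (dp + 1) / 2 + n_alt.
    """
    dps = np.repeat(np.arange(max_dp + 1), np.arange(max_dp + 1) + 1)
    nalts = np.concatenate([np.arange(d + 1) for d in range(max_dp + 1)])
    return _genotype_model_raw(dps, nalts, eps, gq_cap)


def _vector_genotype_model(
    dp: np.ndarray, n_alt: np.ndarray, eps: float, gq_cap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Biallelic genotype model via the cached (dp, n_alt) lookup table."""
    max_dp = int(dp.max()) if dp.size else 0
    # round the table size up so the cache is reused across runs
    table_dp = max(64, 1 << int(max_dp - 1).bit_length()) if max_dp else 64
    called, pl, gq = _genotype_lut(float(eps), int(gq_cap), table_dp)
    idx = (dp.astype(np.int64) * (dp.astype(np.int64) + 1)) // 2 + n_alt
    return called[idx], pl[idx], gq[idx]


def _diploid_genotypes(k: int) -> list[tuple[int, int]]:
    """VCF PL ordering of diploid genotypes over k alleles."""
    return [(i, j) for j in range(k) for i in range(j + 1)]


def _scalar_call(
    genotype: tuple[int, int],
    k: int,
    dp: int,
    eps: float,
    rng: np.random.Generator,
    gq_cap: int,
    ad_override: Optional[Sequence[int]] = None,
) -> SampleCall:
    """Simulate one call at a site with k alleles (general, unvectorised).

    Each read copies one of the genotype's two alleles; with probability
    ``eps`` it is misread as one of the other k-1 alleles (uniformly).
    """
    if dp == 0:
        return SampleCall(gt=None, dp=0, ad=tuple([0] * k), gq=0,
                          pl=tuple([0] * len(_diploid_genotypes(k))))
    if ad_override is not None:
        counts = np.asarray(ad_override, dtype=np.int64)
    else:
        probs = np.zeros(k)
        for a in genotype:
            if eps > 0 and k > 1:
                row = np.full(k, eps / (k - 1))
                row[a] = 1.0 - eps
            else:
                row = np.zeros(k)
                row[a] = 1.0
            probs += 0.5 * row
        counts = rng.multinomial(dp, probs)
    genotypes = _diploid_genotypes(k)
    lls = []
    for g in genotypes:
        p_allele = np.zeros(k)
        for a in g:
            if eps > 0 and k > 1:
                row = np.full(k, eps / (k - 1))
                row[a] = 1.0 - eps
            else:
                row = np.zeros(k)
                row[a] = 1.0
            p_allele += 0.5 * row
        with np.errstate(divide="ignore"):
            ll = float(np.sum(counts * np.log10(np.where(p_allele > 0, p_allele, 1))))
            if np.any((p_allele == 0) & (counts > 0)):
                ll = -np.inf
        lls.append(ll)
    lls = np.array(lls)
    best = lls.max()
    pl = 10.0 * (best - lls)
    pl = np.where(np.isfinite(pl), pl, _PL_CAP)
    pl = np.minimum(np.rint(pl), _PL_CAP).astype(int)
    called = genotypes[int(lls.argmax())]
    gq = int(min(gq_cap, int(np.partition(pl, 1)[1])))
    return SampleCall(
        gt=tuple(sorted(called)),
        dp=int(dp),
        ad=tuple(int(x) for x in counts),
        gq=gq,
        pl=tuple(int(x) for x in pl),
    )


def _binomial_het_call(
    dp: int, eps: float, rng: np.random.Generator, gq_cap: int,
    alt_fraction: float = 0.5,
) -> SampleCall:
    """Biallelic call whose alt reads are Binomial(dp, f) with miscalls."""
    f_eff = alt_fraction * (1.0 - eps) + (1.0 - alt_fraction) * eps
    n_alt = int(rng.binomial(dp, f_eff)) if dp > 0 else 0
    return _scalar_call((0, 1), 2, dp, eps, rng, gq_cap,
                        ad_override=(dp - n_alt, n_alt))


def _attach_strand_and_lowq(
    call: SampleCall, alt_index: int, lowq_dp_mean: float,
    eps: float, rng: np.random.Generator,
) -> SampleCall:
    """Add simulated strand counts and low-quality-read alt counts."""
    n_alt = call.ad[alt_index] if call.ad and alt_index < len(call.ad) else 0
    fwd = int(rng.binomial(n_alt, 0.5)) if n_alt else 0
    lowq_dp = int(rng.poisson(lowq_dp_mean))
    if call.gt is not None and alt_index in call.gt:
        f = 0.5 if call.is_het else 1.0 - eps
    else:
        f = eps
    lowq_alt = int(rng.binomial(lowq_dp, f)) if lowq_dp else 0
    return replace(call, alt_forward=fwd, alt_reverse=n_alt - fwd,
                   lowq_ad_alt=lowq_alt)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _draw_annotations(
    n: int, model: AnnotationModel, rng: np.random.Generator
) -> list[SiteAnnotations]:
    outlier = rng.random(n) < model.outlier_fraction
    qd = np.clip(rng.normal(model.qd_loc, model.qd_scale, n), 0.1, None)
    mq = np.clip(rng.normal(model.mq_loc, model.mq_scale, n), 0.0, None)
    fs = rng.exponential(model.fs_scale, n)
    sor = np.clip(rng.normal(model.sor_loc, model.sor_scale, n), 0.0, None)
    mqrs = rng.normal(0.0, model.rank_sum_scale, n)
    rprs = rng.normal(0.0, model.rank_sum_scale, n)
    bqrs = rng.normal(0.0, model.rank_sum_scale, n)
    qual = np.clip(rng.normal(800.0, 150.0, n), 30.0, None)
    # artifact-like sites: violate the common hard-filter thresholds
    k = int(outlier.sum())
    if k:
        qd[outlier] = rng.uniform(0.0, 2.0, k)
        mq[outlier] = rng.uniform(20.0, 40.0, k)
        fs[outlier] = rng.uniform(60.0, 200.0, k)
        sor[outlier] = rng.uniform(3.0, 9.0, k)
        sign = rng.choice([-1.0, 1.0], k)
        mqrs[outlier] = sign * rng.uniform(12.5, 25.0, k)
        rprs[outlier] = sign * rng.uniform(8.0, 20.0, k)
        bqrs[outlier] = sign * rng.uniform(13.0, 25.0, k)
        qual[outlier] = rng.uniform(10.0, 50.0, k)
    return [
        SiteAnnotations(
            qual=round(float(qual[i]), 2),
            qd=round(float(qd[i]), 2),
            mq=round(float(mq[i]), 2),
            fs=round(float(fs[i]), 3),
            sor=round(float(sor[i]), 3),
            mq_rank_sum=round(float(mqrs[i]), 3),
            read_pos_rank_sum=round(float(rprs[i]), 3),
            base_q_rank_sum=round(float(bqrs[i]), 3),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate_trio(config: SimulationConfig, seed: int) -> SimulatedTrio:
    """Simulate one trio over ``genome_length`` sites.

    Deterministic under (config, seed).  Returns variant-site records (like a
    multi-sample VCF), the truth ledger and a BP-resolution depth/GQ table.
    """
    rng = np.random.default_rng(seed)
    L = config.genome_length
    eps = config.sequencing_error
    depths = config.depths()
    members = [config.father_id, config.mother_id, config.child_id]

    # --- true genotypes (alt-allele dosage per site) ----------------------
    d = config.divergence_to_reference
    p_poly = min(1.0, 2.0 * config.heterozygosity)
    u = rng.random(L)
    is_fixed = u < d
    is_poly = (~is_fixed) & (u < d + p_poly)
    fg = np.zeros(L, dtype=np.int8)
    mg = np.zeros(L, dtype=np.int8)
    n_poly = int(is_poly.sum())
    fg[is_poly] = rng.binomial(2, 0.5, n_poly)
    mg[is_poly] = rng.binomial(2, 0.5, n_poly)
    fg[is_fixed] = 2
    mg[is_fixed] = 2
    # Mendelian transmission: the child receives an alt allele from a parent
    # with probability dosage/2
    hap_f = (rng.random(L) < fg / 2.0).astype(np.int8)
    hap_m = (rng.random(L) < mg / 2.0).astype(np.int8)
    cg = hap_f + hap_m

    # --- germline DNMs ----------------------------------------------------
    n_dnm = int(rng.binomial(2 * L, config.mu_true))
    dnm_sites = rng.choice(L, size=n_dnm, replace=False) if n_dnm else np.empty(0, int)
    cluster_sites: list[tuple[int, int]] = []
    if config.n_cluster_pairs:
        for _ in range(config.n_cluster_pairs):
            a = int(rng.integers(0, max(1, L - config.cluster_span - 1)))
            b = a + int(rng.integers(1, config.cluster_span + 1))
            cluster_sites.append((a, b))

    # --- somatic (mosaic) variants in the child ---------------------------
    background = np.where((fg == 0) & (mg == 0) & (cg == 0))[0]
    dnm_set = set(int(i) for i in dnm_sites)
    dnm_set.update(i for pair in cluster_sites for i in pair)
    avail = background[~np.isin(background, list(dnm_set))] if dnm_set else background
    n_som = min(config.n_somatic, len(avail))
    som_sites = rng.choice(avail, size=n_som, replace=False) if n_som else np.empty(0, int)
    lo, hi = config.somatic_cell_fraction
    som_cf = rng.uniform(lo, hi, n_som)

    # --- depth and biallelic read counts ----------------------------------
    per_member: dict[str, dict[str, np.ndarray]] = {}
    dosages = {config.father_id: fg, config.mother_id: mg, config.child_id: cg}
    for m in members:
        dp = rng.poisson(depths[m], L).astype(np.int32)
        f = dosages[m].astype(np.float64) / 2.0
        f_eff = f * (1.0 - eps) + (1.0 - f) * eps
        n_alt = rng.binomial(dp, f_eff).astype(np.int32)
        called, pl, gq = _vector_genotype_model(dp, n_alt, eps, config.gq_cap)
        per_member[m] = {
            "dp": dp, "n_alt": n_alt, "called": called, "pl": pl, "gq": gq,
        }

    # --- special (multi-allelic-capable) sites: DNMs, clusters, somatic ---
    truth = SimTruth()
    special: dict[int, dict] = {}

    def add_dnm(i: int, kind: str) -> None:
        po = config.father_id if rng.random() < 0.5 else config.mother_id
        inherited_f, inherited_m = int(hap_f[i]), int(hap_m[i])
        if po == config.father_id:
            other_allele = inherited_m
        else:
            other_allele = inherited_f
        # allele space: 0 = ref base, 1 = background alt base (if anyone
        # carries it), 2 = a novel base.  A mutation converts the inherited
        # base to one of the 3 other bases uniformly; when a background alt
        # exists, 1 of those 3 is the other named allele and 2 are novel.
        bg_present = fg[i] > 0 or mg[i] > 0
        mutated_from = inherited_f if po == config.father_id else inherited_m
        if bg_present:
            other_named = 1 - mutated_from
            mutant = other_named if rng.random() < 1.0 / 3.0 else 2
        else:
            mutant = 1
        child_gt = tuple(sorted((other_allele, mutant)))
        if fg[i] == 0 and mg[i] == 0:
            bg = "homref"
        elif fg[i] == 2 and mg[i] == 2:
            bg = "homalt"
        else:
            bg = "het_parent"
        special[i] = {
            "child_gt": child_gt,
            "mutant": mutant,
            "bg_present": bool(bg_present),
        }
        truth.dnms.append(DnmTruth(
            pos=i + 1, parent_of_origin=po, allele="", background=bg, kind=kind,
        ))

    for i in dnm_sites:
        add_dnm(int(i), "dnm")
    for a, b in cluster_sites:
        add_dnm(a, "dnm")
        add_dnm(b, "dnm")

    som_overrides: dict[int, float] = {}
    for i, cf in zip(som_sites, som_cf):
        f = cf / 2.0 if config.somatic_half_fraction else cf
        som_overrides[int(i)] = f
        truth.somatic.append(SomaticTruth(pos=int(i) + 1, cell_fraction=float(cf)))

    # --- which sites become VCF records -----------------------------------
    emit = (fg > 0) | (mg > 0) | (cg > 0)
    for m in members:
        emit |= per_member[m]["called"] > 0
    for i in special:
        emit[i] = True
    # somatic sites are emitted only if the child's resampled reads make the
    # site look variant
    som_calls: dict[int, SampleCall] = {}
    for i, f in som_overrides.items():
        dp = int(per_member[config.child_id]["dp"][i])
        call = _binomial_het_call(dp, eps, rng, config.gq_cap, alt_fraction=f)
        som_calls[i] = call
        if call.gt is not None and call.gt != (0, 0):
            emit[i] = True
        if call.ad is not None and call.ad[1] > 0:
            emit[i] = True

    emit_idx = np.where(emit)[0]
    annotations = _draw_annotations(len(emit_idx), config.annotations, rng)

    # --- assemble records --------------------------------------------------
    truth.forced_het_positions = (
        np.where(is_poly & (((fg == 0) & (mg == 2)) | ((fg == 2) & (mg == 0))))[0] + 1
    )
    truth.alt_background_positions = np.where(is_fixed)[0] + 1

    records: list[TrioSiteRecord] = []
    ref_bases = rng.integers(0, 4, size=len(emit_idx))
    alt_offsets = rng.integers(1, 4, size=len(emit_idx))
    lowq_mean = {m: config.lowq_depth_fraction * depths[m] for m in members}

    for row, i in enumerate(emit_idx):
        i = int(i)
        pos = i + 1
        ref = BASES[int(ref_bases[row])]
        alt1 = BASES[(int(ref_bases[row]) + int(alt_offsets[row])) % 4]
        sp = special.get(i)
        if sp is not None and sp["bg_present"] and max(sp["child_gt"]) == 2:
            third = [b for b in BASES if b not in (ref, alt1)]
            alts: tuple[str, ...] = (alt1, third[int(rng.integers(0, 2))])
        else:
            alts = (alt1,)
        k = 1 + len(alts)

        calls: dict[str, SampleCall] = {}
        for m in members:
            pm = per_member[m]
            if m == config.child_id and sp is not None:
                call = _scalar_call(sp["child_gt"], k, int(pm["dp"][i]), eps, rng,
                                    config.gq_cap)
            elif m == config.child_id and i in som_calls:
                call = som_calls[i]
            elif k > 2:
                dosage = int(dosages[m][i])
                gt = (0, 0) if dosage == 0 else ((0, 1) if dosage == 1 else (1, 1))
                call = _scalar_call(gt, k, int(pm["dp"][i]), eps, rng, config.gq_cap)
            else:
                dp = int(pm["dp"][i])
                n_alt = int(pm["n_alt"][i])
                called = int(pm["called"][i])
                gt = (None if dp == 0 else
                      ((0, 0), (0, 1), (1, 1))[called])
                call = SampleCall(
                    gt=gt, dp=dp, ad=(dp - n_alt, n_alt),
                    gq=int(pm["gq"][i]),
                    pl=tuple(int(x) for x in pm["pl"][i]),
                )
            mut_index = sp["mutant"] if (sp is not None) else 1
            call = _attach_strand_and_lowq(
                call, min(mut_index, k - 1), lowq_mean[m], eps, rng
            )
            calls[m] = call

        records.append(TrioSiteRecord(
            chrom=config.chrom,
            pos=pos,
            ref_allele=ref,
            alt_alleles=alts,
            annotations=annotations[row],
            calls=calls,
        ))
        child_true = sp["child_gt"] if sp is not None else (
            (0, 0) if cg[i] == 0 else ((0, 1) if cg[i] == 1 else (1, 1))
        )
        truth.true_genotypes[pos] = (
            _dosage_gt(int(fg[i])), _dosage_gt(int(mg[i])), child_true,
        )

    # record the mutant allele string in the truth ledger
    rec_by_pos = {r.pos: r for r in records}
    for dn in truth.dnms:
        rec = rec_by_pos.get(dn.pos)
        if rec is not None:
            sp = special[dn.pos - 1]
            mut = min(sp["mutant"], len(rec.alleles) - 1)
            dn.allele = rec.alleles[mut]

    # --- callable table ----------------------------------------------------
    dp_mat = np.stack([per_member[m]["dp"] for m in members], axis=1)
    gq_mat = np.stack([per_member[m]["gq"] for m in members], axis=1)
    parents_homref = (
        (per_member[config.father_id]["called"] == 0)
        & (per_member[config.father_id]["dp"] > 0)
        & (per_member[config.mother_id]["called"] == 0)
        & (per_member[config.mother_id]["dp"] > 0)
    )
    table = CallableTable(
        chrom=config.chrom,
        positions=np.arange(1, L + 1, dtype=np.int64),
        dp=dp_mat,
        gq=gq_mat,
        parents_called_homref=parents_homref,
    )
    stats = {
        m: DepthStats(mean=float(per_member[m]["dp"].mean()),
                      sd=float(per_member[m]["dp"].std()))
        for m in members
    }
    return SimulatedTrio(
        config=config, records=records, truth=truth,
        callable_table=table, depth_stats=stats,
    )


def _dosage_gt(dosage: int) -> tuple[int, int]:
    return ((0, 0), (0, 1), (1, 1))[dosage]


# ---------------------------------------------------------------------------
# spike-in
# ---------------------------------------------------------------------------

def inject_spikes(
    sim: SimulatedTrio, n_spikes: int, seed: int
) -> SimulatedTrio:
    """Convert ``n_spikes`` background homref sites into child heterozygotes.

    Spiked sites are drawn uniformly from sites where both parents are called
    homozygous reference and no record exists; the child's reads are resampled
    as Binomial(DP, 1/2) with the configured miscall rate, PL/GQ recomputed,
    and the truth ledger extended with ``kind="spike"`` entries.
    """
    rng = np.random.default_rng(seed)
    config = sim.config
    eps = config.sequencing_error
    existing = {r.pos for r in sim.records}
    table = sim.callable_table
    mask = table.parents_called_homref.copy()
    occupied = np.isin(table.positions, sorted(existing))
    mask &= ~occupied
    avail = np.where(mask)[0]
    if n_spikes > len(avail):
        raise ValueError(
            f"cannot spike {n_spikes} sites: only {len(avail)} background "
            "parental-homref sites available"
        )
    if n_spikes == 0:
        return sim
    chosen = np.sort(rng.choice(avail, size=n_spikes, replace=False))
    annotations = _draw_annotations(n_spikes, config.annotations, rng)
    members = [config.father_id, config.mother_id, config.child_id]
    lowq_mean = {m: config.lowq_depth_fraction * config.depths()[m] for m in members}

    new_records: list[TrioSiteRecord] = []
    new_truth = SimTruth(
        dnms=list(sim.truth.dnms),
        somatic=list(sim.truth.somatic),
        forced_het_positions=sim.truth.forced_het_positions,
        alt_background_positions=sim.truth.alt_background_positions,
        true_genotypes=dict(sim.truth.true_genotypes),
    )
    ref_bases = rng.integers(0, 4, size=n_spikes)
    alt_offsets = rng.integers(1, 4, size=n_spikes)
    for row, i in enumerate(chosen):
        i = int(i)
        pos = int(table.positions[i])
        ref = BASES[int(ref_bases[row])]
        alt = BASES[(int(ref_bases[row]) + int(alt_offsets[row])) % 4]
        calls = {}
        for col, m in enumerate(members):
            dp = int(table.dp[i, col])
            if m == config.child_id:
                call = _binomial_het_call(dp, eps, rng, config.gq_cap)
            else:
                n_alt = int(rng.binomial(dp, eps)) if dp else 0
                call = _scalar_call((0, 0), 2, dp, eps, rng, config.gq_cap,
                                    ad_override=(dp - n_alt, n_alt))
            call = _attach_strand_and_lowq(call, 1, lowq_mean[m], eps, rng)
            calls[m] = call
        new_records.append(TrioSiteRecord(
            chrom=config.chrom, pos=pos, ref_allele=ref, alt_alleles=(alt,),
            annotations=annotations[row], calls=calls,
        ))
        po = config.father_id if rng.random() < 0.5 else config.mother_id
        new_truth.dnms.append(DnmTruth(
            pos=pos, parent_of_origin=po, allele=alt,
            background="homref", kind="spike",
        ))
        new_truth.true_genotypes[pos] = ((0, 0), (0, 0), (0, 1))

    merged = sorted(sim.records + new_records, key=lambda r: (r.chrom, r.pos))
    return SimulatedTrio(
        config=config, records=merged, truth=new_truth,
        callable_table=sim.callable_table, depth_stats=sim.depth_stats,
    )


# ---------------------------------------------------------------------------
# third generation
# ---------------------------------------------------------------------------

def simulate_third_generation(
    sim: SimulatedTrio,
    seed: int,
    transmission_prob: float = 0.5,
    mean_depth: Optional[float] = None,
) -> SimulatedTrio:
    """Add a grandchild (offspring of the focal child and an unrelated,
    unsequenced homref-background parent) to every record.

    Each true child DNM (and spike) is transmitted with probability
    ``transmission_prob``; the truth ledger records the outcome.  At ordinary
    polymorphic sites the grandchild inherits one of the child's true alleles
    uniformly, plus a population allele (alt with probability 1/2 at
    polymorphic sites, the alt allele at fixed-difference sites, reference
    otherwise).
    """
    rng = np.random.default_rng(seed)
    config = sim.config
    eps = config.sequencing_error
    gid = config.grandchild_id
    depth = mean_depth if mean_depth is not None else config.depths()[config.child_id]
    fixed = set(sim.truth.alt_background_positions.tolist())
    dnm_by_pos = {d.pos: d for d in sim.truth.dnms}
    lowq_mean = config.lowq_depth_fraction * depth

    new_records = []
    for rec in sim.records:
        tg = sim.truth.true_genotypes.get(rec.pos)
        child_gt = tg[2] if tg is not None else (0, 0)
        k = len(rec.alleles)
        dn = dnm_by_pos.get(rec.pos)
        if dn is not None and dn.allele in rec.alleles:
            mut = rec.alleles.index(dn.allele)
            other = [a for a in child_gt if a != mut]
            other_allele = other[0] if other else 0
            transmitted = bool(rng.random() < transmission_prob)
            hap_child = mut if transmitted else other_allele
            dn.transmitted = transmitted
        else:
            hap_child = child_gt[int(rng.integers(0, 2))]
        if rec.pos in fixed:
            hap_pop = 1
        elif tg is not None and (1 in tg[0] or 1 in tg[1]) and rec.pos not in fixed:
            hap_pop = int(rng.random() < 0.5)
        else:
            hap_pop = 0
        g_gt = tuple(sorted((hap_child, hap_pop)))
        dp = int(rng.poisson(depth))
        call = _scalar_call(g_gt, k, dp, eps, rng, config.gq_cap)
        mut_index = rec.alleles.index(dn.allele) if (
            dn is not None and dn.allele in rec.alleles) else 1
        call = _attach_strand_and_lowq(call, min(mut_index, k - 1), lowq_mean, eps, rng)
        calls = dict(rec.calls)
        calls[gid] = call
        new_records.append(replace(rec, calls=calls))

    return SimulatedTrio(
        config=config, records=new_records, truth=sim.truth,
        callable_table=sim.callable_table, depth_stats=sim.depth_stats,
    )
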