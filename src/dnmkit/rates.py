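"""False-discovery correction, per-generation mutation rates, and the
binomial design calculators used when planning a trio sequencing study.

The headline quantity is the per-site per-generation rate of a diploid
genome,

    mu = N * (1 - FDR) / (2 * CG * (1 - FNR)),

where N is the number of candidate DNMs, FDR the false-discovery rate, CG
the callable genome in sites, and FNR the false-negative rate.  Confidence
intervals treat the corrected count as a binomial numerator over the diploid
callable denominator (Wilson score by default; Clopper-Pearson available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .denominator import CallableResult, FnrEstimate


class RateError(ValueError):
    pass


@dataclass
class FdrEstimate:
    value: float
    method: str  # validation | manual_curation | transmission | twin_discordance_input
    basis: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise RateError(f"FDR must lie in [0,1], got {self.value}")


@dataclass
class RateEstimate:
    mu: float
    n_candidates: float
    fdr: FdrEstimate
    cg: CallableResult
    fnr: FnrEstimate
    ci: tuple[float, float]
    ci_level: float
    ci_method: str

    def __post_init__(self):
        low, high = self.ci
        if not (low - 1e-15 <= self.mu <= high + 1e-15):
            raise RateError("confidence interval does not contain the estimate")

    def as_dict(self) -> dict:
        return {
            "mu": self.mu,
            "n_candidates": self.n_candidates,
            "fdr": {"value": self.fdr.value, "method": self.fdr.method},
            "cg_sites": self.cg.cg_sites,
            "cg_method": self.cg.method,
            "fnr": {"value": self.fnr.value, "method": self.fnr.method},
            "ci": list(self.ci),
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
        }


# ---------------------------------------------------------------------------
# FDR estimators
# ---------------------------------------------------------------------------

def fdr_from_validation(validated: int, failed: int) -> FdrEstimate:
    """FDR from amplification-and-resequencing outcomes.

    ``validated`` and ``failed`` are candidates that amplified successfully
    and passed / failed resequencing; candidates that did not amplify belong
    in neither count.
    """
    if validated < 0 or failed < 0:
        raise RateError("counts must be non-negative")
    total = validated + failed
    if total == 0:
        raise RateError("validation FDR undefined: no resolved candidates")
    return FdrEstimate(
        value=failed / total,
        method="validation",
        basis={"validated": validated, "failed": failed},
    )


def fdr_from_curation(curated_fp: int, total: int) -> FdrEstimate:
    """FDR from manual read-alignment curation: curated FPs over total."""
    if total <= 0 or not (0 <= curated_fp <= total):
        raise RateError("need 0 <= curated_fp <= total, total > 0")
    return FdrEstimate(
        value=curated_fp / total, method="manual_curation",
        basis={"curated_fp": curated_fp, "total": total},
    )


def fdr_from_transmission(transmitted: int, total: int) -> FdrEstimate:
    """FDR from the deviation of the transmission rate from 50%.

    Under the model that true DNMs transmit to the next generation at 50%
    and false positives never do, FDR = 1 - 2 * transmitted / total,
    clamped at 0.
    """
    if total <= 0:
        raise RateError("total must be positive")
    if transmitted > total:
        raise RateError("transmitted cannot exceed total")
    return FdrEstimate(
        value=max(0.0, 1.0 - 2.0 * transmitted / total),
        method="transmission",
        basis={"transmitted": transmitted, "total": total},
    )


def fdr_external(value: float, method: str = "twin_discordance_input") -> FdrEstimate:
    """Wrap an externally obtained FDR (e.g. monozygotic-twin discordance)."""
    return FdrEstimate(value=value, method=method)


def corrected_candidates(n: float, fdr: float) -> float:
    """Number of candidates after false-discovery correction: n * (1 - FDR)."""
    if not (0.0 <= fdr <= 1.0):
        raise RateError("fdr must lie in [0,1]")
    return n * (1.0 - fdr)


# ---------------------------------------------------------------------------
# rate and confidence interval
# ---------------------------------------------------------------------------

def rate_confidence_interval(
    effective_n: float,
    denominator_sites: float,
    level: float = 0.95,
    method: str = "wilson",
) -> tuple[float, float]:
    """Binomial CI for the per-site rate effective_n / denominator_sites.

    Wilson score by default (well-behaved for counts near zero); ``beta``
    gives the exact Clopper-Pearson interval.
    """
    if denominator_sites <= 0:
        raise RateError("denominator must be positive")
    if effective_n < 0 or effective_n > denominator_sites:
        raise RateError("need 0 <= effective_n <= denominator_sites")
    if not (0.0 < level < 1.0):
        raise RateError("level must lie in (0,1)")
    low, high = proportion_confint(
        effective_n, denominator_sites, alpha=1.0 - level, method=method
    )
    low = 0.0 if effective_n == 0 else min(max(float(low), 0.0), 1.0)
    high = 1.0 if effective_n == denominator_sites else min(max(float(high), 0.0), 1.0)
    p_hat = effective_n / denominator_sites
    return min(low, p_hat), max(high, p_hat)


def mutation_rate(
    n: float,
    fdr: FdrEstimate | float,
    cg: CallableResult | float,
    fnr: FnrEstimate | float,
    ci_level: float = 0.95,
    ci_method: str = "wilson",
) -> RateEstimate:
    """Per-site per-generation mutation rate with its four ingredients.

    mu = n * (1 - FDR) / (2 * CG * (1 - FNR)).  The CI is computed on the
    corrected count over the diploid, FNR-adjusted denominator; uncertainty
    in FDR and FNR themselves is not propagated.
    """
    fdr_est = fdr if isinstance(fdr, FdrEstimate) else FdrEstimate(float(fdr), "manual_curation")
    cg_res = cg if isinstance(cg, CallableResult) else CallableResult(
        cg_sites=float(cg), method="count_based", total_sites=0
    )
    fnr_est = fnr if isinstance(fnr, FnrEstimate) else FnrEstimate(float(fnr), "ab_empirical")
    if cg_res.cg_sites <= 0:
        raise RateError("callable genome must be positive")
    if fnr_est.value >= 1.0:
        raise RateError("FNR of 1 leaves no detection power")
    effective_n = corrected_candidates(n, fdr_est.value)
    denominator = 2.0 * cg_res.cg_sites * (1.0 - fnr_est.value)
    mu = effective_n / denominator
    ci = rate_confidence_interval(effective_n, denominator, ci_level, ci_method)
    return RateEstimate(
        mu=mu, n_candidates=n, fdr=fdr_est, cg=cg_res, fnr=fnr_est,
        ci=ci, ci_level=ci_level, ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# study-design calculators
# ---------------------------------------------------------------------------

def allele_dropout_probability(depth: int) -> float:
    """Probability that no read samples one given allele of a heterozygote
    at the given depth: 0.5 ** depth."""
    if depth < 0:
        raise RateError("depth must be non-negative")
    return 0.5 ** depth

def expected_dropout_sites(depth: int, n_het_sites: float) -> float:
    """Expected number of heterozygous sites showing allele dropout."""
    if n_het_sites < 0:
        raise RateError("n_het_sites must be non-negative")
    return n_het_sites * allele_dropout_probability(depth)


def somatic_leak_probability(
    depth: int, cell_fraction: float, read_fraction_threshold: float
) -> float:
    """Probability a mosaic variant clears a read-fraction threshold.

    Models the variant-read fraction as equal to the cell fraction:
    P(X >= ceil(threshold * depth)) with X ~ Binomial(depth, cell_fraction).
    """
    for name, v in (("cell_fraction", cell_fraction),
                    ("read_fraction_threshold", read_fraction_threshold)):
        if not (0.0 <= v <= 1.0):
            raise RateError(f"{name} must lie in [0,1]")
    k = math.ceil(read_fraction_threshold * depth)
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, depth, cell_fraction))


def alt_background_fraction(divergence: float) -> float:
    """Approximate fraction of true DNMs arising where both parents are
    homozygous for the alternative allele.

    Under the approximation that fixed differences to the reference occur at
    the sequence divergence rate, this fraction simply equals the divergence
    (e.g. 0.02 -> 1 in 50 DNMs).
    """
    if not (0.0 <= divergence <= 1.0):
        raise RateError("divergence must lie in [0,1]")
    return divergence
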