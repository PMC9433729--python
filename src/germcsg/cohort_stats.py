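"""Cohort-level statistics: diagnostic yield, burden tests, phenotype contrasts.

Diagnostic yield uses the exact (Clopper-Pearson) binomial interval in its
beta-quantile form — the only standard interval that reproduces published
yield CIs at 1-decimal percentage rounding. Per-gene carrier burden compares
the number of carriers (participants with >= 1 filter-retained variant in the
gene, counted once) between case and control cohorts with a two-sided
Fisher's exact test, followed by Benjamini-Hochberg step-up FDR across the
tested gene set. Age contrasts use Welch's two-sample t-test with
Satterthwaite degrees of freedom. Reported percentages round half-up to one
decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import (
    AnnotatedVariant,
    CohortTable,
    GeneModel,
    Role,
    ValidationError,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as in the published tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(x: float, ndigits: int = 1) -> float:
    return round_half_up(100.0 * x, ndigits)


# ---------------------------------------------------------------------------
# diagnostic yield
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YieldEstimate:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    @property
    def as_percent(self) -> tuple[float, float, float]:
        """(proportion, ci_low, ci_high) as half-up-rounded percentages, 1 d.p."""
        return (percent(self.proportion), percent(self.ci_low), percent(self.ci_high))


def diagnostic_yield(carriers: int, cohort_size: int,
                     confidence: float = 0.95) -> YieldEstimate:
    """Carrier proportion with an exact Clopper-Pearson binomial CI."""
    if cohort_size <= 0:
        raise ValidationError("cohort_size must be positive")
    if not (0 <= carriers <= cohort_size):
        raise ValidationError(f"carriers {carriers} outside [0, {cohort_size}]")
    alpha = 1.0 - confidence
    lo = 0.0 if carriers == 0 else float(
        stats.beta.ppf(alpha / 2, carriers, cohort_size - carriers + 1))
    hi = 1.0 if carriers == cohort_size else float(
        stats.beta.ppf(1 - alpha / 2, carriers + 1, cohort_size - carriers))
    return YieldEstimate(carriers, cohort_size, carriers / cohort_size, lo, hi, confidence)


def combine_yield(
    short_variant_carriers: int | Iterable[str],
    short_cohort: int,
    sv_carriers: int | Iterable[str],
    confidence: float = 0.95,
) -> YieldEstimate:
    """Combined short-variant + SV yield over the short-variant cohort size.

    Pass participant-id collections to de-duplicate dual carriers; bare counts
    are summed as-is (the caller asserts disjointness).
    """
    if isinstance(short_variant_carriers, int) != isinstance(sv_carriers, int):
        raise ValidationError(
            "pass ids for both carrier sets (to de-duplicate) or counts for both")
    if isinstance(short_variant_carriers, int):
        numerator = short_variant_carriers + sv_carriers
    else:
        numerator = len(set(short_variant_carriers) | set(sv_carriers))
    return diagnostic_yield(numerator, short_cohort, confidence)


# ---------------------------------------------------------------------------
# Fisher's exact test and group contrasts
# ---------------------------------------------------------------------------


class TestKind(str, Enum):
    fisher_exact = "fisher_exact"
    welch_t = "welch_t"


@dataclass(frozen=True)
class GroupComparison:
    test: TestKind
    statistic: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]] | None = None


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (sample odds ratio, p).

    The odds ratio is the sample OR ad/bc (inf when bc = 0 and ad > 0, nan on
    an all-zero margin, where p = 1 by convention).
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    odds = float("inf") if b * c == 0 else (a * d) / (b * c)
    return odds, p


def compare_groups_fisher(a: int, b: int, c: int, d: int) -> GroupComparison:
    odds, p = fisher_exact_2x2(a, b, c, d)
    return GroupComparison(TestKind.fisher_exact, odds, p, ((a, b), (c, d)))


def welch_age_test(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Welch's two-sample t-test (unequal variances, Satterthwaite df), two-sided."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("Welch's t-test needs >= 2 observations per group")
    res = stats.ttest_ind(np.asarray(group_a, float), np.asarray(group_b, float),
                          equal_var=False)
    return GroupComparison(TestKind.welch_t, float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# per-gene carrier burden
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurdenResult:
    gene_symbol: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int
    odds_ratio: float
    p_value: float
    q_value: float


def carriers_by_gene(variants: Iterable[AnnotatedVariant],
                     participant_ids: set[str]) -> dict[str, set[str]]:
    """gene -> set of carrier participant ids, restricted to the given participants."""
    out: dict[str, set[str]] = {}
    for v in variants:
        if v.participant_id in participant_ids:
            out.setdefault(v.gene_symbol, set()).add(v.participant_id)
    return out


def burden_from_counts(
    counts: Mapping[str, tuple[int, int]],
    case_total: int,
    control_total: int,
) -> list[BurdenResult]:
    """Fisher per gene on (case carriers, control carriers) + BH q across all genes."""
    if control_total <= 0:
        raise ValidationError("empty control set")
    genes = sorted(counts)
    raw = []
    for g in genes:
        ca, co = counts[g]
        if ca > case_total or co > control_total:
            raise ValidationError(f"{g}: carriers exceed cohort totals")
        odds, p = fisher_exact_2x2(ca, case_total - ca, co, control_total - co)
        raw.append((g, ca, co, odds, p))
    pvals = np.array([r[4] for r in raw])
    if len(pvals):
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = np.array([])
    return [
        BurdenResult(g, ca, case_total, co, control_total, odds, p, float(q))
        for (g, ca, co, odds, p), q in zip(raw, qvals)
    ]


def burden_test(
    cases: CohortTable,
    controls: CohortTable,
    retained_variants: Sequence[AnnotatedVariant],
    panel: Sequence[GeneModel],
    ancestry_filter: str | None = "EUR",
    genes: str = "all",
) -> list[BurdenResult]:
    """Per-gene carrier burden of filter-retained variants, cases vs controls.

    ``genes`` selects the FDR family: "all" tests every panel gene;
    "with_case_carriers" restricts to genes carried by >= 1 case.
    """
    if genes not in ("all", "with_case_carriers"):
        raise ValidationError(f"unknown gene-family mode {genes!r}")
    case_ids = {p.participant_id for p in cases.subset(Role.case, ancestry_filter)}
    control_ids = {p.participant_id for p in controls.subset(Role.control, ancestry_filter)}
    if not control_ids:
        raise ValidationError("empty control set")
    case_carr = carriers_by_gene(retained_variants, case_ids)
    control_carr = carriers_by_gene(retained_variants, control_ids)
    tested = [g.gene_symbol for g in panel]
    if genes == "with_case_carriers":
        tested = [g for g in tested if case_carr.get(g)]
    counts = {g: (len(case_carr.get(g, ())), len(control_carr.get(g, ()))) for g in tested}
    return burden_from_counts(counts, len(case_ids), len(control_ids))


# ---------------------------------------------------------------------------
# burden power / calibration
# ---------------------------------------------------------------------------


def simulate_burden_power(
    case_freq: float,
    control_freq: float,
    *,
    n_cases: int = 1336,
    n_controls: int = 5834,
    null_freq: float = 0.002,
    n_null_genes: int = 120,
    replicates: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the burden test for one gene with a true effect.

    Each replicate draws per-gene carrier counts as independent binomials
    (the generative model the cohort simulator uses for carriers), runs the
    Fisher + BH pipeline over the target gene plus ``n_null_genes`` null
    genes, and scores a detection when the target's q-value falls below
    ``alpha``.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xB02D])
    hits = 0
    for _ in range(replicates):
        counts = {"TARGET": (int(rng.binomial(n_cases, case_freq)),
                             int(rng.binomial(n_controls, control_freq)))}
        for i in range(n_null_genes):
            counts[f"NULL{i:03d}"] = (int(rng.binomial(n_cases, null_freq)),
                                      int(rng.binomial(n_controls, null_freq)))
        results = {r.gene_symbol: r for r in
                   burden_from_counts(counts, n_cases, n_controls)}
        if results["TARGET"].q_value < alpha:
            hits += 1
    return hits / replicates


def null_pvalues_by_label_permutation(
    *,
    n_cases: int = 1336,
    n_controls: int = 5834,
    carrier_freq: float = 0.002,
    n_genes: int = 20,
    permutations: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Burden-test p-values with case/control labels permuted (a true null).

    Carrier sets are held fixed while labels are permuted; the induced
    case-carrier count is then exactly hypergeometric, which is how it is
    drawn here. Fisher's exact test is conservative on discrete counts, so
    these p-values stochastically dominate the uniform distribution.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0x9E11])
    total = n_cases + n_controls
    n_carriers = rng.binomial(total, carrier_freq, size=n_genes)
    pvals = []
    for _ in range(permutations):
        for k in n_carriers:
            a = int(rng.hypergeometric(k, total - k, n_cases))
            _, p = fisher_exact_2x2(a, n_cases - a, int(k) - a,
                                    n_controls - (int(k) - a))
            pvals.append(p)
    return np.asarray(pvals)


# ---------------------------------------------------------------------------
# age-cutoff sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeCutoffPoint:
    cutoff: float
    carriers_detected: int
    sensitivity: float          # detected / total carriers
    cohort_under_cutoff: int
    cohort_fraction_under_cutoff: float


def age_cutoff_sweep(
    carrier_ages: Sequence[float],
    cohort_ages: Sequence[float],
    cutoffs: Sequence[float],
) -> list[AgeCutoffPoint]:
    """For each cutoff c: carriers with age < c (testing sensitivity) and the
    share of the whole cohort that would fall under the cutoff."""
    if len(carrier_ages) == 0:
        raise ValidationError("no carrier ages supplied")
    if len(cohort_ages) == 0:
        raise ValidationError("no cohort ages supplied")
    carr = np.asarray(carrier_ages, float)
    coh = np.asarray(cohort_ages, float)
    out = []
    for c in cutoffs:
        detected = int((carr < c).sum())
        under = int((coh < c).sum())
        out.append(AgeCutoffPoint(float(c), detected, detected / len(carr),
                                  under, under / len(coh)))
    return out
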