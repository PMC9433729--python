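"""Structural-variant / gene-model intersection.

A gene is hit when at least one breakpoint falls inside its interval; for
deletions, genes wholly contained in the deleted span are also reported
(default on) — a deletion starting upstream of a gene can remove it without
either breakpoint lying inside it. For deletions the exon indices removed
are annotated; an exon partially overlapped by the deleted span counts as
removed, since a disrupted exon is functionally lost.

Retention filtering is declarative: predicates are (quality field, operator,
threshold) triples evaluated on caller-provided SV quality fields. The
stringent mode applies every configured predicate; the relaxed mode drops a
configured subset, so the stringent-retained set is always a subset of the
relaxed-retained set. The default predicate set is a placeholder standing in
for caller-specific quality filters and should be replaced per call set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .core_model import GeneModel, SVCall, SvFilterMode, SvType, ValidationError


@dataclass(frozen=True)
class SvGeneHit:
    sv: SVCall
    gene: GeneModel
    breakpoints_in_gene: int
    exons_removed: tuple[int, ...] = ()
    fraction_gene_deleted: float = 0.0


def exons_removed(deletion: SVCall, gene: GeneModel) -> list[int]:
    """1-based indices of exons wholly or partly inside the deleted span."""
    if deletion.sv_type is not SvType.deletion:
        raise ValidationError(
            f"exons_removed expects a deletion, got {deletion.sv_type.value}")
    sv = deletion.normalized()
    chrom = sv.breakpoint_a[0]
    if chrom != gene.chromosome:
        return []
    lo, hi = sv.span
    return [i for i, (a, b) in enumerate(gene.exons, start=1) if a <= hi and b >= lo]


def _fraction_deleted(sv: SVCall, gene: GeneModel) -> float:
    lo, hi = sv.span
    overlap = min(hi, gene.gene_end) - max(lo, gene.gene_start) + 1
    return max(overlap, 0) / gene.length


def breakpoint_overlap(
    sv: SVCall,
    panel: Iterable[GeneModel],
    include_contained_genes: bool = True,
) -> list[SvGeneHit]:
    """All panel genes hit by this SV (>=1 breakpoint inside, or fully deleted)."""
    sv = sv.normalized()
    hits: list[SvGeneHit] = []
    for gene in panel:
        n_bp = sum(gene.contains(*bp) for bp in (sv.breakpoint_a, sv.breakpoint_b))
        contained = False
        if (include_contained_genes and n_bp == 0
                and sv.sv_type is SvType.deletion
                and sv.breakpoint_a[0] == gene.chromosome):
            lo, hi = sv.span
            contained = lo <= gene.gene_start and gene.gene_end <= hi
        if n_bp == 0 and not contained:
            continue
        if sv.sv_type is SvType.deletion:
            ex = tuple(exons_removed(sv, gene))
            frac = _fraction_deleted(sv, gene)
        else:
            ex, frac = (), 0.0
        hits.append(SvGeneHit(sv, gene, n_bp, ex, frac))
    return hits


def overlap_all(svs: Sequence[SVCall], panel: Sequence[GeneModel],
                include_contained_genes: bool = True) -> list[SvGeneHit]:
    out: list[SvGeneHit] = []
    for sv in svs:
        out.extend(breakpoint_overlap(sv, panel, include_contained_genes))
    return out


# ---------------------------------------------------------------------------
# declarative retention filtering
# ---------------------------------------------------------------------------

OPS = {
    "ge": lambda value, threshold: value >= threshold,
    "le": lambda value, threshold: value <= threshold,
    "eq": lambda value, threshold: value == threshold,
}


@dataclass(frozen=True)
class SvPredicate:
    quality_key: str
    op: str  # ge | le | eq
    threshold: float | str

    def __post_init__(self):
        if self.op not in OPS:
            raise ValidationError(f"unknown predicate operator {self.op!r}")

    def evaluate(self, sv: SVCall) -> bool:
        if self.quality_key not in sv.quality:
            raise ValidationError(
                f"{sv.participant_id}: SV lacks quality field {self.quality_key!r} "
                f"required by a filter predicate")
        return OPS[self.op](sv.quality[self.quality_key], self.threshold)


@dataclass(frozen=True)
class SvFilterConfig:
    """Placeholder defaults; real predicate sets are caller-pipeline specific."""

    predicates: dict[str, SvPredicate] = field(default_factory=lambda: {
        "min_paired_read_support": SvPredicate("support_reads", "ge", 5),
        "max_cohort_frequency": SvPredicate("cohort_freq", "le", 0.01),
        "caller_pass": SvPredicate("caller_filter", "eq", "PASS"),
    })
    relaxed_exempt: frozenset[str] = frozenset({"caller_pass"})

    def __post_init__(self):
        unknown = self.relaxed_exempt - set(self.predicates)
        if unknown:
            raise ValidationError(f"relaxed_exempt names unknown predicates {sorted(unknown)}")


def filter_svs(
    svs: Sequence[SVCall],
    mode: SvFilterMode | str,
    config: SvFilterConfig | None = None,
) -> list[SVCall]:
    """Apply the stringent or relaxed predicate set; retained SVs are tagged with the mode."""
    mode = SvFilterMode(mode)
    if mode is SvFilterMode.none:
        raise ValidationError("filter mode must be stringent or relaxed")
    config = config or SvFilterConfig()
    active = [p for name, p in sorted(config.predicates.items())
              if mode is SvFilterMode.stringent or name not in config.relaxed_exempt]
    retained = []
    for sv in svs:
        if all(p.evaluate(sv) for p in active):
            retained.append(replace(sv, filter_mode_passed=mode))
    return retained
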