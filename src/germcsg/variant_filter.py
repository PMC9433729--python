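"""Short-variant prioritization cascade.

A variant observation is retained when it lies in a panel gene, is rare
(gnomAD-style popmax allele frequency strictly below the threshold, default
0.5%), and is either loss-of-function (VEP HIGH impact) or a functionally
important MODERATE-impact variant: a missense call must be SIFT-deleterious,
PolyPhen possibly/probably damaging and have CADD Phred >= 20 (inclusive);
an inframe indel only needs the CADD bound. Rules run in a fixed order
(panel -> rarity -> consequence) and every decision is traced. Missing
SIFT/PolyPhen/CADD scores fail the MODERATE clause: a prediction that was
never made is not treated as damaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .core_model import (
    AnnotatedVariant,
    GeneModel,
    HIGH_IMPACT_CONSEQUENCES,
    Consequence,
    Panel,
    PolyPhen,
    Sift,
    ValidationError,
)

logger = logging.getLogger("germcsg")


class PanelScope(str, Enum):
    RCC_CSG = "RCC_CSG"
    OTHER_CSG = "OTHER_CSG"
    ALL = "ALL"


@dataclass(frozen=True)
class FilterConfig:
    max_popmax_af: float = 0.005   # exclusive bound
    cadd_min: float = 20.0         # inclusive bound
    require_sift_deleterious: bool = True
    require_polyphen_damaging: bool = True
    panel_scope: PanelScope = PanelScope.ALL

    def __post_init__(self):
        if not (0.0 < self.max_popmax_af <= 1.0):
            raise ValidationError(f"max_popmax_af {self.max_popmax_af} outside (0, 1]")
        if self.cadd_min < 0:
            raise ValidationError(f"cadd_min {self.cadd_min} must be non-negative")


@dataclass
class FilterTrace:
    """Ordered record of (rule, passed) pairs; evaluation stops at the first failure."""

    variant: AnnotatedVariant
    rules: list[tuple[str, bool]] = field(default_factory=list)
    final_retained: bool = False

    @property
    def first_failed(self) -> str | None:
        for name, ok in self.rules:
            if not ok:
                return name
        return None


RULE_PANEL = "panel"
RULE_RARITY = "rarity"
RULE_CONSEQUENCE = "consequence"


def popmax_af(variant: AnnotatedVariant) -> float:
    """Maximum allele frequency across all annotated populations.

    A variant with no frequency annotation at all is treated as novel
    (popmax 0), the standard convention for variants absent from gnomAD.
    """
    if not variant.af_by_population:
        logger.warning("%s: no population frequencies — treating as novel (popmax 0)",
                       variant.hgvs_c)
        return 0.0
    return max(variant.af_by_population.values())


def _panel_genes(panel: Iterable[GeneModel], scope: PanelScope) -> set[str]:
    if scope is PanelScope.ALL:
        return {g.gene_symbol for g in panel}
    return {g.gene_symbol for g in panel if g.panel.value == scope.value}


def _consequence_retained(v: AnnotatedVariant, config: FilterConfig) -> bool:
    if v.consequence in HIGH_IMPACT_CONSEQUENCES:
        return True
    cadd_ok = v.cadd_phred is not None and v.cadd_phred >= config.cadd_min
    if v.consequence is Consequence.missense:
        sift_ok = (not config.require_sift_deleterious) or v.sift is Sift.deleterious
        poly_ok = (not config.require_polyphen_damaging) or v.polyphen in (
            PolyPhen.possibly_damaging, PolyPhen.probably_damaging)
        return sift_ok and poly_ok and cadd_ok
    if v.consequence is Consequence.inframe_indel:
        return cadd_ok
    return False


def apply_filter_cascade(
    variants: Sequence[AnnotatedVariant],
    panel: Sequence[GeneModel],
    config: FilterConfig | None = None,
) -> tuple[list[AnnotatedVariant], list[FilterTrace]]:
    """Run the cascade; returns the retained variants and one trace per input variant."""
    config = config or FilterConfig()
    in_panel = _panel_genes(panel, config.panel_scope)
    retained: list[AnnotatedVariant] = []
    traces: list[FilterTrace] = []
    for v in variants:
        trace = FilterTrace(v)
        checks = (
            (RULE_PANEL, lambda v=v: v.gene_symbol in in_panel),
            (RULE_RARITY, lambda v=v: popmax_af(v) < config.max_popmax_af),
            (RULE_CONSEQUENCE, lambda v=v: _consequence_retained(v, config)),
        )
        ok = True
        for name, check in checks:
            passed = check()
            trace.rules.append((name, passed))
            if not passed:
                ok = False
                break
        trace.final_retained = ok
        traces.append(trace)
        if ok:
            retained.append(v)
    return retained, traces
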