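import numpy as np
import pytest

from germcsg import load_packaged_panel
from germcsg.core_model import (
    AnnotatedVariant,
    Consequence,
    GeneModel,
    ImpactTier,
    Panel,
    PolyPhen,
    Sift,
    Zygosity,
)

HIGH = (Consequence.stop_gained, Consequence.stop_lost, Consequence.frameshift,
        Consequence.splice_disruption, Consequence.start_lost)
MODERATE = (Consequence.missense, Consequence.inframe_indel)


@pytest.fixture(scope="session")
def panel():
    return load_packaged_panel()


@pytest.fixture(scope="session")
def panel_by_symbol(panel):
    return {g.gene_symbol: g for g in panel}


def impact_for(consequence: Consequence) -> ImpactTier:
    if consequence in HIGH:
        return ImpactTier.HIGH
    if consequence in MODERATE:
        return ImpactTier.MODERATE
    return ImpactTier.LOW if consequence is Consequence.synonymous else ImpactTier.MODIFIER


def random_variant(rng: np.random.Generator, gene_symbols) -> AnnotatedVariant:
    """A random but internally consistent variant observation."""
    consequence = Consequence(list(Consequence)[rng.integers(len(Consequence))])
    n_pops = int(rng.integers(0, 4))
    afs = {f"p{i}": float(rng.uniform(0, 0.02)) for i in range(n_pops)}
    return AnnotatedVariant(
        participant_id=f"R{rng.integers(1, 500):04d}",
        gene_symbol=str(gene_symbols[rng.integers(len(gene_symbols))]),
        hgvs_c=f"c.{rng.integers(1, 9999)}A>G",
        consequence=consequence,
        impact_tier=impact_for(consequence),
        af_by_population=afs,
        sift=list(Sift)[rng.integers(3)],
        polyphen=list(PolyPhen)[rng.integers(4)],
        cadd_phred=None if rng.random() < 0.25 else float(rng.uniform(0, 40)),
        zygosity=Zygosity.het,
    )


def toy_gene(symbol="TOY1", chrom="1", start=1000, exons=((1000, 1100), (1500, 1600), (2000, 2100)),
             end=2500, panel=Panel.RCC_CSG) -> GeneModel:
    return GeneModel(symbol, chrom, start, end, tuple(exons), panel, "ENST_TOY")
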