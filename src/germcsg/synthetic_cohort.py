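"""Synthetic case/control cohorts with known classification truth.

The generator emulates the structure of a WGS cancer-predisposition study:
1336 renal-cell-carcinoma cases versus 5834 healthy controls by default,
with per-gene carrier frequencies, phenotypes drawn from the published
cohort's marginal distributions (mean age at diagnosis 61.3 y, SD 12, range
13-88, truncated normal; 64% male; the published histology/stage mix), and
one annotated variant per simulated carrier. Every variant gets a planted
five-tier truth class (with ACGS temperature for VUSs) realised as a set of
ACMG evidence codes whose point total lands in the class's band, plus
annotations (consequence, population frequencies, SIFT/PolyPhen/CADD) drawn
conditional on the truth class, so the filter cascade and the classifier
have known expected behaviour. With zero annotation noise, planted codes
pushed through the classification engine reproduce the truth classes
exactly.

Controls are emulated only through lower carrier frequencies (the study's
controls were healthy unrelated parents); no pedigree or population
structure is modelled. Control carrier frequencies are order-of-magnitude
configuration guesses, not estimates — the study did not publish per-gene
control counts.

Each consumer draws from its own RNG stream derived from the master seed,
so unrelated draws do not perturb each other.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    AnnotatedVariant,
    CohortTable,
    Consequence,
    Histology,
    ImpactTier,
    Participant,
    PolyPhen,
    Role,
    Sift,
    Stage,
    ValidationError,
    Zygosity,
    write_participant_table,
    write_sv_table,
    write_variant_table,
)
from .acmg_engine import EvidenceProfile, FiveTier, Temperature, classify_profile
from .mutational_signatures import load_signature_matrix

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

TRUTH_CLASSES = ("P", "LP", "VUS_hot", "VUS_warm", "VUS_tepid",
                 "VUS_cool", "VUS_cold", "VUS_ice_cold", "LB", "B")

#: canonical evidence-code set planted for each truth class (points in brackets)
CLASS_EVIDENCE: dict[str, tuple[str, ...]] = {
    "P": ("PVS1", "PM2"),            # 10
    "LP": ("PS1", "PM2"),            # 6
    "VUS_hot": ("PM1", "PM2", "PP3"),  # 5
    "VUS_warm": ("PM1", "PM2"),      # 4
    "VUS_tepid": ("PM2", "PP3"),     # 3
    "VUS_cool": ("PM2",),            # 2
    "VUS_cold": ("PP3",),            # 1
    "VUS_ice_cold": (),              # 0
    "LB": ("BS1", "BP4"),            # -5
    "B": ("BS1", "BS2"),             # -8
}

#: default per-gene (case frequency, control frequency); case values follow the
#: published carrier counts, control values are order-of-magnitude guesses.
DEFAULT_CARRIER_FREQ: dict[str, tuple[float, float]] = {
    "CHEK2": (0.020, 0.005), "MITF": (0.007, 0.002), "SDHA": (0.005, 0.0015),
    "VHL": (0.005, 0.0005), "FLCN": (0.003, 0.0008), "FH": (0.002, 0.0006),
    "SDHB": (0.0015, 0.0005), "ATM": (0.007, 0.003), "FANCM": (0.003, 0.002),
    "BRIP1": (0.002, 0.001), "MSH6": (0.002, 0.001), "BRCA2": (0.0015, 0.001),
    "PMS2": (0.0015, 0.001), "TP53": (0.0015, 0.0008), "MSH2": (0.0007, 0.0005),
    "PALB2": (0.0007, 0.0005),
}

DEFAULT_TRUTH_MIX: dict[str, float] = {
    "P": 0.15, "LP": 0.20, "VUS_hot": 0.10, "VUS_warm": 0.03, "VUS_tepid": 0.06,
    "VUS_cool": 0.02, "VUS_cold": 0.02, "VUS_ice_cold": 0.07, "LB": 0.15, "B": 0.20,
}

HISTOLOGY_MIX: dict[Histology, float] = {
    Histology.clear_cell: 0.677, Histology.non_clear_cell: 0.170,
    Histology.unspecified: 0.107, Histology.not_available: 0.046,
}
STAGE_MIX: dict[Stage, float] = {
    Stage.s1: 0.399, Stage.s2: 0.089, Stage.s3: 0.303, Stage.s4: 0.084,
    Stage.unclassified: 0.001, Stage.not_available: 0.124,
}
ANCESTRY_MIX: dict[str, float] = {"EUR": 0.89, "ASN": 0.04, "AFR": 0.02, "OTH": 0.05}
OTHER_CANCER_MIX: dict[int, float] = {0: 0.816, 1: 0.147, 2: 0.027, 3: 0.010}

POPULATIONS = ("afr", "eas", "nfe", "sas")


@dataclass(frozen=True)
class AnnotationNoise:
    """Probabilities perturbing the annotation layer (not the planted codes)."""

    missing_score_rate: float = 0.02      # each in-silico score independently absent
    benign_look_rate: float = 0.90        # true-benign variant looks benign (fails cascade)

    def __post_init__(self):
        for name, p in (("missing_score_rate", self.missing_score_rate),
                        ("benign_look_rate", self.benign_look_rate)):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} {p} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 1336
    n_controls: int = 5834
    seed: int = 0
    per_gene_carrier_freq: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CARRIER_FREQ))
    truth_class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_MIX))
    age_mean: float = 61.3
    age_sd: float = 12.0
    age_range: tuple[float, float] = (13.0, 88.0)
    male_fraction: float = 0.64
    annotation_noise: AnnotationNoise = field(default_factory=AnnotationNoise)

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ValidationError("n_cases must be positive")
        if self.n_controls <= 0:
            raise ValidationError("n_controls must be positive")
        for gene, (fa, fb) in self.per_gene_carrier_freq.items():
            for f in (fa, fb):
                if not (0.0 <= f <= 1.0):
                    raise ValidationError(f"{gene}: carrier frequency {f} outside [0, 1]")
        total = sum(self.truth_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"truth_class_mix sums to {total}, expected 1")
        unknown = set(self.truth_class_mix) - set(TRUTH_CLASSES)
        if unknown:
            raise ValidationError(f"unknown truth classes {sorted(unknown)}")


@dataclass(frozen=True)
class TruthRecord:
    participant_id: str
    gene_symbol: str
    hgvs_c: str
    true_class: str
    evidence_codes: tuple[str, ...]


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------


def stream(seed: int, name: str) -> np.random.Generator:
    """A named child stream of the master seed, stable under unrelated draws."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      lo: float, hi: float) -> np.ndarray:
    """Rejection-sampled truncated normal ages."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _categorical(rng, keys, probs, size):
    p = np.asarray(probs, float)
    return rng.choice(len(keys), size=size, p=p / p.sum())


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _simulate_participants(config: SimulationConfig) -> list[Participant]:
    rng = stream(config.seed, "phenotypes")
    lo, hi = config.age_range
    ages = _truncated_normal(rng, config.n_cases, config.age_mean, config.age_sd, lo, hi)
    sexes = rng.random(config.n_cases) < config.male_fraction
    hist_keys = list(HISTOLOGY_MIX)
    hist_idx = _categorical(rng, hist_keys, list(HISTOLOGY_MIX.values()), config.n_cases)
    stage_keys = list(STAGE_MIX)
    stage_idx = _categorical(rng, stage_keys, list(STAGE_MIX.values()), config.n_cases)
    anc_keys = list(ANCESTRY_MIX)
    anc_idx = _categorical(rng, anc_keys, list(ANCESTRY_MIX.values()), config.n_cases)
    multi = rng.random(config.n_cases) < 0.036
    oc_keys = list(OTHER_CANCER_MIX)
    oc_idx = _categorical(rng, oc_keys, list(OTHER_CANCER_MIX.values()), config.n_cases)
    participants = [
        Participant(
            participant_id=f"C{i + 1:05d}",
            role=Role.case,
            sex="male" if sexes[i] else "female",
            ancestry_label=anc_keys[anc_idx[i]],
            age_at_diagnosis=round(float(ages[i]), 1),
            histology=hist_keys[hist_idx[i]],
            stage=stage_keys[stage_idx[i]],
            n_rcc_tumours=2 if multi[i] else 1,
            other_cancers=int(oc_keys[oc_idx[i]]),
        )
        for i in range(config.n_cases)
    ]
    ctrl_sex = rng.random(config.n_controls) < 0.5
    participants += [
        Participant(
            participant_id=f"K{i + 1:05d}",
            role=Role.control,
            sex="male" if ctrl_sex[i] else "female",
            ancestry_label="EUR",  # the study's controls were all European-ancestry
        )
        for i in range(config.n_controls)
    ]
    return participants


_LOF_CONSEQUENCES = (Consequence.stop_gained, Consequence.frameshift,
                     Consequence.splice_disruption)


def _annotations_for_class(rng: np.random.Generator, true_class: str,
                           noise: AnnotationNoise) -> dict:
    """Draw consequence/AF/in-silico fields conditional on the planted class."""
    benign_truth = true_class in ("LB", "B")
    benign_look = benign_truth and rng.random() < noise.benign_look_rate

    if true_class in ("P", "LP") and rng.random() < 0.8:
        consequence = _LOF_CONSEQUENCES[rng.integers(len(_LOF_CONSEQUENCES))]
    else:
        consequence = Consequence.missense

    if benign_look:
        style = rng.integers(3)
        if style == 0:  # too common
            afs = {p: round(float(rng.uniform(0.01, 0.2)), 6) for p in POPULATIONS}
            sift, poly = Sift.deleterious, PolyPhen.possibly_damaging
            cadd = round(float(rng.uniform(20, 35)), 2)
        elif style == 1:  # benign in-silico profile
            afs = {p: round(float(rng.uniform(0, 0.002)), 6) for p in POPULATIONS}
            sift, poly = Sift.tolerated, PolyPhen.benign
            cadd = round(float(rng.uniform(0, 15)), 2)
            consequence = Consequence.missense
        else:  # sub-threshold CADD
            afs = {p: round(float(rng.uniform(0, 0.002)), 6) for p in POPULATIONS}
            sift, poly = Sift.deleterious, PolyPhen.possibly_damaging
            cadd = round(float(rng.uniform(10, 19.9)), 2)
            consequence = Consequence.missense
    else:
        afs = ({} if rng.random() < 0.1 else  # novel variant, absent from gnomAD
               {p: round(float(rng.uniform(0, 0.002)), 6) for p in POPULATIONS})
        sift = Sift.deleterious
        poly = (PolyPhen.probably_damaging if rng.random() < 0.6
                else PolyPhen.possibly_damaging)
        cadd = round(float(rng.uniform(20, 35)), 2)

    if consequence in _LOF_CONSEQUENCES:
        impact, sift, poly, cadd = ImpactTier.HIGH, Sift.absent, PolyPhen.absent, None
    else:
        impact = ImpactTier.MODERATE
        if rng.random() < noise.missing_score_rate:
            sift = Sift.absent
        if rng.random() < noise.missing_score_rate:
            poly = PolyPhen.absent
        if rng.random() < noise.missing_score_rate:
            cadd = None
    return dict(consequence=consequence, impact_tier=impact, af_by_population=afs,
                sift=sift, polyphen=poly, cadd_phred=cadd)


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTable, list[TruthRecord]]:
    """Generate the cohort; identical config (incl. seed) gives identical output."""
    participants = _simulate_participants(config)
    case_ids = [p.participant_id for p in participants if p.role is Role.case]
    control_ids = [p.participant_id for p in participants if p.role is Role.control]

    mix_keys = [k for k in TRUTH_CLASSES if config.truth_class_mix.get(k, 0) > 0]
    mix_p = np.array([config.truth_class_mix[k] for k in mix_keys], float)
    mix_p /= mix_p.sum()

    variants: list[AnnotatedVariant] = []
    truth: list[TruthRecord] = []
    for gene in sorted(config.per_gene_carrier_freq):
        case_f, control_f = config.per_gene_carrier_freq[gene]
        rng = stream(config.seed, f"gene:{gene}")
        counter = 0
        for ids, freq in ((case_ids, case_f), (control_ids, control_f)):
            n_carriers = int(rng.binomial(len(ids), freq))
            chosen = rng.choice(len(ids), size=n_carriers, replace=False)
            for idx in np.sort(chosen):
                counter += 1
                pid = ids[idx]
                true_class = mix_keys[rng.choice(len(mix_keys), p=mix_p)]
                ann = _annotations_for_class(rng, true_class, config.annotation_noise)
                hgvs_c = f"c.{counter * 3 + 1}A>G" if ann["consequence"] is Consequence.missense \
                    else f"c.{counter * 3 + 1}del"
                variants.append(AnnotatedVariant(
                    participant_id=pid, gene_symbol=gene, hgvs_c=hgvs_c,
                    zygosity=Zygosity.het, **ann))
                truth.append(TruthRecord(pid, gene, hgvs_c, true_class,
                                         CLASS_EVIDENCE[true_class]))
    return CohortTable(participants, variants, []), truth


def truth_profile(record: TruthRecord) -> EvidenceProfile:
    return EvidenceProfile.from_codes(*record.evidence_codes)


def truth_class_of(result) -> str:
    """Render a ClassificationResult in the truth-label vocabulary."""
    if result.five_tier is FiveTier.VUS and result.temperature is not Temperature.not_applicable:
        return f"VUS_{result.temperature.value}"
    return result.five_tier.value


# ---------------------------------------------------------------------------
# signature catalogs
# ---------------------------------------------------------------------------


def simulate_signature_catalog(
    exposures: Mapping[str, float],
    n_mutations: int,
    seed: int,
    signatures: pd.DataFrame | None = None,
) -> np.ndarray:
    """Multinomial draw of a 96-channel catalog from a signature mixture."""
    if signatures is None:
        signatures = load_signature_matrix()
    if any(w < 0 for w in exposures.values()):
        raise ValidationError("exposures must be non-negative")
    if n_mutations < 0:
        raise ValidationError("n_mutations must be non-negative")
    if n_mutations == 0:
        return np.zeros(96)
    unknown = set(exposures) - set(signatures.columns)
    if unknown:
        raise ValidationError(f"exposures name unknown signatures {sorted(unknown)}")
    w = np.array([exposures.get(s, 0.0) for s in signatures.columns], float)
    if w.sum() <= 0:
        raise ValidationError("exposures must sum to a positive total")
    p = signatures.values @ (w / w.sum())
    rng = stream(seed, "signature_catalog")
    return rng.multinomial(n_mutations, p / p.sum()).astype(float)


# ---------------------------------------------------------------------------
# persistence for the simulate subcommand
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortTable, truth: Sequence[TruthRecord],
                 config: SimulationConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_participant_table(cohort.participants, outdir / "participants.tsv")
    write_variant_table(cohort.variants, outdir / "variants.tsv")
    write_sv_table(cohort.svs, outdir / "svs.tsv")
    pd.DataFrame([{
        "participant_id": t.participant_id, "gene_symbol": t.gene_symbol,
        "hgvs_c": t.hgvs_c, "true_class": t.true_class,
        "evidence_codes": ",".join(t.evidence_codes),
    } for t in truth]).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    import yaml

    cfg = asdict(config)
    cfg["per_gene_carrier_freq"] = {g: list(v) for g, v in cfg["per_gene_carrier_freq"].items()}
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
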