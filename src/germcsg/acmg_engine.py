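"""ACMG/AMP evidence combination as a Bayesian points system.

Evidence codes carry a strength (supporting/moderate/strong/very strong)
mapped to exponent points 1/2/4/8; benign codes count negatively. The
combined points ``p`` convert to a posterior probability of pathogenicity

    odds = O_PVS ** (p / 8),   posterior = odds * prior / ((odds - 1) * prior + 1)

with defaults O_PVS = 350 and prior = 0.10. Five-tier classes follow the
point bands (P >= 10, LP 6..9, VUS 0..5, LB -6..-1, B <= -7); within the VUS
band the six ACGS "temperature" grades map one-to-one onto points 0..5
(equivalently, onto posterior bands). BA1 is a stand-alone benign override:
it forces class B regardless of other applied codes.

Copy-number variants are scored with the 2020 ACMG/ClinGen dosage rubric:
signed per-section scores are summed and classified on the +-0.99/0.90
thresholds. The allowed per-section score ranges are table-driven from a
packaged rubric file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping, Sequence

from .core_model import AnnotatedVariant, ValidationError

# ---------------------------------------------------------------------------
# evidence codes
# ---------------------------------------------------------------------------


class Strength(str, Enum):
    supporting = "supporting"
    moderate = "moderate"
    strong = "strong"
    very_strong = "very_strong"
    stand_alone = "stand_alone"


STRENGTH_POINTS = {
    Strength.supporting: 1,
    Strength.moderate: 2,
    Strength.strong: 4,
    Strength.very_strong: 8,
}

#: valid code id -> (is_benign, default strength)
ACMG_CODES: dict[str, tuple[bool, Strength]] = {
    "PVS1": (False, Strength.very_strong),
    **{f"PS{i}": (False, Strength.strong) for i in range(1, 5)},
    **{f"PM{i}": (False, Strength.moderate) for i in range(1, 7)},
    **{f"PP{i}": (False, Strength.supporting) for i in range(1, 6)},
    "BA1": (True, Strength.stand_alone),
    **{f"BS{i}": (True, Strength.strong) for i in range(1, 5)},
    **{f"BP{i}": (True, Strength.supporting) for i in range(1, 8)},
}


class FiveTier(str, Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


class Temperature(str, Enum):
    hot = "hot"
    warm = "warm"
    tepid = "tepid"
    cool = "cool"
    cold = "cold"
    ice_cold = "ice_cold"
    not_applicable = "not_applicable"


_TEMPERATURE_BY_POINTS = {
    0: Temperature.ice_cold, 1: Temperature.cold, 2: Temperature.cool,
    3: Temperature.tepid, 4: Temperature.warm, 5: Temperature.hot,
}


@dataclass(frozen=True)
class EvidenceProfile:
    """A set of applied ACMG codes, each at most once, with applied strengths."""

    codes: tuple[tuple[str, Strength], ...]

    def __post_init__(self):
        seen = set()
        for code, strength in self.codes:
            if code not in ACMG_CODES:
                raise ValidationError(f"unknown ACMG evidence code {code!r}")
            if code in seen:
                raise ValidationError(f"evidence code {code} applied more than once")
            seen.add(code)
            if strength is Strength.stand_alone and code != "BA1":
                raise ValidationError(f"stand_alone strength is reserved for BA1, got {code}")
            if code == "BA1" and strength is not Strength.stand_alone:
                raise ValidationError("BA1 must be applied at stand_alone strength")

    @classmethod
    def from_codes(cls, *specs: str) -> "EvidenceProfile":
        """Build from ``"PVS1"`` or ``"PS1:moderate"`` specs (default strength when omitted)."""
        pairs = []
        for spec in specs:
            code, _, strength = spec.partition(":")
            code = code.strip()
            if code not in ACMG_CODES:
                raise ValidationError(f"unknown ACMG evidence code {code!r}")
            s = Strength(strength) if strength else ACMG_CODES[code][1]
            pairs.append((code, s))
        return cls(tuple(pairs))

    @property
    def has_ba1(self) -> bool:
        return any(code == "BA1" for code, _ in self.codes)


@dataclass(frozen=True)
class BayesParams:
    prior: float = 0.10
    odds_pvs: float = 350.0

    def __post_init__(self):
        if not (0.0 < self.prior < 1.0):
            raise ValidationError(f"prior {self.prior} outside (0, 1)")
        if self.odds_pvs <= 1.0:
            raise ValidationError(f"odds_pvs {self.odds_pvs} must exceed 1")


@dataclass(frozen=True)
class ClassificationResult:
    points: int
    posterior: float
    five_tier: FiveTier
    temperature: Temperature
    ba1_override: bool = False


# ---------------------------------------------------------------------------
# points -> posterior -> class
# ---------------------------------------------------------------------------


def points_from_profile(profile: EvidenceProfile) -> int:
    """Signed point sum; BA1 contributes no points (it short-circuits classification)."""
    total = 0
    for code, strength in profile.codes:
        if code == "BA1":
            continue
        benign, _ = ACMG_CODES[code]
        pts = STRENGTH_POINTS[strength]
        total += -pts if benign else pts
    return total


def posterior_probability(points: int | float, params: BayesParams | None = None) -> float:
    params = params or BayesParams()
    odds = math.pow(params.odds_pvs, points / 8.0)
    return odds * params.prior / ((odds - 1.0) * params.prior + 1.0)


def classify_five_tier(points: int, ba1: bool = False) -> FiveTier:
    if ba1:
        return FiveTier.B
    if points >= 10:
        return FiveTier.P
    if points >= 6:
        return FiveTier.LP
    if points >= 0:
        return FiveTier.VUS
    if points >= -6:
        return FiveTier.LB
    return FiveTier.B


def vus_temperature(points: int) -> Temperature:
    if points not in _TEMPERATURE_BY_POINTS:
        raise ValidationError(f"points {points} outside the VUS band 0..5")
    return _TEMPERATURE_BY_POINTS[points]


def temperature_posterior_edges(params: BayesParams | None = None) -> dict[Temperature, float]:
    """Lower posterior edge of each temperature grade (the posterior-band equivalent)."""
    return {_TEMPERATURE_BY_POINTS[p]: posterior_probability(p, params) for p in range(6)}


def classify_profile(profile: EvidenceProfile,
                     params: BayesParams | None = None) -> ClassificationResult:
    points = points_from_profile(profile)
    posterior = posterior_probability(points, params)
    tier = classify_five_tier(points, ba1=profile.has_ba1)
    temp = vus_temperature(points) if tier is FiveTier.VUS else Temperature.not_applicable
    return ClassificationResult(points, posterior, tier, temp, ba1_override=profile.has_ba1)


def classify_variant(variant: AnnotatedVariant, profile: EvidenceProfile,
                     params: BayesParams | None = None) -> ClassificationResult:
    """Classify a filter-retained variant observation from its curated evidence codes."""
    return classify_profile(profile, params)


# ---------------------------------------------------------------------------
# ClinGen CNV scoring
# ---------------------------------------------------------------------------


class CnvRubric(str, Enum):
    loss = "loss"
    gain = "gain"


def _load_rubric_table() -> dict[str, dict[str, tuple[float, float]]]:
    raw = json.loads(
        resources.files("germcsg").joinpath("data/clingen_cnv_rubric.json").read_text())
    return {rub: {sec: tuple(rng) for sec, rng in secs.items()} for rub, secs in raw.items()}


_RUBRIC_RANGES = _load_rubric_table()

_CNV_BANDS = (  # (threshold on total score, tier) evaluated top-down
    (0.99, FiveTier.P),
    (0.90, FiveTier.LP),
    (-0.89, FiveTier.VUS),
    (-0.98, FiveTier.LB),
)


@dataclass(frozen=True)
class CnvEvidence:
    """Signed per-section scores under the ClinGen loss or gain rubric."""

    rubric: CnvRubric
    section_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        ranges = _RUBRIC_RANGES[self.rubric.value]
        for section, score in self.section_scores.items():
            key = section[0] if section and section[0] in ranges else section
            if key not in ranges:
                raise ValidationError(
                    f"unknown rubric section {section!r} for {self.rubric.value} rubric")
            lo, hi = ranges[key]
            if not (lo <= score <= hi):
                raise ValidationError(
                    f"section {section}: score {score} outside allowed range [{lo}, {hi}]")


def classify_cnv(evidence: CnvEvidence) -> tuple[float, FiveTier]:
    """Sum section scores and classify on the 2020 dosage-rubric thresholds."""
    total = float(sum(evidence.section_scores.values()))
    for threshold, tier in _CNV_BANDS:
        if total >= threshold:
            return total, tier
    return total, FiveTier.B
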