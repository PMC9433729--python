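"""Domain types and table readers/writers for the germline CSG pipeline.

All genomic intervals are 1-based and inclusive at both ends, matching VCF
and HGVS conventions; any half-open source format must be converted at the
parsing boundary. Missing annotation scores are sentinel-encoded (``.`` in
files, ``None``/``absent`` in memory), never silently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("germcsg")

SENTINEL = "."


class ParseError(ValueError):
    """A file violated the documented dialect (exit code 3 in the CLI)."""


class ValidationError(ValueError):
    """An in-memory object violated a domain invariant (exit code 2 in the CLI)."""


# ---------------------------------------------------------------------------
# enums
# ---------------------------------------------------------------------------

class Panel(str, Enum):
    RCC_CSG = "RCC_CSG"
    OTHER_CSG = "OTHER_CSG"


class Consequence(str, Enum):
    stop_gained = "stop_gained"
    stop_lost = "stop_lost"
    frameshift = "frameshift"
    splice_disruption = "splice_disruption"
    start_lost = "start_lost"
    missense = "missense"
    inframe_indel = "inframe_indel"
    synonymous = "synonymous"
    other = "other"


#: loss-of-function / VEP "HIGH" severity consequence classes
HIGH_IMPACT_CONSEQUENCES = frozenset({
    Consequence.stop_gained,
    Consequence.stop_lost,
    Consequence.frameshift,
    Consequence.splice_disruption,
    Consequence.start_lost,
})

MODERATE_IMPACT_CONSEQUENCES = frozenset({
    Consequence.missense,
    Consequence.inframe_indel,
})


class ImpactTier(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class Sift(str, Enum):
    deleterious = "deleterious"
    tolerated = "tolerated"
    absent = "absent"


class PolyPhen(str, Enum):
    probably_damaging = "probably_damaging"
    possibly_damaging = "possibly_damaging"
    benign = "benign"
    absent = "absent"


class Zygosity(str, Enum):
    het = "het"
    hom = "hom"


class Role(str, Enum):
    case = "case"
    control = "control"


class Histology(str, Enum):
    clear_cell = "clear_cell"
    non_clear_cell = "non_clear_cell"
    unspecified = "unspecified"
    not_available = "not_available"


class Stage(str, Enum):
    s1 = "1"
    s2 = "2"
    s3 = "3"
    s4 = "4"
    unclassified = "unclassified"
    not_available = "not_available"


class SvType(str, Enum):
    deletion = "deletion"
    duplication = "duplication"
    inversion = "inversion"
    translocation = "translocation"


class SvFilterMode(str, Enum):
    stringent = "stringent"
    relaxed = "relaxed"
    none = "none"


def _enum(cls, value, context: str):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ParseError(
            f"{context}: unknown {cls.__name__} value {value!r} (allowed: {allowed})"
        ) from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A panel gene with its canonical transcript's exon structure."""

    gene_symbol: str
    chromosome: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    panel: Panel
    transcript_id: str

    def __post_init__(self):
        if self.gene_start > self.gene_end:
            raise ValidationError(
                f"{self.gene_symbol}: gene interval start {self.gene_start} > end {self.gene_end}"
            )
        prev_end = None
        for i, (a, b) in enumerate(self.exons, start=1):
            if a > b:
                raise ValidationError(f"{self.gene_symbol}: exon {i} start {a} > end {b}")
            if a < self.gene_start or b > self.gene_end:
                raise ValidationError(
                    f"{self.gene_symbol}: exon {i} [{a},{b}] outside gene interval"
                )
            if prev_end is not None and a <= prev_end:
                raise ValidationError(
                    f"{self.gene_symbol}: exon {i} overlaps or is unsorted relative to exon {i - 1}"
                )
            prev_end = b

    @property
    def length(self) -> int:
        return self.gene_end - self.gene_start + 1

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.gene_start <= position <= self.gene_end


@dataclass(frozen=True)
class Participant:
    participant_id: str
    role: Role
    sex: str  # "male" | "female"
    ancestry_label: str = "EUR"
    age_at_diagnosis: float | None = None
    histology: Histology = Histology.not_available
    stage: Stage = Stage.not_available
    n_rcc_tumours: int = 0
    other_cancers: int = 0

    def __post_init__(self):
        if self.age_at_diagnosis is not None and not (0 <= self.age_at_diagnosis <= 120):
            raise ValidationError(
                f"{self.participant_id}: age {self.age_at_diagnosis} outside [0, 120]"
            )
        if self.role is Role.control and (
            self.age_at_diagnosis is not None or self.n_rcc_tumours):
            raise ValidationError(
                f"{self.participant_id}: controls carry no tumour fields"
            )


@dataclass(frozen=True)
class AnnotatedVariant:
    """One participant-variant observation with VEP-style annotations."""

    participant_id: str
    gene_symbol: str
    hgvs_c: str
    consequence: Consequence
    impact_tier: ImpactTier
    af_by_population: Mapping[str, float]
    zygosity: Zygosity
    hgvs_p: str | None = None
    sift: Sift = Sift.absent
    polyphen: PolyPhen = PolyPhen.absent
    cadd_phred: float | None = None

    def __post_init__(self):
        if self.consequence in HIGH_IMPACT_CONSEQUENCES and self.impact_tier is not ImpactTier.HIGH:
            raise ValidationError(
                f"{self.key()}: consequence {self.consequence.value} requires HIGH impact tier"
            )
        if self.consequence in MODERATE_IMPACT_CONSEQUENCES and self.impact_tier is not ImpactTier.MODERATE:
            raise ValidationError(
                f"{self.key()}: consequence {self.consequence.value} requires MODERATE impact tier"
            )
        for pop, af in self.af_by_population.items():
            if not (0.0 <= af <= 1.0):
                raise ValidationError(f"{self.key()}: allele frequency {pop}={af} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"{self.key()}: negative CADD score {self.cadd_phred}")

    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.gene_symbol, self.hgvs_c)


@dataclass(frozen=True)
class SVCall:
    participant_id: str
    sv_type: SvType
    breakpoint_a: tuple[str, int]
    breakpoint_b: tuple[str, int]
    filter_mode_passed: SvFilterMode = SvFilterMode.none
    quality: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self):
        if self.sv_type is not SvType.translocation:
            (ca, pa), (cb, pb) = self.breakpoint_a, self.breakpoint_b
            if ca != cb:
                raise ValidationError(
                    f"{self.participant_id}: non-translocation {self.sv_type.value} "
                    f"spans chromosomes {ca} and {cb}"
                )
            if pa > pb:
                raise ValidationError(
                    f"{self.participant_id}: breakpoint_a {pa} > breakpoint_b {pb}"
                )

    def normalized(self) -> "SVCall":
        """Breakpoints sorted by (chromosome, position); overlap results must not depend on order."""
        a, b = sorted([self.breakpoint_a, self.breakpoint_b])
        return SVCall(self.participant_id, self.sv_type, a, b,
                      self.filter_mode_passed, self.quality)

    @property
    def span(self) -> tuple[int, int]:
        return (self.breakpoint_a[1], self.breakpoint_b[1])


@dataclass
class CohortTable:
    participants: list[Participant]
    variants: list[AnnotatedVariant] = field(default_factory=list)
    svs: list[SVCall] = field(default_factory=list)

    def __post_init__(self):
        ids = {p.participant_id for p in self.participants}
        for v in self.variants:
            if v.participant_id not in ids:
                raise ValidationError(f"variant participant {v.participant_id!r} not in cohort")
        for s in self.svs:
            if s.participant_id not in ids:
                raise ValidationError(f"SV participant {s.participant_id!r} not in cohort")

    @property
    def n_cases(self) -> int:
        return sum(p.role is Role.case for p in self.participants)

    @property
    def n_controls(self) -> int:
        return sum(p.role is Role.control for p in self.participants)

    def subset(self, role: Role | None = None, ancestry: str | None = None) -> list[Participant]:
        out = self.participants
        if role is not None:
            out = [p for p in out if p.role is role]
        if ancestry is not None:
            out = [p for p in out if p.ancestry_label == ancestry]
        return out


# ---------------------------------------------------------------------------
# gene panel I/O
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["gene_symbol", "chrom", "gene_start", "gene_end",
                  "exon_starts", "exon_ends", "panel", "transcript_id"]


def read_gene_panel(path: str | Path) -> list[GeneModel]:
    """Read a BED-like TSV of gene models (1-based inclusive coordinates in-file)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing panel columns {missing}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        sym = row["gene_symbol"]
        if sym in seen:
            raise ParseError(f"{path}:{line}: duplicate gene symbol {sym!r}")
        seen.add(sym)
        panel = _enum(Panel, row["panel"], f"{path}:{line}")
        try:
            starts = [int(x) for x in str(row["exon_starts"]).split(",") if x]
            ends = [int(x) for x in str(row["exon_ends"]).split(",") if x]
            gstart, gend = int(row["gene_start"]), int(row["gene_end"])
        except ValueError as exc:
            raise ParseError(f"{path}:{line}: malformed coordinate field: {exc}") from None
        if len(starts) != len(ends):
            raise ParseError(f"{path}:{line}: exon_starts/exon_ends length mismatch")
        try:
            genes.append(GeneModel(sym, str(row["chrom"]), gstart, gend,
                                   tuple(zip(starts, ends)), panel, row["transcript_id"]))
        except ValidationError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from None
    return genes


def write_gene_panel(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [{
        "gene_symbol": g.gene_symbol, "chrom": g.chromosome,
        "gene_start": g.gene_start, "gene_end": g.gene_end,
        "exon_starts": ",".join(str(a) for a, _ in g.exons),
        "exon_ends": ",".join(str(b) for _, b in g.exons),
        "panel": g.panel.value, "transcript_id": g.transcript_id,
    } for g in genes]
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def packaged_panel_path() -> Path:
    """Path to the packaged 121-gene panel (synthetic coordinates, 18 RCC-CSGs)."""
    return Path(resources.files("germcsg").joinpath("data/csg_panel_synthetic.tsv"))


def load_packaged_panel() -> list[GeneModel]:
    return read_gene_panel(packaged_panel_path())


# ---------------------------------------------------------------------------
# variant table I/O (TSV dialect)
# ---------------------------------------------------------------------------

_VARIANT_FIXED = ["participant_id", "gene_symbol", "hgvs_c", "hgvs_p",
                  "consequence", "impact", "sift", "polyphen", "cadd_phred", "zygosity"]


def _fmt_float(x: float) -> str:
    return repr(float(x))


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    """Read the documented variant TSV dialect; ``af_<pop>`` columns are open-ended."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _VARIANT_FIXED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing variant columns {missing}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    out: list[AnnotatedVariant] = []
    for i, row in df.iterrows():
        line = i + 2
        afs: dict[str, float] = {}
        for c in af_cols:
            raw = row[c]
            if raw in ("", SENTINEL):
                continue
            af = float(raw)
            if not (0.0 <= af <= 1.0):
                raise ParseError(f"{path}:{line}: allele frequency {c}={af} outside [0, 1]")
            afs[c[3:]] = af
        cadd = None if row["cadd_phred"] in ("", SENTINEL) else float(row["cadd_phred"])
        try:
            out.append(AnnotatedVariant(
                participant_id=row["participant_id"],
                gene_symbol=row["gene_symbol"],
                hgvs_c=row["hgvs_c"],
                hgvs_p=None if row["hgvs_p"] in ("", SENTINEL) else row["hgvs_p"],
                consequence=_enum(Consequence, row["consequence"], f"{path}:{line}"),
                impact_tier=_enum(ImpactTier, row["impact"], f"{path}:{line}"),
                af_by_population=afs,
                sift=_enum(Sift, row["sift"] or Sift.absent.value, f"{path}:{line}"),
                polyphen=_enum(PolyPhen, row["polyphen"] or PolyPhen.absent.value, f"{path}:{line}"),
                cadd_phred=cadd,
                zygosity=_enum(Zygosity, row["zygosity"], f"{path}:{line}"),
            ))
        except ValidationError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from None
    return out


def write_variant_table(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    pops = sorted({p for v in variants for p in v.af_by_population})
    cols = _VARIANT_FIXED[:3] + ["hgvs_p", "consequence", "impact"] + \
        [f"af_{p}" for p in pops] + ["sift", "polyphen", "cadd_phred", "zygosity"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            row = [v.participant_id, v.gene_symbol, v.hgvs_c,
                   v.hgvs_p if v.hgvs_p is not None else SENTINEL,
                   v.consequence.value, v.impact_tier.value]
            row += [_fmt_float(v.af_by_population[p]) if p in v.af_by_population else SENTINEL
                    for p in pops]
            row += [v.sift.value, v.polyphen.value,
                    _fmt_float(v.cadd_phred) if v.cadd_phred is not None else SENTINEL,
                    v.zygosity.value]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# minimal VCF dialect
# ---------------------------------------------------------------------------
# One sample per file; annotations live in INFO under GENE, CSQ_CLASS, IMPACT,
# AF_<POP>, SIFT, POLYPHEN, CADD, HGVSC, HGVSP. Genomic coordinates are carried
# but not consumed downstream (the pipeline keys variants on gene + HGVSc), so
# synthetic positions are written on export.

_REQUIRED_INFO = ["GENE", "CSQ_CLASS", "IMPACT", "HGVSC"]


def read_minimal_vcf(path: str | Path) -> list[AnnotatedVariant]:
    import pysam

    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ParseError(f"{path}: expected exactly one sample column, found {len(samples)}")
        sample = samples[0]
        for rec in vcf:
            where = f"{path}:{rec.chrom}:{rec.pos}"
            for key in _REQUIRED_INFO:
                if key not in rec.info:
                    raise ParseError(f"{where}: missing required INFO key {key}")
            gt = rec.samples[sample].get("GT")
            alleles = [a for a in (gt or (None,)) if a is not None]
            if not alleles:
                logger.warning("%s: uncalled genotype ./. — record skipped", where)
                continue
            zyg = Zygosity.hom if len(alleles) > 1 and all(a == 1 for a in alleles) else Zygosity.het
            afs = {}
            for key in rec.info.keys():
                if key.startswith("AF_"):
                    raw = rec.info[key]
                    af = float(raw[0] if isinstance(raw, tuple) else raw)
                    if not (0.0 <= af <= 1.0):
                        raise ParseError(f"{where}: {key}={af} outside [0, 1]")
                    afs[key[3:].lower()] = af

            def info_str(key):
                val = rec.info.get(key)
                if val is None:
                    return None
                return val[0] if isinstance(val, tuple) else str(val)

            cadd = rec.info.get("CADD")
            out.append(AnnotatedVariant(
                participant_id=sample,
                gene_symbol=info_str("GENE"),
                hgvs_c=info_str("HGVSC"),
                hgvs_p=info_str("HGVSP"),
                consequence=_enum(Consequence, info_str("CSQ_CLASS"), where),
                impact_tier=_enum(ImpactTier, info_str("IMPACT"), where),
                af_by_population=afs,
                sift=_enum(Sift, info_str("SIFT") or Sift.absent.value, where),
                polyphen=_enum(PolyPhen, info_str("POLYPHEN") or PolyPhen.absent.value, where),
                cadd_phred=float(cadd) if cadd is not None else None,
                zygosity=zyg,
            ))
    return out


def write_minimal_vcf(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write one sample's variants in the minimal VCF dialect (positions are synthetic)."""
    import pysam

    if not variants:
        raise ValidationError("cannot write an empty minimal VCF (no sample name available)")
    sample_ids = {v.participant_id for v in variants}
    if len(sample_ids) != 1:
        raise ValidationError(
            f"minimal VCF holds one sample; got participants {sorted(sample_ids)}")
    pops = sorted({p for v in variants for p in v.af_by_population})
    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=1,length=400000000>")
    for key, typ, desc in [
        ("GENE", "String", "Gene symbol"), ("CSQ_CLASS", "String", "Consequence class"),
        ("IMPACT", "String", "VEP impact tier"), ("HGVSC", "String", "HGVS coding name"),
        ("HGVSP", "String", "HGVS protein name"), ("SIFT", "String", "SIFT category"),
        ("POLYPHEN", "String", "PolyPhen category"), ("CADD", "Float", "CADD Phred score"),
    ]:
        header.add_meta("INFO", items=[("ID", key), ("Number", "1"), ("Type", typ),
                                       ("Description", desc)])
    for p in pops:
        header.add_meta("INFO", items=[("ID", f"AF_{p.upper()}"), ("Number", "1"),
                                       ("Type", "Float"),
                                       ("Description", f"Population allele frequency ({p})")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_sample(next(iter(sample_ids)))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, v in enumerate(variants):
            rec = vcf.new_record(contig="1", start=i, stop=i + 1, alleles=("N", "A"))
            rec.info["GENE"] = v.gene_symbol
            rec.info["CSQ_CLASS"] = v.consequence.value
            rec.info["IMPACT"] = v.impact_tier.value
            rec.info["HGVSC"] = v.hgvs_c
            if v.hgvs_p is not None:
                rec.info["HGVSP"] = v.hgvs_p
            if v.sift is not Sift.absent:
                rec.info["SIFT"] = v.sift.value
            if v.polyphen is not PolyPhen.absent:
                rec.info["POLYPHEN"] = v.polyphen.value
            if v.cadd_phred is not None:
                rec.info["CADD"] = v.cadd_phred
            for p, af in v.af_by_population.items():
                rec.info[f"AF_{p.upper()}"] = af
            rec.samples[0]["GT"] = (0, 1) if v.zygosity is Zygosity.het else (1, 1)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# participant / SV table I/O
# ---------------------------------------------------------------------------

_PARTICIPANT_COLUMNS = ["participant_id", "role", "sex", "ancestry_label",
                        "age_at_diagnosis", "histology", "stage",
                        "n_rcc_tumours", "other_cancers"]


def read_participant_table(path: str | Path) -> list[Participant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing participant columns {missing}")
    out = []
    for i, row in df.iterrows():
        line = i + 2
        age = None if row["age_at_diagnosis"] in ("", SENTINEL) else float(row["age_at_diagnosis"])
        try:
            out.append(Participant(
                participant_id=row["participant_id"],
                role=_enum(Role, row["role"], f"{path}:{line}"),
                sex=row["sex"],
                ancestry_label=row["ancestry_label"],
                age_at_diagnosis=age,
                histology=_enum(Histology, row["histology"] or "not_available", f"{path}:{line}"),
                stage=_enum(Stage, row["stage"] or "not_available", f"{path}:{line}"),
                n_rcc_tumours=int(row["n_rcc_tumours"] or 0),
                other_cancers=int(row["other_cancers"] or 0),
            ))
        except ValidationError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from None
    return out


def write_participant_table(participants: Sequence[Participant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PARTICIPANT_COLUMNS) + "\n")
        for p in participants:
            fh.write("\t".join([
                p.participant_id, p.role.value, p.sex, p.ancestry_label,
                _fmt_float(p.age_at_diagnosis) if p.age_at_diagnosis is not None else SENTINEL,
                p.histology.value, p.stage.value,
                str(p.n_rcc_tumours), str(p.other_cancers)]) + "\n")


_SV_FIXED = ["participant_id", "sv_type", "chrom_a", "pos_a", "chrom_b", "pos_b"]


def read_sv_table(path: str | Path) -> list[SVCall]:
    """Read the SV TSV dialect; columns beyond the fixed six become quality fields."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SV_FIXED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing SV columns {missing}")
    extra = [c for c in df.columns if c not in _SV_FIXED]
    out = []
    for i, row in df.iterrows():
        line = i + 2
        quality: dict[str, float | str] = {}
        for c in extra:
            raw = row[c]
            if raw in ("", SENTINEL):
                continue
            try:
                quality[c] = float(raw)
            except ValueError:
                quality[c] = raw
        try:
            out.append(SVCall(
                participant_id=row["participant_id"],
                sv_type=_enum(SvType, row["sv_type"], f"{path}:{line}"),
                breakpoint_a=(str(row["chrom_a"]), int(row["pos_a"])),
                breakpoint_b=(str(row["chrom_b"]), int(row["pos_b"])),
                quality=quality,
            ))
        except ValidationError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from None
    return out


def write_sv_table(svs: Sequence[SVCall], path: str | Path) -> None:
    keys = sorted({k for s in svs for k in s.quality})
    with open(path, "w") as fh:
        fh.write("\t".join(_SV_FIXED + keys) + "\n")
        for s in svs:
            row = [s.participant_id, s.sv_type.value,
                   s.breakpoint_a[0], str(s.breakpoint_a[1]),
                   s.breakpoint_b[0], str(s.breakpoint_b[1])]
            for k in keys:
                val = s.quality.get(k)
                if val is None:
                    row.append(SENTINEL)
                elif isinstance(val, float):
                    row.append(_fmt_float(val))
                else:
                    row.append(str(val))
            fh.write("\t".join(row) + "\n")
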