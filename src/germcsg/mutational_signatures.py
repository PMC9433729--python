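"""NNLS decomposition of 96-channel somatic catalogs over mutational signatures.

Catalogs are raw mutation counts over the standard 96 trinucleotide contexts
(6 pyrimidine substitution classes x 16 flanking contexts, alphabetical
within class). Exposures are fit on counts by non-negative least squares;
the packaged signature matrix is a deterministic synthetic stand-in with the
spectral layout of COSMIC v2 for the signatures of interest here (6, 10, 15,
20, 26) plus five backgrounds — a full matrix can be loaded from TSV.

Mismatch-repair deficiency is flagged when signatures 6/15/20/26 jointly
reach a minimum exposure proportion; POLE exonuclease deficiency when
signature 10 does.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_model import ValidationError

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES for five in "ACGT" for three in "ACGT"
)

MMR_SIGNATURES = ("6", "15", "20", "26")
POLE_SIGNATURE = "10"


@dataclass(frozen=True)
class MutationalCatalog:
    counts: tuple[float, ...]

    def __post_init__(self):
        if len(self.counts) != 96:
            raise ValidationError(f"catalog has {len(self.counts)} channels, expected 96")
        if any(c < 0 for c in self.counts):
            raise ValidationError("catalog counts must be non-negative")

    @classmethod
    def from_array(cls, arr) -> "MutationalCatalog":
        return cls(tuple(float(x) for x in np.asarray(arr, float)))

    @property
    def total(self) -> float:
        return float(sum(self.counts))


@dataclass(frozen=True)
class SignatureExposure:
    exposures: Mapping[str, float]
    residual_norm: float

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.exposures.values())
        if total == 0:
            return {k: 0.0 for k in self.exposures}
        return {k: v / total for k, v in self.exposures.items()}


def load_signature_matrix(path: str | Path | None = None) -> pd.DataFrame:
    """96 x k signature probability matrix (rows indexed by context, columns renormalized)."""
    if path is None:
        path = resources.files("germcsg").joinpath(
            "data/signature_matrix_v2_subset_synthetic.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"context": str}).set_index("context")
    df.columns = [str(c) for c in df.columns]
    missing = set(CONTEXTS_96) - set(df.index)
    if missing:
        raise ValidationError(f"signature matrix missing contexts, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CONTEXTS_96)]
    if (df.values < 0).any():
        raise ValidationError("signature probabilities must be non-negative")
    return df / df.sum(axis=0)


def nnls_fit(catalog: MutationalCatalog, signatures: pd.DataFrame) -> SignatureExposure:
    """Exposures minimizing ||catalog - signatures @ x||_2 subject to x >= 0."""
    matrix = signatures.values
    if matrix.shape[0] != 96:
        raise ValidationError(f"signature matrix has {matrix.shape[0]} rows, expected 96")
    y = np.asarray(catalog.counts, float)
    x, residual = nnls(matrix, y)
    return SignatureExposure(
        exposures={sig: float(w) for sig, w in zip(signatures.columns, x)},
        residual_norm=float(residual),
    )


def flag_deficiency(
    exposure: SignatureExposure,
    min_proportion: float = 0.05,
) -> dict[str, bool]:
    """MMR flag from signatures 6/15/20/26; POLE flag from signature 10."""
    needed = set(MMR_SIGNATURES) | {POLE_SIGNATURE}
    missing = needed - set(exposure.exposures)
    if missing:
        raise ValidationError(
            f"exposures were not fit against required signatures {sorted(missing)}")
    props = exposure.proportions
    mmr = sum(props[s] for s in MMR_SIGNATURES)
    return {
        "MMR_deficient": mmr >= min_proportion,
        "POLE_deficient": props[POLE_SIGNATURE] >= min_proportion,
    }


def read_catalog(path: str | Path) -> MutationalCatalog:
    """Catalog TSV: columns context, count (96 rows in any order)."""
    df = pd.read_csv(path, sep="\t", dtype={"context": str}).set_index("context")
    missing = set(CONTEXTS_96) - set(df.index)
    if missing:
        raise ValidationError(f"catalog missing contexts, e.g. {sorted(missing)[:3]}")
    return MutationalCatalog.from_array(df.loc[list(CONTEXTS_96), "count"].values)


def write_catalog(catalog: MutationalCatalog, path: str | Path) -> None:
    pd.DataFrame({"context": CONTEXTS_96, "count": catalog.counts}).to_csv(
        path, sep="\t", index=False)
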