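"""Data model and tidy-TSV I/O for functional-assay tables, annotations and registries.

The in-memory containers are thin wrappers over :class:`pandas.DataFrame` in long
("tidy") form: one internal-control-normalized measurement per row, keyed by
``(variant, lab, assay, replicate)``.  Replicate counts differ between variants
and assays, so a wide matrix is not a faithful container for the raw panel.

Protein-level variant names follow HGVS ``p.`` nomenclature with three-letter
amino-acid codes (e.g. ``p.Glu508Lys``).  Non-substitution labels (in-frame
deletions, wild-type construct backgrounds such as ``WT_Ile27``) are carried as
opaque strings and are deliberately not parseable.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS_3",
    "FormatLevel",
    "ReferenceRole",
    "FormatError",
    "HgvsParseError",
    "VariantAnnotation",
    "FunctionalDataset",
    "parse_protein_hgvs",
    "read_functional_table",
    "write_functional_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_registry_table",
    "write_registry_table",
]

#: Three-letter codes for the 20 standard amino acids (HGVS spelling).
AMINO_ACIDS_3 = frozenset(
    [
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    ]
)


class FormatLevel(str, enum.Enum):
    """Processing level of an assay table.

    Only ``CONTROL_NORMALIZED`` (measurements divided by the internal technical
    control of each assay, e.g. Renilla luciferase for transactivation) is
    accepted by the clustering pipeline; the other two levels exist for
    inspection of upstream/downstream representations.
    """

    RAW = "RAW"
    CONTROL_NORMALIZED = "CONTROL_NORMALIZED"
    WT_NORMALIZED = "WT_NORMALIZED"


class ReferenceRole(str, enum.Enum):
    NONE = "NONE"
    WILD_TYPE = "WILD_TYPE"
    MODY_REFERENCE = "MODY_REFERENCE"
    T2D_REFERENCE = "T2D_REFERENCE"


class FormatError(ValueError):
    """A table violates the declared schema (missing column, bad value, duplicate key)."""


class HgvsParseError(ValueError):
    """A protein HGVS name cannot be parsed into (ref, position, alt)."""


_HGVS_P_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_protein_hgvs(name: str) -> tuple[str, int, str]:
    """Parse a missense protein HGVS name into ``(ref_aa, residue, alt_aa)``.

    >>> parse_protein_hgvs("p.Glu508Lys")
    ('Glu', 508, 'Lys')
    """
    m = _HGVS_P_RE.match(name.strip())
    if m is None:
        raise HgvsParseError(f"not a p.RefPosAlt missense name: {name!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    for code in (ref, alt):
        if code not in AMINO_ACIDS_3:
            raise HgvsParseError(f"unknown amino-acid code {code!r} in {name!r}")
    if pos < 1:
        raise HgvsParseError(f"residue must be positive in {name!r}")
    return ref, pos, alt


@dataclass(frozen=True)
class VariantAnnotation:
    """Identity and context of one variant.

    ``exon`` follows the canonical 10-exon HNF1A gene model; ``gnomad_count``
    is the population allele count (an input column, never queried live).
    """

    hgvs_p: str
    residue: int
    exon: int
    gnomad_count: int = 0
    reference_role: ReferenceRole = ReferenceRole.NONE
    lab: str = ""

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError(f"residue must be >= 1, got {self.residue}")
        if not 1 <= self.exon <= 10:
            raise ValueError(f"exon must be in 1..10, got {self.exon}")
        if self.gnomad_count < 0:
            raise ValueError(f"gnomad_count must be >= 0, got {self.gnomad_count}")


_FUNCTIONAL_COLUMNS = ["variant", "lab", "assay", "replicate", "value"]
_KEY_COLUMNS = ["variant", "lab", "assay", "replicate"]


@dataclass
class FunctionalDataset:
    """Replicate-level functional measurements at a single format level."""

    data: pd.DataFrame
    format_level: FormatLevel = FormatLevel.CONTROL_NORMALIZED

    def __post_init__(self) -> None:
        self.format_level = FormatLevel(self.format_level)
        missing = [c for c in _FUNCTIONAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"functional table missing column(s): {', '.join(missing)}")
        df = self.data.loc[:, _FUNCTIONAL_COLUMNS].copy()
        df["replicate"] = df["replicate"].astype(int)
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"]).all():
            bad = df.index[~np.isfinite(df["value"])].tolist()
            raise FormatError(f"non-finite values at rows {bad}")
        dup = df.duplicated(subset=_KEY_COLUMNS)
        if dup.any():
            keys = df.loc[dup, _KEY_COLUMNS].to_records(index=False).tolist()
            raise FormatError(f"duplicate (variant, lab, assay, replicate) keys: {keys}")
        self.data = df.reset_index(drop=True)

    @property
    def variants(self) -> list[str]:
        return sorted(self.data["variant"].unique())

    @property
    def assays(self) -> list[str]:
        return sorted(self.data["assay"].unique())

    @property
    def labs(self) -> list[str]:
        return sorted(self.data["lab"].unique())

    def subset_lab(self, lab: str) -> "FunctionalDataset":
        return FunctionalDataset(self.data[self.data["lab"] == lab], self.format_level)

    def subset_variants(self, variants: Iterable[str]) -> "FunctionalDataset":
        keep = set(variants)
        return FunctionalDataset(
            self.data[self.data["variant"].isin(keep)], self.format_level
        )

    def sorted(self) -> pd.DataFrame:
        return self.data.sort_values(_KEY_COLUMNS, kind="mergesort").reset_index(drop=True)


def _read_tsv(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s): {', '.join(missing)}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering.
            lines = [int(i) + 2 for i in bad]
            raise FormatError(f"{path.name}: non-numeric {col!r} at line(s) {lines}")
        df[col] = converted
    return df


def read_functional_table(
    path: str | Path, format_level: FormatLevel = FormatLevel.CONTROL_NORMALIZED
) -> FunctionalDataset:
    """Read a long-form functional table; row order is irrelevant downstream."""
    df = _read_tsv(path, _FUNCTIONAL_COLUMNS, ["replicate", "value"])
    return FunctionalDataset(df, format_level)


def write_functional_table(ds: FunctionalDataset, path: str | Path) -> None:
    """Write with deterministic (sorted-by-key) row order for diffable output."""
    ds.sorted().to_csv(path, sep="\t", index=False, na_rep="NA")


_ANNOTATION_COLUMNS = ["variant", "residue", "exon", "gnomad_count", "reference_role", "lab"]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, _ANNOTATION_COLUMNS, ["residue", "exon", "gnomad_count"])
    df["residue"] = df["residue"].astype(int)
    df["exon"] = df["exon"].astype(int)
    df["gnomad_count"] = df["gnomad_count"].astype(int)
    df["reference_role"] = df["reference_role"].map(ReferenceRole)
    # Instantiating validates invariants row by row.
    for row in df.itertuples(index=False):
        VariantAnnotation(
            hgvs_p=row.variant,
            residue=row.residue,
            exon=row.exon,
            gnomad_count=row.gnomad_count,
            reference_role=row.reference_role,
            lab=row.lab,
        )
    return df.sort_values("variant", kind="mergesort").reset_index(drop=True)


def write_annotation_table(annotations: pd.DataFrame, path: str | Path) -> None:
    df = annotations.loc[:, _ANNOTATION_COLUMNS].copy()
    df["reference_role"] = df["reference_role"].map(
        lambda r: r.value if isinstance(r, ReferenceRole) else str(r)
    )
    df.sort_values("variant", kind="mergesort").to_csv(path, sep="\t", index=False, na_rep="NA")


_REGISTRY_COLUMNS = ["variant", "original_class", "registry_id", "co_occurring_pathogenic", "gnomad_count"]


def read_registry_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, _REGISTRY_COLUMNS, ["original_class", "gnomad_count"])
    df["original_class"] = df["original_class"].astype(int)
    df["gnomad_count"] = df["gnomad_count"].astype(int)
    if not df["original_class"].between(1, 5).all():
        bad = df.loc[~df["original_class"].between(1, 5), "variant"].tolist()
        raise FormatError(f"original_class outside 1..5 for {bad}")
    df["co_occurring_pathogenic"] = df["co_occurring_pathogenic"].map(
        {"True": True, "False": False, "true": True, "false": False}
    )
    if df["co_occurring_pathogenic"].isna().any():
        raise FormatError("co_occurring_pathogenic must be True/False")
    return df.sort_values("variant", kind="mergesort").reset_index(drop=True)


def write_registry_table(registry: pd.DataFrame, path: str | Path) -> None:
    registry.loc[:, _REGISTRY_COLUMNS].sort_values("variant", kind="mergesort").to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
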