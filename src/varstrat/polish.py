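"""Dataset "polishing": prepare a functional dataset for multivariate analysis.

Steps, in order: drop DNA-binding (EMSA) variables, aggregate replicates to
one value per (variant, assay variable), append two ordinal position-derived
columns (isoform-expression band from exon, functional-domain band from
residue), then zero-center and scale every column to unit sample variance.

EMSA is excluded from clustering because DNA binding was interrogated for
only a subset of variants; the candidates that warrant EMSA follow-up
(DNA-binding-domain residues, or transactivation below 50% of wild-type) can
still be listed with :func:`emsa_candidates`.

Position scores encode two well-established HNF1A position-phenotype
correlations: exons 8-10 appear only in hepatocyte-dominant isoforms (so
variants there dilute the beta-cell phenotype), and the transactivation
domain (residues 288-631) is more tolerant to variation than the
dimerization/DNA-binding region (1-287).  The numeric score values are
declared conventions, config-overridable; only their ordering carries
meaning (beta-cell-relevant positions weighted higher).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import FormatLevel, FunctionalDataset

__all__ = [
    "PROTEIN_LENGTH",
    "EXON_LAST_RESIDUE",
    "ScoreMap",
    "PositionScores",
    "PolishedMatrix",
    "MissingDataError",
    "residue_to_exon",
    "assign_position_scores",
    "aggregate_replicates",
    "drop_emsa",
    "emsa_candidates",
    "FunctionalDataPolisher",
    "polish_dataset",
]

#: Length of the canonical HNF1A protein.
PROTEIN_LENGTH = 631

#: Last protein residue encoded by each of the 10 exons of the canonical
#: HNF1A gene model (package convention used by the simulator and fixtures;
#: real analyses supply exon as an input column).
EXON_LAST_RESIDUE = (42, 117, 196, 271, 338, 409, 487, 540, 574, 631)

DNA_BINDING_DOMAIN_END = 287

DEFAULT_EMSA_TAGS = ("EMSA", "DNA_BINDING")


def residue_to_exon(residue: int) -> int:
    if not 1 <= residue <= PROTEIN_LENGTH:
        raise ValueError(f"residue must be in 1..{PROTEIN_LENGTH}, got {residue}")
    for exon, last in enumerate(EXON_LAST_RESIDUE, start=1):
        if residue <= last:
            return exon
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ScoreMap:
    """Ordinal weights for isoform-expression and functional-domain bands."""

    all_isoforms: float = 3.0       # exons 1-6: present in every isoform
    two_isoforms: float = 2.0       # exon 7
    liver_dominant: float = 1.0     # exons 8-10: hepatocyte-dominant isoforms
    dna_binding: float = 2.0        # residues 1-287 (dimerization + DNA binding)
    transactivation: float = 1.0    # residues 288-631


@dataclass(frozen=True)
class PositionScores:
    isoform_score: float
    isoform_band: str
    domain_score: float
    domain_band: str


def assign_position_scores(residue: int, exon: int, score_map: ScoreMap | None = None) -> PositionScores:
    """Map exon to the isoform band and residue to the domain band."""
    score_map = score_map or ScoreMap()
    if not 1 <= exon <= 10:
        raise ValueError(f"exon must be in 1..10, got {exon}")
    if residue < 1:
        raise ValueError(f"residue must be >= 1, got {residue}")
    if exon <= 6:
        iso = (score_map.all_isoforms, "ALL_ISOFORMS")
    elif exon == 7:
        iso = (score_map.two_isoforms, "TWO_ISOFORMS")
    else:
        iso = (score_map.liver_dominant, "LIVER_DOMINANT")
    if residue <= DNA_BINDING_DOMAIN_END:
        dom = (score_map.dna_binding, "DNA_BINDING")
    else:
        dom = (score_map.transactivation, "TRANSACTIVATION")
    return PositionScores(iso[0], iso[1], dom[0], dom[1])


class MissingDataError(ValueError):
    """A variant lacks replicates for one or more assay variables."""


_AGGREGATORS = {"mean": "mean", "median": "median"}


def aggregate_replicates(ds: FunctionalDataset, method: str = "mean") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicates to one value per (variant, assay variable).

    Returns ``(values, counts)`` as variant x variable frames.  Raises
    :class:`MissingDataError` listing every (variant, variable) cell with no
    replicates, rather than silently imputing.
    """
    if ds.format_level is not FormatLevel.CONTROL_NORMALIZED:
        raise ValueError(
            "aggregation requires CONTROL_NORMALIZED data, got " + ds.format_level.value
        )
    if method not in _AGGREGATORS:
        raise ValueError(f"unknown aggregation method {method!r}")
    agg = _AGGREGATORS[method]
    values = ds.data.pivot_table(
        index="variant", columns="assay", values="value", aggfunc=agg
    ).sort_index()
    counts = ds.data.pivot_table(
        index="variant", columns="assay", values="value", aggfunc="count"
    ).reindex(index=values.index, columns=values.columns).fillna(0).astype(int)
    if values.isna().any().any():
        offenders = [
            (variant, str(col))
            for col in values.columns
            for variant in values.index[values[col].isna()]
        ]
        raise MissingDataError(f"no replicates for cells: {offenders}")
    values.columns.name = None
    counts.columns.name = None
    return values, counts


def _is_emsa(name: str, tags: tuple[str, ...]) -> bool:
    upper = name.upper()
    return any(tag.upper() in upper for tag in tags)


def drop_emsa(ds: FunctionalDataset, tags: tuple[str, ...] = DEFAULT_EMSA_TAGS) -> FunctionalDataset:
    """Remove DNA-binding/EMSA assay variables; a no-op when absent."""
    keep = ~ds.data["assay"].map(lambda a: _is_emsa(a, tags)).astype(bool)
    return FunctionalDataset(ds.data.loc[keep], ds.format_level)


def emsa_candidates(
    annotations: pd.DataFrame,
    ta_values: pd.DataFrame,
    activity_threshold: float = 0.50,
    domain_end: int = DNA_BINDING_DOMAIN_END,
) -> pd.DataFrame:
    """Variants that warrant DNA-binding (EMSA) follow-up.

    Selected when the residue lies in the DNA-binding domain (<= ``domain_end``)
    OR any transactivation variable (expressed as fraction of wild-type) falls
    below ``activity_threshold``.  Variants with missing TA values are flagged,
    never silently dropped.  The result is reporting-only: EMSA never enters
    clustering.
    """
    ta_cols = [c for c in ta_values.columns if str(c).upper().startswith("TA")]
    ann = annotations.drop_duplicates("variant").set_index("variant")
    rows = []
    for variant, residue in ann["residue"].items():
        in_domain = residue <= domain_end
        if variant in ta_values.index and ta_cols:
            ta = ta_values.loc[variant, ta_cols]
            missing = bool(ta.isna().any())
            low_ta = bool((ta.dropna() < activity_threshold).any())
        else:
            missing, low_ta = True, False
        rows.append(
            {
                "variant": variant,
                "in_dna_binding_domain": bool(in_domain),
                "low_transactivation": low_ta,
                "missing_ta": missing,
                "selected": bool(in_domain or low_ta),
            }
        )
    return pd.DataFrame(rows).sort_values("variant").reset_index(drop=True)


@dataclass
class PolishedMatrix:
    """One row per variant; aggregated assay variables plus the two position
    scores, each column zero-mean and unit sample variance (ddof=1)."""

    values: pd.DataFrame
    replicate_counts: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        means = self.values.mean(axis=0)
        sds = self.values.std(axis=0, ddof=1)
        if not np.allclose(means, 0.0, atol=1e-9) or not np.allclose(sds, 1.0, atol=1e-9):
            raise ValueError("polished columns must be zero-mean, unit-variance")

    def destandardize(self) -> pd.DataFrame:
        return self.values * self.column_sds + self.column_means


ISOFORM_COLUMN = "isoform_score"
DOMAIN_COLUMN = "domain_score"


class FunctionalDataPolisher(BaseEstimator):
    """Transformer from replicate-level functional data to a standardized
    variant x variable matrix ready for PCA/clustering.

    Parameters
    ----------
    aggregate : {"mean", "median"}
        Replicate aggregator (mean by default; replicate counts are kept as
        metadata, never clustered).
    score_map : ScoreMap or None
        Ordinal isoform/domain weights; defaults to :class:`ScoreMap`.
    emsa_tags : tuple of str
        Assay-name fragments identifying DNA-binding variables to exclude.
    with_position_scores : bool
        Append the isoform/domain score columns (on by default).
    """

    def __init__(
        self,
        aggregate: str = "mean",
        score_map: ScoreMap | None = None,
        emsa_tags: tuple[str, ...] = DEFAULT_EMSA_TAGS,
        with_position_scores: bool = True,
    ):
        self.aggregate = aggregate
        self.score_map = score_map
        self.emsa_tags = emsa_tags
        self.with_position_scores = with_position_scores

    def _assemble(self, ds: FunctionalDataset, annotations: pd.DataFrame):
        if ds.format_level is not FormatLevel.CONTROL_NORMALIZED:
            raise ValueError(
                "polishing accepts only CONTROL_NORMALIZED data "
                f"(got {ds.format_level.value}); other levels are inspection-only"
            )
        ds = drop_emsa(ds, self.emsa_tags)
        values, counts = aggregate_replicates(ds, self.aggregate)
        ann = annotations.drop_duplicates("variant").set_index("variant")
        missing = [v for v in values.index if v not in ann.index]
        if missing:
            raise ValueError(f"variants lacking annotation: {missing}")
        if self.with_position_scores:
            scores = [
                assign_position_scores(int(ann.loc[v, "residue"]), int(ann.loc[v, "exon"]), self.score_map)
                for v in values.index
            ]
            values = values.copy()
            values[ISOFORM_COLUMN] = [s.isoform_score for s in scores]
            values[DOMAIN_COLUMN] = [s.domain_score for s in scores]
        return values.sort_index(), counts

    def fit(self, ds: FunctionalDataset, annotations: pd.DataFrame) -> "FunctionalDataPolisher":
        values, _ = self._assemble(ds, annotations)
        self.feature_names_in_ = list(values.columns)
        self.mean_ = values.mean(axis=0)
        self.scale_ = values.std(axis=0, ddof=1)
        constant = [str(c) for c in values.columns[self.scale_ <= 0]]
        if constant:
            raise ValueError(f"constant column(s), cannot scale: {', '.join(constant)}")
        return self

    def transform(self, ds: FunctionalDataset, annotations: pd.DataFrame) -> PolishedMatrix:
        values, counts = self._assemble(ds, annotations)
        standardized = (values[self.feature_names_in_] - self.mean_) / self.scale_
        return PolishedMatrix(
            values=standardized,
            replicate_counts=counts,
            column_means=self.mean_.copy(),
            column_sds=self.scale_.copy(),
            provenance={
                "aggregate": self.aggregate,
                "emsa_tags": list(self.emsa_tags),
                "with_position_scores": self.with_position_scores,
                "n_variants": int(len(standardized)),
            },
        )

    def fit_transform(self, ds: FunctionalDataset, annotations: pd.DataFrame) -> PolishedMatrix:
        return self.fit(ds, annotations).transform(ds, annotations)


def polish_dataset(
    ds: FunctionalDataset,
    annotations: pd.DataFrame,
    aggregate: str = "mean",
    score_map: ScoreMap | None = None,
    emsa_tags: tuple[str, ...] = DEFAULT_EMSA_TAGS,
) -> PolishedMatrix:
    """One-shot polish: drop EMSA, aggregate, score, center, scale."""
    return FunctionalDataPolisher(
        aggregate=aggregate, score_map=score_map, emsa_tags=emsa_tags
    ).fit_transform(ds, annotations)
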