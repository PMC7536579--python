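"""Synthetic two-laboratory functional-assay panels with known latent classes.

Emulates the study design in which two centres each characterize ~40
exome-detected HNF1A missense variants with a shared benchmark subset, using
four internal-control-normalized assay readouts (transactivation on two
promoter/cell contexts, protein abundance, nuclear localization).  Three
latent classes drive the expected signal:

``WT_LIKE``
    full activity on every assay (wild-type == 1.0);
``INTERMEDIATE``
    moderately reduced transactivation (0.6), near-normal abundance and
    localization — the type-2-diabetes-risk-modifier end of the continuum;
``DAMAGING``
    strongly reduced transactivation (0.3, the bottom of the 30%-110%
    activity range seen for such panels), reduced nuclear localization
    (0.5) and moderately reduced protein abundance (0.7) — most variants,
    including damaging ones, still express protein at adequate levels.

Noise is multiplicative log-normal at two levels: per-replicate dispersion
(luciferase-ratio-like, CV ~15% by default) and a per-(lab, assay) batch
factor.  Assay readouts are ratios and strictly positive, which the
log-normal respects.  Damaging variants are drawn preferentially from the
DNA-binding domain / early exons, mirroring the positional bias of
MODY-causal variants that makes position-derived scores informative.

Truth labels are returned separately and never written into the dataset
payload.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS_3,
    FormatLevel,
    FunctionalDataset,
    ReferenceRole,
)
from .polish import PROTEIN_LENGTH, residue_to_exon

__all__ = [
    "WT_LIKE",
    "INTERMEDIATE",
    "DAMAGING",
    "ClassProfile",
    "PanelSpec",
    "default_profiles",
    "generate_panel",
    "generate_references",
    "generate_registry",
]

WT_LIKE = "WT_LIKE"
INTERMEDIATE = "INTERMEDIATE"
DAMAGING = "DAMAGING"

DNA_BINDING_DOMAIN_END = 287

#: Well-characterized loss-of-function HNF1A-MODY positive controls (all in
#: the dimerization/DNA-binding region) and reference type 2 diabetes risk
#: modifiers, used as benchmark entries shared between laboratories.
MODY_REFERENCE_VARIANTS = (
    "p.Pro112Leu",
    "p.Arg203His",
    "p.Ala116Val",
    "p.Arg229Gln",
    "p.Thr260Met",
    "p.Arg271Trp",
)
T2D_REFERENCE_VARIANTS = ("p.Glu508Lys", "p.Ala98Val")
WILD_TYPE_ENTRIES = ("WT_Ile27", "WT_Leu27")


@dataclass(frozen=True)
class ClassProfile:
    """Latent-class signal model: per-assay mean activity (fraction of
    wild-type), per-assay replicate log-normal sdlog, class prevalence, and
    the probability that a variant of this class falls in the DNA-binding
    domain (residues 1-287)."""

    class_label: str
    mean_activity: dict[str, float]
    replicate_sd: dict[str, float]
    class_prevalence: float
    p_dna_binding: float = 0.45

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.mean_activity.values()):
            raise ValueError("mean_activity must be >= 0")
        if any(s < 0 for s in self.replicate_sd.values()):
            raise ValueError("replicate_sd must be >= 0")
        if not 0 <= self.class_prevalence <= 1:
            raise ValueError("class_prevalence must be in [0, 1]")


DEFAULT_ASSAY_VARIABLES = ("TA_HeLa_ALB", "TA_INS1_P2", "PE", "NUC_LOC")


@dataclass(frozen=True)
class PanelSpec:
    """Design of the simulated two-laboratory panel.

    ``n_variants_per_lab`` counts each laboratory's panel *including* the
    ``shared_variant_count`` benchmark variants measured by both, so the
    union across two labs holds ``2 n - shared`` distinct variants
    (40 + 40 - 7 = 73 under the defaults).
    """

    n_variants_per_lab: int = 40
    n_replicates: int = 3
    labs: tuple[str, ...] = ("lab_A", "lab_B")
    shared_variant_count: int = 7
    lab_effect_sd: float = 0.10
    assay_variables: tuple[str, ...] = DEFAULT_ASSAY_VARIABLES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants_per_lab < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        if self.shared_variant_count > self.n_variants_per_lab:
            raise ValueError("shared_variant_count must be <= n_variants_per_lab")
        if self.shared_variant_count < 0:
            raise ValueError("shared_variant_count must be >= 0")
        if not self.assay_variables:
            raise ValueError("assay_variables must be non-empty")
        if not self.labs:
            raise ValueError("labs must be non-empty")
        if self.lab_effect_sd < 0:
            raise ValueError("lab_effect_sd must be >= 0")


def default_profiles(
    assay_variables: tuple[str, ...] = DEFAULT_ASSAY_VARIABLES,
    replicate_sd: float = 0.15,
) -> list[ClassProfile]:
    """Frozen default class profiles (see module docstring for rationale)."""

    def means(ta: float, pe: float, nuc: float) -> dict[str, float]:
        out = {}
        for var in assay_variables:
            if var.upper().startswith("TA"):
                out[var] = ta
            elif "NUC" in var.upper():
                out[var] = nuc
            else:
                out[var] = pe
        return out

    sds = {var: replicate_sd for var in assay_variables}
    return [
        ClassProfile(WT_LIKE, means(1.0, 1.0, 1.0), sds, 0.40, p_dna_binding=0.40),
        ClassProfile(INTERMEDIATE, means(0.6, 0.8, 0.8), sds, 0.30, p_dna_binding=0.50),
        ClassProfile(DAMAGING, means(0.3, 0.7, 0.5), sds, 0.30, p_dna_binding=0.75),
    ]


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one integer seed into independent per-purpose substreams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


_AA = sorted(AMINO_ACIDS_3)
_RESERVED = set(MODY_REFERENCE_VARIANTS) | set(T2D_REFERENCE_VARIANTS) | set(WILD_TYPE_ENTRIES)


def _draw_variant(rng: np.random.Generator, profile: ClassProfile, used: set[str]) -> tuple[str, int]:
    """Draw a unique HGVS-style name with a class-conditional residue."""
    while True:
        if rng.random() < profile.p_dna_binding:
            residue = int(rng.integers(1, DNA_BINDING_DOMAIN_END + 1))
        else:
            residue = int(rng.integers(DNA_BINDING_DOMAIN_END + 1, PROTEIN_LENGTH + 1))
        ref, alt = rng.choice(_AA, size=2, replace=False)
        name = f"p.{ref}{residue}{alt}"
        if name not in used and name not in _RESERVED:
            used.add(name)
            return name, residue


def _measure(
    rng: np.random.Generator,
    rows: list[dict],
    variant: str,
    lab: str,
    profile: ClassProfile,
    spec: PanelSpec,
    lab_factors: dict[tuple[str, str], float],
) -> None:
    for var in spec.assay_variables:
        mean = profile.mean_activity[var]
        sd = profile.replicate_sd[var]
        factor = lab_factors[(lab, var)]
        noise = rng.normal(0.0, sd, size=spec.n_replicates) if sd > 0 else np.zeros(spec.n_replicates)
        values = mean * factor * np.exp(noise)
        for r, v in enumerate(values, start=1):
            rows.append(
                {"variant": variant, "lab": lab, "assay": var, "replicate": r, "value": float(v)}
            )


def _lab_factors(rng: np.random.Generator, spec: PanelSpec) -> dict[tuple[str, str], float]:
    return {
        (lab, var): float(np.exp(rng.normal(0.0, spec.lab_effect_sd))) if spec.lab_effect_sd > 0 else 1.0
        for lab in spec.labs
        for var in spec.assay_variables
    }


def generate_panel(
    spec: PanelSpec, profiles: list[ClassProfile] | None = None
) -> tuple[FunctionalDataset, pd.DataFrame, pd.Series]:
    """Simulate the exome-detected panel for every laboratory.

    Returns ``(dataset, annotations, truth)``: a replicate-level
    CONTROL_NORMALIZED dataset, per-(variant, lab) annotations (residue,
    exon, placeholder allele count 0, role NONE), and per-variant truth
    class labels kept strictly out of the dataset payload.
    """
    if profiles is None:
        profiles = default_profiles(spec.assay_variables)
    by_label = {p.class_label: p for p in profiles}
    for required in (WT_LIKE, INTERMEDIATE, DAMAGING):
        if required not in by_label:
            raise ValueError(f"missing profile for class {required}")
    prevalence = np.array([p.class_prevalence for p in profiles], dtype=float)
    if not np.isclose(prevalence.sum(), 1.0):
        raise ValueError("class prevalences must sum to 1")

    rng_assign, rng_noise = _substreams(spec.seed, 2)
    lab_factors = _lab_factors(rng_noise, spec)

    used: set[str] = set()
    rows: list[dict] = []
    ann_rows: list[dict] = []
    truth: dict[str, str] = {}

    def new_variant() -> tuple[str, int, ClassProfile]:
        profile = profiles[rng_assign.choice(len(profiles), p=prevalence)]
        name, residue = _draw_variant(rng_assign, profile, used)
        truth[name] = profile.class_label
        return name, residue, profile

    shared = [new_variant() for _ in range(spec.shared_variant_count)]
    for lab in spec.labs:
        unique = [new_variant() for _ in range(spec.n_variants_per_lab - spec.shared_variant_count)]
        for name, residue, profile in shared + unique:
            _measure(rng_noise, rows, name, lab, profile, spec, lab_factors)
            ann_rows.append(
                {
                    "variant": name,
                    "residue": residue,
                    "exon": residue_to_exon(residue),
                    "gnomad_count": 0,
                    "reference_role": ReferenceRole.NONE,
                    "lab": lab,
                }
            )

    ds = FunctionalDataset(pd.DataFrame(rows), FormatLevel.CONTROL_NORMALIZED)
    annotations = pd.DataFrame(ann_rows).sort_values(["variant", "lab"]).reset_index(drop=True)
    truth_series = pd.Series(truth, name="truth_class").sort_index()
    return ds, annotations, truth_series


def generate_references(
    spec: PanelSpec, profiles: list[ClassProfile] | None = None
) -> tuple[FunctionalDataset, pd.DataFrame]:
    """Simulate the benchmark entries measured in every laboratory: two
    wild-type constructs (Ile27 and Leu27 backgrounds), six MODY-causal
    positive controls drawn from the DAMAGING profile, and two type 2
    diabetes risk-modifier controls drawn from the INTERMEDIATE profile."""
    if profiles is None:
        profiles = default_profiles(spec.assay_variables)
    by_label = {p.class_label: p for p in profiles}
    rng = _substreams(spec.seed, 3)[2]
    lab_factors = _lab_factors(rng, spec)

    entries: list[tuple[str, int, ReferenceRole, ClassProfile]] = []
    for name in WILD_TYPE_ENTRIES:
        entries.append((name, 27, ReferenceRole.WILD_TYPE, by_label[WT_LIKE]))
    for name in MODY_REFERENCE_VARIANTS:
        residue = int("".join(ch for ch in name if ch.isdigit()))
        entries.append((name, residue, ReferenceRole.MODY_REFERENCE, by_label[DAMAGING]))
    for name in T2D_REFERENCE_VARIANTS:
        residue = int("".join(ch for ch in name if ch.isdigit()))
        entries.append((name, residue, ReferenceRole.T2D_REFERENCE, by_label[INTERMEDIATE]))

    rows: list[dict] = []
    ann_rows: list[dict] = []
    for lab in spec.labs:
        for name, residue, role, profile in entries:
            _measure(rng, rows, name, lab, profile, spec, lab_factors)
            ann_rows.append(
                {
                    "variant": name,
                    "residue": residue,
                    "exon": residue_to_exon(residue),
                    "gnomad_count": 0,
                    "reference_role": role,
                    "lab": lab,
                }
            )
    ds = FunctionalDataset(pd.DataFrame(rows), FormatLevel.CONTROL_NORMALIZED)
    annotations = pd.DataFrame(ann_rows).sort_values(["variant", "lab"]).reset_index(drop=True)
    return ds, annotations


# Class-conditional 5-tier assignment (no misclassification noise):
# DAMAGING -> likely pathogenic/pathogenic, INTERMEDIATE -> likely benign/VUS,
# WT_LIKE -> benign/likely benign.
_CLASS_CHOICES = {DAMAGING: (4, 5), INTERMEDIATE: (2, 3), WT_LIKE: (1, 2)}


def generate_registry(
    truth: pd.Series,
    seed: int,
    misclassification_rate: float = 0.0,
    co_occurrence_rate: float = 0.0,
    registry_id: str = "SYNTH",
) -> pd.DataFrame:
    """Assign 5-tier original classes correlated with the truth class, plus
    gnomAD-style allele counts from class-conditional distributions
    (DAMAGING variants are ultra-rare, allele count <= 2 by default)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    rows = []
    for variant in sorted(truth.index):
        label = truth[variant]
        cls = int(rng.choice(_CLASS_CHOICES[label]))
        if misclassification_rate > 0 and rng.random() < misclassification_rate:
            cls = int(rng.choice([c for c in range(1, 6) if c != cls]))
        if label == DAMAGING:
            count = int(rng.integers(0, 3))  # MODY-compatible: <= 2
        elif label == INTERMEDIATE:
            count = int(np.exp(rng.uniform(np.log(3), np.log(121))))
        else:
            count = int(np.exp(rng.uniform(np.log(20), np.log(5000))))
        rows.append(
            {
                "variant": variant,
                "original_class": cls,
                "registry_id": registry_id,
                "co_occurring_pathogenic": bool(rng.random() < co_occurrence_rate),
                "gnomad_count": count,
            }
        )
    return pd.DataFrame(rows)
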