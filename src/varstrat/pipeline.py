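"""End-to-end orchestration: polish -> PCA -> k vote -> k-means -> Ward ->
zones -> reclassification, per laboratory, with a shared-variant tanglegram
when two laboratories are present.

Every run writes its intermediate artifacts as TSV/JSON/Newick plus a
manifest (config, seeds, package version, input hashes); a rerun with the
same manifest reproduces identical outputs because all randomness flows from
the single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    REGISTRY_TOTALS,
    annotate_zones,
    reclassify_table,
    registry_report,
)
from .cluster import cut_dendrogram, hierarchical_linkage, kmeans, optimal_k
from .decompose import pca, select_components, variable_contributions
from .dendro import exhaustive_minimum, untangle
from .io import (
    FormatLevel,
    FunctionalDataset,
    read_annotation_table,
    read_functional_table,
    read_registry_table,
    write_annotation_table,
    write_functional_table,
    write_registry_table,
)
from .polish import FunctionalDataPolisher, ScoreMap
from .synthetic import PanelSpec, generate_panel, generate_references, generate_registry

__all__ = ["RunConfig", "simulate", "run_pipeline"]

#: Leaf counts up to which the exact rotation-search optimum is also reported
#: next to the greedy tanglegram coefficient.
EXACT_UNTANGLE_MAX_LEAVES = 12


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the synthetic study design."""

    output_dir: str = "varstrat_run"
    seed: int = 0
    synthetic: bool = True
    n_variants_per_lab: int = 40
    n_replicates: int = 3
    shared_variant_count: int = 7
    lab_effect_sd: float = 0.10
    functional_path: str | None = None
    annotation_path: str | None = None
    registry_path: str | None = None
    n_registry_total: int | None = None
    variance_threshold: float = 0.85
    k_range: tuple[int, int] = (2, 8)
    linkage: str = "ward"
    aggregate: str = "mean"
    entanglement_L: float = 1.5
    n_init: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write panel, references, annotations, registry and truth labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = PanelSpec(
        n_variants_per_lab=config.n_variants_per_lab,
        n_replicates=config.n_replicates,
        shared_variant_count=config.shared_variant_count,
        lab_effect_sd=config.lab_effect_sd,
        seed=config.seed,
    )
    panel, panel_ann, truth = generate_panel(spec)
    refs, ref_ann = generate_references(spec)
    ds = FunctionalDataset(
        pd.concat([panel.data, refs.data], ignore_index=True), FormatLevel.CONTROL_NORMALIZED
    )
    annotations = pd.concat([panel_ann, ref_ann], ignore_index=True)
    registry = generate_registry(truth, seed=config.seed)

    paths = {
        "functional": out / "functional.tsv",
        "annotations": out / "annotations.tsv",
        "registry": out / "registry.tsv",
        "truth": out / "truth.tsv",
    }
    write_functional_table(ds, paths["functional"])
    write_annotation_table(annotations, paths["annotations"])
    write_registry_table(registry, paths["registry"])
    truth.rename_axis("variant").reset_index().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _load_inputs(config: RunConfig, out: Path):
    if config.synthetic:
        paths = simulate(config, out / "inputs")
        ds = read_functional_table(paths["functional"])
        annotations = read_annotation_table(paths["annotations"])
        registry = read_registry_table(paths["registry"])
        n_total = config.n_registry_total or len(registry)
        return ds, annotations, registry, n_total, paths
    if not (config.functional_path and config.annotation_path):
        raise ValueError("non-synthetic runs need functional_path and annotation_path")
    ds = read_functional_table(config.functional_path)
    annotations = read_annotation_table(config.annotation_path)
    registry = (
        read_registry_table(config.registry_path) if config.registry_path else None
    )
    n_total = config.n_registry_total or (len(registry) if registry is not None else 0)
    paths = {
        "functional": Path(config.functional_path),
        "annotations": Path(config.annotation_path),
    }
    if config.registry_path:
        paths["registry"] = Path(config.registry_path)
    return ds, annotations, registry, n_total, paths


def _analyze_lab(config: RunConfig, lab: str, ds: FunctionalDataset, annotations: pd.DataFrame, out: Path):
    """Polish one laboratory's panel and cluster it; returns per-lab results."""
    lab_ds = ds.subset_lab(lab)
    lab_ann = annotations[annotations["lab"] == lab]
    matrix = FunctionalDataPolisher(aggregate=config.aggregate).fit_transform(lab_ds, lab_ann)
    decomp = pca(matrix)
    m = select_components(decomp, config.variance_threshold)
    contributions = variable_contributions(decomp, m)
    retained = decomp.scores.iloc[:, :m]

    lo, hi = config.k_range
    vote = optimal_k(retained, k_range=range(lo, hi + 1), seed=config.seed, n_init=config.n_init)
    km = kmeans(retained, vote.winner, seed=config.seed, n_init=config.n_init)
    dend = hierarchical_linkage(retained, config.linkage)
    ward_cut = cut_dendrogram(dend, vote.winner)

    roles = lab_ann.drop_duplicates("variant").set_index("variant")["reference_role"]
    centroids = {
        int(c): retained.loc[ward_cut.index[ward_cut == c]].mean(axis=0).to_numpy()
        for c in ward_cut.unique()
    }
    zones = annotate_zones(ward_cut, roles, centroids)

    prefix = out / f"lab_{lab}"
    matrix.values.rename_axis("variant").to_csv(f"{prefix}_polished.tsv", sep="\t")
    decomp.scores.rename_axis("variant").to_csv(f"{prefix}_pca_scores.tsv", sep="\t")
    decomp.loadings.rename_axis("variable").to_csv(f"{prefix}_pca_loadings.tsv", sep="\t")
    contributions.per_component.assign(overall_pct=contributions.overall).rename_axis(
        "variable"
    ).to_csv(f"{prefix}_contributions.tsv", sep="\t")
    assignments = pd.DataFrame(
        {"kmeans_cluster": km.assignment, "ward_cluster": ward_cut}
    ).rename_axis("variant")
    assignments["zone"] = assignments["ward_cluster"].map(lambda c: zones.zone_of(c).value)
    assignments.to_csv(f"{prefix}_assignments.tsv", sep="\t")
    Path(f"{prefix}_dendrogram.nwk").write_text(dend.to_newick() + "\n")
    return {
        "lab": lab,
        "n_components": m,
        "k_vote": vote,
        "kmeans": km,
        "dendrogram": dend,
        "ward_cut": ward_cut,
        "zones": zones,
        "assignments": assignments,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, annotations, registry, n_total, input_paths = _load_inputs(config, out)

    labs = ds.labs
    per_lab = {lab: _analyze_lab(config, lab, ds, annotations, out) for lab in labs}

    tangle_info = None
    if len(labs) >= 2:
        a, b = labs[0], labs[1]
        shared = set(per_lab[a]["dendrogram"].labels) & set(per_lab[b]["dendrogram"].labels)
        if len(shared) >= 2:
            tg = untangle(
                per_lab[a]["dendrogram"], per_lab[b]["dendrogram"], L=config.entanglement_L
            )
            tangle_info = {
                "labs": [a, b],
                "shared_leaves": sorted(map(str, shared)),
                "entanglement": tg.entanglement,
                "initial_entanglement": tg.initial_entanglement,
                "L": tg.L,
                "rounds": tg.rounds,
                "leaf_order_a": list(map(str, tg.leaf_order_a)),
                "leaf_order_b": list(map(str, tg.leaf_order_b)),
            }
            if len(shared) <= EXACT_UNTANGLE_MAX_LEAVES:
                tangle_info["exhaustive_minimum"] = exhaustive_minimum(
                    per_lab[a]["dendrogram"], per_lab[b]["dendrogram"], L=config.entanglement_L
                )
            (out / "tanglegram.json").write_text(json.dumps(tangle_info, indent=2))

    summary: dict = {
        "labs": {
            lab: {
                "n_components": res["n_components"],
                "k": res["k_vote"].winner,
                "k_votes": res["k_vote"].votes,
                "zones": {int(c): z.value for c, z in res["zones"].zones.items()},
            }
            for lab, res in per_lab.items()
        }
    }

    if registry is not None and len(registry):
        zone_by_variant: dict[str, str] = {}
        exon_by_variant = annotations.drop_duplicates("variant").set_index("variant")["exon"]
        for lab in labs:
            for variant, row in per_lab[lab]["assignments"].iterrows():
                zone_by_variant.setdefault(variant, row["zone"])
        table = registry[registry["variant"].isin(zone_by_variant)].copy()
        table["zone"] = table["variant"].map(zone_by_variant)
        table["exon"] = table["variant"].map(exon_by_variant)
        decisions = reclassify_table(table)
        report = registry_report(decisions, n_total, registry_id=str(registry["registry_id"].iloc[0]))
        decisions.to_csv(out / "reclassification.tsv", sep="\t", index=False)
        summary["reclassification"] = report.summary()

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {name: _hash_file(path) for name, path in input_paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
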