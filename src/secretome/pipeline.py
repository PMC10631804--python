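"""End-to-end orchestration of the secretome analysis.

Sequences the stages — dynamic-labeling kinetics, secreted-protein
classification, label-free filtering/imputation/clustering, and
donor-effect association on the secreted proteins that were also identified
label-free — and writes every intermediate as CSV next to a reproducibility
manifest (config, seed, config hash, per-stage row counts in/out).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate
from .kinetics import DEFAULT_K_CUTOFF, analyze_kinetics
from .labelfree import (
    DEFAULT_SEED,
    average_duplicates,
    dtw_cluster,
    filter_missingness,
    fuzzy_cmeans,
    impute,
    nmf_consensus,
    pca_overview,
    recommend_rank,
    standardize_rows,
)
from .mq_tables import (
    SchemaConfig,
    check_metadata_alignment,
    filter_evidence,
    read_donor_metadata,
    read_evidence,
    read_protein_groups,
)

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    evidence_path: str
    protein_groups_path: str
    metadata_path: str
    out_dir: str
    raw_file_hours: dict = field(default_factory=dict)
    annotations_path: str | None = None
    k_cutoff: float = DEFAULT_K_CUTOFF
    max_missing_frac: float = 0.30
    impute_mode: str = "none"
    fuzzy_clusters: int = 16
    dtw_clusters: int = 8
    nmf_ranks: tuple[int, ...] = (2, 3, 4, 5, 6)
    nmf_runs: int = 30
    seed: int = DEFAULT_SEED

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["nmf_ranks"] = tuple(raw.get("nmf_ranks", (2, 3, 4, 5, 6)))
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("evidence_path", "protein_groups_path", "metadata_path"):
            p = getattr(self, attr)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{attr}: no such file: {p}")
        if not self.raw_file_hours:
            raise ValueError("raw_file_hours map is required to assign time points")
        if self.impute_mode not in ("none", "sample", "protein"):
            raise ValueError(f"unknown impute_mode: {self.impute_mode!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full(config: RunConfig) -> dict:
    """Execute every stage in order and return the manifest dict.

    Fails before any compute if an input path is unreadable.  Outputs:
    ``kinetics.csv``, ``secreted_proteins.csv``, ``lfq_filtered.csv``,
    ``pca_scores.csv``, ``nmf_assignments.csv``, ``fuzzy_memberships.csv``,
    ``dtw_assignments.csv``, ``association.csv``, ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}

    schema = SchemaConfig(raw_file_hours=config.raw_file_hours)

    # --- stage 1: dynamic-labeling kinetics -> secreted list
    evidence = read_evidence(config.evidence_path, schema)
    filtered = filter_evidence(evidence)
    counts["evidence_filter"] = {"in": len(evidence), "out": len(filtered)}
    kinetics = analyze_kinetics(filtered, cutoff=config.k_cutoff)
    kinetics.to_csv(out / "kinetics.csv")
    secreted = kinetics.index[kinetics["classification"] == "secreted"]
    counts["kinetic_classification"] = {
        "in": len(kinetics),
        "out": int((kinetics["classification"] != "unclassified").sum()),
        "secreted": len(secreted),
        "intracellular": int((kinetics["classification"] == "intracellular").sum()),
    }
    pd.Series(secreted, name="protein_id").to_csv(
        out / "secreted_proteins.csv", index=False
    )

    # --- stage 2: label-free matrix
    lfq, annot = read_protein_groups(config.protein_groups_path, schema)
    metadata = read_donor_metadata(config.metadata_path)
    check_metadata_alignment(lfq, metadata)
    lfq_filtered = filter_missingness(lfq, config.max_missing_frac)
    counts["missingness_filter"] = {"in": len(lfq), "out": len(lfq_filtered)}
    lfq_imputed = impute(lfq_filtered, mode=config.impute_mode, seed=config.seed)
    counts["imputation"] = {
        "in": len(lfq_filtered),
        "out": len(lfq_imputed),
        "mode": config.impute_mode,
    }
    lfq_imputed.to_csv(out / "lfq_filtered.csv")

    # --- stage 3: clustering overviews
    scores, variance = pca_overview(lfq_imputed)
    scores.to_csv(out / "pca_scores.csv")
    nmf_input = lfq_imputed / lfq_imputed.sum(axis=0)  # per-sample unit total
    models = nmf_consensus(
        nmf_input, ranks=config.nmf_ranks, n_runs=config.nmf_runs, seed=config.seed
    )
    best_rank = recommend_rank(models)
    nmf_table = pd.DataFrame(
        {
            f"rank_{r}": models[r].assignments for r in models
        }
    )
    nmf_table.to_csv(out / "nmf_assignments.csv")
    counts["nmf"] = {
        "ranks": list(models),
        "cophenetic": {r: models[r].cophenetic for r in models},
        "recommended_rank": best_rank,
    }

    profiles = standardize_rows(
        average_duplicates(pd.DataFrame(np.log2(lfq_imputed)), metadata)
    )
    fuzzy_c = min(config.fuzzy_clusters, max(2, len(profiles) - 1))
    membership, _ = fuzzy_cmeans(profiles, c=fuzzy_c, seed=config.seed)
    membership.to_csv(out / "fuzzy_memberships.csv")
    dtw_k = min(config.dtw_clusters, len(profiles))
    dtw_assign, _ = dtw_cluster(profiles, k_clusters=dtw_k, seed=config.seed)
    dtw_assign.to_csv(out / "dtw_assignments.csv")
    counts["time_course_clustering"] = {
        "proteins": len(profiles),
        "fuzzy_clusters": fuzzy_c,
        "dtw_clusters": dtw_k,
    }

    # --- stage 4: association on secreted ∩ label-free
    secreted_in_lfq = [p for p in secreted if p in lfq.index]
    counts["secreted_overlap"] = {"in": len(secreted), "out": len(secreted_in_lfq)}
    results = associate(lfq, metadata, proteins=secreted_in_lfq)
    results.to_csv(out / "association.csv")
    counts["association"] = {
        "in": len(secreted_in_lfq),
        "out": int(results["converged"].sum()),
    }

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "counts": counts,
        "pca_variance_fractions": [float(v) for v in variance[:5]],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
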