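"""Readers and filters for MaxQuant-style search output tables.

MaxQuant writes tab-separated text files whose column headers drift between
versions.  A :class:`SchemaConfig` maps the logical fields the pipeline needs
onto concrete headers, with defaults matching the 1.6/2.0 conventions, and
carries the raw-file -> labeling-hours map used to assign time points (file
naming is site-specific, so the mapping is configuration, not parsing).

Evidence tables are returned as tidy :class:`pandas.DataFrame` objects with
canonical column names; protein-group tables are split into an LFQ intensity
matrix (proteins x samples, ``NaN`` for non-detection) and a per-protein
annotation frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "SchemaConfig",
    "EVIDENCE_COLUMNS",
    "PROTEIN_GROUP_COLUMNS",
    "read_evidence",
    "filter_evidence",
    "read_protein_groups",
    "read_donor_metadata",
    "check_metadata_alignment",
]

#: Logical field -> MaxQuant 1.6/2.0 evidence.txt header.
EVIDENCE_COLUMNS: dict[str, str] = {
    "peptide_sequence": "Sequence",
    "leading_razor_protein": "Leading razor protein",
    "raw_file": "Raw file",
    "intensity_light": "Intensity L",
    "intensity_heavy": "Intensity H",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}

#: Logical field -> MaxQuant proteinGroups.txt header.
PROTEIN_GROUP_COLUMNS: dict[str, str] = {
    "protein_id": "Protein IDs",
    "gene_name": "Gene names",
    "unique_peptides": "Unique peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    # Per-sample LFQ columns are "LFQ intensity <sample_id>".
    "lfq_prefix": "LFQ intensity ",
}

VALID_TISSUES = frozenset({"ASC", "BMSC"})
VALID_SEXES = frozenset({"M", "F"})


class SchemaError(ValueError):
    """A required column is absent or a table violates its contract."""


@dataclass(frozen=True)
class SchemaConfig:
    """Column-name mapping plus the raw-file -> labeling-hours assignment."""

    evidence_columns: Mapping[str, str] = field(
        default_factory=lambda: dict(EVIDENCE_COLUMNS)
    )
    protein_group_columns: Mapping[str, str] = field(
        default_factory=lambda: dict(PROTEIN_GROUP_COLUMNS)
    )
    raw_file_hours: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ev = dict(EVIDENCE_COLUMNS)
        ev.update(raw.get("evidence_columns", {}))
        pg = dict(PROTEIN_GROUP_COLUMNS)
        pg.update(raw.get("protein_group_columns", {}))
        hours = {str(k): float(v) for k, v in raw.get("raw_file_hours", {}).items()}
        return cls(evidence_columns=ev, protein_group_columns=pg, raw_file_hours=hours)


def _flag(frame: pd.DataFrame, column: str) -> pd.Series:
    """MaxQuant marks reverse/contaminant rows with '+'; blank otherwise."""
    if column not in frame.columns:
        return pd.Series(False, index=frame.index)
    return frame[column].fillna("").astype(str).str.strip().eq("+")


def _require_columns(frame: pd.DataFrame, required: Mapping[str, str], path) -> None:
    missing = [header for header in required.values() if header not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )


def read_evidence(
    path: str | Path, schema: SchemaConfig | None = None
) -> pd.DataFrame:
    """Read a MaxQuant-style ``evidence.txt`` into canonical tidy form.

    Returns one row per evidence row with columns ``peptide_sequence``,
    ``protein_id``, ``time_point`` (hours, via ``schema.raw_file_hours``),
    ``intensity_light``, ``intensity_heavy``, ``is_reverse``,
    ``is_contaminant``.  Missing intensities are read as 0 (unquantified).
    """
    schema = schema or SchemaConfig()
    cols = schema.evidence_columns
    # round_trip parsing keeps every numeric cell bit-identical to the file
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {k: v for k, v in cols.items() if k not in ("reverse", "contaminant")}
    _require_columns(frame, required, path)

    raw_files = frame[cols["raw_file"]].astype(str)
    unmapped = sorted(set(raw_files) - set(schema.raw_file_hours))
    if unmapped:
        raise SchemaError(
            f"{path}: raw file(s) not in the raw_file -> hours map: "
            f"{', '.join(unmapped)}"
        )

    out = pd.DataFrame(
        {
            "peptide_sequence": frame[cols["peptide_sequence"]].astype(str),
            "protein_id": frame[cols["leading_razor_protein"]].astype(str),
            "time_point": raw_files.map(schema.raw_file_hours).astype(float),
            "intensity_light": pd.to_numeric(
                frame[cols["intensity_light"]], errors="coerce"
            ).fillna(0.0),
            "intensity_heavy": pd.to_numeric(
                frame[cols["intensity_heavy"]], errors="coerce"
            ).fillna(0.0),
            "is_reverse": _flag(frame, cols["reverse"]),
            "is_contaminant": _flag(frame, cols["contaminant"]),
        }
    )
    if (out["intensity_light"] < 0).any() or (out["intensity_heavy"] < 0).any():
        raise SchemaError(f"{path}: negative intensities are not valid")
    return out


def filter_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Drop reverse and contaminant rows, preserving order (idempotent)."""
    keep = ~(evidence["is_reverse"] | evidence["is_contaminant"])
    return evidence.loc[keep].copy()


def read_protein_groups(
    path: str | Path,
    schema: SchemaConfig | None = None,
    min_unique_peptides: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``proteinGroups.txt`` into an LFQ matrix and an annotation frame.

    Reverse and contaminant groups are removed first, then groups with fewer
    than ``min_unique_peptides`` unique peptides.  LFQ intensities of 0 are
    recoded as missing (``NaN``): MaxQuant emits 0 for non-detection, not a
    measured zero.

    Returns ``(lfq, annot)`` where ``lfq`` is proteins x samples (sample ids
    taken from the ``LFQ intensity <sample>`` headers) and ``annot`` carries
    ``gene_name`` and ``unique_peptides`` indexed by protein id.
    """
    schema = schema or SchemaConfig()
    cols = schema.protein_group_columns
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {
        k: v
        for k, v in cols.items()
        if k in ("protein_id", "unique_peptides")
    }
    _require_columns(frame, required, path)

    prefix = cols["lfq_prefix"]
    lfq_headers = [c for c in frame.columns if c.startswith(prefix)]
    if not lfq_headers:
        raise SchemaError(f"{path}: no '{prefix}<sample>' columns found")

    keep = ~(_flag(frame, cols["reverse"]) | _flag(frame, cols["contaminant"]))
    frame = frame.loc[keep]
    unique_pep = pd.to_numeric(frame[cols["unique_peptides"]], errors="coerce").fillna(0)
    frame = frame.loc[unique_pep >= min_unique_peptides]

    ids = frame[cols["protein_id"]].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise SchemaError(f"{path}: duplicate protein id(s): {', '.join(dup)}")

    lfq = frame[lfq_headers].apply(pd.to_numeric, errors="coerce")
    lfq.columns = [c[len(prefix):] for c in lfq_headers]
    lfq.index = pd.Index(ids, name="protein_id")
    lfq = lfq.mask(lfq <= 0)  # zeros -> missing

    gene_col = cols.get("gene_name")
    annot = pd.DataFrame(
        {
            "gene_name": (
                frame[gene_col].fillna("").astype(str).to_numpy()
                if gene_col in frame.columns
                else ""
            ),
            "unique_peptides": pd.to_numeric(
                frame[cols["unique_peptides"]], errors="coerce"
            )
            .fillna(0)
            .astype(int)
            .to_numpy(),
        },
        index=lfq.index,
    )
    return lfq, annot


def read_donor_metadata(path: str | Path) -> pd.DataFrame:
    """Read donor metadata CSV (``sample_id,tissue,sex,age_years``)."""
    meta = pd.read_csv(path)
    required = ["sample_id", "tissue", "sex", "age_years"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing column(s): {', '.join(missing)}")
    meta = meta[required].copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    bad_tissue = set(meta["tissue"]) - VALID_TISSUES
    if bad_tissue:
        raise SchemaError(f"{path}: unknown tissue value(s): {sorted(bad_tissue)}")
    bad_sex = set(meta["sex"]) - VALID_SEXES
    if bad_sex:
        raise SchemaError(f"{path}: unknown sex value(s): {sorted(bad_sex)}")
    meta["age_years"] = pd.to_numeric(meta["age_years"])
    if (meta["age_years"] <= 0).any():
        raise SchemaError(f"{path}: ages must be positive")
    return meta


def check_metadata_alignment(lfq: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Every LFQ sample column must have exactly one metadata row."""
    lfq_samples = set(lfq.columns)
    meta_samples = set(metadata["sample_id"])
    missing = sorted(lfq_samples - meta_samples)
    if missing:
        raise SchemaError(f"samples without metadata: {', '.join(missing)}")
    extra = sorted(meta_samples - lfq_samples)
    if extra:
        warnings.warn(f"metadata rows without LFQ columns: {', '.join(extra)}")
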