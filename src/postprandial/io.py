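"""Tabular input/output and validation for the pipeline's file formats.

All tables are tab-separated UTF-8 text; lines starting with ``#`` are
comments.  Readers validate against the study design (five visceral organs,
three digestive time points) and never silently drop rows — malformed input
raises rather than shrinking the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

TISSUES = ("heart", "liver", "stomach", "pancreas", "intestine")
TIMEPOINTS = ("fasting", "24h", "48h")  # classification depends on this order


class FormatError(ValueError):
    """A file does not have the expected columns or cannot be parsed."""


class ValidationError(ValueError):
    """A file parses but violates a design or type invariant."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


@dataclass(frozen=True)
class SampleSheet:
    """The study design: one sample per (tissue, timepoint) cell.

    Timepoints are ordered ``fasting < 24h < 48h`` by the enum, never by
    column order in any file.
    """

    frame: pd.DataFrame  # columns: sample_id, tissue, timepoint

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_for(self, tissue: str) -> dict[str, str]:
        """Map timepoint -> sample_id for one tissue, in timepoint order."""
        if tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {tissue!r}")
        sub = self.frame[self.frame["tissue"] == tissue]
        out = {row.timepoint: row.sample_id for row in sub.itertuples()}
        return {tp: out[tp] for tp in TIMEPOINTS if tp in out}

    def tissues(self) -> list[str]:
        return [t for t in TISSUES if t in set(self.frame["tissue"])]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path)
    _require_columns(df, ("sample_id", "tissue", "timepoint"), path)
    df = df[["sample_id", "tissue", "timepoint"]].astype(str)
    if len(df) == 0:
        raise ValidationError(f"{path}: sample sheet has no samples")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"{path}: duplicate sample_id(s) {dups}")
    bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
    if bad_tissue:
        raise ValidationError(f"{path}: unknown tissue(s) {bad_tissue}")
    bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
    if bad_tp:
        raise ValidationError(f"{path}: unknown timepoint(s) {bad_tp}")
    if df.duplicated(subset=["tissue", "timepoint"]).any():
        raise ValidationError(f"{path}: more than one sample per (tissue, timepoint)")
    return SampleSheet(df.reset_index(drop=True))


def read_count_table(path: str | Path, sheet: SampleSheet) -> pd.DataFrame:
    """Transcript-level fragment counts.

    Columns: transcript_id, gene_id, length_nt, then one column per sample in
    the sheet.  Returns the validated DataFrame.
    """
    df = _read_tsv(path)
    _require_columns(df, ("transcript_id", "gene_id", "length_nt"), path)
    sample_cols = [c for c in df.columns if c not in ("transcript_id", "gene_id", "length_nt")]
    unknown = sorted(set(sample_cols) - set(sheet.sample_ids))
    if unknown:
        raise ValidationError(f"{path}: sample column(s) {unknown} absent from sample sheet")
    if df["transcript_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate transcript_id")
    if (df["length_nt"] < 1).any():
        raise ValidationError(f"{path}: length_nt must be >= 1")
    if (df[sample_cols] < 0).any().any():
        raise ValidationError(f"{path}: negative count")
    return df


def read_protein_id_table(path: str | Path) -> pd.DataFrame:
    """Search-engine style protein identification export.

    Columns: protein_id, annotation, unique_peptides, and optionally empai
    (absent values allowed).
    """
    df = _read_tsv(path)
    _require_columns(df, ("protein_id", "annotation", "unique_peptides"), path)
    if "empai" not in df.columns:
        df = df.assign(empai=float("nan"))
    df = df[["protein_id", "annotation", "unique_peptides", "empai"]].copy()
    df["protein_id"] = df["protein_id"].astype(str)
    df["annotation"] = df["annotation"].astype(str)
    if df["protein_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate protein_id")
    if (df["unique_peptides"] < 0).any():
        raise ValidationError(f"{path}: unique_peptides must be >= 0")
    if (df["empai"].dropna() < 0).any():
        raise ValidationError(f"{path}: empai must be >= 0")
    return df.reset_index(drop=True)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Gene -> GO term annotation; go_terms is a semicolon-separated set."""
    df = _read_tsv(path)
    _require_columns(df, ("gene_id", "go_terms"), path)
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: one row per gene required")
    terms = df["go_terms"].fillna("").astype(str).map(
        lambda s: frozenset(t for t in s.split(";") if t)
    )
    out = pd.DataFrame({"gene_id": df["gene_id"].astype(str), "go_terms": terms})
    if "description" in df.columns:
        out["description"] = df["description"].fillna("").astype(str)
    else:
        out["description"] = ""
    return out


def read_ontology_edges(path: str | Path) -> pd.DataFrame:
    """Child/parent term edges; the edge set must be acyclic."""
    df = _read_tsv(path)
    _require_columns(df, ("child", "parent"), path)
    df = df[["child", "parent"]].astype(str)
    g = nx.DiGraph(df.itertuples(index=False, name=None))
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError(f"{path}: ontology edges contain a cycle")
    return df


def read_pathway_membership(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ("gene_id", "pathway_id", "entry_label"), path)
    df = df[["gene_id", "pathway_id", "entry_label"]].astype(str)
    if df.duplicated(subset=["gene_id", "pathway_id"]).any():
        raise ValidationError(f"{path}: duplicate (gene_id, pathway_id) pair")
    return df


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result as TSV; reals use fixed 6-decimal text."""
    if records is None:
        raise ValidationError("records is None")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV read-back for tables written by :func:`write_table`."""
    return _read_tsv(path)
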