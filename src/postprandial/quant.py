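"""Gene-level abundance and FPKM normalisation.

The gene model mirrors a de-novo transcriptome convention: a gene's count is
the sum of its transcripts' counts, and the longest member transcript
represents the gene's length (no effective-length correction).  FPKM is

    FPKM_{g,s} = C_{g,s} * 1e9 / (L_g * N_s)

with L_g in nucleotides and N_s the per-sample total mapped fragments.  When
no totals are supplied, N_s defaults to the column sums of the gene-level
table, which makes the conservation identity sum_g FPKM*L/1e9 == 1 exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleSheet, ValidationError

META_COLS = ("transcript_id", "gene_id", "length_nt")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    representative_length_nt: int
    member_transcripts: tuple[str, ...]


def aggregate_transcripts_to_genes(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, list[GeneModel]]:
    """Collapse a transcript-level count table to gene level.

    Counts are summed per gene; the representative length is the longest
    member transcript.  Output rows are ordered by gene_id.
    """
    sample_cols = [c for c in counts.columns if c not in META_COLS]
    grouped = counts.groupby("gene_id", sort=True)
    gene_rows = grouped[sample_cols].sum()
    lengths = grouped["length_nt"].max()
    models = [
        GeneModel(
            gene_id=str(gid),
            representative_length_nt=int(lengths.loc[gid]),
            member_transcripts=tuple(sub["transcript_id"]),
        )
        for gid, sub in grouped
    ]
    out = pd.DataFrame({"gene_id": gene_rows.index, "length_nt": lengths.values})
    out = pd.concat([out.reset_index(drop=True), gene_rows.reset_index(drop=True)], axis=1)
    return out, models


def compute_fpkm(
    gene_counts: pd.DataFrame,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM matrix (genes x samples) from a gene-level count table.

    ``totals`` maps sample_id -> total mapped fragments; ``None`` derives
    totals from the column sums of ``gene_counts``.
    """
    sample_cols = [c for c in gene_counts.columns if c not in META_COLS]
    counts = gene_counts[sample_cols].to_numpy(dtype=float)
    lengths = gene_counts["length_nt"].to_numpy(dtype=float)
    if totals is None:
        n_s = counts.sum(axis=0)
    else:
        missing = [s for s in sample_cols if s not in totals.index]
        if missing:
            raise ValidationError(f"totals missing sample(s) {missing}")
        n_s = totals.loc[sample_cols].to_numpy(dtype=float)
    if np.any(n_s <= 0):
        raise ValidationError("per-sample total fragments must be > 0")
    fpkm = counts * 1e9 / (lengths[:, None] * n_s[None, :])
    out = pd.DataFrame(fpkm, index=pd.Index(gene_counts["gene_id"], name="gene_id"), columns=sample_cols)
    out.attrs["length_nt"] = pd.Series(lengths, index=out.index)
    out.attrs["total_fragments"] = pd.Series(n_s, index=sample_cols)
    return out


def log2_median_center(
    expr: pd.DataFrame,
    genes: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(FPKM + pseudocount), then subtract each gene-row's median."""
    if genes is not None:
        if len(genes) == 0:
            raise ValidationError("empty gene subset")
        missing = set(genes) - set(expr.index)
        if missing:
            raise ValidationError(f"genes not in matrix: {sorted(missing)[:5]}")
        expr = expr.loc[genes]
    logged = np.log2(expr + pseudocount)
    return logged.sub(logged.median(axis=1), axis=0)


def filter_by_max_fpkm(
    expr: pd.DataFrame, threshold: float, strict: bool = True
) -> list[str]:
    """Genes whose row maximum exceeds (strict) or meets (non-strict) the cut."""
    row_max = expr.max(axis=1)
    keep = row_max > threshold if strict else row_max >= threshold
    return list(expr.index[keep])


def validate_expression_matrix(expr: pd.DataFrame, sheet: SampleSheet) -> None:
    if (expr.to_numpy() < 0).any():
        raise ValidationError("FPKM values must be non-negative")
    unknown = sorted(set(expr.columns) - set(sheet.sample_ids))
    if unknown:
        raise ValidationError(f"expression columns {unknown} absent from sample sheet")
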