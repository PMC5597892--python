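"""Seven-class expression-trend classification over the digestive time course.

Each gene's FPKM triple (fasting, 24 h, 48 h) is classified by three gates:

1. expression — is max FPKM over ``expr_min`` (default 10)?  If not the gene
   is LOWLY_EXPRESSED.
2. differential expression — does any of the three pairwise comparisons have
   a fold change over ``fc_min`` (default 4)?  If so the gene is a DEG and is
   assigned a directional trend (UP, DOWN, UP_THEN_DOWN, DOWN_THEN_UP).
3. otherwise — HIGHLY_EXPRESSED if max FPKM is over ``high_min`` (default
   200), else MODERATELY_EXPRESSED.

Fold change between two FPKM values uses a small pseudocount so that zeros
are defined:  FC = (max(a,b) + eps) / (min(a,b) + eps), with the direction
being the sign of b - a.  All three class-gate comparisons are strict (">"),
matching the "over 10 / over 4 / over 200" wording of the scheme; the
separate strict-DEG selector for heat maps uses ">=" thresholds (FPKM >= 400
in at least one time point and FC >= 2 in at least one comparison).

The directional trend of a DEG is decided from the two consecutive
transitions (fasting->24h, 24h->48h): if both are significant with signs
(+,-) the gene is UP_THEN_DOWN, with (-,+) DOWN_THEN_UP; otherwise the trend
is the direction of the largest-magnitude significant pairwise comparison
(ties broken in the order (f0,f1), (f0,f2), (f1,f2)).  Records where
significant comparisons disagree in direction without forming a consecutive
up-down or down-up pattern carry an ``ambiguous`` flag, since that corner is
a convention rather than part of the published scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .io import TIMEPOINTS, SampleSheet, ValidationError


class TrendClass(Enum):
    UP = "Upregulated"
    UP_THEN_DOWN = "Up- then downregulated"
    DOWN = "Downregulated"
    DOWN_THEN_UP = "Down- then upregulated"
    HIGHLY_EXPRESSED = "Highly expressed"
    MODERATELY_EXPRESSED = "Moderately expressed"
    LOWLY_EXPRESSED = "Lowly expressed"


#: pathway-map colour per trend class (token, hex)
TREND_COLORS: dict[TrendClass, tuple[str, str]] = {
    TrendClass.UP: ("Red", "#FF0000"),
    TrendClass.DOWN: ("Blue", "#0000FF"),
    TrendClass.UP_THEN_DOWN: ("Yellow", "#FFFF00"),
    TrendClass.DOWN_THEN_UP: ("Brown", "#A52A2A"),
    TrendClass.HIGHLY_EXPRESSED: ("Purple", "#800080"),
    TrendClass.MODERATELY_EXPRESSED: ("Pink", "#FFC0CB"),
    TrendClass.LOWLY_EXPRESSED: ("Dark grey", "#A9A9A9"),
}

DEG_CLASSES = frozenset(
    {TrendClass.UP, TrendClass.DOWN, TrendClass.UP_THEN_DOWN, TrendClass.DOWN_THEN_UP}
)

#: default classification thresholds (strict ">" comparisons)
DEFAULT_THRESHOLDS = {"expr_min": 10.0, "high_min": 200.0, "fc_min": 4.0}
DEFAULT_FC_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class GeneTrendRecord:
    gene_id: str
    fpkm_triple: tuple[float, float, float]
    pairwise_fc: tuple[tuple[float, int], ...]  # ((mag, dir) for (0,1),(0,2),(1,2))
    max_fpkm: float
    trend: TrendClass
    ambiguous: bool = False


def fold_change(a: float, b: float, eps: float = DEFAULT_FC_PSEUDOCOUNT) -> tuple[float, int]:
    """Fold-change magnitude (>= 1) and direction between two FPKM values."""
    if a < 0 or b < 0:
        raise ValidationError("FPKM must be non-negative")
    lo, hi = (a, b) if a <= b else (b, a)
    magnitude = (hi + eps) / (lo + eps)
    direction = 0 if a == b else (1 if b > a else -1)
    return magnitude, direction


def classify_gene(
    f0: float,
    f1: float,
    f2: float,
    gene_id: str = "",
    thresholds: dict[str, float] | None = None,
    eps: float = DEFAULT_FC_PSEUDOCOUNT,
) -> GeneTrendRecord:
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    triple = (float(f0), float(f1), float(f2))
    max_fpkm = max(triple)
    pairs = ((0, 1), (0, 2), (1, 2))
    fcs = tuple(fold_change(triple[i], triple[j], eps) for i, j in pairs)

    ambiguous = False
    if max_fpkm <= thr["expr_min"]:
        trend = TrendClass.LOWLY_EXPRESSED
    elif any(mag > thr["fc_min"] for mag, _ in fcs):
        trend, ambiguous = _deg_trend(fcs, thr["fc_min"])
    elif max_fpkm > thr["high_min"]:
        trend = TrendClass.HIGHLY_EXPRESSED
    else:
        trend = TrendClass.MODERATELY_EXPRESSED
    return GeneTrendRecord(gene_id, triple, fcs, max_fpkm, trend, ambiguous)


def _deg_trend(fcs, fc_min) -> tuple[TrendClass, bool]:
    (m01, d01), (m02, d02), (m12, d12) = fcs
    if m01 > fc_min and m12 > fc_min:
        if d01 > 0 and d12 < 0:
            return TrendClass.UP_THEN_DOWN, False
        if d01 < 0 and d12 > 0:
            return TrendClass.DOWN_THEN_UP, False
    significant = [(m, d) for m, d in fcs if m > fc_min]
    best_mag, best_dir = max(significant, key=lambda md: md[0])
    directions = {d for _, d in significant}
    ambiguous = len(directions) > 1
    return (TrendClass.UP if best_dir > 0 else TrendClass.DOWN), ambiguous


def classify_matrix(
    expr: pd.DataFrame,
    sheet: SampleSheet,
    tissue: str,
    thresholds: dict[str, float] | None = None,
    eps: float = DEFAULT_FC_PSEUDOCOUNT,
) -> list[GeneTrendRecord]:
    """Classify every gene of one tissue; the result is a partition."""
    samples = sheet.samples_for(tissue)
    missing = [tp for tp in TIMEPOINTS if tp not in samples]
    if missing:
        raise ValidationError(f"tissue {tissue!r} lacks timepoint(s) {missing}")
    cols = [samples[tp] for tp in TIMEPOINTS]
    sub = expr[cols]
    return [
        classify_gene(f0, f1, f2, gene_id=str(gid), thresholds=thresholds, eps=eps)
        for gid, (f0, f1, f2) in zip(sub.index, sub.to_numpy())
    ]


def summarize(per_tissue: dict[str, list[GeneTrendRecord]]) -> pd.DataFrame:
    """Count and percentage per trend class per tissue (plus a Total row).

    Percentages are rounded to one decimal of the tissue's gene total.
    """
    if not per_tissue:
        raise ValidationError("no classifications to summarise")
    rows = []
    for tissue, records in per_tissue.items():
        if not records:
            raise ValidationError(f"tissue {tissue!r} has no records")
        total = len(records)
        counts = {cls: 0 for cls in TrendClass}
        for rec in records:
            counts[rec.trend] += 1
        for cls in TrendClass:
            rows.append(
                {
                    "tissue": tissue,
                    "trend": cls.value,
                    "count": counts[cls],
                    "percent": round(100.0 * counts[cls] / total, 1),
                }
            )
        rows.append({"tissue": tissue, "trend": "Total", "count": total, "percent": 100.0})
    return pd.DataFrame(rows)


def select_strict_degs(
    expr: pd.DataFrame,
    sheet: SampleSheet,
    tissue: str,
    fpkm_min: float = 400.0,
    fc_min: float = 2.0,
    eps: float = DEFAULT_FC_PSEUDOCOUNT,
) -> list[str]:
    """Heat-map DEG selector: FPKM >= fpkm_min at >= 1 time point AND
    FC >= fc_min in >= 1 pairwise comparison (both inclusive)."""
    samples = sheet.samples_for(tissue)
    missing = [tp for tp in TIMEPOINTS if tp not in samples]
    if missing:
        raise ValidationError(f"tissue {tissue!r} lacks timepoint(s) {missing}")
    cols = [samples[tp] for tp in TIMEPOINTS]
    selected = []
    for gid, (f0, f1, f2) in zip(expr.index, expr[cols].to_numpy()):
        if max(f0, f1, f2) < fpkm_min:
            continue
        mags = [fold_change(a, b, eps)[0] for a, b in ((f0, f1), (f0, f2), (f1, f2))]
        if any(m >= fc_min for m in mags):
            selected.append(str(gid))
    return selected


def assign_color(trend: TrendClass) -> tuple[str, str]:
    """Colour token and hex for a trend class (total, injective mapping)."""
    return TREND_COLORS[trend]


def records_to_frame(records: list[GeneTrendRecord]) -> pd.DataFrame:
    """Flatten trend records for TSV export."""
    rows = []
    for r in records:
        token, hexcode = assign_color(r.trend)
        rows.append(
            {
                "gene_id": r.gene_id,
                "f0": r.fpkm_triple[0],
                "f1": r.fpkm_triple[1],
                "f2": r.fpkm_triple[2],
                "fc01": r.pairwise_fc[0][0],
                "fc02": r.pairwise_fc[1][0],
                "fc12": r.pairwise_fc[2][0],
                "max_fpkm": r.max_fpkm,
                "class": r.trend.name,
                "color": token,
                "hex": hexcode,
                "ambiguous": int(r.ambiguous),
            }
        )
    return pd.DataFrame(rows)
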