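"""Subtractive identification of the gastric-juice secretome.

The digestive-fluid protein list is reduced by an audited chain of filters:

1. peptide evidence — keep identifications with >= 2 unique peptides;
2. plasma subtraction — remove proteins also identified in plasma (assumed
   blood contamination during collection);
3. prey-homolog subtraction — derive a base search term from every prey
   (mouse) protein name (e.g. "collagen" from "Collagen alpha-1(I) chain")
   and remove python proteins whose annotation contains any base term;
4. categorisation — the survivors are split into gastric mucosal,
   proteolytic, other hydrolytic and other secreted proteins, with
   intracellular / membrane annotations set aside as not secreted.

Every stage records which proteins it removed and why, so the report can be
audited: |retained_i| + |removed_i| = |retained_{i-1}| at every step.

Protein abundance uses the exponentially modified protein abundance index,
emPAI = 10^(N_observed / N_observable) - 1, with N_observable approximated
by the count of distinct fully tryptic peptides of length 6-35.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from scipy.stats import linregress

from .io import ValidationError
from .seqtools import count_observable_peptides

#: tokens that end a base name when deriving prey search terms
DEFAULT_STOP_TOKENS = frozenset(
    {"alpha", "beta", "gamma", "type", "chain", "isoform", "precursor", "subunit"}
)

CATEGORY_ORDER = ("mucosal", "proteolytic", "other_hydrolytic", "other")
NOT_SECRETED = "not_secreted"


@dataclass(frozen=True)
class FilterStage:
    name: str
    retained: pd.DataFrame
    removed: pd.DataFrame
    reasons: dict[str, str]  # protein_id -> why removed

    def audit(self, previous_n: int) -> bool:
        return len(self.retained) + len(self.removed) == previous_n


@dataclass
class FilterChainReport:
    stages: list[FilterStage] = field(default_factory=list)

    def counts(self) -> list[tuple[str, int]]:
        return [(s.name, len(s.retained)) for s in self.stages]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            for pid in stage.removed["protein_id"]:
                rows.append(
                    {"stage": stage.name, "protein_id": pid, "removed": 1,
                     "reason": stage.reasons.get(pid, "")}
                )
        final = self.stages[-1].retained if self.stages else pd.DataFrame(columns=["protein_id"])
        for pid in final["protein_id"]:
            rows.append({"stage": "final", "protein_id": pid, "removed": 0, "reason": ""})
        return pd.DataFrame(rows, columns=["stage", "protein_id", "removed", "reason"])


def compute_empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(observed/observable) - 1."""
    if n_observable < 1:
        raise ValidationError("n_observable must be >= 1")
    if not 0 <= n_observed <= n_observable:
        raise ValidationError("need 0 <= n_observed <= n_observable")
    return 10.0 ** (n_observed / n_observable) - 1.0


def empai_from_sequence(protein_seq: str, n_observed: int,
                        len_min: int = 6, len_max: int = 35) -> float:
    """emPAI with N_observable from in-silico tryptic digestion."""
    observable = count_observable_peptides(protein_seq, len_min, len_max)
    return compute_empai(n_observed, observable)


def filter_min_peptides(table: pd.DataFrame, min_unique: int = 2) -> FilterStage:
    """Keep identifications supported by >= min_unique unique peptides."""
    if min_unique < 1:
        raise ValidationError("min_unique must be >= 1")
    keep = table["unique_peptides"] >= min_unique
    removed = table[~keep]
    reasons = {pid: f"unique_peptides < {min_unique}" for pid in removed["protein_id"]}
    return FilterStage("min_peptides", table[keep].reset_index(drop=True),
                       removed.reset_index(drop=True), reasons)


def subtract_plasma(digestive: pd.DataFrame, plasma: pd.DataFrame) -> FilterStage:
    """Remove digestive-fluid proteins that also appear in plasma."""
    plasma_ids = set(plasma["protein_id"])
    keep = ~digestive["protein_id"].isin(plasma_ids)
    removed = digestive[~keep]
    reasons = {pid: "plasma" for pid in removed["protein_id"]}
    return FilterStage("plasma", digestive[keep].reset_index(drop=True),
                       removed.reset_index(drop=True), reasons)


def derive_base_name(annotation: str, stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS) -> str:
    """Lowercased head noun phrase of a protein name.

    Tokens are accumulated until one opens a parenthesis, is numeric, starts
    with a stop token, or the previous token ended with a comma.  e.g.
    "Collagen alpha-1(I) chain" -> "collagen";
    "Keratin, type II cytoskeletal 1" -> "keratin".
    """
    head: list[str] = []
    for raw in annotation.lower().split():
        token = raw.rstrip(",")
        bare = re.split(r"[-(]", token)[0]
        if head and (bare in stop_tokens or not bare or bare[0].isdigit()
                     or token.startswith("(")):
            break
        head.append(token)
        if raw.endswith(","):
            break
    base = " ".join(head).strip()
    if not base:
        raise ValidationError(f"empty base term from {annotation!r}")
    return base


def subtract_prey_homologs(
    digestive: pd.DataFrame,
    prey: pd.DataFrame,
    stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS,
) -> FilterStage:
    """Remove python proteins whose annotation matches a prey base term."""
    base_terms = sorted({derive_base_name(a, stop_tokens) for a in prey["annotation"]})
    keep_mask, reasons = [], {}
    for row in digestive.itertuples():
        annotation = row.annotation.lower()
        hit = next((t for t in base_terms if t in annotation), None)
        keep_mask.append(hit is None)
        if hit is not None:
            reasons[row.protein_id] = f"prey homolog: {hit}"
    keep = pd.Series(keep_mask, index=digestive.index)
    return FilterStage("prey_homolog", digestive[keep].reset_index(drop=True),
                       digestive[~keep].reset_index(drop=True), reasons)


def load_keyword_map(path: str | Path | None = None) -> dict:
    """Category keyword map; the packaged default is used when path is None."""
    if path is None:
        text = resources.files("postprandial.data").joinpath(
            "secretome_keywords.yaml").read_text()
    else:
        text = Path(path).read_text()
    keyword_map = yaml.safe_load(text)
    missing = [c for c in CATEGORY_ORDER if c not in keyword_map.get("categories", {})]
    if missing:
        raise ValidationError(f"keyword map lacks categories {missing}")
    return keyword_map


def categorize_secretome(
    retained: pd.DataFrame, keyword_map: dict | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each surviving protein a secretome category.

    Not-secreted keywords are consulted first (intracellular and membrane
    proteins are excluded even when they carry e.g. protease keywords, like
    the stomach-specific calpain); the four secreted categories are then
    tried in priority order; unmatched annotations fall into 'other'.
    """
    if keyword_map is None:
        keyword_map = load_keyword_map()
    not_secreted = [k.lower() for k in keyword_map.get(NOT_SECRETED, [])]
    categories = {
        c: [k.lower() for k in keyword_map["categories"][c]] for c in CATEGORY_ORDER
    }
    assigned = []
    for row in retained.itertuples():
        annotation = row.annotation.lower()
        if any(k in annotation for k in not_secreted):
            assigned.append(NOT_SECRETED)
            continue
        for cat in CATEGORY_ORDER:
            if any(k in annotation for k in categories[cat]):
                assigned.append(cat)
                break
        else:
            assigned.append("other")
    out = retained.copy()
    out["category"] = assigned
    counts = {c: int((out["category"] == c).sum()) for c in (*CATEGORY_ORDER, NOT_SECRETED)}
    return out, counts


def correlate_expression_protein(
    empai: pd.Series, fpkm: pd.Series, log_transform: bool = False
) -> dict[str, float]:
    """OLS of emPAI on FPKM over proteins matched to genes; returns R^2."""
    joined = pd.concat([empai.rename("empai"), fpkm.rename("fpkm")], axis=1).dropna()
    if len(joined) < 3:
        raise ValidationError("need >= 3 matched protein/gene pairs")
    x, y = joined["fpkm"], joined["empai"]
    if log_transform:
        import numpy as np

        x, y = np.log10(x + 1.0), np.log10(y + 1.0)
    if float(x.std()) == 0.0:
        raise ValidationError("zero variance in FPKM")
    fit = linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue) ** 2,
        "n": len(joined),
    }


def run_secretome_chain(
    digestive: pd.DataFrame,
    plasma: pd.DataFrame,
    prey: pd.DataFrame,
    min_unique: int = 2,
    keyword_map: dict | None = None,
    stop_tokens: frozenset[str] = DEFAULT_STOP_TOKENS,
) -> tuple[FilterChainReport, pd.DataFrame, dict[str, int]]:
    """Full subtractive workflow; returns (report, categorised table, counts).

    Both evidence filtering and plasma subtraction operate on tables that
    passed the peptide-evidence filter, mirroring the published chain shape
    (all proteins -> >=2 peptides -> minus plasma -> minus prey homologs ->
    categorised secretome).
    """
    report = FilterChainReport()
    stage1 = filter_min_peptides(digestive, min_unique)
    report.stages.append(stage1)
    plasma_kept = filter_min_peptides(plasma, min_unique).retained
    prey_kept = filter_min_peptides(prey, min_unique).retained
    stage2 = subtract_plasma(stage1.retained, plasma_kept)
    report.stages.append(stage2)
    stage3 = subtract_prey_homologs(stage2.retained, prey_kept, stop_tokens)
    report.stages.append(stage3)
    categorized, counts = categorize_secretome(stage3.retained, keyword_map)
    return report, categorized, counts
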