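"""Seeded generators for every pipeline input, with planted ground truth.

All generators are pure functions of (spec, seed): the same call yields
bit-identical output.  Design conditions:

* Trend plants use FPKM level triples separated from every classification
  threshold by a margin of at least 1.5x, so that the default multiplicative
  log-normal noise (sd 0.05) cannot flip a gene's class — planted-label
  recovery is exact, not statistical.
* Counts are realised by inverting the FPKM formula at a library size of
  1e7 fragments per sample and rounding; with the default levels and
  transcript lengths (1500-3000 nt) the rounding error on FPKM is bounded
  below 1% and asserted.
* The proteome plant mirrors the shape of a subtractive gastric-secretome
  chain (549 identifications -> 314 with >= 2 peptides -> minus plasma ->
  minus prey homologs -> 37 secreted), with disjoint strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TIMEPOINTS, TISSUES, SampleSheet, ValidationError
from .trends import DEFAULT_FC_PSEUDOCOUNT, DEFAULT_THRESHOLDS, TrendClass, classify_gene

TISSUE_LETTER = {"heart": "H", "stomach": "S", "intestine": "I", "liver": "L", "pancreas": "P"}


class SpecError(ValidationError):
    """A generator spec cannot realise its planted ground truth."""


# ------------------------------------------------------------- trends


#: planted FPKM triples (fasting, 24 h, 48 h) per trend class
DEFAULT_LEVELS: dict[TrendClass, tuple[float, float, float]] = {
    TrendClass.UP: (20.0, 300.0, 360.0),
    TrendClass.UP_THEN_DOWN: (20.0, 400.0, 20.0),
    TrendClass.DOWN: (300.0, 20.0, 18.0),
    TrendClass.DOWN_THEN_UP: (400.0, 20.0, 400.0),
    TrendClass.HIGHLY_EXPRESSED: (500.0, 480.0, 520.0),
    TrendClass.MODERATELY_EXPRESSED: (80.0, 90.0, 100.0),
    TrendClass.LOWLY_EXPRESSED: (4.0, 5.0, 6.0),
}


@dataclass(frozen=True)
class TrendPlantSpec:
    genes_per_class: int = 200
    levels: dict[TrendClass, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LEVELS)
    )
    noise_sd: float = 0.05  # sd of log-normal multiplicative noise
    transcripts_per_gene: tuple[int, int] = (1, 3)
    library_size: float = 1e7
    length_range: tuple[int, int] = (1500, 3000)
    margin: float = 1.5


def _check_margins(spec: TrendPlantSpec) -> None:
    """Planted triples must keep their class when every threshold moves
    by the margin factor in either direction."""
    for cls, triple in spec.levels.items():
        for factor in (1.0, spec.margin, 1.0 / spec.margin):
            thr = {k: v * factor for k, v in DEFAULT_THRESHOLDS.items()}
            got = classify_gene(*triple, thresholds=thr).trend
            if got is not cls:
                raise SpecError(
                    f"planted level {triple} for {cls.name} classifies as "
                    f"{got.name} at threshold factor {factor:.3f}"
                )


def simulate_counts(
    spec: TrendPlantSpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, SampleSheet, pd.Series, pd.Series]:
    """Transcript count table with planted trend classes in every tissue.

    Returns (count table, sample sheet, per-sample totals, truth labels);
    truth maps gene_id -> TrendClass name, identical across tissues.
    """
    spec = spec or TrendPlantSpec()
    _check_margins(spec)
    rng = np.random.default_rng(seed)

    sheet_rows = [
        {"sample_id": f"{TISSUE_LETTER[t]}{i}", "tissue": t, "timepoint": tp}
        for t in TISSUES
        for i, tp in enumerate(TIMEPOINTS)
    ]
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    sample_ids = sheet.sample_ids

    classes = list(spec.levels)
    n_genes = spec.genes_per_class * len(classes)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    truth = pd.Series(
        [classes[i // spec.genes_per_class].name for i in range(n_genes)],
        index=pd.Index(gene_ids, name="gene_id"),
        name="trend",
    )

    lo, hi = spec.length_range
    n_tx_lo, n_tx_hi = spec.transcripts_per_gene
    rows = []
    totals = pd.Series(spec.library_size, index=sample_ids, dtype=float)
    for gi, gid in enumerate(gene_ids):
        levels = spec.levels[classes[gi // spec.genes_per_class]]
        n_tx = int(rng.integers(n_tx_lo, n_tx_hi + 1))
        lengths = rng.integers(lo, hi + 1, size=n_tx)
        gene_len = int(lengths.max())
        gene_counts = {}
        for t in TISSUES:
            for i, tp in enumerate(TIMEPOINTS):
                sid = f"{TISSUE_LETTER[t]}{i}"
                fpkm = levels[i]
                if spec.noise_sd > 0:
                    fpkm *= float(np.exp(rng.normal(0.0, spec.noise_sd)))
                count = int(round(fpkm * gene_len * spec.library_size / 1e9))
                realised = count * 1e9 / (gene_len * spec.library_size)
                if abs(realised - fpkm) > 0.01 * fpkm:
                    raise SpecError(
                        f"rounding error above 1% for {gid} ({fpkm:.3f} FPKM)"
                    )
                gene_counts[sid] = count
        # split each gene count across member transcripts
        splits = {sid: rng.multinomial(c, np.ones(n_tx) / n_tx) for sid, c in gene_counts.items()}
        for k in range(n_tx):
            row = {
                "transcript_id": f"{gid}.t{k}",
                "gene_id": gid,
                # transcript 0 carries the representative (longest) length
                "length_nt": gene_len if k == 0 else int(min(lengths[k], gene_len)),
            }
            for sid in sample_ids:
                row[sid] = int(splits[sid][k])
            rows.append(row)
    counts = pd.DataFrame(rows)
    return counts, sheet, totals, truth


# ------------------------------------------------------------ proteome


@dataclass(frozen=True)
class ProteomePlantSpec:
    n_single: int = 235  # identifications with a single unique peptide
    n_plasma: int = 50  # plasma contaminants present in the digestive fluid
    n_prey: int = 150  # prey-homolog identifications
    n_intracellular: int = 77  # surviving but not secreted
    n_secreted: tuple[int, int, int, int] = (18, 7, 4, 8)  # mucosal, proteolytic, hydrolytic, other
    n_plasma_only: int = 14  # plasma-table proteins absent from digestive fluid
    n_prey_table: int = 40  # mouse-database identifications


_SECRETED_TEMPLATES = {
    "mucosal": ["mucin-{i}-like", "gastrokine-{i}", "trefoil factor {i}"],
    "proteolytic": [
        "gastricsin-like {i}",
        "embryonic pepsinogen-like {i}",
        "pepsin A-like {i}",
    ],
    "other_hydrolytic": [
        "phospholipase A2 homolog {i}",
        "lysozyme C-{i}",
        "pancreatic lipase-like {i}",
    ],
    "other": ["gastric intrinsic factor {i}", "secreted protein {i}"],
}

_INTRACELLULAR_TEMPLATES = [
    "calpain-{i}",
    "glyceraldehyde-{i}-phosphate dehydrogenase",
    "tubulin-{i}",
    "60S ribosomal protein L{i}",
    "heat shock protein {i}",
    "proteasome subunit {i}",
]

_PREY_NAMES = [
    "Collagen alpha-1(I) chain",
    "Keratin, type II cytoskeletal {i}",
    "Actin, cytoplasmic {i}",
    "Hemoglobin subunit beta-{i}",
    "Titin isoform X{i}",
    "Desmin",
    "Vimentin",
]

#: base terms derivable from _PREY_NAMES; prey-homolog plants embed them
_PREY_BASES = ["collagen", "keratin", "actin", "hemoglobin", "titin", "desmin", "vimentin"]

_PREY_HOMOLOG_TEMPLATES = [
    "collagen alpha-{i}(I) chain-like",
    "keratin-like protein {i}",
    "actin-related protein {i}",
    "hemoglobin-like {i}",
    "titin-like {i}",
    "desmin-like protein {i}",
    "vimentin homolog {i}",
]

_PLASMA_TEMPLATES = [
    "serum albumin-like {i}",
    "apolipoprotein A-{i}",
    "transferrin-like {i}",
    "fibrinogen homolog {i}",
    "anti-haemorrhagic factor {i}",
]

_SINGLE_TEMPLATES = ["uncharacterized protein {i}", "hypothetical protein {i}"]


def _fill(templates: list[str], n: int, start: int = 1) -> list[str]:
    return [templates[i % len(templates)].format(i=start + i) for i in range(n)]


def simulate_protein_tables(
    spec: ProteomePlantSpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Digestive, plasma and prey identification tables with planted strata.

    Returns (digestive, plasma, prey, truth); truth maps each digestive
    protein_id to its stratum (single / plasma / prey_homolog /
    intracellular / mucosal / proteolytic / other_hydrolytic / other).
    """
    spec = spec or ProteomePlantSpec()
    rng = np.random.default_rng(seed)

    strata: list[tuple[str, str]] = []  # (stratum, annotation)
    strata += [("single", a) for a in _fill(_SINGLE_TEMPLATES, spec.n_single)]
    strata += [("plasma", a) for a in _fill(_PLASMA_TEMPLATES, spec.n_plasma)]
    strata += [("prey_homolog", a) for a in _fill(_PREY_HOMOLOG_TEMPLATES, spec.n_prey)]
    strata += [("intracellular", a) for a in _fill(_INTRACELLULAR_TEMPLATES, spec.n_intracellular)]
    for cat, n_cat in zip(_SECRETED_TEMPLATES, spec.n_secreted):
        strata += [(cat, a) for a in _fill(_SECRETED_TEMPLATES[cat], n_cat)]

    for stratum, annotation in strata:
        if stratum not in ("single", "prey_homolog", "plasma"):
            clash = [b for b in _PREY_BASES if b in annotation.lower()]
            if clash:
                raise SpecError(f"{stratum} annotation {annotation!r} matches prey base {clash}")

    rows = []
    truth_rows = []
    for i, (stratum, annotation) in enumerate(strata):
        pid = f"m.{i:04d}_Py95"
        peptides = 1 if stratum == "single" else int(rng.integers(2, 31))
        empai = float(np.round(rng.lognormal(mean=0.0, sigma=1.0), 6))
        rows.append(
            {"protein_id": pid, "annotation": annotation,
             "unique_peptides": peptides, "empai": empai}
        )
        truth_rows.append({"protein_id": pid, "stratum": stratum})
    cols = ["protein_id", "annotation", "unique_peptides", "empai"]
    digestive = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "stratum"])

    plasma_ids = list(truth.loc[truth["stratum"] == "plasma", "protein_id"])
    plasma_rows = [
        dict(digestive[digestive["protein_id"] == pid].iloc[0]) for pid in plasma_ids
    ]
    for j in range(spec.n_plasma_only):
        plasma_rows.append(
            {
                "protein_id": f"pl.{j:04d}_Py95",
                "annotation": _PLASMA_TEMPLATES[j % len(_PLASMA_TEMPLATES)].format(i=1000 + j),
                "unique_peptides": int(rng.integers(2, 31)),
                "empai": float(np.round(rng.lognormal(0.0, 1.0), 6)),
            }
        )
    plasma = pd.DataFrame(plasma_rows, columns=cols).reset_index(drop=True)

    prey_rows = [
        {
            "protein_id": f"sp|M{j:04d}|MOUSE",
            "annotation": _PREY_NAMES[j % len(_PREY_NAMES)].format(i=1 + j),
            "unique_peptides": int(rng.integers(2, 31)),
            "empai": float(np.round(rng.lognormal(0.0, 1.0), 6)),
        }
        for j in range(spec.n_prey_table)
    ]
    prey = pd.DataFrame(prey_rows, columns=cols)
    return digestive, plasma, prey, truth


def expected_chain_counts(spec: ProteomePlantSpec | None = None) -> dict[str, int]:
    """Closed-form per-stage retained counts implied by a proteome plant."""
    spec = spec or ProteomePlantSpec()
    total = (
        spec.n_single + spec.n_plasma + spec.n_prey + spec.n_intracellular
        + sum(spec.n_secreted)
    )
    after_peptides = total - spec.n_single
    after_plasma = after_peptides - spec.n_plasma
    after_prey = after_plasma - spec.n_prey
    return {
        "total": total,
        "min_peptides": after_peptides,
        "plasma": after_plasma,
        "prey_homolog": after_prey,
        "secretome": sum(spec.n_secreted),
        "mucosal": spec.n_secreted[0],
        "proteolytic": spec.n_secreted[1],
        "other_hydrolytic": spec.n_secreted[2],
        "other": spec.n_secreted[3],
        "not_secreted": spec.n_intracellular,
    }


# ---------------------------------------------------------- annotations


def simulate_annotations(
    n_genes: int = 2000,
    n_terms: int = 20,
    planted_k: int = 50,
    n_test: int = 100,
    multiplier: float = 10.0,
    term_size_range: tuple[int, int] = (20, 200),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str], str]:
    """Gene->GO annotation with one planted over-represented term.

    The planted term annotates ``planted_k`` genes; the test set of size
    ``n_test`` is drawn without replacement with sampling odds ``multiplier``
    for planted-term genes (multiplier 1 is the exchangeable null).  Returns
    (annotation table, ontology edges, test set, planted term id).
    """
    if multiplier < 1:
        raise ValidationError("multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    planted = terms[0]

    gene_terms: dict[str, set[str]] = {g: set() for g in genes}
    planted_genes = rng.choice(n_genes, size=planted_k, replace=False)
    for gi in planted_genes:
        gene_terms[genes[gi]].add(planted)
    for t in terms[1:]:
        k_t = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        for gi in rng.choice(n_genes, size=k_t, replace=False):
            gene_terms[genes[gi]].add(t)

    weights = np.ones(n_genes)
    weights[planted_genes] = multiplier
    test_idx = rng.choice(n_genes, size=n_test, replace=False, p=weights / weights.sum())
    test_set = {genes[i] for i in test_idx}

    annotation = pd.DataFrame(
        {
            "gene_id": genes,
            "go_terms": [frozenset(gene_terms[g]) for g in genes],
            "description": "",
        }
    )
    edge_rows = [
        {"child": terms[i], "parent": terms[int(rng.integers(0, i))]}
        for i in range(1, n_terms)
    ]
    edges = pd.DataFrame(edge_rows, columns=["child", "parent"])
    return annotation, edges, test_set, planted


# ----------------------------------------------------------- sequences


def simulate_sequences(
    n: int = 6,
    length: int = 900,
    substitution_rate: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Aligned nucleotide set: one ancestor plus n-1 mutated derivatives.

    Each derived sequence mutates every ancestral site independently with
    probability ``substitution_rate`` to a uniformly chosen different base.
    Returns (sequences, truth) where truth lists the realised proportion of
    differing sites for every unordered pair.
    """
    if not 0 <= substitution_rate <= 0.7:
        raise ValidationError("substitution rate must lie in [0, 0.7]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ancestor = bases[rng.integers(0, 4, size=length)]
    seqs = {"seq0": "".join(ancestor)}
    for i in range(1, n):
        derived = ancestor.copy()
        mutate = rng.random(length) < substitution_rate
        for pos in np.flatnonzero(mutate):
            choices = [b for b in "ACGT" if b != derived[pos]]
            derived[pos] = choices[int(rng.integers(0, 3))]
        seqs[f"seq{i}"] = "".join(derived)
    names = list(seqs)
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            s1, s2 = seqs[names[a]], seqs[names[b]]
            p = sum(x != y for x, y in zip(s1, s2)) / length
            rows.append({"seq_a": names[a], "seq_b": names[b], "p": p})
    return seqs, pd.DataFrame(rows)
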