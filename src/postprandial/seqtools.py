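"""Sequence-level utilities: paired-read QC, tryptic digestion, Tajima-Nei.

Read filtering applies, in a fixed order per pair: adapter removal (exact
substring in either mate drops the pair), ambiguous-base removal (any ``N``
drops the pair), sliding-window quality trimming (scan 5'->3'; at the first
full window of length ``window`` whose mean Phred quality is below ``q_min``
the mate is truncated at that window's start), and a minimum-length gate on
the trimmed mates.

Tryptic digestion cleaves after K or R except when the next residue is P.
``missed_cleavages`` adds all concatenations of up to that many adjacent
fragments.

The Tajima-Nei distance corrects the proportion of differing sites p for
unequal base composition:

    h = sum_{i<j} x_ij^2 / (2 g_i g_j)
    b = (1 - sum_i g_i^2 + p^2 / h) / 2
    d = -b ln(1 - p / b)

with g_i the base frequencies averaged over the two sequences and x_ij the
relative frequency of sites showing the unordered differing pair (i, j),
all computed over comparable sites only (pairwise deletion of gaps and
ambiguity codes).  Identical sequences give d = 0 without evaluating h.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import FormatError, ValidationError

NUCLEOTIDES = "ACGT"


# ---------------------------------------------------------------- read QC


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FormatError(f"{self.read_id}: base/quality length mismatch")


def sliding_window_trim(
    seq: str, qual: tuple[int, ...], window: int = 10, q_min: int = 20
) -> tuple[str, tuple[int, ...]]:
    """Truncate at the start of the first full window with mean quality < q_min."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    for start in range(len(seq) - window + 1):
        if sum(qual[start : start + window]) / window < q_min:
            return seq[:start], qual[:start]
    return seq, qual


def quality_filter_reads(
    pairs,
    adapter: str = "",
    window: int = 10,
    q_min: int = 20,
    min_len: int = 30,
):
    """Apply adapter -> N -> trim -> length filtering to a stream of pairs.

    Returns (retained pairs, stats dict).
    """
    retained = []
    stats = {"input": 0, "adapter": 0, "ambiguous": 0, "short": 0, "retained": 0}
    for pair in pairs:
        stats["input"] += 1
        if adapter and (adapter in pair.seq1 or adapter in pair.seq2):
            stats["adapter"] += 1
            continue
        if "N" in pair.seq1 or "N" in pair.seq2:
            stats["ambiguous"] += 1
            continue
        s1, t1 = sliding_window_trim(pair.seq1, pair.qual1, window, q_min)
        s2, t2 = sliding_window_trim(pair.seq2, pair.qual2, window, q_min)
        if len(s1) < min_len or len(s2) < min_len:
            stats["short"] += 1
            continue
        retained.append(ReadPair(pair.read_id, s1, t1, s2, t2))
        stats["retained"] += 1
    return retained, stats


def read_fastq_pairs(path1: str | Path, path2: str | Path):
    """Yield ReadPair records from two mate FASTQ files (Phred+33)."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for rec1, rec2 in itertools.zip_longest(it1, it2):
        if rec1 is None or rec2 is None:
            raise FormatError("mate files have different read counts")
        yield ReadPair(
            rec1.id,
            str(rec1.seq),
            tuple(rec1.letter_annotations["phred_quality"]),
            str(rec2.seq),
            tuple(rec2.letter_annotations["phred_quality"]),
        )


def write_fastq_pairs(pairs, path1: str | Path, path2: str | Path) -> None:
    recs1, recs2 = [], []
    for p in pairs:
        r1 = SeqRecord(Seq(p.seq1), id=p.read_id, description="")
        r1.letter_annotations["phred_quality"] = list(p.qual1)
        r2 = SeqRecord(Seq(p.seq2), id=p.read_id, description="")
        r2.letter_annotations["phred_quality"] = list(p.qual2)
        recs1.append(r1)
        recs2.append(r2)
    SeqIO.write(recs1, str(path1), "fastq")
    SeqIO.write(recs2, str(path2), "fastq")


# ------------------------------------------------------------- digestion


def tryptic_digest(protein: str, missed_cleavages: int = 0) -> list[str]:
    """Peptides from cleavage after K/R not followed by P, in sequence order.

    With ``missed_cleavages`` = m, all concatenations of up to m+1 adjacent
    zero-missed fragments are appended after the zero-missed set.
    """
    protein = protein.strip().upper()
    if not protein:
        return []
    fragments = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR" and (i + 1 == len(protein) or protein[i + 1] != "P"):
            fragments.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        fragments.append(protein[start:])
    peptides = list(fragments)
    for span in range(2, missed_cleavages + 2):
        for i in range(len(fragments) - span + 1):
            peptides.append("".join(fragments[i : i + span]))
    return peptides


def count_observable_peptides(protein: str, len_min: int = 6, len_max: int = 35) -> int:
    """Distinct zero-missed tryptic peptides within the length bounds."""
    peps = {p for p in tryptic_digest(protein, 0) if len_min <= len(p) <= len_max}
    return len(peps)


# ------------------------------------------------------------ distances


@dataclass(frozen=True)
class TajimaNeiComponents:
    n_comparable: int
    p: float
    g: dict[str, float]
    x: dict[tuple[str, str], float]
    h: float
    b: float
    d: float


class DistanceUndefinedError(ValueError):
    """The corrected distance saturates (p/b >= 1)."""


def tajima_nei_distance(seq1: str, seq2: str) -> TajimaNeiComponents:
    """Tajima-Nei distance with pairwise deletion of non-ACGT sites."""
    if len(seq1) != len(seq2):
        raise ValidationError("aligned sequences must have equal length")
    s1, s2 = seq1.upper(), seq2.upper()
    sites = [
        (a, b)
        for a, b in zip(s1, s2)
        if a in NUCLEOTIDES and b in NUCLEOTIDES
    ]
    m = len(sites)
    if m == 0:
        raise ValidationError("no comparable sites")
    diffs = [(a, b) for a, b in sites if a != b]
    p = len(diffs) / m
    counts = {nt: 0 for nt in NUCLEOTIDES}
    for a, b in sites:
        counts[a] += 1
        counts[b] += 1
    g = {nt: counts[nt] / (2 * m) for nt in NUCLEOTIDES}
    pairs = [(i, j) for i, j in itertools.combinations(NUCLEOTIDES, 2)]
    x = {pair: 0.0 for pair in pairs}
    for a, b in diffs:
        key = (a, b) if (a, b) in x else (b, a)
        x[key] += 1.0 / m
    if p == 0.0:
        return TajimaNeiComponents(m, 0.0, g, x, math.nan, math.nan, 0.0)
    h = sum(
        x[(i, j)] ** 2 / (2 * g[i] * g[j]) for i, j in pairs if x[(i, j)] > 0
    )
    b = 0.5 * (1.0 - sum(v**2 for v in g.values()) + p**2 / h)
    if p / b >= 1.0:
        raise DistanceUndefinedError(
            f"saturated: p={p:.4f} >= b={b:.4f}; distance undefined"
        )
    d = -b * math.log(1.0 - p / b)
    return TajimaNeiComponents(m, p, g, x, h, b, d)


def mean_pairwise_distance(seqs: dict[str, str]) -> float:
    """Arithmetic mean Tajima-Nei distance over all unordered pairs."""
    names = list(seqs)
    if len(names) < 2:
        raise ValidationError("need >= 2 sequences")
    dists = []
    undefined = []
    for a, b in itertools.combinations(names, 2):
        try:
            dists.append(tajima_nei_distance(seqs[a], seqs[b]).d)
        except DistanceUndefinedError:
            undefined.append((a, b))
    if undefined:
        raise DistanceUndefinedError(f"undefined pair(s): {undefined}")
    return sum(dists) / len(dists)


def expand_protein_alignment(
    aligned_proteins: dict[str, str], cds: dict[str, str]
) -> dict[str, str]:
    """Back-translate a protein alignment to a codon-aware nucleotide one.

    Each residue column becomes the corresponding codon triplet from the
    unaligned coding sequence; gap columns become ``---``.  This supports
    running a nucleotide distance model on sequences aligned at the amino
    acid level.
    """
    out = {}
    for name, prot in aligned_proteins.items():
        nt = cds[name].upper().replace("-", "")
        needed = 3 * sum(1 for r in prot if r != "-")
        if len(nt) < needed:
            raise ValidationError(f"{name}: coding sequence shorter than alignment")
        chunks, pos = [], 0
        for residue in prot:
            if residue == "-":
                chunks.append("---")
            else:
                chunks.append(nt[pos : pos + 3])
                pos += 3
        out[name] = "".join(chunks)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
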