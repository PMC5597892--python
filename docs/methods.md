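# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions chosen where the design was open.

## Study design and data model

The pipeline assumes the design of a pooled-library digestive time course:
five visceral organs (heart, liver, stomach, pancreas, intestine) sampled at
three time points (fasting, 24 h, 48 h after feeding), one sample per
(organ, time point) cell, fifteen samples in all. Because biological
replicates are pooled before sequencing there is no dispersion to estimate,
and differential expression is defined by fold-change and expression
thresholds rather than by a count model. Time points are ordered by the
enum `fasting < 24h < 48h`, never by file column order, because trend
classification depends on that order.

Counts are consumed at transcript level (quantifier output is out of scope)
and collapsed to genes: the gene count is the sum of its transcripts' counts
and the gene length is the longest member transcript's length, in
nucleotides. FPKM is `C·1e9/(L·N)`; no effective-length or isoform-level
EM correction is attempted. Per-sample totals `N_s` default to the column
sums of the gene-level table, which makes the conservation identity
`Σ_g FPKM·L/1e9 = 1` hold exactly per sample; an explicit totals table
overrides the default for data where the aligner's totals differ from the
table's column sums (the synthetic generator always emits its totals for
this reason, since planted FPKM levels are only recoverable with the library
sizes used to invert them).

## Trend classification

Parameters (all configurable):

| parameter  | default | meaning                                         |
|------------|---------|-------------------------------------------------|
| `expr_min` | 10 FPKM | expression gate; at or below → lowly expressed  |
| `fc_min`   | 4       | DEG gate on pairwise fold change (strict `>`)   |
| `high_min` | 200 FPKM| highly vs moderately expressed (strict `>`)     |
| `ε_fc`     | 0.1 FPKM| fold-change pseudocount                         |

The three gates are evaluated strictly (`> 10`, `> 4`, `> 200`), matching
the "over" wording of the classification scheme, whereas the separate strict
DEG selector for heat maps uses inclusive thresholds (FPKM ≥ 400, FC ≥ 2),
matching its "greater than or equal to" wording. The fold-change
pseudocount makes FC well defined at zero FPKM; at 0.1 it is small relative
to the `expr_min` gate, so it cannot conjure DEGs among expressed genes.

The directional trend of a DEG is not fully specified by the published
scheme, which gives worked definitions rather than an algorithm. The
implemented decision rule: examine the consecutive transitions
(f₀→f₁, f₁→f₂); if both exceed `fc_min` with signs (+,−) the gene is
up-then-down, with (−,+) down-then-up; otherwise the trend is the direction
of the largest-magnitude significant pairwise comparison, ties broken in the
order (f₀,f₁), (f₀,f₂), (f₁,f₂). The rule is deterministic and reproduces
the worked definitions. Records that reach the fallback with conflicting
directions carry an `ambiguous` flag; in practice the geometry of the three
pairwise ratios makes such conflicts route through the consecutive rule, so
the flag marks a convention corner rather than a common case.

One structural property worth noting: reversing the time axis swaps up- and
downregulated, but the biphasic classes are *fixed points* of the reversal —
a trajectory that rises then falls reads as rise-then-fall in either
direction (e.g. the triple (0, 11, 0) is its own reversal). The property
tests assert exactly this.

## Multivariate views

PCA treats samples as observations and genes as variables, centres columns
and does not scale them (the convention of R's `prcomp`); `scale=True` is
available. Variance proportions are `σ_k²/Σσ²` from the SVD of the centred
matrix. Clustering uses Spearman-correlation distance `d = 1 − ρ_s` with
average ranks for ties, and unweighted average linkage; merge ties are
broken by smallest index pair for determinism. `1 − |ρ|` is a documented
alternative reading of "Spearman correlation distance" but `1 − ρ` is the
default because co-expression sign matters for trend heat maps. Heat-map
export applies `log2(FPKM + 1)` and median-centres each gene row; the
pseudocount of 1 handles zero FPKM and is configurable.

## Enrichment

The over-representation p-value for a term with `K` of `N` reference genes
and `k` of `n` test genes is the hypergeometric tail
`p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)`, evaluated through scipy; an
exhaustive-enumeration oracle in the test suite verifies agreement to 1e−12
over every table with N ≤ 60. The test set remains inside the reference
(the reference is the whole annotated universe); `exclusive=True` forms the
test-vs-rest 2×2 table instead. FDR control is Benjamini–Hochberg step-up
(via statsmodels, verified against a hand-rolled oracle). Terms with k = 0
are skipped: their one-sided p is 1 by construction. Significant terms are
reduced to the most specific ones by ancestor removal: a term is flagged
most-specific iff no other significant term is its descendant under the
transitive closure of the child→parent edge set (is_a/part_of edges only;
full OBO relationship types are out of scope). Pathway-map colour files are
two-column text (entry label, background hex) per pathway, using the fixed
class-colour map.

## Secretome

The subtractive chain is an ordered, audited filter sequence; every stage
records removed ids and reasons and satisfies
`|retained_i| + |removed_i| = |retained_{i−1}|`, and subtraction stages are
idempotent. "Unique peptides" means distinct peptide sequences assigned to
the protein; modified forms count once.

Prey-homolog subtraction derives a base search term from each prey protein
name: lowercase, accumulate head tokens, stop at a token that is a stop word
(alpha, beta, gamma, type, chain, isoform, precursor, subunit), is numeric,
opens a parenthesis, or follows a comma. "Collagen alpha-1(I) chain" yields
"collagen"; "Keratin, type II cytoskeletal 1" yields "keratin". Python
proteins whose annotation contains any base term (case-insensitive
substring) are removed, with the matching term recorded.

Categorisation ships as data, not code: a versioned YAML keyword map with
four secreted categories (mucosal > proteolytic > other hydrolytic > other,
first match in priority order) and a not-secreted list consulted first —
so an intracellular protease such as the stomach-specific calpain is
excluded even though it carries a protease-like name. The map encodes a
manual-reassessment convention and is meant to be edited per study.

emPAI is `10^(N_obs/N_obsbl) − 1`. `N_obsbl` is approximated as the number
of distinct fully tryptic peptides (0 missed cleavages) of length 6–35
residues from in-silico digestion; search engines compute this internally
from mass windows, so the digestion-based count is a documented proxy with
configurable bounds. The mRNA–protein relation is an ordinary least-squares
fit of emPAI on FPKM (R² = 1 − SS_res/SS_tot), on raw values by default
with a log₁₀ option.

## Sequence tools

Read filtering applies, in fixed order: adapter (exact substring anywhere in
either mate drops the pair; adapter-location algorithms are out of scope),
ambiguity (any N drops the pair), sliding-window trimming, minimum length.
Trimming scans full windows of length 10 from the 5′ end and truncates at
the start of the first window whose mean Phred quality is below 20 —
the trim-from-first-failing-window reading of "trimming bases with low
average quality within a sliding window"; windows shorter than 10 at the 3′
end are not evaluated. Trimming never lengthens a read.

Tryptic digestion cleaves after K or R except before P; the zero-missed
fragments concatenate to the input (a tested invariant), and missed
cleavages add concatenations of adjacent fragments. The digest agrees with
an independent engine (pyteomics) applying the same rule.

The Tajima–Nei distance uses pairwise deletion: only columns where both
sequences have an unambiguous A/C/G/T are compared. With `p` the differing
proportion, `g_i` base frequencies averaged over the pair and `x_ij` the
relative frequencies of the six unordered differing pair types,

    h = Σ_{i<j} x_ij²/(2 g_i g_j),  b = ½(1 − Σ g_i² + p²/h),
    d = −b ln(1 − p/b).

Identical sequences short-circuit to d = 0 (h is indeterminate at p = 0).
`p/b ≥ 1` raises a saturation error rather than returning a value. Under
equal base frequencies and uniform pair types b = ¾ and d reduces to the
Jukes–Cantor form −¾ ln(1 − 4p/3), verified to 1e−9. For gastricsin-family
comparisons aligned at the amino-acid level, `expand_protein_alignment`
back-translates each residue column to its codon triplet so a nucleotide
model can be applied to a protein alignment — the only self-consistent
reading of running a nucleotide distance on amino-acid-aligned transcripts.

## Synthetic data

The generators are pure functions of (spec, seed) and define the conditions
under which the pipeline is validated:

* **Trend plant** — seven FPKM level triples, one per class, each separated
  from every threshold by a ≥ 1.5× margin, with multiplicative log-normal
  noise (sd 0.05) whose 3σ envelope stays inside the margin; recovery of
  planted labels is therefore exact, not statistical. Counts are realised by
  inverting the FPKM formula at a library size of 10⁷ fragments per sample
  with transcript lengths of 1500–3000 nt and rounding; the induced FPKM
  error is bounded below 1% and asserted at generation time. Default scale:
  200 genes per class across all 15 samples.
* **Proteome plant** — disjoint strata (235 single-peptide artefacts, 50
  plasma contaminants, 150 prey homologs, 77 intracellular survivors,
  18/7/4/8 secreted) whose arithmetic fixes every stage count of the chain
  (549 → 314 → 264 → 114 → 37); annotations are drawn from vocabularies
  constructed not to cross-match between strata, which the generator checks.
* **Annotation plant** — 2000 genes, 20 terms; one planted term on 50 genes
  and a test set of 100 drawn without replacement with 10× odds for planted
  genes (1× is the exchangeable null); other terms annotate 20–200 random
  genes each; edges form a random tree over terms.
* **Sequence plant** — an ancestor and independently mutated derivatives at
  a per-site substitution rate, each mutation to a uniformly chosen other
  base, so the expected differing proportion against the ancestor equals the
  rate and the mean distance tracks the Jukes–Cantor closed form.

What the generators do *not* emulate: biological replicate dispersion (the
design pools replicates, so there is none to model), isoform-level count
ambiguity, annotation transfer noise, shared-peptide protein inference, and
real search-engine score distributions. Passing the planted-truth tests
therefore demonstrates correctness of the computational procedures under the
stated design, not robustness to those sources of real-data noise.

## Validation scale and known limitations

The end-to-end checks run at these sizes: 1400 genes for trend recovery,
100 random matrices for the partition identity, every 2×2 table with N ≤ 60
for the Fisher oracle plus 1000 random vectors for the BH oracle, 2000 null
and 200 enriched draws for calibration and power, 100 random matrices with
n ≤ 8 for the UPGMA oracle, 50 matrices for the PCA oracle, 1000 random
proteins for digestion, and 10 000 random reads for trimming properties.

Known limitations: headline organ-level counts from any real study depend
on the deposited reads, the assembly and database versions, and are not
reproducible from synthetic data — the package validates procedures, not
those numbers. The base-name and keyword rules are deterministic stand-ins
for manual curation; the emPAI observable-peptide count is a proxy; average
linkage heights are compared to the brute-force oracle at 1e−10 relative
tolerance because the Lance–Williams recursion differs from the direct
cross-pair mean only in floating-point summation order.
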