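"""GO over-representation analysis and pathway-map colour export.

The test is the one-sided Fisher's exact / hypergeometric tail: for a term
annotated on K of N reference genes and k of n test-set genes,

    p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n).

The test set stays inside the reference when forming the 2x2 table (the
reference is the whole annotated universe); ``exclusive=True`` switches to a
test-vs-rest table.  Multiple testing is controlled with Benjamini-Hochberg
step-up adjusted values, and significant terms are reduced to the most
specific ones: a term is flagged most-specific iff no other significant term
is its descendant in the ontology graph.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .trends import GeneTrendRecord, assign_color


def fisher_enrichment(
    test_set: set[str],
    annotation: pd.DataFrame,
    exclusive: bool = False,
) -> pd.DataFrame:
    """One-sided over-representation p and BH q per term with k >= 1.

    ``annotation`` is the reference universe: columns gene_id, go_terms (a
    set per gene).  Terms never seen in the test set are skipped (their
    over-representation p is 1 by construction).
    """
    if len(test_set) == 0:
        raise ValidationError("empty test set")
    universe = set(annotation["gene_id"])
    stray = test_set - universe
    if stray:
        raise ValidationError(f"test genes outside reference: {sorted(stray)[:5]}")

    term_ref: dict[str, int] = {}
    term_test: dict[str, int] = {}
    for gid, terms in zip(annotation["gene_id"], annotation["go_terms"]):
        in_test = gid in test_set
        for t in terms:
            term_ref[t] = term_ref.get(t, 0) + 1
            if in_test:
                term_test[t] = term_test.get(t, 0) + 1

    n = len(test_set)
    N = len(universe)
    rows = []
    for term, k in sorted(term_test.items()):
        K = term_ref[term]
        if exclusive:
            # test vs rest: 2x2 with the test set removed from the reference
            table = [[k, n - k], [K - k, (N - n) - (K - k)]]
            p = float(fisher_exact(table, alternative="greater").pvalue)
        else:
            p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_fdr(result["p"].tolist())
        result = result.sort_values(["p", "term"]).reset_index(drop=True)
    return result


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values."""
    if any(p < 0 or p > 1 for p in pvalues):
        raise ValidationError("p-values must lie in [0, 1]")
    if not pvalues:
        return []
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return list(q)


def reduce_to_most_specific(
    significant: set[str], edges: pd.DataFrame
) -> dict[str, bool]:
    """Flag each significant term as most-specific or not.

    ``edges`` holds child -> parent rows.  A term is most specific iff no
    other significant term lies below it (transitive closure); orphan terms
    are trivially most specific.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges[["child", "parent"]].itertuples(index=False, name=None))
    flags = {}
    for term in significant:
        if term in g:
            # nodes reachable upward from any other significant term include this one?
            has_significant_descendant = any(
                other != term and other in g and nx.has_path(g, other, term)
                for other in significant
            )
        else:
            has_significant_descendant = False
        flags[term] = not has_significant_descendant
    return flags


def kegg_color_export(
    records: list[GeneTrendRecord],
    membership: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """One two-column colour file per pathway: entry label, background hex.

    Genes absent from the membership table are omitted; a gene in several
    pathways appears in each of them.
    """
    out_dir = Path(out_dir)
    by_gene = {r.gene_id: r.trend for r in records}
    files: dict[str, Path] = {}
    for pathway_id, sub in membership.groupby("pathway_id"):
        lines = []
        for row in sub.itertuples():
            trend = by_gene.get(row.gene_id)
            if trend is None:
                continue
            _, hexcode = assign_color(trend)
            lines.append(f"{row.entry_label}\t{hexcode}")
        if not lines:
            continue
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{pathway_id}.txt"
        path.write_text("\n".join(lines) + "\n")
        files[str(pathway_id)] = path
    return files
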