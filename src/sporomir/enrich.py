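"""Hypergeometric term enrichment of DEM target genes, with BH adjustment
and network export.

For a term annotated to K of N background genes, of which k fall in the
selected set of size n, the enrichment p-value is the exact upper tail
P(X >= k) of the hypergeometric distribution.  Adjustment is
Benjamini-Hochberg within each namespace (BP/CC/MF/pathway).  Terms are
linked into a term-term network by shared member genes, and miRNAs into a
miRNA-term network through the genes they target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class Annotation:
    """gene -> terms mapping plus term metadata."""

    table: pd.DataFrame          # columns: gene, term, namespace, name

    def __post_init__(self):
        required = {"gene", "term", "namespace", "name"}
        if not required <= set(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Annotation":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def background(self) -> set[str]:
        return set(self.table.gene)

    def genes_of(self, term: str) -> set[str]:
        return set(self.table.loc[self.table.term == term, "gene"])


def hypergeom_enrich(selected: set[str] | list[str], annotation: Annotation,
                     background: set[str] | None = None) -> pd.DataFrame:
    """Exact hypergeometric enrichment of every term with >= 1 selected
    gene; BH adjustment per namespace; sorted by adjusted p.

    Raises when the selected set is not contained in the background.
    """
    selected = set(selected)
    background = set(background) if background is not None \
        else annotation.background
    stray = selected - background
    if stray:
        raise ValueError("selected genes outside the background: "
                         + ", ".join(sorted(stray)))
    N = len(background)
    n = len(selected)
    rows = []
    meta = annotation.table.drop_duplicates("term").set_index("term")
    for term, grp in annotation.table.groupby("term"):
        term_genes = set(grp.gene) & background
        K = len(term_genes)
        members = sorted(term_genes & selected)
        k = len(members)
        if k < 1:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term=term, namespace=meta.loc[term, "namespace"],
                         name=meta.loc[term, "name"], k=k, K=K, n=n, N=N,
                         p_value=min(p, 1.0), members=";".join(members)))
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adjust"] = []
        return out
    out["p_adjust"] = 1.0
    for ns, idx in out.groupby("namespace").groups.items():
        out.loc[idx, "p_adjust"] = multipletests(
            out.loc[idx, "p_value"], method="fdr_bh")[1]
    return (out.sort_values(["p_adjust", "p_value", "term"])
            .reset_index(drop=True))


def build_networks(records: pd.DataFrame, target_table: pd.DataFrame,
                   dem_direction: dict[str, str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(term-term edges, miRNA-term edges) from enrichment records.

    Terms are linked when they share member genes (weight = shared count);
    a miRNA is linked to a term when it targets at least one member gene.
    Node attributes (p_adjust, DEM direction) ride along as columns.
    """
    if records.empty:
        raise ValueError("no enrichment records to build networks from")
    members = {r.term: set(r.members.split(";")) for r in records.itertuples()}
    padj = dict(zip(records.term, records.p_adjust))
    tt_rows = []
    terms = list(members)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            shared = members[t1] & members[t2]
            if shared:
                tt_rows.append(dict(term1=t1, term2=t2, weight=len(shared),
                                    p_adjust1=padj[t1], p_adjust2=padj[t2],
                                    shared=";".join(sorted(shared))))
    mt_rows = []
    if len(target_table):
        by_mirna = target_table.groupby("mirna_id")["gene_id"].agg(set)
        for mirna, genes in by_mirna.items():
            for term, mem in members.items():
                hit = genes & mem
                if hit:
                    mt_rows.append(dict(
                        mirna_id=mirna, term=term, n_genes=len(hit),
                        p_adjust=padj[term],
                        direction=(dem_direction or {}).get(mirna, ""),
                        genes=";".join(sorted(hit))))
    return pd.DataFrame(tt_rows), pd.DataFrame(mt_rows)


def to_graph(term_term: pd.DataFrame) -> nx.Graph:
    """Term-term edge list as a networkx graph (for export/inspection)."""
    g = nx.Graph()
    for r in term_term.itertuples():
        g.add_edge(r.term1, r.term2, weight=r.weight)
    return g
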