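"""Pathway-level summaries of posterior-based gene rankings.

Per-gene state-posterior scores are summed within tumor groups (for gliomas:
oligodendrogliomas, astrocytomas, glioblastomas) to rank candidate genes of
under- or overexpression per group.  The top-k genes of each group are then
intersected with pathway gene sets (GMT format), and overlaps are compared
to the chance expectation ``k * m / G`` for a pathway with ``m`` genes in a
universe of ``G`` scored genes (the hypergeometric mean).

A curated reference table of genes called overexpressed in the most
discriminative cancer signaling pathways across glioma types ships with the
package (``data/glioma_pathway_calls.tsv``) for membership summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class PathwayCollection:
    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    @property
    def n_universe(self) -> int:
        return len(self.universe)


def read_gmt(path, universe=None) -> PathwayCollection:
    """Read GMT gene sets (name, description, genes...); ids uppercased."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"GMT line {lineno}: no genes")
            sets[fields[0]] = genes
    if not sets:
        raise ValueError("empty GMT file")
    if universe is None:
        uni = frozenset().union(*sets.values())
    else:
        uni = frozenset(g.upper() for g in universe)
    return PathwayCollection(sets=sets, universe=uni)


def aggregate_scores(gene_scores: pd.DataFrame, groups: dict[str, str], state_column: str = "score") -> pd.DataFrame:
    """Sum per-gene posterior scores over the samples of each group.

    ``gene_scores`` needs columns ``gene``, ``sample`` and the score column;
    ``groups`` maps every sample id to exactly one group.  Genes missing in
    a sample contribute 0.  Returns genes x groups.
    """
    samples = set(gene_scores["sample"])
    unassigned = samples - set(groups)
    if unassigned:
        raise ValueError(f"samples without group assignment: {sorted(unassigned)}")
    df = gene_scores.assign(group=gene_scores["sample"].map(groups))
    counts = df.groupby("group")["sample"].nunique()
    for g in set(groups.values()):
        if counts.get(g, 0) == 0:
            raise ValueError(f"group '{g}' contains no samples")
    table = df.pivot_table(index="gene", columns="group", values=state_column, aggfunc="sum", fill_value=0.0)
    table.columns.name = None
    return table


def top_k_genes(scores: pd.Series, k: int) -> list[str]:
    """The k highest-scoring genes; score ties broken by gene id."""
    if k > len(scores):
        raise ValueError("k exceeds the number of scored genes")
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order[:k]]


def top_k_overlap(scores: pd.Series, pathways: PathwayCollection, k: int, universe=None) -> pd.DataFrame:
    """Overlap of the top-k genes with each pathway, plus the chance expectation.

    The universe defaults to the scored genes; the expectation for a pathway
    with ``m`` universe genes is ``k * m / G``.
    """
    uni = frozenset(g.upper() for g in (universe if universe is not None else scores.index))
    top = set(g.upper() for g in top_k_genes(scores, k))
    rows = []
    for name, genes in pathways.sets.items():
        members = genes & uni
        if not members:
            warnings.warn(f"pathway '{name}' is disjoint from the universe", stacklevel=2)
        rows.append((name, len(members), len(top & genes), k * len(members) / len(uni)))
    return pd.DataFrame(rows, columns=["pathway", "size_in_universe", "overlap", "expected"])


def load_glioma_calls() -> pd.DataFrame:
    """Bundled table of overexpressed genes in discriminative glioma pathways.

    Columns: ``gene``; binary overexpression calls for oligodendroglioma
    (``OD``), astrocytoma (``AS``) and glioblastoma (``GBM``); and the
    semicolon-separated ``pathways`` membership of each gene.
    """
    with resources.files("arhohmm.data").joinpath("glioma_pathway_calls.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"gene": str})


def membership_summary(table: pd.DataFrame, group_columns=("OD", "AS", "GBM")) -> dict:
    """Counts over a gene x group call table with pathway memberships.

    Returns total genes, genes in >= 2 pathways, genes in exactly 3
    pathways, per-group call counts, and per-pathway Venn partitions (calls
    per group combination).
    """
    pathways_per_gene = {}
    for _, row in table.iterrows():
        raw = row["pathways"]
        if not isinstance(raw, str) or not raw.strip():
            raise ValueError(f"malformed pathway string for gene {row['gene']}")
        names = [p.strip() for p in raw.split(";")]
        if any(not p for p in names):
            raise ValueError(f"malformed pathway string for gene {row['gene']}")
        pathways_per_gene[row["gene"]] = names
    n_path = {g: len(p) for g, p in pathways_per_gene.items()}
    calls = table.set_index("gene")[list(group_columns)].astype(int)

    venn: dict[str, dict[tuple[str, ...], int]] = {}
    all_pathways = sorted({p for names in pathways_per_gene.values() for p in names})
    for pw in all_pathways:
        venn[pw] = {}
        for r in range(1, len(group_columns) + 1):
            for combo in combinations(group_columns, r):
                n = 0
                for g, names in pathways_per_gene.items():
                    if pw not in names:
                        continue
                    called = tuple(c for c in group_columns if calls.loc[g, c] == 1)
                    if called == combo:
                        n += 1
                if n:
                    venn[pw][combo] = n
    return {
        "total_genes": int(len(table)),
        "genes_in_ge2_pathways": int(sum(1 for v in n_path.values() if v >= 2)),
        "genes_in_3_pathways": int(sum(1 for v in n_path.values() if v == 3)),
        "calls_per_group": {c: int(calls[c].sum()) for c in group_columns},
        "venn": venn,
    }
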