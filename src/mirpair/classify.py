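"""Four-way classification of significant miRNA-mRNA interactions.

Each admitted (gene, miRNA) pair falls in one of four categories from the
sign of its association slope and whether a seed match exists:

* ``repression`` - negative beta with a seed match: canonical miRNA-mediated
  transcript degradation.
* ``negative_no_seed`` - negative beta, no seed match: possible indirect
  repression or a non-canonical site.
* ``positive_no_seed`` - positive beta, no seed match: downstream or
  feedback effects.
* ``positive_with_seed`` - positive beta despite a seed match: candidate
  feedback loops or translational (not transcript-level) repression.

A slope of exactly zero cannot arise from continuous data but is guarded:
such pairs are bucketed as ``no_effect`` and excluded from the four
categories. Admission requires gene-level q <= threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

CATEGORIES = ("repression", "negative_no_seed", "positive_no_seed", "positive_with_seed")


def classify(beta: float, seed_match: bool) -> str:
    """Category of one interaction from slope sign and seed flag."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta == 0:
        return "no_effect"
    if beta < 0:
        return "repression" if seed_match else "negative_no_seed"
    return "positive_with_seed" if seed_match else "positive_no_seed"


@dataclass
class CategorySummary:
    counts: dict[str, int]
    n_interactions: int
    n_unique_mirnas: int
    n_unique_genes: int

    def as_dict(self) -> dict:
        return {
            **self.counts,
            "n_interactions": self.n_interactions,
            "n_unique_mirnas": self.n_unique_mirnas,
            "n_unique_genes": self.n_unique_genes,
        }


def summarize(interactions: pd.DataFrame) -> CategorySummary:
    """Category counts and distinct-feature totals over an interaction table.

    Requires columns ``gene``, ``mirna``, ``beta``, ``seed_match``; duplicated
    (gene, miRNA) rows violate the uniqueness invariant and raise.
    """
    if interactions.duplicated(["gene", "mirna"]).any():
        dups = interactions.loc[interactions.duplicated(["gene", "mirna"]), ["gene", "mirna"]]
        raise ValueError(f"duplicate interactions: {dups.values[:3].tolist()}")
    counts = dict.fromkeys(CATEGORIES, 0)
    for _, row in interactions.iterrows():
        cat = classify(float(row["beta"]), bool(row["seed_match"]))
        if cat in counts:
            counts[cat] += 1
    return CategorySummary(
        counts=counts,
        n_interactions=len(interactions),
        n_unique_mirnas=interactions["mirna"].nunique() if len(interactions) else 0,
        n_unique_genes=interactions["gene"].nunique() if len(interactions) else 0,
    )


def assemble_interactions(
    associations: pd.DataFrame,
    seed_flags,
    q_threshold: float = 0.05,
    fc_low: float = 0.67,
    fc_high: float = 1.50,
    mirna_fc: pd.Series | None = None,
) -> pd.DataFrame:
    """Join association records with seed flags and admit significant pairs.

    ``seed_flags`` is a gene x miRNA boolean frame (missing entries count as
    no seed) or a callable ``(gene, mirna) -> bool``. Pairs are admitted when
    gene-level q <= ``q_threshold``; when ``mirna_fc`` (or a ``mirna_fc``
    column) is available, the miRNA fold-change reporting filter
    (> ``fc_high`` or < ``fc_low``) is applied as well.
    """
    df = associations.copy()
    df = df[df["q"].notna() & (df["q"] <= q_threshold)]
    if mirna_fc is not None:
        df["mirna_fc"] = df["mirna"].map(mirna_fc)
    if "mirna_fc" in df.columns:
        df = df[(df["mirna_fc"] > fc_high) | (df["mirna_fc"] < fc_low)]
    beta_col = "beta_std" if "beta_std" in df.columns else "beta"

    def flag(g, m):
        if callable(seed_flags):
            return bool(seed_flags(g, m))
        try:
            return bool(seed_flags.loc[g, m])
        except KeyError:
            return False

    df = df.assign(
        beta=df[beta_col],
        seed_match=[flag(g, m) for g, m in zip(df["gene"], df["mirna"])],
    )
    df["category"] = [classify(b, s) for b, s in zip(df["beta"], df["seed_match"])]
    return df.sort_values(["gene", "mirna"], kind="mergesort").reset_index(drop=True)


def _build_graph(interactions: pd.DataFrame) -> nx.DiGraph:
    df = interactions.sort_values(["gene", "mirna"], kind="mergesort")
    g = nx.DiGraph()
    for gene in sorted(df["gene"].unique()):
        attrs = {"type": "gene"}
        if "gene_fc" in df.columns:
            fc = float(df.loc[df["gene"] == gene, "gene_fc"].iloc[0])
            attrs.update(fc=fc, direction="up" if fc > 1 else "down")
        g.add_node(gene, **attrs)
    for mir in sorted(df["mirna"].unique()):
        attrs = {"type": "mirna"}
        if "mirna_fc" in df.columns:
            fc = float(df.loc[df["mirna"] == mir, "mirna_fc"].iloc[0])
            attrs.update(fc=fc, direction="up" if fc > 1 else "down")
        g.add_node(mir, **attrs)
    for _, row in df.iterrows():
        attrs = {
            "beta": float(row["beta"]),
            "seed_match": bool(row["seed_match"]),
            "category": row.get("category", classify(float(row["beta"]), bool(row["seed_match"]))),
        }
        if "q" in df.columns and pd.notna(row.get("q", np.nan)):
            attrs["q"] = float(row["q"])
        g.add_edge(row["mirna"], row["gene"], **attrs)
    return g


def export_network(interactions: pd.DataFrame, path, fmt: str = "graphml") -> None:
    """Write the bipartite interaction network as GraphML or SIF.

    Node and edge ordering is deterministic (sorted), so re-export of the
    same table is byte-identical. SIF carries only the edge list
    (miRNA <tab> category <tab> gene); GraphML carries all attributes.
    """
    if fmt == "graphml":
        nx.write_graphml(_build_graph(interactions), str(path))
    elif fmt == "sif":
        df = interactions.sort_values(["gene", "mirna"], kind="mergesort")
        lines = []
        for _, row in df.iterrows():
            cat = row.get("category", classify(float(row["beta"]), bool(row["seed_match"])))
            lines.append(f"{row['mirna']}\t{cat}\t{row['gene']}\n")
        with open(path, "w") as fh:
            fh.writelines(lines)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'graphml' or 'sif'")


class InteractionClassifier:
    """Configured wrapper around :func:`assemble_interactions` / :func:`summarize`."""

    def __init__(self, q_threshold: float = 0.05, fc_low: float = 0.67, fc_high: float = 1.50):
        self.q_threshold = q_threshold
        self.fc_low = fc_low
        self.fc_high = fc_high

    def transform(self, associations: pd.DataFrame, seed_flags, mirna_fc=None) -> pd.DataFrame:
        return assemble_interactions(
            associations, seed_flags, self.q_threshold, self.fc_low, self.fc_high, mirna_fc
        )

    def summarize(self, interactions: pd.DataFrame) -> CategorySummary:
        return summarize(interactions)
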