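"""Readers and assembly for the labeled, confidence-weighted gene network.

Input dialects
--------------
DEG tables are CSV/TSV with (configurable) columns for gene symbol,
log2 fold-change and p-value.  Interaction tables follow the STRING edge-list
dialect: two identifier columns plus a combined confidence score in
(0, 1000].  All readers accept gzip-compressed files transparently
(pandas infers compression from the filename).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum dysregulation magnitude; keeps the sheaf nowhere zero.
DEFAULT_Q_FLOOR = 1e-6


class NetworkFormatError(ValueError):
    """A table does not conform to the documented dialect."""


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene."""

    gene: str
    log2fc: float
    pvalue: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue {self.pvalue!r} outside [0, 1] for {self.gene}")


@dataclass(frozen=True, order=True)
class InteractionEdge:
    """Undirected confidence-scored interaction; endpoints stored sorted."""

    gene_a: str
    gene_b: str
    score: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)
        if not 0 < self.score <= 1000:
            raise ValueError(
                f"score {self.score} outside (0, 1000] for edge "
                f"({self.gene_a}, {self.gene_b})"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class LabeledNetwork:
    """Gene set with dysregulation magnitudes and confidence-weighted edges.

    ``genes`` is lexicographically sorted; ``q`` maps every gene to a strictly
    positive dysregulation magnitude; every edge endpoint is in ``genes``.
    """

    genes: list[str]
    q: dict[str, float]
    edges: list[InteractionEdge]
    score: dict[tuple[str, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes)
        gene_set = set(self.genes)
        if set(self.q) != gene_set:
            raise ValueError("q must be defined exactly on the gene set")
        if any(v <= 0 for v in self.q.values()):
            raise ValueError("all q values must be strictly positive")
        for e in self.edges:
            if e.gene_a not in gene_set or e.gene_b not in gene_set:
                raise ValueError(f"edge endpoint outside gene set: {e.pair}")
        self.edges = sorted(self.edges)
        self.score = {e.pair: e.score for e in self.edges}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledNetwork):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.q == other.q
            and self.edges == other.edges
        )


def read_deg_table(
    path: str | Path,
    *,
    gene_col: str = "gene",
    log2fc_col: str = "log2fc",
    pvalue_col: str = "pvalue",
    dialect: str | None = None,
) -> list[DEGRecord]:
    """Read a DEG table; rows with missing gene or non-numeric log2fc are
    dropped with a logged count.  Duplicate gene symbols are an error.
    """
    sep = _separator(path, dialect)
    df = pd.read_csv(path, sep=sep)
    for col in (gene_col, log2fc_col, pvalue_col):
        if col not in df.columns:
            raise NetworkFormatError(f"missing required column {col!r} in {path}")

    n_raw = len(df)
    df[log2fc_col] = pd.to_numeric(df[log2fc_col], errors="coerce")
    df[pvalue_col] = pd.to_numeric(df[pvalue_col], errors="coerce")
    df = df.dropna(subset=[gene_col, log2fc_col, pvalue_col])
    df = df[df[gene_col].astype(str).str.len() > 0]
    if (dropped := n_raw - len(df)) > 0:
        logger.info("read_deg_table: dropped %d malformed rows from %s", dropped, path)

    dupes = df[gene_col][df[gene_col].duplicated()]
    if not dupes.empty:
        raise NetworkFormatError(
            f"duplicate gene symbol(s) in {path}: {sorted(set(dupes))}"
        )
    return [
        DEGRecord(gene=str(r[gene_col]), log2fc=float(r[log2fc_col]), pvalue=float(r[pvalue_col]))
        for r in df.to_dict("records")
    ]


def select_top_upregulated(
    records: Sequence[DEGRecord], n: int, p_max: float = 0.05
) -> list[DEGRecord]:
    """Top-``n`` up-regulated genes by log2fc (descending).

    Ties break by ascending p-value, then symbol.  Requires at least two
    qualifying records, otherwise the downstream network is degenerate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    qualifying = [r for r in records if r.log2fc > 0 and r.pvalue <= p_max]
    if len(qualifying) < 2:
        raise ValueError(
            f"only {len(qualifying)} up-regulated genes pass p <= {p_max}; "
            "need at least 2 for a non-degenerate network"
        )
    qualifying.sort(key=lambda r: (-r.log2fc, r.pvalue, r.gene))
    return qualifying[:n]


def select_top_downregulated(
    records: Sequence[DEGRecord], n: int, p_max: float = 0.05
) -> list[DEGRecord]:
    """Mirror of :func:`select_top_upregulated` for down-regulated genes,
    ranked by |log2fc|.  Off the default path; provided as a config switch."""
    if n < 1:
        raise ValueError("n must be >= 1")
    qualifying = [r for r in records if r.log2fc < 0 and r.pvalue <= p_max]
    if len(qualifying) < 2:
        raise ValueError("fewer than 2 qualifying down-regulated genes")
    qualifying.sort(key=lambda r: (r.log2fc, r.pvalue, r.gene))
    return qualifying[:n]


def read_interaction_edges(
    path: str | Path,
    *,
    gene_a_col: str = "gene_a",
    gene_b_col: str = "gene_b",
    score_col: str = "score",
    aliases: Mapping[str, str] | None = None,
) -> list[InteractionEdge]:
    """Read a STRING-dialect TSV edge list.

    Self-loops are dropped (with a logged count); reversed duplicates collapse
    to one undirected edge; an out-of-range score is an error naming the row.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (gene_a_col, gene_b_col, score_col):
        if col not in df.columns:
            raise NetworkFormatError(f"missing required column {col!r} in {path}")

    edges: dict[tuple[str, str], InteractionEdge] = {}
    n_loops = 0
    for i, row in enumerate(df.to_dict("records")):
        a, b = str(row[gene_a_col]), str(row[gene_b_col])
        if aliases is not None:
            a, b = aliases.get(a, a), aliases.get(b, b)
        try:
            score = int(row[score_col])
        except (TypeError, ValueError) as exc:
            raise NetworkFormatError(f"non-integer score at row {i} of {path}") from exc
        if a == b:
            n_loops += 1
            continue
        if not 0 < score <= 1000:
            raise NetworkFormatError(
                f"score {score} outside (0, 1000] at row {i} of {path}"
            )
        edge = InteractionEdge(a, b, score)
        prev = edges.get(edge.pair)
        if prev is None or edge.score > prev.score:
            edges[edge.pair] = edge
    if n_loops:
        logger.info("read_interaction_edges: dropped %d self-loops from %s", n_loops, path)
    return sorted(edges.values())


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping foreign identifiers to gene symbols."""
    df = pd.read_csv(path, sep="\t", header=None, names=["from", "to"], dtype=str)
    return dict(zip(df["from"], df["to"]))


def build_labeled_network(
    degs: Sequence[DEGRecord],
    edges: Iterable[InteractionEdge],
    q_floor: float = DEFAULT_Q_FLOOR,
) -> LabeledNetwork:
    """Assemble the network: q(gene) = max(|log2fc|, q_floor); edges restricted
    to pairs with both endpoints among the DEGs; isolated genes retained."""
    if not degs:
        raise ValueError("degs must be nonempty")
    q = {r.gene: max(abs(r.log2fc), q_floor) for r in degs}
    kept = [e for e in edges if e.gene_a in q and e.gene_b in q]
    return LabeledNetwork(genes=list(q), q=q, edges=kept)


def write_labeled_network(network: LabeledNetwork, deg_path: str | Path, edge_path: str | Path) -> None:
    """Write the documented dialect; re-reading round-trips the network
    (p-values are not part of the network and are written as 0)."""
    pd.DataFrame(
        {"gene": network.genes, "log2fc": [network.q[g] for g in network.genes],
         "pvalue": [0.0] * len(network.genes)}
    ).to_csv(deg_path, index=False)
    pd.DataFrame(
        {"gene_a": [e.gene_a for e in network.edges],
         "gene_b": [e.gene_b for e in network.edges],
         "score": [e.score for e in network.edges]}
    ).to_csv(edge_path, sep="\t", index=False)


def read_labeled_network(deg_path: str | Path, edge_path: str | Path,
                         q_floor: float = DEFAULT_Q_FLOOR) -> LabeledNetwork:
    degs = read_deg_table(deg_path)
    edges = read_interaction_edges(edge_path)
    return build_labeled_network(degs, edges, q_floor=q_floor)


def _separator(path: str | Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    name = str(path)
    for ext in (".gz", ".gzip"):
        name = name.removesuffix(ext)
    return "\t" if name.endswith((".tsv", ".txt")) else ","
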