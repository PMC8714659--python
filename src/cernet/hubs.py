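"""Degree-based hub-gene ranking on a protein-protein interaction network.

Consumes a STRING-export style edge list (protein1, protein2,
combined_score), keeps edges at or above a confidence cutoff (0.4 by
default, STRING's "medium confidence"), ranks nodes by degree, and
intersects the top-k hubs with the mRNA nodes of a ceRNA network to pick
validation candidates — genes that are both hubs and ceRNA-regulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import networkx as nx

from .errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class HubRanking:
    """Top-k nodes by degree; ties broken lexicographically by gene id."""

    ranked: list[tuple[str, int, int]]  # (gene, degree, rank starting at 1)
    k: int

    def genes(self) -> list[str]:
        return [g for g, _, _ in self.ranked]


def load_ppi_edges(path: str | Path, min_score: float = 0.4) -> nx.Graph:
    """Load a STRING-style TSV edge list into an undirected graph.

    Edges below ``min_score`` are dropped; duplicate undirected edges
    collapse keeping the maximum score; self-loops are dropped with a
    logged count. Scores in STRING's integer 0-999 convention are rescaled
    by 1/1000 with a warning.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = 0
    n_rows = 0
    rescale_warned = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()  # STRING exports sometimes space-separate
            if lineno == 1 and parts and parts[0].lower() in ("protein1", "gene_a"):
                continue
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'protein1 protein2 combined_score'"
                )
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {raw!r}") from exc
            if score > 1.0:
                if score > 999.0 or score != int(score):
                    raise ValidationError(
                        f"{path}:{lineno}: combined_score {score} outside [0,1] "
                        "and not an integer 0-999 STRING score"
                    )
                if not rescale_warned:
                    logger.warning(
                        "%s: integer 0-999 scores detected; rescaling by 1/1000", path
                    )
                    rescale_warned = True
                score /= 1000.0
            if score < 0.0:
                raise ValidationError(f"{path}:{lineno}: negative combined_score")
            n_rows += 1
            if a == b:
                n_self += 1
                continue
            if score < min_score:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["combined_score"] = max(
                    g.edges[a, b]["combined_score"], score
                )
            else:
                g.add_edge(a, b, combined_score=score)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    if n_rows == 0:
        logger.warning("%s: empty PPI edge list", path)
    return g


def rank_hubs(graph: nx.Graph, k: int = 30) -> HubRanking:
    """Top-k nodes by degree, descending; lexicographic tie-break."""
    if k <= 0:
        raise ConfigurationError(f"hub cutoff k must be positive, got {k}")
    ordered = sorted(graph.nodes, key=lambda n: (-graph.degree[n], n))
    top = ordered[: min(k, len(ordered))]
    return HubRanking(
        ranked=[(g, graph.degree[g], i + 1) for i, g in enumerate(top)], k=k
    )


def select_validation_candidates(hubs: HubRanking, network: nx.Graph) -> list[str]:
    """Hub genes that also appear as mRNA nodes in the ceRNA network,
    ordered by hub rank — both hubs and ceRNA-regulated."""
    mrnas = {
        n for n, d in network.nodes(data=True) if d.get("kind") == "mRNA"
    }
    return [g for g in hubs.genes() if g in mrnas]


def write_hub_table(hubs: HubRanking, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("rank\tgene\tdegree\n")
        for gene, degree, rank in hubs.ranked:
            fh.write(f"{rank}\t{gene}\t{degree}\n")


def write_ppi_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
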