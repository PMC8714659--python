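"""ceRNA triple selection and network assembly.

The ceRNA hypothesis: a noncoding transcript (lncRNA or circRNA) that shares
miRNA response elements with an mRNA competes for the same miRNA, so when
the ceRNA is abundant the miRNA is sequestered and the mRNA is de-repressed.
Operationally the pipeline (i) joins ceRNA-miRNA and mRNA-miRNA target
pairs on their shared miRNA, (ii) keeps only triples whose miRNA is on a
curated, experimentally verified list with a known direction of change in
the case group, (iii) requires the ceRNA and mRNA expression profiles to be
tightly correlated (Pearson r above a strict threshold, 0.95 by default),
optionally with the RISC-competition direction rule (ceRNA and mRNA
co-directional, opposite the miRNA), and (iv) assembles the surviving
triples into an undirected bipartite-style network with node attributes for
kind and regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingFeatureError, ValidationError
from .expression import DERecord, ExpressionMatrix
from .targeting import TargetPair

logger = logging.getLogger(__name__)

CERNA_KINDS = ("lncRNA", "circRNA")


@dataclass(frozen=True)
class CuratedMiRNA:
    """A literature-verified miRNA with its direction in the case group."""

    name: str
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigurationError(
                f"curated miRNA {self.name!r}: direction must be 'up' or 'down'"
            )


#: miRNAs with qPCR-verified dysregulation in Graves' ophthalmopathy orbital
#: fibroblasts: miR-21, miR-146a and miR-155 up; miR-27a and miR-27b down.
DEFAULT_CURATED = (
    CuratedMiRNA("miR-21", "up"),
    CuratedMiRNA("miR-27a", "down"),
    CuratedMiRNA("miR-27b", "down"),
    CuratedMiRNA("miR-146a", "up"),
    CuratedMiRNA("miR-155", "up"),
)


class CandidateTriple(NamedTuple):
    """A (ceRNA, miRNA, mRNA) combination supported by seed-site pairs."""

    cerna_id: str
    mirna_id: str
    mrna_id: str


@dataclass
class CeRNATriple:
    """A candidate that survived every filter, with its evidence."""

    cerna_id: str
    mirna_id: str
    mrna_id: str
    r: float
    cerna_direction: str  # "up" | "down"
    mrna_direction: str
    passed_filters: tuple[str, ...] = ()

    def key(self) -> tuple[str, str, str]:
        return (self.cerna_id, self.mirna_id, self.mrna_id)


def normalize_mirna_name(name: str) -> str:
    """Lowercase and strip an optional species prefix ('hsa-')."""
    n = name.strip().lower()
    if n.startswith("hsa-"):
        n = n[4:]
    return n


def mirna_stem(name: str) -> str:
    """Drop a mature-arm suffix (-3p/-5p) from a normalized name."""
    n = normalize_mirna_name(name)
    for suffix in ("-3p", "-5p"):
        if n.endswith(suffix):
            return n[: -len(suffix)]
    return n


def match_curated(name: str, curated: Sequence[CuratedMiRNA]) -> CuratedMiRNA | None:
    """Curated entry matching ``name``, or None.

    Matching is case-insensitive; an optional 'hsa-' prefix and a mature-arm
    suffix (-3p/-5p) on the candidate match a bare stem in the curated list
    (the literature lists stems such as miR-27b while arrays report arms
    such as hsa-miR-27b-3p).
    """
    n = normalize_mirna_name(name)
    stem = mirna_stem(name)
    for entry in curated:
        cn = normalize_mirna_name(entry.name)
        if n == cn or stem == cn or mirna_stem(entry.name) == n:
            return entry
    return None


def intersect_pairs(
    ce_pairs: Sequence[TargetPair], m_pairs: Sequence[TargetPair]
) -> list[CandidateTriple]:
    """Join ceRNA-miRNA and mRNA-miRNA pairs on the shared miRNA.

    Emits every (ceRNA, miRNA, mRNA) with both pairs present; the count is
    the sum over shared miRNAs of |ceRNAs| x |mRNAs|. Sorted output.
    """
    ce_by_mirna: dict[str, list[str]] = {}
    for p in ce_pairs:
        ce_by_mirna.setdefault(p.mirna_id, []).append(p.target_id)
    out = []
    m_by_mirna: dict[str, list[str]] = {}
    for p in m_pairs:
        m_by_mirna.setdefault(p.mirna_id, []).append(p.target_id)
    for mirna, cernas in ce_by_mirna.items():
        for mrna in m_by_mirna.get(mirna, ()):
            for cerna in cernas:
                out.append(CandidateTriple(cerna, mirna, mrna))
    return sorted(out)


def cross_validate(
    candidates: Sequence[CandidateTriple],
    curated: Sequence[CuratedMiRNA] = DEFAULT_CURATED,
) -> list[CandidateTriple]:
    """Keep candidates whose miRNA matches a curated, verified entry."""
    if not curated:
        raise ConfigurationError(
            "curated miRNA list is empty: cross-validation would discard everything"
        )
    kept = [c for c in candidates if match_curated(c.mirna_id, curated) is not None]
    logger.info("cross_validate: %d/%d candidates kept", len(kept), len(candidates))
    return sorted(kept)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two expression vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r: vectors must be 1-D and equal length")
    if len(x) < 3:
        raise ValidationError("pearson_r: need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("pearson_r: zero variance; correlation undefined")
    r = float((xc * yc).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def _direction(log2fc: float) -> str:
    return "up" if log2fc > 0 else "down"


def filter_correlation(
    candidates: Sequence[CandidateTriple],
    expr: ExpressionMatrix,
    de_records: Sequence[DERecord],
    curated: Sequence[CuratedMiRNA] = DEFAULT_CURATED,
    r_threshold: float = 0.95,
    require_direction_consistency: bool = True,
    method: str = "pearson",
) -> list[CeRNATriple]:
    """Correlation (and optional direction) filter over candidate triples.

    Keeps candidates whose ceRNA and mRNA expression correlate with
    r > ``r_threshold`` (strict) across all samples, case and control
    pooled. With direction consistency on, additionally requires
    sign(log2FC ceRNA) == sign(log2FC mRNA) == opposite of the curated
    miRNA's direction — the RISC-competition signature (abundant ceRNA
    sequesters the miRNA and de-represses the mRNA). Triples whose members
    have zero expression variance are discarded with a log message.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation method: {method!r}")
    fc_by_id = {r.feature_id: r.log2fc for r in de_records}
    out: list[CeRNATriple] = []
    for cand in candidates:
        for member in (cand.cerna_id, cand.mrna_id):
            if member not in expr.values.index:
                raise MissingFeatureError(
                    f"feature {member!r} absent from expression matrix"
                )
        x = expr.values.loc[cand.cerna_id].to_numpy()
        y = expr.values.loc[cand.mrna_id].to_numpy()
        if method == "spearman":
            x = pd.Series(x).rank().to_numpy()
            y = pd.Series(y).rank().to_numpy()
        try:
            r = pearson_r(x, y)
        except ValidationError:
            logger.info(
                "filter_correlation: zero-variance member in %s; discarded", cand
            )
            continue
        if not r > r_threshold:
            continue
        filters = ["pair_intersection", "curated_mirna", f"correlation>{r_threshold:g}"]
        ce_dir = _direction(fc_by_id.get(cand.cerna_id, 0.0))
        m_dir = _direction(fc_by_id.get(cand.mrna_id, 0.0))
        if require_direction_consistency:
            entry = match_curated(cand.mirna_id, curated)
            if entry is None:
                continue
            expected = "down" if entry.direction == "up" else "up"
            if not (ce_dir == expected and m_dir == expected):
                continue
            filters.append("direction_consistency")
        out.append(
            CeRNATriple(
                cerna_id=cand.cerna_id,
                mirna_id=cand.mirna_id,
                mrna_id=cand.mrna_id,
                r=r,
                cerna_direction=ce_dir,
                mrna_direction=m_dir,
                passed_filters=tuple(filters),
            )
        )
    out.sort(key=CeRNATriple.key)
    return out


def assemble_network(
    triples: Sequence[CeRNATriple],
    kinds: Mapping[str, str] | None = None,
    curated: Sequence[CuratedMiRNA] = DEFAULT_CURATED,
) -> nx.Graph:
    """Undirected ceRNA network: ceRNA-miRNA and miRNA-mRNA edges.

    Nodes carry ``kind`` (lncRNA/circRNA/miRNA/mRNA) and ``regulation``
    (up/down/n/a; miRNA regulation from the curated direction). Parallel
    evidence collapses onto one edge whose ``triples`` attribute lists the
    source triples.
    """
    kinds = dict(kinds or {})
    g = nx.Graph()
    for t in triples:
        cerna_kind = kinds.get(t.cerna_id, "lncRNA")
        entry = match_curated(t.mirna_id, curated)
        mi_reg = entry.direction if entry is not None else "n/a"
        g.add_node(t.cerna_id, kind=cerna_kind, regulation=t.cerna_direction)
        g.add_node(t.mirna_id, kind="miRNA", regulation=mi_reg)
        g.add_node(t.mrna_id, kind="mRNA", regulation=t.mrna_direction)
        for a, b in ((t.cerna_id, t.mirna_id), (t.mirna_id, t.mrna_id)):
            if g.has_edge(a, b):
                g.edges[a, b]["triples"].append(t.key())
            else:
                g.add_edge(a, b, triples=[t.key()])
    return g


# ------------------------------------------------------------------ exports


def write_triples_tsv(triples: Sequence[CeRNATriple], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "cerna_id\tmirna_id\tmrna_id\tr\tcerna_direction\tmrna_direction"
            "\tpassed_filters\n"
        )
        for t in triples:
            fh.write(
                f"{t.cerna_id}\t{t.mirna_id}\t{t.mrna_id}\t{t.r:.6f}"
                f"\t{t.cerna_direction}\t{t.mrna_direction}"
                f"\t{','.join(t.passed_filters)}\n"
            )


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "cerna") -> None:
    """Simple-interaction-format export (Cytoscape-loadable)."""
    with Path(path).open("w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        if "triples" in data:
            data["triples"] = ";".join(
                "|".join(k) for k in data["triples"]
            )
    nx.write_graphml(g, str(path))


def write_node_attributes(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\tkind\tregulation\tdegree\n")
        for n in sorted(graph.nodes):
            d = graph.nodes[n]
            fh.write(f"{n}\t{d['kind']}\t{d['regulation']}\t{graph.degree[n]}\n")


def write_edge_attributes(graph: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tn_triples\n")
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{b}\t{len(graph.edges[a, b]['triples'])}\n")


def read_curated_tsv(path: str | Path) -> list[CuratedMiRNA]:
    """Curated miRNA list from TSV (name<TAB>direction), '#' comments allowed."""
    out = []
    with Path(path).open() as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{i}: expected 'name<TAB>direction'")
            out.append(CuratedMiRNA(parts[0], parts[1].lower()))
    names = [normalize_mirna_name(c.name) for c in out]
    if len(names) != len(set(names)):
        raise ValidationError(f"{path}: duplicate curated miRNA names")
    return out


def write_curated_tsv(curated: Sequence[CuratedMiRNA], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("name\tdirection\n")
        for c in curated:
            fh.write(f"{c.name}\t{c.direction}\n")
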