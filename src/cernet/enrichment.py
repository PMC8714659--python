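"""Fisher's-exact over-representation analysis against GMT gene sets.

For a query gene set (here, the mRNAs of the ceRNA network) and each term
of a collection, the one-sided Fisher's exact p-value is the hypergeometric
tail P(X >= k | N, K, n): N universe genes, K in the term, n in the query,
k in the overlap. P-values are Benjamini-Hochberg adjusted across all
tested terms and a term is called significant at q <= 0.05 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """Terms plus the background universe (defaults to the union of terms)."""

    terms: dict[str, GeneSet]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(
                *(t.genes for t in self.terms.values())
            ) if self.terms else frozenset()
        for t in self.terms.values():
            if not t.genes:
                raise ValidationError(f"gene set {t.term_id!r} is empty")


@dataclass
class EnrichmentRecord:
    term_id: str
    name: str
    category: str
    k: int  # overlap
    K: int  # term size in universe
    n: int  # query size in universe
    N: int  # universe size
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    overlap_genes: tuple[str, ...] = ()


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def fisher_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    q_threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """One-sided (over-representation) Fisher's exact test per term.

    The query is restricted to the universe first. Per term,
    p = P(X >= k) under Hypergeometric(N, K, n); BH adjustment across all
    tested terms; records sorted by (q, p, term_id).
    """
    query = set(query)
    universe = collection.universe
    q_in = query & universe
    if not q_in:
        raise ValidationError(
            "query has no genes in the collection universe; nothing to test"
        )
    dropped = len(query) - len(q_in)
    if dropped:
        logger.info("fisher_enrichment: %d query gene(s) outside universe", dropped)
    N, n = len(universe), len(q_in)
    records: list[EnrichmentRecord] = []
    for term in collection.terms.values():
        members = term.genes & universe
        K = len(members)
        if K == 0:
            logger.warning("term %s has no genes in universe; skipped", term.term_id)
            continue
        overlap = sorted(q_in & members)
        k = len(overlap)
        # survival function at k-1 gives P(X >= k), including X = k = 0 -> 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        records.append(
            EnrichmentRecord(
                term_id=term.term_id,
                name=term.name,
                category=term.category,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=min(p, 1.0),
                overlap_genes=tuple(overlap),
            )
        )
    qs = bh_adjust([r.p_value for r in records])
    for r, q in zip(records, qs):
        r.q_value = q
        r.significant = q <= q_threshold
    records.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return records


def category_counts(
    records: Sequence[EnrichmentRecord], collection: GeneSetCollection
) -> pd.DataFrame:
    """Distinct query genes hit per category label (bar-chart data).

    A gene overlapping several terms of one category counts once for it.
    """
    genes_by_cat: dict[str, set[str]] = {}
    terms_by_cat: dict[str, int] = {}
    for r in records:
        genes_by_cat.setdefault(r.category, set()).update(r.overlap_genes)
        terms_by_cat[r.category] = terms_by_cat.get(r.category, 0) + 1
    rows = [
        {"category": c, "n_terms": terms_by_cat[c], "n_genes": len(genes_by_cat[c])}
        for c in sorted(genes_by_cat)
    ]
    return pd.DataFrame(rows, columns=["category", "n_terms", "n_genes"])


# ------------------------------------------------------------------ GMT I/O
# GMT: term<TAB>description<TAB>gene1<TAB>gene2...
# The description field doubles as the category label ("BP", "KEGG", ...);
# a "category|name" description splits into both.


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    terms: dict[str, GeneSet] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT rows need term, description, >= 1 gene"
                )
            term_id, desc = parts[0], parts[1]
            if "|" in desc:
                category, name = desc.split("|", 1)
            else:
                category, name = desc, term_id
            if term_id in terms:
                raise ParseError(f"{path}:{lineno}: duplicate term {term_id!r}")
            genes = frozenset(g for g in parts[2:] if g)
            terms[term_id] = GeneSet(term_id, name, category, genes)
    return GeneSetCollection(
        terms, frozenset(universe) if universe is not None else frozenset()
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in collection.terms.values():
            desc = f"{t.category}|{t.name}" if t.name != t.term_id else t.category
            fh.write(f"{t.term_id}\t{desc}\t" + "\t".join(sorted(t.genes)) + "\n")


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("term_id\tname\tcategory\tk\tK\tn\tN\tp\tq\tsignificant\tgenes\n")
        for r in records:
            fh.write(
                f"{r.term_id}\t{r.name}\t{r.category}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                f"\t{r.p_value:.6g}\t{r.q_value:.6g}\t{r.significant}"
                f"\t{','.join(r.overlap_genes)}\n"
            )


def write_category_counts_tsv(
    records: Sequence[EnrichmentRecord],
    collection: GeneSetCollection,
    path: str | Path,
) -> None:
    category_counts(records, collection).to_csv(path, sep="\t", index=False)
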