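"""Canonical miRNA seed-site prediction on linear and circular transcripts.

A miRNA represses a target through its seed, nucleotides 2-7 of the mature
strand (5'->3'), pairing Watson-Crick and antiparallel to the target. Written
on the target 5'->3', a site therefore reads: [base opposite miRNA position
8][reverse complement of the seed][base opposite miRNA position 1]. The four
canonical site classes are, weakest to strongest:

    6mer     perfect pairing to miRNA positions 2-7
    7mer-A1  6mer plus an adenine on the target opposite miRNA position 1
    7mer-m8  perfect pairing to miRNA positions 2-8
    8mer     7mer-m8 plus the A1 adenine

Each matching position is reported once with the most specific class it
supports. Circular transcripts (back-spliced circRNAs) are scanned on the
doubled sequence so sites spanning the back-splice junction are found;
coordinates are reported modulo the length. Seed-class matching stands in
for full hybridization-energy alignment: the downstream ceRNA logic only
consumes the resulting pairs, and the scorer is pluggable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .seq import clean_rna, complement, reverse_complement

logger = logging.getLogger(__name__)

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
# strength order used for best_site_type and most-specific reporting
_SITE_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}
_SITE_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with its RNA kind and topology."""

    id: str
    kind: str  # mRNA | lncRNA | circRNA | miRNA
    sequence: str
    topology: str = "linear"  # linear | circular

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_rna(self.sequence, context=self.id))
        if self.kind == "circRNA" and self.topology != "circular":
            raise ValidationError(f"{self.id}: circRNA must have circular topology")
        if self.kind != "circRNA" and self.topology == "circular":
            raise ValidationError(f"{self.id}: only circRNAs are circular")


class TranscriptSet:
    """Ordered mapping of transcript id -> :class:`Transcript`."""

    def __init__(self, transcripts: Iterable[Transcript] = ()) -> None:
        self._by_id: dict[str, Transcript] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: Transcript) -> None:
        if t.id in self._by_id:
            raise ValidationError(f"duplicate transcript id: {t.id!r}")
        self._by_id[t.id] = t

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def __getitem__(self, tid: str) -> Transcript:
        return self._by_id[tid]

    def ids(self) -> list[str]:
        return list(self._by_id)

    def subset_kinds(self, kinds: Iterable[str]) -> "TranscriptSet":
        kinds = set(kinds)
        return TranscriptSet(t for t in self if t.kind in kinds)

    # FASTA dialect: kind and topology ride in the description as
    # "kind=lncRNA topology=linear"; T is mapped to U on load.
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(
                Seq(t.sequence),
                id=t.id,
                description=f"kind={t.kind} topology={t.topology}",
            )
            for t in self
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TranscriptSet":
        out = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            tags = dict(
                kv.split("=", 1)
                for kv in rec.description.split()
                if "=" in kv
            )
            kind = tags.get("kind", "mRNA")
            topology = tags.get(
                "topology", "circular" if kind == "circRNA" else "linear"
            )
            out.add(Transcript(rec.id, kind, str(rec.seq), topology))
        return out


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary site on a target.

    ``start`` is the 0-based offset of the site's 5'-most target base
    (half-open span of length 6-8 depending on type); for circular targets
    it is taken modulo the transcript length.
    """

    mirna_id: str
    target_id: str
    site_type: str
    start: int
    site_seq: str


@dataclass(frozen=True)
class TargetPair:
    """Aggregated miRNA-target relation: at least one seed site exists."""

    mirna_id: str
    target_id: str
    target_kind: str
    n_sites: int
    best_site_type: str


def _supported_types(scan: str, core: int, m8_base: str) -> set[str]:
    """Site classes supported by the flanks of the 6mer core at ``core``."""
    has_m8 = core >= 1 and scan[core - 1] == m8_base
    has_a1 = core + 6 < len(scan) and scan[core + 6] == "A"
    types = {"6mer"}
    if has_m8:
        types.add("7mer-m8")
    if has_a1:
        types.add("7mer-A1")
    if has_m8 and has_a1:
        types.add("8mer")
    return types


def find_seed_sites(
    mirna_seq: str,
    target: Transcript,
    allowed_types: Iterable[str] | None = None,
    mirna_id: str = "miRNA",
) -> list[SeedSite]:
    """All seed-complementary sites of one miRNA on one target.

    Every position where the target carries the Watson-Crick reverse
    complement of miRNA positions 2-7 yields exactly one site, typed with
    the most specific class the flanking bases support (restricted to
    ``allowed_types`` when given; positions whose every matching class is
    disallowed are dropped). Circular targets are scanned on the doubled
    sequence and deduplicated modulo the length.
    """
    mirna = clean_rna(mirna_seq, context=f"miRNA {mirna_id}")
    if len(mirna) < 8:
        raise ValidationError(
            f"miRNA {mirna_id} is {len(mirna)} nt; need >= 8 for seed classes"
        )
    allowed = set(SITE_TYPES) if allowed_types is None else set(allowed_types)
    bad = allowed - set(SITE_TYPES)
    if bad:
        raise ValidationError(f"unknown site type(s): {sorted(bad)}")

    seed_rc = reverse_complement(mirna[1:7])  # positions 2-7
    m8_base = complement(mirna[7])  # target base pairing miRNA position 8
    seq = target.sequence
    L = len(seq)
    circular = target.topology == "circular"
    if L < 6:
        return []

    scan = seq + seq if circular else seq
    sites = []
    for core in range(L if circular else L - 5):
        # for circular targets classify the copy whose m8 flank exists in
        # the doubled scan (core 0 wraps; its flank sits at position L - 1)
        probe = core + L if (circular and core == 0) else core
        if scan[probe : probe + 6] != seed_rc:
            continue
        supported = _supported_types(scan, probe, m8_base)
        usable = {
            t for t in supported & allowed
            if _SITE_LEN[t] <= L  # windows longer than the circle rejected
        }
        if not usable:
            continue
        stype = max(usable, key=lambda t: _SITE_RANK[t])
        start = probe - 1 if stype in ("7mer-m8", "8mer") else probe
        site_seq = scan[start : start + _SITE_LEN[stype]]
        sites.append(SeedSite(mirna_id, target.id, stype, start % L, site_seq))
    return sites


def predict_targets(
    mirnas: TranscriptSet,
    targets: TranscriptSet,
    allowed_types: Iterable[str] | None = None,
) -> list[TargetPair]:
    """One :class:`TargetPair` per (miRNA, target) with at least one seed
    site; deterministic, sorted by (mirna_id, target_id)."""
    if len(mirnas) == 0 or len(targets) == 0:
        logger.warning("predict_targets: empty miRNA or target set; no pairs")
        return []
    pairs: list[TargetPair] = []
    for mirna in sorted(mirnas, key=lambda t: t.id):
        if mirna.kind != "miRNA":
            raise ValidationError(f"{mirna.id}: expected kind miRNA, got {mirna.kind}")
        for target in sorted(targets, key=lambda t: t.id):
            sites = find_seed_sites(
                mirna.sequence, target, allowed_types, mirna_id=mirna.id
            )
            if sites:
                best = max(sites, key=lambda s: _SITE_RANK[s.site_type])
                pairs.append(
                    TargetPair(
                        mirna_id=mirna.id,
                        target_id=target.id,
                        target_kind=target.kind,
                        n_sites=len(sites),
                        best_site_type=best.site_type,
                    )
                )
    return pairs


def scan_all_sites(
    mirnas: TranscriptSet,
    targets: TranscriptSet,
    allowed_types: Iterable[str] | None = None,
) -> list[SeedSite]:
    """Every seed site of every miRNA on every target (sorted)."""
    sites: list[SeedSite] = []
    for mirna in sorted(mirnas, key=lambda t: t.id):
        for target in sorted(targets, key=lambda t: t.id):
            sites.extend(
                find_seed_sites(mirna.sequence, target, allowed_types, mirna.id)
            )
    return sites


def write_sites_bed(sites: Sequence[SeedSite], path: str | Path) -> None:
    """BED-like TSV: target_id, start, end, mirna_id, site_type."""
    with Path(path).open("w") as fh:
        fh.write("target_id\tstart\tend\tmirna_id\tsite_type\n")
        for s in sites:
            fh.write(
                f"{s.target_id}\t{s.start}\t{s.start + _SITE_LEN[s.site_type]}"
                f"\t{s.mirna_id}\t{s.site_type}\n"
            )


def write_pairs_tsv(pairs: Sequence[TargetPair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mirna_id\ttarget_id\ttarget_kind\tn_sites\tbest_site_type\n")
        for p in pairs:
            fh.write(
                f"{p.mirna_id}\t{p.target_id}\t{p.target_kind}"
                f"\t{p.n_sites}\t{p.best_site_type}\n"
            )


def read_pairs_tsv(path: str | Path) -> list[TargetPair]:
    pairs = []
    with Path(path).open() as fh:
        header = fh.readline()
        for line in fh:
            m, t, k, n, b = line.rstrip("\n").split("\t")
            pairs.append(TargetPair(m, t, k, int(n), b))
    return pairs
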