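"""Synthetic ceRNA study generator with planted, recoverable ground truth.

Emulates the shape of a paired case/control microarray ceRNA profiling
study: 3 case vs 3 control samples; mRNA, lncRNA, circRNA and miRNA
features on a log2-intensity scale; a minority of features differentially
expressed; and a small set of true ceRNA triples (ceRNA, miRNA, mRNA)
whose members are tightly co-expressed and carry real seed-complementary
sites in their transcript sequences.

Construction, per planted triple with sign s:
  * the ceRNA and mRNA receive a planted case-group shift of +s * log2FC,
    the miRNA the opposite shift (RISC competition: abundant ceRNA
    sequesters the miRNA, de-repressing the mRNA);
  * the ceRNA and mRNA share a per-sample latent profile (the miRNA gets
    its negation) whose amplitude scales with the noise SD, so their
    cross-sample Pearson correlation tends to 1 as the noise SD tends to 0
    while remaining strictly above the independent-noise floor otherwise;
  * one seed site of the triple's miRNA is planted on both the ceRNA and
    the mRNA transcript (wrapping the back-splice junction when the ceRNA
    is circular and the draw lands near the end).

Background sequence is uniform over A/C/G/U *conditional on containing no
seed match for any simulated miRNA* (rejection sampling). This makes the
planted-site table the exact ground truth of the targeting stage, so
zero-noise pipeline runs recover the planted triples with no false
positives — chance seed complements (~L/4096 per miRNA-target pair under
unconditioned uniform sequence) would otherwise blur the truth the
generator exists to define.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoundsError, ConfigurationError
from .expression import ExpressionMatrix
from .network import CuratedMiRNA
from .seq import clean_rna, reverse_complement
from .targeting import SITE_TYPES, Transcript, TranscriptSet, find_seed_sites

_SITE_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
_MAX_DRAWS = 200  # rejection-sampling attempts per transcript


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: 3 case vs 3 control samples,
    three noncoding kinds plus mRNAs, planted |log2FC| of 2 (fold change 4,
    comfortably past the screen's threshold of 1), and 5 planted triples —
    one per curated miRNA.
    """

    n_case: int = 3
    n_control: int = 3
    n_mrna: int = 50
    n_lncrna: int = 20
    n_circrna: int = 20
    n_mirna: int = 10
    frac_de: float = 0.2
    planted_log2fc: float = 2.0
    noise_sd: float = 0.1
    n_triples: int = 5
    transcript_len: int = 100
    mirna_len: int = 22
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    latent_sd_ratio: float = 1.0
    site_type: str = "8mer"
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_mrna", "n_lncrna", "n_circrna",
                     "n_mirna"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_triples < 0:
            raise ConfigurationError(f"n_triples must be >= 0, got {self.n_triples}")
        cap = min(self.n_lncrna + self.n_circrna, self.n_mirna, self.n_mrna)
        if self.n_triples > cap:
            raise ConfigurationError(
                f"n_triples={self.n_triples} exceeds the feature pools (max {cap})"
            )
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.mirna_len < 8:
            raise ConfigurationError(f"mirna_len must be >= 8, got {self.mirna_len}")
        if self.transcript_len < 16:
            raise ConfigurationError(
                f"transcript_len must be >= 16, got {self.transcript_len}"
            )
        if self.site_type not in SITE_TYPES:
            raise ConfigurationError(f"site_type must be one of {SITE_TYPES}")
        if self.latent_sd_ratio < 0:
            raise ConfigurationError(
                f"latent_sd_ratio must be >= 0, got {self.latent_sd_ratio}"
            )


@dataclass
class SyntheticTruth:
    """The planted effects and triples a recovery test checks against."""

    de_features: dict[str, float]  # feature id -> signed planted log2FC
    planted_triples: list[tuple[str, str, str]]  # (cerna, mirna, mrna)
    planted_sites: list[tuple[str, str, int, str]]  # (mirna, target, pos, type)

    def curated_mirnas(self) -> list[CuratedMiRNA]:
        """Curated-list view of the planted miRNAs (direction = planted sign)."""
        out = []
        for _, mirna, _ in self.planted_triples:
            direction = "up" if self.de_features[mirna] > 0 else "down"
            entry = CuratedMiRNA(mirna, direction)
            if entry not in out:
                out.append(entry)
        return out

    def to_tsv(self, directory: str | Path) -> None:
        d = Path(directory)
        with (d / "truth_de_features.tsv").open("w") as fh:
            fh.write("feature_id\tplanted_log2fc\n")
            for fid, fc in self.de_features.items():
                fh.write(f"{fid}\t{fc:g}\n")
        with (d / "truth_triples.tsv").open("w") as fh:
            fh.write("cerna_id\tmirna_id\tmrna_id\n")
            for c, mi, m in self.planted_triples:
                fh.write(f"{c}\t{mi}\t{m}\n")
        with (d / "truth_sites.tsv").open("w") as fh:
            fh.write("mirna_id\ttarget_id\tposition\tsite_type\n")
            for mi, t, pos, st in self.planted_sites:
                fh.write(f"{mi}\t{t}\t{pos}\t{st}\n")

    @classmethod
    def from_tsv(cls, directory: str | Path) -> "SyntheticTruth":
        d = Path(directory)
        de = pd.read_csv(d / "truth_de_features.tsv", sep="\t")
        tr = pd.read_csv(d / "truth_triples.tsv", sep="\t")
        si = pd.read_csv(d / "truth_sites.tsv", sep="\t")
        return cls(
            de_features=dict(zip(de.feature_id, de.planted_log2fc)),
            planted_triples=[tuple(r) for r in tr.itertuples(index=False)],
            planted_sites=[tuple(r) for r in si.itertuples(index=False)],
        )


def site_sequence(mirna_seq: str, site_type: str) -> str:
    """The target-side site string for a miRNA and site class (5'->3').

    Written on the target, a site reads [base pairing miRNA position 8]
    [reverse complement of the seed, miRNA 2-7][A opposite position 1],
    with the flanks present per class.
    """
    m = clean_rna(mirna_seq, context="miRNA")
    if len(m) < 8:
        raise ConfigurationError("miRNA must be >= 8 nt")
    if site_type == "6mer":
        return reverse_complement(m[1:7])
    if site_type == "7mer-A1":
        return reverse_complement(m[1:7]) + "A"
    if site_type == "7mer-m8":
        return reverse_complement(m[1:8])
    if site_type == "8mer":
        return reverse_complement(m[1:8]) + "A"
    raise ConfigurationError(f"unknown site_type {site_type!r}")


def plant_seed_site(
    sequence: str,
    mirna_seq: str,
    position: int,
    site_type: str,
    topology: str = "linear",
) -> str:
    """Overwrite ``sequence`` at ``position`` with a seed site; length kept.

    For circular topology the site may wrap the back-splice junction
    (position < len suffices); linear planting requires the whole site to
    fit.
    """
    seq = list(clean_rna(sequence, context="target"))
    site = site_sequence(mirna_seq, site_type)
    L = len(seq)
    if position < 0:
        raise BoundsError(f"position {position} is negative")
    if topology == "circular":
        if position >= L:
            raise BoundsError(f"position {position} >= circular length {L}")
        for i, base in enumerate(site):
            seq[(position + i) % L] = base
    else:
        if position + len(site) > L:
            raise BoundsError(
                f"site of length {len(site)} at {position} exceeds length {L}"
            )
        seq[position : position + len(site)] = site
    return "".join(seq)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _count_overlapping(haystack: str, needle: str) -> int:
    count = pos = 0
    while (pos := haystack.find(needle, pos)) != -1:
        count += 1
        pos += 1
    return count


def _draw_mirnas(cfg: SimulationConfig, rng: np.random.Generator) -> list[Transcript]:
    """miRNA sequences with pairwise-distinct extended seeds (positions 1-8).

    Sequences whose own planted-site string contains the seed complement
    more than once (repetitive seeds such as poly-A) are redrawn — a single
    unambiguous site could never be planted for them. Likewise, a candidate
    whose seed complement appears inside another accepted miRNA's site
    string (or vice versa) is redrawn, since a site planted for one would
    unavoidably read as a site of the other.
    """
    mirnas: list[Transcript] = []
    accepted: list[tuple[str, str]] = []  # (seed_rc, full site string)
    for i in range(cfg.n_mirna):
        for _ in range(_MAX_DRAWS):
            seq = _random_rna(rng, cfg.mirna_len)
            seed_rc = reverse_complement(seq[1:7])
            site = site_sequence(seq, cfg.site_type)
            if _count_overlapping(site, seed_rc) != 1:
                continue
            if any(
                other_rc in site or seed_rc in other_site
                for other_rc, other_site in accepted
            ):
                continue
            accepted.append((seed_rc, site))
            break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError("could not draw distinct miRNA seeds")
        mirnas.append(Transcript(f"miR-sim-{i + 1:02d}", "miRNA", seq, "linear"))
    return mirnas


def _scan_clean(seq: str, kind: str, topology: str, mirnas: Sequence[Transcript]) -> bool:
    """True when no simulated miRNA has any seed site on ``seq``."""
    probe = Transcript("probe", kind, seq, topology)
    return all(
        not find_seed_sites(m.sequence, probe, mirna_id=m.id) for m in mirnas
    )


def _draw_background(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    kind: str,
    topology: str,
    mirnas: Sequence[Transcript],
) -> str:
    for _ in range(_MAX_DRAWS):
        seq = _random_rna(rng, cfg.transcript_len)
        if _scan_clean(seq, kind, topology, mirnas):
            return seq
    raise ConfigurationError(  # pragma: no cover
        "rejection sampling failed; transcript_len too large for n_mirna"
    )


def _draw_target_with_site(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    kind: str,
    topology: str,
    mirna: Transcript,
    all_mirnas: Sequence[Transcript],
) -> tuple[str, int]:
    """A transcript carrying exactly one site of ``mirna`` and none of the
    other simulated miRNAs; returns (sequence, site start)."""
    site_len = _SITE_LEN[cfg.site_type]
    for _ in range(_MAX_DRAWS):
        seq = _random_rna(rng, cfg.transcript_len)
        if topology == "circular":
            pos = int(rng.integers(0, cfg.transcript_len))
        else:
            pos = int(rng.integers(0, cfg.transcript_len - site_len + 1))
        planted = plant_seed_site(seq, mirna.sequence, pos, cfg.site_type, topology)
        probe = Transcript("probe", kind, planted, topology)
        own = find_seed_sites(mirna.sequence, probe, mirna_id=mirna.id)
        if [(s.start, s.site_type) for s in own] != [(pos, cfg.site_type)]:
            continue
        others = [m for m in all_mirnas if m.id != mirna.id]
        if _scan_clean(planted, kind, topology, others):
            return planted, pos
    raise ConfigurationError(  # pragma: no cover
        "could not plant a unique seed site; relax transcript_len or n_mirna"
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TranscriptSet, SyntheticTruth]:
    """Generate the expression matrix, transcript set and truth tables.

    Deterministic in ``config.rng_seed``: identical configs reproduce the
    dataset bit-for-bit.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    ids = {
        "mRNA": [f"mRNA-{i + 1:04d}" for i in range(cfg.n_mrna)],
        "lncRNA": [f"lncRNA-{i + 1:04d}" for i in range(cfg.n_lncrna)],
        "circRNA": [f"circRNA-{i + 1:04d}" for i in range(cfg.n_circrna)],
    }
    mirnas = _draw_mirnas(cfg, rng)
    mirna_ids = [m.id for m in mirnas]
    kind_of: dict[str, str] = {}
    for kind, lst in ids.items():
        for fid in lst:
            kind_of[fid] = kind
    for mid in mirna_ids:
        kind_of[mid] = "miRNA"
    all_ids = ids["mRNA"] + ids["lncRNA"] + ids["circRNA"] + mirna_ids

    # ---- planted triples: distinct members, one miRNA per triple
    cerna_pool = ids["lncRNA"] + ids["circRNA"]
    triples: list[tuple[str, str, str]] = []
    if cfg.n_triples:
        cernas = [str(x) for x in rng.choice(cerna_pool, size=cfg.n_triples, replace=False)]
        mis = [str(x) for x in rng.choice(mirna_ids, size=cfg.n_triples, replace=False)]
        mrnas = [str(x) for x in rng.choice(ids["mRNA"], size=cfg.n_triples, replace=False)]
        triples = list(zip(cernas, mis, mrnas))

    # ---- planted differential expression
    # Effects are planted in sign-balanced pairs with offset baselines: for
    # every feature shifted by +fc there is a partner at baseline + fc
    # shifted by -fc. Every sample column then carries the identical value
    # multiset, so quantile normalization is the exact identity at zero
    # noise and fold-change-preserving otherwise — mirroring its behaviour
    # on real arrays, where it is only valid when changes are balanced.
    de_features: dict[str, float] = {}
    for cerna, mirna, mrna in triples:
        s = 1.0 if rng.random() < 0.5 else -1.0
        de_features[cerna] = s * cfg.planted_log2fc
        de_features[mrna] = s * cfg.planted_log2fc
        de_features[mirna] = -s * cfg.planted_log2fc
    free = [f for f in all_ids if f not in de_features]
    if len(de_features) > len(free):
        raise ConfigurationError(
            "n_triples too large to balance planted effects: need "
            f"{len(de_features)} free partner features, have {len(free)}"
        )
    partner_of: dict[str, str] = {}
    members = list(de_features.items())
    for (member, fc), pid in zip(
        members, rng.choice(free, size=len(members), replace=False)
    ):
        pid = str(pid)
        de_features[pid] = -fc
        partner_of[pid] = member
    free = [f for f in all_ids if f not in de_features]
    n_extra = max(0, round(cfg.frac_de * len(all_ids)) - len(de_features))
    n_pairs = min(n_extra, len(free)) // 2
    if n_pairs:
        chosen = [str(x) for x in rng.choice(free, size=2 * n_pairs, replace=False)]
        for a, b in zip(chosen[::2], chosen[1::2]):
            s = cfg.planted_log2fc if rng.random() < 0.5 else -cfg.planted_log2fc
            de_features[a] = s
            de_features[b] = -s
            partner_of[b] = a

    # ---- expression values
    n_samples = cfg.n_case + cfg.n_control
    sample_ids = [f"case_{i + 1}" for i in range(cfg.n_case)] + [
        f"control_{i + 1}" for i in range(cfg.n_control)
    ]
    groups = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    case_mask = np.array([g == "case" for g in groups], dtype=float)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(all_ids))
    row_of = {fid: i for i, fid in enumerate(all_ids)}
    for pid, member in partner_of.items():
        baseline[row_of[pid]] = baseline[row_of[member]] + de_features[member]
    X = np.tile(baseline[:, None], (1, n_samples))
    for fid, fc in de_features.items():
        X[row_of[fid]] += fc * case_mask
    latent_sd = cfg.latent_sd_ratio * cfg.noise_sd
    for idx, (cerna, mirna, mrna) in enumerate(triples):
        latent = rng.normal(0.0, latent_sd, size=n_samples)
        X[row_of[cerna]] += latent
        X[row_of[mrna]] += latent
        X[row_of[mirna]] -= latent
    X += rng.normal(0.0, cfg.noise_sd, size=X.shape) if cfg.noise_sd > 0 else 0.0

    expr = ExpressionMatrix(
        pd.DataFrame(X, index=all_ids, columns=sample_ids),
        pd.Series([kind_of[f] for f in all_ids], index=all_ids),
        pd.Series(groups, index=sample_ids),
    )

    # ---- transcript sequences (site-bearing for triple members)
    site_for: dict[str, Transcript] = {}
    for cerna, mirna, _mrna in triples:
        site_for[cerna] = next(m for m in mirnas if m.id == mirna)
        site_for[_mrna] = site_for[cerna]
    transcripts = TranscriptSet(mirnas)
    planted_sites: list[tuple[str, str, int, str]] = []
    for kind in ("mRNA", "lncRNA", "circRNA"):
        topology = "circular" if kind == "circRNA" else "linear"
        for fid in ids[kind]:
            if fid in site_for:
                mir = site_for[fid]
                seq, pos = _draw_target_with_site(
                    cfg, rng, kind, topology, mir, mirnas
                )
                planted_sites.append((mir.id, fid, pos, cfg.site_type))
            else:
                seq = _draw_background(cfg, rng, kind, topology, mirnas)
            transcripts.add(Transcript(fid, kind, seq, topology))

    truth = SyntheticTruth(
        de_features=de_features,
        planted_triples=sorted(triples),
        planted_sites=sorted(planted_sites),
    )
    return expr, transcripts, truth


def rename_features(
    expr: ExpressionMatrix,
    transcripts: TranscriptSet,
    truth: SyntheticTruth,
    mapping: Mapping[str, str],
) -> tuple[ExpressionMatrix, TranscriptSet, SyntheticTruth]:
    """Consistently rename features across the matrix, sequences and truth.

    Useful for giving planted miRNAs literature names (e.g. hsa-miR-27b-3p)
    so the curated-list cross-validation stage is exercisable end to end.
    """
    def rn(fid: str) -> str:
        return mapping.get(fid, fid)

    new_values = expr.values.rename(index=rn)
    new_kinds = expr.feature_kinds.rename(index=rn)
    new_expr = ExpressionMatrix(new_values, new_kinds, expr.sample_groups)
    new_ts = TranscriptSet(
        Transcript(rn(t.id), t.kind, t.sequence, t.topology) for t in transcripts
    )
    new_truth = SyntheticTruth(
        de_features={rn(f): fc for f, fc in truth.de_features.items()},
        planted_triples=sorted(
            (rn(c), rn(m), rn(g)) for c, m, g in truth.planted_triples
        ),
        planted_sites=sorted(
            (rn(m), rn(t), p, st) for m, t, p, st in truth.planted_sites
        ),
    )
    return new_expr, new_ts, new_truth
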