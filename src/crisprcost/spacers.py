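"""CRISPR amplicon processing: size selection, repeat-anchored spacer
extraction, SWARM-style single-linkage clustering, abundance assignment and
spacer classification against phage/host genomes.

Clustering follows the agglomerative single-linkage semantics of SWARM at its
strictest setting: two dereplicated variants belong to the same cluster when
they are connected by a chain of sequences each within edit distance ``d``
(substitutions and indels) of the next, so the similarity threshold is defined
within the dataset rather than fixed globally. Abundances are then assigned by
aligning every sequence to the best cluster centroid at a minimum global
identity (99% of the full alignment length by default).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "AmpliconRead",
    "Spacer",
    "Cluster",
    "SpacerRecord",
    "PamRule",
    "SIZE_RANGES",
    "size_filter",
    "extract_spacers",
    "swarm_cluster",
    "filter_clusters",
    "assign_abundance",
    "classify_spacer",
    "read_amplicon_fasta",
    "write_centroid_fasta",
]

#: Inclusive merged-read length windows per CRISPR locus used for size
#: selection of the amplicon libraries.
SIZE_RANGES: dict[str, tuple[int, int]] = {
    "CRISPR1": (30, 140),
    "CRISPR2": (70, 500),
}

_DNA = set("ACGT")


class SpacerError(ValueError):
    pass


@dataclass(frozen=True)
class AmpliconRead:
    """A merged (pair-spanning) amplicon sequence from one sample and locus."""

    id: str
    sequence: str
    sample: str
    locus: str

    def __post_init__(self):
        if not self.sequence or not set(self.sequence) <= _DNA:
            raise SpacerError(f"read {self.id!r}: sequence must be non-empty over ACGT")


@dataclass(frozen=True)
class Spacer:
    """An inter-repeat segment extracted from an amplicon read.

    ``partial`` marks segments flanked by a repeat on only one side.
    """

    sequence: str
    source_id: str
    locus: str
    partial: bool = False


@dataclass
class Cluster:
    """A group of sequence variants; the centroid is the most abundant member."""

    centroid: str
    members: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.members.values())


@dataclass(frozen=True)
class SpacerRecord:
    """A distinct spacer with its genomic classification and read count."""

    sequence: str
    target: str          # phage | host | unknown
    pam: str             # canonical | non-canonical | NA
    coordinate: int      # 0-based start of protospacer on the target genome, -1 if none
    strand: str          # + | - | .
    count: int
    sample: str = ""
    spacer_id: str = ""

    def __post_init__(self):
        if self.count < 0:
            raise SpacerError(f"count must be >= 0, got {self.count}")
        if self.target not in ("phage", "host", "unknown"):
            raise SpacerError(f"bad target {self.target!r}")
        if self.pam not in ("canonical", "non-canonical", "NA"):
            raise SpacerError(f"bad pam {self.pam!r}")


@dataclass(frozen=True)
class PamRule:
    """Where and what to read as the protospacer-adjacent motif.

    ``side`` is relative to the protospacer on its own strand: ``"3prime"``
    reads the ``len(motif)`` bases immediately downstream, ``"5prime"``
    immediately upstream. The type I-F consensus motif for this host is GG.
    """

    motif: str = "GG"
    side: str = "3prime"
    priming_center: int = 27847

    def __post_init__(self):
        if self.side not in ("3prime", "5prime"):
            raise SpacerError(f"PAM side must be 3prime or 5prime, got {self.side!r}")
        if not self.motif or not set(self.motif) <= _DNA:
            raise SpacerError(f"PAM motif must be non-empty over ACGT, got {self.motif!r}")


def size_filter(reads: list[AmpliconRead],
                ranges: dict[str, tuple[int, int]] | None = None) -> list[AmpliconRead]:
    """Retain reads whose length falls inside the locus-specific window
    (inclusive bounds); input order is preserved."""
    ranges = ranges if ranges is not None else SIZE_RANGES
    out = []
    for read in reads:
        if read.locus not in ranges:
            raise SpacerError(f"unknown locus {read.locus!r} on read {read.id!r}")
        lo, hi = ranges[read.locus]
        if lo <= len(read.sequence) <= hi:
            out.append(read)
    return out


def _hamming_hits(seq: str, repeat: str, max_mismatches: int) -> list[int]:
    """Start positions of repeat occurrences with <= max_mismatches
    substitutions, scanned left to right without overlaps."""
    k = len(repeat)
    hits = []
    i = 0
    n = len(seq)
    while i + k <= n:
        mm = 0
        for x, y in zip(seq[i:i + k], repeat):
            if x != y:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            hits.append(i)
            i += k            # repeats cannot overlap
        else:
            i += 1
    return hits


def extract_spacers(read: AmpliconRead, repeat: str,
                    max_mismatches: int = 2) -> list[Spacer]:
    """Extract inter-repeat segments from a read in 5'->3' order.

    Repeat occurrences are located allowing up to ``max_mismatches``
    substitutions. Non-empty segments before the first or after the last
    repeat are returned flagged ``partial``. A read with no repeat hit yields
    an empty list.
    """
    if len(repeat) < 8:
        raise SpacerError(f"repeat too short ({len(repeat)} nt); need >= 8")
    if len(set(repeat)) == 1:
        logger.warning("degenerate homopolymer repeat %r", repeat)
    hits = _hamming_hits(read.sequence, repeat, max_mismatches)
    if not hits:
        return []
    k = len(repeat)
    spacers = []
    lead = read.sequence[: hits[0]]
    if lead:
        spacers.append(Spacer(lead, read.id, read.locus, partial=True))
    for h0, h1 in zip(hits, hits[1:]):
        seg = read.sequence[h0 + k: h1]
        if seg:
            spacers.append(Spacer(seg, read.id, read.locus))
    tail = read.sequence[hits[-1] + k:]
    if tail:
        spacers.append(Spacer(tail, read.id, read.locus, partial=True))
    return spacers


def edit_distance(s1: str, s2: str, k: int = -1) -> int:
    """Levenshtein distance via edlib; returns -1 if the distance exceeds k."""
    return edlib.align(s1, s2, task="distance", k=k)["editDistance"]


def swarm_cluster(variants: dict[str, int], d: int = 1) -> list[Cluster]:
    """Single-linkage agglomeration of dereplicated variants at edit distance d.

    Clusters are grown greedily from the most abundant unassigned seed
    (ties broken by lexicographically smallest sequence), absorbing any
    variant within edit distance ``d`` of any current member; the result is
    the connected components of the <=d-edit graph. Centroid = highest-count
    member, ties to the lexicographically smallest. Clusters are returned by
    decreasing total abundance (ties by centroid).
    """
    if d < 1:
        raise SpacerError(f"d must be >= 1, got {d}")
    seqs = list(variants)
    if len(seqs) != len(set(seqs)):
        raise SpacerError("variants must be dereplicated (unique sequences)")
    order = sorted(seqs, key=lambda s: (-variants[s], s))
    # index variants by length; edit distance <= d implies |len1 - len2| <= d
    by_len: dict[int, list[str]] = defaultdict(list)
    for s in order:
        by_len[len(s)].append(s)
    unassigned = set(seqs)
    clusters = []
    for seed in order:
        if seed not in unassigned:
            continue
        unassigned.discard(seed)
        members = [seed]
        frontier = [seed]
        while frontier:
            nxt = []
            for m in frontier:
                for ln in range(len(m) - d, len(m) + d + 1):
                    for cand in by_len.get(ln, ()):
                        if cand in unassigned and edit_distance(m, cand, k=d) >= 0:
                            unassigned.discard(cand)
                            members.append(cand)
                            nxt.append(cand)
            frontier = nxt
        centroid = min(members, key=lambda s: (-variants[s], s))
        clusters.append(Cluster(centroid=centroid,
                                members={s: variants[s] for s in members}))
    clusters.sort(key=lambda c: (-c.total, c.centroid))
    return clusters


def filter_clusters(clusters: list[Cluster], min_size: int = 2) -> list[Cluster]:
    """Drop clusters whose total abundance is below ``min_size`` (default 2:
    singleton clusters are removed)."""
    if min_size < 1:
        raise SpacerError(f"min_size must be >= 1, got {min_size}")
    kept = [c for c in clusters if c.total >= min_size]
    removed = sum(c.total for c in clusters) - sum(c.total for c in kept)
    if removed:
        logger.info("cluster size filter removed %d reads in %d clusters",
                    removed, len(clusters) - len(kept))
    return kept


def global_identity(seq: str, ref: str) -> float:
    """Identity over the full global alignment length, as matches / columns."""
    res = edlib.align(seq, ref, mode="NW", task="distance")
    length = max(len(seq), len(ref))
    return 1.0 - res["editDistance"] / length


def assign_abundance(sequences: list[tuple[str, str, int]],
                     centroids: list[str],
                     min_identity: float = 0.99) -> pd.DataFrame:
    """Assign (sequence, sample, count) triples to the best-matching centroid.

    Each sequence goes to the centroid with the highest full-length global
    identity, provided it reaches ``min_identity``; ties go to the centroid
    listed first (centroids are expected in decreasing abundance order).
    Unassignable sequences are accumulated in an ``"unassigned"`` row.
    Returns a clusters x samples count table.
    """
    if not centroids:
        raise SpacerError("no centroids to assign against")
    if not 0.0 < min_identity <= 1.0:
        raise SpacerError(f"min_identity must lie in (0, 1], got {min_identity}")
    samples = sorted({s for _, s, _ in sequences})
    index = centroids + ["unassigned"]
    table = pd.DataFrame(0, index=pd.Index(index, name="cluster"), columns=samples,
                         dtype=int)
    exact = {}
    for cen in centroids:              # first occurrence wins (most abundant)
        exact.setdefault(cen, cen)
    cache: dict[str, str | None] = {}
    for seq, sample, count in sequences:
        if seq not in cache:
            if seq in exact:
                cache[seq] = exact[seq]
            else:
                best, best_ident = None, min_identity
                for cen in centroids:
                    length = max(len(seq), len(cen))
                    k_max = int((1.0 - min_identity) * length)
                    dist = edit_distance(seq, cen, k=k_max) if k_max >= 0 else -1
                    if dist < 0:
                        continue
                    ident = 1.0 - dist / length
                    if ident > best_ident or (best is None and ident >= best_ident):
                        best, best_ident = cen, ident
                cache[seq] = best
        target = cache[seq] if cache[seq] is not None else "unassigned"
        table.loc[target, sample] += count
    return table


def classify_spacer(spacer: str,
                    phage_genome: str,
                    host_genome: str,
                    pam_rule: PamRule | None = None,
                    count: int = 0,
                    sample: str = "") -> SpacerRecord:
    """Locate a spacer's protospacer by exact match and classify its PAM.

    The spacer and its reverse complement are searched in the phage genome
    first, then the host genome. On a hit, the PAM bases are read at the
    configured side of the protospacer *on the protospacer strand* and
    labelled canonical iff they equal the configured motif. Multiple hits are
    resolved to the one nearest the priming site (logged). No hit in either
    genome gives target="unknown", pam="NA".
    """
    pam_rule = pam_rule if pam_rule is not None else PamRule()
    if not phage_genome or not host_genome:
        raise SpacerError("genomes must be non-empty")
    if len(spacer) < 15:
        raise SpacerError(f"spacer of {len(spacer)} nt is too short to map unambiguously")
    for target, genome in (("phage", phage_genome), ("host", host_genome)):
        hits = _exact_hits(spacer, genome)
        if hits:
            if len(hits) > 1:
                logger.info("spacer maps to %d sites in %s genome; "
                            "keeping the one nearest position %d",
                            len(hits), target, pam_rule.priming_center)
            start, strand = min(
                hits, key=lambda h: (abs(h[0] - pam_rule.priming_center), h[1]))
            pam = _read_pam(genome, start, start + len(spacer), strand, pam_rule)
            label = "canonical" if pam == pam_rule.motif else "non-canonical"
            return SpacerRecord(sequence=spacer, target=target, pam=label,
                                coordinate=start, strand=strand,
                                count=count, sample=sample)
    return SpacerRecord(sequence=spacer, target="unknown", pam="NA",
                        coordinate=-1, strand=".", count=count, sample=sample)


def _exact_hits(spacer: str, genome: str) -> list[tuple[int, str]]:
    """All exact matches of spacer or its reverse complement: (start, strand)."""
    rc = str(Seq(spacer).reverse_complement())
    hits = []
    for query, strand in ((spacer, "+"), (rc, "-")):
        i = genome.find(query)
        while i != -1:
            hits.append((i, strand))
            i = genome.find(query, i + 1)
    if spacer == rc:       # palindromic: deduplicate
        hits = sorted(set(hits))
    return hits


def _read_pam(genome: str, start: int, end: int, strand: str, rule: PamRule) -> str:
    """Bases at the PAM side of the protospacer, reported on the protospacer
    strand; empty string if the window runs off the genome."""
    k = len(rule.motif)
    want_downstream = (rule.side == "3prime") == (strand == "+")
    if want_downstream:
        window = genome[end: end + k]
    else:
        window = genome[max(start - k, 0): start]
    if len(window) < k:
        return ""
    return window if strand == "+" else str(Seq(window).reverse_complement())


def read_amplicon_fasta(path) -> list[AmpliconRead]:
    """Read merged amplicons; sample and locus are parsed from header fields
    ``sample=...;locus=...``."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(part.split("=", 1) for part in rec.description.split()[-1].split(";")
                      if "=" in part)
        if "sample" not in fields or "locus" not in fields:
            raise SpacerError(f"header of {rec.id!r} lacks sample=...;locus=... fields")
        reads.append(AmpliconRead(id=rec.id, sequence=str(rec.seq).upper(),
                                  sample=fields["sample"], locus=fields["locus"]))
    return reads


def write_centroid_fasta(clusters: list[Cluster], path) -> None:
    """Write cluster centroids; the header carries the total cluster count."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            fh.write(f">cluster_{i};size={c.total}\n{c.centroid}\n")
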