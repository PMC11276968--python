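"""Core k-mer identification and approximate multi-genome mapping.

The discovery pipeline's first two stages: (i) exact canonical k-mer hashing
across genomes to find "core" k-mers present in at least a threshold fraction
of species, and (ii) mapping every position at which a core k-mer occurs in
each genome within a mismatch budget derived from the identity threshold.

Approximate mapping is exact under the gapless (substitution-only) model: the
k-mer is split into m+1 disjoint seeds, at least one of which must occur
exactly in any window with <= m substitutions (pigeonhole), and candidate
windows are verified by Hamming count.
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Iterable, Mapping

log = logging.getLogger("ucekit.kmer_core")

__all__ = [
    "revcomp",
    "canonical",
    "mismatch_budget",
    "KmerIndex",
    "CoreKmer",
    "KmerHit",
    "SeedIndex",
    "build_index",
    "select_core_kmers",
    "map_kmer_approx",
    "map_core_kmers",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    return seq.translate(_RC)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def mismatch_budget(length: int, min_identity: float) -> int:
    """Largest substitution count m with (length - m)/length >= min_identity.

    Equivalent to floor((1 - min_identity) * length); a small epsilon guards
    against binary-float artifacts on exact rational thresholds.
    """
    return int(math.floor((1.0 - min_identity) * length + 1e-9))


# KmerHit.strand is relative to the k-mer as queried: '+' means the genome
# window equals the query orientation.
KmerHit = namedtuple("KmerHit", "seq_name start strand mismatches")


@dataclass
class KmerIndex:
    """Exact canonical k-mer occurrence counts per species.

    N-containing k-mers are never stored; both strands are represented via
    canonicalization, so a palindromic k-mer's forward and reverse occurrence
    coincide (counted once per genomic position).
    """

    k: int
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def species_presence(self, kmer: str) -> int:
        return len(self.counts.get(kmer, ()))

    def __len__(self) -> int:
        return len(self.counts)


def _iter_kmers(seq: str, k: int):
    """Yield (position, kmer) for every N-free k-length window."""
    last_n = -1
    n = len(seq)
    for j in range(min(k - 1, n)):
        if seq[j] == "N":
            last_n = j
    for i in range(n - k + 1):
        j = i + k - 1
        if seq[j] == "N":
            last_n = j
        if last_n < i:
            yield i, seq[i : i + k]


def build_index(genome_set, k: int = 50) -> KmerIndex:
    """Index the canonical N-free k-mers of every genome with per-species counts."""
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    index = KmerIndex(k=k)
    counts = index.counts
    any_window = False
    for sp in genome_set.species_ids:
        for seq in genome_set.sequences[sp].values():
            for _pos, kmer in _iter_kmers(seq, k):
                any_window = True
                canon = canonical(kmer)
                per = counts.get(canon)
                if per is None:
                    counts[canon] = {sp: 1}
                else:
                    per[sp] = per.get(sp, 0) + 1
    if not any_window:
        log.warning("k=%d exceeds every sequence length; index is empty", k)
    return index


def species_quorum(fraction: float, n_species: int) -> int:
    """ceil(fraction * n_species), guarded against float artifacts."""
    return int(math.ceil(fraction * n_species - 1e-9))


def select_core_kmers(
    index: KmerIndex,
    n_species: int,
    core_fraction: float = 0.5,
    kmer_map_limit: int = 1000,
) -> dict[str, int]:
    """Candidate core k-mers: present exactly in >= ceil(core_fraction * Y)
    genomes and with <= kmer_map_limit exact occurrences in every genome.

    Returns {canonical k-mer: number of species with an exact occurrence}.
    """
    if not 0 < core_fraction <= 1:
        raise ValueError(f"core_fraction must be in (0, 1], got {core_fraction}")
    if kmer_map_limit < 1:
        raise ValueError(f"kmer_map_limit must be >= 1, got {kmer_map_limit}")
    need = species_quorum(core_fraction, n_species)
    out: dict[str, int] = {}
    for kmer, per in index.counts.items():
        if len(per) >= need and max(per.values()) <= kmer_map_limit:
            out[kmer] = len(per)
    return out


class SeedIndex:
    """Exact-substring index of one genome used for pigeonhole candidate lookup.

    Maps every N-free substring of length ``seed_len`` to its (seq_name,
    position) occurrences on the forward strand.
    """

    def __init__(self, sequences: Mapping[str, str], seed_len: int):
        self.seed_len = seed_len
        self.positions: dict[str, list[tuple[str, int]]] = {}
        add = self.positions.setdefault
        for name, seq in sequences.items():
            for pos, sub in _iter_kmers(seq, seed_len):
                add(sub, []).append((name, pos))


def _hamming_within(a: str, b: str, budget: int) -> int:
    """Mismatch count between equal-length strings, or -1 once it exceeds budget."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return -1
    return mism


def map_kmer_approx(
    kmer: str,
    sequences: Mapping[str, str],
    min_identity: float,
    kmer_map_limit: int | None = None,
    seed_index: SeedIndex | None = None,
) -> list[KmerHit] | None:
    """Every position (either strand) where a genome window of length k
    differs from ``kmer`` in at most floor((1-p)*k) substitutions.

    Windows containing N are ineligible.  Returns None when the genome holds
    more than ``kmer_map_limit`` hits (the k-mer is discarded as repetitive).
    """
    k = len(kmer)
    m = mismatch_budget(k, min_identity)
    n_seeds = m + 1
    seed_len = k // n_seeds
    if seed_index is None:
        seed_index = SeedIndex(sequences, seed_len)
    elif seed_index.seed_len != seed_len:
        raise ValueError(
            f"seed index built for length {seed_index.seed_len}, need {seed_len}"
        )
    found: dict[tuple[str, int, str], int] = {}
    for query, strand in ((kmer, "+"), (revcomp(kmer), "-")):
        for chunk in range(n_seeds):
            off = chunk * seed_len
            for seq_name, pos in seed_index.positions.get(
                query[off : off + seed_len], ()
            ):
                start = pos - off
                if start < 0:
                    continue
                seq = sequences[seq_name]
                if start + k > len(seq):
                    continue
                key = (seq_name, start, strand)
                if key in found:
                    continue
                window = seq[start : start + k]
                if "N" in window:
                    continue
                mism = _hamming_within(query, window, m)
                if mism >= 0:
                    found[key] = mism
    hits = sorted(
        KmerHit(sn, st, sd, mm) for (sn, st, sd), mm in found.items()
    )
    if kmer_map_limit is not None and len(hits) > kmer_map_limit:
        return None
    return hits


@dataclass
class CoreKmer:
    """A selected core k-mer with its approximate hits in every genome."""

    sequence: str  # canonical
    species_presence: int
    hits: dict[str, list[KmerHit]] = field(default_factory=dict)


def write_core_kmer_tsv(core_kmers: Iterable["CoreKmer"], path) -> None:
    """Dump mapped core k-mers as TSV: kmer, n_species, total_hits."""
    with open(path, "w") as fh:
        fh.write("kmer\tn_species\ttotal_hits\n")
        for ck in core_kmers:
            total = sum(len(h) for h in ck.hits.values())
            fh.write(f"{ck.sequence}\t{ck.species_presence}\t{total}\n")


def map_core_kmers(
    core: Mapping[str, int],
    genome_set,
    min_identity: float,
    kmer_map_limit: int = 1000,
    seed_cache: dict | None = None,
) -> list[CoreKmer]:
    """Map every candidate core k-mer into every genome; k-mers exceeding the
    per-genome hit cap in any genome are dropped.

    ``seed_cache`` (optional) memoizes per-species seed indexes across calls
    with different identity thresholds.
    """
    if not core:
        return []
    k = len(next(iter(core)))
    seed_len = k // (mismatch_budget(k, min_identity) + 1)
    seed_indexes = {}
    for sp in genome_set.species_ids:
        key = (sp, seed_len)
        if seed_cache is not None and key in seed_cache:
            seed_indexes[sp] = seed_cache[key]
        else:
            seed_indexes[sp] = SeedIndex(genome_set.sequences[sp], seed_len)
            if seed_cache is not None:
                seed_cache[key] = seed_indexes[sp]
    out: list[CoreKmer] = []
    n_dropped = 0
    for kmer in sorted(core):
        record = CoreKmer(sequence=kmer, species_presence=core[kmer])
        for sp in genome_set.species_ids:
            hits = map_kmer_approx(
                kmer,
                genome_set.sequences[sp],
                min_identity,
                kmer_map_limit=kmer_map_limit,
                seed_index=seed_indexes[sp],
            )
            if hits is None:
                record = None
                n_dropped += 1
                break
            if hits:
                record.hits[sp] = hits
        if record is not None:
            out.append(record)
    if n_dropped:
        log.info("dropped %d core k-mers exceeding the per-genome map limit", n_dropped)
    return out
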