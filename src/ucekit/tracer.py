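"""Tracing UCE (or control) sequences into arbitrary target genomes.

Queries are mapped with a glocal aligner — global in the query, local in the
target — implemented as ends-free-in-target global affine-gap dynamic
programming over both strands of every target sequence.  The single best hit
per (query, genome) is kept by bit-score, then filtered by the standard
criteria (aligned length >= 30, E-value <= 0.01) and summarized per species
with a 70% identity cutoff for counting detections.

Bit-scores and E-values use ungapped Karlin-Altschul statistics computed
numerically from the match/mismatch scores and the target base composition,
applied to the gapped score as an approximation; the downstream filters
dominate behaviour, so approximate statistics suffice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from scipy.optimize import brentq

from .genome_io import GeneModel, GenomeSet, Interval
from .kmer_core import revcomp

__all__ = [
    "ScoringScheme",
    "KarlinAltschul",
    "AlignmentHit",
    "TraceSummary",
    "align_glocal",
    "trace",
    "filter_hits",
    "count_detected",
    "sample_control_cds",
    "flank_profile",
]


@dataclass(frozen=True)
class ScoringScheme:
    """DNA alignment scores; a gap of length l costs open + (l-1) * extend."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -12
    gap_extend: int = -4


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class KarlinAltschul:
    """Ungapped Karlin-Altschul parameters lambda, K and relative entropy H."""

    lam: float
    K: float
    H: float

    @classmethod
    def from_scores(
        cls, match: int, mismatch: int, base_freqs: Sequence[float] | None = None
    ) -> "KarlinAltschul":
        """Solve sum p_s e^(lambda s) = 1 and evaluate K by the classical
        lattice series sigma = sum_j (1/j)[P(S_j >= 0) + E(e^(lambda S_j);
        S_j < 0)], K = d lambda e^(-2 sigma) / (H (1 - e^(-lambda d))) with
        d the lattice span (gcd) of the achievable scores."""
        freqs = list(base_freqs) if base_freqs is not None else [0.25] * 4
        total = sum(freqs)
        freqs = [f / total for f in freqs]
        probs: dict[int, float] = {}
        for i, fi in enumerate(freqs):
            for j, fj in enumerate(freqs):
                s = match if i == j else mismatch
                probs[s] = probs.get(s, 0.0) + fi * fj
        scores = sorted(probs)
        mean = sum(s * probs[s] for s in scores)
        if mean >= 0 or scores[-1] <= 0:
            raise ValueError(
                "scoring must have negative expectation and a positive score"
            )
        lam = brentq(
            lambda x: sum(probs[s] * math.exp(x * s) for s in scores) - 1.0,
            1e-9,
            20.0,
            xtol=1e-14,
        )
        H = lam * sum(s * probs[s] * math.exp(lam * s) for s in scores)
        d = 0
        for s in scores:
            d = math.gcd(d, abs(s))
        lo, hi = scores[0], scores[-1]
        step = np.zeros(hi - lo + 1)
        for s in scores:
            step[s - lo] = probs[s]
        cur = np.array([1.0])
        cur_off = 0
        sigma = 0.0
        for j in range(1, 61):
            cur = np.convolve(cur, step)
            cur_off += lo
            vals = cur_off + np.arange(len(cur))
            neg = vals < 0
            sigma += (
                cur[~neg].sum() + (cur[neg] * np.exp(lam * vals[neg])).sum()
            ) / j
        K = d * lam * math.exp(-2 * sigma) / (H * (1 - math.exp(-lam * d)))
        return cls(lam=lam, K=K, H=H)

    def bit_score(self, score: float) -> float:
        return (self.lam * score - math.log(self.K)) / math.log(2)

    def evalue(self, score: float, query_len: int, target_len: int) -> float:
        exponent = min(-self.lam * score, 700.0)  # clamp against overflow
        return self.K * query_len * target_len * math.exp(exponent)


@dataclass(frozen=True)
class AlignmentHit:
    """One glocal alignment of a query onto a target genome.

    ``aligned_length`` counts alignment columns including gap columns;
    identity = matches / aligned_length.
    """

    query_id: str
    species: str
    seq_name: str
    start: int
    end: int
    strand: str
    aligned_length: int
    matches: int
    score: float
    bit_score: float
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    # fit alignment: target overhangs pair with free gaps in the query row,
    # so the query aligns globally inside a local stretch of the target
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


def genome_base_freqs(genome: Mapping[str, str]) -> list[float]:
    counts = {b: 0 for b in "ACGT"}
    for seq in genome.values():
        for b in "ACGT":
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        return [0.25] * 4
    return [counts[b] / total for b in "ACGT"]


def _alignment_stats(alignment, tseq: str, qseq: str) -> tuple[int, int, int, int]:
    """(t_begin, t_end, columns, matches) for the query-spanning region."""
    t_blocks, q_blocks = alignment.aligned
    t_begin, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q_begin, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    block_cols = 0
    matches = 0
    for (tb0, tb1), (qb0, qb1) in zip(t_blocks, q_blocks):
        block_cols += tb1 - tb0
        matches += sum(
            1 for a, b in zip(tseq[tb0:tb1], qseq[qb0:qb1]) if a == b
        )
    columns = (
        block_cols
        + (t_end - t_begin - block_cols)
        + (q_end - q_begin - block_cols)
    )
    return t_begin, t_end, columns, matches


def align_glocal(
    query: str,
    target_genome: Mapping[str, str],
    query_id: str = "query",
    species: str = "target",
    scheme: ScoringScheme = DEFAULT_SCHEME,
    ka: KarlinAltschul | None = None,
) -> AlignmentHit | None:
    """Best glocal hit of ``query`` on either strand of any target sequence,
    by bit-score; ties break by longer alignment, lowest target coordinate,
    then '+' strand.  Returns None for an empty target."""
    if not query:
        raise ValueError("empty query")
    sequences = {name: seq for name, seq in target_genome.items() if seq}
    if not sequences:
        return None
    if ka is None:
        ka = KarlinAltschul.from_scores(
            scheme.match, scheme.mismatch, genome_base_freqs(sequences)
        )
    aligner = _make_aligner(scheme)
    n_total = sum(len(s) for s in sequences.values())

    scored: list[tuple[float, str, str, str]] = []
    for seq_name in sorted(sequences):
        tseq = sequences[seq_name]
        for strand, q in (("+", query), ("-", revcomp(query))):
            scored.append((aligner.score(tseq, q), seq_name, strand, q))
    best_score = max(s[0] for s in scored)

    best: tuple | None = None
    for score, seq_name, strand, q in scored:
        if score != best_score:
            continue
        aln = aligner.align(sequences[seq_name], q)[0]
        t0, t1, columns, matches = _alignment_stats(aln, sequences[seq_name], q)
        rank = (-columns, t0, 0 if strand == "+" else 1, seq_name)
        if best is None or rank < best[0]:
            best = (rank, score, seq_name, strand, t0, t1, columns, matches)
    _rank, score, seq_name, strand, t0, t1, columns, matches = best
    return AlignmentHit(
        query_id=query_id,
        species=species,
        seq_name=seq_name,
        start=t0,
        end=t1,
        strand=strand,
        aligned_length=columns,
        matches=matches,
        score=score,
        bit_score=ka.bit_score(score),
        evalue=ka.evalue(score, len(query), n_total),
    )


def trace(
    queries: Mapping[str, str],
    targets: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[AlignmentHit]:
    """Best hit of every query in every target genome (unfiltered)."""
    hits: list[AlignmentHit] = []
    for species in sorted(targets):
        genome = targets[species]
        ka = KarlinAltschul.from_scores(
            scheme.match, scheme.mismatch, genome_base_freqs(genome)
        )
        for qid in sorted(queries):
            hit = align_glocal(
                queries[qid], genome, query_id=qid, species=species,
                scheme=scheme, ka=ka,
            )
            if hit is not None:
                hits.append(hit)
    return hits


def filter_hits(
    hits: Sequence[AlignmentHit],
    min_len: int = 30,
    max_evalue: float = 0.01,
) -> list[AlignmentHit]:
    """Drop hits with aligned_length < min_len or E-value > max_evalue."""
    return [
        h for h in hits if h.aligned_length >= min_len and h.evalue <= max_evalue
    ]


@dataclass
class TraceSummary:
    species: str
    n_queries: int
    n_detected: int
    mean_identity: float | None
    min_identity: float | None
    max_identity: float | None


def count_detected(
    hits: Sequence[AlignmentHit],
    n_queries: int,
    identity_cutoff: float = 0.70,
) -> dict[str, TraceSummary]:
    """Per-species detection counts (identity >= cutoff) and identity
    summaries over all retained hits.

    Detection counting and identity summaries are filtered separately:
    a hit below the cutoff still contributes to the mean identity.
    """
    by_species: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_species.setdefault(h.species, []).append(h)
    out: dict[str, TraceSummary] = {}
    for sp, sp_hits in sorted(by_species.items()):
        idents = [h.identity for h in sp_hits]
        out[sp] = TraceSummary(
            species=sp,
            n_queries=n_queries,
            n_detected=sum(1 for h in sp_hits if h.identity >= identity_cutoff),
            mean_identity=sum(idents) / len(idents) if idents else None,
            min_identity=min(idents) if idents else None,
            max_identity=max(idents) if idents else None,
        )
    return out


def sample_control_cds(
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
    n: int,
    min_len: int = 100,
    max_len: int = 1300,
    seed: int = 0,
) -> dict[str, str]:
    """Uniform sample (without replacement) of n CDS sequences with length in
    [min_len, max_len], as a size-matched protein-coding control set."""
    eligible: list[tuple[str, Interval]] = []
    for gm in gene_models:
        if gm.biotype != "protein_coding":
            continue
        for iv in gm.cds:
            if min_len <= len(iv) <= max_len:
                eligible.append((gm.gene_id, iv))
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible CDS intervals, need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    out: dict[str, str] = {}
    for idx in sorted(int(i) for i in chosen):
        gene_id, iv = eligible[idx]
        seq = reference[iv.seq_name][iv.start : iv.end]
        out[f"cds_{gene_id}_{iv.start}"] = seq
    return out


def flank_profile(
    uces: Sequence,
    genome_set: GenomeSet,
    flank_bp: int,
) -> dict[int, float]:
    """Mean cross-species gapless identity per position offset relative to
    each element start, over [-flank_bp, length + flank_bp).

    For every (element, species) pair the best gapless diagonal over the
    element core is chosen, then extended into the flanks; offsets are pooled
    across elements (clipped at sequence ends).
    """
    from .uce_caller import CallerWorkspace

    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    intervals = [u.interval if hasattr(u, "interval") else u for u in uces]
    ws = CallerWorkspace(genome_set, seed_len=16, reach=max(flank_bp, 16) + 1)
    match_sum: dict[int, int] = {}
    pair_sum: dict[int, int] = {}
    for iv in intervals:
        diags = ws.diags.get(iv.seq_name, [])
        n_ref = len(genome_set.reference[iv.seq_name])
        for sp in genome_set.species_ids:
            if sp == genome_set.reference_id:
                continue
            best = None
            for dg in diags:
                if dg.species != sp or dg.lo > iv.start or dg.hi < iv.end:
                    continue
                mism = dg.mismatches(iv.start, iv.end)
                if best is None or mism < best[0]:
                    best = (mism, dg)
            if best is None:
                continue
            dg = best[1]
            lo = max(iv.start - flank_bp, dg.lo, 0)
            hi = min(iv.end + flank_bp, dg.hi, n_ref)
            for pos in range(lo, hi):
                off = pos - iv.start
                mism = dg.mismatches(pos, pos + 1)
                match_sum[off] = match_sum.get(off, 0) + (1 - mism)
                pair_sum[off] = pair_sum.get(off, 0) + 1
    return {
        off: match_sum[off] / pair_sum[off] for off in sorted(pair_sum)
    }
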