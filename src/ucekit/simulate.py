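"""Synthetic multi-species genome sets with implanted conserved elements.

The generator emulates the structure a desk-scale conserved-element study
needs: i.i.d. background per species (so all cross-species conservation is
attributable to implants), elements copied from the reference into every
species with Bernoulli substitutions at per-species rates, moderately
diverged flanks around each element core, one high-copy element in a single
host species to exercise repetitive-sequence caps, and an exact record of
every realized copy as ground truth.

The module also provides the brute-force oracle UCE finder used for
exact-equivalence testing of the staged discovery pipeline: by exhaustive
enumeration over every reference window start, a reference base is output
iff it lies in some window of length >= L for which at least ceil(f*Y)
species (reference included) hold a gapless match at identity >= p on either
strand and whose sequence occurs at most multimap_cap times per genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GeneModel, GenomeSet, Interval, merge_intervals
from .uce_caller import UCEParams

__all__ = [
    "SimConfig",
    "SpeciesCopy",
    "ElementTruth",
    "TruthSet",
    "simulate_genomes",
    "oracle_find_uces",
    "OraclePrep",
    "demo_gene_models",
]

_BASES = "ACGT"
_MIN_GAP = 60  # shortest background stretch between implants


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic genome set.

    Per-species element substitution rates cycle through
    ``substitution_rates`` (defaults span realized identities of roughly
    98.4-99.6%, the range reported for placental-mammal UCE remapping).
    ``flank_divergence`` applies to the flanks copied along with each core,
    so element cores are sharply more conserved than their context.
    """

    seed: int
    n_species: int = 6
    genome_length: int = 80_000
    n_elements: int = 24
    element_length_range: tuple[int, int] = (150, 300)
    substitution_rates: tuple[float, ...] = (0.004, 0.008, 0.012, 0.016)
    gc_content: float = 0.5
    flank_length: int = 50
    flank_divergence: float = 0.10
    element_indel_rate: float = 0.0
    n_repeat_copies: int = 150

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_species < 2 or self.n_elements < 1:
            raise ValueError("need >= 2 species and >= 1 element")
        lo, hi = self.element_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad element length range {self.element_length_range}")
        for r in (*self.substitution_rates, self.flank_divergence,
                  self.element_indel_rate, self.gc_content):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.genome_length < 1 or self.flank_length < 0:
            raise ValueError("lengths must be positive")
        if self.n_repeat_copies < 1:
            raise ValueError("n_repeat_copies must be >= 1")


@dataclass
class SpeciesCopy:
    """One realized copy of an element core in one species."""

    interval: Interval
    substitutions: int
    indels: int
    length: int

    def identity(self) -> float:
        return 1.0 - self.substitutions / self.length


@dataclass
class ElementTruth:
    element_id: int
    length: int
    is_repeat: bool
    ref_interval: Interval  # core on the reference
    ref_outer: Interval  # core plus flanks on the reference
    species: dict[str, SpeciesCopy] = field(default_factory=dict)
    repeat_copy_intervals: list[Interval] = field(default_factory=list)

    def n_passing(self, params: UCEParams) -> int:
        """Species (reference included) whose realized copy meets the
        identity threshold over the full core (gapless copies only)."""
        budget = params.budget(self.length)
        n = 1  # the reference copy is exact
        for copy in self.species.values():
            if copy.indels == 0 and copy.substitutions <= budget:
                n += 1
        return n

    def passes(self, params: UCEParams, n_species: int) -> bool:
        return (
            self.length >= params.min_length
            and self.n_passing(params) >= params.quorum(n_species)
        )


@dataclass
class TruthSet:
    config: SimConfig
    elements: list[ElementTruth]
    repeat_host: str | None

    def passing_elements(self, params: UCEParams, n_species: int) -> list[ElementTruth]:
        return [e for e in self.elements if e.passes(params, n_species)]

    def implant_intervals(self) -> list[Interval]:
        """Reference intervals of all implanted loci, flanks included."""
        ivs = [e.ref_outer for e in self.elements]
        return merge_intervals(ivs)


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=n, p=p)
    return "".join(_BASES[c] for c in codes)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Bernoulli substitutions at ``rate``; a substituted base always differs."""
    if rate == 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = {ord(b): i for i, b in enumerate(_BASES)}
    mask = rng.random(len(seq)) < rate
    positions = np.nonzero(mask)[0]
    if positions.size:
        offsets = rng.integers(1, 4, size=positions.size)
        for pos, off in zip(positions, offsets):
            arr[pos] = ord(_BASES[(idx[arr[pos]] + off) % 4])
    return arr.tobytes().decode(), int(positions.size)


def _apply_indels(
    rng: np.random.Generator, seq: str, rate: float, gc: float
) -> tuple[str, int]:
    """Insert or delete 1-3 bases at Bernoulli-chosen positions."""
    if rate == 0:
        return seq, 0
    out: list[str] = []
    n_events = 0
    i = 0
    while i < len(seq):
        if rng.random() < rate:
            n_events += 1
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                i += size  # deletion
                continue
            out.append(_rand_seq(rng, size, gc))  # insertion
        out.append(seq[i])
        i += 1
    return "".join(out), n_events


def simulate_genomes(config: SimConfig) -> tuple[GenomeSet, TruthSet]:
    """Generate a genome set plus exact ground truth under ``config``.

    Element 0 is the repeat element: beyond its ordinary copy in every
    species, ``n_repeat_copies - 1`` extra exact copies of its whole unit
    (flanks included, so flank-extended windows stay repetitive too) are
    implanted into the first non-reference species.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.element_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_elements)
    if config.n_repeat_copies > 1:
        lengths[0] = lo  # keep the high-copy element compact
    cores = [_rand_seq(rng, int(ln), config.gc_content) for ln in lengths]
    flanks = [
        (
            _rand_seq(rng, config.flank_length, config.gc_content),
            _rand_seq(rng, config.flank_length, config.gc_content),
        )
        for _ in range(config.n_elements)
    ]

    species_ids = ["ref"] + [f"sp{i:02d}" for i in range(1, config.n_species)]
    repeat_host = species_ids[1] if config.n_repeat_copies > 1 else None
    rates = {
        sp: config.substitution_rates[i % len(config.substitution_rates)]
        for i, sp in enumerate(species_ids[1:])
    }

    normal_unit_len = sum(
        len(cores[e]) + 2 * config.flank_length for e in range(config.n_elements)
    )
    background_total = config.genome_length - normal_unit_len
    n_gaps_min = config.n_elements + 1
    if background_total < n_gaps_min * _MIN_GAP:
        raise ValueError(
            f"cannot place {config.n_elements} elements "
            f"({normal_unit_len} bp) in a {config.genome_length} bp genome "
            "without overlap"
        )

    elements = [
        ElementTruth(
            element_id=e,
            length=len(cores[e]),
            is_repeat=(e == 0 and config.n_repeat_copies > 1),
            ref_interval=Interval("chr1", 0, 1),  # placeholder, set below
            ref_outer=Interval("chr1", 0, 1),
        )
        for e in range(config.n_elements)
    ]

    sequences: dict[str, dict[str, str]] = {}
    for sp in species_ids:
        # build this species' implant units
        items: list[tuple] = []  # (kind, elem_id, unit, core_off, core_len, subs, ind)
        for e in range(config.n_elements):
            fl, fr = flanks[e]
            if sp == "ref":
                unit = fl + cores[e] + fr
                items.append(("elem", e, unit, len(fl), len(cores[e]), 0, 0))
            else:
                fl_c, _ = _mutate(rng, fl, config.flank_divergence)
                fr_c, _ = _mutate(rng, fr, config.flank_divergence)
                core_c, subs = _mutate(rng, cores[e], rates[sp])
                ind = 0
                if config.element_indel_rate:
                    fl_c, _ = _apply_indels(
                        rng, fl_c, config.element_indel_rate, config.gc_content
                    )
                    core_c, ind = _apply_indels(
                        rng, core_c, config.element_indel_rate, config.gc_content
                    )
                items.append(
                    ("elem", e, fl_c + core_c + fr_c, len(fl_c), len(core_c), subs, ind)
                )
        if sp == repeat_host:
            fl0, fr0 = flanks[0]
            unit0 = fl0 + cores[0] + fr0  # exact copy of the reference unit
            for j in range(config.n_repeat_copies - 1):
                items.append(("repeat", 0, unit0, len(fl0), len(cores[0]), 0, 0))
        order = rng.permutation(len(items))
        items = [items[i] for i in order]

        n_gaps = len(items) + 1
        spare = background_total - n_gaps * _MIN_GAP
        parts = rng.multinomial(spare, [1.0 / n_gaps] * n_gaps)
        gap_sizes = [int(_MIN_GAP + p) for p in parts]

        chunks: list[str] = []
        pos = 0
        for gi, item in enumerate(items):
            gap = _rand_seq(rng, gap_sizes[gi], config.gc_content)
            chunks.append(gap)
            pos += len(gap)
            kind, e, unit, core_off, core_len, subs, ind = item
            core_iv = Interval("chr1", pos + core_off, pos + core_off + core_len)
            if kind == "elem":
                if sp == "ref":
                    elements[e].ref_interval = core_iv
                    elements[e].ref_outer = Interval("chr1", pos, pos + len(unit))
                else:
                    elements[e].species[sp] = SpeciesCopy(
                        interval=core_iv,
                        substitutions=subs,
                        indels=ind,
                        length=core_len,
                    )
            else:
                elements[0].repeat_copy_intervals.append(core_iv)
            chunks.append(unit)
            pos += len(unit)
        chunks.append(_rand_seq(rng, gap_sizes[-1], config.gc_content))
        sequences[sp] = {"chr1": "".join(chunks)}

    genome_set = GenomeSet(
        species_ids=species_ids, sequences=sequences, reference_id="ref"
    )
    truth = TruthSet(config=config, elements=elements, repeat_host=repeat_host)
    return genome_set, truth


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_SIZE_GUARD = 1_000_000  # aggregate bases the quadratic scan will accept
_N_BYTE = ord("N")
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class _OracleDiag:
    __slots__ = ("species", "lo", "hi", "cum")

    def __init__(self, species, lo, hi, cum):
        self.species = species
        self.lo = lo
        self.hi = hi
        self.cum = cum


class OraclePrep:
    """Identity-independent precomputation for the oracle: every gapless
    diagonal between the reference and any oriented genome sequence sharing
    an exact seed of ``seed_len`` bases, with cumulative mismatch arrays.

    Reusable across parameter settings whose pigeonhole-safe seed length is
    at least ``seed_len``.
    """

    def __init__(self, genome_set: GenomeSet, seed_len: int = 16, reach: int = 1000):
        self.seed_len = seed_len
        self.reach = reach
        self.genome_set = genome_set
        self.diags: dict[str, list[_OracleDiag]] = {}
        self.ncum: dict[str, np.ndarray] = {}
        g = seed_len
        ref = genome_set.reference
        lookup: dict[str, list[tuple[str, int]]] = {}
        ref_arr: dict[str, np.ndarray] = {}
        for rname, rseq in ref.items():
            arr = np.frombuffer(rseq.encode(), dtype=np.uint8)
            ref_arr[rname] = arr
            nc = np.zeros(len(rseq) + 1, dtype=np.int64)
            np.cumsum(arr == _N_BYTE, out=nc[1:])
            self.ncum[rname] = nc
            self.diags[rname] = []
            for i in range(len(rseq) - g + 1):
                sub = rseq[i : i + g]
                if "N" not in sub:
                    lookup.setdefault(sub, []).append((rname, i))
        hit_spans: dict[tuple, list[int]] = {}
        arrays: dict[tuple, np.ndarray] = {}
        for sp in genome_set.species_ids:
            for tname, tseq in genome_set.sequences[sp].items():
                for orient in "+-":
                    ts = tseq if orient == "+" else tseq.translate(_RC_TABLE)[::-1]
                    arrays[(sp, tname, orient)] = np.frombuffer(
                        ts.encode(), dtype=np.uint8
                    )
                    for j in range(len(ts) - g + 1):
                        lst = lookup.get(ts[j : j + g])
                        if not lst:
                            continue
                        for rname, i in lst:
                            key = (rname, sp, tname, orient, j - i)
                            span = hit_spans.get(key)
                            if span is None:
                                hit_spans[key] = [i, i]
                            else:
                                span[0] = min(span[0], i)
                                span[1] = max(span[1], i)
        for (rname, sp, tname, orient, d), (minh, maxh) in sorted(hit_spans.items()):
            rarr = ref_arr[rname]
            tarr = arrays[(sp, tname, orient)]
            lo = max(0, -d, minh - reach)
            hi = min(len(rarr), len(tarr) - d, maxh + g + reach)
            if hi - lo < g:
                continue
            tseg = tarr[lo + d : hi + d]
            mism = (rarr[lo:hi] != tseg) | (tseg == _N_BYTE)
            cum = np.zeros(hi - lo + 1, dtype=np.int64)
            np.cumsum(mism, out=cum[1:])
            self.diags[rname].append(_OracleDiag(sp, lo, hi, cum))


def _oracle_seed_len(p: float, L: int, wmax: int) -> int:
    """Pigeonhole-guaranteed exact-run length in any passing window."""
    best = None
    for w in range(L, wmax + 1):
        m = int(math.floor((1 - p) * w + 1e-9))
        run = -(-(w - m) // (m + 1))
        best = run if best is None else min(best, run)
    if best < 8:
        raise ValueError(f"identity {p} too low for exhaustive seeding")
    return min(16, best)


def _diag_feasible_starts(diag: _OracleDiag, p: float, L: int, wmax: int) -> np.ndarray:
    """Diag-local starts j admitting some window of length in [L, wmax] with
    mismatches <= floor((1-p) w): exists e in [j+L, j+wmax] with
    cum[e] - (1-p) e <= cum[j] - (1-p) j."""
    ln = diag.hi - diag.lo
    jmax = ln - L
    if jmax < 0:
        return np.zeros(0, dtype=bool)
    if diag.cum[-1] == 0:  # perfect diagonal (e.g. the reference onto itself)
        return np.ones(jmax + 1, dtype=bool)
    pref = diag.cum.astype(np.float64) - (1 - p) * np.arange(ln + 1)
    span = wmax - L + 1
    padded = np.concatenate([pref, np.full(span, np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, span)
    window_min = windows.min(axis=1)  # window_min[e0] = min pref[e0 : e0+span]
    return window_min[L : L + jmax + 1] <= pref[: jmax + 1] + 1e-6


def oracle_find_uces(
    genome_set: GenomeSet,
    params: UCEParams,
    prep: OraclePrep | None = None,
) -> list[Interval]:
    """Reference base set of all qualifying windows, by exhaustive
    enumeration over every window start (merged intervals)."""
    total = sum(genome_set.total_length(sp) for sp in genome_set.species_ids)
    if total > _SIZE_GUARD:
        raise ValueError(
            f"aggregate genome size {total} exceeds the oracle's "
            f"{_SIZE_GUARD} bp quadratic-scan guard"
        )
    L, wmax, p = params.min_length, params.max_window, params.min_identity
    cap = params.multimap_cap
    T = params.quorum(genome_set.n_species)
    if T < 2:
        raise ValueError("species quorum below 2 is degenerate")
    g = _oracle_seed_len(p, L, wmax)
    if prep is None:
        prep = OraclePrep(genome_set, seed_len=g, reach=wmax)
    elif prep.seed_len > g or prep.reach < wmax:
        raise ValueError("supplied OraclePrep is less sensitive than required")

    w_arr = np.arange(L, wmax + 1)
    limits = np.floor((1 - p) * w_arr + 1e-9).astype(np.int64)

    found: list[Interval] = []
    for rname, rseq in genome_set.reference.items():
        n = len(rseq)
        diags = prep.diags[rname]
        ncum = prep.ncum[rname]

        # species-quorum prefilter over start positions
        sp_masks: dict[str, np.ndarray] = {}
        for dg in diags:
            ok = _diag_feasible_starts(dg, p, L, wmax)
            if ok.size == 0:
                continue
            mask = sp_masks.setdefault(dg.species, np.zeros(n, dtype=bool))
            mask[dg.lo : dg.lo + ok.size] |= ok
        counts = np.zeros(n, dtype=np.int32)
        for mask in sp_masks.values():
            counts += mask
        starts = np.nonzero(counts >= T)[0]
        if starts.size == 0:
            continue

        # contiguous runs of candidate starts share a diagonal shortlist
        runs: list[tuple[int, int]] = []
        run_start = prev = int(starts[0])
        for s in starts[1:]:
            s = int(s)
            if s != prev + 1:
                runs.append((run_start, prev))
                run_start = s
            prev = s
        runs.append((run_start, prev))

        for a, b in runs:
            local = [dg for dg in diags if dg.lo <= b and dg.hi - L >= a]
            for i in range(a, b + 1):
                w_hi = min(wmax, n - i)
                if w_hi < L:
                    continue
                nw = w_hi - L + 1
                ok = (ncum[i + L : i + w_hi + 1] - ncum[i]) == 0
                support = np.zeros(nw, dtype=np.int32)
                by_species: dict[str, list[np.ndarray]] = {}
                for dg in local:
                    if dg.lo > i or dg.hi - i < L:
                        continue
                    wlim = min(w_hi, dg.hi - i)
                    nseg = wlim - L + 1
                    base = i - dg.lo
                    mism = dg.cum[base + L : base + wlim + 1] - dg.cum[base]
                    seg = np.zeros(nw, dtype=bool)
                    seg[:nseg] = mism <= limits[:nseg]
                    by_species.setdefault(dg.species, []).append(seg)
                for sp, segs in by_species.items():
                    present = segs[0]
                    for seg in segs[1:]:
                        present = present | seg
                    support += present
                    if len(segs) > cap:  # multimap cap can only trip here
                        occ = np.zeros(nw, dtype=np.int32)
                        for seg in segs:
                            occ += seg
                        ok = ok & (occ <= cap)
                ok = ok & (support >= T)
                if ok.any():
                    w_best = L + int(np.nonzero(ok)[0][-1])
                    found.append(Interval(rname, i, i + w_best))
    return merge_intervals(found)


# ---------------------------------------------------------------------------
# Synthetic gene annotation fixtures
# ---------------------------------------------------------------------------

def demo_gene_models() -> tuple[list[GeneModel], list[tuple[Interval, str]]]:
    """Hand-planted gene models on a 10 kb sequence plus intervals whose
    genomic-context category is known by construction (one per category)."""
    c = "chr1"
    gene_a = GeneModel(
        gene_id="GA", gene_name="GeneA", biotype="protein_coding", strand="+",
        interval=Interval(c, 1000, 5000),
        exons=[Interval(c, 1000, 1400), Interval(c, 2000, 2600), Interval(c, 4400, 5000)],
        cds=[Interval(c, 1200, 1400), Interval(c, 2000, 2600), Interval(c, 4400, 4600)],
        utr5=[Interval(c, 1000, 1200)],
        utr3=[Interval(c, 4600, 5000)],
    )
    gene_b = GeneModel(
        gene_id="GB", gene_name="LncB", biotype="lncRNA", strand="-",
        interval=Interval(c, 6000, 8000),
        exons=[Interval(c, 6000, 6500), Interval(c, 7500, 8000)],
    )
    gene_c = GeneModel(
        gene_id="GC", gene_name="MirC", biotype="miRNA", strand="+",
        interval=Interval(c, 8500, 8700),
        exons=[Interval(c, 8500, 8700)],
    )
    gene_d = GeneModel(
        gene_id="GD", gene_name="GeneD", biotype="protein_coding", strand="+",
        interval=Interval(c, 9000, 9600),
        exons=[Interval(c, 9000, 9100), Interval(c, 9500, 9600)],
        cds=[Interval(c, 9000, 9100), Interval(c, 9500, 9600)],
    )
    gene_e = GeneModel(
        gene_id="GE", gene_name="LncE", biotype="lncRNA", strand="+",
        interval=Interval(c, 9200, 9900),
        exons=[Interval(c, 9200, 9250), Interval(c, 9800, 9900)],
    )
    models = [gene_a, gene_b, gene_c, gene_d, gene_e]
    planted = [
        (Interval(c, 2100, 2300), "CDS"),
        (Interval(c, 1020, 1140), "five_prime_UTR"),
        (Interval(c, 4700, 4900), "three_prime_UTR"),
        (Interval(c, 1500, 1900), "pc_intron"),
        (Interval(c, 2500, 2700), "pc_intron_exon_junction"),
        (Interval(c, 6100, 6400), "lncRNA_exon"),
        (Interval(c, 6700, 7300), "lncRNA_intron"),
        (Interval(c, 6400, 6600), "lncRNA_intron_exon_junction"),
        (Interval(c, 8550, 8650), "other_gene"),
        (Interval(c, 9300, 9400), "complex_locus"),  # intronic in both gene types
        (Interval(c, 950, 1100), "complex_locus"),  # gene/intergenic straddle
        (Interval(c, 5200, 5400), "intergenic"),
    ]
    return models, planted
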