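"""Calling ultraconserved elements from core k-mer hits.

Stages (iii)-(iv) of the discovery pipeline: merge overlapping core k-mer
hits on the reference into candidate regions, then search each candidate
neighbourhood for every maximal reference window of length >= L for which at
least ceil(f*Y) species (the reference counts as one) carry a gapless match
at identity >= p on either strand, subject to a per-genome multi-mapping cap.

The extension stage re-searches candidate neighbourhoods at full sensitivity
with short exact seeds whose length is chosen by the pigeonhole bound, so a
window passing the identity threshold cannot be missed once its region has
been seeded by a core k-mer.  Identity is evaluated gaplessly against the
reference window: N in the reference makes a window ineligible, N in another
species counts as a mismatch for that species only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.ndimage import minimum_filter1d

from .genome_io import GenomeSet, Interval, merge_intervals
from . import kmer_core
from .kmer_core import CoreKmer, mismatch_budget, species_quorum

log = logging.getLogger("ucekit.uce_caller")

__all__ = [
    "UCEParams",
    "CandidateRegion",
    "SpeciesHit",
    "UCE",
    "CallerWorkspace",
    "build_candidates",
    "extend_and_call",
    "apply_multimap_cap",
    "find_uces",
    "cumulative_scan",
    "uces_to_bed",
]

_FLOAT_TOL = 1e-6  # guards exact rational identity thresholds against float error


@dataclass(frozen=True)
class UCEParams:
    """Thresholds for UCE discovery.

    Defaults are the standard placental-mammal setting: minimum length 100 bp,
    minimum identity 97%, present in at least 50% of species, core k-mer
    length 50 with a 50% species threshold and a 1,000-position map limit,
    and a 100-position multi-mapping cap.  ``max_window`` bounds the longest
    window the caller examines (well above observed UCE lengths, which
    concentrate in 100-200 bp).
    """

    min_length: int = 100
    min_identity: float = 0.97
    min_species_fraction: float = 0.5
    core_k: int = 50
    core_fraction: float = 0.5
    kmer_map_limit: int = 1000
    multimap_cap: int = 100
    max_window: int = 1000
    cumulative_identities: tuple[float, ...] = (1.0, 0.99, 0.98, 0.97)

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError(f"min_identity must be in (0, 1], got {self.min_identity}")
        if not 0 < self.min_species_fraction <= 1:
            raise ValueError(
                f"min_species_fraction must be in (0, 1], got {self.min_species_fraction}"
            )
        if self.min_length < self.core_k:
            raise ValueError(
                f"min_length ({self.min_length}) must be >= core_k ({self.core_k})"
            )
        if self.max_window < self.min_length:
            raise ValueError("max_window must be >= min_length")
        if self.multimap_cap < 1 or self.kmer_map_limit < 1:
            raise ValueError("multimap_cap and kmer_map_limit must be >= 1")

    def quorum(self, n_species: int) -> int:
        """Species (reference included) required to support a window."""
        return species_quorum(self.min_species_fraction, n_species)

    def budget(self, length: int) -> int:
        return mismatch_budget(length, self.min_identity)


def pigeonhole_seed_length(
    min_identity: float, min_length: int, max_window: int, cap: int = 16
) -> int:
    """Longest exact seed guaranteed inside any window of length in
    [min_length, max_window] at identity >= min_identity.

    A window of length w with m substitutions contains an exact run of at
    least ceil((w - m)/(m + 1)) bases; the minimum over w is the safe seed
    length.  Capped (shorter seeds are strictly more sensitive).
    """
    bound = min(
        -(-(w - mismatch_budget(w, min_identity)) // (mismatch_budget(w, min_identity) + 1))
        for w in range(min_length, max_window + 1)
    )
    if bound < 8:
        raise ValueError(
            f"identity threshold {min_identity} too low for exhaustive seeding "
            f"(guaranteed exact run {bound} < 8)"
        )
    return min(cap, bound)


# ---------------------------------------------------------------------------
# Candidate regions (stage iii)
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    """A merged run of core k-mer hits on the reference, with the merged hit
    intervals of its constituent k-mers in every species."""

    interval: Interval
    species: set[str] = field(default_factory=set)
    species_support: dict[str, list[Interval]] = field(default_factory=dict)


def build_candidates(
    core_kmers: Sequence[CoreKmer], reference_id: str
) -> list[CandidateRegion]:
    """Merge overlapping/book-ended reference hits of core k-mers into
    candidate regions; each candidate carries the merged per-species hit
    intervals of the k-mers that compose it."""
    ref_ivs: list[tuple[Interval, int]] = []
    for idx, ck in enumerate(core_kmers):
        k = len(ck.sequence)
        for hit in ck.hits.get(reference_id, ()):
            ref_ivs.append((Interval(hit.seq_name, hit.start, hit.start + k), idx))
    if not ref_ivs:
        return []
    merged = merge_intervals([iv for iv, _ in ref_ivs])
    # assign constituent k-mers to candidates by reference overlap
    members: dict[int, set[int]] = {i: set() for i in range(len(merged))}
    by_seq: dict[str, list[tuple[int, Interval]]] = {}
    for ci, civ in enumerate(merged):
        by_seq.setdefault(civ.seq_name, []).append((ci, civ))
    for iv, idx in ref_ivs:
        for ci, civ in by_seq.get(iv.seq_name, ()):
            if iv.start < civ.end and civ.start < iv.end:
                members[ci].add(idx)
    out: list[CandidateRegion] = []
    for ci, civ in enumerate(merged):
        cand = CandidateRegion(interval=civ)
        sp_ivs: dict[str, list[Interval]] = {}
        for idx in members[ci]:
            ck = core_kmers[idx]
            k = len(ck.sequence)
            for sp, hits in ck.hits.items():
                for h in hits:
                    sp_ivs.setdefault(sp, []).append(
                        Interval(h.seq_name, h.start, h.start + k)
                    )
        cand.species_support = {sp: merge_intervals(ivs) for sp, ivs in sp_ivs.items()}
        cand.species = set(cand.species_support)
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Workspace: oriented genome arrays, seed-discovered diagonals
# ---------------------------------------------------------------------------

_N = ord("N")


class _Diag:
    """One gapless alignment diagonal between a reference sequence and an
    oriented target sequence, with a cumulative mismatch array over the
    reference range it can support."""

    __slots__ = ("species", "tname", "orient", "d", "lo", "hi", "cum", "tlen")

    def __init__(self, species, tname, orient, d, lo, hi, cum, tlen):
        self.species = species
        self.tname = tname
        self.orient = orient
        self.d = d
        self.lo = lo  # first reference position covered (inclusive)
        self.hi = hi  # last reference position covered (exclusive)
        self.cum = cum  # cum[j] = mismatches in ref[lo : lo + j]
        self.tlen = tlen

    def mismatches(self, start: int, end: int) -> int:
        return int(self.cum[end - self.lo] - self.cum[start - self.lo])


class CallerWorkspace:
    """Per-genome-set precomputation shared across parameter settings.

    Discovers all alignment diagonals between the reference and every genome
    (both strands, the reference itself included) that share an exact seed of
    length ``seed_len``, and stores a cumulative mismatch array per diagonal.
    Valid for any identity threshold whose pigeonhole-safe seed length is
    >= ``seed_len``.
    """

    def __init__(self, genome_set: GenomeSet, seed_len: int = 16, reach: int = 1000):
        self.genome_set = genome_set
        self.seed_len = seed_len
        self.reach = reach  # max window length the diagonals must support
        self.ref_id = genome_set.reference_id
        self.cache: dict = {}  # memoized seed indexes / mapped core k-mers
        self.ref_arrays: dict[str, np.ndarray] = {}
        self.ref_ncum: dict[str, np.ndarray] = {}
        self.diags: dict[str, list[_Diag]] = {}
        self._build()

    def _build(self) -> None:
        g = self.seed_len
        gs = self.genome_set
        ref_seqs = gs.reference
        seed_map: dict[str, list[tuple[str, int]]] = {}
        for rname, rseq in ref_seqs.items():
            arr = np.frombuffer(rseq.encode(), dtype=np.uint8)
            self.ref_arrays[rname] = arr
            ncum = np.zeros(len(rseq) + 1, dtype=np.int32)
            np.cumsum(arr == _N, out=ncum[1:])
            self.ref_ncum[rname] = ncum
            self.diags[rname] = []
            for i in range(len(rseq) - g + 1):
                sub = rseq[i : i + g]
                if "N" in sub:
                    continue
                seed_map.setdefault(sub, []).append((rname, i))

        spans: dict[tuple, list[int]] = {}  # diag key -> [min_hit, max_hit]
        oriented: dict[tuple[str, str, str], str] = {}
        for sp in gs.species_ids:
            for tname, tseq in gs.sequences[sp].items():
                for orient, ts in (("+", tseq), ("-", kmer_core.revcomp(tseq))):
                    oriented[(sp, tname, orient)] = ts
                    get = seed_map.get
                    for j in range(len(ts) - g + 1):
                        lst = get(ts[j : j + g])
                        if not lst:
                            continue
                        for rname, i in lst:
                            key = (rname, sp, tname, orient, j - i)
                            span = spans.get(key)
                            if span is None:
                                spans[key] = [i, i]
                            else:
                                if i < span[0]:
                                    span[0] = i
                                elif i > span[1]:
                                    span[1] = i

        reach = self.reach
        t_arrays: dict[tuple[str, str, str], np.ndarray] = {
            key: np.frombuffer(ts.encode(), dtype=np.uint8)
            for key, ts in oriented.items()
        }
        for (rname, sp, tname, orient, d), (minh, maxh) in spans.items():
            rarr = self.ref_arrays[rname]
            tarr = t_arrays[(sp, tname, orient)]
            lo = max(0, -d, minh - reach)
            hi = min(len(rarr), len(tarr) - d, maxh + self.seed_len + reach)
            if hi - lo < self.seed_len:
                continue
            tseg = tarr[lo + d : hi + d]
            mism = (rarr[lo:hi] != tseg) | (tseg == _N)
            cum = np.zeros(hi - lo + 1, dtype=np.int32)
            np.cumsum(mism, out=cum[1:])
            self.diags[rname].append(
                _Diag(sp, tname, orient, d, lo, hi, cum, len(tarr))
            )
        for dlist in self.diags.values():
            dlist.sort(key=lambda dg: (dg.lo, dg.species, dg.tname, dg.orient, dg.d))

    # -- per-parameter machinery ------------------------------------------

    def thresholds(self, params: UCEParams) -> np.ndarray:
        w = np.arange(params.min_length, params.max_window + 1)
        return np.floor((1.0 - params.min_identity) * w + 1e-9).astype(np.int32)

    def feasible_counts(self, rname: str, params: UCEParams) -> np.ndarray:
        """Per reference position, the number of species with any diagonal
        admitting some passing window starting there (superset prefilter)."""
        n = len(self.ref_arrays[rname])
        L, wmax, p = params.min_length, params.max_window, params.min_identity
        size = wmax - L + 1
        size += (size + 1) % 2  # odd-size left-aligned minimum filter
        per_species: dict[str, np.ndarray] = {}
        for dg in self.diags[rname]:
            ln = dg.hi - dg.lo
            pref = dg.cum.astype(np.float64) - (1.0 - p) * np.arange(ln + 1)
            left_min = minimum_filter1d(
                pref, size=size, mode="constant", cval=np.inf, origin=-(size // 2)
            )
            # feasible start j (diag-local): min_{e in [j+L, j+size)} pref[e] <= pref[j]
            jmax = ln - L
            if jmax < 0:
                continue
            ok = left_min[L : L + jmax + 1] <= pref[: jmax + 1] + _FLOAT_TOL
            mask = per_species.get(dg.species)
            if mask is None:
                mask = np.zeros(n, dtype=bool)
                per_species[dg.species] = mask
            mask[dg.lo : dg.lo + jmax + 1] |= ok
        counts = np.zeros(n, dtype=np.int16)
        for mask in per_species.values():
            counts += mask
        return counts


def _evaluate_starts(
    ws: CallerWorkspace,
    rname: str,
    starts: np.ndarray,
    params: UCEParams,
) -> list[tuple[int, int]]:
    """For each candidate start, the maximal window satisfying length,
    identity-quorum and multimap constraints; returns (start, end) pairs."""
    gs = ws.genome_set
    L, wmax = params.min_length, params.max_window
    T = params.quorum(gs.n_species)
    if T < 2:
        raise ValueError(
            "species quorum below 2 degenerates to the whole reference; "
            "raise min_species_fraction or add genomes"
        )
    cap = params.multimap_cap
    thresh = ws.thresholds(params)
    ncum = ws.ref_ncum[rname]
    n = len(ws.ref_arrays[rname])
    diags = ws.diags[rname]

    # sweep: activate a diagonal while it can host a minimal window
    events_add = sorted(diags, key=lambda dg: dg.lo)
    events_rm = sorted(diags, key=lambda dg: dg.hi - L + 1)
    ia = ir = 0
    active: dict[str, list[_Diag]] = {}
    out: list[tuple[int, int]] = []
    for i in map(int, starts):
        while ia < len(events_add) and events_add[ia].lo <= i:
            dg = events_add[ia]
            active.setdefault(dg.species, []).append(dg)
            ia += 1
        while ir < len(events_rm) and events_rm[ir].hi - L + 1 <= i:
            dg = events_rm[ir]
            lst = active.get(dg.species)
            if lst is not None and dg in lst:
                lst.remove(dg)
            ir += 1
        w_hi = min(wmax, n - i)
        if w_hi < L:
            continue
        nw = w_hi - L + 1
        valid = ncum[i + L : i + w_hi + 1] - ncum[i] == 0
        if not valid.any():
            continue
        count = np.zeros(nw, dtype=np.int16)
        occ_checks: list[np.ndarray] = []
        for sp, dlist in active.items():
            if not dlist:
                continue
            pass_vec = np.zeros(nw, dtype=bool)
            need_occ = len(dlist) > cap
            occ = np.zeros(nw, dtype=np.int32) if need_occ else None
            for dg in dlist:
                if dg.lo > i or dg.hi - i < L:
                    continue
                wlim = min(w_hi, dg.hi - i)
                nseg = wlim - L + 1
                base = i - dg.lo
                dm = dg.cum[base + L : base + wlim + 1] - dg.cum[base]
                seg = dm <= thresh[:nseg]
                pass_vec[:nseg] |= seg
                if need_occ:
                    occ[:nseg] += seg
            count += pass_vec
            if need_occ:
                occ_checks.append(occ)
        ok = valid & (count >= T)
        for occ in occ_checks:
            ok &= occ <= cap
        if ok.any():
            w_best = L + int(np.nonzero(ok)[0][-1])
            out.append((i, i + w_best))
    return out


# ---------------------------------------------------------------------------
# UCE records
# ---------------------------------------------------------------------------

class SpeciesHit(NamedTuple):
    seq_name: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class UCE:
    """A called ultraconserved element on the reference."""

    id: str
    interval: Interval
    sequence: str
    species_hits: dict[str, SpeciesHit]
    n_species_passing: int


def _longest_passing_window(
    dg: _Diag, start: int, end: int, p: float, L: int
) -> tuple[int, int, int] | None:
    """Longest sub-window [j, e) of the reference interval, length >= L, with
    gapless identity >= p on this diagonal; returns (j, e, mismatches).

    Ties break to the earliest end, then the earliest start."""
    lo, hi = max(start, dg.lo), min(end, dg.hi)
    if hi - lo < L:
        return None
    base = lo - dg.lo
    ln = hi - lo
    pref = (
        dg.cum[base : base + ln + 1].astype(np.float64)
        - (1.0 - p) * np.arange(ln + 1)
    )
    prefmax = np.maximum.accumulate(pref)
    ends = np.arange(L, ln + 1)
    j_first = np.searchsorted(prefmax, pref[L:] - _FLOAT_TOL, side="left")
    widths = ends - j_first
    valid = widths >= L
    if not valid.any():
        return None
    widths = np.where(valid, widths, -1)
    k = int(np.argmax(widths))
    j, e = int(j_first[k]), int(ends[k])
    mism = int(dg.cum[base + e] - dg.cum[base + j])
    return lo + j, lo + e, mism


def _best_hits(
    ws: CallerWorkspace, rname: str, start: int, end: int, params: UCEParams
) -> tuple[dict[str, SpeciesHit], int, dict[str, int]]:
    """Per-species best hit for a called reference interval, the number of
    species passing, and per-genome occurrence counts of the full interval at
    >= min_identity (for the multimap re-check).

    A species passes when some sub-window of length >= min_length meets the
    identity threshold on one of its diagonals (the criterion under which the
    interval was emitted); its reported hit is the longest such window.
    Species without a passing window are reported with their best full-length
    gapless hit for context.
    """
    length = end - start
    p, L = params.min_identity, params.min_length
    budget = params.budget(length)
    occ: dict[str, int] = {sp: 0 for sp in ws.genome_set.species_ids}
    best_pass: dict[str, tuple] = {}
    best_full: dict[str, tuple] = {}

    def species_coords(dg: _Diag, s: int, e: int) -> tuple[int, int]:
        if dg.orient == "+":
            return s + dg.d, e + dg.d
        return dg.tlen - (e + dg.d), dg.tlen - (s + dg.d)

    for dg in ws.diags[rname]:
        if min(end, dg.hi) - max(start, dg.lo) < L:
            continue
        if dg.lo <= start and end <= dg.hi:
            mism = dg.mismatches(start, end)
            if mism <= budget:
                occ[dg.species] += 1
            identity = 1.0 - mism / length
            t0, t1 = species_coords(dg, start, end)
            rank = (-identity, t0, 0 if dg.orient == "+" else 1, dg.tname)
            cur = best_full.get(dg.species)
            if cur is None or rank < cur[0]:
                best_full[dg.species] = (
                    rank, SpeciesHit(dg.tname, t0, t1, dg.orient, identity)
                )
        win = _longest_passing_window(dg, start, end, p, L)
        if win is not None:
            j, e, mism = win
            identity = 1.0 - mism / (e - j)
            t0, t1 = species_coords(dg, j, e)
            rank = (-(e - j), -identity, t0, 0 if dg.orient == "+" else 1, dg.tname)
            cur = best_pass.get(dg.species)
            if cur is None or rank < cur[0]:
                best_pass[dg.species] = (
                    rank, SpeciesHit(dg.tname, t0, t1, dg.orient, identity)
                )
    hits = {sp: rec[1] for sp, rec in best_full.items()}
    hits.update({sp: rec[1] for sp, rec in best_pass.items()})
    return hits, len(best_pass), occ


def _records_from_intervals(
    ws: CallerWorkspace, intervals: Sequence[Interval], params: UCEParams
) -> list[UCE]:
    gs = ws.genome_set
    uces = []
    for idx, iv in enumerate(
        sorted(intervals, key=lambda v: (v.seq_name, v.start)), 1
    ):
        seq = gs.fetch(gs.reference_id, iv)
        hits, n_pass, _occ = _best_hits(ws, iv.seq_name, iv.start, iv.end, params)
        uces.append(
            UCE(
                id=f"UCE_{idx:05d}",
                interval=iv,
                sequence=seq,
                species_hits=hits,
                n_species_passing=n_pass,
            )
        )
    return uces


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _call_windows(
    ws: CallerWorkspace,
    params: UCEParams,
    allowed: Mapping[str, np.ndarray] | None,
) -> list[Interval]:
    """Evaluate all prefiltered starts (optionally restricted to candidate
    neighbourhoods) and return merged maximal windows."""
    T = params.quorum(ws.genome_set.n_species)
    windows: list[Interval] = []
    for rname in ws.ref_arrays:
        counts = ws.feasible_counts(rname, params)
        eligible = counts >= T
        if allowed is not None:
            mask = allowed.get(rname)
            if mask is None:
                continue
            eligible &= mask
        starts = np.nonzero(eligible)[0]
        if starts.size == 0:
            continue
        for s, e in _evaluate_starts(ws, rname, starts, params):
            windows.append(Interval(rname, s, e))
    return merge_intervals(windows)


def _candidate_mask(
    ws: CallerWorkspace, candidates: Iterable[CandidateRegion], params: UCEParams
) -> dict[str, np.ndarray]:
    masks = {
        rname: np.zeros(len(arr), dtype=bool) for rname, arr in ws.ref_arrays.items()
    }
    pad = params.max_window
    for cand in candidates:
        iv = cand.interval
        mask = masks.get(iv.seq_name)
        if mask is not None:
            mask[max(0, iv.start - pad) : iv.end + pad] = True
    return masks


def extend_and_call(
    candidate: CandidateRegion,
    genome_set: GenomeSet,
    params: UCEParams,
    workspace: CallerWorkspace | None = None,
) -> list[UCE]:
    """Stage (iv) for one candidate: emit every maximal reference window of
    length >= L supported by the species quorum at identity >= p."""
    ws = workspace or CallerWorkspace(
        genome_set,
        seed_len=pigeonhole_seed_length(
            params.min_identity, params.min_length, params.max_window
        ),
        reach=params.max_window,
    )
    mask = _candidate_mask(ws, [candidate], params)
    intervals = _call_windows(ws, params, mask)
    return _records_from_intervals(ws, intervals, params)


def apply_multimap_cap(
    uces: Sequence[UCE],
    genome_set: GenomeSet,
    params: UCEParams,
    workspace: CallerWorkspace | None = None,
) -> list[UCE]:
    """Remove any UCE whose sequence occurs at >= min_identity more than
    multimap_cap times in any single genome; removals are logged with the
    offending genome."""
    ws = workspace or CallerWorkspace(
        genome_set,
        seed_len=pigeonhole_seed_length(
            params.min_identity, params.min_length, params.max_window
        ),
        reach=params.max_window,
    )
    kept: list[UCE] = []
    for uce in uces:
        _hits, _n, occ = _best_hits(
            ws, uce.interval.seq_name, uce.interval.start, uce.interval.end, params
        )
        offender = next(
            (sp for sp, c in occ.items() if c > params.multimap_cap), None
        )
        if offender is None:
            kept.append(uce)
        else:
            log.info(
                "multimap cap: dropping %s (%d occurrences in %s > %d)",
                uce.id,
                occ[offender],
                offender,
                params.multimap_cap,
            )
    return kept


def find_uces(
    genome_set: GenomeSet,
    params: UCEParams | None = None,
    workspace: CallerWorkspace | None = None,
    index: kmer_core.KmerIndex | None = None,
) -> list[UCE]:
    """The full discovery pipeline at a single identity threshold.

    ``workspace`` and ``index`` may be passed in to reuse the identity- and
    parameter-independent precomputation across runs.
    """
    params = params or UCEParams()
    cache = workspace.cache if workspace is not None else None
    if index is None:
        index = kmer_core.build_index(genome_set, params.core_k)
    map_key = (
        "mapped", id(index), params.core_fraction, params.kmer_map_limit,
        params.min_identity,
    )
    if cache is not None and map_key in cache:
        core, core_kmers = cache[map_key]
    else:
        core = kmer_core.select_core_kmers(
            index, genome_set.n_species, params.core_fraction, params.kmer_map_limit
        )
        core_kmers = kmer_core.map_core_kmers(
            core,
            genome_set,
            params.min_identity,
            params.kmer_map_limit,
            seed_cache=cache,
        )
        if cache is not None:
            cache[map_key] = (core, core_kmers)
    candidates = build_candidates(core_kmers, genome_set.reference_id)
    log.info(
        "%d core k-mers -> %d mapped -> %d candidate regions",
        len(core),
        len(core_kmers),
        len(candidates),
    )
    if not candidates:
        return []
    ws = workspace or CallerWorkspace(
        genome_set,
        seed_len=pigeonhole_seed_length(
            params.min_identity, params.min_length, params.max_window
        ),
        reach=params.max_window,
    )
    mask = _candidate_mask(ws, candidates, params)
    intervals = _call_windows(ws, params, mask)
    # the multimap cap is enforced per window during calling; a re-check on
    # the merged interval would be stricter than the window definition
    # (occurrence counts are not monotone in window length)
    return _records_from_intervals(ws, intervals, params)


def cumulative_scan(
    genome_set: GenomeSet,
    params: UCEParams | None = None,
    workspace: CallerWorkspace | None = None,
    index: kmer_core.KmerIndex | None = None,
) -> list[Interval]:
    """Run the pipeline at each identity in ``cumulative_identities``
    (strictest first) and merge the union of the reference intervals."""
    params = params or UCEParams()
    ladder = params.cumulative_identities
    if not ladder:
        raise ValueError("cumulative_identities is empty")
    if list(ladder) != sorted(set(ladder), reverse=True):
        raise ValueError("cumulative_identities must be strictly decreasing")
    if abs(ladder[-1] - params.min_identity) > 1e-9:
        raise ValueError(
            "the last cumulative identity must equal min_identity "
            f"({ladder[-1]} != {params.min_identity})"
        )
    if index is None:
        index = kmer_core.build_index(genome_set, params.core_k)
    intervals: list[Interval] = []
    for ident in ladder:
        run_params = replace(params, min_identity=ident)
        uces = find_uces(genome_set, run_params, workspace=workspace, index=index)
        intervals.extend(u.interval for u in uces)
    return merge_intervals(intervals)


def uces_to_bed(uces: Sequence[UCE]) -> list[Interval]:
    """BED6 representation: name = UCE id, score = per-mille mean identity of
    counted species (reference included), strand '+'."""
    out = []
    for u in uces:
        idents = [
            h.identity for h in u.species_hits.values()
        ]
        mean_ident = sum(idents) / len(idents) if idents else 1.0
        out.append(
            Interval(
                u.interval.seq_name,
                u.interval.start,
                u.interval.end,
                name=u.id,
                score=round(mean_ident * 1000),
                strand="+",
            )
        )
    return out
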