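"""Readers/writers for FASTA, BED, GTF and TSV reports, plus interval algebra.

All coordinates are 0-based half-open (BED convention) everywhere in the
package.  GTF input (1-based closed) is converted on read.  Sequences are
normalized to the alphabet {A, C, G, T, N}: lowercase is folded to uppercase
and every other IUPAC code is folded to N.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeSet",
    "Interval",
    "GeneModel",
    "FormatError",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gtf",
    "write_gtf",
    "merge_intervals",
    "intersect",
    "closest",
]

_IUPAC = "ACGTURYSWKMBDHVN"
_FOLD = str.maketrans(
    _IUPAC + _IUPAC.lower(),
    "ACGTNNNNNNNNNNNN" + "ACGTNNNNNNNNNNNN".lower().upper(),
)
_VALID = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed input file (message names the offending record/line)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and fold non-ACGT IUPAC codes to N."""
    out = seq.translate(_FOLD)
    bad = set(out) - _VALID
    if bad:
        raise FormatError(f"invalid sequence characters: {sorted(bad)!r}")
    return out


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval (BED convention)."""

    seq_name: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_name == other.seq_name and max(
            self.start, other.start
        ) < min(self.end, other.end)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union overlapping and book-ended intervals per sequence.

    Matches ``bedtools merge`` with its default distance of 0: intervals whose
    end equals the next start are joined.  Output is sorted by
    (seq_name, start) and minimal (no two output intervals are mergeable).
    """
    ordered = sorted(intervals, key=lambda iv: (iv.seq_name, iv.start, iv.end))
    out: list[Interval] = []
    for iv in ordered:
        if out and out[-1].seq_name == iv.seq_name and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(iv.seq_name, out[-1].start, iv.end)
        else:
            out.append(Interval(iv.seq_name, iv.start, iv.end))
    return out


@dataclass(frozen=True)
class OverlapRecord:
    a: Interval
    b: Interval
    overlap: int


def intersect(
    a_intervals: Iterable[Interval], b_intervals: Iterable[Interval]
) -> list[OverlapRecord]:
    """All (a, b) pairs with >=1 bp overlap, with the overlap length.

    Semantics match ``bedtools intersect`` on half-open intervals: a pair
    overlaps iff max(starts) < min(ends); book-ended abutment is no overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for b in b_intervals:
        trees.setdefault(b.seq_name, IntervalTree()).addi(b.start, b.end, b)
    records: list[OverlapRecord] = []
    for a in sorted(a_intervals, key=lambda iv: (iv.seq_name, iv.start, iv.end)):
        tree = trees.get(a.seq_name)
        if tree is None:
            continue
        hits = sorted(tree.overlap(a.start, a.end), key=lambda h: (h.begin, h.end))
        for h in hits:
            records.append(
                OverlapRecord(a, h.data, min(a.end, h.end) - max(a.start, h.begin))
            )
    return records


def closest(
    query: Interval, features: Sequence[Interval]
) -> list[tuple[Interval, int]]:
    """All features at minimal genomic distance from ``query``, ties included.

    Distance is the gap length between the half-open intervals (0 for overlap
    or book-ended abutment).  Only features on the query's sequence are
    considered; an empty result means none exist there.
    """
    best: list[tuple[Interval, int]] = []
    best_d: int | None = None
    for f in sorted(features, key=lambda iv: (iv.start, iv.end, iv.name or "")):
        if f.seq_name != query.seq_name:
            continue
        if f.overlaps(query) or f.end == query.start or query.end == f.start:
            d = 0
        elif f.end <= query.start:
            d = query.start - f.end
        else:
            d = f.start - query.end
        if best_d is None or d < best_d:
            best, best_d = [(f, d)], d
        elif d == best_d:
            best.append((f, d))
    return best


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into {name: normalized sequence}.

    Names are taken up to the first whitespace.  Raises FormatError on an
    empty file, a duplicate name, or text before the first header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header, got {first.strip()!r}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6; '#' comment and 'track' lines are skipped."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                iv = Interval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    name=parts[3] if len(parts) > 3 else None,
                    score=float(parts[4]) if len(parts) > 4 and parts[4] != "." else None,
                    strand=parts[5] if len(parts) > 5 else None,
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(
    path: str | Path,
    intervals: Iterable[Interval],
    header_lines: Sequence[str] = (),
) -> None:
    """Write BED6 where optional fields exist, else BED3; header lines are
    emitted as '#'-prefixed comments."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for iv in intervals:
            cols = [iv.seq_name, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                score = 0 if iv.score is None else iv.score
                cols += [
                    iv.name or ".",
                    str(int(round(score))),
                    iv.strand or "+",
                ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene models / GTF
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A flattened gene model: exon/CDS/UTR intervals unioned over transcripts.

    Introns are the gene span minus the exon union, i.e. regions intronic in
    every annotated transcript.
    """

    gene_id: str
    gene_name: str
    biotype: str  # "protein_coding" | "lncRNA" | anything else
    strand: str
    interval: Interval
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in itertools.chain(self.exons, self.cds, self.utr5, self.utr3):
            if iv.start < self.interval.start or iv.end > self.interval.end:
                raise ValueError(
                    f"{self.gene_id}: feature {iv} outside gene span {self.interval}"
                )

    def introns(self) -> list[Interval]:
        merged = merge_intervals(self.exons)
        out: list[Interval] = []
        cur = self.interval.start
        for ex in merged:
            if ex.start > cur:
                out.append(Interval(self.interval.seq_name, cur, ex.start))
            cur = max(cur, ex.end)
        if cur < self.interval.end:
            out.append(Interval(self.interval.seq_name, cur, self.interval.end))
        return out


_UTR_TYPES = {
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
}


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read an Ensembl-dialect GTF into flattened GeneModels.

    Uses gene_id/gene_name/gene_biotype attributes; exon, CDS and UTR
    features are grouped by gene_id and unioned across transcripts.
    Coordinates are converted from 1-based closed to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: dict[str, dict] = {}

    def bucket(feat) -> dict:
        gid = feat.attributes["gene_id"][0]
        if gid not in genes:
            genes[gid] = {
                "gene_id": gid,
                "gene_name": feat.attributes.get("gene_name", [gid])[0],
                "biotype": feat.attributes.get("gene_biotype", ["other"])[0],
                "strand": feat.strand or ".",
                "seq": feat.seqid,
                "span": None,
                "exons": [],
                "cds": [],
                "utr5": [],
                "utr3": [],
            }
        return genes[gid]

    for feat in db.all_features():
        b = bucket(feat)
        iv = Interval(feat.seqid, feat.start - 1, feat.end)
        if feat.featuretype == "gene":
            b["span"] = iv
            b["gene_name"] = feat.attributes.get("gene_name", [b["gene_id"]])[0]
            b["biotype"] = feat.attributes.get("gene_biotype", [b["biotype"]])[0]
            b["strand"] = feat.strand or b["strand"]
        elif feat.featuretype == "exon":
            b["exons"].append(iv)
        elif feat.featuretype == "CDS":
            b["cds"].append(iv)
        elif feat.featuretype in _UTR_TYPES:
            b[_UTR_TYPES[feat.featuretype]].append(iv)

    models: list[GeneModel] = []
    for gid, b in genes.items():
        feats = b["exons"] + b["cds"] + b["utr5"] + b["utr3"]
        span = b["span"]
        if span is None:
            if not feats:
                continue
            span = Interval(
                b["seq"], min(f.start for f in feats), max(f.end for f in feats)
            )
        models.append(
            GeneModel(
                gene_id=gid,
                gene_name=b["gene_name"],
                biotype=b["biotype"],
                strand=b["strand"],
                interval=span,
                exons=merge_intervals(b["exons"]),
                cds=merge_intervals(b["cds"]),
                utr5=merge_intervals(b["utr5"]),
                utr3=merge_intervals(b["utr3"]),
            )
        )
    models.sort(key=lambda g: (g.interval.seq_name, g.interval.start, g.gene_id))
    return models


def write_gtf(path: str | Path, models: Sequence[GeneModel]) -> None:
    """Write flattened GeneModels as Ensembl-dialect GTF (gene/exon/CDS/UTRs)."""

    def attr(g: GeneModel) -> str:
        return (
            f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
            f'gene_biotype "{g.biotype}";'
        )

    def line(g: GeneModel, ftype: str, iv: Interval) -> str:
        return "\t".join(
            [
                iv.seq_name,
                "ucekit",
                ftype,
                str(iv.start + 1),
                str(iv.end),
                ".",
                g.strand,
                ".",
                attr(g) + f' transcript_id "{g.gene_id}.t1";'
                if ftype != "gene"
                else attr(g),
            ]
        )

    with open(path, "w") as fh:
        for g in models:
            fh.write(line(g, "gene", g.interval) + "\n")
            for ex in g.exons:
                fh.write(line(g, "exon", ex) + "\n")
            for c in g.cds:
                fh.write(line(g, "CDS", c) + "\n")
            for u in g.utr5:
                fh.write(line(g, "five_prime_utr", u) + "\n")
            for u in g.utr3:
                fh.write(line(g, "three_prime_utr", u) + "\n")


# ---------------------------------------------------------------------------
# Genome sets
# ---------------------------------------------------------------------------

@dataclass
class GenomeSet:
    """An ordered collection of named genomes with a designated reference.

    ``sequences`` maps species -> {sequence name -> uppercase ACGTN string}.
    """

    species_ids: list[str]
    sequences: dict[str, dict[str, str]]
    reference_id: str

    def __post_init__(self) -> None:
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if self.reference_id not in self.species_ids:
            raise ValueError(f"reference {self.reference_id!r} not in species set")
        missing = set(self.species_ids) - set(self.sequences)
        if missing:
            raise ValueError(f"species without sequences: {sorted(missing)}")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def reference(self) -> dict[str, str]:
        return self.sequences[self.reference_id]

    def total_length(self, species: str) -> int:
        return sum(len(s) for s in self.sequences[species].values())

    def fetch(self, species: str, interval: Interval) -> str:
        seq = self.sequences[species][interval.seq_name]
        return seq[interval.start : interval.end]

    @classmethod
    def from_fasta_files(
        cls, paths: Mapping[str, str | Path], reference_id: str
    ) -> "GenomeSet":
        species = list(paths)
        seqs = {sp: read_fasta(p) for sp, p in paths.items()}
        return cls(species_ids=species, sequences=seqs, reference_id=reference_id)

    @classmethod
    def from_directory(
        cls, directory: str | Path, reference_id: str
    ) -> "GenomeSet":
        """Load every *.fa/*.fasta in a directory; species = file stem."""
        directory = Path(directory)
        paths = sorted(
            itertools.chain(directory.glob("*.fa"), directory.glob("*.fasta"))
        )
        if not paths:
            raise FileNotFoundError(f"no FASTA files in {directory}")
        return cls.from_fasta_files({p.stem: p for p in paths}, reference_id)
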