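"""Genomic context of UCEs: feature-category classification, gene-level UCE
counts, GC content, and flanking-gene synteny between two species.

Classification assigns exactly one category per element under a fixed
precedence: positions irreducible to a single gene type (overlapping both a
protein-coding and a lncRNA gene, or straddling a gene/intergenic boundary)
are complex loci; otherwise the element is placed within the gene that
wholly contains it (CDS, UTRs, exon/intron junction, intron), falling back
to other_gene for other biotypes and intergenic for no gene overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_io import GeneModel, Interval, intersect

__all__ = [
    "CATEGORIES",
    "SyntenyRecord",
    "classify_context",
    "context_fractions",
    "genes_containing_uces",
    "gc_content",
    "assess_synteny",
]

CATEGORIES = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "pc_intron",
    "pc_intron_exon_junction",
    "lncRNA_exon",
    "lncRNA_intron",
    "lncRNA_intron_exon_junction",
    "other_gene",
    "complex_locus",
    "intergenic",
)


def _covered_by(iv: Interval, features: Sequence[Interval]) -> bool:
    """True when every base of ``iv`` lies in the union of the features."""
    pos = iv.start
    for f in sorted(features, key=lambda x: (x.start, x.end)):
        if f.seq_name != iv.seq_name or f.end <= pos:
            continue
        if f.start > pos:
            return False
        pos = f.end
        if pos >= iv.end:
            return True
    return pos >= iv.end


def _overlaps_any(iv: Interval, features: Iterable[Interval]) -> bool:
    return any(iv.overlaps(f) for f in features)


def _gene_kind(gene: GeneModel) -> str:
    if gene.biotype == "protein_coding":
        return "pc"
    if gene.biotype == "lncRNA":
        return "lnc"
    return "other"


def _within_pc(uce: Interval, gene: GeneModel) -> str:
    if gene.cds and _covered_by(uce, gene.cds):
        return "CDS"
    if gene.utr5 and _covered_by(uce, gene.utr5):
        return "five_prime_UTR"
    if gene.utr3 and _covered_by(uce, gene.utr3):
        return "three_prime_UTR"
    introns = gene.introns()
    in_exon = _overlaps_any(uce, gene.exons)
    in_intron = _overlaps_any(uce, introns)
    if in_exon and in_intron:
        return "pc_intron_exon_junction"
    if in_intron:
        return "pc_intron"
    # wholly exonic but spanning a CDS/UTR boundary: prefer the coding label
    if _overlaps_any(uce, gene.cds):
        return "CDS"
    if _overlaps_any(uce, gene.utr3):
        return "three_prime_UTR"
    return "five_prime_UTR"


def _within_lnc(uce: Interval, gene: GeneModel) -> str:
    introns = gene.introns()
    in_exon = _overlaps_any(uce, gene.exons)
    in_intron = _overlaps_any(uce, introns)
    if in_exon and in_intron:
        return "lncRNA_intron_exon_junction"
    if in_intron:
        return "lncRNA_intron"
    return "lncRNA_exon"


def classify_context(uce: Interval, gene_models: Sequence[GeneModel]) -> str:
    """Assign the single genomic-context category of an element."""
    overlapping = [
        g for g in gene_models if g.interval.overlaps(uce)
    ]
    if not overlapping:
        return "intergenic"
    containing = [
        g
        for g in overlapping
        if g.interval.start <= uce.start and uce.end <= g.interval.end
    ]
    if not containing:
        # partially outside every overlapping gene: gene/intergenic straddle
        # or a span across gene boundaries
        return "complex_locus"
    kinds = {_gene_kind(g) for g in containing}
    if "pc" in kinds and "lnc" in kinds:
        return "complex_locus"
    if "pc" in kinds:
        verdicts = {_within_pc(uce, g) for g in containing if _gene_kind(g) == "pc"}
    elif "lnc" in kinds:
        verdicts = {_within_lnc(uce, g) for g in containing if _gene_kind(g) == "lnc"}
    else:
        return "other_gene"
    if len(verdicts) > 1:
        return "complex_locus"
    return verdicts.pop()


def context_fractions(
    uces: Sequence[Interval], gene_models: Sequence[GeneModel]
) -> dict[str, float]:
    """Fraction of elements per category (sums to 1 over a non-empty set)."""
    counts = {cat: 0 for cat in CATEGORIES}
    for uce in uces:
        counts[classify_context(uce, gene_models)] += 1
    total = len(uces)
    return {cat: (c / total if total else 0.0) for cat, c in counts.items()}


def genes_containing_uces(
    uces: Sequence[Interval], gene_models: Sequence[GeneModel]
) -> dict[str, int]:
    """Per-gene count of elements with >= 1 bp overlap; an element
    overlapping several genes counts toward each (all ties kept)."""
    gene_ivs = [
        Interval(
            g.interval.seq_name, g.interval.start, g.interval.end, name=g.gene_id
        )
        for g in gene_models
    ]
    counts: dict[str, int] = {}
    for rec in intersect(uces, gene_ivs):
        gid = rec.b.name
        counts[gid] = counts.get(gid, 0) + 1
    return counts


def gc_content(sequence: str) -> float | None:
    """(G+C)/(A+C+G+T); N is excluded from the denominator; None if no
    unambiguous base remains."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return None
    return gc / denom


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

@dataclass
class SyntenyRecord:
    uce_id: str
    ref_upstream: set[str] = field(default_factory=set)
    ref_downstream: set[str] = field(default_factory=set)
    other_upstream: set[str] = field(default_factory=set)
    other_downstream: set[str] = field(default_factory=set)
    syntenic: bool = False
    reason: str = ""


def _flank_gene_names(
    iv: Interval, genes: Sequence[GeneModel]
) -> tuple[set[str], set[str]]:
    """Nearest protein-coding gene names up- and downstream (all ties);
    genes overlapping the interval appear on both sides at distance 0."""
    pc = [
        g
        for g in genes
        if g.biotype == "protein_coding" and g.interval.seq_name == iv.seq_name
    ]
    up: set[str] = set()
    down: set[str] = set()
    best_up = best_down = None
    for g in pc:
        giv = g.interval
        if giv.overlaps(iv):
            d_up = d_down = 0
        elif giv.end <= iv.start:
            d_up, d_down = iv.start - giv.end, None
        else:
            d_up, d_down = None, giv.start - iv.end
        if d_up is not None:
            if best_up is None or d_up < best_up:
                best_up, up = d_up, {g.gene_name}
            elif d_up == best_up:
                up.add(g.gene_name)
        if d_down is not None:
            if best_down is None or d_down < best_down:
                best_down, down = d_down, {g.gene_name}
            elif d_down == best_down:
                down.add(g.gene_name)
    return up, down


def assess_synteny(
    uce_id: str,
    ref_location: Interval,
    ref_genes: Sequence[GeneModel],
    other_location: Interval | None,
    other_genes: Sequence[GeneModel],
) -> SyntenyRecord:
    """Synteny by flanking protein-coding genes, orientation-agnostic:
    the element is syntenic when any reference flank gene name matches any
    other-species flank gene name (case-insensitive), upstream/downstream
    being interchangeable.  ``other_location`` is the element's best trace
    hit in the other species (None when unmapped)."""
    rec = SyntenyRecord(uce_id=uce_id)
    rec.ref_upstream, rec.ref_downstream = _flank_gene_names(ref_location, ref_genes)
    if other_location is None:
        rec.reason = "unmapped"
        return rec
    rec.other_upstream, rec.other_downstream = _flank_gene_names(
        other_location, other_genes
    )
    ref_all = {n.lower() for n in rec.ref_upstream | rec.ref_downstream}
    other_all = {n.lower() for n in rec.other_upstream | rec.other_downstream}
    rec.syntenic = bool(ref_all & other_all)
    if not rec.syntenic:
        rec.reason = "no-shared-flank-gene"
    return rec
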