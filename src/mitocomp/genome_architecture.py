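"""Intergenic spacers/overlaps and gene-order rearrangement analysis.

The spacer between consecutive features is ``start(downstream) -
end(upstream) - 1``; negative values are overlaps, zero is abutting.  On a
circular genome the adjacency wrapping the origin is included, so the exact
conservation law

    sum(feature sizes) + sum(signed gaps) == genome length

holds for every record (overlapped bases are counted twice in the size sum
and subtracted once by the negative gap).

Gene orders are circular signed permutations of the 37-gene mitochondrial
alphabet (sign = strand; control region excluded, since control-region
boundaries are unreliably annotated, but it is retained for gap accounting).
Rearrangement against a reference (by default the ancestral insect
arrangement) is reported as breakpoints plus a minimal moved-gene set, each
mover classified as shuffling (same strand, no protein-coding gene crossed),
translocation (PCG crossed), inversion (strand flip in place) or
inverted-translocation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .annotation_io import MitogenomeRecord
from .config import ANCESTRAL_INSECT_ORDER, CONTROL_REGION, GENE_ALPHABET, TRNA_NAMES
from .errors import ValidationError

DEFAULT_LONG_SPACER_THRESHOLD = 50  # nt; "long" spacers flagged in reports

SignedGene = tuple[str, int]


# ---------------------------------------------------------------------------
# Spacer / overlap accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdjacencyGap:
    """Signed gap between two consecutive features (negative = overlap)."""

    upstream: str
    downstream: str
    igs: int


@dataclass
class GapReport:
    gaps: list[AdjacencyGap]
    total_spacer: int                 # sum of positive gaps
    n_overlaps: int
    overlap_range: tuple[int, int] | None   # (min, max) overlap magnitude
    longest_spacer: int
    long_spacers: list[AdjacencyGap] = field(default_factory=list)

    def igs_of(self, downstream: str) -> int:
        for g in self.gaps:
            if g.downstream == downstream:
                return g.igs
        raise KeyError(downstream)


def compute_gaps(record: MitogenomeRecord,
                 long_threshold: int = DEFAULT_LONG_SPACER_THRESHOLD) -> GapReport:
    """All adjacency gaps of a record, including the origin-wrapping one.

    Features are taken in start order; a feature wrapping the origin is
    handled through its linearised end (end + genome length).
    """
    feats = record.features
    if len(feats) < 2:
        raise ValidationError("gap accounting needs at least two features")
    starts = [f.start for f in feats]
    if len(set(starts)) != len(starts):
        raise ValidationError("features with identical start positions")

    def linear_end(f) -> int:
        return f.end + record.genome_length if f.wraps_origin else f.end

    gaps: list[AdjacencyGap] = []
    for up, down in zip(feats, feats[1:]):
        gaps.append(AdjacencyGap(up.name, down.name, down.start - linear_end(up) - 1))
    last, first = feats[-1], feats[0]
    wrap_igs = first.start + record.genome_length - linear_end(last) - 1
    gaps.append(AdjacencyGap(last.name, first.name, wrap_igs))

    positive = [g for g in gaps if g.igs > 0]
    overlaps = [-g.igs for g in gaps if g.igs < 0]
    return GapReport(
        gaps=gaps,
        total_spacer=sum(g.igs for g in positive),
        n_overlaps=len(overlaps),
        overlap_range=(min(overlaps), max(overlaps)) if overlaps else None,
        longest_spacer=max((g.igs for g in positive), default=0),
        long_spacers=[g for g in positive if g.igs >= long_threshold],
    )


# ---------------------------------------------------------------------------
# Gene orders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneOrder:
    """Circular signed gene order, stored in canonical rotation.

    Equality is rotation-invariant: orders are rotated to start at trnI (or
    the lexicographically smallest gene when trnI is absent) on construction.
    """

    genes: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate genes in order: {dupes}")
        anchor = "trnI" if "trnI" in names else min(names)
        i = names.index(anchor)
        object.__setattr__(self, "genes", self.genes[i:] + self.genes[:i])

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def sign_of(self, name: str) -> int:
        for g, s in self.genes:
            if g == name:
                return s
        raise KeyError(name)

    def adjacencies(self) -> set[tuple[SignedGene, SignedGene]]:
        """Circular signed adjacencies, closed under reading direction."""
        out: set[tuple[SignedGene, SignedGene]] = set()
        n = len(self.genes)
        for i in range(n):
            (a, sa), (b, sb) = self.genes[i], self.genes[(i + 1) % n]
            out.add(((a, sa), (b, sb)))
            out.add(((b, -sb), (a, -sa)))
        return out

    def remove(self, names: set[str]) -> tuple[SignedGene, ...]:
        return tuple((g, s) for g, s in self.genes if g not in names)


ANCESTRAL_ORDER = GeneOrder(ANCESTRAL_INSECT_ORDER)


def gene_order(record: MitogenomeRecord) -> GeneOrder:
    """Signed gene order of a record (control region dropped).

    All 37 canonical genes must be present; absences are a hard error.
    """
    entries = [(f.name, +1 if f.strand == "H" else -1)
               for f in record.features if f.name != CONTROL_REGION]
    missing = GENE_ALPHABET - {g for g, _ in entries}
    if missing:
        raise ValidationError(f"{record.record_id}: missing canonical genes: {sorted(missing)}")
    extra = {g for g, _ in entries} - GENE_ALPHABET
    if extra:
        raise ValidationError(f"{record.record_id}: non-canonical genes in order: {sorted(extra)}")
    return GeneOrder(tuple(entries))


def _rotations_equal(a: tuple[SignedGene, ...], b: tuple[SignedGene, ...]) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    try:
        i = b.index(a[0])
    except ValueError:
        return False
    return b[i:] + b[:i] == a


# ---------------------------------------------------------------------------
# Rearrangement comparison
# ---------------------------------------------------------------------------

@dataclass
class RearrangementReport:
    breakpoints: int
    moved_genes: tuple[str, ...]
    classification: dict[str, str]              # gene -> event type
    flanking_spacers: dict[str, tuple[int | None, int | None]]

    @property
    def identical(self) -> bool:
        return self.breakpoints == 0


def _minimal_moved_set(query: GeneOrder, reference: GeneOrder,
                       max_moved: int = 4) -> tuple[str, ...] | None:
    """Smallest gene set whose removal equalises the two circular orders.

    Ties at the minimal size prefer tRNA movers, then lexicographic order.
    Exhaustive over subsets up to ``max_moved`` genes; mitogenome
    rearrangements of interest involve very few genes.
    """
    names = query.names
    for k in range(max_moved + 1):
        candidates = []
        for subset in itertools.combinations(sorted(names), k):
            removed = set(subset)
            if _rotations_equal(query.remove(removed), reference.remove(removed)):
                candidates.append(subset)
        if candidates:
            candidates.sort(key=lambda s: (sum(g not in TRNA_NAMES for g in s), s))
            return candidates[0]
    return None


def _insertion_slot(order: GeneOrder, gene: str, backbone: tuple[str, ...]) -> int:
    """Index into ``backbone`` of the backbone gene preceding ``gene``."""
    names = order.names
    i = names.index(gene)
    n = len(names)
    for step in range(1, n):
        pred = names[(i - step) % n]
        if pred in backbone:
            return backbone.index(pred)
    raise ValidationError("no backbone gene found")  # pragma: no cover


def compare_orders(query: GeneOrder, reference: GeneOrder,
                   query_record: MitogenomeRecord | None = None,
                   max_moved: int = 4) -> RearrangementReport:
    """Signed-permutation comparison of two circular gene orders.

    Breakpoints are query adjacencies absent from the reference.  Moved genes
    are a minimal removal set equalising the orders; each mover is classified
    by strand change and whether the shorter circular arc between its old and
    new positions crosses a protein-coding gene.  Flanking spacer sizes are
    read from :func:`compute_gaps` when the query record is supplied.
    """
    if set(query.names) != set(reference.names):
        raise ValidationError("gene alphabets differ between query and reference")
    ref_adj = reference.adjacencies()
    n = len(query.genes)
    breakpoints = sum(
        (query.genes[i], query.genes[(i + 1) % n]) not in ref_adj for i in range(n)
    )
    moved = _minimal_moved_set(query, reference, max_moved)
    if moved is None:
        raise ValidationError(
            f"orders differ by more than {max_moved} moved genes; raise max_moved")

    backbone = tuple(g for g, _ in reference.remove(set(moved)))
    classification: dict[str, str] = {}
    for gene in moved:
        flipped = query.sign_of(gene) != reference.sign_of(gene)
        slot_old = _insertion_slot(reference, gene, backbone)
        slot_new = _insertion_slot(query, gene, backbone)
        if slot_old == slot_new:
            classification[gene] = "inversion" if flipped else "shuffling"
            continue
        m = len(backbone)
        fwd = [(slot_old + j) % m for j in range(1, (slot_new - slot_old) % m + 1)]
        bwd = [(slot_new + j) % m for j in range(1, (slot_old - slot_new) % m + 1)]
        arc = fwd if len(fwd) <= len(bwd) else bwd
        from .config import PCG_NAMES
        crossed_pcg = any(backbone[j] in PCG_NAMES for j in arc)
        if flipped:
            classification[gene] = "inverted-translocation"
        else:
            classification[gene] = "translocation" if crossed_pcg else "shuffling"

    flanking: dict[str, tuple[int | None, int | None]] = {}
    if query_record is not None and len(query_record.features) >= 2:
        report = compute_gaps(query_record)
        up_of = {g.downstream: g.igs for g in report.gaps}
        down_of = {g.upstream: g.igs for g in report.gaps}
        for gene in moved:
            flanking[gene] = (up_of.get(gene), down_of.get(gene))
    else:
        flanking = {gene: (None, None) for gene in moved}

    return RearrangementReport(breakpoints=breakpoints, moved_genes=moved,
                               classification=classification, flanking_spacers=flanking)
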