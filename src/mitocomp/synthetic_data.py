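"""Seeded generator of annotated circular mitogenomes.

Emulates the statistical structure of a cockroach-like insect mitogenome —
circular topology, 37 genes plus control region on two strands, AT-rich
asymmetric base composition, synonymous codon bias, incomplete stop codons,
inserted spacers/overlaps, and applied rearrangement events — so that every
analysis stage in this package has download-free, fully controlled inputs.

Composition control: coding sequence is drawn codon-wise from a product
distribution over bases *calibrated* so that, after conditioning on not
producing a stop codon, the realised base frequencies match the requested
genome-strand composition.  Light-strand genes are drawn from the
complement-swapped composition so the deposited strand stays on target.
Spacers and the control region are drawn from a more AT-rich D-loop-like
composition, echoing the elevated AT content of real insect control regions.

All randomness flows from a single :class:`numpy.random.Generator` derived
from the spec's integer seed; identical specs produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .annotation_io import (
    GeneFeature,
    MitogenomeRecord,
    load_reference_annotation,
    reverse_complement,
)
from .codon_usage import (
    CODON_FAMILY,
    FAMILY_MEMBERS,
    SENSE_CODONS,
    STOP_CODONS,
    stop_nt_of,
    translate,
)
from .config import CONTROL_REGION, PCG_NAMES, feature_class_of
from .errors import ValidationError
from .genome_architecture import ANCESTRAL_ORDER, GeneOrder

BASES = "ACGT"

#: Whole-genome composition target (A, C, G, T), mirroring an AT-rich
#: cockroach mitogenome (45.2% A, 16.06% C, 9.74% G, 29.0% T).
DEFAULT_COMPOSITION: tuple[float, float, float, float] = (0.452, 0.1606, 0.0974, 0.29)

#: D-loop-like composition used for spacers and the control region
#: (AT ~77.5%, strongly positive AT skew, negative GC skew).
DLOOP_COMPOSITION: tuple[float, float, float, float] = (0.531, 0.171, 0.054, 0.244)

DEFAULT_CR_LENGTH = 240


@lru_cache(maxsize=8)
def _reference_plans() -> tuple[dict[str, int], dict[str, str], dict[str, str], dict[str, str]]:
    """Per-gene default lengths / start codons / stop tokens / anticodons,
    taken from the packaged reference annotation."""
    ref = load_reference_annotation()
    lengths = {f.name: f.size for f in ref.features if f.name != CONTROL_REGION}
    starts = {f.name: f.start_codon for f in ref.features if f.start_codon}
    stops = {f.name: f.stop_codon for f in ref.features if f.stop_codon}
    anticodons = {f.name: f.anticodon for f in ref.features if f.anticodon}
    return lengths, starts, stops, anticodons


# ---------------------------------------------------------------------------
# Rearrangement events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoveEvent:
    """Relocate one gene to just after ``new_upstream``; ``spacers`` are the
    intergenic spacer lengths inserted on each side of the moved gene."""

    gene: str
    new_upstream: str
    spacers: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class InversionEvent:
    gene: str


@dataclass(frozen=True)
class TdrlEvent:
    """Tandem-duplication-random-loss over the arc [first..last]; when
    ``keep_mask`` is None the surviving copy of each gene is drawn uniformly."""

    first: str
    last: str
    keep_mask: dict[str, int] | None = None


RearrangementEvent = MoveEvent | InversionEvent | TdrlEvent


@dataclass
class SyntheticGenomeSpec:
    """Full description of one synthetic annotated mitogenome."""

    seed: int = 0
    record_id: str = "synthetic"
    base_composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION
    dloop_composition: tuple[float, float, float, float] = DLOOP_COMPOSITION
    gene_order: GeneOrder | str = "ancestral"
    rearrangement_events: tuple[RearrangementEvent, ...] = ()
    per_gene_lengths: dict[str, int] = field(default_factory=lambda: dict(_reference_plans()[0]))
    start_codon_plan: dict[str, str] = field(default_factory=lambda: dict(_reference_plans()[1]))
    stop_codon_plan: dict[str, str] = field(default_factory=lambda: dict(_reference_plans()[2]))
    anticodon_plan: dict[str, str] = field(default_factory=lambda: dict(_reference_plans()[3]))
    #: NNA weight within four-codon synonymous families; None = codon usage
    #: driven purely by the composition target.
    codon_bias: float | None = None
    #: signed spacer length keyed by downstream gene ("trnI" keys the
    #: origin-wrapping gap, "CR" the gap before the control region).
    spacer_plan: dict[str, int] = field(default_factory=dict)
    cr_length: int = DEFAULT_CR_LENGTH
    include_cr: bool = True

    def validate(self) -> None:
        comp = np.asarray(self.base_composition, float)
        if comp.min() < 0 or abs(comp.sum() - 1) > 1e-6:
            raise ValidationError("base_composition must be non-negative and sum to 1")
        for gene in PCG_NAMES:
            length = self.per_gene_lengths[gene]
            stop = self.stop_codon_plan.get(gene, "TAA")
            if (length - stop_nt_of(stop)) % 3 != 0:
                raise ValidationError(
                    f"{gene}: length {length} incompatible with stop plan {stop!r}")
        if self.codon_bias is not None and not (0 <= self.codon_bias <= 1):
            raise ValidationError("codon_bias must be in [0, 1]")


# ---------------------------------------------------------------------------
# Composition-calibrated codon sampling
# ---------------------------------------------------------------------------

_CODON_BASE_COUNTS = np.array(
    [[c.count(b) for b in BASES] for c in SENSE_CODONS], dtype=float)


@lru_cache(maxsize=32)
def _sense_codon_distribution(comp: tuple[float, ...]) -> tuple[float, ...]:
    """Distribution over the 62 sense codons whose conditional (non-stop)
    product sampling reproduces ``comp`` as per-base frequencies."""
    target = np.asarray(comp, float)
    target = target / target.sum()
    q = target.copy()
    idx = np.array([[BASES.index(b) for b in c] for c in SENSE_CODONS])
    for _ in range(200):
        p = q[idx[:, 0]] * q[idx[:, 1]] * q[idx[:, 2]]
        p /= p.sum()
        achieved = (p[:, None] * _CODON_BASE_COUNTS).sum(axis=0) / 3
        ratio = np.where(achieved > 0, target / achieved, 1.0)
        q = np.clip(q * ratio, 1e-9, None)
        q /= q.sum()
    p = q[idx[:, 0]] * q[idx[:, 1]] * q[idx[:, 2]]
    return tuple(p / p.sum())


def _swap_complement(comp: tuple[float, ...]) -> tuple[float, ...]:
    a, c, g, t = comp
    return (t, g, c, a)


def random_sequence(rng: np.random.Generator, length: int,
                    comp: tuple[float, ...]) -> str:
    p = np.asarray(comp, float)
    draws = rng.choice(4, size=length, p=p / p.sum())
    return "".join(BASES[i] for i in draws)


def random_codons(rng: np.random.Generator, n: int, comp: tuple[float, ...],
                  codon_bias: float | None = None) -> list[str]:
    """Sample sense codons; optional NNA enrichment in 4-fold families."""
    p = np.asarray(_sense_codon_distribution(tuple(comp)))
    codons = [SENSE_CODONS[i] for i in rng.choice(len(SENSE_CODONS), size=n, p=p)]
    if codon_bias is None:
        return codons
    out = []
    for codon in codons:
        members = FAMILY_MEMBERS[CODON_FAMILY[codon]]
        if len(members) == 4:
            nna = next((m for m in members if m.endswith("A")), None)
            if nna is not None:
                if rng.random() < codon_bias:
                    codon = nna
                else:
                    others = [m for m in members if m != nna]
                    codon = others[rng.integers(len(others))]
        out.append(codon)
    return out


def random_cds(rng: np.random.Generator, length: int, comp: tuple[float, ...],
               start_codon: str = "ATG", stop_token: str = "TAA",
               codon_bias: float | None = None) -> str:
    """A legal CDS of exactly ``length`` nt: fixed start, sampled internal
    codons (no in-frame stops by construction), complete or truncated stop."""
    stop_nt = stop_nt_of(stop_token)
    if (length - stop_nt) % 3 != 0 or length < 6:
        raise ValidationError(f"CDS length {length} incompatible with stop {stop_token!r}")
    n_internal = (length - stop_nt) // 3 - 1
    body = random_codons(rng, n_internal, comp, codon_bias)
    terminator = {"TA*": "TA", "T**": "T"}.get(stop_token, stop_token)
    return start_codon + "".join(body) + terminator


# ---------------------------------------------------------------------------
# Gene-order editing
# ---------------------------------------------------------------------------

def apply_move(order: GeneOrder, event: MoveEvent) -> GeneOrder:
    entries = [e for e in order.genes if e[0] != event.gene]
    sign = order.sign_of(event.gene)
    at = next(i for i, (g, _) in enumerate(entries) if g == event.new_upstream) + 1
    return GeneOrder(tuple(entries[:at] + [(event.gene, sign)] + entries[at:]))


def apply_tdrl(order: GeneOrder, segment: tuple[str, str],
               keep_mask: dict[str, int] | None = None,
               rng: np.random.Generator | None = None) -> GeneOrder:
    """Tandem-duplication-random-loss: duplicate the contiguous arc
    ``segment`` in place, then delete one copy of each duplicated gene.

    ``keep_mask`` maps each segment gene to 1 (keep the first copy) or 2
    (keep the second); it must name every segment gene exactly once.  When
    None, copies are chosen uniformly at random (``rng`` required).
    """
    names = list(order.names)
    first, last = segment
    i, j = names.index(first), names.index(last)
    n = len(names)
    span = [(i + k) % n for k in range(((j - i) % n) + 1)]
    seg_genes = [order.genes[k] for k in span]
    seg_names = [g for g, _ in seg_genes]
    if keep_mask is None:
        if rng is None:
            raise ValidationError("random keep_mask requires an rng")
        keep_mask = {g: int(rng.integers(1, 3)) for g in seg_names}
    if set(keep_mask) != set(seg_names) or any(v not in (1, 2) for v in keep_mask.values()):
        raise ValidationError(
            "keep_mask must keep exactly one copy (1 or 2) of every duplicated gene")
    copy1 = [e for e in seg_genes if keep_mask[e[0]] == 1]
    copy2 = [e for e in seg_genes if keep_mask[e[0]] == 2]
    # survivors of copy 1, then survivors of copy 2, then the untouched arc
    new_entries = copy1 + copy2
    tail = []
    k = (span[-1] + 1) % n
    while k != span[0]:
        tail.append(order.genes[k])
        k = (k + 1) % n
    return GeneOrder(tuple(new_entries + tail))


def resolve_gene_order(spec: SyntheticGenomeSpec,
                       rng: np.random.Generator | None = None) -> GeneOrder:
    order = ANCESTRAL_ORDER if spec.gene_order == "ancestral" else spec.gene_order
    for event in spec.rearrangement_events:
        if isinstance(event, MoveEvent):
            order = apply_move(order, event)
        elif isinstance(event, InversionEvent):
            order = GeneOrder(tuple(
                (g, -s) if g == event.gene else (g, s) for g, s in order.genes))
        elif isinstance(event, TdrlEvent):
            order = apply_tdrl(order, (event.first, event.last), event.keep_mask, rng)
        else:  # pragma: no cover
            raise ValidationError(f"unknown rearrangement event {event!r}")
    return order


def _effective_spacers(spec: SyntheticGenomeSpec, order: GeneOrder) -> dict[str, int]:
    spacers = dict(spec.spacer_plan)
    names = order.names
    for event in spec.rearrangement_events:
        if isinstance(event, MoveEvent) and event.spacers != (0, 0):
            i = names.index(event.gene)
            following = names[(i + 1) % len(names)]
            spacers.setdefault(event.gene, event.spacers[0])
            spacers.setdefault(following, event.spacers[1])
    return spacers


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(spec: SyntheticGenomeSpec, with_sequence: bool = True) -> MitogenomeRecord:
    """Emit a fully annotated (optionally sequenced) circular mitogenome.

    The layout walks the resolved gene order starting with trnI at position 1,
    placing each feature after the signed spacer that precedes it; the control
    region is inserted between rrnS and the origin.  Feature sequences honour
    strand, start/stop plans and composition targets; overlapping features
    share genome bases (the downstream feature's sequence wins in the overlap,
    as in real overlapping mitochondrial genes).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = resolve_gene_order(spec, rng)
    spacers = _effective_spacers(spec, order)

    layout: list[tuple[str, int]] = list(order.genes)
    if spec.include_cr:
        at = next(i for i, (g, _) in enumerate(layout) if g == "rrnS") + 1
        layout.insert(at, (CONTROL_REGION, +1))

    features: list[GeneFeature] = []
    prev_end = 0
    for gene, sign in layout:
        size = spec.cr_length if gene == CONTROL_REGION else spec.per_gene_lengths[gene]
        start = 1 if not features else prev_end + spacers.get(gene, 0) + 1
        end = start + size - 1
        features.append(GeneFeature(
            name=gene,
            feature_class=feature_class_of(gene),
            strand="H" if sign > 0 else "L",
            start=start, end=end, size=size,
            anticodon=spec.anticodon_plan.get(gene),
            start_codon=spec.start_codon_plan.get(gene) if gene in PCG_NAMES else None,
            stop_codon=spec.stop_codon_plan.get(gene) if gene in PCG_NAMES else None,
        ))
        prev_end = end
    wrap_spacer = spacers.get(layout[0][0], 0)
    if wrap_spacer < 0:
        raise ValidationError(
            "the origin-wrapping spacer cannot be negative (features may not "
            "overlap across the origin)")
    genome_length = max(f.end for f in features) + wrap_spacer

    sequence = None
    if with_sequence:
        buf = np.frombuffer(
            random_sequence(rng, genome_length, spec.dloop_composition).encode(),
            dtype="S1").copy()
        for f in features:
            if f.feature_class == "PCG":
                comp = (spec.base_composition if f.strand == "H"
                        else _swap_complement(spec.base_composition))
                gene_seq = random_cds(rng, f.size, comp,
                                      start_codon=spec.start_codon_plan.get(f.name, "ATG"),
                                      stop_token=spec.stop_codon_plan.get(f.name, "TAA"),
                                      codon_bias=spec.codon_bias)
                segment = gene_seq if f.strand == "H" else reverse_complement(gene_seq)
            elif f.feature_class == "CR":
                segment = random_sequence(rng, f.size, spec.dloop_composition)
            else:
                segment = random_sequence(rng, f.size, spec.base_composition)
            buf[f.start - 1:f.end] = np.frombuffer(segment.encode(), dtype="S1")
        sequence = buf.tobytes().decode()

    return MitogenomeRecord(spec.record_id, genome_length, features, sequence)


def table2_mirror_spec(seed: int = 0, **overrides) -> SyntheticGenomeSpec:
    """A spec whose layout reproduces the reference annotation exactly:
    the observed gene order (trnS1 between nad3 and trnA) with every printed
    signed spacer, so recomputed gap totals match the published IGS column."""
    from .genome_architecture import compute_gaps, gene_order as order_of

    ref = load_reference_annotation()
    gaps = {g.downstream: g.igs for g in compute_gaps(ref).gaps}
    return SyntheticGenomeSpec(
        seed=seed,
        record_id="synthetic_mirror",
        gene_order=order_of(ref),
        spacer_plan=gaps,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Codon-substitution simulation for related records
# ---------------------------------------------------------------------------

def evolve_pair(record: MitogenomeRecord, omega_plan: dict[str, float] | float,
                divergence: float, seed: int,
                record_id: str | None = None) -> MitogenomeRecord:
    """Derive a diverged relative by codon-substitution simulation.

    Proposals are uniform over single-base changes in the internal codons of
    every protein-coding gene (the start codon and terminator are kept so the
    annotation stays valid); synonymous proposals are always accepted,
    non-synonymous ones with probability omega, stop-creating ones rejected.
    ``divergence`` is the expected number of proposals per coding nucleotide
    site.  Non-coding regions are left untouched.
    """
    from .annotation_io import extract_gene_sequence

    if record.sequence is None:
        raise ValidationError("evolve_pair requires a sequenced record")
    omegas = ({g: float(omega_plan) for g in PCG_NAMES}
              if isinstance(omega_plan, (int, float)) else dict(omega_plan))
    if any(w < 0 for w in omegas.values()):
        raise ValidationError("omega must be non-negative")
    rng = np.random.default_rng(seed)
    buf = np.frombuffer(record.sequence.encode(), dtype="S1").copy()

    for f in record.features:
        if f.feature_class != "PCG" or f.name not in omegas:
            continue
        omega = omegas[f.name]
        cds = extract_gene_sequence(record, f.name)
        stop_nt = len(cds) % 3 or 3
        n_res = (len(cds) - stop_nt) // 3
        codons = [cds[i:i + 3] for i in range(0, 3 * n_res, 3)]
        mutable = list(range(1, n_res))  # codon 0 is the annotated start
        n_prop = rng.poisson(divergence * 3 * len(mutable))
        for _ in range(n_prop):
            ci = mutable[rng.integers(len(mutable))]
            pos = int(rng.integers(3))
            old = codons[ci]
            alts = [b for b in BASES if b != old[pos]]
            new = old[:pos] + alts[rng.integers(3)] + old[pos + 1:]
            if new in STOP_CODONS:
                continue
            if translate(new) != translate(old) and rng.random() >= omega:
                continue
            codons[ci] = new
        new_cds = "".join(codons) + cds[3 * n_res:]
        segment = new_cds if f.strand == "H" else reverse_complement(new_cds)
        buf[f.start - 1:f.end] = np.frombuffer(segment.encode(), dtype="S1")

    return MitogenomeRecord(record_id or f"{record.record_id}_derived",
                            record.genome_length, record.features,
                            buf.tobytes().decode())
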