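"""Base composition, AT content and AT/GC strand skews.

Skews follow the standard mitogenomics definitions

    AT skew = (A - T) / (A + T),    GC skew = (G - C) / (G + C)

computed on the deposited (majority/heavy) strand regardless of which strand
individual genes are encoded on: a single per-class skew value is only
well-defined under one fixed strand convention, and this is the dominant
convention in mitogenome reports.  Overlapping features contribute their full
spans to their own classes, so a base may be counted in two classes; class
size columns then match per-feature size sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .annotation_io import MitogenomeRecord
from .errors import ValidationError

#: region_summary row order (class label -> feature_class key)
REGION_CLASSES = (("PCGs", "PCG"), ("tRNAs", "tRNA"), ("rRNAs", "rRNA"), ("D-loop", "CR"))


@dataclass(frozen=True)
class CompositionStats:
    """Exact base counts plus derived proportions for one region."""

    region_label: str
    a: int
    c: int
    g: int
    t: int
    n: int = 0

    @property
    def total(self) -> int:
        """Counted A+C+G+T bases (N excluded from every denominator)."""
        return self.a + self.c + self.g + self.t

    @property
    def fraction_a(self) -> float:
        return self.a / self.total

    @property
    def fraction_c(self) -> float:
        return self.c / self.total

    @property
    def fraction_g(self) -> float:
        return self.g / self.total

    @property
    def fraction_t(self) -> float:
        return self.t / self.total

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.total

    @property
    def at_skew(self) -> float:
        """(A - T)/(A + T); NaN when A + T == 0 (undefined, not zero)."""
        if self.a + self.t == 0:
            return math.nan
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float:
        """(G - C)/(G + C); NaN when G + C == 0."""
        if self.g + self.c == 0:
            return math.nan
        return (self.g - self.c) / (self.g + self.c)


def base_composition(seq: str, region_label: str = "") -> CompositionStats:
    """Exact base counts of a sequence over {A,C,G,T,N}.

    N is tallied separately and excluded from all proportions.  Any other
    character is a hard error.
    """
    if not seq:
        raise ValidationError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    if sum(counts.values()) != len(seq):
        offenders = sorted(set(seq) - set("ACGTN"))
        raise ValidationError(f"sequence contains non-ACGTN characters: {offenders}")
    return CompositionStats(region_label, counts["A"], counts["C"], counts["G"],
                            counts["T"], counts["N"])


def skews(stats: CompositionStats) -> tuple[float, float]:
    """(AT skew, GC skew); an undefined skew is returned as NaN."""
    return stats.at_skew, stats.gc_skew


def region_summary(record: MitogenomeRecord) -> pd.DataFrame:
    """Per-class composition table (Table 1 / Table 3 analogue).

    For each feature class the member subsequences are concatenated from the
    deposited strand in genome order (no strand flipping) and summarised; a
    Genome row covers the full sequence.  Classes with no members are omitted
    with a warning.  Columns: region, size_bp, at_pct, at_skew, gc_skew plus
    raw fractions.
    """
    if record.sequence is None:
        raise ValidationError(f"{record.record_id}: region_summary requires a sequence")
    rows = []
    for label, fclass in REGION_CLASSES:
        members = record.features_of_class(fclass)
        if not members:
            warnings.warn(f"{record.record_id}: no {label} features; row omitted")
            continue
        chunks = []
        for f in members:
            if f.wraps_origin:
                chunks.append(record.sequence[f.start - 1:] + record.sequence[:f.end])
            else:
                chunks.append(record.sequence[f.start - 1:f.end])
        stats = base_composition("".join(chunks), label)
        rows.append((label, sum(f.size for f in members), stats))
    genome = base_composition(record.sequence, "Genome")
    rows.append(("Genome", record.genome_length, genome))
    return pd.DataFrame({
        "region": [r[0] for r in rows],
        "size_bp": [r[1] for r in rows],
        "at_pct": [100 * r[2].at_content for r in rows],
        "at_skew": [r[2].at_skew for r in rows],
        "gc_skew": [r[2].gc_skew for r in rows],
        "frac_a": [r[2].fraction_a for r in rows],
        "frac_c": [r[2].fraction_c for r in rows],
        "frac_g": [r[2].fraction_g for r in rows],
        "frac_t": [r[2].fraction_t for r in rows],
    })


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal-style half-up rounding used when rendering report tables."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
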