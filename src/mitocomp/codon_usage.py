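"""Codon-level statistics under the invertebrate mitochondrial genetic code.

Uses NCBI translation table 5 (AGA/AGG = Ser, AUA = Met, UGA = Trp) throughout.
Synonymous families split the two-copy isoacceptor pairs the way mitogenome
codon-usage figures conventionally do: Ser into S1 = AGN and S2 = UCN, Leu
into L1 = CUN and L2 = UUR.

Mitochondrial open reading frames frequently end on an incomplete terminator
(``TA*`` or ``T**``) completed to UAA by post-transcriptional polyadenylation;
:func:`classify_codons` recognises these from the CDS length modulo 3 and the
terminal bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product

from Bio.Data import CodonTable

from .annotation_io import GeneFeature
from .errors import ValidationError

#: NCBI translation table 5, invertebrate mitochondrial.
TABLE5 = CodonTable.unambiguous_dna_by_id[5]
STOP_CODONS: frozenset[str] = frozenset(TABLE5.stop_codons)  # {TAA, TAG}
ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product("TCAG", repeat=3))
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: Start codons observed in insect mitogenomes.
MITO_START_CODONS: frozenset[str] = frozenset({"ATG", "ATA", "ATT", "TTG", "GTG"})

COMPLETE_STOPS = ("TAA", "TAG")
INCOMPLETE_STOPS = ("TA*", "T**")


def translate(codon: str) -> str:
    """One-letter amino acid under table 5; '*' for a stop."""
    return "*" if codon in STOP_CODONS else TABLE5.forward_table[codon]


def _family_table() -> dict[str, str]:
    fam: dict[str, str] = {}
    for codon in SENSE_CODONS:
        aa = translate(codon)
        if aa == "S":
            fam[codon] = "Ser(AGN)" if codon.startswith("AG") else "Ser(UCN)"
        elif aa == "L":
            fam[codon] = "Leu(UUR)" if codon.startswith("TT") else "Leu(CUN)"
        else:
            fam[codon] = aa
    return fam


#: codon -> synonymous-family label (S1/S2 and L1/L2 split).
CODON_FAMILY: dict[str, str] = _family_table()

#: family label -> member codons.
FAMILY_MEMBERS: dict[str, tuple[str, ...]] = {
    label: tuple(c for c in SENSE_CODONS if CODON_FAMILY[c] == label)
    for label in dict.fromkeys(CODON_FAMILY.values())
}


@dataclass(frozen=True)
class CodonAnnotation:
    """Start/stop classification and residue count for one coding gene."""

    gene: str
    start_codon: str
    stop_codon: str      # "TAA"/"TAG" or "TA*"/"T**"
    n_residues: int
    stop_nt: int         # nucleotides devoted to the terminator (1, 2 or 3)


def stop_nt_of(stop_token: str) -> int:
    if stop_token in COMPLETE_STOPS:
        return 3
    if stop_token == "TA*":
        return 2
    if stop_token == "T**":
        return 1
    raise ValidationError(f"unrecognised stop token {stop_token!r}")


def classify_codons(cds: str, gene: str = "?") -> CodonAnnotation:
    """Classify start and (possibly incomplete) stop codon of a CDS.

    The terminator type follows from len(cds) mod 3: remainder 0 needs a
    complete TAA/TAG, remainder 2 a trailing "TA", remainder 1 a trailing "T".
    Any other ending is a hard error naming the gene.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 6:
        raise ValidationError(f"{gene}: CDS too short ({len(cds)} nt)")
    rem = len(cds) % 3
    if rem == 0:
        if cds[-3:] not in COMPLETE_STOPS:
            raise ValidationError(
                f"{gene}: length % 3 == 0 but terminal codon {cds[-3:]} is not TAA/TAG")
        stop, stop_nt = cds[-3:], 3
    elif rem == 2:
        if cds[-2:] != "TA":
            raise ValidationError(
                f"{gene}: length % 3 == 2 but sequence ends {cds[-2:]!r}, not 'TA'")
        stop, stop_nt = "TA*", 2
    else:
        if cds[-1] != "T":
            raise ValidationError(
                f"{gene}: length % 3 == 1 but sequence ends {cds[-1]!r}, not 'T'")
        stop, stop_nt = "T**", 1
    return CodonAnnotation(gene=gene, start_codon=cds[:3], stop_codon=stop,
                           n_residues=(len(cds) - stop_nt) // 3, stop_nt=stop_nt)


def annotation_from_feature(feature: GeneFeature) -> CodonAnnotation:
    """CodonAnnotation from annotation metadata alone (no sequence needed).

    Uses the feature's declared size and stop token; the residue count is
    (size - stop_nt) / 3.
    """
    if feature.stop_codon is None:
        raise ValidationError(f"{feature.name}: no stop codon recorded in annotation")
    stop_nt = stop_nt_of(feature.stop_codon)
    if (feature.size - stop_nt) % 3 != 0:
        raise ValidationError(
            f"{feature.name}: size {feature.size} inconsistent with stop {feature.stop_codon}")
    return CodonAnnotation(gene=feature.name, start_codon=feature.start_codon or "?",
                           stop_codon=feature.stop_codon,
                           n_residues=(feature.size - stop_nt) // 3, stop_nt=stop_nt)


def total_residues(annotations: list[CodonAnnotation]) -> tuple[int, int]:
    """(total amino-acid residues, total stop-codon nucleotides)."""
    return (sum(a.n_residues for a in annotations),
            sum(a.stop_nt for a in annotations))


def internal_codons(cds: str, gene: str = "?") -> list[str]:
    """All codons of a CDS except the (possibly incomplete) terminator.

    The start codon is included as an ordinary codon.  An in-frame internal
    stop is a hard error naming the gene and codon position.
    """
    ann = classify_codons(cds, gene)
    coding = cds.upper().replace("U", "T")[:3 * ann.n_residues]
    codons = [coding[i:i + 3] for i in range(0, len(coding), 3)]
    for pos, codon in enumerate(codons, start=1):
        if codon in STOP_CODONS:
            raise ValidationError(f"{gene}: internal stop codon {codon} at codon {pos}")
    return codons


@dataclass
class CodonUsageTable:
    """Pooled codon counts and RSCU values (stop codons excluded)."""

    codon_counts: dict[str, int]
    rscu: dict[str, float]
    family: dict[str, str]

    @property
    def total_codons(self) -> int:
        return sum(self.codon_counts.values())

    def to_rows(self) -> list[tuple[str, str, int, float]]:
        return [(c, self.family[c], self.codon_counts[c], self.rscu[c])
                for c in SENSE_CODONS]


def rscu(cds_set: list[str], genes: list[str] | None = None) -> CodonUsageTable:
    """Relative synonymous codon usage pooled over a set of CDSs.

    RSCU(c) = k * n_c / sum over the k-codon synonymous family of n.  A codon
    never observed in an observed family has RSCU 0; families with zero
    observations have all RSCU 0.  Incomplete terminators are dropped by
    codon extraction; complete terminators are excluded by construction.
    """
    genes = genes or [f"cds{i}" for i in range(len(cds_set))]
    counts: Counter[str] = Counter()
    for cds, gene in zip(cds_set, genes):
        counts.update(internal_codons(cds, gene))
    values: dict[str, float] = {}
    for label, members in FAMILY_MEMBERS.items():
        family_total = sum(counts[c] for c in members)
        for c in members:
            values[c] = len(members) * counts[c] / family_total if family_total else 0.0
    return CodonUsageTable(codon_counts={c: counts[c] for c in SENSE_CODONS},
                           rscu=values, family=dict(CODON_FAMILY))
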