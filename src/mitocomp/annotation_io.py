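"""Reading and writing annotated mitogenomes.

Supported formats: GenBank flat files (via Biopython), Table-2-style TSV
annotation tables (gene, strand, start, end, size, igs, anticodon,
start_codon, stop_codon), and FASTA for raw sequence.  Everything downstream
of this module consumes :class:`MitogenomeRecord` only; no other module knows
about file formats.

Coordinates are 1-based, fully closed (GenBank convention).  The deposited
strand is treated as the heavy/majority strand ("H"); features on the light
strand ("L") are reverse-complemented by :func:`extract_gene_sequence` for all
codon-level analyses.  A feature whose end precedes its start wraps the
origin of the circular molecule.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .config import (
    CONTROL_REGION,
    GENE_ALPHABET,
    feature_class_of,
    normalize_gene_name,
)
from .errors import ParseError, ValidationError

TSV_COLUMNS = ("gene", "strand", "start", "end", "size", "igs",
               "anticodon", "start_codon", "stop_codon")

_CLASS_TO_GENBANK_KEY = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
_GENBANK_KEY_TO_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                         "D-loop": "CR", "D_loop": "CR", "misc_feature": "CR"}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on a circular mitogenome.

    ``stop_codon`` is either a complete terminator (``TAA``/``TAG``) or one of
    the incomplete tokens ``TA*`` / ``T**`` completed to UAA by
    post-transcriptional polyadenylation.
    """

    name: str
    feature_class: str  # {PCG, tRNA, rRNA, CR}
    strand: str         # {H, L}
    start: int          # 1-based
    end: int            # 1-based inclusive
    size: int
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValidationError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if self.start < 1:
            raise ValidationError(f"{self.name}: start must be >= 1, got {self.start}")
        if not self.wraps_origin and self.size != self.end - self.start + 1:
            raise ValidationError(
                f"{self.name}: size {self.size} != end - start + 1 = {self.end - self.start + 1}"
            )
        if self.anticodon is not None and self.feature_class != "tRNA":
            raise ValidationError(f"{self.name}: anticodon given for non-tRNA feature")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start


@dataclass
class MitogenomeRecord:
    """A circular annotated mitochondrial genome."""

    record_id: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: f.start)
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate gene name(s): {sorted(dupes)}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) != self.genome_length:
                raise ValidationError(
                    f"sequence length {len(self.sequence)} != genome_length {self.genome_length}"
                )
        for f in self.features:
            if max(f.start, f.end) > self.genome_length:
                raise ValidationError(
                    f"{f.name}: coordinates exceed genome length {self.genome_length}"
                )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise ValidationError(f"{self.record_id}: no feature named {name!r}")

    def features_of_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]


def extract_gene_sequence(record: MitogenomeRecord, name: str) -> str:
    """Strand-corrected nucleotide sequence of one feature.

    Returns the reverse complement for light-strand features and handles
    features wrapping the origin of the circle.
    """
    if record.sequence is None:
        raise ValidationError(f"{record.record_id}: record has no sequence")
    f = record.feature(name)
    if f.wraps_origin:
        raw = record.sequence[f.start - 1:] + record.sequence[:f.end]
    else:
        raw = record.sequence[f.start - 1:f.end]
    return reverse_complement(raw) if f.strand == "L" else raw


def rotate_record(record: MitogenomeRecord, offset: int) -> MitogenomeRecord:
    """Rotate the circular coordinate system by ``offset`` nucleotides.

    Position 1 of the result corresponds to position ``offset + 1`` of the
    input.  Annotation and sequence stay mutually consistent; features may
    come to wrap the origin.
    """
    n = record.genome_length
    offset %= n

    def shift(pos: int) -> int:
        return (pos - 1 - offset) % n + 1

    feats = [replace(f, start=shift(f.start), end=shift(f.end)) for f in record.features]
    seq = None
    if record.sequence is not None:
        seq = record.sequence[offset:] + record.sequence[:offset]
    return MitogenomeRecord(record.record_id, n, feats, seq, record.circular)


# ---------------------------------------------------------------------------
# TSV annotation tables
# ---------------------------------------------------------------------------

def _parse_int(token: str, context: str) -> int:
    try:
        return int(token.replace(",", "").strip())
    except ValueError as exc:
        raise ParseError(f"{context}: cannot parse integer from {token!r}") from exc


def parse_annotation_table(text: str, record_id: str = "annotation") -> MitogenomeRecord:
    """Parse a Table-2-dialect TSV annotation table.

    Thousands separators in coordinates are stripped.  An ``igs`` column, if
    present, is ignored on input (spacers are always recomputed from
    coordinates; see :mod:`mitocomp.genome_architecture`) but compared against
    the recomputed values, with a warning on any mismatch.  Gene names are
    normalized onto the canonical alphabet.
    """
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        return MitogenomeRecord(record_id, 0, [])
    header = [h.strip().lower() for h in rows[0]]
    required = {"gene", "strand", "start", "end", "size"}
    if not required.issubset(header):
        raise ParseError(f"annotation table header missing columns: {sorted(required - set(header))}")
    idx = {col: header.index(col) for col in header}

    def cell(row: list[str], col: str) -> str:
        i = idx.get(col)
        return row[i].strip() if i is not None and i < len(row) else ""

    features: list[GeneFeature] = []
    stated_igs: dict[str, int] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        raw_name = cell(row, "gene")
        name = normalize_gene_name(raw_name)
        if name is None:
            warnings.warn(f"line {lineno}: unknown gene name {raw_name!r} kept verbatim")
            name = raw_name
            fclass = "CR"
        else:
            fclass = feature_class_of(name)
        strand_tok = cell(row, "strand")
        strand = {"H": "H", "L": "L", "+": "H", "-": "L", "": "H"}.get(strand_tok.upper())
        if strand is None:
            raise ParseError(f"line {lineno} ({raw_name}): bad strand {strand_tok!r}")
        start = _parse_int(cell(row, "start"), f"line {lineno} start")
        end = _parse_int(cell(row, "end"), f"line {lineno} end")
        size = _parse_int(cell(row, "size"), f"line {lineno} size")
        if end >= start and size != end - start + 1:
            raise ParseError(
                f"line {lineno} ({raw_name}): size {size} != end - start + 1 = {end - start + 1}"
            )
        igs_tok = cell(row, "igs")
        if igs_tok not in ("", "-"):
            stated_igs[name] = _parse_int(igs_tok, f"line {lineno} igs")
        features.append(GeneFeature(
            name=name, feature_class=fclass, strand=strand, start=start, end=end, size=size,
            anticodon=cell(row, "anticodon") or None,
            start_codon=cell(row, "start_codon") or None,
            stop_codon=cell(row, "stop_codon") or None,
        ))
    genome_length = max(f.end for f in features)
    record = MitogenomeRecord(record_id, genome_length, features)
    if stated_igs:
        from .genome_architecture import compute_gaps
        recomputed = {g.downstream: g.igs for g in compute_gaps(record).gaps}
        for name, stated in stated_igs.items():
            if name in recomputed and recomputed[name] != stated:
                warnings.warn(
                    f"{name}: stated IGS {stated} != recomputed {recomputed[name]}; "
                    "recomputed value is used"
                )
    return record


def write_annotation_table(record: MitogenomeRecord) -> str:
    """Serialize a record to the canonical 9-column TSV (IGS recomputed)."""
    igs: dict[str, int] = {}
    if len(record.features) >= 2:
        from .genome_architecture import compute_gaps
        igs = {g.downstream: g.igs for g in compute_gaps(record).gaps}
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(TSV_COLUMNS)
    for i, f in enumerate(record.features):
        writer.writerow([
            f.name, f.strand, f.start, f.end, f.size,
            "" if i == 0 else igs.get(f.name, ""),
            f.anticodon or "", f.start_codon or "", f.stop_codon or "",
        ])
    return out.getvalue()


def load_reference_annotation() -> MitogenomeRecord:
    """The packaged C. meridianus (MG518617) annotation table."""
    text = (resources.files("mitocomp") / "data" /
            "cryptocercus_meridianus_mg518617_annotation.tsv").read_text()
    return parse_annotation_table(text, record_id="MG518617")


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

def parse_genbank(text: str) -> MitogenomeRecord:
    """Parse a GenBank flat-file record into a :class:`MitogenomeRecord`.

    Gene names are normalized; ``complement(...)`` locations map to strand L;
    compound locations spanning the origin are folded into wrap-around
    coordinates.  Unknown gene names are kept with a warning, their class
    inferred from the feature key.
    """
    try:
        seqrec = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:
        raise ParseError(f"not a readable GenBank record: {exc}") from exc
    sequence = str(seqrec.seq).upper().replace("U", "T")
    genome_length = len(sequence)

    features: list[GeneFeature] = []
    seen: set[str] = set()
    # `gene` features typically duplicate CDS/tRNA/rRNA entries; take them
    # only for names not otherwise annotated.
    for pass_keys in (set(_GENBANK_KEY_TO_CLASS), {"gene"}):
        for feat in seqrec.features:
            if feat.type not in pass_keys:
                continue
            raw_name = None
            for qual in ("gene", "product", "note"):
                if qual in feat.qualifiers:
                    raw_name = feat.qualifiers[qual][0]
                    if normalize_gene_name(raw_name):
                        break
            if raw_name is None:
                continue
            name = normalize_gene_name(raw_name)
            if name is None:
                warnings.warn(f"unknown gene name {raw_name!r}; kept with inferred class")
                name = raw_name
                fclass = _GENBANK_KEY_TO_CLASS.get(feat.type, "CR")
            else:
                fclass = feature_class_of(name)
            if name in seen:
                if feat.type == "gene":
                    continue
                raise ParseError(f"duplicate canonical gene name: {name}")
            seen.add(name)
            strand = "L" if feat.location.strand == -1 else "H"
            parts = feat.location.parts
            if len(parts) > 1 and int(parts[0].end) == genome_length:
                start = int(parts[0].start) + 1  # wraps the origin
                end = int(parts[-1].end)
                size = (genome_length - start + 1) + end
            else:
                start = int(feat.location.start) + 1
                end = int(feat.location.end)
                size = end - start + 1
            if max(start, end) > genome_length:
                raise ParseError(f"{name}: feature beyond sequence length {genome_length}")
            anticodon = start_codon = stop_codon = None
            for note in feat.qualifiers.get("note", []):
                for item in note.split(";"):
                    key, _, val = item.strip().partition("=")
                    if key == "anticodon":
                        anticodon = val
                    elif key == "start_codon":
                        start_codon = val
                    elif key == "stop_codon":
                        stop_codon = val
            features.append(GeneFeature(name, fclass, strand, start, end, size,
                                        anticodon if fclass == "tRNA" else None,
                                        start_codon, stop_codon))
    return MitogenomeRecord(seqrec.id or seqrec.name, genome_length, features,
                            sequence or None)


def write_genbank(record: MitogenomeRecord) -> str:
    """Serialize to a GenBank flat file (codon metadata stored in /note)."""
    seq = record.sequence if record.sequence is not None else "N" * record.genome_length
    seqrec = SeqRecord(Seq(seq), id=record.record_id, name=record.record_id[:16],
                       description="mitochondrial genome, complete sequence")
    seqrec.annotations.update({"molecule_type": "DNA", "topology": "circular",
                               "data_file_division": "INV"})
    for f in record.features:
        strand = -1 if f.strand == "L" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, record.genome_length, strand),
                FeatureLocation(0, f.end, strand),
            ])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        notes = [f"{key}={val}" for key, val in
                 (("anticodon", f.anticodon), ("start_codon", f.start_codon),
                  ("stop_codon", f.stop_codon)) if val]
        if notes:
            quals["note"] = ["; ".join(notes)]
        seqrec.features.append(SeqFeature(loc, type=_CLASS_TO_GENBANK_KEY[f.feature_class],
                                          qualifiers=quals))
    out = io.StringIO()
    SeqIO.write(seqrec, out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str]) -> str:
    out = []
    for name, seq in sequences.items():
        out.append(f">{name}")
        out.extend(seq[i:i + 70] for i in range(0, len(seq), 70))
    return "\n".join(out) + "\n"


def parse_fasta(text: str) -> dict[str, str]:
    try:
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    except Exception as exc:
        raise ParseError(f"not readable FASTA: {exc}") from exc
    return {r.id: str(r.seq).upper().replace("U", "T") for r in records}


def attach_sequence(record: MitogenomeRecord, sequence: str) -> MitogenomeRecord:
    return MitogenomeRecord(record.record_id, record.genome_length, record.features,
                            sequence, record.circular)
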