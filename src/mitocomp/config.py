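"""Canonical gene alphabet, name normalization, and the ancestral insect gene order.

Animal mitogenomes carry 13 protein-coding genes (PCGs), 22 tRNAs, two rRNAs
and one control region (CR / D-loop).  Depositor naming in GenBank is wildly
inconsistent (ND1 vs nad1, COI vs cox1, s-rRNA vs 12S ...), so every reader in
this package funnels names through :data:`GENE_NAME_ALIASES` before anything
else sees them.  The alias table is versioned so reports can record which
normalization was applied.
"""

from __future__ import annotations

NAME_TABLE_VERSION = "1.0"

#: The 13 protein-coding genes.
PCG_NAMES: tuple[str, ...] = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4L", "nad6", "cytb", "nad1",
)

#: The 22 tRNAs, keyed by amino acid with the two-copy isoacceptors split:
#: trnS1 = tRNA-Ser(AGN), trnS2 = tRNA-Ser(UCN), trnL1 = tRNA-Leu(CUN),
#: trnL2 = tRNA-Leu(UUR).
TRNA_NAMES: tuple[str, ...] = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)

RRNA_NAMES: tuple[str, ...] = ("rrnL", "rrnS")

CONTROL_REGION = "CR"

#: All 37 genes (control region excluded).
GENE_ALPHABET: frozenset[str] = frozenset(PCG_NAMES) | frozenset(TRNA_NAMES) | frozenset(RRNA_NAMES)

_AMINO3_TO_TRNA = {
    "Ile": "trnI", "Gln": "trnQ", "Met": "trnM", "Trp": "trnW", "Cys": "trnC",
    "Tyr": "trnY", "Lys": "trnK", "Asp": "trnD", "Gly": "trnG", "Ala": "trnA",
    "Arg": "trnR", "Asn": "trnN", "Glu": "trnE", "Phe": "trnF", "His": "trnH",
    "Thr": "trnT", "Pro": "trnP", "Val": "trnV",
}


def _alias_table() -> dict[str, str]:
    aliases: dict[str, str] = {}
    for canon in GENE_ALPHABET | {CONTROL_REGION}:
        aliases[canon.lower()] = canon
    # PCG synonyms
    for i in (1, 2, 3, 4, 5, 6):
        aliases[f"nd{i}"] = f"nad{i}"
        aliases[f"nadh{i}"] = f"nad{i}"
    aliases["nd4l"] = "nad4L"
    aliases["nadh4l"] = "nad4L"
    for i, roman in ((1, "i"), (2, "ii"), (3, "iii")):
        aliases[f"co{roman}"] = f"cox{i}"
        aliases[f"coi" if i == 1 else f"co{roman}"] = f"cox{i}"
    aliases.update({"cob": "cytb", "cytochrome b": "cytb", "cyt b": "cytb",
                    "atpase6": "atp6", "atpase8": "atp8"})
    # rRNAs
    for alias, canon in (("12s", "rrnS"), ("12s rrna", "rrnS"), ("s-rrna", "rrnS"),
                         ("srrna", "rrnS"), ("rrns", "rrnS"), ("small subunit ribosomal rna", "rrnS"),
                         ("16s", "rrnL"), ("16s rrna", "rrnL"), ("l-rrna", "rrnL"),
                         ("lrrna", "rrnL"), ("rrnl", "rrnL"), ("large subunit ribosomal rna", "rrnL")):
        aliases[alias] = canon
    # control region
    for alias in ("d-loop", "dloop", "control region", "a+t rich region", "at rich region"):
        aliases[alias] = CONTROL_REGION
    # tRNAs: accept tRNA-Xxx, trnX, and isoacceptor spellings
    for amino3, canon in _AMINO3_TO_TRNA.items():
        aliases[f"trna-{amino3.lower()}"] = canon
        aliases[f"trn{canon[3:].lower()}"] = canon
    for alias, canon in (
        ("trna-ser(agn)", "trnS1"), ("trna-ser^agn^", "trnS1"), ("trna-ser agn", "trnS1"),
        ("trna-ser(ucn)", "trnS2"), ("trna-ser^ucn^", "trnS2"), ("trna-ser ucn", "trnS2"),
        ("trna-leu(cun)", "trnL1"), ("trna-leu^cun^", "trnL1"), ("trna-leu cun", "trnL1"),
        ("trna-leu(uur)", "trnL2"), ("trna-leu^uur^", "trnL2"), ("trna-leu uur", "trnL2"),
        ("trna-ser1", "trnS1"), ("trna-ser2", "trnS2"), ("trna-leu1", "trnL1"), ("trna-leu2", "trnL2"),
    ):
        aliases[alias] = canon
    return aliases


GENE_NAME_ALIASES: dict[str, str] = _alias_table()


def normalize_gene_name(raw: str) -> str | None:
    """Map a depositor gene name onto the canonical alphabet.

    Returns None when the name is not recognised (callers decide whether that
    is a warning or an error).  Matching is case-insensitive and ignores
    surrounding whitespace and italics markers.
    """
    key = raw.strip().strip("*").lower()
    return GENE_NAME_ALIASES.get(key)


def feature_class_of(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in TRNA_NAMES:
        return "tRNA"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == CONTROL_REGION:
        return "CR"
    raise KeyError(f"unknown canonical gene name: {name!r}")


ANCESTRAL_ORDER_VERSION = "1.0"

#: The ancestral (typical Drosophila-like) insect mitogenome arrangement as a
#: circular signed gene order.  Sign encodes strand: +1 = heavy/majority
#: (deposited) strand, -1 = light strand.  The control region sits between
#: rrnS and trnI and is tracked separately as an unsigned anchor.
ANCESTRAL_INSECT_ORDER: tuple[tuple[str, int], ...] = (
    ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("nad2", +1), ("trnW", +1),
    ("trnC", -1), ("trnY", -1), ("cox1", +1), ("trnL2", +1), ("cox2", +1),
    ("trnK", +1), ("trnD", +1), ("atp8", +1), ("atp6", +1), ("cox3", +1),
    ("trnG", +1), ("nad3", +1), ("trnA", +1), ("trnR", +1), ("trnN", +1),
    ("trnS1", +1), ("trnE", +1), ("trnF", -1), ("nad5", -1), ("trnH", -1),
    ("nad4", -1), ("nad4L", -1), ("trnT", +1), ("trnP", -1), ("nad6", +1),
    ("cytb", +1), ("trnS2", +1), ("nad1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1),
)
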