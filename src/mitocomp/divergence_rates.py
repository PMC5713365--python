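"""Pairwise Ka/Ks by the Nei–Gojobori (1986) counting method.

Sites are counted fractionally: each codon position contributes the fraction
of its single-base changes that are synonymous, renormalised over non-stop
alternatives so every aligned codon contributes exactly three sites
(N + S == 3 * codons).  Codons differing at several positions are resolved by
averaging synonymous/non-synonymous difference counts over all minimal
substitution pathways, excluding pathways that pass through a stop codon and
re-weighting the remainder equally.  Proportions are Jukes–Cantor corrected:

    K = -3/4 * ln(1 - 4/3 * p)

Ratios are averaged per gene across species pairs as mean-of-ratios.
Everything runs under translation table 5 (invertebrate mitochondrial).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio.Align import PairwiseAligner

from .annotation_io import MitogenomeRecord, extract_gene_sequence
from .codon_usage import STOP_CODONS, internal_codons, translate
from .config import PCG_NAMES
from .errors import ValidationError

#: Fixed amino-acid alignment scores (identity-based; no substitution matrix).
ALIGN_SCORES = {"match": 1, "mismatch": 0, "open": -5, "extend": -1}

AVERAGING_CONVENTION = "mean-of-ratios"


@dataclass(frozen=True)
class KaKsEstimate:
    """NG86 bookkeeping for one gene in one species pair.

    N/S are non-synonymous/synonymous site counts, Nd/Sd the pathway-averaged
    difference counts.  ``ratio`` is NaN when Ks == 0 or either rate is
    saturated (p >= 3/4, where the Jukes–Cantor log is undefined).
    """

    gene: str
    pair: tuple[str, str]
    N: float
    S: float
    Nd: float
    Sd: float

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else 0.0

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def saturated(self) -> bool:
        return self.pN >= 0.75 or self.pS >= 0.75

    @property
    def ka(self) -> float:
        return _jukes_cantor(self.pN)

    @property
    def ks(self) -> float:
        return _jukes_cantor(self.pS)

    @property
    def ratio(self) -> float:
        if self.saturated or self.ks == 0 or math.isnan(self.ks):
            return math.nan
        return self.ka / self.ks


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - 4 * p / 3)


@lru_cache(maxsize=None)
def _site_fractions(codon: str) -> float:
    """Synonymous sites of one codon (0..3), stop alternatives renormalised out."""
    syn_sites = 0.0
    aa = translate(codon)
    for pos in range(3):
        syn = nonstop = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if translate(alt) == aa:
                syn += 1
        if nonstop:
            syn_sites += syn / nonstop
    return syn_sites


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(Sd, Nd) averaged over all minimal pathways between two codons.

    Pathways through stop codons are excluded and the rest re-weighted
    equally; None when every pathway is blocked (degenerate, codon skipped).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    syn_total = nonsyn_total = 0.0
    n_pathways = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS and nxt != codon_b:
                blocked = True
                break
            steps.append((current, nxt))
            current = nxt
        if blocked:
            continue
        n_pathways += 1
        for before, after in steps:
            if translate(before) == translate(after):
                syn_total += 1
            else:
                nonsyn_total += 1
    if n_pathways == 0:
        return None
    return (syn_total / n_pathways, nonsyn_total / n_pathways)


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str | None, str | None]]:
    """Codon-aware pairwise alignment via global amino-acid alignment.

    The translated sequences are globally aligned (match +1, mismatch 0, gap
    open -5, extend -1) and the alignment is back-translated to codons; gap
    columns carry None and are excluded by downstream site counting.
    Incomplete terminal codons are stripped before alignment.
    """
    codons_a = internal_codons(cds_a, "seq_a")
    codons_b = internal_codons(cds_b, "seq_b")
    aa_a = "".join(translate(c) for c in codons_a)
    aa_b = "".join(translate(c) for c in codons_b)
    if not aa_a or not aa_b:
        raise ValidationError("empty translation; nothing to align")
    if len(aa_a) == len(aa_b):
        identity = sum(x == y for x, y in zip(aa_a, aa_b)) / len(aa_a)
        # For equal-length, high-identity pairs (the regime of congeneric
        # mitochondrial proteins) the ungapped pairing is the global optimum
        # under these scores: a gap costs >= 10 while a mismatch costs only
        # the lost match.  Skipping the quadratic DP keeps long genes fast.
        if identity >= 0.85:
            return list(zip(codons_a, codons_b))
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = ALIGN_SCORES["match"]
    aligner.mismatch_score = ALIGN_SCORES["mismatch"]
    aligner.open_gap_score = ALIGN_SCORES["open"]
    aligner.extend_gap_score = ALIGN_SCORES["extend"]
    alignment = aligner.align(aa_a, aa_b)[0]
    out: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    # Walk the alignment column by column via the gapped strings.
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    for ca, cb in zip(gapped_a, gapped_b):
        pa = codons_a[ia] if ca != "-" else None
        pb = codons_b[ib] if cb != "-" else None
        out.append((pa, pb))
        ia += ca != "-"
        ib += cb != "-"
    return out


def alignment_score(aligned: list[tuple[str | None, str | None]]) -> float:
    """Score of a back-translated alignment under the fixed AA scores."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for pa, pb in aligned:
        if pa is None:
            score += ALIGN_SCORES["extend"] if prev_gap_a else ALIGN_SCORES["open"]
            prev_gap_a, prev_gap_b = True, False
        elif pb is None:
            score += ALIGN_SCORES["extend"] if prev_gap_b else ALIGN_SCORES["open"]
            prev_gap_a, prev_gap_b = False, True
        else:
            score += (ALIGN_SCORES["match"] if translate(pa) == translate(pb)
                      else ALIGN_SCORES["mismatch"])
            prev_gap_a = prev_gap_b = False
    return score


def ng86(aligned: list[tuple[str | None, str | None]],
         gene: str = "?", pair: tuple[str, str] = ("a", "b")) -> KaKsEstimate:
    """NG86 estimate from an aligned codon pair list (gap columns skipped)."""
    N = S = Nd = Sd = 0.0
    for idx, (ca, cb) in enumerate(aligned):
        if ca is None or cb is None:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValidationError(f"{gene}: stop codon in aligned column {idx}")
        diffs = _pathway_differences(ca, cb)
        if diffs is None:
            warnings.warn(f"{gene}: all pathways between {ca} and {cb} pass through "
                          "stops; codon skipped from difference counts")
            continue
        sa, sb = _site_fractions(ca), _site_fractions(cb)
        s_sites = (sa + sb) / 2
        S += s_sites
        N += 3 - s_sites
        Sd += diffs[0]
        Nd += diffs[1]
    return KaKsEstimate(gene=gene, pair=pair, N=N, S=S, Nd=Nd, Sd=Sd)


def pairwise_gene_kaks(rec_a: MitogenomeRecord, rec_b: MitogenomeRecord,
                       genes: list[str] | None = None) -> list[KaKsEstimate]:
    """NG86 for each shared protein-coding gene of two records."""
    shared = genes or [g for g in PCG_NAMES
                       if any(f.name == g for f in rec_a.features)
                       and any(f.name == g for f in rec_b.features)]
    estimates = []
    for gene in shared:
        aligned = codon_align(extract_gene_sequence(rec_a, gene),
                              extract_gene_sequence(rec_b, gene))
        estimates.append(ng86(aligned, gene, (rec_a.record_id, rec_b.record_id)))
    return estimates


def gene_kaks_profile(records: list[MitogenomeRecord]) -> pd.DataFrame:
    """Per-gene mean Ka/Ks over all record pairs (Fig-3-style profile).

    Averaging is mean-of-ratios over pairs; genes with any undefined ratio in
    any pair are flagged in the ``undefined_pairs`` column.
    """
    if len(records) < 2:
        raise ValidationError("gene_kaks_profile needs at least two records")
    per_gene: dict[str, list[KaKsEstimate]] = {}
    for rec_a, rec_b in itertools.combinations(records, 2):
        for est in pairwise_gene_kaks(rec_a, rec_b):
            per_gene.setdefault(est.gene, []).append(est)
    rows = []
    for gene, ests in per_gene.items():
        ratios = [e.ratio for e in ests]
        defined = [r for r in ratios if not math.isnan(r)]
        rows.append({
            "gene": gene,
            "mean_ka": sum(e.ka for e in ests) / len(ests),
            "mean_ks": sum(e.ks for e in ests) / len(ests),
            "mean_ratio": sum(defined) / len(defined) if defined else math.nan,
            "n_pairs": len(ests),
            "undefined_pairs": len(ratios) - len(defined),
        })
    df = pd.DataFrame(rows).sort_values("gene", ignore_index=True)
    df.attrs["averaging"] = AVERAGING_CONVENTION
    return df
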