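"""NG86 Ka/Ks against independent brute-force oracles, plus profile logic."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from Bio.Data import CodonTable

from mitocomp.annotation_io import GeneFeature, MitogenomeRecord
from mitocomp.codon_usage import SENSE_CODONS
from mitocomp.divergence_rates import (
    alignment_score,
    codon_align,
    gene_kaks_profile,
    ng86,
    pairwise_gene_kaks,
)
from mitocomp.errors import ValidationError
from mitocomp.synthetic_data import evolve_pair, random_cds

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

_T5 = CodonTable.unambiguous_dna_by_id[5]
_STOPS = set(_T5.stop_codons)


def _aa(codon):
    return "*" if codon in _STOPS else _T5.forward_table[codon]


def oracle_sites(codon):
    """Synonymous site count of one codon by explicit enumeration."""
    s = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:]
                for b in "ACGT" if b != codon[pos]]
        alts = [a for a in alts if a not in _STOPS]
        if alts:
            s += sum(_aa(a) == _aa(codon) for a in alts) / len(alts)
    return s


def oracle_pathways(ca, cb):
    """All stop-free minimal pathways between two codons, by recursive DFS."""
    results = []

    def walk(current, remaining, syn, nonsyn):
        if not remaining:
            results.append((syn, nonsyn))
            return
        for pos in remaining:
            nxt = current[:pos] + cb[pos] + current[pos + 1:]
            if nxt in _STOPS and nxt != cb:
                continue
            step_syn = _aa(current) == _aa(nxt)
            walk(nxt, [p for p in remaining if p != pos],
                 syn + step_syn, nonsyn + (not step_syn))

    walk(ca, [i for i in range(3) if ca[i] != cb[i]], 0, 0)
    return results


def oracle_ng86(codons_a, codons_b):
    """Nd, Sd, N, S over a gap-free aligned codon list (pathway averaging)."""
    N = S = Nd = Sd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        paths = oracle_pathways(ca, cb)
        if not paths:
            continue
        s_sites = (oracle_sites(ca) + oracle_sites(cb)) / 2
        S += s_sites
        N += 3 - s_sites
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    return N, S, Nd, Sd


def oracle_alignment_score(a, b):
    """Optimal global affine-gap score by exhaustive recursion (tiny inputs)."""
    @lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, (1 if a[i] == b[j] else 0) + rec(i + 1, j + 1, 0))
        if j < len(b):
            best = max(best, (-1 if state == 1 else -5) + rec(i, j + 1, 1))
        if i < len(a):
            best = max(best, (-1 if state == 2 else -5) + rec(i + 1, j, 2))
        return best

    return rec(0, 0, 0)


def _random_codons(rng, n):
    return [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n)]


def _single_gene_record(rec_id, cds, gene="cox1"):
    return MitogenomeRecord(rec_id, len(cds), [
        GeneFeature(gene, "PCG", "H", 1, len(cds), len(cds), None, cds[:3], "TAA")], cds)


# ---------------------------------------------------------------------------
# codon_align
# ---------------------------------------------------------------------------

class TestCodonAlign:
    def test_identical_sequences_align_ungapped(self):
        cds = "ATGAAACCCTAA"
        aligned = codon_align(cds, cds)
        assert aligned == [(c, c) for c in ("ATG", "AAA", "CCC")]

    def test_single_codon_difference(self):
        aligned = codon_align("ATGAAATAA", "ATGGAATAA")
        assert sum(a != b for a, b in aligned) == 1

    def test_gap_columns_for_length_difference(self):
        aligned = codon_align("ATGAAACCCGGGTAA", "ATGAAAGGGTAA")
        assert any(b is None for _, b in aligned)
        assert [a for a, _ in aligned] == ["ATG", "AAA", "CCC", "GGG"]

    def test_matches_exhaustive_dp_oracle_on_small_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            na, nb = rng.integers(2, 7, size=2)
            a = "".join(_random_codons(rng, na)) + "TAA"
            b = "".join(_random_codons(rng, nb)) + "TAA"
            aligned = codon_align(a, b)
            ta = "".join(_aa(x) for x, _ in aligned if x)
            tb = "".join(_aa(y) for _, y in aligned if y)
            assert alignment_score(aligned) == oracle_alignment_score(ta, tb)


# ---------------------------------------------------------------------------
# ng86
# ---------------------------------------------------------------------------

class TestNg86:
    def test_identical_sequences(self):
        est = ng86(codon_align("ATGAAATAA", "ATGAAATAA"))
        assert est.ka == 0 and est.ks == 0
        assert math.isnan(est.ratio)

    def test_synonymous_third_position_change(self):
        est = ng86([("GGA", "GGG")])
        assert (est.Nd, est.Sd) == (0.0, 1.0)

    def test_site_conservation(self):
        rng = np.random.default_rng(1)
        ca, cb = _random_codons(rng, 30), _random_codons(rng, 30)
        est = ng86(list(zip(ca, cb)))
        assert est.N + est.S == pytest.approx(3 * 30, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        ca, cb = _random_codons(rng, 25), _random_codons(rng, 25)
        fwd = ng86(list(zip(ca, cb)))
        rev = ng86(list(zip(cb, ca)))
        for attr in ("N", "S", "Nd", "Sd"):
            assert getattr(fwd, attr) == pytest.approx(getattr(rev, attr), abs=1e-9)

    def test_agrees_with_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ca, cb = _random_codons(rng, 50), _random_codons(rng, 50)
            est = ng86(list(zip(ca, cb)))
            N, S, Nd, Sd = oracle_ng86(ca, cb)
            assert est.N == pytest.approx(N, abs=1e-9)
            assert est.S == pytest.approx(S, abs=1e-9)
            assert est.Nd == pytest.approx(Nd, abs=1e-9)
            assert est.Sd == pytest.approx(Sd, abs=1e-9)

    def test_stop_codon_in_alignment_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            ng86([("TAA", "GGG")])

    def test_saturation_flagged_not_complex(self):
        est = ng86([("GGA", "CCT")] * 5)  # wildly diverged
        assert est.saturated
        assert math.isnan(est.ratio)


# ---------------------------------------------------------------------------
# gene profiles
# ---------------------------------------------------------------------------

class TestGeneKaksProfile:
    def test_three_identical_records_give_zero_ka(self):
        cds = random_cds(np.random.default_rng(0), 303, (0.25,) * 4)
        recs = [_single_gene_record(f"r{i}", cds) for i in range(3)]
        df = gene_kaks_profile(recs)
        assert (df.mean_ka == 0).all()

    def test_two_records_one_gene_equals_single_pairwise_estimate(self):
        rng = np.random.default_rng(4)
        a = _single_gene_record("a", random_cds(rng, 903, (0.25,) * 4))
        b = evolve_pair(a, 0.5, 0.05, seed=9, record_id="b")
        df = gene_kaks_profile([a, b])
        single = pairwise_gene_kaks(a, b)[0]
        assert len(df) == 1
        assert df.loc[0, "mean_ratio"] == pytest.approx(single.ratio)

    def test_fewer_than_two_records_is_error(self):
        with pytest.raises(ValidationError, match="two records"):
            gene_kaks_profile([_single_gene_record("a", "ATGAAATAA")])

    def test_rank_order_recovered_for_contrasting_omegas(self):
        # fast/slow genes: atp8 evolves near-neutrally, cox1 under strong
        # purifying selection; the estimated profile must rank them so
        rng = np.random.default_rng(11)
        comp = (0.452, 0.1606, 0.0974, 0.29)
        genes = {"atp8": 0.6, "cox1": 0.02, "nad2": 0.2}
        feats, seqs, pos = [], [], 0
        for g in genes:
            cds = random_cds(rng, 3 + 3 * 801, comp)
            feats.append(GeneFeature(g, "PCG", "H", pos + 1, pos + len(cds),
                                     len(cds), None, cds[:3], "TAA"))
            seqs.append(cds)
            pos += len(cds)
        base = MitogenomeRecord("base", pos, feats, "".join(seqs))
        recs = [base] + [evolve_pair(base, genes, 0.06, seed=s, record_id=f"d{s}")
                         for s in (21, 22)]
        df = gene_kaks_profile(recs).set_index("gene")
        ratios = df["mean_ratio"]
        assert ratios.idxmax() == "atp8"
        assert ratios.idxmin() == "cox1"
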