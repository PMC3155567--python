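"""NG86 dN/dS estimation and the difference-of-medians permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import hepsex as hx
from hepsex import evolution
from hepsex.gencode import NONSTOP_CODONS, neighbours


# --- independent brute-force oracle (translation via Bio.Seq) ---------------

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon):
    return str(Seq(codon).translate())


def _oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + nt + codon[pos + 1:] for nt in "ACGT" if nt != codon[pos]]
        sense = [a for a in alts if a not in _STOPS]
        if sense:
            syn += sum(_aa(a) == _aa(codon) for a in sense) / len(sense)
    return syn, 3.0 - syn


def _oracle_codon_diffs(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        steps, cur, ok = [], c1, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS and nxt != c2:
                ok = False
                break
            steps.append(_aa(nxt) == _aa(cur))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return None
    sd = np.mean([sum(s) for s in paths])
    nd = np.mean([len(s) - sum(s) for s in paths])
    return sd, nd


def _oracle_dnds(seq_a, seq_b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        c1, c2 = seq_a[i:i + 3], seq_b[i:i + 3]
        s1, n1 = _oracle_sites(c1)
        s2, n2 = _oracle_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        d = _oracle_codon_diffs(c1, c2)
        if d is None:
            return None
        Sd += d[0]
        Nd += d[1]
    ps, pn = Sd / S, Nd / N
    if ps >= 0.75 or pn >= 0.75:
        return None
    ds = -0.75 * math.log(1 - 4 * ps / 3)
    dn = -0.75 * math.log(1 - 4 * pn / 3)
    return dn, ds


class TestNg86:
    def test_identical_sequences_have_no_divergence(self):
        rec = hx.ng86_dnds("ATGGCTAAA", "ATGGCTAAA")
        assert rec.dn == rec.ds == 0.0
        assert not rec.valid and rec.ratio is None

    def test_single_synonymous_change_counts(self):
        # TTT->TTC is the lone difference (Phe->Phe): dN = 0, dS > 0.
        # Hand counts: TTT and TTC each contribute 1/3 synonymous site;
        # GCT (4-fold degenerate 3rd position) contributes exactly 1.
        a = "TTT" + "GCT" * 9
        b = "TTC" + "GCT" * 9
        s, n, sd, nd, _ = evolution.ng86_counts(a, b)
        assert s == pytest.approx(1 / 3 + 9, abs=1e-12)
        assert (sd, nd) == (1.0, 0.0)
        rec = hx.ng86_dnds(a, b)
        assert rec.dn == 0.0 and rec.ds > 0.0

    def test_matches_bruteforce_oracle_on_small_pairs(self):
        # exhaustive pathway enumeration to 6 decimals on <=3-codon pairs,
        # padded with identical codons so the correction stays defined
        rng = np.random.default_rng(42)
        pad = "GGTACCGAA" * 3
        checked = 0
        while checked < 40:
            k = rng.integers(1, 4)
            c_a = [NONSTOP_CODONS[i] for i in rng.integers(0, 61, k)]
            c_b = [NONSTOP_CODONS[i] for i in rng.integers(0, 61, k)]
            a, b = "".join(c_a) + pad, "".join(c_b) + pad
            expected = _oracle_dnds(a, b)
            if expected is None:
                continue
            rec = hx.ng86_dnds(a, b)
            assert rec.dn == pytest.approx(expected[0], abs=1e-6)
            assert rec.ds == pytest.approx(expected[1], abs=1e-6)
            checked += 1

    def test_symmetry_in_sequence_order(self):
        pairs = hx.generate_codon_pairs(5, 60, {"g": 0.2}, seed=3)
        for p in pairs.pairs:
            fwd = hx.ng86_dnds(p.seq_a, p.seq_b)
            rev = hx.ng86_dnds(p.seq_b, p.seq_a)
            assert fwd.dn == pytest.approx(rev.dn, abs=1e-12)
            assert fwd.ds == pytest.approx(rev.ds, abs=1e-12)

    def test_counts_additive_over_concatenation(self):
        pairs = hx.generate_codon_pairs(2, 40, {"g": 0.3}, seed=4).pairs
        (a1, b1), (a2, b2) = (pairs[0].seq_a, pairs[0].seq_b), (pairs[1].seq_a, pairs[1].seq_b)
        c1 = evolution.ng86_counts(a1, b1)
        c2 = evolution.ng86_counts(a2, b2)
        cat = evolution.ng86_counts(a1 + a2, b1 + b2)
        for i in range(4):
            assert cat[i] == pytest.approx(c1[i] + c2[i], abs=1e-10)

    def test_agrees_with_biopython_on_stop_safe_alignments(self):
        # restrict to codons with no stop-codon neighbour and single-site
        # differences, where site/pathway conventions coincide
        from Bio.Align import Alignment
        from Bio.Align import analysis as bio_analysis

        safe = [c for c in NONSTOP_CODONS if len(neighbours(c)) == 9]
        rng = np.random.default_rng(7)
        codons_a, codons_b = [], []
        for _ in range(60):
            c = safe[rng.integers(0, len(safe))]
            codons_a.append(c)
            if rng.random() < 0.3:
                opts = [x for x in neighbours(c) if x in safe]
                codons_b.append(opts[rng.integers(0, len(opts))] if opts else c)
            else:
                codons_b.append(c)
        a, b = "".join(codons_a), "".join(codons_b)
        dn_bio, ds_bio = bio_analysis.calculate_dn_ds(Alignment([a, b]), method="NG86")
        rec = hx.ng86_dnds(a, b)
        assert rec.dn == pytest.approx(dn_bio, abs=1e-9)
        assert rec.ds == pytest.approx(ds_bio, abs=1e-9)

    def test_malformed_alignments_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            hx.ng86_dnds("ATGAAA", "ATG")
        with pytest.raises(ValueError, match="divisible"):
            hx.ng86_dnds("ATGA", "ATGA")
        with pytest.raises(ValueError, match="stop"):
            hx.ng86_dnds("ATGTAAGCT", "ATGTAAGCT")

    def test_ambiguous_codons_skipped_and_counted(self):
        rec = hx.ng86_dnds("ATGNNNGCT", "ATGAAAGCT")
        assert rec.n_skipped_codons == 1


class TestAggregateGeneRatio:
    def test_median_over_accessions(self):
        rec = pd.DataFrame(
            {"gene_id": ["a1", "a2", "a3"], "dnds": [0.1, 0.2, 0.9],
             "valid": True, "group": "g"}
        )
        out = hx.aggregate_gene_ratio(rec, {"a1": "G", "a2": "G", "a3": "G"})
        assert out.loc[0, "dnds"] == pytest.approx(0.2)

    def test_single_accession_and_even_count(self):
        rec = pd.DataFrame(
            {"gene_id": ["a1", "b1", "b2"], "dnds": [0.5, 0.1, 0.3],
             "valid": True, "group": "g"}
        )
        out = hx.aggregate_gene_ratio(rec, {"a1": "A", "b1": "B", "b2": "B"}).set_index("gene")
        assert out.loc["A", "dnds"] == pytest.approx(0.5)
        assert out.loc["B", "dnds"] == pytest.approx(0.2)  # midpoint

    def test_all_invalid_gene_flagged_without_ratio(self):
        rec = pd.DataFrame(
            {"gene_id": ["a1"], "dnds": [np.nan], "valid": [False], "group": "g"}
        )
        out = hx.aggregate_gene_ratio(rec)
        assert not out.loc[0, "valid"]
        assert np.isnan(out.loc[0, "dnds"])


class TestSelectNonSexBiased:
    def _tables(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(200)]
        human = pd.DataFrame(
            {"gene": genes,
             "intensity": rng.uniform(10, 500, 200),
             "fold_change": rng.uniform(-1.5, 1.5, 200) + np.sign(rng.uniform(-1, 1, 200))}
        )
        ortho = pd.DataFrame(
            {"gene": genes,
             "fold_change": rng.uniform(-1.5, 1.5, 200) + np.sign(rng.uniform(-1, 1, 200))}
        )
        return human, ortho

    def test_filter_examples(self):
        human = pd.DataFrame({"gene": ["A", "B"], "intensity": [150, 150],
                              "fold_change": [1.005, 1.005]})
        ortho = pd.DataFrame({"gene": ["A", "B"], "fold_change": [1.005, 1.02]})
        assert hx.select_non_sex_biased(human, ortho) == ["A"]

    def test_low_intensity_rejected(self):
        human = pd.DataFrame({"gene": ["A"], "intensity": [50], "fold_change": [1.005]})
        ortho = pd.DataFrame({"gene": ["A"], "fold_change": [1.005]})
        assert hx.select_non_sex_biased(human, ortho) == []

    def test_matches_bruteforce_scan(self):
        human, ortho = self._tables()
        got = set(hx.select_non_sex_biased(human, ortho))
        expected = set()
        for _, hrow in human.iterrows():
            orow = ortho[ortho["gene"] == hrow["gene"]].iloc[0]
            if hrow["intensity"] > 100 and abs(hrow["fold_change"]) < 1.01 and abs(orow["fold_change"]) < 1.01:
                expected.add(hrow["gene"])
        assert got == expected


class TestMedianPermutationTest:
    def test_identical_groups_give_central_p(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0.1, 0.03, 100)
        res = hx.median_permutation_test(vals, vals, background=rng.normal(0.1, 0.03, 400),
                                         n_perm=2000, seed=14)
        assert res.observed_median_difference == 0.0
        assert 0.35 < res.p_value < 0.65

    def test_planted_median_shift_detected(self):
        rng = np.random.default_rng(15)
        b = rng.normal(0.10, 0.03, 200)
        a = rng.normal(0.15, 0.03, 200)  # +0.05 shift in median
        res = hx.median_permutation_test(a, b, background=np.concatenate([a, b]),
                                         n_perm=2000, seed=16)
        assert res.p_value < 0.01

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        bg = np.concatenate([a, b])
        r1 = hx.median_permutation_test(a, b, bg, n_perm=500, seed=18)
        r2 = hx.median_permutation_test(a, b, bg, n_perm=500, seed=18)
        assert r1.nd == r2.nd

    def test_insufficient_background_rejected(self):
        with pytest.raises(ValueError):
            hx.median_permutation_test([1.0] * 10, [2.0] * 10, background=[0.0] * 15)
        with pytest.raises(ValueError):
            hx.median_permutation_test([], [1.0], background=[0.0] * 5)
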