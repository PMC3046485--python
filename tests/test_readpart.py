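"""Ortholog alignment, variant extraction, read assignment and FPK."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from homoeoscan import readpart, synthdata
from homoeoscan.readpart import (OrthologPairAlignment, ReadMapper, Scoring,
                                 align_ortholog_pair, assign_read,
                                 concordance_with_array, fpk_quantify,
                                 homoeolog_divergence, needleman_wunsch,
                                 partition_fragments)

SCORING = Scoring()


def brute_force_best_score(s, t, sc=SCORING):
    """Best score over every global alignment of two short strings (oracle).

    Independent recursive formulation (gap state carried explicitly);
    memoized so pairs up to ~10 bases stay fast.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j, prev_gap):
        # prev_gap: None, "s" (gap in s), or "t" (gap in t)
        if i == len(s) and j == len(t):
            return 0.0
        best = -np.inf
        if i < len(s) and j < len(t):
            sub = sc.match if s[i] == t[j] else sc.mismatch
            best = max(best, sub + rec(i + 1, j + 1, None))
        if i < len(s):  # consume s[i], gap in t
            cost = sc.gap_extend if prev_gap == "t" else sc.gap_open
            best = max(best, cost + rec(i + 1, j, "t"))
        if j < len(t):  # consume t[j], gap in s
            cost = sc.gap_extend if prev_gap == "s" else sc.gap_open
            best = max(best, cost + rec(i, j + 1, "s"))
        return best

    return rec(0, 0, None)


class TestNeedlemanWunsch:
    def test_identical_sequences_no_variants(self):
        al = align_ortholog_pair("ACGTACGT", "ACGTACGT")
        assert al.variants == [] and al.divergence == 0.0
        assert al.score == 8 * SCORING.match

    def test_single_snp_example(self):
        al = align_ortholog_pair("ACGTACGT", "ACGAACGT")
        assert len(al.variants) == 1
        v = al.variants[0]
        assert (v.type, v.at_position, v.at_allele, v.aa_allele) == \
            ("SNP", 3, "T", "A")

    def test_single_deletion_matches_brute_force(self):
        al = align_ortholog_pair("ACGTACGT", "ACGACGT")
        dels = [v for v in al.variants if v.type == "deletion"]
        assert len(dels) == 1 and len(dels[0].at_allele) == 1
        assert al.score == pytest.approx(
            brute_force_best_score("ACGTACGT", "ACGACGT"))

    def test_scores_match_enumeration_oracle(self, rng):
        for _ in range(40):
            n1, n2 = rng.integers(1, 9, size=2)
            s = "".join(rng.choice(list("ACGT"), n1))
            t = "".join(rng.choice(list("ACGT"), n2))
            score, a, b = needleman_wunsch(s, t)
            assert score == pytest.approx(brute_force_best_score(s, t)), (s, t)
            assert a.replace("-", "") == s and b.replace("-", "") == t

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 10_000))
    def test_scores_match_biopython(self, seed):
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = SCORING.match
        aligner.mismatch_score = SCORING.mismatch
        aligner.open_gap_score = SCORING.gap_open
        aligner.extend_gap_score = SCORING.gap_extend
        r = np.random.default_rng(seed)
        s = "".join(r.choice(list("ACGT"), r.integers(1, 30)))
        t = "".join(r.choice(list("ACGT"), r.integers(1, 30)))
        assert needleman_wunsch(s, t)[0] == pytest.approx(aligner.score(s, t))

    def test_n_columns_never_variants(self):
        al = align_ortholog_pair("ACNTAC", "ACGTAC")
        assert al.variants == []

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            align_ortholog_pair("ACGU", "ACGT")


class TestDivergence:
    def test_identical_zero(self):
        assert homoeolog_divergence("ACGTAC", "ACGTAC") == 0.0

    def test_one_snp_in_hundred(self, rng):
        s = "".join(rng.choice(list("ACGT"), 100))
        t = s[:50] + ("A" if s[50] != "A" else "C") + s[51:]
        assert homoeolog_divergence(s, t) == pytest.approx(0.01)

    def test_generator_truth_recovered(self):
        cfg = synthdata.GeneratorConfig(n_genes=30, seed=31, divergence=0.05)
        seqs, _ = synthdata.generate_parental_sequences(cfg)
        divs = [homoeolog_divergence(seqs.at[g], seqs.aa[g]) for g in seqs.at]
        est = np.mean(divs)
        se = np.sqrt(0.05 * 0.95 / (30 * cfg.gene_length))
        assert abs(est - 0.05) < 4 * se


def make_pair(rng, length=300, divergence=0.06):
    s = "".join(rng.choice(list("ACGT"), length))
    t = list(s)
    for i in rng.choice(length, int(length * divergence), replace=False):
        t[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return s, "".join(t)


@pytest.fixture(scope="module")
def pair():
    rng = np.random.default_rng(5)
    at, aa = make_pair(rng)
    al = align_ortholog_pair(at, aa, gene_id="g1")
    mapper = ReadMapper({"g1": (at, aa)})
    return at, aa, al, mapper


class TestAssignment:

    def test_read_with_no_sites_ambiguous(self, pair):
        at, aa, al, mapper = pair
        # a window identical in both orthologs
        for start in range(0, len(at) - 40):
            if at[start:start + 40] == aa[start:start + 40]:
                break
        else:
            pytest.skip("no conserved window in fixture")
        pls = {s: p for s, (g, p) in mapper.place(at[start:start + 40]).items()}
        res = assign_read("r", "g1", pls, al.variants)
        assert res.call == "ambiguous" and res.informative_sites == 0

    def test_read_matching_aa_alleles_called_aa(self, pair):
        at, aa, al, mapper = pair
        snp = [v for v in al.variants if v.type == "SNP"][3]
        lo = max(0, snp.aa_position - 30)
        read = aa[lo:lo + 72]
        pls = {s: p for s, (g, p) in mapper.place(read).items()}
        res = assign_read("r", "g1", pls, al.variants)
        assert res.call == "Aa" and res.aa_support >= 1 and res.at_support == 0

    def test_unplaced_read_unmapped(self, pair):
        *_, al, mapper = pair
        res = assign_read("r", "g1", {}, al.variants)
        assert res.call == "unmapped"

    def test_label_swap_symmetry(self, pair):
        """Swapping the parental references swaps every call exactly."""
        at, aa, _, _ = pair
        rng = np.random.default_rng(8)
        reads = []
        for k in range(40):
            src = at if k % 2 else aa
            start = int(rng.integers(0, len(src) - 72))
            reads.append((f"r{k}", src[start:start + 72],
                          src[max(0, start - 20):max(0, start - 20) + 72]))
        frame = pd.DataFrame(reads, columns=["read_id", "mate1", "mate2"])
        fwd_al = {"g1": align_ortholog_pair(at, aa, gene_id="g1")}
        rev_al = {"g1": align_ortholog_pair(aa, at, gene_id="g1")}
        fwd = partition_fragments(frame, fwd_al).set_index("read_id")
        rev = partition_fragments(frame, rev_al).set_index("read_id")
        swap = {"At": "Aa", "Aa": "At", "ambiguous": "ambiguous",
                "conflicting": "conflicting", "unmapped": "unmapped"}
        assert fwd["call"].map(swap).tolist() == rev["call"].tolist()

    def test_recovery_against_read_names(self):
        """Synthetic paired reads: nearly every site-overlapping fragment is
        called, and calls match the recorded origin."""
        cfg = synthdata.GeneratorConfig(n_genes=25, seed=41, indel_rate=0.005)
        bundle = synthdata.simulate(cfg, reads=True)
        aligns = {g: align_ortholog_pair(bundle.sequences.at[g],
                                         bundle.sequences.aa[g], gene_id=g)
                  for g in bundle.sequences.at}
        out = partition_fragments(bundle.reads, aligns)
        m = out.merge(bundle.reads[["read_id", "origin"]], on="read_id")
        overlapping = m[m.informative_sites > 0]
        called = m[m["call"].isin(["At", "Aa"])]
        assert len(called) / len(overlapping) >= 0.95
        assert (called["call"] == called["origin"]).mean() >= 0.99


class TestFpk:
    def test_unit_case(self):
        a = pd.DataFrame({"read_id": [f"r{i}" for i in range(100)],
                          "gene_id": "g", "informative_sites": 1,
                          "at_support": 1, "aa_support": 0, "call": "At"})
        out = fpk_quantify(a, {"g": (1000, 1000)})
        assert out["at_fpk"].iloc[0] == pytest.approx(100.0)

    def test_doubling_length_halves_fpk(self):
        a = pd.DataFrame({"read_id": ["r1", "r2"], "gene_id": "g",
                          "informative_sites": 1, "at_support": 0,
                          "aa_support": 1, "call": "Aa"})
        short = fpk_quantify(a, {"g": (500, 500)})
        long = fpk_quantify(a, {"g": (500, 1000)})
        assert long["aa_fpk"].iloc[0] == pytest.approx(
            short["aa_fpk"].iloc[0] / 2)

    def test_gene_without_reads_flagged(self):
        a = pd.DataFrame(columns=["read_id", "gene_id", "informative_sites",
                                  "at_support", "aa_support", "call"])
        out = fpk_quantify(a, {"g": (500, 500)})
        assert out["no_reads"].iloc[0]
        assert np.isnan(out["ratio"].iloc[0])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            fpk_quantify(pd.DataFrame(columns=["gene_id", "call"]),
                         {"g": (0, 100)})

    def test_ambiguous_excluded_but_reported(self):
        a = pd.DataFrame({"read_id": ["r1", "r2", "r3"], "gene_id": "g",
                          "informative_sites": [1, 1, 0],
                          "at_support": [1, 0, 0], "aa_support": [0, 1, 0],
                          "call": ["At", "Aa", "ambiguous"]})
        out = fpk_quantify(a, {"g": (1000, 1000)})
        assert out["at_reads"].iloc[0] == 1 and out["aa_reads"].iloc[0] == 1
        assert out["dropped"].iloc[0] == 1


class TestConcordance:
    def test_perfect_agreement_r2_one(self):
        x = pd.Series(np.linspace(0.1, 0.9, 20))
        _, r2, p = concordance_with_array(x, x)
        assert r2 == pytest.approx(1.0)

    def test_too_few_genes_no_fit(self):
        x = pd.Series(np.linspace(0, 1, 5))
        tab, r2, p = concordance_with_array(x, x)
        assert r2 is None and len(tab) == 5

    def test_permuted_pairing_kills_signal(self, rng):
        truth = rng.random(200)
        a = pd.Series(truth + rng.normal(0, 0.05, 200))
        b = pd.Series(truth + rng.normal(0, 0.05, 200))
        _, r2, _ = concordance_with_array(a, b)
        perm = pd.Series(rng.permutation(b.to_numpy()), index=b.index)
        _, r2p, pp = concordance_with_array(a, perm)
        assert r2 > 0.8 and r2p < 0.1


class TestSamInput:
    def test_sam_votes_match_internal_mapper(self, tmp_path):
        """A SAM rendering of the same placements reproduces the calls."""
        import pysam

        rng = np.random.default_rng(6)
        at, aa = make_pair(rng, length=250)
        al = align_ortholog_pair(at, aa, gene_id="g1")
        reads = []
        for k in range(10):
            start = int(rng.integers(0, len(aa) - 72))
            reads.append((f"r{k}", aa[start:start + 72], start))
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "g1|At", "LN": len(at)},
                         {"SN": "g1|Aa", "LN": len(aa)}]}
        path = tmp_path / "reads.sam"
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for rid, seq, start in reads:
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = rid
                rec.query_sequence = seq
                rec.reference_name = "g1|Aa"
                rec.reference_start = start
                rec.cigarstring = "72M"
                rec.mapping_quality = 60
                fh.write(rec)
        out = readpart.read_sam_votes(path, {"g1": al}).set_index("read_id")
        assert (out["call"].isin(["Aa", "ambiguous"])).all()
        assert (out.loc[out.informative_sites > 0, "call"] == "Aa").all()
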