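import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mocrkit import motif, synth
from mocrkit.seqio import SequenceRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def rec(name, seq):
    return SequenceRecord(id=name, residues=seq)


class TestReverseComplement:
    def test_inverted_repeat_of_ggcca(self):
        assert motif.reverse_complement("GGCCA") == "TGGCC"

    def test_seven_mer(self):
        assert motif.reverse_complement("GTCCACT") == "AGTGGAC"

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_involution(self, s):
        assert motif.reverse_complement(motif.reverse_complement(s)) == s

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            motif.reverse_complement("ACGU")


class TestBuildPwm:
    def test_unanimous_words_dominate_as_pseudocount_vanishes(self):
        pwm = motif.build_pwm(["AAAA"] * 4, pseudocount=1e-9)
        assert np.allclose(pwm.probs[:, 0], 1.0, atol=1e-9)

    def test_columns_always_sum_to_one(self):
        pwm = motif.build_pwm(["ACGT", "AAAA", "CCGG"], pseudocount=2.0)
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0)

    def test_stated_formula_arithmetic(self):
        pwm = motif.build_pwm(["AC", "AG"], pseudocount=1.0)
        assert pwm.probs[1, 1] == pytest.approx(5 / 12)   # C at column 2

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            motif.build_pwm(["ACG", "AC"])


class TestExactPvalues:
    def random_pwm(self, rng, skewed):
        probs = rng.dirichlet([0.8] * 4, size=5)
        bg = rng.dirichlet([6.0] * 4) if skewed else np.full(4, 0.25)
        return motif.PWM(probs=probs, background=bg)

    def test_dp_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        words = ["".join(w) for w in itertools.product("ACGT", repeat=5)]
        for trial in range(10):
            pwm = self.random_pwm(rng, skewed=trial % 2 == 1)
            table = motif.pvalue_lookup(pwm)
            bound = pwm.width * table.step
            scores = np.array([pwm.score(w) for w in words])
            probs = np.array([np.prod([pwm.background["ACGT".index(c)]
                                       for c in w]) for w in words])
            for w, s in zip(words[::41], scores[::41]):
                p = table.pvalue_word(w)
                lo = probs[scores >= s + bound].sum()
                hi = probs[scores >= s - bound].sum()
                assert lo - 1e-12 <= p <= hi + 1e-12

    def test_unique_maximum_word_has_minimal_pvalue(self):
        # one word strictly dominates every column: p(max) = 1 / 4^w
        probs = np.tile([0.7, 0.1, 0.1, 0.1], (5, 1))
        pwm = motif.PWM(probs=probs, background=np.full(4, 0.25))
        table = motif.pvalue_lookup(pwm)
        assert table.pvalue_word("AAAAA") == pytest.approx(1 / 4 ** 5)

    def test_tail_probabilities_are_monotone(self):
        rng = np.random.default_rng(5)
        pwm = self.random_pwm(rng, skewed=True)
        _, tail, _ = motif.score_distribution(pwm)
        assert np.all(np.diff(tail) <= 1e-15)


class TestScan:
    def test_vacuous_threshold_returns_every_offset(self):
        pwm = motif.build_pwm(["ACGTA", "ACGTA", "ACGTC"])
        seqs = [rec("x", "ACGTACGTAC")]
        occ = motif.scan(pwm, seqs, both_strands=True, p_threshold=1.0)
        assert len(occ) == 2 * (10 - 5 + 1)

    def test_short_sequence_skipped(self):
        pwm = motif.build_pwm(["ACGTA"])
        assert motif.scan(pwm, [rec("x", "ACG")], p_threshold=1.0) == []

    def test_reverse_complemented_input_mirrors_occurrences(self):
        pwm = motif.build_pwm(["ACGGT", "ACGGT", "ACGGA"])
        seq = "TTACGGTCCGGACGGTAAT"
        fwd = motif.scan(pwm, [rec("x", seq)], p_threshold=1.0)
        rev = motif.scan(pwm, [rec("x", motif.reverse_complement(seq))],
                         p_threshold=1.0)
        L = len(seq)
        mirrored = {(L - o.end, L - o.start,
                     "-" if o.strand == "+" else "+", round(o.score, 5))
                    for o in rev}
        ours = {(o.start, o.end, o.strand, round(o.score, 5)) for o in fwd}
        assert ours == mirrored

    def test_pvalues_nonincreasing_in_score(self):
        pwm = motif.build_pwm(["ACGGT", "ACGTT", "TCGGA"])
        occ = motif.scan(pwm, [rec("x", "ACGGTTTTACGTACCGT")],
                         p_threshold=1.0)
        by_score = sorted(occ, key=lambda o: o.score)
        for a, b in zip(by_score, by_score[1:]):
            assert a.p_value >= b.p_value - 1e-15


class TestFindRepeatMotifs:
    def test_planted_inverted_repeat_recovered(self):
        seqs, truth = synth.simulate_intergenic(n_seqs=20, seed=21)
        top = motif.find_repeat_motifs(seqs)[0]
        assert top.consensus == truth.core_word
        arch = top.architecture
        assert arch.spacer_mode("inverted") == truth.spacer
        assert arch.n_inverted >= 20
        assert arch.coverage == 1.0

    def test_poly_a_input_rejected_by_low_complexity_filter(self):
        seqs = [rec(f"s{i}", "A" * 60) for i in range(5)]
        assert motif.find_repeat_motifs(seqs) == []

    def test_direct_repeat_mode_reports_both_architectures(self):
        seqs, _ = synth.simulate_intergenic(
            n_seqs=20, length_bp=120, include_direct_repeat=True, seed=22)
        top = motif.find_repeat_motifs(seqs)[0]
        assert top.consensus == "GGCCA"
        assert top.architecture.n_inverted >= 20
        assert top.architecture.n_direct >= 20

    def test_invariant_under_reordering_and_strand_flips(self):
        seqs, _ = synth.simulate_intergenic(n_seqs=12, seed=23)
        base = motif.find_repeat_motifs(seqs)[0]
        shuffled = list(reversed(seqs))
        shuffled[3] = rec(shuffled[3].id,
                          motif.reverse_complement(shuffled[3].residues))
        flipped = motif.find_repeat_motifs(shuffled)[0]
        canonical = min(base.consensus,
                        motif.reverse_complement(base.consensus))
        canonical2 = min(flipped.consensus,
                         motif.reverse_complement(flipped.consensus))
        assert canonical == canonical2
        assert flipped.architecture.spacer_mode("inverted") == \
            base.architecture.spacer_mode("inverted")

    def test_single_mismatch_occurrences_recovered_within_hamming_one(self):
        hits = 0
        for seed in range(5):
            seqs, truth = synth.simulate_intergenic(
                n_seqs=20, seed=30 + seed, mismatch_position=2)
            found = motif.find_repeat_motifs(seqs, min_fraction=0.25)
            if not found:
                continue
            consensus = found[0].refined_consensus
            hamming = sum(a != b for a, b in zip(consensus, truth.core_word))
            hits += hamming <= 1
        assert hits >= 4

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError, match="3 sequences"):
            motif.find_repeat_motifs([rec("a", "ACGTACGT")] * 2)


class TestUniqueness:
    def site_pwm(self, seqs, truth):
        w = len(truth.core_word)
        spans = []
        texts = {r.id: r.residues for r in seqs}
        per_seq = {}
        for sid, start, _, kind in truth.occurrences:
            per_seq.setdefault(sid, []).append(start)
        for sid, starts in per_seq.items():
            starts.sort()
            spans.append(texts[sid][starts[0]:starts[1] + w])
        return motif.build_pwm(spans)

    def test_planted_regions_significant_background_not(self):
        seqs, truth = synth.simulate_intergenic(n_seqs=20, seed=41)
        pwm = self.site_pwm(seqs, truth)
        rng = np.random.default_rng(42)
        bg = [rec(f"b{i}", "".join("ACGT"[j]
                                   for j in rng.integers(0, 4, 100)))
              for i in range(200)]
        res = motif.uniqueness_test(pwm, seqs, bg, alpha=0.05)
        assert res.regulon_fraction >= 0.95
        assert res.background_fraction <= 0.10

    def test_alpha_zero_rejects_nothing(self):
        seqs, truth = synth.simulate_intergenic(n_seqs=5, seed=43)
        pwm = self.site_pwm(seqs, truth)
        res = motif.uniqueness_test(pwm, seqs, seqs, alpha=0.0)
        assert res.regulon_fraction == 0.0

    def test_empty_input_rejected(self):
        pwm = motif.build_pwm(["ACGTA"])
        with pytest.raises(ValueError, match="nonempty"):
            motif.uniqueness_test(pwm, [], [rec("a", "ACGTACGT")])


class TestExport:
    def test_meme_format_smoke(self, tmp_path):
        pwm = motif.build_pwm(["GGCCA", "GGCCA", "GGCCT"])
        p = tmp_path / "m.meme"
        motif.write_meme([("motif_1", pwm)], p)
        text = p.read_text()
        assert "MEME version 4" in text
        assert "w= 5" in text

    def test_occurrence_bed_smoke(self, tmp_path):
        pwm = motif.build_pwm(["ACGTA", "ACGTA"])
        occ = motif.scan(pwm, [rec("x", "TTACGTATT")], p_threshold=1.0)
        p = tmp_path / "occ.tsv"
        motif.write_occurrences_bed(occ, p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("seqid\t")
        assert len(lines) == len(occ) + 1
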