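import math

import numpy as np
import pytest
from scipy import stats

from mocrkit import sdp, synth
from mocrkit.seqio import Alignment, GroupAssignment, SequenceRecord


def aln(*rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Alignment(rows=[SequenceRecord(id=i, residues=r)
                           for i, r in zip(ids, rows)])


def two_groups(ids):
    half = len(ids) // 2
    return GroupAssignment(labels={i: ("G1" if k < half else "G2")
                                   for k, i in enumerate(ids)})


class TestXdetScores:
    def test_conserved_column_scores_zero(self):
        a = aln("AAC", "AAC", "AAD", "AAD")
        scores = sdp.xdet_scores(a, two_groups(a.ids))
        assert scores[0].xdet_corr == 0.0
        assert scores[1].xdet_corr == 0.0

    def test_perfectly_partitioning_column_scores_one(self):
        # independent oracle: Spearman over the 6 explicit pairs
        a = aln("A", "A", "D", "D")
        scores = sdp.xdet_scores(a, two_groups(a.ids), submatrix="identity")
        sims = [1, 0, 0, 0, 0, 1]       # (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        same = [1, 0, 0, 0, 0, 1]
        rho = stats.spearmanr(sims, same).statistic
        assert rho == pytest.approx(1.0)
        assert scores[0].xdet_corr == pytest.approx(rho)

    def test_scores_bounded_and_group_label_invariant(self):
        a, groups, _, _ = synth.simulate_family(
            n_per_group=5, n_cols=25, n_sdp=3, n_conserved=3, seed=2)
        s1 = sdp.xdet_scores(a, groups)
        flipped = GroupAssignment(labels={
            i: ("X" if g == "YczR" else "Y")
            for i, g in groups.labels.items()})
        s2 = sdp.xdet_scores(a, flipped)
        for a_sc, b_sc in zip(s1, s2):
            assert a_sc.xdet_corr == pytest.approx(b_sc.xdet_corr)
            assert -1.0 <= a_sc.xdet_corr <= 1.0

    def test_planted_columns_outrank_background_without_noise(self):
        a, groups, truth, _ = synth.simulate_family(
            n_per_group=10, n_cols=60, n_sdp=5, n_conserved=5,
            leak=0.0, indel_rate=0.0, seed=4)
        scores = sdp.xdet_scores(a, groups)
        planted = {s.xdet_corr for s in scores
                   if s.column in truth.planted_sdp_columns}
        background = {s.xdet_corr for s in scores
                      if s.column not in truth.planted_sdp_columns}
        assert min(planted) > max(background)

    def test_single_group_rejected(self):
        a = aln("AC", "AD")
        ga = GroupAssignment(labels={"s0": "G", "s1": "G"})
        with pytest.raises(ValueError, match="2 groups"):
            sdp.xdet_scores(a, ga)


class TestS3detAnalysis:
    def test_constant_alignment_gives_single_cluster_zero_scores(self):
        a = aln("ACDE", "ACDE", "ACDE")
        clusters, scores = sdp.s3det_analysis(a, n_axes=2)
        assert set(clusters.values()) == {0}
        assert all(s.s3det_assoc == 0.0 for s in scores)

    def test_unsupervised_clusters_recover_planted_groups(self):
        a, groups, _, _ = synth.simulate_family(
            n_per_group=10, n_cols=60, n_sdp=6, n_conserved=6,
            leak=0.0, indel_rate=0.0, seed=8)
        clusters, _ = sdp.s3det_analysis(a, groups=None, kmeans_seed=0)
        assert len(set(clusters.values())) == 2
        by_group = {}
        for sid, c in clusters.items():
            by_group.setdefault(groups.labels[sid], set()).add(c)
        assert all(len(v) == 1 for v in by_group.values())
        assert by_group["YczR"] != by_group["MocR"]

    def test_planted_association_exceeds_background_quantile(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            a, groups, truth, _ = synth.simulate_family(
                n_per_group=20, n_cols=60, n_sdp=4, n_conserved=6,
                leak=0.05, indel_rate=0.0, seed=seed)
            _, scores = sdp.s3det_analysis(a, groups=groups)
            vals = {s.column: s.s3det_assoc for s in scores}
            bg = [v for c, v in vals.items()
                  if c not in truth.planted_sdp_columns]
            q95 = np.quantile(bg, 0.95)
            if all(vals[c] > q95 for c in truth.planted_sdp_columns):
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_invalid_axis_count_rejected(self):
        a = aln("AC", "AD", "AE")
        with pytest.raises(ValueError, match="n_axes"):
            sdp.s3det_analysis(a, n_axes=3)


class TestMapColumns:
    def test_identity_for_identical_alignments(self):
        a = aln("ACD", "ACE")
        assert sdp.map_columns(a, a, "s0") == {0: 0, 1: 1, 2: 2}

    def test_hand_bookkeeping_across_gap_shifts(self):
        a = aln("A-CD", "AECD", ids=["r", "x"])
        b = aln("AC-D", "AECD", ids=["r", "x"])
        assert sdp.map_columns(a, b, "r") == {0: 0, 2: 1, 3: 3}

    def test_composition_is_identity_on_domain(self):
        _, _, _, alt = synth.simulate_family(indel_rate=0.3, seed=6)
        a, _, _, _ = synth.simulate_family(indel_rate=0.3, seed=6)
        fwd = sdp.map_columns(a, alt, a.ids[0])
        back = sdp.map_columns(alt, a, a.ids[0])
        for c, img in fwd.items():
            assert back[img] == c

    def test_mismatched_reference_rejected(self):
        a = aln("ACD", "ACE")
        b = aln("ACQ", "ACE")
        with pytest.raises(ValueError, match="differs"):
            sdp.map_columns(a, b, "s0")


def flags(xa, sa, xb, sb):
    a = [sdp.ColumnScore(column=0, xdet_flag=xa, s3det_flag=sa)]
    b = [sdp.ColumnScore(column=0, xdet_flag=xb, s3det_flag=sb)]
    return sdp.consensus_sdp(a, b, {0: 0})[0]


class TestConsensusRule:
    def test_both_methods_one_side_one_method_other_is_consensus(self):
        assert flags(True, True, False, True) == {0}
        assert flags(False, True, True, True) == {0}

    def test_single_method_in_both_is_not_consensus(self):
        assert flags(False, True, False, True) == set()

    def test_both_methods_in_both_is_consensus(self):
        assert flags(True, True, True, True) == {0}

    def test_unmapped_flagged_column_cannot_be_consensus(self):
        a = [sdp.ColumnScore(column=0, xdet_flag=True, s3det_flag=True)]
        b = [sdp.ColumnScore(column=0, xdet_flag=True, s3det_flag=True)]
        consensus, unmapped = sdp.consensus_sdp(a, b, {})
        assert consensus == set() and unmapped == {0}

    def test_lowering_threshold_grows_consensus(self):
        a, groups, _, alt = synth.simulate_family(seed=12)
        strict = sdp.build_report(a, alt, groups, a.ids[0], z_threshold=2.0)
        loose = sdp.build_report(a, alt, groups, a.ids[0], z_threshold=1.0)
        assert strict.consensus <= loose.consensus


class TestConsensusRecovery:
    def test_recall_and_precision_on_planted_families(self):
        recalls, precisions = [], []
        for seed in range(5):
            a, groups, truth, alt = synth.simulate_family(seed=seed)
            rep = sdp.build_report(a, alt, groups, a.ids[0])
            tp = len(rep.consensus & truth.planted_sdp_columns)
            recalls.append(tp / len(truth.planted_sdp_columns))
            precisions.append(tp / len(rep.consensus) if rep.consensus else 0.0)
        assert np.mean(recalls) >= 0.85
        assert np.mean(precisions) >= 0.85


class TestLogoData:
    def test_conserved_protein_column_reaches_full_information(self):
        a = aln("A", "A", "A", "A")
        data = sdp.logo_data(a)
        assert data.information[0] == pytest.approx(math.log2(20), abs=1e-12)

    def test_uniform_column_carries_no_information(self):
        rows = [r for r in "ACDEFGHIKLMNPQRSTVWY"]
        a = Alignment(rows=[SequenceRecord(id=f"s{i}", residues=r)
                            for i, r in enumerate(rows)])
        data = sdp.logo_data(a)
        assert data.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_and_half_column(self):
        a = aln("A", "A", "C", "C")
        data = sdp.logo_data(a)
        assert data.information[0] == pytest.approx(math.log2(20) - 1,
                                                    abs=1e-12)

    def test_heights_sum_to_information(self):
        a, _, _, _ = synth.simulate_family(n_per_group=5, n_cols=20,
                                           n_sdp=2, n_conserved=2, seed=3)
        data = sdp.logo_data(a)
        np.testing.assert_allclose(data.heights().sum(axis=1),
                                   data.information, atol=1e-9)
        sums = data.frequencies.sum(axis=1)
        np.testing.assert_allclose(sums[sums > 0], 1.0)

    def test_small_sample_correction_reduces_information(self):
        a = aln("A", "A", "A", "A")
        raw = sdp.logo_data(a).information[0]
        corrected = sdp.logo_data(a, small_sample_correction=True).information[0]
        expected = math.log2(20) - 19 / (2 * math.log(2) * 4)
        assert corrected == pytest.approx(expected, abs=1e-12)
        assert corrected < raw


class TestColumnToResidue:
    def test_examples(self):
        a = aln("A-CD", "AECD", ids=["r", "x"])
        assert sdp.column_to_residue(a, "r", 2) == 1
        assert sdp.column_to_residue(a, "r", 1) is None
        assert [sdp.column_to_residue(a, "x", c) for c in range(4)] == \
            [0, 1, 2, 3]

    def test_out_of_range_rejected(self):
        a = aln("ACD", "ACE")
        with pytest.raises(IndexError):
            sdp.column_to_residue(a, "s0", 5)
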