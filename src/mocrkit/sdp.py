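"""Specificity-determining position (SDP) detection.

Two independent per-column statistics are computed on an alignment of a
family split into subfamilies:

* a mutational-correlation score ("Xdet-style"): for every column the vector
  of pairwise residue similarities over all sequence pairs is rank-correlated
  (Spearman, tie-corrected) with the 0/1 indicator of same-subfamily
  membership;
* a correspondence-analysis score ("S3det-style"): the alignment is encoded
  as a binary column×residue indicator matrix, doubly standardised and
  decomposed by SVD; sequences are clustered in the reduced space (k-means,
  k by silhouette when no labels are given), and each column receives the
  maximal between-cluster separation (largest absolute difference of cluster
  mean projections over axes and cluster pairs) of its residue-indicator
  projections — zero for a column whose residues carry no group signal.

Columns are flagged per alignment when their score lies >= ``z_threshold``
standard deviations above the column-score mean.  Predictions from two
alternative alignments of the same sequences are combined by the consensus
rule: a column is a consensus SDP when both methods flag it in one alignment
and at least one method flags its image in the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import GAP, Alignment, GroupAssignment

DEFAULT_Z = 2.0


def _similarity_matrix(name: str):
    from Bio.Align import substitution_matrices

    if name == "identity":
        return None
    return substitution_matrices.load(name)


@dataclass
class ColumnScore:
    column: int
    xdet_corr: Optional[float] = None
    s3det_assoc: Optional[float] = None
    xdet_flag: bool = False
    s3det_flag: bool = False


@dataclass
class SdpReport:
    scores_A: list[ColumnScore]
    scores_B: list[ColumnScore]
    column_map: dict[int, int]
    consensus: set[int] = field(default_factory=set)
    cluster_assignment: Optional[dict[str, int]] = None
    unmapped_flagged: set[int] = field(default_factory=set)

    def to_dataframe(self) -> pd.DataFrame:
        inv = {v: k for k, v in self.column_map.items()}
        rows = []
        for sc in self.scores_A:
            b = self.column_map.get(sc.column)
            sb = self.scores_B[b] if b is not None else None
            rows.append({
                "column_A": sc.column,
                "column_B": b,
                "xdet_A": sc.xdet_corr, "s3det_A": sc.s3det_assoc,
                "xdet_flag_A": sc.xdet_flag, "s3det_flag_A": sc.s3det_flag,
                "xdet_B": sb.xdet_corr if sb else None,
                "s3det_B": sb.s3det_assoc if sb else None,
                "xdet_flag_B": sb.xdet_flag if sb else False,
                "s3det_flag_B": sb.s3det_flag if sb else False,
                "consensus": sc.column in self.consensus,
            })
        return pd.DataFrame(rows)


def xdet_scores(alignment: Alignment, groups: GroupAssignment,
                submatrix: str = "MCLACHLAN",
                z_threshold: float = DEFAULT_Z) -> list[ColumnScore]:
    """Rank correlation between per-pair residue similarity and same-group
    membership, per column.  Constant-similarity columns score 0; columns
    with fewer than two gap-free pairs are reported unscored.
    """
    groups.check_covers(alignment.ids)
    if len({groups.labels[i] for i in alignment.ids}) < 2:
        raise ValueError("supervised scoring needs >= 2 groups")
    mat = _similarity_matrix(submatrix)
    ids = alignment.ids
    n = len(ids)
    rows = [r.residues for r in alignment.rows]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    same = np.array([groups.labels[ids[i]] == groups.labels[ids[j]]
                     for i, j in pairs], dtype=float)

    def sim(a: str, b: str) -> float:
        if mat is None:
            return 1.0 if a == b else 0.0
        try:
            return float(mat[a, b])
        except (KeyError, IndexError):
            return 0.0

    scores: list[ColumnScore] = []
    for k in range(alignment.n_cols):
        col = [row[k] for row in rows]
        s_vals, f_vals = [], []
        for p, (i, j) in enumerate(pairs):
            if col[i] != GAP and col[j] != GAP:
                s_vals.append(sim(col[i], col[j]))
                f_vals.append(same[p])
        sc = ColumnScore(column=k)
        if len(s_vals) >= 2:
            s_arr = np.asarray(s_vals)
            if np.ptp(s_arr) == 0 or np.ptp(f_vals) == 0:
                sc.xdet_corr = 0.0
            else:
                rho = stats.spearmanr(s_arr, f_vals).statistic
                sc.xdet_corr = float(rho) if math.isfinite(rho) else 0.0
        scores.append(sc)
    _apply_flags(scores, "xdet", z_threshold)
    return scores


def _apply_flags(scores: list[ColumnScore], which: str,
                 z_threshold: float = DEFAULT_Z) -> None:
    attr = "xdet_corr" if which == "xdet" else "s3det_assoc"
    flag = "xdet_flag" if which == "xdet" else "s3det_flag"
    vals = np.array([getattr(s, attr) for s in scores
                     if getattr(s, attr) is not None])
    if vals.size == 0:
        return
    mu, sd = vals.mean(), vals.std()
    for s in scores:
        v = getattr(s, attr)
        if v is None:
            continue
        z = (v - mu) / sd if sd > 0 else 0.0
        setattr(s, flag, bool(z >= z_threshold))


def _indicator_matrix(alignment: Alignment, min_count: int = 1
                      ) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Binary sequence x (column, residue) indicator matrix, gaps excluded.

    Residues observed fewer than ``min_count`` times in a column are dropped:
    a category seen once or twice cannot define a subfamily and, under the
    chi-square weighting of correspondence analysis, rare categories would
    otherwise dominate the leading axes with row-specific noise.
    """
    cols: list[tuple[int, str]] = []
    blocks: list[np.ndarray] = []
    rows = [r.residues for r in alignment.rows]
    for k in range(alignment.n_cols):
        col = [row[k] for row in rows]
        for res in sorted({c for c in col if c != GAP}):
            ind = np.array([1.0 if c == res else 0.0 for c in col])
            if ind.sum() >= min_count:
                cols.append((k, res))
                blocks.append(ind)
    if not blocks:
        return np.zeros((len(rows), 0)), []
    return np.column_stack(blocks), cols


def _correspondence_analysis(N: np.ndarray, n_axes: int):
    """Row/column principal coordinates of a nonnegative indicator matrix."""
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(n_axes, len(sv))
    row_coords = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    col_coords = (Vt[:k].T * sv[:k]) / np.sqrt(c)[:, None]
    return row_coords, col_coords, sv[:k]


def s3det_analysis(alignment: Alignment, n_axes: int = 4,
                   groups: Optional[GroupAssignment] = None,
                   z_threshold: float = DEFAULT_Z,
                   kmeans_seed: int = 0,
                   k_range: tuple[int, int] = (2, 5)
                   ) -> tuple[dict[str, int], list[ColumnScore]]:
    """Correspondence-analysis clustering and per-column association scores.

    Returns the sequence -> cluster assignment and one :class:`ColumnScore`
    per column with ``s3det_assoc`` filled in (nonnegative between-cluster
    mean separation of the column's residue-indicator projections; 0 for
    columns carrying no separation).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    if not 1 <= n_axes < alignment.n_rows:
        raise ValueError("n_axes must be in [1, n_rows)")
    min_count = max(2, round(0.2 * alignment.n_rows))
    N, indicator_cols = _indicator_matrix(alignment, min_count)
    if N.shape[1] == 0:
        assignment = {i: 0 for i in alignment.ids}
        scores = [ColumnScore(column=k, s3det_assoc=0.0)
                  for k in range(alignment.n_cols)]
        return assignment, scores

    row_coords, col_coords, sv = _correspondence_analysis(N, n_axes)
    if np.allclose(sv, 0):
        assignment = {i: 0 for i in alignment.ids}
        scores = [ColumnScore(column=k, s3det_assoc=0.0)
                  for k in range(alignment.n_cols)]
        return assignment, scores

    ids = alignment.ids
    if groups is not None:
        groups.check_covers(ids)
        names = sorted({groups.labels[i] for i in ids})
        lab_of = {g: i for i, g in enumerate(names)}
        cluster = np.array([lab_of[groups.labels[i]] for i in ids])
    else:
        best_k, best_sil, best_labels = None, -np.inf, None
        lo, hi = k_range
        for k in range(lo, min(hi, len(ids) - 1) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=kmeans_seed)
            lab = km.fit_predict(row_coords)
            if len(set(lab)) < 2:
                continue
            sil = silhouette_score(row_coords, lab)
            if sil > best_sil:
                best_k, best_sil, best_labels = k, sil, lab
        cluster = best_labels if best_labels is not None else np.zeros(len(ids), int)
    assignment = {i: int(c) for i, c in zip(ids, cluster)}

    # per column: project each sequence onto its residue-indicator coordinate
    # and take the largest between-cluster mean separation across axes
    by_col: dict[int, list[tuple[str, int]]] = {}
    for idx, (k, res) in enumerate(indicator_cols):
        by_col.setdefault(k, []).append((res, idx))
    rows = [r.residues for r in alignment.rows]
    scores = []
    for k in range(alignment.n_cols):
        entries = dict(by_col.get(k, []))
        proj, labs = [], []
        for i, row in enumerate(rows):
            res = row[k]
            if res == GAP or res not in entries:
                continue
            proj.append(col_coords[entries[res]])
            labs.append(cluster[i])
        sc = ColumnScore(column=k)
        if len(proj) >= 2 and len(set(labs)) >= 2:
            proj_arr = np.asarray(proj)
            labs_arr = np.asarray(labs)
            sc.s3det_assoc = _max_separation(proj_arr, labs_arr)
        else:
            sc.s3det_assoc = 0.0
        scores.append(sc)
    _apply_flags(scores, "s3det", z_threshold)
    return assignment, scores


def _max_separation(proj: np.ndarray, labels: np.ndarray) -> float:
    groups = np.unique(labels)
    means = np.stack([proj[labels == g].mean(axis=0) for g in groups])
    best = 0.0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            best = max(best, float(np.abs(means[a] - means[b]).max()))
    return best


def map_columns(aln_A: Alignment, aln_B: Alignment,
                ref_id: str) -> dict[int, int]:
    """Column correspondence via the ungapped residue index of a reference
    row present in both alignments.  Columns where the reference is gapped
    map to nothing."""
    row_a = aln_A.row(ref_id).residues
    row_b = aln_B.row(ref_id).residues
    if row_a.replace(GAP, "") != row_b.replace(GAP, ""):
        raise ValueError(
            f"ungapped reference {ref_id!r} differs between alignments")
    pos_b: dict[int, int] = {}
    u = 0
    for j, ch in enumerate(row_b):
        if ch != GAP:
            pos_b[u] = j
            u += 1
    mapping: dict[int, int] = {}
    u = 0
    for i, ch in enumerate(row_a):
        if ch != GAP:
            mapping[i] = pos_b[u]
            u += 1
    return mapping


def consensus_sdp(scores_A: list[ColumnScore], scores_B: list[ColumnScore],
                  column_map: dict[int, int]) -> tuple[set[int], set[int]]:
    """Consensus rule over two alignments of the same sequences.

    A column (in A coordinates) is consensus when flagged by both methods in
    one alignment and by at least one method at its image in the other.
    Returns (consensus columns, columns flagged-by-both but lacking an image
    under the map).
    """
    b_by_col = {s.column: s for s in scores_B}
    consensus: set[int] = set()
    unmapped: set[int] = set()
    for sa in scores_A:
        both_a = sa.xdet_flag and sa.s3det_flag
        b_col = column_map.get(sa.column)
        if b_col is None:
            if both_a:
                unmapped.add(sa.column)
            continue
        sb = b_by_col[b_col]
        any_b = sb.xdet_flag or sb.s3det_flag
        both_b = sb.xdet_flag and sb.s3det_flag
        any_a = sa.xdet_flag or sa.s3det_flag
        if (both_a and any_b) or (both_b and any_a):
            consensus.add(sa.column)
    return consensus, unmapped


def build_report(aln_A: Alignment, aln_B: Alignment, groups: GroupAssignment,
                 ref_id: str, submatrix: str = "MCLACHLAN",
                 z_threshold: float = DEFAULT_Z, n_axes: int = 4,
                 kmeans_seed: int = 0, supervised_s3det: bool = True
                 ) -> SdpReport:
    """Run both methods on both alignments and combine by the consensus rule."""
    sA_x = xdet_scores(aln_A, groups, submatrix, z_threshold)
    sB_x = xdet_scores(aln_B, groups, submatrix, z_threshold)
    g = groups if supervised_s3det else None
    clustA, sA_s = s3det_analysis(aln_A, n_axes, g, z_threshold, kmeans_seed)
    _, sB_s = s3det_analysis(aln_B, n_axes, g, z_threshold, kmeans_seed)
    scores_A = _merge(sA_x, sA_s)
    scores_B = _merge(sB_x, sB_s)
    cmap = map_columns(aln_A, aln_B, ref_id)
    consensus, unmapped = consensus_sdp(scores_A, scores_B, cmap)
    return SdpReport(scores_A=scores_A, scores_B=scores_B, column_map=cmap,
                     consensus=consensus, cluster_assignment=clustA,
                     unmapped_flagged=unmapped)


def _merge(xdet: list[ColumnScore], s3det: list[ColumnScore]) -> list[ColumnScore]:
    out = []
    for a, b in zip(xdet, s3det):
        out.append(ColumnScore(column=a.column, xdet_corr=a.xdet_corr,
                               s3det_assoc=b.s3det_assoc,
                               xdet_flag=a.xdet_flag, s3det_flag=b.s3det_flag))
    return out


@dataclass
class LogoData:
    """Per-column residue frequencies, information content (bits) and letter
    heights (frequency × IC), as drawn in a sequence logo."""

    frequencies: pd.DataFrame   # columns = residues, index = alignment column
    information: np.ndarray     # bits per column
    alphabet_size: int

    def heights(self) -> pd.DataFrame:
        return self.frequencies.mul(self.information, axis=0)


def logo_data(alignment: Alignment,
              small_sample_correction: bool = False) -> LogoData:
    """Column frequencies over non-gap symbols and information content
    IC = log2(|alphabet|) − H, optionally minus the small-sample correction
    (|alphabet|−1)/(2·ln2·n)."""
    size = 20 if alignment.alphabet == "protein" else 4
    n_cols = alignment.n_cols
    symbols: set[str] = set()
    counts: list[dict[str, int]] = []
    for k in range(n_cols):
        col = [c for c in alignment.column(k) if c != GAP]
        d: dict[str, int] = {}
        for c in col:
            d[c] = d.get(c, 0) + 1
        counts.append(d)
        symbols |= set(d)
    sym = sorted(symbols)
    freq = np.zeros((n_cols, len(sym)))
    info = np.zeros(n_cols)
    for k, d in enumerate(counts):
        n = sum(d.values())
        if n == 0:
            continue
        for s, c in d.items():
            freq[k, sym.index(s)] = c / n
        p = freq[k][freq[k] > 0]
        h = -(p * np.log2(p)).sum()
        ic = math.log2(size) - h
        if small_sample_correction:
            ic -= (size - 1) / (2 * math.log(2) * n)
        info[k] = max(ic, 0.0)
    return LogoData(frequencies=pd.DataFrame(freq, columns=sym),
                    information=info, alphabet_size=size)


def column_to_residue(alignment: Alignment, ref_id: str,
                      column: int) -> Optional[int]:
    """Ungapped residue index of ``ref_id`` at an alignment column, or None
    when the reference is gapped there."""
    row = alignment.row(ref_id).residues
    if not 0 <= column < len(row):
        raise IndexError(f"column {column} out of range")
    if row[column] == GAP:
        return None
    return sum(1 for c in row[:column] if c != GAP)
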