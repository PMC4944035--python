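"""Synthetic protein families and intergenic DNA with planted ground truth.

Two family generators are provided.  :func:`simulate_family` plants
subfamily-diagnostic (SDP) columns and fully conserved columns in an
otherwise uniform-background alignment — the cleanest substrate for testing
column statistics, since every group-separating column is known.
:func:`simulate_clustered_family` additionally evolves the background
columns down a two-clade tree (root → group ancestor → leaf), so that the
two subfamilies are separated in overall distance, the substrate the
UPGMA/bootstrap stage needs.  Both emit an alternative alignment of the same
sequences produced by re-gapping (shifting each indel run), never by
re-aligning, so the true column correspondence stays recoverable.

The intergenic generator plants a word, a spacer and the word's reverse
complement (an inverted repeat, optionally followed by a direct repeat) on a
Markov background of order 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .motif import reverse_complement
from .seqio import GAP, Alignment, GroupAssignment, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

# order-1 background: mild self-preference, rows sum to 1
_ORDER1_TRANSITIONS = np.full((4, 4), 0.15) + np.eye(4) * 0.40


@dataclass
class FamilyTruth:
    group_of: dict[str, str]
    planted_sdp_columns: set[int]
    sdp_residues: dict[int, dict[str, str]]   # column -> group -> residue
    conserved_columns: set[int]
    leak: float
    # background columns whose group ancestors differ (clustered mode only);
    # these separate the groups just as genuinely as the planted columns
    divergent_columns: set[int] = field(default_factory=set)

    def separating_columns(self) -> set[int]:
        return self.planted_sdp_columns | self.divergent_columns

    def __post_init__(self) -> None:
        if self.planted_sdp_columns & self.conserved_columns:
            raise ValueError("planted and conserved column sets overlap")
        if not 0 <= self.leak <= 1:
            raise ValueError("leak must be in [0, 1]")


@dataclass
class MotifTruth:
    core_word: str
    spacer: int
    occurrences: list[tuple[str, int, str, str]]  # (id, start, strand, kind)

    def __post_init__(self) -> None:
        if not 5 <= len(self.core_word) <= 8:
            raise ValueError("core word width must be in [5, 8]")


def _choose_columns(rng, n_cols: int, n_sdp: int, n_conserved: int):
    if n_sdp + n_conserved >= n_cols:
        raise ValueError("n_sdp + n_conserved must be < n_cols")
    cols = rng.permutation(n_cols)
    return (set(int(c) for c in cols[:n_sdp]),
            set(int(c) for c in cols[n_sdp:n_sdp + n_conserved]))


def _mutate(rng, residue: str, alphabet: str = AMINO_ACIDS) -> str:
    others = alphabet.replace(residue, "")
    return others[rng.integers(len(others))]


def _core_matrix(rng, ids: list[str], group_of: dict[str, str],
                 n_cols: int, n_sdp: int, n_conserved: int, leak: float,
                 clustered: bool, within_rate: float, between_rate: float):
    sdp_cols, cons_cols = _choose_columns(rng, n_cols, n_sdp, n_conserved)
    groups = sorted(set(group_of.values()))
    sdp_residues: dict[int, dict[str, str]] = {}
    cons_residue: dict[int, str] = {}
    for c in sorted(sdp_cols):
        x = AMINO_ACIDS[rng.integers(20)]
        y = _mutate(rng, x)
        sdp_residues[c] = {groups[0]: x, groups[1]: y}
    for c in sorted(cons_cols):
        cons_residue[c] = AMINO_ACIDS[rng.integers(20)]

    bg_cols = [c for c in range(n_cols)
               if c not in sdp_cols and c not in cons_cols]
    root = {c: AMINO_ACIDS[rng.integers(20)] for c in bg_cols}
    ancestor: dict[str, dict[int, str]] = {}
    for g in groups:
        anc = {}
        for c in bg_cols:
            r = root[c]
            if clustered and rng.random() < between_rate:
                r = _mutate(rng, r)
            anc[c] = r
        ancestor[g] = anc
    divergent = {c for c in bg_cols
                 if len({ancestor[g][c] for g in groups}) > 1}

    mat = np.empty((len(ids), n_cols), dtype="<U1")
    for i, sid in enumerate(ids):
        g = group_of[sid]
        for c in range(n_cols):
            if c in cons_cols:
                mat[i, c] = cons_residue[c]
            elif c in sdp_cols:
                res = sdp_residues[c][g]
                if rng.random() < leak:
                    res = _mutate(rng, res)
                mat[i, c] = res
            elif clustered:
                r = ancestor[g][c]
                if rng.random() < within_rate:
                    r = _mutate(rng, r)
                mat[i, c] = r
            else:
                mat[i, c] = AMINO_ACIDS[rng.integers(20)]
    truth = FamilyTruth(group_of=dict(group_of),
                        planted_sdp_columns=sdp_cols,
                        sdp_residues=sdp_residues,
                        conserved_columns=cons_cols, leak=leak,
                        divergent_columns=divergent)
    return mat, truth


def _apply_indels(rng, mat: np.ndarray, ids: list[str], indel_rate: float):
    """Delete a short run per affected row; return rows for the true
    alignment (gaps at the true position) and a re-gapped alternative
    (the gap run shifted by 1-2 columns).  Row 0 is kept indel-free so it
    can serve as the cross-alignment reference."""
    n_rows, n_cols = mat.shape
    rows_a, rows_b = [], []
    for i in range(n_rows):
        residues = "".join(mat[i])
        if i == 0 or rng.random() >= indel_rate:
            rows_a.append(residues)
            rows_b.append(residues)
            continue
        length = int(rng.integers(1, 4))
        start = int(rng.integers(0, n_cols - length + 1))
        ungapped = residues[:start] + residues[start + length:]
        row_a = residues[:start] + GAP * length + residues[start + length:]
        delta = int(rng.choice([-2, -1, 1, 2]))
        g = min(max(start + delta, 0), len(ungapped))
        row_b = ungapped[:g] + GAP * length + ungapped[g:]
        rows_a.append(row_a)
        rows_b.append(row_b)
    return rows_a, rows_b


def _assemble(ids: list[str], rows: list[str]) -> Alignment:
    return Alignment(rows=[SequenceRecord(id=i, residues=r)
                           for i, r in zip(ids, rows)], alphabet="protein")


def _simulate(n_per_group: int, n_cols: int, n_sdp: int, n_conserved: int,
              leak: float, indel_rate: float, seed: int, clustered: bool,
              within_rate: float, between_rate: float,
              group_names: tuple[str, str]):
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    rng = np.random.default_rng(seed)
    g1, g2 = group_names
    ids = [f"{g1}_{i:02d}" for i in range(n_per_group)] + \
          [f"{g2}_{i:02d}" for i in range(n_per_group)]
    group_of = {sid: (g1 if sid.startswith(g1) else g2) for sid in ids}
    mat, truth = _core_matrix(rng, ids, group_of, n_cols, n_sdp, n_conserved,
                              leak, clustered, within_rate, between_rate)
    rows_a, rows_b = _apply_indels(rng, mat, ids, indel_rate)
    return (_assemble(ids, rows_a), GroupAssignment(labels=group_of),
            truth, _assemble(ids, rows_b))


def simulate_family(n_per_group: int = 20, n_cols: int = 120, n_sdp: int = 8,
                    n_conserved: int = 20, leak: float = 0.05,
                    indel_rate: float = 0.02, seed: int = 0,
                    group_names: tuple[str, str] = ("YczR", "MocR")):
    """Two-subfamily alignment with planted SDP and conserved columns over a
    uniform amino-acid background; returns (alignment, groups, truth,
    alternative alignment)."""
    return _simulate(n_per_group, n_cols, n_sdp, n_conserved, leak,
                     indel_rate, seed, clustered=False, within_rate=0.0,
                     between_rate=0.0, group_names=group_names)


def simulate_clustered_family(n_per_group: int = 20, n_cols: int = 120,
                              n_sdp: int = 8, n_conserved: int = 20,
                              leak: float = 0.05, indel_rate: float = 0.02,
                              within_rate: float = 0.15,
                              between_rate: float = 0.08, seed: int = 0,
                              group_names: tuple[str, str] = ("YczR", "MocR")):
    """Like :func:`simulate_family` but background columns evolve down a
    two-clade tree: each group ancestor mutates from a shared root at
    ``between_rate`` per site and leaves mutate from their ancestor at
    ``within_rate``.  Background columns whose ancestors ended up different
    are recorded in ``truth.divergent_columns``: they separate the groups
    exactly as the planted columns do.  The defaults give a family with
    ~78% within-group identity (it passes a 90% redundancy filter intact)
    and a clear two-clade distance structure; for between-group divergence
    ~3x the within-group one use within_rate=0.05, between_rate=0.13."""
    return _simulate(n_per_group, n_cols, n_sdp, n_conserved, leak,
                     indel_rate, seed, clustered=True,
                     within_rate=within_rate, between_rate=between_rate,
                     group_names=group_names)


def _background_seq(rng, length: int, order: int) -> list[str]:
    if order == 0:
        return [DNA[i] for i in rng.integers(0, 4, size=length)]
    if order != 1:
        raise ValueError("background_order must be 0 or 1")
    out = [int(rng.integers(4))]
    for _ in range(length - 1):
        out.append(int(rng.choice(4, p=_ORDER1_TRANSITIONS[out[-1]])))
    return [DNA[i] for i in out]


def simulate_intergenic(n_seqs: int = 20, length_bp: int = 100,
                        core_word: str = "GGCCA", spacer: int = 12,
                        include_direct_repeat: bool = False,
                        background_order: int = 0, seed: int = 0,
                        mismatch_position: Optional[int] = None):
    """Intergenic regions each carrying core word + spacer + reverse
    complement (and optionally a third, direct-repeat copy after another
    spacer); returns (records, truth).

    ``mismatch_position`` plants, per sequence, one substitution at that
    word position, applied consistently to every copy of the pair (the
    second copy stays the exact reverse complement of the first).
    """
    if set(core_word) - set(DNA):
        raise ValueError(f"core word must be ACGT, got {core_word!r}")
    if not 5 <= len(core_word) <= 8:
        raise ValueError("core word width must be in [5, 8]")
    w = len(core_word)
    arch = 2 * w + spacer + ((w + spacer) if include_direct_repeat else 0)
    if length_bp < arch:
        raise ValueError(f"length_bp must be >= {arch}")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    occurrences: list[tuple[str, int, str, str]] = []
    for s in range(n_seqs):
        sid = f"ig_{s:03d}"
        seq = _background_seq(rng, length_bp, background_order)
        word = core_word
        if mismatch_position is not None:
            sub = _mutate(rng, core_word[mismatch_position], DNA)
            word = (core_word[:mismatch_position] + sub
                    + core_word[mismatch_position + 1:])
        start = int(rng.integers(0, length_bp - arch + 1))
        copies = [(start, word, "+", "direct"),
                  (start + w + spacer, reverse_complement(word), "-",
                   "inverted")]
        if include_direct_repeat:
            copies.append((start + 2 * (w + spacer), word, "+", "direct"))
        for pos, text, strand, kind in copies:
            seq[pos:pos + w] = list(text)
            occurrences.append((sid, pos, strand, kind))
        records.append(SequenceRecord(id=sid, residues="".join(seq)))
    truth = MotifTruth(core_word=core_word, spacer=spacer,
                       occurrences=occurrences)
    return records, truth


def write_family_truth(truth: FamilyTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\trole\tdetail\n")
        for c in sorted(truth.planted_sdp_columns):
            detail = ",".join(f"{g}:{r}" for g, r in
                              sorted(truth.sdp_residues[c].items()))
            fh.write(f"{c}\tsdp\t{detail}\n")
        for c in sorted(truth.conserved_columns):
            fh.write(f"{c}\tconserved\t.\n")
        for c in sorted(truth.divergent_columns):
            fh.write(f"{c}\tdivergent\t.\n")


def read_family_truth_columns(path: str | Path,
                              roles: tuple[str, ...] = ("sdp",)) -> set[int]:
    cols = set()
    with open(path) as fh:
        next(fh)
        for line in fh:
            c, role, _ = line.rstrip("\n").split("\t")
            if role in roles:
                cols.add(int(c))
    return cols


def write_motif_truth(truth: MotifTruth, path: str | Path) -> None:
    w = len(truth.core_word)
    with open(path, "w") as fh:
        fh.write(f"# core_word={truth.core_word} spacer={truth.spacer}\n")
        fh.write("seqid\tstart\tend\tstrand\tkind\n")
        for sid, start, strand, kind in truth.occurrences:
            fh.write(f"{sid}\t{start}\t{start + w}\t{strand}\t{kind}\n")
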