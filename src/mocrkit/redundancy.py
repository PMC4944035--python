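"""Greedy identity-threshold de-redundancy of sequence sets.

Mirrors CD-HIT semantics: records are sorted by length (longest first,
input order on ties); the first unassigned record founds a cluster and each
later record joins the first representative it matches at or above the
identity threshold (first-fit, not best-fit).  Identity is the fraction of
matching residues over alignment columns where both sequences carry a
residue (gap-excluded denominator).  Unequal-length pairs are globally
aligned first with BLOSUM62, gap open -10 / extend -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GAP, SequenceRecord

ALIGN_PARAMS = {"matrix": "BLOSUM62", "open": -10.0, "extend": -1.0}


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ALIGN_PARAMS["matrix"])
    aligner.open_gap_score = ALIGN_PARAMS["open"]
    aligner.extend_gap_score = ALIGN_PARAMS["extend"]
    return aligner


_PROTEIN_ALIGNER = None


def pairwise_identity(a: SequenceRecord, b: SequenceRecord,
                      aligned: Optional[bool] = None) -> float:
    """Fraction of identical residues over gap-free columns.

    ``aligned=None`` treats equal-length inputs as already aligned
    (positional comparison) and aligns unequal-length pairs globally.
    """
    global _PROTEIN_ALIGNER
    sa, sb = a.residues, b.residues
    if not sa or not sb:
        raise ValueError("empty sequence")
    if aligned is None:
        aligned = len(sa) == len(sb)
    if aligned:
        if len(sa) != len(sb):
            raise ValueError("aligned identity needs equal-length sequences")
        matches = denom = 0
        for x, y in zip(sa, sb):
            if x != GAP and y != GAP:
                denom += 1
                matches += x == y
        return matches / denom if denom else 0.0
    if _PROTEIN_ALIGNER is None:
        _PROTEIN_ALIGNER = _aligner()
    sa, sb = sa.replace(GAP, ""), sb.replace(GAP, "")
    aln = _PROTEIN_ALIGNER.align(sa, sb)[0]
    matches = denom = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        denom += a1 - a0
        for x, y in zip(sa[a0:a1], sb[b0:b1]):
            matches += x == y
    return matches / denom if denom else 0.0


@dataclass
class ClusterSet:
    """Result of greedy clustering: (representative id, member ids) pairs."""

    clusters: list[tuple[str, list[str]]]
    threshold: float

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def cluster_of(self, seq_id: str) -> str:
        for rep, members in self.clusters:
            if seq_id == rep or seq_id in members:
                return rep
        raise KeyError(seq_id)


def greedy_cluster(records: list[SequenceRecord],
                   threshold: float) -> ClusterSet:
    """Greedy first-fit identity clustering at ``threshold`` in (0, 1]."""
    if not records:
        raise ValueError("need at least one record")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(range(len(records)),
                   key=lambda i: (-len(records[i].ungapped()), i))
    reps: list[SequenceRecord] = []
    clusters: list[tuple[str, list[str]]] = []
    for i in order:
        rec = records[i]
        stripped = SequenceRecord(id=rec.id, residues=rec.ungapped())
        placed = False
        for j, rep in enumerate(reps):
            if pairwise_identity(rep, stripped) >= threshold:
                clusters[j][1].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(stripped)
            clusters.append((rec.id, []))
    return ClusterSet(clusters=clusters, threshold=threshold)


def write_cluster_report(cs: ClusterSet, records: list[SequenceRecord],
                         path: str | Path) -> None:
    by_id = {r.id: SequenceRecord(id=r.id, residues=r.ungapped())
             for r in records}
    with open(path, "w") as fh:
        fh.write("representative\tmember\tidentity\n")
        for rep, members in cs.clusters:
            fh.write(f"{rep}\t{rep}\t1.0000\n")
            for m in members:
                ident = pairwise_identity(by_id[rep], by_id[m])
                fh.write(f"{rep}\t{m}\t{ident:.4f}\n")
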