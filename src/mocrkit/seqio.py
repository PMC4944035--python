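"""Reading, writing and validation of the formats the pipeline touches.

Sequences and alignments travel as FASTA, group labels as a two-column TSV
(``id``, ``group``), trees as Newick.  All coordinates inside the package are
0-based half-open; 1-based numbering appears only in rendered reports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = set("ACGTN")
GAP = "-"

_NEWICK_RESERVED = re.compile(r"[\s()\[\]{}:;,']")


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header, illegal character, duplicate id)."""


class AlignmentShapeError(ValueError):
    """Rows of an alignment do not form a rectangle."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; ``residues`` may contain '-' when aligned."""

    id: str
    residues: str
    description: str = ""

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A rectangular gapped sequence set.

    Invariants (enforced by :func:`validate_alignment`): all rows equal
    length, at least two rows, unique ids.  All-gap columns are legal but
    flagged with a warning on read.
    """

    rows: list[SequenceRecord]
    alphabet: str = "protein"

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def column(self, k: int) -> str:
        if not 0 <= k < self.n_cols:
            raise IndexError(f"column {k} out of range [0, {self.n_cols})")
        return "".join(r.residues[k] for r in self.rows)

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        return Alignment(rows=[r for r in self.rows if r.id in keep],
                         alphabet=self.alphabet)


@dataclass
class GroupAssignment:
    """Mapping sequence id -> subfamily label."""

    labels: dict[str, str]

    @property
    def groups(self) -> set[str]:
        return set(self.labels.values())

    def members(self, group: str) -> set[str]:
        return {i for i, g in self.labels.items() if g == group}

    def check_covers(self, ids: Sequence[str]) -> None:
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ValueError(f"ids without a group label: {missing[:5]}")


def _alphabet_set(alphabet: str) -> set[str]:
    if alphabet == "protein":
        return PROTEIN_ALPHABET | {GAP, "X"}
    if alphabet == "dna":
        return DNA_ALPHABET | {GAP}
    raise ValueError(f"unknown alphabet {alphabet!r}")


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Parse a FASTA file into records, preserving order.

    Ids are the first whitespace-delimited token of the header; residues are
    uppercased and '.' gaps converted to '-'.  Errors name the offending line.
    """
    allowed = _alphabet_set(alphabet)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaFormatError(
                f"line {header_line}: record {header!r} has no sequence")
        bad = set(seq) - allowed
        if bad:
            raise FastaFormatError(
                f"line {line_no}: illegal character(s) {sorted(bad)} "
                f"in record {header!r} for alphabet {alphabet!r}")
        records.append(SequenceRecord(id=header, residues=seq, description=desc))
        header = None
        chunks.clear()

    with open(path) as fh:
        last = 0
        for line_no, raw in enumerate(fh, start=1):
            last = line_no
            line = raw.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no - 1)
                body = line[1:].strip()
                if not body:
                    raise FastaFormatError(f"line {line_no}: empty FASTA header")
                parts = body.split(None, 1)
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                header_line = line_no
                if header in seen:
                    raise FastaFormatError(
                        f"line {line_no}: duplicate id {header!r}")
                seen.add(header)
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {line_no}: sequence data before any header")
                chunks.append(line.strip().upper().replace(".", GAP))
        flush(last)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def validate_alignment(records: list[SequenceRecord],
                       alphabet: str = "protein") -> Alignment:
    if len(records) < 2:
        raise AlignmentShapeError(
            f"an alignment needs at least 2 rows, got {len(records)}")
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"ragged alignment: row lengths {sorted(lengths)}")
    aln = Alignment(rows=list(records), alphabet=alphabet)
    for k in range(aln.n_cols):
        if set(aln.column(k)) == {GAP}:
            logger.warning("alignment column %d is all gaps", k)
    return aln


def read_alignment(path: str | Path, alphabet: str = "protein") -> Alignment:
    return validate_alignment(read_fasta(path, alphabet), alphabet)


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a TSV with header columns ``id`` and ``group``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "group"} <= set(df.columns):
        raise ValueError(f"group table must have columns id, group; got {list(df.columns)}")
    if df["id"].duplicated().any():
        raise ValueError("duplicate ids in group table")
    return GroupAssignment(labels=dict(zip(df["id"], df["group"])))


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\n")
        for i, g in groups.labels.items():
            fh.write(f"{i}\t{g}\n")


def _newick_label(name: str) -> str:
    if _NEWICK_RESERVED.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node, parent_height: float | None) -> str:
    if node.is_leaf():
        body = _newick_label(node.name)
    else:
        inner = ",".join(_newick_node(c, node.height) for c in node.children)
        body = f"({inner})"
        if node.support is not None:
            body += format(node.support, "g")
    if parent_height is not None:
        body += ":" + format(parent_height - node.height, "g")
    return body


def write_newick(tree, path: str | Path) -> None:
    """Serialise an ultrametric tree: branch length = parent − child height,
    internal labels = bootstrap support when present."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def newick_string(tree) -> str:
    return _newick_node(tree.root, None) + ";"
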