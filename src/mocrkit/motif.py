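"""Discovery and scanning of short direct/inverted-repeat DNA motifs.

The discovery step enumerates every word of width 5–8 present in a set of
intergenic regions, collapsing each word with its reverse complement into one
candidate, and keeps words that occur at least twice (word or reverse
complement, forward strand) within a bounded spacer in a minimum fraction of
sequences — the architecture a dimeric regulator binding a palindromic or
tandem site leaves in its operators.  Candidates are ranked by (sequence
coverage, total occurrences, PWM information content) and refined by one
round of PWM re-estimation from the best per-sequence matches.

Scanning computes a log-odds score at every offset and an exact p-value by
dynamic programming over the discretised score distribution under the
background model.  The per-region uniqueness test Bonferroni-corrects the
best match p-value for the number of scanned offsets × strands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# p-value DP granularity: each log-odds cell is rounded to the score range
# divided by this many steps; worst-case per-word error is w * step / 2
PVALUE_GRANULARITY = 10_000


def reverse_complement(s: str) -> str:
    if set(s) - set("ACGTN"):
        raise ValueError(f"non-ACGTN character in {s!r}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position frequency matrix with its background and log-odds form."""

    probs: np.ndarray            # (width, 4) column frequencies, rows sum to 1
    background: np.ndarray       # (4,) background frequencies, sums to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        self.background = np.asarray(self.background, float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_content(self) -> float:
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        return float((2.0 + h).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(probs=self.probs[::-1, ::-1].copy(),
                   background=self.background[::-1].copy())

    def score(self, word: str) -> float:
        lo = self.log_odds
        return float(sum(lo[i, BASES.index(c)] for i, c in enumerate(word)))


def build_pwm(words: Sequence[str], background: Optional[Sequence[float]] = None,
              pseudocount: float = 0.5) -> PWM:
    """Frequencies = (counts + pseudocount·background) / (n + pseudocount)."""
    if not words:
        raise ValueError("no words")
    w = len(words[0])
    if any(len(x) != w for x in words):
        raise ValueError("words differ in width")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = np.zeros((w, 4))
    for word in words:
        for i, c in enumerate(word):
            counts[i, BASES.index(c)] += 1
    probs = (counts + pseudocount * bg) / (len(words) + pseudocount)
    return PWM(probs=probs, background=bg)


# ---------------------------------------------------------------------------
# exact p-values

def _discretise(pwm: PWM) -> tuple[np.ndarray, float]:
    lo = pwm.log_odds
    rng = lo.max(axis=1).sum() - lo.min(axis=1).sum()
    step = rng / PVALUE_GRANULARITY if rng > 0 else 1.0
    return np.rint(lo / step).astype(np.int64), step


def score_distribution(pwm: PWM) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact distribution of the discretised log-odds score of a random word
    drawn from the background: (integer scores, tail probabilities P(S >= s),
    discretisation step)."""
    scaled, step = _discretise(pwm)
    offset = -scaled.min(axis=1).sum()
    size = int(scaled.max(axis=1).sum() + offset) + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    lo_cum = 0
    for row in scaled:
        new = np.zeros(size)
        base = int(row.min())
        for b in range(4):
            shift = int(row[b] - base)
            p = pwm.background[b]
            if shift == 0:
                new += p * dist
            else:
                new[shift:] += p * dist[:size - shift]
        lo_cum += base
        dist = new
    support = np.nonzero(dist)[0]
    scores = support + lo_cum
    probs = dist[support]
    # tail: P(S >= s), scores ascending
    tail = probs[::-1].cumsum()[::-1]
    return scores, tail, step


class PvalueTable:
    """Exact tail probabilities of the discretised log-odds score.

    Word p-values are computed on the same integer grid the DP uses, so a
    word's p-value equals exhaustive enumeration over the discretised
    scores; versus the continuous scores the error is bounded by the mass
    of words within width × step of the threshold.
    """

    def __init__(self, pwm: PWM):
        self.scaled, self.step = _discretise(pwm)
        self.scores, self.tail, _ = score_distribution(pwm)

    def _tail_at(self, s: int) -> float:
        idx = np.searchsorted(self.scores, s, side="left")
        if idx >= len(self.scores):
            return 0.0
        return float(self.tail[idx])

    def pvalue_word(self, word: str) -> float:
        s = int(sum(self.scaled[i, BASES.index(c)]
                    for i, c in enumerate(word)))
        return self._tail_at(s)

    def pvalue_score(self, x: float) -> float:
        return self._tail_at(int(round(x / self.step)))


def pvalue_lookup(pwm: PWM) -> PvalueTable:
    return PvalueTable(pwm)


@dataclass
class Occurrence:
    seq_id: str
    start: int
    end: int
    strand: str
    word: str
    score: float
    p_value: float


def _encode_seq(s: str) -> np.ndarray:
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def scan(pwm: PWM, seqs: Sequence[SequenceRecord], both_strands: bool = True,
         p_threshold: float = 1e-3) -> list[Occurrence]:
    """All matches with exact p-value <= threshold, sorted by sequence then
    position.  Minus-strand occurrences carry forward-strand coordinates and
    the matching word as read on the minus strand."""
    w = pwm.width
    table = pvalue_lookup(pwm)
    lo = pwm.log_odds
    out: list[Occurrence] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for rec in seqs:
        seq = rec.residues.upper()
        if len(seq) < w:
            logger.info("sequence %s shorter than motif width, skipped", rec.id)
            continue
        enc = _encode_seq(seq)
        for strand in strands:
            mats = lo if strand == "+" else pwm.reverse_complement().log_odds
            for start in range(len(seq) - w + 1):
                window = enc[start:start + w]
                if (window < 0).any():
                    continue
                s = float(mats[np.arange(w), window].sum())
                # p-value defined on the + orientation score of the match
                word = seq[start:start + w]
                if strand == "-":
                    word = reverse_complement(word)
                p = table.pvalue_word(word)
                if p <= p_threshold:
                    out.append(Occurrence(rec.id, start, start + w, strand,
                                          word, round(s, 6), p))
    out.sort(key=lambda o: (o.seq_id, o.start, o.strand))
    return out


# ---------------------------------------------------------------------------
# repeat discovery

@dataclass
class RepeatPair:
    seq_id: str
    first: tuple[int, str]       # (start, orientation 'w'|'rc')
    second: tuple[int, str]
    kind: str                    # 'direct' | 'inverted'
    spacer: int


@dataclass
class RepeatArchitecture:
    word: str
    width: int
    pairs: list[RepeatPair]
    coverage: float              # fraction of sequences with >= 1 pair
    n_occurrences: int

    @property
    def n_direct(self) -> int:
        return sum(1 for p in self.pairs if p.kind == "direct")

    @property
    def n_inverted(self) -> int:
        return sum(1 for p in self.pairs if p.kind == "inverted")

    def spacer_mode(self, kind: Optional[str] = None) -> Optional[int]:
        sp = [p.spacer for p in self.pairs if kind is None or p.kind == kind]
        if not sp:
            return None
        vals, counts = np.unique(sp, return_counts=True)
        return int(vals[counts.argmax()])

    def spacer_sd(self, kind: Optional[str] = None) -> float:
        sp = [p.spacer for p in self.pairs if kind is None or p.kind == kind]
        return float(np.std(sp)) if sp else float("nan")


@dataclass
class DiscoveredMotif:
    pwm: PWM
    architecture: RepeatArchitecture
    consensus: str
    refined_consensus: str


def _word_occurrences(seq: str, word: str) -> list[tuple[int, str]]:
    """Forward-strand positions of the word ('w') and its reverse
    complement ('rc'); palindromic words are recorded once as 'w'."""
    rc = reverse_complement(word)
    occ: list[tuple[int, str]] = []
    for start in range(len(seq) - len(word) + 1):
        window = seq[start:start + len(word)]
        if window == word:
            occ.append((start, "w"))
        elif window == rc:
            occ.append((start, "rc"))
    return occ


def _pairs_for(seq_id: str, occ: list[tuple[int, str]], width: int,
               max_spacer: int) -> list[RepeatPair]:
    pairs = []
    for a in range(len(occ)):
        for b in range(a + 1, len(occ)):
            (s1, o1), (s2, o2) = occ[a], occ[b]
            spacer = s2 - (s1 + width)
            if spacer < 0 or spacer > max_spacer:
                continue
            kind = "direct" if o1 == o2 else "inverted"
            pairs.append(RepeatPair(seq_id, (s1, o1), (s2, o2), kind, spacer))
    return pairs


def _low_complexity(word: str) -> bool:
    return len(set(word)) < 2


def find_repeat_motifs(seqs: Sequence[SequenceRecord], w_min: int = 5,
                       w_max: int = 8, min_fraction: float = 0.6,
                       max_spacer: int = 40,
                       background: Optional[Sequence[float]] = None,
                       pseudocount: float = 0.5,
                       top_n: int = 10) -> list[DiscoveredMotif]:
    """Enumerate repeated words of width ``w_min..w_max`` and rank them.

    A candidate survives when, in at least ``min_fraction`` of the sequences,
    it (or its reverse complement) occurs >= 2 times with spacer <=
    ``max_spacer``.  Single-letter words are rejected as low complexity.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    if w_min > w_max:
        raise ValueError("w_min must be <= w_max")
    texts = {r.id: r.residues.upper() for r in seqs}
    n_seqs = len(seqs)
    candidates: dict[str, None] = {}
    for seq in texts.values():
        for w in range(w_min, w_max + 1):
            for i in range(len(seq) - w + 1):
                word = seq[i:i + w]
                if "N" in word or _low_complexity(word):
                    continue
                candidates[min(word, reverse_complement(word))] = None

    results: list[tuple[tuple, DiscoveredMotif]] = []
    for word in candidates:
        w = len(word)
        all_pairs: list[RepeatPair] = []
        covered = 0
        words_seen: list[str] = []
        for sid, seq in texts.items():
            occ = _word_occurrences(seq, word)
            pairs = _pairs_for(sid, occ, w, max_spacer)
            if pairs:
                covered += 1
                all_pairs.extend(pairs)
                for start, orient in occ:
                    sub = seq[start:start + w]
                    words_seen.append(sub if orient == "w"
                                      else reverse_complement(sub))
        coverage = covered / n_seqs
        if coverage < min_fraction or not all_pairs:
            continue
        pwm = build_pwm(words_seen, background, pseudocount)
        arch = RepeatArchitecture(word=word, width=w, pairs=all_pairs,
                                  coverage=coverage,
                                  n_occurrences=len(words_seen))
        refined = _refine_consensus(pwm, seqs)
        motif = DiscoveredMotif(pwm=pwm, architecture=arch,
                                consensus=pwm.consensus(),
                                refined_consensus=refined)
        key = (-coverage, -len(words_seen), -pwm.information_content(), word)
        results.append((key, motif))

    if not results:
        logger.info("no repeated motif candidate survived the filters")
    results.sort(key=lambda t: t[0])
    return [m for _, m in results[:top_n]]


def _refine_consensus(pwm: PWM, seqs: Sequence[SequenceRecord]) -> str:
    """One round of PWM re-estimation from the best per-sequence match."""
    best_words = []
    w = pwm.width
    lo = pwm.log_odds
    rc = pwm.reverse_complement().log_odds
    for rec in seqs:
        seq = rec.residues.upper()
        if len(seq) < w:
            continue
        enc = _encode_seq(seq)
        best, best_s = None, -np.inf
        for start in range(len(seq) - w + 1):
            window = enc[start:start + w]
            if (window < 0).any():
                continue
            for mats, is_rc in ((lo, False), (rc, True)):
                s = float(mats[np.arange(w), window].sum())
                if s > best_s:
                    word = seq[start:start + w]
                    best = reverse_complement(word) if is_rc else word
                    best_s = s
        if best is not None:
            best_words.append(best)
    if not best_words:
        return pwm.consensus()
    return build_pwm(best_words, list(pwm.background)).consensus()


# ---------------------------------------------------------------------------
# uniqueness test

@dataclass
class UniquenessVerdict:
    seq_id: str
    best_p: float
    adjusted_p: float
    n_tests: int
    significant: bool


@dataclass
class UniquenessResult:
    regulon: list[UniquenessVerdict]
    background: list[UniquenessVerdict]
    alpha: float

    @property
    def regulon_fraction(self) -> float:
        return float(np.mean([v.significant for v in self.regulon]))

    @property
    def background_fraction(self) -> float:
        return float(np.mean([v.significant for v in self.background]))


def _best_match_verdicts(pwm: PWM, seqs: Sequence[SequenceRecord],
                         alpha: float) -> list[UniquenessVerdict]:
    w = pwm.width
    table = pvalue_lookup(pwm)
    lo = pwm.log_odds
    rc = pwm.reverse_complement().log_odds
    out = []
    for rec in seqs:
        seq = rec.residues.upper()
        enc = _encode_seq(seq)
        n_off = max(len(seq) - w + 1, 0)
        best = -np.inf
        best_word = None
        for start in range(n_off):
            window = enc[start:start + w]
            if (window < 0).any():
                continue
            for mats, is_rc in ((lo, False), (rc, True)):
                s = float(mats[np.arange(w), window].sum())
                if s > best:
                    best = s
                    word = seq[start:start + w]
                    best_word = reverse_complement(word) if is_rc else word
        n_tests = 2 * n_off
        if best_word is None:
            out.append(UniquenessVerdict(rec.id, 1.0, 1.0, n_tests, False))
            continue
        p = table.pvalue_word(best_word)
        adj = min(1.0, p * n_tests)
        out.append(UniquenessVerdict(rec.id, p, adj, n_tests,
                                     bool(adj < alpha)))
    return out


def uniqueness_test(pwm: PWM, regulon_regions: Sequence[SequenceRecord],
                    background_regions: Sequence[SequenceRecord],
                    alpha: float = 0.05) -> UniquenessResult:
    """Per-region best-match significance with Bonferroni correction over
    scanned offsets × strands; summarises the significant fraction in the
    regulon set versus the background set."""
    if not regulon_regions or not background_regions:
        raise ValueError("both sequence sets must be nonempty")
    return UniquenessResult(
        regulon=_best_match_verdicts(pwm, regulon_regions, alpha),
        background=_best_match_verdicts(pwm, background_regions, alpha),
        alpha=alpha)


# ---------------------------------------------------------------------------
# export

def write_meme(pwms: Iterable[tuple[str, PWM]], path) -> None:
    """Minimal MEME motif text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        first = True
        for name, pwm in pwms:
            if first:
                bg = " ".join(f"{b} {f:.5f}" for b, f in
                              zip(BASES, pwm.background))
                fh.write(f"Background letter frequencies\n{bg}\n\n")
                first = False
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def write_occurrences_bed(occurrences: Sequence[Occurrence], path) -> None:
    with open(path, "w") as fh:
        fh.write("seqid\tstart\tend\tname\tscore\tstrand\tp_value\n")
        for o in occurrences:
            fh.write(f"{o.seq_id}\t{o.start}\t{o.end}\t{o.word}\t"
                     f"{o.score:.4f}\t{o.strand}\t{o.p_value:.3e}\n")
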