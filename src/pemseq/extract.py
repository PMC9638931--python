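"""Junction extraction: turn PEM-seq read pairs into breakpoint records.

R1 anchors at the bait primer; the maximal reference-matching bait prefix is
found by extension from the primer, and the remaining suffix is mapped
against genome + viral reference by exact 20-mer seeds and extension on both
strands. The bait and prey alignments are then resolved at the breakpoint:
overlapping bases are microhomology (assigned to the bait side, prey start
advanced), a gap between them is an untemplated insertion. The sonication
fragment length — the duplicate-discrimination feature alongside the RMB —
is recovered from R2, whose post-barcode sequence is the reverse complement
of the fragment end.

Extension tolerates isolated substitutions (a mismatch is absorbed only when
followed by a run of matches), so sequencing errors in the interior of the
bait or prey do not shift the recovered junction; on error-free reads the
behaviour is exact matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .reference import ReferenceBundle, TargetSite, oriented_slice, revcomp

__all__ = [
    "SeedIndex",
    "extract_junctions",
    "resolve_breakpoint",
    "JUNCTION_COLUMNS",
]

JUNCTION_COLUMNS = [
    "read_id",
    "rmb",
    "bait_chrom",
    "bait_end",
    "bait_strand",
    "prey_ref",
    "prey_pos",
    "prey_strand",
    "insertion",
    "microhomology",
    "fragment_length",
    "is_perfect",
    "flags",
]

_ENC = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


class SeedIndex:
    """Sorted-array exact k-mer index over genome + viral forward strands.

    Reverse-strand hits are found by querying the reverse complement of the
    read seed, so only one strand is stored. Lookups are binary searches on
    2-bit-packed k-mer codes.
    """

    def __init__(self, ref: ReferenceBundle, k: int = 20):
        if k > 31:
            raise ValueError("k-mer codes are packed into int64; k must be <= 31")
        self.k = k
        self.names = sorted(ref.chromosomes) + [ref.viral_name]
        seqs = [ref.get(n) for n in self.names]
        self.starts = np.zeros(len(seqs), dtype=np.int64)
        parts = []
        off = 0
        for i, s in enumerate(seqs):
            self.starts[i] = off
            parts.append(_ENC[np.frombuffer(s.encode(), dtype=np.uint8)])
            off += len(s) + 1
            parts.append(np.array([4], dtype=np.int64))  # separator
        cat = np.concatenate(parts[:-1])
        self.lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(cat, k)
        codes = win @ powers
        valid = np.ones(len(codes), dtype=bool)
        for sep in np.flatnonzero(cat == 4):
            valid[max(0, sep - k + 1) : sep + 1] = False
        pos = np.flatnonzero(valid)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def encode_seq(self, seq: str) -> np.ndarray:
        return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]

    def seed_codes(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """(codes, valid) for every k-mer window of ``seq``."""
        arr = self.encode_seq(seq)
        if len(arr) < self.k:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        win = np.lib.stride_tricks.sliding_window_view(arr, self.k)
        codes = win @ powers
        valid = ~(win == 4).any(axis=1)
        return codes, valid

    def lookup_many(self, codes: np.ndarray) -> list[np.ndarray]:
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return [self._pos[l:h] for l, h in zip(lo, hi)]

    def to_local(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        return self.names[i], int(gpos - self.starts[i])


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------

def _extend_right(read: str, x0: int, frame, lookahead: int) -> tuple[int, int]:
    """Extend rightward from read offset ``x0``; frame(x) gives the expected
    base or None outside the reference. Returns (end_exclusive, matches)."""
    n = len(read)
    x = x0
    matches = 0
    while x < n:
        b = frame(x)
        if b is not None and read[x] == b:
            matches += 1
            x += 1
            continue
        if b is None:
            break
        ok = x + lookahead < n
        if ok:
            for j in range(1, lookahead + 1):
                bj = frame(x + j)
                if bj is None or read[x + j] != bj:
                    ok = False
                    break
        if ok:
            x += 1
        else:
            break
    return x, matches


def _extend_left_exact(read: str, x0: int, frame) -> int:
    """Maximal exact leftward extension from read offset ``x0`` (exclusive);
    returns the start offset reached."""
    x = x0
    while x > 0:
        b = frame(x - 1)
        if b is None or read[x - 1] != b:
            break
        x -= 1
    return x


def resolve_junction(
    read: str, bait_frame, prey_frame, e_bait: int, s_prey: int
) -> dict:
    """Resolve the breakpoint between the maximal bait prefix (ending at read
    offset ``e_bait``) and the maximal leftward prey extension (starting at
    ``s_prey``).

    Overlapping alignments -> microhomology, assigned to the bait side.
    A gap between them is scored like an aligner would: an untemplated
    insertion costs 2 per base, a substitution against either flanking frame
    costs 3, and the cheapest interpretation wins (ties keep the insertion).
    Absorbing the gap into the bait re-extends the bait exactly through any
    microhomology. On error-free reads the gap bases are genuine insertions
    unless they happen to resemble the flanking reference, so the rule is a
    deterministic convention, not a heuristic; under sequencing errors it
    keeps a single substitution near the junction from shifting the
    breakpoint.

    Returns dict(insertion, microhomology, bait_end_off, prey_off, aln_start)
    — read offsets; ``prey_off`` is where the reported prey position sits in
    the prey frame, ``aln_start`` the leftmost read offset aligned to prey.
    """
    if s_prey <= e_bait:
        return {
            "insertion": "",
            "microhomology": e_bait - s_prey,
            "bait_end_off": e_bait,
            "prey_off": e_bait,
            "aln_start": s_prey,
        }
    gap = read[e_bait:s_prey]
    m = len(gap)
    h_p = sum(1 for i, c in enumerate(gap) if prey_frame(e_bait + i) != c)
    h_b = sum(1 for i, c in enumerate(gap) if bait_frame(e_bait + i) != c)
    absorb_p = 3 * h_p < 2 * m
    absorb_b = 3 * h_b < 2 * m
    if absorb_p and (h_p <= h_b or not absorb_b):
        return {
            "insertion": "",
            "microhomology": 0,
            "bait_end_off": e_bait,
            "prey_off": e_bait,
            "aln_start": e_bait,
        }
    if absorb_b:
        e2 = s_prey
        n = len(read)
        while e2 < n and bait_frame(e2) == read[e2]:
            e2 += 1
        return {
            "insertion": "",
            "microhomology": e2 - s_prey,
            "bait_end_off": e2,
            "prey_off": e2,
            "aln_start": s_prey,
        }
    return {
        "insertion": gap,
        "microhomology": 0,
        "bait_end_off": e_bait,
        "prey_off": s_prey,
        "aln_start": s_prey,
    }


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _make_frame(seq: str, anchor_pos: int, anchor_off: int, strand: str):
    """Map read offset -> expected base for a prey diagonal."""
    L = len(seq)
    if strand == "+":
        p0 = anchor_pos - anchor_off

        def frame(x: int):
            g = p0 + x
            return seq[g] if 0 <= g < L else None

    else:
        c0 = anchor_pos + anchor_off

        def frame(x: int):
            g = c0 - x
            return _COMP[seq[g]] if 0 <= g < L else None

    return frame


def _frame_pos(anchor_pos: int, anchor_off: int, strand: str, x: int) -> int:
    return anchor_pos + (x - anchor_off) if strand == "+" else anchor_pos - (x - anchor_off)


def resolve_breakpoint(
    read: str,
    bait_read_end: int,
    bait_ref_end: int,
    prey_read_start: int,
    prey_pos_at_start: int,
    prey_strand: str,
) -> tuple[str, int, int, int]:
    """Resolve the breakpoint between a bait alignment ending at read offset
    ``bait_read_end`` and a prey alignment starting at ``prey_read_start``.

    Overlap of k read bases -> microhomology k, assigned to the bait side
    (the reported prey start is advanced by k); a gap of m bases -> an
    untemplated m-mer insertion. Returns
    ``(insertion, microhomology, bait_end, prey_start)`` in reference
    coordinates.
    """
    if bait_read_end >= prey_read_start:
        mh = bait_read_end - prey_read_start
        step = bait_read_end - prey_read_start
        prey = prey_pos_at_start + step if prey_strand == "+" else prey_pos_at_start - step
        return "", mh, bait_ref_end, prey
    ins = read[bait_read_end:prey_read_start]
    return ins, 0, bait_ref_end, prey_pos_at_start


# ---------------------------------------------------------------------------
# main extraction loop
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclass
class _Candidate:
    name: str
    strand: str
    s_prey: int
    right_end: int
    score: int
    prey_at_start: int
    is_viral: bool
    frame: object = None


def extract_junctions(
    r1_path: str | Path,
    r2_path: str | Path,
    ref: ReferenceBundle,
    target: TargetSite,
    *,
    min_prey_match: int = 20,
    max_primer_mismatches: int = 2,
    lookahead: int = 12,
    index: SeedIndex | None = None,
    rmb_length: int = 14,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Convert paired FASTQ into junction records.

    Returns a DataFrame (one row per informative read pair, perfect/uncut
    reads flagged ``is_perfect``) plus a stats dict of per-filter counts.
    Reads without the bait primer, with unmappable prey, or with a suffix
    shorter than ``min_prey_match`` are counted and skipped.
    """
    if index is None:
        index = SeedIndex(ref)
    cseq = ref.chromosomes[target.chromosome]
    ps = target.bait_primer_start
    primer = cseq[ps : target.bait_primer_end]
    cut = target.cut_position

    def bait_frame(x: int):
        g = ps + x
        return cseq[g] if g < len(cseq) else None

    stats = {
        "pairs": 0,
        "no_primer": 0,
        "perfect": 0,
        "junctions": 0,
        "short_suffix": 0,
        "unmapped": 0,
        "ambiguous": 0,
        "fraglen_unresolved": 0,
    }
    rows = []
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in itertools.zip_longest(f1, f2):
            if rec1 is None or rec2 is None:
                raise ValueError("R1/R2 files have different read counts")
            stats["pairs"] += 1
            r1 = rec1.sequence.upper()
            r2 = rec2.sequence.upper()
            if _hamming(r1[: len(primer)], primer) > max_primer_mismatches:
                stats["no_primer"] += 1
                continue
            rmb = r2[:rmb_length]

            e_bait, _ = _extend_right(r1, 0, bait_frame, lookahead)
            if e_bait == len(r1):
                fl, unresolved = _fragment_length(
                    cseq, ps, e_bait, "", cseq, ps + e_bait, "+", r2, rmb_length
                )
                stats["perfect"] += 1
                stats["fraglen_unresolved"] += unresolved
                rows.append(
                    (rec1.name, rmb, target.chromosome, ps + e_bait, "+",
                     target.chromosome, cut, "+", "", 0, fl, True, "")
                )
                continue
            suffix = r1[e_bait:]
            if len(suffix) < min_prey_match:
                stats["short_suffix"] += 1
                continue

            cands = _map_prey(suffix, e_bait, r1, ref, index, lookahead, min_prey_match)
            if not cands:
                stats["unmapped"] += 1
                continue
            best_score = max(c.score for c in cands)
            top = [c for c in cands if c.score == best_score]
            top.sort(key=lambda c: (not c.is_viral, c.name,
                                    _frame_pos(c.prey_at_start, c.s_prey, c.strand,
                                               max(e_bait, c.s_prey)),
                                    c.strand))
            best = top[0]
            flags = []
            if len(top) > 1:
                flags.append("ambiguous")
                stats["ambiguous"] += 1

            res = resolve_junction(r1, bait_frame, best.frame, e_bait, best.s_prey)
            ins, mh = res["insertion"], res["microhomology"]
            bait_end = ps + res["bait_end_off"]
            prey_pos = _frame_pos(best.prey_at_start, best.s_prey, best.strand,
                                  res["prey_off"])
            pseq = ref.get(best.name)
            mirror = None
            if best.is_viral:
                s5, e5 = ref.elements["5LTR"]
                s3, _ = ref.elements["3LTR"]
                if s5 <= prey_pos < e5:
                    mirror = prey_pos - s5 + s3
            fl, unresolved = _fragment_length(
                cseq, ps, res["bait_end_off"], ins, pseq, prey_pos, best.strand,
                r2, rmb_length, ltr_mirror=mirror,
            )
            stats["fraglen_unresolved"] += unresolved
            stats["junctions"] += 1
            rows.append(
                (rec1.name, rmb, target.chromosome, bait_end, "+",
                 best.name, prey_pos, best.strand, ins, mh, fl, False,
                 ",".join(flags))
            )
    df = pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
    return df, stats


def _map_prey(
    suffix: str,
    e_bait: int,
    r1: str,
    ref: ReferenceBundle,
    index: SeedIndex,
    lookahead: int,
    min_prey_match: int,
) -> list[_Candidate]:
    """Seed the suffix on both strands, extend each candidate diagonal over
    the full read, and keep alignments long enough to be informative."""
    k = index.k
    diagonals: dict[tuple[str, str, int], tuple[int, int]] = {}

    codes, valid = index.seed_codes(suffix)
    if len(codes):
        for q, hits in enumerate(index.lookup_many(codes)):
            if not valid[q]:
                continue
            for g in hits:
                name, pos = index.to_local(int(g))
                key = (name, "+", pos - (e_bait + q))
                diagonals.setdefault(key, (pos, e_bait + q))
    rc = revcomp(suffix)
    codes_rc, valid_rc = index.seed_codes(rc)
    Ls = len(suffix)
    if len(codes_rc):
        for q, hits in enumerate(index.lookup_many(codes_rc)):
            if not valid_rc[q]:
                continue
            for g in hits:
                name, pos = index.to_local(int(g))
                off = e_bait + Ls - k - q  # read offset of the seed start
                anchor_pos = pos + k - 1  # genome pos of that read base
                key = (name, "-", anchor_pos + off)
                diagonals.setdefault(key, (anchor_pos, off))

    cands = []
    for (name, strand, _), (apos, aoff) in sorted(diagonals.items()):
        seq = ref.get(name)
        frame = _make_frame(seq, apos, aoff, strand)
        right_end, m_r = _extend_right(r1, aoff, frame, lookahead)
        s_prey = _extend_left_exact(r1, aoff, frame)
        score = m_r + (aoff - s_prey)
        if right_end - s_prey < min_prey_match:
            continue
        cands.append(
            _Candidate(
                name=name,
                strand=strand,
                s_prey=s_prey,
                right_end=right_end,
                score=score,
                prey_at_start=_frame_pos(apos, aoff, strand, s_prey),
                is_viral=ref.is_viral(name),
                frame=frame,
            )
        )
    return cands


def _fragment_length(
    cseq: str,
    ps: int,
    e_bait: int,
    ins: str,
    pseq: str,
    prey_pos: int,
    prey_strand: str,
    r2: str,
    rmb_length: int,
    max_fragment: int = 760,
    ltr_mirror: int | None = None,
) -> tuple[int, int]:
    """Recover the sonication fragment length from R2.

    The template is the reconstructed fragment prefix (bait, insertion, prey
    frame); the post-RMB part of R2, reverse-complemented, is the fragment
    end and is located within the template by exact search. For junctions
    reported under the canonical 5'LTR the fragment may only be explicable
    in the mirrored 3'LTR frame (sequence upstream of the repeat differs),
    so that frame is tried as a fallback. Returns (length, unresolved_flag).
    """
    tail = revcomp(r2[rmb_length:])
    if not tail:
        return 0, 1
    for pos in ([prey_pos] if ltr_mirror is None else [prey_pos, ltr_mirror]):
        template = (
            cseq[ps : ps + e_bait]
            + ins
            + oriented_slice(pseq, pos, prey_strand, max_fragment)
        )
        o = template.find(tail)
        if o >= 0:
            return o + len(tail), 0
    return 0, 1
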