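"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately written the slow, obvious way and shares no
code with the package's implementations.
"""

from __future__ import annotations

import itertools

# the standard genetic code, written out longhand
CODON_TABLE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    CODON_TABLE[_b1 + _b2 + _b3] = _AA[_i]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate_oracle(seq: str, frame: int) -> str:
    """Codon-by-codon table lookup; N-containing codons give X."""
    s = seq if frame > 0 else rc(seq)
    off = abs(frame) - 1
    out = []
    for i in range(off, len(s) - 2, 3):
        out.append(CODON_TABLE.get(s[i : i + 3], "X"))
    return "".join(out)


def orfs_oracle(seq: str, min_aa: int) -> set:
    """(frame, nt_start, nt_end, protein) for every stop-free run."""
    L = len(seq)
    found = set()
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate_oracle(seq, frame)
        off = abs(frame) - 1
        start = 0
        for chunk in prot.split("*"):
            if len(chunk) >= min_aa:
                a = off + 3 * start
                b = off + 3 * (start + len(chunk))
                if frame > 0:
                    found.add((frame, a, b, chunk))
                else:
                    found.add((frame, L - b, L - a, chunk))
            start += len(chunk) + 1
    return found


def motif_mm_oracle(seq: str, sets: list) -> int:
    """sets: per-position frozensets; the full set means N (matches all)."""
    full = frozenset("ACGT")
    mm = 0
    for c, allowed in zip(seq, sets):
        if allowed == full:
            continue
        if c == "N" or c not in allowed:
            mm += 1
    return mm


def brute_force_tirs(
    seq: str,
    anchor_sets: list,
    min_len: int = 8,
    max_len: int = 30,
    max_arm: int = 4,
    max_anchor: int = 1,
    window: int = 200,
) -> set:
    """All-substring-pairs TIR scan; returns (a, a+l, b, b+l, mismatches)."""
    L = len(seq)
    out = set()
    k = len(anchor_sets)
    for a in range(min(window, L)):
        if a + k > L:
            continue
        if motif_mm_oracle(seq[a : a + k], anchor_sets) > max_anchor:
            continue
        for ell in range(min_len, max_len + 1):
            if a + ell > L:
                continue
            arm5 = seq[a : a + ell]
            for b in range(max(a + ell, L - window - ell + 1), L - ell + 1):
                partner = rc(seq[b : b + ell])
                mm = sum(
                    1
                    for x, y in zip(arm5, partner)
                    if x != y or x == "N" or y == "N"
                )
                if mm <= max_arm:
                    out.add((a, a + ell, b, b + ell, mm))
    return out


def enumerate_global_alignments(a: str, b: str):
    """Yield (aligned_a, aligned_b) for every global alignment of a and b."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_global_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb
    if a:
        for ra, rb in enumerate_global_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_global_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb


def score_alignment(aligned_a: str, aligned_b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Affine-gap score: a gap of length k costs gap_open + (k-1)*gap_extend."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            score -= gap_open if not in_gap_a else gap_extend
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= gap_open if not in_gap_b else gap_extend
            in_gap_b, in_gap_a = True, False
        else:
            score += matrix[ca, cb]
            in_gap_a = in_gap_b = False
    return score
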