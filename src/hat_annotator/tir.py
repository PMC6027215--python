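"""Terminal inverted repeat (TIR) detection, deduplication, and consensus.

hAT elements are flanked by TIRs of at least 8 bp: the 5' arm reappears near
the 3' end as its reverse complement. Detection here is anchored on a
degenerate consensus motif at the 5' arm (default "(T/C)A(A/G)NG") with a
mismatch budget on arm-vs-arm complementarity, and enumerates every
qualifying (5' window, 3' window, length) combination so downstream stages
can pick the best pair or audit all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import ConsensusElement
from .motifs import NUCLEOTIDES, DegenerateMotif, motif_mismatches

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class TIRPair:
    """A detected 5'/3' inverted-repeat arm pair (0-based half-open coords).

    ``arm_mismatches`` compares the 5' arm against the reverse complement of
    the 3' arm; ``motif_mismatches`` compares the 5' arm prefix against the
    anchor motif. N bases never match anything.
    """

    five_prime_start: int
    five_prime_end: int
    three_prime_start: int
    three_prime_end: int
    arm_mismatches: int
    motif_mismatches: int

    @property
    def arm_length(self) -> int:
        return self.five_prime_end - self.five_prime_start

    def arms(self, element: ConsensusElement) -> tuple[str, str]:
        return (
            element.sequence[self.five_prime_start : self.five_prime_end],
            element.sequence[self.three_prime_start : self.three_prime_end],
        )


def _sort_key(p: TIRPair):
    return (-p.arm_length, p.arm_mismatches, p.five_prime_start, p.three_prime_start)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_tirs(
    element: ConsensusElement,
    anchor: DegenerateMotif,
    min_len: int = 8,
    max_len: int = 30,
    max_arm_mismatches: int = 4,
    max_anchor_mismatches: int = 1,
    terminal_window: int = 200,
) -> list[TIRPair]:
    """Enumerate all anchored TIR pairs of an element.

    A pair qualifies when: the 5' arm starts within ``terminal_window`` of
    position 0 and the 3' arm ends within ``terminal_window`` of the sequence
    end; the arms do not overlap; the Hamming distance between the 5' arm and
    the reverse complement of the 3' arm is at most ``max_arm_mismatches``;
    and the 5' arm prefix matches the anchor motif with at most
    ``max_anchor_mismatches`` mismatches. Results are sorted by
    (arm_length desc, arm_mismatches asc, five_prime_start asc).
    """
    if min_len < len(anchor):
        raise ValueError(
            f"min_len {min_len} shorter than anchor motif length {len(anchor)}"
        )
    seq = element.sequence
    L = len(seq)
    if L < 2 * min_len:
        raise ValueError(
            f"element {element.element_id!r} of length {L} too short for "
            f"min_len {min_len}"
        )
    fwd = _encode(seq)
    rc = _encode(revcomp(seq))
    n_code = ord("N")

    # anchor mismatch count per candidate 5' start (prefix of length anchor)
    max_a5 = min(terminal_window, L - min_len + 1)
    anchor_mm = np.array(
        [
            motif_mismatches(seq[a : a + len(anchor)], anchor)
            if a + len(anchor) <= L
            else len(anchor)
            for a in range(max_a5)
        ]
    )
    good_a = np.nonzero(anchor_mm <= max_anchor_mismatches)[0]

    pairs: list[TIRPair] = []
    for ell in range(min_len, max_len + 1):
        a_cand = good_a[good_a + ell <= L]
        if a_cand.size == 0:
            continue
        # 3' arm [b, b+ell) must end within terminal_window of the end
        b_lo = max(0, L - terminal_window - ell + 1)
        b_starts = np.arange(b_lo, L - ell + 1)
        if b_starts.size == 0:
            continue
        # compare 5' arm seq[a:a+ell] with revcomp(seq[b:b+ell]) = rc[L-b-ell:L-b]
        A = np.stack([fwd[a : a + ell] for a in a_cand])
        B = np.stack([rc[L - b - ell : L - b] for b in b_starts])
        mism = (
            (A[:, None, :] != B[None, :, :])
            | (A[:, None, :] == n_code)
            | (B[None, :, :] == n_code)
        ).sum(axis=2)
        ok = np.nonzero(mism <= max_arm_mismatches)
        for ia, ib in zip(*ok):
            a = int(a_cand[ia])
            b = int(b_starts[ib])
            if a + ell <= b:  # arms must not overlap
                pairs.append(
                    TIRPair(
                        five_prime_start=a,
                        five_prime_end=a + ell,
                        three_prime_start=b,
                        three_prime_end=b + ell,
                        arm_mismatches=int(mism[ia, ib]),
                        motif_mismatches=int(anchor_mm[a]),
                    )
                )
    pairs.sort(key=_sort_key)
    return pairs


def best_tir(pairs: Sequence[TIRPair]) -> Optional[TIRPair]:
    """The top-ranked pair (longest, then fewest mismatches), if any."""
    return min(pairs, key=_sort_key) if pairs else None


def dedupe_tirs(arms: Sequence[str]) -> list[str]:
    """Drop later exact duplicates of 5'-arm sequences, preserving order."""
    return list(dict.fromkeys(arms))


@dataclass(frozen=True)
class TIRConsensusResult:
    """Column base counts and the degenerate consensus derived from them."""

    frequency_matrix: np.ndarray  # columns x 4, order A,C,G,T
    consensus: str
    motif: DegenerateMotif
    n_input: int
    n_unique: int


def derive_consensus(
    arms: Sequence[str],
    n_columns: int = 8,
    single_threshold: float = 0.6,
    pair_threshold: float = 0.8,
) -> TIRConsensusResult:
    """Derive a degenerate consensus over the first ``n_columns`` arm bases.

    Per column: the top base's fraction >= ``single_threshold`` gives a plain
    letter; failing that, if the top two fractions sum to >= ``pair_threshold``
    and each is >= 1 - ``pair_threshold``, the column is rendered "[X/Y]" with
    X the more frequent (exact ties break T > G > C > A); otherwise N.
    Input arms should already be deduplicated.
    """
    unique = dedupe_tirs(arms)
    if not unique:
        raise ValueError("no arms to build a consensus from")
    for arm in unique:
        if len(arm) < n_columns:
            raise ValueError(
                f"arm {arm!r} shorter than n_columns={n_columns}"
            )
    n = len(unique)
    counts = np.zeros((n_columns, 4), dtype=int)
    index = {c: i for i, c in enumerate(NUCLEOTIDES)}
    for arm in unique:
        for col in range(n_columns):
            c = arm[col]
            if c in index:
                counts[col, index[c]] += 1

    positions: list[tuple[str, ...]] = []
    for col in range(n_columns):
        total = counts[col].sum()
        # rank by count desc, exact ties reverse-alphabetically (T before C)
        ranked = sorted(
            zip(NUCLEOTIDES, counts[col]),
            key=lambda x: (-x[1], "TGCA".index(x[0])),
        )
        (b1, c1), (b2, c2) = ranked[0], ranked[1]
        f1, f2 = c1 / total, c2 / total
        if f1 >= single_threshold:
            positions.append((b1,))
        elif f1 + f2 >= pair_threshold and min(f1, f2) >= 1 - pair_threshold:
            positions.append((b1, b2))
        else:
            positions.append(tuple("ACGT"))
    motif = DegenerateMotif(positions=tuple(positions), dialect="square")
    return TIRConsensusResult(
        frequency_matrix=counts,
        consensus=motif.render(),
        motif=motif,
        n_input=len(arms),
        n_unique=n,
    )
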