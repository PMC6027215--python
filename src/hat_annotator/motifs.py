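"""Degenerate nucleotide motifs such as the hAT TIR anchor "(T/C)A(A/G)NG".

A motif is an ordered list of allowed-nucleotide alternatives per position.
Two bracket dialects occur in the literature, "(T/C)A(A/G)NG" and
"[T/C]AGNGNNG"; both parse, and rendering remembers which dialect and
alternative order the motif was built with so parse/render round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = ("A", "C", "G", "T")
_FULL = frozenset(NUCLEOTIDES)


@dataclass(frozen=True)
class DegenerateMotif:
    """Per-position allowed-nucleotide alternatives; N means any base."""

    #: ordered alternatives per position (order only affects rendering)
    positions: tuple[tuple[str, ...], ...]
    #: bracket style used when rendering multi-letter positions
    dialect: str = field(default="square", compare=False)

    def __post_init__(self) -> None:
        for i, alts in enumerate(self.positions):
            if not alts:
                raise ValueError(f"motif position {i}: empty alternative set")
            for c in alts:
                if c not in NUCLEOTIDES:
                    raise ValueError(f"motif position {i}: illegal letter {c!r}")

    def __len__(self) -> int:
        return len(self.positions)

    def allowed(self, i: int) -> frozenset:
        return frozenset(self.positions[i])

    def is_wild(self, i: int) -> bool:
        """True when position ``i`` accepts any base (an N position)."""
        return self.allowed(i) == _FULL

    def render(self) -> str:
        open_b, close_b = ("[", "]") if self.dialect == "square" else ("(", ")")
        out = []
        for alts in self.positions:
            if frozenset(alts) == _FULL:
                out.append("N")
            elif len(alts) == 1:
                out.append(alts[0])
            else:
                out.append(open_b + "/".join(alts) + close_b)
        return "".join(out)

    def same_pattern(self, other: "DegenerateMotif") -> bool:
        """Equality on allowed sets, ignoring alternative order and dialect."""
        return len(self) == len(other) and all(
            self.allowed(i) == other.allowed(i) for i in range(len(self))
        )


def parse_motif(pattern: str) -> DegenerateMotif:
    """Parse a degenerate motif in either bracket dialect.

    >>> parse_motif("(T/C)A(A/G)NG").render()
    '(T/C)A(A/G)NG'
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    positions: list[tuple[str, ...]] = []
    dialect = "square"
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c in "([":
            dialect = "square" if c == "[" else "round"
            close = "]" if c == "[" else ")"
            j = pattern.find(close, i)
            if j < 0:
                raise ValueError(f"motif parse error at offset {i}: unclosed {c!r}")
            group = [g for g in pattern[i + 1 : j].split("/") if g]
            if not group:
                raise ValueError(f"motif parse error at offset {i}: empty group")
            alts = []
            for g in group:
                if g == "N":
                    alts.extend(NUCLEOTIDES)
                elif g in NUCLEOTIDES:
                    alts.append(g)
                else:
                    raise ValueError(
                        f"motif parse error at offset {i}: illegal letter {g!r}"
                    )
            positions.append(tuple(dict.fromkeys(alts)))
            i = j + 1
        elif c == "N":
            positions.append(NUCLEOTIDES)
            i += 1
        elif c in NUCLEOTIDES:
            positions.append((c,))
            i += 1
        else:
            raise ValueError(f"motif parse error at offset {i}: illegal letter {c!r}")
    return DegenerateMotif(positions=tuple(positions), dialect=dialect)


def motif_mismatches(seq: str, motif: DegenerateMotif) -> int:
    """Mismatches between the first ``len(motif)`` bases of ``seq`` and the
    motif. An N in the sequence never matches a non-N motif position."""
    if len(seq) < len(motif):
        raise ValueError(
            f"sequence length {len(seq)} shorter than motif length {len(motif)}"
        )
    mm = 0
    for i in range(len(motif)):
        c = seq[i]
        if motif.is_wild(i):
            continue  # N position accepts any base, including N
        if c == "N" or c not in motif.allowed(i):
            mm += 1
    return mm
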