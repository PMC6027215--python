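"""Sequence I/O and the element data model shared by every pipeline stage.

Consensus transposable-element sequences arrive as plain FASTA with
Repbase-style headers whose first token usually starts with genus+species
initials ("Os_TEMPINDAS", "Zm_hAT-14"). All coordinates in this package are
0-based, half-open, on the forward strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN")

#: default grammar for the species prefix: a capital + lowercase letter pair
#: leading the first underscore-delimited token ("Os_TEMPINDAS" -> "Os").
DEFAULT_SPECIES_REGEX = r"^([A-Z][a-z])(?:_|$)"


@dataclass(frozen=True)
class ConsensusElement:
    """One consensus TE nucleotide sequence with naming metadata."""

    element_id: str
    species_code: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"element {self.element_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            offset = next(
                i for i, c in enumerate(self.sequence) if c not in VALID_CHARS
            )
            raise ValueError(
                f"element {self.element_id!r}: illegal character "
                f"{self.sequence[offset]!r} at offset {offset}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ElementName:
    """A parsed element name; ``n_suffix_index`` marks an N-suffixed
    nonautonomous derivative ("Os_TEMPINDAS-N1", "hAT-14N1")."""

    stem: str
    n_suffix_index: Optional[int] = None
    raw: str = field(default="", compare=False)

    def render(self) -> str:
        """Reproduce the original name byte-for-byte."""
        return self.raw


# the two derivative-name dialects: "<stem>-N<k>" and "<stem ending in a
# digit>N<k>"
_SUFFIX_RE = re.compile(r"^(?P<stem>.+)-N(?P<k>\d+)$")
_EMBED_RE = re.compile(r"^(?P<stem>.*\d)N(?P<k>\d+)$")


def parse_name(name: str) -> ElementName:
    """Split an element name into stem and optional N-derivative index.

    Unrecognized names fall back to the whole name as stem with no index.
    """
    if not name:
        raise ValueError("empty element name")
    for rx in (_SUFFIX_RE, _EMBED_RE):
        m = rx.match(name)
        if m:
            k = int(m.group("k"))
            if k >= 1:
                return ElementName(stem=m.group("stem"), n_suffix_index=k, raw=name)
    return ElementName(stem=name, n_suffix_index=None, raw=name)


def _species_from_id(element_id: str, species_regex: str) -> str:
    m = re.match(species_regex, element_id)
    return m.group(1) if m else ""


def read_fasta(path, species_regex: str = DEFAULT_SPECIES_REGEX) -> list[ConsensusElement]:
    """Read consensus elements from FASTA.

    Lowercase is uppercased, U mapped to T; characters outside {A,C,G,T,N,U}
    are rejected with the record name and offset. Record order is preserved.
    """
    path = Path(path)
    elements: list[ConsensusElement] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper().replace("U", "T")
        for i, c in enumerate(raw):
            if c not in VALID_CHARS:
                raise ValueError(
                    f"record {rec.id!r}: illegal character {c!r} at offset {i}"
                )
        elements.append(
            ConsensusElement(
                element_id=rec.id,
                species_code=_species_from_id(rec.id, species_regex),
                sequence=raw,
            )
        )
    if not elements:
        raise ValueError(f"no records in {path}")
    return elements


def write_fasta(elements: Iterable[ConsensusElement], path) -> None:
    """Write elements as 60-column-wrapped FASTA (round-trips read_fasta)."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.element_id, description="")
        for e in elements
    ]
    SeqIO.write(records, str(path), "fasta")
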