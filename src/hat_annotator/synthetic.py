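"""Synthetic Repbase-like hAT consensus elements with planted ground truth.

Every generated element follows the canonical hAT layout::

    [TSD][5' TIR][filler][transposase ORF, optional][filler][revcomp TIR][TSD]

with the TIR sampled from a degenerate consensus motif, a 4-8 bp target-site
duplication repeated on both flanks, and (optionally) an internal ORF
encoding a synthetic ~750-aa transposase that carries the five diagnostic
catalytic residues at the maize-Activator-numbered positions. Nonautonomous
derivatives are produced by internal deletion spanning a catalytic residue,
and point-mutation divergence can be applied per element or along a random
generating tree.

Two deliberate departures from plain uniform-random sequence keep the truth
records exact:

* filler is uniform over {A,C,G,T} *except* that the self-reverse-complementary
  stop cassette ``TTAATTAATTAA`` is spliced in every ~250 bp, so no spurious
  long ORF arises outside the planted transposase in any of the six frames;
* elements whose planted transposase is intact accept only synonymous
  substitutions inside the ORF (purifying selection), so an element labelled
  "autonomous" still encodes an active transposase after divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np

from .io import ConsensusElement
from .motifs import NUCLEOTIDES, DegenerateMotif, parse_motif
from .tir import revcomp
from .transposase import _CODON_TO_AA, SIGNATURE_PRESETS, make_signature_spec

STOP_CASSETTE = "TTAATTAATTAA"  # stops in all six frames; its own revcomp
_FILLER_CHUNK = 238  # random bases between consecutive stop cassettes

#: one deterministic codon per amino acid (alphabetically first)
_AA_TO_CODON: dict[str, str] = {}
for _codon in sorted(_CODON_TO_AA):
    _aa = _CODON_TO_AA[_codon]
    if _aa != "*" and _aa not in _AA_TO_CODON:
        _AA_TO_CODON[_aa] = _codon

_REFERENCE_LENGTHS = {"AC": 750, "Hermes": 612}


def synthetic_reference_protein(numbering: str = "AC") -> str:
    """A deterministic invented transposase carrying the preset's five
    diagnostic residues at their reference-numbered positions."""
    if numbering not in SIGNATURE_PRESETS:
        raise ValueError(f"unknown numbering preset {numbering!r}")
    length = _REFERENCE_LENGTHS[numbering]
    rng = np.random.default_rng(987001 if numbering == "AC" else 987002)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    protein = list(rng.choice(aas, size=length))
    for pos, allowed in SIGNATURE_PRESETS[numbering]:
        protein[pos - 1] = sorted(allowed)[-1] if "W" in allowed else sorted(allowed)[0]
    return "".join(protein)


def synthetic_signature_spec(numbering: str = "AC"):
    return make_signature_spec(
        numbering,
        reference_id=f"synthetic_{numbering}_transposase",
        reference_protein=synthetic_reference_protein(numbering),
    )


def reverse_translate(protein: str) -> str:
    return "".join(_AA_TO_CODON[aa] for aa in protein)


def sample_tir(motif: DegenerateMotif, tir_length: int, rng) -> str:
    """Draw a TIR arm: motif positions uniform over their allowed sets, the
    remainder uniform over {A,C,G,T}."""
    if tir_length < len(motif):
        raise ValueError("tir_length shorter than the motif")
    out = [rng.choice(motif.positions[i]) for i in range(len(motif))]
    out += [NUCLEOTIDES[rng.integers(4)] for _ in range(tir_length - len(motif))]
    return "".join(out)


def random_filler(length: int, rng) -> str:
    """Uniform-random filler with a stop cassette spliced every ~250 bp so
    no frame carries a spurious long ORF."""
    parts: list[str] = []
    remaining = length
    while remaining > 0:
        take = min(_FILLER_CHUNK, remaining)
        parts.append("".join(NUCLEOTIDES[i] for i in rng.integers(4, size=take)))
        remaining -= take
        if remaining > 0:
            cassette = STOP_CASSETTE[: min(len(STOP_CASSETTE), remaining)]
            parts.append(cassette)
            remaining -= len(cassette)
    return "".join(parts)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic element family."""

    n_species: int = 5
    elements_per_species: int = 10
    tir_motif: str = "[T/C]AGNGNNG"
    tir_length: int = 12
    tsd_length: int = 6
    element_length: int = 3000
    transposase_fraction: float = 0.5
    knockout_fraction: float = 0.2
    deletion_fraction: float = 0.3
    per_site_mutation_rate: float = 0.0
    tree_leaves: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "transposase_fraction",
            "knockout_fraction",
            "deletion_fraction",
            "per_site_mutation_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 4 <= self.tsd_length <= 8:
            raise ValueError("tsd_length must be in [4,8]")
        if self.tir_length < 8:
            raise ValueError("tir_length must be >= 8")
        if self.per_site_mutation_rate >= 0.75:
            raise ValueError("per_site_mutation_rate must be < 0.75")


@dataclass(frozen=True)
class TruthRecord:
    element_id: str
    true_tir_five: tuple  # (start, end), 0-based half-open
    true_tir_three: tuple
    true_orf: Optional[tuple]  # (start, end) of the coding run, or None
    true_signature_state: str  # intact | knocked_out | deleted | none
    true_autonomy: str  # autonomous | nonautonomous
    parent_id: Optional[str] = None
    generating_tree_position: Optional[str] = None


SPECIES_POOL = ("Os", "Zm", "At", "Ta", "Hv", "Sb", "Bd", "Gm", "Vv", "Pt")


def build_element(
    config: SimulationConfig,
    rng,
    with_transposase: bool,
    element_id: str,
    species_code: str,
    knockout_site: Optional[int] = None,
) -> tuple[ConsensusElement, TruthRecord]:
    """Assemble one element; ``knockout_site`` (1-based index into the five
    signature sites) mutates that site's codon to alanine."""
    motif = parse_motif(config.tir_motif)
    tsd = "".join(NUCLEOTIDES[i] for i in rng.integers(4, size=config.tsd_length))
    tir = sample_tir(motif, config.tir_length, rng)

    orf_dna = ""
    sig_state = "none"
    if with_transposase:
        protein = synthetic_reference_protein("AC")
        codons = [_AA_TO_CODON[aa] for aa in protein]
        if knockout_site is not None:
            pos = SIGNATURE_PRESETS["AC"][knockout_site - 1][0]
            codons[pos - 1] = "GCT"  # alanine
            sig_state = "knocked_out"
        else:
            sig_state = "intact"
        orf_dna = "TAA" + "".join(codons) + "TAA"

    fixed = 2 * config.tsd_length + 2 * config.tir_length + len(orf_dna)
    filler_total = config.element_length - fixed
    if filler_total < 2:
        raise ValueError(
            f"element_length {config.element_length} cannot accommodate the "
            f"planted layout ({fixed} bp fixed)"
        )
    left = filler_total // 2
    seq_parts = [
        tsd,
        tir,
        random_filler(left, rng),
        orf_dna,
        random_filler(filler_total - left, rng),
        revcomp(tir),
        tsd,
    ]
    seq = "".join(seq_parts)
    tir5_start = config.tsd_length
    tir3_end = config.element_length - config.tsd_length
    orf_span = None
    if with_transposase:
        orf_start = config.tsd_length + config.tir_length + left + 3
        orf_span = (orf_start, orf_start + 3 * 750)
    truth = TruthRecord(
        element_id=element_id,
        true_tir_five=(tir5_start, tir5_start + config.tir_length),
        true_tir_three=(tir3_end - config.tir_length, tir3_end),
        true_orf=orf_span,
        true_signature_state=sig_state,
        true_autonomy="autonomous" if sig_state == "intact" else "nonautonomous",
    )
    return ConsensusElement(element_id, species_code, seq), truth


def derive_nonautonomous(
    parent: ConsensusElement,
    parent_truth: TruthRecord,
    rng,
    index: int = 1,
) -> tuple[ConsensusElement, TruthRecord]:
    """Internal-deletion derivative: removes 40-70% of the parent ORF,
    always spanning the third catalytic site, keeps both TIRs, and names the
    child with an "-N<index>" suffix."""
    if parent_truth.true_orf is None:
        raise ValueError("cannot derive a deletion derivative without an ORF")
    orf_start, orf_end = parent_truth.true_orf
    site_pos = SIGNATURE_PRESETS["AC"][2][0]  # R463
    site_start = orf_start + 3 * (site_pos - 1)
    site_end = site_start + 3
    span_len = int((orf_end - orf_start) * rng.uniform(0.4, 0.7))
    lo = max(orf_start, site_end - span_len)
    hi = min(site_start, orf_end - span_len)
    start = int(rng.integers(lo, hi + 1))
    child_seq = parent.sequence[:start] + parent.sequence[start + span_len :]
    child_id = f"{parent.element_id}-N{index}"
    child = ConsensusElement(child_id, parent.species_code, child_seq)
    tir3 = (
        parent_truth.true_tir_three[0] - span_len,
        parent_truth.true_tir_three[1] - span_len,
    )
    truth = TruthRecord(
        element_id=child_id,
        true_tir_five=parent_truth.true_tir_five,
        true_tir_three=tir3,
        true_orf=None,
        true_signature_state="deleted",
        true_autonomy="nonautonomous",
        parent_id=parent.element_id,
    )
    return child, truth


def _mutate_free(seq: list, idx: Sequence[int], rng) -> None:
    for i in idx:
        cur = seq[i]
        alt = [c for c in NUCLEOTIDES if c != cur]
        seq[i] = alt[rng.integers(3)]


def mutate_element(
    element: ConsensusElement,
    rate: float,
    rng,
    protect_orf: Optional[tuple] = None,
) -> ConsensusElement:
    """Apply per-site substitutions at ``rate``. Inside ``protect_orf`` only
    synonymous substitutions are kept (purifying selection on an intact
    transposase); everything else mutates freely."""
    if rate == 0:
        return element
    seq = list(element.sequence)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if protect_orf is None:
        _mutate_free(seq, hits, rng)
    else:
        a, b = protect_orf
        free = [i for i in hits if not a <= i < b]
        _mutate_free(seq, free, rng)
        for i in hits:
            if not a <= i < b:
                continue
            codon_start = a + 3 * ((i - a) // 3)
            old_codon = "".join(seq[codon_start : codon_start + 3])
            cur = seq[i]
            alt = [c for c in NUCLEOTIDES if c != cur]
            new = alt[rng.integers(3)]
            candidate = list(old_codon)
            candidate[i - codon_start] = new
            if _CODON_TO_AA.get("".join(candidate)) == _CODON_TO_AA.get(old_codon):
                seq[i] = new
    return replace(element, sequence="".join(seq))


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    elements: list
    truths: list

    def truth_by_id(self) -> dict:
        return {t.element_id: t for t in self.truths}


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Deterministically generate a labelled element family.

    Base elements carry a transposase with probability
    ``transposase_fraction``; of those, ``knockout_fraction`` get one
    catalytic residue mutated to alanine, and each intact-ORF element spawns
    an internal-deletion "-N1" derivative with probability
    ``deletion_fraction``. Point mutations at ``per_site_mutation_rate``
    are applied last (synonymous-only inside intact ORFs).
    """
    rng = np.random.default_rng(config.seed)
    elements: list[ConsensusElement] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_species * config.elements_per_species):
        species = SPECIES_POOL[i % config.n_species]
        element_id = f"{species}_hAT-{i + 1}"
        with_tpase = bool(rng.random() < config.transposase_fraction)
        knockout = None
        if with_tpase and rng.random() < config.knockout_fraction:
            knockout = int(rng.integers(1, 6))
        elem, truth = build_element(
            config, rng, with_tpase, element_id, species, knockout_site=knockout
        )
        elements.append(elem)
        truths.append(truth)
        if with_tpase and rng.random() < config.deletion_fraction:
            child, child_truth = derive_nonautonomous(elem, truth, rng)
            elements.append(child)
            truths.append(child_truth)

    if config.per_site_mutation_rate > 0:
        mutated = []
        for elem, truth in zip(elements, truths):
            protect = truth.true_orf if truth.true_signature_state == "intact" else None
            mutated.append(
                mutate_element(elem, config.per_site_mutation_rate, rng, protect)
            )
        elements = mutated
    return SyntheticDataset(config=config, elements=elements, truths=truths)


def write_dataset(dataset: SyntheticDataset, fasta_path, truth_path) -> None:
    """FASTA + truth TSV on disk (byte-identical for a fixed seed)."""
    import pandas as pd

    from .io import write_fasta

    write_fasta(dataset.elements, fasta_path)
    rows = []
    for t in dataset.truths:
        rows.append(
            {
                "element_id": t.element_id,
                "tir5_start": t.true_tir_five[0],
                "tir5_end": t.true_tir_five[1],
                "tir3_start": t.true_tir_three[0],
                "tir3_end": t.true_tir_three[1],
                "orf_start": t.true_orf[0] if t.true_orf else "",
                "orf_end": t.true_orf[1] if t.true_orf else "",
                "signature_state": t.true_signature_state,
                "autonomy": t.true_autonomy,
                "parent_id": t.parent_id or "",
            }
        )
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)


def read_truth(truth_path):
    import pandas as pd

    return pd.read_csv(truth_path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# tree-structured radiation


def _random_topology(n_leaves: int, rng) -> dendropy.Node:
    nodes = [dendropy.Node() for _ in range(n_leaves)]
    for i, nd in enumerate(nodes):
        nd.leaf_index = i
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    return root


def _evolve(seq: str, prob: float, rng) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < prob)[0]
    _mutate_free(out, hits, rng)
    return "".join(out)


def radiate_family(
    root_seq: str,
    n_leaves: int,
    rng,
    internal_prob: float = 0.05,
    leaf_prob: float = 0.02,
    label_prefix: str = "L",
) -> tuple[list, list, dendropy.Tree]:
    """Diverge a root sequence along a random unrooted binary tree.

    Each branch substitutes every site independently (``internal_prob`` on
    internal branches, ``leaf_prob`` on terminal ones). Returns leaf labels,
    leaf sequences, and the generating tree (edge lengths = branch
    substitution probabilities) for topology-recovery tests.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    root = _random_topology(n_leaves, rng)
    tns = dendropy.TaxonNamespace()
    labels: list[str] = [""] * n_leaves
    seqs: list[str] = [""] * n_leaves

    def descend(node: dendropy.Node, seq: str) -> None:
        for child in node.child_nodes():
            prob = leaf_prob if child.is_leaf() else internal_prob
            child_seq = _evolve(seq, prob, rng)
            child.edge.length = prob
            if child.is_leaf():
                lab = f"{label_prefix}{child.leaf_index}"
                child.taxon = tns.new_taxon(label=lab)
                labels[child.leaf_index] = lab
                seqs[child.leaf_index] = child_seq
            else:
                descend(child, child_seq)

    descend(root, root_seq)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return labels, seqs, tree


def mutate_and_radiate(
    element: ConsensusElement,
    tree_leaves: int,
    per_site_mutation_rate: float,
    rng,
    internal_prob: Optional[float] = None,
) -> tuple[list, dendropy.Tree]:
    """Radiate one element into a family of diverged copies.

    Returns the leaf elements (ids ``<parent>_leaf<i>``) and the generating
    tree. ``per_site_mutation_rate`` applies to terminal branches;
    internal branches default to the same rate.
    """
    if per_site_mutation_rate >= 0.75:
        raise ValueError("per-site rate must be < 0.75")
    if per_site_mutation_rate == 0:
        internal = internal_prob or 0.0
    else:
        internal = internal_prob if internal_prob is not None else per_site_mutation_rate
    labels, seqs, tree = radiate_family(
        element.sequence,
        tree_leaves,
        rng,
        internal_prob=internal,
        leaf_prob=per_site_mutation_rate,
        label_prefix=f"{element.element_id}_leaf",
    )
    leaves = [
        ConsensusElement(lab, element.species_code, seq)
        for lab, seq in zip(labels, seqs)
    ]
    return leaves, tree


def three_clade_alignment(
    seq_len: int = 10_000,
    n_per_clade: int = 4,
    internal_prob: float = 0.08,
    within_prob: float = 0.02,
    rng=None,
) -> tuple[list, list, dict]:
    """Three long-internal-branch clades radiating from one ancestor — the
    scaled stand-in for a three-kingdom monophyly test.

    Returns (labels, aligned sequences, {clade name: label list}).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    root = "".join(NUCLEOTIDES[i] for i in rng.integers(4, size=seq_len))
    labels: list[str] = []
    seqs: list[str] = []
    groups: dict[str, list] = {}
    for clade in ("A", "B", "C"):
        ancestor = _evolve(root, internal_prob, rng)
        members = []
        for k in range(n_per_clade):
            lab = f"{clade}{k}"
            labels.append(lab)
            seqs.append(_evolve(ancestor, within_prob, rng))
            members.append(lab)
        groups[clade] = members
    return labels, seqs, groups


def make_arm_fixture(
    n_unique: int = 153, n_dup: int = 54, arm_length: int = 10, seed: int = 42
) -> list:
    """A TIR-arm list with planted exact duplicates (defaults mirror a
    207-arm collection collapsing to 153 nonidentical arms). Arms are a bit
    longer than the 8-nt consensus so enough distinct ones exist."""
    rng = np.random.default_rng(seed)
    motif = parse_motif("[T/C]AGNGNNG")
    if 2 * 4 ** (arm_length - len(motif) + 3) < 2 * n_unique:
        raise ValueError("arm_length too short for the requested uniques")
    unique: list[str] = []
    seen = set()
    while len(unique) < n_unique:
        arm = sample_tir(motif, arm_length, rng)
        if arm not in seen:
            seen.add(arm)
            unique.append(arm)
    arms = list(unique)
    for _ in range(n_dup):
        arms.insert(int(rng.integers(len(arms) + 1)), unique[int(rng.integers(n_unique))])
    return arms
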