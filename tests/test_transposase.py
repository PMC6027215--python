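import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from hat_annotator.io import ConsensusElement
from hat_annotator.synthetic import (
    SimulationConfig,
    build_element,
    reverse_translate,
    synthetic_reference_protein,
)
from hat_annotator.transposase import (
    block_frequencies,
    call_transposase,
    check_signature,
    extract_blocks,
    find_orfs,
    global_align,
    make_signature_spec,
    six_frame_translate,
    translate_frame,
)

from oracles import (
    CODON_TABLE,
    enumerate_global_alignments,
    orfs_oracle,
    score_alignment,
    translate_oracle,
)


def test_translation_examples():
    assert translate_frame("ATGGCC", 1) == "MA"
    assert translate_frame("ATGGCC", -1) == "GH"  # revcomp GGCCAT
    assert translate_frame("ATGNCC", 1) == "MX"
    assert translate_frame("ATGAAATAA", 1) == "MK*"


def test_translation_agrees_with_codon_table_oracle():
    """All 64 codons, forward and reverse frames, against an independently
    written genetic-code table."""
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        assert translate_frame(codon, 1) == CODON_TABLE[codon]
        assert translate_frame(codon, -1) == translate_oracle(codon, -1)


def test_six_frames_drop_partial_codons(rng):
    seq = "".join("ACGT"[k] for k in rng.integers(4, size=100))
    frames = six_frame_translate(seq)
    assert set(frames) == {1, 2, 3, -1, -2, -3}
    for f, prot in frames.items():
        assert len(prot) == (100 - (abs(f) - 1)) // 3
        assert prot == translate_oracle(seq, f)


def test_translation_too_short_errors():
    with pytest.raises(ValueError):
        translate_frame("AT", 1)


def test_find_orfs_simple_example():
    (orf,) = [o for o in find_orfs("ATGAAATAA", min_aa=2) if o.frame == 1]
    assert (orf.nt_start, orf.nt_end, orf.protein) == (0, 6, "MK")


def test_find_orfs_all_stops_frame_plus1():
    assert [o for o in find_orfs("TAATAATAA", min_aa=1) if o.frame == 1] == []


def test_find_orfs_matches_brute_force(rng):
    for _ in range(10):
        seq = "".join("ACGT"[k] for k in rng.integers(4, size=300))
        got = {(o.frame, o.nt_start, o.nt_end, o.protein) for o in find_orfs(seq, 5)}
        assert got == orfs_oracle(seq, 5)


def test_find_orfs_no_start_codon_required():
    # stop-free run without ATG still reported
    orfs = find_orfs("AAAAAAAAA", min_aa=3)
    assert any(o.frame == 1 and o.protein == "KKK" for o in orfs)


def test_global_align_identity():
    res = global_align("MKVLD", "MKVLD")
    assert res.aligned_a == res.aligned_b == "MKVLD"
    assert res.position_map == (0, 1, 2, 3, 4)


def test_global_align_matches_enumeration_oracle():
    """Optimal score equals exhaustive enumeration over all alignments."""
    matrix = substitution_matrices.load("BLOSUM62")
    for a, b in [("MKV", "MV"), ("DDE", "DE"), ("WR", "RW"), ("MKVL", "ML")]:
        best = max(
            score_alignment(x, y, matrix, 10.0, 0.5)
            for x, y in enumerate_global_alignments(a, b)
        )
        assert global_align(a, b).score == pytest.approx(best)


def test_global_align_score_symmetry(rng):
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(20):
        a = "".join(rng.choice(aas, size=int(rng.integers(3, 12))))
        b = "".join(rng.choice(aas, size=int(rng.integers(3, 12))))
        assert global_align(a, b).score == pytest.approx(global_align(b, a).score)


def test_global_align_gap_round_trip(rng):
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(10):
        a = "".join(rng.choice(aas, size=20))
        b = "".join(rng.choice(aas, size=15))
        res = global_align(a, b)
        assert res.aligned_a.replace("-", "") == a
        assert res.aligned_b.replace("-", "") == b


def test_global_align_unknown_matrix_errors():
    with pytest.raises(ValueError):
        global_align("MK", "MK", substitution="NOSUCH")


@pytest.mark.parametrize("numbering", ["AC", "Hermes"])
def test_reference_passes_its_own_signature(numbering):
    spec = make_signature_spec(
        numbering, "ref", synthetic_reference_protein(numbering)
    )
    check = check_signature(spec.reference_protein, spec)
    assert check.status == "active"
    assert all(c.passed for c in check.sites)


def test_single_site_knockout_is_truncated(ac_spec):
    for pos, _ in ac_spec.sites:
        mutant = list(ac_spec.reference_protein)
        mutant[pos - 1] = "A"
        check = check_signature("".join(mutant), ac_spec)
        assert check.status == "truncated"
        failed = [c for c in check.sites if not c.passed]
        assert [c.reference_position for c in failed] == [pos]
        assert failed[0].observed == "A"


def test_internal_deletion_spanning_site_is_truncated(ac_spec):
    # 50-residue deletion centred on the third site (R463)
    pos = ac_spec.sites[2][0]
    ref = ac_spec.reference_protein
    deleted = ref[: pos - 25] + ref[pos + 25 :]
    check = check_signature(deleted, ac_spec)
    assert check.status == "truncated"
    site3 = next(c for c in check.sites if c.reference_position == pos)
    assert site3.observed == "-"
    assert not site3.passed


def test_signature_monotone_under_extra_knockouts(ac_spec):
    """Mutating additional sites never flips truncated back to active."""
    mutant = list(ac_spec.reference_protein)
    statuses = []
    for pos, _ in ac_spec.sites:
        mutant[pos - 1] = "A"
        statuses.append(check_signature("".join(mutant), ac_spec).status)
    assert statuses == ["truncated"] * len(ac_spec.sites)


def test_call_transposase_on_planted_element(ac_spec, rng):
    config = SimulationConfig(seed=5)
    elem, truth = build_element(config, rng, True, "Os_hAT-1", "Os")
    orf, check = call_transposase(elem, ac_spec)
    assert check.status == "active"
    assert (orf.nt_start, orf.nt_end) == truth.true_orf
    assert orf.protein == ac_spec.reference_protein


def test_call_transposase_short_element_absent(ac_spec):
    elem = ConsensusElement("DEBOAT", "", "ACGT" * 28)  # 112 nt < 100 aa
    orf, check = call_transposase(elem, ac_spec, min_aa=100)
    assert orf is None
    assert check.status == "absent"


def test_extract_blocks_identical_rows():
    blocks = extract_blocks(["MKVLD", "MKVLD"], min_block_len=3)
    assert [(b.start_col, b.end_col) for b in blocks] == [(0, 5)]


def test_extract_blocks_gap_splits_run():
    blocks = extract_blocks(["MK-V", "MKAV"], min_block_len=2)
    assert [(b.start_col, b.end_col) for b in blocks] == [(0, 2)]


def test_extract_blocks_planted_runs(rng):
    """Three conserved runs planted in low-conservation noise are the only
    blocks recovered; oracle = direct column classification."""
    n_rows, width = 12, 120
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    msa = [
        [aas[k] for k in rng.integers(20, size=width)] for _ in range(n_rows)
    ]
    planted = [(10, 16), (50, 58), (100, 107)]
    for start, end in planted:
        for col in range(start, end):
            res = aas[int(rng.integers(20))]
            for row in msa:
                row[col] = res
    # oracle: columns where the top residue reaches half the rows
    good = []
    for col in range(width):
        column = [row[col] for row in msa]
        good.append(max(column.count(c) for c in set(column)) >= n_rows / 2)
    expected = []
    col = 0
    while col < width:
        if good[col]:
            run = col
            while col < width and good[col]:
                col += 1
            if col - run >= 4:
                expected.append((run, col))
        else:
            col += 1
    blocks = extract_blocks(["".join(r) for r in msa], min_block_len=4,
                            min_column_conservation=0.5)
    got = [(b.start_col, b.end_col) for b in blocks]
    assert got == expected
    for start, end in planted:
        assert any(s <= start and end <= e for s, e in got)


def test_extract_blocks_ragged_rows_error():
    with pytest.raises(ValueError):
        extract_blocks(["MKV", "MK"])


def test_block_frequencies_sum_to_rows(rng):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    msa = ["".join(aas[k] for k in rng.integers(20, size=30)) for _ in range(7)]
    blocks = extract_blocks(msa, min_block_len=1, min_column_conservation=0.0)
    counts = block_frequencies(blocks[0], msa)
    assert (counts.sum(axis=1) == 7).all()


def test_block_frequencies_single_column_unanimous():
    msa = ["D", "D", "D", "D"]
    from hat_annotator.transposase import AMINO_ACIDS, ConservedBlock

    counts = block_frequencies(ConservedBlock(0, 1), msa)
    assert counts[0, AMINO_ACIDS.index("D")] == 4
    assert counts.sum() == 4
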