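import numpy as np
import pytest

from hat_annotator.io import parse_name
from hat_annotator.motifs import motif_mismatches, parse_motif
from hat_annotator.tir import find_tirs, revcomp
from hat_annotator.transposase import call_transposase
from hat_annotator.synthetic import (
    SimulationConfig,
    build_element,
    derive_nonautonomous,
    generate_dataset,
    mutate_element,
    radiate_family,
    sample_tir,
    write_dataset,
)


def test_sample_tir_respects_motif(rng):
    motif = parse_motif("[T/C]AGNGNNG")
    draws = [sample_tir(motif, 10, rng) for _ in range(10_000)]
    first = {d[0] for d in draws}
    assert first == {"T", "C"}
    t_frac = sum(d[0] == "T" for d in draws) / len(draws)
    assert 0.47 <= t_frac <= 0.53
    assert all(motif_mismatches(d, motif) == 0 for d in draws[:200])


def test_sample_tir_single_letter_motif(rng):
    assert sample_tir(parse_motif("A"), 1, rng) == "A"


@pytest.mark.parametrize(
    "kwargs",
    [
        {"tsd_length": 3},
        {"tsd_length": 9},
        {"tir_length": 7},
        {"transposase_fraction": 1.2},
        {"per_site_mutation_rate": 0.8},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_build_element_layout(rng):
    config = SimulationConfig(seed=1)
    elem, truth = build_element(config, rng, True, "Os_hAT-1", "Os")
    assert elem.length == config.element_length
    tsd = elem.sequence[: config.tsd_length]
    assert tsd == elem.sequence[-config.tsd_length :]  # TSD repeated
    a, b = truth.true_tir_five
    c, d = truth.true_tir_three
    assert elem.sequence[c:d] == revcomp(elem.sequence[a:b])
    assert truth.true_autonomy == "autonomous"


def test_build_element_infeasible_length(rng):
    with pytest.raises(ValueError):
        build_element(
            SimulationConfig(element_length=2000), rng, True, "X", "Os"
        )


def test_generate_dataset_deterministic(tmp_path):
    config = SimulationConfig(n_species=3, elements_per_species=4, seed=7,
                              per_site_mutation_rate=0.02)
    a = generate_dataset(config)
    b = generate_dataset(config)
    assert [e.sequence for e in a.elements] == [e.sequence for e in b.elements]
    assert a.truths == b.truths
    fa1, fa2 = tmp_path / "a.fa", tmp_path / "b.fa"
    write_dataset(a, fa1, tmp_path / "a.tsv")
    write_dataset(b, fa2, tmp_path / "b.tsv")
    assert fa1.read_bytes() == fa2.read_bytes()
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_generate_dataset_fractions_within_binomial_bounds():
    config = SimulationConfig(n_species=5, elements_per_species=40,
                              transposase_fraction=0.5, knockout_fraction=0.2,
                              deletion_fraction=0.3, seed=13)
    ds = generate_dataset(config)
    base = [t for t in ds.truths if t.parent_id is None]
    n = len(base)
    assert n == 200
    with_orf = [t for t in base if t.true_signature_state != "none"]
    # 99% binomial bounds (normal approximation, 2.58 sigma)
    def bounds(p, m):
        s = 2.58 * (p * (1 - p) / m) ** 0.5
        return p - s, p + s

    lo, hi = bounds(0.5, n)
    assert lo <= len(with_orf) / n <= hi
    ko = [t for t in with_orf if t.true_signature_state == "knocked_out"]
    lo, hi = bounds(0.2, len(with_orf))
    assert lo <= len(ko) / len(with_orf) <= hi
    derived = [t for t in ds.truths if t.parent_id is not None]
    lo, hi = bounds(0.3, len(with_orf))
    assert lo <= len(derived) / len(with_orf) <= hi


def test_derivative_links_and_keeps_tirs(anchor, ac_spec, rng):
    config = SimulationConfig(seed=3)
    parent, parent_truth = build_element(config, rng, True, "Zm_hAT-9", "Zm")
    child, truth = derive_nonautonomous(parent, parent_truth, rng)
    assert child.element_id == "Zm_hAT-9-N1"
    assert parse_name(child.element_id).stem == "Zm_hAT-9"
    assert truth.true_autonomy == "nonautonomous"
    assert truth.true_signature_state == "deleted"
    # TIRs survive the internal deletion
    pairs = find_tirs(child, anchor)
    assert pairs
    # the deleted transposase is no longer active
    _, check = call_transposase(child, ac_spec)
    assert check.status in ("truncated", "absent")


def test_mutate_zero_rate_is_identity(rng):
    config = SimulationConfig(seed=2)
    elem, _ = build_element(config, rng, False, "Os_hAT-2", "Os")
    assert mutate_element(elem, 0.0, rng) is elem


def test_mutate_preserves_protein_in_protected_orf(rng):
    config = SimulationConfig(seed=4)
    elem, truth = build_element(config, rng, True, "Os_hAT-3", "Os")
    from hat_annotator.transposase import translate_frame

    a, b = truth.true_orf
    frame = a % 3 + 1
    before = translate_frame(elem.sequence, frame)
    mutated = mutate_element(elem, 0.05, rng, protect_orf=truth.true_orf)
    after = translate_frame(mutated.sequence, frame)
    i, j = (a - (frame - 1)) // 3, (b - (frame - 1)) // 3
    assert after[i:j] == before[i:j]  # synonymous-only inside the ORF
    assert mutated.sequence != elem.sequence  # but the rest diverged


def test_radiate_zero_rate_gives_identical_leaves(rng):
    root = "".join("ACGT"[k] for k in rng.integers(4, size=500))
    labels, seqs, tree = radiate_family(root, 5, rng, internal_prob=0.0, leaf_prob=0.0)
    assert all(s == root for s in seqs)
    assert len(labels) == 5


def _path_lambda(tree, la, lb):
    # product of (1 - 4q/3) over branches on the leaf-to-leaf path
    nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    def ancestors(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent_node
        return out
    pa, pb = ancestors(nodes[la]), ancestors(nodes[lb])
    sb = set(id(n) for n in pb)
    mrca = next(n for n in pa if id(n) in sb)
    lam = 1.0
    for chain in (pa, pb):
        for n in chain:
            if n is mrca:
                break
            lam *= 1 - 4 * (n.edge.length or 0.0) / 3
    return lam


def test_pairwise_divergence_matches_binomial_expectation(rng):
    """Observed leaf-pair p-distance sits within 3 standard errors of the
    closed-form substitution probability along the generating path."""
    from hat_annotator.phylogeny import p_distance

    L = 10_000
    root = "".join("ACGT"[k] for k in rng.integers(4, size=L))
    labels, seqs, tree = radiate_family(root, 6, rng,
                                        internal_prob=0.05, leaf_prob=0.03)
    by_label = dict(zip(labels, seqs))
    for la, lb in [(labels[0], labels[1]), (labels[2], labels[5])]:
        expected = 0.75 * (1 - _path_lambda(tree, la, lb))
        observed = p_distance(by_label[la], by_label[lb])
        se = (expected * (1 - expected) / L) ** 0.5
        assert abs(observed - expected) <= 3 * se


def test_nj_recovers_radiation_topology(rng):
    """NJ on JC distances recovers the generating topology for well-separated
    branches (20 seeded trials)."""
    from hat_annotator.phylogeny import bipartitions, msa_distance_matrix, nj

    wins = 0
    for _ in range(20):
        root = "".join("ACGT"[k] for k in rng.integers(4, size=5000))
        labels, seqs, tree = radiate_family(root, 7, rng,
                                            internal_prob=0.05, leaf_prob=0.03)
        est = nj(msa_distance_matrix(labels, seqs))
        wins += set(bipartitions(est)) == set(bipartitions(tree))
    assert wins >= 19


def test_classification_accuracy_degrades_gracefully(ac_spec):
    """Autonomy-call accuracy against planted truth is non-increasing (up to
    one-element sampling noise) as the mutation rate rises."""
    from hat_annotator.pipeline import PipelineConfig, run_pipeline

    accs = []
    for rate in (0.0, 0.01, 0.05, 0.15):
        total = agree = 0
        for rep in range(3):
            config = SimulationConfig(n_species=2, elements_per_species=4,
                                      per_site_mutation_rate=rate,
                                      seed=100 + rep)
            ds = generate_dataset(config)
            res = run_pipeline(ds.elements, ac_spec, PipelineConfig())
            truth = ds.truth_by_id()
            total += len(res.calls)
            agree += sum(
                1 for c in res.calls if c.status == truth[c.element_id].true_autonomy
            )
        accs.append(agree / total)
    slack = 1 / total
    assert all(accs[i] >= accs[i + 1] - slack for i in range(len(accs) - 1))
    assert accs[0] == 1.0
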