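"""End-to-end orchestration: FASTA in, annotation tables out.

The chain is: read elements -> anchored TIR scan -> TIR dedup + consensus ->
six-frame transposase call against a reference -> autonomy classification ->
summary. Every stage's output is a plain TSV so any stage can be rerun in
isolation; a MANIFEST with content hashes marks completeness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import autonomy as autonomy_mod
from . import tir as tir_mod
from .io import ConsensusElement, parse_name, read_fasta
from .motifs import parse_motif
from .phylogeny import bootstrap_support, msa_distance_matrix, nj, to_newick
from .transposase import SignatureSpec, make_signature_spec

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR = "(T/C)A(A/G)NG"


@dataclass(frozen=True)
class PipelineConfig:
    input_fasta: str = ""
    reference_fasta: Optional[str] = None
    numbering: str = "AC"
    check_transposase: bool = True
    anchor: str = DEFAULT_ANCHOR
    min_len: int = 8
    max_len: int = 30
    max_arm_mismatches: int = 4
    max_anchor_mismatches: int = 1
    terminal_window: int = 200
    consensus_columns: int = 8
    single_threshold: float = 0.6
    pair_threshold: float = 0.8
    min_aa: int = 100
    tree: bool = False
    tree_model: str = "jc69"
    bootstrap: int = 100
    seed: int = 0
    out_dir: str = "hat_annotator_out"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    elements: list
    best_tirs: dict  # element_id -> TIRPair or None
    consensus: Optional[tir_mod.TIRConsensusResult]
    n_arms: int
    n_unique_arms: int
    orf_calls: dict  # element_id -> ORFCall or None
    residue_checks: dict  # element_id -> ResidueCheck
    calls: list
    summary: autonomy_mod.DatasetSummary
    newick: Optional[str] = None


def _load_reference(reference_fasta: str) -> tuple[str, str]:
    from Bio import SeqIO

    recs = list(SeqIO.parse(reference_fasta, "fasta"))
    if not recs:
        raise ValueError(f"no records in reference FASTA {reference_fasta}")
    return recs[0].id, str(recs[0].seq).upper()


def run_pipeline(
    elements: Sequence[ConsensusElement],
    spec: Optional[SignatureSpec],
    config: PipelineConfig,
) -> PipelineResult:
    """The full annotation chain on in-memory elements."""
    anchor = parse_motif(config.anchor)
    best_tirs: dict = {}
    arms: list = []
    for e in elements:
        pairs = tir_mod.find_tirs(
            e,
            anchor,
            min_len=config.min_len,
            max_len=config.max_len,
            max_arm_mismatches=config.max_arm_mismatches,
            max_anchor_mismatches=config.max_anchor_mismatches,
            terminal_window=config.terminal_window,
        )
        best = tir_mod.best_tir(pairs)
        best_tirs[e.element_id] = best
        if best is not None:
            arms.append(best.arms(e)[0])
    unique_arms = tir_mod.dedupe_tirs(arms)
    logger.info("TIR arms: %d before dedup, %d nonidentical", len(arms), len(unique_arms))
    consensus = None
    if unique_arms and min(len(a) for a in unique_arms) >= config.consensus_columns:
        consensus = tir_mod.derive_consensus(
            unique_arms,
            n_columns=config.consensus_columns,
            single_threshold=config.single_threshold,
            pair_threshold=config.pair_threshold,
        )
        logger.info("TIR consensus: %s", consensus.consensus)

    orf_calls: dict = {}
    residue_checks: dict = {}
    if config.check_transposase:
        if spec is None:
            raise ValueError(
                "transposase checking requested but no reference signature "
                "spec provided"
            )
        from .transposase import call_transposase

        for e in elements:
            orf, check = call_transposase(e, spec, min_aa=config.min_aa)
            orf_calls[e.element_id] = orf
            residue_checks[e.element_id] = check
        n_active = sum(1 for c in residue_checks.values() if c.status == "active")
        logger.info("active transposases: %d of %d", n_active, len(elements))
    else:
        from .transposase import ABSENT

        for e in elements:
            orf_calls[e.element_id] = None
            residue_checks[e.element_id] = ABSENT

    calls = [
        autonomy_mod.classify(e.element_id, best_tirs[e.element_id], residue_checks[e.element_id])
        for e in elements
    ]
    names = [parse_name(e.element_id) for e in elements]
    calls = autonomy_mod.link_derivatives(calls, names)
    summary = autonomy_mod.summarize(
        elements, calls, consensus.consensus if consensus else ""
    )
    logger.info(
        "autonomous: %d of %d (%.1f%%)",
        summary.n_autonomous,
        summary.n_total,
        summary.autonomous_percent,
    )
    return PipelineResult(
        elements=list(elements),
        best_tirs=best_tirs,
        consensus=consensus,
        n_arms=len(arms),
        n_unique_arms=len(unique_arms),
        orf_calls=orf_calls,
        residue_checks=residue_checks,
        calls=calls,
        summary=summary,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def result_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """The pipeline's TSV-able tables, keyed by output basename."""
    el_rows = [
        {"element_id": e.element_id, "species": e.species_code, "length": e.length}
        for e in result.elements
    ]
    tir_rows = []
    for e in result.elements:
        p = result.best_tirs[e.element_id]
        row = {"element_id": e.element_id, "has_tir": p is not None}
        if p is not None:
            a5, a3 = p.arms(e)
            row.update(
                tir5_start=p.five_prime_start,
                tir5_end=p.five_prime_end,
                tir3_start=p.three_prime_start,
                tir3_end=p.three_prime_end,
                arm_length=p.arm_length,
                arm_mismatches=p.arm_mismatches,
                anchor_mismatches=p.motif_mismatches,
                arm5=a5,
                arm3=a3,
            )
        tir_rows.append(row)
    tp_rows = []
    for e in result.elements:
        orf = result.orf_calls[e.element_id]
        check = result.residue_checks[e.element_id]
        tp_rows.append(
            {
                "element_id": e.element_id,
                "status": check.status,
                "frame": orf.frame if orf else "",
                "orf_start": orf.nt_start if orf else "",
                "orf_end": orf.nt_end if orf else "",
                "orf_aa": len(orf.protein) if orf else 0,
                "site_observed": ";".join(
                    f"{s.reference_position}:{s.observed}" for s in check.sites
                ),
            }
        )
    call_rows = [
        {
            "element_id": c.element_id,
            "status": c.status,
            "reasons": ";".join(sorted(c.reasons)),
            "parent_id": c.parent_id or "",
        }
        for c in result.calls
    ]
    s = result.summary
    summary_rows = [
        {"key": f"n_{sp or 'unknown'}", "value": n} for sp, n in sorted(s.per_species.items())
    ] + [
        {"key": "n_total", "value": s.n_total},
        {"key": "n_autonomous", "value": s.n_autonomous},
        {"key": "autonomous_percent", "value": s.autonomous_percent},
        {"key": "tir_consensus", "value": s.tir_consensus},
    ]
    return {
        "elements.tsv": pd.DataFrame(el_rows),
        "tirs.tsv": pd.DataFrame(tir_rows),
        "transposase.tsv": pd.DataFrame(tp_rows),
        "autonomy.tsv": pd.DataFrame(call_rows),
        "summary.tsv": pd.DataFrame(summary_rows),
    }


def run_all(config: PipelineConfig) -> Path:
    """Run every stage on ``config.input_fasta`` and write TSVs, the
    effective config, an optional bootstrap NJ tree, and a MANIFEST of
    content hashes to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str]] = []
    try:
        if config.check_transposase:
            if not config.reference_fasta:
                raise ValueError(
                    "check_transposase requires a reference transposase FASTA"
                )
            ref_id, ref_seq = _load_reference(config.reference_fasta)
            spec = make_signature_spec(config.numbering, ref_id, ref_seq)
        else:
            spec = None
        elements = read_fasta(config.input_fasta)
        logger.info("read %d elements from %s", len(elements), config.input_fasta)
        result = run_pipeline(elements, spec, config)

        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
        )
        manifest.append(("config.json", _sha256(out / "config.json")))
        for name, df in result_tables(result).items():
            df.to_csv(out / name, sep="\t", index=False)
            manifest.append((name, _sha256(out / name)))
        if result.consensus is not None:
            freq = pd.DataFrame(
                result.consensus.frequency_matrix, columns=list("ACGT")
            )
            freq.insert(0, "column", range(len(freq)))
            freq.to_csv(out / "tir_consensus_counts.tsv", sep="\t", index=False)
            manifest.append(
                ("tir_consensus_counts.tsv", _sha256(out / "tir_consensus_counts.tsv"))
            )
        if config.tree:
            labels = [e.element_id for e in result.elements]
            lengths = {e.length for e in result.elements}
            if len(lengths) != 1:
                raise ValueError(
                    "tree building needs aligned (equal-length) input sequences"
                )
            seqs = [e.sequence for e in result.elements]
            if config.bootstrap > 0:
                tree = bootstrap_support(
                    labels,
                    seqs,
                    n_reps=config.bootstrap,
                    seed=config.seed,
                    model=config.tree_model,
                )
            else:
                tree = nj(msa_distance_matrix(labels, seqs, model=config.tree_model))
            result.newick = to_newick(tree)
            (out / "tree.nwk").write_text(result.newick + "\n")
            manifest.append(("tree.nwk", _sha256(out / "tree.nwk")))
        status = "complete"
    except Exception:
        status = "incomplete"
        raise
    finally:
        lines = [f"# status: {status}"] + [f"{h}\t{n}" for n, h in manifest]
        (out / "MANIFEST").write_text("\n".join(lines) + "\n")
    return out
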