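"""Shared study conditions for the numbered analysis drivers.

One synthetic family of ~210 consensus elements across five species, at two
divergence levels (none, and 5% per site), mirroring the layout rules of
plant hAT elements: anchored TIRs >= 8 bp, 4-8 bp TSDs, and an internal
~750-aa transposase carrying the five catalytic residues when intact.
"""

from pathlib import Path

from hat_annotator.synthetic import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

STUDY_SEED = 17

CLEAN = SimulationConfig(n_species=5, elements_per_species=35, seed=STUDY_SEED)
DIVERGED = SimulationConfig(
    n_species=5, elements_per_species=35, per_site_mutation_rate=0.05,
    seed=STUDY_SEED,
)
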