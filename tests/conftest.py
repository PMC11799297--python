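"""Shared fixtures: small synthetic studies reused across test modules."""

import pytest

import tcrmotif as tm
from tcrmotif.evaluate import SplitSpec
from tcrmotif.pipeline import run_study


@pytest.fixture(scope="session")
def small_study() -> tm.StudyResult:
    """One modest end-to-end run (planted 'AFF' at 3-5) shared by read-only tests."""
    spec = tm.SyntheticSpec(n_strong=60, n_weak=600, seed=11)
    return run_study(
        spec,
        n_top=300,
        n_strong_train=60,
        split_spec=SplitSpec(n_repeats=3, seed=11),
    )


@pytest.fixture()
def planted_system() -> tm.EnergySystem:
    """Energy system for a probability-one 'AFF' plant at positions 3-5."""
    spec = tm.SyntheticSpec(
        n_strong=5, n_weak=5, planted_motifs=(tm.PlantedMotif("AFF", 3, 1.0),), seed=3
    )
    return tm.generate_energy_system(spec, 3)
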