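"""Shared fixtures: tiny hand-built alignments and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from barcodegap.io import LocusAlignment, SpecimenRecord
from barcodegap.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def metadata():
    def rec(sid, morph="spA", loci=("COI", "16S")):
        return SpecimenRecord(
            specimen_id=sid, morphospecies=morph, loci_present=frozenset(loci)
        )

    return {sid: rec(sid) for sid in ("X1", "X2", "X3", "X4")}


@pytest.fixture
def small_alignment():
    return LocusAlignment(
        locus="COI",
        ids=["X1", "X2", "X3"],
        sequences=["ACGTACGTAC", "ACGTACGTAT", "GCGTACGTAC"],
    )


@pytest.fixture
def simulated_dataset():
    """Survey-shaped dataset: 5 morphospecies, mixed clade counts."""
    cfg = SimulationConfig(seed=7)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
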