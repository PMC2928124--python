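"""Shared fixtures: synthetic organelle sets and their aligned TMDs.

The expensive session fixtures (four 99-protein organelle sets and their
GES-scanned alignments) are generated once and shared; tests that need
independent draws take their own generator.
"""

from __future__ import annotations

import numpy as np
import pytest

from tmdscape import GES, annotate_tmd, orient_cytosolic
from tmdscape.synthetic_data import DEFAULT_PRESETS, sample_dataset
from tmdscape.tmd_edges import NoHydrophobicCore

#: Seeds for the default study conditions used across the suite.
SET_SEED = 1
CV_SEED = 1


@pytest.fixture(scope="session")
def default_sets():
    """The four default organelle sets, n=99 each, with generator truths."""
    rng = np.random.default_rng(SET_SEED)
    out = {}
    for key, preset in DEFAULT_PRESETS.items():
        out[key] = sample_dataset(preset, 99, rng)
    return out


def align_set(dataset, scale=GES, flank=10):
    """Scan + orient every protein of a dataset, skipping unscannable ones."""
    aligned, annotations = [], []
    for protein in dataset:
        try:
            ann = annotate_tmd(protein, scale)
        except NoHydrophobicCore:
            continue
        annotations.append(ann)
        aligned.append(orient_cytosolic(protein, ann, flank=flank))
    return aligned, annotations


@pytest.fixture(scope="session")
def default_aligned(default_sets):
    """GES-aligned TMDs and annotations per preset key."""
    return {key: align_set(ds) for key, (ds, _) in default_sets.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(7)
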