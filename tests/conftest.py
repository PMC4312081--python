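"""Shared fixtures: ground-truthed synthetic scenarios at small scale."""

from __future__ import annotations

import pytest

from tundradiet.synthetic_data import (PRIMER_GH, PRIMER_CH, generate_truth,
                                       generate_reference_library,
                                       generate_sample_counts)
from tundradiet.reference_library import in_silico_pcr


@pytest.fixture(scope="session")
def bylot_truth():
    return generate_truth("bylot-like", seed=11)


@pytest.fixture(scope="session")
def gh_library(bylot_truth):
    """Raw and amplicon-trimmed synthetic g-h reference library."""
    lib, amps = generate_reference_library(bylot_truth, PRIMER_GH, seed=12)
    return in_silico_pcr(lib, PRIMER_GH), amps


@pytest.fixture(scope="session")
def small_dataset(bylot_truth, gh_library):
    """A 12-sample two-marker dataset with variant tables and truth."""
    _, amps = gh_library
    return generate_sample_counts(
        bylot_truth, {"Lemmus": 8, "Dicrostonyx": 4}, seed=13,
        amplicons={"g-h": amps, "c-h": amps}, error_rate=0.01)
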