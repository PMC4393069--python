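"""Shared fixtures: synthetic property tables, tiny datasets, the benchmark."""

import numpy as np
import pytest

from sumohunt.aaindex import AAINDEX_RESIDUE_ORDER, PropertyScale, PropertyTable
from sumohunt.dataset import NEGATIVE, POSITIVE, PeptideWindow, WindowDataset
from sumohunt.encoding import EncodedDataset


def synthetic_scale(accession="SYN0000001", values=None, constant=None):
    """A property scale with controlled coefficients for math-core tests."""
    if constant is not None:
        coeffs = {r: float(constant) for r in AAINDEX_RESIDUE_ORDER}
    elif values is not None:
        coeffs = dict(zip(AAINDEX_RESIDUE_ORDER, map(float, values)))
    else:
        coeffs = {r: float(i + 1) for i, r in enumerate(AAINDEX_RESIDUE_ORDER)}
    return PropertyScale(accession, "synthetic scale", coeffs)


@pytest.fixture
def synthetic_table16():
    """16 distinct synthetic scales (scale s maps residue i to i+1 + s/100)."""
    scales = tuple(
        synthetic_scale(
            f"SYN{s:07d}",
            values=[i + 1 + s / 100.0 for i in range(20)],
        )
        for s in range(16)
    )
    return PropertyTable(scales)


@pytest.fixture
def property_table():
    from sumohunt.aaindex import load_property_table

    return load_property_table()


def make_windows(peptides, labels, flank=None):
    flank = flank if flank is not None else len(peptides[0]) // 2
    windows = tuple(
        PeptideWindow(p, flank, lab, accession=f"P{i}", position=flank + 1)
        for i, (p, lab) in enumerate(zip(peptides, labels))
    )
    return WindowDataset(windows, flank)


def encoded_from_arrays(X, y):
    """Wrap raw arrays for forest/evaluation tests (names are placeholders)."""
    X = np.asarray(X, dtype=float)
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    return EncodedDataset(X, np.asarray(y, dtype=bool), names, flank=0)


@pytest.fixture(scope="session")
def benchmark_586():
    """The standard synthetic benchmark: 293 modeled positives + 293 uniform
    negatives, encoded at window 7, seed 0."""
    from sumohunt.synthetic import make_benchmark

    windows, encoded = make_benchmark(293, 293, seed=0, encode_flank=3)
    return windows, encoded


@pytest.fixture(scope="session")
def fixture_proteome():
    """A synthetic proteome with exactly 7639 lysines, 293 of them annotated
    as modified (the curation-scale labeling scenario)."""
    sequences = {}
    k_counts = [400] * 19 + [39]
    for i, k in enumerate(k_counts):
        sequences[f"SYNP{i:03d}"] = "AK" * k  # lysines at even positions
    modified = {"SYNP000": {2 * j for j in range(1, 294)}}  # 293 sites
    return sequences, modified
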