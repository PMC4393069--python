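"""Synthetic window generators emulating curated SUMOylation-site data.

Two generators are provided, both driven by the packaged 20x21 positional
count matrix of the 293 curated modified sites:

* a *deterministic exact-marginal* constructor that lays out windows whose
  positional frequency matrix equals a given count matrix cell-for-cell
  (each column's residues repeated by count in fixed row order, column
  layouts read off row-wise), and
* seeded samplers: positives drawn position-independently from the count
  matrix's per-column distributions, negatives with uniform flanking
  residues around a center lysine.

Columns are modeled independently — the count matrix carries marginal
information only — so these fixtures reproduce per-position composition,
not inter-position dependence, and must not be mistaken for real
SUMOylation data.  Columns whose printed counts fall short of the window
total are treated as terminal padding (the curated 21-mers overhang protein
ends), which the exact-marginal constructor reproduces with 'X' symbols
allocated outward from the center.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .aaindex import load_property_table
from .dataset import (
    NEGATIVE,
    PAD,
    POSITIVE,
    PeptideWindow,
    WindowDataset,
    trim,
)
from .encoding import EncodedDataset, encode_dataset
from .errors import ConstructionError, DataError
from .motif import RESIDUE_ORDER, PositionalFrequencyMatrix, _offset_labels

_COUNTS_FILE = "positional_counts_293.tsv"
_COUNTS_SHA256 = "5a3b3ef8e771574cced20c00c8676f907ac430851120a6dac1c141a2d13a979b"


def curated_site_counts() -> PositionalFrequencyMatrix:
    """The packaged positional count matrix of the 293 modified sites.

    20 residues x 21 offsets (-10..+10); the center column is entirely
    lysine.  The file is checksummed: a corrupt transcription raises
    :class:`DataError`.
    """
    try:
        raw = (
            resources.files("sumohunt").joinpath("data", _COUNTS_FILE).read_bytes()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise DataError(f"packaged count matrix {_COUNTS_FILE} missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _COUNTS_SHA256:
        raise DataError(
            f"packaged count matrix failed its checksum ({digest[:12]}...)"
        )
    matrix = PositionalFrequencyMatrix.from_tsv(raw.decode())
    if matrix.flank != 10 or matrix.n != 293:
        raise DataError("packaged count matrix has unexpected shape")
    return matrix


def exact_marginal_dataset(matrix: PositionalFrequencyMatrix) -> WindowDataset:
    """Deterministic windows whose positional frequencies equal ``matrix``.

    For each offset column the residues are laid out in fixed row order
    repeated by count; row ``i`` of the layout becomes window ``i``
    (columns are independent by construction).  A column whose sum falls
    short of the window total ``n`` (taken from the center column) is
    completed with terminal 'X' padding: at negative offsets the first rows
    are padded, at positive offsets the last rows, which requires deficits
    to grow monotonically outward from the center — otherwise no valid
    end-padded window layout exists and a :class:`ConstructionError` is
    raised.  No randomness is involved.
    """
    flank = matrix.flank
    sums = matrix.column_sums()
    labels = _offset_labels(flank)
    n = int(sums[labels[flank]])
    if n <= 0:
        raise ConstructionError("empty center column")
    deficits = [n - int(sums[c]) for c in labels]
    if min(deficits) < 0:
        raise ConstructionError("column sum exceeds the center column sum")
    left = deficits[:flank]
    right = deficits[flank + 1 :]
    if deficits[flank] != 0:
        raise ConstructionError("center column must sum to the window count")
    if any(left[i] < left[i + 1] for i in range(len(left) - 1)) or any(
        right[i] > right[i + 1] for i in range(len(right) - 1)
    ):
        raise ConstructionError(
            "column deficits must grow monotonically outward from the center"
        )
    columns: list[str] = []
    for j, col_label in enumerate(labels):
        residues = "".join(
            r * int(matrix.counts.at[r, col_label]) for r in RESIDUE_ORDER
        )
        d = deficits[j]
        if j < flank:  # upstream side: pad the first rows
            columns.append(PAD * d + residues)
        else:  # center (d == 0) and downstream side: pad the last rows
            columns.append(residues + PAD * d)
    windows = tuple(
        PeptideWindow(
            "".join(col[i] for col in columns),
            flank,
            POSITIVE,
            accession=f"EM{i + 1:04d}",
            position=flank + 1,
        )
        for i in range(n)
    )
    return WindowDataset(windows, flank, {"generator": "exact-marginal"})


class PositionalModel:
    """Per-position categorical residue distributions derived from counts.

    The center column must be degenerate at lysine; padding counts are not
    modeled (sampled windows are always full length).
    """

    def __init__(self, matrix: PositionalFrequencyMatrix):
        self.flank = matrix.flank
        labels = _offset_labels(matrix.flank)
        probs = []
        for j, col in enumerate(labels):
            counts = matrix.counts[col].to_numpy(dtype=float)
            if counts.sum() <= 0:
                raise ConstructionError(f"column {col} has no counts")
            p = counts / counts.sum()
            if j == matrix.flank and p[RESIDUE_ORDER.index("K")] != 1.0:
                raise ConstructionError("center column must be all lysine")
            probs.append(p)
        self.probs = np.stack(probs, axis=1)  # 20 x (2*flank+1)


def curated_site_model() -> PositionalModel:
    """The positional model of the packaged 293-site count matrix."""
    return PositionalModel(curated_site_counts())


def sample_positives(model: PositionalModel, n: int, seed: int) -> WindowDataset:
    """Draw ``n`` positive windows position-independently from ``model``."""
    if n < 1:
        raise ConstructionError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    width = 2 * model.flank + 1
    residues = np.array(list(RESIDUE_ORDER))
    cols = [
        residues[rng.choice(20, size=n, p=model.probs[:, j])] for j in range(width)
    ]
    windows = tuple(
        PeptideWindow(
            "".join(cols[j][i] for j in range(width)),
            model.flank,
            POSITIVE,
            accession=f"SP{i + 1:05d}",
            position=model.flank + 1,
        )
        for i in range(n)
    )
    return WindowDataset(
        windows, model.flank, {"generator": "sample-positives", "seed": seed}
    )


def sample_negatives(n: int, seed: int, flank: int = 10) -> WindowDataset:
    """``n`` background windows: center K, flanks i.i.d. uniform over 20 residues."""
    if n < 1:
        raise ConstructionError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    residues = np.array(list(RESIDUE_ORDER))
    width = 2 * flank + 1
    draws = residues[rng.integers(0, 20, size=(n, width))]
    draws[:, flank] = "K"
    windows = tuple(
        PeptideWindow(
            "".join(draws[i]), flank, NEGATIVE,
            accession=f"SN{i + 1:05d}", position=flank + 1,
        )
        for i in range(n)
    )
    return WindowDataset(
        windows, flank, {"generator": "sample-negatives", "seed": seed}
    )


def make_benchmark(
    n_pos: int = 293,
    n_neg: int = 293,
    seed: int = 0,
    encode_flank: int = 3,
) -> tuple[WindowDataset, EncodedDataset]:
    """End-to-end benchmark: modeled positives + uniform negatives, encoded.

    Windows are generated at flank 10 (so the same sites can be re-cut at
    any narrower flank) and encoded with the packaged 16-scale property
    table at ``encode_flank``.  Fully determined by ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    positives = sample_positives(curated_site_model(), n_pos, int(seeds[0]))
    negatives = sample_negatives(n_neg, int(seeds[1]), flank=10)
    windows = WindowDataset(
        positives.windows + negatives.windows,
        10,
        {"generator": "benchmark", "seed": seed, "n_pos": n_pos, "n_neg": n_neg},
    )
    encoded = encode_dataset(trim(windows, encode_flank), load_property_table())
    return windows, encoded
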