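"""Window encoding: 16 property values per position.

A window of length ``w = 2*flank + 1`` becomes a real vector of length
``16*w`` (336/176/112 for windows 21/11/7).  Ordering is position-major:
for each position from ``-flank`` to ``+flank`` in sequence order, the 16
property values in fixed table order.  Feature names record this layout
(``pos-3:PRAM900101`` ...), so any consumer can verify it.

The encoded dataset can be written to CSV or to WEKA's ARFF dialect; both
writers render floats with ``repr`` so a read-back parses to bit-identical
values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aaindex import PAD_SYMBOL, PropertyTable, residue_value
from .dataset import NEGATIVE, POSITIVE, PeptideWindow, WindowDataset
from .errors import EncodingError, ParseError

_CLASS_ATTR = "class"


@dataclass(frozen=True)
class FeatureVector:
    """The encoding of one window: values, label, provenance."""

    values: np.ndarray
    label: str
    accession: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise EncodingError("non-finite feature value")


@dataclass(frozen=True)
class EncodedDataset:
    """A feature matrix with labels, names, and per-row provenance.

    ``X`` is an ``(n, 16*w)`` float matrix; ``y`` is boolean with ``True``
    for the positive class.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    flank: int
    provenance: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise EncodingError("feature matrix / feature_names shape mismatch")
        if self.X.shape[0] != self.y.shape[0]:
            raise EncodingError("feature matrix / label length mismatch")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def labels(self) -> list[str]:
        return [POSITIVE if v else NEGATIVE for v in self.y]

    def subset(self, indices: Sequence[int]) -> "EncodedDataset":
        idx = np.asarray(indices, dtype=int)
        prov = tuple(self.provenance[i] for i in idx) if self.provenance else ()
        return EncodedDataset(
            self.X[idx], self.y[idx], self.feature_names, self.flank, prov
        )


def feature_names(flank: int, table: PropertyTable) -> tuple[str, ...]:
    """Position-major feature names, e.g. ``pos-3:PRAM900101`` ... ``pos+3:ZIMJ680104``."""
    names = []
    for offset in range(-flank, flank + 1):
        tag = f"pos{offset:+d}" if offset != 0 else "pos0"
        names.extend(f"{tag}:{acc}" for acc in table.accessions)
    return tuple(names)


def encode_window(window: PeptideWindow, table: PropertyTable) -> FeatureVector:
    """Encode one window as a ``16*(2*flank+1)``-vector.

    Pad symbols encode as the per-scale mean coefficient.
    """
    values = np.empty(len(table) * len(window.peptide))
    k = 0
    for residue in window.peptide:
        for scale_index in range(len(table)):
            values[k] = residue_value(table, scale_index, residue)
            k += 1
    return FeatureVector(values, window.label, window.accession, window.position)


def encode_dataset(dataset: WindowDataset, table: PropertyTable) -> EncodedDataset:
    """Encode every window, preserving order."""
    if len(dataset) == 0:
        raise EncodingError("cannot encode an empty dataset")
    # Vectorized: one lookup row per (residue symbol), gathered per window.
    alphabet = {}
    for w in dataset:
        for ch in w.peptide:
            if ch not in alphabet:
                alphabet[ch] = [
                    residue_value(table, s, ch) for s in range(len(table))
                ]
    lut = {ch: np.asarray(vals) for ch, vals in alphabet.items()}
    X = np.stack(
        [np.concatenate([lut[ch] for ch in w.peptide]) for w in dataset]
    )
    y = np.fromiter((w.label == POSITIVE for w in dataset), dtype=bool, count=len(dataset))
    prov = tuple((w.accession, w.position) for w in dataset)
    return EncodedDataset(X, y, feature_names(dataset.flank, table), dataset.flank, prov)


def _fmt(value: float) -> str:
    return repr(float(value))


def write_csv(dataset: EncodedDataset, include_provenance: bool = False) -> str:
    """CSV text: header of feature names plus ``class``, one row per vector."""
    out = io.StringIO()
    header = list(dataset.feature_names) + [_CLASS_ATTR]
    if include_provenance:
        header = ["accession", "position"] + header
    out.write(",".join(header) + "\n")
    for i in range(len(dataset)):
        fields = [_fmt(v) for v in dataset.X[i]] + [dataset.labels[i]]
        if include_provenance:
            acc, pos = dataset.provenance[i] if dataset.provenance else ("", 0)
            fields = [acc, str(pos)] + fields
        out.write(",".join(fields) + "\n")
    return out.getvalue()


def read_csv(text: str) -> EncodedDataset:
    """Read back :func:`write_csv` output (provenance columns optional)."""
    df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    if _CLASS_ATTR not in df.columns:
        raise ParseError("encoded CSV lacks a 'class' column")
    prov: tuple[tuple[str, int], ...] = ()
    if "accession" in df.columns and "position" in df.columns:
        prov = tuple(zip(df["accession"].astype(str), df["position"].astype(int)))
        df = df.drop(columns=["accession", "position"])
    names = tuple(c for c in df.columns if c != _CLASS_ATTR)
    y = (df[_CLASS_ATTR] == POSITIVE).to_numpy()
    X = df[list(names)].to_numpy(dtype=float)
    flank = _flank_from_names(names)
    return EncodedDataset(X, y, names, flank, prov)


def _flank_from_names(names: Sequence[str]) -> int:
    positions = {n.split(":", 1)[0] for n in names}
    return (len(positions) - 1) // 2


def write_arff(dataset: EncodedDataset, relation_name: str = "sumohunt") -> str:
    """WEKA-dialect ARFF: numeric attributes, final nominal class attribute."""
    name = relation_name.strip() or "sumohunt"
    out = io.StringIO()
    out.write(f"@RELATION {name}\n\n")
    for fname in dataset.feature_names:
        out.write(f"@ATTRIBUTE \"{fname}\" NUMERIC\n")
    out.write(f"@ATTRIBUTE {_CLASS_ATTR} {{{POSITIVE},{NEGATIVE}}}\n\n@DATA\n")
    for i in range(len(dataset)):
        out.write(",".join(_fmt(v) for v in dataset.X[i]))
        out.write(f",{dataset.labels[i]}\n")
    return out.getvalue()


def read_arff(text: str) -> EncodedDataset:
    """Read back :func:`write_arff` output."""
    names: list[str] = []
    rows: list[list[float]] = []
    labels: list[str] = []
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        upper = line.upper()
        if upper.startswith("@RELATION"):
            continue
        if upper.startswith("@ATTRIBUTE"):
            body = line.split(None, 1)[1]
            if body.startswith('"'):
                attr_name = body[1 : body.index('"', 1)]
            else:
                attr_name = body.split()[0]
            if attr_name != _CLASS_ATTR:
                names.append(attr_name)
            continue
        if upper.startswith("@DATA"):
            in_data = True
            continue
        if not in_data:
            raise ParseError(f"ARFF line {lineno}: data before @DATA")
        fields = line.split(",")
        if len(fields) != len(names) + 1:
            raise ParseError(
                f"ARFF line {lineno}: {len(fields)} fields, expected {len(names) + 1}"
            )
        rows.append([float(v) for v in fields[:-1]])
        labels.append(fields[-1])
    if not rows:
        raise ParseError("ARFF input has no data rows")
    X = np.asarray(rows)
    y = np.asarray([lab == POSITIVE for lab in labels])
    return EncodedDataset(X, y, tuple(names), _flank_from_names(names))
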