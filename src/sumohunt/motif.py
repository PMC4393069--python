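"""Positional residue frequencies and the ΨKXE consensus motif.

SUMO attaches to lysines that mostly sit in the consensus ΨKXE: a
hydrophobic residue (Ψ) immediately upstream of the target lysine, any
residue at +1, and glutamate at +2.  This module counts residue occurrences
at each window offset (the positional frequency matrix) and tests windows
against the consensus rule.

Matrix rows follow the fixed residue order A R N D C E Q G H I L K M F P S
T W Y V; columns are signed offsets from the center lysine.  Terminal 'X'
padding is never counted, so a column's sum can fall below the number of
windows when sites sit near protein ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet

import numpy as np
import pandas as pd

from .dataset import PAD, PeptideWindow, WindowDataset
from .errors import ValidationError

#: Row order of frequency matrices (by residue class, alanine ... valine).
RESIDUE_ORDER = "ARNDCEQGHILKMFPSTWYV"

#: Default hydrophobic set Ψ: the standard apolar side chains.
DEFAULT_HYDROPHOBIC = frozenset("AFILMPVW")


def _offset_labels(flank: int) -> list[str]:
    return [f"{o:+d}" if o else "0" for o in range(-flank, flank + 1)]


@dataclass(frozen=True)
class PositionalFrequencyMatrix:
    """Residue-by-offset occurrence counts for a set of windows."""

    counts: pd.DataFrame  # 20 rows (RESIDUE_ORDER) x (2*flank+1) offset columns
    flank: int
    n: int  # number of windows counted

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(RESIDUE_ORDER):
            raise ValidationError("frequency matrix rows must follow RESIDUE_ORDER")
        if list(self.counts.columns) != _offset_labels(self.flank):
            raise ValidationError("frequency matrix columns must be -flank..+flank")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative count in frequency matrix")
        if (self.counts.sum(axis=0).to_numpy() > self.n).any():
            raise ValidationError("column sum exceeds window count")

    def count(self, residue: str, offset: int) -> int:
        """Occurrences of ``residue`` at signed ``offset`` from the lysine."""
        col = f"{offset:+d}" if offset else "0"
        return int(self.counts.at[residue, col])

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self) -> str:
        out = self.counts.copy()
        out.index.name = "residue"
        return out.to_csv(sep="\t")

    @classmethod
    def from_tsv(cls, text: str, n: int | None = None) -> "PositionalFrequencyMatrix":
        import io

        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
        df.columns = [str(c) for c in df.columns]
        flank = (df.shape[1] - 1) // 2
        if n is None:
            n = int(df.sum(axis=0).max())
        return cls(df.astype(int), flank, n)


def positional_frequency(dataset: WindowDataset) -> PositionalFrequencyMatrix:
    """Count residues at every offset across all windows; 'X' not counted."""
    if len(dataset) == 0:
        raise ValidationError("cannot tabulate an empty dataset")
    flank = dataset.flank
    width = 2 * flank + 1
    counts = np.zeros((len(RESIDUE_ORDER), width), dtype=int)
    row = {r: i for i, r in enumerate(RESIDUE_ORDER)}
    for w in dataset:
        for j, ch in enumerate(w.peptide):
            if ch == PAD:
                continue
            counts[row[ch], j] += 1
    df = pd.DataFrame(counts, index=list(RESIDUE_ORDER), columns=_offset_labels(flank))
    return PositionalFrequencyMatrix(df, flank, len(dataset))


@dataclass(frozen=True)
class ConsensusRule:
    """The ΨKXE rule: Ψ at -1, K at 0 (by window invariant), any at +1, E at +2."""

    hydrophobic: FrozenSet[str] = DEFAULT_HYDROPHOBIC

    def __post_init__(self) -> None:
        bad = set(self.hydrophobic) - set(RESIDUE_ORDER)
        if bad:
            raise ValidationError(f"non-residue symbols in hydrophobic set: {bad}")


def matches_consensus(window: PeptideWindow, rule: ConsensusRule = ConsensusRule()) -> bool:
    """True iff the window fits ΨKXE (decided only by offsets -1 and +2)."""
    if window.flank < 2:
        raise ValidationError("consensus matching needs flank >= 2")
    return (
        window.residue_at(-1) in rule.hydrophobic
        and window.residue_at(+2) == "E"
    )


def consensus_fraction(
    dataset: WindowDataset, rule: ConsensusRule = ConsensusRule()
) -> float:
    """Fraction of windows matching the consensus rule."""
    if len(dataset) == 0:
        raise ValidationError("cannot compute a fraction over an empty dataset")
    return sum(matches_consensus(w, rule) for w in dataset) / len(dataset)


def frequency_report(
    pos_matrix: PositionalFrequencyMatrix,
    neg_matrix: PositionalFrequencyMatrix,
) -> dict[str, pd.DataFrame]:
    """Side-by-side composition tables for modified vs unmodified windows.

    Returns absolute counts and per-column relative frequencies (each
    column normalized by its own occupancy, so padded edge columns remain
    comparable), keyed ``positive_counts`` / ``negative_counts`` /
    ``positive_freq`` / ``negative_freq`` — plot-ready.
    """
    if pos_matrix.flank != neg_matrix.flank:
        raise ValidationError(
            f"flank mismatch: {pos_matrix.flank} vs {neg_matrix.flank}"
        )

    def rel(m: PositionalFrequencyMatrix) -> pd.DataFrame:
        sums = m.counts.sum(axis=0).replace(0, 1)
        return m.counts / sums

    return {
        "positive_counts": pos_matrix.counts.copy(),
        "negative_counts": neg_matrix.counts.copy(),
        "positive_freq": rel(pos_matrix),
        "negative_freq": rel(neg_matrix),
    }
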