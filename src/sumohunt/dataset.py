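"""Labeled lysine-window datasets.

Every lysine in a protein is a candidate SUMOylation site.  A dataset row is
a peptide *window* of length ``2*flank + 1`` centered on a lysine, labeled
positive (experimentally modified) or negative (assumed unmodified).  Windows
that overhang a protein terminus are padded with ``'X'`` rather than dropped,
so annotated sites near protein ends stay usable.

Positions in all external files are 1-based; internal string offsets are
0-based.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AnnotationError, BalanceError, ParseError, WindowError

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
PAD = "X"

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
# Ambiguity/rare codes collapsed to the pad symbol on input.
_NONSTANDARD = {"B": PAD, "Z": PAD, "U": PAD, "O": PAD, "J": PAD, "*": ""}


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate site: protein accession, 1-based lysine position, status."""

    accession: str
    position: int
    modified: bool

    def __post_init__(self) -> None:
        if self.position < 1:
            raise AnnotationError(
                f"{self.accession}: position {self.position} is not 1-based"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """A lysine-centered peptide with its label and provenance."""

    peptide: str
    flank: int
    label: str
    accession: str = ""
    position: int = 0

    def __post_init__(self) -> None:
        if len(self.peptide) != 2 * self.flank + 1:
            raise WindowError(
                f"window {self.peptide!r}: length {len(self.peptide)} != "
                f"{2 * self.flank + 1}"
            )
        if self.peptide[self.flank] != "K":
            raise WindowError(f"window {self.peptide!r}: center is not K")
        if self.label not in (POSITIVE, NEGATIVE):
            raise WindowError(f"bad label {self.label!r}")

    def residue_at(self, offset: int) -> str:
        """Residue at signed offset from the center (offset 0 is the lysine)."""
        return self.peptide[self.flank + offset]


@dataclass(frozen=True)
class WindowDataset:
    """An ordered collection of windows sharing one flank size."""

    windows: tuple[PeptideWindow, ...]
    flank: int
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.windows:
            if w.flank != self.flank:
                raise WindowError(
                    f"window flank {w.flank} != dataset flank {self.flank}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[PeptideWindow]:
        return iter(self.windows)

    @property
    def n_positive(self) -> int:
        return sum(w.label == POSITIVE for w in self.windows)

    @property
    def n_negative(self) -> int:
        return len(self.windows) - self.n_positive

    def to_tsv(self) -> str:
        lines = ["peptide\tlabel\taccession\tposition"]
        lines += [
            f"{w.peptide}\t{w.label}\t{w.accession}\t{w.position}"
            for w in self.windows
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "WindowDataset":
        rows = [ln for ln in text.splitlines() if ln.strip()]
        if not rows or rows[0].split("\t")[0] != "peptide":
            raise ParseError("window TSV must start with a 'peptide ...' header")
        windows = []
        for i, ln in enumerate(rows[1:], start=2):
            parts = ln.split("\t")
            if len(parts) != 4:
                raise ParseError(f"line {i}: expected 4 tab-separated fields")
            pep, label, acc, pos = parts
            windows.append(
                PeptideWindow(pep, len(pep) // 2, label, acc, int(pos))
            )
        if not windows:
            raise ParseError("window TSV has no data rows")
        return cls(tuple(windows), windows[0].flank)


def sanitize_sequence(sequence: str, accession: str = "") -> str:
    """Uppercase and map non-standard residue codes (B, Z, U, O, J) to 'X'."""
    seq = sequence.upper()
    out = []
    warned = set()
    for ch in seq:
        if ch in STANDARD_RESIDUES or ch == PAD:
            out.append(ch)
        elif ch in _NONSTANDARD:
            if ch not in warned and ch != "*":
                log.warning("%s: non-standard residue %r mapped to X", accession, ch)
                warned.add(ch)
            out.append(_NONSTANDARD[ch])
        else:
            raise ParseError(f"{accession}: invalid residue character {ch!r}")
    return "".join(out)


def read_fasta(source) -> dict[str, str]:
    """Read protein sequences from a FASTA path or handle.

    Returns accession -> sanitized sequence, in file order.
    """
    if isinstance(source, str):
        handle = open(source)
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        handle = source
    else:
        raise ParseError(f"cannot read FASTA from {type(source).__name__}")
    try:
        with handle if handle is not source else io.StringIO(handle.read()) as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    except ValueError as exc:
        raise ParseError(f"malformed FASTA: {exc}") from exc
    if not records:
        raise ParseError("FASTA input contains no records")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ParseError(f"duplicate FASTA accession {rec.id!r}")
        seqs[rec.id] = sanitize_sequence(str(rec.seq), rec.id)
    return seqs


def read_sites(text: str) -> list[SiteAnnotation]:
    """Parse a sites file: tab-separated ``accession  position  status``.

    ``status`` is ``modified`` or ``unmodified``; positions are 1-based.
    """
    annotations = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(
                f"sites line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        acc, pos_s, status = (p.strip() for p in parts)
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ParseError(
                f"sites line {lineno}: position {pos_s!r} is not an integer"
            ) from exc
        if status not in ("modified", "unmodified"):
            raise ParseError(f"sites line {lineno}: unknown status {status!r}")
        annotations.append(SiteAnnotation(acc, pos, status == "modified"))
    return annotations


def label_lysines(
    sequence: str,
    modified_positions: Iterable[int],
    accession: str = "",
) -> list[SiteAnnotation]:
    """Annotate every lysine in ``sequence``.

    Lysines at the given (1-based) positions are positive; every other
    lysine is assumed unmodified and becomes a negative.  A position
    reported both modified and unmodified upstream of this call must be
    resolved to modified by the caller (see :func:`resolve_conflicts`).
    """
    modified = set(modified_positions)
    for pos in modified:
        if pos < 1 or pos > len(sequence) or sequence[pos - 1] != "K":
            raise AnnotationError(
                f"{accession}: modified position {pos} is not a lysine"
            )
    return [
        SiteAnnotation(accession, i + 1, (i + 1) in modified)
        for i, ch in enumerate(sequence)
        if ch == "K"
    ]


def resolve_conflicts(annotations: Sequence[SiteAnnotation]) -> list[SiteAnnotation]:
    """Collapse duplicate (accession, position) records; modified wins."""
    best: dict[tuple[str, int], bool] = {}
    order: list[tuple[str, int]] = []
    for ann in annotations:
        key = (ann.accession, ann.position)
        if key not in best:
            best[key] = ann.modified
            order.append(key)
        else:
            best[key] = best[key] or ann.modified
    return [SiteAnnotation(acc, pos, best[(acc, pos)]) for acc, pos in order]


def extract_window(sequence: str, position: int, flank: int) -> str:
    """The ``2*flank+1``-mer centered at 1-based ``position``.

    Pads with 'X' where the window overhangs either terminus.
    """
    if position < 1 or position > len(sequence):
        raise WindowError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] != "K":
        raise WindowError(f"position {position}: residue {sequence[position - 1]!r} is not K")
    center = position - 1
    lo, hi = center - flank, center + flank + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(sequence))
    return PAD * left_pad + sequence[max(lo, 0) : min(hi, len(sequence))] + PAD * right_pad


def build_windows(
    sequences: Mapping[str, str],
    annotations: Sequence[SiteAnnotation],
    flank: int,
) -> WindowDataset:
    """Extract one labeled window per annotation, in annotation order."""
    annotations = resolve_conflicts(annotations)
    windows = []
    for ann in annotations:
        if ann.accession not in sequences:
            raise AnnotationError(f"unknown accession {ann.accession!r}")
        pep = extract_window(sequences[ann.accession], ann.position, flank)
        windows.append(
            PeptideWindow(
                pep, flank, POSITIVE if ann.modified else NEGATIVE,
                ann.accession, ann.position,
            )
        )
    return WindowDataset(tuple(windows), flank)


def deduplicate(dataset: WindowDataset) -> WindowDataset:
    """Collapse exact-duplicate peptide strings.

    The first occurrence's provenance is kept and input order is otherwise
    preserved.  If duplicates disagree on the label, the retained window is
    positive: a peptide reported both modified and unmodified is considered
    modified.
    """
    index: dict[str, int] = {}
    kept: list[PeptideWindow] = []
    for w in dataset.windows:
        if w.peptide not in index:
            index[w.peptide] = len(kept)
            kept.append(w)
        elif w.label == POSITIVE:
            i = index[w.peptide]
            if kept[i].label != POSITIVE:
                kept[i] = replace(kept[i], label=POSITIVE)
    return WindowDataset(tuple(kept), dataset.flank, dict(dataset.provenance))


def balance(dataset: WindowDataset, seed: int) -> WindowDataset:
    """Equalize class counts by down-sampling negatives.

    All positives are retained; a seeded uniform sample (without
    replacement) of negatives of equal count is kept.  Original window
    order is preserved among the retained windows and the seed is recorded
    in the dataset provenance.
    """
    pos_idx = [i for i, w in enumerate(dataset.windows) if w.label == POSITIVE]
    neg_idx = [i for i, w in enumerate(dataset.windows) if w.label == NEGATIVE]
    if len(neg_idx) < len(pos_idx):
        raise BalanceError(
            f"cannot balance: {len(neg_idx)} negatives < {len(pos_idx)} positives"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(neg_idx), size=len(pos_idx), replace=False).tolist())
    keep = set(pos_idx) | {neg_idx[j] for j in chosen}
    windows = tuple(w for i, w in enumerate(dataset.windows) if i in keep)
    prov = dict(dataset.provenance)
    prov["balance_seed"] = seed
    return WindowDataset(windows, dataset.flank, prov)


def trim(dataset: WindowDataset, flank: int) -> WindowDataset:
    """Re-cut every window to a narrower flank (same centers, same labels)."""
    if flank > dataset.flank:
        raise WindowError(f"cannot widen windows from flank {dataset.flank} to {flank}")
    if flank == dataset.flank:
        return dataset
    cut = dataset.flank - flank
    windows = tuple(
        PeptideWindow(
            w.peptide[cut : len(w.peptide) - cut], flank, w.label, w.accession, w.position
        )
        for w in dataset.windows
    )
    return WindowDataset(windows, flank, dict(dataset.provenance))
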