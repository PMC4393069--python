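"""Physicochemical property scales in AAIndex1 format.

A *property scale* maps each of the 20 standard amino acids to a real
coefficient (hydropathy, polarity, bulkiness, ...).  The predictor encodes
every window position with a fixed, ordered table of 16 such scales, so the
table's order is part of the feature-vector contract and must be stable.

The AAIndex1 flat-file layout places the 20 coefficients of the ``I`` record
in two rows of ten, column-paired as A/L, R/K, N/M, D/F, C/P, Q/S, E/T, G/W,
H/Y, I/V: the first row carries A R N D C Q E G H I, the second L K M F P S
T W Y V.

The packaged file mixes published scale values with synthetic surrogate
entries (marked in their description lines) for scales whose authentic
coefficients could not be bundled; the surrogates are format-correct and
carry the table's accessions, and nothing downstream depends on specific
coefficient values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

from .errors import DataError, EncodingError, ParseError, ValidationError

#: Canonical AAIndex residue order (first ten = I-record row 1, last ten = row 2).
AAINDEX_RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Padding symbol used for window positions beyond a protein terminus.
PAD_SYMBOL = "X"

_PACKAGED_FILE = "aaindex16_synthetic.txt"

#: Accessions of the 16 scales used by the predictor, in fixed table order.
PROPERTY_ACCESSIONS = (
    "PRAM900101",  # hydrophobicity
    "GRAR740102",  # polarity
    "ZIMJ680102",  # bulkiness
    "KYTJ820101",  # hydropathy index
    "RADA880106",  # accessible surface area
    "CHOC760101",  # residue accessible surface area in tripeptide
    "JANJ780102",  # percentage of buried residues
    "HUTJ700103",  # entropy of formation
    "KRIW790103",  # side-chain volume
    "TAKK010101",  # side-chain contribution to stability
    "ZHOH040103",  # buriability
    "HOPT810101",  # hydrophilicity value
    "FASG760101",  # molecular weight
    "BULH740101",  # transfer free energy to surface
    "CHAM810101",  # steric parameter
    "ZIMJ680104",  # isoelectric point
)


@dataclass(frozen=True)
class PropertyScale:
    """One amino-acid property scale.

    Parameters
    ----------
    accession
        AAIndex identifier, e.g. ``"PRAM900101"``.
    description
        Free-text description from the ``D`` record.
    coefficients
        Mapping from each of the 20 one-letter residue codes to a finite
        real coefficient, in scale-specific units.
    """

    accession: str
    description: str
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.coefficients)
        if keys != set(AAINDEX_RESIDUE_ORDER):
            raise ValidationError(
                f"{self.accession}: expected coefficients for the 20 standard "
                f"residues, got {len(keys)} keys"
            )
        for res, val in self.coefficients.items():
            if not math.isfinite(val):
                raise ValidationError(
                    f"{self.accession}: non-finite coefficient for residue {res}"
                )

    @property
    def mean(self) -> float:
        """Unweighted mean coefficient; the encoding of the 'X' pad symbol."""
        return sum(self.coefficients.values()) / 20.0


@dataclass(frozen=True)
class PropertyTable:
    """An ordered collection of property scales.

    Feature ordering downstream depends on the scale order, which is
    therefore fixed at construction and never re-sorted.
    """

    scales: tuple[PropertyScale, ...]

    def __post_init__(self) -> None:
        accs = [s.accession for s in self.scales]
        if len(set(accs)) != len(accs):
            raise ValidationError("duplicate accessions in property table")

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self) -> Iterator[PropertyScale]:
        return iter(self.scales)

    def __getitem__(self, index: int) -> PropertyScale:
        return self.scales[index]

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(s.accession for s in self.scales)

    def standardized(self) -> "PropertyTable":
        """Z-score every scale across the 20 residues (mean 0, sd 1).

        Raw coefficients are the default everywhere; tree-based models are
        insensitive to monotone per-feature rescaling, so this switch
        exists for interoperability with scale-sensitive consumers.
        """
        scales = []
        for s in self.scales:
            mu = s.mean
            var = sum((v - mu) ** 2 for v in s.coefficients.values()) / 20.0
            sd = math.sqrt(var)
            if sd == 0:
                raise ValidationError(f"{s.accession}: constant scale cannot be standardized")
            scales.append(
                PropertyScale(
                    s.accession,
                    s.description,
                    {r: (v - mu) / sd for r, v in s.coefficients.items()},
                )
            )
        return PropertyTable(tuple(scales))

    def to_json(self) -> str:
        """Serialize for provenance; ``from_json`` round-trips exactly."""
        doc = [
            {
                "accession": s.accession,
                "description": s.description,
                "coefficients": {r: s.coefficients[r] for r in AAINDEX_RESIDUE_ORDER},
            }
            for s in self.scales
        ]
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PropertyTable":
        doc = json.loads(text)
        return cls(
            tuple(
                PropertyScale(e["accession"], e["description"], dict(e["coefficients"]))
                for e in doc
            )
        )


def parse_aaindex1(text: str) -> list[PropertyScale]:
    """Parse AAIndex1 flat-file content into property scales.

    Only the ``H`` (accession), ``D`` (description) and ``I`` (coefficient)
    records are interpreted; other record types are tolerated and skipped.
    ``NA`` coefficients are rejected: the encoder requires a complete scale.
    """
    scales: list[PropertyScale] = []
    accession = ""
    description_parts: list[str] = []
    values: list[float] = []
    in_i = False
    seen_entry = False

    def finish_entry() -> None:
        nonlocal accession, description_parts, values, in_i
        if not accession:
            raise ParseError("AAIndex1 entry terminated without an H record")
        if len(values) != 20:
            raise ValidationError(
                f"{accession}: I record carries {len(values)} values, expected 20"
            )
        row1, row2 = values[:10], values[10:]
        coeffs = dict(zip(AAINDEX_RESIDUE_ORDER[:10], row1))
        coeffs.update(zip(AAINDEX_RESIDUE_ORDER[10:], row2))
        scales.append(
            PropertyScale(accession, " ".join(description_parts).strip(), coeffs)
        )
        accession, description_parts, values, in_i = "", [], [], False

    for raw in text.splitlines():
        if not raw.strip():
            continue
        if raw.startswith("//"):
            finish_entry()
            seen_entry = True
            continue
        tag, body = raw[:1], raw[2:] if len(raw) > 2 else ""
        if tag == "H":
            if accession:
                raise ParseError(f"entry {accession}: second H record before '//'")
            accession = body.strip()
            if not accession:
                raise ParseError("H record with empty accession")
            in_i = False
        elif tag == "D":
            description_parts.append(body.strip())
            in_i = False
        elif tag == "I":
            in_i = True  # header line with the A/L ... I/V column pairs
        elif tag == " " and in_i:
            for tok in raw.split():
                if tok.upper() == "NA":
                    raise ValidationError(
                        f"{accession or '<unknown>'}: 'NA' coefficient not allowed"
                    )
                try:
                    values.append(float(tok))
                except ValueError as exc:
                    raise ParseError(
                        f"{accession or '<unknown>'}: bad coefficient {tok!r}"
                    ) from exc
        else:
            in_i = False  # other record types (R, A, T, J, C, ...) are skipped
    if accession:
        raise ParseError(f"entry {accession}: missing terminating '//'")
    if not seen_entry:
        raise ParseError("no AAIndex1 entries found")
    return scales


def serialize_aaindex1(scales: list[PropertyScale]) -> str:
    """Write scales back to AAIndex1 flat-file text (parse round-trips)."""
    chunks = []
    header = "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
    for s in scales:
        row1 = " ".join(f"{s.coefficients[r]!r:>9}" for r in AAINDEX_RESIDUE_ORDER[:10])
        row2 = " ".join(f"{s.coefficients[r]!r:>9}" for r in AAINDEX_RESIDUE_ORDER[10:])
        chunks.append(
            f"H {s.accession}\nD {s.description}\n{header}\n  {row1}\n  {row2}\n//"
        )
    return "\n".join(chunks) + "\n"


def load_property_table() -> PropertyTable:
    """Load the packaged 16-scale table used for window encoding.

    Returns the scales in the fixed table order (``PRAM900101`` first,
    ``ZIMJ680104`` last).  Raises :class:`DataError` if the packaged file is
    missing or does not contain exactly the expected accessions in order.
    """
    try:
        text = (
            resources.files("sumohunt").joinpath("data", _PACKAGED_FILE).read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise DataError(f"packaged property file {_PACKAGED_FILE} missing") from exc
    scales = parse_aaindex1(text)
    table = PropertyTable(tuple(scales))
    if table.accessions != PROPERTY_ACCESSIONS:
        raise DataError(
            "packaged property file corrupt: accession list does not match "
            "the expected 16-scale table"
        )
    return table


def residue_value(table: PropertyTable, scale_index: int, residue: str) -> float:
    """Coefficient of ``residue`` under scale ``scale_index`` of ``table``.

    The pad symbol ``'X'`` encodes as the unweighted mean of the scale's 20
    coefficients, which keeps feature vectors fully populated for windows
    that overhang a protein terminus.
    """
    if not 0 <= scale_index < len(table):
        raise EncodingError(f"scale index {scale_index} out of range")
    scale = table[scale_index]
    if residue == PAD_SYMBOL:
        return scale.mean
    try:
        return scale.coefficients[residue]
    except KeyError as exc:
        raise EncodingError(f"unknown residue {residue!r}") from exc
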