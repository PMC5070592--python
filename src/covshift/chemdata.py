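"""Molecule tables, fingerprints, assay labeling and temporal splitting.

The raw unit of data is a :class:`MoleculeRecord` (id, SMILES, assay value,
registration date). Records are featurized into fixed-length binary
fingerprints, binarized into active/inactive classes by per-assay cutoff
rules with a discard band in between, and split into master training and
prediction sets by registration date (time-split validation).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "Fingerprint",
    "AssayCutoffs",
    "LabeledInstance",
    "read_molecule_table",
    "write_labeled_table",
    "compute_fingerprint",
    "fingerprint_matrix",
    "tanimoto",
    "assign_label",
    "label_records",
    "temporal_split",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with its assay readout and registration date.

    ``smiles`` may alternatively hold a hex-encoded bit string when the
    record comes from the fingerprint-drift simulator (scheme ``"hex"``).
    """

    id: str
    smiles: str
    assay_value: float
    registration_date: date

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"record {self.id!r}: empty SMILES")
        if not math.isfinite(self.assay_value):
            raise ValueError(f"record {self.id!r}: non-finite assay value")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary feature vector for one molecule."""

    bits: np.ndarray  # uint8 vector of 0/1
    scheme: str

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def __eq__(self, other: object) -> bool:  # array field needs explicit eq
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.scheme == other.scheme and np.array_equal(self.bits, other.bits)


Direction = Literal["<", ">"]


@dataclass(frozen=True)
class AssayCutoffs:
    """Binarization rule for one assay.

    ``positive_rule`` and ``negative_rule`` are (threshold, direction)
    pairs using strict inequalities; e.g. hERG actives are IC50 < 10 uM and
    inactives IC50 > 15 uM. Values satisfying neither rule fall in the
    discard band and are excluded, reducing label noise near the cutoffs.
    Values and thresholds are compared in the unit the assay declares; no
    conversion is attempted.
    """

    assay_name: str
    positive_threshold: float
    positive_direction: Direction
    negative_threshold: float
    negative_direction: Direction

    def __post_init__(self) -> None:
        for d in (self.positive_direction, self.negative_direction):
            if d not in ("<", ">"):
                raise ValueError(f"direction must be '<' or '>', got {d!r}")
        # the two regions must not overlap
        lo, hi = sorted([self.positive_threshold, self.negative_threshold])
        pos_low = self.positive_direction == "<"
        neg_low = self.negative_direction == "<"
        if pos_low == neg_low:
            raise ValueError(
                f"{self.assay_name}: positive and negative rules point the same "
                "way; regions would overlap"
            )
        if pos_low and self.positive_threshold > self.negative_threshold:
            raise ValueError(f"{self.assay_name}: rules overlap")
        if neg_low and self.negative_threshold > self.positive_threshold:
            raise ValueError(f"{self.assay_name}: rules overlap")
        del lo, hi


@dataclass(frozen=True)
class LabeledInstance:
    """A featurized, non-discarded record ready for a classifier."""

    features: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


# ---------------------------------------------------------------------------
# I/O


def _parse_date(raw: object) -> date:
    if isinstance(raw, datetime):
        return raw.date()
    if isinstance(raw, date):
        return raw
    ts = pd.Timestamp(str(raw))
    if pd.isna(ts):
        raise ValueError(f"unparseable date {raw!r}")
    return ts.date()


def read_molecule_table(
    path: str,
    column_map: Mapping[str, str],
    sep: str | None = None,
) -> list[MoleculeRecord]:
    """Read a delimited molecule table into records.

    ``column_map`` maps the logical names ``id``, ``smiles``, ``value``,
    ``date`` to the header names in the file. The delimiter is sniffed
    from the extension (``.tsv`` → tab, otherwise comma) unless given.
    Rows whose value or date fails to parse are skipped with a warning;
    the skip count is logged. Row order is preserved.
    """
    required = {"id", "smiles", "value", "date"}
    missing = required - set(column_map)
    if missing:
        raise KeyError(f"column_map missing entries for {sorted(missing)}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".smi", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for logical, name in column_map.items():
        if name not in df.columns:
            raise KeyError(
                f"required column {name!r} (for {logical!r}) not found in {path}"
            )
    records: list[MoleculeRecord] = []
    n_skipped = 0
    for row_idx, row in df.iterrows():
        rid = str(row[column_map["id"]])
        try:
            value = float(row[column_map["value"]])
            if not math.isfinite(value):
                raise ValueError("non-finite assay value")
            when = _parse_date(row[column_map["date"]])
            rec = MoleculeRecord(
                id=rid,
                smiles=str(row[column_map["smiles"]]),
                assay_value=value,
                registration_date=when,
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping row %s (id=%r): %s", row_idx, rid, exc)
            continue
        records.append(rec)
    logger.info(
        "read %d records from %s (%d rows skipped)", len(records), path, n_skipped
    )
    return records


def write_labeled_table(
    path: str,
    records: Sequence[MoleculeRecord],
    labels: Sequence[str],
) -> None:
    """Write id, smiles, value, date, label as CSV."""
    if len(records) != len(labels):
        raise ValueError("records and labels must align")
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "value": [r.assay_value for r in records],
            "date": [r.registration_date.isoformat() for r in records],
            "label": list(labels),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fingerprints


def _hex_to_bits(hex_string: str, n_bits: int) -> np.ndarray:
    n_bytes = (n_bits + 7) // 8
    raw = bytes.fromhex(hex_string)
    if len(raw) != n_bytes:
        raise ValueError(
            f"hex string encodes {len(raw)} bytes, expected {n_bytes} for "
            f"{n_bits} bits"
        )
    bits = np.unpackbits(np.frombuffer(raw, dtype=np.uint8))[:n_bits]
    return bits.astype(np.uint8)


def bits_to_hex(bits: np.ndarray) -> str:
    """Inverse of the ``"hex"`` fingerprint scheme (pads to whole bytes)."""
    arr = np.asarray(bits, dtype=np.uint8)
    return np.packbits(arr).tobytes().hex()


def compute_fingerprint(
    smiles: str,
    n_bits: int = 2048,
    scheme: str = "path",
    mol_id: str | None = None,
) -> Fingerprint:
    """Featurize a SMILES string as a binary fingerprint.

    Schemes: ``"path"`` (hashed linear atom/bond paths, the open analogue
    of commercial path fingerprints), ``"morgan"`` (circular, radius 2),
    ``"maccs"`` (166 structural keys; ``n_bits`` ignored), and ``"hex"``
    (pass-through: ``smiles`` holds a hex-encoded bit vector, used by the
    synthetic simulators).

    Deterministic: the same input and parameters always yield the same
    bit vector. Unparseable SMILES raises ``ValueError`` naming the input.
    """
    who = mol_id if mol_id is not None else smiles
    if scheme == "hex":
        return Fingerprint(bits=_hex_to_bits(smiles, n_bits), scheme=scheme)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES for {who!r}: {smiles!r}")
    if scheme == "path":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
        bv = gen.GetFingerprint(mol)
    elif scheme == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        bv = gen.GetFingerprint(mol)
    elif scheme == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
    else:
        raise ValueError(f"unknown fingerprint scheme {scheme!r}")
    bits = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, scheme=scheme)


def fingerprint_matrix(
    records: Sequence[MoleculeRecord],
    n_bits: int = 2048,
    scheme: str = "path",
) -> np.ndarray:
    """Stack record fingerprints into an (n, n_bits) float array."""
    rows = [
        compute_fingerprint(r.smiles, n_bits=n_bits, scheme=scheme, mol_id=r.id).bits
        for r in records
    ]
    return np.asarray(rows, dtype=float)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b| of two fingerprints.

    Symmetric, in [0, 1], and 1 exactly when the (non-empty) on-bit sets
    coincide. A pair of all-zero fingerprints has an empty union; that
    degenerate case returns 0 with a warning rather than NaN.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.sum((a.bits & b.bits) != 0))
    union = int(np.sum((a.bits | b.bits) != 0))
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; returning 0")
        return 0.0
    return inter / union


# ---------------------------------------------------------------------------
# Labels


def assign_label(value: float, cutoffs: AssayCutoffs) -> str:
    """Classify an assay value as ``"positive"``, ``"negative"`` or ``"discard"``.

    Both rules use strict inequalities, so a value exactly on a threshold
    lands in the discard band.
    """
    if not math.isfinite(value):
        raise ValueError("assay value must be finite")

    def holds(threshold: float, direction: Direction) -> bool:
        return value < threshold if direction == "<" else value > threshold

    pos = holds(cutoffs.positive_threshold, cutoffs.positive_direction)
    neg = holds(cutoffs.negative_threshold, cutoffs.negative_direction)
    if pos and neg:  # impossible for valid cutoffs, guard anyway
        raise AssertionError("cutoff regions overlap")
    if pos:
        return "positive"
    if neg:
        return "negative"
    return "discard"


def label_records(
    records: Iterable[MoleculeRecord], cutoffs: AssayCutoffs
) -> tuple[list[MoleculeRecord], np.ndarray, int]:
    """Apply the cutoff rules, dropping the discard band.

    Returns the kept records, their binary labels (positive → 1), and the
    number of discarded records.
    """
    kept: list[MoleculeRecord] = []
    labels: list[int] = []
    n_discarded = 0
    for rec in records:
        lab = assign_label(rec.assay_value, cutoffs)
        if lab == "discard":
            n_discarded += 1
            continue
        kept.append(rec)
        labels.append(1 if lab == "positive" else 0)
    return kept, np.asarray(labels, dtype=int), n_discarded


# ---------------------------------------------------------------------------
# Temporal split


def temporal_split(
    records: Sequence[MoleculeRecord], train_fraction: float = 0.75
) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Split records by registration date into master train / prediction sets.

    Records are sorted ascending by date (ties broken by id, so the split
    is invariant to input order); the earliest ``floor(n * train_fraction)``
    form the master training set and the remainder, which postdates it,
    the master prediction set.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    for rec in records:
        if rec.registration_date is None:
            raise ValueError(f"record {rec.id!r} has no registration date")
    ordered = sorted(records, key=lambda r: (r.registration_date, r.id))
    n_train = int(math.floor(len(ordered) * train_fraction))
    return ordered[:n_train], ordered[n_train:]
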