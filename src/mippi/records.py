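"""Domain records and file I/O.

The atomic record is a :class:`MutationEvent`: one single-point missense
mutation on one protein, the partner protein it interacts with, and (when
known) the curated consequence of the mutation for that interaction.  Four
consequence classes are used throughout: ``disrupting``, ``decreasing``,
``no_effect`` and ``increasing``; every probability vector, class-weight
vector or confusion matrix in the package is indexed in that canonical
order.

File formats are deliberately plain: tab-separated tables with a header
row, standard FASTA, and a tab-separated interface-annotation table whose
residue lists use bracketed 1-based ranges (``[12-15,22]``).  All readers
ignore ``#`` comment lines and treat files as UTF-8.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


class LookupError_(KeyError):
    """An accession could not be resolved against the supplied FASTA."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class ImpactLabel(enum.Enum):
    """Consequence of a missense mutation for a specific interaction."""

    DISRUPTING = "disrupting"
    DECREASING = "decreasing"
    NO_EFFECT = "no_effect"
    INCREASING = "increasing"

    @classmethod
    def from_string(cls, text: str) -> "ImpactLabel":
        """Parse a label; case-insensitive, spaces and underscores interchangeable."""
        key = text.strip().lower().replace(" ", "_").replace("-", "_")
        for member in cls:
            if member.value == key:
                return member
        raise ValidationError(f"unknown impact label: {text!r}")

    def __str__(self) -> str:  # lossless round-trip
        return self.value


#: Canonical class order used for every class-indexed vector.
CLASS_ORDER: tuple[ImpactLabel, ...] = (
    ImpactLabel.DISRUPTING,
    ImpactLabel.DECREASING,
    ImpactLabel.NO_EFFECT,
    ImpactLabel.INCREASING,
)

#: Index of each label in :data:`CLASS_ORDER`.
CLASS_INDEX: dict[ImpactLabel, int] = {lab: i for i, lab in enumerate(CLASS_ORDER)}


class Origin(enum.Enum):
    """Provenance of a mutation event within the augmentation scheme."""

    ORIGINAL = "original"
    REVERSED = "reversed"
    NONMUTATED = "nonmutated"


@dataclass(frozen=True)
class MutationEvent:
    """One labeled single-point-mutation interaction event.

    ``position`` is 1-based, matching standard mutation notation
    (p.Asn26His means position 26).  ``mut_protein_seq`` is the
    *reference* (wild-type) full-length sequence of the mutated protein;
    the mutant form is obtained by substituting ``alt_aa`` at
    ``position``.
    """

    event_id: str
    mut_protein_id: str
    mut_protein_seq: str
    position: int
    ref_aa: str
    alt_aa: str
    partner_id: str
    partner_seq: str
    label: ImpactLabel | None = None
    origin: Origin = Origin.ORIGINAL

    def __post_init__(self) -> None:
        if not 1 <= self.position <= len(self.mut_protein_seq):
            raise ValidationError(
                f"event {self.event_id}: position {self.position} outside "
                f"sequence of length {len(self.mut_protein_seq)}"
            )
        if self.origin is Origin.ORIGINAL:
            found = self.mut_protein_seq[self.position - 1]
            if found != self.ref_aa:
                raise ValidationError(
                    f"event {self.event_id}: sequence has {found!r} at position "
                    f"{self.position}, expected ref_aa {self.ref_aa!r}"
                )
        if self.origin in (Origin.ORIGINAL, Origin.REVERSED):
            if self.ref_aa == self.alt_aa:
                raise ValidationError(
                    f"event {self.event_id}: ref_aa == alt_aa is only permitted "
                    f"for nonmutated pseudo-entries"
                )

    @property
    def mutant_seq(self) -> str:
        """Full-length mutant sequence (alt_aa substituted at position)."""
        i = self.position - 1
        return self.mut_protein_seq[:i] + self.alt_aa + self.mut_protein_seq[i + 1:]


@dataclass(frozen=True)
class InterfaceAnnotation:
    """Known interface residues (1-based) of one protein in one interaction."""

    protein_id: str
    interface_positions: frozenset[int]

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.interface_positions):
            raise ValidationError(
                f"{self.protein_id}: interface positions must be positive"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "event_id",
    "mut_protein_id",
    "position",
    "ref_aa",
    "alt_aa",
    "partner_id",
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an accession -> uppercase sequence mapping.

    The accession is the header token before the first whitespace.
    Duplicate accessions are an error.
    """
    mapping: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id
        if acc in mapping:
            raise FormatError(f"duplicate accession in FASTA: {acc}")
        mapping[acc] = str(record.seq).upper()
    return mapping


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_mutation_table(
    path: str | Path, fasta: str | Path | None = None
) -> list[MutationEvent]:
    """Read a mutation-event TSV into a list of events (file order preserved).

    Sequences come either from inline ``mut_protein_seq`` / ``partner_seq``
    columns or, when those are absent, from the FASTA keyed by
    ``mut_protein_id`` / ``partner_id``.
    """
    df = _read_table(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"mutation table {path}: missing column {col!r}")
    seqs: Mapping[str, str] = read_fasta(fasta) if fasta is not None else {}

    def resolve(row: pd.Series, seq_col: str, id_col: str) -> str:
        if seq_col in df.columns and row[seq_col]:
            return row[seq_col].upper()
        acc = row[id_col]
        if acc not in seqs:
            raise LookupError_(f"accession {acc!r} not found in FASTA")
        return seqs[acc]

    has_label = "label" in df.columns
    events: list[MutationEvent] = []
    for _, row in df.iterrows():
        label = None
        if has_label and row["label"]:
            label = ImpactLabel.from_string(row["label"])
        origin = Origin(row["origin"]) if "origin" in df.columns and row.get("origin") else Origin.ORIGINAL
        events.append(
            MutationEvent(
                event_id=row["event_id"],
                mut_protein_id=row["mut_protein_id"],
                mut_protein_seq=resolve(row, "mut_protein_seq", "mut_protein_id"),
                position=int(row["position"]),
                ref_aa=row["ref_aa"].upper(),
                alt_aa=row["alt_aa"].upper(),
                partner_id=row["partner_id"],
                partner_seq=resolve(row, "partner_seq", "partner_id"),
                label=label,
                origin=origin,
            )
        )
    return events


def write_mutation_table(events: Sequence[MutationEvent], path: str | Path) -> None:
    """Write events to a TSV with inline sequences (round-trips with the reader)."""
    rows = [
        {
            "event_id": e.event_id,
            "mut_protein_id": e.mut_protein_id,
            "position": e.position,
            "ref_aa": e.ref_aa,
            "alt_aa": e.alt_aa,
            "partner_id": e.partner_id,
            "mut_protein_seq": e.mut_protein_seq,
            "partner_seq": e.partner_seq,
            "label": str(e.label) if e.label is not None else "",
            "origin": e.origin.value,
        }
        for e in events
    ]
    cols = [
        "event_id", "mut_protein_id", "position", "ref_aa", "alt_aa",
        "partner_id", "mut_protein_seq", "partner_seq", "label", "origin",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


_RANGE_TOKEN = re.compile(r"^(\d+)(?:-(\d+))?$")


def expand_ranges(text: str) -> frozenset[int]:
    """Expand a bracketed 1-based range list like ``[12-15,22]`` to a position set."""
    text = text.strip()
    if not (text.startswith("[") and text.endswith("]")):
        raise FormatError(f"malformed range list: {text!r}")
    inner = text[1:-1].strip()
    if not inner:
        return frozenset()
    positions: set[int] = set()
    for token in inner.split(","):
        token = token.strip()
        m = _RANGE_TOKEN.match(token)
        if m is None:
            raise FormatError(f"malformed range token: {token!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise FormatError(f"malformed range token (empty range): {token!r}")
        positions.update(range(lo, hi + 1))
    return frozenset(positions)


def read_interface_annotations(path: str | Path) -> list[InterfaceAnnotation]:
    """Read an interface-annotation TSV.

    Expected columns: ``protein_a``, ``protein_b``, ``interface_a``,
    ``interface_b`` where the interface columns are bracketed range
    lists in each protein's own 1-based coordinates.  One annotation is
    produced per (row, protein).
    """
    df = _read_table(path)
    for col in ("protein_a", "protein_b", "interface_a", "interface_b"):
        if col not in df.columns:
            raise FormatError(f"interface table {path}: missing column {col!r}")
    annotations: list[InterfaceAnnotation] = []
    for _, row in df.iterrows():
        annotations.append(
            InterfaceAnnotation(row["protein_a"], expand_ranges(row["interface_a"]))
        )
        annotations.append(
            InterfaceAnnotation(row["protein_b"], expand_ranges(row["interface_b"]))
        )
    return annotations


def write_predictions(events, results, path: str | Path) -> None:
    """Write a prediction TSV: event_id, 4 class probabilities, label, confidence."""
    if len(events) != len(results):
        raise ValueError(
            f"length mismatch: {len(events)} events vs {len(results)} results"
        )
    prob_cols = [f"p_{lab.value}" for lab in CLASS_ORDER]
    rows = []
    for e, r in zip(events, results):
        row = {"event_id": e.event_id}
        for col, p in zip(prob_cols, r.probabilities):
            row[col] = f"{float(p):.6f}"
        row["predicted"] = str(r.predicted)
        row["confidence"] = f"{float(r.confidence):.6f}"
        rows.append(row)
    cols = ["event_id", *prob_cols, "predicted", "confidence"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read back a prediction TSV as a DataFrame (probabilities as floats)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df
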