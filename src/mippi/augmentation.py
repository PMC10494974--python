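"""Training-set augmentation: hypothetical reverse mutations and
nonmutated pseudo-entries.

Two rules expand a labeled training set:

* **Reverse mutation** — for ``decreasing``, ``no_effect`` and
  ``increasing`` entries, swap the roles of the wild-type and mutant
  forms (the mutant becomes the reference) and invert the direction of
  the annotated effect (increasing <-> decreasing, no_effect fixed).
  ``disrupting`` entries are excluded: a broken interaction has no
  biologically meaningful reverse.
* **Nonmutated entry** — for every entry, emit a pseudo-entry whose
  reference and "mutant" are the same wild-type sequence, labeled
  ``no_effect``; a model that never sees identical inputs cannot be
  trusted to call them inert.

Both rules apply to the training split only; validation and test data
are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .records import ImpactLabel, MutationEvent, Origin

#: Direction inversion under role swap; disrupting is ineligible.
REVERSE_LABEL_MAP = {
    ImpactLabel.INCREASING: ImpactLabel.DECREASING,
    ImpactLabel.DECREASING: ImpactLabel.INCREASING,
    ImpactLabel.NO_EFFECT: ImpactLabel.NO_EFFECT,
}


@dataclass(frozen=True)
class AugmentationReport:
    n_original: int
    n_reversed: int
    n_nonmutated: int

    @property
    def n_total(self) -> int:
        return self.n_original + self.n_reversed + self.n_nonmutated

    def to_dict(self) -> dict[str, int]:
        return {
            "n_original": self.n_original,
            "n_reversed": self.n_reversed,
            "n_nonmutated": self.n_nonmutated,
            "n_total": self.n_total,
        }


def reverse_entry(event: MutationEvent) -> MutationEvent | None:
    """Build the hypothetical reverse mutation of an original entry.

    Returns ``None`` for ``disrupting`` entries (excluded from the
    strategy).  The reversed entry stores the mutant full-length
    sequence as its reference, swaps ref/alt amino acids, and maps the
    label through :data:`REVERSE_LABEL_MAP`.  The partner is unchanged.
    """
    if event.origin is not Origin.ORIGINAL:
        raise ValueError("only original entries can be reversed")
    if event.label is None:
        raise ValueError(f"event {event.event_id}: cannot reverse an unlabeled entry")
    if event.label not in REVERSE_LABEL_MAP:
        return None
    return replace(
        event,
        event_id=f"{event.event_id}|rev",
        mut_protein_seq=event.mutant_seq,
        ref_aa=event.alt_aa,
        alt_aa=event.ref_aa,
        label=REVERSE_LABEL_MAP[event.label],
        origin=Origin.REVERSED,
    )


def nonmutated_entry(event: MutationEvent) -> MutationEvent:
    """Build the nonmutated pseudo-entry: alt := ref, label no_effect."""
    if event.origin is not Origin.ORIGINAL:
        raise ValueError("nonmutated entries are derived from originals only")
    return replace(
        event,
        event_id=f"{event.event_id}|nm",
        alt_aa=event.ref_aa,
        label=ImpactLabel.NO_EFFECT,
        origin=Origin.NONMUTATED,
    )


def augment_dataset(
    events: Sequence[MutationEvent],
) -> tuple[list[MutationEvent], AugmentationReport]:
    """Apply both augmentation rules to a list of original labeled events.

    Output order is deterministic: originals, then reversed entries in
    original order, then nonmutated entries in original order.
    Accidental duplicates between reversed and original entries are kept
    (counts are plain additive).
    """
    for e in events:
        if e.origin is not Origin.ORIGINAL:
            raise ValueError(f"event {e.event_id}: augmentation input must be original")
        if e.label is None:
            raise ValueError(f"event {e.event_id}: augmentation input must be labeled")
    reversed_entries = [r for r in (reverse_entry(e) for e in events) if r is not None]
    nonmutated_entries = [nonmutated_entry(e) for e in events]
    out = list(events) + reversed_entries + nonmutated_entries
    report = AugmentationReport(
        n_original=len(events),
        n_reversed=len(reversed_entries),
        n_nonmutated=len(nonmutated_entries),
    )
    return out, report
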