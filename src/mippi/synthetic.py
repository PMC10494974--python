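"""Synthetic mutation-event datasets with a planted, recoverable signal.

Real curated interaction-impact data cannot be redistributed, so tests
and desk-scale experiments run on generated events whose labels follow
a simple, fully known rule tying mutation chemistry to a partner motif:

* a fixed 6-residue motif may be planted in the partner sequence
  (``M = 1``); its location doubles as a pseudo-interface, giving the
  attention-interpretation pipeline a ground truth;
* ``dh`` is the Kyte-Doolittle hydropathy change of the substitution
  (alt minus ref);
* label = ``disrupting`` if M=1 and dh < -threshold; ``increasing`` if
  M=1 and dh > +threshold; ``decreasing`` if M=1 and |dh| <= threshold;
  ``no_effect`` if M=0 — then flipped to a uniformly random *other*
  label with probability ``noise_rate``.

The rule is deliberately partner-conditional: a model that ignores the
partner cannot separate ``no_effect`` from the three effect classes, so
removing the partner branch must cost accuracy, mirroring the behavior
of the real classifier on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import AA_ORDER
from .records import CLASS_ORDER, ImpactLabel, MutationEvent

#: Kyte-Doolittle hydropathy scale (embedded constant table).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


@dataclass
class GeneratorConfig:
    n_events: int = 1000
    class_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seq_len_range: tuple[int, int] = (60, 120)
    partner_len_range: tuple[int, int] = (60, 120)
    motif: str = "WWHKKW"
    hydropathy_threshold: float = 2.0
    noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.seq_len_range[0] < 51:
            raise ValueError("mutated-protein length must be at least 51")
        if len(self.motif) != 6:
            raise ValueError("motif must be 6 residues")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")


def hydropathy_delta(ref_aa: str, alt_aa: str) -> float:
    return KYTE_DOOLITTLE[alt_aa] - KYTE_DOOLITTLE[ref_aa]


def rule_label(ref_aa: str, alt_aa: str, motif_present: bool,
               threshold: float = 2.0) -> ImpactLabel:
    """The planted labeling rule, exposed for independent re-evaluation."""
    if not motif_present:
        return ImpactLabel.NO_EFFECT
    dh = hydropathy_delta(ref_aa, alt_aa)
    if dh < -threshold:
        return ImpactLabel.DISRUPTING
    if dh > threshold:
        return ImpactLabel.INCREASING
    return ImpactLabel.DECREASING


@dataclass(frozen=True)
class GroundTruth:
    """Rule inputs per event, for oracle checks and interpretation tests."""

    event_id: str
    motif_present: bool
    motif_start: int | None  # 1-based start in the partner, when planted
    dh: float
    clean_label: ImpactLabel


# substitution pools per rule branch, precomputed once per threshold
def _pair_pools(threshold: float):
    pools = {"disrupting": [], "increasing": [], "decreasing": []}
    for a in AA_ORDER:
        for b in AA_ORDER:
            if a == b:
                continue
            dh = hydropathy_delta(a, b)
            if dh < -threshold:
                pools["disrupting"].append((a, b))
            elif dh > threshold:
                pools["increasing"].append((a, b))
            else:
                pools["decreasing"].append((a, b))
    return pools


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[MutationEvent], list[GroundTruth]]:
    """Generate labeled events (deterministic from ``cfg.seed``).

    The target class of each event is drawn from ``class_probs``; the
    substitution and motif presence are then sampled to satisfy the rule,
    and the final label is re-derived from the rule itself (so with
    ``noise_rate = 0`` the labels are exactly rule-consistent).  With
    probability ``noise_rate`` the label is replaced by a uniformly
    random different class.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pools = _pair_pools(cfg.hydropathy_threshold)
    aa = np.array(list(AA_ORDER))
    events: list[MutationEvent] = []
    truths: list[GroundTruth] = []
    for i in range(cfg.n_events):
        target = CLASS_ORDER[rng.choice(4, p=cfg.class_probs)]
        motif_present = target is not ImpactLabel.NO_EFFECT

        if motif_present:
            pool = pools[target.value]
            ref_aa, alt_aa = pool[rng.integers(len(pool))]
        else:
            while True:
                ref_aa, alt_aa = (str(aa[rng.integers(20)]) for _ in range(2))
                if ref_aa != alt_aa:
                    break

        seq_len = int(rng.integers(cfg.seq_len_range[0], cfg.seq_len_range[1] + 1))
        position = int(rng.integers(1, seq_len + 1))
        seq = "".join(aa[rng.integers(0, 20, size=seq_len)])
        seq = seq[:position - 1] + ref_aa + seq[position:]

        partner_len = int(rng.integers(cfg.partner_len_range[0],
                                       cfg.partner_len_range[1] + 1))
        partner = "".join(aa[rng.integers(0, 20, size=partner_len)])
        motif_start = None
        if motif_present:
            start = int(rng.integers(0, partner_len - len(cfg.motif) + 1))
            partner = (partner[:start] + cfg.motif
                       + partner[start + len(cfg.motif):])
            motif_start = start + 1
        elif cfg.motif in partner:
            # scrub accidental motif occurrences so M=0 is exact
            partner = partner.replace(cfg.motif,
                                      cfg.motif[:-1] + ("A" if cfg.motif[-1] != "A" else "C"))

        clean = rule_label(ref_aa, alt_aa, motif_present, cfg.hydropathy_threshold)
        label = clean
        if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
            others = [lab for lab in CLASS_ORDER if lab is not clean]
            label = others[rng.integers(3)]

        event_id = f"syn-{i:05d}"
        events.append(MutationEvent(
            event_id=event_id,
            mut_protein_id=f"P{i:05d}",
            mut_protein_seq=seq,
            position=position,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            partner_id=f"Q{i:05d}",
            partner_seq=partner,
            label=label,
        ))
        truths.append(GroundTruth(
            event_id=event_id,
            motif_present=motif_present,
            motif_start=motif_start,
            dh=hydropathy_delta(ref_aa, alt_aa),
            clean_label=clean,
        ))
    return events, truths


def pseudo_interfaces(truths: Sequence[GroundTruth], motif_len: int = 6):
    """Interface annotations for the planted motif positions."""
    from .records import InterfaceAnnotation

    annotations = []
    for i, t in enumerate(truths):
        if t.motif_start is not None:
            positions = frozenset(range(t.motif_start, t.motif_start + motif_len))
            annotations.append(InterfaceAnnotation(f"Q{i:05d}", positions))
    return annotations


def make_paper_count_fixture() -> list[MutationEvent]:
    """Deterministic fixture mirroring the published dataset composition:
    16,451 events of which 5,452 are disrupting and 10,999 carry the
    three reversible labels (split 3,667 / 3,666 / 3,666 among
    decreasing, no_effect, increasing).  Sequences are minimal-length
    valid; only label structure matters here."""
    total = 16451
    n_disrupting = 5452
    n_reversible = total - n_disrupting  # 10,999
    base = n_reversible // 3
    counts = {
        ImpactLabel.DISRUPTING: n_disrupting,
        ImpactLabel.DECREASING: base + (n_reversible - 3 * base),
        ImpactLabel.NO_EFFECT: base,
        ImpactLabel.INCREASING: base,
    }
    seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLM"  # 51 residues
    partner = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    events: list[MutationEvent] = []
    i = 0
    for label, n in counts.items():
        for _ in range(n):
            events.append(MutationEvent(
                event_id=f"fix-{i:05d}",
                mut_protein_id=f"FP{i:05d}",
                mut_protein_seq=seq,
                position=26,
                ref_aa=seq[25],
                alt_aa="A" if seq[25] != "A" else "C",
                partner_id=f"FQ{i:05d}",
                partner_seq=partner,
                label=label,
            ))
            i += 1
    return events


def write_ground_truth(truths: Sequence[GroundTruth], path) -> None:
    payload = [
        {
            "event_id": t.event_id,
            "motif_present": t.motif_present,
            "motif_start": t.motif_start,
            "dh": t.dh,
            "clean_label": t.clean_label.value,
        }
        for t in truths
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
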