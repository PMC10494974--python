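"""SKEMPI v2 preprocessing and the reversal-consistency harness.

SKEMPI v2 tabulates binding-affinity changes upon mutation for
structurally characterized complexes.  The bridge keeps binary
complexes (exactly two chains) carrying a single point mutation with
both affinities parsed, computes the binding free-energy change

    ddG = R T ln(Kd_mut / Kd_wt),   R = 1.987e-3 kcal / (K mol),

and buckets entries at the -1 kcal/mol threshold (inclusive on the
stabilized side).  The reversal-consistency harness predicts each entry
in both directions (wild-type -> mutant and the role-swapped input) and
reports, per ddG bucket, the class distribution of both directions plus
the rate at which confident increasing/decreasing calls invert — a
model trained with reverse-mutation augmentation should invert far more
often than one trained without.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import CLASS_ORDER, ImpactLabel, MutationEvent, Origin

#: Gas constant in kcal per kelvin per mole.
R_KCAL = 1.987e-3
DEFAULT_TEMPERATURE = 298.0


@dataclass(frozen=True)
class SkempiEntry:
    pdb_id: str
    chains: tuple[str, str]
    mutation_chain: str
    wild_aa: str
    position: int
    mutant_aa: str
    kd_wt: float
    kd_mut: float
    temperature: float
    ddg: float


def compute_ddg(kd_wt: float, kd_mut: float, temperature: float) -> float:
    """Binding free-energy change R*T*ln(Kd_mut/Kd_wt) in kcal/mol."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive kelvin")
    return R_KCAL * temperature * math.log(kd_mut / kd_wt)


_TEMP_NUM = re.compile(r"([0-9]+(?:\.[0-9]+)?)")
_SINGLE_MUT = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([A-Z])$")


def _parse_temperature(text: str) -> tuple[float, bool]:
    """Extract the leading number from annotated strings like '298(assumed)';
    returns (kelvin, defaulted)."""
    m = _TEMP_NUM.search(str(text))
    if m is None:
        return DEFAULT_TEMPERATURE, True
    return float(m.group(1)), False


def _sniff_reader(path: str | Path):
    text = Path(path).read_text()
    first = text.splitlines()[0] if text else ""
    delim = ";" if first.count(";") >= first.count(",") and ";" in first else ","
    return csv.DictReader(text.splitlines(), delimiter=delim)


def filter_skempi(path_or_rows) -> tuple[list[SkempiEntry], dict]:
    """Filter SKEMPI v2 rows to computable binary single-point entries.

    Accepts a CSV path (comma or semicolon delimited) or an iterable of
    dict rows with the standard columns ``#Pdb`` (``PDB_CHAINS`` form
    like ``1CSE_E_I``), ``Mutation(s)_cleaned``, ``Affinity_wt_parsed``,
    ``Affinity_mut_parsed`` and ``Temperature``.  Keeps complexes with
    exactly two chains and one point mutation, both affinities parsed;
    duplicates are retained.  Returns the entries and a drop-count
    summary.
    """
    if isinstance(path_or_rows, (str, Path)):
        rows = list(_sniff_reader(path_or_rows))
    else:
        rows = [dict(r) for r in path_or_rows]
    counts = {
        "n_input": len(rows),
        "dropped_chains": 0,
        "dropped_multipoint": 0,
        "dropped_affinity": 0,
        "defaulted_temperature": 0,
    }
    entries: list[SkempiEntry] = []
    for row in rows:
        pdb_field = row.get("#Pdb") or row.get("Pdb") or ""
        parts = pdb_field.split("_")
        pdb_id, chain_groups = parts[0], parts[1:]
        chains = [c for group in chain_groups for c in group]
        if len(chains) != 2:
            counts["dropped_chains"] += 1
            continue
        mutations = str(row.get("Mutation(s)_cleaned", "")).split(",")
        if len(mutations) != 1 or not mutations[0].strip():
            counts["dropped_multipoint"] += 1
            continue
        m = _SINGLE_MUT.match(mutations[0].strip())
        if m is None:
            counts["dropped_multipoint"] += 1
            continue
        wild_aa, chain, pos, mutant_aa = m.groups()
        try:
            kd_wt = float(row.get("Affinity_wt_parsed", ""))
            kd_mut = float(row.get("Affinity_mut_parsed", ""))
        except (TypeError, ValueError):
            counts["dropped_affinity"] += 1
            continue
        if not (kd_wt > 0 and kd_mut > 0):
            counts["dropped_affinity"] += 1
            continue
        temperature, defaulted = _parse_temperature(row.get("Temperature", ""))
        if defaulted:
            counts["defaulted_temperature"] += 1
        entries.append(SkempiEntry(
            pdb_id=pdb_id,
            chains=(chains[0], chains[1]),
            mutation_chain=chain,
            wild_aa=wild_aa,
            position=int(pos),
            mutant_aa=mutant_aa,
            kd_wt=kd_wt,
            kd_mut=kd_mut,
            temperature=temperature,
            ddg=compute_ddg(kd_wt, kd_mut, temperature),
        ))
    return entries, counts


def bucket_by_ddg(
    entries: Sequence[SkempiEntry], threshold: float = -1.0
) -> tuple[list[SkempiEntry], list[SkempiEntry]]:
    """Partition entries into (ddG > threshold, ddG <= threshold)."""
    group_gt = [e for e in entries if e.ddg > threshold]
    group_le = [e for e in entries if e.ddg <= threshold]
    return group_gt, group_le


def entries_to_events(
    entries: Sequence[SkempiEntry], sequences: dict[str, str]
) -> list[MutationEvent]:
    """Convert filtered entries to mutation events using supplied chain
    sequences keyed ``PDBID_CHAIN`` (SEQRES-derived FASTA; no structure
    parsing happens here).  Entries whose sequences are missing or whose
    wild residue disagrees with the sequence are skipped."""
    events: list[MutationEvent] = []
    for i, entry in enumerate(entries):
        mut_key = f"{entry.pdb_id}_{entry.mutation_chain}"
        partner_chain = next(
            (c for c in entry.chains if c != entry.mutation_chain), None
        )
        if partner_chain is None:
            continue
        partner_key = f"{entry.pdb_id}_{partner_chain}"
        if mut_key not in sequences or partner_key not in sequences:
            continue
        seq = sequences[mut_key]
        if not (1 <= entry.position <= len(seq)):
            continue
        if seq[entry.position - 1] != entry.wild_aa:
            continue
        events.append(MutationEvent(
            event_id=f"skempi-{i}",
            mut_protein_id=mut_key,
            mut_protein_seq=seq,
            position=entry.position,
            ref_aa=entry.wild_aa,
            alt_aa=entry.mutant_aa,
            partner_id=partner_key,
            partner_seq=sequences[partner_key],
        ))
    return events


def swap_roles(event: MutationEvent) -> MutationEvent:
    """Present an event in the reverse direction (mutant as reference)."""
    return replace(
        event,
        event_id=f"{event.event_id}|swap",
        mut_protein_seq=event.mutant_seq,
        ref_aa=event.alt_aa,
        alt_aa=event.ref_aa,
        origin=Origin.REVERSED,
    )


_FLIP = {ImpactLabel.INCREASING: ImpactLabel.DECREASING,
         ImpactLabel.DECREASING: ImpactLabel.INCREASING}


def reversal_consistency(
    model,
    events: Sequence[MutationEvent],
    confidence: float = 0.5,
    pssm_source: str = "pseudo",
    seed: int = 0,
) -> dict:
    """Class distributions for original vs role-swapped inputs plus the
    flip rate.

    The flip rate is the fraction of original calls in
    {increasing, decreasing} with confidence >= ``confidence`` whose
    role-swapped prediction is the opposite member of the pair.
    """
    from .training import predict_events

    originals = predict_events(model, list(events), pssm_source, seed)
    swapped = predict_events(model, [swap_roles(e) for e in events],
                             pssm_source, seed)

    def distribution(results) -> dict[str, float]:
        counts = {lab.value: 0 for lab in CLASS_ORDER}
        for r in results:
            counts[r.predicted.value] += 1
        total = max(len(results), 1)
        return {k: v / total for k, v in counts.items()}

    n_confident = 0
    n_flipped = 0
    for orig, swap in zip(originals, swapped):
        if orig.predicted in _FLIP and orig.confidence >= confidence:
            n_confident += 1
            if swap.predicted is _FLIP[orig.predicted]:
                n_flipped += 1
    return {
        "original_distribution": distribution(originals),
        "swapped_distribution": distribution(swapped),
        "n_confident_directional": n_confident,
        "n_flipped": n_flipped,
        "flip_rate": n_flipped / n_confident if n_confident else 0.0,
    }


def bucketed_reversal_consistency(
    model,
    entries: Sequence[SkempiEntry],
    sequences: dict[str, str],
    threshold: float = -1.0,
    **kwargs,
) -> dict:
    """Reversal consistency reported separately per ddG bucket."""
    group_gt, group_le = bucket_by_ddg(entries, threshold)
    return {
        "ddg_gt_threshold": reversal_consistency(
            model, entries_to_events(group_gt, sequences), **kwargs),
        "ddg_le_threshold": reversal_consistency(
            model, entries_to_events(group_le, sequences), **kwargs),
        "threshold": threshold,
        "n_gt": len(group_gt),
        "n_le": len(group_le),
    }
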