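"""Attention-weight interpretation: do the partner residues the model
attends to coincide with the physical binding interface?

The last self-attention layer of the partner branch yields, per head,
an L x L weight matrix over non-padded residues.  Each key residue's
*received* attention (column mean over non-padded queries) becomes its
per-residue weight, rescaled so the track maximum is 100.  Per head,
the top-5 residues of every partner protein are pooled and partitioned
by interface membership, and a two-sided Mann-Whitney U test asks
whether interface residues carry systematically higher weights.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .network import AttentionMap
from .records import InterfaceAnnotation


@dataclass(frozen=True)
class ResidueWeightTrack:
    """Per-residue attention weights of one protein, 0-100 scale."""

    protein_id: str
    head: int
    weights: np.ndarray     # over non-padded residues, max = 100
    positions: np.ndarray   # matching 1-based residue positions


def per_residue_weights(attn: AttentionMap, protein_id: str = "") -> ResidueWeightTrack:
    """Reduce an attention matrix to one weight per residue.

    The weight of residue *j* is the mean attention it receives over all
    (non-padded) query positions, rescaled so the largest weight on the
    track equals 100.
    """
    if attn.matrix.size == 0:
        raise ValueError("empty attention map")
    received = attn.matrix.mean(axis=0)
    peak = received.max()
    if peak <= 0:
        raise ValueError("attention map has no positive weights")
    weights = received * (100.0 / peak)
    return ResidueWeightTrack(protein_id=protein_id, head=attn.head,
                              weights=weights, positions=attn.positions)


def top_k_residues(track: ResidueWeightTrack, k: int = 5) -> list[int]:
    """1-based positions of the k highest weights; ties keep the smaller
    position; shorter tracks return all positions."""
    if len(track.weights) == 0:
        raise ValueError("empty track")
    order = sorted(range(len(track.weights)),
                   key=lambda i: (-track.weights[i], track.positions[i]))
    return [int(track.positions[i]) for i in order[:k]]


def exact_mannwhitney_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by permutation enumeration.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes (tie-safe).  Returns (U of group x, p).  Intended for
    small groups; the caller switches to the normal approximation above
    8 per group.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_of(group1: Sequence[float], group2: Sequence[float]) -> float:
        u = 0.0
        for a in group1:
            for b in group2:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(x, y)
    n_le = 0
    n_ge = 0
    total = 0
    indices = range(n1 + n2)
    for combo in itertools.combinations(indices, n1):
        in1 = set(combo)
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in indices if i not in in1]
        u = u_of(g1, g2)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def mannwhitney(x: Sequence[float], y: Sequence[float],
                exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small groups,
    normal approximation with tie correction otherwise."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if len(x) <= exact_max and len(y) <= exact_max:
        return exact_mannwhitney_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def interface_enrichment(
    tracks: Iterable[ResidueWeightTrack],
    annotations: Iterable[InterfaceAnnotation],
    per_head: bool = True,
    k: int = 5,
) -> dict:
    """Interface-vs-noninterface weight comparison over top-k residues.

    Per head (or pooled when ``per_head`` is false), the top-k residues
    of every annotated partner protein are collected; their weights are
    split by interface membership and compared with a two-sided
    Mann-Whitney U test.  Proteins without an annotation are skipped and
    counted.  An empty group leaves the p-value undefined (``None``).
    """
    interface_of = {a.protein_id: a.interface_positions for a in annotations}
    heads: dict[int, dict[str, list[float]]] = {}
    n_skipped = 0
    for track in tracks:
        if track.protein_id not in interface_of:
            n_skipped += 1
            continue
        iface = interface_of[track.protein_id]
        key = track.head if per_head else 0
        bucket = heads.setdefault(key, {"interface": [], "not_interface": []})
        pos_to_weight = dict(zip(track.positions.tolist(), track.weights.tolist()))
        for pos in top_k_residues(track, k):
            group = "interface" if pos in iface else "not_interface"
            bucket[group].append(pos_to_weight[pos])
    results: dict = {"n_skipped_unannotated": n_skipped, "heads": {}}
    for head_key in sorted(heads):
        w_if = heads[head_key]["interface"]
        w_not = heads[head_key]["not_interface"]
        entry = {"n_interface": len(w_if), "n_not_interface": len(w_not)}
        if not w_if or not w_not:
            entry["U"] = None
            entry["p"] = None
        else:
            u, p = mannwhitney(w_if, w_not)
            entry["U"] = u
            entry["p"] = p
        results["heads"][head_key] = entry
    return results
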