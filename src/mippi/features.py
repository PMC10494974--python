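"""Sequence feature encoding.

Every event is encoded as three sequence inputs: a 51-residue window of
the wild-type protein centered on the mutated position, the same window
of the mutant form (differing only at the center), and the first 1,024
residues of the partner protein.  Each input carries integer tokens
(0 = padding/unknown, 1..20 = the standard amino acids in alphabetical
one-letter order), an L x 20 evolutionary profile (PSSM) squashed into
(0, 1) by the logistic sigmoid, and a boolean mask marking real residues.

Profiles come from PSI-BLAST against a large sequence database when one
is available; :func:`pseudo_pssm` is a deterministic, database-free
profile built from BLOSUM62 rows plus seeded noise, used for synthetic
data and tests.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import MutationEvent

#: Fixed token order: the 20 standard amino acids, alphabetical one-letter.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
TOKEN_OF = {aa: i + 1 for i, aa in enumerate(AA_ORDER)}
PAD_TOKEN = 0
#: Character used internally to mark padding slots in window strings.
PAD_CHAR = "-"

WINDOW = 51          # residues, mutation at the center (26th, 1-based)
HALF_WINDOW = 25
PARTNER_LEN = 1024   # partner truncation length


class EnvironmentError_(RuntimeError):
    """An external tool or database needed for a profile is unavailable."""


@dataclass(frozen=True)
class PssmProfile:
    """An L x 20 per-residue profile; ``source`` records how it was made."""

    values: np.ndarray
    source: str  # "psiblast" | "pseudo"

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"profile must be Lx20, got {self.values.shape}")


@dataclass(frozen=True)
class PositionalEncodingSpec:
    """Dimensionality of the sinusoidal positional encoding (must be even)."""

    d_model: int = 64


@dataclass(frozen=True)
class EncodedExample:
    """Token/profile/mask tensors for the three sequence inputs of one event."""

    ref_tokens: np.ndarray      # (51,) int
    mut_tokens: np.ndarray      # (51,) int
    partner_tokens: np.ndarray  # (partner_len,) int
    ref_pssm: np.ndarray        # (51, 20)
    mut_pssm: np.ndarray        # (51, 20)
    partner_pssm: np.ndarray    # (partner_len, 20)
    ref_mask: np.ndarray        # (51,) bool, True = real residue
    mut_mask: np.ndarray
    partner_mask: np.ndarray


def extract_window(
    seq: str, position: int, ref_aa: str, alt_aa: str
) -> tuple[str, str]:
    """Cut the 51-residue reference and mutant windows around ``position``.

    The window covers positions ``position-25 .. position+25`` (1-based);
    slots falling outside the sequence are padding marks.  The mutant
    window is identical except for ``alt_aa`` at the center.
    """
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside sequence of length {len(seq)}")
    if seq[position - 1] != ref_aa:
        raise ValueError(
            f"sequence has {seq[position - 1]!r} at position {position}, "
            f"expected {ref_aa!r}"
        )
    chars = []
    for p in range(position - HALF_WINDOW, position + HALF_WINDOW + 1):
        chars.append(seq[p - 1] if 1 <= p <= len(seq) else PAD_CHAR)
    ref_window = "".join(chars)
    mut_window = ref_window[:HALF_WINDOW] + alt_aa + ref_window[HALF_WINDOW + 1:]
    return ref_window, mut_window


def encode_tokens(window_or_seq: str) -> tuple[np.ndarray, int]:
    """Map a (possibly padded) sequence string to integer tokens.

    Standard amino acids map to 1..20; padding marks and nonstandard
    residues (B, J, O, U, X, Z, ``*``) map to 0.  Returns the token
    vector and the count of nonstandard residues encountered, which is
    also surfaced as a :class:`UserWarning`.
    """
    tokens = np.zeros(len(window_or_seq), dtype=np.int64)
    n_nonstandard = 0
    for i, ch in enumerate(window_or_seq):
        tok = TOKEN_OF.get(ch, PAD_TOKEN)
        tokens[i] = tok
        if tok == PAD_TOKEN and ch != PAD_CHAR:
            n_nonstandard += 1
    if n_nonstandard:
        warnings.warn(
            f"{n_nonstandard} nonstandard residue(s) encoded as token 0",
            UserWarning,
            stacklevel=2,
        )
    return tokens, n_nonstandard


def prepare_partner(seq: str, max_len: int = PARTNER_LEN) -> tuple[np.ndarray, np.ndarray]:
    """Tokenize the partner: truncate at ``max_len``, right-pad with zeros."""
    if not seq:
        raise ValueError("empty partner sequence")
    seq = seq[:max_len]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        tokens, _ = encode_tokens(seq)
    out = np.zeros(max_len, dtype=np.int64)
    out[: len(tokens)] = tokens
    mask = np.zeros(max_len, dtype=bool)
    mask[: len(seq)] = True
    # nonstandard residues are unknown to the model: mask them out too
    mask[: len(seq)] &= tokens != PAD_TOKEN
    return out, mask


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def compute_pssm_psiblast(
    seq: str,
    database: str | Path,
    iterations: int = 3,
    evalue: float = 1e-3,
    executable: str = "psiblast",
) -> PssmProfile:
    """Run PSI-BLAST and parse the raw log-odds PSSM (pre-normalization).

    Defaults follow common profile-building practice for this task:
    3 iterations with an inclusion E-value of 1e-3 against a large
    clustered database such as UniRef90.
    """
    if shutil.which(executable) is None:
        raise EnvironmentError_(
            f"{executable} not found on PATH; use the pseudo profile source "
            f"(pssm.source=pseudo) for database-free operation"
        )
    database = Path(database)
    if not (database.with_suffix(database.suffix + ".pin").exists()
            or database.with_suffix(database.suffix + ".phr").exists()
            or Path(str(database) + ".pal").exists()):
        raise EnvironmentError_(
            f"no BLAST protein database found at {database}; use the pseudo "
            f"profile source (pssm.source=pseudo) for database-free operation"
        )
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        query.write_text(f">query\n{seq}\n")
        out_pssm = Path(tmp) / "out.pssm"
        cmd = [
            executable,
            "-query", str(query),
            "-db", str(database),
            "-num_iterations", str(iterations),
            "-inclusion_ethresh", str(evalue),
            "-out_ascii_pssm", str(out_pssm),
            "-out", str(Path(tmp) / "hits.txt"),
        ]
        subprocess.run(cmd, check=True, capture_output=True)
        return parse_ascii_pssm(out_pssm)


def parse_ascii_pssm(path: str | Path) -> PssmProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file (the first 20-column
    log-odds block, not the percentage block)."""
    lines = Path(path).read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) >= 40 and all(p in TOKEN_OF for p in parts[:20]):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PSSM header row found")
    col_order = lines[header_idx].split()[:20]
    col_to_canonical = [AA_ORDER.index(aa) for aa in col_order]
    rows: list[np.ndarray] = []
    for line in lines[header_idx + 1:]:
        parts = line.split()
        if len(parts) < 22 or not parts[0].isdigit():
            if rows:
                break
            continue
        scores = np.array([float(x) for x in parts[2:22]])
        canonical = np.empty(20)
        canonical[col_to_canonical] = scores
        rows.append(canonical)
    if not rows:
        raise ValueError(f"{path}: no PSSM data rows found")
    return PssmProfile(values=np.vstack(rows), source="psiblast")


def _blosum62_matrix() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = blosum[a, b]
    return mat


_BLOSUM62: np.ndarray | None = None
_NOISE_CACHE: dict[int, np.ndarray] = {}
_NOISE_MAX_LEN = 2048


def _noise_table(seed: int) -> np.ndarray:
    """Per-seed noise keyed by (position, residue token): two sequences
    that agree at a position get identical noise there, mimicking how
    real alignment profiles barely change away from a point mutation."""
    if seed not in _NOISE_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                            0x5A17]))
        _NOISE_CACHE[seed] = rng.normal(0.0, 1.0,
                                        size=(_NOISE_MAX_LEN, 21, 20))
    return _NOISE_CACHE[seed]


def pseudo_pssm(seq: str, seed: int) -> PssmProfile:
    """Deterministic database-free profile for ``seq``.

    Row *i* is the BLOSUM62 substitution-score row of residue *i* plus
    Gaussian noise (sigma = 1) drawn from a seed-keyed table indexed by
    position and residue identity, so the true residue's own column
    scores highest in expectation and a single substitution perturbs
    only its own row.  Nonstandard residues get a zero base row.  The
    profile depends only on ``(seq, seed)``.
    """
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = _blosum62_matrix()
    noise = _noise_table(seed)
    raw = np.zeros((len(seq), 20))
    for i, aa in enumerate(seq):
        tok = TOKEN_OF.get(aa, PAD_TOKEN)
        if tok != PAD_TOKEN:
            raw[i] = _BLOSUM62[tok - 1]
        raw[i] += noise[i % _NOISE_MAX_LEN, tok]
    return PssmProfile(values=raw, source="pseudo")


def normalize_pssm(raw: PssmProfile) -> PssmProfile:
    """Squash raw log-odds entrywise into (0, 1) with the logistic sigmoid."""
    from scipy.special import expit

    return PssmProfile(values=expit(raw.values), source=raw.source)


def positional_encoding(length: int, spec: PositionalEncodingSpec) -> np.ndarray:
    """Sinusoidal positional encoding.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/d_model))`` and
    ``PE[pos, 2i+1] = cos(pos / 10000^(2i/d_model))`` with 0-based ``pos``.
    """
    d = spec.d_model
    if d % 2 != 0:
        raise ValueError(f"d_model must be even, got {d}")
    pos = np.arange(length)[:, None].astype(float)
    i = np.arange(d // 2)[None, :].astype(float)
    angle = pos / np.power(10000.0, 2.0 * i / d)
    pe = np.empty((length, d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _window_pssm(full_profile: np.ndarray, position: int, seq_len: int) -> np.ndarray:
    """Slice a full-length Lx20 profile to the 51-residue window; padding rows zero."""
    out = np.zeros((WINDOW, 20))
    for slot, p in enumerate(range(position - HALF_WINDOW, position + HALF_WINDOW + 1)):
        if 1 <= p <= seq_len:
            out[slot] = full_profile[p - 1]
    return out


def assemble_features(
    event: MutationEvent,
    pssm_source: str = "pseudo",
    *,
    database: str | Path | None = None,
    seed: int = 0,
    partner_len: int = PARTNER_LEN,
) -> EncodedExample:
    """Build the full encoded example for one event.

    The mutant window's profile is computed from the mutant full-length
    sequence (profiles are recomputed after the substitution, keeping the
    two channels self-consistent).  Padded positions carry token 0 and
    all-zero profile rows.
    """
    ref_window, mut_window = extract_window(
        event.mut_protein_seq, event.position, event.ref_aa, event.alt_aa
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ref_tokens, _ = encode_tokens(ref_window)
        mut_tokens, _ = encode_tokens(mut_window)
    ref_mask = ref_tokens != PAD_TOKEN
    mut_mask = mut_tokens != PAD_TOKEN
    partner_tokens, partner_mask = prepare_partner(event.partner_seq, max_len=partner_len)

    if pssm_source == "pseudo":
        ref_profile = normalize_pssm(pseudo_pssm(event.mut_protein_seq, seed)).values
        mut_profile = normalize_pssm(pseudo_pssm(event.mutant_seq, seed)).values
        partner_profile = normalize_pssm(pseudo_pssm(event.partner_seq, seed)).values
    elif pssm_source == "psiblast":
        if database is None:
            raise EnvironmentError_("psiblast profile source requires a database path")
        ref_profile = normalize_pssm(
            compute_pssm_psiblast(event.mut_protein_seq, database)
        ).values
        mut_profile = normalize_pssm(
            compute_pssm_psiblast(event.mutant_seq, database)
        ).values
        partner_profile = normalize_pssm(
            compute_pssm_psiblast(event.partner_seq, database)
        ).values
    else:
        raise ValueError(f"unknown pssm_source: {pssm_source!r}")

    seq_len = len(event.mut_protein_seq)
    ref_pssm = _window_pssm(ref_profile, event.position, seq_len)
    mut_pssm = _window_pssm(mut_profile, event.position, seq_len)
    ref_pssm[~ref_mask] = 0.0
    mut_pssm[~mut_mask] = 0.0

    partner_pssm = np.zeros((partner_len, 20))
    n_real = min(len(event.partner_seq), partner_len)
    partner_pssm[:n_real] = partner_profile[:n_real]
    partner_pssm[~partner_mask] = 0.0

    return EncodedExample(
        ref_tokens=ref_tokens,
        mut_tokens=mut_tokens,
        partner_tokens=partner_tokens,
        ref_pssm=ref_pssm,
        mut_pssm=mut_pssm,
        partner_pssm=partner_pssm,
        ref_mask=ref_mask,
        mut_mask=mut_mask,
        partner_mask=partner_mask,
    )
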