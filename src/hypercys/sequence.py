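"""Sequence-derived cysteine descriptors built on the evolutionary profile.

A PSI-BLAST position-specific scoring matrix (PSSM) is the substrate for
everything here: the smoothed profile (per-position sum of the ws
surrounding rows, zero-padded at the termini), the consensus-sequence
monogram/bigram conservation features, the contact-potential pseudo-energy
(PSEE), and a deterministic propensity-based fallback for secondary
structure and accessibility when no external predictor output is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._tables import (
    CHOU_FASMAN,
    HYDROPATHY,
    PSSM_ALPHABET,
    contact_energy_table,
)

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}

#: Number of sequence-based features per residue:
#: 20 (smoothed PSSM) + 1 (monogram) + 20 (bigram) + 1 (PSEE) + 4 (SSP).
N_SEQUENCE_FEATURES = 46


@dataclass
class PSSMProfile:
    """L x 20 integer log-odds matrix in PSI-BLAST column order."""

    sequence: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.sequence), 20):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PSSM contains non-finite entries")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SmoothedPSSM:
    """Windowed sum of PSSM rows; ws=1 reproduces the source profile."""

    matrix: np.ndarray
    window_size: int


def parse_ascii_pssm(text: str) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (the -out_ascii_pssm layout).

    Only the first 20 (log-odds) columns are read; the weighted-percentage
    block and trailing statistics are ignored.
    """
    sequence: list[str] = []
    rows: list[list[int]] = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) < 22:
            continue
        try:
            int(parts[0])
        except ValueError:
            continue
        aa = parts[1]
        if len(aa) != 1 or not aa.isalpha():
            continue
        try:
            scores = [int(v) for v in parts[2:22]]
        except ValueError as exc:
            raise ValueError(f"malformed PSSM row: {line!r}") from exc
        sequence.append(aa)
        rows.append(scores)
    if not rows:
        raise ValueError("no PSSM score rows found in input")
    return PSSMProfile(sequence="".join(sequence), matrix=np.array(rows, dtype=int))


def write_ascii_pssm(profile: PSSMProfile) -> str:
    """Serialize a profile in the PSI-BLAST ASCII layout (log-odds block)."""
    header = (
        "\nLast position-specific scoring matrix computed, weighted "
        "observed percentages rounded down, information per position, "
        "and relative weight of gapless real matches to pseudocounts\n"
    )
    cols = "            " + "  ".join(PSSM_ALPHABET) + "   " + "  ".join(PSSM_ALPHABET)
    lines = [header, cols]
    for i, aa in enumerate(profile.sequence):
        scores = "".join(f"{int(v):4d}" for v in profile.matrix[i])
        # repeat the block in the percentage slot so row width matches the
        # native layout; the parser only reads the first 20 columns.
        lines.append(f"{i + 1:5d} {aa} {scores} {scores}   0.00 0.00")
    return "\n".join(lines) + "\n"


def smooth_pssm(profile: PSSMProfile, window_size: int) -> SmoothedPSSM:
    """Per-position sum of the ``window_size`` surrounding PSSM rows.

    Row i of the result is sum of rows i-(ws-1)/2 ... i+(ws-1)/2 with zero
    vectors padding both termini.  ws must be odd and in [1, 23].
    """
    ws = int(window_size)
    if ws % 2 == 0 or not (1 <= ws <= 23):
        raise ValueError(f"window size must be odd and in [1, 23], got {ws}")
    if ws == 1:
        return SmoothedPSSM(matrix=profile.matrix.astype(float).copy(), window_size=1)
    half = (ws - 1) // 2
    L = len(profile)
    padded = np.zeros((L + 2 * half, 20))
    padded[half:half + L] = profile.matrix
    csum = np.cumsum(padded, axis=0)
    out = np.empty((L, 20))
    out[0] = csum[ws - 1]
    out[1:] = csum[ws:] - csum[:L - 1]
    return SmoothedPSSM(matrix=out, window_size=ws)


def normalize_pssm(matrix: np.ndarray) -> np.ndarray:
    """Elementwise logistic squashing of log-odds scores into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(matrix, dtype=float)))


def consensus_sequence(profile: PSSMProfile) -> str:
    """Per-position argmax residue; ties break by PSI-BLAST column order."""
    idx = np.argmax(profile.matrix, axis=1)
    return "".join(PSSM_ALPHABET[i] for i in idx)


def monogram(p_norm: np.ndarray, consensus: str) -> np.ndarray:
    """MG(i) = normalized score of the consensus residue at position i."""
    if p_norm.shape[0] != len(consensus):
        raise ValueError("normalized matrix and consensus length mismatch")
    cols = np.array([_AA_INDEX[aa] for aa in consensus])
    return p_norm[np.arange(len(consensus)), cols]


def bigram(p_norm: np.ndarray, consensus: str) -> np.ndarray:
    """BG(n, i) = MG(i) * normalized score of residue n at position i+1.

    The final column (no successor) is all zeros.  Shape (20, L).
    """
    L = len(consensus)
    mg = monogram(p_norm, consensus)
    out = np.zeros((20, L))
    if L > 1:
        out[:, : L - 1] = p_norm[1:].T * mg[: L - 1]
    return out


def psee(
    sequence: str,
    rsa: np.ndarray,
    contact_table: np.ndarray | None = None,
    half_window: int = 2,
) -> np.ndarray:
    """Position-specific estimated energy from burial and contact potential.

    PSEE(i) = sum over in-range j in [i-hw, i+hw], j != i, of
    (1 - rsa_i)(1 - rsa_j) * e(a_i, a_j), with e a symmetric 20x20 residue
    contact potential (default: the shipped Miyazawa-Jernigan-derived
    table).  rsa values are clipped into [0, 1] with a warning.
    """
    L = len(sequence)
    rsa = np.asarray(rsa, dtype=float)
    if rsa.shape != (L,):
        raise ValueError("rsa length does not match sequence")
    if np.any((rsa < 0) | (rsa > 1)):
        logger.warning("rsa values outside [0, 1] clipped")
        rsa = np.clip(rsa, 0.0, 1.0)
    table = contact_energy_table() if contact_table is None else np.asarray(contact_table)
    if not np.allclose(table, table.T):
        raise ValueError("contact table must be symmetric")
    mean_e = float(table.mean())

    def _e(a: str, b: str) -> float:
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is None or ib is None:
            return mean_e
        return float(table[ia, ib])

    burial = 1.0 - rsa
    out = np.zeros(L)
    for i in range(L):
        total = 0.0
        for j in range(max(0, i - half_window), min(L, i + half_window + 1)):
            if j == i:
                continue
            total += burial[i] * burial[j] * _e(sequence[i], sequence[j])
        out[i] = total
    return out


def propensity_ssp_fallback(sequence: str) -> np.ndarray:
    """Deterministic L x 4 (helix_p, strand_p, coil_p, asa_pred) predictor.

    Conformational propensities are averaged over a +-3 window and
    normalized to probabilities; relative accessibility comes from a
    hydropathy scale mapped linearly onto [0, 1] (hydrophobic -> buried).
    A stand-in for external per-residue structure predictors.
    """
    L = len(sequence)
    mean_prop = np.mean([v for v in CHOU_FASMAN.values()], axis=0)
    raw = np.empty((L, 3))
    asa = np.empty(L)
    for i, aa in enumerate(sequence):
        if aa in CHOU_FASMAN:
            raw[i] = CHOU_FASMAN[aa]
            asa[i] = (4.5 - HYDROPATHY[aa]) / 9.0
        else:
            logger.warning("unknown residue %r; using average propensity", aa)
            raw[i] = mean_prop
            asa[i] = 0.5
    smoothed = np.empty_like(raw)
    for i in range(L):
        lo, hi = max(0, i - 3), min(L, i + 4)
        smoothed[i] = raw[lo:hi].mean(axis=0)
    probs = smoothed / smoothed.sum(axis=1, keepdims=True)
    return np.column_stack([probs, np.clip(asa, 0.0, 1.0)])


def parse_ssp_file(text: str, sequence: str | None = None) -> np.ndarray:
    """Adapter for externally produced per-residue SS/ASA predictions.

    Whitespace-delimited columns: index, residue, P(helix), P(strand),
    P(coil), ASA.  Lines starting with '#' are skipped.
    """
    rows: list[list[float]] = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 6:
            raise ValueError(f"malformed SSP row: {line!r}")
        vals = [float(v) for v in parts[2:6]]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError(f"probability/ASA outside [0, 1] in row: {line!r}")
        rows.append(vals)
    out = np.array(rows)
    if sequence is not None and out.shape[0] != len(sequence):
        raise ValueError(
            f"SSP file has {out.shape[0]} rows but sequence length is {len(sequence)}"
        )
    return out


def residue_seq_features(
    smoothed: SmoothedPSSM,
    mg: np.ndarray,
    bg: np.ndarray,
    psee_values: np.ndarray,
    ssp: np.ndarray,
    i: int,
) -> np.ndarray:
    """The 46-component sequence feature vector at 0-based position i.

    Order: 20 smoothed PSSM, monogram, 20 bigram, PSEE, helix_p, strand_p,
    coil_p, asa_pred.
    """
    L = smoothed.matrix.shape[0]
    if not (0 <= i < L):
        raise IndexError(f"position {i} out of range for profile of length {L}")
    if not (len(mg) == bg.shape[1] == len(psee_values) == ssp.shape[0] == L):
        raise ValueError("profile lengths disagree")
    return np.concatenate([
        smoothed.matrix[i],
        [mg[i]],
        bg[:, i],
        [psee_values[i]],
        ssp[i],
    ])
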