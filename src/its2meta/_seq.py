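"""Low-level sequence helpers shared across the pipeline stages."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count over the shared prefix length of two strings."""
    return sum(x != y for x, y in zip(a, b))


def phred_to_error(qual: str) -> np.ndarray:
    """Per-base error probabilities from a Phred+33 quality string."""
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.float64)
    return np.power(10.0, -(q - PHRED_OFFSET) / 10.0)


def expected_errors(qual: str) -> float:
    """maxEE statistic: sum of per-base error probabilities."""
    return float(phred_to_error(qual).sum())


def qual_string(q: int, length: int) -> str:
    if not 0 <= q <= 60:
        raise ValueError(f"Phred score {q} outside [0, 60]")
    return chr(PHRED_OFFSET + q) * length


def error_rate_to_phred(error_rate: float, cap: int = 41) -> int:
    """Constant Phred score encoding a per-base substitution probability."""
    if error_rate <= 0:
        return cap
    return min(cap, max(0, round(-10.0 * np.log10(error_rate))))


def seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from a master seed by hashing.

    Keeps stage-skipping reruns reproducible: a stage's stream does not
    depend on which earlier stages consumed randomness.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**32)
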