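"""Low-level DNA string helpers shared across the package.

All sequences are upper-case ACGT strings; validation of ambiguous bases
happens at the dataset boundary (see :mod:`promsnp.datasets`).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The four orientation transforms applied to assembled contigs whose
#: reading direction is unknown.
TRANSFORMS = ("identity", "complement", "reverse", "reverse_complement")


def complement(seq: str) -> str:
    """Base-pair complement, reading direction kept."""
    return seq.translate(_COMPLEMENT)


def reverse(seq: str) -> str:
    """Reading direction flipped, bases kept."""
    return seq[::-1]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def apply_transform(seq: str, transform: str) -> str:
    if transform == "identity":
        return seq
    if transform == "complement":
        return complement(seq)
    if transform == "reverse":
        return reverse(seq)
    if transform == "reverse_complement":
        return reverse_complement(seq)
    raise ValueError(f"unknown transform {transform!r}")


def invert_transform(seq: str, transform: str) -> str:
    """Undo ``apply_transform``; every transform here is an involution."""
    return apply_transform(seq, transform)


def map_position_back(pos: int, length: int, transform: str) -> int:
    """Map a 0-based position on a transformed sequence back to the original.

    ``complement`` keeps coordinates; ``reverse`` and ``reverse_complement``
    mirror them (p -> L-1-p).
    """
    if transform in ("identity", "complement"):
        return pos
    if transform in ("reverse", "reverse_complement"):
        return length - 1 - pos
    raise ValueError(f"unknown transform {transform!r}")


def map_interval_back(start: int, end: int, length: int, transform: str) -> tuple[int, int]:
    """Map a 0-based half-open interval on a transformed sequence back."""
    if transform in ("identity", "complement"):
        return start, end
    if transform in ("reverse", "reverse_complement"):
        return length - end, length - start
    raise ValueError(f"unknown transform {transform!r}")


def one_hot(seq: str) -> np.ndarray:
    """One-hot encode an ACGT string as a (len, 4) 0/1 matrix.

    Column order is A, C, G, T: A -> (1,0,0,0), C -> (0,1,0,0),
    G -> (0,0,1,0), T -> (0,0,0,1).
    """
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    rows = lut[idx]
    if (rows < 0).any():
        bad = seq[int(np.argmax(rows < 0))]
        raise ValueError(f"ambiguous base {bad!r} cannot be one-hot encoded")
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    mat[np.arange(len(seq)), rows] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("expected a (length, 4) matrix")
    return "".join(BASES[i] for i in mat.argmax(axis=1))


def random_dna(rng: np.random.Generator, length: int, probs=None) -> str:
    """Random ACGT string with the given background composition."""
    if probs is None:
        probs = (0.25, 0.25, 0.25, 0.25)
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("background composition must be a probability 4-vector")
    idx = rng.choice(4, size=length, p=probs)
    arr = np.frombuffer(b"ACGT", dtype=np.uint8)[idx]
    return arr.tobytes().decode("ascii")
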