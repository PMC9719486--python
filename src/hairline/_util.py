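"""Low-level sequence encoding helpers shared across modules.

Bases are stored as uint8 codes 0..3 (A,C,G,T); anything else maps to 255
and is rejected at the boundaries.  The complement of code ``b`` is ``3-b``.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE_TABLE = bytes.maketrans(bytes(range(4)), b"ACGT")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to uint8 codes; raises on other characters."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = chr(seq.encode("ascii")[int(np.argmax(arr > 3))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return np.ascontiguousarray(codes, dtype=np.uint8).tobytes().translate(_DECODE_TABLE).decode()


def decode_flat(flat: np.ndarray, offsets: np.ndarray) -> list[str]:
    """Split a flat code array into per-read strings using offsets (n+1)."""
    big = np.ascontiguousarray(flat, dtype=np.uint8).tobytes().translate(_DECODE_TABLE)
    return [big[offsets[i]:offsets[i + 1]].decode() for i in range(len(offsets) - 1)]


def revcomp(seq: str) -> str:
    return decode(3 - encode(seq)[::-1])


def flatten(seqs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate sequences -> (flat codes, offsets[n+1], lengths)."""
    joined = "".join(seqs)
    flat = encode(joined)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    return flat, offsets, lengths


def segment_ids(offsets: np.ndarray) -> np.ndarray:
    """Per-position read index for a flat array described by offsets."""
    n = int(offsets[-1])
    out = np.zeros(n, dtype=np.int64)
    np.add.at(out, offsets[1:-1], 1)
    return np.cumsum(out)


def positions_within(offsets: np.ndarray) -> np.ndarray:
    """Per-position 0-based offset within its read."""
    n = int(offsets[-1])
    ids = segment_ids(offsets)
    return np.arange(n, dtype=np.int64) - offsets[ids]


def reverse_within_segments(flat: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Reverse each segment of a flat array in place-order (returns a copy)."""
    ids = segment_ids(offsets)
    within = np.arange(flat.size, dtype=np.int64) - offsets[ids]
    lengths = (offsets[1:] - offsets[:-1])[ids]
    idx = offsets[ids] + (lengths - 1 - within)
    return flat[idx]


def phred_to_codes(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33


def gather_segments(flat: np.ndarray, offsets: np.ndarray,
                    indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract segments ``indices`` from a flat array -> (new flat, offsets)."""
    indices = np.asarray(indices, dtype=np.int64)
    lengths = (offsets[1:] - offsets[:-1])[indices]
    new_off = np.zeros(indices.size + 1, dtype=np.int64)
    np.cumsum(lengths, out=new_off[1:])
    total = int(new_off[-1])
    if total == 0:
        return np.empty(0, dtype=flat.dtype), new_off
    rep_start = np.repeat(offsets[indices], lengths)
    within = np.arange(total, dtype=np.int64) - np.repeat(new_off[:-1], lengths)
    return flat[rep_start + within], new_off
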