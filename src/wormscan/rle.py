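"""Run-length encoding of binary masks for JSON-friendly ground truth."""

from __future__ import annotations

import numpy as np


def encode_mask(mask: np.ndarray) -> dict:
    """Encode a 2-D boolean mask as row-major run lengths.

    The encoding is ``{"shape": [h, w], "runs": [start, length, ...]}``
    with starts indexing the flattened array.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    if not flat.any():
        return {"shape": list(mask.shape), "runs": []}
    padded = np.concatenate(([False], flat, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    runs = np.empty(2 * len(starts), dtype=int)
    runs[::2] = starts
    runs[1::2] = ends - starts
    return {"shape": list(mask.shape), "runs": runs.tolist()}


def decode_mask(rle: dict) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    runs = rle["runs"]
    for start, length in zip(runs[::2], runs[1::2]):
        flat[start : start + length] = True
    return flat.reshape(shape)
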