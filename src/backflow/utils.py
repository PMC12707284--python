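"""Shared constants and seeded RNG streams."""

from __future__ import annotations

import zlib

import numpy as np

# Canonical 20-letter amino-acid alphabet; index 20 is the MASK token of the
# discrete flow state.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
MASK_TOKEN = 20
N_TOKENS = 21
UNKNOWN = "X"


def seed_stream(root_seed: int, name: str) -> np.random.Generator:
    """A named, independent RNG stream derived from one root seed.

    Streams are stable across runs and independent across names, so adding a
    new stochastic consumer never perturbs existing ones.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag]))


def tokens_to_string(tokens: np.ndarray) -> str:
    out = []
    for t in tokens:
        out.append("#" if t == MASK_TOKEN else AMINO_ACIDS[int(t)])
    return "".join(out)


def string_to_tokens(seq: str) -> np.ndarray:
    toks = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        if c == "#":
            toks[i] = MASK_TOKEN
        else:
            if c not in AA_TO_INDEX:
                raise ValueError(f"invalid amino-acid letter {c!r} at position {i}")
            toks[i] = AA_TO_INDEX[c]
    return toks
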