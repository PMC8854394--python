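"""Tiny DNA string helpers used throughout the simulator."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator,
                    base_probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    """Random DNA of `length` bases drawn iid from `base_probs` over A,C,G,T."""
    idx = rng.choice(4, size=length, p=list(base_probs))
    return "".join(np.frombuffer(b"ACGT", dtype="S1")[idx].astype(str))
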