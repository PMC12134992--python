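"""Small shared helpers: rounding, complements, random sequence generation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do (70.549 -> 70.55)."""
    q = Decimal(1).scaleb(-ndigits)
    v = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(v)


def round_half_up_int(x: float) -> int:
    return int(round_half_up(x, 0))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. sequence with expected GC fraction ``gc``."""
    if length <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return BASES[idx].tobytes().decode("ascii")


def mutate_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position independently with probability ``rate``.

    Substitutions only (no indels), so repeat periods are preserved.
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # shift by 1..3 positions in the base alphabet -> guaranteed change
        cur = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode("ascii")
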