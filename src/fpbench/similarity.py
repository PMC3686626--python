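"""Similarity measures for bit-string and count-vector fingerprints.

With a = N_A (features in A), b = N_B, c = N_{A&B} (common features),
d = common off-bits and m = bit-string length, the eight measures are

    Dice            2c / (a + b)
    Tanimoto        c / (a + b - c)
    Cosine          c / sqrt(a b)
    Russel          c / m
    Kulczynski      (c/2) (1/a + 1/b)
    McConnaughey    (c (a + b) - a b) / (a b)
    Manhattan       1 - (a + b - 2c) / m
    RogotGoldberg   c / (a + b) + d / (2m - a - b)

Manhattan and Rogot-Goldberg use the common off-bits d; these, and Russel
(which divides by m), need a finite bit universe and are therefore rejected
for unbounded count vectors.  For count vectors the remaining measures use
the multiset generalization c = sum_i min(a_i, b_i), a = sum_i a_i,
b = sum_i b_i.

Dice and Tanimoto produce provably identical rankings: both order B before
C (for a fixed query A) exactly when N_{A&B} (N_A + N_C) > N_{A&C} (N_A + N_B).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .fingerprints import KIND_BITSTRING, KIND_COUNTVECTOR, FingerprintVector

logger = logging.getLogger("fpbench")

__all__ = ["SimilarityMeasure", "get_measure", "available_measures",
           "similarity", "bulk_max_similarity", "SimilarityError"]


class SimilarityError(ValueError):
    """Unsupported measure/fingerprint combination or invalid operands."""


@dataclass(frozen=True)
class SimilarityMeasure:
    name: str
    uses_off_bits: bool  # needs the common off-bit count d
    needs_length: bool   # needs the bit universe size m (superset of the above)
    func: Callable[..., float]


def _dice(a: int, b: int, c: int, d: int, m: int | None) -> float:
    return 2.0 * c / (a + b)


def _tanimoto(a, b, c, d, m):
    return c / (a + b - c)


def _cosine(a, b, c, d, m):
    return c / math.sqrt(a * b)


def _russel(a, b, c, d, m):
    return c / m


def _kulczynski(a, b, c, d, m):
    return 0.5 * c * (1.0 / a + 1.0 / b)


def _mcconnaughey(a, b, c, d, m):
    return (c * (a + b) - a * b) / (a * b)


def _manhattan(a, b, c, d, m):
    return 1.0 - (a + b - 2.0 * c) / m


def _rogot_goldberg(a, b, c, d, m):
    first = c / (a + b) if a + b else 0.0
    second = d / (2.0 * m - a - b) if 2 * m - a - b else 0.0
    return first + second


_MEASURES: dict[str, SimilarityMeasure] = {
    meas.name: meas for meas in [
        SimilarityMeasure("Dice", False, False, _dice),
        SimilarityMeasure("Tanimoto", False, False, _tanimoto),
        SimilarityMeasure("Cosine", False, False, _cosine),
        SimilarityMeasure("Russel", False, True, _russel),
        SimilarityMeasure("Kulczynski", False, False, _kulczynski),
        SimilarityMeasure("McConnaughey", False, False, _mcconnaughey),
        SimilarityMeasure("Manhattan", True, True, _manhattan),
        SimilarityMeasure("RogotGoldberg", True, True, _rogot_goldberg),
    ]
}


def available_measures() -> list[str]:
    return sorted(_MEASURES)


def get_measure(name: str) -> SimilarityMeasure:
    try:
        return _MEASURES[name]
    except KeyError:
        raise SimilarityError(
            f"unknown similarity measure {name!r}; "
            f"available: {', '.join(available_measures())}") from None


def _abc(a: FingerprintVector, b: FingerprintVector) -> tuple[int, int, int]:
    """Feature totals (a, b) and overlap c; multiset overlap for counts."""
    if a.kind == KIND_BITSTRING:
        small, large = (a.data, b.data) if len(a.data) <= len(b.data) else (b.data, a.data)
        c = sum(1 for k in small if k in large)
        return a.n_on, b.n_on, c
    small, large = (a.data, b.data) if len(a.data) <= len(b.data) else (b.data, a.data)
    c = sum(min(v, large[k]) for k, v in small.items() if k in large)
    return a.total, b.total, c


def similarity(a: FingerprintVector, b: FingerprintVector,
               measure: SimilarityMeasure | str = "Dice") -> float:
    """Similarity of two fingerprints of the same kind (symmetric in a, b).

    A molecule with no features at all cannot be meaningfully compared:
    every measure would hit 0/0.  Such comparisons return 0.0 with a
    warning.
    """
    if isinstance(measure, str):
        measure = get_measure(measure)
    if a.kind != b.kind:
        raise SimilarityError(f"fingerprint kinds differ: {a.kind} vs {b.kind}")
    if a.kind == KIND_BITSTRING and a.length != b.length:
        raise SimilarityError(f"bit-string lengths differ: {a.length} vs {b.length}")
    if measure.needs_length and a.kind == KIND_COUNTVECTOR:
        raise SimilarityError(
            f"{measure.name} needs a finite bit universe and is undefined "
            "for unbounded count vectors")
    na, nb, c = _abc(a, b)
    if na == 0 or nb == 0:
        logger.warning("similarity involving an empty fingerprint defined as 0.0")
        return 0.0
    m = a.length
    dcount = 0
    if measure.uses_off_bits:
        union = na + nb - sum(1 for k in a.data if k in b.data)
        dcount = m - union
    return measure.func(na, nb, c, dcount, m)


def bulk_max_similarity(queries: Sequence[FingerprintVector],
                        test: Sequence[FingerprintVector],
                        measure: SimilarityMeasure | str = "Dice") -> list[float]:
    """MAX-fusion score of each test molecule: its highest similarity over
    the query set."""
    if len(queries) == 0:
        raise SimilarityError("empty query set")
    if isinstance(measure, str):
        measure = get_measure(measure)
    return [max(similarity(q, t, measure) for q in queries) for t in test]
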