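"""Stage 1 — scoring: rank each repetition's test set by MAX-fusion
similarity to the query actives.

For every repetition the test set is (actives minus queries) union (decoys
minus training decoys).  Each test molecule is scored by its highest
similarity to any query molecule and the list is sorted by descending
similarity.

Tie-breaking: similarity ties are broken by a seeded random permutation
drawn per (target, repetition) *before* the sort and shared across all
fingerprints of that repetition.  Deterministic file-order tie-breaking
would systematically bias early-recognition metrics whenever many decoys
share a similarity value; the random permutation is unbiased yet
reproducible for a fixed master seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .compound_io import CompoundRecord, TargetDataset, TrainingList, iter_test_set
from .fingerprints import FingerprintDescriptor, FingerprintVector, get_descriptor, mol_from_smiles
from .similarity import SimilarityMeasure, bulk_max_similarity, get_measure

logger = logging.getLogger("fpbench")


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoredEntry:
    similarity: float
    internal_id: str
    is_active: bool


@dataclass(frozen=True)
class RankedScreenResult:
    """The ordered scored list of one (target, fingerprint, repetition)."""

    target_id: str
    fingerprint_name: str
    repetition: int
    entries: tuple[ScoredEntry, ...]


def _tiebreak_key(master_seed: int, target_id: str, repetition: int,
                  internal_id: str) -> int:
    # A seeded pseudo-random draw per molecule, keyed only by
    # (seed, target, repetition, molecule): shared across fingerprints and
    # independent of the order test molecules are enumerated in.
    return zlib.crc32(f"{master_seed}|{target_id}|{repetition}|{internal_id}"
                      .encode("utf-8"))


class FingerprintCache:
    """Per-molecule fingerprint cache shared across repetitions and reused
    for every descriptor of the same molecule set."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], FingerprintVector] = {}

    def get(self, rec: CompoundRecord,
            descriptor: FingerprintDescriptor) -> FingerprintVector | None:
        if not rec.smiles_ok:
            return None
        key = (descriptor.name, rec.internal_id)
        fp = self._store.get(key)
        if fp is None:
            fp = descriptor(mol_from_smiles(rec.smiles))
            self._store[key] = fp
        return fp


def score_repetition(dataset: TargetDataset, tl: TrainingList,
                     descriptor: FingerprintDescriptor,
                     measure: SimilarityMeasure, cache: FingerprintCache,
                     master_seed: int = 0) -> RankedScreenResult:
    queries = []
    for _, idx in tl.query_actives:
        fp = cache.get(dataset.actives[idx], descriptor)
        if fp is not None:
            queries.append(fp)
    if not queries:
        raise ScoringError(
            f"target {dataset.target_id!r} repetition {tl.repetition}: "
            "no valid query actives")
    test = list(iter_test_set(dataset, tl))
    if not any(r.role == "active" and r.smiles_ok for r in test):
        raise ScoringError(
            f"target {dataset.target_id!r} repetition {tl.repetition}: "
            "degenerate repetition with no valid test actives")
    fps, kept = [], []
    for rec in test:
        fp = cache.get(rec, descriptor)
        if fp is None:
            continue  # flagged SMILES: excluded from scoring, count logged upstream
        fps.append(fp)
        kept.append(rec)
    sims = bulk_max_similarity(queries, fps, measure)
    tie = {rec.internal_id: _tiebreak_key(master_seed, dataset.target_id,
                                          tl.repetition, rec.internal_id)
           for rec in kept}
    order = sorted(range(len(kept)),
                   key=lambda i: (-sims[i], tie[kept[i].internal_id],
                                  kept[i].internal_id))
    entries = tuple(ScoredEntry(sims[i], kept[i].internal_id,
                                kept[i].role == "active") for i in order)
    return RankedScreenResult(dataset.target_id, descriptor.name,
                              tl.repetition, entries)


def score_target(dataset: TargetDataset,
                 descriptor: FingerprintDescriptor | str,
                 measure: SimilarityMeasure | str = "Dice",
                 master_seed: int = 0,
                 cache: FingerprintCache | None = None) -> list[RankedScreenResult]:
    """Score all repetitions of one target with one fingerprint.

    Returns one RankedScreenResult per training list, in repetition order.
    """
    if isinstance(descriptor, str):
        descriptor = get_descriptor(descriptor)
    if isinstance(measure, str):
        measure = get_measure(measure)
    if not dataset.training:
        raise ScoringError(f"target {dataset.target_id!r}: no training lists")
    if cache is None:
        cache = FingerprintCache()
    return [score_repetition(dataset, tl, descriptor, measure, cache, master_seed)
            for tl in dataset.training]


# ---------------------------------------------------------------------------
# JSON-lines persistence (similarities rounded to 6 decimals on disk; full
# precision is kept in memory)

def write_scored_lists(path: str | Path, results: Iterable[RankedScreenResult],
                       append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode, encoding="utf-8") as fh:
        for res in results:
            fh.write(json.dumps({
                "target": res.target_id,
                "fingerprint": res.fingerprint_name,
                "repetition": res.repetition,
                "entries": [[round(e.similarity, 6), e.internal_id,
                             int(e.is_active)] for e in res.entries],
            }) + "\n")


def read_scored_lists(path: str | Path) -> list[RankedScreenResult]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                entries = tuple(ScoredEntry(float(s), str(i), bool(a))
                                for s, i, a in obj["entries"])
                out.append(RankedScreenResult(str(obj["target"]),
                                              str(obj["fingerprint"]),
                                              int(obj["repetition"]), entries))
            except (KeyError, ValueError, TypeError) as exc:
                raise ScoringError(
                    f"{path}:{lineno}: malformed scored-list record: {exc}") from exc
    return out
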