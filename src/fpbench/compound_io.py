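"""Reading and writing of compound lists and training lists.

Compound lists are plain-text, whitespace-separated files with one molecule
per line: external ID, internal ID, SMILES.  Lines starting with ``#`` are
comments.  Files may be gzip-compressed (detected by the ``.gz`` suffix).

Internal IDs follow the scheme ``<dataset>_<targetID>_<A|D>_<number>`` where
``A`` marks actives and ``D`` decoys; the number is the 0-based position of
the compound within its list.

Training lists record, for each repetition of the screening experiment,
which actives serve as query molecules and which decoys are held out as
training decoys; the remaining molecules form the test set.  They are
serialized as JSON lines, one repetition per line.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger("fpbench")

INTERNAL_ID_RE = re.compile(r"^(?P<dataset>.+)_(?P<target>[^_]+)_(?P<role>[AD])_(?P<number>\d+)$")

ROLE_ACTIVE = "active"
ROLE_DECOY = "decoy"
_ROLE_LETTER = {ROLE_ACTIVE: "A", ROLE_DECOY: "D"}


class CompoundListError(ValueError):
    """Malformed compound list or internal-ID violation."""


class TrainingListError(ValueError):
    """Invalid or inconsistent training list."""


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule of a benchmark data set.

    ``smiles_ok`` is False when the SMILES could not be parsed; such records
    are retained (so list indices and test-set sizes stay faithful to the
    source file) but are excluded from fingerprinting and scoring.
    """

    external_id: str
    internal_id: str
    smiles: str
    role: str  # "active" | "decoy"
    index: int
    smiles_ok: bool = True

    def __post_init__(self) -> None:
        if self.role not in _ROLE_LETTER:
            raise CompoundListError(f"unknown role {self.role!r}")
        m = INTERNAL_ID_RE.match(self.internal_id)
        if m is None:
            raise CompoundListError(
                f"internal ID {self.internal_id!r} does not match "
                "'<dataset>_<targetID>_<A|D>_<number>'"
            )
        if m.group("role") != _ROLE_LETTER[self.role]:
            raise CompoundListError(
                f"internal ID {self.internal_id!r} disagrees with role {self.role!r}"
            )


@dataclass(frozen=True)
class TrainingList:
    """Query actives and training decoys for one repetition.

    Both lists hold ``(internal_id, index)`` pairs; indices refer to the
    position within the corresponding compound list.
    """

    repetition: int
    query_actives: tuple[tuple[str, int], ...]
    training_decoys: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.query_actives] + [i for i, _ in self.training_decoys]
        if len(set(ids)) != len(ids):
            raise TrainingListError(
                f"repetition {self.repetition}: an internal ID appears twice"
            )


@dataclass
class TargetDataset:
    """All data for one target: actives, decoys and the training lists."""

    target_id: str
    actives: list[CompoundRecord]
    decoys: list[CompoundRecord]
    training: list[TrainingList] = field(default_factory=list)

    @property
    def n_repetitions(self) -> int:
        return len(self.training)

    def validate(self) -> None:
        """Check that every training list refers to existing compounds."""
        for tl in self.training:
            for iid, idx in tl.query_actives:
                _check_ref(self.actives, iid, idx, tl.repetition, "query active")
            for iid, idx in tl.training_decoys:
                _check_ref(self.decoys, iid, idx, tl.repetition, "training decoy")


def _check_ref(records: Sequence[CompoundRecord], iid: str, idx: int,
               rep: int, kind: str) -> None:
    if not 0 <= idx < len(records):
        raise TrainingListError(
            f"repetition {rep}: {kind} index {idx} out of range (list has {len(records)})"
        )
    if records[idx].internal_id != iid:
        raise TrainingListError(
            f"repetition {rep}: {kind} {iid!r} does not match record at index {idx} "
            f"({records[idx].internal_id!r})"
        )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_compound_list(path: str | Path, role: str) -> list[CompoundRecord]:
    """Read a compound list, assigning ``role`` and sequential 0-based indices.

    Unparsable SMILES produce a warning and a flagged record rather than being
    dropped: silently shrinking the list would change every downstream metric.
    """
    records: list[CompoundRecord] = []
    n_bad = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise CompoundListError(
                    f"{path}:{lineno}: expected >=3 whitespace-separated fields, "
                    f"got {len(fields)}"
                )
            external_id, internal_id, smiles = fields[0], fields[1], fields[2]
            ok = Chem.MolFromSmiles(smiles) is not None
            if not ok:
                n_bad += 1
                logger.warning("%s:%d: unparsable SMILES %r (record retained, "
                               "excluded from scoring)", path, lineno, smiles)
            records.append(CompoundRecord(
                external_id=external_id, internal_id=internal_id, smiles=smiles,
                role=role, index=len(records), smiles_ok=ok,
            ))
    if n_bad:
        logger.warning("%s: %d of %d SMILES failed to parse", path, n_bad, len(records))
    return records


def write_compound_list(path: str | Path, records: Iterable[CompoundRecord]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("# external_id internal_id smiles\n")
        for rec in records:
            fh.write(f"{rec.external_id} {rec.internal_id} {rec.smiles}\n")


def make_internal_id(dataset: str, target_id: str, role: str, number: int) -> str:
    return f"{dataset}_{target_id}_{_ROLE_LETTER[role]}_{number}"


def generate_training_lists(
    dataset: TargetDataset,
    n_queries: int = 5,
    decoy_fraction: float = 0.20,
    repetitions: int = 50,
    seed: int = 0,
) -> list[TrainingList]:
    """Draw the per-repetition training splits.

    Each repetition independently samples ``n_queries`` actives (the query
    molecules) and ``round(decoy_fraction * n_decoys)`` decoys without
    replacement.  The held-out molecules form the test set.  Deterministic
    for a fixed seed.
    """
    n_act, n_dec = len(dataset.actives), len(dataset.decoys)
    if not 0 < n_queries < n_act:
        raise TrainingListError(
            f"n_queries={n_queries} must be in (0, n_actives={n_act})"
        )
    if not 0.0 < decoy_fraction < 1.0:
        raise TrainingListError(f"decoy_fraction={decoy_fraction} must be in (0, 1)")
    n_train_dec = round(decoy_fraction * n_dec)
    if n_train_dec == 0:
        raise TrainingListError(
            f"decoy_fraction={decoy_fraction} selects zero training decoys"
        )
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(repetitions):
        qa = sorted(rng.choice(n_act, size=n_queries, replace=False).tolist())
        td = sorted(rng.choice(n_dec, size=n_train_dec, replace=False).tolist())
        out.append(TrainingList(
            repetition=rep,
            query_actives=tuple((dataset.actives[i].internal_id, i) for i in qa),
            training_decoys=tuple((dataset.decoys[i].internal_id, i) for i in td),
        ))
    return out


def write_training_lists(path: str | Path, lists: Iterable[TrainingList]) -> None:
    """Serialize training lists as JSON lines (one repetition per line)."""
    with _open_text(path, "wt") as fh:
        for tl in lists:
            fh.write(json.dumps({
                "repetition": tl.repetition,
                "query_actives": [list(p) for p in tl.query_actives],
                "training_decoys": [list(p) for p in tl.training_decoys],
            }) + "\n")


def read_training_lists(path: str | Path,
                        dataset: TargetDataset | None = None) -> list[TrainingList]:
    """Read JSON-lines training lists; optionally validate against a dataset.

    A training list with an empty decoy section is rejected at generation time
    but accepted here, so that externally produced splits can be loaded.
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TrainingListError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            out.append(TrainingList(
                repetition=int(obj["repetition"]),
                query_actives=tuple((str(i), int(j)) for i, j in obj["query_actives"]),
                training_decoys=tuple((str(i), int(j)) for i, j in obj["training_decoys"]),
            ))
    if dataset is not None:
        probe = TargetDataset(dataset.target_id, dataset.actives, dataset.decoys, out)
        probe.validate()
    return out


def iter_test_set(dataset: TargetDataset, tl: TrainingList) -> Iterator[CompoundRecord]:
    """Yield the test molecules of one repetition: non-query actives followed
    by non-training decoys (file order within each block)."""
    q = {i for _, i in tl.query_actives}
    t = {i for _, i in tl.training_decoys}
    for rec in dataset.actives:
        if rec.index not in q:
            yield rec
    for rec in dataset.decoys:
        if rec.index not in t:
            yield rec
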