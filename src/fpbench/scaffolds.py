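"""Bemis-Murcko scaffold extraction and the scaffold enrichment factor.

A Bemis-Murcko scaffold (BMS) is the union of a molecule's ring systems and
the linkers connecting them, with all side chains removed.  Molecules
without any ring have no framework; they all share the single sentinel key
``"ACYCLIC"`` (counted as one scaffold).

The scaffold EF probes scaffold hopping: instead of counting active
*molecules* recovered in the top fraction chi of a ranked list, it counts
distinct active *scaffolds*, normalised by the random expectation
chi * S_total where S_total is the number of distinct scaffolds among the
test-set actives of that repetition.  When every active has its own
scaffold (BMS/actives = 1) the scaffold EF coincides with the ordinary EF.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .compound_io import CompoundRecord
from .fingerprints import MoleculeError
from .metrics import MetricError
from .scoring import RankedScreenResult

ACYCLIC = "ACYCLIC"


def bemis_murcko(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko framework, or ``"ACYCLIC"``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    core = MurckoScaffold.GetScaffoldForMol(mol)
    smi = Chem.MolToSmiles(core)
    return smi if smi else ACYCLIC


def assign_scaffolds(records: Iterable[CompoundRecord]) -> dict[str, str]:
    """Map internal_id -> scaffold key for every parsable record."""
    return {r.internal_id: bemis_murcko(r.smiles)
            for r in records if r.smiles_ok}


def scaffold_enrichment_factor(result: RankedScreenResult,
                               assignment: Mapping[str, str],
                               chi: float = 0.05) -> float:
    """Scaffold EF at fraction chi for one ranked list.

    (distinct active scaffolds in the top floor(chi*N) entries) divided by
    (chi * distinct scaffolds among the test-set actives).
    """
    if not 0.0 < chi < 1.0:
        raise MetricError(f"scaffold EF requires 0 < chi < 1, got {chi}")
    entries = result.entries
    all_scaffolds = set()
    for e in entries:
        if e.is_active:
            try:
                all_scaffolds.add(assignment[e.internal_id])
            except KeyError:
                raise MetricError(
                    f"test active {e.internal_id!r} has no scaffold key") from None
    if not all_scaffolds:
        raise MetricError("no active scaffolds in the test set")
    top = math.floor(chi * len(entries))
    found = {assignment[e.internal_id] for e in entries[:top] if e.is_active}
    return len(found) / (chi * len(all_scaffolds))


def dataset_scaffold_summary(actives: Iterable[CompoundRecord]) -> tuple[int, float]:
    """(number of distinct BMS among the actives, ratio BMS/actives)."""
    keys, n = set(), 0
    for rec in actives:
        if not rec.smiles_ok:
            continue
        keys.add(bemis_murcko(rec.smiles))
        n += 1
    if n == 0:
        return 0, 0.0
    return len(keys), len(keys) / n
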