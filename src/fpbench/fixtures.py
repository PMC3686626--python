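"""Synthetic benchmark data sets with controllable difficulty.

Real fingerprint benchmarks draw actives and decoys from curated public
collections that come in three styles: few maximally diverse actives
embedded among many assay decoys (MUV-like), analog series of actives with
property-matched decoys (DUD-like), and diverse actives with a small number
of atom-count-matched decoys each (ChEMBL-like).  This module emulates the
*shape* of those collections without any download: molecules are assembled
by string substitution on an internal library of drug-like ring-system
templates and acyclic substituents, so every generated structure is
license-free and deterministic for a fixed seed.

The ``difficulty`` knob in [0, 1] is the fraction of decoys that share a
scaffold with some active: at 0 the decoys come from entirely different
ring systems (easy to separate), at 1 every decoy is an analog of an active
series (hard).

The curation operators mirror the rules used to build the real
collections: MaxMin diversity picking, decoy selection by atom-count
(radius-0 circular count) Dice similarity > 0.5, and removal of molecules
heavier than 700 g/mol or containing metal atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .compound_io import (ROLE_ACTIVE, ROLE_DECOY, CompoundRecord, TargetDataset,
                          generate_training_lists, make_internal_id)
from .fingerprints import compute_fingerprint, get_descriptor, mol_from_smiles
from .similarity import get_measure, similarity

STYLE_MUV = "MUV-like"
STYLE_DUD = "DUD-like"
STYLE_CHEMBL = "ChEMBL-like"

_DATASET_TOKEN = {STYLE_MUV: "SYNMUV", STYLE_DUD: "SYNDUD", STYLE_CHEMBL: "SYNCHEMBL"}


class GenerationError(RuntimeError):
    """Recipe could not be satisfied within the attempt budget."""


# --- internal structure library --------------------------------------------
# Ring-system templates with two substitution slots.  Slot {0} carries an
# optional ring attachment (extends the Bemis-Murcko framework); slot {1}
# carries an acyclic side chain.  Unused slots are filled with "[H]".

TEMPLATES: tuple[str, ...] = (
    "c1cc({0})ccc1{1}",                    # benzene
    "c1cc({0})cnc1{1}",                    # pyridine
    "c1nc({0})ncc1{1}",                    # pyrimidine
    "c1cc({0})oc1{1}",                     # furan
    "c1cc({0})sc1{1}",                     # thiophene
    "c1cc({0})[nH]c1{1}",                  # pyrrole
    "c1nc({0})[nH]c1{1}",                  # imidazole
    "c1sc({0})nc1{1}",                     # thiazole
    "c1oc({0})nc1{1}",                     # oxazole
    "c1cc({0})c2ccccc2c1{1}",              # naphthalene
    "c1ccc2nc({0})ccc2c1{1}",              # quinoline
    "c1ccc2[nH]c({0})cc2c1{1}",            # indole
    "c1ccc2[nH]c({0})nc2c1{1}",            # benzimidazole
    "c1ccc2oc({0})cc2c1{1}",               # benzofuran
    "c1ccc2sc({0})cc2c1{1}",               # benzothiophene
    "C1CCC({0})({1})CC1",                  # cyclohexane
    "C1CCN({0})CC1{1}",                    # piperidine
    "C1CN({0})CCN1{1}",                    # piperazine
    "O1CCN({0})CC1{1}",                    # morpholine
    "C1CCC({0})NC1{1}",                    # piperidine (C-subst.)
)

# ring attachments for slot {0}: extend the framework into a new scaffold
# ring-closure digits 8/9 avoid clashes with the template's own ring numbers
RING_ATTACHMENTS: tuple[str, ...] = (
    "c9ccccc9", "c9ccncc9", "c9ccc(F)cc9", "c9ccc(Cl)cc9",
    "C9CCCCC9", "C9CCNCC9", "c9ccco9", "c9cccs9",
    "Cc9ccccc9", "c8ccc9ccccc9c8",
)

# acyclic substituents for the side-chain slots
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "O", "OC", "OCC", "OC(C)C",
    "N", "NC", "N(C)C", "NCC", "F", "Cl", "Br", "I", "C#N", "C=O",
    "C(=O)O", "C(=O)OC", "C(=O)N", "C(=O)NC", "C(=O)C", "CO", "CN", "CCO",
    "CCN", "C(F)(F)F", "OC(F)(F)F", "S(=O)(=O)C", "S(=O)(=O)N", "SC", "CC#N",
)

# chain prefixes used to extend substituents into larger side chains
_CHAIN_PREFIXES: tuple[str, ...] = ("C", "CC", "CCC", "CO", "CN", "CCO", "CS")


def _side_chain_pool() -> list[str]:
    pool = list(SUBSTITUENTS)
    for p in _CHAIN_PREFIXES:
        for s in SUBSTITUENTS:
            pool.append(p + s)
    return pool


_SIDE_POOL = _side_chain_pool()

# scaffold space: (template index, ring-attachment index or None)
SCAFFOLDS: tuple[tuple[int, int | None], ...] = tuple(
    (t, r) for t in range(len(TEMPLATES))
    for r in [None, *range(len(RING_ATTACHMENTS))]
)


def _assemble(scaffold: tuple[int, int | None], side0: str | None,
              side1: str | None) -> str | None:
    """Canonical SMILES of template + attachments, or None if invalid.

    side0 only applies when the scaffold has no ring attachment.
    """
    t, r = scaffold
    slot0 = RING_ATTACHMENTS[r] if r is not None else (side0 or "[H]")
    slot1 = side1 or "[H]"
    mol = Chem.MolFromSmiles(TEMPLATES[t].format(slot0, slot1))
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class FixtureRecipe:
    """Conditions for one synthetic target.

    Defaults follow the collection style being emulated (see
    :func:`default_recipe`): actives/decoys counts per style, 50
    repetitions with 5 query actives and 20% training decoys.
    """

    style: str
    n_actives: int
    n_decoys: int
    n_series: int
    difficulty: float
    seed: int = 0
    repetitions: int = 50
    n_queries: int = 5
    decoy_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.style not in _DATASET_TOKEN:
            raise GenerationError(f"unknown style {self.style!r}")
        if not 1 <= self.n_series <= self.n_actives:
            raise GenerationError("need 1 <= n_series <= n_actives")
        if not 0.0 <= self.difficulty <= 1.0:
            raise GenerationError("difficulty must be in [0, 1]")


def default_recipe(style: str, seed: int = 0) -> FixtureRecipe:
    """Study-condition defaults per collection style: 30 actives / 15000
    decoys one-per-scaffold for MUV-like, analog series with moderately
    overlapping decoys for DUD-like, and 100 diverse actives with 2 matched
    decoys each for ChEMBL-like."""
    if style == STYLE_MUV:
        return FixtureRecipe(style, 30, 15000, 30, 0.9, seed)
    if style == STYLE_DUD:
        return FixtureRecipe(style, 60, 2500, 12, 0.3, seed)
    if style == STYLE_CHEMBL:
        return FixtureRecipe(style, 100, 200, 25, 0.5, seed)
    raise GenerationError(f"unknown style {style!r}")


def _heavy_atoms(smiles: str) -> int:
    return mol_from_smiles(smiles).GetNumHeavyAtoms()


_FRAME_CACHE: dict[tuple[int, int | None], str] = {}


def _scaffold_frame(scaffold: tuple[int, int | None]) -> str:
    """Murcko framework of the bare scaffold (methyl probe stripped)."""
    frame = _FRAME_CACHE.get(scaffold)
    if frame is None:
        from .scaffolds import bemis_murcko
        frame = bemis_murcko(_assemble(scaffold, None, "C"))
        _FRAME_CACHE[scaffold] = frame
    return frame


def _draw_molecule(rng: np.random.Generator, scaffold: tuple[int, int | None],
                   taken: set[str], max_attempts: int = 200) -> str:
    for _ in range(max_attempts):
        side1 = _SIDE_POOL[rng.integers(len(_SIDE_POOL))]
        side0 = None
        if scaffold[1] is None and rng.random() < 0.5:
            side0 = _SIDE_POOL[rng.integers(len(_SIDE_POOL))]
        smi = _assemble(scaffold, side0, side1)
        if smi is not None and smi not in taken:
            taken.add(smi)
            return smi
    raise GenerationError(
        f"could not draw a fresh molecule on scaffold {scaffold} "
        f"after {max_attempts} attempts")


def generate_target(recipe: FixtureRecipe, target_id: str = "T1") -> TargetDataset:
    """Build one synthetic target data set (actives, decoys and training
    lists) according to the recipe.  Byte-identical output for a fixed
    seed."""
    rng = np.random.default_rng(recipe.seed)
    taken: set[str] = set()

    # partition the scaffold space so that active series are framework-
    # distinct and "easy" decoys never share a framework with an active
    scaffold_order = rng.permutation(len(SCAFFOLDS))
    active_scaffolds: list[tuple[int, int | None]] = []
    active_frames: set[str] = set()
    rest: list[tuple[int, int | None]] = []
    for i in scaffold_order:
        sc = SCAFFOLDS[i]
        frame = _scaffold_frame(sc)
        if len(active_scaffolds) < recipe.n_series and frame not in active_frames:
            active_scaffolds.append(sc)
            active_frames.add(frame)
        else:
            rest.append(sc)
    if len(active_scaffolds) < recipe.n_series:
        raise GenerationError(
            f"scaffold library has fewer than n_series={recipe.n_series} "
            "distinct frameworks")
    other_scaffolds = [sc for sc in rest if _scaffold_frame(sc) not in active_frames]
    if not other_scaffolds and recipe.difficulty < 1.0:
        raise GenerationError("no scaffolds left for dissimilar decoys")

    # actives: round-robin over the series so series sizes differ by <= 1
    active_smiles = []
    for i in range(recipe.n_actives):
        scaffold = active_scaffolds[i % recipe.n_series]
        active_smiles.append(_draw_molecule(rng, scaffold, taken))

    if recipe.style == STYLE_CHEMBL:
        # oversample candidates, keep the most diverse ones
        extra = [_draw_molecule(rng, active_scaffolds[rng.integers(recipe.n_series)],
                                taken) for _ in range(2 * recipe.n_actives)]
        candidates = active_smiles + extra
        picked = pick_diverse(candidates, recipe.n_actives, seed=recipe.seed)
        active_smiles = [candidates[i] for i in picked]

    # decoys
    decoy_smiles: list[str] = []
    active_heavy = [_heavy_atoms(s) for s in active_smiles]
    if recipe.style == STYLE_CHEMBL:
        pool = []
        for _ in range(max(10 * recipe.n_decoys, 200)):
            hard = rng.random() < recipe.difficulty
            pools = active_scaffolds if hard else other_scaffolds
            pool.append(_draw_molecule(rng, pools[rng.integers(len(pools))], taken))
        per_active = max(1, round(recipe.n_decoys / recipe.n_actives))
        chosen = select_decoys_by_atom_count(active_smiles, pool,
                                             per_active=per_active,
                                             seed=recipe.seed)
        decoy_smiles = [pool[i] for i in chosen]
    else:
        attempts = 0
        budget = 200 * recipe.n_decoys + 1000
        while len(decoy_smiles) < recipe.n_decoys:
            attempts += 1
            if attempts > budget:
                raise GenerationError(
                    f"decoy generation exhausted {budget} attempts "
                    f"({len(decoy_smiles)}/{recipe.n_decoys} built)")
            hard = rng.random() < recipe.difficulty
            pools = active_scaffolds if hard else other_scaffolds
            smi = _draw_molecule(rng, pools[rng.integers(len(pools))], taken)
            if recipe.style == STYLE_DUD:
                # property matching: heavy-atom count near some active's
                ref = active_heavy[rng.integers(len(active_heavy))]
                if abs(_heavy_atoms(smi) - ref) > 2:
                    taken.discard(smi)
                    continue
            decoy_smiles.append(smi)

    token = _DATASET_TOKEN[recipe.style]
    actives = [CompoundRecord(
        external_id=f"EXT-A{i}",
        internal_id=make_internal_id(token, target_id, ROLE_ACTIVE, i),
        smiles=s, role=ROLE_ACTIVE, index=i) for i, s in enumerate(active_smiles)]
    decoys = [CompoundRecord(
        external_id=f"EXT-D{i}",
        internal_id=make_internal_id(token, target_id, ROLE_DECOY, i),
        smiles=s, role=ROLE_DECOY, index=i) for i, s in enumerate(decoy_smiles)]

    ds = TargetDataset(target_id=target_id, actives=actives, decoys=decoys)
    ds.training = generate_training_lists(
        ds, n_queries=recipe.n_queries, decoy_fraction=recipe.decoy_fraction,
        repetitions=recipe.repetitions, seed=recipe.seed)
    ds.validate()
    return ds


def generate_collection(style: str, n_targets: int, seed: int = 0,
                        recipe: FixtureRecipe | None = None) -> list[TargetDataset]:
    """Several targets of one style with per-target derived seeds."""
    base = recipe if recipe is not None else default_recipe(style, seed)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_targets):
        sub = int(rng.integers(2 ** 31))
        out.append(generate_target(replace(base, seed=sub), target_id=f"T{i + 1}"))
    return out


# --- curation operators ------------------------------------------------------

def pick_diverse(candidates: Sequence[str], k: int, descriptor: str = "ECFP4",
                 measure: str = "Dice", seed: int = 0) -> list[int]:
    """MaxMin diversity pick: seeded first pick, then greedily add the
    candidate with the largest minimum distance (1 - similarity) to the
    picked set.  Returns indices into ``candidates``."""
    n = len(candidates)
    if k > n:
        raise GenerationError(f"cannot pick {k} of {n} candidates")
    if k == n:
        return list(range(n))
    desc = get_descriptor(descriptor)
    meas = get_measure(measure)
    fps = [compute_fingerprint(s, desc) for s in candidates]
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    picked = [first]
    min_dist = np.array([1.0 - similarity(fps[first], fp, meas) for fp in fps])
    min_dist[first] = -1.0
    while len(picked) < k:
        nxt = int(np.argmax(min_dist))
        picked.append(nxt)
        d = np.array([1.0 - similarity(fps[nxt], fp, meas) for fp in fps])
        min_dist = np.minimum(min_dist, d)
        min_dist[nxt] = -1.0
    return picked


def select_decoys_by_atom_count(actives: Sequence[str], pool: Sequence[str],
                                per_active: int = 2, threshold: float = 0.5,
                                seed: int = 0) -> list[int]:
    """For each active, randomly pick ``per_active`` pool molecules whose
    atom-count-fingerprint (radius-0 circular counts) Dice similarity to
    that active exceeds ``threshold``.  Sampling is without replacement
    across the whole selection.  Returns pool indices."""
    ecfc0 = get_descriptor("ECFC0")
    dice = get_measure("Dice")
    pool_fps = [compute_fingerprint(s, ecfc0) for s in pool]
    rng = np.random.default_rng(seed)
    used: set[int] = set()
    chosen: list[int] = []
    for ai, act in enumerate(actives):
        afp = compute_fingerprint(act, ecfc0)
        eligible = [i for i, pfp in enumerate(pool_fps)
                    if i not in used and similarity(afp, pfp, dice) > threshold]
        if len(eligible) < per_active:
            raise GenerationError(
                f"active #{ai} ({act}): only {len(eligible)} eligible decoys "
                f"(need {per_active}) at Dice > {threshold}")
        take = rng.choice(len(eligible), size=per_active, replace=False)
        for t in sorted(int(x) for x in take):
            used.add(eligible[t])
            chosen.append(eligible[t])
    return chosen


# atoms allowed in non-metal organic molecules; everything else is treated
# as a metal for filtering purposes
NONMETALS = {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}


def filter_compounds(records: Sequence[CompoundRecord], mw_max: float = 700.0,
                     exclude_metals: bool = True) -> list[CompoundRecord]:
    """Drop molecules heavier than ``mw_max`` g/mol and, optionally, any
    containing a metal atom.  Unparsable records are kept (they are flagged
    elsewhere)."""
    out = []
    for rec in records:
        if not rec.smiles_ok:
            out.append(rec)
            continue
        mol = mol_from_smiles(rec.smiles)
        if Descriptors.MolWt(mol) > mw_max:
            continue
        if exclude_metals and any(a.GetSymbol() not in NONMETALS
                                  for a in mol.GetAtoms()):
            continue
        out.append(rec)
    return out
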