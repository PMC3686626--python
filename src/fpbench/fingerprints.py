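"""Named registry of 2D fingerprints.

Fourteen built-in fingerprints spanning three descriptor classes:

* dictionary-based: MACCS (166 public structural keys);
* topological / path-based: AP (atom pairs), TT (topological torsions),
  RDK5 (subgraph hashing up to path length 5), Avalon and its 16384-bit
  variant lAvalon;
* circular: ECFP4/ECFP6 and their 16384-bit variants lECFP4/lECFP6, FCFP4
  (pharmacophoric feature invariants), and the count vectors ECFC4, FCFC4
  and ECFC0 (radius 0 — effectively an atom-type count, used as a baseline).

Bit-string fingerprints default to 1024 bits; "long" variants use 16384
bits.  Count vectors are kept sparse with unfolded 32-bit feature hashes.
All generators delegate to RDKit.  The registry is string-keyed and
user-extensible via :func:`register`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem import rdFingerprintGenerator as _rfg

KIND_BITSTRING = "bitstring"
KIND_COUNTVECTOR = "countvector"

DEFAULT_NBITS = 1024
LONG_NBITS = 16384
MACCS_NBITS = 167  # RDKit's MACCS bit vector; bit 0 is unused padding


class RegistryError(KeyError):
    """Unknown or duplicate fingerprint name."""


class MoleculeError(ValueError):
    """SMILES failed to parse."""


class CapabilityError(RuntimeError):
    """Optional toolkit extension is unavailable."""


@dataclass(frozen=True)
class FingerprintVector:
    """Sparse fingerprint: a map index -> count.

    Bit strings have a finite ``length`` and all counts equal to 1; count
    vectors are unbounded (``length`` is None) with positive integer counts.
    """

    kind: str
    data: dict[int, int]
    length: int | None = None

    def __post_init__(self) -> None:
        if self.kind == KIND_BITSTRING:
            if self.length is None or self.length <= 0:
                raise ValueError("bitstring fingerprint requires a positive length")
        elif self.kind != KIND_COUNTVECTOR:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")

    @property
    def total(self) -> int:
        return sum(self.data.values())

    @property
    def n_on(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class FingerprintDescriptor:
    name: str
    kind: str
    length: int | None
    generator: Callable[[Chem.Mol], FingerprintVector] = field(compare=False, repr=False)

    def __call__(self, mol: Chem.Mol) -> FingerprintVector:
        return self.generator(mol)


def _from_bitvect(bv, length: int) -> FingerprintVector:
    return FingerprintVector(KIND_BITSTRING, {int(i): 1 for i in bv.GetOnBits()},
                             length)


def _from_sparse_counts(sv) -> FingerprintVector:
    return FingerprintVector(
        KIND_COUNTVECTOR,
        {int(k): int(v) for k, v in sv.GetNonzeroElements().items()})


def _morgan_bits(radius: int, nbits: int, features: bool = False):
    kwargs = {"radius": radius, "fpSize": nbits}
    if features:
        kwargs["atomInvariantsGenerator"] = _rfg.GetMorganFeatureAtomInvGen()
    gen = _rfg.GetMorganGenerator(**kwargs)
    return lambda mol: _from_bitvect(gen.GetFingerprint(mol), nbits)


def _morgan_counts(radius: int, features: bool = False):
    kwargs = {"radius": radius}
    if features:
        kwargs["atomInvariantsGenerator"] = _rfg.GetMorganFeatureAtomInvGen()
    gen = _rfg.GetMorganGenerator(**kwargs)
    return lambda mol: _from_sparse_counts(gen.GetSparseCountFingerprint(mol))


def _maccs(mol: Chem.Mol) -> FingerprintVector:
    return _from_bitvect(MACCSkeys.GenMACCSKeys(mol), MACCS_NBITS)


def _atom_pairs():
    gen = _rfg.GetAtomPairGenerator()
    return lambda mol: _from_sparse_counts(gen.GetSparseCountFingerprint(mol))


def _torsions():
    gen = _rfg.GetTopologicalTorsionGenerator()
    return lambda mol: _from_sparse_counts(gen.GetSparseCountFingerprint(mol))


def _rdkit_fp(nbits: int, max_path: int = 5):
    gen = _rfg.GetRDKitFPGenerator(maxPath=max_path, fpSize=nbits)
    return lambda mol: _from_bitvect(gen.GetFingerprint(mol), nbits)


def _avalon(nbits: int):
    # Avalon is an optional RDKit extension; fail at call time with a clear
    # capability error rather than at import time.
    def gen(mol: Chem.Mol) -> FingerprintVector:
        try:
            from rdkit.Avalon import pyAvalonTools
        except ImportError as exc:
            raise CapabilityError(
                "Avalon fingerprints require the RDKit Avalon extension, "
                "which is not available in this toolkit build") from exc
        return _from_bitvect(pyAvalonTools.GetAvalonFP(mol, nBits=nbits), nbits)
    return gen


_REGISTRY: dict[str, FingerprintDescriptor] = {}


def register(name: str, kind: str, length: int | None,
             generator: Callable[[Chem.Mol], FingerprintVector],
             overwrite: bool = False) -> FingerprintDescriptor:
    """Add a fingerprint to the registry (user extension point)."""
    if name in _REGISTRY and not overwrite:
        raise RegistryError(f"fingerprint {name!r} already registered")
    desc = FingerprintDescriptor(name, kind, length, generator)
    _REGISTRY[name] = desc
    return desc


def available() -> list[str]:
    return sorted(_REGISTRY)


def get_descriptor(name: str) -> FingerprintDescriptor:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown fingerprint {name!r}; available: {', '.join(available())}"
        ) from None


def _register_builtins() -> None:
    B, C = KIND_BITSTRING, KIND_COUNTVECTOR
    register("MACCS", B, MACCS_NBITS, _maccs)
    register("AP", C, None, _atom_pairs())
    register("TT", C, None, _torsions())
    register("RDK5", B, DEFAULT_NBITS, _rdkit_fp(DEFAULT_NBITS))
    register("Avalon", B, DEFAULT_NBITS, _avalon(DEFAULT_NBITS))
    register("lAvalon", B, LONG_NBITS, _avalon(LONG_NBITS))
    register("ECFP4", B, DEFAULT_NBITS, _morgan_bits(2, DEFAULT_NBITS))
    register("lECFP4", B, LONG_NBITS, _morgan_bits(2, LONG_NBITS))
    register("ECFP6", B, DEFAULT_NBITS, _morgan_bits(3, DEFAULT_NBITS))
    register("lECFP6", B, LONG_NBITS, _morgan_bits(3, LONG_NBITS))
    register("FCFP4", B, DEFAULT_NBITS, _morgan_bits(2, DEFAULT_NBITS, features=True))
    register("ECFC4", C, None, _morgan_counts(2))
    register("FCFC4", C, None, _morgan_counts(2, features=True))
    register("ECFC0", C, None, _morgan_counts(0))


_register_builtins()


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    return mol


def compute_fingerprint(smiles: str,
                        descriptor: FingerprintDescriptor | str) -> FingerprintVector:
    """Compute one fingerprint for one molecule given as SMILES."""
    if isinstance(descriptor, str):
        descriptor = get_descriptor(descriptor)
    return descriptor(mol_from_smiles(smiles))


def load_fingerprint_config(path: str | Path) -> list[FingerprintDescriptor]:
    """Read a fingerprint-names config file: one canonical name per line,
    ``#`` comments allowed.  Order is preserved and drives column order in
    every downstream table."""
    names: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            names.append(line.split()[0])
    if not names:
        raise RegistryError(f"{path}: no fingerprint names (nothing to benchmark)")
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise RegistryError(f"{path}: duplicate fingerprint names: {sorted(dupes)}")
    return [get_descriptor(n) for n in names]


def folding_collisions(smiles_list: Iterable[str], short_name: str,
                       long_name: str) -> int:
    """Count bits lost to folding: total on-bits in the long variant minus
    on-bits in the short variant, summed over molecules.  Zero means folding
    introduced no collisions for this set."""
    short_d, long_d = get_descriptor(short_name), get_descriptor(long_name)
    lost = 0
    for smi in smiles_list:
        mol = mol_from_smiles(smi)
        lost += long_d(mol).n_on - short_d(mol).n_on
    return lost
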