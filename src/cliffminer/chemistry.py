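"""Structure and potency standardization, fingerprints, similarity, scaffolds.

This module wraps RDKit behind the small set of primitives the rest of the
pipeline needs: canonical (stereo-aware) molecule handling, conversion of
concentration measurements to pKi, 166-key structural fingerprints and
circular atom-environment fingerprints (bond diameter 4), Tanimoto
similarity over feature sets, and Bemis-Murcko-style scaffold extraction.

All fingerprints here are 2D (computed from the molecular graph), so
stereoisomers share a fingerprint even though their canonical forms are kept
distinct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

log = logging.getLogger(__name__)

# RDKit is chatty on malformed input; failures are surfaced as exceptions.
RDLogger.DisableLog("rdApp.error")


class StructureError(ValueError):
    """Raised when a structure encoding cannot be parsed or sanitized."""


class PotencyError(ValueError):
    """Raised when a potency record cannot be converted to a pKi value."""


@dataclass(frozen=True)
class Molecule:
    """A standardized compound structure.

    ``smiles`` is the canonical isomeric SMILES and is the identity used for
    duplicate detection; ``graph_smiles`` drops stereochemistry and is used
    for chirality-cliff categorization.
    """

    smiles: str
    graph_smiles: str
    heavy_atoms: int
    _mol: Chem.Mol = field(repr=False, hash=False, compare=False)

    @property
    def rdkit_mol(self) -> Chem.Mol:
        return self._mol


def standardize_compound(structure_text: str | Chem.Mol, record_id: str | None = None) -> Molecule:
    """Parse and canonicalize a SMILES string (or RDKit mol from an SDF record).

    Two encodings of the same molecular graph + stereochemistry yield the
    same :class:`Molecule`; re-standardizing a canonical form is a no-op.

    Raises
    ------
    StructureError
        If the input cannot be parsed or fails valence sanitization. The
        offending record identifier (when given) is included in the message.
    """
    tag = f" (record {record_id})" if record_id else ""
    if isinstance(structure_text, Chem.Mol):
        mol = structure_text
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # pragma: no cover - rdkit raises subclasses
            raise StructureError(f"unsanitizable structure{tag}: {exc}") from exc
    else:
        mol = Chem.MolFromSmiles(structure_text)
        if mol is None:
            raise StructureError(f"unparseable structure{tag}: {structure_text!r}")
    smiles = Chem.MolToSmiles(mol)
    # round-trip to guarantee canonical atom ordering of the stored mol
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise StructureError(f"empty or invalid structure{tag}: {structure_text!r}")
    return Molecule(
        smiles=smiles,
        graph_smiles=Chem.MolToSmiles(mol, isomericSmiles=False),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        _mol=mol,
    )


# ---------------------------------------------------------------------------
# potency handling
# ---------------------------------------------------------------------------

class MeasurementKind(Enum):
    EQUILIBRIUM = "equilibrium"       # Ki, Kd: assay-independent constants
    IC50 = "ic50"                     # assay-dependent concentrations
    APPROXIMATE = "approximate"       # "% inhibition" and similar annotations

    @classmethod
    def from_standard_type(cls, standard_type: str) -> "MeasurementKind":
        t = standard_type.strip().lower()
        if t in {"ki", "kd", "kb", "ka"}:
            return cls.EQUILIBRIUM
        if t in {"ic50", "ec50", "xc50", "ac50", "gi50"}:
            return cls.IC50
        return cls.APPROXIMATE


#: molar conversion factors, matched case-insensitively
_UNIT_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6, "µm": 1e-6, "μm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
}


@dataclass(frozen=True)
class PotencyRecord:
    """One measurement for one compound against one target."""

    kind: MeasurementKind
    value: float
    units: str | None

    @classmethod
    def from_row(cls, standard_type: str, value: float, units: str) -> "PotencyRecord":
        return cls(MeasurementKind.from_standard_type(standard_type), float(value), units)


def to_pki(record: PotencyRecord) -> float:
    """Convert a concentration measurement to pKi = -log10(molar value).

    Only concentration-typed measurements (equilibrium constants, IC50-like
    values) with positive value and recognized units are convertible.
    Approximate annotations such as "% inhibition" are rejected outright so
    that they can never contaminate a potency comparison.
    """
    if record.kind is MeasurementKind.APPROXIMATE:
        raise PotencyError("approximate annotation")
    if record.value <= 0 or not math.isfinite(record.value):
        raise PotencyError(f"non-positive potency value: {record.value}")
    if record.units is None:
        raise PotencyError("missing units")
    factor = _UNIT_FACTORS.get(record.units.strip().lower())
    if factor is None:
        raise PotencyError(f"unrecognized units: {record.units!r}")
    return -math.log10(record.value * factor)


def pki_to_ki_nm(pki: float) -> float:
    """Inverse of :func:`to_pki` onto nM units (used by writers)."""
    return 10.0 ** (9.0 - pki)


def aggregate_pki(pkis: Iterable[float], span_flag: float = 1.0) -> tuple[float, bool]:
    """Median pKi over repeat measurements of one compound-target pair.

    Returns ``(median, flagged)``; ``flagged`` is True when the span of the
    values exceeds ``span_flag`` log units (discordant measurements).
    """
    values = sorted(pkis)
    if not values:
        raise PotencyError("no pKi values to aggregate")
    n = len(values)
    mid = n // 2
    median = values[mid] if n % 2 else 0.5 * (values[mid - 1] + values[mid])
    return median, (values[-1] - values[0]) > span_flag


# ---------------------------------------------------------------------------
# fingerprints & similarity
# ---------------------------------------------------------------------------

class FingerprintKind(Enum):
    MACCS = "maccs"     # 166 structural keys (fixed-length keyed fingerprint)
    ECFP4 = "ecfp4"     # circular atom environments, bond diameter 4

MACCS_N_KEYS = 166

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)


@dataclass(frozen=True)
class Fingerprint:
    """A molecular fingerprint as a set of on-features.

    For the structural-key kind the features are key indices in 1..166; for
    the circular kind they are hashed atom-environment identifiers.
    """

    kind: FingerprintKind
    features: frozenset[int]

    @property
    def cardinality(self) -> int:
        return len(self.features)


def compute_fingerprint(mol: Molecule, kind: FingerprintKind | str) -> Fingerprint:
    """Deterministic 2D fingerprint of the requested kind."""
    if isinstance(kind, str):
        try:
            kind = FingerprintKind(kind.lower())
        except ValueError:
            raise ValueError(f"unknown fingerprint kind: {kind!r}") from None
    if kind is FingerprintKind.MACCS:
        bv = MACCSkeys.GenMACCSKeys(mol.rdkit_mol)
        # bit 0 of RDKit's 167-bit vector is padding; keys are 1..166
        feats = frozenset(i for i in bv.GetOnBits() if 1 <= i <= MACCS_N_KEYS)
    elif kind is FingerprintKind.ECFP4:
        sparse = _morgan_gen.GetSparseCountFingerprint(mol.rdkit_mol)
        feats = frozenset(sparse.GetNonzeroElements().keys())
    else:  # pragma: no cover
        raise ValueError(f"unknown fingerprint kind: {kind!r}")
    return Fingerprint(kind=kind, features=feats)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient Tc = |A n B| / |A u B| over feature sets.

    Symmetric and bounded in [0, 1]. Two empty fingerprints compare as 0
    (the ratio is undefined; 0 avoids spurious similarity between
    featureless inputs) with a warning.
    """
    if a.kind is not b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    union = len(a.features | b.features)
    if union == 0:
        log.warning("Tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    return len(a.features & b.features) / union


# ---------------------------------------------------------------------------
# scaffolds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """Compound core after removal of terminal R-groups (Murcko framework).

    ``empty`` is set for acyclic molecules, which have no ring framework.
    """

    smiles: str
    empty: bool


def extract_scaffold(mol: Molecule) -> Scaffold:
    """Ring systems plus linkers; terminal acyclic substituents removed.

    Idempotent: the scaffold of a scaffold is itself. Acyclic molecules
    yield an empty-flagged scaffold rather than an error.
    """
    core = MurckoScaffold.GetScaffoldForMol(mol.rdkit_mol)
    if core is None or core.GetNumHeavyAtoms() == 0:
        return Scaffold(smiles="", empty=True)
    return Scaffold(smiles=Chem.MolToSmiles(core), empty=False)
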