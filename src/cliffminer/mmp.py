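"""Matched molecular pairs: single-cut fragmentation, indexing, size rules.

A matched molecular pair (MMP) is a pair of compounds distinguished only by
a structural change at one site — the exchange of one terminal substructure
(the "transformation") around a shared core. Production enumeration uses a
fragment index: every molecule is cut once at every eligible acyclic single
bond, each resulting part is registered as a candidate core keyed by its
canonical form, and compounds meeting at a shared core key with differing
complementary fragments form an MMP. Transformation-size restrictions keep
only small, chemically meaningful replacements.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem

from .chemistry import Molecule

_ATTACH = "*"  # generic attachment-point placeholder in canonical part SMILES


def _part_key(piece: Chem.Mol) -> tuple[str, int]:
    """Canonical SMILES (generic attachment point) + heavy-atom count."""
    piece = Chem.Mol(piece)
    for atom in piece.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    return Chem.MolToSmiles(piece), piece.GetNumHeavyAtoms()


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut decomposition of a molecule into core + fragment.

    The core is the larger of the two parts (ties broken lexicographically);
    both carry one ``*`` attachment point. ``bond_index`` identifies the cut
    bond in the parent's canonical atom ordering.
    """

    parent_smiles: str
    core: str
    fragment: str
    core_heavy: int
    fragment_heavy: int
    bond_index: int

    def reconstruct(self) -> str:
        """Reattach fragment to core; returns the parent canonical SMILES."""
        core = Chem.MolFromSmiles(self.core.replace(_ATTACH, "[1*]"))
        frag = Chem.MolFromSmiles(self.fragment.replace(_ATTACH, "[1*]"))
        params = Chem.MolzipParams()
        params.label = Chem.MolzipLabel.Isotope
        joined = Chem.molzip(Chem.CombineMols(core, frag), params)
        return Chem.MolToSmiles(joined)


def _eligible_bonds(mol: Chem.Mol) -> list[int]:
    """Acyclic single bonds between two heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() is not Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def enumerate_single_cuts(mol: Molecule) -> list[Fragmentation]:
    """All single-cut fragmentations of a molecule.

    One :class:`Fragmentation` per eligible bond; molecules without an
    eligible bond (e.g. plain rings) yield an empty list.
    """
    rdmol = mol.rdkit_mol
    cuts: list[Fragmentation] = []
    for bidx in _eligible_bonds(rdmol):
        pieces = cut_bond(rdmol, bidx)
        if pieces is None:
            continue
        (smi_a, heavy_a), (smi_b, heavy_b) = pieces
        if (heavy_a, smi_a) < (heavy_b, smi_b):
            (smi_a, heavy_a), (smi_b, heavy_b) = (smi_b, heavy_b), (smi_a, heavy_a)
        cuts.append(
            Fragmentation(
                parent_smiles=mol.smiles,
                core=smi_a,
                fragment=smi_b,
                core_heavy=heavy_a,
                fragment_heavy=heavy_b,
                bond_index=bidx,
            )
        )
    return cuts


def cut_bond(rdmol: Chem.Mol, bond_index: int) -> tuple[tuple[str, int], tuple[str, int]] | None:
    """Cut one bond; return ((smiles, heavy), (smiles, heavy)) for the two parts."""
    fragmented = Chem.FragmentOnBonds(rdmol, [bond_index], addDummies=True, dummyLabels=[(1, 1)])
    try:
        pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    except Exception:  # a cut that breaks sanitization is not a valid fragmentation
        return None
    if len(pieces) != 2:
        return None
    return _part_key(pieces[0]), _part_key(pieces[1])


@dataclass(frozen=True)
class SizeRules:
    """Transformation-size restriction for MMPs.

    Defaults: exchanged fragments of at most 13 heavy atoms, differing by at
    most 8 heavy atoms, with a core at least twice the size of each fragment.
    """

    max_fragment_heavy: int = 13
    max_fragment_diff: int = 8
    min_core_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.max_fragment_heavy <= 0 or self.max_fragment_diff <= 0 or self.min_core_ratio <= 0:
            raise ValueError("all size-rule bounds must be positive")


@dataclass(frozen=True)
class MatchedMolecularPair:
    """Unordered compound pair sharing a core and differing by one fragment swap.

    ``id_a < id_b`` by construction, so MMP(A,B) and MMP(B,A) compare equal.
    The transformation is reported from the lower to the higher canonical
    fragment encoding.
    """

    id_a: str
    id_b: str
    core: str
    fragment_a: str
    fragment_b: str
    core_heavy: int
    fragment_a_heavy: int
    fragment_b_heavy: int

    @property
    def transformation(self) -> str:
        lo, hi = sorted((self.fragment_a, self.fragment_b))
        return f"{lo}>>{hi}"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


def _oriented_mmp(
    id_i: str, id_j: str,
    core: str, core_heavy: int,
    frag_i: str, heavy_i: int,
    frag_j: str, heavy_j: int,
) -> MatchedMolecularPair:
    if id_j < id_i:
        id_i, id_j = id_j, id_i
        frag_i, frag_j = frag_j, frag_i
        heavy_i, heavy_j = heavy_j, heavy_i
    return MatchedMolecularPair(
        id_a=id_i, id_b=id_j, core=core,
        fragment_a=frag_i, fragment_b=frag_j,
        core_heavy=core_heavy,
        fragment_a_heavy=heavy_i, fragment_b_heavy=heavy_j,
    )


def find_mmps(compounds: dict[str, Molecule] | Sequence[tuple[str, Molecule]]) -> list[MatchedMolecularPair]:
    """Enumerate all single-cut MMPs over canonicalized, de-duplicated compounds.

    For each pair sharing several valid cores, the MMP with the largest
    shared core is retained (ties broken by lexicographic core SMILES), so
    output is independent of input order. Size rules are NOT applied here;
    see :func:`passes_size_restriction`.
    """
    items = list(compounds.items()) if isinstance(compounds, dict) else list(compounds)
    # core key -> list of (compound id, fragment smiles, fragment heavy, core heavy)
    index: dict[str, list[tuple[str, str, int, int]]] = defaultdict(list)
    for cid, mol in items:
        seen: set[tuple[str, str]] = set()
        for frag in enumerate_single_cuts(mol):
            for core, c_heavy, piece, p_heavy in (
                (frag.core, frag.core_heavy, frag.fragment, frag.fragment_heavy),
                (frag.fragment, frag.fragment_heavy, frag.core, frag.core_heavy),
            ):
                if (core, piece) in seen:
                    continue
                seen.add((core, piece))
                index[core].append((cid, piece, p_heavy, c_heavy))

    # best candidate per compound pair: maximize core size, then min core smiles
    best: dict[tuple[str, str], MatchedMolecularPair] = {}
    for core, entries in index.items():
        if len(entries) < 2:
            continue
        core_heavy = entries[0][3]
        for i in range(len(entries)):
            cid_i, frag_i, heavy_i, _ = entries[i]
            for j in range(i + 1, len(entries)):
                cid_j, frag_j, heavy_j, _ = entries[j]
                if cid_i == cid_j or frag_i == frag_j:
                    continue
                cand = _oriented_mmp(cid_i, cid_j, core, core_heavy,
                                     frag_i, heavy_i, frag_j, heavy_j)
                cur = best.get(cand.pair)
                if cur is None or (cand.core_heavy, _neg_lex(cand.core)) > (cur.core_heavy, _neg_lex(cur.core)):
                    best[cand.pair] = cand
    return sorted(best.values(), key=lambda m: m.pair)


class _neg_lex(str):
    """Reverses lexicographic comparison, so max() picks the smallest string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def passes_size_restriction(mmp: MatchedMolecularPair, rules: SizeRules | None = None) -> bool:
    """True iff the transformation satisfies all size bounds."""
    rules = rules or SizeRules()
    fa, fb = mmp.fragment_a_heavy, mmp.fragment_b_heavy
    if fa > rules.max_fragment_heavy or fb > rules.max_fragment_heavy:
        return False
    if abs(fa - fb) > rules.max_fragment_diff:
        return False
    if mmp.core_heavy < rules.min_core_ratio * max(fa, fb):
        return False
    return True


def size_restricted_mmps(
    compounds: dict[str, Molecule] | Sequence[tuple[str, Molecule]],
    rules: SizeRules | None = None,
) -> list[MatchedMolecularPair]:
    """Convenience: enumerate MMPs, then filter by transformation size."""
    rules = rules or SizeRules()
    return [m for m in find_mmps(compounds) if passes_size_restriction(m, rules)]


def find_mmps_bruteforce(
    compounds: dict[str, Molecule] | Sequence[tuple[str, Molecule]],
) -> list[MatchedMolecularPair]:
    """All-pairs reference enumeration (test oracle; O(n^2) in compounds).

    Compares the full single-cut fragmentation lists of every pair directly,
    with the same largest-core selection rule as :func:`find_mmps`.
    """
    items = list(compounds.items()) if isinstance(compounds, dict) else list(compounds)
    cuts = {cid: enumerate_single_cuts(mol) for cid, mol in items}
    out: list[MatchedMolecularPair] = []
    for i in range(len(items)):
        cid_i = items[i][0]
        for j in range(i + 1, len(items)):
            cid_j = items[j][0]
            best: MatchedMolecularPair | None = None
            for fi in cuts[cid_i]:
                for fj in cuts[cid_j]:
                    for core_i, ch_i, frag_i, fh_i in (
                        (fi.core, fi.core_heavy, fi.fragment, fi.fragment_heavy),
                        (fi.fragment, fi.fragment_heavy, fi.core, fi.core_heavy),
                    ):
                        for core_j, ch_j, frag_j, fh_j in (
                            (fj.core, fj.core_heavy, fj.fragment, fj.fragment_heavy),
                            (fj.fragment, fj.fragment_heavy, fj.core, fj.core_heavy),
                        ):
                            if core_i != core_j or frag_i == frag_j:
                                continue
                            cand = _oriented_mmp(cid_i, cid_j, core_i, ch_i,
                                                 frag_i, fh_i, frag_j, fh_j)
                            if best is None or (
                                (cand.core_heavy, _neg_lex(cand.core))
                                > (best.core_heavy, _neg_lex(best.core))
                            ):
                                best = cand
            if best is not None:
                out.append(best)
    return sorted(out, key=lambda m: m.pair)
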