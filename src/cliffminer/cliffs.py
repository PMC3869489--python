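"""Activity-cliff detection, categorization and threshold calibration.

An activity cliff is a pair of structurally similar compounds, active
against the same target, with a large potency difference. Three similarity
definitions are supported:

* size-restricted MMP formation (the preferred, most conservative default),
* fingerprint Tanimoto similarity at or above a threshold
  (0.85 for the 166 structural keys; 0.56 for circular environments,
  the quantile-equivalent value), and
* an active/inactive mode pairing confirmed inactives with sufficiently
  potent actives (at least pKi 7.0, i.e. 100 nM) — no potency difference is
  computable there.

The potency criterion defaults to at least two orders of magnitude
(delta pKi >= 2.0) on equilibrium constants only. All thresholds are
inclusive so "at least" phrasing holds literally at boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

from .chemistry import (
    Fingerprint,
    FingerprintKind,
    Molecule,
    Scaffold,
    compute_fingerprint,
    extract_scaffold,
    tanimoto,
)
from .mmp import MatchedMolecularPair, SizeRules, find_mmps, passes_size_restriction

DEFAULT_TC_THRESHOLDS = {
    FingerprintKind.MACCS: 0.85,
    FingerprintKind.ECFP4: 0.56,
}

Category = Literal["R-group", "core-change", "chirality"]


@dataclass(frozen=True)
class CliffCriteria:
    """Parameters of an activity-cliff definition.

    ``mode`` selects the similarity criterion; ``delta_pki`` is the potency
    difference threshold in log units (2.0 = 100-fold); ``active_pki`` is
    the minimum potency of the active partner in active/inactive mode
    (7.0 = 100 nM).
    """

    mode: Literal["mmp", "maccs", "ecfp4", "active_inactive"] = "mmp"
    delta_pki: float = 2.0
    tc_threshold: float | None = None
    equilibrium_only: bool = True
    active_pki: float = 7.0
    size_rules: SizeRules = field(default_factory=SizeRules)

    def __post_init__(self) -> None:
        if self.delta_pki <= 0:
            raise ValueError("potency-difference threshold must be positive")
        if self.tc_threshold is not None and not (0 < self.tc_threshold <= 1):
            raise ValueError("Tc threshold must lie in (0, 1]")

    def effective_tc(self, kind: FingerprintKind) -> float:
        return self.tc_threshold if self.tc_threshold is not None else DEFAULT_TC_THRESHOLDS[kind]


@dataclass
class ActivityCliff:
    """A qualified compound pair with its similarity evidence.

    ``isolated`` is None until the pair has been classified by the cliff
    network; ``delta_pki`` is None in active/inactive mode.
    """

    id_a: str
    id_b: str
    target_id: str
    mode: str
    pki_a: float | None
    pki_b: float | None
    delta_pki: float | None
    potent_partner: str
    mmp: MatchedMolecularPair | None = None
    tc: float | None = None
    category: Category | None = None
    isolated: bool | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass
class CliffResult:
    """Cliffs plus the qualifying-pair denominator for frequency surveys."""

    cliffs: list[ActivityCliff]
    qualifying_pairs: list[tuple[str, str]]
    excluded_compounds: list[str] = field(default_factory=list)


def _order(id_a: str, id_b: str, pki: dict[str, float]) -> tuple[str, str]:
    return (id_a, id_b) if id_a < id_b else (id_b, id_a)


def detect_mmp_cliffs(
    compounds: dict[str, Molecule],
    pki: dict[str, float],
    target_id: str,
    mmps: Sequence[MatchedMolecularPair],
    criteria: CliffCriteria | None = None,
) -> CliffResult:
    """Cliffs under the size-restricted-MMP similarity criterion.

    ``mmps`` are assumed already size-restricted; every MMP whose potency
    difference reaches ``criteria.delta_pki`` (inclusive) is a cliff.
    Compounds without a pKi are excluded and reported.
    """
    criteria = criteria or CliffCriteria(mode="mmp")
    excluded = sorted(cid for cid in compounds if cid not in pki)
    cliffs: list[ActivityCliff] = []
    qualifying: list[tuple[str, str]] = []
    for mmp in mmps:
        if mmp.id_a not in pki or mmp.id_b not in pki:
            continue
        qualifying.append(mmp.pair)
        delta = abs(pki[mmp.id_a] - pki[mmp.id_b])
        if delta >= criteria.delta_pki:
            potent = mmp.id_a if pki[mmp.id_a] >= pki[mmp.id_b] else mmp.id_b
            cliffs.append(
                ActivityCliff(
                    id_a=mmp.id_a, id_b=mmp.id_b, target_id=target_id, mode="mmp",
                    pki_a=pki[mmp.id_a], pki_b=pki[mmp.id_b], delta_pki=delta,
                    potent_partner=potent, mmp=mmp,
                )
            )
    cliffs.sort(key=lambda c: c.pair)
    qualifying.sort()
    return CliffResult(cliffs=cliffs, qualifying_pairs=qualifying, excluded_compounds=excluded)


def detect_fingerprint_cliffs(
    compounds: dict[str, Molecule],
    pki: dict[str, float],
    target_id: str,
    kind: FingerprintKind | str,
    criteria: CliffCriteria | None = None,
) -> CliffResult:
    """Cliffs under a fingerprint Tanimoto similarity criterion.

    All pairs at or above the Tc threshold are "qualifying pairs" (the
    survey denominator); those also meeting the potency criterion are
    cliffs.
    """
    if isinstance(kind, str):
        kind = FingerprintKind(kind.lower())
    criteria = criteria or CliffCriteria(mode=kind.value)
    threshold = criteria.effective_tc(kind)
    excluded = sorted(cid for cid in compounds if cid not in pki)
    fps: dict[str, Fingerprint] = {
        cid: compute_fingerprint(mol, kind) for cid, mol in compounds.items() if cid in pki
    }
    cliffs: list[ActivityCliff] = []
    qualifying: list[tuple[str, str]] = []
    for id_a, id_b in combinations(sorted(fps), 2):
        tc = tanimoto(fps[id_a], fps[id_b])
        if tc < threshold:
            continue
        qualifying.append((id_a, id_b))
        delta = abs(pki[id_a] - pki[id_b])
        if delta >= criteria.delta_pki:
            potent = id_a if pki[id_a] >= pki[id_b] else id_b
            cliffs.append(
                ActivityCliff(
                    id_a=id_a, id_b=id_b, target_id=target_id, mode=kind.value,
                    pki_a=pki[id_a], pki_b=pki[id_b], delta_pki=delta,
                    potent_partner=potent, tc=tc,
                )
            )
    return CliffResult(cliffs=cliffs, qualifying_pairs=qualifying, excluded_compounds=excluded)


def detect_active_inactive_cliffs(
    actives: dict[str, Molecule],
    active_pki: dict[str, float],
    confirmed_inactives: dict[str, Molecule],
    target_id: str,
    criteria: CliffCriteria | None = None,
) -> CliffResult:
    """Cliffs pairing potent actives with structurally similar confirmed inactives.

    An active qualifies only at or above ``criteria.active_pki`` (default
    pKi 7.0, i.e. 100 nM). Inactivity must be a confirmed annotation — a
    merely missing potency value never counts. No potency difference is
    defined for these cliffs.
    """
    criteria = criteria or CliffCriteria(mode="active_inactive")
    qualified = {
        cid: mol for cid, mol in actives.items()
        if cid in active_pki and active_pki[cid] >= criteria.active_pki
    }
    merged = dict(qualified)
    merged.update(confirmed_inactives)
    mmps = [m for m in find_mmps(merged) if passes_size_restriction(m, criteria.size_rules)]
    cliffs: list[ActivityCliff] = []
    qualifying: list[tuple[str, str]] = []
    for mmp in mmps:
        in_a, in_b = mmp.id_a in confirmed_inactives, mmp.id_b in confirmed_inactives
        if in_a == in_b:  # active/active handled by standard modes; inactive pairs never qualify
            continue
        qualifying.append(mmp.pair)
        active_id = mmp.id_b if in_a else mmp.id_a
        cliffs.append(
            ActivityCliff(
                id_a=mmp.id_a, id_b=mmp.id_b, target_id=target_id, mode="active_inactive",
                pki_a=active_pki.get(mmp.id_a), pki_b=active_pki.get(mmp.id_b),
                delta_pki=None, potent_partner=active_id, mmp=mmp,
            )
        )
    return CliffResult(cliffs=cliffs, qualifying_pairs=qualifying)


def categorize_cliff(
    cliff: ActivityCliff,
    mol_a: Molecule,
    mol_b: Molecule,
    scaffold_a: Scaffold | None = None,
    scaffold_b: Scaffold | None = None,
) -> Category:
    """Assign a structural category to a cliff.

    chirality: identical molecular graphs, different stereochemistry;
    R-group: identical scaffolds (substituent replacement only);
    core-change: everything else (small modification of the core).
    """
    if mol_a.graph_smiles == mol_b.graph_smiles and mol_a.smiles != mol_b.smiles:
        cat: Category = "chirality"
    else:
        sa = scaffold_a or extract_scaffold(mol_a)
        sb = scaffold_b or extract_scaffold(mol_b)
        cat = "R-group" if sa.smiles == sb.smiles else "core-change"
    cliff.category = cat
    return cat


def calibrate_equivalent_threshold(
    pairs: Sequence[tuple[float, float]],
    ref_threshold: float,
) -> float:
    """Find the target-kind Tc threshold quantile-equivalent to a reference.

    ``pairs`` holds (reference Tc, target Tc) per compound pair. Returns the
    largest target value t such that the fraction of pairs with target
    Tc >= t is at least the fraction with reference Tc >= ``ref_threshold``;
    by construction the two fractions agree within 1/N (exactly, absent
    ties). With no reference pair at or above the threshold the largest
    observed target value is returned.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs with both similarity values")
    ref_vals = [p[0] for p in pairs]
    tgt_vals = sorted((p[1] for p in pairs), reverse=True)
    k = sum(1 for v in ref_vals if v >= ref_threshold)
    if k == 0:
        return tgt_vals[0]
    return tgt_vals[k - 1]
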