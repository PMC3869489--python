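"""Synthetic compound-activity collections with known ground truth.

The generator emulates the shape of a curated bioactivity extraction:
target sets of >= 100 compounds sharing a target, analog series built from a
common scaffold with varied R-groups, Ki-derived pKi values spanning
several log units, and per-compound publication years. Cliffs are planted
with certainty by construction:

* every within-series pair is a single-site analog (scaffold + one R-group),
  so its MMP status is guaranteed;
* "cluster" series contain a few highly potent hubs and many lowly potent
  spokes — every hub-spoke pair is a coordinated cliff;
* "isolated" two-compound series contribute exactly one isolated cliff;
* remaining "plain" series have a narrow potency spread and no cliffs.

Potency offsets are drawn from bounded uniform windows whose margins keep
cliff pairs well above and non-cliff pairs well below the 2-log-unit
threshold, so noise can never cross the boundary. Scaffolds are mutually
non-overlapping ring systems, and a post-generation audit re-runs MMP
enumeration to confirm that the size-restricted MMPs found are exactly the
planted within-series pairs (violations shift the seed and regenerate).

Years are planted so that progression analysis has all three situations:
a cliff whose potent partner gains a strictly later analog (progressed),
a series reported entirely in one year (same-year, not progressed), and a
series whose potent compounds came last (no later analog, not progressed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import pki_to_ki_nm, standardize_compound
from .mmp import SizeRules, size_restricted_mmps

#: substitutable ring systems; mutually non-overlapping so that analogs from
#: different series can never form a small-transformation MMP
SCAFFOLD_TEMPLATES = (
    "c1ccc({r})cc1",             # benzene
    "c1ccnc({r})c1",             # pyridine
    "c1cc({r})ncn1",             # pyrimidine
    "c1ccc2cc({r})ccc2c1",       # naphthalene
    "c1ccc2nc({r})ccc2c1",       # quinoline
    "C1CCC({r})CC1",             # cyclohexane
    "C1CCOC({r})C1",             # tetrahydropyran
    "c1ccc(-c2ccc({r})cc2)cc1",  # biphenyl
    "c1ccc2c(c1)cc({r})[nH]2",   # indole
    "c1ccc2c(c1)oc({r})c2",      # benzofuran
    "c1ccc2c(c1)sc({r})n2",      # benzothiazole
    "C1CC2CCC1CC2{r}",           # bicyclo[2.2.2]octane
    "c1ccc2c(c1)CCC2({r})",      # indane
    "c1cnc2[nH]cc({r})c2c1",     # 5-azaindole
)

#: small substituents (<= 3 heavy atoms) keeping every exchange within the
#: default transformation-size rules on >= 6-atom scaffolds
R_GROUP_LIBRARY = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC",
    "Cl", "F", "Br", "I", "C#N", "[N+](=O)[O-]", "CO", "S", "SC",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic collection."""

    n_sets: int = 3
    set_size: int = 120
    series_size: int = 10
    n_cluster_series: int = 3   # coordinated-cliff plants per set
    hub_count: int = 2          # highly potent compounds per cluster series
    n_isolated_pairs: int = 2   # isolated-cliff plants per set
    scaffold_templates: tuple[str, ...] = SCAFFOLD_TEMPLATES
    r_groups: tuple[str, ...] = R_GROUP_LIBRARY
    pki_mean: float = 6.0       # center of plain-series base potencies
    pki_spread: float = 1.0     # half-width of the base-potency window
    cliff_gap: float = 2.8      # hub offset above the series base window
    low_noise: float = 0.7      # spread of lowly potent members (pairwise < 2)
    high_noise: float = 0.6     # spread of highly potent members
    year_range: tuple[int, int] = (2000, 2012)
    seed: int = 0
    max_retries: int = 5

    def __post_init__(self) -> None:
        if min(self.n_sets, self.set_size, self.series_size, self.hub_count) < 1:
            raise ValueError("all counts must be positive")
        if self.series_size < 3 and self.n_cluster_series > 0:
            raise ValueError("coordinated-cluster series need series_size >= 3")
        if self.hub_count >= self.series_size:
            raise ValueError("hub_count must be smaller than series_size")
        planted_members = self.n_cluster_series * self.series_size + 2 * self.n_isolated_pairs
        if planted_members > self.set_size:
            raise ValueError("planted series exceed the configured set size")
        n_plain = -(-(self.set_size - planted_members) // self.series_size)
        if self.n_cluster_series + self.n_isolated_pairs + n_plain > len(self.scaffold_templates):
            raise ValueError("scaffold library too small for the requested series count")
        if self.series_size > len(self.r_groups):
            raise ValueError("R-group library smaller than series_size")
        if self.low_noise >= 2.0 or self.high_noise >= 2.0:
            raise ValueError("potency noise must stay below the cliff threshold")
        if self.cliff_gap - self.high_noise < 2.0:
            raise ValueError("cliff_gap too small: planted cliffs could fall below 2 log units")

    @property
    def planted_cliffs_per_set(self) -> int:
        return (
            self.n_cluster_series * self.hub_count * (self.series_size - self.hub_count)
            + self.n_isolated_pairs
        )


@dataclass
class GroundTruth:
    """Planted facts for one collection, keyed by target id."""

    mmp_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    cliff_pairs: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    clusters: dict[str, list[list[str]]] = field(default_factory=dict)
    isolated_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    cliff_rate_pct: dict[str, float] = field(default_factory=dict)
    progression: dict[str, dict[tuple[str, str], str]] = field(default_factory=dict)

    def cliff_compounds(self, target_id: str) -> set[str]:
        out: set[str] = set()
        for pair in self.cliff_pairs[target_id]:
            out.update(pair)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mmp_pairs": {t: [list(p) for p in v] for t, v in self.mmp_pairs.items()},
            "cliff_pairs": {
                t: [[a, b, d] for (a, b), d in sorted(v.items())]
                for t, v in self.cliff_pairs.items()
            },
            "clusters": self.clusters,
            "isolated_pairs": {t: [list(p) for p in v] for t, v in self.isolated_pairs.items()},
            "cliff_rate_pct": self.cliff_rate_pct,
            "progression": {
                t: [[a, b, s] for (a, b), s in sorted(v.items())]
                for t, v in self.progression.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gt = cls()
        gt.mmp_pairs = {t: [tuple(p) for p in v] for t, v in payload["mmp_pairs"].items()}
        gt.cliff_pairs = {
            t: {(a, b): d for a, b, d in v} for t, v in payload["cliff_pairs"].items()
        }
        gt.clusters = payload["clusters"]
        gt.isolated_pairs = {t: [tuple(p) for p in v] for t, v in payload["isolated_pairs"].items()}
        gt.cliff_rate_pct = payload["cliff_rate_pct"]
        gt.progression = {
            t: {(a, b): s for a, b, s in v} for t, v in payload["progression"].items()
        }
        return gt


@dataclass
class _Series:
    scaffold: str
    kind: str                # "cluster" | "isolated" | "plain"
    ids: list[str]
    smiles: list[str]
    pki: list[float]
    year: list[int]
    high: list[bool]


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def plant_coordinated_cluster(
    scaffold: str,
    r_groups: list[str],
    ids: list[str],
    base_pki: float,
    hub_count: int,
    years: list[int],
    rng: np.random.Generator,
    cliff_gap: float = 2.8,
    low_noise: float = 0.7,
    high_noise: float = 0.6,
) -> _Series:
    """Build one coordinated-cliff series: potent hubs over lowly potent spokes.

    Every hub-spoke analog pair is a cliff, so the series yields one
    connected cliff-network component of more than two nodes.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("a coordinated cluster needs at least 3 compounds")
    if not 1 <= hub_count < n:
        raise ValueError("hub_count must be in [1, series size)")
    smiles = [scaffold.format(r=r) for r in r_groups[:n]]
    pki, high = [], []
    for i in range(n):
        is_hub = i < hub_count
        offset = (
            cliff_gap + rng.uniform(0.0, high_noise)
            if is_hub
            else rng.uniform(0.0, low_noise)
        )
        pki.append(base_pki + offset)
        high.append(is_hub)
    return _Series(scaffold=scaffold, kind="cluster", ids=list(ids), smiles=smiles,
                   pki=pki, year=list(years), high=high)


def _series_cliffs(series: _Series) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for i in range(len(series.ids)):
        for j in range(i + 1, len(series.ids)):
            delta = abs(series.pki[i] - series.pki[j])
            if series.high[i] != series.high[j]:
                out[_pair(series.ids[i], series.ids[j])] = delta
    return out


def _series_progression(series: _Series) -> dict[tuple[str, str], str]:
    """Apply the progression rule directly to the planted series.

    Within a series every member is an analog of every other, so the potent
    partner of a cliff progressed iff any other member has a strictly later
    year than the cliff's (max-of-pair) year.
    """
    statuses: dict[tuple[str, str], str] = {}
    years = dict(zip(series.ids, series.year))
    pki = dict(zip(series.ids, series.pki))
    for (a, b) in _series_cliffs(series):
        cliff_year = max(years[a], years[b])
        potent = a if pki[a] >= pki[b] else b
        later = any(
            years[cid] > cliff_year for cid in series.ids if cid not in (a, b)
        )
        statuses[(a, b)] = "progressed" if later else "not_progressed"
    return statuses


def _build_target_set(
    target_id: str, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[_Series], dict]:
    year_lo, year_hi = config.year_range
    mid_year = (year_lo + year_hi) // 2
    scaffolds = list(config.scaffold_templates)
    rng.shuffle(scaffolds)
    next_idx = 0
    series_list: list[_Series] = []

    def take_ids(n: int) -> list[str]:
        nonlocal next_idx
        ids = [f"{target_id}-C{next_idx + i:04d}" for i in range(n)]
        next_idx += n
        return ids

    # cluster series: bases above the plain window so hubs top the set
    for c in range(config.n_cluster_series):
        base = config.pki_mean + config.pki_spread * rng.uniform(0.5, 1.0)
        if c == 0:
            # progressed plant: second hub reported two years after the rest
            years = [mid_year] * config.series_size
            years[1] = mid_year + 2
        elif c == 1:
            years = [mid_year] * config.series_size  # same-year: no evidence
        else:
            # potent hubs reported last: nothing later exists
            years = [year_hi] * config.hub_count + [
                int(rng.integers(year_lo, year_hi))
                for _ in range(config.series_size - config.hub_count)
            ]
        r_order = list(config.r_groups)
        rng.shuffle(r_order)
        series_list.append(
            plant_coordinated_cluster(
                scaffolds[len(series_list)], r_order, take_ids(config.series_size),
                base, config.hub_count, years, rng,
                cliff_gap=config.cliff_gap, low_noise=config.low_noise,
                high_noise=config.high_noise,
            )
        )

    # isolated pairs: one high + one low member, own scaffold
    for _ in range(config.n_isolated_pairs):
        base = config.pki_mean + config.pki_spread * rng.uniform(0.2, 0.6)
        r_order = list(config.r_groups)
        rng.shuffle(r_order)
        ids = take_ids(2)
        series_list.append(
            _Series(
                scaffold=scaffolds[len(series_list)], kind="isolated", ids=ids,
                smiles=[scaffolds[len(series_list)].format(r=r) for r in r_order[:2]],
                pki=[
                    base + config.cliff_gap + rng.uniform(0.0, config.high_noise),
                    base + rng.uniform(0.0, config.low_noise),
                ],
                year=[int(rng.integers(year_lo, year_hi + 1)) for _ in range(2)],
                high=[True, False],
            )
        )

    # plain series fill the remainder; narrow spread, no cliffs
    remaining = config.set_size - sum(len(s.ids) for s in series_list)
    while remaining > 0:
        n = min(config.series_size, remaining)
        base = config.pki_mean + config.pki_spread * rng.uniform(-1.0, 0.5)
        r_order = list(config.r_groups)
        rng.shuffle(r_order)
        ids = take_ids(n)
        scaffold = scaffolds[len(series_list)]
        series_list.append(
            _Series(
                scaffold=scaffold, kind="plain", ids=ids,
                smiles=[scaffold.format(r=r) for r in r_order[:n]],
                pki=[base + rng.uniform(0.0, 2 * config.low_noise) for _ in range(n)],
                year=[int(rng.integers(year_lo, year_hi + 1)) for _ in range(n)],
                high=[False] * n,
            )
        )
        remaining -= n

    truth = {
        "mmp_pairs": sorted(
            _pair(s.ids[i], s.ids[j])
            for s in series_list
            for i in range(len(s.ids))
            for j in range(i + 1, len(s.ids))
        ),
        "cliffs": {},
        "clusters": [s.ids for s in series_list if s.kind == "cluster"],
        "isolated": [_pair(*s.ids) for s in series_list if s.kind == "isolated"],
        "progression": {},
    }
    for s in series_list:
        truth["cliffs"].update(_series_cliffs(s))
        truth["progression"].update(_series_progression(s))
    return series_list, truth


def _audit_set(series_list: list[_Series], planted_pairs: list[tuple[str, str]]) -> bool:
    """Check structural uniqueness and exact MMP recovery for one set."""
    compounds = {}
    seen_smiles = set()
    for s in series_list:
        for cid, smi in zip(s.ids, s.smiles):
            mol = standardize_compound(smi, record_id=cid)
            if mol.smiles in seen_smiles:
                return False
            seen_smiles.add(mol.smiles)
            compounds[cid] = mol
    found = sorted(m.pair for m in size_restricted_mmps(compounds, SizeRules()))
    return found == sorted(planted_pairs)


def generate_collection(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a deterministic collection plus its ground-truth sidecar.

    The records table uses the standard input schema (compound_id, smiles,
    target_id, standard_type="Ki", standard_value in nM, standard_units,
    year). Raises on an infeasible configuration, or if the audit keeps
    failing across seed shifts (never observed with the bundled grammar).
    """
    rows = []
    truth = GroundTruth()
    for s in range(config.n_sets):
        target_id = f"T{s + 1:02d}"
        for attempt in range(config.max_retries):
            rng = np.random.default_rng((config.seed + 1000 * attempt) * config.n_sets + s)
            series_list, set_truth = _build_target_set(target_id, config, rng)
            if _audit_set(series_list, set_truth["mmp_pairs"]):
                break
        else:
            raise RuntimeError(
                f"could not generate an audit-clean target set for {target_id}"
            )
        truth.mmp_pairs[target_id] = set_truth["mmp_pairs"]
        truth.cliff_pairs[target_id] = set_truth["cliffs"]
        truth.clusters[target_id] = set_truth["clusters"]
        truth.isolated_pairs[target_id] = set_truth["isolated"]
        truth.progression[target_id] = set_truth["progression"]
        truth.cliff_rate_pct[target_id] = (
            100.0 * len(set_truth["cliffs"]) / len(set_truth["mmp_pairs"])
        )
        for series in series_list:
            for cid, smi, pki, year in zip(series.ids, series.smiles, series.pki, series.year):
                rows.append(
                    {
                        "compound_id": cid,
                        "smiles": smi,
                        "target_id": target_id,
                        "standard_type": "Ki",
                        "standard_value": pki_to_ki_nm(pki),
                        "standard_units": "nM",
                        "year": year,
                    }
                )
    records = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "smiles", "target_id",
            "standard_type", "standard_value", "standard_units", "year",
        ],
    ).sort_values(["target_id", "compound_id"], ignore_index=True)
    return records, truth
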