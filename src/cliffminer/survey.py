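"""Frequency-of-occurrence survey: target-set selection and per-target stats.

A target set is the collection of unique compounds with measured activity
against one target. Sets qualify when, after restriction to
equilibrium-constant measurements and structure-level de-duplication, at
least ``min_size`` compounds remain (100 by default). Per target, the
survey reports the proportion of activity cliffs among all qualifying
similar pairs, the proportion of compounds participating in cliffs, and the
isolated/coordinated split; aggregation is an unweighted mean over targets
(a pair-weighted alternative is reported alongside).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import (
    MeasurementKind,
    Molecule,
    PotencyRecord,
    aggregate_pki,
    standardize_compound,
    to_pki,
)
from .cliffs import CliffResult
from .network import CliffNetwork, IsolationSummary

log = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 100
SIZE_STABILITY_MARKER = 200  # set size above which cliff rates stabilize


@dataclass
class TargetSet:
    """Unique equilibrium-constant compounds sharing one target."""

    target_id: str
    compounds: dict[str, Molecule]
    pki: dict[str, float]
    year: dict[str, int]
    flagged_discordant: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.compounds)


@dataclass
class SelectionLog:
    """Per-stage tallies from target-set selection (part of the contract)."""

    records_read: int = 0
    rejected_measurement_type: int = 0
    rejected_bad_value: int = 0
    rejected_structure: int = 0
    duplicates_merged: int = 0
    targets_excluded: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "records_read": self.records_read,
            "rejected_measurement_type": self.rejected_measurement_type,
            "rejected_bad_value": self.rejected_bad_value,
            "rejected_structure": self.rejected_structure,
            "duplicates_merged": self.duplicates_merged,
            "targets_excluded": dict(sorted(self.targets_excluded.items())),
        }


def select_target_sets(
    records: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SET_SIZE,
    require_all_equilibrium: bool = False,
) -> tuple[list[TargetSet], SelectionLog]:
    """Build qualifying target sets from a standardized compound-activity table.

    Expected columns: compound_id, smiles, target_id, standard_type,
    standard_value, standard_units, year. Per target the set is restricted
    to equilibrium-constant records (IC50 and approximate annotations are
    never mixed in), repeat measurements of one compound are merged as the
    median pKi, duplicates by canonical structure are merged, and targets
    with fewer than ``min_size`` surviving compounds are excluded.

    With ``require_all_equilibrium`` the stricter reading applies: a target
    is discarded outright if any of its compounds lacks an equilibrium
    constant.
    """
    sel = SelectionLog(records_read=len(records))
    sets: list[TargetSet] = []
    for target_id, group in records.groupby("target_id", sort=True):
        per_compound: dict[str, list[float]] = {}
        compound_smiles: dict[str, str] = {}
        compound_year: dict[str, int] = {}
        non_equilibrium = 0
        for row in group.itertuples(index=False):
            rec = PotencyRecord.from_row(row.standard_type, row.standard_value, row.standard_units)
            if rec.kind is not MeasurementKind.EQUILIBRIUM:
                non_equilibrium += 1
                continue
            try:
                pki = to_pki(rec)
            except Exception as exc:
                sel.rejected_bad_value += 1
                log.info("rejected record %s/%s: %s", target_id, row.compound_id, exc)
                continue
            cid = str(row.compound_id)
            per_compound.setdefault(cid, []).append(pki)
            compound_smiles[cid] = row.smiles
            compound_year[cid] = int(row.year)
        sel.rejected_measurement_type += non_equilibrium
        if non_equilibrium and log.isEnabledFor(logging.INFO):
            log.info("target %s: dropped %d non-equilibrium records", target_id, non_equilibrium)
        if require_all_equilibrium and non_equilibrium > 0:
            sel.targets_excluded[str(target_id)] = "contains non-equilibrium measurements"
            continue

        # standardize, merge repeat measurements and structural duplicates
        by_structure: dict[str, tuple[str, list[float], int]] = {}
        for cid in sorted(per_compound):
            try:
                mol = standardize_compound(compound_smiles[cid], record_id=cid)
            except Exception as exc:
                sel.rejected_structure += 1
                log.info("rejected structure %s: %s", cid, exc)
                continue
            if mol.smiles in by_structure:
                kept_id, values, year = by_structure[mol.smiles]
                values.extend(per_compound[cid])
                by_structure[mol.smiles] = (kept_id, values, min(year, compound_year[cid]))
                sel.duplicates_merged += 1
            else:
                by_structure[mol.smiles] = (cid, list(per_compound[cid]), compound_year[cid])

        compounds: dict[str, Molecule] = {}
        pki_map: dict[str, float] = {}
        year_map: dict[str, int] = {}
        flagged: set[str] = set()
        for smiles, (cid, values, year) in by_structure.items():
            median, discordant = aggregate_pki(values)
            compounds[cid] = standardize_compound(smiles)
            pki_map[cid] = median
            year_map[cid] = year
            if discordant:
                flagged.add(cid)
        if len(compounds) < min_size:
            sel.targets_excluded[str(target_id)] = (
                f"only {len(compounds)} qualifying compounds (< {min_size})"
            )
            continue
        sets.append(
            TargetSet(
                target_id=str(target_id), compounds=compounds, pki=pki_map,
                year=year_map, flagged_discordant=flagged,
            )
        )
    return sets, sel


@dataclass
class TargetStats:
    """Per-target cliff frequency statistics."""

    target_id: str
    mode: str
    set_size: int
    n_qualifying_pairs: int
    n_cliffs: int
    n_cliff_compounds: int
    n_isolated: int
    n_coordinated: int
    excluded: bool = False  # True when no qualifying pairs exist

    @property
    def cliff_pct(self) -> float | None:
        if self.n_qualifying_pairs == 0:
            return None
        return 100.0 * self.n_cliffs / self.n_qualifying_pairs

    @property
    def compound_pct(self) -> float:
        return 100.0 * self.n_cliff_compounds / self.set_size

    @property
    def isolated_pct(self) -> float | None:
        if self.n_cliffs == 0:
            return None
        return 100.0 * self.n_isolated / self.n_cliffs

    @property
    def coordinated_pct(self) -> float | None:
        if self.n_cliffs == 0:
            return None
        return 100.0 * self.n_coordinated / self.n_cliffs


def per_target_statistics(
    target_set: TargetSet,
    result: CliffResult,
    network: CliffNetwork,
    isolation: IsolationSummary,
    mode: str,
) -> TargetStats:
    """Assemble the per-target frequency statistics for one detection mode."""
    return TargetStats(
        target_id=target_set.target_id,
        mode=mode,
        set_size=target_set.size,
        n_qualifying_pairs=len(result.qualifying_pairs),
        n_cliffs=len(result.cliffs),
        n_cliff_compounds=network.n_nodes,
        n_isolated=isolation.n_isolated,
        n_coordinated=isolation.n_coordinated,
        excluded=len(result.qualifying_pairs) == 0,
    )


@dataclass
class SurveySummary:
    """Aggregate of per-target stats for one mode (unweighted over targets)."""

    mode: str
    n_targets: int
    n_targets_excluded: int
    mean_cliff_pct: float
    mean_compound_pct: float
    mean_isolated_pct: float | None
    mean_coordinated_pct: float | None
    pair_weighted_cliff_pct: float
    cliff_pct_five_number: tuple[float, float, float, float, float]
    compound_pct_five_number: tuple[float, float, float, float, float]


def aggregate_survey(stats_list: list[TargetStats]) -> SurveySummary:
    """Unweighted mean over targets of cliff%, compound% and the isolation split.

    Targets with zero qualifying pairs contribute nothing and are counted in
    the exclusion tally. The pair-weighted rate (total cliffs over total
    qualifying pairs) is reported alongside the per-target mean.
    """
    usable = [s for s in stats_list if not s.excluded]
    if not usable:
        raise ValueError("no target statistics with qualifying pairs to aggregate")
    mode = usable[0].mode
    cliff_pcts = [s.cliff_pct for s in usable]
    compound_pcts = [s.compound_pct for s in usable]
    iso = [s.isolated_pct for s in usable if s.isolated_pct is not None]
    coord = [s.coordinated_pct for s in usable if s.coordinated_pct is not None]
    total_pairs = sum(s.n_qualifying_pairs for s in usable)
    total_cliffs = sum(s.n_cliffs for s in usable)
    return SurveySummary(
        mode=mode,
        n_targets=len(usable),
        n_targets_excluded=len(stats_list) - len(usable),
        mean_cliff_pct=float(np.mean(cliff_pcts)),
        mean_compound_pct=float(np.mean(compound_pcts)),
        mean_isolated_pct=float(np.mean(iso)) if iso else None,
        mean_coordinated_pct=float(np.mean(coord)) if coord else None,
        pair_weighted_cliff_pct=100.0 * total_cliffs / total_pairs,
        cliff_pct_five_number=five_number_summary(cliff_pcts),
        compound_pct_five_number=five_number_summary(compound_pcts),
    )


def five_number_summary(values) -> tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) of a sample.

    Quartile convention: linear interpolation between order statistics — for
    probability p over n sorted values v, h = p*(n-1), and the quantile is
    v[floor(h)] + (h - floor(h)) * (v[floor(h)+1] - v[floor(h)]). Stated
    explicitly (rather than delegating to a library call) so summaries are
    reproducible bit-exactly.
    """
    v = sorted(float(x) for x in values)
    if not v:
        raise ValueError("empty input")
    n = len(v)

    def quantile(p: float) -> float:
        h = p * (n - 1)
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return (v[0], quantile(0.25), quantile(0.5), quantile(0.75), v[-1])


def size_frequency_table(stats_list: list[TargetStats], size_marker: int = SIZE_STABILITY_MARKER) -> pd.DataFrame:
    """Set size vs cliff frequency, with dispersion split at the size marker.

    One row per target (cliff%, compound%, above-marker flag at
    size >= marker, inclusive). The frame's ``attrs['dispersion']`` carries
    the variance of cliff% separately for the below- and above-marker
    groups — small sets fluctuate; large sets are expected to be stable.
    """
    rows = []
    for s in sorted(stats_list, key=lambda s: (s.set_size, s.target_id)):
        rows.append(
            {
                "target_id": s.target_id,
                "set_size": s.set_size,
                "cliff_pct": s.cliff_pct if s.cliff_pct is not None else math.nan,
                "compound_pct": s.compound_pct,
                "above_marker": s.set_size >= size_marker,
            }
        )
    df = pd.DataFrame(rows, columns=["target_id", "set_size", "cliff_pct", "compound_pct", "above_marker"])
    dispersion = {}
    for flag, label in ((False, "below_marker"), (True, "above_marker")):
        vals = df.loc[df["above_marker"] == flag, "cliff_pct"].dropna()
        dispersion[label] = float(np.var(vals)) if len(vals) else None
    df.attrs["dispersion"] = dispersion
    df.attrs["size_marker"] = size_marker
    return df
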