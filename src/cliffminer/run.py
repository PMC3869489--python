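"""End-to-end runs tying the stages together behind the CLI.

Each run reads one compound-activity table, applies one activity-cliff
definition across all qualifying target sets, and writes its reports plus a
``manifest.json`` echoing every effective parameter and the per-stage
tallies, which is sufficient to reproduce the run. All outputs are sorted
on canonical keys (target id, then compound-id pair) so repeated runs are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)

from . import io as cio
from .chemistry import FingerprintKind, standardize_compound
from .cliffs import (
    ActivityCliff,
    CliffCriteria,
    CliffResult,
    categorize_cliff,
    detect_active_inactive_cliffs,
    detect_fingerprint_cliffs,
    detect_mmp_cliffs,
)
from .mmp import SizeRules, size_restricted_mmps
from .network import (
    CliffNetwork,
    build_cliff_network,
    classify_isolated_coordinated,
    export_edge_list,
    export_graphml,
    potency_color_attributes,
)
from .pathway import (
    build_analog_graph,
    cliff_progression_status,
    find_optimization_pathway,
    pathway_success_rates,
    top_decile,
)
from .survey import (
    TargetSet,
    aggregate_survey,
    per_target_statistics,
    select_target_sets,
    size_frequency_table,
)
from .synthetic import GeneratorConfig, generate_collection


@dataclass(frozen=True)
class RunConfig:
    """Effective parameters of one pipeline run."""

    input: str | None = None
    out_dir: str = "out"
    mode: str = "mmp"                 # mmp | maccs | ecfp4 | active_inactive
    min_set_size: int = 100
    delta_pki: float = 2.0
    tc_threshold: float | None = None
    active_pki: float = 7.0
    frag_max: int = 13
    frag_diff_max: int = 8
    core_ratio: float = 2.0
    require_all_equilibrium: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        return replace(cfg, **{k: v for k, v in overrides.items() if v is not None})

    @property
    def size_rules(self) -> SizeRules:
        return SizeRules(
            max_fragment_heavy=self.frag_max,
            max_fragment_diff=self.frag_diff_max,
            min_core_ratio=self.core_ratio,
        )

    @property
    def criteria(self) -> CliffCriteria:
        return CliffCriteria(
            mode=self.mode, delta_pki=self.delta_pki, tc_threshold=self.tc_threshold,
            active_pki=self.active_pki, size_rules=self.size_rules,
        )

    def manifest(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class TargetRun:
    """Per-target intermediate results of one mined run."""

    target_set: TargetSet
    result: CliffResult
    network: CliffNetwork
    isolation: object
    mmps: list = field(default_factory=list)


def _read_input(config: RunConfig) -> pd.DataFrame:
    if config.input is None:
        raise ValueError("no input table configured")
    path = Path(config.input)
    if path.suffix.lower() == ".sdf":
        return cio.read_sdf(path)
    return cio.read_compound_table(path)


def mine_collection(records: pd.DataFrame, config: RunConfig) -> tuple[dict[str, TargetRun], dict]:
    """Select target sets and detect, categorize and classify cliffs per target."""
    active_records = records
    if "confirmed_inactive" in records.columns:
        active_records = records[~records["confirmed_inactive"].astype(bool)]
    target_sets, selection = select_target_sets(
        active_records, min_size=config.min_set_size,
        require_all_equilibrium=config.require_all_equilibrium,
    )
    runs: dict[str, TargetRun] = {}
    for ts in target_sets:
        mmps = []
        if config.mode == "mmp":
            mmps = size_restricted_mmps(ts.compounds, config.size_rules)
            result = detect_mmp_cliffs(ts.compounds, ts.pki, ts.target_id, mmps, config.criteria)
        elif config.mode in ("maccs", "ecfp4"):
            result = detect_fingerprint_cliffs(
                ts.compounds, ts.pki, ts.target_id,
                FingerprintKind(config.mode), config.criteria,
            )
            mmps = size_restricted_mmps(ts.compounds, config.size_rules)
        elif config.mode == "active_inactive":
            inactive_rows = records[
                records.get("confirmed_inactive", pd.Series(False, index=records.index)).astype(bool)
                & (records["target_id"].astype(str) == ts.target_id)
            ]
            inactives = {
                str(r.compound_id): standardize_compound(r.smiles, record_id=str(r.compound_id))
                for r in inactive_rows.itertuples(index=False)
            }
            result = detect_active_inactive_cliffs(
                ts.compounds, ts.pki, inactives, ts.target_id, config.criteria
            )
            for cid, mol in inactives.items():
                ts.compounds.setdefault(cid, mol)
        else:
            raise ValueError(f"unknown mode: {config.mode!r}")
        for cliff in result.cliffs:
            categorize_cliff(cliff, ts.compounds[cliff.id_a], ts.compounds[cliff.id_b])
        network = build_cliff_network(result.cliffs, pki=ts.pki, target_id=ts.target_id)
        isolation = classify_isolated_coordinated(network, result.cliffs)
        runs[ts.target_id] = TargetRun(
            target_set=ts, result=result, network=network, isolation=isolation, mmps=mmps
        )
    return runs, selection.as_dict()


def run_simulate(config: RunConfig, generator: GeneratorConfig | None = None) -> Path:
    """Generate a synthetic collection; write CSV + ground-truth sidecar."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = generator or GeneratorConfig(seed=config.seed)
    records, truth = generate_collection(gen)
    cio.write_compound_table(records, out / "compounds.csv")
    truth.to_json(out / "ground_truth.json")
    manifest = config.manifest()
    manifest["generator"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in gen.__dict__.items()
    }
    manifest["records_written"] = int(len(records))
    cio.write_manifest(manifest, out / "manifest.json")
    return out


def run_mine(config: RunConfig) -> Path:
    """Full per-target pipeline; writes cliff + MMP tables and networks."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = _read_input(config)
    runs, tallies = mine_collection(records, config)
    all_cliffs: list[ActivityCliff] = []
    all_mmps = []
    for target_id in sorted(runs):
        tr = runs[target_id]
        all_cliffs.extend(tr.result.cliffs)
        all_mmps.extend((target_id, m) for m in tr.mmps)
        _export_network(tr.network, target_id, out)
    cio.write_cliff_table(all_cliffs, out / "cliffs.csv")
    cio.write_mmp_table(all_mmps, out / "mmps.csv")
    manifest = config.manifest()
    manifest["tallies"] = tallies
    manifest["n_target_sets"] = len(runs)
    manifest["n_cliffs"] = len(all_cliffs)
    cio.write_manifest(manifest, out / "manifest.json")
    return out


def run_network(config: RunConfig) -> Path:
    """Networks only (GraphML + edge lists) for the configured mode."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = _read_input(config)
    runs, tallies = mine_collection(records, config)
    for target_id in sorted(runs):
        _export_network(runs[target_id].network, target_id, out)
    manifest = config.manifest()
    manifest["tallies"] = tallies
    cio.write_manifest(manifest, out / "manifest.json")
    return out


def _export_network(network: CliffNetwork, target_id: str, out: Path) -> None:
    if not network.n_nodes:
        return
    pkis = [network.graph.nodes[n].get("pki") for n in network.graph.nodes]
    if all(p is not None for p in pkis):
        potency_color_attributes(network)
    export_graphml(network, out / f"network_{target_id}.graphml")
    export_edge_list(network, out / f"edges_{target_id}.csv")


def _stats_frame(stats_list) -> pd.DataFrame:
    rows = []
    for s in stats_list:
        rows.append(
            {
                "target_id": s.target_id, "mode": s.mode, "set_size": s.set_size,
                "n_qualifying_pairs": s.n_qualifying_pairs, "n_cliffs": s.n_cliffs,
                "n_cliff_compounds": s.n_cliff_compounds,
                "cliff_pct": s.cliff_pct, "compound_pct": s.compound_pct,
                "isolated_pct": s.isolated_pct, "coordinated_pct": s.coordinated_pct,
                "excluded": s.excluded,
            }
        )
    return pd.DataFrame(rows).sort_values("target_id", ignore_index=True)


def run_survey(config: RunConfig) -> Path:
    """Frequency survey: per-target stats, aggregate summary, size table."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = _read_input(config)
    runs, tallies = mine_collection(records, config)
    stats = [
        per_target_statistics(tr.target_set, tr.result, tr.network, tr.isolation, config.mode)
        for _, tr in sorted(runs.items())
    ]
    if not stats or all(s.excluded for s in stats):
        log.warning("no qualifying target sets; writing empty survey outputs")
        for name in ("per_target_stats.csv", "summary.csv", "size_frequency.csv"):
            (out / name).write_text("")
        manifest = config.manifest()
        manifest["tallies"] = tallies
        manifest["n_target_sets"] = 0
        cio.write_manifest(manifest, out / "manifest.json")
        return out
    _stats_frame(stats).to_csv(out / "per_target_stats.csv", index=False)
    summary = aggregate_survey(stats)
    srow = {
        "mode": summary.mode,
        "n_targets": summary.n_targets,
        "n_targets_excluded": summary.n_targets_excluded,
        "mean_cliff_pct": summary.mean_cliff_pct,
        "mean_compound_pct": summary.mean_compound_pct,
        "mean_isolated_pct": summary.mean_isolated_pct,
        "mean_coordinated_pct": summary.mean_coordinated_pct,
        "pair_weighted_cliff_pct": summary.pair_weighted_cliff_pct,
    }
    pd.DataFrame([srow]).to_csv(out / "summary.csv", index=False)
    sft = size_frequency_table(stats)
    sft.to_csv(out / "size_frequency.csv", index=False)
    manifest = config.manifest()
    manifest["tallies"] = tallies
    manifest["quartile_convention"] = "linear interpolation between order statistics"
    manifest["dispersion"] = sft.attrs["dispersion"]
    manifest["five_number_cliff_pct"] = list(summary.cliff_pct_five_number)
    manifest["five_number_compound_pct"] = list(summary.compound_pct_five_number)
    cio.write_manifest(manifest, out / "manifest.json")
    return out


def run_pathways(config: RunConfig) -> Path:
    """Progression + pathway-success reports under the MMP analog relation."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = _read_input(config)
    runs, tallies = mine_collection(records, config)
    prog_lines = ["target_id,compound_id_1,compound_id_2,cliff_year,status"]
    rate_rows = []
    path_lines = ["target_id,compound_id,group,reached,path_length,witness_path"]
    for target_id in sorted(runs):
        tr = runs[target_id]
        ts = tr.target_set
        graph = build_analog_graph(ts, tr.mmps)
        decile = top_decile(ts)
        for cliff in sorted(tr.result.cliffs, key=lambda c: c.pair):
            status = cliff_progression_status(cliff, graph, ts.year)
            cliff_year = max(ts.year[cliff.id_a], ts.year[cliff.id_b])
            prog_lines.append(
                f"{target_id},{cliff.id_a},{cliff.id_b},{cliff_year},{status}"
            )
        cliff_compounds = {cid for c in tr.result.cliffs for cid in c.pair}
        non_cliff = sorted(set(ts.compounds) - cliff_compounds)
        for group, members in (("cliff", sorted(cliff_compounds)), ("non_cliff", non_cliff)):
            for cid in members:
                res = find_optimization_pathway(graph, cid, decile.members)
                path_lines.append(
                    f"{target_id},{cid},{group},{res.reached},{res.length},{'|'.join(res.path)}"
                )
        rates = pathway_success_rates(graph, cliff_compounds, non_cliff, decile.members)
        rate_rows.append(
            {
                "target_id": target_id,
                "rate_cliff_pct": rates.rate_cliff_pct,
                "rate_noncliff_pct": rates.rate_noncliff_pct,
                "n_cliff": rates.n_cliff, "n_noncliff": rates.n_noncliff,
                "n_cliff_in_decile": rates.n_cliff_in_decile,
                "n_noncliff_in_decile": rates.n_noncliff_in_decile,
            }
        )
    (out / "progression.csv").write_text("\n".join(prog_lines) + "\n")
    (out / "pathway_paths.csv").write_text("\n".join(path_lines) + "\n")
    pd.DataFrame(rate_rows).to_csv(out / "pathway_success.csv", index=False)
    manifest = config.manifest()
    manifest["tallies"] = tallies
    cio.write_manifest(manifest, out / "manifest.json")
    return out
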