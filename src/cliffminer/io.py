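"""Readers and writers for the tabular interchange formats.

Input is the standard compound-activity CSV schema (compound_id, smiles,
target_id, standard_type, standard_value, standard_units, year) with an
optional ``confirmed_inactive`` flag column; SDF input is accepted with the
same fields as record properties. Output tables are written with full-
precision floats and canonical row ordering, so repeated runs are
byte-identical and tables round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .cliffs import ActivityCliff
from .mmp import MatchedMolecularPair

REQUIRED_COLUMNS = [
    "compound_id", "smiles", "target_id",
    "standard_type", "standard_value", "standard_units", "year",
]


def read_compound_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a compound-activity CSV."""
    df = pd.read_csv(path, dtype={"compound_id": str, "target_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")
    return df


def read_sdf(path: str | Path) -> pd.DataFrame:
    """Read an SDF whose records carry the standard fields as properties.

    The structure block provides the molecule; SMILES are regenerated from
    it, so downstream standardization behaves exactly as for CSV input.
    """
    rows = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        rows.append(
            {
                "compound_id": str(props.get("compound_id", mol.GetProp("_Name") if mol.HasProp("_Name") else "")),
                "smiles": Chem.MolToSmiles(mol),
                "target_id": str(props.get("target_id", "")),
                "standard_type": props.get("standard_type", "Ki"),
                "standard_value": float(props.get("standard_value", "nan")),
                "standard_units": props.get("standard_units", "nM"),
                "year": int(props.get("year", 0)),
            }
        )
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def write_compound_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


MMP_COLUMNS = [
    "compound_id_1", "compound_id_2", "core", "fragment_1", "fragment_2",
    "core_size", "frag1_size", "frag2_size",
]


def write_mmp_table(mmps: list[tuple[str, MatchedMolecularPair]], path: str | Path) -> None:
    """MMP CSV; rows sorted by (target, pair) for reproducible diffs."""
    lines = ["target_id," + ",".join(MMP_COLUMNS)]
    for target_id, m in sorted(mmps, key=lambda tm: (tm[0], tm[1].pair)):
        lines.append(
            ",".join(
                [
                    target_id, m.id_a, m.id_b, m.core, m.fragment_a, m.fragment_b,
                    str(m.core_heavy), str(m.fragment_a_heavy), str(m.fragment_b_heavy),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


CLIFF_COLUMNS = [
    "compound_id_1", "compound_id_2", "target_id", "mode",
    "core", "fragment_1", "fragment_2", "core_size", "frag1_size", "frag2_size",
    "tc", "pki_1", "pki_2", "delta_pki", "category", "potent_partner", "isolated",
]


def write_cliff_table(cliffs: list[ActivityCliff], path: str | Path) -> None:
    """Activity-cliff CSV with full similarity evidence; round-trips exactly."""
    lines = [",".join(CLIFF_COLUMNS)]
    for c in sorted(cliffs, key=lambda c: (c.target_id, c.pair)):
        m = c.mmp
        lines.append(
            ",".join(
                [
                    c.id_a, c.id_b, c.target_id, c.mode,
                    m.core if m else "", m.fragment_a if m else "", m.fragment_b if m else "",
                    str(m.core_heavy) if m else "", str(m.fragment_a_heavy) if m else "",
                    str(m.fragment_b_heavy) if m else "",
                    _fmt(c.tc), _fmt(c.pki_a), _fmt(c.pki_b), _fmt(c.delta_pki),
                    c.category or "", c.potent_partner,
                    "" if c.isolated is None else str(c.isolated),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cliff_table(path: str | Path) -> list[ActivityCliff]:
    """Inverse of :func:`write_cliff_table`."""
    cliffs: list[ActivityCliff] = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split(",")
    if header != CLIFF_COLUMNS:
        raise ValueError(f"unexpected cliff-table header in {path}")
    for line in lines[1:]:
        f = dict(zip(CLIFF_COLUMNS, line.split(",")))
        mmp = None
        if f["core"]:
            mmp = MatchedMolecularPair(
                id_a=f["compound_id_1"], id_b=f["compound_id_2"], core=f["core"],
                fragment_a=f["fragment_1"], fragment_b=f["fragment_2"],
                core_heavy=int(f["core_size"]),
                fragment_a_heavy=int(f["frag1_size"]), fragment_b_heavy=int(f["frag2_size"]),
            )
        cliffs.append(
            ActivityCliff(
                id_a=f["compound_id_1"], id_b=f["compound_id_2"],
                target_id=f["target_id"], mode=f["mode"],
                pki_a=float(f["pki_1"]) if f["pki_1"] else None,
                pki_b=float(f["pki_2"]) if f["pki_2"] else None,
                delta_pki=float(f["delta_pki"]) if f["delta_pki"] else None,
                potent_partner=f["potent_partner"], mmp=mmp,
                tc=float(f["tc"]) if f["tc"] else None,
                category=f["category"] or None,
                isolated=None if f["isolated"] == "" else f["isolated"] == "True",
            )
        )
    return cliffs


def write_manifest(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
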