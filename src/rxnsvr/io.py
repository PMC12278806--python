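"""On-disk formats: reaction CSV, template TSV, .smi pools, split manifests.

Reaction datasets are CSV with columns record_id, product_smiles,
reactant1_smiles, reactant2_smiles, pki, provenance. Templates are TSV with
columns template_id, retro_smarts, query1_smarts, query2_smarts.
Building-block pools are .smi files (SMILES<TAB>identifier).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import chem
from .errors import ConfigurationError
from .templates import ReactantPair, ReactionRecord, RetroTemplate

REACTION_COLUMNS = [
    "record_id",
    "product_smiles",
    "reactant1_smiles",
    "reactant2_smiles",
    "pki",
    "provenance",
]


def write_records(records: Sequence[ReactionRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "product_smiles": r.product.smiles,
            "reactant1_smiles": r.pair.r1.smiles,
            "reactant2_smiles": r.pair.r2.smiles,
            "pki": repr(float(r.y)),
            "provenance": r.provenance,
        }
        for r in records
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REACTION_COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def read_records(path: str | Path) -> list[ReactionRecord]:
    df = pd.read_csv(path, dtype={"record_id": str}, float_precision="round_trip")
    missing = set(REACTION_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"reaction CSV {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ReactionRecord(
                record_id=str(row.record_id),
                product=chem.canonicalize(row.product_smiles),
                pair=ReactantPair(
                    r1=chem.canonicalize(row.reactant1_smiles),
                    r2=chem.canonicalize(row.reactant2_smiles),
                ),
                y=float(row.pki),
                provenance=str(row.provenance),
            )
        )
    return records


def write_templates(templates: Sequence[RetroTemplate], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["template_id", "retro_smarts", "query1_smarts", "query2_smarts"])
        for t in templates:
            writer.writerow([t.template_id, t.retro_smarts, *t.component_queries])


def read_templates(path: str | Path) -> list[RetroTemplate]:
    df = pd.read_csv(path, sep="\t")
    return [
        RetroTemplate(
            template_id=str(row.template_id),
            retro_smarts=str(row.retro_smarts),
            component_queries=(str(row.query1_smarts), str(row.query2_smarts)),
        )
        for row in df.itertuples(index=False)
    ]


def write_pool(pool: Sequence[chem.MoleculeRef], path: str | Path, prefix: str = "BB") -> None:
    with open(path, "w") as fh:
        for i, mol in enumerate(pool):
            fh.write(f"{mol.smiles}\t{prefix}{i:06d}\n")


def read_pool(path: str | Path) -> list[chem.MoleculeRef]:
    """Read a .smi pool, deduplicated by canonical SMILES, order preserved."""
    out: list[chem.MoleculeRef] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            smiles = line.split()[0]
            ref = chem.canonicalize(smiles)
            if ref.smiles not in seen:
                seen.add(ref.smiles)
                out.append(ref)
    return out


def write_split_manifest(assignments: dict[str, str], path: str | Path) -> None:
    """CSV of record_id -> assignment in {train, test, discarded}."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["record_id", "assignment"])
        for record_id in sorted(assignments):
            writer.writerow([record_id, assignments[record_id]])
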