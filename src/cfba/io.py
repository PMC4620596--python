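"""Model serialization (versioned JSON schema) and tabular result export.

The model format is a plain JSON document with schema id ``cfba-model/1``.
Loading is strict: unknown fields and unknown schema versions are rejected
with field-level messages.  Infinite bounds are encoded as the strings
``"inf"`` / ``"-inf"``.

Trajectories, variability envelopes, scan results and kcat tables are
exchanged as tidy TSV (one row per variable per interval).
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd

from .calibrate import KcatTable
from .model import (
    CFBAModel,
    CapacityConstraint,
    Compound,
    MaintenanceConstraint,
    QuotaConstraint,
    Reaction,
)

__all__ = [
    "SCHEMA_ID",
    "ModelFormatError",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
    "write_kcat_table",
    "read_kcat_table",
    "config_hash",
]

SCHEMA_ID = "cfba-model/1"


class ModelFormatError(ValueError):
    """A model file violates the schema."""


def _enc(x: float) -> float | str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return x


def _dec(x) -> float:
    if isinstance(x, str):
        if x == "inf":
            return math.inf
        if x == "-inf":
            return -math.inf
        raise ModelFormatError(f"invalid numeric value {x!r}")
    return float(x)


def model_to_dict(model: CFBAModel) -> dict:
    return {
        "schema": SCHEMA_ID,
        "name": model.name,
        "time_unit": model.time_unit,
        "biomass_start_cap": model.biomass_start_cap,
        "externals": list(model.externals),
        "compounds": [
            {"id": c.id, "kind": c.kind, "biomass_weight": c.biomass_weight}
            for c in model.compounds
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(r.stoichiometry),
                "reversible": r.reversible,
                "lower_bound": _enc(r.lower_bound),
                "upper_bound": _enc(r.upper_bound),
                "light_driven": r.light_driven,
            }
            for r in model.reactions
        ],
        "capacity_constraints": [
            {
                "catalyst": c.catalyst_id,
                "terms": [[rid, inv] for rid, inv in c.terms],
                "light_modulated": c.light_modulated,
            }
            for c in model.capacity_constraints
        ],
        "quota_constraints": [
            {"members": list(q.members), "fraction": q.fraction, "enforce": q.enforce}
            for q in model.quota_constraints
        ],
        "maintenance_constraints": [
            {"flux_terms": dict(m.flux_terms), "biomass_coefficient": m.biomass_coefficient}
            for m in model.maintenance_constraints
        ],
    }


def _check_fields(obj: dict, allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ModelFormatError(f"unknown field(s) {sorted(unknown)} in {where}")
    missing = required - set(obj)
    if missing:
        raise ModelFormatError(f"missing field(s) {sorted(missing)} in {where}")


def model_from_dict(doc: dict) -> CFBAModel:
    if not isinstance(doc, dict):
        raise ModelFormatError("model document must be a JSON object")
    if doc.get("schema") != SCHEMA_ID:
        raise ModelFormatError(
            f"unsupported schema version {doc.get('schema')!r}; expected {SCHEMA_ID!r}"
        )
    _check_fields(
        doc,
        {
            "schema", "name", "time_unit", "biomass_start_cap", "externals",
            "compounds", "reactions", "capacity_constraints",
            "quota_constraints", "maintenance_constraints",
        },
        {"schema", "name", "compounds", "reactions"},
        "model",
    )
    compounds = []
    for c in doc["compounds"]:
        _check_fields(c, {"id", "kind", "biomass_weight"}, {"id", "kind"}, f"compound {c.get('id')!r}")
        compounds.append(Compound(c["id"], c["kind"], float(c.get("biomass_weight", 0.0))))
    reactions = []
    for r in doc["reactions"]:
        _check_fields(
            r,
            {"id", "stoichiometry", "reversible", "lower_bound", "upper_bound", "light_driven"},
            {"id", "stoichiometry"},
            f"reaction {r.get('id')!r}",
        )
        reactions.append(
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                reversible=bool(r.get("reversible", False)),
                lower_bound=_dec(r.get("lower_bound", 0.0)),
                upper_bound=_dec(r.get("upper_bound", "inf")),
                light_driven=bool(r.get("light_driven", False)),
            )
        )
    caps = []
    for c in doc.get("capacity_constraints", []):
        _check_fields(c, {"catalyst", "terms", "light_modulated"}, {"catalyst", "terms"},
                      f"capacity constraint {c.get('catalyst')!r}")
        caps.append(
            CapacityConstraint(
                c["catalyst"],
                tuple((rid, float(inv)) for rid, inv in c["terms"]),
                light_modulated=bool(c.get("light_modulated", False)),
            )
        )
    quotas = []
    for q in doc.get("quota_constraints", []):
        _check_fields(q, {"members", "fraction", "enforce"}, {"members", "fraction"}, "quota constraint")
        quotas.append(
            QuotaConstraint(
                tuple(q["members"]), float(q["fraction"]), q.get("enforce", "all_timepoints")
            )
        )
    maints = []
    for m in doc.get("maintenance_constraints", []):
        _check_fields(m, {"flux_terms", "biomass_coefficient"}, {"flux_terms"}, "maintenance constraint")
        maints.append(
            MaintenanceConstraint(
                {k: float(v) for k, v in m["flux_terms"].items()},
                biomass_coefficient=float(m.get("biomass_coefficient", 0.0)),
            )
        )
    return CFBAModel(
        name=doc["name"],
        compounds=compounds,
        reactions=reactions,
        capacity_constraints=caps,
        quota_constraints=quotas,
        maintenance_constraints=maints,
        biomass_start_cap=float(doc.get("biomass_start_cap", 1.0)),
        externals=tuple(doc.get("externals", ())),
        time_unit=doc.get("time_unit", "h"),
    )


def save_model(model: CFBAModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def load_model(path: str | Path) -> CFBAModel:
    try:
        text = Path(path).read_text()
    except OSError as e:
        raise ModelFormatError(f"cannot read model file {path}: {e}") from e
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ModelFormatError(
            f"model file {path} is not valid JSON: {e.msg} at offset {e.pos}"
        ) from e
    return model_from_dict(doc)


def write_kcat_table(table: KcatTable, path: str | Path) -> None:
    rows = [
        {"reaction_id": rid, "catalyst_id": cat, "kcat_per_h": k}
        for (rid, cat), k in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["reaction_id", "catalyst_id", "kcat_per_h"]).to_csv(
        path, sep="\t", index=False
    )


def read_kcat_table(path: str | Path) -> KcatTable:
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "catalyst_id", "kcat_per_h"}
    if not required <= set(df.columns):
        raise ValueError(f"kcat table must have columns {sorted(required)}")
    table = KcatTable()
    for _, row in df.iterrows():
        table.kcats[(row["reaction_id"], row["catalyst_id"])] = float(row["kcat_per_h"])
    return table


def config_hash(config: dict) -> str:
    """Stable hash of a run configuration for reproducible run manifests."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
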