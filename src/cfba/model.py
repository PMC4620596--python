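"""Core data model for conditional flux balance analysis (cFBA).

A cFBA model is an ordinary stoichiometric network augmented with three
ingredients that make growth *conditional* on the cell's own composition:

* compounds are partitioned into a *balanced* set (instantaneous mass
  balance, ``S_B v = 0``, like classic FBA metabolites) and a *dynamic* set
  whose amounts ``M`` accumulate over time via an explicit Euler update;
* *capacity constraints* tie every flux to the amount of the dynamic
  compound that catalyzes it, ``sum_i v_i / kcat_ij <= M_j``;
* *quota* and *maintenance* constraints force the synthesis of
  non-catalytic biomass components and a biomass-proportional ATP demand.

Biomass is the weighted sum ``b = w^T M`` over dynamic compounds, and the
objective of the surrounding optimization is the cyclic growth factor
``alpha`` with ``M(T) >= alpha * M(0)`` componentwise over one period.

All quantities use a single consistent unit system: amounts in arbitrary
"amount" units, time in hours (``time_unit``), fluxes in amount/h, and
capacity coefficients (inverse catalytic efficiencies) in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "Compound",
    "Reaction",
    "CapacityConstraint",
    "QuotaConstraint",
    "MaintenanceConstraint",
    "CFBAModel",
    "ValidationReport",
    "validate_model",
    "biomass",
    "scale_kcat",
]

BALANCED = "balanced"
DYNAMIC = "dynamic"
ALL_TIMEPOINTS = "all_timepoints"
START_ONLY = "start_only"


@dataclass(frozen=True)
class Compound:
    """A chemical species.

    ``kind`` is ``"balanced"`` (steady state at every interval) or
    ``"dynamic"`` (accumulates; part of the amount vector M).
    ``biomass_weight`` is the weight w_j of the compound in the biomass sum;
    balanced compounds must have weight 0.
    """

    id: str
    kind: str
    biomass_weight: float = 0.0


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry over compound ids.

    ``light_driven`` marks environmental light-input reactions whose upper
    bound is forced to zero during dark intervals (e.g. photon uptake).
    """

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = math.inf
    light_driven: bool = False


@dataclass(frozen=True)
class CapacityConstraint:
    """``sum_i inverse_kcat_i * v_i <= M_catalyst`` (amounts at interval start).

    ``terms`` is a tuple of ``(reaction_id, inverse_kcat)`` pairs with
    inverse kcats in hours.  ``light_modulated`` rows additionally carry the
    per-interval factor gamma^k multiplying every inverse kcat (varying
    light acting on pigment-limited light harvesting).
    """

    catalyst_id: str
    terms: tuple[tuple[str, float], ...]
    light_modulated: bool = False


@dataclass(frozen=True)
class QuotaConstraint:
    """``sum_{j in members} M_j >= fraction * b`` at gridpoints.

    ``enforce`` is ``"all_timepoints"`` or ``"start_only"`` (e.g. a DNA
    quota that must hold only at the beginning of the cycle).
    """

    members: tuple[str, ...]
    fraction: float
    enforce: str = ALL_TIMEPOINTS


@dataclass(frozen=True)
class MaintenanceConstraint:
    """``sum_i flux_terms_i * v_i - biomass_coefficient * b >= 0`` per interval.

    Covers both forms used in diurnal models: flux coupling rows such as
    ``v_Maint - 0.05 v_ATPase >= 0`` (``biomass_coefficient = 0``) and
    biomass-proportional demands ``v_Maint >= 0.00641 b``.
    """

    flux_terms: Mapping[str, float]
    biomass_coefficient: float = 0.0


@dataclass
class CFBAModel:
    """A complete cFBA model.

    ``externals`` lists environmental boundary species (e.g. photon): they
    appear in reaction stoichiometries and are mass-balanced exactly like
    balanced compounds, but they are not cellular compounds and are not part
    of ``compounds``.
    """

    name: str
    compounds: list[Compound]
    reactions: list[Reaction]
    capacity_constraints: list[CapacityConstraint] = field(default_factory=list)
    quota_constraints: list[QuotaConstraint] = field(default_factory=list)
    maintenance_constraints: list[MaintenanceConstraint] = field(default_factory=list)
    biomass_start_cap: float = 1.0
    externals: tuple[str, ...] = ()
    time_unit: str = "h"

    # -- derived views -------------------------------------------------

    @property
    def dynamic_compounds(self) -> list[Compound]:
        return [c for c in self.compounds if c.kind == DYNAMIC]

    @property
    def balanced_compounds(self) -> list[Compound]:
        return [c for c in self.compounds if c.kind == BALANCED]

    @property
    def dynamic_ids(self) -> list[str]:
        return [c.id for c in self.dynamic_compounds]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def weights(self) -> np.ndarray:
        """Biomass weight vector over dynamic compounds (model order)."""
        return np.array([c.biomass_weight for c in self.dynamic_compounds])

    def compound(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrices(self) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
        """Return ``(S_B, S_A)``: balanced-row (incl. externals) and dynamic-row
        blocks of the stoichiometric matrix, columns in reaction order."""
        bal_ids = [c.id for c in self.balanced_compounds] + list(self.externals)
        dyn_ids = self.dynamic_ids
        bal_index = {cid: i for i, cid in enumerate(bal_ids)}
        dyn_index = {cid: i for i, cid in enumerate(dyn_ids)}
        sb = sparse.lil_matrix((len(bal_ids), len(self.reactions)))
        sa = sparse.lil_matrix((len(dyn_ids), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for cid, coef in rxn.stoichiometry.items():
                if cid in bal_index:
                    sb[bal_index[cid], j] = coef
                elif cid in dyn_index:
                    sa[dyn_index[cid], j] = coef
                else:
                    raise KeyError(f"reaction {rxn.id!r} references unknown compound {cid!r}")
        return sb.tocsr(), sa.tocsr()


def biomass(M: np.ndarray, w: np.ndarray) -> float:
    """Biomass ``b = w^T M``, the weighted sum over dynamic compound amounts."""
    M = np.asarray(M, dtype=float)
    w = np.asarray(w, dtype=float)
    if M.shape != w.shape:
        raise ValueError(f"dimension mismatch: M has shape {M.shape}, w has shape {w.shape}")
    return float(w @ M)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _producers(model: CFBAModel, cid: str) -> list[str]:
    out = []
    for r in model.reactions:
        coef = r.stoichiometry.get(cid, 0.0)
        if coef > 0 or (coef < 0 and r.reversible):
            out.append(r.id)
    return out


def validate_model(model: CFBAModel) -> ValidationReport:
    """Check every structural invariant of a model; never raises.

    Returns a report whose ``errors`` list is empty iff the model is usable
    by the LP assembler.
    """
    rep = ValidationReport()
    err, warn = rep.errors.append, rep.warnings.append

    ids = [c.id for c in model.compounds] + list(model.externals)
    dupes = {i for i in ids if ids.count(i) > 1}
    for d in sorted(dupes):
        err(f"duplicate compound id {d!r}")
    known = set(ids)
    dynamic = {c.id for c in model.compounds if c.kind == DYNAMIC}

    for c in model.compounds:
        if c.kind not in (BALANCED, DYNAMIC):
            err(f"compound {c.id!r}: unknown kind {c.kind!r}")
        if c.kind == BALANCED and c.biomass_weight != 0:
            err(f"balanced compound {c.id!r} has nonzero biomass weight")
        if c.biomass_weight < 0:
            err(f"compound {c.id!r} has negative biomass weight")

    rids = [r.id for r in model.reactions]
    for d in sorted({i for i in rids if rids.count(i) > 1}):
        err(f"duplicate reaction id {d!r}")
    for r in model.reactions:
        if not r.stoichiometry:
            err(f"reaction {r.id!r} has empty stoichiometry")
        for cid in r.stoichiometry:
            if cid not in known:
                err(f"reaction {r.id!r} references unknown compound {cid!r}")
        if not r.reversible and r.lower_bound < 0:
            err(f"irreversible reaction {r.id!r} has negative lower bound")
        if r.lower_bound > r.upper_bound:
            err(f"reaction {r.id!r} has lower bound above upper bound")

    rid_set = set(rids)
    seen_pairs: set[tuple[str, str]] = set()
    for cap in model.capacity_constraints:
        if cap.catalyst_id not in dynamic:
            err(f"capacity catalyst {cap.catalyst_id!r} is not a dynamic compound")
        if not cap.terms:
            err(f"capacity constraint for {cap.catalyst_id!r} has no terms")
        for rid, inv in cap.terms:
            if rid not in rid_set:
                err(f"capacity constraint for {cap.catalyst_id!r} references unknown reaction {rid!r}")
            if not (inv > 0 and math.isfinite(inv)):
                err(f"capacity constraint for {cap.catalyst_id!r}: inverse kcat for {rid!r} must be positive")
            pair = (cap.catalyst_id, rid)
            if pair in seen_pairs:
                err(f"reaction {rid!r} appears twice in capacity constraints of {cap.catalyst_id!r}")
            seen_pairs.add(pair)

    weights = {c.id: c.biomass_weight for c in model.compounds}
    for q in model.quota_constraints:
        if not (0 < q.fraction < 1):
            err(f"quota fraction {q.fraction} not in (0, 1)")
        if q.enforce not in (ALL_TIMEPOINTS, START_ONLY):
            err(f"quota enforce mode {q.enforce!r} unknown")
        for m in q.members:
            if m not in dynamic:
                err(f"quota member {m!r} is not a dynamic compound")
            elif weights.get(m, 0.0) <= 0:
                err(f"quota member {m!r} has non-positive biomass weight")
            elif not _producers(model, m):
                err(f"unproducible quota compound {m!r}")

    for mt in model.maintenance_constraints:
        if not any(v != 0 for v in mt.flux_terms.values()) and mt.biomass_coefficient == 0:
            err("maintenance constraint with all-zero terms")
        for rid in mt.flux_terms:
            if rid not in rid_set:
                err(f"maintenance constraint references unknown reaction {rid!r}")

    if not model.biomass_start_cap > 0:
        err(f"biomass_start_cap must be positive, got {model.biomass_start_cap}")

    for cid in sorted(dynamic):
        touched = any(cid in r.stoichiometry for r in model.reactions)
        if not touched:
            warn(f"dynamic compound {cid!r} is never produced or consumed")

    return rep


def scale_kcat(model: CFBAModel, catalyst_id: str, fold: float) -> CFBAModel:
    """Return a copy with every kcat of ``catalyst_id`` multiplied by ``fold``
    (inverse kcats divided by ``fold``)."""
    if not fold > 0:
        raise ValueError("fold change must be positive")
    found = False
    caps = []
    for cap in model.capacity_constraints:
        if cap.catalyst_id == catalyst_id:
            found = True
            caps.append(
                replace(cap, terms=tuple((rid, inv / fold) for rid, inv in cap.terms))
            )
        else:
            caps.append(cap)
    if not found:
        raise KeyError(f"no capacity constraint with catalyst {catalyst_id!r}")
    return replace(model, capacity_constraints=caps)
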