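"""Light profiles, robustness scans and trajectory summaries.

The scenario layer builds the per-interval light environment (binary
day/night or a bell-shaped intensity curve), runs fold-change scans of
catalytic efficiencies, detects synthesis reactions that stay active in
darkness, and summarizes trajectories as relative biomass composition and
capacity utilization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import LightProfile, TimeGrid
from .model import CFBAModel, scale_kcat
from .optimizer import NoGrowthError, Trajectory, maximize_alpha

__all__ = [
    "binary_light",
    "bell_light",
    "ScanResult",
    "kcat_scan",
    "night_activity",
    "composition_timecourse",
    "capacity_utilization",
]


def binary_light(grid: TimeGrid) -> LightProfile:
    """Constant full light during the light phase, none in the dark phase.

    Light harvesting is then limited only by the amount of pigments
    (gamma = 1 in every light interval); photon-driven uptake is shut off
    in dark intervals.
    """
    is_light = grid.is_light
    return LightProfile(gamma=np.ones(grid.n_t), dark=~is_light)


def bell_light(grid: TimeGrid, peak: float = 1.0) -> LightProfile:
    """Bell-shaped light intensity over the light phase.

    The intensity is ``I(t) = peak * sin^2(pi * t / T_L)`` for t in the
    light phase and zero in the dark (a smooth bell with maximum ``peak``
    at midday and integral ``peak * T_L / 2``).  The effective factor on
    light-modulated capacity rows is ``gamma^k = 1 / I(t_mid)`` at the
    interval midpoint; zero-intensity intervals are treated as dark.
    """
    if peak <= 0:
        raise ValueError("peak intensity must be positive")
    T_L = grid.light_hours
    gamma = np.ones(grid.n_t)
    dark = ~grid.is_light
    if T_L > 0:
        for k in range(grid.n_t):
            if dark[k]:
                continue
            intensity = peak * math.sin(math.pi * grid.midpoints[k] / T_L) ** 2
            if intensity <= 1e-12:
                dark[k] = True
            else:
                gamma[k] = 1.0 / intensity
    return LightProfile(gamma=gamma, dark=dark)


@dataclass
class ScanResult:
    """Outcome of a fold-change scan of one catalyst's kcats."""

    catalyst_id: str
    fold_changes: list[float]
    alpha_curve: list[float]
    composition: list[dict[str, float] | None]
    night_active: list[set[str] | None]
    status: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, a, s in zip(self.fold_changes, self.alpha_curve, self.status):
            rows.append((self.catalyst_id, f, a, s))
        return pd.DataFrame(rows, columns=["catalyst", "fold_change", "alpha", "status"])


def kcat_scan(
    model: CFBAModel,
    grid: TimeGrid,
    light: LightProfile,
    catalyst_id: str,
    fold_changes,
    *,
    night_tol: float = 1e-6,
    **solve_kwargs,
) -> ScanResult:
    """Re-run growth maximization with the catalyst's kcats scaled by each
    fold change, recording alpha, end-of-period composition, and the set of
    synthesis reactions active in darkness.

    Infeasibility at the lower growth bound is recorded as status
    ``"no-growth-infeasible"`` rather than raised.
    """
    folds = sorted(float(f) for f in fold_changes)
    result = ScanResult(catalyst_id, folds, [], [], [], [])
    for f in folds:
        perturbed = scale_kcat(model, catalyst_id, f)
        try:
            alpha, traj = maximize_alpha(perturbed, grid, light, **solve_kwargs)
        except NoGrowthError:
            result.alpha_curve.append(float("nan"))
            result.composition.append(None)
            result.night_active.append(None)
            result.status.append("no-growth-infeasible")
            continue
        b_end = float(traj.biomass_series[-1])
        comp = {
            cid: float(traj.M[-1, j] / b_end) if b_end > 0 else 0.0
            for j, cid in enumerate(perturbed.dynamic_ids)
        }
        active = night_activity(traj, tol=night_tol) if np.any(light.dark) else set()
        result.alpha_curve.append(alpha)
        result.composition.append(comp)
        result.night_active.append(active)
        result.status.append("ok")
    return result


def _synthesis_reactions(model: CFBAModel) -> list[str]:
    dynamic = set(model.dynamic_ids)
    return [
        r.id
        for r in model.reactions
        if any(coef > 0 and cid in dynamic for cid, coef in r.stoichiometry.items())
    ]


def night_activity(traj: Trajectory, tol: float = 1e-6) -> set[str]:
    """Synthesis reactions whose integrated dark-phase flux exceeds
    ``tol`` times their integrated total flux over the cycle."""
    dark = traj.light.dark
    dt = traj.grid.dt
    active = set()
    rxn_ids = traj.model.reaction_ids
    for rid in _synthesis_reactions(traj.model):
        j = rxn_ids.index(rid)
        total = float(np.abs(traj.v[:, j]) @ dt)
        dark_int = float(np.abs(traj.v[dark, j]) @ dt[dark]) if dark.any() else 0.0
        if total > 0 and dark_int > tol * total:
            active.add(rid)
    return active


def composition_timecourse(
    traj: Trajectory, w: np.ndarray | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Relative biomass composition and total biomass per gridpoint.

    Returns a DataFrame of composition shares (rows = gridpoints, columns =
    weight-positive compounds, each row summing to 1 where biomass is
    positive) and the biomass series b^k.
    """
    w = traj.model.weights if w is None else np.asarray(w, dtype=float)
    if w.shape != (len(traj.model.dynamic_ids),):
        raise ValueError("weight vector does not match the dynamic compounds")
    b = traj.M @ w
    cols = [cid for j, cid in enumerate(traj.model.dynamic_ids) if w[j] > 0]
    idx = [j for j, _ in enumerate(traj.model.dynamic_ids) if w[j] > 0]
    shares = np.zeros((traj.M.shape[0], len(cols)))
    pos = b > 0
    shares[pos] = (traj.M[pos][:, idx] * w[idx]) / b[pos, None]
    return pd.DataFrame(shares, columns=cols), b


def capacity_utilization(traj: Trajectory) -> pd.DataFrame:
    """Per-interval utilization of each capacity row.

    Utilization is (sum_i coef_i gamma^k v_i^k) / M_catalyst^{k-1}; NaN
    where the catalyst amount is ~0.  Rows are indexed by catalyst id.
    """
    model, grid, light = traj.model, traj.grid, traj.light
    rxn_index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    dyn_index = {cid: j for j, cid in enumerate(model.dynamic_ids)}
    out = np.full((len(model.capacity_constraints), grid.n_t), np.nan)
    labels = []
    for i, cap in enumerate(model.capacity_constraints):
        labels.append(cap.catalyst_id)
        jcat = dyn_index[cap.catalyst_id]
        for k in range(grid.n_t):
            factor = light.gamma[k] if cap.light_modulated else 1.0
            lhs = sum(inv * factor * traj.v[k, rxn_index[rid]] for rid, inv in cap.terms)
            M = traj.M[k, jcat]
            if M > 1e-12:
                out[i, k] = lhs / M
    return pd.DataFrame(out, index=labels, columns=range(1, grid.n_t + 1))
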