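"""Assembly of the global linear program for a fixed growth factor alpha.

For a model with ``n_d`` dynamic compounds and ``n_r`` reactions on a grid
of ``n_t`` intervals, the LP variables are stacked as

    x = [M^0, ..., M^{n_t}, v^1, ..., v^{n_t}]

and the constraint blocks are

* ``steady_state``   S_B v^k = 0 for every interval (balanced compounds and
  external boundary species such as photon);
* ``euler_update``   M^k = M^{k-1} + dt_k S_A v^k;
* ``capacity``       sum_i inv_kcat_ij (gamma^k) v_i^k <= M_j^{k-1} — flux
  capacity in an interval depends on the catalyst amount at the interval's
  *start*;
* ``quota``          sum_{j in members} M_j^k >= fraction * w^T M^k at every
  gridpoint (or only k = 0 for start-only quotas);
* ``maintenance``    sum_i c_i v_i^k >= coeff * w^T M^{k-1} per interval;
* ``cyclic_growth``  M^{n_t} >= alpha * M^0 componentwise (equality in
  strict mode);
* ``start_biomass``  w^T M^0 = B0 by default (the inequality form <= B0
  alone would admit the degenerate all-zero start).

Flux bounds and ``M >= 0`` are carried as variable bounds; light-driven
reactions get an upper bound of zero in dark intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .grid import LightProfile, TimeGrid
from .model import CFBAModel, validate_model

__all__ = ["LinearProgram", "assemble_lp", "check_solution"]


@dataclass
class LinearProgram:
    """Assembled LP in ``A_eq x = b_eq``, ``A_ub x <= b_ub``, ``lb <= x <= ub`` form.

    ``blocks`` maps a block name to ``(kind, start, stop)`` row ranges so
    every constraint row is traceable to its origin.
    """

    model: CFBAModel
    grid: TimeGrid
    light: LightProfile
    alpha: float
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    blocks: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    @property
    def n_d(self) -> int:
        return len(self.model.dynamic_ids)

    @property
    def n_r(self) -> int:
        return len(self.model.reactions)

    @property
    def n_vars(self) -> int:
        return (self.grid.n_t + 1) * self.n_d + self.grid.n_t * self.n_r

    def m_slice(self, k: int) -> slice:
        """Columns of the amount vector M^k (k = 0..n_t)."""
        return slice(k * self.n_d, (k + 1) * self.n_d)

    def v_slice(self, k: int) -> slice:
        """Columns of the flux vector v^k (k = 1..n_t)."""
        off = (self.grid.n_t + 1) * self.n_d
        return slice(off + (k - 1) * self.n_r, off + k * self.n_r)

    def split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Reshape a solution vector into (M, v) arrays of shapes
        ``(n_t+1, n_d)`` and ``(n_t, n_r)``."""
        n_t, n_d, n_r = self.grid.n_t, self.n_d, self.n_r
        M = np.asarray(x[: (n_t + 1) * n_d]).reshape(n_t + 1, n_d)
        v = np.asarray(x[(n_t + 1) * n_d : self.n_vars]).reshape(n_t, n_r)
        return M, v


class _Builder:
    """Accumulates sparse rows for one matrix (eq or ub)."""

    def __init__(self, n_vars: int):
        self.n_vars = n_vars
        self.rows: list[int] = []
        self.cols: list[int] = []
        self.vals: list[float] = []
        self.rhs: list[float] = []
        self.n_rows = 0

    def add_row(self, cols: np.ndarray | list[int], vals: np.ndarray | list[float], rhs: float):
        n = len(cols)
        self.rows.extend([self.n_rows] * n)
        self.cols.extend(int(c) for c in cols)
        self.vals.extend(float(v) for v in vals)
        self.rhs.append(float(rhs))
        self.n_rows += 1

    def matrix(self) -> tuple[sparse.csr_matrix, np.ndarray]:
        A = sparse.coo_matrix(
            (self.vals, (self.rows, self.cols)), shape=(self.n_rows, self.n_vars)
        ).tocsr()
        return A, np.array(self.rhs)


def assemble_lp(
    model: CFBAModel,
    grid: TimeGrid,
    alpha: float,
    light: LightProfile,
    *,
    cyclic_equality: bool = False,
    start_biomass_equality: bool = True,
    validated: bool = False,
) -> LinearProgram:
    """Assemble the global LP of one cyclic-growth problem at fixed alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if light.n_t != grid.n_t:
        raise ValueError("light profile and grid disagree on the number of intervals")
    if not validated:
        rep = validate_model(model)
        if not rep.ok:
            raise ValueError("model fails validation: " + "; ".join(rep.errors))

    dyn_ids = model.dynamic_ids
    n_d, n_r, n_t = len(dyn_ids), len(model.reactions), grid.n_t
    dyn_index = {cid: i for i, cid in enumerate(dyn_ids)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    S_B, S_A = model.stoichiometric_matrices()
    w = model.weights
    dt = grid.dt
    n_vars = (n_t + 1) * n_d + n_t * n_r
    v_off = (n_t + 1) * n_d

    def mcol(k: int, j: int) -> int:
        return k * n_d + j

    def vcol(k: int, j: int) -> int:
        return v_off + (k - 1) * n_r + j

    eq = _Builder(n_vars)
    ub = _Builder(n_vars)
    blocks: dict[str, tuple[str, int, int]] = {}

    def mark(name: str, builder: _Builder, start: int):
        blocks[name] = (("eq" if builder is eq else "ub"), start, builder.n_rows)

    # steady state: S_B v^k = 0
    start = eq.n_rows
    sb_rows = [S_B.getrow(i).tocoo() for i in range(S_B.shape[0])]
    for k in range(1, n_t + 1):
        base = v_off + (k - 1) * n_r
        for row in sb_rows:
            if row.nnz:
                eq.add_row(base + row.col, row.data, 0.0)
    mark("steady_state", eq, start)

    # Euler update: M^k - M^{k-1} - dt_k * S_A v^k = 0
    start = eq.n_rows
    sa_rows = [S_A.getrow(i).tocoo() for i in range(n_d)]
    for k in range(1, n_t + 1):
        base = v_off + (k - 1) * n_r
        for j in range(n_d):
            row = sa_rows[j]
            cols = [mcol(k, j), mcol(k - 1, j)] + list(base + row.col)
            vals = [1.0, -1.0] + list(-dt[k - 1] * row.data)
            eq.add_row(cols, vals, 0.0)
    mark("euler_update", eq, start)

    # capacity: sum_i coef * v_i^k - M_cat^{k-1} <= 0
    start = ub.n_rows
    for k in range(1, n_t + 1):
        g = light.gamma[k - 1]
        for cap in model.capacity_constraints:
            factor = g if cap.light_modulated else 1.0
            cols = [vcol(k, rxn_index[rid]) for rid, _ in cap.terms]
            vals = [inv * factor for _, inv in cap.terms]
            cols.append(mcol(k - 1, dyn_index[cap.catalyst_id]))
            vals.append(-1.0)
            ub.add_row(cols, vals, 0.0)
    mark("capacity", ub, start)

    # quota: fraction * w^T M^k - sum_members M^k <= 0
    start = ub.n_rows
    wcols = np.nonzero(w)[0]
    for q in model.quota_constraints:
        points = [0] if q.enforce == "start_only" else list(range(n_t + 1))
        member_idx = [dyn_index[m] for m in q.members]
        for k in points:
            coef = {int(j): q.fraction * w[j] for j in wcols}
            for j in member_idx:
                coef[j] = coef.get(j, 0.0) - 1.0
            cols = [mcol(k, j) for j in coef]
            ub.add_row(cols, list(coef.values()), 0.0)
    mark("quota", ub, start)

    # maintenance: coeff * w^T M^{k-1} - sum_i c_i v_i^k <= 0
    start = ub.n_rows
    for mt in model.maintenance_constraints:
        for k in range(1, n_t + 1):
            cols = [vcol(k, rxn_index[rid]) for rid in mt.flux_terms]
            vals = [-c for c in mt.flux_terms.values()]
            if mt.biomass_coefficient:
                cols += [mcol(k - 1, int(j)) for j in wcols]
                vals += [mt.biomass_coefficient * w[j] for j in wcols]
            ub.add_row(cols, vals, 0.0)
    mark("maintenance", ub, start)

    # cyclic growth: alpha * M^0 - M^{n_t} <= 0 (componentwise), or equality
    target = eq if cyclic_equality else ub
    start = target.n_rows
    for j in range(n_d):
        target.add_row([mcol(0, j), mcol(n_t, j)], [alpha, -1.0], 0.0)
    mark("cyclic_growth", target, start)

    # start biomass: w^T M^0 = B0 (default) or <= B0
    target = eq if start_biomass_equality else ub
    start = target.n_rows
    target.add_row([mcol(0, int(j)) for j in wcols], [w[j] for j in wcols], model.biomass_start_cap)
    mark("start_biomass", target, start)

    # variable bounds
    lb = np.zeros(n_vars)
    ubv = np.full(n_vars, np.inf)
    for k in range(1, n_t + 1):
        dark = bool(light.dark[k - 1])
        for j, rxn in enumerate(model.reactions):
            c = vcol(k, j)
            lo, hi = rxn.lower_bound, rxn.upper_bound
            if rxn.light_driven and dark:
                lo, hi = 0.0, 0.0
            lb[c], ubv[c] = lo, hi

    A_eq, b_eq = eq.matrix()
    A_ub, b_ub = ub.matrix()
    return LinearProgram(
        model=model, grid=grid, light=light, alpha=float(alpha),
        A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, lb=lb, ub=ubv, blocks=blocks,
    )


def check_solution(
    lp: LinearProgram, M: np.ndarray, v: np.ndarray
) -> dict[str, float]:
    """Maximal violation of every constraint block for an explicit ``(M, v)``.

    The returned mapping includes variable-bound violations under keys
    ``"nonnegativity"`` and ``"flux_bounds"``.  Useful both as a test oracle
    (an explicitly constructed trajectory must be accepted) and to verify
    solver output independently of the backend.
    """
    x = np.concatenate([np.asarray(M, float).ravel(), np.asarray(v, float).ravel()])
    if x.size != lp.n_vars:
        raise ValueError("solution has wrong dimensions for this LP")
    out: dict[str, float] = {}
    res_eq = lp.A_eq @ x - lp.b_eq if lp.A_eq.shape[0] else np.zeros(0)
    res_ub = lp.A_ub @ x - lp.b_ub if lp.A_ub.shape[0] else np.zeros(0)
    for name, (kind, start, stop) in lp.blocks.items():
        if stop == start:
            out[name] = 0.0
        elif kind == "eq":
            out[name] = float(np.abs(res_eq[start:stop]).max())
        else:
            out[name] = float(np.maximum(res_ub[start:stop], 0.0).max())
    n_m = (lp.grid.n_t + 1) * lp.n_d
    out["nonnegativity"] = float(np.maximum(-x[:n_m], 0.0).max())
    viol = np.maximum(lp.lb[n_m:] - x[n_m:], 0.0)
    viol = np.maximum(viol, np.maximum(x[n_m:] - lp.ub[n_m:], 0.0))
    out["flux_bounds"] = float(viol.max()) if viol.size else 0.0
    return out
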