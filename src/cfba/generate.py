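"""Synthetic model generators for testing and benchmarking.

The single-autocatalyst model has a closed-form optimum under the Euler
discretization — ``alpha* = (1 + c dt)^{n_t}`` — and serves as the exact
oracle for the growth-maximization machinery; the random chain generator
produces small validated autocatalytic networks for property-based tests.
"""

from __future__ import annotations

import numpy as np

from .model import (
    CFBAModel,
    CapacityConstraint,
    Compound,
    QuotaConstraint,
    Reaction,
)

__all__ = [
    "single_autocatalyst_model",
    "single_autocatalyst_alpha",
    "random_autocatalytic_model",
]


def single_autocatalyst_model(kcat: float = 0.1, B0: float = 1.0) -> CFBAModel:
    """One dynamic compound E produced by a reaction it catalyzes itself.

    With capacity ``v <= kcat * E`` and Euler updates the amount multiplies
    by exactly ``1 + kcat * dt`` per interval, so the maximal cyclic growth
    factor is ``(1 + kcat * dt)^{n_t}`` (→ ``exp(kcat T)`` as the grid is
    refined).
    """
    if kcat <= 0:
        raise ValueError("kcat must be positive")
    return CFBAModel(
        name="single_autocatalyst",
        compounds=[Compound("E", "dynamic", biomass_weight=1.0)],
        reactions=[Reaction("make_E", {"E": 1.0})],
        capacity_constraints=[CapacityConstraint("E", (("make_E", 1.0 / kcat),))],
        biomass_start_cap=B0,
    )


def single_autocatalyst_alpha(kcat: float, T: float, n_t: int) -> float:
    """Closed-form maximal growth factor of the single-autocatalyst model."""
    return float((1.0 + kcat * T / n_t) ** n_t)


def random_autocatalytic_model(seed: int, n_enzymes: int) -> CFBAModel:
    """A random autocatalytic chain with one quota compound.

    ``E_0`` catalyzes its own synthesis; each further enzyme ``E_i`` is
    synthesized under the capacity of ``E_{i-1}``; the last enzyme also
    catalyzes production of a non-catalytic product ``P`` that carries a
    start-only quota.  kcats are drawn uniformly from [0.15, 0.6] per hour;
    identical seeds give identical models.
    """
    if n_enzymes < 1:
        raise ValueError("n_enzymes must be >= 1")
    rng = np.random.default_rng(seed)
    kcats = rng.uniform(0.15, 0.6, size=n_enzymes + 1)
    compounds = [Compound(f"E_{i}", "dynamic", biomass_weight=1.0) for i in range(n_enzymes)]
    compounds.append(Compound("P", "dynamic", biomass_weight=1.0))
    reactions = [Reaction(f"make_E_{i}", {f"E_{i}": 1.0}) for i in range(n_enzymes)]
    reactions.append(Reaction("make_P", {"P": 1.0}))
    terms_by_catalyst: dict[str, list[tuple[str, float]]] = {}
    terms_by_catalyst.setdefault("E_0", []).append(("make_E_0", 1.0 / kcats[0]))
    for i in range(1, n_enzymes):
        terms_by_catalyst.setdefault(f"E_{i-1}", []).append((f"make_E_{i}", 1.0 / kcats[i]))
    terms_by_catalyst.setdefault(f"E_{n_enzymes-1}", []).append(("make_P", 1.0 / kcats[n_enzymes]))
    caps = [
        CapacityConstraint(cat, tuple(terms)) for cat, terms in terms_by_catalyst.items()
    ]
    return CFBAModel(
        name=f"random_autocatalytic_{seed}_{n_enzymes}",
        compounds=compounds,
        reactions=reactions,
        capacity_constraints=caps,
        quota_constraints=[QuotaConstraint(("P",), 0.2, enforce="start_only")],
        biomass_start_cap=1.0,
    )
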