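"""Self-consistent estimation of catalytic efficiencies (kcats).

When direct kcat measurements are unavailable, capacity coefficients can
be calibrated from a reference flux distribution (e.g. a conventional FBA
solution) and reference catalyst amounts, under the *self-consistency*
assumption: the amount of each catalyzing compound accumulated over the
reference period is exactly sufficient to catalyze its own reference flux
distribution, i.e. the capacity row

    sum_{i in R_j} v_ref_i / kcat_ij  =  M_ref_j

holds with equality.  When a compound catalyzes several reactions, equal
shares of the catalyst are assigned to each reaction, giving

    kcat_ij = |R_j| * v_ref_i / M_ref_j.

Catalysts listed in ``shared_kcat`` (e.g. ribosomes over all enzyme
synthesis reactions) instead use one common kcat per catalyst, fitted so
the summed capacity row is tight: ``kcat_j = sum_i v_ref_i / M_ref_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ReferenceState",
    "KcatTable",
    "estimate_kcats",
    "check_self_consistency",
]


@dataclass
class ReferenceState:
    """A reference operating point for kcat calibration.

    ``v_ref`` maps reaction id to reference flux (amount/h, nonnegative for
    catalyzed reactions); ``M_ref`` maps catalyst compound id to its
    reference amount; ``catalysis_map`` maps each catalyst to the set of
    reaction ids it catalyzes; ``shared_kcat`` names catalysts whose
    reactions share a single common kcat.  ``T_ref`` records the duration
    over which the reference amounts are synthesized (informational;
    12 h light period by convention).
    """

    v_ref: Mapping[str, float]
    M_ref: Mapping[str, float]
    catalysis_map: Mapping[str, frozenset[str] | set[str]]
    T_ref: float = 12.0
    shared_kcat: frozenset[str] | set[str] = field(default_factory=frozenset)

    def validate(self) -> None:
        for j, rxns in self.catalysis_map.items():
            if not rxns:
                raise ValueError(f"catalyst {j!r} has an empty reaction set")
            if j not in self.M_ref:
                raise ValueError(f"no reference amount for catalyst {j!r}")
            if not self.M_ref[j] > 0:
                raise ValueError(f"reference amount for catalyst {j!r} must be positive")
            for i in rxns:
                if i not in self.v_ref:
                    raise ValueError(f"no reference flux for catalyzed reaction {i!r}")
                if self.v_ref[i] < 0:
                    raise ValueError(f"reference flux for {i!r} is negative")


@dataclass
class KcatTable:
    """Map ``(reaction_id, catalyst_id) -> kcat`` (1/h, positive finite)."""

    kcats: dict[tuple[str, str], float] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.kcats[key]

    def __len__(self) -> int:
        return len(self.kcats)

    def items(self):
        return self.kcats.items()


def estimate_kcats(ref: ReferenceState) -> KcatTable:
    """Estimate kcats from a reference state under self-consistency.

    Raises ``ValueError`` on zero catalyst amounts or zero reference flux
    through a catalyzed reaction (which would imply an infinite or zero
    capacity coefficient) — never produces silent infinities.
    """
    ref.validate()
    table = KcatTable()
    for j, rxns in ref.catalysis_map.items():
        rxns = sorted(rxns)
        M = ref.M_ref[j]
        if j in ref.shared_kcat:
            total = sum(ref.v_ref[i] for i in rxns)
            if total <= 0:
                raise ValueError(
                    f"shared-kcat catalyst {j!r} has zero total reference flux"
                )
            kcat = total / M
            for i in rxns:
                table.kcats[(i, j)] = kcat
        else:
            n = len(rxns)
            for i in rxns:
                v = ref.v_ref[i]
                if v <= 0:
                    raise ValueError(
                        f"reference flux for reaction {i!r} catalyzed by {j!r} is zero; "
                        "cannot infer a finite kcat"
                    )
                table.kcats[(i, j)] = n * v / M
    return table


def check_self_consistency(
    kcats: KcatTable, ref: ReferenceState, rtol: float = 1e-9
) -> dict[str, float]:
    """Relative slack of every capacity row at the reference state.

    Returns a mapping catalyst id -> relative deviation of
    ``sum_i v_ref_i / kcat_ij`` from ``M_ref_j``; only rows whose deviation
    exceeds ``rtol`` are included (empty dict = fully self-consistent).
    """
    flagged: dict[str, float] = {}
    for j, rxns in ref.catalysis_map.items():
        M = ref.M_ref[j]
        used = sum(ref.v_ref[i] / kcats[(i, j)] for i in rxns)
        dev = abs(used - M) / M
        if dev > rtol:
            flagged[j] = dev
    return flagged
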