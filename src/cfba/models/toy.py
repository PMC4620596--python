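"""Three-reaction toy network illustrating conditional growth.

A substrate X is taken up (v1) and converted either into an enzyme Y (v2)
or into a target compound Z (v3).  Both conversions are catalyzed by Y
itself, so the system is autocatalytic: building Y early raises the
capacity available later.  X is balanced; Y and Z accumulate.  Z carries
no catalytic activity and is forced into the solution only by a minimal
quota of 0.5 at the start of the cycle.

The optimal cyclic program is bang-bang: the full shared capacity of Y is
first spent on self-synthesis, then switched to Z production for the rest
of the period, and the solution at the optimum is unique.

Parameter values (not dictated by the network structure) are module
constants below: kcats of 0.3 h^-1 for both catalyzed reactions, a
non-binding uptake bound on v1, unit biomass weights on Y and Z, and a
start biomass of 1.
"""

from __future__ import annotations

from ..model import (
    CFBAModel,
    CapacityConstraint,
    Compound,
    QuotaConstraint,
    Reaction,
)

#: catalytic efficiency of Y for its own synthesis (v2), 1/h
KCAT_V2 = 0.3
#: catalytic efficiency of Y for Z synthesis (v3), 1/h
KCAT_V3 = 0.3
#: upper bound on substrate uptake v1, amount/h (non-binding safeguard: the
#: shared capacity of Y, not uptake, must limit growth for the bang-bang
#: program with its unique solution)
V1_UPPER = 1000.0
#: minimal relative quota of Z at the start of the cycle
Z_QUOTA = 0.5
#: start biomass cap B0
B0 = 1.0


def build_toy_model() -> CFBAModel:
    return CFBAModel(
        name="toy",
        compounds=[
            Compound("X", "balanced"),
            Compound("Y", "dynamic", biomass_weight=1.0),
            Compound("Z", "dynamic", biomass_weight=1.0),
        ],
        reactions=[
            Reaction("v1", {"X": 1.0}, upper_bound=V1_UPPER),
            Reaction("v2", {"X": -1.0, "Y": 1.0}),
            Reaction("v3", {"X": -1.0, "Z": 1.0}),
        ],
        capacity_constraints=[
            CapacityConstraint(
                "Y", (("v2", 1.0 / KCAT_V2), ("v3", 1.0 / KCAT_V3))
            ),
        ],
        quota_constraints=[
            QuotaConstraint(members=("Z",), fraction=Z_QUOTA, enforce="start_only"),
        ],
        biomass_start_cap=B0,
    )
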