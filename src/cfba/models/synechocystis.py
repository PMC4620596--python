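"""Minimal diurnal model of *Synechocystis* sp. PCC 6803.

The network covers the photosynthetic light reactions (PSII, Cytb6f, PSI,
FNR, cyclic electron flow, ATPase), carbon uptake and fixation by a lumped
Calvin-Benson cycle (RubisCo + regeneration), lumped synthesis reactions
for the main biomass components (amino acids, pigments, RNA, DNA, lipids,
cell wall, soluble pool, inorganic ions, ribosomes), glycogen storage and
mobilization, a TCA cycle and respiratory chain for dark metabolism, and
one synthesis reaction per catalytic enzyme.  It comprises 52 reactions
and 50 cellular compounds; the photon is treated as an environmental
boundary species (mass-balanced, but not a cellular compound).

Units: amounts in model units, time in hours; capacity coefficients are
inverse catalytic efficiencies in hours.

Notes on transcription choices (flagged; the source tables typeset some
constraint labels as figures, leaving the assignment of a few printed
coefficients ambiguous):

* The two-term capacity row with coefficient ratio ~4:1
  (0.002549/0.0006371) is taken as the pigment light-harvesting row over
  (PSII, PSI) — PSII absorbs 4 photons per turnover, PSI one — and is the
  light-modulated (gamma^k) row.
* The equal-coefficient pair 0.0008281 is assigned to E_PSI over
  (PSI, PSIcyc), cyclic electron flow being mediated by PSI.
* The equal-coefficient pair 0.00278 is the ribosome row over all 25
  enzyme-synthesis reactions (one common ribosomal kcat) plus ribosome
  assembly (Ribosome_S).
* The remaining 22 single-term coefficients are assigned, in printed
  order, to the remaining 22 single-reaction enzymes in the order of the
  enzyme list.
* Biomass weights are not printed in the source tables; every dynamic
  compound carries unit weight except free amino acids (AA), which have
  weight zero and consequently a nominal steady amount of zero.
* Quota constants: cell wall 0.059, lipid 0.12, and RNA / inorganic ions /
  soluble pool / non-catalytic protein pool (E_Others) 0.029 each, all
  enforced at every timepoint; DNA 0.031 at the start of the cycle only.
"""

from __future__ import annotations

from ..model import (
    CFBAModel,
    CapacityConstraint,
    Compound,
    MaintenanceConstraint,
    QuotaConstraint,
    Reaction,
)

#: the 25 enzymes, in table order; each has a synthesis reaction "<e>_S"
ENZYMES = (
    "E_AA_S", "E_ATPase", "E_Inorganic_Ion_S", "E_Calvin", "E_Cell_Wall_S",
    "E_Cyt6bf", "E_CytC", "E_DNA_S", "E_FNR", "E_Glycogen_S",
    "E_Glycogen_Use", "E_Lipid_S", "E_Maintenance", "E_NDH", "E_Others",
    "E_PSI", "E_PSII", "E_Pigment_S", "E_RNA_S", "E_Ribosome_S",
    "E_Ribosome_comp", "E_Rubisco", "E_Soluble_Pool_S", "E_TCA",
    "E_Carbon_Uptake",
)

#: ATP cost per unit of any enzyme synthesized (plus one unit of AA)
ENZYME_SYNTHESIS_ATP = 104.56

BALANCED = (
    "ATP", "ADP", "NADPH", "NADP", "Q", "QH2", "oxPC", "redPC",
    "oxFd", "redFd", "Hx", "C3", "C5", "CO2", "O2",
)

#: dynamic biomass components with unit weight
_WEIGHTED = (
    "Inorganic_Ion", "Cell_Wall", "DNA", "Lipid", "Pigment", "RNA",
    "Ribosome", "Soluble_Pool", "Glycogen",
) + ENZYMES

#: single-reaction enzyme capacity coefficients (inverse kcat, hours),
#: printed values assigned in enzyme-list order (see module docstring)
CAPACITY_SINGLE = {
    "E_AA_S": ("AA_S", 4.36),
    "E_ATPase": ("ATPase", 0.3814),
    "E_Inorganic_Ion_S": ("Inorganic_Ion_S", 0.001171),
    "E_Calvin": ("Calvin", 12.88),
    "E_Cell_Wall_S": ("Cell_Wall_S", 0.008816),
    "E_Cyt6bf": ("Cyt6bf", 0.4419),
    "E_CytC": ("CytC", 0.00009621),
    "E_DNA_S": ("DNA_S", 0.000001396),
    "E_FNR": ("FNR", 2.515),
    "E_Glycogen_S": ("Glycogen_S", 0.001658),
    "E_Glycogen_Use": ("Glycogen_Use", 0.0001272),
    "E_Lipid_S": ("Lipid_S", 17.49),
    "E_Maintenance": ("Maintenance", 0.00005342),
    "E_NDH": ("NDH", 0.001041),
    "E_PSII": ("PSII", 0.02612),
    "E_Pigment_S": ("Pigment_S", 3.423),
    "E_RNA_S": ("RNA_S", 1.084),
    "E_Ribosome_S": ("Ribosome_S", 0.2214),
    "E_Rubisco": ("Rubisco", 0.002621),
    "E_Soluble_Pool_S": ("Soluble_Pool_S", 3.193),
    "E_TCA": ("TCA", 0.0222),
    "E_Carbon_Uptake": ("Uptake_Carbon", 0.0003567),
}

#: pigment light-harvesting row (gamma-modulated): PSII vs PSI photon use
PIGMENT_ROW = (("PSII", 0.002549), ("PSI", 0.0006371))
#: E_PSI covers both linear and cyclic electron flow through PSI
E_PSI_ROW = (("PSI", 0.0008281), ("PSIcyc", 0.0008281))
#: one common ribosomal coefficient for all protein synthesis
RIBOSOME_COEF = 0.00278

#: relative quota constants (fraction of biomass)
QUOTAS_ALL_TIMES = {
    "Cell_Wall": 0.059,
    "Lipid": 0.12,
    "RNA": 0.029,
    "Inorganic_Ion": 0.029,
    "Soluble_Pool": 0.029,
    "E_Others": 0.029,
}
DNA_QUOTA_START = 0.031

#: maintenance constants: coupling to ATPase and biomass-proportional demand
MAINTENANCE_ATPASE_COUPLING = 0.05
MAINTENANCE_BIOMASS = 0.00641


def build_synechocystis_model() -> CFBAModel:
    compounds = [Compound(c, "balanced") for c in BALANCED]
    compounds.append(Compound("AA", "dynamic", biomass_weight=0.0))
    compounds += [Compound(c, "dynamic", biomass_weight=1.0) for c in _WEIGHTED]

    reactions = [
        Reaction("ATPase", {"Hx": -14, "ADP": -3, "ATP": 3}),
        Reaction("Calvin", {"NADPH": -5, "C3": -5, "ATP": -8,
                            "NADP": 5, "C5": 3, "ADP": 8}),
        Reaction("Cyt6bf", {"QH2": -1, "oxPC": -2, "Q": 1, "Hx": 4, "redPC": 2}),
        Reaction("CytC", {"O2": -1, "redPC": -4, "Hx": 4, "oxPC": 4}),
        Reaction("FNR", {"redFd": -2, "NADP": -1, "oxFd": 2, "NADPH": 1}),
        Reaction("Maintenance", {"ATP": -1, "ADP": 1}),
        Reaction("NDH", {"Q": -1, "NADPH": -1, "QH2": 1, "Hx": 4, "NADP": 1}),
        Reaction("PSI", {"photon": -1, "redPC": -1, "oxFd": -1,
                         "oxPC": 1, "redFd": 1}),
        Reaction("PSII", {"photon": -4, "Q": -2, "QH2": 2, "Hx": 4, "O2": 1}),
        Reaction("PSIcyc", {"Q": -1, "redFd": -2, "QH2": 1, "Hx": 4, "oxFd": 2}),
        Reaction("Rubisco", {"C5": -1, "CO2": -1, "C3": 2}),
        Reaction("TCA", {"NADP": -4, "C3": -1, "ADP": -1,
                         "NADPH": 4, "ATP": 1, "CO2": 3}),
        Reaction("AA_S", {"NADPH": -66.41, "C3": -15.48, "ATP": -19.89,
                          "O2": 0.321, "NADP": 66.41, "ADP": 19.89,
                          "CO2": 1.483, "AA": 1}),
        Reaction("Inorganic_Ion_S", {"NADPH": -4.544, "ATP": -9.62,
                                     "NADP": 4.544, "ADP": 9.62,
                                     "Inorganic_Ion": 1}),
        Reaction("Cell_Wall_S", {"NADPH": -49.46, "C3": -14.82, "ATP": -31.07,
                                 "CO2": -0.4276, "NADP": 49.46, "ADP": 31.07,
                                 "Cell_Wall": 1}),
        Reaction("DNA_S", {"NADPH": -52.89, "C3": -9.912, "ATP": -40.27,
                           "CO2": -2.014, "NADP": 52.89, "ADP": 40.27, "DNA": 1}),
        Reaction("Lipid_S", {"NADPH": -61.82, "C3": -18.48, "ATP": -38.84,
                             "O2": 2.678, "NADP": 61.82, "ADP": 38.84, "Lipid": 1}),
        Reaction("Pigment_S", {"NADPH": -58.54, "C3": -25.67, "ATP": -21.73,
                               "O2": 5.71, "NADP": 58.54, "ADP": 21.73,
                               "CO2": 12.54, "Pigment": 1}),
        Reaction("RNA_S", {"NADPH": -47.07, "C3": -9.087, "ATP": -38.54,
                           "CO2": -2.35, "NADP": 47.07, "ADP": 38.54, "RNA": 1}),
        Reaction("Ribosome_S", {"E_Ribosome_comp": -0.339, "RNA": -0.661,
                                "ATP": -0.21, "Ribosome": 1, "ADP": 0.21}),
        Reaction("Soluble_Pool_S", {"NADPH": -24.95, "C3": -4.937, "ATP": -15.69,
                                    "O2": 0.12, "NADP": 24.95, "ADP": 15.69,
                                    "CO2": 1.716, "Soluble_Pool": 1}),
        Reaction("Glycogen_S", {"NADPH": -2, "C3": -2, "ATP": -2,
                                "NADP": 2, "ADP": 2, "Glycogen": 1}),
        Reaction("Glycogen_Use", {"NADP": -2, "Glycogen": -1, "NADPH": 2, "C3": 2}),
    ]
    for e in ENZYMES:
        reactions.append(
            Reaction(f"{e}_S", {"ATP": -ENZYME_SYNTHESIS_ATP, "AA": -1,
                                "ADP": ENZYME_SYNTHESIS_ATP, e: 1})
        )
    reactions += [
        Reaction("CO2_Export", {"CO2": -1}),
        Reaction("O2_Export", {"O2": -1}, reversible=True, lower_bound=float("-inf")),
        Reaction("Photon_Uptake", {"photon": 1}, light_driven=True),
        Reaction("Uptake_Carbon", {"ATP": -1, "ADP": 1, "CO2": 1}),
    ]

    capacity = [
        CapacityConstraint("Pigment", PIGMENT_ROW, light_modulated=True),
        CapacityConstraint("E_PSI", E_PSI_ROW),
        CapacityConstraint(
            "Ribosome",
            tuple((f"{e}_S", RIBOSOME_COEF) for e in ENZYMES)
            + (("Ribosome_S", RIBOSOME_COEF),),
        ),
    ]
    for catalyst, (rid, coef) in CAPACITY_SINGLE.items():
        capacity.append(CapacityConstraint(catalyst, ((rid, coef),)))

    quotas = [
        QuotaConstraint(members=(cid,), fraction=frac)
        for cid, frac in QUOTAS_ALL_TIMES.items()
    ]
    quotas.append(
        QuotaConstraint(members=("DNA",), fraction=DNA_QUOTA_START, enforce="start_only")
    )

    maintenance = [
        MaintenanceConstraint({"Maintenance": 1.0, "ATPase": -MAINTENANCE_ATPASE_COUPLING}),
        MaintenanceConstraint({"Maintenance": 1.0}, biomass_coefficient=MAINTENANCE_BIOMASS),
    ]

    return CFBAModel(
        name="synechocystis",
        compounds=compounds,
        reactions=reactions,
        capacity_constraints=capacity,
        quota_constraints=quotas,
        maintenance_constraints=maintenance,
        biomass_start_cap=1.0,
        externals=("photon",),
    )
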