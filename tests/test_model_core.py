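"""Data-model invariants, validation, and the packaged networks."""

import numpy as np
import pytest

from cfba import (
    CapacityConstraint,
    CFBAModel,
    Compound,
    QuotaConstraint,
    Reaction,
    biomass,
    scale_kcat,
    validate_model,
)


def _tiny_model(**overrides):
    base = dict(
        name="tiny",
        compounds=[
            Compound("X", "balanced"),
            Compound("E", "dynamic", biomass_weight=1.0),
        ],
        reactions=[
            Reaction("uptake", {"X": 1.0}),
            Reaction("make_E", {"X": -1.0, "E": 1.0}),
        ],
        capacity_constraints=[CapacityConstraint("E", (("make_E", 2.0),))],
    )
    base.update(overrides)
    return CFBAModel(**base)


class TestBiomass:
    @pytest.mark.parametrize(
        "M, w, expected",
        [
            ([0.0, 0.0], [1.0, 1.0], 0.0),
            ([2.0, 3.0], [1.0, 1.0], 5.0),
            ([4.0, 9.0], [0.5, 0.0], 2.0),  # zero-weight compound excluded
        ],
    )
    def test_weighted_sum(self, M, w, expected):
        assert biomass(np.array(M), np.array(w)) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            biomass(np.ones(3), np.ones(2))


class TestValidation:
    def test_tiny_model_valid(self):
        assert validate_model(_tiny_model()).ok

    def test_unproducible_quota_compound(self):
        m = _tiny_model(
            compounds=[
                Compound("X", "balanced"),
                Compound("E", "dynamic", biomass_weight=1.0),
                Compound("Q", "dynamic", biomass_weight=1.0),
            ],
            quota_constraints=[QuotaConstraint(("Q",), 0.1)],
        )
        rep = validate_model(m)
        assert any("unproducible quota compound" in e for e in rep.errors)

    def test_balanced_catalyst_rejected(self):
        m = _tiny_model(
            capacity_constraints=[CapacityConstraint("X", (("make_E", 2.0),))]
        )
        rep = validate_model(m)
        assert len([e for e in rep.errors if "not a dynamic compound" in e]) == 1

    def test_duplicate_ids(self):
        m = _tiny_model(
            compounds=[
                Compound("X", "balanced"),
                Compound("X", "balanced"),
                Compound("E", "dynamic", biomass_weight=1.0),
            ]
        )
        assert not validate_model(m).ok

    def test_irreversible_negative_lower_bound(self):
        m = _tiny_model(
            reactions=[
                Reaction("uptake", {"X": 1.0}, lower_bound=-1.0),
                Reaction("make_E", {"X": -1.0, "E": 1.0}),
            ]
        )
        assert any("negative lower bound" in e for e in validate_model(m).errors)

    def test_balanced_weight_rejected(self):
        m = _tiny_model(
            compounds=[
                Compound("X", "balanced", biomass_weight=0.5),
                Compound("E", "dynamic", biomass_weight=1.0),
            ]
        )
        assert any("nonzero biomass weight" in e for e in validate_model(m).errors)

    def test_untouched_dynamic_compound_warns(self):
        m = _tiny_model(
            compounds=[
                Compound("X", "balanced"),
                Compound("E", "dynamic", biomass_weight=1.0),
                Compound("idle", "dynamic", biomass_weight=0.0),
            ]
        )
        rep = validate_model(m)
        assert rep.ok and any("idle" in w for w in rep.warnings)


class TestToyModel:
    def test_validates(self, toy_model):
        assert validate_model(toy_model).ok

    def test_structure(self, toy_model):
        assert len(toy_model.reactions) == 3
        (quota,) = toy_model.quota_constraints
        assert quota.fraction == 0.5 and quota.enforce == "start_only"
        assert quota.members == ("Z",)
        # shared capacity of Y over both conversions
        (cap,) = toy_model.capacity_constraints
        assert cap.catalyst_id == "Y"
        assert {rid for rid, _ in cap.terms} == {"v2", "v3"}


class TestSynechocystisModel:
    def test_validates(self, syn_model):
        rep = validate_model(syn_model)
        assert rep.errors == []

    def test_every_metabolic_reaction_has_one_enzyme_row(self, syn_model):
        """Each metabolic reaction sits in exactly one dedicated-enzyme
        capacity row; protein synthesis is covered by the ribosome row and
        light harvesting additionally by the pigment row."""
        exchanges = {"CO2_Export", "O2_Export", "Photon_Uptake"}
        coverage: dict[str, int] = {}
        for cap in syn_model.capacity_constraints:
            if cap.catalyst_id in ("Pigment", "Ribosome"):
                continue
            for rid, _ in cap.terms:
                coverage[rid] = coverage.get(rid, 0) + 1
        (rib,) = [c for c in syn_model.capacity_constraints if c.catalyst_id == "Ribosome"]
        ribosome_covered = {rid for rid, _ in rib.terms}
        for r in syn_model.reactions:
            if r.id in exchanges:
                continue
            if r.id.endswith("_S") and r.id[:-2].startswith("E_"):
                assert r.id in ribosome_covered, f"{r.id} missing from the ribosome row"
            else:
                assert coverage.get(r.id, 0) == 1, f"{r.id} not covered exactly once"

    def test_pigment_row_is_light_modulated(self, syn_model):
        (pigment,) = [
            c for c in syn_model.capacity_constraints if c.catalyst_id == "Pigment"
        ]
        assert pigment.light_modulated
        assert {rid for rid, _ in pigment.terms} == {"PSI", "PSII"}
        assert all(
            not c.light_modulated
            for c in syn_model.capacity_constraints
            if c.catalyst_id != "Pigment"
        )

    def test_ribosome_shares_one_coefficient(self, syn_model):
        (rib,) = [
            c for c in syn_model.capacity_constraints if c.catalyst_id == "Ribosome"
        ]
        coefs = {inv for _, inv in rib.terms}
        assert coefs == {0.00278}
        assert sum(rid.endswith("_S") for rid, _ in rib.terms) == len(rib.terms)


class TestScaleKcat:
    def test_divides_inverse_coefficients(self, toy_model):
        doubled = scale_kcat(toy_model, "Y", 2.0)
        orig = dict(toy_model.capacity_constraints[0].terms)
        new = dict(doubled.capacity_constraints[0].terms)
        for rid in orig:
            assert new[rid] == pytest.approx(orig[rid] / 2.0)
        # original untouched
        assert toy_model.capacity_constraints[0].terms[0][1] == orig["v2"]

    def test_unknown_catalyst(self, toy_model):
        with pytest.raises(KeyError):
            scale_kcat(toy_model, "nope", 2.0)

    def test_invalid_fold(self, toy_model):
        with pytest.raises(ValueError):
            scale_kcat(toy_model, "Y", 0.0)
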