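"""Network builder: profiles, transforms, conservation groups, exports."""

import math

import numpy as np
import pytest

import proteopath as pp
from proteopath.model import DEFAULT_RATE_CONSTANTS, IRREVERSIBLE_STEPS


class TestBiophysicalProfile:
    def test_derived_reverse_rates(self):
        p = pp.PROFILES["default"]
        assert p.k_unfold == pytest.approx(p.k_fold / p.K_fold)
        assert p.k_unmis == pytest.approx(0.01)  # 1 / 100
        agg = pp.PROFILES["aggregator"]
        # the critical concentration controls disaggregation: k_dis = k_ag * c*
        assert agg.k_dis == pytest.approx(10.0 * 0.01)

    def test_characteristic_profiles(self):
        # Slow Folder folds slowest into the most stable native state
        assert pp.PROFILES["slow_folder"].k_fold == min(p.k_fold for p in pp.PROFILES.values())
        assert pp.PROFILES["slow_folder"].K_fold == max(p.K_fold for p in pp.PROFILES.values())
        # Bad Folder has the most stable misfolded trap
        assert pp.PROFILES["bad_folder"].K_mis == max(p.K_mis for p in pp.PROFILES.values())
        # Aggregator misfolds and aggregates fastest
        assert pp.PROFILES["aggregator"].k_mis == max(p.k_mis for p in pp.PROFILES.values())
        assert pp.PROFILES["aggregator"].k_ag == max(p.k_ag for p in pp.PROFILES.values())

    @pytest.mark.parametrize("bad", [
        dict(k_fold=0.0), dict(K_fold=-1.0), dict(k_mis=float("nan")), dict(c_crit=0.0),
    ])
    def test_rejects_nonpositive_parameters(self, bad):
        kw = dict(k_fold=1.0, K_fold=10.0, k_mis=1.0, K_mis=10.0, k_ag=0.1, c_crit=0.1)
        kw.update(bad)
        with pytest.raises(ValueError):
            pp.BiophysicalProfile(**kw)


class TestBuildModel:
    def test_reverse_rates_in_reaction_list(self, default_model):
        assert default_model.rate("k_unfold") == pytest.approx(0.1 / 1e4)
        assert default_model.rate("k_unmis") == pytest.approx(0.01)
        assert default_model.rate("k_dis") == pytest.approx(0.1 * 0.1)

    def test_conservation_totals_match_levels(self, default_model):
        totals = default_model.conservation_totals()
        lv = default_model.levels
        assert totals["DnaK"] == pytest.approx(lv.dnak)
        assert totals["DnaJ"] == pytest.approx(lv.dnaj)
        assert totals["GroEL"] == pytest.approx(lv.groel)
        assert totals["GroES"] == pytest.approx(lv.groes)
        assert totals["Lon"] == pytest.approx(lv.lon)
        assert totals["TF"] == pytest.approx(lv.trigger_factor)
        assert totals["ClpB"] == pytest.approx(lv.clpb)

    def test_deterministic_build(self):
        m1 = pp.build_model(pp.PROFILES["default"])
        m2 = pp.build_model(pp.PROFILES["default"])
        assert [s.name for s in m1.species] == [s.name for s in m2.species]
        assert [(r.name, r.value, r.reactants, r.products) for r in m1.reactions] == [
            (r.name, r.value, r.reactants, r.products) for r in m2.reactions
        ]

    def test_disabling_bkje_removes_prepared_aggregates(self):
        opts = pp.ModelOptions(
            enabled_systems=pp.ALL_SYSTEMS - {pp.System.BKJE}
        )
        m = pp.build_model(pp.PROFILES["default"], options=opts)
        assert not any(s.name.endswith("*") for s in m.species)
        assert not any(r.constant in ("k_prep", "k_extract") for r in m.reactions)

    def test_bkje_requires_kje_and_aggregation(self):
        with pytest.raises(ValueError):
            pp.ModelOptions(enabled_systems=frozenset({pp.System.BKJE}))
        with pytest.raises(ValueError):
            pp.ModelOptions(enable_aggregation=False)  # B+KJE on by default

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            pp.build_model(pp.PROFILES["default"], overrides={"k_bogus": 1.0})

    def test_override_applied_everywhere(self):
        m = pp.build_model(pp.PROFILES["default"], overrides={"k_ag": 7.0})
        values = {r.value for r in m.reactions if r.constant == "k_ag"}
        assert values == {7.0}

    def test_nmax_bounds(self):
        with pytest.raises(ValueError):
            pp.ModelOptions(n_max=1)
        m = pp.build_model(pp.PROFILES["default"], options=pp.ModelOptions(n_max=5))
        sizes = sorted(s.agg_size for s in m.species if s.agg_size and not s.name.endswith("*"))
        assert sizes == [2, 3, 4, 5]
        # reflecting boundary: no growth reaction out of the largest size
        assert not any(r.name == "growth_5" for r in m.reactions)

    def test_detailed_balance_pairing(self, default_model):
        """Every binding step is paired with an unbinding step except the
        designated irreversible ones (hydrolysis, release, extraction,
        degradation, encapsulation, trans-ring capture)."""
        by_name = {r.name: r for r in default_model.reactions}
        for r in default_model.reactions:
            if r.reversible_partner is not None:
                partner = by_name[r.reversible_partner]
                assert dict(partner.reactants) == dict(r.products)
                assert dict(partner.products) == dict(r.reactants)
            else:
                assert r.constant in IRREVERSIBLE_STEPS or r.name.startswith("trans_")

    def test_every_chaperone_in_exactly_one_group(self, default_model):
        seen = {}
        for group, weights in default_model.conservation_groups.items():
            for sp in weights:
                if default_model.species[default_model.species_index(sp)].role == "chaperone":
                    assert sp not in seen, f"{sp} in {seen[sp]} and {group}"
                    seen[sp] = group
        chaperones = {s.name for s in default_model.species if s.role == "chaperone"}
        assert set(seen) == chaperones


class TestTransforms:
    def test_binding_factor_identity(self, default_model):
        m = pp.apply_binding_factor(default_model, 1.0)
        assert [r.value for r in m.reactions] == [r.value for r in default_model.reactions]

    def test_binding_factor_scaling(self, default_model):
        m = pp.apply_binding_factor(default_model, 2.0)
        assert m.rate("k_gu_on") == pytest.approx(2 * default_model.rate("k_gu_on"))
        assert m.rate("k_gm_on") == pytest.approx(2 * default_model.rate("k_gm_on"))
        assert m.rate("k_ku_on") == pytest.approx(default_model.rate("k_ku_on") / 2)
        assert m.rate("k_km_on") == pytest.approx(default_model.rate("k_km_on") / 2)
        # everything else untouched
        assert m.rate("k_cycle") == default_model.rate("k_cycle")
        assert m.rate("k_fold") == default_model.rate("k_fold")

    def test_binding_factor_multiplicative(self, default_model):
        twice = pp.apply_binding_factor(pp.apply_binding_factor(default_model, 0.1), 0.1)
        once = pp.apply_binding_factor(default_model, 0.01)
        np.testing.assert_allclose(
            [r.value for r in twice.reactions], [r.value for r in once.reactions]
        )

    def test_binding_factor_at_build_matches_transform(self):
        built = pp.build_model(
            pp.PROFILES["default"], options=pp.ModelOptions(binding_factor=3.0)
        )
        transformed = pp.apply_binding_factor(pp.build_model(pp.PROFILES["default"]), 3.0)
        np.testing.assert_allclose(
            [r.value for r in built.reactions], [r.value for r in transformed.reactions]
        )

    def test_binding_factor_positive(self, default_model):
        with pytest.raises(ValueError):
            pp.apply_binding_factor(default_model, 0.0)

    def test_capacity_factor(self, default_model):
        m = pp.apply_capacity_factor(default_model, 0.5)
        assert m.species[m.species_index("GrL_T")].initial == pytest.approx(21.0)
        assert m.species[m.species_index("GrS")].initial == pytest.approx(17.5)
        # nothing else changes
        assert m.species[m.species_index("K_T")].initial == pytest.approx(30.0)
        assert [r.value for r in m.reactions] == [r.value for r in default_model.reactions]

    def test_capacity_zero_equals_knockout_initials(self, default_model):
        g0 = pp.apply_capacity_factor(default_model, 0.0)
        ko = pp.knockout_system(default_model, "GroELS")
        assert [s.initial for s in g0.species] == [s.initial for s in ko.species]

    def test_knockout_idempotent_and_scoped(self, default_model):
        ko = pp.knockout_system(default_model, pp.System.GROELS)
        ko2 = pp.knockout_system(ko, pp.System.GROELS)
        assert [s.initial for s in ko.species] == [s.initial for s in ko2.species]
        assert ko.species[ko.species_index("GrL_T")].initial == 0.0
        assert ko.species[ko.species_index("GrS")].initial == 0.0
        assert ko.species[ko.species_index("K_T")].initial == pytest.approx(30.0)
        assert len(ko.reactions) == len(default_model.reactions)

    def test_knockout_kje_zeroes_all_three(self, default_model):
        ko = pp.knockout_system(default_model, "KJE")
        for name in ("K_T", "J2", "GrpE"):
            assert ko.species[ko.species_index(name)].initial == 0.0

    def test_knockout_unknown_system(self, default_model):
        with pytest.raises(ValueError):
            pp.knockout_system(default_model, "Hsp90")


def test_tsv_export(tmp_path, small_model):
    sp, rx = tmp_path / "species.tsv", tmp_path / "reactions.tsv"
    small_model.to_tsv(sp, rx)
    lines = sp.read_text().strip().split("\n")
    assert len(lines) == len(small_model.species) + 1
    lines = rx.read_text().strip().split("\n")
    assert len(lines) == len(small_model.reactions) + 1
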