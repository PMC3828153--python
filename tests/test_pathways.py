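"""Entry-channel decomposition, fluxes, mediation, proportionality fits."""

import numpy as np
import pytest

import proteopath as pp
from proteopath.committor import NonConvergenceError

import proteopath.pathways as pw


def toy_mu():
    """M -> U direct (rate 1); M -> X (1), X -> U (1), X -> M (1)."""
    K = np.zeros((3, 3))  # order M, U, X
    K[1, 0] = 1.0  # M -> U
    K[2, 0] = 1.0  # M -> X
    K[1, 2] = 1.0  # X -> U
    K[0, 2] = 1.0  # X -> M
    np.fill_diagonal(K, -K.sum(axis=0))
    return pp.RateMatrix.from_array(K, labels=["M", "U", "X"])


class TestToyDecomposition:
    def test_two_channel_probabilities(self):
        K = toy_mu()
        T = pp.build_transition_matrix(K)
        channels = {"direct": [("M", "U")], "viaX": [("X", "U")]}
        d = pp.pathway_probabilities(T, ["M"], ["U"], channels=channels)
        assert d.probabilities["direct"] == pytest.approx(2 / 3, abs=1e-10)
        assert d.probabilities["viaX"] == pytest.approx(1 / 3, abs=1e-10)

    def test_fluxes_on_toy(self):
        K = toy_mu()
        T = pp.build_transition_matrix(K)
        channels = {"direct": [("M", "U")], "viaX": [("X", "U")]}
        d = pp.pathway_probabilities(T, ["M"], ["U"], channels=channels)
        fl = pp.pathway_flux(d, K, {"M": 1.0})
        # direct flux 1*1; via-X flux 1*P(U before M | X) = 0.5
        assert fl["direct"] == pytest.approx(1.0, abs=1e-10)
        assert fl["viaX"] == pytest.approx(0.5, abs=1e-10)
        assert fl["direct"] / fl["viaX"] == pytest.approx(2.0, abs=1e-9)

    def test_single_channel_gets_probability_one(self):
        K = toy_mu()
        T = pp.build_transition_matrix(K)
        channels = {"all": [("M", "U"), ("X", "U")]}
        d = pp.pathway_probabilities(T, ["M"], ["U"], channels=channels)
        assert d.probabilities["all"] == pytest.approx(1.0)

    def test_incomplete_partition_rejected(self):
        K = toy_mu()
        T = pp.build_transition_matrix(K)
        with pytest.raises(ValueError):
            pp.pathway_probabilities(T, ["M"], ["U"], channels={"direct": [("M", "U")]})

    def test_duplicated_edge_rejected(self):
        K = toy_mu()
        T = pp.build_transition_matrix(K)
        channels = {"a": [("M", "U"), ("X", "U")], "b": [("X", "U")]}
        with pytest.raises(ValueError):
            pp.pathway_probabilities(T, ["M"], ["U"], channels=channels)

    def test_zero_reactive_probability_flagged(self):
        # U unreachable from M: the only M edge returns via X
        K = np.zeros((3, 3))
        K[2, 0] = 1.0  # M -> X
        K[0, 2] = 1.0  # X -> M
        K[0, 1] = 1.0  # U -> M (so U has dynamics but is never entered)
        np.fill_diagonal(K, -K.sum(axis=0))
        T = pp.build_transition_matrix(pp.RateMatrix.from_array(K, labels=["M", "U", "X"]))
        with pytest.raises(NonConvergenceError):
            pp.pathway_probabilities(T, ["M"], ["U"], channels={})


class TestFullModelDecomposition:
    def test_exactly_five_reactive_channels(self, default_decomp):
        nonzero = {ch for ch, p in default_decomp.probabilities.items() if p > 0}
        assert nonzero == {"direct", "KJE", "GroELS", "B+KJE", "degradation"}

    def test_channel_probabilities_sum_to_one(self, default_decomp):
        assert sum(default_decomp.probabilities.values()) == pytest.approx(1.0, abs=1e-8)

    def test_holder_channels_carry_no_mass(self, default_decomp):
        # trigger factor and Lon complexes are entered only from U itself
        assert default_decomp.probabilities["TriggerFactor"] == 0.0
        assert default_decomp.probabilities["Lon_release"] == 0.0

    def test_tau_refinement_invariance(self, default_K, default_decomp):
        T2 = pp.build_transition_matrix(default_K, safety=0.25)
        d2 = pp.pathway_probabilities(T2, ["M"], ["U"], K=default_K)
        for ch, p in default_decomp.probabilities.items():
            assert abs(d2.probabilities[ch] - p) < 1e-6

    def test_groels_knockout_zeroes_channel(self, default_model):
        ko = pp.knockout_system(default_model, "GroELS")
        d, fl, _, _, _ = pp.run_point(ko, pp.AnalysisConfig(n_points=5), ("M", "U"))
        assert fl["GroELS"] == pytest.approx(0.0, abs=1e-15)

    def test_folding_direct_flux_is_kfold_times_u(
        self, default_model, default_state, default_K, default_T
    ):
        d = pp.pathway_probabilities(default_T, ["U"], ["N"], K=default_K)
        fl = pp.pathway_flux(d, default_K, default_state)
        assert fl["direct"] == pytest.approx(
            default_model.rate("k_fold") * default_state["U"], rel=1e-12
        )
        # folding proceeds through exactly two channels: direct and GroELS
        nonzero = {ch for ch, p in d.probabilities.items() if p > 0}
        assert nonzero == {"direct", "GroELS"}


class TestMediation:
    def test_forced_mediation_is_one(self):
        # A -> x; x -> {A, C}; C -> {x, B}: every reactive A->B path passes C
        K = np.zeros((4, 4))
        K[2, 0] = 1.0  # A -> x
        K[0, 2] = 1.0  # x -> A
        K[3, 2] = 1.0  # x -> C
        K[2, 3] = 1.0  # C -> x
        K[1, 3] = 1.0  # C -> B
        np.fill_diagonal(K, -K.sum(axis=0))
        T = pp.build_transition_matrix(pp.RateMatrix.from_array(K, labels=["A", "B", "x", "C"]))
        assert pp.mediation_probability(T, ["A"], ["B"], ["C"]) == pytest.approx(1.0, abs=1e-10)

    def test_unreachable_mediator_is_zero(self):
        Km = np.zeros((4, 4))  # A B x c ; c has dynamics but is never entered
        Km[2, 0] = 1.0  # A -> x
        Km[1, 2] = 1.0  # x -> B
        Km[0, 2] = 1.0  # x -> A
        Km[2, 3] = 1.0  # c -> x (c never entered)
        np.fill_diagonal(Km, -Km.sum(axis=0))
        T = pp.build_transition_matrix(pp.RateMatrix.from_array(Km, labels=["A", "B", "x", "c"]))
        assert pp.mediation_probability(T, ["A"], ["B"], ["c"]) == pytest.approx(0.0, abs=1e-12)

    def test_toy_channel_equivalence(self):
        """When the mediator's only exits toward the target are its release
        edges, mediation equals the channel probability."""
        K = toy_mu()
        T = pp.build_transition_matrix(K)
        channels = {"direct": [("M", "U")], "viaX": [("X", "U")]}
        d = pp.pathway_probabilities(T, ["M"], ["U"], channels=channels)
        m = pp.mediation_probability(T, ["M"], ["U"], ["X"])
        assert m == pytest.approx(d.probabilities["viaX"], abs=1e-10)

    def test_full_model_mediation_bounds_channel(self, default_T, default_K, default_decomp):
        """On the full network a GroEL-visiting path can still enter U through
        the N->U conversion edge, so mediation >= channel probability."""
        C = [s.label for s in default_K.states if s.system is pp.System.GROELS]
        m = pp.mediation_probability(default_T, ["M"], ["U"], C)
        assert m >= default_decomp.probabilities["GroELS"] - 1e-10
        assert m <= 1.0


class TestEntranceRates:
    def test_lookup_matches_construction(self, default_model, default_state, default_K):
        rates = pp.entrance_rates(default_K, "M", ["K_T:M", "GrL_T:M"])
        assert rates["K_T:M"] == pytest.approx(
            default_model.rate("k_km_on") * default_state["K_T"]
        )
        assert rates["GrL_T:M"] == pytest.approx(
            default_model.rate("k_gm_on") * default_state["GrL_T"]
        )

    def test_chaperonin_entrance_faster_than_dnak(self, default_K):
        rates = pp.entrance_rates(default_K, "M", ["K_T:M", "GrL_T:M"])
        assert rates["GrL_T:M"] > rates["K_T:M"]

    def test_binding_factor_scales_entrance(self):
        cfg = pp.AnalysisConfig(n_points=5)
        rates = {}
        for lam in (1.0, 2.0):
            m = pp.build_model(
                pp.PROFILES["default"],
                options=pp.ModelOptions(binding_factor=lam, ribosome_activation_rate=1e-6),
            )
            final = pp.propagate(m, cfg)[-1]
            K = pp.extract_rate_matrix(m, final)
            rates[lam] = (
                pp.entrance_rates(K, "M", ["GrL_T:M"])["GrL_T:M"] / final["GrL_T"],
                pp.entrance_rates(K, "M", ["K_T:M"])["K_T:M"] / final["K_T"],
            )
        assert rates[2.0][0] == pytest.approx(2 * rates[1.0][0])
        assert rates[2.0][1] == pytest.approx(rates[1.0][1] / 2)

    def test_unknown_state_rejected(self, default_K):
        with pytest.raises(KeyError):
            pp.entrance_rates(default_K, "M", ["Hsp104:M"])


class TestProportionalityFit:
    def test_exact_proportionality(self):
        fit = pp.fit_proportionality([(1, 2), (2, 4)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_least_squares_value(self):
        fit = pp.fit_proportionality([(1, 1), (2, 4)])
        assert fit.slope == pytest.approx(9 / 5)

    def test_single_point(self):
        assert pp.fit_proportionality([(3, 6)]).slope == pytest.approx(2.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pp.fit_proportionality([])
        with pytest.raises(ValueError):
            pp.fit_proportionality([(0.0, 1.0)])
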