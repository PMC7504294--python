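"""The ten-channel reaction network: stoichiometry, propensities, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mablabel import _core
from mablabel.reaction_network import (
    CHANNEL_ORDER,
    STATE_FIELDS,
    GeometryParams,
    InvariantViolation,
    ParameterError,
    RateConstants,
    SystemState,
    apply_channel,
    build_channels,
    change_matrix,
    propensities,
)
from conftest import random_states

# Printed change matrix, columns (A_b, A_c, A_o, AR, ARR, R) transposed from
# the published row layout; frozen here independently of the implementation.
EXPECTED_DELTAS = {
    "k_2p": (1, 0, 0, 0, 0, 0),
    "k_2n": (-1, 0, 0, 0, 0, 0),
    "k_1p": (-1, 1, 0, 0, 0, 0),
    "k_1n": (1, -1, 0, 0, 0, 0),
    "k_on": (0, -1, 1, 0, 0, 0),
    "k_off": (0, 1, -1, 0, 0, 0),
    "k_mp": (0, 0, -1, 1, 0, -1),
    "k_mn": (0, 0, 1, -1, 0, 1),
    "k_bp": (0, 0, 0, -1, 1, -1),
    "k_bn": (0, 0, 0, 1, -1, 1),
}


def brute_force_propensities(state, rates):
    """Direct transcription of the propensity formulas, used as the oracle."""
    return np.array([
        rates.k_2p * state.A_s,
        rates.k_2n * state.A_b,
        rates.k_1p * state.A_b,
        rates.k_1n * state.A_c,
        rates.k_on * state.A_c,
        rates.k_off * state.A_o,
        rates.k_mp * state.A_o * state.R,
        rates.k_mn * state.AR,
        rates.k_bp * state.AR * state.R,
        rates.k_bn * state.ARR,
    ])


class TestRateConstants:
    def test_derived_diffusion_rates(self):
        """Hop rates are D/h^2; for the default geometry 0.5e-10/(3.75e-6)^2."""
        rates = RateConstants.from_geometry()
        expected = 0.5e-10 / (3.75e-6) ** 2  # = 3.5556/s by hand
        assert expected == pytest.approx(3.5555555e0, rel=1e-6)
        for name in ("k_2p", "k_2n", "k_1p", "k_1n", "k_on"):
            assert getattr(rates, name) == pytest.approx(expected)
        assert rates.k_off == pytest.approx(0.5 * expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            RateConstants.from_geometry().with_binding(k_bp=-1.0)

    def test_geometry_must_be_positive(self):
        with pytest.raises(ParameterError):
            GeometryParams(D=0.0)


class TestChannels:
    def test_canonical_order_and_deltas(self, channels):
        assert [ch.name for ch in channels] == list(CHANNEL_ORDER)
        for ch in channels:
            assert ch.delta == EXPECTED_DELTAS[ch.name]

    def test_receptor_conservation_per_channel(self, channels):
        """dR + dAR + 2*dARR = 0 for every channel."""
        i_ar, i_arr, i_r = (STATE_FIELDS.index(f) for f in ("AR", "ARR", "R"))
        for ch in channels:
            assert ch.delta[i_r] + ch.delta[i_ar] + 2 * ch.delta[i_arr] == 0

    def test_mab_flux_per_channel(self, channels):
        """Total tracked mAb changes only through the source exchange pair."""
        expected_flux = {"k_2p": 1, "k_2n": -1}
        for ch in channels:
            flux = sum(ch.delta[STATE_FIELDS.index(f)]
                       for f in ("A_b", "A_c", "A_o", "AR", "ARR"))
            assert flux == expected_flux.get(ch.name, 0)

    def test_compiled_kernel_matrix_matches(self, channels):
        np.testing.assert_array_equal(_core.CHANGE_MATRIX,
                                      change_matrix(channels))


class TestPropensities:
    def test_oracle_equivalence_on_random_states(self, similar_rates,
                                                 channels, rng):
        """Channel-object propensities equal the formula transcription."""
        for state in random_states(rng, 1000):
            np.testing.assert_allclose(
                propensities(state, channels),
                brute_force_propensities(state, similar_rates), rtol=1e-12)

    def test_bimolecular_product(self, similar_rates, channels):
        state = SystemState(A_o=6000, R=100_000)
        alpha = propensities(state, channels)
        assert alpha[CHANNEL_ORDER.index("k_mp")] == pytest.approx(
            1e-4 * 6000 * 100_000)  # = 6.0e4 /s

    def test_only_source_channel_active_in_empty_system(self, similar_rates,
                                                        channels):
        state = SystemState(A_s=3000)
        alpha = propensities(state, channels)
        assert alpha[0] == pytest.approx(similar_rates.k_2p * 3000)
        assert np.all(alpha[1:] == 0.0)

    def test_source_influx_rate_from_geometry(self, channels):
        """alpha_2p = (D/h_t^2) * A_s with independently computed D/h^2."""
        state = SystemState(A_s=3000)
        alpha = propensities(state, channels)
        assert alpha[0] == pytest.approx(0.5e-10 / 3.75e-6 ** 2 * 3000)


class TestApplyChannel:
    def test_monovalent_binding_event(self, channels):
        state = SystemState(A_o=5, R=10, A_s=0)
        new = apply_channel(state, channels[CHANNEL_ORDER.index("k_mp")])
        assert (new.A_o, new.R, new.AR) == (4, 9, 1)

    def test_bivalent_dissociation_event(self, channels):
        state = SystemState(AR=3, ARR=2, R=0, A_s=0)
        new = apply_channel(state, channels[CHANNEL_ORDER.index("k_bn")])
        assert (new.AR, new.ARR, new.R) == (4, 1, 1)

    def test_hop_round_trip(self, channels, small_state):
        i_fwd = CHANNEL_ORDER.index("k_1p")
        i_bwd = CHANNEL_ORDER.index("k_1n")
        back = apply_channel(apply_channel(small_state, channels[i_fwd]),
                             channels[i_bwd])
        assert back.as_array().tolist() == small_state.as_array().tolist()

    def test_source_count_untouched(self, channels, small_state):
        for ch in channels:
            assert apply_channel(small_state, ch).A_s == small_state.A_s

    def test_negative_count_raises(self, channels):
        state = SystemState(A_b=0, A_s=0)
        with pytest.raises(InvariantViolation):
            apply_channel(state, channels[CHANNEL_ORDER.index("k_2n")])

    def test_receptor_conservation_over_random_sequences(self, channels, rng):
        state = SystemState(A_b=50, A_c=50, A_o=50, AR=50, ARR=50, R=200,
                            A_s=100)
        total = state.receptor_total
        for _ in range(500):
            feasible = [ch for ch in channels
                        if all(getattr(state, f) >= 1
                               for f in ch.reactant_spec if f != "A_s")]
            state = apply_channel(state, feasible[rng.randint(len(feasible))])
            assert state.receptor_total == total


counts_strategy = st.integers(min_value=0, max_value=10 ** 6)


class TestStateProperties:
    @settings(derandomize=True, max_examples=200)
    @given(A_b=counts_strategy, A_c=counts_strategy, A_o=counts_strategy,
           AR=counts_strategy, ARR=counts_strategy, R=counts_strategy,
           A_s=counts_strategy)
    def test_propensities_nonnegative_and_zero_iff_no_reactant(
            self, A_b, A_c, A_o, AR, ARR, R, A_s):
        """alpha >= 0 always; alpha = 0 exactly when a reactant count is 0."""
        rates = RateConstants.from_geometry()
        channels = build_channels(rates)
        state = SystemState(A_b=A_b, A_c=A_c, A_o=A_o, AR=AR, ARR=ARR, R=R,
                            A_s=A_s)
        for ch, a in zip(channels, propensities(state, channels)):
            assert a >= 0.0
            has_reactants = all(getattr(state, f) > 0
                                for f in ch.reactant_spec)
            assert (a > 0) == has_reactants

    @settings(derandomize=True, max_examples=200)
    @given(AR=counts_strategy, ARR=counts_strategy, R=counts_strategy,
           idx=st.integers(min_value=0, max_value=9))
    def test_any_feasible_event_conserves_receptors(self, AR, ARR, R, idx):
        rates = RateConstants.from_geometry()
        channels = build_channels(rates)
        state = SystemState(A_b=5, A_c=5, A_o=5, AR=AR, ARR=ARR, R=R, A_s=5)
        ch = channels[idx]
        if any(getattr(state, f) < 1 for f in ch.reactant_spec
               if f != "A_s"):
            return  # infeasible channel for this state
        new = apply_channel(state, ch)
        assert new.receptor_total == state.receptor_total


class TestSystemState:
    def test_abc_accessor(self):
        s = SystemState(AR=3, ARR=4)
        assert s.abc == 7
        assert s.bound_receptors == 11

    def test_counts_must_be_integers(self):
        with pytest.raises(ParameterError):
            SystemState(A_b=1.5)

    def test_counts_must_be_nonnegative(self):
        with pytest.raises(ParameterError):
            SystemState(R=-1)
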