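"""Cell-cycle compartment progression, checkpoints and phase-resolved kill."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radioresponse import RadiobiologyParams
from radioresponse.cellcycle import (
    N_G1,
    N_S,
    N_SLOTS,
    CheckpointPolicy,
    PhaseState,
    advance_one_hour,
    checkpoint_draw,
    irradiate_phases,
    phase_percentages,
)

OXIC_PO2 = 40.0
TABLE_T0 = {"G1": 68.44, "S": 20.04, "G2": 8.77, "M": 2.75}


def open_policy(p1=1.0, p2=1.0):
    return CheckpointPolicy(g1s_probability=p1, g2m_probability=p2)


class TestCheckpointDraw:
    def test_degenerate_probabilities(self, rng):
        assert checkpoint_draw(1000, 1.0, rng) == 1000
        assert checkpoint_draw(1000, 0.0, rng) == 0
        assert checkpoint_draw(0, 0.5, rng) == 0

    def test_large_population_within_three_sigma(self):
        """Normal-approximated draws agree with the binomial moments."""
        n, p = 10**6, 0.5
        sd = np.sqrt(n * p * (1 - p))
        draws = [
            checkpoint_draw(n, p, np.random.default_rng(seed))
            for seed in range(100)
        ]
        assert max(abs(d - n * p) for d in draws) <= 3 * sd

    def test_small_population_exact_binomial_support(self, rng):
        draws = [checkpoint_draw(10, 0.3, rng) for _ in range(200)]
        assert all(0 <= d <= 10 for d in draws)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            checkpoint_draw(10, 1.5, rng)


class TestAdvance:
    def test_pure_shift_within_phase(self, params):
        state = PhaseState()
        state.slots[4] = 1000.0  # G1 compartment 5
        out = advance_one_hour(state, OXIC_PO2, open_policy(), params=params)
        assert out.slots[5] == 1000.0
        assert out.total == 1000.0

    def test_mitosis_doubles_into_first_g1_slot(self, params):
        state = PhaseState()
        state.slots[N_SLOTS - 1] = 100.0  # cells completing M
        out = advance_one_hour(state, OXIC_PO2, open_policy(), params=params)
        assert out.slots[0] == 200.0
        assert out.total == 200.0

    def test_g1s_failures_become_quiescent(self, params):
        state = PhaseState()
        state.slots[N_G1 - 1] = 1000.0
        out = advance_one_hour(state, OXIC_PO2, open_policy(p1=0.0), params=params)
        assert out.g0 == 1000.0
        assert out.slots.sum() == 0.0

    def test_g2m_failures_arrest_in_place(self, params):
        """A closed G2/M checkpoint accumulates cells in the last G2
        compartment (they retry later) rather than discarding them."""
        state = PhaseState()
        state.slots[N_SLOTS - 2] = 500.0  # last G2 compartment
        out = advance_one_hour(state, OXIC_PO2, open_policy(p2=0.0), params=params)
        assert out.slots[N_SLOTS - 2] == 500.0
        assert out.slots[N_SLOTS - 1] == 0.0
        assert out.g0 == 0.0

    def test_quiescent_cells_reattempt_entry(self, params):
        state = PhaseState(g0=1000.0)
        out = advance_one_hour(state, OXIC_PO2, open_policy(p1=0.25), params=params)
        assert out.slots[N_G1] == 250.0  # first S compartment
        assert out.g0 == 750.0

    def test_open_checkpoints_double_population_in_24h(self, params):
        state = PhaseState.cycling_uniform(24000.0)
        for _ in range(24):
            state = advance_one_hour(state, OXIC_PO2, open_policy(), params=params)
        assert state.total == pytest.approx(48000.0, rel=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_count_conserved_except_mitosis(self, seed):
        params = RadiobiologyParams()
        r = np.random.default_rng(seed)
        state = PhaseState(r.uniform(0, 100, N_SLOTS), g0=float(r.uniform(0, 100)))
        m_out = state.slots[N_SLOTS - 1]
        policy = open_policy(p1=float(r.uniform(0, 1)), p2=float(r.uniform(0, 1)))
        out = advance_one_hour(state, OXIC_PO2, policy, params=params)
        assert out.total == pytest.approx(state.total + m_out, rel=1e-9)

    def test_stochastic_mode_conserves_integers(self, params, rng):
        state = PhaseState(np.full(N_SLOTS, 1000.0), g0=500.0)
        out = advance_one_hour(state, OXIC_PO2, open_policy(p1=0.5, p2=0.5),
                               rng=rng, params=params)
        assert out.total == state.total + 1000  # all 1000 M cells divided
        assert np.all(out.slots == np.rint(out.slots))


class TestIrradiation:
    def test_zero_dose_is_identity(self, params):
        state = PhaseState.cycling_uniform(1e6)
        out, killed = irradiate_phases(state, 0.0, 5.0, params)
        assert killed == 0.0
        np.testing.assert_array_equal(out.slots, state.slots)

    def test_equal_weights_scale_every_phase_alike(self, params):
        p = params.replace(phase_weights={k: 1.0 for k in "G0 G1 S G2 M".split()})
        state = PhaseState(np.linspace(10, 100, N_SLOTS), g0=50.0)
        out, killed = irradiate_phases(state, 1.0, 5.0, p)
        sf = out.slots / state.slots
        np.testing.assert_allclose(sf, sf[0], rtol=1e-12)
        assert killed == pytest.approx(state.total - out.total)

    def test_s_phase_share_enriched_among_survivors(self, params):
        """S is the most radioresistant cycling phase, so its share of the
        surviving cycling population exceeds its pre-irradiation share."""
        state = PhaseState.cycling_uniform(1e6)
        pre = phase_percentages(state)
        out, _ = irradiate_phases(state, 2.0, 5.0, params)
        post = phase_percentages(out)
        assert post["S"] > pre["S"]

    def test_arrest_engaged_after_dose(self, params):
        state = PhaseState.cycling_uniform(1e6)
        out, _ = irradiate_phases(state, 1.0, 5.0, params)
        assert out.arrest_remaining == params.arrest_duration

    def test_post_rt_g2_peak_and_s_dip_then_relaxation(self, params):
        """After a fraction the G2 share peaks (checkpoint block) while S
        drains, and the distribution relaxes once the arrest expires."""
        policy = CheckpointPolicy(g1s_probability=0.66)
        state = PhaseState.cycling_uniform(1e6)
        for _ in range(20):
            state = advance_one_hour(state, OXIC_PO2, policy, params=params)
        pre = phase_percentages(state)
        state, _ = irradiate_phases(state, 2.0, OXIC_PO2, params)
        g2_traj, s_traj = [], []
        for _ in range(20):
            state = advance_one_hour(state, OXIC_PO2, policy, params=params)
            pct = phase_percentages(state)
            g2_traj.append(pct["G2"])
            s_traj.append(pct["S"])
        peak_hour = int(np.argmax(g2_traj))
        assert max(g2_traj) > pre["G2"]
        assert peak_hour <= params.arrest_duration + 1
        assert g2_traj[-1] < 0.5 * max(g2_traj)  # relaxation
        assert min(s_traj) < pre["S"]


class TestPhasePercentages:
    def test_all_in_s(self):
        state = PhaseState()
        state.slots[N_G1 : N_G1 + N_S] = 10.0
        pct = phase_percentages(state)
        assert pct["S"] == 100.0
        assert pct["G1"] == pct["G2"] == pct["M"] == 0.0

    def test_sums_to_100_including_g0(self, rng):
        state = PhaseState(rng.uniform(0, 50, N_SLOTS), g0=123.0)
        assert sum(phase_percentages(state).values()) == pytest.approx(100.0, abs=1e-9)

    def test_percentage_roundtrip(self):
        state = PhaseState.from_phase_percentages(TABLE_T0, total=1e6)
        pct = phase_percentages(state)
        for phase, value in TABLE_T0.items():
            assert pct[phase] == pytest.approx(value, abs=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            phase_percentages(PhaseState())
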