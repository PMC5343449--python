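"""Game engine: phases, payoff bookkeeping, and cross-engine identity."""

import numpy as np
import pytest

from normknock import SimConfig
from normknock.engine import (
    init_generation,
    play_phase_A,
    play_phase_B,
    run_generation,
)
from normknock._kernel import generation_kernel
from normknock.norms import ALLB, ALLG, GOOD, SH
from normknock.reference import naive_run_generation


def _config(n=6, rounds=5, **kw):
    kw.setdefault("benefit", 5.0)
    kw.setdefault("cost", 1.0)
    return SimConfig(n_agents=n, generations=1, rounds=rounds, **kw)


class TestInitGeneration:
    def test_fresh_state_all_good_zero_payoffs(self):
        cfg = _config(n=3)
        state = init_generation(cfg, np.array([ALLG, SH, ALLB]))
        assert np.all(state.images == GOOD)
        assert state.images.shape == (3, 3)
        assert np.all(state.payoffs == 0)
        assert np.all(state.received == 0) and np.all(state.given == 0)
        assert state.round_index == 0

    def test_two_agent_boundary(self, rs):
        cfg = _config(n=2, rounds=1)
        state = init_generation(cfg, np.array([ALLG, ALLG]))
        rec = play_phase_A(state, rs())
        # each donor's only possible recipient is the other agent
        assert list(rec.recipients) == [1, 0]

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError, match="norms"):
            init_generation(_config(n=4), np.zeros(3, dtype=np.int64))

    def test_rejects_knocked_out_norms(self):
        cfg = _config(knockout=frozenset({SH}))
        with pytest.raises(ValueError, match="knocked-out"):
            init_generation(cfg, np.full(6, SH, dtype=np.int64))


class TestPhaseA:
    def test_all_good_payoffs_and_conservation(self, rs):
        cfg = _config(n=4, benefit=5.0, cost=1.0)
        state = init_generation(cfg, np.full(4, ALLG, dtype=np.int64))
        play_phase_A(state, rs(7))
        # everyone cooperated once as donor
        assert np.array_equal(state.payoffs, 5.0 * state.received - 1.0)
        assert state.payoffs.sum() == 4 * (5.0 - 1.0)
        assert state.coop_counts == [4]

    def test_bad_image_means_defection(self, rs):
        cfg = _config(n=2, rounds=1)
        state = init_generation(cfg, np.array([ALLG, ALLG]))
        state.images[0, 1] = 0  # donor 0 sees its only recipient as Bad
        rec = play_phase_A(state, rs())
        assert rec.realized[0] == 0
        # donor 0 paid nothing and transferred nothing; it still received
        # donor 1's gift, so only the b it was given shows up
        assert state.payoffs[0] == cfg.benefit
        assert state.given[0] == 0 and state.received[1] == 0

    def test_q_half_flips_about_half(self, rs):
        cfg = _config(n=50, q_error=0.5)
        state = init_generation(cfg, np.full(50, ALLG, dtype=np.int64))
        total = 0
        rounds = 200
        rng = rs(1)
        for _ in range(rounds):
            rec = play_phase_A(state, rng)
            state.images[:] = GOOD  # keep intentions all-C
            total += int(rec.realized.sum())
        n_draws = 50 * rounds
        sigma = np.sqrt(n_draws * 0.25)
        assert abs(total - 0.5 * n_draws) < 4 * sigma

    def test_never_donates_to_self(self, rs):
        cfg = _config(n=9, rounds=1)
        state = init_generation(cfg, np.full(9, ALLG, dtype=np.int64))
        for seed in range(30):
            rec = play_phase_A(state, rs(seed))
            assert np.all(rec.recipients != np.arange(9))
            assert np.all((0 <= rec.recipients) & (rec.recipients < 9))


class TestPhaseB:
    def test_allb_population_turns_all_bad_after_round_one(self, rs):
        cfg = _config(n=5)
        state = init_generation(cfg, np.full(5, ALLB, dtype=np.int64))
        rec = play_phase_A(state, rs(3))
        play_phase_B(state, rec, rs(4))
        off = ~np.eye(5, dtype=bool)
        assert np.all(state.images[off] == 0)
        assert np.all(np.diag(state.images) == GOOD)

    def test_allg_population_is_a_fixed_point(self, rs):
        cfg = _config(n=5)
        state = init_generation(cfg, np.full(5, ALLG, dtype=np.int64))
        for _ in range(3):
            rec = play_phase_A(state, rs(1))
            play_phase_B(state, rec, rs(2))
        assert np.all(state.images == GOOD)

    def test_p_one_negates_every_off_diagonal_assessment(self, rs):
        cfg = _config(n=5, p_error=1.0)
        state = init_generation(cfg, np.full(5, ALLG, dtype=np.int64))
        rec = play_phase_A(state, rs(0))
        play_phase_B(state, rec, rs(0))
        off = ~np.eye(5, dtype=bool)
        assert np.all(state.images[off] == 0)  # ALLG assesses Good, flipped to Bad
        assert np.all(np.diag(state.images) == GOOD)

    def test_diagonal_stays_good_under_noise(self, rs):
        cfg = _config(n=8, p_error=0.4, q_error=0.3)
        state = init_generation(cfg, rs(5).randint(0, 16, 8))
        rng = rs(11)
        for _ in range(6):
            rec = play_phase_A(state, rng)
            play_phase_B(state, rec, rng)
            assert np.all(np.diag(state.images) == GOOD)


class TestRunGeneration:
    def test_monomorphic_allg_full_cooperation(self, rs):
        cfg = _config(n=6, rounds=8)
        pay, coop = run_generation(cfg, np.full(6, ALLG, dtype=np.int64), rs(0))
        assert list(coop) == [6] * 8
        assert np.array_equal(pay.payoffs, cfg.benefit * pay.received - cfg.cost * 8)
        assert pay.received.sum() == 6 * 8

    def test_monomorphic_allb_cooperates_only_in_round_one(self, rs):
        # all images start Good so round 1 is all-C; ALLB then paints
        # everyone Bad and no donation happens again
        cfg = _config(n=6, rounds=10)
        _, coop = run_generation(cfg, np.full(6, ALLB, dtype=np.int64), rs(2))
        assert list(coop) == [6] + [0] * 9
        assert coop.sum() / (6 * 10) == pytest.approx(1 / 10)

    def test_single_round_boundary(self, rs):
        cfg = _config(n=4, rounds=1)
        _, coop = run_generation(cfg, np.full(4, ALLG, dtype=np.int64), rs(0))
        assert coop.shape == (1,)

    @pytest.mark.parametrize("timing", ["same_round", "lagged"])
    def test_payoff_conservation_random_runs(self, rs, timing):
        master = rs(99)
        for _ in range(100):
            n = int(master.randint(2, 12))
            cfg = _config(
                n=n,
                rounds=int(master.randint(1, 8)),
                benefit=float(master.randint(2, 7)),
                cost=1.0,
                p_error=float(master.choice([0.0, 0.001, 0.3])),
                q_error=float(master.choice([0.0, 0.001, 0.3])),
                evaluation_timing=timing,
            )
            norms = master.randint(0, 16, n)
            pay, coop = run_generation(cfg, norms, rs(int(master.randint(2**31))))
            assert pay.payoffs.sum() == pytest.approx(
                (cfg.benefit - cfg.cost) * coop.sum()
            )
            assert np.array_equal(
                pay.payoffs, cfg.benefit * pay.received - cfg.cost * pay.given
            )


class TestEngineEquivalence:
    """The vectorized, naive-reference and numba engines share one draw
    protocol and must produce bit-identical generations."""

    @pytest.mark.parametrize("timing", ["same_round", "lagged"])
    def test_vectorized_matches_naive_reference(self, rs, timing):
        master = rs(42)
        for _ in range(50):
            n = int(master.randint(2, 21))
            cfg = _config(
                n=n,
                rounds=int(master.randint(1, 21)),
                benefit=float(master.randint(2, 7)),
                p_error=float(master.choice([0.0, 0.001, 0.2])),
                q_error=float(master.choice([0.0, 0.001, 0.2])),
                evaluation_timing=timing,
            )
            norms = master.randint(0, 16, n)
            seed = int(master.randint(2**31))
            pay_v, coop_v = run_generation(cfg, norms, rs(seed))
            pay_n, coop_n, _ = naive_run_generation(cfg, norms, rs(seed))
            assert np.array_equal(pay_v.payoffs, pay_n.payoffs)
            assert np.array_equal(pay_v.received, pay_n.received)
            assert np.array_equal(pay_v.given, pay_n.given)
            assert np.array_equal(coop_v, coop_n)

    @pytest.mark.parametrize("timing", ["same_round", "lagged"])
    def test_numba_kernel_matches_naive_reference(self, rs, timing):
        master = rs(43)
        for _ in range(20):
            n = int(master.randint(2, 16))
            rounds = int(master.randint(1, 12))
            p = float(master.choice([0.0, 0.05]))
            q = float(master.choice([0.0, 0.05]))
            cfg = _config(n=n, rounds=rounds, p_error=p, q_error=q,
                          evaluation_timing=timing)
            norms = master.randint(0, 16, n)
            seed = int(master.randint(2**31))
            u, w, v, coop, img = generation_kernel(
                norms, rounds, cfg.benefit, cfg.cost, p, q, timing, seed
            )
            pay_n, coop_n, img_n = naive_run_generation(cfg, norms, rs(seed))
            assert np.array_equal(u, pay_n.payoffs)
            assert np.array_equal(coop, coop_n)
            assert np.array_equal(img, img_n)
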