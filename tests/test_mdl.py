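import warnings

import numpy as np
import pytest

from ditras.diary import TypicalDiary, parse_diary
from ditras.mdl import (
    AbstractTrajectory,
    MarkovDiaryModel,
    abstractify,
    diary_to_abstract,
    estimate_typical_diary,
    fit_markov,
    md_generate,
)


def records_from_hourly(slots):
    """Build (timestamp, location) records from a per-hour description.

    Each entry is None (no observation), a single id, or a list of ids
    observed within that hour.
    """
    recs = []
    for h, entry in enumerate(slots):
        if entry is None:
            continue
        ids = entry if isinstance(entry, list) else [entry]
        for k, loc in enumerate(ids):
            recs.append((h * 3600.0 + 60.0 * (k + 1), loc))
    return recs


class TestAbstractify:
    def test_gap_filling_and_overall_frequency_tie_break(self):
        # [A, A, •, •, B, (C,C,B,B)]: gaps inherit A; the last slot ties C/B
        # within the slot and resolves to B by overall frequency
        recs = records_from_hourly(["A", "A", None, None, "B", ["C", "C", "B", "B"]])
        traj = abstractify(recs, 3600, start=0.0, n_slots=6)
        assert traj.symbols == ("A", "A", "A", "A", "B", "B")

    def test_constant_records(self):
        recs = records_from_hourly(["H"] * 4)
        assert abstractify(recs, 3600, start=0.0, n_slots=4).symbols == ("H",) * 4

    def test_full_tie_breaks_lexicographically(self):
        # X and Y tie in the slot and overall: smaller id wins, deterministically
        recs = records_from_hourly([["Y", "X"], None])
        traj = abstractify(recs, 3600, start=0.0, n_slots=2)
        assert traj.symbols == ("X", "X")

    def test_leading_gap_backfilled(self):
        recs = records_from_hourly([None, None, "B", "C"])
        assert abstractify(recs, 3600, start=0.0, n_slots=4).symbols == ("B", "B", "B", "C")

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError, match="sorted"):
            abstractify([(7200.0, "A"), (0.0, "B")], 3600)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            abstractify([], 3600)


class TestTypicalDiary:
    def test_majority_home(self):
        traj = AbstractTrajectory(tuple(["H"] * 10 + ["W"] * 5))
        assert estimate_typical_diary(traj).home_symbol == "H"

    def test_single_slot(self):
        assert estimate_typical_diary(AbstractTrajectory(("Z",))).home_symbol == "Z"

    def test_tie_goes_to_smaller_id(self):
        traj = AbstractTrajectory(("B", "A", "A", "B"))
        assert estimate_typical_diary(traj).home_symbol == "A"


class TestFitMarkov:
    def test_degenerate_always_home(self):
        corpus = [
            (AbstractTrajectory(("H",) * 12), TypicalDiary(12, "H")) for _ in range(3)
        ]
        model = fit_markov(corpus, n_period=4)
        for h in range(4):
            assert model.prob((h, 1), ((h + 1) % 4, 1)) == 1.0

    def test_hand_tallied_two_user_corpus(self):
        # user 1: H H X H; user 2: H X X H, period 4.  Chain events:
        #   u1: (0,1)->(1,1); (1,1)->(2,0) tau=1; (2,0)->(3,1)
        #   u2: (0,1)->(2,0) tau=2;              (2,0)->(3,1)
        corpus = [
            (AbstractTrajectory(("H", "H", "X", "H")), TypicalDiary(4, "H")),
            (AbstractTrajectory(("H", "X", "X", "H")), TypicalDiary(4, "H")),
        ]
        model = fit_markov(corpus, n_period=4)
        assert model.prob((0, 1), (1, 1)) == pytest.approx(0.5)
        assert model.prob((0, 1), (2, 0)) == pytest.approx(0.5)
        assert model.prob((1, 1), (2, 0)) == pytest.approx(1.0)
        assert model.prob((2, 0), (3, 1)) == pytest.approx(1.0)

    def test_rows_are_stochastic(self, fitted_model):
        for s, row in fitted_model.transitions.items():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(p >= 0 for p in row.values())

    def test_only_legal_transition_types(self, fitted_model):
        P = fitted_model.n_period
        for (h, r), row in fitted_model.transitions.items():
            for (h2, r2) in row:
                if r2 == 1:
                    assert h2 == (h + 1) % P  # returns advance one slot
                else:
                    assert 1 <= (h2 - h) % P <= P - 1  # stays last tau slots

    def test_rejects_too_short_trajectories(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_markov([(AbstractTrajectory(("H",)), TypicalDiary(1, "H"))])


class TestGenerate:
    def test_all_home_chain_gives_all_ones(self):
        transitions = {(h, 1): {((h + 1) % 4, 1): 1.0} for h in range(4)}
        model = MarkovDiaryModel(transitions, n_period=4)
        d = md_generate(model, 10, np.random.default_rng(0))
        assert d.text == "1" * 10

    def test_deterministic_walk_trace(self):
        # (0,1)->(1,1)->(3,0) with tau=2 ->(4,1): emits 1, 1, |00, |1
        transitions = {
            (0, 1): {(1, 1): 1.0},
            (1, 1): {(3, 0): 1.0},
            (3, 0): {(4, 1): 1.0},
            (4, 1): {(5, 1): 1.0},
        }
        model = MarkovDiaryModel(transitions, n_period=8)
        d = md_generate(model, 5, np.random.default_rng(0))
        assert d.text == "11|00|1"

    def test_unobserved_row_falls_back_home_with_warning(self):
        model = MarkovDiaryModel({(0, 1): {(2, 0): 1.0}}, n_period=4)
        with pytest.warns(UserWarning, match="no observed transitions"):
            d = md_generate(model, 6, np.random.default_rng(0))
        assert d.n_slots == 6

    def test_emitted_diaries_always_parse(self, fitted_model):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = md_generate(fitted_model, 168, rng)
            assert parse_diary(d.text) == d
            assert d.n_slots == 168


def sparse_reference_chain(n_period=24):
    """A hand-specified daily chain with night/day contrast and short breaks.

    Sparse in its transition structure (at most three destinations per
    state) while every state is visited often in a multi-week walk.
    """
    transitions = {}
    for h in range(n_period):
        night = h % 24 in set(range(7)) | {22, 23}
        cont = 0.9 if night else 0.7
        transitions[(h, 1)] = {
            ((h + 1) % n_period, 1): cont,
            ((h + 2) % n_period, 0): (1 - cont) * 0.7,
            ((h + 3) % n_period, 0): (1 - cont) * 0.3,
        }
        transitions[(h, 0)] = {
            ((h + 1) % n_period, 1): 0.6,
            ((h + 2) % n_period, 0): 0.4,
        }
    return MarkovDiaryModel(transitions, n_period=n_period)


class TestRecovery:
    def test_refit_recovers_generating_probabilities(self):
        true = sparse_reference_chain()
        rng = np.random.default_rng(123)
        corpus = []
        for _ in range(500):
            d = md_generate(true, 4 * 168, rng)
            traj = diary_to_abstract(d)
            corpus.append((traj, TypicalDiary(len(traj), "home")))
        refit = fit_markov(corpus, n_period=24)
        # compare on the true probabilities of every observed transition
        errs = []
        for s, row in refit.transitions.items():
            for s2, p_hat in row.items():
                errs.append(abs(p_hat - true.prob(s, s2)))
        assert max(errs) < 0.05

    def test_routine_occupancy_matches_closed_form(self):
        # period 2: slot 0 always routine; slot 1 routine w.p. 0.75
        # => expected fraction of '1' slots is (1 + 0.75)/2 = 0.875
        transitions = {
            (0, 1): {(1, 1): 0.75, (1, 0): 0.25},
            (1, 1): {(0, 1): 1.0},
            (1, 0): {(0, 1): 1.0},
        }
        model = MarkovDiaryModel(transitions, n_period=2)
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(100):
            d = md_generate(model, 200, rng)
            flags = d.routine_flags
            fracs.append(np.mean(flags))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.875) < 3 * se


class TestSerialization:
    def test_csv_round_trip(self, fitted_model, tmp_path):
        p = tmp_path / "model.csv"
        fitted_model.to_csv(p)
        back = MarkovDiaryModel.from_csv(p)
        assert back.n_period == fitted_model.n_period
        assert back.slot_seconds == fitted_model.slot_seconds
        assert set(back.transitions) == set(fitted_model.transitions)
        for s, row in fitted_model.transitions.items():
            for s2, prob in row.items():
                assert back.prob(s, s2) == pytest.approx(prob, abs=1e-12)

    def test_loader_rejects_broken_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# N_period=4\n# slot_seconds=3600\n"
            "h_from,R_from,h_to,R_to,prob\n0,1,1,1,0.6\n"
        )
        with pytest.raises(ValueError, match="sums to"):
            MarkovDiaryModel.from_csv(p)
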