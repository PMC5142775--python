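import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmaloo import (
    ABTruth,
    ArmRecord,
    DesignSpec,
    MCMCConfig,
    NMANetwork,
    best_treatment_change,
    bin_fold_changes,
    fold_change,
    logor_change,
    run_loo,
    sample_design,
    simulate_ab,
    summarize,
)
from nmaloo.ab_model import ABDerived, or_matrix_from_risks
from nmaloo.loo import LOOOptions, _one_exclusion


class TestFoldChange:
    def test_worked_examples(self):
        assert fold_change(0.70, 0.50) == pytest.approx(1.40)
        assert fold_change(0.40, 0.60) == pytest.approx(1.50)

    @given(st.floats(0.01, 0.99))
    @settings(max_examples=30, deadline=None)
    def test_identity_at_equal_rates(self, x):
        assert fold_change(x, x) == pytest.approx(1.0)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_at_least_one(self, a, b):
        f = fold_change(a, b)
        assert f >= 1.0
        assert f == pytest.approx(fold_change(b, a))

    def test_boundary_rates_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.5)
        with pytest.raises(ValueError):
            fold_change(0.5, 1.0)


class TestLogORChange:
    def test_no_change_is_zero(self):
        assert logor_change(2.0, 2.0) == 0.0

    def test_log_identity(self):
        assert logor_change(np.e * 1.7, 1.7) == pytest.approx(1.0)

    @given(st.floats(0.05, 20.0), st.floats(0.05, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_under_pair_reversal(self, a, b):
        # OR for the reversed pair is the reciprocal in both fits
        assert logor_change(1 / a, 1 / b) == pytest.approx(-logor_change(a, b))

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            logor_change(-1.0, 2.0)


class TestBinning:
    def test_three_values_three_bins(self):
        assert bin_fold_changes([1.05, 1.15, 1.25]).tolist() == pytest.approx(
            [1 / 3, 1 / 3, 1 / 3, 0, 0, 0]
        )

    def test_boundary_value_closed_first_bin(self):
        # 1.10 belongs to [1.00, 1.10], not (1.10, 1.20]
        assert bin_fold_changes([1.10]).tolist() == [1, 0, 0, 0, 0, 0]

    def test_matches_brute_force_oracle(self, rng):
        edges = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]
        vals = np.concatenate([
            1.0 + rng.exponential(0.2, 10_000), np.array(edges, dtype=float)
        ])
        props = bin_fold_changes(vals)
        brute = np.zeros(6)
        for v in vals:
            if v <= 1.1:
                brute[0] += 1
            elif v <= 1.2:
                brute[1] += 1
            elif v <= 1.3:
                brute[2] += 1
            elif v <= 1.4:
                brute[3] += 1
            elif v <= 1.5:
                brute[4] += 1
            else:
                brute[5] += 1
        assert np.allclose(props, brute / len(vals))
        assert props.sum() == pytest.approx(1.0)

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bin_fold_changes([])
        with pytest.raises(ValueError):
            bin_fold_changes([0.9])


def _derived(pi_point, pbest, treatments=("T1", "T2", "T3")):
    pi = np.tile(np.asarray(pi_point), (4, 1))
    return ABDerived(
        treatments=tuple(treatments),
        pi_samples=pi,
        pi_point=np.asarray(pi_point, dtype=float),
        or_samples=np.stack([or_matrix_from_risks(p) for p in pi]),
        or_point=or_matrix_from_risks(np.asarray(pi_point, dtype=float)),
        pbest=np.asarray(pbest, dtype=float),
        direction="beneficial",
    )


class TestBestTreatmentChange:
    def test_unchanged_ranking_returns_none(self):
        d = _derived([0.3, 0.5, 0.4], [0.1, 0.7, 0.2])
        assert best_treatment_change(d, d) is None

    def test_moved_mass_reports_new_best_with_its_pbest(self):
        full = _derived([0.3, 0.5, 0.4], [0.1, 0.7, 0.2])
        red = _derived([0.3, 0.4, 0.5], [0.1, 0.2, 0.7])
        change = best_treatment_change(full, red, "S9")
        assert change.new_best == "T3"
        assert change.new_pbest == pytest.approx(0.7)
        assert change.full_best == "T2"
        assert change.study_id == "S9"

    def test_tie_reports_lowest_index_and_flags(self):
        full = _derived([0.3, 0.5, 0.4], [0.0, 1.0, 0.0])
        red = _derived([0.3, 0.4, 0.5], [0.5, 0.0, 0.5])
        change = best_treatment_change(full, red)
        assert change.new_best == "T1"
        assert change.tie

    def test_treatment_set_mismatch_rejected(self):
        full = _derived([0.3, 0.5, 0.4], [0.1, 0.7, 0.2])
        red = _derived([0.3, 0.5, 0.4], [0.1, 0.7, 0.2], treatments=("A", "B", "C"))
        with pytest.raises(ValueError):
            best_treatment_change(full, red)


@pytest.fixture(scope="module")
def bridge_network() -> NMANetwork:
    """Removing the only bridging trial S5 disconnects {T1,T2} from {T3,T4}."""
    arms = (
        ArmRecord("S1", "T1", 10, 50), ArmRecord("S1", "T2", 12, 50),
        ArmRecord("S2", "T1", 11, 50), ArmRecord("S2", "T2", 14, 50),
        ArmRecord("S3", "T3", 13, 50), ArmRecord("S3", "T4", 9, 50),
        ArmRecord("S4", "T3", 15, 50), ArmRecord("S4", "T4", 8, 50),
        ArmRecord("S5", "T2", 10, 50), ArmRecord("S5", "T3", 12, 50),
    )
    return NMANetwork(("T1", "T2", "T3", "T4"), arms)


@pytest.fixture(scope="module")
def bridge_result(bridge_network):
    cfg = MCMCConfig(n_chains=2, n_adapt=150, n_burnin=100, n_iter=400, thin=1, seed=9)
    return run_loo(bridge_network, cfg)


class TestRunLOO:
    def test_disconnecting_exclusion_flagged_ineligible(self, bridge_result):
        rec = {r.excluded_study: r for r in bridge_result.records}
        assert not rec["S5"].eligible
        assert rec["S5"].reason == "disconnected"
        assert all(rec[s].eligible for s in ("S1", "S2", "S3", "S4"))

    def test_one_record_per_trial(self, bridge_result, bridge_network):
        assert len(bridge_result.records) == bridge_network.n_trials

    def test_change_matrices_antisymmetric(self, bridge_result):
        for r in bridge_result.eligible_records():
            assert np.allclose(r.ab_logor_changes, -r.ab_logor_changes.T, atol=1e-12)
            assert np.allclose(r.cb_logor_changes, -r.cb_logor_changes.T, atol=1e-12)
            assert np.all(r.fold_changes >= 1.0)

    def test_summary_bins_sum_to_one(self, bridge_result):
        summ = summarize(bridge_result)
        assert summ.bin_proportions.sum() == pytest.approx(1.0)
        assert summ.max_fold_change >= summ.mean_fold_change >= 1.0
        assert summ.n_cells == 4 * 4  # 4 eligible exclusions x K=4

    def test_reproducible_end_to_end(self, bridge_network, bridge_result):
        cfg = MCMCConfig(n_chains=2, n_adapt=150, n_burnin=100, n_iter=400, thin=1, seed=9)
        again = run_loo(bridge_network, cfg)
        for a, b in zip(bridge_result.records, again.records):
            assert a.eligible == b.eligible
            if a.eligible:
                assert np.array_equal(a.fold_changes, b.fold_changes)
                assert np.array_equal(a.ab_logor_changes, b.ab_logor_changes)
                assert np.array_equal(a.cb_logor_changes, b.cb_logor_changes)

    def test_treatment_removal_marks_record_ineligible(self, tiny_mcmc):
        # a frequency-1 treatment vanishes with its only trial; the engine
        # must stay safe even though such networks fail the inclusion rule
        arms = (
            ArmRecord("S1", "T1", 5, 20), ArmRecord("S1", "T2", 6, 20),
            ArmRecord("S2", "T1", 5, 20), ArmRecord("S2", "T2", 7, 20),
            ArmRecord("S3", "T2", 5, 20), ArmRecord("S3", "T3", 8, 20),
        )
        net = NMANetwork(("T1", "T2", "T3"), arms)
        dummy = _derived([0.3, 0.3, 0.3], [1 / 3, 1 / 3, 1 / 3])
        rec = _one_exclusion(net, "S3", tiny_mcmc, LOOOptions(), dummy,
                             dummy.or_point, dummy.or_point)
        assert not rec.eligible
        assert "T3" in rec.reason

    def test_inclusion_violating_network_rejected(self, toy_network, tiny_mcmc):
        with pytest.raises(ValueError, match="inclusion"):
            run_loo(toy_network, tiny_mcmc)
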