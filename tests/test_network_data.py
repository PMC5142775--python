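import numpy as np
import pytest

from nmaloo import (
    ArmRecord,
    NMANetwork,
    NetworkValidationError,
    geometry_summary,
    read_network,
    remove_trial,
    validate_inclusion,
    write_network,
)


def _write_csv(tmp_path, rows, header="study,treatment,events,n"):
    p = tmp_path / "net.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadNetwork:
    def test_parses_long_csv(self, tmp_path):
        p = _write_csv(tmp_path, [
            "A,T1,5,20", "A,T2,8,25", "B,T1,3,30", "B,T3,9,30",
        ])
        net = read_network(p)
        assert net.n_treatments == 3
        assert net.n_trials == 2
        assert net.treatments == ("T1", "T2", "T3")  # first-appearance order
        assert net.arms[0] == ArmRecord("A", "T1", 5, 20)

    def test_single_arm_study_names_offender(self, tmp_path):
        p = _write_csv(tmp_path, ["A,T1,5,20", "A,T2,8,25", "B,T1,3,30"])
        with pytest.raises(NetworkValidationError, match="'B'"):
            read_network(p)

    def test_events_exceeding_n_rejected(self, tmp_path):
        p = _write_csv(tmp_path, ["A,T1,25,20", "A,T2,8,25"])
        with pytest.raises(NetworkValidationError, match="0 <= y <= n"):
            read_network(p)

    def test_zero_event_arms_are_legal(self, tmp_path):
        p = _write_csv(tmp_path, [
            "A,T1,0,20", "A,T2,8,25", "B,T1,3,30", "B,T2,0,30",
        ])
        net = read_network(p)
        assert geometry_summary(net).n_zero_event_arms == 2

    def test_missing_columns_rejected(self, tmp_path):
        p = _write_csv(tmp_path, ["A,T1,5"], header="study,treatment,events")
        with pytest.raises(NetworkValidationError, match="header"):
            read_network(p)

    def test_sidecar_declares_order_and_direction(self, tmp_path):
        p = _write_csv(tmp_path, ["A,T1,5,20", "A,T2,8,25", "B,T2,3,30", "B,T1,9,30"])
        (tmp_path / "net.yaml").write_text(
            "outcome_direction: harmful\ntreatments: [T2, T1]\n"
        )
        net = read_network(p)
        assert net.outcome_direction == "harmful"
        assert net.treatments == ("T2", "T1")


def test_write_read_round_trip(tmp_path, toy_network):
    path = tmp_path / "toy.csv"
    write_network(toy_network, path)
    back = read_network(path)
    assert sorted(back.arms) == sorted(toy_network.arms)
    assert back.treatments == toy_network.treatments
    assert back.outcome_direction == toy_network.outcome_direction


class TestInvariants:
    def test_duplicate_arm_rejected(self):
        arms = (
            ArmRecord("A", "T1", 1, 10), ArmRecord("A", "T1", 2, 10),
        )
        with pytest.raises(NetworkValidationError, match="duplicate arm"):
            NMANetwork(("T1",), arms)

    def test_unknown_treatment_label_rejected(self):
        arms = (ArmRecord("A", "T1", 1, 10), ArmRecord("A", "TX", 2, 10))
        with pytest.raises(NetworkValidationError, match="'TX'"):
            NMANetwork(("T1",), arms)

    def test_nonpositive_sample_size_rejected(self):
        with pytest.raises(NetworkValidationError, match="sample_size"):
            ArmRecord("A", "T1", 0, 0)


class TestGeometry:
    def test_closed_loop_frequencies(self):
        arms = (
            ArmRecord("S1", "1", 1, 10), ArmRecord("S1", "2", 1, 10),
            ArmRecord("S2", "1", 1, 10), ArmRecord("S2", "3", 1, 10),
            ArmRecord("S3", "2", 1, 10), ArmRecord("S3", "3", 1, 10),
        )
        net = NMANetwork(("1", "2", "3"), arms)
        g = geometry_summary(net)
        assert g.treatment_frequency == {"1": 2, "2": 2, "3": 2}
        assert g.connected
        assert g.min_frequency == g.max_frequency == 2

    def test_two_components_detected(self):
        arms = (
            ArmRecord("S1", "1", 1, 10), ArmRecord("S1", "2", 1, 10),
            ArmRecord("S2", "3", 1, 10), ArmRecord("S2", "4", 1, 10),
        )
        net = NMANetwork(("1", "2", "3", "4"), arms)
        assert not geometry_summary(net).connected

    def test_connectivity_matches_transitive_closure_oracle(self, rng):
        """Co-occurrence connectivity agrees with a brute-force
        reachability oracle on random networks of up to 12 treatments."""
        for _ in range(30):
            K = int(rng.integers(3, 13))
            I = int(rng.integers(2, 15))
            sets = []
            for _ in range(I):
                m = int(rng.integers(2, min(K, 4) + 1))
                sets.append(rng.choice(K, size=m, replace=False))
            arms = tuple(
                ArmRecord(f"S{i}", str(k), 1, 10)
                for i, s in enumerate(sets) for k in s
            )
            labels = tuple(str(k) for k in range(K))
            net = NMANetwork(labels, arms)
            # Warshall-style closure over co-occurrence
            reach = np.eye(K, dtype=bool)
            for s in sets:
                for a in s:
                    for b in s:
                        reach[a, b] = True
            for _ in range(K):
                reach = reach | (reach @ reach)
            assert geometry_summary(net).connected == bool(reach.all())


class TestInclusionRule:
    def test_pass_when_all_frequencies_two(self, toy_network):
        # T4 appears once -> fails; the closed loop alone passes
        report = validate_inclusion(remove_trial(toy_network, "S4"))
        assert report.passed

    def test_low_frequency_treatment_listed(self, toy_network):
        report = validate_inclusion(toy_network)
        assert not report.passed
        assert report.low_frequency_treatments == ("T4",)

    def test_disconnected_network_fails_with_flag(self):
        arms = (
            ArmRecord("S1", "1", 1, 10), ArmRecord("S1", "2", 1, 10),
            ArmRecord("S2", "1", 1, 10), ArmRecord("S2", "2", 1, 10),
            ArmRecord("S3", "3", 1, 10), ArmRecord("S3", "4", 1, 10),
            ArmRecord("S4", "3", 1, 10), ArmRecord("S4", "4", 1, 10),
        )
        net = NMANetwork(("1", "2", "3", "4"), arms)
        report = validate_inclusion(net)
        assert not report.passed
        assert not report.connected
        assert report.low_frequency_treatments == ()


class TestRemoveTrial:
    def test_removes_study_and_prunes_treatments(self, tmp_path):
        arms = (
            ArmRecord("A", "T1", 1, 10), ArmRecord("A", "T2", 2, 10),
            ArmRecord("B", "T1", 3, 10), ArmRecord("B", "T3", 4, 10),
        )
        net = NMANetwork(("T1", "T2", "T3"), arms)
        reduced = remove_trial(net, "B")
        assert reduced.n_trials == 1
        assert reduced.treatments == ("T1", "T2")
        assert net.n_trials == 2  # original untouched

    def test_other_studies_bitwise_unchanged(self, toy_network):
        reduced = remove_trial(toy_network, "S2")
        remaining = [a for a in toy_network.arms if a.study_id != "S2"]
        assert list(reduced.arms) == remaining

    def test_remove_and_readd_restores_arm_multiset(self, toy_network):
        removed = toy_network.arms_of("S3")
        reduced = remove_trial(toy_network, "S3")
        restored = NMANetwork(
            toy_network.treatments, reduced.arms + removed,
            toy_network.outcome_direction, toy_network.name,
        )
        assert sorted(restored.arms) == sorted(toy_network.arms)

    def test_frequency_drops_but_treatment_persists(self, toy_network):
        # T3 appears in S2, S3, S4; removing S4 keeps T3 present
        reduced = remove_trial(toy_network, "S4")
        assert "T3" in reduced.treatments
        assert geometry_summary(reduced).treatment_frequency["T3"] == 2

    def test_unknown_study_errors(self, toy_network):
        with pytest.raises(KeyError):
            remove_trial(toy_network, "nope")
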