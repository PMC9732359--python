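import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degronscan.psi_screen import (
    CountTableError,
    DeltaPsiResult,
    GateCountTable,
    annotate_psi,
    call_degrons,
    compute_psi,
    delta_psi_analysis,
    drop_ambiguous,
    e3_overlap,
    filter_low_coverage,
    label_for_training,
    normalize_gates,
)


def make_table(count_rows, ids=None, strain="s"):
    count_rows = np.atleast_2d(count_rows)
    ids = ids or [f"p{i}" for i in range(len(count_rows))]
    df = pd.DataFrame(count_rows, columns=["G1", "G2", "G3", "G4"])
    df.insert(0, "peptide_id", ids)
    return GateCountTable(counts=df, strain=strain)


class TestNormalizeGates:
    def test_unequal_gate_depths(self):
        # depths (100, 200, 100, 100); first peptide (10, 20, 0, 0)
        table = make_table([[10, 20, 0, 0], [90, 180, 100, 100]])
        f = normalize_gates(table)
        np.testing.assert_allclose(f.iloc[0], [0.1, 0.1, 0.0, 0.0])

    def test_zero_depth_gate_gives_zero_frequency(self):
        table = make_table([[10, 0, 0, 30], [10, 0, 5, 5]])
        f = normalize_gates(table)
        assert (f["G2"] == 0).all()

    def test_all_gates_empty_error(self):
        table = make_table([[0, 0, 0, 0]])
        with pytest.raises(CountTableError, match="all gate totals"):
            normalize_gates(table)

    def test_absent_peptide_all_zero(self):
        table = make_table([[0, 0, 0, 0], [10, 10, 10, 10]])
        f = normalize_gates(table)
        assert (f.iloc[0] == 0).all()


class TestComputePsi:
    def test_boundary_and_symmetry_cases(self, toy_counts):
        psi = compute_psi(toy_counts).set_index("peptide_id")["psi"]
        assert psi["all_g1"] == 1.0
        assert psi["all_g4"] == 4.0
        assert psi["uniform"] == pytest.approx(2.5)
        assert psi["split"] == pytest.approx(3.25)  # 0.25*1 + 0.75*4

    def test_unscorable_peptides_dropped(self):
        table = make_table([[0, 0, 0, 0], [5, 5, 5, 5]])
        psi = compute_psi(table)
        assert list(psi["peptide_id"]) == ["p1"]

    def test_matches_weighted_mean_oracle(self, rng):
        counts = rng.integers(0, 500, size=(1000, 4))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = make_table(counts)
        psi = compute_psi(table)["psi"].to_numpy()
        depths = counts.sum(axis=0).astype(float)
        freqs = counts / depths
        oracle = (freqs * np.array([1, 2, 3, 4])).sum(axis=1) / freqs.sum(axis=1)
        np.testing.assert_allclose(psi, oracle, atol=1e-12, rtol=0)

    def test_depth_invariance(self, rng):
        """Multiplying one gate's counts by a constant leaves PSI unchanged."""
        counts = rng.integers(1, 100, size=(50, 4))
        scaled = counts.copy()
        scaled[:, 2] *= 7
        psi_a = compute_psi(make_table(counts))["psi"]
        psi_b = compute_psi(make_table(scaled))["psi"]
        np.testing.assert_allclose(psi_a, psi_b, atol=1e-12)

    @given(st.lists(st.lists(st.integers(0, 1000), min_size=4, max_size=4),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_psi_bounded(self, rows):
        rows = np.array(rows)
        if rows.sum() == 0:
            rows[0, 0] = 1
        psi = compute_psi(make_table(rows))["psi"]
        assert ((psi >= 1.0) & (psi <= 4.0)).all()

    def test_monotone_under_mass_shift(self):
        """Moving reads from a lower to a higher gate never decreases PSI."""
        base = make_table([[40, 30, 20, 10], [40, 30, 20, 10]],
                          ids=["a", "b"])
        shifted = make_table([[30, 30, 20, 20], [40, 30, 20, 10]],
                             ids=["a", "b"])
        psi0 = compute_psi(base).set_index("peptide_id")["psi"]
        psi1 = compute_psi(shifted).set_index("peptide_id")["psi"]
        assert psi1["a"] > psi0["a"]


class TestFilters:
    def test_read_filter_is_strict(self):
        table = make_table([[13, 13, 13, 12], [50, 0, 0, 0]], ids=["keep", "drop"])
        kept = filter_low_coverage(table, min_reads=50)
        assert list(kept.counts["peptide_id"]) == ["keep"]  # 51 > 50, 50 is out

    def test_zero_threshold_keeps_any_read(self):
        table = make_table([[1, 0, 0, 0], [0, 0, 0, 0]], ids=["one", "zero"])
        kept = filter_low_coverage(table, min_reads=0)
        assert list(kept.counts["peptide_id"]) == ["one"]

    def test_ambiguous_sequences_dropped(self):
        df = pd.DataFrame({
            "peptide_id": ["a", "b", "c"],
            "sequence": ["A" * 17, "A" * 17, "C" * 17],
            "G1": [1, 1, 1], "G2": [0, 0, 0], "G3": [0, 0, 0], "G4": [0, 0, 0],
        })
        out = drop_ambiguous(GateCountTable(counts=df))
        assert list(out.counts["peptide_id"]) == ["c"]

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({
            "peptide_id": ["a", "a"],
            "G1": [1, 1], "G2": [0, 0], "G3": [0, 0], "G4": [0, 0],
        })
        with pytest.raises(CountTableError, match="duplicate"):
            GateCountTable(counts=df)


class TestLabels:
    def test_training_labels(self):
        psi = pd.DataFrame({"peptide_id": ["u", "s", "mid"],
                            "psi": [1.39, 3.25, 2.5]})
        labeled = label_for_training(psi)
        assert dict(zip(labeled["peptide_id"], labeled["label"])) == {
            "u": "unstable", "s": "stable"}
        assert "mid" not in set(labeled["peptide_id"])

    def test_inverted_thresholds_error(self):
        psi = pd.DataFrame({"peptide_id": ["a"], "psi": [2.0]})
        with pytest.raises(ValueError, match="unstable_max"):
            label_for_training(psi, unstable_max=3.0, stable_min=2.0)

    def test_degron_call_strict_boundary(self):
        psi = pd.DataFrame({"peptide_id": ["deg", "edge"],
                            "psi": [1.44, 1.7]})
        ids, frac = call_degrons(psi, cutoff=1.7)
        assert ids == {"deg"}
        assert frac == pytest.approx(0.5)
        ids_incl, _ = call_degrons(psi, cutoff=1.7, inclusive=True)
        assert ids_incl == {"deg", "edge"}

    def test_uniform_psi_degron_fraction(self, rng):
        """PSI ~ U(1,4) gives a degron fraction of 0.7/3 at cutoff 1.7."""
        psi = pd.DataFrame({"peptide_id": np.arange(200_000),
                            "psi": rng.uniform(1, 4, size=200_000)})
        _, frac = call_degrons(psi, cutoff=1.7)
        assert frac == pytest.approx(0.7 / 3, abs=0.005)

    def test_annotate_consistency(self):
        psi = pd.DataFrame({"peptide_id": list("abcd"),
                            "psi": [1.2, 1.69, 2.5, 3.1]})
        ann = annotate_psi(psi)
        assert ann["is_degron"].tolist() == [True, True, False, False]
        assert ann["label"].tolist() == ["unstable", "unstable",
                                         "intermediate", "stable"]


def psi_frame(ids, values):
    return pd.DataFrame({"peptide_id": ids, "psi": values})


class TestDeltaPsi:
    def test_control_vs_control_null(self):
        ctrl = psi_frame([f"p{i}" for i in range(10)],
                         np.linspace(1.0, 1.6, 10))
        res = delta_psi_analysis(ctrl, {"ko": ctrl.copy()})["ko"]
        assert (res.table["delta_psi"] == 0).all()
        assert res.stabilized == set()

    def test_threshold_arithmetic_on_hand_vector(self):
        """Threshold equals mean + 2*sd/sqrt(n) on a 5-value vector."""
        deltas = np.array([0.1, -0.2, 0.3, 0.0, 0.05])
        ctrl = psi_frame([f"p{i}" for i in range(5)], [1.5] * 5)
        ko = psi_frame([f"p{i}" for i in range(5)], 1.5 + deltas)
        res = delta_psi_analysis(ctrl, {"ko": ko})["ko"]
        expected = deltas.mean() + 2 * deltas.std(ddof=1) / np.sqrt(5)
        assert res.threshold == pytest.approx(expected, abs=1e-12)
        assert res.stabilized == {
            f"p{i}" for i in range(5) if deltas[i] > expected}

    def test_spiked_stabilization_recovered(self, rng):
        n_null, n_spiked = 2000, 100
        ids = [f"p{i}" for i in range(n_null + n_spiked)]
        ctrl = psi_frame(ids, np.full(len(ids), 1.5))
        deltas = np.concatenate([rng.normal(0, 0.1, n_null),
                                 np.full(n_spiked, 1.0)])
        ko = psi_frame(ids, 1.5 + deltas)
        res = delta_psi_analysis(ctrl, {"ko": ko})["ko"]
        spiked_ids = set(ids[n_null:])
        recovered = len(spiked_ids & res.stabilized) / n_spiked
        assert recovered >= 0.95

    def test_restricted_to_control_degrons(self):
        ctrl = psi_frame(["deg", "stable"], [1.5, 3.0])
        ko = psi_frame(["deg", "stable", "x", "y", "z"],
                       [2.5, 3.0, 1, 1, 1])
        with pytest.raises(ValueError, match="shared"):
            delta_psi_analysis(ctrl, {"ko": ko})

    def test_sd_rule_option(self):
        deltas = np.array([0.1, -0.2, 0.3, 0.0, 0.05])
        ctrl = psi_frame([f"p{i}" for i in range(5)], [1.5] * 5)
        ko = psi_frame([f"p{i}" for i in range(5)], 1.5 + deltas)
        res = delta_psi_analysis(ctrl, {"ko": ko}, se_rule="sd")["ko"]
        assert res.threshold == pytest.approx(
            deltas.mean() + 2 * deltas.std(ddof=1), abs=1e-12)


def result_from_ranking(strain, ids, deltas):
    tab = pd.DataFrame({
        "peptide_id": ids,
        "psi_control": 1.5,
        "psi_ko": 1.5 + np.asarray(deltas),
        "delta_psi": deltas,
    })
    return DeltaPsiResult(strain=strain, table=tab, threshold=np.inf)


class TestE3Overlap:
    def test_identical_rankings_fully_overlap(self):
        ids = [f"p{i}" for i in range(100)]
        deltas = np.linspace(0, 1, 100)
        results = {s: result_from_ranking(s, ids, deltas) for s in "AB"}
        out = e3_overlap(results, top_fraction=0.10)
        assert out["regions"]["A&B"] == 10
        assert out["fraction_multi_e3"] == 1.0

    def test_disjoint_rankings(self):
        ids = [f"p{i}" for i in range(100)]
        up = np.linspace(0, 1, 100)
        results = {
            "A": result_from_ranking("A", ids, up),
            "B": result_from_ranking("B", ids, up[::-1]),
        }
        out = e3_overlap(results, top_fraction=0.10)
        assert out["regions"]["A&B"] == 0
        assert out["fraction_multi_e3"] == 0.0

    def test_random_rankings_match_hypergeometric_expectation(self, rng):
        """Mean pairwise overlap of random top-218 sets out of 2175 ids
        is 218^2/2175 (~21.8)."""
        n, k, n_seeds = 2175, 218, 60
        ids = np.array([f"p{i}" for i in range(n)])
        overlaps = []
        for _ in range(n_seeds):
            tops = [set(ids[rng.permutation(n)[:k]]) for _ in range(2)]
            overlaps.append(len(tops[0] & tops[1]))
        expected = k * k / n
        # binomial-ish sd per draw ~ 4.4; allow 4 standard errors
        assert np.mean(overlaps) == pytest.approx(
            expected, abs=4 * 4.5 / np.sqrt(n_seeds))

    def test_top_set_size_uses_ceiling(self):
        ids = [f"p{i}" for i in range(25)]
        results = {s: result_from_ranking(s, ids, np.arange(25.0))
                   for s in "AB"}
        out = e3_overlap(results, top_fraction=0.10)
        assert out["top_set_sizes"] == {"A": 3, "B": 3}  # ceil(2.5)
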