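import numpy as np
import pytest

from wormmem.components import (
    DELTA_COMPONENTS,
    DeltaMatrix,
    arrow_map,
    build_delta_matrix,
    kmeans_threshold,
    pca_filter,
)
from oracles import oracle_kmeans_2part
from wormmem.regression import TrialAveragedActivity

CONDS = ("STAP-T", "STAP-M", "STAV-T", "STAV-M", "NAIVE")


def _conditions(rng, neurons, T=10, noise=0.1, bumps=None):
    """Trial-averaged inputs; ``bumps[(cond, neuron)]`` adds a constant."""
    bumps = bumps or {}
    base = {n: rng.normal(size=(6, T)) for n in neurons}
    out = {}
    for g in CONDS:
        out[g] = {
            n: TrialAveragedActivity(
                n, g,
                base[n] + bumps.get((g, n), 0.0)
                + rng.normal(scale=noise, size=(6, T)),
            )
            for n in neurons
        }
    return out


class TestBuildDeltaMatrix:
    def test_full_design_has_36_rows(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0", "n1"]))
        assert dm.data.shape == (36, 20)
        comps = [c for c, _ in dm.row_labels]
        assert set(comps) == set(DELTA_COMPONENTS)
        assert all(comps.count(c) == 6 for c in DELTA_COMPONENTS)

    def test_identical_groups_give_zero_matrix(self, rng):
        neurons = ["n0"]
        base = {n: rng.normal(size=(6, 8)) for n in neurons}
        conds = {g: {n: TrialAveragedActivity(n, g, base[n]) for n in neurons}
                 for g in CONDS}
        dm = build_delta_matrix(conds)
        np.testing.assert_allclose(dm.data, 0.0, atol=1e-12)

    def test_planted_effect_appears_only_in_its_rows(self, rng):
        # +delta on STAP-T for n0 -> CS(AP) and VAL(T) rows carry it
        delta = 0.7
        conds = _conditions(rng, ["n0", "n1"], noise=0.0,
                            bumps={("STAP-T", "n0"): delta})
        dm = build_delta_matrix(conds)
        sl = dm.neuron_slice("n0")
        for (comp, _trial), row in zip(dm.row_labels, dm.data):
            expected = delta if comp in ("CS(AP)", "VAL(T)") else 0.0
            assert row[sl].mean() == pytest.approx(expected, abs=1e-10)
            assert row[dm.neuron_slice("n1")].mean() == pytest.approx(0.0, abs=1e-10)

    def test_missing_condition_named(self, rng):
        conds = _conditions(rng, ["n0"])
        del conds["NAIVE"]
        with pytest.raises(ValueError, match="NAIVE"):
            build_delta_matrix(conds)


class TestPcaFilter:
    def test_keeping_all_components_reproduces_input(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0", "n1", "n2"], T=12))
        _, report = pca_filter(dm, keep=(1,))
        n_comp = report["n_components"]
        recon, _ = pca_filter(dm, keep=range(1, n_comp + 1))
        np.testing.assert_allclose(recon.data, dm.data, atol=1e-9)

    def test_planted_two_dim_subspace_exact(self, rng):
        # rows constructed from exactly two basis vectors
        b1, b2 = rng.normal(size=(2, 40))
        coeff = rng.normal(size=(36, 2))
        data = coeff @ np.stack([b1, b2])
        dm = DeltaMatrix(data=data, row_labels=[(c, t) for c in DELTA_COMPONENTS
                                                for t in range(6)],
                         neurons=["n0", "n1"], n_time=20)
        recon, report = pca_filter(dm, keep=(1, 2))
        np.testing.assert_allclose(recon.data, dm.data, atol=1e-9)
        assert report["filtered_fraction"] == pytest.approx(0.0, abs=1e-9)

    def test_variance_fractions_sum_to_one(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0", "n1"]))
        _, report = pca_filter(dm, keep=(1, 2, 3, 5))
        assert report["retained_fraction"] + report["filtered_fraction"] == 1.0
        assert sum(report["eigenvalue_fractions"]) == pytest.approx(1.0)

    def test_frobenius_error_equals_discarded_eigenvalues(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0", "n1"]))
        recon, report = pca_filter(dm, keep=(1, 2, 3))
        X = dm.data - dm.data.mean(axis=0)
        eig = np.linalg.svd(X, compute_uv=False) ** 2
        err = np.sum((recon.data - dm.data) ** 2)
        assert err == pytest.approx(np.sum(eig[3:]), rel=1e-9)

    def test_at_most_35_components_for_36_rows(self, rng):
        # 36 mean-centered rows can span at most 35 dimensions
        data = rng.normal(size=(36, 50))
        dm = DeltaMatrix(data=data, row_labels=[(c, t) for c in DELTA_COMPONENTS
                                                for t in range(6)],
                         neurons=["n0"], n_time=50)
        _, report = pca_filter(dm, keep=(1,))
        assert report["n_components"] <= 35

    def test_out_of_range_component_rejected(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0"]))
        with pytest.raises(ValueError, match="exceeds"):
            pca_filter(dm, keep=(100,))

    def test_default_keep_is_1_2_3_5(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0", "n1", "n2"]))
        _, report = pca_filter(dm)
        assert report["kept"] == [1, 2, 3, 5]


class TestArrowMap:
    def test_zero_deltas_zero_arrows(self):
        data = np.zeros((36, 10))
        dm = DeltaMatrix(data=data, row_labels=[(c, t) for c in DELTA_COMPONENTS
                                                for t in range(6)],
                         neurons=["n0"], n_time=10)
        am = arrow_map(dm, {"n0": 1.0})
        assert (am["mean"] == 0).all() and (am["sd"] == 0).all()

    def test_planted_arrow_arithmetic(self, rng):
        # +delta per time point on one neuron-component; amplitude A
        delta, A, T = 0.3, 2.0, 10
        conds = _conditions(rng, ["n0", "n1"], T=T, noise=0.0,
                            bumps={("STAP-M", "n0"): delta})
        dm = build_delta_matrix(conds)  # US+ and VAL(M) rows get +delta, CS(AP) -delta
        am = arrow_map(dm, {"n0": A, "n1": A})
        lookup = am.set_index(["neuron", "component"])["mean"]
        assert lookup[("n0", "US+")] == pytest.approx(delta * T / A, abs=1e-9)
        assert lookup[("n0", "CS(AP)")] == pytest.approx(-delta * T / A, abs=1e-9)
        assert lookup[("n1", "US+")] == pytest.approx(0.0, abs=1e-9)

    def test_sd_over_exactly_six_trials(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0"]))
        am = arrow_map(dm, {"n0": 1.0})
        assert (am["n_trials"] == 6).all()

    def test_weighting_switch(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0"]))
        div = arrow_map(dm, {"n0": 2.0}, weighting="divide")
        mul = arrow_map(dm, {"n0": 2.0}, weighting="multiply")
        np.testing.assert_allclose(mul["mean"], 4.0 * div["mean"])

    def test_zero_amplitude_neuron_excluded(self, rng):
        dm = build_delta_matrix(_conditions(rng, ["n0", "n1"]))
        am = arrow_map(dm, {"n0": 1.0, "n1": 0.0})
        assert set(am["neuron"]) == {"n0"}


class TestKmeansThreshold:
    def test_hand_case(self):
        labels, boundary = kmeans_threshold(np.array([0, 0.01, 0.02, 1.0, 1.1]))
        assert labels.tolist() == [False, False, False, True, True]

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 11))
            vals = rng.normal(size=n)
            labels, _ = kmeans_threshold(vals)
            ss_o, labels_o = oracle_kmeans_2part(vals)
            assert labels.tolist() == labels_o

    def test_all_equal_none_significant(self):
        labels, _ = kmeans_threshold(np.full(6, 0.3))
        assert not labels.any()

    def test_scale_equivariant(self, rng):
        vals = rng.normal(size=12)
        a, _ = kmeans_threshold(vals)
        b, _ = kmeans_threshold(vals * 17.3)
        assert a.tolist() == b.tolist()
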