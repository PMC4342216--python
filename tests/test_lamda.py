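import numpy as np
import pytest

from fuzzygrade import (
    FMG1,
    FMG3,
    LamdaModel,
    aggregate_gad,
    classify,
    compute_mads,
    score_from_gads,
)
from fuzzygrade.fuzzify import MembershipParams, StandardizationBounds
from fuzzygrade.lamda import load_model, save_model


def make_model(rho1, rho3, alpha=0.7, connective="minmax", family="binomial",
               spread=0.1, nic=False, max_missing_fraction=0.2):
    rho1 = np.atleast_1d(np.asarray(rho1, dtype=float))
    rho3 = np.atleast_1d(np.asarray(rho3, dtype=float))
    p = rho1.size
    probe_ids = np.array([f"p{i}" for i in range(p)])
    params = MembershipParams(
        family=family,
        class_labels=(FMG1, FMG3),
        center=np.vstack([rho1, rho3]),
        spread=np.full((2, p), spread) if family == "gaussian" else None,
        probe_ids=probe_ids,
    )
    bounds = StandardizationBounds(
        x_min=np.zeros(p), x_max=np.ones(p), probe_ids=probe_ids
    )
    return LamdaModel(
        params=params, bounds=bounds, probe_ids=probe_ids, alpha=alpha,
        connective=connective, nic=nic, max_missing_fraction=max_missing_fraction,
    )


class TestAggregateGad:
    @pytest.mark.parametrize(
        "alpha, expected", [(1.0, 0.6), (0.0, 0.8), (0.5, 0.7)]
    )
    def test_minmax_interpolation(self, alpha, expected):
        assert aggregate_gad(np.array([0.8, 0.6]), alpha) == pytest.approx(expected)

    def test_prodsum_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            mads = rng.random(rng.integers(1, 20))
            alpha = rng.random()
            got = aggregate_gad(mads, alpha, "prodsum")
            want = alpha * np.prod(mads) + (1 - alpha) * (1 - np.prod(1 - mads))
            assert got == pytest.approx(want, abs=1e-12)

    def test_gad_between_min_and_max_for_minmax(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            mads = rng.random(rng.integers(1, 30))
            alpha = rng.random()
            gad = aggregate_gad(mads, alpha)
            assert mads.min() - 1e-12 <= gad <= mads.max() + 1e-12

    def test_missing_mads_excluded(self):
        assert aggregate_gad(np.array([0.8, np.nan, 0.6]), 1.0) == pytest.approx(0.6)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gad(np.array([]), 0.5)
        with pytest.raises(ValueError):
            aggregate_gad(np.array([np.nan]), 0.5)


class TestComputeMads:
    def test_half_prototypes_give_half_mads(self):
        model = make_model([0.5, 0.5], [0.5, 0.5])
        mads = compute_mads(np.array([0.2, 0.9]), model, FMG1)
        assert np.allclose(mads, 0.5, atol=1e-6)

    def test_gaussian_prototype_match_gives_unit_mads(self):
        model = make_model([0.2, 0.3], [0.8, 0.7], family="gaussian")
        mads = compute_mads(np.array([0.8, 0.7]), model, FMG3)
        assert np.allclose(mads, 1.0)

    def test_single_probe_delegates_to_binomial(self):
        from fuzzygrade.fuzzify import membership_binomial

        model = make_model([0.3], [0.8])
        mads = compute_mads(np.array([0.6]), model, FMG3)
        assert mads[0] == pytest.approx(float(membership_binomial(0.6, 0.8)))


class TestClassify:
    def test_normalized_memberships_point_eight_point_two(self):
        # one probe, alpha irrelevant: GADs are the memberships themselves
        model = make_model([0.9], [0.1], alpha=1.0)
        call = classify(np.array([0.9]), model, standardized=True)
        assert call.score == pytest.approx(
            call.gad3 / (call.gad1 + call.gad3)
        )
        # crafted so the two displayed memberships are 0.8 / 0.2
        assert score_from_gads(0.8, 0.2) == pytest.approx(0.2)
        assert score_from_gads(0.8, 0.2) < 0.5  # fMG1 side

    @pytest.mark.parametrize(
        "gad1, gad3, label, equivocal",
        [
            (0.5, 0.5, FMG3, True),  # s = 0.5 exactly: boundary inclusive
            (0.51, 0.49, FMG1, True),  # s = 0.49
            (0.4, 0.4, FMG3, True),  # equal GADs
            (0.2, 0.8, FMG3, False),
            (0.8, 0.2, FMG1, False),
        ],
    )
    def test_score_label_equivocal_rules(self, gad1, gad3, label, equivocal):
        s = score_from_gads(gad1, gad3)
        assert (s >= 0.5) == (label == FMG3)
        assert (0.48 <= s <= 0.52) == equivocal

    def test_zero_gads_fall_back_to_indeterminate(self, caplog):
        with caplog.at_level("WARNING"):
            assert score_from_gads(0.0, 0.0) == 0.5

    def test_class_swap_complements_score(self):
        rng = np.random.default_rng(10)
        rho1, rho3 = rng.random(6), rng.random(6)
        model = make_model(rho1, rho3, alpha=0.8)
        swapped = make_model(rho3, rho1, alpha=0.8)
        x = rng.random(6)
        s = classify(x, model, standardized=True).score
        s_swapped = classify(x, swapped, standardized=True).score
        assert s_swapped == pytest.approx(1.0 - s)

    def test_score_monotone_when_grade3_prototype_higher(self):
        # product t-norm at full exigency: raising any coordinate moves the
        # score toward fMG3 whenever rho3 > rho1 on every probe
        model = make_model([0.2, 0.3], [0.8, 0.9], alpha=1.0, connective="prodsum")
        grid = np.linspace(0, 1, 21)
        prev = -1.0
        for x0 in grid:
            s = classify(np.array([x0, 0.5]), model, standardized=True).score
            assert s >= prev - 1e-12
            prev = s

    def test_missing_probes_renormalized_and_refused_beyond_limit(self):
        model = make_model([0.2] * 5, [0.8] * 5)
        x = np.array([0.9, 0.9, 0.9, 0.9, np.nan])
        call = classify(x, model, standardized=True)
        assert call.n_probes_used == 4
        assert call.label == FMG3
        x2 = np.array([0.9, 0.9, np.nan, np.nan, np.nan])
        with pytest.raises(ValueError, match="refusing"):
            classify(x2, model, standardized=True)

    def test_classification_is_deterministic(self):
        model = make_model([0.1, 0.2, 0.3], [0.9, 0.8, 0.7])
        x = np.array([0.6, 0.7, 0.4])
        calls = [classify(x, model, standardized=True) for _ in range(3)]
        assert len({c.score for c in calls}) == 1

    def test_nic_marks_low_confidence(self):
        model = make_model([0.05], [0.95], alpha=1.0, nic=True)
        # a mid sample fits neither extreme prototype as well as the
        # non-informative class fits anything
        call = classify(np.array([0.5]), model, standardized=True)
        assert call.low_confidence
        call2 = classify(np.array([0.95]), model, standardized=True)
        assert not call2.low_confidence


def test_model_json_round_trip(tmp_path):
    model = make_model([0.2, 0.4], [0.8, 0.6], alpha=0.9, family="gaussian")
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.alpha == model.alpha
    assert loaded.connective == model.connective
    assert np.allclose(loaded.params.center, model.params.center)
    assert np.allclose(loaded.params.spread, model.params.spread)
    assert np.array_equal(loaded.probe_ids, model.probe_ids)
    x = np.array([0.3, 0.7])
    assert classify(x, loaded, standardized=True).score == pytest.approx(
        classify(x, model, standardized=True).score
    )
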