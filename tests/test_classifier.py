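"""CPT estimation, posterior computation, deterministic calls, ROC, serialization."""

import itertools

import numpy as np
import pytest

import peakbn as pb
from peakbn.classifier import ClassifierParams, fit_parameters, posterior
from peakbn.network import CLASS_NODE


def _params(cpts, prior=(0.5, 0.5), boundaries=None, threshold=0.5):
    boundaries = boundaries or {f: (0.0, 1.0) for f in cpts}
    return ClassifierParams(
        class_labels=["neg", "pos"],
        class_prior=np.asarray(prior, float),
        cpts={f: np.asarray(t, float) for f, t in cpts.items()},
        boundaries=boundaries,
        decision_threshold=threshold,
        positive_class="pos",
    )


def _uniform_cpt():
    return np.full((3, 2), 1 / 3)


# --- fit_parameters ----------------------------------------------------------

def _six_case_fixture():
    """Hand-computable worked example: 6 cases, 1 feature, 3 bins."""
    net = pb.BayesNet()
    net.add_arc(CLASS_NODE, "f", "first-level")
    bins = np.array([[0], [0], [1], [2], [2], [2]])
    y = np.array([0, 0, 0, 1, 1, 1])
    return net, bins, y


def test_cpts_match_hand_computed_counts():
    net, bins, y = _six_case_fixture()
    params = fit_parameters(
        net, bins, ["f"], y, ["a", "b"], np.array([[0.0, 1.0]]), pseudocount=1.0
    )
    # class a: bins 0,0,1 -> counts (2,1,0)+1 = (3,2,1)/6
    # class b: bins 2,2,2 -> counts (0,0,3)+1 = (1,1,4)/6
    np.testing.assert_allclose(params.cpts["f"][:, 0], [3 / 6, 2 / 6, 1 / 6])
    np.testing.assert_allclose(params.cpts["f"][:, 1], [1 / 6, 1 / 6, 4 / 6])
    np.testing.assert_allclose(params.class_prior, [0.5, 0.5])


def test_unobserved_bin_gets_laplace_mass():
    net, bins, y = _six_case_fixture()
    params = fit_parameters(
        net, bins, ["f"], y, ["a", "b"], np.array([[0.0, 1.0]]), pseudocount=1.0
    )
    # bin 2 never observed in class a: entry = (0+1)/(3+3)
    assert params.cpts["f"][2, 0] == pytest.approx(1 / (3 + 3))
    assert (params.cpts["f"] > 0).all()


def test_fit_parameters_errors():
    net = pb.BayesNet()  # no first-level feature
    with pytest.raises(ValueError, match="first-level"):
        fit_parameters(net, np.zeros((2, 1), int), ["f"], np.array([0, 1]),
                       ["a", "b"], np.array([[0.0, 1.0]]))


# --- posterior ---------------------------------------------------------------

def test_uninformative_cpts_return_prior():
    params = _params({"f": _uniform_cpt()}, prior=(0.3, 0.7))
    post = posterior(params, {"f": 2})
    np.testing.assert_allclose(post, [0.3, 0.7], atol=1e-12)


def test_single_feature_bayes_arithmetic():
    cpt = np.array([[0.6, 0.05], [0.3, 0.05], [0.1, 0.9]])  # P(bin|class)
    params = _params({"f": cpt})
    post = posterior(params, {"f": 2})
    # equal priors: P(pos|high) = 0.9 / (0.9 + 0.1)
    assert post[1] == pytest.approx(0.9)


def test_posterior_matches_joint_enumeration():
    # brute-force oracle: full joint table over all 3^7 bin patterns
    rng = np.random.default_rng(8)
    feats = [f"f{i}" for i in range(7)]
    cpts = {}
    for f in feats:
        t = rng.random((3, 2)) + 0.05
        cpts[f] = t / t.sum(axis=0)
    prior = np.array([0.4, 0.6])
    params = _params(cpts, prior=prior)
    joint = {}
    for pattern in itertools.product((0, 1, 2), repeat=7):
        p = prior.copy()
        for f, b in zip(feats, pattern):
            p = p * cpts[f][b]
        joint[pattern] = p
    for pattern in [(0,) * 7, (2, 1, 0, 2, 1, 0, 2), (1,) * 7]:
        expected = joint[pattern] / joint[pattern].sum()
        got = posterior(params, dict(zip(feats, pattern)))
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_posterior_sums_to_one_and_no_underflow_with_many_features():
    rng = np.random.default_rng(0)
    cpts = {}
    for i in range(2000):
        t = rng.random((3, 2)) + 0.01
        cpts[f"f{i}"] = t / t.sum(axis=0)
    params = _params(cpts)
    post = posterior(params, {f: int(i % 3) for i, f in enumerate(cpts)})
    assert np.isfinite(post).all()
    assert post.sum() == pytest.approx(1.0, abs=1e-12)


def test_adding_uninformative_feature_keeps_posterior():
    cpt = np.array([[0.7, 0.2], [0.2, 0.2], [0.1, 0.6]])
    p1 = _params({"f": cpt})
    p2 = _params({"f": cpt, "g": _uniform_cpt()})
    for b in (0, 1, 2):
        a = posterior(p1, {"f": b})
        bpost = posterior(p2, {"f": b, "g": 1})
        np.testing.assert_allclose(a, bpost, atol=1e-9)


def test_invalid_bin_value_rejected():
    params = _params({"f": _uniform_cpt()})
    with pytest.raises(ValueError, match="bin value"):
        posterior(params, {"f": 3})


# --- classify ----------------------------------------------------------------

def _table(values, labels=None):
    values = np.asarray(values, float).reshape(-1, 1)
    return pb.SampleTable(
        case_ids=[f"c{i}" for i in range(len(values))],
        class_labels=labels,
        feature_ids=[10.0],
        abundances=values,
    )


def test_posterior_exactly_at_threshold_is_negative_call():
    params = _params({10.0: _uniform_cpt()}, boundaries={10.0: (0.0, 1.0)})
    # uninformative: posterior is exactly (0.5, 0.5) for every case
    table = _table([0.5, 2.0], labels=["pos", "neg"])
    out = pb.classify(params, table)
    assert list(out["calls"]) == ["neg", "neg"]


def test_out_of_range_values_bin_as_extremes():
    cpt = np.array([[0.8, 0.1], [0.1, 0.1], [0.1, 0.8]])
    params = _params({10.0: cpt}, boundaries={10.0: (1.0, 2.0)})
    table = _table([-50.0, 50.0], labels=["neg", "pos"])
    out = pb.classify(params, table)
    assert list(out["calls"]) == ["neg", "pos"]
    assert out["error_rate"] == 0.0


def test_roc_perfect_separation_passes_through_corner():
    cpt = np.array([[0.98, 0.01], [0.01, 0.01], [0.01, 0.98]])
    params = _params({10.0: cpt}, boundaries={10.0: (0.4, 0.6)})
    labels = ["neg"] * 10 + ["pos"] * 10
    table = _table([0.0] * 10 + [1.0] * 10, labels=labels)
    out = pb.classify(params, table)
    fpr, tpr = out["roc"]["fpr"], out["roc"]["tpr"]
    assert any((f == 0.0 and t == 1.0) for f, t in zip(fpr, tpr))


def test_roc_is_monotone(default_dataset):
    table, _ = default_dataset
    clf = pb.BayesNetClassifier(
        n_permutations=20, feature_ids=list(table.feature_ids), random_state=0
    )
    clf.fit(table.abundances, table.class_labels)
    out = pb.classify(clf.params_, table)
    assert (np.diff(out["roc"]["tpr"]) >= 0).all()
    assert (np.diff(out["roc"]["fpr"]) >= 0).all()
    # refit-free application to its own training data: error no worse than
    # typical cross-validated estimates for this generator
    assert out["error_rate"] <= 0.15


def test_missing_feature_is_hard_error():
    params = _params({99.0: _uniform_cpt()}, boundaries={99.0: (0.0, 1.0)})
    with pytest.raises(ValueError, match="99"):
        pb.classify(params, _table([1.0, 2.0], labels=["pos", "neg"]))


def test_unlabeled_table_gets_calls_only():
    params = _params({10.0: _uniform_cpt()}, boundaries={10.0: (0.0, 1.0)})
    out = pb.classify(params, _table([0.5, 2.0]))
    assert "error_rate" not in out and "roc" not in out
    assert len(out["calls"]) == 2


# --- serialization -----------------------------------------------------------

def test_params_json_roundtrip(tmp_path):
    cpt = np.array([[0.5, 0.2], [0.3, 0.2], [0.2, 0.6]])
    params = _params({10.0: cpt}, prior=(0.45, 0.55))
    p = tmp_path / "clf.json"
    params.to_json(p)
    back = ClassifierParams.from_json(p)
    np.testing.assert_allclose(back.class_prior, params.class_prior)
    np.testing.assert_allclose(back.cpts[10.0], cpt)
    assert back.boundaries[10.0] == (0.0, 1.0)
    assert back.decision_threshold == 0.5
    assert back.positive_class == "pos"


def test_cpt_validation():
    bad = np.array([[0.5, 0.2], [0.3, 0.2], [0.3, 0.6]])  # col 0 sums to 1.1
    with pytest.raises(ValueError, match="sum to 1"):
        _params({"f": bad})


# --- estimator surface -------------------------------------------------------

def test_estimator_sklearn_contract(small_table):
    from sklearn.base import clone

    clf = pb.BayesNetClassifier(n_permutations=5, random_state=0)
    clone(clf)  # get_params/set_params round trip
    clf.fit(small_table.abundances, small_table.class_labels)
    assert set(clf.classes_) == {"a", "b"}
    proba = clf.predict_proba(small_table.abundances)
    assert proba.shape == (small_table.n_cases, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    acc = clf.score(small_table.abundances, small_table.class_labels)
    assert acc > 0.9  # feature separated by 3 SD
    assert clf.network_.first_level == [0]
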