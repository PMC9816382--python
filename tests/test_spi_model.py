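import numpy as np
import pytest

from golfspi import (
    LabeledDataset,
    SPIModel,
    fit_log_distance_scaling,
    fit_pca_on_pros,
    fit_spi_model,
    kmo,
    load_model,
    normalize,
    save_model,
    smote_balance,
    spi_score,
    worked_example_fixture,
)
from golfspi.spi_model import SPIModelError, pc_transform, pro_stats


def _dataset(X_pro, X_am, names=("a", "b", "c")):
    X = np.vstack([X_pro, X_am])
    n_p, n_a = len(X_pro), len(X_am)
    return LabeledDataset(
        X=X[:, : len(names)],
        groups=np.array(["pro"] * n_p + ["amateur"] * n_a),
        subject_ids=np.array([f"s{i}" for i in range(n_p + n_a)]),
        swing_ids=np.array([f"w{i}" for i in range(n_p + n_a)]),
        synthetic=np.zeros(n_p + n_a, dtype=bool),
        metric_names=tuple(names),
    )


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def test_normalize_pro_rows_have_zero_mean_unit_sd():
    rng = np.random.default_rng(5)
    X = rng.normal(50, 12, size=(30, 4))
    mean, sd = pro_stats(X, np.ones(30, dtype=bool), list("abcd"))
    z = normalize(X, mean, sd)
    assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)  # population convention
    # an amateur exactly at the pro mean maps to the zero vector
    assert np.allclose(normalize(mean[None, :], mean, sd), 0.0)
    # direct formula oracle
    assert np.allclose(z, (X - X.mean(0)) / X.std(0))


def test_normalize_zero_variance_names_the_metric():
    X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    with pytest.raises(SPIModelError, match="b"):
        pro_stats(X, np.ones(5, dtype=bool), ["a", "b"])


# ---------------------------------------------------------------------------
# KMO
# ---------------------------------------------------------------------------

def _kmo_bruteforce(X):
    """Straight transcription of the anti-image formula."""
    R = np.corrcoef(X, rowvar=False)
    Rinv = np.linalg.inv(R)
    p = R.shape[0]
    A = np.zeros_like(R)
    for i in range(p):
        for j in range(p):
            A[i, j] = -Rinv[i, j] / np.sqrt(Rinv[i, i] * Rinv[j, j])
    num_j = np.zeros(p)
    den_j = np.zeros(p)
    for j in range(p):
        for i in range(p):
            if i != j:
                num_j[j] += R[i, j] ** 2
                den_j[j] += A[i, j] ** 2
    per_var = num_j / (num_j + den_j)
    overall = num_j.sum() / (num_j.sum() + den_j.sum())
    return overall, per_var


def test_kmo_two_variable_closed_form_is_half():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    y = 0.6 * x + 0.8 * rng.normal(size=200)
    overall, per_var = kmo(np.column_stack([x, y]))
    # with 2 variables the anti-image partial equals -r, so KMO = 1/2 exactly
    assert overall == pytest.approx(0.5, abs=1e-12)
    assert np.allclose(per_var, 0.5, atol=1e-12)


@pytest.mark.parametrize("p", [3, 4, 5])
def test_kmo_agrees_with_bruteforce(p):
    rng = np.random.default_rng(p)
    base = rng.normal(size=(60, 2))
    X = base @ rng.normal(size=(2, p)) + 0.7 * rng.normal(size=(60, p))
    overall, per_var = kmo(X)
    o2, pv2 = _kmo_bruteforce(X)
    assert overall == pytest.approx(o2, abs=1e-10)
    assert np.allclose(per_var, pv2, atol=1e-10)
    assert 0.0 <= overall <= 1.0


def test_kmo_scale_invariant_exactly():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 3)) @ np.array([[1, 0.5, 0], [0, 1, 0.3], [0, 0, 1.0]])
    o1, pv1 = kmo(X)
    o2, pv2 = kmo(X * np.array([3.0, 0.01, 250.0]) + np.array([5, -2, 11.0]))
    assert o1 == pytest.approx(o2, abs=1e-12)
    assert np.allclose(pv1, pv2, atol=1e-12)


def test_kmo_separates_unstructured_from_factorable_data():
    rng = np.random.default_rng(42)
    # independent variables: partial correlations track the raw ones, so the
    # ratio settles near one half (the classic "mediocre" adequacy value)
    X = rng.normal(size=(20000, 4))
    overall, _ = kmo(X)
    assert overall == pytest.approx(0.5, abs=0.05)
    # a strong single common factor drives the measure toward 1
    f = rng.normal(size=(20000, 1))
    Y = f + 0.3 * rng.normal(size=(20000, 4))
    strong, _ = kmo(Y)
    assert strong > 0.7 > overall


def test_kmo_constant_column_is_error():
    X = np.column_stack([np.arange(10.0), np.full(10, 1.0)])
    with pytest.raises(SPIModelError, match="constant"):
        kmo(X)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def test_smote_equalises_counts_and_flags_synthetic():
    rng = np.random.default_rng(1)
    ds = _dataset(rng.normal(size=(10, 3)), rng.normal(size=(4, 3)))
    out = smote_balance(ds, seed=7)
    assert (out.groups == "pro").sum() == (out.groups == "amateur").sum() == 10
    assert out.synthetic.sum() == 6
    assert not out.synthetic[: len(ds.X)].any()


def test_smote_rows_lie_on_nearest_neighbour_segments():
    rng = np.random.default_rng(3)
    minority = rng.normal(size=(5, 2))
    ds = _dataset(rng.normal(size=(12, 2)), minority, names=("a", "b"))
    out = smote_balance(ds, seed=11)
    d2 = ((minority[:, None] - minority[None, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)
    for row in out.X[out.synthetic]:
        on_some_segment = False
        for j in range(5):
            p, q = minority[j], minority[nn[j]]
            seg = q - p
            u = np.dot(row - p, seg) / np.dot(seg, seg)
            if 0.0 <= u <= 1.0 and np.allclose(p + u * seg, row, atol=1e-9):
                on_some_segment = True
                break
        assert on_some_segment, f"synthetic row {row} not on any NN segment"


def test_smote_deterministic_and_identity_when_balanced():
    rng = np.random.default_rng(4)
    ds = _dataset(rng.normal(size=(8, 3)), rng.normal(size=(3, 3)))
    a = smote_balance(ds, seed=5)
    b = smote_balance(ds, seed=5)
    np.testing.assert_array_equal(a.X, b.X)
    even = _dataset(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
    assert smote_balance(even, seed=1) is even
    tiny = _dataset(rng.normal(size=(4, 3)), rng.normal(size=(1, 3)))
    with pytest.raises(SPIModelError, match="at least 2"):
        smote_balance(tiny, seed=1)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_axis_aligned_data():
    rng = np.random.default_rng(6)
    Z = np.column_stack([rng.normal(0, 3, 50), np.zeros(50)])
    W, evals, center = fit_pca_on_pros(Z)
    assert np.allclose(np.abs(W[0]), [1.0, 0.0])
    assert W[0][np.argmax(np.abs(W[0]))] > 0  # sign convention


def test_pca_diagonalises_and_reconstructs():
    rng = np.random.default_rng(8)
    Z = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3))
    W, evals, center = fit_pca_on_pros(Z)
    assert np.allclose(W @ W.T, np.eye(3), atol=1e-10)
    pcs = pc_transform(Z, W)
    pcs_c = pcs - pcs.mean(axis=0)
    cov = pcs_c.T @ pcs_c / len(Z)
    off = cov - np.diag(np.diag(cov))
    assert np.max(np.abs(off)) < 1e-10
    assert np.allclose(pcs @ W, Z, atol=1e-10)  # full-rank reconstruction
    assert np.all(np.diff(evals) <= 1e-12)  # decreasing eigenvalues


def test_pca_matches_sklearn_up_to_sign():
    from sklearn.decomposition import PCA

    rng = np.random.default_rng(9)
    Z = rng.normal(size=(30, 3))
    W, _, _ = fit_pca_on_pros(Z)
    sk = PCA(n_components=3).fit(Z)
    for row, ref in zip(W, sk.components_):
        assert np.allclose(row, ref, atol=1e-8) or np.allclose(row, -ref, atol=1e-8)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _fixture_model():
    ds, printed = worked_example_fixture()
    center, mu, sd = fit_log_distance_scaling(ds.X[ds.is_pro], center=np.zeros(3))
    model = SPIModel(
        subset=("pc1", "pc2", "pc3"), pro_mean=np.zeros(3), pro_sd=np.ones(3),
        pca_components=np.eye(3), pro_pc_center=center,
        log_dist_mean=mu, log_dist_sd=sd,
    )
    return ds, printed, model


def test_fixture_spot_scores():
    _, _, model = _fixture_model()
    assert round(float(spi_score(np.array([[2.16, -0.47, -0.49]]), model)[0])) == 92
    assert round(float(spi_score(np.array([[-0.18, -0.17, 0.17]]), model)[0])) == 126


def test_score_at_centroid_is_floored_and_maximal():
    _, _, model = _fixture_model()
    at_center = spi_score(model.pro_pc_center[None, :], model)[0]
    near = spi_score(model.pro_pc_center[None, :] + 1e-4, model)[0]
    assert at_center > near
    assert np.isfinite(at_center)
    # strictly decreasing in distance beyond the floor
    d = np.array([1e-3, 1e-2, 0.1, 1.0, 10.0])
    scores = [spi_score(model.pro_pc_center[None, :] + di, model)[0] for di in d]
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_spi_invariant_to_log_base():
    ds, _, model = _fixture_model()
    ell10 = np.log10(np.linalg.norm(ds.X[ds.is_pro], axis=1))
    mu10, sd10 = ell10.mean(), ell10.std()
    s_e = spi_score(ds.X, model)
    s_10 = 100.0 - 10.0 * (np.log10(np.linalg.norm(ds.X, axis=1)) - mu10) / sd10
    assert np.allclose(s_e, s_10, atol=1e-9)


def test_spi_invariant_to_joint_rotation_of_pc_space():
    ds, _, model = _fixture_model()
    rng = np.random.default_rng(12)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rotated = ds.X @ Q.T
    center, mu, sd = fit_log_distance_scaling(rotated[ds.is_pro], center=np.zeros(3))
    m2 = SPIModel(
        subset=model.subset, pro_mean=model.pro_mean, pro_sd=model.pro_sd,
        pca_components=np.eye(3), pro_pc_center=center, log_dist_mean=mu, log_dist_sd=sd,
    )
    assert np.allclose(spi_score(rotated, m2), spi_score(ds.X, model), atol=1e-9)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def test_fitted_pipeline_anchors_pros_at_100_10(cohort_dataset):
    model, balanced, scores = fit_spi_model(
        cohort_dataset,
        ["pelvis.peak_pre_impact", "pelvis.at_impact", "torso.peak_post_impact"],
        seed=3,
    )
    pro = scores[balanced.is_pro & ~balanced.synthetic]
    assert pro.mean() == pytest.approx(100.0, abs=1e-9)
    assert pro.std() == pytest.approx(10.0, abs=1e-9)
    assert (balanced.groups == "pro").sum() == (balanced.groups == "amateur").sum()


def test_duplicating_pro_rows_leaves_model_unchanged(cohort_dataset):
    import dataclasses

    subset = ["pelvis.peak_pre_impact", "torso.peak_post_impact"]
    m1, _, _ = fit_spi_model(cohort_dataset, subset, seed=3)
    pro_idx = np.flatnonzero(cohort_dataset.is_pro)
    dup = LabeledDataset(
        X=np.vstack([cohort_dataset.X, cohort_dataset.X[pro_idx]]),
        groups=np.concatenate([cohort_dataset.groups, cohort_dataset.groups[pro_idx]]),
        subject_ids=np.concatenate([cohort_dataset.subject_ids, cohort_dataset.subject_ids[pro_idx]]),
        swing_ids=np.concatenate([cohort_dataset.swing_ids, cohort_dataset.swing_ids[pro_idx]]),
        synthetic=np.concatenate([cohort_dataset.synthetic, np.zeros(len(pro_idx), bool)]),
        metric_names=cohort_dataset.metric_names,
    )
    m2, _, _ = fit_spi_model(dup, subset, seed=3)
    assert np.allclose(m1.pro_mean, m2.pro_mean)
    assert np.allclose(m1.pro_sd, m2.pro_sd)
    assert np.allclose(m1.pca_components, m2.pca_components)
    assert m1.log_dist_mean == pytest.approx(m2.log_dist_mean, abs=1e-9)
    assert m1.log_dist_sd == pytest.approx(m2.log_dist_sd, abs=1e-9)


def test_subset_size_validated(cohort_dataset):
    with pytest.raises(SPIModelError, match="1 to 3"):
        fit_spi_model(cohort_dataset, [m for m in cohort_dataset.metric_names[:4]], seed=1)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def test_model_round_trip_bit_identical_scores(tmp_path, cohort_dataset):
    model, balanced, scores = fit_spi_model(
        cohort_dataset, ["pelvis.peak_pre_impact", "pelvis.at_impact"], seed=9
    )
    path = tmp_path / "model.spi"
    save_model(model, path)
    back = load_model(path)
    assert back.subset == model.subset
    for attr in ("pro_mean", "pro_sd", "pca_components", "pro_pc_center"):
        np.testing.assert_allclose(getattr(back, attr), getattr(model, attr), atol=1e-12)
    z = normalize(cohort_dataset.select(model.subset).X, back.pro_mean, back.pro_sd)
    s2 = spi_score(pc_transform(z, back.pca_components), back)
    z1 = normalize(cohort_dataset.select(model.subset).X, model.pro_mean, model.pro_sd)
    s1 = spi_score(pc_transform(z1, model.pca_components), model)
    np.testing.assert_array_equal(s1, s2)


def test_model_schema_errors(tmp_path):
    _, _, model = _fixture_model()
    path = tmp_path / "model.spi"
    save_model(model, path)
    text = path.read_text().replace("log_dist_mean", "log_dist_avg")
    path.write_text(text)
    with pytest.raises(SPIModelError, match="schema"):
        load_model(path)
    path.write_text(text.replace("spi-model/1", "spi-model/999"))
    with pytest.raises(SPIModelError, match="schema"):
        load_model(path)
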