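"""Diurnal statistics cascade: transforms, screens, PCA, peaking classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isodiel.stats import (
    anova_screen,
    autoscale_rows,
    classify_peaking,
    cv_gate,
    geomean_normalize,
    log2_condition_means,
    pairwise_screen,
    pca_scores,
)


def make_matrix(rows, samples):
    return pd.DataFrame(rows, index=[f"r{i}" for i in range(len(rows))], columns=samples)


def make_design(conditions_reps):
    rows = []
    for cond, reps in conditions_reps.items():
        for r in range(1, reps + 1):
            rows.append({"sample_id": f"{cond}_{r}", "condition": cond, "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


DESIGN2 = make_design({"M": 3, "MD": 3})
SAMPLES2 = list(DESIGN2.index)


def test_log2_condition_means_examples():
    matrix = make_matrix([[4, 4, 4, 2, 8, 4]], SAMPLES2)
    means = log2_condition_means(matrix, DESIGN2)
    assert means.loc["r0", "M"] == pytest.approx(2.0)
    # replicates (2, 8): mean of log2 = mean of (1, 3) = 2 (geometric behavior)
    assert np.mean(np.log2([2, 8, 4])) == pytest.approx(means.loc["r0", "MD"])


def test_log2_condition_means_names_offending_cell():
    matrix = make_matrix([[4, 0, 4, 2, 8, 4]], SAMPLES2)
    with pytest.raises(ValueError, match="r0.*M_2"):
        log2_condition_means(matrix, DESIGN2)


def test_autoscale_rows():
    matrix = make_matrix([[1, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2]], SAMPLES2)
    scaled, flagged = autoscale_rows(matrix)
    assert scaled.loc["r0"].mean() == pytest.approx(0.0)
    assert scaled.loc["r0"].std(ddof=1) == pytest.approx(1.0)
    assert (scaled.loc["r1"] == 0).all()
    assert list(flagged) == ["r1"]
    # affine invariance: a*x + b scales to the same z-scores
    scaled2, _ = autoscale_rows(matrix * 3.7 + 11.0)
    assert np.allclose(scaled2.loc["r0"], scaled.loc["r0"])


def test_geomean_normalize():
    out = geomean_normalize(np.array([1.0, 2.0, 4.0]))
    assert out == pytest.approx([0.5, 1.0, 2.0])
    assert geomean_normalize(np.full(5, 3.3)) == pytest.approx(np.ones(5))
    with pytest.raises(ValueError):
        geomean_normalize(np.array([1.0, 0.0]))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8))
def test_geomean_normalize_identities(row):
    out = geomean_normalize(np.array(row))
    assert np.prod(out) == pytest.approx(1.0, rel=1e-6)
    # log2 of the normalized row equals mean-centered log2 of the raw row
    log2 = np.log2(np.array(row))
    assert np.allclose(np.log2(out), log2 - log2.mean(), atol=1e-9)


DESIGN5 = make_design({c: 3 for c in ["M", "MD", "E", "MN", "CL"]})
SAMPLES5 = list(DESIGN5.index)


def _row(cond_means, cv, rng):
    values = []
    for m in cond_means:
        values.extend(m * rng.lognormal(0, cv, 3))
    return values


def test_anova_screen_detects_planted_fold_change():
    rng = np.random.default_rng(1)
    matrix = make_matrix([_row([4, 1, 1, 1, 1], 0.1, rng)], SAMPLES5)
    (rec,) = anova_screen(matrix, DESIGN5)
    assert rec.significant
    assert rec.fold_change > 1.5
    assert rec.peaking == "M"


def test_anova_screen_fold_change_gate_blocks_small_effects():
    """p < 0.05 with fold change 1.2 must NOT be significant."""
    rng = np.random.default_rng(2)
    matrix = make_matrix([_row([1.2, 1, 1, 1, 1], 0.01, rng)], SAMPLES5)
    (rec,) = anova_screen(matrix, DESIGN5)
    assert rec.p_value < 0.05
    assert rec.fold_change < 1.5
    assert not rec.significant


def test_screen_gates_are_conjunctive_and_order_free():
    rng = np.random.default_rng(3)
    rows = [_row([rng.uniform(1, 4)] + [1] * 4, 0.15, rng) for _ in range(60)]
    records = anova_screen(make_matrix(rows, SAMPLES5), DESIGN5, alpha=0.05, fc_min=1.5)
    for rec in records:
        assert rec.significant == ((rec.p_value < 0.05) and (rec.fold_change > 1.5))


def test_pairwise_identical_groups_not_significant():
    matrix = make_matrix([[2, 2, 2, 2, 2, 2]], SAMPLES2)
    (rec,) = pairwise_screen(matrix, DESIGN2, "M", "MD")
    assert not rec.significant
    assert rec.fold_change == pytest.approx(1.0)


def test_pairwise_detects_planted_two_fold_difference():
    rng = np.random.default_rng(4)
    matrix = make_matrix([_row([2, 1, 1, 1, 1], 0.1, rng)], SAMPLES5)
    (rec,) = pairwise_screen(matrix, DESIGN5, "M", "CL")
    assert rec.significant
    assert rec.peaking == "M"


def test_pairwise_requires_replicates():
    design = make_design({"MD": 1, "CL": 3})
    matrix = make_matrix([[1, 2, 2, 2]], list(design.index))
    with pytest.raises(ValueError):
        pairwise_screen(matrix, design, "MD", "CL")


def test_cv_gate_hand_computed():
    row_pass = list(np.tile([90.0, 100.0, 110.0], 5))  # CV = 10/100 = 0.1
    row_fail = list(np.tile([10.0, 100.0, 190.0], 5))  # CV = 90/100 = 0.9
    matrix = make_matrix([row_pass, row_fail], SAMPLES5)
    assert cv_gate(matrix, DESIGN5, cv_max=0.3) == ["r0"]


def test_cv_gate_identical_replicates_survive():
    matrix = make_matrix([[5.0] * 15], SAMPLES5)
    assert cv_gate(matrix, DESIGN5) == ["r0"]


def test_pca_duplicate_samples_coincide():
    rng = np.random.default_rng(5)
    matrix = make_matrix(rng.normal(size=(8, 15)), SAMPLES5)
    matrix["MD_1"] = matrix["M_1"]  # duplicate sample
    scores, _, _ = pca_scores(matrix, DESIGN5)
    assert np.allclose(scores.loc["M_1"], scores.loc["MD_1"], atol=1e-9)


def test_pca_explained_variance_sums_to_total():
    rng = np.random.default_rng(6)
    matrix = make_matrix(rng.normal(size=(6, 15)), SAMPLES5)
    _, ratio, _ = pca_scores(matrix, DESIGN5, n_components=15)
    assert ratio.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(ratio) <= 1e-12)  # non-increasing


def test_pca_matches_eigendecomposition_oracle():
    """Scores equal brute-force eigen-decomposition of the covariance, up to sign."""
    rng = np.random.default_rng(7)
    matrix = make_matrix(rng.normal(size=(10, 5)), [f"s{i}" for i in range(5)])
    design = pd.DataFrame(
        {"condition": ["M"] * 5, "replicate": range(5)},
        index=pd.Index(matrix.columns, name="sample_id"),
    )
    scores, _, _ = pca_scores(matrix, design, n_components=2)
    X = matrix.to_numpy().T
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    oracle = Xc @ eigvec[:, order[:2]]
    for k in range(2):
        col = scores.iloc[:, k].to_numpy()
        assert np.allclose(col, oracle[:, k], atol=1e-8) or np.allclose(
            col, -oracle[:, k], atol=1e-8
        )


def test_pca_ellipses_cover_conditions(default_bundle):
    """Replicates cluster: within-condition PC distances < between-condition."""
    from isodiel.pairing import build_abundance_matrix, pair_with_internal_standard
    from isodiel.stats import autoscale_rows

    pairs = {
        s: pair_with_internal_standard(f)
        for s, f in default_bundle.mixed_features.items()
    }
    matrix = build_abundance_matrix(pairs, default_bundle.design)
    scaled, _ = autoscale_rows(np.log2(matrix))
    scores, _, ellipses = pca_scores(scaled, default_bundle.design)
    assert set(ellipses) == {"M", "MD", "E", "MN", "CL"}
    pts = scores[["PC1", "PC2"]]
    conds = default_bundle.design["condition"]
    within, between = [], []
    samples = list(pts.index)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            d = float(np.linalg.norm(pts.loc[a] - pts.loc[b]))
            (within if conds[a] == conds[b] else between).append(d)
    assert np.mean(within) < np.mean(between)


def test_classify_peaking():
    assert classify_peaking({"M": 1, "MD": 5, "E": 2, "MN": 1}) == ("MD", False)
    assert classify_peaking({"M": 2, "MD": 2, "E": 2, "MN": 2}) == ("M", True)
    with pytest.raises(ValueError, match="missing"):
        classify_peaking({"M": 1, "MD": 5, "E": 2})
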