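"""RPKM, log2, mixed-model normalization and PCA QC."""

import numpy as np
import pandas as pd
import pytest

from smirnet import normalize
from smirnet.matrix import ExpressionMatrix
from smirnet.normalize import NormalizationError


def counts_matrix(values, transcripts, samples):
    return ExpressionMatrix(
        pd.DataFrame(values, index=transcripts, columns=samples), "counts"
    )


def annotation_frame(lengths):
    return pd.DataFrame(
        {
            "transcript_id": list(lengths),
            "biotype": "mRNA",
            "length_bp": list(lengths.values()),
            "is_tf": False,
        }
    ).set_index("transcript_id", drop=False)


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------


def test_rpkm_round_number_examples():
    m = counts_matrix([[100], [0], [500]], ["a", "b", "c"], ["s1"])
    ann = annotation_frame({"a": 1000, "b": 1000, "c": 2000})
    out = normalize.rpkm(m, ann, mapped_reads_millions=pd.Series({"s1": 10.0}))
    assert out.values.loc["a", "s1"] == pytest.approx(10.0)
    assert out.values.loc["b", "s1"] == 0.0
    # 500 reads / (25M x 2 kb) = 10
    out25 = normalize.rpkm(m, ann, mapped_reads_millions=pd.Series({"s1": 25.0}))
    assert out25.values.loc["c", "s1"] == pytest.approx(10.0)


def test_rpkm_linear_in_counts_and_depth_invariant():
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 500, size=(20, 4))
    ids = [f"t{i}" for i in range(20)]
    ann = annotation_frame({i: int(l) for i, l in zip(ids, rng.integers(200, 3000, 20))})
    m = counts_matrix(vals, ids, ["s1", "s2", "s3", "s4"])
    base = normalize.rpkm(m, ann)
    # doubling one column's counts doubles its implied depth: RPKM unchanged
    vals2 = vals.copy()
    vals2[:, 1] *= 2
    m2 = counts_matrix(vals2, ids, ["s1", "s2", "s3", "s4"])
    doubled = normalize.rpkm(m2, ann)
    np.testing.assert_allclose(
        doubled.values["s2"].to_numpy(), base.values["s2"].to_numpy()
    )


def test_rpkm_zero_depth_names_sample():
    m = counts_matrix([[0], [0]], ["a", "b"], ["bad_sample"])
    ann = annotation_frame({"a": 100, "b": 100})
    with pytest.raises(NormalizationError, match="bad_sample"):
        normalize.rpkm(m, ann)


# ---------------------------------------------------------------------------
# log2
# ---------------------------------------------------------------------------


def test_log2_examples():
    m = counts_matrix([[1]], ["a"], ["s1"])
    ann = annotation_frame({"a": 1000})
    r = normalize.rpkm(m, ann, mapped_reads_millions=pd.Series({"s1": 1.0}))
    r.values.loc["a", "s1"] = 0.0
    assert normalize.log2_transform(r).values.loc["a", "s1"] == 0.0
    r.values.loc["a", "s1"] = 1.0
    assert normalize.log2_transform(r).values.loc["a", "s1"] == pytest.approx(1.0)
    r.values.loc["a", "s1"] = 7.0
    assert normalize.log2_transform(r).values.loc["a", "s1"] == pytest.approx(3.0)
    with pytest.raises(ValueError):
        normalize.log2_transform(r, offset=0.0)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------


def _sheet(libraries, tissues=None, animals=None):
    n = len(libraries)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "animal": animals or [f"A{i % 2}" for i in range(n)],
            "tissue": tissues or ["TP", "HE"] * (n // 2),
            "library": libraries,
        }
    ).set_index("sample_id", drop=False)


def _log2_matrix(values, samples):
    df = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(len(values))],
        columns=list(samples.index),
    )
    return ExpressionMatrix(df, "log2rpkm")


def test_single_library_passes_through():
    samples = _sheet(["L1"] * 4)
    m = _log2_matrix(np.random.default_rng(0).normal(5, 1, (10, 4)), samples)
    fit, out = normalize.fit_mixed_model(m, samples)
    pd.testing.assert_frame_equal(out.values, m.values)
    assert out.stage == "normalized"


def test_constant_library_shift_is_removed():
    rng = np.random.default_rng(1)
    samples = _sheet(["L1", "L1", "L2", "L2"] * 2, tissues=["TP", "HE"] * 4,
                     animals=["A1", "A2", "A3", "A4"] * 2)
    base = rng.normal(5, 1, (30, 8))
    shifted = base.copy()
    delta = 0.8
    is_l2 = (samples["library"] == "L2").to_numpy()
    shifted[:, is_l2] += delta
    m = _log2_matrix(shifted, samples)
    fit, out = normalize.fit_mixed_model(m, samples)
    means = {
        lib: out.values.to_numpy()[:, (samples["library"] == lib).to_numpy()].mean()
        for lib in ("L1", "L2")
    }
    assert abs(means["L1"] - means["L2"]) < 1e-6
    assert fit.library_effects.sum() == pytest.approx(0.0, abs=1e-9)


def test_fit_is_idempotent():
    rng = np.random.default_rng(2)
    samples = _sheet(["L1", "L2"] * 4, tissues=["TP", "HE", "TE", "TP"] * 2,
                     animals=[f"A{i//2}" for i in range(8)])
    m = _log2_matrix(rng.normal(4, 1.2, (40, 8)), samples)
    _, once = normalize.fit_mixed_model(m, samples)
    relabeled = ExpressionMatrix(once.values, "log2rpkm")
    _, twice = normalize.fit_mixed_model(relabeled, samples)
    assert np.abs(once.values.to_numpy() - twice.values.to_numpy()).max() < 1e-6


def test_blup_solutions_match_gls_oracle():
    """Henderson MME solutions equal the V-based GLS/BLUP closed forms on a
    small dense problem with known variance ratios."""
    rng = np.random.default_rng(3)
    n = 12
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
    Z1 = pd.get_dummies(rng.integers(0, 3, n)).to_numpy(dtype=float)
    Z2 = pd.get_dummies(rng.integers(0, 4, n)).to_numpy(dtype=float)
    y = rng.normal(0, 1, n)
    s_e, s_1, s_2 = 1.0, 0.5, 0.25
    beta, (u1, u2) = normalize.solve_mme(
        y, X, [Z1, Z2], [s_e / s_1, s_e / s_2]
    )
    # independent oracle: marginal covariance inversion
    V = s_1 * Z1 @ Z1.T + s_2 * Z2 @ Z2.T + s_e * np.eye(n)
    Vi = np.linalg.inv(V)
    beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta_gls
    u1_gls = s_1 * Z1.T @ Vi @ resid
    u2_gls = s_2 * Z2.T @ Vi @ resid
    np.testing.assert_allclose(beta, beta_gls, atol=1e-8)
    np.testing.assert_allclose(u1, u1_gls, atol=1e-8)
    np.testing.assert_allclose(u2, u2_gls, atol=1e-8)


def test_variance_components_can_be_supplied():
    samples = _sheet(["L1", "L2"] * 4, tissues=["TP", "HE", "TE", "TP"] * 2,
                     animals=[f"A{i//2}" for i in range(8)])
    m = _log2_matrix(np.random.default_rng(4).normal(4, 1, (20, 8)), samples)
    fit, out = normalize.fit_mixed_model(
        m,
        samples,
        variance_components={
            "gene": 1.0,
            "gene_x_tissue": 0.3,
            "gene_x_animal": 0.1,
            "residual": 0.2,
        },
    )
    assert fit.n_iter == 0 and fit.converged
    assert out.stage == "normalized"


# ---------------------------------------------------------------------------
# PCA QC
# ---------------------------------------------------------------------------


def test_pca_duplicate_samples_get_identical_coordinates():
    rng = np.random.default_rng(5)
    col = rng.normal(0, 1, 30)
    data = np.column_stack([col, col, rng.normal(0, 1, 30), rng.normal(0, 1, 30)])
    m = ExpressionMatrix(
        pd.DataFrame(data, index=[f"t{i}" for i in range(30)],
                     columns=["a", "a2", "b", "c"]),
        "normalized",
    )
    coords, _ = normalize.pca_qc(m)
    np.testing.assert_allclose(coords.loc["a"], coords.loc["a2"], atol=1e-8)


def test_pca_rank_one_matrix_has_full_first_component():
    u = np.array([1.0, 2.0, 3.0, 4.0])
    v = np.array([1.0, -1.0, 0.5])
    m = ExpressionMatrix(
        pd.DataFrame(np.outer(u, v), index=list("abcd"), columns=["s1", "s2", "s3"]),
        "normalized",
    )
    _, var = normalize.pca_qc(m)
    assert var[0] == pytest.approx(1.0)


def test_pca_separates_planted_clusters_on_pc1():
    rng = np.random.default_rng(6)
    data = rng.normal(0, 0.1, (50, 8))
    data[:, 4:] += 3.0  # second cluster shifted on every transcript
    m = ExpressionMatrix(
        pd.DataFrame(data, index=[f"t{i}" for i in range(50)],
                     columns=[f"s{j}" for j in range(8)]),
        "normalized",
    )
    coords, var = normalize.pca_qc(m)
    pc1 = coords["PC1"].to_numpy()
    assert (pc1[:4].max() < pc1[4:].min()) or (pc1[:4].min() > pc1[4:].max())
    assert var[0] > 0.9


def test_pca_constant_matrix_rejected():
    m = ExpressionMatrix(
        pd.DataFrame(np.ones((5, 4)), index=list("abcde"),
                     columns=["s1", "s2", "s3", "s4"]),
        "normalized",
    )
    with pytest.raises(ValueError, match="constant"):
        normalize.pca_qc(m)
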