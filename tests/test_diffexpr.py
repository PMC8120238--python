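"""Expression filter, moderated t, BH adjustment, DE calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smirnet import diffexpr
from smirnet.matrix import ExpressionMatrix


def rpkm_matrix(values, transcripts=None):
    values = np.asarray(values, dtype=float)
    transcripts = transcripts or [f"t{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=transcripts,
                     columns=[f"s{j}" for j in range(values.shape[1])]),
        "rpkm",
    )


def norm_matrix(values, samples):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"t{i}" for i in range(values.shape[0])],
                     columns=list(samples.index)),
        "normalized",
    )


def two_group_sheet(n1=4, n2=4):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n1 + n2)],
            "animal": [f"A{i}" for i in range(n1 + n2)],
            "tissue": ["HE"] * n1 + ["TP"] * n2,
            "library": ["L1"] * (n1 + n2),
        }
    ).set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# filter
# ---------------------------------------------------------------------------


def test_filter_examples():
    vals = np.zeros((3, 12))
    vals[1, :3] = 5.0  # expressed in exactly 3 samples
    vals[2, :] = 10.0
    m = rpkm_matrix(vals, ["zero", "borderline", "high"])
    kept, removed = diffexpr.filter_low_expression(m, min_rpkm=2, min_samples=3)
    assert "zero" in removed
    assert "borderline" in kept
    assert "high" in kept
    assert sorted(kept + removed) == sorted(m.transcript_ids)

    kept_all, removed_none = diffexpr.filter_low_expression(m, min_rpkm=0)
    assert removed_none == []


def test_filter_min_samples_exceeding_n_rejected():
    m = rpkm_matrix(np.ones((2, 4)))
    with pytest.raises(ValueError):
        diffexpr.filter_low_expression(m, min_samples=5)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def test_d0_zero_reduces_to_ordinary_pooled_t():
    rng = np.random.default_rng(0)
    samples = two_group_sheet()
    vals = rng.normal(5, 1, (50, 8))
    m = norm_matrix(vals, samples)
    table = diffexpr.moderated_t(m, samples, "HE/TP", d0=0.0, s0_sq=1.0)
    t_ref, p_ref = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1, equal_var=True)
    np.testing.assert_allclose(table["t_mod"], t_ref, atol=1e-10)
    np.testing.assert_allclose(table["p"], p_ref, atol=1e-10)


def test_d0_infinite_uses_prior_variance_only():
    rng = np.random.default_rng(1)
    samples = two_group_sheet()
    vals = rng.normal(5, 1, (20, 8))
    m = norm_matrix(vals, samples)
    s0_sq = 0.7
    table = diffexpr.moderated_t(m, samples, "HE/TP", d0=math.inf, s0_sq=s0_sq)
    lfc = vals[:, :4].mean(axis=1) - vals[:, 4:].mean(axis=1)
    expected = lfc / (math.sqrt(s0_sq) * math.sqrt(1 / 4 + 1 / 4))
    np.testing.assert_allclose(table["t_mod"], expected, atol=1e-10)


def test_moderated_t_matches_hand_formula_with_fixed_prior():
    """4-vs-4 toy evaluated against a direct transcription of the formula."""
    rng = np.random.default_rng(2)
    samples = two_group_sheet()
    vals = rng.normal(0, 1, (10, 8))
    d0, s0_sq = 4.0, 0.5
    m = norm_matrix(vals, samples)
    table = diffexpr.moderated_t(m, samples, "HE/TP", d0=d0, s0_sq=s0_sq)
    for i in range(10):
        g1, g2 = vals[i, :4], vals[i, 4:]
        lfc = g1.mean() - g2.mean()
        s2 = (3 * g1.var(ddof=1) + 3 * g2.var(ddof=1)) / 6
        s2_post = (d0 * s0_sq + 6 * s2) / (d0 + 6)
        t_exp = lfc / math.sqrt(s2_post * 0.5)
        assert table["t_mod"].iloc[i] == pytest.approx(t_exp, abs=1e-10)
        p_exp = 2 * stats.t.sf(abs(t_exp), d0 + 6)
        assert table["p"].iloc[i] == pytest.approx(p_exp, abs=1e-10)


def test_moderated_t_continuous_in_d0_near_zero():
    rng = np.random.default_rng(3)
    samples = two_group_sheet()
    vals = rng.normal(5, 1, (20, 8))
    m = norm_matrix(vals, samples)
    t0 = diffexpr.moderated_t(m, samples, "HE/TP", d0=0.0, s0_sq=1.0)["t_mod"]
    t_eps = diffexpr.moderated_t(m, samples, "HE/TP", d0=1e-8, s0_sq=1.0)["t_mod"]
    np.testing.assert_allclose(t0, t_eps, atol=1e-6)


def test_sign_convention_up_in_first_named_tissue():
    samples = two_group_sheet(2, 2)
    vals = np.array([[10.0, 10.0, 2.0, 2.0], [5.0, 6.0, 5.5, 4.5]])
    m = norm_matrix(vals, samples)
    table = diffexpr.moderated_t(m, samples, "HE/TP", d0=0, s0_sq=1)
    assert table["log2fc"].iloc[0] == pytest.approx(8.0)


def test_too_few_samples_rejected():
    samples = two_group_sheet(1, 4)
    m = norm_matrix(np.ones((3, 5)), samples)
    with pytest.raises(ValueError, match=">= 2 samples"):
        diffexpr.moderated_t(m, samples, "HE/TP")


def test_prior_estimation_recovers_known_hyperparameters():
    """Sample variances drawn from the scaled chi-square hierarchy should
    give back (d0, s0^2) close to the generating values."""
    rng = np.random.default_rng(4)
    d0_true, s0_true, df = 5.0, 0.8, 6
    n = 20000
    true_var = s0_true * d0_true / rng.chisquare(d0_true, n)
    s2 = true_var * rng.chisquare(df, n) / df
    d0_hat, s0_hat = diffexpr.estimate_prior(s2, df)
    assert d0_hat == pytest.approx(d0_true, rel=0.15)
    assert s0_hat == pytest.approx(s0_true, rel=0.05)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def test_bh_worked_example():
    np.testing.assert_allclose(
        diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_trivial_cases():
    assert diffexpr.bh_adjust([0.33])[0] == pytest.approx(0.33)
    np.testing.assert_allclose(diffexpr.bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    assert len(diffexpr.bh_adjust([])) == 0


def _bh_oracle(p):
    """Step-up BH coded independently from first principles."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
)
def test_bh_matches_first_principles_oracle(p):
    np.testing.assert_allclose(diffexpr.bh_adjust(p), _bh_oracle(p), atol=1e-12)


# ---------------------------------------------------------------------------
# DE calling
# ---------------------------------------------------------------------------


def _de_frame(rows):
    return pd.DataFrame(
        rows, columns=["transcript_id", "comparison", "log2fc", "t_mod", "p"]
    )


def test_call_de_rules():
    table = _de_frame(
        [
            ("a", "HE/TP", 2.0, 5.0, 0.001),
            ("b", "HE/TP", 0.5, 5.0, 0.001),
            ("c", "HE/TP", -3.0, -5.0, 0.9),
        ]
    )
    out = diffexpr.call_de(table, alpha=0.05, lfc_threshold=1.0)
    flags = out.set_index("transcript_id")["is_de"]
    assert flags["a"] and not flags["b"] and not flags["c"]
    assert (out["p_adj"] >= out["p"] - 1e-15).all()


def test_call_de_alpha_zero_flags_nothing():
    table = _de_frame([("a", "HE/TP", 5.0, 9.0, 1e-12)])
    out = diffexpr.call_de(table, alpha=0.0)
    assert not out["is_de"].any()


def test_call_de_invalid_alpha_rejected():
    table = _de_frame([("a", "HE/TP", 5.0, 9.0, 1e-12)])
    with pytest.raises(ValueError):
        diffexpr.call_de(table, alpha=1.5)
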