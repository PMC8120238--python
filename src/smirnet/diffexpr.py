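"""Differential expression: expression filter, empirical-Bayes moderated t, FDR.

Per pairwise tissue comparison the per-transcript statistic is a two-group
pooled t with the sample variance shrunk toward an empirical-Bayes prior:

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_tilde   = log2fc / (s_tilde * sqrt(1/n1 + 1/n2))

with (d0, s0^2) estimated by closed-form method of moments on log s_g^2
and p-values from a t distribution on d0 + d_g degrees of freedom. A
positive log2 fold change means up-regulation in the first-named tissue of
the comparison. Multiple testing is controlled by Benjamini-Hochberg;
a transcript is called DE when p_adj <= alpha and |log2fc| >= the log2
fold-change threshold (default 1, i.e. two-fold).
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

COMPARISON_SEP = "/"


def comparison_tissues(comparison: str) -> Tuple[str, str]:
    t1, t2 = comparison.split(COMPARISON_SEP)
    return t1, t2


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_low_expression(
    m: ExpressionMatrix, min_rpkm: float = 2.0, min_samples: int = 3
) -> Tuple[List[str], List[str]]:
    """Partition transcripts into (kept, removed) by detectable expression.

    A transcript is kept iff it reaches ``min_rpkm`` in at least
    ``min_samples`` samples.
    """
    if m.stage != "rpkm":
        raise ValueError(f"expected rpkm stage, got {m.stage!r}")
    if min_rpkm < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    if min_samples > m.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {m.shape[1]} available samples"
        )
    n_ok = (m.values >= min_rpkm).sum(axis=1)
    keep = n_ok >= min_samples
    kept = list(m.transcript_ids[keep])
    removed = list(m.transcript_ids[~keep])
    return kept, removed


# ---------------------------------------------------------------------------
# empirical-Bayes prior estimation (method of moments on log s^2)
# ---------------------------------------------------------------------------


def estimate_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Estimate (d0, s0^2) from per-transcript sample variances.

    Moments of log(s^2) for chi-square distributed variances give closed
    forms: the excess spread of log s^2 over what df residual degrees of
    freedom explain determines d0 (via the inverse trigamma), and the
    location determines s0^2. Returns d0 = inf when the observed spread is
    at or below the theoretical minimum.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2))
    if excess <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2)) - math.log(d0 / 2))
    return float(d0), float(s0_sq)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def moderated_t(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    comparison: str,
    d0: Optional[float] = None,
    s0_sq: Optional[float] = None,
) -> pd.DataFrame:
    """Per-transcript moderated t for one pairwise tissue comparison.

    Returns a DataFrame with columns transcript_id, comparison, log2fc,
    t_mod, p (unadjusted). ``d0``/``s0_sq`` override the empirical-Bayes
    prior (d0=0 reduces to the ordinary pooled t; d0=inf shrinks fully to
    s0). When the prior cannot be estimated, falls back to the ordinary t
    with a warning.
    """
    if m.stage not in ("normalized", "log2rpkm"):
        raise ValueError(f"expected normalized/log2rpkm stage, got {m.stage!r}")
    t1, t2 = comparison_tissues(comparison)
    g1 = [s for s in m.sample_ids if samples.loc[s, "tissue"] == t1]
    g2 = [s for s in m.sample_ids if samples.loc[s, "tissue"] == t2]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"comparison {comparison}: need >= 2 samples per tissue (got {n1}, {n2})"
        )

    Y1 = m.values[g1].to_numpy(dtype=float)
    Y2 = m.values[g2].to_numpy(dtype=float)
    lfc = Y1.mean(axis=1) - Y2.mean(axis=1)
    v1 = Y1.var(axis=1, ddof=1)
    v2 = Y2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    if np.all(s2 == 0):
        raise ValueError("zero variance for every transcript")

    if d0 is None or s0_sq is None:
        try:
            est_d0, est_s0 = estimate_prior(s2, df)
        except ValueError:
            warnings.warn("prior estimation failed; using ordinary t")
            est_d0, est_s0 = 0.0, 1.0
        if not math.isfinite(est_d0) and est_d0 != math.inf:
            warnings.warn("non-finite prior df; using ordinary t")
            est_d0, est_s0 = 0.0, 1.0
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    return pd.DataFrame(
        {
            "transcript_id": m.transcript_ids,
            "comparison": comparison,
            "log2fc": lfc,
            "t_mod": t,
            "p": p,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# multiple testing and DE calling
# ---------------------------------------------------------------------------


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    table: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 1.0
) -> pd.DataFrame:
    """Adjust p-values within each comparison and flag DE transcripts.

    is_de <=> p_adj <= alpha and |log2fc| >= lfc_threshold.
    """
    if not 0 < alpha < 1:
        if alpha == 0:
            # degenerate but well-defined: nothing can pass
            pass
        else:
            raise ValueError("alpha must lie in (0, 1)")
    out = table.copy()
    out["p_adj"] = np.nan
    for comp, idx in out.groupby("comparison").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["is_de"] = (out["p_adj"] <= alpha) & (out["log2fc"].abs() >= lfc_threshold)
    return out


def run_differential_expression(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    comparisons: Sequence[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Moderated t + BH + DE calls for every comparison, one stacked table."""
    tables = [moderated_t(m, samples, comp) for comp in comparisons]
    return call_de(pd.concat(tables, ignore_index=True), alpha, lfc_threshold)


def de_ids(table: pd.DataFrame, comparison: Optional[str] = None) -> List[str]:
    """Transcripts called DE, optionally restricted to one comparison."""
    sub = table[table["is_de"]]
    if comparison is not None:
        sub = sub[sub["comparison"] == comparison]
    return sorted(sub["transcript_id"].unique())
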