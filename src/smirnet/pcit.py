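"""PCIT: partial-correlation-with-information-theory edge significance.

For every trio of nodes (x, y, z) the three first-order partial
correlations are computed,

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

and a local tolerance

    eps_xyz = (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|) / 3.

An edge (x, y) is declared non-significant if some third node z dominates
it: |r_xy| <= |eps_xyz * r_xz| and |r_xy| <= |eps_xyz * r_yz|; otherwise it
is significant. The scan is O(n^3) and deterministic; denominators within
1e-12 of zero are guarded (the partial is treated as 0, and ratio terms
with a zero direct correlation contribute 0), so the significance matrix
never contains NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

_GUARD = 1e-12


@dataclass
class CorrelationMatrix:
    r: np.ndarray  # symmetric, unit diagonal
    ids: List[str]
    n_samples: int
    constant_ids: List[str]  # rows with zero variance (r forced to 0)


@dataclass
class PcitResult:
    significant: np.ndarray  # boolean, symmetric, False diagonal
    ids: List[str]


def correlation_matrix(
    m: ExpressionMatrix, ids: Optional[Sequence[str]] = None
) -> CorrelationMatrix:
    """Pearson correlations across all samples for the selected transcripts.

    Constant transcripts get r = 0 against everything (flagged in
    ``constant_ids``) rather than NaN.
    """
    if m.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlations")
    sub = m if ids is None else m.subset_transcripts(ids)
    data = sub.to_numpy()
    sd = data.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.atleast_2d(r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(
        r=r,
        ids=list(sub.transcript_ids),
        n_samples=m.shape[1],
        constant_ids=[i for i, c in zip(sub.transcript_ids, constant) if c],
    )


def pcit_significant(c: CorrelationMatrix) -> PcitResult:
    """Flag significant co-expression edges by the PCIT trio scan.

    Vectorized over the conditioning node: for each z the three partials of
    every trio (x, y, z) come from closed forms in the correlation matrix,
    so memory stays O(n^2) while work is O(n^3).
    """
    R = np.asarray(c.r, dtype=float)
    n = R.shape[0]
    if n < 3:
        warnings.warn("fewer than 3 nodes; all off-diagonal edges kept significant")
        sig = np.ones((n, n), dtype=bool)
        np.fill_diagonal(sig, False)
        return PcitResult(significant=sig, ids=list(c.ids))

    absR = np.abs(R)
    one_minus_sq = 1.0 - R**2
    dominated = np.zeros((n, n), dtype=bool)

    pair_ok = one_minus_sq >= _GUARD  # 1 - r_xy^2 clear of the guard
    for z in range(n):
        rz = R[:, z]  # r_xz for all x
        omz = one_minus_sq[:, z]  # 1 - r_xz^2
        ok_z = omz >= _GUARD

        # partial r_xy.z for all (x, y); 0 when either denominator factor
        # (1 - r_xz^2, 1 - r_yz^2) is within the guard of zero
        mask_a = ok_z[:, None] & ok_z[None, :]
        den_a = np.sqrt(np.where(mask_a, np.outer(omz, omz), 1.0))
        A = np.where(mask_a, (R - np.outer(rz, rz)) / den_a, 0.0)

        # partial r_xz.y for all (x, y): conditioning on y
        mask_b = pair_ok & ok_z[None, :]
        den_b = np.sqrt(np.where(mask_b, one_minus_sq * omz[None, :], 1.0))
        B = np.where(mask_b, (rz[:, None] - R * rz[None, :]) / den_b, 0.0)

        # partial r_yz.x = B transposed on (x, y)
        C = B.T

        eps = (
            _guarded_ratio(A, R)
            + _guarded_ratio(B, rz[:, None] * np.ones((1, n)))
            + _guarded_ratio(C, rz[None, :] * np.ones((n, 1)))
        ) / 3.0

        thr_x = np.abs(eps * rz[:, None])  # |eps * r_xz|
        thr_y = np.abs(eps * rz[None, :])  # |eps * r_yz|
        dom_z = (absR <= thr_x) & (absR <= thr_y)
        # z cannot dominate edges incident to itself, nor the diagonal
        dom_z[z, :] = False
        dom_z[:, z] = False
        dominated |= dom_z

    sig = ~dominated
    np.fill_diagonal(sig, False)
    sig &= sig.T  # symmetric by construction; enforce exactly
    return PcitResult(significant=sig, ids=list(c.ids))


def _guarded_ratio(partial: np.ndarray, direct: np.ndarray) -> np.ndarray:
    """|partial / direct| with zero direct correlations contributing 0."""
    out = np.zeros_like(partial)
    ok = np.abs(direct) > _GUARD
    out[ok] = np.abs(partial[ok] / direct[ok])
    return out


def extreme_edges(
    c: CorrelationMatrix, p: PcitResult, cutoff: float = 0.95
) -> pd.DataFrame:
    """PCIT-significant edges with |r| above the extreme-correlation cutoff.

    Returns a DataFrame (node_a, node_b, r) with node_a < node_b.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    rows = []
    n = len(c.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if p.significant[i, j] and abs(c.r[i, j]) > cutoff:
                rows.append(
                    {"node_a": c.ids[i], "node_b": c.ids[j], "r": float(c.r[i, j])}
                )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "r"])


def edge_table(c: CorrelationMatrix, p: PcitResult, cutoff: float = 0.95) -> pd.DataFrame:
    """Full edge list with significance and extreme flags (for export)."""
    rows = []
    n = len(c.ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(c.r[i, j])
            sig = bool(p.significant[i, j])
            rows.append(
                {
                    "node_a": c.ids[i],
                    "node_b": c.ids[j],
                    "r": r,
                    "pcit_significant": sig,
                    "extreme": sig and abs(r) > cutoff,
                }
            )
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "r", "pcit_significant", "extreme"]
    )
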