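"""Expression normalization: RPKM, log2, mixed-model library correction, PCA QC.

The mixed model is

    y_gs = mu + L_l(s)  +  G_g + (GT)_g,t(s) + (GA)_g,a(s) + e_gs

with the sequencing library L a fixed effect and gene (G), gene x tissue
(GT) and gene x animal (GA) random. Because the only fixed effect is a
sample-level factor and every random effect is gene-indexed, the marginal
covariance of the data is block-diagonal by gene with one common
(samples x samples) block; REML therefore reduces exactly to computations
on that small block, whatever the number of transcripts. Variance
components are estimated by restricted maximum likelihood (quasi-Newton
search on log-variances); the normalized matrix is the input
minus the estimated (sum-to-zero constrained) library effects. Tissue- and
gene-level structure is deliberately left in the data: the downstream
differential-expression contrasts are between tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


class NormalizationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# RPKM and log2
# ---------------------------------------------------------------------------


def rpkm(
    counts: ExpressionMatrix,
    annotation: pd.DataFrame,
    mapped_reads_millions: Optional[pd.Series] = None,
) -> ExpressionMatrix:
    """Reads per kilobase of exon per million mapped reads.

    value = count / (mapped_reads_millions * length_kb). Depth defaults to
    the matrix's own column totals / 1e6 (exon-assigned reads) unless true
    mapped-read totals are supplied.
    """
    if counts.stage != "counts":
        raise ValueError(f"expected counts stage, got {counts.stage!r}")
    missing = set(counts.transcript_ids) - set(annotation.index)
    if missing:
        raise KeyError(f"no annotation for {sorted(missing)[:5]}")
    depth = (
        mapped_reads_millions
        if mapped_reads_millions is not None
        else counts.mapped_reads_millions
    )
    depth = depth.reindex(counts.sample_ids)
    zero = depth[depth <= 0]
    if len(zero):
        raise NormalizationError(f"zero mapped reads for sample {zero.index[0]!r}")
    length_kb = annotation.loc[counts.transcript_ids, "length_bp"].astype(float) / 1000.0
    values = counts.values.astype(float).div(depth, axis=1).div(length_kb, axis=0)
    out = counts.advance(values, "rpkm")
    out.mapped_reads_millions = depth
    return out


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(rpkm + offset); the offset keeps zeros finite and maps 0 -> 0
    at the default offset of 1."""
    if m.stage != "rpkm":
        raise ValueError(f"expected rpkm stage, got {m.stage!r}")
    if offset <= 0:
        raise ValueError("offset must be > 0")
    return m.advance(np.log2(m.values + offset), "log2rpkm")


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

RANDOM_EFFECTS = ("gene", "gene_x_tissue", "gene_x_animal")


@dataclass
class MixedModelFit:
    """Estimated mixed model: variance components, library solutions,
    convergence record."""

    variance_components: Dict[str, float]
    library_effects: pd.Series  # sum-to-zero across libraries
    intercept: float
    converged: bool
    n_iter: int
    history: List[Dict[str, float]] = field(default_factory=list)
    dropped_animal_interaction: bool = False


def _within_gene_designs(
    samples: pd.DataFrame, sample_ids: Sequence[str], drop_animal: bool
) -> Dict[str, np.ndarray]:
    sub = samples.loc[list(sample_ids)]
    n = len(sub)
    designs = {"gene": np.ones((n, 1))}
    designs["gene_x_tissue"] = pd.get_dummies(sub["tissue"]).to_numpy(dtype=float)
    if not drop_animal:
        designs["gene_x_animal"] = pd.get_dummies(sub["animal"]).to_numpy(dtype=float)
    return designs


def _library_design(samples: pd.DataFrame, sample_ids: Sequence[str]):
    """Intercept + sum-to-zero library contrasts."""
    sub = samples.loc[list(sample_ids)]
    libraries = sorted(sub["library"].unique())
    n = len(sub)
    X = np.ones((n, len(libraries)))
    for j, lib in enumerate(libraries[:-1]):
        X[:, j + 1] = np.where(
            sub["library"] == lib, 1.0, np.where(sub["library"] == libraries[-1], -1.0, 0.0)
        )
    return X, libraries


def fit_mixed_model(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    variance_components: Optional[Dict[str, float]] = None,
    drop_animal_interaction: bool = False,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> Tuple[MixedModelFit, ExpressionMatrix]:
    """Estimate the mixed model and return library-corrected expression.

    With a single library there is no fixed effect to remove and the input
    passes through unchanged. Supplying ``variance_components`` skips the
    REML step (the GLS library solutions are still computed under those
    components). Components driven to the boundary are reported as zero;
    failure to converge within ``max_iter`` iterations raises with the
    evaluation trace attached.
    """
    if m.stage != "log2rpkm":
        raise ValueError(f"expected log2rpkm stage, got {m.stage!r}")
    sample_ids = list(m.sample_ids)
    missing = set(sample_ids) - set(samples.index)
    if missing:
        raise KeyError(f"samples missing from sheet: {sorted(missing)}")

    X, libraries = _library_design(samples, sample_ids)
    if len(libraries) == 1:
        fit = MixedModelFit(
            variance_components={},
            library_effects=pd.Series([0.0], index=libraries),
            intercept=float(m.values.to_numpy().mean()),
            converged=True,
            n_iter=0,
            dropped_animal_interaction=drop_animal_interaction,
        )
        return fit, m.advance(m.values.copy(), "normalized")

    designs = _within_gene_designs(samples, sample_ids, drop_animal_interaction)
    Y = m.values.to_numpy(dtype=float)  # genes x samples
    n_genes, n_samp = Y.shape

    history: List[Dict[str, float]] = []
    if variance_components is None:
        theta, history, converged, n_iter = _fit_reml(
            Y, X, designs, tol=tol, max_iter=max_iter
        )
        if not converged:
            raise NormalizationError(
                f"REML did not converge in {n_iter} iterations; trace: {history[-5:]}"
            )
    else:
        theta = {k: float(variance_components.get(k, 0.0)) for k in designs}
        theta["residual"] = float(variance_components.get("residual", 1.0))
        converged, n_iter = True, 0

    V1 = _marginal_block(theta, designs, n_samp)
    W = np.linalg.inv(V1)
    M = X.T @ W @ X
    beta = np.linalg.solve(M, X.T @ W @ (Y.mean(axis=0)))
    # map sum-to-zero contrasts back to per-library effects
    effects = np.zeros(len(libraries))
    effects[:-1] = beta[1:]
    effects[-1] = -beta[1:].sum()
    lib_effects = pd.Series(effects, index=libraries)

    per_sample = samples.loc[sample_ids, "library"].map(lib_effects).to_numpy()
    normalized = m.values - per_sample[None, :]

    fit = MixedModelFit(
        variance_components=theta,
        library_effects=lib_effects,
        intercept=float(beta[0]),
        converged=converged,
        n_iter=n_iter,
        history=history,
        dropped_animal_interaction=drop_animal_interaction,
    )
    return fit, m.advance(normalized, "normalized")


def _marginal_block(theta, designs, n_samp) -> np.ndarray:
    V = theta["residual"] * np.eye(n_samp)
    for name, Z in designs.items():
        V += theta[name] * (Z @ Z.T)
    return V


def _restricted_loglik(theta, Y, X, designs):
    """REML log-likelihood (up to a constant).

    The marginal covariance is block-diagonal by gene with one common
    block, so determinants and quadratic forms reduce to that block.
    """
    n_genes, n_samp = Y.shape
    V1 = _marginal_block(theta, designs, n_samp)
    try:
        W = np.linalg.inv(V1)
    except np.linalg.LinAlgError:
        return -np.inf, None
    M = X.T @ W @ X
    beta = np.linalg.solve(M, X.T @ W @ Y.mean(axis=0))
    R = Y - beta @ X.T
    WR = R @ W.T
    sign_v, logdet_v = np.linalg.slogdet(V1)
    sign_m, logdet_m = np.linalg.slogdet(n_genes * M)
    if sign_v <= 0 or sign_m <= 0:
        return -np.inf, None
    ll = -0.5 * (n_genes * logdet_v + logdet_m + float(np.sum(WR * R)))
    return ll, beta


def _fit_reml(Y, X, designs, tol, max_iter):
    """Maximize the restricted likelihood over the variance components.

    Log-parameterized (sigma_k^2 = scale * exp(phi_k)) quasi-Newton search;
    components driven to the lower boundary are reported as 0. Sub-second
    because every evaluation is algebra on the common within-gene block.
    """
    from scipy import optimize

    names = list(designs) + ["residual"]
    var_total = max(float(Y.var()), 1e-12)
    k = len(names)
    lo, hi = np.log(1e-10), np.log(1e4)

    def unpack(phi):
        return {name: var_total * float(np.exp(p)) for name, p in zip(names, phi)}

    evals = []

    def objective(phi):
        theta = unpack(phi)
        ll, _ = _restricted_loglik(theta, Y, X, designs)
        evals.append({**theta, "loglik": ll})
        return -ll if np.isfinite(ll) else 1e12

    phi0 = np.full(k, np.log(1.0 / k))
    res = optimize.minimize(
        objective,
        phi0,
        method="L-BFGS-B",
        bounds=[(lo, hi)] * k,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    theta = unpack(res.x)
    # boundary components are zero for all practical purposes
    floor = 1e-8 * var_total
    for name in designs:
        if theta[name] < floor:
            theta[name] = 0.0
    theta["residual"] = max(theta["residual"], floor)
    return theta, evals, bool(res.success), int(res.nit)


# ---------------------------------------------------------------------------
# Henderson mixed-model equations (dense, for small problems / cross-checks)
# ---------------------------------------------------------------------------


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z_blocks: Sequence[np.ndarray],
    variance_ratios: Sequence[float],
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Solve Henderson's mixed-model equations directly.

    ``variance_ratios`` are lambda_k = sigma_e^2 / sigma_k^2 per random
    block. Returns (BLUE fixed effects, list of BLUP vectors).
    """
    Z = np.hstack(Z_blocks) if Z_blocks else np.zeros((len(y), 0))
    p = X.shape[1]
    q = Z.shape[1]
    lhs = np.zeros((p + q, p + q))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ Z
    lhs[p:, :p] = Z.T @ X
    lhs[p:, p:] = Z.T @ Z
    offset = 0
    for Zk, lam in zip(Z_blocks, variance_ratios):
        qk = Zk.shape[1]
        lhs[p + offset : p + offset + qk, p + offset : p + offset + qk] += lam * np.eye(qk)
        offset += qk
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    beta = sol[:p]
    blups = []
    offset = p
    for Zk in Z_blocks:
        blups.append(sol[offset : offset + Zk.shape[1]])
        offset += Zk.shape[1]
    return beta, blups


# ---------------------------------------------------------------------------
# PCA QC
# ---------------------------------------------------------------------------


def pca_qc(m: ExpressionMatrix, n_components: int = 3) -> Tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA for quality control.

    Centered (not scaled) PCA via SVD on the samples x transcripts matrix.
    PC signs are fixed by making the largest-magnitude transcript loading
    positive. Returns (coordinates DataFrame indexed by sample, variance
    explained per component).
    """
    if m.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    data = m.to_numpy().T  # samples x transcripts
    centered = data - data.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant expression matrix; PCA undefined")
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(S))
    total_var = float(np.sum(S**2))
    coords = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            coords[:, j] = -coords[:, j]
            Vt[j] = -Vt[j]
    var_explained = (S[:k] ** 2) / total_var
    frame = pd.DataFrame(
        coords, index=m.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, var_explained
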