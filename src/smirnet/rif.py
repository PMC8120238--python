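"""Regulatory Impact Factor (RIF) scoring of DE small RNAs.

For a pairwise tissue comparison, candidate regulators are the
differentially expressed small RNAs (miRNA / snRNA / snoRNA) and targets
the differentially expressed mRNAs of the same comparison. With e1_j, e2_j
the mean normalized expression of target j in the two conditions,
r1_ij, r2_ij the regulator-target Pearson correlations within each
condition, PIF_j = (e1_j + e2_j)(e1_j - e2_j)/2 and differential wiring
DW_ij = r1_ij - r2_ij:

    RIF1_i = (1/n) * sum_j PIF_j * DW_ij^2
    RIF2_i = (1/n) * sum_j [(e1_j r1_ij)^2 - (e2_j r2_ij)^2]

Raw scores are z-standardized across regulators within the comparison; a
regulator is significant when |z1| >= 1.96 or |z2| >= 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import SMALL_RNA_BIOTYPES
from .matrix import ExpressionMatrix
from .diffexpr import comparison_tissues, de_ids


@dataclass
class RifInputs:
    regulators: List[str]
    targets: List[str]
    e1: np.ndarray  # mean expression of targets, condition 1 (first tissue)
    e2: np.ndarray
    r1: np.ndarray  # regulators x targets correlations within condition 1
    r2: np.ndarray
    comparison: str


def build_rif_inputs(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    de_table: pd.DataFrame,
    annotation: pd.DataFrame,
    comparison: str,
    regulator_ids: Optional[Sequence[str]] = None,
) -> Optional[RifInputs]:
    """Assemble expression means and within-condition correlations.

    Condition 1 is the first-named tissue of the comparison. Regulators
    default to the comparison's DE small RNAs; an explicit
    ``regulator_ids`` list (e.g. a transcription-factor panel) overrides
    the biotype rule. Returns None (with a warning) when there are no
    candidate regulators; raises when there are no DE mRNA targets.
    """
    t1, t2 = comparison_tissues(comparison)
    g1 = [s for s in m.sample_ids if samples.loc[s, "tissue"] == t1]
    g2 = [s for s in m.sample_ids if samples.loc[s, "tissue"] == t2]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError(
            f"comparison {comparison}: need >= 3 samples per condition for "
            f"within-condition correlations (got {len(g1)}, {len(g2)})"
        )

    de_in_comp = de_ids(de_table, comparison)
    biotype = annotation["biotype"]
    targets = [
        t for t in de_in_comp if t in biotype.index and biotype[t] == "mRNA"
    ]
    if not targets:
        raise ValueError(f"comparison {comparison}: no DE mRNA targets")
    if regulator_ids is None:
        regulators = [
            t
            for t in de_in_comp
            if t in biotype.index and biotype[t] in SMALL_RNA_BIOTYPES
        ]
    else:
        regulators = [r for r in regulator_ids if r in m.transcript_ids]
    if not regulators:
        warnings.warn(f"comparison {comparison}: no candidate regulators")
        return None

    T1 = m.values.loc[targets, g1].to_numpy(dtype=float)
    T2 = m.values.loc[targets, g2].to_numpy(dtype=float)
    R1 = m.values.loc[regulators, g1].to_numpy(dtype=float)
    R2 = m.values.loc[regulators, g2].to_numpy(dtype=float)

    return RifInputs(
        regulators=regulators,
        targets=targets,
        e1=T1.mean(axis=1),
        e2=T2.mean(axis=1),
        r1=_rowwise_correlation(R1, T1),
        r2=_rowwise_correlation(R2, T2),
        comparison=comparison,
    )


def _rowwise_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between every row of A and every row of B
    (within one condition); constant rows yield r = 0."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    denom = np.outer(sa, sb)
    num = Ac @ Bc.T
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def rif_scores(inputs: RifInputs, z_threshold: float = 1.96) -> pd.DataFrame:
    """RIF1/RIF2 raw and z-standardized scores with significance flags.

    With a single regulator (or zero variance across regulators) the z
    scores are undefined: NaN is emitted with significant = False and a
    warning.
    """
    e1, e2 = inputs.e1, inputs.e2
    pif = 0.5 * (e1 + e2) * (e1 - e2)
    dw = inputs.r1 - inputs.r2
    n_de = len(inputs.targets)
    rif1 = (pif[None, :] * dw**2).sum(axis=1) / n_de
    rif2 = (
        (e1[None, :] * inputs.r1) ** 2 - (e2[None, :] * inputs.r2) ** 2
    ).sum(axis=1) / n_de

    z1 = _zscore(rif1)
    z2 = _zscore(rif2)
    significant = (np.abs(z1) >= z_threshold) | (np.abs(z2) >= z_threshold)
    significant = np.where(np.isnan(z1) & np.isnan(z2), False, significant)

    return pd.DataFrame(
        {
            "regulator_id": inputs.regulators,
            "comparison": inputs.comparison,
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "z1": z1,
            "z2": z2,
            "significant": significant,
        }
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if not np.isfinite(sd) or sd == 0:
        warnings.warn("zero variance across regulators; z-scores undefined")
        return np.full_like(np.asarray(x, dtype=float), np.nan)
    return (x - x.mean()) / sd


def run_rif(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    de_table: pd.DataFrame,
    annotation: pd.DataFrame,
    comparisons: Sequence[str],
    z_threshold: float = 1.96,
    regulator_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """RIF across comparisons; comparisons without regulators yield no rows."""
    frames = []
    for comp in comparisons:
        try:
            inputs = build_rif_inputs(
                m, samples, de_table, annotation, comp, regulator_ids
            )
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        if inputs is None:
            continue
        frames.append(rif_scores(inputs, z_threshold))
    if not frames:
        return pd.DataFrame(
            columns=[
                "regulator_id",
                "comparison",
                "rif1_raw",
                "rif2_raw",
                "z1",
                "z2",
                "significant",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def significant_regulators(rif_table: pd.DataFrame) -> List[str]:
    """Regulators significant in at least one comparison."""
    if rif_table.empty:
        return []
    return sorted(rif_table.loc[rif_table["significant"], "regulator_id"].unique())
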