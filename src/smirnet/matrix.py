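"""Stage-tagged expression matrix container.

The pipeline passes a single matrix type through its stages
(``counts -> rpkm -> log2rpkm -> normalized``); the stage tag makes it
impossible to, e.g., feed raw counts into the correlation step by accident.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

STAGES = ("counts", "rpkm", "log2rpkm", "normalized")

_ALLOWED_TRANSITIONS = {
    "counts": {"rpkm"},
    "rpkm": {"log2rpkm"},
    "log2rpkm": {"normalized"},
    "normalized": set(),
}


class ExpressionMatrix:
    """Transcripts x samples expression values at a named processing stage.

    Parameters
    ----------
    values
        DataFrame with transcript ids as index and sample ids as columns.
    stage
        One of ``counts``, ``rpkm``, ``log2rpkm``, ``normalized``.
    mapped_reads_millions
        Per-sample sequencing depth in millions of mapped reads. Defaults to
        the column sums of the counts divided by 1e6 (exon-assigned reads);
        override when true mapped-read totals are known.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        stage: str,
        mapped_reads_millions: Optional[pd.Series] = None,
    ):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if values.isna().any().any():
            raise ValueError("expression matrix contains NaN")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.values = values.astype(float) if stage != "counts" else values
        self.stage = stage
        if mapped_reads_millions is None and stage == "counts":
            mapped_reads_millions = values.sum(axis=0) / 1e6
        self.mapped_reads_millions = mapped_reads_millions

    # -- basic introspection -------------------------------------------------

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self):
        return self.values.shape

    def subset_transcripts(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown transcript ids: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.values.loc[ids], self.stage, self.mapped_reads_millions
        )

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        missing = set(ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
        mapped = (
            self.mapped_reads_millions.loc[ids]
            if self.mapped_reads_millions is not None
            else None
        )
        return ExpressionMatrix(self.values[ids], self.stage, mapped)

    def advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix at the next stage, enforcing the stage order."""
        if stage not in _ALLOWED_TRANSITIONS.get(self.stage, set()):
            raise ValueError(f"illegal stage transition {self.stage} -> {stage}")
        return ExpressionMatrix(values, stage, self.mapped_reads_millions)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        n_t, n_s = self.values.shape
        return f"ExpressionMatrix(stage={self.stage!r}, {n_t} transcripts x {n_s} samples)"
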