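"""Count-matrix container and pre-analysis hygiene.

The processing contract mirrors the screen's published order: (1) remove
guides under-represented in the pre-injection cell controls (raw counts,
strict ``< min_reads`` in at least one control replicate), (2) total
normalization scaling every sample to the mean raw column total, (3) removal
of guides with no reads in any sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class CountMatrixError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Guides x samples count table with sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Index = guide_id, columns = sample_id, nonnegative values
        (integers when raw, reals when normalized).
    genes : pandas.Series
        guide_id -> gene symbol, aligned with ``values.index``.
    sample_groups : dict
        sample_id -> group label (e.g. ``cells_500x``, ``lung_4h``,
        ``lung_19d`` or a cohort label).
    normalized : bool
        Whether :func:`total_normalize` has been applied.
    size_factors : pandas.Series or None
        Per-sample scaling factors recorded by normalization.
    """

    values: pd.DataFrame
    genes: pd.Series
    sample_groups: dict[str, str] = field(default_factory=dict)
    normalized: bool = False
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise CountMatrixError("count matrix contains negative values")
        if not self.values.index.is_unique:
            raise CountMatrixError("duplicate guide_ids in count matrix")
        self.genes = self.genes.reindex(self.values.index)
        if self.genes.isna().any():
            missing = self.genes.index[self.genes.isna()].tolist()[:5]
            raise CountMatrixError(f"guides without gene annotation: {missing}")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups.get(s) == group]

    def subset_guides(self, keep: pd.Index | list[str]) -> "CountMatrix":
        return CountMatrix(
            self.values.loc[keep],
            self.genes.loc[keep],
            dict(self.sample_groups),
            self.normalized,
            self.size_factors,
        )

    # -- I/O ------------------------------------------------------------
    # TSV dialect: first column sgRNA, second gene, then one column per sample.
    def write_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", self.genes)
        out.index.name = "sgRNA"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        sample_groups: dict[str, str] | None = None,
        normalized: bool = False,
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sgRNA")
        if "gene" not in df.columns:
            raise CountMatrixError(f"{path}: missing 'gene' column")
        genes = df["gene"]
        values = df.drop(columns="gene")
        return cls(values, genes, sample_groups or {}, normalized=normalized)


def filter_by_control_minimum(
    cm: CountMatrix, control_ids: list[str], min_reads: int = 30
) -> tuple[CountMatrix, list[str]]:
    """Remove guides with fewer than ``min_reads`` raw reads in at least one
    control sample. Returns (filtered matrix, removed guide_ids).

    The boundary is strict: a guide with exactly ``min_reads`` in every
    control is retained.
    """
    if cm.normalized:
        raise CountMatrixError("control-minimum filter must run on raw counts")
    if not control_ids:
        raise CountMatrixError("control_ids must be non-empty")
    missing = [s for s in control_ids if s not in cm.values.columns]
    if missing:
        raise CountMatrixError(f"control samples absent from matrix: {missing}")
    ctrl = cm.values[control_ids]
    removed_mask = (ctrl < min_reads).any(axis=1)
    removed = list(cm.values.index[removed_mask])
    return cm.subset_guides(cm.values.index[~removed_mask]), removed


def total_normalize(cm: CountMatrix) -> CountMatrix:
    """Total-count normalization: scale each column by
    (mean raw column total) / (its own total), so every normalized column
    sums to the mean raw total. Size factors are recorded on the result."""
    if cm.normalized:
        raise CountMatrixError("matrix is already normalized")
    totals = cm.values.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise CountMatrixError(f"zero-total sample(s): {list(zero.index)}")
    mean_total = totals.mean()
    factors = mean_total / totals
    values = cm.values.astype(float) * factors
    return CountMatrix(values, cm.genes, dict(cm.sample_groups), normalized=True, size_factors=factors)


def drop_absent_guides(cm: CountMatrix) -> tuple[CountMatrix, list[str]]:
    """Remove guides whose value is zero in every sample."""
    absent_mask = (cm.values == 0).all(axis=1)
    removed = list(cm.values.index[absent_mask])
    return cm.subset_guides(cm.values.index[~absent_mask]), removed
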