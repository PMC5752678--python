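"""Expression-panel normalization and differential expression.

Count panels (~100 probes with designated positive-control and housekeeping
probes) are normalized in two stages — positive-control scaling within each
sample, then scaling by each sample's housekeeping geometric mean — and
compared between groups as log2 fold changes of normalized group means with
per-gene Welch t p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DataError

__all__ = [
    "HOUSEKEEPING_GENES",
    "ExpressionMatrix",
    "normalize_positive",
    "normalize_housekeeping",
    "differential_expression",
    "de_table",
]

# the eight housekeeping probes of the striatal panel
HOUSEKEEPING_GENES = (
    "Gins1",
    "Myh15",
    "Pank2",
    "Poc1b",
    "Pum2",
    "Slc25a15",
    "Ssrp1",
    "Utp3",
)


@dataclass
class ExpressionMatrix:
    """Gene x sample count matrix with gene classes and sample groups.

    ``gene_class`` maps each gene to one of ``endogenous``, ``housekeeping``,
    ``positive`` or ``negative``; ``sample_group`` maps each sample to its
    treatment group.
    """

    counts: pd.DataFrame  # genes x samples
    gene_class: pd.Series
    sample_group: pd.Series
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        if not self.gene_class.index.equals(self.counts.index):
            raise DataError("gene_class index must match the count matrix genes")
        if not self.sample_group.index.equals(self.counts.columns):
            raise DataError("sample_group index must match the count matrix samples")

    def genes_of_class(self, cls: str) -> pd.Index:
        return self.gene_class.index[self.gene_class == cls]

    @property
    def housekeeping_ids(self) -> pd.Index:
        return self.genes_of_class("housekeeping")

    def copy_with(self, counts: pd.DataFrame, normalized: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts,
            self.gene_class,
            self.sample_group,
            self.normalized if normalized is None else normalized,
        )


def _geometric_mean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.log(values).mean(axis=axis))


def normalize_positive(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to the internal positive-control standards.

    Each sample is multiplied by (cohort geometric mean of positive-control
    sums) / (that sample's positive-control sum), removing per-sample assay
    efficiency differences.
    """
    pos = matrix.genes_of_class("positive")
    if len(pos) == 0:
        raise DataError("no positive-control genes designated")
    pos_sum = matrix.counts.loc[pos].sum(axis=0)
    if (pos_sum <= 0).any():
        bad = pos_sum.index[pos_sum <= 0].tolist()
        raise DataError(f"zero positive-control signal in sample(s) {bad}")
    factors = _geometric_mean(pos_sum.to_numpy()) / pos_sum
    return matrix.copy_with(matrix.counts.mul(factors, axis=1))


def normalize_housekeeping(
    matrix: ExpressionMatrix, hk_ids=None, target_level: float = 1000.0
) -> ExpressionMatrix:
    """Scale each sample by its housekeeping geometric mean.

    Each sample is multiplied by ``target_level / (its housekeeping
    geometric mean)``, so that after normalization the housekeeping
    geometric mean equals ``target_level`` in every sample.  With a fixed
    target the operation is idempotent and exactly per-sample
    scale-invariant: a sample whose raw counts were multiplied by any
    constant is fully restored.  (A cohort-derived target — e.g. the mean of
    the housekeeping geometric means — would shift with the very sample
    being corrected and break both properties; ``target_level`` is therefore
    a fixed nominal count level, and its choice cancels out of all fold
    changes and test statistics.)
    """
    hk = pd.Index(hk_ids) if hk_ids is not None else matrix.housekeeping_ids
    missing = hk.difference(matrix.counts.index)
    if len(missing):
        raise DataError(f"housekeeping genes absent from matrix: {missing.tolist()}")
    hk_counts = matrix.counts.loc[hk]
    zero = hk_counts.le(0)
    if zero.to_numpy().any():
        g, s = np.argwhere(zero.to_numpy())[0]
        raise DataError(
            f"non-positive housekeeping count: gene {hk[g]!r}, sample "
            f"{matrix.counts.columns[s]!r}"
        )
    gm = pd.Series(_geometric_mean(hk_counts.to_numpy(), axis=0), index=matrix.counts.columns)
    factors = target_level / gm
    return matrix.copy_with(matrix.counts.mul(factors, axis=1), normalized=True)


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str = "ad_lib",
    group_b: str = "TRF",
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential expression between two groups.

    ``log2_fold_change = log2(mean_b / mean_a)`` on normalized values, with
    a per-gene two-sided Welch t p-value and its -log10.  Genes with a zero
    group mean get an undefined fold change and are excluded from ranking.
    The significance flag uses ``p_threshold`` (default raw p < 0.05, no
    multiple-testing correction; see ``bh_fdr`` column for the adjusted
    alternative).
    """
    groups = matrix.sample_group
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise DataError("each group needs at least two samples")
    a = matrix.counts[a_cols].to_numpy(dtype=float)
    b = matrix.counts[b_cols].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_b / mean_a)
    t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    defined = (mean_a > 0) & (mean_b > 0) & np.isfinite(p)
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p)
    out = pd.DataFrame(
        {
            "gene_id": matrix.counts.index,
            "gene_class": matrix.gene_class.to_numpy(),
            "log2_fold_change": lfc,
            "p_value": p,
            "neg_log10_p": neg_log10_p,
            "direction": np.where(lfc >= 0, "up", "down"),
            "significant": (p < p_threshold) & defined,
            "defined": defined,
        }
    ).reset_index(drop=True)
    # BH-FDR over defined endogenous genes (optional adjusted column)
    endo = out["defined"] & (out["gene_class"] == "endogenous")
    out["bh_fdr"] = np.nan
    if endo.any():
        out.loc[endo, "bh_fdr"] = _bh_adjust(out.loc[endo, "p_value"].to_numpy())
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_table(results: pd.DataFrame) -> pd.DataFrame:
    """Ranked differential-expression report over endogenous genes.

    Control probes and genes with undefined fold change are dropped; rows
    sort ascending by p, ties broken by |log2FC| descending then gene id.
    """
    keep = results[(results["gene_class"] == "endogenous") & results["defined"]].copy()
    keep["abs_lfc"] = keep["log2_fold_change"].abs()
    keep = keep.sort_values(
        ["p_value", "abs_lfc", "gene_id"], ascending=[True, False, True], kind="stable"
    ).drop(columns=["abs_lfc", "defined", "gene_class"])
    return keep.reset_index(drop=True)


def read_expression_csv(counts_path, annotation_path) -> ExpressionMatrix:
    """Read a panel from a counts CSV (genes x samples, first column
    ``gene_id``) and an annotation CSV with ``sample,group`` and
    ``gene_id,gene_class`` columns (either long table or both blocks)."""
    counts = pd.read_csv(counts_path, index_col=0)
    annot = pd.read_csv(annotation_path)
    if {"sample", "group"}.issubset(annot.columns):
        sg = annot.dropna(subset=["sample"]).set_index("sample")["group"]
    else:
        raise DataError("annotation needs 'sample' and 'group' columns")
    if {"gene_id", "gene_class"}.issubset(annot.columns):
        gc = annot.dropna(subset=["gene_id"]).set_index("gene_id")["gene_class"]
    else:
        raise DataError("annotation needs 'gene_id' and 'gene_class' columns")
    return ExpressionMatrix(
        counts=counts,
        gene_class=gc.reindex(counts.index),
        sample_group=sg.reindex(counts.columns),
    )


def write_expression_csv(matrix: ExpressionMatrix, counts_path, annotation_path) -> None:
    matrix.counts.to_csv(counts_path)
    genes = pd.DataFrame(
        {"gene_id": matrix.counts.index, "gene_class": matrix.gene_class.to_numpy(),
         "sample": np.nan, "group": np.nan}
    )
    samples = pd.DataFrame(
        {"gene_id": np.nan, "gene_class": np.nan,
         "sample": matrix.counts.columns, "group": matrix.sample_group.to_numpy()}
    )
    pd.concat([genes, samples], ignore_index=True).to_csv(annotation_path, index=False)
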