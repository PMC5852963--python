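"""Expression normalization and summarization.

Two normalization routes mirror the two data sources the pipeline targets:

* tumor RNA-seq quantified as RSEM: per-sample median normalization
  followed by per-gene averaging within each cancer cohort;
* organ RNA-seq exon coverage: RPKM, then log2(RPKM + pseudocount), then a
  per-organ Z-score so expression is comparable across organs.

An :class:`ExpressionMatrix` carries an explicit normalization state so the
two routes cannot be mixed accidentally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

STATES = ("RAW", "MEDIAN_NORMALIZED", "RPKM", "LOG2", "ZSCORE")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values plus their normalization state."""

    values: pd.DataFrame
    state: str = "RAW"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state in ("RAW", "MEDIAN_NORMALIZED", "RPKM"):
            if (self.values.values < 0).any():
                raise ValueError(f"negative values not allowed in state {self.state}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its median over genes with positive values.

    After normalization the per-sample median over the originally positive
    genes is exactly 1, so the operation is idempotent.  A sample with no
    positive values cannot be normalized and raises, naming the sample.
    """
    if matrix.state not in ("RAW", "MEDIAN_NORMALIZED"):
        raise ValueError(f"cannot median-normalize a {matrix.state} matrix")
    values = matrix.values.astype(float)
    out = {}
    for sample in values.columns:
        col = values[sample]
        positive = col[col > 0]
        if positive.empty:
            raise ValueError(f"sample {sample!r} has no positive values")
        out[sample] = col / positive.median()
    return ExpressionMatrix(pd.DataFrame(out, index=values.index), "MEDIAN_NORMALIZED")


def mean_per_gene(
    matrix: ExpressionMatrix, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Arithmetic mean per gene within each sample group (cohort or organ)."""
    groups = pd.Series(dict(groups))
    missing = [s for s in matrix.samples if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    return matrix.values.T.groupby(groups.reindex(matrix.samples)).mean().T


def rpkm(read_count, feature_length_bp, total_mapped_reads):
    """Reads per kilobase of feature per million mapped reads."""
    read_count = np.asarray(read_count, dtype=float)
    feature_length_bp = np.asarray(feature_length_bp, dtype=float)
    total_mapped_reads = np.asarray(total_mapped_reads, dtype=float)
    if np.any(feature_length_bp <= 0):
        raise ValueError("feature_length_bp must be > 0")
    if np.any(total_mapped_reads <= 0):
        raise ValueError("total_mapped_reads must be > 0")
    value = read_count / ((feature_length_bp / 1e3) * (total_mapped_reads / 1e6))
    if value.ndim == 0:
        return float(value)
    return value


def rpkm_from_exons(
    exons: pd.DataFrame, library_sizes: Mapping[str, int] | None = None
) -> ExpressionMatrix:
    """Per-gene RPKM from exon coverage rows.

    ``exons`` columns: gene, exon_id, exon_length_bp, sample, read_count.
    Per gene, counts are summed over exons and divided by the summed exon
    length; the library size defaults to the per-sample total read count.
    """
    required = {"gene", "exon_id", "exon_length_bp", "sample", "read_count"}
    missing = required - set(exons.columns)
    if missing:
        raise ValueError(f"missing exon-table columns: {sorted(missing)}")
    if library_sizes is None:
        library_sizes = exons.groupby("sample")["read_count"].sum().to_dict()
    counts = exons.pivot_table(
        index="gene", columns="sample", values="read_count", aggfunc="sum", fill_value=0
    )
    # exon lengths are a property of the gene model, not of the sample
    lengths = exons.drop_duplicates(["gene", "exon_id"]).groupby("gene")[
        "exon_length_bp"
    ].sum()
    lib = pd.Series({s: library_sizes[s] for s in counts.columns}, dtype=float)
    values = rpkm(
        counts.values,
        lengths.reindex(counts.index).values[:, None],
        lib.values[None, :],
    )
    return ExpressionMatrix(pd.DataFrame(values, counts.index, counts.columns), "RPKM")


def log2_zscore(
    matrix: ExpressionMatrix, pseudocount: float = 1.0, ddof: int = 1
) -> ExpressionMatrix:
    """log2(value + pseudocount) then per-column (per-organ) Z-score.

    Each output column has mean 0 and sample standard deviation 1 (ddof=1).
    A zero-variance column raises.  Applying the operation to an already
    Z-scored matrix re-standardizes it, which is the identity.
    """
    values = matrix.values.astype(float)
    if matrix.state in ("RAW", "RPKM"):
        values = np.log2(values + pseudocount)
    elif matrix.state not in ("LOG2", "ZSCORE"):
        raise ValueError(f"cannot z-score a {matrix.state} matrix")
    sd = values.std(axis=0, ddof=ddof)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance columns: {flat}")
    z = (values - values.mean(axis=0)) / sd
    return ExpressionMatrix(z, "ZSCORE")


def set_expression_vectors(
    summarized: pd.DataFrame, labels: pd.Series
) -> dict[str, dict[str, np.ndarray]]:
    """Split a gene × group summary into per-set value vectors per group."""
    out: dict[str, dict[str, np.ndarray]] = {}
    labels = labels.reindex(summarized.index)
    for group in summarized.columns:
        out[group] = {
            lab: summarized.loc[labels == lab, group].dropna().to_numpy()
            for lab in labels.dropna().unique()
        }
    return out
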