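"""Somatic-mutation profiling over MAF-like tables.

Mutation tables are held as pandas DataFrames with four canonical columns:
``gene``, ``sample``, ``cohort``, ``variant_class``.  Variant classes use a
closed ten-value vocabulary; silent and non-coding-RNA records are the ones
removed by the non-silent filter because they leave the protein unchanged.

The per-gene mutation-rate statistic is (total mutations, silent included,
per case) divided by gene length in bp — i.e. mutations per base pair per
case for one gene in one cohort.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .geneset import GeneSetPartition, normalize_symbol

#: closed variant-class vocabulary
VARIANT_CLASSES = (
    "MISSENSE",
    "NONSENSE",
    "SILENT",
    "IN_FRAME_INS",
    "FRAME_SHIFT_INS",
    "FRAME_SHIFT_DEL",
    "IN_FRAME_DEL",
    "SPLICE_SITE",
    "NONSTOP",
    "RNA",
)

#: protein-altering classes kept by the non-silent filter
NON_SILENT = frozenset(
    (
        "MISSENSE",
        "NONSENSE",
        "IN_FRAME_INS",
        "FRAME_SHIFT_INS",
        "FRAME_SHIFT_DEL",
        "IN_FRAME_DEL",
        "SPLICE_SITE",
        "NONSTOP",
    )
)

#: standard MAF Variant_Classification tokens -> canonical vocabulary
MAF_CLASS_MAP = {
    "Missense_Mutation": "MISSENSE",
    "Nonsense_Mutation": "NONSENSE",
    "Silent": "SILENT",
    "In_Frame_Ins": "IN_FRAME_INS",
    "Frame_Shift_Ins": "FRAME_SHIFT_INS",
    "Frame_Shift_Del": "FRAME_SHIFT_DEL",
    "In_Frame_Del": "IN_FRAME_DEL",
    "Splice_Site": "SPLICE_SITE",
    "Nonstop_Mutation": "NONSTOP",
    "RNA": "RNA",
}

#: default potential functional-impact map (configurable in classify_functional_impact)
DEFAULT_IMPACT_MAP = {
    "NONSENSE": "LOF_POTENTIAL",
    "FRAME_SHIFT_INS": "LOF_POTENTIAL",
    "FRAME_SHIFT_DEL": "LOF_POTENTIAL",
    "SPLICE_SITE": "LOF_POTENTIAL",
    "NONSTOP": "LOF_POTENTIAL",
    "MISSENSE": "GOF_POTENTIAL",
    "IN_FRAME_INS": "GOF_POTENTIAL",
    "IN_FRAME_DEL": "GOF_POTENTIAL",
    "SILENT": "EXCLUDED",
    "RNA": "EXCLUDED",
}

_MAF_RENAME = {
    "Hugo_Symbol": "gene",
    "Tumor_Sample_Barcode": "sample",
    "Variant_Classification": "variant_class",
}

COLUMNS = ["gene", "sample", "cohort", "variant_class"]


def read_mutation_table(
    path,
    cohort: str | None = None,
    cohort_column: str | None = None,
    dedup: bool = False,
) -> pd.DataFrame:
    """Read a MAF or minimal 4-column TSV into the canonical mutation frame.

    Standard MAF column names (Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification) and the canonical names are both accepted.  The
    cohort comes from ``cohort_column`` (default: a ``cohort`` /
    ``cancer_type`` column if present) or the constant ``cohort``.  Records
    with Variant_Classification tokens outside the vocabulary are skipped;
    their count is kept in ``df.attrs["skipped_classes"]``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.rename(columns=_MAF_RENAME)
    if cohort_column is not None:
        if cohort_column not in df.columns:
            raise ValueError(f"missing cohort column {cohort_column!r}")
        df = df.rename(columns={cohort_column: "cohort"})
    elif "cohort" not in df.columns and "cancer_type" in df.columns:
        df = df.rename(columns={"cancer_type": "cohort"})
    if "cohort" not in df.columns:
        if cohort is None:
            raise ValueError(
                "no cohort column found and no constant cohort label given"
            )
        df["cohort"] = cohort
    for col in ("gene", "sample", "variant_class"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    df["gene"] = df["gene"].map(normalize_symbol)
    mapped = df["variant_class"].map(
        lambda t: MAF_CLASS_MAP.get(t, t if t in VARIANT_CLASSES else None)
    )
    skipped = mapped.isna()
    skipped_tokens = df.loc[skipped, "variant_class"].value_counts().to_dict()
    if skipped.any():
        warnings.warn(
            f"skipped {int(skipped.sum())} records with unmapped "
            f"variant classes: {skipped_tokens}"
        )
    df = df.loc[~skipped, ["gene", "sample", "cohort"]].assign(
        variant_class=mapped[~skipped]
    )
    if dedup:
        df = df.drop_duplicates()
    df = df.reset_index(drop=True)
    df.attrs["skipped_classes"] = skipped_tokens
    df.attrs["n_skipped"] = int(skipped.sum())
    return df


def filter_non_silent(records: pd.DataFrame) -> pd.DataFrame:
    """Drop silent and non-coding-RNA records; keep the eight protein-altering
    classes in their original order."""
    keep = records["variant_class"].isin(NON_SILENT)
    return records.loc[keep].reset_index(drop=True)


def count_per_gene(
    records: pd.DataFrame,
    partition: GeneSetPartition,
    scope: str = "ALL",
) -> pd.Series:
    """Mutation count per partition gene, for one cohort or all combined.

    Every partition gene appears in the result (zero when unmutated);
    records for genes outside the partition are ignored.
    """
    if scope != "ALL":
        records = records[records["cohort"] == scope]
    counts = records.groupby("gene").size()
    return counts.reindex(partition.genes, fill_value=0).astype(int).rename("count")


def mutation_rate(total_count, n_cases, length_bp):
    """Per-gene mutation rate: (mutations per case) per base pair.

    Accepts scalars or aligned array-likes; total_count should include both
    silent and non-silent mutations.
    """
    total_count = np.asarray(total_count, dtype=float)
    n_cases = np.asarray(n_cases, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(n_cases <= 0):
        raise ValueError("n_cases must be > 0")
    if np.any(length_bp <= 0):
        raise ValueError("length_bp must be > 0")
    rate = (total_count / n_cases) / length_bp
    if rate.ndim == 0:
        return float(rate)
    return rate


def classify_functional_impact(
    variant_class: str | Iterable[str],
    impact_map: Mapping[str, str] | None = None,
):
    """Map variant classes to potential functional impact.

    Truncating classes (nonsense, frameshift, splice-site, nonstop) default
    to LOF_POTENTIAL; protein-preserving-length classes (missense, in-frame
    indels) to GOF_POTENTIAL; silent/RNA are EXCLUDED.  The mapping is
    user-overridable.
    """
    impact_map = dict(DEFAULT_IMPACT_MAP if impact_map is None else impact_map)
    if isinstance(variant_class, str):
        return impact_map[variant_class]
    seq = pd.Series(list(variant_class))
    return seq.map(impact_map).tolist()


def build_profiles(
    records: pd.DataFrame,
    partition: GeneSetPartition,
    cohort_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene per-cohort mutation profiles.

    ``records`` must be the unfiltered table (silent included): the rate uses
    total silent+non-silent counts while ``n_nonsilent`` applies the
    non-silent filter.  RNA records enter neither count.  ``cohort_sizes``
    overrides the per-cohort case number (default: distinct sample ids seen
    in that cohort's records).
    """
    cohorts = sorted(records["cohort"].unique())
    if cohort_sizes is None:
        cohort_sizes = records.groupby("cohort")["sample"].nunique().to_dict()
    missing = [c for c in cohorts if c not in cohort_sizes]
    if missing:
        raise ValueError(f"no case number for cohorts: {missing}")
    labels = partition.labels()
    lengths = partition.lengths()
    nonsilent = filter_non_silent(records)
    total = records[records["variant_class"] != "RNA"]
    rows = []
    for cohort in cohorts:
        n_cases = int(cohort_sizes[cohort])
        ns = count_per_gene(nonsilent, partition, scope=cohort)
        tot = count_per_gene(total, partition, scope=cohort)
        frame = pd.DataFrame(
            {
                "gene": ns.index,
                "set_label": labels.reindex(ns.index).values,
                "cohort": cohort,
                "n_nonsilent": ns.values,
                "n_total": tot.values,
                "n_cases": n_cases,
                "length_bp": lengths.reindex(ns.index).values,
            }
        )
        frame["rate"] = mutation_rate(
            frame["n_total"], frame["n_cases"], frame["length_bp"]
        )
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)
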