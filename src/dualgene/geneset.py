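"""Assembly of the four disjoint cancer gene sets.

Genes curated as oncogenes in one database and as tumor suppressors in
another are *candidate* dual-role genes; only the literature-curated subset
is labelled POTSF (proto-oncogene with tumor-suppressor function).  The
remaining genes fall into ONC (oncogene only), TSG (tumor suppressor only)
or NCRG (non-cancer-related).  Candidates that were never curated stay
UNRESOLVED and are excluded from every comparison set by default.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

#: the four primary comparison sets, in canonical display order
SET_LABELS = ("POTSF", "ONC", "TSG", "NCRG")
#: label for overlap candidates without literature curation
UNRESOLVED = "UNRESOLVED"
#: functional classes of POTSF genes
POTSF_CLASSES = ("TF", "KINASE", "OTHER")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-stripped, uppercase."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the comparison universe.

    ``length_bp`` is the coding/exonic length used as the mutation-rate
    denominator; it defaults to 1 when a list supplies no length so that a
    partition can be built from bare symbol lists.
    """

    gene_id: str
    length_bp: int = 1
    set_label: str = "NCRG"
    potsf_class: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be > 0 for {self.gene_id!r}")
        if self.set_label not in SET_LABELS + (UNRESOLVED,):
            raise ValueError(f"unknown set_label {self.set_label!r}")
        if (self.set_label == "POTSF") != (self.potsf_class is not None):
            raise ValueError(
                f"potsf_class must be set iff set_label == 'POTSF' ({self.gene_id!r})"
            )
        if self.potsf_class is not None and self.potsf_class not in POTSF_CLASSES:
            raise ValueError(f"unknown potsf_class {self.potsf_class!r}")


@dataclass
class GeneSetPartition:
    """Disjoint assignment of every universe gene to exactly one label.

    ``unresolved_policy`` controls what :meth:`members` does with UNRESOLVED
    overlap candidates: ``"exclude"`` (default) keeps them out of all four
    comparison sets; ``"share"`` returns them in both ONC and TSG.
    """

    records: dict[str, GeneRecord]
    unresolved_policy: str = "exclude"
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unresolved_policy not in ("exclude", "share"):
            raise ValueError(f"unknown unresolved_policy {self.unresolved_policy!r}")

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(r.set_label for r in self.records.values())
        return {lab: c.get(lab, 0) for lab in SET_LABELS + (UNRESOLVED,)}

    def members(self, label: str) -> list[str]:
        """Sorted gene symbols belonging to one comparison set."""
        out = [g for g, r in self.records.items() if r.set_label == label]
        if self.unresolved_policy == "share" and label in ("ONC", "TSG"):
            out += [g for g, r in self.records.items() if r.set_label == UNRESOLVED]
        return sorted(out)

    def set_label(self, gene: str) -> str:
        return self.records[normalize_symbol(gene)].set_label

    def length(self, gene: str) -> int:
        return self.records[normalize_symbol(gene)].length_bp

    @property
    def genes(self) -> list[str]:
        return sorted(self.records)

    def lengths(self) -> pd.Series:
        return pd.Series(
            {g: r.length_bp for g, r in self.records.items()}, name="length_bp"
        ).sort_index()

    def labels(self) -> pd.Series:
        return pd.Series(
            {g: r.set_label for g, r in self.records.items()}, name="set_label"
        ).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": r.gene_id,
                "length_bp": r.length_bp,
                "set_label": r.set_label,
                "potsf_class": r.potsf_class or "NA",
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


@dataclass(frozen=True)
class AnnotationTally:
    """Share of one cancer type (or tissue category) among all gene-item pairs."""

    item_label: str
    gene_count: int
    percentage: float


def load_gene_list(path) -> dict[str, int | None]:
    """Read a gene list: one symbol per line, optional TSV length column.

    Lines starting with ``#`` are comments.  Symbols are case-normalized.
    """
    genes: dict[str, int | None] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sym = normalize_symbol(parts[0])
            length = int(parts[1]) if len(parts) > 1 and parts[1] else None
            genes[sym] = length
    return genes


def intersect_candidates(
    onc_list: Iterable[str], tsg_list: Iterable[str]
) -> list[str]:
    """Overlap of the oncogene and tumor-suppressor lists — the dual-role candidates.

    Returns the sorted set intersection after symbol normalization.  An empty
    input list is an error; an empty *intersection* only warns.
    """
    onc = {normalize_symbol(g) for g in onc_list}
    tsg = {normalize_symbol(g) for g in tsg_list}
    if not onc:
        raise ValueError("oncogene list is empty")
    if not tsg:
        raise ValueError("tumor-suppressor list is empty")
    shared = sorted(onc & tsg)
    if not shared:
        warnings.warn("oncogene and tumor-suppressor lists share no genes")
    return shared


def partition_universe(
    universe: Mapping[str, int | None] | Iterable[str],
    onc_list: Iterable[str],
    tsg_list: Iterable[str],
    curated_potsf: Iterable[str],
    class_map: Mapping[str, str] | None = None,
    unresolved_policy: str = "exclude",
) -> GeneSetPartition:
    """Assign every universe gene to POTSF / ONC / TSG / NCRG / UNRESOLVED.

    Curated POTSF symbols must be a subset of the ONC∩TSG overlap; violations
    raise with the offending symbols listed.  ONC/TSG list entries missing
    from the universe are skipped with a warning (counts kept on the result).
    """
    if not isinstance(universe, Mapping):
        universe = {g: None for g in universe}
    lengths = {normalize_symbol(g): l for g, l in universe.items()}
    onc = {normalize_symbol(g) for g in onc_list}
    tsg = {normalize_symbol(g) for g in tsg_list}
    curated = {normalize_symbol(g) for g in curated_potsf}
    overlap = onc & tsg
    rogue = sorted(curated - overlap)
    if rogue:
        raise ValueError(
            "curated POTSF genes outside the oncogene/TSG overlap: "
            + ", ".join(rogue)
        )
    skipped = {
        "onc_not_in_universe": len(onc - lengths.keys()),
        "tsg_not_in_universe": len(tsg - lengths.keys()),
    }
    if skipped["onc_not_in_universe"] or skipped["tsg_not_in_universe"]:
        warnings.warn(
            f"{skipped['onc_not_in_universe']} oncogene and "
            f"{skipped['tsg_not_in_universe']} tumor-suppressor list entries "
            "are absent from the universe and were skipped"
        )

    records: dict[str, GeneRecord] = {}
    for gene, length in lengths.items():
        if gene in curated:
            label = "POTSF"
        elif gene in overlap:
            label = UNRESOLVED
        elif gene in onc:
            label = "ONC"
        elif gene in tsg:
            label = "TSG"
        else:
            label = "NCRG"
        potsf_class = None
        if label == "POTSF":
            potsf_class = (class_map or {}).get(gene, "OTHER")
        records[gene] = GeneRecord(
            gene_id=gene,
            length_bp=length if length else 1,
            set_label=label,
            potsf_class=potsf_class,
        )
    return GeneSetPartition(records, unresolved_policy=unresolved_policy, skipped=skipped)


def classify_potsf(
    potsf_genes: Iterable[str], class_map: Mapping[str, str]
) -> dict[str, int]:
    """Count TF / KINASE / OTHER among the curated dual-role genes.

    Genes absent from ``class_map`` fall into OTHER with a warning; the
    counts always sum to the number of input genes.
    """
    class_map = {normalize_symbol(g): c for g, c in class_map.items()}
    counts = {c: 0 for c in POTSF_CLASSES}
    missing = []
    for gene in {normalize_symbol(g) for g in potsf_genes}:
        cls = class_map.get(gene)
        if cls is None:
            missing.append(gene)
            cls = "OTHER"
        if cls not in POTSF_CLASSES:
            raise ValueError(f"unknown class {cls!r} for {gene}")
        counts[cls] += 1
    if missing:
        warnings.warn(
            f"{len(missing)} POTSF genes missing from class map, counted as OTHER: "
            + ", ".join(sorted(missing))
        )
    return counts


def tally_associations(
    pairs: Iterable[tuple[str, str]],
) -> tuple[dict[str, int], list[AnnotationTally]]:
    """Per-gene association counts and per-item percentage tallies.

    ``pairs`` are (gene, item) associations, e.g. gene-to-cancer-type; they
    are deduplicated before counting.  Percentages are item pair counts over
    all pairs, returned in descending order (ties broken lexicographically).
    """
    uniq = {(normalize_symbol(g), item.strip()) for g, item in pairs}
    per_gene: Counter[str] = Counter(g for g, _ in uniq)
    per_item: Counter[str] = Counter(item for _, item in uniq)
    item_genes: dict[str, set[str]] = {}
    for g, item in uniq:
        item_genes.setdefault(item, set()).add(g)
    total = sum(per_item.values())
    tallies = [
        AnnotationTally(
            item_label=item,
            gene_count=len(item_genes[item]),
            percentage=100.0 * n / total,
        )
        for item, n in per_item.items()
    ]
    tallies.sort(key=lambda t: (-t.percentage, t.item_label))
    return dict(per_gene), tallies


def load_table1() -> pd.DataFrame:
    """Packaged curated POTSF table: ``gene_id`` and ``potsf_class`` columns."""
    src = resources.files("dualgene.data").joinpath("table1_potsf.tsv")
    with resources.as_file(src) as path:
        return pd.read_csv(path, sep="\t", comment="#")
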