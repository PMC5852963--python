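"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the study's four data layers at configurable scale:

* a gene universe partitioned into POTSF / ONC / TSG / NCRG with log-normal
  coding lengths;
* a MAF-like somatic mutation table with per-gene Poisson counts whose
  means scale with gene length, cohort size and a set-specific rate
  multiplier, and variant classes drawn from a categorical distribution;
* log-normal expression matrices with set-specific log2 location shifts;
* a hub-biased growth interactome in which each new node attaches to
  ``m`` existing nodes with probability ∝ (degree + 1) × set
  attractiveness (the +1 offset lets isolated early nodes be chosen);
* codon-pair sequences diverged at a controlled dN/dS (ω).

Default effect sizes mirror the study's reported contrasts: mutation-rate
multipliers 3.0 / 2.5 / 1.05 / 1.0 for POTSF / ONC / TSG / NCRG (the ratios
of the reported per-gene non-silent mutation means 70 / 58 / 24 / 23),
POTSF network attractiveness ×4 (hub bias), and a TSG-high expression
profile as seen in normal organs.  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from .geneset import GeneRecord, GeneSetPartition, SET_LABELS
from .dnds import SENSE_CODONS, STOP_CODONS, _CODE
from .expression import ExpressionMatrix
from . import mutations as mut

#: printed per-class mutation counts of the source cohort (their sum exceeds
#: the stated 617,354 total; used only as relative class frequencies)
CLASS_COUNTS = {
    "MISSENSE": 416_847,
    "SILENT": 134_635,
    "NONSENSE": 39_869,
    "FRAME_SHIFT_DEL": 10_743,
    "RNA": 10_659,
    "SPLICE_SITE": 10_190,
    "FRAME_SHIFT_INS": 5_134,
    "IN_FRAME_DEL": 3_590,
    "IN_FRAME_INS": 916,
    "NONSTOP": 784,
}

#: fixture totals pinned to the source cohort's stated bookkeeping
FIXTURE_TOTAL = 617_354
FIXTURE_SILENT = 134_635
FIXTURE_RNA = 10_659

#: published per-cohort RNA-seq sample counts (COADREAD merges colon+rectal)
DEFAULT_COHORTS = {
    "BLCA": 129,
    "BRCA": 817,
    "COADREAD": 382,
    "GBM": 166,
    "HNSC": 279,
    "KIRC": 469,
    "LAML": 173,
    "LUAD": 230,
    "LUSC": 501,
    "OV": 307,
    "UCEC": 333,
}


def _default_class_probs() -> dict[str, float]:
    total = sum(CLASS_COUNTS.values())
    return {c: CLASS_COUNTS[c] / total for c in mut.VARIANT_CLASSES}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    ``base_rate`` is mutations per bp per case for an NCRG gene; the default
    6e-6 reproduces the source cohort's per-gene scale (~29.5 mutations per
    gene over 3281 cases and ~1.5 kb of coding sequence).
    """

    n_genes: dict[str, int] = field(
        default_factory=lambda: {"POTSF": 83, "ONC": 1320, "TSG": 952, "NCRG": 1000}
    )
    length_mu_log: float = float(np.log(1500.0))
    length_sigma_log: float = 0.6
    cohorts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    base_rate: float = 6e-6
    rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {"POTSF": 3.0, "ONC": 2.5, "TSG": 1.05, "NCRG": 1.0}
    )
    class_probs: dict[str, float] = field(default_factory=_default_class_probs)
    expr_location: dict[str, float] = field(
        default_factory=lambda: {"POTSF": 0.8, "ONC": 0.0, "TSG": 1.0, "NCRG": 0.0}
    )
    expr_sigma: float = 2.0
    expr_samples: int = 50
    network_m: int = 2
    attractiveness: dict[str, float] = field(
        default_factory=lambda: {"POTSF": 4.0, "ONC": 1.0, "TSG": 1.0, "NCRG": 1.0}
    )
    omega: float = 0.2
    branch_length: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs sum to {total}, expected 1")
        for label, m in self.rate_multiplier.items():
            if m <= 0:
                raise ValueError(f"rate multiplier for {label} must be > 0")
        for label, a in self.attractiveness.items():
            if a <= 0:
                raise ValueError(f"attractiveness for {label} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def generate_universe(config: SimulationConfig) -> GeneSetPartition:
    """Gene universe with exact set sizes and log-normal coding lengths."""
    rng = _rng(config, 1)
    records: dict[str, GeneRecord] = {}
    for label in SET_LABELS:
        n = config.n_genes.get(label, 0)
        lengths = np.maximum(
            90,
            rng.lognormal(config.length_mu_log, config.length_sigma_log, size=n),
        ).astype(int)
        for i in range(n):
            gene = f"{label}{i + 1:05d}"
            potsf_class = None
            if label == "POTSF":
                potsf_class = ("TF", "KINASE", "OTHER")[i % 3]
            records[gene] = GeneRecord(
                gene_id=gene,
                length_bp=int(lengths[i]),
                set_label=label,
                potsf_class=potsf_class,
            )
    return GeneSetPartition(records)


def generate_mutations(
    partition: GeneSetPartition,
    config: SimulationConfig,
    fixture_mode: bool = False,
) -> pd.DataFrame:
    """MAF-like mutation table.

    Default mode: per gene and cohort the record count is
    Poisson(base_rate × multiplier(set) × length × n_cases), classes drawn
    from ``class_probs`` and sample ids uniform over the cohort's cases.

    ``fixture_mode`` instead emits exactly 617,354 records with exactly
    134,635 SILENT and 10,659 RNA records (non-silent classes apportioned
    from the printed class counts by largest remainder), reproducing the
    source cohort's filter bookkeeping at full size.
    """
    rng = _rng(config, 2)
    genes = np.array(partition.genes)
    lengths = partition.lengths().reindex(genes).to_numpy(dtype=float)
    labels = partition.labels().reindex(genes)
    mult = labels.map(lambda s: config.rate_multiplier.get(s, 1.0)).to_numpy(dtype=float)

    classes = np.array(mut.VARIANT_CLASSES)
    probs = np.array([config.class_probs[c] for c in classes])

    if fixture_mode:
        n_nonsilent = FIXTURE_TOTAL - FIXTURE_SILENT - FIXTURE_RNA
        ns_classes = [c for c in classes if c in mut.NON_SILENT]
        weights = np.array([CLASS_COUNTS[c] for c in ns_classes], dtype=float)
        quota = weights / weights.sum() * n_nonsilent
        counts = np.floor(quota).astype(int)
        remainder = n_nonsilent - counts.sum()
        order = np.argsort(-(quota - np.floor(quota)))
        counts[order[:remainder]] += 1
        class_col = np.concatenate(
            [np.repeat(c, k) for c, k in zip(ns_classes, counts)]
            + [np.repeat("SILENT", FIXTURE_SILENT), np.repeat("RNA", FIXTURE_RNA)]
        )
        rng.shuffle(class_col)
        n_rows = class_col.size
        cohort_names = np.array(list(config.cohorts))
        cohort_sizes = np.array([config.cohorts[c] for c in cohort_names], dtype=float)
        cohort_idx = rng.choice(
            cohort_names.size, size=n_rows, p=cohort_sizes / cohort_sizes.sum()
        )
        gene_col = rng.choice(genes, size=n_rows, p=mult * lengths / (mult * lengths).sum())
        case_ids = rng.integers(0, cohort_sizes[cohort_idx].astype(int))
        sample_col = np.char.add(
            np.char.add(cohort_names[cohort_idx], "-"), case_ids.astype(str)
        )
        return pd.DataFrame(
            {
                "gene": gene_col,
                "sample": sample_col,
                "cohort": cohort_names[cohort_idx],
                "variant_class": class_col,
            }
        )

    frames = []
    for cohort, n_cases in config.cohorts.items():
        lam = config.base_rate * mult * lengths * n_cases
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        gene_col = np.repeat(genes, counts)
        class_col = classes[rng.choice(classes.size, size=total, p=probs)]
        case_ids = rng.integers(n_cases, size=total)
        sample_col = np.char.add(f"{cohort}-", case_ids.astype(str))
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene_col,
                    "sample": sample_col,
                    "cohort": cohort,
                    "variant_class": class_col,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=mut.COLUMNS)
    return pd.concat(frames, ignore_index=True)


def generate_expression(
    partition: GeneSetPartition,
    config: SimulationConfig,
    n_samples: int | None = None,
) -> ExpressionMatrix:
    """Log-normal expression: value = 2^N(location(set), sigma) per gene/sample."""
    rng = _rng(config, 3)
    genes = partition.genes
    loc = (
        partition.labels()
        .reindex(genes)
        .map(lambda s: config.expr_location.get(s, 0.0))
        .to_numpy(dtype=float)
    )
    n = config.expr_samples if n_samples is None else n_samples
    log2_vals = rng.normal(loc[:, None], config.expr_sigma, size=(len(genes), n))
    values = pd.DataFrame(
        np.power(2.0, log2_vals),
        index=genes,
        columns=[f"S{i:04d}" for i in range(n)],
    )
    return ExpressionMatrix(values, "RAW")


def generate_network(
    partition: GeneSetPartition, config: SimulationConfig
) -> nx.Graph:
    """Hub-biased growth network over the universe genes.

    Nodes arrive in random order; the i-th arrival (0-based) attaches to
    min(m, i) distinct existing nodes drawn without replacement with
    probability ∝ (degree + 1) × attractiveness, so a graph on n ≥ m nodes
    has exactly m·(n − m) + m·(m − 1)/2 edges.
    """
    rng = _rng(config, 4)
    genes = np.array(partition.genes)
    rng.shuffle(genes)
    labels = partition.labels()
    attract = np.array(
        [config.attractiveness.get(labels[g], 1.0) for g in genes], dtype=float
    )
    m = config.network_m
    G = nx.Graph()
    for i, g in enumerate(genes):
        G.add_node(g, set_label=labels[g])
    degree = np.zeros(len(genes))
    for i in range(len(genes)):
        if i == 0:
            continue
        k = min(m, i)
        weights = (degree[:i] + 1.0) * attract[:i]
        targets = rng.choice(i, size=k, replace=False, p=weights / weights.sum())
        for t in targets:
            G.add_edge(genes[i], genes[t])
            degree[i] += 1
            degree[t] += 1
    return G


def generate_codon_pair(
    n_codons: int, omega: float, t: float, seed: int | np.random.Generator
) -> tuple[str, str]:
    """Ancestor sequence and a copy diverged at dN/dS ≈ ``omega``.

    ``t`` is the expected number of *proposed* point mutations per codon
    along the branch.  Proposals pick a uniform codon position and an
    alternative nucleotide; synonymous proposals are always accepted,
    nonsynonymous ones with probability ``omega``, and proposals creating a
    stop codon are always rejected.
    """
    if n_codons <= 0:
        raise ValueError("n_codons must be > 0")
    if omega < 0 or t < 0:
        raise ValueError("omega and t must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sense = np.array(SENSE_CODONS)
    ancestor = list(sense[rng.integers(sense.size, size=n_codons)])
    evolved = list(ancestor)
    n_events = rng.poisson(t * n_codons)
    nts = "ACGT"
    for _ in range(n_events):
        idx = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = evolved[idx]
        alt = nts.replace(codon[pos], "")[int(rng.integers(3))]
        candidate = codon[:pos] + alt + codon[pos + 1 :]
        if candidate in STOP_CODONS:
            continue
        if _CODE[candidate] != _CODE[codon] and rng.random() >= omega:
            continue
        evolved[idx] = candidate
    return "".join(ancestor), "".join(evolved)


def write_outputs(config: SimulationConfig, outdir) -> dict[str, str]:
    """Generate one full synthetic data set and write it as plain-text files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition = generate_universe(config)
    paths = {}

    frame = partition.to_frame()
    paths["partition"] = str(outdir / "partition.tsv")
    frame.to_csv(paths["partition"], sep="\t", index=False)
    paths["universe"] = str(outdir / "universe.tsv")
    frame[["gene_id", "length_bp"]].to_csv(
        paths["universe"], sep="\t", index=False, header=False
    )
    for label, fname in (("ONC", "onc_list.tsv"), ("TSG", "tsg_list.tsv")):
        members = frame.loc[
            frame["set_label"].isin([label, "POTSF"]), "gene_id"
        ]
        (outdir / fname).write_text("\n".join(members) + "\n")
        paths[label.lower() + "_list"] = str(outdir / fname)
    curated = frame.loc[frame["set_label"] == "POTSF", "gene_id"]
    (outdir / "curated_potsf.tsv").write_text("\n".join(curated) + "\n")
    paths["curated"] = str(outdir / "curated_potsf.tsv")

    maf = generate_mutations(partition, config)
    paths["maf"] = str(outdir / "mutations.maf.tsv")
    maf.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample": "Tumor_Sample_Barcode",
            "variant_class": "Variant_Classification",
        }
    ).to_csv(paths["maf"], sep="\t", index=False)

    expr = generate_expression(partition, config)
    paths["expression"] = str(outdir / "expression.tsv")
    expr.values.to_csv(paths["expression"], sep="\t")

    G = generate_network(partition, config)
    paths["edges"] = str(outdir / "edges.tsv")
    with open(paths["edges"], "w") as fh:
        for a, b in sorted(G.edges):
            fh.write(f"{a}\t{b}\n")

    rng = _rng(config, 5)
    paths["codon_pairs"] = str(outdir / "codon_pairs.fasta")
    with open(paths["codon_pairs"], "w") as fh:
        for i in range(10):
            a, b = generate_codon_pair(300, config.omega, config.branch_length, rng)
            fh.write(f">pair{i:02d}_1\n{a}\n>pair{i:02d}_2\n{b}\n")
    return paths
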