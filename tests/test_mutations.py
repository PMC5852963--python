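"""Mutation-table parsing, the non-silent filter, counts and the rate statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dualgene import mutations as mut
from dualgene import simulate as sim


def _write_maf(path, rows, header=("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "cohort")):
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadMutationTable:
    def test_toy_maf_maps_standard_tokens(self, tmp_path):
        path = _write_maf(
            tmp_path / "toy.maf",
            [
                ("TP53", "s1", "Missense_Mutation", "BRCA"),
                ("KRAS", "s2", "Silent", "BRCA"),
                ("EGFR", "s1", "Frame_Shift_Del", "LUAD"),
            ],
        )
        df = mut.read_mutation_table(path)
        assert list(df["variant_class"]) == ["MISSENSE", "SILENT", "FRAME_SHIFT_DEL"]
        assert list(df.columns) == mut.COLUMNS

    def test_unmapped_token_skipped_and_tallied(self, tmp_path):
        path = _write_maf(
            tmp_path / "toy.maf",
            [
                ("TP53", "s1", "Missense_Mutation", "BRCA"),
                ("TP53", "s1", "Translation_Start_Site", "BRCA"),
            ],
        )
        with pytest.warns(UserWarning, match="Translation_Start_Site"):
            df = mut.read_mutation_table(path)
        assert len(df) == 1
        assert df.attrs["n_skipped"] == 1
        assert df.attrs["skipped_classes"] == {"Translation_Start_Site": 1}

    def test_missing_required_column_named(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Hugo_Symbol\tcohort\nTP53\tBRCA\n")
        with pytest.raises(ValueError, match="sample"):
            mut.read_mutation_table(path)

    def test_constant_cohort_and_dedup(self, tmp_path):
        path = _write_maf(
            tmp_path / "toy.maf",
            [("TP53", "s1", "Silent"), ("TP53", "s1", "Silent")],
            header=("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"),
        )
        df = mut.read_mutation_table(path, cohort="OV", dedup=True)
        assert len(df) == 1 and df.loc[0, "cohort"] == "OV"

    def test_generated_table_roundtrips_through_reader(self, tmp_path, small_config, small_partition):
        table = sim.generate_mutations(small_partition, small_config)
        path = tmp_path / "sim.maf"
        table.rename(
            columns={
                "gene": "Hugo_Symbol",
                "sample": "Tumor_Sample_Barcode",
                "variant_class": "Variant_Classification",
            }
        ).to_csv(path, sep="\t", index=False)
        back = mut.read_mutation_table(path)
        expected = table["variant_class"].value_counts().to_dict()
        assert back["variant_class"].value_counts().to_dict() == expected
        assert len(back) == len(table)


class TestFilterNonSilent:
    def test_retains_exactly_the_protein_altering_classes(self):
        df = pd.DataFrame(
            {
                "gene": ["g"] * 10,
                "sample": ["s"] * 10,
                "cohort": ["c"] * 10,
                "variant_class": list(mut.VARIANT_CLASSES),
            }
        )
        kept = mut.filter_non_silent(df)
        assert set(kept["variant_class"]) == set(mut.NON_SILENT)
        assert len(kept) == 8

    def test_all_missense_unchanged(self):
        df = pd.DataFrame(
            {"gene": ["a", "b"], "sample": ["s", "s"], "cohort": ["c", "c"],
             "variant_class": ["MISSENSE", "MISSENSE"]}
        )
        assert mut.filter_non_silent(df)["gene"].tolist() == ["a", "b"]

    def test_all_silent_empty(self):
        df = pd.DataFrame(
            {"gene": ["a"], "sample": ["s"], "cohort": ["c"], "variant_class": ["SILENT"]}
        )
        assert mut.filter_non_silent(df).empty

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(mut.VARIANT_CLASSES), max_size=60))
    def test_conservation(self, classes):
        df = pd.DataFrame(
            {"gene": "g", "sample": "s", "cohort": "c",
             "variant_class": pd.Series(classes, dtype=object)}
        )
        kept = mut.filter_non_silent(df)
        removed = sum(c in ("SILENT", "RNA") for c in classes)
        assert len(kept) + removed == len(classes)


class TestCountPerGene:
    def test_zero_for_unmutated_genes(self, small_partition):
        df = pd.DataFrame(
            {
                "gene": [small_partition.genes[0]] * 3,
                "sample": ["s1", "s2", "s3"],
                "cohort": ["A"] * 3,
                "variant_class": ["MISSENSE"] * 3,
            }
        )
        counts = mut.count_per_gene(df, small_partition)
        assert counts[small_partition.genes[0]] == 3
        assert counts.drop(small_partition.genes[0]).eq(0).all()
        assert counts.sum() == len(df)

    def test_all_scope_is_sum_of_cohort_scopes(self, small_config, small_partition):
        table = sim.generate_mutations(small_partition, small_config)
        total = mut.count_per_gene(table, small_partition, scope="ALL")
        per = sum(
            mut.count_per_gene(table, small_partition, scope=c)
            for c in small_config.cohorts
        )
        assert total.equals(per)

    def test_poisson_mean_recovered(self):
        # 200 genes, constant length/rate chosen for a per-gene mean of 5
        cfg = sim.SimulationConfig(
            n_genes={"POTSF": 0, "ONC": 0, "TSG": 0, "NCRG": 200},
            length_sigma_log=1e-9,
            length_mu_log=float(np.log(1000.0)),
            base_rate=5 / (1000 * 100),
            cohorts={"A": 100},
            seed=11,
        )
        part = sim.generate_universe(cfg)
        counts = mut.count_per_gene(sim.generate_mutations(part, cfg), part)
        se = np.sqrt(5 / 200)
        assert abs(counts.mean() - 5) < 3 * se


class TestMutationRate:
    def test_formula(self):
        assert mut.mutation_rate(10, 5, 1000) == pytest.approx(0.002)

    def test_zero_count(self):
        assert mut.mutation_rate(0, 100, 5000) == 0.0

    @pytest.mark.parametrize("n_cases,length", [(0, 10), (10, 0), (-1, 10), (10, -5)])
    def test_nonpositive_denominators_raise(self, n_cases, length):
        with pytest.raises(ValueError):
            mut.mutation_rate(1, n_cases, length)

    def test_vectorized_matches_scalar(self):
        counts, cases, lengths = [3, 0, 7], [10, 10, 20], [100, 200, 50]
        vec = mut.mutation_rate(counts, cases, lengths)
        for v, (c, n, l) in zip(vec, zip(counts, cases, lengths)):
            assert v == pytest.approx(mut.mutation_rate(c, n, l))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        count=st.integers(min_value=0, max_value=10**6),
        cases=st.integers(min_value=1, max_value=10**4),
        length=st.integers(min_value=1, max_value=10**6),
    )
    def test_homogeneity(self, count, cases, length):
        base = mut.mutation_rate(count, cases, length)
        assert mut.mutation_rate(2 * count, cases, length) == pytest.approx(2 * base)
        assert mut.mutation_rate(count, 2 * cases, length) == pytest.approx(base / 2)
        assert mut.mutation_rate(count, cases, 2 * length) == pytest.approx(base / 2)


class TestFunctionalImpact:
    @pytest.mark.parametrize(
        "variant_class,impact",
        [
            ("NONSENSE", "LOF_POTENTIAL"),
            ("FRAME_SHIFT_INS", "LOF_POTENTIAL"),
            ("SPLICE_SITE", "LOF_POTENTIAL"),
            ("NONSTOP", "LOF_POTENTIAL"),
            ("MISSENSE", "GOF_POTENTIAL"),
            ("IN_FRAME_DEL", "GOF_POTENTIAL"),
            ("SILENT", "EXCLUDED"),
            ("RNA", "EXCLUDED"),
        ],
    )
    def test_default_map(self, variant_class, impact):
        assert mut.classify_functional_impact(variant_class) == impact

    def test_custom_map_override(self):
        custom = dict(mut.DEFAULT_IMPACT_MAP, MISSENSE="LOF_POTENTIAL")
        assert mut.classify_functional_impact("MISSENSE", custom) == "LOF_POTENTIAL"

    def test_sequence_input(self):
        out = mut.classify_functional_impact(["MISSENSE", "SILENT"])
        assert out == ["GOF_POTENTIAL", "EXCLUDED"]


class TestBuildProfiles:
    def test_rate_uses_total_counts_and_given_cases(self, small_config, small_partition):
        table = sim.generate_mutations(small_partition, small_config)
        profiles = mut.build_profiles(table, small_partition, cohort_sizes=small_config.cohorts)
        assert set(profiles["cohort"]) == set(small_config.cohorts)
        assert (profiles["n_nonsilent"] <= profiles["n_total"]).all()
        row = profiles.iloc[profiles["n_total"].idxmax()]
        assert row["rate"] == pytest.approx(
            (row["n_total"] / row["n_cases"]) / row["length_bp"]
        )
        # every partition gene appears once per cohort
        assert len(profiles) == len(small_partition.genes) * len(small_config.cohorts)
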