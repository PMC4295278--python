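import numpy as np
import pandas as pd
import pytest

from coexpair.errors import InputError
from coexpair.ingest import (
    AnnotationMap,
    ClassMap,
    collapse_probes,
    read_annotation,
    read_class_assignments,
    read_expression_matrix,
)

from .conftest import make_matrix


class TestReadExpressionMatrix:
    def test_round_trip_preserves_ids_and_values(self, small_matrix_file):
        expr = read_expression_matrix(small_matrix_file)
        assert expr.row_ids == ["G1", "G2", "G3"]
        assert expr.sample_ids == ["S1", "S2", "S3", "S4"]
        assert expr.values[1, 3] == 8.0

    def test_header_only_is_an_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("gene_id\tS1\tS2\n")
        with pytest.raises(InputError, match="no data rows"):
            read_expression_matrix(path)

    @pytest.mark.parametrize("bad_cell", ["NA", "x", ""])
    def test_non_numeric_cell_reported_with_position(self, tmp_path, bad_cell):
        path = tmp_path / "bad.tsv"
        path.write_text(
            f"gene_id\tS1\tS2\nG1\t1.0\t2.0\nG2\t{bad_cell}\t3.0\n"
        )
        with pytest.raises(InputError, match="'G2'.*'S1'"):
            read_expression_matrix(path)

    def test_duplicate_sample_names_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\tS1\tS1\nG1\t1\t2\nG2\t3\t4\n")
        with pytest.raises(InputError, match="duplicate sample"):
            read_expression_matrix(path)

    def test_single_sample_rejected(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text("gene_id\tS1\nG1\t1\nG2\t2\n")
        with pytest.raises(InputError, match="at least 2 samples"):
            read_expression_matrix(path)


class TestReadClassAssignments:
    def test_two_column_dialect(self, two_class_file):
        cls = read_class_assignments(two_class_file)
        assert cls.class_names == ("leaf", "peel")  # order of first appearance
        assert cls.samples("leaf") == ["S1", "S2", "S3", "S4"]
        assert cls.class_sizes() == (4, 4)

    def test_per_class_listing_dialect(self, tmp_path):
        path = tmp_path / "classes.tsv"
        path.write_text(
            "leaf\tS1\tS2\tS3\tS4\npeel\tS5\tS6\tS7\tS8\n"
        )
        cls = read_class_assignments(path)
        assert cls.class_names == ("leaf", "peel")
        assert cls.samples("peel") == ["S5", "S6", "S7", "S8"]

    def test_three_classes_rejected(self, tmp_path):
        path = tmp_path / "three.tsv"
        lines = [f"S{i}\tc{i % 3}" for i in range(12)]
        path.write_text("\n".join(lines))
        with pytest.raises(InputError, match="exactly two classes"):
            read_class_assignments(path)

    def test_small_class_rejected_citing_fisher_requirement(self, tmp_path):
        path = tmp_path / "small.tsv"
        lines = [f"S{i}\tbig" for i in range(5)] + ["S9\tsmall", "S10\tsmall", "S11\tsmall"]
        path.write_text("\n".join(lines))
        with pytest.raises(InputError, match="minimum 4.*Fisher"):
            read_class_assignments(path)

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        lines = ["S1\ta", "S1\ta", "S2\ta", "S3\ta"] + [f"S{i}\tb" for i in range(4, 8)]
        path.write_text("\n".join(lines))
        with pytest.raises(InputError, match="assigned twice"):
            read_class_assignments(path)


class TestReadAnnotation:
    def _write(self, tmp_path, rows):
        path = tmp_path / "annot.csv"
        body = "\n".join(f'"{p}","{g}"' for p, g in rows)
        path.write_text('"Probe Set ID","Gene Symbol"\n' + body + "\n")
        return path

    def test_single_mapped_retained_multi_and_missing_dropped(self, tmp_path):
        path = self._write(
            tmp_path,
            [("A_at", "GeneX"), ("B_at", "GeneY /// GeneZ"), ("C_at", "---")],
        )
        annot = read_annotation(path, id_type="gene_symbol")
        assert annot.probe_to_id == {"A_at": "GeneX"}

    def test_missing_column_lists_available(self, tmp_path):
        path = self._write(tmp_path, [("A_at", "GeneX")])
        with pytest.raises(InputError, match="Ensembl.*available columns"):
            read_annotation(path, id_type="ensembl")

    def test_all_multi_mapped_gives_empty_map_and_warning(self, tmp_path):
        path = self._write(tmp_path, [("A_at", "X /// Y"), ("B_at", "P /// Q")])
        with pytest.warns(UserWarning, match="no single-mapped probes"):
            annot = read_annotation(path, id_type="gene_symbol")
        assert annot.probe_to_id == {}


class TestCollapseProbes:
    def test_per_sample_max_uses_different_probes_per_sample(self):
        # P1 highest in sample 1, P3 highest in sample 2
        expr = make_matrix(
            [[5.0, 1.0], [3.0, 2.0], [1.0, 6.0], [9.9, 9.8]],
            row_ids=["P1", "P2", "P3", "P4"],
            id_level="probe",
        )
        annot = AnnotationMap({"P1": "G1", "P2": "G1", "P3": "G1", "P4": "G2"})
        collapsed = collapse_probes(expr, annot)
        assert collapsed.id_level == "gene"
        assert collapsed.data.loc["G1"].tolist() == [5.0, 6.0]

    def test_single_probe_gene_copied_unchanged(self):
        expr = make_matrix([[1.0, 2.0], [3.0, 4.0]], row_ids=["P1", "P2"], id_level="probe")
        annot = AnnotationMap({"P1": "G1", "P2": "G2"})
        collapsed = collapse_probes(expr, annot)
        assert collapsed.data.loc["G1"].tolist() == [1.0, 2.0]
        assert collapsed.data.loc["G2"].tolist() == [3.0, 4.0]

    def test_matches_explicit_per_sample_loop_oracle(self):
        rng = np.random.default_rng(42)
        values = rng.normal(8, 1, size=(10, 6))
        probes = [f"P{i}" for i in range(10)]
        genes = [f"G{i % 3}" for i in range(10)]
        expr = make_matrix(values, row_ids=probes, id_level="probe")
        annot = AnnotationMap(dict(zip(probes, genes)))
        collapsed = collapse_probes(expr, annot)
        # oracle: explicit per-sample max over each gene's probes
        for gene in sorted(set(genes)):
            idx = [i for i, g in enumerate(genes) if g == gene]
            for j in range(6):
                expected = max(values[i, j] for i in idx)
                assert collapsed.data.loc[gene].iloc[j] == expected

    def test_identity_map_changes_nothing(self):
        values = np.arange(8.0).reshape(4, 2)
        expr = make_matrix(values, row_ids=list("ABCD"), id_level="probe")
        annot = AnnotationMap({r: r for r in "ABCD"})
        collapsed = collapse_probes(expr, annot)
        assert np.array_equal(collapsed.values, values)

    def test_every_value_comes_from_some_probe_and_row_count_matches(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(12, 5))
        probes = [f"P{i:02d}" for i in range(12)]
        genes = [f"G{i % 4}" for i in range(12)]
        expr = make_matrix(values, row_ids=probes, id_level="probe")
        collapsed = collapse_probes(expr, AnnotationMap(dict(zip(probes, genes))))
        assert collapsed.data.shape[0] == len(set(genes))
        for gene in collapsed.row_ids:
            idx = [i for i, g in enumerate(genes) if g == gene]
            for j in range(5):
                assert collapsed.data.loc[gene].iloc[j] in values[idx, j]

    def test_disjoint_annotation_is_an_error(self):
        expr = make_matrix([[1.0, 2.0], [3.0, 4.0]], row_ids=["P1", "P2"], id_level="probe")
        annot = AnnotationMap({"Q1": "G1"})
        with pytest.raises(InputError, match="no probe"):
            collapse_probes(expr, annot)


def test_class_map_requires_two_classes_and_min_samples():
    with pytest.raises(InputError, match="exactly two"):
        ClassMap({f"S{i}": "only" for i in range(8)})
    with pytest.raises(InputError, match="minimum 4"):
        ClassMap({"S1": "a", "S2": "a", "S3": "a", "S4": "a", "S5": "b", "S6": "b", "S7": "b"})


def test_expression_matrix_rejects_non_finite():
    with pytest.raises(InputError, match="non-finite"):
        make_matrix([[1.0, np.nan], [2.0, 3.0]])
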