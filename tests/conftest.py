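import numpy as np
import pandas as pd
import pytest

from coexpair.ingest import ClassMap, ExpressionMatrix


@pytest.fixture
def small_matrix_file(tmp_path):
    """3 genes x 4 samples TSV."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tS1\tS2\tS3\tS4\n"
        "G1\t1.0\t2.0\t3.0\t4.0\n"
        "G2\t2.0\t4.0\t6.0\t8.0\n"
        "G3\t5.5\t1.2\t3.3\t0.1\n"
    )
    return path


@pytest.fixture
def two_class_file(tmp_path):
    """8 samples, 4 per class, two-column dialect."""
    path = tmp_path / "classes.tsv"
    lines = [f"S{i}\tleaf" for i in range(1, 5)] + [f"S{i}\tpeel" for i in range(5, 9)]
    path.write_text("# sample\tclass\n" + "\n".join(lines) + "\n")
    return path


def make_matrix(values, row_ids=None, sample_ids=None, id_level="gene"):
    values = np.asarray(values, dtype=float)
    rows = row_ids or [f"G{i + 1}" for i in range(values.shape[0])]
    cols = sample_ids or [f"S{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=rows, columns=cols), id_level=id_level)


def make_class_map(n1, n2, names=("classA", "classB")):
    assignments = {f"S{i + 1}": names[0] for i in range(n1)}
    assignments.update({f"S{n1 + i + 1}": names[1] for i in range(n2)})
    return ClassMap(assignments)


def edge_frame(edges):
    """Pair table from a list of (gene_a, gene_b, r[, p]) tuples."""
    rows = []
    for edge in edges:
        a, b, r = edge[0], edge[1], edge[2]
        p = edge[3] if len(edge) > 3 else 0.01
        if a > b:
            a, b = b, a
        rows.append({"gene_a": a, "gene_b": b, "r": r, "n": 20, "t": 0.0, "p": p})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "n", "t", "p"])
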