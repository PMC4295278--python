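"""Synthetic two-class expression data with planted structure.

Generates log2-intensity-like matrices containing planted gene pairs with
chosen per-class population correlations, planted dense modules (genes
sharing one latent factor in a designated class and independent in the
other), and independent noise genes. Ground-truth labels are returned so
downstream recovery can be scored.

The construction is the bivariate/latent-factor Gaussian
x = rho*f + sqrt(1-rho^2)*eps, matching the distributional assumptions of
the pipeline's statistics (t test on r, Fisher z); values are shifted and
scaled to resemble log2 microarray intensities (mean 8, sd 1 by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpr import BASE_R
from .errors import InputError
from .ingest import ClassMap, ExpressionMatrix


@dataclass
class SimulationConfig:
    """Recipe for one synthetic dataset.

    planted_pairs: list of (target_r1, target_r2, count) — population
    correlations of the pair in class 1 and class 2.
    planted_modules: list of (size, class_label_index, within_r) —
    a block of ``size`` genes with pairwise correlation ``within_r`` in
    the designated class (0 or 1) and independence in the other.
    """

    n_genes: int = 100
    n1: int = 50
    n2: int = 50
    planted_pairs: list[tuple[float, float, int]] = field(default_factory=list)
    planted_modules: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    mean: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n1 < 4 or self.n2 < 4:
            raise InputError("each class needs at least 4 samples")
        for r1, r2, count in self.planted_pairs:
            if abs(r1) >= 1 or abs(r2) >= 1:
                raise InputError("target correlations must satisfy |r| < 1")
            if count < 0:
                raise InputError("pair counts must be >= 0")
        for size, class_idx, within_r in self.planted_modules:
            if size < 2 or class_idx not in (0, 1) or not 0 < within_r < 1:
                raise InputError(f"invalid planted module {(size, class_idx, within_r)}")

    @property
    def planted_gene_count(self) -> int:
        return 2 * sum(c for _, _, c in self.planted_pairs) + sum(
            s for s, _, _ in self.planted_modules
        )


@dataclass
class GroundTruth:
    """Planted-structure labels keyed by canonical gene pair / module index."""

    pair_categories: dict[tuple[str, str], str] = field(default_factory=dict)
    pair_targets: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    modules: list[tuple[str, ...]] = field(default_factory=list)
    module_classes: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "pairs": [
                {"gene_a": a, "gene_b": b, "category": cat,
                 "r1": self.pair_targets[(a, b)][0], "r2": self.pair_targets[(a, b)][1]}
                for (a, b), cat in sorted(self.pair_categories.items())
            ],
            "modules": [
                {"members": list(m), "class_index": c}
                for m, c in zip(self.modules, self.module_classes)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def intended_category(r1: float, r2: float, base_r: float = BASE_R) -> str:
    """Category a pair with population correlations (r1, r2) should receive."""
    c1, c2 = abs(r1) > base_r, abs(r2) > base_r
    if c1 and c2:
        if r1 > 0 and r2 > 0:
            return "PCCGP"
        if r1 < 0 and r2 < 0:
            return "NCCGP"
        return "CCNCGP"
    if c1 or c2:
        return "DCNCGP"
    return "none"


def _correlated_rows(rho: float, n: int, rng: np.random.Generator):
    """Two length-n rows with population correlation rho (standard scale)."""
    f = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    a = f
    b = rho * f + math.sqrt(1.0 - rho * rho) * eps
    return a, b


def simulate_pair(
    r1: float, r2: float, n1: int, n2: int, rng: np.random.Generator
):
    """Two gene rows over n1 + n2 samples with per-class correlations (r1, r2)."""
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise InputError("target correlations must satisfy |r| < 1")
    a1, b1 = _correlated_rows(r1, n1, rng)
    a2, b2 = _correlated_rows(r2, n2, rng)
    return np.concatenate([a1, a2]), np.concatenate([b1, b2])


def _module_block(
    size: int, within_r: float, n_active: int, n_other: int,
    active_first: bool, rng: np.random.Generator,
) -> np.ndarray:
    """size x (n1+n2) block: one shared factor in the active class only.

    Loading sqrt(within_r) on a shared factor gives pairwise correlation
    within_r between every two members in the active class.
    """
    loading = math.sqrt(within_r)
    f = rng.standard_normal(n_active)
    active = loading * f[None, :] + math.sqrt(1.0 - within_r) * rng.standard_normal(
        (size, n_active)
    )
    other = rng.standard_normal((size, n_other))
    return np.hstack([active, other]) if active_first else np.hstack([other, active])


def simulate_dataset(config: SimulationConfig):
    """Build (ExpressionMatrix, ClassMap, GroundTruth) from a config.

    Planted pair and module genes come first, then independent noise genes
    filling up to ``n_genes``. Reproducible: identical (config, seed)
    yields identical output.
    """
    if config.planted_gene_count > config.n_genes:
        raise InputError(
            f"planted structures need {config.planted_gene_count} genes, "
            f"but n_genes = {config.n_genes}"
        )
    rng = np.random.default_rng(config.seed)
    n1, n2 = config.n1, config.n2
    width = len(str(max(config.n_genes, 1)))
    rows: list[np.ndarray] = []
    names: list[str] = []
    truth = GroundTruth()

    def next_name() -> str:
        names.append(f"G{len(names) + 1:0{width}d}")
        return names[-1]

    for r1, r2, count in config.planted_pairs:
        for _ in range(count):
            row_a, row_b = simulate_pair(r1, r2, n1, n2, rng)
            ga, gb = next_name(), next_name()
            rows.extend([row_a, row_b])
            pair = (ga, gb) if ga < gb else (gb, ga)
            truth.pair_categories[pair] = intended_category(r1, r2)
            truth.pair_targets[pair] = (r1, r2)

    for size, class_idx, within_r in config.planted_modules:
        n_active = n1 if class_idx == 0 else n2
        n_other = n2 if class_idx == 0 else n1
        block = _module_block(size, within_r, n_active, n_other, class_idx == 0, rng)
        members = tuple(next_name() for _ in range(size))
        rows.extend(block)
        truth.modules.append(members)
        truth.module_classes.append(class_idx)

    while len(names) < config.n_genes:
        next_name()
        rows.append(rng.standard_normal(n1 + n2))

    values = config.mean + config.noise_sd * np.vstack(rows)
    samples = [f"S{i + 1:03d}A" for i in range(n1)] + [
        f"S{i + 1:03d}B" for i in range(n2)
    ]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=names, columns=samples), id_level="gene"
    )
    assignments = {s: ("classA" if s.endswith("A") else "classB") for s in samples}
    cls = ClassMap(assignments)
    return expr, cls, truth


def write_dataset(expr: ExpressionMatrix, cls: ClassMap, out_dir) -> dict[str, Path]:
    """Write matrix + class file in the dialects the ingest module reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_path = out / "expression.tsv"
    expr.data.to_csv(expr_path, sep="\t", index_label="gene_id")
    cls_path = out / "classes.tsv"
    with open(cls_path, "w") as handle:
        handle.write("# sample\tclass\n")
        for sample, label in cls.assignments.items():
            handle.write(f"{sample}\t{label}\n")
    return {"expression": expr_path, "classes": cls_path}
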