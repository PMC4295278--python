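"""Pipeline orchestration, checkpointing, and output writers.

Stage order: ingest -> per-class coexpression -> density scan and r_bs
selection -> |r| and top-fraction filters -> Fisher z classification ->
module detection -> writers. Each completed stage is checkpointed under
``<output_dir>/checkpoints`` keyed by a hash of the analysis parameters:
an interrupted run resumes from the last completed stage, and a rerun on
a completed project recomputes nothing and rewrites identical outputs.

Output layout::

    <output_dir>/
      Output/<CATEGORY>/pairs.tsv
      Output/<CATEGORY>/Modules/{modules.txt, module_edges.txt}
      Output/class_networks/<class>/pairs.tsv (+ Modules/)
      Output/density/<class>.tsv
      run.log
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import coexpr, density, diffclass, ingest
from .ipca import (
    DEFAULT_DIAMETER,
    DEFAULT_MIN_SIZE,
    DEFAULT_T_IN,
    Module,
    build_module_graph,
)
from .ipca import ipca as detect_modules
from .errors import CoexpairError, InputError, StageError

logger = logging.getLogger(__name__)

STAGES = ("ingest", "coexpr", "density", "classify", "modules")

PAIR_OUTPUT_COLUMNS = ["gene_a", "gene_b", "r1", "p1", "r2", "p2", "Z", "p_diff"]


@dataclass
class RunConfig:
    """Every knob of one pipeline run."""

    expression: str
    classes: str
    output_dir: str
    annotation: str | None = None
    id_type: str = "gene_symbol"
    corr_method: str = "pearson"
    base_r: float = coexpr.BASE_R
    top_fraction: float = 1.0
    diff_alpha: float = 0.05
    t_in: float = DEFAULT_T_IN
    d: int = DEFAULT_DIAMETER
    min_size: int = DEFAULT_MIN_SIZE
    shared_rbs: bool = False
    overlap_modules: bool = True
    gate_all: bool = False
    seed: int = 0
    n_workers: int = 1

    def __post_init__(self):
        if self.corr_method not in ("pearson", "spearman"):
            raise InputError(f"corr_method must be pearson|spearman, got {self.corr_method!r}")
        if not any(abs(self.top_fraction - f) < 1e-9 for f in density.TOP_FRACTIONS):
            raise InputError(f"top_fraction must be one of {density.TOP_FRACTIONS}")
        if not any(abs(self.diff_alpha - a) < 1e-9 for a in diffclass.DIFF_ALPHAS):
            raise InputError(f"diff_alpha must be one of {diffclass.DIFF_ALPHAS}")

    def analysis_hash(self) -> str:
        """Hash of everything that can change results (not worker count)."""
        payload = dataclasses.asdict(self)
        payload.pop("n_workers")
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory results of a run (fields are None past ``stop_after``)."""

    config: RunConfig
    class_names: tuple[str, str]
    rbs: dict[str, float] | None = None
    profiles: dict[str, density.DensityProfile] | None = None
    filtered: dict[str, pd.DataFrame] | None = None
    classified: pd.DataFrame | None = None
    modules: dict[str, list[Module]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


class Checkpointer:
    """Stage cache under <output_dir>/checkpoints, keyed by analysis hash."""

    def __init__(self, output_dir: Path, analysis_hash: str):
        self.dir = Path(output_dir) / "checkpoints"
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = {"analysis_hash": analysis_hash, "stages": {}}
        if self.manifest_path.exists():
            stored = json.loads(self.manifest_path.read_text())
            if stored.get("analysis_hash") == analysis_hash:
                self.manifest = stored
            else:
                logger.info("parameters changed; discarding previous checkpoints")

    def done(self, stage: str) -> bool:
        return bool(self.manifest["stages"].get(stage))

    def mark(self, stage: str) -> None:
        self.manifest["stages"][stage] = True
        tmp = self.manifest_path.with_suffix(".partial")
        tmp.write_text(json.dumps(self.manifest, indent=1))
        tmp.replace(self.manifest_path)

    def path(self, name: str) -> Path:
        return self.dir / name

    def save_frame(self, name: str, frame: pd.DataFrame) -> None:
        tmp = self.path(name + ".partial")
        frame.to_csv(tmp, sep="\t", index=False)
        tmp.replace(self.path(name))

    def load_frame(self, name: str) -> pd.DataFrame:
        frame = pd.read_csv(self.path(name), sep="\t")
        for col in ("gene_a", "gene_b"):
            if col in frame.columns:
                frame[col] = frame[col].astype(str)
        return frame

    def save_json(self, name: str, payload) -> None:
        tmp = self.path(name + ".partial")
        tmp.write_text(json.dumps(payload, indent=1))
        tmp.replace(self.path(name))

    def load_json(self, name: str):
        return json.loads(self.path(name).read_text())


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> PipelineResult:
    """Execute the pipeline, resuming from checkpoints when present.

    ``stop_after`` names a stage (see ``STAGES``) after which to halt;
    completed stages stay checkpointed so a later call resumes there.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise InputError(f"unknown stage {stop_after!r}; stages are {STAGES}")
    out_dir = Path(config.output_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory not writable: {exc}") from exc

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="a")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("coexpair")
    root.addHandler(handler)
    previous_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run(config, out_dir, stop_after)
    finally:
        root.removeHandler(handler)
        root.setLevel(previous_level)
        handler.close()


def _run(config: RunConfig, out_dir: Path, stop_after: str | None = None) -> PipelineResult:
    ckpt = Checkpointer(out_dir, config.analysis_hash())
    logger.info("run parameters: %s", json.dumps(dataclasses.asdict(config), sort_keys=True))

    # --- ingest ---------------------------------------------------------
    try:
        expr = ingest.read_expression_matrix(
            config.expression,
            id_level="probe" if config.annotation else "gene",
        )
        cls = ingest.read_class_assignments(config.classes)
        ingest.check_consistency(expr, cls)
        if config.annotation:
            annot = ingest.read_annotation(config.annotation, id_type=config.id_type)
            expr = ingest.collapse_probes(expr, annot)
    except InputError:
        raise
    except CoexpairError as exc:
        raise StageError("ingest", str(exc)) from exc
    ckpt.mark("ingest")
    class1, class2 = cls.class_names
    n_by_class = dict(zip(cls.class_names, cls.class_sizes()))
    logger.info(
        "ingest: %d genes, classes %s (n=%d) / %s (n=%d)",
        len(expr.row_ids), class1, n_by_class[class1], class2, n_by_class[class2],
    )
    if stop_after == "ingest":
        return PipelineResult(config=config, class_names=cls.class_names)

    lookups: dict[str, coexpr.CorrelationLookup] = {}

    def get_lookup(label: str) -> coexpr.CorrelationLookup:
        if label not in lookups:
            lookups[label] = coexpr.class_correlation_lookup(
                expr, cls, label,
                method=config.corr_method, n_workers=config.n_workers,
            )
        return lookups[label]

    # --- per-class coexpression ----------------------------------------
    base_edges: dict[str, pd.DataFrame] = {}
    if ckpt.done("coexpr"):
        for label in cls.class_names:
            base_edges[label] = ckpt.load_frame(f"base_network_{label}.tsv")
        logger.info("coexpr: loaded from checkpoint")
    else:
        for label in cls.class_names:
            try:
                net = coexpr.build_base_network(
                    expr, cls, label,
                    method=config.corr_method,
                    base_r=config.base_r,
                    n_workers=config.n_workers,
                )
            except CoexpairError as exc:
                raise StageError("coexpr", str(exc)) from exc
            base_edges[label] = net.edges
            ckpt.save_frame(f"base_network_{label}.tsv", net.edges)
            logger.info(
                "coexpr: class %s base network has %d edges (|r| > %g), "
                "%d zero-variance genes skipped",
                label, len(net), config.base_r, len(net.skipped_genes),
            )
        ckpt.mark("coexpr")
    if stop_after == "coexpr":
        return PipelineResult(config=config, class_names=cls.class_names)

    # --- density scan + filters ----------------------------------------
    profiles: dict[str, density.DensityProfile] = {}
    rbs: dict[str, float] = {}
    filtered: dict[str, pd.DataFrame] = {}
    if ckpt.done("density"):
        rbs = {k: float(v) for k, v in ckpt.load_json("rbs.json").items()}
        for label in cls.class_names:
            filtered[label] = ckpt.load_frame(f"filtered_{label}.tsv")
            profile = density.DensityProfile(ckpt.load_frame(f"profile_{label}.tsv"))
            profile.r_bs = rbs[label]
            profiles[label] = profile
        logger.info("density: loaded from checkpoint (r_bs = %s)", rbs)
    else:
        try:
            if config.shared_rbs:
                pooled = pd.concat(
                    [base_edges[c] for c in cls.class_names], ignore_index=True
                )
                shared = density.select_rbs(density.density_profile(pooled))
            for label in cls.class_names:
                if base_edges[label].empty:
                    # empty base network: r_bs undefined, keep the base
                    # cutoff so the class contributes zero pairs downstream
                    logger.warning(
                        "density: class %s base network is empty; "
                        "using base cutoff %.2f as r_bs", label, config.base_r,
                    )
                    profiles[label] = density.density_profile(
                        base_edges[label], grid=density.DEFAULT_GRID
                    )
                    rbs[label] = config.base_r
                    profiles[label].r_bs = rbs[label]
                    filtered[label] = base_edges[label]
                    ckpt.save_frame(f"filtered_{label}.tsv", base_edges[label])
                    ckpt.save_frame(f"profile_{label}.tsv", profiles[label].table)
                    continue
                profile = density.density_profile(base_edges[label])
                profiles[label] = profile
                rbs[label] = shared if config.shared_rbs else density.select_rbs(profile)
                profile.r_bs = rbs[label]
                after_rbs = density.filter_by_rbs(base_edges[label], rbs[label])
                kept = density.filter_top_fraction(after_rbs, config.top_fraction)
                filtered[label] = kept
                ckpt.save_frame(f"filtered_{label}.tsv", kept)
                ckpt.save_frame(f"profile_{label}.tsv", profile.table)
                logger.info(
                    "density: class %s r_bs=%.2f; %d -> %d pairs after r_bs, "
                    "top-fraction %.2f -> %d pairs",
                    label, rbs[label], len(base_edges[label]), len(after_rbs),
                    config.top_fraction, len(kept),
                )
        except CoexpairError as exc:
            raise StageError("density", str(exc)) from exc
        ckpt.save_json("rbs.json", rbs)
        ckpt.mark("density")
    if stop_after == "density":
        return PipelineResult(
            config=config, class_names=cls.class_names,
            rbs=rbs, profiles=profiles, filtered=filtered,
        )

    # --- classification -------------------------------------------------
    if ckpt.done("classify"):
        classified = ckpt.load_frame("classified.tsv")
        logger.info("classify: loaded from checkpoint")
    else:
        try:
            classified = diffclass.classify_pairs(
                filtered[class1], filtered[class2],
                get_lookup(class1), get_lookup(class2),
                alpha=config.diff_alpha, gate_all=config.gate_all,
            )
        except CoexpairError as exc:
            raise StageError("classify", str(exc)) from exc
        ckpt.save_frame("classified.tsv", classified)
        ckpt.mark("classify")
    counts = {cat: int((classified["category"] == cat).sum())
              for cat in diffclass.CATEGORIES}
    logger.info("classify: pair counts %s", counts)
    if stop_after == "classify":
        return PipelineResult(
            config=config, class_names=cls.class_names,
            rbs=rbs, profiles=profiles, filtered=filtered,
            classified=classified, counts=counts,
        )

    # --- modules --------------------------------------------------------
    modules: dict[str, list[Module]] = {}
    if ckpt.done("modules"):
        stored = ckpt.load_json("modules.json")
        for name, mods in stored.items():
            modules[name] = [
                Module(
                    module_id=m["module_id"],
                    members=tuple(m["members"]),
                    edges=tuple(tuple(e) for e in m["edges"]),
                    t_in=config.t_in, d=config.d,
                )
                for m in mods
            ]
        logger.info("modules: loaded from checkpoint")
    else:
        try:
            edge_sets: dict[str, pd.DataFrame] = {
                cat: classified.loc[classified["category"] == cat]
                for cat in diffclass.CATEGORIES
            }
            for label in cls.class_names:
                edge_sets[f"class:{label}"] = filtered[label]
            for name, edges in edge_sets.items():
                if len(edges):
                    graph = build_module_graph(edges)
                    modules[name] = detect_modules(
                        graph,
                        t_in=config.t_in, d=config.d,
                        min_size=config.min_size, overlap=config.overlap_modules,
                    )
                else:
                    modules[name] = []
                logger.info("modules: %s -> %d modules", name, len(modules[name]))
        except CoexpairError as exc:
            raise StageError("modules", str(exc)) from exc
        ckpt.save_json(
            "modules.json",
            {
                name: [
                    {"module_id": m.module_id, "members": list(m.members),
                     "edges": [list(e) for e in m.edges]}
                    for m in mods
                ]
                for name, mods in modules.items()
            },
        )
        ckpt.mark("modules")

    result = PipelineResult(
        config=config,
        class_names=cls.class_names,
        rbs=rbs,
        profiles=profiles,
        filtered=filtered,
        classified=classified,
        modules=modules,
        counts=counts,
    )
    write_outputs(result, out_dir)
    return result


def _write_module_files(modules: list[Module], mod_dir: Path) -> None:
    mod_dir.mkdir(parents=True, exist_ok=True)
    with open(mod_dir / "modules.txt", "w") as handle:
        for module in modules:
            handle.write(f"{module.module_id}\t{','.join(module.members)}\n")
    with open(mod_dir / "module_edges.txt", "w") as handle:
        for module in modules:
            for u, v in module.edges:
                handle.write(f"{u}\t{v}\n")


def read_modules_file(path) -> list[tuple[int, tuple[str, ...]]]:
    """Parse a modules.txt file back into (id, members) records."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        mid, members = line.split("\t")
        records.append((int(mid), tuple(members.split(","))))
    return records


def write_outputs(result: PipelineResult, out_dir) -> Path:
    """Write the Output/ tree: category pair tables, module files, density."""
    out = Path(out_dir) / "Output"
    for cat in diffclass.CATEGORIES:
        cat_dir = out / cat
        cat_dir.mkdir(parents=True, exist_ok=True)
        rows = result.classified.loc[result.classified["category"] == cat]
        table = rows[PAIR_OUTPUT_COLUMNS].sort_values(
            ["gene_a", "gene_b"], kind="mergesort"
        )
        table.to_csv(cat_dir / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
        _write_module_files(result.modules.get(cat, []), cat_dir / "Modules")
    for label in result.class_names:
        cls_dir = out / "class_networks" / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        result.filtered[label].sort_values(
            ["gene_a", "gene_b"], kind="mergesort"
        ).to_csv(cls_dir / "pairs.tsv", sep="\t", index=False, float_format="%.6g")
        _write_module_files(result.modules.get(f"class:{label}", []), cls_dir / "Modules")
    dens_dir = out / "density"
    dens_dir.mkdir(parents=True, exist_ok=True)
    for label, profile in result.profiles.items():
        profile.table.to_csv(
            dens_dir / f"{label}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    logger.info("outputs written under %s", out)
    return out
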