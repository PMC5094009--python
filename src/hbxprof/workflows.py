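"""End-to-end workflows: the tissue-panel chain and the staged-series chain.

``run_tissue_workflow`` executes call -> normalize -> cluster -> label ->
specificity -> exclusivity and writes group lists, the breadth table, the
class summary, the exclusive-gene table and a heatmap.
``run_staged_workflow`` executes call -> turnover -> boundary detection ->
normalize -> temporal grouping for a stage-ranked series.

Every run directory receives the exact config used (``config.yaml``), a
log with gene/sample counts after each stage (``run.log``) and a manifest
of the tabular outputs with SHA-256 checksums (``manifest.tsv``); two runs
with identical config and inputs produce identical manifests. Figures are
excluded from the manifest (their bytes depend on the plotting backend).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calling, clustering, exclusivity, io, phases, specificity, synthetic

logger = logging.getLogger("hbxprof")


@dataclass
class RunConfig:
    """Serialisable description of one analysis run."""

    # inputs: either explicit paths or a synthetic preset
    matrix: str | None = None
    genes: str | None = None
    samples: str | None = None
    preset: str | None = None  # "human-panel" | "mouse-series"
    # expression calling
    threshold: float = 2.0
    cmp: str = "ge"
    # clustering
    distance: str = "correlation"
    linkage: str = "average"
    k: int = 6
    # specificity
    widespread_min_fraction: float = 0.9
    adult_only: bool = False
    # exclusivity
    target_group: str = "reproductive_dev"
    add_samples: tuple = ()
    window: tuple | None = None  # (rank_lo, rank_hi)
    # staged series
    n_boundaries: int = 3
    # misc
    seed: int = 0
    outdir: str = "results"

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["add_samples"] = list(self.add_samples)
        d["window"] = list(self.window) if self.window is not None else None
        return d

    def to_yaml(self, path):
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.add_samples = tuple(cfg.add_samples or ())
        if cfg.window is not None:
            cfg.window = tuple(int(v) for v in cfg.window)
        return cfg


@contextmanager
def _stage(name):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done", name)


def _load_bundle(config, kind):
    if config.preset is not None:
        if config.preset == "human-panel":
            panel = synthetic.generate_tissue_panel(seed=config.seed,
                                                    threshold=config.threshold)
            return io.align(panel.matrix, panel.gene_ann, panel.sample_ann), panel
        if config.preset == "mouse-series":
            series = synthetic.generate_staged_series(seed=config.seed,
                                                      threshold=config.threshold)
            return io.align(series.matrix, series.gene_ann, series.sample_ann), series
        raise ValueError(f"unknown preset {config.preset!r}")
    if config.matrix is None:
        raise ValueError(f"config for the {kind} workflow needs a matrix path or a preset")
    if config.genes is None or config.samples is None:
        raise ValueError("config needs gene and sample annotation paths")
    matrix = io.read_matrix(config.matrix)
    gene_ann, sample_ann = io.read_annotations(config.genes, config.samples)
    return io.align(matrix, gene_ann, sample_ann), None


def _write_tsv(df, path, index_name=None):
    out = df.copy()
    if index_name is not None:
        out.index.name = index_name
    out.to_csv(path, sep="\t")


def _write_manifest(outdir):
    outdir = Path(outdir)
    lines = []
    for path in sorted(outdir.iterdir()):
        if path.name in ("manifest.tsv", "run.log") or path.suffix == ".png":
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        lines.append(f"{path.name}\t{digest}")
    (outdir / "manifest.tsv").write_text("file\tsha256\n" + "\n".join(lines) + "\n")


@contextmanager
def _run_logging(outdir):
    handler = logging.FileHandler(Path(outdir) / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    level = logger.level
    logger.setLevel(logging.INFO)
    try:
        yield
    finally:
        logger.removeHandler(handler)
        handler.close()
        logger.setLevel(level)


def run_tissue_workflow(config):
    """Run the full tissue-panel analysis described by ``config``.

    Returns a dict of in-memory results; all tables are also written to
    ``config.outdir``.
    """
    if config.matrix is None and config.preset is None:
        raise ValueError("config needs a matrix path or a preset (checked before any computation)")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    with _run_logging(outdir):
        with _stage("load"):
            bundle, source = _load_bundle(config, "tissue")
            logger.info("loaded %d genes x %d samples",
                        *bundle.matrix.shape)
        with _stage("call"):
            called = calling.call_expression(bundle.matrix, config.threshold, config.cmp)
            logger.info("expressed calls: %d", int(called.gt(0).to_numpy().sum()))
        with _stage("normalize"):
            norm = calling.normalize_to_max(called)
        with _stage("cluster"):
            dend = clustering.cluster_genes(norm, config.distance, config.linkage)
            groups = clustering.cut_groups(dend, k=config.k)
            groups = clustering.label_groups(
                groups, called, bundle.sample_ann,
                widespread_fraction=config.widespread_min_fraction,
            )
            logger.info("groups: %s", {g.label: len(g.genes) for g in groups})
        with _stage("specificity"):
            subset = None
            if config.adult_only:
                subset = list(
                    bundle.sample_ann.index[bundle.sample_ann["category"] == "adult_tissue"]
                )
            b = specificity.breadth(called, sample_subset=subset)
            summary = specificity.class_summary(b, bundle.gene_ann)
            per_sample = specificity.genes_per_sample(called)
            widespread = specificity.classify_widespread(
                b, min_fraction=config.widespread_min_fraction, groups=groups
            )
            logger.info("widespread genes (%s route): %d",
                        widespread.route, len(widespread.genes))
        with _stage("exclusivity"):
            targets = frozenset(
                bundle.sample_ann.index[bundle.sample_ann["group"] == config.target_group]
            )
            targets = exclusivity.augment_target_set(
                targets, config.add_samples, bundle.matrix.columns
            )
            excl = exclusivity.exclusive_to(called, targets, sample_ann=bundle.sample_ann)
            logger.info("exclusive genes: %d", len(excl.exclusive_genes))
            window_genes = None
            if config.window is not None:
                window_genes = exclusivity.peak_in_window(
                    excl, bundle.sample_ann, config.window
                )
                logger.info("peak-in-window genes: %d", len(window_genes))
        with _stage("write"):
            _write_tsv(called, outdir / "called.tsv", "gene_id")
            _write_tsv(norm, outdir / "normalized.tsv", "gene_id")
            clustering.export_heatmap(
                norm, dend,
                matrix_path=outdir / "ordered_matrix.tsv",
                image_path=outdir / "heatmap.png",
            )
            group_series = groups.as_series()
            _write_tsv(group_series.to_frame(), outdir / "groups.tsv", "gene_id")
            _write_tsv(b.to_frame(), outdir / "breadth.tsv", "gene_id")
            summary_out = summary.copy()
            summary_out["outliers"] = summary_out["outliers"].map(",".join)
            _write_tsv(summary_out, outdir / "class_summary.tsv")
            _write_tsv(per_sample.to_frame(), outdir / "genes_per_sample.tsv", "sample_id")
            widespread_df = pd.DataFrame(
                {"gene_id": sorted(widespread.genes), "route": widespread.route}
            ).set_index("gene_id")
            _write_tsv(widespread_df, outdir / "widespread.tsv")
            excl_out = excl.table.copy()
            if window_genes is not None:
                excl_out["peak_in_window"] = [
                    g in window_genes for g in excl_out.index
                ]
            _write_tsv(excl_out, outdir / "exclusive.tsv", "gene_id")
            config.to_yaml(outdir / "config.yaml")
            _write_manifest(outdir)
    results.update(
        bundle=bundle, source=source, called=called, norm=norm, dendrogram=dend,
        groups=groups, breadth=b, class_summary=summary,
        genes_per_sample=per_sample, widespread=widespread, exclusivity=excl,
        window_genes=window_genes, outdir=outdir,
    )
    return results


def run_staged_workflow(config):
    """Run the staged-series analysis described by ``config``."""
    if config.matrix is None and config.preset is None:
        raise ValueError("config needs a matrix path or a preset (checked before any computation)")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _run_logging(outdir):
        with _stage("load"):
            bundle, source = _load_bundle(config, "staged")
            ranked = bundle.sample_ann["temporal_rank"].notna()
            if not ranked.all():
                missing = list(bundle.sample_ann.index[~ranked])
                raise ValueError(f"staged workflow requires ranked samples; missing: {missing}")
            if bundle.matrix.shape[1] < 2:
                raise ValueError("staged workflow requires at least 2 stages")
            logger.info("loaded %d genes x %d stages", *bundle.matrix.shape)
        with _stage("call"):
            called = calling.call_expression(bundle.matrix, config.threshold, config.cmp)
        with _stage("normalize"):
            norm = calling.normalize_to_max(called)
        with _stage("phases"):
            assignment = phases.segment_phases(
                called, norm, bundle.sample_ann, n_boundaries=config.n_boundaries
            )
            logger.info("boundaries at %s -> %d phases",
                        assignment.boundaries, assignment.n_phases)
        with _stage("cluster"):
            stage_cols = phases.stage_order(bundle.sample_ann, samples=norm.columns)
            ordered_norm = norm[stage_cols]
            dend = clustering.cluster_genes(ordered_norm, config.distance, config.linkage)
        with _stage("write"):
            _write_tsv(called, outdir / "called.tsv", "gene_id")
            _write_tsv(norm, outdir / "normalized.tsv", "gene_id")
            assignment.turnover.to_csv(outdir / "turnover.tsv", sep="\t", index=False)
            boundary_rows = assignment.turnover[
                assignment.turnover["position"].isin(assignment.boundaries)
            ]
            boundary_rows.to_csv(outdir / "boundaries.tsv", sep="\t", index=False)
            _write_tsv(assignment.groups, outdir / "temporal_groups.tsv", "gene_id")
            clustering.export_heatmap(
                ordered_norm, dend,
                matrix_path=outdir / "ordered_matrix.tsv",
                image_path=outdir / "heatmap.png",
            )
            config.to_yaml(outdir / "config.yaml")
            _write_manifest(outdir)
    return {
        "bundle": bundle, "source": source, "called": called, "norm": norm,
        "assignment": assignment, "dendrogram": dend, "outdir": outdir,
    }
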