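"""Synthetic expression panels with planted archetypes and truth labels.

The generator emulates the two study designs the pipeline targets: a
human-style tissue panel (242 genes x 59 samples spanning adult tissues,
immune cell types and preimplantation stages) and a mouse-style staged
whole-embryo series (278 genes x 12 stages from oocyte to e11.5), each
with known per-gene archetype labels so that every downstream
classification can be checked against planted truth.

Value model
-----------
Each archetype (widespread, module-specific, exclusive-with-peak,
temporal-phase, silent) owns a *shape*: one expression level per
supported sample, drawn log-normally on the FPKM scale (location 3,
scale 1 on log-FPKM by default) and clipped below at the calling
threshold so every planted expressed value is unambiguously expressed.
A gene is its archetype's shape times a per-gene amplitude (>= 1), plus a
sub-threshold background floor (uniform on [0, 1.5]) everywhere else.
Because genes of an archetype share the shape, their called,
max-normalized profiles are identical at zero noise — planted structure
is exactly recoverable, and the :func:`corrupt` operation adds dropout
and multiplicative noise on top to stress that recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HBX_CLASSES, validate_gene_annotations, validate_sample_annotations

#: Preimplantation stages, in temporal order (ranks 0..6).
PREIMPLANTATION_STAGES = (
    "oocyte", "zygote", "2cell", "4cell", "8cell", "morula", "blastocyst",
)

#: The 12-stage mouse-style whole-embryo series (ranks 0..11).
MOUSE_STAGES = PREIMPLANTATION_STAGES + ("e7.5", "e8.5", "e9.5", "e10.5", "e11.5")

ARCHETYPE_NAMES = (
    "widespread", "module_specific", "exclusive_peak",
    "maternal", "ega_burst", "cleavage_blastocyst", "postimplantation",
    "phase", "silent",
)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted expression archetype.

    Parameters
    ----------
    name : str
        Archetype kind (one of :data:`ARCHETYPE_NAMES`).
    label : str
        Unique truth label for this spec's genes (the planted cluster id).
    n_genes : int
    class_mix : mapping
        Relative weights over homeobox classes; converted to integer
        counts by largest remainder.
    sample_group : str, optional
        For ``module_specific``: the sample-annotation group in which the
        genes are expressed.
    support_samples : tuple, optional
        Explicit support (overrides ``sample_group``); required for
        temporal-phase archetypes and usable for ``exclusive_peak``.
    peak_sample : str, optional
        For ``exclusive_peak``: the sample forced to carry the maximum.
    loc, scale : float
        Location/scale of the expressed-value log-normal on log-FPKM.
    """

    name: str
    label: str
    n_genes: int
    class_mix: dict = field(default_factory=lambda: {"ANTP": 1})
    sample_group: str | None = None
    support_samples: tuple | None = None
    peak_sample: str | None = None
    loc: float = 3.0
    scale: float = 1.0

    def __post_init__(self):
        if self.name not in ARCHETYPE_NAMES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.name == "exclusive_peak" and self.peak_sample is None:
            raise ValueError(f"spec {self.label!r}: exclusive_peak needs a peak_sample")
        unknown = set(self.class_mix) - set(HBX_CLASSES)
        if unknown:
            raise ValueError(f"spec {self.label!r}: unknown class(es) {sorted(unknown)}")
        if any(w < 0 for w in self.class_mix.values()) or not any(self.class_mix.values()):
            raise ValueError(f"spec {self.label!r}: class_mix weights must be >= 0, not all 0")


@dataclass(frozen=True)
class TissuePanel:
    matrix: pd.DataFrame
    gene_ann: pd.DataFrame
    sample_ann: pd.DataFrame
    truth: pd.DataFrame
    target_group: str = "reproductive_dev"
    extra_target_samples: tuple = ()
    peak_window: tuple = (0, 0)


@dataclass(frozen=True)
class StagedSeries:
    matrix: pd.DataFrame
    gene_ann: pd.DataFrame
    sample_ann: pd.DataFrame
    truth: pd.DataFrame
    boundaries: tuple


def _mix_counts(mix, n):
    """Largest-remainder apportionment of n genes over class weights."""
    if n == 0:
        return {}
    total = float(sum(mix.values()))
    exact = {c: n * w / total for c, w in mix.items()}
    counts = {c: math.floor(v) for c, v in exact.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(
        mix, key=lambda c: (-(exact[c] - counts[c]), HBX_CLASSES.index(c))
    )
    for c in by_frac[:remainder]:
        counts[c] += 1
    return {c: k for c, k in counts.items() if k > 0}


def _resolve_support(spec, sample_ann):
    samples = list(sample_ann.index)
    if spec.name == "silent":
        return []
    if spec.support_samples is not None:
        unknown = [s for s in spec.support_samples if s not in sample_ann.index]
        if unknown:
            raise ValueError(f"spec {spec.label!r}: unknown support sample(s) {unknown}")
        return [s for s in samples if s in set(spec.support_samples)]
    if spec.sample_group is not None:
        support = [s for s in samples if sample_ann.at[s, "group"] == spec.sample_group]
        if not support:
            raise ValueError(
                f"spec {spec.label!r}: no sample has group {spec.sample_group!r}"
            )
        return support
    if spec.name == "widespread":
        return samples
    raise ValueError(f"spec {spec.label!r}: no support defined")


def _plant(specs, sample_ann, rng, threshold, background_high):
    """Core generator shared by both presets. Returns (matrix, gene_ann, truth)."""
    samples = list(sample_ann.index)
    col_index = {s: i for i, s in enumerate(samples)}
    n_total = sum(spec.n_genes for spec in specs)
    X = np.empty((n_total, len(samples)))
    gene_ids, classes, archetypes, labels, peaks = [], [], [], [], []
    row = 0
    for spec in specs:
        support = _resolve_support(spec, sample_ann)
        if spec.peak_sample is not None and spec.peak_sample not in support:
            raise ValueError(
                f"spec {spec.label!r}: peak sample {spec.peak_sample!r} not in support"
            )
        shape = np.maximum(
            rng.lognormal(mean=spec.loc, sigma=spec.scale, size=len(support)), threshold
        )
        if spec.peak_sample is not None and len(support):
            shape[support.index(spec.peak_sample)] = 1.5 * shape.max()
        support_cols = [col_index[s] for s in support]
        for cls, count in _mix_counts(spec.class_mix, spec.n_genes).items():
            for _ in range(count):
                amp = math.exp(abs(rng.normal(0.0, 0.5)))
                values = rng.uniform(0.0, background_high, size=len(samples))
                values[support_cols] = amp * shape
                X[row] = values
                gene_ids.append(f"g{row:04d}")
                classes.append(cls)
                archetypes.append(spec.name)
                labels.append(spec.label)
                peaks.append(spec.peak_sample)
                row += 1
    matrix = pd.DataFrame(X[:row], index=gene_ids, columns=samples)
    gene_ann = validate_gene_annotations(
        pd.DataFrame({"gene_id": gene_ids, "hbx_class": classes})
    )
    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "label": labels,
            "peak_sample": peaks,
            "hbx_class": classes,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return matrix, gene_ann, truth


# --- human-style tissue panel -------------------------------------------------

_NEURAL = (
    "cerebral_cortex", "cerebellum", "hippocampus", "amygdala",
    "substantia_nigra", "corpus_callosum", "parietal_lobe", "fetal_brain",
    "retina", "optic_nerve", "spinal_cord", "pituitary",
)
_IMMUNE_CELLS = ("b_cells", "t_cells", "monocytes", "neutrophils")
_IMMUNE_TISSUES = ("bone_marrow", "spleen", "thymus", "lymph_node")
_ORGANS = (
    "liver", "kidney", "heart", "lung", "pancreas", "stomach", "colon",
    "duodenum", "ileum", "prostate", "bladder", "uterus", "ovary",
    "gall_bladder", "esophagus", "thyroid", "adrenal_gland", "skin",
    "adipose", "skeletal_muscle", "smooth_muscle", "aorta",
    "coronary_artery", "salivary_gland", "tongue", "trachea", "bone",
    "appendix", "breast", "cervix",
)


def human_panel_samples():
    """59-sample annotation: 7 preimplantation stages, testis/placenta,
    12 neural, 8 immune and 30 organ samples.

    Ovary is annotated in the ``organ`` group (it does not co-cluster with
    the reproductive/developmental set) and is re-attached downstream via
    manual target-set augmentation.
    """
    rows = []
    for rank, stage in enumerate(PREIMPLANTATION_STAGES):
        rows.append((stage, "developmental_stage", "reproductive_dev", rank))
    for s in ("testis", "placenta"):
        rows.append((s, "adult_tissue", "reproductive_dev", None))
    for s in _NEURAL:
        rows.append((s, "adult_tissue", "neural", None))
    for s in _IMMUNE_CELLS:
        rows.append((s, "cell_type", "immune", None))
    for s in _IMMUNE_TISSUES:
        rows.append((s, "adult_tissue", "immune", None))
    for s in _ORGANS:
        rows.append((s, "adult_tissue", "organ", None))
    table = pd.DataFrame(rows, columns=["sample_id", "category", "group", "temporal_rank"])
    return validate_sample_annotations(table)


def human_panel_specs():
    """Default 242-gene archetype list for the human-style panel.

    Counts mirror the study design being emulated: 20 widespread genes
    (mostly TALE/ZF/CERS), tissue-module genes for the neural, immune and
    organ groups (ANTP/PRD-heavy), 23 genes exclusive to reproductive and
    early developmental samples of which 13 peak inside the
    8-cell..morula window, and 44 silent genes.
    """
    return [
        ArchetypeSpec(
            name="widespread", label="widespread", n_genes=20,
            class_mix={"TALE": 6, "ZF": 8, "CERS": 3, "PRD": 1, "SINE": 1, "CUT": 1},
        ),
        ArchetypeSpec(
            name="module_specific", label="neural", n_genes=60, sample_group="neural",
            class_mix={"ANTP": 25, "PRD": 15, "LIM": 8, "POU": 5, "SINE": 4, "ZF": 3},
        ),
        ArchetypeSpec(
            name="module_specific", label="immune", n_genes=25, sample_group="immune",
            class_mix={"ANTP": 8, "PRD": 5, "POU": 4, "CUT": 3, "ZF": 3, "TALE": 2},
        ),
        ArchetypeSpec(
            name="module_specific", label="organ", n_genes=70, sample_group="organ",
            class_mix={"ANTP": 35, "PRD": 12, "LIM": 8, "HNF": 3, "CUT": 3,
                       "PROS": 2, "SINE": 3, "POU": 4},
        ),
        ArchetypeSpec(
            name="exclusive_peak", label="excl_8cell", n_genes=7,
            support_samples=PREIMPLANTATION_STAGES, peak_sample="8cell",
            class_mix={"PRD": 6, "ANTP": 1},
        ),
        ArchetypeSpec(
            name="exclusive_peak", label="excl_morula", n_genes=6,
            support_samples=PREIMPLANTATION_STAGES, peak_sample="morula",
            class_mix={"PRD": 5, "ANTP": 1},
        ),
        ArchetypeSpec(
            name="exclusive_peak", label="excl_gonadal", n_genes=10,
            support_samples=("testis", "placenta", "ovary"), peak_sample="testis",
            class_mix={"PRD": 4, "ANTP": 3, "POU": 2, "LIM": 1},
        ),
        ArchetypeSpec(
            name="silent", label="silent", n_genes=44,
            class_mix={"ANTP": 22, "PRD": 11, "LIM": 6, "SINE": 2, "POU": 3},
        ),
    ]


def generate_tissue_panel(specs=None, samples=None, seed=0, threshold=2.0,
                          background_high=1.5):
    """Generate a tissue-panel matrix with planted archetypes.

    Deterministic for a given ``(specs, seed)``. With the defaults the
    panel is 242 genes x 59 samples with truth labels supporting every
    tissue-workflow check: widespread genes are expressed in all samples,
    module genes in exactly their sample group, exclusive genes only in
    reproductive/developmental samples (peak at the planted stage), and
    silent genes below threshold everywhere.
    """
    sample_ann = human_panel_samples() if samples is None else samples
    if specs is None:
        specs = human_panel_specs()
    if len(sample_ann.index) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    matrix, gene_ann, truth = _plant(specs, sample_ann, rng, threshold, background_high)
    ranks = sample_ann["temporal_rank"]
    window = (
        (int(ranks.get("8cell")), int(ranks.get("morula")))
        if "8cell" in ranks.index and "morula" in ranks.index
        and not pd.isna(ranks.get("8cell")) and not pd.isna(ranks.get("morula"))
        else (0, 0)
    )
    return TissuePanel(
        matrix=matrix, gene_ann=gene_ann, sample_ann=sample_ann, truth=truth,
        target_group="reproductive_dev",
        extra_target_samples=("ovary",) if "ovary" in sample_ann.index else (),
        peak_window=window,
    )


# --- mouse-style staged series ------------------------------------------------


def mouse_series_specs(stage_names=MOUSE_STAGES, boundaries=(1, 2, 6)):
    """Default 278-gene archetype list for the 12-stage series.

    Four temporal phases separated by the planted boundaries: maternal
    transcripts (oocyte..zygote, PRD-heavy), a 2-cell activation burst
    (PRD-heavy, matching the first wave of embryonic genome activation),
    a cleavage-to-blastocyst phase, and a post-implantation phase
    dominated by ANTP (HOXL) genes; plus silent genes.
    """
    intervals = _phase_intervals(boundaries, len(stage_names))
    names = ("maternal", "ega_burst", "cleavage_blastocyst", "postimplantation")
    mixes = (
        {"PRD": 40, "POU": 5, "ZF": 5, "TALE": 5, "LIM": 5},
        {"PRD": 45, "ANTP": 5},
        {"POU": 10, "PRD": 15, "ANTP": 15, "SINE": 10, "TALE": 10, "ZF": 10},
        {"ANTP": 55, "LIM": 10, "PRD": 8, "HNF": 5},
    )
    sizes = (60, 50, 70, 78)
    if len(intervals) != 4:
        raise ValueError("mouse_series_specs expects exactly 3 boundaries (4 phases)")
    specs = [
        ArchetypeSpec(
            name=name, label=name, n_genes=size, class_mix=mix,
            support_samples=tuple(stage_names[lo : hi + 1]),
        )
        for name, mix, size, (lo, hi) in zip(names, mixes, sizes, intervals)
    ]
    specs.append(
        ArchetypeSpec(name="silent", label="silent", n_genes=20,
                      class_mix={"ANTP": 10, "PRD": 5, "LIM": 5})
    )
    return specs


def _phase_intervals(boundaries, n_stages):
    bounds = tuple(int(b) for b in boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError(f"boundaries must be strictly increasing, got {bounds}")
    if bounds and (bounds[0] < 0 or bounds[-1] > n_stages - 2):
        raise ValueError(
            f"boundaries must lie in [0, {n_stages - 2}], got {bounds}"
        )
    edges = (-1,) + bounds + (n_stages - 1,)
    return [(lo + 1, hi) for lo, hi in zip(edges, edges[1:])]


def staged_series_samples(n_stages=12):
    """Stage annotation for a whole-embryo series, ranks 0..n_stages-1."""
    if n_stages == 12:
        names = MOUSE_STAGES
    else:
        names = tuple(f"stage{i:02d}" for i in range(n_stages))
    rows = []
    for rank, stage in enumerate(names):
        group = (
            ("preimplantation" if rank <= 6 else "postimplantation")
            if n_stages == 12
            else "series"
        )
        rows.append((stage, "developmental_stage", group, rank))
    table = pd.DataFrame(rows, columns=["sample_id", "category", "group", "temporal_rank"])
    return validate_sample_annotations(table)


def generate_staged_series(specs=None, n_stages=12, boundaries=(1, 2, 6), seed=0,
                           threshold=2.0, background_high=1.5):
    """Generate a stage-ordered series with planted temporal phases.

    Each temporal archetype is expressed only within its phase interval,
    so at zero noise the expressed-gene set is constant within a phase
    and turns over completely at each planted boundary. Deterministic
    for a given ``(specs, boundaries, seed)``.
    """
    sample_ann = staged_series_samples(n_stages)
    intervals = _phase_intervals(boundaries, n_stages)
    if specs is None:
        stage_names = tuple(sample_ann.index)
        if len(intervals) == 4:
            specs = mouse_series_specs(stage_names, boundaries)
        else:
            per_phase = max(1, 258 // len(intervals))
            specs = [
                ArchetypeSpec(
                    name="phase", label=f"phase_{i + 1}", n_genes=per_phase,
                    class_mix={"ANTP": 1, "PRD": 1},
                    support_samples=tuple(stage_names[lo : hi + 1]),
                )
                for i, (lo, hi) in enumerate(intervals)
            ]
            specs.append(
                ArchetypeSpec(name="silent", label="silent", n_genes=20,
                              class_mix={"ANTP": 1})
            )
    rng = np.random.default_rng(seed)
    matrix, gene_ann, truth = _plant(specs, sample_ann, rng, threshold, background_high)
    return StagedSeries(
        matrix=matrix, gene_ann=gene_ann, sample_ann=sample_ann, truth=truth,
        boundaries=tuple(int(b) for b in boundaries),
    )


def corrupt(matrix, dropout_rate, noise_scale, seed, threshold=2.0):
    """Degrade a matrix with dropout and multiplicative log-normal noise.

    Dropout zeroes each nonzero entry independently with probability
    ``dropout_rate`` (so rate 1 yields an all-zero matrix). Noise
    multiplies each surviving expressed entry (value >= ``threshold``) by
    ``exp(noise_scale * Z)``, Z standard normal — dispersion of detected
    signal; the sub-threshold background floor is already the noise model
    for silent measurements. Noisy expressed values may fall below the
    threshold and be zeroed by downstream calling.
    """
    if not 0 <= dropout_rate <= 1:
        raise ValueError(f"dropout_rate must be in [0, 1], got {dropout_rate}")
    if noise_scale < 0:
        raise ValueError(f"noise_scale must be >= 0, got {noise_scale}")
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float).copy()
    drop = rng.random(X.shape) < dropout_rate
    X[(X > 0) & drop] = 0.0
    noise = np.exp(rng.normal(0.0, 1.0, size=X.shape) * noise_scale)
    expressed = X >= threshold
    X[expressed] *= noise[expressed]
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
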