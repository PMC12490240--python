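"""Simulation configuration for synthetic MCL cohorts.

The generator plants ground truth for every downstream stage: malignant B
cells carrying clonal BCRs with a fixed light chain, CCND1 overexpression,
multiplicative copy-number segments, non-malignant immune populations,
longitudinal clone trees with per-sample cancer-cell fractions, and
multi-caller somatic variant tables with caller-specific error profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

MIXTURE_TYPES = ("malignantB", "normalB", "T", "NK", "myeloid")


@dataclass
class ClonotypeSpec:
    """One planted malignant BCR clonotype.

    ``fractions`` gives, per sample, the fraction of *malignant* cells that
    carry this clonotype; fractions must sum to 1 across clonotypes in every
    sample. ``shm_count`` is the number of nucleotide substitutions planted
    into the germline IGHV sequence.
    """

    clonotype_id: str
    heavy_v: str
    heavy_j: str
    heavy_cdr3_aa: str
    light_v: str
    light_j: str
    light_cdr3_aa: str
    light_chain: str  # "kappa" | "lambda"
    shm_count: int
    fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class CnvSegmentSpec:
    """A planted copy-number segment acting multiplicatively on expression.

    ``chrom`` plus ``start_gene``/``n_genes`` select a contiguous run of
    genes in genome order on that chromosome (``n_genes=None`` takes the
    whole chromosome). ``copy_ratio`` multiplies the negative-binomial mean
    of those genes in affected cells; ``clonotypes`` restricts the segment
    to cells of the listed clonotypes (None = all malignant cells).
    """

    chrom: str
    start_gene: int
    n_genes: Optional[int]
    copy_ratio: float
    clonotypes: Optional[list[str]] = None


@dataclass
class CallerProfile:
    name: str
    sensitivity: float = 0.9
    fp_rate: float = 1e-6  # false positives per basepair of callable genome


@dataclass
class CloneTreeSpec:
    """Planted clonal architecture: parent map + per-sample CCFs.

    ``parents`` maps clone id -> parent clone id (root maps to None).
    ``ccf`` maps sample -> {clone: ccf}; the values must satisfy the sum
    rule (parent CCF >= sum of child CCFs in every sample).
    """

    parents: dict[str, Optional[str]] = field(default_factory=dict)
    ccf: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def root(self) -> str:
        roots = [c for c, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"clone tree must have exactly one root, got {roots}")
        return roots[0]

    def validate(self, epsilon: float = 1e-6) -> None:
        if not self.parents:
            raise ValueError("empty clone tree")
        root = self.root
        children: dict[str, list[str]] = {c: [] for c in self.parents}
        for c, p in self.parents.items():
            if p is not None:
                if p not in self.parents:
                    raise ValueError(f"unknown parent {p!r} of clone {c!r}")
                children[p].append(c)
        for sample, ccfs in self.ccf.items():
            missing = set(self.parents) - set(ccfs)
            if missing:
                raise ValueError(f"sample {sample}: missing CCFs for {sorted(missing)}")
            for clone, kids in children.items():
                if kids and sum(ccfs[k] for k in kids) > ccfs[clone] + epsilon:
                    raise ValueError(
                        f"sum rule violated in sample {sample} at clone {clone}"
                    )
        if abs(max(self.ccf[s][root] for s in self.ccf) - 0.0) < 1e-12:
            raise ValueError("root clone has zero CCF in all samples")


@dataclass
class QcNoiseSpec:
    """Fractions (of the nominal cell count) of planted QC-failing cells."""

    low_gene: float = 0.02
    high_mito: float = 0.02
    doublet: float = 0.03


@dataclass
class SimulationConfig:
    n_samples: int = 3
    sample_ids: Optional[list[str]] = None
    n_cells: int = 2000
    mixture: dict[str, float] = field(
        default_factory=lambda: {
            "malignantB": 0.40,
            "normalB": 0.15,
            "T": 0.30,
            "NK": 0.10,
            "myeloid": 0.05,
        }
    )
    n_genes: int = 2000
    n_chromosomes: int = 22
    nb_dispersion: float = 10.0
    baseline_mean_log: float = -0.7
    baseline_sigma: float = 1.2
    marker_mean: float = 6.0
    ccnd1_fold: float = 4.0
    ccnd1_base_mean: float = 0.8
    clonotypes: list[ClonotypeSpec] = field(default_factory=list)
    cnv_segments: list[CnvSegmentSpec] = field(default_factory=list)
    clone_tree: Optional[CloneTreeSpec] = None
    variants_per_clone: int = 50
    purity: dict[str, float] = field(default_factory=dict)
    depth: float = 200.0
    caller_profiles: list[CallerProfile] = field(default_factory=list)
    n_panel_samples: int = 10
    n_panel_artifacts: int = 5
    genome_size: float = 3.0e7
    bcr_capture: float = 0.9
    normal_kappa_fraction: float = 0.6
    qc_noise: QcNoiseSpec = field(default_factory=QcNoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length must equal n_samples")
        total = sum(self.mixture.get(t, 0.0) for t in MIXTURE_TYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell-type mixture must sum to 1, got {total}")
        if any(v < 0 or v > 1 for v in self.mixture.values()):
            raise ValueError("mixture proportions must lie in [0, 1]")
        if self.ccnd1_fold < 1.0:
            raise ValueError("ccnd1_fold must be >= 1")
        for seg in self.cnv_segments:
            if seg.n_genes is not None and seg.n_genes > self.n_genes:
                raise ValueError("CNV segment longer than the gene panel")
        if self.clonotypes:
            for s in self.sample_ids:
                tot = sum(ct.fractions.get(s, 0.0) for ct in self.clonotypes)
                if tot > 1.0 + 1e-9:
                    raise ValueError(f"clonotype fractions exceed 1 in sample {s}")
        if self.clone_tree is not None:
            self.clone_tree.validate()
        if not self.purity:
            self.purity = {s: 0.8 for s in self.sample_ids}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        if "clonotypes" in raw:
            raw["clonotypes"] = [ClonotypeSpec(**c) for c in raw["clonotypes"]]
        if "cnv_segments" in raw:
            raw["cnv_segments"] = [CnvSegmentSpec(**c) for c in raw["cnv_segments"]]
        if raw.get("clone_tree") is not None:
            raw["clone_tree"] = CloneTreeSpec(**raw["clone_tree"])
        if "caller_profiles" in raw:
            raw["caller_profiles"] = [CallerProfile(**c) for c in raw["caller_profiles"]]
        if "qc_noise" in raw:
            raw["qc_noise"] = QcNoiseSpec(**raw["qc_noise"])
        return cls(**raw)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions: a 3-sample longitudinal cohort.

    Three samples of one patient (primary and two follow-ups), 2,000 cells
    and 2,000 genes each, two dominant kappa-restricted malignant clonotypes,
    a whole-chromosome gain (chr3, ratio 2.0, all malignant cells) and a
    clonotype-restricted loss (chr9, ratio 0.5, clonotype ct1), CCND1 4-fold
    overexpression, a 4-clone tree with shifting CCFs, WGS depth 200x, and
    five callers at sensitivity 0.9.
    """
    clonotypes = [
        ClonotypeSpec(
            clonotype_id="ct1",
            heavy_v="IGHV3-21",
            heavy_j="IGHJ4",
            heavy_cdr3_aa="CARDLRGYFDYW",
            light_v="IGKV4-1",
            light_j="IGKJ1",
            light_cdr3_aa="CQQYYSTPRTF",
            light_chain="kappa",
            shm_count=2,
            fractions={"S1": 0.70, "S2": 0.55, "S3": 0.45},
        ),
        ClonotypeSpec(
            clonotype_id="ct2",
            heavy_v="IGHV4-34",
            heavy_j="IGHJ6",
            heavy_cdr3_aa="CARGGVVTDYYGMDVW",
            light_v="IGKV1-39",
            light_j="IGKJ2",
            light_cdr3_aa="CQQSYSTPLTF",
            light_chain="kappa",
            shm_count=0,
            fractions={"S1": 0.30, "S2": 0.45, "S3": 0.55},
        ),
    ]
    segments = [
        CnvSegmentSpec(chrom="chr3", start_gene=0, n_genes=None, copy_ratio=2.0),
        CnvSegmentSpec(
            chrom="chr9", start_gene=0, n_genes=None, copy_ratio=0.5,
            clonotypes=["ct1"],
        ),
    ]
    tree = CloneTreeSpec(
        parents={"c1": None, "c2": "c1", "c3": "c1", "c4": "c2"},
        ccf={
            "S1": {"c1": 1.0, "c2": 0.60, "c3": 0.30, "c4": 0.00},
            "S2": {"c1": 1.0, "c2": 0.70, "c3": 0.20, "c4": 0.40},
            "S3": {"c1": 1.0, "c2": 0.25, "c3": 0.60, "c4": 0.15},
        },
    )
    callers = [
        CallerProfile("lancet"),
        CallerProfile("strelka2"),
        CallerProfile("muse"),
        CallerProfile("mutect2"),
        CallerProfile("somaticsniper"),
    ]
    cfg = dict(
        clonotypes=clonotypes,
        cnv_segments=segments,
        clone_tree=tree,
        caller_profiles=callers,
        purity={"S1": 0.8, "S2": 0.7, "S3": 0.75},
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)
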