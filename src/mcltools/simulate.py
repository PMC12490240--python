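"""Synthetic multi-sample MCL cohort generator with planted ground truth.

Generates the four input families the analysis pipeline consumes:

* sparse 10x-style count matrices with malignant B cells (clonal BCR, fixed
  light chain, CCND1 overexpression, multiplicative CNV segments),
  non-malignant immune populations and planted QC-failing cells;
* AIRR-style scBCR rearrangement tables with germline-anchored somatic
  hypermutation;
* per-caller somatic variant tables driven by a planted clone tree with
  per-sample CCFs, plus a germline panel, per-sample pileups and bulk WGS
  copy-number segments;
* the gene annotation table (chromosome, position, GDI, bulk FPKM).

Counts follow a per-gene negative binomial (gamma-Poisson) with shared
dispersion; CNV acts multiplicatively on the NB mean, which is what
window-smoothing of relative expression detects downstream. All randomness
derives from ``config.seed`` via ``numpy.random.SeedSequence`` spawning, so
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SimulationConfig, CloneTreeSpec

NUCLEOTIDES = np.array(list("ACGT"))
AA_ALPHABET = list("ACDEFGHIKLMNPQRSTVWY")

# (symbol, chromosome) for genes with a role in the pipeline; positions on
# the synthetic genome, not real coordinates.
_SPECIAL_GENES = [
    ("CD19", "chr16"), ("MS4A1", "chr11"), ("CD79A", "chr19"),
    ("CD3D", "chr11"), ("CD3E", "chr11"), ("CD3G", "chr11"),
    ("CD4", "chr12"), ("CD8A", "chr2"),
    ("XCL2", "chr1"), ("NKG7", "chr19"), ("GNLY", "chr2"),
    ("CD68", "chr17"), ("CD33", "chr19"), ("CST3", "chr20"),
    ("HBQ1", "chr16"), ("HBM", "chr16"), ("GYPA", "chr4"),
    ("CCND1", "chr11"), ("ATM", "chr11"),
    ("CD40", "chr20"), ("CD40LG", "chr21"), ("CD70", "chr19"), ("CD27", "chr12"),
    ("IGKC", "chr2"),
    ("IGLC1", "chr22"), ("IGLC2", "chr22"), ("IGLC3", "chr22"),
    ("IGLC4", "chr22"), ("IGLC5", "chr22"), ("IGLC6", "chr22"),
    ("IGLC7", "chr22"), ("IGHM", "chr14"),
]
_MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
]
_RIBO_GENES = [f"RPL{i}" for i in range(1, 21)] + [f"RPS{i}" for i in range(1, 21)]

_IG_PREFIXES = ("IGK", "IGL", "IGH")

# expression means for marker genes in their home cell type
_TYPE_MARKERS = {
    "B": ["CD19", "MS4A1", "CD79A", "CD40", "IGHM"],
    "T": ["CD3D", "CD3E", "CD3G", "CD4", "CD8A", "CD40LG", "CD27"],
    "NK": ["XCL2", "NKG7", "GNLY"],
    "myeloid": ["CD68", "CD33", "CST3"],
}

_GENE_SPAN = 1_000  # bp per gene body on the synthetic genome
_GENE_STEP = 100_000  # spacing of gene starts


@dataclass
class GroundTruth:
    """Planted truth for one simulated cohort.

    Every simulated cell and variant appears exactly once; the tables
    round-trip through JSON serialization.
    """

    cells: pd.DataFrame  # index cell_id: sample, cell_type, clonotype_id, light_chain, qc_class
    gene_panel: pd.DataFrame  # index gene: chrom, start, gdi, fpkm, flags
    clonotypes: pd.DataFrame
    cnv_genes: pd.DataFrame  # per (clonotype, gene) planted copy ratio != 1
    variants: Optional[pd.DataFrame] = None
    clone_tree: Optional[CloneTreeSpec] = None

    def to_json(self, path) -> None:
        def frame(df):
            return None if df is None else json.loads(df.to_json(orient="split"))

        payload = {
            "cells": frame(self.cells),
            "gene_panel": frame(self.gene_panel),
            "clonotypes": frame(self.clonotypes),
            "cnv_genes": frame(self.cnv_genes),
            "variants": frame(self.variants),
            "clone_tree": None
            if self.clone_tree is None
            else {"parents": self.clone_tree.parents, "ccf": self.clone_tree.ccf},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)

        def unframe(obj):
            if obj is None:
                return None
            return pd.DataFrame(
                obj["data"], index=obj["index"], columns=obj["columns"]
            )

        tree = payload["clone_tree"]
        return cls(
            cells=unframe(payload["cells"]),
            gene_panel=unframe(payload["gene_panel"]),
            clonotypes=unframe(payload["clonotypes"]),
            cnv_genes=unframe(payload["cnv_genes"]),
            variants=unframe(payload["variants"]),
            clone_tree=None
            if tree is None
            else CloneTreeSpec(parents=tree["parents"], ccf=tree["ccf"]),
        )


# ---------------------------------------------------------------------------
# gene panel


def build_gene_panel(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene annotation table for a config.

    Genes are laid out in genome order over ``n_chromosomes`` autosomes plus
    chrMT, with fixed marker/immunoglobulin/mitochondrial/ribosomal genes on
    their (synthetic) home chromosomes and numbered filler genes spread
    evenly. GDI and bulk FPKM are drawn from lognormals seeded independently
    of the expression noise; a handful of filler genes are forced above the
    GDI and below the FPKM filter thresholds so the variant cascade has
    something to remove.
    """
    special = list(_SPECIAL_GENES)
    special += [(g, "chrMT") for g in _MITO_GENES]
    n_fill = config.n_genes - len(special) - len(_RIBO_GENES)
    if n_fill < 0:
        raise ValueError("n_genes too small for the fixed gene panel")
    chroms = [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]
    rows = []
    for i in range(n_fill):
        rows.append((f"G{i + 1:04d}", chroms[i % len(chroms)]))
    for i, g in enumerate(_RIBO_GENES):
        rows.append((g, chroms[(n_fill + i) % len(chroms)]))
    rows.extend(special)

    df = pd.DataFrame(rows, columns=["gene", "chrom"])
    order = {c: i for i, c in enumerate(chroms + ["chrMT"])}
    df["chrom_rank"] = df["chrom"].map(order)
    df = df.sort_values(["chrom_rank", "gene"], kind="stable").reset_index(drop=True)
    df["start"] = df.groupby("chrom").cumcount() * _GENE_STEP + 1
    df["end"] = df["start"] + _GENE_SPAN - 1

    df["is_mito"] = df["gene"].str.startswith("MT-")
    df["is_ribo"] = df["gene"].str.startswith(("RPL", "RPS"))
    df["is_ig"] = df["gene"].str.startswith(_IG_PREFIXES)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9001]))
    df["gdi"] = np.round(rng.lognormal(np.log(300.0), 0.8, len(df)), 1)
    df["fpkm"] = np.round(rng.lognormal(np.log(5.0), 1.0, len(df)), 3)
    filler = df.index[df["gene"].str.startswith("G")]
    df.loc[filler[:5], "gdi"] = 3000.0  # noise-prone genes for the GDI filter
    df.loc[filler[5:10], "fpkm"] = 0.1  # unexpressed genes for the FPKM filter
    df.loc[df["gene"] == "ATM", "gdi"] = 2500.0  # high-GDI but kept by exception
    df.loc[df["gene"] == "ATM", "fpkm"] = 8.0

    df = df.drop(columns="chrom_rank").set_index("gene")
    return df


def _segment_gene_mask(config: SimulationConfig, panel: pd.DataFrame, seg) -> np.ndarray:
    on_chrom = np.flatnonzero((panel["chrom"] == seg.chrom).to_numpy())
    n = len(on_chrom) - seg.start_gene if seg.n_genes is None else seg.n_genes
    if seg.start_gene + n > len(on_chrom):
        raise ValueError(
            f"CNV segment exceeds {seg.chrom} ({len(on_chrom)} genes available)"
        )
    mask = np.zeros(len(panel), dtype=bool)
    mask[on_chrom[seg.start_gene : seg.start_gene + n]] = True
    return mask


# ---------------------------------------------------------------------------
# cell assignment (shared between expression and BCR generators)


def _assign_cells(config: SimulationConfig) -> pd.DataFrame:
    """Per-cell sample, type, clonotype and QC-noise class, seed-stable."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    types = list(config.mixture)
    probs = np.array([config.mixture[t] for t in types])
    records = []
    for sample in config.sample_ids:
        n_by_type = rng.multinomial(config.n_cells, probs)
        base_types = np.repeat(types, n_by_type)
        rng.shuffle(base_types)
        qc = np.array(["pass"] * len(base_types), dtype=object)
        extra_types, extra_qc = [], []
        for cls, frac in (
            ("low_gene", config.qc_noise.low_gene),
            ("high_mito", config.qc_noise.high_mito),
            ("doublet", config.qc_noise.doublet),
        ):
            n_extra = int(round(frac * config.n_cells))
            for _ in range(n_extra):
                if cls == "doublet":
                    extra_types.append("doublet")
                else:
                    extra_types.append(rng.choice(types, p=probs))
                extra_qc.append(cls)
        all_types = np.concatenate([base_types, np.array(extra_types, dtype=object)])
        all_qc = np.concatenate([qc, np.array(extra_qc, dtype=object)])
        for i, (t, q) in enumerate(zip(all_types, all_qc)):
            records.append((f"{sample}:BC{i + 1:05d}", sample, t, q))
    cells = pd.DataFrame(
        records, columns=["cell_id", "sample", "cell_type", "qc_class"]
    ).set_index("cell_id")

    # clonotype assignment for malignant cells (doublets inherit one too:
    # their B component is a malignant cell)
    cells["clonotype_id"] = None
    cells["light_chain"] = None
    if config.clonotypes:
        for sample in config.sample_ids:
            in_sample = cells["sample"] == sample
            mal = in_sample & cells["cell_type"].isin(["malignantB", "doublet"])
            idx = cells.index[mal]
            fr = np.array([ct.fractions.get(sample, 0.0) for ct in config.clonotypes])
            if fr.sum() <= 0:
                continue
            fr = fr / fr.sum()
            choice = rng.choice(len(config.clonotypes), size=len(idx), p=fr)
            cells.loc[idx, "clonotype_id"] = [
                config.clonotypes[c].clonotype_id for c in choice
            ]
            cells.loc[idx, "light_chain"] = [
                config.clonotypes[c].light_chain for c in choice
            ]
    normal_b = cells.index[cells["cell_type"] == "normalB"]
    kappa = rng.random(len(normal_b)) < config.normal_kappa_fraction
    cells.loc[normal_b, "light_chain"] = np.where(kappa, "kappa", "lambda")
    return cells


# ---------------------------------------------------------------------------
# expression


def generate_expression(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate the cohort count matrix.

    Returns an :class:`anndata.AnnData` with raw integer counts in ``.X``
    (CSR), per-cell metadata in ``.obs`` (sample, barcode) and the gene
    annotation in ``.var``, plus the :class:`GroundTruth`.
    """
    panel = build_gene_panel(config)
    cells = _assign_cells(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_genes = len(panel)
    genes = panel.index.to_numpy()
    gene_idx = {g: i for i, g in enumerate(genes)}

    base = np.ones(n_genes)
    filler_mask = panel.index.str.startswith("G")
    base[filler_mask] = rng.lognormal(
        config.baseline_mean_log, config.baseline_sigma, int(filler_mask.sum())
    )
    base[panel["is_mito"].to_numpy()] = 11.0
    base[panel["is_ribo"].to_numpy()] = 11.0
    for g in [s for s, _ in _SPECIAL_GENES]:
        base[gene_idx[g]] = 0.05
    base[gene_idx["ATM"]] = 1.0
    base[gene_idx["CCND1"]] = config.ccnd1_base_mean

    def type_means(cell_type: str) -> np.ndarray:
        mu = base.copy()
        home = {"malignantB": "B", "normalB": "B"}.get(cell_type, cell_type)
        for g in _TYPE_MARKERS.get(home, []):
            mu[gene_idx[g]] = config.marker_mean
        if cell_type == "malignantB":
            mu[gene_idx["CCND1"]] = config.ccnd1_base_mean * config.ccnd1_fold
            mu[gene_idx["CD70"]] = 3.0
        return mu

    mu_by_type = {t: type_means(t) for t in ["malignantB", "normalB", "T", "NK", "myeloid"]}

    iglc = [f"IGLC{i}" for i in range(1, 8)]

    def light_chain_means(mu: np.ndarray, chain: Optional[str]) -> None:
        if chain == "kappa":
            mu[gene_idx["IGKC"]] = 40.0
        elif chain == "lambda":
            mu[gene_idx["IGLC1"]] = 30.0
            mu[gene_idx["IGLC2"]] = 8.0

    seg_masks = [_segment_gene_mask(config, panel, s) for s in config.cnv_segments]

    def cnv_multiplier(clonotype: Optional[str]) -> np.ndarray:
        mult = np.ones(n_genes)
        for seg, mask in zip(config.cnv_segments, seg_masks):
            if seg.clonotypes is None or clonotype in seg.clonotypes:
                mult[mask] *= seg.copy_ratio
        return mult

    mito_mask = panel["is_mito"].to_numpy()
    theta = config.nb_dispersion

    blocks = []
    for sample in config.sample_ids:
        sub = cells[cells["sample"] == sample]
        mu = np.empty((len(sub), n_genes))
        rows_by_type = {t: np.flatnonzero((sub["cell_type"] == t).to_numpy())
                        for t in mu_by_type}
        for t, rows in rows_by_type.items():
            mu[rows] = mu_by_type[t]
        for pos, (cid, row) in enumerate(sub.iterrows()):
            ctype = row["cell_type"]
            if ctype == "doublet":
                b = mu_by_type["malignantB"].copy()
                light_chain_means(b, row["light_chain"])
                b *= cnv_multiplier(row["clonotype_id"])
                mu[pos] = b + mu_by_type["T"]
                continue
            if row["light_chain"] is not None:
                mu[pos] = mu[pos].copy()
                light_chain_means(mu[pos], row["light_chain"])
            if ctype == "malignantB":
                mu[pos] = mu[pos] * cnv_multiplier(row["clonotype_id"])
            if row["qc_class"] == "high_mito":
                mu[pos] = mu[pos].copy()
                mu[pos, mito_mask] *= 8.0
            elif row["qc_class"] == "low_gene":
                mu[pos] = mu[pos] * 0.04
        size = rng.lognormal(0.0, 0.15, len(sub))
        mu *= size[:, None]
        lam = rng.gamma(theta, mu / theta)
        counts = rng.poisson(lam).astype(np.int32)
        blocks.append((sub.index.to_numpy(), sp.csr_matrix(counts)))

    X = sp.vstack([b for _, b in blocks], format="csr")
    obs_index = np.concatenate([ids for ids, _ in blocks])
    obs = pd.DataFrame(index=pd.Index(obs_index, name="cell_id"))
    obs["sample"] = cells.loc[obs_index, "sample"].to_numpy()
    obs["barcode"] = [c.split(":", 1)[1] for c in obs_index]
    adata = ad.AnnData(X=X, obs=obs, var=panel.copy())

    cnv_rows = []
    for seg, mask in zip(config.cnv_segments, seg_masks):
        targets = (
            [ct.clonotype_id for ct in config.clonotypes]
            if seg.clonotypes is None and config.clonotypes
            else (seg.clonotypes or ["*"])
        )
        for ct in targets:
            for g in genes[mask]:
                cnv_rows.append((ct, g, seg.copy_ratio))
    truth = GroundTruth(
        cells=cells,
        gene_panel=panel,
        clonotypes=clonotype_table(config),
        cnv_genes=pd.DataFrame(cnv_rows, columns=["clonotype_id", "gene", "copy_ratio"]),
        clone_tree=config.clone_tree,
    )
    return adata, truth


def clonotype_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for ct in config.clonotypes:
        for sample in config.sample_ids:
            rows.append(
                (
                    ct.clonotype_id,
                    sample,
                    ct.heavy_v,
                    ct.heavy_j,
                    ct.heavy_cdr3_aa,
                    ct.light_v,
                    ct.light_j,
                    ct.light_cdr3_aa,
                    ct.light_chain,
                    ct.shm_count,
                    ct.fractions.get(sample, 0.0),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "clonotype_id", "sample", "heavy_v", "heavy_j", "heavy_cdr3_aa",
            "light_v", "light_j", "light_cdr3_aa", "light_chain",
            "shm_count", "fraction_malignant",
        ],
    )


# ---------------------------------------------------------------------------
# BCR


def germline_ighv(v_call: str, length: int = 300) -> str:
    """Deterministic pseudo-germline nucleotide sequence for a V gene name."""
    rng = np.random.default_rng(zlib.crc32(v_call.encode()))
    return "".join(rng.choice(NUCLEOTIDES, length))


def write_germline_fasta(v_calls, path) -> None:
    with open(path, "w") as fh:
        for v in sorted(set(v_calls)):
            fh.write(f">{v}\n{germline_ighv(v)}\n")


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    if n_mut > len(seq):
        raise ValueError("SHM count exceeds IGHV length")
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        options = [b for b in "ACGT" if b != arr[p]]
        arr[p] = options[rng.integers(3)]
    return "".join(arr)


def generate_bcr(config: SimulationConfig, cells: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Simulate the AIRR-style rearrangement table for the cohort's B cells.

    Cells are the same ones :func:`generate_expression` produces (shared
    seed stream). Malignant cells carry their planted clonotype with the
    configured SHM count against the stored germline IGHV; normal B cells
    get pairwise-distinct background clonotypes. A configured fraction of
    cells is captured at all; small fractions of unpaired and non-productive
    contigs exercise the quality filters downstream.
    """
    if cells is None:
        cells = _assign_cells(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ct_by_id = {ct.clonotype_id: ct for ct in config.clonotypes}

    clono_heavy_seq = {}
    for ct in config.clonotypes:
        sub_rng = np.random.default_rng(
            zlib.crc32(f"{ct.clonotype_id}|{ct.heavy_v}".encode())
        )
        clono_heavy_seq[ct.clonotype_id] = _mutate(
            germline_ighv(ct.heavy_v), ct.shm_count, sub_rng
        )

    bg_v_pool = [f"IGHV{f}-{n}" for f, n in
                 [(1, 2), (1, 69), (2, 5), (3, 7), (3, 23), (3, 30), (4, 39),
                  (4, 59), (5, 51), (6, 1)]]
    rows = []
    bcr_cells = cells[cells["cell_type"].isin(["malignantB", "normalB", "doublet"])]
    seen_bg = set()
    for cell_id, row in bcr_cells.iterrows():
        if rng.random() > config.bcr_capture:
            continue
        unpaired = rng.random() < 0.03
        nonproductive = (not unpaired) and rng.random() < 0.02
        if row["clonotype_id"] is not None:
            ct = ct_by_id[row["clonotype_id"]]
            heavy = (ct.heavy_v, ct.heavy_j, ct.heavy_cdr3_aa,
                     clono_heavy_seq[ct.clonotype_id])
            light_locus = "IGK" if ct.light_chain == "kappa" else "IGL"
            light = (ct.light_v, ct.light_j, ct.light_cdr3_aa)
        else:
            v = bg_v_pool[rng.integers(len(bg_v_pool))]
            while True:
                cdr3 = "C" + "".join(
                    np.array(AA_ALPHABET)[rng.integers(0, 20, 11)]
                ) + "W"
                if cdr3 not in seen_bg:
                    seen_bg.add(cdr3)
                    break
            shm = int(rng.integers(0, 16))
            seq = _mutate(germline_ighv(v), shm, rng)
            heavy = (v, f"IGHJ{rng.integers(1, 7)}", cdr3, seq)
            if row["light_chain"] == "kappa":
                light_locus = "IGK"
                light = (f"IGKV1-{rng.integers(2, 40)}", "IGKJ1",
                         "CQQ" + "".join(np.array(AA_ALPHABET)[rng.integers(0, 20, 6)]) + "F")
            else:
                light_locus = "IGL"
                light = (f"IGLV2-{rng.integers(2, 24)}", "IGLJ2",
                         "CSS" + "".join(np.array(AA_ALPHABET)[rng.integers(0, 20, 6)]) + "F")
        rows.append(
            dict(cell_id=cell_id, sample=row["sample"], locus="IGH",
                 v_call=heavy[0], j_call=heavy[1], cdr3_aa=heavy[2],
                 sequence=heavy[3], productive=not nonproductive,
                 complete_vdj=True, high_confidence=True)
        )
        if not unpaired:
            rows.append(
                dict(cell_id=cell_id, sample=row["sample"], locus=light_locus,
                     v_call=light[0], j_call=light[1], cdr3_aa=light[2],
                     sequence=germline_ighv(light[0]), productive=True,
                     complete_vdj=True, high_confidence=True)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# somatic variants


def expected_vaf(ccf: float, purity: float, copy_number: float = 2.0,
                 multiplicity: float = 1.0) -> float:
    """Expected VAF of a mutation at the given CCF, purity and local CN."""
    denom = purity * copy_number + (1.0 - purity) * 2.0
    return purity * ccf * multiplicity / denom


def generate_variant_tables(config: SimulationConfig) -> dict:
    """Simulate per-caller somatic variant tables plus all side inputs.

    Returns a dict with keys ``calls`` (per-sample per-caller long table),
    ``panel`` (germline-panel VAF table), ``pileup`` (per-sample high-quality
    depth/alt counts at every candidate position), ``wgs_segments`` (bulk
    copy-number segments incl. an immunoglobulin-locus segment that the
    cascade must discard), ``ig_loci`` (1-based inclusive Ig intervals),
    ``truth`` (planted variants with clone, per-sample CCF and category).

    True-variant VAFs are Binomial(depth, purity*CCF*mult / ploidy-adjusted
    denominator)/depth draws; each caller detects a present variant with its
    configured sensitivity (requiring >=2 alt reads) and contributes false
    positives at ``fp_rate`` per bp of ``genome_size``. Panel artifacts are
    planted into >30% of germline panel samples and into the tumor tables.
    """
    if config.clone_tree is None:
        raise ValueError("config.clone_tree is required to simulate variants")
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    config.clone_tree.validate()
    panel_genes = build_gene_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    seg_chroms = {s.chrom for s in config.cnv_segments}
    clean = panel_genes[
        (panel_genes["gdi"] <= 2000)
        & (panel_genes["fpkm"] >= 0.5)
        & ~panel_genes["is_ig"] & ~panel_genes["is_mito"] & ~panel_genes["is_ribo"]
        & ~panel_genes["chrom"].isin(seg_chroms)
        & (panel_genes.index != "ATM")
    ]
    high_gdi = panel_genes[(panel_genes["gdi"] > 2000) & (panel_genes.index != "ATM")]
    low_fpkm = panel_genes[panel_genes["fpkm"] < 0.5]

    def draw_site(gene_row):
        pos = int(gene_row["start"] + rng.integers(0, _GENE_SPAN))
        ref = str(rng.choice(NUCLEOTIDES))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return pos, ref, alt

    clones = list(config.clone_tree.parents)
    records = []
    used_sites = set()

    def add_variant(gene_name, gene_row, clone, category):
        while True:
            pos, ref, alt = draw_site(gene_row)
            if (gene_row["chrom"], pos) not in used_sites:
                used_sites.add((gene_row["chrom"], pos))
                break
        records.append(
            dict(chrom=gene_row["chrom"], pos=pos, ref=ref, alt=alt,
                 gene=gene_name, clone=clone, category=category)
        )

    clean_names = clean.index.to_numpy()
    for clone in clones:
        picks = rng.choice(len(clean_names), config.variants_per_clone, replace=False)
        for i in picks:
            add_variant(clean_names[i], clean.loc[clean_names[i]], clone, "true")
    root = config.clone_tree.root
    add_variant("ATM", panel_genes.loc["ATM"], root, "true")  # kept despite GDI>2000
    for i in range(3):
        g = high_gdi.index[i % len(high_gdi)]
        add_variant(g, high_gdi.loc[g], root, "gdi_probe")
    for i in range(2):
        g = low_fpkm.index[i % len(low_fpkm)]
        add_variant(g, low_fpkm.loc[g], root, "fpkm_probe")
    for i in range(config.n_panel_artifacts):
        g = clean_names[rng.integers(len(clean_names))]
        add_variant(g, clean.loc[g], None, "panel_artifact")

    truth = pd.DataFrame(records)
    ccfs = config.clone_tree.ccf
    for sample in config.sample_ids:
        truth[f"ccf_{sample}"] = [
            ccfs[sample][c] if c is not None else np.nan for c in truth["clone"]
        ]

    # pileups: one high-quality depth/alt draw per (variant, sample)
    pile_rows = []
    call_rows = []
    callers = config.caller_profiles
    for sample in config.sample_ids:
        purity = config.purity[sample]
        for _, v in truth.iterrows():
            depth = max(int(rng.poisson(config.depth)), 1)
            if v["category"] == "panel_artifact":
                true_vaf = 0.10
            else:
                true_vaf = expected_vaf(v[f"ccf_{sample}"], purity)
            alt_reads = int(rng.binomial(depth, true_vaf))
            vaf = alt_reads / depth
            pile_rows.append(
                dict(sample=sample, chrom=v["chrom"], pos=v["pos"], ref=v["ref"],
                     alt=v["alt"], depth=depth, alt_depth=alt_reads)
            )
            if alt_reads >= 2:
                for caller in callers:
                    if rng.random() < caller.sensitivity:
                        call_rows.append(
                            dict(sample=sample, chrom=v["chrom"], pos=v["pos"],
                                 ref=v["ref"], alt=v["alt"], caller=caller.name,
                                 vaf=vaf, depth=depth, alt_depth=alt_reads)
                        )
        # caller-private false positives at random positions
        for caller in callers:
            n_fp = rng.poisson(caller.fp_rate * config.genome_size)
            for _ in range(n_fp):
                g = clean_names[rng.integers(len(clean_names))]
                pos, ref, alt = draw_site(clean.loc[g])
                depth = max(int(rng.poisson(config.depth)), 1)
                alt_reads = max(int(rng.binomial(depth, 0.04)), 2)
                call_rows.append(
                    dict(sample=sample, chrom=clean.loc[g, "chrom"], pos=pos,
                         ref=ref, alt=alt, caller=caller.name,
                         vaf=alt_reads / depth, depth=depth, alt_depth=alt_reads)
                )

    # germline panel: artifacts present in >30% of panel samples
    panel_rows = []
    artifact_idx = truth.index[truth["category"] == "panel_artifact"]
    n_present = max(int(np.ceil(0.3 * config.n_panel_samples)) + 1, 1)
    for i in artifact_idx:
        v = truth.loc[i]
        present_in = rng.choice(config.n_panel_samples, n_present, replace=False)
        for p in present_in:
            depth = max(int(rng.poisson(config.depth)), 1)
            alt_reads = max(int(rng.binomial(depth, 0.08)), 1)
            panel_rows.append(
                dict(panel_sample=f"P{p + 1:02d}", chrom=v["chrom"], pos=v["pos"],
                     ref=v["ref"], alt=v["alt"], vaf=alt_reads / depth, depth=depth)
            )
    panel_df = pd.DataFrame(
        panel_rows,
        columns=["panel_sample", "chrom", "pos", "ref", "alt", "vaf", "depth"],
    )

    # bulk WGS segments: planted CNVs (copy number = 2 * ratio), one neutral
    # segment, and an immunoglobulin-locus segment the cascade must drop
    seg_rows = []
    for sample in config.sample_ids:
        for seg in config.cnv_segments:
            mask = _segment_gene_mask(config, panel_genes, seg)
            span = panel_genes[mask]
            seg_rows.append(
                dict(sample=sample, chrom=seg.chrom, start=int(span["start"].min()),
                     end=int(span["end"].max()), copy_number=2.0 * seg.copy_ratio)
            )
        chr1 = panel_genes[panel_genes["chrom"] == "chr1"]
        seg_rows.append(
            dict(sample=sample, chrom="chr1", start=int(chr1["start"].min()),
                 end=int(chr1["end"].max()), copy_number=2.0)
        )
        ighm = panel_genes.loc["IGHM"]
        seg_rows.append(
            dict(sample=sample, chrom=ighm["chrom"], start=int(ighm["start"]),
                 end=int(ighm["end"]), copy_number=3.2)
        )

    return dict(
        calls=pd.DataFrame(call_rows),
        panel=panel_df,
        pileup=pd.DataFrame(pile_rows),
        wgs_segments=pd.DataFrame(seg_rows),
        ig_loci=ig_loci_table(panel_genes),
        truth=truth,
    )


def ig_loci_table(panel_genes: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive genomic intervals of the immunoglobulin loci."""
    rows = []
    for prefix in _IG_PREFIXES:
        sub = panel_genes[panel_genes.index.str.startswith(prefix)]
        for chrom, grp in sub.groupby("chrom"):
            rows.append(dict(locus=prefix, chrom=chrom,
                             start=int(grp["start"].min()), end=int(grp["end"].max())))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted expression programs (for consensus-NMF checks)


def generate_program_data(
    n_cells: int = 300,
    n_genes: int = 300,
    n_programs: int = 3,
    genes_per_program: int = 30,
    program_scale: float = 10.0,
    background: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts drawn from ``Poisson(W @ H)`` with orthogonal planted programs.

    Each program owns ``genes_per_program`` exclusive high-scoring genes and
    each cell is dominated by one program (weight 0.85). Returns
    ``(counts, W_true, H_true)``.
    """
    if n_programs * genes_per_program > n_genes:
        raise ValueError("programs do not fit in the gene panel")
    rng = np.random.default_rng(seed)
    H = np.full((n_programs, n_genes), background)
    for k in range(n_programs):
        H[k, k * genes_per_program : (k + 1) * genes_per_program] = program_scale
    W = np.zeros((n_cells, n_programs))
    owner = rng.integers(0, n_programs, n_cells)
    for i in range(n_cells):
        w = rng.dirichlet(np.ones(n_programs)) * 0.15
        w[owner[i]] += 0.85
        W[i] = w
    counts = rng.poisson(W @ H).astype(np.int32)
    return counts, W, H
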