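"""Somatic-variant consensus and filter cascade over multi-caller tables.

Stages, in the order the cascade applies them:

1. consensus: keep variants called by at least two callers;
2. germline-panel filter: drop variants present (any high-quality alt
   read) in >=30% of the panel's germline samples;
3. paired-sample rescue: a timepoint-specific variant with alt reads in the
   partner sample is relabeled shared; specific status requires partner
   coverage of more than 2 total reads, otherwise it is unassessable;
4. gene-level filters: drop genes with GDI > 2000 (ATM exempt) and genes
   with mean bulk FPKM < 0.5;
5. recurrence: a gene is reportable when nonsilently mutated in >= 2
   patients, or in one patient but previously reported.

Every stage appends a replayable record (dropped keys / relabels) to the
set's filter trail; no stage ever adds a variant key. Bulk WGS segments
are classified amplified (>= 2.3 copies) / deleted (<= 1.7) with
immunoglobulin-locus segments removed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KEY_COLS = ["chrom", "pos", "ref", "alt"]
GDI_MAX = 2000.0
GDI_EXEMPT = {"ATM"}
FPKM_MIN = 0.5
PANEL_FRACTION = 0.3
RESCUE_MIN_READS = 2  # partner coverage must be strictly greater
CN_AMP = 2.3
CN_DEL = 1.7


@dataclass
class ConsensusSet:
    """Filtered consensus variants plus the ordered, replayable filter trail."""

    variants: pd.DataFrame  # one row per (sample, chrom, pos, ref, alt)
    trail: list[dict] = field(default_factory=list)

    def keys(self) -> set[tuple]:
        return set(map(tuple, self.variants[KEY_COLS].itertuples(index=False)))

    def _log(self, name: str, before: pd.DataFrame, after: pd.DataFrame, **params):
        dropped = sorted(
            set(map(tuple, before[["sample"] + KEY_COLS].itertuples(index=False)))
            - set(map(tuple, after[["sample"] + KEY_COLS].itertuples(index=False)))
        )
        self.trail.append(
            dict(filter=name, params=params, n_before=len(before),
                 n_after=len(after), dropped=dropped)
        )


def consensus_calls(calls: pd.DataFrame, min_callers: int = 2) -> ConsensusSet:
    """Merge per-caller tables; retain variants called by >= 2 callers.

    ``calls`` is a long table (sample, chrom, pos, ref, alt, caller, vaf,
    depth[, alt_depth]); duplicate (sample, key, caller) rows are
    deduplicated with a warning. SNVs and indels are treated identically.
    """
    df = calls.copy()
    dup = df.duplicated(subset=["sample", "caller"] + KEY_COLS)
    if dup.any():
        warnings.warn(f"deduplicated {int(dup.sum())} duplicate caller rows")
        df = df[~dup]
    agg = {"vaf": "median", "depth": "median"}
    if "alt_depth" in df.columns:
        agg["alt_depth"] = "median"
    grouped = df.groupby(["sample"] + KEY_COLS, sort=True)
    out = grouped.agg(agg).reset_index()
    out["callers"] = grouped["caller"].apply(lambda s: tuple(sorted(s))).to_numpy()
    out["n_callers"] = out["callers"].map(len)
    kept = out[out["n_callers"] >= min_callers].reset_index(drop=True)
    cs = ConsensusSet(variants=kept)
    cs.trail.append(
        dict(filter="consensus", params={"min_callers": min_callers},
             n_before=len(out), n_after=len(kept),
             dropped=sorted(
                 set(map(tuple, out[["sample"] + KEY_COLS].itertuples(index=False)))
                 - set(map(tuple, kept[["sample"] + KEY_COLS].itertuples(index=False)))
             ))
    )
    return cs


def germline_panel_filter(
    cs: ConsensusSet,
    panel: pd.DataFrame,
    n_panel_samples: int | None = None,
    strict: bool = False,
) -> ConsensusSet:
    """Drop variants seen in too many germline panel samples.

    Presence in a panel sample means at least one high-quality alt read
    (VAF > 0); positions missing from the panel are treated as absent. The
    default drops a variant present in >= ceil(0.3 * N) samples (3-of-10
    for the default 10-sample panel); ``strict=True`` requires strictly
    more than 30%.
    """
    before = cs.variants
    if n_panel_samples is None:
        n_panel_samples = panel["panel_sample"].nunique() if len(panel) else 0
    if n_panel_samples < 2:
        warnings.warn("germline panel too small; set unchanged")
        out = before.copy()
        new = ConsensusSet(out, list(cs.trail))
        new._log("germline_panel", before, out, n_panel=n_panel_samples)
        return new
    present = panel[panel["vaf"] > 0]
    counts = (
        present.groupby(KEY_COLS)["panel_sample"].nunique()
        if len(present)
        else pd.Series(dtype=int)
    )
    if strict:
        bad = set(counts.index[counts > PANEL_FRACTION * n_panel_samples])
    else:
        bad = set(counts.index[counts >= math.ceil(PANEL_FRACTION * n_panel_samples)])
    keys = list(map(tuple, before[KEY_COLS].itertuples(index=False)))
    keep = np.array([k not in bad for k in keys])
    out = before[keep].reset_index(drop=True)
    new = ConsensusSet(out, list(cs.trail))
    new._log("germline_panel", before, out,
             n_panel=n_panel_samples, strict=strict)
    return new


def rescue_paired(
    cs: ConsensusSet,
    pileup: pd.DataFrame,
    pair: tuple[str, str],
) -> ConsensusSet:
    """Timepoint-specific vs shared status for a primary/relapse pair.

    For each variant key present in only one of the two samples, the
    partner's high-quality pileup decides: alt reads observed -> relabeled
    ``shared``; no alt reads with total reads > 2 -> confirmed
    ``{sample}_specific``; partner coverage <= 2 or missing ->
    ``unassessable``. Only labels change; no variant key is added or
    removed.
    """
    a, b = pair
    before = cs.variants
    out = before.copy()
    pile = pileup.set_index(["sample"] + KEY_COLS)
    sub = out[out["sample"].isin(pair)]
    by_key: dict[tuple, set] = {}
    for row in sub[["sample"] + KEY_COLS].itertuples(index=False):
        by_key.setdefault(tuple(row[1:]), set()).add(row[0])
    status: dict[tuple, str] = {}
    for key, samples in by_key.items():
        if samples == {a, b}:
            status[key] = "shared"
            continue
        (owner,) = samples
        partner = b if owner == a else a
        try:
            p = pile.loc[(partner,) + key]
        except KeyError:
            status[key] = "unassessable"
            continue
        if p["alt_depth"] > 0:
            status[key] = "shared"
        elif p["depth"] > RESCUE_MIN_READS:
            status[key] = f"{owner}_specific"
        else:
            status[key] = "unassessable"
    col = f"status_{a}_{b}"
    out[col] = [
        status.get(tuple(k), None) if s in pair else None
        for s, *k in out[["sample"] + KEY_COLS].itertuples(index=False)
    ]
    new = ConsensusSet(out, list(cs.trail))
    new.trail.append(
        dict(filter="rescue_paired", params={"pair": pair},
             n_before=len(before), n_after=len(out),
             relabeled={str(k): v for k, v in status.items()}, dropped=[])
    )
    return new


def annotate_genes(cs: ConsensusSet, gene_panel: pd.DataFrame) -> ConsensusSet:
    """Assign each variant its overlapping gene from the annotation table."""
    out = cs.variants.copy()
    genes = []
    by_chrom = {c: g for c, g in gene_panel.groupby("chrom")}
    end = gene_panel["end"] if "end" in gene_panel else gene_panel["start"] + 999
    gene_panel = gene_panel.assign(_end=end)
    by_chrom = {c: g for c, g in gene_panel.groupby("chrom")}
    for row in out.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        hit = None
        if sub is not None:
            m = sub[(sub["start"] <= row.pos) & (sub["_end"] >= row.pos)]
            if len(m):
                hit = m.index[0]
        genes.append(hit)
    out["gene"] = genes
    new = ConsensusSet(out, list(cs.trail))
    new.trail.append(dict(filter="annotate_genes", params={},
                          n_before=len(out), n_after=len(out), dropped=[]))
    return new


def gene_level_filters(
    cs: ConsensusSet,
    annotation: pd.DataFrame,
    gdi_max: float = GDI_MAX,
    fpkm_min: float = FPKM_MIN,
) -> ConsensusSet:
    """Drop noise-prone (GDI > 2000, ATM exempt) and unexpressed (FPKM < 0.5) genes.

    ``annotation`` is indexed by gene with ``gdi`` and ``fpkm`` columns.
    Variants in unannotated genes are kept and flagged.
    """
    before = cs.variants
    out = before.copy()
    if "gene" not in out.columns:
        raise ValueError("variants must carry a 'gene' column (run annotate_genes)")
    gdi = out["gene"].map(annotation["gdi"])
    fpkm = out["gene"].map(annotation["fpkm"])
    unannotated = out["gene"].isna() | gdi.isna() | fpkm.isna()
    out["unannotated"] = unannotated
    drop_gdi = (~unannotated) & (gdi > gdi_max) & ~out["gene"].isin(GDI_EXEMPT)
    drop_fpkm = (~unannotated) & (fpkm < fpkm_min)
    kept = out[~(drop_gdi | drop_fpkm)].reset_index(drop=True)
    new = ConsensusSet(kept, list(cs.trail))
    new._log("gene_gdi", before, out[~drop_gdi], gdi_max=gdi_max)
    new._log("gene_fpkm", out[~drop_gdi], kept, fpkm_min=fpkm_min)
    return new


def recurrence_annotation(
    patient_gene_sets: dict[str, set[str]],
    known_genes: list[str] | None = None,
) -> set[str]:
    """Reportable genes: nonsilently mutated in >= 2 patients, or in one
    patient and previously reported."""
    known = set(known_genes or [])
    if not known:
        warnings.warn("empty known-gene list: only the >=2-patient rule applies")
    counts: dict[str, int] = {}
    for genes in patient_gene_sets.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= 2 or (n >= 1 and g in known)}


def classify_cnv_segments(
    segments: pd.DataFrame,
    ig_loci: pd.DataFrame | None = None,
    amp: float = CN_AMP,
    deletion: float = CN_DEL,
) -> pd.DataFrame:
    """Classify copy-number segments and drop immunoglobulin loci.

    Inclusive thresholds: amplified iff CN >= 2.3, deleted iff CN <= 1.7,
    else neutral. Segments overlapping any supplied Ig interval (1-based
    inclusive) are removed.
    """
    if (segments["copy_number"] < 0).any():
        raise ValueError("copy numbers must be >= 0")
    if (segments["start"] > segments["end"]).any():
        raise ValueError("inverted segment intervals")
    out = segments.copy()
    out["class"] = "neutral"
    out.loc[out["copy_number"] >= amp, "class"] = "amplified"
    out.loc[out["copy_number"] <= deletion, "class"] = "deleted"
    if ig_loci is not None and len(ig_loci):
        keep = np.ones(len(out), dtype=bool)
        for _, ig in ig_loci.iterrows():
            overlap = (
                (out["chrom"] == ig["chrom"])
                & (out["start"] <= ig["end"])
                & (out["end"] >= ig["start"])
            )
            keep &= ~overlap.to_numpy()
        out = out[keep].reset_index(drop=True)
    return out


def replay_trail(initial: pd.DataFrame, trail: list[dict]) -> pd.DataFrame:
    """Reapply a recorded filter trail to the stage-0 variant table.

    Drops the recorded (sample, key) tuples in order; relabel-only stages
    leave the rows untouched. The result must equal the cascade's output.
    """
    df = initial.copy()
    for record in trail:
        dropped = set(map(tuple, record.get("dropped", [])))
        if not dropped:
            continue
        keys = list(map(tuple, df[["sample"] + KEY_COLS].itertuples(index=False)))
        df = df[[k not in dropped for k in keys]]
    return df.reset_index(drop=True)
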