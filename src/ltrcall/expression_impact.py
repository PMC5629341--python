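"""Transcriptional impact of new insertions on target and adjacent genes.

Consumes a gene count table (control/heat, replicated) and a differential-
expression table. Presence calling uses the counts-per-million filter
(> 5 CPM in at least two replicates); activation is log2FC >= 1 at
BH FDR < 0.05. Insertions are mapped to a target gene (insertion point
within the gene or its <500 bp promoter) and to adjacent genes within a
configurable radius (default 12 kb, the maximum distance at which an
element's regulatory influence has been observed), recording sense/antisense
orientation of the element relative to each transcript and the distance.

A self-contained fallback DE test (pooled-replicate binomial test with BH
correction) is included so the synthetic end-to-end path needs no external
DE engine; it is a deliberately simple approximation, not an equivalent of
a negative-binomial DE model, and real analyses should supply a DE table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import AnnotationModel


@dataclass
class ImpactRecord:
    insertion_id: str
    gene_id: str
    relation: str  # target | adjacent
    orientation: str  # sense | antisense | unknown
    distance: int  # bp, 0 for targets
    location: str  # body | promoter (targets), '.' for adjacent
    expressed: bool = False
    status: str = "not_expressed"  # activated | downregulated | unchanged | not_expressed


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization: 1e6 * count / library size, with
    library size the column sum."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive library size")
    return counts.astype(float) * 1e6 / lib


def presence_filter(cpm_matrix: pd.DataFrame, min_cpm: float = 5.0,
                    min_reps: int = 2) -> set[str]:
    """Genes with strictly more than ``min_cpm`` in at least ``min_reps``
    samples are deemed expressed."""
    keep = (cpm_matrix > min_cpm).sum(axis=1) >= min_reps
    return set(cpm_matrix.index[keep])


def classify_de(de_table: pd.DataFrame, lfc_min: float = 1.0,
                fdr_max: float = 0.05) -> pd.Series:
    """Per-gene status from a DE table with columns ``log2fc`` and ``fdr``:
    activated (log2FC >= threshold, FDR below cutoff), downregulated
    (log2FC <= -threshold), else unchanged."""
    if not {"log2fc", "fdr"} <= set(de_table.columns):
        raise ValueError("DE table needs 'log2fc' and 'fdr' columns")
    sig = de_table["fdr"] < fdr_max
    status = pd.Series("unchanged", index=de_table.index)
    status[sig & (de_table["log2fc"] >= lfc_min)] = "activated"
    status[sig & (de_table["log2fc"] <= -lfc_min)] = "downregulated"
    return status


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors: per-sample median of count /
    per-gene geometric mean, over genes expressed everywhere. Robust to a
    minority of strongly regulated genes, unlike total-count scaling."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in every sample")
    log_geomean = np.log(positive).mean(axis=1)
    sf = np.exp(np.log(positive).sub(log_geomean, axis=0).median(axis=0))
    return sf


def naive_de(counts: pd.DataFrame, control_samples: list[str],
             heat_samples: list[str], pseudocount: float = 0.5) -> pd.DataFrame:
    """Fallback DE: per-gene two-sided binomial test on pooled replicate
    counts (success probability = the heat share of the median-of-ratios
    normalized totals), BH-adjusted.

    This ignores biological dispersion and is anti-conservative relative to
    a negative-binomial model; it exists to close the synthetic loop, not to
    replace a DE engine.
    """
    sf = size_factors(counts)
    c = counts[control_samples].sum(axis=1)
    h = counts[heat_samples].sum(axis=1)
    lib_c = float(sf[control_samples].sum())
    lib_h = float(sf[heat_samples].sum())
    p0 = lib_h / (lib_h + lib_c)
    log2fc = np.log2((h / lib_h + pseudocount / lib_h) / (c / lib_c + pseudocount / lib_c))
    pvals = np.ones(len(counts))
    tot = (c + h).to_numpy()
    hh = h.to_numpy()
    for i in range(len(counts)):
        if tot[i] > 0:
            pvals[i] = stats.binomtest(int(hh[i]), int(tot[i]), p0).pvalue
    fdr = stats.false_discovery_control(pvals, method="bh")
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvals, "fdr": fdr},
                        index=counts.index)


# ---------------------------------------------------------------------------
# Mapping insertions to genes


def map_insertions_to_genes(calls, annotation: AnnotationModel,
                            adjacent_radius: int = 12_000) -> list[ImpactRecord]:
    """Relate each insertion call to its target and adjacent genes.

    Target: the gene whose span — from 500 bp upstream of the TSS through
    the gene end — contains the insertion point (location 'promoter' when
    the point is upstream of the gene itself). Adjacent: every other gene
    within ``adjacent_radius`` of the point; distance is to the nearer gene
    boundary. Orientation is sense when the element's 5'->3' axis matches
    the transcription direction.
    """
    records: list[ImpactRecord] = []
    for i, call in enumerate(calls):
        ins_id = getattr(call, "insertion_id", f"ins{i:04d}")
        chrom, point = call.chrom, call.start
        orientation = getattr(call, "orientation", ".")

        def orient_vs(gene) -> str:
            if orientation not in "+-":
                return "unknown"
            return "sense" if orientation == gene.strand else "antisense"

        target = None
        for g in annotation.genes_in(chrom, point - 1, point + 1) or []:
            if g.interval.start <= point < g.interval.end:
                target = (g, "body")
                break
        if target is None:
            best = None
            for g in annotation.genes_in(chrom, point - 500, point + 501):
                d = (g.interval.start - point) if g.strand == "+" else (point - g.interval.end + 1)
                if 0 < d <= 500 and (best is None or d < best[1]):
                    best = (g, d)
            if best is not None:
                target = (best[0], "promoter")
        if target is not None:
            g, loc = target
            records.append(ImpactRecord(ins_id, g.gene_id, "target", orient_vs(g), 0, loc))

        target_id = target[0].gene_id if target else None
        for g in annotation.genes_in(chrom, point - adjacent_radius, point + adjacent_radius):
            if g.gene_id == target_id:
                continue
            if g.interval.start <= point < g.interval.end:
                d = 0
            else:
                d = min(abs(point - g.interval.start), abs(point - (g.interval.end - 1)))
            if d > adjacent_radius:
                continue
            records.append(ImpactRecord(ins_id, g.gene_id, "adjacent", orient_vs(g), d, "."))
    return records


def annotate_impact(records: list[ImpactRecord], expressed_genes: set[str],
                    de_status: pd.Series | dict) -> list[ImpactRecord]:
    """Fill expression flag and DE status into impact records."""
    status_of = dict(de_status) if not isinstance(de_status, dict) else de_status
    for r in records:
        r.expressed = r.gene_id in expressed_genes
        r.status = status_of.get(r.gene_id, "unchanged") if r.expressed else "not_expressed"
    return records


def impact_summary(records: list[ImpactRecord]) -> dict:
    """Aggregate fractions, always reporting numerator and denominator.

    * among expressed target genes with sense insertions: fraction activated;
    * among expressed promoter-insertion targets: fraction activated;
    * among expressed adjacent genes: fraction altered (activated or
      downregulated), plus the distance vectors of altered vs unaltered
      adjacent genes for a KS comparison.

    Fractions with a zero denominator are reported as NaN.
    """
    def frac(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sense_targets = [r for r in records if r.relation == "target"
                     and r.orientation == "sense" and r.expressed]
    n_sense = len(sense_targets)
    n_sense_act = sum(r.status == "activated" for r in sense_targets)

    prom_targets = [r for r in records if r.relation == "target"
                    and r.location == "promoter" and r.expressed]
    n_prom = len(prom_targets)
    n_prom_act = sum(r.status == "activated" for r in prom_targets)

    adjacent = [r for r in records if r.relation == "adjacent" and r.expressed]
    altered = [r for r in adjacent if r.status in ("activated", "downregulated")]
    unaltered = [r for r in adjacent if r.status not in ("activated", "downregulated")]

    return {
        "sense_target_expressed": n_sense,
        "sense_target_activated": n_sense_act,
        "sense_target_fraction_activated": frac(n_sense_act, n_sense),
        "promoter_target_expressed": n_prom,
        "promoter_target_activated": n_prom_act,
        "promoter_target_fraction_activated": frac(n_prom_act, n_prom),
        "adjacent_expressed": len(adjacent),
        "adjacent_altered": len(altered),
        "adjacent_fraction_altered": frac(len(altered), len(adjacent)),
        "distances_altered": [r.distance for r in altered],
        "distances_unaltered": [r.distance for r in unaltered],
    }
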