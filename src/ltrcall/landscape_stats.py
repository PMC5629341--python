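"""Statistical characterization of the chromosomal insertion landscape.

Covers per-chromosome insertion densities, euchromatin enrichment (Fisher's
exact test of insertion counts against class sizes in Mbp), genic
classification into eight positional categories and hypergeometric gene-space
enrichment, the matched-random-locus permutation test of window-count
variance with a gamma fitted to the permutation null by moment matching,
a two-sample Kolmogorov-Smirnov distance comparison, and a gene-length-
corrected chi-squared test of functional-class enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import ChromatinPartition
from .formats_io import AnnotationModel, GenomicInterval

#: Arabidopsis thaliana TAIR10 nuclear chromosome lengths (bp).
TAIR10_CHROM_LENGTHS = {
    "chr1": 30_427_671,
    "chr2": 19_698_289,
    "chr3": 23_459_830,
    "chr4": 18_585_056,
    "chr5": 26_975_502,
}

#: Positional categories in genomic-table order.
CATEGORIES = (
    "promoter_500_1000",
    "promoter_lt500",
    "utr5",
    "exon",
    "intron",
    "utr3",
    "intergenic_gt1000",
    "te",
)


@dataclass
class EnrichmentResult:
    table: tuple[tuple[float, float], tuple[float, float]] | None
    odds_ratio: float
    p_value: float
    test_name: str


@dataclass
class PermutationTestResult:
    observed_variance: float
    permuted_variances: np.ndarray
    shape: float  # gamma k
    scale: float  # gamma theta
    p_value: float  # upper gamma tail at the observed variance
    empirical_p: float  # empirical tail proportion

    @property
    def gamma_defined(self) -> bool:
        return np.isfinite(self.shape) and self.shape > 0


# ---------------------------------------------------------------------------
# Densities and categories


def insertion_density(counts: dict[str, int], chrom_lengths: dict[str, int]):
    """Insertions per Mbp, per chromosome and genome-wide.

    Returns ``(per_chromosome Series, total density)`` at full precision;
    round to one decimal for table display.
    """
    dens = {}
    for chrom, L in chrom_lengths.items():
        if L <= 0:
            raise ValueError(f"zero-length chromosome {chrom}")
        dens[chrom] = counts.get(chrom, 0) / (L / 1e6)
    total = sum(counts.get(c, 0) for c in chrom_lengths) / (sum(chrom_lengths.values()) / 1e6)
    return pd.Series(dens), total


def classify_insertion(chrom: str, pos: int, annotation: AnnotationModel,
                       assembly_lengths: dict[str, int] | None = None) -> str:
    """Assign one of the eight positional categories to an insertion point.

    Precedence: TE feature > gene body (exon > 5'UTR > 3'UTR > intron by
    containment) > promoter distance to the nearest TSS on that gene's
    strand (<500 bp, then 500-1000 bp) > intergenic.
    """
    if assembly_lengths is not None:
        if chrom not in assembly_lengths or not (0 <= pos < assembly_lengths[chrom]):
            raise ValueError(f"insertion point {chrom}:{pos} outside assembly")
    if annotation.tes_at(chrom, pos):
        return "te"
    genes = annotation.genes_at(chrom, pos)
    if genes:
        g = genes[0]
        if any(e.start <= pos < e.end for e in g.exons):
            return "exon"
        if g.utr5 is not None and g.utr5.contains_point(chrom, pos):
            return "utr5"
        if g.utr3 is not None and g.utr3.contains_point(chrom, pos):
            return "utr3"
        return "intron"
    # promoter: upstream of a TSS on the gene's strand, nearest gene wins
    best = None
    for g in annotation.genes_in(chrom, pos - 1000, pos + 1001):
        d = (g.interval.start - pos) if g.strand == "+" else (pos - g.interval.end + 1)
        if 0 < d < 1000 and (best is None or d < best):
            best = d
    if best is not None:
        return "promoter_lt500" if best < 500 else "promoter_500_1000"
    return "intergenic_gt1000"


def category_table(categories: list[str]) -> pd.DataFrame:
    """Counts, percentages and cumulative genic roll-ups per category.

    The roll-up rows accumulate: transcribed regions (5'UTR + exon + intron
    + 3'UTR), plus promoter <500 bp, plus promoter 500-1000 bp.
    """
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int)
    for c in categories:
        if c not in counts.index:
            raise ValueError(f"unknown category {c!r}")
        counts[c] += 1
    total = counts.sum()
    pct = 100.0 * counts / total if total else counts.astype(float)
    df = pd.DataFrame({"count": counts, "percent": pct})
    transcribed = pct[["utr5", "exon", "intron", "utr3"]].sum()
    df.attrs["cumulative_genic"] = (
        transcribed,
        transcribed + pct["promoter_lt500"],
        transcribed + pct["promoter_lt500"] + pct["promoter_500_1000"],
    )
    return df


# ---------------------------------------------------------------------------
# Enrichment tests


def fisher_exact_2x2(table) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed one —
    the 'fisher.test for count data' convention. A zero margin gives p = 1.
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    odds = (a * d) / (b * c) if b * c else np.inf if a * d else np.nan
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return EnrichmentResult(((a, b), (c, d)), odds, 1.0, "fisher_exact")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
    return EnrichmentResult(((a, b), (c, d)), odds, min(p, 1.0), "fisher_exact")


def genic_enrichment_hypergeom(n_genic: int, n_total: int, genic_bp: int,
                               total_bp: int, resolution: int = 1) -> EnrichmentResult:
    """Upper-tail hypergeometric probability of >= ``n_genic`` genic hits
    when ``n_total`` insertion sites are drawn from ``total_bp`` positions of
    which ``genic_bp`` are genic. ``resolution`` coarsens the bp population
    (e.g. 1000 to draw kb units)."""
    if n_genic > n_total or genic_bp > total_bp:
        raise ValueError("inconsistent counts")
    M = max(total_bp // resolution, n_total)
    K = genic_bp // resolution
    p = float(stats.hypergeom.sf(n_genic - 1, M, K, n_total))
    return EnrichmentResult(None, np.nan, p, "hypergeometric_upper")


# ---------------------------------------------------------------------------
# Matched random loci and the permutation variance test


def _euchromatin_arrays(euchromatin: list[GenomicInterval]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in euchromatin}:
        segs = sorted((iv.start, iv.end) for iv in euchromatin if iv.chrom == chrom)
        by_chrom[chrom] = (np.array([s for s, _ in segs], dtype=np.int64),
                           np.array([e for _, e in segs], dtype=np.int64))
    return by_chrom


def _sample_positions(starts: np.ndarray, ends: np.ndarray, length: int,
                      size: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform start positions of ``length``-bp loci that stay inside one
    segment (loci may not cross class boundaries)."""
    cap = np.maximum(ends - starts - length + 1, 0)
    total = cap.sum()
    if total <= 0:
        raise ValueError("no euchromatin segment can hold a locus of this length")
    cum = np.cumsum(cap)
    u = rng.integers(0, total, size=size)
    seg = np.searchsorted(cum, u, side="right")
    return starts[seg] + (u - (cum[seg] - cap[seg]))


def sample_matched_loci(calls: list[GenomicInterval], partition: ChromatinPartition,
                        rng: np.random.Generator) -> list[GenomicInterval]:
    """One random euchromatic locus per call: same chromosome, same length,
    uniform over that chromosome's euchromatin, never crossing a class
    boundary."""
    arrays = _euchromatin_arrays(partition.euchromatin)
    out: list[GenomicInterval] = []
    for call in calls:
        if call.chrom not in arrays:
            raise ValueError(f"chromosome {call.chrom} has no euchromatin")
        starts, ends = arrays[call.chrom]
        pos = _sample_positions(starts, ends, len(call), 1, rng)[0]
        out.append(GenomicInterval(call.chrom, int(pos), int(pos) + len(call)))
    return out


def euchromatin_windows(euchromatin: list[GenomicInterval], window: int = 1_000_000,
                        step: int = 100_000) -> list[GenomicInterval]:
    """Sliding windows laid over each euchromatin segment; a segment shorter
    than the window contributes itself as a single window."""
    out: list[GenomicInterval] = []
    for iv in sorted(euchromatin):
        if len(iv) <= window:
            out.append(iv)
            continue
        start = iv.start
        while start + window <= iv.end:
            out.append(GenomicInterval(iv.chrom, start, start + window))
            start += step
    if not out:
        raise ValueError("no windows: empty euchromatin")
    return out


def window_count_variance(loci: list[GenomicInterval], windows: list[GenomicInterval]) -> float:
    """Population variance of per-window locus counts (a locus is counted in
    every window containing its midpoint)."""
    counts = _window_counts(
        {c: np.array([(l.start + l.end) // 2 for l in loci if l.chrom == c])[None, :]
         for c in {l.chrom for l in loci}},
        windows,
    )
    return float(counts[0].var())


def _window_counts(positions_by_chrom: dict[str, np.ndarray],
                   windows: list[GenomicInterval]) -> np.ndarray:
    """Counts of positions per window; ``positions_by_chrom[c]`` has shape
    (n_perm, n_loci_on_c). Returns (n_perm, n_windows)."""
    n_perm = next(iter(positions_by_chrom.values())).shape[0] if positions_by_chrom else 1
    blocks = []
    for chrom in sorted({w.chrom for w in windows}):
        ws = np.array([w.start for w in windows if w.chrom == chrom])
        we = np.array([w.end for w in windows if w.chrom == chrom])
        pos = positions_by_chrom.get(chrom)
        if pos is None or pos.shape[1] == 0:
            blocks.append(np.zeros((n_perm, len(ws)), dtype=np.int64))
            continue
        inside = (pos[:, :, None] >= ws[None, None, :]) & (pos[:, :, None] < we[None, None, :])
        blocks.append(inside.sum(axis=1))
    return np.concatenate(blocks, axis=1)


def fit_gamma_moments(sample: np.ndarray) -> tuple[float, float]:
    """Moment-matching gamma fit: shape k = mean^2/var, scale = var/mean."""
    mean = float(np.mean(sample))
    var = float(np.var(sample))
    if mean <= 0 or var <= 0:
        return np.nan, np.nan
    return mean * mean / var, var / mean


def permutation_variance_test(calls: list[GenomicInterval], partition: ChromatinPartition,
                              rng: np.random.Generator, n_perm: int = 1000,
                              window: int = 1_000_000, step: int = 100_000,
                              ) -> PermutationTestResult:
    """Is the window-count variance of the observed insertions larger than
    expected for matched random loci?

    ``n_perm`` sets of matched loci (same chromosome and length per call,
    uniform within euchromatin) are drawn; a gamma distribution is fitted to
    their window-count variances by moment matching, and the p-value is the
    upper gamma tail at the observed variance. The empirical tail proportion
    is reported alongside; if the permuted variances are all equal the gamma
    is undefined and the empirical tail is used with a warning.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    eu_by_chrom = _euchromatin_arrays(partition.euchromatin)
    windows = euchromatin_windows(partition.euchromatin, window, step)
    observed = window_count_variance(calls, windows)

    positions: dict[str, np.ndarray] = {}
    for chrom in sorted({c.chrom for c in calls}):
        if chrom not in eu_by_chrom:
            raise ValueError(f"chromosome {chrom} has no euchromatin")
        starts, ends = eu_by_chrom[chrom]
        lens = [len(c) for c in calls if c.chrom == chrom]
        cols = []
        for L in lens:
            p = _sample_positions(starts, ends, L, n_perm, rng) + L // 2
            cols.append(p)
        positions[chrom] = np.stack(cols, axis=1)
    perm_vars = _window_counts(positions, windows).var(axis=1)

    empirical = float(np.mean(perm_vars >= observed))
    k, theta = fit_gamma_moments(perm_vars)
    if not (np.isfinite(k) and k > 0):
        warnings.warn("degenerate permutation null; falling back to empirical tail")
        p = empirical
    else:
        p = float(stats.gamma.sf(observed, a=k, scale=theta))
    return PermutationTestResult(observed, perm_vars, k, theta, p, empirical)


# ---------------------------------------------------------------------------
# Distance and length-corrected tests


def ks_distance_test(distances_affected, distances_unaffected) -> tuple[float, float]:
    """Two-sample KS comparison of insertion-to-gene distance distributions
    (asymptotic p)."""
    a = np.asarray(distances_affected, dtype=float)
    b = np.asarray(distances_unaffected, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def length_corrected_chisq(category_flags, all_gene_lengths, all_flags) -> tuple[float, float, int]:
    """Pearson chi-squared of functional-class counts among targeted genes
    against an expectation proportional to the summed gene length per class.

    Long genes present a larger insertion target; weighting the expectation
    by class-wise total gene length removes the length confound from an
    apparent class enrichment.
    """
    flags = list(category_flags)
    classes = sorted(set(all_flags))
    observed = np.array([sum(f == cl for f in flags) for cl in classes], dtype=float)
    length_per_class = np.array(
        [sum(L for L, f in zip(all_gene_lengths, all_flags) if f == cl) for cl in classes],
        dtype=float,
    )
    if (length_per_class <= 0).any():
        raise ValueError("every class must have positive total gene length")
    expected = length_per_class / length_per_class.sum() * observed.sum()
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p), len(classes) - 1
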