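"""Synthetic genomes, planted TE insertions, alignments, chromatin tracks and
RNA count tables.

The generator emulates the data a heat-stress retrotransposition experiment
produces: a multi-chromosome genome with pericentromeric heterochromatin
blocks and gene models in euchromatin, pre-existing copies of an LTR
retrotransposon, new insertions planted with canonical target-site
duplications (TSDs), paired-end reads mapped against a TE-masked reference
(yielding discordant pairs and junction reads around each new insertion), an
H3K9me2-like tile enrichment track, and negative-binomial count tables with
insertion-linked heat activation.

Alignments are emitted directly as SAM records rather than FASTQ plus an
external aligner, so the full pipeline is testable without third-party
binaries; :func:`write_fastq` is provided for users who want to run a real
aligner. All randomness flows through one ``numpy.random.Generator`` passed
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    AlignmentRecord,
    AnnotationModel,
    Gene,
    GenomeAssembly,
    GenomicInterval,
    TEFeature,
    TileTrack,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass(frozen=True)
class TEConsensus:
    """An LTR retrotransposon consensus: identical long terminal repeats at
    both extremities flanking an internal region."""

    te_id: str
    sequence: str
    ltr5: tuple[int, int]  # [start, end) within element, start == 0
    ltr3: tuple[int, int]  # end == len(sequence)

    def __post_init__(self) -> None:
        if self.ltr5[0] != 0 or self.ltr3[1] != len(self.sequence):
            raise ValueError("LTRs must sit at the element extremities")
        if self.ltr5_seq != self.ltr3_seq:
            raise ValueError("5' and 3' LTR sequences must be identical")

    @property
    def ltr5_seq(self) -> str:
        return self.sequence[self.ltr5[0] : self.ltr5[1]]

    @property
    def ltr3_seq(self) -> str:
        return self.sequence[self.ltr3[0] : self.ltr3[1]]

    @property
    def ltr_len(self) -> int:
        return self.ltr5[1] - self.ltr5[0]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantedInsertion:
    """Ground truth for one planted insertion (reference coordinates)."""

    chrom: str
    pos: int  # insertion point in the reference, 0-based
    orientation: str  # '+' or '-'
    tsd_len: int
    genic: bool


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Read length 75 bp paired-end mirrors the DNA-sequencing design the
    detector targets; element/LTR sizes mirror a Ty1/copia element (~5 kb
    with ~0.4 kb LTRs). TSD length defaults to 5 bp, canonical for
    Ty1/copia-like integrases, and is never assumed by the detector.
    """

    n_chromosomes: int = 3
    chrom_length: int = 200_000
    gene_density: float = 0.4  # fraction of euchromatin covered by gene models
    het_fraction: float = 0.15  # central heterochromatin block per chromosome
    n_te_copies: int = 9
    n_insertions: int = 30
    genic_bias: float = 0.9
    coverage: float = 30.0
    read_len: int = 75
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    tsd_len: int = 5
    element_len: int = 5000
    ltr_len: int = 400

    def __post_init__(self) -> None:
        if not (0 <= self.genic_bias <= 1 and 0 <= self.het_fraction < 1):
            raise ValueError("probabilities/fractions must lie in [0, 1]")
        if min(self.n_chromosomes, self.chrom_length, self.read_len) <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.coverage < 0 or self.error_rate < 0 or self.tsd_len < 0:
            raise ValueError("rates and tsd_len must be non-negative")


def build_te_consensus(rng: np.random.Generator, element_len: int = 5000, ltr_len: int = 400,
                       te_id: str = "element") -> TEConsensus:
    """Random element sequence whose first and last ``ltr_len`` bp are
    byte-identical (the defining LTR property)."""
    if 2 * ltr_len >= element_len:
        raise ValueError("2*ltr_len must be < element_len")
    ltr = random_dna(rng, ltr_len)
    internal = random_dna(rng, element_len - 2 * ltr_len)
    return TEConsensus(te_id, ltr + internal + ltr,
                       ltr5=(0, ltr_len), ltr3=(element_len - ltr_len, element_len))


@dataclass
class ToyGenome:
    """A simulated reference bundle."""

    assembly: GenomeAssembly
    annotation: AnnotationModel
    heterochromatin: list[GenomicInterval]
    te: TEConsensus
    config: SimulationConfig


def build_toy_genome(config: SimulationConfig, rng: np.random.Generator,
                     te: TEConsensus | None = None) -> ToyGenome:
    """Build the reference genome the detector runs against.

    Each chromosome carries one central heterochromatin block of the
    configured fraction; stranded multi-exon genes with UTRs tile the
    euchromatin at ``gene_density``; pre-existing element copies are written
    into the sequence (majority inside heterochromatin), so they are part of
    the reference just like resident TE copies in a real assembly.
    """
    if te is None:
        te = build_te_consensus(rng, config.element_len, config.ltr_len)
    seqs: dict[str, str] = {}
    genes: list[Gene] = []
    te_feats: list[TEFeature] = []
    het: list[GenomicInterval] = []

    L = config.chrom_length
    chrom_names = [f"chr{ci + 1}" for ci in range(config.n_chromosomes)]
    eu_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom in chrom_names:
        arr = _BASES[rng.integers(0, 4, size=L)]
        seqs[chrom] = arr.tobytes().decode()
        block_len = int(round(L * config.het_fraction))
        if block_len > 0:
            h0 = (L - block_len) // 2
            het.append(GenomicInterval(chrom, h0, h0 + block_len))
            eu_by_chrom[chrom] = [(0, h0), (h0 + block_len, L)]
        else:
            eu_by_chrom[chrom] = [(0, L)]

    # place pre-existing element copies first (majority in heterochromatin),
    # overwriting background sequence so reference coordinates are untouched
    n_het = int(round(config.n_te_copies * 2 / 3)) if het else 0
    placed = 0
    attempts = 0
    while placed < config.n_te_copies:
        attempts += 1
        if attempts > 20_000:
            raise ValueError("could not place the requested number of TE copies")
        want_het = placed < n_het
        chrom = chrom_names[int(rng.integers(0, config.n_chromosomes))]
        blocks = [h for h in het if h.chrom == chrom]
        if want_het and blocks:
            b = blocks[0]
            if len(b) <= len(te) + 400:
                continue
            start = int(rng.integers(b.start + 100, b.end - len(te) - 100))
        else:
            start = int(rng.integers(1000, L - len(te) - 1000))
        end = start + len(te)
        if any(t.interval.chrom == chrom and t.interval.start < end + 2000
               and start < t.interval.end + 2000 for t in te_feats):
            continue
        seq = seqs[chrom]
        seqs[chrom] = seq[:start] + te.sequence + seq[end:]
        te_feats.append(TEFeature(f"copy{placed}", GenomicInterval(chrom, start, end, "+"),
                                  family=te.te_id))
        placed += 1

    # genes tile euchromatin, skipping around placed copies
    for chrom in chrom_names:
        forbidden = sorted((t.interval.start - 300, t.interval.end + 300)
                           for t in te_feats if t.interval.chrom == chrom)
        for seg_start, seg_end in eu_by_chrom[chrom]:
            if config.gene_density <= 0:
                break
            pos = seg_start + int(rng.integers(100, 400))
            while True:
                glen = int(rng.integers(1200, 3500))
                gap = int(glen * (1 - config.gene_density) / config.gene_density)
                if pos + glen + 100 > seg_end:
                    break
                clash = next((f for f in forbidden if f[0] < pos + glen and pos < f[1]), None)
                if clash is not None:
                    pos = clash[1] + 100
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(_make_gene(chrom, pos, glen, strand, rng, len(genes)))
                pos += glen + max(gap, 200) + int(rng.integers(0, 200))
    if config.gene_density > 0 and not genes:
        raise ValueError("gene density incompatible with chromosome length")

    return ToyGenome(GenomeAssembly(seqs), AnnotationModel(genes, te_feats), het, te, config)


def _make_gene(chrom: str, start: int, glen: int, strand: str,
               rng: np.random.Generator, idx: int) -> Gene:
    """Gene model: 5'UTR, 2-4 exons with introns, 3'UTR (genomic order;
    UTR identity assigned by strand)."""
    end = start + glen
    u1 = int(rng.integers(80, 250))
    u2 = int(rng.integers(80, 250))
    body_start, body_end = start + u1, end - u2
    n_exons = int(rng.integers(2, 5))
    cuts = np.sort(rng.integers(body_start + 50, body_end - 50, size=2 * (n_exons - 1)))
    bounds = [body_start, *cuts.tolist(), body_end]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        if bounds[i + 1] > bounds[i]:
            exons.append(GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]), strand))
    left_utr = GenomicInterval(chrom, start, start + u1, strand)
    right_utr = GenomicInterval(chrom, end - u2, end, strand)
    utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)
    return Gene(f"gene{idx:05d}", GenomicInterval(chrom, start, end, strand),
                strand, exons, utr5=utr5, utr3=utr3)


# ---------------------------------------------------------------------------
# Planting insertions


@dataclass
class Segment:
    """One piece of a mutated chromosome.

    ``kind`` is 'genome' (maps linearly to the reference from ``ref_start``)
    or 'element' (element coordinates, possibly reverse-complemented).
    """

    mut_start: int
    mut_end: int
    kind: str
    ref_start: int = 0
    orient: str = "+"


@dataclass
class MutatedGenome:
    assembly: GenomeAssembly
    truth: list[PlantedInsertion]
    segments: dict[str, list[Segment]] = field(default_factory=dict)


def plant_insertions(genome: ToyGenome, config: SimulationConfig,
                     rng: np.random.Generator) -> MutatedGenome:
    """Insert element copies with canonical TSDs into the reference.

    At each site the ``tsd_len`` bp immediately 3' of the insertion point are
    duplicated flanking the element; orientation is Bernoulli(0.5); with
    probability ``genic_bias`` the site falls inside an annotated gene.
    Sites are kept at least one insert-size apart from each other, from
    chromosome ends and from pre-existing element copies.
    """
    te, ann = genome.te, genome.annotation
    spacing = int(config.insert_mean + 3 * config.insert_sd) + config.read_len
    margin = spacing + config.tsd_len + 10
    chosen: list[PlantedInsertion] = []
    lengths = genome.assembly.lengths
    genes_by_chrom = {c: ann.genes_on(c) for c in lengths}

    te_ivs = [t.interval for t in ann.te_features]
    cluster_guard = 2 * spacing  # keep clear of resident copies

    attempts = 0
    while len(chosen) < config.n_insertions:
        attempts += 1
        if attempts > 200 * max(config.n_insertions, 1):
            raise ValueError("cannot place requested insertions under spacing constraint")
        genic = rng.random() < config.genic_bias
        if genic:
            all_genes = [g for gs in genes_by_chrom.values() for g in gs]
            if not all_genes:
                continue
            g = all_genes[int(rng.integers(0, len(all_genes)))]
            pos = int(rng.integers(g.interval.start + 1, g.interval.end - 1))
            chrom = g.interval.chrom
        else:
            chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
            pos = int(rng.integers(margin, lengths[chrom] - margin))
            if ann.genes_at(chrom, pos):
                continue
        if not (margin <= pos <= lengths[chrom] - margin):
            continue
        if any(c.chrom == chrom and abs(c.pos - pos) < spacing for c in chosen):
            continue
        if any(iv.chrom == chrom and iv.start - cluster_guard < pos < iv.end + cluster_guard
               for iv in te_ivs):
            continue
        orient = "+" if rng.random() < 0.5 else "-"
        chosen.append(PlantedInsertion(chrom, pos, orient, config.tsd_len,
                                       genic=bool(ann.genes_at(chrom, pos))))

    truth = sorted(chosen, key=lambda p: (p.chrom, p.pos))
    elem_fwd = te.sequence
    elem_rev = revcomp(te.sequence)

    seqs: dict[str, str] = {}
    segmap: dict[str, list[Segment]] = {}
    for chrom, refseq in genome.assembly.items():
        parts: list[str] = []
        segs: list[Segment] = []
        cursor = 0  # reference coordinate
        mut = 0
        for ins in [t for t in truth if t.chrom == chrom]:
            p, t = ins.pos, ins.tsd_len
            left = refseq[cursor : p + t]  # includes the TSD copy
            parts.append(left)
            segs.append(Segment(mut, mut + len(left), "genome", ref_start=cursor))
            mut += len(left)
            elem = elem_fwd if ins.orientation == "+" else elem_rev
            parts.append(elem)
            segs.append(Segment(mut, mut + len(elem), "element", orient=ins.orientation))
            mut += len(elem)
            cursor = p  # second TSD copy starts the next genome segment
        tail = refseq[cursor:]
        parts.append(tail)
        segs.append(Segment(mut, mut + len(tail), "genome", ref_start=cursor))
        seqs[chrom] = "".join(parts)
        segmap[chrom] = segs
    return MutatedGenome(GenomeAssembly(seqs), truth, segmap)


# ---------------------------------------------------------------------------
# Read simulation


def simulate_alignments(mutated: MutatedGenome, masked_intervals: list[GenomicInterval],
                        config: SimulationConfig, rng: np.random.Generator,
                        ) -> list[AlignmentRecord]:
    """Draw paired-end fragments along the mutated genome and report each
    mate's placement on the TE-masked reference.

    A mate is reported mapped only when its fragment lies entirely within a
    single reference-derived segment whose reference footprint avoids every
    masked interval; reads overlapping an insertion junction, the inserted
    element, or a masked (pre-existing copy) region are reported unmapped
    with their sequence retained — exactly the evidence classes the detector
    consumes. Coverage 0 yields an empty list.
    """
    rl = config.read_len
    out: list[AlignmentRecord] = []
    lengths = mutated.assembly.lengths
    total = sum(lengths.values())
    n_pairs = int(round(total * config.coverage / (2 * rl)))
    if n_pairs == 0:
        return out

    chroms = list(lengths)
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=probs)
    frag_lens = np.maximum(rng.normal(config.insert_mean, config.insert_sd, n_pairs),
                           2 * rl).astype(np.int64)

    masked_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in chroms:
        ivs = sorted((iv.start, iv.end) for iv in masked_intervals if iv.chrom == c)
        masked_by_chrom[c] = (np.array([a for a, _ in ivs], dtype=np.int64),
                              np.array([b for _, b in ivs], dtype=np.int64))

    pair_no = 0
    for ci, chrom in enumerate(chroms):
        sel = np.where(chrom_idx == ci)[0]
        if sel.size == 0:
            continue
        L = lengths[chrom]
        flens = np.minimum(frag_lens[sel], L)
        starts = (rng.random(sel.size) * (L - flens)).astype(np.int64)
        segs = mutated.segments[chrom]
        seg_starts = np.array([s.mut_start for s in segs], dtype=np.int64)
        seg_ends = np.array([s.mut_end for s in segs], dtype=np.int64)
        seg_kind_genome = np.array([s.kind == "genome" for s in segs])
        seg_ref = np.array([s.ref_start for s in segs], dtype=np.int64)
        m_starts, m_ends = masked_by_chrom[chrom]
        seq = mutated.assembly[chrom]

        # left mate [s, s+rl) forward; right mate [s+f-rl, s+f) reverse
        a1, b1 = starts, starts + rl
        a2, b2 = starts + flens - rl, starts + flens

        def place(a: np.ndarray, b: np.ndarray):
            i = np.searchsorted(seg_starts, a, side="right") - 1
            inside = (b <= seg_ends[i]) & seg_kind_genome[i]
            r = seg_ref[i] + (a - seg_starts[i])
            if m_starts.size:
                j = np.searchsorted(m_starts, r + rl)
                hit = (j > 0) & (m_ends[np.maximum(j - 1, 0)] > r)
                inside &= ~hit
            return inside, r

        ok1, r1 = place(a1, b1)
        ok2, r2 = place(a2, b2)
        read1_is_left = rng.random(sel.size) < 0.5
        err_counts = rng.binomial(rl, config.error_rate, size=(sel.size, 2))

        for k in range(sel.size):
            name = f"frag{pair_no:08d}"
            pair_no += 1
            s_left = seq[a1[k] : b1[k]]
            s_right = revcomp(seq[a2[k] : b2[k]])
            if err_counts[k, 0]:
                s_left = _inject_errors(s_left, err_counts[k, 0], rng)
            if err_counts[k, 1]:
                s_right = _inject_errors(s_right, err_counts[k, 1], rng)
            left_mate = 1 if read1_is_left[k] else 2
            rec_left = AlignmentRecord(
                qname=name, mate=left_mate, mapped=bool(ok1[k]),
                chrom=chrom if ok1[k] else None, pos=int(r1[k]) if ok1[k] else None,
                strand="+", match_len=rl if ok1[k] else 0,
                clip_left=0, clip_right=0,
                mate_mapped=bool(ok2[k]),
                mate_chrom=chrom if ok2[k] else None,
                mate_pos=int(r2[k]) if ok2[k] else None,
                seq=s_left,
            )
            rec_right = AlignmentRecord(
                qname=name, mate=3 - left_mate, mapped=bool(ok2[k]),
                chrom=chrom if ok2[k] else None, pos=int(r2[k]) if ok2[k] else None,
                strand="-", match_len=rl if ok2[k] else 0,
                clip_left=0, clip_right=0,
                mate_mapped=bool(ok1[k]),
                mate_chrom=chrom if ok1[k] else None,
                mate_pos=int(r1[k]) if ok1[k] else None,
                seq=s_right,
            )
            out.append(rec_left)
            out.append(rec_right)
    return out


def _inject_errors(seq: str, n: int, rng: np.random.Generator) -> str:
    arr = bytearray(seq, "ascii")
    for pos in rng.integers(0, len(arr), size=n):
        cur = arr[pos]
        choices = [b for b in b"ACGT" if b != cur]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return arr.decode()


def write_fastq(records: list[AlignmentRecord], path1: str, path2: str) -> None:
    """Emit simulated mates as a FASTQ pair (constant quality) for use with
    an external aligner."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        by_name: dict[str, dict[int, AlignmentRecord]] = {}
        for r in records:
            by_name.setdefault(r.qname, {})[r.mate] = r
        for name, mates in by_name.items():
            for idx, fh in ((1, f1), (2, f2)):
                r = mates[idx]
                fh.write(f"@{name}/{idx}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# Chromatin track


def simulate_h3k9me2_track(het_truth: list[GenomicInterval], genome: GenomeAssembly,
                           rng: np.random.Generator, tile_width: int = 60,
                           signal_high: float = 3.0, signal_low: float = 0.5,
                           noise_sd: float = 0.3) -> TileTrack:
    """Two-level tile enrichment: Normal(high, sd) inside heterochromatin,
    Normal(low, sd) elsewhere, floored at 0. A tile is 'inside' when its
    midpoint falls within a truth interval."""
    values: dict[str, np.ndarray] = {}
    for chrom, L in genome.lengths.items():
        n = -(-L // tile_width)
        mids = np.arange(n) * tile_width + tile_width / 2
        level = np.full(n, signal_low, dtype=float)
        for iv in het_truth:
            if iv.chrom == chrom:
                level[(mids >= iv.start) & (mids < iv.end)] = signal_high
        vals = level + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
        values[chrom] = np.maximum(vals, 0.0)
    return TileTrack(tile_width, values)


# ---------------------------------------------------------------------------
# Count tables


def simulate_count_table(annotation: AnnotationModel, activated_genes: set[str],
                         rng: np.random.Generator, baseline_mean: float = 500.0,
                         dispersion: float = 0.05, fold_change: float = 8.0,
                         silent_fraction: float = 0.3, n_reps: int = 2):
    """Negative-binomial gene counts for control/heat with ``n_reps``
    biological replicates each.

    Genes in ``activated_genes`` get their heat-condition mean multiplied by
    ``fold_change`` (>= 2 so a log2FC >= 1 effect is recoverable); a
    ``silent_fraction`` of the remaining genes are near-silent to exercise
    the presence-call filter. Returns ``(counts DataFrame, effects
    DataFrame)`` with samples control_1..control_n, heat_1..heat_n.
    """
    import pandas as pd

    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    gene_ids = [g.gene_id for g in annotation.genes]
    n = len(gene_ids)
    base = rng.lognormal(np.log(baseline_mean), 0.6, size=n)
    silent = np.zeros(n, dtype=bool)
    candidates = [i for i, g in enumerate(gene_ids) if g not in activated_genes]
    n_silent = int(round(silent_fraction * len(candidates)))
    if n_silent:
        silent[rng.choice(candidates, size=n_silent, replace=False)] = True
    # near-zero mean: at desk-scale library sizes the CPM cutoff corresponds
    # to well under one read, so silent genes must be essentially count-free
    base[silent] = 0.02
    activated = np.array([g in activated_genes for g in gene_ids])
    heat_mean = np.where(activated, base * fold_change, base)

    def nb(mean_vec: np.ndarray) -> np.ndarray:
        r = 1.0 / dispersion
        p = r / (r + mean_vec)
        return rng.negative_binomial(r, p)

    data = {}
    for rep in range(1, n_reps + 1):
        data[f"control_{rep}"] = nb(base)
    for rep in range(1, n_reps + 1):
        data[f"heat_{rep}"] = nb(heat_mean)
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    effects = pd.DataFrame(
        {"activated": activated, "silent": silent,
         "fold_change": np.where(activated, fold_change, 1.0)},
        index=counts.index,
    )
    return counts, effects
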