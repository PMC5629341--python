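"""Two-step detection of new LTR-retrotransposon insertions.

Step 1 mines discordant read pairs against a TE-masked reference: pairs in
which one mate maps uniquely to a chromosome while the other is unmapped but
matches the element's LTR. Step 2 recovers junction reads — unmapped reads
whose prefix or suffix matches an LTR extremity — trims away the element
part and remaps the remaining genomic fragment exactly, which resolves the
insertion point to base precision and, when both junction sides are seen,
the target-site duplication (TSD): the 5'-side junction lies downstream of
the 3'-side junction by exactly the TSD length.

Evidence from both steps is clustered by position; clusters are called as
novel insertions unless they coincide with a pre-existing element copy
(masked region or annotated TE), recur in a control dataset (background
subtraction), or fall below the support thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    AlignmentRecord,
    GenomeAssembly,
    GenomicInterval,
    group_pairs,
)
from .synthetic_data import TEConsensus, revcomp


@dataclass
class DetectionParams:
    """Tunable thresholds. All are declared defaults, exposed on the CLI."""

    min_ltr_match: int = 25
    min_ltr_identity: float = 0.9
    min_fragment_len: int = 20
    cluster_window: int = 500  # ~ insert size mean + 3 sd
    min_discordant: int = 2
    min_junction: int = 1
    max_tsd: int = 20
    remap_max_mismatches: int = 0

    def __post_init__(self) -> None:
        if min(self.min_ltr_match, self.min_fragment_len, self.cluster_window,
               self.min_discordant, self.min_junction, self.max_tsd) <= 0:
            raise ValueError("all thresholds must be positive")
        if not 0 < self.min_ltr_identity <= 1:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass
class TEMatch:
    """An ungapped local match of a read to the LTR (or its reverse
    complement). ``ltr_span`` is in coordinates of the matched target string
    (the LTR for strand '+', its reverse complement for strand '-')."""

    strand: str
    read_span: tuple[int, int]
    ltr_span: tuple[int, int]
    length: int
    identity: float


@dataclass
class Evidence:
    kind: str  # discordant | junction5 | junction3
    qname: str
    chrom: str
    start: int
    end: int
    strand: str
    te_offset: int = 0
    te_len: int = 0
    junction_point: int | None = None
    flank: str | None = None  # 'left' (upstream of element) or 'right'
    elem_orient: str | None = None

    @property
    def position(self) -> int:
        """Representative genomic position used for clustering."""
        if self.junction_point is not None:
            return self.junction_point
        return self.end if self.strand == "+" else self.start


@dataclass
class InsertionCall:
    chrom: str
    start: int
    end: int  # == start + tsd_len when both junction sides recovered
    orientation: str
    tsd_len: int
    tsd_seq: str | None
    n_discordant: int
    n_junction5: int
    n_junction3: int
    status: str  # novel | preexisting | control_shared | low_support

    @property
    def point(self) -> int:
        return self.start


@dataclass
class JunctionFragment:
    sequence: str
    qname: str
    kind: str  # junction5/junction3 (element extremity matched)
    flank: str  # left/right in read-forward coordinates
    elem_orient: str


# ---------------------------------------------------------------------------
# Masking


def mask_te_copies(genome: GenomeAssembly, te_intervals: list[GenomicInterval]) -> GenomeAssembly:
    """Replace the bases of every pre-existing element copy with N.

    Overlapping intervals are merged silently; out-of-bounds intervals raise.
    Chromosome lengths are unchanged, so coordinates stay comparable.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in te_intervals:
        if iv.chrom not in genome:
            raise ValueError(f"interval on unknown chromosome {iv.chrom}")
        if iv.end > genome.lengths[iv.chrom]:
            raise ValueError(f"interval {iv} out of bounds")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    new_seqs: dict[str, str] = {}
    for chrom, ivs in by_chrom.items():
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        seq = genome[chrom]
        parts, cursor = [], 0
        for s, e in merged:
            parts.append(seq[cursor:s])
            parts.append("N" * (e - s))
            cursor = e
        parts.append(seq[cursor:])
        new_seqs[chrom] = "".join(parts)
    return genome.with_sequences(new_seqs)


def masked_runs(genome: GenomeAssembly, min_len: int = 50) -> list[GenomicInterval]:
    """N-runs of a (masked) assembly, for labeling clusters at old copies."""
    out = []
    for chrom, seq in genome.items():
        i = seq.find("N")
        while i != -1:
            j = i
            while j < len(seq) and seq[j] == "N":
                j += 1
            if j - i >= min_len:
                out.append(GenomicInterval(chrom, i, j))
            i = seq.find("N", j)
    return out


# ---------------------------------------------------------------------------
# LTR matching (seed and extend, ungapped)

_SEED_K = 14
_SEED_STEP = 7


class LTRIndex:
    """Exact k-mer seed index over the LTR and its reverse complement."""

    def __init__(self, te: TEConsensus):
        self.te = te
        self.targets = {"+": te.ltr5_seq, "-": revcomp(te.ltr5_seq)}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for strand, target in self.targets.items():
            for j in range(len(target) - _SEED_K + 1):
                self.seeds.setdefault(target[j : j + _SEED_K], []).append((strand, j))


def _best_diagonal_segment(read: str, target: str, diag: int) -> tuple[int, int, int, int]:
    """Best-scoring ungapped segment on a diagonal (read pos - target pos =
    diag), via 1-D Smith-Waterman (match +1, mismatch -3). Returns
    (read_start, read_end, matches, length)."""
    i0 = max(0, diag)
    i1 = min(len(read), len(target) + diag)
    best = (0, 0, 0, 0)
    score = 0.0
    seg_start = i0
    seg_matches = 0
    best_score = 0.0
    for i in range(i0, i1):
        hit = read[i] == target[i - diag]
        delta = 1.0 if hit else -3.0
        if score + delta <= 0:
            score = 0.0
            seg_start = i + 1
            seg_matches = 0
            continue
        score += delta
        seg_matches += int(hit)
        if score > best_score:
            best_score = score
            best = (seg_start, i + 1, seg_matches, i + 1 - seg_start)
    return best


def match_to_ltr(sequence: str, te_or_index: TEConsensus | LTRIndex,
                 params: DetectionParams) -> TEMatch | None:
    """Best ungapped local match of a read to either LTR, on either strand.

    Returns ``None`` unless the match reaches ``min_ltr_match`` bp at
    ``min_ltr_identity``. Because the two LTRs are identical by definition,
    matching is performed against a single LTR sequence; the offset is an
    LTR-internal coordinate.
    """
    if len(sequence) < params.min_ltr_match:
        return None
    index = te_or_index if isinstance(te_or_index, LTRIndex) else LTRIndex(te_or_index)
    diagonals: set[tuple[str, int]] = set()
    for i in range(0, len(sequence) - _SEED_K + 1, _SEED_STEP):
        for strand, j in index.seeds.get(sequence[i : i + _SEED_K], ()):
            diagonals.add((strand, i - j))
    best: TEMatch | None = None
    for strand, diag in diagonals:
        target = index.targets[strand]
        r0, r1, matches, length = _best_diagonal_segment(sequence, target, diag)
        if length < params.min_ltr_match:
            continue
        identity = matches / length
        if identity < params.min_ltr_identity:
            continue
        if best is None or length > best.length:
            best = TEMatch(strand=strand, read_span=(r0, r1),
                           ltr_span=(r0 - diag, r1 - diag),
                           length=length, identity=identity)
    return best


# ---------------------------------------------------------------------------
# Step 1: discordant pairs


def find_discordant_candidates(alignments: list[AlignmentRecord], te: TEConsensus,
                               params: DetectionParams,
                               index: LTRIndex | None = None) -> list[Evidence]:
    """Pairs with exactly one uniquely mapped mate whose unmapped partner
    matches the LTR become discordant evidence anchored at the mapped mate."""
    index = index or LTRIndex(te)
    out: list[Evidence] = []
    for qname, mates in group_pairs(alignments).items():
        recs = [r for lst in mates.values() for r in lst]
        mapped = [r for r in recs if r.mapped and r.unique]
        unmapped = [r for r in recs if not r.mapped]
        if len(mapped) != 1 or len(unmapped) != 1:
            continue
        if match_to_ltr(unmapped[0].seq, index, params) is None:
            continue
        anchor = mapped[0]
        out.append(Evidence(kind="discordant", qname=qname, chrom=anchor.chrom,
                            start=anchor.pos, end=anchor.reference_end,
                            strand=anchor.strand))
    return out


# ---------------------------------------------------------------------------
# Step 2: junction reads

_EXTREMITY_SLACK = 2  # bp of tolerance for the match reaching read/LTR ends


def find_junction_fragments(reads: list[AlignmentRecord], te: TEConsensus,
                            params: DetectionParams,
                            index: LTRIndex | None = None) -> list[JunctionFragment]:
    """Trim the element part off reads that span a genome/LTR junction.

    A read qualifies when its prefix or suffix matches an LTR *extremity* —
    the match must reach the element's outer end — leaving a genomic
    fragment of at least ``min_fragment_len`` bp. The element extremity
    (5' vs 3') and match strand determine the element's orientation and
    which flank the fragment represents. Reads matching the LTR over their
    whole length yield no fragment.
    """
    index = index or LTRIndex(te)
    ltr_len = te.ltr_len
    out: list[JunctionFragment] = []
    for rec in reads:
        seq = rec.seq
        m = match_to_ltr(seq, index, params)
        if m is None:
            continue
        r0, r1 = m.read_span
        j0, j1 = m.ltr_span
        n = len(seq)
        te_at_end = (n - r1 <= _EXTREMITY_SLACK) and (j0 <= _EXTREMITY_SLACK)
        te_at_start = (r0 <= _EXTREMITY_SLACK) and (ltr_len - j1 <= _EXTREMITY_SLACK)
        if te_at_end and te_at_start:
            continue  # read is entirely LTR
        if te_at_end:
            frag = seq[:r0]
            flank = "left"
            extremity = "5" if m.strand == "+" else "3"
            orient = "+" if m.strand == "+" else "-"
        elif te_at_start:
            frag = seq[r1:]
            flank = "right"
            extremity = "3" if m.strand == "+" else "5"
            orient = "+" if m.strand == "+" else "-"
        else:
            continue  # internal LTR match: not a junction at an extremity
        if len(frag) < params.min_fragment_len:
            continue
        out.append(JunctionFragment(sequence=frag, qname=rec.qname,
                                    kind=f"junction{extremity}",
                                    flank=flank, elem_orient=orient))
    return out


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _find_with_mismatch(haystack: str, needle: str) -> list[int]:
    """Occurrences with <= 1 mismatch, by pigeonhole on exact halves."""
    half = len(needle) // 2
    cands = set()
    for off, part in ((0, needle[:half]), (half, needle[half:])):
        for p in _find_all(haystack, part):
            cands.add(p - off)
    out = []
    for p in sorted(cands):
        if p < 0 or p + len(needle) > len(haystack):
            continue
        mm = sum(a != b for a, b in zip(haystack[p : p + len(needle)], needle))
        if mm <= 1:
            out.append(p)
    return out


def remap_fragments(fragments: list[JunctionFragment], genome: GenomeAssembly,
                    params: DetectionParams) -> tuple[list[Evidence], int]:
    """Place trimmed genomic fragments by exact search on both strands of
    the unmasked reference.

    Fragments with exactly one hit become junction evidence whose junction
    point is the reference coordinate abutting the trimmed element sequence;
    ambiguous (>=2 hits) or unplaceable fragments are discarded and counted.
    A minus-strand placement flips flank side and element orientation.
    """
    finder = _find_all if params.remap_max_mismatches == 0 else _find_with_mismatch
    evidence: list[Evidence] = []
    discarded = 0
    for frag in fragments:
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(frag.sequence)
        for chrom, seq in genome.items():
            hits += [(chrom, p, "+") for p in finder(seq, frag.sequence)]
            hits += [(chrom, p, "-") for p in finder(seq, rc)]
            if len(hits) > 1:
                break
        if len(hits) != 1:
            discarded += 1
            continue
        chrom, pos, strand = hits[0]
        end = pos + len(frag.sequence)
        if strand == "+":
            flank, orient = frag.flank, frag.elem_orient
        else:  # reverse placement: element sits on the other side
            flank = "right" if frag.flank == "left" else "left"
            orient = "-" if frag.elem_orient == "+" else "+"
        point = end if flank == "left" else pos
        evidence.append(Evidence(kind=frag.kind, qname=frag.qname, chrom=chrom,
                                 start=pos, end=end, strand=strand,
                                 junction_point=point, flank=flank,
                                 elem_orient=orient))
    return evidence, discarded


# ---------------------------------------------------------------------------
# Clustering and calling


@dataclass
class EvidenceCluster:
    chrom: str
    evidence: list[Evidence] = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(e.kind == kind for e in self.evidence)

    @property
    def positions(self) -> list[int]:
        return [e.position for e in self.evidence]


def cluster_evidence(evidence: list[Evidence], params: DetectionParams) -> list[EvidenceCluster]:
    """Single-linkage clustering of evidence positions within
    ``cluster_window``; invariant to input order."""
    clusters: list[EvidenceCluster] = []
    for ev in sorted(evidence, key=lambda e: (e.chrom, e.position, e.qname, e.kind)):
        if (clusters and clusters[-1].chrom == ev.chrom
                and ev.position - clusters[-1].positions[-1] <= params.cluster_window):
            clusters[-1].evidence.append(ev)
        else:
            clusters.append(EvidenceCluster(ev.chrom, [ev]))
    return clusters


def _near(pos: int, chrom: str, intervals: list[GenomicInterval], window: int) -> bool:
    return any(iv.chrom == chrom and iv.start - window <= pos < iv.end + window
               for iv in intervals)


def call_insertions(clusters: list[EvidenceCluster],
                    preexisting_te_intervals: list[GenomicInterval],
                    control_calls: list[InsertionCall],
                    params: DetectionParams,
                    genome: GenomeAssembly | None = None) -> list[InsertionCall]:
    """Resolve clusters into insertion calls with TSD and status.

    Insertion interval: when both junction flanks are present it spans
    [3'-side junction, 5'-side junction) and its length is the TSD length
    (sequence extracted from ``genome`` when given); with one flank it is
    that single junction point; with none, the midpoint of the discordant
    anchors. Junction points within one evidence cluster are sub-clustered
    at ``max_tsd`` linkage, so two nearby insertions whose read evidence
    chains together still resolve separately; a both-sided sub-cluster whose
    implied TSD exceeds ``max_tsd`` is split into two single-sided
    candidates.
    """
    calls: list[InsertionCall] = []
    for cluster in clusters:
        junction_ev = sorted((e for e in cluster.evidence if e.junction_point is not None),
                             key=lambda e: e.junction_point)
        discordant_ev = [e for e in cluster.evidence if e.kind == "discordant"]

        # sub-cluster junction points: one sub-cluster per insertion site
        subclusters: list[list[Evidence]] = []
        for ev in junction_ev:
            if (subclusters
                    and ev.junction_point - subclusters[-1][-1].junction_point <= params.max_tsd):
                subclusters[-1].append(ev)
            else:
                subclusters.append([ev])
        if not subclusters:
            subclusters = [[]]

        # each discordant pair supports the nearest sub-cluster
        centers = [int(np.median([e.junction_point for e in sub])) if sub else None
                   for sub in subclusters]
        disc_of: list[list[Evidence]] = [[] for _ in subclusters]
        for ev in discordant_ev:
            if len(subclusters) == 1 or all(c is None for c in centers):
                disc_of[0].append(ev)
            else:
                k = min(range(len(centers)),
                        key=lambda i: abs(ev.position - centers[i]) if centers[i] is not None else 1 << 60)
                disc_of[k].append(ev)

        for sub, disc in zip(subclusters, disc_of):
            members = sub + disc
            nd = len(disc)
            n_j5 = sum(e.kind == "junction5" for e in sub)
            n_j3 = sum(e.kind == "junction3" for e in sub)
            left = sorted(e.junction_point for e in sub if e.flank == "left")
            right = sorted(e.junction_point for e in sub if e.flank == "right")

            sides: list[tuple[int, int, int, int, int]] = []  # start, end, nd, n5, n3
            if left and right:
                jl, jr = int(np.median(left)), int(np.median(right))
                start, end = min(jl, jr), max(jl, jr)
                if end - start > params.max_tsd:
                    half_l = [e for e in sub if e.flank == "left"]
                    half_r = [e for e in sub if e.flank == "right"]
                    sides.append((jl, jl, 0, sum(e.kind == "junction5" for e in half_l),
                                  sum(e.kind == "junction3" for e in half_l)))
                    sides.append((jr, jr, nd, sum(e.kind == "junction5" for e in half_r),
                                  sum(e.kind == "junction3" for e in half_r)))
                else:
                    sides.append((start, end, nd, n_j5, n_j3))
            elif left or right:
                p = int(np.median(left or right))
                sides.append((p, p, nd, n_j5, n_j3))
            elif disc:
                p = int(np.median([e.position for e in disc]))
                sides.append((p, p, nd, 0, 0))
            else:
                continue

            orient_votes = [e.elem_orient for e in members if e.elem_orient]
            if orient_votes:
                orientation = max(("+", "-"), key=orient_votes.count)
            else:
                orientation = "."

            for start, end, nd, n5, n3 in sides:
                tsd_len = end - start
                tsd_seq = None
                if tsd_len > 0 and genome is not None and cluster.chrom in genome:
                    tsd_seq = genome[cluster.chrom][start:end]
                if _near(start, cluster.chrom, preexisting_te_intervals, params.cluster_window):
                    status = "preexisting"
                elif any(c.chrom == cluster.chrom and abs(c.start - start) <= params.cluster_window
                         for c in control_calls):
                    status = "control_shared"
                elif nd < params.min_discordant or (n5 + n3) < params.min_junction:
                    status = "low_support"
                else:
                    status = "novel"
                calls.append(InsertionCall(chrom=cluster.chrom, start=start, end=end,
                                           orientation=orientation, tsd_len=tsd_len,
                                           tsd_seq=tsd_seq, n_discordant=nd,
                                           n_junction5=n5, n_junction3=n3, status=status))
    return calls


# ---------------------------------------------------------------------------
# End-to-end pipeline


def detect_insertions(alignments: list[AlignmentRecord], reference: GenomeAssembly,
                      te: TEConsensus, te_intervals: list[GenomicInterval],
                      params: DetectionParams | None = None,
                      control_calls: list[InsertionCall] | None = None) -> list[InsertionCall]:
    """Run the full two-step detection on a set of alignments.

    ``reference`` is the unmasked assembly; ``te_intervals`` locate the
    pre-existing element copies (they drive both masking-awareness in the
    status assignment and the 'preexisting' label).
    """
    params = params or DetectionParams()
    control_calls = control_calls or []
    index = LTRIndex(te)
    discordant = find_discordant_candidates(alignments, te, params, index)
    unmapped = [r for r in alignments if not r.mapped]
    clipped = [r for r in alignments
               if r.mapped and max(r.clip_left, r.clip_right) >= params.min_ltr_match]
    fragments = find_junction_fragments(unmapped + clipped, te, params, index)
    junction_ev, _ = remap_fragments(fragments, reference, params)
    clusters = cluster_evidence(discordant + junction_ev, params)
    masked_reference = mask_te_copies(reference, te_intervals)
    known = list(te_intervals) + masked_runs(masked_reference)
    return call_insertions(clusters, known, control_calls, params, genome=reference)


# ---------------------------------------------------------------------------
# In-silico PCR validation


def insilico_pcr(chrom_seq: str, left_primer: str, right_primer: str,
                 max_product: int = 30_000) -> int | None:
    """Product length of a primer pair on one chromosome sequence, or None.

    ``right_primer`` is given 5'->3' on the minus strand, as a bench primer
    would be; amplification requires its reverse complement downstream of
    the left primer within ``max_product`` bp.
    """
    a = chrom_seq.find(left_primer)
    if a == -1:
        return None
    site = revcomp(right_primer)
    b = chrom_seq.find(site, a)
    if b == -1 or b + len(site) - a > max_product:
        return None
    return b + len(site) - a


def validate_call_by_pcr(call: InsertionCall, reference: GenomeAssembly,
                         mutated: GenomeAssembly, element_len: int,
                         primer_len: int = 25, offset: int = 150) -> bool:
    """Design flanking primers around a call and check that they amplify a
    product longer by exactly element + TSD in the insertion-carrying genome
    than in the reference."""
    seq_ref = reference[call.chrom]
    left = seq_ref[call.start - offset : call.start - offset + primer_len]
    right_site = seq_ref[call.end + offset - primer_len : call.end + offset]
    right = revcomp(right_site)
    prod_ref = insilico_pcr(seq_ref, left, right)
    prod_mut = insilico_pcr(mutated[call.chrom], left, right)
    if prod_ref is None or prod_mut is None:
        return False
    return prod_mut - prod_ref == element_len + call.tsd_len
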