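"""From raw reads to classified mtDNA polymorphisms.

Stages: read QC (trim, length, mean-Phred), cost-based semi-global alignment
(mismatch 2, insertion/deletion 3, 80% identity acceptance), duplicate
exclusion, strand-split pileup, two-pass consensus/remap, threshold-based
variant calling (>=50 supporting reads, >=3% frequency, both strands),
SNP vs heteroplasmic-variant classification, annotation, per-gene-region
susceptibility densities, and mean variant load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .genome import (AnnotatedGenome, MthapError, ReadRecord, feature_at,
                     revcomp, translate_codon_change)
from .simulate import HaplotypeConsensus

log = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_BASE = "ACGTN-"
_DEL = 5  # allele code for a deletion in the pileup


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCParams:
    min_length: int = 15
    trim_each_end: int = 1
    min_phred: float = 15.0

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.trim_each_end < 0 or self.min_phred < 0:
            raise ValueError("QC parameters must be >= 0")


@dataclass
class QCReport:
    n_input: int = 0
    n_too_short: int = 0
    n_low_quality: int = 0
    n_kept: int = 0


def qc_reads(reads: Sequence[ReadRecord],
             params: QCParams = QCParams()) -> tuple[list[ReadRecord], QCReport]:
    """Trim first, then drop short reads, then drop low mean-Phred reads."""
    report = QCReport()
    kept: list[ReadRecord] = []
    t = params.trim_each_end
    for r in reads:
        report.n_input += 1
        bases = r.bases[t: len(r.bases) - t] if t else r.bases
        quals = r.quals[t: len(r.quals) - t] if t else r.quals
        if len(bases) < params.min_length:
            report.n_too_short += 1
            continue
        if sum(quals) / len(quals) < params.min_phred:
            report.n_low_quality += 1
            continue
        kept.append(ReadRecord(r.id, bases, list(quals)))
        report.n_kept += 1
    return kept, report


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignParams:
    mismatch_cost: float = 2.0
    indel_cost: float = 3.0
    min_identity: float = 0.80
    kmer: int = 13
    band_width: int = 16   # window padding around a seeded locus for DP

    def __post_init__(self) -> None:
        if self.mismatch_cost <= 0 or self.indel_cost <= 0:
            raise ValueError("alignment costs must be positive")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0,1]")


@dataclass
class AlignedRead:
    id: str
    ref_start: int            # 1-based inclusive
    ref_end: int
    strand: str
    ops: list[tuple[str, int]]  # runs of M(match) X(mismatch) I(ins) D(del)
    identity: float
    cost: float
    bases: str                # read bases in reference orientation

    @property
    def span_key(self) -> tuple[int, int, str]:
        return (self.ref_start, self.ref_end, self.strand)


class ReferenceIndex:
    """Exact k-mer index over a reference sequence for seeding alignments."""

    def __init__(self, sequence: str, k: int = 13):
        self.sequence = sequence
        self.k = k
        self.index: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            self.index.setdefault(sequence[i: i + k], []).append(i)

    def candidates(self, read: str, max_seeds: int = 4) -> set[int]:
        """Candidate 0-based start offsets of the read on the reference."""
        k = self.k
        if len(read) < k:
            return set(range(0, len(self.sequence) - len(read) + 1))
        offsets = sorted({0, len(read) // 3, 2 * len(read) // 3,
                          len(read) - k})[:max_seeds]
        cands: set[int] = set()
        for off in offsets:
            for hit in self.index.get(read[off: off + k], ()):
                start = hit - off
                if 0 <= start <= len(self.sequence) - 1:
                    cands.add(start)
        if not cands and len(read) < 3 * k:
            # a short read cannot host a mismatch-free seed window at every
            # offset; fall back to scanning all placements
            return set(range(0, len(self.sequence) - len(read) + 1))
        return cands


def _gapless(read: str, ref: str, start: int) -> Optional[tuple[float, int]]:
    """(cost, mismatches) of a gapless placement, or None if out of range."""
    if start < 0 or start + len(read) > len(ref):
        return None
    window = ref[start: start + len(read)]
    mm = sum(1 for a, b in zip(read, window) if a != b)
    return (2.0 * mm, mm)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0.0
    aligner.mismatch_score = -params.mismatch_cost
    aligner.open_gap_score = -params.indel_cost
    aligner.extend_gap_score = -params.indel_cost
    # read global, reference local: the reference overhang (end gaps in the
    # query row) is free
    if hasattr(type(aligner), "open_end_deletion_score"):
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # older attribute names
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def _dp_align(read: str, ref: str, window_start: int, window_end: int,
              aligner: Align.PairwiseAligner
              ) -> Optional[tuple[float, int, int, list[tuple[str, int]], float]]:
    """DP alignment of the read within ref[window_start:window_end].

    Returns (cost, ref_start0, ref_end0_exclusive, ops, identity).
    """
    window = ref[max(0, window_start): min(len(ref), window_end)]
    base = max(0, window_start)
    if not window:
        return None
    aln = aligner.align(window, read)[0]
    cost = -aln.score
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return None
    ops: list[tuple[str, int]] = []
    matches = 0

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if prev_t is not None:
            push("D", t0 - prev_t)   # gap in query = deletion from read
            push("I", q0 - prev_q)   # gap in target = insertion in read
        for a, b in zip(window[t0:t1], read[q0:q1]):
            if a == b:
                push("M", 1)
                matches += 1
            else:
                push("X", 1)
        prev_t, prev_q = t1, q1
    # query end gaps (read bases beyond the window edge) count as insertions
    push("I", qblocks[0][0])
    push("I", len(read) - qblocks[-1][1])
    columns = sum(n for _, n in ops)
    identity = matches / columns if columns else 0.0
    ref_start0 = base + tblocks[0][0]
    ref_end0 = base + tblocks[-1][1]
    return cost, ref_start0, ref_end0, ops, identity


def align_read(read: ReadRecord, reference: str, params: AlignParams,
               index: Optional[ReferenceIndex] = None,
               aligner: Optional[Align.PairwiseAligner] = None,
               ) -> Optional[AlignedRead]:
    """Minimum-cost semi-global placement of a read; None if rejected.

    Both orientations are tried and the better kept. A read placing at two
    distinct loci with equal cost is flagged multi-mapping and excluded.
    Candidate loci come from exact k-mer seeds; a gapless placement with <= 2
    mismatches is provably optimal under the cost scheme (an indel pair costs
    more), otherwise a windowed dynamic program refines the best locus.
    """
    if index is None:
        index = ReferenceIndex(reference, params.kmer)
    if aligner is None:
        aligner = _make_aligner(params)

    best: Optional[dict] = None
    tie = False
    for strand, oriented in (("+", read.bases), ("-", revcomp(read.bases))):
        cands = index.candidates(oriented)
        if not cands:
            continue
        scored = []
        for start in cands:
            g = _gapless(oriented, reference, start)
            if g is not None:
                scored.append((g[0], g[1], start))
        if not scored:
            continue
        scored.sort()
        for cost, mm, start in scored[:3]:
            if mm <= 1:  # provably optimal: any indel pair costs >= 6
                result = dict(
                    cost=cost, strand=strand, bases=oriented,
                    ref_start0=start, ref_end0=start + len(oriented),
                    ops=_gapless_ops(oriented, reference, start),
                    identity=(len(oriented) - mm) / len(oriented),
                )
            else:
                pad = int(params.band_width)
                dp = _dp_align(oriented, reference, start - pad,
                               start + len(oriented) + pad, aligner)
                if dp is None:
                    continue
                cost, s0, e0, ops, ident = dp
                result = dict(cost=cost, strand=strand, bases=oriented,
                              ref_start0=s0, ref_end0=e0, ops=ops,
                              identity=ident)
            if best is None or result["cost"] < best["cost"] - 1e-9:
                best, tie = result, False
            elif abs(result["cost"] - best["cost"]) <= 1e-9:
                if (abs(result["ref_start0"] - best["ref_start0"]) > 5
                        or result["strand"] != best["strand"]):
                    tie = True

    if best is None:
        return None
    if tie:
        log.debug("read %s flagged multi-mapping; excluded", read.id)
        return None
    if best["identity"] < params.min_identity:
        return None
    return AlignedRead(
        id=read.id,
        ref_start=best["ref_start0"] + 1,
        ref_end=best["ref_end0"],
        strand=best["strand"],
        ops=best["ops"],
        identity=best["identity"],
        cost=best["cost"],
        bases=best["bases"],
    )


def _gapless_ops(read: str, ref: str, start: int) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    for a, b in zip(read, ref[start: start + len(read)]):
        op = "M" if a == b else "X"
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ops


def align_reads(reads: Sequence[ReadRecord], reference: str,
                params: AlignParams = AlignParams()) -> list[AlignedRead]:
    index = ReferenceIndex(reference, params.kmer)
    aligner = _make_aligner(params)
    out = []
    for r in reads:
        a = align_read(r, reference, params, index, aligner)
        if a is not None:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def dedup(aligned: Sequence[AlignedRead]) -> tuple[list[AlignedRead], int]:
    """Collapse reads sharing (ref_start, ref_end, strand) to the first seen."""
    seen: set[tuple[int, int, str]] = set()
    kept: list[AlignedRead] = []
    for a in aligned:
        if a.span_key in seen:
            continue
        seen.add(a.span_key)
        kept.append(a)
    n_removed = len(aligned) - len(kept)
    if n_removed:
        log.info("dedup: removed %d duplicate reads", n_removed)
    return kept, n_removed


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

@dataclass
class Pileup:
    """Per-position allele counts split by strand over [1, L].

    counts[strand, code, pos0] with codes A,C,G,T,N and deletion; anchored
    insertion sequences are tallied separately.
    """

    length: int
    counts: np.ndarray                      # (2, 6, L) int32
    insertions: dict[tuple[int, str], list] # (anchor pos, seq) -> [fwd, rev]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(0, 1))

    def allele_counts(self, position: int) -> dict[str, tuple[int, int]]:
        """allele -> (fwd, rev) at a 1-based position."""
        c = self.counts[:, :, position - 1]
        return {_CODE_BASE[k]: (int(c[0, k]), int(c[1, k]))
                for k in range(6) if c[:, k].sum() > 0}


def build_pileup(aligned: Sequence[AlignedRead], length: int) -> Pileup:
    counts = np.zeros((2, 6, length), dtype=np.int32)
    insertions: dict[tuple[int, str], list] = {}
    lut = np.full(256, 4, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c

    pos_chunks: dict[int, list[np.ndarray]] = {0: [], 1: []}
    code_chunks: dict[int, list[np.ndarray]] = {0: [], 1: []}

    for a in aligned:
        si = 0 if a.strand == "+" else 1
        simple = all(op in "MX" for op, _ in a.ops)
        if simple:
            codes = lut[np.frombuffer(a.bases.encode(), dtype=np.uint8)]
            pos_chunks[si].append(
                np.arange(a.ref_start - 1, a.ref_start - 1 + len(codes)))
            code_chunks[si].append(codes)
            continue
        # walk ops for gapped reads
        rpos = a.ref_start - 1
        qpos = 0
        for op, n in a.ops:
            if op in "MX":
                for k in range(n):
                    counts[si, lut[ord(a.bases[qpos + k])], rpos + k] += 1
                rpos += n
                qpos += n
            elif op == "D":
                counts[si, _DEL, rpos: rpos + n] += 1
                rpos += n
            else:  # I: inserted bases anchored after the previous ref position
                key = (rpos, a.bases[qpos: qpos + n])  # anchor = rpos (1-based)
                insertions.setdefault(key, [0, 0])[si] += 1
                qpos += n

    for si in (0, 1):
        if pos_chunks[si]:
            allpos = np.concatenate(pos_chunks[si])
            allcode = np.concatenate(code_chunks[si]).astype(np.int64)
            np.add.at(counts[si], (allcode, allpos), 1)
    return Pileup(length=length, counts=counts, insertions=insertions)


# ---------------------------------------------------------------------------
# consensus and calling
# ---------------------------------------------------------------------------

@dataclass
class CallThresholds:
    min_variant_reads: int = 50
    min_frequency: float = 0.03
    require_both_strands: bool = True
    min_consensus_depth: int = 10


def build_consensus(pileup: Pileup, reference: AnnotatedGenome,
                    min_consensus_depth: int = 10) -> HaplotypeConsensus:
    """Majority-rule representative sequence for an individual.

    Per position: the majority allele (including deletion) replaces the
    reference base if its frequency exceeds 0.5 and depth >= the floor;
    otherwise the reference base is retained. Majority insertions are folded
    in. The result carries a projection map back to reference numbering.
    """
    totals = pileup.counts.sum(axis=0)           # (6, L)
    depth = totals.sum(axis=0)
    ins_by_anchor: dict[int, str] = {}
    for (anchor, seq), (f, r) in pileup.insertions.items():
        if anchor >= 1 and depth[anchor - 1] >= min_consensus_depth:
            if (f + r) / depth[anchor - 1] > 0.5:
                ins_by_anchor[anchor] = seq

    seq: list[str] = []
    ref_map: list[Optional[int]] = []
    for pos in range(1, reference.length + 1):
        base = reference.base(pos)
        if depth[pos - 1] >= min_consensus_depth:
            k = int(totals[:, pos - 1].argmax())
            if totals[k, pos - 1] / depth[pos - 1] > 0.5:
                if k == _DEL:
                    base = None
                elif _CODE_BASE[k] != "N":
                    base = _CODE_BASE[k]
        if base is not None:
            seq.append(base)
            ref_map.append(pos)
        if pos in ins_by_anchor:
            for b in ins_by_anchor[pos]:
                seq.append(b)
                ref_map.append(None)
    return HaplotypeConsensus("consensus", "".join(seq), ref_map)


@dataclass
class VariantCall:
    position: int            # reference coordinate (anchor for indels)
    ref: str
    alt: str
    kind: str                # SNV | insertion | deletion
    frequency: float
    fwd_count: int
    rev_count: int
    depth: int
    name: str

    def __post_init__(self) -> None:
        if not 0 < self.frequency <= 1:
            raise ValueError("frequency must be in (0,1]")


def _call_name(position, ref, alt, kind, suffix=0) -> str:
    pos = f"{position}+{suffix}" if suffix else str(position)
    if kind == "SNV":
        return f"{pos}{ref}>{alt}"
    if kind == "deletion":
        return f"{pos}del{ref}"
    return f"{pos}ins{alt}"


def remap_and_call(reads: Sequence[ReadRecord],
                   consensus: HaplotypeConsensus,
                   reference: AnnotatedGenome,
                   align_params: AlignParams = AlignParams(),
                   thresholds: CallThresholds = CallThresholds(),
                   ) -> list[VariantCall]:
    """Second alignment pass against the representative sequence, then calls.

    An allele is called at a (projected) reference position when it differs
    from the reference allele there and meets ALL of: supporting reads >= the
    floor, frequency >= the threshold, and >= 1 forward plus >= 1 reverse
    supporting read. Positions created by consensus insertions (no reference
    coordinate) are reported with a "+k" suffix on the anchor coordinate.
    """
    aligned = align_reads(reads, consensus.sequence, align_params)
    aligned, _ = dedup(aligned)
    pileup = build_pileup(aligned, len(consensus.sequence))
    return call_from_pileup(pileup, consensus, reference, thresholds)


def call_from_pileup(pileup: Pileup, consensus: HaplotypeConsensus,
                     reference: AnnotatedGenome,
                     thresholds: CallThresholds) -> list[VariantCall]:
    calls: list[VariantCall] = []
    depth = pileup.depth
    t = thresholds

    def emit(position, ref, alt, kind, fwd, rev, dp, suffix=0):
        support = fwd + rev
        if dp == 0 or support < t.min_variant_reads:
            return
        freq = support / dp
        if freq < t.min_frequency:
            return
        if t.require_both_strands and (fwd < 1 or rev < 1):
            return
        calls.append(VariantCall(
            position=position, ref=ref, alt=alt, kind=kind,
            frequency=freq, fwd_count=fwd, rev_count=rev, depth=int(dp),
            name=_call_name(position, ref, alt, kind, suffix)))

    # anchor info for consensus insertions (positions with no ref coordinate)
    last_ref = 0
    suffix_k = 0
    for i in range(len(consensus.sequence)):
        ref_pos = consensus.ref_map[i]
        dp = int(depth[i])
        if ref_pos is not None:
            last_ref, suffix_k = ref_pos, 0
            ref_base = reference.base(ref_pos)
        else:
            suffix_k += 1
            ref_base = None
        for allele, (f, r) in pileup.allele_counts(i + 1).items():
            if allele == "N":
                continue
            if ref_pos is not None:
                if allele == ref_base:
                    continue
                if allele == "-":
                    emit(ref_pos, ref_base, "", "deletion", f, r, dp)
                else:
                    emit(ref_pos, ref_base, allele, "SNV", f, r, dp)
            else:
                # inside a consensus insertion: the inserted allele itself is
                # an insertion relative to the reference; anything else gets
                # the suffix-coordinate convention
                if allele == "-":
                    continue
                emit(last_ref, "", allele, "insertion", f, r, dp,
                     suffix=0 if allele == consensus.sequence[i] else suffix_k)

    # read-level insertions relative to the consensus
    for (anchor, seq), (f, r) in pileup.insertions.items():
        if anchor < 1:
            continue
        dp = int(depth[anchor - 1])
        ref_pos = consensus.ref_map[anchor - 1]
        if ref_pos is None:
            ref_pos = next((p for p in reversed(consensus.ref_map[:anchor])
                            if p is not None), 0)
        emit(ref_pos, "", seq, "insertion", f, r, dp)

    calls.sort(key=lambda c: (c.position, c.name))
    return calls


def call_variants(reads: Sequence[ReadRecord],
                  reference: AnnotatedGenome,
                  qc_params: QCParams = QCParams(),
                  align_params: AlignParams = AlignParams(),
                  thresholds: CallThresholds = CallThresholds(),
                  ) -> tuple[list[VariantCall], HaplotypeConsensus, QCReport]:
    """Full two-pass pipeline: QC -> align -> dedup -> consensus -> remap -> call."""
    kept, report = qc_reads(reads, qc_params)
    aligned = align_reads(kept, reference.sequence, align_params)
    aligned, _ = dedup(aligned)
    pileup = build_pileup(aligned, reference.length)
    consensus = build_consensus(pileup, reference,
                                thresholds.min_consensus_depth)
    calls = remap_and_call(kept, consensus, reference, align_params, thresholds)
    return calls, consensus, report


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifiedPolymorphism:
    individual: str
    haplotype: str
    call: VariantCall
    cls: str                      # haplotype_SNP | heteroplasmic_variant | unclassified
    feature: str = ""
    complex: str = ""
    aa_change: Optional[str] = None


def classify_polymorphisms(
    calls_by_individual: dict[str, list[VariantCall]],
    haplotype_of: dict[str, str],
    snp_frequency: float = 0.90,
    variant_band: tuple[float, float] = (0.03, 0.49),
) -> list[ClassifiedPolymorphism]:
    """Partition calls into haplotype SNPs, heteroplasmic variants, and the rest.

    A haplotype SNP is an allele present at > ``snp_frequency`` in every
    replicate of exactly one haplotype and in no individual of any other
    haplotype. Heteroplasmic variants sit in the 3-49% band. Frequencies in
    (49%, 90%] that fail the SNP rule are reported as unclassified, never
    dropped.
    """
    missing = set(calls_by_individual) - set(haplotype_of)
    if missing:
        raise MthapError(f"individuals missing a haplotype label: "
                         f"{sorted(missing)}")
    by_hap: dict[str, list[str]] = {}
    for ind, hap in haplotype_of.items():
        if ind in calls_by_individual:
            by_hap.setdefault(hap, []).append(ind)

    def key(c: VariantCall):
        return (c.position, c.alt, c.kind)

    high: dict[tuple, set[str]] = {}   # variant key -> individuals at >90%
    for ind, calls in calls_by_individual.items():
        for c in calls:
            if c.frequency > snp_frequency:
                high.setdefault(key(c), set()).add(ind)

    snp_keys: set[tuple] = set()
    for k, carriers in high.items():
        haps = {haplotype_of[i] for i in carriers}
        if len(haps) == 1:
            (hap,) = haps
            if carriers == set(by_hap.get(hap, [])):
                snp_keys.add(k)

    lo, hi = variant_band
    out: list[ClassifiedPolymorphism] = []
    for ind, calls in calls_by_individual.items():
        for c in calls:
            if c.frequency > snp_frequency and key(c) in snp_keys:
                cls = "haplotype_SNP"
            elif lo <= c.frequency <= hi:
                cls = "heteroplasmic_variant"
            else:
                cls = "unclassified"
            out.append(ClassifiedPolymorphism(
                individual=ind, haplotype=haplotype_of[ind], call=c, cls=cls))
    return out


def annotate_polymorphisms(classified: Sequence[ClassifiedPolymorphism],
                           genome: AnnotatedGenome) -> None:
    """Attach feature names, ETC complex, and amino-acid change in place."""
    for item in classified:
        c = item.call
        feats = feature_at(genome, max(1, min(c.position, genome.length)))
        item.feature = ";".join(f.name for f in feats) or "intergenic"
        item.complex = ";".join(sorted({f.complex for f in feats if f.complex}))
        if c.kind == "SNV":
            for f in feats:
                if f.kind == "CDS":
                    try:
                        item.aa_change = translate_codon_change(
                            genome, f, c.position, c.ref, c.alt).hgvs
                    except MthapError:
                        item.aa_change = None
                    break


# ---------------------------------------------------------------------------
# susceptibility and variant load
# ---------------------------------------------------------------------------

def susceptibility_profile(variants: Sequence[VariantCall],
                           genome: AnnotatedGenome) -> pd.DataFrame:
    """Variant counts normalized to the size (bp) of each gene region.

    A variant overlapping two features is counted once per feature; ETC
    complexes aggregate the counts and lengths of their member CDSs. Variants
    in unannotated gaps are tallied under "intergenic".
    """
    rows = []
    counts: dict[str, int] = {f.name: 0 for f in genome.features}
    counts["intergenic"] = 0
    for v in variants:
        feats = feature_at(genome, max(1, min(v.position, genome.length)))
        if not feats:
            counts["intergenic"] += 1
        for f in feats:
            counts[f.name] += 1

    intergenic_len = genome.length - len({
        p for f in genome.features if f.kind != "motif"
        for p in range(f.start, f.end + 1)})
    for f in genome.features:
        rows.append(("feature", f.name, f.kind, f.complex or "",
                     counts[f.name], f.length(genome.length)))
    rows.append(("feature", "intergenic", "intergenic", "",
                 counts["intergenic"], max(intergenic_len, 1)))

    for cplx in ("I", "III", "IV", "V"):
        members = [f for f in genome.features
                   if f.kind == "CDS" and f.complex == cplx]
        if not members:
            continue
        total = sum(counts[f.name] for f in members)
        size = sum(f.length(genome.length) for f in members)
        rows.append(("complex", cplx, "CDS", cplx, total, size))

    df = pd.DataFrame(rows, columns=["level", "region", "kind", "complex",
                                     "variant_count", "length_bp"])
    df["density"] = df["variant_count"] / df["length_bp"]
    return df


def variant_load(calls_by_individual: dict[str, list[VariantCall]],
                 haplotype_of: dict[str, str],
                 frequency_floor: float = 0.0,
                 band: tuple[float, float] = (0.03, 0.49)) -> dict[str, float]:
    """Mean heteroplasmic-variant count per sample, per haplotype.

    With ``frequency_floor`` = 0.25 only variants above 25% frequency count,
    reproducing the ">25%" subset used for oocyte-quality correlations.
    """
    groups: dict[str, list[int]] = {}
    lo, hi = band
    for ind, calls in calls_by_individual.items():
        if ind not in haplotype_of:
            raise MthapError(f"individual {ind} has no haplotype label")
        n = sum(1 for c in calls
                if lo <= c.frequency <= hi and c.frequency > frequency_floor)
        groups.setdefault(haplotype_of[ind], []).append(n)
    empty = [h for h, ns in groups.items() if not ns]
    if empty or not groups:
        raise MthapError("every haplotype group needs >= 1 sample")
    return {h: float(np.mean(ns)) for h, ns in sorted(groups.items())}
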