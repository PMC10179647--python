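"""Amplicon editing-outcome classification.

Pipeline mirroring standard CRISPR amplicon practice: quality-trim paired
reads, merge mates over their overlap, align merged reads globally to the
reporter reference (free end gaps on the reference side), call indels over
a defined guide window, and count unique window haplotypes into frame
classes (unedited / substitution-only / N−1 / N−2 / N−3 in-frame / HDR).

When a repaired reference is supplied (the defective reference with the
template-restored segment inserted), each read is assigned the backbone
that explains it better; reads explained by the repaired backbone without
any indel in the window are called HDR — point substitutions are treated
as sequencing noise there, exactly as they are for unedited reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .reporter_model import EditEvent, FrameClass, frame_class, revcomp


class PairingError(ValueError):
    pass


class EmptyTableError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisWindow:
    """0-based half-open window on the reference (≥ 20 nt)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 20:
            raise ValueError(f"window {self.name}: length must be >= 20")

    @classmethod
    def from_one_based(cls, name: str, start1: int, end1: int) -> "AnalysisWindow":
        """From 1-based inclusive coordinates (GenBank convention)."""
        return cls(name, start1 - 1, end1)


# ---------------------------------------------------------------- trimming


def quality_trim(
    reads: list[BioSeqRecord], min_q: int = 20, window: int = 4, min_len: int = 40
) -> list[BioSeqRecord]:
    """3'-trim each read at the first sliding window whose mean Phred
    quality falls below ``min_q``; drop reads shorter than ``min_len``."""
    out = []
    for rec in reads:
        quals = rec.letter_annotations["phred_quality"]
        cut = len(rec)
        for i in range(0, len(quals) - window + 1):
            if sum(quals[i : i + window]) / window < min_q:
                # cut at the first failing base inside the window
                cut = next(j for j in range(i, i + window) if quals[j] < min_q)
                break
        if cut >= min_len:
            out.append(rec[:cut] if cut < len(rec) else rec)
    return out


# ----------------------------------------------------------------- merging


@dataclass
class MergeResult:
    merged: list[BioSeqRecord]
    unmerged: list[tuple[BioSeqRecord, BioSeqRecord]]


def _merge_one(
    r1: BioSeqRecord, r2: BioSeqRecord, min_overlap: int, max_mismatch_frac: float
) -> BioSeqRecord | None:
    s1 = str(r1.seq)
    s2 = revcomp(str(r2.seq))
    q1 = np.asarray(r1.letter_annotations["phred_quality"])
    q2 = np.asarray(r2.letter_annotations["phred_quality"])[::-1]
    a = np.frombuffer(s1.encode(), dtype="S1")
    b = np.frombuffer(s2.encode(), dtype="S1")
    l1, l2 = len(a), len(b)

    best_o, best_frac = 0, None
    for o in range(min_overlap, min(l1, l2) + 1):
        frac = float(np.count_nonzero(a[l1 - o :] != b[:o])) / o
        if best_frac is None or frac < best_frac - 1e-12 or (abs(frac - best_frac) <= 1e-12 and o > best_o):
            best_o, best_frac = o, frac
    if best_frac is None or best_frac > max_mismatch_frac:
        return None

    o = best_o
    ov_a, ov_b = a[l1 - o :].copy(), b[:o]
    qa, qb = q1[l1 - o :].copy(), q2[:o]
    take_b = qb > qa
    ov_a[take_b] = ov_b[take_b]
    qa = np.maximum(qa, qb)
    seq = a[: l1 - o].tobytes().decode() + ov_a.tobytes().decode() + b[o:].tobytes().decode()
    quals = list(q1[: l1 - o]) + list(qa) + list(q2[o:])
    rec = BioSeqRecord(r1.seq.__class__(seq), id=r1.id, description="merged")
    rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
    return rec


def merge_pairs(
    r1s: list[BioSeqRecord],
    r2s: list[BioSeqRecord],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergeResult:
    """Merge mate pairs over the best overlap of their 3' ends.

    R2 is reverse-complemented; the overlap length minimizing the mismatch
    fraction (ties to the longer overlap) is accepted when the fraction is
    at most ``max_mismatch_frac``; disagreeing bases take the
    higher-quality call.
    """
    if len(r1s) != len(r2s):
        raise PairingError(f"mate count mismatch: {len(r1s)} vs {len(r2s)}")
    res = MergeResult([], [])
    for r1, r2 in zip(r1s, r2s):
        m = _merge_one(r1, r2, min_overlap, max_mismatch_frac)
        if m is None:
            res.unmerged.append((r1, r2))
        else:
            res.merged.append(m)
    return res


# ---------------------------------------------------------------- alignment


@dataclass
class AlignScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0  # charged once per gap, on top of per-base extension
    gap_extend: float = -1.0


@dataclass
class Alignment:
    """Glocal alignment of a read against the reference.

    ``ops`` is a CIGAR-like list of (op, length) with op in {'M','I','D'};
    'M' covers both matches and mismatches. ``ref_start`` is the reference
    coordinate of the first aligned base.
    """

    read: str
    ref_start: int
    ops: list[tuple[str, int]]
    score: float

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD")


_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(sc: AlignScoring) -> Align.PairwiseAligner:
    key = (sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
    if key not in _aligner_cache:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = sc.match
        al.mismatch_score = sc.mismatch
        al.open_gap_score = sc.gap_open + sc.gap_extend
        al.extend_gap_score = sc.gap_extend
        # reference (target) overhangs are free: end gaps in the query row
        al.open_left_deletion_score = 0.0
        al.extend_left_deletion_score = 0.0
        al.open_right_deletion_score = 0.0
        al.extend_right_deletion_score = 0.0
        _aligner_cache[key] = al
    return _aligner_cache[key]


def align_to_reference(
    read: str,
    reference: str,
    scoring: AlignScoring | None = None,
    min_score_frac: float = 0.25,
) -> Alignment | None:
    """Global affine-gap alignment, end-free on the reference side.

    Gap of length L costs ``gap_open + L * gap_extend``. Returns None for
    unalignable reads (score below ``min_score_frac * match * len(read)``).
    """
    sc = scoring or AlignScoring()
    aln = _aligner(sc).align(reference, read)
    best = aln[0]
    if best.score < min_score_frac * sc.match * len(read):
        return None
    blocks_ref, blocks_read = best.aligned
    if len(blocks_ref) == 0:
        return None
    ops: list[tuple[str, int]] = []
    ref_start = int(blocks_ref[0][0])
    prev_r, prev_q = None, None
    for (rs, re_), (qs, qe) in zip(blocks_ref, blocks_read):
        if prev_r is not None:
            if rs > prev_r:
                ops.append(("D", int(rs - prev_r)))
            if qs > prev_q:
                ops.append(("I", int(qs - prev_q)))
        ops.append(("M", int(re_ - rs)))
        prev_r, prev_q = re_, qe
    # leading/trailing unaligned read bases (should not occur for amplicon
    # reads; represent as insertions so read coordinates stay consistent)
    lead = int(blocks_read[0][0])
    if lead:
        ops.insert(0, ("I", lead))
    tail = len(read) - int(blocks_read[-1][1])
    if tail:
        ops.append(("I", tail))
    merged_ops: list[tuple[str, int]] = []
    for op, n in ops:
        if merged_ops and merged_ops[-1][0] == op:
            merged_ops[-1] = (op, merged_ops[-1][1] + n)
        else:
            merged_ops.append((op, n))
    return Alignment(read=read, ref_start=ref_start, ops=merged_ops, score=float(best.score))


def _left_align(ref: str, ev: EditEvent) -> EditEvent:
    """Shift an indel to its leftmost equivalent representation within a
    homopolymer/repeat context."""
    pos, ins, dl = ev.position, ev.inserted, ev.deleted_len
    if dl and not ins:
        while pos > 0 and ref[pos - 1] == ref[pos + dl - 1]:
            pos -= 1
    elif ins and not dl:
        while pos > 0 and ref[pos - 1] == ins[-1]:
            ins = ref[pos - 1] + ins[:-1]
            pos -= 1
    return EditEvent(ev.region, pos, ins, dl, ev.is_hdr)


def _walk(aln: Alignment):
    """Yield (op, ref_pos, read_pos, length) for each alignment op."""
    r, q = aln.ref_start, 0
    for op, n in aln.ops:
        yield op, r, q, n
        if op in "MD":
            r += n
        if op in "MI":
            q += n


def windowed_read_seq(aln: Alignment, window: AnalysisWindow) -> str | None:
    """Read bases aligned within the window, or None if the alignment does
    not fully span it. Insertions strictly inside the window are included."""
    if aln.ref_start > window.start or aln.ref_end < window.end:
        return None
    parts = []
    for op, r, q, n in _walk(aln):
        if op == "M":
            lo = max(r, window.start)
            hi = min(r + n, window.end)
            if hi > lo:
                parts.append(aln.read[q + (lo - r) : q + (hi - r)])
        elif op == "I" and window.start < r < window.end:
            parts.append(aln.read[q : q + n])
    return "".join(parts)


def call_events(
    aln: Alignment, window: AnalysisWindow, reference: str, region: str = "SOI"
) -> list[EditEvent]:
    """Left-aligned indel events intersecting the window.

    Raises ValueError if the alignment does not cover the window fully
    (such reads are excluded upstream with a reason code).
    """
    if aln.ref_start > window.start or aln.ref_end < window.end:
        raise ValueError("alignment does not span the analysis window")
    events = []
    for op, r, q, n in _walk(aln):
        if op == "D":
            ev = _left_align(reference, EditEvent(region, r, "", n))
            if ev.position < window.end and ev.position + n > window.start:
                events.append(ev)
        elif op == "I":
            ev = _left_align(reference, EditEvent(region, r, aln.read[q : q + n], 0))
            if window.start < r < window.end or window.start < ev.position < window.end:
                events.append(ev)
    return events


# ------------------------------------------------------------ haplotypes


@dataclass
class Haplotype:
    window_seq: str
    count: int
    events: list[EditEvent]
    fclass: FrameClass


@dataclass
class HaplotypeTable:
    window: AnalysisWindow
    haplotypes: list[Haplotype]
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def class_fractions(self) -> dict[FrameClass, float]:
        total = self.n_classified
        out = {c: 0.0 for c in FrameClass}
        for h in self.haplotypes:
            out[h.fclass] += h.count
        return {c: v / total for c, v in out.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "window": self.window.name,
                "sequence": h.window_seq,
                "count": h.count,
                "class": h.fclass.value,
                "net_indel": sum(e.net for e in h.events),
            }
            for h in sorted(self.haplotypes, key=lambda h: -h.count)
        ]
        return pd.DataFrame(rows, columns=["window", "sequence", "count", "class", "net_indel"])


def single_insertion_diff(reference: str, repaired: str) -> tuple[int, int]:
    """(position, length) of the single insertion turning ``reference``
    into ``repaired``."""
    if len(repaired) <= len(reference):
        raise ValueError("repaired reference is not longer than the defective one")
    delta = len(repaired) - len(reference)
    a = 0
    while a < len(reference) and reference[a] == repaired[a]:
        a += 1
    b = 0
    while b < len(reference) - a and reference[len(reference) - 1 - b] == repaired[len(repaired) - 1 - b]:
        b += 1
    j = min(a, len(reference) - b)
    return j, delta


def _shift_window(window: AnalysisWindow, j: int, delta: int) -> AnalysisWindow:
    start = window.start if window.start < j else window.start + delta
    end = window.end if window.end <= j else window.end + delta
    return AnalysisWindow(window.name, start, end)


def classify_reads(
    reads: list[str],
    reference: str,
    window: AnalysisWindow,
    repaired_reference: str | None = None,
    region: str = "SOI",
    scoring: AlignScoring | None = None,
) -> HaplotypeTable:
    """Classify merged reads over a guide window into a haplotype table.

    Unique sequences are aligned once and counted. With a repaired
    reference, each read is assigned the better-scoring backbone; repaired-
    backbone reads with no indel in the (shifted) window are HDR.
    """
    if not reads:
        raise EmptyTableError("no reads to classify")
    rep_window = None
    if repaired_reference is not None:
        j, delta = single_insertion_diff(reference, repaired_reference)
        rep_window = _shift_window(window, j, delta)

    counts = Counter(reads)
    haps: dict[str, Haplotype] = {}
    excluded: Counter = Counter()
    for seq, n in counts.items():
        aln = align_to_reference(seq, reference, scoring)
        use_repaired = False
        aln_rep = None
        if repaired_reference is not None:
            aln_rep = align_to_reference(seq, repaired_reference, scoring)
            if aln_rep is not None and (aln is None or aln_rep.score > aln.score):
                use_repaired = True
        if use_repaired:
            wseq = windowed_read_seq(aln_rep, rep_window)
            if wseq is None:
                excluded["window_not_covered"] += n
                continue
            events = call_events(aln_rep, rep_window, repaired_reference, region)
            if not events:
                fclass = FrameClass.HDR
                events = [
                    EditEvent(
                        region,
                        rep_window.start,
                        repaired_reference[rep_window.start : rep_window.start + delta],
                        0,
                        is_hdr=True,
                    )
                ]
            else:
                # template backbone plus extra indels: classify by the total
                # net shift relative to the defective reference
                net = delta + sum(e.net for e in events)
                fclass = _net_class(net)
        else:
            if aln is None:
                excluded["unalignable"] += n
                continue
            wseq = windowed_read_seq(aln, window)
            if wseq is None:
                excluded["window_not_covered"] += n
                continue
            events = call_events(aln, window, reference, region)
            if events:
                fclass = _net_class(sum(e.net for e in events))
            elif wseq == reference[window.start : window.end]:
                fclass = FrameClass.UNEDITED
            else:
                fclass = FrameClass.SUBSTITUTION_ONLY
        if wseq in haps:
            haps[wseq].count += n
        else:
            haps[wseq] = Haplotype(wseq, n, events, fclass)
    if not haps:
        raise EmptyTableError("zero classifiable reads")
    return HaplotypeTable(window, list(haps.values()), dict(excluded))


def _net_class(net: int) -> FrameClass:
    if net % 3 == 2:
        return FrameClass.N1
    if net % 3 == 1:
        return FrameClass.N2
    return FrameClass.N3_INFRAME


def summarize(
    reads: list[str],
    reference: str,
    window: AnalysisWindow,
    repaired_reference: str | None = None,
    region: str = "SOI",
    scoring: AlignScoring | None = None,
) -> HaplotypeTable:
    """Alias of :func:`classify_reads` — unique haplotype counting plus
    per-class fractions over a guide window."""
    return classify_reads(reads, reference, window, repaired_reference, region, scoring)


def analyze_amplicon(
    r1s: list[BioSeqRecord],
    r2s: list[BioSeqRecord],
    reference: str,
    window: AnalysisWindow,
    repaired_reference: str | None = None,
    region: str = "SOI",
    min_q: int = 20,
    trim_window: int = 4,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    scoring: AlignScoring | None = None,
) -> HaplotypeTable:
    """Full pipeline: trim, merge, align, call, count."""
    if len(r1s) != len(r2s):
        raise PairingError("R1/R2 record counts differ")
    t1 = quality_trim(r1s, min_q, trim_window)
    t2 = quality_trim(r2s, min_q, trim_window)
    by_id1 = {r.id: r for r in t1}
    by_id2 = {r.id: r for r in t2}
    shared = [i for i in by_id1 if i in by_id2]
    merged = merge_pairs(
        [by_id1[i] for i in shared], [by_id2[i] for i in shared], min_overlap, max_mismatch_frac
    )
    table = classify_reads(
        [str(m.seq) for m in merged.merged],
        reference,
        window,
        repaired_reference,
        region,
        scoring,
    )
    if merged.unmerged:
        table.excluded["unmerged"] = table.excluded.get("unmerged", 0) + len(merged.unmerged)
    dropped = len(r1s) - len(shared)
    if dropped:
        table.excluded["trimmed_away"] = table.excluded.get("trimmed_away", 0) + dropped
    return table
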