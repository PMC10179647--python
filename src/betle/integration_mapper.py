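"""Transgene integration-site mapping from tagmentation-style reads.

Reads are first filtered to those containing one of the transgene's two
terminal k-mers (default 15-mers, either strand) within a small Levenshtein
edit distance (default 2). For each passing junction read the transgene
segment is masked, the genomic flank is placed on the reference by exact
20-mer seeding, and nearby junctions are clustered into integration calls
with position, orientation and supporting-read count.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .reporter_model import revcomp

ReadLike = BioSeqRecord  # single reads; pairs are tuples of these


@dataclass
class TransgeneEnds:
    """Terminal k-mers of a transgene used as junction baits.

    When the full transgene sequence is attached, junction calls
    additionally require the read to continue into the transgene body
    beyond the matched k-mer, which suppresses genome-resident near-matches
    of a terminal k-mer (these recur in every read covering the locus, so
    a support threshold alone cannot remove them).
    """

    left_kmer: str
    right_kmer: str
    k: int = 15
    max_edit: int = 2
    transgene: str | None = None

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.max_edit >= self.k / 3:
            raise ValueError("max_edit must be < k/3")
        if len(self.left_kmer) != self.k or len(self.right_kmer) != self.k:
            raise ValueError("terminal k-mers must have length k")

    @classmethod
    def from_transgene(cls, seq: str, k: int = 15, max_edit: int = 2) -> "TransgeneEnds":
        seq = seq.upper()
        return cls(seq[:k], seq[-k:], k, max_edit, transgene=seq)


@dataclass
class IntegrationCall:
    contig: str
    position: int
    orientation: str  # '+' or '-'
    supporting_reads: int
    end: str  # 'left', 'right' or 'both'


def _contains_kmer(seq: str, ends: TransgeneEnds) -> bool:
    for kmer in (ends.left_kmer, ends.right_kmer):
        for probe in (kmer, revcomp(kmer)):
            hit = edlib.align(probe, seq, mode="HW", task="distance", k=ends.max_edit)
            if hit["editDistance"] != -1:
                return True
    return False


def terminal_kmer_filter(
    reads: list[ReadLike] | list[tuple[ReadLike, ReadLike]],
    ends: TransgeneEnds,
) -> list:
    """Keep reads (or pairs where at least one mate matches) containing a
    substring within edit distance ``max_edit`` of either terminal k-mer on
    either strand."""
    passing = []
    for item in reads:
        mates = item if isinstance(item, tuple) else (item,)
        if any(_contains_kmer(str(m.seq).upper(), ends) for m in mates):
            passing.append(item)
    return passing


def _best_variant(seq: str, ends: TransgeneEnds):
    """Best-matching terminal k-mer variant in ``seq``.

    Returns (variant, start, end_exclusive, distance) with variant in
    {'Lf','Rf','Lr','Rr'} (left/right end, forward/reverse-complement), or
    None.
    """
    best = None
    for variant, probe in (
        ("Lf", ends.left_kmer),
        ("Rf", ends.right_kmer),
        ("Lr", revcomp(ends.left_kmer)),
        ("Rr", revcomp(ends.right_kmer)),
    ):
        hit = edlib.align(probe, seq, mode="HW", task="locations", k=ends.max_edit)
        if hit["editDistance"] == -1:
            continue
        s, e = hit["locations"][0]
        if best is None or hit["editDistance"] < best[3]:
            best = (variant, s, e + 1, hit["editDistance"])
    return best


def _extends_into_transgene(seq: str, s: int, e: int, variant: str, ends: TransgeneEnds) -> bool:
    """After canonicalization, the read segment on the transgene side of
    the k-mer match must resemble the transgene body (up to ~10% edits)."""
    probe_len = 50
    if variant == "Lf":
        segment = seq[s : e + probe_len]
        body = ends.transgene[: len(segment) + ends.max_edit]
    else:
        segment = seq[max(0, s - probe_len) : e]
        body = ends.transgene[-(len(segment) + ends.max_edit) :]
    allowed = max(ends.max_edit, len(segment) // 10)
    hit = edlib.align(segment, body, mode="HW", task="distance", k=allowed)
    return hit["editDistance"] != -1


def _locate_flank(flank_seed: str, genome: dict[str, str]) -> tuple[str, int, str] | None:
    """Unique exact placement of a seed on either strand of the genome.

    Returns (contig, start, strand) or None when absent/ambiguous.
    """
    hits = []
    rc = revcomp(flank_seed)
    for contig, seq in genome.items():
        for probe, strand in ((flank_seed, "+"), (rc, "-")):
            start = 0
            while True:
                i = seq.find(probe, start)
                if i < 0:
                    break
                hits.append((contig, i, strand))
                if len(hits) > 1:
                    return None
                start = i + 1
    return hits[0] if len(hits) == 1 else None


def _junction_from_read(
    seq: str, ends: TransgeneEnds, genome: dict[str, str], min_flank: int
) -> tuple[str, int, str, str] | None:
    """(contig, position, orientation, transgene end) for one read, or
    None when the read carries no usable junction."""
    best = _best_variant(seq, ends)
    if best is None:
        return None
    variant, s, e, _ = best
    if variant in ("Lr", "Rr"):
        # canonicalize so the transgene appears in forward orientation
        seq = revcomp(seq)
        L = len(seq)
        s, e = L - e, L - s
        variant = "Lf" if variant == "Lr" else "Rf"

    if ends.transgene is not None and not _extends_into_transgene(seq, s, e, variant, ends):
        return None

    if variant == "Lf":
        flank = seq[:s]  # genomic sequence left of the transgene start
        if len(flank) < min_flank:
            return None
        seed = flank[-20:]
        hit = _locate_flank(seed, genome)
        if hit is None:
            return None
        contig, g, strand = hit
        position = g + len(seed) if strand == "+" else g
        orientation = strand
        return contig, position, orientation, "left"

    flank = seq[e:]  # genomic sequence right of the transgene end
    if len(flank) < min_flank:
        return None
    seed = flank[:20]
    hit = _locate_flank(seed, genome)
    if hit is None:
        return None
    contig, g, strand = hit
    position = g if strand == "+" else g + len(seed)
    orientation = strand
    return contig, position, orientation, "right"


def call_integration_sites(
    reads: list[ReadLike] | list[tuple[ReadLike, ReadLike]],
    genome: list,
    ends: TransgeneEnds,
    min_support: int = 2,
    cluster_window: int = 10,
    min_flank: int = 20,
) -> list[IntegrationCall]:
    """Cluster per-read junction placements into integration calls.

    ``genome`` is a list of sequence records (id/seq attributes). Junctions
    on the same contig and orientation within ``cluster_window`` merge;
    clusters supported by fewer than ``min_support`` reads are dropped. The
    reported position is the cluster median.
    """
    if not genome:
        raise ValueError("empty genome")
    gdict = {r.id: str(r.seq).upper() for r in genome}
    junctions: list[tuple[str, int, str, str]] = []
    for item in reads:
        mates = item if isinstance(item, tuple) else (item,)
        for m in mates:
            j = _junction_from_read(str(m.seq).upper(), ends, gdict, min_flank)
            if j is not None:
                junctions.append(j)
                break

    groups: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for contig, pos, orient, end in junctions:
        groups.setdefault((contig, orient), []).append((pos, end))

    calls: list[IntegrationCall] = []
    for (contig, orient), items in groups.items():
        items.sort()
        cluster: list[tuple[int, str]] = []
        for pos, end in items + [(None, None)]:  # sentinel flush
            if cluster and (pos is None or pos - cluster[-1][0] > cluster_window):
                positions = sorted(p for p, _ in cluster)
                ends_seen = {e for _, e in cluster}
                if len(cluster) >= min_support:
                    calls.append(
                        IntegrationCall(
                            contig=contig,
                            position=positions[len(positions) // 2],
                            orientation=orient,
                            supporting_reads=len(cluster),
                            end="both" if len(ends_seen) > 1 else ends_seen.pop(),
                        )
                    )
                cluster = []
            if pos is not None:
                cluster.append((pos, end))
    calls.sort(key=lambda c: (c.contig, c.position))
    return calls
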