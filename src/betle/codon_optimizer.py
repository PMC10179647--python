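"""Frame-constrained codon optimization.

A sequence-of-interest placed upstream of out-of-frame reporter cassettes
must be free of stop codons (TAA, TAG, TGA) in *all three* reading frames:
a frameshift anywhere in the SOI must be able to read through to the
downstream cassette. Off-frame stop triplets always span exactly two
adjacent codons, so a dynamic program over synonymous-codon pairs finds the
maximum-usage-weight recoding exactly.

The optimizer also excludes arbitrary forbidden motifs (by default the
Esp3I recognition sequence on both strands, so a designed SOI can be
dropped into a Golden Gate exchange site without creating extra cut sites).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
ESP3I_SITE = "CGTCTC"
ESP3I_SITE_RC = "GAGACG"
DEFAULT_FORBIDDEN = (ESP3I_SITE, ESP3I_SITE_RC)
_DNA = frozenset("ACGT")


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T}."""


class DesignError(ValueError):
    """A requested coding sequence cannot satisfy the design constraints."""


def _check_dna(seq: str) -> str:
    seq = seq.upper()
    if not seq or not set(seq) <= _DNA:
        bad = sorted(set(seq) - _DNA)
        raise AlphabetError(f"non-ACGT characters in sequence: {bad!r}")
    return seq


def stops_by_frame(seq: str) -> tuple[int, int, int]:
    """Count complete stop triplets in each of the three reading frames.

    Frames are offsets 0, 1, 2 from the start of ``seq``; incomplete
    terminal triplets are ignored.
    """
    seq = _check_dna(seq)
    counts = [0, 0, 0]
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            counts[i % 3] += 1
    return tuple(counts)  # type: ignore[return-value]


def _standard_synonymous() -> dict[str, list[str]]:
    fwd = unambiguous_dna_by_id[1].forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


@dataclass
class CodonTable:
    """Synonymous codons per amino acid, with optional usage weights.

    Weights per amino acid must sum to 1 when provided; absent weights mean
    a uniform distribution over the synonymous codons.
    """

    codons: dict[str, list[str]] = field(default_factory=_standard_synonymous)
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for aa, cods in self.codons.items():
            if any(len(c) != 3 for c in cods):
                raise ValueError(f"codon of wrong length for {aa}")
        if self.weights is not None:
            for aa, cods in self.codons.items():
                total = sum(self.weights.get(c, 0.0) for c in cods)
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(f"weights for {aa} sum to {total}, expected 1")

    def log_weight(self, aa: str, codon: str) -> float:
        if self.weights is None:
            return math.log(1.0 / len(self.codons[aa]))
        w = self.weights.get(codon, 0.0)
        if w <= 0.0:
            return -math.inf
        return math.log(w)

    @classmethod
    def uniform(cls) -> "CodonTable":
        return cls()

    @classmethod
    def from_tsv(cls, path) -> "CodonTable":
        """Load a table from TSV columns (amino acid, codon, weight)."""
        codons: dict[str, list[str]] = {}
        weights: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                aa, codon, w = row[0].strip(), row[1].strip().upper(), float(row[2])
                codons.setdefault(aa, []).append(codon)
                weights[codon] = w
        for aa in codons:
            codons[aa].sort()
        return cls(codons=codons, weights=weights)


@dataclass
class OptimizationResult:
    cds: str
    protein: str
    score: float
    feasible: bool
    failure: str | None = None


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _find_motifs(seq: str, motifs: tuple[str, ...]) -> list[tuple[int, str]]:
    hits = []
    for m in motifs:
        start = 0
        while True:
            i = seq.find(m, start)
            if i < 0:
                break
            hits.append((i, m))
            start = i + 1
    return sorted(hits)


def _pair_ok(a: str, b: str, motifs: tuple[str, ...]) -> bool:
    """Junction check for two adjacent codons.

    Off-frame stops (offsets 1 and 2 of the 6-mer) span both codons;
    forbidden motifs are rejected whenever an occurrence in the 6-mer
    touches both codons or lies at offset 0.
    """
    six = a + b
    if six[1:4] in STOP_CODONS or six[2:5] in STOP_CODONS:
        return False
    for i, m in _find_motifs(six, motifs):
        if i < 3 and i + len(m) > 3:
            return False
        if i == 0 and len(m) <= 3:
            return False
    return True


def _triple_ok(a: str, b: str, c: str, motifs: tuple[str, ...]) -> bool:
    """Reject forbidden motifs spanning all three codons of a 9-mer."""
    nine = a + b + c
    for i, m in _find_motifs(nine, motifs):
        if i < 3 and i + len(m) > 6:
            return False
    return True


def _codon_ok(codon: str, motifs: tuple[str, ...]) -> bool:
    if codon in STOP_CODONS:
        return False
    return all(m not in codon for m in motifs if len(m) <= 3)


def optimize(
    protein: str,
    table: CodonTable | None = None,
    forbid_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN,
) -> OptimizationResult:
    """Recode ``protein`` into a CDS with no stop codon in any frame.

    Dynamic programming over adjacent synonymous-codon pairs; the pair
    state makes motif checks exact for motifs up to 7 nt (a 6-mer motif can
    span three codons, which the pair transition sees as a full 9-mer).
    Returns the feasible assignment maximizing the summed log usage weight;
    ties break toward the lexicographically smallest CDS. Longer motifs are
    re-checked on the assembled CDS and reported as infeasible if present.
    """
    if not protein:
        raise ValueError("empty protein")
    protein = protein.upper().rstrip("*")
    if "*" in protein:
        raise ValueError("internal stop symbol in protein")
    table = table or CodonTable.uniform()
    motifs = tuple(m.upper() for m in forbid_motifs)

    try:
        options = [
            [c for c in table.codons[aa] if _codon_ok(c, motifs)] for aa in protein
        ]
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc}") from exc

    def fail(idx: int, why: str) -> OptimizationResult:
        return OptimizationResult("", protein, -math.inf, False, f"residue {idx}: {why}")

    for i, opts in enumerate(options):
        if not opts:
            return fail(i, "no admissible codon")

    n = len(protein)
    if n == 1:
        top = max(table.log_weight(protein[0], c) for c in options[0])
        best = min(
            c for c in options[0] if table.log_weight(protein[0], c) >= top - 1e-12
        )
        return OptimizationResult(best, protein, top, True)

    # DP state after residue i (i >= 1): the codon pair (c_{i-1}, c_i).
    # value: (score, cds_prefix); higher score wins, then smaller prefix.
    def better(x: tuple[float, str], y: tuple[float, str] | None) -> bool:
        return y is None or x[0] > y[0] + 1e-12 or (abs(x[0] - y[0]) <= 1e-12 and x[1] < y[1])

    frontier: dict[tuple[str, str], tuple[float, str]] = {}
    for a in options[0]:
        for b in options[1]:
            if _pair_ok(a, b, motifs):
                val = (
                    table.log_weight(protein[0], a) + table.log_weight(protein[1], b),
                    a + b,
                )
                if better(val, frontier.get((a, b))):
                    frontier[(a, b)] = val
    if not frontier:
        return fail(1, "no stop-free, motif-free codon pair at junction 0-1")

    for i in range(2, n):
        nxt: dict[tuple[str, str], tuple[float, str]] = {}
        for (a, b), (score, prefix) in frontier.items():
            for c in options[i]:
                if not _pair_ok(b, c, motifs) or not _triple_ok(a, b, c, motifs):
                    continue
                val = (score + table.log_weight(protein[i], c), prefix + c)
                if better(val, nxt.get((b, c))):
                    nxt[(b, c)] = val
        if not nxt:
            return fail(i, f"no admissible codon at junction {i - 1}-{i}")
        frontier = nxt

    top = max(v[0] for v in frontier.values())
    cds = min(v[1] for v in frontier.values() if abs(v[0] - top) <= 1e-12)
    score = top

    leftover = [m for m in motifs if len(m) > 7 and m in cds]
    if leftover:
        return fail(n - 1, f"motif {leftover[0]} unavoidable by pairwise design")
    return OptimizationResult(cds, protein, score, True)


def verify_recoding(
    cds: str,
    protein: str,
    forbid_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN,
) -> bool:
    """True iff ``cds`` encodes ``protein``, is stop-free in all frames and
    contains no forbidden motif."""
    cds = _check_dna(cds)
    if len(cds) != 3 * len(protein):
        raise ValueError(f"length mismatch: {len(cds)} nt vs {len(protein)} aa")
    if translate(cds) != protein.upper():
        return False
    if stops_by_frame(cds) != (0, 0, 0):
        return False
    return not _find_motifs(cds, tuple(m.upper() for m in forbid_motifs))
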