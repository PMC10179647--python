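"""In-silico Cas editing and read simulation.

Generates edited molecule populations (NHEJ indel spectra and exact
template repair), single- and multi-integrant cells, amplicon read pairs
with i.i.d. substitution error, and transgene-bearing toy genomes with
known integration truth — everything the downstream classifiers need,
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .reporter_model import (
    EditEvent,
    FrameClass,
    PhenotypeVector,
    ReporterCassette,
    SequenceRecord,
    cell_phenotype,
    frame_class,
    predict_phenotype,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class TargetSiteError(ValueError):
    """Protospacer+PAM absent or not unique in the target."""


class SimulationError(ValueError):
    pass


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _iupac_match(pattern: str, seq: str) -> bool:
    return len(pattern) == len(seq) and all(b in _IUPAC[p] for p, b in zip(pattern, seq))


@dataclass
class CutSiteModel:
    """A guide and its Cas enzyme.

    spCas9 and saCas9 cut blunt between protospacer positions −4 and −3
    relative to the PAM-proximal end (3 nt 5' of the PAM); asCas12a has a
    5' TTTV PAM and leaves staggered ends, cut after protospacer positions
    18 (non-target strand) and 23 (target strand) — the returned blunt
    representative is the position-18 cut. These geometries are standard
    conventions for the enzymes.
    """

    enzyme: str  # spCas9 | saCas9 | asCas12a
    protospacer: str
    pam: str = ""

    def __post_init__(self) -> None:
        self.enzyme = self.enzyme.strip()
        if self.enzyme not in ("spCas9", "saCas9", "asCas12a"):
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        self.protospacer = self.protospacer.upper()
        if not self.pam:
            self.pam = {"spCas9": "NGG", "saCas9": "NNGRRT", "asCas12a": "TTTV"}[self.enzyme]
        self.pam = self.pam.upper()

    @property
    def pam_is_5prime(self) -> bool:
        return self.enzyme == "asCas12a"

    @property
    def cut_offsets(self) -> tuple[int, int]:
        """Cut positions from the protospacer 5' end (both strands)."""
        if self.enzyme == "asCas12a":
            return (18, 23)
        n = len(self.protospacer)
        return (n - 3, n - 3)


def locate_cut(model: CutSiteModel, target: str) -> int:
    """0-based cut position on ``target`` (last base left of the break).

    The protospacer with its adjacent PAM must occur exactly once on either
    strand; otherwise a :class:`TargetSiteError` is raised.
    """
    target = target.upper()
    proto = model.protospacer
    plen, pamlen = len(proto), len(model.pam)
    hits: list[tuple[int, str]] = []
    for s in range(len(target) - plen + 1):
        if target[s : s + plen] == proto:
            if model.pam_is_5prime:
                pam = target[s - pamlen : s]
                if len(pam) == pamlen and _iupac_match(model.pam, pam):
                    hits.append((s, "+"))
            else:
                pam = target[s + plen : s + plen + pamlen]
                if len(pam) == pamlen and _iupac_match(model.pam, pam):
                    hits.append((s, "+"))
    proto_rc = revcomp(proto)
    for s in range(len(target) - plen + 1):
        if target[s : s + plen] == proto_rc:
            if model.pam_is_5prime:
                pam = target[s + plen : s + plen + pamlen]
                if len(pam) == pamlen and _iupac_match(model.pam, revcomp(pam)):
                    hits.append((s, "-"))
            else:
                pam = target[s - pamlen : s]
                if len(pam) == pamlen and _iupac_match(model.pam, revcomp(pam)):
                    hits.append((s, "-"))
    if len(hits) != 1:
        raise TargetSiteError(
            f"protospacer+PAM matched {len(hits)} times in target (need exactly 1)"
        )
    s, strand = hits[0]
    five_cut = model.cut_offsets[0]
    if strand == "+":
        return s + five_cut - 1
    # mirror: position `five_cut` from the protospacer 5' end, which sits at
    # the right end of the plus-strand match
    return s + plen - five_cut - 1


@dataclass
class IndelSpectrum:
    """Distribution over (deleted_len, inserted_len) outcomes of NHEJ.

    The default mixes geometric-tailed deletions (p=0.5, truncated at 30)
    with 1-nt insertions at 4:1 — a generic desk-scale stand-in for a
    repair-outcome profile, configurable via TSV.
    """

    entries: list[tuple[tuple[int, int], float]]

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum probabilities sum to {total}")
        if any(abs(ins - dele) > 30 for (dele, ins), _ in self.entries):
            raise ValueError("net indel support exceeds ±30")

    @classmethod
    def default(cls, max_del: int = 30, p_geom: float = 0.5, ins_frac: float = 0.2) -> "IndelSpectrum":
        weights = [p_geom ** L for L in range(1, max_del + 1)]
        z = sum(weights)
        entries = [((L, 0), (1 - ins_frac) * w / z) for L, w in zip(range(1, max_del + 1), weights)]
        entries.append(((0, 1), ins_frac))
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "IndelSpectrum":
        import csv

        entries = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                entries.append(((int(row[0]), int(row[1])), float(row[2])))
        return cls(entries)

    def class_probabilities(self) -> dict[FrameClass, float]:
        out = {FrameClass.N1: 0.0, FrameClass.N2: 0.0, FrameClass.N3_INFRAME: 0.0}
        for (dele, ins), p in self.entries:
            net = ins - dele
            if net % 3 == 2:
                out[FrameClass.N1] += p
            elif net % 3 == 1:
                out[FrameClass.N2] += p
            else:
                out[FrameClass.N3_INFRAME] += p
        return out

    def conditioned_on(self, fclass: FrameClass) -> "IndelSpectrum":
        """Restrict (and renormalize) to outcomes of one frame class."""
        want = {FrameClass.N1: 2, FrameClass.N2: 1, FrameClass.N3_INFRAME: 0}[fclass]
        kept = [(de_in, p) for de_in, p in self.entries if (de_in[1] - de_in[0]) % 3 == want]
        z = sum(p for _, p in kept)
        if z == 0:
            raise ValueError(f"spectrum has no mass in class {fclass}")
        return IndelSpectrum([(de_in, p / z) for de_in, p in kept])

    def sample(self, rng: np.random.Generator) -> tuple[int, int]:
        idx = rng.choice(len(self.entries), p=[p for _, p in self.entries])
        return self.entries[idx][0]


@dataclass
class SimulatedCell:
    integrant_events: list[EditEvent | None]
    phenotype: PhenotypeVector


@dataclass
class ReadSimParams:
    read_len: int = 250
    paired: bool = True
    substitution_error: float = 0.001
    coverage: int = 5000  # total reads (pairs when paired)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_error < 0.1):
            raise ValueError("substitution error must be in [0, 0.1)")
        if self.read_len < 50:
            raise ValueError("read length must be >= 50")


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def indel_event(
    region: str, cut: int, deleted_len: int, inserted_len: int, rng: np.random.Generator
) -> EditEvent:
    """Place an NHEJ indel at a blunt cut: deletions centred on the break,
    insertions immediately 3' of it."""
    if deleted_len > 0:
        pos = cut + 1 - deleted_len // 2
    else:
        pos = cut + 1
    return EditEvent(
        region=region,
        position=pos,
        inserted=_random_bases(rng, inserted_len),
        deleted_len=deleted_len,
    )


def apply_event(seq: str, event: EditEvent) -> str:
    """Molecule sequence after applying one edit to ``seq``."""
    p = event.position
    return seq[:p] + event.inserted + seq[p + event.deleted_len :]


def infer_hdr_insertion(reference: str, template: str) -> tuple[int, str]:
    """Locate an HDR template on the reference: homology arms must match
    the reference exactly and flank one junction; returns (junction
    position, restored segment)."""
    anchor = template[:20]
    q = reference.find(anchor)
    if q < 0 or reference.find(anchor, q + 1) >= 0:
        raise SimulationError("template left arm not found uniquely in reference")
    a = 0
    while a < len(template) and q + a < len(reference) and template[a] == reference[q + a]:
        a += 1
    j = q + a
    # longest template suffix matching the reference right of j, under a
    # single-insertion model: template = ref[..j] + mid + ref[j..]
    t = len(template)
    b = 0
    for cand in range(t - a - 1, 0, -1):
        if j + cand <= len(reference) and template[t - cand :] == reference[j : j + cand]:
            b = cand
            break
    inserted = template[a : t - b]
    if not inserted or b == 0:
        raise SimulationError("template does not describe a single insertion")
    return j, inserted


def hdr_event(reference: str, template: str, region: str = "SOI") -> EditEvent:
    j, inserted = infer_hdr_insertion(reference, template)
    return EditEvent(region=region, position=j, inserted=inserted, is_hdr=True)


def simulate_population(
    cassette: ReporterCassette,
    model: CutSiteModel,
    spectrum: IndelSpectrum,
    n_cells: int,
    integrants_per_cell: int = 1,
    edit_prob: float = 0.8,
    hdr_template: SequenceRecord | None = None,
    hdr_prob: float = 0.0,
    seed: int = 0,
    inframe_disrupts_function: bool = True,
) -> list[SimulatedCell]:
    """Simulate cells whose integrants are edited independently.

    Each integrant is unedited with probability 1−``edit_prob``; edited
    integrants undergo template repair with probability ``hdr_prob`` (a
    template must be supplied) and otherwise draw an indel from
    ``spectrum`` at the guide's cut site.
    """
    if not (0 <= edit_prob <= 1 and 0 <= hdr_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if hdr_prob > 0 and hdr_template is None:
        raise SimulationError("hdr_prob > 0 requires an HDR template")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    ref = cassette.record.seq
    cut = locate_cut(model, ref)
    region = cassette.region_of(cut)
    hdr_ev = hdr_event(ref, hdr_template.seq, region) if hdr_template is not None else None

    cells = []
    for _ in range(n_cells):
        events: list[EditEvent | None] = []
        phenos = []
        for _ in range(integrants_per_cell):
            if rng.random() >= edit_prob:
                events.append(None)
                phenos.append(predict_phenotype(region, FrameClass.UNEDITED))
                continue
            if hdr_ev is not None and rng.random() < hdr_prob:
                events.append(hdr_ev)
                phenos.append(predict_phenotype(region, FrameClass.HDR))
            else:
                dele, ins = spectrum.sample(rng)
                ev = indel_event(region, cut, dele, ins, rng)
                events.append(ev)
                phenos.append(
                    predict_phenotype(region, frame_class(ev), inframe_disrupts_function)
                )
        cells.append(SimulatedCell(events, cell_phenotype(phenos)))
    return cells


def simulate_sorted_molecules(
    cassette: ReporterCassette,
    model: CutSiteModel,
    spectrum: IndelSpectrum,
    mixture: dict[FrameClass, float],
    n_molecules: int,
    hdr_template: SequenceRecord | None = None,
    seed: int = 0,
) -> list[str]:
    """Molecule pool for a sorted subpopulation with known class mixture.

    ``mixture`` maps frame classes (UNEDITED, N1, N2, N3_INFRAME, HDR) to
    fractions summing to 1; indel-bearing classes draw from ``spectrum``
    conditioned on the class.
    """
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    rng = np.random.default_rng(seed)
    ref = cassette.record.seq
    cut = locate_cut(model, ref)
    region = cassette.region_of(cut)
    classes = list(mixture)
    probs = [mixture[c] for c in classes]
    conditioned = {
        c: spectrum.conditioned_on(c)
        for c in classes
        if c in (FrameClass.N1, FrameClass.N2, FrameClass.N3_INFRAME)
    }
    hdr_ev = None
    if FrameClass.HDR in classes:
        if hdr_template is None:
            raise SimulationError("HDR in mixture requires a template")
        hdr_ev = hdr_event(ref, hdr_template.seq, region)

    molecules = []
    draw = rng.choice(len(classes), size=n_molecules, p=probs)
    for k in draw:
        c = classes[k]
        if c == FrameClass.UNEDITED:
            molecules.append(ref)
        elif c == FrameClass.HDR:
            molecules.append(apply_event(ref, hdr_ev))
        else:
            dele, ins = conditioned[c].sample(rng)
            molecules.append(apply_event(ref, indel_event(region, cut, dele, ins, rng)))
    return molecules


class AmplificationError(ValueError):
    pass


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        orig = arr[hit]
        subs = _BASES[rng.integers(0, 4, size=hit.size)]
        same = subs == orig
        while same.any():
            subs[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = subs == orig
        arr[hit] = subs
    return arr.tobytes().decode()


def simulate_amplicon_reads(
    molecules: list[str],
    primers: tuple[str, str],
    params: ReadSimParams,
) -> tuple[list[BioSeqRecord], list[BioSeqRecord]]:
    """Paired amplicon reads: R1 from the forward-primer end, R2
    reverse-complemented from the other end, uniform over molecules,
    substitution errors i.i.d., constant Q30 qualities."""
    fwd, rev = primers[0].upper(), primers[1].upper()
    rev_rc = revcomp(rev)
    amplicons = []
    for i, mol in enumerate(molecules):
        f = mol.find(fwd)
        r = mol.find(rev_rc)
        if f < 0 or r < 0 or r + len(rev_rc) <= f:
            raise AmplificationError(f"primer not found in molecule {i}")
        amplicons.append(mol[f : r + len(rev_rc)])

    rng = np.random.default_rng(params.seed)
    n = params.coverage
    picks = rng.integers(0, len(amplicons), size=n)
    r1s, r2s = [], []
    for ridx, k in enumerate(picks):
        amp = amplicons[k]
        truncated = len(amp) < params.read_len
        r1 = amp[: params.read_len]
        r2 = revcomp(amp)[: params.read_len]
        r1 = _mutate(r1, params.substitution_error, rng)
        r2 = _mutate(r2, params.substitution_error, rng)
        desc = "truncated" if truncated else ""
        name = f"read{ridx}"
        rec1 = BioSeqRecord(Seq(r1), id=name, description=desc)
        rec1.letter_annotations["phred_quality"] = [30] * len(r1)
        r1s.append(rec1)
        rec2 = BioSeqRecord(Seq(r2), id=name, description=desc)
        rec2.letter_annotations["phred_quality"] = [30] * len(r2)
        r2s.append(rec2)
    return r1s, r2s


@dataclass
class IntegrationTruth:
    contig: str
    position: int  # 0-based: transgene inserted between position-1 and position
    orientation: str  # '+' or '-'


def simulate_integrations(
    genome: list[SequenceRecord],
    transgene: SequenceRecord,
    n_sites: int,
    seed: int = 0,
    min_separation: int = 500,
) -> tuple[list[SequenceRecord], list[IntegrationTruth]]:
    """Insert ``transgene`` at uniform random positions/orientations.

    Returns the modified genome and the ground-truth junction records
    (positions in original-genome coordinates). Overlapping draws are
    redrawn; persistent failure raises a capacity error.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    total = sum(len(r.seq) for r in genome)
    if total < 10 * len(transgene.seq):
        raise SimulationError("genome too small relative to transgene (capacity)")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(r.seq) for r in genome], dtype=float)
    truth: list[IntegrationTruth] = []
    for _ in range(10000):
        if len(truth) == n_sites:
            break
        ci = int(rng.choice(len(genome), p=lengths / lengths.sum()))
        pos = int(rng.integers(min_separation, len(genome[ci].seq) - min_separation))
        if any(
            t.contig == genome[ci].id and abs(t.position - pos) < min_separation for t in truth
        ):
            continue
        orient = "+" if rng.random() < 0.5 else "-"
        truth.append(IntegrationTruth(genome[ci].id, pos, orient))
    else:
        raise SimulationError("could not place all insertions (capacity)")

    modified = []
    for rec in genome:
        here = sorted(
            (t for t in truth if t.contig == rec.id), key=lambda t: t.position, reverse=True
        )
        seq = rec.seq
        for t in here:
            ins = transgene.seq if t.orientation == "+" else revcomp(transgene.seq)
            seq = seq[: t.position] + ins + seq[t.position :]
        modified.append(SequenceRecord(rec.id, seq, rec.description))
    return modified, sorted(truth, key=lambda t: (t.contig, t.position))


def simulate_genomic_reads(
    genome: list[SequenceRecord],
    n_reads: int,
    read_len: int = 150,
    substitution_error: float = 0.001,
    seed: int = 0,
) -> list[BioSeqRecord]:
    """Uniform single-end reads from both strands of ``genome`` (a
    tagmentation-style shotgun stand-in: no fragment-size model)."""
    rng = np.random.default_rng(seed)
    lengths = np.array([max(0, len(r.seq) - read_len + 1) for r in genome], dtype=float)
    reads = []
    for i in range(n_reads):
        ci = int(rng.choice(len(genome), p=lengths / lengths.sum()))
        start = int(rng.integers(0, len(genome[ci].seq) - read_len + 1))
        seq = genome[ci].seq[start : start + read_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        seq = _mutate(seq, substitution_error, rng)
        rec = BioSeqRecord(Seq(seq), id=f"gread{i}", description="")
        rec.letter_annotations["phred_quality"] = [30] * len(seq)
        reads.append(rec)
    return reads
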