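"""Data model for a bivalent traffic-light editing (BETLE-style) reporter.

The reporter encodes a constitutive mCherry linked through a 2A peptide to
an exchangeable sequence-of-interest (SOI), followed by two out-of-frame
cassettes: a P2A-mTagBFP2 cassette in the −2 register and a T2A-NanoLuc
cassette in the −1 register. A CRISPR-induced indel whose net length is
congruent to −1 (mod 3) brings NanoLuc in frame; −2 (mod 3) brings
mTagBFP2 in frame; in-frame (0 mod 3) indels disrupt the target without a
frameshift. Homology-directed repair restores a functional moxGFP from the
defective SOI. The SOI sits between two Esp3I (BsmBI) Golden Gate sites
with distinct overhangs, so it can be exchanged without re-synthesizing
the reporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from Bio.Seq import Seq

from .codon_optimizer import (
    AlphabetError,
    DesignError,
    ESP3I_SITE,
    ESP3I_SITE_RC,
    stops_by_frame,
    _check_dna,
)

__all__ = [
    "SequenceRecord",
    "FeatureName",
    "CassetteFeature",
    "ReporterCassette",
    "EditEvent",
    "FrameClass",
    "PhenotypeVector",
    "Violation",
    "scan_esp3i",
    "validate_cassette",
    "swap_soi",
    "frame_class",
    "predict_phenotype",
    "cell_phenotype",
]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class SequenceRecord:
    """A named DNA sequence. ``N`` is permitted only for read data."""

    id: str
    seq: str
    description: str = ""
    allow_n: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        allowed = set("ACGTN") if self.allow_n else set("ACGT")
        if not self.seq or not set(self.seq) <= allowed:
            raise AlphabetError(f"record {self.id!r}: invalid sequence alphabet")

    def __len__(self) -> int:
        return len(self.seq)


class FeatureName(str, Enum):
    promoter = "promoter"
    mCherry = "mCherry"
    P2A_1 = "P2A_1"
    SOI = "SOI"
    P2A_2 = "P2A_2"
    mTagBFP2_cassette = "mTagBFP2_cassette"
    T2A_NanoLuc_cassette = "T2A_NanoLuc_cassette"
    other = "other"


@dataclass
class CassetteFeature:
    """0-based half-open annotation on the reporter sequence."""

    name: FeatureName
    start: int
    end: int
    declared_frame_shift: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"feature {self.name}: bad interval [{self.start}, {self.end})")
        if self.declared_frame_shift not in (0, -1, -2):
            raise ValueError(f"feature {self.name}: frame shift must be 0, -1 or -2")


@dataclass
class ReporterCassette:
    record: SequenceRecord
    features: list[CassetteFeature]
    esp3i_overhangs: tuple[str, str] = ("", "")

    def feature(self, name: FeatureName | str) -> CassetteFeature:
        name = FeatureName(name)
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name.value}")

    def feature_seq(self, name: FeatureName | str) -> str:
        f = self.feature(name)
        return self.record.seq[f.start : f.end]

    @property
    def soi_seq(self) -> str:
        return self.feature_seq(FeatureName.SOI)

    def region_of(self, position: int) -> str:
        """Name the editing region ('mCherry', 'SOI' or 'other') for a
        0-based position on the reporter."""
        for f in self.features:
            if f.start <= position < f.end:
                if f.name in (FeatureName.mCherry, FeatureName.SOI):
                    return f.name.value
                return "other"
        return "other"


class FrameClass(Enum):
    UNEDITED = "UNEDITED"
    N1 = "N1"
    N2 = "N2"
    N3_INFRAME = "N3_INFRAME"
    HDR = "HDR"
    SUBSTITUTION_ONLY = "SUBSTITUTION_ONLY"


@dataclass
class EditEvent:
    """A located indel or HDR incorporation on the reporter.

    ``position`` is the 0-based leftmost affected base; deletions remove
    ``deleted_len`` bases starting there, and ``inserted`` is placed at the
    same coordinate.
    """

    region: str
    position: int
    inserted: str = ""
    deleted_len: int = 0
    is_hdr: bool = False

    def __post_init__(self) -> None:
        if not self.inserted and self.deleted_len == 0 and not self.is_hdr:
            raise ValueError("event with no insertion, no deletion and no HDR flag")
        if self.deleted_len < 0:
            raise ValueError("negative deletion length")

    @property
    def net(self) -> int:
        return len(self.inserted) - self.deleted_len


@dataclass(frozen=True)
class PhenotypeVector:
    """Boolean reporter readouts for one integrant or one cell."""

    mCherry: bool
    moxGFP: bool
    mTagBFP2: bool
    NanoLuc: bool

    def __or__(self, other: "PhenotypeVector") -> "PhenotypeVector":
        return PhenotypeVector(
            self.mCherry or other.mCherry,
            self.moxGFP or other.moxGFP,
            self.mTagBFP2 or other.mTagBFP2,
            self.NanoLuc or other.NanoLuc,
        )


@dataclass(frozen=True)
class Violation:
    code: str
    message: str


def scan_esp3i(seq: str) -> list[tuple[int, str]]:
    """All Esp3I recognition sites: CGTCTC on '+' and GAGACG on '−'.

    Positions are 0-based at the first base of the recognition hexamer,
    sorted by position.
    """
    seq = _check_dna(seq)
    hits: list[tuple[int, str]] = []
    for motif, strand in ((ESP3I_SITE, "+"), (ESP3I_SITE_RC, "-")):
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            hits.append((i, strand))
            start = i + 1
    return sorted(hits)


_EXPECTED_SHIFTS = {
    FeatureName.SOI: 0,
    FeatureName.mTagBFP2_cassette: -2,
    FeatureName.T2A_NanoLuc_cassette: -1,
}

_STOPS = {"TAA", "TAG", "TGA"}


def validate_cassette(cassette: ReporterCassette) -> list[Violation]:
    """Check every structural invariant of the reporter; violations are
    returned as data, not raised."""
    v: list[Violation] = []
    seq = cassette.record.seq
    feats = cassette.features

    prev_end = 0
    for f in feats:
        if f.end > len(seq):
            v.append(Violation("feature_bounds", f"{f.name.value} ends at {f.end} > {len(seq)}"))
        if f.start < prev_end:
            v.append(Violation("feature_order", f"{f.name.value} overlaps or precedes previous feature"))
        prev_end = max(prev_end, f.end)
        expected = _EXPECTED_SHIFTS.get(f.name)
        if expected is not None and f.declared_frame_shift != expected:
            v.append(
                Violation(
                    "frame_shift",
                    f"{f.name.value} declares frame shift {f.declared_frame_shift}, expected {expected}",
                )
            )

    try:
        soi = cassette.feature(FeatureName.SOI)
    except KeyError:
        v.append(Violation("missing_soi", "no SOI feature"))
        return v

    sites = scan_esp3i(seq)
    if len(sites) != 2:
        v.append(Violation("esp3i_count", f"expected exactly 2 Esp3I sites, found {len(sites)}"))
    else:
        (p1, s1), (p2, s2) = sites
        if not (s1 == "+" and p1 < soi.start and s2 == "-" and p2 >= soi.end):
            v.append(
                Violation(
                    "esp3i_flanking",
                    f"Esp3I sites at {sites} do not flank SOI [{soi.start}, {soi.end}) head-to-head",
                )
            )
    up, down = cassette.esp3i_overhangs
    if up == down:
        v.append(Violation("overhangs_identical", f"Esp3I overhangs are both {up!r}"))

    soi_seq = seq[soi.start : soi.end]
    if len(soi_seq) % 3 != 0:
        v.append(Violation("soi_length", f"SOI length {len(soi_seq)} not a multiple of 3"))
    for frame, count in enumerate(stops_by_frame(soi_seq)):
        if count:
            v.append(Violation("soi_stop", f"SOI contains {count} stop codon(s) in frame +{frame}"))

    try:
        mch = cassette.feature(FeatureName.mCherry)
    except KeyError:
        v.append(Violation("missing_mcherry", "no mCherry feature"))
        return v
    if (soi.start - mch.start) % 3 != 0:
        v.append(Violation("orf_frame", "SOI is not in frame with mCherry"))
    else:
        for i in range(mch.start, soi.end - 2, 3):
            if seq[i : i + 3] in _STOPS:
                v.append(Violation("orf_stop", f"main ORF stop codon at {i}"))
                break
    return v


def swap_soi(cassette: ReporterCassette, new_soi: SequenceRecord) -> ReporterCassette:
    """Exchange the SOI through its flanking Esp3I sites.

    The replacement must be stop-free in all three frames, a multiple of 3
    long, and free of internal Esp3I sites on either strand. Downstream
    feature coordinates shift by the length difference.
    """
    new_seq = new_soi.seq
    if len(new_seq) % 3 != 0:
        raise DesignError(f"SOI length {len(new_seq)} is not a multiple of 3")
    for frame, count in enumerate(stops_by_frame(new_seq)):
        if count:
            offset = next(
                i for i in range(frame, len(new_seq) - 2, 3) if new_seq[i : i + 3] in _STOPS
            )
            raise DesignError(f"stop codon in frame +{frame} at offset {offset}")
    internal = scan_esp3i(new_seq)
    if internal:
        raise DesignError(f"internal Esp3I site(s) at {internal}")

    soi = cassette.feature(FeatureName.SOI)
    delta = len(new_seq) - (soi.end - soi.start)
    seq = cassette.record.seq[: soi.start] + new_seq + cassette.record.seq[soi.end :]
    feats = []
    for f in cassette.features:
        if f.name == FeatureName.SOI:
            feats.append(replace(f, start=soi.start, end=soi.start + len(new_seq)))
        elif f.start >= soi.end:
            feats.append(replace(f, start=f.start + delta, end=f.end + delta))
        else:
            feats.append(replace(f))
    record = SequenceRecord(cassette.record.id, seq, cassette.record.description)
    return ReporterCassette(record, feats, cassette.esp3i_overhangs)


def frame_class(event: EditEvent) -> FrameClass:
    """Reading-frame register of an edit.

    N−1 and N−2 are the equivalence classes of the net indel length mod 3
    (a 1-nt deletion and a 2-nt insertion both read N−1); in-frame events
    with any indel present are N−3.
    """
    if event.is_hdr:
        return FrameClass.HDR
    net = event.net
    if net % 3 == 2:  # net ≡ −1 (mod 3)
        return FrameClass.N1
    if net % 3 == 1:  # net ≡ −2 (mod 3)
        return FrameClass.N2
    if event.inserted or event.deleted_len:
        return FrameClass.N3_INFRAME
    return FrameClass.UNEDITED


_OFF = PhenotypeVector(False, False, False, False)


def predict_phenotype(
    region: str,
    fclass: FrameClass,
    inframe_disrupts_function: bool = True,
) -> PhenotypeVector:
    """Reporter readout of a single integrant given where and how it was
    edited.

    A frameshift in mCherry kills mCherry and re-frames everything
    downstream; a frameshift in the SOI leaves mCherry intact (its 2A
    peptide is upstream of the break). N−1 reaches the T2A-NanoLuc
    cassette, N−2 the P2A-mTagBFP2 cassette. HDR restores moxGFP alongside
    mCherry. In-frame indels in mCherry are assumed to disrupt fluorescence
    (``inframe_disrupts_function``); in-frame indels in the SOI leave only
    mCherry on.
    """
    if region not in ("mCherry", "SOI"):
        raise ValueError(f"unsupported region {region!r}")
    if fclass == FrameClass.HDR:
        return PhenotypeVector(True, True, False, False)
    if fclass in (FrameClass.UNEDITED, FrameClass.SUBSTITUTION_ONLY):
        return PhenotypeVector(True, False, False, False)
    if region == "mCherry":
        if fclass == FrameClass.N1:
            return PhenotypeVector(False, False, False, True)
        if fclass == FrameClass.N2:
            return PhenotypeVector(False, False, True, False)
        if inframe_disrupts_function:
            return _OFF
        return PhenotypeVector(True, False, False, False)
    if fclass == FrameClass.N1:
        return PhenotypeVector(True, False, False, True)
    if fclass == FrameClass.N2:
        return PhenotypeVector(True, False, True, False)
    return PhenotypeVector(True, False, False, False)


def cell_phenotype(integrant_phenotypes: list[PhenotypeVector]) -> PhenotypeVector:
    """Elementwise OR over the phenotypes of a cell's integrants."""
    if not integrant_phenotypes:
        raise ValueError("cell has no integrants")
    out = _OFF
    for p in integrant_phenotypes:
        out = out | p
    return out
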