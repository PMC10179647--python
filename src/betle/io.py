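"""FASTA/FASTQ/GenBank readers and writers.

Thin wrappers over Biopython's SeqIO that move between on-disk formats and
the package's domain types. GenBank features use 1-based inclusive
coordinates and are converted to the internal 0-based half-open
convention; cassette feature names travel in the ``/label`` qualifier.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .reporter_model import (
    CassetteFeature,
    FeatureName,
    ReporterCassette,
    SequenceRecord,
)


class ParseError(ValueError):
    pass


def read_fasta(path, allow_n: bool = False) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), rec.description, allow_n=allow_n)
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path) -> list[BioSeqRecord]:
    """Phred+33 FASTQ; malformed records raise with the record index."""
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            records.append(rec)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTQ near record {len(records)}: {exc}") from exc
    return records


def write_fastq(records: list[BioSeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


_LABEL_TO_NAME = {n.value: n for n in FeatureName}


def read_genbank(path) -> ReporterCassette:
    """Read an annotated cassette; features whose /label matches a known
    cassette part become CassetteFeatures (others map to 'other')."""
    rec = SeqIO.read(str(path), "genbank")
    features = []
    for f in rec.features:
        if f.type == "source":
            continue
        label = (f.qualifiers.get("label") or [""])[0]
        name = _LABEL_TO_NAME.get(label, FeatureName.other)
        shift = int((f.qualifiers.get("frame_shift") or ["0"])[0])
        features.append(
            CassetteFeature(
                name,
                int(f.location.start),
                int(f.location.end),
                declared_frame_shift=shift,
                strand="-" if f.location.strand == -1 else "+",
            )
        )
    features.sort(key=lambda f: f.start)
    up = down = ""
    comment = rec.annotations.get("comment", "")
    for token in str(comment).split():
        if token.startswith("esp3i_overhang_up="):
            up = token.split("=", 1)[1]
        elif token.startswith("esp3i_overhang_down="):
            down = token.split("=", 1)[1]
    record = SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
    return ReporterCassette(record, features, (up, down))


def write_genbank(cassette: ReporterCassette, path) -> None:
    rec = BioSeqRecord(
        Seq(cassette.record.seq),
        id=cassette.record.id[:16],
        name=cassette.record.id[:16],
        description=cassette.record.description,
        annotations={
            "molecule_type": "DNA",
            "comment": (
                f"esp3i_overhang_up={cassette.esp3i_overhangs[0]} "
                f"esp3i_overhang_down={cassette.esp3i_overhangs[1]}"
            ),
        },
    )
    for f in cassette.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="misc_feature",
                qualifiers={
                    "label": [f.name.value],
                    "frame_shift": [str(f.declared_frame_shift)],
                },
            )
        )
    SeqIO.write(rec, str(path), "genbank")


def read_windows_tsv(path):
    """Window TSV (name, start, end), 1-based inclusive coordinates."""
    from .amplicon_analysis import AnalysisWindow

    windows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, start, end = line.split("\t")[:3]
        windows.append(AnalysisWindow.from_one_based(name, int(start), int(end)))
    if not windows:
        raise ParseError(f"{path}: no windows")
    return windows
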