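"""Demultiplexing, restriction-site verification and quality filtering.

This stage is a simplified equivalent of the demultiplex/trim/filter step of
RADseq preprocessing (a process_radtags-like pass): reads carry an inline
sample barcode followed by the restriction-enzyme overhang remnant (TGCAGG
for SbfI).  A read is assigned to a sample when its prefix is within a small
Hamming distance of exactly one barcode; the overhang must then match
exactly — it is the locus anchor, so no mismatch tolerance is allowed there.
An optional sliding-window mean-quality filter drops degraded reads.

Every input read is accounted for: retained per sample, or counted under one
of the drop reasons (unknown barcode, ambiguous barcode, missing restriction
site, low quality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .io_utils import FastqRecord, PathLike, read_fastq, write_fastq

logger = logging.getLogger(__name__)

VALID_SEXES = ("M", "F")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual: id, inline barcode and phenotypic sex."""

    sample_id: str
    barcode: str
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if not self.barcode or set(self.barcode) - set("ACGT"):
            raise ValueError(f"barcode must be non-empty ACGT, got {self.barcode!r}")


@dataclass
class SampleSheet:
    """Sample metadata table: unique ids, unique well-separated barcodes.

    Barcodes must be the same length and pairwise >= 2 mismatches apart so
    that single-mismatch rescue can never be ambiguous between exact hits.
    """

    records: List[SampleRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("sample sheet is empty")
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sheet")
        lengths = {len(r.barcode) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"barcodes must share one length, got {sorted(lengths)}")
        for i, a in enumerate(self.records):
            for b in self.records[i + 1 :]:
                if hamming(a.barcode, b.barcode) < 2:
                    raise ValueError(
                        f"barcodes {a.barcode} ({a.sample_id}) and {b.barcode} "
                        f"({b.sample_id}) are <2 mismatches apart"
                    )

    @property
    def sample_ids(self) -> List[str]:
        return [r.sample_id for r in self.records]

    @property
    def barcode_length(self) -> int:
        return len(self.records[0].barcode)

    def sex_of(self) -> Dict[str, str]:
        return {r.sample_id: r.sex for r in self.records}

    def require_both_sexes(self) -> None:
        sexes = {r.sex for r in self.records}
        if sexes != {"M", "F"}:
            raise ValueError(
                "sex-marker stages need at least one male and one female; "
                f"sheet has only {sorted(sexes)}"
            )

    def write(self, path: PathLike) -> None:
        with open(path, "w") as out:
            out.write("sample_id\tbarcode\tsex\n")
            for r in self.records:
                out.write(f"{r.sample_id}\t{r.barcode}\t{r.sex}\n")

    @classmethod
    def read(cls, path: PathLike) -> "SampleSheet":
        records = []
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header[:3] != ["sample_id", "barcode", "sex"]:
                raise ValueError(f"unexpected sample sheet header: {header}")
            for line in handle:
                line = line.rstrip("\n")
                if not line:
                    continue
                sample_id, barcode, sex = line.split("\t")[:3]
                records.append(SampleRecord(sample_id, barcode, sex))
        return cls(records)


@dataclass
class DemuxReport:
    """Read accounting for one demultiplexing pass.

    Invariant: sum(per_sample.values()) + all dropped counts == total_reads.
    """

    per_sample: Dict[str, int] = field(default_factory=dict)
    dropped_unknown_barcode: int = 0
    dropped_ambiguous_barcode: int = 0
    dropped_missing_site: int = 0
    dropped_low_quality: int = 0
    total_reads: int = 0

    @property
    def retained(self) -> int:
        return sum(self.per_sample.values())

    @property
    def dropped(self) -> int:
        return (
            self.dropped_unknown_barcode
            + self.dropped_ambiguous_barcode
            + self.dropped_missing_site
            + self.dropped_low_quality
        )

    def check_conservation(self) -> None:
        if self.retained + self.dropped != self.total_reads:
            raise AssertionError(
                f"demux accounting broken: {self.retained} retained + "
                f"{self.dropped} dropped != {self.total_reads} input"
            )

    def write(self, path: PathLike) -> None:
        with open(path, "w") as out:
            out.write("category\tcount\n")
            for sid, n in self.per_sample.items():
                out.write(f"retained:{sid}\t{n}\n")
            out.write(f"dropped:unknown_barcode\t{self.dropped_unknown_barcode}\n")
            out.write(f"dropped:ambiguous_barcode\t{self.dropped_ambiguous_barcode}\n")
            out.write(f"dropped:missing_restriction_site\t{self.dropped_missing_site}\n")
            out.write(f"dropped:low_quality\t{self.dropped_low_quality}\n")
            out.write(f"total\t{self.total_reads}\n")


def _window_means_below(qual: str, window: int, threshold: float) -> bool:
    """True if any length-`window` sliding window has mean phred < threshold."""
    phreds = [ord(c) - 33 for c in qual]
    w = min(window, len(phreds))
    if w == 0:
        return False
    running = sum(phreds[:w])
    if running / w < threshold:
        return True
    for i in range(w, len(phreds)):
        running += phreds[i] - phreds[i - w]
        if running / w < threshold:
            return True
    return False


def quality_filter(
    reads: Iterable[FastqRecord], window: int = 15, threshold: float = 10.0
) -> Tuple[List[FastqRecord], int]:
    """Drop reads containing any sliding window of mean phred < threshold.

    Retained reads are passed through unmodified.  Returns (retained,
    n_dropped).  A read whose quality string length differs from its sequence
    length is a hard error.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kept: List[FastqRecord] = []
    dropped = 0
    for title, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(
                f"sequence/quality length mismatch in read {title!r}: "
                f"{len(seq)} vs {len(qual)}"
            )
        if _window_means_below(qual, window, threshold):
            dropped += 1
        else:
            kept.append((title, seq, qual))
    return kept, dropped


def _assign_barcode(
    prefix: str, barcodes: Dict[str, str], max_mismatch: int
) -> Optional[str]:
    """Return the sample_id for this read prefix, or None.

    Exact match wins outright (barcodes are >=2 apart, so it is unique).
    Otherwise a unique barcode within max_mismatch rescues the read; two
    candidates within tolerance is ambiguity, signalled by raising KeyError.
    """
    if prefix in barcodes:
        return barcodes[prefix]
    if max_mismatch == 0:
        return None
    hits = [
        sid
        for bc, sid in barcodes.items()
        if hamming(prefix, bc) <= max_mismatch
    ]
    if len(hits) > 1:
        raise KeyError("ambiguous")
    return hits[0] if hits else None


def demultiplex(
    reads: Union[PathLike, Iterable[FastqRecord]],
    sheet: SampleSheet,
    overhang: str = "TGCAGG",
    allow_barcode_mismatch: int = 1,
    check_overhang: bool = True,
    trim_length: Optional[int] = None,
    quality_window: Optional[int] = None,
    quality_threshold: float = 10.0,
) -> Tuple[Dict[str, List[FastqRecord]], DemuxReport]:
    """Assign barcoded reads to samples and strip the barcode.

    A read is assigned to the unique sample whose barcode is within
    ``allow_barcode_mismatch`` of the read prefix; ambiguity (two barcodes in
    tolerance) drops the read rather than risking misassignment.  With
    ``check_overhang``, the bases immediately after the barcode must equal
    ``overhang`` exactly.  Assigned reads are emitted barcode-removed and
    overhang-retained, trimmed to ``trim_length`` if given, else to the
    shortest retained read length.  When ``quality_window`` is set, the
    sliding-window filter of :func:`quality_filter` is applied in the same
    pass and counted in the report.
    """
    if check_overhang and not overhang:
        raise ValueError("overhang must be non-empty when check_overhang is set")
    if allow_barcode_mismatch < 0:
        raise ValueError("allow_barcode_mismatch must be >= 0")

    barcodes = {r.barcode: r.sample_id for r in sheet.records}
    bc_len = sheet.barcode_length
    report = DemuxReport(per_sample={r.sample_id: 0 for r in sheet.records})
    out: Dict[str, List[FastqRecord]] = {r.sample_id: [] for r in sheet.records}

    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)

    for title, seq, qual in reads:
        report.total_reads += 1
        if len(seq) != len(qual):
            raise ValueError(
                f"sequence/quality length mismatch in read {title!r}"
            )
        if len(seq) < bc_len + (len(overhang) if check_overhang else 0):
            report.dropped_unknown_barcode += 1
            continue
        try:
            sid = _assign_barcode(seq[:bc_len], barcodes, allow_barcode_mismatch)
        except KeyError:
            report.dropped_ambiguous_barcode += 1
            continue
        if sid is None:
            report.dropped_unknown_barcode += 1
            continue
        if check_overhang and seq[bc_len : bc_len + len(overhang)] != overhang:
            report.dropped_missing_site += 1
            continue
        trimmed_seq, trimmed_qual = seq[bc_len:], qual[bc_len:]
        if quality_window is not None and _window_means_below(
            trimmed_qual, quality_window, quality_threshold
        ):
            report.dropped_low_quality += 1
            continue
        out[sid].append((title, trimmed_seq, trimmed_qual))
        report.per_sample[sid] += 1

    target = trim_length
    if target is None:
        lengths = [len(r[1]) for recs in out.values() for r in recs]
        target = min(lengths) if lengths else None
    if target is not None:
        for sid, recs in out.items():
            out[sid] = [(t, s[:target], q[:target]) for t, s, q in recs]

    report.check_conservation()
    logger.info(
        "demultiplexed %d reads: %d retained, %d dropped",
        report.total_reads, report.retained, report.dropped,
    )
    return out, report


def write_demultiplexed(
    demuxed: Dict[str, List[FastqRecord]], out_dir: PathLike
) -> Dict[str, Path]:
    """Write one FASTQ per sample; returns sample_id -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid, records in demuxed.items():
        path = out_dir / f"{sid}.fastq"
        write_fastq(path, records)
        paths[sid] = path
    return paths
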