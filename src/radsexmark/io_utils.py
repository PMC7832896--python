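"""Thin FASTQ and table I/O helpers shared by the pipeline stages.

FASTQ parsing delegates to Biopython's :func:`FastqGeneralIterator`; the
wrapper here only adds gzip transparency and error messages that name the
offending record index, which the downstream stages rely on.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Tuple, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

FastqRecord = Tuple[str, str, str]  # (title, sequence, quality)
PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(source: Union[PathLike, IO[str]]) -> Iterator[FastqRecord]:
    """Yield ``(title, sequence, quality)`` tuples from a FASTQ file or handle.

    Transparently decompresses ``.gz`` paths.  A malformed record raises
    :class:`ValueError` naming the (0-based) index of the record at which
    parsing failed.
    """
    if isinstance(source, (str, Path)):
        handle = _open_text(source)
        close = True
    else:
        handle, close = source, False
    n = 0
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                record = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {n}: {exc}"
                ) from exc
            yield record
            n += 1
    finally:
        if close:
            handle.close()


def write_fastq(path: PathLike, records: Iterable[FastqRecord]) -> int:
    """Write 4-line FASTQ records; returns the number written."""
    n = 0
    with _open_text(path, "wt") as out:
        for title, seq, qual in records:
            out.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq_sequences(path: PathLike) -> list[str]:
    """Sequences only — the shape the tag caller and confirmation scan use."""
    return [seq for _, seq, _ in read_fastq(path)]
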