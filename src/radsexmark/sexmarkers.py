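"""Sex-specific marker identification with raw-read confirmation.

The core screen of the pipeline.  From the locus presence/absence matrix, a
locus is *putatively* sex-specific when it is present in at least
``min_carriers`` individuals of one sex and in **zero** individuals of the
other — absence in the other sex is absolute, because the tolerance for
error belongs to the next step, not to the screen.

The *confirmation* step then searches the raw (post-demultiplex,
pre-tag-calling) reads of the opposite sex for each putative marker's allele
sequences.  Any match disqualifies the marker: a locus sequenced below the
tag-calling depth threshold in one sex is invisible to the presence matrix
yet present in that sex's read files, and would otherwise masquerade as
sex-specific.  Confirmed markers are therefore a subset of putative ones.

Confirmed male-specific markers indicate Y-linked sequence and hence an
XX/XY system; confirmed female-specific markers indicate W-linkage and a
ZZ/ZW system.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .io_utils import PathLike, read_fastq_sequences
from .radtags import Locus

logger = logging.getLogger(__name__)

MALE, FEMALE = "MALE", "FEMALE"
_SPECIFICITY_SEX = {MALE: "M", FEMALE: "F"}
_OPPOSITE_SEX = {MALE: "F", FEMALE: "M"}


@dataclass(frozen=True)
class SexMarker:
    """A candidate sex-specific locus and the evidence about it.

    ``confirmed`` is None until the raw-read confirmation has run; when
    False, ``disconfirming_evidence`` lists (sample_id, n_matching_reads)
    for every opposite-sex individual whose reads contained an allele.
    """

    locus_id: str
    specificity: str
    sequences: Tuple[str, ...]
    n_carriers: int
    carriers: Tuple[str, ...] = ()
    confirmed: Optional[bool] = None
    disconfirming_evidence: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.specificity not in (MALE, FEMALE):
            raise ValueError(f"specificity must be MALE or FEMALE, got {self.specificity!r}")
        if self.confirmed is False and not self.disconfirming_evidence:
            raise ValueError("a disconfirmed marker must carry evidence")


@dataclass(frozen=True)
class SystemCall:
    """Heterogamety inference from confirmed marker counts."""

    system: str  # XY | ZW | UNRESOLVED
    n_male_specific_confirmed: int
    n_female_specific_confirmed: int


def default_min_carriers(n_sex: int) -> int:
    """Half the individuals of the specific sex, rounded up (min 1)."""
    return max(1, math.ceil(n_sex / 2))


def find_putative(
    matrix: pd.DataFrame,
    sexes: pd.Series,
    loci_by_id: Optional[Mapping[str, Locus]] = None,
    min_carriers: Optional[int] = None,
) -> List[SexMarker]:
    """Screen the presence matrix for putatively sex-specific loci.

    A locus is putatively MALE-specific iff present in >= min_carriers males
    and zero females (symmetric for FEMALE).  min_carriers defaults per sex
    to half that sex's sample size, rounded up.  Output is sorted by carrier
    count descending, then locus id, for diffable reports.
    """
    sexes = sexes.reindex(matrix.columns)
    male_cols = [c for c in matrix.columns if sexes[c] == "M"]
    female_cols = [c for c in matrix.columns if sexes[c] == "F"]
    if not male_cols or not female_cols:
        raise ValueError("presence matrix must contain both sexes")
    thresholds = {
        MALE: min_carriers if min_carriers is not None
        else default_min_carriers(len(male_cols)),
        FEMALE: min_carriers if min_carriers is not None
        else default_min_carriers(len(female_cols)),
    }

    markers: List[SexMarker] = []
    n_males = matrix[male_cols].sum(axis=1)
    n_females = matrix[female_cols].sum(axis=1)
    for locus_id in matrix.index:
        m, f = int(n_males[locus_id]), int(n_females[locus_id])
        if f == 0 and m >= thresholds[MALE]:
            spec, count, cols = MALE, m, male_cols
        elif m == 0 and f >= thresholds[FEMALE]:
            spec, count, cols = FEMALE, f, female_cols
        else:
            continue
        carriers = tuple(c for c in cols if matrix.at[locus_id, c])
        sequences: Tuple[str, ...] = ()
        if loci_by_id is not None:
            sequences = tuple(loci_by_id[locus_id].alleles)
        markers.append(SexMarker(
            locus_id=locus_id, specificity=spec, sequences=sequences,
            n_carriers=count, carriers=carriers,
        ))
    markers.sort(key=lambda mk: (-mk.n_carriers, mk.locus_id))
    logger.info(
        "putative markers: %d male-specific, %d female-specific",
        sum(mk.specificity == MALE for mk in markers),
        sum(mk.specificity == FEMALE for mk in markers),
    )
    return markers


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


class _ReadIndex:
    """Per-sample read-sequence lookup for the confirmation scan."""

    def __init__(self, sequences: Sequence[str]):
        self.counts: Dict[str, int] = {}
        for s in sequences:
            self.counts[s] = self.counts.get(s, 0) + 1
        self._prefix_cache: Dict[int, Dict[str, int]] = {}

    def _prefix_counts(self, length: int) -> Dict[str, int]:
        cached = self._prefix_cache.get(length)
        if cached is None:
            cached = {}
            for s, n in self.counts.items():
                if len(s) >= length:
                    p = s[:length]
                    cached[p] = cached.get(p, 0) + n
            self._prefix_cache[length] = cached
        return cached

    def matches(self, tag: str, max_mismatches: int) -> int:
        """Reads whose prefix equals the tag within max_mismatches."""
        prefixes = self._prefix_counts(len(tag))
        if max_mismatches == 0:
            return prefixes.get(tag, 0)
        return sum(
            n for p, n in prefixes.items()
            if _hamming_at_most(p, tag, max_mismatches)
        )


def confirm(
    markers: Sequence[SexMarker],
    reads_by_sample: Mapping[str, Union[PathLike, Sequence[str]]],
    sexes: Mapping[str, str],
    max_mismatches: int = 0,
) -> List[SexMarker]:
    """Confirm putative markers against the opposite sex's raw reads.

    A marker is confirmed iff none of its allele sequences matches any
    opposite-sex read at <= max_mismatches over the full tag length (reads
    and tags share the restriction-site anchor, so comparison is positional,
    no alignment).  Both alleles of a two-allele locus are checked — either
    one appearing in the opposite sex disqualifies sex linkage.  A missing
    read file for any opposite-sex sample is a hard error: silently skipping
    it would inflate confirmation.
    """
    needed_sexes = {_OPPOSITE_SEX[m.specificity] for m in markers}
    indexes: Dict[str, _ReadIndex] = {}
    for sample_id, sex in sexes.items():
        if sex not in needed_sexes:
            continue
        if sample_id not in reads_by_sample:
            raise ValueError(
                f"missing raw reads for opposite-sex sample {sample_id}"
            )
        source = reads_by_sample[sample_id]
        if isinstance(source, (str, Path)):
            sequences: Sequence[str] = read_fastq_sequences(source)
        else:
            sequences = source
        indexes[sample_id] = _ReadIndex(sequences)

    out: List[SexMarker] = []
    for marker in markers:
        if not marker.sequences:
            raise ValueError(
                f"marker {marker.locus_id} has no allele sequences to confirm"
            )
        opposite = _OPPOSITE_SEX[marker.specificity]
        evidence: List[Tuple[str, int]] = []
        for sample_id, sex in sexes.items():
            if sex != opposite:
                continue
            n = sum(
                indexes[sample_id].matches(seq, max_mismatches)
                for seq in marker.sequences
            )
            if n > 0:
                evidence.append((sample_id, n))
        out.append(replace(
            marker,
            confirmed=not evidence,
            disconfirming_evidence=tuple(evidence),
        ))
    logger.info(
        "confirmation: %d/%d markers confirmed",
        sum(bool(m.confirmed) for m in out), len(out),
    )
    return out


def call_system(markers: Sequence[SexMarker], min_markers: int = 1) -> SystemCall:
    """Infer heterogamety from confirmed marker counts.

    XY requires >= min_markers confirmed male-specific markers and zero
    confirmed female-specific ones; ZW is symmetric; anything else (both
    positive, or both below threshold) is UNRESOLVED.
    """
    n_male = sum(m.specificity == MALE and m.confirmed for m in markers)
    n_female = sum(m.specificity == FEMALE and m.confirmed for m in markers)
    if n_male >= min_markers and n_female == 0:
        system = "XY"
    elif n_female >= min_markers and n_male == 0:
        system = "ZW"
    else:
        system = "UNRESOLVED"
    return SystemCall(system, n_male, n_female)


# ---------------------------------------------------------------------------
# report writers

def markers_to_frame(markers: Sequence[SexMarker]) -> pd.DataFrame:
    rows = []
    for m in markers:
        rows.append({
            "locus_id": m.locus_id,
            "specificity": m.specificity,
            "n_carriers": m.n_carriers,
            "carriers": ",".join(m.carriers),
            "sequences": ",".join(m.sequences),
            "confirmed": "" if m.confirmed is None else str(m.confirmed),
            "disconfirming_evidence": ";".join(
                f"{sid}:{n}" for sid, n in m.disconfirming_evidence
            ),
        })
    return pd.DataFrame(
        rows,
        columns=["locus_id", "specificity", "n_carriers", "carriers",
                 "sequences", "confirmed", "disconfirming_evidence"],
    )


def write_markers(markers: Sequence[SexMarker], path: PathLike,
                  header_params: str = "") -> None:
    with open(path, "w") as out:
        if header_params:
            out.write(f"# {header_params}\n")
        markers_to_frame(markers).to_csv(out, sep="\t", index=False)


def write_markers_fasta(markers: Sequence[SexMarker], path: PathLike) -> None:
    """Confirmed-marker alleles as FASTA — input to downstream BLAST."""
    with open(path, "w") as out:
        for m in markers:
            for k, seq in enumerate(m.sequences, start=1):
                out.write(f">{m.locus_id}_allele{k} {m.specificity.lower()}_specific\n")
                out.write(f"{seq}\n")


def write_system_call(call: SystemCall, path: PathLike) -> None:
    with open(path, "w") as out:
        json.dump({
            "system": call.system,
            "n_male_specific_confirmed": call.n_male_specific_confirmed,
            "n_female_specific_confirmed": call.n_female_specific_confirmed,
        }, out, indent=2, sort_keys=True)
        out.write("\n")
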