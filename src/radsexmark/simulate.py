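"""Synthetic RADseq read simulator with known sex chromosome architecture.

Emulates the sampling design of a single-enzyme (SbfI) RADseq study of two
gecko populations: a handful of males and females, 150-bp-class forward
reads of the form ``barcode + overhang + tag``, and a genome containing

* autosomal loci (optionally polymorphic, two alleles one SNP apart, carried
  under Hardy-Weinberg proportions),
* sex-limited loci — Y-hemizygous under an XY system, W-specific under ZW —
  whose tags occur only in the heterogametic sex,
* gametolog pairs: a shared (X- or Z-linked) allele carried by everyone plus
  a diverged allele carried only by the heterogametic sex, mimicking X/Y or
  Z/W sequence divergence,
* optional planted false-positive loci: autosomal tags sequenced at a fixed
  depth below any sensible tag-calling threshold in the homogametic sex but
  at full depth in the heterogametic sex.  These are invisible to
  presence/absence analysis in one sex yet present in its raw reads — the
  exact failure mode the raw-read confirmation step exists to catch.

Per-tag depth is Poisson; allelic dropout zeroes an individual x locus cell;
sequencing error is an i.i.d. per-base substitution applied downstream of
the barcode.  Identical parameters + seed give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .io_utils import PathLike, write_fastq
from .preprocess import SampleRecord, SampleSheet, hamming

BASES = np.frombuffer(b"ACGT", dtype="S1")

CLASS_AUTOSOMAL = "AUTOSOMAL"
CLASS_SEXLIMITED = "SEXLIMITED"
CLASS_GAMETOLOG_SHARED = "GAMETOLOG_SHARED"
CLASS_GAMETOLOG_SEXLIMITED = "GAMETOLOG_SEXLIMITED"
TRUTH_CLASSES = (
    CLASS_AUTOSOMAL,
    CLASS_SEXLIMITED,
    CLASS_GAMETOLOG_SHARED,
    CLASS_GAMETOLOG_SEXLIMITED,
)

SYSTEMS = ("XY", "ZW", "NONE")

# Minimum pairwise Hamming distance between independently drawn tag cores;
# keeps locus clustering unambiguous at simulation scale.
MIN_TAG_DISTANCE = 10


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated RADseq dataset.

    ``system`` selects heterogamety: under XY the males carry the sex-limited
    and diverged-gametolog tags, under ZW the females do, and NONE forbids
    both locus classes.  ``allele_div`` is realised as an exact count of
    substituted positions, ``round(allele_div * tag_length)``, so whether a
    gametolog pair co-clusters with its partner allele is deterministic.
    """

    n_males: int
    n_females: int
    system: str = "NONE"
    n_autosomal_loci: int = 0
    n_sexlimited_loci: int = 0
    n_gametolog_pairs: int = 0
    n_planted_fp: int = 0
    tag_length: int = 140
    barcode_length: int = 6
    overhang: str = "TGCAGG"
    mean_depth: float = 20.0
    error_rate: float = 0.001
    dropout_rate: float = 0.02
    allele_div: float = 0.05
    poly_fraction: float = 0.3
    alt_allele_freq: float = 0.3
    fp_low_depth: int = 2
    lowqual_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_males=self.n_males,
            n_females=self.n_females,
            n_autosomal_loci=self.n_autosomal_loci,
            n_sexlimited_loci=self.n_sexlimited_loci,
            n_gametolog_pairs=self.n_gametolog_pairs,
            n_planted_fp=self.n_planted_fp,
            tag_length=self.tag_length,
            barcode_length=self.barcode_length,
        )
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_males == 0 and self.n_females == 0:
            raise ValueError("need at least one individual (n_males=n_females=0)")
        if self.system not in SYSTEMS:
            raise ValueError(f"system must be one of {SYSTEMS}, got {self.system!r}")
        for name in ("error_rate", "dropout_rate", "allele_div",
                     "poly_fraction", "alt_allele_freq", "lowqual_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.system == "NONE" and (
            self.n_sexlimited_loci or self.n_gametolog_pairs or self.n_planted_fp
        ):
            raise ValueError(
                "system=NONE admits no sex-limited loci, gametolog pairs or "
                "planted false positives"
            )
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if set(self.overhang) - set("ACGT"):
            raise ValueError(f"overhang must be ACGT, got {self.overhang!r}")

    @property
    def heterogametic_sex(self) -> Optional[str]:
        return {"XY": "M", "ZW": "F", "NONE": None}[self.system]


@dataclass(frozen=True)
class TruthLocus:
    """Ground truth for one locus: its tag sequence(s) and true carriers.

    ``sequences`` are full post-barcode sequences (overhang + tag core);
    ``carriers`` is one frozenset of sample ids per sequence.
    """

    locus_id: str
    locus_class: str
    sequences: Tuple[str, ...]
    carriers: Tuple[FrozenSet[str], ...]

    def __post_init__(self) -> None:
        if self.locus_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown locus class {self.locus_class!r}")
        if not self.sequences or len(self.sequences) > 2:
            raise ValueError("a truth locus has one or two sequences")
        if len(self.sequences) != len(self.carriers):
            raise ValueError("one carrier set per sequence required")


@dataclass
class TruthTable:
    loci: List[TruthLocus]

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus_id in truth table")

    def by_class(self, locus_class: str) -> List[TruthLocus]:
        return [l for l in self.loci if l.locus_class == locus_class]

    def all_sequences(self) -> Dict[str, str]:
        """sequence -> locus_id over every allele in the table."""
        return {s: l.locus_id for l in self.loci for s in l.sequences}


def write_truth(truth: TruthTable, path: PathLike) -> None:
    """Serialise a truth table as TSV (one row per locus).

    Carrier sets are comma-joined per allele and '|'-joined across alleles;
    an allele nobody carries is recorded as '-'.
    """
    if not truth.loci:
        raise ValueError("refusing to write an empty truth table")
    with open(path, "w") as out:
        out.write("locus_id\tclass\tsequences\tcarriers\n")
        for locus in truth.loci:
            carriers = "|".join(
                ",".join(sorted(c)) if c else "-" for c in locus.carriers
            )
            out.write(
                f"{locus.locus_id}\t{locus.locus_class}\t"
                f"{','.join(locus.sequences)}\t{carriers}\n"
            )


def read_truth(path: PathLike) -> TruthTable:
    loci: List[TruthLocus] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["locus_id", "class", "sequences", "carriers"]:
            raise ValueError(f"unexpected truth table header: {header}")
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            locus_id, cls, seqs, carriers = line.split("\t")
            carrier_sets = tuple(
                frozenset() if group == "-" else frozenset(group.split(","))
                for group in carriers.split("|")
            )
            loci.append(TruthLocus(locus_id, cls, tuple(seqs.split(",")), carrier_sets))
    if not loci:
        raise ValueError(f"truth table {path} contains no loci")
    return TruthTable(loci)


@dataclass
class SimulatedDataset:
    params: SimParams
    sheet: SampleSheet
    truth: TruthTable
    fastq_paths: Dict[str, Path]
    pooled_path: Path
    sheet_path: Path
    truth_path: Path


def _random_core(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _draw_cores(rng: np.random.Generator, n: int, length: int) -> List[str]:
    """Independent tag cores, pairwise >= MIN_TAG_DISTANCE apart (rejection)."""
    min_dist = min(MIN_TAG_DISTANCE, length)
    cores: List[str] = []
    attempts = 0
    while len(cores) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError(
                "could not draw well-separated tag cores; tag_length too short "
                f"for {n} loci"
            )
        candidate = _random_core(rng, length)
        if all(hamming(candidate, c) >= min_dist for c in cores):
            cores.append(candidate)
    return cores


def _mutate_positions(
    rng: np.random.Generator, core: str, n_positions: int
) -> str:
    """Substitute exactly n_positions distinct sites, each to a new base."""
    n_positions = min(n_positions, len(core))
    arr = np.frombuffer(core.encode(), dtype="S1").copy()
    sites = rng.choice(len(core), size=n_positions, replace=False)
    for site in sites:
        alternatives = BASES[BASES != arr[site]]
        arr[site] = rng.choice(alternatives)
    return arr.tobytes().decode()


def _draw_barcodes(rng: np.random.Generator, n: int, length: int) -> List[str]:
    barcodes: List[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise RuntimeError(f"cannot place {n} barcodes of length {length}")
        candidate = _random_core(rng, length)
        if all(hamming(candidate, b) >= 2 for b in barcodes):
            barcodes.append(candidate)
    return barcodes


def _apply_errors(
    rng: np.random.Generator, seq: str, n_copies: int, error_rate: float
) -> List[str]:
    """n_copies reads of seq with i.i.d. per-base substitution errors."""
    if n_copies == 0:
        return []
    if error_rate == 0.0:
        return [seq] * n_copies
    arr = np.frombuffer(seq.encode(), dtype="S1")
    reads = np.tile(arr, (n_copies, 1))
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err:
        # shift by 1-3 positions in base order: always a different base
        originals = reads[mask]
        idx = np.searchsorted(BASES, originals)
        shift = rng.integers(1, 4, size=n_err)
        reads[mask] = BASES[(idx + shift) % 4]
    return [row.tobytes().decode() for row in reads]


def _build_truth(params: SimParams, rng: np.random.Generator,
                 sheet: SampleSheet) -> TruthTable:
    all_ids = frozenset(sheet.sample_ids)
    het = params.heterogametic_sex
    het_ids = frozenset(r.sample_id for r in sheet.records if r.sex == het)
    hom_ids = all_ids - het_ids

    n_cores = (
        params.n_autosomal_loci
        + params.n_sexlimited_loci
        + params.n_gametolog_pairs
        + params.n_planted_fp
    )
    cores = _draw_cores(rng, n_cores, params.tag_length)
    it = iter(cores)
    oh = params.overhang
    loci: List[TruthLocus] = []

    for i in range(params.n_autosomal_loci):
        ref = next(it)
        if rng.random() < params.poly_fraction:
            alt = _mutate_positions(rng, ref, 1)
            q = params.alt_allele_freq
            ref_carriers, alt_carriers = set(), set()
            for sid in sheet.sample_ids:
                genotype = rng.random(2) < q  # True = alt
                if not genotype.all():
                    ref_carriers.add(sid)
                if genotype.any():
                    alt_carriers.add(sid)
            loci.append(TruthLocus(
                f"AUTO_{i + 1:04d}", CLASS_AUTOSOMAL,
                (oh + ref, oh + alt),
                (frozenset(ref_carriers), frozenset(alt_carriers)),
            ))
        else:
            loci.append(TruthLocus(
                f"AUTO_{i + 1:04d}", CLASS_AUTOSOMAL, (oh + ref,), (all_ids,)
            ))

    for i in range(params.n_sexlimited_loci):
        loci.append(TruthLocus(
            f"SEXLIM_{i + 1:04d}", CLASS_SEXLIMITED, (oh + next(it),), (het_ids,)
        ))

    n_div = max(1, round(params.allele_div * params.tag_length))
    for i in range(params.n_gametolog_pairs):
        shared = next(it)
        diverged = _mutate_positions(rng, shared, n_div)
        loci.append(TruthLocus(
            f"GAM_{i + 1:04d}_shared", CLASS_GAMETOLOG_SHARED,
            (oh + shared,), (all_ids,)
        ))
        loci.append(TruthLocus(
            f"GAM_{i + 1:04d}_sexlim", CLASS_GAMETOLOG_SEXLIMITED,
            (oh + diverged,), (het_ids,)
        ))

    for i in range(params.n_planted_fp):
        loci.append(TruthLocus(
            f"FP_{i + 1:04d}", CLASS_AUTOSOMAL, (oh + next(it),), (all_ids,)
        ))

    return TruthTable(loci)


def simulate_dataset(params: SimParams, out_dir: PathLike) -> SimulatedDataset:
    """Simulate a RADseq dataset into ``out_dir``.

    Writes one barcoded FASTQ per individual, a pooled ``reads.fastq``
    (concatenation in sample-sheet order, the demultiplexer's input), a
    ``samples.tsv`` sample sheet and a ``truth.tsv`` ground-truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    n = params.n_males + params.n_females
    barcodes = _draw_barcodes(rng, n, params.barcode_length)
    records = []
    for i in range(params.n_males):
        records.append(SampleRecord(f"M{i + 1:02d}", barcodes[i], "M"))
    for i in range(params.n_females):
        records.append(SampleRecord(f"F{i + 1:02d}", barcodes[params.n_males + i], "F"))
    sheet = SampleSheet(records)
    het = params.heterogametic_sex

    truth = _build_truth(params, rng, sheet)

    fastq_paths: Dict[str, Path] = {}
    pooled_path = out_dir / "reads.fastq"
    qual_template = "I" * (params.barcode_length + len(params.overhang)
                           + params.tag_length)
    with open(pooled_path, "w") as pooled:
        for record in sheet.records:
            reads = []
            for locus in truth.loci:
                planted_fp = locus.locus_id.startswith("FP_")
                drop = (
                    not planted_fp
                    and params.dropout_rate > 0
                    and rng.random() < params.dropout_rate
                )
                for ai, (seq, carriers) in enumerate(
                    zip(locus.sequences, locus.carriers)
                ):
                    if record.sample_id not in carriers:
                        continue
                    if planted_fp:
                        depth = (
                            int(round(params.mean_depth))
                            if record.sex == het
                            else params.fp_low_depth
                        )
                    else:
                        depth = int(rng.poisson(params.mean_depth))
                    if drop or depth == 0:
                        continue
                    for copy, read_seq in enumerate(
                        _apply_errors(rng, seq, depth, params.error_rate)
                    ):
                        title = f"{record.sample_id}:{locus.locus_id}:a{ai}:{copy}"
                        qual = qual_template
                        if (params.lowqual_fraction > 0
                                and rng.random() < params.lowqual_fraction):
                            start = int(rng.integers(0, len(qual) - 14))
                            qual = (qual[:start] + "#" * 15 + qual[start + 15:])
                        reads.append((title, record.barcode + read_seq, qual))
            path = out_dir / f"{record.sample_id}.fastq"
            write_fastq(path, reads)
            fastq_paths[record.sample_id] = path
            for title, seq, qual in reads:
                pooled.write(f"@{title}\n{seq}\n+\n{qual}\n")

    sheet_path = out_dir / "samples.tsv"
    sheet.write(sheet_path)
    truth_path = out_dir / "truth.tsv"
    write_truth(truth, truth_path)
    return SimulatedDataset(
        params=params, sheet=sheet, truth=truth, fastq_paths=fastq_paths,
        pooled_path=pooled_path, sheet_path=sheet_path, truth_path=truth_path,
    )


def simulate_synteny_inputs(
    out_dir: PathLike,
    n_genes: int = 38,
    n_on_target: int = 19,
    target_chromosome: str = "chr10",
    n_chromosomes: int = 20,
    genes_on_target_chromosome: int = 400,
    total_genes: int = 15200,
    seed: int = 0,
) -> Dict[str, Path]:
    """Build BLAST-tabular fixtures for the synteny stage, entirely synthetic.

    Produces a gene-level annotation (gene_id -> chromosome) in which
    ``target_chromosome`` holds ``genes_on_target_chromosome`` of
    ``total_genes`` annotated genes, plus two 12-column BLAST hit tables
    chaining marker -> transcript -> gene such that ``n_on_target`` of the
    ``n_genes`` uniquely-hit genes lie on the target chromosome.  Decoy hits
    with worse e-values / failing bitscores exercise best-hit resolution.
    """
    if not 0 <= n_on_target <= n_genes:
        raise ValueError("need 0 <= n_on_target <= n_genes")
    if genes_on_target_chromosome > total_genes:
        raise ValueError("target chromosome cannot exceed the gene universe")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    others = [f"chr{i}" for i in range(1, n_chromosomes + 1)
              if f"chr{i}" != target_chromosome]
    remaining = total_genes - genes_on_target_chromosome
    base, extra = divmod(remaining, len(others))
    chrom_counts = {target_chromosome: genes_on_target_chromosome}
    for i, chrom in enumerate(others):
        chrom_counts[chrom] = base + (1 if i < extra else 0)

    annot_path = out_dir / "annotation.tsv"
    gene_names: Dict[str, List[str]] = {}
    with open(annot_path, "w") as out:
        out.write("gene_id\tchromosome\n")
        for chrom in sorted(chrom_counts):
            gene_names[chrom] = [
                f"{chrom}_g{j + 1:05d}" for j in range(chrom_counts[chrom])
            ]
            for g in gene_names[chrom]:
                out.write(f"{g}\t{chrom}\n")

    # pick the hit genes: n_on_target from the target, rest spread elsewhere
    hit_genes = [gene_names[target_chromosome][j] for j in range(n_on_target)]
    pool = [g for chrom in sorted(others) for g in gene_names[chrom][:5]]
    off_target = rng.choice(len(pool), size=n_genes - n_on_target, replace=False)
    hit_genes += [pool[i] for i in sorted(off_target)]

    m2t_path = out_dir / "markers_vs_transcripts.tsv"
    t2g_path = out_dir / "transcripts_vs_genes.tsv"

    def blast_row(q, s, evalue, bitscore):
        return (f"{q}\t{s}\t98.5\t140\t2\t0\t1\t140\t1\t140\t"
                f"{evalue:.2e}\t{bitscore:.1f}\n")

    with open(m2t_path, "w") as m2t, open(t2g_path, "w") as t2g:
        for i, gene in enumerate(hit_genes):
            marker, transcript = f"marker_{i + 1:03d}", f"trans_{i + 1:03d}"
            m2t.write(blast_row(marker, transcript, 1e-40, 250.0))
            # decoys: worse e-value for the marker; sub-threshold second hit
            m2t.write(blast_row(marker, f"trans_decoy_{i + 1:03d}", 1e-12, 90.0))
            t2g.write(blast_row(transcript, gene, 1e-35, 220.0))
            t2g.write(blast_row(transcript, f"{gene}_decoy", 1e-3, 40.0))
    return {
        "markers_vs_transcripts": m2t_path,
        "transcripts_vs_genes": t2g_path,
        "annotation": annot_path,
    }
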