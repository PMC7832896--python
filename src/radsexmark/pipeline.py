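"""Pipeline orchestration: config, run-all, summary and truth evaluation.

A single strict config drives the whole chain simulate -> demultiplex ->
tag/locus calling -> sex-marker screen + confirmation -> (optional) synteny
enrichment.  Every stage leaves its artifacts on disk under the run
directory, every tunable is stamped into output headers, and a
machine-readable ``summary.json`` records the counts at each stage.  Re-running
with an identical config and inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from . import radtags as rt
from . import sexmarkers as sm
from . import synteny as syn
from .io_utils import PathLike, read_fastq_sequences
from .preprocess import SampleSheet, demultiplex, write_demultiplexed
from .simulate import (
    CLASS_AUTOSOMAL,
    CLASS_GAMETOLOG_SEXLIMITED,
    CLASS_GAMETOLOG_SHARED,
    CLASS_SEXLIMITED,
    SimParams,
    TruthTable,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and (if known) its artifact path."""

    def __init__(self, stage: str, message: str, artifact: Optional[Path] = None):
        self.stage = stage
        self.artifact = artifact
        where = f" (artifact: {artifact})" if artifact else ""
        super().__init__(f"stage {stage!r} failed{where}: {message}")


def _check_keys(section: Mapping[str, Any], allowed: Sequence[str], name: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")


@dataclass(frozen=True)
class DemuxConfig:
    overhang: str = "TGCAGG"
    allow_barcode_mismatch: int = 1
    check_overhang: bool = True
    quality_window: int = 15
    quality_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.allow_barcode_mismatch < 0:
            raise ValueError("allow_barcode_mismatch must be >= 0")
        if self.quality_window < 1:
            raise ValueError("quality_window must be >= 1")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")


@dataclass(frozen=True)
class RadtagsConfig:
    min_depth: int = 5
    max_allele_mismatch: int = 3
    per_individual_filter: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_allele_mismatch < 0:
            raise ValueError("max_allele_mismatch must be >= 0")


@dataclass(frozen=True)
class SexmarkersConfig:
    min_carriers: Optional[int] = None  # None -> half the specific sex
    max_mismatches: int = 0
    min_markers: int = 1

    def __post_init__(self) -> None:
        if self.min_carriers is not None and self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1 (or null for default)")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")


@dataclass(frozen=True)
class SyntenyConfig:
    markers_vs_transcripts: str = ""
    transcripts_vs_genes: str = ""
    annotation: str = ""
    evalue_max: float = 1e-10
    alpha: float = 0.05
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full run.

    Exactly one of ``simulate`` (generate the inputs) or ``inputs``
    (pre-existing pooled FASTQ + sample sheet paths) must be provided.
    Unknown keys anywhere are rejected at load time.
    """

    simulate: Optional[SimParams] = None
    reads: Optional[str] = None
    sheet: Optional[str] = None
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    radtags: RadtagsConfig = field(default_factory=RadtagsConfig)
    sexmarkers: SexmarkersConfig = field(default_factory=SexmarkersConfig)
    synteny: Optional[SyntenyConfig] = None

    def __post_init__(self) -> None:
        have_sim = self.simulate is not None
        have_inputs = self.reads is not None and self.sheet is not None
        if have_sim == have_inputs:
            raise ValueError(
                "config needs either a 'simulate' section or both "
                "'inputs.reads' and 'inputs.sheet', not both/neither"
            )

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        _check_keys(raw, ["simulate", "inputs", "demux", "radtags",
                          "sexmarkers", "synteny"], "<root>")
        sim = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"])
            _check_keys(sim_raw, [f.name for f in dataclasses.fields(SimParams)],
                        "simulate")
            sim = SimParams(**sim_raw)
        reads = sheet = None
        if "inputs" in raw:
            inputs = dict(raw["inputs"])
            _check_keys(inputs, ["reads", "sheet"], "inputs")
            reads, sheet = inputs.get("reads"), inputs.get("sheet")

        def build(section: str, klass):
            data = dict(raw.get(section, {}))
            _check_keys(data, [f.name for f in dataclasses.fields(klass)], section)
            return klass(**data)

        synteny_cfg = None
        if "synteny" in raw:
            synteny_cfg = build("synteny", SyntenyConfig)
            for key in ("markers_vs_transcripts", "transcripts_vs_genes",
                        "annotation"):
                if not getattr(synteny_cfg, key):
                    raise ValueError(f"synteny config requires {key!r}")
        return cls(
            simulate=sim,
            reads=reads,
            sheet=sheet,
            demux=build("demux", DemuxConfig),
            radtags=build("radtags", RadtagsConfig),
            sexmarkers=build("sexmarkers", SexmarkersConfig),
            synteny=synteny_cfg,
        )

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> Dict[str, Any]:
        out: Dict[str, Any] = {
            "demux": dataclasses.asdict(self.demux),
            "radtags": dataclasses.asdict(self.radtags),
            "sexmarkers": dataclasses.asdict(self.sexmarkers),
        }
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        else:
            out["inputs"] = {"reads": self.reads, "sheet": self.sheet}
        if self.synteny is not None:
            out["synteny"] = dataclasses.asdict(self.synteny)
        return out

    def stamp(self) -> str:
        """One-line parameter provenance for output headers."""
        parts = [
            f"min_depth={self.radtags.min_depth}",
            f"max_allele_mismatch={self.radtags.max_allele_mismatch}",
            f"min_carriers={self.sexmarkers.min_carriers}",
            f"max_mismatches={self.sexmarkers.max_mismatches}",
            f"overhang={self.demux.overhang}",
        ]
        if self.simulate is not None:
            parts.append(f"seed={self.simulate.seed}")
        return " ".join(parts)


def run_pipeline(config: PipelineConfig, out_dir: PathLike) -> Dict[str, Any]:
    """Run all stages, leaving artifacts and ``summary.json`` under out_dir.

    Returns the summary dict.  Any stage error is re-raised as
    :class:`PipelineError` carrying the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, Any] = {"config": config.to_dict(), "stages": {}}
    t0 = time.perf_counter()

    # --- stage: simulate (or load inputs) ---------------------------------
    try:
        if config.simulate is not None:
            sim = simulate_dataset(config.simulate, out_dir / "sim")
            pooled, sheet = sim.pooled_path, sim.sheet
            summary["stages"]["simulate"] = {
                "n_individuals": len(sheet.records),
                "system": config.simulate.system,
                "truth_loci": len(sim.truth.loci),
            }
        else:
            pooled = Path(config.reads)  # type: ignore[arg-type]
            sheet = SampleSheet.read(config.sheet)  # type: ignore[arg-type]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc
    logger.info("stage simulate done (%.2fs)", time.perf_counter() - t0)

    # --- stage: demultiplex ----------------------------------------------
    t = time.perf_counter()
    demux_dir = out_dir / "demux"
    try:
        demuxed, report = demultiplex(
            pooled, sheet,
            overhang=config.demux.overhang,
            allow_barcode_mismatch=config.demux.allow_barcode_mismatch,
            check_overhang=config.demux.check_overhang,
            quality_window=config.demux.quality_window,
            quality_threshold=config.demux.quality_threshold,
        )
        demux_paths = write_demultiplexed(demuxed, demux_dir)
        report.write(demux_dir / "demux_report.tsv")
        summary["stages"]["demux"] = {
            "total_reads": report.total_reads,
            "retained": report.retained,
            "dropped_unknown_barcode": report.dropped_unknown_barcode,
            "dropped_ambiguous_barcode": report.dropped_ambiguous_barcode,
            "dropped_missing_site": report.dropped_missing_site,
            "dropped_low_quality": report.dropped_low_quality,
            "per_sample": dict(report.per_sample),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("demux", str(exc), demux_dir) from exc
    logger.info("stage demux done (%.2fs)", time.perf_counter() - t)

    # --- stage: tag and locus calling ------------------------------------
    t = time.perf_counter()
    loci_dir = out_dir / "loci"
    try:
        loci_dir.mkdir(exist_ok=True)
        seqs_by_sample = {sid: [r[1] for r in recs] for sid, recs in demuxed.items()}
        tags = rt.call_tags_all(seqs_by_sample, min_depth=config.radtags.min_depth)
        loci = rt.cluster_loci(
            tags,
            max_allele_mismatch=config.radtags.max_allele_mismatch,
            per_individual_filter=config.radtags.per_individual_filter,
        )
        matrix, sexes = rt.presence_matrix(loci, sheet)
        rt.write_loci_fasta(loci, loci_dir / "loci.fasta", config.stamp())
        rt.write_presence_matrix(matrix, sexes, loci_dir / "presence.tsv",
                                 config.stamp())
        summary["stages"]["loci"] = {
            "n_tags": len(tags),
            "n_loci": len(loci),
            "n_excluded": sum(l.excluded for l in loci),
            "n_retained": len(loci) - sum(l.excluded for l in loci),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("loci", str(exc), loci_dir) from exc
    logger.info("stage loci done (%.2fs)", time.perf_counter() - t)

    # --- stage: sex markers ----------------------------------------------
    t = time.perf_counter()
    markers_dir = out_dir / "markers"
    try:
        markers_dir.mkdir(exist_ok=True)
        sheet.require_both_sexes()
        loci_by_id = {l.locus_id: l for l in loci}
        putative = sm.find_putative(
            matrix, sexes, loci_by_id=loci_by_id,
            min_carriers=config.sexmarkers.min_carriers,
        )
        confirmed_all = sm.confirm(
            putative, seqs_by_sample, sheet.sex_of(),
            max_mismatches=config.sexmarkers.max_mismatches,
        )
        confirmed = [m for m in confirmed_all if m.confirmed]
        system = sm.call_system(confirmed_all,
                                min_markers=config.sexmarkers.min_markers)
        sm.write_markers(putative, markers_dir / "putative.tsv", config.stamp())
        sm.write_markers(confirmed_all, markers_dir / "confirmed.tsv",
                         config.stamp())
        sm.write_markers_fasta(confirmed, markers_dir / "confirmed.fasta")
        sm.write_system_call(system, markers_dir / "system_call.json")
        summary["stages"]["sexmarkers"] = {
            "n_putative_male": sum(m.specificity == sm.MALE for m in putative),
            "n_putative_female": sum(m.specificity == sm.FEMALE for m in putative),
            "n_confirmed_male": system.n_male_specific_confirmed,
            "n_confirmed_female": system.n_female_specific_confirmed,
            "system": system.system,
        }
        summary["system"] = system.system
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("sexmarkers", str(exc), markers_dir) from exc
    logger.info("stage sexmarkers done (%.2fs)", time.perf_counter() - t)

    # --- stage: synteny (optional) ----------------------------------------
    if config.synteny is not None:
        t = time.perf_counter()
        syn_dir = out_dir / "synteny"
        try:
            syn_dir.mkdir(exist_ok=True)
            annotation = syn.AnnotationTable.from_tsv(config.synteny.annotation)
            if annotation.gene_to_chromosome is None:
                raise ValueError(
                    "synteny stage needs a gene-level annotation "
                    "(gene_id<TAB>chromosome) to place hit genes"
                )
            chains = syn.resolve_hits(
                config.synteny.markers_vs_transcripts,
                config.synteny.transcripts_vs_genes,
                annotation.gene_to_chromosome,
                evalue_max=config.synteny.evalue_max,
            )
            result = syn.enrichment_table(
                chains, annotation,
                alpha=config.synteny.alpha,
                bonferroni=config.synteny.bonferroni,
            )
            syn.write_enrichment(result, syn_dir / "enrichment.tsv",
                                 config.stamp())
            summary["stages"]["synteny"] = {
                "n_unique_genes": result.n_genes,
                "top_chromosome": result.top_chromosome,
                "top_p": result.top_p,
                "top_observed": next(
                    r.observed for r in result.rows
                    if r.chromosome == result.top_chromosome
                ),
                "top_significant": result.top_significant,
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("synteny", str(exc), syn_dir) from exc
        logger.info("stage synteny done (%.2fs)", time.perf_counter() - t)

    with open(out_dir / "summary.json", "w") as out:
        json.dump(summary, out, indent=2, sort_keys=True)
        out.write("\n")
    logger.info("pipeline done (%.2fs total)", time.perf_counter() - t0)
    return summary


# ---------------------------------------------------------------------------
# truth evaluation

SEXLINKED_TRUTH_CLASSES = (CLASS_SEXLIMITED, CLASS_GAMETOLOG_SEXLIMITED)


def _match_truth_locus(sequences: Sequence[str], truth: TruthTable,
                       radius: int = 3) -> str:
    """Map a called marker to its truth locus by allele sequence.

    Exact sequence match first; else nearest truth sequence within
    ``radius`` mismatches (tag-calling can promote an error read to an
    allele).  No match at all is a hard error — the marker does not belong
    to the simulated genome.
    """
    seq_to_locus = truth.all_sequences()
    for seq in sequences:
        if seq in seq_to_locus:
            return seq_to_locus[seq]
    for seq in sequences:
        for truth_seq, locus_id in seq_to_locus.items():
            if len(truth_seq) == len(seq):
                if sum(a != b for a, b in zip(truth_seq, seq)) <= radius:
                    return locus_id
    raise ValueError(
        f"marker sequences {[s[:20] + '...' for s in sequences]} match no "
        "truth locus"
    )


def evaluate(
    truth: TruthTable,
    confirmed_markers: Sequence[sm.SexMarker],
    system: Optional[str] = None,
    expected_system: Optional[str] = None,
) -> Dict[str, Any]:
    """Score a run against ground truth.

    sensitivity   = recovered sex-limited truth loci / total sex-limited;
    specificity   = non-sex-linked truth loci *not* called / total
                    non-sex-linked (AUTOSOMAL + GAMETOLOG_SHARED);
    diverged gametolog alleles are genuinely sex-linked, so their recovery
    is reported separately and they count against neither metric.
    """
    confirmed = [m for m in confirmed_markers if m.confirmed]
    recovered_ids = {
        _match_truth_locus(m.sequences, truth) for m in confirmed
    }

    sexlim = truth.by_class(CLASS_SEXLIMITED)
    gam_sexlim = truth.by_class(CLASS_GAMETOLOG_SEXLIMITED)
    neutral = (truth.by_class(CLASS_AUTOSOMAL)
               + truth.by_class(CLASS_GAMETOLOG_SHARED))

    n_recovered = sum(l.locus_id in recovered_ids for l in sexlim)
    n_gam_recovered = sum(l.locus_id in recovered_ids for l in gam_sexlim)
    n_false = sum(l.locus_id in recovered_ids for l in neutral)

    metrics: Dict[str, Any] = {
        "n_sexlimited_truth": len(sexlim),
        "n_sexlimited_recovered": n_recovered,
        "sensitivity": n_recovered / len(sexlim) if sexlim else float("nan"),
        "n_neutral_truth": len(neutral),
        "n_false_positive": n_false,
        "specificity": (
            (len(neutral) - n_false) / len(neutral) if neutral else float("nan")
        ),
        "n_gametolog_sexlimited_recovered": n_gam_recovered,
    }
    if system is not None and expected_system is not None:
        metrics["system"] = system
        metrics["expected_system"] = expected_system
        metrics["system_correct"] = system == expected_system
    return metrics


def load_confirmed_markers(path: PathLike) -> List[sm.SexMarker]:
    """Read a confirmed.tsv written by the sexmarkers stage."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    markers = []
    for _, row in df.iterrows():
        evidence = tuple(
            (part.split(":")[0], int(part.split(":")[1]))
            for part in row["disconfirming_evidence"].split(";") if part
        )
        markers.append(sm.SexMarker(
            locus_id=row["locus_id"],
            specificity=row["specificity"],
            sequences=tuple(s for s in row["sequences"].split(",") if s),
            n_carriers=int(row["n_carriers"]),
            carriers=tuple(c for c in row["carriers"].split(",") if c),
            confirmed={"True": True, "False": False, "": None}[row["confirmed"]],
            disconfirming_evidence=evidence,
        ))
    return markers
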