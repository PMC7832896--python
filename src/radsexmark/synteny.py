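"""Chromosome assignment of sex-linked markers by synteny enrichment.

Sex-specific RAD markers from a species without a reference genome are
localised by a two-step BLAST chain: marker -> transcript of a related
species -> annotated gene of a well-assembled reference genome (classically
chicken, the standard amniote synteny reference).  This module consumes the
two BLAST tabular (outfmt-6-style, 12 column) hit files — BLAST itself is
never invoked — resolves best hits, collapses to unique genes, and tests
each reference chromosome for enrichment of hit genes.

Under the null that hit genes fall on chromosomes in proportion to their
annotated gene counts, the number of hits on a chromosome holding K of N
annotated genes, out of n unique hit genes, is Hypergeometric(N, K, n); the
reported p-value is the upper tail P(X >= k), answering the one-sided
question "significantly more genes than expected?".  Expected counts are
n*K/N.  The lowest-p chromosome is the top call for the sex-linkage group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .io_utils import PathLike

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitChain:
    """One marker's resolved path to a unique reference gene."""

    marker_id: str
    transcript_id: str
    gene_id: str
    chromosome: str
    evalue_marker_transcript: float
    evalue_transcript_gene: float


@dataclass
class AnnotationTable:
    """Per-chromosome annotated gene counts, optionally with a gene map.

    Built either from a gene-level table (gene_id -> chromosome; counts are
    derived and ``gene_to_chromosome`` is populated) or from bare
    per-chromosome counts (then a gene map must be supplied separately to
    resolve hit chains).
    """

    counts: Dict[str, int]
    gene_to_chromosome: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("annotated gene counts must be >= 0")
        if self.total == 0:
            raise ValueError("annotation covers zero genes")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_tsv(cls, path: PathLike) -> "AnnotationTable":
        """Auto-detect layout: gene_id/chromosome rows or chromosome/count."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = [c.lower() for c in df.columns]
        if cols[:2] == ["gene_id", "chromosome"]:
            mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
            counts: Dict[str, int] = {}
            for chrom in mapping.values():
                counts[chrom] = counts.get(chrom, 0) + 1
            return cls(counts=counts, gene_to_chromosome=mapping)
        if cols[:2] == ["chromosome", "gene_count"]:
            counts = {
                str(c): int(n) for c, n in zip(df.iloc[:, 0], df.iloc[:, 1])
            }
            return cls(counts=counts)
        raise ValueError(
            f"unrecognised annotation header {list(df.columns)}; expected "
            "gene_id/chromosome or chromosome/gene_count"
        )


def read_blast6(path: PathLike) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file; malformed rows name their line."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 BLAST tabular "
                    f"columns, got {len(parts)}"
                )
            try:
                parts[10] = float(parts[10])  # type: ignore[call-overload]
                parts[11] = float(parts[11])  # type: ignore[call-overload]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad evalue/bitscore: {exc}"
                ) from exc
            rows.append(parts)
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def best_hits(hits: pd.DataFrame) -> Dict[str, pd.Series]:
    """Best hit per query: lowest e-value, ties by bitscore desc then sseqid."""
    best: Dict[str, pd.Series] = {}
    ordered = hits.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    for _, row in ordered.iterrows():
        best.setdefault(row["qseqid"], row)
    return best


def resolve_hits(
    markers_vs_transcripts: Union[PathLike, pd.DataFrame],
    transcripts_vs_genes: Union[PathLike, pd.DataFrame],
    gene_to_chromosome: Mapping[str, str],
    evalue_max: float = 1e-10,
) -> List[HitChain]:
    """Chain markers to unique reference genes through transcript best hits.

    Per marker, the best transcript hit is chained to that transcript's best
    gene hit; chains failing ``evalue_max`` at either step are dropped.  The
    result is collapsed to unique genes — a gene reached by several markers
    counts once (the chain with the smallest marker e-value, then marker id,
    is kept), since enrichment draws are genes, not markers.
    """
    m2t = (markers_vs_transcripts if isinstance(markers_vs_transcripts, pd.DataFrame)
           else read_blast6(markers_vs_transcripts))
    t2g = (transcripts_vs_genes if isinstance(transcripts_vs_genes, pd.DataFrame)
           else read_blast6(transcripts_vs_genes))

    best_transcript = best_hits(m2t)
    best_gene = best_hits(t2g)

    chains: List[HitChain] = []
    for marker_id in sorted(best_transcript):
        t_hit = best_transcript[marker_id]
        if t_hit["evalue"] > evalue_max:
            continue
        g_hit = best_gene.get(t_hit["sseqid"])
        if g_hit is None or g_hit["evalue"] > evalue_max:
            continue
        gene_id = g_hit["sseqid"]
        chromosome = gene_to_chromosome.get(gene_id)
        if chromosome is None:
            raise ValueError(
                f"gene {gene_id} (via marker {marker_id}) is absent from the "
                "annotation"
            )
        chains.append(HitChain(
            marker_id=marker_id,
            transcript_id=t_hit["sseqid"],
            gene_id=gene_id,
            chromosome=chromosome,
            evalue_marker_transcript=float(t_hit["evalue"]),
            evalue_transcript_gene=float(g_hit["evalue"]),
        ))

    unique: Dict[str, HitChain] = {}
    for chain in sorted(
        chains, key=lambda c: (c.gene_id, c.evalue_marker_transcript, c.marker_id)
    ):
        unique.setdefault(chain.gene_id, chain)
    resolved = sorted(unique.values(), key=lambda c: c.marker_id)
    logger.info(
        "resolved %d marker chains to %d unique genes", len(chains), len(resolved)
    )
    return resolved


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Population of N genes, K of them on the chromosome of interest, n drawn
    (the unique BLAST-hit genes), k observed on that chromosome.  Computed
    in log space from log-factorials and summed over the upper support, so
    tails around 1e-21 are representable without underflow.  k <= the lower
    support bound gives exactly 1.0; k beyond min(K, n) gives 0.0.
    """
    for name, value in (("k", k), ("N", N), ("K", K), ("n", n)):
        if int(value) != value:
            raise ValueError(f"{name} must be an integer, got {value!r}")
    k, N, K, n = int(k), int(N), int(K), int(n)
    if k < 0:
        raise ValueError("k must be >= 0")
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    lo = max(0, n + K - N)
    hi = min(K, n)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    lg = math.lgamma
    log_denom = lg(N + 1) - lg(n + 1) - lg(N - n + 1)
    logs = []
    for j in range(k, hi + 1):
        logs.append(
            lg(K + 1) - lg(j + 1) - lg(K - j + 1)
            + lg(N - K + 1) - lg(n - j + 1) - lg(N - K - n + j + 1)
            - log_denom
        )
    peak = max(logs)
    total = sum(math.exp(x - peak) for x in logs)
    return min(1.0, math.exp(peak) * total)


@dataclass(frozen=True)
class EnrichmentRow:
    chromosome: str
    observed: int
    expected: float
    p: float
    significant: bool


@dataclass(frozen=True)
class EnrichmentResult:
    rows: Tuple[EnrichmentRow, ...]
    top_chromosome: str
    top_p: float
    top_significant: bool
    n_genes: int
    alpha: float
    bonferroni: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "chromosome": r.chromosome, "observed": r.observed,
                "expected": r.expected, "p": r.p, "significant": r.significant,
            } for r in self.rows]
        )


def enrichment_table(
    chains: Sequence[HitChain],
    annotation: AnnotationTable,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> EnrichmentResult:
    """Per-chromosome observed/expected gene counts and upper-tail p-values.

    Expected counts are n*K/N (they sum to n over chromosomes); p-values are
    raw upper-tail hypergeometric probabilities, optionally Bonferroni-
    adjusted across chromosomes for the significance flag.  Rows are sorted
    by p ascending (ties by chromosome name) and the lowest-p chromosome is
    the top call.
    """
    if not chains:
        raise ValueError("no resolved gene hits to test")
    observed: Dict[str, int] = {chrom: 0 for chrom in annotation.counts}
    for chain in chains:
        if chain.chromosome not in observed:
            raise ValueError(
                f"gene {chain.gene_id} lies on {chain.chromosome!r}, which is "
                "missing from the annotation"
            )
        observed[chain.chromosome] += 1
    n = len(chains)
    N = annotation.total
    if n > N:
        raise ValueError(f"{n} unique genes exceed the annotation universe {N}")

    m_tests = len(annotation.counts)
    rows = []
    for chrom in annotation.counts:
        K = annotation.counts[chrom]
        k = observed[chrom]
        p = hypergeom_sf(k, N, K, n)
        p_adj = min(1.0, p * m_tests) if bonferroni else p
        rows.append(EnrichmentRow(
            chromosome=chrom,
            observed=k,
            expected=n * K / N,
            p=p,
            significant=p_adj < alpha,
        ))
    rows.sort(key=lambda r: (r.p, r.chromosome))
    top = rows[0]
    return EnrichmentResult(
        rows=tuple(rows),
        top_chromosome=top.chromosome,
        top_p=top.p,
        top_significant=top.significant,
        n_genes=n,
        alpha=alpha,
        bonferroni=bonferroni,
    )


def write_enrichment(result: EnrichmentResult, path: PathLike,
                     header_params: str = "") -> None:
    """TSV of the enrichment table — also the observed-vs-expected plot data."""
    with open(path, "w") as out:
        if header_params:
            out.write(f"# {header_params}\n")
        out.write(f"# n_genes={result.n_genes} alpha={result.alpha} "
                  f"bonferroni={result.bonferroni}\n")
        result.to_frame().to_csv(out, sep="\t", index=False, float_format="%.6g")


def plot_enrichment(result: EnrichmentResult, path: PathLike,
                    max_chromosomes: int = 30) -> None:
    """Observed vs expected bar chart per chromosome (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    rows = sorted(result.rows, key=lambda r: r.chromosome)[:max_chromosomes]
    x = np.arange(len(rows))
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(rows)), 4))
    ax.bar(x - 0.2, [r.observed for r in rows], width=0.4,
           color="black", label="observed")
    ax.bar(x + 0.2, [r.expected for r in rows], width=0.4,
           color="grey", label="expected")
    ax.set_xticks(x)
    ax.set_xticklabels([r.chromosome for r in rows], rotation=90)
    ax.set_ylabel("genes with BLAST match")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
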