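"""Prevalence statistics of a gene panel within normalized SAGE catalogues.

The central quantity is the panel's cumulative tags-per-million in a
library: the sum of tpm over the panel's distinct tags.  Dividing by 10^6
gives the panel's share of the library's transcriptome; the per-gene mean
(cumulative / panel size, undetected genes included) and the single most
abundant gene complete the per-library summary.  Dominance — the fraction
of the cumulative signal carried by the top gene alone — distinguishes
libraries where one transcript (e.g. PTPN14 in bronchial epithelium)
accounts for nearly all panel expression from balanced profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sage_io import NormalizedCatalogue, TPM_SCALE
from .tag_annotation import GeneTagCatalogue


@dataclass
class PrevalenceSummary:
    """Per-library panel expression summary (all tpm units)."""

    accession: str
    cluster: str = ""
    sum_tpm: float = 0.0
    avg_tpm: float = 0.0
    max_tpm: float = 0.0
    max_gene: str = ""

    @property
    def percent_of_transcriptome(self) -> float:
        return self.sum_tpm / TPM_SCALE * 100.0

    @property
    def dominance(self) -> float:
        """max_tpm / sum_tpm, 0 for an all-zero library."""
        return self.max_tpm / self.sum_tpm if self.sum_tpm > 0 else 0.0


@dataclass
class ExpressionMatrix:
    """Libraries x panel-genes tpm matrix, plus the gene -> tag mapping.

    Genes sharing a tag each carry that tag's tpm; cumulative statistics
    therefore sum over distinct tags, not gene columns, so a shared tag is
    never double-counted.
    """

    values: pd.DataFrame  # rows: accessions; columns: gene symbols
    gene_tags: dict[str, str]

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DetectionProfile:
    gene_symbol: str
    n_libraries_detected: int
    min_level_only: bool


def build_matrix(
    catalogues: Sequence[NormalizedCatalogue], panel: GeneTagCatalogue
) -> ExpressionMatrix:
    """Match every panel tag against every catalogue.

    Cell (library, gene) holds the tpm of the gene's tag in that library,
    0 when undetected.  If two panel genes share a tag, both columns receive
    the tag's tpm and a warning is emitted.
    """
    gene_tags = panel.tags()
    shared = panel.shared_tags()
    if shared:
        warnings.warn(
            f"panel tags shared by multiple genes (counted once in sums): {shared}",
            stacklevel=2,
        )
    data = {
        cat.accession: [cat[tag] for tag in gene_tags.values()] for cat in catalogues
    }
    frame = pd.DataFrame.from_dict(
        data, orient="index", columns=list(gene_tags.keys()), dtype=float
    )
    return ExpressionMatrix(values=frame, gene_tags=gene_tags)


def summarize_library(
    row: pd.Series,
    n_panel_genes: int,
    gene_tags: Mapping[str, str] | None = None,
    cluster: str = "",
) -> PrevalenceSummary:
    """Summarize one library row (gene symbol -> tpm).

    ``gene_tags`` enables distinct-tag summation when panel genes share a
    tag; without it every column is treated as its own tag.  The average
    divides by the full panel size, undetected genes included.  Ties for
    the top gene break to the lexicographically smallest symbol.
    """
    if n_panel_genes <= 0:
        raise ValueError("n_panel_genes must be positive")
    if gene_tags is not None:
        seen: set[str] = set()
        total = 0.0
        for gene, value in row.items():
            tag = gene_tags.get(gene, gene)
            if tag in seen:
                continue
            seen.add(tag)
            total += float(value)
    else:
        total = float(row.sum())
    if len(row):
        max_gene = min(row.index[row == row.max()])
        max_tpm = float(row.max())
    else:
        max_gene, max_tpm = "", 0.0
    return PrevalenceSummary(
        accession=str(row.name) if row.name is not None else "",
        cluster=cluster,
        sum_tpm=total,
        avg_tpm=total / n_panel_genes,
        max_tpm=max_tpm,
        max_gene=max_gene if max_tpm > 0 else "",
    )


def summarize_matrix(
    matrix: ExpressionMatrix,
    clusters: Mapping[str, str] | None = None,
    n_panel_genes: int | None = None,
) -> list[PrevalenceSummary]:
    """Per-library summaries for a whole expression matrix."""
    n = n_panel_genes if n_panel_genes is not None else len(matrix.genes)
    clusters = clusters or {}
    return [
        summarize_library(
            matrix.values.loc[acc],
            n,
            gene_tags=matrix.gene_tags,
            cluster=clusters.get(acc, ""),
        )
        for acc in matrix.accessions
    ]


def dominance_report(summary: PrevalenceSummary) -> float:
    """Percent of the panel's cumulative tpm carried by its top gene."""
    if summary.sum_tpm <= 0:
        raise ValueError(f"{summary.accession}: dominance undefined for zero cumulative tpm")
    return summary.max_tpm / summary.sum_tpm * 100.0


def rank_deciles(
    summaries: Sequence[PrevalenceSummary], fraction: float = 0.10
) -> tuple[list[PrevalenceSummary], list[PrevalenceSummary]]:
    """Libraries with the top and bottom ``fraction`` of cumulative expression.

    List length is ceil(fraction * n); ties in cumulative tpm break by
    accession so the ranking is deterministic.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    if not summaries:
        return [], []
    n = math.ceil(fraction * len(summaries))
    top = sorted(summaries, key=lambda s: (-s.sum_tpm, s.accession))[:n]
    bottom = sorted(summaries, key=lambda s: (s.sum_tpm, s.accession))[:n]
    return top, bottom


def detection_profiles(
    matrix: ExpressionMatrix,
    raw_counts: Mapping[tuple[str, str], int],
) -> list[DetectionProfile]:
    """Per-gene detection tallies across the cohort.

    A gene is detected in a library when its tpm is nonzero; the detection
    is "minimum level" when the underlying raw tag count is 1 (a single
    observed tag, the smallest nonzero signal a library can report).
    ``raw_counts`` maps (accession, tag) to the raw count.
    """
    profiles = []
    for gene in matrix.genes:
        tag = matrix.gene_tags[gene]
        column = matrix.values[gene]
        detected = [acc for acc in matrix.accessions if column.loc[acc] > 0]
        min_only = bool(detected) and all(
            raw_counts.get((acc, tag), 0) == 1 for acc in detected
        )
        profiles.append(
            DetectionProfile(
                gene_symbol=gene,
                n_libraries_detected=len(detected),
                min_level_only=min_only,
            )
        )
    return profiles


def cohort_statistics(
    summaries: Sequence[PrevalenceSummary],
) -> tuple[dict[str, float], float]:
    """Unweighted mean percent-of-transcriptome per cluster and overall.

    Every library counts equally regardless of depth; empty clusters are
    omitted from the per-cluster map.
    """
    if not summaries:
        return {}, float("nan")
    by_cluster: dict[str, list[float]] = {}
    for s in summaries:
        by_cluster.setdefault(s.cluster, []).append(s.percent_of_transcriptome)
    per_cluster = {c: float(np.mean(v)) for c, v in by_cluster.items()}
    overall = float(np.mean([s.percent_of_transcriptome for s in summaries]))
    return per_cluster, overall


def write_summaries_tsv(summaries: Iterable[PrevalenceSummary], path) -> None:
    """Summary table (tpm columns to 2 dp), sorted by cumulative tpm descending."""
    rows = sorted(summaries, key=lambda s: (-s.sum_tpm, s.accession))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tcluster\tsum_tpm\tavg_tpm\tmax_tpm\tmax_gene\tpercent\n")
        for s in rows:
            fh.write(
                f"{s.accession}\t{s.cluster}\t{s.sum_tpm:.2f}\t{s.avg_tpm:.2f}\t"
                f"{s.max_tpm:.2f}\t{s.max_gene}\t{s.percent_of_transcriptome:.2f}\n"
            )


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.4f", index_label="accession")
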