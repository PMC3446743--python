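"""Library selection criteria and per-cluster summaries.

A library enters the analysis only if it (i) comes from a genetically
unaltered/unmodified sample, (ii) holds at least ``min_tags`` reliable tags
(default 20,000, inclusive), and (iii) has a complete dataset available.
Criteria (i) and (iii) are metadata judgements supplied by the caller; the
pipeline does not attempt to infer them from sample descriptions.

Selected libraries carry one of four cohort codes: C (cancer tissue),
N (normal tissue and cells), IV (cells cultured in vitro), D (nontumorous
disease tissue and cells).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .sage_io import SageCatalogue

CLUSTER_CODES = ("C", "N", "IV", "D")

#: Long-form cohort names, for report output.
CLUSTER_NAMES = {
    "C": "cancer tissue",
    "N": "normal tissue and cells",
    "IV": "cells cultured in vitro",
    "D": "nontumorous disease tissue and cells",
}


@dataclass(frozen=True)
class LibraryMetadata:
    accession: str
    description: str = ""
    cluster: str = "N"
    genetically_altered: bool = False
    complete_dataset: bool = True

    def __post_init__(self) -> None:
        if self.cluster not in CLUSTER_CODES:
            raise ValueError(
                f"{self.accession}: cluster must be one of {CLUSTER_CODES}, "
                f"got {self.cluster!r}"
            )


@dataclass
class SelectionReport:
    kept: list[str]
    excluded: dict[str, str]  # accession -> first failing criterion: "i"|"ii"|"iii"
    per_cluster_counts: dict[str, int]
    per_cluster_tags: dict[str, int]
    total_tags: int


def select_libraries(
    catalogues: Sequence[SageCatalogue],
    metadata: Mapping[str, LibraryMetadata],
    min_tags: int = 20_000,
) -> SelectionReport:
    """Apply the three selection criteria to cleaned catalogues.

    An excluded library records the first failing criterion in the order
    i (genetically altered), ii (undersized), iii (incomplete dataset).
    The reliable (post-cleaning) total is compared against ``min_tags``.
    """
    kept: list[str] = []
    excluded: dict[str, str] = {}
    per_cluster_counts = {c: 0 for c in CLUSTER_CODES}
    per_cluster_tags = {c: 0 for c in CLUSTER_CODES}
    total = 0
    for cat in catalogues:
        meta = metadata.get(cat.accession)
        if meta is None:
            raise KeyError(f"no metadata for accession {cat.accession}")
        if not cat.is_clean:
            raise ValueError(f"{cat.accession}: catalogue must be cleaned first")
        if meta.genetically_altered:
            excluded[cat.accession] = "i"
        elif cat.reliable_total < min_tags:
            excluded[cat.accession] = "ii"
        elif not meta.complete_dataset:
            excluded[cat.accession] = "iii"
        else:
            kept.append(cat.accession)
            per_cluster_counts[meta.cluster] += 1
            per_cluster_tags[meta.cluster] += cat.reliable_total
            total += cat.reliable_total
    return SelectionReport(
        kept=kept,
        excluded=excluded,
        per_cluster_counts=per_cluster_counts,
        per_cluster_tags=per_cluster_tags,
        total_tags=total,
    )


def summarize_clusters(report: SelectionReport) -> list[tuple[str, int, int]]:
    """Per-cluster (cluster, n_catalogues, n_tags) rows plus a Total row."""
    rows = [
        (c, report.per_cluster_counts.get(c, 0), report.per_cluster_tags.get(c, 0))
        for c in CLUSTER_CODES
    ]
    rows.append(
        ("Total", sum(r[1] for r in rows), sum(r[2] for r in rows))
    )
    return rows


def cluster_table(
    per_cluster_counts: Mapping[str, int], per_cluster_tags: Mapping[str, int]
) -> list[tuple[str, int, int]]:
    """Summary rows from raw per-cluster tallies (e.g. a printed summary table)."""
    report = SelectionReport(
        kept=[],
        excluded={},
        per_cluster_counts=dict(per_cluster_counts),
        per_cluster_tags=dict(per_cluster_tags),
        total_tags=sum(per_cluster_tags.values()),
    )
    return summarize_clusters(report)


def read_metadata_tsv(path) -> dict[str, LibraryMetadata]:
    """Read metadata TSV: accession, description, cluster, genetically_altered, complete_dataset."""
    out: dict[str, LibraryMetadata] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            acc = row["accession"]
            if acc in out:
                raise ValueError(f"duplicate accession in metadata: {acc}")
            out[acc] = LibraryMetadata(
                accession=acc,
                description=row.get("description", ""),
                cluster=row["cluster"],
                genetically_altered=row["genetically_altered"].strip() in ("1", "true", "True"),
                complete_dataset=row["complete_dataset"].strip() in ("1", "true", "True"),
            )
    return out


def write_metadata_tsv(metadata: Mapping[str, LibraryMetadata], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tdescription\tcluster\tgenetically_altered\tcomplete_dataset\n")
        for meta in metadata.values():
            fh.write(
                f"{meta.accession}\t{meta.description}\t{meta.cluster}\t"
                f"{int(meta.genetically_altered)}\t{int(meta.complete_dataset)}\n"
            )
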