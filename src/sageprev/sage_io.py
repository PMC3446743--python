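"""SAGE catalogue ingestion, cleaning, deduplication and tpm normalization.

A SAGE catalogue is one library's tag -> raw count table.  Cleaning removes
the noninformative (A)10 tag — which arises from poly-A tails rather than a
real transcript — and optionally applies a per-tag minimum-count filter as a
tag-level stand-in for the clone-level "clean-up" some libraries received at
construction time.  The surviving counts constitute the library's reliable
tags, and tags-per-million values are

    tpm[t] = count[t] / reliable_total * 1,000,000.

Two input dialects are supported: plain two-column TSV (TAG<TAB>COUNT) and
the GEO SOFT GSM sample format, whose count table sits between the
``!sample_table_begin`` and ``!sample_table_end`` markers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

POLY_A_TAG = "A" * 10
TPM_SCALE = 1_000_000

_TAG_RE = re.compile(r"[ACGT]{10}\Z")


@dataclass
class SageCatalogue:
    """One library's tag -> raw count map, with cleaning bookkeeping."""

    accession: str
    counts: dict[str, int]
    reliable_total: int | None = None
    noninformative_removed: int = 0
    metadata: list[str] = field(default_factory=list)

    @property
    def raw_total(self) -> int:
        return sum(self.counts.values())

    @property
    def is_clean(self) -> bool:
        return self.reliable_total is not None


@dataclass
class NormalizedCatalogue:
    """Tags-per-million view of a cleaned catalogue."""

    accession: str
    tpm: dict[str, float]
    reliable_total: int

    def __getitem__(self, tag: str) -> float:
        """tpm for ``tag``; absent tags read as 0 (undetected)."""
        return self.tpm.get(tag, 0.0)


def _parse_count_line(line: str, line_no: int, path: str) -> tuple[str, int] | None:
    stripped = line.strip()
    if not stripped:
        return None
    fields = stripped.split("\t")
    if len(fields) < 2:
        fields = stripped.split()
    if len(fields) < 2:
        raise ValueError(f"{path}:{line_no}: expected TAG and COUNT columns")
    tag, count_str = fields[0].upper(), fields[1]
    if tag in ("TAG", "SEQUENCE"):  # header row
        return None
    if not _TAG_RE.match(tag):
        raise ValueError(f"{path}:{line_no}: malformed tag {fields[0]!r}")
    try:
        count = int(count_str)
    except ValueError:
        raise ValueError(f"{path}:{line_no}: malformed count {count_str!r}") from None
    if count < 0:
        raise ValueError(f"{path}:{line_no}: negative count {count}")
    return tag, count


def read_catalogue(path, dialect: str = "tsv", accession: str | None = None) -> SageCatalogue:
    """Read a raw catalogue in the ``tsv`` or ``geo_soft`` dialect.

    Counts are preserved verbatim; call :func:`clean_catalogue` afterwards.
    Repeated tag rows are summed.  For the GEO SOFT dialect, header lines
    outside the table block are retained as opaque metadata strings and the
    accession is taken from ``^SAMPLE`` when present.
    """
    path = str(path)
    counts: dict[str, int] = {}
    metadata: list[str] = []
    acc = accession
    with open(path, encoding="utf-8") as fh:
        if dialect == "tsv":
            for line_no, line in enumerate(fh, start=1):
                parsed = _parse_count_line(line, line_no, path)
                if parsed:
                    counts[parsed[0]] = counts.get(parsed[0], 0) + parsed[1]
        elif dialect == "geo_soft":
            in_table = False
            for line_no, line in enumerate(fh, start=1):
                stripped = line.strip()
                if stripped.lower().startswith("!sample_table_begin"):
                    in_table = True
                    continue
                if stripped.lower().startswith("!sample_table_end"):
                    in_table = False
                    continue
                if not in_table:
                    if stripped:
                        metadata.append(stripped)
                        m = re.match(r"\^SAMPLE\s*=\s*(\S+)", stripped)
                        if m and accession is None:
                            acc = m.group(1)
                    continue
                parsed = _parse_count_line(line, line_no, path)
                if parsed:
                    counts[parsed[0]] = counts.get(parsed[0], 0) + parsed[1]
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    if acc is None:
        acc = re.sub(r"\.[^.]*$", "", path.rsplit("/", 1)[-1])
    return SageCatalogue(accession=acc, counts=counts, metadata=metadata)


def clean_catalogue(cat: SageCatalogue, min_count: int = 1) -> SageCatalogue:
    """Remove the (A)10 tag and low-count tags; recompute the reliable total.

    ``min_count=1`` keeps every informative tag.  ``min_count=5`` drops tags
    seen four times or fewer, a tag-level emulation of the clone-level
    clean-up applied to some published libraries (clones with <=4 tags are
    not recoverable from the published tag tables).
    """
    poly_a = cat.counts.get(POLY_A_TAG, 0)
    kept = {
        t: c
        for t, c in cat.counts.items()
        if t != POLY_A_TAG and c >= min_count
    }
    return SageCatalogue(
        accession=cat.accession,
        counts=kept,
        reliable_total=sum(kept.values()),
        noninformative_removed=cat.noninformative_removed + poly_a,
        metadata=list(cat.metadata),
    )


def normalize(cat: SageCatalogue) -> NormalizedCatalogue:
    """Convert a cleaned catalogue to tags-per-million."""
    if not cat.is_clean:
        raise ValueError(f"{cat.accession}: catalogue must be cleaned before normalization")
    total = cat.reliable_total
    if total == 0:
        if cat.counts:
            raise ValueError(f"{cat.accession}: zero reliable total with nonempty counts")
        return NormalizedCatalogue(cat.accession, {}, 0)
    tpm = {t: c / total * TPM_SCALE for t, c in cat.counts.items()}
    return NormalizedCatalogue(cat.accession, tpm, total)


def deduplicate(
    catalogues: Sequence[SageCatalogue],
    known_equivalences: Iterable[tuple[str, str]] | None = None,
) -> tuple[list[SageCatalogue], list[tuple[str, str]]]:
    """Drop duplicate library entries.

    Two rules apply, in order: (1) for every known equivalence pair the
    later-listed accession is dropped in favour of the first; (2) any two
    catalogues with identical counts maps are collapsed to the
    first-in-file-order one.  Returns the kept catalogues (input order
    preserved) and a (kept, removed) report.
    """
    by_acc = {c.accession: c for c in catalogues}
    if len(by_acc) != len(catalogues):
        raise ValueError("accessions must be unique before deduplication")

    removed: dict[str, str] = {}  # removed accession -> kept accession
    for pair in known_equivalences or ():
        keep, drop = pair
        if keep not in by_acc or drop not in by_acc:
            warnings.warn(
                f"equivalence pair ({keep}, {drop}) references absent accession",
                stacklevel=2,
            )
            continue
        if drop not in removed:
            removed[drop] = keep

    kept: list[SageCatalogue] = []
    seen_contents: dict[tuple, str] = {}
    for cat in catalogues:
        if cat.accession in removed:
            continue
        key = tuple(sorted(cat.counts.items()))
        if key in seen_contents:
            removed[cat.accession] = seen_contents[key]
            continue
        seen_contents[key] = cat.accession
        kept.append(cat)

    report = [(keeper, dropped) for dropped, keeper in removed.items()]
    return kept, report


def write_catalogue_tsv(cat: SageCatalogue, path) -> None:
    """Write a catalogue as canonical two-column TSV (tags sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for tag in sorted(cat.counts):
            fh.write(f"{tag}\t{cat.counts[tag]}\n")


def write_normalized_tsv(cat: SageCatalogue, norm: NormalizedCatalogue, path) -> None:
    """Write TAG, COUNT, TPM columns for a cleaned catalogue (tpm to 2 dp)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("TAG\tCOUNT\tTPM\n")
        for tag in sorted(cat.counts):
            fh.write(f"{tag}\t{cat.counts[tag]}\t{norm[tag]:.2f}\n")
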