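"""Virtual SAGE tag extraction for a gene panel.

SAGE (serial analysis of gene expression) identifies a transcript by the
short tag immediately 3' of the 3'-most anchoring-enzyme recognition site
on the mRNA.  This module scans transcript sequences for the recognition
site of a chosen anchoring enzyme (NlaIII by default, the enzyme behind
the GPL4 SAGE libraries), extracts the 10-nt tag, and assembles a
gene -> tag catalogue for an imprinted-gene panel.

Sequences are taken 5'->3' in mRNA sense orientation; no reverse-complement
search is performed.  The tag is the ``tag_length`` nucleotides strictly
3'-adjacent to the recognition site, excluding the site itself.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "AnchoringEnzyme",
    "NLAIII",
    "SAU3AI",
    "RSAI",
    "ENZYMES",
    "POLY_A_TAG",
    "NoSiteError",
    "InsufficientDownstreamError",
    "GeneTagRecord",
    "GeneTagCatalogue",
    "AnnotationReport",
    "find_sites",
    "extract_tag",
    "annotate_panel",
    "load_panel_fixture",
    "read_fasta_panel",
    "write_catalogue_tsv",
    "read_catalogue_tsv",
]

POLY_A_TAG = "A" * 10

_TAG_RE = re.compile(r"[ACGT]{10}\Z")
_SEQ_RE = re.compile(r"[ACGTN]+\Z")

_FLAG_NAMES = ("multi", "repetitive", "replaced")


class NoSiteError(ValueError):
    """The sequence contains no anchoring-enzyme recognition site at all."""


class InsufficientDownstreamError(ValueError):
    """No recognition site has a full clean tag's worth of downstream sequence."""


@dataclass(frozen=True)
class AnchoringEnzyme:
    """A SAGE anchoring enzyme: 4-nt recognition site and resulting tag length."""

    name: str
    recognition_site: str
    tag_length: int = 10

    def __post_init__(self) -> None:
        if len(self.recognition_site) != 4:
            raise ValueError("recognition site must be 4 nt")
        if self.tag_length < 1:
            raise ValueError("tag length must be >= 1")


NLAIII = AnchoringEnzyme("NlaIII", "CATG")
SAU3AI = AnchoringEnzyme("Sau3AI", "GATC")
RSAI = AnchoringEnzyme("RsaI", "GTAC")

#: Lookup by lowercase name, as accepted on the command line.
ENZYMES: Mapping[str, AnchoringEnzyme] = {
    "nlaiii": NLAIII,
    "sau3ai": SAU3AI,
    "rsai": RSAI,
}


@dataclass(frozen=True)
class GeneTagRecord:
    """One panel gene with its annotated SAGE tag and mapping flags."""

    gene_symbol: str
    gene_name: str = ""
    aliases: str = ""
    location: str = ""
    status: str = "Candidate"
    expressed_allele: str = "Unknown"
    tag: str = ""
    multi_mapping: bool = False
    repetitive: bool = False
    replaced_unreliable: bool = False
    accession: str = ""

    def __post_init__(self) -> None:
        if not _TAG_RE.match(self.tag):
            raise ValueError(
                f"{self.gene_symbol}: tag {self.tag!r} is not a 10-nt ACGT string"
            )
        if self.tag == POLY_A_TAG:
            raise ValueError(
                f"{self.gene_symbol}: tag equals the noninformative poly-A tag"
            )
        if self.status not in ("Imprinted", "Candidate"):
            raise ValueError(f"{self.gene_symbol}: bad status {self.status!r}")

    @property
    def flags(self) -> str:
        parts = []
        if self.multi_mapping:
            parts.append("multi")
        if self.repetitive:
            parts.append("repetitive")
        if self.replaced_unreliable:
            parts.append("replaced")
        return ",".join(parts)


@dataclass
class GeneTagCatalogue:
    """Ordered gene -> tag catalogue for one anchoring enzyme."""

    records: list[GeneTagRecord]
    enzyme: AnchoringEnzyme = NLAIII

    def __post_init__(self) -> None:
        symbols = [r.gene_symbol for r in self.records]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in catalogue: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.status] = counts.get(rec.status, 0) + 1
        return counts

    def tags(self) -> dict[str, str]:
        """gene_symbol -> tag mapping."""
        return {r.gene_symbol: r.tag for r in self.records}

    def shared_tags(self) -> dict[str, list[str]]:
        """Tags carried by more than one panel gene (tag -> gene symbols)."""
        by_tag: dict[str, list[str]] = {}
        for rec in self.records:
            by_tag.setdefault(rec.tag, []).append(rec.gene_symbol)
        return {t: genes for t, genes in by_tag.items() if len(genes) > 1}


@dataclass
class AnnotationReport:
    """Genes that failed extraction or disagreed with an expected-tag table."""

    no_site_genes: list[str] = field(default_factory=list)
    mismatch_genes: list[str] = field(default_factory=list)


def find_sites(sequence: str, enzyme: AnchoringEnzyme) -> list[int]:
    """Return the 0-based start positions of every recognition-site occurrence.

    Matching is case-insensitive and exact; overlapping occurrences are all
    reported.  ``N`` bases never match.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if not _SEQ_RE.match(seq):
        raise ValueError("sequence alphabet must be A/C/G/T/N")
    site = enzyme.recognition_site
    positions = []
    start = seq.find(site)
    while start != -1:
        positions.append(start)
        start = seq.find(site, start + 1)  # step 1 so overlaps are kept
    return positions


def extract_tag(sequence: str, enzyme: AnchoringEnzyme) -> tuple[str, dict[str, bool]]:
    """Extract the reliable 3' SAGE tag from a sense-strand transcript.

    The tag is taken from the 3'-most recognition site followed by at least
    ``tag_length`` clean (non-N) nucleotides.  When the 3'-most site lacks a
    full clean tag, the next site upstream is used and ``from_fallback_site``
    is set.  A tag equal to (A)10 is returned with ``noninformative`` set;
    such tags are uninformative because they also arise from poly-A tails.

    Raises
    ------
    NoSiteError
        If the sequence carries no recognition site at all.
    InsufficientDownstreamError
        If no site has a full clean tag downstream.
    """
    seq = sequence.upper()
    sites = find_sites(seq, enzyme)
    if not sites:
        raise NoSiteError(f"no {enzyme.name} site ({enzyme.recognition_site}) found")
    k = enzyme.tag_length
    fallback = False
    for pos in reversed(sites):
        tag = seq[pos + 4 : pos + 4 + k]
        if len(tag) == k and "N" not in tag:
            flags = {"from_fallback_site": fallback, "noninformative": tag == POLY_A_TAG}
            return tag, flags
        fallback = True
    raise InsufficientDownstreamError(
        f"no {enzyme.name} site with >= {k} clean downstream nucleotides"
    )


def annotate_panel(
    sequences: Mapping[str, str],
    enzyme: AnchoringEnzyme = NLAIII,
    expected_tags: Mapping[str, str] | None = None,
) -> tuple[GeneTagCatalogue, AnnotationReport]:
    """Annotate every gene in ``sequences`` with its SAGE tag.

    Genes whose sequence has no recognition site (or no usable one) are
    excluded from the catalogue and listed in the report, mirroring how a
    site-less gene drops out of a virtual-tag panel.  When ``expected_tags``
    is given, extracted tags that disagree are listed in ``mismatch_genes``;
    the extracted tag is kept, never overridden.
    """
    records: list[GeneTagRecord] = []
    report = AnnotationReport()
    seen: set[str] = set()
    for gene, seq in sequences.items():
        if gene in seen:
            raise ValueError(f"duplicate gene symbol: {gene}")
        seen.add(gene)
        try:
            tag, flags = extract_tag(seq, enzyme)
        except (NoSiteError, InsufficientDownstreamError):
            report.no_site_genes.append(gene)
            continue
        if flags["noninformative"]:
            # an (A)10 tag cannot identify the gene in a catalogue
            report.no_site_genes.append(gene)
            continue
        if expected_tags is not None and gene in expected_tags:
            if expected_tags[gene] != tag:
                report.mismatch_genes.append(gene)
        records.append(
            GeneTagRecord(
                gene_symbol=gene,
                tag=tag,
                replaced_unreliable=flags["from_fallback_site"],
            )
        )
    return GeneTagCatalogue(records, enzyme=enzyme), report


def _record_from_row(row: Mapping[str, str], line_no: int) -> GeneTagRecord:
    flags = {f.strip() for f in row.get("flags", "").split(",") if f.strip()}
    bad = flags - set(_FLAG_NAMES)
    if bad:
        raise ValueError(f"row {line_no}: unknown flags {sorted(bad)}")
    try:
        return GeneTagRecord(
            gene_symbol=row["gene_symbol"],
            gene_name=row.get("gene_name", ""),
            aliases=row.get("aliases", ""),
            location=row.get("location", ""),
            status=row["status"],
            expressed_allele=row.get("expressed_allele", "Unknown"),
            tag=row["tag"],
            multi_mapping="multi" in flags,
            repetitive="repetitive" in flags,
            replaced_unreliable="replaced" in flags,
            accession=row.get("accession", ""),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"row {line_no}: {exc}") from exc


_CATALOGUE_COLUMNS = (
    "gene_symbol",
    "gene_name",
    "aliases",
    "location",
    "status",
    "expressed_allele",
    "tag",
    "flags",
    "accession",
)


def read_catalogue_tsv(path, enzyme: AnchoringEnzyme = NLAIII) -> GeneTagCatalogue:
    """Read a gene->tag catalogue from the 9-column TSV layout."""
    records: list[GeneTagRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_CATALOGUE_COLUMNS):
            raise ValueError(f"bad catalogue header: {header}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            values = line.rstrip("\n").split("\t")
            if len(values) != len(_CATALOGUE_COLUMNS):
                raise ValueError(
                    f"row {line_no}: expected {len(_CATALOGUE_COLUMNS)} columns, "
                    f"got {len(values)}"
                )
            records.append(_record_from_row(dict(zip(_CATALOGUE_COLUMNS, values)), line_no))
    return GeneTagCatalogue(records, enzyme=enzyme)


def write_catalogue_tsv(catalogue: GeneTagCatalogue, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CATALOGUE_COLUMNS) + "\n")
        for r in catalogue:
            fh.write(
                "\t".join(
                    [
                        r.gene_symbol,
                        r.gene_name,
                        r.aliases,
                        r.location,
                        r.status,
                        r.expressed_allele,
                        r.tag,
                        r.flags,
                        r.accession,
                    ]
                )
                + "\n"
            )


def load_panel_fixture() -> GeneTagCatalogue:
    """Load the packaged 173-gene imprinted/candidate panel (NlaIII tags).

    The panel covers 53 established imprinted genes and 120 high-confidence
    candidates, each annotated with its 10-nt NlaIII virtual SAGE tag.
    """
    ref = resources.files("sageprev.data").joinpath("imprinted_panel_nlaiii.tsv")
    with resources.as_file(ref) as path:
        catalogue = read_catalogue_tsv(path, enzyme=NLAIII)
    shared = catalogue.shared_tags()
    if shared:
        warnings.warn(f"panel tags shared by multiple genes: {shared}", stacklevel=2)
    return catalogue


def read_fasta_panel(path) -> dict[str, str]:
    """Read a multi-FASTA of transcript sequences keyed by record id (gene symbol)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate gene symbol in FASTA: {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences
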