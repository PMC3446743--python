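"""Synthetic SAGE cohorts with the statistical structure the pipeline assumes.

The generator emulates what a real tag-count download looks like to the
pipeline: heavy-tailed background tag abundances (Zipf by default), library
depths spanning ~2x10^4 to a few 10^5 tags, a noninformative (A)10
contamination fraction, exact-copy duplicate entries under fresh
accessions, libraries planted to violate each selection criterion, and a
controllable cumulative panel fraction per library — the imprinted-gene
share of the transcriptome, spanning roughly 0.0008 to 0.045 in observed
cohorts.  Every draw derives from a single seed, so a cohort is exactly
reproducible, and the ground truth (realized fractions, duplicate pairs,
planted exclusions) is returned alongside the data for parameter-recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .library_selection import CLUSTER_CODES, LibraryMetadata
from .sage_io import POLY_A_TAG, SageCatalogue
from .tag_annotation import NLAIII, AnchoringEnzyme, GeneTagCatalogue

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings.

    ``panel_fraction`` is the target share of each library's informative
    tags carried by the panel, either a scalar or a per-cluster map.
    ``dirichlet_alpha`` controls single-gene dominance of the panel signal:
    small values concentrate the panel's expression in one gene (the
    PTPN14-like regime), large values spread it evenly.
    """

    n_libraries: int = 50
    library_size_range: tuple[int, int] = (20_000, 400_000)
    background_tag_pool: int = 5_000
    abundance_model: str = "zipf"
    abundance_shape: float = 1.1
    panel_fraction: float | Mapping[str, float] = 0.01
    dirichlet_alpha: float = 1.0
    polyA_fraction: float = 0.0
    duplicate_rate: float = 0.0
    cluster_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.4, "N": 0.35, "IV": 0.2, "D": 0.05}
    )
    n_altered: int = 0
    n_undersized: int = 0
    n_incomplete: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError("library_size_range must satisfy 1 <= min <= max")
        if not 0 <= self.polyA_fraction < 1:
            raise ValueError("polyA_fraction must be in [0, 1)")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        fracs = (
            self.panel_fraction.values()
            if isinstance(self.panel_fraction, Mapping)
            else [self.panel_fraction]
        )
        if any(not 0 <= f < 1 for f in fracs):
            raise ValueError("panel fractions must be in [0, 1)")
        if self.abundance_model not in ("zipf", "lognormal"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        total = sum(self.cluster_proportions.get(c, 0.0) for c in CLUSTER_CODES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")


@dataclass
class SimTruth:
    """Ground truth recorded while generating a cohort."""

    panel_fraction_target: dict[str, float]
    panel_fraction_realized: dict[str, float]
    gene_tpm: dict[str, dict[str, float]]  # accession -> gene -> true tpm
    duplicate_pairs: list[tuple[str, str]]  # (original, copy)
    planted_exclusions: dict[str, str]  # accession -> criterion code

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "panel_fraction_target": self.panel_fraction_target,
                    "panel_fraction_realized": self.panel_fraction_realized,
                    "gene_tpm": self.gene_tpm,
                    "duplicate_pairs": self.duplicate_pairs,
                    "planted_exclusions": self.planted_exclusions,
                },
                fh,
                indent=1,
            )


def _random_tags(rng: np.random.Generator, n: int, exclude: set[str]) -> list[str]:
    """n distinct random 10-mers avoiding ``exclude`` and the poly-A tag."""
    out: list[str] = []
    seen = set(exclude) | {POLY_A_TAG}
    while len(out) < n:
        block = rng.integers(0, 4, size=(max(n - len(out), 16), 10))
        for row in block:
            tag = "".join(_BASES[row])
            if tag not in seen:
                seen.add(tag)
                out.append(tag)
                if len(out) == n:
                    break
    return out


def _background_weights(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    m = config.background_tag_pool
    if config.abundance_model == "zipf":
        w = np.arange(1, m + 1, dtype=float) ** (-config.abundance_shape)
    else:
        w = np.exp(rng.normal(0.0, config.abundance_shape, size=m))
    return w / w.sum()


def simulate_cohort(
    config: SimConfig, panel: GeneTagCatalogue
) -> tuple[list[SageCatalogue], dict[str, LibraryMetadata], SimTruth]:
    """Generate a reproducible cohort of raw SAGE catalogues plus metadata.

    Each library draws its depth uniformly from the configured range,
    allocates a binomial share of informative tags to the panel at the
    library's target fraction (split over genes by a Dirichlet draw), fills
    the rest from the heavy-tailed background pool, and injects (A)10
    contamination.  Duplicates are exact copies under new accessions;
    planted selection violators are flagged in metadata (criteria i/iii) or
    drawn undersized (criterion ii).
    """
    rng = np.random.default_rng(config.seed)
    panel_tags = list(panel.tags().values())
    panel_genes = list(panel.tags().keys())
    background = _random_tags(rng, config.background_tag_pool, set(panel_tags))
    bg_weights = _background_weights(config, rng)

    clusters = list(CLUSTER_CODES)
    cluster_p = np.array([config.cluster_proportions.get(c, 0.0) for c in clusters])

    n_planted = config.n_altered + config.n_undersized + config.n_incomplete
    if n_planted > config.n_libraries:
        raise ValueError("more planted violators than libraries")

    catalogues: list[SageCatalogue] = []
    metadata: dict[str, LibraryMetadata] = {}
    truth = SimTruth({}, {}, {}, [], {})

    lo, hi = config.library_size_range
    for idx in range(config.n_libraries):
        acc = f"SIM{idx:04d}"
        cluster = clusters[int(rng.choice(len(clusters), p=cluster_p))]
        violation = None
        if idx < config.n_altered:
            violation = "i"
        elif idx < config.n_altered + config.n_undersized:
            violation = "ii"
        elif idx < n_planted:
            violation = "iii"

        if violation == "ii":
            size = int(rng.integers(1_000, max(lo - 1, 1_001)))
        else:
            size = int(rng.integers(lo, hi + 1))

        n_polya = int(rng.binomial(size, config.polyA_fraction))
        n_informative = size - n_polya
        if isinstance(config.panel_fraction, Mapping):
            target = float(config.panel_fraction.get(cluster, 0.0))
        else:
            target = float(config.panel_fraction)
        n_panel = int(rng.binomial(n_informative, target))
        n_background = n_informative - n_panel

        gene_share = rng.dirichlet(
            np.full(len(panel_genes), config.dirichlet_alpha)
        )
        gene_counts = rng.multinomial(n_panel, gene_share)
        bg_counts = rng.multinomial(n_background, bg_weights)

        counts: dict[str, int] = {}
        for tag, c in zip(panel_tags, gene_counts):
            if c:
                counts[tag] = counts.get(tag, 0) + int(c)
        for tag, c in zip(background, bg_counts):
            if c:
                counts[tag] = counts.get(tag, 0) + int(c)
        if n_polya:
            counts[POLY_A_TAG] = n_polya

        catalogues.append(SageCatalogue(accession=acc, counts=counts))
        metadata[acc] = LibraryMetadata(
            accession=acc,
            description=f"synthetic library {idx}",
            cluster=cluster,
            genetically_altered=violation == "i",
            complete_dataset=violation != "iii",
        )
        truth.panel_fraction_target[acc] = target
        truth.panel_fraction_realized[acc] = (
            n_panel / n_informative if n_informative else 0.0
        )
        truth.gene_tpm[acc] = {
            g: c / n_informative * 1e6 if n_informative else 0.0
            for g, c in zip(panel_genes, gene_counts)
            if c
        }
        if violation:
            truth.planted_exclusions[acc] = violation

    # exact-copy duplicates under fresh accessions
    n_dup = int(round(config.duplicate_rate * config.n_libraries))
    if n_dup:
        originals = rng.choice(config.n_libraries, size=n_dup, replace=False)
        for j, orig_idx in enumerate(sorted(int(i) for i in originals)):
            orig = catalogues[orig_idx]
            acc = f"SIMDUP{j:04d}"
            catalogues.append(
                SageCatalogue(accession=acc, counts=dict(orig.counts))
            )
            src_meta = metadata[orig.accession]
            metadata[acc] = LibraryMetadata(
                accession=acc,
                description=src_meta.description + " (duplicate entry)",
                cluster=src_meta.cluster,
                genetically_altered=src_meta.genetically_altered,
                complete_dataset=src_meta.complete_dataset,
            )
            truth.duplicate_pairs.append((orig.accession, acc))

    return catalogues, metadata, truth


def _sequence_without_site(
    rng: np.random.Generator, length: int, site: str
) -> str:
    seq = list("".join(_BASES[rng.integers(0, 4, size=length)]))
    text = "".join(seq)
    while site in text:
        pos = text.index(site)
        # mutate one base inside the occurrence to break it
        current = text[pos]
        choices = [b for b in "ACGT" if b != current]
        seq[pos] = choices[int(rng.integers(0, 3))]
        text = "".join(seq)
    return text


def simulate_panel_sequences(
    panel: GeneTagCatalogue,
    enzyme: AnchoringEnzyme = NLAIII,
    seed: int = 0,
    background_length: int = 400,
    no_site_genes: tuple[str, ...] = (),
) -> dict[str, str]:
    """Transcript-like sequences whose 3'-most usable site yields each
    gene's tag, so tag extraction inverts the construction exactly.

    Each sequence is a random background followed by the recognition site
    and the gene's tag, ending at the tag (any site inside the tag lacks a
    full downstream tag and cannot be chosen).  Genes listed in
    ``no_site_genes`` instead get a sequence free of the recognition site,
    emulating a transcript that cannot be tag-annotated at all.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    for rec in panel:
        if rec.gene_symbol in no_site_genes:
            sequences[rec.gene_symbol] = _sequence_without_site(
                rng, background_length, enzyme.recognition_site
            )
            continue
        bg = "".join(_BASES[rng.integers(0, 4, size=background_length)])
        sequences[rec.gene_symbol] = bg + enzyme.recognition_site + rec.tag
    return sequences
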