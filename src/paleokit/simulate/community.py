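"""Simulate a KrakenUniq-style classification report from a mixed community.

Reads are allocated multinomially to species with probability proportional to
``source_weight(category) × within-category relative abundance``.  Unique
k-mer counts and the report's coverage column are generated with the geometry
that separates genuine from spurious assignments: genuine taxa scatter their
reads along the genome (many distinct k-mers, local fold coverage near 1),
while spurious taxa stack reads on a short locus (≤2 new k-mers per read,
high local fold coverage).  The report's ``cov`` column is the local fold
coverage of the covered region, so the k-mer dispersion statistic
``(kmers/reads)/cov`` is high for genuine hits and low for spurious ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import substream
from ..records import TaxonRecord

__all__ = ["SpeciesSpec", "CommunityProfile", "CommunityTruth", "simulate_taxon_report"]

_KMER = 31  # k-mer size assumed for distinct-k-mer capacity


@dataclass
class SpeciesSpec:
    name: str
    taxid: int
    genome_size: int
    abundance: float  # relative within its source category
    spurious: bool = False  # if True, hits concentrate on one short locus


@dataclass
class CommunityProfile:
    source_weights: dict  # category -> proportion, summing to 1
    species_pools: dict  # category -> list[SpeciesSpec]
    library_size: int = 100_000
    read_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.source_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"source_weights must sum to 1 (got {total})")
        if not self.species_pools or all(not v for v in self.species_pools.values()):
            raise ValueError("species_pools must contain at least one species")
        for cat, pool in self.species_pools.items():
            for sp in pool:
                if sp.abundance < 0:
                    raise ValueError(f"negative abundance for {sp.name}")
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")


@dataclass
class CommunityTruth:
    """Ground truth for one simulated report."""

    category_of: dict  # taxid -> source category
    spurious: set  # taxids flagged spurious
    reads_per_category: dict  # category -> realised read total
    reads_per_taxid: dict


def simulate_taxon_report(community: CommunityProfile):
    """Return ``(records, truth)``: TaxonRecord rows plus generation truth."""
    rng = substream(community.seed, "taxon-report")
    species: list = []
    probs: list = []
    for cat, pool in community.species_pools.items():
        w = community.source_weights.get(cat, 0.0)
        pool_total = sum(sp.abundance for sp in pool)
        for sp in pool:
            species.append((cat, sp))
            probs.append(w * sp.abundance / pool_total if pool_total > 0 else 0.0)
    probs = np.asarray(probs)
    if probs.sum() <= 0:
        raise ValueError("all species have zero sampling probability")
    probs = probs / probs.sum()

    counts = (
        rng.multinomial(community.library_size, probs)
        if community.library_size > 0
        else np.zeros(len(probs), dtype=int)
    )

    L = community.read_length
    records: list = []
    truth = CommunityTruth(category_of={}, spurious=set(), reads_per_category={}, reads_per_taxid={})
    for (cat, sp), n_reads in zip(species, counts):
        truth.category_of[sp.taxid] = cat
        if sp.spurious:
            truth.spurious.add(sp.taxid)
        truth.reads_per_category[cat] = truth.reads_per_category.get(cat, 0) + int(n_reads)
        truth.reads_per_taxid[sp.taxid] = int(n_reads)
        if n_reads == 0:
            continue
        capacity = max(sp.genome_size - _KMER + 1, 1)
        if sp.spurious:
            # reads pile on one short locus: few distinct k-mers, deep local coverage
            locus = int(rng.integers(L, 3 * L))
            covered = min(locus + _KMER, sp.genome_size)
            kmers = int(min(2 * n_reads, max(locus - _KMER + 1, 1)))
        else:
            # reads scattered along the genome; distinct coverage saturates
            covered = int(round(capacity * (1.0 - np.exp(-n_reads * L / capacity))))
            covered = max(covered, L)
            kmers = max(covered - _KMER + 1, 1)
        cov = n_reads * L / covered  # local fold coverage of the covered region
        # mild multiplicative jitter so integer fields are not exactly deterministic
        kmers = max(1, int(round(kmers * rng.lognormal(0.0, 0.05))))
        cov = float(cov * rng.lognormal(0.0, 0.05))
        dup = n_reads * L / max(kmers, 1)
        records.append(
            TaxonRecord(
                taxid=sp.taxid,
                name=sp.name,
                rank="species",
                reads=int(n_reads),
                tax_reads=int(n_reads),
                kmers=kmers,
                coverage=round(cov, 6),
                pct=round(100.0 * n_reads / community.library_size, 4)
                if community.library_size
                else 0.0,
                dup=round(dup, 3),
            )
        )
    return records, truth


def default_species_pools(spurious_fraction: float = 0.0, seed: int = 0) -> dict:
    """A small realistic source panel: oral, gut, skin and soil species pools.

    ``spurious_fraction`` of each pool (rounded down) is flagged spurious to
    exercise dispersion-based filtering.
    """
    rng = substream(seed, "species-pools")
    pools = {
        "oral": [
            ("Anaerolineaceae bacterium oral taxon 439", 1889813, 2_042_000),
            ("Olsenella sp. oral taxon 807", 712411, 2_070_000),
            ("Desulfomicrobium orale", 132132, 2_670_000),
            ("Actinomyces sp. oral taxon 414", 712122, 3_100_000),
            ("Tannerella forsythia", 28112, 3_405_000),
            ("Porphyromonas gingivalis", 837, 2_354_000),
            ("Streptococcus sanguinis", 1305, 2_388_000),
            ("Fretibacterium fastidiosum", 651822, 2_501_000),
        ],
        "gut": [
            ("Bacteroides fragilis", 817, 5_205_000),
            ("Faecalibacterium prausnitzii", 853, 3_090_000),
            ("Escherichia coli", 562, 4_641_000),
        ],
        "skin": [
            ("Cutibacterium acnes", 1747, 2_560_000),
            ("Staphylococcus epidermidis", 1282, 2_499_000),
        ],
        "soil": [
            ("Bradyrhizobium japonicum", 375, 9_105_000),
            ("Streptomyces coelicolor", 1902, 8_667_000),
            ("Mycobacterium smegmatis", 1772, 6_988_000),
            ("Pseudomonas fluorescens", 294, 6_438_000),
        ],
    }
    out = {}
    for cat, entries in pools.items():
        n_spur = int(len(entries) * spurious_fraction)
        spur_idx = set(rng.choice(len(entries), size=n_spur, replace=False).tolist())
        out[cat] = [
            SpeciesSpec(
                name=name,
                taxid=taxid,
                genome_size=gsize,
                abundance=float(rng.lognormal(0.0, 1.0)),
                spurious=i in spur_idx,
            )
            for i, (name, taxid, gsize) in enumerate(entries)
        ]
    return out
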