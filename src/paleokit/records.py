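"""Core record types shared across the pipeline.

These are deliberately small frozen-ish dataclasses: one classification-report
row, one variant-call record, one peptide identification, plus the two matrix
containers (merged variant-site table and SNP alignment) that the panel
builder produces.  Coordinates are 1-based inclusive throughout, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TaxonRecord",
    "SampleCall",
    "VariantCallRecord",
    "VariantSiteTable",
    "SnpAlignment",
    "DamageProfile",
    "PeptideRecord",
    "AlignedRead",
]

MISSING = None  # convention: absent FORMAT fields surface as None, never 0


@dataclass
class TaxonRecord:
    """One row of a KrakenUniq-style classification report.

    ``escore`` is derived (k-mer dispersion statistic), unset until computed.
    """

    taxid: int
    name: str
    rank: str
    reads: int
    tax_reads: int
    kmers: int
    coverage: float
    pct: float = 0.0
    dup: float = 0.0
    escore: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reads < self.tax_reads or self.tax_reads < 0:
            raise ValueError(
                f"taxon {self.name!r}: need reads >= tax_reads >= 0 "
                f"(reads={self.reads}, tax_reads={self.tax_reads})"
            )
        if self.kmers < 0 or self.coverage < 0:
            raise ValueError(f"taxon {self.name!r}: negative kmers/coverage")


@dataclass
class SampleCall:
    """Per-sample genotype fields at one site; None means the field is absent."""

    gt: Optional[tuple] = None  # allele indices, e.g. (0, 0); None = missing ./.
    dp: Optional[int] = None
    ad: Optional[tuple] = None  # depth per allele, length 1 + n_alts
    gq: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.gt is None or any(a is None for a in self.gt)


@dataclass
class VariantCallRecord:
    """One VCF data line: site coordinates, alleles, and per-sample calls."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple
    calls: dict = field(default_factory=dict)  # sample_id -> SampleCall

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.contig}:{self.pos}: VCF positions are 1-based")
        n_alleles = 1 + len(self.alts)
        for sid, c in self.calls.items():
            if c.ad is not None and len(c.ad) != n_alleles:
                raise ValueError(
                    f"{self.contig}:{self.pos} sample {sid}: AD length "
                    f"{len(c.ad)} != allele count {n_alleles}"
                )
            if c.gt is not None:
                for a in c.gt:
                    if a is not None and a >= n_alleles:
                        raise ValueError(
                            f"{self.contig}:{self.pos} sample {sid}: GT index {a} "
                            f">= allele count {n_alleles}"
                        )

    @property
    def alleles(self) -> tuple:
        return (self.ref,) + tuple(self.alts)

    def is_indel(self) -> bool:
        return any(len(a) != 1 for a in self.alleles)


@dataclass
class VariantSiteTable:
    """Merged site x sample genotype calls (union of per-sample VCFs).

    ``sites`` is a list of VariantCallRecord sorted by (contig, pos), each
    carrying calls for every sample in ``sample_ids`` (missing where a sample
    had no record).
    """

    sample_ids: list
    sites: list  # list[VariantCallRecord]

    def __post_init__(self) -> None:
        coords = [(s.contig, s.pos) for s in self.sites]
        if coords != sorted(coords):
            raise ValueError("sites must be sorted by (contig, pos)")
        if len(set(coords)) != len(coords):
            raise ValueError("duplicate (contig, pos) in site table")


@dataclass
class SnpAlignment:
    """Variant-column multi-sequence alignment over the {A,C,G,T,N} alphabet."""

    sample_ids: list
    site_coords: list  # list[(contig, pos)]
    matrix: np.ndarray  # shape (n_samples, n_sites), dtype '<U1'

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.shape != (len(self.sample_ids), len(self.site_coords)):
            raise ValueError(
                f"alignment shape {self.matrix.shape} != "
                f"({len(self.sample_ids)}, {len(self.site_coords)})"
            )
        bad = set(self.matrix.ravel().tolist()) - set("ACGTN")
        if bad:
            raise ValueError(f"alignment contains non-ACGTN symbols: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_coords)

    def row(self, sample_id: str) -> str:
        return "".join(self.matrix[self.sample_ids.index(sample_id)])


@dataclass
class DamageProfile:
    """Terminal substitution frequencies: C->T from the 5' end, G->A from the 3' end.

    Frequencies are defined only where the per-offset denominator (count of
    eligible reference bases) is positive; elsewhere they are NaN.
    """

    n_positions: int
    ct_5prime_num: np.ndarray  # C->T observations at 5' offset i
    ct_5prime_den: np.ndarray  # reference-C count at 5' offset i
    ga_3prime_num: np.ndarray
    ga_3prime_den: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.ct_5prime_num, self.ct_5prime_den, self.ga_3prime_num, self.ga_3prime_den):
            if len(arr) != self.n_positions:
                raise ValueError("profile arrays must have length n_positions")
        if np.any(self.ct_5prime_num > self.ct_5prime_den) or np.any(
            self.ga_3prime_num > self.ga_3prime_den
        ):
            raise ValueError("damage numerator exceeds denominator")

    @property
    def ct_5prime(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.ct_5prime_den > 0, self.ct_5prime_num / self.ct_5prime_den, np.nan)

    @property
    def ga_3prime(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.ga_3prime_den > 0, self.ga_3prime_num / self.ga_3prime_den, np.nan)


@dataclass
class AlignedRead:
    """An ungapped read placed on a reference: 1-based start, full-match sequence."""

    read_id: str
    contig: str
    start: int  # 1-based, inclusive
    sequence: str
    mapq: int = 60

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + self.length - 1


# Recognised variable PTM types in peptide tables.
PTM_TYPES = (
    "deamidation-N",
    "deamidation-Q",
    "oxidation-M",
    "hydroxylation-P",
    "pyro-Glu",
    "carbamidomethyl-C",
)


@dataclass
class PeptideRecord:
    """One peptide-spectrum identification from a post-search results table."""

    sample_id: str
    sequence: str
    score: float  # lower = better for the primary engine
    psm_count: int
    modifications: list = field(default_factory=list)  # [(1-based position, type)]
    protein_accession: str = ""
    protein_name: str = ""
    taxon: str = ""
    is_blank_hit: bool = False

    def __post_init__(self) -> None:
        if self.psm_count < 1:
            raise ValueError(f"peptide {self.sequence!r}: psm_count must be >= 1")
        for pos, mtype in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"peptide {self.sequence!r}: modification position {pos} "
                    f"outside 1..{len(self.sequence)}"
                )
            if mtype not in PTM_TYPES:
                raise ValueError(f"unknown PTM type {mtype!r}")
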