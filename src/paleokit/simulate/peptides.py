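"""Simulate post-search peptide identification tables with deamidation.

Generates random tryptic-looking peptide sequences with amino acids at
vertebrate background frequencies, flags each asparagine/glutamine as
deamidated with a configurable rate, assigns origins (human, vertebrate,
bacteria, ...) from a mixture, and plants a known fraction of contaminant
records (blank-shared sequences and cRAP-style accessions), including human
collagen entries that the removal step must retain under its exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import substream
from ..records import PeptideRecord

__all__ = ["PeptideSimParams", "PeptideTruth", "simulate_peptide_table"]

# vertebrate background amino-acid frequencies (approximate, sum to 1)
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [
        0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
        0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

ORIGIN_CATEGORIES = (
    "human", "vertebrate", "bacteria", "plants", "fungi",
    "obligate intracellular", "amoeba", "insect",
)

_ORIGIN_TAXA = {
    "human": ["Homo sapiens"],
    "vertebrate": ["Bos taurus", "Ovis aries", "Sus scrofa"],
    "bacteria": [
        "Anaerolineaceae bacterium oral taxon 439",
        "Tannerella forsythia",
        "Streptomyces coelicolor",
    ],
    "plants": ["Triticum aestivum", "Hordeum vulgare"],
    "fungi": ["Aspergillus niger"],
    "obligate intracellular": ["Chlamydia trachomatis"],
    "amoeba": ["Entamoeba histolytica"],
    "insect": ["Drosophila melanogaster"],
}

# cRAP-style contaminant accessions planted by the generator
CONTAMINANT_ACCESSIONS = ("K1C9_HUMAN", "K2C1_HUMAN", "TRYP_PIG", "ALBU_BOVIN", "CAS1_BOVIN")
HUMAN_COLLAGEN_ACCESSIONS = ("CO1A1_HUMAN", "CO1A2_HUMAN")


@dataclass
class PeptideSimParams:
    n_peptides: int = 2000
    deamidation_rate: float = 0.25
    length_mean: float = 18.0
    length_sd: float = 5.0
    origin_mix: dict = field(
        default_factory=lambda: {"human": 0.2, "vertebrate": 0.5, "bacteria": 0.3}
    )
    contaminant_fraction: float = 0.1
    collagen_fraction: float = 0.15  # fraction of human-origin records that are collagen
    score_pass_fraction: float = 0.85  # records with score <= 0.01
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.deamidation_rate <= 1:
            raise ValueError("deamidation_rate must be in [0, 1]")
        if abs(sum(self.origin_mix.values()) - 1.0) > 1e-9:
            raise ValueError("origin_mix must sum to 1")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be in [0, 1]")
        unknown = set(self.origin_mix) - set(ORIGIN_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown origin categories: {sorted(unknown)}")


@dataclass
class PeptideTruth:
    origin_of: list  # per-record origin category
    is_contaminant: list  # per-record: planted as contaminant (blank or cRAP accession)
    contaminant_reason: list  # None | "blank" | "accession"
    is_human_collagen: list
    n_nq_residues: int
    n_deamidated: int


def simulate_peptide_table(params: PeptideSimParams):
    """Return ``(records, blank_records, contaminant_accessions, truth)``."""
    rng = substream(params.seed, "peptides")
    origins = list(params.origin_mix)
    origin_p = np.array([params.origin_mix[o] for o in origins])

    records: list = []
    blank_records: list = []
    truth = PeptideTruth([], [], [], [], 0, 0)
    for k in range(params.n_peptides):
        n = max(7, int(round(rng.normal(params.length_mean, params.length_sd))))
        seq = "".join(rng.choice(_AA, size=n, p=_AA_FREQ))
        mods = []
        for i, aa in enumerate(seq):
            if aa in "NQ":
                truth.n_nq_residues += 1
                if rng.random() < params.deamidation_rate:
                    mods.append((i + 1, f"deamidation-{aa}"))
                    truth.n_deamidated += 1
        origin = origins[int(rng.choice(len(origins), p=origin_p))]
        taxon = _ORIGIN_TAXA[origin][int(rng.integers(len(_ORIGIN_TAXA[origin])))]

        is_collagen = origin == "human" and rng.random() < params.collagen_fraction
        if is_collagen:
            acc = HUMAN_COLLAGEN_ACCESSIONS[int(rng.integers(2))]
            pname = "Collagen alpha-1(I) chain" if acc == "CO1A1_HUMAN" else "Collagen alpha-2(I) chain"
        else:
            acc = f"P{int(rng.integers(40)):04d}_{origin[:3].upper()}"
            pname = f"{origin} protein {acc}"

        if rng.random() < params.score_pass_fraction:
            score = float(rng.uniform(0.0, 0.01))
        else:
            score = float(rng.uniform(0.0101, 0.1))

        contaminant = rng.random() < params.contaminant_fraction
        reason = None
        if contaminant:
            if is_collagen or rng.random() < 0.5:
                # blank-shared sequence (collagen contaminants are planted this
                # way too, so the accession exception is genuinely exercised)
                reason = "blank"
            else:
                reason = "accession"
                acc = CONTAMINANT_ACCESSIONS[int(rng.integers(len(CONTAMINANT_ACCESSIONS)))]
                pname = f"contaminant {acc}"

        rec = PeptideRecord(
            sample_id=params.sample_id,
            sequence=seq,
            score=score,
            psm_count=1 + int(rng.poisson(1.0)),
            modifications=mods,
            protein_accession=acc,
            protein_name=pname,
            taxon=taxon,
        )
        records.append(rec)
        if reason == "blank":
            blank_records.append(
                PeptideRecord(
                    sample_id="BLANK",
                    sequence=seq,
                    score=float(rng.uniform(0.0, 0.01)),
                    psm_count=1,
                    protein_accession=acc,
                    protein_name=pname,
                    taxon=taxon,
                    is_blank_hit=True,
                )
            )
        truth.origin_of.append(origin)
        truth.is_contaminant.append(contaminant)
        truth.contaminant_reason.append(reason)
        truth.is_human_collagen.append(is_collagen)

    contaminant_accessions = set(CONTAMINANT_ACCESSIONS) | set(HUMAN_COLLAGEN_ACCESSIONS)
    return records, blank_records, contaminant_accessions, truth
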