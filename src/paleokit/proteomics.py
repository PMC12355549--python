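"""Post-search palaeoproteomic filtering and statistics.

Acceptance rules for peptide identifications (score cut, blank/cRAP
contaminant removal with a human-collagen exception, ≥2 unique peptides per
protein), deamidation and PTM quantification, origin classification and
Venn-region counting.  All filters are record-local predicates, so filtering
order never changes the result.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .errors import DataError, ParameterError
from .records import PeptideRecord

__all__ = [
    "ProteoFilterParams",
    "filter_peptides",
    "is_human_collagen",
    "remove_contaminants",
    "aggregate_protein_groups",
    "deamidation_stats",
    "classify_origins",
    "group_overlap_counts",
    "ORIGIN_CATEGORIES",
]

log = logging.getLogger(__name__)

ORIGIN_CATEGORIES = (
    "human", "vertebrate", "bacteria", "plants", "fungi",
    "obligate intracellular", "amoeba", "insect",
)

_HUMAN_TAXA = {"homo sapiens", "human"}


@dataclass
class ProteoFilterParams:
    max_peptide_score: float = 0.01  # lower score = better identification
    min_psms_per_protein: int = 2  # distinct peptide sequences per protein
    keep_human_collagen: bool = True
    collagen_name_tokens: tuple = ("collagen",)

    def __post_init__(self) -> None:
        if self.max_peptide_score <= 0:
            raise ParameterError("max_peptide_score must be > 0")
        if self.min_psms_per_protein < 1:
            raise ParameterError("min_psms_per_protein must be >= 1")


def filter_peptides(records, params: ProteoFilterParams = None) -> list:
    """Keep records with score ≤ max_peptide_score (inclusive), order preserved."""
    params = params or ProteoFilterParams()
    return [r for r in records if r.score <= params.max_peptide_score]


def is_human_collagen(record: PeptideRecord, params: ProteoFilterParams) -> bool:
    """A collagen-chain protein of human origin (the removal exception)."""
    name = record.protein_name.lower()
    return record.taxon.lower() in _HUMAN_TAXA and any(
        tok in name for tok in params.collagen_name_tokens
    )


def remove_contaminants(records, blank_records, contaminant_accessions,
                        params: ProteoFilterParams = None):
    """Drop blank-shared sequences and contaminant-database accessions.

    A record is dropped if its peptide sequence occurs in the extraction
    blank OR its protein accession is in the contaminant list — unless
    ``keep_human_collagen`` and the record is a human collagen chain.
    Returns ``(kept, drop_log)`` where drop_log counts drops by reason.
    """
    params = params or ProteoFilterParams()
    blank_seqs = {b.sequence for b in blank_records}
    contaminant_accessions = set(contaminant_accessions)
    kept, drop_log = [], Counter()
    for r in records:
        in_blank = r.sequence in blank_seqs
        in_crap = r.protein_accession in contaminant_accessions
        if (in_blank or in_crap) and not (
            params.keep_human_collagen and is_human_collagen(r, params)
        ):
            drop_log["blank_sequence" if in_blank else "contaminant_accession"] += 1
            continue
        kept.append(r)
    if drop_log:
        log.info("remove_contaminants: dropped %s", dict(drop_log))
    return kept, drop_log


def aggregate_protein_groups(records, params: ProteoFilterParams = None) -> dict:
    """Group by protein accession; keep groups with enough unique peptides.

    Support is counted as distinct peptide sequences (the bare amino-acid
    string); raw PSM totals are tallied alongside.  Returns
    ``{accession: {"protein_name", "unique_peptides", "total_psms", "records"}}``.
    """
    params = params or ProteoFilterParams()
    groups: dict = defaultdict(list)
    for r in records:
        groups[r.protein_accession].append(r)
    out = {}
    for acc, recs in groups.items():
        unique_seqs = {r.sequence for r in recs}
        if len(unique_seqs) < params.min_psms_per_protein:
            continue
        out[acc] = {
            "protein_name": recs[0].protein_name,
            "unique_peptides": len(unique_seqs),
            "total_psms": sum(r.psm_count for r in recs),
            "records": recs,
        }
    return out


def deamidation_stats(records) -> dict:
    """Per-sample N/Q deamidation fraction, PTM proportion, length histogram.

    deamidation fraction = deamidated N/Q residues / all N/Q residues;
    PTM proportion = all modification annotations / all amino acids.  A
    sample with no N/Q residues reports NaN for the fraction.
    """
    per_sample: dict = defaultdict(lambda: {"nq": 0, "deam": 0, "ptm": 0, "aa": 0,
                                            "lengths": Counter()})
    for r in records:
        s = per_sample[r.sample_id]
        s["nq"] += sum(1 for aa in r.sequence if aa in "NQ")
        s["deam"] += sum(1 for _, t in r.modifications if t.startswith("deamidation"))
        s["ptm"] += len(r.modifications)
        s["aa"] += len(r.sequence)
        s["lengths"][len(r.sequence)] += 1
    out = {}
    for sid, s in per_sample.items():
        out[sid] = {
            "n_peptides": sum(s["lengths"].values()),
            "nq_residues": s["nq"],
            "deamidation_fraction": s["deam"] / s["nq"] if s["nq"] else float("nan"),
            "ptm_proportion": s["ptm"] / s["aa"] if s["aa"] else float("nan"),
            "length_histogram": dict(sorted(s["lengths"].items())),
            "mean_length": float(np.mean([l for l, c in s["lengths"].items() for _ in range(c)]))
            if s["aa"] else float("nan"),
        }
    return out


def classify_origins(records, taxonomy: dict, oral_species=()) -> dict:
    """Per-sample origin-category counts and proportions.

    ``taxonomy`` maps taxon name → origin category; unmapped taxa land in
    ``"unclassified"`` (never dropped).  Bacterial peptides are additionally
    split oral / non-oral against ``oral_species``.
    """
    for taxon, cat in taxonomy.items():
        if cat not in ORIGIN_CATEGORIES:
            raise ParameterError(f"taxon {taxon!r}: unknown origin category {cat!r}")
    oral = set(oral_species)
    out: dict = {}
    for r in records:
        s = out.setdefault(
            r.sample_id,
            {"counts": Counter(), "oral_bacteria": 0, "nonoral_bacteria": 0},
        )
        cat = taxonomy.get(r.taxon, "unclassified")
        s["counts"][cat] += 1
        if cat == "bacteria":
            if r.taxon in oral:
                s["oral_bacteria"] += 1
            else:
                s["nonoral_bacteria"] += 1
    for s in out.values():
        total = sum(s["counts"].values())
        s["proportions"] = {c: n / total for c, n in s["counts"].items()}
        s["counts"] = dict(s["counts"])
    return out


def group_overlap_counts(sets: dict) -> dict:
    """Cardinality of every Venn region for 2–4 labelled sets.

    Keys are tuples of the labels whose exclusive intersection the region is;
    region sizes partition the union.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 4:
        raise ParameterError(f"group_overlap_counts supports 2-4 groups, got {len(labels)}")
    sets = {k: set(v) for k, v in sets.items()}
    regions = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            regions[combo] = len(inside - outside)
    return regions
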