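"""Taxonomic-report filtering and compositional community analysis.

The E-score is a per-taxon authenticity statistic: unique k-mers per read
relative to the genome coverage reported for the taxon.  Hits spread along a
reference accumulate many distinct k-mers at low local coverage (high E);
spurious hits stack reads on one locus (low E).  Reports are filtered on
E-score and read count, curated against reference source panels for source
tracking, rarefied, CLR-transformed and embedded with PCA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import as_generator
from .errors import DataError, ParameterError
from .records import TaxonRecord

__all__ = [
    "EscoreParams",
    "SourceCurationParams",
    "AbundanceMatrix",
    "ESCORE_STRATEGIES",
    "compute_escore",
    "filter_taxa",
    "records_to_matrix",
    "curate_for_sourcetracking",
    "rarefy_counts",
    "rarefy_matrix",
    "clr_transform",
    "pca_embed",
    "build_oral_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class EscoreParams:
    min_escore: float = 7.0
    min_reads: int = 10
    strategy: str = "kmers_per_read_over_cov"

    def __post_init__(self) -> None:
        if self.min_escore < 0 or self.min_reads < 0:
            raise ParameterError("EscoreParams thresholds must be >= 0")


@dataclass
class SourceCurationParams:
    min_ref_reads: int = 200
    min_target_reads: int = 50
    min_global_abundance: float = 0.0002  # 0.02% of the merged dataset
    rarefaction_depth: int = 100

    def __post_init__(self) -> None:
        if min(self.min_ref_reads, self.min_target_reads, self.rarefaction_depth) < 0:
            raise ParameterError("SourceCurationParams counts must be >= 0")
        if self.min_global_abundance < 0:
            raise ParameterError("min_global_abundance must be >= 0")


# E-score strategies: the prose definition ("proportion of kmers by read per
# genome coverage") is read literally as (kmers/reads)/cov; alternatives plug
# in here by name.
ESCORE_STRATEGIES = {
    "kmers_per_read_over_cov": lambda r: (r.kmers / r.reads) / r.coverage,
    "log_kmers_per_read_over_cov": lambda r: math.log10(1 + (r.kmers / r.reads) / r.coverage),
}


def compute_escore(record: TaxonRecord, strategy: str = "kmers_per_read_over_cov") -> float:
    """k-mer dispersion score; higher ⇒ hits spread further along the genome."""
    if record.reads <= 0 or record.coverage <= 0:
        raise DataError(
            f"taxon {record.name!r}: E-score undefined (reads={record.reads}, "
            f"cov={record.coverage})"
        )
    if record.kmers == 0:
        return 0.0
    return float(ESCORE_STRATEGIES[strategy](record))


def filter_taxa(records, params: EscoreParams = None) -> list:
    """Keep records with E-score ≥ min_escore and reads ≥ min_reads, in order.

    Records whose E-score is undefined (zero reads or coverage) are excluded
    and logged.
    """
    params = params or EscoreParams()
    kept = []
    n_undefined = 0
    for r in records:
        try:
            e = compute_escore(r, params.strategy) if r.escore is None else r.escore
        except DataError:
            n_undefined += 1
            continue
        r.escore = e
        if e >= params.min_escore and r.reads >= params.min_reads:
            kept.append(r)
    if n_undefined:
        log.info("filter_taxa: %d record(s) with undefined E-score excluded", n_undefined)
    return kept


@dataclass
class AbundanceMatrix:
    """Samples × species count matrix with aligned id lists."""

    sample_ids: list
    species: list  # list[(name, taxid)]
    counts: np.ndarray  # shape (n_samples, n_species), non-negative ints
    sample_labels: Optional[list] = None  # source category per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.species)):
            raise ParameterError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.sample_ids)}, {len(self.species)})"
            )
        if np.any(self.counts < 0):
            raise ParameterError("negative counts in abundance matrix")

    @property
    def taxids(self) -> list:
        return [t for _, t in self.species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=[n for n, _ in self.species]
        )


def records_to_matrix(per_sample_records: dict, sample_labels: Optional[dict] = None) -> AbundanceMatrix:
    """Stack per-sample TaxonRecord lists into one matrix keyed by taxid."""
    sample_ids = list(per_sample_records)
    species_seen: dict = {}
    for recs in per_sample_records.values():
        for r in recs:
            species_seen.setdefault(r.taxid, r.name)
    species = sorted(species_seen.items())  # by taxid, deterministic
    index = {taxid: j for j, (taxid, _) in enumerate(species)}
    counts = np.zeros((len(sample_ids), len(species)), dtype=int)
    for i, sid in enumerate(sample_ids):
        for r in per_sample_records[sid]:
            counts[i, index[r.taxid]] += r.reads
    return AbundanceMatrix(
        sample_ids=sample_ids,
        species=[(name, taxid) for taxid, name in species],
        counts=counts,
        sample_labels=[sample_labels.get(s) for s in sample_ids] if sample_labels else None,
    )


def curate_for_sourcetracking(
    target: AbundanceMatrix,
    references: AbundanceMatrix,
    params: SourceCurationParams = None,
) -> AbundanceMatrix:
    """Merge one target sample (sink) with reference source samples.

    Species are kept iff their total reads across reference samples reach
    ``min_ref_reads`` AND their reads in the target reach
    ``min_target_reads``; species whose relative abundance in the merged
    dataset falls below ``min_global_abundance`` are then discarded.  The
    target is appended as the last row.  Species are reconciled by taxid.
    """
    params = params or SourceCurationParams()
    if len(target.sample_ids) != 1:
        raise ParameterError("target must contain exactly one sample (the sink)")
    ref_by_taxid = {t: j for j, t in enumerate(references.taxids)}
    tgt_by_taxid = {t: j for j, t in enumerate(target.taxids)}
    shared = [t for t in references.taxids if t in tgt_by_taxid]

    kept = []
    for t in shared:
        ref_total = int(references.counts[:, ref_by_taxid[t]].sum())
        tgt_reads = int(target.counts[0, tgt_by_taxid[t]])
        if ref_total >= params.min_ref_reads and tgt_reads >= params.min_target_reads:
            kept.append(t)

    if kept:
        ref_cols = references.counts[:, [ref_by_taxid[t] for t in kept]]
        tgt_row = target.counts[:, [tgt_by_taxid[t] for t in kept]]
        merged = np.vstack([ref_cols, tgt_row])
        grand = merged.sum()
        if grand > 0 and params.min_global_abundance > 0:
            frac = merged.sum(axis=0) / grand
            keep_mask = frac >= params.min_global_abundance
            kept = [t for t, k in zip(kept, keep_mask) if k]
            merged = merged[:, keep_mask]
    else:
        merged = np.zeros((len(references.sample_ids) + 1, 0), dtype=int)
    if not kept:
        log.info("curate_for_sourcetracking: empty species intersection after curation")

    name_of = {t: n for n, t in references.species}
    labels = (
        (references.sample_labels or ["reference"] * len(references.sample_ids)) + ["sink"]
    )
    return AbundanceMatrix(
        sample_ids=references.sample_ids + target.sample_ids,
        species=[(name_of[t], t) for t in kept],
        counts=merged,
        sample_labels=labels,
    )


def rarefy_counts(counts, depth: int, seed=0) -> np.ndarray:
    """Subsample a count vector without replacement to exactly ``depth``."""
    counts = np.asarray(counts, dtype=int)
    total = int(counts.sum())
    if total < depth:
        raise DataError(f"cannot rarefy: total {total} < depth {depth}")
    rng = as_generator(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(int)


def rarefy_matrix(matrix: AbundanceMatrix, depth: int, seed=0) -> AbundanceMatrix:
    """Rarefy each sample; samples below depth are excluded (logged)."""
    rng = as_generator(seed)
    rows, ids, labels = [], [], []
    for i, sid in enumerate(matrix.sample_ids):
        try:
            rows.append(rarefy_counts(matrix.counts[i], depth, rng))
        except DataError:
            log.info("rarefy_matrix: sample %s below depth %d, excluded", sid, depth)
            continue
        ids.append(sid)
        if matrix.sample_labels:
            labels.append(matrix.sample_labels[i])
    return AbundanceMatrix(
        sample_ids=ids,
        species=list(matrix.species),
        counts=np.array(rows, dtype=int).reshape(len(ids), len(matrix.species)),
        sample_labels=labels or None,
    )


def clr_transform(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio transform, row-wise.

    Adds ``pseudocount``, closes each row to proportions, takes logs and
    subtracts the row's log mean; every output row sums to zero.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if np.any(X < 0):
        raise ParameterError("clr_transform requires non-negative counts")
    X = X + pseudocount
    if np.any(X.sum(axis=1) == 0) or np.any(X == 0):
        raise DataError("clr undefined: zero entries remain (use a positive pseudocount)")
    P = X / X.sum(axis=1, keepdims=True)
    logp = np.log(P)
    return logp - logp.mean(axis=1, keepdims=True)


def pca_embed(X, n_components: int = 2):
    """Column-centred SVD ordination.

    Returns ``(scores, loadings, explained_fractions)``; loadings are
    orthonormal columns, explained-variance fractions are non-increasing, and
    each component's sign is fixed so its largest-|loading| entry is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("pca_embed needs a 2-d matrix with >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise DataError("pca_embed: non-finite entries")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (s**2).sum()
    if total_var <= 1e-300:
        raise DataError("pca_embed: rank-0 (constant) input")
    k = min(n_components, len(s))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| coordinate of each component positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    loadings = Vt.T
    explained = (s**2) / total_var
    return scores, loadings, explained


def build_oral_matrix(per_sample_records: dict, oral_species, params: EscoreParams = None):
    """Abundance matrix restricted to oral species passing the E-score filter.

    ``oral_species`` is a collection of taxids (or (name, taxid) pairs).
    Returns ``(AbundanceMatrix, log10 view)`` where the view is a DataFrame of
    log10(reads) with absent (zero-read) cells as NaN.
    """
    params = params or EscoreParams()
    oral_taxids = {t if isinstance(t, int) else t[1] for t in oral_species}
    if not oral_taxids:
        raise ParameterError("oral species list is empty")
    filtered = {
        sid: [r for r in filter_taxa(list(recs), params) if r.taxid in oral_taxids]
        for sid, recs in per_sample_records.items()
    }
    matrix = records_to_matrix(filtered)
    logv = np.full(matrix.counts.shape, np.nan)
    np.log10(matrix.counts, where=matrix.counts > 0, out=logv)
    view = pd.DataFrame(logv, index=matrix.sample_ids, columns=[n for n, _ in matrix.species])
    return matrix, view
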