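"""Multi-sample variant calls → masked SNP alignment → distances → NJ tree.

Re-implements the SNP-dataset construction used for low-coverage ancient
bacterial strains: merge per-sample VCFs over the union of sites, genotype
each call as the majority allele if its allele-depth fraction passes a
heterozygous-ratio threshold (else N), require minimum genotype quality and
depth, discard indels, keep variant biallelic sites present in a minimum
fraction of samples, enforce a minimum spacing between retained positions,
and emit the variant columns as a multi-FASTA.  Pairwise p-distances and a
deterministic neighbor-joining tree serve as desk-scale phylogenetic checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .records import SampleCall, SnpAlignment, VariantCallRecord, VariantSiteTable

__all__ = [
    "SnpPanelParams",
    "merge_union_sites",
    "genotype_site",
    "genotype_table",
    "select_panel_sites",
    "build_snp_alignment",
    "build_panel",
    "pairwise_p_distance",
    "neighbor_joining",
]

log = logging.getLogger(__name__)


@dataclass
class SnpPanelParams:
    """Filter thresholds, mirroring the flags -r/-q/-d/-m/-p."""

    het_ratio: float = 0.9  # -r: majority allele-depth fraction to call homozygous
    min_gq: int = 30  # -q
    min_depth: int = 3  # -d
    min_presence: float = 0.75  # -m: fraction of samples with a non-N call
    min_spacing: int = 3  # -p: minimum bp between retained positions
    strict_het_ratio: bool = False  # True: require f > het_ratio instead of >=

    def __post_init__(self) -> None:
        if not 0.5 < self.het_ratio <= 1:
            raise ParameterError("het_ratio must be in (0.5, 1]")
        if not 0 < self.min_presence <= 1:
            raise ParameterError("min_presence must be in (0, 1]")
        if self.min_spacing < 1:
            raise ParameterError("min_spacing must be >= 1")
        if self.min_gq < 0 or self.min_depth < 0:
            raise ParameterError("min_gq and min_depth must be >= 0")


def merge_union_sites(per_sample_calls: dict) -> VariantSiteTable:
    """Union-merge per-sample call sets (the bcftools ``--merge all`` shape).

    Sites are keyed by (contig, pos); alt-allele sets are unioned (sorted
    lexicographically for determinism) and each sample's GT/AD indices are
    remapped onto the merged allele list.  A sample without a record at a
    site holds a missing call.  Conflicting REF alleles raise
    :class:`DataError` naming the site.
    """
    sample_ids = list(per_sample_calls)
    merged: dict = {}  # (contig, pos) -> {"ref": str, "alts": set, "calls": {sid: (rec, call)}}
    for sid, records in per_sample_calls.items():
        for rec in records:
            key = (rec.contig, rec.pos)
            entry = merged.setdefault(key, {"ref": rec.ref, "alts": set(), "calls": {}})
            if entry["ref"] != rec.ref:
                raise DataError(
                    f"conflicting REF at {rec.contig}:{rec.pos}: "
                    f"{entry['ref']!r} vs {rec.ref!r} (sample {sid})"
                )
            entry["alts"].update(rec.alts)
            if sid in entry["calls"]:
                raise DataError(f"duplicate record for sample {sid} at {rec.contig}:{rec.pos}")
            entry["calls"][sid] = rec

    sites = []
    for (contig, pos), entry in sorted(merged.items()):
        ref = entry["ref"]
        alts = tuple(sorted(entry["alts"]))
        alleles = (ref,) + alts
        calls = {}
        for sid in sample_ids:
            src = entry["calls"].get(sid)
            if src is None:
                calls[sid] = SampleCall()
                continue
            old_alleles = src.alleles
            remap = [alleles.index(a) for a in old_alleles]
            c = src.calls[sid]
            new_gt = None
            if c.gt is not None:
                new_gt = tuple(None if a is None else remap[a] for a in c.gt)
            new_ad = None
            if c.ad is not None:
                ad = np.zeros(len(alleles), dtype=int)
                for old_i, d in enumerate(c.ad):
                    ad[remap[old_i]] += d
                new_ad = tuple(int(x) for x in ad)
            calls[sid] = SampleCall(gt=new_gt, dp=c.dp, ad=new_ad, gq=c.gq)
        sites.append(VariantCallRecord(contig=contig, pos=pos, ref=ref, alts=alts, calls=calls))
    return VariantSiteTable(sample_ids=sample_ids, sites=sites)


def genotype_site(call: SampleCall, alleles: tuple, params: SnpPanelParams) -> str:
    """Collapse one per-sample call to a single base or N.

    N if the call is missing, GQ below ``min_gq``, depth below ``min_depth``,
    or the majority allele-depth fraction fails the heterozygous-ratio test
    (ties always mask).  Otherwise the majority allele's base.
    """
    if call is None or call.is_missing:
        return "N"
    if call.gq is None or call.gq < params.min_gq:
        return "N"
    depth = call.dp if call.dp is not None else (sum(call.ad) if call.ad else None)
    if depth is None or depth < params.min_depth:
        return "N"
    if call.ad is None:
        return "N"
    total = sum(call.ad)
    if total == 0:
        raise DataError(f"allele depths all zero with depth {depth}")
    ad = np.asarray(call.ad)
    best = int(ad.argmax())
    # exact tie in allele depths: no majority exists
    if int((ad == ad[best]).sum()) > 1:
        return "N"
    f = ad[best] / total
    passes = f > params.het_ratio if params.strict_het_ratio else f >= params.het_ratio
    if not passes:
        return "N"
    base = alleles[best]
    return base if base in "ACGT" else "N"


def genotype_table(table: VariantSiteTable, params: SnpPanelParams) -> np.ndarray:
    """Apply :func:`genotype_site` to every entry → (n_samples, n_sites) matrix."""
    M = np.full((len(table.sample_ids), len(table.sites)), "N", dtype="<U1")
    for j, site in enumerate(table.sites):
        alleles = site.alleles
        for i, sid in enumerate(table.sample_ids):
            M[i, j] = genotype_site(site.calls.get(sid), alleles, params)
    return M


def select_panel_sites(table: VariantSiteTable, geno: np.ndarray, params: SnpPanelParams) -> list:
    """Indices of retained sites, coordinate order.

    Rules, in order: discard indel sites; require exactly two distinct non-N
    bases across samples (variant and biallelic after masking); require a
    non-N fraction ≥ ``min_presence``; finally a greedy left-to-right spacing
    scan per contig keeps a site only if it lies ≥ ``min_spacing`` bp from the
    last kept position.
    """
    n_samples = geno.shape[0]
    candidates = []
    for j, site in enumerate(table.sites):
        if site.is_indel():
            continue
        col = geno[:, j]
        bases = set(col.tolist()) - {"N"}
        if len(bases) != 2:
            continue
        if (col != "N").sum() / n_samples < params.min_presence:
            continue
        candidates.append(j)
    retained = []
    last_pos: dict = {}
    for j in candidates:
        site = table.sites[j]
        prev = last_pos.get(site.contig)
        if prev is None or site.pos - prev >= params.min_spacing:
            retained.append(j)
            last_pos[site.contig] = site.pos
    return retained


def build_snp_alignment(table: VariantSiteTable, geno: np.ndarray, retained: list) -> SnpAlignment:
    return SnpAlignment(
        sample_ids=list(table.sample_ids),
        site_coords=[(table.sites[j].contig, table.sites[j].pos) for j in retained],
        matrix=geno[:, retained] if retained else np.empty((geno.shape[0], 0), dtype="<U1"),
    )


def build_panel(per_sample_calls: dict, params: SnpPanelParams = None):
    """Full chain: merge → genotype → select → alignment.

    Returns ``(alignment, table, retained_indices)`` and logs the site tally
    at each stage.
    """
    params = params or SnpPanelParams()
    table = merge_union_sites(per_sample_calls)
    geno = genotype_table(table, params)
    retained = select_panel_sites(table, geno, params)
    log.info(
        "snp panel: %d merged sites -> %d retained biallelic positions "
        "across %d samples",
        len(table.sites), len(retained), len(table.sample_ids),
    )
    return build_snp_alignment(table, geno, retained), table, retained


def pairwise_p_distance(alignment: SnpAlignment):
    """p-distance matrix: mismatches over comparable (both non-N) columns.

    Returns ``(D, n_comparable)``; pairs with zero comparable columns get
    NaN distance.
    """
    M = alignment.matrix
    n = alignment.n_samples
    D = np.zeros((n, n))
    C = np.zeros((n, n), dtype=int)
    for a in range(n):
        for b in range(a + 1, n):
            ok = (M[a] != "N") & (M[b] != "N")
            n_ok = int(ok.sum())
            C[a, b] = C[b, a] = n_ok
            if n_ok == 0:
                D[a, b] = D[b, a] = np.nan
            else:
                d = float((M[a][ok] != M[b][ok]).sum() / n_ok)
                D[a, b] = D[b, a] = d
    return D, C


def neighbor_joining(D, labels: list) -> str:
    """Neighbor joining with deterministic lowest-index tie-breaking → newick.

    Standard Saitou–Nei agglomeration on a symmetric non-negative matrix with
    zero diagonal; the minimal Q-matrix pair is chosen, ties broken by the
    lexicographically smallest (i, j) index pair.  Branch lengths are the
    usual limb-length formulas (not clamped), so additive inputs are
    recovered exactly.
    """
    D = np.array(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ParameterError("distance matrix shape must match label count")
    if np.isnan(D).any():
        raise DataError("NaN in distance matrix (pair with no comparable columns?)")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise DataError("distance matrix must be symmetric, non-negative, zero-diagonal")

    nodes = [str(l) for l in labels]  # newick fragment per active node
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def d(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    frag = {i: nodes[i] for i in range(n)}
    while len(active) > 2:
        m = len(active)
        totals = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - totals[i] - totals[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, u), max(k, u))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        dist[(u, u)] = 0.0
        frag[u] = f"({frag[i]}:{li:.10g},{frag[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    return f"({frag[i]}:{d(i, j):.10g},{frag[j]}:0);"
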