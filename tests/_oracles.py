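"""Independent naive re-implementations used as oracles.

Everything here is deliberately written in plain Python, without touching the
package's own genotyping/filtering code paths, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- SNP panel

def naive_genotype(call, alleles, het_ratio=0.9, min_gq=30, min_depth=3, strict=False):
    """Site genotyping re-derived from the stated rules, loop-free numpy avoided."""
    if call is None:
        return "N"
    gt, dp, ad, gq = call.gt, call.dp, call.ad, call.gq
    if gt is None or any(a is None for a in gt):
        return "N"
    if gq is None or gq < min_gq:
        return "N"
    depth = dp if dp is not None else (sum(ad) if ad else None)
    if depth is None or depth < min_depth:
        return "N"
    if ad is None:
        return "N"
    total = sum(ad)
    if total == 0:
        raise ValueError("AD all zero with depth present")
    best_depth = max(ad)
    if sum(1 for x in ad if x == best_depth) > 1:
        return "N"
    frac = best_depth / total
    ok = frac > het_ratio if strict else frac >= het_ratio
    if not ok:
        return "N"
    base = alleles[ad.index(best_depth)]
    return base if base in "ACGT" else "N"


def naive_panel(table, het_ratio=0.9, min_gq=30, min_depth=3,
                min_presence=0.75, min_spacing=3, strict=False):
    """Merged table -> (retained (contig,pos) list, {sample: row string}).

    Independent pass over the stated rules: genotype every cell, drop indel
    sites, keep exactly-biallelic variant columns, apply the presence cut,
    then a left-to-right spacing scan per contig.
    """
    samples = list(table.sample_ids)
    genotyped = []  # (contig, pos, {sample: base})
    for site in table.sites:
        alleles = list(site.alleles)
        col = {}
        for s in samples:
            col[s] = naive_genotype(site.calls.get(s), alleles,
                                    het_ratio, min_gq, min_depth, strict)
        genotyped.append((site, col))

    survivors = []
    for site, col in genotyped:
        if any(len(a) != 1 for a in site.alleles):
            continue
        observed = sorted({b for b in col.values() if b != "N"})
        if len(observed) != 2:
            continue
        n_called = sum(1 for b in col.values() if b != "N")
        if n_called / len(samples) < min_presence:
            continue
        survivors.append((site, col))

    retained, rows = [], {s: [] for s in samples}
    last = {}
    for site, col in survivors:
        prev = last.get(site.contig)
        if prev is not None and site.pos - prev < min_spacing:
            continue
        last[site.contig] = site.pos
        retained.append((site.contig, site.pos))
        for s in samples:
            rows[s].append(col[s])
    return retained, {s: "".join(v) for s, v in rows.items()}


# ---------------------------------------------------------------- screening

def naive_escore_filter(rows, min_escore=7.0, min_reads=10):
    """One-pass scan over (reads, kmers, cov) dict rows; returns kept indices."""
    kept = []
    for i, r in enumerate(rows):
        if r["reads"] <= 0 or r["cov"] <= 0:
            continue
        e = 0.0 if r["kmers"] == 0 else (r["kmers"] / r["reads"]) / r["cov"]
        if e >= min_escore and r["reads"] >= min_reads:
            kept.append(i)
    return kept


def naive_curation(target_counts, ref_counts, min_ref=200, min_target=50, min_abund=0.0002):
    """Three-pass manual filter on dict-of-dicts counts keyed by taxid.

    ``target_counts``: {taxid: reads}; ``ref_counts``: {sample: {taxid: reads}}.
    Returns the kept taxid list in reference-species order.
    """
    order = []
    for s in ref_counts.values():
        for t in s:
            if t not in order:
                order.append(t)
    step1 = []
    for t in order:
        if t not in target_counts:
            continue
        ref_total = sum(s.get(t, 0) for s in ref_counts.values())
        if ref_total >= min_ref and target_counts[t] >= min_target:
            step1.append(t)
    grand = sum(sum(s.get(t, 0) for s in ref_counts.values()) + target_counts[t] for t in step1)
    if grand == 0 or min_abund == 0:
        return step1
    kept = []
    for t in step1:
        tot = sum(s.get(t, 0) for s in ref_counts.values()) + target_counts[t]
        if tot / grand >= min_abund:
            kept.append(t)
    return kept


# ---------------------------------------------------------------- mappability

def naive_unique_coverage(reference, read_len):
    """Exhaustive substring-count oracle for the saturating-depth mappability."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    covered = [False] * len(reference)
    n_starts = len(reference) - read_len + 1
    windows = [reference[p:p + read_len] for p in range(n_starts)]
    from collections import Counter

    counts = Counter(windows)
    for p, w in enumerate(windows):
        rc = "".join(comp[c] for c in reversed(w))
        occ = counts[w] + (counts[rc] if rc != w else 0)
        if occ == 1:
            for q in range(p, p + read_len):
                covered[q] = True
    return sum(covered) / len(reference)


# ---------------------------------------------------------------- random tables

def random_call_table(rng, max_sites=50, max_samples=10):
    """A random merged-shape per-sample call dict exercising every filter rule."""
    from paleokit.records import SampleCall, VariantCallRecord

    n_samples = int(rng.integers(2, max_samples + 1))
    n_sites = int(rng.integers(1, max_sites + 1))
    samples = [f"s{i}" for i in range(n_samples)]
    positions = sorted(rng.choice(np.arange(1, 4 * max_sites), size=n_sites, replace=False).tolist())
    bases = "ACGT"
    per_sample = {s: [] for s in samples}
    for pos in positions:
        ref = bases[int(rng.integers(4))]
        if rng.random() < 0.1:  # occasional indel allele
            alts = (ref + "A",)
        else:
            alts = tuple(sorted({bases[int(rng.integers(4))] for _ in range(int(rng.integers(1, 3)))} - {ref}))
            if not alts:
                alts = (bases[(bases.index(ref) + 1) % 4],)
        n_alleles = 1 + len(alts)
        for s in samples:
            if rng.random() < 0.15:  # sample absent at this site
                continue
            if rng.random() < 0.1:
                call = SampleCall()  # explicit ./.
            else:
                dp = int(rng.integers(0, 40))
                if rng.random() < 0.7:
                    # clean-ish call: one dominant allele, occasional minor reads
                    probs = np.full(n_alleles, 0.03 / max(n_alleles - 1, 1))
                    probs[int(rng.integers(n_alleles))] = 0.97
                    ad = rng.multinomial(dp, probs / probs.sum())
                else:
                    # messy call: depth spread across alleles (masks to N)
                    ad = rng.multinomial(dp, np.ones(n_alleles) / n_alleles)
                gq = int(rng.integers(0, 100)) if rng.random() > 0.05 else None
                gt_i = int(np.argmax(ad)) if dp else 0
                call = SampleCall(gt=(gt_i, gt_i), dp=dp,
                                  ad=tuple(int(x) for x in ad), gq=gq)
            per_sample[s].append(
                VariantCallRecord(contig="c1", pos=int(pos), ref=ref, alts=alts,
                                  calls={s: call})
            )
    return per_sample
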