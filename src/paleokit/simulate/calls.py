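"""Simulate per-strain variant-call records from a simulated strain panel.

Emulates the shape of a genotyper's per-sample output: GT/DP/AD/GQ at each
true variant position (and, optionally, homozygous-reference records at every
other position, as produced by an all-sites emission mode).  Depth is Poisson
around a target fold coverage; allele depths optionally carry a
cross-contamination noise fraction routed to the site's other allele.
"""

from __future__ import annotations

import numpy as np

from .._rng import substream
from ..records import SampleCall, VariantCallRecord
from .strains import StrainSet

__all__ = ["simulate_sample_calls"]


def _default_gq(rng: np.random.Generator, n: int) -> np.ndarray:
    # clipped discretised normal; occasional low-GQ calls exercise the -q filter
    return np.clip(np.round(rng.normal(60, 15, size=n)), 0, 99).astype(int)


def simulate_sample_calls(
    strain_set: StrainSet,
    coverage_mean: float = 30.0,
    gq_model=None,
    emit_all_sites: bool = False,
    noise: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> dict:
    """Return ``{strain_name: [VariantCallRecord, ...]}``, one call set per strain.

    Parameters
    ----------
    coverage_mean : target fold coverage; DP ~ Poisson(coverage_mean) per site.
    gq_model : callable ``(rng, n) -> int array`` of genotype qualities;
        defaults to a clipped normal around 60.
    emit_all_sites : also emit homozygous-reference records at non-variant
        positions (all-sites emission).
    noise : fraction of reads at a variant site supporting the site's other
        allele (cross-contamination / damage stand-in).
    dropout : probability that a strain has no record at a variant site.
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be > 0")
    if not 0 <= noise < 0.5:
        raise ValueError("noise must be in [0, 0.5)")
    gq_model = gq_model or _default_gq
    rng = substream(seed, "sample-calls")
    contig = strain_set.contig
    anc = strain_set.ancestor
    variant_pos = {pos for pos, _, _ in strain_set.variant_sites}

    out: dict = {}
    for name in strain_set.strain_names:
        records = []
        for pos, ref, alleles in strain_set.variant_sites:
            if dropout and rng.random() < dropout:
                continue
            own = alleles[name]
            site_alleles = sorted(set(alleles.values()) | {ref})
            others = [a for a in site_alleles if a != own]
            dp = int(rng.poisson(coverage_mean))
            rec_alts = tuple(a for a in site_alleles if a != ref)
            allele_order = (ref,) + rec_alts
            ad = np.zeros(len(allele_order), dtype=int)
            if dp > 0:
                n_noise = int(rng.binomial(dp, noise)) if noise and others else 0
                ad[allele_order.index(own)] = dp - n_noise
                if n_noise:
                    # noise reads support one uniformly chosen other allele
                    tgt = others[int(rng.integers(len(others)))]
                    ad[allele_order.index(tgt)] += n_noise
            gq = int(gq_model(rng, 1)[0])
            gt_idx = allele_order.index(own)
            records.append(
                VariantCallRecord(
                    contig=contig,
                    pos=pos,
                    ref=ref,
                    alts=rec_alts,
                    calls={
                        name: SampleCall(
                            gt=(gt_idx, gt_idx), dp=dp, ad=tuple(int(x) for x in ad), gq=gq
                        )
                    },
                )
            )
        if emit_all_sites:
            gqs = gq_model(rng, len(anc))
            for pos0, base in enumerate(anc):
                pos = pos0 + 1
                if pos in variant_pos:
                    continue
                dp = int(rng.poisson(coverage_mean))
                records.append(
                    VariantCallRecord(
                        contig=contig,
                        pos=pos,
                        ref=base,
                        alts=(),
                        calls={
                            name: SampleCall(gt=(0, 0), dp=dp, ad=(dp,), gq=int(gqs[pos0]))
                        },
                    )
                )
            records.sort(key=lambda r: (r.contig, r.pos))
        out[name] = records
    return out
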