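"""Ancient-DNA authenticity signals.

Four diagnostics: terminal deamination profiles (C→T at the 5′ end, G→A at
the 3′ end, counted per offset against the reference), fragment-length
summaries, reference mappability by simulated uniquely-placeable reads, and
the chrY read-fraction used for genetic sex determination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import DataError, ParameterError
from .records import AlignedRead, DamageProfile

__all__ = [
    "AuthParams",
    "compute_damage_profile",
    "fragment_length_summary",
    "compute_mappability",
    "unique_coverage_fraction",
    "genetic_sex_ratio",
    "damage_profile_frame",
]


@dataclass
class AuthParams:
    min_mapping_quality: int = 30
    mappability_read_length: int = 50
    mappability_depth: float = 30.0

    def __post_init__(self) -> None:
        if min(self.min_mapping_quality, self.mappability_read_length) < 0:
            raise ParameterError("AuthParams fields must be >= 0")
        if self.mappability_depth < 0:
            raise ParameterError("mappability_depth must be >= 0")


def compute_damage_profile(
    reads,
    reference: str,
    n_positions: int = 25,
    min_mapq: int = 0,
) -> DamageProfile:
    """Count terminal substitution frequencies against the reference.

    For 5′ offset i: frequency = #(ref C, read T at i) / #(ref C at i), and
    symmetrically G→A counting offsets inward from the 3′ end.  Reads shorter
    than ``n_positions`` contribute only to the offsets they cover; both end
    windows of one read may overlap in the middle of a short read.
    """
    W = n_positions
    ct_num = np.zeros(W, dtype=int)
    ct_den = np.zeros(W, dtype=int)
    ga_num = np.zeros(W, dtype=int)
    ga_den = np.zeros(W, dtype=int)
    L = len(reference)
    for r in reads:
        if r.mapq < min_mapq:
            continue
        if r.start < 1 or r.end > L:
            raise DataError(f"read {r.read_id} [{r.start},{r.end}] extends past reference (len {L})")
        ref_seg = reference[r.start - 1 : r.end]
        n = r.length
        w = min(W, n)
        for i in range(w):
            if ref_seg[i] == "C":
                ct_den[i] += 1
                if r.sequence[i] == "T":
                    ct_num[i] += 1
            # 3' offset i counts from the last base inward
            j = n - 1 - i
            if ref_seg[j] == "G":
                ga_den[i] += 1
                if r.sequence[j] == "A":
                    ga_num[i] += 1
    return DamageProfile(
        n_positions=W,
        ct_5prime_num=ct_num,
        ct_5prime_den=ct_den,
        ga_3prime_num=ga_num,
        ga_3prime_den=ga_den,
    )


def damage_profile_frame(profile: DamageProfile) -> pd.DataFrame:
    """Tidy per-offset table: end, offset, numerator, denominator, frequency."""
    rows = []
    for end, num, den in (
        ("5p_CT", profile.ct_5prime_num, profile.ct_5prime_den),
        ("3p_GA", profile.ga_3prime_num, profile.ga_3prime_den),
    ):
        for i in range(profile.n_positions):
            rows.append(
                {
                    "end": end,
                    "offset": i,
                    "numerator": int(num[i]),
                    "denominator": int(den[i]),
                    "frequency": float(num[i] / den[i]) if den[i] > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def fragment_length_summary(reads) -> dict:
    """Integer length histogram plus exact median/mean; empty input → count 0."""
    lengths = [r.length for r in reads]
    if not lengths:
        return {"n": 0, "histogram": {}, "median": None, "mean": None}
    return {
        "n": len(lengths),
        "histogram": dict(sorted(Counter(lengths).items())),
        "median": float(np.median(lengths)),
        "mean": float(np.mean(lengths)),
    }


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _window_occurrences(reference: str, read_len: int) -> Counter:
    """Occurrence count of every length-``read_len`` window, both strands folded."""
    counts: Counter = Counter()
    for p in range(len(reference) - read_len + 1):
        counts[reference[p : p + read_len]] += 1
    return counts


def _unique_start_mask(reference: str, read_len: int) -> np.ndarray:
    """True at start p iff the window at p occurs exactly once in the reference
    counting both its forward sequence and its reverse complement."""
    counts = _window_occurrences(reference, read_len)
    n_starts = len(reference) - read_len + 1
    mask = np.zeros(n_starts, dtype=bool)
    for p in range(n_starts):
        w = reference[p : p + read_len]
        rc = _revcomp(w)
        occ = counts[w] + (counts[rc] if rc != w else 0)
        mask[p] = occ == 1
    return mask


def unique_coverage_fraction(reference: str, read_len: int = 50) -> float:
    """Exhaustive oracle: fraction of positions covered by ≥1 uniquely
    placeable window — the saturating-depth limit of :func:`compute_mappability`."""
    mask = _unique_start_mask(reference, read_len)
    covered = np.zeros(len(reference), dtype=bool)
    for p in np.flatnonzero(mask):
        covered[p : p + read_len] = True
    return float(covered.mean())


def compute_mappability(reference: str, params: AuthParams = None, seed: int = 0) -> float:
    """Fraction of the reference covered by uniquely placeable simulated reads.

    Reads of the configured length are drawn uniformly to the configured fold
    depth; a read is uniquely placeable iff its sequence (or reverse
    complement) occurs exactly once in the reference — the exact-occurrence
    analogue of a mapping-quality cutoff.
    """
    params = params or AuthParams()
    L = len(reference)
    rl = params.mappability_read_length
    if L <= rl:
        raise ParameterError(f"reference length {L} must exceed read length {rl}")
    if params.mappability_depth == 0:
        return 0.0
    rng = substream(seed, "mappability")
    n_reads = int(np.ceil(params.mappability_depth * L / rl))
    mask = _unique_start_mask(reference, rl)
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    covered = np.zeros(L, dtype=bool)
    for p in starts:
        if mask[p]:
            covered[p : p + rl] = True
    return float(covered.mean())


def genetic_sex_ratio(reads_y: int, reads_x: int) -> float:
    """chrY fraction: reads_y / (reads_x + reads_y)."""
    if reads_x < 0 or reads_y < 0:
        raise ParameterError("read counts must be >= 0")
    total = reads_x + reads_y
    if total == 0:
        raise DataError("undefined sex ratio: no reads on X or Y")
    return reads_y / total
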