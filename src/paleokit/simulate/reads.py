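"""Simulate short ancient-DNA fragments with terminal deamination damage.

Post-mortem cytosine deamination is read as C→T at the 5′ end of a fragment
and (on double-stranded libraries) G→A at the 3′ end, with a frequency that
is highest at the terminal base and decays toward the interior.  The model
here is geometric: at 5′ offset i a reference C becomes T with probability
``d5 * decay**i``; symmetrically at 3′ offset j a reference G becomes A with
probability ``d3 * decay**j``.  Fragment lengths are log-normal.  The
generator counts every damage event it introduces, per offset, so profile
estimators can be checked against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import substream
from ..records import AlignedRead, DamageProfile

__all__ = ["DamageModelParams", "DamageTruth", "simulate_damaged_reads"]


@dataclass
class DamageModelParams:
    d5: float = 0.3  # C->T probability at the 5'-terminal base
    d3: float = 0.3  # G->A probability at the 3'-terminal base
    decay: float = 0.5  # per-position geometric decay, in (0, 1)
    frag_median: float = 60.0  # median fragment length (bp); log-normal scale exp(mu)
    frag_sd: float = 0.3  # log-scale sigma of the fragment-length distribution
    n_reads: int = 10_000
    seq_error: float = 0.0
    min_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.d5 <= 1 and 0 <= self.d3 <= 1):
            raise ValueError("d5 and d3 must be in [0, 1]")
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0, 1)")
        if not 25 <= self.frag_median <= 150:
            raise ValueError("frag_median must give a median fragment in [25, 150] bp")
        if not 0 <= self.seq_error <= 1:
            raise ValueError("seq_error must be in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass
class DamageTruth:
    """Exact per-offset damage tallies recorded while generating reads."""

    window: int
    ct_num: np.ndarray  # C->T events introduced at 5' offset i (i < window)
    ct_den: np.ndarray  # reference-C occurrences at 5' offset i
    ga_num: np.ndarray  # G->A events at 3' offset j
    ga_den: np.ndarray  # reference-G occurrences at 3' offset j

    def as_profile(self) -> DamageProfile:
        return DamageProfile(
            n_positions=self.window,
            ct_5prime_num=self.ct_num.copy(),
            ct_5prime_den=self.ct_den.copy(),
            ga_3prime_num=self.ga_num.copy(),
            ga_3prime_den=self.ga_den.copy(),
        )


def simulate_damaged_reads(
    genome: str,
    params: DamageModelParams,
    contig: str = "ref",
    truth_window: int = 25,
):
    """Place ungapped fragments uniformly on ``genome`` and damage their ends.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    :class:`AlignedRead` and ``truth`` a :class:`DamageTruth` whose counters
    record exactly which bases were deaminated at each terminal offset
    (sequencing error, applied afterwards, is not counted as damage).
    """
    rng = substream(params.seed, "damaged-reads")
    L = len(genome)
    garr = np.frombuffer(genome.encode(), dtype="S1")

    lengths = np.round(
        rng.lognormal(mean=np.log(params.frag_median), sigma=params.frag_sd, size=params.n_reads)
    ).astype(int)
    lengths = np.clip(lengths, params.min_length, max(params.min_length, L - 1))
    if L <= lengths.max():
        raise ValueError(f"genome length {L} must exceed max fragment length {lengths.max()}")

    W = truth_window
    truth = DamageTruth(
        window=W,
        ct_num=np.zeros(W, dtype=int),
        ct_den=np.zeros(W, dtype=int),
        ga_num=np.zeros(W, dtype=int),
        ga_den=np.zeros(W, dtype=int),
    )
    bases = np.frombuffer(b"ACGT", dtype="S1")
    reads = []
    for k in range(params.n_reads):
        n = int(lengths[k])
        start0 = int(rng.integers(0, L - n + 1))
        frag = garr[start0 : start0 + n].copy()

        offsets = np.arange(n)
        is_c = frag == b"C"
        is_g = frag == b"G"
        p5 = params.d5 * params.decay**offsets
        p3 = params.d3 * params.decay**(offsets[::-1])
        hit5 = is_c & (rng.random(n) < p5)
        hit3 = is_g & (rng.random(n) < p3)
        frag[hit5] = b"T"
        frag[hit3] = b"A"

        w5 = min(W, n)
        truth.ct_den[:w5] += is_c[:w5]
        truth.ct_num[:w5] += hit5[:w5]
        # 3' offsets count from the read's last base inward
        truth.ga_den[:w5] += is_g[::-1][:w5]
        truth.ga_num[:w5] += hit3[::-1][:w5]

        if params.seq_error > 0:
            err = rng.random(n) < params.seq_error
            for i in np.flatnonzero(err):
                frag[i] = rng.choice(bases[bases != frag[i]])

        reads.append(
            AlignedRead(
                read_id=f"read_{k:06d}",
                contig=contig,
                start=start0 + 1,
                sequence=frag.tobytes().decode(),
            )
        )
    return reads, truth
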