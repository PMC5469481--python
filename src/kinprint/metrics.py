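"""Pairwise genotype-mismatch statistics from packed fingerprints.

For a pair of samples compared over the fingerprint panel:

* AGMR (all-genotype mismatch rate) — fraction of SNPs, non-missing in
  both samples, where the two genotypes differ (IBS < 2).
* HGMR (homozygous-genotype mismatch rate) — among SNPs where both
  samples are homozygous, the fraction carrying *different* homozygotes
  (N_DO / (N_DO + N_SO)).

Both are computed per 64-SNP word with bitwise kernels.  With the 2-bit
code table (00 hom-a1, 01 het, 10 hom-a2, 11 missing):

    valid    = NOT(hiA AND loA) AND NOT(hiB AND loB)
    mismatch = ((hiA XOR hiB) OR (loA XOR loB)) AND valid
    bothhom  = (NOT loA) AND (NOT loB) AND valid
    DO       = bothhom AND (hiA XOR hiB)

and all counts are popcount sums.  Pad bits are stored as missing, so no
length masking is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .fingerprint import FingerprintSet, PackedFingerprint

__all__ = ["PairStats", "pair_stats", "all_pairs_stats", "pair_stats_against"]

_U64MAX = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class PairStats:
    """Mismatch counts and rates for one sample pair.

    ``hgmr`` is None (undefined) when the pair shares no doubly
    homozygous SNP; ``comparable`` is False when ``n_compared`` is zero
    or below the caller's minimum.
    """

    id_a: str
    id_b: str
    n_compared: int
    n_mismatch: int
    n_both_hom: int
    n_DO: int

    @property
    def n_SO(self) -> int:
        return self.n_both_hom - self.n_DO

    @property
    def agmr(self) -> float | None:
        if self.n_compared == 0:
            return None
        return self.n_mismatch / self.n_compared

    @property
    def hgmr(self) -> float | None:
        if self.n_both_hom == 0:
            return None
        return self.n_DO / self.n_both_hom

    @property
    def comparable(self) -> bool:
        return self.n_compared > 0


def _kernel_words(hi_a, lo_a, hi_b, lo_b):
    """Per-word masks (valid, mismatch, bothhom, DO); inputs broadcast."""
    valid = ~(hi_a & lo_a) & ~(hi_b & lo_b)
    mismatch = ((hi_a ^ hi_b) | (lo_a ^ lo_b)) & valid
    bothhom = ~lo_a & ~lo_b & valid
    do = bothhom & (hi_a ^ hi_b)
    return valid, mismatch, bothhom, do


def pair_stats(fp_a: PackedFingerprint, fp_b: PackedFingerprint) -> PairStats:
    """Compare two fingerprints built on the same panel."""
    if fp_a.n_snps != fp_b.n_snps:
        raise ValueError("fingerprints were built on different panels")
    valid, mismatch, bothhom, do = _kernel_words(
        fp_a.words_hi, fp_a.words_lo, fp_b.words_hi, fp_b.words_lo
    )
    return PairStats(
        id_a=fp_a.sample_id,
        id_b=fp_b.sample_id,
        n_compared=int(np.bitwise_count(valid).sum()),
        n_mismatch=int(np.bitwise_count(mismatch).sum()),
        n_both_hom=int(np.bitwise_count(bothhom).sum()),
        n_DO=int(np.bitwise_count(do).sum()),
    )


def pair_stats_against(
    fps: FingerprintSet, i: int, others: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized counts of sample ``i`` against rows ``others``.

    Returns (n_compared, n_mismatch, n_both_hom, n_DO) arrays.
    """
    valid, mismatch, bothhom, do = _kernel_words(
        fps.hi[i], fps.lo[i], fps.hi[others], fps.lo[others]
    )
    count = lambda w: np.bitwise_count(w).sum(axis=1).astype(np.int64)
    return count(valid), count(mismatch), count(bothhom), count(do)


def all_pairs_stats(
    fps: FingerprintSet, min_compared: int = 64
) -> Iterator[PairStats]:
    """Exhaustive all-pairs statistics (the naive driver), streamed.

    Emits n(n-1)/2 records; pairs with ``n_compared < min_compared``
    are still emitted so callers can flag them.
    """
    n = len(fps)
    if n < 2:
        raise ValueError("need at least two fingerprints")
    for i in range(n - 1):
        others = np.arange(i + 1, n)
        nc, nm, nb, ndo = pair_stats_against(fps, i, others)
        for j, idx in enumerate(others):
            yield PairStats(
                id_a=fps.ids[i],
                id_b=fps.ids[idx],
                n_compared=int(nc[j]),
                n_mismatch=int(nm[j]),
                n_both_hom=int(nb[j]),
                n_DO=int(ndo[j]),
            )


def stats_to_frame(records) -> pd.DataFrame:
    """PairStats records -> TSV-ready DataFrame (rates at 6 decimals)."""
    rows = [
        {
            "id_a": r.id_a,
            "id_b": r.id_b,
            "n_compared": r.n_compared,
            "n_mismatch": r.n_mismatch,
            "n_both_hom": r.n_both_hom,
            "n_DO": r.n_DO,
            "agmr": round(r.agmr, 6) if r.agmr is not None else "",
            "hgmr": round(r.hgmr, 6) if r.hgmr is not None else "",
        }
        for r in records
    ]
    return pd.DataFrame(rows)
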