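"""Finding identical sample pairs (same subject or MZ twin).

Three scanners of increasing sophistication, all reporting pairs whose
full-panel AGMR falls below a cutoff (default 20%):

* ``naive_scan`` — O(n^2 S): every pair compared over the whole panel.
  The reference oracle for the other two.
* ``quadratic_scan`` — O(n^2): per pair, genotype words are compared
  only until at least ``m`` non-null comparisons accumulate; the pair is
  abandoned if ``k`` or more mismatches are seen by then, otherwise it
  is verified over the full panel.  Defaults m=64 (one word), k=8.
  Because survivors are verified, specificity is 1 by construction; the
  false-negative rate is the binomial tail of ``theory.quadratic_fn_rate``.
* ``subquadratic_scan`` — O(n log n) per round: each round draws ``m``
  low-missingness SNPs, codes each sample's genotypes at those SNPs into
  an integer key, sorts the keys, and treats equal adjacent keys as
  putative identical pairs, verified over the full panel.  Rounds repeat
  until ``c`` consecutive rounds add no new confirmed pair.  Per-round
  sensitivity for a pair with per-SNP missing-or-mismatch rate delta is
  ~e^{-m*delta}; intended for datasets with low missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fingerprint import FingerprintSet
from .metrics import PairStats, pair_stats, pair_stats_against
from .plinkio import MISSING

log = logging.getLogger(__name__)

__all__ = ["IdenticalPair", "naive_scan", "quadratic_scan", "subquadratic_scan"]

DEFAULT_AGMR_CUTOFF = 0.20


@dataclass(frozen=True)
class IdenticalPair:
    id_a: str
    id_b: str
    stats: PairStats
    detected_by: str

    def key(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


def _as_pair(fps: FingerprintSet, i: int, j: int, nc, nm, nb, ndo, algo) -> IdenticalPair:
    st = PairStats(fps.ids[i], fps.ids[j], int(nc), int(nm), int(nb), int(ndo))
    return IdenticalPair(fps.ids[i], fps.ids[j], st, algo)


def naive_scan(
    fps: FingerprintSet,
    agmr_cutoff: float = DEFAULT_AGMR_CUTOFF,
    min_compared: int = 64,
) -> list[IdenticalPair]:
    """Exhaustive full-panel scan; the oracle for the faster scanners."""
    n = len(fps)
    if n < 2:
        raise ValueError("need at least two fingerprints")
    out: list[IdenticalPair] = []
    for i in range(n - 1):
        others = np.arange(i + 1, n)
        nc, nm, nb, ndo = pair_stats_against(fps, i, others)
        ok = (nc >= min_compared) & (nm < agmr_cutoff * nc)
        for j in others[ok]:
            w = j - i - 1
            out.append(_as_pair(fps, i, int(j), nc[w], nm[w], nb[w], ndo[w], "naive"))
    return out


def quadratic_scan(
    fps: FingerprintSet,
    m: int = 64,
    k: int = 8,
    agmr_cutoff: float = DEFAULT_AGMR_CUTOFF,
    min_compared: int = 64,
) -> list[IdenticalPair]:
    """Early-termination scan: screen on the first >= m non-null comparisons.

    Words are accumulated until at least ``m`` non-null comparisons have
    been made (block-aligned: the screen stops at the first whole word
    that carries the count to >= m); if ``k`` or more mismatches are seen
    by then the pair is abandoned, otherwise it is verified over the full
    panel.  Pairs never reaching ``m`` non-null comparisons cannot be
    screened out and go straight to verification.
    """
    n = len(fps)
    if n < 2:
        raise ValueError("need at least two fingerprints")
    out: list[IdenticalPair] = []
    W = fps.hi.shape[1]
    for i in range(n - 1):
        others = np.arange(i + 1, n)
        hi_a, lo_a = fps.hi[i], fps.lo[i]
        hi_b, lo_b = fps.hi[others], fps.lo[others]
        valid = ~(hi_a & lo_a) & ~(hi_b & lo_b)
        mism = ((hi_a ^ hi_b) | (lo_a ^ lo_b)) & valid
        cv = np.cumsum(np.bitwise_count(valid), axis=1)
        cm = np.cumsum(np.bitwise_count(mism), axis=1)
        # index of first word at which >= m non-null comparisons accumulated
        first = (cv < m).sum(axis=1)
        reached = first < W
        screen_mism = np.where(reached, cm[np.arange(len(others)), np.minimum(first, W - 1)], cm[:, -1])
        survives = screen_mism < k
        # survivors: full-panel verification (totals already available)
        nc_full = cv[:, -1]
        nm_full = cm[:, -1]
        cand = survives & (nc_full >= min_compared) & (nm_full < agmr_cutoff * nc_full)
        if not cand.any():
            continue
        idx = others[cand]
        nc, nm, nb, ndo = pair_stats_against(fps, i, idx)
        for w, j in enumerate(idx):
            out.append(
                _as_pair(fps, i, int(j), nc[w], nm[w], nb[w], ndo[w], "quadratic")
            )
    return out


def _missing_rates(codes: np.ndarray) -> np.ndarray:
    return (codes == MISSING).mean(axis=0)


def subquadratic_scan(
    fps: FingerprintSet,
    m: int = 20,
    c: int = 10,
    seed: int = 0,
    agmr_cutoff: float = DEFAULT_AGMR_CUTOFF,
    min_compared: int = 64,
    pool_quantile: float = 0.2,
    max_rounds: int | None = None,
) -> list[IdenticalPair]:
    """Sort-based randomized scan for datasets with low missingness.

    SNPs are ranked by missing rate; each round draws ``m`` SNPs (without
    replacement within the round, with replacement across rounds) from
    the low-missingness pool — the SNPs at or below the ``pool_quantile``
    missing rate, widened to at least ``10*m`` SNPs.  Samples with any
    missing genotype among the drawn SNPs get a sentinel key and sit out
    the round (counted in the log).  Equal-key runs after sorting yield
    putative pairs (all within-run pairs, so duplicate clusters are
    covered), each verified over the full panel.  The loop ends after
    ``c`` consecutive rounds without a new confirmed pair, or after
    ``max_rounds`` rounds if given.
    """
    if m > 32:
        raise ValueError("m must be <= 32 so keys fit in 64 bits")
    n = len(fps)
    if n < 2:
        raise ValueError("need at least two fingerprints")
    rng = np.random.default_rng(seed)
    codes = fps.codes()
    miss_rate = _missing_rates(codes)
    order = np.argsort(miss_rate, kind="stable")
    cutoff_rate = np.quantile(miss_rate, pool_quantile)
    pool_size = max(int((miss_rate <= cutoff_rate).sum()), min(10 * m, fps.n_snps))
    pool = order[:pool_size]

    confirmed: dict[frozenset, IdenticalPair] = {}
    putative: set[frozenset] = set()
    rounds_without_new = 0
    round_index = 0
    while rounds_without_new < c:
        if max_rounds is not None and round_index >= max_rounds:
            break
        round_index += 1
        snps = rng.choice(pool, size=m, replace=False)
        sel = codes[:, snps].astype(np.uint64)
        usable = ~(sel == MISSING).any(axis=1)
        keys = np.zeros(n, dtype=np.uint64)
        for b in range(m):
            keys = (keys << np.uint64(2)) | sel[:, b]
        n_sentinel = int((~usable).sum())
        if n_sentinel:
            log.debug("round %d: %d samples excluded (missing at drawn SNPs)",
                      round_index, n_sentinel)
        active = np.flatnonzero(usable)
        sorted_active = active[np.argsort(keys[active], kind="stable")]
        sorted_keys = keys[sorted_active]
        new_this_round = 0
        run_start = 0
        for t in range(1, len(sorted_active) + 1):
            if t == len(sorted_active) or sorted_keys[t] != sorted_keys[run_start]:
                run = sorted_active[run_start:t]
                if len(run) > 1:
                    for a in range(len(run) - 1):
                        for b in range(a + 1, len(run)):
                            i, j = int(run[a]), int(run[b])
                            key = frozenset((fps.ids[i], fps.ids[j]))
                            if key in putative:
                                continue
                            putative.add(key)
                            st = pair_stats(fps[min(i, j)], fps[max(i, j)])
                            if (
                                st.n_compared >= min_compared
                                and st.n_mismatch < agmr_cutoff * st.n_compared
                            ):
                                confirmed[key] = IdenticalPair(
                                    st.id_a, st.id_b, st, "subquadratic"
                                )
                                new_this_round += 1
                run_start = t
        rounds_without_new = 0 if new_this_round else rounds_without_new + 1
    log.info("subquadratic scan: %d rounds, %d putative, %d confirmed",
             round_index, len(putative), len(confirmed))
    return list(confirmed.values())
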