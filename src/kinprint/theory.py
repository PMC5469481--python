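"""Closed-form expectations for genotype-mismatch statistics.

Under a homogeneous, random-mating population in Hardy-Weinberg
equilibrium, the probability that two individuals show a given
identity-by-state (IBS) count ``I`` at a bi-allelic SNP depends only on
their identity-by-descent (IBD) count ``Z`` at that SNP and the allele
frequency ``p``.  Averaging over an allele-frequency distribution gives
the expected all-genotype mismatch rate (AGMR, the fraction of SNPs with
``I < 2``) and the expected homozygous-genotype mismatch rate (HGMR, the
fraction of doubly homozygous SNPs carrying opposite homozygotes) for
each relationship class.  These expectations parameterize the Bayes
relationship classifier and serve as independent oracles for the
simulator and the pairwise kernels.

All integrands are polynomials in ``p``, so expectations over a uniform
frequency interval are computed by exact polynomial integration rather
than quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.stats import binom, norm

__all__ = [
    "IBDProfile",
    "FreqSpec",
    "ScanDesign",
    "PROFILES",
    "p_ibs_given_ibd",
    "expected_agmr",
    "expected_hgmr",
    "sd_hgmr",
    "sd_agmr",
    "quadratic_fn_rate",
    "quadratic_fp_rate",
    "subquadratic_sensitivity",
    "kinship",
    "separation_delta",
    "p_z0_from_i0",
]


@dataclass(frozen=True)
class IBDProfile:
    """P(Z=0), P(Z=1), P(Z=2) for a relationship class (no inbreeding)."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for p in (self.p0, self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("IBD probabilities must lie in [0, 1]")
        if not math.isclose(self.p0 + self.p1 + self.p2, 1.0, abs_tol=1e-9):
            raise ValueError("IBD probabilities must sum to 1")


#: Standard outbred relationship classes: identical pair / MZ twin (ID),
#: parent-offspring (PO), full sibling (FS), second degree (D2, e.g.
#: half sibling, avuncular, grandparent-grandchild), third degree (D3,
#: e.g. first cousin), unrelated (UN).
PROFILES: dict[str, IBDProfile] = {
    "ID": IBDProfile(0.0, 0.0, 1.0),
    "PO": IBDProfile(0.0, 1.0, 0.0),
    "FS": IBDProfile(0.25, 0.5, 0.25),
    "D2": IBDProfile(0.5, 0.5, 0.0),
    "D3": IBDProfile(0.75, 0.25, 0.0),
    "UN": IBDProfile(1.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class FreqSpec:
    """Allele-frequency model used when averaging per-SNP probabilities.

    ``uniform_interval`` treats the frequency as uniform on (lo, hi);
    ``explicit`` averages over a supplied list of per-SNP frequencies.
    """

    kind: str = "uniform_interval"
    lo: float = 0.1
    hi: float = 0.9
    freqs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform_interval", "explicit"):
            raise ValueError(f"unknown FreqSpec kind {self.kind!r}")
        if self.kind == "uniform_interval":
            if not 0.0 < self.lo < self.hi < 1.0:
                raise ValueError("need 0 < lo < hi < 1")
        else:
            if self.freqs is None or len(self.freqs) == 0:
                raise ValueError("explicit FreqSpec requires freqs")
            if not all(0.0 < f < 1.0 for f in self.freqs):
                raise ValueError("explicit frequencies must lie in (0, 1)")

    @classmethod
    def explicit(cls, freqs: Sequence[float]) -> "FreqSpec":
        return cls(kind="explicit", freqs=tuple(float(f) for f in freqs))

    def expect(self, poly: Polynomial) -> float:
        """E[poly(p)] under this frequency model (exact for uniform)."""
        if self.kind == "uniform_interval":
            anti = poly.integ()
            return float(anti(self.hi) - anti(self.lo)) / (self.hi - self.lo)
        return float(np.mean(poly(np.asarray(self.freqs))))


# polynomial building blocks, q = 1 - p
_P = Polynomial([0.0, 1.0])
_Q = Polynomial([1.0, -1.0])
# P(I = 2 | Z) per IBD state
_MATCH_Z0 = _P**4 + _Q**4 + 4 * (_P * _Q) ** 2
_MATCH_Z1 = _P**3 + _Q**3 + _P**2 * _Q + _P * _Q**2
# doubly homozygous outcomes: different (DO) / same (SO) homozygotes
_DO_Z0 = 2 * (_P * _Q) ** 2
_SO_Z0 = _P**4 + _Q**4
_SO_Z1 = _P**3 + _Q**3
_SO_Z2 = _P**2 + _Q**2


def p_ibs_given_ibd(p: float) -> np.ndarray:
    """3x3 table P(I|Z): rows I = 0,1,2; columns Z = 0,1,2.

    Derived by enumerating genotype outcomes for a pair sharing 0, 1 or 2
    alleles by descent at a SNP with allele frequencies (p, q).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    q = 1.0 - p
    return np.array(
        [
            [2 * p**2 * q**2, 0.0, 0.0],
            [4 * p**3 * q + 4 * p * q**3, 2 * p**2 * q + 2 * p * q**2, 0.0],
            [p**4 + q**4 + 4 * p**2 * q**2, p**3 + q**3 + p**2 * q + p * q**2, 1.0],
        ]
    )


def expected_agmr(profile: IBDProfile, freq: FreqSpec = FreqSpec()) -> float:
    """Expected AGMR = P(I<2) for a relationship, averaged over ``freq``.

    P(I<2|Z=2) = 0, so only the Z=0 and Z=1 components contribute.
    """
    return profile.p0 * (1.0 - freq.expect(_MATCH_Z0)) + profile.p1 * (
        1.0 - freq.expect(_MATCH_Z1)
    )


def _do_so(profile: IBDProfile, freq: FreqSpec) -> tuple[float, float]:
    p_do = profile.p0 * freq.expect(_DO_Z0)
    p_so = (
        profile.p0 * freq.expect(_SO_Z0)
        + profile.p1 * freq.expect(_SO_Z1)
        + profile.p2 * freq.expect(_SO_Z2)
    )
    return p_do, p_so


def expected_hgmr(profile: IBDProfile, freq: FreqSpec = FreqSpec()) -> float:
    """Expected HGMR = E[P(DO)] / E[P(DO) + P(SO)] over ``freq``.

    The ratio-of-expectations form: counts of DO and SO sites are sums of
    per-SNP Bernoulli outcomes, and the denominator's coefficient of
    variation is small, so E[DO/(DO+SO)] is well approximated by the
    quotient of expectations.
    """
    p_do, p_so = _do_so(profile, freq)
    return p_do / (p_do + p_so)


def sd_hgmr(profile: IBDProfile, freq: FreqSpec = FreqSpec(), S: int = 10_000) -> float:
    """Predicted SD of HGMR over a panel of ``S`` independent SNPs.

    Since the same-homozygote count dominates the denominator, the
    variance is driven almost entirely by the binomial variance of the
    different-homozygote count.
    """
    if S < 1:
        raise ValueError("panel size must be >= 1")
    p_do, p_so = _do_so(profile, freq)
    return math.sqrt(p_do * (1.0 - p_do) / S) / (p_do + p_so)


def sd_agmr(profile: IBDProfile, freq: FreqSpec = FreqSpec(), S: int = 10_000) -> float:
    """Binomial SD of AGMR over ``S`` independent SNPs (companion to sd_hgmr)."""
    if S < 1:
        raise ValueError("panel size must be >= 1")
    mu = expected_agmr(profile, freq)
    return math.sqrt(mu * (1.0 - mu) / S)


@dataclass(frozen=True)
class ScanDesign:
    """Parameters of the screening duplicate scanners.

    m: non-null genotype comparisons screened per pair; k: mismatch
    threshold at which a pair is abandoned; epsilon: per-genotype
    mismatch rate of a true identical pair (genotyping error); eta:
    mismatch rate of an unrelated pair; delta_rate: per-SNP
    missing-or-mismatch rate for the sort-based scanner; r: rounds;
    c: convergence rounds; S: full panel size.
    """

    m: int = 64
    k: int = 8
    epsilon: float = 0.0
    eta: float = 0.54
    S: int = 10_000
    delta_rate: float = 0.0
    r: int = 1
    c: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.m <= self.S:
            raise ValueError("need 0 <= k <= m <= S")
        for rate in (self.epsilon, self.eta, self.delta_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.r < 1:
            raise ValueError("r must be >= 1")


def quadratic_fn_rate(design: ScanDesign) -> float:
    """False-negative rate of the early-termination screen.

    A true identical pair with per-genotype mismatch rate epsilon is
    abandoned when >= k mismatches occur among the first m non-null
    comparisons: the upper binomial tail P(X >= k), X ~ Bin(m, epsilon).
    """
    if design.k == 0:
        return 1.0
    return float(binom.sf(design.k - 1, design.m, design.epsilon))


def quadratic_fp_rate(design: ScanDesign) -> float:
    """Probability an unrelated pair survives the screen: P(X < k), X ~ Bin(m, eta)."""
    if design.k == 0:
        return 0.0
    return float(binom.cdf(design.k - 1, design.m, design.eta))


def subquadratic_sensitivity(design: ScanDesign) -> tuple[float, float]:
    """(per-round sensitivity, FN after r rounds) of the sort-based scanner.

    With per-SNP missing-or-mismatch rate delta, the chance that none of
    the m drawn SNPs is corrupted for a true identical pair is ~e^{-m*delta}
    (Poisson approximation); after r independent rounds the residual
    false-negative rate is (1 - e^{-m*delta})^r.
    """
    per_round = math.exp(-design.m * design.delta_rate)
    return per_round, (1.0 - per_round) ** design.r


def kinship(profile: IBDProfile) -> float:
    """Kinship coefficient phi = P(Z=2)/2 + P(Z=1)/4."""
    return profile.p2 / 2.0 + profile.p1 / 4.0


def separation_delta(
    mu_x: float, sd_x: float, mu_y: float, sd_y: float
) -> tuple[float, float]:
    """Binormal separation statistic between two metric distributions.

    delta = (mu_x - mu_y) / sqrt(sd_x^2 + sd_y^2); AUC = Phi(delta).
    Larger |delta| means the two relationship classes are better
    separated by the metric.
    """
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("standard deviations must be positive")
    delta = (mu_x - mu_y) / math.hypot(sd_x, sd_y)
    return delta, float(norm.cdf(delta))


def p_z0_from_i0(rate_i0: float, p: float) -> float:
    """Method-of-moments P(Z=0) estimate from the observed rate of IBS-0 SNPs.

    P(Z=0) = P(I=0) / P(I=0|Z=0) with P(I=0|Z=0) = 2 p^2 q^2.  Documented
    helper only: the classifier works directly on mismatch rates and never
    estimates IBD probabilities, precisely because this ratio can exceed 1
    on observed data.
    """
    denom = p_ibs_given_ibd(p)[0, 0]
    return rate_i0 / denom
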