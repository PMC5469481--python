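import numpy as np
import pytest

from kinprint import SimConfig, simulate

# genotype codes
HOM_A1, HET, HOM_A2, MISSING = 0, 1, 2, 3


def scalar_pair_stats(codes_a, codes_b):
    """Independent per-SNP oracle for the bitwise pair kernel.

    Returns (n_compared, n_mismatch, n_both_hom, n_DO) via a plain loop
    over genotype codes.
    """
    nc = nm = nb = ndo = 0
    for a, b in zip(codes_a, codes_b):
        if a == MISSING or b == MISSING:
            continue
        nc += 1
        if a != b:
            nm += 1
        if a in (HOM_A1, HOM_A2) and b in (HOM_A1, HOM_A2):
            nb += 1
            if a != b:
                ndo += 1
    return nc, nm, nb, ndo


@pytest.fixture(scope="session")
def small_study():
    """A reusable simulated study: families, unrelated samples, duplicates."""
    cfg = SimConfig(
        S=2_000,
        n_families=4,
        family_template="nuclear",
        n_unrelated=30,
        n_planted_duplicates=3,
        error_rate=0.005,
        missing_rate=0.01,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_fps(small_study):
    return small_study.fingerprints()
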