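"""Synthetic fingerprint datasets with known truth.

Generates a fingerprint panel, founder genotypes under Hardy-Weinberg
equilibrium at per-SNP allele frequencies drawn once from a frequency
spec, offspring by Mendelian gene dropping (one allele transmitted per
parent, independently across SNPs — a homogeneous random-mating
population with no linkage), planted duplicate samples, genotyping
error and missingness.  Every downstream module is testable against the
returned truth table without any external data.

Error model: with probability ``error_rate`` a genotype is replaced by
one of the other two genotypes uniformly, so the realized mismatch rate
of a duplicate pair equals the error rate applied to the copy.
Duplicates copy the source sample's realized (post-error) genotypes and
then receive their own errors and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fingerprint import FingerprintSet, pack_genotypes
from .panel import FingerprintPanel, SNPRecord
from .pedigree import PedigreeGraph, expected_relationship
from .plinkio import MISSING, PlinkDataset, SampleRecord
from .theory import FreqSpec

__all__ = ["SimConfig", "TruthTable", "SimResult", "simulate", "plant_report",
           "simulate_panel", "to_plink"]

FAMILY_TEMPLATES = ("nuclear", "three_generation", "half_sib", "cousin")


@dataclass(frozen=True)
class SimConfig:
    """Study-generation settings.

    Defaults emulate the fingerprinting setting: a 10,000-SNP panel with
    allele frequencies uniform on (0.1, 0.9), modest genotyping error
    and per-call missingness.
    """

    S: int = 10_000
    freq: FreqSpec = field(default_factory=FreqSpec)
    n_families: int = 10
    family_template: str = "nuclear"
    n_unrelated: int = 50
    n_planted_duplicates: int = 5
    error_rate: float = 0.005
    missing_rate: float = 0.01
    duplicate_error_rate: float | None = None  # defaults to error_rate
    platform_mask: np.ndarray | None = None  # bool per SNP: False = not assayed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 64:
            raise ValueError("panel size must be >= 64")
        if self.family_template not in FAMILY_TEMPLATES:
            raise ValueError(f"unknown family template {self.family_template!r}")
        for r in (self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth: per-pair relationship and duplicate provenance."""

    relationships: dict[frozenset, str]  # close pairs only; absent => UN
    duplicates: set[frozenset]  # planted identical sample pairs
    subject_of: dict[str, str]  # sample -> subject (duplicates share a subject)

    def relationship(self, a: str, b: str) -> str:
        if self.subject_of.get(a, a) == self.subject_of.get(b, b):
            return "ID"
        return self.relationships.get(frozenset((a, b)), "UN")

    def pairs_with(self, label: str) -> set[frozenset]:
        if label == "ID":
            return set(self.duplicates)
        return {k for k, v in self.relationships.items() if v == label}


@dataclass
class SimResult:
    config: SimConfig
    panel: FingerprintPanel
    freqs: np.ndarray  # realized per-SNP alternate-allele frequencies
    genotypes: np.ndarray  # (n_samples, S) codes 0/1/2/3
    sample_ids: list[str]
    pedigree: PedigreeGraph
    truth: TruthTable

    def fingerprints(self) -> FingerprintSet:
        return pack_genotypes(self.genotypes, self.sample_ids, self.config.S)


_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


def simulate_panel(S: int, freq: FreqSpec, rng: np.random.Generator) -> tuple[FingerprintPanel, np.ndarray]:
    """Synthetic fingerprint panel: spaced autosomal non-complementary SNPs."""
    if freq.kind == "explicit":
        if len(freq.freqs) != S:
            raise ValueError("explicit FreqSpec must supply one frequency per SNP")
        freqs = np.asarray(freq.freqs, dtype=float)
    else:
        freqs = rng.uniform(freq.lo, freq.hi, size=S)
    per_chrom = -(-S // 22)
    snps = []
    for j in range(S):
        chrom = j // per_chrom + 1
        pos = (j % per_chrom + 1) * 60_000  # >= 50 kb spacing by construction
        a1, a2 = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        snps.append(
            SNPRecord(f"rs{j + 1}", str(chrom), pos, a1, a2,
                      maf=float(min(freqs[j], 1 - freqs[j])))
        )
    return FingerprintPanel(tuple(snps)), freqs


def _founder(rng: np.random.Generator, freqs: np.ndarray) -> np.ndarray:
    """HWE genotype draw: code = count of allele2, frequency q per SNP."""
    return rng.binomial(2, freqs).astype(np.uint8)


def _child(rng: np.random.Generator, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """Mendelian gene dropping: one allele per parent, independent across SNPs."""
    t_f = (rng.random(father.shape[0]) < father / 2.0).astype(np.uint8)
    t_m = (rng.random(mother.shape[0]) < mother / 2.0).astype(np.uint8)
    return t_f + t_m


def _build_family(
    template: str, fam: str, rng: np.random.Generator, freqs: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, tuple[str | None, str | None]], dict[str, str]]:
    """Genotypes, parent edges and sexes for one family of the given shape."""
    g: dict[str, np.ndarray] = {}
    parents: dict[str, tuple[str | None, str | None]] = {}
    sexes: dict[str, str] = {}

    def founder(name: str, sex: str) -> str:
        ind = f"{fam}_{name}"
        g[ind] = _founder(rng, freqs)
        parents[ind] = (None, None)
        sexes[ind] = sex
        return ind

    def child(name: str, father: str, mother: str, sex: str) -> str:
        ind = f"{fam}_{name}"
        g[ind] = _child(rng, g[father], g[mother])
        parents[ind] = (father, mother)
        sexes[ind] = sex
        return ind

    if template == "nuclear":
        f = founder("dad", "male")
        m = founder("mom", "female")
        child("kid1", f, m, "male")
        child("kid2", f, m, "female")
    elif template == "three_generation":
        gf = founder("gpa", "male")
        gm = founder("gma", "female")
        p = child("dad", gf, gm, "male")
        sp = founder("mom", "female")
        child("kid1", p, sp, "male")
        child("kid2", p, sp, "female")
    elif template == "half_sib":
        m = founder("mom", "female")
        f1 = founder("dad1", "male")
        f2 = founder("dad2", "male")
        child("kid1", f1, m, "male")
        child("kid2", f2, m, "female")
    elif template == "cousin":
        gf = founder("gpa", "male")
        gm = founder("gma", "female")
        s1 = child("dad", gf, gm, "male")
        s2 = child("aunt", gf, gm, "female")
        sp1 = founder("mom", "female")
        sp2 = founder("uncle", "male")
        child("kid1", s1, sp1, "male")
        child("cousin1", sp2, s2, "female")
    return g, parents, sexes


def _apply_error(
    rng: np.random.Generator, codes: np.ndarray, rate: float
) -> np.ndarray:
    """Replace each genotype with one of the other two, with probability ``rate``."""
    if rate == 0.0:
        return codes
    out = codes.copy()
    hit = rng.random(codes.shape) < rate
    shift = rng.integers(1, 3, size=codes.shape).astype(np.uint8)
    out[hit] = ((codes[hit] + shift[hit]) % 3).astype(np.uint8)
    return out


def simulate(config: SimConfig) -> SimResult:
    """Generate a study: families, unrelated samples, duplicates, noise.

    Deterministic for a fixed config (seed included).  Sample ids equal
    individual ids; planted duplicates are named ``<source>_dup<i>`` and
    share the source's subject in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    panel, freqs = simulate_panel(config.S, config.freq, rng)

    genotypes: dict[str, np.ndarray] = {}
    parents: dict[str, tuple[str | None, str | None]] = {}
    families: dict[str, str] = {}
    sexes: dict[str, str] = {}
    for i in range(config.n_families):
        fam = f"F{i + 1}"
        g, par, sx = _build_family(config.family_template, fam, rng, freqs)
        genotypes.update(g)
        parents.update(par)
        sexes.update(sx)
        families.update({ind: fam for ind in g})
    for i in range(config.n_unrelated):
        ind = f"U{i + 1}"
        genotypes[ind] = _founder(rng, freqs)
        parents[ind] = (None, None)
        families[ind] = f"FU{i + 1}"
        sexes[ind] = "male" if i % 2 == 0 else "female"

    sample_ids = list(genotypes)
    obs = {sid: _apply_error(rng, genotypes[sid], config.error_rate)
           for sid in sample_ids}

    dup_rate = (
        config.error_rate
        if config.duplicate_error_rate is None
        else config.duplicate_error_rate
    )
    duplicates: set[frozenset] = set()
    subject_of = {sid: sid for sid in sample_ids}
    if config.n_planted_duplicates:
        if config.n_planted_duplicates > len(sample_ids):
            raise ValueError("more planted duplicates than source samples")
        sources = rng.choice(
            np.array(sample_ids), size=config.n_planted_duplicates, replace=False
        )
        for i, src in enumerate(sources):
            dup = f"{src}_dup{i + 1}"
            obs[dup] = _apply_error(rng, obs[str(src)], dup_rate)
            subject_of[dup] = str(src)
            families[dup] = families[str(src)]
            sexes[dup] = sexes[str(src)]
            duplicates.add(frozenset((str(src), dup)))
            sample_ids.append(dup)

    codes = np.stack([obs[sid] for sid in sample_ids]).astype(np.uint8)
    if config.missing_rate:
        codes[rng.random(codes.shape) < config.missing_rate] = MISSING
    if config.platform_mask is not None:
        mask = np.asarray(config.platform_mask, dtype=bool)
        if mask.shape != (config.S,):
            raise ValueError("platform_mask must be a boolean vector over the panel")
        codes[:, ~mask] = MISSING

    ped = PedigreeGraph(
        parents=parents, families=families, sexes=sexes,
        sample_to_subject={sid: subject_of[sid] for sid in sample_ids},
    )
    relationships: dict[frozenset, str] = {}
    inds = [sid for sid in sample_ids if sid in parents]
    by_family: dict[str, list[str]] = {}
    for ind in inds:
        by_family.setdefault(families[ind], []).append(ind)
    for members in by_family.values():
        for i in range(len(members) - 1):
            for j in range(i + 1, len(members)):
                rel = expected_relationship(ped, members[i], members[j])
                if rel in ("PO", "FS", "D2", "D3"):
                    relationships[frozenset((members[i], members[j]))] = rel

    truth = TruthTable(
        relationships=relationships, duplicates=duplicates, subject_of=subject_of
    )
    return SimResult(
        config=config, panel=panel, freqs=freqs, genotypes=codes,
        sample_ids=sample_ids, pedigree=ped, truth=truth,
    )


def to_plink(result: SimResult) -> PlinkDataset:
    """Express a simulated study as an in-memory PLINK dataset.

    Genotype codes count copies of allele2, so hom-allele1 = code 0.
    """
    samples = []
    for sid in result.sample_ids:
        f, m = result.pedigree.parents_of(sid)
        samples.append(
            SampleRecord(
                family_id=result.pedigree.families.get(sid, "F0"),
                sample_id=sid,
                father_id=f,
                mother_id=m,
                sex=result.pedigree.sexes.get(sid, "unknown"),
            )
        )
    return PlinkDataset(
        snps=list(result.panel),
        samples=samples,
        genotypes=result.genotypes.T.copy(),
    )


def plant_report(
    truth: TruthTable,
    detected_duplicates: set[frozenset] | None = None,
    predicted_labels: dict[frozenset, str] | None = None,
) -> dict:
    """Sensitivity/FDR of detections against the planted truth.

    ``detected_duplicates`` is compared exactly against the planted
    duplicate set; ``predicted_labels`` (pair -> label) yields a per-
    relationship confusion summary.
    """
    out: dict = {}
    if detected_duplicates is not None:
        true_set = truth.duplicates
        tp = len(detected_duplicates & true_set)
        out["duplicates"] = {
            "n_true": len(true_set),
            "n_detected": len(detected_duplicates),
            "sensitivity": tp / len(true_set) if true_set else float("nan"),
            "fdr": (
                (len(detected_duplicates) - tp) / len(detected_duplicates)
                if detected_duplicates
                else 0.0
            ),
        }
    if predicted_labels is not None:
        per_rel: dict[str, dict] = {}
        for rel in ("PO", "FS", "D2", "D3"):
            true_pairs = truth.pairs_with(rel)
            correct = sum(
                1 for p in true_pairs if predicted_labels.get(p) == rel
            )
            called = {p for p, lab in predicted_labels.items() if lab == rel}
            fp = sum(1 for p in called if truth.relationship(*tuple(p)) != rel)
            per_rel[rel] = {
                "n_true": len(true_pairs),
                "sensitivity": correct / len(true_pairs) if true_pairs else float("nan"),
                "fdr": fp / len(called) if called else 0.0,
            }
        out["relationships"] = per_rel
    return out
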