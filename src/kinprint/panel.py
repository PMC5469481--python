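"""Fingerprint SNP panels: selection rules and cross-platform allele harmonization.

A fingerprint panel is a fixed, ordered set of common, well-spaced,
bi-allelic autosomal SNPs with no strand-ambiguous (A/T or G/C) allele
pairs, used as the comparison universe for every sample regardless of
which genotyping platform produced it.  Excluding complementary allele
pairs lets genotypes from assays reporting opposite DNA strands be
reconciled without knowing strand orientation: an A/G SNP typed as T/C
elsewhere can only be the complement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SNPRecord",
    "FingerprintPanel",
    "select_panel",
    "harmonize_alleles",
    "read_panel",
    "write_panel",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass(frozen=True)
class SNPRecord:
    """One bi-allelic SNP: identifier, 1-based position, two alleles, optional MAF."""

    marker_id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str
    maf: float | None = None

    def is_valid_biallelic(self) -> bool:
        return (
            self.allele1 in COMPLEMENT
            and self.allele2 in COMPLEMENT
            and self.allele1 != self.allele2
        )

    def is_complementary(self) -> bool:
        """True for strand-ambiguous pairs (A/T or G/C)."""
        return COMPLEMENT.get(self.allele1) == self.allele2

    def is_autosomal(self) -> bool:
        return self.chromosome.removeprefix("chr") in _AUTOSOMES


@dataclass(frozen=True)
class FingerprintPanel:
    """Ordered fingerprint SNP list; order defines bit positions in packed fingerprints."""

    snps: tuple[SNPRecord, ...]

    def __post_init__(self) -> None:
        key = [(s.chromosome.removeprefix("chr"), s.position) for s in self.snps]
        sort_key = [(int(c) if c.isdigit() else 99, p) for c, p in key]
        if sort_key != sorted(sort_key):
            raise ValueError("panel SNPs must be sorted by (chromosome, position)")

    @property
    def size(self) -> int:
        return len(self.snps)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def by_marker_id(self) -> dict[str, int]:
        return {s.marker_id: i for i, s in enumerate(self.snps)}

    def by_position(self) -> dict[tuple[str, int], int]:
        return {
            (s.chromosome.removeprefix("chr"), s.position): i
            for i, s in enumerate(self.snps)
        }


def _chrom_sort_key(snp: SNPRecord) -> tuple[int, int]:
    c = snp.chromosome.removeprefix("chr")
    return (int(c) if c.isdigit() else 99, snp.position)


def select_panel(
    candidates: Iterable[SNPRecord],
    platform_presence: Mapping[str, float] | None = None,
    freq_source: Mapping[str, float] | None = None,
    min_platform: float = 0.8,
    min_maf: float = 0.17,
    min_spacing: int = 50_000,
) -> FingerprintPanel:
    """Apply the fingerprint selection rules and return the surviving panel.

    A candidate survives if it (1) appears on at least ``min_platform`` of
    the genotyping platforms, (2) is a valid bi-allelic autosomal SNP,
    (3) has MAF > ``min_maf`` (when a frequency source is supplied),
    (4) is at least ``min_spacing`` bp from the previously retained SNP on
    the same chromosome (greedy left-to-right), and (5) is not
    strand-ambiguous (no A/T, no G/C).  Returns however many candidates
    survive; a warning is logged with the number rejected.
    """
    ordered = sorted(candidates, key=_chrom_sort_key)
    kept: list[SNPRecord] = []
    n_rejected = 0
    last_kept: dict[str, int] = {}
    for snp in ordered:
        maf = snp.maf
        if freq_source is not None and snp.marker_id in freq_source:
            maf = freq_source[snp.marker_id]
        ok = (
            snp.is_valid_biallelic()
            and snp.is_autosomal()
            and not snp.is_complementary()
            and (
                platform_presence is None
                or platform_presence.get(snp.marker_id, 0.0) >= min_platform
            )
            and (maf is None or maf > min_maf)
        )
        if ok:
            chrom = snp.chromosome.removeprefix("chr")
            prev = last_kept.get(chrom)
            if prev is not None and snp.position - prev < min_spacing:
                ok = False
        if ok:
            chrom = snp.chromosome.removeprefix("chr")
            last_kept[chrom] = snp.position
            if freq_source is not None and snp.marker_id in freq_source:
                snp = SNPRecord(
                    snp.marker_id,
                    snp.chromosome,
                    snp.position,
                    snp.allele1,
                    snp.allele2,
                    maf=freq_source[snp.marker_id],
                )
            kept.append(snp)
        else:
            n_rejected += 1
    if n_rejected:
        log.warning("select_panel rejected %d of %d candidates", n_rejected, len(ordered))
    return FingerprintPanel(tuple(kept))


def harmonize_alleles(dataset_snp: SNPRecord, panel_snp: SNPRecord) -> str:
    """Orientation of a dataset SNP's alleles relative to the panel's canonical pair.

    Returns one of ``same``, ``swapped``, ``flipped`` (opposite strand),
    ``swapped_flipped`` or ``incompatible``.  Requires the panel SNP to be
    non-complementary, which is what makes the orientation unambiguous.
    ``swapped`` orientations mean the dataset's allele1/allele2 roles are
    reversed, so hom-allele1 and hom-allele2 genotype codes must be
    exchanged downstream.
    """
    if panel_snp.is_complementary():
        raise ValueError(
            f"panel SNP {panel_snp.marker_id} has complementary alleles; "
            "orientation is ambiguous"
        )
    a1, a2 = dataset_snp.allele1, dataset_snp.allele2
    p1, p2 = panel_snp.allele1, panel_snp.allele2
    if (a1, a2) == (p1, p2):
        return "same"
    if (a1, a2) == (p2, p1):
        return "swapped"
    f1, f2 = COMPLEMENT.get(a1), COMPLEMENT.get(a2)
    if (f1, f2) == (p1, p2):
        return "flipped"
    if (f1, f2) == (p2, p1):
        return "swapped_flipped"
    return "incompatible"


_PANEL_COLUMNS = ["marker_id", "chrom", "pos", "allele1", "allele2", "maf"]


def write_panel(panel: FingerprintPanel, path) -> None:
    """Write a panel as TSV: marker_id, chrom, pos, allele1, allele2, maf."""
    df = pd.DataFrame(
        [
            (s.marker_id, s.chromosome, s.position, s.allele1, s.allele2,
             "" if s.maf is None else s.maf)
            for s in panel
        ],
        columns=_PANEL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> FingerprintPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} lacks columns: {sorted(missing)}")
    snps = tuple(
        SNPRecord(
            str(r.marker_id),
            str(r.chrom),
            int(r.pos),
            str(r.allele1),
            str(r.allele2),
            maf=None if pd.isna(r.maf) else float(r.maf),
        )
        for r in df.itertuples()
    )
    return FingerprintPanel(snps)
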