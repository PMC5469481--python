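"""Minimal PLINK 1.x binary (.bed/.bim/.fam) reader and writer.

Only the SNP-major dialect (magic bytes 0x6C 0x1B, mode 0x01) is
supported.  Each SNP occupies ceil(n_samples/4) bytes; sample ``j`` sits
in bits ``2*(j % 4)`` of byte ``j // 4`` with the PLINK code table
00 = homozygous allele1, 01 = missing, 10 = heterozygous,
11 = homozygous allele2.  Internally genotypes are re-coded to
0 = hom-allele1, 1 = het, 2 = hom-allele2, 3 = missing (the packed
fingerprint convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel import SNPRecord

__all__ = [
    "SampleRecord",
    "PlinkDataset",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "HOM_A1",
    "HET",
    "HOM_A2",
    "MISSING",
]

# internal genotype codes (2-bit): chosen so that "is homozygous" is the
# complement of the low bit and "is missing" is hi AND lo.
HOM_A1, HET, HOM_A2, MISSING = 0, 1, 2, 3

_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = 0x01

# PLINK 2-bit value -> internal code
_FROM_PLINK = np.array([HOM_A1, MISSING, HET, HOM_A2], dtype=np.uint8)
# internal code -> PLINK 2-bit value
_TO_PLINK = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)


class PlinkFormatError(ValueError):
    """Malformed or unsupported PLINK binary input."""


@dataclass(frozen=True)
class SampleRecord:
    """One .fam line: family, individual, parents, sex."""

    family_id: str
    sample_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # male / female / unknown


@dataclass
class PlinkDataset:
    """Parsed dataset: SNP metadata, sample metadata and a genotype matrix.

    ``genotypes`` has shape (n_snps, n_samples) with the internal codes.
    """

    snps: list[SNPRecord]
    samples: list[SampleRecord]
    genotypes: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _parse_sex(token: str) -> str:
    return {"1": "male", "2": "female"}.get(token, "unknown")


def _read_fam(fam_path) -> list[SampleRecord]:
    samples = []
    seen: set[str] = set()
    for line in Path(fam_path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 6:
            raise PlinkFormatError(f"{fam_path}: expected 6 columns, got {len(f)}")
        if f[1] in seen:
            raise PlinkFormatError(f"{fam_path}: duplicate sample id {f[1]!r}")
        seen.add(f[1])
        samples.append(
            SampleRecord(
                family_id=f[0],
                sample_id=f[1],
                father_id=None if f[2] == "0" else f[2],
                mother_id=None if f[3] == "0" else f[3],
                sex=_parse_sex(f[4]),
            )
        )
    return samples


def _read_bim(bim_path) -> list[SNPRecord]:
    snps = []
    for line in Path(bim_path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6:
            raise PlinkFormatError(f"{bim_path}: expected 6 columns, got {len(f)}")
        chrom, marker, _cm, pos, a1, a2 = f
        snps.append(SNPRecord(marker, chrom, int(pos), a1, a2))
    return snps


def read_plink(bed_path, bim_path=None, fam_path=None) -> PlinkDataset:
    """Read a .bed/.bim/.fam trio (paths inferred from ``bed_path`` if omitted)."""
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    snps = _read_bim(bim_path)
    samples = _read_fam(fam_path)
    n_snps, n_samples = len(snps), len(samples)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK .bed file)")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{bed_path}: mode byte 0x{raw[2]:02x}; only SNP-major (0x01) is supported"
        )
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: file length {len(raw)} != expected {expected} "
            f"({n_snps} SNPs x ceil({n_samples}/4) bytes + 3)"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    # expand each byte into four 2-bit fields, low bits first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts) & 0b11
    codes = codes.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    genotypes = _FROM_PLINK[codes]
    return PlinkDataset(snps=snps, samples=samples, genotypes=genotypes)


def write_plink(dataset: PlinkDataset, prefix) -> None:
    """Write a dataset as ``prefix``.bed/.bim/.fam (SNP-major)."""
    prefix = Path(prefix)
    n_snps, n_samples = dataset.genotypes.shape
    if n_snps != len(dataset.snps) or n_samples != len(dataset.samples):
        raise ValueError("genotype matrix shape disagrees with metadata")

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in dataset.snps:
            fh.write(
                f"{s.chromosome}\t{s.marker_id}\t0\t{s.position}\t{s.allele1}\t{s.allele2}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        sex_code = {"male": "1", "female": "2", "unknown": "0"}
        for r in dataset.samples:
            fh.write(
                f"{r.family_id}\t{r.sample_id}\t{r.father_id or 0}\t"
                f"{r.mother_id or 0}\t{sex_code[r.sex]}\t-9\n"
            )

    plink_codes = _TO_PLINK[dataset.genotypes]
    bytes_per_snp = (n_samples + 3) // 4
    padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = plink_codes
    quads = padded.reshape(n_snps, bytes_per_snp, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
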