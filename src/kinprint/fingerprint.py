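"""Bit-packed genotype fingerprints.

Genotypes over the fingerprint panel are stored two bits per SNP, split
across two parallel 64-bit words: SNP ``j`` occupies bit ``j % 64`` of
high word ``j // 64`` and the same bit of the low word.  The code table

    (hi, lo) = (0,0) hom-allele1, (0,1) het, (1,0) hom-allele2, (1,1) missing

is chosen so that "is homozygous" is ``NOT lo`` and "is missing" is
``hi AND lo``, which lets the pairwise mismatch kernels run on whole
words with a handful of bitwise operations.  Pad bits beyond the panel
size are set to missing so popcounts never need length masking.

Persistent layout (``save_fingerprints``): ASCII magic ``KPFP1``,
little-endian uint32 panel size S and uint32 n_samples, then per sample a
uint16 id length + UTF-8 id + uint32 n_genotyped, then the high words of
all samples followed by the low words, each an (n_samples, ceil(S/64))
little-endian uint64 array in C order.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .panel import FingerprintPanel, harmonize_alleles
from .plinkio import HET, HOM_A1, HOM_A2, MISSING, PlinkDataset

log = logging.getLogger(__name__)

__all__ = [
    "PackedFingerprint",
    "FingerprintSet",
    "pack_genotypes",
    "unpack_genotypes",
    "extract_fingerprints",
    "save_fingerprints",
    "load_fingerprints",
]

_MAGIC = b"KPFP1"


@dataclass(frozen=True)
class PackedFingerprint:
    """One sample's panel genotypes in paired 64-bit words."""

    sample_id: str
    words_hi: np.ndarray  # uint64, length ceil(S/64)
    words_lo: np.ndarray
    n_snps: int
    n_genotyped: int

    def codes(self) -> np.ndarray:
        """Unpack to per-SNP codes 0=hom-a1, 1=het, 2=hom-a2, 3=missing."""
        return _unpack_row(self.words_hi, self.words_lo, self.n_snps)


class FingerprintSet:
    """Fingerprints of many samples over one panel, stacked for vector kernels.

    ``hi`` and ``lo`` have shape (n_samples, ceil(S/64)).
    """

    def __init__(
        self,
        ids: Sequence[str],
        hi: np.ndarray,
        lo: np.ndarray,
        n_snps: int,
        n_genotyped: np.ndarray | None = None,
    ):
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")
        self.ids = list(ids)
        self.hi = np.ascontiguousarray(hi, dtype=np.uint64)
        self.lo = np.ascontiguousarray(lo, dtype=np.uint64)
        self.n_snps = int(n_snps)
        expected_words = (self.n_snps + 63) // 64
        if self.hi.shape != (len(self.ids), expected_words) or self.hi.shape != self.lo.shape:
            raise ValueError("word array shape mismatch")
        if n_genotyped is None:
            miss = np.bitwise_count(self.hi & self.lo).sum(axis=1).astype(np.int64)
            n_genotyped = self.n_snps - (miss - (expected_words * 64 - self.n_snps))
        self.n_genotyped = np.asarray(n_genotyped, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> PackedFingerprint:
        return PackedFingerprint(
            sample_id=self.ids[i],
            words_hi=self.hi[i],
            words_lo=self.lo[i],
            n_snps=self.n_snps,
            n_genotyped=int(self.n_genotyped[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def index_of(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def codes(self) -> np.ndarray:
        """Unpack all samples to an (n_samples, S) code matrix."""
        return unpack_genotypes(self)

    def low_genotyped(self, min_genotyped: int = 1000) -> list[str]:
        """Sample ids with fewer genotyped panel SNPs than ``min_genotyped``."""
        return [
            sid
            for sid, n in zip(self.ids, self.n_genotyped)
            if n < min_genotyped
        ]


def _pack_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, S = codes.shape
    W = (S + 63) // 64
    padded = np.full((n, W * 64), MISSING, dtype=np.uint8)
    padded[:, :S] = codes
    bits_hi = (padded >> 1) & 1
    bits_lo = padded & 1
    weights = (np.uint64(1) << np.arange(64, dtype=np.uint64))
    hi = (bits_hi.reshape(n, W, 64).astype(np.uint64) * weights).sum(
        axis=2, dtype=np.uint64
    )
    lo = (bits_lo.reshape(n, W, 64).astype(np.uint64) * weights).sum(
        axis=2, dtype=np.uint64
    )
    return hi, lo


def _unpack_row(hi: np.ndarray, lo: np.ndarray, n_snps: int) -> np.ndarray:
    W = hi.shape[0]
    shifts = np.arange(64, dtype=np.uint64)
    bits_hi = ((hi[:, None] >> shifts) & np.uint64(1)).astype(np.uint8)
    bits_lo = ((lo[:, None] >> shifts) & np.uint64(1)).astype(np.uint8)
    codes = (bits_hi << 1) | bits_lo
    return codes.reshape(W * 64)[:n_snps]


def pack_genotypes(
    codes: np.ndarray, ids: Sequence[str], n_snps: int | None = None
) -> FingerprintSet:
    """Pack an (n_samples, S) genotype-code matrix into a FingerprintSet."""
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.ndim != 2:
        raise ValueError("expected a 2-D (n_samples, S) code matrix")
    if n_snps is None:
        n_snps = codes.shape[1]
    hi, lo = _pack_matrix(codes)
    n_genotyped = (codes != MISSING).sum(axis=1).astype(np.int64)
    return FingerprintSet(ids, hi, lo, n_snps, n_genotyped)


def unpack_genotypes(fps: FingerprintSet) -> np.ndarray:
    shifts = np.arange(64, dtype=np.uint64)
    bits_hi = ((fps.hi[:, :, None] >> shifts) & np.uint64(1)).astype(np.uint8)
    bits_lo = ((fps.lo[:, :, None] >> shifts) & np.uint64(1)).astype(np.uint8)
    codes = (bits_hi << 1) | bits_lo
    return codes.reshape(len(fps), -1)[:, : fps.n_snps]


# genotype-code remap for swapped allele orientations (hom-a1 <-> hom-a2)
_SWAP = np.array([HOM_A2, HET, HOM_A1, MISSING], dtype=np.uint8)
_KEEP = np.array([HOM_A1, HET, HOM_A2, MISSING], dtype=np.uint8)


def extract_fingerprints(
    dataset: PlinkDataset,
    panel: FingerprintPanel,
    match_key: str = "rsid",
    min_genotyped: int = 1000,
    dataset_prefix: str | None = None,
) -> FingerprintSet:
    """Project a PLINK dataset onto the panel and pack fingerprints.

    Panel SNPs are located in the dataset by marker id (``match_key='rsid'``,
    with a chromosome/position fallback for markers absent by id) or by
    position alone (``match_key='position'``).  Dataset alleles are
    harmonized to the panel's canonical pair; swapped orientations have
    their homozygote codes exchanged, incompatible or monomorphic ("0"
    allele) records and panel SNPs missing from the dataset are encoded
    missing.  Samples genotyped at fewer than ``min_genotyped`` panel SNPs
    are logged (and reported by ``FingerprintSet.low_genotyped``).
    """
    if match_key not in ("rsid", "position"):
        raise ValueError("match_key must be 'rsid' or 'position'")
    by_id = {s.marker_id: i for i, s in enumerate(dataset.snps)}
    by_pos = {
        (s.chromosome.removeprefix("chr"), s.position): i
        for i, s in enumerate(dataset.snps)
    }

    n_samples = dataset.n_samples
    S = panel.size
    codes = np.full((n_samples, S), MISSING, dtype=np.uint8)
    n_incompatible = 0
    for j, psnp in enumerate(panel):
        idx = None
        if match_key == "rsid":
            idx = by_id.get(psnp.marker_id)
        if idx is None:
            idx = by_pos.get((psnp.chromosome.removeprefix("chr"), psnp.position))
        if idx is None:
            continue
        dsnp = dataset.snps[idx]
        if "0" in (dsnp.allele1, dsnp.allele2) or not dsnp.is_valid_biallelic():
            n_incompatible += 1
            continue
        orientation = harmonize_alleles(dsnp, psnp)
        if orientation == "incompatible":
            n_incompatible += 1
            continue
        remap = _SWAP if orientation in ("swapped", "swapped_flipped") else _KEEP
        codes[:, j] = remap[dataset.genotypes[idx]]
    if n_incompatible:
        log.warning(
            "%d panel SNPs present in dataset but allele-incompatible; encoded missing",
            n_incompatible,
        )

    ids = [s.sample_id for s in dataset.samples]
    if dataset_prefix:
        ids = [f"{dataset_prefix}:{sid}" for sid in ids]
    fps = pack_genotypes(codes, ids, S)
    low = fps.low_genotyped(min_genotyped)
    if low:
        log.warning(
            "%d samples have fewer than %d genotyped panel SNPs", len(low), min_genotyped
        )
    return fps


def merge_fingerprints(sets: Iterable[FingerprintSet]) -> FingerprintSet:
    """Concatenate fingerprint sets built on the same panel.

    Duplicate sample ids across sets are disambiguated with a numeric
    dataset prefix and logged.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("no fingerprint sets to merge")
    S = sets[0].n_snps
    if any(fs.n_snps != S for fs in sets):
        raise ValueError("fingerprint sets built on different panels")
    ids: list[str] = []
    seen: set[str] = set()
    for d, fs in enumerate(sets):
        for sid in fs.ids:
            if sid in seen:
                new = f"ds{d}:{sid}"
                log.warning("duplicate sample id %r renamed to %r", sid, new)
                sid = new
            seen.add(sid)
            ids.append(sid)
    hi = np.vstack([fs.hi for fs in sets])
    lo = np.vstack([fs.lo for fs in sets])
    n_gt = np.concatenate([fs.n_genotyped for fs in sets])
    return FingerprintSet(ids, hi, lo, S, n_gt)


def save_fingerprints(fps: FingerprintSet, path) -> None:
    """Write a FingerprintSet in the flat binary layout documented above."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<II", fps.n_snps, len(fps)))
        for sid, n in zip(fps.ids, fps.n_genotyped):
            b = sid.encode()
            fh.write(struct.pack("<H", len(b)))
            fh.write(b)
            fh.write(struct.pack("<I", int(n)))
        fh.write(fps.hi.astype("<u8").tobytes())
        fh.write(fps.lo.astype("<u8").tobytes())


def load_fingerprints(path) -> FingerprintSet:
    raw = Path(path).read_bytes()
    if raw[: len(_MAGIC)] != _MAGIC:
        raise ValueError(f"{path}: not a kinprint fingerprint file")
    off = len(_MAGIC)
    S, n = struct.unpack_from("<II", raw, off)
    off += 8
    ids, n_gt = [], []
    for _ in range(n):
        (ln,) = struct.unpack_from("<H", raw, off)
        off += 2
        ids.append(raw[off : off + ln].decode())
        off += ln
        (g,) = struct.unpack_from("<I", raw, off)
        off += 4
        n_gt.append(g)
    W = (S + 63) // 64
    hi = np.frombuffer(raw, dtype="<u8", count=n * W, offset=off).reshape(n, W)
    off += n * W * 8
    lo = np.frombuffer(raw, dtype="<u8", count=n * W, offset=off).reshape(n, W)
    return FingerprintSet(ids, hi.copy(), lo.copy(), S, np.array(n_gt, dtype=np.int64))
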