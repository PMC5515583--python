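"""Reading and writing MSMC-style "multihetsep" variant tables.

The multihetsep format is a tab-separated text file with one row per
segregating site and at least four columns::

    chromosome  position  called_since_last  alleles

``position`` is 1-based, ``called_since_last`` counts the confidently
called sites since the previous segregating site (including the site
itself), and ``alleles`` is a string of observed bases with one character
per haplotype.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["VariantStream", "read_multihetsep", "write_multihetsep", "from_vcf"]


@dataclass
class VariantStream:
    """Columnar container for multihetsep records.

    Positions must be strictly increasing within each chromosome, the
    called-site count must be >= 1 for every record, and the allele
    string must have a constant length (the number of haplotypes).
    """

    chrom: np.ndarray
    pos: np.ndarray
    called: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.called = np.asarray(self.called, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.called) == len(self.alleles) == n):
            raise ValueError("VariantStream columns must have equal length")
        if n == 0:
            return
        if np.any(self.called < 1):
            raise ValueError("called_since_last must be >= 1 for every record")
        lengths = {len(a) for a in self.alleles}
        if len(lengths) != 1:
            raise ValueError(f"allele strings have inconsistent lengths: {sorted(lengths)}")
        for name, p in self.by_chromosome():
            if np.any(np.diff(p.pos) <= 0):
                i = int(np.argmax(np.diff(p.pos) <= 0))
                raise ValueError(
                    f"positions not strictly increasing on chromosome {name} "
                    f"(record {i + 1} -> {i + 2})"
                )

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_haplotypes(self) -> int:
        if len(self) == 0:
            raise ValueError("empty stream has no haplotype count")
        return len(self.alleles[0])

    def chromosomes(self) -> list:
        """Chromosome names in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def by_chromosome(self) -> Iterator[tuple]:
        """Yield ``(name, sub-stream)`` pairs in order of appearance."""
        for name in self.chromosomes():
            mask = self.chrom == name
            sub = VariantStream.__new__(VariantStream)
            sub.chrom = self.chrom[mask]
            sub.pos = self.pos[mask]
            sub.called = self.called[mask]
            sub.alleles = self.alleles[mask]
            yield name, sub

    @staticmethod
    def empty() -> "VariantStream":
        return VariantStream(
            np.array([], dtype=object),
            np.array([], dtype=np.int64),
            np.array([], dtype=np.int64),
            np.array([], dtype=object),
        )

    @staticmethod
    def concatenate(streams: Iterable["VariantStream"]) -> "VariantStream":
        streams = [s for s in streams if len(s)]
        if not streams:
            return VariantStream.empty()
        return VariantStream(
            np.concatenate([s.chrom for s in streams]),
            np.concatenate([s.pos for s in streams]),
            np.concatenate([s.called for s in streams]),
            np.concatenate([s.alleles for s in streams]),
        )


def read_multihetsep(path) -> VariantStream:
    """Parse a multihetsep file into a :class:`VariantStream`.

    Raises ``ValueError`` naming the offending line on malformed rows or
    non-monotone positions.
    """
    chroms: list = []
    pos: list = []
    called: list = []
    alleles: list = []
    last: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 tab-separated columns")
            c = parts[0]
            try:
                p = int(parts[1])
                n_called = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer position or called count") from exc
            if n_called < 1:
                raise ValueError(f"{path}: line {lineno}: called_since_last must be >= 1")
            if c in last and p <= last[c]:
                raise ValueError(
                    f"{path}: line {lineno}: position {p} not greater than previous "
                    f"position {last[c]} on chromosome {c}"
                )
            last[c] = p
            chroms.append(c)
            pos.append(p)
            called.append(n_called)
            alleles.append(parts[3])
    if not pos:
        return VariantStream.empty()
    return VariantStream(np.array(chroms, dtype=object), pos, called, np.array(alleles, dtype=object))


def write_multihetsep(stream: VariantStream, path) -> None:
    with open(path, "w") as fh:
        for c, p, n, a in zip(stream.chrom, stream.pos, stream.called, stream.alleles):
            fh.write(f"{c}\t{p}\t{n}\t{a}\n")


def from_vcf(path, samples=None) -> VariantStream:
    """Convert a VCF with diploid genotypes to a :class:`VariantStream`.

    Delegates parsing to :mod:`cyvcf2`. Only biallelic SNPs with fully
    called genotypes are kept; ``called_since_last`` is approximated by
    the distance to the previous kept site (no mask information).
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), samples=samples)
    chroms: list = []
    pos: list = []
    called: list = []
    alleles: list = []
    last: dict = {}
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            continue
        gts = rec.genotype.array()[:, :2]
        if (gts < 0).any():
            continue
        bases = [rec.REF] + rec.ALT
        astr = "".join(bases[g] for g in gts.reshape(-1))
        if len(set(astr)) < 2:
            continue
        prev = last.get(rec.CHROM, 0)
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        called.append(max(rec.POS - prev, 1))
        alleles.append(astr)
        last[rec.CHROM] = rec.POS
    if not pos:
        return VariantStream.empty()
    return VariantStream(np.array(chroms, dtype=object), pos, called, np.array(alleles, dtype=object))
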