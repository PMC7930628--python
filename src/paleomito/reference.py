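"""Circular mitochondrial reference model, variants, haplotypes and loci.

The human mtDNA reference (rCRS) is a 16,569 bp circle with community-standard
1-based coordinates and an N placeholder at position 3107.  This module models
the circle (wrap-around arithmetic, 500 bp elongation used for circular read
mapping), normalized variants, haplotypes materialized from a variant set, and
a locus map used to classify variant positions by biotype.

A packaged synthetic 16,569 bp stand-in reference (random sequence with
rCRS-like base composition and the N placeholder at 3107) ships with the
package so that no external download is ever required; any user-supplied
single-record FASTA is accepted transparently.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq

MT_LENGTH = 16_569
N_PLACEHOLDER_POS = 3107
DEFAULT_ELONGATION = 500


class ReferenceFormatError(ValueError):
    """Raised for malformed reference FASTA input."""


@dataclass
class CircularReference:
    """A circular nucleotide reference with wrap-around coordinates.

    Coordinates are 1-based and inclusive throughout.  ``elongated()`` returns
    the sequence followed by its first ``elongation_length`` bases, the form
    used to map reads across the origin.
    """

    name: str
    sequence: str
    elongation_length: int = DEFAULT_ELONGATION
    codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ReferenceFormatError("empty reference sequence")
        try:
            self.codes = _seq.encode(self.sequence)
        except ValueError as exc:
            raise ReferenceFormatError(str(exc)) from exc
        if self.elongation_length > len(self.sequence):
            raise ValueError("elongation_length exceeds reference length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, position: int) -> int:
        """Map any 1-based position onto the circle: wrap(length + k) == k."""
        return (position - 1) % self.length + 1

    def base(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def elongated(self) -> str:
        return self.sequence + self.sequence[: self.elongation_length]

    def elongated_codes(self) -> np.ndarray:
        return np.concatenate([self.codes, self.codes[: self.elongation_length]])

    def fetch(self, start: int, length: int) -> str:
        """Fetch ``length`` bases starting at 1-based ``start``, wrapping the origin."""
        idx = (np.arange(start - 1, start - 1 + length)) % self.length
        return _seq.decode(self.codes[idx])


VCLASS_SNP = "SNP"
VCLASS_INS = "insertion"
VCLASS_DEL = "deletion"


@dataclass(frozen=True, order=True)
class MtVariant:
    """A normalized variant: 1-based position, ref and alt alleles.

    Representation is minimal and left-aligned (VCF-style anchored indels):
    a SNP has both alleles of length 1; an insertion/deletion shares its first
    (anchor) base between ref and alt.
    """

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def vclass(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return VCLASS_SNP
        if len(self.alt_allele) > len(self.ref_allele):
            return VCLASS_INS
        return VCLASS_DEL

    @property
    def is_snp(self) -> bool:
        return self.vclass == VCLASS_SNP

    def validate(self, ref: CircularReference) -> None:
        seg = ref.fetch(self.position, len(self.ref_allele))
        if seg != self.ref_allele:
            raise ValueError(
                f"ref allele mismatch at {self.position}: variant says "
                f"{self.ref_allele!r}, reference has {seg!r}"
            )


@dataclass
class Haplotype:
    """A reference plus an ordered, non-overlapping variant set."""

    reference: CircularReference
    variants: tuple[MtVariant, ...]

    def __post_init__(self) -> None:
        self.variants = tuple(sorted(self.variants))
        last_end = 0
        for v in self.variants:
            v.validate(self.reference)
            if v.position <= last_end:
                raise ValueError(f"overlapping variants at position {v.position}")
            last_end = v.position + len(v.ref_allele) - 1

    def materialize(self, n_fill: str | None = None) -> str:
        """Apply the variants and return the haplotype sequence.

        Indels shift downstream coordinates in the output only; variant
        coordinates remain reference-based.  ``n_fill`` optionally replaces
        N placeholders (e.g. the rCRS 3107 N) with a concrete base, the way a
        physical molecule would read through that position.
        """
        ref_seq = self.reference.sequence
        parts: list[str] = []
        cursor = 0  # 0-based position in ref_seq
        for v in self.variants:
            parts.append(ref_seq[cursor : v.position - 1])
            parts.append(v.alt_allele)
            cursor = v.position - 1 + len(v.ref_allele)
        parts.append(ref_seq[cursor:])
        out = "".join(parts)
        if n_fill is not None:
            out = out.replace("N", n_fill.upper())
        return out

    @property
    def length(self) -> int:
        shift = sum(len(v.alt_allele) - len(v.ref_allele) for v in self.variants)
        return self.reference.length + shift


def apply_variants(ref: CircularReference, variants) -> str:
    """Materialize a variant set onto the reference (convenience wrapper)."""
    return Haplotype(ref, tuple(variants)).materialize()


def load_reference(
    fasta_path: str | Path, elongation_length: int = DEFAULT_ELONGATION
) -> CircularReference:
    """Load a single-record FASTA as a circular reference.

    Rejects multi-record files, empty sequences, and sequences with characters
    outside {A, C, G, T, N} (the error names the offending position).
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ReferenceFormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ReferenceFormatError(
            f"expected a single-record FASTA, found {len(records)} records in {path}"
        )
    rec = records[0]
    return CircularReference(
        name=rec.id, sequence=str(rec.seq), elongation_length=elongation_length
    )


def write_fasta(name: str, sequence: str, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(sequence), id=name, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


# ---------------------------------------------------------------------------
# Locus map


@dataclass(frozen=True)
class Locus:
    start: int  # 1-based inclusive; start > end denotes a wrap-around interval
    end: int
    name: str
    biotype: str

    def contains(self, position: int) -> bool:
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def span(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


BIOTYPES = ("protein_coding", "rRNA", "tRNA", "D-loop/intergenic")


class LocusMap:
    """Non-overlapping loci whose union covers every position of the circle.

    The control region may wrap the origin (start > end).  Construction fails
    if any position in 1..length is uncovered or covered twice.
    """

    def __init__(self, loci, genome_length: int):
        self.loci = tuple(loci)
        self.genome_length = genome_length
        covered = np.zeros(genome_length, dtype=np.int32)
        for locus in self.loci:
            if locus.biotype not in BIOTYPES:
                raise ValueError(f"unknown biotype {locus.biotype!r}")
            if locus.start <= locus.end:
                covered[locus.start - 1 : locus.end] += 1
            else:
                covered[locus.start - 1 :] += 1
                covered[: locus.end] += 1
        if (covered == 0).any():
            pos = int(np.argmax(covered == 0)) + 1
            raise ValueError(f"locus map leaves position {pos} uncovered")
        if (covered > 1).any():
            pos = int(np.argmax(covered > 1)) + 1
            raise ValueError(f"locus map covers position {pos} more than once")

    def classify(self, position: int) -> Locus:
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside 1..{self.genome_length}"
            )
        for locus in self.loci:
            if locus.contains(position):
                return locus
        raise AssertionError("unreachable: map covers every position")

    @classmethod
    def from_tsv(cls, path: str | Path, genome_length: int) -> "LocusMap":
        """Read a 4-column tab-separated map: start, end, name, biotype (1-based inclusive)."""
        loci = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                start, end, name, biotype = line.split("\t")
                loci.append(Locus(int(start), int(end), name, biotype))
        return cls(loci, genome_length)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for locus in self.loci:
                fh.write(f"{locus.start}\t{locus.end}\t{locus.name}\t{locus.biotype}\n")


def classify_locus(position: int, locus_map: LocusMap) -> Locus:
    return locus_map.classify(position)


# ---------------------------------------------------------------------------
# Packaged synthetic fixtures


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("paleomito") / "data" / name))


def packaged_reference(elongation_length: int = DEFAULT_ELONGATION) -> CircularReference:
    """The packaged synthetic 16,569 bp reference (N at 3107)."""
    return load_reference(_data_path("synthetic_mt.fasta"), elongation_length)


def packaged_locus_map() -> LocusMap:
    return LocusMap.from_tsv(_data_path("synthetic_mt_loci.tsv"), MT_LENGTH)
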