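"""Read mapping to the elongated circular reference plus NumtS-like decoys.

The mapper performs ungapped, substitution-only alignment of short single-end
reads against the 500 bp-elongated mitochondrial circle and any decoy
sequences, on both strands.  A pigeonhole k-mer seed index guarantees that
every placement with at most ``max_mismatch`` substitutions is found (a read
split into ``max_mismatch + 1`` disjoint chunks must have one exact chunk),
so the best placement, the count of equal-best placements and the second-best
mismatch count are exact within that radius — equivalent to an exhaustive
minimum-mismatch scan.

Mapping-quality convention: MQ 37 for a unique best placement with fewer
than 2 mismatches, MQ 25 for a unique best with 2 or more, MQ 0 for ties.
Downstream variant calling admits only MQ >= 30.  Placements starting in the
elongated tail are canonicalized back onto the circle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from . import _seq
from .reference import CircularReference
from .simulate import Decoy, ReadSet

MT_TARGET = "mt"

MAPQ_UNIQUE_CLEAN = 37
MAPQ_UNIQUE_MISMATCHY = 25
MAPQ_TIE = 0

REASON_SHORT = "too-short"
REASON_QUALITY = "low-mean-quality"
REASON_DEGENERATE = "degenerate"
REASON_UNMAPPED = "no-placement"

REMOVE_DECOY_BEST = "decoy-best"
REMOVE_TIE = "tie"
REMOVE_SUBOPTIMAL = "suboptimal-close"
REMOVE_LOW_MAPQ = "low-mapq"


@dataclass
class Alignment:
    """A single ungapped placement of a read."""

    read_index: int
    target: str  # "mt" or a decoy name
    start: int  # 1-based leftmost coordinate (canonicalized to the circle for mt)
    strand: str  # "+" or "-"
    length: int
    mismatches: int
    mapq: int
    n_best: int
    second_best_mismatches: int | None
    duplicate: bool = False
    ambiguous: bool = False

    @property
    def end(self) -> int:
        """1-based inclusive end; may exceed the genome length for origin-spanning reads."""
        return self.start + self.length - 1


class ReadIndex:
    """Exact k-mer index over the elongated reference and decoy sequences."""

    def __init__(
        self,
        ref: CircularReference,
        decoys: tuple[Decoy, ...] = (),
        max_mismatch: int = 4,
        k: int = 20,
    ):
        self.ref = ref
        self.max_mismatch = max_mismatch
        self.k = k
        self.targets: list[tuple[str, np.ndarray, bool]] = [
            (MT_TARGET, ref.elongated_codes(), True)
        ]
        for d in decoys:
            self.targets.append((d.name, d.codes, False))
        self._index: dict[bytes, list[tuple[int, int]]] = {}
        for tid, (_, codes, _c) in enumerate(self.targets):
            buf = codes.tobytes()
            for p in range(len(codes) - k + 1):
                kmer = buf[p : p + k]
                self._index.setdefault(kmer, []).append((tid, p))

    def candidates(self, read_codes: np.ndarray) -> set[tuple[int, int]]:
        """Candidate (target, 0-based start) placements from pigeonhole seeding."""
        m = len(read_codes)
        out: set[tuple[int, int]] = set()
        if m < self.k * (self.max_mismatch + 1):
            # short read: exhaustive scan keeps the pigeonhole guarantee
            for tid, (_, codes, _c) in enumerate(self.targets):
                if len(codes) < m:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(codes, m)
                mism = (windows != read_codes).sum(axis=1)
                for p in np.flatnonzero(mism <= self.max_mismatch):
                    out.add((tid, int(p)))
            return out
        buf = read_codes.tobytes()
        n_chunks = self.max_mismatch + 1
        offsets = [i * self.k for i in range(n_chunks)]
        for off in offsets:
            for tid, p in self._index.get(buf[off : off + self.k], ()):
                start = p - off
                if start >= 0 and start + m <= len(self.targets[tid][1]):
                    out.add((tid, start))
        return out


def _placements(read_codes: np.ndarray, index: ReadIndex):
    """All placements with <= max_mismatch substitutions, canonicalized and
    deduplicated across the two copies of the elongated tail.

    Returns a list of (target_id, canonical_start0, strand, mismatches).
    """
    L = index.ref.length
    found: dict[tuple[int, int, str], int] = {}
    for strand, codes in (("+", read_codes), ("-", _seq.revcomp(read_codes))):
        for tid, p in index.candidates(codes):
            tcodes = index.targets[tid][1]
            seg = tcodes[p : p + len(codes)]
            mm = int(np.count_nonzero(seg != codes))
            if mm > index.max_mismatch:
                continue
            circular = index.targets[tid][2]
            canon = p % L if circular else p
            key = (tid, canon, strand)
            if key not in found or mm < found[key]:
                found[key] = mm
    return [(tid, p, s, mm) for (tid, p, s), mm in found.items()]


def map_read(
    read,
    index: ReadIndex,
    read_index: int = 0,
    min_length: int = 30,
    min_mean_quality: float = 30.0,
):
    """Map one read; returns an Alignment, or (None, reason) if rejected/unmapped.

    ``read`` is (codes, quals) as numpy arrays or a (sequence, quality-string)
    pair.  Admission contract: length >= 30, mean base quality >= 30, not
    all-N.
    """
    if isinstance(read[0], str):
        codes = _seq.encode(read[0])
        quals = np.frombuffer(read[1].encode(), dtype=np.uint8).astype(np.int32) - 33
    else:
        codes, quals = read
    if len(codes) < min_length:
        return None, REASON_SHORT
    if (codes == _seq.N).all():
        return None, REASON_DEGENERATE
    if float(np.mean(quals)) < min_mean_quality:
        return None, REASON_QUALITY
    placements = _placements(codes, index)
    if not placements:
        return None, REASON_UNMAPPED
    placements.sort(key=lambda t: t[3])
    best_mm = placements[0][3]
    best = [p for p in placements if p[3] == best_mm]
    n_best = len(best)
    rest = [p[3] for p in placements if p[3] > best_mm]
    second = min(rest) if rest else None
    tid, p, strand, mm = best[0]
    if n_best == 1:
        mapq = MAPQ_UNIQUE_CLEAN if mm < 2 else MAPQ_UNIQUE_MISMATCHY
    else:
        mapq = MAPQ_TIE
        # deterministic tie representative: lowest (target, start, strand)
        tid, p, strand, mm = min(best)
    aln = Alignment(
        read_index=read_index,
        target=index.targets[tid][0],
        start=p + 1,
        strand=strand,
        length=len(codes),
        mismatches=mm,
        mapq=mapq,
        n_best=n_best,
        second_best_mismatches=second,
    )
    return aln, None


def map_reads(
    reads: ReadSet,
    index: ReadIndex,
    min_length: int = 30,
    min_mean_quality: float = 30.0,
):
    """Map a read set; returns (alignments, rejected) where rejected is a
    list of (read_index, reason)."""
    alignments: list[Alignment] = []
    rejected: list[tuple[int, str]] = []
    for i in range(len(reads)):
        n = int(reads.lengths[i])
        aln, reason = map_read(
            (reads.seqs[i, :n], reads.quals[i, :n]),
            index,
            read_index=i,
            min_length=min_length,
            min_mean_quality=min_mean_quality,
        )
        if aln is None:
            rejected.append((i, reason))
        else:
            alignments.append(aln)
    return alignments, rejected


def deduplicate(alignments: list[Alignment], reads: ReadSet) -> list[Alignment]:
    """Flag coordinate duplicates, keeping one representative per group.

    Reads sharing (target, start, end, strand) collapse to the read with the
    highest summed base quality (ties: lowest read index).  Returns the input
    alignments with duplicate flags set.
    """
    qsum = {
        a.read_index: int(reads.quals[a.read_index, : reads.lengths[a.read_index]].sum())
        for a in alignments
    }
    groups: dict[tuple, list[Alignment]] = {}
    for a in alignments:
        groups.setdefault((a.target, a.start, a.end, a.strand), []).append(a)
    for members in groups.values():
        keeper = min(members, key=lambda a: (-qsum[a.read_index], a.read_index))
        for a in members:
            a.duplicate = a is not keeper
    return alignments


def filter_ambiguous(
    alignments: list[Alignment], delta: int = 0, min_mapq: int = 30
) -> tuple[list[Alignment], list[tuple[Alignment, str]]]:
    """Retain mitochondrially unique, unambiguous alignments.

    Keeps mt-target alignments with a unique best placement whose second-best
    competitor (if any) has more than ``mismatches + delta`` mismatches and
    whose MQ passes ``min_mapq``; everything else is removed with a reason
    (decoy-best, tie, suboptimal-close, low-mapq) — the NumtS exclusion step.
    """
    kept: list[Alignment] = []
    removed: list[tuple[Alignment, str]] = []
    for a in alignments:
        if a.n_best > 1:
            a.ambiguous = True
            removed.append((a, REMOVE_TIE))
        elif a.target != MT_TARGET:
            removed.append((a, REMOVE_DECOY_BEST))
        elif (
            a.second_best_mismatches is not None
            and a.second_best_mismatches <= a.mismatches + delta
        ):
            a.ambiguous = True
            removed.append((a, REMOVE_SUBOPTIMAL))
        elif a.mapq < min_mapq:
            removed.append((a, REMOVE_LOW_MAPQ))
        else:
            kept.append(a)
    return kept, removed


# ---------------------------------------------------------------------------
# Damage profile estimation and quality rescaling


@dataclass
class DamageProfile:
    """Observed terminal misincorporation rates from aligned reads.

    ``rate5_ct[i]`` is the fraction of reference-C positions at read 5'
    offset ``i`` observed as T; ``rate3_ga`` analogously for reference-G at
    3' offsets.  Offsets with no observations carry NaN (undefined, not 0).
    """

    rate5_ct: np.ndarray
    rate3_ga: np.ndarray
    n5: np.ndarray
    n3: np.ndarray

    @property
    def window(self) -> int:
        return len(self.rate5_ct)


def _oriented_matrices(alignments, reads: ReadSet, ref: CircularReference):
    """Read and reference base matrices in read orientation for equal-length
    mt alignments (the common fast path); falls back to None for mixed lengths."""
    mt = [a for a in alignments if a.target == MT_TARGET and not a.duplicate]
    if not mt:
        return None
    lengths = {a.length for a in mt}
    if len(lengths) != 1:
        return mt, None, None
    m = lengths.pop()
    starts0 = np.array([a.start - 1 for a in mt], dtype=np.int64)
    ridx = np.array([a.read_index for a in mt], dtype=np.int64)
    minus = np.array([a.strand == "-" for a in mt])
    ref2 = np.concatenate([ref.codes, ref.codes])
    refmat = ref2[starts0[:, None] + np.arange(m)[None, :]]
    # reads are stored as sequenced, which IS read orientation for both
    # strands; only the reference segment needs flipping into read
    # orientation for minus-strand placements
    readmat = reads.seqs[ridx, :m]
    if minus.any():
        refmat[minus] = _seq._COMP[refmat[minus]][:, ::-1]
    return mt, readmat, refmat


def estimate_damage_profile(
    alignments, reads: ReadSet, ref: CircularReference, window: int = 12
) -> DamageProfile:
    """Estimate terminal C>T / G>A rates from non-duplicate mt alignments.

    Rates are computed in read orientation over reference-C (5') and
    reference-G (3') sites only; zero-denominator offsets are NaN.
    """
    res = _oriented_matrices(alignments, reads, ref)
    if res is None:
        raise ValueError("no usable alignments for damage estimation")
    mt, readmat, refmat = res
    n5 = np.zeros(window, dtype=np.int64)
    c5 = np.zeros(window, dtype=np.int64)
    n3 = np.zeros(window, dtype=np.int64)
    c3 = np.zeros(window, dtype=np.int64)
    if readmat is not None:
        m = readmat.shape[1]
        w = min(window, m)
        for i in range(w):
            ref_c = refmat[:, i] == _seq.C
            n5[i] = int(ref_c.sum())
            c5[i] = int((ref_c & (readmat[:, i] == _seq.T)).sum())
            ref_g = refmat[:, m - 1 - i] == _seq.G
            n3[i] = int(ref_g.sum())
            c3[i] = int((ref_g & (readmat[:, m - 1 - i] == _seq.A)).sum())
    else:  # mixed read lengths: per-alignment loop
        ref2 = np.concatenate([ref.codes, ref.codes])
        for a in mt:
            seg = ref2[a.start - 1 : a.start - 1 + a.length]
            rd = reads.seqs[a.read_index, : a.length]
            if a.strand == "-":
                seg = _seq.revcomp(seg)
            else:
                rd = rd
            w = min(window, a.length)
            for i in range(w):
                if seg[i] == _seq.C:
                    n5[i] += 1
                    c5[i] += rd[i] == _seq.T
                j = a.length - 1 - i
                if seg[j] == _seq.G:
                    n3[i] += 1
                    c3[i] += rd[j] == _seq.A
    with np.errstate(invalid="ignore"):
        rate5 = np.where(n5 > 0, c5 / np.maximum(n5, 1), np.nan)
        rate3 = np.where(n3 > 0, c3 / np.maximum(n3, 1), np.nan)
    return DamageProfile(rate5_ct=rate5, rate3_ga=rate3, n5=n5, n3=n3)


def rescale_qualities(
    alignments, reads: ReadSet, ref: CircularReference, profile: DamageProfile
) -> ReadSet:
    """Downscale base qualities of likely damaged positions.

    For read bases observed as T over reference C within the 5' window (and A
    over reference G within the 3' window), the new quality is
    ``floor(-10*log10(d + 10**(-q/10)))`` where ``d`` is the profile rate at
    that offset.  Other bases are untouched; a quality is never raised.
    Returns a new ReadSet sharing sequences with the input.
    """
    quals = reads.quals.copy()
    res = _oriented_matrices(alignments, reads, ref)
    if res is None:
        return dataclasses.replace(reads, quals=quals)
    mt, readmat, refmat = res
    window = profile.window
    rate5 = np.nan_to_num(profile.rate5_ct, nan=0.0)
    rate3 = np.nan_to_num(profile.rate3_ga, nan=0.0)

    def new_q(q: np.ndarray, d: float) -> np.ndarray:
        return np.floor(-10.0 * np.log10(d + 10.0 ** (-q / 10.0))).astype(np.uint8)

    if readmat is None:
        raise NotImplementedError("rescaling requires uniform read lengths")
    m = readmat.shape[1]
    ridx = np.array([a.read_index for a in mt], dtype=np.int64)
    for i in range(min(window, m)):
        # read-orientation columns index the stored (sequenced) reads directly
        for (col, refbase, readbase, d) in (
            (i, _seq.C, _seq.T, rate5[i]),
            (m - 1 - i, _seq.G, _seq.A, rate3[i]),
        ):
            if d <= 0.0:
                continue
            hit = (refmat[:, col] == refbase) & (readmat[:, col] == readbase)
            if not hit.any():
                continue
            rows = ridx[hit]
            old = quals[rows, col].astype(np.float64)
            quals[rows, col] = np.minimum(quals[rows, col], new_q(old, d))
    return dataclasses.replace(reads, quals=quals)


# ---------------------------------------------------------------------------
# SAM text IO (optional interchange)


def write_sam(
    alignments,
    reads: ReadSet,
    ref: CircularReference,
    decoys: tuple[Decoy, ...],
    path: str | Path,
) -> None:
    """Write alignments as SAM v1 text (pure-match CIGAR, NM tag)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": MT_TARGET, "LN": ref.length}]
        + [{"SN": d.name, "LN": len(d.sequence)} for d in decoys],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = f"read{a.read_index:06d}"
            seq = reads.read_seq(a.read_index)
            qual = reads.quals[a.read_index, : a.length]
            if a.strand == "-":
                seq = _seq.revcomp_str(seq)
                qual = qual[::-1]
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in qual)
            )
            seg.reference_id = fh.header.get_tid(a.target)
            seg.reference_start = a.start - 1
            seg.mapping_quality = a.mapq
            seg.cigarstring = f"{a.length}M"
            seg.flag = (16 if a.strand == "-" else 0) | (1024 if a.duplicate else 0)
            seg.set_tag("NM", a.mismatches)
            seg.set_tag("X1", a.n_best)
            if a.second_best_mismatches is not None:
                seg.set_tag("XS", a.second_best_mismatches)
            fh.write(seg)


def read_sam(path: str | Path):
    """Read SAM text back into Alignment records plus (codes, quals) reads."""
    alignments: list[Alignment] = []
    seqs: list[np.ndarray] = []
    quals: list[np.ndarray] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, seg in enumerate(fh):
            strand = "-" if seg.is_reverse else "+"
            seq = seg.query_sequence
            qual = np.array(seg.query_qualities, dtype=np.uint8)
            if seg.is_reverse:
                seq = _seq.revcomp_str(seq)
                qual = qual[::-1]
            seqs.append(_seq.encode(seq))
            quals.append(qual)
            alignments.append(
                Alignment(
                    read_index=i,
                    target=seg.reference_name,
                    start=seg.reference_start + 1,
                    strand=strand,
                    length=seg.query_length,
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    mapq=seg.mapping_quality,
                    n_best=int(seg.get_tag("X1")) if seg.has_tag("X1") else 1,
                    second_best_mismatches=(
                        int(seg.get_tag("XS")) if seg.has_tag("XS") else None
                    ),
                    duplicate=bool(seg.flag & 1024),
                )
            )
    return alignments, seqs, quals
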