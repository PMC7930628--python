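"""Pileup construction and per-site variant calling with allele fractions.

The caller emits, for every non-reference allele clearing the emission floor
(allele fraction >= 5% by default), a candidate call carrying allele depth
(AD), reference depth (RD), total depth (DP), allele fraction (AF = AD/DP),
a log10 likelihood-ratio score, strand counts and read-end-distance evidence.
Filters mirror a Mutect2-style multilevel scheme: low allele fraction,
read-position bias, an exact-conditional strand-bias test, a contamination
rule driven by an externally supplied contamination rate, and a weak-evidence
log-odds gate.  Tags are cumulative; a call is PASS iff it carries no tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _seq
from .mapping import MT_TARGET
from .reference import CircularReference

FILTER_LOW_AF = "low_af"
FILTER_POSITION_BIAS = "position_bias"
FILTER_STRAND_BIAS = "strand_bias"
FILTER_CONTAMINATION = "contamination"
FILTER_WEAK_EVIDENCE = "weak_evidence"
ALL_FILTERS = (
    FILTER_LOW_AF,
    FILTER_POSITION_BIAS,
    FILTER_STRAND_BIAS,
    FILTER_CONTAMINATION,
    FILTER_WEAK_EVIDENCE,
)


@dataclass
class AlleleEvidence:
    count: int
    fwd: int
    rev: int
    quals: np.ndarray
    end_distances: np.ndarray


@dataclass
class SiteCounts:
    """Per-site pileup evidence split by allele."""

    position: int  # 1-based
    depth: int
    alleles: dict[str, AlleleEvidence]

    def allele_count(self, allele: str) -> int:
        ev = self.alleles.get(allele)
        return ev.count if ev else 0


@dataclass
class VariantCall:
    """One candidate variant allele at one site."""

    position: int
    ref_allele: str
    alt_allele: str
    ad: int
    rd: int
    dp: int
    af: float
    lod: float
    alt_fwd: int = 0
    alt_rev: int = 0
    ref_fwd: int = 0
    ref_rev: int = 0
    median_end_distance: float | None = None
    filters: set[str] = field(default_factory=set)
    cr_used: float = 0.0

    @property
    def is_pass(self) -> bool:
        return not self.filters

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    def filter_string(self) -> str:
        return "PASS" if self.is_pass else ";".join(sorted(self.filters))


class Pileup:
    """Column-store pileup over the circular genome.

    Built from retained alignments after base-quality and mapping-quality
    admission; every covered position is queryable, and candidate sites (a
    non-reference allele above the emission floor) are enumerated without
    materializing 16,569 per-site objects.
    """

    def __init__(self, ref: CircularReference, pos0, base, qual, fwd, end_dist):
        self.ref = ref
        order = np.argsort(pos0, kind="stable")
        self.pos0 = pos0[order]
        self.base = base[order]
        self.qual = qual[order]
        self.fwd = fwd[order]
        self.end_dist = end_dist[order]
        self._bounds = np.searchsorted(self.pos0, np.arange(ref.length + 1))
        counts = np.zeros((ref.length, 5), dtype=np.int64)
        np.add.at(counts, (self.pos0, self.base), 1)
        self.counts = counts

    def depth_map(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def site_counts(self, position: int) -> SiteCounts:
        lo, hi = self._bounds[position - 1], self._bounds[position]
        alleles: dict[str, AlleleEvidence] = {}
        b = self.base[lo:hi]
        for code in np.unique(b):
            m = b == code
            alleles[_seq.BASES[code]] = AlleleEvidence(
                count=int(m.sum()),
                fwd=int(self.fwd[lo:hi][m].sum()),
                rev=int((~self.fwd[lo:hi][m]).sum()),
                quals=self.qual[lo:hi][m].copy(),
                end_distances=self.end_dist[lo:hi][m].copy(),
            )
        return SiteCounts(position=position, depth=int(hi - lo), alleles=alleles)

    def candidate_sites(self, min_af: float = 0.05) -> list[int]:
        """1-based positions with any non-reference allele at AF >= min_af."""
        dp = self.depth_map()
        ref_codes = self.ref.codes
        nonref = self.counts.copy()
        in_range = ref_codes < 5
        nonref[np.arange(self.ref.length)[in_range], ref_codes[in_range]] = 0
        best = nonref.max(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ok = (dp > 0) & (best >= 1) & (best / np.maximum(dp, 1) >= min_af)
        return [int(p) + 1 for p in np.flatnonzero(ok)]


def build_pileup(
    alignments,
    reads,
    ref: CircularReference,
    min_bq: int = 20,
    min_mq: int = 30,
) -> Pileup:
    """Assemble the pileup from mt alignments passing MQ/BQ admission.

    Bases below ``min_bq`` are excluded from all counts; duplicates and
    sub-threshold mapping qualities are skipped; circular wrap is respected.
    An empty alignment set yields an empty pileup.
    """
    keep = [
        a
        for a in alignments
        if a.target == MT_TARGET and not a.duplicate and a.mapq >= min_mq
    ]
    pos_l, base_l, qual_l, fwd_l, dist_l = [], [], [], [], []
    for a in keep:
        n = a.length
        rd = reads.seqs[a.read_index, :n]
        rq = reads.quals[a.read_index, :n]
        if a.strand == "-":
            aligned = _seq._COMP[rd][::-1]
            aq = rq[::-1]
        else:
            aligned = rd
            aq = rq
        offs = np.arange(n)
        pos = (a.start - 1 + offs) % ref.length
        dist = np.minimum(offs, n - 1 - offs)
        ok = aq >= min_bq
        pos_l.append(pos[ok])
        base_l.append(aligned[ok])
        qual_l.append(aq[ok])
        fwd_l.append(np.full(int(ok.sum()), a.strand == "+"))
        dist_l.append(dist[ok])
    if pos_l:
        pos0 = np.concatenate(pos_l)
        base = np.concatenate(base_l)
        qual = np.concatenate(qual_l)
        fwd = np.concatenate(fwd_l)
        dist = np.concatenate(dist_l)
    else:
        pos0 = np.empty(0, dtype=np.int64)
        base = np.empty(0, dtype=np.uint8)
        qual = np.empty(0, dtype=np.uint8)
        fwd = np.empty(0, dtype=bool)
        dist = np.empty(0, dtype=np.int64)
    return Pileup(ref, pos0, base, qual, fwd, dist)


def _lod(site: SiteCounts, ref_allele: str, alt_allele: str, af: float) -> float:
    """log10 likelihood ratio of 'alt present at af' vs 'errors only'.

    Per-base error e = 10^(-q/10); a read base matches an allele with
    probability 1-e and any specific other base with probability e/3.
    """
    total = 0.0
    for base, ev in site.alleles.items():
        e = 10.0 ** (-ev.quals.astype(np.float64) / 10.0)
        p_alt = np.where(base == alt_allele, 1.0 - e, e / 3.0)
        p_ref = np.where(base == ref_allele, 1.0 - e, e / 3.0)
        p_mix = af * p_alt + (1.0 - af) * p_ref
        total += float(np.sum(np.log10(p_mix) - np.log10(p_ref)))
    return total


def call_site(
    site: SiteCounts,
    ref_allele: str,
    min_af: float = 0.05,
    lod_threshold: float = 0.0,
) -> list[VariantCall]:
    """Candidate calls for one site: one per non-reference allele.

    Emission requires allele count >= 1, AF >= the emission floor, and
    lod >= lod_threshold (default 0).  Multi-allele sites emit one candidate
    per allele (split representation) sharing DP.
    """
    dp = site.depth
    if dp < 1:
        return []
    ref_ev = site.alleles.get(ref_allele)
    calls = []
    for allele, ev in sorted(site.alleles.items()):
        if allele == ref_allele or allele == "N":
            continue
        af = ev.count / dp
        if af < min_af:
            continue
        lod = _lod(site, ref_allele, allele, af)
        if lod < lod_threshold:
            continue
        calls.append(
            VariantCall(
                position=site.position,
                ref_allele=ref_allele,
                alt_allele=allele,
                ad=ev.count,
                rd=ref_ev.count if ref_ev else 0,
                dp=dp,
                af=af,
                lod=lod,
                alt_fwd=ev.fwd,
                alt_rev=ev.rev,
                ref_fwd=ref_ev.fwd if ref_ev else 0,
                ref_rev=ref_ev.rev if ref_ev else 0,
                median_end_distance=float(np.median(ev.end_distances)),
            )
        )
    return calls


def call_variants(
    pileup: Pileup, min_af: float = 0.05, lod_threshold: float = 0.0
) -> list[VariantCall]:
    """Run call_site over every candidate site of the pileup."""
    calls: list[VariantCall] = []
    for pos in pileup.candidate_sites(min_af=min_af):
        site = pileup.site_counts(pos)
        ref_allele = pileup.ref.base(pos)
        calls.extend(call_site(site, ref_allele, min_af=min_af, lod_threshold=lod_threshold))
    return calls


def apply_call_filters(
    calls: list[VariantCall],
    cr: float,
    min_af: float = 0.05,
    min_median_end: float = 3.0,
    sb_p: float = 1e-3,
) -> list[VariantCall]:
    """Tag calls with the multilevel filters; tags are cumulative.

    contamination applies only to minor alleles (AF < 0.5): a majority allele
    is never discarded as contaminant.  strand_bias requires both a
    significant exact conditional test and the alt allele present on a single
    strand.
    """
    if not 0.0 <= cr < 1.0:
        raise ValueError("cr must be in [0, 1)")
    for c in calls:
        c.filters.clear()
        c.cr_used = cr
        if c.af < min_af:
            c.filters.add(FILTER_LOW_AF)
        if c.median_end_distance is not None and c.median_end_distance < min_median_end:
            c.filters.add(FILTER_POSITION_BIAS)
        if (c.alt_fwd == 0 or c.alt_rev == 0) and (c.alt_fwd + c.alt_rev) > 0:
            table = [[c.alt_fwd, c.alt_rev], [c.ref_fwd, c.ref_rev]]
            if stats.fisher_exact(table, alternative="two-sided")[1] < sb_p:
                c.filters.add(FILTER_STRAND_BIAS)
        if c.af < 0.5 and c.dp > 0:
            margin = 2.0 * math.sqrt(c.af * (1.0 - c.af) / c.dp)
            if c.af <= cr + margin:
                c.filters.add(FILTER_CONTAMINATION)
        if c.lod < 0.0:
            c.filters.add(FILTER_WEAK_EVIDENCE)
    return calls


def normalize_variants(calls: list[VariantCall], ref: CircularReference) -> list[VariantCall]:
    """Left-align and minimalize indel representations (idempotent for SNPs).

    The returned calls keep their evidence fields; positions and alleles are
    rewritten to the left-most minimal representation against the reference.
    """
    out = []
    for c in calls:
        pos, ra, aa = _normalize_one(c.position, c.ref_allele, c.alt_allele, ref)
        if (pos, ra, aa) != (c.position, c.ref_allele, c.alt_allele):
            c = VariantCall(
                position=pos,
                ref_allele=ra,
                alt_allele=aa,
                ad=c.ad,
                rd=c.rd,
                dp=c.dp,
                af=c.af,
                lod=c.lod,
                alt_fwd=c.alt_fwd,
                alt_rev=c.alt_rev,
                ref_fwd=c.ref_fwd,
                ref_rev=c.ref_rev,
                median_end_distance=c.median_end_distance,
                filters=set(c.filters),
                cr_used=c.cr_used,
            )
        out.append(c)
    return out


def _normalize_one(pos: int, ref_allele: str, alt_allele: str, ref: CircularReference):
    seg = ref.fetch(pos, len(ref_allele))
    if seg != ref_allele:
        raise ValueError(
            f"inconsistent ref allele at {pos}: {ref_allele!r} vs reference {seg!r}"
        )
    ra, aa = ref_allele, alt_allele
    # trim identical trailing bases; extend left when an allele would empty
    while len(ra) > 1 and len(aa) > 1 and ra[-1] == aa[-1]:
        ra, aa = ra[:-1], aa[:-1]
    while ra[-1] == aa[-1] and (len(ra) > 1 or len(aa) > 1) and pos > 1:
        prev = ref.base(pos - 1)
        ra, aa = prev + ra[:-1], prev + aa[:-1]
        pos -= 1
    # trim identical leading bases for multi-base substitutions
    while len(ra) > 1 and len(aa) > 1 and ra[0] == aa[0]:
        ra, aa = ra[1:], aa[1:]
        pos += 1
    return pos, ra, aa
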