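"""Filter-pattern grid, multiallelic resolution and consensus assembly.

A filter pattern is one row of the benchmarked grid: a contamination-rate
mode (none / mean / highest), a minimum variant allele depth (AD), a minimum
allele fraction (5% or 50%) and a minimum site depth (DP).  Retained calls
are resolved one-allele-per-site (two surviving alternatives fall back to
the reference) and substituted into the reference to build a consensus
sequence, with N written at zero-depth sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calling import FILTER_CONTAMINATION, VariantCall, apply_call_filters
from .reference import CircularReference, write_fasta

CR_MODES = ("none", "mean", "highest")
AD_CHOICES = (None, 2, 3, 5, 10)
AF_CHOICES = (5, 50)
DP_CHOICES = (None, 3, 4, 5, 10, 20)


@dataclass(frozen=True)
class FilterPattern:
    """One combination of the variant-retention thresholds."""

    cr_mode: str = "none"
    min_ad: int | None = None
    min_af_pct: float = 50
    min_dp: int | None = None
    expert: bool = False

    def __post_init__(self) -> None:
        if self.cr_mode not in CR_MODES:
            raise ValueError(f"cr_mode must be one of {CR_MODES}")
        if not self.expert:
            if self.min_ad not in AD_CHOICES:
                raise ValueError(f"min_ad must be one of {AD_CHOICES} (or use expert mode)")
            if self.min_af_pct not in AF_CHOICES:
                raise ValueError(f"min_af_pct must be 5 or 50 (or use expert mode)")
            if self.min_dp not in DP_CHOICES:
                raise ValueError(f"min_dp must be one of {DP_CHOICES} (or use expert mode)")

    @classmethod
    def parse(cls, text: str) -> "FilterPattern":
        """Parse e.g. 'AD10,AF50', 'AD2,AF5,DP4', 'AF50,CR=mean'."""
        kwargs: dict = {}
        for tok in text.replace("/", ",").split(","):
            tok = tok.strip()
            if not tok:
                continue
            upper = tok.upper()
            if upper.startswith("CR="):
                kwargs["cr_mode"] = tok[3:].lower()
            elif upper.startswith("AD"):
                kwargs["min_ad"] = int(tok[2:])
            elif upper.startswith("AF"):
                kwargs["min_af_pct"] = float(tok[2:])
            elif upper.startswith("DP"):
                kwargs["min_dp"] = int(tok[2:])
            else:
                raise ValueError(f"unrecognized pattern token {tok!r}")
        return cls(**kwargs)

    def label(self) -> str:
        parts = []
        if self.min_ad is not None:
            parts.append(f"AD{self.min_ad}")
        parts.append(f"AF{self.min_af_pct:g}")
        if self.min_dp is not None:
            parts.append(f"DP{self.min_dp}")
        if self.cr_mode != "none":
            parts.append(f"CR={self.cr_mode}")
        return ",".join(parts)


def default_pattern_grid() -> list[FilterPattern]:
    """The benchmarked grid: AD paired with its DP companion at both AF
    levels, plus CR-mode rows at AF 50."""
    ad_dp = [(None, None), (2, 4), (3, 5), (5, 10), (10, 20)]
    grid = []
    for (ad, dp), af, with_dp in itertools.product(ad_dp, AF_CHOICES, (True, False)):
        grid.append(
            FilterPattern(min_ad=ad, min_af_pct=af, min_dp=dp if with_dp else None)
        )
    for mode in ("mean", "highest"):
        for ad in AD_CHOICES:
            grid.append(FilterPattern(cr_mode=mode, min_ad=ad, min_af_pct=50))
    # drop duplicates created by dp=None pairing
    return list(dict.fromkeys(grid))


def apply_pattern(
    calls: list[VariantCall],
    pattern: FilterPattern,
    cr_mean: float = 0.0,
    cr_high: float = 0.0,
) -> list[VariantCall]:
    """Retain PASS calls meeting the pattern's AD/DP/AF thresholds.

    The pattern's cr_mode selects which contamination-rate scalar is
    re-applied through the contamination rule before retention; 'none'
    disables that rule entirely.
    """
    cr = {"none": 0.0, "mean": cr_mean, "highest": cr_high}[pattern.cr_mode]
    retained = []
    for c in calls:
        filters = set(c.filters) - {FILTER_CONTAMINATION}
        if pattern.cr_mode != "none" and c.af < 0.5 and c.dp > 0:
            margin = 2.0 * np.sqrt(c.af * (1.0 - c.af) / c.dp)
            if c.af <= cr + margin:
                filters.add(FILTER_CONTAMINATION)
        if filters:
            continue
        if pattern.min_ad is not None and c.ad < pattern.min_ad:
            continue
        if pattern.min_dp is not None and c.dp < pattern.min_dp:
            continue
        if c.af < pattern.min_af_pct / 100.0:
            continue
        retained.append(c)
    return retained


def resolve_multiallelic(site_calls: list[VariantCall]) -> VariantCall | None:
    """Resolve retained calls at one site to a single allele.

    Exactly one surviving alternative wins; two or more (or zero) fall back
    to the reference (returns None).
    """
    if len(site_calls) == 1:
        return site_calls[0]
    return None


@dataclass
class ConsensusSequence:
    """A per-sample consensus with its provenance."""

    sequence: str
    inserted_variants: list[VariantCall]
    coverage_pct: float
    mean_depth: float

    def write(self, name: str, path: str | Path) -> None:
        write_fasta(name, self.sequence, path)


def coverage_stats(depth_map: np.ndarray) -> tuple[float, float]:
    """(fraction of sites with depth >= 1, mean depth) over the genome."""
    depth_map = np.asarray(depth_map)
    coverage_pct = float((depth_map >= 1).mean())
    return coverage_pct, float(depth_map.mean())


def build_consensus(
    ref: CircularReference,
    retained_calls: list[VariantCall],
    depth_map: np.ndarray,
) -> ConsensusSequence:
    """Substitute resolved alleles into the reference; N at zero-depth sites.

    Multiallelic sites are resolved first (ties -> reference).  SNPs are
    applied in place; indels are applied afterwards in descending position
    order so reference-based coordinates stay valid.  Overlapping indels are
    an error listing the conflicting positions.
    """
    by_site: dict[int, list[VariantCall]] = {}
    for c in retained_calls:
        by_site.setdefault(c.position, []).append(c)
    resolved = [
        r for r in (resolve_multiallelic(v) for v in sorted(by_site.values(), key=lambda g: g[0].position)) if r is not None
    ]
    seq = list(ref.sequence)
    for pos0 in np.flatnonzero(np.asarray(depth_map) == 0):
        seq[pos0] = "N"
    snps = [c for c in resolved if c.is_snp]
    indels = sorted((c for c in resolved if not c.is_snp), key=lambda c: -c.position)
    for c in snps:
        seq[c.position - 1] = c.alt_allele
    spans = sorted(
        (c.position, c.position + len(c.ref_allele) - 1) for c in indels
    )
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping indel insertions at positions {s1} and {s2}")
    for c in indels:
        seq[c.position - 1 : c.position - 1 + len(c.ref_allele)] = list(c.alt_allele)
    coverage_pct, mean_depth = coverage_stats(depth_map)
    return ConsensusSequence(
        sequence="".join(seq),
        inserted_variants=resolved,
        coverage_pct=coverage_pct,
        mean_depth=mean_depth,
    )
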