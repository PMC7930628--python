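"""Heteroplasmy site selection, AF-bin profiles, substitution spectra and
multi-sample sharing summaries.

Potential heteroplasmies are variant sites where both the variant and the
reference allele are well supported (AD >= 10 and RD >= 10 by default).
Profiles bin allele fractions into [5,10), [10,20), ..., [80,90), [90,100]
percent; sites below 10% are "potential low heteroplasmies" and sites at or
above 90% "quasi-homoplasmies".  Substitution composition is reported over
the 12 reference-strand base-change classes, with the aDNA-typical type 1
(A>G, T>C) and type 2 (C>T, G>A) transition shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import VariantCall
from .reference import LocusMap

TRANSITIONS = {"A>G", "G>A", "C>T", "T>C"}
TYPE1 = {"A>G", "T>C"}
TYPE2 = {"C>T", "G>A"}
SUBSTITUTION_CLASSES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

# lower bin edges in percent; the last bin [90, 100] is closed on both sides
BIN_EDGES_PCT = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90)
BIN_LABELS = tuple(
    f"[{lo},{hi})" for lo, hi in zip(BIN_EDGES_PCT[:-1], BIN_EDGES_PCT[1:])
) + ("[90,100]",)


def select_heteroplasmy_sites(
    calls: list[VariantCall], min_ad: int = 10, min_rd: int = 10
) -> list[VariantCall]:
    """PASS calls with both alleles well supported (thresholds inclusive)."""
    return [c for c in calls if c.is_pass and c.ad >= min_ad and c.rd >= min_rd]


@dataclass
class HeteroplasmyProfile:
    sample: str
    sites: list[VariantCall]
    bin_counts: dict[str, int]
    n_low: int  # AF < 10%
    n_quasi: int  # AF >= 90%
    n_indel: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def percentages(self) -> dict[str, float]:
        total = self.n_sites
        if total == 0:
            return {label: 0.0 for label in BIN_LABELS}
        return {label: 100.0 * n / total for label, n in self.bin_counts.items()}


def af_bin_profile(selected: list[VariantCall], sample: str = "sample") -> HeteroplasmyProfile:
    """Bin selected sites by allele fraction.

    Bins are half-open on the left edge except the top bin, which includes
    both 90% and 100%.  An empty selection yields an empty profile.
    """
    edges = np.array(BIN_EDGES_PCT, dtype=float)
    counts = {label: 0 for label in BIN_LABELS}
    for c in selected:
        pct = 100.0 * c.af
        idx = int(np.searchsorted(edges, pct, side="right")) - 1
        idx = min(max(idx, 0), len(BIN_LABELS) - 1)
        counts[BIN_LABELS[idx]] += 1
    return HeteroplasmyProfile(
        sample=sample,
        sites=list(selected),
        bin_counts=counts,
        n_low=sum(1 for c in selected if c.af < 0.10),
        n_quasi=sum(1 for c in selected if c.af >= 0.90),
        n_indel=sum(1 for c in selected if not c.is_snp),
    )


def base_change_composition(calls: list[VariantCall]) -> dict:
    """Counts over the 12 substitution classes plus type 1/2 shares.

    Only SNP calls contribute; classes are reported in reference-strand
    orientation.
    """
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for c in calls:
        # N-reference calls (e.g. at the rCRS placeholder site) have no class
        if c.is_snp and f"{c.ref_allele}>{c.alt_allele}" in counts:
            counts[f"{c.ref_allele}>{c.alt_allele}"] += 1
    total = sum(counts.values())
    type1 = sum(counts[cls] for cls in TYPE1)
    type2 = sum(counts[cls] for cls in TYPE2)
    return {
        "counts": counts,
        "total": total,
        "type1_share": type1 / total if total else 0.0,
        "type2_share": type2 / total if total else 0.0,
    }


def titv_ratio(calls: list[VariantCall]) -> float | None:
    """Transitions / transversions over SNP calls; None when no transversion."""
    ts = tv = 0
    for c in calls:
        key = f"{c.ref_allele}>{c.alt_allele}"
        if not c.is_snp or key not in set(SUBSTITUTION_CLASSES):
            continue
        if key in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def shared_variant_table(
    per_sample_calls: dict[str, list[VariantCall]],
    locus_map: LocusMap | None = None,
) -> tuple[pd.DataFrame, int, pd.DataFrame | None]:
    """Variant x sample presence matrix, singleton count and locus density.

    Returns (matrix, n_singletons, density) where the matrix is indexed by
    "pos ref>alt" with boolean sample columns plus an occurrence count, and
    density (per-locus variants per bp) is computed when a locus map is
    given.
    """
    if not per_sample_calls:
        raise ValueError("at least one sample required")
    keys: dict[tuple[int, str, str], dict[str, bool]] = {}
    for sample, calls in per_sample_calls.items():
        for c in calls:
            keys.setdefault((c.position, c.ref_allele, c.alt_allele), {})[sample] = True
    samples = list(per_sample_calls)
    rows = []
    for (pos, ra, aa), present in sorted(keys.items()):
        row = {"position": pos, "ref": ra, "alt": aa}
        for s in samples:
            row[s] = present.get(s, False)
        row["occurrence"] = sum(present.get(s, False) for s in samples)
        rows.append(row)
    matrix = pd.DataFrame(rows)
    n_singletons = int((matrix["occurrence"] == 1).sum()) if len(matrix) else 0
    density = None
    if locus_map is not None and len(matrix):
        locus_names = [locus_map.classify(int(p)).name for p in matrix["position"]]
        matrix = matrix.assign(locus=locus_names)
        per_locus = matrix.groupby("locus").size()
        spans = {l.name: l.span(locus_map.genome_length) for l in locus_map.loci}
        density = pd.DataFrame(
            {
                "n_variants": per_locus,
                "length_bp": [spans[n] for n in per_locus.index],
            }
        )
        density["variants_per_bp"] = density["n_variants"] / density["length_bp"]
    return matrix, n_singletons, density
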