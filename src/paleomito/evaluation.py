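"""Whole-genome confusion-matrix evaluation of a call set against a
reference set, with the nine derived statistics and exclusion lists.

Every one of the genome's sites is classified exactly once: TP at sites
where test and reference agree on a variant allele, FP at test-only sites
(and at allele mismatches, by convention), FN at reference-only sites, TN
everywhere else, so TP+TN+FP+FN always equals the genome length.  Exclusion
lists model positions the benchmarked caller is known to suppress: a
blacklist of artifact positions (the N-placeholder site 3107 by default) and
the rare reference polymorphisms (1189, 4769, 7028, 8860) never emitted for
internal reasons.  Test-set variants at excluded positions are dropped
before classification; reference-set variants there are dropped from FN
accounting when ``exclude_reference`` is set (the real-sample convention) or
kept as FN otherwise (the simulation-benchmark convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calling import VariantCall
from .reference import MT_LENGTH

DEFAULT_BLACKLIST = frozenset({3107})
DEFAULT_RCRS_RARE = frozenset({1189, 4769, 7028, 8860})


@dataclass(frozen=True)
class ExclusionLists:
    blacklist: frozenset[int] = DEFAULT_BLACKLIST
    rcrs_rare: frozenset[int] = DEFAULT_RCRS_RARE

    def all(self) -> frozenset[int]:
        return self.blacklist | self.rcrs_rare

    def validate(self, genome_length: int) -> None:
        bad = [p for p in self.all() if not 1 <= p <= genome_length]
        if bad:
            raise ValueError(f"excluded positions outside genome: {bad}")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    genome_length: int = MT_LENGTH

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn != self.genome_length:
            raise ValueError(
                f"counts sum to {self.tp + self.tn + self.fp + self.fn}, "
                f"expected genome length {self.genome_length}"
            )


@dataclass
class Metrics:
    """The nine derived statistics; None marks an undefined (0/0) value."""

    ppv: float | None
    sn: float | None
    spc: float | None
    fnr: float | None
    fpr: float | None
    npv: float | None
    fdr: float | None
    for_: float | None
    acc: float | None

    FIELDS = ("ppv", "sn", "spc", "fnr", "fpr", "npv", "fdr", "for_", "acc")

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in self.FIELDS}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """PPV, SN, SPC, FNR, FPR, NPV, FDR, FOR and ACC from confusion counts.

    Values are kept at full precision; rounding happens at display time only
    (see ``format_metrics``).  Identities FDR = 1-PPV and FNR = 1-SN hold
    exactly.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    ppv = _ratio(tp, tp + fp)
    sn = _ratio(tp, tp + fn)
    return Metrics(
        ppv=ppv,
        sn=sn,
        spc=_ratio(tn, tn + fp),
        fnr=None if sn is None else 1.0 - sn,
        fpr=_ratio(fp, fp + tn),
        npv=_ratio(tn, tn + fn),
        fdr=None if ppv is None else 1.0 - ppv,
        for_=_ratio(fn, fn + tn),
        acc=_ratio(tp + tn, counts.genome_length),
    )


def _as_position_map(calls) -> dict[int, str]:
    """Normalize a call collection into position -> allele-key."""
    out: dict[int, str] = {}
    if isinstance(calls, Mapping):
        items = calls.items()
        for pos, allele in items:
            if pos in out:
                raise ValueError(f"duplicate position {pos} in call set")
            out[pos] = str(allele)
        return out
    for c in calls:
        if isinstance(c, VariantCall):
            pos, key = c.position, f"{c.ref_allele}>{c.alt_allele}"
        else:  # MtVariant-like
            pos, key = c.position, f"{c.ref_allele}>{c.alt_allele}"
        if pos in out:
            raise ValueError(f"duplicate position {pos} in call set")
        out[pos] = key
    return out


def classify_calls(
    test_set,
    reference_set,
    exclusions: ExclusionLists | None = None,
    genome_length: int = MT_LENGTH,
    exclude_reference: bool = True,
) -> tuple[ConfusionCounts, list[int]]:
    """Classify every genome site against a reference (truth) variant set.

    Both sets are position -> allele maps (or VariantCall/MtVariant
    collections).  An allele mismatch at a shared position counts as FP only
    (the test called the wrong variant); the missed reference allele is
    returned in the side report so the convention stays auditable.
    """
    exclusions = exclusions or ExclusionLists()
    exclusions.validate(genome_length)
    test = _as_position_map(test_set)
    refv = _as_position_map(reference_set)
    for name, posmap in (("test", test), ("reference", refv)):
        bad = [p for p in posmap if not 1 <= p <= genome_length]
        if bad:
            raise ValueError(f"{name} set has positions outside the genome: {bad}")
    excluded = exclusions.all()
    test = {p: a for p, a in test.items() if p not in excluded}
    if exclude_reference:
        refv = {p: a for p, a in refv.items() if p not in excluded}
    tp = fp = fn = 0
    mismatched: list[int] = []
    for pos, allele in test.items():
        if pos in refv:
            if refv[pos] == allele:
                tp += 1
            else:
                fp += 1
                mismatched.append(pos)
        else:
            fp += 1
    for pos in refv:
        if pos not in test:
            fn += 1
    tn = genome_length - tp - fp - fn
    return ConfusionCounts(tp, tn, fp, fn, genome_length), mismatched


def aggregate(per_sample: Mapping[str, tuple[ConfusionCounts, Metrics]]) -> pd.DataFrame:
    """Per-sample table plus Mean and Median rows.

    Mean/median are taken column-wise over the per-sample values (not
    recomputed from pooled counts); undefined metric cells are skipped.
    """
    if not per_sample:
        raise ValueError("at least one sample required")
    rows = []
    for sample, (counts, metrics) in per_sample.items():
        row = {"sample": sample, "TP": counts.tp, "TN": counts.tn, "FP": counts.fp, "FN": counts.fn}
        row.update({k.rstrip("_").upper(): v for k, v in metrics.as_dict().items()})
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample")
    summary = pd.DataFrame(
        {"Mean": df.mean(numeric_only=True, skipna=True), "Median": df.median(numeric_only=True, skipna=True)}
    ).T
    summary.index.name = "sample"
    return pd.concat([df, summary])


def format_metrics(metrics: Metrics) -> dict[str, str]:
    """Display rounding: 2 decimals, FPR at 2 and FOR at 3 significant digits
    in scientific notation; undefined values render as '-'."""
    out = {}
    for name, value in metrics.as_dict().items():
        key = name.rstrip("_").upper()
        if value is None:
            out[key] = "-"
        elif name == "fpr":
            out[key] = f"{value:.1E}"
        elif name == "for_":
            out[key] = f"{value:.2E}"
        else:
            out[key] = f"{value:.2f}"
    return out


def write_report(df: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t")
    if json_path is not None:
        df.to_json(json_path, orient="index", double_precision=15)
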