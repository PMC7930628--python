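"""VCF v4.2 reading and writing for per-site variant calls.

Writing emits a minimal, lossless representation of the caller's output:
FORMAT AD (ref,alt), DP and AF; FILTER carries the multilevel tags; INFO
carries the log-odds score, strand counts, median read-end distance and the
contamination rate used.  Reading goes through cyvcf2 and accepts externally
produced VCFs that carry at least AD/DP/AF, splitting multiallelic records
into per-allele calls sharing DP.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .calling import ALL_FILTERS, VariantCall
from .reference import CircularReference

_FILTER_DESCRIPTIONS = {
    "low_af": "Allele fraction below the emission floor",
    "position_bias": "Median distance of variant bases from the nearer read end below threshold",
    "strand_bias": "Alt allele on a single strand with significant exact conditional test",
    "contamination": "Minor allele fraction consistent with the supplied contamination rate",
    "weak_evidence": "log10 likelihood ratio below 0",
}


class VcfParseError(ValueError):
    pass


def write_vcf(
    calls: list[VariantCall],
    sample: str,
    path: str | Path,
    ref: CircularReference | None = None,
    contig: str = "mt",
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=paleomito",
    ]
    if ref is not None:
        lines.append(f"##contig=<ID={contig},length={ref.length}>")
    for tag in ALL_FILTERS:
        lines.append(f'##FILTER=<ID={tag},Description="{_FILTER_DESCRIPTIONS[tag]}">')
    lines += [
        '##INFO=<ID=LOD,Number=1,Type=Float,Description="log10 likelihood ratio">',
        '##INFO=<ID=SB,Number=4,Type=Integer,Description="Strand counts: alt_fwd,alt_rev,ref_fwd,ref_rev">',
        '##INFO=<ID=MED,Number=1,Type=Float,Description="Median distance of alt bases from nearer read end">',
        '##INFO=<ID=CR,Number=1,Type=Float,Description="Contamination rate used for filtering">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for c in sorted(calls, key=lambda c: (c.position, c.alt_allele)):
        info = f"LOD={c.lod:.4f};SB={c.alt_fwd},{c.alt_rev},{c.ref_fwd},{c.ref_rev};CR={c.cr_used:.6g}"
        if c.median_end_distance is not None:
            info += f";MED={c.median_end_distance:.6g}"
        lines.append(
            "\t".join(
                [
                    contig,
                    str(c.position),
                    ".",
                    c.ref_allele,
                    c.alt_allele,
                    ".",
                    c.filter_string(),
                    info,
                    "AD:DP:AF",
                    f"{c.rd},{c.ad}:{c.dp}:{c.af:.6g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[VariantCall]:
    """Parse a VCF into VariantCall records, splitting multiallelic sites."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    calls: list[VariantCall] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise VcfParseError(f"cannot parse {path}: {exc}") from exc
    for line_no, v in enumerate(vcf, start=1):
        filters = set() if v.FILTER is None else set(v.FILTER.split(";")) - {"PASS", "."}
        try:
            dp = int(v.format("DP")[0][0]) if v.format("DP") is not None else (v.INFO.get("DP") or 0)
            ad_arr = v.format("AD")
            af_arr = v.format("AF")
            sb = v.INFO.get("SB")
            lod = v.INFO.get("LOD")
            med = v.INFO.get("MED")
            cr = v.INFO.get("CR")
            for ai, alt in enumerate(v.ALT):
                if ad_arr is not None:
                    rd = int(ad_arr[0][0])
                    ad = int(ad_arr[0][ai + 1])
                else:
                    rd, ad = 0, 0
                if af_arr is not None:
                    af = float(np.atleast_1d(af_arr[0])[ai])
                elif dp:
                    af = ad / dp
                else:
                    af = 0.0
                calls.append(
                    VariantCall(
                        position=v.POS,
                        ref_allele=v.REF,
                        alt_allele=alt,
                        ad=ad,
                        rd=rd,
                        dp=int(dp),
                        af=af,
                        lod=float(lod) if lod is not None else 0.0,
                        alt_fwd=int(sb[0]) if sb is not None else 0,
                        alt_rev=int(sb[1]) if sb is not None else 0,
                        ref_fwd=int(sb[2]) if sb is not None else 0,
                        ref_rev=int(sb[3]) if sb is not None else 0,
                        median_end_distance=float(med) if med is not None else None,
                        filters=set(filters),
                        cr_used=float(cr) if cr is not None else 0.0,
                    )
                )
        except (TypeError, ValueError, IndexError) as exc:
            raise VcfParseError(f"{path}: malformed record at data line {line_no}: {exc}") from exc
    return calls
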