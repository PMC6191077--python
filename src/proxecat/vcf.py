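"""Optional VCF ingestion: build a per-variant table from two sites-only VCFs.

Counts come from AC/AN-style INFO fields of a case VCF and a control VCF,
matched by ``CHROM:POS:REF:ALT`` (1-based positions); consequence and gene
come from a VEP ``CSQ``-style annotation on either file.  Sites present in
only one dataset contribute zero alleles on the absent side (with the
allele number left at 0 there, so MAF filters skip that side).  Multi-allelic
sites must be pre-split (e.g. ``bcftools norm -m-``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_vcf_pair"]


def _csq_fields(header_line: str) -> list[str]:
    # "... Format: Allele|Consequence|SYMBOL|..."
    fmt = header_line.rsplit("Format:", 1)[-1].strip().strip('">')
    return [f.strip() for f in fmt.split("|")]


def _iter_sites(path: str | Path):
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    csq_fields: list[str] | None = None
    for h in vcf.header_iter():
        info = h.info()
        if info.get("ID") == "CSQ":
            csq_fields = _csq_fields(info.get("Description", ""))
    for v in vcf:
        key = f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0] if v.ALT else '.'}"
        ac = v.INFO.get("AC")
        if isinstance(ac, tuple):
            ac = ac[0]
        an = v.INFO.get("AN")
        gene, cons = None, None
        raw = v.INFO.get("CSQ")
        if raw is not None and csq_fields:
            first = str(raw).split(",")[0].split("|")
            rec = dict(zip(csq_fields, first))
            gene = rec.get("SYMBOL") or rec.get("Gene")
            cons = rec.get("Consequence")
        yield key, int(ac or 0), int(an or 0), gene, cons


def read_vcf_pair(case_vcf: str | Path, ctrl_vcf: str | Path) -> pd.DataFrame:
    """Merge case and control VCFs into the per-variant table format.

    Returns columns ``gene, variant_id, consequence, case_ac, case_an,
    ctrl_ac, ctrl_an``; sites lacking a gene symbol or consequence in both
    files are dropped.
    """
    case = {k: (ac, an, g, c) for k, ac, an, g, c in _iter_sites(case_vcf)}
    ctrl = {k: (ac, an, g, c) for k, ac, an, g, c in _iter_sites(ctrl_vcf)}
    rows = []
    for key in sorted(set(case) | set(ctrl)):
        cac, can, cg, cc = case.get(key, (0, 0, None, None))
        tac, tan, tg, tc = ctrl.get(key, (0, 0, None, None))
        gene = cg or tg
        cons = cc or tc
        if not gene or not cons:
            continue
        rows.append({
            "gene": gene, "variant_id": key, "consequence": cons,
            "case_ac": cac, "case_an": can, "ctrl_ac": tac, "ctrl_an": tan,
        })
    return pd.DataFrame(rows, columns=["gene", "variant_id", "consequence",
                                       "case_ac", "case_an", "ctrl_ac", "ctrl_an"])
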