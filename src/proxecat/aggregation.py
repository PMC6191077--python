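"""Reduce per-variant annotated allele counts to per-gene count quadruples.

The pipeline is: orient each variant to its minor allele, filter on minor
allele frequency (internally in both datasets, optionally against external
reference-population frequencies), classify each variant as functional or
proxy from its Sequence Ontology consequence terms, then sum minor-allele
counts per gene and drop genes with too few alleles in either class.

Three nested proxy definitions are supported: synonymous variants only
(``SYN``), Ensembl low-impact terms (``LOW``), or everything that is not
functional (``NOT_FUNC``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GeneCounts

__all__ = [
    "FUNCTIONAL_TERMS",
    "LOW_TERMS",
    "VariantRecord",
    "ClassificationStrategy",
    "FilterConfig",
    "compute_maf",
    "classify",
    "filter_variants",
    "aggregate",
]

#: Sequence Ontology terms counted as functional (protein-altering).
FUNCTIONAL_TERMS: frozenset[str] = frozenset({
    "splice_donor_variant",
    "splice_acceptor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "initiator_codon_variant",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
})

#: Ensembl low-impact terms; a superset of the synonymous class.
LOW_TERMS: frozenset[str] = frozenset({
    "splice_region_variant",
    "incomplete_terminal_codon_variant",
    "stop_retained_variant",
    "synonymous_variant",
})

_PROXY_MODES = ("SYN", "LOW", "NOT_FUNC")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with per-dataset allele counts.

    ``consequence_terms`` holds one or more Sequence Ontology strings.
    ``external_afs`` are optional reference-population allele frequencies
    (e.g. the five primary continental groups of a public panel).
    Multi-allelic sites must be pre-split into biallelic records.
    """

    gene_id: str
    consequence_terms: tuple[str, ...]
    case_ac: int
    case_an: int
    ctrl_ac: int
    ctrl_an: int
    external_afs: tuple[float, ...] = ()
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if not self.consequence_terms:
            raise ValueError("a variant needs at least one consequence term")
        for ac, an in ((self.case_ac, self.case_an), (self.ctrl_ac, self.ctrl_an)):
            if ac < 0 or an < 0 or (an > 0 and ac > an):
                raise ValueError(f"invalid allele count/number pair ({ac}, {an})")


@dataclass(frozen=True)
class ClassificationStrategy:
    """Functional/proxy classification by Sequence Ontology terms.

    ``proxy_mode``:

    * ``SYN`` — proxy = synonymous_variant only;
    * ``LOW`` — proxy = any Ensembl low-impact term;
    * ``NOT_FUNC`` — proxy = anything not in the functional set.

    The three proxy sets are nested (SYN ⊂ LOW ⊂ NOT_FUNC).  A variant
    carrying both functional and non-functional terms is functional.
    """

    proxy_mode: str = "SYN"
    functional_terms: frozenset[str] = FUNCTIONAL_TERMS
    low_terms: frozenset[str] = LOW_TERMS

    def __post_init__(self) -> None:
        if self.proxy_mode not in _PROXY_MODES:
            raise ValueError(f"proxy_mode must be one of {_PROXY_MODES}")


@dataclass(frozen=True)
class FilterConfig:
    """MAF and per-gene allele-count thresholds.

    ``internal_maf_max`` applies in both cases and controls (typical values
    0.01, or 0.001 when no external filter is available);
    ``external_maf_max``, when set, must hold in every reference ancestry
    group.  ``min_alleles`` is the minimum per-gene total required
    separately for the functional and the proxy class.
    """

    internal_maf_max: float = 0.01
    external_maf_max: float | None = None
    min_alleles: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.internal_maf_max <= 0.5):
            raise ValueError("internal_maf_max must be in (0, 0.5]")
        if self.external_maf_max is not None and not (0 < self.external_maf_max <= 0.5):
            raise ValueError("external_maf_max must be in (0, 0.5]")
        if self.min_alleles < 1:
            raise ValueError("min_alleles must be >= 1")


def compute_maf(ac: int, an: int) -> tuple[float, bool]:
    """Minor allele frequency and a flag for flipped orientation.

    Returns ``(min(f, 1-f), f > 0.5)`` for f = ac/an.  With ``an == 0``
    (site not genotyped in this dataset) the frequency is missing (NaN).
    """
    if an <= 0:
        return float("nan"), False
    f = ac / an
    return min(f, 1.0 - f), f > 0.5


def _split_terms(consequence: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(consequence, str):
        for sep in ("&", ","):
            consequence = consequence.replace(sep, " ")
        return tuple(t for t in consequence.split() if t)
    return tuple(consequence)


def classify(record: VariantRecord | str | Sequence[str], strategy: ClassificationStrategy) -> str:
    """Classify a variant as ``functional``, ``proxy`` or ``excluded``.

    Accepts a :class:`VariantRecord` or the consequence annotation itself
    (an SO term, an ``&``- or comma-joined multi-term string, or a
    sequence of terms).  Functional terms take precedence; otherwise the
    proxy rule of the strategy decides.
    """
    if isinstance(record, VariantRecord):
        terms = set(record.consequence_terms)
    else:
        terms = set(_split_terms(record))
    if terms & strategy.functional_terms:
        return "functional"
    if strategy.proxy_mode == "SYN":
        return "proxy" if "synonymous_variant" in terms else "excluded"
    if strategy.proxy_mode == "LOW":
        return "proxy" if terms & strategy.low_terms else "excluded"
    return "proxy"  # NOT_FUNC: everything not functional


def _as_frame(records: Iterable[VariantRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "consequence" in df.columns and "consequence_terms" not in df.columns:
            df["consequence_terms"] = df["consequence"].map(_split_terms)
        ext_cols = sorted(c for c in df.columns if c.startswith("ext_af"))
        if "external_afs" not in df.columns:
            if ext_cols:
                df["external_afs"] = list(map(tuple, df[ext_cols].to_numpy(float)))
            else:
                df["external_afs"] = [()] * len(df)
        return df
    rows = []
    for r in records:
        rows.append({
            "gene": r.gene_id,
            "variant_id": r.variant_id,
            "consequence_terms": r.consequence_terms,
            "case_ac": r.case_ac,
            "case_an": r.case_an,
            "ctrl_ac": r.ctrl_ac,
            "ctrl_an": r.ctrl_an,
            "external_afs": r.external_afs,
        })
    cols = ["gene", "variant_id", "consequence_terms",
            "case_ac", "case_an", "ctrl_ac", "ctrl_an", "external_afs"]
    return pd.DataFrame(rows, columns=cols)


def filter_variants(
    records: Iterable[VariantRecord] | pd.DataFrame,
    config: FilterConfig,
) -> pd.DataFrame:
    """Apply the MAF filters; returns the retained variants with MAF columns.

    A variant is retained when its minor allele frequency is at or below
    ``internal_maf_max`` in *both* datasets (a failure in either removes it
    from both), every available external reference frequency is at or
    below ``external_maf_max`` (when configured), and it carries at least
    one minor allele in cases or controls.  MAF rules are evaluated only
    where an allele number is available.
    """
    df = _as_frame(records)
    if df.empty:
        out = df.copy()
        for col in ("case_maf", "ctrl_maf", "case_flipped", "ctrl_flipped"):
            out[col] = []
        return out
    case = [compute_maf(a, n) for a, n in zip(df["case_ac"], df["case_an"])]
    ctrl = [compute_maf(a, n) for a, n in zip(df["ctrl_ac"], df["ctrl_an"])]
    df["case_maf"] = [m for m, _ in case]
    df["case_flipped"] = [fl for _, fl in case]
    df["ctrl_maf"] = [m for m, _ in ctrl]
    df["ctrl_flipped"] = [fl for _, fl in ctrl]

    def _minor_count(ac, an, flipped):
        return (an - ac) if flipped else ac

    df["case_minor"] = [
        _minor_count(a, n, fl) for a, n, fl in zip(df["case_ac"], df["case_an"], df["case_flipped"])
    ]
    df["ctrl_minor"] = [
        _minor_count(a, n, fl) for a, n, fl in zip(df["ctrl_ac"], df["ctrl_an"], df["ctrl_flipped"])
    ]

    keep = np.ones(len(df), bool)
    # internal filter, where computable; failing either dataset removes the
    # variant from both
    for col in ("case_maf", "ctrl_maf"):
        maf = df[col].to_numpy(float)
        keep &= ~(np.isfinite(maf) & (maf > config.internal_maf_max))
    if config.external_maf_max is not None:
        ext_ok = np.array([
            all(f <= config.external_maf_max for f in afs if np.isfinite(f))
            for afs in df["external_afs"]
        ])
        keep &= ext_ok
    # variants absent from both datasets carry no information
    keep &= (df["case_minor"].to_numpy(float) + df["ctrl_minor"].to_numpy(float)) > 0
    return df.loc[keep].reset_index(drop=True)


def aggregate(
    records: Iterable[VariantRecord] | pd.DataFrame,
    strategy: ClassificationStrategy = ClassificationStrategy(),
    config: FilterConfig = FilterConfig(),
    *,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Per-gene count quadruples from a variant table.

    Filters (unless ``prefiltered``), classifies, sums minor-allele counts
    per gene into ``x1f, x1p, x0f, x0p``, and keeps only genes whose
    functional total (x1f + x0f) and proxy total (x1p + x0p) each reach
    ``config.min_alleles``.  Returns a DataFrame indexed by position with a
    ``gene`` column, ready for the gene-level tests.
    """
    df = _as_frame(records) if prefiltered else filter_variants(records, config)
    if df.empty:
        return pd.DataFrame(columns=["gene", "x1f", "x1p", "x0f", "x0p"])
    if "case_minor" not in df.columns:
        case = [compute_maf(a, n) for a, n in zip(df["case_ac"], df["case_an"])]
        ctrl = [compute_maf(a, n) for a, n in zip(df["ctrl_ac"], df["ctrl_an"])]
        df["case_minor"] = [
            (n - a) if fl else a for (a, n, (_, fl)) in zip(df["case_ac"], df["case_an"], case)
        ]
        df["ctrl_minor"] = [
            (n - a) if fl else a for (a, n, (_, fl)) in zip(df["ctrl_ac"], df["ctrl_an"], ctrl)
        ]
    df["category"] = [classify(t, strategy) for t in df["consequence_terms"]]
    df = df[df["category"] != "excluded"]
    if df.empty:
        return pd.DataFrame(columns=["gene", "x1f", "x1p", "x0f", "x0p"])
    is_f = df["category"] == "functional"
    agg = pd.DataFrame({
        "gene": df["gene"],
        "x1f": df["case_minor"].where(is_f, 0),
        "x1p": df["case_minor"].where(~is_f, 0),
        "x0f": df["ctrl_minor"].where(is_f, 0),
        "x0p": df["ctrl_minor"].where(~is_f, 0),
    }).groupby("gene", sort=True, as_index=False).sum()
    func_total = agg["x1f"] + agg["x0f"]
    prox_total = agg["x1p"] + agg["x0p"]
    keep = (func_total >= config.min_alleles) & (prox_total >= config.min_alleles)
    return agg.loc[keep].reset_index(drop=True)
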