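"""Instrument construction for drug-target MR.

A drug-target instrument set is built in three stages: restrict to the cis
window around the target gene and to genome-wide-significant associations,
thin by greedy LD clumping, then drop weak instruments by the F statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .gwas_io import GeneRegion, GwasRecord, LdMatrix, ValidationError


@dataclass
class InstrumentSet:
    """Clumped, strength-filtered cis variants for one target/trait pair."""

    label: str
    target_gene: Optional[GeneRegion]
    trait: str
    records: List[GwasRecord]
    r2_threshold: float
    f_stats: List[float]
    stage_log: Dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def select_cis_variants(
    records: Sequence[GwasRecord],
    region: GeneRegion,
    window_bp: int,
    p_threshold: float,
) -> List[GwasRecord]:
    """Keep variants inside the cis window with p strictly below the threshold.

    The window is [start - window_bp, end + window_bp], clamped at position 1 for
    genes near a chromosome start. Input order is preserved; variants on other
    chromosomes are filtered out.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    lo = max(1, region.start - window_bp)
    hi = region.end + window_bp
    return [
        r
        for r in records
        if r.chromosome == region.chromosome
        and lo <= r.position <= hi
        and r.pvalue < p_threshold
    ]


def clump(
    records: Sequence[GwasRecord],
    ld: LdMatrix,
    r2_threshold: float,
    window_kb: int,
) -> List[GwasRecord]:
    """Greedy LD clumping.

    Repeatedly retain the most significant remaining variant (p ascending, ties
    broken by variant_id) and discard every remaining variant that is both in LD
    with it (r2 >= r2_threshold) and on the same chromosome within window_kb of
    it. The retained set is returned sorted by position and is independent of the
    input order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    for r in records:
        if r.variant_id not in ld:
            raise ValidationError(f"variant {r.variant_id!r} absent from LD matrix")
    window_bp = window_kb * 1000
    pending = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
    retained: List[GwasRecord] = []
    while pending:
        best = pending.pop(0)
        retained.append(best)
        pending = [
            r
            for r in pending
            if not (
                r.chromosome == best.chromosome
                and abs(r.position - best.position) <= window_bp
                and ld.r2_between(best.variant_id, r.variant_id) >= r2_threshold
            )
        ]
    return sorted(retained, key=lambda r: (r.chromosome, r.position, r.variant_id))


def f_statistic(record: GwasRecord) -> float:
    """Per-variant instrument strength F = (beta / se)^2."""
    return (record.beta / record.se) ** 2


def build_instrument_set(
    records: Sequence[GwasRecord],
    region: GeneRegion,
    trait: str,
    window_bp: int,
    p_threshold: float,
    ld: LdMatrix,
    r2_threshold: float,
    f_cutoff: float,
    label: Optional[str] = None,
) -> InstrumentSet:
    """Compose cis selection, clumping and F filtering into an instrument set.

    An empty final set is a valid (warning-level) result: downstream code decides
    what to do with it. The stage log records variant counts after each stage.
    """
    cis = select_cis_variants(records, region, window_bp, p_threshold)
    clumped = clump(cis, ld, r2_threshold, window_kb=10_000) if cis else []
    strong = [r for r in clumped if f_statistic(r) > f_cutoff]
    return InstrumentSet(
        label=label or f"{region.gene}|{trait}",
        target_gene=region,
        trait=trait,
        records=strong,
        r2_threshold=r2_threshold,
        f_stats=[f_statistic(r) for r in strong],
        stage_log={
            "input": len(records),
            "cis_significant": len(cis),
            "clumped": len(clumped),
            "strong": len(strong),
        },
    )


def build_genomewide_instrument_set(
    records: Sequence[GwasRecord],
    trait: str,
    p_threshold: float,
    ld: LdMatrix,
    r2_threshold: float,
    window_kb: int,
    f_cutoff: float,
) -> InstrumentSet:
    """Instrument set for a metabolite/protein trait: genome-wide significance
    filter and clumping without any cis restriction (no anchor gene)."""
    sig = [r for r in records if r.pvalue < p_threshold]
    clumped = clump(sig, ld, r2_threshold, window_kb) if sig else []
    strong = [r for r in clumped if f_statistic(r) > f_cutoff]
    return InstrumentSet(
        label=trait,
        target_gene=None,
        trait=trait,
        records=strong,
        r2_threshold=r2_threshold,
        f_stats=[f_statistic(r) for r in strong],
        stage_log={
            "input": len(records),
            "significant": len(sig),
            "clumped": len(clumped),
            "strong": len(strong),
        },
    )
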