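"""Align exposure and outcome summary statistics to a common effect allele.

Summary files from different consortia may report the same variant on opposite
strands or with effect/other alleles swapped. Harmonization resolves both and
drops variants whose orientation cannot be established: palindromic (A/T, C/G)
variants are kept only when the allele frequencies on both sides are informative
(minor-allele frequency below a limit, conventionally 0.42) and agree on which
allele is which; everything irreconcilable is dropped with an explicit status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from .gwas_io import GwasRecord

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_PALINDROMIC_EAF_LIMIT = 0.42

STATUS_KEPT = "kept"
STATUS_FLIPPED = "flipped"
STATUS_DROPPED_PALINDROMIC = "dropped_palindromic"
STATUS_DROPPED_MISMATCH = "dropped_mismatch"

_RETAINED = (STATUS_KEPT, STATUS_FLIPPED)


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects aligned to one effect allele.

    Dropped pairs carry no outcome betas (set to None) so they cannot leak into
    estimator input.
    """

    variant_id: str
    effect_allele: str
    status: str
    beta_exposure: Optional[float] = None
    se_exposure: Optional[float] = None
    beta_outcome: Optional[float] = None
    se_outcome: Optional[float] = None
    eaf_exposure: Optional[float] = None
    eaf_outcome: Optional[float] = None

    @property
    def retained(self) -> bool:
        return self.status in _RETAINED


def is_palindromic(a: str, b: str) -> bool:
    return COMPLEMENT.get(a) == b


def _dropped(exposure: GwasRecord, status: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exposure.variant_id,
        effect_allele=exposure.effect_allele,
        status=status,
    )


def harmonize_pair(
    exposure: GwasRecord,
    outcome: GwasRecord,
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT,
) -> HarmonizedPair:
    """Harmonize one exposure/outcome record pair sharing a variant id.

    Non-palindromic variants: direct allele match is kept as-is; swapped alleles
    flip the outcome beta (and eaf -> 1 - eaf); strand complementation is tried
    before declaring a mismatch. Palindromic variants are aligned by allele
    frequency alone: kept (unchanged) when both eafs are informative
    (min(eaf, 1-eaf) < limit) and fall on the same side of 0.5, else dropped.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure.variant_id!r} vs {outcome.variant_id!r}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    ea_o, oa_o = outcome.effect_allele, outcome.other_allele

    def _pair(beta_outcome: float, status: str, eaf_outcome: Optional[float]) -> HarmonizedPair:
        return HarmonizedPair(
            variant_id=exposure.variant_id,
            effect_allele=ea,
            status=status,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=beta_outcome,
            se_outcome=outcome.se,
            eaf_exposure=exposure.eaf,
            eaf_outcome=eaf_outcome,
        )

    if is_palindromic(ea, oa):
        if {ea_o, oa_o} != {ea, oa}:
            return _dropped(exposure, STATUS_DROPPED_MISMATCH)
        eaf_e, eaf_u = exposure.eaf, outcome.eaf
        if eaf_e is None or eaf_u is None:
            return _dropped(exposure, STATUS_DROPPED_PALINDROMIC)
        if min(eaf_e, 1 - eaf_e) >= palindromic_eaf_limit:
            return _dropped(exposure, STATUS_DROPPED_PALINDROMIC)
        if min(eaf_u, 1 - eaf_u) >= palindromic_eaf_limit:
            return _dropped(exposure, STATUS_DROPPED_PALINDROMIC)
        if (eaf_e - 0.5) * (eaf_u - 0.5) <= 0:
            return _dropped(exposure, STATUS_DROPPED_PALINDROMIC)
        # Frequencies agree on the orientation: the outcome's effect allele plays
        # the exposure effect allele's role whatever strand it was reported on.
        return _pair(outcome.beta, STATUS_KEPT, eaf_u)

    if (ea_o, oa_o) == (ea, oa):
        return _pair(outcome.beta, STATUS_KEPT, outcome.eaf)
    if (ea_o, oa_o) == (oa, ea):
        flipped_eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
        return _pair(-outcome.beta, STATUS_FLIPPED, flipped_eaf)
    cea, coa = COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)
    if (cea, coa) == (ea, oa):
        return _pair(outcome.beta, STATUS_KEPT, outcome.eaf)
    if (cea, coa) == (oa, ea):
        flipped_eaf = None if outcome.eaf is None else 1.0 - outcome.eaf
        return _pair(-outcome.beta, STATUS_FLIPPED, flipped_eaf)
    return _dropped(exposure, STATUS_DROPPED_MISMATCH)


def harmonize_records(
    exposures: Sequence[GwasRecord],
    outcomes: Iterable[GwasRecord],
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT,
) -> List[HarmonizedPair]:
    """Join two tables on variant_id (string equality only) and harmonize.

    Exposure order is preserved; exposure variants absent from the outcome table
    are silently skipped (they cannot be harmonized at all).
    """
    by_id: Dict[str, GwasRecord] = {r.variant_id: r for r in outcomes}
    pairs: List[HarmonizedPair] = []
    for exp in exposures:
        out = by_id.get(exp.variant_id)
        if out is None:
            continue
        pairs.append(harmonize_pair(exp, out, palindromic_eaf_limit))
    return pairs


def retained_pairs(pairs: Iterable[HarmonizedPair]) -> List[HarmonizedPair]:
    """Pairs eligible as estimator input (status kept or flipped)."""
    return [p for p in pairs if p.retained]
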