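"""Orchestration of the full two-step drug-target MR mediation design.

Stages, in order:

1. Build cis instrument sets for every (target gene, lipid trait) pair.
2. MR of every target against a positive-control outcome; targets whose
   FDR-adjusted control p-value is non-significant, or whose estimate direction
   disagrees with MR-Egger, are excluded from everything downstream.
3. Step-1 MR: surviving targets against the final outcome(s) (beta3) and
   against each mediator (beta1).
4. Step-2 MR: mediators against the outcome(s) (beta2), with the stricter
   metabolite clumping threshold.
5. BH FDR within each outcome family, reliability flags, and the mediation
   proportion (beta1*beta2) / (beta3 + beta1*beta2) for every triple whose
   three betas are statistically significant.

Every analysis is deterministic given the study seed: bootstrap seeds are
derived from the seed and the analysis label, never from global state.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from statsmodels.stats.multitest import multipletests

from . import report
from .estimators import (
    METHOD_EGGER,
    METHOD_IVW,
    METHOD_WALD,
    MrResult,
    ivw,
    mode_estimate,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from .gwas_io import GeneRegion, GwasRecord, LdMatrix, ValidationError, write_results_table
from .harmonize import DEFAULT_PALINDROMIC_EAF_LIMIT, harmonize_records, retained_pairs
from .instruments import InstrumentSet, build_genomewide_instrument_set, build_instrument_set
from .sensitivity import diagnostics

ALL_METHODS = (METHOD_IVW, METHOD_EGGER, "weighted_median", "simple_mode", "weighted_mode")


class PipelineError(Exception):
    """A stage failure, annotated with stage context."""


class UndefinedProportionError(ZeroDivisionError):
    """Total effect is numerically zero; the mediated proportion is undefined."""


@dataclass
class StudyConfig:
    """All thresholds and structure for one study run.

    Defaults mirror the conventional drug-target MR settings: +/-100 kb cis
    window, genome-wide significance 5e-8, instrument clumping at r2 < 0.30
    (weak-LD instruments maximize strength for a single gene), metabolite
    clumping at r2 < 0.001, 10,000-kb clump window, F > 10, alpha 0.05.
    """

    targets: List[Tuple[str, str]] = field(default_factory=list)  # (gene, exposure trait)
    mediators: List[str] = field(default_factory=list)
    outcomes: List[str] = field(default_factory=list)
    control_outcome: Optional[str] = None
    window_kb: float = 100.0
    p_threshold: float = 5e-8
    r2_instruments: float = 0.30
    r2_metabolites: float = 0.001
    clump_window_kb: int = 10_000
    f_cutoff: float = 10.0
    alpha: float = 0.05
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT
    seed: int = 20231116
    n_boot: int = 1000
    fdr_family: str = "outcome"  # or "global"
    mediation_gate: str = "raw"  # or "fdr"
    methods: Tuple[str, ...] = ALL_METHODS
    trait_types: Dict[str, str] = field(default_factory=dict)  # trait -> quantitative|binary

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("window_kb", "p_threshold", "r2_instruments", "r2_metabolites", "f_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MediationResult:
    """The three mediation betas and the proportion mediated.

    beta1: exposure-proxy effect on the mediator (SD per SD); beta2: mediator
    effect on the outcome (log-odds per SD); beta3: the step-1 MR estimate of
    the exposure proxy on the outcome (log-odds). indirect = beta1*beta2;
    total = beta3 + indirect; proportion = indirect / total. Note beta3 is the
    unadjusted step-1 estimate, which in a single-exposure MR is conventionally
    the *total* effect even though the mediation formula treats it as direct;
    the printed formula is implemented exactly as stated.
    """

    target_label: str
    mediator: str
    outcome: str
    beta1: float
    beta2: float
    beta3: float
    indirect: float
    total: float
    proportion: float
    computed: bool = True

    @property
    def proportion_pct(self) -> float:
        return self.proportion * 100.0


@dataclass
class Analysis:
    """One exposure->outcome MR with all requested methods and diagnostics."""

    label: str
    outcome: str
    n_snps: int
    results: Dict[str, MrResult]
    primary: Optional[MrResult]
    egger: Optional[MrResult]


@dataclass
class StudyResult:
    instruments: Dict[str, InstrumentSet]
    analyses: Dict[Tuple[str, str], Analysis]
    results: List[MrResult]
    excluded_targets: List[str]
    mediation: List[MediationResult]
    manifest: Dict

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_results_table(self.results, os.path.join(out_dir, "mr_results.tsv"))
        report.render_mediation_table(self.mediation, os.path.join(out_dir, "mediation.tsv"))
        primaries = [a.primary for a in self.analyses.values() if a.primary is not None]
        report.render_forest_data(primaries, os.path.join(out_dir, "forest_data.tsv"))
        with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def bh_fdr(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    pvals = list(pvalues)
    for p in pvals:
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"p-value {p} outside (0, 1]")
    if not pvals:
        return []
    return [float(x) for x in multipletests(pvals, method="fdr_bh")[1]]


def reliability_check(primary: MrResult, egger: Optional[MrResult], alpha: float = 0.05) -> bool:
    """A causal estimate is reliable when the IVW/Wald estimate is significant
    and its sign agrees with MR-Egger's; single-instrument sets (no Egger fit
    possible) pass on significance alone and are flagged direction-unverified
    by the caller."""
    if primary.method not in (METHOD_IVW, METHOD_WALD):
        raise ValueError("primary result must come from ivw or wald_ratio")
    if primary.pvalue >= alpha:
        return False
    if egger is None:
        return True
    return (primary.beta >= 0) == (egger.beta >= 0)


def mediation_proportion(
    beta1: float,
    beta2: float,
    beta3: float,
    target_label: str = "",
    mediator: str = "",
    outcome: str = "",
    computed: bool = True,
) -> MediationResult:
    """Proportion mediated = (beta1*beta2) / (beta3 + beta1*beta2)."""
    indirect = beta1 * beta2
    total = beta3 + indirect
    if abs(total) < 1e-12:
        raise UndefinedProportionError("total effect is numerically zero")
    return MediationResult(
        target_label=target_label,
        mediator=mediator,
        outcome=outcome,
        beta1=beta1,
        beta2=beta2,
        beta3=beta3,
        indirect=indirect,
        total=total,
        proportion=indirect / total,
        computed=computed,
    )


def positive_control_gate(
    control_analyses: Mapping[str, Analysis],
    alpha: float,
) -> List[str]:
    """Exclude targets that fail the positive-control analysis.

    A target is excluded when its FDR-adjusted control p-value (adjusted across
    all targets) is >= alpha or when the reliability check (significance +
    Egger direction agreement) fails. Targets with no control estimate at all
    are excluded too.
    """
    labels = sorted(control_analyses)
    testable = [l for l in labels if control_analyses[l].primary is not None]
    adj = bh_fdr([control_analyses[l].primary.pvalue for l in testable])
    excluded = [l for l in labels if control_analyses[l].primary is None]
    for label, adj_p in zip(testable, adj):
        a = control_analyses[label]
        a.primary.fdr_pvalue = adj_p
        if adj_p >= alpha or not reliability_check(a.primary, a.egger, alpha):
            excluded.append(label)
    return sorted(excluded)


def _analysis_seed(base_seed: int, label: str, outcome: str) -> int:
    return (base_seed ^ zlib.crc32(f"{label}->{outcome}".encode())) % (2**31)


def _run_analysis(
    label: str,
    outcome_name: str,
    exposure_records: Sequence[GwasRecord],
    outcome_records: Sequence[GwasRecord],
    config: StudyConfig,
) -> Optional[Analysis]:
    pairs = retained_pairs(
        harmonize_records(exposure_records, outcome_records, config.palindromic_eaf_limit)
    )
    n = len(pairs)
    if n == 0:
        return None
    results: Dict[str, MrResult] = {}
    seed = _analysis_seed(config.seed, label, outcome_name)
    if n == 1:
        results[METHOD_WALD] = wald_ratio(pairs[0], exposure=label, outcome=outcome_name)
    else:
        if METHOD_IVW in config.methods:
            results[METHOD_IVW] = ivw(pairs, exposure=label, outcome=outcome_name)
        if n >= 3:
            if METHOD_EGGER in config.methods:
                results[METHOD_EGGER] = mr_egger(pairs, exposure=label, outcome=outcome_name)
            if "weighted_median" in config.methods:
                results["weighted_median"] = weighted_median(
                    pairs, config.n_boot, seed, exposure=label, outcome=outcome_name
                )
            if "simple_mode" in config.methods:
                results["simple_mode"] = mode_estimate(
                    pairs, weighted=False, n_boot=config.n_boot, seed=seed,
                    exposure=label, outcome=outcome_name,
                )
            if "weighted_mode" in config.methods:
                results["weighted_mode"] = mode_estimate(
                    pairs, weighted=True, n_boot=config.n_boot, seed=seed,
                    exposure=label, outcome=outcome_name,
                )
    sens = diagnostics(pairs) if n >= 2 else None
    if sens is not None:
        for res in results.values():
            res.q_stat = sens.q_stat
            res.q_pvalue = sens.q_pvalue
            if res.method != METHOD_EGGER:
                res.egger_intercept = sens.egger_intercept
                res.egger_intercept_pvalue = sens.egger_intercept_pvalue
    primary = results.get(METHOD_IVW) or results.get(METHOD_WALD)
    return Analysis(
        label=label,
        outcome=outcome_name,
        n_snps=n,
        results=results,
        primary=primary,
        egger=results.get(METHOD_EGGER),
    )


def run_two_step(
    config: StudyConfig,
    datasets: Mapping[str, Sequence[GwasRecord]],
    ld: LdMatrix,
    regions: Mapping[str, GeneRegion],
) -> StudyResult:
    """Execute the full design and return the results bundle (see module docs)."""
    for _, trait in config.targets:
        if trait not in datasets:
            raise PipelineError(f"instrument stage: exposure trait {trait!r} not in datasets")
    for name in list(config.mediators) + list(config.outcomes):
        if name not in datasets:
            raise PipelineError(f"dataset for trait {name!r} missing")
    if config.control_outcome is not None and config.control_outcome not in datasets:
        raise PipelineError(f"control outcome {config.control_outcome!r} not in datasets")

    instruments: Dict[str, InstrumentSet] = {}
    for gene, trait in config.targets:
        if gene not in regions:
            raise PipelineError(f"instrument stage: no region for gene {gene!r}")
        instruments[f"{gene}|{trait}"] = build_instrument_set(
            datasets[trait],
            regions[gene],
            trait,
            window_bp=int(config.window_kb * 1000),
            p_threshold=config.p_threshold,
            ld=ld,
            r2_threshold=config.r2_instruments,
            f_cutoff=config.f_cutoff,
        )

    analyses: Dict[Tuple[str, str], Analysis] = {}

    # (a) positive-control gate
    excluded: List[str] = []
    if config.control_outcome is not None:
        control_analyses: Dict[str, Analysis] = {}
        for label, inst in instruments.items():
            a = _run_analysis(label, config.control_outcome, inst.records,
                              datasets[config.control_outcome], config)
            if a is None:
                a = Analysis(label, config.control_outcome, 0, {}, None, None)
            control_analyses[label] = a
            analyses[(label, config.control_outcome)] = a
        excluded = positive_control_gate(control_analyses, config.alpha)
    surviving = [l for l in instruments if l not in excluded]

    # (b) targets -> outcomes, (c) targets -> mediators
    for label in surviving:
        inst = instruments[label]
        for outcome_name in list(config.outcomes) + list(config.mediators):
            a = _run_analysis(label, outcome_name, inst.records, datasets[outcome_name], config)
            if a is not None:
                analyses[(label, outcome_name)] = a

    # (d) mediators -> outcomes, with the stricter metabolite clumping
    med_instruments: Dict[str, InstrumentSet] = {}
    for mediator in config.mediators:
        med_instruments[mediator] = build_genomewide_instrument_set(
            datasets[mediator],
            mediator,
            config.p_threshold,
            ld,
            config.r2_metabolites,
            config.clump_window_kb,
            config.f_cutoff,
        )
        for outcome_name in config.outcomes:
            a = _run_analysis(mediator, outcome_name, med_instruments[mediator].records,
                              datasets[outcome_name], config)
            if a is not None:
                analyses[(mediator, outcome_name)] = a
    instruments_all = dict(instruments)
    instruments_all.update(med_instruments)

    # FDR within each outcome family (control handled inside the gate) + reliability
    families: Dict[str, List[Analysis]] = {}
    for (label, outcome_name), a in analyses.items():
        if outcome_name == config.control_outcome or a.primary is None:
            continue
        key = "all" if config.fdr_family == "global" else outcome_name
        families.setdefault(key, []).append(a)
    for members in families.values():
        members.sort(key=lambda a: (a.label, a.outcome))
        for a, adj in zip(members, bh_fdr([a.primary.pvalue for a in members])):
            a.primary.fdr_pvalue = adj
    for a in analyses.values():
        if a.primary is not None:
            a.primary.reliable = reliability_check(a.primary, a.egger, config.alpha)

    # mediation triples
    mediation: List[MediationResult] = []
    gate_attr = "fdr_pvalue" if config.mediation_gate == "fdr" else "pvalue"

    def _gate_p(a: Optional[Analysis]) -> Optional[float]:
        if a is None or a.primary is None:
            return None
        return getattr(a.primary, gate_attr)

    for label in surviving:
        _, trait = next((g, t) for g, t in config.targets if f"{g}|{t}" == label)
        for mediator in config.mediators:
            for outcome_name in config.outcomes:
                a1 = analyses.get((label, mediator))
                a2 = analyses.get((mediator, outcome_name))
                a3 = analyses.get((label, outcome_name))
                p1, p2, p3 = _gate_p(a1), _gate_p(a2), _gate_p(a3)
                if any(p is None or p >= config.alpha for p in (p1, p2, p3)):
                    continue
                mediation.append(
                    mediation_proportion(
                        a1.primary.beta,
                        a2.primary.beta,
                        a3.primary.beta,
                        target_label=label,
                        mediator=mediator,
                        outcome=outcome_name,
                    )
                )

    all_rows = [res for a in analyses.values() for res in a.results.values()]
    manifest = {
        "config": _jsonable(dataclasses.asdict(config)),
        "instrument_stage_logs": {k: v.stage_log for k, v in instruments_all.items()},
        "excluded_targets": excluded,
        "direction_unverified": sorted(
            a.label for a in analyses.values()
            if a.primary is not None and a.egger is None and a.primary.reliable
        ),
        "n_analyses": len(analyses),
        "n_results": len(all_rows),
        "n_mediation": len(mediation),
    }
    return StudyResult(
        instruments=instruments_all,
        analyses=analyses,
        results=all_rows,
        excluded_targets=excluded,
        mediation=mediation,
        manifest=manifest,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
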