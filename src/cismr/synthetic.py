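"""Synthetic GWAS summary statistics with a known causal chain.

The generator works at the summary-statistic level: per-SNP true marginal
effects are constructed analytically from sparse standardized causal effects
convolved through an AR(1) LD structure, and observed betas are drawn from
Normal(true, se^2) with the standard asymptotic standard errors

    se_j = 1 / sqrt(2 maf_j (1 - maf_j) n)                      (quantitative)
    se_j = 1 / sqrt(2 maf_j (1 - maf_j) n phi (1 - phi))        (binary, case
                                                                 fraction phi)

The causal chain is exposure -> mediator -> outcome with a direct
exposure -> outcome path, so at the target locus the outcome's per-SNP effect
is (direct + beta1*beta2) * beta_marginal — MR at that locus recovers the
*generative total effect*, not the direct path alone. The mediator's own
genetics live in a second, independent locus, which is what makes the
mediator -> outcome step (beta2) identifiable.

Default parameter values emulate the study conditions of a lipid-trait /
plasma-protein / lung-cancer design: a very large quantitative exposure GWAS
(n = 439,214), a small mediator GWAS (n = 3,301; plasma protein levels), a
binary outcome GWAS of 40,187 with case fraction 0.578, and a binary positive
control of 86,995 with case fraction 0.256. The small mediator GWAS keeps
exposure-locus SNPs from reaching genome-wide significance for the mediator,
so step-2 instruments come from the mediator's own locus, as they do in the
real data sources this emulates.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .gwas_io import (
    GeneRegion,
    GwasRecord,
    LdMatrix,
    write_gwas,
    write_ld_matrix,
    write_regions,
)

_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass
class SimulationConfig:
    """Generative parameters for one cis region and its three traits."""

    n_snps: int = 100
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.8
    n_exposure: int = 439_214
    n_mediator: int = 3_301
    n_outcome: int = 40_187
    case_fraction: float = 0.578
    causal_beta_exposure_outcome: float = -0.20  # direct path, log-odds per SD
    beta1_true: float = 0.24  # exposure -> mediator, SD per SD
    beta2_true: float = -0.08  # mediator -> outcome, log-odds per SD
    n_causal_snps: int = 20
    gamma_sd: float = 0.1  # per-SNP standardized effect scale at the target locus
    mediator_gamma_sd: float = 0.5  # per-SNP effect scale at the mediator's own locus
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    mediator_noise_sd: float = 0.0
    palindromic_fraction: float = 0.0
    n_control: int = 86_995
    control_case_fraction: float = 0.256
    control_beta: float = -0.45  # exposure -> control outcome, log-odds per SD
    chromosome: str = "1"
    region_start: int = 1_000_000
    snp_spacing: int = 1_000
    seed: int = 20231116

    def __post_init__(self) -> None:
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps must be <= n_snps")
        for name in ("n_exposure", "n_mediator", "n_outcome", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class RegionLatents:
    """Latent quantities of one simulated locus (shared across its traits)."""

    chromosome: str
    variant_ids: List[str]
    positions: np.ndarray
    alleles: List[Tuple[str, str]]
    mafs: np.ndarray
    eafs: np.ndarray
    corr: np.ndarray  # signed AR(1) correlation matrix
    gamma: np.ndarray  # sparse causal effects
    beta_marginal: np.ndarray  # LD-convolved marginal effects

    @property
    def ld(self) -> LdMatrix:
        return LdMatrix(tuple(self.variant_ids), self.corr**2)

    def region(self, gene: str, pad: int = 0) -> GeneRegion:
        return GeneRegion(
            gene=gene,
            chromosome=self.chromosome,
            start=max(1, int(self.positions.min()) - pad),
            end=int(self.positions.max()) + pad,
        )


@dataclass
class SimulatedRegion:
    gene_region: GeneRegion
    exposure: List[GwasRecord]
    mediator: List[GwasRecord]
    outcome: List[GwasRecord]
    ld: LdMatrix
    truth: Dict


@dataclass
class SimulatedStudy:
    datasets: Dict[str, List[GwasRecord]]
    ld: LdMatrix
    regions: Dict[str, GeneRegion]
    truth: Dict
    config: SimulationConfig


def _simulate_latents(
    rng: np.random.Generator,
    config: SimulationConfig,
    chromosome: str,
    gamma_sd: float,
    id_prefix: str,
) -> RegionLatents:
    n = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], n)
    idx = np.arange(n)
    corr = float(config.ld_rho) ** np.abs(idx[:, None] - idx[None, :])
    causal = np.sort(rng.choice(n, config.n_causal_snps, replace=False))
    gamma = np.zeros(n)
    gamma[causal] = rng.normal(0.0, gamma_sd, config.n_causal_snps)
    alleles: List[Tuple[str, str]] = []
    for i in range(n):
        if rng.random() < config.palindromic_fraction:
            pair = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            pair = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        if rng.random() < 0.5:
            pair = (pair[1], pair[0])
        alleles.append(pair)
    eafs = np.where(rng.random(n) < 0.5, mafs, 1.0 - mafs)
    positions = config.region_start + idx * config.snp_spacing
    return RegionLatents(
        chromosome=chromosome,
        variant_ids=[f"{id_prefix}_{i:04d}" for i in range(n)],
        positions=positions,
        alleles=alleles,
        mafs=mafs,
        eafs=eafs,
        corr=corr,
        gamma=gamma,
        beta_marginal=corr @ gamma,
    )


def _observe(
    rng: np.random.Generator,
    latents: RegionLatents,
    true_betas: np.ndarray,
    n_samples: int,
    case_fraction: Optional[float] = None,
) -> List[GwasRecord]:
    """Draw observed summary statistics around the true marginal effects."""
    var_factor = 2.0 * latents.mafs * (1.0 - latents.mafs) * n_samples
    if case_fraction is not None:
        var_factor = var_factor * case_fraction * (1.0 - case_fraction)
    ses = 1.0 / np.sqrt(var_factor)
    betas = rng.normal(true_betas, ses)
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
    return [
        GwasRecord(
            variant_id=vid,
            chromosome=latents.chromosome,
            position=int(pos),
            effect_allele=ea,
            other_allele=oa,
            eaf=float(eaf),
            beta=float(b),
            se=float(s),
            pvalue=float(p),
            n=int(n_samples),
        )
        for vid, pos, (ea, oa), eaf, b, s, p in zip(
            latents.variant_ids, latents.positions, latents.alleles,
            latents.eafs, betas, ses, pvals,
        )
    ]


def simulate_region(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    gene: str = "TARGET1",
) -> SimulatedRegion:
    """Simulate one cis region for the exposure, mediator and binary outcome.

    The exposure's marginal effects are the convolved causal effects; the
    mediator responds with beta1 (plus optional mediator-specific per-SNP
    noise); the outcome responds with direct + beta1*beta2 plus per-SNP
    pleiotropy drawn Normal(pleiotropy_mean, pleiotropy_sd^2).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lat = _simulate_latents(rng, config, config.chromosome, config.gamma_sd, f"snp{config.chromosome}")
    pleio = (
        rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, config.n_snps)
        if (config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0)
        else np.zeros(config.n_snps)
    )
    med_noise = (
        rng.normal(0.0, config.mediator_noise_sd, config.n_snps)
        if config.mediator_noise_sd > 0
        else np.zeros(config.n_snps)
    )
    total = config.causal_beta_exposure_outcome + config.beta1_true * config.beta2_true
    exposure_true = lat.beta_marginal
    mediator_true = config.beta1_true * lat.beta_marginal + med_noise
    outcome_true = total * lat.beta_marginal + pleio
    exposure = _observe(rng, lat, exposure_true, config.n_exposure)
    mediator = _observe(rng, lat, mediator_true, config.n_mediator)
    outcome = _observe(rng, lat, outcome_true, config.n_outcome, config.case_fraction)
    truth = {
        "gamma": lat.gamma.tolist(),
        "beta_marginal": lat.beta_marginal.tolist(),
        "pleiotropy": pleio.tolist(),
        "total_effect": total,
        "direct_effect": config.causal_beta_exposure_outcome,
        "beta1_true": config.beta1_true,
        "beta2_true": config.beta2_true,
        "mediation_proportion_generative": (config.beta1_true * config.beta2_true) / total,
        "config": dataclasses.asdict(config),
    }
    return SimulatedRegion(
        gene_region=lat.region(gene),
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        ld=lat.ld,
        truth=truth,
    )


def _block_diag_ld(blocks: Sequence[LdMatrix]) -> LdMatrix:
    ids: List[str] = []
    for b in blocks:
        ids.extend(b.variant_ids)
    mat = np.zeros((len(ids), len(ids)))
    off = 0
    for b in blocks:
        k = len(b.variant_ids)
        mat[off : off + k, off : off + k] = b.r2
        off += k
    return LdMatrix(tuple(ids), mat)


def simulate_study(
    config: SimulationConfig,
    include_null_control_target: bool = False,
) -> SimulatedStudy:
    """Simulate the full two-step study: a target locus, an independent mediator
    locus, and optionally a second target locus whose control-outcome effect is
    null (to exercise the positive-control gate).

    Trait tables span every locus (with null true effects where a locus does
    not influence a trait), exactly as genome-wide summary files would.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_a, rng_b, rng_c = (np.random.default_rng(s) for s in ss.spawn(3))
    zeros = np.zeros(config.n_snps)
    total = config.causal_beta_exposure_outcome + config.beta1_true * config.beta2_true

    # locus A: the drug-target gene; exposure causal, everything downstream responds
    lat_a = _simulate_latents(rng_a, config, "1", config.gamma_sd, "snp1")
    pleio = (
        rng_a.normal(config.pleiotropy_mean, config.pleiotropy_sd, config.n_snps)
        if (config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0)
        else zeros
    )
    exposure = _observe(rng_a, lat_a, lat_a.beta_marginal, config.n_exposure)
    mediator = _observe(rng_a, lat_a, config.beta1_true * lat_a.beta_marginal, config.n_mediator)
    outcome = _observe(rng_a, lat_a, total * lat_a.beta_marginal + pleio,
                       config.n_outcome, config.case_fraction)
    control = _observe(rng_a, lat_a, config.control_beta * lat_a.beta_marginal,
                       config.n_control, config.control_case_fraction)
    regions = {"TARGET1": lat_a.region("TARGET1")}
    blocks = [lat_a.ld]

    # locus B: the mediator's own cis region; exposure unaffected
    lat_b = _simulate_latents(rng_b, config, "2", config.mediator_gamma_sd, "snp2")
    exposure += _observe(rng_b, lat_b, zeros, config.n_exposure)
    mediator += _observe(rng_b, lat_b, lat_b.beta_marginal, config.n_mediator)
    outcome += _observe(rng_b, lat_b, config.beta2_true * lat_b.beta_marginal,
                        config.n_outcome, config.case_fraction)
    control += _observe(rng_b, lat_b, zeros, config.n_control, config.control_case_fraction)
    regions["MEDGENE"] = lat_b.region("MEDGENE")
    blocks.append(lat_b.ld)

    if include_null_control_target:
        # locus C: a target whose instruments carry no control-outcome effect
        lat_c = _simulate_latents(rng_c, config, "3", config.gamma_sd, "snp3")
        exposure += _observe(rng_c, lat_c, lat_c.beta_marginal, config.n_exposure)
        mediator += _observe(rng_c, lat_c, zeros, config.n_mediator)
        outcome += _observe(rng_c, lat_c, zeros, config.n_outcome, config.case_fraction)
        control += _observe(rng_c, lat_c, zeros, config.n_control, config.control_case_fraction)
        regions["NULLTGT"] = lat_c.region("NULLTGT")
        blocks.append(lat_c.ld)

    truth = {
        "total_effect": total,
        "direct_effect": config.causal_beta_exposure_outcome,
        "beta1_true": config.beta1_true,
        "beta2_true": config.beta2_true,
        "control_beta": config.control_beta,
        "mediation_proportion_generative": (config.beta1_true * config.beta2_true) / total,
        "config": dataclasses.asdict(config),
    }
    return SimulatedStudy(
        datasets={
            "lipid": exposure,
            "ceramidase": mediator,
            "lung_cancer": outcome,
            "chd": control,
        },
        ld=_block_diag_ld(blocks),
        regions=regions,
        truth=truth,
        config=config,
    )


def study_config_for(sim: SimulatedStudy, **overrides):
    """A StudyConfig matching a simulated study's trait and gene names."""
    from .pipeline import StudyConfig

    targets = [("TARGET1", "lipid")]
    if "NULLTGT" in sim.regions:
        targets.append(("NULLTGT", "lipid"))
    defaults = dict(
        targets=targets,
        mediators=["ceramidase"],
        outcomes=["lung_cancer"],
        control_outcome="chd",
        seed=sim.config.seed,
        trait_types={
            "lipid": "quantitative",
            "ceramidase": "quantitative",
            "lung_cancer": "binary",
            "chd": "binary",
        },
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)


def write_study(sim: SimulatedStudy, out_dir) -> None:
    """Write a simulated study as plain-text inputs plus truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    for trait, records in sorted(sim.datasets.items()):
        write_gwas(records, os.path.join(out_dir, f"{trait}.tsv"))
    write_ld_matrix(sim.ld, os.path.join(out_dir, "ld.tsv"))
    write_regions(
        [sim.regions[g] for g in sorted(sim.regions)], os.path.join(out_dir, "regions.tsv")
    )
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(sim.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_fixture_suite(out_dir, seed: int = 20231116) -> None:
    """Write a small deterministic fixture set used by the tests and docs.

    Fixtures: ``strong`` (well-powered instruments), ``weak`` (F straddling the
    cutoff of 10), ``palindromic`` (A/T and C/G variants with informative and
    uninformative frequencies), ``swapped`` (outcome alleles swapped relative
    to the exposure), and ``study`` (a full two-locus study including a
    null-control target for the gate).
    """
    os.makedirs(out_dir, exist_ok=True)

    strong = simulate_region(
        SimulationConfig(n_snps=20, n_causal_snps=20, ld_rho=0.3, seed=seed),
        gene="STRONG1",
    )
    write_gwas(strong.exposure, os.path.join(out_dir, "strong_exposure.tsv"))
    write_gwas(strong.outcome, os.path.join(out_dir, "strong_outcome.tsv"))
    write_ld_matrix(strong.ld, os.path.join(out_dir, "strong_ld.tsv"))
    write_regions([strong.gene_region], os.path.join(out_dir, "strong_regions.tsv"))

    def rec(i, ea, oa, eaf, beta, se, chrom="1"):
        z = abs(beta / se)
        p = float(np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0))
        return GwasRecord(
            variant_id=f"fx_{i:03d}",
            chromosome=chrom,
            position=1_000_000 + i * 1000,
            effect_allele=ea,
            other_allele=oa,
            eaf=eaf,
            beta=beta,
            se=se,
            pvalue=p,
            n=100_000,
        )

    # F = (beta/se)^2: 400, 100, 9.99 (weak), 4 (weak)
    weak = [
        rec(0, "A", "G", 0.3, 0.10, 0.005),
        rec(1, "T", "C", 0.2, 0.10, 0.010),
        rec(2, "A", "C", 0.4, 0.0316, 0.010),
        rec(3, "T", "G", 0.1, 0.02, 0.010),
    ]
    write_gwas(weak, os.path.join(out_dir, "weak_exposure.tsv"))

    pal_exp = [
        rec(0, "A", "T", 0.10, 0.10, 0.005),
        rec(1, "C", "G", 0.85, 0.08, 0.005),
        rec(2, "A", "T", 0.50, 0.06, 0.005),
        rec(3, "G", "C", 0.45, 0.05, 0.005),
    ]
    pal_out = [
        rec(0, "A", "T", 0.12, 0.02, 0.01),
        rec(1, "G", "C", 0.18, -0.01, 0.01),
        rec(2, "A", "T", 0.50, 0.01, 0.01),
        rec(3, "C", "G", 0.44, 0.00, 0.01),
    ]
    write_gwas(pal_exp, os.path.join(out_dir, "palindromic_exposure.tsv"))
    write_gwas(pal_out, os.path.join(out_dir, "palindromic_outcome.tsv"))

    swap_exp = [
        rec(0, "A", "G", 0.3, 0.10, 0.005),
        rec(1, "T", "C", 0.2, -0.08, 0.005),
        rec(2, "C", "A", 0.6, 0.12, 0.005),
    ]
    swap_out = [
        rec(0, "G", "A", 0.7, 0.05, 0.01),
        rec(1, "C", "T", 0.8, 0.04, 0.01),
        rec(2, "A", "C", 0.4, -0.06, 0.01),
    ]
    write_gwas(swap_exp, os.path.join(out_dir, "swapped_exposure.tsv"))
    write_gwas(swap_out, os.path.join(out_dir, "swapped_outcome.tsv"))

    study = simulate_study(SimulationConfig(seed=seed), include_null_control_target=True)
    write_study(study, os.path.join(out_dir, "study"))
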