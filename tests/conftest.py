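import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cismr.gwas_io import GwasRecord
from cismr.harmonize import HarmonizedPair, STATUS_KEPT

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    variant_id="rs1",
    chromosome="1",
    position=1_000_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    n=100_000,
):
    return GwasRecord(
        variant_id=variant_id,
        chromosome=chromosome,
        position=position,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_pairs(bx, by, sy, sx=None):
    """Harmonized pairs from parallel beta/se sequences."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, dtype=float)
    return [
        HarmonizedPair(
            variant_id=f"rs{i}",
            effect_allele="A",
            status=STATUS_KEPT,
            beta_exposure=float(x),
            se_exposure=float(s_x),
            beta_outcome=float(y),
            se_outcome=float(s_y),
        )
        for i, (x, s_x, y, s_y) in enumerate(zip(bx, sx, by, sy))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20231116)


def random_pairs(rng, n, slope=0.5, het=0.0):
    """Random well-behaved instrument sets for oracle comparisons."""
    bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
    sy = rng.uniform(0.01, 0.1, n)
    by = slope * bx + rng.normal(0, het, n)
    sx = rng.uniform(0.001, 0.01, n)
    return make_pairs(bx, by, sy, sx)
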