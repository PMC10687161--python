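import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cismr.gwas_io import GeneRegion, LdMatrix, ValidationError
from cismr.instruments import (
    build_instrument_set,
    clump,
    f_statistic,
    select_cis_variants,
)
from conftest import make_record


def ld_from(ids, entries):
    n = len(ids)
    mat = np.eye(n)
    for (a, b), r2 in entries.items():
        i, j = ids.index(a), ids.index(b)
        mat[i, j] = mat[j, i] = r2
    return LdMatrix(tuple(ids), mat)


REGION = GeneRegion("APOB", "1", 1_000_000, 1_050_000)


class TestCisSelection:
    def test_window_boundary_retained(self):
        rec = make_record(position=950_000, pvalue=1e-9)
        assert select_cis_variants([rec], REGION, 100_000, 5e-8) == [rec]

    def test_outside_window_excluded(self):
        rec = make_record(position=1_160_000, pvalue=1e-20)
        assert select_cis_variants([rec], REGION, 100_000, 5e-8) == []

    def test_threshold_is_strict(self):
        rec = make_record(position=1_020_000, pvalue=5.0e-8)
        assert select_cis_variants([rec], REGION, 100_000, 5e-8) == []

    def test_other_chromosome_excluded(self):
        rec = make_record(chromosome="2", position=1_020_000, pvalue=1e-10)
        assert select_cis_variants([rec], REGION, 100_000, 5e-8) == []

    def test_zero_window_equals_gene_body(self):
        inside = make_record(variant_id="in", position=1_000_000, pvalue=1e-9)
        outside = make_record(variant_id="out", position=999_999, pvalue=1e-9)
        assert select_cis_variants([inside, outside], REGION, 0, 5e-8) == [inside]

    def test_window_clamped_at_position_one(self):
        region = GeneRegion("EDGE", "1", 50, 100)
        rec = make_record(position=1, pvalue=1e-9)
        assert select_cis_variants([rec], region, 1000, 5e-8) == [rec]


def brute_force_clump(records, ld, r2_threshold, window_kb):
    """Independent greedy oracle: explicit index bookkeeping over a table."""
    window_bp = window_kb * 1000
    alive = {r.variant_id: r for r in records}
    kept = []
    while alive:
        best = min(alive.values(), key=lambda r: (r.pvalue, r.variant_id))
        kept.append(best)
        del alive[best.variant_id]
        for vid in list(alive):
            r = alive[vid]
            close = (
                r.chromosome == best.chromosome
                and abs(r.position - best.position) <= window_bp
            )
            if close and ld.r2_between(best.variant_id, vid) >= r2_threshold:
                del alive[vid]
    return sorted(kept, key=lambda r: (r.chromosome, r.position, r.variant_id))


def three_variants():
    a = make_record(variant_id="A", position=1_000_000, pvalue=1e-10)
    b = make_record(variant_id="B", position=1_001_000, pvalue=1e-9)
    c = make_record(variant_id="C", position=1_002_000, pvalue=1e-8)
    ld = ld_from(["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): 0.1, ("B", "C"): 0.2})
    return [a, b, c], ld


class TestClump:
    def test_correlated_runnerup_discarded(self):
        recs, ld = three_variants()
        kept = clump(recs, ld, 0.30, 10_000)
        assert [r.variant_id for r in kept] == ["A", "C"]
        assert kept == brute_force_clump(recs, ld, 0.30, 10_000)

    def test_strict_threshold_keeps_only_index(self):
        recs, ld = three_variants()
        kept = clump(recs, ld, 0.001, 10_000)
        assert [r.variant_id for r in kept] == ["A"]
        assert kept == brute_force_clump(recs, ld, 0.001, 10_000)

    def test_unlinked_variants_all_retained(self):
        recs, ld = three_variants()
        ld = LdMatrix(ld.variant_ids, np.eye(3))
        assert len(clump(recs, ld, 0.30, 10_000)) == 3

    def test_threshold_one_retains_everything_not_identical(self):
        recs, ld = three_variants()
        assert len(clump(recs, ld, 1.0, 10_000)) == 3

    def test_outside_window_not_discarded_despite_ld(self):
        a = make_record(variant_id="A", position=1_000_000, pvalue=1e-10)
        b = make_record(variant_id="B", position=12_000_000, pvalue=1e-9)
        ld = ld_from(["A", "B"], {("A", "B"): 0.9})
        assert len(clump([a, b], ld, 0.30, 10_000)) == 2

    def test_missing_variant_in_ld_names_it(self):
        recs, ld = three_variants()
        ld = LdMatrix(("A", "B"), np.eye(2))
        with pytest.raises(ValidationError, match="C"):
            clump(recs, ld, 0.30, 10_000)

    def test_idempotent(self):
        recs, ld = three_variants()
        once = clump(recs, ld, 0.30, 10_000)
        assert clump(once, ld, 0.30, 10_000) == once

    @given(st.randoms(use_true_random=False))
    def test_order_invariance_matches_oracle(self, random):
        rng = np.random.default_rng(random.randrange(2**31))
        n = int(rng.integers(2, 9))
        recs = [
            make_record(
                variant_id=f"v{i}",
                position=1_000_000 + int(rng.integers(0, 50)) * 1000,
                pvalue=float(rng.choice([1e-10, 1e-9, 1e-8])),
            )
            for i in range(n)
        ]
        base = rng.uniform(0, 1, (n, n))
        mat = np.clip((base + base.T) / 2, 0, 1)
        np.fill_diagonal(mat, 1.0)
        ld = LdMatrix(tuple(f"v{i}" for i in range(n)), mat)
        expected = brute_force_clump(recs, ld, 0.30, 10_000)
        for perm in itertools.islice(itertools.permutations(recs), 6):
            assert clump(list(perm), ld, 0.30, 10_000) == expected


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.01, 100.0), (0.0, 0.5, 0.0), (0.0316, 0.01, 9.9856)],
    )
    def test_closed_form(self, beta, se, expected):
        rec = make_record(beta=beta, se=se)
        assert f_statistic(rec) == pytest.approx(expected, abs=1e-9)
        if expected < 10:
            assert f_statistic(rec) <= 10  # flagged weak at the conventional cutoff


class TestBuildInstrumentSet:
    def test_single_survivor(self):
        recs, ld = three_variants()
        inst = build_instrument_set(
            recs, REGION, "LDL", 100_000, 5e-8, ld, 0.001, 10.0
        )
        assert len(inst) == 1 and inst.records[0].variant_id == "A"
        assert inst.label == "APOB|LDL"
        assert inst.stage_log == {"input": 3, "cis_significant": 3, "clumped": 1, "strong": 1}

    def test_all_weak_yields_empty_set_with_log(self):
        recs, ld = three_variants()
        weak = [
            make_record(variant_id=r.variant_id, position=r.position,
                        pvalue=r.pvalue, beta=0.01, se=0.01)
            for r in recs
        ]  # F = 1
        inst = build_instrument_set(weak, REGION, "LDL", 100_000, 5e-8, ld, 0.30, 10.0)
        assert len(inst) == 0
        assert inst.stage_log["clumped"] > 0 and inst.stage_log["strong"] == 0

    def test_retained_set_exhaustively_satisfies_r2_bound(self):
        from cismr.synthetic import SimulationConfig, simulate_region

        cfg = SimulationConfig(n_snps=50, n_causal_snps=50, ld_rho=0.9,
                               gamma_sd=0.3, seed=99)
        region = simulate_region(cfg)
        inst = build_instrument_set(
            region.exposure, region.gene_region, "lipid",
            100_000, 5e-8, region.ld, 0.30, 10.0,
        )
        assert len(inst) > 1
        for a in inst.records:
            for b in inst.records:
                if a.variant_id != b.variant_id:
                    assert region.ld.r2_between(a.variant_id, b.variant_id) < 0.30
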