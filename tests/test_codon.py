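import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dotkit.codon import (
    CAI_CODONS,
    CodonUsageTable,
    FAMILIES,
    FAMILY_SIZES,
    GENETIC_CODE,
    SENSE_CODONS,
    cai,
    count_codons,
    effective_number_of_codons,
    loess_regime,
    no_bias_cai,
    relative_adaptiveness,
    select_reference_set,
)
from dotkit.synthio import (
    codon_table_from_preferences,
    generate_codon_tables,
    preferred_codon_table,
    sample_codon_table,
)

# ---------------------------------------------------------------------------
# independent oracles (no shared code with the implementation)

_ORACLE_FAMILIES: dict[str, list[str]] = {}
for _c, _a in GENETIC_CODE.items():
    _ORACLE_FAMILIES.setdefault(_a, []).append(_c)


def oracle_nc(counts: dict) -> float:
    f_sums = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in _ORACLE_FAMILIES.items():
        k = len(codons)
        if k == 1:
            continue
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n <= 1:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            f_sums[k].append(f)
    fbar = {k: sum(v) / len(v) if v else None for k, v in f_sums.items()}
    if fbar[3] is None:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    return 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]


def oracle_cai(counts: dict, ref_counts: dict) -> float:
    logs, n = 0.0, 0
    for aa, codons in _ORACLE_FAMILIES.items():
        if len(codons) == 1:
            continue
        floored = {c: ref_counts.get(c, 0) if ref_counts.get(c, 0) > 0 else 0.5
                   for c in codons}
        mx = max(floored.values())
        for c in codons:
            cnt = counts.get(c, 0)
            if cnt:
                logs += cnt * math.log(floored[c] / mx)
                n += cnt
    return math.exp(logs / n)


def test_family_size_census():
    assert FAMILY_SIZES == {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}
    assert len(SENSE_CODONS) == 61
    assert len(CAI_CODONS) == 59


class TestCountCodons:
    def test_basic_with_stop_dropped(self):
        t, skipped = count_codons("ATGGCTGCTTAA")
        assert t.counts == {"ATG": 1, "GCT": 2}
        assert skipped == 0

    def test_n_codons_skipped(self):
        t, skipped = count_codons("ATGNNNGCT")
        assert t.counts == {"ATG": 1, "GCT": 1}
        assert skipped == 1

    def test_internal_stop_error(self):
        with pytest.raises(ValueError, match="codon index 1"):
            count_codons("ATGTAAGCT")

    def test_frame_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            count_codons("ATGC")


class TestNc:
    def test_maximal_bias_is_20(self):
        opt = preferred_codon_table()
        t = CodonUsageTable({c: 100.0 for c in opt.values()})
        assert effective_number_of_codons(t).nc == pytest.approx(20.0, abs=1e-12)

    def test_uniform_usage_finite_sample(self):
        # F2=(200*0.5-1)/199 etc.: Nc = 2 + 9*199/99 + 299/99 + 5*399/99
        #   + 3*599/99 = 61.41414...
        t = CodonUsageTable({c: 100.0 for c in SENSE_CODONS})
        expected = 2 + 9 / (99 / 199) + 1 / (99 / 299) + 5 / (99 / 399) + 3 / (99 / 599)
        assert effective_number_of_codons(t).nc == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(61.4141, abs=1e-4)

    def test_lambda_zero_simulation_range(self):
        opt = preferred_codon_table()
        rng = np.random.default_rng(0)
        values = []
        for _ in range(100):
            t = sample_codon_table(rng, 3000, 0.0, opt)
            values.append(effective_number_of_codons(t).nc)
        assert all(57 <= v <= 62.0 for v in values)

    def test_f3_imputation_flag(self):
        t = CodonUsageTable(
            {c: 10.0 for c in SENSE_CODONS if GENETIC_CODE[c] != "I"}
        )
        res = effective_number_of_codons(t)
        assert res.imputed_f3

    def test_undefined_when_no_families(self):
        with pytest.raises(ValueError):
            effective_number_of_codons(CodonUsageTable({"ATG": 5.0}))

    def test_matches_oracle_on_random_genes(self):
        rng = np.random.default_rng(7)
        opt = preferred_codon_table()
        for _ in range(50):
            lam = float(rng.uniform(0, 0.9))
            t = sample_codon_table(rng, int(rng.integers(200, 800)), lam, opt)
            assert effective_number_of_codons(t).nc == pytest.approx(
                oracle_nc(t.counts), abs=1e-9
            )

    def test_converges_with_count_scaling(self):
        t = {c: 2.0 for c in SENSE_CODONS}
        prev = effective_number_of_codons(CodonUsageTable(t)).nc
        for scale in (10, 100, 1000):
            cur = effective_number_of_codons(
                CodonUsageTable({c: 2.0 * scale for c in t})
            ).nc
            assert cur < prev  # monotone toward the infinite-count limit
            assert cur > 61.0  # finite-sample correction keeps it above 61
            prev = cur
        assert prev < 61.1


class TestRelativeAdaptiveness:
    def test_floor_rule(self):
        ref = CodonUsageTable({"GCT": 90.0, "GCC": 10.0})
        w = relative_adaptiveness(ref)
        assert w.w["GCT"] == 1.0
        assert w.w["GCC"] == pytest.approx(10 / 90)
        assert w.w["GCA"] == pytest.approx(0.5 / 90)
        assert w.w["GCG"] == pytest.approx(0.5 / 90)

    def test_uniform_reference_all_ones(self):
        w = relative_adaptiveness(CodonUsageTable({c: 7.0 for c in SENSE_CODONS}))
        assert all(v == 1.0 for v in w.w.values())

    def test_single_codon_families_always_one(self):
        w = relative_adaptiveness(CodonUsageTable({"GCT": 5.0}))
        assert w.w["ATG"] == 1.0 and w.w["TGG"] == 1.0


class TestCai:
    def test_all_optimal_is_one(self):
        opt = preferred_codon_table()
        ref = CodonUsageTable({c: 50.0 for c in opt.values()})
        w = relative_adaptiveness(ref)
        gene = CodonUsageTable({opt["A"]: 10.0, opt["G"]: 5.0})
        assert cai(gene, w) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        ref = CodonUsageTable({"GCT": 80.0, "GCC": 20.0, "GGT": 50.0})
        w = relative_adaptiveness(ref)
        gene = CodonUsageTable({"GCT": 1.0, "GCC": 1.0})
        assert cai(gene, w) == pytest.approx(math.sqrt(0.25))

    def test_met_only_gene_errors(self):
        w = relative_adaptiveness(CodonUsageTable({c: 1.0 for c in SENSE_CODONS}))
        with pytest.raises(ValueError):
            cai(CodonUsageTable({"ATG": 3.0}), w)

    def test_invariant_to_duplication(self):
        rng = np.random.default_rng(1)
        t = sample_codon_table(rng, 300, 0.3, preferred_codon_table())
        ref = codon_table_from_preferences(preferred_codon_table())
        w = relative_adaptiveness(ref)
        doubled = CodonUsageTable({c: 2 * v for c, v in t.counts.items()})
        assert cai(t, w) == pytest.approx(cai(doubled, w), rel=1e-12)

    def test_matches_oracle_on_random_genes(self):
        rng = np.random.default_rng(8)
        opt = preferred_codon_table()
        ref = sample_codon_table(rng, 5000, 0.7, opt)
        w = relative_adaptiveness(ref)
        for _ in range(50):
            t = sample_codon_table(rng, int(rng.integers(150, 600)), 0.2, opt)
            assert cai(t, w) == pytest.approx(
                oracle_cai(t.counts, ref.counts), abs=1e-9
            )


class TestNoBiasCai:
    def test_uniform_reference(self):
        w = relative_adaptiveness(CodonUsageTable({c: 3.0 for c in SENSE_CODONS}))
        assert no_bias_cai(w) == pytest.approx(1.0)

    def test_twofold_half(self):
        # every 2-fold family w = {1, 0.5}, others uniform
        counts = {}
        for aa, codons in FAMILIES.items():
            if len(codons) == 2:
                counts[codons[0]] = 100.0
                counts[codons[1]] = 50.0
            else:
                for c in codons:
                    counts[c] = 10.0
        w = relative_adaptiveness(CodonUsageTable(counts))
        assert no_bias_cai(w) == pytest.approx(math.exp(9 * math.log(0.5) / 59), abs=1e-12)

    def test_monotone_in_w(self):
        ref = CodonUsageTable({"GCT": 90.0, "GCC": 10.0})
        low = no_bias_cai(relative_adaptiveness(ref, zero_floor=0.5))
        high = no_bias_cai(relative_adaptiveness(ref, zero_floor=5.0))
        assert high >= low


class TestReferenceSet:
    def test_identical_genes_converges_immediately(self):
        t = {f"g{i}": CodonUsageTable({"GCT": 10.0, "GGT": 5.0}) for i in range(20)}
        sel, _, converged = select_reference_set(t)
        assert converged and len(sel) == 2

    def test_planted_high_bias_recovered(self):
        lams = [0.95] * 40 + [0.0] * 160
        tables = generate_codon_tables(17, 200, 300, lams)
        sel, _, _ = select_reference_set(tables)
        planted = {f"g{i:04d}" for i in range(40)}
        assert len(set(sel) & planted) / len(sel) >= 0.8

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            select_reference_set({"a": CodonUsageTable({"GCT": 1.0}),
                                  "b": CodonUsageTable({"GCC": 1.0})})


class TestLoessRegime:
    def test_negative_line_is_selection(self, rng):
        nc = rng.uniform(30, 61, 100)
        call = loess_regime(nc, 1 - nc / 100)
        assert call.verdict == "selection"
        assert np.all(call.slopes < 0)
        assert np.allclose(call.fitted_cai, 1 - nc / 100, atol=1e-9)

    def test_positive_line_is_mutational(self, rng):
        nc = rng.uniform(30, 61, 100)
        call = loess_regime(nc, nc / 100)
        assert call.verdict == "mutational_bias"

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError):
            loess_regime([50.0] * 30, list(np.linspace(0, 1, 30)))

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            loess_regime([1, 2, 3], [1, 2, 3])


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_cai_order_invariance(seed):
    # CAI depends only on the codon multiset, which the table encodes
    rng = np.random.default_rng(seed)
    t = sample_codon_table(rng, 200, 0.4, preferred_codon_table())
    ref = codon_table_from_preferences(preferred_codon_table())
    w = relative_adaptiveness(ref)
    reordered = CodonUsageTable(dict(reversed(list(t.counts.items()))))
    assert cai(t, w) == pytest.approx(cai(reordered, w), rel=1e-12)
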