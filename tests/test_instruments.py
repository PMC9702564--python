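import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from reprocausal.exceptions import DomainError
from reprocausal.instruments import (
    build_instruments,
    clump,
    compute_strength,
    filter_weak,
    find_proxy,
    prune_confounder,
    select_genome_wide,
)
from reprocausal.sumstats_io import LDTable

from conftest import make_table, make_variant


class TestSelectGenomeWide:
    def test_strict_threshold_arithmetic(self):
        tab = make_table(
            [
                make_variant("rs1", pvalue=1e-9),
                make_variant("rs2", pvalue=4e-8),
                make_variant("rs3", pvalue=6e-8),
            ]
        )
        sel = select_genome_wide(tab)
        assert [v.variant_id for v in sel] == ["rs1", "rs2"]

    def test_no_hits_gives_empty_selection(self):
        tab = make_table([make_variant(f"rs{i}", pvalue=0.5) for i in range(5)])
        assert select_genome_wide(tab) == []

    def test_selected_count_matches_direct_pvalue_count(self, rng):
        """With true z near 8 essentially every true instrument is selected
        and the selection equals a direct count at the threshold."""
        k, n_null = 50, 1000
        z = np.concatenate([rng.normal(8, 1, k), rng.normal(0, 1, n_null)])
        se = 0.01
        pvals = 2 * sps.norm.sf(np.abs(z))
        recs = [
            make_variant(f"rs{i:05d}", beta=float(z[i] * se), se=se,
                         pvalue=float(max(pvals[i], 1e-300)))
            for i in range(k + n_null)
        ]
        tab = make_table(recs)
        sel = select_genome_wide(tab)
        direct = {r.variant_id for r in recs if r.pvalue < 5e-8}
        assert {v.variant_id for v in sel} == direct
        assert abs(len(sel) - k) <= 4  # binomial tolerance around P(z>5.45)~0.995


def _brute_force_clump(candidates, ld, r2_threshold):
    """Independent re-implementation: scan candidates in (p, id) order and
    admit each one iff uncorrelated with everything already admitted."""
    admitted = []
    for cand in sorted(candidates, key=lambda r: (r.pvalue, r.variant_id)):
        if all(ld.r2(cand.variant_id, kept.variant_id) <= r2_threshold for kept in admitted):
            admitted.append(cand)
    return admitted


class TestClump:
    def test_greedy_rule_keeps_smallest_p_per_group(self):
        s1 = make_variant("s1", pvalue=1e-12)
        s2 = make_variant("s2", pvalue=1e-10)
        s3 = make_variant("s3", pvalue=1e-9)
        ld = LDTable.from_pairs([("s1", "s2", 0.5)])
        kept = clump([s1, s2, s3], ld)
        assert [v.variant_id for v in kept] == ["s1", "s3"]

    def test_unlinked_candidates_all_retained(self):
        cands = [make_variant(f"s{i}", pvalue=10 ** -(9 + i)) for i in range(5)]
        kept = clump(cands, LDTable())
        assert len(kept) == 5

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            n = 50
            cands = [
                make_variant(f"s{i:03d}", pvalue=float(rng.uniform(1e-12, 1e-8)))
                for i in range(n)
            ]
            pairs = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.08:
                        pairs.append((f"s{i:03d}", f"s{j:03d}", float(rng.uniform(0, 1))))
            ld = LDTable.from_pairs(pairs)
            got = {v.variant_id for v in clump(cands, ld)}
            want = {v.variant_id for v in _brute_force_clump(cands, ld, 0.01)}
            assert got == want
            # retained set is pairwise quasi-independent
            got_list = sorted(got)
            assert all(
                ld.r2(a, b) <= 0.01
                for i, a in enumerate(got_list)
                for b in got_list[i + 1:]
            )

    def test_result_is_input_order_independent(self, rng):
        cands = [
            make_variant(f"s{i}", pvalue=float(rng.uniform(1e-12, 1e-8)))
            for i in range(20)
        ]
        ld = LDTable.from_pairs([("s1", "s5", 0.9), ("s2", "s7", 0.3)])
        ref = [v.variant_id for v in clump(cands, ld)]
        shuffled = list(cands)
        rng.shuffle(shuffled)
        assert [v.variant_id for v in clump(shuffled, ld)] == ref

    def test_window_clump_discards_nearby_candidates(self):
        a = make_variant("a", pvalue=1e-12, chrom="1", pos=1_000_000)
        b = make_variant("b", pvalue=1e-10, chrom="1", pos=2_000_000)
        c = make_variant("c", pvalue=1e-9, chrom="2", pos=1_500_000)
        kept = clump([a, b, c], LDTable(), window_bp=10_000_000)
        assert [v.variant_id for v in kept] == ["a", "c"]


class TestComputeStrength:
    def test_worked_example(self):
        r2, f = compute_strength(make_variant(beta=0.1, se=0.02, eaf=0.3, n=10000))
        assert r2 == pytest.approx(0.01 / 4.01, rel=1e-12)
        assert f == pytest.approx(25.0, abs=0.01)

    def test_zero_beta_gives_zero(self):
        r2, f = compute_strength(make_variant(beta=0.0))
        assert (r2, f) == (0.0, 0.0)

    def test_eaf_symmetry(self):
        a = compute_strength(make_variant(eaf=0.3))
        b = compute_strength(make_variant(eaf=0.7))
        assert a == pytest.approx(b, rel=1e-14)

    def test_small_sample_is_domain_error(self):
        with pytest.raises(DomainError):
            compute_strength(make_variant(n=2))

    @settings(derandomize=True, max_examples=200)
    @given(
        beta=st.floats(-2, 2, allow_nan=False),
        se=st.floats(1e-4, 1.0),
        eaf=st.floats(0.01, 0.99),
        n=st.integers(10, 1_000_000),
    )
    def test_printed_form_equals_simplified_form(self, beta, se, eaf, n):
        r2, _ = compute_strength(make_variant(beta=beta, se=se, eaf=eaf, n=n))
        simplified = beta**2 / (beta**2 + se**2 * n)
        assert r2 == pytest.approx(simplified, abs=1e-12, rel=1e-12)

    def test_f_monotone_in_beta_n_and_se(self):
        base = compute_strength(make_variant(beta=0.1, se=0.02, n=10000))[1]
        assert compute_strength(make_variant(beta=0.2, se=0.02, n=10000))[1] > base
        assert compute_strength(make_variant(beta=0.1, se=0.02, n=20000))[1] > base
        assert compute_strength(make_variant(beta=0.1, se=0.04, n=10000))[1] < base


class TestFilterWeak:
    def _instruments(self, fs):
        # invert F ~ (beta/se)^2 approximately via beta choice
        recs = []
        for i, f in enumerate(fs):
            beta = 0.02 * np.sqrt(f)
            recs.append(make_variant(f"rs{i}", beta=float(beta), se=0.02, n=100000))
        return build_instruments(recs)

    def test_rejects_below_ten_and_recomputes_mean(self):
        inst = build_instruments(
            [
                make_variant("a", beta=0.1, se=0.02, n=10000),  # F ~ 25
                make_variant("b", beta=0.063, se=0.02, n=10000),  # F ~ 9.9
                make_variant("c", beta=0.127, se=0.02, n=10000),  # F ~ 40
            ]
        )
        out = filter_weak(inst, exposure_name="x")
        assert [r.variant_id for r in out.retained] == ["a", "c"]
        assert all(r.excluded_reason == "weak_instrument" for r in out.excluded)
        expected = np.mean([r.f_stat for r in out.retained])
        assert out.mean_f == pytest.approx(expected)
        assert len(out) == 3  # partition conserved

    def test_all_strong_is_identity(self):
        inst = self._instruments([20, 30, 40])
        out = filter_weak(inst)
        assert len(out.retained) == 3 and not out.excluded


class TestFindProxy:
    def _setup(self):
        out = make_table(
            [
                make_variant("p1", pvalue=1e-4),
                make_variant("p2", pvalue=1e-2),
                make_variant("p3", pvalue=1e-6),
            ],
            trait_type="outcome",
        )
        return out

    def test_highest_r2_wins(self):
        out = self._setup()
        ld = LDTable.from_pairs([("miss", "p1", 0.85), ("miss", "p3", 0.95)])
        got = find_proxy(make_variant("miss"), out, ld)
        assert got.variant_id == "p3"

    def test_below_threshold_gives_none(self):
        out = self._setup()
        ld = LDTable.from_pairs([("miss", "p1", 0.7)])
        assert find_proxy(make_variant("miss"), out, ld) is None

    def test_ties_broken_by_outcome_pvalue_then_id(self):
        out = self._setup()
        ld = LDTable.from_pairs([("miss", "p1", 0.9), ("miss", "p2", 0.9)])
        assert find_proxy(make_variant("miss"), out, ld).variant_id == "p1"


class TestPruneConfounder:
    def test_associated_excluded_absent_kept(self):
        inst = filter_weak(
            build_instruments(
                [make_variant(f"rs{i}", beta=0.1, se=0.02, n=10000) for i in range(10)]
            ),
            exposure_name="AFB",
        )
        bmi = make_table(
            [
                make_variant("rs0", pvalue=1e-9),
                make_variant("rs1", pvalue=1e-10),
                make_variant("rs2", pvalue=0.3),
            ],
            name="BMI",
            trait_type="confounder",
        )
        pruned = prune_confounder(inst, bmi)
        # two BMI-associated SNPs deleted: 10 -> 8 retained
        assert pruned.n_retained == 8
        reasons = {r.variant_id: r.excluded_reason for r in pruned.excluded}
        assert reasons == {
            "rs0": "confounder_associated",
            "rs1": "confounder_associated",
        }
        assert len(pruned) == len(inst)  # conservation
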