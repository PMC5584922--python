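import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guidescreen import ranking as rk
from guidescreen.candidates import GuideCandidate
from guidescreen.config import DesignConfig
from guidescreen.reference_io import VariantRecord
from guidescreen.scoring import OffTargetHit


def make_cand(start=100, spacer="ACT" * 6 + "AT", efficiency=0.5, specificity=90.0,
              conservation=0.5, commonality=1.0, variant_kinds=(), perfect=()):
    L = len(spacer)
    cand = GuideCandidate(
        gene_id="G", chrom="c", strand="+", start=start, end=start + L,
        spacer=spacer, pam="AGG", cut_site=start + L - 3,
        efficiency=efficiency, specificity=specificity,
        conservation=conservation, commonality=commonality,
    )
    cand.variant_hits = [
        VariantRecord("c", start + 3, "A", "G", 0.2 if k == "SNP" else None, k)
        for k in variant_kinds
    ]
    cand.perfect_hits = [
        OffTargetHit("c", 1000 + 30 * i, 1020 + 30 * i, "+", (), cat)
        for i, cat in enumerate(perfect)
    ]
    return cand


class TestFilterCandidates:
    def test_guanine_boundary_is_strict(self):
        """9/20 G (45%) is filtered, 8/20 G (40%) retained."""
        high = make_cand(spacer="G" * 9 + "A" * 11)
        edge = make_cand(start=200, spacer="G" * 8 + "A" * 12)
        report = rk.filter_candidates([high, edge])
        assert report.reasons[high.key] == [rk.HIGH_G]
        assert edge in report.passed

    def test_guanine_boundary_19mer(self):
        # 8/19 = 42.1% > 40%
        high = make_cand(spacer="G" * 8 + "A" * 11)
        report = rk.filter_candidates([high])
        assert report.reasons[high.key] == [rk.HIGH_G]

    def test_efficiency_boundary_is_strict(self):
        low = make_cand(efficiency=-0.01)
        edge = make_cand(start=200, efficiency=0.0)
        report = rk.filter_candidates([low, edge])
        assert report.reasons[low.key] == [rk.LOW_EFFICIENCY]
        assert edge in report.passed

    def test_unscorable_candidate_filtered(self):
        cand = make_cand(efficiency=None)
        report = rk.filter_candidates([cand])
        assert report.reasons[cand.key] == [rk.UNSCORABLE]

    def test_snp_overlap_filters(self):
        cand = make_cand(variant_kinds=("SNP",))
        report = rk.filter_candidates([cand])
        assert report.reasons[cand.key] == [rk.VARIANT_OVERLAP]

    def test_somatic_only_counts_when_requested(self):
        cand = make_cand(variant_kinds=("SOMATIC",))
        assert cand in rk.filter_candidates([cand], use_somatic=False).passed
        report = rk.filter_candidates([make_cand(variant_kinds=("SOMATIC",))], use_somatic=True)
        assert list(report.reasons.values()) == [[rk.VARIANT_OVERLAP]]

    def test_offtarget_only_goes_to_rescue_pool(self):
        cand = make_cand(perfect=("NON_EXON",))
        report = rk.filter_candidates([cand])
        assert report.rescue_pool["NON_EXON"] == [cand]
        assert report.filtered == []

    def test_worst_category_keys_the_pool(self):
        cand = make_cand(perfect=("NON_EXON", "CODING", "EXON_NONCODING"))
        report = rk.filter_candidates([cand])
        assert report.rescue_pool["CODING"] == [cand]

    def test_offtarget_plus_other_rule_not_rescuable(self):
        cand = make_cand(perfect=("NON_EXON",), efficiency=-1.0)
        report = rk.filter_candidates([cand])
        assert cand in report.filtered
        assert set(report.reasons[cand.key]) == {rk.LOW_EFFICIENCY, rk.PERFECT_OFFTARGET}

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()), max_size=12))
    def test_partition_property(self, flags):
        cands = [
            make_cand(
                start=100 + 40 * i,
                spacer=("G" * 9 + "A" * 11) if high_g else "ACT" * 6 + "AT",
                efficiency=-1.0 if low_eff else 0.5,
                perfect=("NON_EXON",) if offt else (),
            )
            for i, (high_g, low_eff, offt) in enumerate(flags)
        ]
        report = rk.filter_candidates(cands)
        assert report.n_input == len(cands)
        ids = (
            [id(c) for c in report.passed]
            + [id(c) for c in report.filtered]
            + [id(c) for v in report.rescue_pool.values() for c in v]
        )
        assert sorted(ids) == sorted(id(c) for c in cands)


def critic_oracle(raw, conflict="sum"):
    """Independent step-by-step CRITIC: pure-python normalise -> stdev ->
    Pearson -> information -> weights."""
    n, m = len(raw), len(raw[0])
    cols = [[row[j] for row in raw] for j in range(m)]
    norm = []
    for col in cols:
        lo, hi = min(col), max(col)
        norm.append([(x - lo) / (hi - lo) if hi > lo else 0.0 for x in col])
    if n < 3:
        return [1.0 / m] * m
    sig = [statistics.stdev(col) for col in norm]

    def pearson(a, b):
        ma, mb = statistics.fmean(a), statistics.fmean(b)
        num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        da = math.sqrt(sum((x - ma) ** 2 for x in a))
        db = math.sqrt(sum((y - mb) ** 2 for y in b))
        if da == 0 or db == 0:
            return 0.0
        return num / (da * db)

    C = []
    for j in range(m):
        terms = [1.0 - pearson(norm[j], norm[k]) for k in range(m) if k != j]
        agg = sum(terms) if conflict == "sum" else math.prod(terms)
        C.append(sig[j] * agg)
    total = sum(C)
    if total <= 0:
        return [1.0 / m] * m
    return [c / total for c in C]


class TestCriticWeights:
    def weights(self, raw, conflict="sum"):
        norm = rk._minmax(np.asarray(raw, dtype=float))
        return rk.critic_weights(norm, conflict)[3]

    def test_single_varying_column_takes_all_weight(self):
        raw = [[1, 5, 5, 5], [2, 5, 5, 5], [3, 5, 5, 5], [4, 5, 5, 5]]
        w = self.weights(raw)
        assert w == pytest.approx([1, 0, 0, 0])

    def test_duplicated_columns_share_reduced_weight(self):
        # perfectly correlated pair: r = 1 knocks out their mutual conflict
        raw = [[1, 1, 5, 5], [2, 2, 5, 5], [3, 3, 5, 5], [4, 4, 5, 5]]
        w = self.weights(raw)
        assert w[0] == pytest.approx(w[1])
        alone = self.weights([[r[0]] + r[2:] + [5] for r in raw])
        assert w[0] < alone[0] == 1.0

    @pytest.mark.parametrize("conflict", ["sum", "product"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle(self, seed, conflict):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(-5, 20, size=(5, 4))
        w = self.weights(raw, conflict)
        expected = critic_oracle(raw.tolist(), conflict)
        assert w == pytest.approx(expected, abs=1e-9)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()

    def test_fewer_than_three_rows_uniform(self):
        assert self.weights([[1, 2, 3, 4], [4, 3, 2, 1]]) == pytest.approx([0.25] * 4)

    def test_all_constant_uniform(self):
        raw = [[5, 5, 5, 5]] * 4
        assert self.weights(raw) == pytest.approx([0.25] * 4)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 1, size=(6, 4))
        scaled = raw.copy()
        scaled[:, 2] = 1000.0 * raw[:, 2] - 77.0
        assert self.weights(raw) == pytest.approx(self.weights(scaled), abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rk.CriteriaMatrix.from_candidates("G", [])


class TestSummaryScores:
    def matrix(self, cands):
        return rk.CriteriaMatrix.from_candidates("G", cands)

    def test_dominating_candidate_ranks_first(self):
        cands = [
            make_cand(start=100, efficiency=0.9, specificity=99, conservation=0.9, commonality=1.0),
            make_cand(start=200, efficiency=0.5, specificity=80, conservation=0.5, commonality=0.5),
            make_cand(start=300, efficiency=0.1, specificity=60, conservation=0.2, commonality=0.25),
        ]
        m = self.matrix(cands)
        scores = {c.key: s for c, s in zip(m.candidates, m.summary_scores())}
        ranked = rk._ranked(cands, scores)
        assert ranked[0].start == 100 and ranked[-1].start == 300

    def test_degenerate_weights_reduce_to_single_criterion(self):
        rng = np.random.default_rng(2)
        cands = [
            make_cand(start=100 + 40 * i, efficiency=float(e), specificity=50.0,
                      conservation=0.5, commonality=0.5)
            for i, e in enumerate(rng.uniform(0, 1, size=6))
        ]
        m = self.matrix(cands)
        assert m.weights == pytest.approx([1, 0, 0, 0])
        scores = m.summary_scores()
        order = [m.candidates[i].efficiency for i in np.argsort(-scores)]
        assert order == sorted(order, reverse=True)

    def test_hand_computed_dot_products(self):
        cands = [
            make_cand(start=100, efficiency=0.0, specificity=0.0, conservation=0.0, commonality=0.0),
            make_cand(start=200, efficiency=1.0, specificity=0.5, conservation=0.2, commonality=1.0),
            make_cand(start=300, efficiency=0.5, specificity=1.0, conservation=1.0, commonality=0.4),
        ]
        m = self.matrix(cands)
        norm = m.normalized
        for i in range(3):
            assert m.summary_scores()[i] == pytest.approx(float(norm[i] @ m.weights))

    def test_raising_a_criterion_never_lowers_rank(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 1, size=(5, 4))
        m0 = rk._minmax(raw)
        w = rk.critic_weights(m0)[3]
        s0 = m0 @ w
        bumped = m0.copy()
        bumped[2, 1] = min(1.0, bumped[2, 1] + 0.3)
        s1 = bumped @ w
        rank0 = (s0 > s0[2]).sum()
        rank1 = (s1 > s1[2]).sum()
        assert rank1 <= rank0


class TestRescue:
    def report_with(self, pool):
        return rk.FilterReport(passed=[], filtered=[], reasons={}, rescue_pool=pool)

    def test_category_precedence(self):
        a = make_cand(start=100, perfect=("NON_EXON",))
        b = make_cand(start=200, perfect=("CODING",))
        report = rk.filter_candidates([a, b])
        out = rk.rescue(report, {a.key: 0.5, b.key: 0.9}, needed=1)
        assert out == [a]
        assert a.status == "RESCUED_NON_EXON"

    def test_fewer_hits_first(self):
        a = make_cand(start=100, perfect=("NON_EXON", "NON_EXON"))
        b = make_cand(start=200, perfect=("NON_EXON",))
        report = rk.filter_candidates([a, b])
        out = rk.rescue(report, {a.key: 0.9, b.key: 0.1}, needed=1)
        assert out == [b]

    def test_summary_score_breaks_ties(self):
        a = make_cand(start=100, perfect=("NON_EXON",))
        b = make_cand(start=200, perfect=("NON_EXON",))
        report = rk.filter_candidates([a, b])
        out = rk.rescue(report, {a.key: 0.1, b.key: 0.9}, needed=1)
        assert out == [b]

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["NON_EXON", "EXON_NONCODING", "CODING"]),
                st.integers(1, 3),
                st.floats(0, 1),
            ),
            min_size=1,
            max_size=10,
        ),
        st.integers(1, 10),
    )
    def test_rescue_order_property(self, pool_spec, needed):
        """Ordering always satisfies category > hit count > summary score;
        no CODING rescue while a NON_EXON candidate remains unrescued."""
        cands, scores = [], {}
        for i, (cat, nhits, score) in enumerate(pool_spec):
            c = make_cand(start=100 + 40 * i, perfect=(cat,) * nhits)
            cands.append(c)
            scores[c.key] = score
        report = rk.filter_candidates(cands)
        out = rk.rescue(report, scores, needed)
        assert len(out) == min(needed, len(cands))
        keys = [
            (rk.RESCUE_ORDER.index(c.status.removeprefix("RESCUED_")),
             len(c.perfect_hits), -scores[c.key])
            for c in out
        ]
        assert keys == sorted(keys)
        # anything left unrescued is no better than everything rescued
        left = [c for c in cands if not c.status.startswith("RESCUED")]
        if out and left:
            worst_out = max(keys)
            best_left = min(
                (rk.RESCUE_ORDER.index(next(cat for cat in rk.RESCUE_ORDER if c in report.rescue_pool[cat])),
                 len(c.perfect_hits), -scores[c.key])
                for c in left
            )
            assert worst_out <= best_left


class TestSelectGuides:
    def test_clean_candidates_descending_summary(self):
        rng = np.random.default_rng(5)
        cands = [
            make_cand(start=100 + 40 * i, efficiency=float(rng.uniform(0, 1)),
                      specificity=float(rng.uniform(50, 100)),
                      conservation=float(rng.uniform(0, 1)),
                      commonality=float(rng.choice([0.5, 1.0])))
            for i in range(10)
        ]
        sel = rk.select_guides("G", cands, 5)
        assert len(sel.guides) == 5
        assert all(c.status == "PASSED" for c in sel.guides)
        scores = [sel.summary[c.key] for c in sel.guides]
        assert scores == sorted(scores, reverse=True)
        assert sel.weights.sum() == pytest.approx(1.0)

    def test_rescue_fills_shortfall_in_category_order(self):
        clean = [make_cand(start=100 + 40 * i) for i in range(2)]
        pool = [
            make_cand(start=300, perfect=("CODING",)),
            make_cand(start=340, perfect=("NON_EXON",)),
            make_cand(start=380, perfect=("EXON_NONCODING",)),
            make_cand(start=420, perfect=("NON_EXON", "NON_EXON")),
        ]
        sel = rk.select_guides("G", clean + pool, 5)
        assert len(sel.guides) == 5
        statuses = [c.status for c in sel.guides]
        assert statuses[:2] == ["PASSED", "PASSED"]
        assert statuses[2:] == [
            "RESCUED_NON_EXON", "RESCUED_NON_EXON", "RESCUED_EXON_NONCODING"
        ]
        # fewer hits first within NON_EXON
        assert sel.guides[2].start == 340

    def test_zero_candidates_warns(self, caplog):
        sel = rk.select_guides("G", [], 5)
        assert sel.guides == []
        assert any("only 0 designable" in r.message for r in caplog.records)

    def test_n_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            rk.select_guides("G", [make_cand()], 31)
        with pytest.raises(ValueError):
            rk.select_guides("G", [make_cand()], 0)
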