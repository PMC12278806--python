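"""Fast combination scorer: tables, top-k exactness, filters, focused library."""

import numpy as np
import pytest

from rxnsvr import chem, models, screening
from rxnsvr.chem import canonicalize
from rxnsvr.errors import ContractError
from rxnsvr.kernels import KernelSpec, tanimoto
from rxnsvr.screening import (
    ad_filter,
    build_tables,
    eligibility_filter,
    focused_library,
    score_all,
    score_one_instrumented,
)
from rxnsvr.templates import find_candidates, forward_products

from conftest import random_fingerprint, random_pair
from test_models import manual_model


def random_model(rng, n_sv=5, n_bits=256):
    svs = [random_pair(rng, n_bits) for _ in range(n_sv)]
    return manual_model(svs, rng.normal(size=n_sv), float(rng.normal()))


def brute_force_scores(model, fps1, fps2):
    n1, n2 = len(fps1), len(fps2)
    out = np.empty((n1, n2))
    for i in range(n1):
        for j in range(n2):
            out[i, j] = models.predict(model, [(fps1[i], fps2[j])])[0]
    return out


def brute_force_topk(scores, k):
    n1, n2 = scores.shape
    entries = [
        (-scores[i, j], i, j) for i in range(n1) for j in range(n2)
    ]
    entries.sort()
    return [(i, j, -neg) for neg, i, j in entries[:k]]


class TestBuildTables:
    def test_matches_double_loop(self, rng):
        model = random_model(rng, n_sv=5)
        fps1 = [random_fingerprint(rng) for _ in range(20)]
        fps2 = [random_fingerprint(rng) for _ in range(15)]
        t1, t2 = build_tables(model, fps1, fps2)
        for i in range(5):
            for c in range(20):
                assert t1.values[i, c] == pytest.approx(
                    tanimoto(model.sv_fp1[i], fps1[c]), abs=1e-12
                )
            for c in range(15):
                assert t2.values[i, c] == pytest.approx(
                    tanimoto(model.sv_fp2[i], fps2[c]), abs=1e-12
                )

    def test_candidate_equal_to_sv_gives_unit_entry(self, rng):
        model = random_model(rng, n_sv=3)
        fps1 = [model.sv_fp1[1], random_fingerprint(rng)]
        fps2 = [random_fingerprint(rng)]
        t1, _ = build_tables(model, fps1, fps2)
        assert t1.values[1, 0] == 1.0

    def test_non_product_kernel_rejected(self, rng):
        sum_model = manual_model([random_pair(rng)], [1.0], 0.0, kind="sum")
        with pytest.raises(ContractError):
            build_tables(sum_model, [random_fingerprint(rng)], [random_fingerprint(rng)])


class TestScoreAll:
    def test_all_ones_tables_tie_break(self, rng):
        fp = random_fingerprint(rng)
        model = manual_model([(fp, fp)], [1.0], 0.0)
        tables = build_tables(model, [fp, fp], [fp, fp])
        top = score_all(model, tables, top_k=1)
        assert (top[0].idx1, top[0].idx2) == (0, 0)
        assert top[0].y_hat == pytest.approx(1.0)

    def test_matches_predict_on_sampled_combinations(self, rng):
        model = random_model(rng, n_sv=6)
        fps1 = [random_fingerprint(rng) for _ in range(12)]
        fps2 = [random_fingerprint(rng) for _ in range(9)]
        tables = build_tables(model, fps1, fps2)
        ranked = score_all(model, tables, top_k=12 * 9)
        for combo in ranked[::7]:
            direct = models.predict(
                model, [(fps1[combo.idx1], fps2[combo.idx2])]
            )[0]
            assert combo.y_hat == pytest.approx(direct, abs=1e-9)

    def test_topk_equals_brute_force_sort(self, rng):
        model = random_model(rng, n_sv=7)
        fps1 = [random_fingerprint(rng) for _ in range(30)]
        fps2 = [random_fingerprint(rng) for _ in range(25)]
        tables = build_tables(model, fps1, fps2)
        got = score_all(model, tables, top_k=40, chunk=8)
        ref = brute_force_topk(brute_force_scores(model, fps1, fps2), 40)
        assert [(c.idx1, c.idx2) for c in got] == [(i, j) for i, j, _ in ref]
        for c, (_, _, y) in zip(got, ref):
            assert c.y_hat == pytest.approx(y, abs=1e-9)

    @pytest.mark.parametrize("chunk", [1, 3, 7, 64, 1000])
    def test_chunk_independence(self, rng, chunk):
        model = random_model(rng, n_sv=4)
        fps1 = [random_fingerprint(rng) for _ in range(17)]
        fps2 = [random_fingerprint(rng) for _ in range(13)]
        tables = build_tables(model, fps1, fps2)
        ref = score_all(model, tables, top_k=25, chunk=17)
        got = score_all(model, tables, top_k=25, chunk=chunk)
        assert got == ref

    def test_topk_larger_than_grid_returns_all(self, rng):
        model = random_model(rng, n_sv=3)
        fps1 = [random_fingerprint(rng) for _ in range(4)]
        fps2 = [random_fingerprint(rng) for _ in range(3)]
        tables = build_tables(model, fps1, fps2)
        assert len(score_all(model, tables, top_k=10_000)) == 12

    def test_exact_ties_resolved_by_index_order(self, rng):
        fp = random_fingerprint(rng)
        model = manual_model([(fp, fp)], [1.0], 0.0)
        tables = build_tables(model, [fp] * 3, [fp] * 2)
        got = [(c.idx1, c.idx2) for c in score_all(model, tables, top_k=6, chunk=2)]
        assert got == [(0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)]


class TestInstrumentedScorer:
    def test_operation_count_formula(self, rng):
        """2*nSV multiplications + (nSV-1) + 1 additions per combination."""
        for n_sv in (1, 7, 100):
            model = random_model(rng, n_sv=n_sv)
            fps1 = [random_fingerprint(rng) for _ in range(2)]
            fps2 = [random_fingerprint(rng) for _ in range(2)]
            tables = build_tables(model, fps1, fps2)
            y, counts = score_one_instrumented(model, tables, 1, 0)
            assert counts["mult"] == 2 * n_sv
            assert counts["add"] == (n_sv - 1) + 1
            assert counts["total"] == 2 * n_sv + (n_sv - 1) + 1
            direct = models.predict(model, [(fps1[1], fps2[0])])[0]
            assert y == pytest.approx(direct, abs=1e-9)


class TestAdFilter:
    def test_zero_threshold_keeps_all(self, rng):
        model = random_model(rng)
        cands = [random_fingerprint(rng) for _ in range(10)]
        assert ad_filter(model, cands, 1, 0.0) == list(range(10))

    def test_sv_identical_candidate_survives_high_threshold(self, rng):
        model = random_model(rng)
        cands = [model.sv_fp2[0], random_fingerprint(rng)]
        assert 0 in ad_filter(model, cands, 2, 0.99)

    def test_matches_brute_force_max_similarity(self, rng):
        model = random_model(rng, n_sv=6)
        cands = [random_fingerprint(rng) for _ in range(40)]
        kept = set(ad_filter(model, cands, 1, 0.2))
        for i, c in enumerate(cands):
            max_sim = max(tanimoto(sv, c) for sv in model.sv_fp1)
            assert (i in kept) == (max_sim >= 0.2)

    def test_monotone_in_threshold(self, rng):
        model = random_model(rng)
        cands = [random_fingerprint(rng) for _ in range(30)]
        previous = set(ad_filter(model, cands, 1, 0.0))
        for t in (0.1, 0.2, 0.4, 0.8, 1.0):
            current = set(ad_filter(model, cands, 1, t))
            assert current <= previous
            previous = current


class TestEligibilityFilter:
    def test_rules(self):
        mols = [
            canonicalize("C1CCCCCCC1"),   # 8-ring: out
            canonicalize("c1ccccc1"),      # in
            canonicalize("C[Si](C)(C)C"),  # silicon: out
            canonicalize("CCNC(C)C"),      # in
        ]
        kept = eligibility_filter(mols)
        assert kept == [mols[1], mols[3]]


class TestFocusedLibrary:
    def test_tiny_pool_matches_brute_force_pipeline(
        self, small_library, pk_model, baseline_model
    ):
        template = small_library["template"]
        cands1 = find_candidates(small_library["pool1"], template.component_queries[0])[:6]
        cands2 = find_candidates(small_library["pool2"], template.component_queries[1])[:6]
        entries = focused_library(
            pk_model, baseline_model, cands1, cands2, template,
            stage1_k=36, stage2_k=36,
        )
        assert len(entries) == 36
        # oracle: assemble every pair, predict with both models directly
        for e in entries[:10]:
            prods = forward_products(
                template, cands1[e.idx1].mol(), cands2[e.idx2].mol()
            )
            assert prods[0].smiles == e.product.smiles
            pk_direct = models.predict(
                pk_model,
                [(chem.ecfp4(cands1[e.idx1]), chem.ecfp4(cands2[e.idx2]))],
            )[0]
            base_direct = models.predict_products(
                baseline_model, [chem.ecfp4(prods[0])]
            )[0]
            assert e.y_hat_pk == pytest.approx(pk_direct, abs=1e-9)
            assert e.y_hat_baseline == pytest.approx(base_direct, abs=1e-9)
        # ranking is by baseline prediction, descending
        base_vals = [e.y_hat_baseline for e in entries]
        assert base_vals == sorted(base_vals, reverse=True)

    def test_survivors_pass_roundtrip(self, small_library, pk_model, baseline_model):
        template = small_library["template"]
        cands1 = find_candidates(small_library["pool1"], template.component_queries[0])[:5]
        cands2 = find_candidates(small_library["pool2"], template.component_queries[1])[:5]
        entries = focused_library(
            pk_model, baseline_model, cands1, cands2, template,
            stage1_k=25, stage2_k=10,
        )
        assert any(e.passed_filters for e in entries)
        for e in entries:
            if e.passed_filters:
                from rxnsvr.templates import dissect_product

                keys = {
                    (p.unmarked()[0].smiles, p.unmarked()[1].smiles)
                    for p in dissect_product(e.product, template)
                }
                assert (cands1[e.idx1].smiles, cands2[e.idx2].smiles) in keys
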