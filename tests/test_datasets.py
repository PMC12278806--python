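"""Curation rules, overlap pruning and the two splitting strategies."""

import numpy as np
import pytest

from rxnsvr import datasets
from rxnsvr.chem import canonicalize
from rxnsvr.datasets import (
    alternating_order,
    curate,
    dataset_overlap_prune,
    passes_eligibility,
    product_split,
    reactant_split,
)
from rxnsvr.errors import ConfigurationError
from rxnsvr.synthetic import AMINE_ALKYLATION
from rxnsvr.templates import ReactionRecord, dissect_product


def make_record(product_smiles, rid, y=6.0):
    product = canonicalize(product_smiles)
    pair = dissect_product(product, AMINE_ALKYLATION)[0]
    return ReactionRecord(record_id=rid, product=product, pair=pair, y=y)


class TestEligibility:
    @pytest.mark.parametrize(
        "smiles,ok",
        [
            ("c1ccccc1", True),
            ("C1CCCCCCC1", False),       # 8-membered ring
            ("C1CCCCCC1", True),          # 7-membered ring
            ("C[Si](C)(C)C", False),      # disallowed element
            ("OB(O)c1ccccc1", False),     # boron
            ("ClCCBr", True),
        ],
    )
    def test_structure_rules(self, smiles, ok):
        assert passes_eligibility(canonicalize(smiles)) is ok

    def test_molecular_weight_boundary(self):
        # C57H116: MW 801.5 > 800; C56H114: 787.5 <= 800
        assert not passes_eligibility(canonicalize("C" * 57))
        assert passes_eligibility(canonicalize("C" * 56))


class TestCurate:
    def test_disallowed_element_in_reactant_removes_reaction(self):
        ok = [make_record("CCNC(C)C" + "C" * i, f"r{i}") for i in range(3)]
        bad = make_record("CCNC(C)CC[Si](C)(C)C", "bad")
        out = curate(ok + [bad], min_size=1)
        assert bad not in out and len(out) == 3

    def test_iqr_fence_removes_heavy_atom_outlier(self):
        recs = [
            make_record("CCNC(C)C" + "C" * (i % 3), f"r{i}") for i in range(12)
        ]
        outlier = make_record("CCNC(C)" + "C" * 40, "outlier")
        everything = recs + [outlier]
        # brute-force oracle for the fence on component 2 heavy atoms
        counts = np.array([r.pair.r2.mol().GetNumHeavyAtoms() for r in everything])
        q1, q3 = np.percentile(counts, [25, 75])
        assert counts[-1] > q3 + 1.5 * (q3 - q1)
        out = curate(everything, min_size=1)
        assert outlier not in out
        assert len(out) == 12

    def test_min_size_rule(self):
        recs = [make_record("CCNC(C)C" + "C" * (i % 3), f"r{i}") for i in range(12)]
        assert curate(recs, min_size=13) == []
        assert len(curate(recs, min_size=12)) == 12

    def test_idempotent(self, small_library):
        once = curate(small_library["records"], min_size=10)
        assert curate(once, min_size=10) == once


class TestOverlapPrune:
    def _ds(self, smileses, tag):
        return [make_record(s, f"{tag}{i}") for i, s in enumerate(smileses)]

    def test_disjoint_unchanged(self):
        a = self._ds(["CCNC(C)C", "CCCNC(C)C"], "a")
        b = self._ds(["CCCCNC(C)C", "CCCCCNC(C)C"], "b")
        assert dataset_overlap_prune([a, b]) == [a, b]

    def test_subset_dropped(self):
        a = self._ds(["CCNC(C)C", "CCCNC(C)C", "CCCCNC(C)C"], "a")
        b = self._ds(["CCNC(C)C", "CCCNC(C)C"], "b")
        assert dataset_overlap_prune([a, b]) == [a]

    def test_exactly_sixty_percent_dropped(self):
        shared = [f"CCNC(C){'C' * i}" for i in range(6)]
        only_a = [f"CCCCNC(C){'C' * i}" for i in range(14)]
        only_b = [f"c1ccccc1CNC(C){'C' * i}" for i in range(4)]
        a = self._ds(shared + only_a, "a")   # 20 products
        b = self._ds(shared + only_b, "b")   # 10 products, overlap 6/10 = 0.6
        assert dataset_overlap_prune([a, b]) == [a]


class TestProductSplit:
    def test_partition_and_ratio(self, small_library):
        records = small_library["records"]
        res = product_split(records, seed=3)
        assert len(res.train) + len(res.test) + len(res.discarded) == len(records)
        products = {r.product.smiles for r in records}
        train_products = {r.product.smiles for r in res.train}
        other = {r.product.smiles for r in res.test + res.discarded}
        assert not (train_products & other)
        assert len(train_products) == round(0.6 * len(products))

    def test_identical_test_product_discarded(self):
        base = [make_record(f"CCNC(C){'C' * i}", f"r{i}") for i in range(10)]
        res = product_split(base, sim_cutoff=1.0, seed=0)
        # with cutoff 1.0 nothing can be discarded (no duplicates across sets)
        assert not res.discarded
        res2 = product_split(base, sim_cutoff=0.0, seed=0)
        # cutoff 0 discards every test product
        assert not res2.test

    def test_dissimilar_products_keep_test_set(self, small_library):
        res = product_split(small_library["records"], sim_cutoff=0.999, seed=1)
        assert res.test  # near-duplicates only would be discarded

    def test_deterministic(self, small_library):
        a = product_split(small_library["records"], seed=5)
        b = product_split(small_library["records"], seed=5)
        assert [r.record_id for r in a.train] == [r.record_id for r in b.train]


class TestAlternatingOrder:
    def test_five_items(self):
        assert alternating_order(["f5", "f4", "f3", "f2", "f1"]) == [
            "f5", "f1", "f4", "f2", "f3",
        ]

    def test_even_count(self):
        assert alternating_order(["a", "b", "c", "d"]) == ["a", "d", "b", "c"]


class TestReactantSplit:
    def test_partition_and_disjoint_reactants(self, small_library):
        records = small_library["records"]
        res = reactant_split(records)
        assert len(res.train) + len(res.test) + len(res.discarded) == len(records)
        for comp in ("r1", "r2"):
            train_set = {getattr(r.pair, comp).smiles for r in res.train}
            test_set = {getattr(r.pair, comp).smiles for r in res.test}
            assert not (train_set & test_set)

    def test_cut_matches_exhaustive_area_search(self, small_library):
        """Oracle: enumerate all cuts and minimize |ratio - 0.6| directly."""
        records = small_library["records"]
        res = reactant_split(records)
        n1 = len({r.pair.r1.smiles for r in records})
        n2 = len({r.pair.r2.smiles for r in records})
        best = min(
            (
                abs(a * b / (a * b + (n1 - a) * (n2 - b)) - 0.6)
                for a in range(1, n1)
                for b in range(1, n2)
            )
        )
        a_rows = len({r.pair.r1.smiles for r in res.train})
        b_cols = len({r.pair.r2.smiles for r in res.train})
        got = abs(
            a_rows * b_cols
            / (a_rows * b_cols + (n1 - a_rows) * (n2 - b_cols))
            - 0.6
        )
        assert got == pytest.approx(best, abs=1e-12)

    def test_fully_observed_grid_exact_ratio(self):
        # 10x10 grid: the closest achievable area ratio to 6:4 is exact (30:20)
        recs = []
        for i in range(10):
            for j in range(10):
                recs.append(
                    make_record(f"C{'C' * i}CNC(C)C{'C' * j}", f"g{i}_{j}")
                )
        res = reactant_split(recs)
        n_train_rows = len({r.pair.r1.smiles for r in res.train})
        n_train_cols = len({r.pair.r2.smiles for r in res.train})
        area_train = n_train_rows * n_train_cols
        area_test = (10 - n_train_rows) * (10 - n_train_cols)
        assert area_train / (area_train + area_test) == pytest.approx(0.6)

    def test_single_reactant_component_rejected(self):
        recs = [make_record("CCNC(C)C", "a"), make_record("CCNC(C)C", "b")]
        with pytest.raises(ConfigurationError):
            reactant_split(recs)

    def test_observed_count_mode_runs_and_partitions(self, small_library):
        res = reactant_split(small_library["records"], count_mode="observed")
        assert res.strategy == "reactant_based"
        total = len(res.train) + len(res.test) + len(res.discarded)
        assert total == len(small_library["records"])
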