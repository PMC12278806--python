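"""End-to-end benchmark workflows on synthetic libraries.

These wire the full pipeline together — generate a library, split, augment,
train, evaluate or screen — and are shared by the example scripts and the
acceptance harness so that every headline comparison is produced by exactly
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import chem, datasets, models, screening, synthetic, thompson
from .evaluation import MetricReport, metrics
from .kernels import KernelSpec
from .models import SVRConfig
from .synthetic import FixtureSpec
from .templates import ReactionRecord, RetroTemplate, augment_records


def evaluate_on_split(
    train_records: Sequence[ReactionRecord],
    test_records: Sequence[ReactionRecord],
    spec: KernelSpec,
    config: SVRConfig,
) -> MetricReport:
    """Train one model and evaluate it per product on the test records.

    Predictions for multiple reactant pairs forming the same product are
    averaged, so pair-kernel and product-baseline models are scored on
    identical product sets.
    """
    model = models.train(train_records, spec, config)
    by_product: dict[str, list[ReactionRecord]] = {}
    for rec in test_records:
        by_product.setdefault(rec.product.smiles, []).append(rec)
    product_ids = sorted(by_product)
    y_true = [by_product[p][0].y for p in product_ids]
    if spec.is_pair:
        groups = {
            p: [
                (
                    chem.ecfp4(r.pair.r1, spec.n_bits),
                    chem.ecfp4(r.pair.r2, spec.n_bits),
                )
                for r in by_product[p]
            ]
            for p in product_ids
        }
        preds_map = models.predict_product_averaged(model, groups)
        y_pred = [preds_map[p] for p in product_ids]
    else:
        fps = [chem.ecfp4(by_product[p][0].product, spec.n_bits) for p in product_ids]
        y_pred = list(models.predict_products(model, fps))
    return metrics(y_true, y_pred)


def kernel_parity_benchmark(
    base: FixtureSpec = FixtureSpec(),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    config: SVRConfig = SVRConfig(),
) -> dict[str, dict[int, float]]:
    """Product-kernel vs product-baseline R² over product-based splits.

    For each seed: generate a library, split 6:4 by product, augment the
    training records of the pair-kernel model with alternative dissections,
    train both models and evaluate per product on the shared test set.
    Returns per-seed test R² for keys ``"pk"`` and ``"baseline"``.
    """
    out: dict[str, dict[int, float]] = {"pk": {}, "baseline": {}}
    for seed in seeds:
        records, _, _, template, _ = synthetic.generate_library(replace(base, seed=seed))
        split = datasets.product_split(records, seed=seed)
        cfg = replace(config, cv_seed=seed)
        augmented = augment_records(split.train, template)
        out["pk"][seed] = evaluate_on_split(
            augmented, split.test, KernelSpec("product"), cfg
        ).r2
        out["baseline"][seed] = evaluate_on_split(
            split.train, split.test, KernelSpec("single_tanimoto"), cfg
        ).r2
    return out


def augmentation_benchmark(
    base: FixtureSpec = FixtureSpec(
        ambiguous_fraction=0.5, randomize_observed_dissection=True
    ),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    config: SVRConfig = SVRConfig(),
) -> dict[str, dict[int, float]]:
    """Augmentation on/off for the product kernel under reactant-based splits.

    The fixture randomizes which dissection of an ambiguous product is
    recorded, so without augmentation the training grid misrepresents the
    reactants actually shared with the test block — the failure mode the
    augmentation step corrects. Returns per-seed test R² for keys
    ``"augmented"`` and ``"plain"``.
    """
    out: dict[str, dict[int, float]] = {"augmented": {}, "plain": {}}
    for seed in seeds:
        records, _, _, template, _ = synthetic.generate_library(replace(base, seed=seed))
        split = datasets.reactant_split(records)
        cfg = replace(config, cv_seed=seed)
        out["plain"][seed] = evaluate_on_split(
            split.train, split.test, KernelSpec("product"), cfg
        ).r2
        out["augmented"][seed] = evaluate_on_split(
            augment_records(split.train, template),
            split.test,
            KernelSpec("product"),
            cfg,
        ).r2
    return out


@dataclass
class ScreeningComparison:
    """Exhaustive ranking vs Thompson sampling on one planted landscape."""

    exhaustive_max: float
    thompson_max: float
    gap: float
    best_is_planted: bool
    thompson_found_planted: bool
    thompson_unique_r1: int
    thompson_unique_r2: int
    n_combinations: int


def screening_vs_thompson(
    seed: int = 0,
    base: FixtureSpec = FixtureSpec(),
    n_pool: int = 300,
    budget: int = 10_000,
    n_warm: int = 3,
    config: SVRConfig = SVRConfig(),
) -> ScreeningComparison:
    """Planted-optimum screening duel on an ``n_pool`` x ``n_pool`` grid.

    A product-kernel model is trained on the synthetic library; candidate
    pools of ``n_pool`` building blocks per component (supersets of the
    library reactants) get one planted dominant candidate each. Exhaustive
    table-based ranking scores every combination; Thompson sampling gets a
    budget of ``budget`` scored pairs on the same score landscape. The gap
    between the exhaustive maximum and Thompson's best found score is >= 0
    by construction; how often it is strictly positive is the sampling
    method's miss rate.
    """
    spec = replace(base, seed=seed)
    records, pool1, pool2, template, truth = synthetic.generate_library(spec)
    model = models.train(
        augment_records(records, template),
        KernelSpec("product"),
        replace(config, cv_seed=seed),
    )

    cands1 = synthetic.enumerate_candidates(spec.template_kind, 1, n_pool - 1)
    cands2 = synthetic.enumerate_candidates(spec.template_kind, 2, n_pool - 1)
    cands1, cands2, planted = synthetic.plant_known_optimum(
        cands1, cands2, truth, template
    )

    fps1 = [chem.ecfp4(m) for m in cands1]
    fps2 = [chem.ecfp4(m) for m in cands2]
    tables = screening.build_tables(
        model,
        fps1,
        fps2,
        [m.smiles for m in cands1],
        [m.smiles for m in cands2],
    )
    top = screening.score_all(model, tables, top_k=1)
    exhaustive_max = top[0].y_hat

    t1, t2 = tables[0].values, tables[1].values
    coefs = model.dual_coefs

    def score_fn(i: int, j: int) -> float:
        return float(coefs @ (t1[:, i] * t2[:, j]) + model.intercept)

    ts = thompson.run(
        score_fn,
        [m.smiles for m in cands1],
        [m.smiles for m in cands2],
        n_total=budget,
        n_warm=n_warm,
        seed=seed,
    )
    ts_best = ts.best()
    best_pair = (cands1[top[0].idx1].smiles, cands2[top[0].idx2].smiles)
    ts_pair = (cands1[ts_best.idx1].smiles, cands2[ts_best.idx2].smiles)
    return ScreeningComparison(
        exhaustive_max=exhaustive_max,
        thompson_max=ts_best.y_hat,
        gap=exhaustive_max - ts_best.y_hat,
        best_is_planted=best_pair == planted,
        thompson_found_planted=ts_pair == planted,
        thompson_unique_r1=ts.unique_reactants1,
        thompson_unique_r2=ts.unique_reactants2,
        n_combinations=len(cands1) * len(cands2),
    )
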