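"""Dissect products with a retro template and augment the training data.

A secondary amine formed from an aldehyde and a linear primary amine has two
chemically valid cut points; the augmentation step adds the alternative
reactant pair so the model also learns from precursors that could equally
have produced the compound.
"""

from rxnsvr import canonicalize
from rxnsvr.synthetic import AMINE_ALKYLATION
from rxnsvr.templates import ReactionRecord, augment_records, dissect_product

product = canonicalize("CCCNCc1ccccc1")  # N-benzyl-propylamine
pairs = dissect_product(product, AMINE_ALKYLATION)

print(f"product {product.smiles} dissects {len(pairs)} ways:")
for pair in pairs:
    r1, r2 = pair.unmarked()
    print(f"  aldehyde {r1.smiles:>18}  +  amine {r2.smiles}")

record = ReactionRecord(record_id="ex", product=product, pair=pairs[0], y=7.2)
augmented = augment_records([record], AMINE_ALKYLATION)
print(f"\n1 observed record -> {len(augmented)} after augmentation")
for rec in augmented:
    print(f"  {rec.provenance:>9}: {rec.pair.r1.smiles} + {rec.pair.r2.smiles} (pKi {rec.y})")
# Both records share the product's measured pKi; only the assumed precursor
# pair differs. Isotope 1000 marks the reaction-center atoms, 900 the
# leaving-group oxygen introduced by the retro transform.
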