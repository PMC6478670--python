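"""Pre-/post-test risk updating for a sequential detection strategy.

The reference scenario: the 3-year psychosis risk is 0.43% in the general
population, 15% in help-seeking samples referred for a high-risk assessment
(the recruitment step is the strongest "test"), 26% after a positive
assessment and 1.56% after a negative one.
"""

import polyrisk as pr

general, referred, positive, negative = 0.0043, 0.15, 0.26, 0.0156

print(f"recruitment enrichment: {general:.2%} -> {referred:.0%}, "
      f"{pr.fold_change(referred, general):.1f}-fold "
      f"(LR {pr.derive_lr(general, referred):.1f})")

lr_pos = pr.derive_lr(referred, positive)
lr_neg = pr.derive_lr(referred, negative)
print(f"positive assessment: LR {lr_pos:.2f} -> "
      f"{pr.update_risk(referred, lr_pos).posttest_prob:.0%} "
      f"({pr.fold_change(positive, referred):.1f}-fold increase)")
print(f"negative assessment: LR {lr_neg:.3f} -> "
      f"{pr.update_risk(referred, lr_neg).posttest_prob:.2%} "
      f"({pr.fold_change(referred, negative):.1f}-fold decrease)")

chained = pr.chain_tests(general, [pr.derive_lr(general, referred), lr_pos])
print(f"\nchained recruitment + assessment from the general population: "
      f"{chained.posttest_prob:.0%} (LR product {chained.likelihood_ratio:.0f})")
print("Most of the risk enrichment happens at recruitment, not at the")
print("assessment itself — which is why better pre-test enrichment matters.")
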