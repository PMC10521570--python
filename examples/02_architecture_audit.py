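"""Audit the segmentation network's layer schedule and parameter budget.

Builds the residual encoder-decoder network under its default block
convention, prints the per-block output schedule (which must reproduce the
published architecture table), counts parameters along two independent
routes — the arrays the engine allocates and the closed-form per-layer
formulas — and prints the convention-reconciliation report that documents
which published totals are and are not reproducible.
"""

import strokeseg as ss
from strokeseg.models import (
    PUBLISHED_NON_TRAINABLE,
    PUBLISHED_TRAINABLE,
    PUBLISHED_UNET_TOTAL,
    reconcile_conventions,
    render_reconciliation,
)

model, spec = ss.build_cnnres()
print("block output schedule (H, W, C):")
for block, shape in spec.block_output_shapes():
    print(f"  {block:28s} {shape}")

report = ss.verify_parameter_counts(model)  # raises if the two routes differ
print(f"\ntrainable parameters:     {report.trainable:>12,}")
print(f"non-trainable parameters: {report.non_trainable:>12,} "
      f"(published: {PUBLISHED_NON_TRAINABLE:,} — "
      f"{'match' if report.non_trainable == PUBLISHED_NON_TRAINABLE else 'MISMATCH'})")
print(f"(published trainable {PUBLISHED_TRAINABLE:,} is not reproduced by any "
      "table-consistent convention; see the reconciliation below)")

unet, _ = ss.build_unet_baseline(160)
ureport = ss.verify_parameter_counts(unet)
print(f"\nU-Net baseline total:     {ureport.total:>12,} "
      f"(published: {PUBLISHED_UNET_TOTAL:,} — "
      f"{'match' if ureport.total == PUBLISHED_UNET_TOTAL else 'MISMATCH'})")
print(f"parameter ratio U-Net / residual net: {ureport.total / report.total:.2f}x")

print()
print(render_reconciliation(reconcile_conventions()))
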