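"""Reproduce the sample-count arithmetic of dihedral augmentation.

Every training slice expands into 8 (rotations of the original and of its
mirror); validation/test slices expand into 2 (identity + mirror). The
printed ledger reproduces the clinical cohort's counts per modality and
the external challenge cohort's training total.
"""

import numpy as np

import strokeseg as ss
from strokeseg.io import SlicePair


def blank_slices(n):
    return [SlicePair(image=np.zeros((8, 8), np.float32), mask=np.zeros((8, 8), np.uint8),
                      subject_id=f"s{i}", modality="DWI", slice_index=i)
            for i in range(n)]


train_n, val_n, test_n = 560, 120, 112  # per-modality clinical slice counts
train_aug = len(ss.augment_slices(blank_slices(train_n), ss.train_policy()))
val_aug = len(ss.augment_slices(blank_slices(val_n), ss.eval_policy()))
test_aug = len(ss.augment_slices(blank_slices(test_n), ss.eval_policy()))

print("per modality:")
print(f"  train {train_n:>4} -> {train_aug:>5}  (x8: rotations of original + mirror)")
print(f"  val   {val_n:>4} -> {val_aug:>5}  (x2: identity + mirror)")
print(f"  test  {test_n:>4} -> {test_aug:>5}")
print("two modalities:")
print(f"  train {2 * train_aug}, val {2 * val_aug}, test {2 * test_aug}")

challenge_train = 275  # external challenge cohort: training slices per modality
challenge_total = len(ss.augment_slices(blank_slices(challenge_train), ss.train_policy())) * 2
print(f"challenge cohort: {challenge_train} x 8 x 2 modalities -> {challenge_total} training samples")
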