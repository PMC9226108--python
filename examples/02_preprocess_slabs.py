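"""Standardize a sweep, drop blank frames, and build 3-slice model slabs.

Blank frames (probe not yet acquiring) are removed by the >= 20% non-zero
pixel rule; each remaining frame becomes a (3, S, S) slab of its neighbours.
"""

import sonotkv as sk

spec = sk.sample_spec(seed=3, difficulty="centered")
stack, mask, _ = sk.render_phantom(spec)

cfg = sk.PreprocessConfig(target_inplane=128, slab_size=64)
stack_std, mask_std = sk.standardize_stack(stack, cfg, mask)
kept = sk.filter_blank_frames(stack_std, cfg)
print(f"frames kept by the blank-frame filter: {len(kept)} of {stack.n_frames}")

z = kept[len(kept) // 2]
slab, mslab = sk.make_slab(stack_std, z, cfg, mask_std)
print(f"slab for frame {z}: shape {slab.shape} (channels are frames "
      f"{z - 1}, {z}, {z + 1}), mask slab foreground {int(mslab.sum())} px")
# Model inputs are 64x64 here (desk scale); predictions are mapped back to
# the 128x128 storage geometry with sk.upsample_prediction before volumetry.
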