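"""Fuse a memory-colour prior with a grey-perception signal.

A single observer adjusted a banana image to its remembered yellow five
times, and a neutral disk to grey five times.  Projected onto the
banana's typical-hue axis, those adjustments give the two Gaussian cues;
their precision-weighted fusion is the predicted memory colour effect.
"""

from memcolour import predict_effect

# projections onto the typical-hue axis (DKL-plane units)
typical = [0.28, 0.31, 0.26, 0.33, 0.30]   # remembered banana yellow
disk_grey = [0.04, -0.06, 0.01, 0.07, -0.03]  # grey settings of the disk

post = predict_effect(typical, disk_grey)

print(f"prior weight w1      = {post.w_prior:.3f}")
print(f"predicted effect M   = {post.M:.4f}")
print(f"posterior SD         = {post.sd:.4f}")
print()
print("M is the shift (in chromaticity-plane units, along the banana's")
print("hue axis) that the model expects grey adjustments of the banana")
print("to show: the less reliable the grey signal relative to the colour")
print("memory, the larger the weight w1 of the prior and hence the shift.")
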