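"""Simulate a scaffold z-stack, count nuclei per layer, compare with truth.

A 14-layer stack (7 µm step) of 60 nuclei is generated with Hill-type
depth colonisation, segmented layer by layer, deduplicated across focal
planes, and the per-layer census is compared with the generator's ground
truth.
"""

import numpy as np

from infiltra import (
    StackParams,
    generate_stack,
    link_and_assign,
    score_against_truth,
    segment_stack,
)

params = StackParams(n_nuclei=60, width_px=512, height_px=512, seed=42)
stack, truth = generate_stack(params)
print(f"generated {stack.n_layers}-layer stack, {len(truth.table)} nuclei")

masks = segment_stack(stack)
n_raw = sum(m.n_objects for m in masks)
records = link_and_assign(stack, masks)
print(f"raw detections across all layers: {n_raw}")
print(f"deduplicated nuclei:              {len(records)}")

score = score_against_truth(records, truth)
print("\nlayer :", " ".join(f"{i:3d}" for i in range(stack.n_layers)))
print("found :", " ".join(f"{c:3d}" for c in score["count_profile"]))
print("truth :", " ".join(f"{c:3d}" for c in score["true_profile"]))
print(f"\nfraction of nuclei on their true layer: {score['layer_accuracy']:.3f}")
print(f"ground-truth nuclei counted twice:      {score['n_duplicate_truth']}")

# Each nucleus appears blurred in neighbouring layers, so raw detections
# exceed the true count; SSIM chaining + focus assignment collapses them
# onto the single in-focus layer, recovering the true depth census.
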