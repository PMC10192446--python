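"""Automated counting: render a column, train a pixel classifier, count.

Mirrors the automated workflow: (a) 8-bit conversion and maximum-intensity
z-projection, (b) a shallow trainable pixel classifier (bagged trees over a
filter bank) built from sparse scribbles on a few training images, (c)
object labelling with a minimum-size filter and the unbiased counting frame.
Training scribbles are derived here from the simulator's ground truth; on
real data a user draws them.

Takes a couple of minutes on one CPU (the training images span two seeding
densities).
"""

import scaffoldcount as sc

cfg = sc.RenderConfig()

# -- train on two rendered columns at different densities ------------------
images, scribbles = [], []
for i, n_cells in enumerate((10_000, 125_000)):
    spec = sc.ScaffoldSpec(volume_ul=500.0, n_cells=n_cells)
    pts = sc.generate_points(spec, seed=100 + i)
    col = sc.design_columns(spec, seed=200 + i).columns[0]
    stack = sc.render_stack(pts, col, cfg, seed=300 + i)
    images.append(sc.max_project(sc.to_8bit(stack)))
    truth_mask = sc.ground_truth_projection_mask(pts, col, cfg)
    scribbles.append(sc.sample_training_labels(truth_mask, 2000, seed=i))
model = sc.train_pixel_classifier(images, scribbles, seed=0)
print(f"trained on {model.training_meta['n_labeled_pixels']} labelled pixels")

# -- apply to a fresh column ----------------------------------------------
spec = sc.ScaffoldSpec(volume_ul=500.0, n_cells=10_000)
pts = sc.generate_points(spec, seed=7)
col = sc.design_columns(spec, seed=8).columns[0]
stack = sc.render_stack(pts, col, cfg, seed=9)

projection = sc.max_project(sc.to_8bit(stack))
foreground = sc.segment(projection, model=model)
mask = sc.label_and_filter(
    foreground, min_area_px=sc.default_min_area_px(cfg.pixel_size)
)
result = sc.count_projection(mask, col)
truth = sc.points_in_column(pts, col)

print(f"automated count : {result.count}")
print(f"ground truth    : {truth}")
print(f"column estimate : {result.count * 500.0 / col.volume_ul:,.0f} "
      "cells/scaffold")
# One column extrapolates with c * V / v_col; a full run averages 9 columns.
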