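# Default segmentation parameters (mirrors pcflow.AlgorithmParams).
# Values selected by the numerical-optimization harness on synthetic
# training phantoms; see docs/methods.md.
snake_iterations: 50
edge_weight: 6.0
tension_weight: 0.05
rigidity_weight: 0.1
gradient_sigma: 2.0
scale_factor: 1.05
search_radius: 10
step_size: 0.1
n_contour_points: 48
curvature_mode: pca            # pca | curvature-force
curvature_weight: 0.5          # used in curvature-force mode only
patch_margin: 4
reconstruct_every_k_iterations: 0
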