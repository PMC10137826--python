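"""The core invariance: pair features ignore platform distortions.

The same latent cohort is rendered noise-free through two very different
platforms (a nonlinear expression-scale map and a negated Ct-scale map).
Expression-level differential expression disagrees between the two
renderings; the binary pair matrices are bit-identical.
"""

import mirpair as mp

latent = mp.generate_latent(
    n_copd=30, n_healthy=30, n_features=20, n_planted=3, p_flip=0.0,
    mean_shift=2.0, n_shifted=4, seed=11,
)
array = mp.render_platform(
    latent, mp.PlatformSpec(name="array", transform="affine", slope=2.0)
)
qpcr = mp.render_platform(
    latent, mp.PlatformSpec(name="qpcr", scale="ct", transform="affine", slope=0.5)
)

de_array = set(mp.differential_expression(array).flagged)
de_qpcr = set(mp.differential_expression(qpcr).flagged)
print("differentially expressed miRNAs (|logFC| > 1.5, p < 0.05):")
print(f"  array rendering: {sorted(de_array)}")
print(f"  qPCR rendering:  {sorted(de_qpcr)}")
print(f"  agreement: {de_array == de_qpcr}")

pm_array = mp.build_pair_matrix(array)
pm_qpcr = mp.build_pair_matrix(qpcr)
print(f"\npair matrices identical: {pm_array.scores.equals(pm_qpcr.scores)}")
print(
    "\nThe same samples, the same biology - the fold-change analysis flags"
    "\ndifferent miRNAs on each platform because it reads absolute values,"
    "\nwhile the rank-based pair features are untouched by any strictly"
    "\nincreasing distortion."
)
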