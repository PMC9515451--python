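"""Generate a small synthetic H&E-like cohort and inspect it.

Each slide is a tiled pyramidal TIFF with a known tumor mask; the
annotation is exported at downsample 4, mirroring a typical pathology
annotation workflow.
"""

from histocascade import CohortSpec, generate_cohort

spec = CohortSpec(n_wsi=4, seed=7)
wsis, manifest = generate_cohort(spec, "example_cohort")

print(manifest[["wsi_path", "grade", "split"]])
for wsi in wsis:
    pyr = wsi.pyramid
    tumor_frac = wsi.tumor_mask_level0.mean()
    print(f"grade {wsi.grade}: {pyr.width}x{pyr.height} px, "
          f"{len(pyr.levels)} levels, tumor covers {tumor_frac:.1%} of the slide")
# The tumor fraction is of the whole slide; relative to tissue it falls in
# the spec's tumor_of_tissue_range (default 25-55%).
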