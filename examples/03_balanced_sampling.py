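"""Hierarchical balanced sampling from a deliberately skewed cohort.

One grade-I slide competes with nine grade-II slides, and within the
grade-I slide tumor patches are outnumbered 100:1.  The tree sampler still
draws grade I half the time and tumor half the time, because every stage
(grade -> WSI -> class -> patch) is a uniform choice.
"""

import numpy as np

from histocascade.preprocess import PatchIndexTable, PatchRecord
from histocascade.sampler import build_tree, draw_patch


def table(wsi_id, grade, n_tumor, n_nontumor):
    recs = [PatchRecord(wsi_id, 256 * i, 0, 1, 1.0, 1.0)
            for i in range(n_tumor)]
    recs += [PatchRecord(wsi_id, 256 * i, 256, 0, 1.0, 0.0)
             for i in range(n_nontumor)]
    return PatchIndexTable(recs, wsi_id, grade)


tables = [table("rare_grade_I", "I", 10, 1000)]
tables += [table(f"grade_II_{i}", "II", 50, 50) for i in range(9)]
tree = build_tree(tables)

rng = np.random.default_rng(0)
draws = [draw_patch(tree, rng) for _ in range(20000)]
p_grade1 = np.mean([d.wsi_id == "rare_grade_I" for d in draws])
p_tumor = np.mean([d.label == 1 for d in draws])
print(f"P(grade I)  = {p_grade1:.3f}  (uniform over the 10 WSIs would give 0.10)")
print(f"P(tumor)    = {p_tumor:.3f}  (pooling all patches would give ~0.24)")
# Both probabilities sit near 1/2: the hierarchy neutralises cohort skew.
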