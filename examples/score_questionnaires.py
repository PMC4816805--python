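"""Score the two imagery questionnaires and correlate the results.

Builds item-level responses for a handful of synthetic respondents, scores
the 2x14-item auditory scale (1-7) and the 16-item visual scale (1-5,
inverted so higher = more vivid), and reports the vividness-control
correlation.
"""

import numpy as np

from imagerylink import behavioral

rng = np.random.default_rng(0)

viv_scores, ctl_scores, vviq_scores = [], [], []
for _ in range(30):
    base = rng.uniform(2, 6)
    viv_items = np.clip(np.round(base + rng.normal(0, 1, 14)), 1, 7).astype(int)
    ctl_items = np.clip(np.round(base + rng.normal(0.3, 1, 14)), 1, 7).astype(int)
    vviq_items = np.clip(np.round(6 - base * 5 / 7 + rng.normal(0, 0.8, 16)), 1, 5).astype(int)
    v, c, total = behavioral.score_bais(viv_items, ctl_items)
    viv_scores.append(v)
    ctl_scores.append(c)
    vviq_scores.append(behavioral.score_vviq(vviq_items))

res = behavioral.pearson_r(viv_scores, ctl_scores)
print(f"vividness mean = {np.mean(viv_scores):.2f}, control mean = {np.mean(ctl_scores):.2f}")
print(f"vividness-control r = {res.r:.2f} (p = {res.p_two_sided:.2g}, n = {res.n})")
cross = behavioral.pearson_r(viv_scores, vviq_scores)
print(f"auditory-visual vividness r = {cross.r:.2f} (p = {cross.p_two_sided:.2g})")
print("Both scales point the same way: higher scores mean more vivid imagery,")
print("so positive r means people vivid in one modality report vividness in the other.")
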