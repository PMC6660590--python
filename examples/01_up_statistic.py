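"""The Uniform Product statistic: joint probability of a run of p-values.

Five consecutive CpG tests with p-values [0.01, 0.04, 0.20, 0.03, 0.02]
individually hover around significance; the UP tail probability asks how
likely a product that small is if all five were null (Uniform(0,1)).
"""

import numpy as np

from updmr import up_tail_probability

p_run = [0.01, 0.04, 0.20, 0.03, 0.02]
x = float(np.prod(p_run))
up = up_tail_probability(x, len(p_run))
print(f"site p-values      : {p_run}")
print(f"product            : {x:.3g}")
print(f"UP tail probability: {up:.3g}")
print("-> the run is far stronger evidence than any single site:",
      f"{up:.1e} vs best site p = {min(p_run):.0e}")

# the same product is unremarkable when spread over many more sites
print(f"same product over 20 sites: {up_tail_probability(x, 20):.3f} (not significant)")
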