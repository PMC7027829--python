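"""Partition a tiny pixel x feature matrix by hand-checkable numbers.

Four pixels with one spectral feature, grouped into two communities of two.
When the communities are internally identical but differ from each other,
all variation is among communities (beta); when each community spans the
full range, all variation is within (alpha).
"""

import numpy as np

from specvar import CommunityGrid, partition_all

grid = CommunityGrid(assignment=np.array([0, 0, 1, 1]), q=2, m=2)

for name, values in [
    ("pure beta", [0.0, 0.0, 2.0, 2.0]),   # communities {0,0} and {2,2}
    ("pure alpha", [0.0, 2.0, 0.0, 2.0]),  # both communities {0,2}
]:
    Y = np.asarray(values)[:, None]
    part = partition_all(Y, grid)
    print(f"{name}: SS_gamma={part.ss_gamma:.0f} = SS_beta {part.ss_beta:.0f}"
          f" + SS_alpha {part.ss_alpha:.0f};  SD_gamma={part.sd_gamma:.4f}")

# Both cases have SS_gamma = 4 (the same four values), but the 4 splits
# entirely into the among-community or the within-community component
# depending on how the values are arranged across communities.
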