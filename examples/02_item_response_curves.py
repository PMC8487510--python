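"""Category probabilities of two Katz items along the disability scale.

Bathing has low thresholds (lost early, at mild disability) while
continence has high ones (lost last); toileting's huge partial→total
gap means it stays partially limited across a wide severity range.
"""

import numpy as np

from adlirt import category_probs
from adlirt.data_model import KatzItem
from adlirt.reference import REFERENCE_ITEM_PARAMS

grid = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0])
for item in (KatzItem.BATHING, KatzItem.TOILETING, KatzItem.CONTINENCE):
    p = REFERENCE_ITEM_PARAMS[item]
    print(f"{item.value:12s} alpha={p.alpha:.3f} "
          f"kappa=({p.kappa_partial:.3f}, {p.kappa_total:.3f})")
    for theta in grid:
        p0, p1, p2 = category_probs(p, theta)
        print(f"  theta={theta:5.1f}  none={p0:.3f} partial={p1:.3f} total={p2:.3f}")
# Probabilities in each row sum to 1; as theta grows, mass moves from
# "no limitation" through "partial" to "totally limited".
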