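"""Build a small item bank, inspect GRM probabilities, and inject uniform DIF.

Shows how a constant threshold shift in the focal group lowers the
expected item score at every trait level — the definition of uniform DIF.
"""

import numpy as np

from difpower import (
    grm_category_probabilities,
    inject_uniform_dif,
    sample_item_parameters,
)

rng = np.random.default_rng(7)
bank = sample_item_parameters(n_items=10, n_categories=5, rng=rng)
print("item 1: a = %.3f, thresholds = %s" % (bank.discrimination[0], np.round(bank.thresholds[0], 3)))

focal = inject_uniform_dif(bank, item=0, delta=0.5)
cats = np.arange(1, 6)
for theta in (-1.0, 0.0, 1.0):
    p_ref = grm_category_probabilities(theta, bank.discrimination[0], bank.thresholds[0])
    p_foc = grm_category_probabilities(theta, focal.discrimination[0], focal.thresholds[0])
    print(
        f"theta={theta:+.1f}:  E[score] reference = {cats @ p_ref:.3f}, "
        f"focal (+0.5 shift) = {cats @ p_foc:.3f}"
    )

# The focal expectation is lower at every theta: the item is uniformly
# harder for the focal group, by the same amount across the trait range.
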