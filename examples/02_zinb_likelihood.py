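"""Evaluate the zero-inflated negative binomial likelihood on toy counts.

The ZINB density is pi*1[x=0] + (1-pi)*NB(x | mu, theta): a dropout point
mass at zero mixed with an overdispersed count distribution. The printed
numbers show how zero inflation reallocates probability mass.
"""

import numpy as np

from scdistill import ZINBParams, zinb_nll

x = np.arange(6.0)
for pi in (0.0, 0.3):
    params = ZINBParams(mu=np.full_like(x, 2.0), theta=np.full_like(x, 2.0),
                        pi=np.full_like(x, pi))
    nll = zinb_nll(x, params, reduce="none")
    probs = np.exp(-nll)
    print(f"pi={pi}: P(x=0..5) =", np.round(probs, 4))
# With pi=0.3 the probability of a zero jumps (dropout) while the
# probabilities of positive counts shrink by the factor (1-pi).
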