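"""Genus-level enrichment of BGC counts (negative-binomial model).

Simulates two genera with a four-fold difference in mean NRPS count and
recovers the contrast on the log10 scale with a 95% interval.
"""

import numpy as np
import pandas as pd

from bgconserve import TraitTable, nb_enrichment

rng = np.random.default_rng(21)
theta, n = 10.0, 150
counts = np.concatenate(
    [
        rng.negative_binomial(theta, theta / (theta + 2.0), n),  # genus A, mean 2
        rng.negative_binomial(theta, theta / (theta + 8.0), n),  # genus B, mean 8
    ]
)
idx = [f"g{i}" for i in range(2 * n)]
table = TraitTable(
    pd.DataFrame({"NRPS": counts}, index=idx),
    pd.DataFrame({"genus": ["A"] * n + ["B"] * n}, index=idx),
)

res = nb_enrichment(table, "NRPS", reference_genus="A")
print(res.per_genus.round(4).to_string(index=False))
print(f"dispersion theta = {res.dispersion:.2f}  model = {res.model}")
# log10_mean is the fitted mean count per genome on the log10 scale; the
# true contrast is log10(8/2) = 0.602.  p_value tests each genus against
# the reference.
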