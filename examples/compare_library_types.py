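"""Compare chimera loads between individually amplified (type A) and
pool-amplified (type B) libraries.

Simulates per-group chimera percentages under the two protocols — pooling
before the indexing PCR adds PCR chimeras on top of sequencing chimeras —
and runs the standard rank statistics.
"""

import numpy as np
import pandas as pd

from quadchim import compare_library_types

rng = np.random.default_rng(0)
reads_per_group = 50_000
rows = []
for lib, typ, rate in [
    ("A-1", "A", 0.006), ("A-2", "A", 0.006), ("A-3", "A", 0.007),
    ("B-1", "B", 0.012), ("B-2", "B", 0.011), ("B-3", "B", 0.012),
]:
    for g in range(10):
        chim = rng.binomial(reads_per_group, rate)
        rows.append((lib, typ, f"{lib}-g{g}", 100 * chim / reads_per_group))
df = pd.DataFrame(
    rows, columns=["library_id", "library_type", "group_id", "pct_chimeric"]
)

res = compare_library_types(df)
mw = res["mann_whitney"]
kw = res["kruskal_wallis"]
print(f"A vs B Mann-Whitney: U = {mw['U']:.0f}, p = {mw['p_value']:.2e}")
print(f"across libraries Kruskal-Wallis: H = {kw['H']:.1f}, p = {kw['p_value']:.2e}")
print("\nDunn post-hoc (Holm-adjusted):")
print(res["dunn"].to_string(index=False))
print(
    "\nPooled amplification roughly doubles the chimeric fraction, and the "
    "difference dwarfs the variation between libraries of the same type."
)
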