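"""Normalize read profiles by counted specimens and remove background signal.

Reads mapped to each ASV-3 are converted to estimated specimen counts by
sharing out the slice's sorted-specimen total. Because some reads come from
sources that were never counted (soft-bodied taxa, gut contents), the
counts/ASV-3 index can fall below 1; a single global threshold zeroes
low-count cells until every populated slice has index > 1.
"""

import pandas as pd

from meiobar import background_zero, normalize_profile

# one slice profile: mapped meiofaunal reads per ASV-3, 50 counted specimens
reads = {"ASV3_0001": 60, "ASV3_0002": 30, "ASV3_0003": 10}
est = normalize_profile(reads, total_count=50)
print("estimated counts:", est)          # proportional allocation: 30/15/5

# a matrix with a background-contaminated slice (total 2 over five cells)
matrix = pd.DataFrame({
    "clean_slice": [5.0, 4.0, 0.0, 0.0, 0.0],
    "noisy_slice": [1.0, 0.4, 0.3, 0.2, 0.1],
}, index=[f"ASV3_{i:04d}" for i in range(5)])
totals = {"clean_slice": 9, "noisy_slice": 2}
res = background_zero(matrix, totals)
print(f"zeroing threshold tau* = {res.tau}")
print("counts/ASV-3 index after zeroing:")
print(res.index.round(2).to_string())
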