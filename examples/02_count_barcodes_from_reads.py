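"""Turn raw reads into a barcode count column.

Simulates reads (constant flanks around a 12-nt barcode, 0.5% per-base
substitution errors), then recovers counts by anchored flank search plus
Hamming matching with one allowed mismatch.  The library's pairwise barcode
distance of >= 3 makes one-mismatch assignment unambiguous.
"""

import numpy as np
import pandas as pd

from frepscreen import (
    ReadLayout, SimConfig, count_barcodes, simulate_guide_library, simulate_reads,
)

library = simulate_guide_library(SimConfig(n_genes=20, seed=2))
layout = ReadLayout()
rng = np.random.default_rng(0)
true_counts = pd.Series(rng.integers(0, 100, len(library)), index=library.barcodes)

column, qc = count_barcodes(
    simulate_reads(library, true_counts, layout, error_rate=0.005, seed=3),
    library, layout, max_mismatch=1,
)
print("QC:", qc.to_dict())
recovered = (column == true_counts).mean()
print(f"assigned fraction: {qc.reads_assigned / qc.reads_total:.4f} "
      "(lost reads carry >1 error in flank or barcode)")
print(f"barcodes recovered exactly: {recovered:.3f}; "
      f"count correlation r = {np.corrcoef(column, true_counts)[0, 1]:.5f}")
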