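"""Quality-trim, primer-strip, filter and merge one slice's read pairs.

The funnel mirrors the analytical bookkeeping of the pipeline: raw pairs >=
filtered pairs >= merged reads. With noise-free high-quality reads every
pair survives and merges back into the exact amplicon insert.
"""

from meiobar import SimulationConfig
from meiobar.qc import QCParams, qc_slice
from meiobar.simulate import simulate_study

cfg = SimulationConfig(n_sites=1, depths_m=(54,), n_species=6,
                       n_background_species=2, n_other_species=0,
                       n_cores_per_site=1, reads_per_slice=100, seed=2)
simulate_study(cfg, outdir="scratch/example_qc")

merged, stats = qc_slice(
    "scratch/example_qc/reads/S0_C0_0-1_R1.fastq.gz",
    "scratch/example_qc/reads/S0_C0_0-1_R2.fastq.gz",
    QCParams(), slice_id="S0:C0:0-1",
)
print(f"raw pairs:      {stats.n_raw_pairs}")
print(f"filtered pairs: {stats.n_filtered_pairs}")
print(f"merged reads:   {stats.n_merged}")
print(f"reject reasons: {stats.reject_reasons or 'none'}")
print(f"first merged read: {merged[0][1][:60]}... ({len(merged[0][1])} bp)")
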