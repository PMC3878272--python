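"""TRAP telomerase quantification and hormone-correlation analysis.

First reduces simulated qPCR amplification curves to Cq values and a
2^-dCq fold change; then draws copula-structured assay panels at every
sampling age and tabulates the hormone vs telomerase/telomere Spearman
correlations with Benjamini-Hochberg adjustment.
"""

import pandas as pd

import telovita as tv
from telovita.assays import cq_table, summarize_triplicates

# --- relative telomerase activity from amplification curves -------------
curves = tv.simulate_amplification_curves(true_delta_cq=1.5, noise_sd=0.01, seed=1)
cq = summarize_triplicates(cq_table(curves, threshold=1e-3))
vals = dict(zip(cq["sample"], cq["cq"]))
ra = tv.relative_activity(vals["sample"], vals["reference"])
print(f"Cq sample = {vals['sample']:.2f}, Cq reference = {vals['reference']:.2f} "
      f"-> relative telomerase activity 2^-dCq = {ra:.3f}")
print("(a true dCq of 1.5 cycles corresponds to 2^-1.5 = 0.354-fold activity)")

# --- hormone/telomerase/telomere correlation table ----------------------
cfg = tv.SimConfig(seed=1)
frames = [
    tv.simulate_assay_panel(cfg, age, sex, organ)
    for age in cfg.sampling_ages
    for sex in ("M", "F")
    for organ in ("gill", "liver")
]
panel = pd.concat(frames, ignore_index=True)
table = tv.correlation_table(panel)
sig = table[table["p_adj"] < 0.05]
print(f"\n{len(sig)} of {len(table)} hormone-measure correlations significant "
      "after FDR adjustment (per-sex families):")
print(sig.to_string(index=False,
                    formatters={"rho": "{:.2f}".format,
                                "p": "{:.2g}".format, "p_adj": "{:.2g}".format}))
print("Pooled-over-age correlations mix the configured within-age rank "
      "structure with shared age trajectories (E2 and telomerase both peak "
      "at 8 months in females, strengthening those rows); the pure "
      "within-age male-gill telomerase-TRF association is shown by drawing "
      "a single-age panel, as in the acceptance checks.")
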