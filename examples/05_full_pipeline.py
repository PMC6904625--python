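"""Run the complete pipeline on a small synthetic cohort.

Three phantom 'placentas' are generated, point-counted with pooled
sampling passes, measured, and summarized into the results bundle
(composition table, vesicle size table, contact and network summaries,
running-mean adequacy) written under ``scratch_pipeline_demo/``.
"""

from stromametry import RunConfig, run_pipeline

config = RunConfig(
    out_dir="scratch_pipeline_demo",
    n_placentas=3,
    passes_per_placenta=5,
    seed=2,
)
bundle = run_pipeline(config)

print(bundle["composition"].to_string(index=False))
print()
print(bundle["sizes"].to_string(index=False))
print()
print("contacts:", bundle["contacts"].get("pct_stellate_contact"), "% stellate")
print("networks:", round(bundle["networks"]["mean_nuclei_per_network"], 2),
      "nuclei per network over", bundle["networks"]["n_networks"], "networks")
# Rerunning with the same config and seed reproduces every CSV
# byte-for-byte; the report.json carries the full config echo.
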