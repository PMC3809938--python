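"""Generate a synthetic probe-level dataset with the MAQC factorial design.

Two reference RNAs (UHRR, HBRR) and their 75/25 and 25/75 mixtures are
assayed at several sites with five replicate arrays each; every probe set
carries 11-20 PM/MM probe pairs.
"""
from imputebench import GeneratorConfig, generate_dataset

config = GeneratorConfig(n_probe_sets=200, n_sites=2, seed=42)
table = generate_dataset(config)

print(f"samples: {len(table.samples)} "
      f"({config.n_sites} sites x {len(config.pool_mixtures)} pools x "
      f"{config.n_replicates} replicates)")
print(f"probe-level rows: {len(table.probes)}")
print(table.probes.head(3).to_string(index=False))
# Each row is one probe pair on one array: the PM intensity carries signal
# plus background, the MM intensity mostly cross-hybridisation background.
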