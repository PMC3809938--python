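"""From probe pairs to one expression value per probe set per array.

An ideal mismatch keeps PM - IM positive, a one-step Tukey biweight of
log2(PM - IM) summarises each probe set robustly, and every array is scaled
to a common trimmed-mean target intensity of 500.
"""
from imputebench import (GeneratorConfig, detect, filter_complete, generate_dataset,
                         scale_normalize, summarize)

table = generate_dataset(GeneratorConfig(n_probe_sets=120, n_sites=1, seed=7))
calls = detect(table)
retained = filter_complete(calls, table.samples, "site1", "A")
cell_arrays = [s for s in table.sample_ids if s.startswith("site1_A_")]

matrix = scale_normalize(summarize(table, retained, sample_ids=cell_arrays))
print(f"complete matrix: {matrix.shape[0]} probe sets x {matrix.shape[1]} replicate arrays")
print(matrix.head(4).round(1).to_string())
# Rows are detected transcripts, columns replicate arrays of one site/pool
# cell; values are positive expression intensities on a common scale.
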