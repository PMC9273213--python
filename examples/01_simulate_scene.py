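"""Generate one synthetic condition and look at its ground truth.

Builds 3 four-channel fields (nuclei / reporter / marker / mitochondria)
with known per-cell truth, writes them to ./scratch_example_scene/ as TIFFs
plus a truth CSV, and prints the per-cell table. The `theta` column is the
mislocalized fraction: the share of each cell's reporter signal sitting on
its mitochondrial network instead of the Golgi.
"""

import mitoloc as ml
from mitoloc.io import truths_to_dataframe, write_condition

params = ml.SynthParams(n_fields=3, misloc_fraction=0.4, seed=11)
pairs, manifest = ml.generate_condition(params, "demo")

outdir = write_condition("scratch_example_scene", pairs, manifest)
print(f"wrote {len(pairs)} fields to {outdir}/")

for field, truths in pairs:
    df = truths_to_dataframe(truths, field.field_id)
    cols = ["cell_id", "theta", "expression_level", "transfected", "cell_area_px"]
    print(f"\n{field.field_id}:")
    print(df[cols].to_string(index=False))
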