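"""Render a per-atom attention heatmap for 1H-indazole.

Attention coefficients are each atom's share of the molecule's attention
minus the molecular average (they sum to zero); the diverging color scale
is centered at zero, so tinted atoms draw more or less attention than an
average atom of the molecule.
"""

from pathlib import Path

import molmpn as m
from molmpn import training as tr

records = m.clean_dataset(m.make_records(m.FixtureConfig(n=300, seed=7, noise_sd=0.1)))
plan = m.stratified_split(records, k=10, seed=0)
fold = plan.folds[0]
model, _ = m.fit([records[i] for i in fold["train"]], [records[i] for i in fold["val"]],
                 config=tr.TrainConfig(epochs=5, batch_size=50, seed=0),
                 hidden_size=32, depth=3, seed=0)

smiles = "c1ccc2[nH]ncc2c1"  # 1H-indazole
result = model.attention_result(smiles)
print("attention coefficients (sum to zero):")
for i, c in enumerate(result.coefficients):
    print(f"  atom {i}: {c:+.4f}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = m.render_heatmap(
    m.HeatmapSpec(smiles=smiles, coefficients=result.coefficients,
                  property_name="lipophilicity"), out / "indazole.svg")
print(f"heatmap written to {path} (+ {path}.atoms.csv)")
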