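"""Small random draw from the standard hyperparameter lattice.

Points are sampled from the full grid (activation x depth x hidden size x
dropout x head layers) and ranked by validation RMSE; the budget here is
tiny so the script stays fast.
"""

import molmpn as m
from molmpn import evaluation as ev
from molmpn import training as tr

records = m.clean_dataset(m.make_records(m.FixtureConfig(n=200, seed=7, noise_sd=0.1)))
space = ev.GridSpace(hidden_sizes=(32, 64), depths=(2, 3))  # narrowed for speed
best, table = m.grid_search(records, space, budget=4, seed=0,
                            config=tr.TrainConfig(epochs=5, batch_size=50, seed=0))
print(table.sort_values("val_rmse").to_string(index=False))
print("best point:", best)
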