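"""Round-trip a dataset through CSV with a declared column mapping.

Shows the file-based workflow: save a dataset (a JSON sidecar records the
column map), reload it, split train/test, fit, and save/reload the model.
"""
import tempfile
from pathlib import Path

import numpy as np

import hnet

train, _, _ = hnet.generate_nie2021(hnet.DGPSpec(n_train=300, n_test=1, seed=2))

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "study.csv"
    hnet.save_dataset(train, path)
    column_map = {"covariates": [f"x{i}" for i in range(1, 7)],
                  "treatment": "t", "outcome": "y"}
    ds = hnet.load_dataset(path, column_map)
    print(f"reloaded {ds.n} rows, p={ds.p} covariates, tau={ds.tau}")

    tr, te = hnet.train_test_split(ds, n_test=60, seed=0)
    model = hnet.fit(tr, hnet.TrainConfig(max_epochs=120, n_restarts=1), seed=0)
    mse = hnet.mse_loss(model, (te.X, te.T, te.Y))
    print(f"held-out outcome MSE: {mse:.3f} (outcome variance {te.Y.var():.3f})")

    mpath = Path(tmp) / "model.npz"
    model.save(mpath)
    back = hnet.HNetModel.load(mpath)
    same = np.array_equal(back.forward_batch(te.X, te.T),
                          model.forward_batch(te.X, te.T))
    print(f"model round-trips through {mpath.name}: {same}")
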