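"""Shared test utilities: importance-table construction and the brute-force
OOB permutation oracle used to cross-check the forest engine."""

import numpy as np
import pandas as pd

from gutbrain.forest_engine import ImportanceTable, _oob_index_lists


def make_imp(values: dict, mode: str = "classification") -> ImportanceTable:
    return ImportanceTable(values=pd.Series(values, dtype=float), mode=mode)


def oob_permutation_oracle(model, X, y, mode, n_perm=1000, seed=0):
    """Direct estimate of OOB permutation importance.

    For every feature and every tree, permutes the feature's values among
    that tree's out-of-bag samples ``n_perm`` times and averages the change
    in OOB loss (error rate for classification, MSE for regression) over
    permutations and trees.  Estimates the same expectation as the engine's
    one-permutation-per-tree computation, independently of its code path.
    """
    rng = np.random.default_rng(seed)
    Xv = np.ascontiguousarray(np.asarray(X, dtype=float), dtype=np.float32)
    yv = np.asarray(y)
    enc = np.searchsorted(model.classes_, yv) if mode == "classification" else None
    oobs = _oob_index_lists(model, len(yv))
    imps = np.zeros(Xv.shape[1])
    for j in range(Xv.shape[1]):
        total, count = 0.0, 0
        for est, oob in zip(model.estimators_, oobs):
            if len(oob) == 0:
                continue
            Xo = Xv[oob].copy()
            pred = est.predict(Xo, check_input=False)
            if mode == "classification":
                base = np.mean(pred != enc[oob])
            else:
                base = np.mean((pred - yv[oob]) ** 2)
            col = Xo[:, j].copy()
            acc = 0.0
            for _ in range(n_perm):
                Xo[:, j] = col[rng.permutation(len(oob))]
                pred = est.predict(Xo, check_input=False)
                if mode == "classification":
                    acc += np.mean(pred != enc[oob])
                else:
                    acc += np.mean((pred - yv[oob]) ** 2)
            total += acc / n_perm - base
            count += 1
        imps[j] = total / count
    return imps
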