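"""Independent brute-force oracles used to verify the implementation.

These deliberately re-implement the logic they check (objective minimisation
by exhaustive grid search, cross-validation fold structure by plain loops)
instead of calling the package's evaluation code paths.
"""

import itertools

import numpy as np

from lignoclass import svm


def grid_oracle(X, y, C, span=6.0, step=0.01):
    """Exhaustive minimisation of the L1 + squared-hinge objective.

    Evaluates the objective over a regular grid of weight vectors in
    [-span, span]^n (n = 1 or 2 features) and returns (best_w, best_value).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[1]
    assert n in (1, 2), "oracle supports only 1 or 2 features"
    axis = np.arange(-span, span + step / 2, step)
    if n == 1:
        W = axis[:, None]
    else:
        W = np.array(list(itertools.product(axis, axis)))
    margins = 1.0 - y[None, :] * (W @ X.T)
    hinge = np.clip(margins, 0.0, None)
    values = np.abs(W).sum(axis=1) + C * (hinge ** 2).sum(axis=1)
    best = int(values.argmin())
    return W[best], float(values[best])


def _minmax_fit(X):
    return X.min(axis=0), X.max(axis=0)


def _minmax_apply(X, mins, maxs):
    span = maxs - mins
    out = np.zeros_like(X, dtype=float)
    ok = span > 0
    out[:, ok] = (X[:, ok] - mins[ok]) / span[ok]
    return out


def _fit_predict(X, y, train_idx, test_idx, C, scale):
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte = X[test_idx]
    if scale:
        mins, maxs = _minmax_fit(Xtr)
        Xtr = _minmax_apply(Xtr, mins, maxs)
        Xte = _minmax_apply(Xte, mins, maxs)
    model = svm.train(Xtr, ytr, C, 1e-6)
    values = Xte @ model.w
    return np.where(values > 0, 1, -1)


def loo_oracle(X, y, C, scale=False):
    """Plain leave-one-out loop; returns (predictions, macro_accuracy)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        preds[i] = _fit_predict(X, y, rest, [i], C, scale)[0]
    return preds, macc(y, preds)


def macc(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recall = (y_pred[y_true == 1] == 1).mean()
    tnr = (y_pred[y_true == -1] == -1).mean()
    return (recall + tnr) / 2


def nested_oracle(X, y, C_values, scale=False):
    """Independent double-loop nested CV.

    Outer leave-one-out; inner leave-one-out grid search over the remaining
    samples picks C (ties toward smaller C); model at that C trained on all
    remaining samples predicts the held-out one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    outer_preds = np.empty(n, dtype=int)
    chosen = np.empty(n)
    for i in range(n):
        rest = [j for j in range(n) if j != i]
        Xr, yr = X[rest], y[rest]
        best_c, best_m = None, -1.0
        for C in sorted(C_values):
            _, m = loo_oracle(Xr, yr, C, scale=scale)
            if m > best_m:  # ties keep the smaller C because of ascending order
                best_c, best_m = C, m
        chosen[i] = best_c
        outer_preds[i] = _fit_predict(X, y, rest, [i], best_c, scale)[0]
    return outer_preds, chosen, macc(y, outer_preds)


def random_toy_problem(rng, n_samples, n_features, binary=False):
    """A labelled toy problem with both classes guaranteed present."""
    if binary:
        X = (rng.random((n_samples, n_features)) < 0.5).astype(float)
    else:
        X = rng.uniform(-1.0, 1.0, size=(n_samples, n_features))
    y = rng.choice([-1, 1], size=n_samples)
    y[0], y[1] = 1, -1  # force both classes
    return X, y
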