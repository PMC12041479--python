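"""Shapley-value feature attribution (SHAP) with interventional expectations.

The attribution of feature ``j`` for instance ``x`` under model ``f`` is the
Shapley value

    phi_j = sum over S subset of features\\{j} of
            |S|! (d - |S| - 1)! / d! * [v(S u {j}) - v(S)],

where the coalition value ``v(S)`` is realized as the interventional
expectation: features in ``S`` take their values from ``x``, features outside
``S`` are replaced by rows of a background set, and the model scores are
averaged.  Exact mode enumerates all ``2^d`` coalitions (feasible up to 12
features); sampled mode averages marginal contributions over random feature
permutations, which converges to the same values.

Both modes satisfy the efficiency identity
``sum(phi) = f(x) - E_background[f]`` -- exactly in exact mode, stochastically
in sampled mode.
"""

from __future__ import annotations

from math import factorial

import numpy as np

EXACT_MAX_FEATURES = 12


def _coalition_rows(
    x: np.ndarray, background: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """Background copies with masked features replaced by the instance values.

    masks: (k, d) boolean; returns (k * m, d) rows ordered coalition-major.
    """
    k = masks.shape[0]
    m = background.shape[0]
    rows = np.repeat(background[None, :, :], k, axis=0)  # (k, m, d)
    sel = np.broadcast_to(masks[:, None, :], rows.shape)
    rows = np.where(sel, x[None, None, :], rows)
    return rows.reshape(k * m, -1)


def _coalition_values(
    model_fn, x: np.ndarray, background: np.ndarray, masks: np.ndarray,
    batch_rows: int = 262144,
) -> np.ndarray:
    """v(S) for each mask: mean model score over background replacements."""
    m = background.shape[0]
    per_call = max(batch_rows // m, 1)
    values = np.empty(masks.shape[0])
    for start in range(0, masks.shape[0], per_call):
        chunk = masks[start : start + per_call]
        rows = _coalition_rows(x, background, chunk)
        scores = np.asarray(model_fn(rows), dtype=float).reshape(len(chunk), m)
        values[start : start + len(chunk)] = scores.mean(axis=1)
    return values


def _exact_shap(model_fn, x, background, batch_rows):
    d = x.size
    n_masks = 1 << d
    bits = ((np.arange(n_masks)[:, None] >> np.arange(d)) & 1).astype(bool)
    v = _coalition_values(model_fn, x, background, bits, batch_rows)
    sizes = bits.sum(axis=1)
    weights = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    phi = np.zeros(d)
    for j in range(d):
        without_j = ~bits[:, j]
        masks_s = np.flatnonzero(without_j)
        masks_sj = masks_s | (1 << j)
        phi[j] = np.sum(weights[sizes[masks_s]] * (v[masks_sj] - v[masks_s]))
    return phi


def _sampled_shap(model_fn, x, background, n_permutations, rng, batch_rows):
    d = x.size
    m = background.shape[0]
    perms_per_call = max(batch_rows // ((d + 1) * m), 1)
    phi = np.zeros(d)
    done = 0
    while done < n_permutations:
        k = min(perms_per_call, n_permutations - done)
        perms = np.stack([rng.permutation(d) for _ in range(k)])  # (k, d)
        # cumulative coalition masks along each permutation: (k, d+1, d)
        masks = np.zeros((k, d + 1, d), dtype=bool)
        for pos in range(d):
            masks[:, pos + 1] = masks[:, pos]
            masks[np.arange(k), pos + 1, perms[:, pos]] = True
        flat = masks.reshape(k * (d + 1), d)
        v = _coalition_values(model_fn, x, background, flat, batch_rows)
        v = v.reshape(k, d + 1)
        marginals = np.diff(v, axis=1)  # (k, d) in permutation order
        np.add.at(phi, perms.ravel(), marginals.ravel())
        done += k
    return phi / n_permutations


def shap_attribute(
    model_fn,
    instance: np.ndarray,
    background: np.ndarray,
    mode: str = "exact",
    n_permutations: int = 2000,
    seed: int = 0,
    batch_rows: int = 262144,
) -> np.ndarray:
    """Per-feature Shapley attributions of one instance.

    Parameters
    ----------
    model_fn
        Callable mapping an (n, d) array to n scalar scores.
    instance
        The (d,) instance to explain.
    background
        (m, d) background rows defining the interventional expectation.
    mode
        ``"exact"`` (subset enumeration, d <= 12) or ``"sampled"``
        (permutation sampling with ``n_permutations`` draws).
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[1] != x.size:
        raise ValueError("background and instance feature counts differ")
    if mode == "exact":
        if x.size > EXACT_MAX_FEATURES:
            raise ValueError(
                f"exact mode supports at most {EXACT_MAX_FEATURES} features "
                f"(got {x.size}); use mode='sampled'"
            )
        return _exact_shap(model_fn, x, bg, batch_rows)
    if mode == "sampled":
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        return _sampled_shap(model_fn, x, bg, n_permutations, rng, batch_rows)
    raise ValueError(f"unknown mode {mode!r}; expected 'exact' or 'sampled'")


def shap_matrix(
    model_fn,
    X: np.ndarray,
    background: np.ndarray,
    mode: str = "sampled",
    n_permutations: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Attributions for every row of ``X``; returns an (n, d) matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.stack(
        [
            shap_attribute(
                model_fn, X[i], background, mode=mode,
                n_permutations=n_permutations, seed=seed + i,
            )
            for i in range(X.shape[0])
        ]
    )
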