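"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain layer-by-layer / enumeration loops over
the dataclasses, deliberately sharing no code with the package's evaluation
paths.
"""

from __future__ import annotations

import math

import numpy as np


def naive_forward_sequence(model, series):
    """Layer-by-layer recurrent forward pass (pure-python loops)."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    T = series.shape[1]
    states = [[0.0] * len(var.sets) for var in model.inputs]
    preds = []
    for t in range(T):
        # layer 2: recurrent Gaussian memberships
        memb = []
        for i, var in enumerate(model.inputs):
            row = []
            for j, fs in enumerate(var.sets):
                phi = series[i, t] + var.feedback_weights[j] * states[i][j]
                row.append(math.exp(-(((phi - fs.center) / fs.width) ** 2)))
            memb.append(row)
        states = memb
        # layer 3: product AND
        firing = []
        for rule in model.rules:
            f = 1.0
            for i, j in enumerate(rule.precondition):
                f *= memb[i][j]
            firing.append(f)
        # layer 4: per-output sums
        a = [0.0] * len(model.outputs)
        for rule, f in zip(model.rules, firing):
            a[rule.consequent] += f
        # layer 5: width-weighted average
        num = den = 0.0
        for j, node in enumerate(model.outputs):
            num += node.width * node.center * a[j]
            den += node.width * a[j]
        if den < 1e-12:
            k = max(range(len(firing)), key=lambda r: firing[r])
            preds.append(model.outputs[model.rules[k].consequent].center)
        else:
            preds.append(num / den)
    return np.array(preds)


def brute_regulation_score(label_rows, out_labels):
    """Literal transition enumeration of the lag-1 regulation score.

    ``label_rows`` is a list of per-regulator label tuples, ``out_labels``
    the target's labels.  Returns (rs or None, n_ic).
    """
    T = len(out_labels)
    contributions = []
    for t in range(1, T - 1):  # transition t pairs with output transition t+1
        if all(row[t] != row[t - 1] for row in label_rows):
            diff = out_labels[t + 1] - out_labels[t]
            contributions.append(0 if diff == 0 else (1 if diff > 0 else -1))
    if not contributions:
        return None, 0
    return sum(contributions) / len(contributions), len(contributions)


def quadrature_similarity(a, b, n_points: int = 200_001):
    """Overlap/union similarity by fine-grid quadrature."""
    lo = min(a.center - 8 * a.width, b.center - 8 * b.width)
    hi = max(a.center + 8 * a.width, b.center + 8 * b.width)
    x = np.linspace(lo, hi, n_points)
    mu_a = np.exp(-(((x - a.center) / a.width) ** 2))
    mu_b = np.exp(-(((x - b.center) / b.width) ** 2))
    overlap = np.trapezoid(np.minimum(mu_a, mu_b), x)
    union = np.trapezoid(np.maximum(mu_a, mu_b), x)
    return overlap / union
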