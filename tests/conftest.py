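import numpy as np
import pytest

from enfrn.core_network import ENFRNModel, FuzzySet, InputVariable, OutputNode, Rule


def random_model(rng, n_inputs=None, max_sets=4, max_rules=5, max_outputs=3) -> ENFRNModel:
    """Random small valid network (every output node referenced by a rule)."""
    n_inputs = n_inputs or int(rng.integers(1, 4))
    inputs = []
    for _ in range(n_inputs):
        n_sets = int(rng.integers(1, max_sets + 1))
        inputs.append(InputVariable(
            sets=[FuzzySet(float(rng.uniform(0, 1)), float(rng.uniform(0.05, 0.5)))
                  for _ in range(n_sets)],
            feedback_weights=[float(rng.uniform(-0.9, 0.9)) for _ in range(n_sets)],
            state=[0.0] * n_sets,
        ))
    n_out = int(rng.integers(1, max_outputs + 1))
    outputs = [OutputNode(float(rng.uniform(0, 1)), float(rng.uniform(0.05, 0.5)))
               for _ in range(n_out)]
    n_rules = int(rng.integers(n_out, max_rules + n_out))
    rules = []
    for k in range(n_rules):
        precondition = [int(rng.integers(0, len(v.sets))) for v in inputs]
        # first n_out rules cover each output node so none is orphaned
        consequent = k if k < n_out else int(rng.integers(0, n_out))
        rules.append(Rule(precondition, consequent))
    model = ENFRNModel(inputs=inputs, rules=rules, outputs=outputs,
                       input_names=[f"g{i}" for i in range(n_inputs)],
                       output_name="target")
    model.validate()
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pair():
    """A 24-point activator pair: y(t+1) is a monotone map of x(t) + noise."""
    gen = np.random.default_rng(7)
    t = np.arange(24)
    x = 0.5 + 0.45 * np.sin(2 * np.pi * t / 8.0 + 0.8)
    y = np.empty_like(x)
    y[0] = 0.5
    y[1:] = 1.0 / (1.0 + np.exp(-6.0 * 0.8 * (x[:-1] - 0.5)))
    x = np.clip(x + gen.normal(0, 0.03, x.shape), 0.001, 0.999)
    y = np.clip(y + gen.normal(0, 0.03, y.shape), 0.001, 0.999)
    x = (x - x.min()) / np.ptp(x)
    y = (y - y.min()) / np.ptp(y)
    return x, y
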