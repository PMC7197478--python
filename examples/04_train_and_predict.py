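"""Train the naive-Bayes phase predictor and predict held-out cells.

Five quadrature marker genes are fit on 300 labeled training cells; the
model is serialized to JSON, reloaded, and used to predict 100 test cells;
the circular error against the known truth is printed.
"""

import numpy as np

from cyclephase import (
    circular_error,
    predict_phase,
    train_predictor,
)
from cyclephase import simulate as sim
from cyclephase.model_io import deserialize_model, serialize_model

offsets = np.linspace(0, 2 * np.pi, 5, endpoint=False)


def panel(theta, seed):
    rng = np.random.default_rng(seed)
    y = np.array([np.cos(theta + o) for o in offsets])
    return y + rng.normal(0, 0.3, y.shape)


theta_train = sim.simulate_phases(300, seed=5)
theta_test = sim.simulate_phases(100, seed=6)
gene_ids = ["CDK1", "UBE2C", "TOP2A", "H4C5", "H4C3"]

model = train_predictor(panel(theta_train, 7), theta_train, gene_ids)
print("per-gene residual scales:",
      {t.gene_id: round(t.sigma, 3) for t in model.trends})

serialize_model(model, "/tmp/cyclephase_model.json")
model = deserialize_model("/tmp/cyclephase_model.json")

preds = predict_phase(panel(theta_test, 8).T, model)
errs = circular_error(np.array([p.theta_hat for p in preds]), theta_test)
print(f"mean prediction error: {100 * errs.mean():.1f}% of the cycle "
      f"(random guessing would give 25%)")
print(f"K = {model.grid.K} candidate phases evaluated per cell")
# With amplitude-1 trends and sigma = 0.3 noise, five genes pin the phase
# to a few percent of the cycle.
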