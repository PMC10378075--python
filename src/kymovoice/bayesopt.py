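"""Bayesian optimization with a Gaussian-process surrogate.

A compact sequential optimizer for the handful of continuous/integer
hyperparameters tuned here: random exploration for the first trials, then
a Matern-5/2 GP fit to the observed (params, score) pairs and the next
trial placed at the expected-improvement maximum over a random candidate
pool. Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern


@dataclasses.dataclass
class Dimension:
    """One search dimension. ``scale='log'`` searches in log-space;
    ``integer=True`` rounds the decoded value."""

    name: str
    low: float
    high: float
    scale: str = "linear"
    integer: bool = False

    def decode(self, u: float):
        if self.scale == "log":
            val = np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low)))
        else:
            val = self.low + u * (self.high - self.low)
        return int(round(val)) if self.integer else float(val)


def maximize(
    objective,
    dimensions: list[Dimension],
    n_trials: int = 50,
    n_initial: int = 10,
    seed: int = 0,
    candidate_pool: int = 512,
):
    """Maximize ``objective(params_dict)`` over the search space.

    Returns ``(best_params, best_score, history)`` where history is a list
    of (params, score) in evaluation order.
    """
    rng = np.random.default_rng(seed)
    d = len(dimensions)
    n_initial = min(n_initial, n_trials)
    X: list[np.ndarray] = []
    y: list[float] = []
    history = []

    def run(u: np.ndarray) -> None:
        params = {dim.name: dim.decode(u[i]) for i, dim in enumerate(dimensions)}
        score = float(objective(params))
        X.append(u)
        y.append(score)
        history.append((params, score))

    for _ in range(n_initial):
        run(rng.random(d))

    kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.5), nu=2.5)
    for _ in range(n_trials - n_initial):
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-6, normalize_y=True,
            n_restarts_optimizer=1, random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.vstack(X), np.asarray(y))
        cand = rng.random((candidate_pool, d))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(y)
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        run(cand[int(np.argmax(ei))])

    i_best = int(np.argmax(y))
    return history[i_best][0], y[i_best], history
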