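"""Bayesian optimization of the regressor's four hyperparameters.

The search space is the discrete lattice: message-passing iterations 1..10
(step 1), interatomic scaler and dropout 0..0.5 (step 0.05), hidden
dimension 100..3000 (step 50).  A Gaussian-process surrogate (Matern 5/2 on
the unit-cube-scaled lattice) with expected-improvement acquisition proposes
candidates, which are always snapped to the lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = ["SearchSpace", "bayes_optimize"]


@dataclass(frozen=True)
class SearchSpace:
    mp_iterations: tuple = tuple(range(1, 11))
    interatomic_scaler: tuple = tuple(np.round(np.arange(0, 0.51, 0.05), 2))
    dropout: tuple = tuple(np.round(np.arange(0, 0.51, 0.05), 2))
    hidden_dim: tuple = tuple(range(100, 3001, 50))

    @property
    def dims(self) -> dict[str, tuple]:
        return {
            "mp_iterations": self.mp_iterations,
            "interatomic_scaler": self.interatomic_scaler,
            "dropout": self.dropout,
            "hidden_dim": self.hidden_dim,
        }

    def contains(self, config: dict) -> bool:
        return all(
            any(np.isclose(config[k], v) for v in values)
            for k, values in self.dims.items()
        )


def _to_unit(space: SearchSpace, configs: np.ndarray) -> np.ndarray:
    out = np.empty_like(configs, dtype=np.float64)
    for j, values in enumerate(space.dims.values()):
        lo, hi = min(values), max(values)
        out[:, j] = (configs[:, j] - lo) / (hi - lo) if hi > lo else 0.0
    return out


def _sample_lattice(space: SearchSpace, rng: np.random.Generator, n: int) -> np.ndarray:
    cols = [rng.choice(values, size=n) for values in space.dims.values()]
    return np.column_stack(cols).astype(np.float64)


def _neighbors(space: SearchSpace, x: np.ndarray) -> np.ndarray:
    """All lattice points within one step of x in a single dimension."""
    out = []
    values_list = list(space.dims.values())
    for j, values in enumerate(values_list):
        v = np.asarray(values, dtype=np.float64)
        pos = int(np.argmin(np.abs(v - x[j])))
        for step in (-1, 1):
            if 0 <= pos + step < len(v):
                y = x.copy()
                y[j] = v[pos + step]
                out.append(y)
    return np.array(out) if out else np.empty((0, len(values_list)))


def _as_config(space: SearchSpace, x: np.ndarray) -> dict:
    cfg = {}
    for j, (name, values) in enumerate(space.dims.items()):
        v = np.asarray(values, dtype=np.float64)
        snapped = values[int(np.argmin(np.abs(v - x[j])))]
        cfg[name] = int(snapped) if name in ("mp_iterations", "hidden_dim") else float(snapped)
    return cfg


@dataclass
class Trace:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def bayes_optimize(objective, space: SearchSpace | None = None, budget: int = 30,
                   seed: int = 0, n_init: int | None = None,
                   n_candidates: int = 2048) -> tuple[dict, pd.DataFrame]:
    """Minimize `objective(config dict) -> float` over the lattice.

    Starts from a seeded random design, then fits a Gaussian process to the
    evaluations and picks the lattice candidate maximizing expected
    improvement (candidate pool: fresh random lattice samples plus the
    one-step neighborhood of the incumbent).  An objective that raises is
    scored +inf and the search continues.  Returns the best evaluated config
    and the full trace.
    """
    space = space or SearchSpace()
    if budget < 5:
        raise ValueError("budget must be at least 5")
    rng = np.random.default_rng(seed)
    n_init = n_init or min(10, budget)

    evaluated: list[np.ndarray] = []
    scores: list[float] = []
    trace = Trace()

    def run(x: np.ndarray) -> None:
        cfg = _as_config(space, x)
        try:
            val = float(objective(cfg))
        except Exception:
            val = np.inf
        evaluated.append(np.array([cfg[k] for k in space.dims], dtype=np.float64))
        scores.append(val)
        trace.rows.append({**cfg, "objective": val, "iteration": len(scores) - 1})

    seen: set[tuple] = set()

    def dedupe(cands: np.ndarray) -> np.ndarray:
        keep = [x for x in cands if tuple(np.round(x, 6)) not in seen]
        return np.array(keep) if keep else np.empty((0, cands.shape[1]))

    init = _sample_lattice(space, rng, 4 * n_init)
    init = dedupe(init)[:n_init]
    for x in init:
        seen.add(tuple(np.round(x, 6)))
        run(x)

    kernel = 1.0 * Matern(length_scale=0.2 * np.ones(4), nu=2.5)
    while len(scores) < budget:
        finite = np.isfinite(scores)
        y = np.asarray(scores, dtype=np.float64)
        worst = y[finite].max() if finite.any() else 0.0
        y = np.where(finite, y, worst + 1.0)
        x_unit = _to_unit(space, np.vstack(evaluated))
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-8,
                                      normalize_y=True,
                                      n_restarts_optimizer=1,
                                      random_state=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(x_unit, y)

        best_so_far = y.min()
        incumbent = evaluated[int(np.argmin(y))]
        cands = np.vstack([
            _sample_lattice(space, rng, n_candidates),
            _neighbors(space, incumbent),
        ])
        cands = dedupe(cands)
        if len(cands) == 0:
            cands = _sample_lattice(space, rng, n_candidates)
        mu, sd = gp.predict(_to_unit(space, cands), return_std=True)
        sd = np.maximum(sd, 1e-12)
        z = (best_so_far - mu) / sd
        ei = (best_so_far - mu) * norm.cdf(z) + sd * norm.pdf(z)
        x_next = cands[int(np.argmax(ei))]
        seen.add(tuple(np.round(x_next, 6)))
        run(x_next)

    best_idx = int(np.argmin(scores))
    return _as_config(space, evaluated[best_idx]), trace.to_frame()
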