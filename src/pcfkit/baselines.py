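"""Classical fingerprint baselines: {ANN, RF, SVM} x {MACCS, PATH, ECFP4}.

Each baseline maps a fixed fingerprint to the PCF target with a standard
scikit-learn regressor, tuned by 5-fold grid search on cross-validated RMSE
and refit on the full training set.  These nine models are the reference
points the transformer is benchmarked against.
"""

from __future__ import annotations

import io
import json
import pickle
import zipfile
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .datakit import Dataset
from .featurize import FINGERPRINT_KINDS, compute_fingerprint

__all__ = ["BaselineSpec", "BaselineModel", "default_grid", "train_baseline",
           "predict_baseline", "all_baseline_specs"]

ALGORITHMS = ("ANN", "RF", "SVM")


def default_grid(algorithm: str) -> dict[str, list]:
    """Small honest grids; the emphasis is the protocol, not exhaustive
    tuning.  RF uses sqrt-feature subsampling, the usual choice for
    2048-bit fingerprints."""
    if algorithm == "RF":
        return {"n_estimators": [100, 300], "max_depth": [None, 10]}
    if algorithm == "SVM":
        return {"C": [1.0, 10.0, 100.0], "epsilon": [0.1, 0.5]}
    if algorithm == "ANN":
        return {"hidden_layer_sizes": [(100,)], "alpha": [1e-4, 1e-2]}
    raise ValueError(f"unknown algorithm: {algorithm!r}")


@dataclass
class BaselineSpec:
    algorithm: str
    fingerprint: str
    grid: dict[str, list] = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.fingerprint not in FINGERPRINT_KINDS:
            raise ValueError(f"fingerprint must be one of {FINGERPRINT_KINDS}")
        if not self.grid:
            self.grid = default_grid(self.algorithm)
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid values must be non-empty")
        if self.cv_folds != 5:
            raise ValueError("cross-validation uses 5 folds")

    @property
    def name(self) -> str:
        return f"{self.fingerprint}-{self.algorithm}"


def all_baseline_specs(seed: int = 0) -> list[BaselineSpec]:
    return [BaselineSpec(algorithm=a, fingerprint=f, seed=seed)
            for f, a in product(FINGERPRINT_KINDS, ALGORITHMS)]


def _make_estimator(spec: BaselineSpec, point: dict):
    if spec.algorithm == "RF":
        return RandomForestRegressor(random_state=spec.seed, max_features="sqrt",
                                     n_jobs=1, **point)
    if spec.algorithm == "SVM":
        return SVR(kernel="rbf", **point)
    return MLPRegressor(random_state=spec.seed, max_iter=300, solver="adam",
                        early_stopping=False, **point)


def _fingerprint_matrix(smiles: list[str], kind: str) -> np.ndarray:
    return np.vstack([compute_fingerprint(s, kind).bits for s in smiles]).astype(np.float64)


@dataclass
class BaselineModel:
    spec: BaselineSpec
    estimator: object
    chosen: dict
    cv_rmse: float

    @property
    def name(self) -> str:
        return self.spec.name

    def predict(self, smiles: str) -> float:
        x = compute_fingerprint(smiles, self.spec.fingerprint).bits.astype(np.float64)
        return float(self.estimator.predict(x[None, :])[0])

    def save(self, path) -> None:
        meta = {
            "format": "pcfkit-baseline-checkpoint-1",
            "algorithm": self.spec.algorithm,
            "fingerprint": self.spec.fingerprint,
            "chosen": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.chosen.items()},
            "cv_rmse": self.cv_rmse,
            "seed": self.spec.seed,
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            zf.writestr("estimator.pkl", pickle.dumps(self.estimator))

    @classmethod
    def load(cls, path) -> "BaselineModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            est = pickle.loads(zf.read("estimator.pkl"))
        chosen = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in meta["chosen"].items()}
        spec = BaselineSpec(algorithm=meta["algorithm"],
                            fingerprint=meta["fingerprint"],
                            seed=meta["seed"])
        return cls(spec=spec, estimator=est, chosen=chosen, cv_rmse=meta["cv_rmse"])


def train_baseline(train_ds: Dataset, spec: BaselineSpec) -> BaselineModel:
    """5-fold grid search on cross-validated RMSE, ties broken by grid
    order; the winner is refit on the full training set."""
    if len(train_ds) < 25:
        raise ValueError(f"need at least 25 records (5 per fold), got {len(train_ds)}")
    y = train_ds.targets
    if np.allclose(y, y[0]):
        raise ValueError("zero-variance target: every record has the same PCF")
    x = _fingerprint_matrix(train_ds.smiles, spec.fingerprint)

    keys = list(spec.grid)
    points = [dict(zip(keys, combo)) for combo in product(*(spec.grid[k] for k in keys))]
    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(kf.split(x))

    best: tuple[float, dict] | None = None
    for point in points:
        sq_errors = []
        for tr_idx, va_idx in folds:
            est = _make_estimator(spec, point)
            est.fit(x[tr_idx], y[tr_idx])
            resid = est.predict(x[va_idx]) - y[va_idx]
            sq_errors.append(np.mean(resid ** 2))
        score = float(np.sqrt(np.mean(sq_errors)))
        if best is None or score < best[0]:  # strict: ties keep earlier point
            best = (score, point)

    final = _make_estimator(spec, best[1])
    final.fit(x, y)
    return BaselineModel(spec=spec, estimator=final, chosen=best[1], cv_rmse=best[0])


def predict_baseline(model: BaselineModel, smiles: str) -> float:
    return model.predict(smiles)
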