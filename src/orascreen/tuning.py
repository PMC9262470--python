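"""DBN hyperparameter tuning by the enhanced grasshopper optimizer.

The search space is a 5-dimensional box decoded into a training
configuration:

    [log10 learning_rate in (-4, -1);  hidden1 in [16, 256] (int);
     hidden2 in [8, 128] (int);  epochs_pretrain in [5, 50] (int);
     batch_size in [8, 64] (int)]

Fitness of a position is 1 - validation accuracy of a DBN trained with
the decoded configuration on a seeded stratified 80/20 split of the
training portion (lower is better).  The optimizer never sees test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .dbn import DBNClassifier, TrainConfig
from .egoa import Bounds, GOAConfig, OptimizeResult, egoa_optimize

__all__ = [
    "default_search_space",
    "decode_position",
    "tune_dbn",
    "TuneResult",
    "EGOATunedDBN",
]

SEARCH_NAMES = ("log10_learning_rate", "hidden1", "hidden2", "epochs_pretrain", "batch_size")


def default_search_space() -> Bounds:
    return Bounds(
        lower=np.array([-4.0, 16.0, 8.0, 5.0, 8.0]),
        upper=np.array([-1.0, 256.0, 128.0, 50.0, 64.0]),
        integer_mask=np.array([False, True, True, True, True]),
    )


def decode_position(
    position: np.ndarray,
    bounds: Bounds,
    seed: int,
    epochs_finetune: int = 30,
) -> tuple[TrainConfig, tuple[int, int]]:
    """Decode a continuous position into (TrainConfig, architecture)."""
    z = bounds.decode(np.asarray(position, dtype=float))
    config = TrainConfig(
        learning_rate=float(10.0 ** z[0]),
        batch_size=int(z[4]),
        cd_steps=1,
        epochs_pretrain=int(z[3]),
        epochs_finetune=epochs_finetune,
        seed=seed,
    )
    return config, (int(z[1]), int(z[2]))


@dataclass
class TuneResult:
    config: TrainConfig
    architecture: tuple[int, int]
    best_fitness: float
    history: list[float]
    n_evaluations: int


def tune_dbn(
    features: np.ndarray,
    labels,
    search_space: Bounds | None = None,
    goa_config: GOAConfig | None = None,
    epochs_finetune: int = 30,
    train_seed: int = 0,
) -> TuneResult:
    """Pick DBN hyperparameters minimising inner-validation error.

    ``features`` must already be min-max scaled to [0, 1].  The inner
    80/20 split is stratified and fixed by ``goa_config.seed`` so fitness
    is a deterministic function of position.
    """
    bounds = search_space or default_search_space()
    goa_config = goa_config or GOAConfig(population=8, max_iterations=10)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("tuning needs >= 2 samples of each class")
    X_tr, X_val, y_tr, y_val = train_test_split(
        features,
        labels,
        test_size=0.2,
        random_state=goa_config.seed % (2**32),
        stratify=labels,
    )
    if np.unique(y_val).size < classes.size:
        raise ValueError("a class is missing from the inner validation split")

    def fitness(position: np.ndarray) -> float:
        config, arch = decode_position(position, bounds, train_seed, epochs_finetune)
        clf = DBNClassifier(
            hidden_layer_sizes=arch,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            cd_steps=config.cd_steps,
            epochs_pretrain=config.epochs_pretrain,
            epochs_finetune=config.epochs_finetune,
            random_state=config.seed,
        )
        clf.fit(X_tr, y_tr)
        return 1.0 - clf.score(X_val, y_val)

    result: OptimizeResult = egoa_optimize(fitness, bounds, goa_config)
    config, arch = decode_position(result.best_position, bounds, train_seed, epochs_finetune)
    return TuneResult(
        config=config,
        architecture=arch,
        best_fitness=result.best_fitness,
        history=result.history,
        n_evaluations=result.n_evaluations,
    )


class EGOATunedDBN:
    """Classifier that tunes a DBN with the grasshopper optimizer, then refits.

    ``fit`` runs the swarm search on the training data (inner stratified
    validation split), decodes the best position, retrains a final
    :class:`DBNClassifier` on all training rows, and exposes it through
    the usual predict/predict_proba/score surface.

    Fitted attributes: ``tune_result_``, ``model_``, ``classes_``.
    """

    def __init__(
        self,
        search_space: Bounds | None = None,
        population: int = 8,
        max_iterations: int = 10,
        epochs_finetune: int = 30,
        random_state: int = 0,
    ):
        self.search_space = search_space
        self.population = population
        self.max_iterations = max_iterations
        self.epochs_finetune = epochs_finetune
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "search_space": self.search_space,
            "population": self.population,
            "max_iterations": self.max_iterations,
            "epochs_finetune": self.epochs_finetune,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "EGOATunedDBN":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y) -> "EGOATunedDBN":
        goa_config = GOAConfig(
            population=self.population,
            max_iterations=self.max_iterations,
            seed=self.random_state,
        )
        self.tune_result_ = tune_dbn(
            X,
            y,
            search_space=self.search_space,
            goa_config=goa_config,
            epochs_finetune=self.epochs_finetune,
            train_seed=self.random_state,
        )
        cfg = self.tune_result_.config
        self.model_ = DBNClassifier(
            hidden_layer_sizes=self.tune_result_.architecture,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            cd_steps=cfg.cd_steps,
            epochs_pretrain=cfg.epochs_pretrain,
            epochs_finetune=cfg.epochs_finetune,
            random_state=cfg.seed,
        ).fit(X, y)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)

    def score(self, X: np.ndarray, y) -> float:
        return self.model_.score(X, y)
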