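"""Penalized-regression prediction indices.

Four families of indices drive the simulator, each with its own covariate
timing contract:

* ``incidence`` — annual onset/occurrence of each disease attribute from
  previous-year health status, disease history, treatments, complications;
* ``treatment_use`` — hydroxyurea / transfusion use from current persistent
  status, history, and previous-year treatments and complications;
* ``complication`` — treatment complications from current status and
  treatment plus history and previous-year complications;
* ``utilization`` — annual utilization counts (log-link) from all
  current-year blocks.

Binary outcomes are penalized logistic regressions (lasso or elastic net);
utilization counts are L2-penalized Poisson regressions.  The sample is
split at the beneficiary level into training (50%) and two test sets (25%
each); penalty strength can be chosen by grouped k-fold cross-validation on
the training part; parameter uncertainty comes from beneficiary-level
bootstrap refits on the first test set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, PoissonRegressor
from sklearn.metrics import log_loss

from scdsim.features import (
    TREATMENT_FLAGS,
    UTILIZATION_CATEGORIES,
    design_columns,
    panel_blocks,
)
from scdsim.registry import AttributeRegistry, Persistence
from scdsim.rng import substream

__all__ = [
    "Design",
    "SplitSpec",
    "PenaltySpec",
    "PredictionIndex",
    "BootstrapSet",
    "build_design",
    "split_sample",
    "fit_index",
    "predict_probability",
    "bootstrap_uncertainty",
    "save_indices",
    "load_indices",
]


@dataclass
class Design:
    """A fitting-ready design: covariates, outcome, beneficiary groups."""

    outcome_name: str
    family: str
    X: pd.DataFrame
    y: pd.Series
    groups: pd.Series  # beneficiary id per row

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class PenaltySpec:
    """Penalty configuration: fixed strength, or a CV grid.

    ``strength`` is the regularization weight (sklearn ``C = 1/strength``
    for logistic models, ``alpha = strength`` for Poisson).  When
    ``strength_grid`` is given instead, the strength is chosen by grouped
    k-fold cross-validation on the training data.
    """

    kind: str = "elastic_net"  # or "lasso"
    l1_ratio: float = 0.5
    strength: float | None = 0.01
    strength_grid: tuple[float, ...] | None = None
    cv_folds: int = 5
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-4

    def effective_l1_ratio(self) -> float:
        return 1.0 if self.kind == "lasso" else self.l1_ratio


@dataclass
class PredictionIndex:
    """A fitted index: named coefficients plus its covariate contract."""

    outcome_name: str
    family: str
    link: str  # "logit" or "log"
    intercept: float
    coefficients: dict[str, float]
    penalty: dict = field(default_factory=dict)

    @property
    def feature_list(self) -> list[str]:
        return list(self.coefficients)

    def weights(self) -> np.ndarray:
        return np.fromiter(self.coefficients.values(), dtype=float,
                           count=len(self.coefficients))

    def linear_predictor(self, x: np.ndarray) -> float:
        return float(self.intercept + self.weights() @ x)

    def shifted(self, delta: float) -> "PredictionIndex":
        """Copy with the intercept shifted by ``delta`` (calibration)."""
        return PredictionIndex(
            self.outcome_name, self.family, self.link,
            self.intercept + delta, dict(self.coefficients), dict(self.penalty),
        )


@dataclass
class BootstrapSet:
    outcome_name: str
    feature_list: list[str]
    intercepts: np.ndarray  # (n_replicates,)
    coefficients: np.ndarray  # (n_replicates, n_features)

    @property
    def n_replicates(self) -> int:
        return len(self.intercepts)


# ---------------------------------------------------------------------------
# design construction


def _outcome_column(outcome_name: str, family: str, registry: AttributeRegistry) -> str:
    if family == "incidence":
        names = {a.name for a in registry.disease_attributes}
        if outcome_name not in names:
            raise ValueError(
                f"outcome {outcome_name!r} is not a disease attribute "
                f"(family incidence)"
            )
        return f"attr_{outcome_name}"
    if family == "treatment_use":
        if outcome_name not in TREATMENT_FLAGS:
            raise ValueError(f"outcome {outcome_name!r} is not a treatment flag")
        return f"tx_{outcome_name}"
    if family == "complication":
        comp = {a.name for a in registry.complication_attributes}
        if outcome_name not in comp:
            raise ValueError(f"outcome {outcome_name!r} is not a complication")
        return f"attr_{outcome_name}"
    if family == "utilization":
        if outcome_name not in UTILIZATION_CATEGORIES:
            raise ValueError(
                f"outcome {outcome_name!r} is not a utilization category"
            )
        return f"util_{outcome_name}"
    raise ValueError(f"unknown family {family!r}")


def build_design(
    panel: pd.DataFrame,
    outcome_name: str,
    family: str,
    registry: AttributeRegistry,
    blocks: pd.DataFrame | None = None,
) -> Design:
    """One row per eligible person-year with the family's covariate blocks.

    Lagged families (incidence, treatment_use, complication) keep only rows
    with an immediately preceding observed year.  For absorbing outcomes
    (chronic disorders, chronic-persistence complications) person-years
    where the condition is already present are excluded from that outcome's
    design.  ``blocks`` may be passed to reuse the precomputed covariate
    blocks across outcomes.
    """
    ycol = _outcome_column(outcome_name, family, registry)
    if blocks is None:
        blocks = panel_blocks(panel, registry)
    df = blocks
    if family != "utilization":
        df = df[df["has_lag"]]
    if family in ("incidence", "complication"):
        attr = registry.attributes.get(outcome_name)
        if attr is not None and attr.persistence is Persistence.CHRONIC:
            df = df[df[f"prevflag__{outcome_name}"] == 0.0]
    X = design_columns(df, family, registry)
    y = df[ycol].astype(float if family == "utilization" else int)
    return Design(outcome_name, family, X, y, df["beneficiary_id"])


def split_sample(
    panel: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Beneficiary-level partition into train / test1 / test2 panels."""
    spec = spec or SplitSpec()
    bids = np.sort(panel["beneficiary_id"].unique())
    if len(bids) < 4:
        raise ValueError("need at least 4 beneficiaries to split")
    rng = substream(spec.seed, "split")
    rng.shuffle(bids)
    n = len(bids)
    cuts = np.round(np.cumsum(spec.fractions) * n).astype(int)
    parts = np.split(bids, cuts[:-1])
    return tuple(
        panel[panel["beneficiary_id"].isin(set(p))].copy() for p in parts
    )


# ---------------------------------------------------------------------------
# fitting


def _check_binary(design: Design) -> None:
    values = design.y.to_numpy()
    if values.min() == values.max():
        raise ValueError(
            f"degenerate outcome {design.outcome_name!r}: all values are "
            f"{values.min()}"
        )


def _fit_logistic(X, y, spec: PenaltySpec, strength: float) -> LogisticRegression:
    model = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        C=1.0 / max(strength, 1e-12),
        l1_ratio=spec.effective_l1_ratio(),
        max_iter=spec.max_iter,
        tol=spec.tol,
        random_state=0,  # saga shuffles internally; pin for determinism
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def _cv_strength(design: Design, spec: PenaltySpec) -> float:
    """Grouped k-fold CV over the strength grid (log-loss, binary only)."""
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    groups = design.groups.to_numpy()
    n_folds = min(spec.cv_folds, len(np.unique(groups)))
    # deterministic fold assignment: shuffle groups with the spec seed
    rng = substream(spec.seed, "cv", design.outcome_name)
    uniq = np.sort(np.unique(groups))
    rng.shuffle(uniq)
    fold_of = {g: i % n_folds for i, g in enumerate(uniq)}
    folds = np.array([fold_of[g] for g in groups])
    best, best_loss = None, np.inf
    for strength in spec.strength_grid:
        losses = []
        for k in range(n_folds):
            tr, te = folds != k, folds == k
            if len(np.unique(y[tr])) < 2 or te.sum() == 0:
                continue
            m = _fit_logistic(X[tr], y[tr], spec, strength)
            p = m.predict_proba(X[te])[:, 1]
            losses.append(log_loss(y[te], p, labels=[0, 1]))
        loss = float(np.mean(losses)) if losses else np.inf
        if loss < best_loss:
            best, best_loss = strength, loss
    return best if best is not None else spec.strength_grid[0]


def fit_index(design: Design, penalty_spec: PenaltySpec | None = None) -> PredictionIndex:
    """Penalized fit for one outcome; deterministic given the spec seed."""
    spec = penalty_spec or PenaltySpec()
    names = list(design.X.columns)
    if design.family == "utilization":
        strength = spec.strength if spec.strength is not None else 1e-4
        model = PoissonRegressor(alpha=strength, max_iter=spec.max_iter, tol=spec.tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(design.X.to_numpy(), design.y.to_numpy())
        return PredictionIndex(
            design.outcome_name, design.family, "log",
            float(model.intercept_),
            dict(zip(names, model.coef_.tolist())),
            {"kind": "ridge_poisson", "strength": strength},
        )
    _check_binary(design)
    if spec.strength_grid is not None:
        strength = _cv_strength(design, spec)
    else:
        strength = spec.strength
    model = _fit_logistic(design.X.to_numpy(), design.y.to_numpy(), spec, strength)
    return PredictionIndex(
        design.outcome_name, design.family, "logit",
        float(model.intercept_[0]),
        dict(zip(names, model.coef_[0].tolist())),
        {
            "kind": spec.kind,
            "l1_ratio": spec.effective_l1_ratio(),
            "strength": float(strength),
        },
    )


def predict_probability(index: PredictionIndex, covariates) -> float:
    """Inverse-link prediction for one covariate vector.

    ``covariates`` may be a mapping/Series keyed by feature name or an
    ndarray already in the index's feature order.  A missing named
    covariate raises ``KeyError`` naming it.
    """
    if isinstance(covariates, np.ndarray):
        x = covariates
    else:
        try:
            x = np.array([covariates[name] for name in index.coefficients], dtype=float)
        except KeyError as exc:
            raise KeyError(f"missing covariate {exc.args[0]!r}") from None
    eta = index.linear_predictor(x)
    if index.link == "logit":
        return float(expit(eta))
    return float(np.exp(eta))


def bootstrap_uncertainty(
    design: Design,
    penalty_spec: PenaltySpec,
    n_replicates: int,
    seed: int = 0,
    max_retries: int = 10,
) -> BootstrapSet:
    """Beneficiary-level bootstrap refits (out-of-sample uncertainty).

    Each replicate resamples beneficiaries with replacement and refits at
    the point estimate's penalty strength.  Replicates with a degenerate
    outcome are redrawn up to ``max_retries`` times (with a warning).
    """
    names = list(design.X.columns)
    if n_replicates == 0:
        return BootstrapSet(design.outcome_name, names,
                            np.empty(0), np.empty((0, len(names))))
    _check_binary(design)
    rng = substream(seed, "bootstrap", design.outcome_name)
    bids = np.sort(design.groups.unique())
    rows_of = {b: np.flatnonzero(design.groups.to_numpy() == b) for b in bids}
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    strength = penalty_spec.strength if penalty_spec.strength is not None else 0.01
    intercepts, coefs = [], []
    for _ in range(n_replicates):
        for attempt in range(max_retries + 1):
            sample = rng.choice(bids, size=len(bids), replace=True)
            rows = np.concatenate([rows_of[b] for b in sample])
            if len(np.unique(y[rows])) == 2:
                break
            if attempt == max_retries:
                raise RuntimeError(
                    f"bootstrap for {design.outcome_name!r}: degenerate "
                    f"resamples after {max_retries} retries"
                )
            warnings.warn(
                f"degenerate bootstrap resample for {design.outcome_name!r}; redrawing"
            )
        m = _fit_logistic(X[rows], y[rows], penalty_spec, strength)
        intercepts.append(float(m.intercept_[0]))
        coefs.append(m.coef_[0])
    return BootstrapSet(
        design.outcome_name, names, np.array(intercepts), np.array(coefs)
    )


# ---------------------------------------------------------------------------
# serialization (indices.json)


def save_indices(indices: dict[str, PredictionIndex], path: str | Path) -> None:
    payload = {
        name: {
            "outcome": ix.outcome_name,
            "family": ix.family,
            "link": ix.link,
            "intercept": ix.intercept,
            "coefficients": ix.coefficients,
            "penalty": ix.penalty,
        }
        for name, ix in indices.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_indices(path: str | Path) -> dict[str, PredictionIndex]:
    payload = json.loads(Path(path).read_text())
    return {
        name: PredictionIndex(
            entry["outcome"], entry["family"], entry["link"],
            entry["intercept"], entry["coefficients"], entry.get("penalty", {}),
        )
        for name, entry in payload.items()
    }


def save_bootstrap(sets: dict[str, BootstrapSet], path: str | Path) -> None:
    payload = {
        name: {
            "outcome": b.outcome_name,
            "features": b.feature_list,
            "intercepts": b.intercepts.tolist(),
            "coefficients": b.coefficients.tolist(),
        }
        for name, b in sets.items()
    }
    Path(path).write_text(json.dumps(payload))


def load_bootstrap(path: str | Path) -> dict[str, BootstrapSet]:
    payload = json.loads(Path(path).read_text())
    return {
        name: BootstrapSet(
            entry["outcome"], entry["features"],
            np.asarray(entry["intercepts"], dtype=float),
            np.asarray(entry["coefficients"], dtype=float),
        )
        for name, entry in payload.items()
    }
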