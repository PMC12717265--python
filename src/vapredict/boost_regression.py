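"""Gradient-boosted regression of visual acuity from tabular features.

The observation table holds one row per eye and optical condition:
uncorrected (coefficients as measured), corrected (second-order Zernike
terms zeroed) and, for dominant eyes, nine trial-lens defocus conditions
from -3.00 to +1.00 D in 0.50 D steps applied over the corrected baseline.
Features are a leading subset of OSA Zernike coefficients (5, 9, 14 or all
36), age and, optionally, a gated amplitude of accommodation: since
accommodation can only compensate hyperopic (negative trial-lens) defocus,
the subject's AA enters a row only when the condition's defocus is
negative and is zero otherwise; uncorrected rows gate on the sign of the
eye's spherical equivalent.

Least-squares boosting (LSBoost) is implemented from scratch: a constant
initial fit (the target mean) followed by CART regression trees fitted to
the current residuals, each added with shrinkage ``nu``. XGBoost is wrapped
behind the same fit/predict/importance surface as a faster alternative.

Error metrics follow chart conventions: absolute errors in logMAR, mode on
the 0.02-logMAR letter grid (ties broken toward the smaller error), and an
optional one-pass 3-sigma outlier screen on the test errors.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .wavefront_optics import (apply_correction, apply_defocus_condition,
                               spherical_equivalent, ZernikeSet, N_COEFFS)

__all__ = [
    "DEFOCUS_LEVELS",
    "ZERNIKE_SUBSETS",
    "build_observation_table",
    "split_train_test",
    "make_features",
    "RegressionTree",
    "fit_tree",
    "LSBoostModel",
    "fit_lsboost",
    "XGBoostModel",
    "fit_xgboost",
    "MetricsReport",
    "evaluate",
    "remove_outliers_3sigma",
    "removal_percentage",
    "percent_change",
    "feature_importance",
    "stratify",
    "AGE_BINS",
]

#: Defocus-curve trial-lens powers in diopters.
DEFOCUS_LEVELS = tuple(round(-3.0 + 0.5 * k, 2) for k in range(9))

#: Evaluated leading Zernike subsets (OSA indices: z1..z5, z1..z9, z1..z14, z0..z35).
ZERNIKE_SUBSETS = (5, 9, 14, 36)

AGE_BINS = ((30, 40), (41, 44), (45, 50), (51, 55), (56, 60), (61, 65))

_Z_COLS = [f"z{j}" for j in range(N_COEFFS)]


def defocus_column(level: float) -> str:
    return f"va_defocus_{level:+.2f}"


# ---------------------------------------------------------------------------
# Observation-table construction


def build_observation_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Expand an eye-level cohort into per-condition observations.

    Emits one row per (eye, uncorrected), (eye, corrected) and, for each
    dominant eye, one row per defocus level; rows whose VA is missing are
    dropped. Returns a DataFrame with condition-modified Zernike columns,
    ``age``, ``aa_gated``, ``condition``, ``delta_d``, ``va`` and ids, and
    attrs ``n_built`` / ``n_retained``.
    """
    rows = []
    n_built = 0
    built_by_condition = {"uncorrected": 0, "corrected": 0, "defocus": 0}
    for _, eye in cohort.iterrows():
        if "dominant" not in eye or pd.isna(eye["dominant"]):
            warnings.warn(f"eye {eye.get('subject_id')}/{eye.get('eye')} lacks "
                          "a dominant-eye flag; skipped", stacklevel=2)
            continue
        z = np.array([eye[c] for c in _Z_COLS], dtype=float)
        zset = ZernikeSet(z, pupil_radius=float(eye.get("pupil_radius_mm", 1.5)))
        aa = float(eye.get("aa_d", 0.0))
        se = spherical_equivalent(float(eye["sphere_d"]), float(eye["cylinder_d"]))
        base = {
            "subject_id": eye.get("subject_id", ""),
            "eye": eye.get("eye", ""),
            "age": float(eye["age"]),
            "sphere_d": float(eye["sphere_d"]),
            "cylinder_d": float(eye["cylinder_d"]),
        }

        def emit(zs: ZernikeSet, condition: str, delta_d: float,
                 aa_gated: float, va) -> None:
            nonlocal n_built
            n_built += 1
            built_by_condition[condition] += 1
            if va is None or (isinstance(va, float) and math.isnan(va)) or pd.isna(va):
                return
            row = dict(base)
            row.update({f"z{j}": zs.coeffs[j] for j in range(N_COEFFS)})
            row.update(condition=condition, delta_d=delta_d,
                       aa_gated=aa_gated, va=float(va))
            rows.append(row)

        emit(zset, "uncorrected", 0.0, aa if se < 0 else 0.0,
             eye.get("va_uncorrected_logmar"))
        emit(apply_correction(zset), "corrected", 0.0, 0.0,
             eye.get("va_corrected_logmar"))
        if int(eye["dominant"]):
            for level in DEFOCUS_LEVELS:
                emit(apply_defocus_condition(zset, level), "defocus", level,
                     aa if level < 0 else 0.0, eye.get(defocus_column(level)))
    table = pd.DataFrame(rows)
    table.attrs["n_built"] = n_built
    table.attrs["n_built_by_condition"] = built_by_condition
    table.attrs["n_retained"] = len(table)
    return table


def split_train_test(table: pd.DataFrame, fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform partition; the test set takes floor((1-fraction) n) rows."""
    if len(table) == 0:
        raise ValueError("table is empty")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_test = int(n * (1.0 - fraction))
    idx = rng.permutation(n)
    test = table.iloc[idx[:n_test]]
    train = table.iloc[idx[n_test:]]
    return train, test


def make_features(table: pd.DataFrame, k_zernike: int = 9,
                  use_age: bool = True, use_aa: bool = False):
    """Feature matrix (X, y, names) for a Zernike subset.

    ``k_zernike`` of 36 uses z0..z35; the smaller subsets use z1..zk,
    matching how the leading coefficients were counted when the subsets
    were evaluated.
    """
    if k_zernike not in ZERNIKE_SUBSETS:
        raise ValueError(f"k_zernike must be one of {ZERNIKE_SUBSETS}")
    if k_zernike == 36:
        names = [f"z{j}" for j in range(36)]
    else:
        names = [f"z{j}" for j in range(1, k_zernike + 1)]
    if use_age:
        names.append("age")
    if use_aa:
        names.append("aa_gated")
    X = table[names].to_numpy(dtype=float)
    y = table["va"].to_numpy(dtype=float)
    return X, y, names


# ---------------------------------------------------------------------------
# CART regression tree (greedy variance-reduction splitting)


@dataclass
class RegressionTree:
    """Axis-aligned binary regression tree; leaves predict the training mean."""

    node: dict
    max_depth: int
    min_leaf: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        self._predict_into(self.node, X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, node, X, idx, out):
        if "value" in node:
            out[idx] = node["value"]
            return
        go_left = X[idx, node["feature"]] <= node["threshold"]
        self._predict_into(node["left"], X, idx[go_left], out)
        self._predict_into(node["right"], X, idx[~go_left], out)

    def gains_by_feature(self, n_features: int) -> np.ndarray:
        g = np.zeros(n_features)

        def walk(node):
            if "value" in node:
                return
            g[node["feature"]] += node["gain"]
            walk(node["left"])
            walk(node["right"])

        walk(self.node)
        return g


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (feature, threshold, gain) by exhaustive scan with prefix sums."""
    n = len(y)
    total_sse = float(np.sum(y * y) - np.sum(y) ** 2 / n)
    best = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs, ys = X[order, f], y[order]
        s1 = np.cumsum(ys)
        s2 = np.cumsum(ys * ys)
        i = np.arange(min_leaf, n - min_leaf + 1)
        if len(i) == 0:
            continue
        i = i[xs[i - 1] < xs[i]]  # split only between distinct feature values
        if len(i) == 0:
            continue
        left_sse = s2[i - 1] - s1[i - 1] ** 2 / i
        right_n = n - i
        right_s1 = s1[-1] - s1[i - 1]
        right_s2 = s2[-1] - s2[i - 1]
        right_sse = right_s2 - right_s1 ** 2 / right_n
        gain = total_sse - (left_sse + right_sse)
        k = int(np.argmax(gain))
        if gain[k] > 1e-12 and (best is None or gain[k] > best[2] + 1e-15):
            thr = 0.5 * (xs[i[k] - 1] + xs[i[k]])
            best = (f, float(thr), float(gain[k]))
    return best


def _grow(X, y, depth, max_depth, min_leaf):
    if depth >= max_depth or len(y) < 2 * min_leaf:
        return {"value": float(np.mean(y))}
    split = _best_split(X, y, min_leaf)
    if split is None:
        return {"value": float(np.mean(y))}
    f, thr, gain = split
    left = X[:, f] <= thr
    return {
        "feature": f, "threshold": thr, "gain": gain,
        "left": _grow(X[left], y[left], depth + 1, max_depth, min_leaf),
        "right": _grow(X[~left], y[~left], depth + 1, max_depth, min_leaf),
    }


def fit_tree(X: np.ndarray, y: np.ndarray, max_depth: int = 4,
             min_leaf: int = 5) -> RegressionTree:
    """Greedy CART fit minimizing within-node squared error.

    At each node every (feature, threshold) pair is scanned and the split
    with the largest squared-error reduction is taken; growth stops at
    ``max_depth``, when a child would fall below ``min_leaf`` samples, or
    when no split reduces the error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(y) < 1:
        raise ValueError("need at least one sample")
    return RegressionTree(node=_grow(X, y, 0, max_depth, min_leaf),
                          max_depth=max_depth, min_leaf=min_leaf)


# ---------------------------------------------------------------------------
# LSBoost


@dataclass
class LSBoostModel:
    """Least-squares boosting ensemble: F(x) = F0 + sum nu * tree_m(x)."""

    f0: float
    trees: list = field(default_factory=list)
    nu: float = 0.1
    n_features: int = 0
    feature_names: list = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.n_features and X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        pred = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            pred += self.nu * tree.predict(X)
        return pred

    def to_json(self) -> str:
        return json.dumps({
            "f0": self.f0, "nu": self.nu, "n_features": self.n_features,
            "feature_names": self.feature_names, "hyperparams": self.hyperparams,
            "trees": [{"node": t.node, "max_depth": t.max_depth,
                       "min_leaf": t.min_leaf} for t in self.trees],
        })

    @classmethod
    def from_json(cls, text: str) -> "LSBoostModel":
        d = json.loads(text)
        trees = [RegressionTree(**t) for t in d.pop("trees")]
        return cls(trees=trees, **d)


def fit_lsboost(X: np.ndarray, y: np.ndarray, n_stages: int = 300,
                nu: float = 0.1, max_depth: int = 4, min_leaf: int = 5,
                seed: int = 0, feature_names=None) -> LSBoostModel:
    """Fit LSBoost: stage m fits a CART tree to the residuals of F_{m-1}.

    F0 is the target mean; each stage's tree enters with shrinkage ``nu``.
    The training squared error is non-increasing in the stage count. The
    fit itself is deterministic; ``seed`` is recorded for provenance.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if not 0 < nu <= 1:
        raise ValueError("nu must be in (0, 1]")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    model = LSBoostModel(
        f0=float(np.mean(y)), nu=nu, n_features=X.shape[1],
        feature_names=list(feature_names) if feature_names is not None else [],
        hyperparams={"n_stages": n_stages, "nu": nu, "max_depth": max_depth,
                     "min_leaf": min_leaf, "seed": seed})
    current = np.full(len(y), model.f0)
    for _ in range(n_stages):
        residual = y - current
        tree = fit_tree(X, residual, max_depth=max_depth, min_leaf=min_leaf)
        model.trees.append(tree)
        current = current + nu * tree.predict(X)
    return model


# ---------------------------------------------------------------------------
# XGBoost wrapper


class XGBoostModel:
    """Thin adapter exposing the same predict/importance surface."""

    def __init__(self, booster, feature_names, hyperparams):
        self.booster = booster
        self.feature_names = list(feature_names) if feature_names else []
        self.hyperparams = hyperparams

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.booster.predict(np.atleast_2d(X)), dtype=float)


def fit_xgboost(X: np.ndarray, y: np.ndarray, n_estimators: int = 300,
                learning_rate: float = 0.1, max_depth: int = 4,
                seed: int = 0, feature_names=None, **params) -> XGBoostModel:
    """Fit an XGBoost regressor behind the common model surface."""
    try:
        from xgboost import XGBRegressor
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("xgboost is not installed; the XGBoost engine is "
                           "unavailable (use the lsboost engine)") from exc
    hp = {"n_estimators": n_estimators, "learning_rate": learning_rate,
          "max_depth": max_depth, "random_state": seed, "n_jobs": 1, **params}
    reg = XGBRegressor(objective="reg:squarederror", **hp)
    reg.fit(np.atleast_2d(np.asarray(X, dtype=float)),
            np.asarray(y, dtype=float))
    return XGBoostModel(reg, feature_names, hp)


def feature_importance(model) -> np.ndarray:
    """Per-feature importance, normalized to sum to 1.

    For LSBoost: total squared-error reduction attributed to each feature
    over every split of every stage. For the wrapped booster: the gain
    importances, renormalized the same way.
    """
    if isinstance(model, LSBoostModel):
        g = np.zeros(model.n_features)
        for tree in model.trees:
            g += tree.gains_by_feature(model.n_features)
    elif isinstance(model, XGBoostModel):
        g = np.asarray(model.booster.feature_importances_, dtype=float)
    else:
        raise TypeError(f"unsupported model type {type(model)!r}")
    total = g.sum()
    return g / total if total > 0 else g


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    """The standard error suite on absolute logMAR errors."""

    mse: float
    rmse: float
    mae: float
    r2: float
    max_e: float
    min_e: float
    mode_e: float
    median_e: float
    n_total: int
    n_used: int
    outlier_policy: str = "none"

    def to_dict(self) -> dict:
        return dict(vars(self))


def _grid_mode(e: np.ndarray, grid: float = 0.02) -> float:
    """Most frequent error after rounding to the letter grid; ties -> smallest."""
    snapped = np.round(np.asarray(e, dtype=float) / grid) * grid
    values, counts = np.unique(np.round(snapped, 10), return_counts=True)
    return float(values[counts == counts.max()].min())


def remove_outliers_3sigma(errors: np.ndarray):
    """One-pass 3-sigma screen on an absolute-error sample.

    Returns ``(mask, removed_percentage)`` where the mask retains errors
    <= 3 x std(errors). A zero-spread sample removes nothing.
    """
    e = np.asarray(errors, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least two errors")
    sd = float(np.std(e))
    # all-equal errors leave sd at (numerical) zero: remove nothing
    if sd <= 1e-12 * max(1.0, float(np.max(e))):
        mask = np.ones(len(e), dtype=bool)
    else:
        mask = e <= 3.0 * sd
    return mask, removal_percentage(len(e), int(mask.sum()))


def removal_percentage(n_total: int, n_retained: int) -> float:
    """Percentage of entries removed when n_total reduces to n_retained."""
    return (n_total - n_retained) / n_total * 100.0


def percent_change(old: float, new: float) -> float:
    """Relative change from old to new, in percent."""
    return (new - old) / old * 100.0


def evaluate(y: np.ndarray, yhat: np.ndarray,
             outlier_policy: str = "none") -> MetricsReport:
    """MSE/RMSE/MAE/R2 plus MaxE/MinE/mode/median of absolute errors.

    With ``outlier_policy="drop3sigma"`` rows whose absolute error exceeds
    3 x std(errors) are removed before the metrics are computed; both the
    original and retained counts are reported.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or len(y) < 1:
        raise ValueError("y and yhat must be equal-length, non-empty")
    n_total = len(y)
    e = np.abs(y - yhat)
    if outlier_policy == "drop3sigma":
        mask, _ = remove_outliers_3sigma(e)
        y, yhat, e = y[mask], yhat[mask], e[mask]
    elif outlier_policy != "none":
        raise ValueError(f"unknown outlier policy {outlier_policy!r}")
    mse = float(np.mean((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance targets; R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return MetricsReport(
        mse=mse, rmse=math.sqrt(mse), mae=float(np.mean(e)), r2=r2,
        max_e=float(np.max(e)), min_e=float(np.min(e)),
        mode_e=_grid_mode(e), median_e=float(np.median(e)),
        n_total=n_total, n_used=len(y), outlier_policy=outlier_policy)


# ---------------------------------------------------------------------------
# Stratified analyses


def stratify(table: pd.DataFrame, scheme: str) -> dict:
    """Split an observation table into named clinical strata.

    ``scheme="age_bins"`` uses the six inclusive age bins 30-40, 41-44,
    45-50, 51-55, 56-60 and 61-65 (ages floored to whole years before
    binning). ``scheme="se_groups"`` classifies by spherical equivalent —
    myopic SE < -0.5 D, emmetropic -0.5 <= SE <= 0.5 D, hyperopic
    SE > 0.5 D — restricted to the uncorrected (as-measured) rows, the
    ones that reflect each eye's real refractive state. Rows outside every
    stratum are reported under ``attrs['n_unbinned']`` and excluded.
    """
    out: dict[str, pd.DataFrame] = {}
    if scheme == "age_bins":
        ages = np.floor(table["age"].to_numpy(dtype=float)).astype(int)
        assigned = np.zeros(len(table), dtype=bool)
        for lo, hi in AGE_BINS:
            sel = (ages >= lo) & (ages <= hi)
            out[f"{lo}-{hi}"] = table.iloc[np.flatnonzero(sel)]
            assigned |= sel
        n_unbinned = int((~assigned).sum())
    elif scheme == "se_groups":
        sub = table[table["condition"] == "uncorrected"]
        se = np.array([spherical_equivalent(s, c) for s, c in
                       zip(sub["sphere_d"], sub["cylinder_d"])])
        out["myopic"] = sub.iloc[np.flatnonzero(se < -0.5)]
        out["emmetropic"] = sub.iloc[np.flatnonzero((se >= -0.5) & (se <= 0.5))]
        out["hyperopic"] = sub.iloc[np.flatnonzero(se > 0.5)]
        n_unbinned = 0
    else:
        raise ValueError("scheme must be 'age_bins' or 'se_groups'")
    for name, sub in out.items():
        sub.attrs["stratum"] = name
    if n_unbinned:
        warnings.warn(f"{n_unbinned} rows fell outside every stratum",
                      stacklevel=2)
    for sub in out.values():
        sub.attrs["n_unbinned"] = n_unbinned
    return out
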