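"""Linear blood-pressure calibration: BP = A0 + A1*F1 + ... + An*Fn.

The estimator is organized the way statsmodels organizes regression
models: :class:`BPRegression` is built from data (or from a feature
DataFrame via :meth:`BPRegression.from_dataframe`), its :meth:`fit`
performs forward-stepwise feature selection under cross-validated
squared error and returns a :class:`BPRegressionResults` carrying the
coefficients, their standard errors, residual diagnostics and a
``summary()`` table.  Separate models are fitted for systolic and
diastolic pressure.

Feature selection is deliberately simple and fully deterministic given
the seed: starting from the intercept-only model, at each step the
candidate whose addition most reduces K-fold cross-validated MSE is
added, and selection stops as soon as no candidate improves the score.
The underlying least-squares fit on the selected subset is ordinary OLS
(delegated to statsmodels).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

__all__ = ["BPRegression", "BPRegressionResults", "select_features"]

CLAMP_RANGE = (40.0, 260.0)
MIN_TRAIN_SUBJECTS = 30
SERIAL_VERSION = "1.0"


def _cv_fold_mse(
    X: np.ndarray, y: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    out = np.empty(len(folds))
    for i, (tr, te) in enumerate(folds):
        Xtr = np.column_stack([np.ones(tr.size), X[tr]])
        Xte = np.column_stack([np.ones(te.size), X[te]])
        beta, *_ = np.linalg.lstsq(Xtr, y[tr], rcond=None)
        r = y[te] - Xte @ beta
        out[i] = float(r @ r) / te.size
    return out


def select_features(
    feature_table: pd.DataFrame,
    targets: Sequence[float],
    method: str = "forward-cv",
    seed: int = 0,
    n_folds: int = 5,
    max_features: int | None = None,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Ordered feature subset plus the full selection path.

    Returns ``(selected, path)`` where ``path`` is a list of
    ``(feature_name, cv_mse_after_adding)`` in selection order.
    """
    if method != "forward-cv":
        raise ValueError(f"unknown selection method {method!r}")
    X = feature_table.to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float)
    n = y.size
    names = list(feature_table.columns)
    kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in kf.split(X)]
    selected: list[int] = []
    path: list[tuple[str, float]] = []
    best_folds = _cv_fold_mse(X[:, :0], y, folds)  # intercept-only baseline
    limit = max_features if max_features is not None else len(names)
    while len(selected) < limit:
        scores = []
        for j in range(len(names)):
            if j in selected:
                continue
            trial = selected + [j]
            scores.append((float(np.mean(_cv_fold_mse(X[:, trial], y, folds))),
                           j))
        if not scores:
            break
        _, j = min(scores)
        cand_folds = _cv_fold_mse(X[:, selected + [j]], y, folds)
        # paired one-standard-error rule: accept only if the improvement
        # clearly exceeds its own fold-to-fold uncertainty
        diff = best_folds - cand_folds
        se = float(np.std(diff, ddof=1)) / math.sqrt(len(folds)) \
            if len(folds) > 1 else 0.0
        if float(np.mean(diff)) <= se:
            break
        best_folds = cand_folds
        selected.append(j)
        path.append((names[j], float(np.mean(cand_folds))))
    return [names[j] for j in selected], path


class BPRegression:
    """Linear-regression model of one BP target from pulse-wave features."""

    def __init__(
        self,
        endog: Sequence[float],
        exog: pd.DataFrame,
        target: str = "sbp",
    ) -> None:
        endog = pd.Series(np.asarray(endog, dtype=float), name=target)
        if not isinstance(exog, pd.DataFrame):
            raise TypeError("exog must be a DataFrame with named feature columns")
        if len(endog) != len(exog):
            raise ValueError("endog and exog lengths differ")
        exog = exog.reset_index(drop=True)
        endog = endog.reset_index(drop=True)
        mask = endog.notna() & exog.notna().all(axis=1)
        if mask.sum() < len(endog):
            exog = exog.loc[mask.to_numpy()]
            endog = endog.loc[mask.to_numpy()]
        constant = [c for c in exog.columns if exog[c].nunique(dropna=True) <= 1]
        if constant:
            warnings.warn(
                f"dropping constant feature column(s): {constant}", stacklevel=2
            )
            exog = exog.drop(columns=constant)
        self.endog = endog.reset_index(drop=True)
        self.exog = exog.reset_index(drop=True)
        self.target = target

    @classmethod
    def from_dataframe(
        cls,
        features: pd.DataFrame,
        targets: pd.DataFrame | pd.Series,
        target: str = "sbp",
        feature_cols: Sequence[str] | None = None,
        target_col: str | None = None,
    ) -> "BPRegression":
        """Build from a record-level feature table and a cuff-reference table.

        ``targets`` may be a Series (used directly) or a DataFrame from
        which ``target_col`` (default ``"<target>_mean"``) is taken.
        Rows are aligned positionally; align on subject id upstream.
        """
        if isinstance(targets, pd.DataFrame):
            col = target_col or f"{target}_mean"
            if col not in targets.columns:
                raise KeyError(f"target column {col!r} not in cuff table")
            y = targets[col]
        else:
            y = targets
        drop = {"subject_id", "n_beats", "n_beats_min_feature"}
        if feature_cols is None:
            feature_cols = [
                c for c in features.columns
                if c not in drop and pd.api.types.is_numeric_dtype(features[c])
            ]
        return cls(y.to_numpy(dtype=float), features[list(feature_cols)], target)

    def fit(
        self,
        selection: str | None = "forward-cv",
        seed: int = 0,
        n_folds: int = 5,
        max_features: int | None = None,
        min_subjects: int = MIN_TRAIN_SUBJECTS,
    ) -> "BPRegressionResults":
        n, p = self.exog.shape
        if n < min_subjects:
            raise ValueError(
                f"need at least {min_subjects} complete training subjects, "
                f"have {n}"
            )
        if selection is None and n <= p:
            raise ValueError(
                f"refusing to fit an unregularized model with {p} features and "
                f"only {n} subjects; enable feature selection"
            )
        if selection is not None:
            selected, path = select_features(
                self.exog, self.endog, method=selection, seed=seed,
                n_folds=n_folds, max_features=max_features,
            )
            if not selected:  # nothing beats the intercept-only model
                selected = []
        else:
            selected, path = list(self.exog.columns), []
        X = sm.add_constant(self.exog[selected], has_constant="add")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # identify offending columns via correlated pairs
            bad = _collinear_columns(X)
            raise ValueError(
                f"rank-deficient design matrix; offending columns: {bad}"
            )
        res = sm.OLS(self.endog, X).fit()
        return BPRegressionResults(
            target=self.target,
            params=res.params,
            bse=res.bse,
            resid_sd=float(np.sqrt(res.scale)),
            nobs=int(res.nobs),
            selected_features=list(selected),
            selection_path=path,
            conf_int=res.conf_int(),
            rsquared=float(res.rsquared) if res.df_resid > 0 else float("nan"),
            _sm_results=res,
        )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols = [c for c in X.columns if c != "const"]
    bad = []
    arr = X[cols].to_numpy()
    for i, c in enumerate(cols):
        others = np.delete(np.arange(len(cols)), i)
        if others.size == 0:
            continue
        r = np.linalg.matrix_rank(arr[:, others])
        if np.linalg.matrix_rank(arr) == r:
            bad.append(c)
    return bad or cols


@dataclass
class BPRegressionResults:
    """Fitted BP calibration: intercept A0, coefficients A1..An, diagnostics."""

    target: str
    params: pd.Series
    bse: pd.Series
    resid_sd: float
    nobs: int
    selected_features: list[str]
    selection_path: list[tuple[str, float]]
    conf_int: pd.DataFrame | None = None
    rsquared: float = float("nan")
    _sm_results: object | None = field(default=None, repr=False)

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def predict(
        self,
        features: pd.DataFrame | pd.Series | dict,
        clamp: tuple[float, float] = CLAMP_RANGE,
    ) -> np.ndarray | float:
        """Affine evaluation; output clamped to a physiological range."""
        scalar = isinstance(features, (pd.Series, dict))
        df = (pd.DataFrame([features]) if scalar
              else features.copy())
        missing = [f for f in self.selected_features if f not in df.columns
                   or df[f].isna().any()]
        if missing:
            raise ValueError(
                f"missing selected feature(s) for prediction: {missing}"
            )
        pred = np.full(len(df), self.intercept, dtype=float)
        for f in self.selected_features:
            pred += float(self.params[f]) * df[f].to_numpy(dtype=float)
        if clamp is not None:
            out_of_range = (pred < clamp[0]) | (pred > clamp[1])
            if out_of_range.any():
                warnings.warn(
                    f"{int(out_of_range.sum())} prediction(s) clamped to "
                    f"[{clamp[0]}, {clamp[1]}] mmHg", stacklevel=2,
                )
            pred = np.clip(pred, clamp[0], clamp[1])
        return float(pred[0]) if scalar else pred

    def summary(self) -> str:
        """Human-readable coefficient table (statsmodels style)."""
        lines = [
            f"BP calibration results - target: {self.target.upper()}",
            f"n = {self.nobs}, residual sd = {self.resid_sd:.3f} mmHg, "
            f"R^2 = {self.rsquared:.4f}",
            f"{'term':<20}{'coef':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<20}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
            )
        if self.selection_path:
            lines.append("selection path: " + " -> ".join(
                f"{n} (cv mse {m:.3f})" for n, m in self.selection_path))
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "serial_version": SERIAL_VERSION,
            "target": self.target,
            "intercept_mmhg": self.intercept,
            "coefficients": {
                f: float(self.params[f]) for f in self.selected_features
            },
            "std_errors": {k: float(v) for k, v in self.bse.items()},
            "resid_sd_mmhg": self.resid_sd,
            "nobs": self.nobs,
            "selected_features": self.selected_features,
            "selection_path": [[n, float(m)] for n, m in self.selection_path],
            "rsquared": self.rsquared,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "BPRegressionResults":
        params = pd.Series(
            {"const": d["intercept_mmhg"], **d["coefficients"]}, dtype=float
        )
        return cls(
            target=d["target"],
            params=params,
            bse=pd.Series(d.get("std_errors", {}), dtype=float),
            resid_sd=float(d["resid_sd_mmhg"]),
            nobs=int(d["nobs"]),
            selected_features=list(d["selected_features"]),
            selection_path=[(n, float(m)) for n, m in d.get("selection_path", [])],
            rsquared=float(d.get("rsquared", float("nan"))),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "BPRegressionResults":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
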