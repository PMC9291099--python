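"""Monte-Carlo bias benchmarking and repeated k-fold cross-validation.

Two experiments compare the joint-SEM condition index with the stepwise
multiple-regression baseline:

* ``run_bias_experiment`` simulates many datasets from a generating model
  with known condition-variable effects, re-estimates those effects with each
  method, and summarizes the mean bias ``B = mean(theta_hat_i) - theta`` and
  the empirical standard error ``E = sd(theta_hat_i)`` (nsim-1 denominator)
  per parameter.
* ``cross_validate`` repeatedly partitions a dataset into k folds, fits both
  methods on the training part, predicts survival out-of-fold, and pools the
  predictions into RMSE and R-squared per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import engine as _engine
from .conventional import _fit_steps, stepwise_condition_index, stepwise_predict
from .model import COMPOSED_OF, ModelSpec
from .simulate import TrueModel, condition_true_effects, simulate_dataset

__all__ = [
    "SimulationResult",
    "CVResult",
    "bias_metrics",
    "run_bias_experiment",
    "cross_validate",
]

log = logging.getLogger(__name__)

#: parameters with |true value| below this are flagged as "too close to zero"
#: for a meaningful relative bias
RELATIVE_BIAS_THRESHOLD = 0.05


@dataclass
class SimulationResult:
    """Per-parameter bias table for one estimation method."""

    method: str
    table: pd.DataFrame   # index: parameter; true_value, mean_estimate, bias,
                          # empirical_se, relative_bias (NaN when unflagged)
    nsim: int
    n: int
    seed: int
    n_nonconverged: int = 0

    def recompute(self, estimates: Mapping[str, np.ndarray]) -> pd.DataFrame:
        """Re-derive the table from raw estimates (bitwise consistency check)."""
        rows = {}
        for param, est in estimates.items():
            rows[param] = bias_metrics(np.asarray(est), self.table.loc[param, "true_value"])
        return pd.DataFrame(rows).T


@dataclass
class CVResult:
    folds: int
    repeats: int
    seed: int
    metrics: pd.DataFrame       # index: method; columns rmse, r_squared, n_fits
    predictions: pd.DataFrame   # row, repeat, fold, observed, one column per method


def bias_metrics(estimates: np.ndarray, true_value: float,
                 threshold: float = RELATIVE_BIAS_THRESHOLD) -> dict:
    """Mean bias, empirical standard error and relative bias of an estimator.

    ``bias = mean(est) - theta``; ``empirical_se = sd(est)`` with the
    (nsim - 1) denominator; ``relative_bias = 100 * bias / theta`` reported
    as NaN when ``|theta| < threshold`` (no meaningful relative scale).
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least two estimates for an empirical SE")
    bias = float(est.mean() - true_value)
    emp_se = float(est.std(ddof=1))
    rel = 100.0 * bias / true_value if abs(true_value) >= threshold else float("nan")
    return {
        "true_value": float(true_value),
        "mean_estimate": float(est.mean()),
        "bias": bias,
        "empirical_se": emp_se,
        "relative_bias": rel,
    }


def _sem_total_effects(fit, spec: ModelSpec, composite: str, outcome: str) -> dict:
    """gamma * weight per composite cause: the per-variable effect on the outcome."""
    gamma = fit.estimate(outcome, "~", composite)
    out = {}
    for term in spec.causes_of(composite):
        w = fit.estimate(composite, COMPOSED_OF, term.rhs)
        out[term.rhs] = gamma * w
    return out


def run_bias_experiment(
    model: TrueModel,
    nsim: int,
    n: int,
    methods: Sequence[str] = ("sem", "stepwise"),
    seed: int = 0,
    true_effects: Optional[Mapping[str, float]] = None,
    variable_map: Optional[Mapping[str, str]] = None,
) -> dict:
    """Simulate ``nsim`` datasets of ``n`` rows from *model* and estimate the
    condition-variable effects on survival with each method.

    Returns a :class:`SimulationResult` per method.  Replicates whose SEM fit
    fails to converge are excluded with a logged rate; more than 10%
    non-convergence aborts with diagnostics.
    """
    if nsim < 2:
        raise ValueError("need nsim >= 2")
    spec = model.spec
    composites = spec.composites
    if len(composites) != 1:
        raise ValueError("bias experiment expects a single composite condition index")
    composite = composites[0]
    outcome = next(
        t.lhs for t in spec.terms if t.op == "~" and t.rhs == composite
    )
    if true_effects is None:
        true_effects = condition_true_effects()
    scm_alias = {"scm": variable_map.get("mass", "mass") if variable_map else "mass"}

    collected: dict = {m: {} for m in methods}
    n_bad = 0
    for i in range(nsim):
        data = simulate_dataset(model, n, seed=seed, stream=i)
        if "sem" in methods:
            fit = _engine.fit_ml(spec, data)
            if not fit.converged:
                n_bad += 1
                log.warning("replicate %d: SEM fit did not converge, skipped", i)
                if n_bad > 0.1 * nsim:
                    raise _engine.ConvergenceError(
                        f"{n_bad} of {i + 1} replicates failed to converge "
                        f"(last gradient norm {fit.grad_norm:.3g})"
                    )
                continue
            eff = _sem_total_effects(fit, spec, composite, outcome)
            for cause, v in eff.items():
                key = scm_alias.get(cause, cause)
                collected["sem"].setdefault(key, []).append(v)
        if "stepwise" in methods:
            res = stepwise_condition_index(data, variable_map)
            coef = res.step2_coefficients
            for name, v in coef.items():
                if name == "const":
                    continue
                key = "mass" if name == "resid_mass" else name
                collected["stepwise"].setdefault(key, []).append(v)

    results = {}
    for m in methods:
        rows = {}
        for param, est in collected[m].items():
            if param not in true_effects:
                continue
            rows[param] = bias_metrics(np.asarray(est), true_effects[param])
        results[m] = SimulationResult(
            method=m,
            table=pd.DataFrame(rows).T,
            nsim=nsim, n=n, seed=seed,
            n_nonconverged=n_bad if m == "sem" else 0,
        )
    if n_bad:
        log.info("bias experiment: %d/%d replicates non-converged and excluded", n_bad, nsim)
    return results


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    """A random partition of ``range(n)`` into ``folds`` near-equal folds."""
    idx = rng.permutation(n)
    out = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(idx, folds)):
        out[chunk] = k
    return out


def _sem_cv_predict(spec, train: pd.DataFrame, test: pd.DataFrame, survival: str):
    fit = _engine.fit_ml(spec, train)
    if not fit.converged:
        return None
    composite = spec.composites[0]
    scores_tr = _engine.factor_scores(fit, train)[composite]
    scores_te = _engine.factor_scores(fit, test)[composite]
    gamma = fit.estimate(survival, "~", composite)
    ybar = train[survival].mean()
    # scores are centered at the training means, so the linear predictor is
    # anchored on the training survival mean
    return ybar + gamma * (scores_te - scores_tr.mean())


def cross_validate(
    data: pd.DataFrame,
    sem_spec: ModelSpec,
    variable_map: Optional[Mapping[str, str]] = None,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    mode: str = "kfold",
    test_fraction: float = 0.2,
) -> CVResult:
    """Repeated out-of-sample comparison of the SEM and stepwise indices.

    ``mode="kfold"`` (default) partitions the rows into ``folds`` folds per
    repeat — 10 folds x 3 repeats gives 30 distinct training/test splits.
    ``mode="split"`` instead draws ``folds x repeats`` random splits holding
    out ``test_fraction`` of the rows each time.  RMSE and R-squared are
    computed on the pooled out-of-fold predictions (R-squared can be
    negative for a model worse than the pooled mean).
    """
    if folds < 2:
        raise ValueError("need at least two folds")
    vmap = dict(variable_map or {})
    survival = vmap.get("survival", "survival")
    needed = list(dict.fromkeys(list(sem_spec.observed)))
    frame = data.dropna(subset=needed).reset_index(drop=True)
    n = len(frame)
    if n < folds:
        raise ValueError("fewer rows than folds")
    nfree = len([t for t in sem_spec.terms if t.free])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2**20]))

    records = []
    skipped = 0
    for rep in range(repeats):
        if mode == "kfold":
            assignment = _fold_assignment(n, folds, rng)
            splits = [(k, np.where(assignment != k)[0], np.where(assignment == k)[0])
                      for k in range(folds)]
        elif mode == "split":
            splits = []
            for k in range(folds):
                test_idx = rng.choice(n, size=max(1, int(round(test_fraction * n))),
                                      replace=False)
                mask = np.ones(n, dtype=bool)
                mask[test_idx] = False
                splits.append((k, np.where(mask)[0], test_idx))
        else:
            raise ValueError("mode must be 'kfold' or 'split'")
        for k, tr_idx, te_idx in splits:
            if len(tr_idx) <= nfree:
                raise ValueError(
                    f"training fold has {len(tr_idx)} rows for {nfree} free "
                    "parameters; use fewer folds"
                )
            train, test = frame.iloc[tr_idx], frame.iloc[te_idx]
            sem_pred = _sem_cv_predict(sem_spec, train, test, survival)
            if sem_pred is None:
                skipped += 1
                if skipped > 0.1 * folds * repeats:
                    raise _engine.ConvergenceError(
                        "more than 10% of CV folds failed to converge"
                    )
                continue
            step1, step2, _, _ = _fit_steps(train, vmap)
            conv_pred = stepwise_predict((step1.params, step2.params), test, vmap)
            rec = pd.DataFrame({
                "row": te_idx, "repeat": rep, "fold": k,
                "observed": test[survival].to_numpy(),
                "sem": sem_pred.to_numpy(),
                "conventional": conv_pred.to_numpy(),
            })
            records.append(rec)
    preds = pd.concat(records, ignore_index=True)

    metrics = {}
    y = preds["observed"].to_numpy()
    sst = float(np.sum((y - y.mean()) ** 2))
    for m in ("sem", "conventional"):
        e = y - preds[m].to_numpy()
        sse = float(np.sum(e ** 2))
        metrics[m] = {
            "rmse": float(np.sqrt(np.mean(e ** 2))),
            "r_squared": 1.0 - sse / sst,
            "n_fits": int(preds.groupby(["repeat", "fold"]).ngroups),
        }
    return CVResult(
        folds=folds, repeats=repeats, seed=seed,
        metrics=pd.DataFrame(metrics).T,
        predictions=preds,
    )
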