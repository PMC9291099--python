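"""Maximum-likelihood estimation of covariance-structure models.

The engine works in the RAM (reticular action model) parameterization: all
variables of the model — observed, latent and composite — form one vector of
length ``t``; a directed-coefficient matrix ``A`` holds loadings, regression
slopes and composite weights; a symmetric matrix ``S`` holds residual
variances, exogenous (co)variances and error covariances; and a selector
``F`` picks out the observed rows.  The model-implied covariance of the
observed variables is

    Sigma(theta) = F (I - A)^-1 S (I - A)^-T F^T

and parameters are estimated by minimizing the classical Wishart maximum-
likelihood discrepancy

    F_ML = ln|Sigma| + tr(S_sample Sigma^-1) - ln|S_sample| - p

per group, weighted by (N_g - 1)/(N - G).  The chi-square statistic is
``T = sum_g (N_g - 1) F_g``.  Composites enter ``A`` like latents but with
their diagonal of ``S`` pinned to 0, so a composite is fully determined by
its causes.  Estimation is deterministic given data and model: there is no
randomness anywhere in the fitting path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .model import (
    COMPOSED_OF,
    COVARIES_WITH,
    MEASURED_BY,
    OP_CLASS,
    REGRESSED_ON,
    ModelError,
    ModelSpec,
    apply_identification,
    count_free_parameters,
    model_df,
)

__all__ = [
    "SampleMoments",
    "RAMMatrices",
    "FittedModel",
    "implied_covariance",
    "discrepancy_fml",
    "fit_ml",
    "standard_errors",
    "standardized_solution",
    "factor_scores",
    "fit_indices",
    "chisq_diff_test",
    "ConvergenceError",
]

log = logging.getLogger(__name__)

_SINGLE_GROUP = ""

PARAM_COLUMNS = [
    "lhs", "op", "rhs", "group", "free", "fixed_value",
    "start", "estimate", "se", "z", "pvalue", "std_estimate",
]


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# sample moments
# ---------------------------------------------------------------------------

@dataclass
class SampleMoments:
    """Sample covariance matrix (denominator N-1), means and N for one group."""

    cov: np.ndarray
    means: np.ndarray
    n: int
    var_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        p = len(self.var_order)
        if self.cov.shape != (p, p):
            raise ValueError("covariance shape does not match variable order")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("sample covariance must be symmetric")
        if np.any(np.diag(self.cov) < 0):
            raise ValueError("negative variance on the covariance diagonal")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, variables: Sequence[str]) -> "SampleMoments":
        sub = data.loc[:, list(variables)].astype(float)
        complete = sub.dropna()
        dropped = len(sub) - len(complete)
        if dropped:
            log.info("listwise deletion removed %d of %d rows", dropped, len(sub))
        n = len(complete)
        if n < len(variables) + 1:
            raise ModelError(
                f"need at least p+1 = {len(variables) + 1} complete rows, got {n}"
            )
        x = complete.to_numpy()
        return cls(
            cov=np.cov(x, rowvar=False, ddof=1),
            means=x.mean(axis=0),
            n=n,
            var_order=tuple(variables),
        )


# ---------------------------------------------------------------------------
# RAM matrices
# ---------------------------------------------------------------------------

@dataclass
class RAMMatrices:
    """Directed coefficients ``A``, symmetric (co)variances ``Ssym`` and the
    observed-row selector ``Fsel`` over the full variable vector."""

    A: np.ndarray
    Ssym: np.ndarray
    Fsel: np.ndarray

    def full_covariance(self) -> np.ndarray:
        """Implied covariance of the complete (observed + unmeasured) vector."""
        t = self.A.shape[0]
        try:
            B = linalg.solve(np.eye(t) - self.A, np.eye(t))
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded by DAG check
            raise ModelError("(I - A) is singular: structural cycle") from exc
        V = B @ self.Ssym @ B.T
        return (V + V.T) / 2.0


def implied_covariance(ram: RAMMatrices) -> np.ndarray:
    """``Fsel (I-A)^-1 Ssym (I-A)^-T Fsel^T`` — the observed-variable block."""
    V = ram.full_covariance()
    return ram.Fsel @ V @ ram.Fsel.T


def discrepancy_fml(S: Union[SampleMoments, np.ndarray], sigma: np.ndarray) -> float:
    """Wishart ML discrepancy between a sample and an implied covariance.

    Non-negative, and zero exactly when the two matrices coincide.
    """
    s = S.cov if isinstance(S, SampleMoments) else np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = s.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(s)
    try:
        c = linalg.cholesky(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise ModelError("implied covariance is not positive definite") from exc
    if sign_s <= 0:
        raise ModelError("sample covariance is not positive definite")
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    sigma_inv = linalg.cho_solve((c, True), np.eye(p))
    return float(logdet_sigma + np.trace(s @ sigma_inv) - logdet_s - p)


# ---------------------------------------------------------------------------
# internal parameter template
# ---------------------------------------------------------------------------

@dataclass
class _Slot:
    matrix: str      # "A" | "S" | "M"
    i: int
    j: int
    pid: int         # free-parameter index, -1 when fixed
    value: float     # fixed value (ignored when free)
    row: int         # index into the parameter-table rows


@dataclass
class _Template:
    spec: ModelSpec
    names: list
    obs: list
    group_labels: list
    rows: pd.DataFrame
    slots: dict               # group label -> list[_Slot]
    npar: int
    variance_pids: set

    @property
    def t(self) -> int:
        return len(self.names)

    @property
    def obs_idx(self) -> np.ndarray:
        return np.array([self.names.index(v) for v in self.obs])


def _build_template(spec: ModelSpec, group_labels: Sequence) -> _Template:
    if not spec.identified:
        spec = apply_identification(spec)
    names = list(spec.observed) + [v for v in spec.names if v not in spec.observed]
    idx = {n: k for k, n in enumerate(names)}
    rows = []
    slots: dict = {g: [] for g in group_labels}
    pids: dict = {}
    variance_pids = set()

    def place(term) -> tuple[str, int, int]:
        if term.op == REGRESSED_ON:
            return "A", idx[term.lhs], idx[term.rhs]
        if term.op == MEASURED_BY:
            return "A", idx[term.rhs], idx[term.lhs]
        if term.op == COMPOSED_OF:
            return "A", idx[term.lhs], idx[term.rhs]
        return "S", idx[term.lhs], idx[term.rhs]

    nrow = 0
    for g in group_labels:
        for k, term in enumerate(spec.terms):
            mat, i, j = place(term)
            if term.free:
                shared = term.label is not None or OP_CLASS[term.op] in spec.group_equal
                key = ("L", term.label) if term.label is not None else (
                    ("S", k) if shared else ("G", g, k)
                )
                if key not in pids:
                    pids[key] = len(pids)
                pid = pids[key]
                if mat == "S" and i == j:
                    variance_pids.add(pid)
            else:
                pid = -1
            slots[g].append(_Slot(mat, i, j, pid, term.fixed_value or 0.0, nrow))
            rows.append({
                "lhs": term.lhs, "op": term.op, "rhs": term.rhs, "group": g,
                "free": term.free, "fixed_value": term.fixed_value,
                "start": np.nan, "estimate": np.nan, "se": np.nan,
                "z": np.nan, "pvalue": np.nan, "std_estimate": np.nan,
            })
            nrow += 1
        if spec.meanstructure:
            for v in spec.observed:
                key = ("M", g, v)
                pids[key] = len(pids)
                slots[g].append(_Slot("M", idx[v], 0, pids[key], 0.0, nrow))
                rows.append({
                    "lhs": v, "op": "~1", "rhs": "", "group": g,
                    "free": True, "fixed_value": None,
                    "start": np.nan, "estimate": np.nan, "se": np.nan,
                    "z": np.nan, "pvalue": np.nan, "std_estimate": np.nan,
                })
                nrow += 1

    return _Template(
        spec=spec, names=names, obs=list(spec.observed),
        group_labels=list(group_labels),
        rows=pd.DataFrame(rows, columns=PARAM_COLUMNS[:7] + PARAM_COLUMNS[7:]),
        slots=slots, npar=len(pids), variance_pids=variance_pids,
    )


def _start_values(tmpl: _Template, moments: dict) -> np.ndarray:
    """Spec'd starting values: loadings/weights 1, regressions 0, observed
    residual variances half the sample variance, latent variances half the
    variance of the scale-setting indicator; exogenous observed (co)variances
    start at their sample values."""
    spec = tmpl.spec
    theta = np.full(tmpl.npar, np.nan)
    endo = spec.endogenous()

    def sample_stat(g, a, b=None):
        m = moments[g]
        order = list(m.var_order)
        ia = order.index(a)
        if b is None:
            return m.cov[ia, ia]
        return m.cov[ia, order.index(b)]

    scale_indicator = {}
    for lat in spec.latents:
        loads = spec.loadings_of(lat)
        fixed = [t for t in loads if not t.free]
        pick = (fixed or loads)[0].rhs
        scale_indicator[lat] = pick

    for g in tmpl.group_labels:
        for k, term in enumerate(spec.terms):
            slot = tmpl.slots[g][k]
            if slot.pid < 0 or not np.isnan(theta[slot.pid]):
                continue
            if term.op in (MEASURED_BY, COMPOSED_OF):
                val = 1.0
            elif term.op == REGRESSED_ON:
                val = 0.0
            else:  # covariance terms
                a, b = term.lhs, term.rhs
                if a == b:
                    role = spec.role(a)
                    if role == "observed":
                        s = sample_stat(g, a)
                        val = s if a not in endo else 0.5 * s
                    elif role == "latent":
                        ind = scale_indicator[a]
                        val = 0.5 * sample_stat(g, ind) if ind in spec.observed else 0.5
                    else:
                        val = 0.0
                else:
                    if spec.role(a) == "observed" and spec.role(b) == "observed" \
                            and a not in endo and b not in endo:
                        val = sample_stat(g, a, b)
                    else:
                        val = 0.0
            theta[slot.pid] = val
        if spec.meanstructure:
            for slot in tmpl.slots[g][len(spec.terms):]:
                theta[slot.pid] = moments[g].means[tmpl.obs.index(tmpl.names[slot.i])]
    theta[np.isnan(theta)] = 0.0
    return theta


def _fill(tmpl: _Template, theta: np.ndarray, g) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = tmpl.t
    A = np.zeros((t, t))
    S = np.zeros((t, t))
    M = np.zeros(t)
    for slot in tmpl.slots[g]:
        val = theta[slot.pid] if slot.pid >= 0 else slot.value
        if slot.matrix == "A":
            A[slot.i, slot.j] = val
        elif slot.matrix == "S":
            S[slot.i, slot.j] = val
            S[slot.j, slot.i] = val
        else:
            M[slot.i] = val
    return A, S, M


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    spec: ModelSpec
    params: pd.DataFrame
    fml: float
    chisq: float
    df: int
    converged: bool
    per_group_moments: dict
    group_labels: list
    n_total: int
    n_groups: int
    grad_norm: float
    n_scaling: str = "n-1"
    _template: _Template = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)

    def estimate(self, lhs: str, op: str, rhs: str, group=None) -> float:
        """Look up one estimated value from the parameter table."""
        tab = self.params
        m = (tab.lhs == lhs) & (tab.op == op) & (tab.rhs == rhs)
        if op == COVARIES_WITH:
            m |= (tab.lhs == rhs) & (tab.op == op) & (tab.rhs == lhs)
        if group is not None:
            m &= tab.group == group
        sub = tab[m]
        if sub.empty:
            raise KeyError(f"no parameter {lhs} {op} {rhs}")
        return float(sub.estimate.iloc[0])

    def ram(self, group=None) -> RAMMatrices:
        g = self.group_labels[0] if group is None else group
        A, S, _ = _fill(self._template, self._theta, g)
        t = self._template.t
        F = np.zeros((len(self._template.obs), t))
        F[np.arange(len(self._template.obs)), self._template.obs_idx] = 1.0
        return RAMMatrices(A=A, Ssym=S, Fsel=F)

    def summary(self) -> dict:
        fi = fit_indices(self)
        fi["n"] = self.n_total
        fi["converged"] = self.converged
        return fi


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _objective_factory(tmpl: _Template, moments: dict, weights: dict):
    """Return f(theta) -> (objective, gradient) for the weighted discrepancy
    ``sum_g w_g F_g``.  The gradient is analytic (O(t^3) per group via the
    trace identities of the RAM parameterization)."""
    spec = tmpl.spec
    obs_idx = tmpl.obs_idx
    t = tmpl.t
    p = len(tmpl.obs)
    eye = np.eye(t)
    pre = {}
    for g, m in moments.items():
        sign, logdet_s = np.linalg.slogdet(m.cov)
        if sign <= 0:
            raise ModelError(f"sample covariance for group {g!r} is not positive definite")
        pre[g] = logdet_s

    def fun(theta: np.ndarray):
        f = 0.0
        grad = np.zeros(tmpl.npar)
        for g, m in moments.items():
            w = weights[g]
            A, S, mu_vec = _fill(tmpl, theta, g)
            B = linalg.solve(eye - A, eye)
            G = B[obs_idx, :]
            Sigma = G @ S @ G.T
            Sigma = (Sigma + Sigma.T) / 2.0
            try:
                c = linalg.cholesky(Sigma, lower=True)
            except linalg.LinAlgError:
                return 1e10, np.zeros(tmpl.npar)
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            Sigma_inv = linalg.cho_solve((c, True), np.eye(p))
            fml = logdet + float(np.sum(Sigma_inv * m.cov)) - pre[g] - p
            W = Sigma_inv - Sigma_inv @ m.cov @ Sigma_inv
            if spec.meanstructure:
                mu = G @ mu_vec
                d = m.means - mu
                sid = Sigma_inv @ d
                fml += float(d @ sid)
                W = W - np.outer(sid, sid)
            f += w * fml
            K = np.zeros((t, t))
            K[np.ix_(obs_idx, obs_idx)] = W
            KB = K @ B
            Q = B.T @ KB                     # gradient w.r.t. S entries
            V = B @ S @ B.T
            P = V @ KB                       # gradient w.r.t. A entries
            for slot in tmpl.slots[g]:
                if slot.pid < 0:
                    continue
                i, j = slot.i, slot.j
                if slot.matrix == "A":
                    gval = 2.0 * P[j, i]
                elif slot.matrix == "S":
                    gval = Q[i, i] if i == j else 2.0 * Q[i, j]
                else:
                    gval = 0.0
                grad[slot.pid] += w * gval
            if spec.meanstructure:
                # mean-structure contributions: d f / d m = -2 G^T Sigma^-1 d
                # and an extra A-term  -2 (B^T F^T Sigma^-1 d)_i (B m)_j
                mu = G @ mu_vec
                d = m.means - mu
                sid = Sigma_inv @ d
                gm = -2.0 * (G.T @ sid)
                rvec = np.zeros(t)
                rvec[obs_idx] = sid
                rB = B.T @ rvec
                q = B @ mu_vec
                for slot in tmpl.slots[g]:
                    if slot.pid < 0:
                        continue
                    if slot.matrix == "M":
                        grad[slot.pid] += w * gm[slot.i]
                    elif slot.matrix == "A":
                        grad[slot.pid] += w * (-2.0 * rB[slot.i] * q[slot.j])
        return f, grad

    return fun


def _prepare_groups(spec, data, group):
    """Split data / moments into per-group SampleMoments."""
    variables = list(spec.observed)
    if isinstance(data, SampleMoments):
        return {_SINGLE_GROUP: _reorder(data, variables)}, [_SINGLE_GROUP]
    if isinstance(data, dict):
        labels = list(data)
        return {g: _reorder(m, variables) for g, m in data.items()}, labels
    if not isinstance(data, pd.DataFrame):
        raise TypeError("data must be a DataFrame, SampleMoments or dict thereof")
    gcol = group or spec.groups
    if gcol is None:
        return {_SINGLE_GROUP: SampleMoments.from_dataframe(data, variables)}, [_SINGLE_GROUP]
    if gcol not in data.columns:
        raise ModelError(f"grouping column {gcol!r} not in data")
    moments, labels = {}, []
    for g, sub in data.groupby(gcol, sort=False):
        labels.append(g)
        moments[g] = SampleMoments.from_dataframe(sub, variables)
        if moments[g].n <= len(variables):
            raise ModelError(f"group {g!r} has N <= p")
    return moments, labels


def _reorder(m: SampleMoments, variables) -> SampleMoments:
    if list(m.var_order) == list(variables):
        return m
    try:
        order = [list(m.var_order).index(v) for v in variables]
    except ValueError as exc:
        raise ModelError(f"moment matrix is missing a model variable: {exc}") from exc
    return SampleMoments(
        cov=m.cov[np.ix_(order, order)], means=m.means[order],
        n=m.n, var_order=tuple(variables),
    )


def _scaling_vector(tmpl: _Template, moments: dict, weights: dict) -> tuple:
    """Pooled observed standard deviations for internal standardization.

    Fitting happens on unit-variance rescaled moments (the ML discrepancy is
    invariant to diagonal rescaling) which keeps the optimization landscape
    well conditioned whatever the measurement units; estimates are mapped
    back afterwards.  Latent and composite variables keep scale 1.  When an
    equality-constrained parameter spans slots with different scale factors
    the rescaling is skipped (identity scaling) to preserve the constraint.
    """
    t = tmpl.t
    d = np.ones(t)
    for k, v in enumerate(tmpl.obs):
        pooled = sum(
            weights[g] * moments[g].cov[k, k] for g in tmpl.group_labels
        )
        d[tmpl.obs_idx[k]] = np.sqrt(pooled)
    if np.any(d <= 0):
        raise ModelError("zero-variance observed variable")

    pid_factor = np.ones(tmpl.npar)
    consistent = True
    seen: dict = {}
    for g in tmpl.group_labels:
        for slot in tmpl.slots[g]:
            if slot.matrix == "A":
                f = d[slot.i] / d[slot.j]
            elif slot.matrix == "S":
                f = d[slot.i] * d[slot.j]
            else:
                f = d[slot.i]
            if slot.pid >= 0:
                if slot.pid in seen and not np.isclose(seen[slot.pid], f):
                    consistent = False
                seen[slot.pid] = f
    if not consistent:
        return np.ones(t), np.ones(tmpl.npar)
    for pid, f in seen.items():
        pid_factor[pid] = f
    return d, pid_factor


def _scaled_problem(tmpl: _Template, moments: dict, d: np.ndarray):
    """Rescaled moments and a template copy with transformed fixed values."""
    obs_d = d[tmpl.obs_idx]
    scaled_moments = {}
    for g, m in moments.items():
        scaled_moments[g] = SampleMoments(
            cov=m.cov / np.outer(obs_d, obs_d),
            means=m.means / obs_d,
            n=m.n,
            var_order=m.var_order,
        )
    slots = {}
    for g, slist in tmpl.slots.items():
        new = []
        for s in slist:
            if s.matrix == "A":
                v = s.value * d[s.j] / d[s.i]
            elif s.matrix == "S":
                v = s.value / (d[s.i] * d[s.j])
            else:
                v = s.value / d[s.i]
            new.append(_Slot(s.matrix, s.i, s.j, s.pid, v, s.row))
        slots[g] = new
    scaled_tmpl = _Template(
        spec=tmpl.spec, names=tmpl.names, obs=tmpl.obs,
        group_labels=tmpl.group_labels, rows=tmpl.rows, slots=slots,
        npar=tmpl.npar, variance_pids=tmpl.variance_pids,
    )
    return scaled_tmpl, scaled_moments


def fit_ml(
    spec: ModelSpec,
    data,
    group: Optional[str] = None,
    n_scaling: str = "n-1",
    max_iter: int = 10_000,
) -> FittedModel:
    """Fit *spec* to *data* by multi-group maximum likelihood.

    *data* may be a DataFrame (rows with missing values on model variables
    are listwise-deleted), a :class:`SampleMoments`, or a dict of group label
    -> SampleMoments.  ``n_scaling`` selects the (N-1) Wishart convention
    (default) or plain N for the chi-square scaling.
    """
    if n_scaling not in ("n-1", "n"):
        raise ValueError("n_scaling must be 'n-1' or 'n'")
    spec = apply_identification(spec) if not spec.identified else spec
    moments, labels = _prepare_groups(spec, data, group)
    n_groups = len(labels)
    df = model_df(spec, n_groups)

    factor = {g: (m.n - 1 if n_scaling == "n-1" else m.n) for g, m in moments.items()}
    total = sum(factor.values())
    weights = {g: factor[g] / total for g in labels}

    tmpl = _build_template(spec, labels)
    d, pid_factor = _scaling_vector(tmpl, moments, weights)
    scaled_tmpl, scaled_moments = _scaled_problem(tmpl, moments, d)
    theta0_scaled = _start_values(scaled_tmpl, scaled_moments)
    fun = _objective_factory(scaled_tmpl, scaled_moments, weights)

    bounds = [
        (1e-10, None) if pid in scaled_tmpl.variance_pids else (None, None)
        for pid in range(scaled_tmpl.npar)
    ]
    if tmpl.npar:
        res = optimize.minimize(
            fun, theta0_scaled, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                     "ftol": 1e-14, "gtol": 1e-9},
        )
        theta_scaled = res.x
        f_min, grad = fun(theta_scaled)
        grad_norm = float(np.max(np.abs(grad)))
        converged = bool(res.success or grad_norm < 1e-5)
        theta = theta_scaled * pid_factor
        theta0 = theta0_scaled * pid_factor
    else:
        theta = theta0 = theta0_scaled
        f_min, _ = fun(theta)
        grad_norm = 0.0
        converged = True
    if not converged:
        log.warning("fit did not converge: gradient max-norm %.3g (%s)",
                    grad_norm, getattr(res, "message", ""))
    f_min = max(f_min, 0.0)
    chisq = max(total * f_min, 0.0)

    rows = tmpl.rows.copy()
    for g in labels:
        for slot in tmpl.slots[g]:
            est = theta[slot.pid] if slot.pid >= 0 else slot.value
            rows.loc[slot.row, "estimate"] = est
            if slot.pid >= 0:
                rows.loc[slot.row, "start"] = theta0[slot.pid]

    n_total = sum(m.n for m in moments.values())
    return FittedModel(
        spec=spec, params=rows, fml=float(f_min), chisq=float(chisq), df=df,
        converged=converged, per_group_moments=moments, group_labels=labels,
        n_total=n_total, n_groups=n_groups, grad_norm=grad_norm,
        n_scaling=n_scaling, _template=tmpl, _theta=theta,
    )


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def standard_errors(fitted: FittedModel) -> pd.DataFrame:
    """Fill Wald standard errors, z statistics and two-sided normal p-values.

    The observed information is the numerical Hessian (central differences of
    the analytic gradient) of the chi-square/2-scaled objective; a singular
    information matrix yields per-parameter NA with a warning rather than an
    error.
    """
    if not fitted.converged:
        raise ConvergenceError("cannot compute standard errors on a non-converged fit")
    tmpl = fitted._template
    if tmpl.npar == 0:
        return fitted.params
    moments = fitted.per_group_moments
    factor = {g: (m.n - 1 if fitted.n_scaling == "n-1" else m.n)
              for g, m in moments.items()}
    total = sum(factor.values())
    weights = {g: factor[g] / total for g in fitted.group_labels}
    fun = _objective_factory(tmpl, moments, weights)
    theta = fitted._theta
    npar = tmpl.npar
    scale = total / 2.0

    H = np.zeros((npar, npar))
    for k in range(npar):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        _, gp = fun(tp)
        _, gm = fun(tm)
        H[k, :] = (gp - gm) / (2.0 * h)
    H = scale * (H + H.T) / 2.0

    se = np.full(npar, np.nan)
    try:
        cov = linalg.inv(H)
        d = np.diag(cov)
        bad = d <= 0
        if bad.any():
            warnings.warn("non-positive information diagonal for some parameters; SEs set to NA")
        se[~bad] = np.sqrt(d[~bad])
    except linalg.LinAlgError:
        warnings.warn("singular information matrix; all SEs set to NA")

    rows = fitted.params
    for g in fitted.group_labels:
        for slot in tmpl.slots[g]:
            if slot.pid < 0:
                continue
            s = se[slot.pid]
            rows.loc[slot.row, "se"] = s
            if np.isfinite(s) and s > 0:
                z = rows.loc[slot.row, "estimate"] / s
                rows.loc[slot.row, "z"] = z
                rows.loc[slot.row, "pvalue"] = 2.0 * stats.norm.sf(abs(z))
    return rows


# ---------------------------------------------------------------------------
# standardized solution
# ---------------------------------------------------------------------------

def standardized_solution(fitted: FittedModel) -> pd.DataFrame:
    """Fill ``std_estimate``: every directed coefficient b(x -> y) becomes
    b * sd(x)/sd(y) with model-implied standard deviations, covariances
    become correlations, and variances become proportions of the implied
    variance (so the variance of a standardized exogenous latent is 1)."""
    if not fitted.converged:
        raise ConvergenceError("cannot standardize a non-converged fit")
    tmpl = fitted._template
    rows = fitted.params
    idx = {n: k for k, n in enumerate(tmpl.names)}
    for g in fitted.group_labels:
        A, S, _ = _fill(tmpl, fitted._theta, g)
        t = tmpl.t
        B = linalg.solve(np.eye(t) - A, np.eye(t))
        V = B @ S @ B.T
        var = np.diag(V).copy()
        if np.any(var <= 0):
            bad = [tmpl.names[k] for k in np.where(var <= 0)[0]]
            raise ModelError(f"zero or negative implied variance for {bad}")
        sd = np.sqrt(var)
        for slot in tmpl.slots[g]:
            r = rows.loc[slot.row]
            est = r["estimate"]
            if r["op"] == "~1":
                continue
            li, ri = idx[r["lhs"]], idx[r["rhs"]]
            if r["op"] == REGRESSED_ON or r["op"] == COMPOSED_OF:
                stdv = est * sd[ri] / sd[li]       # predictor rhs -> response lhs
            elif r["op"] == MEASURED_BY:
                stdv = est * sd[li] / sd[ri]       # latent lhs -> indicator rhs
            else:
                if li == ri:
                    stdv = est / var[li]
                else:
                    stdv = est / (sd[li] * sd[ri])
            rows.loc[slot.row, "std_estimate"] = stdv
    return rows


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def factor_scores(fitted: FittedModel, data: pd.DataFrame, group: Optional[str] = None) -> pd.DataFrame:
    """Per-row scores for every latent and composite variable.

    Latent scores use the regression method ``Sigma_Lx Sigma_xx^-1 (x - xbar)``
    on the model-implied covariances; composite scores are the fitted weighted
    sum of their (centered) causes, cause scores computed recursively.  Rows
    with missing indicator values are skipped with a warning.
    """
    if not fitted.converged:
        raise ConvergenceError("cannot score a non-converged fit")
    tmpl = fitted._template
    spec = fitted.spec
    obs = list(spec.observed)
    gcol = group or spec.groups
    unmeasured = list(spec.unmeasured)

    complete = data.dropna(subset=obs)
    skipped = data.index.difference(complete.index)
    if len(skipped):
        warnings.warn(
            f"{len(skipped)} rows skipped for missing indicator values "
            f"(indices {list(skipped[:10])}{'...' if len(skipped) > 10 else ''})"
        )

    out = pd.DataFrame(index=complete.index, columns=unmeasured, dtype=float)
    if gcol is not None and gcol in complete.columns and len(fitted.group_labels) > 1:
        parts = [(g, sub) for g, sub in complete.groupby(gcol, sort=False)]
    else:
        parts = [(fitted.group_labels[0], complete)]

    idx = {n: k for k, n in enumerate(tmpl.names)}
    obs_pos = [idx[v] for v in obs]
    for g, sub in parts:
        if g not in fitted.group_labels:
            raise ModelError(f"group {g!r} was not part of the fit")
        A, S, _ = _fill(tmpl, fitted._theta, g)
        t = tmpl.t
        B = linalg.solve(np.eye(t) - A, np.eye(t))
        V = B @ S @ B.T
        xbar = fitted.per_group_moments[g].means
        X = sub.loc[:, obs].to_numpy(dtype=float) - xbar

        lat_pos = [idx[v] for v in spec.latents]
        scores = {}
        if lat_pos:
            Sxx = V[np.ix_(obs_pos, obs_pos)]
            Slx = V[np.ix_(lat_pos, obs_pos)]
            L = X @ linalg.solve(Sxx, Slx.T)
            for k, name in enumerate(spec.latents):
                scores[name] = L[:, k]
        for v, col in zip(obs, X.T):
            scores[v] = col

        # composites in dependency order: weighted sum of composed-of causes
        remaining = list(spec.composites)
        while remaining:
            progressed = False
            for comp in list(remaining):
                causes = spec.causes_of(comp)
                if all(c.rhs in scores for c in causes):
                    vals = np.zeros(len(sub))
                    for c in causes:
                        w = fitted.estimate(comp, COMPOSED_OF, c.rhs, group=g)
                        vals += w * scores[c.rhs]
                    scores[comp] = vals
                    remaining.remove(comp)
                    progressed = True
            if not progressed:  # pragma: no cover - DAG guarantees progress
                raise ModelError("circular composite definitions")
        for name in unmeasured:
            out.loc[sub.index, name] = scores[name]
    return out


# ---------------------------------------------------------------------------
# fit indices and model comparison
# ---------------------------------------------------------------------------

def _independence_chisq(fitted: FittedModel) -> tuple[float, int]:
    """Baseline (independence) model: free variances, zero covariances.

    Its ML solution is closed-form (Sigma = diag(S)), giving per group
    F_b = -ln|R| with R the sample correlation matrix."""
    T_b = 0.0
    df_b = 0
    for g, m in fitted.per_group_moments.items():
        sd = np.sqrt(np.diag(m.cov))
        R = m.cov / np.outer(sd, sd)
        sign, logdet_r = np.linalg.slogdet(R)
        if sign <= 0:
            raise ModelError("sample correlation matrix is singular")
        factor = m.n - 1 if fitted.n_scaling == "n-1" else m.n
        T_b += factor * (-logdet_r)
        p = len(m.var_order)
        df_b += p * (p - 1) // 2
    return T_b, df_b


def fit_indices(fitted: FittedModel, baseline: Optional[FittedModel] = None) -> dict:
    """Chi-square, df, p-value and the comparative fit index.

    CFI = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0), clipped to [0, 1];
    the default baseline is the independence model on the same moments.
    """
    T, df = fitted.chisq, fitted.df
    if baseline is None:
        T_b, df_b = _independence_chisq(fitted)
    else:
        T_b, df_b = baseline.chisq, baseline.df
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    if T_b <= df_b:
        warnings.warn("baseline chi-square does not exceed its df; CFI reported as 1")
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    cfi = float(min(max(cfi, 0.0), 1.0))
    pvalue = float(stats.chi2.sf(T, df)) if df > 0 else float("nan")
    return {"chisq": float(T), "df": int(df), "pvalue": pvalue, "cfi": cfi}


def chisq_diff_test(nested: FittedModel, full: FittedModel) -> dict:
    """Likelihood-ratio comparison of two nested fits on the same data."""
    if set(nested.per_group_moments) != set(full.per_group_moments):
        raise ModelError("models were fitted to different groups")
    for g in nested.per_group_moments:
        a, b = nested.per_group_moments[g], full.per_group_moments[g]
        if a.n != b.n or a.var_order != b.var_order or not np.allclose(a.cov, b.cov):
            raise ModelError("models were fitted to different datasets")
    delta_df = nested.df - full.df
    if delta_df == 0:
        raise ModelError("models have equal df: not a nested comparison")
    if delta_df < 0:
        raise ModelError("'nested' model must have more df than 'full'")
    delta = nested.chisq - full.chisq
    if delta < -1e-6:
        warnings.warn(
            f"nested model fits better than the full model (delta chisq = {delta:.3g}); "
            "check convergence"
        )
    delta = max(delta, 0.0)
    return {
        "delta_chisq": float(delta),
        "delta_df": int(delta_df),
        "pvalue": float(stats.chi2.sf(delta, delta_df)),
    }
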