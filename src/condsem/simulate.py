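"""Gaussian data generation from any model with stated true parameters.

A :class:`TrueModel` pairs an identified model specification with a value for
every free parameter; the generator draws multivariate-normal rows from the
model-implied covariance, so the model fitted back to its own simulation is
correctly specified by construction.  The packaged fixtures emulate the
shorebird case-study data: two strongly correlated energy-stores measures
(r around 0.9), three colour components whose intercorrelation differs by age
group, five weakly intercorrelated physiological variables, structural-size
and handling confounders, and a continuous area-level survival response with
a density covariate.  Fixture values are arbitrary but fixed here, in one
source of truth, and chosen so that the composite condition index has two
dominant contributors (size-corrected mass, corticosterone) and four weak
ones, with density depressing condition and condition raising survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import linalg

from .engine import SampleMoments, _build_template, _fill
from .model import ModelError, ModelSpec, apply_identification, parse_model

__all__ = ["TrueModel", "simulate_dataset", "fixture_true_model", "FIXTURES"]

FIXTURES = ("energy", "colour_grouped", "condition", "full")

_SINGLE = ""


@dataclass
class TrueModel:
    """An identified spec plus true values for every free parameter.

    ``values`` maps ``"lhs op rhs"`` keys to reals; for grouped models it maps
    group label -> {key: value}.  The implied covariance per group is cached.
    """

    spec: ModelSpec
    values: Mapping
    group_labels: tuple = (_SINGLE,)
    _implied: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.spec.identified:
            self.spec = apply_identification(self.spec)
        if self.spec.groups is not None and tuple(self.group_labels) == (_SINGLE,):
            self.group_labels = tuple(self.values.keys())
        self._check_complete()

    def _per_group(self, g) -> Mapping[str, float]:
        if self.spec.groups is None:
            return self.values
        return self.values[g]

    def _check_complete(self) -> None:
        for g in self.group_labels:
            vals = self._per_group(g)
            for t in self.spec.terms:
                if t.free and _lookup(vals, t) is None:
                    raise ModelError(
                        f"no true value for free parameter {_key(t)!r}"
                        + (f" in group {g!r}" if self.spec.groups else "")
                    )

    def theta_template(self):
        """The engine template plus the true parameter vector (per group)."""
        tmpl = _build_template(self.spec, list(self.group_labels))
        theta = np.zeros(tmpl.npar)
        for g in self.group_labels:
            vals = self._per_group(g)
            for slot, term in zip(tmpl.slots[g], self.spec.terms):
                if slot.pid >= 0:
                    theta[slot.pid] = _lookup(vals, term)
        return tmpl, theta

    def implied_covariance(self, group=_SINGLE) -> tuple[np.ndarray, tuple]:
        """Model-implied covariance of the observed variables for one group."""
        if group not in self._implied:
            tmpl, theta = self.theta_template()
            A, S, _ = _fill(tmpl, theta, group)
            t = tmpl.t
            B = linalg.solve(np.eye(t) - A, np.eye(t))
            V = B @ S @ B.T
            oi = tmpl.obs_idx
            sigma = V[np.ix_(oi, oi)]
            eigmin = float(np.linalg.eigvalsh(sigma).min())
            if eigmin <= 0:
                raise ModelError(
                    f"implied covariance for group {group!r} is not positive "
                    f"definite (min eigenvalue {eigmin:.3g}); check the stated "
                    "exogenous covariances"
                )
            self._implied[group] = (sigma, tuple(self.spec.observed))
        return self._implied[group]

    def true_value(self, lhs: str, op: str, rhs: str, group=_SINGLE) -> float:
        vals = self._per_group(group)
        v = vals.get(f"{lhs} {op} {rhs}")
        if v is None and op == "~~":
            v = vals.get(f"{rhs} {op} {lhs}")
        if v is None:
            raise KeyError(f"no true value for {lhs} {op} {rhs}")
        return float(v)


def _key(term) -> str:
    return f"{term.lhs} {term.op} {term.rhs}"


def _lookup(vals: Mapping, term) -> Optional[float]:
    """Fetch a true value; covariance keys are order-insensitive."""
    v = vals.get(f"{term.lhs} {term.op} {term.rhs}")
    if v is None and term.op == "~~":
        v = vals.get(f"{term.rhs} {term.op} {term.lhs}")
    return v


def simulate_dataset(
    model: TrueModel,
    n: Union[int, Mapping],
    seed: int,
    stream: int = 0,
) -> pd.DataFrame:
    """Draw multivariate-normal rows from the model-implied covariance.

    Deterministic per ``(seed, stream)``: a single seed fans out to
    per-dataset substreams via the counter, so replicate datasets of a
    simulation study are individually reproducible.  Grouped models take
    ``n`` per group (one integer, or a mapping group -> rows) and gain a
    grouping column.  Means are zero unless the model carries a mean
    structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))
    frames = []
    grouped = model.spec.groups is not None
    for g in model.group_labels:
        n_g = int(n[g]) if isinstance(n, Mapping) else int(n)
        if n_g < 1:
            raise ValueError("need at least one row per group")
        sigma, order = model.implied_covariance(g)
        chol = np.linalg.cholesky(sigma)
        x = rng.standard_normal((n_g, len(order))) @ chol.T
        frame = pd.DataFrame(x, columns=list(order))
        if grouped:
            frame[model.spec.groups] = g
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]


def moments_from_true(model: TrueModel, n: int = 10_000) -> dict:
    """Exact population moments packaged as SampleMoments (for noiseless fits)."""
    out = {}
    for g in model.group_labels:
        sigma, order = model.implied_covariance(g)
        out[g] = SampleMoments(cov=sigma, means=np.zeros(len(order)), n=n, var_order=order)
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _cov_block(names, variances, corr):
    """Helper building '~~' value entries from a correlation specification."""
    vals = {}
    sd = {v: np.sqrt(variances[v]) for v in names}
    for i, a in enumerate(names):
        vals[f"{a} ~~ {a}"] = variances[a]
        for b in names[i + 1:]:
            r = corr.get((a, b), corr.get((b, a), 0.0))
            vals[f"{a} ~~ {b}"] = r * sd[a] * sd[b]
    return vals


_SIZES = ("tarsus", "head", "wing")
_PHYS = ("buffy_coat", "haematocrit", "cholesterol", "uric_acid", "corticosterone")


def _energy_fixture() -> TrueModel:
    spec = parse_model(
        "energy =~ mass + ratio\n"
        "energy ~ tarsus + head + wing\n"
    )
    vals = {
        "energy =~ ratio": 0.95,
        "energy ~ tarsus": 0.45,
        "energy ~ head": 0.25,
        "energy ~ wing": 0.15,
        "energy ~~ energy": 0.50,
        "mass ~~ mass": 0.10,
        "ratio ~~ ratio": 0.10,
    }
    vals.update(_cov_block(
        _SIZES, {v: 1.0 for v in _SIZES},
        {(a, b): 0.5 for i, a in enumerate(_SIZES) for b in _SIZES[i + 1:]},
    ))
    return TrueModel(spec=apply_identification(spec), values=vals)


def _colour_fixture() -> TrueModel:
    spec = parse_model("colour =~ hue + chroma + luminance", groups="age_class")
    adult = {
        "colour =~ chroma": -0.95,
        "colour =~ luminance": 0.95,
        "colour ~~ colour": 0.80,
        "hue ~~ hue": 0.20,
        "chroma ~~ chroma": 0.25,
        "luminance ~~ luminance": 0.25,
    }
    subadult = {
        "colour =~ chroma": 1.20,
        "colour =~ luminance": 1.10,
        "colour ~~ colour": 0.15,
        "hue ~~ hue": 0.90,
        "chroma ~~ chroma": 0.60,
        "luminance ~~ luminance": 0.65,
    }
    return TrueModel(
        spec=apply_identification(spec),
        values={"adult": adult, "subadult": subadult},
        group_labels=("adult", "subadult"),
    )


#: composite-cause total effects of the condition fixture: two dominant
#: contributors and four near zero, density negative, condition -> survival
#: positive.  gamma * weight gives the per-variable slope on survival.
_CONDITION_GAMMA = 0.4
_CONDITION_WEIGHTS = {
    "scm": 1.0,            # fixed scale; total effect 0.40
    "buffy_coat": 0.10,    # total effect 0.04
    "haematocrit": 0.05,
    "cholesterol": 0.10,
    "uric_acid": 0.05,
    "corticosterone": -0.75,  # total effect -0.30
}
_CONDITION_DENSITY = -0.40


def _condition_fixture() -> TrueModel:
    from .builders import build_model

    spec = build_model("condition_composite")
    exo = _SIZES + _PHYS + ("density",)
    variances = {v: 1.0 for v in exo}
    corr = {}
    for i, a in enumerate(_SIZES):
        for b in _SIZES[i + 1:]:
            corr[(a, b)] = 0.5
    for i, a in enumerate(_PHYS):
        for b in _PHYS[i + 1:]:
            corr[(a, b)] = 0.10
    for s in _SIZES:            # corticosterone tracks structural size
        corr[(s, "corticosterone")] = 0.30
        for p in _PHYS[:-1]:
            corr[(s, p)] = 0.10
    for p in _PHYS:
        corr[(p, "density")] = 0.10

    vals = _cov_block(exo, variances, corr)
    vals.update({
        "scm ~ tarsus": 0.45,
        "scm ~ head": 0.25,
        "scm ~ wing": 0.15,
        "scm ~~ scm": 0.50,                 # residual (size-free) mass variation
        # residual mass correlates with the other condition measures
        "scm ~~ buffy_coat": 0.15,
        "scm ~~ haematocrit": 0.10,
        "scm ~~ cholesterol": 0.15,
        "scm ~~ uric_acid": 0.10,
        "scm ~~ corticosterone": -0.10,
        "scm ~~ density": -0.25,
        "condition ~ density": _CONDITION_DENSITY,
        "survival ~ condition": _CONDITION_GAMMA,
        "survival ~~ survival": 0.80,
    })
    for cause, w in _CONDITION_WEIGHTS.items():
        if cause != "scm":
            vals[f"condition <~ {cause}"] = w
    return TrueModel(spec=spec, values=vals)


def _full_fixture() -> TrueModel:
    from .builders import build_model

    spec = build_model("full_model")
    exo = _SIZES + ("handling_time", "sex", "age_class", "bill_tip", "density")
    corr = {}
    for i, a in enumerate(_SIZES):
        for b in _SIZES[i + 1:]:
            corr[(a, b)] = 0.5
    for s in _SIZES:
        corr[(s, "sex")] = 0.35            # size dimorphism
        corr[(s, "bill_tip")] = 0.15
    corr[("handling_time", "density")] = 0.10
    vals = _cov_block(exo, {v: 1.0 for v in exo}, corr)
    vals.update({
        "energy =~ ratio": 0.95,
        "energy ~ tarsus": 0.40,
        "energy ~ head": 0.20,
        "energy ~ wing": 0.15,
        "energy ~ handling_time": -0.15,
        "energy ~~ energy": 0.50,
        "mass ~~ mass": 0.08,
        "ratio ~~ ratio": 0.08,
        "hue_c ~ sex": -0.25,
        "hue_c ~ bill_tip": 0.22,
        "hue_c ~~ hue_c": 0.85,
        "condition ~ density": -0.40,
        "survival ~ condition": 0.40,
        "survival ~~ survival": 0.80,
    })
    phys_effects = {
        "buffy_coat": {"handling_time": 0.15, "sex": 0.10, "age_class": 0.10},
        "haematocrit": {"handling_time": -0.10, "sex": 0.15, "age_class": 0.10},
        "cholesterol": {"handling_time": 0.10, "sex": 0.10, "age_class": -0.10},
        "uric_acid": {"handling_time": 0.20, "sex": 0.05, "age_class": 0.05},
        "corticosterone": {"handling_time": 0.30, "sex": -0.10, "age_class": 0.10},
    }
    for p, eff in phys_effects.items():
        for conf, b in eff.items():
            vals[f"{p}_c ~ {conf}"] = b
        vals[f"{p}_c ~~ {p}_c"] = 0.85
    vals["haematocrit_c ~~ cholesterol_c"] = 0.20
    weights = {
        "hue_c": 0.10,
        "buffy_coat_c": 0.10,
        "haematocrit_c": 0.05,
        "cholesterol_c": 0.10,
        "uric_acid_c": 0.05,
        "corticosterone_c": -0.60,
    }
    for cause, w in weights.items():
        vals[f"condition <~ {cause}"] = w
    return TrueModel(spec=spec, values=vals)


def fixture_true_model(kind: str) -> TrueModel:
    """Return one of the packaged oystercatcher-like generating models."""
    builders = {
        "energy": _energy_fixture,
        "colour_grouped": _colour_fixture,
        "condition": _condition_fixture,
        "full": _full_fixture,
    }
    if kind not in builders:
        raise ModelError(f"unknown fixture {kind!r}; choose from {', '.join(FIXTURES)}")
    return builders[kind]()


def condition_true_effects() -> dict:
    """True per-variable total effects on survival in the condition fixture."""
    return {
        ("mass" if c == "scm" else c): _CONDITION_GAMMA * w
        for c, w in _CONDITION_WEIGHTS.items()
    }
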