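"""Declarative SEM model descriptions.

A model is written in a line-oriented syntax closely following the de-facto
SEM convention used by most R and Python SEM software, so that measurement
("latent measured by indicators"), structural ("response regressed on
predictors"), composite ("index composed of causes") and covariance terms can
be translated line-for-line from published model listings:

    energy =~ mass + ratio        # latent measured by two indicators
    energy ~ tarsus + head        # covariates regressing on the latent
    condition <~ energy + cort    # unknown-weight composite
    survival ~ condition
    haematocrit ~~ cholesterol    # correlated residuals
    1*x, 0.5*x                    # fixed parameter values
    a*x                           # labelled (equality-constrained) parameter

``parse_model`` turns text into a :class:`ModelSpec`; ``apply_identification``
adds the scale-setting and variance conventions needed for maximum-likelihood
fitting; ``model_df`` counts degrees of freedom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "ModelError",
    "VariableDecl",
    "PathTerm",
    "ModelSpec",
    "parse_model",
    "serialize",
    "apply_identification",
    "model_df",
    "MEASURED_BY",
    "REGRESSED_ON",
    "COMPOSED_OF",
    "COVARIES_WITH",
]

MEASURED_BY = "=~"
REGRESSED_ON = "~"
COMPOSED_OF = "<~"
COVARIES_WITH = "~~"

#: operators ordered so that longer ones are matched before ``~``
_OPS = (MEASURED_BY, COVARIES_WITH, COMPOSED_OF, REGRESSED_ON)

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")

#: parameter class of each operator, used for cross-group equality constraints
OP_CLASS = {
    MEASURED_BY: "loadings",
    REGRESSED_ON: "regressions",
    COMPOSED_OF: "composites",
    COVARIES_WITH: "residuals",
}


class ModelError(ValueError):
    """Raised for malformed, conflicting or unidentifiable model descriptions."""


@dataclass(frozen=True)
class VariableDecl:
    name: str
    role: str  # "observed" | "latent" | "composite"

    def __post_init__(self) -> None:
        if self.role not in ("observed", "latent", "composite"):
            raise ModelError(f"unknown variable role {self.role!r}")


@dataclass(frozen=True)
class PathTerm:
    """One edge of the model graph.

    ``lhs op rhs`` with the operator drawn from the four path kinds.  A term is
    either free (``fixed_value is None``) or fixed, never both; ``label`` names
    a free parameter so that equally-labelled terms share one parameter.
    """

    lhs: str
    op: str
    rhs: str
    fixed_value: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ModelError(f"unknown operator {self.op!r}")
        if self.fixed_value is not None and self.label is not None:
            raise ModelError(
                f"term {self.lhs} {self.op} {self.rhs} cannot be both fixed and labelled"
            )

    @property
    def free(self) -> bool:
        return self.fixed_value is None

    def key(self) -> tuple:
        """Order-insensitive key for covariances, directed key otherwise."""
        if self.op == COVARIES_WITH:
            a, b = sorted((self.lhs, self.rhs))
            return (self.op, a, b)
        return (self.op, self.lhs, self.rhs)


@dataclass(frozen=True)
class ModelSpec:
    variables: tuple[VariableDecl, ...]
    terms: tuple[PathTerm, ...]
    groups: Optional[str] = None
    group_equal: frozenset = frozenset()
    meanstructure: bool = False
    identified: bool = False

    # -- convenience views -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def role(self, name: str) -> str:
        for v in self.variables:
            if v.name == name:
                return v.role
        raise KeyError(name)

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "observed")

    @property
    def latents(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "latent")

    @property
    def composites(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "composite")

    @property
    def unmeasured(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role != "observed")

    def loadings_of(self, latent: str) -> tuple[PathTerm, ...]:
        return tuple(t for t in self.terms if t.op == MEASURED_BY and t.lhs == latent)

    def causes_of(self, composite: str) -> tuple[PathTerm, ...]:
        return tuple(t for t in self.terms if t.op == COMPOSED_OF and t.lhs == composite)

    def regressions_on(self, var: str) -> tuple[PathTerm, ...]:
        return tuple(t for t in self.terms if t.op == REGRESSED_ON and t.lhs == var)

    def directed_edges(self) -> list[tuple[str, str]]:
        """(cause, effect) pairs of the directed part of the graph."""
        edges = []
        for t in self.terms:
            if t.op == MEASURED_BY:
                edges.append((t.lhs, t.rhs))  # latent -> indicator
            elif t.op in (REGRESSED_ON, COMPOSED_OF):
                edges.append((t.rhs, t.lhs))  # predictor/cause -> target
        return edges

    def endogenous(self) -> set[str]:
        return {effect for _, effect in self.directed_edges()}

    def exogenous(self) -> set[str]:
        return set(self.names) - self.endogenous()


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_item(item: str, lineno: int) -> tuple[str, Optional[float], Optional[str]]:
    """Parse one right-hand-side item, e.g. ``x``, ``1*x`` or ``a*x``."""
    item = item.strip()
    fixed = None
    label = None
    if "*" in item:
        prefix, _, name = item.partition("*")
        prefix, name = prefix.strip(), name.strip()
        try:
            fixed = float(prefix)
        except ValueError:
            if not _NAME_RE.match(prefix):
                raise ModelError(f"line {lineno}: bad parameter prefix {prefix!r}")
            label = prefix
    else:
        name = item
    if not _NAME_RE.match(name):
        raise ModelError(f"line {lineno}: bad variable name {name!r}")
    return name, fixed, label


def _merge_terms(terms: Iterable[PathTerm]) -> list[PathTerm]:
    """Deduplicate terms; conflicting fixed values are an error, a fixed term
    wins over an otherwise-identical free one."""
    out: dict[tuple, PathTerm] = {}
    for t in terms:
        k = t.key()
        if k not in out:
            out[k] = t
            continue
        prev = out[k]
        if prev.fixed_value is not None and t.fixed_value is not None:
            if prev.fixed_value != t.fixed_value:
                raise ModelError(
                    f"conflicting fixed values for {t.lhs} {t.op} {t.rhs}: "
                    f"{prev.fixed_value} vs {t.fixed_value}"
                )
        elif t.fixed_value is not None:
            out[k] = t
        elif t.label is not None and prev.fixed_value is None:
            out[k] = t
    return list(out.values())


def parse_model(
    text: str,
    groups: Optional[str] = None,
    group_equal: Iterable[str] = (),
    meanstructure: bool = False,
) -> ModelSpec:
    """Parse model-syntax text into a :class:`ModelSpec`.

    Undeclared names appearing on the left of ``=~`` become latent, on the
    left of ``<~`` composite, and observed otherwise.  ``#`` starts a comment.
    """
    if not text or not text.strip():
        raise ModelError("empty model description")

    roles: dict[str, str] = {}
    order: list[str] = []
    terms: list[PathTerm] = []

    def note(name: str, role: str, lineno: int) -> None:
        prev = roles.get(name)
        if prev is None:
            roles[name] = role
            order.append(name)
        elif role != "observed" and prev == "observed":
            roles[name] = role
        elif role != "observed" and prev != "observed" and prev != role:
            raise ModelError(
                f"line {lineno}: {name!r} declared both {prev} and {role}"
            )

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        op = next((o for o in _OPS if o in line), None)
        if op is None:
            raise ModelError(f"line {lineno}: no operator found in {raw!r}")
        lhs_txt, rhs_txt = line.split(op, 1)
        lhs = lhs_txt.strip()
        if not _NAME_RE.match(lhs):
            raise ModelError(f"line {lineno}: bad left-hand side {lhs!r}")
        if not rhs_txt.strip():
            raise ModelError(f"line {lineno}: empty right-hand side")
        if op == MEASURED_BY:
            note(lhs, "latent", lineno)
        elif op == COMPOSED_OF:
            note(lhs, "composite", lineno)
        else:
            note(lhs, "observed", lineno)
        for item in rhs_txt.split("+"):
            name, fixed, label = _parse_item(item, lineno)
            note(name, "observed", lineno)
            terms.append(PathTerm(lhs, op, name, fixed_value=fixed, label=label))

    spec = ModelSpec(
        variables=tuple(VariableDecl(n, roles[n]) for n in order),
        terms=tuple(_merge_terms(terms)),
        groups=groups,
        group_equal=frozenset(group_equal),
        meanstructure=meanstructure,
    )
    _validate(spec)
    return spec


def _validate(spec: ModelSpec) -> None:
    names = [v.name for v in spec.variables]
    if len(names) != len(set(names)):
        raise ModelError("duplicate variable names")
    for t in spec.terms:
        for n in (t.lhs, t.rhs):
            if n not in names:
                raise ModelError(f"term references undeclared variable {n!r}")
    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_edges_from(spec.directed_edges())
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ModelError(f"directed part of the model contains a cycle: {cycle}")


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def apply_identification(spec: ModelSpec, std_lv: bool = False) -> ModelSpec:
    """Return a copy of *spec* with scale-setting and variance conventions.

    For every latent without a user-set scale constraint the first listed
    loading is fixed to 1 (``std_lv=True`` fixes the latent variance to 1
    instead).  For every composite the first cause weight is fixed to 1
    unless another cause (or an outgoing path) is already fixed, and the
    composite residual variance is pinned to exactly 0.  All variables gain
    a variance term; exogenous observed variables (and exogenous latents)
    gain free pairwise covariances unless explicitly suppressed.

    The operation is idempotent.
    """
    terms = list(spec.terms)
    have = {t.key(): t for t in terms}

    def has_var(name: str) -> Optional[PathTerm]:
        return have.get((COVARIES_WITH, name, name))

    def add(term: PathTerm) -> None:
        terms.append(term)
        have[term.key()] = term

    # latents: scale setting
    for lat in spec.latents:
        loadings = spec.loadings_of(lat)
        if not loadings:
            raise ModelError(f"latent {lat!r} has no indicators")
        var_term = has_var(lat)
        scale_fixed = any(not t.free for t in loadings) or (
            var_term is not None and not var_term.free
        )
        if not scale_fixed:
            if std_lv:
                add(PathTerm(lat, COVARIES_WITH, lat, fixed_value=1.0))
            else:
                first = loadings[0]
                idx = terms.index(first)
                new = replace(first, fixed_value=1.0, label=None)
                terms[idx] = new
                have[new.key()] = new

    # composites: scale + zero residual
    for comp in spec.composites:
        causes = spec.causes_of(comp)
        if not causes:
            raise ModelError(f"composite {comp!r} has no contributing causes")
        outgoing_fixed = any(
            not t.free
            for t in spec.terms
            if t.op == REGRESSED_ON and t.rhs == comp
        )
        if not any(not t.free for t in causes) and not outgoing_fixed:
            first = causes[0]
            idx = terms.index(first)
            new = replace(first, fixed_value=1.0, label=None)
            terms[idx] = new
            have[new.key()] = new
        var_term = has_var(comp)
        if var_term is None:
            add(PathTerm(comp, COVARIES_WITH, comp, fixed_value=0.0))
        elif var_term.fixed_value != 0.0:
            raise ModelError(
                f"composite {comp!r} residual variance must be fixed to 0, "
                f"found {var_term.fixed_value}"
            )

    # variances for every variable
    for v in spec.variables:
        if has_var(v.name) is None:
            add(PathTerm(v.name, COVARIES_WITH, v.name))

    # free covariances among exogenous observed, and among exogenous latents
    exo = spec.exogenous()
    exo_obs = [n for n in spec.observed if n in exo]
    exo_lat = [n for n in spec.latents if n in exo]
    for block in (exo_obs, exo_lat):
        for i, a in enumerate(block):
            for b in block[i + 1:]:
                k = (COVARIES_WITH,) + tuple(sorted((a, b)))
                if k not in have:
                    add(PathTerm(a, COVARIES_WITH, b))

    out = replace(spec, terms=tuple(terms), identified=True)
    _validate(out)
    return out


# ---------------------------------------------------------------------------
# degrees of freedom
# ---------------------------------------------------------------------------

def count_free_parameters(spec: ModelSpec, n_groups: int = 1) -> int:
    """Number of distinct free parameters across all groups.

    Unlabelled free terms are replicated per group; labelled terms and terms
    whose parameter class is listed in ``group_equal`` are shared.
    """
    shared_labels = set()
    n_free_shared = 0
    n_free_per_group = 0
    for t in spec.terms:
        if not t.free:
            continue
        if t.label is not None:
            if t.label not in shared_labels:
                shared_labels.add(t.label)
                n_free_shared += 1
        elif OP_CLASS[t.op] in spec.group_equal:
            n_free_shared += 1
        else:
            n_free_per_group += 1
    n = n_free_shared + n_groups * n_free_per_group
    if spec.meanstructure:
        # saturated observed intercepts per group (latent/composite means 0)
        n += n_groups * len(spec.observed)
    return n


def model_df(spec: ModelSpec, n_groups: int = 1) -> int:
    """Model degrees of freedom: sample moments minus free parameters.

    Raises :class:`ModelError` when negative (under-identified model).
    """
    if not spec.identified:
        spec = apply_identification(spec)
    p = len(spec.observed)
    moments = n_groups * p * (p + 1) // 2
    if spec.meanstructure:
        moments += n_groups * p
    df = moments - count_free_parameters(spec, n_groups)
    if df < 0:
        raise ModelError(
            f"model is under-identified: {moments} sample moments but "
            f"{moments - df} free parameters (df = {df})"
        )
    return df


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def serialize(spec: ModelSpec) -> str:
    """Write *spec* back to model syntax; ``parse_model`` round-trips it."""
    lines = []
    for t in spec.terms:
        if t.fixed_value is not None:
            rhs = f"{t.fixed_value:g}*{t.rhs}"
        elif t.label is not None:
            rhs = f"{t.label}*{t.rhs}"
        else:
            rhs = t.rhs
        lines.append(f"{t.lhs} {t.op} {rhs}")
    return "\n".join(lines) + "\n"
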