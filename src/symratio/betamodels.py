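"""Beta and beta-mixture models for intra-genomic marker-ratio data.

The analysis variable is the per-cell proportion X = C_C100 : C_TOTAL, the
fraction of a cell's ITS2 rDNA copies belonging to ribotype C100.  Three
competing hypotheses describe the frequency distribution of X within a coral
colony:

* ``H0`` — a single population of genetically *heterogeneous* symbionts
  carrying a non-diagnostic polymorphism: ``X ~ Beta(a, b)`` with
  ``a > 1, b > 1`` (one interior mode).
* ``H1`` — two coexisting populations of genetically *homogeneous*
  symbionts: ``X ~ Beta(a, b)`` with ``a < 1, b < 1`` (U-shaped density,
  modes at the boundaries).
* ``H2`` — a mixture of homogeneous and heterogeneous populations,
  consistent with inter-lineage recombination:
  ``X ~ pi * Beta(a1, b1) + (1 - pi) * Beta(a2, b2)`` with ``0 < pi < 1``.

Each hypothesis is fitted by bounded maximum likelihood (L-BFGS-B with
analytic gradients) from a fixed, seedless grid of starting values, and the
candidates are compared with small-sample-corrected Akaike weights (AICc).
An Akaike weight above 0.90 is treated as unambiguous support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma

__all__ = [
    "RatioSample",
    "HypothesisSpec",
    "HypothesisFit",
    "ModelSelectionResult",
    "CellClassification",
    "HYPOTHESES",
    "log_beta_pdf",
    "clamp_ratios",
    "mixture_loglik",
    "default_starts",
    "fit_hypothesis",
    "aicc",
    "akaike_weights",
    "select_model",
    "classify_cells",
]

#: margin used to turn the hypotheses' strict inequalities into closed
#: boxes for the bounded optimizer
BOUND_MARGIN = 1e-3

#: default clamp distance for ratios observed at exactly 0 or 1
CLAMP_EPS = 1e-3


@dataclass
class RatioSample:
    """Per-cell marker ratios for one coral colony (branches pooled)."""

    colony_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("a ratio sample needs at least one cell")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("ratios must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class HypothesisSpec:
    """One candidate model: name, parameter count and box constraints.

    Parameter vectors are ``(a, b)`` for the single-beta hypotheses and
    ``(pi, a1, b1, a2, b2)`` for the two-component mixture.
    """

    name: str
    k: int
    bounds: tuple[tuple[float, float], ...]

    def contains(self, params: Sequence[float]) -> bool:
        p = np.asarray(params, dtype=float)
        if p.shape != (self.k,):
            return False
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return bool(np.all(p >= lo) and np.all(p <= hi))


HYPOTHESES: dict[str, HypothesisSpec] = {
    "H0": HypothesisSpec(
        "H0", 2, (((1.0 + BOUND_MARGIN), 200.0), ((1.0 + BOUND_MARGIN), 200.0))
    ),
    "H1": HypothesisSpec(
        "H1", 2, ((BOUND_MARGIN, 1.0 - BOUND_MARGIN), (BOUND_MARGIN, 1.0 - BOUND_MARGIN))
    ),
    "H2": HypothesisSpec(
        "H2",
        5,
        (
            (0.01, 0.99),
            (BOUND_MARGIN, 500.0),
            (BOUND_MARGIN, 500.0),
            (BOUND_MARGIN, 500.0),
            (BOUND_MARGIN, 500.0),
        ),
    ),
}


def log_beta_pdf(x, alpha: float, beta: float):
    """Log-density of Beta(alpha, beta) at ``x`` (scalar or array).

    Raises
    ------
    ValueError
        If any ``x`` lies outside the open interval (0, 1) or a shape
        parameter is non-positive.
    """
    x = np.asarray(x, dtype=float)
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shape parameters must be positive")
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("x must lie strictly inside (0, 1); clamp ratios first")
    out = (alpha - 1.0) * np.log(x) + (beta - 1.0) * np.log1p(-x) - betaln(alpha, beta)
    return out if out.ndim else float(out)


def clamp_ratios(values, policy: str = "fixed-eps", eps: float = CLAMP_EPS,
                 total_copies=None) -> np.ndarray:
    """Map boundary ratios into the open interval (0, 1).

    Observed ratios of exactly 0 (and potentially 1) occur — e.g. cells with a
    pure non-C100 rDNA array — but the beta likelihoods are undefined there.

    policy ``"fixed-eps"`` maps 0 to ``eps`` and 1 to ``1 - eps``;
    policy ``"half-copy"`` uses a per-cell ``eps_i = 1 / (2 * total_copies_i)``
    (half a marker copy), requiring ``total_copies``.  Interior values pass
    through unchanged.
    """
    x = np.asarray(values, dtype=float).copy()
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("ratios must lie in [0, 1]")
    if policy == "fixed-eps":
        e = np.full_like(x, float(eps))
    elif policy == "half-copy":
        if total_copies is None:
            raise ValueError("half-copy policy requires total_copies")
        e = 1.0 / (2.0 * np.asarray(total_copies, dtype=float))
    else:
        raise ValueError(f"unknown clamp policy: {policy!r}")
    x = np.where(x <= 0.0, e, x)
    x = np.where(x >= 1.0, 1.0 - e, x)
    return x


def mixture_loglik(values, spec: HypothesisSpec, params: Sequence[float]) -> float:
    """Log-likelihood of ``params`` under hypothesis ``spec``.

    Sum over cells of ``ln f(x)`` for the single-beta hypotheses, or
    ``ln[pi f1(x) + (1 - pi) f2(x)]`` for the mixture.  A non-finite result
    (e.g. from mass concentrated at a boundary) is returned as-is so callers
    can flag it; it is never silently replaced.
    """
    params = np.asarray(params, dtype=float)
    x = np.asarray(values, dtype=float)
    if spec.name in ("H0", "H1"):
        return float(np.sum(log_beta_pdf(x, params[0], params[1])))
    pi, a1, b1, a2, b2 = params
    l1 = np.log(pi) + log_beta_pdf(x, a1, b1)
    l2 = np.log1p(-pi) + log_beta_pdf(x, a2, b2)
    return float(np.sum(np.logaddexp(l1, l2)))


def _nll_grad(params: np.ndarray, x: np.ndarray, spec: HypothesisSpec):
    """Negative log-likelihood and its analytic gradient."""
    lx = np.log(x)
    l1mx = np.log1p(-x)
    n = x.size
    if spec.name in ("H0", "H1"):
        a, b = params
        ll = (a - 1) * lx.sum() + (b - 1) * l1mx.sum() - n * betaln(a, b)
        da = lx.sum() - n * (digamma(a) - digamma(a + b))
        db = l1mx.sum() - n * (digamma(b) - digamma(a + b))
        return -ll, -np.array([da, db])
    pi, a1, b1, a2, b2 = params
    lp1 = np.log(pi) + (a1 - 1) * lx + (b1 - 1) * l1mx - betaln(a1, b1)
    lp2 = np.log1p(-pi) + (a2 - 1) * lx + (b2 - 1) * l1mx - betaln(a2, b2)
    lm = np.logaddexp(lp1, lp2)
    r1 = np.exp(lp1 - lm)
    r2 = 1.0 - r1
    ll = lm.sum()
    dpi = r1.sum() / pi - r2.sum() / (1.0 - pi)
    da1 = np.sum(r1 * (lx - (digamma(a1) - digamma(a1 + b1))))
    db1 = np.sum(r1 * (l1mx - (digamma(b1) - digamma(a1 + b1))))
    da2 = np.sum(r2 * (lx - (digamma(a2) - digamma(a2 + b2))))
    db2 = np.sum(r2 * (l1mx - (digamma(b2) - digamma(a2 + b2))))
    return -ll, -np.array([dpi, da1, db1, da2, db2])


# fixed, seedless multi-start grids: deterministic fits without an RNG
_H0_SHAPE_GRID = (1.5, 3.0, 10.0, 50.0)
_H1_SHAPE_GRID = (0.1, 0.3, 0.5, 0.9)
_H2_PI_GRID = (0.2, 0.5, 0.8)
_H2_MEAN_GRID = (0.05, 0.5, 0.8, 0.95)
_H2_CONC_GRID = (5.0, 50.0)


def default_starts(spec: HypothesisSpec) -> list[np.ndarray]:
    """The fixed multi-start grid for a hypothesis.

    Single-beta hypotheses use all shape combinations from a small grid; the
    mixture pairs every two distinct component means (parameterised as
    ``a = m * c``, ``b = (1 - m) * c`` at concentration ``c``) with a grid of
    mixing proportions.
    """
    if spec.name == "H0":
        grid = _H0_SHAPE_GRID
        return [np.array([a, b]) for a in grid for b in grid]
    if spec.name == "H1":
        grid = _H1_SHAPE_GRID
        return [np.array([a, b]) for a in grid for b in grid]
    starts = []
    for m1, m2 in combinations(_H2_MEAN_GRID, 2):
        for c in _H2_CONC_GRID:
            for pi in _H2_PI_GRID:
                starts.append(
                    np.array([pi, m1 * c, (1 - m1) * c, m2 * c, (1 - m2) * c])
                )
    return starts


@dataclass
class HypothesisFit:
    """Result of a bounded multi-start maximum-likelihood fit."""

    spec: HypothesisSpec
    params: np.ndarray
    loglik: float
    aicc: float
    n: int
    n_starts: int
    converged: bool
    at_boundary: bool
    best_start: np.ndarray

    @property
    def component_means(self) -> np.ndarray:
        """Mean a/(a+b) of each fitted component (ascending for H2)."""
        if self.spec.name == "H2":
            _, a1, b1, a2, b2 = self.params
            return np.array([a1 / (a1 + b1), a2 / (a2 + b2)])
        a, b = self.params
        return np.array([a / (a + b)])


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    ``AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """Normalized model evidence w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).

    ``delta_i`` is each AICc minus the minimum, so the weights are invariant
    to adding a constant to every AICc.  Candidates with infinite AICc (failed
    fits) receive weight 0.
    """
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValueError("akaike_weights requires at least one AICc value")
    if np.all(np.isinf(a)):
        raise ValueError("all candidate AICc values are infinite")
    delta = a - np.min(a[np.isfinite(a)])
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(a)] = 0.0
    return w / w.sum()


def fit_hypothesis(
    sample: RatioSample,
    spec: HypothesisSpec,
    starts: Sequence[Sequence[float]] | None = None,
    tol: float = 1e-8,
) -> HypothesisFit:
    """Fit one hypothesis by bounded ML from every start on the grid.

    The returned log-likelihood is guaranteed to be at least the
    log-likelihood at every starting vector (an optimizer run that ends worse
    than its own start falls back to the start).  Ties across starts resolve
    to the lowest start index.  Mixture components are reported in ascending
    order of their means to resolve label switching.

    Raises
    ------
    ValueError
        If ``n <= k + 1`` (AICc denominator non-positive) or the start grid
        is empty or violates the bounds.
    """
    x = np.asarray(sample.values, dtype=float)
    n = x.size
    if n <= spec.k + 1:
        raise ValueError(
            f"{spec.name} needs n > k+1 = {spec.k + 1} cells; got n={n}"
        )
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("sample must be clamped into (0, 1) before fitting")
    if starts is None:
        starts = default_starts(spec)
    starts = [np.asarray(s, dtype=float) for s in starts]
    if not starts:
        raise ValueError("empty start grid")
    for s in starts:
        if not spec.contains(s):
            raise ValueError(f"start {s} outside bounds of {spec.name}")

    def objective(p):
        nll, g = _nll_grad(p, x, spec)
        if not np.isfinite(nll):
            return 1e12, np.zeros_like(p)
        return nll, g

    best_ll = -np.inf
    best_params = starts[0]
    best_start = starts[0]
    best_ok = False
    for s in starts:
        start_ll = -objective(s)[0]
        try:
            res = minimize(
                objective,
                s,
                jac=True,
                method="L-BFGS-B",
                bounds=spec.bounds,
                options={"ftol": tol, "gtol": 1e-6, "maxiter": 500},
            )
            cand_ll, cand_params, ok = -res.fun, res.x, bool(res.success)
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            cand_ll, cand_params, ok = -np.inf, s, False
        if cand_ll < start_ll:  # optimizer regressed; keep the start point
            cand_ll, cand_params, ok = start_ll, s, False
        if cand_ll > best_ll:
            best_ll, best_params, best_start, best_ok = cand_ll, cand_params, s, ok

    params = np.asarray(best_params, dtype=float)
    if spec.name == "H2":
        pi, a1, b1, a2, b2 = params
        if a1 / (a1 + b1) > a2 / (a2 + b2):
            params = np.array([1.0 - pi, a2, b2, a1, b1])
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    at_boundary = bool(
        np.any(np.isclose(params, lo, atol=1e-6)) or np.any(np.isclose(params, hi, atol=1e-6))
    )
    converged = best_ok and np.isfinite(best_ll)
    return HypothesisFit(
        spec=spec,
        params=params,
        loglik=float(best_ll),
        aicc=aicc(best_ll, spec.k, n) if np.isfinite(best_ll) else np.inf,
        n=n,
        n_starts=len(starts),
        converged=converged,
        at_boundary=at_boundary,
        best_start=np.asarray(best_start, dtype=float),
    )


@dataclass
class CellClassification:
    """Per-cell component assignment under the best-supported model."""

    component_roles: list[str]
    cell_components: np.ndarray  # index of the max-responsibility component
    cell_roles: list[str]
    responsibilities: np.ndarray  # cells x components, rows sum to 1
    proportion_heterogeneous: float
    roles_ambiguous: bool


@dataclass
class ModelSelectionResult:
    """AICc-weighted comparison of the three candidate hypotheses."""

    colony_id: str
    fits: dict[str, HypothesisFit | None]
    fit_errors: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    best: str = ""
    unambiguous: bool = False
    proportion_heterogeneous: float = float("nan")
    component_roles: list[str] = field(default_factory=list)
    classification: CellClassification | None = None


def _component_role(alpha: float, beta: float, t_low: float, t_high: float) -> str:
    """Role of one fitted beta component by its mean and shape."""
    m = alpha / (alpha + beta)
    if m < t_low:
        return "homogeneous-C109"
    if m > t_high:
        return "homogeneous-C100"
    if alpha < 1.0 and beta < 1.0:
        return "both-homogeneous"  # U-shaped: mass at both boundaries
    return "heterogeneous"


def classify_cells(
    result: ModelSelectionResult,
    sample: RatioSample,
    role_thresholds: tuple[float, float] = (0.15, 0.85),
) -> CellClassification:
    """Assign each cell to a component of the best model and label roles.

    Component roles follow the component mean ``m = a/(a+b)``: below
    ``t_low`` the component represents homogeneous non-C100 (C109) cells;
    above ``t_high`` homogeneous C100 cells (trace-level C109 bands are
    undetectable above that ratio); a U-shaped component (both shapes < 1)
    covers both homogeneous classes; anything else is heterogeneous.  Cells
    go to the component with the highest posterior responsibility; within a
    U-shaped component they split to the C109/C100 homogeneous roles at
    x = 0.5.  ``proportion_heterogeneous`` is the fraction of cells landing
    in heterogeneous-role components.
    """
    t_low, t_high = role_thresholds
    fit = result.fits.get(result.best)
    if fit is None:
        raise ValueError("best hypothesis was not fitted")
    x = clamp_ratios(sample.values)
    if fit.spec.name == "H2":
        pi, a1, b1, a2, b2 = fit.params
        comp = [(pi, a1, b1), (1.0 - pi, a2, b2)]
    else:
        a, b = fit.params
        comp = [(1.0, a, b)]
    roles = [_component_role(a, b, t_low, t_high) for _, a, b in comp]
    logr = np.column_stack(
        [np.log(w) + log_beta_pdf(x, a, b) for w, a, b in comp]
    )
    logr -= logr.max(axis=1, keepdims=True)
    resp = np.exp(logr)
    resp /= resp.sum(axis=1, keepdims=True)
    assign = np.argmax(resp, axis=1)
    cell_roles = []
    for i, j in enumerate(assign):
        role = roles[j]
        if role == "both-homogeneous":
            role = "homogeneous-C109" if x[i] < 0.5 else "homogeneous-C100"
        cell_roles.append(role)
    prop_het = float(np.mean([r == "heterogeneous" for r in cell_roles]))
    ambiguous = len(set(roles)) < len(roles)
    if ambiguous:
        warnings.warn(
            f"colony {result.colony_id}: both mixture components share the "
            f"role {roles[0]!r}; classification flagged ambiguous",
            stacklevel=2,
        )
    return CellClassification(
        component_roles=roles,
        cell_components=assign,
        cell_roles=cell_roles,
        responsibilities=resp,
        proportion_heterogeneous=prop_het,
        roles_ambiguous=ambiguous,
    )


# names ordered so that argmax-style ties resolve to the simplest model
_HYPOTHESIS_ORDER = ("H0", "H1", "H2")


def select_model(
    sample: RatioSample,
    starts: dict[str, Sequence[Sequence[float]]] | None = None,
    cutoff: float = 0.90,
    role_thresholds: tuple[float, float] = (0.15, 0.85),
    clamp_policy: str = "fixed-eps",
    clamp_eps: float = CLAMP_EPS,
    tol: float = 1e-8,
) -> ModelSelectionResult:
    """Fit all three hypotheses and weigh them by AICc.

    Ratios are clamped into (0, 1), each hypothesis is fitted from its fixed
    start grid, and Akaike weights are computed over the successful fits.  A
    hypothesis that cannot be fitted (e.g. the mixture when ``n <= 6``)
    receives weight 0 with a warning.  Ties in weight resolve toward the
    hypothesis with fewer parameters.  The result is deterministic for a
    given sample and start grid.
    """
    clamped = RatioSample(
        sample.colony_id, clamp_ratios(sample.values, policy=clamp_policy, eps=clamp_eps)
    )
    fits: dict[str, HypothesisFit | None] = {}
    errors: dict[str, str] = {}
    for name in _HYPOTHESIS_ORDER:
        spec = HYPOTHESES[name]
        try:
            fits[name] = fit_hypothesis(
                clamped,
                spec,
                starts=None if starts is None else starts.get(name),
                tol=tol,
            )
        except ValueError as exc:
            fits[name] = None
            errors[name] = str(exc)
            warnings.warn(
                f"colony {sample.colony_id}: {name} not fitted ({exc}); weight 0",
                stacklevel=2,
            )
    aiccs = np.array(
        [fits[h].aicc if fits[h] is not None else np.inf for h in _HYPOTHESIS_ORDER]
    )
    w = akaike_weights(aiccs)
    weights = dict(zip(_HYPOTHESIS_ORDER, (float(v) for v in w)))
    best = _HYPOTHESIS_ORDER[int(np.argmax(w))]  # first max: fewest-parameter tie-break
    result = ModelSelectionResult(
        colony_id=sample.colony_id,
        fits=fits,
        fit_errors=errors,
        weights=weights,
        best=best,
        unambiguous=bool(np.max(w) > cutoff),
    )
    cls = classify_cells(result, clamped, role_thresholds=role_thresholds)
    result.classification = cls
    result.proportion_heterogeneous = cls.proportion_heterogeneous
    result.component_roles = cls.component_roles
    return result
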