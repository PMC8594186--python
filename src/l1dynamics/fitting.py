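"""Constrained maximum-likelihood fitting and AIC model comparison.

Nine constraint sets on the six BiSSE rates (the unconstrained model plus
eight equality/zero constraints) are fitted by maximizing the pooled
log-likelihood over a tree sample, and ranked by AIC = 2*df - 2*logL.
Optimization runs on log-transformed free parameters (the non-negativity
constraint disappears and the scales of rates spanning several orders of
magnitude are evened out), multi-started from log-uniform draws plus one
deterministic Yule-scale start.  The change-point extension adds one free
speciation multiplier per epoch boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bisse import BisseParams, ChangePointSpec, RootOptions, pooled_loglik
from .treeio import TipStates, TreeSample, UnitConversion

__all__ = [
    "PARAM_NAMES",
    "ModelConstraint",
    "FitResult",
    "ChangePointFit",
    "builtin_constraints",
    "fit_model",
    "fit_changepoint",
    "model_table",
]

PARAM_NAMES = ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10")

_PENALTY = 1e10  # objective value for non-finite likelihoods during search
_LOG_LO, _LOG_HI = -30.0, 30.0  # search box for log-rates (~1e-13 .. 1e13)


@dataclass(frozen=True)
class ModelConstraint:
    """Equality ties and zero-fixes on the six rates.

    ``groups`` maps each rate name to a free-parameter group label, or to
    None for a rate fixed at zero; rates sharing a label are constrained
    equal.  ``df`` is the number of distinct groups.
    """

    id: str
    groups: tuple[str | None, ...]  # aligned with PARAM_NAMES

    def __post_init__(self) -> None:
        if len(self.groups) != 6:
            raise ValueError("groups must cover all six rates")
        if self.df < 1:
            raise ValueError("constraint leaves no free parameter")

    @property
    def df(self) -> int:
        return len({g for g in self.groups if g is not None})

    @property
    def free_groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.groups:
            if g is not None and g not in seen:
                seen.append(g)
        return tuple(seen)

    def params_from_free(self, free: dict[str, float]) -> BisseParams:
        vals = [0.0 if g is None else free[g] for g in self.groups]
        return BisseParams(*vals)

    def describe(self) -> str:
        parts = []
        by_group: dict[str, list[str]] = {}
        zeros = []
        for name, g in zip(PARAM_NAMES, self.groups):
            if g is None:
                zeros.append(name)
            else:
                by_group.setdefault(g, []).append(name)
        for g, names in by_group.items():
            if len(names) > 1:
                parts.append(" = ".join(names))
        if zeros:
            parts.append(" = ".join(zeros) + " = 0")
        return "; ".join(parts) if parts else "unconstrained"


def _c(cid: str, **kw: str | None) -> ModelConstraint:
    groups = tuple(kw.get(n, n) for n in PARAM_NAMES)
    return ModelConstraint(cid, groups)


def builtin_constraints() -> list[ModelConstraint]:
    """The nine constraint sets of the published model comparison.

    The unconstrained model (df 6) plus eight constrained variants with
    df 5, 5, 5, 4, 5, 5, 3, 3, in table order.
    """
    return [
        _c("unconstrained"),
        _c("mu0=mu1", mu0="mu", mu1="mu"),
        _c("lambda0=lambda1", lambda0="lambda", lambda1="lambda"),
        _c("q01=q10", q01="q", q10="q"),
        _c("mu0=mu1=0", mu0=None, mu1=None),
        _c("lambda0=0", lambda0=None),
        _c("q01=0", q01=None),
        _c("mu0=mu1=lambda0=0", mu0=None, mu1=None, lambda0=None),
        _c("mu0=mu1=q01=0", mu0=None, mu1=None, q01=None),
    ]


@dataclass(frozen=True)
class StartResult:
    x0: tuple[float, ...]
    loglik: float
    converged: bool
    message: str


@dataclass(frozen=True)
class FitResult:
    """A constrained maximum-likelihood fit with its AIC."""

    constraint: ModelConstraint
    params: BisseParams
    loglik: float
    df: int
    aic: float
    root: RootOptions
    seed: int
    n_starts: int
    starts: tuple[StartResult, ...]
    data_hash: str

    @property
    def converged(self) -> bool:
        return any(s.converged for s in self.starts)

    def to_dict(self) -> dict:
        return {
            "constraint": self.constraint.id,
            "params": self.params.as_dict(),
            "loglik": self.loglik,
            "df": self.df,
            "aic": self.aic,
            "root_mode": self.root.mode,
            "condition_on_survival": self.root.condition_on_survival,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "data_hash": self.data_hash,
        }


@dataclass(frozen=True)
class ChangePointFit:
    """A change-point fit: base FitResult fields plus the epoch multipliers."""

    fit: FitResult
    cp: ChangePointSpec
    multiplier_identifiable: tuple[bool, ...]

    @property
    def multipliers(self) -> tuple[float, ...]:
        return self.cp.multipliers

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def loglik(self) -> float:
        return self.fit.loglik


def _yule_start(sample: TreeSample, constraint: ModelConstraint) -> dict[str, float]:
    """Deterministic start: lambda at the Yule scale (n-1)/T, q at half, mu a tenth."""
    tree = sample[0]
    lam = max((tree.n_tips - 1) / max(tree.total_branch_length, 1e-12), 1e-6)
    start: dict[str, float] = {}
    for name, g in zip(PARAM_NAMES, constraint.groups):
        if g is None or g in start:
            continue
        if name.startswith("lambda"):
            start[g] = lam
        elif name.startswith("mu"):
            start[g] = 0.1 * lam
        else:
            start[g] = 0.5 * lam
    return start


def _optimize(
    objective,
    start_points: list[np.ndarray],
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, list[StartResult]]:
    """Minimize over log-parameters from several starts; return the best."""
    best_x, best_f = None, math.inf
    starts: list[StartResult] = []
    for x0 in start_points:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(_LOG_LO, _LOG_HI)] * x0.shape[0],
            options={"maxiter": 500, "ftol": tol, "gtol": 1e-8},
        )
        f = float(res.fun)
        starts.append(
            StartResult(tuple(map(float, x0)), -f if f < _PENALTY / 2 else -math.inf,
                        bool(res.success), str(res.message))
        )
        if f < best_f:
            best_x, best_f = res.x, f
    if best_x is None or best_f >= _PENALTY / 2:
        raise RuntimeError(
            "no optimizer start reached a finite likelihood; starts: "
            + "; ".join(s.message for s in starts)
        )
    return best_x, best_f, starts


def _start_points(
    n_free: int,
    n_starts: int,
    seed: int,
    deterministic_first: np.ndarray,
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    pts = [deterministic_first]
    lo, hi = math.log(1e-2), math.log(1e4)
    for _ in range(max(n_starts - 1, 0)):
        pts.append(rng.uniform(lo, hi, size=n_free))
    return pts[:n_starts] if n_starts >= 1 else pts[:1]


def fit_model(
    sample: TreeSample,
    states: TipStates,
    constraint: ModelConstraint,
    n_starts: int = 10,
    seed: int = 0,
    root: RootOptions = RootOptions(),
    conv: UnitConversion = UnitConversion(),
    init: BisseParams | None = None,
) -> FitResult:
    """Maximize the pooled likelihood under one constraint set.

    ``init`` warm-starts the deterministic first start from a previous
    fit's rates (zero-fixed rates in ``init`` enter at a small floor) —
    useful when fitting nested models in sequence.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    groups = constraint.free_groups
    k = len(groups)

    def objective(x: np.ndarray) -> float:
        free = {g: math.exp(v) for g, v in zip(groups, np.clip(x, _LOG_LO, _LOG_HI))}
        try:
            params = constraint.params_from_free(free)
            ll = pooled_loglik(sample, states, params, root=root, conv=conv)
        except (ValueError, ArithmeticError, OverflowError):
            return _PENALTY
        if not math.isfinite(ll):
            return _PENALTY
        return -ll

    if init is not None:
        by_group: dict[str, float] = {}
        for name, g in zip(PARAM_NAMES, constraint.groups):
            if g is not None and g not in by_group:
                by_group[g] = max(getattr(init, name), 1e-8)
        det = np.log(np.array([by_group[g] for g in groups]))
    else:
        det = np.log(
            np.array([_yule_start(sample, constraint)[g] for g in groups])
        )
    x, f, starts = _optimize(objective, _start_points(k, n_starts, seed, det))
    free = {g: math.exp(v) for g, v in zip(groups, x)}
    params = constraint.params_from_free(free)
    loglik = -f
    df = constraint.df
    return FitResult(
        constraint=constraint,
        params=params,
        loglik=loglik,
        df=df,
        aic=2.0 * df - 2.0 * loglik,
        root=root,
        seed=seed,
        n_starts=n_starts,
        starts=tuple(starts),
        data_hash=sample.data_hash(states),
    )


def fit_changepoint(
    sample: TreeSample,
    states: TipStates,
    base_constraint: ModelConstraint,
    cp_boundaries: tuple[float, ...],
    conv: UnitConversion = UnitConversion(),
    n_starts: int = 10,
    seed: int = 0,
    root: RootOptions = RootOptions(),
    fixed_multipliers: tuple[float, ...] | None = None,
    init: FitResult | None = None,
) -> ChangePointFit:
    """Jointly fit base rates and per-epoch speciation multipliers.

    ``cp_boundaries`` are in generations before present.  Each boundary
    adds one free multiplier (and one df) unless ``fixed_multipliers``
    pins them (the df still counts the change-point parameters, so fixing
    a multiplier at 1 is the 'wasted df' diagnostic: AIC = base + 2 per
    boundary).  A boundary deeper than every tree in the sample makes its
    multiplier unidentifiable; this is flagged, not an error.
    """
    groups = base_constraint.free_groups
    k = len(groups)
    ncp = len(cp_boundaries)
    if ncp < 1:
        raise ValueError("need at least one change-point boundary")
    bounds_sub = [conv.generations_to_substitutions(b) for b in cp_boundaries]
    max_depth = max(t.depth for t in sample)
    identifiable = tuple(b < max_depth for b in bounds_sub)

    free_mult = fixed_multipliers is None

    def make_cp(mults: tuple[float, ...]) -> ChangePointSpec:
        return ChangePointSpec(tuple(cp_boundaries), mults)

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, _LOG_LO, _LOG_HI)
        free = {g: math.exp(v) for g, v in zip(groups, x[:k])}
        mults = (
            tuple(math.exp(v) for v in x[k:]) if free_mult else tuple(fixed_multipliers)
        )
        try:
            params = base_constraint.params_from_free(free)
            ll = pooled_loglik(
                sample, states, params, cp=make_cp(mults), conv=conv, root=root
            )
        except (ValueError, ArithmeticError, OverflowError):
            return _PENALTY
        if not math.isfinite(ll):
            return _PENALTY
        return -ll

    if init is not None:
        by_group: dict[str, float] = {}
        for name, g in zip(PARAM_NAMES, base_constraint.groups):
            if g is not None and g not in by_group:
                by_group[g] = max(getattr(init.params, name), 1e-10)
        det_rates = np.log(np.array([by_group[g] for g in groups]))
    else:
        det_rates = np.log(np.array([_yule_start(sample, base_constraint)[g] for g in groups]))
    n_x = k + (ncp if free_mult else 0)
    det = np.concatenate([det_rates, np.zeros(n_x - k)])  # multipliers start at 1
    x, f, starts = _optimize(objective, _start_points(n_x, n_starts, seed, det))
    free = {g: math.exp(v) for g, v in zip(groups, x[:k])}
    mults = tuple(math.exp(v) for v in x[k:]) if free_mult else tuple(fixed_multipliers)
    params = base_constraint.params_from_free(free)
    loglik = -f
    df = base_constraint.df + ncp  # one change-point parameter per boundary
    fit = FitResult(
        constraint=base_constraint,
        params=params,
        loglik=loglik,
        df=df,
        aic=2.0 * df - 2.0 * loglik,
        root=root,
        seed=seed,
        n_starts=n_starts,
        starts=tuple(starts),
        data_hash=sample.data_hash(states),
    )
    return ChangePointFit(fit=fit, cp=make_cp(mults), multiplier_identifiable=identifiable)


def model_table(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits by AIC (ties broken by fewer df, then constraint id).

    All fits must be on identical data; mirrors the published comparison
    table with columns constraint, df, parameter values, log-likelihood,
    AIC, delta-AIC and a best-model flag.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    h0 = fits[0].data_hash
    for f in fits[1:]:
        if f.data_hash != h0:
            raise ValueError("fits were computed on different data; refusing to rank")
    rows = []
    for f in fits:
        rows.append(
            {
                "constraint": f.constraint.id,
                "df": f.df,
                "parameters": ", ".join(
                    f"{k}={v:.4g}" for k, v in f.params.as_dict().items()
                ),
                "loglik": f.loglik,
                "aic": f.aic,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["aic", "df", "constraint"], kind="mergesort").reset_index(
        drop=True
    )
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["best"] = False
    df.loc[0, "best"] = True
    return df


def save_fits(fits: list[FitResult], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in fits], fh, indent=1, sort_keys=True)
        fh.write("\n")
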