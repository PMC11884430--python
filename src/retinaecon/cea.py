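"""Incremental cost-effectiveness, deterministic and probabilistic sensitivity analysis.

Sign conventions follow the way dominance tables are usually printed for a
cost-saving intervention: ``delta_cost`` is comparator minus intervention
(positive = the intervention saves money) and ``delta_qaly`` is
intervention minus comparator (positive = the intervention gains QALYs).
Net monetary benefit is ``wtp × delta_qaly + delta_cost``; the intervention
is *dominant* over a comparator when it is both cheaper and more effective.

The probabilistic sensitivity analysis draws every uncertain parameter
from its assigned distribution (beta for proportions, gamma for costs,
normal otherwise), re-runs the full model for every treatment under
common random numbers (all treatments share each draw's parameter set),
and summarises dominance and cost-effectiveness probabilities; the
cost-effectiveness acceptability curve reports, per willingness-to-pay
value, the fraction of draws in which each treatment has the highest NMB.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes import EconResult, evaluate
from .parameters import (
    ConfigSchemaError,
    ParameterSet,
    ParameterValidationError,
    PhaseTag,
    get_path,
    set_path,
)

__all__ = [
    "IncrementalResult",
    "DSABound",
    "PSAEntry",
    "PSASpec",
    "CEACurve",
    "PSAResult",
    "incremental_analysis",
    "full_cea",
    "run_dsa",
    "derive_bounds",
    "sample_parameters",
    "run_psa",
    "ceac",
    "load_psa_spec",
    "save_psa_spec",
]

logger = logging.getLogger(__name__)

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental result of the intervention against one comparator."""

    comparator: str
    delta_cost: float  # comparator − intervention: positive = intervention saves
    delta_qaly: float  # intervention − comparator: positive = intervention gains
    icer: float | None  # cost per QALY when a trade-off exists, else None
    label: str
    nmb: float

    def as_row(self) -> dict[str, object]:
        return {
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "label": self.label,
            "nmb": self.nmb,
        }


def incremental_analysis(intervention: EconResult, comparator: EconResult,
                         wtp: float) -> IncrementalResult:
    """Incremental costs, QALYs, ICER with dominance label, and NMB."""
    delta_cost = comparator.total_cost - intervention.total_cost
    delta_qaly = intervention.qalys - comparator.qalys
    nmb = wtp * delta_qaly + delta_cost
    if delta_qaly > 0 and delta_cost > 0:
        icer, label = None, DOMINANT
    elif delta_qaly < 0 and delta_cost < 0:
        icer, label = None, DOMINATED
    elif delta_qaly == 0:
        icer = None
        if delta_cost == 0:
            label = "equivalent"
        else:
            label = "equal effect, cheaper" if delta_cost > 0 else "equal effect, costlier"
    else:
        # trade-off quadrants: conventional ICER = Δcost/ΔQALY, intervention − comparator
        icer = (intervention.total_cost - comparator.total_cost) / delta_qaly
        label = "more effective, costlier" if delta_qaly > 0 else "less effective, cheaper"
    return IncrementalResult(
        comparator=comparator.treatment,
        delta_cost=float(delta_cost),
        delta_qaly=float(delta_qaly),
        icer=None if icer is None else float(icer),
        label=label,
        nmb=float(nmb),
    )


def full_cea(ps: ParameterSet, wtp: float | None = None
             ) -> tuple[list[EconResult], list[IncrementalResult]]:
    """Evaluate every treatment and compare the intervention against each comparator."""
    if wtp is None:
        wtp = ps.settings.wtp_threshold
    results = [evaluate(ps, t) for t in ps.treatments]
    incr = [incremental_analysis(results[0], r, wtp) for r in results[1:]]
    return results, incr


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis (tornado)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSABound:
    """One-way bound for a parameter, with the rule that produced it."""

    parameter: str
    low: float
    high: float
    rule: str  # "CI95", "P30_P70" or "PCT10"

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ParameterValidationError(
                f"DSA bound for {self.parameter!r} must have low < high"
            )


def _pairwise_nmb(ps: ParameterSet, wtp: float, comparator: str) -> float:
    inter = evaluate(ps, ps.intervention)
    comp = evaluate(ps, comparator)
    return incremental_analysis(inter, comp, wtp).nmb


def run_dsa(ps: ParameterSet, bounds: list[DSABound], wtp: float | None = None,
            comparator: str | None = None) -> pd.DataFrame:
    """One-at-a-time tornado analysis on the intervention-vs-comparator NMB.

    Each bound is substituted on each side with a full model re-run; rows
    come back sorted by absolute swing, the tornado ordering.
    """
    if wtp is None:
        wtp = ps.settings.wtp_threshold
    if comparator is None:
        comparator = ps.treatments[1].name
    base_nmb = _pairwise_nmb(ps, wtp, comparator)
    rows = []
    for b in bounds:
        get_path(ps, b.parameter)  # raises ConfigSchemaError if unresolvable
        nmb_low = _pairwise_nmb(set_path(ps, b.parameter, b.low), wtp, comparator)
        nmb_high = _pairwise_nmb(set_path(ps, b.parameter, b.high), wtp, comparator)
        rows.append({
            "parameter": b.parameter,
            "low": b.low,
            "high": b.high,
            "rule": b.rule,
            "nmb_low": nmb_low,
            "nmb_high": nmb_high,
            "swing": abs(nmb_high - nmb_low),
        })
    out = pd.DataFrame(rows, columns=["parameter", "low", "high", "rule",
                                      "nmb_low", "nmb_high", "swing"])
    out.attrs["base_nmb"] = base_nmb
    return out.sort_values("swing", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_FAMILIES = ("beta", "gamma", "normal")


@dataclass(frozen=True)
class PSAEntry:
    """Distributional assumption for one scalar parameter.

    ``params`` are the distribution's native hyperparameters:
    beta ``{a, b}``, gamma ``{shape, scale}``, normal ``{mu, sigma}``.
    ``ci`` optionally carries a reported 95% confidence interval used by
    the deterministic bounds in preference to distribution percentiles.
    """

    path: str
    family: str
    params: dict[str, float]
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterValidationError(f"unknown PSA family {self.family!r}")

    def distribution(self):
        p = self.params
        if self.family == "beta":
            return stats.beta(p["a"], p["b"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        return stats.norm(p["mu"], p["sigma"])

    @property
    def mean(self) -> float:
        return float(self.distribution().mean())

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "beta":
            return float(rng.beta(p["a"], p["b"]))
        if self.family == "gamma":
            if p["shape"] == np.inf or p["scale"] == 0.0:
                return self.mean
            return float(rng.gamma(p["shape"], p["scale"]))
        return float(rng.normal(p["mu"], p["sigma"]))


@dataclass
class PSASpec:
    """Per-parameter sampling distributions for the Monte Carlo analysis."""

    entries: list[PSAEntry]
    n_draws: int = 1000
    seed: int = 0
    matrix_logit_sd: float = 0.0  # log-scale row perturbation of transition matrices

    def validate(self, base: ParameterSet) -> None:
        for e in self.entries:
            v = get_path(base, e.path)
            if e.family == "beta" and not 0 <= v <= 1:
                raise ParameterValidationError(
                    f"beta distribution assigned to {e.path!r} but base value {v} is not in [0,1]"
                )
            if e.family == "gamma" and v < 0:
                raise ParameterValidationError(
                    f"gamma distribution assigned to {e.path!r} but base value {v} is negative"
                )


def derive_bounds(ps: ParameterSet, psa: PSASpec) -> list[DSABound]:
    """Deterministic bounds per parameter: ±10% for drug acquisition costs,
    a reported 95% CI when available, otherwise the 30th/70th percentiles
    of the parameter's PSA distribution."""
    psa.validate(ps)
    bounds = []
    for e in psa.entries:
        base = get_path(ps, e.path)
        if e.path.endswith("drug_cost_per_injection"):
            if base > 0:
                bounds.append(DSABound(e.path, 0.9 * base, 1.1 * base, "PCT10"))
            continue
        if e.ci is not None:
            bounds.append(DSABound(e.path, e.ci[0], e.ci[1], "CI95"))
            continue
        dist = e.distribution()
        lo, hi = float(dist.ppf(0.30)), float(dist.ppf(0.70))
        if lo < hi:
            bounds.append(DSABound(e.path, lo, hi, "P30_P70"))
    return bounds


def _perturb_matrices(ps: ParameterSet, sd: float, rng: np.random.Generator) -> None:
    """Multiplicative log-normal noise on each matrix row, renormalised in place.

    Masked (structurally zero) cells stay zero, so phase legality is
    preserved by construction; rows re-sum to 1 exactly.
    """
    mats = [m for t in ps.treatments for tag in PhaseTag for m in t.matrices[tag]]
    if ps.natural_history is not None:
        mats.append(ps.natural_history)
    for m in mats:
        probs = m.probs
        for r in range(probs.shape[0]):
            nz = probs[r] > 0
            if nz.sum() <= 1:
                continue
            noisy = probs[r, nz] * np.exp(rng.normal(0.0, sd, size=int(nz.sum())))
            probs[r, nz] = noisy / noisy.sum()


def sample_parameters(psa: PSASpec, base: ParameterSet, draw_index: int,
                      _attempt: int = 0) -> ParameterSet:
    """One reproducible parameter draw: (seed, draw_index) fixes every value."""
    if draw_index >= psa.n_draws:
        raise ValueError(f"draw_index {draw_index} out of range for n_draws={psa.n_draws}")
    rng = np.random.default_rng([psa.seed, draw_index, _attempt])
    ps = copy.deepcopy(base)
    for e in psa.entries:
        ps = set_path(ps, e.path, e.sample(rng))
    if psa.matrix_logit_sd > 0:
        _perturb_matrices(ps, psa.matrix_logit_sd, rng)
    return ps


def save_psa_spec(psa: PSASpec, path: str) -> str:
    import yaml

    doc = {
        "schema_version": 1,
        "n_draws": int(psa.n_draws),
        "seed": int(psa.seed),
        "matrix_logit_sd": float(psa.matrix_logit_sd),
        "entries": [
            {
                "path": e.path,
                "family": e.family,
                "params": {k: float(v) for k, v in e.params.items()},
                **({"ci": [float(e.ci[0]), float(e.ci[1])]} if e.ci else {}),
            }
            for e in psa.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)
    return path


def load_psa_spec(path: str) -> PSASpec:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        entries = [
            PSAEntry(
                path=e["path"],
                family=e["family"],
                params={k: float(v) for k, v in e["params"].items()},
                ci=tuple(e["ci"]) if e.get("ci") else None,
            )
            for e in doc["entries"]
        ]
        return PSASpec(entries=entries, n_draws=doc.get("n_draws", 1000),
                       seed=doc.get("seed", 0),
                       matrix_logit_sd=doc.get("matrix_logit_sd", 0.0))
    except KeyError as e:
        raise ConfigSchemaError(f"{path}: missing required key {e.args[0]!r}") from None


@dataclass
class PSAResult:
    """Per-draw costs/QALYs for every treatment plus the dominance summary."""

    draws: pd.DataFrame  # columns: draw, treatment, cost, qalys
    summary: pd.DataFrame  # per-treatment means
    p_dominant: pd.Series  # per comparator: P(intervention cheaper and better)
    p_cost_effective: float  # P(intervention has the highest NMB at the given WTP)
    wtp: float
    n_resampled: int = 0

    @property
    def treatments(self) -> list[str]:
        return list(self.summary.index)


def run_psa(ps: ParameterSet, psa: PSASpec, wtp: float | None = None,
            max_resample: int = 20) -> PSAResult:
    """Monte Carlo PSA: every draw re-runs the full model for every treatment.

    All treatments share each draw's sampled parameter set (common random
    numbers), so between-treatment differences are not diluted by sampling
    noise. Draws that fail validation are logged and re-sampled.
    """
    if wtp is None:
        wtp = ps.settings.wtp_threshold
    psa.validate(ps)
    names = [t.name for t in ps.treatments]
    rows = []
    n_resampled = 0
    for k in range(psa.n_draws):
        for attempt in range(max_resample):
            drawn = sample_parameters(psa, ps, k, _attempt=attempt)
            try:
                drawn.validate()
                results = {t.name: evaluate(drawn, t) for t in drawn.treatments}
            except (ParameterValidationError, ValueError) as exc:
                n_resampled += 1
                logger.warning("PSA draw %d attempt %d invalid (%s); re-sampling", k, attempt, exc)
                continue
            break
        else:
            raise RuntimeError(f"PSA draw {k} failed validation {max_resample} times")
        for name in names:
            r = results[name]
            rows.append((k, name, r.total_cost, r.qalys))
    draws = pd.DataFrame(rows, columns=["draw", "treatment", "cost", "qalys"])

    wide_cost = draws.pivot(index="draw", columns="treatment", values="cost")
    wide_qaly = draws.pivot(index="draw", columns="treatment", values="qalys")
    inter = names[0]
    p_dom = {}
    for comp in names[1:]:
        cheaper = wide_cost[comp] > wide_cost[inter]
        better = wide_qaly[inter] > wide_qaly[comp]
        p_dom[comp] = float((cheaper & better).mean())
    nmb = wtp * wide_qaly - wide_cost
    win = _winner_weights(nmb[names].to_numpy())
    p_ce = float(win[:, 0].mean())
    summary = pd.DataFrame({
        "mean_cost": wide_cost[names].mean(),
        "mean_qalys": wide_qaly[names].mean(),
    }).loc[names]
    summary.index.name = "treatment"
    return PSAResult(draws=draws, summary=summary, p_dominant=pd.Series(p_dom),
                     p_cost_effective=p_ce, wtp=float(wtp), n_resampled=n_resampled)


def _winner_weights(nmb: np.ndarray) -> np.ndarray:
    """Per-draw optimality weights: 1 for the strict NMB maximiser, ties split equally."""
    best = nmb.max(axis=1, keepdims=True)
    is_best = nmb >= best - 1e-12
    return is_best / is_best.sum(axis=1, keepdims=True)


@dataclass
class CEACurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probabilities: pd.DataFrame  # index: wtp, one column per treatment

    def to_long(self) -> pd.DataFrame:
        long = self.probabilities.reset_index().melt(
            id_vars="wtp", var_name="treatment", value_name="probability"
        )
        return long.sort_values(["wtp", "treatment"], ignore_index=True)


def ceac(psa_draws: pd.DataFrame, wtp_grid) -> CEACurve:
    """Probability each treatment is optimal (highest NMB) at each WTP value."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("the willingness-to-pay grid must contain at least one value")
    if psa_draws.empty:
        raise ValueError("at least one PSA draw is required")
    wide_cost = psa_draws.pivot(index="draw", columns="treatment", values="cost")
    wide_qaly = psa_draws.pivot(index="draw", columns="treatment", values="qalys")
    names = list(wide_cost.columns)
    cost = wide_cost.to_numpy()
    qaly = wide_qaly.to_numpy()
    probs = np.empty((grid.size, len(names)))
    for i, wtp in enumerate(grid):
        weights = _winner_weights(wtp * qaly - cost)
        probs[i] = weights.mean(axis=0)
    frame = pd.DataFrame(probs, columns=names)
    frame.insert(0, "wtp", grid)
    frame = frame.set_index("wtp")
    return CEACurve(wtp_grid=grid, probabilities=frame)
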