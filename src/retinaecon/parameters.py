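"""Typed, validated model inputs for the bilateral retinal-disease cost-utility model.

Every input the model consumes lives here as a dataclass with explicit
invariants: the six ETDRS visual-acuity health states, the phase-specific
transition matrices, per-treatment injection schedules and unit costs,
the utility map, supportive-care and adverse-event costs, second-eye
incidence, and the economic settings (cycle length, horizon, discounting,
discontinuation). Parameter sets round-trip losslessly through a single
human-editable YAML file per scenario.

Sign convention
---------------
State index increases as vision *worsens* (index 0 = best vision, >85
letters). Phase movement rules are stated in vision-gain terms, as
clinicians phrase them: a "shift" of +1 is a one-category vision gain,
which is a *decrease* of 1 in index space. The conversion happens exactly
once, in :meth:`Phase.allowed_index_shifts`.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "N_STATES",
    "SCHEMA_VERSION",
    "ConfigSchemaError",
    "ParameterValidationError",
    "PhaseMaskError",
    "VAState",
    "PhaseTag",
    "Phase",
    "TransitionMatrix",
    "Treatment",
    "UtilityModel",
    "SupportiveCare",
    "EconomicSettings",
    "BilateralInputs",
    "ParameterSet",
    "default_states",
    "load_parameter_set",
    "save_parameter_set",
    "get_path",
    "set_path",
]

N_STATES = 6
SCHEMA_VERSION = 1

_ROW_TOL = 1e-9


class ConfigSchemaError(KeyError):
    """A scenario file is missing a required key or has the wrong shape."""


class ParameterValidationError(ValueError):
    """A parameter value violates a model invariant."""


class PhaseMaskError(ParameterValidationError):
    """A transition matrix places probability mass on a movement the phase forbids."""


# ---------------------------------------------------------------------------
# health states and phases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VAState:
    """One visual-acuity health state (ETDRS letter band)."""

    index: int
    label: str
    letter_range: tuple[int, int]  # inclusive (lower, upper)


_DEFAULT_STATE_SPECS = [
    (0, ">85", (86, 100)),
    (1, "85-71", (71, 85)),
    (2, "70-56", (56, 70)),
    (3, "55-41", (41, 55)),
    (4, "40-26", (26, 40)),
    (5, "<=25", (0, 25)),
]


def default_states() -> list[VAState]:
    """The standard six ETDRS-letter health states, best vision first."""
    return [VAState(i, lab, rng) for i, lab, rng in _DEFAULT_STATE_SPECS]


def _validate_states(states: Sequence[VAState]) -> None:
    if len(states) != N_STATES:
        raise ParameterValidationError(f"exactly {N_STATES} VA states required, got {len(states)}")
    for i, s in enumerate(states):
        if s.index != i:
            raise ParameterValidationError(f"state {i} has index {s.index}; must be ordered best→worst")
        lo, hi = s.letter_range
        if lo > hi:
            raise ParameterValidationError(f"state {i} letter_range {s.letter_range} inverted")
    for a, b in zip(states, states[1:]):
        # contiguous, non-overlapping, decreasing vision
        if b.letter_range[1] != a.letter_range[0] - 1:
            raise ParameterValidationError(
                f"states {a.label!r} and {b.label!r} are not contiguous in letters"
            )
    if states[0].letter_range[1] != 100 or states[-1].letter_range[0] != 0:
        raise ParameterValidationError("letter ranges must span 0..100")


class PhaseTag(str, enum.Enum):
    YEAR1 = "YEAR1"
    YEAR2 = "YEAR2"
    YEAR3PLUS = "YEAR3PLUS"


# Movement rules in vision-GAIN terms: Year 1 (loading) allows gains of up to
# two categories or a one-category loss; Year 2 (stabilisation) one category
# either way; Year 3+ (maintenance) losses of one or two categories only.
_ALLOWED_GAINS: dict[PhaseTag, frozenset[int]] = {
    PhaseTag.YEAR1: frozenset({+2, +1, 0, -1}),
    PhaseTag.YEAR2: frozenset({+1, 0, -1}),
    PhaseTag.YEAR3PLUS: frozenset({0, -1, -2}),
}


@dataclass(frozen=True)
class Phase:
    """A treatment phase with its permitted per-cycle state movements."""

    tag: PhaseTag

    @property
    def allowed_shifts(self) -> frozenset[int]:
        """Permitted movements in vision-gain terms (+1 = one category gained)."""
        return _ALLOWED_GAINS[self.tag]

    @property
    def allowed_index_shifts(self) -> frozenset[int]:
        """Permitted movements as column−row index shifts (negative = gain)."""
        return frozenset(-g for g in _ALLOWED_GAINS[self.tag])

    def allowed_columns(self, row: int) -> frozenset[int]:
        """Columns reachable from ``row``; off-grid moves truncate to the edge."""
        return frozenset(min(max(row - g, 0), N_STATES - 1) for g in self.allowed_shifts)


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Phase-tagged row-stochastic 6×6 matrix of per-4-week-cycle probabilities."""

    phase: PhaseTag
    probs: np.ndarray
    baseline_stratum: int | None = None  # Year-1 matrices may condition on baseline VA

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)

    def validate(self, context: str = "") -> None:
        where = f"{context}[{self.phase.value}" + (
            f", stratum {self.baseline_stratum}]" if self.baseline_stratum is not None else "]"
        )
        if self.probs.shape != (N_STATES, N_STATES):
            raise ParameterValidationError(f"{where}: matrix must be {N_STATES}x{N_STATES}")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ParameterValidationError(f"{where}: entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_TOL)
        if bad.size:
            raise ParameterValidationError(
                f"{where}: row {int(bad[0])} sums to {sums[bad[0]]:.12g}, not 1"
            )
        mask = Phase(self.phase)
        for r in range(N_STATES):
            allowed = mask.allowed_columns(r)
            for c in range(N_STATES):
                if c not in allowed and self.probs[r, c] != 0.0:
                    raise PhaseMaskError(
                        f"{where}: row {r} places mass {self.probs[r, c]:.3g} on column {c}, "
                        f"a movement the {self.phase.value} phase forbids"
                    )

    def __eq__(self, other: object) -> bool:  # value equality, for round-trip tests
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return (
            self.phase == other.phase
            and self.baseline_stratum == other.baseline_stratum
            and np.array_equal(self.probs, other.probs)
        )


# ---------------------------------------------------------------------------
# treatments, utilities, costs, settings
# ---------------------------------------------------------------------------

@dataclass
class Treatment:
    """An anti-VEGF regimen: injection schedule, unit costs, transition dynamics.

    ``matrices`` maps each phase to the matrices that govern on-treatment
    transitions in that phase. Year-1 entries may be stratified by baseline
    VA state (one matrix per stratum); later phases are single matrices.
    """

    name: str
    injections_year1: float
    injections_year2: float
    injections_year3plus: float
    drug_cost_per_injection: float
    admin_cost_per_injection: float
    monitoring_cost_per_visit: float
    matrices: dict[PhaseTag, list[TransitionMatrix]]

    def injections_for(self, phase: PhaseTag) -> float:
        return {
            PhaseTag.YEAR1: self.injections_year1,
            PhaseTag.YEAR2: self.injections_year2,
            PhaseTag.YEAR3PLUS: self.injections_year3plus,
        }[phase]

    def matrix_for(self, phase: PhaseTag, stratum: int | None = None) -> TransitionMatrix:
        """The matrix governing ``phase``; Year-1 lookups may name a baseline stratum."""
        mats = self.matrices[phase]
        if len(mats) == 1:
            return mats[0]
        if stratum is None:
            raise ParameterValidationError(
                f"{self.name}: {phase.value} matrices are stratified; a baseline stratum is required"
            )
        for m in mats:
            if m.baseline_stratum == stratum:
                return m
        raise ParameterValidationError(f"{self.name}: no {phase.value} matrix for stratum {stratum}")

    def validate(self) -> None:
        ctx = f"treatment {self.name!r}"
        for fname in ("injections_year1", "injections_year2", "injections_year3plus"):
            if getattr(self, fname) < 0:
                raise ParameterValidationError(f"{ctx}: {fname} must be >= 0")
        for fname in ("drug_cost_per_injection", "admin_cost_per_injection", "monitoring_cost_per_visit"):
            if getattr(self, fname) < 0:
                raise ParameterValidationError(f"{ctx}: {fname} must be >= 0")
        for tag in PhaseTag:
            mats = self.matrices.get(tag)
            if not mats:
                raise ParameterValidationError(f"{ctx}: missing {tag.value} transition matrix")
            strata = [m.baseline_stratum for m in mats]
            if len(mats) > 1:
                if tag is not PhaseTag.YEAR1:
                    raise ParameterValidationError(
                        f"{ctx}: only YEAR1 matrices may be stratified, {tag.value} has {len(mats)}"
                    )
                if sorted(strata) != list(range(N_STATES)):
                    raise ParameterValidationError(
                        f"{ctx}: YEAR1 strata must cover states 0..{N_STATES - 1}, got {strata}"
                    )
            for m in mats:
                if m.phase != tag:
                    raise ParameterValidationError(f"{ctx}: matrix filed under {tag.value} is tagged {m.phase.value}")
                m.validate(context=ctx)


@dataclass
class UtilityModel:
    """State→utility map plus optional per-injection decrement and age slope."""

    state_utilities: np.ndarray  # one per VA state, non-increasing with worsening vision
    injection_disutility: float = 0.0
    age_coefficient: float | None = None

    def __post_init__(self) -> None:
        self.state_utilities = np.asarray(self.state_utilities, dtype=float)

    def validate(self) -> None:
        u = self.state_utilities
        if u.shape != (N_STATES,):
            raise ParameterValidationError(f"state_utilities must have {N_STATES} entries")
        if np.any(u < -1) or np.any(u > 1):
            raise ParameterValidationError("state utilities must lie in [-1, 1]")
        if np.any(np.diff(u) > 1e-12):
            raise ParameterValidationError("state utilities must be non-increasing as vision worsens")
        if self.injection_disutility < 0:
            raise ParameterValidationError("injection_disutility must be >= 0 (a decrement)")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UtilityModel):
            return NotImplemented
        return (
            np.array_equal(self.state_utilities, other.state_utilities)
            and self.injection_disutility == other.injection_disutility
            and self.age_coefficient == other.age_coefficient
        )


@dataclass(frozen=True)
class SupportiveCare:
    """Annual cost of vision aids incurred once the better eye reaches a threshold state."""

    threshold_state: int
    annual_cost: float

    def validate(self) -> None:
        if not 0 <= self.threshold_state < N_STATES:
            raise ParameterValidationError("threshold_state must index a VA state")
        if self.annual_cost < 0:
            raise ParameterValidationError("supportive annual_cost must be >= 0")


@dataclass(frozen=True)
class EconomicSettings:
    """Cycle structure, horizon, discounting, discontinuation and shared costs."""

    cycle_weeks: int = 4
    cycles_per_year: int = 13
    horizon_years: int = 25
    discount_rate_costs: float = 0.05
    discount_rate_effects: float = 0.05
    wtp_threshold: float = 5988.0
    discontinuation_year: int = 5
    discontinuation_fraction: float = 0.85
    ae_cost_per_cycle: float = 0.0
    mortality_annual_prob: float = 0.0
    half_cycle_correction: bool = False
    currency: str = "USD"

    @property
    def total_cycles(self) -> int:
        return self.horizon_years * self.cycles_per_year

    @property
    def discontinuation_cycle(self) -> int:
        """First cycle of the year after treatment stops (rule fires once, here)."""
        return self.discontinuation_year * self.cycles_per_year + 1

    def validate(self) -> None:
        for fname in ("discount_rate_costs", "discount_rate_effects"):
            if getattr(self, fname) < 0:
                raise ParameterValidationError(f"{fname} must be >= 0")
        for fname in ("discontinuation_fraction", "mortality_annual_prob"):
            v = getattr(self, fname)
            if not 0 <= v <= 1:
                raise ParameterValidationError(f"{fname} must lie in [0, 1]")
        if self.cycle_weeks != 4 or self.cycles_per_year != 13:
            raise ParameterValidationError("the model is defined on 4-week cycles, 13 per year")
        if self.horizon_years < 1:
            raise ParameterValidationError("horizon_years must be >= 1")
        if self.ae_cost_per_cycle < 0 or self.wtp_threshold < 0:
            raise ParameterValidationError("costs and WTP must be >= 0")


@dataclass(frozen=True)
class BilateralInputs:
    """Second-eye disease incidence and the visit-cost share of the fellow eye."""

    baseline_second_eye_prob: float
    monthly_second_eye_prob: float
    second_eye_admin_share: float = 0.5

    def validate(self) -> None:
        for fname in dataclasses.fields(self):
            v = getattr(self, fname.name)
            if not 0 <= v <= 1:
                raise ParameterValidationError(f"bilateral.{fname.name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """Everything the deterministic model needs for one disease scenario.

    The first treatment in ``treatments`` is the intervention; the rest are
    comparators. ``natural_history``, when given, supplies the off-treatment
    dynamics used for mass that has discontinued; by default discontinued
    mass follows its own treatment's YEAR3PLUS matrix.
    """

    disease: str  # "DME" or "nAMD"
    states: list[VAState]
    baseline_va_distribution_first_eye: np.ndarray
    baseline_va_distribution_second_eye: np.ndarray
    treatments: list[Treatment]
    utilities: UtilityModel
    supportive: SupportiveCare
    bilateral: BilateralInputs
    settings: EconomicSettings = field(default_factory=EconomicSettings)
    natural_history: TransitionMatrix | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline_va_distribution_first_eye = np.asarray(
            self.baseline_va_distribution_first_eye, dtype=float
        )
        self.baseline_va_distribution_second_eye = np.asarray(
            self.baseline_va_distribution_second_eye, dtype=float
        )

    @property
    def intervention(self) -> Treatment:
        return self.treatments[0]

    @property
    def comparators(self) -> list[Treatment]:
        return self.treatments[1:]

    def off_treatment_matrix(self, treatment: Treatment) -> TransitionMatrix:
        if self.natural_history is not None:
            return self.natural_history
        return treatment.matrices[PhaseTag.YEAR3PLUS][0]

    def validate(self) -> "ParameterSet":
        if self.disease not in ("DME", "nAMD"):
            raise ParameterValidationError(f"disease must be 'DME' or 'nAMD', got {self.disease!r}")
        _validate_states(self.states)
        for key, dist in (
            ("baseline_va_distribution_first_eye", self.baseline_va_distribution_first_eye),
            ("baseline_va_distribution_second_eye", self.baseline_va_distribution_second_eye),
        ):
            if dist.shape != (N_STATES,):
                raise ParameterValidationError(f"{key} must have {N_STATES} entries")
            if np.any(dist < 0):
                raise ParameterValidationError(f"{key} has negative mass")
            if abs(float(dist.sum()) - 1.0) > _ROW_TOL:
                raise ParameterValidationError(
                    f"{key} sums to {float(dist.sum()):.12g}, not 1"
                )
        if len(self.treatments) < 2:
            raise ParameterValidationError("at least 2 treatments (intervention + comparator) required")
        names = [t.name for t in self.treatments]
        if len(set(names)) != len(names):
            raise ParameterValidationError(f"treatment names must be unique, got {names}")
        for t in self.treatments:
            t.validate()
        self.utilities.validate()
        self.supportive.validate()
        self.bilateral.validate()
        self.settings.validate()
        if self.natural_history is not None:
            if self.natural_history.phase is not PhaseTag.YEAR3PLUS:
                raise ParameterValidationError("natural_history matrix must be a YEAR3PLUS matrix")
            self.natural_history.validate(context="natural_history")
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return _to_dict(self) == _to_dict(other)


# ---------------------------------------------------------------------------
# serialization: a single human-editable YAML file per scenario
# ---------------------------------------------------------------------------

def _matrix_to_dict(m: TransitionMatrix, labels: Sequence[str]) -> dict[str, Any]:
    d: dict[str, Any] = {"phase": m.phase.value}
    if m.baseline_stratum is not None:
        d["baseline_stratum"] = m.baseline_stratum
    d["rows"] = {labels[r]: [float(x) for x in m.probs[r]] for r in range(N_STATES)}
    return d


def _matrix_from_dict(d: Mapping[str, Any], labels: Sequence[str], where: str) -> TransitionMatrix:
    try:
        phase = PhaseTag(d["phase"])
        rows = d["rows"]
    except KeyError as e:
        raise ConfigSchemaError(f"{where}: missing key {e.args[0]!r}") from None
    probs = np.zeros((N_STATES, N_STATES))
    for r, lab in enumerate(labels):
        if lab not in rows:
            raise ConfigSchemaError(f"{where}: missing matrix row {lab!r}")
        row = rows[lab]
        if len(row) != N_STATES:
            raise ConfigSchemaError(f"{where}: row {lab!r} must have {N_STATES} entries")
        probs[r] = row
    return TransitionMatrix(phase=phase, probs=probs, baseline_stratum=d.get("baseline_stratum"))


def _to_dict(ps: ParameterSet) -> dict[str, Any]:
    labels = [s.label for s in ps.states]
    return {
        "schema_version": SCHEMA_VERSION,
        "disease": ps.disease,
        "states": [
            {"index": s.index, "label": s.label, "letters": list(s.letter_range)} for s in ps.states
        ],
        "baseline_va_distribution": {
            "first_eye": [float(x) for x in ps.baseline_va_distribution_first_eye],
            "second_eye": [float(x) for x in ps.baseline_va_distribution_second_eye],
        },
        "treatments": [
            {
                "name": t.name,
                "injections_per_year": {
                    "year1": float(t.injections_year1),
                    "year2": float(t.injections_year2),
                    "year3plus": float(t.injections_year3plus),
                },
                "costs": {
                    "drug_per_injection": float(t.drug_cost_per_injection),
                    "admin_per_injection": float(t.admin_cost_per_injection),
                    "monitoring_per_visit": float(t.monitoring_cost_per_visit),
                    "currency": ps.settings.currency,
                },
                "transition_matrices": [
                    _matrix_to_dict(m, labels) for tag in PhaseTag for m in t.matrices[tag]
                ],
            }
            for t in ps.treatments
        ],
        "utilities": {
            "state_utilities": [float(x) for x in ps.utilities.state_utilities],
            "injection_disutility": float(ps.utilities.injection_disutility),
            "age_coefficient": ps.utilities.age_coefficient,
        },
        "supportive_care": {
            "threshold_state": ps.supportive.threshold_state,
            "annual_cost": float(ps.supportive.annual_cost),
        },
        "bilateral": {
            "baseline_second_eye_prob": float(ps.bilateral.baseline_second_eye_prob),
            "monthly_second_eye_prob": float(ps.bilateral.monthly_second_eye_prob),
            "second_eye_admin_share": float(ps.bilateral.second_eye_admin_share),
        },
        "settings": {
            f.name: getattr(ps.settings, f.name) for f in dataclasses.fields(EconomicSettings)
        },
        "natural_history": (
            _matrix_to_dict(ps.natural_history, labels) if ps.natural_history is not None else None
        ),
        "metadata": ps.metadata,
    }


def _require(d: Mapping[str, Any], key: str, where: str = "") -> Any:
    if key not in d:
        path = f"{where}.{key}" if where else key
        raise ConfigSchemaError(f"missing required key {path!r}")
    return d[key]


def _from_dict(doc: Mapping[str, Any]) -> ParameterSet:
    version = _require(doc, "schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigSchemaError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    states = [
        VAState(index=_require(s, "index", "states"), label=_require(s, "label", "states"),
                letter_range=tuple(_require(s, "letters", "states")))
        for s in _require(doc, "states")
    ]
    labels = [s.label for s in states]
    baseline = _require(doc, "baseline_va_distribution")
    treatments = []
    for td in _require(doc, "treatments"):
        name = _require(td, "name", "treatments")
        inj = _require(td, "injections_per_year", f"treatments[{name}]")
        costs = _require(td, "costs", f"treatments[{name}]")
        mats: dict[PhaseTag, list[TransitionMatrix]] = {tag: [] for tag in PhaseTag}
        for md in _require(td, "transition_matrices", f"treatments[{name}]"):
            m = _matrix_from_dict(md, labels, where=f"treatments[{name}]")
            mats[m.phase].append(m)
        treatments.append(
            Treatment(
                name=name,
                injections_year1=_require(inj, "year1", f"treatments[{name}].injections_per_year"),
                injections_year2=_require(inj, "year2", f"treatments[{name}].injections_per_year"),
                injections_year3plus=_require(inj, "year3plus", f"treatments[{name}].injections_per_year"),
                drug_cost_per_injection=_require(costs, "drug_per_injection", f"treatments[{name}].costs"),
                admin_cost_per_injection=_require(costs, "admin_per_injection", f"treatments[{name}].costs"),
                monitoring_cost_per_visit=_require(costs, "monitoring_per_visit", f"treatments[{name}].costs"),
                matrices=mats,
            )
        )
    util = _require(doc, "utilities")
    supp = _require(doc, "supportive_care")
    bil = _require(doc, "bilateral")
    settings_doc = dict(_require(doc, "settings"))
    nh_doc = doc.get("natural_history")
    return ParameterSet(
        disease=_require(doc, "disease"),
        states=states,
        baseline_va_distribution_first_eye=_require(baseline, "first_eye", "baseline_va_distribution"),
        baseline_va_distribution_second_eye=_require(baseline, "second_eye", "baseline_va_distribution"),
        treatments=treatments,
        utilities=UtilityModel(
            state_utilities=_require(util, "state_utilities", "utilities"),
            injection_disutility=util.get("injection_disutility", 0.0),
            age_coefficient=util.get("age_coefficient"),
        ),
        supportive=SupportiveCare(
            threshold_state=_require(supp, "threshold_state", "supportive_care"),
            annual_cost=_require(supp, "annual_cost", "supportive_care"),
        ),
        bilateral=BilateralInputs(
            baseline_second_eye_prob=_require(bil, "baseline_second_eye_prob", "bilateral"),
            monthly_second_eye_prob=_require(bil, "monthly_second_eye_prob", "bilateral"),
            second_eye_admin_share=bil.get("second_eye_admin_share", 0.5),
        ),
        settings=EconomicSettings(**settings_doc),
        natural_history=(
            _matrix_from_dict(nh_doc, labels, where="natural_history") if nh_doc else None
        ),
        metadata=doc.get("metadata") or {},
    )


def save_parameter_set(ps: ParameterSet, path: str) -> str:
    """Write a validated scenario to a YAML file; returns the path."""
    ps.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(ps), fh, sort_keys=False, default_flow_style=None)
    return path


def load_parameter_set(path: str) -> ParameterSet:
    """Read and fully validate a scenario file, naming the offending key on failure."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigSchemaError(f"{path}: scenario file must be a mapping at top level")
    return _from_dict(doc).validate()


# ---------------------------------------------------------------------------
# dotted key paths, used by the sensitivity analyses
# ---------------------------------------------------------------------------

def _walk(obj: Any, path: str) -> tuple[Any, str | int]:
    """Resolve all but the last segment of a dotted/indexed key path."""
    tokens: list[str | int] = []
    for part in path.split("."):
        while "[" in part:
            head, rest = part.split("[", 1)
            idx, part = rest.split("]", 1)
            if head:
                tokens.append(head)
            tokens.append(int(idx))
        if part:
            tokens.append(part)
    if not tokens:
        raise ConfigSchemaError("empty parameter path")
    cur = obj
    for tok in tokens[:-1]:
        try:
            cur = cur[tok] if isinstance(tok, int) else getattr(cur, tok)
        except (AttributeError, IndexError, KeyError, TypeError):
            raise ConfigSchemaError(f"cannot resolve {tok!r} in parameter path {path!r}") from None
    return cur, tokens[-1]


def get_path(ps: ParameterSet, path: str) -> float:
    """Read a scalar model parameter by key path, e.g. ``treatments[0].drug_cost_per_injection``."""
    parent, last = _walk(ps, path)
    try:
        val = parent[last] if isinstance(last, int) else getattr(parent, last)
    except (AttributeError, IndexError, KeyError, TypeError):
        raise ConfigSchemaError(f"cannot resolve {last!r} in parameter path {path!r}") from None
    if isinstance(val, np.ndarray) or not isinstance(val, (int, float)):
        raise ConfigSchemaError(f"parameter path {path!r} does not name a scalar")
    return float(val)


def set_path(ps: ParameterSet, path: str, value: float) -> ParameterSet:
    """Return a deep copy of ``ps`` with the parameter at ``path`` replaced."""
    new = copy.deepcopy(ps)
    parent, last = _walk(new, path)
    if isinstance(last, int):
        parent[last] = value
    elif dataclasses.is_dataclass(parent) and getattr(type(parent), "__dataclass_params__").frozen:
        # frozen dataclasses (settings, bilateral, supportive) are replaced in their holder
        holder, hlast = _walk(new, path.rsplit(".", 1)[0])
        replaced = dataclasses.replace(parent, **{str(last): value})
        if isinstance(hlast, int):
            holder[hlast] = replaced
        else:
            setattr(holder, str(hlast), replaced)
    else:
        if not hasattr(parent, str(last)):
            raise ConfigSchemaError(f"cannot resolve {last!r} in parameter path {path!r}")
        setattr(parent, str(last), value)
    return new
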