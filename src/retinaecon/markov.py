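"""Two-eye Markov cohort engine on 4-week cycles.

The cohort is propagated as expected state-occupancy masses. Each eye is
tracked as a marginal distribution over the six visual-acuity states; the
second eye additionally carries an "unaffected" (no disease yet) pool that
converts to affected disease via baseline and per-cycle incidence. People
are split by treatment status so that mass which discontinues treatment at
the end of year 5 genuinely follows the natural-history (off-treatment)
dynamics and accrues no drug or administration costs.

Within a cycle, events are applied in a fixed, documented order:
state transitions → second-eye incidence → mortality → discontinuation.
The per-cycle record (state, injections) is taken at cycle start, which is
also where costs and utilities are accrued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .parameters import (
    N_STATES,
    BilateralInputs,
    EconomicSettings,
    ParameterSet,
    PhaseTag,
    TransitionMatrix,
    Treatment,
)

__all__ = [
    "CohortState",
    "CycleRecord",
    "Trajectory",
    "letters_to_shift",
    "phase_for_cycle",
    "step_eye",
    "apply_second_eye_incidence",
    "apply_discontinuation",
    "run_cohort",
]

_MASS_TOL = 1e-9

# ETDRS letter-change thresholds that define category movements
GAIN_2_LETTERS = 22.5
GAIN_1_LETTERS = 7.5


def letters_to_shift(delta_letters: float) -> int:
    """Map a change in ETDRS letters to a health-state movement (+ = vision gain).

    A gain of more than 22.5 letters moves the patient up two categories;
    a gain in (7.5, 22.5] moves up one; changes within ±7.5 letters leave
    the patient stable; losses mirror the gains.
    """
    d = float(delta_letters)
    if not math.isfinite(d):
        raise ValueError(f"letter change must be finite, got {delta_letters!r}")
    if d > GAIN_2_LETTERS:
        return 2
    if d > GAIN_1_LETTERS:
        return 1
    if d >= -GAIN_1_LETTERS:
        return 0
    if d >= -GAIN_2_LETTERS:
        return -1
    return -2


def phase_for_cycle(cycle: int, cycles_per_year: int = 13, total_cycles: int | None = None) -> PhaseTag:
    """The treatment phase governing a 1-based cycle index.

    Cycles 1–13 are the Year-1 loading phase, 14–26 the Year-2 stabilisation
    phase, and 27 onward the long-term maintenance phase.
    """
    if cycle < 1 or (total_cycles is not None and cycle > total_cycles):
        raise ValueError(f"cycle {cycle} outside the model horizon")
    if cycle <= cycles_per_year:
        return PhaseTag.YEAR1
    if cycle <= 2 * cycles_per_year:
        return PhaseTag.YEAR2
    return PhaseTag.YEAR3PLUS


def step_eye(distribution: np.ndarray, matrix: TransitionMatrix) -> np.ndarray:
    """Advance one eye's occupancy mass a single cycle: row-vector × matrix."""
    matrix.validate()
    dist = np.asarray(distribution, dtype=float)
    out = dist @ matrix.probs
    if abs(out.sum() - dist.sum()) > 1e-12:
        raise ValueError("transition lost probability mass")
    return out


@dataclass
class CohortState:
    """Expected occupancy masses for one cycle, split by treatment status.

    ``first_on``/``first_off`` hold the first (index) eye's distribution for
    people still on treatment / discontinued. ``second_on``/``second_off``
    hold the affected second-eye distribution; ``unaffected_on``/``_off``
    the mass whose second eye has no disease yet. ``dead`` absorbs mortality.
    All masses are fractions of the original cohort.
    """

    first_on: np.ndarray
    first_off: np.ndarray
    second_on: np.ndarray
    second_off: np.ndarray
    unaffected_on: float
    unaffected_off: float
    dead: float = 0.0

    @classmethod
    def initial(cls, ps: ParameterSet) -> "CohortState":
        return cls(
            first_on=np.asarray(ps.baseline_va_distribution_first_eye, dtype=float).copy(),
            first_off=np.zeros(N_STATES),
            second_on=np.zeros(N_STATES),
            second_off=np.zeros(N_STATES),
            unaffected_on=1.0,
            unaffected_off=0.0,
        )

    # -- aggregate views ----------------------------------------------------
    @property
    def first_eye(self) -> np.ndarray:
        """Marginal first-eye distribution (sums to the alive mass)."""
        return self.first_on + self.first_off

    @property
    def second_eye(self) -> np.ndarray:
        """Marginal affected second-eye distribution."""
        return self.second_on + self.second_off

    @property
    def unaffected(self) -> float:
        return self.unaffected_on + self.unaffected_off

    @property
    def on_treatment_fraction(self) -> float:
        return float(self.first_on.sum())

    @property
    def dead_fraction(self) -> float:
        return self.dead

    @property
    def alive(self) -> float:
        return float(self.first_eye.sum())

    def copy(self) -> "CohortState":
        return CohortState(
            self.first_on.copy(), self.first_off.copy(),
            self.second_on.copy(), self.second_off.copy(),
            self.unaffected_on, self.unaffected_off, self.dead,
        )

    def check(self) -> None:
        for arr in (self.first_on, self.first_off, self.second_on, self.second_off):
            if np.any(arr < -_MASS_TOL):
                raise ValueError("negative occupancy mass")
        if min(self.unaffected_on, self.unaffected_off) < -_MASS_TOL or self.dead < -_MASS_TOL:
            raise ValueError("negative pool mass")
        if abs(self.alive + self.dead - 1.0) > _MASS_TOL:
            raise ValueError(f"alive+dead mass is {self.alive + self.dead:.12g}, not 1")
        second_total = float(self.second_eye.sum()) + self.unaffected
        if abs(second_total - (1.0 - self.dead)) > _MASS_TOL:
            raise ValueError("second-eye affected+unaffected mass does not match alive mass")


@dataclass(frozen=True)
class CycleRecord:
    """One cycle of a trajectory, recorded at cycle start."""

    cycle: int
    phase: PhaseTag
    state: CohortState
    injections_first_eye: float
    injections_second_eye: float

    @property
    def injections(self) -> float:
        """Expected injections per original cohort member this cycle, both eyes."""
        return self.injections_first_eye + self.injections_second_eye


@dataclass
class Trajectory:
    """Per-cycle records of a cohort run, plus export to a delimited table."""

    treatment: str
    records: list[CycleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CycleRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> CycleRecord:
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            s = r.state
            row: dict[str, float] = {"cycle": r.cycle, "phase": r.phase.value}
            for i in range(N_STATES):
                row[f"first_eye_{i}"] = s.first_eye[i]
            for i in range(N_STATES):
                row[f"second_eye_{i}"] = s.second_eye[i]
            row["second_eye_unaffected"] = s.unaffected
            row["on_treatment"] = s.on_treatment_fraction
            row["dead"] = s.dead
            row["injections"] = r.injections
            rows.append(row)
        return pd.DataFrame(rows)


def apply_second_eye_incidence(
    state: CohortState,
    bilateral: BilateralInputs,
    cycle: int,
    baseline_dist_second_eye: np.ndarray,
) -> CohortState:
    """Convert part of the unaffected second-eye pool to affected disease.

    At cycle 1 the baseline bilateral-disease share converts; every cycle
    thereafter the per-cycle (monthly) incidence erodes what remains.
    Converted mass enters the affected states per the second-eye baseline
    VA distribution. Total mass is conserved.
    """
    if cycle < 1:
        raise ValueError("cycle indices are 1-based")
    p = bilateral.baseline_second_eye_prob if cycle == 1 else bilateral.monthly_second_eye_prob
    dist = np.asarray(baseline_dist_second_eye, dtype=float)
    new = state.copy()
    for pool, target in (("unaffected_on", "second_on"), ("unaffected_off", "second_off")):
        converting = getattr(new, pool) * p
        setattr(new, pool, getattr(new, pool) - converting)
        setattr(new, target, getattr(new, target) + converting * dist)
    return new


def apply_discontinuation(state: CohortState, settings: EconomicSettings, cycle: int) -> CohortState:
    """Move the discontinuing share off treatment at the first cycle of year 6.

    The rule fires exactly once, at ``settings.discontinuation_cycle``; at
    every other cycle the state is returned unchanged.
    """
    if cycle != settings.discontinuation_cycle:
        return state
    f = settings.discontinuation_fraction
    new = state.copy()
    new.first_off = new.first_off + new.first_on * f
    new.first_on = new.first_on * (1.0 - f)
    new.second_off = new.second_off + new.second_on * f
    new.second_on = new.second_on * (1.0 - f)
    new.unaffected_off += new.unaffected_on * f
    new.unaffected_on *= 1.0 - f
    return new


def _apply_mortality(state: CohortState, per_cycle_prob: float) -> CohortState:
    if per_cycle_prob == 0.0:
        return state
    keep = 1.0 - per_cycle_prob
    new = state.copy()
    dying = state.alive * per_cycle_prob
    new.first_on = new.first_on * keep
    new.first_off = new.first_off * keep
    new.second_on = new.second_on * keep
    new.second_off = new.second_off * keep
    new.unaffected_on *= keep
    new.unaffected_off *= keep
    new.dead += dying
    return new


def _step_stratified(dist: np.ndarray, mats: list[TransitionMatrix],
                     strata_split: np.ndarray | None) -> np.ndarray:
    """Advance a distribution under possibly baseline-stratified Year-1 matrices.

    With stratified matrices the cohort's Year-1 mass is propagated per
    baseline stratum (``strata_split`` holds one distribution row per
    stratum); pooled matrices act on the marginal directly.
    """
    if len(mats) == 1:
        return dist @ mats[0].probs
    assert strata_split is not None
    out = np.zeros(N_STATES)
    for m in mats:
        out += strata_split[m.baseline_stratum] @ m.probs
    return out


def run_cohort(ps: ParameterSet, treatment: Treatment | str | None = None) -> Trajectory:
    """Propagate the full two-eye cohort over the model horizon for one treatment.

    Returns a :class:`Trajectory` whose per-cycle records carry the state at
    cycle start and the expected injections administered during the cycle
    (first and second eye separately; off-treatment mass receives none).
    """
    if treatment is None:
        treatment = ps.intervention
    elif isinstance(treatment, str):
        treatment = next(t for t in ps.treatments if t.name == treatment)
    if all(t.name != treatment.name for t in ps.treatments):
        raise ValueError(f"treatment {treatment.name!r} is not part of this parameter set")

    settings = ps.settings
    cpy = settings.cycles_per_year
    mort_cycle = 1.0 - (1.0 - settings.mortality_annual_prob) ** (1.0 / cpy)
    off_matrix = ps.off_treatment_matrix(treatment)

    state = CohortState.initial(ps)

    # Year-1 matrices may be conditioned on baseline VA: keep per-stratum mass
    # for each eye while the loading phase lasts.
    y1 = treatment.matrices[PhaseTag.YEAR1]
    stratified = len(y1) > 1
    first_strata = np.diag(state.first_on) if stratified else None  # row s = mass starting in stratum s
    second_strata = np.zeros((N_STATES, N_STATES)) if stratified else None

    traj = Trajectory(treatment=treatment.name)
    baseline2 = np.asarray(ps.baseline_va_distribution_second_eye, dtype=float)

    for cycle in range(1, settings.total_cycles + 1):
        phase = phase_for_cycle(cycle, cpy, settings.total_cycles)
        inj_rate = treatment.injections_for(phase) / cpy
        inj_first = state.first_on.sum() * inj_rate
        inj_second = state.second_on.sum() * inj_rate
        traj.records.append(
            CycleRecord(cycle, phase, state.copy(), float(inj_first), float(inj_second))
        )

        # 1. state transitions (on-treatment with the treatment's matrices,
        #    discontinued mass with the natural-history matrix)
        mats = treatment.matrices[phase]
        new = state.copy()
        if phase is PhaseTag.YEAR1 and stratified:
            # per-stratum propagation: each stratum row follows its own matrix
            first_strata = _advance_strata(mats, first_strata)
            second_strata = _advance_strata(mats, second_strata)
            new.first_on = first_strata.sum(axis=0)
            new.second_on = second_strata.sum(axis=0)
        else:
            new.first_on = _step_stratified(state.first_on, mats, None)
            new.second_on = _step_stratified(state.second_on, mats, None)
        new.first_off = state.first_off @ off_matrix.probs
        new.second_off = state.second_off @ off_matrix.probs
        state = new

        # 2. second-eye incidence
        state = apply_second_eye_incidence(state, ps.bilateral, cycle, baseline2)
        if stratified and phase is PhaseTag.YEAR1:
            # newly affected on-treatment mass starts in its baseline stratum
            converted = state.second_on - (second_strata.sum(axis=0) if second_strata is not None else 0)
            second_strata = second_strata + np.diag(converted)

        # 3. mortality
        if mort_cycle > 0:
            state = _apply_mortality(state, mort_cycle)
            if stratified and phase is PhaseTag.YEAR1:
                first_strata = first_strata * (1.0 - mort_cycle)
                second_strata = second_strata * (1.0 - mort_cycle)

        # 4. discontinuation (fires once, at the first cycle of year 6,
        #    which is always after the loading phase)
        state = apply_discontinuation(state, settings, cycle)

        state.check()

    return traj


def _advance_strata(mats: list[TransitionMatrix], strata: np.ndarray) -> np.ndarray:
    out = np.zeros_like(strata)
    for m in mats:
        out[m.baseline_stratum] = strata[m.baseline_stratum] @ m.probs
    return out
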