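"""Individual-level Monte Carlo validator for the cohort engine.

Simulates the same two-eye process as :func:`retinaecon.markov.run_cohort`
one person at a time: each walker carries a first-eye state, a second-eye
state (or "unaffected"), a treatment-status flag and an alive flag, and
experiences the identical per-cycle event order (transition → second-eye
incidence → mortality → discontinuation). Averaging walkers recovers the
cohort's expected occupancies up to sampling error, which is what makes
this an independent correctness oracle for the deterministic engine: the
two implementations share no propagation code, only the parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import Trajectory, phase_for_cycle
from .parameters import N_STATES, ParameterSet, PhaseTag, Treatment

__all__ = ["MicrosimResult", "microsimulate", "compare_to_cohort"]


@dataclass
class MicrosimResult:
    """Per-cycle mean occupancies across walkers (fractions of the cohort)."""

    n_walkers: int
    first_eye: np.ndarray  # (cycles, 6)
    second_eye: np.ndarray  # (cycles, 6) affected states
    unaffected: np.ndarray  # (cycles,)
    on_treatment: np.ndarray  # (cycles,)
    dead: np.ndarray  # (cycles,)
    injections: np.ndarray  # (cycles,) expected per person


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """One categorical draw per row of ``probs``."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return (cum < u[:, None]).sum(axis=1).astype(np.int64)


def _transition(rng: np.random.Generator, states: np.ndarray, base: np.ndarray,
                mats, mask: np.ndarray) -> None:
    """Advance ``states[mask]`` in place under possibly stratified matrices."""
    if not mask.any():
        return
    if len(mats) == 1:
        rows = mats[0].probs[states[mask]]
    else:
        stacked = np.empty((N_STATES, N_STATES, N_STATES))
        for m in mats:
            stacked[m.baseline_stratum] = m.probs
        rows = stacked[base[mask], states[mask]]
    states[mask] = _sample_categorical(rng, rows)


def microsimulate(ps: ParameterSet, treatment: Treatment | str | None = None,
                  n_walkers: int = 100_000, seed: int = 0) -> MicrosimResult:
    """Monte Carlo simulation of ``n_walkers`` individuals over the horizon."""
    if treatment is None:
        treatment = ps.intervention
    elif isinstance(treatment, str):
        treatment = next(t for t in ps.treatments if t.name == treatment)
    s = ps.settings
    rng = np.random.default_rng(seed)
    n = int(n_walkers)
    cycles = s.total_cycles
    mort = 1.0 - (1.0 - s.mortality_annual_prob) ** (1.0 / s.cycles_per_year)
    off_probs = ps.off_treatment_matrix(treatment).probs
    baseline2 = np.asarray(ps.baseline_va_distribution_second_eye, dtype=float)

    first = _sample_categorical(rng, np.tile(ps.baseline_va_distribution_first_eye, (n, 1)))
    first_base = first.copy()
    second = np.full(n, -1, dtype=np.int64)  # -1 = unaffected
    second_base = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    on = np.ones(n, dtype=bool)

    out = MicrosimResult(
        n_walkers=n,
        first_eye=np.zeros((cycles, N_STATES)),
        second_eye=np.zeros((cycles, N_STATES)),
        unaffected=np.zeros(cycles),
        on_treatment=np.zeros(cycles),
        dead=np.zeros(cycles),
        injections=np.zeros(cycles),
    )

    for cycle in range(1, cycles + 1):
        k = cycle - 1
        phase = phase_for_cycle(cycle, s.cycles_per_year, cycles)
        rate = treatment.injections_for(phase) / s.cycles_per_year

        # record at cycle start, mirroring the cohort engine
        out.first_eye[k] = np.bincount(first[alive], minlength=N_STATES) / n
        aff = alive & (second >= 0)
        out.second_eye[k] = np.bincount(second[aff], minlength=N_STATES) / n
        out.unaffected[k] = (alive & (second < 0)).sum() / n
        out.on_treatment[k] = (alive & on).sum() / n
        out.dead[k] = (~alive).sum() / n
        out.injections[k] = rate * ((alive & on).sum() + (alive & on & (second >= 0)).sum()) / n

        # 1. transitions
        mats = treatment.matrices[phase]
        on_alive = alive & on
        off_alive = alive & ~on
        _transition(rng, first, first_base, mats, on_alive)
        _transition(rng, second, second_base, mats, on_alive & (second >= 0))
        if off_alive.any():
            for states_arr, m in ((first, off_alive), (second, off_alive & (second >= 0))):
                if m.any():
                    rows = off_probs[states_arr[m]]
                    states_arr[m] = _sample_categorical(rng, rows)

        # 2. second-eye incidence
        p_inc = (ps.bilateral.baseline_second_eye_prob if cycle == 1
                 else ps.bilateral.monthly_second_eye_prob)
        if p_inc > 0:
            pool = alive & (second < 0)
            converting = pool & (rng.random(n) < p_inc)
            m = int(converting.sum())
            if m:
                onset = _sample_categorical(rng, np.tile(baseline2, (m, 1)))
                second[converting] = onset
                second_base[converting] = onset

        # 3. mortality
        if mort > 0:
            alive &= ~(alive & (rng.random(n) < mort))

        # 4. discontinuation
        if cycle == s.discontinuation_cycle:
            stopping = on & (rng.random(n) < s.discontinuation_fraction)
            on &= ~stopping

    return out


def compare_to_cohort(traj: Trajectory, micro: MicrosimResult, z: float = 3.0,
                      familywise_alpha: float | None = 0.01) -> tuple[bool, float]:
    """Check cohort occupancies against the microsimulation within sampling error.

    Every occupancy cell of every cycle is scored in binomial standard
    errors (with a 1/n discreteness floor). Because thousands of cells are
    compared at once, the pass threshold per cell is the larger of ``z``
    and the Šidák bound for the total number of comparisons at family-wise
    level ``familywise_alpha`` — the per-cell z below which even an exact
    engine would be rejected by chance. Pass ``familywise_alpha=None`` to
    apply ``z`` per cell uncorrected. Returns (ok, worst z-score).
    """
    from scipy import stats

    n = micro.n_walkers
    scores = []
    for k, rec in enumerate(traj):
        s = rec.state
        pairs = list(zip(s.first_eye, micro.first_eye[k]))
        pairs += list(zip(s.second_eye, micro.second_eye[k]))
        pairs += [
            (s.unaffected, micro.unaffected[k]),
            (s.on_treatment_fraction, micro.on_treatment[k]),
            (s.dead, micro.dead[k]),
        ]
        for expected, observed in pairs:
            se = np.sqrt(max(expected * (1.0 - expected), 0.0) / n) + 1.0 / n
            scores.append(abs(observed - expected) / se)
    threshold = z
    if familywise_alpha is not None:
        threshold = max(z, float(stats.norm.ppf(1.0 - familywise_alpha / (2 * len(scores)))))
    worst = max(scores)
    return worst <= threshold, float(worst)
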