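"""Pairwise drug-combination screening with the coefficient of drug interaction.

The normalized effect of a treatment on a readout is

    E = readout(treated) / readout(vehicle)

at a fixed evaluation time (default 48 h), and synergy of a drug pair is
scored with the coefficient of drug interaction

    CDI = E12 / (E1 * E2)

where E12 is the combined effect: CDI < 1 synergistic, = 1 additive,
> 1 antagonistic.  The screen combines a PI3Kalpha anchor (1 uM
BYL719-equivalent) with each of the 24 registry co-targets (fractional
inhibition f = 0.9 by default), evaluates per-ensemble-set CDIs on
cyclin D1, pRb and pS6, and ranks co-targets by ascending mean CDI
(ties broken by name).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import ParameterEnsemble
from .network import (
    DrugPerturbation,
    NetworkModel,
    StimulusInput,
    extract_readouts,
    simulate_timecourse,
)

__all__ = [
    "EffectMeasurement",
    "SynergyRecord",
    "ScreenResult",
    "DoseResponseCurve",
    "single_node_effect",
    "compute_cdi",
    "synergy_screen",
    "estimate_icx",
    "p21_sweep",
    "DEFAULT_T_EVAL",
    "DEFAULT_COTARGET_FRACTION",
]

DEFAULT_T_EVAL = 48 * 60.0  # minutes
DEFAULT_COTARGET_FRACTION = 0.9
SCREEN_READOUTS = ("cyclin D1", "pRb", "pS6")


@dataclass(frozen=True)
class EffectMeasurement:
    readout: str
    E: float  # treated / vehicle, > 0
    condition: str = ""

    def __post_init__(self):
        if not (self.E > 0):
            raise ValueError(f"normalized effect must be > 0, got {self.E}")


@dataclass(frozen=True)
class SynergyRecord:
    co_target: str
    readout: str
    CDI: float
    mean_CDI: float | None = None
    se_CDI: float | None = None

    @property
    def synergy_index(self) -> float:
        return math.log2(self.CDI)

    @property
    def label(self) -> str:
        if self.CDI < 1.0:
            return "synergistic"
        if self.CDI == 1.0:
            return "additive"
        return "antagonistic"


@dataclass
class ScreenResult:
    """Ranked per-readout synergy table over the co-target registry."""

    readouts: tuple
    co_targets: list
    t_eval: float
    # readout -> co_target -> array of per-set CDI values
    cdi: dict = field(default_factory=dict)

    def table(self, readout: str):
        """Rows (co_target, mean_CDI, se_CDI, log2_index, rank), rank-ordered."""
        rows = []
        for ct in self.co_targets:
            vals = np.asarray(self.cdi[readout][ct], dtype=float)
            ok = vals[~np.isnan(vals)]
            if len(ok) == 0:
                rows.append((ct, float("nan"), float("nan"), float("nan")))
                continue
            mean = float(ok.mean())
            se = float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else 0.0
            rows.append((ct, mean, se, math.log2(mean)))
        # ascending mean CDI, ties broken by name; not-evaluable rows last
        rows.sort(key=lambda r: (math.isnan(r[1]), r[1], r[0]))
        return [(ct, m, se, l2, rank + 1) for rank, (ct, m, se, l2) in enumerate(rows)]

    def ranking(self, readout: str):
        return [row[0] for row in self.table(readout)]


@dataclass
class DoseResponseCurve:
    doses: np.ndarray
    responses: np.ndarray  # normalized to vehicle = 1
    IC50: float | None = None
    IC75: float | None = None


# ---------------------------------------------------------------------------


def _readout_at(model, readout, drugs, t_eval, stimulus=None, params=None):
    if stimulus is None:
        stimulus = StimulusInput("growth-medium", 1.0)
    grid = np.linspace(0.0, t_eval, max(2, int(t_eval / 120) + 1))
    traj = simulate_timecourse(model, stimulus, drugs=drugs, grid=grid,
                               params=params)
    mapping = {readout: model.observable_map[readout]}
    value = float(extract_readouts(traj, mapping, times=[t_eval])[readout][0])
    # fully inhibited readouts land at the solver's negativity clip; floor at
    # a tiny positive value so normalized effects stay well defined
    return max(value, 1e-12)


def single_node_effect(
    model: NetworkModel,
    ensemble: ParameterEnsemble | None,
    target: str,
    level: DrugPerturbation,
    readout: str,
    t_eval: float = DEFAULT_T_EVAL,
    stimulus=None,
) -> list:
    """Per-ensemble-set normalized effect E of inhibiting one node.

    ``level.target_node`` is ignored in favor of ``target``.  With
    ensemble=None, the model's own parameters are used (one measurement).
    """
    drug = DrugPerturbation(target, mode=level.mode, dose=level.dose,
                            K_I=level.K_I, drug_label=level.drug_label)
    param_sets = [None] if ensemble is None else list(ensemble.linear_sets())
    free = None if ensemble is None else ensemble.parameter_names
    out = []
    for pset in param_sets:
        params = None
        if pset is not None:
            params = model.parameter_vector()
            pidx = {n: i for i, n in enumerate(model.parameters)}
            for name, v in zip(free, pset):
                params[pidx[name]] = v
        vehicle = _readout_at(model, readout, [], t_eval, stimulus, params)
        if vehicle == 0:
            raise ZeroDivisionError(
                f"vehicle readout {readout!r} is zero; effect undefined"
            )
        treated = _readout_at(model, readout, [drug], t_eval, stimulus, params)
        out.append(EffectMeasurement(readout, treated / vehicle,
                                     condition=f"{target}:{level.mode}"))
    return out


def compute_cdi(E1, E2, E12) -> SynergyRecord:
    """CDI = E12 / (E1 * E2) for matching readouts."""
    for e in (E1, E2, E12):
        if not isinstance(e, EffectMeasurement):
            raise TypeError("compute_cdi expects EffectMeasurement inputs")
    if not (E1.readout == E2.readout == E12.readout):
        raise ValueError("mismatched readouts")
    cdi = E12.E / (E1.E * E2.E)
    return SynergyRecord(co_target="", readout=E1.readout, CDI=cdi)


def synergy_screen(
    model: NetworkModel,
    ensemble: ParameterEnsemble | None,
    anchor: DrugPerturbation | None = None,
    readouts=SCREEN_READOUTS,
    t_eval: float = DEFAULT_T_EVAL,
    co_target_fraction: float = DEFAULT_COTARGET_FRACTION,
    co_targets=None,
    stimulus=None,
) -> ScreenResult:
    """CDI screen of anchor + each registry co-target, per readout.

    For each ensemble set, simulates vehicle, anchor alone, each co-target
    alone and each pair, computes per-set CDIs on every readout, and ranks
    co-targets ascending by mean CDI.
    """
    if anchor is None:
        from .presets import byl719

        anchor = byl719(1.0)
    if co_targets is None:
        co_targets = list(model.perturbable_registry)
    if stimulus is None:
        stimulus = StimulusInput("growth-medium", 1.0)

    param_sets = [None] if ensemble is None else list(ensemble.linear_sets())
    free = None if ensemble is None else ensemble.parameter_names
    pidx = {n: i for i, n in enumerate(model.parameters)}

    cdi = {r: {ct: [] for ct in co_targets} for r in readouts}
    for pset in param_sets:
        params = None
        if pset is not None:
            params = model.parameter_vector()
            for name, v in zip(free, pset):
                params[pidx[name]] = v

        def all_readouts(drugs):
            grid = np.linspace(0.0, t_eval, max(2, int(t_eval / 120) + 1))
            traj = simulate_timecourse(model, stimulus, drugs=drugs, grid=grid,
                                       params=params)
            mapping = {r: model.observable_map[r] for r in readouts}
            vals = extract_readouts(traj, mapping, times=[t_eval])
            return {r: float(vals[r][0]) for r in readouts}

        vehicle = all_readouts([])
        for r in readouts:
            if vehicle[r] == 0:
                raise ZeroDivisionError(f"vehicle readout {r!r} is zero")
        e_anchor = all_readouts([anchor])
        for ct in co_targets:
            drug_ct = DrugPerturbation(ct, mode="fraction",
                                       dose=co_target_fraction)
            e_single = all_readouts([drug_ct])
            e_combo = all_readouts([anchor, drug_ct])
            for r in readouts:
                E1 = e_anchor[r] / vehicle[r]
                E2 = e_single[r] / vehicle[r]
                E12 = e_combo[r] / vehicle[r]
                cdi[r][ct].append(E12 / (E1 * E2))

    return ScreenResult(readouts=tuple(readouts), co_targets=list(co_targets),
                        t_eval=t_eval, cdi=cdi)


def estimate_icx(
    doses,
    responses,
    x: float = 0.5,
    tol: float = 1e-9,
) -> float:
    """Dose at which the normalized response crosses (1 - x).

    ``responses`` must be normalized (vehicle = 1) and monotone
    non-increasing over the increasing ``doses`` grid; the crossing is found
    by bisection on the piecewise-linear interpolant.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be strictly increasing")
    if np.any(np.diff(responses) > 1e-9):
        raise ValueError("response must be monotone non-increasing over doses")
    if not (0 < x < 1):
        raise ValueError("x must lie in (0, 1)")
    target = 1.0 - x
    if responses[0] < target or responses[-1] > target:
        raise ValueError(
            f"no crossing: response spans [{responses[-1]:.4g}, "
            f"{responses[0]:.4g}], target {target:.4g} not bracketed"
        )

    def f(d):
        return float(np.interp(d, doses, responses)) - target

    lo, hi = float(doses[0]), float(doses[-1])
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def dose_response(
    model: NetworkModel,
    target: str,
    doses,
    readout: str,
    t_eval: float = DEFAULT_T_EVAL,
    mode: str = "fraction",
    K_I: float = 1.0,
    params=None,
    stimulus=None,
) -> DoseResponseCurve:
    """Normalized readout (vehicle = 1) over a dose grid, with IC50/IC75."""
    doses = np.asarray(doses, dtype=float)
    vehicle = _readout_at(model, readout, [], t_eval, stimulus, params)
    resp = []
    for d in doses:
        drug = DrugPerturbation(target, mode=mode, dose=float(d), K_I=K_I)
        resp.append(_readout_at(model, readout, [drug], t_eval, stimulus, params)
                    / vehicle)
    resp = np.array(resp)
    curve = DoseResponseCurve(doses=doses, responses=resp)
    try:
        curve.IC50 = estimate_icx(doses, resp, 0.5)
    except ValueError:
        curve.IC50 = None
    try:
        curve.IC75 = estimate_icx(doses, resp, 0.75)
    except ValueError:
        curve.IC75 = None
    return curve


def p21_sweep(
    model: NetworkModel,
    ensemble: ParameterEnsemble | None,
    levels,
    background: DrugPerturbation | None = None,
    readouts=SCREEN_READOUTS,
    t_eval: float = DEFAULT_T_EVAL,
    stimulus=None,
) -> dict:
    """Readouts vs p21 expression level under a BYL719 background.

    ``levels`` are fold changes relative to the parental basal p21 level
    (positive, increasing).  Each level derives a sustained-expression
    variant of the model (as in the resistant derivation), simulates under
    the background drug, and records the readouts at t_eval per ensemble
    set.  Returns {"levels", "readouts", "values" (level x readout x set),
    "mean", "se"}.
    """
    from .resistant import derive_resistant_model

    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0) or np.any(np.diff(levels) <= 0):
        raise ValueError("p21 levels must be positive and increasing")
    if background is None:
        from .presets import byl719

        background = byl719(1.0)
    if stimulus is None:
        stimulus = StimulusInput("growth-medium", 1.0)

    param_sets = [None] if ensemble is None else list(ensemble.linear_sets())
    free = None if ensemble is None else ensemble.parameter_names

    values = np.empty((len(levels), len(readouts), len(param_sets)))
    for li, lev in enumerate(levels):
        variant = derive_resistant_model(model, {"p21": float(lev)})
        pidx = {n: i for i, n in enumerate(variant.parameters)}
        # parameters the derivation rescaled (sustained p21 synthesis)
        ratio = {
            k: variant.parameters[k] / model.parameters[k]
            for k in variant.parameters
            if variant.parameters[k] != model.parameters[k]
        }
        for si, pset in enumerate(param_sets):
            params = None
            if pset is not None:
                params = variant.parameter_vector()
                for name, v in zip(free, pset):
                    if name in pidx:
                        params[pidx[name]] = v
                # keep the level-sustaining synthesis scaling under ensemble
                # parameter overrides
                for name, r in ratio.items():
                    if name in free:
                        params[pidx[name]] *= r
            grid = np.linspace(0.0, t_eval, max(2, int(t_eval / 120) + 1))
            traj = simulate_timecourse(variant, stimulus, drugs=[background],
                                       grid=grid, params=params)
            mapping = {r: variant.observable_map[r] for r in readouts}
            vals = extract_readouts(traj, mapping, times=[t_eval])
            for ri, r in enumerate(readouts):
                values[li, ri, si] = float(vals[r][0])

    n = values.shape[2]
    mean = values.mean(axis=2)
    se = (values.std(axis=2, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros_like(mean)
    return {
        "levels": levels,
        "readouts": tuple(readouts),
        "values": values,
        "mean": mean,
        "se": se,
    }
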