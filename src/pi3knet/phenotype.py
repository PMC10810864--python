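"""Phenomenological cell-fate model coupled to the signaling network.

A fixed population of cells is distributed over five states — G1, S, G2/M
(``M``), DNA repair (``R``) and apoptosis (``A``) — with two auxiliary
variables: a DNA-damage level ``DD`` and CHK1 activity.  Transitions:

* G1 -> S, driven by the cyclin D1 and cyclin E outputs of the network model
  (saturating activation);
* S -> M, blocked by active CHK1 (the CDC25-mediated checkpoint, folded
  into CHK1 per the model's simplifications);
* M -> G1 wrap-around;
* S -> R and M -> R, damage-gated repair entry proportional to DD x CHK1;
* R -> M, repair success proportional to CHK1;
* G1/S/M -> A, apoptosis flux proportional to DD.

DD is produced at a basal rate (replication stress) plus a rate proportional
to PI3Kalpha-inhibitor occupancy, decays first-order, and is cleared by
repair (proportional to CHK1 x R).  CHK1 is activated saturably by DD and
deactivates first-order.  MK-8776 scales CHK1 activity wherever it acts.
Cell viability is the fraction in repair or G2/M: ``V = R + M``.

The total population is conserved exactly (no birth term over the screen
window), so fractions always sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .calibration import ParameterEnsemble
from .network import DrugPerturbation, NetworkModel, StimulusInput
from .screen import ScreenResult, estimate_icx

__all__ = [
    "PhenotypicState",
    "PhenotypicModel",
    "DEFAULT_PHENOTYPIC_PARAMS",
    "build_phenotypic_model",
    "simulate_phenotypic",
    "viability",
    "phenotypic_screen",
]

#: transition-rate parameters (per minute unless noted)
DEFAULT_PHENOTYPIC_PARAMS = {
    "k_g1s": 0.015,       # max G1->S rate, gated by cyclins
    "K_cycd": 1.3,        # cyclin D1 half-activation (fold of parental basal)
    "K_cyce": 1.3,        # cyclin E half-activation (fold of parental basal)
    "n_cyc": 3.0,         # Hill steepness of the cyclin gate
    "k_sm": 0.008,        # S -> G2/M
    "K_chk_sm": 0.5,      # CHK1 level halving the S->M transition
    "k_mg1": 0.006,       # M -> G1 wrap-around
    "k_sr": 0.005,        # S -> R, x DD x CHK1
    "k_mr": 0.005,        # M -> R, x DD x CHK1
    "k_rm": 0.01,         # R -> M, x CHK1 (repair success)
    "k_apop": 0.004,      # G1/S/M/R -> A, x DD, tempered by CHK1 protection
    "K_chk_protect": 0.3, # CHK1 level halving damage-induced death
    "k_dd_basal": 0.00025,# basal DNA damage production (replication stress)
    "k_dd_byl": 0.004,    # DD production per unit PI3Kalpha-inhibitor occupancy
    "k_dd_decay": 0.001,  # passive DD decay
    "k_dd_repair": 0.1,   # DD clearance x CHK1 x R
    "k_chk_on": 0.05,     # CHK1 activation, saturating in DD
    "K_chk_dd": 0.5,      # DD half-saturation for CHK1 activation
    "k_chk_off": 0.02,    # CHK1 deactivation
}

STATE_NAMES = ("G1", "S", "M", "R", "A", "DD", "CHK1")


@dataclass
class PhenotypicState:
    """Population fractions plus damage and checkpoint activity."""

    G1: float
    S: float
    M: float
    R: float
    A: float
    DD: float = 0.0
    CHK1: float = 0.0

    def __post_init__(self):
        for name in ("G1", "S", "M", "R", "A", "DD", "CHK1"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be >= 0")
        total = self.G1 + self.S + self.M + self.R + self.A
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"population fractions must sum to 1, got {total}")

    def as_array(self):
        return np.array([self.G1, self.S, self.M, self.R, self.A,
                         self.DD, self.CHK1])


@dataclass
class PhenotypicModel:
    """Cell-fate model with cyclin inputs from a network model."""

    network: NetworkModel
    params: dict = field(default_factory=lambda: dict(DEFAULT_PHENOTYPIC_PARAMS))
    registry: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("cyclin D1", "cyclin E"):
            if name not in self.network.observable_map:
                raise ValueError(f"network model lacks observable {name!r}")
        for k, v in self.params.items():
            if v < 0:
                raise ValueError(f"phenotypic rate {k} must be >= 0")
        if not self.registry:
            self.registry = list(self.network.perturbable_registry) + ["CHK1"]

    def basal_cyclins(self, stimulus=None):
        """Parental basal cyclin D1/E levels used to normalize inputs."""
        from .network import extract_readouts, simulate_timecourse

        if stimulus is None:
            stimulus = StimulusInput("growth-medium", 1.0)
        key = (stimulus.ligand, stimulus.concentration)
        cache = getattr(self, "_basal_cache", None)
        if cache is not None and cache[0] == key:
            return cache[1]
        grid = np.linspace(0.0, 60.0, 3)
        traj = simulate_timecourse(self.network, stimulus, grid=grid)
        ro = extract_readouts(
            traj,
            {k: self.network.observable_map[k] for k in ("cyclin D1", "cyclin E")},
            times=[0.0],
        )
        out = (float(ro["cyclin D1"][0]), float(ro["cyclin E"][0]))
        self._basal_cache = (key, out)
        return out


def build_phenotypic_model(network: NetworkModel, params=None) -> PhenotypicModel:
    """Couple the cell-fate model to a network model's cyclin outputs."""
    p = dict(DEFAULT_PHENOTYPIC_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise KeyError(f"unknown phenotypic parameters: {sorted(unknown)}")
        p.update(params)
    model = PhenotypicModel(network=network, params=p)
    if len(model.registry) != 25:
        raise ValueError(
            f"phenotypic registry must have 25 entries, got {len(model.registry)}"
        )
    return model


def _phen_rhs(t, y, p, cycd_f, cyce_f, byl_occ, chk1_scale):
    G1, S, M, R, A, DD, CHK1 = y
    chk = CHK1 * chk1_scale  # MK-8776 attenuates CHK1 activity in all fluxes
    cd, ce = cycd_f(t), cyce_f(t)
    n = p.get("n_cyc", 2.0)
    hd = cd**n / (p["K_cycd"]**n + cd**n)
    he = ce**n / (p["K_cyce"]**n + ce**n)
    f_g1s = p["k_g1s"] * G1 * hd * he
    f_sm = p["k_sm"] * S / (1.0 + chk / p["K_chk_sm"])
    f_mg1 = p["k_mg1"] * M
    f_sr = p["k_sr"] * DD * chk * S
    f_mr = p["k_mr"] * DD * chk * M
    f_rm = p["k_rm"] * chk * R
    # checkpoint arrest shelters damaged cells: CHK1 tempers the death flux,
    # so checkpoint inhibition under damage precipitates mitotic catastrophe
    death = p["k_apop"] * DD / (1.0 + chk / p["K_chk_protect"])
    a_g1 = death * G1
    a_s = death * S
    a_m = death * M
    a_r = death * R
    dG1 = -f_g1s + f_mg1 - a_g1
    dS = f_g1s - f_sm - f_sr - a_s
    dM = f_sm - f_mg1 - f_mr + f_rm - a_m
    dR = f_sr + f_mr - f_rm - a_r
    dA = a_g1 + a_s + a_m + a_r
    dDD = (p["k_dd_basal"] + p["k_dd_byl"] * byl_occ
           - p["k_dd_decay"] * DD - p["k_dd_repair"] * chk * R * DD)
    dCHK1 = p["k_chk_on"] * DD / (p["K_chk_dd"] + DD) - p["k_chk_off"] * CHK1
    return [dG1, dS, dM, dR, dA, dDD, dCHK1]


def _split_drugs(model: PhenotypicModel, drugs):
    """Separate CHK1 inhibition from network perturbations and BYL occupancy."""
    chk1_scale = 1.0
    byl_occ = 0.0
    network_drugs = []
    for d in drugs:
        if d.target_node == "CHK1":
            chk1_scale *= d.activity_scale
        else:
            if d.target_node not in model.network.node_forms and \
               d.target_node not in model.network.species_names:
                raise KeyError(f"unknown phenotypic target {d.target_node!r}")
            network_drugs.append(d)
            if d.target_node == "PI3Ka":
                byl_occ = max(byl_occ, 1.0 - d.activity_scale)
    return network_drugs, chk1_scale, byl_occ


def simulate_phenotypic(
    model: PhenotypicModel,
    drugs=(),
    horizon: float = 48 * 60.0,
    y0: PhenotypicState | None = None,
    grid=None,
    params_network=None,
    stimulus=None,
    rtol=1e-8,
    atol=1e-10,
):
    """Integrate the cell-fate model under drugs over ``horizon`` minutes.

    Network-level drugs act on the cyclin D1/E inputs through a network
    simulation; CHK1 drugs attenuate CHK1 activity; a PI3Kalpha dose drug
    additionally sources DNA damage proportional to its occupancy.  Returns
    (times, states) with states rows ordered as STATE_NAMES.
    """
    from .network import extract_readouts, simulate_timecourse

    if stimulus is None:
        stimulus = StimulusInput("growth-medium", 1.0)
    if grid is None:
        grid = np.linspace(0.0, horizon, max(2, int(horizon / 60) + 1))
    grid = np.asarray(grid, dtype=float)

    network_drugs, chk1_scale, byl_occ = _split_drugs(model, drugs)

    # cyclin inputs, normalized to the parental basal level
    cycd0, cyce0 = model.basal_cyclins(stimulus)
    net_grid = np.linspace(0.0, grid[-1] if grid[-1] > 0 else 1.0, 49)
    traj = simulate_timecourse(model.network, stimulus, drugs=network_drugs,
                               grid=net_grid, params=params_network)
    ro = extract_readouts(
        traj,
        {k: model.network.observable_map[k] for k in ("cyclin D1", "cyclin E")},
    )
    cycd = np.maximum(ro["cyclin D1"] / max(cycd0, 1e-12), 0.0)
    cyce = np.maximum(ro["cyclin E"] / max(cyce0, 1e-12), 0.0)

    def cycd_f(t):
        return float(np.interp(t, traj.time_grid, cycd))

    def cyce_f(t):
        return float(np.interp(t, traj.time_grid, cyce))

    if y0 is None:
        y0 = basal_state(model, stimulus=stimulus)
    yv = y0.as_array()

    sol = solve_ivp(
        _phen_rhs,
        (grid[0], grid[-1]),
        yv,
        t_eval=grid,
        args=(model.params, cycd_f, cyce_f, byl_occ, chk1_scale),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"phenotypic integration failed: {sol.message}")
    states = np.maximum(sol.y, -atol)
    totals = states[:5].sum(axis=0)
    if np.any(np.abs(totals - 1.0) > 1e-6):
        raise RuntimeError("population conservation violated beyond 1e-6")
    return sol.t, states


def basal_state(model: PhenotypicModel, stimulus=None) -> PhenotypicState:
    """Steady distribution of the undrugged cell-fate model.

    Long-horizon integration of the phase-transition system with basal DNA
    damage, starting from an all-G1 population.
    """
    y0 = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    p = model.params

    def const1(t):
        return 1.0

    # basal damage only; no drugs; apoptosis slowly drains, so equilibrate the
    # cycling distribution over a bounded window instead of t -> infinity
    sol = solve_ivp(
        _phen_rhs,
        (0.0, 5e3),
        y0,
        args=(p, const1, const1, 0.0, 1.0),
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError("phenotypic basal equilibration failed")
    g1, s, m, r, a, dd, chk1 = np.maximum(sol.y[:, -1], 0.0)
    live = g1 + s + m + r
    if live <= 0:
        raise RuntimeError("basal phenotypic state has no live cells")
    # renormalize the live compartments (the basal screen starts from a
    # viable population); keep basal DD/CHK1
    return PhenotypicState(G1=g1 / live, S=s / live, M=m / live, R=r / live,
                           A=0.0, DD=dd, CHK1=chk1)


def viability(times, states, t_eval: float) -> float:
    """Cell viability V(t_eval) = R + M (repairing or in G2/M)."""
    times = np.asarray(times, dtype=float)
    if t_eval < times[0] - 1e-9 or t_eval > times[-1] + 1e-9:
        raise ValueError("t_eval outside trajectory horizon")
    r = float(np.interp(t_eval, times, states[STATE_NAMES.index("R")]))
    m = float(np.interp(t_eval, times, states[STATE_NAMES.index("M")]))
    return r + m


def _viability_under(model, drugs, t_eval, y0, params_network=None):
    t, s = simulate_phenotypic(model, drugs=drugs, horizon=t_eval, y0=y0,
                               params_network=params_network)
    return viability(t, s, t_eval)


def phenotypic_screen(
    model: PhenotypicModel,
    ensemble: ParameterEnsemble | None = None,
    pairing: str = "ic50",
    t_eval: float = 48 * 60.0,
    anchor_max_uM: float = 10.0,
    fraction_grid=None,
    co_targets=None,
) -> ScreenResult:
    """Viability CDI screen over the 25-node registry at ICx pairing doses.

    For each drug (the PI3Kalpha anchor on a uM dose grid; co-targets on a
    fractional-inhibition grid), the single-drug viability dose response is
    normalized to vehicle and its IC50 or IC75 extracted by bisection; the
    pair is then simulated with each drug at its own ICx dose and scored
    with CDI on viability.  Co-targets whose single-drug response never
    crosses the ICx level are reported as not evaluable (NaN CDI).
    """
    if pairing not in ("ic50", "ic75"):
        raise ValueError("pairing must be 'ic50' or 'ic75'")
    x = 0.5 if pairing == "ic50" else 0.75
    if co_targets is None:
        co_targets = list(model.registry)
    if fraction_grid is None:
        fraction_grid = np.array([0.0, 0.3, 0.6, 0.8, 0.9, 0.95, 0.99])
    dose_grid = np.array([0.0, 0.05, 0.2, 1.0, 3.0, anchor_max_uM])

    from .presets import byl719

    param_sets = [None] if ensemble is None else list(ensemble.linear_sets())
    free = None if ensemble is None else ensemble.parameter_names
    pidx = {n: i for i, n in enumerate(model.network.parameters)}

    cdi = {"viability": {ct: [] for ct in co_targets}}
    for pset in param_sets:
        params = None
        if pset is not None:
            params = model.network.parameter_vector()
            for name, v in zip(free, pset):
                params[pidx[name]] = v
        y0 = basal_state(model)
        vehicle = _viability_under(model, [], t_eval, y0, params)
        if vehicle <= 0:
            raise ZeroDivisionError("vehicle viability is zero")

        # anchor dose response and ICx
        resp_a = [
            _viability_under(model, [byl719(d)] if d > 0 else [], t_eval, y0,
                             params) / vehicle
            for d in dose_grid
        ]
        resp_a = np.minimum.accumulate(resp_a)  # enforce tiny numeric monotone
        anchor_icx = estimate_icx(dose_grid, resp_a, x)
        anchor_drug = byl719(anchor_icx)
        E1 = _viability_under(model, [anchor_drug], t_eval, y0, params) / vehicle

        for ct in co_targets:
            if ct == "CHK1":
                mk = lambda f: DrugPerturbation("CHK1", mode="fraction", dose=f)
            else:
                mk = lambda f, _ct=ct: DrugPerturbation(_ct, mode="fraction",
                                                        dose=f)
            resp = [
                _viability_under(model, [mk(f)] if f > 0 else [], t_eval, y0,
                                 params) / vehicle
                for f in fraction_grid
            ]
            resp = np.minimum.accumulate(resp)
            try:
                icx = estimate_icx(fraction_grid, resp, x)
            except ValueError:
                cdi["viability"][ct].append(np.nan)  # not evaluable
                continue
            ct_drug = mk(icx)
            E2 = _viability_under(model, [ct_drug], t_eval, y0, params) / vehicle
            E12 = _viability_under(model, [anchor_drug, ct_drug], t_eval, y0,
                                   params) / vehicle
            cdi["viability"][ct].append(E12 / (E1 * E2))

    return ScreenResult(readouts=("viability",), co_targets=list(co_targets),
                        t_eval=t_eval, cdi=cdi)
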