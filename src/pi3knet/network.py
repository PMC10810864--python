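"""Mechanistic ODE network model: species, reactions, simulation.

The signaling network is represented as a list of :class:`Species` (state
variables, arbitrary normalized units) and a list of :class:`Reaction` objects
with one of five rate-law kinds (mass action, Michaelis-Menten, Hill
induction, first-order synthesis, first-order degradation).  The right-hand
side of the ODE system is generated as Python source from the reaction list
and compiled once per model, which keeps simulation cost low enough for
screens and genetic-algorithm fitting.

Drugs act by scaling the *catalytic activity* of a target node: every
occurrence of the node's active form(s) in an enzyme/modifier position uses
the effective concentration ``activity_scale * abundance``.  Scales compose
multiplicatively, so two drugs on the same node multiply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Modifier",
    "Reaction",
    "StimulusInput",
    "DrugPerturbation",
    "NetworkModel",
    "Trajectory",
    "simulate_timecourse",
    "equilibrate",
    "apply_inhibition",
    "extract_readouts",
    "SteadyStateError",
    "SimulationError",
]

RATE_LAWS = (
    "mass_action",
    "michaelis_menten",
    "hill",
    "synthesis",
    "degradation",
)

#: ligand names accepted by StimulusInput
LIGANDS = ("IGF-1", "insulin", "HRG", "growth-medium")

# solver defaults; tiny negative excursions below -ATOL are treated as errors
RTOL = 1e-8
ATOL = 1e-10


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries solver diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SteadyStateError(RuntimeError):
    """Raised when pre-equilibration does not reach a steady state."""

    def __init__(self, message, residual):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Species:
    """A state variable of the network (protein form, lipid, or complex)."""

    name: str
    role: str = "kinase"
    initial: float = 0.0
    phospho_partner: str | None = None
    observables: tuple[str, ...] = ()

    def __post_init__(self):
        if self.initial < 0:
            raise ValueError(f"initial abundance of {self.name} must be >= 0")


@dataclass(frozen=True)
class Modifier:
    """A species that tunes a reaction flux without being consumed.

    kind:
      * ``sat``   -- saturating: activator term x/(K+x), inhibitor 1/(1+x/K)
      * ``boost`` -- linear boost (activators only): (1 + x/K)
      * ``lin``   -- linear enzyme term: x/K (the usual kcat*E form with K=1)
    """

    species: str
    sign: int  # +1 activator/enzyme, -1 inhibitor
    param: str  # name of the K parameter
    kind: str = "sat"

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("modifier sign must be +1 or -1")
        if self.kind not in ("sat", "boost", "lin"):
            raise ValueError(f"unknown modifier kind {self.kind!r}")
        if self.kind == "boost" and self.sign != +1:
            raise ValueError("boost modifiers must be activators")


@dataclass(frozen=True)
class Reaction:
    """A single reaction with a named rate law.

    ``params`` maps rate-law slots to parameter names:
      * mass_action: ``k``
      * michaelis_menten: ``k`` and ``Km`` (substrate = first reactant,
        enzyme(s) supplied as modifiers)
      * hill: ``k``, ``K``, ``n`` (inducer = first modifier; no reactants)
      * synthesis: ``k`` (zeroth order, optionally modulated)
      * degradation: ``k`` (first order in the sole reactant)
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_law: str
    params: dict = field(default_factory=dict)
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self):
        if self.rate_law not in RATE_LAWS:
            raise ValueError(f"unknown rate law {self.rate_law!r} in {self.id}")


@dataclass(frozen=True)
class StimulusInput:
    """Extracellular stimulus: a ligand at a concentration, from onset_time."""

    ligand: str
    concentration: float  # nM
    onset_time: float = 0.0  # minutes

    def __post_init__(self):
        if self.ligand not in LIGANDS:
            raise ValueError(f"unknown ligand {self.ligand!r}")
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError("ligand concentration must be finite and >= 0")
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")


@dataclass(frozen=True)
class DrugPerturbation:
    """Inhibition of a network node.

    mode="dose": activity scaled by 1/(1 + dose/K_I) (dose in uM).
    mode="fraction": activity scaled by (1 - f), f in [0, 1].
    """

    target_node: str
    mode: str = "fraction"
    dose: float = 0.0
    K_I: float = 1.0
    drug_label: str = "generic"

    def __post_init__(self):
        if self.mode not in ("dose", "fraction"):
            raise ValueError(f"unknown drug mode {self.mode!r}")
        if self.mode == "fraction" and not (0.0 <= self.dose <= 1.0):
            raise ValueError("fractional inhibition must lie in [0, 1]")
        if self.mode == "dose" and self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.K_I <= 0:
            raise ValueError("K_I must be > 0")

    @property
    def activity_scale(self) -> float:
        if self.mode == "fraction":
            return 1.0 - self.dose
        return 1.0 / (1.0 + self.dose / self.K_I)


@dataclass
class Trajectory:
    """Solution of the network ODEs on a time grid (minutes)."""

    time_grid: np.ndarray
    abundance_matrix: np.ndarray  # species x time
    species_names: list
    solver_diagnostics: dict = field(default_factory=dict)

    def series(self, species: str) -> np.ndarray:
        try:
            i = self.species_names.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in trajectory") from None
        return self.abundance_matrix[i]


def _mod_expr(term_x: str, mod: Modifier, pname_idx) -> str:
    K = f"p[{pname_idx[mod.param]}]"
    if mod.kind == "lin":
        return f"({term_x}/{K})"
    if mod.kind == "boost":
        return f"(1.0 + {term_x}/{K})"
    if mod.sign > 0:
        return f"({term_x}/({K} + {term_x}))"
    return f"(1.0/(1.0 + {term_x}/{K}))"


class NetworkModel:
    """The mechanistic ODE model: species, reactions, parameter vector.

    Parameters are stored on linear scale in ``parameters`` (an ordered dict);
    calibration works on log10 of a chosen free subset.  ``ligand_map`` maps
    ligand names to the model-internal input identifiers referenced by
    reactions; ``node_forms`` maps perturbable node names to the species forms
    whose catalytic activity a drug on that node attenuates.
    """

    def __init__(
        self,
        species,
        reactions,
        parameters,
        ligand_map=None,
        node_forms=None,
        perturbable_registry=(),
        observable_map=None,
        conservation_groups=(),
        growth_medium=None,
        parameter_bounds=None,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = dict(parameters)
        self.ligand_map = dict(ligand_map or {})
        self.node_forms = dict(node_forms or {})
        self.perturbable_registry = list(perturbable_registry)
        self.observable_map = dict(observable_map or {})
        self.conservation_groups = [tuple(g) for g in conservation_groups]
        # composite growth-medium stimulus: ligand -> basal concentration (nM)
        self.growth_medium = dict(
            growth_medium or {"IGF-1": 1.0, "insulin": 10.0, "HRG": 0.1}
        )
        # log10 bounds per parameter, default [-3, 3]
        self.parameter_bounds = dict(parameter_bounds or {})
        self._validate()
        self._rhs = None
        self._index = {s.name: i for i, s in enumerate(self.species)}
        self._pindex = {n: i for i, n in enumerate(self.parameters)}

    # -- validation ---------------------------------------------------------

    def _validate(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species names: {dup}")
        known = set(names) | set(self.ligand_map.values())
        used = set()
        for r in self.reactions:
            for s in r.reactants + r.products:
                if s not in known:
                    raise ValueError(f"reaction {r.id} references missing species {s!r}")
                used.add(s)
            for m in r.modifiers:
                if m.species not in known:
                    raise ValueError(
                        f"reaction {r.id} modifier references missing species {m.species!r}"
                    )
                used.add(m.species)
            for pname in r.params.values():
                if isinstance(pname, str) and pname not in self.parameters:
                    raise ValueError(f"reaction {r.id} dangling parameter {pname!r}")
            for m in r.modifiers:
                if m.param not in self.parameters:
                    raise ValueError(f"reaction {r.id} dangling parameter {m.param!r}")
        orphans = set(names) - used
        if orphans:
            raise ValueError(f"species in no reaction: {sorted(orphans)}")
        for s in self.species:
            if s.phospho_partner is not None:
                partner = next(
                    (q for q in self.species if q.name == s.phospho_partner), None
                )
                if partner is None:
                    raise ValueError(
                        f"{s.name} phospho_partner {s.phospho_partner!r} missing"
                    )
        for node, forms in self.node_forms.items():
            for f in forms:
                if f not in known:
                    raise ValueError(f"node {node!r} maps to missing species {f!r}")
        for v in self.parameters.values():
            if v < 0:
                raise ValueError("kinetic parameters must be >= 0")

    # -- introspection ------------------------------------------------------

    @property
    def species_names(self):
        return [s.name for s in self.species]

    def initial_vector(self) -> np.ndarray:
        return np.array([s.initial for s in self.species], dtype=float)

    def parameter_vector(self) -> np.ndarray:
        return np.array(list(self.parameters.values()), dtype=float)

    def with_parameters(self, values) -> "NetworkModel":
        """Return a copy with the full parameter vector replaced (linear scale)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.parameters),):
            raise ValueError("parameter vector length mismatch")
        new = self.copy()
        new.parameters = dict(zip(self.parameters, values))
        return new

    def with_updates(self, updates: dict) -> "NetworkModel":
        new = self.copy()
        for k, v in updates.items():
            if k not in new.parameters:
                raise KeyError(f"unknown parameter {k!r}")
            new.parameters[k] = float(v)
        return new

    def with_initials(self, updates: dict) -> "NetworkModel":
        new = self.copy()
        sp = []
        for s in new.species:
            if s.name in updates:
                sp.append(replace(s, initial=float(updates[s.name])))
            else:
                sp.append(s)
        new.species = sp
        new._index = {s.name: i for i, s in enumerate(new.species)}
        new._rhs = None
        return new

    def copy(self) -> "NetworkModel":
        new = object.__new__(NetworkModel)
        new.species = list(self.species)
        new.reactions = list(self.reactions)
        new.parameters = dict(self.parameters)
        new.ligand_map = dict(self.ligand_map)
        new.node_forms = dict(self.node_forms)
        new.perturbable_registry = list(self.perturbable_registry)
        new.observable_map = {k: list(v) for k, v in self.observable_map.items()}
        new.conservation_groups = list(self.conservation_groups)
        new.growth_medium = dict(self.growth_medium)
        new.parameter_bounds = dict(self.parameter_bounds)
        new._rhs = None
        new._index = dict(self._index)
        new._pindex = dict(self._pindex)
        # pending drug scales are part of model state
        new._drug_scales = dict(getattr(self, "_drug_scales", {}))
        return new

    # -- drug state ---------------------------------------------------------

    @property
    def drug_scales(self) -> dict:
        """Per-species activity scales accumulated by apply_inhibition."""
        return dict(getattr(self, "_drug_scales", {}))

    # -- code generation ----------------------------------------------------

    def _compile(self):
        """Generate the RHS function rhs(t, y, p, u, a) from the reaction list.

        y: state vector, p: parameter vector, u: dict of ligand input values,
        a: per-species activity-scale vector (drug attenuation).
        """
        idx = self._index
        pidx = self._pindex
        ligand_ids = set(self.ligand_map.values())

        def conc(name, catalytic):
            # catalytic positions see the drug-scaled effective concentration
            if name in ligand_ids:
                return f"u[{name!r}]"
            i = idx[name]
            if catalytic:
                return f"(a[{i}]*y[{i}])"
            return f"y[{i}]"

        flux_lines = []
        stoich = {}  # species index -> list of (flux_var, +/-1)
        for n, r in enumerate(self.reactions):
            fv = f"v{n}"
            mods = []
            for m in r.modifiers:
                mods.append(_mod_expr(conc(m.species, True), m, pidx))
            mod_prod = "*".join(mods) if mods else ""
            if r.rate_law == "mass_action":
                k = f"p[{pidx[r.params['k']]}]"
                terms = [k] + [conc(s, False) for s in r.reactants]
                expr = "*".join(terms)
            elif r.rate_law == "michaelis_menten":
                k = f"p[{pidx[r.params['k']]}]"
                Km = f"p[{pidx[r.params['Km']]}]"
                S = conc(r.reactants[0], False)
                expr = f"{k}*{S}/({Km} + {S})"
            elif r.rate_law == "hill":
                k = f"p[{pidx[r.params['k']]}]"
                K = f"p[{pidx[r.params['K']]}]"
                nH = f"p[{pidx[r.params['n']]}]"
                A = conc(r.modifiers[0].species, True)
                expr = f"{k}*({A}**{nH})/({K}**{nH} + {A}**{nH} + 1e-300)"
                mods = mods[1:]  # first modifier is the inducer itself
                mod_prod = "*".join(mods) if mods else ""
            elif r.rate_law == "synthesis":
                expr = f"p[{pidx[r.params['k']]}]"
            elif r.rate_law == "degradation":
                k = f"p[{pidx[r.params['k']]}]"
                expr = f"{k}*{conc(r.reactants[0], False)}"
            else:  # pragma: no cover
                raise AssertionError(r.rate_law)
            if mod_prod:
                expr = f"{expr}*{mod_prod}"
            flux_lines.append(f"    {fv} = {expr}")
            for s in r.reactants:
                if s in idx:
                    stoich.setdefault(idx[s], []).append((fv, -1))
            for s in r.products:
                if s in idx:
                    stoich.setdefault(idx[s], []).append((fv, +1))

        dy_lines = []
        for i in range(len(self.species)):
            contribs = stoich.get(i, [])
            if not contribs:
                dy_lines.append(f"    dy[{i}] = 0.0")
                continue
            parts = "".join(
                (f" + {fv}" if sgn > 0 else f" - {fv}") for fv, sgn in contribs
            )
            dy_lines.append(f"    dy[{i}] ={parts}")

        src = (
            "def _rhs(t, y, p, u, a, dy):\n"
            + "\n".join(flux_lines)
            + "\n"
            + "\n".join(dy_lines)
            + "\n    return dy\n"
        )
        ns = {}
        exec(compile(src, f"<network-rhs:{id(self)}>", "exec"), ns)
        self._rhs_source = src
        self._rhs = ns["_rhs"]

    def rhs(self):
        if self._rhs is None:
            self._compile()
        return self._rhs

    # -- simulation helpers -------------------------------------------------

    def _activity_vector(self, drugs=()) -> np.ndarray:
        a = np.ones(len(self.species), dtype=float)
        scales = dict(getattr(self, "_drug_scales", {}))
        for d in drugs:
            forms = self._forms_for(d.target_node)
            for f in forms:
                scales[f] = scales.get(f, 1.0) * d.activity_scale
        for name, s in scales.items():
            a[self._index[name]] = s
        return a

    def _forms_for(self, node: str):
        if node in self.node_forms:
            return self.node_forms[node]
        if node in self._index:
            return [node]
        raise KeyError(f"unknown perturbation target {node!r}")

    def _inputs(self, stimulus) -> dict:
        u = {lid: 0.0 for lid in set(self.ligand_map.values())}
        stimuli = stimulus if isinstance(stimulus, (list, tuple)) else [stimulus]
        for st in stimuli:
            if st is None:
                continue
            if st.ligand == "growth-medium":
                for lig, conc in self.growth_medium.items():
                    u[self.ligand_map[lig]] += conc * st.concentration
            else:
                u[self.ligand_map[st.ligand]] += st.concentration
        return u

    def residual_norm(self, stimulus=None, drugs=()) -> float:
        """max |dy/dt| at the current initial conditions."""
        y = self.initial_vector()
        p = self.parameter_vector()
        u = self._inputs(stimulus)
        a = self._activity_vector(drugs)
        dy = np.empty_like(y)
        self.rhs()(0.0, y, p, u, a, dy)
        return float(np.max(np.abs(dy)))


def simulate_timecourse(
    model: NetworkModel,
    stimulus=None,
    drugs=(),
    grid=None,
    rtol=RTOL,
    atol=ATOL,
    method="LSODA",
    params=None,
) -> Trajectory:
    """Integrate the network ODEs over ``grid`` (minutes).

    ``stimulus`` may be a StimulusInput, a list of them, or None (starved).
    ``params`` optionally overrides the full parameter vector (linear scale)
    without copying the model -- used heavily during calibration.
    """
    if grid is None:
        grid = np.linspace(0.0, 1440.0, 97)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing with >= 2 points")
    if grid[-1] > 72 * 60 * 1.0000001:
        raise ValueError("time grid must lie within [0, 72 h]")

    y0 = model.initial_vector()
    p = model.parameter_vector() if params is None else np.asarray(params, float)
    a = model._activity_vector(drugs)
    rhs = model.rhs()
    dy_buf = np.empty_like(y0)

    stimuli = stimulus if isinstance(stimulus, (list, tuple)) else [stimulus]
    onsets = sorted({s.onset_time for s in stimuli if s is not None})
    breakpoints = [t for t in onsets if grid[0] < t < grid[-1]]

    segments = []
    edges = [grid[0]] + breakpoints + [grid[-1]]
    for lo, hi in zip(edges[:-1], edges[1:]):
        segments.append((lo, hi))

    times = [grid[0]]
    states = [y0.copy()]
    y = y0
    nsteps = 0
    for lo, hi in segments:
        active = [
            s
            for s in stimuli
            if s is not None and s.onset_time <= lo + 1e-12
        ]
        u = model._inputs(active)
        t_eval = grid[(grid > lo + 1e-12) & (grid <= hi + 1e-12)]
        t_eval = np.unique(np.concatenate([t_eval, [hi]]))
        sol = solve_ivp(
            lambda t, yy: rhs(t, yy, p, u, a, dy_buf).copy(),
            (lo, hi),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed in [{lo}, {hi}]: {sol.message}",
                diagnostics={"segment": (lo, hi), "message": sol.message},
            )
        nsteps += sol.t.size
        for tt, col in zip(sol.t, sol.y.T):
            if any(abs(tt - g) < 1e-9 for g in grid):
                if tt > times[-1] + 1e-12:
                    times.append(tt)
                    states.append(col)
        y = sol.y[:, -1]

    Y = np.array(states).T
    if not np.all(np.isfinite(Y)):
        raise SimulationError("non-finite abundances in trajectory")
    if np.min(Y) < -atol * 100:
        raise SimulationError(f"negative abundance beyond tolerance: min={np.min(Y)}")
    Y = np.maximum(Y, -atol)
    return Trajectory(
        time_grid=np.array(times),
        abundance_matrix=Y,
        species_names=model.species_names,
        solver_diagnostics={"n_time_points": nsteps, "rtol": rtol, "atol": atol},
    )


def equilibrate(
    model: NetworkModel,
    basal_stimulus=None,
    horizon=1e5,
    tol=1e-8,
    rtol=RTOL,
    atol=ATOL,
) -> NetworkModel:
    """Replace initial conditions by the basal steady state.

    Integrates up to ``horizon`` minutes under ``basal_stimulus`` (default:
    the model's growth-medium composite) and checks max |dy/dt| < tol.
    """
    if basal_stimulus is None:
        basal_stimulus = StimulusInput("growth-medium", 1.0)
    stimuli = (
        basal_stimulus if isinstance(basal_stimulus, (list, tuple)) else [basal_stimulus]
    )
    u = model._inputs(stimuli)
    p = model.parameter_vector()
    a = model._activity_vector()
    rhs = model.rhs()
    dy_buf = np.empty(len(model.species))
    y = model.initial_vector()

    t_done = 0.0
    chunk = 5e3
    while t_done < horizon:
        t_end = min(t_done + chunk, horizon)
        sol = solve_ivp(
            lambda t, yy: rhs(t, yy, p, u, a, dy_buf).copy(),
            (t_done, t_end),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"equilibration failed: {sol.message}")
        y = sol.y[:, -1]
        t_done = t_end
        res = float(np.max(np.abs(rhs(0.0, y, p, u, a, dy_buf))))
        if res < tol:
            break
        chunk *= 2
    else:
        res = float(np.max(np.abs(rhs(0.0, y, p, u, a, dy_buf))))
    if res >= tol:
        raise SteadyStateError(
            f"no steady state within {horizon:g} min (residual {res:.3e})", res
        )
    y = np.maximum(y, 0.0)
    return model.with_initials(dict(zip(model.species_names, y)))


def apply_inhibition(model: NetworkModel, drug: DrugPerturbation) -> NetworkModel:
    """Return a model whose target node activity is persistently attenuated.

    Composable: applying two drugs multiplies their scales.
    """
    forms = model._forms_for(drug.target_node)  # raises for unknown targets
    new = model.copy()
    scales = dict(getattr(new, "_drug_scales", {}))
    for f in forms:
        scales[f] = scales.get(f, 1.0) * drug.activity_scale
    new._drug_scales = scales
    return new


def extract_readouts(trajectory: Trajectory, mapping: dict, times=None):
    """Sum mapped species to observables at requested times.

    ``mapping``: observable name -> list of species names.  Returns a dict
    observable -> np.ndarray over ``times`` (default: the full grid).
    """
    out = {}
    tg = trajectory.time_grid
    for obs, specs in mapping.items():
        if not specs:
            raise KeyError(f"observable {obs!r} maps to no species")
        total = np.zeros_like(tg)
        for s in specs:
            total = total + trajectory.series(s)
        if times is None:
            out[obs] = total
        else:
            times = np.asarray(times, dtype=float)
            vals = np.interp(times, tg, total)
            for t in times:
                if t < tg[0] - 1e-9 or t > tg[-1] + 1e-9:
                    raise ValueError(f"time {t} outside trajectory horizon")
            out[obs] = vals
    return out


def conservation_check(model: NetworkModel, group) -> bool:
    """Verify by stoichiometry that a species group total is invariant.

    True iff every reaction's net stoichiometric change summed over the group
    is zero (synthesis/degradation reactions touching the group fail this).
    """
    gset = set(group)
    for r in model.reactions:
        net = 0
        for s in r.reactants:
            if s in gset:
                net -= 1
        for s in r.products:
            if s in gset:
                net += 1
        if net != 0:
            return False
    return True
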