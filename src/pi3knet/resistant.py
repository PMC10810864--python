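"""Resistant-model derivation by fold-change adjustment of initial conditions.

BYL719-resistant T47D pools show durably rewired basal expression relative to
parental cells; the resistant network model is the parental model with the
initial abundance of the affected species scaled by the measured fold change
(default: p21 x7, cyclin D1 x3, AKT and ERK x1), with wiring and kinetics
otherwise identical.

Two derivation modes are supported.  With ``reequilibrate=False`` the fold
is applied verbatim to the unmodified form's initial condition (the scaled
totals are exact).  With ``reequilibrate=True`` (the default) the elevated
expression is made self-sustaining — the synthesis fluxes feeding a folded
expression-level species are scaled by the same fold so the new level is a
fixed point rather than a transient — and the model is re-equilibrated under
the basal growth-medium stimulus to redistribute phospho/complex forms.
Without this, first-order turnover would relax p21 and cyclin D1 back to
parental levels within hours, contradicting the stable resistant phenotype
the fold changes describe.
"""

from __future__ import annotations

import numpy as np

from .network import (
    DrugPerturbation,
    NetworkModel,
    equilibrate,
    extract_readouts,
    simulate_timecourse,
)

__all__ = ["FoldChangeTable", "DEFAULT_FOLDS", "derive_resistant_model",
           "compare_states"]

#: measured basal fold changes, resistant vs parental
DEFAULT_FOLDS = {"p21": 7.0, "cycD1": 3.0, "AKT": 1.0, "ERK": 1.0}


class FoldChangeTable(dict):
    """Mapping species name -> positive fold change."""

    def __init__(self, folds=None):
        super().__init__(DEFAULT_FOLDS if folds is None else folds)
        for name, f in self.items():
            if not (f > 0):
                raise ValueError(f"fold for {name!r} must be > 0")

    def validate(self, model: NetworkModel):
        for name in self:
            if name not in model.species_names:
                raise KeyError(f"fold-change species {name!r} not in model")


def _moiety_members(model: NetworkModel, name: str):
    for group in model.conservation_groups:
        if name in group:
            return list(group)
    return [name]


def derive_resistant_model(
    parental: NetworkModel,
    folds=None,
    reequilibrate: bool = True,
    basal_stimulus=None,
) -> NetworkModel:
    """Scale initial conditions (and, by default, sustaining synthesis) by folds."""
    table = folds if isinstance(folds, FoldChangeTable) else FoldChangeTable(folds)
    table.validate(parental)

    # fold the initial abundance of every form of the species' moiety
    updates = {}
    for name, f in table.items():
        for member in _moiety_members(parental, name):
            idx = parental.species_names.index(member)
            updates[member] = parental.species[idx].initial * f
    model = parental.with_initials(updates)

    if reequilibrate:
        # make folded expression levels self-sustaining: scale the synthesis
        # fluxes that feed any form of the folded moiety
        pupd = {}
        for name, f in table.items():
            if f == 1.0:
                continue
            members = set(_moiety_members(parental, name))
            for r in parental.reactions:
                if r.rate_law in ("synthesis", "hill") and set(r.products) & members:
                    kname = r.params["k"]
                    pupd[kname] = model.parameters[kname] * f
        if pupd:
            model = model.with_updates(pupd)
        model = equilibrate(model, basal_stimulus=basal_stimulus)
    return model


def compare_states(
    parental: NetworkModel,
    resistant: NetworkModel,
    drug: DrugPerturbation | None = None,
    readouts=("pAKT", "pERK", "pS6"),
    stimulus=None,
    grid=None,
) -> dict:
    """Simulate both models under the same stimulus/drug; return paired readouts.

    Returns {"times": t, "parental": {obs: arr}, "resistant": {obs: arr},
    "difference": {obs: resistant - parental}}.
    """
    if set(parental.species_names) != set(resistant.species_names):
        raise ValueError("models do not share a species set")
    if grid is None:
        grid = np.linspace(0.0, 2880.0, 49)
    if stimulus is None:
        from .network import StimulusInput

        stimulus = StimulusInput("growth-medium", 1.0)
    drugs = [drug] if drug is not None else []
    mapping_p = {r: parental.observable_map[r] for r in readouts}
    mapping_r = {r: resistant.observable_map[r] for r in readouts}
    tr_p = simulate_timecourse(parental, stimulus, drugs=drugs, grid=grid)
    tr_r = simulate_timecourse(resistant, stimulus, drugs=drugs, grid=grid)
    ro_p = extract_readouts(tr_p, mapping_p)
    ro_r = extract_readouts(tr_r, mapping_r)
    return {
        "times": np.asarray(grid, dtype=float),
        "parental": ro_p,
        "resistant": ro_r,
        "difference": {r: ro_r[r] - ro_p[r] for r in readouts},
    }
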