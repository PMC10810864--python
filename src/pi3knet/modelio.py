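"""File formats: model tables, observations, ensembles, SBML export.

A model directory holds three tab-separated tables:

* ``species.tsv``    — name, role, initial, phospho_partner, observables
* ``reactions.tsv``  — id, reactants, products, modifiers, rate_law, params
* ``parameters.tsv`` — name, value, log10_lower, log10_upper

plus an optional ``meta.tsv`` with ligand mapping, node forms, registry,
observable map and conservation groups (key/value rows, ``;``-separated
lists).  Observations are long-format CSV; ensembles are CSV matrices (one
row per retained set).  All readers reject malformed input with an error
naming the file and line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ObservationSet, ParameterEnsemble
from .network import Modifier, NetworkModel, Reaction, Species, StimulusInput

__all__ = [
    "save_model_tables",
    "load_model_tables",
    "save_observations",
    "load_observations",
    "save_ensemble",
    "load_ensemble",
    "export_sbml",
    "count_sbml",
    "model_digest",
    "write_manifest",
]


class ModelFormatError(ValueError):
    """Schema violation in a model table, located by file and line."""


# ---------------------------------------------------------------------------
# model tables


def _join(items):
    return ";".join(items) if items else ""


def _split(text):
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    return str(text).split(";")


def save_model_tables(model: NetworkModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sp = pd.DataFrame(
        [
            {
                "name": s.name,
                "role": s.role,
                "initial": repr(s.initial),
                "phospho_partner": s.phospho_partner or "",
                "observables": _join(s.observables),
            }
            for s in model.species
        ]
    )
    sp.to_csv(path / "species.tsv", sep="\t", index=False)

    rx = pd.DataFrame(
        [
            {
                "id": r.id,
                "reactants": _join(r.reactants),
                "products": _join(r.products),
                "modifiers": _join(
                    f"{m.species}:{m.sign}:{m.kind}:{m.param}" for m in r.modifiers
                ),
                "rate_law": r.rate_law,
                "params": _join(f"{slot}={name}" for slot, name in r.params.items()),
            }
            for r in model.reactions
        ]
    )
    rx.to_csv(path / "reactions.tsv", sep="\t", index=False)

    pm = pd.DataFrame(
        [
            {
                "name": n,
                "value": repr(v),
                "log10_lower": model.parameter_bounds.get(n, ("", ""))[0],
                "log10_upper": model.parameter_bounds.get(n, ("", ""))[1],
            }
            for n, v in model.parameters.items()
        ]
    )
    pm.to_csv(path / "parameters.tsv", sep="\t", index=False)

    meta = {
        "ligand_map": json.dumps(model.ligand_map),
        "node_forms": json.dumps(model.node_forms),
        "perturbable_registry": _join(model.perturbable_registry),
        "observable_map": json.dumps(model.observable_map),
        "conservation_groups": json.dumps(
            [list(g) for g in model.conservation_groups]
        ),
        "growth_medium": json.dumps(model.growth_medium),
    }
    with open(path / "meta.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for k, v in meta.items():
            fh.write(f"{k}\t{v}\n")


def _read_tsv(path: Path, required_cols):
    if not path.exists():
        raise ModelFormatError(f"{path}: file missing")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(required_cols) - set(df.columns)
    if missing:
        raise ModelFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_model_tables(path) -> NetworkModel:
    path = Path(path)
    sp_df = _read_tsv(path / "species.tsv",
                      ["name", "role", "initial", "phospho_partner", "observables"])
    species = []
    for i, row in sp_df.iterrows():
        try:
            species.append(
                Species(
                    name=row["name"],
                    role=row["role"],
                    initial=float(row["initial"]),
                    phospho_partner=row["phospho_partner"] or None,
                    observables=tuple(_split(row["observables"])),
                )
            )
        except (ValueError, TypeError) as e:
            raise ModelFormatError(f"{path/'species.tsv'}:{i + 2}: {e}") from e

    pm_df = _read_tsv(path / "parameters.tsv",
                      ["name", "value", "log10_lower", "log10_upper"])
    parameters, bounds = {}, {}
    for i, row in pm_df.iterrows():
        name = row["name"]
        if name in parameters:
            raise ModelFormatError(
                f"{path/'parameters.tsv'}:{i + 2}: duplicate parameter {name!r}"
            )
        try:
            parameters[name] = float(row["value"])
        except ValueError as e:
            raise ModelFormatError(f"{path/'parameters.tsv'}:{i + 2}: {e}") from e
        if row["log10_lower"] != "" and row["log10_upper"] != "":
            bounds[name] = (float(row["log10_lower"]), float(row["log10_upper"]))

    rx_df = _read_tsv(path / "reactions.tsv",
                      ["id", "reactants", "products", "modifiers", "rate_law",
                       "params"])
    reactions = []
    for i, row in rx_df.iterrows():
        line = i + 2
        mods = []
        for tok in _split(row["modifiers"]):
            parts = tok.split(":")
            if len(parts) != 4:
                raise ModelFormatError(
                    f"{path/'reactions.tsv'}:{line}: bad modifier {tok!r}"
                )
            mods.append(Modifier(parts[0], int(parts[1]), parts[3], kind=parts[2]))
        params = {}
        for tok in _split(row["params"]):
            if "=" not in tok:
                raise ModelFormatError(
                    f"{path/'reactions.tsv'}:{line}: bad param slot {tok!r}"
                )
            slot, pname = tok.split("=", 1)
            params[slot] = pname
        try:
            reactions.append(
                Reaction(
                    id=row["id"],
                    reactants=tuple(_split(row["reactants"])),
                    products=tuple(_split(row["products"])),
                    rate_law=row["rate_law"],
                    params=params,
                    modifiers=tuple(mods),
                )
            )
        except ValueError as e:
            raise ModelFormatError(f"{path/'reactions.tsv'}:{line}: {e}") from e

    meta = {}
    meta_path = path / "meta.tsv"
    if meta_path.exists():
        meta_df = _read_tsv(meta_path, ["key", "value"])
        meta = dict(zip(meta_df["key"], meta_df["value"]))

    try:
        return NetworkModel(
            species=species,
            reactions=reactions,
            parameters=parameters,
            ligand_map=json.loads(meta.get("ligand_map", "{}")),
            node_forms=json.loads(meta.get("node_forms", "{}")),
            perturbable_registry=_split(meta.get("perturbable_registry", "")),
            observable_map=json.loads(meta.get("observable_map", "{}")),
            conservation_groups=json.loads(meta.get("conservation_groups", "[]")),
            growth_medium=json.loads(meta.get("growth_medium", "null")) or None,
            parameter_bounds=bounds,
        )
    except ValueError as e:
        raise ModelFormatError(f"{path}: {e}") from e


def model_digest(model: NetworkModel) -> str:
    """Stable content hash of topology, parameters and initial conditions."""
    h = hashlib.sha256()
    for s in model.species:
        h.update(f"{s.name}|{s.role}|{s.initial!r}|{s.phospho_partner}".encode())
    for r in model.reactions:
        h.update(
            f"{r.id}|{r.reactants}|{r.products}|{r.rate_law}|{sorted(r.params.items())}"
            .encode()
        )
        for m in r.modifiers:
            h.update(f"{m.species}|{m.sign}|{m.kind}|{m.param}".encode())
    for n, v in model.parameters.items():
        h.update(f"{n}={v!r}".encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# observations


def save_observations(observations, path) -> None:
    rows = []
    for o in observations:
        stim = o.stimulus if not isinstance(o.stimulus, (list, tuple)) else o.stimulus[0]
        drug = o.drugs[0] if o.drugs else None
        for t, m, v in zip(o.times, o.means, o.variances):
            rows.append(
                {
                    "condition_id": o.condition_id,
                    "ligand": stim.ligand,
                    "ligand_nM": repr(stim.concentration),
                    "drug": drug.drug_label if drug else "",
                    "drug_uM": repr(drug.dose) if drug else "",
                    "observable": o.observable,
                    "time_min": repr(float(t)),
                    "mean": repr(float(m)),
                    "variance": repr(float(v)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_observations(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"condition_id", "ligand", "ligand_nM", "observable", "time_min",
                "mean", "variance"}
    missing = required - set(df.columns)
    if missing:
        raise ModelFormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (cid, obs), grp in df.groupby(["condition_id", "observable"], sort=False):
        grp = grp.sort_values("time_min", key=lambda s: s.astype(float))
        first = grp.iloc[0]
        stim = StimulusInput(first["ligand"], float(first["ligand_nM"]))
        drugs = ()
        if "drug" in grp.columns and first.get("drug", ""):
            from .presets import byl719

            drugs = (byl719(float(first["drug_uM"])),)
        out.append(
            ObservationSet(
                condition_id=cid,
                stimulus=stim,
                drugs=drugs,
                observable=obs,
                times=grp["time_min"].astype(float).to_numpy(),
                means=grp["mean"].astype(float).to_numpy(),
                variances=grp["variance"].astype(float).to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ensembles


def save_ensemble(ensemble: ParameterEnsemble, path) -> None:
    cols = {"seed": ensemble.seeds, "J": [repr(float(j)) for j in ensemble.J_values]}
    for j, name in enumerate(ensemble.parameter_names):
        cols[name] = [repr(float(v)) for v in ensemble.sets[:, j]]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_ensemble(path, retention_tolerance: float = 0.2) -> ParameterEnsemble:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "J" not in df.columns or "seed" not in df.columns:
        raise ModelFormatError(f"{path}: ensemble CSV needs 'seed' and 'J' columns")
    names = [c for c in df.columns if c not in ("seed", "J")]
    return ParameterEnsemble(
        parameter_names=names,
        sets=df[names].astype(float).to_numpy(),
        J_values=df["J"].astype(float).to_numpy(),
        seeds=df["seed"].to_numpy(),
        retention_tolerance=retention_tolerance,
    )


# ---------------------------------------------------------------------------
# SBML export (minimal Level 3 Version 2 writer)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_SUPPORTED_LAWS = {"mass_action", "michaelis_menten", "hill", "synthesis",
                   "degradation"}


class UnsupportedRateLawError(ValueError):
    pass


def _mathml_rate(E, r: Reaction, model: NetworkModel):
    """Build a <math> expression mirroring the generated rate expression."""

    def ci(name):
        el = E("ci")
        el.text = f" {name} "
        return el

    def cn(value):
        el = E("cn")
        el.text = f" {value} "
        return el

    def apply(op, *args):
        el = E("apply")
        el.append(E(op))
        for a in args:
            el.append(a)
        return el

    def mod_term(m: Modifier):
        x = ci(m.species)
        K = ci(m.param)
        if m.kind == "lin":
            return apply("divide", x, K)
        if m.kind == "boost":
            return apply("plus", cn(1), apply("divide", ci(m.species), K))
        if m.sign > 0:
            return apply("divide", x, apply("plus", K, ci(m.species)))
        return apply("divide", cn(1),
                     apply("plus", cn(1), apply("divide", x, K)))

    factors = []
    if r.rate_law == "mass_action":
        factors.append(ci(r.params["k"]))
        factors.extend(ci(s) for s in r.reactants)
        mods = r.modifiers
    elif r.rate_law == "michaelis_menten":
        S = r.reactants[0]
        factors.append(ci(r.params["k"]))
        factors.append(
            apply("divide", ci(S), apply("plus", ci(r.params["Km"]), ci(S)))
        )
        mods = r.modifiers
    elif r.rate_law == "hill":
        A = r.modifiers[0].species
        k, K, n = r.params["k"], r.params["K"], r.params["n"]
        num = apply("power", ci(A), ci(n))
        den = apply("plus", apply("power", ci(K), ci(n)),
                    apply("power", ci(A), ci(n)))
        factors.append(ci(k))
        factors.append(apply("divide", num, den))
        mods = r.modifiers[1:]
    elif r.rate_law == "synthesis":
        factors.append(ci(r.params["k"]))
        mods = r.modifiers
    elif r.rate_law == "degradation":
        factors.append(ci(r.params["k"]))
        factors.append(ci(r.reactants[0]))
        mods = r.modifiers
    else:
        raise UnsupportedRateLawError(
            f"rate law {r.rate_law!r} has no SBML mapping"
        )
    factors.extend(mod_term(m) for m in mods)
    if len(factors) == 1:
        return factors[0]
    return apply("times", *factors)


def _sbml_id(name: str) -> str:
    out = []
    for ch in name:
        out.append(ch if (ch.isalnum() or ch == "_") else "_")
    sid = "".join(out)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "s_" + sid
    return sid


def export_sbml(model: NetworkModel, path) -> None:
    """Write the model as a minimal SBML Level 3 Version 2 document."""
    from lxml import etree

    for r in model.reactions:
        if r.rate_law not in _SUPPORTED_LAWS:
            raise UnsupportedRateLawError(
                f"rate law {r.rate_law!r} in reaction {r.id} is not exportable"
            )

    # species names may contain characters invalid in SBML ids
    rename = {s.name: _sbml_id(s.name) for s in model.species}
    for lid in set(model.ligand_map.values()):
        rename[lid] = _sbml_id(lid)

    NSMAP = {None: SBML_NS}
    sbml = etree.Element("sbml", nsmap=NSMAP, level="3", version="2")
    m = etree.SubElement(sbml, "model", id="pi3k_network")
    lc = etree.SubElement(m, "listOfCompartments")
    etree.SubElement(lc, "compartment", id="cell", constant="true", size="1")

    ls = etree.SubElement(m, "listOfSpecies")
    for s in model.species:
        etree.SubElement(
            ls, "species", id=rename[s.name], name=s.name, compartment="cell",
            initialConcentration=repr(s.initial), constant="false",
            hasOnlySubstanceUnits="false", boundaryCondition="false",
        )
    for lid in sorted(set(model.ligand_map.values())):
        etree.SubElement(
            ls, "species", id=rename[lid], name=lid, compartment="cell",
            initialConcentration="0", constant="false",
            hasOnlySubstanceUnits="false", boundaryCondition="true",
        )

    lp = etree.SubElement(m, "listOfParameters")
    for n, v in model.parameters.items():
        etree.SubElement(lp, "parameter", id=_sbml_id(n), name=n,
                         value=repr(v), constant="true")

    lr = etree.SubElement(m, "listOfReactions")
    ME = lambda tag: etree.Element(f"{{{MATHML_NS}}}{tag}")  # noqa: E731
    for r in model.reactions:
        rx = etree.SubElement(lr, "reaction", id=_sbml_id(r.id),
                              reversible="false")
        if r.reactants:
            lre = etree.SubElement(rx, "listOfReactants")
            for s in r.reactants:
                etree.SubElement(lre, "speciesReference", species=rename[s],
                                 stoichiometry="1", constant="true")
        if r.products:
            lpr = etree.SubElement(rx, "listOfProducts")
            for s in r.products:
                etree.SubElement(lpr, "speciesReference", species=rename[s],
                                 stoichiometry="1", constant="true")
        if r.modifiers:
            lmo = etree.SubElement(rx, "listOfModifiers")
            seen = set()
            for mod in r.modifiers:
                if mod.species in seen:
                    continue
                seen.add(mod.species)
                etree.SubElement(lmo, "modifierSpeciesReference",
                                 species=rename[mod.species])
        kl = etree.SubElement(rx, "kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        # rename species inside the math expression
        expr = _mathml_rate(ME, r, model)
        for ci in expr.iter(f"{{{MATHML_NS}}}ci"):
            token = ci.text.strip()
            ci.text = f" {rename.get(token, _sbml_id(token))} "
        if expr.tag == f"{{{MATHML_NS}}}ci":
            token = expr.text.strip()
            expr.text = f" {rename.get(token, _sbml_id(token))} "
        math.append(expr)

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def count_sbml(path) -> dict:
    """Species/parameter/reaction counts of an SBML file (round-trip check)."""
    from lxml import etree

    tree = etree.parse(str(path))
    ns = {"s": SBML_NS}
    boundary = tree.xpath(
        "//s:listOfSpecies/s:species[@boundaryCondition='true']", namespaces=ns
    )
    species = tree.xpath("//s:listOfSpecies/s:species", namespaces=ns)
    params = tree.xpath("//s:listOfParameters/s:parameter", namespaces=ns)
    reactions = tree.xpath("//s:listOfReactions/s:reaction", namespaces=ns)
    values = {p.get("name", p.get("id")): float(p.get("value"))
              for p in params}
    return {
        "n_species": len(species) - len(boundary),
        "n_boundary": len(boundary),
        "n_parameters": len(params),
        "n_reactions": len(reactions),
        "parameter_values": values,
    }


# ---------------------------------------------------------------------------
# run manifests


def write_manifest(out_dir, config: dict, inputs=None) -> Path:
    """Write a reproducibility manifest (config, versions, input digests)."""
    import pi3knet

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [f"pi3knet_version: {pi3knet.__version__}"]
    lines.append(f"numpy_version: {np.__version__}")
    for k in sorted(config):
        lines.append(f"{k}: {config[k]}")
    for label, p in sorted((inputs or {}).items()):
        p = Path(p)
        if p.is_file():
            digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        elif p.is_dir():
            h = hashlib.sha256()
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    h.update(f.read_bytes())
            digest = h.hexdigest()[:16]
        else:
            digest = "missing"
        lines.append(f"input_{label}: {p} sha256:{digest}")
    manifest = out_dir / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
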