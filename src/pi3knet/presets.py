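"""Builtin model presets.

``build_parental_model`` constructs the integrated PI3K signaling network:
receptor tyrosine kinases (IGFR/IR, ErbB), the PI3Kalpha/beta-PIP3 axis with
PDK1/AKT/mTOR effectors, the SGK1/FOXO3 and SGK3/NDRG1 arms, the
Ras/Raf/MEK/ERK cascade, the ERalpha transcriptional module, and the
cell-cycle machinery (cyclin D1/E, CDK4/6, CDK2, Rb, E2F, p21), wired with
the documented feedback and crosstalk loops:

* hyper-phosphorylated Rb suppresses mTORC2 activation (Rb -| mTORC2/AKT)
* cyclin D1-CDK4/6 phosphorylates and inhibits TSC2 (positive loop to mTORC1)
* S6K1-mediated negative feedback on IRS
* PIP3 -> GAB -> PI3K positive feedback
* P-Rex1/Rac1 -> p110beta positive feedback, and Rac1 -> MEK
* ERK negative feedback on Ras and on ErbB (nested short/long loops)
* AKT/SGK1 -| FOXO3 -> ERalpha; ERalpha -> cMyc and -> SGK3; ERK -> ERalpha
* NDRG1 -| ErbB; SGK1/3 -> pNDRG1 -> degradation
* Ras -> PI3Kalpha; AKT -| Raf; ERK -| GAB
* mTORC1-dependent translation of cMyc and cyclin D1
* sequential Rb phosphorylation (cyclin D1-CDK4/6 then cyclin E-CDK2)
* E2F auto-activation and E2F(+Myc) induction of cyclin E
* ERK-driven p21 expression; AKT stabilizes p21
* p21 dual role: promotes cyclin D1-CDK4/6 assembly, inhibits cyclin E-CDK2

The default parameter values are a hand-calibrated demo parameterization:
they reproduce the qualitative behaviors the model is used for (growth-factor
-> pathway activation, PI3Kalpha inhibition -> pAKT/pS6 suppression,
p21/cyclin D1 overexpression -> partial pS6/pRb rescue) and serve as the
center of the packaged demo ensemble.  Full-data calibration uses the
machinery in :mod:`pi3knet.calibration`.
"""

from __future__ import annotations

import numpy as np

from .network import (
    DrugPerturbation,
    Modifier,
    NetworkModel,
    Reaction,
    Species,
    StimulusInput,
)

__all__ = [
    "build_parental_model",
    "toy_chain3",
    "toy_birth_death",
    "toy_pi3k_chain",
    "byl719",
    "mk8776_fraction",
    "PERTURBABLE_NODES",
    "OBSERVABLE_MAP",
]

#: the 24-node co-target registry: named signaling nodes excluding the
#: PI3Kalpha anchor, pure lipid species (PIP2/PIP3) and readout-only species.
PERTURBABLE_NODES = [
    "IGFR/IR",
    "ErbB",
    "GAB",
    "IRS",
    "Ras",
    "Raf",
    "MEK",
    "ERK",
    "PI3Kb",
    "P-Rex1",
    "Rac1",
    "PDK1",
    "AKT",
    "mTORC1",
    "mTORC2",
    "TSC2",
    "S6K1",
    "SGK1",
    "SGK3",
    "FOXO3",
    "ERa",
    "cMyc",
    "CDK4/6",
    "CDK2",
]

OBSERVABLE_MAP = {
    "pAKT": ["pAKT_T308", "ppAKT"],
    "pAKT-T308": ["pAKT_T308", "ppAKT"],
    "pAKT-S473": ["ppAKT"],
    "pERK": ["pERK"],
    "pS6": ["pS6"],
    "cyclin D1": ["cycD1", "CycD1CDK46"],
    "cyclin E": ["cycE", "CycECDK2"],
    "pRb": ["pRb", "ppRb"],
    "p21": ["p21"],
    "cMyc": ["cMyc"],
    "pNDRG1": ["pNDRG1"],
}


def byl719(dose_uM: float = 1.0) -> DrugPerturbation:
    """BYL719 (alpelisib): PI3Kalpha inhibitor in dose mode, K_I = 0.05 uM.

    The inhibition constant is chosen so that the standard 1 uM treatment
    attenuates PI3Kalpha catalytic activity to ~5%, which suppresses pAKT in
    the demo parameterization as seen experimentally.
    """
    return DrugPerturbation("PI3Ka", mode="dose", dose=dose_uM, K_I=0.05,
                            drug_label="BYL719")


def mk8776_fraction(f: float = 0.9) -> DrugPerturbation:
    """MK-8776: fractional CHK1 inhibition (consumed by the phenotypic model)."""
    return DrugPerturbation("CHK1", mode="fraction", dose=f, drug_label="MK-8776")


class _Builder:
    def __init__(self):
        self.species = []
        self.reactions = []
        self.params = {}
        self.bounds = {}
        self.params["K_unit"] = 1.0  # fixed scale for linear enzyme terms

    def sp(self, name, role="kinase", initial=0.0, partner=None, obs=()):
        self.species.append(
            Species(name, role=role, initial=initial, phospho_partner=partner,
                    observables=tuple(obs))
        )

    def par(self, name, value, free=True):
        self.params[name] = float(value)
        if free:
            self.bounds[name] = (-3.0, 3.0)
        return name

    def enz(self, species):
        return Modifier(species, +1, "K_unit", kind="lin")

    def act(self, species, K, free=True):
        return Modifier(species, +1, self.par(K[0], K[1], free=free), kind="sat")

    def inh(self, species, K, free=True):
        return Modifier(species, -1, self.par(K[0], K[1], free=free), kind="sat")

    def boost(self, species, K, free=True):
        return Modifier(species, +1, self.par(K[0], K[1], free=free), kind="boost")

    def mm(self, rid, sub, prod, k, Km, modifiers=()):
        kn = self.par(f"k_{rid}", k)
        Kn = self.par(f"Km_{rid}", Km)
        self.reactions.append(
            Reaction(rid, (sub,), (prod,), "michaelis_menten",
                     {"k": kn, "Km": Kn}, tuple(modifiers))
        )

    def ma(self, rid, reactants, products, k, modifiers=()):
        kn = self.par(f"k_{rid}", k)
        self.reactions.append(
            Reaction(rid, tuple(reactants), tuple(products), "mass_action",
                     {"k": kn}, tuple(modifiers))
        )

    def hill(self, rid, product, inducer, k, K, n=1.0, extra=()):
        kn = self.par(f"k_{rid}", k)
        Kn = self.par(f"K_{rid}", K)
        nn = self.par(f"n_{rid}", n, free=False)
        mods = (Modifier(inducer, +1, Kn, kind="sat"),) + tuple(extra)
        self.reactions.append(
            Reaction(rid, (), (product,), "hill", {"k": kn, "K": Kn, "n": nn}, mods)
        )

    def synth(self, rid, product, k, modifiers=()):
        kn = self.par(f"k_{rid}", k)
        self.reactions.append(
            Reaction(rid, (), (product,), "synthesis", {"k": kn}, tuple(modifiers))
        )

    def deg(self, rid, sub, k, modifiers=()):
        kn = self.par(f"k_{rid}", k)
        self.reactions.append(
            Reaction(rid, (sub,), (), "degradation", {"k": kn}, tuple(modifiers))
        )


def build_parental_model() -> NetworkModel:
    """Build the builtin parental PI3K network model (demo parameterization).

    Returns an un-equilibrated model; call :func:`pi3knet.network.equilibrate`
    (default growth-medium basal stimulus) before simulating treatments.
    """
    b = _Builder()

    # -- state variables ---------------------------------------------------
    pairs = [
        # (inactive, active, role)
        ("IGFR", "pIGFR", "receptor"),
        ("ErbB", "pErbB", "receptor"),
        ("IRS", "pIRS", "adaptor"),
        ("GAB", "pGAB", "adaptor"),
        ("PI3Ka", "aPI3Ka", "kinase"),
        ("PI3Kb", "aPI3Kb", "kinase"),
        ("PRex1", "aPRex1", "adaptor"),
        ("Rac1", "aRac1", "kinase"),
        ("PDK1", "aPDK1", "kinase"),
        ("SGK1", "aSGK1", "kinase"),
        ("FOXO3", "pFOXO3", "transcription factor"),
        ("Ras", "aRas", "kinase"),
        ("Raf", "aRaf", "kinase"),
        ("MEK", "pMEK", "kinase"),
        ("ERK", "pERK", "kinase"),
        ("TSC2", "pTSC2", "adaptor"),
        ("mTORC1", "amTORC1", "kinase"),
        ("mTORC2", "amTORC2", "kinase"),
        ("S6K1", "pS6K1", "kinase"),
        ("S6", "pS6", "kinase"),
    ]
    for inact, act, role in pairs:
        b.sp(inact, role=role, initial=1.0, partner=act)
        b.sp(act, role=role, initial=0.0, partner=inact)
    b.sp("PIP2", role="lipid second messenger", initial=1.0, partner="PIP3")
    b.sp("PIP3", role="lipid second messenger", initial=0.0, partner="PIP2")
    # expression-level species (synthesized/degraded)
    b.sp("SGK3", role="kinase", initial=0.3, partner="aSGK3")
    b.sp("aSGK3", role="kinase", initial=0.0, partner="SGK3")
    b.sp("NDRG1", role="adaptor", initial=0.3, partner="pNDRG1")
    b.sp("pNDRG1", role="adaptor", initial=0.0, partner="NDRG1")
    b.sp("ERa", role="transcription factor", initial=0.5, partner="aERa")
    b.sp("aERa", role="transcription factor", initial=0.0, partner="ERa")
    b.sp("cMyc", role="transcription factor", initial=0.1)
    b.sp("cycD1", role="cell-cycle protein", initial=0.2)
    b.sp("CDK46", role="cell-cycle protein", initial=1.0)
    b.sp("CycD1CDK46", role="complex", initial=0.0)
    b.sp("cycE", role="cell-cycle protein", initial=0.1)
    b.sp("CDK2", role="cell-cycle protein", initial=1.0)
    b.sp("CycECDK2", role="complex", initial=0.0)
    b.sp("Rb", role="cell-cycle protein", initial=1.0, partner="pRb")
    b.sp("pRb", role="cell-cycle protein", initial=0.0, partner="Rb")
    b.sp("ppRb", role="cell-cycle protein", initial=0.0)
    b.sp("E2F", role="transcription factor", initial=0.05)
    b.sp("p21", role="cell-cycle protein", initial=0.1)

    # -- receptors ---------------------------------------------------------
    b.mm("IGFR_act_igf", "IGFR", "pIGFR", 1.0, 0.3,
         [b.act("L_IGF1", ("K_lig_IGF1", 3.0))])
    b.mm("IGFR_act_ins", "IGFR", "pIGFR", 1.0, 0.3,
         [b.act("L_INS", ("K_lig_INS", 5.0))])
    b.ma("IGFR_de", ["pIGFR"], ["IGFR"], 1.5)
    # ErbB: HRG-driven; NDRG1 -| ErbB; long ERK negative feedback
    b.mm("ErbB_act", "ErbB", "pErbB", 3.0, 0.3,
         [b.act("L_HRG", ("K_lig_HRG", 0.2)),
          b.inh("NDRG1", ("K_ndrg1_erbb", 1.0)),
          b.inh("pERK", ("K_erk_erbb", 1.5))])
    b.ma("ErbB_de", ["pErbB"], ["ErbB"], 1.5)

    # -- adaptors ----------------------------------------------------------
    b.mm("IRS_act", "IRS", "pIRS", 2.0, 0.3,
         [b.enz("pIGFR"), b.inh("pS6K1", ("K_s6k_irs", 0.2))])
    b.ma("IRS_de", ["pIRS"], ["IRS"], 0.5)
    b.mm("GAB_act", "GAB", "pGAB", 2.0, 0.3,
         [b.enz("pErbB"), b.boost("PIP3", ("K_pip3_gab", 0.3)),
          b.inh("pERK", ("K_erk_gab", 1.0))])
    b.ma("GAB_de", ["pGAB"], ["GAB"], 1.0)

    # -- PI3K isoforms and lipids ------------------------------------------
    b.mm("PI3Ka_act_irs", "PI3Ka", "aPI3Ka", 1.0, 0.3, [b.enz("pIRS")])
    b.mm("PI3Ka_act_gab", "PI3Ka", "aPI3Ka", 1.0, 0.3, [b.enz("pGAB")])
    b.mm("PI3Ka_act_ras", "PI3Ka", "aPI3Ka", 0.4, 0.3, [b.enz("aRas")])
    b.ma("PI3Ka_de", ["aPI3Ka"], ["PI3Ka"], 1.0)
    b.mm("PI3Kb_act_gab", "PI3Kb", "aPI3Kb", 0.3, 0.3, [b.enz("pGAB")])
    b.mm("PI3Kb_act_rac", "PI3Kb", "aPI3Kb", 0.3, 0.3, [b.enz("aRac1")])
    b.ma("PI3Kb_de", ["aPI3Kb"], ["PI3Kb"], 1.0)
    b.mm("PIP3_prod_a", "PIP2", "PIP3", 1.5, 0.3, [b.enz("aPI3Ka")])
    b.mm("PIP3_prod_b", "PIP2", "PIP3", 0.5, 0.3, [b.enz("aPI3Kb")])
    b.ma("PIP3_pten", ["PIP3"], ["PIP2"], 1.2)

    # -- P-Rex1 / Rac1 loop -------------------------------------------------
    b.mm("PRex1_act", "PRex1", "aPRex1", 1.0, 0.3, [b.enz("PIP3")])
    b.ma("PRex1_de", ["aPRex1"], ["PRex1"], 0.5)
    b.mm("Rac1_act", "Rac1", "aRac1", 1.0, 0.3, [b.enz("aPRex1")])
    b.ma("Rac1_de", ["aRac1"], ["Rac1"], 0.5)

    # -- PDK1 / AKT (two-site) / SGKs ---------------------------------------
    b.mm("PDK1_act", "PDK1", "aPDK1", 1.5, 0.3, [b.enz("PIP3")])
    b.ma("PDK1_de", ["aPDK1"], ["PDK1"], 0.5)
    b.mm("AKT_T308", "AKT", "pAKT_T308", 1.2, 0.3,
         [b.act("aPDK1", ("K_pdk1_akt", 0.4))])
    b.ma("AKT_T308_de", ["pAKT_T308"], ["AKT"], 0.5)
    b.mm("AKT_S473", "pAKT_T308", "ppAKT", 1.5, 0.3, [b.enz("amTORC2")])
    b.ma("AKT_S473_de", ["ppAKT"], ["pAKT_T308"], 0.5)
    b.mm("SGK1_act", "SGK1", "aSGK1", 0.8, 0.3,
         [b.act("aPDK1", ("K_pdk1_sgk1", 0.05))])
    b.ma("SGK1_de", ["aSGK1"], ["SGK1"], 0.5)
    # SGK3: ERa-induced expression; PDK1-activated
    b.hill("SGK3_syn", "SGK3", "aERa", 0.005, 0.3)
    b.synth("SGK3_syn0", "SGK3", 0.002)
    b.deg("SGK3_deg", "SGK3", 0.01)
    b.mm("SGK3_act", "SGK3", "aSGK3", 0.8, 0.3,
         [b.act("aPDK1", ("K_pdk1_sgk3", 0.05))])
    b.ma("SGK3_de", ["aSGK3"], ["SGK3"], 0.5)
    b.deg("aSGK3_deg", "aSGK3", 0.01)

    # -- NDRG1: SGK1/3 phosphorylation primes degradation -------------------
    b.synth("NDRG1_syn", "NDRG1", 0.02)
    b.deg("NDRG1_deg", "NDRG1", 0.01)
    b.mm("NDRG1_ph_sgk1", "NDRG1", "pNDRG1", 0.5, 0.3, [b.enz("aSGK1")])
    b.mm("NDRG1_ph_sgk3", "NDRG1", "pNDRG1", 0.5, 0.3, [b.enz("aSGK3")])
    b.deg("pNDRG1_deg", "pNDRG1", 0.05)

    # -- FOXO3 / ERalpha ----------------------------------------------------
    b.mm("FOXO3_ph_akt", "FOXO3", "pFOXO3", 1.0, 0.3, [b.enz("ppAKT")])
    b.mm("FOXO3_ph_sgk1", "FOXO3", "pFOXO3", 0.8, 0.3, [b.enz("aSGK1")])
    b.ma("FOXO3_de", ["pFOXO3"], ["FOXO3"], 0.2)
    b.hill("ERa_syn", "ERa", "FOXO3", 0.01, 0.3)
    b.synth("ERa_syn0", "ERa", 0.003)
    b.deg("ERa_deg", "ERa", 0.01)
    b.mm("ERa_act", "ERa", "aERa", 0.5, 0.3, [b.enz("pERK")])
    b.ma("ERa_de", ["aERa"], ["ERa"], 0.2)
    b.deg("aERa_deg", "aERa", 0.01)

    # -- Ras/Raf/MEK/ERK with feedbacks --------------------------------------
    b.mm("Ras_act_erbb", "Ras", "aRas", 1.5, 0.3,
         [b.enz("pErbB"), b.inh("pERK", ("K_erk_ras", 0.8))])
    b.mm("Ras_act_irs", "Ras", "aRas", 0.5, 0.3,
         [b.enz("pIRS"), b.inh("pERK", ("K_erk_ras2", 0.8))])
    b.ma("Ras_de", ["aRas"], ["Ras"], 0.5)
    b.mm("Raf_act", "Raf", "aRaf", 1.5, 0.3,
         [b.enz("aRas"), b.inh("ppAKT", ("K_akt_raf", 1.0))])
    b.ma("Raf_de", ["aRaf"], ["Raf"], 0.4)
    b.mm("MEK_act_raf", "MEK", "pMEK", 1.5, 0.3, [b.enz("aRaf")])
    b.mm("MEK_act_rac", "MEK", "pMEK", 0.3, 0.3, [b.enz("aRac1")])
    b.ma("MEK_de", ["pMEK"], ["MEK"], 0.4)
    b.mm("ERK_act", "ERK", "pERK", 2.0, 0.3, [b.enz("pMEK")])
    b.ma("ERK_de", ["pERK"], ["ERK"], 0.6)

    # -- TSC2 / mTORC1 / mTORC2 / S6K / S6 -----------------------------------
    b.mm("TSC2_ph_akt", "TSC2", "pTSC2", 1.0, 0.3, [b.enz("ppAKT")])
    b.mm("TSC2_ph_cdk46", "TSC2", "pTSC2", 0.25, 0.3, [b.enz("CycD1CDK46")])
    b.mm("TSC2_ph_sgk1", "TSC2", "pTSC2", 0.4, 0.3, [b.enz("aSGK1")])
    b.mm("TSC2_ph_sgk3", "TSC2", "pTSC2", 0.4, 0.3, [b.enz("aSGK3")])
    b.ma("TSC2_de", ["pTSC2"], ["TSC2"], 0.5)
    b.mm("mTORC1_act", "mTORC1", "amTORC1", 4.0, 0.3,
         [b.inh("TSC2", ("K_tsc2_mtorc1", 0.05))])
    b.ma("mTORC1_de", ["amTORC1"], ["mTORC1"], 0.5)
    b.mm("mTORC2_act", "mTORC2", "amTORC2", 1.2, 0.3,
         [b.enz("PIP3"), b.inh("ppRb", ("K_pprb_mtorc2", 0.5))])
    b.ma("mTORC2_de", ["amTORC2"], ["mTORC2"], 0.3)
    b.mm("S6K1_act", "S6K1", "pS6K1", 2.5, 2.0, [b.enz("amTORC1")])
    b.ma("S6K1_de", ["pS6K1"], ["S6K1"], 0.5)
    b.mm("S6_ph", "S6", "pS6", 3.0, 2.0, [b.enz("pS6K1")])
    b.ma("S6_de", ["pS6"], ["S6"], 0.5)

    # -- cMyc / cyclin D1 (mTORC1-controlled translation) --------------------
    b.hill("cMyc_syn_era", "cMyc", "aERa", 0.005, 0.3,
           extra=[b.boost("amTORC1", ("K_mtorc1_myc", 0.3))])
    b.hill("cMyc_syn_erk", "cMyc", "pERK", 0.005, 0.3,
           extra=[b.boost("amTORC1", ("K_mtorc1_myc2", 0.3))])
    b.synth("cMyc_syn0", "cMyc", 0.001)
    b.deg("cMyc_deg", "cMyc", 0.03)
    b.hill("cycD1_syn_myc", "cycD1", "cMyc", 0.004, 0.2,
           extra=[b.boost("amTORC1", ("K_mtorc1_ccnd", 0.3))])
    b.hill("cycD1_syn_erk", "cycD1", "pERK", 0.002, 0.3)
    b.synth("cycD1_syn0", "cycD1", 0.0005)
    b.deg("cycD1_deg", "cycD1", 0.03)

    # -- CDK complexes: p21 promotes D-CDK4/6 assembly -----------------------
    b.ma("CycD1CDK46_on", ["cycD1", "CDK46"], ["CycD1CDK46"], 0.02,
         [b.boost("p21", ("K_p21_asm", 0.3))])
    b.ma("CycD1CDK46_off", ["CycD1CDK46"], ["cycD1", "CDK46"], 0.05)
    b.hill("cycE_syn", "cycE", "E2F", 0.005, 0.15,
           extra=[b.boost("cMyc", ("K_myc_ccne", 0.3))])
    b.synth("cycE_syn0", "cycE", 0.0005)
    b.deg("cycE_deg", "cycE", 0.03)
    b.ma("CycECDK2_on", ["cycE", "CDK2"], ["CycECDK2"], 0.05)
    b.ma("CycECDK2_off", ["CycECDK2"], ["cycE", "CDK2"], 0.05)

    # -- Rb / E2F: sequential phosphorylation, p21 inhibits E-CDK2 -----------
    b.mm("Rb_ph1", "Rb", "pRb", 0.6, 0.3, [b.enz("CycD1CDK46")])
    b.mm("Rb_ph2", "pRb", "ppRb", 0.5, 0.3,
         [b.enz("CycECDK2"), b.inh("p21", ("K_p21_cdk2", 0.3))])
    b.ma("Rb_de2", ["ppRb"], ["pRb"], 0.15)
    b.ma("Rb_de1", ["pRb"], ["Rb"], 0.15)
    b.synth("E2F_syn0", "E2F", 0.002,
            [b.inh("Rb", ("K_rb_e2f", 0.3))])
    b.hill("E2F_syn_auto", "E2F", "E2F", 0.02, 0.3,
           extra=[b.inh("Rb", ("K_rb_e2f2", 0.3))])
    b.deg("E2F_deg", "E2F", 0.03)

    # -- p21: ERK-driven expression, AKT-stabilized --------------------------
    b.hill("p21_syn_erk", "p21", "pERK", 0.003, 0.3)
    b.synth("p21_syn0", "p21", 0.0005)
    b.deg("p21_deg", "p21", 0.03,
          [b.inh("ppAKT", ("K_akt_p21", 0.3))])

    node_forms = {
        "IGFR/IR": ["pIGFR"],
        "ErbB": ["pErbB"],
        "GAB": ["pGAB"],
        "IRS": ["pIRS"],
        "Ras": ["aRas"],
        "Raf": ["aRaf"],
        "MEK": ["pMEK"],
        "ERK": ["pERK"],
        "PI3Ka": ["aPI3Ka"],
        "PI3Kb": ["aPI3Kb"],
        "P-Rex1": ["aPRex1"],
        "Rac1": ["aRac1"],
        "PDK1": ["aPDK1"],
        "AKT": ["pAKT_T308", "ppAKT"],
        "mTORC1": ["amTORC1"],
        "mTORC2": ["amTORC2"],
        "TSC2": ["TSC2"],
        "S6K1": ["pS6K1"],
        "SGK1": ["aSGK1"],
        "SGK3": ["aSGK3"],
        "FOXO3": ["FOXO3"],
        "ERa": ["aERa"],
        "cMyc": ["cMyc"],
        "CDK4/6": ["CycD1CDK46"],
        "CDK2": ["CycECDK2"],
    }

    # AKT species are created here (three-form chain)
    idx = {s.name for s in b.species}
    assert "AKT" not in idx
    b.species.insert(0, Species("AKT", role="kinase", initial=1.0,
                                phospho_partner="pAKT_T308"))
    b.species.insert(1, Species("pAKT_T308", role="kinase", initial=0.0,
                                phospho_partner="AKT"))
    b.species.insert(2, Species("ppAKT", role="kinase", initial=0.0))

    conservation_groups = [
        ("IGFR", "pIGFR"),
        ("ErbB", "pErbB"),
        ("IRS", "pIRS"),
        ("GAB", "pGAB"),
        ("PI3Ka", "aPI3Ka"),
        ("PI3Kb", "aPI3Kb"),
        ("PIP2", "PIP3"),
        ("PRex1", "aPRex1"),
        ("Rac1", "aRac1"),
        ("PDK1", "aPDK1"),
        ("AKT", "pAKT_T308", "ppAKT"),
        ("SGK1", "aSGK1"),
        ("FOXO3", "pFOXO3"),
        ("Ras", "aRas"),
        ("Raf", "aRaf"),
        ("MEK", "pMEK"),
        ("ERK", "pERK"),
        ("TSC2", "pTSC2"),
        ("mTORC1", "amTORC1"),
        ("mTORC2", "amTORC2"),
        ("S6K1", "pS6K1"),
        ("S6", "pS6"),
        ("CDK46", "CycD1CDK46"),
        ("CDK2", "CycECDK2"),
        ("Rb", "pRb", "ppRb"),
    ]

    model = NetworkModel(
        species=b.species,
        reactions=b.reactions,
        parameters=b.params,
        ligand_map={"IGF-1": "L_IGF1", "insulin": "L_INS", "HRG": "L_HRG"},
        node_forms=node_forms,
        perturbable_registry=list(PERTURBABLE_NODES),
        observable_map={k: list(v) for k, v in OBSERVABLE_MAP.items()},
        conservation_groups=conservation_groups,
        parameter_bounds=b.bounds,
    )
    if len(model.perturbable_registry) != 24:
        raise ValueError(
            f"perturbable registry must have 24 entries, "
            f"got {len(model.perturbable_registry)}"
        )
    return model


# ---------------------------------------------------------------------------
# toy models


def toy_chain3(k1: float = 1.0, k2: float = 0.5) -> NetworkModel:
    """Linear 3-species conversion chain A -> B -> C (mass action)."""
    species = [
        Species("A", initial=1.0),
        Species("B", initial=0.0),
        Species("C", initial=0.0),
    ]
    reactions = [
        Reaction("r1", ("A",), ("B",), "mass_action", {"k": "k1"}),
        Reaction("r2", ("B",), ("C",), "mass_action", {"k": "k2"}),
    ]
    return NetworkModel(
        species, reactions, {"k1": k1, "k2": k2},
        conservation_groups=[("A", "B", "C")],
        parameter_bounds={"k1": (-3, 3), "k2": (-3, 3)},
    )


def toy_birth_death(k_s: float = 0.2, k_d: float = 0.1) -> NetworkModel:
    """Single species with zeroth-order synthesis and first-order decay."""
    species = [Species("X", initial=0.0)]
    reactions = [
        Reaction("syn", (), ("X",), "synthesis", {"k": "k_s"}),
        Reaction("deg", ("X",), (), "degradation", {"k": "k_d"}),
    ]
    return NetworkModel(species, reactions, {"k_s": k_s, "k_d": k_d})


def toy_pi3k_chain() -> NetworkModel:
    """Reduced receptor -> PI3K -> AKT -> S6 chain with S6K-type feedback.

    Used for calibration benchmarks: small enough for desk-scale genetic
    algorithm fitting, with a negative feedback (pS6 inhibits receptor
    activation) standing in for the S6K1 -| IRS loop of the full model.
    """
    species = [
        Species("R", initial=1.0, phospho_partner="pR"),
        Species("pR", initial=0.0, phospho_partner="R"),
        Species("PI3K", initial=1.0, phospho_partner="aPI3K"),
        Species("aPI3K", initial=0.0, phospho_partner="PI3K"),
        Species("AKT", initial=1.0, phospho_partner="pAKT"),
        Species("pAKT", initial=0.0, phospho_partner="AKT"),
        Species("S6", initial=1.0, phospho_partner="pS6"),
        Species("pS6", initial=0.0, phospho_partner="S6"),
    ]
    params = {
        "K_unit": 1.0,
        "k_Ract": 1.0,
        "Km_Ract": 0.3,
        "K_lig": 2.0,
        "K_fb": 0.5,
        "k_Rde": 0.2,
        "k_Pact": 1.0,
        "Km_Pact": 0.3,
        "k_Pde": 0.3,
        "k_Aact": 1.0,
        "Km_Aact": 0.3,
        "k_Ade": 0.3,
        "k_Sact": 0.8,
        "Km_Sact": 0.3,
        "k_Sde": 0.2,
    }
    reactions = [
        Reaction("Ract", ("R",), ("pR",), "michaelis_menten",
                 {"k": "k_Ract", "Km": "Km_Ract"},
                 (Modifier("L_IGF1", +1, "K_lig", "sat"),
                  Modifier("pS6", -1, "K_fb", "sat"))),
        Reaction("Rde", ("pR",), ("R",), "mass_action", {"k": "k_Rde"}),
        Reaction("Pact", ("PI3K",), ("aPI3K",), "michaelis_menten",
                 {"k": "k_Pact", "Km": "Km_Pact"},
                 (Modifier("pR", +1, "K_unit", "lin"),)),
        Reaction("Pde", ("aPI3K",), ("PI3K",), "mass_action", {"k": "k_Pde"}),
        Reaction("Aact", ("AKT",), ("pAKT",), "michaelis_menten",
                 {"k": "k_Aact", "Km": "Km_Aact"},
                 (Modifier("aPI3K", +1, "K_unit", "lin"),)),
        Reaction("Ade", ("pAKT",), ("AKT",), "mass_action", {"k": "k_Ade"}),
        Reaction("Sact", ("S6",), ("pS6",), "michaelis_menten",
                 {"k": "k_Sact", "Km": "Km_Sact"},
                 (Modifier("pAKT", +1, "K_unit", "lin"),)),
        Reaction("Sde", ("pS6",), ("S6",), "mass_action", {"k": "k_Sde"}),
    ]
    free = ["k_Ract", "k_Rde", "k_Pact", "k_Pde", "k_Aact", "k_Ade",
            "k_Sact", "k_Sde"]
    return NetworkModel(
        species,
        reactions,
        params,
        ligand_map={"IGF-1": "L_IGF1", "insulin": "L_IGF1", "HRG": "L_IGF1"},
        node_forms={"PI3K": ["aPI3K"], "AKT": ["pAKT"], "R": ["pR"]},
        perturbable_registry=["R", "PI3K", "AKT"],
        observable_map={"pAKT": ["pAKT"], "pS6": ["pS6"], "pR": ["pR"]},
        conservation_groups=[("R", "pR"), ("PI3K", "aPI3K"),
                             ("AKT", "pAKT"), ("S6", "pS6")],
        parameter_bounds={k: (-3.0, 3.0) for k in free},
    )


def demo_ensemble(model: NetworkModel, n: int = 5, seed: int = 0,
                  sigma: float = 0.05):
    """Small illustrative parameter ensemble around a model's own values.

    Deterministic log-normal jitter (standard deviation ``sigma`` on log10
    scale) of the model's free parameters, clipped to their bounds.  This
    exercises the ensemble-prediction machinery (mean +/- SE bands, per-set
    screens) around the demo parameterization; it is not a product of the
    genetic-algorithm calibration, which is validated separately on toy
    problems and available for full runs via the replication preset.
    """
    from .calibration import ParameterEnsemble

    rng = np.random.default_rng(seed)
    free = list(model.parameter_bounds)
    center = np.log10([model.parameters[k] for k in free])
    sets = []
    for _ in range(n):
        jit = center + rng.normal(0.0, sigma, size=len(free))
        lo = np.array([model.parameter_bounds[k][0] for k in free])
        hi = np.array([model.parameter_bounds[k][1] for k in free])
        sets.append(np.clip(jit, lo, hi))
    return ParameterEnsemble(
        parameter_names=free,
        sets=np.array(sets),
        J_values=np.ones(n),
        seeds=np.arange(n),
        retention_tolerance=0.2,
    )
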