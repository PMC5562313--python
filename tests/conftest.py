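"""Shared fixtures: toy metabolic model, small lattices, strain records."""

from __future__ import annotations

import numpy as np
import pytest

import dfba3d as d

#: toy-network stoichiometry (ATP per glucose aerobically/fermentatively,
#: O2 per glucose, acetate per fermented glucose, ATP per acetate)
TOY_Y_AERO = 10.0
TOY_Y_FERM = 2.0
TOY_O2_PER_GLC = 3.0
TOY_AC_PER_GLC = 2.0
TOY_Y_AC = 4.0
TOY_O2_PER_AC = 2.0


def make_toy_model():
    """Five-reaction toy network with an analytically known optimum.

    Aerobic catabolism: glc + 3 o2 -> 10 atp
    Fermentation:       glc -> 2 ac + 2 atp
    Acetate oxidation:  ac + 2 o2 -> 4 atp
    Biomass:            GAM atp -> (objective)
    plus exchanges for glucose, O2 and acetate.

    With glucose bound G and O2 bound O the optimum routes
    v_aero = min(G, O/3) through respiration and ferments the rest:
    mu = (10 v_aero + 2 (G - v_aero)) / GAM, acetate = 2 (G - v_aero).
    """
    import cobra

    m = cobra.Model("toy")
    glc = cobra.Metabolite("glc__D_e")
    o2 = cobra.Metabolite("o2_e")
    ac = cobra.Metabolite("ac_e")
    atp = cobra.Metabolite("atp_c")
    for rid, met in (("EX_glc__D_e", glc), ("EX_o2_e", o2),
                     ("EX_ac_e", ac)):
        rxn = cobra.Reaction(rid, lower_bound=0.0, upper_bound=1000.0)
        rxn.add_metabolites({met: -1.0})
        m.add_reactions([rxn])
    aero = cobra.Reaction("AERO", lower_bound=0.0, upper_bound=1000.0)
    aero.add_metabolites({glc: -1.0, o2: -TOY_O2_PER_GLC, atp: TOY_Y_AERO})
    ferm = cobra.Reaction("FERM", lower_bound=0.0, upper_bound=1000.0)
    ferm.add_metabolites({glc: -1.0, ac: TOY_AC_PER_GLC, atp: TOY_Y_FERM})
    acup = cobra.Reaction("ACOX", lower_bound=0.0, upper_bound=1000.0)
    acup.add_metabolites({ac: -1.0, o2: -TOY_O2_PER_AC, atp: TOY_Y_AC})
    bm = cobra.Reaction("BIOMASS", lower_bound=0.0, upper_bound=1000.0)
    bm.add_metabolites({atp: -50.0})
    m.add_reactions([aero, ferm, acup, bm])
    m.objective = "BIOMASS"
    return m


def toy_optimum(G: float, O: float, gam: float):
    """Closed-form optimum of the toy network (glucose phenotype)."""
    v_aero = min(G, O / TOY_O2_PER_GLC)
    v_ferm = G - v_aero
    mu = (TOY_Y_AERO * v_aero + TOY_Y_FERM * v_ferm) / gam
    return mu, TOY_AC_PER_GLC * v_ferm


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture
def mg1655() -> d.StrainRecord:
    return d.STRAINS["MG1655"]


@pytest.fixture
def consts() -> d.CellConstants:
    return d.CellConstants()


def make_state(n=(5, 5, 5), dx=10.0, n_agar=0, species=None):
    """Small lattice with a flat agar slab of n_agar layers."""
    species = species or d.default_species()
    phase = np.zeros(n, dtype=np.int8)
    phase[:, :, :n_agar] = d.AGAR
    C = {}
    for name, sp in species.items():
        fld = np.zeros(n)
        fld[phase == d.AGAR] = sp.init_agar
        if sp.gaseous:
            fld[phase == d.AIR] = sp.boundary_value
        C[name] = fld
    return d.LatticeState(dx=dx, phase=phase, C=C,
                          m=np.zeros((2,) + tuple(n)))


@pytest.fixture
def uniform_state():
    return make_state()
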