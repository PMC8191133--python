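"""Reaction kinetics of the coupled body-axis / organizer / tentacle model.

Nine scalar fields evolve on the tissue surface, organised as three
activator-inhibitor pattern-formation systems plus auxiliary species:

* body axis: nuclear beta-Catenin/TCF (``beta_cat``) and its antagonist
  (``beta_cat_ant``, phenomenologically Dickkopf1/2/4-like);
* head organizer: ``wnt3`` and a diffusive Wnt3 antagonist (``wnt3_ant``,
  summarizing Sp5/HmTSP-like inhibition);
* tentacle system: ``tent`` activator and ``tent_ant`` antagonist;
* ``head``: head-specific factors downstream of Wnt3;
* ``has``: the Wnt3-degrading astacin proteinase, activated by ``head`` and
  locally repressed by Wnt3, degrading Wnt3 in turn (negative feedback);
* ``sd``: source density, Meinhardt's slow long-term store of head-forming
  potential, fed by beta-Catenin.

All quantities are dimensionless.  Experimental perturbations are encoded as
named scenarios editing single coefficients or the initial source-density
offset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: canonical species ordering used by every (9, n_vertices) state array
SPECIES = ("beta_cat", "beta_cat_ant", "wnt3", "wnt3_ant", "head",
           "has", "tent", "tent_ant", "sd")

SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

#: floor applied to inhibitor fields used as divisors
EPS_DIV = 1e-12


@dataclass
class ModelParameters:
    """Coefficients of the nine reaction-diffusion equations.

    ``a*`` are diffusion coefficients, ``b*`` production rates, ``c*``
    coupling/saturation constants, ``d*`` decay rates and ``e*`` feedback
    strengths; numbering follows the species order of :data:`SPECIES`
    (1 = beta_cat ... 9 = sd).  Defaults are the published coefficient set of
    the unperturbed system.  ``k_*`` are the additive basal terms inside
    production numerators and ``s_*`` the constant baseline productions.
    """

    # body-axis activator (beta_cat)
    a1: float = 9e-5
    b1: float = 3e-3
    c1: float = 3e-2
    d1: float = 3e-3
    # body-axis antagonist
    a2: float = 11e-3
    b2: float = 3e-3
    c2: float = 3e-2
    d2: float = 4e-3
    # organizer activator (wnt3)
    a3: float = 6e-5
    b3: float = 7e-3
    c3: float = 3e-3
    d3: float = 12e-2
    e3: float = 1e2
    # organizer antagonist
    a4: float = 24e-3
    b4: float = 1e-2
    c4: float = 3e-3
    d4: float = 18e-2
    # head factors
    a5: float = 25e-3
    b5: float = 1.0
    d5: float = 1e-2
    # proteinase (HAS)
    a6: float = 25e-3
    b6: float = 1e-1
    c6: float = 1e1
    d6: float = 5e-2
    # tentacle activator
    a7: float = 25e-5
    b7: float = 2e-3
    c7: float = 12e-2
    e7: float = 3e-2
    d7: float = 2e-2
    # tentacle antagonist
    a8: float = 27e-3
    b8: float = 3e-3
    c8: float = 12e-2
    e8: float = 3e-2
    d8: float = 3e-2
    # source density (a9 printed with a dropped exponent base; 11e-5 by
    # analogy with the rest of the list)
    a9: float = 11e-5
    b9: float = 3e-5
    d9: float = 3e-5
    # constant baseline production of the beta_cat antagonist (0 in the
    # published system; used by the antagonist-removal experiment, where
    # b2 = 0 and the antagonist is held at a passive baseline level)
    s_bcatant: float = 0.0
    # basal production numerator offsets
    k_bcat_num: float = 0.05
    k_wnt_num: float = 0.05
    k_wntant_num: float = 0.005
    k_tent_num: float = 0.005
    # constant baseline productions
    s_wntant: float = 0.035
    s_tentant: float = 0.014
    s_sd: float = 0.00003
    # additive Wnt3 production (overexpression scenario only)
    wnt3_oe_const: float = 0.0
    # interpretation switches (see docs/methods.md)
    eq34_multiplier: str = "beta_cat"      # or "beta_cat_ant"
    head_ant_source: str = "head"          # or "wnt3_ant"
    eps_div: float = EPS_DIV

    def __post_init__(self):
        # diffusion coefficients may be zeroed for reaction-only oracle runs
        for name in ("a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8", "a9"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.eq34_multiplier not in ("beta_cat", "beta_cat_ant"):
            raise ValueError("eq34_multiplier must be 'beta_cat' or "
                             "'beta_cat_ant'")
        if self.head_ant_source not in ("head", "wnt3_ant"):
            raise ValueError("head_ant_source must be 'head' or 'wnt3_ant'")

    def diffusion_coefficients(self) -> np.ndarray:
        """Diffusion coefficient per species, in :data:`SPECIES` order."""
        return np.array([self.a1, self.a2, self.a3, self.a4, self.a5,
                         self.a6, self.a7, self.a8, self.a9])

    def replace(self, **edits) -> "ModelParameters":
        return dataclasses.replace(self, **edits)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_parameters() -> ModelParameters:
    """The published coefficient set of the unperturbed system."""
    return ModelParameters()


@dataclass
class FieldState:
    """The nine concentration fields over mesh vertices at one time.

    ``values`` is a (9, n_vertices) array in :data:`SPECIES` order; named
    accessors are provided for readability.
    """

    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(SPECIES):
            raise ValueError(f"values must be ({len(SPECIES)}, n_vertices), "
                             f"got {self.values.shape}")

    def __getattr__(self, name):
        idx = SPECIES_INDEX.get(name)
        if idx is None:
            raise AttributeError(name)
        return self.values[idx]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FieldState":
        return FieldState(self.values.copy(), self.time)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value in species "
                             f"{SPECIES[bad[0]]!r} at vertex {bad[1]}")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(f"negative value in species "
                             f"{SPECIES[bad[0]]!r} at vertex {bad[1]}")


def reaction_terms(values: np.ndarray, params: ModelParameters
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Production and linear-decay-rate arrays of the reaction kinetics.

    Splits each species' kinetics as ``du/dt = production - decay_rate * u``
    where ``production >= 0`` and ``decay_rate >= 0`` whenever all fields are
    non-negative.  Inhibitor fields used as divisors (beta_cat_ant, wnt3_ant,
    tent_ant) are floored at ``params.eps_div`` before division.

    Parameters
    ----------
    values : (9, n) array
        Field values in :data:`SPECIES` order.
    params : ModelParameters

    Returns
    -------
    production, decay_rate : (9, n) arrays
    """
    p = params
    bcat, bcat_ant, wnt3, wnt3_ant, head, has, tent, tent_ant, sd = values

    bcat_ant_f = np.maximum(bcat_ant, p.eps_div)
    wnt3_ant_f = np.maximum(wnt3_ant, p.eps_div)
    tent_ant_f = np.maximum(tent_ant, p.eps_div)

    wnt3_sq = wnt3 * wnt3
    tent_sq = tent * tent
    bcat_sq = bcat * bcat

    mult = bcat if p.eq34_multiplier == "beta_cat" else bcat_ant
    head_ant = head if p.head_ant_source == "head" else wnt3_ant

    production = np.empty_like(values)
    decay_rate = np.empty_like(values)

    # body-axis activator
    production[0] = p.b1 * (1.0 + p.c1 * wnt3) * sd * \
        (p.k_bcat_num + bcat_sq) / bcat_ant_f
    decay_rate[0] = p.d1
    # body-axis antagonist
    production[1] = p.b2 * (1.0 + p.c2 * wnt3) * sd * bcat_sq + p.s_bcatant
    decay_rate[1] = p.d2
    # organizer activator, degraded by the proteinase
    production[2] = p.b3 * mult * (p.k_wnt_num + wnt3_sq) / \
        (wnt3_ant_f * (1.0 + p.c3 * wnt3_sq)) + p.wnt3_oe_const
    decay_rate[2] = p.d3 * (1.0 + p.e3 * has)
    # organizer antagonist
    production[3] = p.b4 * mult * (p.k_wntant_num + wnt3_sq) / \
        (1.0 + p.c4 * wnt3_sq) + p.s_wntant
    decay_rate[3] = p.d4
    # head factors
    production[4] = p.b5 * wnt3
    decay_rate[4] = p.d5
    # proteinase: activated by head factors, locally repressed by Wnt3
    production[5] = p.b6 * head / (1.0 + p.c6 * wnt3)
    decay_rate[5] = p.d6
    # tentacle activator
    tent_common = sd * (p.k_tent_num + tent_sq) / (1.0 + p.c7 * tent_sq)
    production[6] = p.b7 * tent_common / \
        (tent_ant_f * (1.0 + p.e7 * head_ant))
    decay_rate[6] = p.d7
    # tentacle antagonist (saturation constant c8, feedback e8)
    production[7] = p.b8 * sd * (p.k_tent_num + tent_sq) / \
        ((1.0 + p.c8 * tent_sq) * (1.0 + p.e8 * head_ant)) + p.s_tentant
    decay_rate[7] = p.d8
    # source density
    production[8] = p.b9 * bcat + p.s_sd
    decay_rate[8] = p.d9

    return production, decay_rate


def reaction_rhs(state: FieldState | np.ndarray, params: ModelParameters
                 ) -> np.ndarray:
    """Reaction-only time derivatives (no diffusion), per species and vertex."""
    values = state.values if isinstance(state, FieldState) else np.asarray(state)
    # overflow at pathological states is caught below, not warned about
    with np.errstate(over="ignore", invalid="ignore"):
        production, decay_rate = reaction_terms(values, params)
        rhs = production - decay_rate * values
    if not np.all(np.isfinite(rhs)):
        bad = np.argwhere(~np.isfinite(rhs))[0]
        raise FloatingPointError(
            f"non-finite reaction rate for species {SPECIES[bad[0]]!r} at "
            f"vertex {bad[1]}")
    return rhs


@dataclass
class Scenario:
    """A named experimental perturbation.

    ``sd_offset`` is added to the initial source-density gradient (systemic
    GSK-3beta inhibition, 'AZK'); ``parameter_edits`` replace individual
    coefficients (knockdowns / overexpression).
    """

    name: str
    sd_offset: float = 0.0
    parameter_edits: dict = field(default_factory=dict)
    seed: int = 0

    def describe(self) -> str:
        edits = ", ".join(f"{k}={v}" for k, v in self.parameter_edits.items())
        return (f"{self.name}: sd_offset={self.sd_offset}"
                + (f", {edits}" if edits else ""))


_DEFAULTS = default_parameters()

#: scenario registry: the five simulated experiments plus plain knockdown
SCENARIOS = {
    "unperturbed": dict(sd_offset=0.0, parameter_edits={}),
    "azk": dict(sd_offset=2.0, parameter_edits={}),
    "has_kd": dict(sd_offset=0.0, parameter_edits={"b6": 0.0}),
    "has_kd_azk": dict(sd_offset=2.0, parameter_edits={"b6": 0.0}),
    "dkk_kd_azk": dict(sd_offset=2.0,
                       parameter_edits={"d2": 2.0 * _DEFAULTS.d2}),
    "wnt3_oe": dict(sd_offset=0.0, parameter_edits={"wnt3_oe_const": 0.1}),
}


def get_scenario(name: str, seed: int = 0) -> Scenario:
    """Look up a named scenario; raises KeyError for unknown names."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: "
                       f"{sorted(SCENARIOS)}")
    entry = SCENARIOS[name]
    return Scenario(name=name, sd_offset=entry["sd_offset"],
                    parameter_edits=dict(entry["parameter_edits"]), seed=seed)


def apply_scenario(params: ModelParameters, scenario: Scenario
                   ) -> ModelParameters:
    """Return a copy of ``params`` with the scenario's edits applied."""
    if scenario.name not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario.name!r}")
    unknown = set(scenario.parameter_edits) - set(params.to_dict())
    if unknown:
        raise KeyError(f"scenario edits unknown coefficients: {unknown}")
    if not scenario.parameter_edits:
        return params.replace()
    return params.replace(**scenario.parameter_edits)
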