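"""Macro-reaction network for the reduced *Tisochrysis lutea* metabolic model.

The central carbon metabolism of the microalga is represented by a handful of
macroscopic reactions (MRs), each the net stoichiometry of one quasi-steady-state
sub-network of the core metabolic network: photosynthesis (MR1), upper glycolysis
(MR2/MR2'), lower glycolysis (MR3), carbohydrate synthesis (MR4), neutral-lipid
synthesis (MR5) and functional-biomass synthesis (MR6).  Metabolites at the
junctions between sub-networks — GAP, G6P, PEP, PA (neutral lipids) and CARB
(carbohydrates) — are allowed to accumulate and constitute the dynamic pools A.
Functional biomass B (proteins, nucleic acids, chlorophyll, membrane lipids) is
total particulate carbon minus the accumulating pools.

Five model variants are supported: ``w/oEx`` (no excretion) and four variants
each adding a single excretion macro-reaction MR7 draining one accumulating pool
into a dissolved organic product:

======== ======== ================
variant  locus    excreted product
======== ======== ================
ExCARB   CARB     EPS (exopolysaccharide)
ExG6P    G6P      EPS
ExPEP    PEP      ACE (acetate)
ExGAP    GAP      GLYC (glycerol)
======== ======== ================

Cofactors (ATP/ADP, NAD(H), NADP(H), Pi, H, H2O, O2, SO4, Mg) and light are
carried in the stoichiometry for auditing purposes but are not part of the
dynamic state; on the macro-reaction level they are treated as carbon- and
nitrogen-free exchange currencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "KineticLaw",
    "MacroReaction",
    "ModelVariant",
    "MacroReactionNetwork",
    "VARIANTS",
    "DYNAMIC_SPECIES",
    "build_variant",
    "infer_element_content",
    "element_balance",
]

#: identifiers of the five supported model variants
VARIANTS = ("w/oEx", "ExCARB", "ExG6P", "ExPEP", "ExGAP")

#: dynamic state of the ODE system, in order: substrate, accumulating pools,
#: functional biomass, excreted product
DYNAMIC_SPECIES = ("NO3", "GAP", "G6P", "PEP", "PA", "CARB", "B", "P")

#: accumulating intracellular pools (the A vector)
ACCUMULATING = ("GAP", "G6P", "PEP", "PA", "CARB")

_ROLES = (
    "external_substrate",
    "accumulating",
    "functional_biomass",
    "excreted_product",
    "cofactor",
    "inorganic",
    "light",
)

# molar masses used to convert mol-based state to mass-based observables
MW_C = 12.011
MW_N = 14.007


@dataclass(frozen=True)
class Species:
    """A chemical species of the macro-reaction network.

    ``carbon_atoms``/``nitrogen_atoms`` count atoms per molecule (per mole of
    pool for the lumped pools PA, CARB and B, whose formulas are non-integer
    by construction of the sub-network reduction).
    """

    name: str
    carbon_atoms: float
    nitrogen_atoms: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown species role {self.role!r}")
        if self.carbon_atoms < 0 or self.nitrogen_atoms < 0:
            raise ValueError("atom counts must be non-negative")


@dataclass(frozen=True)
class KineticLaw:
    """Mass-action rate law of a macro-reaction, on a specific (per-B) basis.

    The specific rate is

        alpha = k_fwd * prod(A_i / B) * [I] * [S]  -  k_rev * prod(A_j / B)

    where ``fwd_ratios``/``rev_ratios`` name the accumulating pools entering as
    intracellular ratios, ``uses_light`` multiplies by the instantaneous light
    intensity I(t) and ``uses_substrate`` by the extracellular nitrate
    concentration S.
    """

    fwd_constant: str
    fwd_ratios: tuple[str, ...] = ()
    uses_light: bool = False
    uses_substrate: bool = False
    rev_constant: str | None = None
    rev_ratios: tuple[str, ...] = ()

    @property
    def reversible(self) -> bool:
        return self.rev_constant is not None


@dataclass(frozen=True)
class MacroReaction:
    """One macroscopic reaction: signed stoichiometry (products > 0) + kinetics."""

    id: str
    name: str
    stoichiometry: dict[str, float]
    kinetics: KineticLaw

    def coefficient(self, species: str) -> float:
        return self.stoichiometry.get(species, 0.0)


@dataclass(frozen=True)
class ModelVariant:
    id: str
    excretion_locus: str | None  # None | CARB | G6P | PEP | GAP
    excreted_species: str | None  # None | EPS | ACE | GLYC


# ---------------------------------------------------------------------------
# reaction table
# ---------------------------------------------------------------------------

_MR1_6: list[MacroReaction] = [
    MacroReaction(
        "MR1",
        "photosynthesis",
        {"Light": -30, "CO2": -3, "H2O": -2, "Pi": -1, "GAP": 1, "O2": 3},
        KineticLaw("k_MR1", uses_light=True),
    ),
    MacroReaction(
        "MR2",
        "upper glycolysis",
        {"GAP": -2, "H2O": -1, "G6P": 1, "Pi": 1},
        KineticLaw("k_MR2", ("GAP",)),
    ),
    MacroReaction(
        "MR2p",
        "upper glycolysis (gluconeogenic reversal)",
        {"G6P": -1, "ATP": -1, "H": 1, "ADP": 1, "GAP": 2},
        KineticLaw("k_MR2p", ("G6P",)),
    ),
    MacroReaction(
        "MR3",
        "lower glycolysis",
        {
            "GAP": -1, "ADP": -1, "Pi": -1, "NAD": -1,
            "PEP": 1, "ATP": 1, "NADH": 1, "H2O": 1, "H": 1,
        },
        KineticLaw("k_MR3", ("GAP",), rev_constant="k_MR3p", rev_ratios=("PEP",)),
    ),
    MacroReaction(
        "MR4",
        "carbohydrate synthesis",
        {"G6P": -1, "CARB": 1, "Pi": 1},
        KineticLaw("k_MR4", ("G6P",), rev_constant="k_MR4p", rev_ratios=("CARB",)),
    ),
    MacroReaction(
        "MR5",
        "neutral lipid synthesis",
        {
            "GAP": -1, "PEP": -16.61, "ADP": -2, "NAD": -13.46,
            "NADPH": -29.3, "H": -34.48, "O2": -2.15,
            "PA": 1, "Pi": 14.61, "ATP": 2, "NADH": 13.46,
            "NADP": 29.3, "H2O": 4.31, "CO2": 16.61,
        },
        KineticLaw("k_MR5", ("GAP", "PEP"), rev_constant="k_MR5p", rev_ratios=("PA",)),
    ),
    MacroReaction(
        "MR6",
        "functional biomass synthesis",
        {
            "PEP": -3.13, "O2": -7.37, "H": -4.46, "NO3": -1.31,
            "G6P": -1.14, "PA": -0.11, "SO4": -0.03, "Mg": -0.0025,
            "B": 1, "CO2": 11.67, "Pi": 4.23, "H2O": 6,
        },
        KineticLaw("k_MR6", ("PEP", "G6P", "PA"), uses_substrate=True),
    ),
]

_MR7: dict[str, MacroReaction] = {
    "ExCARB": MacroReaction(
        "MR7", "EPS excretion from carbohydrates",
        {"CARB": -1, "P": 1},
        KineticLaw("k_EX", ("CARB",)),
    ),
    "ExG6P": MacroReaction(
        "MR7", "EPS excretion from glucose 6-phosphate",
        {"G6P": -1, "P": 1, "Pi": 1},
        KineticLaw("k_EX", ("G6P",)),
    ),
    "ExPEP": MacroReaction(
        "MR7", "acetate excretion from phosphoenolpyruvate",
        {"PEP": -1, "NAD": -1, "ADP": -2, "Pi": -1, "H": -1,
         "P": 1, "CO2": 1, "NADH": 1, "ATP": 2},
        KineticLaw("k_EX", ("PEP",)),
    ),
    "ExGAP": MacroReaction(
        "MR7", "glycerol excretion from glyceraldehyde 3-phosphate",
        {"GAP": -1, "H2O": -1, "H": -1, "NADPH": -1,
         "P": 1, "Pi": 1, "NADP": 1},
        KineticLaw("k_EX", ("GAP",)),
    ),
}

_VARIANT_META = {
    "w/oEx": ModelVariant("w/oEx", None, None),
    "ExCARB": ModelVariant("ExCARB", "CARB", "EPS"),
    "ExG6P": ModelVariant("ExG6P", "G6P", "EPS"),
    "ExPEP": ModelVariant("ExPEP", "PEP", "ACE"),
    "ExGAP": ModelVariant("ExGAP", "GAP", "GLYC"),
}

_COFACTORS = ("ATP", "ADP", "NAD", "NADH", "NADP", "NADPH",
              "Pi", "H", "H2O", "O2", "SO4", "Mg")

# atom-count anchors: CO2 and NO3 by formula, GAP fixed by MR1 (3 CO2 -> GAP);
# cofactors are carbon/nitrogen-free exchange currencies at this granularity
_ANCHORS_C = {"CO2": 1.0, "NO3": 0.0, "GAP": 3.0, "Light": 0.0,
              **{c: 0.0 for c in _COFACTORS}}
_ANCHORS_N = {"CO2": 0.0, "NO3": 1.0, "GAP": 0.0, "Light": 0.0,
              **{c: 0.0 for c in _COFACTORS}}


@dataclass
class MacroReactionNetwork:
    """A model variant's reactions plus the Eq.-style dynamic bookkeeping.

    ``K_prime`` is the stoichiometric matrix restricted to the dynamic species
    (rows ordered as :data:`DYNAMIC_SPECIES`, columns as ``reactions``); the
    dynamic state evolves as dx/dt = K' alpha B + D (S_in e_S) - D x.
    """

    variant: ModelVariant
    reactions: list[MacroReaction]
    species: list[Species] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = self._build_species()

    # -- construction -------------------------------------------------------

    def _build_species(self) -> list[Species]:
        carbon = infer_element_content(self.reactions, "C")
        nitrogen = infer_element_content(self.reactions, "N")
        names: list[str] = []
        for rxn in self.reactions:
            for sp in rxn.stoichiometry:
                if sp not in names:
                    names.append(sp)
        out = []
        for name in names:
            if name == "NO3":
                role = "external_substrate"
            elif name in ACCUMULATING:
                role = "accumulating"
            elif name == "B":
                role = "functional_biomass"
            elif name == "P":
                role = "excreted_product"
            elif name == "Light":
                role = "light"
            elif name == "CO2":
                role = "inorganic"
            else:
                role = "cofactor"
            out.append(Species(name, carbon.get(name, 0.0), nitrogen.get(name, 0.0), role))
        return out

    # -- views ---------------------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def K_prime(self) -> np.ndarray:
        K = np.zeros((len(DYNAMIC_SPECIES), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for i, sp in enumerate(DYNAMIC_SPECIES):
                K[i, j] = rxn.coefficient(sp)
        return K

    def atoms(self, element: str) -> dict[str, float]:
        """Atom content per species for ``element`` in {'C', 'N'}."""
        idx = {"C": "carbon_atoms", "N": "nitrogen_atoms"}[element]
        return {s.name: getattr(s, idx) for s in self.species}

    def dynamic_atoms(self, element: str) -> np.ndarray:
        content = self.atoms(element)
        return np.array([content.get(sp, 0.0) for sp in DYNAMIC_SPECIES])

    def species_by_name(self, name: str) -> Species:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def rate_constant_names(self) -> list[str]:
        names: list[str] = []
        for rxn in self.reactions:
            names.append(rxn.kinetics.fwd_constant)
            if rxn.kinetics.rev_constant:
                names.append(rxn.kinetics.rev_constant)
        return names

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variant": {
                "id": self.variant.id,
                "excretion_locus": self.variant.excretion_locus,
                "excreted_species": self.variant.excreted_species,
            },
            "species": [
                {"name": s.name, "carbon_atoms": s.carbon_atoms,
                 "nitrogen_atoms": s.nitrogen_atoms, "role": s.role}
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": r.stoichiometry,
                    "kinetics": {
                        "fwd_constant": r.kinetics.fwd_constant,
                        "fwd_ratios": list(r.kinetics.fwd_ratios),
                        "uses_light": r.kinetics.uses_light,
                        "uses_substrate": r.kinetics.uses_substrate,
                        "rev_constant": r.kinetics.rev_constant,
                        "rev_ratios": list(r.kinetics.rev_ratios),
                    },
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MacroReactionNetwork":
        variant = ModelVariant(**d["variant"])
        species = [Species(**s) for s in d["species"]]
        reactions = []
        for r in d["reactions"]:
            k = r["kinetics"]
            law = KineticLaw(
                k["fwd_constant"], tuple(k["fwd_ratios"]),
                k["uses_light"], k["uses_substrate"],
                k["rev_constant"], tuple(k["rev_ratios"]),
            )
            reactions.append(MacroReaction(r["id"], r["name"], r["stoichiometry"], law))
        return cls(variant=variant, reactions=reactions, species=species)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "MacroReactionNetwork":
        return cls.from_dict(json.loads(text))


def build_variant(variant_id: str) -> MacroReactionNetwork:
    """Build the macro-reaction network of one model variant.

    Parameters
    ----------
    variant_id
        One of ``w/oEx``, ``ExCARB``, ``ExG6P``, ``ExPEP``, ``ExGAP``.
    """
    if variant_id not in VARIANTS:
        raise ValueError(
            f"unknown variant {variant_id!r}; valid identifiers: {', '.join(VARIANTS)}"
        )
    reactions = list(_MR1_6)
    if variant_id != "w/oEx":
        reactions.append(_MR7[variant_id])
    return MacroReactionNetwork(variant=_VARIANT_META[variant_id], reactions=reactions)


def infer_element_content(
    reactions: list[MacroReaction], element: str, tol: float = 1e-6
) -> dict[str, float]:
    """Solve species atom counts from element balance of the reactions.

    CO2 (1 C), NO3 (1 N) and GAP (3 C, by the photosynthesis stoichiometry) are
    fixed anchors; cofactors count zero. The remaining species' contents are
    the unique values making every reaction element-balanced; an inconsistency
    beyond ``tol`` atoms raises, naming the offending reaction.
    """
    if element not in ("C", "N"):
        raise ValueError("element must be 'C' or 'N'")
    anchors = _ANCHORS_C if element == "C" else _ANCHORS_N

    unknowns: list[str] = []
    for rxn in reactions:
        for sp in rxn.stoichiometry:
            if sp not in anchors and sp not in unknowns:
                unknowns.append(sp)

    A = np.zeros((len(reactions), len(unknowns)))
    b = np.zeros(len(reactions))
    for i, rxn in enumerate(reactions):
        for sp, coeff in rxn.stoichiometry.items():
            if sp in anchors:
                b[i] -= coeff * anchors[sp]
            else:
                A[i, unknowns.index(sp)] += coeff
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    x[np.abs(x) < 1e-9] = 0.0  # numerical zeros from the least-squares solve
    content = dict(anchors)
    content.update(dict(zip(unknowns, x)))

    for rxn in reactions:
        resid = element_balance(rxn, content, element)
        if abs(resid) > tol:
            raise ValueError(
                f"reaction {rxn.id} is not {element}-balanced under inferred "
                f"contents (residual {resid:.3g} atoms)"
            )
    return content


def element_balance(
    reaction: MacroReaction, content: dict[str, float], element: str
) -> float:
    """Signed net atom flux of ``reaction``: sum of coefficient x atom count."""
    total = 0.0
    for sp, coeff in reaction.stoichiometry.items():
        if sp not in content:
            raise KeyError(f"species {sp!r} missing from content map")
        total += coeff * content[sp]
    return total
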