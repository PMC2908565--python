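"""Synthetic fixtures: toy methylotroph network, random networks, chemostat data.

The toy network is a ~50-reaction, compartmentalized (cytosol,
mitochondria, peroxisome, extracellular) caricature of methylotrophic
yeast central metabolism.  It contains the full methanol utilization
pathway — peroxisomal alcohol oxidase (AOD) and catalase, the
assimilatory xylulose-5-P cycle (DAS, DAK, pentose rearrangement) and
the glutathione-dependent dissimilatory branch (FALDH, SFGTH, FDH) —
the glycerol reactions (GLYCDy, G3PD1ir, G3PT), sorbitol and glucose
entry points, a lumped glycolysis/TCA core, an oxidative-phosphorylation
block with a tunable P/O ratio (ATPS3m, CYOOm), butanediol
dehydrogenase (BTDD: acetoin + NADH -> 2,3-butanediol) and a biomass
equation with growth-associated ATP.  Lumping choices that matter for
the analyses (where NADH pools live, how P/O is encoded) are documented
in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .maintenance import ChemostatPoint, ChemostatSeries
from .model import MetabolicModel, Metabolite, Reaction, parse_equation

__all__ = [
    "ToyNetworkSpec",
    "ChemostatGeneratorSpec",
    "build_toy_methanol_network",
    "generate_random_network",
    "generate_chemostat_series",
    "TOY_FORMULAS",
    "TOY_CARBON_SOURCES",
]

#: elemental formulas of the toy metabolites (base ids); the cytochrome
#: pool and protons are treated as element-free carriers
TOY_FORMULAS: dict[str, str] = {
    "mthl": "CH4O",
    "o2": "O2",
    "co2": "CO2",
    "h2o": "H2O",
    "h2o2": "H2O2",
    "fald": "CH2O",
    "for": "CH2O2",
    "gsh": "C10H17N3O6S",
    "fgt": "C11H17N3O7S",
    "nad": "C21H27N7O14P2",
    "nadh": "C21H27N7O14P2",
    "atp": "C10H16N5O13P3",
    "adp": "C10H15N5O10P2",
    "pi": "HO4P",
    "glc": "C6H12O6",
    "fru": "C6H12O6",
    "srbt": "C6H14O6",
    "glyc": "C3H8O3",
    "dha": "C3H6O3",
    "dhap": "C3H7O6P",
    "g3p": "C3H9O6P",
    "gap": "C3H7O6P",
    "xu5p": "C5H11O8P",
    "pyr": "C3H4O3",
    "ala": "C3H7NO2",
    "nh4": "H4N",
    "prot": "C3H5NO",
    "carb": "C6H10O5",
    "actn": "C4H8O2",
    "btd": "C4H10O2",
}

#: (name, exchange id, carbons) of the screenable toy carbon sources
TOY_CARBON_SOURCES: list[tuple[str, str, int]] = [
    ("glucose", "EX_glc", 6),
    ("glycerol", "EX_glyc", 3),
    ("methanol", "EX_mthl", 1),
    ("sorbitol", "EX_srbt", 6),
]


@dataclass
class ToyNetworkSpec:
    """Tunable parameters of the toy methylotroph network.

    po_ratio :
        Operational P/O ratio encoded in the oxidase proton
        stoichiometry (mol ATP per mol O atom reduced).
    biomass_yield_params :
        mmol of each macromolecule drained per gDCW of biomass.
    gam :
        Growth-associated ATP for polymerization, mmol ATP/gDCW,
        embedded in the biomass equation (distinct from NGAM, which is
        imposed on the ATPM reaction at simulation time).
    include_peroxisome :
        When false, AOD and catalase run in the cytosol instead of the
        peroxisome (no [x] compartment, no peroxisomal transports).
    """

    include_peroxisome: bool = True
    po_ratio: float = 1.48
    biomass_yield_params: Mapping[str, float] = field(
        default_factory=lambda: {"protein": 8.0, "carbohydrate": 3.0}
    )
    gam: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.po_ratio <= 0:
            raise ValueError("po_ratio must be > 0")
        if any(v < 0 for v in self.biomass_yield_params.values()):
            raise ValueError("biomass coefficients must be >= 0")
        if all(v == 0 for v in self.biomass_yield_params.values()):
            raise ValueError("biomass equation needs a non-zero coefficient")


@dataclass
class ChemostatGeneratorSpec:
    """Parameters of the synthetic chemostat series generator."""

    m_s: float = 0.1  # maintenance substrate flux, mmol/gDCW-hr
    y_max: float = 0.09  # maximal yield, gDCW/mmol substrate
    d_values: Sequence[float] = (0.05, 0.08, 0.11, 0.14, 0.17, 0.2)
    noise_sd: float = 0.0  # relative sd of multiplicative Gaussian noise
    seed: int = 0
    substrate_id: str = "EX_glc"

    def __post_init__(self) -> None:
        if self.m_s < 0 or self.y_max <= 0 or self.noise_sd < 0:
            raise ValueError("invalid chemostat generator parameters")
        if len(self.d_values) < 2:
            raise ValueError("need >= 2 dilution rates")


def build_toy_methanol_network(
    spec: ToyNetworkSpec | None = None,
) -> MetabolicModel:
    """Construct the toy methylotroph model (see module docstring)."""
    spec = spec or ToyNetworkSpec()
    x = "x" if spec.include_peroxisome else "c"
    # protons translocated per oxidase turnover (per mol O2); the ATP
    # synthase uses 3 protons per ATP, so P/O = pumped / 6
    pumped = 6.0 * spec.po_ratio
    prot = spec.biomass_yield_params.get("protein", 0.0)
    carb = spec.biomass_yield_params.get("carbohydrate", 0.0)
    gam = spec.gam

    R: list[tuple[str, str, str, str]] = []  # id, equation, gpr, subsystem

    # --- exchanges (negative flux = uptake); carbon sources are closed
    # by default and opened through simulation conditions, while the
    # non-carbon minimal-medium components stay freely available
    carbon_ex = ("mthl", "glyc", "glc", "srbt", "actn", "btd", "co2")
    mineral_ex = ("o2", "nh4", "h2o", "pi")
    for mid in carbon_ex:
        R.append((f"EX_{mid}", f"{mid}[e] ->", "", "Exchange"))
    for mid in mineral_ex:
        R.append((f"EX_{mid}", f"{mid}[e] <=>", "", "Exchange"))

    # --- transport
    R += [
        ("MEOHt", "mthl[e] <=> mthl[c]", "", "Transport, Extracellular"),
        ("GLYCt", "glyc[e] <=> glyc[c]", "", "Transport, Extracellular"),
        ("GLCt", "glc[e] -> glc[c]", "g_glct", "Transport, Extracellular"),
        ("SBTt", "srbt[e] -> srbt[c]", "", "Transport, Extracellular"),
        ("ACTNt", "actn[e] <=> actn[c]", "", "Transport, Extracellular"),
        ("BTDt", "btd[c] -> btd[e]", "", "Transport, Extracellular"),
        ("NH4t", "nh4[e] -> nh4[c]", "", "Transport, Extracellular"),
        ("O2t", "o2[e] <=> o2[c]", "", "Transport, Extracellular"),
        ("CO2t", "co2[c] <=> co2[e]", "", "Transport, Extracellular"),
        ("H2Ot", "h2o[e] <=> h2o[c]", "", "Transport, Extracellular"),
        ("PIt", "pi[e] <=> pi[c]", "", "Transport, Extracellular"),
        ("O2tm", "o2[c] <=> o2[m]", "", "Transport, Mitochondrial"),
        ("CO2tm", "co2[m] <=> co2[c]", "", "Transport, Mitochondrial"),
        ("H2Otm", "h2o[c] <=> h2o[m]", "", "Transport, Mitochondrial"),
        ("PItm", "pi[c] <=> pi[m]", "", "Transport, Mitochondrial"),
        ("PYRtm", "pyr[c] -> pyr[m]", "g_pyrt", "Transport, Mitochondrial"),
        (
            "ANT",
            "atp[m] + adp[c] -> atp[c] + adp[m]",
            "g_ant",
            "Transport, Mitochondrial",
        ),
        (
            "NADHS",
            "nadh[c] + nad[m] -> nad[c] + nadh[m]",
            "g_shuttle",
            "Transport, Mitochondrial",
        ),
    ]
    if spec.include_peroxisome:
        R += [
            ("MEOHtx", "mthl[c] <=> mthl[x]", "", "Transport, Peroxisomal"),
            ("O2tx", "o2[c] <=> o2[x]", "", "Transport, Peroxisomal"),
            ("H2Otx", "h2o[c] <=> h2o[x]", "", "Transport, Peroxisomal"),
            ("FALDtx", "fald[x] <=> fald[c]", "", "Transport, Peroxisomal"),
        ]

    # --- methanol utilization (assimilatory + dissimilatory branches)
    R += [
        (
            "AOD",
            f"mthl[{x}] + o2[{x}] -> fald[{x}] + h2o2[{x}]",
            "g_aod1 or g_aod2",
            "Methanol Metabolism",
        ),
        (
            "CAT",
            f"2 h2o2[{x}] -> 2 h2o[{x}] + o2[{x}]",
            "g_cat",
            "Methanol Metabolism",
        ),
        (
            "DAS",
            "fald[c] + xu5p[c] -> dha[c] + gap[c]",
            "g_das",
            "Methanol Metabolism",
        ),
        (
            "DAK",
            "dha[c] + atp[c] -> dhap[c] + adp[c]",
            "g_dak",
            "Methanol Metabolism",
        ),
        (
            "XPREGEN",
            "3 dhap[c] + 2 gap[c] + 2 h2o[c] -> 3 xu5p[c] + 2 pi[c]",
            "g_tkt and g_tal",
            "Pentose Phosphate Pathway",
        ),
        (
            "FALDH",
            "fald[c] + gsh[c] + nad[c] -> fgt[c] + nadh[c]",
            "g_fld1",
            "Methanol Metabolism",
        ),
        (
            "SFGTH",
            "fgt[c] + h2o[c] -> for[c] + gsh[c]",
            "g_fgh1",
            "Methanol Metabolism",
        ),
        (
            "FDH",
            "for[c] + nad[c] -> co2[c] + nadh[c]",
            "g_fdh1",
            "Methanol Metabolism",
        ),
    ]

    # --- glycerol / sorbitol / glucose entry
    R += [
        (
            "GLYCDy",
            "glyc[c] + nad[c] -> dha[c] + nadh[c]",
            "g_gcy1",
            "Complex Alcohol Metabolism",
        ),
        (
            "G3PD1ir",
            "dhap[c] + nadh[c] -> g3p[c] + nad[c]",
            "g_gpd1",
            "Glycerolipid Metabolism",
        ),
        (
            "G3PT",
            "g3p[c] + h2o[c] -> glyc[c] + pi[c]",
            "g_gpp1",
            "Glycerolipid Metabolism",
        ),
        (
            "SBTD",
            "srbt[c] + nad[c] -> fru[c] + nadh[c]",
            "g_sdh",
            "Alternate Carbon Metabolism",
        ),
        (
            "HEXUP",
            "glc[c] + 2 atp[c] -> 2 gap[c] + 2 adp[c]",
            "g_hxk and g_pfk",
            "Glycolysis/Gluconeogenesis",
        ),
        (
            "FRUUP",
            "fru[c] + 2 atp[c] -> 2 gap[c] + 2 adp[c]",
            "g_hxk and g_pfk",
            "Glycolysis/Gluconeogenesis",
        ),
        ("TPI", "dhap[c] <=> gap[c]", "g_tpi", "Glycolysis/Gluconeogenesis"),
    ]

    # --- lumped lower glycolysis, TCA, alanine/protein/carbohydrate
    # (glycolytic NADH is delivered to the mitochondrial pool: the lump
    # includes the redox shuttle, see methods note)
    R += [
        (
            "GLYCLO",
            "gap[c] + 2 adp[c] + pi[c] + nad[m] -> "
            "pyr[c] + 2 atp[c] + nadh[m] + h2o[c]",
            "g_gapdh and g_pyk",
            "Glycolysis/Gluconeogenesis",
        ),
        (
            "TCA",
            "pyr[m] + 5 nad[m] + 2 h2o[m] + adp[m] + pi[m] -> "
            "3 co2[m] + 5 nadh[m] + atp[m]",
            "g_pdh and g_cs",
            "Citric Acid Cycle",
        ),
        (
            "ALASYN",
            "pyr[c] + nh4[c] <=> ala[c] + h2o[c]",
            "g_alt1",
            "Alanine and Aspartate Metabolism",
        ),
        (
            "PROTSYN",
            "ala[c] + 3 atp[c] + 2 h2o[c] -> prot[c] + 3 adp[c] + 3 pi[c]",
            "g_rib",
            "Biomass requirement",
        ),
        (
            "CARBSYN",
            "2 gap[c] + atp[c] + 2 h2o[c] -> carb[c] + adp[c] + 3 pi[c]",
            "g_ugp",
            "Biomass requirement",
        ),
    ]

    # --- oxidative phosphorylation (tunable P/O) and maintenance
    R += [
        (
            "RESPm",
            "nadh[m] + 2 cytco[m] -> nad[m] + 2 cytcr[m]",
            "g_ndi1",
            "Oxidative Phosphorylation",
        ),
        (
            "CYOOm",
            f"4 cytcr[m] + o2[m] + {pumped:g} h[m] -> "
            f"4 cytco[m] + 2 h2o[m] + {pumped:g} h_i[m]",
            "g_cox",
            "Oxidative Phosphorylation",
        ),
        (
            "ATPS3m",
            "adp[m] + pi[m] + 3 h_i[m] -> atp[m] + h2o[m] + 3 h[m]",
            "g_atp1",
            "Oxidative Phosphorylation",
        ),
        ("ATPM", "atp[c] + h2o[c] -> adp[c] + pi[c]", "", "ATP maintenance"),
    ]

    # --- biotransformation target and biomass
    R += [
        (
            "BTDD",
            "actn[c] + nadh[c] -> btd[c] + nad[c]",
            "g_bdh1",
            "Complex Alcohol Metabolism",
        ),
        (
            "BIOMASS",
            f"{prot:g} prot[c] + {carb:g} carb[c] + {gam:g} atp[c] + "
            f"{gam:g} h2o[c] -> {gam:g} adp[c] + {gam:g} pi[c]",
            "",
            "Biomass requirement",
        ),
    ]

    reactions = []
    met_ids: set[str] = set()
    for rid, eqn, gpr, subsystem in R:
        stoich, reversible = parse_equation(eqn)
        reactions.append(
            Reaction(rid, stoich, reversible, gpr=gpr, subsystem=subsystem)
        )
        met_ids |= set(stoich)

    metabolites = [
        Metabolite(mid, formula=TOY_FORMULAS.get(mid[: mid.index("[")]))
        for mid in sorted(met_ids)
    ]
    return MetabolicModel(
        metabolites, reactions, objective_id="BIOMASS", name="toy_methylotroph"
    )


# ---------------------------------------------------------------------------
# random networks for oracle testing


def generate_random_network(n_reactions: int, seed: int) -> MetabolicModel:
    """A random small network with a guaranteed substrate->biomass path.

    All bounds are finite (required by the vertex-enumeration oracle).
    The skeleton is EX_sub -> transport -> a short linear chain ending
    in a biomass drain; the remaining reactions connect random internal
    metabolite pairs with random coefficients, some reversible.
    Deterministic for a given seed.
    """
    if not 4 <= n_reactions <= 15:
        raise ValueError("n_reactions must be in [4, 15]")
    rng = np.random.default_rng(seed)

    chain_len = int(rng.integers(1, 3))
    internal = [f"m{i}[c]" for i in range(max(2, chain_len + 1))]

    reactions: list[Reaction] = []
    uptake = float(rng.uniform(1.0, 5.0))
    reactions.append(
        Reaction("EX_sub", {"sub[e]": 1.0}, True, lower_bound=-uptake,
                 upper_bound=0.0)
    )
    reactions.append(
        Reaction("SUBt", {"sub[e]": -1.0, internal[0]: 1.0}, False,
                 upper_bound=BIG_M_FINITE)
    )
    for i in range(chain_len):
        yield_coef = float(rng.uniform(0.5, 2.0))
        reactions.append(
            Reaction(
                f"C{i}",
                {internal[i]: -1.0, internal[i + 1]: yield_coef},
                False,
                upper_bound=BIG_M_FINITE,
            )
        )
    reactions.append(
        Reaction(
            "BIOMASS",
            {internal[chain_len]: -1.0},
            False,
            upper_bound=BIG_M_FINITE,
        )
    )

    i = 0
    while len(reactions) < n_reactions:
        a, b = rng.choice(len(internal), size=2, replace=False)
        coef_a = float(rng.uniform(0.5, 2.0))
        coef_b = float(rng.uniform(0.5, 2.0))
        reversible = bool(rng.random() < 0.3)
        ub = float(rng.uniform(1.0, 10.0))
        reactions.append(
            Reaction(
                f"R{i}",
                {internal[a]: -coef_a, internal[b]: coef_b},
                reversible,
                lower_bound=-ub if reversible else 0.0,
                upper_bound=ub,
            )
        )
        i += 1

    met_ids = sorted({m for r in reactions for m in r.stoichiometry})
    mets = [Metabolite(mid) for mid in met_ids]
    return MetabolicModel(
        mets, reactions, objective_id="BIOMASS", name=f"random_{seed}"
    )


#: finite cap used inside random networks so vertex enumeration applies
BIG_M_FINITE = 20.0


# ---------------------------------------------------------------------------
# chemostat series


def generate_chemostat_series(
    spec: ChemostatGeneratorSpec | None = None,
) -> ChemostatSeries:
    """Synthetic q_s-vs-D series from the linear maintenance model.

    q_s(D) = D / y_max + m_s, perturbed multiplicatively by
    Normal(0, noise_sd) noise; deterministic under a fixed seed.
    """
    spec = spec or ChemostatGeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    points = []
    for d in spec.d_values:
        q = d / spec.y_max + spec.m_s
        if spec.noise_sd > 0:
            q *= 1.0 + rng.normal(0.0, spec.noise_sd)
        points.append(ChemostatPoint(d, max(q, 0.0)))
    return ChemostatSeries(points, spec.substrate_id)
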