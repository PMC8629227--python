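"""Phenotypic trait simulation under an additive-dominance-epistasis model.

Eleven traits (PT1..PT11) are each controlled by 40 marker loci chosen
from a fixed candidate grid (eight evenly spaced candidates per linkage
group).  The genotypic value of an individual is

    G = mu + sum_j p_j c_j + sum_{j=1..39} p_j c_j c_{j+1}

where c_j is the contribution of the coded genotype at the j-th control
locus in genome order (a for AA, d = dom_degree * a for Aa, -a for aa)
and the locus weights p_j are Uniform(0,1) draws.  Environmental noise
is scaled to hit a target heritability: sigma_e^2 = (1 - h2) sigma_g^2 / h2,
with sigma_g^2 the empirical variance of G in the realized population,
so phenotypes are Y = G + eps with eps ~ N(0, sigma_e^2).

Trait overlap (pleiotropy) is what the study manipulates: PT1 is the
principal trait (loci on groups 1-5, h2 = 0.5); PT2 mirrors it on groups
6-10 with no shared loci; PT3-PT5 share loci with PT1 at three
heritability tiers; PT6-PT8 and PT9-PT11 overlap progressively less.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap, GenotypeMatrix, candidate_control_loci

__all__ = [
    "TRAIT_IDS",
    "TRAIT_HERITABILITY",
    "TRAIT_LAYOUT",
    "SCENARIO_POSITIONS",
    "ScenarioConfig",
    "TraitArchitecture",
    "PhenotypeTable",
    "assign_control_loci",
    "genotypic_contribution",
    "genotypic_value",
    "build_architectures",
    "simulate_phenotypes",
    "realized_heritability",
]

TRAIT_IDS = tuple(f"PT{i}" for i in range(1, 12))

#: target heritability per trait
TRAIT_HERITABILITY = {
    "PT1": 0.5, "PT2": 0.5,
    "PT3": 0.3, "PT4": 0.5, "PT5": 0.8,
    "PT6": 0.3, "PT7": 0.5, "PT8": 0.8,
    "PT9": 0.3, "PT10": 0.5, "PT11": 0.8,
}

#: control loci per linkage group (LG1..LG10): 8 = all candidates in the
#: group, 4 = the scenario's four candidate positions, 0 = none.
TRAIT_LAYOUT = {
    "PT1": (8, 8, 8, 8, 8, 0, 0, 0, 0, 0),
    "PT2": (0, 0, 0, 0, 0, 8, 8, 8, 8, 8),
    "PT3": (4, 4, 4, 4, 4, 4, 4, 4, 4, 4),
    "PT4": (4, 4, 4, 4, 4, 4, 4, 4, 4, 4),
    "PT5": (4, 4, 4, 4, 4, 4, 4, 4, 4, 4),
    "PT6": (4, 4, 4, 0, 0, 8, 8, 4, 4, 4),
    "PT7": (4, 4, 4, 0, 0, 8, 8, 4, 4, 4),
    "PT8": (4, 4, 4, 0, 0, 8, 8, 4, 4, 4),
    "PT9": (4, 0, 0, 0, 0, 8, 8, 8, 8, 4),
    "PT10": (4, 0, 0, 0, 0, 8, 8, 8, 8, 4),
    "PT11": (4, 0, 0, 0, 0, 8, 8, 8, 8, 4),
}

#: within-group candidate positions used where a trait takes 4 of the 8
SCENARIO_POSITIONS = {
    1: (10, 20, 30, 40),
    2: (50, 60, 70, 80),
    3: (10, 20, 70, 80),
    4: (30, 40, 50, 60),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One of the four study scenarios: which four of the eight
    within-group candidate positions a 4-locus trait uses."""

    scenario_id: int

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_POSITIONS:
            raise ValueError(
                f"unknown scenario {self.scenario_id}; valid scenarios are "
                f"{sorted(SCENARIO_POSITIONS)}"
            )

    @property
    def selected_positions(self) -> tuple[int, ...]:
        return SCENARIO_POSITIONS[self.scenario_id]


def assign_control_loci(
    trait_id: str, scenario: ScenarioConfig | int, gmap: GenomeMap
) -> np.ndarray:
    """Global marker ids of a trait's 40 control loci, in genome order."""
    if trait_id not in TRAIT_LAYOUT:
        raise ValueError(f"unknown trait {trait_id!r}; expected one of {TRAIT_IDS}")
    if not isinstance(scenario, ScenarioConfig):
        scenario = ScenarioConfig(scenario)
    candidates = candidate_control_loci(gmap)
    m = gmap.markers_per_group
    # scenario positions are within-group candidate indices on the default
    # map; rescale through candidate rank so non-default maps stay valid
    rank = {10: 0, 20: 1, 30: 2, 40: 3, 50: 4, 60: 5, 70: 6, 80: 7}
    sel = [rank[p] for p in scenario.selected_positions]
    loci: list[np.ndarray] = []
    for g, count in enumerate(TRAIT_LAYOUT[trait_id], start=1):
        if count == 8:
            loci.append(candidates[g])
        elif count == 4:
            loci.append(candidates[g][sel])
        elif count != 0:
            raise ValueError(f"invalid per-group locus count {count}")
    out = np.sort(np.concatenate(loci))
    return out


@dataclass
class TraitArchitecture:
    """Genetic architecture of one trait: its control loci, their
    weights, and the noise scale implied by the target heritability."""

    trait_id: str
    control_loci: np.ndarray
    weights: np.ndarray
    h2: float
    mu: float = 100.0
    additive_effect: float = 1.0
    dominance_degree: float = 0.5

    def __post_init__(self) -> None:
        self.control_loci = np.asarray(self.control_loci)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.control_loci) != len(self.weights):
            raise ValueError("one weight is required per control locus")
        if not 0 < self.h2 <= 1:
            raise ValueError(f"heritability must be in (0, 1], got {self.h2}")


def genotypic_contribution(g, a: float = 1.0, dom_degree: float = 0.5):
    """Contribution of a coded genotype: a for AA (1), dom_degree*a for
    Aa (0), -a for aa (-1).  Vectorized over ``g``."""
    garr = np.asarray(g)
    if not np.isin(garr, (1, 0, -1)).all():
        raise ValueError("genotype codes must be in {1, 0, -1}")
    out = np.where(garr == 1, a, np.where(garr == 0, dom_degree * a, -a))
    return float(out) if np.isscalar(g) else out


def genotypic_value(genotypes, arch: TraitArchitecture):
    """Genotypic value(s) under the additive + adjacent-epistasis model.

    ``genotypes`` holds coded genotypes at the trait's control loci in
    genome order; a 1-D vector gives one individual, a 2-D array one row
    per individual.  The epistatic term multiplies adjacent contributions
    and carries the weight of the left locus of each pair.
    """
    g = np.atleast_2d(np.asarray(genotypes))
    if g.shape[1] != len(arch.control_loci):
        raise ValueError(
            f"expected genotypes at {len(arch.control_loci)} control loci, got {g.shape[1]}"
        )
    c = genotypic_contribution(g, arch.additive_effect, arch.dominance_degree)
    p = arch.weights
    additive = c @ p
    epistatic = (c[:, :-1] * c[:, 1:]) @ p[:-1]
    values = arch.mu + additive + epistatic
    return float(values[0]) if np.asarray(genotypes).ndim == 1 else values


@dataclass
class PhenotypeTable:
    """Simulated phenotypes with their oracle components.

    Y = G + eps columnwise; G includes the trait mean.  The genotypic
    and error components are kept so realized heritability and genetic
    correlations can be computed exactly rather than estimated.
    """

    phenotypes: pd.DataFrame
    genotypic_values: pd.DataFrame
    errors: pd.DataFrame
    sigma_g2: pd.Series
    sigma_e2: pd.Series
    architectures: dict[str, TraitArchitecture] = field(default_factory=dict)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.phenotypes.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.phenotypes)

    def to_csv(self, path, keep_oracle: bool = False) -> None:
        df = self.phenotypes.copy()
        if keep_oracle:
            for t in self.trait_ids:
                df[f"G_{t}"] = self.genotypic_values[t]
                df[f"eps_{t}"] = self.errors[t]
        df.to_csv(path, index=False)


def build_architectures(
    scenario: ScenarioConfig | int,
    gmap: GenomeMap,
    seed: int | np.random.Generator | None = None,
    mu: float = 100.0,
    additive_effect: float = 1.0,
    dominance_degree: float = 0.5,
    shared_weights: bool = True,
    trait_ids=TRAIT_IDS,
) -> dict[str, TraitArchitecture]:
    """Draw locus weights and assemble the full 11-trait architecture.

    By default one Uniform(0,1) weight is drawn per candidate locus and
    reused by every trait that locus controls, so pleiotropic traits have
    well-defined genetic correlations; ``shared_weights=False`` draws
    independent weights per trait instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = np.concatenate(list(candidate_control_loci(gmap).values()))
    shared = dict(zip(candidates, rng.uniform(size=len(candidates))))
    archs: dict[str, TraitArchitecture] = {}
    for tid in trait_ids:
        loci = assign_control_loci(tid, scenario, gmap)
        if shared_weights:
            w = np.array([shared[l] for l in loci])
        else:
            w = rng.uniform(size=len(loci))
        archs[tid] = TraitArchitecture(
            tid, loci, w, TRAIT_HERITABILITY[tid], mu, additive_effect, dominance_degree
        )
    return archs


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    architectures: dict[str, TraitArchitecture],
    seed: int | np.random.Generator | None = None,
) -> PhenotypeTable:
    """Compute genotypic values and add heritability-scaled noise.

    The noise variance comes from the realized genotypic variance of the
    simulated population (sigma_e^2 = (1-h2) sigma_g^2 / h2), so the
    realized heritability of every replicate tracks its target.
    """
    if not architectures:
        raise ValueError("at least one trait architecture is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = genotypes.n_individuals
    G, Y, E, sg2, se2 = {}, {}, {}, {}, {}
    for tid, arch in architectures.items():
        g_loci = genotypes.at_markers(arch.control_loci)
        gv = genotypic_value(g_loci, arch)
        var_g = float(np.var(gv))
        if var_g == 0:
            raise ValueError(
                f"degenerate genotypic variance for {tid}; population carries no variation"
            )
        var_e = (1.0 - arch.h2) * var_g / arch.h2
        eps = rng.normal(0.0, np.sqrt(var_e), size=n) if var_e > 0 else np.zeros(n)
        G[tid], E[tid], Y[tid] = gv, eps, gv + eps
        sg2[tid], se2[tid] = var_g, var_e
    return PhenotypeTable(
        phenotypes=pd.DataFrame(Y),
        genotypic_values=pd.DataFrame(G),
        errors=pd.DataFrame(E),
        sigma_g2=pd.Series(sg2),
        sigma_e2=pd.Series(se2),
        architectures=dict(architectures),
    )


def realized_heritability(table: PhenotypeTable, trait_id: str) -> float:
    """Var(G) / Var(Y) of one trait in the realized population."""
    var_y = float(np.var(table.phenotypes[trait_id]))
    if var_y == 0:
        raise ValueError(f"zero phenotypic variance for {trait_id}")
    return float(np.var(table.genotypic_values[trait_id])) / var_y


def architectures_to_frame(architectures: dict[str, TraitArchitecture]) -> pd.DataFrame:
    """Tidy (trait_id, marker_id, weight) table for export."""
    rows = [
        (tid, int(m), float(w))
        for tid, arch in architectures.items()
        for m, w in zip(arch.control_loci, arch.weights)
    ]
    return pd.DataFrame(rows, columns=["trait_id", "marker_id", "weight"])
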