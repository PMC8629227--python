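"""Correlation structure, trait grouping and indirect selection response.

The response in trait *y* to truncation selection on trait *x* is
GS_y(x) = i * h_x * r_g * s_y, with *i* the standardized selection
intensity of the selected fraction, h_x the square root of the selected
trait's heritability, r_g the genetic correlation between the traits and
s_y the phenotypic standard deviation of *y*.  Because the simulator
stores genotypic values, r_g can be computed exactly (oracle mode) as
well as estimated from phenotypes the way field data would require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import PhenotypeTable

__all__ = [
    "selection_intensity",
    "pearson_matrix",
    "genetic_correlation",
    "SelectionGainInput",
    "indirect_gain",
    "trait_groups",
    "correlation_edges",
]

#: trait groups by shared-control-loci structure
TRAIT_GROUPS = {
    "PT1": 1, "PT2": 2,
    "PT3": 3, "PT4": 3, "PT5": 3,
    "PT6": 4, "PT7": 4, "PT8": 4,
    "PT9": 5, "PT10": 5, "PT11": 5,
}


def selection_intensity(selected_fraction: float) -> float:
    """Standardized selection differential i = phi(z)/p for truncation
    selection keeping the top fraction p of a normal trait."""
    p = float(selected_fraction)
    if not 0 < p < 1:
        raise ValueError(f"selected fraction must be in (0, 1), got {p}")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def pearson_matrix(
    phenotypes: pd.DataFrame | PhenotypeTable,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided t-test significance.

    Returns (r, p_value, flag) data frames; flags are '**' at the 1%
    level, '*' at 5%, 'ns' otherwise, and 'undef' for constant traits.
    """
    Y = phenotypes.phenotypes if isinstance(phenotypes, PhenotypeTable) else pd.DataFrame(phenotypes)
    n = len(Y)
    if n < 3:
        raise ValueError("need at least 3 individuals for a correlation t-test")
    cols = list(Y.columns)
    constant = [c for c in cols if np.var(Y[c].to_numpy(float)) == 0]
    r = Y.corr()
    tstat = r * np.sqrt((n - 2) / (1.0 - r**2).clip(lower=np.finfo(float).tiny))
    pval = pd.DataFrame(
        2 * stats.t.sf(np.abs(tstat), df=n - 2), index=cols, columns=cols
    )
    np.fill_diagonal(pval.values, 0.0)
    flag = pd.DataFrame("ns", index=cols, columns=cols)
    flag[pval < 0.05] = "*"
    flag[pval < 0.01] = "**"
    for c in constant:
        flag.loc[c, :] = flag.loc[:, c] = "undef"
    return r, pval, flag


def genetic_correlation(
    table: PhenotypeTable, x: str, y: str, mode: str = "oracle"
) -> float:
    """Genetic correlation between two traits.

    ``oracle`` mode correlates the stored genotypic values directly
    (exact, possible only in simulation); ``inference`` mode uses the
    field-data estimator r_g = r_p / (h_x * h_y) with h the square root
    of each trait's target heritability, clipped to [-1, 1].
    """
    if mode == "oracle":
        gx = table.genotypic_values[x].to_numpy(float)
        gy = table.genotypic_values[y].to_numpy(float)
        return float(np.corrcoef(gx, gy)[0, 1])
    if mode == "inference":
        hx = np.sqrt(table.architectures[x].h2)
        hy = np.sqrt(table.architectures[y].h2)
        if hx == 0 or hy == 0:
            raise ValueError("inference-mode genetic correlation undefined at h = 0")
        rp = float(
            np.corrcoef(
                table.phenotypes[x].to_numpy(float), table.phenotypes[y].to_numpy(float)
            )[0, 1]
        )
        return float(np.clip(rp / (hx * hy), -1.0, 1.0))
    raise ValueError(f"mode must be 'oracle' or 'inference', got {mode!r}")


@dataclass(frozen=True)
class SelectionGainInput:
    """Inputs of the indirect selection response formula."""

    i: float                 # selection intensity, standardized units
    h_x: float               # sqrt of the selected trait's heritability
    r_g: float               # genetic correlation between x and y
    s_gy: float              # phenotypic standard deviation of y, trait units
    mu_y: float = float("nan")  # mean of y, for the percentage gain

    def __post_init__(self) -> None:
        if self.i <= 0:
            raise ValueError("selection intensity must be positive")
        if not 0 <= self.h_x <= 1:
            raise ValueError("h_x must be in [0, 1]")
        if abs(self.r_g) > 1:
            raise ValueError("genetic correlation must be in [-1, 1]")
        if self.s_gy <= 0:
            raise ValueError("phenotypic standard deviation must be positive")


def indirect_gain(inp: SelectionGainInput) -> tuple[float, float]:
    """(gain in trait units, gain as a percentage of the trait mean)."""
    gs = inp.i * inp.h_x * inp.r_g * inp.s_gy
    if np.isnan(inp.mu_y):
        return gs, float("nan")
    if inp.mu_y == 0:
        raise ValueError("percentage gain undefined for a zero trait mean")
    return gs, 100.0 * gs / inp.mu_y


def trait_groups(trait_ids) -> dict[str, int]:
    """Deterministic structural grouping of the traits (1..5)."""
    unknown = [t for t in trait_ids if t not in TRAIT_GROUPS]
    if unknown:
        raise ValueError(f"unknown trait(s) {unknown}; expected PT1..PT11")
    return {t: TRAIT_GROUPS[t] for t in trait_ids}


def correlation_edges(phenotypes: pd.DataFrame | PhenotypeTable) -> pd.DataFrame:
    """Adjacency list (trait_a, trait_b, r, abs_r, significance, group_a,
    group_b) for network-style summaries of the correlation structure."""
    r, _, flag = pearson_matrix(phenotypes)
    groups = trait_groups(list(r.columns))
    rows = []
    cols = list(r.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            rows.append(
                (a, b, r.loc[a, b], abs(r.loc[a, b]), flag.loc[a, b], groups[a], groups[b])
            )
    return pd.DataFrame(
        rows,
        columns=["trait_a", "trait_b", "r", "abs_r", "significance", "group_a", "group_b"],
    )
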