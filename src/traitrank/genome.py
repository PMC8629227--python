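"""Marker maps and F2 genotype simulation.

The simulated genome is a set of linkage groups with evenly spaced
codominant biallelic markers.  An F2 population descends from a cross
between two fully contrasting homozygous parents: every P1 allele is
coded 1, every P2 allele 0, so the F1 is uniformly heterozygous and the
F2 segregates 1:2:1 at each marker.  Gametes are generated by a Markov
walk along each linkage group — the allele at the first marker is a fair
coin, and each subsequent allele switches phase with the recombination
probability of the adjacent interval — so different groups assort
independently and there is no crossover interference (Haldane map by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMap",
    "GenotypeMatrix",
    "build_genome_map",
    "recombination_fraction",
    "simulate_f2",
    "simulate_gametes",
    "parental_population",
    "candidate_control_loci",
]

#: coded genotype classes
CODE_AA, CODE_HET, CODE_aa = 1, 0, -1


@dataclass(frozen=True)
class GenomeMap:
    """Layout of markers on linkage groups.

    Markers are evenly spaced: with ``markers_per_group`` markers over
    ``group_length_cm`` centimorgans the spacing is their ratio, and
    marker *i* (1-based within its group) sits at ``i * spacing`` cM.
    Global marker ids run 1..n_markers, group by group.
    """

    n_groups: int
    markers_per_group: int
    group_length_cm: float

    def __post_init__(self) -> None:
        if self.n_groups <= 0 or self.markers_per_group <= 0 or self.group_length_cm <= 0:
            raise ValueError(
                "n_groups, markers_per_group and group_length_cm must all be positive; "
                f"got ({self.n_groups}, {self.markers_per_group}, {self.group_length_cm})"
            )

    @property
    def n_markers(self) -> int:
        return self.n_groups * self.markers_per_group

    @property
    def spacing_cm(self) -> float:
        """Distance between adjacent markers within a group."""
        return self.group_length_cm / self.markers_per_group

    @property
    def marker_ids(self) -> np.ndarray:
        """Global 1-based marker ids."""
        return np.arange(1, self.n_markers + 1)

    @property
    def groups(self) -> np.ndarray:
        """Linkage group (1-based) of each marker, in marker-id order."""
        return np.repeat(np.arange(1, self.n_groups + 1), self.markers_per_group)

    @property
    def positions_cm(self) -> np.ndarray:
        """Within-group cM coordinate of each marker (1-based convention)."""
        within = self.spacing_cm * np.arange(1, self.markers_per_group + 1)
        return np.tile(within, self.n_groups)

    def group_of(self, marker_id: int | np.ndarray) -> int | np.ndarray:
        """Linkage group of a global marker id."""
        return -(-np.asarray(marker_id) // self.markers_per_group)

    def to_frame(self) -> pd.DataFrame:
        """3-column map table (marker_id, linkage_group, position_cm)."""
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "linkage_group": self.groups,
                "position_cm": self.positions_cm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_genome_map(
    n_groups: int = 10,
    markers_per_group: int = 100,
    group_length_cm: float = 100.0,
) -> GenomeMap:
    """Build an evenly spaced marker map; defaults give 1,000 markers on
    10 linkage groups of 100 cM (1 cM spacing)."""
    return GenomeMap(n_groups, markers_per_group, group_length_cm)


def candidate_control_loci(gmap: GenomeMap) -> dict[int, np.ndarray]:
    """Candidate control-locus marker ids per linkage group.

    The candidates are the eight markers at within-group indices
    m/10, 2m/10, ..., 8m/10 (with m markers per group) — for the default
    map, within-group positions 10, 20, ..., 80 on every group.
    """
    m = gmap.markers_per_group
    if m < 10:
        raise ValueError("need at least 10 markers per group to place control loci")
    within = np.array([round(m * k / 10) for k in range(1, 9)], dtype=int)
    return {
        g: (g - 1) * m + within for g in range(1, gmap.n_groups + 1)
    }


def recombination_fraction(d_cm: float, mapping: str = "haldane") -> float:
    """Recombination fraction between two loci ``d_cm`` centimorgans apart.

    Haldane (default, no interference): r = (1 - exp(-2d/100)) / 2.
    Kosambi: r = tanh(2d/100) / 2.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError(f"map distance must be non-negative, got {d_cm}")
    if mapping == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    elif mapping == "kosambi":
        r = 0.5 * np.tanh(2.0 * d / 100.0)
    else:
        raise ValueError(f"unknown mapping function {mapping!r}; use 'haldane' or 'kosambi'")
    return float(r) if np.isscalar(d_cm) else r


@dataclass
class GenotypeMatrix:
    """Coded genotypes, individuals x markers, entries AA=1, Aa=0, aa=-1."""

    values: np.ndarray
    marker_ids: np.ndarray
    generation_tag: str = "F2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.marker_ids = np.asarray(self.marker_ids)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x markers)")
        if self.values.shape[1] != len(self.marker_ids):
            raise ValueError("number of marker ids must match number of columns")
        if not np.isin(self.values, (CODE_AA, CODE_HET, CODE_aa)).all():
            raise ValueError("genotype codes must be in {1, 0, -1}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def at_markers(self, marker_ids: np.ndarray) -> np.ndarray:
        """Genotype sub-matrix for the given global marker ids (columns
        returned in the order requested)."""
        idx = np.searchsorted(self.marker_ids, marker_ids)
        if not np.array_equal(self.marker_ids[idx], marker_ids):
            raise KeyError("some requested marker ids are not in this matrix")
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=[f"M{m}" for m in self.marker_ids]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, generation_tag: str = "F2") -> "GenotypeMatrix":
        df = pd.read_csv(path)
        ids = np.array([int(c.lstrip("M")) for c in df.columns])
        return cls(df.to_numpy(dtype=np.int8), ids, generation_tag)


def simulate_gametes(
    gmap: GenomeMap,
    n_gametes: int,
    seed: int | np.random.Generator | None = None,
    mapping: str = "haldane",
) -> np.ndarray:
    """Simulate F1 gametes as 0/1 allele vectors over all markers.

    Within each linkage group the allele sequence is a two-state Markov
    chain: a fair coin at the first marker, then a phase switch with the
    interval's recombination fraction.  Groups are independent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = recombination_fraction(gmap.spacing_cm, mapping)
    m = gmap.markers_per_group
    out = np.empty((n_gametes, gmap.n_markers), dtype=np.int8)
    for g in range(gmap.n_groups):
        first = rng.random((n_gametes, 1)) < 0.5
        flips = rng.random((n_gametes, m - 1)) < r
        # cumulative number of crossovers mod 2 gives the phase at each marker
        phase = np.concatenate([first, flips], axis=1)
        out[:, g * m : (g + 1) * m] = np.cumsum(phase, axis=1) % 2
    return out


def simulate_f2(
    gmap: GenomeMap,
    n: int = 500,
    seed: int | np.random.Generator | None = None,
    mapping: str = "haldane",
) -> GenotypeMatrix:
    """Simulate an F2 population of ``n`` individuals.

    Each individual is the union of two independent F1 gametes; the
    coded genotype is (allele sum - 1) so AA/Aa/aa map to 1/0/-1.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maternal = simulate_gametes(gmap, n, rng, mapping)
    paternal = simulate_gametes(gmap, n, rng, mapping)
    coded = maternal + paternal - 1
    return GenotypeMatrix(coded, gmap.marker_ids, "F2")


def parental_population(gmap: GenomeMap, n: int, generation: str) -> GenotypeMatrix:
    """Deterministic P1 (all AA), P2 (all aa) or F1 (all Aa) populations."""
    fills = {"P1": CODE_AA, "P2": CODE_aa, "F1": CODE_HET}
    if generation not in fills:
        raise ValueError(f"generation must be one of {sorted(fills)}, got {generation!r}")
    values = np.full((n, gmap.n_markers), fills[generation], dtype=np.int8)
    return GenotypeMatrix(values, gmap.marker_ids, generation)
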