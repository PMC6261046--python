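"""Collapse neuron-level synapses into directed area-level connectomes.

A connection from area i to area j exists when at least ``min_axons``
synapses run from neurons of i onto neurons of j. Within-area synapses and
the diagonal are excluded from every statistic. The pairwise structural
measures mirror those used on empirical connectomes: signed and absolute
neuron-density difference and Euclidean distance between area centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sheet import CorticalSheet


@dataclass
class AreaConnectome:
    """Directed binary area x area connectome with per-pair axon counts."""

    axon_counts: np.ndarray  # (n, n) non-negative ints, zero diagonal
    min_axons: int

    @property
    def n_areas(self) -> int:
        return self.axon_counts.shape[0]

    @property
    def exists(self) -> np.ndarray:
        e = self.axon_counts >= self.min_axons
        np.fill_diagonal(e, False)
        return e

    def rethreshold(self, min_axons: int) -> "AreaConnectome":
        """Same counts, different binarization threshold (e.g. 10 axons)."""
        return AreaConnectome(self.axon_counts, min_axons)


@dataclass
class PairMeasures:
    """Structural measures for all ordered area pairs, from the final sheet."""

    densities: np.ndarray  # (n,)
    centroids: np.ndarray  # (n, 2)

    @property
    def n_areas(self) -> int:
        return len(self.densities)

    @property
    def density_difference(self) -> np.ndarray:
        """Signed density difference, origin minus termination: (n, n)."""
        return self.densities[:, None] - self.densities[None, :]

    @property
    def abs_density_difference(self) -> np.ndarray:
        return np.abs(self.density_difference)

    @property
    def distance(self) -> np.ndarray:
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((d**2).sum(axis=2))


def offdiag_mask(n: int) -> np.ndarray:
    m = np.ones((n, n), dtype=bool)
    np.fill_diagonal(m, False)
    return m


def aggregate_connectome(
    synapses: pd.DataFrame,
    neuron_area: np.ndarray,
    n_areas: int,
    min_axons: int = 1,
) -> AreaConnectome:
    """Count axons between areas and binarize at ``min_axons``.

    ``synapses`` must carry ``source_neuron_id`` and ``target_neuron_id``
    columns; every neuron id must be mapped to an area in ``neuron_area``.
    """
    src = synapses["source_neuron_id"].to_numpy()
    tgt = synapses["target_neuron_id"].to_numpy()
    if len(src) and (src.max() >= len(neuron_area) or tgt.max() >= len(neuron_area)):
        raise ValueError("synapse table references unmapped neuron ids")
    counts = np.zeros((n_areas, n_areas), dtype=np.int64)
    if len(src):
        sa = neuron_area[src]
        ta = neuron_area[tgt]
        keep = sa != ta  # within-area synapses are ignored
        np.add.at(counts, (sa[keep], ta[keep]), 1)
    return AreaConnectome(counts, min_axons)


def structural_measures(sheet: CorticalSheet) -> PairMeasures:
    """Density and centroid measures from the finalized sheet."""
    return PairMeasures(densities=sheet.densities(), centroids=sheet.centroids())


def fraction_connected(connectome: AreaConnectome) -> float:
    """Fraction of ordered off-diagonal pairs with a present connection."""
    n = connectome.n_areas
    if n < 2:
        raise ValueError("need at least two areas")
    return float(connectome.exists.sum()) / (n * (n - 1))


def n_connections(connectome: AreaConnectome) -> int:
    return int(connectome.exists.sum())


def area_degree(connectome: AreaConnectome) -> np.ndarray:
    """Afferent plus efferent connection count per area."""
    e = connectome.exists
    return e.sum(axis=1) + e.sum(axis=0)
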