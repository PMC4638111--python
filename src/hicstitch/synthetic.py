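"""Ground-truth genomes and power-law contact maps for verification.

Chromosomes are smoothed (persistent) random-walk chains placed in distinct
territories, emulating the intra-chromosomal contact excess of interphase
nuclei.  Contacts decay as a power law of true Euclidean distance, with
optional Poisson noise.  Not a biophysical polymer model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .contacts import ContactMap
from .genome import GenomeBins, bin_genome
from .mds import Configuration3D

__all__ = ["SyntheticGenome", "simulate_structure", "simulate_contacts"]


@dataclass(frozen=True)
class SyntheticGenome:
    """A known 3D genome: per-chromosome truth chains plus bin bookkeeping."""

    bins: GenomeBins
    chrom_coords: dict[str, np.ndarray]
    territory_spacing: float
    chain_step: float
    seed: int

    def truth_coords(self) -> np.ndarray:
        return np.concatenate(
            [self.chrom_coords[c] for c in self.bins.chrom_names], axis=0
        )

    def truth_configuration(self) -> Configuration3D:
        return Configuration3D(self.truth_coords(), np.arange(self.bins.n_bins))

    def chrom_configuration(self, chrom: str) -> Configuration3D:
        labels = np.arange(self.bins.n_bins)[self.bins.chrom_slice(chrom)]
        return Configuration3D(self.chrom_coords[chrom], labels)


def _place_territories(n_chroms: int, spacing: float, rng) -> np.ndarray:
    """Territory centers with pairwise separation >= spacing (rejection
    sampling in a slowly growing ball), recentered on the origin."""
    if n_chroms == 1:
        return np.zeros((1, 3))
    radius = spacing * max(1.0, n_chroms ** (1.0 / 3.0))
    centers = [np.zeros(3)]
    failures = 0
    while len(centers) < n_chroms:
        cand = rng.uniform(-radius, radius, size=3)
        if all(np.linalg.norm(cand - c) >= spacing for c in centers):
            centers.append(cand)
            failures = 0
        else:
            failures += 1
            if failures > 200:
                radius *= 1.2
                failures = 0
    arr = np.array(centers)
    return arr - arr.mean(axis=0)


def _chain(n_bins: int, step: float, rng) -> np.ndarray:
    """Persistent random walk with consecutive steps of length
    ``step * U(0.85, 1.15)`` (within the +-20% contract), centered."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    points = np.zeros((n_bins, 3))
    for i in range(1, n_bins):
        direction = 0.6 * direction + 0.4 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        points[i] = points[i - 1] + step * rng.uniform(0.85, 1.15) * direction
    return points - points.mean(axis=0)


def simulate_structure(
    n_chroms: int,
    bins_per_chrom: int | list[int],
    territory_spacing: float = 10.0,
    chain_step: float = 1.0,
    seed: int = 0,
    resolution: int = 1_000_000,
) -> SyntheticGenome:
    """Generate a ground-truth multi-chromosome 3D structure.

    Each chromosome is a smoothed random-walk chain centered on its
    territory; territory centers are pairwise separated by at least
    ``territory_spacing``.  Deterministic given ``seed``.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if isinstance(bins_per_chrom, int):
        sizes = [bins_per_chrom] * n_chroms
    else:
        sizes = list(bins_per_chrom)
        if len(sizes) != n_chroms:
            raise ValueError("bins_per_chrom list must have n_chroms entries")
    if any(s < 4 for s in sizes):
        raise ValueError("each chromosome needs at least 4 bins")
    if territory_spacing <= 0 or chain_step <= 0:
        raise ValueError("territory_spacing and chain_step must be positive")

    rng = np.random.default_rng(seed)
    centers = _place_territories(n_chroms, territory_spacing, rng)
    names = [f"chr{k + 1}" for k in range(n_chroms)]
    bins = bin_genome(
        {name: size * resolution for name, size in zip(names, sizes)}, resolution
    )
    chrom_coords = {
        name: _chain(size, chain_step, rng) + centers[k]
        for k, (name, size) in enumerate(zip(names, sizes))
    }
    return SyntheticGenome(bins, chrom_coords, territory_spacing, chain_step, seed)


def simulate_contacts(
    genome: SyntheticGenome,
    alpha_true: float = 1.0,
    count_scale: float = 1.0,
    noise: str = "none",
    seed: int = 0,
) -> ContactMap:
    """Draw a contact map from a ground-truth structure.

    Expected counts are ``count_scale * D ** (-1 / alpha_true)`` from true
    Euclidean distances, so converting the noise-free map back with index
    ``alpha_true`` recovers the distances exactly (up to the count scale).
    Poisson mode draws integer counts with those means.
    """
    if alpha_true <= 0:
        raise ValueError("alpha_true must be positive")
    if count_scale <= 0:
        raise ValueError("count_scale must be positive")
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    coords = genome.truth_coords()
    D = squareform(pdist(coords))
    with np.errstate(divide="ignore"):
        mu = count_scale * np.where(D > 0, D, np.nan) ** (-1.0 / alpha_true)
    mu[np.isnan(mu)] = 0.0
    np.fill_diagonal(mu, 0.0)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        iu = np.triu_indices(mu.shape[0], k=1)
        counts = np.zeros_like(mu)
        counts[iu] = rng.poisson(mu[iu])
        F = counts + counts.T
    else:
        F = mu
    return ContactMap.from_dense(genome.bins, F)


def intra_inter_ratio(contacts: ContactMap) -> float:
    """Total intra-chromosomal over total inter-chromosomal count mass."""
    chroms = contacts.bins.chrom_names
    intra = 0.0
    for chrom in chroms:
        block = contacts.block(chrom, chrom)
        intra += np.triu(block).sum()
    total = contacts.total_mass()
    inter = total - intra
    if inter <= 0:
        return np.inf
    return float(intra / inter)
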