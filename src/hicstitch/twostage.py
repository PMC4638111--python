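"""Two-stage whole-genome reconstruction.

Stage 1 reconstructs each chromosome independently from its
intra-chromosomal contacts (power-law distances, weighted penalized MDS,
per-chromosome power-law index).  Stage 2 samples loci from the stage-1
solutions, assembles a hybrid distance matrix — exact Euclidean distances
within chromosomes, power-law distances with exponent
``sqrt(alpha_k * alpha_k')`` between them — embeds the sampled loci, and
similarity-maps each full-resolution chromosome onto its sampled image.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .contacts import ContactMap
from .distances import AlphaEstimate, estimate_alpha, freq_to_dist
from .genome import GenomeBins
from .mds import Configuration3D, MDSConfig, solve_mds

__all__ = [
    "ChromReconstruction",
    "SamplePlan",
    "HybridDistance",
    "SimilarityTransform",
    "GenomeReconstruction",
    "aggregate_group_freqs",
    "sample_equispaced",
    "sample_aggregate",
    "sample_pc1",
    "build_plan",
    "build_hybrid",
    "procrustes_fit",
    "reconstruct_chromosomes",
    "position_genome",
    "reconstruct_genome",
    "thin_to_resolution",
    "read_configuration",
]

SCHEMES = ("equispaced", "aggregate", "pc1")


# ---------------------------------------------------------------------------
# stage-1 result
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromReconstruction:
    """A single-chromosome 3D solution with its power-law index."""

    chrom: str
    config: Configuration3D
    alpha: AlphaEstimate
    stress: float

    @property
    def n_bins(self) -> int:
        return self.config.n_points


# ---------------------------------------------------------------------------
# sampling schemes
# ---------------------------------------------------------------------------


def sample_equispaced(n_k: int, fraction: float, offset: int = 0) -> np.ndarray:
    """Evenly spaced bin indices at the prescribed sampling proportion.

    ``step = max(1, round(1/fraction))``; fraction 1.0 selects every bin.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    step = max(1, round(1.0 / fraction))
    if not 0 <= offset < step:
        raise ValueError(f"offset must be in [0, {step}), got {offset}")
    idx = np.arange(offset, n_k, step)
    if idx.size < 2:
        raise ValueError(
            f"equispaced sampling of {n_k} bins at fraction {fraction} yields "
            f"{idx.size} < 2 points; use a larger fraction"
        )
    return idx


def sample_aggregate(
    coords: np.ndarray, fraction: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Aggregate consecutive bins into groups and return centroid points.

    Groups are consecutive runs of ``round(1/fraction)`` bins (the trailing
    group may be shorter); each representative point is the centroid of its
    members' stage-1 coordinates.  Returns ``(rep_coords, groups)``.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    coords = np.asarray(coords, dtype=float)
    n_k = coords.shape[0]
    g = max(1, round(1.0 / fraction))
    groups = [np.arange(s, min(s + g, n_k)) for s in range(0, n_k, g)]
    if len(groups) < 2:
        raise ValueError(
            f"aggregation of {n_k} bins at fraction {fraction} yields "
            f"{len(groups)} < 2 groups; use a larger fraction"
        )
    reps = np.array([coords[grp].mean(axis=0) for grp in groups])
    return reps, groups


def sample_pc1(coords: np.ndarray, fraction: float) -> np.ndarray:
    """Select bins at equi-spaced ranks along the first principal component.

    Points are projected onto PC1 of the stage-1 coordinates and ordered by
    that projection; ``ceil(fraction * n_k)`` equi-spaced order statistics
    are selected.  Degenerate (zero-variance) inputs fall back to
    equi-spaced genomic sampling with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    coords = np.asarray(coords, dtype=float)
    n_k = coords.shape[0]
    if n_k < 3:
        raise ValueError("pc1 sampling needs at least 3 points")
    centered = coords - coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] <= 1e-12:
        warnings.warn(
            "degenerate coordinates (all points identical); "
            "falling back to equi-spaced sampling",
            RuntimeWarning,
            stacklevel=2,
        )
        return sample_equispaced(n_k, fraction)
    proj = centered @ vt[0]
    order = np.argsort(proj, kind="stable")
    m = math.ceil(fraction * n_k)
    if m < 2:
        raise ValueError(
            f"pc1 sampling at fraction {fraction} yields {m} < 2 points; "
            "use a larger fraction"
        )
    ranks = np.unique(np.round(np.linspace(0, n_k - 1, m)).astype(int))
    return np.sort(order[ranks])


@dataclass(frozen=True)
class SamplePlan:
    """Per-chromosome sampling used to form the stage-2 problem.

    For ``equispaced`` and ``pc1`` the plan stores strictly increasing
    local bin indices per chromosome; for ``aggregate`` it stores the
    consecutive-bin groups whose centroids act as sampled points.
    """

    scheme: str
    fraction: float
    offset: int
    indices: dict[str, np.ndarray] = field(default_factory=dict)
    groups: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def m_k(self, chrom: str) -> int:
        if self.scheme == "aggregate":
            return len(self.groups[chrom])
        return len(self.indices[chrom])

    @property
    def chroms(self) -> list[str]:
        source = self.groups if self.scheme == "aggregate" else self.indices
        return list(source)

    @property
    def m(self) -> int:
        return sum(self.m_k(c) for c in self.chroms)


def build_plan(
    chrom_recs: dict[str, ChromReconstruction],
    scheme: str = "equispaced",
    fraction: float = 0.1,
    offset: int = 0,
) -> SamplePlan:
    """Construct a :class:`SamplePlan` over all chromosomes."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown sampling scheme {scheme!r}; choose from {SCHEMES}")
    indices: dict[str, np.ndarray] = {}
    groups: dict[str, list[np.ndarray]] = {}
    for chrom, rec in chrom_recs.items():
        if scheme == "equispaced":
            indices[chrom] = sample_equispaced(rec.n_bins, fraction, offset)
        elif scheme == "pc1":
            indices[chrom] = sample_pc1(rec.config.coords, fraction)
        else:
            _, groups[chrom] = sample_aggregate(rec.config.coords, fraction)
    return SamplePlan(scheme, fraction, offset, indices, groups)


def _sampled_points(rec: ChromReconstruction, plan: SamplePlan) -> np.ndarray:
    """Stage-1 coordinates of the sampled loci (group centroids for
    the aggregate scheme)."""
    coords = rec.config.coords
    if plan.scheme == "aggregate":
        return np.array([coords[grp].mean(axis=0) for grp in plan.groups[rec.chrom]])
    return coords[plan.indices[rec.chrom]]


def _membership(groups: list[np.ndarray], n_k: int) -> np.ndarray:
    M = np.zeros((len(groups), n_k))
    for g, grp in enumerate(groups):
        M[g, grp] = 1.0
    return M


def aggregate_group_freqs(
    block: np.ndarray, groups_a: list[np.ndarray], groups_b: list[np.ndarray]
) -> np.ndarray:
    """Group-level contact frequencies: sums over all member-bin pairs."""
    Ma = _membership(groups_a, block.shape[0])
    Mb = _membership(groups_b, block.shape[1])
    return Ma @ np.asarray(block, float) @ Mb.T


def _sampled_freqs(
    contacts: ContactMap, plan: SamplePlan, chrom_a: str, chrom_b: str
) -> np.ndarray:
    """Contact frequencies between the sampled loci of two chromosomes.

    For the aggregate scheme, member-pair frequencies are summed and then
    divided by the number of contributing pairs.  The normalization keeps
    group-level frequencies on the same count scale as single-bin
    frequencies: raw sums would inflate counts by the group-pair count and
    hence shrink the power-law distances by ~``g**alpha`` relative to the
    Euclidean (centroid) diagonal blocks, which misplaces chromosomes.
    """
    block = contacts.block(chrom_a, chrom_b)
    if plan.scheme == "aggregate":
        ga, gb = plan.groups[chrom_a], plan.groups[chrom_b]
        sums = aggregate_group_freqs(block, ga, gb)
        sizes_a = np.array([len(g) for g in ga], dtype=float)
        sizes_b = np.array([len(g) for g in gb], dtype=float)
        return sums / np.outer(sizes_a, sizes_b)
    return block[np.ix_(plan.indices[chrom_a], plan.indices[chrom_b])]


# ---------------------------------------------------------------------------
# hybrid distance matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HybridDistance:
    """Stage-2 target distances over the sampled loci.

    ``matrix`` is symmetric with zero diagonal; ``block_slices`` gives each
    chromosome's index range.  In hybrid mode the diagonal blocks are exact
    Euclidean distances among sampled stage-1 points and the off-blocks are
    power-law distances; in non-hybrid mode the power law is applied
    within chromosomes as well.
    """

    matrix: np.ndarray
    block_slices: dict[str, slice]
    hybrid: bool
    isolated_pairs: tuple[tuple[str, str], ...] = ()


def build_hybrid(
    chrom_recs: dict[str, ChromReconstruction],
    plan: SamplePlan,
    contacts: ContactMap,
    zero_mode: str = "pseudocount",
    pseudocount: float | None = None,
    hybrid: bool = True,
) -> HybridDistance:
    """Assemble the stage-2 distance matrix from stage-1 solutions.

    Cross-chromosome entries use ``F ** -sqrt(alpha_k * alpha_k')``.  Zero
    sampled cross frequencies are replaced by a pseudocount (default: half
    the smallest positive sampled cross frequency) or become infinite in
    penalty mode; a chromosome pair with no finite cross entry is permitted
    in penalty mode but flagged via ``isolated_pairs``.
    """
    chroms = list(chrom_recs)
    for chrom in chroms:
        if chrom_recs[chrom].alpha is None:
            raise ValueError(f"missing power-law index for chromosome {chrom!r}")
    points = {c: _sampled_points(chrom_recs[c], plan) for c in chroms}
    sizes = [points[c].shape[0] for c in chroms]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    block_slices = {
        c: slice(int(offsets[k]), int(offsets[k + 1])) for k, c in enumerate(chroms)
    }
    m = int(offsets[-1])
    matrix = np.zeros((m, m))

    cross_freqs = {}
    for a_idx, ca in enumerate(chroms):
        for cb in chroms[a_idx + 1 :]:
            cross_freqs[(ca, cb)] = _sampled_freqs(contacts, plan, ca, cb)
    if zero_mode == "pseudocount" and pseudocount is None and cross_freqs:
        positive = np.concatenate(
            [blk[blk > 0].ravel() for blk in cross_freqs.values()]
        )
        if positive.size == 0:
            raise ValueError(
                "no positive sampled cross-chromosome frequencies; cannot "
                "derive a pseudocount (use penalty mode)"
            )
        pseudocount = float(positive.min()) / 2.0

    for ca in chroms:
        sa = block_slices[ca]
        if hybrid:
            matrix[sa, sa] = cdist(points[ca], points[ca])
        else:
            freqs = _sampled_freqs(contacts, plan, ca, ca)
            matrix[sa, sa] = freq_to_dist(
                freqs, chrom_recs[ca].alpha.alpha, zero_mode=zero_mode,
                pseudocount=pseudocount if zero_mode == "pseudocount" else None,
            )

    isolated: list[tuple[str, str]] = []
    for (ca, cb), freqs in cross_freqs.items():
        exponent = math.sqrt(chrom_recs[ca].alpha.alpha * chrom_recs[cb].alpha.alpha)
        if zero_mode == "pseudocount":
            freqs = np.where(freqs > 0, freqs, pseudocount)
        with np.errstate(divide="ignore"):
            block = np.where(freqs > 0, freqs, np.nan) ** -exponent
        block[np.isnan(block)] = np.inf
        if not np.isfinite(block).any():
            isolated.append((ca, cb))
        sa, sb = block_slices[ca], block_slices[cb]
        matrix[sa, sb] = block
        matrix[sb, sa] = block.T

    if isolated:
        warnings.warn(
            f"chromosome pairs with no finite cross distances: {isolated}; "
            "relative placement relies on the penalty term",
            RuntimeWarning,
            stacklevel=2,
        )
    np.fill_diagonal(matrix, 0.0)
    return HybridDistance(matrix, block_slices, hybrid, tuple(isolated))


# ---------------------------------------------------------------------------
# Procrustes mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimilarityTransform:
    """``x -> scale * R @ x + t`` with orthogonal ``R`` (reflections allowed)."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthogonal")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation.T + self.translation


def procrustes_fit(
    source: np.ndarray,
    target: np.ndarray,
    allow_scale: bool = True,
    allow_reflection: bool = True,
) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``source`` onto ``target``.

    Closed form via SVD of the cross-covariance (Kabsch/Umeyama).  Requires
    at least 3 points; collinear sources leave the rotation about the line
    undetermined and trigger a warning.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError(
            f"point sets differ in shape: {source.shape} vs {target.shape}"
        )
    n = source.shape[0]
    if n < 3:
        raise ValueError("procrustes_fit needs at least 3 points")
    mu_s, mu_t = source.mean(axis=0), target.mean(axis=0)
    Sc, Tc = source - mu_s, target - mu_t
    C = Tc.T @ Sc / n
    U, svals, Vt = np.linalg.svd(C)
    if svals[1] <= 1e-12 * max(svals[0], 1.0):
        warnings.warn(
            "source points are (nearly) collinear; rotation is not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    sign = np.ones(3)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        sign[-1] = -1.0
    R = U @ np.diag(sign) @ Vt
    if allow_scale:
        var_s = (Sc**2).sum() / n
        scale = float((svals * sign).sum() / var_s)
        if scale <= 0:
            scale = 1e-12
    else:
        scale = 1.0
    t = mu_t - scale * R @ mu_s
    return SimilarityTransform(R, scale, t)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeReconstruction:
    """Assembled whole-genome solution.

    ``chrom_configs`` hold the full-resolution per-chromosome coordinates
    after similarity mapping (labels are global bin indices);
    ``coarse`` is the stage-2 solution over the sampled loci (``None`` for
    a single-chromosome genome, where stage 2 is skipped).
    """

    bins: GenomeBins
    chrom_configs: dict[str, Configuration3D]
    transforms: dict[str, SimilarityTransform]
    stage1: dict[str, ChromReconstruction]
    coarse: Configuration3D | None
    plan: SamplePlan | None
    metadata: dict

    @property
    def alphas(self) -> dict[str, float]:
        return {c: rec.alpha.alpha for c, rec in self.stage1.items()}

    def coords(self) -> np.ndarray:
        """All-bin coordinates in global bin order."""
        out = np.empty((self.bins.n_bins, 3))
        for chrom, cfg in self.chrom_configs.items():
            out[self.bins.chrom_slice(chrom)] = cfg.coords
        return out

    def configuration(self) -> Configuration3D:
        return Configuration3D(self.coords(), np.arange(self.bins.n_bins))

    def to_frame(self) -> pd.DataFrame:
        frame = self.bins.to_frame().drop(columns="bin")
        frame[["x", "y", "z"]] = self.coords()
        return frame

    def write(self, outdir) -> None:
        """Write per-chromosome and whole-genome TSVs plus JSON metadata."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        frame.to_csv(outdir / "genome.tsv", sep="\t", index=False)
        for chrom in self.bins.chrom_names:
            sub = frame[frame["chrom"] == chrom]
            sub.to_csv(outdir / f"chrom_{chrom}.tsv", sep="\t", index=False)
        if self.coarse is not None:
            coarse = self.coarse.to_frame()
            coarse.to_csv(outdir / "coarse.tsv", sep="\t", index=False)
        meta = dict(self.metadata)
        meta["alphas"] = {
            c: {
                "alpha": rec.alpha.alpha,
                "bracket": list(rec.alpha.bracket),
                "achieved_stress": rec.alpha.achieved_stress,
                "n_evals": rec.alpha.n_evals,
            }
            for c, rec in self.stage1.items()
        }
        meta["transforms"] = {
            c: {
                "rotation": tr.rotation.tolist(),
                "scale": tr.scale,
                "translation": tr.translation.tolist(),
            }
            for c, tr in self.transforms.items()
        }
        if self.plan is not None:
            meta["plan"] = {
                "scheme": self.plan.scheme,
                "fraction": self.plan.fraction,
                "offset": self.plan.offset,
                "m_k": {c: self.plan.m_k(c) for c in self.plan.chroms},
            }
        with open(outdir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def reconstruct_chromosomes(
    contacts: ContactMap,
    stage1_cfg: MDSConfig | None = None,
    alpha_bracket: tuple[float, float] = (0.1, 3.0),
    alpha_tol: float = 1e-2,
    zero_mode: str = "pseudocount",
    seed: int = 0,
) -> dict[str, ChromReconstruction]:
    """Stage 1: per-chromosome power-law index estimation + 3D embedding."""
    if stage1_cfg is None:
        stage1_cfg = MDSConfig()
    recs: dict[str, ChromReconstruction] = {}
    chroms = contacts.bins.chrom_names
    seeds = _spawn_seeds(seed, len(chroms))
    for chrom, chrom_seed in zip(chroms, seeds):
        cfg = replace(stage1_cfg, seed=chrom_seed)
        freqs = contacts.block(chrom, chrom)
        est = estimate_alpha(
            freqs, cfg, bracket=alpha_bracket, tol=alpha_tol, zero_mode=zero_mode
        )
        D = freq_to_dist(freqs, est.alpha, zero_mode=zero_mode)
        result = solve_mds(D, cfg)
        labels = np.arange(contacts.bins.n_bins)[contacts.bins.chrom_slice(chrom)]
        config = Configuration3D(result.config.coords, labels)
        recs[chrom] = ChromReconstruction(chrom, config, est, result.stress)
    return recs


def position_genome(
    chrom_recs: dict[str, ChromReconstruction],
    contacts: ContactMap,
    stage2_cfg: MDSConfig | None = None,
    scheme: str = "equispaced",
    fraction: float = 0.1,
    offset: int = 0,
    zero_mode: str = "pseudocount",
    hybrid: bool = True,
    seed: int = 0,
) -> GenomeReconstruction:
    """Stage 2: sample, embed the hybrid matrix, and stitch chromosomes.

    The per-chromosome similarity fit allows reflection (each stage-1
    solution has arbitrary chirality) and rescaling.
    """
    bins = contacts.bins
    chroms = list(chrom_recs)
    metadata = {
        "scheme": scheme,
        "fraction": fraction,
        "offset": offset,
        "zero_mode": zero_mode,
        "hybrid": hybrid,
        "seed": seed,
        "stage2_weights": stage2_cfg.weight_scheme if stage2_cfg else "inverse",
    }

    if len(chroms) == 1:
        chrom = chroms[0]
        rec = chrom_recs[chrom]
        return GenomeReconstruction(
            bins,
            {chrom: rec.config},
            {chrom: SimilarityTransform.identity()},
            chrom_recs,
            None,
            None,
            metadata,
        )

    plan = build_plan(chrom_recs, scheme=scheme, fraction=fraction, offset=offset)
    for chrom in chroms:
        if plan.m_k(chrom) < 3:
            raise ValueError(
                f"chromosome {chrom!r} has only {plan.m_k(chrom)} sampled points; "
                "at least 3 are needed for a unique similarity fit "
                "(use a larger fraction)"
            )
    hybrid_dist = build_hybrid(
        chrom_recs, plan, contacts, zero_mode=zero_mode, hybrid=hybrid
    )
    if stage2_cfg is None:
        stage2_cfg = MDSConfig()
    if stage2_cfg.n_restarts is None:
        # random restarts guard against local minima, which matter most for
        # small sampled problems; above ~800 loci the classical init is
        # reliable and restarts are not worth their cost
        stage2_cfg = replace(stage2_cfg, n_restarts=5 if plan.m <= 800 else 0)
    cfg = replace(stage2_cfg, seed=_spawn_seeds(seed, 1)[0])
    stage2 = solve_mds(hybrid_dist.matrix, cfg)
    coarse = stage2.config

    chrom_configs: dict[str, Configuration3D] = {}
    transforms: dict[str, SimilarityTransform] = {}
    for chrom in chroms:
        rec = chrom_recs[chrom]
        source = _sampled_points(rec, plan)
        target = coarse.coords[hybrid_dist.block_slices[chrom]]
        tr = procrustes_fit(source, target, allow_scale=True, allow_reflection=True)
        transforms[chrom] = tr
        chrom_configs[chrom] = Configuration3D(
            tr.apply(rec.config.coords), rec.config.labels
        )
    metadata["stage2_stress"] = stage2.stress
    return GenomeReconstruction(
        bins, chrom_configs, transforms, chrom_recs, coarse, plan, metadata
    )


def reconstruct_genome(
    contacts: ContactMap,
    stage1_cfg: MDSConfig | None = None,
    stage2_cfg: MDSConfig | None = None,
    scheme: str = "equispaced",
    fraction: float = 0.1,
    offset: int = 0,
    zero_mode: str = "pseudocount",
    hybrid: bool = True,
    alpha_bracket: tuple[float, float] = (0.1, 3.0),
    alpha_tol: float = 1e-2,
    seed: int = 0,
) -> GenomeReconstruction:
    """Run the full two-stage pipeline on a contact map."""
    s1_seed, s2_seed = _spawn_seeds(seed, 2)
    recs = reconstruct_chromosomes(
        contacts,
        stage1_cfg,
        alpha_bracket=alpha_bracket,
        alpha_tol=alpha_tol,
        zero_mode=zero_mode,
        seed=s1_seed,
    )
    return position_genome(
        recs,
        contacts,
        stage2_cfg,
        scheme=scheme,
        fraction=fraction,
        offset=offset,
        zero_mode=zero_mode,
        hybrid=hybrid,
        seed=s2_seed,
    )


# ---------------------------------------------------------------------------
# cross-resolution thinning
# ---------------------------------------------------------------------------


def thin_to_resolution(
    fine: GenomeReconstruction, coarse_bins: GenomeBins
) -> tuple[Configuration3D, np.ndarray]:
    """Select fine-resolution points matching coarse bin starts.

    Returns the thinned configuration (one point per coarse bin, labelled
    by coarse global bin index) and the selected fine global indices, for
    Procrustes comparison against a coarse reconstruction.
    """
    fine_res = fine.bins.resolution
    coarse_res = coarse_bins.resolution
    if coarse_res % fine_res != 0:
        raise ValueError(
            f"fine resolution {fine_res} does not divide coarse resolution "
            f"{coarse_res}"
        )
    step = coarse_res // fine_res
    selected: list[int] = []
    for g in range(coarse_bins.n_bins):
        chrom, local = coarse_bins.to_local(g)
        fine_local = local * step
        if fine_local >= fine.bins.chrom_n_bins(chrom):
            raise ValueError(
                f"coarse bin {g} ({chrom}:{local}) has no matching fine bin"
            )
        selected.append(fine.bins.global_index(chrom, fine_local))
    selected_arr = np.asarray(selected)
    coords = fine.coords()[selected_arr]
    return Configuration3D(coords, np.arange(coarse_bins.n_bins)), selected_arr


def read_configuration(path) -> Configuration3D:
    """Read a whole-genome or per-chromosome configuration TSV."""
    frame = pd.read_csv(path, sep="\t")
    coords = frame[["x", "y", "z"]].to_numpy()
    return Configuration3D(coords, np.arange(len(frame)))
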