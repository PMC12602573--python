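"""Activation Likelihood Estimation: MA maps, union ALE, nulls, inference.

The engine follows the revised ALE algorithm. Each experiment's foci become
centers of 3-D Gaussian probability kernels whose width reflects spatial
uncertainty and shrinks with sample size (:mod:`cbmeta.kernels`); per-voxel
aggregation across the foci of one experiment takes the voxelwise maximum,
yielding a modeled activation (MA) map. The union across MA maps,
``ALE = 1 - prod(1 - MA_i)``, scores convergence at each voxel. Voxelwise
significance is judged against an analytic null that samples a voxel at
random from each MA map and takes the same union; cluster-level FWE is
controlled by comparing suprathreshold cluster sizes against the maximum
cluster size observed in simulated datasets of randomly distributed foci
with the same number of experiments, per-experiment sample sizes and foci
counts. Contrasts between two experiment pools use label-exchange
permutations of the pooled experiments; conjunctions use the minimum
statistic over cluster-corrected maps.

Null computation note: the union is additive on the scale
``L = -log(1 - ALE)``, so per-map histograms of L are combined by exact
convolution instead of pairwise union lattices; for the small MA values that
occur in practice, L ~ ALE and the default bin width (1e-5) keeps the
discretization error far below Monte-Carlo tolerances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve

from cbmeta.io import BrainGrid, Experiment, ExperimentSet
from cbmeta.kernels import KernelSpec, kernel_cube, kernel_sigma

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1e-5
MIN_EXPERIMENTS_GUIDELINE = 17


# --------------------------------------------------------------------------
# MA maps and ALE
# --------------------------------------------------------------------------

@dataclass
class MAMap:
    """Per-experiment modeled-activation probabilities on the grid."""

    values: np.ndarray
    grid: BrainGrid
    experiment: Experiment | None = None

    def in_mask(self) -> np.ndarray:
        return self.values[self.grid.mask]


def _connectivity_structure(connectivity: int = 26) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _place_kernels_max(out: np.ndarray, centers_ijk: np.ndarray,
                       cube: np.ndarray) -> None:
    """Voxelwise-max insertion of a kernel cube at each center (in place)."""
    shape = np.array(out.shape)
    radii = (np.array(cube.shape) - 1) // 2
    for ijk in centers_ijk:
        lo = ijk - radii
        hi = ijk + radii + 1
        cl = np.clip(lo, 0, shape)
        ch = np.clip(hi, 0, shape)
        if np.any(cl >= ch):
            continue
        ksl = tuple(slice(c - l, cube.shape[a] - (h - c2))
                    for a, (l, c, h, c2) in enumerate(zip(lo, cl, hi, ch)))
        vsl = tuple(slice(c, c2) for c, c2 in zip(cl, ch))
        np.maximum(out[vsl], cube[ksl], out=out[vsl])


def make_ma_map(exp: Experiment, grid: BrainGrid,
                spec: KernelSpec | None = None,
                additive: bool = False) -> MAMap:
    """Modeled-activation map for one experiment.

    Foci outside the grid bounding box are skipped with a warning. The
    default aggregation over an experiment's foci is the voxelwise maximum;
    ``additive=True`` sums kernel probabilities instead (clipped at 1), kept
    for comparison with the pre-revision algorithm.
    """
    if spec is None:
        spec = kernel_sigma(exp.n)
    cube = kernel_cube(spec, grid.voxel_sizes_mm, grid.voxel_volume_mm3)
    ijk = np.rint(grid.mm_to_voxel(exp.foci_array())).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.array(grid.shape)), axis=1)
    if not inside.all():
        warnings.warn(
            f"experiment {exp.experiment_id}: "
            f"{int((~inside).sum())} focus/foci outside grid bounding box; skipped"
        )
        logger.warning("skipped %d out-of-grid foci for %s",
                       int((~inside).sum()), exp.experiment_id)
        ijk = ijk[inside]
    values = np.zeros(grid.shape)
    if additive:
        radii = (np.array(cube.shape) - 1) // 2
        for c in ijk:
            lo, hi = c - radii, c + radii + 1
            cl, ch = np.clip(lo, 0, grid.shape), np.clip(hi, 0, grid.shape)
            if np.any(cl >= ch):
                continue
            ksl = tuple(slice(a - b, cube.shape[i] - (d - e))
                        for i, (b, a, d, e) in enumerate(zip(lo, cl, hi, ch)))
            vsl = tuple(slice(a, b) for a, b in zip(cl, ch))
            values[vsl] += cube[ksl]
        np.clip(values, 0.0, 1.0, out=values)
    else:
        _place_kernels_max(values, ijk, cube)
    values[~grid.mask] = 0.0
    return MAMap(values=values, grid=grid, experiment=exp)


def compute_ale(ma_maps: list[MAMap] | np.ndarray) -> np.ndarray:
    """Union ALE across MA maps: ``1 - prod_i (1 - MA_i)`` voxelwise."""
    if isinstance(ma_maps, np.ndarray):
        stack = ma_maps
    else:
        if not ma_maps:
            raise ValueError("need at least one MA map")
        shapes = {m.values.shape for m in ma_maps}
        if len(shapes) > 1:
            raise ValueError(f"MA maps on mismatched grids: {shapes}")
        stack = np.stack([m.values for m in ma_maps])
    return -np.expm1(np.log1p(-stack).sum(axis=0))


def _ma_matrix(experiments: list[Experiment], grid: BrainGrid) -> np.ndarray:
    """(n_experiments, n_in_mask_voxels) matrix of MA values."""
    return np.stack([make_ma_map(e, grid).in_mask() for e in experiments])


# --------------------------------------------------------------------------
# Analytic null and voxelwise p
# --------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Discretized null of the ALE union statistic.

    Binned on the ``L = -log(1 - ALE)`` axis with width ``bin_width``;
    ``pmf[i]`` is the probability of bin center ``i * bin_width`` and ``sf``
    the inclusive upper-tail ``P(ALE >= bin i)``.
    """

    bin_width: float
    pmf: np.ndarray
    sf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = self.pmf.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"null probabilities sum to {total}, not 1")
        sf = self.pmf[::-1].cumsum()[::-1]
        self.sf = np.minimum(sf / sf[0], 1.0)  # exact 1 at the zero bin

    def _index(self, ale: np.ndarray) -> np.ndarray:
        L = -np.log1p(-np.asarray(ale, dtype=float))
        idx = np.rint(L / self.bin_width).astype(int)
        above = idx >= len(self.pmf)
        if np.any(above):
            logger.info("%d ALE value(s) above null support; assigned smallest tail",
                        int(above.sum()))
        return np.clip(idx, 0, len(self.pmf) - 1)

    def p_of_ale(self, ale: np.ndarray) -> np.ndarray:
        """Upper-tail P(ALE_null >= ale); 1 at ale = 0."""
        p = self.sf[self._index(ale)]
        floor = self.sf[-1] if self.sf[-1] > 0 else np.finfo(float).tiny
        return np.clip(p, floor, 1.0)

    def ale_threshold(self, p: float) -> float:
        """Smallest ALE value whose upper-tail probability is below ``p``."""
        idx = np.argmax(self.sf < p)
        if self.sf[idx] >= p:  # never drops below p
            return np.inf
        return float(-np.expm1(-(idx - 0.5) * self.bin_width))


def _l_histogram(values: np.ndarray, bin_width: float) -> np.ndarray:
    L = -np.log1p(-values)
    idx = np.rint(L / bin_width).astype(int)
    return np.bincount(idx) / len(idx)


def analytic_null(ma_maps: list[MAMap] | np.ndarray,
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  mask: np.ndarray | None = None) -> NullDistribution:
    """Null of the ALE score under random spatial association.

    Conceptually: draw one in-mask voxel at random from each experiment's MA
    map and take the union of the drawn values. Computed exactly (up to
    discretization) by convolving the per-map histograms of
    ``-log(1 - MA)``, on which scale the union is additive.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(ma_maps, np.ndarray):
        rows = list(ma_maps)
    else:
        rows = [m.in_mask() if isinstance(m, MAMap) else np.asarray(m, float)
                for m in ma_maps]
        if rows and rows[0].size == 0:
            raise ValueError("empty mask")
    if not rows:
        raise ValueError("need at least one MA map")
    pmf = _l_histogram(rows[0], bin_width)
    for values in rows[1:]:
        h = _l_histogram(values, bin_width)
        if len(h) == 1 or len(pmf) == 1:  # point mass: plain outer shift
            pmf = np.convolve(pmf, h)
        else:
            pmf = fftconvolve(pmf, h)
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    return NullDistribution(bin_width=bin_width, pmf=pmf)


def ale_to_p(ale: np.ndarray, null: NullDistribution,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel upper-tail p of the ALE map under the analytic null."""
    p = null.p_of_ale(ale)
    if mask is not None:
        p = np.where(mask, p, 1.0)
    return p


# --------------------------------------------------------------------------
# Cluster-level FWE
# --------------------------------------------------------------------------

@dataclass
class ALEResult:
    """Main-effect ALE analysis: maps, null, and FWE-corrected clusters."""

    ale: np.ndarray
    p: np.ndarray
    cluster_table: pd.DataFrame
    thresholded: np.ndarray
    labels: np.ndarray
    null: NullDistribution
    ale_cluster_forming: float
    crit_size: float
    null_max_sizes: np.ndarray
    grid: BrainGrid
    experiments: list[Experiment]

    @property
    def significant_cluster_ids(self) -> list[int]:
        t = self.cluster_table
        return t.loc[t["significant"], "cluster_id"].tolist()


def simulate_max_cluster_sizes(foci_counts: list[int], ns: list[int],
                               grid: BrainGrid, ale_threshold: float,
                               n_sim: int, rng: np.random.Generator,
                               connectivity: int = 26) -> np.ndarray:
    """Max suprathreshold cluster size in datasets of randomly placed foci.

    Each simulated dataset matches the observed one in number of
    experiments, per-experiment sample size and foci count; foci are drawn
    uniformly over in-mask voxel centers.
    """
    structure = _connectivity_structure(connectivity)
    mask_ijk = np.array(np.nonzero(grid.mask)).T
    cubes = {n: kernel_cube(kernel_sigma(n), grid.voxel_sizes_mm,
                            grid.voxel_volume_mm3) for n in set(ns)}
    max_sizes = np.zeros(n_sim, dtype=int)
    for s in range(n_sim):
        log_one_minus = np.zeros(grid.shape)
        ma = np.empty(grid.shape)
        for n_foci, n_subj in zip(foci_counts, ns):
            ma.fill(0.0)
            idx = rng.integers(0, len(mask_ijk), size=n_foci)
            _place_kernels_max(ma, mask_ijk[idx], cubes[n_subj])
            log_one_minus += np.log1p(-ma)
        ale = -np.expm1(log_one_minus)
        supra = (ale >= ale_threshold) & grid.mask
        if supra.any():
            labels, n_lab = ndimage.label(supra, structure=structure)
            if n_lab:
                max_sizes[s] = int(np.bincount(labels.ravel())[1:].max())
    return max_sizes


def cluster_fwe(experiments: list[Experiment] | ExperimentSet,
                grid: BrainGrid | None = None,
                cluster_forming_p: float = 0.001,
                alpha: float = 0.05,
                n_sim: int = 10000,
                seed: int | np.random.Generator | None = None,
                connectivity: int = 26,
                bin_width: float = DEFAULT_BIN_WIDTH,
                min_experiments: int = MIN_EXPERIMENTS_GUIDELINE,
                null_max_sizes: np.ndarray | None = None) -> ALEResult:
    """Main-effect ALE with cluster-level family-wise-error correction.

    Voxels with analytic-null ``p < cluster_forming_p`` form clusters under
    26-connectivity (configurable); a cluster is significant if its size
    exceeds the ``1 - alpha`` quantile of the maximum cluster size over
    ``n_sim`` simulated random-foci datasets. A precomputed ``null_max_sizes``
    array may be supplied when several analyses share one generative
    configuration.
    """
    if isinstance(experiments, ExperimentSet):
        if grid is None:
            grid = experiments.grid
        experiments = list(experiments.experiments)
    if grid is None:
        raise ValueError("a grid is required")
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments")
    if len(experiments) < min_experiments:
        warnings.warn(
            f"only {len(experiments)} experiments; fewer than the "
            f"{min_experiments}-experiment guideline for stable ALE results"
        )
    if null_max_sizes is None and n_sim < 100:
        warnings.warn(f"n_sim={n_sim} is very low for cluster-level FWE")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ma_maps = [make_ma_map(e, grid) for e in experiments]
    ale = compute_ale(ma_maps)
    null = analytic_null(ma_maps, bin_width=bin_width)
    p = ale_to_p(ale, null, mask=grid.mask)
    ale_thresh = null.ale_threshold(cluster_forming_p)

    supra = (p < cluster_forming_p) & grid.mask
    structure = _connectivity_structure(connectivity)
    labels, n_clusters = ndimage.label(supra, structure=structure)

    if null_max_sizes is None:
        null_max_sizes = simulate_max_cluster_sizes(
            [len(e.foci) for e in experiments], [e.n for e in experiments],
            grid, ale_thresh, n_sim, rng, connectivity=connectivity,
        )
    null_max_sizes = np.asarray(null_max_sizes)
    # alpha = 1 reports every suprathreshold cluster
    crit_size = (-np.inf if alpha >= 1.0
                 else float(np.quantile(null_max_sizes, 1.0 - alpha)))

    rows = []
    for cid in range(1, n_clusters + 1):
        voxels = labels == cid
        size = int(voxels.sum())
        cluster_ale = np.where(voxels, ale, -np.inf)
        peak_idx = np.unravel_index(np.argmax(cluster_ale), ale.shape)
        peak_mm = grid.voxel_to_mm(np.array(peak_idx))[0]
        p_fwe = float((null_max_sizes >= size).mean())
        rows.append({
            "cluster_id": cid,
            "size": size,
            "peak_ale": float(ale[peak_idx]),
            "peak_x": peak_mm[0], "peak_y": peak_mm[1], "peak_z": peak_mm[2],
            "p_fwe": p_fwe,
            "significant": size > crit_size,
        })
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_ale", "peak_x", "peak_y",
                       "peak_z", "p_fwe", "significant"],
    ).sort_values("size", ascending=False, ignore_index=True)

    thresholded = np.zeros_like(ale)
    for cid in table.loc[table["significant"], "cluster_id"]:
        thresholded[labels == cid] = ale[labels == cid]
    logger.info("cluster FWE: %d suprathreshold clusters, %d significant "
                "(critical size %.1f voxels)", n_clusters,
                int(table["significant"].sum()), crit_size)
    return ALEResult(ale=ale, p=p, cluster_table=table, thresholded=thresholded,
                     labels=labels, null=null, ale_cluster_forming=ale_thresh,
                     crit_size=crit_size, null_max_sizes=null_max_sizes,
                     grid=grid, experiments=experiments)


# --------------------------------------------------------------------------
# Conjunctions and contrasts
# --------------------------------------------------------------------------

def _apply_extent(values: np.ndarray, extent: int,
                  connectivity: int = 26) -> np.ndarray:
    """Zero out connected components smaller than ``extent`` voxels."""
    structure = _connectivity_structure(connectivity)
    labels, n_lab = ndimage.label(values > 0, structure=structure)
    if n_lab == 0:
        return np.zeros_like(values)
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n_lab + 1, dtype=bool)
    keep[1:] = sizes[1:] >= extent
    return np.where(keep[labels], values, 0.0)


def conjunction(thresholded_maps: list[np.ndarray], extent: int = 25,
                connectivity: int = 26) -> np.ndarray:
    """Minimum-statistic conjunction of cluster-corrected maps.

    A voxel survives only if significant (nonzero) in every input map; the
    surviving value is the voxelwise minimum. Connected components smaller
    than ``extent`` voxels are removed as presumably incidental overlap.
    """
    if len(thresholded_maps) < 2:
        raise ValueError("conjunction needs at least 2 maps")
    shapes = {m.shape for m in thresholded_maps}
    if len(shapes) > 1:
        raise ValueError(f"maps on mismatched grids: {shapes}")
    stack = np.stack(thresholded_maps)
    minmap = stack.min(axis=0)
    minmap[np.any(stack <= 0, axis=0)] = 0.0
    return _apply_extent(minmap, extent, connectivity)


def contrast(setA: list[Experiment] | ExperimentSet,
             setB: list[Experiment] | ExperimentSet,
             grid: BrainGrid,
             thresholded_A: np.ndarray,
             thresholded_B: np.ndarray,
             n_perm: int = 25000,
             prob_threshold: float = 0.95,
             extent: int = 25,
             seed: int | np.random.Generator | None = None,
             connectivity: int = 26,
             min_perm: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Label-exchange permutation contrast between two experiment pools.

    The observed voxelwise difference of the two unthresholded ALE maps is
    compared to differences obtained by randomly splitting the pooled
    experiments into groups of the original sizes. The per-voxel posterior
    probability of a true difference is the proportion of permuted
    differences strictly below the observed one (ties count against the
    observed difference); voxels with probability above ``prob_threshold``
    survive, inclusively masked by the respective main effect, with an
    ``extent``-voxel cluster threshold. Returns the (A>B, B>A) maps holding
    the observed ALE difference at surviving voxels.
    """
    exps_a = list(setA.experiments) if isinstance(setA, ExperimentSet) else list(setA)
    exps_b = list(setB.experiments) if isinstance(setB, ExperimentSet) else list(setB)
    if not exps_a or not exps_b:
        raise ValueError("both experiment sets must be nonempty")
    if n_perm < min_perm:
        warnings.warn(f"n_perm={n_perm} below the configured floor of {min_perm}")

    # Canonical orientation: the permutation stream must not depend on which
    # set was passed first, so that contrast(B, A) is exactly the swap of
    # contrast(A, B) under the same seed.
    def _key(exps):
        return (len(exps), tuple(sorted((e.study_id, e.experiment_id) for e in exps)))

    if _key(exps_b) < _key(exps_a):
        map_b, map_a = contrast(exps_b, exps_a, grid, thresholded_B,
                                thresholded_A, n_perm=n_perm,
                                prob_threshold=prob_threshold, extent=extent,
                                seed=seed, connectivity=connectivity,
                                min_perm=min_perm)
        return map_a, map_b
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # only voxels inside either main effect can survive the inclusive mask
    analysis = ((thresholded_A > 0) | (thresholded_B > 0)) & grid.mask
    if not analysis.any():
        return np.zeros(grid.shape), np.zeros(grid.shape)
    vox = np.nonzero(analysis)

    pooled = exps_a + exps_b
    log1m = np.stack([np.log1p(-make_ma_map(e, grid).values[vox]) for e in pooled])
    n_a = len(exps_a)
    total = log1m.sum(axis=0)
    obs_a = -np.expm1(log1m[:n_a].sum(axis=0))
    obs_b = -np.expm1(total - log1m[:n_a].sum(axis=0))
    obs_diff = obs_a - obs_b

    lower_a = np.zeros(obs_diff.shape, dtype=np.int64)
    lower_b = np.zeros(obs_diff.shape, dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))[:n_a]
        sum_a = log1m[idx].sum(axis=0)
        diff = -np.expm1(sum_a) + np.expm1(total - sum_a)
        lower_a += diff < obs_diff
        lower_b += -diff < -obs_diff
    prob_a = lower_a / n_perm
    prob_b = lower_b / n_perm

    map_a = np.zeros(grid.shape)
    map_b = np.zeros(grid.shape)
    map_a[vox] = np.where((prob_a > prob_threshold) & (thresholded_A[vox] > 0),
                          obs_diff, 0.0)
    map_b[vox] = np.where((prob_b > prob_threshold) & (thresholded_B[vox] > 0),
                          -obs_diff, 0.0)
    map_a = _apply_extent(map_a, extent, connectivity)
    map_b = _apply_extent(map_b, extent, connectivity)
    return map_a, map_b


# --------------------------------------------------------------------------
# Contribution analysis
# --------------------------------------------------------------------------

def contribution(cluster_voxels: np.ndarray,
                 experiments: list[Experiment],
                 grid: BrainGrid,
                 ma_maps: list[MAMap] | None = None) -> pd.DataFrame:
    """Leave-one-experiment-out contribution to a cluster's summarized ALE.

    The summarized ALE is the sum of the union ALE over all cluster voxels;
    it is recomputed leaving each experiment out. Percent contribution is
    ``100 * (S_all - S_without) / S_all``; an experiment counts as
    contributing if removing it strictly decreases the summarized ALE.
    """
    cluster_voxels = np.asarray(cluster_voxels, dtype=bool)
    if not cluster_voxels.any():
        raise ValueError("empty cluster")
    vox = np.nonzero(cluster_voxels)
    if ma_maps is None:
        ma_maps = [make_ma_map(e, grid) for e in experiments]
    log1m = np.stack([np.log1p(-m.values[vox]) for m in ma_maps])
    total = log1m.sum(axis=0)
    s_all = float((-np.expm1(total)).sum())
    rows = []
    for i, exp in enumerate(experiments):
        s_without = float((-np.expm1(total - log1m[i])).sum())
        pct = 100.0 * (s_all - s_without) / s_all if s_all > 0 else 0.0
        rows.append({
            "experiment_id": exp.experiment_id,
            "study_id": exp.study_id,
            "s_with": s_all,
            "s_without": s_without,
            "percent_contribution": pct,
            "contributing": s_without < s_all,
        })
    return pd.DataFrame(rows)
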