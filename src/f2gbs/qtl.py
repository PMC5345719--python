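"""Single-QTL genome scan with multiple imputation.

Genotypes are drawn on a fixed-step cM grid from their conditional
distribution given the flanking observed markers under a no-interference
(Markov) model with Haldane recombination probabilities.  For every grid
point and draw a linear model ``trait ~ additive + dominance`` is fitted
(additive contrast -1/0/+1 for A/H/B, dominance indicator for H) and the
LOD is ``(n/2) log10(RSS0/RSS1)``; evidence over draws is combined as
``log10(mean(10^LOD))``.  Genome-wide significance comes from permuting the
phenotype vector, rescanning, and taking the (1-alpha) quantile of the
maximum LOD; credible intervals from normalizing 10^LOD to unit area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .linkage import inverse_haldane
from .model import ABHMatrix, GeneticMap

_LN10 = np.log(10.0)

# ordered two-gamete states (gamete1 allele, gamete2 allele); allele 0 comes
# from parent 1, allele 1 from parent 2
_STATES = [(0, 0), (0, 1), (1, 0), (1, 1)]
# genotype (0=A,1=H,2=B) of each ordered state
_STATE_GENO = np.array([0, 1, 1, 2])
# compatibility of observed genotype (rows A,H,B) with ordered states
_COMPAT = np.array([
    [1, 0, 0, 0],
    [0, 1, 1, 0],
    [0, 0, 0, 1],
], dtype=float)


@dataclass
class GenotypeDraws:
    """Multiple-imputation genotype draws on a cM grid.

    ``draws`` holds small-integer genotypes (0=A, 1=H, 2=B) with shape
    ``(n_individuals, n_positions, n_draws)``; ``grid_chrom``/``grid_cM``
    give the genome position of each column.
    """

    individuals: list[str]
    grid_chrom: np.ndarray
    grid_cM: np.ndarray
    draws: np.ndarray
    marker_col: dict[str, int] = field(default_factory=dict)  # marker id -> grid column

    @property
    def n_positions(self) -> int:
        return len(self.grid_cM)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[2]

    def chrom_slices(self) -> list[tuple[str, slice]]:
        out, start = [], 0
        for i in range(1, len(self.grid_chrom) + 1):
            if i == len(self.grid_chrom) or self.grid_chrom[i] != self.grid_chrom[start]:
                out.append((str(self.grid_chrom[start]), slice(start, i)))
                start = i
        return out


def _transition(c: np.ndarray) -> np.ndarray:
    """Per-gamete 2x2 transition matrices for recombination fractions c."""
    c = np.asarray(c, dtype=float)
    T = np.empty(c.shape + (2, 2))
    T[..., 0, 0] = T[..., 1, 1] = 1.0 - c
    T[..., 0, 1] = T[..., 1, 0] = c
    return T


def _pair_transition(c: np.ndarray) -> np.ndarray:
    """4x4 transition over ordered gamete pairs (independent gametes)."""
    T = _transition(c)
    A = np.empty(c.shape + (4, 4))
    for si, (a1, a2) in enumerate(_STATES):
        for sj, (b1, b2) in enumerate(_STATES):
            A[..., si, sj] = T[..., a1, b1] * T[..., a2, b2]
    return A


def conditional_genotype_draws(g: ABHMatrix, gmap: GeneticMap,
                               step_cM: float = 1.0, n_draws: int = 16,
                               seed: int | np.random.Generator = 0) -> GenotypeDraws:
    """Draw grid genotypes conditional on the flanking observed markers.

    The grid on each chromosome is the union of a fixed-step lattice from 0
    to the chromosome length and the marker positions themselves, so every
    marker lies on the grid.  At a grid point the conditional distribution
    given the nearest non-missing marker on each side follows from the
    4-state (phase-known) Markov chain over gamete pairs with Haldane
    recombination probabilities; a point with no flank on one side (or an
    individual with no called marker on the chromosome) falls back to the
    1:2:1 prior on that side.  A point coinciding with a called marker
    reproduces the observed genotype in every draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid_chrom_parts, grid_cm_parts = [], []
    chrom_marker_pos: dict[str, np.ndarray] = {}
    chrom_marker_cols: dict[str, np.ndarray] = {}
    marker_col: dict[str, int] = {}
    offset = 0
    id_to_col = {mid: j for j, mid in enumerate(g.marker_ids)}
    for chrom in gmap.chromosomes:
        ids = [mid for mid in gmap.marker_ids(chrom) if mid in id_to_col]
        pos = np.array([dict(gmap.chromosomes[chrom])[mid] for mid in ids])
        length = gmap.chrom_length(chrom)
        lattice = np.arange(0.0, length + step_cM / 2, step_cM)
        grid = np.unique(np.concatenate([lattice, pos]))
        grid_chrom_parts.append(np.full(len(grid), chrom, dtype=object))
        grid_cm_parts.append(grid)
        chrom_marker_pos[chrom] = pos
        chrom_marker_cols[chrom] = np.array([id_to_col[m] for m in ids], dtype=int)
        for mid, p in zip(ids, pos):
            marker_col[mid] = offset + int(np.searchsorted(grid, p))
        offset += len(grid)
    grid_chrom = np.concatenate(grid_chrom_parts)
    grid_cm = np.concatenate(grid_cm_parts)
    n_pos = len(grid_cm)
    draws = np.empty((g.n_individuals, n_pos, n_draws), dtype=np.int8)

    code_int = np.full(g.codes.shape, -1, dtype=np.int8)
    for c, v in (("A", 0), ("H", 1), ("B", 2)):
        code_int[g.codes == c] = v

    col = 0
    for chrom in gmap.chromosomes:
        pos = chrom_marker_pos[chrom]
        cols = chrom_marker_cols[chrom]
        grid = grid_cm_parts.pop(0)
        npts = len(grid)
        sl = slice(col, col + npts)
        obs_all = code_int[:, cols]  # (n_ind, n_markers_on_chrom)
        for i in range(g.n_individuals):
            obs = obs_all[i]
            called = obs >= 0
            mpos = pos[called]
            mgen = obs[called]
            probs = _conditional_probs(grid, mpos, mgen)
            u = rng.random((npts, n_draws))
            cum = np.cumsum(probs, axis=1)
            draws[i, sl, :] = (u[:, None, :] > cum[:, :, None]).sum(axis=1)
        col += npts
    return GenotypeDraws(
        individuals=list(g.individuals),
        grid_chrom=grid_chrom,
        grid_cM=grid_cm,
        draws=draws,
        marker_col=marker_col,
    )


def _conditional_probs(grid: np.ndarray, mpos: np.ndarray,
                       mgen: np.ndarray) -> np.ndarray:
    """(npts, 3) conditional genotype probabilities at each grid point."""
    npts = len(grid)
    if len(mpos) == 0:
        return np.tile([0.25, 0.5, 0.25], (npts, 1))
    right_idx = np.searchsorted(mpos, grid, side="left")
    left_idx = np.searchsorted(mpos, grid, side="right") - 1
    has_left = left_idx >= 0
    has_right = right_idx < len(mpos)
    d_left = np.where(has_left, grid - mpos[np.clip(left_idx, 0, None)], 0.0)
    d_right = np.where(has_right,
                       mpos[np.clip(right_idx, None, len(mpos) - 1)] - grid, 0.0)
    cL = inverse_haldane(d_left)
    cR = inverse_haldane(d_right)
    AL = _pair_transition(cL)   # (npts, 4, 4)
    AR = _pair_transition(cR)
    gl = np.where(has_left, mgen[np.clip(left_idx, 0, None)], 0)
    gr = np.where(has_right, mgen[np.clip(right_idx, None, len(mpos) - 1)], 0)
    uL = _COMPAT[gl]            # (npts, 4) indicator over ordered left states
    uR = _COMPAT[gr]
    left_term = np.einsum("ps,psa->pa", uL, AL)
    left_term = np.where(has_left[:, None], left_term, 0.5)  # prior per state
    right_term = np.einsum("pab,pb->pa", AR, uR)
    right_term = np.where(has_right[:, None], right_term, 1.0)
    state_post = left_term * right_term  # unnormalized, prior 1/4 cancels
    probs = np.zeros((npts, 3))
    for s, gidx in enumerate(_STATE_GENO):
        probs[:, gidx] += state_post[:, s]
    total = probs.sum(axis=1, keepdims=True)
    return probs / np.where(total > 0, total, 1.0)


# ---------------------------------------------------------------------------
# scanning

def _design_sums(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per (position, draw): X^T X (with intercept) and its pseudo-inverse.

    Design columns: 1, additive contrast (-1,0,1), dominance indicator.
    """
    n = draws.shape[0]
    xa = draws.astype(np.float64) - 1.0          # (n, P, D)
    xd = (draws == 1).astype(np.float64)
    sa = xa.sum(axis=0)
    sd = xd.sum(axis=0)
    saa = (xa * xa).sum(axis=0)
    sad = (xa * xd).sum(axis=0)
    P, D = sa.shape
    XtX = np.empty((P, D, 3, 3))
    XtX[..., 0, 0] = n
    XtX[..., 0, 1] = XtX[..., 1, 0] = sa
    XtX[..., 0, 2] = XtX[..., 2, 0] = sd
    XtX[..., 1, 1] = saa
    XtX[..., 1, 2] = XtX[..., 2, 1] = sad
    XtX[..., 2, 2] = sd
    return XtX, np.linalg.pinv(XtX)


def _xty(draws: np.ndarray, y: np.ndarray) -> np.ndarray:
    """X^T y per (position, draw): shape (P, D, 3[, n_pheno])."""
    xa = draws.astype(np.float64) - 1.0
    xd = (draws == 1).astype(np.float64)
    if y.ndim == 1:
        return np.stack([
            np.full(draws.shape[1:], y.sum()),
            np.einsum("npd,n->pd", xa, y),
            np.einsum("npd,n->pd", xd, y),
        ], axis=-1)
    return np.stack([
        np.broadcast_to(y.sum(axis=0), draws.shape[1:] + (y.shape[1],)),
        np.einsum("npd,nq->pdq", xa, y),
        np.einsum("npd,nq->pdq", xd, y),
    ], axis=-2)


def _combine_lods(lod_draws: np.ndarray, axis: int = -1) -> np.ndarray:
    """log10 of the mean over draws of 10^LOD."""
    k = lod_draws.shape[axis]
    return (logsumexp(lod_draws * _LN10, axis=axis) - np.log(k)) / _LN10


def scan_single_qtl(phenotype: np.ndarray, draws: GenotypeDraws) -> np.ndarray:
    """LOD profile over the grid, combined across imputation draws.

    Raises if the phenotype is constant (zero null residual variance).
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n != draws.draws.shape[0]:
        raise ValueError("phenotype length must match number of individuals")
    rss0 = float(np.sum((y - y.mean()) ** 2))
    if rss0 <= 0:
        raise ValueError("constant phenotype: null model has zero residual variance")
    XtX, XtXinv = _design_sums(draws.draws)
    xty = _xty(draws.draws, y)                       # (P, D, 3)
    beta = np.einsum("pdij,pdj->pdi", XtXinv, xty)
    yty = float(y @ y)
    rss1 = yty - np.einsum("pdi,pdi->pd", beta, xty)
    rss1 = np.maximum(rss1, 1e-12)
    lod_draws = (n / 2.0) * np.log10(rss0 / rss1)
    lod_draws = np.maximum(lod_draws, 0.0)
    return _combine_lods(lod_draws)


def permutation_threshold(phenotype: np.ndarray, draws: GenotypeDraws,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int | np.random.Generator = 0,
                          return_distribution: bool = False):
    """Genome-wide LOD threshold from phenotype permutations.

    Permutes the phenotype across individuals (genotypes, and therefore the
    genome's LD structure, stay fixed), rescans, and records the maximum
    LOD per permutation; the threshold is the (1 - alpha) empirical
    quantile of that null distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    Y = np.empty((n, n_perm))
    for p in range(n_perm):
        Y[:, p] = y[rng.permutation(n)]
    rss0 = np.sum((y - y.mean()) ** 2)  # permutation-invariant
    yty = float(y @ y)
    d = draws.draws
    P = d.shape[1]
    max_lod_draws = np.full((P, d.shape[2], n_perm), -np.inf)
    _, XtXinv = _design_sums(d)
    # block over positions to bound memory
    block = max(1, int(2e7 // (d.shape[2] * n_perm * 3)))
    for start in range(0, P, block):
        sl = slice(start, min(start + block, P))
        xty = _xty(d[:, sl, :], Y)                   # (b, D, 3, n_perm)
        beta = np.einsum("pdij,pdjq->pdiq", XtXinv[sl], xty)
        rss1 = yty - np.einsum("pdiq,pdiq->pdq", beta, xty)
        rss1 = np.maximum(rss1, 1e-12)
        max_lod_draws[sl] = np.maximum((n / 2.0) * np.log10(rss0 / rss1), 0.0)
    lod = _combine_lods(max_lod_draws, axis=1)       # (P, n_perm)
    max_lods = lod.max(axis=0)
    threshold = float(np.quantile(max_lods, 1.0 - alpha))
    if return_distribution:
        return threshold, max_lods
    return threshold


def bayes_credible_interval(grid_cM: np.ndarray, lod: np.ndarray,
                            prob: float = 0.95) -> tuple[float, float]:
    """Connected credible interval under the rescaled 10^LOD profile.

    The profile's 10^LOD is normalized to unit area (trapezoid rule) and
    the smallest connected interval containing the peak with at least
    ``prob`` of the area is grown outward from the peak, expanding toward
    the larger neighbouring value (both sides on ties); endpoints land on
    grid points.  A flat profile yields a centred interval covering
    ``prob`` of the chromosome.
    """
    grid = np.asarray(grid_cM, dtype=float)
    lod = np.asarray(lod, dtype=float)
    if len(grid) == 1:
        return float(grid[0]), float(grid[0])
    w = np.power(10.0, lod - lod.max())
    total = np.trapezoid(w, grid)
    if total <= 0:
        return float(grid[0]), float(grid[-1])
    peak_candidates = np.where(lod == lod.max())[0]
    p = int(peak_candidates[len(peak_candidates) // 2])
    i = j = p
    area = 0.0
    while area / total < prob and (i > 0 or j < len(grid) - 1):
        left_val = w[i - 1] if i > 0 else -np.inf
        right_val = w[j + 1] if j < len(grid) - 1 else -np.inf
        go_left = left_val >= right_val
        go_right = right_val >= left_val
        if go_left:
            area += 0.5 * (w[i - 1] + w[i]) * (grid[i] - grid[i - 1])
            i -= 1
        if go_right and area / total < prob or (go_right and not go_left):
            area += 0.5 * (w[j] + w[j + 1]) * (grid[j + 1] - grid[j])
            j += 1
    return float(grid[i]), float(grid[j])


def variance_explained(phenotype: np.ndarray, genotype: np.ndarray) -> float:
    """Percent phenotypic variance explained by the single-QTL model.

    100 * R^2 of ``trait ~ additive + dominance`` at the peak genotypes
    (integer codes 0/1/2 for A/H/B).
    """
    y = np.asarray(phenotype, dtype=float)
    gi = np.asarray(genotype)
    if gi.dtype.kind in "US":
        gi = np.array([{"A": 0, "H": 1, "B": 2}.get(c, -1) for c in gi])
    ok = gi >= 0
    y, gi = y[ok], gi[ok]
    xa = gi.astype(float) - 1.0
    xd = (gi == 1).astype(float)
    X = np.column_stack([np.ones(len(y)), xa, xd])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss <= 0:
        return 0.0
    return float(100.0 * (1.0 - np.sum(resid ** 2) / tss))


def qtl_effects(phenotype: np.ndarray, genotype: np.ndarray) -> tuple[float, float]:
    """Additive and dominance effects from genotype-class phenotype means.

    additive = (mean_B - mean_A)/2 (positive = parent-2 allele increases the
    trait); dominance = mean_H - (mean_A + mean_B)/2.  All three genotype
    classes must be present.
    """
    y = np.asarray(phenotype, dtype=float)
    gi = np.asarray(genotype)
    if gi.dtype.kind in "US":
        gi = np.array([{"A": 0, "H": 1, "B": 2}.get(c, -1) for c in gi])
    means = []
    for cls in (0, 1, 2):
        sel = gi == cls
        if not np.any(sel):
            raise ValueError(f"genotype class {'AHB'[cls]} absent at the peak")
        means.append(float(y[sel].mean()))
    mA, mH, mB = means
    return (mB - mA) / 2.0, mH - (mA + mB) / 2.0


# ---------------------------------------------------------------------------
# high-level scan

@dataclass
class QTLPeak:
    chromosome: str
    position_cM: float
    lod: float
    interval_cM: tuple[float, float]
    percent_variance: float
    additive_effect: float
    dominance_effect: float


@dataclass
class QTLScanResult:
    """LOD profile on the step grid plus genome-wide threshold and peaks."""

    grid_chrom: np.ndarray
    grid_cM: np.ndarray
    lod: np.ndarray
    threshold: float
    alpha: float
    peaks: list[QTLPeak]


def scan(g: ABHMatrix, gmap: GeneticMap, phenotype: dict[str, float] | np.ndarray,
         step_cM: float = 1.0, n_draws: int = 16, n_perm: int = 1000,
         alpha: float = 0.05, prob: float = 0.95,
         seed: int | np.random.Generator = 0) -> QTLScanResult:
    """Full single-QTL genome scan on an ABH matrix and its genetic map.

    ``phenotype`` is a dict (individual id -> value) or an array aligned
    with ``g.individuals``.  Peak effects and variance explained are
    computed from the observed genotypes at the marker nearest each peak.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(phenotype, dict):
        missing = [ind for ind in g.individuals if ind not in phenotype]
        if missing:
            raise ValueError(f"phenotype missing for individuals: {missing[:5]}...")
        y = np.array([phenotype[ind] for ind in g.individuals], dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    draws = conditional_genotype_draws(g, gmap, step_cM=step_cM,
                                       n_draws=n_draws, seed=rng)
    lod = scan_single_qtl(y, draws)
    threshold = permutation_threshold(y, draws, n_perm=n_perm, alpha=alpha, seed=rng)
    peaks = []
    for chrom, sl in draws.chrom_slices():
        clod = lod[sl]
        if clod.max() < threshold:
            continue
        k = int(np.argmax(clod))
        peak_cm = float(draws.grid_cM[sl][k])
        left, right = bayes_credible_interval(draws.grid_cM[sl], clod, prob=prob)
        geno = _nearest_marker_genotypes(g, gmap, chrom, peak_cm)
        try:
            add, dom = qtl_effects(y, geno)
        except ValueError:
            add = dom = float("nan")
        pve = variance_explained(y, geno)
        peaks.append(QTLPeak(
            chromosome=chrom, position_cM=peak_cm, lod=float(clod.max()),
            interval_cM=(left, right), percent_variance=pve,
            additive_effect=add, dominance_effect=dom,
        ))
    return QTLScanResult(
        grid_chrom=draws.grid_chrom, grid_cM=draws.grid_cM, lod=lod,
        threshold=threshold, alpha=alpha, peaks=peaks,
    )


def _nearest_marker_genotypes(g: ABHMatrix, gmap: GeneticMap, chrom: str,
                              cm: float) -> np.ndarray:
    id_to_col = {mid: j for j, mid in enumerate(g.marker_ids)}
    ids = [m for m in gmap.marker_ids(chrom) if m in id_to_col]
    pos = np.array([dict(gmap.chromosomes[chrom])[m] for m in ids])
    k = int(np.argmin(np.abs(pos - cm)))
    return g.codes[:, id_to_col[ids[k]]]
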