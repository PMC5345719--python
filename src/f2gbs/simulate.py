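"""F2 cross and GBS-noise simulator, plus the power-study driver.

The genetic model: each F2 individual carries two gametes per chromosome,
each the product of an independent meiosis.  Crossovers follow the
chi-square (gamma renewal) interference model: chiasma intermediates form a
Poisson process at rate ``2(m+1)`` per 100 cM along the bundle, every
``(m+1)``-th one (random phase) resolves as a chiasma, and each chiasma
involves a given chromatid with probability 1/2.  The expected crossover
count per gamete is length/100 for any ``m``; ``m = 0`` recovers the
no-interference Poisson model, while the default ``m = 10`` emulates the
strong positive interference of plant meiosis, under which close double
crossovers — the patterns the error-correction passes treat as errors —
are vanishingly rare.  The phenotype is the sum of QTL contributions
``a*x + d*1(het)`` with additive contrast x in {-1, 0, +1} for the
parent-1 homozygote / heterozygote / parent-2 homozygote, plus Gaussian
residual noise.

The GBS noise layer emulates the three error sources seen in real
reduced-representation data: random missing genotypes, depth-dependent
heterozygote undercalling (all reads at a true heterozygote sampled from
one allele, probability ``2*(1/2)^depth``), and a small set of
systematically error-prone markers whose calls flip with fixed rates
(heterozygote miscalled as a parent-2 homozygote, and a parent-1 homozygote
miscalled as heterozygote — the two co-occurring error types real data
shows at structurally divergent sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ABHMatrix, GeneticMap, Marker, SiteMatrix
from .qtl import scan as qtl_scan_full

# chromosome lengths (cM) of the rice microsatellite consensus map used as
# the simulation default; chromosomes 1-12
DEFAULT_CHR_LENGTHS_CM = (140.0, 115.0, 130.0, 110.0, 100.0, 105.0,
                          110.0, 100.0, 75.0, 80.0, 100.0, 105.0)

_INT_TO_CODE = np.array(["A", "H", "B"])


@dataclass(frozen=True)
class QTLSpec:
    """One simulated QTL: location plus additive and dominance effects."""

    chromosome: str
    position_cM: float
    additive: float
    dominance: float = 0.0


@dataclass
class F2SimConfig:
    """Simulation conditions for one F2 population."""

    chr_lengths_cM: tuple[float, ...] = DEFAULT_CHR_LENGTHS_CM
    n_markers: int = 400
    spacing: str = "equal"           # 'equal' (ends included) or 'random'
    n_individuals: int = 200
    qtl: tuple[QTLSpec, ...] = ()
    residual_sd: float = 1.0
    interference_m: int = 10         # chi-square model; 0 = Poisson crossovers
    seed: int = 0

    def __post_init__(self):
        if any(l <= 0 for l in self.chr_lengths_cM):
            raise ValueError("chromosome lengths must be positive")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.spacing not in ("equal", "random"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        names = {self.chrom_name(i) for i in range(len(self.chr_lengths_cM))}
        for q in self.qtl:
            if q.chromosome not in names:
                raise ValueError(f"QTL on unknown chromosome {q.chromosome!r}")
            idx = int(q.chromosome) - 1
            if not 0 <= q.position_cM <= self.chr_lengths_cM[idx]:
                raise ValueError(f"QTL position {q.position_cM} outside chromosome")

    @staticmethod
    def chrom_name(i: int) -> str:
        return str(i + 1)


@dataclass
class GBSNoiseConfig:
    """GBS-specific noise model applied to a clean ABH matrix.

    ``depth`` is the read depth model for heterozygote undercalling: a
    fixed integer, a mean for Poisson-distributed depths, or None for
    infinite depth (no undercalling).  ``error_flip_rates`` maps
    ``"X->Y"`` transitions to per-cell flip probabilities applied at the
    designated error-prone markers.
    """

    missing_rate: float = 0.0
    depth: int | float | None = None
    depth_model: str = "fixed"       # 'fixed' or 'poisson'
    error_marker_fraction: float = 0.0
    error_flip_rates: dict[str, float] = field(
        default_factory=lambda: {"H->B": 0.15, "A->H": 0.3})

    def __post_init__(self):
        for name, rate in [("missing_rate", self.missing_rate),
                           ("error_marker_fraction", self.error_marker_fraction),
                           *self.error_flip_rates.items()]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {name} must be in [0, 1], got {rate}")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth model {self.depth_model!r}")


def sim_map(config: F2SimConfig) -> GeneticMap:
    """Simulate a marker map over the configured chromosomes.

    Markers are allocated to chromosomes proportionally to length (at least
    2 per chromosome) and placed either equally spaced including both
    chromosome ends, or uniformly at random (then sorted, with the first
    marker defining 0 after shifting — random maps keep their absolute
    positions and simply start wherever the first draw lands).
    Deterministic given the config seed.
    """
    lengths = np.asarray(config.chr_lengths_cM, dtype=float)
    n_chrom = len(lengths)
    if config.n_markers < 2 * n_chrom:
        raise ValueError(
            f"need >= {2 * n_chrom} markers for {n_chrom} chromosomes")
    # largest-remainder allocation proportional to length, minimum 2
    raw = lengths / lengths.sum() * config.n_markers
    alloc = np.maximum(np.floor(raw).astype(int), 2)
    while alloc.sum() > config.n_markers:
        alloc[np.argmax(alloc)] -= 1
    rema = raw - np.floor(raw)
    while alloc.sum() < config.n_markers:
        k = int(np.argmax(np.where(rema > -1, rema, -np.inf)))
        alloc[k] += 1
        rema[k] = -1
    rng = np.random.default_rng(config.seed)
    chromosomes: dict[str, list[tuple[str, float]]] = {}
    for ci, (length, n_mark) in enumerate(zip(lengths, alloc)):
        chrom = config.chrom_name(ci)
        if config.spacing == "equal":
            pos = np.linspace(0.0, length, n_mark)
        else:
            pos = np.sort(rng.uniform(0.0, length, n_mark))
            pos -= pos[0]
        chromosomes[chrom] = [(f"c{chrom}m{k + 1}", float(p))
                              for k, p in enumerate(pos)]
    return GeneticMap(chromosomes=chromosomes)


def _crossover_positions(rng: np.random.Generator, length: float,
                         m: int) -> np.ndarray:
    """Crossover locations of one gamete under chi-square interference."""
    if m == 0:
        n_xo = rng.poisson(length / 100.0)
        return np.sort(rng.uniform(0.0, length, n_xo))
    n_ev = rng.poisson(2.0 * (m + 1) * length / 100.0)
    events = np.sort(rng.uniform(0.0, length, n_ev))
    phase = rng.integers(0, m + 1)
    chiasmata = events[phase::m + 1]
    keep = rng.random(len(chiasmata)) < 0.5  # no chromatid interference
    return chiasmata[keep]


def _sim_gamete_genotypes(rng: np.random.Generator, length: float,
                          positions: np.ndarray, m: int = 0) -> np.ndarray:
    """Alleles (0/1) of one gamete at the given positions."""
    start = rng.integers(0, 2)
    xo = _crossover_positions(rng, length, m)
    if len(xo) == 0:
        return np.full(len(positions), start, dtype=np.int8)
    crossings = np.searchsorted(xo, positions, side="right")
    return ((start + crossings) % 2).astype(np.int8)


def sim_f2(gmap: GeneticMap, config: F2SimConfig,
           rng: np.random.Generator | None = None
           ) -> tuple[ABHMatrix, np.ndarray, pd.DataFrame]:
    """Simulate an F2 population on a genetic map.

    Returns the ABH genotype matrix (positions in cM), the phenotype
    vector, and a frame of true genotypes at the QTL positions
    (columns named ``<chrom>@<cM>``, integer codes 0/1/2).
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_individuals
    chroms = list(gmap.chromosomes)
    qtl_by_chrom: dict[str, list[QTLSpec]] = {c: [] for c in chroms}
    for q in config.qtl:
        qtl_by_chrom[q.chromosome].append(q)
    marker_ids, chrom_labels, cm_positions = [], [], []
    geno_parts = []
    qtl_geno: dict[str, np.ndarray] = {}
    for chrom in chroms:
        mpos = gmap.positions(chrom)
        qpos = np.array([q.position_cM for q in qtl_by_chrom[chrom]])
        allpos = np.concatenate([mpos, qpos])
        length = max(gmap.chrom_length(chrom), float(allpos.max()) if allpos.size else 0.0)
        geno = np.empty((n, len(allpos)), dtype=np.int8)
        for i in range(n):
            g1 = _sim_gamete_genotypes(rng, length, allpos, config.interference_m)
            g2 = _sim_gamete_genotypes(rng, length, allpos, config.interference_m)
            geno[i] = g1 + g2
        geno_parts.append(geno[:, :len(mpos)])
        for k, q in enumerate(qtl_by_chrom[chrom]):
            qtl_geno[f"{chrom}@{q.position_cM:g}"] = geno[:, len(mpos) + k].copy()
        marker_ids.extend(gmap.marker_ids(chrom))
        chrom_labels.extend([chrom] * len(mpos))
        cm_positions.extend(mpos.tolist())
    genotypes = np.concatenate(geno_parts, axis=1)  # 0=A,1=H,2=B
    phenotype = rng.normal(0.0, config.residual_sd, n)
    for q in config.qtl:
        x = qtl_geno[f"{q.chromosome}@{q.position_cM:g}"].astype(float) - 1.0
        phenotype += q.additive * x + q.dominance * (x == 0.0)
    abh = ABHMatrix(
        individuals=[f"F2_{i + 1:04d}" for i in range(n)],
        marker_ids=marker_ids,
        chromosomes=np.array(chrom_labels),
        positions=np.array(cm_positions, dtype=float),
        codes=_INT_TO_CODE[genotypes],
        units="cM",
    )
    true_qtl = pd.DataFrame(qtl_geno, index=abh.individuals)
    return abh, phenotype, true_qtl


def apply_gbs_noise(g: ABHMatrix, noise: GBSNoiseConfig,
                    seed: int | np.random.Generator = 0) -> ABHMatrix:
    """Overlay missingness, heterozygote undercalling, and marker errors.

    Cells are independently set to missing at ``missing_rate``.  Remaining
    heterozygous cells receive a read depth from the depth model and are
    undercalled (replaced by A or B with equal odds) with probability
    ``2*(1/2)^depth``.  A random fraction of markers is designated
    error-prone: their cells flip according to ``error_flip_rates``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = g.copy()
    codes = out.codes
    shape = codes.shape
    # systematic errors at designated markers first (they act at the
    # genotype-calling stage, before depth-driven undercalling of what
    # remains heterozygous)
    n_err = int(round(noise.error_marker_fraction * g.n_markers))
    error_markers = rng.choice(g.n_markers, size=n_err, replace=False) \
        if n_err else np.array([], dtype=int)
    for transition, rate in noise.error_flip_rates.items():
        if rate == 0 or n_err == 0:
            continue
        src, dst = transition.split("->")
        sub = codes[:, error_markers]
        flip = (sub == src) & (rng.random(sub.shape) < rate)
        sub[flip] = dst
        codes[:, error_markers] = sub
    # depth-dependent heterozygote undercalling
    if noise.depth is not None:
        het = codes == "H"
        n_het = int(het.sum())
        if noise.depth_model == "fixed":
            depths = np.full(n_het, int(noise.depth))
        else:
            depths = rng.poisson(float(noise.depth), n_het)
        p_uc = 2.0 * 0.5 ** np.maximum(depths, 1)
        p_uc[depths == 0] = 1.0  # zero reads: the call cannot be heterozygous
        undercalled = rng.random(n_het) < p_uc
        to = np.where(rng.random(n_het) < 0.5, "A", "B")
        new = np.where(undercalled, to, "H")
        codes[het] = new
    # random missingness
    if noise.missing_rate > 0:
        codes[rng.random(shape) < noise.missing_rate] = "N"
    out.error_marker_indices = np.sort(error_markers)  # for diagnostics
    return out


def inject_genotype_errors(g: ABHMatrix, error_rate: float,
                           seed: int | np.random.Generator = 0) -> ABHMatrix:
    """Flip a fraction of called cells to a uniformly chosen different code."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = g.copy()
    codes = out.codes
    called = codes != "N"
    flip = called & (rng.random(codes.shape) < error_rate)
    idx = np.flatnonzero(flip.ravel())
    flat = codes.ravel()
    for pos in idx:
        others = [c for c in "ABH" if c != flat[pos]]
        flat[pos] = others[rng.integers(0, len(others))]
    out.codes = flat.reshape(codes.shape)
    return out


# ---------------------------------------------------------------------------
# simulated SiteMatrix (nucleotide-level fixture for the filtering stage)

def sim_site_matrix(g: ABHMatrix, rng: np.random.Generator | None = None,
                    mean_depth: float = 30.0, n_parent_reps: int = 3,
                    bp_per_cM: float = 260_000.0) -> SiteMatrix:
    """Dress an ABH matrix up as nucleotide-level calls with read depths.

    Parent-1 sites are all given G/T alleles (parent 1 = G); triplicate
    homozygous parental samples are prepended.  Heterozygote allele depths
    are split binomially from a Poisson total; homozygote depths go to one
    allele.  Positions are converted to bp at ``bp_per_cM`` when the input
    is on the genetic scale.  Intended as a synthetic front-end fixture for
    the filtering stage.
    """
    rng = rng or np.random.default_rng(0)
    n_sites = g.n_markers
    if g.units == "cM":
        positions = np.round(g.positions * bp_per_cM).astype(int) + 1
    else:
        positions = g.positions.astype(int)
    markers = [Marker(mid, str(c), int(p), "G", "T")
               for mid, c, p in zip(g.marker_ids, g.chromosomes, positions)]
    sample_ids = ([f"P1_rep{i + 1}" for i in range(n_parent_reps)]
                  + [f"P2_rep{i + 1}" for i in range(n_parent_reps)]
                  + list(g.individuals))
    roles = (["parent1_rep"] * n_parent_reps + ["parent2_rep"] * n_parent_reps
             + ["f2"] * g.n_individuals)
    n_samples = len(sample_ids)
    a1 = np.empty((n_sites, n_samples), dtype="U1")
    a2 = np.empty((n_sites, n_samples), dtype="U1")
    a1[:, :n_parent_reps] = "G"
    a2[:, :n_parent_reps] = "G"
    a1[:, n_parent_reps:2 * n_parent_reps] = "T"
    a2[:, n_parent_reps:2 * n_parent_reps] = "T"
    code_map1 = {"A": "G", "B": "T", "H": "G", "N": ""}
    code_map2 = {"A": "G", "B": "T", "H": "T", "N": ""}
    codesT = g.codes.T
    for code, al in code_map1.items():
        a1[:, 2 * n_parent_reps:][codesT == code] = al
    for code, al in code_map2.items():
        a2[:, 2 * n_parent_reps:][codesT == code] = al
    total = rng.poisson(mean_depth, (n_sites, n_samples)).astype(int)
    total = np.maximum(total, 7)
    dref = np.zeros_like(total)
    dalt = np.zeros_like(total)
    is_ref_hom = (a1 == "G") & (a2 == "G")
    is_alt_hom = (a1 == "T") & (a2 == "T")
    is_het = (a1 != "") & (a1 != a2)
    dref[is_ref_hom] = total[is_ref_hom]
    dalt[is_alt_hom] = total[is_alt_hom]
    het_tot = total[is_het]
    het_ref = rng.binomial(het_tot, 0.5)
    dref[is_het] = het_ref
    dalt[is_het] = het_tot - het_ref
    return SiteMatrix(
        markers=markers, sample_ids=sample_ids, roles=roles,
        allele1=a1, allele2=a2, depth_ref=dref, depth_alt=dalt,
    ).sorted_by_position()


# ---------------------------------------------------------------------------
# power study

def power_experiment(config: F2SimConfig, n_grid, marker_grid,
                     reps: int = 100, window_cM: float = 10.0,
                     alpha: float = 0.05, n_perm: int = 200,
                     n_draws: int = 8, step_cM: float = 2.0,
                     noise: GBSNoiseConfig | None = None,
                     postprocess_data: bool = False,
                     seed: int | None = None) -> pd.DataFrame:
    """Detection power over a grid of population and marker-count sizes.

    For every (n individuals, n markers) cell: simulate ``reps``
    populations, run the single-QTL scan with permutation thresholds, and
    count a QTL as detected when some scan position within ``window_cM``
    of its true location reaches the genome-wide threshold.  Reports
    per-QTL power and the probability that all QTL are detected at once.
    The permutation count defaults to 200 to keep desk-scale runs short;
    raise it to 1000 for final results.
    """
    from .abh import postprocess as abh_postprocess

    base_seed = config.seed if seed is None else seed
    rows = []
    root = np.random.default_rng(base_seed)
    for n_ind in n_grid:
        for n_mark in marker_grid:
            cfg = F2SimConfig(
                chr_lengths_cM=config.chr_lengths_cM, n_markers=n_mark,
                spacing=config.spacing, n_individuals=n_ind, qtl=config.qtl,
                residual_sd=config.residual_sd, seed=base_seed,
            )
            gmap = sim_map(cfg)
            per_qtl = np.zeros(len(cfg.qtl))
            all_hits = 0
            for rep in range(reps):
                rng = np.random.default_rng(root.integers(2 ** 31))
                g, y, _ = sim_f2(gmap, cfg, rng)
                if noise is not None:
                    g = apply_gbs_noise(g, noise, rng)
                if postprocess_data:
                    g, _ = abh_postprocess(g)
                result = qtl_scan_full(g, gmap, y, step_cM=step_cM,
                                       n_draws=n_draws, n_perm=n_perm,
                                       alpha=alpha, seed=rng)
                hits = _detected_qtl(result, cfg.qtl, window_cM)
                per_qtl += hits
                all_hits += int(hits.all())
            row = {"n_individuals": n_ind, "n_markers": n_mark,
                   "prob_all_detected": all_hits / reps}
            for qi, q in enumerate(cfg.qtl):
                row[f"power_qtl_{q.chromosome}@{q.position_cM:g}"] = per_qtl[qi] / reps
            rows.append(row)
    return pd.DataFrame(rows)


def _detected_qtl(result, qtl: tuple[QTLSpec, ...],
                  window_cM: float) -> np.ndarray:
    hits = np.zeros(len(qtl), dtype=bool)
    for qi, q in enumerate(qtl):
        on_chrom = result.grid_chrom == q.chromosome
        near = on_chrom & (np.abs(result.grid_cM - q.position_cM) <= window_cM)
        if np.any(near) and result.lod[near].max() >= result.threshold:
            hits[qi] = True
    return hits
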