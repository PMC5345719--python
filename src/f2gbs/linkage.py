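"""Recombination-fraction estimation and genetic-map construction.

Two-point maximum likelihood for an F2 intercross: the 3x3 table of joint
genotypes at two markers has class probabilities determined by the
recombination fraction r; the double-heterozygote class is a mixture of the
two phase configurations (0 or 2 recombinant gametes).  The MLE is found by
EM on the expected number of recombinant gametes.  Maps are built by
chaining adjacent-pair estimates along each chromosome in physical order
and accumulating distances through a map function (Haldane by default,
Kosambi available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import ABHMatrix, GeneticMap

_R_CAP = 0.4999  # keep map-function transforms finite

_CODE_TO_INT = {"A": 0, "H": 1, "B": 2}


# ---------------------------------------------------------------------------
# map functions

def haldane_cm(r: float) -> float:
    """Haldane map distance in cM: d = -50 ln(1 - 2r).  No interference."""
    r = np.minimum(r, _R_CAP)
    return -50.0 * np.log(1.0 - 2.0 * r)


def inverse_haldane(cm: float) -> float:
    """Recombination fraction for a Haldane distance: r = (1 - e^(-2d/100))/2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(cm, dtype=float) / 100.0))


def kosambi_cm(r: float) -> float:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r))."""
    r = np.minimum(r, _R_CAP)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def inverse_kosambi(cm: float) -> float:
    """Recombination fraction for a Kosambi distance: r = tanh(2d/100)/2."""
    return 0.5 * np.tanh(2.0 * np.asarray(cm, dtype=float) / 100.0)


MAP_FUNCTIONS = {
    "haldane": (haldane_cm, inverse_haldane),
    "kosambi": (kosambi_cm, inverse_kosambi),
}


def recombination_density(map_length_cM: float, physical_length_Mb: float) -> float:
    """Genome-average recombination density in cM/Mb."""
    return map_length_cM / physical_length_Mb


def double_crossover_risk(map_length_cM: float, physical_length_Mb: float,
                          window_Mb: float = 1.0) -> float:
    """Probability of a double crossover within a physical window.

    The per-window recombination probability is the genome-average density
    times the window size, expressed as a fraction (cM/100); two independent
    crossovers in the same window then occur with the square of that.  This
    bounds how often flank-based imputation silently skips a real double
    recombinant.
    """
    per_window = recombination_density(map_length_cM, physical_length_Mb) \
        * window_Mb / 100.0
    return per_window ** 2


# ---------------------------------------------------------------------------
# two-point EM

@dataclass
class RFEstimate:
    """Maximum-likelihood recombination fraction between two markers."""

    r_hat: float
    n_informative: int
    log_likelihood: float


def _joint_probs(r: float) -> np.ndarray:
    """3x3 F2 joint genotype probabilities, rows/cols indexed A,H,B."""
    s = 1.0 - r
    return np.array([
        [s * s / 4, r * s / 2, r * r / 4],
        [r * s / 2, (s * s + r * r) / 2, r * s / 2],
        [r * r / 4, r * s / 2, s * s / 4],
    ])


def pair_counts(col_i: np.ndarray, col_j: np.ndarray) -> np.ndarray:
    """3x3 table of joint A/H/B counts over individuals called at both markers."""
    ok = (col_i != "N") & (col_j != "N")
    gi = np.array([_CODE_TO_INT[c] for c in col_i[ok]], dtype=int)
    gj = np.array([_CODE_TO_INT[c] for c in col_j[ok]], dtype=int)
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (gi, gj), 1)
    return counts


# recombinant gametes (out of 2) implied by each genotype pair; the double
# heterozygote (None) is phase-ambiguous and handled in the E-step
_N_REC = np.array([
    [0.0, 1.0, 2.0],
    [1.0, np.nan, 1.0],
    [2.0, 1.0, 0.0],
])


def estimate_rf_em(col_i, col_j, tol: float = 1e-8,
                   max_iter: int = 1000) -> RFEstimate:
    """EM estimate of the recombination fraction from two ABH columns.

    E-step: the expected recombinant-gamete count of a double heterozygote
    is ``2 r^2 / (r^2 + (1-r)^2)``; every other class has a fixed count.
    M-step: r = expected recombinants / (2n).  Iterated to ``|dr| < tol``
    and clipped to [0, 0.5].
    """
    counts = pair_counts(np.asarray(col_i), np.asarray(col_j))
    return estimate_rf_from_counts(counts, tol=tol, max_iter=max_iter)


def estimate_rf_from_counts(counts: np.ndarray, tol: float = 1e-8,
                            max_iter: int = 1000) -> RFEstimate:
    """EM recombination-fraction estimate from a 3x3 joint genotype table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 individuals informative at both markers")
    r = 0.25
    for _ in range(max_iter):
        hh = 2.0 * r * r / (r * r + (1.0 - r) ** 2) if 0 < r else 0.0
        nrec = np.where(np.isnan(_N_REC), hh, _N_REC)
        r_new = float((counts * nrec).sum() / (2.0 * n))
        r_new = min(max(r_new, 0.0), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    probs = _joint_probs(min(r, _R_CAP))
    with np.errstate(divide="ignore"):
        ll = float(np.sum(counts * np.log(np.where(probs > 0, probs, 1))))
    return RFEstimate(r_hat=r, n_informative=int(n), log_likelihood=ll)


def rf_log_likelihood(counts: np.ndarray, r: float) -> float:
    """F2 two-point log-likelihood of a 3x3 genotype table at a given r."""
    probs = _joint_probs(r)
    with np.errstate(divide="ignore"):
        lp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1)), -np.inf)
    masked = np.where(counts > 0, lp, 0.0)
    if np.any((counts > 0) & np.isneginf(lp)):
        return -np.inf
    return float(np.sum(counts * masked))


def estimate_map(g: ABHMatrix, map_function: str = "haldane") -> GeneticMap:
    """Chain adjacent-pair recombination fractions into a genetic map.

    Markers must be in physical order within chromosomes (the ABH matrix
    invariant guarantees it).  Each adjacent estimate is capped just below
    0.5 before the map-function transform so distances stay finite.
    Chromosomes with fewer than 2 markers come out with zero length.
    """
    forward, _ = MAP_FUNCTIONS[map_function]
    chrom_entries: dict[str, list[tuple[str, float]]] = {}
    for chrom, sl in g.chrom_blocks():
        ids = g.marker_ids[sl.start:sl.stop]
        entries = [(ids[0], 0.0)]
        if len(ids) < 2:
            warnings.warn(f"chromosome {chrom} has <2 markers; zero-length")
        pos = 0.0
        for k in range(sl.start + 1, sl.stop):
            est = estimate_rf_em(g.codes[:, k - 1], g.codes[:, k])
            pos += float(forward(min(est.r_hat, _R_CAP)))
            entries.append((g.marker_ids[k], pos))
        chrom_entries[chrom] = entries
    return GeneticMap(chromosomes=chrom_entries)
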