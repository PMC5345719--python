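"""Error-motif census and genotype summary statistics.

A three-marker window ``x y x`` with equal outer genotypes and a different
centre (all of A/B/H; windows containing N are ignored) flags the centre
call as a likely error: in an F2, a genuine x-y-x pattern needs a double
crossover within the window.  The six possible motifs are HAH, HBH, AHA,
BHB, ABA, and BAB.  Counting is done on imputed but *uncorrected* data —
after correction the patterns are gone by construction.  Overlapping
windows are all counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .model import ABHMatrix

MOTIFS = ("HAH", "HBH", "AHA", "BHB", "ABA", "BAB")


@dataclass
class ErrorMotifCounts:
    """Motif counts aggregated per marker and per individual."""

    per_marker: pd.DataFrame      # index marker id, columns MOTIFS
    per_individual: pd.DataFrame  # index individual id, columns MOTIFS

    def totals(self) -> pd.Series:
        return self.per_marker.sum(axis=0)


def count_motifs(g: ABHMatrix) -> ErrorMotifCounts:
    """Census of x-y-x windows along every individual and chromosome.

    Each window ``x y x`` (x != y, both called genotypes) increments motif
    ``xyx`` for the *centre* marker and for the individual.
    """
    per_marker = np.zeros((g.n_markers, len(MOTIFS)), dtype=int)
    per_ind = np.zeros((g.n_individuals, len(MOTIFS)), dtype=int)
    motif_idx = {m: k for k, m in enumerate(MOTIFS)}
    codes = g.codes
    for _, sl in g.chrom_blocks():
        block = codes[:, sl]
        if block.shape[1] < 3:
            continue
        left, centre, right = block[:, :-2], block[:, 1:-1], block[:, 2:]
        valid = (left == right) & (left != centre) \
            & (left != "N") & (centre != "N")
        for m, k in motif_idx.items():
            hit = valid & (left == m[0]) & (centre == m[1])
            per_marker[sl.start + 1:sl.stop - 1, k] += hit.sum(axis=0)
            per_ind[:, k] += hit.sum(axis=1)
    return ErrorMotifCounts(
        per_marker=pd.DataFrame(per_marker, index=g.marker_ids, columns=list(MOTIFS)),
        per_individual=pd.DataFrame(per_ind, index=g.individuals, columns=list(MOTIFS)),
    )


def genotype_composition(g: ABHMatrix) -> tuple[dict[str, float], pd.DataFrame]:
    """Global and per-marker fractions of A, B, H, N (each row sums to 1)."""
    per_marker = pd.DataFrame(
        {c: (g.codes == c).mean(axis=0) for c in "ABHN"},
        index=g.marker_ids,
    )
    return g.composition(), per_marker


def allele_frequency_profile(g: ABHMatrix) -> pd.DataFrame:
    """Per-marker A/H/B frequencies and a chi-square test against 1:2:1.

    Missing genotypes are excluded from the denominators.  The returned
    frame has columns ``freq_A/freq_H/freq_B`` (NaN when a marker is all
    missing), the 2-df chi-square statistic against the Mendelian 1:2:1
    expectation, and its p-value.  The chi-square column is a convenience
    statistic for spotting segregation distortion.
    """
    nA = (g.codes == "A").sum(axis=0).astype(float)
    nH = (g.codes == "H").sum(axis=0).astype(float)
    nB = (g.codes == "B").sum(axis=0).astype(float)
    n = nA + nH + nB
    with np.errstate(invalid="ignore", divide="ignore"):
        fA, fH, fB = nA / n, nH / n, nB / n
        exp = np.stack([n / 4, n / 2, n / 4])
        obs = np.stack([nA, nH, nB])
        chi2 = np.where(n > 0, np.sum((obs - exp) ** 2 / np.where(exp > 0, exp, 1),
                                      axis=0), np.nan)
    nan = n == 0
    for arr in (fA, fH, fB):
        arr[nan] = np.nan
    pval = sstats.chi2.sf(chi2, df=2)
    return pd.DataFrame(
        {"n_called": n.astype(int), "freq_A": fA, "freq_H": fH, "freq_B": fB,
         "chi2_121": chi2, "p_value": pval},
        index=g.marker_ids,
    )


def marker_density(chromosomes: np.ndarray, positions_bp: np.ndarray,
                   bin_bp: int = 1_000_000,
                   chrom_lengths: dict[str, int] | None = None
                   ) -> dict[str, np.ndarray]:
    """Marker counts in half-open physical bins [k*bin, (k+1)*bin) per chromosome.

    ``chrom_lengths`` forces the bin vector of a chromosome to cover the
    stated length even when its right end carries no markers (and allows
    empty chromosomes to appear with all-zero bins).
    """
    chromosomes = np.asarray(chromosomes)
    positions_bp = np.asarray(positions_bp)
    out: dict[str, np.ndarray] = {}
    chroms = list(dict.fromkeys(chromosomes.tolist()))
    if chrom_lengths:
        for c in chrom_lengths:
            if c not in chroms:
                chroms.append(c)
    for chrom in chroms:
        pos = positions_bp[chromosomes == chrom]
        length = None if chrom_lengths is None else chrom_lengths.get(chrom)
        top = max(int(pos.max()) if pos.size else 0, length or 0)
        n_bins = max(top // bin_bp + 1, 1)
        counts = np.zeros(n_bins, dtype=int)
        if pos.size:
            idx = pos // bin_bp
            np.add.at(counts, idx.astype(int), 1)
        out[str(chrom)] = counts
    return out
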