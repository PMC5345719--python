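"""ABH encoding, imputation, error correction, and population merging.

The error model these passes address is specific to low-coverage GBS of an
F2 population: genotypes are laid out along chromosomes in long parental
haplotype blocks, so an isolated genotype that disagrees with both of its
neighbours is far more likely to be a calling error (most prominently an
undercalled heterozygote) than a genuine double crossover.  Three passes are
applied, always in the same order:

1. ``impute_flanked_missing`` — fill runs of missing genotypes whose two
   nearest non-missing neighbours agree (any run length);
2. ``correct_undercalled_het`` — a run of homozygous/missing genotypes of
   length <= 4 flanked by heterozygotes on both sides becomes heterozygous;
3. ``correct_short_stretches`` — a single genotype disagreeing with two
   equal neighbours is replaced by the neighbouring value.

Each pass computes its maximal runs from its *input* row, never from the
partially rewritten one, so results do not depend on scan direction.
Chromosomes are processed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .model import ABHMatrix, SiteMatrix, ValidationError


@dataclass
class CorrectionParams:
    """Tunables of the correction passes.

    ``het_run_max``: longest homozygous/missing run replaced when flanked by
    heterozygotes (default 4).  ``stretch_run_max``: longest run replaced
    when both neighbours agree with each other (default 1, i.e. singletons).
    The application order impute -> het-correct -> stretch-correct is fixed.
    """

    het_run_max: int = 4
    stretch_run_max: int = 1

    def __post_init__(self):
        if self.het_run_max < 1 or self.stretch_run_max < 1:
            raise ValueError("run-length thresholds must be >= 1")


def encode_abh(m: SiteMatrix) -> ABHMatrix:
    """Translate nucleotide calls of the F2 samples into A/B/H/N codes.

    Requires parental consensus alleles (recorded by the parental
    consistency filter).  A call homozygous for the parent-1 allele becomes
    ``A``, homozygous parent-2 becomes ``B``, one of each ``H``; missing
    calls and calls carrying any allele matching neither parent become
    ``N`` (such off-parent alleles typically reflect structural divergence
    from the reference and are left to the correction passes downstream).
    """
    if m.parent1_allele is None or m.parent2_allele is None:
        raise ValidationError("parental consensus missing; run "
                              "filter_parental_consistency before encoding")
    f2 = m.f2_indices
    a1 = m.allele1[:, f2]
    a2 = m.allele2[:, f2]
    p1 = m.parent1_allele[:, None]
    p2 = m.parent2_allele[:, None]
    codes = np.full(a1.shape, "N", dtype="U1")
    is1_a = a1 == p1
    is1_b = a1 == p2
    is2_a = a2 == p1
    is2_b = a2 == p2
    codes[is1_a & is2_a] = "A"
    codes[is1_b & is2_b] = "B"
    codes[(is1_a & is2_b) | (is1_b & is2_a)] = "H"
    return ABHMatrix(
        individuals=[m.sample_ids[i] for i in f2],
        marker_ids=[mk.id for mk in m.markers],
        chromosomes=np.array([mk.chromosome for mk in m.markers]),
        positions=np.array([mk.position_bp for mk in m.markers], dtype=int),
        codes=codes.T.copy(),
        units="bp",
    )


# ---------------------------------------------------------------------------
# run-based passes on single rows

def _runs(row) -> list[tuple[str, int, int]]:
    """Maximal runs of equal values as (value, start, stop) half-open."""
    out = []
    pos = 0
    for value, grp in groupby(row):
        n = sum(1 for _ in grp)
        out.append((value, pos, pos + n))
        pos += n
    return out


def _impute_row(row: np.ndarray) -> np.ndarray:
    out = row.copy()
    runs = _runs(row)
    for k, (value, start, stop) in enumerate(runs):
        if value != "N" or k == 0 or k == len(runs) - 1:
            continue
        left = runs[k - 1][0]
        right = runs[k + 1][0]
        if left == right:  # flanks are non-N by maximality of the run
            out[start:stop] = left
    return out


def _het_correct_row(row: np.ndarray, het_run_max: int) -> np.ndarray:
    # maximal stretches of non-H codes (A/B/N mixed), flanked by H
    out = row.copy()
    n = len(row)
    i = 0
    while i < n:
        if row[i] == "H":
            i += 1
            continue
        j = i
        while j < n and row[j] != "H":
            j += 1
        # stretch [i, j) of non-H codes
        if i > 0 and j < n and (j - i) <= het_run_max:
            out[i:j] = "H"
        i = j
    return out


def _stretch_correct_row(row: np.ndarray, stretch_run_max: int) -> np.ndarray:
    out = row.copy()
    runs = _runs(row)
    for k, (value, start, stop) in enumerate(runs):
        if stop - start > stretch_run_max or k == 0 or k == len(runs) - 1:
            continue
        left = runs[k - 1][0]
        right = runs[k + 1][0]
        if left == right and left != value and left != "N":
            out[start:stop] = left
    return out


def _apply_rowwise(g: ABHMatrix, fn) -> ABHMatrix:
    out = g.copy()
    for _, sl in g.chrom_blocks():
        for i in range(g.n_individuals):
            out.codes[i, sl] = fn(g.codes[i, sl])
    return out


def impute_flanked_missing(g: ABHMatrix) -> ABHMatrix:
    """Fill runs of missing genotypes whose two flanking genotypes agree.

    Per individual and chromosome, every maximal run of ``N`` whose nearest
    non-missing genotypes on both sides exist and are equal is replaced by
    that genotype; any other run (conflicting flanks, or a run touching a
    chromosome end) is left unchanged.  Run length is unrestricted.
    """
    return _apply_rowwise(g, _impute_row)


def correct_undercalled_het(g: ABHMatrix, het_run_max: int = 4) -> ABHMatrix:
    """Replace short homozygous/missing stretches flanked by heterozygotes.

    Every maximal run consisting only of A, B, or N, of length at most
    ``het_run_max``, with an ``H`` immediately on both sides, becomes all
    ``H``.  This reverses heterozygote undercalling, where low read depth
    sampled only one of the two alleles.
    """
    return _apply_rowwise(g, lambda row: _het_correct_row(row, het_run_max))


def correct_short_stretches(g: ABHMatrix, stretch_run_max: int = 1) -> ABHMatrix:
    """Replace isolated genotypes that disagree with two equal neighbours.

    Every maximal run of a single code, of length at most
    ``stretch_run_max``, whose immediate left and right neighbours are equal
    to each other, different from the run value, and not ``N``, is replaced
    by the neighbouring value.  Runs of ``N`` may be rewritten, but a
    neighbouring value of ``N`` never overwrites a called genotype, so this
    pass cannot introduce missing data.
    """
    return _apply_rowwise(g, lambda row: _stretch_correct_row(row, stretch_run_max))


# ---------------------------------------------------------------------------
# full post-processing and merging

@dataclass
class PostprocessStats:
    """Before/after composition and change counts of a postprocess run."""

    composition_before: dict[str, float]
    composition_after: dict[str, float]
    cells_imputed: int = 0
    cells_het_corrected: int = 0
    cells_stretch_corrected: int = 0
    imputed_run_lengths: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "composition_before": self.composition_before,
            "composition_after": self.composition_after,
            "cells_imputed": self.cells_imputed,
            "cells_het_corrected": self.cells_het_corrected,
            "cells_stretch_corrected": self.cells_stretch_corrected,
            "imputed_run_lengths": self.imputed_run_lengths,
        }


def _imputed_run_lengths(before: ABHMatrix, after: ABHMatrix) -> dict[int, int]:
    lengths: dict[int, int] = {}
    changed = before.codes != after.codes
    for i in range(before.n_individuals):
        for _, sl in before.chrom_blocks():
            row = changed[i, sl]
            for value, start, stop in _runs(row):
                if value:
                    lengths[stop - start] = lengths.get(stop - start, 0) + 1
    return lengths


def postprocess(g: ABHMatrix, params: CorrectionParams | None = None
                ) -> tuple[ABHMatrix, PostprocessStats]:
    """Apply impute -> het-correct -> stretch-correct and report statistics."""
    params = params or CorrectionParams()
    before = g.composition()
    g1 = impute_flanked_missing(g)
    g2 = correct_undercalled_het(g1, params.het_run_max)
    g3 = correct_short_stretches(g2, params.stretch_run_max)
    stats = PostprocessStats(
        composition_before=before,
        composition_after=g3.composition(),
        cells_imputed=int(np.sum(g.codes != g1.codes)),
        cells_het_corrected=int(np.sum(g1.codes != g2.codes)),
        cells_stretch_corrected=int(np.sum(g2.codes != g3.codes)),
        imputed_run_lengths=_imputed_run_lengths(g, g1),
    )
    return g3, stats


def merge_populations(g1: ABHMatrix, g2: ABHMatrix,
                      reimpute: bool = True) -> ABHMatrix:
    """Merge two populations genotyped at different marker sets.

    Markers are unioned by physical position, individuals are concatenated,
    and every cell at a marker not assayed in an individual's source
    population is ``N``; flank-based imputation is then re-run so each
    population's haplotype blocks fill in the other's marker positions.
    The two populations must not share individuals; a marker present at the
    same (chromosome, position) in both inputs must carry the same id.
    """
    if g1.units != g2.units:
        raise ValidationError("cannot merge matrices with different position units")
    if set(g1.individuals) & set(g2.individuals):
        raise ValidationError("populations share individuals")
    key1 = {(str(c), int(p) if g1.units == "bp" else float(p)): mid
            for c, p, mid in zip(g1.chromosomes, g1.positions, g1.marker_ids)}
    key2 = {(str(c), int(p) if g2.units == "bp" else float(p)): mid
            for c, p, mid in zip(g2.chromosomes, g2.positions, g2.marker_ids)}
    for k in set(key1) & set(key2):
        if key1[k] != key2[k]:
            raise ValidationError(
                f"conflicting markers at {k[0]}:{k[1]}: {key1[k]!r} vs {key2[k]!r}")
    all_keys = sorted(set(key1) | set(key2))
    marker_ids = [key1.get(k, key2.get(k)) for k in all_keys]
    chromosomes = np.array([k[0] for k in all_keys])
    positions = np.array([k[1] for k in all_keys])
    n_ind = g1.n_individuals + g2.n_individuals
    codes = np.full((n_ind, len(all_keys)), "N", dtype="U1")
    col_of = {k: j for j, k in enumerate(all_keys)}
    for src, row_offset in ((g1, 0), (g2, g1.n_individuals)):
        src_keys = [(str(c), int(p) if src.units == "bp" else float(p))
                    for c, p in zip(src.chromosomes, src.positions)]
        cols = [col_of[k] for k in src_keys]
        codes[row_offset:row_offset + src.n_individuals, cols] = src.codes
    merged = ABHMatrix(
        individuals=list(g1.individuals) + list(g2.individuals),
        marker_ids=marker_ids,
        chromosomes=chromosomes,
        positions=positions,
        codes=codes,
        units=g1.units,
    )
    return impute_flanked_missing(merged) if reimpute else merged
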