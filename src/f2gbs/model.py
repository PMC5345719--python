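"""Domain types: variant sites with per-sample calls, ABH genotype matrices,
and genetic maps.

Conventions used throughout the package:

* physical coordinates are 1-based inclusive (HapMap/VCF convention);
* a heterozygous genotype is unordered (``G/T`` and ``T/G`` are the same call);
* ABH codes: ``A`` = parent-1 homozygote, ``B`` = parent-2 homozygote,
  ``H`` = heterozygote, ``N`` = missing;
* missing nucleotide alleles are represented by the empty string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ABH_CODES = ("A", "B", "H", "N")

ROLE_PARENT1 = "parent1_rep"
ROLE_PARENT2 = "parent2_rep"
ROLE_F2 = "f2"
VALID_ROLES = (ROLE_PARENT1, ROLE_PARENT2, ROLE_F2)

_BASES = set("ACGT")


class ValidationError(ValueError):
    """An input violated a structural invariant of the data model."""


@dataclass(frozen=True)
class Marker:
    """A biallelic variant site anchored on the physical reference."""

    id: str
    chromosome: str
    position_bp: int
    ref_allele: str = "N"
    alt_allele: str = "N"

    def __post_init__(self):
        if self.position_bp < 1:
            raise ValidationError(
                f"marker {self.id}: position_bp must be >= 1, got {self.position_bp}"
            )
        if self.ref_allele == self.alt_allele and self.ref_allele in _BASES:
            raise ValidationError(
                f"marker {self.id}: ref and alt alleles are identical ({self.ref_allele})"
            )


@dataclass
class SiteMatrix:
    """Variant sites x samples of genotype calls with per-allele read depths.

    ``allele1``/``allele2`` are ``(n_sites, n_samples)`` arrays of single
    characters, empty string meaning missing; a call is missing iff both
    alleles are missing.  ``depth_ref``/``depth_alt`` count reads supporting
    the marker's ref and alt allele; once parental consensus is known
    (``parent1_allele``/``parent2_allele``), parent-oriented depths can be
    obtained with :meth:`parent_depths`.
    """

    markers: list[Marker]
    sample_ids: list[str]
    roles: list[str]
    allele1: np.ndarray
    allele2: np.ndarray
    depth_ref: np.ndarray
    depth_alt: np.ndarray
    # consensus parental alleles, filled in by filter_parental_consistency
    parent1_allele: np.ndarray | None = None
    parent2_allele: np.ndarray | None = None

    def __post_init__(self):
        n_sites, n_samples = len(self.markers), len(self.sample_ids)
        for name in ("allele1", "allele2", "depth_ref", "depth_alt"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_samples):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected {(n_sites, n_samples)}"
                )
        if len(self.roles) != n_samples:
            raise ValidationError("one role per sample required")
        bad = set(self.roles) - set(VALID_ROLES)
        if bad:
            raise ValidationError(f"unknown sample roles: {sorted(bad)}")
        seen = {}
        for i, m in enumerate(self.markers):
            key = (m.chromosome, m.position_bp)
            if key in seen:
                raise ValidationError(
                    f"duplicated site {m.chromosome}:{m.position_bp} "
                    f"(markers {self.markers[seen[key]].id!r} and {m.id!r})"
                )
            seen[key] = i
        miss1 = self.allele1 == ""
        miss2 = self.allele2 == ""
        if np.any(miss1 != miss2):
            raise ValidationError("a call must have both alleles set or both missing")
        if np.any(self.depth_ref < 0) or np.any(self.depth_alt < 0):
            raise ValidationError("read depths must be non-negative")

    # -- structure ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def role_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)

    @property
    def f2_indices(self) -> np.ndarray:
        return self.role_indices(ROLE_F2)

    def missing_mask(self) -> np.ndarray:
        """(n_sites, n_samples) boolean mask of missing calls."""
        return self.allele1 == ""

    def is_sorted(self) -> bool:
        keys = [(m.chromosome, m.position_bp) for m in self.markers]
        return keys == sorted(keys)

    def sorted_by_position(self) -> "SiteMatrix":
        """Stable sort of sites by (chromosome, position_bp)."""
        order = sorted(range(self.n_sites),
                       key=lambda i: (self.markers[i].chromosome,
                                      self.markers[i].position_bp))
        return self.take_sites(np.array(order, dtype=int))

    def take_sites(self, idx: np.ndarray) -> "SiteMatrix":
        return SiteMatrix(
            markers=[self.markers[i] for i in idx],
            sample_ids=list(self.sample_ids),
            roles=list(self.roles),
            allele1=self.allele1[idx].copy(),
            allele2=self.allele2[idx].copy(),
            depth_ref=self.depth_ref[idx].copy(),
            depth_alt=self.depth_alt[idx].copy(),
            parent1_allele=None if self.parent1_allele is None else self.parent1_allele[idx].copy(),
            parent2_allele=None if self.parent2_allele is None else self.parent2_allele[idx].copy(),
        )

    def total_depth(self) -> np.ndarray:
        return self.depth_ref + self.depth_alt

    def parent_depths(self) -> tuple[np.ndarray, np.ndarray]:
        """Depths oriented to (parent1 allele, parent2 allele).

        Requires parental consensus; sites where parent1 carries the alt
        allele get their ref/alt depths swapped.
        """
        if self.parent1_allele is None:
            raise ValidationError("parental consensus not available; run "
                                  "filter_parental_consistency first")
        refs = np.array([m.ref_allele for m in self.markers])
        p1_is_ref = (self.parent1_allele == refs)[:, None]
        d1 = np.where(p1_is_ref, self.depth_ref, self.depth_alt)
        d2 = np.where(p1_is_ref, self.depth_alt, self.depth_ref)
        return d1, d2


@dataclass
class ABHMatrix:
    """Individuals x physically ordered markers, coded A/B/H/N.

    ``positions`` are base pairs by default; set ``units='cM'`` for matrices
    that live directly on the genetic scale (e.g. simulator output).
    """

    individuals: list[str]
    marker_ids: list[str]
    chromosomes: np.ndarray  # (n_markers,) chromosome label per marker
    positions: np.ndarray    # (n_markers,) bp (int) or cM (float)
    codes: np.ndarray        # (n_individuals, n_markers) single chars
    units: str = "bp"

    def __post_init__(self):
        n_ind, n_mark = len(self.individuals), len(self.marker_ids)
        self.chromosomes = np.asarray(self.chromosomes)
        self.positions = np.asarray(self.positions)
        if self.chromosomes.shape != (n_mark,) or self.positions.shape != (n_mark,):
            raise ValidationError("chromosomes/positions must have one entry per marker")
        if self.codes.shape != (n_ind, n_mark):
            raise ValidationError(
                f"codes shape {self.codes.shape} != {(n_ind, n_mark)}")
        if self.units not in ("bp", "cM"):
            raise ValidationError(f"unknown units {self.units!r}")
        bad = set(np.unique(self.codes)) - set(ABH_CODES)
        if bad:
            raise ValidationError(f"codes outside A/B/H/N: {sorted(bad)}")
        # markers grouped by chromosome, non-decreasing positions within each
        for chrom, sl in self.chrom_blocks():
            pos = self.positions[sl]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(f"positions not sorted on chromosome {chrom}")
        blocks = [c for c, _ in self.chrom_blocks()]
        if len(blocks) != len(set(blocks)):
            raise ValidationError("markers of one chromosome must be contiguous")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chrom_blocks(self) -> list[tuple[str, slice]]:
        """Contiguous (chromosome, slice) blocks in marker order."""
        blocks = []
        chroms = self.chromosomes
        if len(chroms) == 0:
            return blocks
        start = 0
        for i in range(1, len(chroms)):
            if chroms[i] != chroms[start]:
                blocks.append((str(chroms[start]), slice(start, i)))
                start = i
        blocks.append((str(chroms[start]), slice(start, len(chroms))))
        return blocks

    def copy(self) -> "ABHMatrix":
        return ABHMatrix(
            individuals=list(self.individuals),
            marker_ids=list(self.marker_ids),
            chromosomes=self.chromosomes.copy(),
            positions=self.positions.copy(),
            codes=self.codes.copy(),
            units=self.units,
        )

    def composition(self) -> dict[str, float]:
        """Global fraction of each code; fractions sum to 1."""
        total = self.codes.size
        return {c: float(np.sum(self.codes == c)) / total for c in ABH_CODES}


@dataclass
class GeneticMap:
    """Per-chromosome ordered marker positions in centiMorgans.

    ``chromosomes`` maps a chromosome label to a list of ``(marker_id, cM)``
    pairs; positions are non-decreasing and start at 0 within a chromosome.
    """

    chromosomes: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, entries in self.chromosomes.items():
            pos = [p for _, p in entries]
            if pos and abs(pos[0]) > 1e-9:
                raise ValidationError(f"chromosome {chrom}: first marker must be at 0 cM")
            if any(b < a - 1e-9 for a, b in zip(pos, pos[1:])):
                raise ValidationError(f"chromosome {chrom}: positions must be non-decreasing")

    def chrom_length(self, chrom: str) -> float:
        entries = self.chromosomes[chrom]
        return entries[-1][1] if entries else 0.0

    def total_length_cM(self) -> float:
        return float(sum(self.chrom_length(c) for c in self.chromosomes))

    def positions(self, chrom: str) -> np.ndarray:
        return np.array([p for _, p in self.chromosomes[chrom]], dtype=float)

    def marker_ids(self, chrom: str) -> list[str]:
        return [m for m, _ in self.chromosomes[chrom]]
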