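"""Site- and call-level filters applied between SNP calling and ABH encoding.

The pipeline order is fixed: parental consistency -> minor allele frequency ->
read-depth mask -> 64-bp thinning -> per-site missingness.  Every stage is
recorded in a :class:`FilterReport` so the audit trail (sites in/out, calls
masked, parameters) can be serialized as JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ROLE_F2, ROLE_PARENT1, ROLE_PARENT2, SiteMatrix


@dataclass
class FilterReport:
    """Ordered audit trail of filter stages."""

    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, sites_in: int, sites_out: int,
               calls_masked: int = 0, **params) -> None:
        if sites_out > sites_in:
            raise ValueError(f"stage {name}: sites out > sites in")
        self.stages.append({
            "stage": name,
            "sites_in": sites_in,
            "sites_out": sites_out,
            "calls_masked": calls_masked,
            "params": params,
        })

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def _consensus(alleles1: np.ndarray, alleles2: np.ndarray) -> tuple[str, str] | None:
    """Consensus unordered genotype of a set of replicate calls.

    Returns None when the non-missing calls disagree or none exist.
    """
    genotypes = set()
    for a, b in zip(alleles1, alleles2):
        if a == "":
            continue
        genotypes.add(frozenset((a, b)) if a != b else frozenset((a,)))
    if len(genotypes) != 1:
        return None
    g = sorted(next(iter(genotypes)))
    return (g[0], g[0]) if len(g) == 1 else (g[0], g[1])


def filter_parental_consistency(m: SiteMatrix,
                                report: FilterReport | None = None) -> SiteMatrix:
    """Keep sites with consistent, homozygous, and different parental calls.

    A site is retained when (1) all non-missing parent-1 replicate calls
    agree and all parent-2 replicate calls agree, (2) both parental
    consensus genotypes are homozygous, and (3) the two consensus alleles
    differ.  Sites with no non-missing call for either parent are dropped
    and counted.  Consensus parental alleles are recorded on the result.
    """
    p1 = m.role_indices(ROLE_PARENT1)
    p2 = m.role_indices(ROLE_PARENT2)
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("parental filtering requires samples of both parent roles")
    keep, cons1, cons2 = [], [], []
    for i in range(m.n_sites):
        c1 = _consensus(m.allele1[i, p1], m.allele2[i, p1])
        c2 = _consensus(m.allele1[i, p2], m.allele2[i, p2])
        if c1 is None or c2 is None:
            continue
        if c1[0] != c1[1] or c2[0] != c2[1]:
            continue  # heterozygous parent
        if c1[0] == c2[0]:
            continue  # identical parental alleles: uninformative
        keep.append(i)
        cons1.append(c1[0])
        cons2.append(c2[0])
    out = m.take_sites(np.array(keep, dtype=int))
    out.parent1_allele = np.array(cons1, dtype="U1")
    out.parent2_allele = np.array(cons2, dtype="U1")
    if report is not None:
        report.record("parental_consistency", m.n_sites, out.n_sites)
    return out


def site_maf(m: SiteMatrix) -> np.ndarray:
    """Per-site minor allele frequency over the F2 samples.

    Each homozygote contributes two copies of its allele, each heterozygote
    one copy of each; only the marker's two alleles are counted.  Sites with
    no counted F2 allele get MAF = NaN.
    """
    f2 = m.f2_indices
    refs = np.array([mk.ref_allele for mk in m.markers])
    alts = np.array([mk.alt_allele for mk in m.markers])
    a1 = m.allele1[:, f2]
    a2 = m.allele2[:, f2]
    n_ref = (a1 == refs[:, None]).sum(axis=1) + (a2 == refs[:, None]).sum(axis=1)
    n_alt = (a1 == alts[:, None]).sum(axis=1) + (a2 == alts[:, None]).sum(axis=1)
    total = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(n_ref, n_alt) / total
    return np.where(total > 0, maf, np.nan)


def filter_maf(m: SiteMatrix, threshold: float = 0.25,
               report: FilterReport | None = None) -> SiteMatrix:
    """Remove sites whose F2 minor allele frequency is strictly below threshold.

    Sites where every F2 call is missing are removed as well.
    """
    maf = site_maf(m)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= threshold)[0]
    out = m.take_sites(keep)
    if report is not None:
        report.record("maf", m.n_sites, out.n_sites, threshold=threshold)
    return out


def mask_low_depth(m: SiteMatrix, min_depth: int = 7,
                   report: FilterReport | None = None) -> SiteMatrix:
    """Set F2 calls with total read depth below ``min_depth`` to missing.

    Parental replicate calls are left untouched: the triplicate-consistency
    rule already protects them.  Only genotypes are changed (to missing);
    depths are kept for the audit trail.
    """
    out = m.take_sites(np.arange(m.n_sites))
    f2 = m.f2_indices
    total = out.depth_ref[:, f2] + out.depth_alt[:, f2]
    low = (total < min_depth) & (out.allele1[:, f2] != "")
    sub1 = out.allele1[:, f2]
    sub2 = out.allele2[:, f2]
    sub1[low] = ""
    sub2[low] = ""
    out.allele1[:, f2] = sub1
    out.allele2[:, f2] = sub2
    if report is not None:
        report.record("depth_mask", m.n_sites, out.n_sites,
                      calls_masked=int(low.sum()), min_depth=min_depth)
    return out


def undercall_probability(depth: int) -> float:
    """Probability that all reads at a true heterozygote come from one parent.

    Under equal sampling of the two alleles, each of the ``depth`` reads is
    an independent coin flip, so the chance of seeing only one allele is
    ``2 * (1/2)**depth``.  At the pipeline's default minimum depth of 7 this
    is 0.015625, i.e. at most ~1.6% of heterozygotes can be undercalled.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    return 2.0 * 0.5 ** depth


def thin_sites(m: SiteMatrix, min_bp: int = 64,
               report: FilterReport | None = None) -> SiteMatrix:
    """Greedy left-to-right thinning to a minimum inter-site distance.

    Per chromosome, the first site is kept and each subsequent site is kept
    iff its position is at least ``min_bp`` greater than the last kept
    site's position (a distance of exactly ``min_bp`` qualifies).  This
    removes redundant SNPs called from the same sequencing tag.
    """
    keep = []
    last_chrom, last_pos = None, None
    for i, mk in enumerate(m.markers):
        if mk.chromosome != last_chrom or mk.position_bp - last_pos >= min_bp:
            keep.append(i)
            last_chrom, last_pos = mk.chromosome, mk.position_bp
    out = m.take_sites(np.array(keep, dtype=int))
    if report is not None:
        report.record("thin", m.n_sites, out.n_sites, min_bp=min_bp)
    return out


def filter_site_missingness(m: SiteMatrix, max_missing: float = 0.75,
                            report: FilterReport | None = None) -> SiteMatrix:
    """Remove sites whose fraction of missing F2 calls exceeds ``max_missing``."""
    f2 = m.f2_indices
    frac = (m.allele1[:, f2] == "").mean(axis=1) if len(f2) else np.zeros(m.n_sites)
    keep = np.where(frac <= max_missing)[0]
    out = m.take_sites(keep)
    if report is not None:
        report.record("missingness", m.n_sites, out.n_sites, max_missing=max_missing)
    return out


@dataclass
class AllelicDepthStats:
    """Summary of parent-1/parent-2 read-depth ratios at heterozygous F2 calls."""

    n_het: int
    n_zero_denominator: int
    fraction_within_twofold: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    ratios: np.ndarray


def allelic_depth_ratio_stats(m: SiteMatrix, bins: int = 30) -> AllelicDepthStats:
    """Relative allelic depth at heterozygous F2 calls.

    For every heterozygous F2 call with both per-parent depths positive,
    computes depth_p1/depth_p2 and reports the fraction of ratios strictly
    inside the two-fold band (0.5, 2.0) plus a histogram of log2 ratios.
    A strong departure from 1 would indicate allele-specific amplification
    or mapping bias.  Calls with a zero denominator are counted separately.
    """
    f2 = m.f2_indices
    d1, d2 = m.parent_depths()
    a1 = m.allele1[:, f2]
    a2 = m.allele2[:, f2]
    het = (a1 != "") & (a1 != a2)
    d1 = d1[:, f2][het]
    d2 = d2[:, f2][het]
    ok = (d1 > 0) & (d2 > 0)
    n_zero = int((~ok).sum())
    ratios = d1[ok] / d2[ok]
    within = float(np.mean((ratios > 0.5) & (ratios < 2.0))) if ratios.size else float("nan")
    log2r = np.log2(ratios) if ratios.size else np.array([])
    counts, edges = np.histogram(log2r, bins=bins) if ratios.size else (np.zeros(bins, int), np.linspace(-3, 3, bins + 1))
    return AllelicDepthStats(
        n_het=int(het.sum()),
        n_zero_denominator=n_zero,
        fraction_within_twofold=within,
        hist_counts=counts,
        hist_edges=edges,
        ratios=ratios,
    )


def filter_pipeline(m: SiteMatrix, *, maf_threshold: float = 0.25,
                    min_depth: int = 7, thin_bp: int = 64,
                    max_missing: float = 0.75) -> tuple[SiteMatrix, FilterReport]:
    """Run all filters in the fixed pipeline order and return the report."""
    report = FilterReport()
    m = filter_parental_consistency(m, report)
    m = filter_maf(m, maf_threshold, report)
    m = mask_low_depth(m, min_depth, report)
    m = thin_sites(m, thin_bp, report)
    m = filter_site_missingness(m, max_missing, report)
    return m, report
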