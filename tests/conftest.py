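"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use a different mechanism (per-cell index
scanning) than the run-length-encoding implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from f2gbs.model import ABHMatrix, Marker, SiteMatrix


# ---------------------------------------------------------------------------
# construction helpers

def abh_from_rows(rows: list[str], chromosomes: list[str] | None = None,
                  positions: list[int] | None = None, units: str = "bp") -> ABHMatrix:
    """Build an ABH matrix from genotype strings (one per individual)."""
    n_mark = len(rows[0])
    if chromosomes is None:
        chromosomes = ["1"] * n_mark
    if positions is None:
        pos, last_chrom, p = [], None, 0
        for c in chromosomes:
            p = p + 1000 if c == last_chrom else 1000
            pos.append(p)
            last_chrom = c
        positions = pos
    return ABHMatrix(
        individuals=[f"ind{i}" for i in range(len(rows))],
        marker_ids=[f"m{j}" for j in range(n_mark)],
        chromosomes=np.array(chromosomes),
        positions=np.array(positions),
        codes=np.array([list(r) for r in rows], dtype="U1"),
        units=units,
    )


def site_matrix_from_calls(genotypes: list[list[str]], roles: list[str],
                           chromosomes: list[str] | None = None,
                           positions: list[int] | None = None,
                           ref: str = "G", alt: str = "T",
                           depths: list[list[tuple[int, int]]] | None = None
                           ) -> SiteMatrix:
    """Build a SiteMatrix from genotype tokens like 'GG', 'GT', 'NN'."""
    n_sites = len(genotypes)
    n_samples = len(roles)
    if chromosomes is None:
        chromosomes = ["1"] * n_sites
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_sites)]
    a1 = np.empty((n_sites, n_samples), dtype="U1")
    a2 = np.empty((n_sites, n_samples), dtype="U1")
    for i, row in enumerate(genotypes):
        for j, tok in enumerate(row):
            if tok in ("NN", "N", "--", "./."):
                a1[i, j] = a2[i, j] = ""
            else:
                a1[i, j], a2[i, j] = tok[0], tok[1]
    if depths is None:
        dref = np.where(a1 != "", 10, 0)
        dalt = np.zeros((n_sites, n_samples), dtype=int)
    else:
        dref = np.array([[d[0] for d in row] for row in depths], dtype=int)
        dalt = np.array([[d[1] for d in row] for row in depths], dtype=int)
    markers = [Marker(f"s{i}", chromosomes[i], positions[i], ref, alt)
               for i in range(n_sites)]
    return SiteMatrix(markers=markers,
                      sample_ids=[f"smp{j}" for j in range(n_samples)],
                      roles=list(roles), allele1=a1, allele2=a2,
                      depth_ref=dref, depth_alt=dalt)


# ---------------------------------------------------------------------------
# naive per-cell oracles for the ABH passes

def oracle_impute(s: str) -> str:
    out = list(s)
    n = len(s)
    for i, ch in enumerate(s):
        if ch != "N":
            continue
        l = i - 1
        while l >= 0 and s[l] == "N":
            l -= 1
        r = i + 1
        while r < n and s[r] == "N":
            r += 1
        if l >= 0 and r < n and s[l] == s[r]:
            out[i] = s[l]
    return "".join(out)


def oracle_het_correct(s: str, k: int = 4) -> str:
    out = list(s)
    n = len(s)
    for i, ch in enumerate(s):
        if ch == "H":
            continue
        l = i
        while l > 0 and s[l - 1] != "H":
            l -= 1
        r = i
        while r < n - 1 and s[r + 1] != "H":
            r += 1
        if l > 0 and r < n - 1 and (r - l + 1) <= k:
            out[i] = "H"
    return "".join(out)


def oracle_stretch_correct(s: str, k: int = 1) -> str:
    out = list(s)
    n = len(s)
    for i, ch in enumerate(s):
        l = i
        while l > 0 and s[l - 1] == ch:
            l -= 1
        r = i
        while r < n - 1 and s[r + 1] == ch:
            r += 1
        if (r - l + 1) <= k and l > 0 and r < n - 1 \
                and s[l - 1] == s[r + 1] and s[l - 1] != ch and s[l - 1] != "N":
            out[i] = s[l - 1]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)
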