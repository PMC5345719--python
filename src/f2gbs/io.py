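"""Readers and writers for genotype-level formats.

Supported formats:

* TASSEL-style HapMap text (11 metadata columns, then one column per sample;
  genotypes as IUPAC single letters or unphased base pairs);
* VCF v4.2 with ``GT`` and ``AD`` per-sample fields (read via cyvcf2);
* the package's ABH-CSV dialect (see :func:`write_abh_csv`);
* a two-column roles table mapping sample id to
  ``parent1_rep``/``parent2_rep``/``f2``;
* phenotype CSV (``id,trait``) and genetic-map TSV (``chromosome marker cM``).
"""

from __future__ import annotations

import os

import numpy as np

from .model import (
    ABH_CODES,
    ABHMatrix,
    GeneticMap,
    Marker,
    SiteMatrix,
    VALID_ROLES,
    ValidationError,
)


class ParseError(ValueError):
    """A file did not conform to the named format."""


# IUPAC ambiguity codes for the 2-base heterozygotes HapMap uses
_IUPAC_HET = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}
_HET_TO_IUPAC = {frozenset(v): k for k, v in _IUPAC_HET.items()}


def read_roles(path: str) -> dict[str, str]:
    """Read a two-column (sample id, role) whitespace/tab-separated table."""
    roles: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 'sample role', got {line!r}")
            sample, role = parts
            if role not in VALID_ROLES:
                raise ParseError(
                    f"{path}:{ln}: unknown role {role!r} (expected one of {VALID_ROLES})")
            roles[sample] = role
    return roles


def _decode_genotype(token: str) -> tuple[str, str]:
    """Decode a HapMap genotype token to an unordered allele pair ('' = missing)."""
    token = token.strip()
    if token in ("N", "NN", "-", "--", "./.", ".", "N/N"):
        return "", ""
    if "/" in token:
        a, b = token.split("/")
    elif len(token) == 2:
        a, b = token[0], token[1]
    elif len(token) == 1:
        if token in "ACGT":
            return token, token
        if token in _IUPAC_HET:
            return _IUPAC_HET[token]
        return "", ""
    else:
        raise ParseError(f"cannot decode genotype token {token!r}")
    a, b = a.upper(), b.upper()
    if a in (".", "N") or b in (".", "N"):
        return "", ""
    return a, b


def read_site_matrix(path: str, format: str, roles: dict[str, str] | str) -> SiteMatrix:
    """Read genotype calls into a :class:`SiteMatrix`, sorted by position.

    ``roles`` maps each sample id in the file to its role, or is the path of
    a roles table.  Per-sample allele depths are taken from ``AD`` fields
    when present (VCF); HapMap carries no depths, so they are zero.
    """
    if isinstance(roles, str):
        roles = read_roles(roles)
    if format == "hapmap":
        m = _read_hapmap(path, roles)
    elif format == "vcf":
        m = _read_vcf(path, roles)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'hapmap' or 'vcf')")
    return m.sorted_by_position()


def _roles_for(sample_ids: list[str], roles: dict[str, str], path: str) -> list[str]:
    unknown = [s for s in sample_ids if s not in roles]
    if unknown:
        raise ValidationError(
            f"{path}: samples missing from roles table: {unknown}")
    return [roles[s] for s in sample_ids]


def _read_hapmap(path: str, roles: dict[str, str]) -> SiteMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}:1: empty HapMap file")
        cols = header.split("\t")
        if len(cols) < 12 or cols[0] not in ("rs#", "rs"):
            raise ParseError(
                f"{path}:1: not a HapMap header (needs 11 metadata columns "
                "starting with 'rs#')")
        sample_ids = cols[11:]
        markers: list[Marker] = []
        a1_rows, a2_rows = [], []
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"{path}:{ln}: {len(parts)} columns, header has {len(cols)}")
            rs, alleles, chrom, pos = parts[0], parts[1], parts[2], parts[3]
            try:
                position = int(pos)
            except ValueError:
                raise ParseError(f"{path}:{ln}: position {pos!r} is not an integer")
            ref, alt = "N", "N"
            if "/" in alleles:
                ref, alt = (alleles.split("/") + ["N"])[:2]
            try:
                marker = Marker(rs, chrom, position, ref, alt)
            except ValidationError as e:
                raise ParseError(f"{path}:{ln}: {e}")
            markers.append(marker)
            row1, row2 = [], []
            for tok in parts[11:]:
                a, b = _decode_genotype(tok)
                row1.append(a)
                row2.append(b)
            a1_rows.append(row1)
            a2_rows.append(row2)
    n_sites, n_samples = len(markers), len(sample_ids)
    shape = (n_sites, n_samples)
    return SiteMatrix(
        markers=markers,
        sample_ids=sample_ids,
        roles=_roles_for(sample_ids, roles, path),
        allele1=np.array(a1_rows, dtype="U1").reshape(shape),
        allele2=np.array(a2_rows, dtype="U1").reshape(shape),
        depth_ref=np.zeros(shape, dtype=int),
        depth_alt=np.zeros(shape, dtype=int),
    )


def _read_vcf(path: str, roles: dict[str, str]) -> SiteMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    markers: list[Marker] = []
    a1_rows, a2_rows, dref_rows, dalt_rows = [], [], [], []
    for var in vcf:
        ref = var.REF
        alt = var.ALT[0] if var.ALT else "N"
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        try:
            marker = Marker(mid, var.CHROM, var.POS, ref, alt)
        except ValidationError as e:
            raise ParseError(f"{path}: {var.CHROM}:{var.POS}: {e}")
        markers.append(marker)
        gts = var.genotypes  # [allele1, allele2, phased]
        row1, row2 = [], []
        for g in gts:
            i, j = g[0], g[1]
            if i < 0 or j < 0:
                row1.append("")
                row2.append("")
            else:
                alleles = [ref] + list(var.ALT)
                row1.append(alleles[i])
                row2.append(alleles[j])
        ad = var.format("AD")
        if ad is not None:
            dref = np.maximum(ad[:, 0], 0)
            dalt = np.maximum(ad[:, 1], 0) if ad.shape[1] > 1 else np.zeros(len(gts), int)
        else:
            dref = np.zeros(len(gts), dtype=int)
            dalt = np.zeros(len(gts), dtype=int)
        a1_rows.append(row1)
        a2_rows.append(row2)
        dref_rows.append(dref)
        dalt_rows.append(dalt)
    shape = (len(markers), len(sample_ids))
    return SiteMatrix(
        markers=markers,
        sample_ids=sample_ids,
        roles=_roles_for(sample_ids, roles, path),
        allele1=np.array(a1_rows, dtype="U1").reshape(shape),
        allele2=np.array(a2_rows, dtype="U1").reshape(shape),
        depth_ref=np.array(dref_rows, dtype=int).reshape(shape),
        depth_alt=np.array(dalt_rows, dtype=int).reshape(shape),
    )


def write_vcf(m: SiteMatrix, path: str) -> None:
    """Write a SiteMatrix as minimal VCF v4.2 with GT and AD fields."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=f2gbs (coordinates 1-based inclusive)\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.sample_ids) + "\n")
        for i, mk in enumerate(m.markers):
            fields = [mk.chromosome, str(mk.position_bp), mk.id,
                      mk.ref_allele, mk.alt_allele, ".", "PASS", ".", "GT:AD"]
            for j in range(m.n_samples):
                a, b = m.allele1[i, j], m.allele2[i, j]
                if a == "":
                    gt = "./."
                else:
                    idx = {mk.ref_allele: "0", mk.alt_allele: "1"}
                    gt = f"{idx.get(a, '.')}/{idx.get(b, '.')}"
                fields.append(f"{gt}:{m.depth_ref[i, j]},{m.depth_alt[i, j]}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# ABH-CSV dialect

def write_abh_csv(matrix: ABHMatrix, path: str) -> None:
    """Write the ABH-CSV dialect.

    Line 1: ``id,<marker ids>``; line 2: ``chrom,<labels>``; line 3:
    ``pos,<positions>``; then one line per individual with A/B/H/N codes.
    If the matrix is on the genetic scale a ``# units=cM`` comment line is
    written first.  Comma separated, no quoting, LF line endings.
    """
    with open(path, "w", newline="\n") as fh:
        if matrix.units == "cM":
            fh.write("# units=cM\n")
        fh.write("id," + ",".join(matrix.marker_ids) + "\n")
        fh.write("chrom," + ",".join(str(c) for c in matrix.chromosomes) + "\n")
        if matrix.units == "cM":
            pos_txt = [format(float(p), "g") for p in matrix.positions]
        else:
            pos_txt = [str(int(p)) for p in matrix.positions]
        fh.write("pos," + ",".join(pos_txt) + "\n")
        for i, ind in enumerate(matrix.individuals):
            fh.write(ind + "," + ",".join(matrix.codes[i]) + "\n")


def read_abh_csv(path: str) -> ABHMatrix:
    """Read the ABH-CSV dialect written by :func:`write_abh_csv`.

    A ``-`` cell is accepted as missing and parsed as ``N``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    units = "bp"
    if lines and lines[0].startswith("#"):
        if "units=cM" in lines[0]:
            units = "cM"
        lines = lines[1:]
    if len(lines) < 3:
        raise ParseError(f"{path}: need id/chrom/pos header lines")
    head = lines[0].split(",")
    if head[0] != "id":
        raise ParseError(f"{path}:1: first header cell must be 'id', got {head[0]!r}")
    marker_ids = head[1:]
    ncol = len(head)
    chrom_row = lines[1].split(",")
    pos_row = lines[2].split(",")
    if chrom_row[0] != "chrom" or pos_row[0] != "pos":
        raise ParseError(f"{path}: lines 2 and 3 must start with 'chrom' and 'pos'")
    if len(chrom_row) != ncol or len(pos_row) != ncol:
        raise ParseError(f"{path}: header rows disagree on column count")
    chromosomes = np.array(chrom_row[1:])
    try:
        if units == "cM":
            positions = np.array([float(p) for p in pos_row[1:]])
        else:
            positions = np.array([int(p) for p in pos_row[1:]], dtype=int)
    except ValueError as e:
        raise ParseError(f"{path}: bad position value ({e})")
    individuals, rows = [], []
    for ln, line in enumerate(lines[3:], 4):
        parts = line.split(",")
        if len(parts) != ncol:
            raise ParseError(
                f"{path}:{ln}: {len(parts)} columns, header has {ncol}")
        individuals.append(parts[0])
        row = []
        for col, cell in enumerate(parts[1:], 2):
            if cell == "-":
                cell = "N"
            if cell not in ABH_CODES:
                raise ParseError(
                    f"{path}:{ln}: column {col}: invalid code {cell!r}")
            row.append(cell)
        rows.append(row)
    codes = np.array(rows, dtype="U1").reshape(len(individuals), len(marker_ids))
    return ABHMatrix(
        individuals=individuals,
        marker_ids=marker_ids,
        chromosomes=chromosomes,
        positions=positions,
        codes=codes,
        units=units,
    )


# ---------------------------------------------------------------------------
# phenotype and map tables

def read_phenotype_csv(path: str) -> dict[str, float]:
    """Read a phenotype CSV with header ``id,trait``."""
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",")[:2] != ["id", "trait"]:
            raise ParseError(f"{path}:1: expected header 'id,trait', got {header!r}")
        values: dict[str, float] = {}
        for ln, line in enumerate(fh, 2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 'id,value'")
            try:
                values[parts[0]] = float(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-numeric trait {parts[1]!r}")
    return values


def write_map_tsv(gmap: GeneticMap, path: str) -> None:
    """Write a genetic map as TSV: chromosome, marker, position_cM."""
    with open(path, "w", newline="\n") as fh:
        fh.write("chromosome\tmarker\tposition_cM\n")
        for chrom, entries in gmap.chromosomes.items():
            for marker, cm in entries:
                fh.write(f"{chrom}\t{marker}\t{cm:.6f}\n")


def read_map_tsv(path: str) -> GeneticMap:
    chroms: dict[str, list[tuple[str, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chromosome"):
            raise ParseError(f"{path}:1: expected 'chromosome\\tmarker\\tposition_cM'")
        for ln, line in enumerate(fh, 2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 3 tab-separated columns")
            chrom, marker, cm = parts
            chroms.setdefault(chrom, []).append((marker, float(cm)))
    return GeneticMap(chromosomes=chroms)
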