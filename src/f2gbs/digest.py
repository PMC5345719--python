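"""In-silico restriction digests for GBS enzyme selection.

Counting recognition sites of candidate rare cutters across a genome
predicts how many fragments — and therefore how much per-site read depth at
a fixed sequencing budget — a GBS library will produce.  A 6-bp cutter with
fewer sites concentrates reads on fewer loci, allowing deeper multiplexing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme identified by its recognition sequence."""

    name: str
    recognition_sequence: str

    def __post_init__(self):
        seq = self.recognition_sequence.upper()
        if not seq or any(b not in ambiguous_dna_values for b in seq):
            raise ValueError(
                f"{self.name}: recognition sequence must be non-empty IUPAC DNA, "
                f"got {self.recognition_sequence!r}")
        object.__setattr__(self, "recognition_sequence", seq)

    @property
    def is_palindromic(self) -> bool:
        return str(Seq(self.recognition_sequence).reverse_complement()) \
            == self.recognition_sequence

    def pattern(self) -> re.Pattern:
        """Overlap-tolerant regex; ambiguous genome bases (N) never match."""
        return re.compile("(?=" + _iupac_regex(self.recognition_sequence) + ")")


BUILTIN_ENZYMES = {
    "PstI": EnzymeSpec("PstI", "CTGCAG"),
    "KpnI": EnzymeSpec("KpnI", "GGTACC"),
    "MspI": EnzymeSpec("MspI", "CCGG"),
}


def _iupac_regex(seq: str) -> str:
    parts = []
    for base in seq:
        options = ambiguous_dna_values[base]
        parts.append(options if len(options) == 1 else f"[{options}]")
    return "".join(parts)


def _site_starts(sequence: str, enzyme: EnzymeSpec) -> np.ndarray:
    """Start positions (0-based) of recognition sites on the given strand.

    Non-palindromic enzymes are additionally matched against the reverse
    complement of the site, reported at its position on the forward strand;
    palindromic sites are counted once per genomic location.
    """
    starts = [m.start() for m in enzyme.pattern().finditer(sequence)]
    if not enzyme.is_palindromic:
        rc = str(Seq(enzyme.recognition_sequence).reverse_complement())
        rc_pat = re.compile("(?=" + _iupac_regex(rc) + ")")
        starts.extend(m.start() for m in rc_pat.finditer(sequence))
        starts = sorted(set(starts))
    return np.array(starts, dtype=int)


def count_sites(fasta_path: str, enzyme: EnzymeSpec,
                respect_mask: bool = False) -> tuple[dict[str, int], int]:
    """Count recognition sites per sequence and in total.

    Overlapping matches are all counted.  Soft-masked (lowercase) bases are
    uppercased before matching unless ``respect_mask`` is set, in which
    case masked stretches never match.
    """
    per_seq: dict[str, int] = {}
    for record in SeqIO.parse(fasta_path, "fasta"):
        seq = str(record.seq)
        if respect_mask:
            seq = "".join("N" if c.islower() else c for c in seq)
        else:
            seq = seq.upper()
        per_seq[record.id] = len(_site_starts(seq, enzyme))
    return per_seq, sum(per_seq.values())


def predict_gbs_fragments(fasta_path: str, rare: EnzymeSpec, common: EnzymeSpec,
                          size_range: tuple[int, int] | None = None
                          ) -> tuple[int, np.ndarray]:
    """Enumerate rare/common-cutter fragments as GBS would capture them.

    A fragment is a genomic interval bounded by one rare-cutter site and
    one common-cutter site with no internal site of either enzyme, i.e. the
    two sites are adjacent in the merged site list and of different type.
    The fragment spans from the start of the left site to the end of the
    right one (cut-position offsets within the recognition sites are
    ignored).  Returns the number of fragments within ``size_range``
    (inclusive bounds) and the array of their lengths.
    """
    lengths = []
    for record in SeqIO.parse(fasta_path, "fasta"):
        seq = str(record.seq).upper()
        rare_starts = _site_starts(seq, rare)
        common_starts = _site_starts(seq, common)
        sites = sorted(
            [(int(p), "rare", len(rare.recognition_sequence)) for p in rare_starts]
            + [(int(p), "common", len(common.recognition_sequence)) for p in common_starts])
        for (p1, t1, _), (p2, t2, l2) in zip(sites, sites[1:]):
            if t1 != t2:
                lengths.append(p2 + l2 - p1)
    lengths = np.array(lengths, dtype=int)
    if size_range is not None:
        lo, hi = size_range
        lengths = lengths[(lengths >= lo) & (lengths <= hi)]
    return len(lengths), lengths
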