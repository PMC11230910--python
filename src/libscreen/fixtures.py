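"""Packaged synthetic library design.

The template below is a SYNTHETIC 102-codon coding sequence (ATG start, no
internal stop), not the deposited gene of any published library: it is a
stand-in constructed so that single-nucleotide deletions inside the
sequenced window (residues 19-83) frameshift into premature stops with
strong hotspots at residues 40 and 60 — the positional signature the
truncation-enrichment analysis is designed to detect. Eight degenerate
sites mixing the NDT/VRC/RRC schemes are placed away from the hotspot
codons so that site randomization does not erase the hotspots.

Any user-supplied design file can replace this fixture everywhere; nothing
in the pipeline is specific to it.
"""

from __future__ import annotations

from .library import LibraryDesign, Site

__all__ = ["SYNTHETIC_TEMPLATE_CDS", "SYNTHETIC_SITES", "synthetic_design"]

#: synthetic 306-nt (102-codon) template; see module docstring.
SYNTHETIC_TEMPLATE_CDS = (
    "ATGAAGCCACCATTATGTAACGTACTGATGTGCGCCAGCGTTGTGGATCAGGGTTATGAA"
    "TCGTGGGCAGTTGGTTTGTGTTTCCGCACTATACCTGACGAAGCTTGTTATAATGCTGTG"
    "AAGAGTAACCCACGCTTGGCTTCTTTTGGTACAGGAACGCCCTACCCGCATATATTATTA"
    "ATTAATCCCTTCCTCGATGGCCAAAGGCGCTGGTCTAACATTCAAGCCTCATGTTTCCGG"
    "TCGGTGCTTTTCCTAACGCTGCTACAGCCTTCAGTCGATAATGAAAAATGGAAGCGGCGG"
    "AACTAA"
)

#: eight randomized codons mixing the three stop-free schemes.
SYNTHETIC_SITES = (
    Site(22, "NDT"),
    Site(26, "VRC"),
    Site(31, "RRC"),
    Site(37, "NDT"),
    Site(46, "NDT"),
    Site(52, "VRC"),
    Site(66, "RRC"),
    Site(74, "NDT"),
)


def synthetic_design() -> LibraryDesign:
    """The packaged synthetic design: 102-codon template, 8 degenerate
    sites, sequenced window residues 19-83."""
    return LibraryDesign(SYNTHETIC_TEMPLATE_CDS, SYNTHETIC_SITES, (19, 83))
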