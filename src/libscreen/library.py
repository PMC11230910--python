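"""Degenerate-codon library model.

A combinatorial protein library is described by a template coding sequence
plus a set of randomized codon positions, each carrying a 3-letter IUPAC
degenerate codon ("scheme", e.g. NDT). This module expands schemes into
concrete codon/amino-acid sets, computes theoretical diversity, samples
library members, introduces single-nucleotide indels, and translates
sequences with premature-stop bookkeeping.

Coordinates are 1-based: codon/residue indices count from the first codon of
the full-length protein; nucleotide positions count from the first base of
the coding strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

__all__ = [
    "IUPAC",
    "LibraryDesign",
    "Variant",
    "Site",
    "expand_degenerate_codon",
    "theoretical_diversity",
    "sample_variants",
    "apply_indel",
    "translate",
    "load_design",
    "save_design",
    "write_fasta",
]

#: IUPAC nucleotide ambiguity codes -> set of concrete bases.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_STANDARD_TABLE = unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with '*' for the three stop codons.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"


class InvalidSchemeError(ValueError):
    """Raised when a degenerate codon contains a non-IUPAC letter."""


def expand_degenerate_codon(scheme: str) -> tuple[set[str], set[str]]:
    """Expand a 3-letter IUPAC degenerate codon.

    Returns ``(codons, amino_acids)``: the full Cartesian expansion into
    concrete codons and their standard-genetic-code translations ('*' marks
    stop). E.g. NDT -> 12 codons encoding 12 distinct amino acids.
    """
    scheme = scheme.upper()
    if len(scheme) != 3 or any(b not in IUPAC for b in scheme):
        raise InvalidSchemeError(f"not a 3-letter IUPAC codon: {scheme!r}")
    codons = {"".join(c) for c in itertools.product(*(IUPAC[b] for b in scheme))}
    return codons, {CODON_TO_AA[c] for c in codons}


@dataclass(frozen=True)
class Site:
    """A randomized codon position: 1-based codon index plus IUPAC scheme."""

    codon_index: int
    scheme: str

    def codons(self) -> set[str]:
        return expand_degenerate_codon(self.scheme)[0]

    def amino_acids(self) -> set[str]:
        return expand_degenerate_codon(self.scheme)[1]


@dataclass(frozen=True)
class LibraryDesign:
    """Template coding sequence plus degenerate sites and sequenced window.

    ``variable_window`` is the inclusive residue range covered by the
    amplicon; only this region is observed by sequencing.
    """

    template_cds: str
    sites: tuple[Site, ...]
    variable_window: tuple[int, int] = (19, 83)

    def __post_init__(self) -> None:
        cds = self.template_cds.upper()
        object.__setattr__(self, "template_cds", cds)
        object.__setattr__(self, "sites", tuple(
            s if isinstance(s, Site) else Site(**s) for s in self.sites
        ))
        if len(cds) % 3:
            raise ValueError("template length must be divisible by 3")
        if set(cds) - set("ACGT"):
            raise ValueError("template must be unambiguous ACGT")
        prot, stop = translate(cds)
        if stop is not None and stop <= len(cds) // 3 - 1:
            raise ValueError(f"template has internal stop at residue {stop}")
        n_codons = len(cds) // 3
        for s in self.sites:
            if not 1 <= s.codon_index <= n_codons:
                raise ValueError(f"site index {s.codon_index} outside template")
            expand_degenerate_codon(s.scheme)  # validates letters
        lo, hi = self.variable_window
        if not 1 <= lo <= hi <= n_codons:
            raise ValueError(f"variable window {self.variable_window} outside template")

    @property
    def n_codons(self) -> int:
        return len(self.template_cds) // 3

    @property
    def window_nt(self) -> tuple[int, int]:
        """1-based inclusive nucleotide range of the variable window."""
        lo, hi = self.variable_window
        return 3 * (lo - 1) + 1, 3 * hi

    def window_sequence(self, nt_sequence: str | None = None) -> str:
        """Slice the variable window out of a coding sequence.

        For a mutated sequence whose length differs from the template, the
        window start is anchored at the template coordinate (indels are
        modelled inside the window only) and the end absorbs the net length
        change.
        """
        seq = self.template_cds if nt_sequence is None else nt_sequence
        lo, hi = self.window_nt
        shift = len(seq) - len(self.template_cds)
        return seq[lo - 1 : hi + shift]

    def degenerate_window(self) -> str:
        """Variable-window sequence with site codons replaced by their
        IUPAC scheme letters (used for degenerate-aware alignment)."""
        seq = list(self.template_cds)
        for s in self.sites:
            seq[3 * (s.codon_index - 1) : 3 * s.codon_index] = s.scheme.upper()
        lo, hi = self.window_nt
        return "".join(seq[lo - 1 : hi])

    def template_protein(self) -> str:
        return translate(self.template_cds)[0]


@dataclass(frozen=True)
class Variant:
    """A single library member.

    ``true_labels`` carries simulator ground truth (class, stop residue) and
    is absent for observed data.
    """

    nt_sequence: str
    provenance: str = "sampled"  # sampled | mutated | observed
    true_labels: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.nt_sequence:
            raise ValueError("empty variant sequence")
        if set(self.nt_sequence) - set("ACGT"):
            raise ValueError("variant sequences must be concrete ACGT")


def theoretical_diversity(design: LibraryDesign, level: str = "nucleotide") -> int:
    """Number of distinct library members: product over sites of the codon
    set size (``nucleotide``) or amino-acid set size (``protein``)."""
    if level not in ("nucleotide", "protein"):
        raise ValueError(f"level must be nucleotide|protein, got {level!r}")
    n = 1
    for s in design.sites:
        codons, aas = expand_degenerate_codon(s.scheme)
        n *= len(codons) if level == "nucleotide" else len(aas)
    return n


def sample_variants(design: LibraryDesign, n: int, seed: int | np.random.Generator) -> list[Variant]:
    """Draw ``n`` library members, each site codon uniform over its expansion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    site_codons = [sorted(s.codons()) for s in design.sites]
    out = []
    template = list(design.template_cds)
    for _ in range(n):
        seq = template.copy()
        for s, codons in zip(design.sites, site_codons):
            c = codons[rng.integers(len(codons))]
            seq[3 * (s.codon_index - 1) : 3 * s.codon_index] = c
        out.append(Variant("".join(seq), provenance="sampled"))
    return out


def apply_indel(variant: Variant, position: int, kind: str, inserted_base: str | None = None) -> Variant:
    """Insert or delete one nucleotide at a 1-based position.

    ``del1`` removes the base at ``position``; ``ins1`` inserts
    ``inserted_base`` before ``position`` (position may be len+1 to append).
    ``true_labels`` is refreshed from brute-force translation of the result.
    """
    seq = variant.nt_sequence
    if kind == "del1":
        if not 1 <= position <= len(seq):
            raise ValueError(f"position {position} out of range")
        new = seq[: position - 1] + seq[position:]
    elif kind == "ins1":
        if not 1 <= position <= len(seq) + 1:
            raise ValueError(f"position {position} out of range")
        if inserted_base not in ("A", "C", "G", "T"):
            raise ValueError("ins1 requires inserted_base in ACGT")
        new = seq[: position - 1] + inserted_base + seq[position - 1 :]
    else:
        raise ValueError(f"kind must be del1|ins1, got {kind!r}")
    _, stop = translate(new)
    labels = {
        "class": "premature_stop" if stop is not None and stop < len(new) // 3 + 1 else "frameshift",
        "stop_residue": stop,
        "net_indel": len(new) - len(seq),
        "indel_position": position,
        "indel_kind": kind,
    }
    return replace(variant, nt_sequence=new, provenance="mutated", true_labels=labels)


def translate(nt_sequence: str, frame_offset: int = 0) -> tuple[str, int | None]:
    """Translate with the standard genetic code, running to the first stop or
    sequence end.

    Returns ``(protein, first_stop)`` where ``first_stop`` is the 1-based
    residue index of the first stop codon (counted in the given frame), or
    None if no stop is reached. A trailing partial codon is ignored.
    """
    seq = nt_sequence[frame_offset:].upper()
    prot = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = CODON_TO_AA.get(seq[i : i + 3], "X")
        if aa == "*":
            return "".join(prot), i // 3 + 1
        prot.append(aa)
    return "".join(prot), None


# ---------------------------------------------------------------------------
# design-file and FASTA IO

def load_design(path) -> LibraryDesign:
    """Read a YAML/JSON design file with keys ``template_cds``,
    ``sites`` ([{codon_index, scheme}]) and ``variable_window``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return LibraryDesign(
        template_cds=doc["template_cds"],
        sites=tuple(Site(int(s["codon_index"]), s["scheme"]) for s in doc.get("sites", [])),
        variable_window=tuple(doc.get("variable_window", (19, 83))),
    )


def save_design(design: LibraryDesign, path) -> None:
    doc = {
        "template_cds": design.template_cds,
        "sites": [{"codon_index": s.codon_index, "scheme": s.scheme} for s in design.sites],
        "variable_window": list(design.variable_window),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_fasta(variants, path) -> None:
    """Write sampled variants to FASTA, one record per member."""
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(v.nt_sequence), id=f"variant_{i}", description=v.provenance)
        for i, v in enumerate(variants)
    ]
    SeqIO.write(records, str(path), "fasta")
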