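"""Shared fixtures: a small stop-free toy template and the packaged design."""

import numpy as np
import pytest

from libscreen.fixtures import synthetic_design
from libscreen.library import CODON_TO_AA, LibraryDesign, Site


def make_toy_design(n_codons: int = 60, seed: int = 11,
                    sites: tuple = ()) -> LibraryDesign:
    """A random stop-free template whose sequenced window covers the whole
    protein (handy for exhaustive mutant enumeration)."""
    rng = np.random.default_rng(seed)
    sense = sorted(c for c, a in CODON_TO_AA.items() if a != "*")
    cds = "ATG" + "".join(rng.choice(sense) for _ in range(n_codons - 1))
    return LibraryDesign(cds, sites, (1, n_codons))


@pytest.fixture(scope="session")
def toy_design() -> LibraryDesign:
    return make_toy_design()


@pytest.fixture(scope="session")
def design() -> LibraryDesign:
    return synthetic_design()


def oracle_translate(nt: str) -> tuple[str, int | None]:
    """Independent translation oracle via Biopython: protein up to the first
    stop plus the stop's 1-based codon index (None when absent)."""
    from Bio.Seq import Seq

    trimmed = nt[: len(nt) - len(nt) % 3]
    prot = str(Seq(trimmed).translate())
    idx = prot.find("*")
    if idx == -1:
        return prot, None
    return prot[:idx], idx + 1
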