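"""Template alignment, frameshift/premature-stop calling and enrichment.

Each observed variant (a merged read covering the sequenced window of the
coding sequence) is globally aligned to the template window, classified as
full-length / premature-stop / frameshift-without-stop / unalignable, and
aggregated into positional truncation spectra and round-over-round
fold-enrichment tables.

Degenerate library positions are scored as matches for any codon of their
scheme by aligning against the window with IUPAC letters at the sites.
Indels are left-aligned so that reported positions are reproducible.
Stop positions are reported in full-protein residue numbering (the window
starts at a codon boundary, so the merged read is in frame at its start).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

import edlib

from .library import IUPAC, LibraryDesign, translate

__all__ = [
    "Alignment",
    "VariantCall",
    "TruncationSpectrum",
    "align_to_template",
    "call_variant",
    "call_round_table",
    "truncation_spectrum",
    "enrichment",
    "fold_enrichment",
]

CLASSES = ("full_length", "premature_stop", "frameshift_no_stop_in_window", "unalignable")

#: IUPAC equivalence pairs for edlib (ambiguity code matches each base).
_EQUALITIES = [(code, b) for code, bases in IUPAC.items() for b in bases if code not in "ACGT"]

_CIG = re.compile(r"(\d+)([=XID])")


@dataclass
class Alignment:
    """Global alignment of a read against the template window.

    ``ops`` is a list of (op, length) with op in {'=', 'X', 'I', 'D'}:
    'I' = base present in the read but not the template (insertion),
    'D' = template base missing from the read (deletion).
    """

    query: str
    target: str
    ops: list[tuple[str, int]]
    edit_distance: int

    @property
    def identity(self) -> float:
        return 1.0 - self.edit_distance / max(len(self.target), 1)

    @property
    def n_insertions(self) -> int:
        return sum(n for op, n in self.ops if op == "I")

    @property
    def n_deletions(self) -> int:
        return sum(n for op, n in self.ops if op == "D")

    @property
    def n_indel_events(self) -> int:
        return sum(1 for op, _ in self.ops if op in "ID")

    @property
    def net_indel(self) -> int:
        return self.n_insertions - self.n_deletions

    def aligned_pair(self) -> tuple[str, str]:
        """(query_aligned, target_aligned) with '-' gaps."""
        qa, ta = [], []
        qi = ti = 0
        for op, n in self.ops:
            if op in "=X":
                qa.append(self.query[qi : qi + n]); ta.append(self.target[ti : ti + n])
                qi += n; ti += n
            elif op == "I":
                qa.append(self.query[qi : qi + n]); ta.append("-" * n)
                qi += n
            else:
                qa.append("-" * n); ta.append(self.target[ti : ti + n])
                ti += n
        return "".join(qa), "".join(ta)


def _left_align_ops(query: str, target: str, ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Left-align indel runs in an op list.

    Works on expanded columns: a 'D' run over target bases t[a..b] slides one
    left when t[a-1] == t[b] and the preceding column is a diagonal one;
    an 'I' run over query bases q[a..b] slides when q[a-1] == q[b].
    Sliding through a diagonal column preserves the edit distance because the
    jumped base is identical.
    """
    cols = []
    for op, n in ops:
        cols.extend([op] * n)
    qpos, tpos = [], []  # query/target index consumed at each column
    qi = ti = 0
    for op in cols:
        qpos.append(qi); tpos.append(ti)
        if op in "=XI":
            qi += 1
        if op in "=XD":
            ti += 1
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(cols):
            if cols[i] not in "ID":
                i += 1
                continue
            op = cols[i]
            j = i
            while j + 1 < len(cols) and cols[j + 1] == op:
                j += 1
            while i > 0 and cols[i - 1] in "=X":
                if op == "D":
                    if target[tpos[i - 1]] != target[tpos[j]]:
                        break
                else:
                    if query[qpos[i - 1]] != query[qpos[j]]:
                        break
                # rotate: diagonal column moves to the right end of the run
                cols[i - 1 : j + 1] = [op] * (j - i + 1) + [cols[i - 1]]
                changed = True
                # recompute consumed indices for the touched span
                qi, ti = qpos[i - 1], tpos[i - 1]
                for k in range(i - 1, j + 1):
                    qpos[k], tpos[k] = qi, ti
                    if cols[k] in "=XI":
                        qi += 1
                    if cols[k] in "=XD":
                        ti += 1
                i -= 1
                j -= 1
            i = j + 1
    # re-run-length encode; recompute =/X against possibly shifted pairing
    out: list[tuple[str, int]] = []
    qi = ti = 0
    for op in cols:
        if op in "=X":
            op = "=" if _matches(query[qi], target[ti]) else "X"
            qi += 1; ti += 1
        elif op == "I":
            qi += 1
        else:
            ti += 1
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _matches(q: str, t: str) -> bool:
    return q in IUPAC.get(t, t)


def align_to_template(read_nt: str, template_window_nt: str,
                      identity_floor: float = 0.7) -> Alignment | None:
    """Global (Needleman-Wunsch) alignment of a read to the template window.

    ``template_window_nt`` may contain IUPAC ambiguity letters at degenerate
    sites; any base of the code is then scored as a match. Unit mismatch and
    linear unit gap costs; gaps are normalised leftmost. Returns None when
    alignment identity falls below ``identity_floor`` (unalignable).
    """
    if not read_nt or not template_window_nt:
        raise ValueError("empty sequence")
    res = edlib.align(read_nt, template_window_nt, task="path", mode="NW",
                      additionalEqualities=_EQUALITIES)
    ops = [(op, int(n)) for n, op in _CIG.findall(res["cigar"])]
    ops = _left_align_ops(read_nt, template_window_nt, ops)
    aln = Alignment(read_nt, template_window_nt, ops, res["editDistance"])
    if aln.identity < identity_floor:
        return None
    return aln


@dataclass
class VariantCall:
    """Per-variant classification against the library design."""

    klass: str
    stop_residue: int | None = None
    net_indel: int = 0
    substitutions: list[tuple[int, str]] = field(default_factory=list)
    gained_cys: bool = False
    n_indel_events: int = 0
    reason: str | None = None  # for unalignable: "identity" | "complex"

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if (self.stop_residue is not None) != (self.klass == "premature_stop"):
            raise ValueError("stop_residue set iff class is premature_stop")


def call_variant(aln: Alignment | None, design: LibraryDesign,
                 max_indel_events: int = 3) -> VariantCall:
    """Classify an aligned read.

    The window starts at a codon boundary, so the frame implied by the
    global alignment at the read's first base is frame 0; the read is
    translated codon-by-codon and the first stop reached within the window
    is reported in full-protein residue coordinates. ``net_indel`` is the
    signed nucleotide offset (insertions - deletions) tracked through the
    alignment; a read whose net offset is not a multiple of three but that
    reaches the window end without an in-frame stop is a frameshift without
    visible stop (the stop, if any, lies outside the sequenced window).
    """
    if aln is None:
        return VariantCall("unalignable", reason="identity")
    if aln.n_indel_events > max_indel_events:
        return VariantCall("unalignable", reason="complex",
                           net_indel=aln.net_indel, n_indel_events=aln.n_indel_events)

    wlo, _ = design.variable_window
    protein, stop_codon = translate(aln.query)
    site_index = {s.codon_index: s for s in design.sites}

    # map template codons -> read codons (gapless only) for substitution
    # records at the randomized sites
    q2t: dict[int, int] = {}
    qi = ti = 0
    for op, n in aln.ops:
        for _ in range(n):
            if op in "=X":
                q2t[ti] = qi
                qi += 1; ti += 1
            elif op == "I":
                qi += 1
            else:
                ti += 1
    substitutions: list[tuple[int, str]] = []
    for ci, site in sorted(site_index.items()):
        t0 = 3 * (ci - wlo)  # window-relative nt offset of the site codon
        if t0 < 0:
            continue
        reads = [q2t.get(t0 + k) for k in range(3)]
        if None in reads or reads[2] - reads[0] != 2:
            continue  # codon disrupted by an indel
        codon = aln.query[reads[0] : reads[0] + 3]
        tcodon = design.template_cds[3 * (ci - 1) : 3 * ci]
        if codon != tcodon:
            substitutions.append((ci, codon))

    # gained Cys: a C at a residue whose design (template aa, or scheme set
    # at a randomized site) cannot encode C — the frameshift byproduct signal
    template_protein = design.template_protein()
    gained = False
    for k, aa in enumerate(protein):
        if aa != "C":
            continue
        res = wlo + k  # nominal full-protein residue (frame-naive, k 0-based)
        allowed = set()
        if res <= len(template_protein):
            allowed.add(template_protein[res - 1])
        if res in site_index:
            allowed |= site_index[res].amino_acids()
        if "C" not in allowed:
            gained = True
            break

    common = dict(net_indel=aln.net_indel, substitutions=substitutions,
                  gained_cys=gained, n_indel_events=aln.n_indel_events)
    if stop_codon is not None:
        return VariantCall("premature_stop", stop_residue=wlo - 1 + stop_codon, **common)
    if aln.net_indel % 3 != 0:
        return VariantCall("frameshift_no_stop_in_window", **common)
    return VariantCall("full_length", **common)


def call_round_table(round_table, design: LibraryDesign,
                     identity_floor: float = 0.7,
                     max_indel_events: int = 3) -> dict[str, VariantCall]:
    """Call every unique variant sequence appearing in a RoundTable."""
    window = design.degenerate_window()
    calls: dict[str, VariantCall] = {}
    for seq in round_table.sequences():
        aln = align_to_template(seq, window, identity_floor=identity_floor)
        calls[seq] = call_variant(aln, design, max_indel_events=max_indel_events)
    return calls


@dataclass
class TruncationSpectrum:
    """Positional truncation counts per sorting round.

    ``counts``: DataFrame indexed by stop residue, one column per round, of
    reads truncated at that residue. ``totals``: per-round denominators
    (reads with a usable call). ``class_counts``: reads per class per round
    (all four classes; fractions sum to 1).
    """

    counts: pd.DataFrame
    totals: pd.Series
    class_counts: pd.DataFrame
    weighting: str = "reads"

    @property
    def fractions(self) -> pd.DataFrame:
        return self.counts / self.totals

    @property
    def total_truncated_fraction(self) -> pd.Series:
        return self.counts.sum(axis=0) / self.totals

    @property
    def class_fractions(self) -> pd.DataFrame:
        return self.class_counts / self.class_counts.sum(axis=0)


def truncation_spectrum(round_table, calls: dict[str, "VariantCall"],
                        design: LibraryDesign | None = None,
                        weighting: str = "reads") -> TruncationSpectrum:
    """Count-weighted positional truncation spectrum.

    ``weighting='reads'`` weights each sequence by its read count (default);
    ``'variants'`` counts each unique sequence once. Unalignable reads are
    excluded from the spectrum denominator but reported in
    ``class_counts``.
    """
    if weighting not in ("reads", "variants"):
        raise ValueError("weighting must be reads|variants")
    rounds = round_table.round_labels()
    positions: dict[int, dict[str, int]] = {}
    class_counts = {r: dict.fromkeys(CLASSES, 0) for r in rounds}
    totals = dict.fromkeys(rounds, 0)
    for r in rounds:
        for seq, count in round_table.counts(r).items():
            call = calls[seq]
            w = count if weighting == "reads" else 1
            class_counts[r][call.klass] += w
            if call.klass == "unalignable":
                continue
            totals[r] += w
            if call.klass == "premature_stop":
                positions.setdefault(call.stop_residue, dict.fromkeys(rounds, 0))
                positions[call.stop_residue][r] += w
    counts = pd.DataFrame.from_dict(positions, orient="index", columns=list(rounds)).fillna(0)
    counts = counts.sort_index().astype(int)
    counts.index.name = "stop_residue"
    return TruncationSpectrum(
        counts=counts,
        totals=pd.Series(totals, dtype=float),
        class_counts=pd.DataFrame(class_counts).reindex(list(CLASSES)).fillna(0).astype(int),
        weighting=weighting,
    )


def fold_enrichment(freq_input: float, freq_round: float) -> float:
    """Plain fold change of a frequency versus the input round."""
    if freq_input <= 0:
        raise ValueError("fold change undefined for zero input frequency")
    return freq_round / freq_input


def enrichment(spectrum: TruncationSpectrum, round_label: str | None = None,
               input_label: str | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Round-over-round enrichment of truncations, per position and overall.

    Rows: one per stop residue plus "any" (all truncations pooled). Fold
    change is freq_round / freq_input; confidence intervals are Wilson
    score intervals on each proportion, propagated to the fold by dividing
    opposite bounds (conservative under independence). Positions absent from
    the input round are flagged ``defined=False`` rather than infinite.
    """
    rounds = list(spectrum.totals.index)
    if len(rounds) < 2:
        raise ValueError("enrichment needs at least two rounds")
    r0 = input_label or rounds[0]
    rk = round_label or rounds[-1]
    n0, nk = spectrum.totals[r0], spectrum.totals[rk]

    rows = []
    items = [("any", spectrum.counts[r0].sum(), spectrum.counts[rk].sum())]
    items += [(pos, spectrum.counts.at[pos, r0], spectrum.counts.at[pos, rk])
              for pos in spectrum.counts.index]
    for pos, c0, ck in items:
        f0, fk = c0 / n0, ck / nk
        lo0, hi0 = proportion_confint(c0, n0, alpha=alpha, method="wilson")
        lok, hik = proportion_confint(ck, nk, alpha=alpha, method="wilson")
        defined = f0 > 0
        rows.append({
            "position": pos,
            "freq_input": f0,
            "freq_round": fk,
            "fold_change": fk / f0 if defined else np.nan,
            "ci_low": lok / hi0 if defined and hi0 > 0 else np.nan,
            "ci_high": hik / lo0 if defined and lo0 > 0 else np.inf if defined else np.nan,
            "defined": defined,
        })
    df = pd.DataFrame(rows)
    df.attrs["input_round"] = r0
    df.attrs["round"] = rk
    df.attrs["ci_method"] = "wilson"
    return df
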