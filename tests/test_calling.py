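"""Template alignment, frameshift/stop calling, spectra and enrichment."""

import numpy as np
import pytest

from libscreen.calling import (
    align_to_template,
    call_variant,
    call_round_table,
    enrichment,
    fold_enrichment,
    truncation_spectrum,
)
from libscreen.kinetics import round_sig
from libscreen.library import apply_indel, sample_variants, Variant
from libscreen.reads import dereplicate
from conftest import oracle_translate


def _call_mutant(read, design):
    aln = align_to_template(read, design.degenerate_window())
    return call_variant(aln, design)


class TestAlignToTemplate:
    def test_self_alignment_all_match(self, toy_design):
        w = toy_design.window_sequence()
        aln = align_to_template(w, toy_design.degenerate_window())
        assert aln.ops == [("=", len(w))]
        assert aln.identity == 1.0

    def test_sampled_variant_matches_degenerate_window(self, design):
        (v,) = sample_variants(design, 1, seed=4)
        aln = align_to_template(design.window_sequence(v.nt_sequence),
                                design.degenerate_window())
        assert aln.edit_distance == 0

    def test_single_deletion_is_one_leftmost_gap(self, toy_design):
        w = toy_design.window_sequence()
        # delete inside a homopolymer run so the gap position is ambiguous
        run_start = next(i for i in range(len(w) - 1) if w[i] == w[i + 1])
        read = w[: run_start + 1] + w[run_start + 2 :]  # drop 2nd base of run
        aln = align_to_template(read, toy_design.degenerate_window())
        dels = [(op, n) for op, n in aln.ops if op == "D"]
        assert dels == [("D", 1)]
        # the deletion is reported at the start of the run (leftmost)
        consumed = 0
        for op, n in aln.ops:
            if op == "D":
                break
            if op in "=X":
                consumed += n
        assert consumed == run_start

    def test_unrelated_sequence_unalignable(self, toy_design):
        rng = np.random.default_rng(9)
        junk = "".join(rng.choice(list("ACGT"), len(toy_design.template_cds)))
        assert align_to_template(junk, toy_design.degenerate_window()) is None \
            or _call_mutant(junk, toy_design).klass == "unalignable"

    def test_empty_sequence_rejected(self, toy_design):
        with pytest.raises(ValueError):
            align_to_template("", toy_design.degenerate_window())


class TestCallVariant:
    def test_error_free_member_is_full_length(self, design):
        (v,) = sample_variants(design, 1, seed=4)
        call = _call_mutant(design.window_sequence(v.nt_sequence), design)
        assert call.klass == "full_length"
        assert call.net_indel == 0
        # randomized site codons are recorded as substitutions when they
        # differ from the template codon
        assert all(1 <= ci <= design.n_codons for ci, _ in call.substitutions)

    def test_del_in_codon38_matches_translation_oracle(self, design):
        # a sampled member (site codons within their schemes) with a del1;
        # the raw template itself is not a library member
        (v,) = sample_variants(design, 1, seed=4)
        m = apply_indel(v, 3 * 37 + 2, "del1")  # inside codon 38
        read = design.window_sequence(m.nt_sequence)
        _, stop = oracle_translate(m.nt_sequence)
        call = _call_mutant(read, design)
        assert call.klass == "premature_stop"
        assert call.stop_residue == stop

    def test_compensating_indels_have_zero_net_offset(self, design):
        (v,) = sample_variants(design, 1, seed=4)
        m = apply_indel(apply_indel(v, 100, "del1"), 130, "ins1", inserted_base="G")
        read = design.window_sequence(m.nt_sequence)
        _, stop = oracle_translate(m.nt_sequence)
        call = _call_mutant(read, design)
        assert call.net_indel == 0
        expected = "premature_stop" if stop else "full_length"
        assert call.klass == expected

    def test_many_indels_binned_as_complex(self, design):
        v = Variant(design.template_cds)
        for pos in (60, 90, 120, 150):
            v = apply_indel(v, pos, "del1")
        call = _call_mutant(design.window_sequence(v.nt_sequence), design)
        assert call.klass == "unalignable"
        assert call.reason == "complex"

    def test_frameshift_gains_cys_byproduct(self, design):
        # frameshifts read Cys codons into frame before the new stop
        v = sample_variants(design, 1, seed=1)[0]
        m = apply_indel(v, 62, "del1")
        call = _call_mutant(design.window_sequence(m.nt_sequence), design)
        assert call.klass == "premature_stop"
        assert call.stop_residue == 40
        assert call.gained_cys

    def test_sampled_members_never_gain_cys(self, design):
        # NDT encodes Cys, so designed site codons are not "gained"
        for v in sample_variants(design, 20, seed=6):
            call = _call_mutant(design.window_sequence(v.nt_sequence), design)
            assert not call.gained_cys


class TestSpectrumAndEnrichment:
    def _table_and_calls(self, design, planted):
        """Build a two-round table from (sequence, count_in, count_out)."""
        table = dereplicate({
            "input": [s for s, a, _ in planted for _ in range(a)],
            "sort": [s for s, _, b in planted for _ in range(b)],
        })
        return table, call_round_table(table, design)

    def test_no_stops_gives_empty_spectrum(self, design):
        seqs = [design.window_sequence(v.nt_sequence)
                for v in sample_variants(design, 5, seed=2)]
        table, calls = self._table_and_calls(design, [(s, 2, 1) for s in seqs])
        spec = truncation_spectrum(table, calls)
        assert spec.counts.empty or (spec.counts.values == 0).all()
        assert (spec.total_truncated_fraction == 0).all()

    def test_total_equals_sum_over_positions(self, design):
        vs = sample_variants(design, 30, seed=3)
        rng = np.random.default_rng(0)
        lo, hi = design.window_nt
        planted = []
        for i, v in enumerate(vs):
            if i % 3 == 0:
                v = apply_indel(v, int(rng.integers(lo, hi + 1)), "del1")
            planted.append((design.window_sequence(v.nt_sequence), 3, 2))
        table, calls = self._table_and_calls(design, planted)
        spec = truncation_spectrum(table, calls)
        for r in ("input", "sort"):
            assert spec.total_truncated_fraction[r] == pytest.approx(
                spec.fractions[r].sum())
        # class fractions cover everything
        assert spec.class_fractions.sum(axis=0).round(12).eq(1).all()

    def test_planted_fractions_recovered_exactly(self, design):
        v0, v1 = sample_variants(design, 2, seed=1)
        stop40 = apply_indel(v0, 62, "del1")  # truncates at residue 40
        planted = [(design.window_sequence(v1.nt_sequence), 80, 50),
                   (design.window_sequence(stop40.nt_sequence), 20, 50)]
        table, calls = self._table_and_calls(design, planted)
        spec = truncation_spectrum(table, calls)
        assert spec.fractions.loc[40, "input"] == pytest.approx(0.2)
        assert spec.fractions.loc[40, "sort"] == pytest.approx(0.5)
        df = enrichment(spec)
        row = df[df.position == 40].iloc[0]
        assert row.fold_change == pytest.approx(2.5)
        assert row.ci_low < 2.5 < row.ci_high

    def test_identical_rounds_have_unit_fold(self, design):
        v0, v1 = sample_variants(design, 2, seed=8)
        stop = apply_indel(v0, 62, "del1")
        planted = [(design.window_sequence(v1.nt_sequence), 10, 10),
                   (design.window_sequence(stop.nt_sequence), 5, 5)]
        table, calls = self._table_and_calls(design, planted)
        df = enrichment(truncation_spectrum(table, calls))
        assert np.allclose(df[df.defined].fold_change, 1.0)

    def test_absent_input_position_flagged_not_infinite(self, design):
        v0, v1 = sample_variants(design, 2, seed=8)
        stop = apply_indel(v0, 62, "del1")
        planted = [(design.window_sequence(v1.nt_sequence), 10, 5),
                   (design.window_sequence(stop.nt_sequence), 0, 5)]
        table, calls = self._table_and_calls(design, planted)
        df = enrichment(truncation_spectrum(table, calls))
        row = df[df.position == 40].iloc[0]
        assert not row.defined and np.isnan(row.fold_change)

    def test_variant_weighting_differs_from_read_weighting(self, design):
        v0, v1 = sample_variants(design, 2, seed=1)
        stop = apply_indel(v0, 62, "del1")
        planted = [(design.window_sequence(v1.nt_sequence), 90, 90),
                   (design.window_sequence(stop.nt_sequence), 10, 10)]
        table, calls = self._table_and_calls(design, planted)
        by_reads = truncation_spectrum(table, calls, weighting="reads")
        by_vars = truncation_spectrum(table, calls, weighting="variants")
        assert by_reads.total_truncated_fraction["input"] == pytest.approx(0.1)
        assert by_vars.total_truncated_fraction["input"] == pytest.approx(0.5)


class TestFoldEnrichment:
    def test_published_stop_frequencies_give_1p6_fold(self):
        assert round_sig(fold_enrichment(0.17, 0.27), 2) == 1.6

    def test_zero_input_undefined(self):
        with pytest.raises(ValueError):
            fold_enrichment(0.0, 0.1)
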