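import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from mitoray.annotation import GeneFeature, MitogenomeRecord
from mitoray.codons import (
    ALL_CODONS,
    CodonError,
    STANDARD,
    VERTEBRATE_MITO,
    codon_usage_table,
    count_codons,
    enc,
    extract_codons,
    rscu,
    tabulate_start_stop,
)


def usage_tables(code):
    """Random codon-usage dictionaries over the code's sense codons."""
    sense = sorted(code.forward)
    return st.lists(
        st.integers(min_value=0, max_value=50), min_size=len(sense), max_size=len(sense)
    ).map(lambda ns: dict(zip(sense, ns)))


class TestGeneticCode:
    def test_vertebrate_mito_stop_set(self):
        assert VERTEBRATE_MITO.stop_codons == frozenset({"TAA", "TAG", "AGA", "AGG"})

    def test_vertebrate_mito_reassignments(self):
        assert VERTEBRATE_MITO.translate("ATA") == "M"
        assert VERTEBRATE_MITO.translate("TGA") == "W"

    def test_family_partition_covers_every_sense_codon_once(self):
        for code in (VERTEBRATE_MITO, STANDARD):
            members = [c for fam in code.families.values() for c in fam]
            assert sorted(members) == sorted(code.forward)

    def test_degeneracy_classes(self):
        # table 2: 12 two-fold, 6 four-fold, 2 six-fold, no singles
        assert VERTEBRATE_MITO.degeneracy_classes == {2: 12, 4: 6, 6: 2}
        # standard code keeps Met/Trp singles and three-fold Ile
        assert STANDARD.degeneracy_classes == {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}


class TestExtractCodons:
    def _record(self, seq, strand="+", name="toy"):
        feat = GeneFeature(name, "PCG", strand, 1, len(seq), start_codon="ATG", stop_codon="TAA")
        return MitogenomeRecord("r", [feat], sequence=seq if strand == "+" else seq), feat

    def test_simple_gene_with_complete_stop(self):
        rec, feat = self._record("ATGAAATAA")
        ext = extract_codons(rec, feat)
        assert ext.codons == ["ATG", "AAA", "TAA"]
        assert ext.stop_codon == "TAA" and ext.incomplete_stop is None
        assert ext.sense_codons == ["ATG", "AAA"]

    def test_691bp_gene_yields_230_codons_and_incomplete_stop(self):
        """The length-691 case: 230 complete codons, trailing T -> T(AA)."""
        seq = "ATG" + "GCC" * 229 + "T"
        assert len(seq) == 691
        rec, feat = self._record(seq)
        ext = extract_codons(rec, feat)
        assert len(ext.codons) == 230
        assert ext.incomplete_stop == "T"
        assert ext.stop_codon == "T(AA)"

    def test_two_base_remainder_reported_as_ta_a(self):
        rec, feat = self._record("ATG" + "GCC" * 3 + "TA")
        assert extract_codons(rec, feat).stop_codon == "TA(A)"

    def test_light_strand_gene_read_from_reverse_complement(self):
        # coding sequence ATG GCA TAG, stored reverse-complemented
        from mitoray.annotation import reverse_complement

        coding = "ATGGCATAG"
        genome = reverse_complement(coding)
        feat = GeneFeature("ND6", "PCG", "-", 1, 9, start_codon="ATG", stop_codon="TAG")
        rec = MitogenomeRecord("r", [feat], sequence=genome)
        ext = extract_codons(rec, feat)
        assert ext.codons == ["ATG", "GCA", "TAG"]
        assert ext.stop_codon == "TAG"

    def test_unrecognized_stop_warns_and_reports_none(self):
        rec, feat = self._record("ATGAAAGCC")
        with pytest.warns(UserWarning, match="no recognized stop"):
            ext = extract_codons(rec, feat)
        assert ext.stop_codon == "none"

    def test_internal_stop_positions_warned(self):
        rec, feat = self._record("ATGTAAAAATAA")
        with pytest.warns(UserWarning, match="internal stop"):
            ext = extract_codons(rec, feat)
        assert ext.internal_stop_positions == [2]

    def test_too_short_gene_rejected(self):
        short = GeneFeature("g", "PCG", "+", 1, 2, start_codon="ATG", stop_codon="TAA")
        with pytest.raises(CodonError):
            extract_codons(MitogenomeRecord("r", [short], sequence="AT"), short)

    def test_synthetic_genome_start_stop_table_matches_template(self, synthetic_genome):
        record, _ = synthetic_genome
        table = tabulate_start_stop(record)
        starts = [v[0] for v in table.values()]
        assert starts.count("ATG") == 12 and table["COX1"][0] == "GTG"
        assert table["ND6"][1] == "TAG"
        assert table["COX2"][1] == "T(AA)" and table["ND4"][1] == "T(AA)"


class TestRscu:
    def test_equal_usage_gives_unity(self):
        counts = {c: 5 for c in ALL_CODONS}
        values = rscu(counts, VERTEBRATE_MITO)
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_single_codon_usage_hits_degeneracy_bound(self):
        fam = VERTEBRATE_MITO.families["V"]  # four-fold
        counts = {fam[0]: 8}
        values = rscu(counts, VERTEBRATE_MITO)
        assert values[fam[0]] == pytest.approx(4.0)
        assert all(values[c] == 0.0 for c in fam[1:])

    def test_unused_family_has_absent_rscu(self):
        values = rscu({}, VERTEBRATE_MITO)
        assert all(v is None for v in values.values())

    @given(usage_tables(VERTEBRATE_MITO))
    @settings(max_examples=100, deadline=None)
    def test_family_sums_equal_degeneracy(self, counts):
        values = rscu(counts, VERTEBRATE_MITO)
        for aa, fam in VERTEBRATE_MITO.families.items():
            total = sum(counts[c] for c in fam)
            if total == 0:
                assert all(values[c] is None for c in fam)
            else:
                assert sum(values[c] for c in fam) == pytest.approx(len(fam))

    def test_hand_computed_two_gene_table(self):
        # Phe family TTT/TTC with counts 3 and 1: mean 2 -> RSCU 1.5 / 0.5
        values = rscu({"TTT": 3, "TTC": 1}, VERTEBRATE_MITO)
        assert values["TTT"] == pytest.approx(1.5)
        assert values["TTC"] == pytest.approx(0.5)


class TestEnc:
    def test_uniform_usage_reaches_the_code_maximum(self):
        counts = {c: 1000 for c in ALL_CODONS}
        assert enc(counts, STANDARD) == pytest.approx(61.0, abs=1e-9)
        assert enc(counts, VERTEBRATE_MITO) == pytest.approx(60.0, abs=1e-9)

    def test_single_codon_per_family_hits_the_floor(self):
        for code in (STANDARD, VERTEBRATE_MITO):
            counts = {fam[0]: 50 for fam in code.families.values()}
            assert enc(counts, code) == pytest.approx(code.min_enc)

    def test_insufficient_usage_is_an_error(self):
        with pytest.raises(CodonError, match="insufficient"):
            enc({}, VERTEBRATE_MITO)

    @given(usage_tables(VERTEBRATE_MITO))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_oracle_agreement(self, counts):
        try:
            value = enc(counts, VERTEBRATE_MITO)
        except CodonError:
            return
        assert 1.0 <= value <= 61.0
        assert value == pytest.approx(helpers.oracle_enc(counts, VERTEBRATE_MITO))

    def test_scale_invariance(self):
        base = {c: (i % 7) + 1 for i, c in enumerate(sorted(VERTEBRATE_MITO.forward))}
        # F is scale-free in the large-n limit; compare two large scales
        scaled = {c: 1_000_000 * n for c, n in base.items()}
        big = {c: 10_000 * n for c, n in base.items()}
        assert enc(scaled, VERTEBRATE_MITO) == pytest.approx(enc(big, VERTEBRATE_MITO), abs=0.02)

    def test_concentration_decreases_enc(self):
        """Moving usage onto fewer codons within one family lowers ENc."""
        spread = {c: 60 for c in ALL_CODONS}
        leu = VERTEBRATE_MITO.families["L"]
        concentrated = dict(spread)
        for c in leu[1:]:
            concentrated[c] = 10
        concentrated[leu[0]] = 60 + 50 * (len(leu) - 1)  # mean preserved
        assert enc(concentrated, VERTEBRATE_MITO) < enc(spread, VERTEBRATE_MITO)

    def test_biased_synthetic_genome_scores_below_unbiased(self):
        from mitoray import simulate

        biased_spec = simulate.SyntheticGenomeSpec(codon_alpha=0.2)
        uniform_spec = simulate.SyntheticGenomeSpec(codon_alpha=500.0)
        biased, _ = simulate.generate_genome(biased_spec, seed=5)
        uniform, _ = simulate.generate_genome(uniform_spec, seed=5)
        enc_biased = codon_usage_table(biased)["enc"]
        enc_uniform = codon_usage_table(uniform)["enc"]
        assert enc_biased < enc_uniform


class TestWholeGenomeTable:
    def test_codon_accounting_closes(self, synthetic_genome):
        """3 x complete codons + incomplete-stop nucleotides = PCG bp total."""
        record, _ = synthetic_genome
        table = codon_usage_table(record)
        trailing = sum(1 if v == "T(AA)" else 2 for v in table["incomplete_stops"].values())
        pcg_bp = sum(f.length() for f in record.pcgs)
        assert 3 * table["total_complete_codons"] + trailing == pcg_bp

    def test_reported_enc_in_range_and_total_codons(self, synthetic_genome):
        record, _ = synthetic_genome
        table = codon_usage_table(record)
        assert 20 <= table["enc"] <= 61
        assert table["total_complete_codons"] == 3811
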