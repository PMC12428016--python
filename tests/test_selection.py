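import random

import numpy as np
import pytest

import helpers
from mitoray import simulate
from mitoray.codons import VERTEBRATE_MITO
from mitoray.selection import SelectionError, ng86_pair, sitewise_screen


class TestNg86Pair:
    def test_identical_sequences(self):
        codons = ["ATG", "GCC", "AAA"]
        r = ng86_pair(codons, codons)
        assert r.pS == 0.0 and r.pN == 0.0
        assert r.omega is None  # dS = 0
        assert r.S + r.N == pytest.approx(3 * 3)

    def test_single_synonymous_third_position_change(self):
        """Lys codons: one AAA->AAG change is purely synonymous, and each
        AAA/AAG codon carries exactly 1/3 synonymous site."""
        a = ["AAA", "AAA", "AAA"]
        b = ["AAA", "AAA", "AAG"]
        r = ng86_pair(a, b, correct=False)
        assert r.S == pytest.approx(1.0)
        assert r.pS == pytest.approx(1.0)
        assert r.pN == pytest.approx(0.0)

    def test_symmetry(self):
        rng = random.Random(1)
        a, b = helpers.random_codon_pair(rng, VERTEBRATE_MITO, 40)
        r1, r2 = ng86_pair(a, b), ng86_pair(b, a)
        assert (r1.S, r1.N, r1.Sd, r1.Nd) == pytest.approx((r2.S, r2.N, r2.Sd, r2.Nd))

    def test_length_mismatch_rejected(self):
        with pytest.raises(SelectionError):
            ng86_pair(["AAA"], ["AAA", "AAA"])

    def test_internal_stop_rejected(self):
        with pytest.raises(SelectionError):
            ng86_pair(["TAA"], ["AAA"])

    def test_gapped_codons_pairwise_deleted(self):
        r = ng86_pair(["AAA", "---", "GCC"], ["AAA", "GGG", "GCC"])
        assert r.n_codons == 2

    def test_saturation_reports_absent_distances(self):
        # force pS towards 1 with many synonymous changes over few sites
        a = ["AAA"] * 50
        b = ["AAG"] * 50
        with pytest.warns(UserWarning, match="saturated"):
            r = ng86_pair(a, b, correct=True)
        assert r.dS is None and r.omega is None

    def test_matches_exhaustive_pathway_oracle(self):
        """Site and pathway counts agree with independent enumeration on
        random 30-codon pairs."""
        rng = random.Random(99)
        for _ in range(100):
            a, b = helpers.random_codon_pair(rng, VERTEBRATE_MITO, 30)
            r = ng86_pair(a, b, correct=False)
            S, N, Sd, Nd = helpers.oracle_ng86(a, b, VERTEBRATE_MITO)
            assert r.S == pytest.approx(S)
            assert r.N == pytest.approx(N)
            assert r.Sd == pytest.approx(Sd)
            assert r.Nd == pytest.approx(Nd)


class TestOmegaRecovery:
    def test_purifying_and_neutral_omega_recovered(self):
        """Mean NG86 omega over 20 replicate 500-codon pairs lands within
        +-0.15 of the simulated ratio (neutrality saturates slightly below
        1 because stop-neighboring changes count as nonsynonymous sites
        but are inaccessible to the simulator)."""
        code = VERTEBRATE_MITO
        for omega_true in (0.2, 1.0):
            estimates = []
            for rep in range(20):
                rng = np.random.default_rng(500 + rep)
                weights = simulate._family_codon_weights(code, 16.0, rng)
                root = simulate._sample_sense_codons(500, weights, code, rng)
                a = simulate.evolve_codons(root, 0.08, 1.0, omega_true, code, rng)
                b = simulate.evolve_codons(root, 0.08, 1.0, omega_true, code, rng)
                r = ng86_pair(a, b)
                if r.omega is not None:
                    estimates.append(r.omega)
            assert abs(np.mean(estimates) - omega_true) <= 0.15


def _alignment_from(codon_lists):
    return {taxon: "".join(codons) for taxon, codons in codon_lists.items()}


class TestSitewiseScreen:
    def test_identical_foreground_yields_no_flags(self):
        base = ["ATG", "GCC", "AAA", "TTC"] * 5
        aln = {"g1": _alignment_from({"fg": base, "b1": base, "b2": base})}
        [screen] = sitewise_screen(aln, foreground="fg")
        assert screen.flagged_codons == []
        assert screen.n_screenable == 20

    def test_planted_foreground_substitutions_flagged(self):
        """5 planted foreground-specific nonsynonymous codons: at least 4
        recovered (all, here, since the background is conserved)."""
        rng = np.random.default_rng(8)
        code = VERTEBRATE_MITO
        weights = simulate._family_codon_weights(code, 16.0, rng)
        base = simulate._sample_sense_codons(60, weights, code, rng)
        fg = list(base)
        planted = [3, 10, 25, 40, 55]
        for idx in planted:
            aa = code.forward[fg[idx]]
            other = next(c for a2, fam in code.families.items() if a2 != aa for c in fam)
            fg[idx] = other
        aln = {"g1": _alignment_from({"fg": fg, "b1": base, "b2": base, "b3": base})}
        [screen] = sitewise_screen(aln, foreground="fg")
        assert sum(1 for i in planted if i + 1 in screen.flagged_codons) >= 4

    def test_background_polymorphism_masks_site(self):
        base = ["ATG", "GCC", "AAA"] * 4
        b2 = list(base)
        b2[5] = "CTA"  # background disagrees at this codon
        fg = list(base)
        fg[5] = "TTT"
        aln = {"g1": _alignment_from({"fg": fg, "b1": base, "b2": b2})}
        [screen] = sitewise_screen(aln, foreground="fg")
        assert 6 not in screen.flagged_codons
        assert screen.n_screenable == len(base) - 1

    def test_needs_three_sequences_and_known_foreground(self):
        aln = {"g": _alignment_from({"a": ["ATG"], "b": ["ATG"]})}
        with pytest.raises(SelectionError):
            sitewise_screen(aln, foreground="a")
        with pytest.raises(SelectionError):
            sitewise_screen({"g": _alignment_from({"a": ["ATG"], "b": ["ATG"], "c": ["ATG"]})},
                            foreground="zz")

    def test_neutral_evolution_rarely_flags_genes(self):
        """Gene-level enrichment under neutral (omega = 1) evolution is
        significant in at most ~5% of gene tests."""
        code = VERTEBRATE_MITO
        significant = total = 0
        for rep in range(10):
            rng = np.random.default_rng(7000 + rep)
            weights = simulate._family_codon_weights(code, 16.0, rng)
            aln = {}
            for g in range(8):
                root = simulate._sample_sense_codons(60, weights, code, rng)
                seqs = {}
                for taxon in ("fg", "b1", "b2", "b3"):
                    seqs[taxon] = "".join(
                        simulate.evolve_codons(root, 0.03, 1.0, 1.0, code, rng)
                    )
                aln[f"gene{g}"] = seqs
            for screen in sitewise_screen(aln, foreground="fg"):
                total += 1
                significant += screen.significant
        assert significant / total <= 0.05 + 1e-9
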