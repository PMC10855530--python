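import itertools
import math

import numpy as np
import pytest

from mitocompare.codon import CODON_TO_AA, MITO_STOP_CODONS
from mitocompare.divergence import (PairwiseDivergence, SaturatedPairError,
                                    k2p_distance, k2p_from_counts,
                                    nei_gojobori_kaks, ng86_site_counts,
                                    p_distance, pairwise_counts,
                                    saturation_profile, sliding_window_pi)

SENSE_CODONS = [c for c, a in CODON_TO_AA.items() if a != "*"]


class TestCounts:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "GCGT", (4, 1, 0)),   # A<->G transition
        ("ACGT", "CCGT", (4, 0, 1)),   # A<->C transversion
        ("ACGT", "ATGT", (4, 1, 0)),   # C<->T transition
        ("ACGT", "AAGT", (4, 0, 1)),   # C<->A transversion
    ])
    def test_classification(self, a, b, expected):
        assert pairwise_counts(a, b) == expected

    def test_identical_sequences(self):
        assert pairwise_counts("A" * 100, "A" * 100) == (100, 0, 0)

    def test_pairwise_deletion(self):
        assert pairwise_counts("ACN-", "AC-T") == (2, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            pairwise_counts("ACG", "AC")


class TestK2P:
    def test_zero_divergence(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_closed_form_against_independent_oracle(self):
        # 100 sites, 10 transitions, 5 transversions
        d = k2p_from_counts(100, 10, 5)
        oracle = -0.5 * math.log((1 - 2 * 0.10 - 0.05)
                                 * math.sqrt(1 - 2 * 0.05))
        assert d == pytest.approx(oracle, abs=1e-9)
        assert d == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_raises(self):
        with pytest.raises(SaturatedPairError):
            k2p_from_counts(100, 50, 10)

    def test_correction_never_shrinks(self, rng):
        # K2P >= p-distance on 1000 random valid pairs; equality iff p = 0
        n_checked = 0
        while n_checked < 1000:
            L = 200
            a = "".join(rng.choice(list("ACGT"), size=L))
            b = list(a)
            nmut = int(rng.integers(0, 40))
            for _ in range(nmut):
                i = int(rng.integers(L))
                b[i] = rng.choice(list("ACGT"))
            b = "".join(b)
            try:
                d = k2p_distance(a, b)
            except SaturatedPairError:
                continue
            p = p_distance(a, b)
            assert d >= p - 1e-12
            if p == 0:
                assert d == 0
            else:
                assert d > p
            n_checked += 1

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(rng.choice(list("ACGT"), size=300))
        try:
            assert k2p_distance(a, b) == k2p_distance(b, a)
        except SaturatedPairError:
            pass
        assert pairwise_counts(a, b) == pairwise_counts(b, a)


class TestNG86:
    def test_identical_sequences_ratio_undefined(self):
        r = nei_gojobori_kaks("ATGGCT", "ATGGCT")
        assert r.ka == 0.0 and r.ks == 0.0 and r.ka_ks is None
        assert any("Ks = 0" in f for f in r.flags)

    def test_single_synonymous_codon_correction_undefined(self):
        # TTT vs TTC (both Phe): Sd=1 but S=1/3 -> pS=3, JC undefined
        r = nei_gojobori_kaks("TTT", "TTC")
        assert r.Sd == pytest.approx(1.0)
        assert r.S == pytest.approx(1.0 / 3.0)
        assert r.ks is None
        assert any("Ks correction undefined" in f for f in r.flags)

    def test_site_conservation_every_codon(self):
        # S + N = 3 for every sense codon of the mitochondrial code
        for c in SENSE_CODONS:
            S, N = ng86_site_counts(c)
            assert S + N == pytest.approx(3.0)

    def test_multi_difference_codon_pathway_averaging(self):
        # TTT (Phe) vs GTC (Val): 2 diffs, both orders allowed.
        # path via GTT: nonsyn (F->V) + syn (V->V); via TTC: syn + nonsyn.
        r = nei_gojobori_kaks("TTT", "GTC")
        assert r.Sd == pytest.approx(1.0)
        assert r.Nd == pytest.approx(1.0)

    def test_pathways_through_stops_excluded(self):
        # TTA (Leu) vs AGA is a stop in this code, so use TCA (Ser) vs AGA?
        # AGA is a stop codon -> codon skipped entirely.
        r = nei_gojobori_kaks("TTATTG", "AGATTG")
        assert r.codons_compared == 1  # the AGA-containing codon is skipped

    def test_codons_with_gaps_or_n_skipped(self):
        r = nei_gojobori_kaks("ATGGCTAAA", "ATGGC-AAN")
        assert r.codons_compared == 1

    def test_matches_biopython_reference_implementation(self, rng):
        from Bio.Align import Alignment, analysis
        from Bio.Data import CodonTable
        from Bio.Seq import Seq

        table = CodonTable.unambiguous_dna_by_id[2]
        for _ in range(3):
            a = "".join(rng.choice(SENSE_CODONS, size=150))
            b = list(a)
            nmut = 0
            while nmut < 45:
                i = int(rng.integers(len(a)))
                ci = i // 3
                cand = "".join(b[3 * ci : 3 * ci + 3])
                new = cand[: i % 3] + rng.choice(list("ACGT")) + cand[i % 3 + 1 :]
                if new in MITO_STOP_CODONS:
                    continue
                b[3 * ci : 3 * ci + 3] = list(new)
                nmut += 1
            b = "".join(b)
            mine = nei_gojobori_kaks(a, b)
            aln = Alignment([Seq(a), Seq(b)],
                            np.array([[0, len(a)], [0, len(a)]]))
            dn, ds = analysis.calculate_dn_ds(aln, method="NG86",
                                              codon_table=table)
            assert mine.ka == pytest.approx(dn, abs=1e-9)
            assert mine.ks == pytest.approx(ds, abs=1e-9)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(SENSE_CODONS, size=50))
        b = "".join(rng.choice(SENSE_CODONS, size=50))
        ra, rb = nei_gojobori_kaks(a, b), nei_gojobori_kaks(b, a)
        assert ra.ka == rb.ka and ra.ks == rb.ks

    def test_synonymous_only_evolution(self):
        # omega = 0: the realized nonsynonymous count is exactly zero, and
        # any nonzero Nd in the NG86 estimate is attributable purely to
        # pathway-ambiguous multi-hit codons (pairs like TTA/CTT, where one
        # minimal pathway is fully synonymous and the other is not; equal
        # pathway weighting then contributes fractional Nd)
        import itertools

        from mitocompare.synthetic import SimulationSpec, simulate_family

        def has_synonymous_path(c1, c2):
            diff = [i for i in range(3) if c1[i] != c2[i]]
            for order in itertools.permutations(diff):
                cur, ok = c1, True
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if CODON_TO_AA.get(nxt, "*") != CODON_TO_AA[cur]:
                        ok = False
                        break
                    cur = nxt
                if ok:
                    return True
            return False

        spec = SimulationSpec(seed=5, n_taxa=2, tree_height=0.3,
                              per_gene_omega={"ND1": 0.0},
                              genome_template=(("ND1", "PCG", 1500, "H"),),
                              cr_repeat_taxon=None, rearrangements=())
        genomes, truth = simulate_family(spec)
        assert truth.substitutions["ND1"]["nonsyn"] == 0
        assert truth.substitutions["ND1"]["syn"] > 0
        a = genomes[0].feature_seq(genomes[0].features[0])
        b = genomes[1].feature_seq(genomes[1].features[0])
        r = nei_gojobori_kaks(a, b)
        assert r.ks > 0.0
        assert r.ka < 0.01
        from mitocompare.divergence import _PAIR_DIFFS

        for i in range(0, len(a), 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if ca in MITO_STOP_CODONS or cb in MITO_STOP_CODONS:
                continue
            if _PAIR_DIFFS[(ca, cb)][1] > 0:
                assert has_synonymous_path(ca, cb)


class TestSlidingPi:
    def test_identical_alignment_all_zero(self):
        prof = sliding_window_pi(["ACGT" * 100] * 3)
        assert all(p == 0.0 for p in prof.pi)
        assert prof.polymorphic_sites == 0
        assert prof.overall_pi == 0.0

    def test_first_window_value_and_grid(self):
        a = "A" * 400
        b = "C" * 4 + "A" * 396  # 4 mismatches in the first 200 bp
        prof = sliding_window_pi([a, b])
        assert prof.pi[0] == pytest.approx(0.02)
        assert prof.window_bp == 200 and prof.step_bp == 25
        # windows anchored at 1, partial trailing window dropped
        assert len(prof.pi) == (400 - 200) // 25 + 1
        assert prof.midpoints[0] == 100
        assert prof.polymorphic_sites == 4

    def test_complete_column_deletion(self):
        a = "ANAA" * 100
        b = "AACA" * 100
        prof = sliding_window_pi([a, b], window=200, step=200)
        # N columns dropped everywhere; diffs at 'C' columns
        assert prof.overall_pi == pytest.approx(100 / 300)

    def test_window_longer_than_alignment_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_window_pi(["ACGT" * 10] * 2)


class TestSaturation:
    def test_identical_pair_row(self):
        df = saturation_profile({"a": "ACGT" * 50, "b": "ACGT" * 50})
        assert len(df) == 1
        row = df.iloc[0]
        assert row.distance == 0 and row.s == 0 and row.v == 0

    def test_saturated_pairs_flagged_not_dropped(self):
        df = saturation_profile({"a": "A" * 100, "b": "G" * 100,
                                 "c": "A" * 100})
        assert df.saturated.sum() >= 1
        assert len(df) == 3

    def test_monotone_on_simulated_family(self, small_family):
        genomes, _ = small_family
        from mitocompare.mito_io import concat_partition

        seqs = {g.accession: concat_partition(g, ["COI", "ND5", "Cytb"])
                for g in genomes}
        df = saturation_profile(seqs).sort_values("distance")
        # low-divergence family: transitions grow with distance overall
        s = df.s.to_numpy()
        d = df.distance.to_numpy()
        assert np.corrcoef(d, s)[0, 1] > 0.9
        assert not df.saturated.any()
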