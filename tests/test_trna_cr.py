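import numpy as np
import pytest

from mitocompare.synthetic import build_cr, build_trna
from mitocompare.trna_cr import (find_tandem_repeats, fold_cloverleaf,
                                 load_motif_library, scan_conserved_blocks)
from mitocompare.util import reverse_complement


class TestCloverleaf:
    def test_canonical_trna_all_arms_found(self, rng):
        seq = build_trna(rng, "GAA", with_dhu=True)
        f = fold_cloverleaf(seq)
        assert set(f.arms) == {"acceptor", "DHU", "anticodon", "TpsiC"}
        assert f.dhu_present
        assert not f.non_canonical
        assert f.anticodon_triplet == "GAA"

    def test_trna_without_dhu_arm(self, rng):
        # the trnS1 layout: D-domain collapsed to a connector
        seq = build_trna(rng, "GCT", with_dhu=False)
        f = fold_cloverleaf(seq)
        assert not f.dhu_present
        assert f.anticodon_triplet == "GCT"

    def test_constructed_wobble_pairs_counted(self, rng):
        seq = build_trna(rng, "TTC", with_dhu=True, n_wobble=2)
        f = fold_cloverleaf(seq)
        assert f.wobble_pairs == 2

    def test_anticodon_hint_anchors_layout(self, rng):
        seq = build_trna(rng, "TGC", with_dhu=True)
        f = fold_cloverleaf(seq, anticodon_hint="TGC")
        assert f.anticodon_triplet == "TGC"

    def test_scoring_invariants(self, rng):
        for i in range(5):
            r = np.random.default_rng(i)
            seq = build_trna(r, "CAT", with_dhu=True)
            f = fold_cloverleaf(seq)
            for arm in f.arms.values():
                assert arm.paired <= arm.stem5[1] - arm.stem5[0]
                assert arm.wobble <= arm.paired

    def test_random_sequence_flagged_non_canonical(self, rng):
        # random 70-mer is unlikely to pair 5 of 7 acceptor positions with
        # the best layout... it often does by chance, so only check the flag
        # is consistent with the reported pairing
        seq = "".join(rng.choice(list("ACGT"), size=70))
        f = fold_cloverleaf(seq)
        assert f.non_canonical == (f.arms["acceptor"].paired < 5)

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="55-95"):
            fold_cloverleaf("ACGT" * 10)


class TestConservedBlocks:
    def test_identical_crs_all_blocks_perfect(self, rng):
        cr, _ = build_cr(rng)
        blocks = scan_conserved_blocks({f"sp{i}": cr for i in range(4)})
        assert len(blocks) == 9
        for b in blocks:
            assert len(b.matches) == 4
            assert b.absent == []
            assert b.variable_columns == 0
            assert all(m.identity == 100.0 for m in b.matches.values())

    def test_planted_mutations_counted_as_variable_columns(self, rng):
        cr, ann = build_cr(rng)
        lib = load_motif_library()
        start = ann["blocks"]["CSB-E"]["start"] - 1
        flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
        # 6 distinct variable columns inside CSB-E, spread over two species
        # (as between-species variability is in real data)
        mut1, mut2 = list(cr), list(cr)
        for off in (1, 4, 7):
            mut1[start + off] = flip[mut1[start + off]]
        for off in (10, 13, 16):
            mut2[start + off] = flip[mut2[start + off]]
        crs = {"ref": cr, "mut1": "".join(mut1), "mut2": "".join(mut2)}
        blocks = {b.label: b for b in scan_conserved_blocks(crs)}
        assert blocks["CSB-E"].absent == []
        assert blocks["CSB-E"].variable_columns == 6
        assert blocks["CSB-D"].variable_columns == 0

    def test_csb_d_is_longest_central_domain(self):
        lib = load_motif_library()
        ccds = {k: v for k, v in lib.items() if k in
                ("CSB-A", "CSB-B", "CSB-C", "CSB-D", "CSB-E", "CSB-F")}
        assert max(ccds, key=lambda k: len(ccds[k])) == "CSB-D"
        assert len(lib["CSB-D"]) == 33

    def test_library_scanned_against_itself_is_exact(self):
        lib = load_motif_library()
        fake_cr = "AT".join(lib.values())
        blocks = scan_conserved_blocks({"a": fake_cr, "b": fake_cr})
        assert all(m.identity == 100.0 for b in blocks
                   for m in b.matches.values())

    def test_divergent_species_reported_absent(self, rng):
        cr, _ = build_cr(rng)
        noise = "".join(rng.choice(list("AT"), size=len(cr)))
        blocks = scan_conserved_blocks({"good": cr, "bad": noise},
                                       min_identity=0.9)
        assert any("bad" in b.absent for b in blocks)

    def test_skip_list_excludes_species(self, rng):
        cr, _ = build_cr(rng)
        blocks = scan_conserved_blocks({"a": cr, "b": cr, "weird": cr},
                                       skip=("weird",))
        assert all("weird" not in b.matches and "weird" not in b.absent
                   for b in blocks)


class TestTandemRepeats:
    def test_printed_etas_motif_two_point_seven_copies(self):
        motif = "CATATATGTATAGTAAC"
        seq = (motif * 3)[: 2 * 17 + 12]  # 2 full copies + first 12 bases
        [rep] = find_tandem_repeats(seq)
        assert rep.period == 17
        assert rep.copy_number == 2.7
        assert rep.consensus == motif
        assert rep.identity == 100.0

    def test_seeded_random_sequence_has_no_repeat(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        assert find_tandem_repeats(seq) == []

    def test_dinucleotide_run_with_small_min_period(self):
        [rep] = find_tandem_repeats("AC" * 25, min_period=2)
        assert rep.period == 2
        assert rep.copy_number == 25.0

    def test_reverse_complement_mirror(self):
        # at identity 1.0 the maximal self-match run is direction-symmetric,
        # so the detector must find the reverse-complemented consensus at
        # the mirrored location
        motif = "CATATATGTATAGTAAC"
        rng = np.random.default_rng(3)
        flank5 = "".join(rng.choice(list("ACGT"), size=60))
        flank3 = "".join(rng.choice(list("ACGT"), size=60))
        seq = flank5 + motif * 3 + flank3
        [fwd] = find_tandem_repeats(seq, min_identity=1.0)
        [rev] = find_tandem_repeats(reverse_complement(seq), min_identity=1.0)
        assert rev.period == fwd.period
        assert rev.copy_number == fwd.copy_number
        # mirrored location
        assert rev.start == len(seq) - fwd.stop + 1
        # consensus is the reverse complement up to copy rotation
        doubled = reverse_complement(fwd.consensus) * 2
        assert rev.consensus in doubled

    def test_copy_number_identity_definition(self):
        motif = "GATTACAGATCCA"  # 13 bp, min_period allows 10
        seq = motif * 4
        [rep] = find_tandem_repeats(seq, min_period=10, max_period=20)
        assert rep.copy_number == pytest.approx(
            round((rep.stop - rep.start + 1) / rep.period, 1))
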