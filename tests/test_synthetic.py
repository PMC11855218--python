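import random

import pytest

from cryptorf import (
    ConfigurationError,
    GenerationError,
    PlantSpec,
    continuity_test,
    default_code,
    find_insertion_blocks,
    flank_similarity,
    hnh_motif_scan,
    intron_signature,
    make_benchmark,
    make_host_family,
    make_intein_fixture,
    make_group2_fixture,
    make_littlee_fixture,
    make_pacc40_fixture,
    make_shilan_fixture,
    plant_hidden_orf,
    scan_hidden_orfs,
    translate,
    znf_motif_scan,
)
from cryptorf.synthetic import mutate


class TestShilanFixture:
    def test_printed_layout(self, shilan):
        insertion, truth = shilan
        assert len(insertion) == 606
        assert insertion[17:20] == "GTG"
        assert insertion[602:605] == "TAA"
        assert insertion[-4:] == "TAAC"

    def test_host_frame_202aa_seamless(self, shilan, code):
        insertion, _ = shilan
        host = translate(insertion, 0, code)
        assert len(host) == 202
        assert "*" not in host.residues

    def test_frame3_product_195aa(self, shilan, code):
        insertion, truth = shilan
        top = scan_hidden_orfs(insertion, code)[0]
        assert top.product_len_aa == 195
        assert truth.orf["product_len_aa"] == 195
        assert top.frame_index == 3

    def test_intron_signature_negative(self, shilan):
        insertion, _ = shilan
        ev = intron_signature(insertion)
        assert not ev.g_3prime and not ev.gtgcg_5prime

    def test_planted_motifs_recovered_exactly(self, shilan, code):
        insertion, truth = shilan
        product = scan_hidden_orfs(insertion, code)[0].product
        hnh = hnh_motif_scan(product)
        assert hnh.selected == (tuple(truth.motifs["hnh"]),)
        assert hnh.hits == hnh.selected  # nothing but the planted triad
        znf = znf_motif_scan(product)
        expected_pairs = {
            (tuple(a), tuple(b)) for a, b in truth.motifs["znf_pairs"]
        }
        assert {(p[0], p[1]) for p in znf.pairs} == expected_pairs

    def test_determinism(self):
        a, _ = make_shilan_fixture(seed=42)
        b, _ = make_shilan_fixture(seed=42)
        c, _ = make_shilan_fixture(seed=43)
        assert a.residues == b.residues
        assert a.residues != c.residues


class TestLittleeFixture:
    def test_first_stop_at_30(self, littlee, code):
        insertion, truth = littlee
        assert continuity_test(insertion, code).first_stop_offset_nt == 30
        assert truth.first_stop_offset_nt == 30

    def test_terminal_g(self, littlee):
        insertion, _ = littlee
        assert intron_signature(insertion).g_3prime

    def test_determinism(self):
        assert make_littlee_fixture(7)[0] == make_littlee_fixture(7)[0]

    def test_custom_offset(self, code):
        insertion, _ = make_littlee_fixture(seed=1, first_stop_offset_nt=45)
        assert continuity_test(insertion, code).first_stop_offset_nt == 45

    def test_bad_offset(self):
        with pytest.raises(ConfigurationError):
            make_littlee_fixture(seed=1, first_stop_offset_nt=31)


class TestPacc40Fixture:
    def test_160aa_product_from_483nt_span(self, pacc40, code):
        insertion, truth = pacc40
        top = scan_hidden_orfs(insertion, code)[0]
        assert top.stop_nt - top.start_nt + 1 == 483
        assert top.product_len_aa == 160
        assert top.frame_index != 1
        assert continuity_test(insertion, code).seamless


class TestPlantHiddenOrf:
    def test_random_specs_recovered_by_scanner(self, code):
        rng = random.Random(100)
        for trial in range(40):
            n_codons = rng.randrange(120, 200)
            frame = rng.choice((2, 3))
            o0 = (frame - 1) + 3 * rng.randrange(0, 5)
            product_len = rng.randrange(55, 120)
            spec = PlantSpec(
                insertion_len_nt=3 * n_codons,
                orf_start_nt=o0 + 1,
                orf_stop_nt=o0 + 3 * (product_len + 1),
                start_codon=rng.choice(("ATG", "GTG", "TTG")),
                plant_hnh=rng.random() < 0.7,
                plant_znf_pairs=rng.randrange(0, 2),
                terminal_motif=None,
            )
            insertion, truth = plant_hidden_orf(spec, seed=trial)
            top = scan_hidden_orfs(insertion, code, min_len_aa=50)[0]
            assert top.start_nt == spec.orf_start_nt
            assert top.stop_nt == spec.orf_stop_nt
            assert top.frame_index == frame
            assert top.start_codon == spec.start_codon
            assert top.product_len_aa == product_len
            assert continuity_test(insertion, code).seamless

    def test_degenerate_frame1_allowed(self, code):
        spec = PlantSpec(
            insertion_len_nt=300,
            orf_start_nt=1,
            orf_stop_nt=300,
            start_codon="ATG",
            plant_hnh=False,
            plant_znf_pairs=0,
            terminal_motif=None,
        )
        insertion, _ = plant_hidden_orf(spec, seed=0)
        top = scan_hidden_orfs(insertion, code, min_len_aa=50)[0]
        assert top.frame_index == 1 and top.start_nt == 1

    def test_invalid_span_rejected(self):
        with pytest.raises(ConfigurationError):
            PlantSpec(insertion_len_nt=300, orf_start_nt=10, orf_stop_nt=100)

    def test_conflicting_constraints_named(self):
        spec = PlantSpec(
            insertion_len_nt=606,
            orf_start_nt=18,
            orf_stop_nt=605,
            terminal_motif="GGGG",  # clashes with the TAA stop forced at 603-605
        )
        with pytest.raises(GenerationError):
            plant_hidden_orf(spec, seed=0)

    def test_determinism(self):
        spec = PlantSpec(terminal_motif=None)
        assert plant_hidden_orf(spec, seed=3)[0] == plant_hidden_orf(spec, seed=3)[0]


class TestHostFamily:
    def test_zero_divergence_uninvaded_identical(self):
        homologs, _ = make_host_family(1, 3, gene_len_aa=120, divergence=0.0, seed=0)
        seqs = {
            homologs.members[m][0].residues
            for m in homologs.uninvaded_ids
        }
        assert len(seqs) == 1

    def test_same_seed_identical_output(self):
        a, _ = make_host_family(2, 2, gene_len_aa=110, seed=5)
        b, _ = make_host_family(2, 2, gene_len_aa=110, seed=5)
        assert {m: c.residues for m, (c, _) in a.members.items()} == {
            m: c.residues for m, (c, _) in b.members.items()
        }
        assert a.alignment == b.alignment

    def test_boundary_recovery_at_low_divergence(self):
        homologs, truths = make_host_family(3, 3, gene_len_aa=140, divergence=0.05, seed=6)
        loci = find_insertion_blocks(homologs)
        got = {(l.host_id, l.aa_start, l.aa_end) for l in loci}
        expected = {(t.host_id, t.aa_start, t.aa_end) for t in truths}
        assert got == expected

    def test_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            make_host_family(0, 1)
        with pytest.raises(ConfigurationError):
            make_host_family(1, 1, gene_len_aa=50)
        with pytest.raises(ConfigurationError):
            make_host_family(1, 1, divergence=0.6)
        with pytest.raises(ConfigurationError):
            make_host_family(1, 1, flank_mimicry=0.5)  # needs inert class

    def test_mimicry_recovery(self):
        # 12 families x 3 invaded x 11 residues = 396 Bernoulli draws
        target = 0.7
        vals = []
        for fam in range(12):
            homologs, _ = make_host_family(
                3, 2, gene_len_aa=120, divergence=0.05, seed=fam,
                element_class="inert", insertion_len_nt=150, flank_mimicry=target,
            )
            for locus in find_insertion_blocks(homologs):
                head = translate(locus.insertion_nt).residues[:11]
                vals.append(flank_similarity(head, locus.c_flank_aa, 11))
        mean = sum(vals) / len(vals)
        n = len(vals) * 11
        se = 100 * (target * (1 - target) / n) ** 0.5
        assert abs(mean - 100 * target) <= 3 * se


class TestMutate:
    def test_rate_zero_is_identity(self):
        seq, _ = make_littlee_fixture(0)
        assert mutate(seq, 0.0, random.Random(0)) == seq

    def test_rate_one_changes_every_base(self):
        seq, _ = make_littlee_fixture(0)
        mutated = mutate(seq, 1.0, random.Random(0))
        assert all(a != b for a, b in zip(seq.residues, mutated.residues))

    def test_bad_rate(self):
        seq, _ = make_littlee_fixture(0)
        with pytest.raises(ConfigurationError):
            mutate(seq, 1.5, random.Random(0))


class TestBenchmark:
    def test_balanced_and_deterministic(self):
        items = make_benchmark(3, seed=9)
        assert len(items) == 12
        labels = [it.truth_label for it in items]
        for cls in ("hidden_orf", "intein_like", "group1_intron_like", "group2_intron_like"):
            assert labels.count(cls) == 3
        again = make_benchmark(3, seed=9)
        assert [it.insertion.residues for it in items] == [
            it.insertion.residues for it in again
        ]

    def test_intein_items_splice_compatible(self):
        insertion, c_flank, _ = make_intein_fixture(seed=1)
        host = translate(insertion).residues
        assert host[-1] == "N"
        assert c_flank[0] in "TSC"
        assert "*" not in host

    def test_group2_head(self):
        insertion, _ = make_group2_fixture(seed=1)
        assert insertion[:5] == "GTGCG"
        assert insertion[-1] != "G"
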