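import random
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptorf import (
    ConfigurationError,
    NucSeq,
    flank_similarity,
    group_flank_similarity,
    hnh_motif_scan,
    intein_signature,
    intron_signature,
    znf_motif_scan,
)
from cryptorf.signatures import MotifPattern, load_motif_patterns

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80)


class TestInteinSignature:
    def test_splicing_compatible_element(self):
        ev = intein_signature("TELEMENTBODYHN", "TQHHEARIQAK")
        assert ev.plus1_residue == "T" and ev.plus1_pass
        assert not ev.proline_flag
        assert ev.terminal_status == "asn"

    def test_proline_flank_flagged(self):
        ev = intein_signature("TELEMENTBODYHN", "PQHHEARIQAK")
        assert not ev.plus1_pass
        assert ev.proline_flag

    def test_ser_variant_terminus(self):
        ev = intein_signature("TELEMENTBODYS", "SQHH")
        assert ev.terminal_status == "ser_variant"

    def test_terminal_fail(self):
        assert intein_signature("TELEMENTBODYK", "TQHH").terminal_status == "fail"

    def test_empty_insertion_rejected(self):
        with pytest.raises(ValueError):
            intein_signature("", "TQHH")

    def test_missing_flank_skips_plus1(self):
        ev = intein_signature("TELEMENTBODYHN", None)
        assert ev.plus1_residue is None and ev.plus1_pass is None

    def test_motifs_found(self):
        # block_A (^[CST]), block_B (T..H) and block_G ([HG]N$) all present
        ev = intein_signature("CAATGAHLLLLLGN", "TQ")
        names = {name for name, _, _ in ev.motifs_found}
        assert {"block_A", "block_B", "block_G"} <= names

    def test_no_motifs(self):
        ev = intein_signature("AAAAAAAAAAAK", "TQ")
        assert ev.motifs_found == ()


class TestIntronSignature:
    def test_taac_terminus_is_not_group1(self, shilan):
        insertion, _ = shilan
        ev = intron_signature(insertion)
        assert not ev.g_3prime
        assert not ev.gtgcg_5prime

    def test_gtgcg_head(self):
        assert intron_signature("GTGCGAAAAA").gtgcg_5prime

    def test_terminal_g(self):
        assert intron_signature("AAAAAG").g_3prime

    def test_too_short(self):
        with pytest.raises(ValueError):
            intron_signature("ACGT")


class TestFlankSimilarity:
    def test_identical(self):
        assert flank_similarity("KLMNVWYHTSR", "KLMNVWYHTSR", 11) == 100.0

    def test_all_different(self):
        assert flank_similarity("AAAAAAAAAAA", "GGGGGGGGGGG", 11) == 0.0

    def test_counting_oracle(self):
        rng = random.Random(0)
        for _ in range(200):
            n = rng.randrange(1, 30)
            a = "".join(rng.choice("ACDEF") for _ in range(n))
            b = "".join(rng.choice("ACDEF") for _ in range(n))
            w = rng.randrange(1, n + 1)
            expected = 100.0 * sum(a[i] == b[i] for i in range(w)) / w
            assert flank_similarity(a, b, w) == pytest.approx(expected)

    @given(a=aa_text, b=aa_text)
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_case_insensitive(self, a, b):
        assert flank_similarity(a, b) == flank_similarity(b, a)
        assert flank_similarity(a.lower(), b) == flank_similarity(a, b.lower())

    def test_clips_to_shorter(self):
        assert flank_similarity("KL", "KLMNO", 5) == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            flank_similarity("", "KLM", 3)

    def test_bounds(self):
        rng = random.Random(1)
        for _ in range(50):
            a = "".join(rng.choice("AG") for _ in range(11))
            b = "".join(rng.choice("AG") for _ in range(11))
            assert 0.0 <= flank_similarity(a, b, 11) <= 100.0


class TestGroupFlankSimilarity:
    def test_single_member(self):
        out = group_flank_similarity({"invaded": [("KLM", "KLQ")]}, window=3)
        assert out["invaded"] == pytest.approx(100 * 2 / 3)

    def test_mean(self):
        pairs = [("AAAAA", "AAAGG"), ("AAAAA", "AAAAG")]  # 60% and 80%
        out = group_flank_similarity({"g": pairs}, window=5)
        assert out["g"] == pytest.approx(70.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            group_flank_similarity({"g": []})


class TestHnhScan:
    def test_planted_motif(self):
        product = "A" * 10 + "H" + "A" * 15 + "N" + "A" * 15 + "H" + "A" * 10
        scan = hnh_motif_scan(product, spacing=(10, 60, 10, 60))
        assert scan.hits == ((10, 26, 42),)
        assert scan.selected == ((10, 26, 42),)

    def test_no_histidine(self):
        assert hnh_motif_scan("AAAANAAAA").hits == ()

    def test_spacing_bounds(self):
        product = "H" + "A" * 9 + "N" + "A" * 9 + "H"  # spacings exactly 10/10
        assert hnh_motif_scan(product, spacing=(10, 60, 10, 60)).hits == ((0, 10, 20),)
        assert hnh_motif_scan(product, spacing=(11, 60, 10, 60)).hits == ()

    def test_matches_brute_force_on_dense_sequences(self):
        rng = random.Random(2)
        for _ in range(50):
            s = "".join(rng.choice("HNA") for _ in range(rng.randrange(3, 60)))
            spacing = (2, 10, 2, 10)
            expected = {
                (i, j, k)
                for i in range(len(s)) if s[i] == "H"
                for j in range(len(s)) if s[j] == "N"
                for k in range(len(s)) if s[k] == "H"
                if 2 <= j - i <= 10 and 2 <= k - j <= 10
            }
            assert set(hnh_motif_scan(s, spacing).hits) == expected

    def test_selected_hits_do_not_overlap(self):
        s = "HANAHANAHANAH"
        scan = hnh_motif_scan(s, spacing=(1, 12, 1, 12))
        spans = [(i, k) for i, _, k in scan.selected]
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert a2 > b1

    def test_coordinates_in_bounds(self):
        rng = random.Random(3)
        for _ in range(30):
            s = "".join(rng.choice("HNAG") for _ in range(40))
            for i, j, k in hnh_motif_scan(s, (1, 30, 1, 30)).hits:
                assert 0 <= i < j < k < len(s)


class TestZnfScan:
    def test_pair_within_window(self):
        product = "CAAC" + "A" * 10 + "CAAAC"
        scan = znf_motif_scan(product, pair_window=10)
        assert (0, 3) in scan.motifs and (14, 18) in scan.motifs
        assert ((0, 3), (14, 18)) in scan.pairs

    def test_pair_outside_window(self):
        product = "CAAC" + "A" * 11 + "CAAAC"
        assert znf_motif_scan(product, pair_window=10).pairs == ()

    def test_no_cysteines(self):
        scan = znf_motif_scan("AAAAAAAA")
        assert scan.motifs == () and scan.pairs == ()

    def test_matches_brute_force(self):
        rng = random.Random(4)
        for _ in range(60):
            s = "".join(rng.choice("CA") for _ in range(rng.randrange(4, 40)))
            motifs = set()
            for i in range(len(s)):
                if s[i] == "C":
                    if i + 3 < len(s) and s[i + 3] == "C":
                        motifs.add((i, i + 3))
                    if i + 4 < len(s) and s[i + 4] == "C":
                        motifs.add((i, i + 4))
            scan = znf_motif_scan(s, pair_window=6)
            assert set(scan.motifs) == motifs
            expected_pairs = {
                (m1, m2)
                for m1 in motifs
                for m2 in motifs
                if m2[0] > m1[1] and m2[0] - m1[1] - 1 <= 6
            }
            assert set(scan.pairs) == expected_pairs


class TestMotifPatterns:
    def test_bad_regex_rejected(self):
        with pytest.raises(re.error):
            MotifPattern("bad", "([")

    def test_load_from_yaml(self, tmp_path):
        path = tmp_path / "motifs.yaml"
        path.write_text(
            "- name: block_A\n  pattern: '^[CST]'\n"
            "- name: custom\n  pattern: 'W.W'\n  target: hidden_orf_product\n"
        )
        patterns = load_motif_patterns(path)
        assert [p.name for p in patterns] == ["block_A", "custom"]
        assert patterns[1].target == "hidden_orf_product"

    def test_non_list_rejected(self, tmp_path):
        path = tmp_path / "motifs.yaml"
        path.write_text("name: nope\n")
        with pytest.raises(ConfigurationError):
            load_motif_patterns(path)
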