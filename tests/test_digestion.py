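"""Lyase and heparanase engines: site rules, chemistry, conservation, confluence."""

from __future__ import annotations

import random
from collections import Counter

import pytest

from hepseq.digestion import (
    digest_combined,
    digest_heparanase,
    digest_lyase,
    heparanase_sites,
    heparanase_verdict,
    lyase_sites,
)
from hepseq.masses import MASS_H2O, neutral_mass
from hepseq.nomenclature import composition_of, parse_sequence

from conftest import random_sequence


def codes(counter: Counter) -> Counter:
    return Counter(str(composition_of(s)) for s in counter.elements())


class TestLyaseSites:
    def test_octamer_sites_blocked_next_to_anhydromannitol(self, octamer_i2s):
        sites = lyase_sites(octamer_i2s)
        assert [s.bond for s in sites] == [1, 3]  # bond 5 blocked by the aM.ol end

    def test_atbr_tetrasaccharide_fully_resistant(self):
        seq = parse_sequence("ΔU–ANAc6S–G–ANS3S6S")
        assert lyase_sites(seq) == []

    def test_disaccharides_have_no_internal_site(self):
        for text in ("I2S–ANS6S", "G–ANS3S6S", "ΔU2S–ANS6S"):
            assert lyase_sites(parse_sequence(text)) == []

    def test_enzyme_specificity_subsets(self):
        # A(NS6S)->I2S is a heparinase I site but not a heparinase III site
        seq = parse_sequence("I2S–ANS6S–I2S–ANS")
        assert [s.bond for s in lyase_sites(seq, ["hepI"])] == [1]
        assert lyase_sites(seq, ["hepIII"]) == []
        # A(NAc)->I(2OH) is heparinase III territory
        seq2 = parse_sequence("I–ANAc6S–I–ANS")
        assert [s.bond for s in lyase_sites(seq2, ["hepIII"])] == [1]
        assert lyase_sites(seq2, ["hepI"]) == []


class TestLyaseDigestion:
    def test_both_octamers_give_printed_product_set(self, octamer_g, octamer_i2s):
        result = digest_lyase([octamer_g, octamer_i2s])
        assert codes(result.products) == Counter(
            {"U2,3,0": 2, "ΔU2,3,0": 2, "ΔU4,5,0–aM.ol": 2}
        )
        # the two saturated disaccharides are structurally distinct
        sat = {s for s in result.products if str(composition_of(s)) == "U2,3,0"}
        assert sat == {parse_sequence("G–ANS3S6S"), parse_sequence("I2S–ANS6S")}
        # no tetrasulfated disaccharide in the digest
        assert "U2,4,0" not in codes(result.products)
        assert "ΔU2,4,0" not in codes(result.products)

    def test_unsaturated_product_keeps_2O_sulfate(self, octamer_i2s):
        result = digest_lyase([octamer_i2s])
        assert parse_sequence("ΔU2S–ANS6S") in result.products

    def test_mass_conservation_is_exact(self, octamer_g):
        result = digest_lyase([octamer_g])
        total = sum(neutral_mass(p) * c for p, c in result.products.items())
        assert total == pytest.approx(neutral_mass(octamer_g), abs=1e-9)


class TestHeparanaseVerdicts:
    @pytest.mark.parametrize(
        "text, verdict, rule",
        [
            ("ΔU–ANAc6S–G–ANS3S", "resist", "R1"),     # RE lacks 6-O-sulfate
            ("ΔU2S–ANS–G–ANS3S6S", "resist", "R2"),    # preceding glucosamine lacks 6S
            ("ΔU2S–ANS6S–G–ANS3S6S", "partial", "R3"), # 2-O-sulfated uronic two back
            ("ΔU–ANS6S–G–ANS3S6S", "cleave", "R4"),
        ],
    )
    def test_rule_table_ordering(self, text, verdict, rule):
        seq = parse_sequence(text)
        site = heparanase_verdict(seq, 2)
        assert (site.verdict, site.rule_id) == (verdict, rule)

    def test_terminal_g_with_no_context_cleaves(self, octamer_g):
        site = heparanase_verdict(octamer_g, 0)
        assert site.verdict == "cleave" and site.rule_id == "R4"

    def test_site_requires_unsulfated_glucuronic(self, octamer_i2s):
        assert heparanase_sites(octamer_i2s) == []
        with pytest.raises(ValueError):
            heparanase_verdict(octamer_i2s, 0)

    def test_anhydromannitol_acceptor_resists(self):
        site = heparanase_verdict(parse_sequence("I2S–ANS6S–G–aM.ol6S"), 2)
        assert site.verdict == "resist" and site.rule_id == "R0-end"


class TestHeparanaseDigestion:
    def test_terminal_monosaccharide_release(self, octamer_g):
        result = digest_heparanase([octamer_g])
        assert codes(result.products) == Counter({"U1,0,0": 1, "A7,11,0–aM.ol": 1})
        assert not result.partial_survivors

    def test_fully_sulfated_isomer_unchanged(self, octamer_i2s):
        result = digest_heparanase([octamer_i2s])
        assert result.products == Counter({octamer_i2s: 1})

    @pytest.mark.parametrize(
        "fixture, pair",
        [
            ("octamer_minor_1", {"U3,3,0", "A5,8,0–aM.ol"}),
            ("octamer_minor_2", {"U5,6,0", "A3,5,0–aM.ol"}),
        ],
    )
    def test_intrachain_g_is_partial(self, fixture, pair, request):
        parent = request.getfixturevalue(fixture)
        result = digest_heparanase([parent])
        assert set(codes(result.products)) == pair
        assert result.partial_survivors == Counter({parent: 1})

    def test_hydrolysis_adds_one_water_per_cut(self, octamer_g):
        result = digest_heparanase([octamer_g])
        cuts = sum(1 for *_, enz in result.provenance if enz.startswith("heparanase"))
        total = sum(neutral_mass(p) * c for p, c in result.products.items())
        assert total == pytest.approx(neutral_mass(octamer_g) + cuts * MASS_H2O, abs=1e-9)

    def test_two_site_hexamer_reaches_disaccharides_without_intermediates(self):
        hexamer = parse_sequence("ΔU–ANS6S–G–ANS3S6S–G–ANS3S6S")
        result = digest_heparanase([hexamer])
        assert codes(result.products) == Counter({"ΔU3,2,0": 1, "A2,3,0": 1, "A1,3,0": 1})
        # saturated glucosamine–glucuronic disaccharide, no pentasaccharide
        assert parse_sequence("ANS3S6S–G") in result.products
        assert all(len(p) < 5 for p in result.products)


class TestCombinedAndProperties:
    def test_empty_pool(self):
        result = digest_combined([], then_heparanase=True)
        assert not result.products and not result.partial_survivors

    def test_lyase_then_heparanase_removes_cleavable_tetrasaccharides(self):
        # an ATBR-bearing octamer: lyases trim to the resistant tetrasaccharide,
        # heparanase then cleaves it (6-O-sulfated glucosamines flank the G)
        parent = parse_sequence("I2S–ANS6S–I–ANS6S–G–ANS3S6S–I2S–ANS6S")
        combined = digest_combined([parent], then_heparanase=True)
        only_lyase = digest_lyase([parent])
        assert "ΔU4,5,0" in codes(only_lyase.products)
        assert "ΔU4,5,0" not in codes(combined.products)

    def test_counts_conserved_across_digests(self):
        # residue/sulfate/acetyl conservation, checked on chains that digest
        # without partial-cleavage duplication (partials emit parent AND pieces)
        rng = random.Random(7)
        pool = [
            s
            for s in (random_sequence(rng, 4, 8) for _ in range(40))
            if not digest_heparanase(digest_lyase([s]).products).partial_survivors
        ]
        assert len(pool) > 10
        result = digest_combined(pool, then_heparanase=True)
        obs = list(result.products.elements())
        assert sum(len(s) for s in obs) == sum(len(s) for s in pool)
        assert sum(s.n_sulfates for s in obs) == sum(s.n_sulfates for s in pool)
        assert sum(s.n_acetyls for s in obs) == sum(s.n_acetyls for s in pool)

    def test_fixed_point_has_no_live_sites(self):
        # each stage's fixed point is free of its own cleavable sites (a
        # heparanase cut may legitimately unblock a lyase site afterwards:
        # the sequential protocol does not re-expose products to lyases)
        rng = random.Random(11)
        pool = [random_sequence(rng, 4, 8) for _ in range(40)]
        stage1 = digest_lyase(pool)
        for product in stage1.products:
            assert lyase_sites(product) == []
        stage2 = digest_heparanase(stage1.products)
        for product in stage2.products:
            assert all(s.verdict != "cleave" for s in heparanase_sites(product))

    def test_confluence_under_randomized_order(self):
        rng = random.Random(13)
        pool = [random_sequence(rng, 4, 8) for _ in range(25)]
        reference_l = digest_lyase(pool).products
        reference_h = digest_heparanase(pool).products
        for seed in (1, 2, 3, 4, 5):
            seq_rng = random.Random(seed)
            assert digest_lyase(pool, strategy="sequential", rng=seq_rng).products == reference_l
            seq_rng = random.Random(seed + 100)
            assert (
                digest_heparanase(pool, strategy="sequential", rng=seq_rng).products
                == reference_h
            )
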