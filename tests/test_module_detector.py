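import numpy as np
import pytest

from difmod import (Replicon, call_and_label_modules, call_modules, find_orfs,
                    label_module, read_catalog, scan_replicon)
from difmod.module_detector import DifModule
from difmod.synthetic_data import (default_module_templates, mutate_site,
                                   realize_template)

from tests.conftest import make_background, plant

SENSE_CODON = "GCT"  # alanine


def orf_sequence(n_codons_total):
    """ATG + sense codons + TAA, length 3*n_codons_total."""
    return "ATG" + SENSE_CODON * (n_codons_total - 2) + "TAA"


@pytest.fixture(scope="module")
def catalog():
    return read_catalog()


@pytest.fixture(scope="module")
def catalog_map(catalog):
    return {e.name: e.reference_sequence for e in catalog}


def realized(label, catalog_map, rng):
    (tmpl,) = [t for t in default_module_templates() if t.label == label]
    return realize_template(tmpl, catalog_map, 0.4, rng)


class TestFindOrfs:
    def test_constructed_300bp_orf(self, rng):
        # 98 sense codons framed by start/stop = 100 codons = 300 bp
        seq = "CCC" + orf_sequence(100) + "CCC"
        rep = Replicon(id="orf", sequence=seq, topology="linear", category="contig")
        orfs = [o for o in find_orfs(rep, min_len=150) if o.strand == "+"]
        assert any((o.start, o.end, o.length) == (4, 303, 300) for o in orfs)

    def test_no_orfs_in_monotone_sequence(self):
        rep = Replicon(id="polyA", sequence="A" * 2000, topology="linear",
                       category="contig")
        assert find_orfs(rep, min_len=150) == []

    def test_reverse_strand_orf_coordinates(self):
        from difmod._seq import revcomp

        fwd = "CCC" + orf_sequence(60) + "CCCC"
        rep = Replicon(id="rev", sequence=revcomp(fwd), topology="linear",
                       category="contig")
        (orf,) = [o for o in find_orfs(rep, min_len=150) if o.strand == "-"]
        L = rep.length
        assert (orf.start, orf.end) == (L - 183 + 1, L - 4 + 1)
        assert orf.length == 180

    def test_wrap_orf_across_origin(self):
        body = orf_sequence(80)  # 240 bp
        # rotate so the ORF spans the origin of a circular replicon
        seq = body[100:] + "TTTT" + "C" * 300 + "TTTT" + body[:100]
        rep = Replicon(id="circ", sequence=seq, topology="circular",
                       category="plasmid")
        orfs = [o for o in find_orfs(rep, min_len=150) if o.length == 240]
        assert len(orfs) == 1
        assert orfs[0].end > rep.length  # wrap convention

    def test_planted_978bp_cargo_recovered_exactly(self, catalog_map, rng):
        seq = plant(make_background(2000, rng, circular=False),
                    catalog_map["terC"], 501)
        rep = Replicon(id="terc", sequence=seq, topology="linear",
                       category="plasmid")
        assert any(o.length == 978 and o.start == 501 and o.end == 1478
                   for o in find_orfs(rep, min_len=150))

    def test_min_len_floor_enforced(self):
        rep = Replicon(id="x", sequence="A" * 100, topology="linear",
                       category="contig")
        with pytest.raises(ValueError):
            find_orfs(rep, min_len=30)

    def test_translation_starts_with_methionine_field(self, rng):
        seq = "CC" + orf_sequence(70)
        rep = Replicon(id="tr", sequence=seq, topology="linear", category="contig")
        orf = [o for o in find_orfs(rep, min_len=150) if o.strand == "+"][0]
        assert orf.translation.startswith("M") and orf.translation.endswith("*")


class TestCallModules:
    def test_planted_terc_module_span_1221(self, catalog, catalog_map, rng):
        r = realized("terC_dif", catalog_map, rng)
        assert r.span == 1221
        seq = plant(make_background(4000, rng, circular=False), r.sequence, 1501)
        rep = Replicon(id="m", sequence=seq, topology="linear", category="plasmid")
        mods = call_and_label_modules(scan_replicon(rep), rep, catalog)
        assert len(mods) == 1
        m = mods[0]
        assert (m.start, m.end, m.length) == (1501, 2721, 1221)
        assert m.length == len(m.module_sequence)
        assert m.label == "terC_dif"

    def test_length_cap_excludes_distant_pair(self, cd_ref, rng):
        seq = make_background(40_000, rng, circular=False)
        seq = plant(seq, cd_ref, 1001)
        seq = plant(seq, cd_ref, 31_001)   # 30 kb apart
        rep = Replicon(id="far", sequence=seq, topology="linear", category="plasmid")
        assert call_modules(scan_replicon(rep), rep, max_len=20_000,
                            require_orf=False) == []

    def test_three_sites_give_two_consecutive_candidates(self, cd_ref, rng):
        seq = make_background(10_000, rng, circular=False)
        for pos in (1001, 4001, 7001):
            seq = plant(seq, cd_ref, pos)
        rep = Replicon(id="three", sequence=seq, topology="linear",
                       category="plasmid")
        mods = call_modules(scan_replicon(rep), rep, require_orf=False)
        spans = [(m.left_site.start, m.right_site.start) for m in mods]
        assert spans == [(1001, 4001), (4001, 7001)]

    def test_require_orf_drops_empty_candidates(self, cd_ref, rng):
        seq = make_background(5000, rng, circular=False)
        seq = plant(seq, cd_ref, 1001)
        seq = plant(seq, cd_ref, 2001)
        # palindromic stop-codon tiling: every frame on both strands hits TAA
        # within a few codons, so no ORF >= 150 bp can cross the interior
        interior = ("TTAATTAA" * 130)[:972]
        seq = plant(seq, interior, 1029)
        rep = Replicon(id="noorf", sequence=seq, topology="linear",
                       category="plasmid")
        assert call_modules(scan_replicon(rep), rep, require_orf=True) == []
        assert len(call_modules(scan_replicon(rep), rep, require_orf=False)) == 1

    def test_fewer_than_two_sites_no_modules(self, replicon_with_cd_site):
        sites = scan_replicon(replicon_with_cd_site)
        assert call_modules(sites, replicon_with_cd_site) == []

    def test_removing_one_flank_removes_exactly_that_module(self, catalog,
                                                            catalog_map, rng):
        r1 = realized("terC_dif", catalog_map, rng)
        r2 = realized("add_dif", catalog_map, rng)
        bg = make_background(60_000, rng, circular=False)
        seq = plant(bg, r1.sequence, 5001)
        seq = plant(seq, r2.sequence, 40_001)
        rep = Replicon(id="two", sequence=seq, topology="linear", category="plasmid")
        mods = call_and_label_modules(scan_replicon(rep), rep, catalog)
        assert sorted(m.label for m in mods) == ["add_toxin-add_antitoxin_dif",
                                                 "terC_dif"]
        # mutate the left flank of the terC module below threshold
        broken = plant(seq, mutate_site(seq[5000:5028], 9, rng), 5001)
        rep2 = Replicon(id="two", sequence=broken, topology="linear",
                        category="plasmid")
        mods2 = call_and_label_modules(scan_replicon(rep2), rep2, catalog)
        assert [m.label for m in mods2] == ["add_toxin-add_antitoxin_dif"]

    def test_circular_wrap_pair_considered(self, catalog_map, rng):
        r = realized("add_dif", catalog_map, rng)
        # background long enough that the complementary arc exceeds the cap
        bg = make_background(22_000, rng)
        whole = plant(bg, r.sequence, 1001)
        rotated = whole[1300:] + whole[:1300]   # module now spans the origin
        rep = Replicon(id="rot", sequence=rotated, topology="circular",
                       category="plasmid")
        mods = call_modules(scan_replicon(rep), rep)
        assert len(mods) == 1
        assert mods[0].length == 768
        assert mods[0].end > rep.length

    def test_overlapping_sites_rejected(self, replicon_with_cd_site):
        (site,) = scan_replicon(replicon_with_cd_site)
        from dataclasses import replace

        shifted = replace(site, start=site.start + 5, end=site.end + 5)
        with pytest.raises(ValueError, match="overlap"):
            call_modules([site, shifted], replicon_with_cd_site)


class TestLabelModule:
    def build_module(self, interior, catalog, rng, cd_ref, dc_ref):
        seq = plant(make_background(len(interior) + 2 * 28 + 2000, rng,
                                    circular=False),
                    cd_ref + interior + dc_ref, 1001)
        rep = Replicon(id="lm", sequence=seq, topology="linear", category="plasmid")
        mods = call_modules(scan_replicon(rep), rep, require_orf=False)
        assert len(mods) == 1
        return mods[0]

    def test_single_cargo_label(self, catalog, catalog_map, rng, cd_ref, dc_ref):
        m = self.build_module("GG" + catalog_map["terC"] + "CC", catalog, rng,
                              cd_ref, dc_ref)
        assert label_module(m, catalog) == "terC_dif"

    def test_two_cargo_joined_in_coordinate_order(self, catalog, catalog_map, rng,
                                                  cd_ref, dc_ref):
        m = self.build_module(catalog_map["sulP"] + "AC" + catalog_map["uspA"],
                              catalog, rng, cd_ref, dc_ref)
        assert label_module(m, catalog) == "sulP-uspA_dif"

    def test_degraded_cargo_still_matches_at_99pct(self, catalog, catalog_map, rng,
                                                   cd_ref, dc_ref):
        cargo = list(catalog_map["terC"])
        for pos in rng.choice(len(cargo), size=9, replace=False):  # ~1% divergence
            cargo[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cargo[pos]]
        m = self.build_module("".join(cargo), catalog, rng, cd_ref, dc_ref)
        assert label_module(m, catalog) == "terC_dif"

    def test_random_cargo_unlabeled(self, catalog, rng, cd_ref, dc_ref):
        m = self.build_module(make_background(900, rng, circular=False),
                              catalog, rng, cd_ref, dc_ref)
        assert label_module(m, catalog) == "unlabeled"

    def test_empty_catalog_rejected(self, catalog, catalog_map, rng, cd_ref, dc_ref):
        m = self.build_module("GG" + catalog_map["terC"] + "CC", catalog, rng,
                              cd_ref, dc_ref)
        with pytest.raises(ValueError):
            label_module(m, [])
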