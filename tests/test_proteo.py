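"""Enamel-proteome screening: PTM counting, motif, sites, AMELY."""

import pytest

from paleomolar import proteo, synth
from paleomolar.core import ValidationError


def psm(peptide, protein="ENAM_SYN", start=1, mods=(), support=None,
        blank=False):
    return proteo.PSM(peptide=peptide, protein=protein, start=start,
                      mods=list(mods),
                      site_support=dict(support or {}), is_blank=blank)


class TestPtmRate:
    def test_simple_fraction(self):
        table = [psm("ASK", mods=[(1, "Phospho")] if i < 3 else [])
                 for i in range(10)]
        # peptide contains S at position 2; phospho sits on A -> not counted
        r = proteo.ptm_rate(table, "Phospho", "S")
        assert r.pct == 0.0
        table = [psm("ASK", mods=[(2, "Phospho")] if i < 3 else [])
                 for i in range(10)]
        r = proteo.ptm_rate(table, "Phospho", "S")
        assert r.pct == pytest.approx(30.0)

    def test_undefined_when_no_target_residue(self):
        r = proteo.ptm_rate([psm("AKG")], "Phospho", "STY")
        assert r.undefined
        assert r.pct is None

    def test_matches_enumeration_oracle_on_synthetic_table(self):
        table, _ = synth.gen_psm_table(
            n_psm=400, ptm_rates={"Deamidation": ("NQ", 0.4)}, seed=17)
        r = proteo.ptm_rate(table, "Deamidation", "NQ")
        n_with = sum(1 for p in table if not p.is_blank
                     and set("NQ") & set(p.peptide))
        n_mod = sum(1 for p in table if not p.is_blank
                    and any(m == "Deamidation" and p.peptide[i - 1] in "NQ"
                            for i, m in p.mods))
        assert r.n_with_residue == n_with
        assert r.n_modified == n_mod
        assert r.pct == pytest.approx(100.0 * n_mod / n_with)
        assert abs(r.pct - 40.0) < 10.0     # binomial error band

    def test_monotone_in_added_modified_psms(self):
        table = [psm("ASK") for _ in range(5)]
        base = proteo.ptm_rate(table, "Phospho", "S").pct
        table.append(psm("ASK", mods=[(2, "Phospho")]))
        assert proteo.ptm_rate(table, "Phospho", "S").pct > base

    def test_blanks_excluded_everywhere(self):
        table, _ = synth.gen_psm_table(
            n_psm=150, ptm_rates={"Phospho": ("STY", 0.3)}, seed=4)
        before = proteo.ptm_rate(table, "Phospho", "STY")
        spiked = table + [psm("SSSS", mods=[(1, "Phospho")], blank=True)
                          for _ in range(50)]
        after = proteo.ptm_rate(spiked, "Phospho", "STY")
        assert before.pct == after.pct
        assert before.n_with_residue == after.n_with_residue


class TestPhosphoMotif:
    def test_all_sxe_contexts(self):
        table = [psm("ASAEK", mods=[(2, "Phospho")]) for _ in range(4)]
        out = proteo.phospho_motif(table)
        assert out["sxe_fraction"] == 1.0

    def test_terminal_sites_excluded_from_denominator(self):
        table = [psm("AAS", mods=[(3, "Phospho")]),      # +2 undefined
                 psm("ASAEK", mods=[(2, "Phospho")])]
        out = proteo.phospho_motif(table)
        assert out["n_phospho_s"] == 2
        assert out["n_sxe_defined"] == 1
        assert out["sxe_fraction"] == 1.0

    def test_background_frequency_without_enrichment(self):
        table, _ = synth.gen_psm_table(
            n_psm=600, ptm_rates={"Phospho": ("S", 0.5)},
            motif_enrichment=0.0, seed=23)
        out = proteo.phospho_motif(table)
        # background fraction ~ frequency of E at +2 in the toy proteome
        assert 0.0 <= out["sxe_fraction"] < 0.5

    def test_enrichment_raises_fraction(self):
        lo = proteo.phospho_motif(synth.gen_psm_table(
            n_psm=600, ptm_rates={"Phospho": ("S", 0.5)},
            motif_enrichment=0.0, seed=23)[0])["sxe_fraction"]
        hi = proteo.phospho_motif(synth.gen_psm_table(
            n_psm=600, ptm_rates={"Phospho": ("S", 0.5)},
            motif_enrichment=0.95, seed=23)[0])["sxe_fraction"]
        assert hi > lo

    def test_counts_table_covers_offsets(self):
        table = [psm("ASAEK", mods=[(2, "Phospho")])]
        out = proteo.phospho_motif(table, offsets=range(-2, 3))
        assert list(out["counts"].columns) == [-2, -1, 0, 1, 2]
        assert out["counts"].loc["S", 0] == 1

    def test_no_phospho_raises(self):
        with pytest.raises(ValidationError):
            proteo.phospho_motif([psm("AAA")])


class TestDiagnosticCoverage:
    PANEL = synth.DEFAULT_SITE_PANEL

    def test_hominin_only_sites_give_genus_call(self):
        table, _ = synth.gen_psm_table(n_psm=100,
                                       diagnostic_sites_covered=True, seed=9)
        out = proteo.diagnostic_coverage(table, self.PANEL)
        assert out["call"] == "genus Homo; within-Homo indeterminate"
        assert set(out["compatible_lineages"]) == synth.HOMO_LINEAGES

    def test_denisovan_specific_site_narrows_call(self):
        # supported observation of the Denisovan state at the within-Homo site
        table = [psm("YEPMG", protein="AMELX_SYN", start=38,
                     support={3: True})]
        # residue at protein position 40 is P -> sapiens/neanderthal state;
        # replace with S to observe the Denisovan state
        table = [psm("YESMG", protein="AMELX_SYN", start=38,
                     support={3: True})]
        out = proteo.diagnostic_coverage(table, self.PANEL)
        assert "Denisovan" in out["compatible_lineages"]
        assert "H. sapiens" not in out["compatible_lineages"]

    def test_unsupported_sites_are_excluded(self):
        table = [psm("YESMG", protein="AMELX_SYN", start=38,
                     support={3: False})]
        out = proteo.diagnostic_coverage(table, self.PANEL)
        assert out["n_resolved"] == 0
        assert out["call"].startswith("indeterminate")

    def test_conflicting_observations_flagged_and_excluded(self):
        table = [psm("YESMG", protein="AMELX_SYN", start=38,
                     support={3: True}),
                 psm("YEPMG", protein="AMELX_SYN", start=38,
                     support={3: True})]
        out = proteo.diagnostic_coverage(table, self.PANEL)
        site = [s for s in out["sites"] if s["position"] == 40][0]
        assert site["conflict"]
        assert out["n_resolved"] == 0

    def test_call_never_narrows_when_sites_removed(self):
        table, _ = synth.gen_psm_table(n_psm=50,
                                       diagnostic_sites_covered="all", seed=3)
        full = proteo.diagnostic_coverage(table, self.PANEL)
        reduced_panel = proteo.SitePanel(entries={
            k: v for k, v in list(self.PANEL.entries.items())[:2]})
        reduced = proteo.diagnostic_coverage(table, reduced_panel)
        assert set(full["compatible_lineages"]) <= \
            set(reduced["compatible_lineages"])


class TestAmelyScreen:
    def test_detection_infers_male(self):
        table, _ = synth.gen_psm_table(n_psm=30, amely_present=True, seed=1)
        out = proteo.amely_screen(table, synth.AMELY_PEPTIDES)
        assert out["amely_detected"]
        assert out["inference"] == "male"

    def test_absence_never_bare_female(self):
        table, _ = synth.gen_psm_table(n_psm=30, amely_present=False, seed=1)
        out = proteo.amely_screen(table, synth.AMELY_PEPTIDES)
        assert not out["amely_detected"]
        assert out["inference"] == "female or degraded beyond detection"
        assert out["inference"] != "female"

    def test_shared_peptides_not_counted(self):
        # a peptide present in both amelogenin isoforms is not Y-specific
        shared = "MPLPPHPGHPGYINFSYEVL"
        out = proteo.amely_screen([psm(shared, protein="AMELX_SYN")],
                                  synth.AMELY_PEPTIDES)
        assert not out["amely_detected"]

    def test_il_equivalence(self):
        ref = synth.AMELY_PEPTIDES[0]
        swapped = ref.replace("L", "I")
        out = proteo.amely_screen([psm(swapped, protein="AMELY_SYN")],
                                  synth.AMELY_PEPTIDES)
        assert out["amely_detected"]


class TestFilteringAndIO:
    def test_single_peptide_proteins_removed(self):
        table = [psm("AAAK", protein="KRT_SYN"),
                 psm("AAAK", protein="KRT_SYN"),      # same peptide twice
                 psm("PEPTA", protein="AMBN_SYN"),
                 psm("PEPTB", protein="AMBN_SYN")]
        kept = proteo.filter_psms(table)
        assert {p.protein for p in kept} == {"AMBN_SYN"}

    def test_contaminants_removed(self):
        table = [psm("PEPTA", protein="AMBN_SYN"),
                 psm("PEPTB", protein="AMBN_SYN")]
        kept = proteo.filter_psms(table, contaminants={"AMBN_SYN"})
        assert kept == []

    def test_tsv_round_trip(self, tmp_path):
        table, _ = synth.gen_psm_table(
            n_psm=40, ptm_rates={"Phospho": ("STY", 0.3)}, n_blank=5, seed=2)
        path = tmp_path / "psms.tsv"
        synth.write_psm_tsv(table, path)
        back = proteo.read_psm_tsv(path)
        assert len(back) == len(table)
        for a, b in zip(table, back):
            assert (a.peptide, a.protein, a.start, a.is_blank) == \
                (b.peptide, b.protein, b.start, b.is_blank)
            assert sorted(a.mods) == sorted(b.mods)
            assert a.site_support == b.site_support

    def test_screening_report_structure(self):
        table, _ = synth.gen_psm_table(
            n_psm=200, ptm_rates={"Phospho": ("STY", 0.3)},
            diagnostic_sites_covered=True, n_blank=10, seed=6)
        rep = proteo.screening_report(table, synth.DEFAULT_SITE_PANEL,
                                      synth.AMELY_PEPTIDES)
        assert rep["amely"]["inference"] == \
            "female or degraded beyond detection"
        assert rep["diagnostic_sites"]["call"] == \
            "genus Homo; within-Homo indeterminate"
        assert rep["n_psm_after_filter"] <= rep["n_psm_input"]
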