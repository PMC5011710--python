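"""Slippery-site scanning, frameshift gene models and the -2 alternative."""

import numpy as np
import pytest

from prfmap import (
    SimulationConfig,
    SlipperyMotif,
    Transcript,
    build_frameshift_model,
    classical_motifs,
    conceptual_minus2,
    default_motif_catalog,
    generate_transcriptome,
    peptide_monoisotopic_mass,
    scan_slippery_sites,
)
from prfmap.frameshift import FrameshiftModelError
from prfmap.genetic_code import translate_segment

from helpers import oracle_residue_mass


class TestMotifCatalog:
    def test_twelve_distinct_motifs(self):
        catalog = default_motif_catalog()
        assert len(catalog) == 12
        assert len({m.label for m in catalog}) == 12

    def test_classical_and_novel_flags(self):
        by_label = {m.label: m for m in default_motif_catalog()}
        assert by_label["AAA-UAA"].classical
        assert by_label["AAA-UAG"].classical
        assert not by_label["UUU-UAG"].classical
        assert sum(1 for m in default_motif_catalog() if m.classical) == 2

    def test_shifty_stop_is_enforced(self):
        with pytest.raises(ValueError):
            SlipperyMotif("AAA", "UGA")


class TestScan:
    def test_toy_site_position_and_next_codon(self, euplotes):
        t = Transcript("t", "AUGAAAUAAAUAA")
        sites = scan_slippery_sites(t, classical_motifs(), code=euplotes)
        assert len(sites) == 1
        s = sites[0]
        assert (s.skip_pos, s.next_codon, s.motif.label) == (6, "AAA", "AAA-UAA")

    def test_aag_next_codon_encodes_lysine(self, euplotes):
        # ...AAA UAA G...: after the skip the ribosome reads AAG (Lys)
        t = Transcript("t", "AUGGAUAAAUAAGCUCAUUAA")
        sites = scan_slippery_sites(t, code=euplotes)
        assert len(sites) == 1
        assert sites[0].next_codon == "AAG"
        assert euplotes.codon_to_aa["AAG"] == "K"

    def test_no_in_frame_stop_gives_no_sites(self, euplotes):
        t = Transcript("t", "AUGGCUGCUGCUGCU")
        assert scan_slippery_sites(t, code=euplotes) == []

    def test_short_transcript_is_empty_not_error(self, euplotes):
        assert scan_slippery_sites(Transcript("t", "AUGAA"), code=euplotes) == []

    def test_out_of_frame_motif_is_ignored_when_tracking(self, euplotes):
        # AAA-UAA present but shifted out of the tracked frame
        t = Transcript("t", "AUGCAAAUAAGGGUAA")
        tracked = scan_slippery_sites(t, frame_tracking=True, code=euplotes)
        naive = scan_slippery_sites(t, frame_tracking=False, code=euplotes)
        assert tracked == []
        assert [s.skip_pos for s in naive] == [7]

    def test_terminal_stop_without_continuation_is_not_a_site(self, euplotes):
        # ends ...AAA UAA with nothing after the stop: no +1 codon to read
        t = Transcript("t", "AUGGCUAAAUAA")
        assert scan_slippery_sites(t, code=euplotes) == []

    def test_two_site_transcript(self, toy_two_site_transcript, euplotes):
        sites = scan_slippery_sites(toy_two_site_transcript, code=euplotes)
        assert [s.skip_pos for s in sites] == [30, 61]
        assert [s.next_codon for s in sites] == ["AAG", "AAU"]

    def test_empty_motif_set_is_an_error(self, euplotes):
        with pytest.raises(ValueError):
            scan_slippery_sites(Transcript("t", "AUGAAAUAAAUAA"), set(), code=euplotes)


class TestBuildModel:
    def test_toy_gene_junction_and_protein(self, euplotes):
        # AUG GCU AAA |UAA -> resume at AAA GCU GAU...
        t = Transcript("t", "AUGGCUAAAUAAAGCUGAUAA")
        sites = scan_slippery_sites(t, code=euplotes)
        m = build_frameshift_model(t, sites, euplotes)
        assert m.protein == "MAKKAD"
        assert m.junctions == (2,)
        assert m.frame_of_residue == (0, 0, 0, 1, 1, 1)

    def test_no_sites_is_plain_translation(self, euplotes):
        from prfmap import translate_frame

        t = Transcript("t", "AUGGCUGAUUAAGGG")
        m = build_frameshift_model(t, [], euplotes)
        assert m.junctions == ()
        assert m.protein == translate_frame(t, 0, euplotes, "halt")

    def test_two_sites_give_three_frame_segments(
        self, toy_two_site_transcript, euplotes
    ):
        t = toy_two_site_transcript
        m = build_frameshift_model(t, scan_slippery_sites(t, code=euplotes), euplotes)
        assert m.n_junctions == 2
        assert m.segment_frames() == (0, 1, 2)
        assert m.protein == "M" + "A" * 8 + "K" + "K" + "D" * 8 + "K" + "N" + "V" * 8

    def test_segment_retranslation_round_trip(self, euplotes):
        cfg = SimulationConfig(n_genes=40, seed=3)
        transcripts, _ = generate_transcriptome(cfg, euplotes)
        for t in transcripts:
            sites = scan_slippery_sites(t, code=euplotes)
            m = build_frameshift_model(t, sites, euplotes)
            starts = [0] + [s.skip_pos + 1 for s in sites]
            ends = [s.skip_pos for s in sites] + [None]
            offset = 0
            for start, end in zip(starts, ends):
                seg = translate_segment(
                    t.seq, start, euplotes,
                    end=end if end is not None else len(t.seq),
                )
                assert m.protein[offset : offset + len(seg)] == seg
                offset += len(seg)
            assert offset == len(m.protein)

    def test_inconsistent_site_is_rejected(self, euplotes):
        t = Transcript("t", "AUGGCUAAAUAAAGCUGAUAA")
        good = scan_slippery_sites(t, code=euplotes)[0]
        from dataclasses import replace

        bad = replace(good, skip_pos=6)
        with pytest.raises(FrameshiftModelError):
            build_frameshift_model(t, [bad], euplotes)


class TestJunctionResiduePairs:
    @pytest.mark.parametrize(
        "after_stop, expected_pair",
        [("G", ("K", "K")), ("C", ("K", "N")), ("A", ("K", "K"))],
    )
    def test_aaa_uaa_contexts(self, euplotes, after_stop, expected_pair):
        t = Transcript("t", "AUGGCUAAAUAA" + after_stop + "GCUCAUGGGUAA")
        m = build_frameshift_model(t, scan_slippery_sites(t, code=euplotes), euplotes)
        j = m.junctions[0]
        assert (m.protein[j], m.protein[j + 1]) == expected_pair


class TestConceptualMinus2:
    def test_aaa_uaa_context_inserts_asparagine(self, euplotes):
        t = Transcript("t", "AUGGCUAAAUAAAGCUGAUAA")
        site = scan_slippery_sites(t, code=euplotes)[0]
        prod = conceptual_minus2(site, t, euplotes)
        assert prod.extra_residue == "N"
        assert prod.mass_delta == pytest.approx(114.04293, abs=1e-5)

    def test_aaa_uag_context_also_asparagine(self, euplotes):
        t = Transcript("t", "AUGGCUAAAUAGUGAUCAUAA")
        site = scan_slippery_sites(t, code=euplotes)[0]
        assert conceptual_minus2(site, t, euplotes).extra_residue == "N"

    def test_mass_gap_exceeds_100da_for_all_classical_contexts(self, euplotes):
        for stop in ("UAA", "UAG"):
            for nxt in "ACGU":
                t = Transcript("t", "AUGGCUAAA" + stop + nxt + "CUCAUGGGUAA")
                site = scan_slippery_sites(t, classical_motifs(), code=euplotes)[0]
                assert conceptual_minus2(site, t, euplotes).mass_delta > 100.0

    def test_delta_matches_peptide_mass_additivity(self, euplotes):
        """mass(product with extra residue) - mass(product) == residue mass."""
        t = Transcript("t", "AUGGCUAAAUAAAGCUGAUAA")
        site = scan_slippery_sites(t, code=euplotes)[0]
        prod = conceptual_minus2(site, t, euplotes)
        plus1 = "KKAD"   # junction-spanning stretch under +1
        minus2 = "K" + prod.extra_residue + "KAD"
        delta = peptide_monoisotopic_mass(minus2) - peptide_monoisotopic_mass(plus1)
        assert delta == pytest.approx(prod.mass_delta, abs=1e-9)
        assert prod.mass_delta == pytest.approx(
            oracle_residue_mass(prod.extra_residue), abs=1e-6
        )


def test_scan_recovers_exactly_the_planted_sites(euplotes):
    """Perfect recall and precision on the synthetic transcriptome."""
    cfg = SimulationConfig(n_genes=300, seed=9)
    transcripts, truth = generate_transcriptome(cfg, euplotes)
    assert any(truth.genes[t.id].prf for t in transcripts)
    for t in transcripts:
        sites = scan_slippery_sites(t, code=euplotes)
        g = truth.genes[t.id]
        assert tuple(s.skip_pos for s in sites) == g.skip_positions
        assert tuple(s.motif.label for s in sites) == g.motif_labels
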