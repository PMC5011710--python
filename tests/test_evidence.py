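"""Peptide mapping, evidence classes a-d, localization and +1 vs -2 calls."""

import pytest

from prfmap import (
    Transcript,
    build_frameshift_model,
    classify_protein,
    conceptual_minus2,
    discriminate_direction,
    localize_site,
    map_peptide,
    peptide_monoisotopic_mass,
    scan_slippery_sites,
    summarize,
    summary_from_counts,
)
from prfmap.digestion import PeptideRecord
from prfmap.evidence import DOWNSTREAM, SPANNING, UPSTREAM


def _pep_on(model, start, end, enzyme="gluc"):
    return PeptideRecord(
        sequence=model.protein[start:end],
        protein_id=model.transcript_id,
        start=start,
        end=end,
        missed_cleavages=0,
        enzyme=enzyme,
    )


@pytest.fixture()
def one_site_model(euplotes):
    # protein MAKKAD, junction at residue 2 (K|K)
    t = Transcript("g1", "AUGGCUAAAUAAAGCUGAUAA")
    m = build_frameshift_model(t, scan_slippery_sites(t, code=euplotes), euplotes)
    return t, m


@pytest.fixture()
def two_site_model(toy_two_site_transcript, euplotes):
    t = toy_two_site_transcript
    m = build_frameshift_model(t, scan_slippery_sites(t, code=euplotes), euplotes)
    return t, m


class TestMapPeptide:
    def test_relations_around_a_single_junction(self, one_site_model):
        _, m = one_site_model
        j = m.junctions[0]
        assert map_peptide(_pep_on(m, j - 1, j + 2), m).relation_per_junction == (SPANNING,)
        assert map_peptide(_pep_on(m, 0, j + 1), m).relation_per_junction == (UPSTREAM,)
        assert map_peptide(_pep_on(m, j + 1, j + 3), m).relation_per_junction == (DOWNSTREAM,)

    def test_peptide_ending_exactly_at_junction_is_upstream(self, one_site_model):
        _, m = one_site_model
        j = m.junctions[0]
        mp = map_peptide(_pep_on(m, 0, j + 1), m)  # last residue is j itself
        assert mp.relation_per_junction == (UPSTREAM,)

    def test_covered_frames_follow_annotation(self, one_site_model):
        _, m = one_site_model
        j = m.junctions[0]
        assert map_peptide(_pep_on(m, j, j + 2), m).covered_frames == {0, 1}
        assert map_peptide(_pep_on(m, 0, j), m).covered_frames == {0}

    def test_middle_peptide_relates_differently_to_each_junction(self, two_site_model):
        _, m = two_site_model
        j1, j2 = m.junctions
        mp = map_peptide(_pep_on(m, j1 + 2, j2), m)
        assert mp.relation_per_junction == (DOWNSTREAM, UPSTREAM)

    def test_sequence_mismatch_is_rejected(self, one_site_model):
        _, m = one_site_model
        bad = PeptideRecord(
            sequence="WWWWW", protein_id=m.transcript_id,
            start=0, end=5, missed_cleavages=0, enzyme="gluc",
        )
        with pytest.raises(ValueError):
            map_peptide(bad, m)


class TestClassify:
    def test_spanning_gives_class_a(self, one_site_model):
        _, m = one_site_model
        j = m.junctions[0]
        ev = classify_protein([map_peptide(_pep_on(m, j - 1, j + 2), m)], m)
        assert ev.evidence_class == "a"
        assert ev.spanning_count == 1

    def test_both_sides_without_spanning_is_class_b(self, one_site_model):
        _, m = one_site_model
        j = m.junctions[0]
        maps = [map_peptide(_pep_on(m, 0, j), m), map_peptide(_pep_on(m, j + 1, j + 3), m)]
        assert classify_protein(maps, m).evidence_class == "b"

    def test_downstream_only_is_class_c(self, one_site_model):
        _, m = one_site_model
        j = m.junctions[0]
        maps = [map_peptide(_pep_on(m, j + 1, j + 3), m)]
        assert classify_protein(maps, m).evidence_class == "c"

    def test_upstream_only_is_class_d(self, one_site_model):
        _, m = one_site_model
        j = m.junctions[0]
        maps = [map_peptide(_pep_on(m, 0, j), m)]
        assert classify_protein(maps, m).evidence_class == "d"

    def test_no_peptides_is_class_none(self, one_site_model):
        _, m = one_site_model
        assert classify_protein([], m).evidence_class == "none"

    def test_model_without_junctions_is_never_classified(self, euplotes):
        t = Transcript("g0", "AUGGCUGAUCAUUAA")
        m = build_frameshift_model(t, [], euplotes)
        ev = classify_protein([map_peptide(_pep_on(m, 0, 4), m)], m)
        assert ev.evidence_class == "none"

    def test_one_spanning_junction_suffices_on_two_site_model(self, two_site_model):
        _, m = two_site_model
        j1 = m.junctions[0]
        ev = classify_protein([map_peptide(_pep_on(m, j1 - 2, j1 + 2), m)], m)
        assert ev.evidence_class == "a"

    def test_classes_partition_evidenced_models(self, small_study):
        evidenced = [ev for ev in small_study.evidences]
        prf_models = [ev for ev in evidenced if ev.evidence_class in "abcd"]
        junction_ids = {
            m.transcript_id for m in small_study.models if m.n_junctions
        }
        for ev in evidenced:
            if ev.model_id in junction_ids:
                assert ev.evidence_class in "abcd"
            else:
                assert ev.evidence_class == "none"
        counts = small_study.summary.class_counts
        assert sum(counts.values()) == len(prf_models)


class TestLocalize:
    def test_spanning_peptide_pinpoints_site_and_direction(self, one_site_model):
        t, m = one_site_model
        j = m.junctions[0]
        mp = map_peptide(_pep_on(m, j - 1, j + 2), m)
        [(site, direction)] = localize_site(mp, m, t)
        assert site.skip_pos == 9          # the "U" of the AAA-UAA motif
        assert direction == "+1"
        assert (m.protein[j], m.protein[j + 1]) == ("K", "K")

    def test_non_spanning_mapping_is_a_precondition_error(self, one_site_model):
        t, m = one_site_model
        mp = map_peptide(_pep_on(m, 0, m.junctions[0]), m)
        with pytest.raises(ValueError):
            localize_site(mp, m, t)

    def test_each_spanned_junction_is_localized(self, two_site_model):
        t, m = two_site_model
        j1, j2 = m.junctions
        mp = map_peptide(_pep_on(m, j1 - 1, j2 + 2), m)
        sites = localize_site(mp, m, t)
        assert [s.skip_pos for s, _ in sites] == [30, 61]
        assert all(d == "+1" for _, d in sites)


class TestDiscriminateDirection:
    def test_observed_plus1_mass_calls_plus1(self, one_site_model):
        t, m = one_site_model
        j = m.junctions[0]
        pep = _pep_on(m, j - 1, j + 2)
        call = discriminate_direction(
            peptide_monoisotopic_mass(pep), pep, 0, m, t
        )
        assert call.call == "+1"

    def test_asn_shifted_mass_calls_minus2(self, one_site_model):
        t, m = one_site_model
        j = m.junctions[0]
        pep = _pep_on(m, j - 1, j + 2)
        call = discriminate_direction(
            peptide_monoisotopic_mass(pep) + 114.04293, pep, 0, m, t
        )
        assert call.call == "-2"
        assert call.minus2_mass - call.plus1_mass == pytest.approx(114.04293, abs=1e-5)

    def test_never_ambiguous_at_classical_sites(self, one_site_model, rng):
        t, m = one_site_model
        site = m.sites[0]
        delta = conceptual_minus2(site, t).mass_delta
        assert delta > 100
        j = m.junctions[0]
        pep = _pep_on(m, j - 1, j + 2)
        base = peptide_monoisotopic_mass(pep)
        for _ in range(50):
            ppm = float(rng.uniform(-20, 20))
            call = discriminate_direction(base * (1 + ppm * 1e-6), pep, 0, m, t)
            assert call.call == "+1"


class TestSummarize:
    def test_published_style_counts(self):
        s = summary_from_counts({"a": 6, "b": 81, "c": 74, "d": 65}, 2842)
        assert s.prf_protein_count == 226
        assert s.prf_percent == 8.0
        assert s.prf_percent_int == 8

    def test_empty_input_gives_zero_table(self):
        s = summarize([], 0)
        assert s.prf_protein_count == 0
        assert s.total_proteins == 0
        assert s.prf_percent == 0.0

    def test_total_smaller_than_prf_count_rejected(self):
        with pytest.raises(ValueError):
            summary_from_counts({"a": 5}, 3)

    def test_fraction_invariant_to_input_order(self, small_study):
        import random

        evs = list(small_study.evidences)
        random.Random(0).shuffle(evs)
        models = {m.transcript_id: m for m in small_study.models}
        s1 = summarize(evs, len(evs), models)
        s2 = small_study.summary
        assert s1.to_dict() == s2.to_dict()
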