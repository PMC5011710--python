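"""End-to-end orchestration: predict → digest → search → classify → report.

The stages are plain functions over in-memory objects; file I/O lives
at the edges so the same code path serves the CLI, the test suite and
fully synthetic studies.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import io as pio
from .digestion import (
    CARBAMIDOMETHYL_C,
    OXIDATION_M,
    PeptideRecord,
    apply_modifications,
    default_enzymes,
    digest,
    get_enzyme,
    peptide_monoisotopic_mass,
)
from .evidence import (
    ProteinEvidence,
    ShiftDirectionCall,
    Summary,
    classify_protein,
    discriminate_direction,
    localize_site,
    map_peptide,
    summarize,
)
from .frameshift import (
    FrameshiftGeneModel,
    build_frameshift_model,
    classical_motifs,
    default_motif_catalog,
    scan_slippery_sites,
)
from .genetic_code import GeneticCode, Transcript, build_euplotes_code
from .matching import (
    ObservedSpectrum,
    PeptideDatabase,
    SpectrumMatch,
    build_decoys,
    fdr_partition,
    match_spectrum,
)
from .simulate import (
    SimulationConfig,
    SyntheticTruth,
    generate_transcriptome,
    simulate_detection,
    simulate_spectra,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StudyResult",
    "predict_models",
    "build_search_database",
    "search_spectra",
    "classify_models",
    "run_synthetic_study",
    "run_pipeline",
    "render_report",
    "write_sites_tsv",
    "write_segments_gff3",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Search and classification parameters.

    Defaults mirror the study conditions: the trypsin/GluC/chymotrypsin
    panel, 20 ppm precursor and 0.1 Da fragment tolerances, q = 0.01
    peptide- and protein-level FDR, up to 2 missed cleavages, fixed
    carbamidomethyl(C) and variable oxidation(M).
    """

    enzymes: tuple[str, ...] = ("trypsin", "gluc", "chymotrypsin")
    ppm_tol: float = 20.0
    frag_tol_da: float = 0.1
    fdr_q: float = 0.01
    min_len: int = 6
    max_len: int = 50
    max_missed: int = 2
    max_variable_mods: int = 2
    motif_catalog: str = "default"  # "default" | "classical"
    max_sites: int = 3
    seed: int = 0

    def motifs(self):
        if self.motif_catalog == "classical":
            return classical_motifs()
        if self.motif_catalog == "default":
            return default_motif_catalog()
        raise ValueError(f"unknown motif catalog {self.motif_catalog!r}")


def predict_models(
    transcripts: Sequence[Transcript],
    cfg: PipelineConfig | None = None,
    code: GeneticCode | None = None,
) -> list[FrameshiftGeneModel]:
    """Scan every transcript for slippery sites and build joined models."""
    cfg = cfg or PipelineConfig()
    code = code or build_euplotes_code()
    motifs = cfg.motifs()
    models = []
    for t in transcripts:
        sites = scan_slippery_sites(t, motifs, code=code, max_sites=cfg.max_sites)
        models.append(build_frameshift_model(t, sites, code))
    return models


def build_search_database(
    models: Sequence[FrameshiftGeneModel],
    cfg: PipelineConfig | None = None,
) -> tuple[PeptideDatabase, dict[str, set[str]]]:
    """Digest target + reversed-decoy proteins into a mass-indexed DB.

    Returns the database and a map from peptide sequence to the set of
    *target* models containing it (used to exclude shared peptides
    from classification).
    """
    cfg = cfg or PipelineConfig()
    targets = [(m.transcript_id, m.protein) for m in models if m.protein]
    decoys = build_decoys(targets)
    enzymes = [get_enzyme(n, max_missed=cfg.max_missed) for n in cfg.enzymes]

    records: list[PeptideRecord] = []
    peptide_to_models: dict[str, set[str]] = {}
    for pid, protein in targets + decoys:
        is_target = not pid.startswith("DECOY_")
        for enz in enzymes:
            for pep in digest(
                protein, enz, cfg.min_len, cfg.max_len, protein_id=pid
            ):
                if is_target:
                    peptide_to_models.setdefault(pep.sequence, set()).add(pid)
                records.extend(
                    apply_modifications(
                        pep,
                        fixed=(CARBAMIDOMETHYL_C,),
                        variable=(OXIDATION_M,),
                        max_variable=cfg.max_variable_mods,
                    )
                )
    return PeptideDatabase(records), peptide_to_models


def search_spectra(
    spectra: Sequence[ObservedSpectrum],
    db: PeptideDatabase,
    cfg: PipelineConfig | None = None,
) -> list[SpectrumMatch]:
    """Match every spectrum against the database (best hit per spectrum)."""
    cfg = cfg or PipelineConfig()
    matches = []
    for obs in spectra:
        m = match_spectrum(obs, db, ppm_tol=cfg.ppm_tol, frag_tol_da=cfg.frag_tol_da)
        if m is not None:
            matches.append(m)
    return matches


def classify_models(
    accepted: Sequence[SpectrumMatch],
    models: Sequence[FrameshiftGeneModel],
    peptide_to_models: Mapping[str, set[str]],
    transcripts: Mapping[str, Transcript],
    cfg: PipelineConfig | None = None,
) -> tuple[list[ProteinEvidence], list[dict]]:
    """Map accepted peptides onto models and classify each model.

    Peptides whose sequence occurs in more than one model are excluded
    (unique-peptide accounting).  Returns the evidence list (one entry
    per model with >= 1 unique accepted peptide) and, for every
    spanning peptide, a localization/direction record.
    """
    cfg = cfg or PipelineConfig()
    model_by_id = {m.transcript_id: m for m in models}
    by_model: dict[str, dict[tuple, PeptideRecord]] = {}
    observed_mass: dict[tuple, float] = {}
    for match in accepted:
        pep = match.peptide
        if len(peptide_to_models.get(pep.sequence, ())) != 1:
            continue
        key = (pep.protein_id, pep.start, pep.end, pep.sequence)
        by_model.setdefault(pep.protein_id, {})[key] = pep
        obs_mass = peptide_monoisotopic_mass(pep) * (
            1.0 + match.precursor_error_ppm * 1e-6
        )
        observed_mass[key] = obs_mass

    evidences: list[ProteinEvidence] = []
    localizations: list[dict] = []
    for model_id, peps in sorted(by_model.items()):
        model = model_by_id[model_id]
        mappings = [map_peptide(p, model) for p in peps.values()]
        ev = classify_protein(mappings, model)
        evidences.append(ev)
        t = transcripts[model_id]
        for mp in mappings:
            if not mp.spans_any:
                continue
            for (site, direction), k in zip(
                localize_site(mp, model, t), mp.spanned_junctions()
            ):
                key = (
                    mp.peptide.protein_id,
                    mp.peptide.start,
                    mp.peptide.end,
                    mp.peptide.sequence,
                )
                call = discriminate_direction(
                    observed_mass[key],
                    mp.peptide,
                    k,
                    model,
                    t,
                    ppm_tol=cfg.ppm_tol,
                )
                localizations.append(
                    {
                        "model_id": model_id,
                        "junction_index": k,
                        "skip_pos": site.skip_pos,
                        "motif": site.motif.label,
                        "peptide": mp.peptide.sequence,
                        "sequence_direction": direction,
                        "mass_call": call.call,
                        "plus1_mass": call.plus1_mass,
                        "minus2_mass": call.minus2_mass,
                        "observed_mass": call.observed_mass,
                    }
                )
    return evidences, localizations


@dataclass
class StudyResult:
    """Everything a synthetic end-to-end run produces."""

    transcripts: list[Transcript]
    models: list[FrameshiftGeneModel]
    truth: SyntheticTruth
    spectra: list[ObservedSpectrum]
    accepted: list[SpectrumMatch]
    accepted_decoys: list[SpectrumMatch]
    evidences: list[ProteinEvidence]
    localizations: list[dict]
    summary: Summary
    peptide_to_models: dict[str, set[str]]

    @property
    def decoy_fraction(self) -> float:
        n_t, n_d = len(self.accepted), len(self.accepted_decoys)
        return n_d / n_t if n_t else 0.0

    def planted_detected_fraction(self) -> tuple[float, int]:
        """Truth-side detected PRF fraction under the same unique-peptide
        accounting the classifier uses; returns (fraction, n_detected)."""
        detected_genes: set[str] = set()
        for rec in self.truth.spectra.values():
            if len(self.peptide_to_models.get(rec.peptide, ())) == 1:
                detected_genes.add(rec.protein_id)
        if not detected_genes:
            return 0.0, 0
        n_prf = sum(1 for g in detected_genes if self.truth.genes[g].prf)
        return n_prf / len(detected_genes), len(detected_genes)


def run_synthetic_study(
    sim_cfg: SimulationConfig,
    pipe_cfg: PipelineConfig | None = None,
) -> StudyResult:
    """Generate a synthetic study and push it through the full pipeline."""
    pipe_cfg = pipe_cfg or PipelineConfig(seed=sim_cfg.seed)
    code = build_euplotes_code()

    t0 = time.perf_counter()
    transcripts, truth = generate_transcriptome(sim_cfg, code)
    models = predict_models(transcripts, pipe_cfg, code)
    enzymes = [get_enzyme(n, max_missed=pipe_cfg.max_missed) for n in pipe_cfg.enzymes]
    detected = simulate_detection(
        models, sim_cfg, truth, enzymes,
        min_len=pipe_cfg.min_len, max_len=pipe_cfg.max_len,
    )
    spectra = simulate_spectra(detected, sim_cfg, truth)
    logger.info(
        "simulated %d genes -> %d spectra in %.1fs",
        sim_cfg.n_genes, len(spectra), time.perf_counter() - t0,
    )

    db, peptide_to_models = build_search_database(models, pipe_cfg)
    matches = search_spectra(spectra, db, pipe_cfg)
    accepted, accepted_decoys = fdr_partition(matches, pipe_cfg.fdr_q)
    logger.info(
        "searched %d spectra against %d candidates: %d accepted (%d decoys)",
        len(spectra), len(db), len(accepted), len(accepted_decoys),
    )

    tmap = {t.id: t for t in transcripts}
    evidences, localizations = classify_models(
        accepted, models, peptide_to_models, tmap, pipe_cfg
    )
    total = len(evidences)
    model_map = {m.transcript_id: m for m in models}
    summary = summarize(evidences, total, model_map)
    return StudyResult(
        transcripts=transcripts,
        models=models,
        truth=truth,
        spectra=spectra,
        accepted=accepted,
        accepted_decoys=accepted_decoys,
        evidences=evidences,
        localizations=localizations,
        summary=summary,
        peptide_to_models=peptide_to_models,
    )


# ---------------------------------------------------------------------------
# reporting and file output


def render_report(summary: Summary) -> tuple[str, dict]:
    """Human-readable text plus the equivalent JSON-ready dict."""
    d = summary.to_dict()
    lines = [
        "+1 PRF evidence summary",
        "=======================",
        f"proteins with peptide evidence : {d['total_proteins']}",
        f"+1 PRF proteins                : {d['prf_protein_count']}"
        f" ({d['prf_percent']}%, approximately {d['prf_percent_int']}%)",
        "evidence classes:",
    ]
    for c in "abcd":
        lines.append(f"  class {c} : {d['class_counts'][c]}")
    lines.append(
        f"motif usage: {d['classical_motif_protein_count']} classical, "
        f"{d['novel_motif_protein_count']} novel"
    )
    for label, n in sorted(d["motif_counts"].items()):
        lines.append(f"  {label} : {n}")
    return "\n".join(lines) + "\n", d


def write_sites_tsv(models: Sequence[FrameshiftGeneModel], path) -> None:
    rows = []
    for m in models:
        for k, site in enumerate(m.sites):
            rows.append(
                {
                    "transcript_id": m.transcript_id,
                    "skip_pos": site.skip_pos,
                    "motif": site.motif.label,
                    "classical": site.motif.classical,
                    "next_codon": site.next_codon,
                    "junction_index": m.junctions[k],
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "skip_pos", "motif", "classical",
            "next_codon", "junction_index",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_segments_gff3(models: Sequence[FrameshiftGeneModel], path) -> None:
    """GFF3-style frame-segment annotation (1-based inclusive, nt coords)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            starts = [0] + [s.skip_pos + 1 for s in m.sites]
            bounds = [s.skip_pos for s in m.sites] + [None]
            offset = 0
            for k, (nt_start, nt_stop) in enumerate(zip(starts, bounds)):
                seg_res = (
                    (m.junctions[k] + 1 if k < len(m.junctions) else len(m.protein))
                    - offset
                )
                offset += seg_res
                nt_end = nt_stop if nt_stop is not None else nt_start + 3 * seg_res
                fh.write(
                    "\t".join(
                        [
                            m.transcript_id, "prfmap", "frame_segment",
                            str(nt_start + 1), str(nt_end), ".", "+", ".",
                            f"ID={m.transcript_id}.seg{k};frame={nt_start % 3}",
                        ]
                    )
                    + "\n"
                )


def write_psms_tsv(
    matches: Sequence[SpectrumMatch],
    accepted: Sequence[SpectrumMatch],
    path,
) -> None:
    accepted_ids = {(m.spectrum_id, m.peptide.sequence) for m in accepted}
    rows = [
        {
            "spectrum_id": m.spectrum_id,
            "peptide": m.peptide.sequence,
            "protein_id": m.peptide.protein_id,
            "start": m.peptide.start,
            "end": m.peptide.end,
            "enzyme": m.peptide.enzyme,
            "score": m.score,
            "ppm_error": m.precursor_error_ppm,
            "is_decoy": m.is_decoy,
            "accepted": (m.spectrum_id, m.peptide.sequence) in accepted_ids,
        }
        for m in matches
    ]
    pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "peptide", "protein_id", "start", "end",
            "enzyme", "score", "ppm_error", "is_decoy", "accepted",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_evidence_tsv(evidences: Sequence[ProteinEvidence], path) -> None:
    rows = [
        {
            "model_id": ev.model_id,
            "class": ev.evidence_class,
            "n_peptides": len(ev.peptides),
            "n_spanning": ev.spanning_count,
        }
        for ev in evidences
    ]
    pd.DataFrame(
        rows, columns=["model_id", "class", "n_peptides", "n_spanning"]
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(
    transcripts_fasta,
    spectra_mgf,
    out_dir,
    pipe_cfg: PipelineConfig | None = None,
) -> Summary:
    """File-based end-to-end run: FASTA + MGF in, TSV/JSON report out.

    Writes ``models.fasta``, ``sites.tsv``, ``segments.gff3``,
    ``psms.tsv``, ``evidence.tsv``, ``localizations.tsv``,
    ``report.json`` and ``report.txt`` under ``out_dir``.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    code = build_euplotes_code()

    transcripts = pio.read_transcripts(transcripts_fasta)
    spectra = pio.read_mgf(spectra_mgf)
    models = predict_models(transcripts, pipe_cfg, code)
    db, peptide_to_models = build_search_database(models, pipe_cfg)
    matches = search_spectra(spectra, db, pipe_cfg)
    accepted, _decoys = fdr_partition(matches, pipe_cfg.fdr_q)
    tmap = {t.id: t for t in transcripts}
    evidences, localizations = classify_models(
        accepted, models, peptide_to_models, tmap, pipe_cfg
    )
    model_map = {m.transcript_id: m for m in models}
    summary = summarize(evidences, len(evidences), model_map)

    pio.write_fasta(
        [(m.transcript_id, m.protein) for m in models if m.protein],
        os.path.join(out_dir, "models.fasta"),
    )
    write_sites_tsv(models, os.path.join(out_dir, "sites.tsv"))
    write_segments_gff3(models, os.path.join(out_dir, "segments.gff3"))
    write_psms_tsv(matches, accepted, os.path.join(out_dir, "psms.tsv"))
    write_evidence_tsv(evidences, os.path.join(out_dir, "evidence.tsv"))
    pd.DataFrame(localizations).to_csv(
        os.path.join(out_dir, "localizations.tsv"), sep="\t", index=False
    )
    text, d = render_report(summary)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out_dir, "report.txt"), "w") as fh:
        fh.write(text)
    return summary
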