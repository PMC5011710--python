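"""Ground-truthed synthetic transcriptomes, detections and spectra.

The generator emulates the statistical structure of a Euplotes
macronuclear transcriptome as the analysis assumes it: ~11.4% of genes
carry 1-3 +1 PRF junctions, ~94.2% of junctions use the classical
AAA-UAR motif (the remainder drawn from the novel-motif catalog),
protein abundance is log-normal, peptide detectability saturates with
abundance, and PRF proteins are systematically lower-abundance — which
is what depresses the *detected* PRF fraction below the planted one.

Every emitted spectrum is traceable to exactly one truth record, so
end-to-end closure (generate → digest → simulate → search → classify)
can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .digestion import (
    CARBAMIDOMETHYL_C,
    EnzymeSpec,
    PeptideRecord,
    apply_modifications,
    default_enzymes,
    digest,
    mz,
    peptide_monoisotopic_mass,
)
from .frameshift import (
    FrameshiftGeneModel,
    SlipperyMotif,
    classical_motifs,
    default_motif_catalog,
)
from .genetic_code import GeneticCode, Transcript, build_euplotes_code
from .matching import ObservedSpectrum, generate_by_ions

__all__ = [
    "SimulationConfig",
    "GeneTruth",
    "SpectrumTruth",
    "SyntheticTruth",
    "generate_transcriptome",
    "simulate_detection",
    "simulate_spectra",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults encode the conditions the analysis targets: 11.4% PRF
    genes, 94.2% classical junction motifs, up to three junctions per
    gene.  Abundance is log-normal on the natural-log scale;
    ``prf_abundance_factor`` multiplies PRF-gene abundance to emulate
    the documented depletion of frameshifted proteins in MS data.
    Detection probability per theoretical peptide is the saturating
    function ``detection_max * A / (A + detection_k)`` of the parent
    protein's abundance ``A``.
    """

    n_genes: int = 1000
    prf_fraction: float = 0.114
    classical_motif_fraction: float = 0.942
    junction_probs: tuple[tuple[int, float], ...] = ((1, 0.85), (2, 0.12), (3, 0.03))
    mean_gene_length: int = 150  # codons
    abundance_mu: float = 0.0
    abundance_sigma: float = 2.0
    prf_abundance_factor: float = 0.4
    detection_max: float = 0.9
    detection_k: float = 75.0
    mass_error_ppm: float = 5.0
    fragment_error_da: float = 0.01
    noise_peaks: int = 10
    charge2_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prf_fraction", "classical_motif_fraction", "charge2_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if abs(sum(p for _, p in self.junction_probs) - 1.0) > 1e-9:
            raise ValueError("junction_probs must sum to 1")

    def noiseless(self) -> "SimulationConfig":
        """Copy of this config with all measurement noise switched off."""
        from dataclasses import replace

        return replace(self, mass_error_ppm=0.0, fragment_error_da=0.0, noise_peaks=0)


@dataclass(frozen=True)
class GeneTruth:
    """Planted ground truth for one gene."""

    gene_id: str
    prf: bool
    skip_positions: tuple[int, ...]
    motif_labels: tuple[str, ...]


@dataclass(frozen=True)
class SpectrumTruth:
    """Provenance of one simulated spectrum."""

    spectrum_id: str
    peptide: str
    protein_id: str
    enzyme: str
    charge: int
    true_mass: float
    start: int
    end: int


@dataclass
class SyntheticTruth:
    """Ground-truth tables linking every artifact to its source."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    spectra: dict[str, SpectrumTruth] = field(default_factory=dict)


def _non_stop_codons(code: GeneticCode) -> list[str]:
    return sorted(c for c in code.codon_to_aa if c not in code.stop_codons)


def _segment_lengths(rng: np.random.Generator, total: int, k: int, min_seg: int = 25) -> list[int]:
    """Split ``total`` codons over ``k`` segments, each >= ``min_seg``."""
    total = max(total, min_seg * k + k)
    free = total - min_seg * k
    props = rng.dirichlet(np.ones(k))
    lens = [min_seg + int(free * p) for p in props]
    lens[-1] += total - sum(lens)
    return lens


def generate_transcriptome(
    cfg: SimulationConfig,
    code: GeneticCode | None = None,
) -> tuple[list[Transcript], SyntheticTruth]:
    """Draw a synthetic transcriptome with planted +1 PRF junctions.

    Codon usage is uniform over the 61 non-stop codons of the variant
    code, so the tracked reading frame of every gene is stop-free
    except at planted junctions and the terminal stop.  PRF genes embed
    their junction context so that the 0-frame ORF terminates exactly
    at the planted shifty stop and the downstream segment continues in
    the +1 frame; genes end at their terminal stop with no trailing
    sequence, so chance motifs next to terminal stops can never satisfy
    the scanner's downstream-continuation requirement (the generator's
    hard-negative set lives in untracked frames).
    """
    code = code or build_euplotes_code()
    rng = np.random.default_rng([cfg.seed, 0])
    codons = _non_stop_codons(code)
    novel = sorted(
        (m for m in default_motif_catalog() if not m.classical),
        key=lambda m: m.label,
    )
    ks = [k for k, _ in cfg.junction_probs]
    kp = [p for _, p in cfg.junction_probs]

    transcripts: list[Transcript] = []
    truth = SyntheticTruth()
    for g in range(cfg.n_genes):
        gid = f"SYN.{g + 1:05d}"
        is_prf = bool(rng.random() < cfg.prf_fraction)
        n_junc = int(rng.choice(ks, p=kp)) if is_prf else 0
        total_codons = int(
            rng.integers(
                max(30, int(0.6 * cfg.mean_gene_length)),
                int(1.4 * cfg.mean_gene_length) + 1,
            )
        )
        seg_lens = _segment_lengths(rng, total_codons, n_junc + 1)

        parts: list[str] = ["AUG"]
        length = 3
        skip_positions: list[int] = []
        motif_labels: list[str] = []
        for s in range(n_junc):
            if rng.random() < cfg.classical_motif_fraction:
                stop = "UAA" if rng.random() < 0.9 else "UAG"
                motif = SlipperyMotif("AAA", stop, classical=True)
            else:
                motif = novel[int(rng.integers(len(novel)))]
            body = list(rng.choice(codons, size=seg_lens[s] - 1))
            body[-1] = motif.pre_codon
            parts.extend(body)
            length += 3 * len(body)
            skip_positions.append(length)
            motif_labels.append(motif.label)
            # stop codon occupies [skip, skip+3); the first +1-frame codon
            # starts at skip+1 and shares the stop's last two bases
            first_down = motif.stop_codon[1:] + str(rng.choice(list("ACGU")))
            parts.append(motif.stop_codon[0] + first_down)
            length += 4
        tail = list(rng.choice(codons, size=max(1, seg_lens[-1] - 1)))
        parts.extend(tail)
        length += 3 * len(tail)
        parts.append("UAA" if rng.random() < 0.5 else "UAG")

        transcripts.append(Transcript(gid, "".join(parts)))
        truth.genes[gid] = GeneTruth(
            gene_id=gid,
            prf=is_prf,
            skip_positions=tuple(skip_positions),
            motif_labels=tuple(motif_labels),
        )
    return transcripts, truth


def simulate_detection(
    models: Sequence[FrameshiftGeneModel],
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    enzymes: Sequence[EnzymeSpec] | None = None,
    *,
    min_len: int = 6,
    max_len: int = 50,
) -> list[PeptideRecord]:
    """Bernoulli peptide detection with abundance-dependent probability.

    Each protein draws one log-normal abundance (scaled down for PRF
    proteins); every theoretical peptide of every enzyme is then
    detected independently with the saturating probability
    ``detection_max * A / (A + detection_k)``.  Detected peptides carry
    the fixed carbamidomethyl modification; abundances are recorded in
    ``truth.abundances``.
    """
    enzymes = tuple(enzymes) if enzymes is not None else default_enzymes()
    rng = np.random.default_rng([cfg.seed, 1])
    detected: list[PeptideRecord] = []
    for model in models:
        a = float(
            np.exp(rng.normal(cfg.abundance_mu, cfg.abundance_sigma))
        )
        if model.n_junctions:
            a *= cfg.prf_abundance_factor
        truth.abundances[model.transcript_id] = a
        p = cfg.detection_max * a / (a + cfg.detection_k)
        for enz in enzymes:
            peptides = digest(
                model.protein,
                enz,
                min_len,
                max_len,
                protein_id=model.transcript_id,
            )
            picks = rng.random(len(peptides)) < p
            for pep, hit in zip(peptides, picks):
                if hit:
                    modded = apply_modifications(
                        pep, fixed=(CARBAMIDOMETHYL_C,), variable=(), max_variable=0
                    )[0]
                    detected.append(modded)
    return detected


def simulate_spectra(
    detected: Sequence[PeptideRecord],
    cfg: SimulationConfig,
    truth: SyntheticTruth,
) -> list[ObservedSpectrum]:
    """Emit one HCD-like spectrum per detected peptide.

    Precursors get Gaussian ppm error; the full singly-charged b/y
    ladder gets Gaussian Da error; ``noise_peaks`` uniform peaks are
    added in the 300-1800 m/z survey window.  Charge is 2 with
    probability ``charge2_prob``, else 3.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    spectra: list[ObservedSpectrum] = []
    for i, pep in enumerate(detected):
        sid = f"scan={i + 1:06d}|{pep.protein_id}"
        mass = peptide_monoisotopic_mass(pep)
        charge = 2 if rng.random() < cfg.charge2_prob else 3
        ppm_err = rng.normal(0.0, cfg.mass_error_ppm) if cfg.mass_error_ppm else 0.0
        precursor = mz(mass * (1.0 + ppm_err * 1e-6), charge)

        theo = generate_by_ions(pep)
        ions = np.array(theo.b_ions + theo.y_ions)
        if cfg.fragment_error_da:
            ions = ions + rng.normal(0.0, cfg.fragment_error_da, size=ions.size)
        intensities = rng.uniform(10.0, 100.0, size=ions.size)
        peaks = list(zip(ions.tolist(), intensities.tolist()))
        if cfg.noise_peaks:
            noise_mz = rng.uniform(300.0, 1800.0, size=cfg.noise_peaks)
            noise_it = rng.uniform(1.0, 10.0, size=cfg.noise_peaks)
            peaks.extend(zip(noise_mz.tolist(), noise_it.tolist()))
        peaks.sort()
        spectra.append(
            ObservedSpectrum(
                id=sid,
                precursor_mz=precursor,
                precursor_charge=charge,
                peaks=tuple(peaks),
            )
        )
        truth.spectra[sid] = SpectrumTruth(
            spectrum_id=sid,
            peptide=pep.sequence,
            protein_id=pep.protein_id,
            enzyme=pep.enzyme,
            charge=charge,
            true_mass=mass,
            start=pep.start,
            end=pep.end,
        )
    return spectra
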