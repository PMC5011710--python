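"""Slippery-site detection and frameshift-joined gene models.

In Euplotes +1 programmed ribosomal frameshifting the ribosome reaches
a "shifty stop" (UAA or UAG) whose first nucleotide it skips: having
just translated the codon immediately 5' of the stop (AAA-Lys in the
classical AAA-UAR motif), it advances a single extra nucleotide and
resumes translation in the +1 frame at the codon that starts inside
the stop (for AAA-UAA-N that codon is AAN).  A gene may carry up to
three such junctions; the joined product is one protein whose residues
derive from successive reading frames 0 -> 1 -> 2.

Coordinates are 0-based with half-open intervals.  ``skip_pos`` is the
index of the skipped nucleotide itself, i.e. the first base of the
stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .digestion import RESIDUE_MONO
from .genetic_code import (
    STOP,
    GeneticCode,
    Transcript,
    build_euplotes_code,
    translate_segment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SlipperyMotif",
    "SlipperySite",
    "FrameshiftGeneModel",
    "ConceptualMinus2Product",
    "FrameshiftModelError",
    "default_motif_catalog",
    "classical_motifs",
    "scan_slippery_sites",
    "build_frameshift_model",
    "conceptual_minus2",
]

SHIFTY_STOPS = frozenset({"UAA", "UAG"})


class FrameshiftModelError(ValueError):
    """A site or segment is inconsistent with its transcript."""


@dataclass(frozen=True)
class SlipperyMotif:
    """A slippery sequence: the codon before the shift plus the shifty stop."""

    pre_codon: str
    stop_codon: str
    classical: bool = False

    def __post_init__(self) -> None:
        if self.stop_codon not in SHIFTY_STOPS:
            raise ValueError(
                f"shifty stop must be UAA or UAG, got {self.stop_codon!r}"
            )
        if len(self.pre_codon) != 3 or set(self.pre_codon) - set("ACGU"):
            raise ValueError(f"pre_codon must be an RNA 3-mer, got {self.pre_codon!r}")

    @property
    def label(self) -> str:
        return f"{self.pre_codon}-{self.stop_codon}"


def classical_motifs() -> frozenset[SlipperyMotif]:
    """The classical Euplotes motif AAA-UAR (both stop variants)."""
    return frozenset(
        {
            SlipperyMotif("AAA", "UAA", classical=True),
            SlipperyMotif("AAA", "UAG", classical=True),
        }
    )


# Ten distinct putative novel slippery sequences observed in proteins
# whose 0-frame ORF ends in a non-AAA codon.
_NOVEL = (
    ("UUU", "UAG"),
    ("UUU", "UAA"),
    ("AUU", "UAA"),
    ("AUU", "UAG"),
    ("AAG", "UAA"),
    ("ACC", "UAA"),
    ("AGA", "UAG"),
    ("UAU", "UAG"),
    ("CUU", "UAA"),
    ("AAU", "UAA"),
)


def default_motif_catalog() -> frozenset[SlipperyMotif]:
    """Classical AAA-UAR motifs plus the ten novel slippery sequences."""
    novel = {SlipperyMotif(pre, stop, classical=False) for pre, stop in _NOVEL}
    return classical_motifs() | novel


@dataclass(frozen=True)
class SlipperySite:
    """One accepted slippery site on a transcript.

    ``skip_pos`` is the 0-based index of the skipped nucleotide (the
    first base of the stop codon); ``next_codon`` is the codon read
    immediately after the skip, ``transcript[skip_pos+1 : skip_pos+4]``.
    """

    transcript_id: str
    skip_pos: int
    motif: SlipperyMotif
    next_codon: str
    shift: int = 1

    def validate(self, t: Transcript) -> None:
        seq = t.seq
        p = self.skip_pos
        if p < 3 or p + 3 > len(seq):
            raise FrameshiftModelError(
                f"{t.id}: skip_pos {p} leaves no room for motif context"
            )
        if seq[p : p + 3] != self.motif.stop_codon:
            raise FrameshiftModelError(
                f"{t.id}: stop codon check failed at {p}: "
                f"{seq[p:p+3]!r} != {self.motif.stop_codon!r}"
            )
        if seq[p - 3 : p] != self.motif.pre_codon:
            raise FrameshiftModelError(
                f"{t.id}: pre-codon check failed at {p}: "
                f"{seq[p-3:p]!r} != {self.motif.pre_codon!r}"
            )
        if seq[p + 1 : p + 4] != self.next_codon:
            raise FrameshiftModelError(
                f"{t.id}: next_codon mismatch at {p}"
            )


@dataclass(frozen=True)
class FrameshiftGeneModel:
    """A transcript's joined protein with per-residue frame annotation.

    ``junctions[k] == j`` means protein residue ``j`` is the last
    residue of frame segment ``k`` and residue ``j+1`` the first of
    segment ``k+1``.
    """

    transcript_id: str
    sites: tuple[SlipperySite, ...]
    protein: str
    junctions: tuple[int, ...]
    frame_of_residue: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.junctions) != len(self.sites):
            raise ValueError("one junction index per slippery site required")
        if len(self.frame_of_residue) != len(self.protein):
            raise ValueError("frame annotation must cover every residue")

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    def segment_frames(self) -> tuple[int, ...]:
        """Distinct frames in residue order (one entry per segment)."""
        frames: list[int] = []
        for f in self.frame_of_residue:
            if not frames or frames[-1] != f:
                frames.append(f)
        return tuple(frames)


@dataclass(frozen=True)
class ConceptualMinus2Product:
    """The -2 alternative at a site: one extra residue and its mass cost.

    A -2 shift at the same stop re-reads a codon that starts two bases
    before the stop, then rejoins the same downstream frame as the +1
    product, so the two conceptual products differ by exactly one
    residue near the junction and hence by that residue's monoisotopic
    mass.
    """

    site: SlipperySite
    extra_residue: str
    mass_delta: float

    def __post_init__(self) -> None:
        if self.mass_delta <= 0:
            raise ValueError("mass_delta must be positive")


def scan_slippery_sites(
    t: Transcript,
    motifs: Iterable[SlipperyMotif] | None = None,
    frame_tracking: bool = True,
    *,
    code: GeneticCode | None = None,
    max_sites: int = 3,
    min_downstream_codons: int = 1,
) -> list[SlipperySite]:
    """Find slippery sites on a transcript.

    In the default frame-tracking mode the scan walks codons from frame
    0; the first in-frame stop either matches a motif (its pre-codon is
    the codon just translated) and becomes a site — after which reading
    resumes one nucleotide downstream, i.e. in the next frame — or it
    terminates the open reading frame and the scan.  A site is accepted
    only when at least ``min_downstream_codons`` complete codons follow
    the skip.  With ``frame_tracking=False`` every motif occurrence at
    any position is reported (exploratory mode, no ORF logic).

    Sites whose 7-nucleotide motif windows overlap a previously
    accepted site are rejected with a warning.
    """
    if motifs is None:
        motifs = default_motif_catalog()
    motif_map = {(m.pre_codon, m.stop_codon): m for m in motifs}
    if not motif_map:
        raise ValueError("motif set must be non-empty")
    code = code or build_euplotes_code()
    seq = t.seq
    n = len(seq)
    sites: list[SlipperySite] = []

    def _make_site(p: int, m: SlipperyMotif) -> SlipperySite:
        return SlipperySite(t.id, p, m, seq[p + 1 : p + 4])

    if not frame_tracking:
        for p in range(3, n - 2):
            m = motif_map.get((seq[p - 3 : p], seq[p : p + 3]))
            if m is not None and p + 1 + 3 * min_downstream_codons <= n:
                sites.append(_make_site(p, m))
        return sites

    i = 0
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if codon not in code.stop_codons:
            i += 3
            continue
        motif = motif_map.get((seq[i - 3 : i], codon)) if i >= 3 else None
        accept = (
            motif is not None
            and len(sites) < max_sites
            and i + 1 + 3 * min_downstream_codons <= n
        )
        if accept and sites and i - sites[-1].skip_pos < 7:
            logger.warning(
                "%s: slippery motif at %d overlaps the 7-mer window of the "
                "site at %d; rejected",
                t.id,
                i,
                sites[-1].skip_pos,
            )
            accept = False
        if not accept:
            break  # this stop terminates the tracked ORF
        sites.append(_make_site(i, motif))
        i += 1  # resume translation one nucleotide downstream (+1 frame)
    return sites


def build_frameshift_model(
    t: Transcript,
    sites: Sequence[SlipperySite],
    code: GeneticCode | None = None,
) -> FrameshiftGeneModel:
    """Join frame segments across ``sites`` into one protein model.

    Segment 1 is translated in frame 0 up to the codon before the first
    slippery stop; at each site one nucleotide is skipped and
    translation continues in the next frame.  The terminal segment runs
    to its first in-frame stop (or the sequence end).  With no sites
    the model is the plain halted frame-0 translation.
    """
    code = code or build_euplotes_code()
    seq = t.seq
    sites = tuple(sites)
    if len(sites) > 3:
        raise FrameshiftModelError("at most 3 junctions per gene are supported")
    for k, site in enumerate(sites):
        site.validate(t)
        if k and site.skip_pos <= sites[k - 1].skip_pos:
            raise FrameshiftModelError(f"{t.id}: sites must be ordered by position")

    seg_proteins: list[str] = []
    seg_frames: list[int] = []
    start = 0
    for k, site in enumerate(sites):
        p = site.skip_pos
        if (p - start) % 3:
            raise FrameshiftModelError(
                f"{t.id}: site at {p} is not in the tracked frame (segment "
                f"start {start})"
            )
        aa = translate_segment(seq, start, code, end=p, readthrough=True)
        if STOP in aa:
            raise FrameshiftModelError(
                f"{t.id}: internal stop codon inside segment {k} upstream of "
                f"the site at {p}"
            )
        if not aa:
            raise FrameshiftModelError(
                f"{t.id}: zero-residue segment before the site at {p}"
            )
        seg_proteins.append(aa)
        seg_frames.append(start % 3)
        start = p + 1
    terminal = translate_segment(seq, start, code, readthrough=False)
    if sites and not terminal:
        raise FrameshiftModelError(
            f"{t.id}: zero-residue segment downstream of the final site"
        )
    seg_proteins.append(terminal)
    seg_frames.append(start % 3)

    protein = "".join(seg_proteins)
    junctions: list[int] = []
    acc = 0
    for aa in seg_proteins[:-1]:
        acc += len(aa)
        junctions.append(acc - 1)
    frame_of_residue: list[int] = []
    for aa, f in zip(seg_proteins, seg_frames):
        frame_of_residue.extend([f] * len(aa))
    return FrameshiftGeneModel(
        transcript_id=t.id,
        sites=sites,
        protein=protein,
        junctions=tuple(junctions),
        frame_of_residue=tuple(frame_of_residue),
    )


def conceptual_minus2(
    site: SlipperySite,
    t: Transcript,
    code: GeneticCode | None = None,
) -> ConceptualMinus2Product:
    """Mass consequence of the -2 alternative at a slippery site.

    The -2 product re-reads one extra codon starting two bases before
    the stop (``skip_pos - 2``) and then continues identically to the
    +1 product, so it carries one additional residue; the returned
    ``mass_delta`` is that residue's monoisotopic mass.  For every
    AAA-UAR context the extra codon is AAU (Asn), a gap of ~114 Da —
    far beyond instrument tolerance, which is what makes the two shift
    directions distinguishable from a single accurate precursor mass.
    """
    code = code or build_euplotes_code()
    site.validate(t)
    p = site.skip_pos
    if p < 2:
        raise FrameshiftModelError("skip_pos < 2: no room for a -2 re-read")
    extra_codon = t.seq[p - 2 : p + 1]
    aa = code.translate_codon(extra_codon)
    if aa == STOP:
        raise FrameshiftModelError(
            f"-2 re-read codon {extra_codon!r} is a stop; no conceptual product"
        )
    return ConceptualMinus2Product(site=site, extra_residue=aa, mass_delta=RESIDUE_MONO[aa])
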