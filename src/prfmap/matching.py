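"""Theoretical b/y ladders, simplified spectrum matching, target-decoy FDR.

The scorer is deliberately simple: the fraction of theoretical
singly-charged b/y ions found in the observed peak list within the
fragment tolerance.  The downstream biology depends on peptide
identity and accurate precursor mass, not on any particular score
scale, so no attempt is made to reproduce a commercial search engine's
probabilistic score.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .digestion import (
    PROTON,
    RESIDUE_MONO,
    WATER,
    PeptideRecord,
    peptide_monoisotopic_mass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TheoreticalSpectrum",
    "ObservedSpectrum",
    "SpectrumMatch",
    "PeptideDatabase",
    "generate_by_ions",
    "match_spectrum",
    "build_decoys",
    "fdr_filter",
    "fdr_partition",
    "observed_neutral_mass",
]


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """Singly-charged b/y fragment ladders of one peptide."""

    peptide: PeptideRecord
    charge: int
    b_ions: tuple[float, ...]
    y_ions: tuple[float, ...]


@dataclass(frozen=True)
class ObservedSpectrum:
    """An MS/MS peak list with precursor information."""

    id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), sorted by m/z

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            raise ValueError(f"spectrum {self.id!r}: peaks must be sorted by m/z")
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError(f"spectrum {self.id!r}: negative intensity")


@dataclass(frozen=True)
class SpectrumMatch:
    """A peptide-spectrum match with its score and mass accuracy."""

    spectrum_id: str
    peptide: PeptideRecord
    score: float
    precursor_error_ppm: float
    is_decoy: bool


def _residue_masses(p: PeptideRecord) -> list[float]:
    masses = [RESIDUE_MONO[aa] for aa in p.sequence]
    for pos, mod in p.mods:
        masses[pos] += mod.delta_mass
    return masses


def generate_by_ions(peptide: PeptideRecord, charge: int = 1) -> TheoreticalSpectrum:
    """b/y ladders: ``b_i`` is the protonated N-terminal prefix of length
    ``i``; ``y_j`` the protonated C-terminal suffix of length ``j`` plus
    water.  Fragments are singly charged."""
    n = len(peptide.sequence)
    if n < 2:
        raise ValueError("fragment ladders require a peptide of length >= 2")
    masses = _residue_masses(peptide)
    prefix = np.cumsum(masses)
    b = tuple(float(prefix[i - 1] + PROTON) for i in range(1, n))
    total = float(prefix[-1])
    y = tuple(total - float(prefix[n - j - 1]) + WATER + PROTON for j in range(1, n))
    return TheoreticalSpectrum(peptide=peptide, charge=charge, b_ions=b, y_ions=y)


def observed_neutral_mass(obs: ObservedSpectrum) -> float:
    """Neutral precursor mass implied by the precursor m/z and charge."""
    z = obs.precursor_charge
    return obs.precursor_mz * z - z * PROTON


class PeptideDatabase:
    """Candidate peptides indexed by neutral monoisotopic mass."""

    def __init__(self, peptides: Iterable[PeptideRecord]):
        records = list(peptides)
        masses = np.array([peptide_monoisotopic_mass(p) for p in records])
        order = np.argsort(masses, kind="stable")
        self.records: list[PeptideRecord] = [records[i] for i in order]
        self.masses: np.ndarray = masses[order]

    def __len__(self) -> int:
        return len(self.records)

    def candidates(self, neutral_mass: float, ppm_tol: float) -> list[tuple[PeptideRecord, float]]:
        """Peptides within ``ppm_tol`` of ``neutral_mass`` with ppm errors."""
        half = neutral_mass * ppm_tol * 1e-6
        lo = int(np.searchsorted(self.masses, neutral_mass - half, side="left"))
        hi = int(np.searchsorted(self.masses, neutral_mass + half, side="right"))
        out = []
        for i in range(lo, hi):
            theo = float(self.masses[i])
            err = (neutral_mass - theo) / theo * 1e6
            if abs(err) <= ppm_tol:
                out.append((self.records[i], err))
        return out


def _count_matched(ladder: Sequence[float], peak_mzs: Sequence[float], used: set[int], tol: float) -> int:
    """Greedy one-to-one peak assignment: each observed peak can support
    at most one theoretical ion; the closest unused peak wins."""
    matched = 0
    for ion in ladder:
        idx = bisect.bisect_left(peak_mzs, ion)
        best_j, best_d = -1, tol
        for j in (idx - 1, idx, idx + 1):
            if 0 <= j < len(peak_mzs) and j not in used:
                d = abs(peak_mzs[j] - ion)
                if d <= best_d:
                    best_j, best_d = j, d
        if best_j >= 0:
            used.add(best_j)
            matched += 1
    return matched


def score_match(obs: ObservedSpectrum, peptide: PeptideRecord, frag_tol_da: float) -> float:
    """Fraction of theoretical b/y ions matched in the observed peaks."""
    spec = generate_by_ions(peptide)
    peak_mzs = [p[0] for p in obs.peaks]
    used: set[int] = set()
    matched = _count_matched(spec.b_ions, peak_mzs, used, frag_tol_da)
    matched += _count_matched(spec.y_ions, peak_mzs, used, frag_tol_da)
    return matched / (len(spec.b_ions) + len(spec.y_ions))


def match_spectrum(
    obs: ObservedSpectrum,
    candidates: PeptideDatabase | Sequence[PeptideRecord],
    ppm_tol: float = 20.0,
    frag_tol_da: float = 0.1,
    *,
    decoy_prefix: str = "DECOY_",
) -> SpectrumMatch | None:
    """Best-scoring candidate within the precursor tolerance, or ``None``.

    Ties are broken by smaller absolute precursor error, then by
    lexicographic peptide sequence (deterministic output).
    """
    if not obs.peaks:
        return None
    if not isinstance(candidates, PeptideDatabase):
        candidates = PeptideDatabase(candidates)
    neutral = observed_neutral_mass(obs)
    best: SpectrumMatch | None = None
    for pep, err in candidates.candidates(neutral, ppm_tol):
        score = score_match(obs, pep, frag_tol_da)
        key = (-score, abs(err), pep.sequence)
        if best is None or key < (-best.score, abs(best.precursor_error_ppm), best.peptide.sequence):
            best = SpectrumMatch(
                spectrum_id=obs.id,
                peptide=pep,
                score=score,
                precursor_error_ppm=err,
                is_decoy=pep.protein_id.startswith(decoy_prefix),
            )
    return best


def build_decoys(
    proteins: Sequence[tuple[str, str]],
    *,
    prefix: str = "DECOY_",
    method: str = "reverse",
) -> list[tuple[str, str]]:
    """Reversed-sequence decoy proteins, ids prefixed.

    ``method="pseudo_reverse"`` reverses between cleavage-like anchors
    (keeps K/R in place), a common alternative dialect.
    """
    out = []
    for rid, seq in proteins:
        if method == "reverse":
            decoy = seq[::-1]
        elif method == "pseudo_reverse":
            chunk: list[str] = []
            buf: list[str] = []
            for aa in seq:
                if aa in "KR":
                    chunk.append("".join(reversed(buf)) + aa)
                    buf = []
                else:
                    buf.append(aa)
            chunk.append("".join(reversed(buf)))
            decoy = "".join(chunk)
        else:
            raise ValueError(f"unknown decoy method {method!r}")
        if decoy == seq:
            logger.warning("palindromic protein %s: decoy equals target", rid)
        out.append((prefix + rid, decoy))
    return out


def _threshold_filter(items: list[tuple[float, bool]], q: float) -> float | None:
    """Loosest score s such that decoys/targets <= q among items with
    score >= s; ``None`` when no threshold admits any target."""
    order = sorted(items, key=lambda x: -x[0])
    best_thr = None
    n_t = n_d = 0
    for score, is_decoy in order:
        if is_decoy:
            n_d += 1
        else:
            n_t += 1
        if n_t > 0 and n_d / n_t <= q:
            best_thr = score
    return best_thr


def fdr_partition(
    matches: Sequence[SpectrumMatch],
    q: float = 0.01,
) -> tuple[list[SpectrumMatch], list[SpectrumMatch]]:
    """Target-decoy filtering at peptide level, then protein level.

    The peptide score is the best match score per (sequence, decoy
    flag); the protein score is the best surviving peptide score per
    protein.  At each level the loosest threshold with an estimated
    FDR (#decoys / #targets) <= ``q`` is applied.

    Returns ``(accepted_targets, accepted_decoys)`` — the decoy matches
    surviving both thresholds are returned separately so the realized
    decoy fraction can be measured.
    """
    if not matches:
        return [], []

    pep_best: dict[tuple[str, bool], float] = {}
    for m in matches:
        key = (m.peptide.sequence, m.is_decoy)
        if key not in pep_best or m.score > pep_best[key]:
            pep_best[key] = m.score
    pep_thr = _threshold_filter([(s, d) for (_, d), s in pep_best.items()], q)
    if pep_thr is None:
        return [], []
    surviving_peps = {
        (seq, d) for (seq, d), s in pep_best.items() if s >= pep_thr
    }

    prot_best: dict[tuple[str, bool], float] = {}
    for m in matches:
        if m.score < pep_thr or (m.peptide.sequence, m.is_decoy) not in surviving_peps:
            continue
        key = (m.peptide.protein_id, m.is_decoy)
        if key not in prot_best or m.score > prot_best[key]:
            prot_best[key] = m.score
    prot_thr = _threshold_filter([(s, d) for (_, d), s in prot_best.items()], q)
    if prot_thr is None:
        return [], []
    surviving_prots = {
        (pid, d) for (pid, d), s in prot_best.items() if s >= prot_thr
    }

    accepted = [
        m
        for m in matches
        if m.score >= pep_thr
        and (m.peptide.sequence, m.is_decoy) in surviving_peps
        and (m.peptide.protein_id, m.is_decoy) in surviving_prots
    ]
    targets = [m for m in accepted if not m.is_decoy]
    decoys = [m for m in accepted if m.is_decoy]
    return targets, decoys


def fdr_filter(
    matches: Sequence[SpectrumMatch],
    q: float = 0.01,
) -> list[SpectrumMatch]:
    """Accepted *target* matches after peptide- and protein-level FDR
    control at ``q`` (see :func:`fdr_partition`)."""
    targets, _ = fdr_partition(matches, q)
    return targets
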