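"""Peptide-to-model mapping, the four-class evidence taxonomy, shift
direction discrimination and summary statistics.

Proteins predicted to require +1 frameshifting are classified by where
their identified peptides fall relative to the frame junction(s):

* **a** — at least one junction is covered by a *spanning* peptide
  (one that includes both the last pre-shift residue and the first
  post-shift residue), pinpointing the site and direction;
* **b** — no spanning peptide, but coverage on both sides of the
  junction (for multi-junction models: every frame segment adjacent to
  a junction covered, or all frames covered);
* **c** — downstream (+1 frame) coverage only;
* **d** — upstream (0 frame) coverage only.

Classes partition the evidenced models; a model with mapped peptides
receives exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .digestion import PeptideRecord, peptide_monoisotopic_mass
from .frameshift import (
    ConceptualMinus2Product,
    FrameshiftGeneModel,
    SlipperySite,
    conceptual_minus2,
)
from .genetic_code import GeneticCode, Transcript, build_euplotes_code

__all__ = [
    "PeptideMapping",
    "ProteinEvidence",
    "ShiftDirectionCall",
    "Summary",
    "map_peptide",
    "classify_protein",
    "localize_site",
    "discriminate_direction",
    "summarize",
    "summary_from_counts",
]

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
SPANNING = "spanning"
NONE = "none"


@dataclass(frozen=True)
class PeptideMapping:
    """One peptide placed on one frameshift gene model."""

    peptide: PeptideRecord
    model_id: str
    covered_frames: frozenset[int]
    relation_per_junction: tuple[str, ...]

    @property
    def spans_any(self) -> bool:
        return SPANNING in self.relation_per_junction

    def spanned_junctions(self) -> tuple[int, ...]:
        return tuple(
            k for k, r in enumerate(self.relation_per_junction) if r == SPANNING
        )


@dataclass(frozen=True)
class ProteinEvidence:
    """All mapped peptides of one model plus its evidence class."""

    model_id: str
    peptides: tuple[PeptideMapping, ...]
    evidence_class: str  # "a" | "b" | "c" | "d" | "none"
    spanning_count: int


@dataclass(frozen=True)
class ShiftDirectionCall:
    """+1 vs -2 discrimination for one spanned junction.

    ``plus1_mass`` is the theoretical mass of the spanning peptide under
    the +1 model; ``minus2_mass`` adds the extra residue a -2 shift
    would introduce.  The two differ by >100 Da at classical AAA-UAR
    sites, so an accurate precursor mass decides the direction.
    """

    junction: int
    observed_mass: float
    plus1_mass: float
    minus2_mass: float
    call: str  # "+1" | "-2" | "ambiguous"


def map_peptide(p: PeptideRecord, m: FrameshiftGeneModel) -> PeptideMapping:
    """Locate a peptide on a model and relate it to every junction.

    The peptide's protein coordinates must slice the model protein to
    its own sequence.  A peptide *spans* junction ``j`` iff it covers
    residues ``j`` and ``j+1``; a peptide ending exactly at ``j`` is
    upstream of that junction.
    """
    if not (0 <= p.start < p.end <= len(m.protein)):
        raise ValueError(
            f"peptide coordinates [{p.start},{p.end}) outside model "
            f"{m.transcript_id} of length {len(m.protein)}"
        )
    if m.protein[p.start : p.end] != p.sequence:
        raise ValueError(
            f"peptide {p.sequence!r} does not match model slice "
            f"{m.protein[p.start:p.end]!r} on {m.transcript_id}"
        )
    relations = []
    for j in m.junctions:
        if p.start <= j and p.end >= j + 2:
            relations.append(SPANNING)
        elif p.end <= j + 1:
            relations.append(UPSTREAM)
        else:
            relations.append(DOWNSTREAM)
    frames = frozenset(m.frame_of_residue[p.start : p.end])
    return PeptideMapping(
        peptide=p,
        model_id=m.transcript_id,
        covered_frames=frames,
        relation_per_junction=tuple(relations),
    )


def classify_protein(
    mappings: Sequence[PeptideMapping],
    m: FrameshiftGeneModel,
) -> ProteinEvidence:
    """Assign one of the four evidence classes (or ``none``).

    Class a takes priority: any spanned junction suffices, regardless
    of how many peptides span it (junctions are counted, not
    peptides).  For class b on multi-junction models, covering the 0
    frame and at least one downstream frame — i.e. both sides of the
    first junction — is what qualifies; requiring every junction to be
    flanked would leave partially covered multi-junction models with
    no class at all and break the partition property.  Models without
    junctions always classify as ``none``.
    """
    for mp in mappings:
        if mp.model_id != m.transcript_id:
            raise ValueError(
                f"mapping for {mp.model_id} passed to model {m.transcript_id}"
            )
    spanning_count = sum(1 for mp in mappings if mp.spans_any)
    if not mappings or not m.junctions:
        cls = NONE
    elif spanning_count:
        cls = "a"
    else:
        has_up_first = any(mp.relation_per_junction[0] == UPSTREAM for mp in mappings)
        has_down_first = any(
            mp.relation_per_junction[0] == DOWNSTREAM for mp in mappings
        )
        if has_up_first and has_down_first:
            cls = "b"
        elif has_down_first:
            cls = "c"
        else:
            cls = "d"
    return ProteinEvidence(
        model_id=m.transcript_id,
        peptides=tuple(mappings),
        evidence_class=cls,
        spanning_count=spanning_count,
    )


def localize_site(
    spanning: PeptideMapping,
    m: FrameshiftGeneModel,
    t: Transcript,
    code: GeneticCode | None = None,
) -> list[tuple[SlipperySite, str]]:
    """Frameshift site(s) localized by a spanning peptide.

    For each junction the peptide spans, returns the model's slippery
    site together with the shift direction implied by the junction
    residue pair: the residue before the junction must be encoded by
    the motif's pre-codon and the residue after it by the codon read
    one nucleotide downstream of the skipped base.  A residue pair
    inconsistent with skipping exactly one nucleotide is flagged
    ``"-2?"`` for mass-based follow-up.
    """
    if not spanning.spans_any:
        raise ValueError("mapping does not span any junction")
    if t.id != m.transcript_id:
        raise ValueError("transcript does not belong to this model")
    code = code or build_euplotes_code()
    out = []
    for k in spanning.spanned_junctions():
        site = m.sites[k]
        j = m.junctions[k]
        pre_aa = code.translate_codon(site.motif.pre_codon)
        next_aa = code.translate_codon(site.next_codon)
        consistent = m.protein[j] == pre_aa and m.protein[j + 1] == next_aa
        out.append((site, "+1" if consistent else "-2?"))
    return out


def discriminate_direction(
    observed_mass: float,
    peptide: PeptideRecord,
    junction_index: int,
    m: FrameshiftGeneModel,
    t: Transcript,
    *,
    ppm_tol: float = 20.0,
    code: GeneticCode | None = None,
) -> ShiftDirectionCall:
    """Decide +1 vs -2 from the observed mass of a spanning peptide.

    ``plus1_mass`` is the peptide's theoretical mass under the +1
    joined model; ``minus2_mass`` adds the single extra residue the -2
    alternative would insert at the junction.  Whichever alternative
    lies within ``ppm_tol`` of the observed mass is called; if both or
    neither fit the call is ``ambiguous`` (which cannot happen at
    AAA-UAR sites, where the alternatives differ by >100 Da).
    """
    site = m.sites[junction_index]
    extra: ConceptualMinus2Product = conceptual_minus2(site, t, code)
    plus1 = peptide_monoisotopic_mass(peptide)
    minus2 = plus1 + extra.mass_delta

    def fits(theo: float) -> bool:
        return abs((observed_mass - theo) / theo) * 1e6 <= ppm_tol

    p1, m2 = fits(plus1), fits(minus2)
    if p1 and not m2:
        call = "+1"
    elif m2 and not p1:
        call = "-2"
    else:
        call = "ambiguous"
    return ShiftDirectionCall(
        junction=junction_index,
        observed_mass=observed_mass,
        plus1_mass=plus1,
        minus2_mass=minus2,
        call=call,
    )


@dataclass(frozen=True)
class Summary:
    """Study-level tallies over a set of classified models."""

    class_counts: Mapping[str, int]
    prf_protein_count: int
    total_proteins: int
    prf_percent: float          # one decimal, half-away-from-zero
    prf_percent_int: int        # headline "approximately N%" figure
    motif_counts: Mapping[str, int] = field(default_factory=dict)
    classical_motif_protein_count: int = 0
    novel_motif_protein_count: int = 0

    def to_dict(self) -> dict:
        return {
            "class_counts": dict(self.class_counts),
            "prf_protein_count": self.prf_protein_count,
            "total_proteins": self.total_proteins,
            "prf_percent": self.prf_percent,
            "prf_percent_int": self.prf_percent_int,
            "motif_counts": dict(self.motif_counts),
            "classical_motif_protein_count": self.classical_motif_protein_count,
            "novel_motif_protein_count": self.novel_motif_protein_count,
        }


def _round_half_away(x: float, ndigits: int = 0) -> float:
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def summary_from_counts(
    class_counts: Mapping[str, int],
    total_proteins: int,
    *,
    motif_counts: Mapping[str, int] | None = None,
    classical_count: int | None = None,
    novel_count: int | None = None,
) -> Summary:
    """Core arithmetic shared by :func:`summarize` and external tallies."""
    counts = {c: int(class_counts.get(c, 0)) for c in "abcd"}
    prf_count = sum(counts.values())
    if total_proteins < prf_count:
        raise ValueError(
            f"total_proteins ({total_proteins}) smaller than PRF protein "
            f"count ({prf_count})"
        )
    pct = 100.0 * prf_count / total_proteins if total_proteins else 0.0
    return Summary(
        class_counts=counts,
        prf_protein_count=prf_count,
        total_proteins=total_proteins,
        prf_percent=_round_half_away(pct, 1),
        prf_percent_int=int(_round_half_away(pct, 0)),
        motif_counts=dict(motif_counts or {}),
        classical_motif_protein_count=(
            classical_count if classical_count is not None else 0
        ),
        novel_motif_protein_count=(novel_count if novel_count is not None else 0),
    )


def summarize(
    evidences: Sequence[ProteinEvidence],
    total_proteins: int,
    models: Mapping[str, FrameshiftGeneModel] | None = None,
) -> Summary:
    """Tally class counts, PRF fraction and motif usage.

    ``total_proteins`` is the number of detected/evidenced proteins the
    PRF fraction is measured against.  When ``models`` is given, motif
    usage is tabulated per PRF protein (a protein counts as classical
    when all its sites use classical motifs).
    """
    class_counts = {c: 0 for c in "abcd"}
    for ev in evidences:
        if ev.evidence_class in class_counts:
            class_counts[ev.evidence_class] += 1
    motif_counts: dict[str, int] = {}
    classical = novel = 0
    if models is not None:
        for ev in evidences:
            if ev.evidence_class not in "abcd":
                continue
            model = models[ev.model_id]
            for site in model.sites:
                motif_counts[site.motif.label] = (
                    motif_counts.get(site.motif.label, 0) + 1
                )
            if all(site.motif.classical for site in model.sites):
                classical += 1
            else:
                novel += 1
    return summary_from_counts(
        class_counts,
        total_proteins,
        motif_counts=motif_counts,
        classical_count=classical,
        novel_count=novel,
    )
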