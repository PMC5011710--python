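"""Multi-protease in-silico digestion and monoisotopic mass arithmetic.

The shotgun strategy modeled here digests each protein independently
with trypsin, GluC and chymotrypsin.  Trypsin alone is a poor tool for
recovering Euplotes +1 frameshift junctions — in the large majority of
these genes the codon immediately 5' of the shifty stop is AAA (Lys),
so the tryptic cut falls exactly on the junction — which is why the
two additional proteases are first-class citizens of the pipeline.

Masses are monoisotopic throughout.  Residue masses come from
pyteomics; the independent cross-check against a hand-frozen residue
table lives in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "WATER",
    "PROTON",
    "RESIDUE_MONO",
    "EnzymeSpec",
    "ModificationSpec",
    "PeptideRecord",
    "CARBAMIDOMETHYL_C",
    "OXIDATION_M",
    "get_enzyme",
    "default_enzymes",
    "cleavage_sites",
    "digest",
    "apply_modifications",
    "peptide_monoisotopic_mass",
    "mz",
]

#: Monoisotopic mass of water (Da), added once per peptide chain.
WATER: float = float(_pmass.calculate_mass(formula="H2O"))
#: Monoisotopic mass of a proton (Da), used for m/z and fragment ions.
PROTON: float = 1.00727646688

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Monoisotopic residue (i.e. dehydrated) masses for the 20 amino acids.
RESIDUE_MONO: dict[str, float] = {aa: float(_pmass.std_aa_mass[aa]) for aa in _AA20}


@dataclass(frozen=True)
class EnzymeSpec:
    """Cleavage rule: cut C-terminal to ``cleave_after`` residues,
    suppressed when the next residue is in ``blocked_by_next``."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()
    max_missed: int = 2

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError(f"enzyme {self.name!r} has an empty cleavage set")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")


# Specificity dialects follow the common search-engine defaults; GluC in
# ammonium-bicarbonate buffer cleaves after E only (after D/E variant
# available as "gluc_de"), chymotrypsin is the high-specificity F/W/Y/L
# rule (add M via "chymotrypsin_m").
_ENZYMES: dict[str, EnzymeSpec] = {
    "trypsin": EnzymeSpec("trypsin", frozenset("KR"), frozenset("P")),
    "gluc": EnzymeSpec("gluc", frozenset("E")),
    "gluc_de": EnzymeSpec("gluc_de", frozenset("DE")),
    "chymotrypsin": EnzymeSpec("chymotrypsin", frozenset("FWYL"), frozenset("P")),
    "chymotrypsin_m": EnzymeSpec("chymotrypsin_m", frozenset("FWYLM"), frozenset("P")),
}


def get_enzyme(name: str, *, max_missed: int | None = None) -> EnzymeSpec:
    """Look up a protease preset by name (case-insensitive)."""
    try:
        spec = _ENZYMES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; available: {sorted(_ENZYMES)}"
        ) from None
    if max_missed is not None:
        spec = replace(spec, max_missed=max_missed)
    return spec


def default_enzymes(max_missed: int = 2) -> tuple[EnzymeSpec, ...]:
    """The three-protease panel used throughout: trypsin, GluC, chymotrypsin."""
    return tuple(
        get_enzyme(n, max_missed=max_missed) for n in ("trypsin", "gluc", "chymotrypsin")
    )


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable post-translational/chemical modification."""

    name: str
    target_residue: str
    delta_mass: float
    mode: str = "fixed"  # "fixed" | "variable"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be 'fixed' or 'variable', got {self.mode!r}")


#: Iodoacetamide alkylation of cysteine, applied as a fixed modification.
CARBAMIDOMETHYL_C = ModificationSpec("carbamidomethyl", "C", 57.021464, "fixed")
#: Methionine oxidation, enumerated as a variable modification.
OXIDATION_M = ModificationSpec("oxidation", "M", 15.994915, "variable")


@dataclass(frozen=True)
class PeptideRecord:
    """A digestion product located on its parent protein.

    ``start``/``end`` are 0-based half-open coordinates on the protein;
    ``mods`` holds ``(position_in_peptide, ModificationSpec)`` pairs.
    """

    sequence: str
    protein_id: str
    start: int
    end: int
    missed_cleavages: int
    enzyme: str
    mods: tuple[tuple[int, ModificationSpec], ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"peptide {self.sequence!r}: coordinates [{self.start},{self.end}) "
                "do not match its length"
            )

    @property
    def mod_key(self) -> tuple[tuple[int, str], ...]:
        return tuple((pos, m.name) for pos, m in self.mods)


def _check_protein(protein: str) -> None:
    bad = set(protein) - set(RESIDUE_MONO)
    if bad:
        raise ValueError(f"invalid residue letters in protein: {sorted(bad)!r}")


def cleavage_sites(protein: str, enzyme: EnzymeSpec) -> list[int]:
    """Internal cut positions (index i means a cut between i-1 and i)."""
    sites = []
    for i in range(len(protein) - 1):
        if protein[i] in enzyme.cleave_after and protein[i + 1] not in enzyme.blocked_by_next:
            sites.append(i + 1)
    return sites


def digest(
    protein: str,
    enzyme: EnzymeSpec,
    min_len: int = 6,
    max_len: int = 50,
    *,
    protein_id: str = "",
    max_missed: int | None = None,
) -> list[PeptideRecord]:
    """Fully specific digestion with up to ``max_missed`` missed cleavages.

    The protein N- and C-termini count as cleavage boundaries.  Output
    is ordered by (start, end) and is invariant to input case.
    """
    protein = protein.upper()
    if not protein:
        raise ValueError("cannot digest an empty protein")
    if "*" in protein:
        raise ValueError("protein contains '*'; translate with stop_policy='halt'")
    _check_protein(protein)
    if max_missed is None:
        max_missed = enzyme.max_missed

    boundaries = [0] + cleavage_sites(protein, enzyme) + [len(protein)]
    out: list[PeptideRecord] = []
    for i in range(len(boundaries) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(boundaries):
                break
            start, end = boundaries[i], boundaries[j]
            if not (min_len <= end - start <= max_len):
                continue
            out.append(
                PeptideRecord(
                    sequence=protein[start:end],
                    protein_id=protein_id,
                    start=start,
                    end=end,
                    missed_cleavages=missed,
                    enzyme=enzyme.name,
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def apply_modifications(
    peptide: PeptideRecord,
    fixed: Sequence[ModificationSpec] = (CARBAMIDOMETHYL_C,),
    variable: Sequence[ModificationSpec] = (OXIDATION_M,),
    max_variable: int = 2,
) -> list[PeptideRecord]:
    """Enumerate modification states of one peptide.

    Fixed modifications are applied to every target residue; variable
    modifications are enumerated over 0..``max_variable`` occurrences
    (bounding the combinatorics).  The first returned record carries the
    fixed modifications only.
    """
    base: list[tuple[int, ModificationSpec]] = []
    for m in fixed:
        base.extend((i, m) for i, aa in enumerate(peptide.sequence) if aa == m.target_residue)

    var_slots: list[tuple[int, ModificationSpec]] = []
    for m in variable:
        var_slots.extend(
            (i, m) for i, aa in enumerate(peptide.sequence) if aa == m.target_residue
        )

    out = []
    for k in range(min(max_variable, len(var_slots)) + 1):
        for combo in itertools.combinations(var_slots, k):
            mods = tuple(sorted(base + list(combo)))
            out.append(replace(peptide, mods=mods))
    return out


def peptide_monoisotopic_mass(p: PeptideRecord | str) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    if isinstance(p, str):
        seq, mods = p.upper(), ()
    else:
        seq, mods = p.sequence, p.mods
    if not seq:
        raise ValueError("empty peptide sequence")
    try:
        total = sum(RESIDUE_MONO[aa] for aa in seq)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return total + WATER + sum(m.delta_mass for _, m in mods)


def mz(mass: float, charge: int) -> float:
    """m/z of a ``charge``-protonated ion of the given neutral mass."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON) / charge
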