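"""Independent oracles for the test suite.

These deliberately take different code paths from the package: peptide
masses are composed from elemental formulas and atomic masses rather
than a residue-mass table, and the digestion oracle enumerates all
substrings instead of walking cleavage boundaries.
"""

from __future__ import annotations

# Monoisotopic atomic masses (u), typed from the standard atomic mass
# evaluation tables.
ATOM = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

# Residue (dehydrated amino acid) elemental compositions: (C, H, N, O, S)
RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}


def formula_mass(c: int, h: int, n: int, o: int, s: int) -> float:
    return (
        c * ATOM["C"] + h * ATOM["H"] + n * ATOM["N"] + o * ATOM["O"] + s * ATOM["S"]
    )


def oracle_residue_mass(aa: str) -> float:
    return formula_mass(*RESIDUE_FORMULA[aa])


def oracle_peptide_mass(sequence: str, mod_deltas: float = 0.0) -> float:
    """Neutral monoisotopic peptide mass from elemental composition."""
    water = formula_mass(0, 2, 0, 1, 0)
    return sum(oracle_residue_mass(aa) for aa in sequence) + water + mod_deltas


def brute_force_digest(
    protein: str,
    cleave_after: set[str],
    blocked_by_next: set[str],
    min_len: int,
    max_len: int,
    max_missed: int,
) -> set[tuple[int, int, int]]:
    """All fully-specific peptides by exhaustive substring enumeration.

    Returns ``(start, end, missed)`` triples.
    """
    n = len(protein)
    sites = {
        i + 1
        for i in range(n - 1)
        if protein[i] in cleave_after and protein[i + 1] not in blocked_by_next
    }
    boundaries = sites | {0, n}
    out = set()
    for s in range(n):
        if s not in boundaries:
            continue
        for e in range(s + 1, n + 1):
            if e not in boundaries:
                continue
            if not (min_len <= e - s <= max_len):
                continue
            missed = sum(1 for x in sites if s < x < e)
            if missed <= max_missed:
                out.add((s, e, missed))
    return out


def random_protein(rng, length: int) -> str:
    letters = sorted(RESIDUE_FORMULA)
    return "".join(rng.choice(letters, size=length))


def random_peptide(rng, min_len: int = 2, max_len: int = 40) -> str:
    return random_protein(rng, int(rng.integers(min_len, max_len + 1)))
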