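"""Genetic codes and frame-aware conceptual translation.

Euplotes ciliates use a variant nuclear genetic code (NCBI translation
table 10, "Euplotid Nuclear") in which the codon UGA is reassigned to
cysteine, leaving UAA and UAG as the only stop codons.  Because UGA no
longer terminates translation, a +1 programmed ribosomal frameshift at
a UAA/UAG "shifty stop" is the only way these genes can be read through
to a full-length product, and conceptual translation under the variant
code is the starting point of every downstream analysis in this
package.

Sequences are handled internally as RNA; DNA input (T) is silently
normalized to U, lowercase is uppercased, and ambiguity codes are
rejected because the downstream mass arithmetic cannot tolerate
undefined residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from Bio.Data import CodonTable

STOP = "*"
RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "STOP",
    "GeneticCode",
    "Transcript",
    "build_standard_code",
    "build_euplotes_code",
    "normalize_rna",
    "translate_frame",
]


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/U(T)."""


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase a nucleotide string and convert DNA T to RNA U.

    Ambiguity codes (N, R, Y, ...) and gaps are rejected rather than
    translated to X, because peptide masses are undefined for X.
    """
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"{context} contains non-A/C/G/U characters after normalization: "
            f"{sorted(bad)!r}"
        )
    return s


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 RNA codons to amino acids (STOP = ``*``)."""

    name: str
    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code {self.name!r} maps {len(self.codon_to_aa)} "
                "codons, expected 64"
            )

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    def translate_codon(self, codon: str) -> str:
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            raise SequenceAlphabetError(f"invalid codon {codon!r}") from None

    @classmethod
    def from_ncbi_table(cls, table_id: int, name: str | None = None) -> "GeneticCode":
        table = CodonTable.unambiguous_rna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = STOP
        return cls(name=name or table.names[0], codon_to_aa=mapping)


def build_standard_code() -> GeneticCode:
    """The universal genetic code (stops UAA/UAG/UGA)."""
    return GeneticCode.from_ncbi_table(1, "standard")


def build_euplotes_code() -> GeneticCode:
    """The Euplotes variant code: UGA encodes Cys; stops are UAA and UAG."""
    return GeneticCode.from_ncbi_table(10, "euplotes")


@dataclass(frozen=True)
class Transcript:
    """A named RNA sequence (DNA input is normalized on construction)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        norm = normalize_rna(self.seq, context=f"transcript {self.id!r}")
        if not norm:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)


def translate_frame(
    t: Transcript,
    frame: int,
    code: GeneticCode,
    stop_policy: str = "halt",
) -> str:
    """Conceptually translate ``t`` in one reading frame.

    Parameters
    ----------
    frame:
        Offset in {0, 1, 2} at which codon reading starts; must be
        smaller than the sequence length.
    stop_policy:
        ``"halt"`` ends the translation before the first stop codon;
        ``"readthrough"`` renders stops as ``*`` and continues.  The
        trailing partial codon, if any, is ignored in both modes.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if frame >= len(t.seq):
        raise ValueError(
            f"frame {frame} out of range for transcript of length {len(t.seq)}"
        )
    if stop_policy not in ("halt", "readthrough"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    return translate_segment(t.seq, frame, code, readthrough=(stop_policy == "readthrough"))


def translate_segment(
    seq: str,
    start: int,
    code: GeneticCode,
    *,
    end: int | None = None,
    readthrough: bool = False,
) -> str:
    """Translate codons from ``start`` (to ``end`` or the sequence end).

    Helper shared with the frameshift-model builder, which translates
    arbitrary same-frame segments of a transcript.
    """
    if end is None:
        end = len(seq)
    out: list[str] = []
    for i in range(start, end - 2, 3):
        aa = code.translate_codon(seq[i : i + 3])
        if aa == STOP and not readthrough:
            break
        out.append(aa)
    return "".join(out)
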