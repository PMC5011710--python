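"""FASTA / MGF / tabular input-output helpers.

Thin wrappers over Biopython (FASTA) and pyteomics (Mascot generic
format) so that the analysis modules never touch file formats directly.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .genetic_code import Transcript

__all__ = [
    "read_transcripts",
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
]


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a multi-FASTA file into ``(id, sequence)`` pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(os.fspath(path), "fasta")]


def read_transcripts(path: str | os.PathLike) -> list[Transcript]:
    """Read nucleotide FASTA as :class:`Transcript` (DNA normalized to RNA)."""
    return [Transcript(rid, seq) for rid, seq in read_fasta(path)]


def write_fasta(
    records: Iterable[tuple[str, str]],
    path: str | os.PathLike,
    *,
    width: int = 60,
) -> None:
    """Write ``(id, sequence)`` pairs as wrapped multi-FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(os.fspath(path), wrap=width)
    writer.write_file(seq_records)


def write_mgf(spectra: Sequence, path: str | os.PathLike) -> None:
    """Write observed spectra as an MGF peak list (pyteomics dialect).

    ``spectra`` are :class:`prfmap.matching.ObservedSpectrum` objects;
    TITLE carries the spectrum id, PEPMASS the precursor m/z and CHARGE
    the assumed precursor charge.
    """
    entries = []
    for s in spectra:
        mz_arr = [p[0] for p in s.peaks]
        it_arr = [p[1] for p in s.peaks]
        entries.append(
            {
                "m/z array": mz_arr,
                "intensity array": it_arr,
                "params": {
                    "title": s.id,
                    "pepmass": (s.precursor_mz, None),
                    "charge": f"{s.precursor_charge}+",
                },
            }
        )
    _mgf.write(entries, output=os.fspath(path), file_mode="w")


def read_mgf(path: str | os.PathLike) -> list:
    """Read an MGF peak list into :class:`ObservedSpectrum` objects."""
    from .matching import ObservedSpectrum  # local import avoids a cycle

    out = []
    with _mgf.MGF(os.fspath(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise ValueError(f"MGF block {title!r} lacks a PEPMASS line")
            charge_field = params.get("charge")
            if charge_field:
                charge = int(charge_field[0])
            else:
                charge = 2
            peaks = sorted(
                zip(
                    (float(x) for x in entry["m/z array"]),
                    (float(x) for x in entry["intensity array"]),
                )
            )
            out.append(
                ObservedSpectrum(
                    id=title,
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    peaks=tuple(peaks),
                )
            )
    return out
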