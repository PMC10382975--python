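"""Reading, writing and the in-memory model of DIA spectral libraries.

A spectral (assay) library is a flat transition table: one row per
fragment ion, rows grouped implicitly into precursors (a modified peptide
at a charge state), precursors into peptides (by modified sequence) and
peptides into protein groups. This module parses OpenSWATH-style
transition TSVs into that hierarchy and writes it back losslessly.

Two column dialects are supported: ``openswath`` (the canonical schema)
and ``diann`` (``Tr_recalibrated`` for the normalized RT and
``ProteinGroup`` for the protein assignment). Unknown extra columns are
carried through as opaque per-row metadata so that downstream filters do
not destroy information they do not understand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import FormatError, ValidationError

#: Canonical column order of the transition TSV.
CANONICAL_COLUMNS = [
    "PrecursorMz",
    "ProductMz",
    "LibraryIntensity",
    "NormalizedRetentionTime",
    "PeptideSequence",
    "ModifiedPeptideSequence",
    "PrecursorCharge",
    "FragmentType",
    "FragmentCharge",
    "FragmentSeriesNumber",
    "ProteinId",
]

#: Per-dialect renames applied on top of the canonical schema.
DIALECTS: dict[str, dict[str, str]] = {
    "openswath": {},
    "diann": {
        "NormalizedRetentionTime": "Tr_recalibrated",
        "ProteinId": "ProteinGroup",
    },
}

_MOD_TAG = re.compile(r"\[[^\]]*\]|\([^()]*\)")


def strip_modifications(modified_sequence: str) -> str:
    """Remove modification tags, keeping only upper-case residues.

    Tags are treated as opaque substrings — bracketed ``[...]`` blocks,
    parenthesised ``(...)`` blocks (applied repeatedly so nested
    parentheses unwind), terminal underscores and any remaining
    non-letter characters are dropped. No mass arithmetic is performed.
    """
    s = modified_sequence
    while True:
        stripped = _MOD_TAG.sub("", s)
        if stripped == s:
            break
        s = stripped
    return "".join(c for c in s if c.isalpha() and c.isupper())


@dataclass
class FragmentIon:
    """One product ion of a precursor.

    ``series_type`` is typically ``b`` or ``y``; ``series_number`` is the
    1-based index along the peptide backbone and must be smaller than the
    peptide length. ``extra`` holds unrecognised input columns verbatim.
    """

    product_mz: float
    fragment_charge: int
    series_type: str
    series_number: int
    library_intensity: float
    extra: dict[str, object] = field(default_factory=dict)

    def key(self) -> tuple[str, int, int]:
        return (self.series_type, self.series_number, self.fragment_charge)


@dataclass
class PrecursorRecord:
    """A charged, modified peptide with its fragment ions.

    The identity key within a library is ``(modified_sequence,
    precursor_charge)``. ``normalized_rt`` lives on the dimensionless iRT
    scale and may be negative. ``leading_protein`` is the representative
    accession of ``protein_group``.
    """

    modified_sequence: str
    stripped_sequence: str
    precursor_charge: int
    precursor_mz: float
    normalized_rt: float
    fragments: list[FragmentIon]
    protein_group: list[str]
    leading_protein: str

    def key(self) -> tuple[str, int]:
        return (self.modified_sequence, self.precursor_charge)

    def __post_init__(self) -> None:
        if self.protein_group and self.leading_protein not in self.protein_group:
            raise ValidationError(
                f"leading protein {self.leading_protein!r} not in group "
                f"{self.protein_group!r}"
            )


@dataclass
class SpectralLibrary:
    """A collection of precursors with peptide- and protein-level views."""

    precursors: list[PrecursorRecord]
    provenance: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.precursors)

    def __iter__(self) -> Iterator[PrecursorRecord]:
        return iter(self.precursors)

    def peptides(self) -> dict[str, list[PrecursorRecord]]:
        """Group precursors by modified sequence (insertion order kept)."""
        out: dict[str, list[PrecursorRecord]] = {}
        for prec in self.precursors:
            out.setdefault(prec.modified_sequence, []).append(prec)
        return out

    def proteins(self) -> dict[str, list[PrecursorRecord]]:
        """Group precursors by leading protein accession."""
        out: dict[str, list[PrecursorRecord]] = {}
        for prec in self.precursors:
            out.setdefault(prec.leading_protein, []).append(prec)
        return out

    def n_fragment_rows(self) -> int:
        return sum(len(p.fragments) for p in self.precursors)

    def replace(self, precursors: Iterable[PrecursorRecord], note: str | None = None) -> "SpectralLibrary":
        """Shallow-copy with a new precursor list, appending to the filter history."""
        prov = dict(self.provenance)
        if note:
            history = list(prov.get("filter_history", []))
            history.append(note)
            prov["filter_history"] = history
        return SpectralLibrary(list(precursors), prov)


def _dialect_columns(dialect: str) -> dict[str, str]:
    try:
        rename = DIALECTS[dialect]
    except KeyError:
        raise FormatError(
            f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}"
        ) from None
    return {canon: rename.get(canon, canon) for canon in CANONICAL_COLUMNS}


def read_library(path: str | Path, dialect: str = "openswath") -> SpectralLibrary:
    """Parse a transition TSV into a :class:`SpectralLibrary`.

    One :class:`PrecursorRecord` is created per distinct
    ``(modified_sequence, precursor_charge)`` pair; every input row
    becomes exactly one :class:`FragmentIon`, in file order. Rows sharing
    a fragment key within a precursor but disagreeing on intensity raise
    :class:`~diaspeclib.errors.ValidationError`.
    """
    path = Path(path)
    colmap = _dialect_columns(dialect)  # canonical -> file column
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty library file") from None
    if df.empty:
        raise FormatError(f"{path}: library file has a header but no rows")
    missing = [fc for fc in colmap.values() if fc not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    inverse = {fc: canon for canon, fc in colmap.items()}
    extra_cols = [c for c in df.columns if c not in inverse]

    precursors: list[PrecursorRecord] = []
    work = df.rename(columns=inverse)
    grouped = work.groupby(["ModifiedPeptideSequence", "PrecursorCharge"], sort=False)
    for (mod_seq, charge), rows in grouped:
        frags: list[FragmentIon] = []
        seen: dict[tuple[str, int, int], float] = {}
        for _, row in rows.iterrows():
            frag = FragmentIon(
                product_mz=float(row["ProductMz"]),
                fragment_charge=int(row["FragmentCharge"]),
                series_type=str(row["FragmentType"]),
                series_number=int(row["FragmentSeriesNumber"]),
                library_intensity=float(row["LibraryIntensity"]),
                extra={c: row[c] for c in extra_cols},
            )
            prev = seen.get(frag.key())
            if prev is not None and prev != frag.library_intensity:
                raise ValidationError(
                    f"{path}: conflicting duplicate rows for fragment "
                    f"{frag.key()} of precursor ({mod_seq}, {charge})"
                )
            seen[frag.key()] = frag.library_intensity
            frags.append(frag)
        first = rows.iloc[0]
        group = str(first["ProteinId"]).split(";")
        precursors.append(
            PrecursorRecord(
                modified_sequence=str(mod_seq),
                stripped_sequence=str(first["PeptideSequence"]),
                precursor_charge=int(charge),
                precursor_mz=float(first["PrecursorMz"]),
                normalized_rt=float(first["NormalizedRetentionTime"]),
                fragments=frags,
                protein_group=group,
                leading_protein=group[0],
            )
        )
    return SpectralLibrary(
        precursors,
        provenance={"source": str(path), "dialect": dialect, "filter_history": []},
    )


def library_to_frame(lib: SpectralLibrary, dialect: str = "openswath") -> pd.DataFrame:
    """Flatten a library to one row per fragment with dialect column names."""
    colmap = _dialect_columns(dialect)
    rows = []
    extra_keys: list[str] = []
    for prec in lib.precursors:
        for frag in prec.fragments:
            row = {
                colmap["PrecursorMz"]: prec.precursor_mz,
                colmap["ProductMz"]: frag.product_mz,
                colmap["LibraryIntensity"]: frag.library_intensity,
                colmap["NormalizedRetentionTime"]: prec.normalized_rt,
                colmap["PeptideSequence"]: prec.stripped_sequence,
                colmap["ModifiedPeptideSequence"]: prec.modified_sequence,
                colmap["PrecursorCharge"]: prec.precursor_charge,
                colmap["FragmentType"]: frag.series_type,
                colmap["FragmentCharge"]: frag.fragment_charge,
                colmap["FragmentSeriesNumber"]: frag.series_number,
                colmap["ProteinId"]: ";".join(prec.protein_group),
            }
            for k, v in frag.extra.items():
                row[k] = v
                if k not in extra_keys:
                    extra_keys.append(k)
            rows.append(row)
    columns = [colmap[c] for c in CANONICAL_COLUMNS] + extra_keys
    return pd.DataFrame(rows, columns=columns)


def write_library(lib: SpectralLibrary, path: str | Path, dialect: str = "openswath") -> None:
    """Write a library as a transition TSV (one row per fragment ion).

    Floats are rendered with 10 significant digits so a write/read
    round-trip reproduces every numeric field well within 1e-6 relative
    tolerance. Writing an empty library is an error and creates no file.
    """
    if not lib.precursors:
        raise ValidationError("refusing to write an empty library")
    frame = library_to_frame(lib, dialect)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
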