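"""Library characterization and multi-library comparison.

Entity counts follow the library hierarchy — precursors keyed by
(modified sequence, charge), peptides by modified sequence, proteins by
leading accession — so counts always satisfy
``n_proteins <= n_peptides <= n_precursors``. Library comparison
produces exclusive (UpSet-style) intersection counts: for every
non-empty subset of the input libraries, the number of entities present
in exactly those libraries, which partition the union. Gene-set
coverage measures what fraction of an external identifier list a
library's proteins account for.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .speclib_io import SpectralLibrary

_ISOFORM_SUFFIX = re.compile(r"-\d+$")
MAX_LIBRARIES = 16


@dataclass(frozen=True)
class EntityCounts:
    n_precursors: int
    n_peptides: int
    n_proteins: int

    def __post_init__(self) -> None:
        if not self.n_proteins <= self.n_peptides <= self.n_precursors:
            raise ValidationError(
                "entity counts must satisfy proteins <= peptides <= precursors"
            )


def count_entities(lib: SpectralLibrary) -> EntityCounts:
    """Count precursors, peptides and proteins of a library."""
    return EntityCounts(
        n_precursors=len({p.key() for p in lib.precursors}),
        n_peptides=len({p.modified_sequence for p in lib.precursors}),
        n_proteins=len({p.leading_protein for p in lib.precursors}),
    )


def strip_isoform_suffix(accession: str) -> str:
    return _ISOFORM_SUFFIX.sub("", accession)


def library_keys(
    lib: SpectralLibrary,
    level: str,
    stripped_peptides: bool = False,
    keep_isoforms: bool = False,
) -> set:
    """Extract the comparison key set of a library at a given level."""
    if level == "precursor":
        return {p.key() for p in lib.precursors}
    if level == "peptide":
        if stripped_peptides:
            return {p.stripped_sequence for p in lib.precursors}
        return {p.modified_sequence for p in lib.precursors}
    if level == "protein":
        accs = {p.leading_protein for p in lib.precursors}
        if not keep_isoforms:
            accs = {strip_isoform_suffix(a) for a in accs}
        return accs
    raise ValueError(f"unknown level {level!r}")


@dataclass
class IntersectionTable:
    """Exclusive intersection counts over k libraries.

    ``counts`` maps each non-empty subset of library names (as a sorted
    tuple) to the number of entities present in exactly those libraries;
    the counts partition the union.
    """

    names: list[str]
    counts: dict[tuple[str, ...], int]
    totals: dict[str, int] = field(default_factory=dict)
    union_size: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pattern": "&".join(pattern), "degree": len(pattern), "count": n}
            for pattern, n in sorted(
                self.counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["pattern", "degree", "count"])


def intersect_libraries(
    libs: Sequence[SpectralLibrary] | Sequence[set] | Mapping[str, set],
    level: str = "protein",
    names: Sequence[str] | None = None,
    stripped_peptides: bool = False,
    keep_isoforms: bool = False,
) -> IntersectionTable:
    """Exclusive intersection counts over >= 2 libraries or key sets.

    Every element of the union is assigned to exactly one presence
    pattern (the subset of libraries containing it); all 2^k - 1
    patterns are reported, zeros included.
    """
    if isinstance(libs, Mapping):
        names = list(libs.keys())
        inputs: list = list(libs.values())
    else:
        inputs = list(libs)
    if len(inputs) < 2:
        raise ValidationError("need at least 2 libraries to intersect")
    if len(inputs) > MAX_LIBRARIES:
        raise ValidationError(
            f"refusing to build a {2 ** len(inputs) - 1}-row table; "
            f"at most {MAX_LIBRARIES} libraries supported"
        )
    if names is None:
        names = [f"lib{i + 1}" for i in range(len(inputs))]
    key_sets = [
        library_keys(x, level, stripped_peptides, keep_isoforms)
        if isinstance(x, SpectralLibrary)
        else set(x)
        for x in inputs
    ]
    counts: dict[tuple[str, ...], int] = {
        tuple(sorted(combo)): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    union = set().union(*key_sets)
    for element in union:
        pattern = tuple(
            sorted(n for n, ks in zip(names, key_sets) if element in ks)
        )
        counts[pattern] += 1
    return IntersectionTable(
        names=list(names),
        counts=counts,
        totals={n: len(ks) for n, ks in zip(names, key_sets)},
        union_size=len(union),
    )


def _normalize_identifier(ident: str) -> str:
    return strip_isoform_suffix(ident.strip()).casefold()


@dataclass
class CoverageResult:
    coverage: float
    covered: list[str]
    uncovered: list[str]


def gene_set_coverage(
    lib_proteins: Iterable[str],
    gene_set: Sequence[str],
    mapping: Mapping[str, str] | None = None,
) -> CoverageResult:
    """Fraction of a gene/protein identifier list covered by a library.

    ``mapping`` optionally translates library accessions to the gene
    identifier space before comparison. Identifiers are compared after
    case-folding and isoform-suffix stripping.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("gene_set must be non-empty")
    lib_ids = set()
    mapping_norm = (
        {_normalize_identifier(k): v for k, v in mapping.items()} if mapping else None
    )
    for acc in lib_proteins:
        norm = _normalize_identifier(acc)
        if mapping_norm is not None and norm in mapping_norm:
            lib_ids.add(_normalize_identifier(mapping_norm[norm]))
        else:
            lib_ids.add(norm)
    covered = [g for g in gene_set if _normalize_identifier(g) in lib_ids]
    uncovered = [g for g in gene_set if _normalize_identifier(g) not in lib_ids]
    return CoverageResult(
        coverage=len(covered) / len(gene_set), covered=covered, uncovered=uncovered
    )


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_mapping_table(path) -> dict[str, str]:
    """Two-column TSV accession → gene symbol (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
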