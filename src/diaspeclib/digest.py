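"""In-silico trypsin digestion and peptide classification.

Trypsin cleaves C-terminal to lysine (K) and arginine (R); by default
cleavage is suppressed when the next residue is proline. Two digestion
modes are provided:

* ``full`` — both peptide termini coincide with a cleavage site or a
  protein terminus, with at most ``max_missed_cleavages`` uncut internal
  sites;
* ``semi`` — additionally every N- or C-terminal truncation of a full
  peptide, i.e. peptides with exactly one tryptic-consistent terminus.
  Such semi-tryptic peptides arise from in-vivo or in-process protein
  truncation and the full set is always a subset of the semi set.

The module also classifies arbitrary peptides against a protein database
(full-tryptic / semi-tryptic / non-tryptic / not found) and detects
isoform-specific peptides: digestion products of an isoform sequence
that do not occur anywhere in the canonical sequence, which are the only
direct sequence evidence that discriminates a proteoform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import FormatError, ValidationError

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_ISOFORM_SUFFIX = re.compile(r"^(?P<base>.+)-(?P<n>\d+)$")


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings; defaults are the common search-engine ones
    (peptides of 7-50 residues, up to 2 missed cleavages, cleavage after
    K/R suppressed before proline)."""

    min_length: int = 7
    max_length: int = 50
    max_missed_cleavages: int = 2
    cleave_after: frozenset[str] = frozenset({"K", "R"})
    suppress_before_proline: bool = True
    mode: str = "full"

    def __post_init__(self) -> None:
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.mode not in {"full", "semi"}:
            raise ValueError(f"mode must be 'full' or 'semi', got {self.mode!r}")
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))


class PeptideClass(Enum):
    """Tryptic consistency of a peptide's termini within a protein.

    The suffix letter names the terminus that IS tryptic-consistent:
    ``semi_tryptic_C`` has a tryptic C-terminus and a ragged N-terminus,
    ``semi_tryptic_N`` the reverse. Ranking (best first): full_tryptic,
    semi_tryptic_C, semi_tryptic_N, non_tryptic, not_found.
    """

    full_tryptic = 4
    semi_tryptic_C = 3
    semi_tryptic_N = 2
    non_tryptic = 1
    not_found = 0


@dataclass
class ClassifiedPeptide:
    value: PeptideClass
    matched_accessions: list[str] = field(default_factory=list)


@dataclass
class ProteinDB:
    """Accession → sequence mapping with isoform bookkeeping.

    Isoform accessions follow the UniProt ``-N`` suffix convention
    (``P12345-2`` is the second isoform of canonical ``P12345``);
    ``canonical_of`` maps each isoform accession to its canonical base.
    """

    records: dict[str, str]
    canonical_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, seq in self.records.items():
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                raise ValidationError(
                    f"{acc}: invalid residue(s) {''.join(sorted(bad))!r}"
                )
        if not self.canonical_of:
            self.canonical_of = {
                acc: m.group("base")
                for acc in self.records
                if (m := _ISOFORM_SUFFIX.match(acc))
            }

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinDB":
        """Read a UniProt-style FASTA; the accession is the second
        pipe-delimited header token (or the whole first word)."""
        records: dict[str, str] = {}
        acc: str | None = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    if acc is not None:
                        records[acc] = "".join(chunks)
                    header = line[1:].split()[0]
                    parts = header.split("|")
                    acc = parts[1] if len(parts) >= 2 else parts[0]
                    chunks = []
                elif line:
                    chunks.append(line.strip().upper())
        if acc is not None:
            records[acc] = "".join(chunks)
        if not records:
            raise FormatError(f"{path}: no FASTA records found")
        return cls(records)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for acc, seq in self.records.items():
                fh.write(f">sp|{acc}|{acc.replace('-', '_')}_SYNTH\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def cleavage_sites(seq: str, params: DigestParams = DigestParams()) -> list[int]:
    """Internal cleavage positions: index i means a cut between
    ``seq[i-1]`` and ``seq[i]``."""
    return [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in params.cleave_after
        and not (params.suppress_before_proline and seq[i] == "P")
    ]


def digest_protein(seq: str, params: DigestParams = DigestParams()) -> set[str]:
    """Digest one protein sequence into peptides.

    Protein termini count as valid peptide termini. Peptides containing
    the undefined residue X are excluded. In ``semi`` mode the result
    additionally contains every prefix/suffix truncation of each full
    peptide that meets the length bounds; the full set is a subset of
    the semi set by construction.
    """
    if not seq:
        raise ValidationError("empty protein sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValidationError(f"invalid residue(s) {''.join(sorted(bad))!r}")
    sites = [0] + cleavage_sites(seq, params) + [len(seq)]
    lo, hi = params.min_length, params.max_length

    def ok(pep: str) -> bool:
        return lo <= len(pep) <= hi and "X" not in pep

    out: set[str] = set()
    for i in range(len(sites) - 1):
        # j - i - 1 internal sites are left uncut (missed cleavages)
        for j in range(i + 1, min(i + params.max_missed_cleavages + 2, len(sites))):
            start, end = sites[i], sites[j]
            pep = seq[start:end]
            if ok(pep):
                out.add(pep)
            if params.mode == "semi":
                for cut in range(start + 1, end):
                    prefix = seq[start:cut]  # tryptic N-terminus
                    if ok(prefix):
                        out.add(prefix)
                    suffix = seq[cut:end]  # tryptic C-terminus
                    if ok(suffix):
                        out.add(suffix)
    return out


def digest_db(db: ProteinDB, params: DigestParams = DigestParams()) -> dict[str, set[str]]:
    """Digest every protein of a database; accession → peptide set."""
    return {acc: digest_protein(seq, params) for acc, seq in db.records.items()}


def _termini_flags(seq: str, start: int, end: int, params: DigestParams) -> tuple[bool, bool]:
    """Tryptic consistency of the two termini of ``seq[start:end]``."""
    n_ok = start == 0 or (
        seq[start - 1] in params.cleave_after
        and not (params.suppress_before_proline and seq[start] == "P")
    )
    c_ok = end == len(seq) or (
        seq[end - 1] in params.cleave_after
        and not (params.suppress_before_proline and seq[end] == "P")
    )
    return n_ok, c_ok


def classify_peptide(
    pep: str, db: ProteinDB, params: DigestParams = DigestParams()
) -> ClassifiedPeptide:
    """Classify a peptide by its best tryptic consistency over all
    occurrences in all database sequences.

    Only termini are inspected (missed cleavages are not limited here).
    ``matched_accessions`` lists the accessions in which an occurrence
    achieving the best class was found, in sorted order.
    """
    if not pep:
        raise ValidationError("empty peptide")
    if not params.min_length <= len(pep) <= params.max_length:
        raise ValidationError(
            f"peptide length {len(pep)} outside [{params.min_length}, {params.max_length}]"
        )
    pep = pep.upper()
    best = PeptideClass.not_found
    matches: dict[PeptideClass, set[str]] = {}
    for acc, seq in db.records.items():
        start = seq.find(pep)
        while start != -1:
            n_ok, c_ok = _termini_flags(seq, start, start + len(pep), params)
            if n_ok and c_ok:
                cls = PeptideClass.full_tryptic
            elif c_ok:
                cls = PeptideClass.semi_tryptic_C
            elif n_ok:
                cls = PeptideClass.semi_tryptic_N
            else:
                cls = PeptideClass.non_tryptic
            matches.setdefault(cls, set()).add(acc)
            if cls.value > best.value:
                best = cls
            start = seq.find(pep, start + 1)
    accs = sorted(matches.get(best, set()))
    return ClassifiedPeptide(value=best, matched_accessions=accs)


def isoform_specific_peptides(
    db: ProteinDB,
    accession: str,
    params: DigestParams = DigestParams(),
    strict: bool = False,
) -> set[str]:
    """Digestion products of an isoform that do not occur in its
    canonical sequence.

    Exclusion is by substring containment, not digest membership: a
    peptide present anywhere in the canonical sequence cannot
    discriminate the isoform. With ``strict=True`` the peptide must also
    be absent from every other database sequence.
    """
    if accession not in db.records:
        raise ValidationError(f"accession {accession!r} not in database")
    canonical = db.canonical_of.get(accession)
    if canonical is None or canonical not in db.records:
        raise ValidationError(f"no canonical partner for {accession!r} in database")
    iso_seq = db.records[accession]
    canon_seq = db.records[canonical]
    peps = {p for p in digest_protein(iso_seq, params) if p not in canon_seq}
    if strict:
        others = [s for a, s in db.records.items() if a != accession]
        peps = {p for p in peps if not any(p in s for s in others)}
    return peps
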