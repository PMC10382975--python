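"""Three-stage quality control of a spectral library.

The filter cascade removes library entries that are unusable for
DIA scoring:

1. **Stage 1** keeps only precursors with at least ``min_fragments``
   fragment ions and a normalized RT inside the closed window
   ``[rt_min, rt_max]`` (the iRT scale may be negative, so the window
   default reaches down to -60).
2. **Stage 2** drops fragments with a library intensity below
   ``min_fragment_intensity`` and whole precursors whose charge is in
   ``excluded_precursor_charges`` (singly charged by default). A
   precursor whose surviving fragment count falls below
   ``min_fragments`` is then dropped too — a one-fragment precursor
   cannot be scored.
3. **RT consistency** checks that the precursors of a peptide agree on
   their normalized RT. Deviations are taken from the peptide's mean RT;
   precursors deviating by more than ``max_rt_deviation`` are removed.
   If *every* precursor deviates, the check falls back to the median RT
   and keeps precursors strictly within the threshold. Single-precursor
   peptides pass unchanged.

Each stage returns the filtered library plus a :class:`QCReport`
tallying removals per rule; a precursor is attributed to the first rule
that removes it. ``run_qc`` chains the stages and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from statistics import mean, median

from .speclib_io import PrecursorRecord, SpectralLibrary


@dataclass(frozen=True)
class QCThresholds:
    """Tunable thresholds of the QC cascade (defaults follow common
    curation practice for iRT-normalized pan-human libraries)."""

    min_fragments: int = 2
    rt_min: float = -60.0
    rt_max: float = 200.0
    min_fragment_intensity: float = 10.0
    excluded_precursor_charges: frozenset[int] = frozenset({1})
    max_rt_deviation: float = 5.0

    def __post_init__(self) -> None:
        if self.rt_min >= self.rt_max:
            raise ValueError("rt_min must be below rt_max")
        if self.min_fragments < 1:
            raise ValueError("min_fragments must be >= 1")
        if self.max_rt_deviation <= 0:
            raise ValueError("max_rt_deviation must be positive")
        object.__setattr__(
            self, "excluded_precursor_charges", frozenset(self.excluded_precursor_charges)
        )


@dataclass
class QCReport:
    """Per-rule removal counts plus input/output entity counts.

    Counts satisfy the conservation law: at each entity level, input
    minus removals equals output.
    """

    precursors_removed_min_fragments: int = 0
    precursors_removed_rt_range: int = 0
    precursors_removed_charge: int = 0
    fragments_removed_low_intensity: int = 0
    precursors_removed_low_fragments_after_intensity: int = 0
    precursors_removed_rt_inconsistent: int = 0
    peptides_removed_rt_inconsistent: int = 0
    input_counts: dict[str, int] = field(default_factory=dict)
    output_counts: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "QCReport") -> "QCReport":
        """Combine two stage reports; input from self, output from other."""
        merged = QCReport(
            input_counts=dict(self.input_counts),
            output_counts=dict(other.output_counts),
        )
        for f in fields(QCReport):
            if f.type == "int":
                setattr(
                    merged, f.name, getattr(self, f.name) + getattr(other, f.name)
                )
        return merged

    def to_dict(self) -> dict[str, int]:
        out = {
            f.name: getattr(self, f.name) for f in fields(QCReport) if f.type == "int"
        }
        for k, v in self.input_counts.items():
            out[f"input_{k}"] = v
        for k, v in self.output_counts.items():
            out[f"output_{k}"] = v
        return out


def _entity_counts(lib: SpectralLibrary) -> dict[str, int]:
    return {
        "precursors": len(lib.precursors),
        "peptides": len(lib.peptides()),
        "proteins": len(lib.proteins()),
        "fragments": lib.n_fragment_rows(),
    }


def filter_stage1(
    lib: SpectralLibrary, t: QCThresholds = QCThresholds()
) -> tuple[SpectralLibrary, QCReport]:
    """Keep precursors with enough fragments and RT in the closed window."""
    report = QCReport(input_counts=_entity_counts(lib))
    kept: list[PrecursorRecord] = []
    for prec in lib.precursors:
        if len(prec.fragments) < t.min_fragments:
            report.precursors_removed_min_fragments += 1
        elif not (t.rt_min <= prec.normalized_rt <= t.rt_max):
            report.precursors_removed_rt_range += 1
        else:
            kept.append(prec)
    out = lib.replace(kept, note="stage1:fragment-count+rt-window")
    report.output_counts = _entity_counts(out)
    return out, report


def filter_stage2(
    lib: SpectralLibrary, t: QCThresholds = QCThresholds()
) -> tuple[SpectralLibrary, QCReport]:
    """Drop low-intensity fragments and excluded precursor charges."""
    report = QCReport(input_counts=_entity_counts(lib))
    kept: list[PrecursorRecord] = []
    for prec in lib.precursors:
        if prec.precursor_charge in t.excluded_precursor_charges:
            report.precursors_removed_charge += 1
            continue
        good = [f for f in prec.fragments if f.library_intensity >= t.min_fragment_intensity]
        n_dropped = len(prec.fragments) - len(good)
        report.fragments_removed_low_intensity += n_dropped
        if len(good) < t.min_fragments:
            report.precursors_removed_low_fragments_after_intensity += 1
            continue
        kept.append(replace(prec, fragments=good) if n_dropped else prec)
    out = lib.replace(kept, note="stage2:intensity+charge")
    report.output_counts = _entity_counts(out)
    return out, report


def rt_consistency_filter(
    lib: SpectralLibrary,
    t: QCThresholds = QCThresholds(),
    scope: str = "precursor",
) -> tuple[SpectralLibrary, QCReport]:
    """Remove precursors whose RT disagrees with their peptide's consensus.

    ``scope='precursor'`` (default) removes only the deviant precursors;
    ``scope='peptide'`` removes the whole peptide as soon as any of its
    precursors deviates. Deviation is measured from the mean normalized
    RT (strictly greater than ``max_rt_deviation`` fails); when every
    precursor fails, deviations are recomputed from the median and
    precursors strictly within the threshold are rescued.
    """
    if scope not in {"precursor", "peptide"}:
        raise ValueError(f"unknown scope {scope!r}")
    report = QCReport(input_counts=_entity_counts(lib))
    survivors: dict[tuple[str, int], PrecursorRecord] = {}
    for pep_seq, precs in lib.peptides().items():
        if len(precs) == 1:
            survivors[precs[0].key()] = precs[0]
            continue
        rts = [p.normalized_rt for p in precs]
        center = mean(rts)
        kept = [p for p in precs if abs(p.normalized_rt - center) <= t.max_rt_deviation]
        if not kept:
            center = median(rts)
            kept = [p for p in precs if abs(p.normalized_rt - center) < t.max_rt_deviation]
        removed = len(precs) - len(kept)
        if scope == "peptide" and removed:
            kept, removed = [], len(precs)
        report.precursors_removed_rt_inconsistent += removed
        if not kept:
            report.peptides_removed_rt_inconsistent += 1
        for p in kept:
            survivors[p.key()] = p
    ordered = [p for p in lib.precursors if p.key() in survivors]
    out = lib.replace(ordered, note=f"rt-consistency:scope={scope}")
    report.output_counts = _entity_counts(out)
    return out, report


def run_qc(
    lib: SpectralLibrary,
    t: QCThresholds = QCThresholds(),
    scope: str = "precursor",
) -> tuple[SpectralLibrary, QCReport]:
    """Run the full cascade: stage 1, stage 2, then RT consistency."""
    s1, r1 = filter_stage1(lib, t)
    s2, r2 = filter_stage2(s1, t)
    s3, r3 = rt_consistency_filter(s2, t, scope=scope)
    return s3, r1.merge(r2).merge(r3)
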