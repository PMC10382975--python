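"""Deterministic synthetic data: protein databases, spectral libraries
with planted QC violations, anchor RT data, and labeled cohorts.

Every generator draws from a named substream of a single master seed
(`SeedSequence` keyed by a stable hash of the stream name), so adding a
new generator never perturbs the output of an existing one and the same
seed always yields byte-identical files.

The generators emulate the statistical structure the curation
procedures assume — tryptic peptides of realistic length, iRT-scale
retention times produced by an affine map of run RT, log-normal protein
abundances with a planted fraction of differential proteins — not the
physics of fragmentation or chromatography. Each generator returns a
ground-truth ledger (planted violation ids, true RT map, true effect
sizes) sufficient to compute the exact expected output of the
downstream module it feeds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import DigestParams, ProteinDB, digest_protein
from .rt import AnchorSet
from .speclib_io import FragmentIon, PrecursorRecord, SpectralLibrary

_AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # K/R drawn separately


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG for a named component."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SynthSpec:
    """All knobs of the synthetic test bed (defaults give a small,
    fast fixture that still exercises every filter rule)."""

    seed: int
    # protein database
    n_proteins: int = 20
    protein_length_mean: int = 300
    protein_length_sd: int = 60
    kr_density: float = 0.08
    n_isoforms: int = 2
    substitution_block_length: int = 8
    # spectral library
    peptides_per_protein: int = 12
    fragment_count_low: int = 4
    fragment_count_high: int = 8
    rt_true_slope: float = 2.0
    rt_true_intercept: float = -20.0
    rt_noise_sd: float = 0.0
    # planted violation counts (absolute, kept disjoint)
    n_singleton_fragment: int = 0
    n_rt_outlier: int = 0
    n_low_intensity_fragment: int = 0
    n_charge1: int = 0
    n_rt_inconsistent_peptides: int = 0
    # cohort
    cohort_n_per_class: tuple[int, int] = (20, 20)
    cohort_n_proteins: int = 200
    de_fraction: float = 0.1
    log2fc_effect: float = 2.0
    cohort_noise_sd: float = 0.5
    mcar_rate: float = 0.0
    mnar_rate: float = 0.0
    class_names: tuple[str, str] = ("benign", "tumor")


@dataclass
class LibraryLedger:
    """Ground truth of planted library violations (precursor keys)."""

    singleton_fragment: list[tuple[str, int]] = field(default_factory=list)
    rt_outlier: list[tuple[str, int]] = field(default_factory=list)
    low_intensity_fragment: list[tuple[str, int]] = field(default_factory=list)
    charge1: list[tuple[str, int]] = field(default_factory=list)
    rt_inconsistent_peptides: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "singleton_fragment": len(self.singleton_fragment),
            "rt_outlier": len(self.rt_outlier),
            "low_intensity_fragment": len(self.low_intensity_fragment),
            "charge1": len(self.charge1),
            "rt_inconsistent_peptides": len(self.rt_inconsistent_peptides),
        }


def _random_protein(rng: np.random.Generator, length: int, kr_density: float) -> str:
    picks = rng.random(length)
    body = [
        ("K" if rng.random() < 0.5 else "R")
        if p < kr_density
        else _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))]
        for p in picks
    ]
    return "".join(body)


def generate_protein_db(spec: SynthSpec) -> ProteinDB:
    """Random protein database with recorded isoform substitution blocks.

    Isoforms copy a canonical sequence and replace a contiguous block
    (``substitution_block_length`` residues) with fresh random residues
    guaranteed to differ, so isoform-specific peptides exist whenever
    the block is long enough to fall inside a digestible peptide.
    """
    rng = substream(spec.seed, "protein_db")
    records: dict[str, str] = {}
    for i in range(spec.n_proteins):
        length = max(
            50, int(rng.normal(spec.protein_length_mean, spec.protein_length_sd))
        )
        records[f"P{i + 1:05d}"] = _random_protein(rng, length, spec.kr_density)
    accs = list(records)
    for j in range(min(spec.n_isoforms, len(accs))):
        canonical = accs[j]
        seq = records[canonical]
        blk = spec.substitution_block_length
        if blk <= 0 or blk >= len(seq):
            records[f"{canonical}-2"] = seq
            continue
        start = int(rng.integers(1, len(seq) - blk))
        while True:
            block = "".join(
                _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))] for _ in range(blk)
            )
            if block != seq[start : start + blk]:
                break
        records[f"{canonical}-2"] = seq[:start] + block + seq[start + blk :]
    return ProteinDB(records)


def _make_fragments(
    rng: np.random.Generator, pep_len: int, n_frags: int, min_intensity: float = 10.0
) -> list[FragmentIon]:
    frags = []
    numbers = rng.choice(np.arange(1, pep_len), size=min(n_frags, pep_len - 1), replace=False)
    for k, num in enumerate(sorted(int(x) for x in numbers)):
        frags.append(
            FragmentIon(
                product_mz=float(np.round(rng.uniform(200, 1500), 4)),
                fragment_charge=1,
                series_type="y" if k % 2 == 0 else "b",
                series_number=num,
                library_intensity=float(
                    np.round(min_intensity + rng.lognormal(4.0, 1.0), 4)
                ),
            )
        )
    return frags


def generate_library(
    db: ProteinDB, spec: SynthSpec
) -> tuple[SpectralLibrary, LibraryLedger]:
    """Spectral library from digested peptides with planted violations.

    The clean library assigns every precursor of a peptide the same
    normalized RT (an affine map of a uniform "run RT" plus optional
    noise), fragment intensities >= 10 and charges 2/3, so it passes QC
    untouched. Violations are then planted in disjoint precursor sets
    at the exact counts requested in the spec and recorded in the
    ledger:

    * ``singleton_fragment`` — precursor reduced to one fragment;
    * ``rt_outlier`` — normalized RT pushed outside [-60, 200];
    * ``low_intensity_fragment`` — one extra sub-threshold fragment
      added (the precursor itself survives QC);
    * ``charge1`` — an extra +1 charge state appended for a peptide;
    * ``rt_inconsistent_peptides`` — a third precursor added 30 iRT
      units away from its two consistent siblings, which the
      consistency rule removes via the median fallback.
    """
    if not db.records:
        raise ValueError("empty protein database")
    rng = substream(spec.seed, "library")
    params = DigestParams()
    precursors: list[PrecursorRecord] = []
    seen_peptides: set[str] = set()
    for acc in db.records:
        seq = db.records[acc]
        peps = sorted(digest_protein(seq, params))
        if not peps:
            continue
        take = min(spec.peptides_per_protein, len(peps))
        chosen = rng.choice(len(peps), size=take, replace=False)
        for idx in sorted(int(i) for i in chosen):
            pep = peps[idx]
            if pep in seen_peptides:
                continue
            seen_peptides.add(pep)
            run_rt = float(rng.uniform(5, 95))
            irt = spec.rt_true_slope * run_rt + spec.rt_true_intercept
            if spec.rt_noise_sd > 0:
                irt += float(rng.normal(0, spec.rt_noise_sd))
            charges = [2, 3] if rng.random() < 0.4 else [2]
            for charge in charges:
                n_frags = int(
                    rng.integers(spec.fragment_count_low, spec.fragment_count_high + 1)
                )
                precursors.append(
                    PrecursorRecord(
                        modified_sequence=pep,
                        stripped_sequence=pep,
                        precursor_charge=charge,
                        precursor_mz=float(np.round(rng.uniform(400, 1200), 4)),
                        normalized_rt=float(np.round(irt, 4)),
                        fragments=_make_fragments(rng, len(pep), n_frags),
                        protein_group=[acc],
                        leading_protein=acc,
                    )
                )
    ledger = LibraryLedger()
    # violations are planted on disjoint PEPTIDES so rules never interact
    # and the ledger predicts the QC report exactly
    peptide_first: dict[str, int] = {}
    for idx, p in enumerate(precursors):
        peptide_first.setdefault(p.modified_sequence, idx)
    peptide_pool = list(peptide_first)
    needed = (
        spec.n_singleton_fragment
        + spec.n_rt_outlier
        + spec.n_low_intensity_fragment
        + spec.n_charge1
        + spec.n_rt_inconsistent_peptides
    )
    if needed > len(peptide_pool):
        raise ValueError("not enough peptides to plant the requested violations")
    order = rng.permutation(len(peptide_pool))
    victims = [peptide_first[peptide_pool[int(i)]] for i in order[:needed]]
    pos = 0

    def take(n: int) -> list[int]:
        nonlocal pos
        sel = victims[pos : pos + n]
        pos += n
        return sel

    for i in take(spec.n_singleton_fragment):
        p = precursors[i]
        p.fragments = p.fragments[:1]
        ledger.singleton_fragment.append(p.key())
    for i in take(spec.n_rt_outlier):
        p = precursors[i]
        p.normalized_rt = float(
            np.round(float(rng.choice([-200.0, 300.0])) + rng.uniform(0, 50), 4)
        )
        ledger.rt_outlier.append(p.key())
    for i in take(spec.n_low_intensity_fragment):
        p = precursors[i]
        used = {f.key() for f in p.fragments}
        series_type, series_number = next(
            (st, num)
            for num in range(1, len(p.modified_sequence))
            for st in ("y", "b")
            if (st, num, 1) not in used
        )
        p.fragments = p.fragments + [
            FragmentIon(
                product_mz=float(np.round(rng.uniform(200, 1500), 4)),
                fragment_charge=1,
                series_type=series_type,
                series_number=series_number,
                library_intensity=float(np.round(rng.uniform(0.5, 9.5), 4)),
            )
        ]
        ledger.low_intensity_fragment.append(p.key())
    for i in take(spec.n_charge1):
        base = precursors[i]
        precursors.append(
            PrecursorRecord(
                modified_sequence=base.modified_sequence,
                stripped_sequence=base.stripped_sequence,
                precursor_charge=1,
                precursor_mz=base.precursor_mz,
                normalized_rt=base.normalized_rt,
                fragments=_make_fragments(rng, len(base.modified_sequence), 4),
                protein_group=list(base.protein_group),
                leading_protein=base.leading_protein,
            )
        )
        ledger.charge1.append((base.modified_sequence, 1))
    for i in take(spec.n_rt_inconsistent_peptides):
        base = precursors[i]
        # add one consistent and one deviant extra charge state: the
        # peptide's RTs become {r, ..., r, r+30}, all mean-deviations
        # exceed the threshold, and the median fallback rescues
        # everything except the deviant precursor
        for charge, rt_shift in ((4, 0.0), (5, 30.0)):
            precursors.append(
                PrecursorRecord(
                    modified_sequence=base.modified_sequence,
                    stripped_sequence=base.stripped_sequence,
                    precursor_charge=charge,
                    precursor_mz=base.precursor_mz,
                    normalized_rt=float(np.round(base.normalized_rt + rt_shift, 4)),
                    fragments=_make_fragments(rng, len(base.modified_sequence), 4),
                    protein_group=list(base.protein_group),
                    leading_protein=base.leading_protein,
                )
            )
        ledger.rt_inconsistent_peptides.append(base.modified_sequence)
    lib = SpectralLibrary(
        precursors, provenance={"source": "synth", "seed": spec.seed, "filter_history": []}
    )
    return lib, ledger


def generate_anchor_data(
    spec: SynthSpec, n_anchors: int = 100, n_runs: int = 1
) -> tuple[AnchorSet, list[dict[str, float]]]:
    """Anchor peptides with reference iRTs plus per-run observed RTs.

    Observed run RT is the inverse affine map of the reference iRT with
    Gaussian noise of ``rt_noise_sd`` minutes, emulating independent
    chromatographic runs of the same anchor panel.
    """
    rng = substream(spec.seed, "anchors")
    seqs = []
    while len(seqs) < n_anchors:
        length = int(rng.integers(8, 16))
        s = _random_protein(rng, length - 1, 0.0) + ("K" if rng.random() < 0.5 else "R")
        if s not in seqs:
            seqs.append(s)
    irts = np.round(rng.uniform(-20, 150, size=n_anchors), 4)
    anchors = AnchorSet(dict(zip(seqs, (float(v) for v in irts))))
    runs = []
    for _ in range(n_runs):
        noise = rng.normal(0, spec.rt_noise_sd, size=n_anchors) if spec.rt_noise_sd > 0 else 0.0
        observed = (irts - spec.rt_true_intercept) / spec.rt_true_slope + noise
        runs.append({s: float(rt) for s, rt in zip(seqs, np.atleast_1d(observed))})
    return anchors, runs


def generate_cohort(spec: SynthSpec):
    """Labeled quantity matrix with planted differential proteins.

    Abundances are log-normal: each protein gets a baseline log2 mean in
    [14, 24]; samples add Gaussian noise (``cohort_noise_sd`` on the
    log2 scale). A ``de_fraction`` of proteins receives a
    ``log2fc_effect`` shift (random sign) in the second class.
    Missingness is applied after effects: completely-at-random cells at
    ``mcar_rate`` plus, optionally, censoring of the lowest
    ``mnar_rate`` quantile. Returns the QuantMatrix and a truth table
    (protein, is_de, true_log2fc).
    """
    from .cohort import QuantMatrix

    rng = substream(spec.seed, "cohort")
    n1, n2 = spec.cohort_n_per_class
    n_prot = spec.cohort_n_proteins
    proteins = [f"P{i + 1:05d}" for i in range(n_prot)]
    baseline = rng.uniform(14, 24, size=n_prot)
    n_de = int(round(spec.de_fraction * n_prot))
    de_idx = rng.choice(n_prot, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(n_prot)
    effects[de_idx] = signs * spec.log2fc_effect
    log2 = np.empty((n1 + n2, n_prot))
    log2[:n1] = baseline + rng.normal(0, spec.cohort_noise_sd, size=(n1, n_prot))
    log2[n1:] = (
        baseline + effects + rng.normal(0, spec.cohort_noise_sd, size=(n2, n_prot))
    )
    values = np.power(2.0, log2)
    if spec.mnar_rate > 0:
        cutoff = np.quantile(values, spec.mnar_rate)
        values[values < cutoff] = np.nan
    if spec.mcar_rate > 0:
        mask = rng.random(values.shape) < spec.mcar_rate
        values[mask] = np.nan
    samples = [f"{spec.class_names[0]}_{i + 1:03d}" for i in range(n1)] + [
        f"{spec.class_names[1]}_{i + 1:03d}" for i in range(n2)
    ]
    labels = pd.Series(
        [spec.class_names[0]] * n1 + [spec.class_names[1]] * n2,
        index=samples,
        name="label",
    )
    data = pd.DataFrame(values, index=samples, columns=proteins)
    truth = pd.DataFrame(
        {"is_de": effects != 0, "true_log2fc": effects}, index=proteins
    )
    return QuantMatrix(data=data, labels=labels), truth
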