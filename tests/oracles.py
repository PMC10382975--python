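"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the library's own code paths: the QC oracle
works on the flat row table with pandas group-bys, the digestion oracle
enumerates every substring, and the intersection oracle tallies
per-element membership patterns one by one.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd


def naive_qc(frame: pd.DataFrame, t, scope: str = "precursor") -> pd.DataFrame:
    """Row-wise re-implementation of the three-stage QC cascade.

    ``frame`` is the flat transition table (openswath columns); returns
    the surviving rows.
    """
    df = frame.copy()
    key = ["ModifiedPeptideSequence", "PrecursorCharge"]

    # stage 1: fragment count and RT window
    sizes = df.groupby(key)["ProductMz"].transform("size")
    ok_count = sizes >= t.min_fragments
    ok_rt = (df["NormalizedRetentionTime"] >= t.rt_min) & (
        df["NormalizedRetentionTime"] <= t.rt_max
    )
    df = df[ok_count & ok_rt]

    # stage 2: intensity, charge, then re-check fragment count
    df = df[~df["PrecursorCharge"].isin(list(t.excluded_precursor_charges))]
    df = df[df["LibraryIntensity"] >= t.min_fragment_intensity]
    sizes = df.groupby(key)["ProductMz"].transform("size")
    df = df[sizes >= t.min_fragments]

    # stage 3: RT consistency per peptide
    keep_keys = []
    for pep, grp in df.groupby("ModifiedPeptideSequence"):
        prec = grp.drop_duplicates(subset=key)[
            ["PrecursorCharge", "NormalizedRetentionTime"]
        ]
        if len(prec) == 1:
            keep_keys.extend((pep, c) for c in prec["PrecursorCharge"])
            continue
        rts = prec["NormalizedRetentionTime"].to_numpy(dtype=float)
        dev = np.abs(rts - rts.mean())
        kept = prec["PrecursorCharge"][dev <= t.max_rt_deviation].tolist()
        if not kept:
            dev = np.abs(rts - np.median(rts))
            kept = prec["PrecursorCharge"][dev < t.max_rt_deviation].tolist()
        if scope == "peptide" and len(kept) < len(prec):
            kept = []
        keep_keys.extend((pep, c) for c in kept)
    keyset = set(keep_keys)
    mask = [
        (row.ModifiedPeptideSequence, row.PrecursorCharge) in keyset
        for row in df.itertuples()
    ]
    return df[mask]


def brute_force_digest(seq: str, params) -> set[str]:
    """Enumerate every substring and keep those satisfying the
    terminus / missed-cleavage / length predicates for the mode."""
    seq = seq.upper()
    n = len(seq)
    sites = set(
        i
        for i in range(1, n)
        if seq[i - 1] in params.cleave_after
        and not (params.suppress_before_proline and seq[i] == "P")
    )
    out = set()
    for a in range(n):
        for b in range(a + params.min_length, min(a + params.max_length, n) + 1):
            pep = seq[a:b]
            if "X" in pep:
                continue
            internal = sum(1 for s in sites if a < s < b)
            if internal > params.max_missed_cleavages:
                continue
            n_ok = a == 0 or a in sites
            c_ok = b == n or b in sites
            if params.mode == "full":
                if n_ok and c_ok:
                    out.add(pep)
            else:
                if n_ok or c_ok:
                    out.add(pep)
    return out


def brute_force_classify(pep: str, sequences: dict[str, str], params) -> str:
    """Best tryptic class of a peptide over every occurrence."""
    rank = ["not_found", "non_tryptic", "semi_tryptic_N", "semi_tryptic_C", "full_tryptic"]
    best = "not_found"
    for seq in sequences.values():
        n = len(seq)
        for a in range(n - len(pep) + 1):
            if seq[a : a + len(pep)] != pep:
                continue
            b = a + len(pep)
            n_ok = a == 0 or (
                seq[a - 1] in params.cleave_after
                and not (params.suppress_before_proline and seq[a] == "P")
            )
            c_ok = b == n or (
                seq[b - 1] in params.cleave_after
                and not (params.suppress_before_proline and seq[b] == "P")
            )
            if n_ok and c_ok:
                cls = "full_tryptic"
            elif c_ok:
                cls = "semi_tryptic_C"
            elif n_ok:
                cls = "semi_tryptic_N"
            else:
                cls = "non_tryptic"
            if rank.index(cls) > rank.index(best):
                best = cls
    return best


def brute_force_intersections(named_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Per-element membership tally over all non-empty name subsets."""
    names = list(named_sets)
    counts = {
        tuple(sorted(c)): 0
        for r in range(1, len(names) + 1)
        for c in combinations(names, r)
    }
    for element in set().union(*named_sets.values()):
        pattern = tuple(sorted(n for n in names if element in named_sets[n]))
        counts[pattern] += 1
    return counts


def pearson_textbook(x, y) -> float:
    """Closed-form Pearson correlation from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))
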