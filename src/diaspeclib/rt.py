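"""Anchor-based retention-time normalization onto the iRT scale.

Chromatographic retention times drift between runs, so libraries store a
*normalized* RT on a dimensionless reference (iRT) scale instead. The
mapping for a run is estimated from anchor peptides — conserved,
high-abundance endogenous peptides (CiRT) with known reference iRT
values — by ordinary least squares from observed run RT (minutes) to
iRT, optionally discarding a fraction of the worst-fitting anchors in a
single trimming pass. Fit quality is summarised by the Pearson
correlation between observed RT and reference iRT over the anchors used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, FormatError, InsufficientAnchorsError
from .speclib_io import SpectralLibrary

MIN_ANCHORS = 3


@dataclass(frozen=True)
class AnchorSet:
    """Anchor peptides mapped to their reference iRT values."""

    entries: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnchorSet":
        """Read a two-column anchor table (ModifiedPeptideSequence, iRT)."""
        df = pd.read_csv(path, sep="\t")
        required = {"ModifiedPeptideSequence", "iRT"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(sorted(missing))}"
            )
        if df["ModifiedPeptideSequence"].duplicated().any():
            raise FormatError(f"{path}: duplicate anchor sequences")
        return cls(dict(zip(df["ModifiedPeptideSequence"], df["iRT"].astype(float))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"ModifiedPeptideSequence": list(self.entries), "iRT": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass(frozen=True)
class RTFit:
    """An affine run-RT → iRT calibration with its diagnostics."""

    slope: float
    intercept: float
    pearson_r: float
    n_anchors_used: int
    residual_sd: float

    def transform(self, rt: float) -> float:
        return self.slope * rt + self.intercept

    def inverse(self) -> "RTFit":
        if self.slope == 0:
            raise DegenerateFitError("cannot invert a zero-slope fit")
        return RTFit(
            slope=1.0 / self.slope,
            intercept=-self.intercept / self.slope,
            pearson_r=self.pearson_r,
            n_anchors_used=self.n_anchors_used,
            residual_sd=self.residual_sd / abs(self.slope),
        )


def fit_rt_anchor(
    observed: Mapping[str, float],
    anchors: AnchorSet,
    trim_fraction: float = 0.0,
) -> RTFit:
    """Fit the run-RT → iRT line over anchors shared with ``observed``.

    With ``trim_fraction > 0`` an initial fit is made on all shared
    anchors, the ``floor(trim_fraction * n)`` points with the largest
    absolute residual are discarded (never going below three points),
    and the line is refit once. ``pearson_r`` and ``residual_sd`` are
    computed on the points used in the final fit.
    """
    if not 0.0 <= trim_fraction <= 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5]")
    shared = sorted(set(observed) & set(anchors.entries))
    if len(shared) < MIN_ANCHORS:
        raise InsufficientAnchorsError(
            f"need >= {MIN_ANCHORS} shared anchors, found {len(shared)}"
        )
    x = np.array([observed[s] for s in shared], dtype=float)
    y = np.array([anchors.entries[s] for s in shared], dtype=float)

    def _ols(xv: np.ndarray, yv: np.ndarray) -> tuple[float, float]:
        res = stats.linregress(xv, yv)
        return float(res.slope), float(res.intercept)

    slope, intercept = _ols(x, y)
    n_trim = int(np.floor(trim_fraction * len(x)))
    if n_trim > 0 and len(x) - n_trim >= MIN_ANCHORS:
        resid = np.abs(y - (slope * x + intercept))
        keep = np.argsort(resid, kind="stable")[: len(x) - n_trim]
        x, y = x[np.sort(keep)], y[np.sort(keep)]
        slope, intercept = _ols(x, y)

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 0.0  # degenerate: correlation undefined, report 0
    else:
        r = float(stats.pearsonr(x, y).statistic)
    resid = y - (slope * x + intercept)
    dof = max(len(x) - 2, 1)
    return RTFit(
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        n_anchors_used=len(x),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def apply_rt_fit(target, fit: RTFit):
    """Apply an affine RT calibration.

    ``target`` may be a :class:`SpectralLibrary` (returns a new library
    with transformed ``normalized_rt``), a mapping sequence → RT, or a
    sequence of RT values. Ordering of RTs is preserved for positive
    slope.
    """
    if fit.slope == 0:
        raise DegenerateFitError("zero-slope fit cannot be applied")
    if isinstance(target, SpectralLibrary):
        from dataclasses import replace

        precs = [
            replace(p, normalized_rt=fit.transform(p.normalized_rt))
            for p in target.precursors
        ]
        return target.replace(precs, note=f"rt-fit:slope={fit.slope:g}")
    if isinstance(target, Mapping):
        return {k: fit.transform(v) for k, v in target.items()}
    arr = np.asarray(target, dtype=float)
    return fit.slope * arr + fit.intercept


def evaluate_runs(
    per_run_observed: Sequence[Mapping[str, float]],
    anchors: AnchorSet,
    trim_fraction: float = 0.0,
    run_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fit every run against the anchor set and tabulate fit quality.

    Returns one row per run with slope/intercept/pearson_r columns plus
    a trailing ``mean`` summary row (mean and SD of pearson_r over the
    runs that could be fitted). Runs failing the anchor precondition are
    reported with ``status='skipped'`` rather than aborting the table.
    """
    ids = list(run_ids) if run_ids is not None else [f"run{i}" for i in range(len(per_run_observed))]
    rows = []
    for run_id, obs in zip(ids, per_run_observed):
        try:
            fit = fit_rt_anchor(obs, anchors, trim_fraction)
        except InsufficientAnchorsError as exc:
            rows.append({"run": run_id, "status": "skipped", "detail": str(exc)})
            continue
        rows.append(
            {
                "run": run_id,
                "status": "ok",
                "slope": fit.slope,
                "intercept": fit.intercept,
                "pearson_r": fit.pearson_r,
                "n_anchors_used": fit.n_anchors_used,
                "residual_sd": fit.residual_sd,
            }
        )
    table = pd.DataFrame(rows)
    fitted = table[table["status"] == "ok"] if not table.empty else table
    summary = {
        "run": "mean",
        "status": "summary",
        "pearson_r": float(fitted["pearson_r"].mean()) if len(fitted) else float("nan"),
        "pearson_r_sd": float(fitted["pearson_r"].std(ddof=1)) if len(fitted) > 1 else float("nan"),
    }
    summary_row = pd.DataFrame([summary])
    return pd.concat([table, summary_row], ignore_index=True)
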