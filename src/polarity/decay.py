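"""mRNA half-life estimation from rifampicin run-off time-courses.

After transcription initiation is blocked with rifampicin, the remaining
amount of a transcript decays (approximately) exponentially.  Amounts
are measured by qRT-PCR against an exogenous spike-in reference using
efficiency-corrected (Pfaffl) relative quantification, the t=0 amount is
set to 100%, and the half-life comes from an ordinary least-squares fit
of ln(amount) against time.  A series whose slope is not significantly
negative is flagged "no decay" rather than given a half-life.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecaySeries",
    "HalfLifeEstimate",
    "ReplicateSummary",
    "StabilizationResult",
    "DEFAULT_TIMEPOINTS_S",
    "pfaffl_ratio",
    "relative_amount",
    "fit_halflife",
    "reconcile_replicates",
    "stabilization_fold",
    "read_cq_table",
    "halflife_table",
]

#: Sampling grid in seconds: before rifampicin, then 1/2/4/6/8 min after.
DEFAULT_TIMEPOINTS_S = (0, 60, 120, 240, 360, 480)


def _check_efficiency(eff: float, name: str) -> None:
    if not (1.0 < eff <= 2.0):
        raise ValueError(f"{name} must be in (1, 2], got {eff}")


@dataclass
class DecaySeries:
    """One gene/condition/replicate Cq time-course with its spike-in.

    ``eff_target``/``eff_spike`` are per-cycle amplification efficiencies
    in (1, 2] (2 = perfect doubling); they default to 2.0 with a warning
    when a table omits them.
    """

    gene_id: str
    condition: str
    replicate: int
    timepoints_s: np.ndarray
    cq_target: np.ndarray
    cq_spike: np.ndarray
    eff_target: float = 2.0
    eff_spike: float = 2.0

    def __post_init__(self) -> None:
        self.timepoints_s = np.asarray(self.timepoints_s, dtype=float)
        self.cq_target = np.asarray(self.cq_target, dtype=float)
        self.cq_spike = np.asarray(self.cq_spike, dtype=float)
        if not (
            len(self.timepoints_s) == len(self.cq_target) == len(self.cq_spike)
        ):
            raise ValueError("timepoints, cq_target and cq_spike must align")
        if self.timepoints_s[0] != 0:
            raise ValueError("t = 0 timepoint is required (it anchors 100%)")
        if np.any(np.diff(self.timepoints_s) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        _check_efficiency(self.eff_target, "eff_target")
        _check_efficiency(self.eff_spike, "eff_spike")


@dataclass
class HalfLifeEstimate:
    gene_id: str
    condition: str
    t_half_s: float
    se_s: float
    r_squared: float
    slope_per_s: float
    no_decay: bool
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not self.no_decay and not self.t_half_s > 0:
            raise ValueError("t_half_s must be positive unless no_decay")


@dataclass
class ReplicateSummary:
    """Across-replicate reconciliation in the style of a half-life table.

    When every replicate shows decay and their spread is modest
    (CV <= threshold) the mean +/- sd is reported; otherwise the raw
    replicate values are listed verbatim (no-decay entries as "n.dc.")
    and ``needs_second_primer`` flags the gene for re-measurement with an
    independent primer pair.
    """

    gene_id: str
    condition: str
    mean_s: float | None
    sd_s: float | None
    replicate_values: list[float | None]
    needs_second_primer: bool

    def format(self) -> str:
        if not self.needs_second_primer and self.mean_s is not None:
            if self.sd_s is None:
                return f"{self.mean_s:.0f}"
            return f"{self.mean_s:.0f} ± {self.sd_s:.0f}"
        return ", ".join(
            "n.dc." if v is None else f"{v:.0f}" for v in self.replicate_values
        )


@dataclass
class StabilizationResult:
    gene_id: str
    fold_change: float | None
    undefined: bool = False


def pfaffl_ratio(
    eff_target: float, dcq_target: float, eff_ref: float, dcq_ref: float
) -> float:
    """Efficiency-corrected relative quantification.

    ratio = E_target^dCq_target / E_ref^dCq_ref, with dCq = Cq(control)
    - Cq(treated).  Efficiencies must exceed 1 (no amplification) and are
    at most 2 (perfect doubling).
    """
    _check_efficiency(eff_target, "eff_target")
    _check_efficiency(eff_ref, "eff_ref")
    return eff_target**dcq_target / eff_ref**dcq_ref


def relative_amount(series: DecaySeries) -> np.ndarray:
    """Spike-in-normalized transcript amount per timepoint, t0 = 100%.

    A(t) = E_target^(Cq_target(0) - Cq_target(t))
         / E_spike^(Cq_spike(0) - Cq_spike(t)) * 100.
    A drifting spike-in Cq (loss during extraction) is corrected away by
    the denominator.
    """
    dcq_t = series.cq_target[0] - series.cq_target
    dcq_s = series.cq_spike[0] - series.cq_spike
    return (
        series.eff_target**dcq_t / series.eff_spike**dcq_s * 100.0
    )


def fit_halflife(series: DecaySeries, p_threshold: float = 0.05) -> HalfLifeEstimate:
    """Half-life from an OLS fit of ln(amount) vs time.

    All timepoints including t=0 enter the fit with a free intercept
    (A(0)=100 is a fitted point, not a constraint).  Non-positive
    amounts are dropped with a warning; at least 3 usable points are
    required.  The series is flagged no-decay when the slope is >= 0 or
    not significantly negative (one-sided p > ``p_threshold``); the
    half-life is ln(2)/(-slope) with its SE propagated from the slope SE.
    """
    amounts = relative_amount(series)
    t = series.timepoints_s
    keep = amounts > 0
    if not keep.all():
        warnings.warn(
            f"{series.gene_id}: dropped {int((~keep).sum())} non-positive amounts"
        )
    t, amounts = t[keep], amounts[keep]
    if len(t) < 3:
        raise ValueError(f"{series.gene_id}: fewer than 3 usable timepoints")
    fit = stats.linregress(t, np.log(amounts))
    slope = fit.slope
    # one-sided test of slope < 0
    p_one_sided = fit.pvalue / 2 if slope < 0 else 1 - fit.pvalue / 2
    no_decay = slope >= 0 or p_one_sided > p_threshold
    if no_decay:
        t_half = math.inf
        se_t = math.nan
    else:
        t_half = math.log(2) / (-slope)
        se_t = math.log(2) * fit.stderr / slope**2
    return HalfLifeEstimate(
        gene_id=series.gene_id,
        condition=series.condition,
        t_half_s=t_half,
        se_s=se_t,
        r_squared=fit.rvalue**2,
        slope_per_s=slope,
        no_decay=no_decay,
        replicate=series.replicate,
    )


def reconcile_replicates(
    estimates: Sequence[HalfLifeEstimate], cv_threshold: float = 0.5
) -> ReplicateSummary:
    """Summarize replicate half-lives, flagging inconsistent sets.

    Mean +/- sd is reported when all replicates decayed and the
    coefficient of variation is <= ``cv_threshold``; otherwise the raw
    replicate list is kept verbatim and the needs-second-primer flag is
    set (the convention for 'very different' replicate outcomes).
    """
    if not estimates:
        raise ValueError("no replicate estimates")
    gene_id = estimates[0].gene_id
    condition = estimates[0].condition
    values = [None if e.no_decay else e.t_half_s for e in estimates]
    decayed = [v for v in values if v is not None]
    any_no_decay = len(decayed) < len(values)
    if not any_no_decay:
        mean = float(np.mean(decayed))
        sd = float(np.std(decayed, ddof=1)) if len(decayed) > 1 else None
        cv = (sd / mean) if (sd is not None and mean > 0) else 0.0
        if cv <= cv_threshold:
            return ReplicateSummary(gene_id, condition, mean, sd, values, False)
    return ReplicateSummary(gene_id, condition, None, None, values, True)


def stabilization_fold(
    est_minus: HalfLifeEstimate | float,
    est_plus: HalfLifeEstimate | float,
    gene_id: str | None = None,
) -> StabilizationResult:
    """Fold change of half-life upon treatment: t1/2(+) / t1/2(-).

    Undefined (and flagged) when either side shows no decay.
    """

    def unpack(e):
        if isinstance(e, HalfLifeEstimate):
            return (None if e.no_decay else e.t_half_s), e.gene_id
        return float(e), None

    minus, gid_m = unpack(est_minus)
    plus, gid_p = unpack(est_plus)
    gid = gene_id or gid_m or gid_p or ""
    if minus is None or plus is None or not math.isfinite(minus) or not math.isfinite(plus):
        return StabilizationResult(gid, None, undefined=True)
    return StabilizationResult(gid, plus / minus)


# ---------------------------------------------------------------------------
# Tables


def read_cq_table(path) -> list[DecaySeries]:
    """Read a long-format Cq CSV into DecaySeries.

    Columns: gene_id, condition, replicate, time_s, cq_target, cq_spike,
    and optionally eff_target/eff_spike (default 2.0 with a warning).
    """
    df = pd.read_csv(path)
    required = {"gene_id", "condition", "replicate", "time_s", "cq_target", "cq_spike"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "eff_target" not in df.columns or "eff_spike" not in df.columns:
        warnings.warn(f"{path}: primer efficiencies absent; defaulting to 2.0")
    series = []
    for (gene, cond, rep), grp in df.groupby(
        ["gene_id", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_s")
        series.append(
            DecaySeries(
                gene_id=str(gene),
                condition=str(cond),
                replicate=int(rep),
                timepoints_s=grp["time_s"].values,
                cq_target=grp["cq_target"].values,
                cq_spike=grp["cq_spike"].values,
                eff_target=float(grp["eff_target"].iloc[0])
                if "eff_target" in grp
                else 2.0,
                eff_spike=float(grp["eff_spike"].iloc[0])
                if "eff_spike" in grp
                else 2.0,
            )
        )
    return series


def halflife_table(summaries: Sequence[ReplicateSummary]) -> pd.DataFrame:
    """Replicate summaries as a half-life table (one row per gene/condition)."""
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "condition": s.condition,
                "half_life": s.format(),
                "needs_second_primer": s.needs_second_primer,
            }
            for s in summaries
        ]
    )
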