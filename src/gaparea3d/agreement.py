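"""Observer-agreement and summary statistics for fracture measurements.

Reliability of a cases x observers measurement table is quantified with
the intraclass correlation coefficient ICC(2,1): two-way random effects,
absolute agreement, single rater. From the two-way ANOVA decomposition
(rows = cases with mean square MS_R, columns = observers MS_C, residual
MS_E, n cases, k observers):

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with the F-based 95% confidence interval for this form. Absolute agreement
is the right model when raters are interchangeable: a constant bias of one
observer lowers the coefficient. Qualitative bands follow the conventional
cut-points: poor < 0.40, fair 0.40-0.59, good 0.60-0.74, excellent >= 0.75.

Descriptives use median / interquartile range (linear interpolation between
order statistics -- the common statistics-package default, recorded in the
result because printed IQR endpoints depend on it).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("gaparea3d")

ICC_MODEL = "two-way random, absolute agreement, single rater (ICC(2,1))"

#: Qualitative ICC bands: label applies from the given lower bound upward.
ICC_BANDS = (("poor", -np.inf), ("fair", 0.40), ("good", 0.60),
             ("excellent", 0.75))


@dataclass
class ObserverTable:
    """Measurements with rows = cases and columns = observers.

    ``kind`` names the measured quantity (``gap_mm``, ``stepoff_mm`` or
    ``gap_area_mm2``). Rows with missing cells are dropped (complete-case
    analysis); at least a 2 x 2 complete table must remain.
    """

    data: pd.DataFrame
    kind: str = "gap_area_mm2"
    generative_icc: float | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).astype(float)
        complete = df.dropna(axis=0, how="any")
        if len(complete) < len(df):
            logger.info("dropped %d incomplete case(s)", len(df) - len(complete))
        self.data = complete
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError("observer table needs >= 2 complete cases "
                             "and >= 2 observers")
        if (self.data.values < 0).any():
            warnings.warn("observer table contains negative measurements",
                          stacklevel=2)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_cases(self) -> int:
        return self.data.shape[0]

    @property
    def n_observers(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "gap_area_mm2"
                 ) -> "ObserverTable":
        """Load ``case_id, observer_1..observer_k`` shaped CSV."""
        df = pd.read_csv(path)
        case_col = df.columns[0]
        df = df.set_index(case_col)
        return cls(data=df, kind=kind)


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    band: str
    model: str = ICC_MODEL
    n_cases: int = 0
    n_observers: int = 0
    anova: dict = field(default_factory=dict)


@dataclass
class OutcomeRecord:
    """One patient's questionnaire scores and displacement group."""

    case_id: str
    dash: float
    prwe: float
    displacement_group: str  # "below" | "above"

    def __post_init__(self) -> None:
        for name, v in (("dash", self.dash), ("prwe", self.prwe)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} score {v} outside 0-100")
        if self.displacement_group not in ("below", "above"):
            raise ValueError("displacement_group must be 'below' or 'above'")


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _two_way_anova(x: np.ndarray) -> dict:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return {
        "ms_rows": ss_rows / (n - 1),
        "ms_cols": ss_cols / (k - 1),
        "ms_err": max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        "n": n, "k": k,
    }


def icc_single_rater(table: ObserverTable, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its F-based 95% confidence interval.

    Raises on a degenerate table (zero total variance), where the
    coefficient is undefined.
    """
    x = table.matrix
    if np.allclose(x, x.flat[0]):
        raise ValueError("degenerate table: zero total variance")
    a = _two_way_anova(x)
    n, k = a["n"], a["k"]
    msr, msc, mse = a["ms_rows"], a["ms_cols"], a["ms_err"]
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    est = (msr - mse) / denom
    est = float(np.clip(est, -1.0, 1.0))

    if 1.0 - est < 1e-12:
        lo = hi = 1.0
    else:
        fa = (k * est) / (n * (1.0 - est))
        fb = 1.0 + (k * est * (n - 1.0)) / (n * (1.0 - est))
        v_num = (fa * msc + fb * mse) ** 2
        v_den = ((fa * msc) ** 2 / (k - 1.0)
                 + (fb * mse) ** 2 / ((n - 1.0) * (k - 1.0)))
        v = v_num / v_den if v_den > 0 else 1.0
        f_u = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lo = (n * (msr - f_u * mse)
              / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_l * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_l * msr))
        lo = float(np.clip(lo, -1.0, 1.0))
        hi = float(np.clip(hi, -1.0, 1.0))
        lo = min(lo, est)
        hi = max(hi, est)
    return ICCResult(estimate=est, ci_low=lo, ci_high=hi, band=band(est),
                     n_cases=n, n_observers=k, anova=a)


def band(estimate: float) -> str:
    """Qualitative agreement label for an ICC estimate."""
    if not np.isfinite(estimate):
        raise ValueError("ICC estimate must be finite")
    label = ICC_BANDS[0][0]
    for name, lower in ICC_BANDS:
        if estimate >= lower:
            label = name
    return label


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("median of empty sequence")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def observer_median_difference(table: ObserverTable, mode: str = "pooled"
                               ) -> tuple[float, float, float]:
    """Median (and IQR) absolute difference between observers.

    ``pooled``: all per-case pairwise absolute differences between
    observers are pooled and summarized together. ``per_case``: each case
    is first reduced to the median of its pairwise differences. For two
    columns (a repeat-measurement design) both modes equal the per-case
    |first - second| summary.
    """
    x = table.matrix
    n, k = x.shape
    per_case = [
        [abs(x[i, a] - x[i, b]) for a in range(k) for b in range(a + 1, k)]
        for i in range(n)
    ]
    if mode == "pooled":
        pooled = [d for row in per_case for d in row]
        return median_iqr(pooled)
    if mode == "per_case":
        return median_iqr([float(np.median(row)) for row in per_case])
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# outcome summaries
# ---------------------------------------------------------------------------

def load_outcomes_csv(path: str | Path, groups: dict[str, str] | None = None
                      ) -> list[OutcomeRecord]:
    """Load ``case_id, dash, prwe[, displacement_group]`` CSV rows.

    ``groups`` maps case_id to 'below'/'above' when the file itself does
    not carry the grouping (it then comes from the reference observer's 2D
    measurements).
    """
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        cid = str(row.iloc[0])
        grp = (str(row["displacement_group"]) if "displacement_group" in df.columns
               else (groups or {}).get(cid))
        if grp is None:
            raise ValueError(f"no displacement group for case {cid}")
        records.append(OutcomeRecord(case_id=cid, dash=float(row["dash"]),
                                     prwe=float(row["prwe"]),
                                     displacement_group=grp))
    return records


def group_records(dash_prwe: dict[str, tuple[float, float]],
                  reference_cases: dict[str, bool]) -> list[OutcomeRecord]:
    """Build outcome records from scores plus the reference observer's
    above-cut-off flags (True = above)."""
    return [OutcomeRecord(case_id=cid, dash=d, prwe=p,
                          displacement_group="above" if reference_cases[cid]
                          else "below")
            for cid, (d, p) in dash_prwe.items()]


def outcome_group_summary(records: list[OutcomeRecord]) -> dict:
    """Counts and DASH/PRWE median (IQR) per displacement group.

    Empty groups are reported with count 0 and no medians.
    """
    out = {}
    for grp in ("below", "above"):
        sub = [r for r in records if r.displacement_group == grp]
        entry: dict = {"count": len(sub)}
        if sub:
            for score in ("dash", "prwe"):
                med, q1, q3 = median_iqr([getattr(r, score) for r in sub])
                entry[score] = {"median": med, "q1": q1, "q3": q3}
        out[grp] = entry
    return out
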