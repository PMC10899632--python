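"""Kinetic statistics computed from seven-bin fraction tables.

Implements the study's quantification conventions exactly as stated:

* mean transcript length at a timepoint = sum over bins of (fraction x bin
  midpoint), the midpoint being each bin's "theoretical RNA length";
* average elongation rate = mean over timepoints of
  (mean length - stall) / t, in nt/s.  This estimator is deliberately the
  published formula: it is biased low once transcripts saturate at the
  template end (the length increase plateaus while t keeps growing), and we
  document rather than correct that;
* pause kinetics at the stall from the two-point exponential
  C2 = C1 * exp(-k (t2 - t1)), giving k and t_1/2 = ln 2 / k;
* relative rates (to the histone-free condition) and relative half-lives
  (to WT without TFS, whose entry is 1.00 by construction);
* replicate summaries as mean +/- standard error (sd / sqrt(n)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinScheme, default_bin_scheme

__all__ = [
    "PauseKinetics",
    "mean_transcript_length",
    "average_elongation_rate",
    "relative_rate",
    "pause_half_life",
    "relative_half_life",
    "full_length_fraction",
    "summarize_replicates",
    "replicate_rates",
    "condition_results",
]

BIN_COLS = [f"bin{b}" for b in range(1, 8)]


@dataclass(frozen=True)
class PauseKinetics:
    """Two-point exponential escape kinetics of the stalled species.

    C1, C2 are the bin-1 fractions at t1 and t2.  When C2 >= C1 (no decay
    within the window) the half-life is undefined and flagged, never
    reported as a negative number.
    """

    C1: float
    C2: float
    t1: float
    t2: float
    k: float
    t_half: float  # nan when undefined

    @property
    def defined(self) -> bool:
        return math.isfinite(self.t_half)


def mean_transcript_length(
    fractions: np.ndarray, scheme: BinScheme | None = None
) -> float:
    """Midpoint-weighted mean RNA length (nt) for one lane's bin fractions."""
    scheme = scheme or default_bin_scheme()
    f = np.asarray(fractions, dtype=float)
    if f.shape != (7,):
        raise ValueError("expected seven bin fractions")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"bin fractions sum to {f.sum():.8f}, not 1")
    return float(np.dot(f, scheme.midpoints))


def average_elongation_rate(
    replicate_rows: pd.DataFrame,
    scheme: BinScheme | None = None,
    stall_pos: float = 58.0,
) -> float:
    """Average elongation rate (nt/s) for one replicate's time course.

    The unweighted mean over observation times of
    (mean transcript length at t - stall) / t.
    """
    scheme = scheme or default_bin_scheme()
    if len(replicate_rows) == 0:
        raise ValueError("no timepoints")
    times = replicate_rows["time_s"].to_numpy(dtype=float)
    if np.any(times <= 0):
        raise ValueError("timepoints must be positive")
    per_t = []
    for _, row in replicate_rows.sort_values("time_s").iterrows():
        f = row[BIN_COLS].to_numpy(dtype=float)
        lbar = mean_transcript_length(f, scheme)
        per_t.append((lbar - stall_pos) / row["time_s"])
    return float(np.mean(per_t))


def relative_rate(r_condition: float, r_free: float) -> float:
    """Rate relative to the histone-free template."""
    if r_free <= 0:
        raise ValueError("reference rate must be positive")
    return r_condition / r_free


def pause_half_life(
    C1: float, C2: float, t1: float = 15.0, t2: float = 240.0
) -> PauseKinetics:
    """Two-point estimate of the stalled-complex escape kinetics.

    Inverts C2 = C1 e^{-k (t2-t1)} for k, then t_1/2 = ln2 / k.  Exact
    (machine precision) when fed fractions that truly decay exponentially.
    """
    if C1 <= 0 or C2 <= 0:
        raise ValueError("C1 and C2 must be positive fractions")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    k = math.log(C1 / C2) / (t2 - t1)
    t_half = math.log(2) / k if k > 0 else math.nan
    return PauseKinetics(C1=C1, C2=C2, t1=t1, t2=t2, k=k, t_half=t_half)


def relative_half_life(
    kinetics: dict[tuple[str, bool], PauseKinetics],
    reference: tuple[str, bool] = ("WT", False),
) -> pd.DataFrame:
    """Half-life of each (condition, tfs) relative to the reference.

    The reference entry is exactly 1.0 by construction; undefined
    half-lives propagate as NaN and are flagged.
    """
    if reference not in kinetics:
        raise KeyError(f"reference condition {reference} missing")
    ref = kinetics[reference]
    if not ref.defined:
        raise ValueError("reference half-life is undefined")
    rows = []
    for (cond, tfs), pk in kinetics.items():
        rel = 1.0 if (cond, tfs) == reference else (
            pk.t_half / ref.t_half if pk.defined else math.nan
        )
        rows.append(
            {
                "condition": cond,
                "tfs": int(tfs),
                "t_half_s": pk.t_half,
                "relative_t_half": rel,
                "defined": pk.defined,
            }
        )
    return pd.DataFrame(rows)


def full_length_fraction(row: pd.Series | np.ndarray) -> float:
    """Fraction of transcripts that reached the template end (bin 7)."""
    if isinstance(row, pd.Series):
        return float(row["bin7"])
    f = np.asarray(row, dtype=float)
    return float(f[6])


def replicate_rates(
    bin_table: pd.DataFrame,
    scheme: BinScheme | None = None,
    stall_pos: float = 58.0,
) -> pd.DataFrame:
    """Per-replicate average elongation rates for every condition."""
    scheme = scheme or default_bin_scheme()
    out = []
    for (cond, tfs, rep), grp in bin_table.groupby(
        ["condition", "tfs", "replicate"], sort=False
    ):
        out.append(
            {
                "condition": cond,
                "tfs": tfs,
                "replicate": rep,
                "rate_nt_s": average_elongation_rate(grp, scheme, stall_pos),
            }
        )
    return pd.DataFrame(out)


def summarize_replicates(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error across replicates.

    SE = sample sd / sqrt(n); undefined (NaN) with fewer than two
    replicates.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("no replicates")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) >= 2 else math.nan
    return mean, se


def condition_results(
    bin_table: pd.DataFrame,
    scheme: BinScheme | None = None,
    stall_pos: float = 58.0,
    free_condition: str = "HTkA-free",
    reference: tuple[str, bool] = ("WT", False),
    t1: float = 15.0,
    t2: float = 240.0,
    averaging: str = "per_replicate",
) -> pd.DataFrame:
    """Full per-condition kinetics summary from a binned fraction table.

    For each (condition, tfs): mean +/- SE of the per-replicate average
    rate, rate relative to the histone-free -TFS mean, mean full-length
    fraction at the last timepoint, and the pause half-life computed from
    replicate-mean bin-1 fractions at t1 and t2 (the tabulated convention),
    relative to the reference condition.

    ``averaging`` selects the replicate-handling convention for the rate:
    ``per_replicate`` (default) computes a rate per replicate and averages
    those (SE across replicates); ``mean_percentage`` averages the bin
    fractions across replicates first and computes one rate from the mean
    time course (SE undefined), matching figure-style presentation.
    """
    scheme = scheme or default_bin_scheme()
    if averaging not in ("per_replicate", "mean_percentage"):
        raise ValueError(
            "averaging must be 'per_replicate' or 'mean_percentage'"
        )
    if averaging == "mean_percentage":
        pooled = (
            bin_table.groupby(["condition", "tfs", "time_s"], sort=False)[
                BIN_COLS
            ]
            .mean()
            .reset_index()
        )
        pooled["replicate"] = 0
        # renormalize away floating drift in the replicate means
        total = pooled[BIN_COLS].sum(axis=1)
        pooled[BIN_COLS] = pooled[BIN_COLS].div(total, axis=0)
        rates = replicate_rates(pooled, scheme, stall_pos)
    else:
        rates = replicate_rates(bin_table, scheme, stall_pos)
    free = rates[(rates["condition"] == free_condition) & (rates["tfs"] == 0)]
    if len(free) == 0:
        raise ValueError(f"histone-free condition {free_condition!r} missing")
    r_free = float(free["rate_nt_s"].mean())

    kinetics: dict[tuple[str, bool], PauseKinetics] = {}
    rows = []
    for (cond, tfs), grp in bin_table.groupby(["condition", "tfs"], sort=False):
        rr = rates[(rates["condition"] == cond) & (rates["tfs"] == tfs)]
        mean_r, se_r = summarize_replicates(rr["rate_nt_s"].to_numpy())
        t_last = grp["time_s"].max()
        fl = grp[grp["time_s"] == t_last]["bin7"].to_numpy(dtype=float)
        c1 = grp[grp["time_s"] == t1]["bin1"].mean()
        c2 = grp[grp["time_s"] == t2]["bin1"].mean()
        pk = None
        if np.isfinite(c1) and np.isfinite(c2) and c1 > 0 and c2 > 0:
            pk = pause_half_life(float(c1), float(c2), t1, t2)
            kinetics[(cond, bool(tfs))] = pk
        rows.append(
            {
                "condition": cond,
                "tfs": tfs,
                "n_replicates": len(rr),
                "rate_nt_s": mean_r,
                "rate_se": se_r,
                "relative_rate": relative_rate(mean_r, r_free),
                "full_length_fraction": float(fl.mean()),
                "t_half_s": pk.t_half if pk is not None else math.nan,
            }
        )
    result = pd.DataFrame(rows)
    if reference in kinetics and kinetics[reference].defined:
        rel = relative_half_life(kinetics, reference)
        result = result.merge(
            rel[["condition", "tfs", "relative_t_half"]],
            on=["condition", "tfs"],
            how="left",
        )
    else:
        result["relative_t_half"] = math.nan
    return result
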