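"""Tumor growth response quantification for two-arm PDX efficacy studies.

The analysis chain mirrors standard preclinical oncology practice: caliper
diameters are converted to volumes (``V = a*b^2/2``), each mouse's trajectory
is expressed as relative tumor volume (RTV, volume divided by its day-0
volume), tumor growth inhibition (TGI) compares mean RTV between arms day by
day, and per-mouse relative tumor volume variation (RTVV = Vt/Vc - 1, with Vc
the control-group median end-of-treatment volume) drives waterfall plots and
responder calls.  A model is called responding when its optimal TGI exceeds
50% with a significant t-test on individual RTVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ihc

ARMS = ("control", "treated")

#: Default per-mouse responder threshold on RTVV.
RTVV_THRESHOLD = -0.5


class MeasurementOrderError(ValueError):
    """Raised when the two caliper diameters are given in the wrong order."""


@dataclass
class GrowthStudy:
    """Longitudinal caliper measurements for one or more two-arm studies.

    ``measurements`` columns: mouse, model, arm, day, a, b (mm).  ``metadata``
    optionally maps model id to tumor subtype.
    """

    measurements: pd.DataFrame
    metadata: Mapping[str, str] = field(default_factory=dict)

    REQUIRED = ("mouse", "model", "arm", "day", "a", "b")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.measurements)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"growth table missing columns: {missing}")
        if (df["a"] < df["b"]).any():
            bad = df.loc[df["a"] < df["b"], "mouse"].unique()
            raise MeasurementOrderError(
                f"largest diameter a must be >= smallest diameter b (mice: {list(bad)[:5]})"
            )
        if (df["b"] <= 0).any():
            raise ValueError("diameters must be positive")
        if (df["day"] < 0).any():
            raise ValueError("days must be >= 0")
        if df.duplicated(["mouse", "day"]).any():
            raise ValueError("duplicate (mouse, day) measurement")
        baseline = df.groupby("mouse")["day"].min()
        no_baseline = baseline[baseline != 0]
        if len(no_baseline):
            raise ValueError(f"mice without day-0 baseline: {list(no_baseline.index)[:5]}")
        df = df.sort_values(["model", "arm", "mouse", "day"]).reset_index(drop=True)
        df["volume"] = tumor_volume(df["a"].to_numpy(), df["b"].to_numpy())
        self.measurements = df

    @property
    def models(self) -> list[str]:
        return list(pd.unique(self.measurements["model"]))

    def model_frame(self, model_id: str) -> pd.DataFrame:
        out = self.measurements[self.measurements["model"] == model_id]
        if out.empty:
            raise KeyError(f"unknown model {model_id!r}")
        return out

    @classmethod
    def from_csv(cls, path, metadata: Mapping[str, str] | None = None) -> "GrowthStudy":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep), metadata or {})


@dataclass(frozen=True)
class ResponseSummary:
    """Per-model response readout of a two-arm study."""

    model_id: str
    optimal_tgi: float       # percent
    tgi_day: float
    p_value: float
    rtvv_per_mouse: Mapping[str, float]
    responder_fraction: float
    model_call: str          # "responding" | "non-responding"


def tumor_volume(a, b):
    """Ellipsoid-like caliper volume ``a*b^2/2`` (mm^3), requiring ``a >= b > 0``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("diameters must be positive")
    if np.any(a < b):
        raise MeasurementOrderError("largest diameter a must be >= smallest diameter b")
    out = a * b**2 / 2.0
    return float(out) if out.ndim == 0 else out


def relative_tumor_volume(volumes: pd.DataFrame) -> pd.DataFrame:
    """Add an ``rtv`` column: each volume divided by the mouse's day-0 volume.

    ``volumes`` needs columns mouse, day, volume; every mouse must have a
    positive day-0 measurement.
    """
    df = volumes.copy()
    base = df.loc[df["day"] == 0].set_index("mouse")["volume"]
    missing = set(df["mouse"]) - set(base.index)
    if missing:
        raise ValueError(f"missing day-0 baseline for mice: {sorted(missing)[:5]}")
    if (base <= 0).any():
        raise ValueError("day-0 volumes must be positive")
    df["rtv"] = df["volume"].to_numpy() / base.reindex(df["mouse"]).to_numpy()
    return df


def _rtv_frame(study: GrowthStudy, model_id: str) -> pd.DataFrame:
    return relative_tumor_volume(study.model_frame(model_id))


def tgi_curve(study: GrowthStudy, model_id: str, min_per_arm: int = 2):
    """Per-day TGI percentages and the optimal (maximum) TGI for one model.

    TGI% at a day is ``100 * (1 - mean RTV treated / mean RTV control)``,
    computed only on days where both arms still have at least ``min_per_arm``
    mice.  Returns ``(curve, optimal_tgi, optimal_day)``; ties on the maximum
    resolve to the earliest day.
    """
    df = _rtv_frame(study, model_id)
    mean_rtv = df.pivot_table(index="day", columns="arm", values="rtv", aggfunc="mean")
    counts = df.pivot_table(index="day", columns="arm", values="rtv", aggfunc="count")
    for arm in ARMS:
        if arm not in mean_rtv.columns:
            raise ValueError(f"model {model_id}: missing {arm} arm")
    ok = (counts[ARMS[0]].fillna(0) >= min_per_arm) & (counts[ARMS[1]].fillna(0) >= min_per_arm)
    curve = mean_rtv.loc[ok].rename(columns={"control": "mean_rtv_control", "treated": "mean_rtv_treated"})
    if curve.empty:
        raise ValueError(f"model {model_id}: no day with both arms measured")
    curve["tgi"] = 100.0 * (1.0 - curve["mean_rtv_treated"] / curve["mean_rtv_control"])
    post = curve.loc[curve.index > 0, "tgi"]
    if post.empty:
        post = curve["tgi"]
    optimal_day = post.idxmax()  # idxmax returns the first (earliest) maximum
    return curve.reset_index(), float(post.loc[optimal_day]), float(optimal_day)


def tgi_test(study: GrowthStudy, model_id: str, day: float, equal_var: bool = False) -> float:
    """Two-sample t-test p-value comparing individual RTVs between arms at ``day``.

    Welch's unequal-variance form by default (``equal_var=True`` for the
    classical pooled test).  Two degenerate arms with equal means give p = 1.
    """
    df = _rtv_frame(study, model_id)
    at_day = df[df["day"] == day]
    x = at_day.loc[at_day["arm"] == "treated", "rtv"].to_numpy()
    y = at_day.loc[at_day["arm"] == "control", "rtv"].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"model {model_id}: need >= 2 mice per arm at day {day}")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue)


def rtvv(treated_volume: float, control_median_volume: float) -> float:
    """Relative tumor volume variation ``Vt/Vc - 1`` of one treated mouse."""
    if control_median_volume <= 0:
        raise ValueError("control median volume must be positive")
    return float(treated_volume) / float(control_median_volume) - 1.0


def _volume_at_or_carry_forward(df: pd.DataFrame, day: float) -> pd.Series:
    """Per-mouse volume at ``day``; a mouse censored earlier (sacrificed at the
    volume endpoint) contributes its last observed volume."""
    upto = df[df["day"] <= day]
    last = upto.sort_values("day").groupby("mouse").tail(1)
    return last.set_index("mouse")["volume"]


def end_of_treatment_day(study: GrowthStudy, model_id: str) -> float:
    """Last scheduled day with measurements present in both arms."""
    df = study.model_frame(model_id)
    days = [
        d for d, sub in df.groupby("day")
        if set(sub["arm"].unique()) >= set(ARMS)
    ]
    if not days:
        raise ValueError(f"model {model_id}: no day with both arms measured")
    return float(max(days))


def rtvv_table(study: GrowthStudy, model_id: str, day: float | None = None) -> pd.Series:
    """Per-treated-mouse RTVV at the end-of-treatment day (or a given day)."""
    df = study.model_frame(model_id)
    if day is None:
        day = end_of_treatment_day(study, model_id)
    vols = _volume_at_or_carry_forward(df, day)
    control_mice = df.loc[df["arm"] == "control", "mouse"].unique()
    treated_mice = df.loc[df["arm"] == "treated", "mouse"].unique()
    vc = float(np.median(vols.reindex(control_mice).dropna()))
    vt = vols.reindex(treated_mice).dropna()
    return pd.Series({m: rtvv(v, vc) for m, v in vt.items()}, name="rtvv")


@dataclass(frozen=True)
class WaterfallResult:
    table: pd.DataFrame            # mouse, rtvv, label; sorted descending
    fraction_negative: float
    fraction_responding: float


def classify_responders(rtvv_values, threshold: float = RTVV_THRESHOLD) -> WaterfallResult:
    """Label mice as responder/non-responder and order them for a waterfall plot.

    A mouse responds when its RTVV is strictly below ``threshold`` (default
    -0.5, i.e. a treated volume under half the control median).
    """
    s = pd.Series(rtvv_values, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("RTVV values must be finite")
    table = s.rename("rtvv").rename_axis("mouse").reset_index()
    table["label"] = np.where(table["rtvv"] < threshold, "responder", "non-responder")
    table = table.sort_values("rtvv", ascending=False, kind="mergesort").reset_index(drop=True)
    n = len(table)
    return WaterfallResult(
        table=table,
        fraction_negative=float((table["rtvv"] < 0).sum()) / n,
        fraction_responding=float((table["label"] == "responder").sum()) / n,
    )


def model_call(optimal_tgi: float, p_value: float, tgi_cutoff: float = 50.0, alpha: float = 0.05) -> str:
    """Model-level call: responding iff optimal TGI > 50% and the test is significant."""
    return "responding" if (optimal_tgi > tgi_cutoff and p_value <= alpha) else "non-responding"


def summarize_model(
    study: GrowthStudy,
    model_id: str,
    rtvv_threshold: float = RTVV_THRESHOLD,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> ResponseSummary:
    """Full response readout for one model (TGI, significance, RTVV, call)."""
    _, opt_tgi, opt_day = tgi_curve(study, model_id)
    p = tgi_test(study, model_id, opt_day, equal_var=equal_var)
    per_mouse = rtvv_table(study, model_id)
    wf = classify_responders(per_mouse, threshold=rtvv_threshold)
    return ResponseSummary(
        model_id=model_id,
        optimal_tgi=opt_tgi,
        tgi_day=opt_day,
        p_value=p,
        rtvv_per_mouse=dict(per_mouse),
        responder_fraction=wf.fraction_responding,
        model_call=model_call(opt_tgi, p, alpha=alpha),
    )


def summarize_study(study: GrowthStudy, **kwargs) -> pd.DataFrame:
    """Per-model ResponseSummary table for every model in the study."""
    rows = []
    for model_id in study.models:
        s = summarize_model(study, model_id, **kwargs)
        rows.append(
            {
                "model": s.model_id,
                "optimal_tgi": s.optimal_tgi,
                "tgi_day": s.tgi_day,
                "p_value": s.p_value,
                "responder_fraction": s.responder_fraction,
                "model_call": s.model_call,
            }
        )
    return pd.DataFrame(rows)


def relapse_summary(relapse_times_by_arm: Mapping[str, Sequence[float]], followup_end: float) -> pd.DataFrame:
    """Relapse incidence, Kaplan-Meier median time-to-relapse and log-rank p.

    ``relapse_times_by_arm`` maps arm name to per-mouse relapse days; times
    beyond ``followup_end`` (or infinite) are censored at follow-up end.
    Returns a per-arm frame with the log-rank statistic/p in ``attrs``.
    """
    times, events, groups = [], [], []
    for arm, ts in relapse_times_by_arm.items():
        ts = np.asarray(list(ts), dtype=float)
        if np.any(ts <= 0):
            raise ValueError("relapse times must be positive")
        obs = np.minimum(ts, followup_end)
        ev = (ts <= followup_end).astype(int)
        times.append(obs)
        events.append(ev)
        groups.append(np.repeat(arm, len(ts)))
    km = ihc.km_logrank(np.concatenate(times), np.concatenate(events), np.concatenate(groups))
    rows = []
    for arm, ts in relapse_times_by_arm.items():
        ts = np.asarray(list(ts), dtype=float)
        rows.append(
            {
                "arm": arm,
                "n": len(ts),
                "n_relapsed": int((ts <= followup_end).sum()),
                "median_time_to_relapse": km.medians[arm],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["logrank_statistic"] = km.statistic
    out.attrs["logrank_p"] = km.p_value
    return out


def plot_growth_curves(study: GrowthStudy, model_id: str, path) -> None:
    """Mean RTV (+/- s.e.) per arm over time, exported to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = _rtv_frame(study, model_id)
    fig, ax = plt.subplots(figsize=(5, 4))
    for arm, marker in zip(ARMS, ("o", "s")):
        sub = df[df["arm"] == arm].groupby("day")["rtv"].agg(["mean", "sem"])
        ax.errorbar(sub.index, sub["mean"], yerr=sub["sem"], marker=marker, label=arm)
    ax.set_xlabel("days from first dose")
    ax.set_ylabel("mean RTV")
    ax.set_title(model_id)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_waterfall(rtvv_values, path, threshold: float = RTVV_THRESHOLD) -> None:
    """Waterfall of per-mouse RTVV, responders highlighted below threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wf = classify_responders(rtvv_values, threshold=threshold)
    colors = ["#c0392b" if l == "responder" else "#7f8c8d" for l in wf.table["label"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(wf.table)), wf.table["rtvv"], color=colors)
    ax.axhline(threshold, linestyle="--", color="black", linewidth=0.8)
    ax.set_ylabel("RTVV (Vt/Vc - 1)")
    ax.set_xlabel("treated mice (ordered)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
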