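"""Cross-variant aggregation: release-time table, activity correlation,
and the machine-readable run report.

Enzyme activities are experimental inputs supplied as a CSV table
(variant, activity, unit); the package never computes them.  The headline
statistic is the Pearson correlation between per-variant release times from
the segmentation stage and those activities — a slower simulated release
should go with a lower measured glycine-cleavage activity.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CompletenessError, JoinError, SampleSizeError

__all__ = ["CorrelationResult", "VariantSummary", "correlate",
           "read_activity_table", "run_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str = "pearson"

    def to_dict(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "n": self.n,
                "method": self.method}


@dataclass
class VariantSummary:
    variant: str
    release_time_ns: float | None
    step_durations_ns: dict
    activity: float | None = None
    activity_unit: str | None = None
    activity_relative_to_wt: float | None = None

    def to_dict(self) -> dict:
        return {"variant": self.variant,
                "release_time_ns": self.release_time_ns,
                "step_durations_ns": self.step_durations_ns,
                "activity": self.activity,
                "activity_unit": self.activity_unit,
                "activity_relative_to_wt": self.activity_relative_to_wt}


def correlate(release_times: Mapping[str, float],
              activities: Mapping[str, float],
              method: str = "pearson",
              strict: bool = True) -> CorrelationResult:
    """Correlation between per-variant release times and activities.

    Variants are matched by name.  With ``strict`` (default) any name present
    in only one table raises a join error listing the unmatched keys;
    otherwise the intersection is used.  Pearson's r comes with a two-sided
    p-value from the t transform ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees
    of freedom; ``method="spearman"`` is available for a rank-based check.
    """
    rt_keys, act_keys = set(release_times), set(activities)
    unmatched = sorted(rt_keys ^ act_keys)
    if strict and unmatched:
        raise JoinError(f"variants present in only one table: {unmatched}")
    common = sorted(rt_keys & act_keys)
    if len(common) < 3:
        raise SampleSizeError(
            f"correlation needs >= 3 matched variants, got {len(common)}")
    x = np.array([release_times[k] for k in common], dtype=np.float64)
    y = np.array([activities[k] for k in common], dtype=np.float64)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SampleSizeError(
            "correlation undefined: one variable is constant")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(r=float(res.statistic),
                             p_value=float(res.pvalue),
                             n=len(common), method=method)


def read_activity_table(path) -> tuple[dict[str, float], dict[str, str]]:
    """Read a (variant, activity, unit) CSV into two name-keyed dicts."""
    df = pd.read_csv(path)
    required = {"variant", "activity"}
    if not required.issubset(df.columns):
        raise JoinError(f"activity table needs columns {sorted(required)}")
    activities = dict(zip(df["variant"].astype(str), df["activity"].astype(float)))
    units = (dict(zip(df["variant"].astype(str), df["unit"].astype(str)))
             if "unit" in df.columns else {})
    return activities, units


_MANDATORY_STAGES = ("config", "variants", "pmf", "correlation")


def run_report(config: Mapping, variants: Mapping[str, Mapping],
               pmf: Mapping, correlation: Mapping,
               activities: Mapping[str, float] | None = None,
               activity_units: Mapping[str, str] | None = None,
               timestamp: str | None = None) -> dict:
    """Assemble the versioned end-of-run JSON document.

    ``variants`` maps variant name to its step-report dict; the wild type
    ("WT") must be present because it anchors relative activities.  All four
    stages (config echo, variants, pmf/barrier, correlation) are mandatory;
    a missing one raises a completeness error naming the stage.
    """
    stages = {"config": config, "variants": variants, "pmf": pmf,
              "correlation": correlation}
    for name in _MANDATORY_STAGES:
        if stages[name] is None or (hasattr(stages[name], "__len__")
                                    and len(stages[name]) == 0):
            raise CompletenessError(f"mandatory stage missing: {name}")
    if "WT" not in variants:
        raise CompletenessError(
            "mandatory stage missing: variants must include WT "
            "(the activity-normalization anchor)")

    activities = dict(activities or {})
    units = dict(activity_units or {})
    wt_activity = activities.get("WT")
    summaries = {}
    for name, rep in variants.items():
        act = activities.get(name)
        rel = (act / wt_activity if act is not None and wt_activity
               else None)
        summaries[name] = VariantSummary(
            variant=name,
            release_time_ns=rep.get("release_time_ns"),
            step_durations_ns=rep.get("step_durations_ns", {}),
            activity=act, activity_unit=units.get(name),
            activity_relative_to_wt=rel).to_dict()

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "timestamp": timestamp if timestamp is not None
        else datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": dict(config),
        "variants": summaries,
        "pmf": dict(pmf),
        "correlation": dict(correlation),
    }


def validate_report(report: Mapping) -> None:
    """Schema check: versioned keys present and well-typed."""
    for key in ("schema_version", "timestamp", "config", "variants",
                "pmf", "correlation"):
        if key not in report:
            raise CompletenessError(f"report missing key: {key}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise CompletenessError(
            f"unsupported schema version {report['schema_version']!r}")
    if "WT" not in report["variants"]:
        raise CompletenessError("report variants must include WT")


def write_report(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
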