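"""The four-level feature/index ablation study.

Level 1 trains the SLP on every single (index, feature) scalar; level 2 on
every feature pair within each index; level 3 on all six features of each
index; level 4 on full-feature combinations of 2–5 indices with the thermal
channel excluded.  Each level runs for the short (12-day, 5 key days) and
long (25-day, 7 key days) monitoring periods, and every entry is a
trial-averaged accuracy with its mean confusion matrix and training time —
the rows of the study's report tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .classifier import TrainResult, trial_average
from .io_formats import FEATURE_NAMES, FeatureTable
from .indices import IndexName

ENTROPY_LIKE = ("entropy", "max_min")


@dataclass(frozen=True)
class PeriodSpec:
    name: str
    days: tuple[int, ...]

    @property
    def n_classes(self) -> int:
        return len(self.days)


SHORT_PERIOD = PeriodSpec("short", (1, 3, 6, 8, 12))
LONG_PERIOD = PeriodSpec("long", (1, 3, 6, 8, 12, 19, 25))
PERIODS = {"short": SHORT_PERIOD, "long": LONG_PERIOD}


@dataclass
class StudyReport:
    level: str  # single | pair | full_index | index_combo
    entries: pd.DataFrame  # one row per (configuration, period)
    results: dict = field(default_factory=dict)  # row key -> TrainResult

    def __len__(self) -> int:
        return len(self.entries)


def _restrict(table: FeatureTable, period: PeriodSpec) -> FeatureTable:
    missing = set(period.days) - set(table.days)
    if missing:
        raise ValidationError(f"table is missing key days {sorted(missing)}")
    frame = table.frame[table.frame["day_label"].isin(period.days)]
    return FeatureTable(frame.copy())


def _run_seed(master_seed: int, *parts: str) -> int:
    """Stable per-configuration seed derived from the master seed."""
    h = np.int64(int(master_seed) % (2**31))
    for part in parts:
        for ch in str(part):
            h = np.int64((h * 131 + ord(ch)) % 2147483647)
    return int(h)


def _available_indices(table: FeatureTable) -> list[str]:
    order = [n.value for n in IndexName]
    present = set(table.frame["index_name"].unique())
    return [n for n in order if n in present]


def run_single_feature_study(
    table: FeatureTable, period: PeriodSpec | str = LONG_PERIOD,
    n_trials: int = 100, seed: int = 0,
) -> StudyReport:
    """One trial-averaged run per (index, feature) scalar; 60 entries for 10 indices.

    The best feature of each index is flagged (``is_index_max``), mirroring
    the bold-max convention of the per-feature report table.
    """
    period = PERIODS[period] if isinstance(period, str) else period
    sub = _restrict(table, period)
    rows, results = [], {}
    for index_name in _available_indices(sub):
        for feat in FEATURE_NAMES:
            key = f"{index_name}/{feat}/{period.name}"
            res = trial_average(
                sub, [(index_name, feat)], n_trials=n_trials,
                seed=_run_seed(seed, "single", key),
            )
            results[key] = res
            rows.append(
                dict(index=index_name, feature=feat, period=period.name,
                     accuracy=res.mean_accuracy, time_s=res.training_time_s)
            )
    entries = pd.DataFrame(rows)
    entries["is_index_max"] = entries.groupby("index")["accuracy"].transform(
        lambda a: a == a.max()
    )
    return StudyReport(level="single", entries=entries, results=results)


def run_pair_study(
    table: FeatureTable, periods: tuple = ("short", "long"),
    n_trials: int = 100, seed: int = 0,
) -> StudyReport:
    """All C(6,2)=15 feature pairs within each index, for both periods.

    Each entry is flagged when the pair contains entropy or max−min (the
    entropy-like high-level features).  ``diagonal_accuracy`` carries the
    best single-feature accuracy of that index/period — the matrix diagonal
    of the pair-accuracy report.
    """
    periods = [PERIODS[p] if isinstance(p, str) else p for p in periods]
    rows, results = [], {}
    singles: dict[tuple[str, str, str], float] = {}
    for period in periods:
        sub = _restrict(table, period)
        for index_name in _available_indices(sub):
            for feat in FEATURE_NAMES:
                res = trial_average(
                    sub, [(index_name, feat)], n_trials=n_trials,
                    seed=_run_seed(seed, "single", f"{index_name}/{feat}/{period.name}"),
                )
                singles[(index_name, feat, period.name)] = res.mean_accuracy
            best_single = max(
                singles[(index_name, f, period.name)] for f in FEATURE_NAMES
            )
            for fa, fb in itertools.combinations(FEATURE_NAMES, 2):
                key = f"{index_name}/{fa}+{fb}/{period.name}"
                res = trial_average(
                    sub, [(index_name, fa), (index_name, fb)], n_trials=n_trials,
                    seed=_run_seed(seed, "pair", key),
                )
                results[key] = res
                rows.append(
                    dict(index=index_name, feature_a=fa, feature_b=fb,
                         period=period.name, accuracy=res.mean_accuracy,
                         time_s=res.training_time_s,
                         has_entropy_like=(fa in ENTROPY_LIKE or fb in ENTROPY_LIKE),
                         diagonal_accuracy=best_single)
                )
    return StudyReport(level="pair", entries=pd.DataFrame(rows), results=results)


def rank_pairs(report: StudyReport, top_k: int = 20) -> pd.DataFrame:
    """Rank feature pairs by accuracy_short + accuracy_long (descending),
    breaking ties by summed training time (ascending).

    The returned frame carries ``entropy_like_share``: the fraction of the
    top-k pairs containing entropy or max−min.
    """
    if report.level != "pair":
        raise ValidationError("rank_pairs needs a pair-level report")
    e = report.entries
    wide = e.pivot_table(
        index=["index", "feature_a", "feature_b", "has_entropy_like"],
        columns="period", values=["accuracy", "time_s"],
    ).reset_index()
    wide.columns = ["_".join(filter(None, map(str, c))) for c in wide.columns]
    per_cols = [c for c in wide.columns if c.startswith("accuracy_")]
    time_cols = [c for c in wide.columns if c.startswith("time_s_")]
    wide["accuracy_sum"] = wide[per_cols].sum(axis=1)
    wide["time_sum"] = wide[time_cols].sum(axis=1)
    wide = wide.sort_values(
        ["accuracy_sum", "time_sum"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    top = wide.head(top_k)
    wide.attrs["entropy_like_share"] = float(top["has_entropy_like"].mean())
    return wide


def run_full_index_study(
    table: FeatureTable, periods: tuple = ("short", "long"),
    n_trials: int = 100, seed: int = 0,
) -> StudyReport:
    """Each index on its own with all six features (M=6, N=6), both periods."""
    periods = [PERIODS[p] if isinstance(p, str) else p for p in periods]
    rows, results = [], {}
    for period in periods:
        sub = _restrict(table, period)
        for index_name in _available_indices(sub):
            key = f"{index_name}/all6/{period.name}"
            subset = [(index_name, f) for f in FEATURE_NAMES]
            res = trial_average(
                sub, subset, n_trials=n_trials, seed=_run_seed(seed, "full", key)
            )
            results[key] = res
            rows.append(
                dict(index=index_name, period=period.name,
                     accuracy=res.mean_accuracy, time_s=res.training_time_s)
            )
    return StudyReport(level="full_index", entries=pd.DataFrame(rows), results=results)


def run_index_combo_study(
    table: FeatureTable, periods: tuple = ("short", "long"),
    combo_sizes: tuple = (2, 3), combos: list[tuple[str, ...]] | None = None,
    exclude: tuple = ("TIR",), n_trials: int = 100, seed: int = 0,
    max_combos_per_size: int | None = None,
) -> StudyReport:
    """Full-feature-vector runs over combinations of indices (TIR excluded).

    A combination of ``k`` indices uses M = 6k inputs and N = k + 5 hidden
    neurons.  Sizes 2–3 are enumerated exhaustively by default; larger sizes
    can be capped with ``max_combos_per_size`` (deterministic subsample).
    """
    periods = [PERIODS[p] if isinstance(p, str) else p for p in periods]
    pool = [n for n in _available_indices(table) if n not in exclude]
    if combos is not None:
        for combo in combos:
            bad = set(combo) & set(exclude)
            if bad:
                raise ValidationError(f"combination {combo} uses excluded indices {bad}")
        chosen = [tuple(c) for c in combos]
    else:
        chosen = []
        for size in combo_sizes:
            all_c = list(itertools.combinations(pool, size))
            if max_combos_per_size is not None and len(all_c) > max_combos_per_size:
                rng = np.random.default_rng(_run_seed(seed, "combo-sample", str(size)))
                keep = rng.choice(len(all_c), size=max_combos_per_size, replace=False)
                all_c = [all_c[i] for i in sorted(keep)]
            chosen.extend(all_c)
    rows, results = [], {}
    for period in periods:
        sub = _restrict(table, period)
        for combo in chosen:
            key = f"{'+'.join(combo)}/{period.name}"
            subset = [(idx, f) for idx in combo for f in FEATURE_NAMES]
            res = trial_average(
                sub, subset, n_trials=n_trials, seed=_run_seed(seed, "combo", key)
            )
            results[key] = res
            rows.append(
                dict(combo=",".join(combo), size=len(combo), period=period.name,
                     accuracy=res.mean_accuracy, time_s=res.training_time_s)
            )
    return StudyReport(level="index_combo", entries=pd.DataFrame(rows), results=results)


def write_report(report: StudyReport, out_dir) -> None:
    """Per-level CSV, a JSON summary, and one confusion-matrix CSV per entry."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    report.entries.to_csv(
        os.path.join(out_dir, f"{report.level}_report.csv"),
        index=False, float_format="%.10g",
    )
    summary = {"level": report.level, "n_entries": int(len(report.entries))}
    if "accuracy" in report.entries:
        summary["best_accuracy"] = float(report.entries["accuracy"].max())
    with open(os.path.join(out_dir, f"{report.level}_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    cm_dir = os.path.join(out_dir, "confusion")
    os.makedirs(cm_dir, exist_ok=True)
    for key, res in report.results.items():
        safe = key.replace("/", "_").replace("+", "-")
        days = res.day_labels
        frame = pd.DataFrame(res.mean_confusion,
                             index=[f"d{d:02d}" for d in days],
                             columns=[f"d{d:02d}" for d in days])
        frame.to_csv(os.path.join(cm_dir, f"{safe}.csv"), float_format="%.10g")
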