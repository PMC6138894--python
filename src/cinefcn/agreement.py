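"""Pairwise measurement agreement: absolute/relative differences and
Bland-Altman statistics, plus the computer-vs-human observer study layout."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clinical import measures_report
from .seg_metrics import evaluate_case

__all__ = [
    "PairedDifferences",
    "BlandAltman",
    "paired_differences",
    "bland_altman",
    "bland_altman_plot",
    "observer_study",
    "COMPARISON_COLUMNS",
]

COMPARISON_COLUMNS = ("Auto vs Manual", "O1 vs O2", "O2 vs O3", "O3 vs O1")


@dataclass(frozen=True)
class PairedDifferences:
    mean_abs: float
    sd_abs: float
    mean_rel_pct: float
    sd_rel_pct: float
    n: int
    n_excluded: int  # pairs with zero mean, excluded from the relative form


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    n: int


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def paired_differences(pairs) -> PairedDifferences:
    """Mean/SD of |a-b| and of the relative difference 100|a-b| / ((a+b)/2).

    SDs are sample SDs (n-1 denominator).  Pairs with a + b = 0 are excluded
    from the relative form and counted in ``n_excluded``.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be a nonempty sequence of (a, b)")
    a, b = arr[:, 0], arr[:, 1]
    absdiff = np.abs(a - b)
    mean = (a + b) / 2.0
    ok = mean != 0
    rel = 100.0 * absdiff[ok] / np.abs(mean[ok])
    return PairedDifferences(
        mean_abs=float(absdiff.mean()),
        sd_abs=_sd(absdiff),
        mean_rel_pct=float(rel.mean()) if rel.size else float("nan"),
        sd_rel_pct=_sd(rel),
        n=arr.shape[0],
        n_excluded=int((~ok).sum()),
    )


def bland_altman(pairs) -> BlandAltman:
    """Bias = mean(a - b); limits of agreement = bias +/- 1.96 sample SD."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = arr[:, 0] - arr[:, 1]
    bias = float(diff.mean())
    spread = 1.96 * _sd(diff)
    return BlandAltman(bias, bias - spread, bias + spread, arr.shape[0])


def bland_altman_plot(pairs, ax=None, label: str = ""):
    """Scatter of (a-b) against (a+b)/2 with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    arr = np.asarray(list(pairs), dtype=float)
    stats = bland_altman(arr)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(arr.mean(axis=1), arr[:, 0] - arr[:, 1], s=12)
    ax.axhline(stats.bias, color="k", linestyle="--")
    for y in (stats.loa_low, stats.loa_high):
        ax.axhline(y, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("mean of two measurements")
    ax.set_ylabel("difference")
    if label:
        ax.set_title(label)
    return ax


def observer_study(cases: list[dict]) -> dict[str, pd.DataFrame]:
    """Agreement tables over a set of cases with multiple raters.

    Each case is a dict of segmentations keyed ``auto``, ``manual``, ``o1``,
    ``o2``, ``o3`` (missing raters drop the affected comparison columns).
    Returns three tables with one comparison column per pair:

    * ``dice`` / ``mcd`` / ``hd``: mean (SD) of each metric per structure;
    * ``measures_abs`` / ``measures_rel``: mean (SD) of absolute and relative
      clinical-measure differences.
    """
    if len(cases) < 2:
        raise ValueError("observer study needs at least 2 cases")
    pair_defs = {
        "Auto vs Manual": ("auto", "manual"),
        "O1 vs O2": ("o1", "o2"),
        "O2 vs O3": ("o2", "o3"),
        "O3 vs O1": ("o3", "o1"),
    }
    available = {
        name: (x, y)
        for name, (x, y) in pair_defs.items()
        if all(x in c and y in c for c in cases)
    }
    if not available:
        raise ValueError("no comparison pair is present in every case")

    some_seg = next(iter(cases[0].values()))
    structures = some_seg.scheme.foreground()

    metric_rows: dict[str, dict] = {m: {} for m in ("dice", "mcd", "hd")}
    measure_pairs: dict[str, dict[str, list]] = {name: {} for name in available}
    for name, (x, y) in available.items():
        per_struct = {s: {"dice": [], "mcd": [], "hd": []} for s in structures}
        for case in cases:
            cm = evaluate_case(case[x], case[y])
            for s in structures:
                sm = cm[s]
                if sm.dice is not None:
                    per_struct[s]["dice"].append(sm.dice)
                if sm.mcd_mm is not None:
                    per_struct[s]["mcd"].append(sm.mcd_mm)
                if sm.hd_mm is not None:
                    per_struct[s]["hd"].append(sm.hd_mm)
            mx = measures_report(case[x]).as_dict()
            my = measures_report(case[y]).as_dict()
            for key, vx in mx.items():
                vy = my.get(key)
                if key.endswith("frame") or vx is None or vy is None:
                    continue
                measure_pairs[name].setdefault(key, []).append((vx, vy))
        for s in structures:
            for metric in ("dice", "mcd", "hd"):
                vals = np.asarray(per_struct[s][metric])
                cell = (
                    f"{vals.mean():.3f} ({_sd(vals):.3f})" if vals.size else "n/a"
                )
                metric_rows[metric].setdefault(s, {})[name] = cell

    tables = {
        metric: pd.DataFrame.from_dict(rows, orient="index")
        for metric, rows in metric_rows.items()
    }
    abs_rows: dict[str, dict] = {}
    rel_rows: dict[str, dict] = {}
    for name, per_measure in measure_pairs.items():
        for key, pairs in per_measure.items():
            pd_stats = paired_differences(pairs)
            abs_rows.setdefault(key, {})[name] = (
                f"{pd_stats.mean_abs:.2f} ({pd_stats.sd_abs:.2f})"
            )
            rel_rows.setdefault(key, {})[name] = (
                f"{pd_stats.mean_rel_pct:.2f} ({pd_stats.sd_rel_pct:.2f})"
            )
    tables["measures_abs"] = pd.DataFrame.from_dict(abs_rows, orient="index")
    tables["measures_rel"] = pd.DataFrame.from_dict(rel_rows, orient="index")
    return tables
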