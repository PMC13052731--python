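"""Group comparisons and report assembly.

Two groups are compared with an unpaired two-sided t-test (pooled
variance by default, Welch optional); three or more groups with one-way
ANOVA followed by Tukey's HSD post hoc test at a family-wise alpha of
0.05.  ``build_report`` assembles stage outputs into a deterministic
JSON + CSV bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__

__all__ = ["GroupComparison", "compare_groups", "build_report"]


@dataclass
class GroupComparison:
    groups: list[str]
    values: dict[str, np.ndarray]
    test: str  # "t-test (pooled)" | "t-test (Welch)" | "one-way ANOVA + Tukey HSD"
    statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    #: (group_a, group_b, p_adj, significant) rows; only for >= 3 groups
    tukey: list[tuple[str, str, float, bool]] = field(default_factory=list)


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    alpha: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Compare independent groups following standard conventions.

    Exactly two groups get an unpaired two-sided t-test; three or more get
    one-way ANOVA with Tukey HSD pairwise comparisons.  Every group needs
    at least 2 values.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for n in names:
        a = np.asarray(values_by_group[n], dtype=np.float64)
        if a.size < 2:
            raise ValueError(f"group {n!r} has fewer than 2 values")
        arrays.append(a)

    if len(names) == 2:
        with warnings.catch_warnings():
            # constant groups trigger a precision warning; handled below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(arrays[0], arrays[1], equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # identical constant groups: no difference
            stat, p = 0.0, 1.0
        return GroupComparison(
            groups=names,
            values=dict(zip(names, arrays)),
            test="t-test (Welch)" if welch else "t-test (pooled)",
            statistic=stat,
            p_value=p,
            significant=p < alpha,
            alpha=alpha,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_res = stats.f_oneway(*arrays)
    stat, p = float(f_res.statistic), float(f_res.pvalue)
    if np.isnan(stat):
        stat, p = 0.0, 1.0
    tukey_res = stats.tukey_hsd(*arrays)
    rows: list[tuple[str, str, float, bool]] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            padj = float(tukey_res.pvalue[i, j])
            rows.append((names[i], names[j], padj, padj < alpha))
    return GroupComparison(
        groups=names,
        values=dict(zip(names, arrays)),
        test="one-way ANOVA + Tukey HSD",
        statistic=stat,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        tukey=rows,
    )


def _comparison_record(c: GroupComparison) -> dict:
    return {
        "groups": c.groups,
        "test": c.test,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "significant": bool(c.significant),
        "alpha": c.alpha,
        "tukey": [
            {"a": a, "b": b, "p_adj": p, "significant": bool(s)}
            for a, b, p, s in c.tukey
        ],
        "n_per_group": {g: int(len(v)) for g, v in c.values.items()},
    }


def build_report(
    stage_outputs: dict[str, object],
    out_dir: str | Path,
    config: dict | None = None,
) -> Path:
    """Write a deterministic report bundle from stage outputs.

    ``stage_outputs`` maps a section name to a ``pandas.DataFrame`` (written
    as ``<name>.csv`` and summarized by row count), a
    :class:`GroupComparison`, or any JSON-serializable object.  The bundle
    is ``report.json`` plus one CSV per tabular section; field ordering is
    sorted so reruns on identical inputs are byte-identical.

    Returns the path to ``report.json``.
    """
    if not stage_outputs:
        raise ValueError("no stage outputs supplied")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "nucmorph", "version": __version__},
        "config": config or {},
        "sections": {},
    }
    for name in sorted(stage_outputs):
        obj = stage_outputs[name]
        if isinstance(obj, pd.DataFrame):
            csv_path = out_dir / f"{name}.csv"
            obj.to_csv(csv_path, index=False, lineterminator="\n")
            report["sections"][name] = {
                "kind": "table",
                "csv": csv_path.name,
                "n_rows": int(len(obj)),
                "columns": list(obj.columns),
            }
        elif isinstance(obj, GroupComparison):
            report["sections"][name] = {
                "kind": "comparison",
                **_comparison_record(obj),
            }
        else:
            report["sections"][name] = {"kind": "value", "value": obj}
    path = out_dir / "report.json"
    path.write_text(
        json.dumps(report, sort_keys=True, indent=2, default=_json_default) + "\n"
    )
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
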