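"""Statistical comparison of segmentation methods and study-report tables.

One-way ANOVA compares per-subject scores across segmentation methods
(manual observer pairs, the pretrained model, the fine-tuned model),
followed by Tukey's HSD for pairwise method contrasts.  Summaries report
median, range and interquartile range with the linear-interpolation
quantile convention.  ``build_report`` assembles the full study report:
per-method score summaries with ANOVA p per test set and metric, the
consensus-level recall table with per-level ANOVA p, and a per-subject
listing ordered by truth volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_DEFAULT = 0.05


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    reject: bool


@dataclass
class TukeyResult:
    alpha: float
    pairs: list[TukeyPair]


@dataclass
class SummaryStats:
    median: float
    min: float
    max: float
    q1: float
    q3: float


def _clean_groups(groups: dict) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        out[str(name)] = arr
    return out


def one_way_anova(groups: dict) -> AnovaResult:
    """Classical one-way ANOVA over labelled score groups.

    Degenerate input (all values identical everywhere) is flagged and
    reported as F = 0, p = 1 rather than an error.
    """
    g = _clean_groups(groups)
    if len(g) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for name, arr in g.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    samples = list(g.values())
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return AnovaResult(0.0, 1.0, k - 1, n_total - k, degenerate=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = sps.f_oneway(*samples)
    if not np.isfinite(F):  # zero within-group variance with distinct means
        return AnovaResult(float("inf"), 0.0, k - 1, n_total - k, degenerate=True)
    return AnovaResult(float(F), float(p), k - 1, n_total - k)


def tukey_hsd(groups: dict, alpha: float = ALPHA_DEFAULT) -> TukeyResult:
    """Tukey honestly-significant-difference test over all group pairs."""
    g = _clean_groups(groups)
    if len(g) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    for name, arr in g.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    names = list(g.keys())
    samples = [g[n] for n in names]
    pooled = np.concatenate(samples)
    pairs: list[TukeyPair] = []
    if np.ptp(pooled) == 0:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append(TukeyPair(names[i], names[j], 0.0, 1.0, False))
        return TukeyResult(alpha=alpha, pairs=pairs)
    res = sps.tukey_hsd(*samples)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(res.pvalue[i, j])
            diff = float(np.mean(samples[i]) - np.mean(samples[j]))
            pairs.append(TukeyPair(names[i], names[j], diff, p_adj, p_adj < alpha))
    return TukeyResult(alpha=alpha, pairs=pairs)


def summarize(scores) -> SummaryStats:
    """Median, range, and quartiles (linear-interpolation convention)."""
    arr = np.asarray(list(scores), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarize an empty score list")
    return SummaryStats(
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        q1=float(np.quantile(arr, 0.25)),
        q3=float(np.quantile(arr, 0.75)),
    )


# ---------------------------------------------------------------------------
# Study report
# ---------------------------------------------------------------------------

METRICS = ("dsc", "precision", "recall")


def _per_subject_model_scores(df: pd.DataFrame, metric: str) -> pd.Series:
    """Model-arm scores per subject (median over observer references)."""
    return df.groupby("subject_id")[metric].median()


def method_groups(records: pd.DataFrame, metric: str, pool_observer_pairs: bool = True) -> dict[str, np.ndarray]:
    """Group scores by segmentation method for ANOVA.

    Model arms contribute one score per subject (median across observer
    references when several exist).  The manual arm (observer-vs-observer
    records, predictor label starting with "RO") contributes one score per
    subject-pair when ``pool_observer_pairs`` else per-subject medians.
    """
    groups: dict[str, np.ndarray] = {}
    manual = records[records["predictor"].str.startswith("RO")]
    if len(manual):
        if pool_observer_pairs:
            groups["manual"] = manual[metric].to_numpy(dtype=float)
        else:
            groups["manual"] = manual.groupby("subject_id")[metric].median().to_numpy(dtype=float)
    for model in sorted(records.loc[~records["predictor"].str.startswith("RO"), "predictor"].unique()):
        sub = records[records["predictor"] == model]
        groups[model] = _per_subject_model_scores(sub, metric).to_numpy(dtype=float)
    return groups


def build_report(
    records: pd.DataFrame,
    consensus: pd.DataFrame | None = None,
    manifest_info: dict | None = None,
    alpha: float = ALPHA_DEFAULT,
    pool_observer_pairs: bool = True,
) -> dict:
    """Assemble the study report from tidy evaluation records.

    ``records`` columns: test_set, predictor, reference, subject_id, dsc,
    precision, recall, truth_volume_voxels, degenerate.  ``consensus``
    columns: predictor, subject_id, level, recall.  Returns a
    JSON-serializable dict; ``write_report`` persists it as JSON plus CSV
    tables that agree value-for-value.
    """
    required = {"test_set", "predictor", "subject_id"} | set(METRICS)
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    model_arms = sorted(records.loc[~records["predictor"].str.startswith("RO"), "predictor"].unique())
    if len(model_arms) < 2:
        raise ValueError("report needs evaluation records for at least two model arms")

    report: dict = {"alpha": alpha, "manifest": manifest_info or {}}

    score_tables: dict = {}
    for test_set, df_set in records.groupby("test_set"):
        entry: dict = {}
        for metric in METRICS:
            groups = method_groups(df_set, metric, pool_observer_pairs)
            per_method = {
                name: asdict(summarize(vals)) | {"n": int(np.isfinite(vals).sum())}
                for name, vals in groups.items()
                if np.isfinite(vals).any()
            }
            stats_block: dict = {}
            testable = {k: v for k, v in groups.items() if np.sum(np.isfinite(v)) >= 2}
            if len(testable) >= 2:
                anova = one_way_anova(testable)
                stats_block["anova"] = asdict(anova)
                tk = tukey_hsd(testable, alpha)
                stats_block["tukey"] = [asdict(p) for p in tk.pairs]
            entry[metric] = {"methods": per_method, "stats": stats_block}
        score_tables[str(test_set)] = entry
    report["scores"] = score_tables

    if consensus is not None and len(consensus):
        levels = sorted(consensus["level"].unique(), reverse=True)
        table4: dict = {}
        for level in levels:
            df_l = consensus[consensus["level"] == level]
            per_model = {}
            for model, df_m in df_l.groupby("predictor"):
                vals = df_m["recall"].to_numpy(dtype=float)
                if np.isfinite(vals).any():
                    per_model[str(model)] = asdict(summarize(vals)) | {"n": int(np.isfinite(vals).sum())}
            groups = {
                str(m): df_m["recall"].to_numpy(dtype=float)
                for m, df_m in df_l.groupby("predictor")
            }
            testable = {k: v for k, v in groups.items() if np.sum(np.isfinite(v)) >= 2}
            stats_block = {}
            if len(testable) >= 2:
                stats_block["anova"] = asdict(one_way_anova(testable))
            table4[f"level_{int(level)}"] = {"methods": per_model, "stats": stats_block}
        report["consensus_recall"] = table4

    listing = (
        records.sort_values(["test_set", "truth_volume_voxels", "subject_id", "predictor", "reference"])
        .reset_index(drop=True)
    )
    report["per_subject"] = json.loads(listing.to_json(orient="records"))
    return report


def write_report(report: dict, outdir) -> dict[str, str]:
    """Write the report bundle: report.json + flat CSV tables. Returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report, sort_keys=True, indent=1, allow_nan=True))
    paths["json"] = str(json_path)

    rows = []
    for test_set, entry in report.get("scores", {}).items():
        for metric, block in entry.items():
            for method, summ in block["methods"].items():
                anova_p = block["stats"].get("anova", {}).get("p")
                rows.append({"test_set": test_set, "metric": metric, "method": method,
                             **{k: summ[k] for k in ("median", "min", "max", "q1", "q3", "n")},
                             "anova_p": anova_p})
    scores_csv = outdir / "scores_summary.csv"
    pd.DataFrame(rows).to_csv(scores_csv, index=False)
    paths["scores_csv"] = str(scores_csv)

    if "consensus_recall" in report:
        rows = []
        for level, block in report["consensus_recall"].items():
            for method, summ in block["methods"].items():
                rows.append({"level": level, "method": method,
                             **{k: summ[k] for k in ("median", "min", "max", "q1", "q3", "n")},
                             "anova_p": block["stats"].get("anova", {}).get("p")})
        cons_csv = outdir / "consensus_recall.csv"
        pd.DataFrame(rows).to_csv(cons_csv, index=False)
        paths["consensus_csv"] = str(cons_csv)

    subj_csv = outdir / "per_subject.csv"
    pd.DataFrame(report["per_subject"]).to_csv(subj_csv, index=False)
    paths["per_subject_csv"] = str(subj_csv)
    return paths
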