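"""End-to-end plumbing: records -> feature table -> summary tables.

Shared by the command-line interface and scripts; the science lives in
:mod:`preprocess`, :mod:`nld_features` and :mod:`group_stats`.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gait_io import GaitRecord, Group, RATIO_PAIRS, SERIES_COLUMNS, Side, validate_record
from .group_stats import GROUP_ORDER, group_table, kruskal_wallis, rank_groups
from .nld_features import FeatureConfig, extract_all
from .preprocess import PreprocessConfig, trim_startup

__all__ = [
    "SERIES_ROW_ORDER",
    "FEATURE_COLUMNS",
    "features_table",
    "summary_tables",
]

#: Summary-table row order: per phase, left / right / ratio.
SERIES_ROW_ORDER: tuple[str, ...] = (
    "left_stride_s", "right_stride_s", "ratio_stride_s",
    "left_swing_s", "right_swing_s", "ratio_swing_s",
    "left_swing_pct", "right_swing_pct", "ratio_swing_pct",
    "left_stance_s", "right_stance_s", "ratio_stance_s",
    "left_stance_pct", "right_stance_pct", "ratio_stance_pct",
)

#: The scalar features summarised per series.
FEATURE_COLUMNS: tuple[str, ...] = ("c0", "sampen", "wavelet_entropy", "wavelet_coeff")


def features_table(
    records: Iterable[GaitRecord],
    cfg: FeatureConfig | None = None,
    pre: PreprocessConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """One feature row per (subject, series kind); invalid records excluded.

    A record with any negative interval (the database's corrupt-record
    marker) is excluded from analysis and logged; too-short series are
    skipped per series. Start-up strides are trimmed before extraction.
    Returns ``(table, log_lines)``.
    """
    cfg = cfg or FeatureConfig()
    pre = pre or PreprocessConfig()
    rows: list[dict] = []
    log: list[str] = []
    n_valid = 0
    for rec in records:
        findings = validate_record(rec)
        negatives = [f for f in findings if f.kind == "negative_value"]
        if negatives:
            log.append(
                f"EXCLUDED {rec.subject_id} ({rec.group.value}): "
                f"{len(negatives)} negative interval(s), e.g. {negatives[0]}"
            )
            continue
        n_valid += 1
        trimmed = trim_startup(rec, pre)
        feats, skipped = extract_all(trimmed, cfg, pre)
        for name, reason in skipped:
            log.append(f"SKIPPED {rec.subject_id}/{name}: {reason}")
        for fv in feats:
            row = asdict(fv)
            row["group"] = fv.group.value
            row["startup_trim_s"] = pre.startup_trim
            row["filter_n"] = cfg.filter.n if cfg.prefilter else 0
            rows.append(row)
        log.append(f"OK {rec.subject_id} ({rec.group.value}): {len(feats)} series")
    if n_valid == 0:
        raise ValueError("no valid records to analyse")
    return pd.DataFrame(rows), log


def _wide_table(per_subject: pd.DataFrame, value_col: str, pooled: bool) -> pd.DataFrame:
    """Series-kind x group table of 'mean ± sd' cells for one statistic."""
    cells: dict[str, dict[str, str]] = {}
    for kind in SERIES_ROW_ORDER:
        sub = per_subject[per_subject.series_kind == kind]
        if sub.empty:
            continue
        summaries = group_table(
            sub, value_col, feature_name=kind, weights_col="n" if pooled else None
        )
        cells[kind] = {s.group.value: s.cell() for s in summaries}
    df = pd.DataFrame.from_dict(cells, orient="index")
    return df.reindex(columns=[g.value for g in GROUP_ORDER])


def summary_tables(
    features: pd.DataFrame, pooled: bool = False
) -> dict[str, pd.DataFrame]:
    """The per-group summary tables plus Kruskal–Wallis tests and rankings.

    Returns tables keyed ``gait_stats`` (per-series mean, the raw-data
    analogue), ``c0``, ``sampen``, ``wavelet_entropy``, ``wavelet_coeff``,
    ``kruskal_wallis`` and ``rankings``. Aggregation weights subjects
    equally unless ``pooled`` (stride-count weighting).
    """
    if "group" not in features.columns:
        raise ValueError("features table lacks a 'group' column")
    tables = {"gait_stats": _wide_table(features, "series_mean", pooled)}
    for feat in FEATURE_COLUMNS:
        tables[feat] = _wide_table(features, feat, pooled)

    present = [g for g in GROUP_ORDER if g.value in set(features.group)]
    kw_rows, rank_rows = [], []
    for feat in FEATURE_COLUMNS:
        for kind in SERIES_ROW_ORDER:
            sub = features[features.series_kind == kind]
            if sub.empty:
                continue
            samples = [
                sub.loc[sub.group == g.value, feat].to_numpy(dtype=float) for g in present
            ]
            samples = [s[np.isfinite(s)] for s in samples]
            if len(samples) < 2 or any(s.size == 0 for s in samples):
                continue
            kw = kruskal_wallis(samples, groups=present)
            kw_rows.append(
                {"feature": feat, "series_kind": kind, "H": kw.H, "p_value": kw.p_value}
            )
            if set(present) == set(GROUP_ORDER):
                summaries = group_table(sub, feat, feature_name=kind)
                order, tie = rank_groups(summaries, feature=kind)
                rank_rows.append(
                    {
                        "feature": feat,
                        "series_kind": kind,
                        "ranking": ">".join(g.value for g in order),
                        "tie": tie,
                    }
                )
    tables["kruskal_wallis"] = pd.DataFrame(
        kw_rows, columns=["feature", "series_kind", "H", "p_value"]
    )
    tables["rankings"] = pd.DataFrame(
        rank_rows, columns=["feature", "series_kind", "ranking", "tie"]
    )
    return tables
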