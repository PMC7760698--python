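"""Summaries of filtering and screening outcomes.

Covers the reporting surfaces a profiling study needs: per-mode volcano
classification counts with retained percentages, the total of
blank-enriched (matrix background) features, per-protocol counts of
significant metabolites with their median CVs, pairwise list overlaps,
and long-format volcano-plot tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .blank_filter import FeatureClassification, classify_features
from .config import PipelineConfig
from .feature_table import FeatureTable

__all__ = [
    "ClassificationSummary",
    "ProtocolSummary",
    "classification_summary",
    "blank_enriched_total",
    "protocol_summary",
    "overlap_summary",
    "volcano_table",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (so 25.65 -> 25.7, not banker's 25.6)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassificationSummary:
    mode: str
    n_cell_derived: int
    n_ecm_enriched: int
    n_uninformative: int
    n_untestable: int
    n_total: int           # cell + ecm + uninformative (untestable separate)
    retained_pct: float    # 100 * cell / total, 1 decimal


@dataclass(frozen=True)
class ProtocolSummary:
    protocol: str
    mode: str
    n_significant: int
    median_cv_pct: float   # NaN when no significant metabolites


def classification_summary(classifications: list[FeatureClassification],
                           include_untestable: bool = True
                           ) -> list[ClassificationSummary]:
    """Per-mode label counts and the retained (cell-derived) percentage.

    ``include_untestable=False`` drops untestable features from the
    denominator; by default they count as uninformative background.
    """
    if not classifications:
        raise ValueError("no classifications given")
    by_mode: dict[str, dict[str, int]] = {}
    for c in classifications:
        d = by_mode.setdefault(c.mode, {"cell_derived": 0, "ecm_enriched": 0,
                                        "uninformative": 0, "untestable": 0})
        d[c.label] += 1
    out = []
    for mode, d in by_mode.items():
        n_uninf = d["uninformative"]
        n_untest = d["untestable"]
        total = d["cell_derived"] + d["ecm_enriched"] + n_uninf
        if include_untestable:
            total += n_untest
        pct = round_half_up(100.0 * d["cell_derived"] / total) if total else 0.0
        out.append(ClassificationSummary(
            mode, d["cell_derived"], d["ecm_enriched"], n_uninf, n_untest,
            total, pct))
    out.sort(key=lambda s: s.mode)
    return out


def blank_enriched_total(summaries: list[ClassificationSummary]) -> int:
    """Total ECM-enriched (blank-higher) features across all modes."""
    return sum(s.n_ecm_enriched for s in summaries)


def protocol_summary(tables: dict[tuple[str, str], FeatureTable],
                     cfg: PipelineConfig | None = None
                     ) -> list[ProtocolSummary]:
    """Rate sample-preparation protocols per analytical mode.

    ``tables`` maps (protocol, mode) to a table with biological and blank
    samples. The protocol-rating rule is applied (median fold change > 1,
    Welch p < 0.05, uncorrected); the summary reports the count of
    significant metabolites and the median CV (%) of exactly those
    metabolites across the biological replicates.
    """
    cfg = cfg or PipelineConfig.protocol_rating()
    out = []
    for (protocol, mode), table in sorted(tables.items()):
        cls = classify_features(table, cfg, statistic=cfg.blank_statistic)
        sig = [c.feature_id for c in cls if c.label == "cell_derived"]
        if sig:
            bio = table.abundance[table.sample_ids("biological")]
            v = bio.loc[sig].to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cvs = (np.nanstd(v, axis=1, ddof=1)
                       / np.nanmean(v, axis=1)) * 100.0
            med = float(np.nanmedian(cvs))
        else:
            med = float("nan")
        out.append(ProtocolSummary(protocol, mode, len(sig), med))
    return out


def overlap_summary(lists: dict[str, list[str]],
                    definition: str = "jaccard") -> pd.DataFrame:
    """Pairwise overlap percentages between metabolite lists.

    ``definition`` selects the denominator: ``jaccard`` uses the union,
    ``min_size`` the smaller list. The returned frame carries one row per
    unordered pair plus attrs ``union_count`` (size of the union over all
    lists).
    """
    if definition not in ("jaccard", "min_size"):
        raise ValueError(f"unknown overlap definition {definition!r}")
    keys = list(lists)
    sets = {k: set(lists[k]) for k in keys}
    rows = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            inter = len(sets[a] & sets[b])
            if definition == "jaccard":
                denom = len(sets[a] | sets[b])
            else:
                denom = min(len(sets[a]), len(sets[b]))
            pct = round_half_up(100.0 * inter / denom) if denom else 0.0
            rows.append((a, b, inter, pct))
    df = pd.DataFrame(rows, columns=["list_a", "list_b", "n_common",
                                     "overlap_pct"])
    df.attrs["union_count"] = len(set().union(*sets.values())) if sets else 0
    return df


def volcano_table(classifications: list[FeatureClassification]
                  ) -> pd.DataFrame:
    """Long-format (log2 FC, -log10 p, label) rows for volcano plotting.

    Untestable features are omitted; the number dropped is stored in
    ``attrs['n_untestable']``. p-values of 0 map to +inf on the -log10
    axis.
    """
    rows, n_untestable = [], 0
    for c in classifications:
        if c.label == "untestable":
            n_untestable += 1
            continue
        with np.errstate(divide="ignore"):
            rows.append((c.feature_id, c.mode, float(np.log2(c.fc)),
                         float(-np.log10(c.p_value)) if c.p_value > 0
                         else float("inf"), c.label))
    df = pd.DataFrame(rows, columns=["feature_id", "mode", "log2_fc",
                                     "neg_log10_p", "label"])
    df.attrs["n_untestable"] = n_untestable
    return df
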