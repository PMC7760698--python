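"""Two-step ECM-blank background filtering.

Organoids must be cultured inside a protein-rich extracellular matrix
(ECM), and the matrix contributes abundant ion signals of its own. The
filter compares biological samples against cell-free ECM blanks feature by
feature and keeps only features that are both *significantly* (Welch's
unequal-variance t-test on log2 areas, two-sided, uncorrected p < alpha)
and *relevantly* (fold change above ``fc_up``) more abundant in the
biological samples:

* ``cell_derived``   : fc > fc_up  and p < alpha  — retained
* ``ecm_enriched``   : fc < fc_down and p < alpha — matrix background
* ``uninformative``  : everything else            — removed
* ``untestable``     : too few usable values for the t-test

Fold changes are ratios of raw-scale group statistics (mean by default;
median for the protocol-rating preset); p-values are deliberately used
uncorrected at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .feature_table import FeatureTable, subset

__all__ = [
    "FeatureClassification",
    "welch_log2_p",
    "fold_change",
    "classify_features",
    "retained_table",
    "BlankFilterModel",
    "BlankFilterResults",
]

LABELS = ("cell_derived", "ecm_enriched", "uninformative", "untestable")


@dataclass(frozen=True)
class FeatureClassification:
    feature_id: str
    fc: float          # biological/blank ratio; NaN when untestable
    p_value: float     # two-sided Welch p on log2 values; NaN when untestable
    label: str
    mode: str


def _usable_log2(values) -> np.ndarray:
    """log2 of the positive, present values; zeros/negatives are missing."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    return np.log2(v)


def welch_log2_p(group_a, group_b) -> float:
    """Two-sided Welch t-test p-value on log2-transformed values.

    Uses the Welch-Satterthwaite degrees of freedom. Values that are
    missing or <= 0 are dropped before the transform. Returns NaN when
    either group retains fewer than two values (the feature is untestable);
    returns 1.0 when both groups are constant with equal means and 0.0
    when they are constant with different means.
    """
    a = _usable_log2(group_a)
    b = _usable_log2(group_b)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    se2 = va / len(a) + vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def fold_change(bio, blank, statistic: str = "mean") -> float:
    """Raw-scale biological/blank ratio of group means or medians.

    Returns NaN (untestable) when the blank statistic is zero or the blank
    group is all-missing. Missing values are ignored; zeros participate —
    a genuine zero peak area lowers the group statistic.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be mean or median, got {statistic!r}")
    stat = np.nanmean if statistic == "mean" else np.nanmedian
    bio = np.asarray(bio, dtype=float)
    blank = np.asarray(blank, dtype=float)
    if np.all(np.isnan(blank)) or np.all(np.isnan(bio)):
        return float("nan")
    denom = float(stat(blank))
    if denom <= 0:
        return float("nan")
    return float(stat(bio)) / denom


def _welch_p_matrix(bio: np.ndarray, blank: np.ndarray) -> np.ndarray:
    """Row-wise Welch p on log2 values; NaN rows where <2 usable values."""
    a = np.where(np.isfinite(bio) & (bio > 0), np.log2(
        np.where(bio > 0, bio, 1.0)), np.nan)
    b = np.where(np.isfinite(blank) & (blank > 0), np.log2(
        np.where(blank > 0, blank, 1.0)), np.nan)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where((na < 2) | (nb < 2), np.nan, p)
    both_const = (va == 0) & (vb == 0) & (na >= 2) & (nb >= 2)
    p = np.where(both_const, np.where(ma == mb, 1.0, 0.0), p)
    return p


def classify_features(table: FeatureTable, cfg: PipelineConfig | None = None,
                      statistic: str | None = None
                      ) -> list[FeatureClassification]:
    """Apply the two-step filter to every feature of a table.

    ``statistic`` overrides ``cfg.blank_statistic`` (mean for the
    proof-of-concept rule, median for protocol rating).
    """
    cfg = cfg or PipelineConfig()
    statistic = statistic or cfg.blank_statistic
    bio_ids = table.sample_ids("biological")
    blank_ids = table.sample_ids("blank")
    if not blank_ids:
        raise ValueError("classification requires blank samples")
    if len(bio_ids) < 2 or len(blank_ids) < 2:
        raise ValueError("need >=2 biological and >=2 blank samples")

    bio = table.abundance[bio_ids].to_numpy(dtype=float)
    blank = table.abundance[blank_ids].to_numpy(dtype=float)
    p = _welch_p_matrix(bio, blank)

    stat = np.nanmean if statistic == "mean" else np.nanmedian
    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        num = stat(bio, axis=1)
        den = stat(blank, axis=1)
        fc = np.where(den > 0, num / den, np.nan)
    all_missing = np.all(np.isnan(bio), axis=1) | np.all(np.isnan(blank), axis=1)
    fc = np.where(all_missing, np.nan, fc)

    out = []
    modes = table.features["mode"].to_numpy()
    for i, fid in enumerate(table.features.index):
        if np.isnan(p[i]) or np.isnan(fc[i]):
            label = "untestable"
        elif fc[i] > cfg.fc_up and p[i] < cfg.alpha:
            label = "cell_derived"
        elif fc[i] < cfg.fc_down and p[i] < cfg.alpha:
            label = "ecm_enriched"
        else:
            label = "uninformative"
        out.append(FeatureClassification(fid, float(fc[i]), float(p[i]),
                                         label, modes[i]))
    return out


def retained_table(table: FeatureTable,
                   classifications: list[FeatureClassification]
                   ) -> FeatureTable:
    """Subset of `table` holding exactly the cell-derived features."""
    keep = [c.feature_id for c in classifications if c.label == "cell_derived"]
    return subset(table, feature_ids=keep)


# -- model/results surface -------------------------------------------------

class BlankFilterModel:
    """Blank-vs-biological filtering as a fitted model.

    Parameters
    ----------
    table : FeatureTable
        Must contain >=2 biological and >=2 blank samples.
    config : PipelineConfig, optional
        Thresholds; defaults to the proof-of-concept rule
        (mean FC > 1.2, Welch p < 0.05).
    """

    def __init__(self, table: FeatureTable,
                 config: PipelineConfig | None = None):
        self.table = table
        self.config = config or PipelineConfig()

    @classmethod
    def from_csv(cls, matrix_path, sample_sheet_path,
                 config: PipelineConfig | None = None) -> "BlankFilterModel":
        from .feature_table import read_feature_table
        return cls(read_feature_table(matrix_path, sample_sheet_path), config)

    def fit(self, statistic: str | None = None) -> "BlankFilterResults":
        cls = classify_features(self.table, self.config, statistic)
        return BlankFilterResults(self, cls)


class BlankFilterResults:
    """Per-feature classifications plus summary/reporting helpers."""

    def __init__(self, model: BlankFilterModel,
                 classifications: list[FeatureClassification]):
        self.model = model
        self.classifications = classifications

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.feature_id, c.mode, c.fc, c.p_value, c.label)
             for c in self.classifications],
            columns=["feature_id", "mode", "fc", "p_value", "label"],
        ).set_index("feature_id")

    def label_counts(self) -> pd.DataFrame:
        f = self.frame
        return f.groupby("mode")["label"].value_counts().unstack(fill_value=0)

    def retained(self) -> FeatureTable:
        return retained_table(self.model.table, self.classifications)

    def summary(self) -> str:
        from .report import classification_summary
        rows = classification_summary(self.classifications)
        lines = ["Blank filter (fc_up={:.3g}, fc_down={:.3g}, alpha={:.3g})"
                 .format(self.model.config.fc_up, self.model.config.fc_down,
                         self.model.config.alpha),
                 f"{'mode':8s}{'cell':>8s}{'ecm':>8s}{'uninf':>8s}"
                 f"{'untest':>8s}{'total':>8s}{'kept %':>9s}"]
        for s in rows:
            lines.append(f"{s.mode:8s}{s.n_cell_derived:8d}{s.n_ecm_enriched:8d}"
                         f"{s.n_uninformative:8d}{s.n_untestable:8d}"
                         f"{s.n_total:8d}{s.retained_pct:9.1f}")
        return "\n".join(lines)
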