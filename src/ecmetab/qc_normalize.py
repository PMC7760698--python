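"""QC-anchored drift correction and normalization.

Repeated injections of a pooled QC sample track the multiplicative signal
drift of the instrument over a batch. For each feature a LOESS curve
(tricube-weighted local polynomial regression, no robustness iterations)
is fitted to the QC intensities versus injection order; every sample's
value is then divided by the fitted trend at its own injection position,
normalized to the feature's QC median, so a drift-free feature is left
unchanged. Features whose QC CV remains >= 20% after correction are
removed; surviving data are total-sum normalized per sample, and —
for dose-response presentation — scaled to the mean of each experiment's
control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, subset

__all__ = [
    "DriftModel",
    "loess_smooth",
    "loess_correct",
    "qc_cv",
    "qc_cv_filter",
    "sum_normalize",
    "control_scale",
    "preprocess",
]


def loess_smooth(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
                 span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point the ``ceil(span * n)`` nearest observations
    (never fewer than ``degree + 1``) are weighted by
    ``(1 - (d/d_max)^3)^3`` and a degree-``degree`` polynomial is fitted by
    weighted least squares. No robustness iterations are performed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    k = int(np.ceil(span * n))
    k = min(max(k, degree + 1), n)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(len(x_eval))
    for j, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(xs - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[j] = ys[idx].mean()
            continue
        w = (1.0 - np.clip(d[idx] / dmax, 0.0, 1.0) ** 3) ** 3
        # centre x to keep the Vandermonde well conditioned
        X = np.vander(xs[idx] - x0, N=degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[idx] * sw, rcond=None)
        out[j] = beta[0]
    return out


@dataclass
class DriftModel:
    """Per-feature drift trend fitted on QC injections.

    ``fitted`` holds the LOESS trend evaluated at the QC injection orders
    (features x QC positions); ``reference`` is the per-feature QC median
    the trend is normalized against. Features in ``uncorrected`` carry the
    identity correction (too few QCs, or a non-positive fitted value).
    """

    qc_orders: np.ndarray
    fitted: pd.DataFrame
    reference: pd.Series
    span: float
    degree: int
    uncorrected: list[str] = field(default_factory=list)

    def factor(self, feature_id: str, orders: np.ndarray) -> np.ndarray:
        """Correction divisor at arbitrary injection orders.

        Linear interpolation between QC positions, constant extrapolation
        beyond the first/last QC; identity for uncorrected features.
        """
        orders = np.asarray(orders, dtype=float)
        if feature_id in set(self.uncorrected):
            return np.ones_like(orders)
        trend = np.interp(orders, self.qc_orders,
                          self.fitted.loc[feature_id].to_numpy())
        return trend / self.reference.loc[feature_id]


def loess_correct(table: FeatureTable, span: float = 0.75, degree: int = 2,
                  min_qc: int = 5) -> tuple[FeatureTable, DriftModel]:
    """Divide every sample by its feature's QC drift trend.

    Requires injection orders on all samples and at least ``min_qc`` QC
    injections. Features with fewer than ``min_qc`` present QC values, or
    whose fitted trend is non-positive anywhere it is needed, are left
    uncorrected and flagged in the returned :class:`DriftModel`.
    """
    qc_ids = table.sample_ids("qc")
    if table.samples["injection_order"].isna().any():
        raise ValueError("all samples need an injection_order")
    if len(qc_ids) < min_qc:
        raise ValueError(f"need >= {min_qc} QC samples, have {len(qc_ids)}")

    qc_orders = table.samples.loc[qc_ids, "injection_order"].to_numpy(float)
    sort = np.argsort(qc_orders)
    qc_ids = [qc_ids[i] for i in sort]
    qc_orders = qc_orders[sort]
    all_orders = table.samples["injection_order"].to_numpy(float)

    qc_vals = table.abundance[qc_ids].to_numpy(float)
    fitted = np.ones_like(qc_vals)
    reference = np.ones(table.n_features)
    corrected = table.abundance.to_numpy(float).copy()
    uncorrected: list[str] = []

    for i, fid in enumerate(table.features.index):
        y = qc_vals[i]
        ok = np.isfinite(y)
        if ok.sum() < min_qc:
            uncorrected.append(fid)
            continue
        trend = loess_smooth(qc_orders[ok], y[ok], qc_orders, span, degree)
        ref = float(np.median(y[ok]))
        if np.any(trend <= 0) or ref <= 0:
            uncorrected.append(fid)
            continue
        fitted[i] = trend
        reference[i] = ref
        fac = np.interp(all_orders, qc_orders, trend) / ref
        corrected[i] = corrected[i] / fac

    out = table.copy()
    out.abundance = pd.DataFrame(corrected, index=table.abundance.index,
                                 columns=table.abundance.columns)
    out.validate()
    model = DriftModel(
        qc_orders=qc_orders,
        fitted=pd.DataFrame(fitted, index=table.features.index,
                            columns=qc_ids),
        reference=pd.Series(reference, index=table.features.index),
        span=span, degree=degree, uncorrected=uncorrected,
    )
    return out, model


def preprocess(table: FeatureTable, cfg=None
               ) -> tuple[FeatureTable, dict[str, int]]:
    """Full preprocessing chain in the canonical order.

    LOESS drift correction -> QC CV filter -> blank filter (keep the
    cell-derived features) -> total-sum normalization. Returns the
    processed table plus the feature count after each stage, so reports
    can show where features were lost.
    """
    from .blank_filter import classify_features, retained_table
    from .config import PipelineConfig
    cfg = cfg or PipelineConfig()
    counts = {"input": table.n_features}
    table, _ = loess_correct(table, cfg.loess_span, cfg.loess_degree,
                             cfg.min_qc)
    counts["loess"] = table.n_features
    table = qc_cv_filter(table, cfg.qc_cv_max)
    counts["qc_cv_filter"] = table.n_features
    table = retained_table(table, classify_features(table, cfg))
    counts["blank_filter"] = table.n_features
    table = sum_normalize(table)
    counts["sum_normalize"] = table.n_features
    return table, counts


def qc_cv(table: FeatureTable) -> pd.Series:
    """Per-feature CV (sample sd / mean, raw scale) over QC injections."""
    qc_ids = table.sample_ids("qc")
    if len(qc_ids) < 2:
        raise ValueError("need >= 2 QC samples to compute a CV")
    v = table.abundance[qc_ids].to_numpy(float)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(v, axis=1, ddof=1)
        mean = np.nanmean(v, axis=1)
        cv = np.where(mean != 0, sd / mean, np.inf)
    return pd.Series(cv, index=table.features.index, name="qc_cv")


def qc_cv_filter(table: FeatureTable, qc_cv_max: float = 0.20) -> FeatureTable:
    """Remove features whose QC CV is >= ``qc_cv_max`` (boundary removed)."""
    cv = qc_cv(table)
    keep = table.features.index[(cv < qc_cv_max).to_numpy()]
    return subset(table, feature_ids=list(keep))


def sum_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each value by its sample's total peak area.

    After normalization the present values of every sample sum to 1;
    missing values stay missing. A sample with no positive total is an
    error (it carries no usable signal).
    """
    v = table.abundance.to_numpy(float)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        totals = np.nansum(v, axis=0)
    empty = np.all(np.isnan(v), axis=0) | (totals <= 0)
    if np.any(empty):
        bad = list(table.samples.index[empty])
        raise ValueError(f"sample(s) with no positive total: {bad}")
    out = table.copy()
    out.abundance = table.abundance / totals
    out.validate()
    return out


def control_scale(table: FeatureTable, control_dose: float = 0.0
                  ) -> FeatureTable:
    """Scale each feature to its experiment's control-group mean.

    Within every experiment, each feature's values are divided by the mean
    of that feature over the experiment's biological control samples
    (``dose_uM == control_dose``), so the control mean maps to 1. Features
    whose control mean is zero or undefined in some experiment are left
    unscaled there (flagged in ``table.features['control_scale_flagged']``).
    """
    s = table.samples
    out = table.copy()
    v = out.abundance.to_numpy(float)
    flagged = np.zeros(table.n_features, dtype=bool)
    for exp_id, grp in s.groupby("experiment_id", dropna=False):
        ctrl = grp.index[(grp["role"] == "biological")
                         & (grp["dose_uM"] == control_dose)]
        if len(ctrl) == 0:
            raise ValueError(f"experiment {exp_id!r} has no control samples")
        cols = np.isin(out.abundance.columns, grp.index)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ctrl_mean = np.nanmean(
                out.abundance[list(ctrl)].to_numpy(float), axis=1)
        ok = np.isfinite(ctrl_mean) & (ctrl_mean > 0)
        flagged |= ~ok
        v[np.ix_(ok, cols)] = v[np.ix_(ok, cols)] / ctrl_mean[ok, None]
    out.abundance = pd.DataFrame(v, index=table.abundance.index,
                                 columns=table.abundance.columns)
    out.features = out.features.assign(control_scale_flagged=flagged)
    out.validate()
    return out
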