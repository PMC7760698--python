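"""Dose-response screening of preprocessed feature tables.

Features whose abundance tracks the dose of a perturbing drug are found
by Spearman rank correlation against dose (doses are heavily tied: the
default design has 5 replicates at each of 0/1/10/100 uM), with
Benjamini-Hochberg adjustment per analytical mode. A feature counts as a
hit when |r_s| > 0.7 and q < 0.05. Experiments are screened independently
and a feature is reported when it is significant, with a consistent
direction, in at least two of three experiments; a joint analysis pools
all experiments after scaling each to its own control-group mean.

Before testing, implausibly low values (instrument dropouts) are excluded:
within each treatment group a value below 1% of the group median is marked
missing, at most one value (the smallest) per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .feature_table import FeatureTable, subset
from .qc_normalize import control_scale

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseResult",
    "ConsolidatedHit",
    "exclude_low_outliers",
    "spearman_dose",
    "bh_adjust",
    "per_experiment_hits",
    "consolidate_hits",
    "joint_analysis",
    "DoseResponseModel",
    "DoseResponseResults",
]


@dataclass(frozen=True)
class DoseResponseResult:
    feature_id: str
    experiment_id: str          # experiment label or "joint"
    rs: float
    p_raw: float
    q_bh: float
    direction: str              # up | down, from sign(rs)
    significant: bool
    mode: str


@dataclass(frozen=True)
class ConsolidatedHit:
    mean_mass: float
    mean_rt: float
    mode: str
    n_experiments_significant: int
    direction: str
    annotation: str | None
    feature_ids: tuple          # (experiment_id, feature_id) pairs


def exclude_low_outliers(table: FeatureTable, outlier_fraction: float = 0.01
                         ) -> FeatureTable:
    """Mark near-zero biological values missing, at most one per group.

    Treatment groups are (experiment_id, dose_uM) among biological
    samples. Within each group a feature's value is excluded when it is
    below ``outlier_fraction`` of the group median (median computed over
    all present values, the candidate included); when several values
    qualify only the smallest is excluded.
    """
    out = table.copy()
    v = out.abundance.to_numpy(float)
    s = table.samples
    bio = s[s["role"] == "biological"]
    col_pos = {sid: j for j, sid in enumerate(table.abundance.columns)}
    for (_, _), grp in bio.groupby(["experiment_id", "dose_uM"], dropna=False):
        cols = [col_pos[sid] for sid in grp.index]
        if len(cols) < 2:
            continue  # a single value is its own median; nothing to exclude
        block = v[:, cols]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(block, axis=1)
            low = block < (outlier_fraction * med)[:, None]
        rows = np.flatnonzero(np.any(low, axis=1))
        for i in rows:
            cand = np.flatnonzero(low[i])
            worst = cand[np.argmin(block[i, cand])]
            v[i, cols[worst]] = np.nan
    out.abundance = pd.DataFrame(v, index=table.abundance.index,
                                 columns=table.abundance.columns)
    out.validate()
    return out


def spearman_dose(feature_values, doses) -> tuple[float, float]:
    """Spearman correlation (average-rank ties) of one feature vs dose.

    Computed as the Pearson correlation of midranks; the two-sided p-value
    uses the t approximation with n-2 degrees of freedom (|r_s| = 1 gives
    p = 0). Requires >= 3 non-missing pairs and >= 2 distinct doses;
    returns (nan, nan) for constant values.
    """
    v = np.asarray(feature_values, dtype=float)
    d = np.asarray(doses, dtype=float)
    ok = np.isfinite(v) & np.isfinite(d)
    v, d = v[ok], d[ok]
    n = len(v)
    if n < 3:
        raise ValueError("need >= 3 non-missing (value, dose) pairs")
    if len(np.unique(d)) < 2:
        raise ValueError("need >= 2 distinct doses")
    if np.all(v == v[0]):
        return float("nan"), float("nan")
    rv = stats.rankdata(v)
    rd = stats.rankdata(d)
    rv = rv - rv.mean()
    rd = rd - rd.mean()
    rs = float(rv @ rd / np.sqrt((rv @ rv) * (rd @ rd)))
    rs = max(-1.0, min(1.0, rs))
    if abs(rs) == 1.0:
        return rs, 0.0
    t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rs, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _screen_table(table: FeatureTable, cfg: PipelineConfig,
                  experiment_label: str) -> list[DoseResponseResult]:
    """Spearman + BH on the biological samples of one (pooled) table."""
    bio = subset(table, sample_predicate=lambda r: r["role"] == "biological")
    doses = bio.samples["dose_uM"].to_numpy(float)
    if len(np.unique(doses[np.isfinite(doses)])) < 2:
        raise ValueError(f"{experiment_label}: fewer than 2 dose levels")
    v = bio.abundance.to_numpy(float)
    modes = bio.features["mode"].to_numpy()
    fids = list(bio.features.index)

    rs = np.full(len(fids), np.nan)
    p = np.full(len(fids), np.nan)
    for i in range(len(fids)):
        ok = np.isfinite(v[i])
        if ok.sum() < 3 or len(np.unique(doses[ok])) < 2:
            continue
        try:
            rs[i], p[i] = spearman_dose(v[i], doses)
        except ValueError:
            continue

    q = np.full(len(fids), np.nan)
    families = ([np.flatnonzero(modes == m) for m in pd.unique(modes)]
                if cfg.bh_per_mode else [np.arange(len(fids))])
    for fam in families:
        testable = fam[np.isfinite(p[fam])]
        if len(testable):
            q[testable] = bh_adjust(p[testable])

    out = []
    for i, fid in enumerate(fids):
        if not np.isfinite(rs[i]):
            continue
        sig = bool(abs(rs[i]) > cfg.rs_min and q[i] < cfg.q_max)
        out.append(DoseResponseResult(
            fid, experiment_label, float(rs[i]), float(p[i]), float(q[i]),
            "up" if rs[i] > 0 else "down", sig, modes[i]))
    return out


def per_experiment_hits(tables: list[FeatureTable],
                        cfg: PipelineConfig | None = None
                        ) -> list[DoseResponseResult]:
    """Screen each preprocessed experiment table independently.

    Applies the low-value outlier exclusion, then per-feature Spearman vs
    dose and BH adjustment per analytical mode within each experiment.
    Tables are expected to be drift-corrected, QC-CV filtered, blank
    filtered and sum normalized.
    """
    cfg = cfg or PipelineConfig()
    results: list[DoseResponseResult] = []
    for table in tables:
        exp_ids = table.samples["experiment_id"].dropna().unique()
        label = str(exp_ids[0]) if len(exp_ids) else "E?"
        try:
            cleaned = exclude_low_outliers(table, cfg.outlier_fraction)
            results.extend(_screen_table(cleaned, cfg, label))
        except ValueError as err:
            logger.warning("skipping experiment %s: %s", label, err)
    return results


def consolidate_hits(per_experiment: list[DoseResponseResult],
                     tables: list[FeatureTable],
                     cfg: PipelineConfig | None = None
                     ) -> list[ConsolidatedHit]:
    """Merge per-experiment hits into cross-experiment consolidated hits.

    Significant features are matched across experiments by mass within
    ``mass_tol_ppm`` and RT within ``rt_tol_match`` (nearest mass wins on
    ambiguity); a consolidated hit requires a consistent direction in at
    least ``min_experiments`` experiments. Representative mass/RT are
    means over the matched features.
    """
    cfg = cfg or PipelineConfig()
    meta = {}
    for t in tables:
        exp_ids = t.samples["experiment_id"].dropna().unique()
        label = str(exp_ids[0]) if len(exp_ids) else "E?"
        meta[label] = t.features
    sig = [r for r in per_experiment if r.significant]

    groups: list[dict] = []
    for r in sig:
        if r.experiment_id not in meta or r.feature_id not in meta[r.experiment_id].index:
            continue
        row = meta[r.experiment_id].loc[r.feature_id]
        mass, rt = float(row["neutral_mass"]), float(row["rt"])
        best, best_dm = None, None
        for g in groups:
            if g["mode"] != r.mode or g["direction"] != r.direction:
                continue
            if r.experiment_id in g["experiments"]:
                continue
            gm = np.mean(g["masses"])
            dm_ppm = abs(mass - gm) / gm * 1e6
            if dm_ppm <= cfg.mass_tol_ppm and abs(rt - np.mean(g["rts"])) <= cfg.rt_tol_match:
                if best is None or dm_ppm < best_dm:
                    best, best_dm = g, dm_ppm
        if best is None:
            conflict = any(
                g["mode"] == r.mode and g["direction"] != r.direction
                and abs(mass - np.mean(g["masses"])) / np.mean(g["masses"]) * 1e6
                <= cfg.mass_tol_ppm
                and abs(rt - np.mean(g["rts"])) <= cfg.rt_tol_match
                for g in groups)
            if conflict:
                logger.info("direction conflict for %s %s at %.4f Da",
                            r.experiment_id, r.feature_id, mass)
            groups.append({
                "mode": r.mode, "direction": r.direction,
                "masses": [mass], "rts": [rt],
                "experiments": {r.experiment_id},
                "members": [(r.experiment_id, r.feature_id)],
                "annotation": meta[r.experiment_id].loc[r.feature_id,
                                                        "annotation"],
            })
        else:
            best["masses"].append(mass)
            best["rts"].append(rt)
            best["experiments"].add(r.experiment_id)
            best["members"].append((r.experiment_id, r.feature_id))
            if best["annotation"] is None:
                best["annotation"] = meta[r.experiment_id].loc[
                    r.feature_id, "annotation"]

    hits = []
    for g in groups:
        if len(g["experiments"]) >= cfg.min_experiments:
            ann = g["annotation"]
            if ann is not None and (isinstance(ann, float) and np.isnan(ann)):
                ann = None
            hits.append(ConsolidatedHit(
                mean_mass=float(np.mean(g["masses"])),
                mean_rt=float(np.mean(g["rts"])),
                mode=g["mode"],
                n_experiments_significant=len(g["experiments"]),
                direction=g["direction"],
                annotation=ann,
                feature_ids=tuple(g["members"]),
            ))
    hits.sort(key=lambda h: (h.mode, h.mean_mass))
    return hits


def joint_analysis(tables: list[FeatureTable],
                   cfg: PipelineConfig | None = None,
                   control_dose: float = 0.0) -> list[DoseResponseResult]:
    """Pooled screen over all experiments on control-scaled data.

    Each experiment's table is scaled to its control-group mean, the
    biological samples are pooled over the shared features (feature ids
    are assumed stable across the experiments of one batch), and the
    Spearman + BH screen is run once on the pooled values.
    """
    cfg = cfg or PipelineConfig()
    scaled = []
    for t in tables:
        t = exclude_low_outliers(t, cfg.outlier_fraction)
        scaled.append(control_scale(t, control_dose))
    common = scaled[0].features.index
    for t in scaled[1:]:
        common = common.intersection(t.features.index)
    if len(common) == 0:
        raise ValueError("experiments share no features")
    bio_parts, sample_frames = [], []
    for t in scaled:
        bio = subset(t, sample_predicate=lambda r: r["role"] == "biological",
                     feature_ids=list(common))
        bio_parts.append(bio.abundance)
        sample_frames.append(bio.samples)
    pooled = FeatureTable(
        scaled[0].features.loc[common].drop(
            columns=["control_scale_flagged"], errors="ignore"),
        pd.concat(sample_frames),
        pd.concat(bio_parts, axis=1),
    )
    return _screen_table(pooled, cfg, "joint")


# -- model/results surface -------------------------------------------------

class DoseResponseModel:
    """Dose-response screen over one or more preprocessed experiments.

    Parameters
    ----------
    tables : list of FeatureTable
        One preprocessed (drift-corrected, filtered, sum-normalized) table
        per independent experiment.
    config : PipelineConfig, optional
    """

    def __init__(self, tables: list[FeatureTable],
                 config: PipelineConfig | None = None):
        if not tables:
            raise ValueError("need at least one experiment table")
        self.tables = list(tables)
        self.config = config or PipelineConfig()

    def fit(self, joint: bool = True) -> "DoseResponseResults":
        per_exp = per_experiment_hits(self.tables, self.config)
        hits = consolidate_hits(per_exp, self.tables, self.config)
        joint_res = (joint_analysis(self.tables, self.config)
                     if joint else [])
        return DoseResponseResults(self, per_exp, hits, joint_res)


class DoseResponseResults:
    """Estimates and hit lists from a fitted dose-response screen."""

    def __init__(self, model: DoseResponseModel,
                 per_experiment: list[DoseResponseResult],
                 hits: list[ConsolidatedHit],
                 joint: list[DoseResponseResult]):
        self.model = model
        self.per_experiment = per_experiment
        self.hits = hits
        self.joint = joint

    @staticmethod
    def _frame(results: list[DoseResponseResult]) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.feature_id, r.experiment_id, r.mode, r.rs, r.p_raw, r.q_bh,
              r.direction, r.significant) for r in results],
            columns=["feature_id", "experiment_id", "mode", "rs", "p_raw",
                     "q_bh", "direction", "significant"])

    @property
    def per_experiment_frame(self) -> pd.DataFrame:
        return self._frame(self.per_experiment)

    @property
    def joint_frame(self) -> pd.DataFrame:
        return self._frame(self.joint)

    @property
    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.mode, h.mean_mass, h.mean_rt, h.direction,
              h.n_experiments_significant, h.annotation) for h in self.hits],
            columns=["mode", "mean_mass", "rt", "regulation",
                     "n_experiments", "annotation"])

    def summary(self) -> str:
        cfg = self.model.config
        n_sig = sum(r.significant for r in self.per_experiment)
        n_joint = sum(r.significant for r in self.joint)
        lines = [
            f"Dose-response screen (|rs| > {cfg.rs_min:g}, q < {cfg.q_max:g})",
            f"  experiments screened : {len(self.model.tables)}",
            f"  per-experiment hits  : {n_sig}",
            f"  consolidated (>= {cfg.min_experiments} experiments) : "
            f"{len(self.hits)}",
            f"  joint-analysis hits  : {n_joint}",
        ]
        if self.hits:
            lines.append(f"  {'mode':8s}{'mass':>10s}{'rt':>7s}"
                         f"{'dir':>5s}{'n':>3s}  annotation")
            for h in self.hits:
                arrow = "up" if h.direction == "up" else "down"
                lines.append(
                    f"  {h.mode:8s}{h.mean_mass:10.4f}{h.mean_rt:7.2f}"
                    f"{arrow:>5s}{h.n_experiments_significant:3d}  "
                    f"{h.annotation or 'na'}")
        return "\n".join(lines)
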