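"""Synthetic LC-MS feature tables with known ground truth.

The generator emulates the statistical structure of an organoid profiling
study: a small number of biological replicates embedded in a protein
matrix, ECM-blank samples sharing most features with the biological ones,
pooled-QC injections interleaved through the batch and subject to smooth
multiplicative instrument drift, log-normal replicate noise with CVs in
the 7-35% range, and a small planted set of features that respond
monotonically to the dose of a perturbing drug.

Every draw is taken from one seeded :class:`numpy.random.Generator`, so a
fixed seed fixes the full output bit for bit.

Noise model
-----------
Peak areas are positive and right-skewed, so replicate noise is
multiplicative log-normal: a value with target mean ``m`` and coefficient
of variation ``c`` is drawn as ``m * exp(z * s - s^2/2)`` with
``s = sqrt(log(1 + c^2))`` and ``z`` standard normal, which gives exactly
``E[X] = m`` and ``CV[X] = c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, MODES

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "generate_blank_experiment",
    "generate_dose_experiment",
]


@dataclass
class SimulationDesign:
    """Parameters of a simulated acquisition.

    The class fractions, replicate counts and dose ladder default to the
    study design the pipeline targets: 5 biological replicates vs 3 ECM
    blanks, doses 0/1/10/100 uM with 5 replicates each in 3 independent
    experiments, and per-feature replicate CVs drawn from 7-35%.
    """

    n_features: int = 1000
    frac_cell_derived: float = 0.2
    frac_ecm_enriched: float = 0.1
    n_bio: int = 5
    n_blank: int = 3
    n_qc: int = 0                     # extra QCs for the blank experiment
    doses: tuple = (0.0, 1.0, 10.0, 100.0)
    n_experiments: int = 3
    replicate_cv: float | tuple = (0.07, 0.35)
    qc_cv: float = 0.08               # QC injection repeatability
    drift_amplitude: float = 0.0      # fractional change across the batch
    drift_shape: str = "linear_sine"  # or "linear"
    qc_every: int = 5                 # one QC per this many injections
    frac_dose_responsive: float = 0.0
    dose_effect: tuple = (1.0, 1.3, 1.8, 2.5)  # per-dose factors, planted up
    dropout_rate: float = 0.0         # P(near-zero value) per bio cell
    fc_up: float = 1.2
    fc_down: float = 0.8
    separation_margin: float = 1.25   # planted classes sit this far past cut-offs
    mode: str = "HILIC+"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_cell_derived <= 1
                and 0 <= self.frac_ecm_enriched <= 1
                and self.frac_cell_derived + self.frac_ecm_enriched <= 1):
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if list(self.doses) != sorted(self.doses):
            raise ValueError("doses must be sorted ascending")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.dose_effect) != len(self.doses):
            raise ValueError("dose_effect must give one factor per dose")
        if self.drift_shape not in ("linear", "linear_sine"):
            raise ValueError(f"unknown drift_shape {self.drift_shape!r}")

    def cv_draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if np.isscalar(self.replicate_cv):
            return np.full(n, float(self.replicate_cv))
        lo, hi = self.replicate_cv
        return rng.uniform(lo, hi, n)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    true_class: pd.Series            # feature_id -> cell_derived/ecm_enriched/background
    dose_direction: pd.Series        # feature_id -> up/down/none
    bio_blank_ratio: pd.Series       # expected biological/blank mean ratio
    drift: pd.DataFrame = field(default_factory=pd.DataFrame)  # injection_order, factor


def _lognormal_sigma(cv: np.ndarray | float) -> np.ndarray | float:
    return np.sqrt(np.log1p(np.square(cv)))


def _noisy(rng: np.random.Generator, mean, cv):
    """Log-normal draw with exact mean `mean` and CV `cv` (elementwise)."""
    s = _lognormal_sigma(np.asarray(cv, dtype=float))
    z = rng.standard_normal(np.shape(mean))
    return np.asarray(mean) * np.exp(z * s - 0.5 * s * s)


def _feature_frame(rng: np.random.Generator, n: int, mode: str,
                   prefix: str = "F") -> pd.DataFrame:
    ids = [f"{prefix}{i:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "neutral_mass": rng.uniform(80.0, 900.0, n),
            "rt": rng.uniform(0.5, 15.0, n),
            "mode": mode,
            "annotation": None,
            "msi_level": np.nan,
        },
        index=pd.Index(ids, name="feature_id"),
    )


def _assign_classes(rng: np.random.Generator, design: SimulationDesign):
    """Per-feature class labels and expected biological/blank mean ratios.

    Planted ratios sit at least `separation_margin` beyond the fold-change
    cut-offs, then extend upward by up to 1.5 log2 units — cell-derived
    metabolites are frequently near-absent from blanks, so ratios of
    1.5-4x are on the conservative side of realistic.
    """
    n = design.n_features
    n_cell = int(round(design.frac_cell_derived * n))
    n_ecm = int(round(design.frac_ecm_enriched * n))
    labels = np.array(["background"] * n, dtype=object)
    idx = rng.permutation(n)
    labels[idx[:n_cell]] = "cell_derived"
    labels[idx[n_cell:n_cell + n_ecm]] = "ecm_enriched"

    ratio = np.ones(n)
    up_floor = np.log2(design.fc_up * design.separation_margin)
    dn_floor = np.log2(design.separation_margin / design.fc_down)
    is_cell = labels == "cell_derived"
    is_ecm = labels == "ecm_enriched"
    ratio[is_cell] = 2.0 ** (up_floor + rng.uniform(0.0, 1.5, is_cell.sum()))
    ratio[is_ecm] = 2.0 ** -(dn_floor + rng.uniform(0.0, 1.5, is_ecm.sum()))
    return labels, ratio


def generate_blank_experiment(design: SimulationDesign
                              ) -> tuple[FeatureTable, GroundTruth]:
    """Simulate one biological-vs-ECM-blank acquisition.

    Cell-derived features are planted with expected biological/blank mean
    ratios past ``fc_up * separation_margin``, ECM-enriched features below
    ``fc_down / separation_margin``, background features at ratio 1; all
    values carry log-normal replicate noise at the design CV.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_features
    fdf = _feature_frame(rng, n, design.mode)
    labels, ratio = _assign_classes(rng, design)

    blank_mean = 10.0 ** rng.uniform(4.0, 7.0, n)
    bio_mean = blank_mean * ratio
    cv = design.cv_draw(rng, n)

    sample_ids, roles = [], []
    cols = []
    for i in range(design.n_bio):
        sample_ids.append(f"BIO{i + 1}")
        roles.append("biological")
        cols.append(_noisy(rng, bio_mean, cv))
    for i in range(design.n_blank):
        sample_ids.append(f"BLK{i + 1}")
        roles.append("blank")
        cols.append(_noisy(rng, blank_mean, cv))
    qc_mean = (bio_mean * design.n_bio + blank_mean * design.n_blank) / (
        design.n_bio + design.n_blank)
    for i in range(design.n_qc):
        sample_ids.append(f"QC{i + 1}")
        roles.append("qc")
        cols.append(_noisy(rng, qc_mean, design.qc_cv))

    order = rng.permutation(len(sample_ids)) + 1
    sdf = pd.DataFrame(
        {
            "role": roles,
            "dose_uM": [np.nan] * len(sample_ids),
            "experiment_id": "E1",
            "injection_order": order,
            "protocol": None,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ab = pd.DataFrame(np.column_stack(cols), index=fdf.index, columns=sdf.index)
    table = FeatureTable(fdf, sdf, ab)
    truth = GroundTruth(
        true_class=pd.Series(labels, index=fdf.index, name="true_class"),
        dose_direction=pd.Series("none", index=fdf.index, name="dose_direction"),
        bio_blank_ratio=pd.Series(ratio, index=fdf.index, name="bio_blank_ratio"),
    )
    return table, truth


def _drift_factor(design: SimulationDesign, order: np.ndarray,
                  n_inj: int) -> np.ndarray:
    """Multiplicative drift at each injection position, mean ~1 over the batch."""
    if design.drift_amplitude == 0:
        return np.ones_like(order, dtype=float)
    x = (order - 1) / max(n_inj - 1, 1)  # 0..1 across the batch
    g = 1.0 + design.drift_amplitude * (x - 0.5)
    if design.drift_shape == "linear_sine":
        g = g + 0.1 * design.drift_amplitude * np.sin(2.0 * np.pi * x)
    return g


def generate_dose_experiment(design: SimulationDesign
                             ) -> tuple[list[FeatureTable], GroundTruth]:
    """Simulate a multi-experiment dose-response study.

    Each experiment contains ``n_bio`` biological replicates per dose,
    ``n_blank`` ECM blanks and interleaved pooled-QC injections. A planted
    fraction of features responds monotonically to dose via the
    ``dose_effect`` factors (half up, half mirrored down); QC samples are
    noisy copies of the all-sample mean; every injection is scaled by the
    drift function at its position; dropouts replace a biological value by
    a near-zero one at ``dropout_rate``.

    Feature identifiers are shared across experiments, but each
    experiment's exported masses and retention times carry small
    measurement jitter (within a few ppm / hundredths of a minute).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_features
    true_mass = rng.uniform(80.0, 900.0, n)
    true_rt = rng.uniform(0.5, 15.0, n)
    ids = pd.Index([f"F{i:05d}" for i in range(n)], name="feature_id")

    labels, ratio = _assign_classes(rng, design)
    blank_mean = 10.0 ** rng.uniform(4.0, 7.0, n)
    bio_base = blank_mean * ratio

    # planted dose response, half up / half down, on cell-derived features
    # where possible so the hits survive the blank filter
    direction = np.array(["none"] * n, dtype=object)
    n_resp = int(round(design.frac_dose_responsive * n))
    cell_idx = np.flatnonzero(labels == "cell_derived")
    pool = cell_idx if len(cell_idx) >= n_resp else np.arange(n)
    resp = rng.choice(pool, size=n_resp, replace=False)
    direction[resp[: (n_resp + 1) // 2]] = "up"
    direction[resp[(n_resp + 1) // 2:]] = "down"
    effect = np.asarray(design.dose_effect, dtype=float)

    cv = design.cv_draw(rng, n)
    n_bio_total = design.n_bio * len(design.doses)

    tables: list[FeatureTable] = []
    drift_rows = []
    for e in range(design.n_experiments):
        exp_id = f"E{e + 1}"
        # batch effect: each experiment re-extracts and re-acquires
        exp_scale = 2.0 ** rng.normal(0.0, 0.25)
        fdf = pd.DataFrame(
            {
                "neutral_mass": true_mass * (1.0 + rng.normal(0.0, 3e-6, n)),
                "rt": true_rt + rng.normal(0.0, 0.02, n),
                "mode": design.mode,
                "annotation": None,
                "msi_level": np.nan,
            },
            index=ids,
        )

        sample_ids, roles, doses_col = [], [], []
        means = []
        for d_i, dose in enumerate(design.doses):
            for r in range(design.n_bio):
                sample_ids.append(f"{exp_id}_D{d_i}_R{r + 1}")
                roles.append("biological")
                doses_col.append(dose)
                m = bio_base * exp_scale
                fac = np.where(direction == "up", effect[d_i],
                               np.where(direction == "down", 1.0 / effect[d_i], 1.0))
                means.append(m * fac)
        for b in range(design.n_blank):
            sample_ids.append(f"{exp_id}_BLK{b + 1}")
            roles.append("blank")
            doses_col.append(np.nan)
            means.append(blank_mean * exp_scale)

        # injection sequence: randomized study samples, QC every qc_every
        n_study = len(sample_ids)
        study_perm = rng.permutation(n_study)
        seq: list[int | None] = []  # None marks a QC injection
        seq.append(None)
        for k, s in enumerate(study_perm):
            seq.append(s)
            if (k + 1) % design.qc_every == 0 and k + 1 < n_study:
                seq.append(None)
        seq.append(None)
        n_inj = len(seq)

        qc_mean = np.mean(np.column_stack(means), axis=1)
        orders = np.zeros(n_study, dtype=int)
        qc_cols, qc_ids, qc_orders = [], [], []
        g_all = _drift_factor(design, np.arange(1, n_inj + 1, dtype=float), n_inj)
        for pos, s in enumerate(seq, start=1):
            if s is None:
                qc_ids.append(f"{exp_id}_QC{len(qc_ids) + 1}")
                qc_orders.append(pos)
                qc_cols.append(_noisy(rng, qc_mean * g_all[pos - 1], design.qc_cv))
            else:
                orders[s] = pos

        cols = []
        for s in range(n_study):
            g = g_all[orders[s] - 1]
            cols.append(_noisy(rng, means[s] * g, cv))
        # dropouts: near-zero values in biological samples
        if design.dropout_rate > 0:
            for s in range(n_study):
                if roles[s] != "biological":
                    continue
                hit = rng.random(n) < design.dropout_rate
                cols[s] = np.where(hit, cols[s] * 1e-3, cols[s])

        all_ids = sample_ids + qc_ids
        sdf = pd.DataFrame(
            {
                "role": roles + ["qc"] * len(qc_ids),
                "dose_uM": doses_col + [np.nan] * len(qc_ids),
                "experiment_id": exp_id,
                "injection_order": list(orders) + qc_orders,
                "protocol": None,
            },
            index=pd.Index(all_ids, name="sample_id"),
        )
        ab = pd.DataFrame(np.column_stack(cols + qc_cols),
                          index=ids, columns=sdf.index)
        tables.append(FeatureTable(fdf, sdf, ab))
        drift_rows.append(pd.DataFrame({
            "experiment_id": exp_id,
            "injection_order": np.arange(1, n_inj + 1),
            "factor": g_all,
        }))

    truth = GroundTruth(
        true_class=pd.Series(labels, index=ids, name="true_class"),
        dose_direction=pd.Series(direction, index=ids, name="dose_direction"),
        bio_blank_ratio=pd.Series(ratio, index=ids, name="bio_blank_ratio"),
        drift=pd.concat(drift_rows, ignore_index=True),
    )
    return tables, truth
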