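"""Tolerance-based feature annotation against reference compounds.

A feature is matched to a reference compound by accurate mass (+/-15 ppm)
and, when available, retention time (+/-0.2 min; +/-0.7 min for targeted
extraction windows). Each candidate match carries a weighted composite
score built from up to four components — mass, isotope abundance, isotope
spacing and RT, weighted 100/60/50/20 — where each component score ramps
linearly from 100 at zero error to 0 at its tolerance:

    s_i = 100 * max(0, 1 - |error_i| / tol_i)
    composite = sum(w_i * s_i) / sum(w_i)   over available components

A match is accepted when at least two of {mass within tolerance, RT within
tolerance, composite > 70%} hold. Identification confidence is tracked as
an MSI level (1 = confirmed against an authentic standard by RT and MS/MS,
2 = putative spectral-database match); levels are bookkeeping derived from
the evidence type, never computed from spectra here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics.mass import calculate_mass

from .config import PipelineConfig
from .feature_table import FeatureTable

__all__ = [
    "ReferenceCompound",
    "MatchResult",
    "ppm_error",
    "monoisotopic_mass",
    "composite_score",
    "targeted_match",
    "read_reference_list",
]

#: evidence type -> MSI confidence level
MSI_FROM_EVIDENCE = {"standard_rt_msms": 1, "spectral_db_match": 2}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_KNOWN_ELEMENTS = {"C", "H", "N", "O", "P", "S", "Na", "K", "Cl", "F", "Br", "I"}


@dataclass(frozen=True)
class ReferenceCompound:
    name: str
    monoisotopic_mass: float            # Da, neutral
    formula: str | None = None
    expected_rt: float | None = None    # minutes
    msi_evidence: str | None = None     # key of MSI_FROM_EVIDENCE

    def __post_init__(self) -> None:
        if not self.monoisotopic_mass > 0:
            raise ValueError(f"{self.name}: monoisotopic_mass must be > 0")
        if self.formula:
            calc = monoisotopic_mass(self.formula)
            if abs(calc - self.monoisotopic_mass) > 1e-3:
                raise ValueError(
                    f"{self.name}: formula mass {calc:.4f} differs from "
                    f"stated mass {self.monoisotopic_mass:.4f} by > 1 mDa")
        if self.msi_evidence is not None and \
                self.msi_evidence not in MSI_FROM_EVIDENCE:
            raise ValueError(f"{self.name}: unknown evidence "
                             f"{self.msi_evidence!r}")

    @property
    def msi_level(self) -> int | None:
        if self.msi_evidence is None:
            return None
        return MSI_FROM_EVIDENCE[self.msi_evidence]

    @classmethod
    def from_formula(cls, name: str, formula: str, **kw) -> "ReferenceCompound":
        return cls(name, monoisotopic_mass(formula), formula=formula, **kw)


@dataclass(frozen=True)
class MatchResult:
    feature_id: str
    compound: str
    ppm_error: float
    rt_error: float | None
    component_scores: dict          # name -> score in [0, 100]
    composite: float                # [0, 100]
    criteria_met: int
    accepted: bool
    msi_level: int | None = None


def ppm_error(observed_mass: float, theoretical_mass: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mass <= 0:
        raise ValueError("theoretical_mass must be > 0")
    return 1e6 * (observed_mass - theoretical_mass) / theoretical_mass


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of an elemental formula.

    Accepts Hill-style formulas like ``"C9H12N2O5"``; an empty formula
    has mass 0.
    """
    if not formula:
        return 0.0
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if m.group(1) not in _KNOWN_ELEMENTS:
            raise ValueError(f"unknown element {m.group(1)!r} in {formula!r}")
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return float(calculate_mass(formula=formula))


def _ramp(err: float, tol: float) -> float:
    return 100.0 * max(0.0, 1.0 - abs(err) / tol)


def composite_score(observed_mass: float, ref: ReferenceCompound,
                    cfg: PipelineConfig | None = None,
                    observed_rt: float | None = None,
                    isotope_abundance_dev: float | None = None,
                    isotope_spacing_dev_mda: float | None = None,
                    feature_id: str = "") -> MatchResult:
    """Score one feature against one reference compound.

    ``isotope_abundance_dev`` is the mean relative deviation of the
    observed isotope-envelope intensities from theory (fraction);
    ``isotope_spacing_dev_mda`` the mean isotope-spacing deviation in mDa.
    Both are optional, as is the RT; the composite is the weight-normalized
    mean over the components actually available.
    """
    cfg = cfg or PipelineConfig()
    w = cfg.score_weights
    ppm = ppm_error(observed_mass, ref.monoisotopic_mass)
    scores = {"mass": _ramp(ppm, cfg.mass_tol_ppm)}
    weights = {"mass": w.mass}
    rt_err = None
    if observed_rt is not None and ref.expected_rt is not None:
        rt_err = observed_rt - ref.expected_rt
        scores["rt"] = _ramp(rt_err, cfg.rt_tol_match)
        weights["rt"] = w.rt
    if isotope_abundance_dev is not None:
        scores["isotope_abundance"] = _ramp(isotope_abundance_dev,
                                            cfg.isotope_abundance_tol)
        weights["isotope_abundance"] = w.isotope_abundance
    if isotope_spacing_dev_mda is not None:
        scores["isotope_spacing"] = _ramp(isotope_spacing_dev_mda,
                                          cfg.isotope_spacing_tol_mda)
        weights["isotope_spacing"] = w.isotope_spacing
    total_w = sum(weights.values())
    composite = sum(weights[k] * scores[k] for k in scores) / total_w

    mass_ok = abs(ppm) <= cfg.mass_tol_ppm
    rt_ok = rt_err is not None and abs(rt_err) <= cfg.rt_tol_match
    score_ok = composite > cfg.score_min
    criteria_met = int(mass_ok) + int(rt_ok) + int(score_ok)
    if cfg.annotation_rule == "two_of_three":
        accepted = criteria_met >= 2
    else:  # score_and_two: the score must pass and two criteria overall
        accepted = score_ok and criteria_met >= 2
    return MatchResult(feature_id, ref.name, float(ppm),
                       None if rt_err is None else float(rt_err),
                       scores, float(composite), criteria_met, accepted,
                       ref.msi_level)


def targeted_match(table: FeatureTable, refs: list[ReferenceCompound],
                   rt_window: float | None = None,
                   cfg: PipelineConfig | None = None) -> list[MatchResult]:
    """Match each reference compound to its best feature in the table.

    For every reference, candidate features lie within the ppm tolerance
    and (when both RTs are known) within ``rt_window`` minutes (default:
    the targeted-extraction window of 0.7 min); the candidate with the
    smallest |ppm| wins, ties broken by smaller RT error. At most one
    match per reference; references without a candidate are omitted.
    """
    cfg = cfg or PipelineConfig()
    if rt_window is None:
        rt_window = cfg.rt_tol_targeted
    if not refs:
        raise ValueError("reference list is empty")
    masses = table.features["neutral_mass"].to_numpy(float)
    rts = table.features["rt"].to_numpy(float)
    fids = list(table.features.index)
    out: list[MatchResult] = []
    for ref in refs:
        ppm = 1e6 * (masses - ref.monoisotopic_mass) / ref.monoisotopic_mass
        cand = np.abs(ppm) <= cfg.mass_tol_ppm
        if ref.expected_rt is not None:
            cand &= np.abs(rts - ref.expected_rt) <= rt_window
        idx = np.flatnonzero(cand)
        if len(idx) == 0:
            continue
        rt_err = (np.abs(rts[idx] - ref.expected_rt)
                  if ref.expected_rt is not None else np.zeros(len(idx)))
        best = idx[np.lexsort((rt_err, np.round(np.abs(ppm[idx]), 9)))][0]
        out.append(composite_score(
            masses[best], ref, cfg,
            observed_rt=rts[best] if ref.expected_rt is not None else None,
            feature_id=fids[best]))
    return out


def read_reference_list(path: str | Path) -> list[ReferenceCompound]:
    """Load reference compounds from CSV.

    Columns: ``name, formula, monoisotopic_mass, expected_rt,
    msi_evidence``; ``monoisotopic_mass`` may be blank when a formula is
    given.
    """
    df = pd.read_csv(path)
    refs = []
    for _, row in df.iterrows():
        formula = row.get("formula")
        formula = None if pd.isna(formula) else str(formula)
        mass = row.get("monoisotopic_mass")
        if pd.isna(mass):
            if not formula:
                raise ValueError(f"{row['name']}: need a mass or a formula")
            mass = monoisotopic_mass(formula)
        rt = row.get("expected_rt")
        ev = row.get("msi_evidence")
        refs.append(ReferenceCompound(
            name=str(row["name"]), monoisotopic_mass=float(mass),
            formula=formula,
            expected_rt=None if pd.isna(rt) else float(rt),
            msi_evidence=None if pd.isna(ev) else str(ev)))
    return refs
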