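"""The four TEP output measures, per subject and hotspot.

* EPD — least-squares slope of the single-pulse TEP over 60-100 ms (µV/ms).
* LPD — least-squares slope over 100-180 ms (µV/ms).
* WFA — waveform adherence: Pearson correlation between the subject's
  single-pulse TEP and a normative healthy template over 20-300 ms.
* STP — short-term plasticity index
  ``(MFP_single - MFP_i) / (MFP_single + MFP_i)`` where MFP is the mean
  rectified amplitude of the 20-300 ms window for the single-pulse and
  inhibitory-protocol TEPs respectively.

Operationalisation choices (the source definitions are verbal): WFA is a
Pearson correlation (scale/offset invariant; cosine similarity available
via ``metric=``), MFP is mean |amplitude| (a global-field-power variant
across electrodes would be incompatible with per-hotspot STP), and slopes
are signed.  Undefined values (zero variance, both MFPs zero) are returned
as NaN — flagged missing, never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import HotspotTEPSet, PROXIMAL_HOTSPOTS

__all__ = [
    "MEASURES",
    "LeakageError",
    "NormativeTemplate",
    "compute_slope",
    "compute_wfa",
    "compute_mfp",
    "compute_stp",
    "build_template",
    "compute_feature_table",
    "build_feature_vector",
]

MEASURES = ("epd", "lpd", "wfa", "stp")

EPD_WINDOW_MS = (60.0, 100.0)
LPD_WINDOW_MS = (100.0, 180.0)

MIN_TEMPLATE_SUBJECTS = 5


class LeakageError(RuntimeError):
    """Raised when template reference subjects overlap an evaluation set."""


@dataclass
class NormativeTemplate:
    """Mean healthy TEP per hotspot on the 20-300 ms grid."""

    hotspots: list[str]
    times: np.ndarray
    data: np.ndarray  # (n_hotspots, n_times)
    reference_ids: tuple[str, ...]
    age_band: str = "adult"

    def waveform(self, hotspot: str) -> np.ndarray:
        return self.data[self.hotspots.index(hotspot)]

    def assert_disjoint(self, subject_ids) -> None:
        overlap = set(self.reference_ids) & set(subject_ids)
        if overlap:
            raise LeakageError(
                "template reference subjects appear in the evaluation set: "
                f"{sorted(overlap)}")


def compute_slope(amplitude: np.ndarray, times_ms: np.ndarray,
                  t0: float, t1: float) -> float:
    """OLS slope (µV/ms) of amplitude vs. time over ``t0 <= t <= t1``."""
    t = np.asarray(times_ms, dtype=float)
    y = np.asarray(amplitude, dtype=float)
    if t0 < t[0] or t1 > t[-1]:
        raise ValueError(f"slope window [{t0}, {t1}] outside grid "
                         f"[{t[0]}, {t[-1]}] ms")
    mask = (t >= t0) & (t <= t1)
    if mask.sum() < 3:
        raise ValueError(f"slope window [{t0}, {t1}] has fewer than 3 samples")
    tw, yw = t[mask], y[mask]
    tc = tw - tw.mean()
    return float(tc @ (yw - yw.mean()) / (tc @ tc))


def compute_wfa(amplitude: np.ndarray, template: np.ndarray,
                metric: str = "pearson") -> float:
    """Adherence of a TEP to the normative template; NaN if undefined."""
    a = np.asarray(amplitude, dtype=float)
    b = np.asarray(template, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveform and template grids differ")
    if metric == "pearson":
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0.0 or nb == 0.0:
            return float("nan")
        return float(a @ b / (na * nb))
    raise ValueError(f"unknown WFA metric {metric!r}")


def compute_mfp(amplitude: np.ndarray) -> float:
    """Mean rectified amplitude (µV) over the analysis window."""
    return float(np.mean(np.abs(np.asarray(amplitude, dtype=float))))


def compute_stp(mfp_single: float, mfp_i: float) -> float:
    """Normalized single-vs-inhibitory MFP difference ratio, in [-1, 1]."""
    if mfp_single < 0 or mfp_i < 0:
        raise ValueError("MFP values must be >= 0")
    total = mfp_single + mfp_i
    if total == 0.0:
        return float("nan")
    return (mfp_single - mfp_i) / total


def build_template(teps: HotspotTEPSet, reference_ids,
                   age_band: str = "adult",
                   evaluation_ids=None) -> NormativeTemplate:
    """Pointwise-mean single-pulse template from healthy reference subjects.

    ``reference_ids`` must contain at least 5 subjects and must be disjoint
    from ``evaluation_ids`` when given (leakage guard).
    """
    reference_ids = tuple(reference_ids)
    if len(reference_ids) < MIN_TEMPLATE_SUBJECTS:
        raise ValueError(
            f"need >= {MIN_TEMPLATE_SUBJECTS} reference subjects, "
            f"got {len(reference_ids)}")
    if evaluation_ids is not None:
        overlap = set(reference_ids) & set(evaluation_ids)
        if overlap:
            raise LeakageError(
                f"reference subjects {sorted(overlap)} are in the "
                "evaluation set")
    ci = teps.conditions.index("single")
    idx = [teps.subjects.index(s) for s in reference_ids]
    data = teps.data[idx, ci].mean(axis=0)
    return NormativeTemplate(list(teps.hotspots), teps.times, data,
                             reference_ids, age_band)


def compute_feature_table(teps: HotspotTEPSet,
                          template: NormativeTemplate,
                          subjects=None,
                          wfa_metric: str = "pearson") -> pd.DataFrame:
    """Long table: one row per (subject, hotspot) with all measures.

    Subjects used to build the template may not be evaluated here
    (hard error).
    """
    if subjects is None:
        subjects = [s for s in teps.subjects
                    if s not in set(template.reference_ids)]
    template.assert_disjoint(subjects)
    ci_s = teps.conditions.index("single")
    ci_i = teps.conditions.index("inhibitory")
    rows = []
    for s in subjects:
        si = teps.subjects.index(s)
        for hi, hotspot in enumerate(teps.hotspots):
            single = teps.data[si, ci_s, hi]
            inhib = teps.data[si, ci_i, hi]
            mfp_s = compute_mfp(single)
            mfp_i = compute_mfp(inhib)
            rows.append({
                "subject_id": s,
                "hotspot": hotspot,
                "epd": compute_slope(single, teps.times, *EPD_WINDOW_MS),
                "lpd": compute_slope(single, teps.times, *LPD_WINDOW_MS),
                "wfa": compute_wfa(single, template.waveform(hotspot),
                                   wfa_metric),
                "mfp_single": mfp_s,
                "mfp_i": mfp_i,
                "stp": compute_stp(mfp_s, mfp_i),
            })
    return pd.DataFrame(rows)


@dataclass
class FeatureVectorLog:
    imputed: list[tuple[str, str, str]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def build_feature_vector(table: pd.DataFrame,
                         hotspots=PROXIMAL_HOTSPOTS,
                         measures=MEASURES,
                         max_missing_frac: float = 0.25):
    """Subject-by-feature matrix in fixed hotspot-major, measure-minor order.

    Default: 4 proximal hotspots x (EPD, LPD, WFA, STP) = 16 columns.
    Missing cells are imputed with the cohort median of the same
    (hotspot, measure) column; subjects missing more than
    ``max_missing_frac`` of their cells are dropped.  Returns
    ``(DataFrame, FeatureVectorLog)``.
    """
    cols = [(h, m) for h in hotspots for m in measures]
    wide = table.pivot(index="subject_id", columns="hotspot")
    X = pd.DataFrame(index=wide.index)
    for h, m in cols:
        try:
            X[f"{h}:{m}"] = wide[(m, h)]
        except KeyError as exc:
            raise ValueError(f"feature table lacks {m} for hotspot {h!r}") from exc
    log = FeatureVectorLog()
    frac_missing = X.isna().mean(axis=1)
    drop = frac_missing[frac_missing > max_missing_frac].index
    log.dropped = list(drop)
    X = X.drop(index=drop)
    for col in X.columns:
        miss = X.index[X[col].isna()]
        if len(miss):
            med = X[col].median(skipna=True)
            X.loc[miss, col] = med
            h, m = col.split(":")
            log.imputed.extend((s, h, m) for s in miss)
    return X, log
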