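"""Marker-intensity and qPCR relative-expression quantification.

Two readouts of flow-responsive gene expression:

* **Nuclear marker intensity** — the mean fluorescence of a
  transcription-factor channel (KLF4-like) inside each nucleus ROI,
  using the nuclear label map as the reference, mirroring the
  threshold-the-DAPI / measure-in-the-marker-channel workflow.

* **qPCR relative expression** by the Livak 2^(−ΔΔCq) method: target
  Cq normalised to a reference gene (ΔCq), then to a control condition
  (ΔΔCq); replicate Cq values are averaged before differencing.
  Standard curves across a dilution series give the amplification
  efficiency E = 10^(−1/slope) − 1 (slope in Cq per log₁₀ dilution;
  −3.32 for perfect doubling chemistry).

Group comparisons (rank-sum, t-test, one-way ANOVA with Tukey HSD) are
thin wrappers over scipy/statsmodels, provided so reports carry the
conventional statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

__all__ = [
    "nuclear_marker_intensity",
    "livak_fold_change",
    "livak_table",
    "QpcrPlate",
    "StandardCurve",
    "standard_curve_fit",
    "DEFAULT_DILUTIONS",
    "rank_sum_test",
    "t_test",
    "anova_tukey",
]

#: Standard-curve dilution series used by default (1:10, 1:25, 1:50).
DEFAULT_DILUTIONS = (0.1, 0.04, 0.02)


def nuclear_marker_intensity(nucleus_labels: np.ndarray, marker: np.ndarray,
                             condition: str = "", min_area: int = 30,
                             erode_px: int = 1) -> pd.DataFrame:
    """Per-nucleus mean marker intensity.

    Columns: nucleus_id, area_px, mean_intensity, condition.  Labels
    smaller than ``min_area`` pixels (after erosion) are dropped.  Each
    ROI is eroded by ``erode_px`` before measuring, so the rim of
    partial-volume pixels where nuclear signal mixes with background
    does not dilute the mean; pass 0 to measure the full ROI.
    """
    nucleus_labels = np.asarray(nucleus_labels)
    marker = np.asarray(marker, dtype=float)
    if nucleus_labels.shape != marker.shape:
        raise ValueError("label map and marker image shapes differ")
    if erode_px > 0:
        interior = ndi.binary_erosion(nucleus_labels > 0, iterations=erode_px)
        nucleus_labels = np.where(interior, nucleus_labels, 0)
    ids = np.unique(nucleus_labels)
    ids = ids[ids != 0]
    if len(ids) == 0:
        return pd.DataFrame(columns=["nucleus_id", "area_px", "mean_intensity", "condition"])
    areas = ndi.sum_labels(np.ones_like(marker), nucleus_labels, index=ids)
    means = ndi.mean(marker, nucleus_labels, index=ids)
    df = pd.DataFrame({
        "nucleus_id": ids.astype(int),
        "area_px": areas.astype(int),
        "mean_intensity": means,
        "condition": condition,
    })
    return df[df["area_px"] >= min_area].reset_index(drop=True)


def _mean_cq(value) -> float:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValueError("Cq values must be finite and non-empty")
    return float(arr.mean())


def livak_fold_change(cq_target_sample, cq_ref_sample,
                      cq_target_control, cq_ref_control) -> float:
    """Relative expression 2^(−ΔΔCq).

    ΔΔCq = (Cq_target,sample − Cq_ref,sample)
         − (Cq_target,control − Cq_ref,control);
    replicate arrays are averaged before differencing.
    """
    dcq_sample = _mean_cq(cq_target_sample) - _mean_cq(cq_ref_sample)
    dcq_control = _mean_cq(cq_target_control) - _mean_cq(cq_ref_control)
    return float(2.0 ** (-(dcq_sample - dcq_control)))


@dataclass
class QpcrPlate:
    """Cq measurements as a long table: gene, sample, replicate, cq."""

    data: pd.DataFrame
    reference_gene: str = "GAPDH"
    control_sample: str = "static"

    def __post_init__(self) -> None:
        required = {"gene", "sample", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Cq table missing columns: {sorted(missing)}")
        if (self.data["cq"] <= 0).any() or not np.all(np.isfinite(self.data["cq"])):
            raise ValueError("Cq values must be finite and positive")
        samples = set(self.data["sample"])
        ref_samples = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        for s in sorted(samples - ref_samples):
            raise ValueError(
                f"sample {s!r} has no {self.reference_gene} (reference gene) measurement")
        if self.control_sample not in samples:
            raise ValueError(f"control sample {self.control_sample!r} not in table")

    def mean_cq(self, gene: str, sample: str) -> float:
        sel = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        if sel.empty:
            raise ValueError(f"no Cq for gene {gene!r}, sample {sample!r}")
        return float(sel["cq"].mean())


def livak_table(plate: QpcrPlate, aggregate: str = "mean") -> pd.DataFrame:
    """Fold change of every (gene, sample) vs the control sample.

    Columns: gene, sample, delta_cq, delta_delta_cq, fold_change.  The
    reference gene itself is omitted.  ``aggregate`` may be "mean"
    (default) or "median" for replicate aggregation.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    agg = np.mean if aggregate == "mean" else np.median
    df = plate.data
    rows = []
    for gene in sorted(set(df["gene"]) - {plate.reference_gene}):
        cq_t_ctl = agg(df[(df["gene"] == gene) & (df["sample"] == plate.control_sample)]["cq"])
        cq_r_ctl = agg(df[(df["gene"] == plate.reference_gene)
                          & (df["sample"] == plate.control_sample)]["cq"])
        dcq_ctl = cq_t_ctl - cq_r_ctl
        for sample in sorted(set(df.loc[df["gene"] == gene, "sample"])):
            cq_t = agg(df[(df["gene"] == gene) & (df["sample"] == sample)]["cq"])
            cq_r = agg(df[(df["gene"] == plate.reference_gene)
                          & (df["sample"] == sample)]["cq"])
            dcq = cq_t - cq_r
            ddcq = dcq - dcq_ctl
            rows.append({"gene": gene, "sample": sample, "delta_cq": dcq,
                         "delta_delta_cq": ddcq, "fold_change": 2.0 ** (-ddcq)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares Cq vs log₁₀(dilution) with amplification efficiency."""

    dilutions: tuple
    mean_cq: tuple
    slope: float        # Cq per log₁₀ dilution; < 0 for a valid curve
    intercept: float
    r_squared: float
    efficiency: float   # E = 10^(−1/slope) − 1; 1.0 = 100 %

    @property
    def valid(self) -> bool:
        return self.slope < 0


def standard_curve_fit(dilutions, cq_means) -> StandardCurve:
    """Fit a qPCR standard curve over a dilution series.

    ``dilutions`` are relative template amounts (e.g. 0.1 for 1:10); Cq
    is regressed on log₁₀(dilution).  A non-negative slope marks the
    curve invalid (efficiency NaN) rather than raising.
    """
    d = np.asarray(dilutions, dtype=float)
    cq = np.asarray(cq_means, dtype=float)
    if d.size != cq.size or d.size < 2:
        raise ValueError("need at least two (dilution, Cq) points")
    if np.any(d <= 0):
        raise ValueError("dilution factors must be positive")
    if np.unique(d).size < 2:
        raise ValueError("degenerate design: all dilution factors identical")
    res = stats.linregress(np.log10(d), cq)
    slope = float(res.slope)
    eff = float(10.0 ** (-1.0 / slope) - 1.0) if slope < 0 else float("nan")
    return StandardCurve(
        dilutions=tuple(d), mean_cq=tuple(cq), slope=slope,
        intercept=float(res.intercept), r_squared=float(res.rvalue ** 2),
        efficiency=eff)


def rank_sum_test(a, b) -> dict:
    """Two-sided Mann–Whitney rank-sum comparison of two groups."""
    r = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mann-whitney", "statistic": float(r.statistic), "p_value": float(r.pvalue)}


def t_test(a, b, equal_var: bool = False) -> dict:
    """Two-sided unpaired t-test (Welch by default)."""
    r = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"test": "t-test", "statistic": float(r.statistic), "p_value": float(r.pvalue)}


def anova_tukey(groups: dict) -> dict:
    """One-way ANOVA over named groups with Tukey HSD pairwise tests."""
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    f = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[f"{names[i]} vs {names[j]}"] = float(tukey.pvalue[i, j])
    return {"test": "anova+tukey", "f_statistic": float(f.statistic),
            "p_value": float(f.pvalue), "tukey_p": pairwise}
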