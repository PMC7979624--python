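"""HU-threshold tissue subclassification and per-slice volumetry.

The segmentation networks delineate semantic body regions; tissues are then
identified by a logical conjunction of an HU threshold range and the region
containing the voxel:

* adipose-range HU (-190..-30) inside the abdominal cavity  -> VAT
* adipose-range HU inside the subcutaneous tissue region    -> SAT
* muscle-range HU (-29..150) inside the muscle region       -> muscle
* everything else                                           -> none

Volumes are reported per axial slice and in total, in mL, always at the
native CT resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .losses_metrics import BlandAltman, bland_altman, icc
from .volume_io import (ABDOMINAL_CAVITY, IGNORE, MUSCLE, SUBCUTANEOUS,
                        CTVolume, LabelMap)

__all__ = [
    "TissueThresholds", "TissueReport", "classify_voxel", "classify_volume",
    "quantify_volumes", "agreement_report", "AgreementResult",
    "plot_slice_volumes", "plot_bland_altman",
]

TISSUES = ("sat", "vat", "muscle")


@dataclass(frozen=True)
class TissueThresholds:
    """Inclusive HU ranges for adipose and muscular tissue."""

    adipose: tuple[int, int] = (-190, -30)
    muscle: tuple[int, int] = (-29, 150)

    def __post_init__(self):
        a, m = self.adipose, self.muscle
        if not (a[0] <= a[1] and m[0] <= m[1]):
            raise ValueError("threshold ranges must be ordered")
        if max(a[0], m[0]) <= min(a[1], m[1]):
            raise ValueError("adipose and muscle HU ranges must be disjoint")


@dataclass
class TissueReport:
    """Per-slice and total SAT/VAT/muscle volumes in mL."""

    per_slice: pd.DataFrame  # columns: slice, sat_ml, vat_ml, muscle_ml
    totals: dict[str, float]
    voxel_volume_mm3: float

    def to_csv(self, path: str) -> None:
        self.per_slice.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"totals_ml": self.totals,
                       "voxel_volume_mm3": self.voxel_volume_mm3}, fh, indent=2)


def classify_voxel(hu: float, region: int,
                   thresholds: TissueThresholds | None = None) -> str:
    """Classify a single voxel into ``sat`` / ``vat`` / ``muscle`` / ``none``."""
    t = thresholds or TissueThresholds()
    if t.adipose[0] <= hu <= t.adipose[1]:
        if region == ABDOMINAL_CAVITY:
            return "vat"
        if region == SUBCUTANEOUS:
            return "sat"
    elif t.muscle[0] <= hu <= t.muscle[1] and region == MUSCLE:
        return "muscle"
    return "none"


def classify_volume(ct: CTVolume, labels: LabelMap,
                    thresholds: TissueThresholds | None = None) -> dict[str, np.ndarray]:
    """Vectorized tissue masks; ignore-labelled voxels belong to no tissue."""
    t = thresholds or TissueThresholds()
    hu = ct.voxels
    lab = labels.labels
    if hu.shape != lab.shape:
        raise ValueError(f"CT shape {hu.shape} != label shape {lab.shape}")
    adipose = (hu >= t.adipose[0]) & (hu <= t.adipose[1])
    muscular = (hu >= t.muscle[0]) & (hu <= t.muscle[1])
    annotated = lab != IGNORE
    return {
        "sat": adipose & (lab == SUBCUTANEOUS) & annotated,
        "vat": adipose & (lab == ABDOMINAL_CAVITY) & annotated,
        "muscle": muscular & (lab == MUSCLE) & annotated,
    }


def quantify_volumes(ct: CTVolume, labels: LabelMap,
                     thresholds: TissueThresholds | None = None) -> TissueReport:
    """Per-slice tissue volumes: voxel count x voxel volume, in mL."""
    if ct.spacing is None or any(s <= 0 for s in ct.spacing):
        raise ValueError("CT volume lacks a valid voxel spacing")
    masks = classify_volume(ct, labels, thresholds)
    vox_mm3 = ct.voxel_volume_mm3
    ml_per_voxel = vox_mm3 / 1000.0
    nz = ct.shape[0]
    data = {"slice": np.arange(nz)}
    totals = {}
    for name in TISSUES:
        per_slice = masks[name].sum(axis=(1, 2)) * ml_per_voxel
        data[f"{name}_ml"] = per_slice
        totals[name] = float(per_slice.sum())
    return TissueReport(per_slice=pd.DataFrame(data), totals=totals,
                        voxel_volume_mm3=vox_mm3)


@dataclass
class AgreementResult:
    """Per-tissue ICC and Bland-Altman statistics of per-slice volumes."""

    icc: dict[str, float]
    bland_altman: dict[str, BlandAltman]
    n_slices: int


def agreement_report(pred_report: TissueReport, truth_report: TissueReport,
                     slices: np.ndarray | None = None) -> AgreementResult:
    """Slice-by-slice agreement between predicted and ground-truth volumetry.

    ``slices`` restricts the comparison (e.g. to annotated slices only).
    """
    p = pred_report.per_slice.set_index("slice")
    t = truth_report.per_slice.set_index("slice")
    common = p.index.intersection(t.index)
    if slices is not None:
        common = common.intersection(pd.Index(slices))
    if len(common) < 3:
        raise ValueError(f"need >= 3 matched slices, got {len(common)}")
    iccs, bas = {}, {}
    for name in TISSUES:
        a = p.loc[common, f"{name}_ml"].to_numpy()
        b = t.loc[common, f"{name}_ml"].to_numpy()
        iccs[name] = icc(a, b)
        bas[name] = bland_altman(a, b)
    return AgreementResult(icc=iccs, bland_altman=bas, n_slices=len(common))


# ---------------------------------------------------------------------------
# figures

def plot_slice_volumes(report: TissueReport, path: str) -> None:
    """Stacked bar chart of muscle/SAT/VAT volume per axial slice."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_slice
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = np.zeros(len(df))
    for name, color in [("muscle_ml", "#e6c229"), ("sat_ml", "#c03030"),
                        ("vat_ml", "#3ba13b")]:
        ax.bar(df["slice"], df[name], bottom=bottom,
               label=name.replace("_ml", "").upper(), color=color, width=0.9)
        bottom += df[name].to_numpy()
    ax.set_xlabel("axial slice")
    ax.set_ylabel("volume [mL]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_bland_altman(pred_report: TissueReport, truth_report: TissueReport,
                      path: str, slices: np.ndarray | None = None) -> None:
    """Bland-Altman panels (difference vs mean) for SAT, VAT and muscle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = pred_report.per_slice.set_index("slice")
    t = truth_report.per_slice.set_index("slice")
    common = p.index.intersection(t.index)
    if slices is not None:
        common = common.intersection(pd.Index(slices))
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, name in zip(axes, TISSUES):
        a = p.loc[common, f"{name}_ml"].to_numpy()
        b = t.loc[common, f"{name}_ml"].to_numpy()
        ba = bland_altman(a, b)
        ax.scatter((a + b) / 2, a - b, s=12, alpha=0.7)
        for y, style in [(ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")]:
            ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
        ax.set_title(name.upper())
        ax.set_xlabel("mean [mL]")
    axes[0].set_ylabel("difference [mL]")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
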