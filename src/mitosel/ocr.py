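"""Extracellular-flux (oxygen consumption rate) derived metrics.

A plate run is a 32-cycle OCR time course per well: 8 untreated cycles, an
injection of FCCP (uncoupler) or 1% DMSO (vehicle control) before cycle 9,
20 post-injection cycles, then sodium azide (complex IV inhibitor) before
cycle 29 and 4 terminal cycles measuring non-mitochondrial respiration.

Derived metrics per the Agilent-style definitions used here:

    basal   = mean(DMSO window) - non-mitochondrial OCR
    maximal = mean(FCCP window) - non-mitochondrial OCR
    spare   = mean(FCCP window) - mean(DMSO window)

so that ``spare == maximal - basal`` holds as an algebraic identity (the
non-mitochondrial term is the azide-phase mean pooled across sample
wells, since azide abolishes mitochondrial respiration in every well).
Species presets for the response window: nematode plateaus differ, cycles
10-13 for the fast-responding species preset ("mephisto") and 13-16 for
the slower one ("elegans").  All OCR values are background-subtracted and
normalized to pmol O2/min/worm before any window averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_PRESETS = {"mephisto": (10, 13), "elegans": (13, 16)}
UNTREATED_WINDOW = (5, 8)


@dataclass
class OCRPlate:
    """Plate-format OCR time course.

    ``wells``: columns well, group, worms, role (sample|background).
    ``measurements``: columns well, cycle, ocr (and optionally time_min).
    ``injections``: last untreated cycle and last post-injection-1 cycle.
    """

    wells: pd.DataFrame
    measurements: pd.DataFrame
    injections: tuple[int, int] = (8, 28)

    def __post_init__(self):
        for colset, df in (
            ({"well", "group", "worms", "role"}, self.wells),
            ({"well", "cycle", "ocr"}, self.measurements),
        ):
            missing = colset - set(df.columns)
            if missing:
                raise ValueError(f"missing columns: {sorted(missing)}")
        samples = self.wells[self.wells.role == "sample"]
        if (samples.worms <= 0).any():
            raise ValueError("sample wells must have worm count > 0")
        if not (self.wells.role == "background").any():
            raise ValueError("at least one background well is required")
        cycles = np.sort(self.measurements.cycle.unique())
        if not np.all(np.diff(cycles) > 0):
            raise ValueError("cycle indices must be strictly increasing")
        self.cycles = cycles

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @classmethod
    def from_csv(cls, wells_path, measurements_path, injections=(8, 28)) -> "OCRPlate":
        return cls(
            wells=pd.read_csv(wells_path),
            measurements=pd.read_csv(measurements_path),
            injections=tuple(injections),
        )


def normalize(plate: OCRPlate) -> pd.DataFrame:
    """Background-subtracted per-worm OCR for every sample well.

    Subtraction precedes per-worm normalization: for each cycle, the mean
    OCR of the background wells is subtracted, then the residual is
    divided by the well's worm count.  Returns a tidy frame with columns
    well, group, cycle, ocr_per_worm.
    """
    bg_wells = plate.wells.loc[plate.wells.role == "background", "well"]
    bg = (
        plate.measurements[plate.measurements.well.isin(bg_wells)]
        .groupby("cycle")["ocr"]
        .mean()
    )
    samples = plate.wells[plate.wells.role == "sample"]
    rows = []
    for _, w in samples.iterrows():
        m = plate.measurements[plate.measurements.well == w.well]
        for _, r in m.iterrows():
            rows.append(
                {
                    "well": w.well,
                    "group": w.group,
                    "cycle": int(r.cycle),
                    "ocr_per_worm": (r.ocr - bg.get(r.cycle, 0.0)) / w.worms,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OCRMetrics:
    basal: float
    maximal: float
    spare: float
    untreated: float
    non_mitochondrial: float
    response_window: tuple[int, int]
    untreated_window: tuple[int, int]
    azide_window: tuple[int, int]
    warnings: list[str] = field(default_factory=list)


def _window_mean(df: pd.DataFrame, group: str, window: tuple[int, int]) -> float:
    sel = df[(df.group == group) & df.cycle.between(window[0], window[1])]
    if sel.empty:
        raise ValueError(f"no measurements for group {group!r} in window {window}")
    # average within well first so unequal cycle coverage cannot bias a group
    return float(sel.groupby("well")["ocr_per_worm"].mean().mean())


def derive_metrics(
    plate: OCRPlate,
    species_window: str | tuple[int, int] = "mephisto",
    untreated_window: tuple[int, int] = UNTREATED_WINDOW,
    fccp_group: str = "FCCP",
    dmso_group: str = "DMSO",
) -> OCRMetrics:
    """Basal, maximal and spare respiratory capacity for one plate.

    ``species_window`` is a preset name or an explicit (first, last) cycle
    pair for the post-injection-1 response window.  The azide window is
    the final four recorded cycles.  Negative metrics are reported as-is
    with a warning; clipping would hide assay failure.
    """
    window = (
        WINDOW_PRESETS[species_window]
        if isinstance(species_window, str)
        else tuple(species_window)
    )
    lo, hi = int(plate.cycles.min()), int(plate.cycles.max())
    for name, (a, b) in (
        ("response", window),
        ("untreated", untreated_window),
    ):
        if not (lo <= a <= b <= hi):
            raise ValueError(f"{name} window {(a, b)} outside recorded cycles [{lo},{hi}]")
    azide_window = (int(plate.cycles[-4]) if plate.n_cycles >= 4 else lo, hi)

    norm = normalize(plate)
    groups = set(norm.group)
    for g in (fccp_group, dmso_group):
        if g not in groups:
            raise ValueError(f"missing treatment group {g!r}")

    fccp = _window_mean(norm, fccp_group, window)
    dmso = _window_mean(norm, dmso_group, window)
    azide_sel = norm[norm.cycle.between(*azide_window)]
    non_mito = float(azide_sel.groupby("well")["ocr_per_worm"].mean().mean())
    untreated = float(
        norm[norm.cycle.between(*untreated_window)]
        .groupby("well")["ocr_per_worm"]
        .mean()
        .mean()
    )

    basal = dmso - non_mito
    maximal = fccp - non_mito
    spare = fccp - dmso
    warnings = [
        f"negative {name} respiration ({value:.3g})"
        for name, value in (("basal", basal), ("maximal", maximal), ("spare", spare))
        if value < 0
    ]
    for w in warnings:
        logger.warning(w)
    return OCRMetrics(
        basal=basal,
        maximal=maximal,
        spare=spare,
        untreated=untreated,
        non_mitochondrial=non_mito,
        response_window=window,
        untreated_window=tuple(untreated_window),
        azide_window=azide_window,
        warnings=warnings,
    )


def fold_change(metric_a: float, metric_b: float) -> dict:
    """Ratio a/b with a division-by-zero guard.

    Returns a dict with both inputs, the ratio (None when undefined) and a
    flag, so reports always carry the raw values alongside the ratio.
    """
    undefined = metric_b == 0
    return {
        "a": float(metric_a),
        "b": float(metric_b),
        "ratio": None if undefined else float(metric_a / metric_b),
        "undefined": bool(undefined),
    }
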