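"""Accuracy and repeatability reports.

Three analyses mirror the validation experiments: inter-marker spacing
accuracy against the known template separations, pose repeatability
across scan planes and table positions against a baseline acquisition,
and the overall detection rate.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .device_template import DeviceTemplate, PAIRS
from .pose_geometry import DeviceDetection, pose_difference

__all__ = [
    "SpacingReport",
    "RepeatabilityReport",
    "spacing_accuracy",
    "repeatability",
    "detection_rate",
]


@dataclass
class SpacingReport:
    """Signed per-pair spacing errors plus a global absolute summary.

    ``per_pair`` maps (group, pair-label) to mean +- SD of the signed
    (measured - true) separation in mm; the global summary is the mean +-
    SD of the absolute differences pooled over every group, pair and
    replicate.
    """

    per_pair: dict = field(default_factory=dict)  # (group, "A-B") -> (mean, sd, n)
    global_abs_mean_mm: float = float("nan")
    global_abs_sd_mm: float = float("nan")
    n_values: int = 0
    detection_rate: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "per_pair": {
                f"{g}|{p}": {"mean_mm": m, "sd_mm": s, "n": n}
                for (g, p), (m, s, n) in self.per_pair.items()
            },
            "global_abs_mean_mm": self.global_abs_mean_mm,
            "global_abs_sd_mm": self.global_abs_sd_mm,
            "n_values": self.n_values,
            "detection_rate": self.detection_rate,
        }

    def save(self, path: str) -> None:
        _save_report(self.to_dict(), self._rows(), path)

    def _rows(self) -> list[dict]:
        rows = []
        for (g, p), (m, s, n) in sorted(self.per_pair.items()):
            rows.append({"group": g, "pair": p, "mean_mm": m, "sd_mm": s, "n": n})
        return rows


@dataclass
class RepeatabilityReport:
    """Per-acquisition pose differences versus a baseline (commanded table
    shifts removed): per-axis and norm COM differences (mm), angle
    differences (degrees), plus maxima and averages."""

    rows: list = field(default_factory=list)  # dicts with name + pose_difference fields
    max_dcom_mm: float = 0.0
    mean_dcom_mm: float = 0.0
    max_dangle_deg: float = 0.0

    def to_dict(self) -> dict:
        return {
            "acquisitions": self.rows,
            "max_dcom_mm": self.max_dcom_mm,
            "mean_dcom_mm": self.mean_dcom_mm,
            "max_dangle_deg": self.max_dangle_deg,
        }

    def save(self, path: str) -> None:
        _save_report(self.to_dict(), self.rows, path)


def _save_report(payload: dict, rows: list[dict], path: str) -> None:
    root, ext = os.path.splitext(path)
    if ext == ".json":
        with open(path, "w") as f:
            json.dump(payload, f, indent=2, sort_keys=True)
    elif ext == ".csv":
        if not rows:
            raise ValueError("no rows to write")
        with open(path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=list(rows[0]))
            w.writeheader()
            w.writerows(rows)
    else:
        raise ValueError(f"unknown report format {ext!r} (use .json or .csv)")


def spacing_accuracy(
    detections: Sequence[tuple[str, DeviceDetection]] | Sequence[DeviceDetection],
    t: DeviceTemplate,
    n_attempted: int | None = None,
) -> SpacingReport:
    """Compare measured inter-marker spacings with the template's.

    ``detections`` is a sequence of DeviceDetection, optionally as
    (group, detection) pairs to aggregate per acquisition group (e.g. per
    preset).  For each detection the six labeled pairwise COM distances are
    subtracted from the true template separations; per-(group, pair) means
    and SDs of the signed differences are reported alongside the pooled
    mean +- SD of the absolute differences.
    """
    items: list[tuple[str, DeviceDetection]] = []
    for d in detections:
        items.append(d if isinstance(d, tuple) else ("all", d))
    if not items:
        raise ValueError("no detections given")
    true = t.separations
    signed: dict[tuple[str, str], list[float]] = {}
    all_abs: list[float] = []
    for group, det in items:
        meas = det.separations()
        for (a, b), m, tr in zip(PAIRS, meas, true):
            diff = float(m - tr)
            signed.setdefault((group, f"{a}-{b}"), []).append(diff)
            all_abs.append(abs(diff))
    per_pair = {
        key: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0, len(v))
        for key, v in signed.items()
    }
    rep = SpacingReport(
        per_pair=per_pair,
        global_abs_mean_mm=float(np.mean(all_abs)),
        global_abs_sd_mm=float(np.std(all_abs, ddof=1)) if len(all_abs) > 1 else 0.0,
        n_values=len(all_abs),
    )
    if n_attempted is not None:
        rep.detection_rate = len(items) / n_attempted if n_attempted else float("nan")
    return rep


def repeatability(
    detections: Sequence[tuple[str, DeviceDetection]],
    baseline: DeviceDetection,
    commanded_shifts: dict[str, Sequence[float]] | None = None,
) -> RepeatabilityReport:
    """Pose differences of each named acquisition versus the baseline.

    ``commanded_shifts`` maps acquisition names to deliberately applied
    world translations (removed before comparison); unnamed acquisitions
    are assumed unshifted.
    """
    shifts = commanded_shifts or {}
    rows = []
    for name, det in detections:
        diff = pose_difference(baseline, det, shifts.get(name))
        row = {"name": name, **diff}
        row["max_abs_dangle_deg"] = max(abs(diff["dtheta_deg"]), abs(diff["dphi_deg"]))
        rows.append(row)
    if not rows:
        raise ValueError("no detections given")
    dcoms = [r["dcom_mm"] for r in rows]
    dangles = [r["max_abs_dangle_deg"] for r in rows]
    return RepeatabilityReport(
        rows=rows,
        max_dcom_mm=float(max(dcoms)),
        mean_dcom_mm=float(np.mean(dcoms)),
        max_dangle_deg=float(max(dangles)),
    )


def detection_rate(results: Sequence) -> dict:
    """Fraction of successful detections, with a per-group breakdown.

    ``results`` holds (group, outcome) pairs or bare outcomes, where an
    outcome is a DeviceDetection (success), an exception, or a bool.
    """
    if not len(results):
        raise ValueError("no results")
    items = [(r if isinstance(r, tuple) else ("all", r)) for r in results]

    def ok(outcome) -> bool:
        if isinstance(outcome, bool):
            return outcome
        return isinstance(outcome, DeviceDetection)

    per_group: dict[str, list[bool]] = {}
    for g, outcome in items:
        per_group.setdefault(g, []).append(ok(outcome))
    flat = [s for v in per_group.values() for s in v]
    return {
        "rate": sum(flat) / len(flat),
        "n_success": int(sum(flat)),
        "n_attempted": len(flat),
        "per_group": {g: sum(v) / len(v) for g, v in per_group.items()},
    }
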