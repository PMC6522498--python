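"""Slow/fast classification of backbone amides from HDX peak intensities.

After dissolving a protonated, freeze-dried sample in D2O, amide protons in
stable hydrogen bonds exchange slowly and their HSQC peaks persist; exposed
amides exchange within minutes and their peaks vanish. Classification is by
the intensity ratio at a reference exchange time (default 15 min) relative
to the H2O control: ratio >= threshold (default 0.2) means slow. Prolines
(no amide) and residues without a control peak are excluded. An optional
slope criterion over all time points is available instead of the
single-time ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["HDXSeries", "HDXMap", "classify_hdx", "compare_hdx",
           "read_hdx_csv", "write_hdx_map_csv"]

SLOW_ASSIGNED = "+"
SLOW_UNASSIGNED_POLYQ = "*"
FAST = "fast"
EXCLUDED = "excluded"


@dataclass
class HDXSeries:
    """Peak intensities per residue: H2O control plus exchange time points.

    ``labels`` carries the 10Q-frame numbering (fractional for inserted
    glutamines); ``assigned`` flags residues with a site-specific assignment.
    """

    sequence: str
    times: tuple[float, ...]  # minutes, strictly increasing
    control: np.ndarray  # shape (n,)
    intensities: np.ndarray  # shape (n_times, n)
    assigned: np.ndarray  # bool, shape (n,)
    labels: np.ndarray | None = None  # 10Q-frame residue labels
    name: str = ""

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.assigned = np.asarray(self.assigned, dtype=bool)
        n = len(self.sequence)
        if self.control.shape != (n,) or self.assigned.shape != (n,):
            raise ValueError("control/assigned must have one entry per residue")
        if self.intensities.shape != (len(self.times), n):
            raise ValueError("intensities must be (n_times, n_residues)")
        if (self.control < 0).any() or (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")
        if not all(a < b for a, b in zip(self.times, self.times[1:])):
            raise ValueError("time points must be strictly increasing")
        if self.labels is None:
            self.labels = np.arange(1, n + 1, dtype=float)


@dataclass
class HDXMap:
    """One label per residue: '+', '*', 'fast' or 'excluded'."""

    sequence: str
    labels: list[str]
    residue_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence):
            raise ValueError("one label per residue required")
        if self.residue_labels is None:
            self.residue_labels = np.arange(1, len(self.sequence) + 1, dtype=float)

    def slow_mask(self) -> np.ndarray:
        return np.array(
            [lab in (SLOW_ASSIGNED, SLOW_UNASSIGNED_POLYQ) for lab in self.labels]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.residue_labels,
                "aa": list(self.sequence),
                "hdx": self.labels,
            }
        )


def classify_hdx(
    series: HDXSeries,
    t_ref: float = 15.0,
    ratio_threshold: float = 0.2,
    polyq_region: tuple[int, int] | None = None,
    use_slope: bool = False,
) -> HDXMap:
    """Label each amide slow or fast from its intensity persistence.

    Slow iff intensity(t_ref) / intensity(control) >= ratio_threshold (or,
    with ``use_slope``, iff the fitted log-intensity decay over all time
    points is shallow enough to leave that ratio at t_ref). Unassigned slow
    glutamines inside ``polyq_region`` are marked '*' instead of '+'.
    Classification is invariant under uniform intensity rescaling.
    """
    if t_ref not in series.times:
        raise ValueError(f"t_ref {t_ref} not among time points {series.times}")
    if not (series.control > 0).any():
        raise ValueError("no control intensities present")
    t_idx = series.times.index(t_ref)

    labels: list[str] = []
    for i, aa in enumerate(series.sequence):
        ctrl = series.control[i]
        if aa == "P" or ctrl <= 0:
            labels.append(EXCLUDED)
            continue
        if use_slope:
            times = np.asarray(series.times)
            vals = np.maximum(series.intensities[:, i] / ctrl, 1e-12)
            rate = -np.polyfit(times, np.log(vals), 1)[0]
            ratio = float(np.exp(-rate * t_ref))
        else:
            ratio = series.intensities[t_idx, i] / ctrl
        if ratio >= ratio_threshold:
            in_polyq = (
                polyq_region is not None
                and polyq_region[0] <= series.labels[i] <= polyq_region[1]
            )
            if not series.assigned[i] and in_polyq:
                labels.append(SLOW_UNASSIGNED_POLYQ)
            else:
                labels.append(SLOW_ASSIGNED)
        else:
            labels.append(FAST)
    return HDXMap(sequence=series.sequence, labels=labels,
                  residue_labels=series.labels)


def compare_hdx(
    a: HDXMap, b: HDXMap, region: tuple[int, int]
) -> tuple[int, int, int]:
    """Slow-amide counts of each map inside a 10Q-frame region and b - a."""
    def count(m: HDXMap) -> int:
        lo, hi = region
        mask = (m.residue_labels >= lo) & (m.residue_labels <= hi + 0.999)
        return int((m.slow_mask() & mask).sum())

    n_a, n_b = count(a), count(b)
    return n_a, n_b, n_b - n_a


def read_hdx_csv(path: str | Path, name: str = "") -> HDXSeries:
    """Read ``index,aa,assigned,ctrl,i15,i60,i120`` rows."""
    frame = pd.read_csv(path)
    required = {"index", "aa", "assigned", "ctrl"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    time_cols = [c for c in frame.columns if c.startswith("i") and c[1:].isdigit()]
    times = tuple(sorted(float(c[1:]) for c in time_cols))
    frame = frame.sort_values("index")
    intensities = np.vstack([frame[f"i{int(t)}"].to_numpy(float) for t in times])
    return HDXSeries(
        sequence="".join(frame["aa"]),
        times=times,
        control=frame["ctrl"].to_numpy(float),
        intensities=intensities,
        assigned=frame["assigned"].astype(bool).to_numpy(),
        labels=frame["index"].to_numpy(float),
        name=name,
    )


def write_hdx_map_csv(hdx_map: HDXMap, path: str | Path) -> None:
    hdx_map.to_frame().to_csv(path, index=False)
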