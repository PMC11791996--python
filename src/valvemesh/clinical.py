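"""Hemodynamic indices of aortic stenosis from time-resolved traces and
geometry-derived volumes.

Implements the standard echocardiographic quantities: the dimensionless
velocity index DVI = V_LVOT / V_peak, transvalvular pressure gradients
(measured from paired pressure traces or via the simplified Bernoulli
relation dP = 4 v^2), the Teichholz LV volume estimate
LVV = 7.0 / (2.4 + LVID) * LVID^3, and the ejection fraction
LVEF = 100 (EDV - ESV) / EDV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: CSV column names for flow traces
TRACE_COLUMNS = ("time_s", "v_av_ms", "v_lvot_ms", "p_up_mmHg",
                 "p_down_mmHg", "lv_vol_ml")


@dataclass
class FlowTrace:
    """One or more cardiac cycles of velocity / pressure / volume samples."""

    time: np.ndarray                      # s, strictly increasing
    velocity_av: np.ndarray               # m/s across the aortic valve
    velocity_lvot: np.ndarray | None = None
    pressure_up: np.ndarray | None = None    # mmHg upstream (LV side)
    pressure_down: np.ndarray | None = None  # mmHg downstream (aortic side)
    lv_volume: np.ndarray | None = None      # mL

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name in ("velocity_av", "velocity_lvot", "pressure_up",
                     "pressure_down", "lv_volume"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    @classmethod
    def from_csv(cls, path: str) -> "FlowTrace":
        df = pd.read_csv(path)
        get = lambda col: df[col].to_numpy() if col in df else None
        return cls(df["time_s"].to_numpy(), df["v_av_ms"].to_numpy(),
                   get("v_lvot_ms"), get("p_up_mmHg"), get("p_down_mmHg"),
                   get("lv_vol_ml"))


def dvi(v_lvot: float, v_peak: float) -> float:
    """Dimensionless velocity index V_LVOT / V_peak (flow-independent
    stenosis severity; < 0.25 suggests severe obstruction)."""
    if v_peak <= 0:
        raise ValueError("peak velocity must be positive")
    return float(v_lvot / v_peak)


def teichholz_volume(lvid_cm: float) -> float:
    """Teichholz LV volume (mL) from the internal diameter (cm):
    LVV = 7.0 / (2.4 + LVID) * LVID^3."""
    if lvid_cm <= 0:
        raise ValueError("LV internal diameter must be positive")
    return float(7.0 / (2.4 + lvid_cm) * lvid_cm**3)


def lvef(edv_ml: float, esv_ml: float) -> float:
    """Left ventricular ejection fraction, percent."""
    if edv_ml <= 0:
        raise ValueError("end-diastolic volume must be positive")
    if esv_ml < 0 or esv_ml > edv_ml:
        raise ValueError("need 0 <= ESV <= EDV")
    return float(100.0 * (edv_ml - esv_ml) / edv_ml)


def extract_peaks_and_gradients(trace: FlowTrace,
                                systole_fraction: float = 0.1,
                                ) -> dict[str, float]:
    """Peak AV velocity and peak/mean transvalvular pressure gradients.

    With both pressure traces present, dP(t) = P_up - P_down; dP_max is the
    maximum over systole and dP_mean the mean over the positive-gradient
    interval.  Without pressures, the simplified Bernoulli estimate
    dP = 4 v^2 is used.  Systole is taken as the interval where the AV
    velocity exceeds ``systole_fraction`` of its cycle maximum.
    """
    v = trace.velocity_av
    if v is None or len(v) == 0:
        raise ValueError("trace has no AV velocity samples")
    v_peak = float(np.max(v))
    sys_mask = v >= systole_fraction * v_peak
    if not sys_mask.any():
        sys_mask = np.ones_like(v, dtype=bool)
    if trace.pressure_up is not None and trace.pressure_down is not None:
        dp = trace.pressure_up - trace.pressure_down
        dp_sys = dp[sys_mask]
        dp_max = float(np.max(dp_sys))
        pos = dp_sys > 0
        dp_mean = float(np.mean(dp_sys[pos])) if pos.any() else 0.0
    else:
        dp = 4.0 * v**2
        dp_max = float(np.max(dp[sys_mask]))
        dp_mean = float(np.mean(dp[sys_mask]))
    return {"v_peak": v_peak, "dp_max": dp_max, "dp_mean": dp_mean}


def lvef_from_trace(trace: FlowTrace) -> float:
    """Ejection fraction from the LV volume trace (max = EDV, min = ESV)."""
    if trace.lv_volume is None:
        raise ValueError("trace has no LV volume samples")
    return lvef(float(np.max(trace.lv_volume)), float(np.min(trace.lv_volume)))


def deviation_summary(model: dict[str, float], clinical: dict[str, float],
                      ) -> tuple[dict[str, float], float, float]:
    """Per-metric absolute percent deviation of model vs clinical values,
    with the aggregate mean and (population) standard deviation.

    Metrics with a zero clinical reference are skipped with a warning.
    """
    import warnings
    devs: dict[str, float] = {}
    for key in model:
        if key not in clinical:
            raise ValueError(f"clinical reference missing metric {key!r}")
        if clinical[key] == 0:
            warnings.warn(f"clinical value for {key!r} is zero; skipped")
            continue
        devs[key] = 100.0 * abs(model[key] - clinical[key]) / abs(clinical[key])
    vals = np.array(list(devs.values()))
    return devs, float(vals.mean()), float(vals.std())


def effective_orifice_area(free_edge_points: np.ndarray,
                           annulus_normal: np.ndarray) -> float:
    """Projected orifice area of the leaflet free-edge polygon onto the
    annulus plane (an anatomic EOA interpretation from deformed geometry).

    ``free_edge_points`` must be ordered around the orifice.
    """
    n = np.asarray(annulus_normal, dtype=float)
    n = n / np.linalg.norm(n)
    pts = np.asarray(free_edge_points, dtype=float)
    c = pts.mean(axis=0)
    # in-plane basis
    a = np.eye(3)[np.argmin(np.abs(n))]
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    uv = np.column_stack([(pts - c) @ e1, (pts - c) @ e2])
    x, y = uv[:, 0], uv[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)
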