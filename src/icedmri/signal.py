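"""Multi-echo FLASH signal estimation at desk scale.

Three computations from multiparameter-mapping (MPM) protocols:

* ESTATICS: a joint log-linear OLS fit of mono-exponential echo decay
  across up to three contrast-weighted echo trains (T1w/PDw/MTw) with a
  single common R2* slope and per-contrast TE=0 intercepts.
* The Ernst equation for the steady-state spoiled gradient-echo signal,
  and exact dual-flip-angle inversion for R1 (with the classical
  small-angle rational approximation as a labelled alternative).
* Proton-density calibration: rescaling a PD map so the white-matter
  mean equals 69 percent units.

Echo times are millisecond at the interface and converted to seconds
internally, so relaxation rates come out in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import optimize

__all__ = [
    "EchoSeries",
    "MultiEchoSet",
    "EstaticsResult",
    "PROTOCOL_TE_MS",
    "PROTOCOL_TE_PDW_MS",
    "estatics_fit",
    "ernst_signal",
    "dual_flip_angle_r1",
    "dual_flip_angle_r1_approx",
    "calibrate_pd",
]

# protocol echo times: six equidistant echoes 2.34..14.04 ms for the
# T1w and MTw trains; the PDw train adds echoes at 16.38 and 18.72 ms
PROTOCOL_TE_MS = tuple(np.round(np.linspace(2.34, 14.04, 6), 2))
PROTOCOL_TE_PDW_MS = PROTOCOL_TE_MS + (16.38, 18.72)

PROTOCOL_TR_MS = 24.5
PROTOCOL_FLIP_DEG = {"T1w": 21.0, "PDw": 6.0, "MTw": 6.0}


@dataclass(frozen=True)
class EchoSeries:
    """One contrast-weighted echo train."""

    echo_times_ms: tuple
    signals: tuple
    flip_angle_deg: float
    tr_ms: float

    def __post_init__(self):
        te = np.asarray(self.echo_times_ms, float)
        s = np.asarray(self.signals, float)
        if te.size != s.size:
            raise ValueError("echo_times_ms and signals lengths differ")
        if te.size < 2:
            raise ValueError("at least 2 echoes are required per contrast")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("signals must be positive for log-linear fitting")


@dataclass(frozen=True)
class MultiEchoSet:
    """Up to three labelled echo trains (e.g. T1w, PDw, MTw)."""

    contrasts: Mapping[str, EchoSeries]

    def __post_init__(self):
        if not (1 <= len(self.contrasts) <= 3):
            raise ValueError("between 1 and 3 contrasts are supported")


@dataclass(frozen=True)
class EstaticsResult:
    """Joint-decay fit: common R2* (1/s), per-contrast TE=0 intercepts (a.u.)."""

    r2star: float
    intercepts: dict
    residual_sse: float


def estatics_fit(echoes: MultiEchoSet) -> EstaticsResult:
    """Joint log-linear OLS over all contrasts with one shared decay slope.

    Stacks log-signals of every echo of every contrast; the design has
    one intercept column per contrast and a common -TE column, so the
    slope is the shared R2* and the exponentiated intercepts are the
    contrast signals extrapolated to TE = 0.
    """
    labels = list(echoes.contrasts)
    te_s, logs, which = [], [], []
    for j, lab in enumerate(labels):
        ser = echoes.contrasts[lab]
        te_s.extend(np.asarray(ser.echo_times_ms, float) / 1000.0)
        logs.extend(np.log(np.asarray(ser.signals, float)))
        which.extend([j] * len(ser.signals))
    te_s = np.asarray(te_s)
    logs = np.asarray(logs)
    if np.ptp(te_s) <= 0:
        raise ValueError("degenerate echo-time spread; slope not identifiable")
    X = np.zeros((te_s.size, len(labels) + 1))
    for row, j in enumerate(which):
        X[row, j] = 1.0
    X[:, -1] = -te_s
    beta, _, rank, _ = np.linalg.lstsq(X, logs, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design; fit not identifiable")
    resid = logs - X @ beta
    return EstaticsResult(
        r2star=float(beta[-1]),
        intercepts={lab: float(np.exp(beta[j])) for j, lab in enumerate(labels)},
        residual_sse=float(resid @ resid),
    )


def ernst_signal(
    amplitude: float, r1: float, flip_angle_deg: float, tr_ms: float
) -> float:
    """Steady-state spoiled gradient-echo signal.

    S = A sin(a) (1 - E1) / (1 - cos(a) E1) with E1 = exp(-TR * R1).
    """
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    if not 0 < flip_angle_deg <= 90:
        raise ValueError("flip angle must be in (0, 90] degrees")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    a = np.deg2rad(flip_angle_deg)
    e1 = np.exp(-tr_ms / 1000.0 * r1)
    return float(amplitude * np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1))


_R1_BRACKET = (1e-4, 100.0)  # 1/s


def dual_flip_angle_r1(
    s_low: float,
    s_high: float,
    alpha_low_deg: float,
    alpha_high_deg: float,
    tr_ms: float,
) -> tuple[float, float]:
    """Recover (R1, amplitude) from two spoiled-GRE signals at two flip angles.

    Solves the pair of Ernst equations with a common amplitude exactly,
    by a bracketed root of the signal-ratio equation in R1 on
    (1e-4, 100) 1/s.  Returns ``(r1, amplitude)``.
    """
    if s_low <= 0 or s_high <= 0:
        raise ValueError("signals must be positive")
    if not alpha_low_deg < alpha_high_deg:
        raise ValueError("alpha_low must be smaller than alpha_high")

    al = np.deg2rad(alpha_low_deg)
    ah = np.deg2rad(alpha_high_deg)
    tr_s = tr_ms / 1000.0

    def ratio_mismatch(r1):
        e1 = np.exp(-tr_s * r1)
        return s_low * np.sin(ah) * (1 - np.cos(al) * e1) - s_high * np.sin(al) * (
            1 - np.cos(ah) * e1
        )

    lo, hi = _R1_BRACKET
    flo, fhi = ratio_mismatch(lo), ratio_mismatch(hi)
    if flo == 0.0:
        r1 = lo
    elif np.sign(flo) == np.sign(fhi):
        raise ValueError(
            "no R1 root in (1e-4, 100) 1/s; signals inconsistent with the "
            "Ernst model at these flip angles"
        )
    else:
        r1 = float(optimize.brentq(ratio_mismatch, lo, hi, xtol=1e-12, rtol=1e-14))
    e1 = np.exp(-tr_s * r1)
    amplitude = s_low * (1 - np.cos(al) * e1) / (np.sin(al) * (1 - e1))
    return r1, float(amplitude)


def dual_flip_angle_r1_approx(
    s_low: float,
    s_high: float,
    alpha_low_deg: float,
    alpha_high_deg: float,
    tr_ms: float,
) -> float:
    """Small-angle rational approximation for dual-flip-angle R1.

    R1 ~ (S_high a_high - S_low a_low) / (2 TR (S_low/a_low - S_high/a_high)),
    angles in radians.  Provided for comparison with the exact inversion.
    """
    al = np.deg2rad(alpha_low_deg)
    ah = np.deg2rad(alpha_high_deg)
    tr_s = tr_ms / 1000.0
    num = s_high * ah - s_low * al
    den = 2.0 * tr_s * (s_low / al - s_high / ah)
    if den <= 0:
        raise ValueError("signals inconsistent with the small-angle regime")
    return float(num / den)


def calibrate_pd(pd_map, wm_mask, target: float = 69.0):
    """Scale a PD map so its white-matter mean equals ``target`` (p.u.).

    The global proton-density scale is not identifiable without an
    external standard, so the map is calibrated to a nominal
    white-matter water content of 69 percent units.
    """
    pd_map = np.asarray(pd_map, float)
    wm_mask = np.asarray(wm_mask, bool)
    if wm_mask.shape != pd_map.shape:
        raise ValueError("mask shape does not match map shape")
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    mean = pd_map[wm_mask].mean()
    if mean <= 0:
        raise ValueError("masked mean must be positive for calibration")
    return pd_map * (target / mean)
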