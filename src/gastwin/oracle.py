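"""Steady-state multi-compartment pulmonary gas-exchange simulator.

Maps a 19-parameter virtual-patient state to the four arterial blood-gas
markers (PaO2, PaCO2, HCO3, pH).  The lung is a set of ``N_comp`` parallel
alveolar compartments whose ventilation and perfusion shares derive from
affine resistance profiles; venous admixture combines an anatomical shunt
with closed (de-recruited) compartments, partially re-opened by PEEP.

Model summary
-------------
* O2 carriage: Severinghaus haemoglobin saturation
  ``S(P) = 1 / (23400 / (P^3 + 150 P) + 1)`` plus dissolved O2;
  content ``C = 1.34 * Hb[g/dL] * S(P) + 0.003 * P`` (mL/dL).
* CO2 carriage: linearised content curve ``C = 48 + 0.7 (P - 40)`` (mL/dL).
* Per-compartment steady state: bisection on the CO2 ventilation–perfusion
  mass balance ``VA/Q = 8.63 * (CvCO2 - C(PACO2)) / PACO2``; alveolar O2
  from the alveolar gas equation ``PAO2 = PiO2 - PACO2 / RQ``.
* Mixing: flow-weighted end-capillary contents plus shunted mixed-venous
  blood; arterial pressures recovered by inverting the content curves.
* Acid–base: Henderson–Hasselbalch with a Van Slyke base-excess relation,
  solved for pH by bisection.

This is a steady-state model: the intra-breath inputs ``IE_ratio`` and
``P_EI`` are carried in the state but do not influence the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import INPUT_COLUMNS, OUTPUT_COLUMNS, SchemaError

__all__ = [
    "OracleConstants", "GasOutputs", "ConvergenceError", "PhysiologicRangeError",
    "saturation", "o2_pressure_from_saturation", "blood_o2_content",
    "o2_pressure_from_content", "blood_co2_content", "co2_pressure_from_content",
    "alveolar_ventilation", "effective_shunt", "compartment_weights",
    "solve_compartment", "solve_acid_base", "simulate", "simulate_batch",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Iterative solver failed to converge; carries the last iterate."""

    def __init__(self, message: str, last=None, residual=None):
        super().__init__(message)
        self.last = last
        self.residual = residual


class PhysiologicRangeError(ValueError):
    """A quantity left the solvable physiologic envelope."""


@dataclass(frozen=True)
class OracleConstants:
    """Fixed physical constants and solver settings of the simulator."""

    Pb: float = 760.0          # barometric pressure, mmHg
    PH2O: float = 47.0         # saturated water vapour pressure, mmHg
    hufner: float = 1.34       # Huefner number, mL O2 per g Hb
    alpha_O2: float = 0.003    # dissolved O2, mL/dL/mmHg
    hb_convert: float = 1.611  # g/dL per mmol/L of haemoglobin
    co2_c0: float = 48.0       # CO2 content at 40 mmHg, mL/dL
    co2_slope: float = 0.7     # CO2 content slope, mL/dL/mmHg
    k_vent: float = 863.0      # BTPS/STPD ventilation constant, mmHg
    N_comp: int = 100          # alveolar compartments
    tol_P: float = 0.01        # pressure convergence tolerance, mmHg
    max_iter: int = 200

    def __post_init__(self):
        for f in ("Pb", "PH2O", "hufner", "alpha_O2", "hb_convert",
                  "co2_c0", "co2_slope", "k_vent", "N_comp", "tol_P"):
            if getattr(self, f) <= 0:
                raise ValueError(f"constant {f} must be positive")
        if self.tol_P > 0.1:
            raise ValueError("tol_P must be <= 0.1 mmHg")

    @property
    def PiO2_factor(self) -> float:
        """Inspired PO2 per unit FiO2 fraction: Pb - PH2O (mmHg)."""
        return self.Pb - self.PH2O


DEFAULT_CONSTANTS = OracleConstants()


@dataclass(frozen=True)
class GasOutputs:
    """Arterial blood-gas markers produced per patient state."""

    PaO2: float    # mmHg
    PaCO2: float   # mmHg
    HCO3: float    # mmol/L
    pH: float      # dimensionless

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.PaO2, self.PaCO2, self.HCO3, self.pH)


# ----------------------------------------------------------------------
# Blood gas carriage
# ----------------------------------------------------------------------

def saturation(P):
    """Haemoglobin O2 saturation (Severinghaus) as a fraction in (0, 1)."""
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise PhysiologicRangeError("saturation requires PO2 > 0 mmHg")
    s = 1.0 / (23400.0 / (P ** 3 + 150.0 * P) + 1.0)
    return s if s.ndim else float(s)


def o2_pressure_from_saturation(S, lo: float = 0.5, hi: float = 700.0,
                                iters: int = 60):
    """Invert :func:`saturation` by bisection on [lo, hi] mmHg.

    Saturations above ``saturation(hi)`` are clamped to ``hi`` (the curve is
    asymptotically flat there and the pressure is no longer identifiable).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0) or np.any(S >= 1):
        raise PhysiologicRangeError("saturation must lie strictly in (0, 1)")
    target = np.minimum(S, saturation(hi))
    a = np.full_like(target, lo)
    b = np.full_like(target, hi)
    for _ in range(iters):
        m = 0.5 * (a + b)
        high = saturation(m) >= target
        b = np.where(high, m, b)
        a = np.where(high, a, m)
    m = 0.5 * (a + b)
    return m if m.ndim else float(m)


def blood_o2_content(P, Hb_mmolL, constants: OracleConstants = DEFAULT_CONSTANTS):
    """Whole-blood O2 content (mL/dL): Hb-bound plus dissolved."""
    Hb = np.asarray(Hb_mmolL, dtype=float)
    if np.any(Hb < 0):
        raise PhysiologicRangeError("haemoglobin must be >= 0")
    c = (constants.hufner * constants.hb_convert * Hb * saturation(P)
         + constants.alpha_O2 * np.asarray(P, dtype=float))
    return c if np.ndim(c) else float(c)


def o2_pressure_from_content(C, Hb_mmolL,
                             constants: OracleConstants = DEFAULT_CONSTANTS,
                             lo: float = 0.05, hi: float = 713.001,
                             iters: int = 60):
    """Invert :func:`blood_o2_content` in P by bisection (content monotone)."""
    C = np.asarray(C, dtype=float)
    Hb = np.broadcast_to(np.asarray(Hb_mmolL, dtype=float), C.shape)
    c_lo = blood_o2_content(lo, Hb, constants)
    c_hi = blood_o2_content(hi, Hb, constants)
    if np.any(C < c_lo) or np.any(C > c_hi):
        raise PhysiologicRangeError(
            "O2 content outside invertible range of the dissociation curve")
    a = np.full_like(C, lo)
    b = np.full_like(C, hi)
    for _ in range(iters):
        m = 0.5 * (a + b)
        high = blood_o2_content(m, Hb, constants) >= C
        b = np.where(high, m, b)
        a = np.where(high, a, m)
    m = 0.5 * (a + b)
    return m if m.ndim else float(m)


def blood_co2_content(P, constants: OracleConstants = DEFAULT_CONSTANTS):
    """Linearised whole-blood CO2 content (mL/dL)."""
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise PhysiologicRangeError("blood_co2_content requires PCO2 > 0")
    c = constants.co2_c0 + constants.co2_slope * (P - 40.0)
    return c if c.ndim else float(c)


def co2_pressure_from_content(C, constants: OracleConstants = DEFAULT_CONSTANTS):
    """Exact inverse of :func:`blood_co2_content` (the curve is linear)."""
    C = np.asarray(C, dtype=float)
    P = 40.0 + (C - constants.co2_c0) / constants.co2_slope
    if np.any(P <= 0):
        raise PhysiologicRangeError("CO2 content below the curve floor")
    return P if P.ndim else float(P)


# ----------------------------------------------------------------------
# Ventilation, shunt and compartment structure
# ----------------------------------------------------------------------

def alveolar_ventilation(state: Mapping,
                         constants: OracleConstants = DEFAULT_CONSTANTS):
    """Alveolar ventilation VA (L/min): RR * (Vt - VD), floored.

    The floor ``0.2 * Vt`` guards against non-positive fresh-gas flow when
    the sampled deadspace exceeds the tidal volume.
    """
    RR = np.asarray(state["RR"], dtype=float)
    Vt_L = np.asarray(state["Vt"], dtype=float) / 1000.0
    VD = np.asarray(state["VD_phys"], dtype=float)
    va = RR * np.maximum(Vt_L - VD, 0.2 * Vt_L)
    return va if va.ndim else float(va)


def effective_shunt(state: Mapping,
                    constants: OracleConstants = DEFAULT_CONSTANTS):
    """Total venous-admixture fraction Qs/Qt in [0, 0.95].

    Anatomical shunt plus the closed-compartment fraction, the latter
    linearly recruited away as PEEP rises to 20 cmH2O.
    """
    asht = np.asarray(state["asht"], dtype=float)
    v_nc = np.asarray(state["v_nc"], dtype=float)
    peep = np.asarray(state["PEEP"], dtype=float)
    recruit = 1.0 - np.minimum(peep / 20.0, 1.0)
    f = np.clip(asht + (v_nc / constants.N_comp) * recruit, 0.0, 0.95)
    return f if f.ndim else float(f)


def compartment_weights(state: Mapping, N: int | None = None,
                        constants: OracleConstants = DEFAULT_CONSTANTS
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Normalised ventilation and perfusion shares of the open compartments.

    Compartment ``i`` (of ``N_open = N - v_nc``) sits at grid position
    ``x_i = i / N`` and has flow resistance ``v_inR + v_sR * x_i`` and
    vascular resistance ``v_inVR + v_sVR * x_i``; shares are proportional
    to the reciprocal resistances.
    """
    if N is None:
        N = constants.N_comp
    v_nc = int(state["v_nc"])
    n_open = N - v_nc
    if n_open < 1:
        raise PhysiologicRangeError(
            f"degenerate lung: v_nc={v_nc} closes all {N} compartments")
    x = np.arange(1, n_open + 1) / N
    R = float(state["v_inR"]) + float(state["v_sR"]) * x
    VR = float(state["v_inVR"]) + float(state["v_sVR"]) * x
    if np.any(R <= 0) or np.any(VR <= 0):
        raise PhysiologicRangeError("non-positive compartment resistance")
    v = (1.0 / R) / np.sum(1.0 / R)
    q = (1.0 / VR) / np.sum(1.0 / VR)
    return v, q


# ----------------------------------------------------------------------
# Per-compartment steady state
# ----------------------------------------------------------------------

def _bisect_compartment_co2(vaq, CvCO2, constants, iters: int = 55):
    """Vectorised bisection for alveolar PCO2 from the V/Q CO2 mass balance.

    Solves ``vaq * P = 8.63 * (CvCO2 - C(P))`` on the bracket
    ``(0.1, P(CvCO2))``; the upper end is the venous-equivalent pressure at
    which gas exchange would vanish.
    """
    kc = constants.k_vent / 100.0  # content is per dL; 863/100 = 8.63
    lo = np.full(np.shape(vaq), 0.1)
    hi = np.maximum(co2_pressure_from_content(CvCO2, constants), 0.2)
    hi = np.broadcast_to(hi, lo.shape).copy()

    def g(P):
        return vaq * P - kc * (CvCO2 - blood_co2_content(P, constants))

    if np.any(g(lo) > 0) or np.any(g(hi) < 0):
        raise ConvergenceError(
            "no sign change bracketing the compartment CO2 balance",
            last=vaq)
    a, b = lo, hi
    for _ in range(iters):
        m = 0.5 * (a + b)
        pos = g(m) >= 0
        b = np.where(pos, m, b)
        a = np.where(pos, a, m)
    return 0.5 * (a + b)


def solve_compartment(vaq, venous: tuple, FiO2, RQ, Hb,
                      constants: OracleConstants = DEFAULT_CONSTANTS):
    """Steady state of one (or an array of) alveolar compartment(s).

    Parameters
    ----------
    vaq
        Ventilation/perfusion ratio(s), > 0.
    venous
        ``(CvO2, CvCO2)`` mixed-venous contents in mL/dL.
    FiO2
        Inspired O2 fraction in percent.
    RQ, Hb
        Respiratory quotient and haemoglobin (mmol/L).

    Returns
    -------
    (PAO2, PACO2, CcO2, CcCO2)
        Alveolar pressures (mmHg) and end-capillary contents (mL/dL).
    """
    vaq = np.asarray(vaq, dtype=float)
    if np.any(vaq <= 0):
        raise PhysiologicRangeError("V/Q ratio must be > 0")
    _, CvCO2 = venous
    PACO2 = _bisect_compartment_co2(vaq, CvCO2, constants)
    PiO2 = np.asarray(FiO2, dtype=float) / 100.0 * constants.PiO2_factor
    PAO2 = np.maximum(PiO2 - PACO2 / np.asarray(RQ, dtype=float), 0.5)
    CcO2 = blood_o2_content(PAO2, Hb, constants)
    CcCO2 = blood_co2_content(PACO2, constants)
    return PAO2, PACO2, CcO2, CcCO2


# ----------------------------------------------------------------------
# Acid–base
# ----------------------------------------------------------------------

def solve_acid_base(PaCO2, BE_a,
                    constants: OracleConstants = DEFAULT_CONSTANTS,
                    iters: int = 60):
    """pH and bicarbonate from PaCO2 and base excess.

    Bisection on pH in [6.5, 7.9] of the Van Slyke relation
    ``BE = 0.9287 * (HCO3 - 24.4 + 14.83 * (pH - 7.4))`` with
    Henderson–Hasselbalch ``HCO3 = 0.03 * PaCO2 * 10^(pH - 6.1)``.
    The left-hand side is strictly increasing in pH, so the root is unique.
    """
    PaCO2 = np.asarray(PaCO2, dtype=float)
    BE = np.asarray(BE_a, dtype=float)
    if np.any(PaCO2 <= 5.0) or np.any(PaCO2 >= 250.0):
        raise PhysiologicRangeError("PaCO2 outside solvable range (5, 250) mmHg")
    if np.any(np.abs(BE) > 30.0):
        raise PhysiologicRangeError("base excess outside [-30, 30] mmol/L")

    def hco3(ph):
        return 0.03 * PaCO2 * 10.0 ** (ph - 6.1)

    def g(ph):
        return 0.9287 * (hco3(ph) - 24.4 + 14.83 * (ph - 7.4)) - BE

    a = np.full(np.broadcast(PaCO2, BE).shape, 6.5)
    b = np.full_like(a, 7.9)
    if np.any(g(a) > 0) or np.any(g(b) < 0):
        raise PhysiologicRangeError("acid-base root outside pH [6.5, 7.9]")
    for _ in range(iters):
        m = 0.5 * (a + b)
        pos = g(m) >= 0
        b = np.where(pos, m, b)
        a = np.where(pos, a, m)
    ph = 0.5 * (a + b)
    hc = hco3(ph)
    if ph.ndim:
        return ph, hc
    return float(ph), float(hc)


# ----------------------------------------------------------------------
# Whole-patient steady state
# ----------------------------------------------------------------------

def _simulate_arrays(cols: Mapping[str, np.ndarray],
                     constants: OracleConstants):
    """Vectorised steady state for ``n`` patient states.

    Returns ``(outputs, ok, diag)`` where ``outputs`` is an ``(n, 4)`` array
    of (PaO2, PaCO2, HCO3, pH), ``ok`` a boolean convergence/validity mask
    and ``diag`` a dict of per-row bookkeeping quantities (valid where ok).

    The CO2 side of the model is affine in the arterial CO2 content, so the
    outer fixed point on PaCO2 is solved by secant acceleration and then
    verified against ``tol_P``.
    """
    n = len(next(iter(cols.values())))
    N = constants.N_comp
    out = np.full((n, 4), np.nan)
    ok = np.ones(n, dtype=bool)
    diag = {k: np.full(n, np.nan) for k in
            ("o2_uptake_comp", "o2_uptake_art", "co2_output", "vco2_target",
             "shunt", "VA")}
    if n == 0:
        return out, ok, diag

    v_nc = cols["v_nc"].astype(int)
    ok &= v_nc < N
    ok &= (cols["SvO2"] > 0) & (cols["SvO2"] < 100)

    # compartment grid and weights, masked over closed compartments
    x = np.arange(1, N + 1)[None, :] / N                    # (1, N)
    open_mask = np.arange(N)[None, :] < (N - v_nc)[:, None]  # (n, N)
    R = cols["v_inR"][:, None] + cols["v_sR"][:, None] * x
    VR = cols["v_inVR"][:, None] + cols["v_sVR"][:, None] * x
    ok &= ~np.any((R <= 0) & open_mask, axis=1)
    ok &= ~np.any((VR <= 0) & open_mask, axis=1)
    R = np.where(open_mask & (R > 0), R, np.inf)
    VR = np.where(open_mask & (VR > 0), VR, np.inf)
    v = (1.0 / R) / np.sum(1.0 / R, axis=1, keepdims=True)
    q = (1.0 / VR) / np.sum(1.0 / VR, axis=1, keepdims=True)

    VA = np.asarray(alveolar_ventilation(cols, constants), dtype=float)
    shunt = np.asarray(effective_shunt(cols, constants), dtype=float)
    CO = cols["CO"]
    Q_comp = CO * (1.0 - shunt)
    ok &= (VA > 0) & (Q_comp > 0)

    # mixed-venous O2 anchored to the SvO2 input
    sv = np.clip(cols["SvO2"] / 100.0, 1e-6, 1.0 - 1e-9)
    PvO2 = o2_pressure_from_saturation(np.where(ok, sv, 0.5))
    CvO2 = blood_o2_content(PvO2, cols["Hb"], constants)

    vco2 = cols["RQ"] * cols["VO2"]            # L/min STPD
    dC_v = 100.0 * vco2 / CO                   # venous-arterial CO2 content gap

    safe = ok.copy()
    vaq = np.where(open_mask, (VA[:, None] * v)
                   / np.maximum(Q_comp[:, None] * q, 1e-300), 1.0)
    vaq = np.clip(vaq, 1e-6, 1e6)

    def step(PaCO2_guess, idx):
        """Outer map PaCO2 -> mixed arterial PaCO2, on the row subset idx."""
        PaCO2_guess = np.clip(PaCO2_guess, 1.0, 400.0)
        CaCO2 = blood_co2_content(PaCO2_guess, constants)
        CvCO2 = CaCO2 + dC_v[idx]
        PACO2 = _bisect_compartment_co2(vaq[idx], CvCO2[:, None], constants)
        PiO2 = cols["FiO2"][idx, None] / 100.0 * constants.PiO2_factor
        PAO2 = np.maximum(PiO2 - PACO2 / cols["RQ"][idx, None], 0.5)
        CcO2 = blood_o2_content(PAO2, cols["Hb"][idx, None], constants)
        CcCO2 = blood_co2_content(PACO2, constants)
        om = open_mask[idx]
        qi = q[idx]
        mixCc_O2 = np.sum(np.where(om, qi * CcO2, 0.0), axis=1)
        mixCc_CO2 = np.sum(np.where(om, qi * CcCO2, 0.0), axis=1)
        CaO2_new = (1.0 - shunt[idx]) * mixCc_O2 + shunt[idx] * CvO2[idx]
        CaCO2_new = (1.0 - shunt[idx]) * mixCc_CO2 + shunt[idx] * CvCO2
        return co2_pressure_from_content(CaCO2_new, constants), CaO2_new, mixCc_O2

    all_idx = np.arange(n)
    x1_full = np.full(n, 40.0)
    converged_full = np.zeros(n, dtype=bool)

    active = all_idx[safe]
    x0 = np.full(len(active), 40.0)
    f0, _, _ = step(x0, active)
    done = np.abs(f0 - x0) < constants.tol_P
    x1_full[active] = np.clip(f0, 1.0, 400.0)
    converged_full[active] = done
    x0_a, f0_a = x0[~done], f0[~done]
    active = active[~done]
    it = 0
    while len(active) and it < constants.max_iter:
        x1 = x1_full[active]
        f1, _, _ = step(x1, active)
        denom = x1 - x0_a
        ok_d = np.abs(denom) > 1e-12
        m = np.where(ok_d, (f1 - f0_a) / np.where(ok_d, denom, 1.0), 0.0)
        # secant fixed point of the affine map; fall back to plain iteration
        contr = np.abs(1.0 - m) > 1e-9
        x_next = np.where(contr, (f0_a - m * x0_a) / np.where(contr, 1.0 - m, 1.0),
                          f1)
        x_next = np.clip(x_next, 1.0, 400.0)
        done = np.abs(f1 - x1) < constants.tol_P
        converged_full[active[done]] = True
        keep = ~done
        x1_full[active[keep]] = x_next[keep]
        x0_a, f0_a = x1[keep], f1[keep]
        active = active[keep]
        it += 1
    safe &= converged_full
    PaCO2 = np.full(n, 40.0)
    CaO2 = np.full(n, np.nan)
    mixCc_O2 = np.full(n, np.nan)
    safe_idx = all_idx[safe]
    if len(safe_idx):
        PaCO2_s, CaO2_s, mix_s = step(x1_full[safe_idx], safe_idx)
        PaCO2[safe_idx] = PaCO2_s
        CaO2[safe_idx] = CaO2_s
        mixCc_O2[safe_idx] = mix_s

    # arterial O2 tension from the mixed content
    try:
        PaO2 = o2_pressure_from_content(np.where(safe, CaO2, 10.0),
                                        cols["Hb"], constants)
    except PhysiologicRangeError:
        PaO2 = np.full(n, np.nan)
        for i in range(n):
            if not safe[i]:
                continue
            try:
                PaO2[i] = o2_pressure_from_content(CaO2[i], cols["Hb"][i],
                                                   constants)
            except PhysiologicRangeError:
                safe[i] = False

    # acid-base; rows outside the solvable envelope are flagged, not raised
    inrange = safe & (PaCO2 > 5.0) & (PaCO2 < 250.0) & (np.abs(cols["BE_a"]) <= 30)
    ph = np.full(n, np.nan)
    hco3 = np.full(n, np.nan)
    if np.any(inrange):
        pc = np.where(inrange, PaCO2, 40.0)
        be = np.where(inrange, cols["BE_a"], 0.0)
        g_lo = 0.9287 * (0.03 * pc * 10 ** (6.5 - 6.1) - 24.4 + 14.83 * (6.5 - 7.4)) - be
        g_hi = 0.9287 * (0.03 * pc * 10 ** (7.9 - 6.1) - 24.4 + 14.83 * (7.9 - 7.4)) - be
        bracketed = (g_lo <= 0) & (g_hi >= 0)
        inrange &= bracketed
        if np.any(inrange):
            ph_v, hco3_v = solve_acid_base(np.where(inrange, PaCO2, 40.0),
                                           np.where(inrange, cols["BE_a"], 0.0),
                                           constants)
            ph = np.where(inrange, ph_v, np.nan)
            hco3 = np.where(inrange, hco3_v, np.nan)
    safe = inrange

    out[:, 0] = PaO2
    out[:, 1] = PaCO2
    out[:, 2] = hco3
    out[:, 3] = ph

    diag["shunt"] = shunt
    diag["VA"] = VA
    diag["vco2_target"] = vco2
    diag["o2_uptake_comp"] = Q_comp * (mixCc_O2 - CvO2) / 100.0
    diag["o2_uptake_art"] = CO * (CaO2 - CvO2) / 100.0
    CaCO2_final = blood_co2_content(np.where(safe, PaCO2, 40.0), constants)
    diag["co2_output"] = CO * ((CaCO2_final + dC_v) - CaCO2_final) / 100.0
    return out, safe, diag


def _state_to_cols(state: Mapping) -> dict[str, np.ndarray]:
    missing = [c for c in INPUT_COLUMNS if c not in state]
    if missing:
        raise SchemaError(f"patient state missing field(s): {missing}")
    return {c: np.atleast_1d(np.asarray(state[c], dtype=float))
            for c in INPUT_COLUMNS}


def simulate(state: Mapping,
             constants: OracleConstants = DEFAULT_CONSTANTS,
             full_output: bool = False):
    """Steady-state blood gases for one patient state.

    Parameters
    ----------
    state
        Mapping with the 19 input fields.
    full_output
        If true also return the mass-balance diagnostics dict.

    Raises
    ------
    ConvergenceError / PhysiologicRangeError
        If the state admits no steady state inside the physiologic envelope.
    """
    cols = _state_to_cols(state)
    out, ok, diag = _simulate_arrays(cols, constants)
    if not ok[0]:
        raise ConvergenceError(
            "no physiologic steady state for this patient state",
            last=out[0], residual=None)
    gas = GasOutputs(*[float(v) for v in out[0]])
    if full_output:
        return gas, {k: float(v[0]) for k, v in diag.items()}
    return gas


def simulate_batch(table: pd.DataFrame, workers: int = 1,
                   constants: OracleConstants = DEFAULT_CONSTANTS
                   ) -> pd.DataFrame:
    """Label a cohort with the four simulator outputs.

    Row order follows the input regardless of ``workers``; rows with no
    physiologic steady state are dropped (count logged).

    Raises
    ------
    RuntimeError
        If every row fails.
    """
    extra = [c for c in table.columns if c not in INPUT_COLUMNS]
    if extra or list(table.columns)[:19] != list(INPUT_COLUMNS):
        raise SchemaError(
            f"simulate_batch expects an inputs-only cohort table; got columns "
            f"{list(table.columns)}")
    n = len(table)
    if n == 0:
        empty = table.copy()
        for c in OUTPUT_COLUMNS:
            empty[c] = pd.Series(dtype=float)
        return empty

    cols = {c: table[c].to_numpy(dtype=float) for c in INPUT_COLUMNS}
    if workers > 1:
        from joblib import Parallel, delayed
        bounds = np.array_split(np.arange(n), workers)
        parts = Parallel(n_jobs=workers)(
            delayed(_simulate_arrays)(
                {c: a[idx] for c, a in cols.items()}, constants)
            for idx in bounds if len(idx))
        out = np.concatenate([p[0] for p in parts], axis=0)
        ok = np.concatenate([p[1] for p in parts], axis=0)
    else:
        out, ok, _ = _simulate_arrays(cols, constants)

    n_fail = int(np.sum(~ok))
    if n_fail == n:
        raise RuntimeError(f"all {n} rows failed to reach a steady state")
    if n_fail:
        logger.info("simulate_batch: dropped %d of %d rows with no "
                    "physiologic steady state", n_fail, n)
    labelled = table.loc[ok].reset_index(drop=True).copy()
    for j, c in enumerate(OUTPUT_COLUMNS):
        labelled[c] = out[ok, j]
    return labelled
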