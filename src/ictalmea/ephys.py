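"""Single-neuron chloride electrophysiology calculations.

Covers the quantities needed to interpret GABA_A receptor signalling in
whole-cell voltage-clamp experiments on pyramidal neurons:

* intracellular bicarbonate from the Henderson–Hasselbalch relation at fixed pCO2;
* the Goldman–Hodgkin–Katz (GHK) reversal potential of the Cl-/HCO3--permeable
  GABA_A channel, its pure-Cl- (Nernst) limit, and the algebraic inversion that
  converts a reversal shift into an intracellular Cl- concentration;
* reversal-potential estimation from I–V point sets (zero crossing of an
  ordinary-least-squares line) and the GABA_A driving force;
* liquid junction potentials by the generalized Henderson equation with a bundled
  relative-mobility table;
* whole-cell capacitance and series resistance from the slow capacitive transient
  evoked by a rectangular voltage step;
* series-resistance stability quality control;
* tonic GABA_A current estimation as the shift between the modes of all-point
  current histograms recorded before and during GABA_A blockade.

Conventions: potentials in mV, currents in pA, concentrations in mmol/L,
resistances in MOhm, capacitances in pF, temperatures in K.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ictalmea.errors import ConfigError, DomainError, EstimationError

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Relative ionic mobilities (K+ == 1) for the generalized Henderson equation.
#: Values from the limiting-conductivity compilations used by junction-potential
#: calculators (Barry & Lynch 1991, J Membr Biol 121:101; Ng & Barry 1995,
#: J Neurosci Methods 56:37).
RELATIVE_MOBILITIES: dict[str, float] = {
    "H": 4.757,
    "Li": 0.526,
    "Na": 0.682,
    "K": 1.0,
    "Cs": 1.050,
    "Mg": 0.361,
    "Ca": 0.4048,
    "Cl": 1.0388,
    "Br": 1.063,
    "F": 0.753,
    "HCO3": 0.605,
    "NO3": 0.972,
    "H2PO4": 0.449,
    "HPO4": 0.390,
    "SO4": 0.544,
    "acetate": 0.556,
    "gluconate": 0.33,
    "methanesulfonate": 0.663,
    "HEPES": 0.301,
    "EGTA": 0.243,
}


def thermal_voltage_mv(temperature_k: float) -> float:
    """RT/F in mV (~26.3 mV at 32 degC); computed, never hard-coded."""
    return GAS_CONSTANT * temperature_k / FARADAY * 1000.0


@dataclass
class IonConditions:
    """Ionic conditions entering the GHK reversal for a Cl-/HCO3- permeable channel.

    ``perm_ratio`` is the HCO3-/Cl- permeability ratio (0.3 for GABA_A receptors).
    The default temperature is the 32 degC bath temperature of slice experiments.
    """

    cl_i_mM: float
    cl_o_mM: float
    hco3_i_mM: float = 16.41
    hco3_o_mM: float = 26.0
    perm_ratio: float = 0.3
    temperature_K: float = 305.15
    ph_i: float | None = None
    ph_o: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl_i_mM", "cl_o_mM", "hco3_i_mM", "hco3_o_mM"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.perm_ratio < 0:
            raise ConfigError("perm_ratio must be >= 0")
        if self.temperature_K <= 0:
            raise ConfigError("temperature_K must be > 0")


@dataclass
class IVCurve:
    """GABA_A current amplitudes versus (junction-corrected) command voltage."""

    points: list[tuple[float, float]]  # (v_mV, i_pA)
    site: str = "soma"
    ljp_mV: float = 0.0
    ljp_corrected: bool = True
    ejection_distance_um: float | None = None

    def __post_init__(self) -> None:
        if len({v for v, _ in self.points}) < 2:
            raise ConfigError("IVCurve needs >= 2 distinct voltages")
        if self.site not in ("soma", "dendrite"):
            raise ConfigError(f"site must be soma|dendrite, got {self.site!r}")


@dataclass
class ReversalEstimate:
    """Reversal potential from an I–V zero crossing, with the fitted line."""

    e_gaba_mV: float
    site: str
    df_mV: float | None  # driving force E_GABA - V_rest
    slope_nS: float
    residual_pA: float
    flagged_negative_slope: bool = False


@dataclass
class SolutionComposition:
    """An electrolyte solution as (species, charge, concentration) triples.

    Mobilities are looked up in :data:`RELATIVE_MOBILITIES` unless supplied in
    ``extra_mobilities``.
    """

    species: list[tuple[str, int, float]]  # (name, charge, concentration_mM)
    extra_mobilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species:
            raise ConfigError("solution must contain at least one species")
        for name, charge, conc in self.species:
            if conc < 0:
                raise ConfigError(f"negative concentration for {name}")
            if charge == 0:
                raise ConfigError(f"species {name} has zero charge")

    def mobility(self, name: str) -> float:
        if name in self.extra_mobilities:
            return self.extra_mobilities[name]
        try:
            return RELATIVE_MOBILITIES[name]
        except KeyError:
            raise KeyError(
                f"no relative mobility for species {name!r}; supply it via extra_mobilities"
            ) from None


@dataclass
class TonicResult:
    """Tonic GABA_A current as a holding-current shift under receptor blockade."""

    i_hold_before_pA: float
    i_hold_during_pA: float
    tonic_pA: float
    capacity_pF: float | None = None
    density_pA_per_pF: float | None = None
    rs_before_MOhm: float | None = None
    rs_during_MOhm: float | None = None
    qc_pass: bool | None = None
    ambiguous_before: bool = False
    ambiguous_during: bool = False


def hh_bicarbonate(ph_i: float, ph_o: float, hco3_o_mM: float = 26.0) -> float:
    """Intracellular bicarbonate from the Henderson–Hasselbalch relation.

    Assumes CO2 equilibrates freely across the membrane (equal pCO2 inside and
    out), so [HCO3-]_i = [HCO3-]_o * 10**(pH_i - pH_o).  At pH_i 7.2, pH_o 7.4
    and 26 mmol/L extracellular bicarbonate this gives 16.41 mmol/L.
    """
    for name, ph in (("ph_i", ph_i), ("ph_o", ph_o)):
        if not 0.0 < ph < 14.0:
            raise ConfigError(f"{name} out of range (0, 14): {ph}")
    if hco3_o_mM <= 0:
        raise ConfigError("hco3_o_mM must be > 0")
    return hco3_o_mM * 10.0 ** (ph_i - ph_o)


def ghk_reversal(c: IonConditions) -> float:
    """GHK reversal potential (mV) of a channel permeable to Cl- and HCO3-.

    Anion convention: E = (RT/F) ln[(Cl_i + r HCO3_i) / (Cl_o + r HCO3_o)].
    With ``perm_ratio`` r = 0 this reduces to the Cl- Nernst potential.
    """
    vt = thermal_voltage_mv(c.temperature_K)
    num = c.cl_i_mM + c.perm_ratio * c.hco3_i_mM
    den = c.cl_o_mM + c.perm_ratio * c.hco3_o_mM
    return vt * math.log(num / den)


def nernst_cl(cl_i_mM: float, cl_o_mM: float, temperature_K: float = 305.15) -> float:
    """Cl- Nernst potential (mV); the r = 0 limit of :func:`ghk_reversal`."""
    return ghk_reversal(
        IonConditions(cl_i_mM=cl_i_mM, cl_o_mM=cl_o_mM, perm_ratio=0.0, temperature_K=temperature_K)
    )


def invert_ghk_cl(e_mV: float, c: IonConditions) -> float:
    """Intracellular Cl- implied by a reversal potential; inverse of :func:`ghk_reversal`.

    ``c.cl_i_mM`` is ignored (it is the unknown).  Raises :class:`DomainError`
    when the requested reversal would require a non-positive [Cl-]_i, reporting
    the most negative attainable reversal.
    """
    vt = thermal_voltage_mv(c.temperature_K)
    den = c.cl_o_mM + c.perm_ratio * c.hco3_o_mM
    cl_i = math.exp(e_mV / vt) * den - c.perm_ratio * c.hco3_i_mM
    if cl_i <= 0:
        bound = vt * math.log(c.perm_ratio * c.hco3_i_mM / den) if c.perm_ratio > 0 else -math.inf
        raise DomainError(
            f"E = {e_mV:.3f} mV implies [Cl-]_i = {cl_i:.6g} <= 0 mmol/L; "
            f"the HCO3- leak bounds the reversal below by {bound:.3f} mV"
        )
    return cl_i


def estimate_reversal_from_iv(iv: IVCurve, v_rest_mV: float | None = None) -> ReversalEstimate:
    """Reversal potential from the zero crossing of an OLS line through (V, I).

    E is the voltage where the fitted current is zero; the slope is the chord
    conductance in nS (pA/mV).  A zero slope is an estimation error; a negative
    slope (non-physiological for an agonist-evoked conductance) is returned but
    flagged.
    """
    v = np.array([p[0] for p in iv.points], dtype=float)
    i = np.array([p[1] for p in iv.points], dtype=float)
    if np.ptp(i) == 0.0:
        raise EstimationError("all currents identical; I-V slope is zero, no reversal crossing")
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0.0:
        raise EstimationError("I-V slope is zero; no reversal crossing")
    e_gaba = -intercept / slope
    resid = float(np.sqrt(np.mean((slope * v + intercept - i) ** 2)))
    df = None if v_rest_mV is None else float(e_gaba - v_rest_mV)
    return ReversalEstimate(
        e_gaba_mV=float(e_gaba),
        site=iv.site,
        df_mV=df,
        slope_nS=float(slope),
        residual_pA=resid,
        flagged_negative_slope=bool(slope < 0),
    )


def ljp_henderson(
    pipette: SolutionComposition,
    bath: SolutionComposition,
    temperature_K: float = 305.15,
) -> float:
    """Liquid junction potential (mV) by the generalized Henderson equation.

    Returns the potential of the bath relative to the pipette solution, i.e. the
    value to subtract from command potentials when correcting offline.  With a
    slow anion (e.g. gluconate) in the pipette the result is positive, matching
    the sign of published whole-cell corrections.
    """
    names = sorted(
        {n for n, _, _ in pipette.species} | {n for n, _, _ in bath.species}
    )
    cp = {n: 0.0 for n in names}
    cb = {n: 0.0 for n in names}
    charge: dict[str, int] = {}
    for sol, cc in ((pipette, cp), (bath, cb)):
        for n, z, conc in sol.species:
            cc[n] += conc
            if n in charge and charge[n] != z:
                raise ConfigError(f"species {n} declared with conflicting charges")
            charge[n] = z

    def mob(n: str) -> float:
        if n in pipette.extra_mobilities:
            return pipette.extra_mobilities[n]
        if n in bath.extra_mobilities:
            return bath.extra_mobilities[n]
        try:
            return RELATIVE_MOBILITIES[n]
        except KeyError:
            raise KeyError(
                f"no relative mobility for species {n!r}; supply it via extra_mobilities"
            ) from None

    num = sum(charge[n] * mob(n) * (cb[n] - cp[n]) for n in names)
    den = sum(charge[n] ** 2 * mob(n) * (cb[n] - cp[n]) for n in names)
    sp = sum(charge[n] ** 2 * mob(n) * cp[n] for n in names)
    sb = sum(charge[n] ** 2 * mob(n) * cb[n] for n in names)
    if den == 0.0 or sp == 0.0 or sb == 0.0:
        return 0.0
    vt = thermal_voltage_mv(temperature_K)
    # Potential of bath minus pipette (Henderson; see Barry & Lynch 1991).
    return float(vt * (num / den) * math.log(sp / sb))


def rc_from_transient(trace_pA: np.ndarray, fs_hz: float, dv_mV: float) -> tuple[float, float]:
    """Capacitance (pF) and series resistance (MOhm) from a capacitive transient.

    For a baseline-subtracted current transient evoked by a rectangular voltage
    step dV: Rs = dV / I_peak and C = (integral of I dt) / dV.  Signs are handled
    so that both estimates are positive for a passive cell regardless of the
    step polarity.
    """
    if dv_mV == 0:
        raise ConfigError("dv_mV must be nonzero")
    trace = np.asarray(trace_pA, dtype=float)
    if trace.size == 0 or not np.any(trace):
        raise EstimationError("transient trace is empty or all zeros")
    peak_idx = int(np.argmax(np.abs(trace)))
    i_peak_pA = trace[peak_idx]
    if i_peak_pA == 0:
        raise EstimationError("zero peak current in transient")
    charge_pC = float(np.trapezoid(trace, dx=1.0 / fs_hz))  # pA * s = pC
    rs_mohm = abs(dv_mV / (i_peak_pA / 1000.0))  # mV / nA = MOhm
    cap_pF = abs(charge_pC / dv_mV * 1000.0)  # pC / mV -> pF
    return cap_pF, rs_mohm


def qc_series_resistance(rs_series_MOhm: "np.ndarray | list[float]") -> bool:
    """Series-resistance stability check: pass iff no value deviates from the
    first by strictly more than 20% (a 20% change exactly still passes)."""
    rs = np.asarray(rs_series_MOhm, dtype=float)
    if rs.size < 2:
        raise ConfigError("need >= 2 series-resistance values")
    if rs[0] <= 0:
        raise ConfigError("initial series resistance must be > 0")
    rel = np.abs(rs - rs[0]) / rs[0]
    return bool(np.max(rel) <= 0.20)


def _histogram_mode(trace: np.ndarray, bin_pA: float) -> tuple[float, bool]:
    """Mode of the all-point histogram with parabolic sub-bin interpolation.

    Returns (mode, ambiguous).  Ambiguous means a second, non-adjacent local
    peak reaches within 5% of the modal count.
    """
    lo, hi = float(np.min(trace)), float(np.max(trace))
    if hi - lo < bin_pA:
        return float(np.median(trace)), False
    edges = np.arange(lo, hi + bin_pA, bin_pA)
    counts, edges = np.histogram(trace, bins=edges)
    k = int(np.argmax(counts))
    centers = (edges[:-1] + edges[1:]) / 2.0
    mode = centers[k]
    if 0 < k < len(counts) - 1:
        y0, y1, y2 = counts[k - 1 : k + 2].astype(float)
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            mode = centers[k] + 0.5 * (y0 - y2) / denom * bin_pA
    # local peaks away from the modal bin
    c = counts.astype(float)
    interior = (c[1:-1] >= c[:-2]) & (c[1:-1] >= c[2:])
    peak_idx = np.flatnonzero(interior) + 1
    peak_idx = peak_idx[np.abs(peak_idx - k) > 1]
    ambiguous = bool(peak_idx.size and np.max(c[peak_idx]) >= 0.95 * c[k])
    return float(mode), ambiguous


def tonic_from_histogram(
    trace_before_pA: np.ndarray,
    trace_during_pA: np.ndarray,
    fs_hz: float,
    bin_pA: float = 1.0,
    capacity_pF: float | None = None,
    rs_before_MOhm: float | None = None,
    rs_during_MOhm: float | None = None,
    min_duration_s: float = 10.0,
) -> TonicResult:
    """Tonic GABA_A current from all-point current histograms.

    The holding current of each trace is the mode of its all-point histogram
    (default 1 pA bins, parabolic interpolation around the modal bin); the mode
    is robust to the tail of superimposed synaptic events, which is why the
    histogram peak rather than the mean is used.  The tonic current is the
    during-blocker mode minus the before mode (positive for an outward shift on
    GABA_A blockade), and its density is tonic / capacitance.  A second
    histogram peak within 5% of the modal count attaches an ambiguity warning.
    """
    if bin_pA <= 0:
        raise ConfigError("bin_pA must be > 0")
    before = np.asarray(trace_before_pA, dtype=float)
    during = np.asarray(trace_during_pA, dtype=float)
    for name, tr in (("before", before), ("during", during)):
        if tr.size / fs_hz < min_duration_s:
            raise ConfigError(
                f"trace_{name} is {tr.size / fs_hz:.1f} s; need >= {min_duration_s} s"
            )
    mode_before, amb_b = _histogram_mode(before, bin_pA)
    mode_during, amb_d = _histogram_mode(during, bin_pA)
    if amb_b or amb_d:
        warnings.warn(
            "all-point histogram has competing modes within 5% of the modal count; "
            "holding-current estimate may be ambiguous",
            stacklevel=2,
        )
    tonic = mode_during - mode_before
    density = None if capacity_pF in (None, 0) else tonic / capacity_pF
    qc = None
    if rs_before_MOhm is not None and rs_during_MOhm is not None:
        qc = qc_series_resistance([rs_before_MOhm, rs_during_MOhm])
    return TonicResult(
        i_hold_before_pA=mode_before,
        i_hold_during_pA=mode_during,
        tonic_pA=tonic,
        capacity_pF=capacity_pF,
        density_pA_per_pF=density,
        rs_before_MOhm=rs_before_MOhm,
        rs_during_MOhm=rs_during_MOhm,
        qc_pass=qc,
        ambiguous_before=amb_b,
        ambiguous_during=amb_d,
    )
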