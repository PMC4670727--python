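"""MAPK (Raf–MEK–ERK) network ODE model and its ablation variants.

The network is the classic three-tier kinase cascade driven by a
growth-factor receptor, wrapped by four regulatory layers:

* a fast negative feedback from active ERK to Raf, mediated by an explicit
  feedback species (NFB) whose activation integrates active ERK with a
  receptor-activity feed-forward input;
* an NGF-specific positive feedback from active ERK to Raf, mediated by a
  slowly activating species (PFB) whose activation likewise integrates
  active ERK with a receptor feed-forward input.  The onset delay of the
  positive feedback is implicit in the activation kinetics of PFB; no
  explicit delay equation is used;
* a slow transcriptional negative feedback: active ERK drives DUSP mRNA
  synthesis, the translated phosphatase dephosphorylates ERK, and both
  species turn over with a 90-min half-life;
* optionally (one ablation variant), receptor internalization/degradation
  in place of the receptor feed-forward crosstalk.

Kinetics: Michaelis–Menten (de)phosphorylation cycles for Raf/MEK/ERK
(each species conserved, ``X_inactive = X_tot - X_act``), mass-action
first-order receptor and DUSP turnover.  Feedback integration is a
multiplicative AND gate: loop activation is proportional to
``ERK_act * (basal + (1 - basal) * f(R_act))`` where ``f`` is a saturating
feed-forward function of receptor activity.  Removing a crosstalk pins the
corresponding gate at its ceiling of 1.

Concentrations are dimensionless (totals default to 1); time is minutes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "VariantTag",
    "FfwModality",
    "NetworkVariant",
    "ModelParameters",
    "STATE_NAMES",
    "build_parameters",
    "default_parameter_dict",
    "rhs",
    "resting_state",
]


class VariantTag(str, Enum):
    """Published network topologies."""

    FULL = "FULL"
    NO_PFB_CROSSTALK = "NO_PFB_CROSSTALK"
    NO_DELAY_NO_CROSSTALK = "NO_DELAY_NO_CROSSTALK"
    NO_DUSP = "NO_DUSP"
    NO_NFB_CROSSTALK = "NO_NFB_CROSSTALK"
    RECEPTOR_INTERNALIZATION = "RECEPTOR_INTERNALIZATION"


class FfwModality(str, Enum):
    """Shape of the receptor feed-forward input onto the positive feedback."""

    LINEAR = "LINEAR"
    HILL = "HILL"


@dataclass(frozen=True)
class NetworkVariant:
    tag: VariantTag = VariantTag.FULL
    ffw_modality: FfwModality = FfwModality.HILL

    def __post_init__(self):
        object.__setattr__(self, "tag", VariantTag(self.tag))
        object.__setattr__(self, "ffw_modality", FfwModality(self.ffw_modality))

    @property
    def internalization(self) -> bool:
        return self.tag is VariantTag.RECEPTOR_INTERNALIZATION

    @property
    def crosstalk_nfb(self) -> bool:
        """Receptor feed-forward onto the negative feedback present?"""
        return self.tag not in (VariantTag.NO_NFB_CROSSTALK,
                                VariantTag.RECEPTOR_INTERNALIZATION)

    @property
    def crosstalk_pfb(self) -> bool:
        return self.tag is not VariantTag.NO_PFB_CROSSTALK

    @property
    def no_delay(self) -> bool:
        """Positive feedback collapsed to an instantaneous ERK->Raf gain?"""
        return self.tag is VariantTag.NO_DELAY_NO_CROSSTALK

    @property
    def has_dusp(self) -> bool:
        return self.tag is not VariantTag.NO_DUSP


# State vector layout. Inactive cascade forms follow by conservation.
STATE_NAMES = ("R", "R_act", "R_int", "Raf_act", "MEK_act", "ERK_act",
               "NFB_act", "PFB_act", "DUSP_mRNA", "DUSP_prot")
I_R, I_RACT, I_RINT, I_RAF, I_MEK, I_ERK, I_NFB, I_PFB, I_DM, I_DP = range(10)

# Packed parameter-vector layout consumed by the compiled right-hand side.
PARAM_ORDER = (
    "raf_tot", "mek_tot", "erk_tot", "nfb_tot", "pfb_tot", "phos_tot",
    "k_ract", "k_rdeact", "k_egf", "k_ngf",
    "k_rsyn", "k_rdeg", "k_int", "k_rec", "k_deg_internal",
    "raf_basal_act",
    "k_raf_act", "km_raf_act", "v_raf_deact", "km_raf_deact",
    "k_mek_act", "km_mek_act", "v_mek_deact", "km_mek_deact",
    "k_erk_act", "km_erk_act", "v_erk_deact", "km_erk_deact",
    "k3_f", "nfb_gain_scale", "nfb_deact", "nfb_basal",
    "nfb_ffw_k", "nfb_ffw_h", "nfb_raf_gain",
    "k_pfb_act", "k_pfb_deact", "pfb_basal",
    "pfb_ffw_vmax", "pfb_ffw_k", "pfb_ffw_h", "pfb_raf_gain",
    "nd_erk_raf_gain",
    "dusp_mrna_syn", "dusp_translation", "dusp_mrna_deg", "dusp_prot_deg",
    "dusp_kcat", "dusp_km",
    "pfb_erk_km", "nfb_inh_h", "nfb_erk_km", "nfb_self_km", "pfb_pos_km",
)
_NP = len(PARAM_ORDER)
# trailing topology flags
F_INTERNAL, F_XTALK_NFB, F_XTALK_PFB, F_NO_DELAY, F_HILL = range(_NP, _NP + 5)
PACKED_SIZE = _NP + 5

# Fields that may legitimately be zero (everything else must be > 0).
_MAY_BE_ZERO = {"raf_basal_act", "dusp_mrna_syn", "nd_erk_raf_gain"}
# Conserved cycles checked by the simulator: (total-field, active-state-index).
CONSERVED_CYCLES = (("raf_tot", I_RAF), ("mek_tot", I_MEK), ("erk_tot", I_ERK),
                    ("nfb_tot", I_NFB), ("pfb_tot", I_PFB))


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated parameter record for one network variant.

    All rates are per minute, Michaelis constants and totals in the same
    dimensionless concentration units as the state vector, dose
    half-saturations (``k_egf``, ``k_ngf``) in ng/ml.
    ``t_half_internal`` (minutes) sets the degradation rate of internalized
    receptor in the internalization variant.
    """

    # totals
    raf_tot: float
    mek_tot: float
    erk_tot: float
    nfb_tot: float
    pfb_tot: float
    phos_tot: float
    # receptor
    k_ract: float
    k_rdeact: float
    k_egf: float
    k_ngf: float
    # receptor turnover / internalization (internalization variant only)
    k_rsyn: float
    k_rdeg: float
    k_int: float
    k_rec: float
    t_half_internal: float
    # cascade
    raf_basal_act: float
    k_raf_act: float
    km_raf_act: float
    v_raf_deact: float
    km_raf_deact: float
    k_mek_act: float
    km_mek_act: float
    v_mek_deact: float
    km_mek_deact: float
    k_erk_act: float
    km_erk_act: float
    v_erk_deact: float
    km_erk_deact: float
    # negative feedback
    k3_f: float
    nfb_gain_scale: float
    nfb_deact: float
    nfb_basal: float
    nfb_ffw_k: float
    nfb_ffw_h: float
    nfb_raf_gain: float
    # positive feedback
    k_pfb_act: float
    k_pfb_deact: float
    pfb_basal: float
    pfb_ffw_vmax: float
    pfb_ffw_k: float
    pfb_ffw_h: float
    pfb_raf_gain: float
    nd_erk_raf_gain: float
    # DUSP module
    dusp_mrna_syn: float
    dusp_translation: float
    dusp_mrna_deg: float
    dusp_prot_deg: float
    dusp_kcat: float
    dusp_km: float
    # nonlinearity shapes: ERK half-saturation of PFB activation (the
    # activation is second-order in ERK, stabilizing the resting state)
    # and Hill coefficient of NFB inhibition of Raf
    pfb_erk_km: float
    nfb_inh_h: float
    # ERK half-saturation of NFB activation: the loop activation saturates
    # in ERK, so the receptor feed-forward gate (not ERK level) sets the
    # standing feedback strength
    nfb_erk_km: float
    # product inhibition of NFB activation: activation is fast from rest
    # but stalls as active NFB accumulates, keeping the standing level
    # mid-range and receptor-sensitive
    nfb_self_km: float
    # half-saturation of the PFB->Raf transfer: the positive-feedback drive
    # is quadratic at small PFB levels, so trace amounts of active PFB do
    # not leak drive into the cascade
    pfb_pos_km: float
    # topology
    variant: NetworkVariant = NetworkVariant()

    @property
    def k_deg_internal(self) -> float:
        return math.log(2.0) / self.t_half_internal

    def pack(self) -> np.ndarray:
        """Flatten to the float vector consumed by the compiled RHS."""
        p = np.empty(PACKED_SIZE)
        for i, name in enumerate(PARAM_ORDER):
            p[i] = getattr(self, name) if name != "k_deg_internal" else 0.0
        p[PARAM_ORDER.index("k_deg_internal")] = self.k_deg_internal
        v = self.variant
        p[F_INTERNAL] = 1.0 if v.internalization else 0.0
        p[F_XTALK_NFB] = 1.0 if v.crosstalk_nfb else 0.0
        p[F_XTALK_PFB] = 1.0 if v.crosstalk_pfb else 0.0
        p[F_NO_DELAY] = 1.0 if v.no_delay else 0.0
        p[F_HILL] = 1.0 if v.ffw_modality is FfwModality.HILL else 0.0
        return p

    def replace(self, **kw) -> "ModelParameters":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
             if f.name != "variant"}
        d["variant"] = self.variant.tag.value
        d["ffw_modality"] = self.variant.ffw_modality.value
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParameters)} - {"variant"}


def default_parameter_dict() -> dict:
    """The calibrated full-model defaults shipped with the package."""
    text = resources.files("erkpulse").joinpath("defaults/full_model.json").read_text()
    return json.loads(text)


def build_parameters(variant: NetworkVariant | VariantTag | str = VariantTag.FULL,
                     overrides: dict | None = None) -> ModelParameters:
    """Assemble a validated parameter record for a network variant.

    Starts from the shipped calibrated defaults, applies ``overrides``
    (which may only name declared parameter fields), then applies
    variant-specific adjustments (e.g. zero DUSP synthesis for the
    DUSP-less topology).
    """
    if not isinstance(variant, NetworkVariant):
        variant = NetworkVariant(tag=VariantTag(variant))
    values = default_parameter_dict()
    for name, val in (overrides or {}).items():
        if name not in _FIELD_NAMES:
            raise ValueError(f"unknown parameter override {name!r}")
        values[name] = float(val)
    for name, val in values.items():
        lo_ok = (val >= 0.0) if name in _MAY_BE_ZERO else (val > 0.0)
        if not np.isfinite(val) or not lo_ok:
            raise ValueError(f"parameter {name!r} must be strictly positive, got {val}")
    if not variant.has_dusp:
        if "dusp_mrna_syn" not in (overrides or {}):
            values["dusp_mrna_syn"] = 0.0
        elif values["dusp_mrna_syn"] != 0.0:
            raise ValueError("dusp_mrna_syn must be 0 for the NO_DUSP variant")
    return ModelParameters(variant=variant, **values)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _rhs_core(y, u, ngf, p):
    """Time derivatives for a constant receptor drive ``u`` in [0, 1).

    ``ngf`` is 1.0 when the stimulating growth factor is NGF (enabling the
    positive-feedback pathway), else 0.0.
    """
    R = y[0]
    Ract = y[1]
    Rint = y[2]
    Raf = y[3]
    MEK = y[4]
    ERK = y[5]
    NFB = y[6]
    PFB = y[7]
    Dm = y[8]
    Dp = y[9]

    dy = np.zeros(10)

    act = p[6] * u * R          # k_ract
    deact = p[7] * Ract         # k_rdeact
    if p[F_INTERNAL] > 0.5:
        exch = p[12] * Ract - p[13] * Rint          # k_int, k_rec
        dy[0] = p[10] - p[11] * R - act + deact     # k_rsyn, k_rdeg
        dy[1] = act - deact - exch
        dy[2] = exch - p[14] * Rint                 # k_deg_internal
    else:
        dy[0] = -act + deact
        dy[1] = act - deact
        dy[2] = 0.0

    # feed-forward gates (attenuate loop activation below the ceiling of 1)
    if p[F_XTALK_NFB] > 0.5:
        rh = Ract ** p[33]                          # nfb_ffw_h
        fN = rh / (rh + p[32] ** p[33])             # nfb_ffw_k
        gateN = p[31] + (1.0 - p[31]) * fN          # nfb_basal
    else:
        gateN = 1.0
    if p[F_XTALK_PFB] > 0.5:
        if p[F_HILL] > 0.5:
            rh = Ract ** p[40]                      # pfb_ffw_h
            fP = p[38] * rh / (rh + p[39] ** p[40])  # pfb_ffw_vmax, pfb_ffw_k
        else:
            # linear dependency on receptor activity, calibrated to the
            # Hill form's half-effect point and local sensitivity there
            fP = p[38] * (0.5 + p[40] / (4.0 * p[39]) * (Ract - p[39]))
            if fP > p[38]:
                fP = p[38]
            elif fP < 0.0:
                fP = 0.0
        gateP = p[37] + (1.0 - p[37]) * fP          # pfb_basal
    else:
        gateP = 1.0

    # Raf cycle; NFB inhibits the receptor-driven activation route with a
    # steep (Hill) dependence so that adaptation is deep at feedback steady
    # state yet recovery is complete once NFB relaxes; PFB provides a
    # parallel activation route (NGF only) that is not subject to the
    # inhibitory feedback
    inhib = 1.0 / (1.0 + (p[34] * NFB) ** p[50])    # nfb_raf_gain, nfb_inh_h
    if p[F_NO_DELAY] > 0.5:
        pos = ngf * p[42] * ERK                     # nd_erk_raf_gain
    else:
        # PFB amplifies ongoing ERK activity (cooperative in both PFB and
        # ERK): it boosts active responses and holds a latched high state,
        # but leaks no drive at low ERK or trace PFB levels
        e4p = ERK ** 4
        fEp = e4p / (p[49] ** 4 + e4p)              # pfb_erk_km
        pos = ngf * p[41] * fEp * PFB * PFB / (p[53] + PFB)
    raf_in = p[0] - Raf
    dy[3] = ((p[16] * (Ract + p[15]) * inhib + pos) * raf_in / (p[17] + raf_in)
             - p[18] * Raf / (p[19] + Raf))

    mek_in = p[1] - MEK
    dy[4] = (p[20] * Raf * mek_in / (p[21] + mek_in)
             - p[22] * MEK / (p[23] + MEK))

    erk_in = p[2] - ERK
    dy[5] = (p[24] * MEK * erk_in / (p[25] + erk_in)
             - p[26] * p[5] * ERK / (p[27] + ERK)
             - p[47] * Dp * ERK / (p[48] + ERK))    # dusp_kcat, dusp_km

    # negative feedback species: activation saturates in ERK (Michaelis)
    # and is product-inhibited with a receptor-gated stall ceiling, so the
    # feed-forward input sets the level the loop refills to on every pulse
    eN = ERK / (p[51] + ERK)                        # nfb_erk_km
    ks = p[52] * gateN                              # nfb_self_km * gate
    stall = ks / (ks + NFB)
    dy[6] = (p[28] * p[29] * eN * stall * (p[3] - NFB)    # k3_f * nfb_gain_scale
             - p[30] * NFB)                                # nfb_deact

    # positive feedback species (slow activation -> implicit onset delay);
    # activation is cooperatively gated by ERK (4th-order Hill) so the loop
    # neither bootstraps from basal ERK at rest nor accumulates appreciably
    # at intermediate ERK levels
    if p[F_NO_DELAY] > 0.5:
        dy[7] = 0.0
    else:
        e4 = ERK ** 4
        fE = e4 / (p[49] ** 4 + e4)                 # pfb_erk_km
        dy[7] = ngf * p[35] * fE * gateP * (p[4] - PFB) - p[36] * PFB

    # DUSP transcriptional module
    dy[8] = p[43] * ERK - p[45] * Dm                # dusp_mrna_syn, dusp_mrna_deg
    dy[9] = p[44] * Dm - p[46] * Dp                 # dusp_translation, dusp_prot_deg
    return dy


try:  # jit-compile the hot loop when numba is importable
    from numba import njit

    _rhs_core = njit(cache=False)(_rhs_core)
except ImportError:  # pragma: no cover
    pass


def rhs(state, t, params: ModelParameters, protocol) -> np.ndarray:
    """Model derivatives at time ``t`` under a stimulation protocol.

    Raises if any state component is negative (which signals integrator
    misconfiguration rather than model behavior).
    """
    from .stimulus import receptor_drive

    y = np.asarray(state, dtype=float)
    if y.shape != (10,):
        raise ValueError("state must be a length-10 vector")
    if np.any(y < -1e-9):
        raise ValueError(f"negative state component: {y.min():.3e}")
    u = receptor_drive(protocol.dose, protocol.gf, params) if protocol.is_on(t) else 0.0
    ngf = 1.0 if protocol.gf == "NGF" else 0.0
    return _rhs_core(y, u, ngf, params.pack())


def resting_state(params: ModelParameters, gf: str = "EGF",
                  horizon: float = 5000.0, tol: float = 1e-8) -> np.ndarray:
    """Pre-stimulus steady state (zero growth-factor drive).

    Equilibrates by integration then polishes with a Newton solve; the
    result satisfies ``|rhs| < tol`` componentwise and is used as the
    initial condition for every simulation.
    """
    ngf = 1.0 if str(gf).upper() == "NGF" else 0.0
    p = params.pack()
    y0 = np.zeros(10)
    y0[I_R] = (params.k_rsyn / params.k_rdeg) if params.variant.internalization else 1.0

    fun = lambda t, y: _rhs_core(y, 0.0, ngf, p)
    sol = solve_ivp(fun, (0.0, horizon), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    y = sol.y[:, -1]
    res = root(lambda z: _rhs_core(z, 0.0, ngf, p), y, method="hybr",
               options={"xtol": 1e-13})
    if res.success and np.all(res.x > -1e-12):
        y = np.clip(res.x, 0.0, None)
    resid = float(np.max(np.abs(_rhs_core(y, 0.0, ngf, p))))
    if resid > tol:
        raise RuntimeError(
            f"resting state failed to converge: residual norm {resid:.3e} > {tol:g}")
    return y
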