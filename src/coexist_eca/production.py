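"""Plant carbon-nitrogen production model and its monoculture equilibrium.

The model couples a sun/shade Farquhar canopy (with a Medlyn optimal-stomata
intercellular CO2) to simple carbon and nitrogen pools:

* daily canopy gross photosynthesis (GPP) from leaf area index (LAI), leaf
  N:C and weather; NPP = Y * GPP (whole-plant respiration proportional to
  photosynthesis);
* carbon allocated to foliage (fraction ``af``) and roots (``1 - af``), each
  pool turning over at its rate (``sf`` = 1 yr-1 foliage, ``sr`` roots);
* nitrogen uptake a saturating function of root biomass,
  ``N_up = N_min (1 - exp(-kr Br))``, with retranslocation fraction ``lam``
  recovered from senescing foliage and root N:C ``rho`` times leaf N:C.

A monoculture run to steady state defines the equilibrium production NPP*
and, from it, the two residual-resource statistics of resource-use
competition theory:

* ``R* = N_min exp(-kr (1-af)/sr NPP*)`` - residual soil N supply;
* ``I* = IPAR exp(-ks 0.4 SLA af / [C]_f NPP*)`` - residual light at the
  soil surface,

where 0.4 scales leaf-level to canopy-level specific leaf area and
``[C]_f`` = 0.44 g C g-1 DM is foliage carbon content.

Two routes to the equilibrium are provided and cross-checked: a 23-year
daily simulation with the forcing recycled each year, and an analytic
annual-balance fixed point on (NPP, leaf N:C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import DAYS_PER_YEAR, AnnualForcing, DailyWeather
from .traits import TRAIT_FIELDS, TraitVector, trait_arrays

__all__ = [
    "ModelConstants",
    "PhotosynthesisConstants",
    "DEFAULT_CONSTANTS",
    "PlantState",
    "Equilibrium",
    "intercellular_co2",
    "leaf_assimilation",
    "canopy_gpp_day",
    "simulate_monoculture",
    "simulate_monocultures",
    "solve_equilibrium",
    "solve_equilibria",
    "r_star",
    "i_star",
    "equilibria_to_frame",
]


@dataclass(frozen=True)
class ModelConstants:
    """Whole-model constants held fixed across the study."""

    nmin: float = 3.0  # net soil N mineralization, g N m-2 yr-1
    cf: float = 0.44  # foliage carbon concentration, g C g-1 DM
    canopy_sla_factor: float = 0.4  # leaf-to-canopy SLA scaling
    sf: float = 1.0  # foliage turnover, yr-1
    ca_ambient: float = 360.0  # ppm
    ca_elevated: float = 550.0  # ppm
    diffuse_fraction: float = 0.3  # diffuse share of incident PAR
    nf_min: float = 0.005  # leaf N:C clamp, g N g-1 C
    nf_max: float = 0.10


@dataclass(frozen=True)
class PhotosynthesisConstants:
    """C3 biochemistry: Rubisco/RuBP kinetics with Arrhenius T-responses.

    Reference values at 25 degC; activation energies in J mol-1.  The
    electron-transport light response is a non-rectangular hyperbola with
    curvature ``theta_j`` and quantum yield ``alpha_j`` (mol e- per mol
    absorbed photon).
    """

    gamma_star_25: float = 42.75  # CO2 compensation point, umol mol-1
    e_gamma_star: float = 37830.0
    kc_25: float = 404.9  # Michaelis constant for CO2, umol mol-1
    e_kc: float = 79430.0
    ko_25: float = 278.4  # Michaelis constant for O2, mmol mol-1
    e_ko: float = 36380.0
    o2: float = 210.0  # intercellular O2, mmol mol-1
    e_vcmax: float = 65330.0
    e_jmax: float = 43540.0
    theta_j: float = 0.7
    alpha_j: float = 0.26
    leaf_absorptance: float = 0.85  # PAR absorbed / PAR intercepted
    #: Fraction of potential canopy assimilation realised over the year,
    #: standing in for unmodelled phenology (dormancy, regrowth, senescence);
    #: calibrated once so baseline equilibrium production falls in the
    #: 200-450 g C m-2 yr-1 range reported for N-limited temperate grassland.
    activity_factor: float = 0.55
    mol_photon_per_mj: float = 4.6  # PAR energy-to-quanta conversion
    gc_per_umol_co2: float = 12.0e-6  # g C per umol CO2


DEFAULT_CONSTANTS = ModelConstants()
DEFAULT_PHOTO = PhotosynthesisConstants()

_RGAS = 8.314  # J mol-1 K-1
_TREF = 298.15  # K

# 3-point Gauss-Legendre nodes/weights on [0, 1] for the diurnal integral.
_GAUSS_X = np.array([0.5 - math.sqrt(15.0) / 10.0, 0.5, 0.5 + math.sqrt(15.0) / 10.0])
_GAUSS_W = np.array([5.0 / 18.0, 8.0 / 18.0, 5.0 / 18.0])

_EPS = 1e-12


# ---------------------------------------------------------------------------
# State and equilibrium containers

@dataclass
class PlantState:
    """Carbon and nitrogen pools of one (mono)culture, g C or g N per m2."""

    bf: float  # foliage biomass, g C m-2
    br: float  # root biomass, g C m-2
    nplant: float  # whole-plant N pool, g N m-2

    def nf(self, traits: TraitVector, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
        """Leaf N:C (g N g-1 C), derived from the pool and clamped."""
        structural = self.bf + traits.rho * self.br
        if structural <= 0.0:
            return constants.nf_min
        return float(np.clip(self.nplant / structural, constants.nf_min, constants.nf_max))

    def lai(self, traits: TraitVector, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
        """Leaf area index from foliage biomass via canopy-scaled SLA."""
        return (
            constants.canopy_sla_factor
            * (traits.sla / 1000.0)
            * self.bf
            / constants.cf
        )


@dataclass(frozen=True)
class Equilibrium:
    """Monoculture steady state and its resource-use statistics."""

    species_id: str
    npp_star: float  # g C m-2 yr-1
    bf_star: float  # g C m-2
    br_star: float  # g C m-2
    nf_star: float  # g N g-1 C
    lai_star: float  # m2 m-2
    nup_star: float  # g N m-2 yr-1
    r_star: float  # g N m-2 yr-1
    i_star: float  # MJ m-2 yr-1
    converged: bool
    years_run: int
    # Final-year integrated N fluxes (daily simulation route only): used for
    # the uptake-vs-loss closure diagnostic.
    nup_flux: float | None = None
    nloss_flux: float | None = None


# ---------------------------------------------------------------------------
# Leaf and canopy photosynthesis

def _arrhenius(k25, e_act, tair):
    tk = np.asarray(tair) + 273.15
    return k25 * np.exp(e_act * (tk - _TREF) / (_TREF * _RGAS * tk))


def intercellular_co2(ca, vpd, g1):
    """Leaf intercellular CO2 (ppm) from the Medlyn optimal-stomata model.

    ``ci = ca * g1 / (g1 + sqrt(vpd))`` with VPD in kPa; always below ``ca``
    and increasing in the stomatal operating point ``g1``.
    """
    vpd = np.asarray(vpd, dtype=float)
    if np.any(vpd <= 0.0):
        raise ValueError("vpd must be strictly positive")
    out = np.asarray(ca) * g1 / (g1 + np.sqrt(vpd))
    return float(out) if out.ndim == 0 else out


def leaf_assimilation(
    vcmax_area,
    jmax_area,
    ci,
    tair,
    irradiance,
    photo: PhotosynthesisConstants = DEFAULT_PHOTO,
):
    """Gross leaf assimilation (umol CO2 m-2 s-1): min(Rubisco, RuBP) limited.

    ``irradiance`` is absorbed PPFD per unit leaf area (umol photon m-2 s-1).
    No day respiration is subtracted here; whole-plant respiration enters
    once, via the carbon use efficiency Y.
    """
    gamma = _arrhenius(photo.gamma_star_25, photo.e_gamma_star, tair)
    kc = _arrhenius(photo.kc_25, photo.e_kc, tair)
    ko = _arrhenius(photo.ko_25, photo.e_ko, tair)
    km = kc * (1.0 + photo.o2 / ko)
    vc = _arrhenius(1.0, photo.e_vcmax, tair) * np.asarray(vcmax_area)
    jm = _arrhenius(1.0, photo.e_jmax, tair) * np.asarray(jmax_area)

    # Non-rectangular hyperbola for electron transport.
    aq = photo.alpha_j * np.asarray(irradiance)
    b = aq + jm
    disc = np.maximum(b * b - 4.0 * photo.theta_j * aq * jm, 0.0)
    j = (b - np.sqrt(disc)) / (2.0 * photo.theta_j)

    ci = np.asarray(ci, dtype=float)
    a_c = vc * (ci - gamma) / (ci + km)
    a_j = (j / 4.0) * (ci - gamma) / (ci + 2.0 * gamma)
    out = np.maximum(np.minimum(a_c, a_j), 0.0)
    return float(out) if np.ndim(out) == 0 else out


def _canopy_assim_inst(
    i0, lai, ks, vcmax_area, jmax_area, ci, tair,
    constants: ModelConstants, photo: PhotosynthesisConstants,
):
    """Instantaneous canopy assimilation (umol m-2 ground s-1), sun/shade.

    All incident PAR is split into a fixed diffuse fraction and a beam; both
    attenuate with the species' extinction coefficient ``ks``.  Beam is
    absorbed by sunlit leaves only; diffuse is shared by depth.  Each class
    is treated as a big leaf at its mean absorbed irradiance.
    """
    lai = np.asarray(lai, dtype=float)
    e1 = np.exp(-ks * lai)
    l_sun = (1.0 - e1) / ks
    l_shade = np.maximum(lai - l_sun, 0.0)

    i_beam = (1.0 - constants.diffuse_fraction) * i0
    i_diff = constants.diffuse_fraction * i0
    q_beam_sun = i_beam * (1.0 - e1)
    q_diff_sun = i_diff * (1.0 - np.exp(-2.0 * ks * lai)) / 2.0
    q_diff_shade = i_diff * (1.0 - e1) - q_diff_sun

    q_sun = photo.leaf_absorptance * (q_beam_sun + q_diff_sun) / np.maximum(l_sun, _EPS)
    q_shade = photo.leaf_absorptance * q_diff_shade / np.maximum(l_shade, _EPS)

    a_sun = leaf_assimilation(vcmax_area, jmax_area, ci, tair, q_sun, photo)
    a_shade = leaf_assimilation(vcmax_area, jmax_area, ci, tair, q_shade, photo)
    return l_sun * a_sun + l_shade * a_shade


def _canopy_gpp_day_arrays(
    lai, nf, ks, g1, vcmax_per_n, jmax_ratio, sla,
    par, tair, vpd, daylength, ca,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    photo: PhotosynthesisConstants = DEFAULT_PHOTO,
):
    """Daily canopy GPP (g C m-2 day-1); all arguments broadcast together.

    The diurnal course of irradiance is a half-sine over the daylength whose
    integral equals the daily PAR total; the diurnal integral of canopy
    assimilation uses 3-point Gaussian quadrature.
    """
    ci = intercellular_co2(ca, vpd, g1)
    narea = np.asarray(nf) * 1000.0 * constants.cf / np.asarray(sla)  # g N m-2 leaf
    vcmax_area = np.asarray(vcmax_per_n) * narea
    jmax_area = np.asarray(jmax_ratio) * vcmax_area

    dl_s = np.asarray(daylength) * 3600.0
    q_day = np.asarray(par) * photo.mol_photon_per_mj * 1.0e6  # umol m-2 day-1
    i_peak = np.pi * q_day / (2.0 * dl_s)

    total = 0.0
    for xk, wk in zip(_GAUSS_X, _GAUSS_W):
        i0 = i_peak * math.sin(math.pi * xk)
        total = total + wk * _canopy_assim_inst(
            i0, lai, ks, vcmax_area, jmax_area, ci, tair, constants, photo
        )
    gpp_umol = photo.activity_factor * dl_s * total
    return gpp_umol * photo.gc_per_umol_co2


def canopy_gpp_day(
    state: PlantState,
    traits: TraitVector,
    weather: DailyWeather,
    ca: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Daily gross canopy photosynthesis (g C m-2 day-1) of one monoculture."""
    out = _canopy_gpp_day_arrays(
        state.lai(traits, constants),
        state.nf(traits, constants),
        traits.ks, traits.g1, traits.vcmax_per_n, traits.jmax_ratio, traits.sla,
        weather.par, weather.tair, weather.vpd, weather.daylength, ca,
        constants,
    )
    return float(out)


# ---------------------------------------------------------------------------
# Daily monoculture simulation

#: Initial pools: modest live biomass with leaf N:C 0.03 g N g-1 C.
_INIT_BF = 50.0
_INIT_BR = 50.0
_INIT_NF = 0.03

#: Relative change in annual NPP between successive years taken as equilibrium.
NPP_CONVERGENCE_RTOL = 1e-3


def _simulate_batch(
    tr: dict[str, np.ndarray],
    forcing: AnnualForcing,
    ca: float,
    years: int,
    constants: ModelConstants,
    photo: PhotosynthesisConstants = DEFAULT_PHOTO,
):
    """Daily-step simulation of n independent monocultures (vectorised).

    Returns (annual npp of final year, bf, br, nplant, nf, lai, converged,
    years_run arrays).
    """
    n = tr["af"].shape[0]
    bf = np.full(n, _INIT_BF)
    br = np.full(n, _INIT_BR)
    nplant = _INIT_NF * (bf + tr["rho"] * br)

    sla_factor = constants.canopy_sla_factor * (tr["sla"] / 1000.0) / constants.cf
    sf_d = constants.sf / DAYS_PER_YEAR
    sr_d = tr["sr"] / DAYS_PER_YEAR
    nmin_d = constants.nmin / DAYS_PER_YEAR

    npp_prev_year = None
    converged = np.zeros(n, dtype=bool)
    years_run = 0

    # Year-mean state accumulators (reported for the final year): the daily
    # state cycles seasonally, so annual means are the equilibrium diagnostics
    # comparable with the annual-balance solution.
    bf_mean = br_mean = nf_mean = np.zeros(n)

    nup_year = nloss_year = np.zeros(n)

    for year in range(years):
        npp_year = np.zeros(n)
        bf_sum = np.zeros(n)
        br_sum = np.zeros(n)
        nf_sum = np.zeros(n)
        nup_sum = np.zeros(n)
        nloss_sum = np.zeros(n)
        for d in range(DAYS_PER_YEAR):
            structural = bf + tr["rho"] * br
            nf = np.where(
                structural > 0.0,
                nplant / np.maximum(structural, _EPS),
                constants.nf_min,
            )
            nf = np.clip(nf, constants.nf_min, constants.nf_max)
            lai = sla_factor * bf
            bf_sum += bf
            br_sum += br
            nf_sum += nf
            gpp = _canopy_gpp_day_arrays(
                lai, nf,
                tr["ks"], tr["g1"], tr["vcmax_per_n"], tr["jmax_ratio"], tr["sla"],
                forcing.par[d], forcing.tair[d], forcing.vpd[d],
                forcing.daylength[d], ca, constants, photo,
            )
            npp = tr["Y"] * gpp
            uptake = nmin_d * (1.0 - np.exp(-tr["kr"] * br))
            loss = (1.0 - tr["lam"]) * nf * sf_d * bf + tr["rho"] * nf * sr_d * br
            dn = uptake - loss
            nup_sum += uptake
            nloss_sum += loss
            bf = bf + tr["af"] * npp - sf_d * bf
            br = br + (1.0 - tr["af"]) * npp - sr_d * br
            nplant = np.maximum(nplant + dn, 0.0)
            npp_year += npp
        years_run = year + 1
        if npp_prev_year is not None:
            converged = np.abs(npp_year - npp_prev_year) < (
                NPP_CONVERGENCE_RTOL * np.maximum(np.abs(npp_prev_year), _EPS)
            )
        npp_prev_year = npp_year
        bf_mean = bf_sum / DAYS_PER_YEAR
        br_mean = br_sum / DAYS_PER_YEAR
        nf_mean = nf_sum / DAYS_PER_YEAR
        nup_year = nup_sum
        nloss_year = nloss_sum

    npp_final = npp_prev_year
    lai_mean = sla_factor * bf_mean
    return (
        npp_final, bf_mean, br_mean, nplant, nf_mean, lai_mean,
        converged, years_run, nup_year, nloss_year,
    )


def _equilibrium_from_arrays(
    tr, npp, bf, br, nf, lai, converged, years, forcing, constants,
    nup_flux=None, nloss_flux=None,
):
    out = []
    nup = constants.nmin * (1.0 - np.exp(-tr["kr"] * br))
    rs = _r_star_arrays(tr["kr"], tr["af"], tr["sr"], npp, constants)
    istars = _i_star_arrays(tr["ks"], tr["sla"], tr["af"], npp, forcing.ipar, constants)
    conv = np.broadcast_to(converged, npp.shape)
    for i in range(npp.shape[0]):
        out.append(
            Equilibrium(
                species_id=str(tr["species_id"][i]),
                npp_star=float(npp[i]),
                bf_star=float(bf[i]),
                br_star=float(br[i]),
                nf_star=float(nf[i]),
                lai_star=float(lai[i]),
                nup_star=float(nup[i]),
                r_star=float(rs[i]),
                i_star=float(istars[i]),
                converged=bool(conv[i]),
                years_run=int(years),
                nup_flux=None if nup_flux is None else float(nup_flux[i]),
                nloss_flux=None if nloss_flux is None else float(nloss_flux[i]),
            )
        )
    return out


def simulate_monocultures(
    species: list[TraitVector],
    forcing: AnnualForcing,
    ca: float,
    years: int = 23,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[Equilibrium]:
    """Run the daily model for many species at once; see simulate_monoculture."""
    if years < 1:
        raise ValueError("years must be >= 1")
    tr = trait_arrays(species)
    npp, bf, br, nplant, nf, lai, converged, years_run, nup_fl, nloss_fl = (
        _simulate_batch(tr, forcing, ca, years, constants)
    )
    return _equilibrium_from_arrays(
        tr, npp, bf, br, nf, lai, converged, years_run, forcing, constants,
        nup_flux=nup_fl, nloss_flux=nloss_fl,
    )


def simulate_monoculture(
    traits: TraitVector,
    forcing: AnnualForcing,
    ca: float,
    years: int = 23,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> Equilibrium:
    """Daily-step monoculture run to (approximate) equilibrium.

    The forcing year is recycled ``years`` times (default 23, by which time
    the system has equilibrated for the trait space considered here);
    ``converged`` reports whether the final two annual NPP totals agree to
    0.1% relative.  Non-convergence is flagged, never silent.
    """
    return simulate_monocultures([traits], forcing, ca, years, constants)[0]


# ---------------------------------------------------------------------------
# Analytic equilibrium (annual-balance fixed point)

_FP_MAX_ITER = 10_000
_FP_RTOL = 1e-6
_FP_DAMPING = 0.5


def _annual_gpp_arrays(lai, nf, tr, forcing, ca, constants, photo=DEFAULT_PHOTO):
    """Annual canopy GPP (g C m-2 yr-1) at fixed LAI and leaf N:C."""
    gpp_daily = _canopy_gpp_day_arrays(
        np.asarray(lai)[:, None], np.asarray(nf)[:, None],
        tr["ks"][:, None], tr["g1"][:, None], tr["vcmax_per_n"][:, None],
        tr["jmax_ratio"][:, None], tr["sla"][:, None],
        forcing.par[None, :], forcing.tair[None, :], forcing.vpd[None, :],
        forcing.daylength[None, :], ca, constants, photo,
    )
    return gpp_daily.sum(axis=1)


#: Equilibria that decline below this NPP (g C m-2 yr-1) are treated as the
#: collapsed (nonviable-monoculture) fixed point at zero production.
_NPP_COLLAPSE = 0.05


def _solve_batch(
    tr: dict[str, np.ndarray],
    forcing: AnnualForcing,
    ca: float,
    constants: ModelConstants,
):
    """Annual-balance fixed point for n species at once.

    Balances: ``bf = af NPP / sf``; ``br = (1-af) NPP / sr``; leaf N:C from
    the N-uptake = N-loss closure (so it is a function of NPP); and
    ``NPP = Y * GPP_annual(LAI, nf)``.  The resulting one-dimensional map
    is iterated with damping and Aitken delta-squared acceleration on the
    shrinking set of unconverged species; trajectories declining below a
    small production floor are taken to the collapsed zero equilibrium.
    """
    n = tr["af"].shape[0]
    sla_factor = constants.canopy_sla_factor * (tr["sla"] / 1000.0) / constants.cf
    loss_coeff = (1.0 - tr["lam"]) * tr["af"] + tr["rho"] * (1.0 - tr["af"])

    def balance_map(npp_vec: np.ndarray, idx: np.ndarray):
        """One application of the annual-balance map on a species subset."""
        af = tr["af"][idx]
        bf = af * npp_vec / constants.sf
        br = (1.0 - af) * npp_vec / tr["sr"][idx]
        lai = sla_factor[idx] * bf
        nup = constants.nmin * (1.0 - np.exp(-tr["kr"][idx] * br))
        denom = npp_vec * loss_coeff[idx]
        nf = np.where(denom > _EPS, nup / np.maximum(denom, _EPS), constants.nf_max)
        nf = np.clip(nf, constants.nf_min, constants.nf_max)
        tr_sub = {k: v[idx] for k, v in tr.items() if k != "species_id"}
        gpp = _annual_gpp_arrays(lai, nf, tr_sub, forcing, ca, constants)
        return tr["Y"][idx] * gpp, nf

    npp = np.full(n, 200.0)
    nf = np.full(n, _INIT_NF)
    converged = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    max_cycles = _FP_MAX_ITER // 2
    for _ in range(max_cycles):
        x0 = npp[idx]
        h1, _ = balance_map(x0, idx)
        x1 = x0 + _FP_DAMPING * (h1 - x0)
        h2, nf2 = balance_map(x1, idx)
        x2 = x1 + _FP_DAMPING * (h2 - x1)
        d1 = x1 - x0
        d2 = x2 - x1
        denom = d2 - d1
        with np.errstate(divide="ignore", invalid="ignore"):
            aitken = x2 - d2 * d2 / denom
        usable = np.isfinite(aitken) & (np.abs(denom) > _EPS) & (aitken > 0.0)
        x_next = np.where(usable, aitken, x2)
        collapsing = (x2 < _NPP_COLLAPSE) & (d2 <= 0.0)
        x_next = np.where(collapsing, 0.0, x_next)
        done = collapsing | (np.abs(d2) <= _FP_RTOL * np.maximum(np.abs(x2), 1.0))
        npp[idx] = x_next
        nf[idx] = nf2
        converged[idx] = done
        idx = idx[~done]
        if idx.size == 0:
            break

    # One consistency pass at the accepted solution for the derived state.
    all_idx = np.arange(n)
    _, nf = balance_map(npp, all_idx)
    bf = tr["af"] * npp / constants.sf
    br = (1.0 - tr["af"]) * npp / tr["sr"]
    lai = sla_factor * bf
    return npp, bf, br, nf, lai, converged


def solve_equilibria(
    species: list[TraitVector],
    forcing: AnnualForcing,
    ca: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> list[Equilibrium]:
    """Analytic-equilibrium counterpart of simulate_monocultures."""
    tr = trait_arrays(species)
    npp, bf, br, nf, lai, converged = _solve_batch(tr, forcing, ca, constants)
    if not converged.all():
        bad = [str(tr["species_id"][i]) for i in np.nonzero(~converged)[0]]
        raise RuntimeError(f"equilibrium fixed point failed to converge for {bad}")
    return _equilibrium_from_arrays(tr, npp, bf, br, nf, lai, converged, 0, forcing, constants)


def solve_equilibrium(
    traits: TraitVector,
    forcing: AnnualForcing,
    ca: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> Equilibrium:
    """Solve the annual-balance fixed point directly (no daily simulation)."""
    return solve_equilibria([traits], forcing, ca, constants)[0]


# ---------------------------------------------------------------------------
# Residual-resource statistics

def _r_star_arrays(kr, af, sr, npp_star, constants):
    return constants.nmin * np.exp(-kr * (1.0 - af) / sr * npp_star)


def _i_star_arrays(ks, sla, af, npp_star, ipar, constants):
    return ipar * np.exp(
        -ks * constants.canopy_sla_factor * (sla / 1000.0) * af / constants.cf * npp_star
    )


def r_star(
    traits: TraitVector,
    npp_star: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Residual soil N supply at equilibrium (g N m-2 yr-1).

    ``R* = N_min exp(-kr (1-af)/sr NPP*)``: the unconsumed share of the net
    mineralization flux.  Strictly decreasing in NPP*, kr and (1-af)/sr.
    """
    if npp_star < 0.0:
        raise ValueError("npp_star must be nonnegative")
    return float(_r_star_arrays(traits.kr, traits.af, traits.sr, npp_star, constants))


def i_star(
    traits: TraitVector,
    npp_star: float,
    ipar: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Residual light at the soil surface at equilibrium (MJ m-2 yr-1).

    ``I* = IPAR exp(-ks 0.4 SLA af/[C]_f NPP*)`` with SLA converted to
    m2 g-1 DM.  Strictly decreasing in NPP*, ks, SLA and af.
    """
    if npp_star < 0.0:
        raise ValueError("npp_star must be nonnegative")
    return float(
        _i_star_arrays(traits.ks, traits.sla, traits.af, npp_star, ipar, constants)
    )


# ---------------------------------------------------------------------------
# Export

def equilibria_to_frame(
    species: list[TraitVector], equilibria: list[Equilibrium]
) -> pd.DataFrame:
    """Join surface: one row per species, trait columns + equilibrium columns."""
    if len(species) != len(equilibria):
        raise ValueError("species and equilibria lists differ in length")
    tframe = pd.DataFrame(
        [{"species_id": s.species_id, **{f: getattr(s, f) for f in TRAIT_FIELDS}} for s in species]
    )
    eframe = pd.DataFrame(
        [
            {
                "npp_star": e.npp_star,
                "bf_star": e.bf_star,
                "br_star": e.br_star,
                "nf_star": e.nf_star,
                "lai_star": e.lai_star,
                "nup_star": e.nup_star,
                "r_star": e.r_star,
                "i_star": e.i_star,
                "converged": e.converged,
            }
            for e in equilibria
        ]
    )
    return pd.concat([tframe, eframe], axis=1)
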