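"""Membrane parameter fitting under three soma-dendritic membrane models.

The spatial distribution of specific membrane resistance over the
soma-dendritic surface is not known for these neurons, so three bracketing
assumptions are fitted in parallel:

* ``uniform``        — Rms = Rmd, one free resistance;
* ``leaky_soma``     — Rmd fixed at 50 kOhm*cm^2, Rms (< Rmd) free;
* ``leaky_dendrite`` — Rms fixed at 50 kOhm*cm^2, Rmd (< Rms) free.

For each neuron the free resistance is adjusted by bisection until the
somatic DC input resistance matches the experimental population mean
(130 MOhm, tolerance 0.1 MOhm).  Specific membrane capacitance, uniform
over the surface, is then set per population so that the model membrane
time constant matches its physiological value (17.0 ms WT / 16.9 ms TG) —
either on the experimental 0.5 uF/cm^2 grid with a one-sample t-test
selection, or continuously per neuron.

TG' neurons — TG morphology carrying WT-like membrane — are built by
scaling each fitted TG resistance by the ratio of population-mean WT to
TG resistances and adopting the WT capacitance, with no refit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from . import cable, config
from .morphology import Morphology, compartmentalize, fold_spines_all

__all__ = [
    "MembraneModelSpec",
    "FitResult",
    "CmFitReport",
    "TgPrimeRecipe",
    "build_model",
    "fit_rm",
    "fit_cm",
    "build_tg_prime",
]

KINDS = ("uniform", "leaky_soma", "leaky_dendrite")

#: bisection bracket for the free specific resistance, Ohm*cm^2
_RM_LO, _RM_HI = 0.5e3, 500e3
_MAX_ITER = 60


@dataclass(frozen=True)
class MembraneModelSpec:
    """One soma-dendritic membrane model with concrete parameter values."""

    kind: str
    rms_ohmcm2: float
    rmd_ohmcm2: float
    cm_uf_cm2: float
    ra_ohmcm: float = config.RA_OHMCM

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown membrane model kind {self.kind!r}")
        if self.kind == "uniform" and not math.isclose(self.rms_ohmcm2, self.rmd_ohmcm2):
            raise ValueError("uniform model requires Rms == Rmd")

    @property
    def free_resistance(self) -> float:
        """The resistance that was (or will be) fitted, Ohm*cm^2."""
        return self.rmd_ohmcm2 if self.kind == "leaky_dendrite" else self.rms_ohmcm2

    def with_free_resistance(self, rm: float) -> "MembraneModelSpec":
        if self.kind == "uniform":
            return replace(self, rms_ohmcm2=rm, rmd_ohmcm2=rm)
        if self.kind == "leaky_soma":
            return replace(self, rms_ohmcm2=rm)
        return replace(self, rmd_ohmcm2=rm)


@dataclass
class FitResult:
    """Fitted membrane parameters for one neuron."""

    neuron_id: str
    group: str
    spec: MembraneModelSpec
    achieved_rin_mohm: float
    achieved_tau_ms: float
    tau_per_unit_cm_ms: float  # tau at Cm = 1 uF/cm^2; tau scales linearly in Cm
    iterations: int
    morphology: Morphology


@dataclass
class CmFitReport:
    """Outcome of the population-level capacitance fit."""

    cm_uf_cm2: float
    mode: str
    p_value: float | None  # one-sample t-test at the selected Cm (grid mode)
    neighbor_p: tuple[float | None, float | None]
    ok: bool
    taus_ms: np.ndarray


@dataclass
class TgPrimeRecipe:
    """Population-derived scaling used to build TG' membranes."""

    kind: str
    resistance_scale: float  # mean WT free resistance / mean TG free resistance
    wt_cm_uf_cm2: float


def build_model(
    m: Morphology,
    spec: MembraneModelSpec,
    spine_density: float | None = None,
    spine_area: float = config.SPINE_AREA_UM2,
    max_len: float = config.MAX_COMPARTMENT_LEN_UM,
) -> cable.CompartmentalModel:
    """Discretize, spine-fold and assemble one neuron under a membrane spec."""
    if spine_density is None:
        spine_density = config.SPINE_DENSITY_PER_UM[m.group.value]
    comps = fold_spines_all(compartmentalize(m, max_len), spine_density, spine_area)
    return cable.assemble(
        comps, m.soma_area, spec.rms_ohmcm2, spec.rmd_ohmcm2,
        spec.cm_uf_cm2, spec.ra_ohmcm,
    )


def _spec_template(kind: str, cm: float, ra: float,
                   fixed_rm_ohmcm2: float | None = None) -> MembraneModelSpec:
    """Spec with the fixed side set and a placeholder free resistance."""
    fixed = (config.FIXED_RM_KOHMCM2 * 1e3 if fixed_rm_ohmcm2 is None
             else fixed_rm_ohmcm2)
    # the free side is overwritten by with_free_resistance(); uniform keeps
    # both sides tied
    return MembraneModelSpec(kind, fixed, fixed, cm, ra)


def fit_rm(
    m: Morphology,
    kind: str,
    target_rin_mohm: float = config.TARGET_RIN_MOHM,
    tol_mohm: float = config.RIN_TOL_MOHM,
    cm_uf_cm2: float = 1.0,
    ra_ohmcm: float = config.RA_OHMCM,
    spine_density: float | None = None,
    spine_area: float = config.SPINE_AREA_UM2,
    max_len: float = config.MAX_COMPARTMENT_LEN_UM,
) -> FitResult:
    """Bisect the free specific resistance until R_in matches the target.

    The somatic DC input resistance is strictly increasing in the free
    resistance (more membrane leak anywhere only lowers R_in), so
    bisection on [0.5, 500] kOhm*cm^2 converges monotonically.  Spine
    folding with the neuron's group density is applied throughout, sharing
    the local specific resistance being fitted.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown membrane model kind {kind!r}")
    if tol_mohm <= 0:
        raise ValueError("tolerance must be positive")
    if spine_density is None:
        spine_density = config.SPINE_DENSITY_PER_UM[m.group.value]
    comps = fold_spines_all(compartmentalize(m, max_len), spine_density, spine_area)
    template = _spec_template(kind, cm_uf_cm2, ra_ohmcm)

    def _rin(rm: float) -> float:
        spec = template.with_free_resistance(rm)
        model = cable.assemble(
            comps, m.soma_area, spec.rms_ohmcm2, spec.rmd_ohmcm2,
            spec.cm_uf_cm2, spec.ra_ohmcm,
        )
        return cable.input_resistance(model)

    lo, hi = _RM_LO, _RM_HI
    r_lo, r_hi = _rin(lo), _rin(hi)
    if not (r_lo <= target_rin_mohm <= r_hi):
        raise ValueError(
            f"target R_in {target_rin_mohm} MOhm outside attainable range "
            f"[{r_lo:.2f}, {r_hi:.2f}] MOhm for {m.neuron_id} ({kind})"
        )
    it = 0
    rm = 0.5 * (lo + hi)
    rin = _rin(rm)
    while abs(rin - target_rin_mohm) > tol_mohm and it < _MAX_ITER:
        if rin < target_rin_mohm:
            lo = rm
        else:
            hi = rm
        rm = 0.5 * (lo + hi)
        rin = _rin(rm)
        it += 1
    if abs(rin - target_rin_mohm) > tol_mohm:
        raise RuntimeError(f"R_in bisection did not converge for {m.neuron_id}")

    spec = template.with_free_resistance(rm)
    model = cable.assemble(
        comps, m.soma_area, spec.rms_ohmcm2, spec.rmd_ohmcm2, 1.0, spec.ra_ohmcm
    )
    tau1 = cable.system_time_constant(model)  # tau at Cm = 1
    return FitResult(
        neuron_id=m.neuron_id,
        group=m.group.value,
        spec=spec,
        achieved_rin_mohm=rin,
        achieved_tau_ms=tau1 * cm_uf_cm2,
        tau_per_unit_cm_ms=tau1,
        iterations=it,
        morphology=m,
    )


def fit_cm(
    population: list[FitResult],
    target_tau_ms: float,
    mode: str = "grid",
    grid_step: float = config.CM_GRID_STEP_UF_CM2,
    alpha: float = config.ALPHA,
) -> CmFitReport:
    """Set the population capacitance so model time constants match target.

    With fixed resistances the slowest time constant is exactly linear in
    Cm, so per-neuron taus are ``Cm * tau_per_unit_cm``.  Grid mode picks
    the 0.5-step value whose population mean tau is statistically
    indistinguishable from the target (one-sample t-test, p > alpha) while
    both grid neighbours are rejected; continuous mode solves Cm per
    neuron so tau equals the target exactly (the report carries the mean).
    Fitted specs in `population` are updated in place.
    """
    if not population:
        raise ValueError("empty population")
    tau1 = np.array([fr.tau_per_unit_cm_ms for fr in population])

    def _pvalue(cm: float) -> float:
        taus = cm * tau1
        if np.allclose(taus, target_tau_ms):
            return 1.0
        return float(stats.ttest_1samp(taus, target_tau_ms).pvalue)

    if mode == "continuous":
        cms = target_tau_ms / tau1
        for fr, cm in zip(population, cms):
            fr.spec = replace(fr.spec, cm_uf_cm2=float(cm))
            fr.achieved_tau_ms = target_tau_ms
        return CmFitReport(
            cm_uf_cm2=float(np.mean(cms)), mode=mode, p_value=None,
            neighbor_p=(None, None), ok=True, taus_ms=np.full(len(tau1), target_tau_ms),
        )
    if mode != "grid":
        raise ValueError("mode must be 'grid' or 'continuous'")

    # candidate grid spanning the population's plausible Cm range
    c_lo = max(grid_step, grid_step * math.floor(target_tau_ms / tau1.max() / grid_step))
    c_hi = grid_step * math.ceil(target_tau_ms / tau1.min() / grid_step) + grid_step
    candidates = np.arange(c_lo, c_hi + grid_step / 2, grid_step)
    best_cm, best_p = None, -1.0
    chosen = None
    for cm in candidates:
        p = _pvalue(cm)
        if p > best_p:
            best_cm, best_p = cm, p
        p_dn, p_up = _pvalue(cm - grid_step), _pvalue(cm + grid_step)
        if p > alpha and p_dn <= alpha and p_up <= alpha:
            if chosen is None or p > chosen[1]:
                chosen = (cm, p, p_dn, p_up)
    if chosen is not None:
        cm, p, p_dn, p_up = chosen
        ok = True
    else:  # no grid value passes the mirror criterion; report best candidate
        cm, p = best_cm, best_p
        p_dn, p_up = _pvalue(cm - grid_step), _pvalue(cm + grid_step)
        ok = False
    taus = cm * tau1
    for fr, tau in zip(population, taus):
        fr.spec = replace(fr.spec, cm_uf_cm2=float(cm))
        fr.achieved_tau_ms = float(tau)
    return CmFitReport(
        cm_uf_cm2=float(cm), mode=mode, p_value=p,
        neighbor_p=(p_dn, p_up), ok=ok, taus_ms=taus,
    )


def build_tg_prime(
    tg_pop: list[FitResult],
    wt_pop: list[FitResult],
    spine_density: float | None = None,
    spine_area: float = config.SPINE_AREA_UM2,
    max_len: float = config.MAX_COMPARTMENT_LEN_UM,
) -> tuple[list[FitResult], TgPrimeRecipe]:
    """Construct TG' neurons: TG morphology, WT-like membrane.

    The free resistance of every TG neuron is multiplied by the ratio of
    population-mean WT to TG fitted resistances, and the WT population's
    capacitance is adopted; input resistance and time constant are then
    re-measured (no refit to the 130 MOhm target).  Spine density stays at
    the TG value — spine loss is part of the morphology being kept.
    """
    if not tg_pop or not wt_pop:
        raise ValueError("both populations must be non-empty")
    kinds = {fr.spec.kind for fr in tg_pop} | {fr.spec.kind for fr in wt_pop}
    if len(kinds) != 1:
        raise ValueError(f"membrane model kind mismatch between populations: {kinds}")
    kind = kinds.pop()
    scale = float(
        np.mean([fr.spec.free_resistance for fr in wt_pop])
        / np.mean([fr.spec.free_resistance for fr in tg_pop])
    )
    wt_cm = float(np.mean([fr.spec.cm_uf_cm2 for fr in wt_pop]))
    recipe = TgPrimeRecipe(kind=kind, resistance_scale=scale, wt_cm_uf_cm2=wt_cm)

    out: list[FitResult] = []
    for fr in tg_pop:
        dens = spine_density
        if dens is None:
            dens = config.SPINE_DENSITY_PER_UM[fr.morphology.group.value]
        spec = replace(
            fr.spec.with_free_resistance(fr.spec.free_resistance * scale),
            cm_uf_cm2=wt_cm,
        )
        model = build_model(fr.morphology, spec, dens, spine_area, max_len)
        tau1_model = cable.assemble(
            model.compartments, fr.morphology.soma_area,
            spec.rms_ohmcm2, spec.rmd_ohmcm2, 1.0, spec.ra_ohmcm,
        )
        tau1 = cable.system_time_constant(tau1_model)
        out.append(
            FitResult(
                neuron_id=fr.neuron_id + "'",
                group="TG_PRIME",
                spec=spec,
                achieved_rin_mohm=cable.input_resistance(model),
                achieved_tau_ms=tau1 * wt_cm,
                tau_per_unit_cm_ms=tau1,
                iterations=0,
                morphology=fr.morphology,
            )
        )
    return out, recipe
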