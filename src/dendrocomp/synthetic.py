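"""Stochastic generator of WT-like and TG-like pyramidal morphologies.

The reconstructions behind the reference morphometrics are not public, so
populations of synthetic layer II/III pyramidal neurons are generated
whose summary statistics match the published group profiles: total apical
length, apical and basal membrane area including spines, oblique and
bifurcation counts, diameters by centrifugal order, spine density and
curvature ratio, for wild-type (WT) and amyloid-overexpressing (TG)
groups.

Growth model (deliberately simple — only the summary marginals are
constrained by data):

* an apical shaft subdivided at sampled oblique branch points, carrying
  oblique chains (OT1..OT5) and ending in a terminal tuft binary tree
  (T1..T3), with order-labelled diameters;
* per-neuron totals drawn from a 3-sigma-truncated normal whose SD is the
  published SEM scaled by sqrt(n); the headline totals are sampled by
  stratified quantiles so a population's mean sits on the profile mean far
  more tightly than independent draws would allow, while per-neuron
  spread stays realistic;
* apical length and area are drawn comonotonically (big neurons are big
  in both), and the shaft length fraction is solved so the sampled spiny
  membrane area is met exactly given the sampled diameters;
* basal arbors: 3-6 unbranched dendrites whose total length is
  back-computed from the basal area-including-spines target (the profile
  has no basal length entry) using an inferred basal diameter;
* the curvature ratio shortens the straight-line extent used when the
  neuron is laid out in 3D for SWC export; path lengths are unaffected.

Populations are a pure function of (profile, n, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import config
from ._stats import weighted_ks
from .morphology import Group, Morphology, Section, morphometrics

__all__ = [
    "MorphometricProfile",
    "default_profile",
    "generate_population",
    "validate_population",
    "PopulationReport",
]

_POP_N = 29  # reference population size behind the published SEMs


@dataclass(frozen=True)
class MorphometricProfile:
    """Group-level morphometric targets (mean, per-neuron SD)."""

    group: str
    apical_length_um: tuple[float, float]
    apical_area_incl_um2: tuple[float, float]
    basal_area_incl_um2: tuple[float, float]
    oblique_count: tuple[float, float]
    bifurcation_count: tuple[float, float]
    curvature_ratio: tuple[float, float]
    diam_um: dict  # order label -> (mean, per-neuron SD)
    spine_density_per_um: float
    spine_area_um2: float = config.SPINE_AREA_UM2
    basal_diam_um: tuple[float, float] = (0.75, 0.10)  # inferred, not published
    n: int = _POP_N

    def shifted(self, factor: float) -> "MorphometricProfile":
        """All means scaled by `factor` (dispersion kept) — for power checks."""
        def s(t):
            return (t[0] * factor, t[1])
        return replace(
            self,
            apical_length_um=s(self.apical_length_um),
            apical_area_incl_um2=s(self.apical_area_incl_um2),
            basal_area_incl_um2=s(self.basal_area_incl_um2),
            oblique_count=s(self.oblique_count),
            bifurcation_count=s(self.bifurcation_count),
        )


# Published group means +- SEM; per-neuron SD = SEM * sqrt(29).
_TABLE = {
    "WT": dict(
        apical_length=(1083.0, 92.0),
        apical_area=(5189.0, 434.0),
        basal_area=(1448.0, 80.0),
        obliques=(4.78, 0.33),
        bifurcations=(14.9, 1.3),
        curvature=(0.99, 0.01),
        spine_density=2.0,
        diam={
            "shaft": (0.96, 0.06), "OT1": (0.57, 0.02), "OT2": (0.45, 0.02),
            "OT3": (0.41, 0.03), "OT4": (0.36, 0.02), "OT5": (0.32, 0.02),
            "T1": (0.71, 0.03), "T2": (0.57, 0.04), "T3": (0.39, 0.05),
        },
    ),
    "TG": dict(
        apical_length=(806.0, 60.0),
        apical_area=(3242.0, 209.0),
        basal_area=(1148.0, 77.0),
        obliques=(3.27, 0.28),
        bifurcations=(10.0, 0.7),
        curvature=(0.96, 0.04),
        spine_density=1.5,
        diam={
            "shaft": (1.13, 0.05), "OT1": (0.68, 0.04), "OT2": (0.52, 0.03),
            "OT3": (0.38, 0.03), "OT4": (0.26, 0.02), "OT5": (0.22, 0.02),
            "T1": (0.98, 0.05), "T2": (0.65, 0.03), "T3": (0.41, 0.04),
        },
    ),
}


def default_profile(group: str) -> MorphometricProfile:
    """Reference morphometric profile for ``WT`` or ``TG``.

    Per-neuron dispersion is the published SEM scaled by sqrt(n), n = 29.
    """
    if group not in _TABLE:
        raise ValueError(f"unknown group {group!r} (expected 'WT' or 'TG')")
    t = _TABLE[group]
    rt = math.sqrt(_POP_N)

    def sd(pair):
        return (pair[0], pair[1] * rt)

    return MorphometricProfile(
        group=group,
        apical_length_um=sd(t["apical_length"]),
        apical_area_incl_um2=sd(t["apical_area"]),
        basal_area_incl_um2=sd(t["basal_area"]),
        oblique_count=sd(t["obliques"]),
        bifurcation_count=sd(t["bifurcations"]),
        curvature_ratio=sd(t["curvature"]),
        diam_um={k: sd(v) for k, v in t["diam"].items()},
        spine_density_per_um=t["spine_density"],
    )


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               size: int | None = None, nsig: float = 3.0):
    """Normal truncated at +-3 sigma (avoids negative geometry)."""
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    a, b = -nsig, nsig
    u = rng.random(size)
    lo, hi = stats.norm.cdf(a), stats.norm.cdf(b)
    z = stats.norm.ppf(lo + u * (hi - lo))
    return mean + sd * z


def _stratified_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                          n: int, nsig: float = 3.0) -> np.ndarray:
    """n truncated-normal draws with stratified quantiles (ordered).

    One draw per probability stratum: the sample mean converges to the
    profile mean ~n times faster than with independent draws while the
    marginal distribution is unchanged.
    """
    if sd == 0:
        return np.full(n, mean)
    lo, hi = stats.norm.cdf(-nsig), stats.norm.cdf(nsig)
    u = (np.arange(n) + rng.random(n)) / n
    z = stats.norm.ppf(lo + u * (hi - lo))
    return mean + sd * z


# ---------------------------------------------------------------------------
# single-neuron growth
# ---------------------------------------------------------------------------

def _grow_neuron(
    profile: MorphometricProfile,
    rng: np.random.Generator,
    neuron_id: str,
    draws: dict,
) -> Morphology:
    rho = profile.spine_density_per_um
    s_area = profile.spine_area_um2
    apical_length = draws["apical_length"]
    apical_area = draws["apical_area"]
    basal_area = draws["basal_area"]
    diam = {k: max(0.05, float(draws[f"diam_{k}"])) for k in profile.diam_um}
    # taper constraints: obliques thinner than the trunk they leave, and
    # diameters non-increasing with order along oblique and tuft branches
    diam["OT1"] = min(diam["OT1"], 0.85 * diam["shaft"])
    for k in range(2, 6):
        diam[f"OT{k}"] = min(diam[f"OT{k}"], diam[f"OT{k - 1}"])
    for k in range(2, 4):
        diam[f"T{k}"] = min(diam[f"T{k}"], diam[f"T{k - 1}"])

    n_obl = int(max(0, round(draws["obliques"])))
    n_bif = int(max(n_obl + 1, round(draws["bifurcations"])))
    curvature = float(np.clip(draws["curvature"], 0.5, 1.0))

    # target mean diameter so that pi*dbar*L + rho*s*L equals the area draw
    a_smooth = apical_area - rho * s_area * apical_length
    a_smooth = max(a_smooth, 0.2 * apical_area)
    dbar = a_smooth / (math.pi * apical_length)

    sections: list[dict] = []

    def add(parent, arbor, label, d):
        sec = dict(id=len(sections), parent_id=parent, arbor=arbor,
                   order_label=label, diameter=d, weight=0.0, length=0.0)
        sections.append(sec)
        return sec["id"]

    # --- apical topology ---------------------------------------------------
    shaft_ids = []
    prev = None
    for _ in range(n_obl + 1):
        prev = add(prev, "apical", "shaft", diam["shaft"])
        shaft_ids.append(prev)

    obl_ids: list[int] = []
    for j in range(n_obl):
        # obliques are short side branches: one or two orders deep
        depth = 1 + int(rng.random() < 0.35)
        par = shaft_ids[j]
        for k in range(depth):
            lab = f"OT{min(k + 1, 5)}"
            par = add(par, "apical", lab, diam[lab])
            obl_ids.append(par)

    tuft_ids: list[int] = []

    def tuft(parent, budget, depth):
        """Binary subtree with `budget` additional bifurcations below."""
        lab = f"T{min(depth, 3)}"
        sid = add(parent, "apical", lab, diam[lab])
        tuft_ids.append(sid)
        if budget > 0:
            b = budget - 1
            b1 = b // 2 + int(rng.integers(-1, 2))
            b1 = int(np.clip(b1, 0, b))
            tuft(sid, b1, depth + 1)
            tuft(sid, b - b1, depth + 1)

    extra = max(0, n_bif - n_obl - 1)
    b1 = extra // 2 + int(rng.integers(-1, 2)) if extra else 0
    b1 = int(np.clip(b1, 0, extra))
    tuft(shaft_ids[-1], b1, 1)
    tuft(shaft_ids[-1], extra - b1, 1)

    # --- apical length allocation ------------------------------------------
    # non-shaft weights: obliques thin out with depth, tuft branches
    # lengthen distally
    kids_count: dict[int, int] = {}
    for d in sections:
        if d["parent_id"] is not None:
            kids_count[d["parent_id"]] = kids_count.get(d["parent_id"], 0) + 1
    for sid in obl_ids:
        sections[sid]["weight"] = rng.uniform(0.7, 1.3)
    for sid in tuft_ids:
        # short stretches between branch points, longer terminal branches
        base = 0.35 if kids_count.get(sid) else 1.3
        sections[sid]["weight"] = base * rng.uniform(0.7, 1.3)
    rest = obl_ids + tuft_ids
    w = np.array([sections[sid]["weight"] for sid in rest])
    d_of_rest = np.array([sections[sid]["diameter"] for sid in rest])
    d_sh = diam["shaft"]
    # shaft share follows from the absolute trunk length draw; shrunk
    # further when the thick shaft would make the sampled membrane area
    # unreachable with the sampled branch diameters
    f_sh = float(np.clip(draws["shaft_length"] / apical_length, 0.04, 0.30))
    d_min = float(d_of_rest.min())
    if d_sh > d_min and (dbar - f_sh * d_sh) / (1.0 - f_sh) < 1.02 * d_min:
        f_feas = (dbar - 1.02 * d_min) / (d_sh - 1.02 * d_min)
        f_sh = float(np.clip(f_feas, 0.03, f_sh))

    # tilt the non-shaft length weights between thick and thin branches
    # (w_i * exp(-beta * d_i), beta solved by bisection) so the sampled
    # spiny membrane area is met by the length mix at fixed diameters
    d_target_rest = (dbar - f_sh * d_sh) / (1.0 - f_sh)
    d_target_rest = float(np.clip(d_target_rest, d_of_rest.min(), d_of_rest.max()))

    def _mean_d(beta: float) -> float:
        wt = w * np.exp(-beta * d_of_rest)
        return float(np.sum(wt * d_of_rest) / np.sum(wt))

    if abs(_mean_d(0.0) - d_target_rest) > 1e-4 and np.ptp(d_of_rest) > 1e-6:
        lo, hi = -30.0, 30.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _mean_d(mid) > d_target_rest:
                lo = mid  # larger beta -> thinner mix -> smaller mean d
            else:
                hi = mid
        beta = 0.5 * (lo + hi)
        w = w * np.exp(-beta * d_of_rest)
        for sid, wt in zip(rest, w):
            sections[sid]["weight"] = float(wt)

    l_shaft = f_sh * apical_length
    parts = rng.dirichlet(np.full(len(shaft_ids), 4.0)) * l_shaft
    for sid, L in zip(shaft_ids, parts):
        sections[sid]["length"] = max(0.5, float(L))
    l_rest = (1.0 - f_sh) * apical_length
    scaled = w / w.sum() * l_rest
    for sid, L in zip(rest, scaled):
        sections[sid]["length"] = max(0.5, float(L))

    # --- basal arbor --------------------------------------------------------
    n_basal = int(rng.integers(3, 7))
    d_b = draws["basal_diam"]
    l_basal = basal_area / (math.pi * d_b + rho * s_area)
    parts = rng.dirichlet(np.full(n_basal, 4.0)) * l_basal
    for L in parts:
        add(None, "basal", "basal", d_b)
        sections[-1]["length"] = max(0.5, float(L))

    secs = [
        Section(id=d["id"], parent_id=d["parent_id"], arbor=d["arbor"],
                order_label=d["order_label"], length=d["length"],
                diameter=d["diameter"])
        for d in sections
    ]
    return Morphology(
        neuron_id=neuron_id,
        group=Group(profile.group if profile.group in ("WT", "TG") else "TG_PRIME"),
        soma_area=config.SOMA_AREA_UM2,
        sections=secs,
        curvature_ratio=curvature,
    )


def generate_population(
    profile: MorphometricProfile, n: int, seed: int
) -> list[Morphology]:
    """Generate `n` morphologies; pure function of (profile, n, seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence([int(seed), 0xD37D])
    rng_pop = np.random.default_rng(ss)

    def strat(pair, perm=None, floor=None):
        v = _stratified_truncnorm(rng_pop, *pair, n)
        v = v[perm if perm is not None else rng_pop.permutation(n)]
        if floor is not None:
            v = np.maximum(v, floor)
        return v

    # headline totals comonotone (big neurons are big in length and area);
    # everything else gets its own stratification and shuffle
    order = rng_pop.permutation(n)
    draws = {
        "apical_length": strat(profile.apical_length_um, order, 50.0),
        "apical_area": strat(profile.apical_area_incl_um2, order, 100.0),
        "basal_area": strat(profile.basal_area_incl_um2, floor=50.0),
        # branch counts comonotone with size: big arbors branch more, which
        # keeps terminal path lengths (and electrotonic depth) realistic
        "obliques": strat(profile.oblique_count, order, floor=0.0),
        "bifurcations": strat(profile.bifurcation_count, order, floor=1.0),
        "curvature": strat(profile.curvature_ratio),
        "basal_diam": strat(profile.basal_diam_um, floor=0.2),
        # absolute trunk length: set by cortical depth, not arbor size
        "shaft_length": strat((120.0, 25.0), floor=50.0),
    }
    for lab, pair in profile.diam_um.items():
        draws[f"diam_{lab}"] = strat(pair, floor=0.05)

    children = ss.spawn(n)
    pop = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        pop.append(
            _grow_neuron(
                profile, rng, f"{profile.group}_{seed}_{i:03d}",
                {k: float(v[i]) for k, v in draws.items()},
            )
        )
    return pop


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class PopulationReport:
    """Generator self-consistency report for one population."""

    t_tests: dict = field(default_factory=dict)  # name -> (mean, target, p)
    ks_tests: dict = field(default_factory=dict)  # name -> (D, p)
    failures: list = field(default_factory=list)
    alpha: float = config.ALPHA

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_population(
    pop: list[Morphology],
    profile: MorphometricProfile,
    alpha: float = config.ALPHA,
) -> PopulationReport:
    """Check a generated population against its profile.

    One-sample t-tests of each headline summary against the profile mean,
    plus a weighted KS comparison between the length-weighted and the
    surface-weighted path-distance distributions (these should agree when
    spine density is uniform, mirroring the observation that dendritic
    surface fraction tracks synapse fraction).
    """
    if len(pop) < 2:
        raise ValueError("need at least 2 neurons")
    rep = PopulationReport(alpha=alpha)
    mm = [morphometrics(m, profile.spine_density_per_um, profile.spine_area_um2)
          for m in pop]

    checks = {
        "apical_length_um": (
            [x["apical"]["length"] for x in mm], profile.apical_length_um[0]),
        "apical_area_incl_um2": (
            [x["apical"]["area_incl_spines"] for x in mm],
            profile.apical_area_incl_um2[0]),
        "basal_area_incl_um2": (
            [x["basal"]["area_incl_spines"] for x in mm],
            profile.basal_area_incl_um2[0]),
        "oblique_count": ([x["n_obliques"] for x in mm], profile.oblique_count[0]),
        "bifurcation_count": (
            [x["n_bifurcations_apical"] for x in mm], profile.bifurcation_count[0]),
        "shaft_diam_um": (
            [x["diam_by_order"].get("shaft", np.nan) for x in mm],
            profile.diam_um["shaft"][0]),
    }
    for name, (vals, target) in checks.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if np.allclose(vals.std(), 0.0):
            p = 1.0 if np.allclose(vals.mean(), target, rtol=0.05) else 0.0
        else:
            p = float(stats.ttest_1samp(vals, target).pvalue)
        rep.t_tests[name] = (float(np.mean(vals)), target, p)
        if p <= alpha:
            rep.failures.append(f"t-test {name}: mean {np.mean(vals):.3g} vs {target:.3g} (p={p:.3g})")

    # length- vs surface-weighted distance distributions
    mids, wl, wa = [], [], []
    for m in pop:
        for s in m.sections:
            mids.append(m.path_distance_to_start(s.id) + s.length / 2)
            wl.append(s.length)
            wa.append(s.lateral_area
                      + profile.spine_density_per_um * s.length * profile.spine_area_um2)
    d, p = weighted_ks(mids, wl, mids, wa)
    rep.ks_tests["length_vs_surface_distance"] = (d, p)
    if p <= alpha:
        rep.failures.append(f"KS length vs surface distance distributions (p={p:.3g})")
    return rep
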