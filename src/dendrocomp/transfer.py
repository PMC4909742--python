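"""Dendritic signal-transfer metrics and binned two-group comparisons.

For each fitted neuron, simulated synaptic sites are spread over the
dendrites so that neighbouring sites are never farther apart than 37 um
and 0.2 local space constants.  Five subthreshold metrics are computed
per site, all for somatopetal propagation:

* ``vt_dc``  — steady-state voltage transfer u_soma / u_site;
* ``vt_50``  — 50 Hz sinusoidal voltage transfer |V_soma / V_site|;
* ``ct``     — current transfer, the fraction of injected charge
  dissipated through the soma membrane (g_soma * u_soma per unit
  current; at DC all charge that reaches the soma node exits there);
* ``local_delay_ms`` / ``propagation_delay_ms`` — centroid delays from
  the moment solves.

Each site carries the membrane surface (spines included) of the stretch
of dendrite it represents, so site weights partition the neuron's total
dendritic area and surface-weighted metric distributions read as
"percentage of synapses operating in this metric range".

Group comparisons bin per-neuron metric means along a chosen axis and
apply the Mann-Whitney test per bin; the summary percentage of
significant bins among tested bins quantifies how different two groups'
dendritic signaling is.  The compensation assessment asks, in every bin
where WT and TG' (atrophied morphology, healthy membrane) differ, whether
WT and TG (atrophied morphology, altered membrane) do not — i.e. whether
the membrane change rescued signaling there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd
from scipy import stats
import scipy.sparse as sp

from . import cable, config
from ._stats import weighted_ks
from .fitting import FitResult
from .morphology import compartmentalize, fold_spines_all

__all__ = [
    "TransferRecord",
    "ComparisonGraph",
    "CompensationReport",
    "place_sites",
    "compute_transfers",
    "records_to_frame",
    "comparison_graphs",
    "surface_weighted_distribution",
    "normalize_scales",
    "compensation_assessment",
    "METRICS",
]

METRICS = ("vt_dc", "vt_50", "ct", "local_delay_ms", "propagation_delay_ms")


@dataclass(frozen=True)
class TransferRecord:
    neuron_id: str
    group: str
    site: int  # node index in the site-resolution model
    arbor: str
    path_distance_um: float
    electrotonic_distance: float
    vt_dc: float
    vt_50: float
    ct: float
    local_delay_ms: float
    propagation_delay_ms: float
    surface_weight_um2: float  # dendritic membrane incl. spines represented


def place_sites(
    fit: FitResult,
    spine_density: float | None = None,
    spine_area: float = config.SPINE_AREA_UM2,
    max_spacing_um: float = config.MAX_SITE_SPACING_UM,
    max_spacing_lambda: float = config.MAX_SITE_SPACING_LAMBDA,
) -> cable.CompartmentalModel:
    """Discretize a fitted neuron at injection-site resolution.

    Every section is cut so compartment length (= neighbour site spacing)
    is at most min(37 um, 0.2 lambda_local), with lambda computed from the
    fitted dendritic resistance, spine-folded.  Every dendritic
    compartment midpoint is an injection site; its surface weight is the
    compartment's spiny membrane area, so weights partition the arbor.
    """
    m = fit.morphology
    if spine_density is None:
        spine_density = config.SPINE_DENSITY_PER_UM[m.group.value]
    spec = fit.spec

    def bound(sec):
        q = 1.0 + spine_density * spine_area / (math.pi * sec.diameter)
        lam = cable.space_constant_um(sec.diameter, spec.rmd_ohmcm2, spec.ra_ohmcm, q)
        return min(max_spacing_um, max_spacing_lambda * lam)

    comps = fold_spines_all(compartmentalize(m, bound), spine_density, spine_area)
    return cable.assemble(
        comps, m.soma_area, spec.rms_ohmcm2, spec.rmd_ohmcm2,
        spec.cm_uf_cm2, spec.ra_ohmcm,
    )


def compute_transfers(
    fit: FitResult,
    model: cable.CompartmentalModel | None = None,
    f_hz: float = 50.0,
) -> list[TransferRecord]:
    """All five transfer/delay metrics at every injection site of a neuron."""
    if model is None:
        model = place_sites(fit)
    n = model.n_nodes
    G = model.G.toarray()
    W = np.linalg.inv(G)  # transfer resistance matrix, W[j, i] = u_j per A at i
    c = model.c
    # first moments: w_j(i) = [W diag(c) W]_{j,i}
    M = W @ (c[:, None] * W)
    Z = np.linalg.inv(G + 1j * 2 * math.pi * f_hz * np.diag(c))

    # electrotonic path distance to each compartment midpoint
    lam = model.space_constants_um()
    pi_mid = np.zeros(len(model.compartments))
    pi_end = {}  # compartment id -> electrotonic distance to distal end
    for comp in model.compartments:  # parents precede children (DFS order)
        base = 0.0 if comp.parent_id is None else pi_end[comp.parent_id]
        step = comp.length / lam[comp.id]
        pi_mid[comp.id] = base + step / 2.0
        pi_end[comp.id] = base + step

    g_soma = model.g_membrane[0]
    out = []
    for comp in model.compartments:
        i = comp.id + 1
        u_site, u_soma = W[i, i], W[0, i]
        local = M[i, i] / u_site
        prop = M[0, i] / u_soma - local
        out.append(
            TransferRecord(
                neuron_id=fit.neuron_id,
                group=fit.group,
                site=i,
                arbor=comp.arbor,
                path_distance_um=comp.midpoint_path_distance,
                electrotonic_distance=float(pi_mid[comp.id]),
                vt_dc=float(u_soma / u_site),
                vt_50=float(abs(Z[0, i] / Z[i, i])),
                ct=float(g_soma * u_soma),
                local_delay_ms=1e3 * float(local),
                propagation_delay_ms=1e3 * float(prop),
                surface_weight_um2=comp.q * comp.A_d,
            )
        )
    return out


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# comparison graphs
# ---------------------------------------------------------------------------

@dataclass
class ComparisonGraph:
    """Binned two-group comparison of one metric along one axis."""

    axis: str
    metric: str
    bin_edges: np.ndarray
    mean_a: np.ndarray  # per-bin mean of per-neuron means, group A
    mean_b: np.ndarray
    n_a: np.ndarray  # contributing neurons per bin
    n_b: np.ndarray
    p_values: np.ndarray  # NaN where not tested
    tested: np.ndarray  # bool
    significant: np.ndarray  # bool
    alpha: float

    @property
    def percent_difference(self) -> float:
        """100 * (significant bins) / (tested bins); NaN if none tested."""
        nt = int(self.tested.sum())
        if nt == 0:
            return float("nan")
        return 100.0 * float(self.significant.sum()) / nt


def _per_neuron_bin_means(df: pd.DataFrame, axis: str, metric: str,
                          edges: np.ndarray) -> pd.DataFrame:
    d = df.copy()
    d["bin"] = np.digitize(d[axis].to_numpy(), edges) - 1
    d = d[(d["bin"] >= 0) & (d["bin"] < len(edges) - 1)]
    return d.groupby(["neuron_id", "bin"], sort=True)[metric].mean().reset_index()


def comparison_graphs(
    records_a,
    records_b,
    metric: str,
    axis: str = "path_distance_um",
    bin_width: float = config.BIN_WIDTH_PATH_UM,
    alpha: float = config.ALPHA,
    min_n: int = config.MIN_NEURONS_PER_BIN,
) -> ComparisonGraph:
    """Mann-Whitney comparison of per-neuron bin means between two groups.

    The sampling unit per bin is the neuron (mean over its sites in the
    bin), avoiding pseudo-replication across the many sites of a single
    cell.  A bin is tested only when at least ``min_n`` neurons of each
    group contribute.
    """
    fa, fb = records_to_frame(records_a), records_to_frame(records_b)
    if fa.empty or fb.empty:
        raise ValueError("both record sets must be non-empty")
    hi = max(fa[axis].max(), fb[axis].max())
    nbins = max(1, math.ceil((hi + 1e-9) / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    ga = _per_neuron_bin_means(fa, axis, metric, edges)
    gb = _per_neuron_bin_means(fb, axis, metric, edges)

    mean_a = np.full(nbins, np.nan)
    mean_b = np.full(nbins, np.nan)
    n_a = np.zeros(nbins, dtype=int)
    n_b = np.zeros(nbins, dtype=int)
    pvals = np.full(nbins, np.nan)
    tested = np.zeros(nbins, dtype=bool)
    sig = np.zeros(nbins, dtype=bool)
    for b in range(nbins):
        xa = ga.loc[ga["bin"] == b, metric].to_numpy()
        xb = gb.loc[gb["bin"] == b, metric].to_numpy()
        n_a[b], n_b[b] = len(xa), len(xb)
        if len(xa):
            mean_a[b] = xa.mean()
        if len(xb):
            mean_b[b] = xb.mean()
        if len(xa) >= min_n and len(xb) >= min_n:
            tested[b] = True
            if np.allclose(xa, xa.mean()) and np.allclose(xb, xb.mean()) \
                    and np.isclose(xa.mean(), xb.mean()):
                pvals[b] = 1.0
            else:
                pvals[b] = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            sig[b] = pvals[b] < alpha
    return ComparisonGraph(
        axis=axis, metric=metric, bin_edges=edges, mean_a=mean_a, mean_b=mean_b,
        n_a=n_a, n_b=n_b, p_values=pvals, tested=tested, significant=sig,
        alpha=alpha,
    )


def surface_weighted_distribution(
    records_a,
    records_b,
    metric: str,
    bin_width: float = config.BIN_WIDTH_TRANSFER,
) -> dict:
    """Percent of total dendritic surface per metric bin, per group.

    Mirrors the "weight of a given transfer/delay value" view: the mass in
    a bin is the fraction of the group's dendritic membrane (~synapses)
    whose local PSPs see that metric value.  Returns the two normalized
    histograms plus a weighted two-sample KS comparison.
    """
    fa, fb = records_to_frame(records_a), records_to_frame(records_b)
    hi = max(fa[metric].max(), fb[metric].max())
    nbins = max(1, math.ceil((hi + 1e-9) / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    out = {}
    for name, f in (("a", fa), ("b", fb)):
        h, _ = np.histogram(
            f[metric], bins=edges, weights=f["surface_weight_um2"]
        )
        out[f"percent_{name}"] = 100.0 * h / f["surface_weight_um2"].sum()
    d, p = weighted_ks(
        fa[metric], fa["surface_weight_um2"], fb[metric], fb["surface_weight_um2"]
    )
    out.update(bin_edges=edges, ks_stat=d, ks_p=p)
    return out


def normalize_scales(records) -> list[TransferRecord]:
    """Express distances and metrics as percent of each neuron's maximum.

    Removes natural size variation between neurons: the most distal site
    of every neuron maps to distance 100, the largest delay to 100, etc.
    Idempotent (a normalized set normalizes to itself).
    """
    df = records_to_frame(records)
    fields = ["path_distance_um", "electrotonic_distance", *METRICS]
    maxima = df.groupby("neuron_id")[fields].max()
    if (maxima <= 0).any().any():
        raise ValueError("cannot normalize: a neuron has a non-positive maximum")
    out = []
    for r in records:
        mx = maxima.loc[r.neuron_id]
        out.append(
            replace(
                r,
                path_distance_um=100.0 * r.path_distance_um / mx["path_distance_um"],
                electrotonic_distance=100.0 * r.electrotonic_distance
                / mx["electrotonic_distance"],
                vt_dc=100.0 * r.vt_dc / mx["vt_dc"],
                vt_50=100.0 * r.vt_50 / mx["vt_50"],
                ct=100.0 * r.ct / mx["ct"],
                local_delay_ms=100.0 * r.local_delay_ms / mx["local_delay_ms"],
                propagation_delay_ms=100.0 * r.propagation_delay_ms
                / mx["propagation_delay_ms"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# compensation assessment
# ---------------------------------------------------------------------------

@dataclass
class CompensationRow:
    metric: str
    arbor: str
    ranges_needed: int  # bins where WT vs TG' differ (compensation needed)
    ranges_success: int  # ... and WT vs TG do not differ (compensation worked)

    @property
    def success_rate(self) -> float:
        if self.ranges_needed == 0:
            return float("nan")  # N/A: no compensation was needed
        return self.ranges_success / self.ranges_needed


@dataclass
class CompensationReport:
    rows: list[CompensationRow] = field(default_factory=list)

    @property
    def overall_needed(self) -> int:
        return sum(r.ranges_needed for r in self.rows)

    @property
    def overall_success(self) -> int:
        return sum(r.ranges_success for r in self.rows)

    @property
    def overall_rate(self) -> float:
        if self.overall_needed == 0:
            return float("nan")
        return self.overall_success / self.overall_needed


def _bin_width_for(metric: str, cfg_delay: float, cfg_transfer: float) -> float:
    return cfg_delay if metric.endswith("_ms") else cfg_transfer


def compensation_assessment(
    wt_records,
    tg_records,
    tgp_records,
    metrics=METRICS,
    axis: str = "path_distance_um",
    bin_width: float = config.BIN_WIDTH_PATH_UM,
    alpha: float = config.ALPHA,
    min_n: int = config.MIN_NEURONS_PER_BIN,
) -> CompensationReport:
    """Quantify how well membrane alterations rescue dendritic signaling.

    For each metric and arbor: a bin "needs" compensation when WT and TG'
    (atrophy only) differ significantly there; compensation "succeeded"
    when WT and TG (atrophy plus membrane change) do not differ in that
    same bin.  The success rate is successes / needs.
    """
    report = CompensationReport()
    for metric in metrics:
        for arbor in ("apical", "basal"):
            wt = [r for r in wt_records if r.arbor == arbor]
            tg = [r for r in tg_records if r.arbor == arbor]
            tgp = [r for r in tgp_records if r.arbor == arbor]
            if not wt or not tg or not tgp:
                continue
            g_prime = comparison_graphs(wt, tgp, metric, axis, bin_width, alpha, min_n)
            g_tg = comparison_graphs(wt, tg, metric, axis, bin_width, alpha, min_n)
            nb = min(len(g_prime.significant), len(g_tg.significant))
            needed = g_prime.significant[:nb] & g_tg.tested[:nb]
            success = needed & ~g_tg.significant[:nb]
            report.rows.append(
                CompensationRow(
                    metric=metric, arbor=arbor,
                    ranges_needed=int(needed.sum()),
                    ranges_success=int(success.sum()),
                )
            )
    return report
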