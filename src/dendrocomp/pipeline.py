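"""End-to-end experiment orchestration and reporting.

``run_experiment`` drives the whole comparison: generate synthetic WT and
TG populations, fit the three membrane models per neuron, construct TG'
neurons (TG morphology, WT-like membrane), compute per-site transfer and
delay records, build binned comparison graphs for WT-TG and WT-TG',
assess compensation, and compute pattern-recognition predictors.  The
bundle is a pure function of the configuration (which contains the master
seed); ``report`` serializes it to CSV tables and figures, each output
file carrying the configuration hash in a comment header.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import fitting, predictors as predictors_mod, synthetic, transfer
from .config import ExperimentConfig
from .morphology import Morphology, write_swc

__all__ = ["ExperimentBundle", "KindResult", "run_experiment", "report"]

_PAIRS = (("WT", "TG"), ("WT", "TG_PRIME"))


@dataclass
class KindResult:
    """Everything computed under one membrane model kind."""

    kind: str
    fits: dict = field(default_factory=dict)  # group -> list[FitResult]
    cm_reports: dict = field(default_factory=dict)  # group -> CmFitReport
    tg_prime_recipe: fitting.TgPrimeRecipe | None = None
    records: dict = field(default_factory=dict)  # group -> list[TransferRecord]
    graphs: dict = field(default_factory=dict)  # (metric, arbor, pair) -> graph
    compensation: transfer.CompensationReport | None = None
    predictors: dict = field(default_factory=dict)  # group -> list[preds]
    predictor_comparisons: dict = field(default_factory=dict)  # pair -> dict


@dataclass
class ExperimentBundle:
    cfg: ExperimentConfig
    populations: dict  # group -> list[Morphology]
    kinds: dict  # kind -> KindResult

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.cfg.to_yaml().encode()).hexdigest()[:12]


def _percent_difference_table(kr: KindResult) -> pd.DataFrame:
    rows = []
    for (metric, arbor, pair), g in kr.graphs.items():
        rows.append(
            dict(kind=kr.kind, metric=metric, arbor=arbor,
                 comparison="-".join(pair),
                 tested_bins=int(g.tested.sum()),
                 significant_bins=int(g.significant.sum()),
                 percent_difference=g.percent_difference)
        )
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig, log=print) -> ExperimentBundle:
    """Run the full generate -> fit -> analyze -> compare pipeline."""
    cfg.validate()
    log(f"generating populations (n={cfg.n_per_group}, seed={cfg.seed})")
    populations = {
        g: synthetic.generate_population(
            synthetic.default_profile(g), cfg.n_per_group, cfg.seed
        )
        for g in ("WT", "TG")
    }

    kinds: dict[str, KindResult] = {}
    for kind in cfg.model_kinds:
        kr = KindResult(kind=kind)
        for group in ("WT", "TG"):
            fits = []
            for m in populations[group]:
                fr = fitting.fit_rm(
                    m, kind,
                    target_rin_mohm=cfg.target_rin_mohm,
                    tol_mohm=cfg.rin_tol_mohm,
                    ra_ohmcm=cfg.ra_ohmcm,
                    spine_density=cfg.spine_density_per_um[group],
                    spine_area=cfg.spine_area_um2,
                    max_len=cfg.max_compartment_len_um,
                )
                fits.append(fr)
                log(f"  [{kind}/{group}] {fr.neuron_id}: free Rm = "
                    f"{fr.spec.free_resistance / 1e3:.2f} kOhm*cm^2, "
                    f"R_in = {fr.achieved_rin_mohm:.2f} MOhm "
                    f"({fr.iterations} iter)")
            kr.cm_reports[group] = fitting.fit_cm(
                fits, cfg.target_tau_ms[group], mode=cfg.cm_mode,
                grid_step=cfg.cm_grid_step, alpha=cfg.alpha,
            )
            log(f"  [{kind}/{group}] Cm = {kr.cm_reports[group].cm_uf_cm2:.2f} "
                f"uF/cm^2 (mode={cfg.cm_mode})")
            kr.fits[group] = fits
        tgp, recipe = fitting.build_tg_prime(
            kr.fits["TG"], kr.fits["WT"],
            spine_density=cfg.spine_density_per_um["TG_PRIME"],
            spine_area=cfg.spine_area_um2,
            max_len=cfg.max_compartment_len_um,
        )
        kr.fits["TG_PRIME"] = tgp
        kr.tg_prime_recipe = recipe
        log(f"  [{kind}] TG' resistance scale = {recipe.resistance_scale:.3f}, "
            f"Cm = {recipe.wt_cm_uf_cm2:.2f} uF/cm^2")

        for group, fits in kr.fits.items():
            recs = []
            for fr in fits:
                recs.extend(
                    transfer.compute_transfers(
                        fr,
                        transfer.place_sites(
                            fr,
                            spine_density=cfg.spine_density_per_um[group],
                            spine_area=cfg.spine_area_um2,
                        ),
                    )
                )
            kr.records[group] = recs
            kr.predictors[group] = [
                p
                for fr in fits
                for p in predictors_mod.predictors(
                    fr, cfg.spine_density_per_um[group], cfg.spine_area_um2
                )
            ]

        for pair in _PAIRS:
            ra = kr.records[pair[0]]
            rb = kr.records[pair[1]]
            for metric in transfer.METRICS:
                for arbor in ("apical", "basal"):
                    kr.graphs[(metric, arbor, pair)] = transfer.comparison_graphs(
                        [r for r in ra if r.arbor == arbor],
                        [r for r in rb if r.arbor == arbor],
                        metric,
                        bin_width=cfg.bin_width_path_um,
                        alpha=cfg.alpha,
                        min_n=cfg.min_neurons_per_bin,
                    )
            kr.predictor_comparisons[pair] = predictors_mod.compare_predictors(
                kr.predictors[pair[0]], kr.predictors[pair[1]], cfg.alpha
            )

        kr.compensation = transfer.compensation_assessment(
            kr.records["WT"], kr.records["TG"], kr.records["TG_PRIME"],
            bin_width=cfg.bin_width_path_um, alpha=cfg.alpha,
            min_n=cfg.min_neurons_per_bin,
        )
        log(f"  [{kind}] compensation: {kr.compensation.overall_success}/"
            f"{kr.compensation.overall_needed} ranges rescued")
        kinds[kind] = kr
    return ExperimentBundle(cfg=cfg, populations=populations, kinds=kinds)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def report(bundle: ExperimentBundle, out_dir: str | None = None) -> dict:
    """Serialize a bundle: CSV tables, SWC morphologies, summary figures.

    Returns a dict of written paths.  A partial bundle (missing kinds or
    groups) produces a partial report with warnings rather than failing.
    """
    cfg = bundle.cfg
    out = out_dir or cfg.out_dir
    os.makedirs(out, exist_ok=True)
    h = bundle.config_hash
    written: dict[str, str] = {}
    warnings: list[str] = []

    with open(os.path.join(out, "config.yaml"), "w") as fh:
        fh.write(f"# config_hash: {h}\n" + cfg.to_yaml())
    written["config"] = os.path.join(out, "config.yaml")

    # population manifest + SWC
    swc_dir = os.path.join(out, "morphologies")
    os.makedirs(swc_dir, exist_ok=True)
    man_rows = []
    for group, pop in bundle.populations.items():
        for m in pop:
            p = os.path.join(swc_dir, f"{m.neuron_id}.swc")
            write_swc(m, p)
            man_rows.append(
                dict(neuron_id=m.neuron_id, group=group, seed=cfg.seed,
                     apical_length_um=m.total_length("apical"),
                     basal_length_um=m.total_length("basal"),
                     n_sections=len(m.sections), swc=os.path.basename(p))
            )
    _write_csv(pd.DataFrame(man_rows), os.path.join(out, "population_manifest.csv"), h)
    written["manifest"] = os.path.join(out, "population_manifest.csv")

    fit_rows, rec_frames, pct_frames, comp_rows, pred_rows = [], [], [], [], []
    for kind, kr in bundle.kinds.items():
        for group, fits in kr.fits.items():
            for fr in fits:
                fit_rows.append(
                    dict(kind=kind, group=group, neuron_id=fr.neuron_id,
                         rms_ohmcm2=fr.spec.rms_ohmcm2,
                         rmd_ohmcm2=fr.spec.rmd_ohmcm2,
                         cm_uf_cm2=fr.spec.cm_uf_cm2,
                         rin_mohm=fr.achieved_rin_mohm,
                         tau_ms=fr.achieved_tau_ms,
                         iterations=fr.iterations)
                )
        for group, recs in kr.records.items():
            f = transfer.records_to_frame(recs)
            f.insert(0, "kind", kind)
            rec_frames.append(f)
        pct_frames.append(_percent_difference_table(kr))
        if kr.compensation is None:
            warnings.append(f"kind {kind}: no compensation report")
        else:
            for row in kr.compensation.rows:
                comp_rows.append(
                    dict(kind=kind, metric=row.metric, arbor=row.arbor,
                         ranges_needed=row.ranges_needed,
                         ranges_success=row.ranges_success,
                         success_rate=row.success_rate)
                )
            comp_rows.append(
                dict(kind=kind, metric="ALL", arbor="both",
                     ranges_needed=kr.compensation.overall_needed,
                     ranges_success=kr.compensation.overall_success,
                     success_rate=kr.compensation.overall_rate)
            )
        for group, preds in kr.predictors.items():
            for p in preds:
                pred_rows.append(
                    dict(kind=kind, group=group, neuron_id=p.neuron_id,
                         arbor=p.arbor, n=p.n, mean_pi=p.mean_pi,
                         var_pi=p.var_pi)
                )

    for name, df in (
        ("fits", pd.DataFrame(fit_rows)),
        ("transfer_records", pd.concat(rec_frames, ignore_index=True)
         if rec_frames else pd.DataFrame()),
        ("percent_differences", pd.concat(pct_frames, ignore_index=True)
         if pct_frames else pd.DataFrame()),
        ("compensation", pd.DataFrame(comp_rows)),
        ("predictors", pd.DataFrame(pred_rows)),
    ):
        path = os.path.join(out, f"{name}.csv")
        _write_csv(df, path, h)
        written[name] = path

    # -- figures ------------------------------------------------------------
    try:
        written["fig_percent_difference"] = _plot_percent_difference(
            pd.concat(pct_frames, ignore_index=True), out
        )
        written["fig_predictors"] = _plot_predictors(pd.DataFrame(pred_rows), out)
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        warnings.append(f"plotting failed: {exc}")

    if warnings:
        written["warnings"] = "; ".join(warnings)
    return written


def _plot_percent_difference(df: pd.DataFrame, out: str) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=True)
    for ax, comparison in zip(axes, ("WT-TG", "WT-TG_PRIME")):
        sub = df[df["comparison"] == comparison]
        if sub.empty:
            continue
        piv = sub.pivot_table(index="metric", columns=["kind", "arbor"],
                              values="percent_difference")
        piv.plot.bar(ax=ax, legend=False)
        ax.set_title(comparison)
        ax.set_ylabel("% of tested ranges significant")
        ax.tick_params(axis="x", rotation=45)
    axes[-1].legend(fontsize=6)
    fig.tight_layout()
    path = os.path.join(out, "percent_differences.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def _plot_predictors(df: pd.DataFrame, out: str) -> str:
    kinds = sorted(df["kind"].unique())
    fig, axes = plt.subplots(2, len(kinds), figsize=(4 * len(kinds), 7),
                             squeeze=False)
    for j, kind in enumerate(kinds):
        for i, valcol in enumerate(("mean_pi", "var_pi")):
            ax = axes[i][j]
            sub = df[(df["kind"] == kind) & (df["arbor"] != "all")]
            data, labels = [], []
            for arbor in ("apical", "basal"):
                for group in ("WT", "TG", "TG_PRIME"):
                    vals = sub[(sub["group"] == group) & (sub["arbor"] == arbor)][valcol]
                    vals = vals.dropna()
                    if len(vals):
                        data.append(vals.to_numpy())
                        labels.append(f"{arbor[:2]}-{group}")
            if data:
                ax.boxplot(data, tick_labels=labels, showmeans=True)
            ax.set_title(f"{kind}: {valcol}")
            ax.tick_params(axis="x", rotation=60, labelsize=6)
    fig.tight_layout()
    path = os.path.join(out, "predictors.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
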