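"""Predictors of synaptic input pattern recognition capacity.

Pattern-recognition studies on large model-neuron ensembles found that a
neuron's ability to discriminate learnt from novel synaptic input
patterns correlates inversely with two simple electrotonic statistics:
the mean electrotonic distance of its synapses from the soma and the
within-cell variance of those distances.  With one synapse per dendritic
segment, both reduce to statistics of Pi_i, the electrotonic distance of
the midpoint of the i-th segment:

    mean_Pi = (1/n) sum_i Pi_i,     var_Pi = (1/n) sum_i (Pi_i - mean)^2

where Pi accumulates physical length over local space constants along the
path from the soma, with spine-folded membrane (q divides the effective
specific resistance).  Populations are compared per arbor with the
Mann-Whitney test: a significant shift in either predictor flags altered
pattern recognition capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import cable, config
from .fitting import FitResult

__all__ = [
    "PatternRecognitionPredictors",
    "electrotonic_midpoints",
    "predictors",
    "compare_predictors",
]


@dataclass(frozen=True)
class PatternRecognitionPredictors:
    neuron_id: str
    group: str
    arbor: str  # "apical" | "basal" | "all"
    n: int
    mean_pi: float
    var_pi: float  # population (divide-by-n) variance


def electrotonic_midpoints(
    fit: FitResult,
    spine_density: float | None = None,
    spine_area: float = config.SPINE_AREA_UM2,
) -> dict[int, tuple[str, float]]:
    """Electrotonic distance Pi of every dendritic segment's midpoint.

    A segment is an unbranched section (branch point to branch point).
    The space constant is uniform within a section, so the midpoint value
    is exact: Pi(start of section) + (L/2)/lambda, accumulated recursively
    from the soma.  Returns {section_id: (arbor, Pi)}.
    """
    m = fit.morphology
    if spine_density is None:
        spine_density = config.SPINE_DENSITY_PER_UM[m.group.value]
    spec = fit.spec

    lam = {}
    for s in m.sections:
        q = 1.0 + spine_density * spine_area / (math.pi * s.diameter)
        lam[s.id] = cable.space_constant_um(s.diameter, spec.rmd_ohmcm2,
                                            spec.ra_ohmcm, q)
    parent = {s.id: s.parent_id for s in m.sections}
    step = {s.id: s.length / lam[s.id] for s in m.sections}
    pi_end: dict[int, float] = {}

    def end_of(sid: int) -> float:
        if sid not in pi_end:
            p = parent[sid]
            pi_end[sid] = (end_of(p) if p is not None else 0.0) + step[sid]
        return pi_end[sid]

    out = {}
    for s in m.sections:
        out[s.id] = (s.arbor, end_of(s.id) - step[s.id] / 2.0)
    return out


def predictors(
    fit: FitResult,
    spine_density: float | None = None,
    spine_area: float = config.SPINE_AREA_UM2,
) -> list[PatternRecognitionPredictors]:
    """mean_Pi and var_Pi per arbor and for the whole cell."""
    mids = electrotonic_midpoints(fit, spine_density, spine_area)
    out = []
    for arbor in ("apical", "basal", "all"):
        vals = np.array(
            [pi for a, pi in mids.values() if arbor == "all" or a == arbor]
        )
        if len(vals) == 0:
            out.append(
                PatternRecognitionPredictors(
                    fit.neuron_id, fit.group, arbor, 0, float("nan"), float("nan")
                )
            )
            continue
        out.append(
            PatternRecognitionPredictors(
                neuron_id=fit.neuron_id,
                group=fit.group,
                arbor=arbor,
                n=len(vals),
                mean_pi=float(vals.mean()),
                var_pi=float(vals.var()),  # population variance
            )
        )
    return out


def compare_predictors(
    preds_a: list[PatternRecognitionPredictors],
    preds_b: list[PatternRecognitionPredictors],
    alpha: float = config.ALPHA,
) -> dict:
    """Mann-Whitney comparison of both predictors, per arbor.

    Returns {arbor: {"mean_pi_p": p, "var_pi_p": p, "altered": bool}};
    "altered" pattern recognition is flagged when either predictor
    differs significantly.
    """
    out = {}
    for arbor in ("apical", "basal"):
        res = {}
        for field_name in ("mean_pi", "var_pi"):
            xa = [getattr(p, field_name) for p in preds_a
                  if p.arbor == arbor and p.n > 0]
            xb = [getattr(p, field_name) for p in preds_b
                  if p.arbor == arbor and p.n > 0]
            if len(xa) < 2 or len(xb) < 2:
                res[f"{field_name}_p"] = float("nan")
                continue
            if np.allclose(xa, np.mean(xa)) and np.allclose(xb, np.mean(xb)) \
                    and np.isclose(np.mean(xa), np.mean(xb)):
                res[f"{field_name}_p"] = 1.0
            else:
                res[f"{field_name}_p"] = float(
                    stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
                )
        ps = [res.get("mean_pi_p", float("nan")), res.get("var_pi_p", float("nan"))]
        res["altered"] = bool(any(p < alpha for p in ps if not math.isnan(p)))
        out[arbor] = res
    return out
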