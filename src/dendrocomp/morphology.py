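"""Neuronal morphologies: SWC I/O, sectioned trees, discretization, spine folding.

A :class:`Morphology` is a rooted tree of cylindrical dendritic
:class:`Section` objects hanging off a single isopotential soma of known
membrane area.  Sections carry an arbor tag (apical / basal) and a
centrifugal order label (apical shaft, oblique orders OT1..OT5, terminal
tuft orders T1..T3, or basal).  For electrical work a morphology is cut
into short cylindrical :class:`Compartment` pieces; dendritic spines are
not modelled as explicit compartments but folded into each compartment's
membrane constants through the area ratio

    q = (A_s + A_d) / A_d

where ``A_d`` is the smooth cylinder area and ``A_s`` the summed area of
the spines the stretch of dendrite carries.  Membrane conductance and
capacitance per unit area are later scaled by ``q`` so that total membrane
(shaft plus spines) is conserved without altering cable geometry.

Lengths are in micrometres, areas in square micrometres.  Path distance is
measured along the tree from the soma surface; the soma contributes zero
length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Group",
    "Section",
    "Morphology",
    "Compartment",
    "SwcError",
    "read_swc",
    "write_swc",
    "compartmentalize",
    "fold_spines",
    "fold_spines_all",
    "morphometrics",
]

#: Default soma membrane area (um^2) used when the SWC soma geometry is
#: overridden; an isopotential equivalent soma — only its area matters.
DEFAULT_SOMA_AREA_UM2 = 452.0

#: Default single-spine membrane area (um^2).
DEFAULT_SPINE_AREA_UM2 = 1.5

#: Default compartment length bound (um).
DEFAULT_MAX_COMPARTMENT_LEN_UM = 37.0

APICAL_ORDER_LABELS = ("shaft", "OT1", "OT2", "OT3", "OT4", "OT5", "T1", "T2", "T3")


class Group(str, Enum):
    """Experimental group of a neuron."""

    WT = "WT"
    TG = "TG"
    TG_PRIME = "TG_PRIME"


class SwcError(ValueError):
    """Raised for malformed SWC input (cycles, orphans, unknown types)."""


@dataclass(frozen=True)
class Section:
    """An unbranched cylindrical stretch of dendrite.

    ``parent_id is None`` means the section is attached to the soma;
    otherwise it is attached to the distal end of the parent section.
    Diameter is uniform over the section (mean of any tapered samples).
    """

    id: int
    parent_id: int | None
    arbor: str  # "apical" | "basal"
    order_label: str  # "shaft", "OT1".."OT5", "T1".."T3", "basal"
    length: float  # um
    diameter: float  # um

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(
                f"section {self.id}: length and diameter must be positive "
                f"(got L={self.length}, d={self.diameter})"
            )
        if self.arbor not in ("apical", "basal"):
            raise ValueError(f"section {self.id}: unknown arbor {self.arbor!r}")

    @property
    def lateral_area(self) -> float:
        """Smooth cylinder membrane area pi*d*L (um^2)."""
        return math.pi * self.diameter * self.length


@dataclass
class Morphology:
    """Soma plus a rooted tree of dendritic sections."""

    neuron_id: str
    group: Group
    soma_area: float  # um^2
    sections: list[Section] = field(default_factory=list)
    #: euclidean extent / path length per section; <= 1; used only to lay
    #: out meandering dendrites in 3D when writing SWC.
    curvature_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.soma_area <= 0:
            raise ValueError("soma_area must be positive")
        self.validate()

    # -- tree helpers -----------------------------------------------------

    def validate(self) -> None:
        """Check tree structure: unique ids, parents exist, no cycles."""
        ids = {s.id for s in self.sections}
        if len(ids) != len(self.sections):
            raise ValueError("duplicate section ids")
        for s in self.sections:
            if s.parent_id is not None and s.parent_id not in ids:
                raise ValueError(f"section {s.id} references missing parent {s.parent_id}")
        # cycle check by walking to root from every node
        parent = {s.id: s.parent_id for s in self.sections}
        for sid in ids:
            seen = set()
            cur: int | None = sid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle through section {cur}")
                seen.add(cur)
                cur = parent[cur]

    def children_map(self) -> dict[int | None, list[Section]]:
        out: dict[int | None, list[Section]] = {}
        for s in self.sections:
            out.setdefault(s.parent_id, []).append(s)
        return out

    def section_by_id(self, sid: int) -> Section:
        for s in self.sections:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def path_distance_to_start(self, sid: int) -> float:
        """Path length (um) from soma surface to the proximal end of a section."""
        parent = {s.id: s.parent_id for s in self.sections}
        length = {s.id: s.length for s in self.sections}
        dist = 0.0
        cur = parent[sid]
        while cur is not None:
            dist += length[cur]
            cur = parent[cur]
        return dist

    def total_length(self, arbor: str | None = None) -> float:
        return sum(s.length for s in self.sections if arbor is None or s.arbor == arbor)


@dataclass(frozen=True)
class Compartment:
    """A short cylinder produced by discretizing a section.

    ``A_s`` is the folded spine area; ``q`` is the fold factor applied later
    to membrane conductance and capacitance.
    """

    id: int
    parent_id: int | None  # None = attached to the soma node
    section_id: int
    length: float  # um
    diameter: float  # um
    arbor: str
    midpoint_path_distance: float  # um from soma
    A_s: float = 0.0  # um^2 of folded spines

    @property
    def A_d(self) -> float:
        """Smooth membrane area pi*d*l (um^2)."""
        return math.pi * self.diameter * self.length

    @property
    def q(self) -> float:
        """Spine fold factor (A_s + A_d)/A_d >= 1."""
        return (self.A_s + self.A_d) / self.A_d


# ---------------------------------------------------------------------------
# SWC input / output
# ---------------------------------------------------------------------------

_SWC_SOMA, _SWC_BASAL, _SWC_APICAL = 1, 3, 4
_ARBOR_OF_TYPE = {_SWC_BASAL: "basal", _SWC_APICAL: "apical"}


def read_swc(
    path,
    *,
    neuron_id: str | None = None,
    group: Group = Group.WT,
    soma_area_um2: float | None = DEFAULT_SOMA_AREA_UM2,
) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Type codes 1 (soma), 3 (basal dendrite) and 4 (apical dendrite) are
    accepted.  All soma samples collapse into a single isopotential soma
    whose area is ``soma_area_um2`` if given, else a sphere computed from
    the mean soma sample radius.  Consecutive unbranched dendrite samples
    of one type form a section; section length is the summed 3D
    point-to-point distance and the diameter the distance-weighted mean.
    Apical order labels (shaft / oblique / tuft) are re-inferred from
    diameters and topology, see :func:`_assign_apical_labels`.
    """
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            sid = int(parts[0])
            typ = int(parts[1])
            x, y, z, r = map(float, parts[2:6])
            par = int(parts[6])
            if typ not in (_SWC_SOMA, _SWC_BASAL, _SWC_APICAL):
                raise SwcError(f"{path}:{lineno}: unknown SWC type code {typ} (sample {sid})")
            if sid in rows:
                raise SwcError(f"{path}:{lineno}: duplicate sample id {sid}")
            rows[sid] = (typ, x, y, z, r, par)

    if not rows:
        raise SwcError(f"{path}: empty SWC file")

    soma_ids = [sid for sid, row in rows.items() if row[0] == _SWC_SOMA]
    if not soma_ids:
        raise SwcError(f"{path}: no soma (type 1) sample")

    # orphan / cycle detection on raw samples
    for sid, row in rows.items():
        par = row[5]
        if par != -1 and par not in rows:
            raise SwcError(f"{path}: sample {sid} references missing parent {par}")
    for sid in rows:
        seen: set[int] = set()
        cur = sid
        while cur != -1:
            if cur in seen:
                raise SwcError(f"{path}: cycle through sample {cur}")
            seen.add(cur)
            cur = rows[cur][5]

    children: dict[int, list[int]] = {}
    for sid, row in rows.items():
        if row[5] != -1:
            children.setdefault(row[5], []).append(sid)

    if soma_area_um2 is not None:
        soma_area = float(soma_area_um2)
    else:
        mean_r = float(np.mean([rows[s][4] for s in soma_ids]))
        soma_area = 4.0 * math.pi * mean_r**2

    # dendritic roots: non-soma samples whose parent is a soma sample (or -1)
    def _is_root(sid: int) -> bool:
        par = rows[sid][5]
        return par == -1 or rows[par][0] == _SWC_SOMA

    sections: list[dict] = []

    def _walk(start: int, parent_sec: int | None) -> None:
        """Collect one section starting at sample `start`, then recurse."""
        typ = rows[start][0]
        arbor = _ARBOR_OF_TYPE[typ]
        pts: list[int] = [start]
        cur = start
        while True:
            kids = [k for k in children.get(cur, []) if rows[k][0] != _SWC_SOMA]
            if len(kids) == 1 and rows[kids[0]][0] == typ:
                cur = kids[0]
                pts.append(cur)
            else:
                break
        # geometry: segment from attachment point to each sample; root
        # sections attach at their soma parent sample
        par = rows[start][5]
        chain = [par] + pts if par != -1 else pts
        length = 0.0
        wdiam = 0.0
        for a, b in zip(chain[:-1], chain[1:]):
            _, xa, ya, za, _, _ = rows[a]
            _, xb, yb, zb, rb, _ = rows[b]
            seg = math.dist((xa, ya, za), (xb, yb, zb))
            length += seg
            wdiam += seg * 2.0 * rb
        if length <= 0:
            # degenerate single-sample section: use a tiny positive stub
            raise SwcError(f"{path}: zero-length section at sample {start}")
        diam = wdiam / length
        sec_id = len(sections)
        sections.append(
            dict(id=sec_id, parent_id=parent_sec, arbor=arbor, length=length,
                 diameter=diam, _tip=cur)
        )
        for k in children.get(cur, []):
            if rows[k][0] == _SWC_SOMA:
                continue
            _walk(k, sec_id)

    for sid in sorted(rows):
        if rows[sid][0] != _SWC_SOMA and _is_root(sid):
            _walk(sid, None)

    labels = _assign_order_labels(sections)
    secs = [
        Section(id=d["id"], parent_id=d["parent_id"], arbor=d["arbor"],
                order_label=labels[d["id"]], length=d["length"], diameter=d["diameter"])
        for d in sections
    ]
    nid = neuron_id if neuron_id is not None else str(path)
    return Morphology(neuron_id=nid, group=group, soma_area=soma_area, sections=secs)


def _assign_order_labels(sections: Sequence[dict]) -> dict[int, str]:
    """Infer order labels from topology and diameters.

    Basal sections are labelled ``basal``.  For each apical root the main
    shaft is followed from the soma: an unbranched continuation stays
    shaft; at a bifurcation the shaft continues into the thickest child
    provided it is at least 60% of the current shaft diameter and clearly
    thicker (by 5% of the shaft diameter) than its siblings, which then
    root oblique subtrees (OT1, children OT2, ... capped at OT5).  Where
    no such dominant child exists — typically the near-equal daughters at
    the tuft origin — the distal subtree is the terminal tuft (T1, T2, T3
    by centrifugal order).
    """
    kids: dict[int | None, list[dict]] = {}
    for d in sections:
        kids.setdefault(d["parent_id"], []).append(d)
    labels: dict[int, str] = {}

    def _label_sub(d: dict, kind: str, order: int) -> None:
        cap = 5 if kind == "OT" else 3
        labels[d["id"]] = f"{kind}{min(order, cap)}"
        for c in kids.get(d["id"], []):
            _label_sub(c, kind, order + 1)

    for root in kids.get(None, []):
        if root["arbor"] == "basal":
            stack = [root]
            while stack:
                d = stack.pop()
                labels[d["id"]] = "basal"
                stack.extend(kids.get(d["id"], []))
            continue
        cur = root
        while True:
            labels[cur["id"]] = "shaft"
            cs = kids.get(cur["id"], [])
            if not cs:
                break
            if len(cs) == 1:
                cur = cs[0]
                continue
            ranked = sorted(cs, key=lambda c: c["diameter"], reverse=True)
            d1, d2 = ranked[0]["diameter"], ranked[1]["diameter"]
            if d1 >= 0.6 * cur["diameter"] and d1 - d2 >= 0.05 * cur["diameter"]:
                for c in ranked[1:]:
                    _label_sub(c, "OT", 1)
                cur = ranked[0]
            else:
                for c in cs:
                    _label_sub(c, "T", 1)
                break
    return labels


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as standard SWC.

    The layout is schematic: the soma is a single sphere at the origin
    with the morphology's soma area, the apical arbor grows along +z and
    basal dendrites fan into the lower hemisphere.  Each section is written
    as two samples (an off-axis midpoint plus the distal endpoint) chosen
    so that the summed point-to-point distance equals the section's path
    length while the straight-line extent is ``curvature_ratio`` times
    shorter — dendritic meandering is preserved in the aggregate even
    though the embedding is synthetic.
    """
    c = min(1.0, m.curvature_ratio)
    soma_r = math.sqrt(m.soma_area / (4.0 * math.pi))
    lines = ["# generated by dendrocomp", "1 1 0.0 0.0 0.0 %.9f -1" % soma_r]
    next_id = 2
    kids = m.children_map()
    # sample id and position of each section's distal endpoint
    end_pos: dict[int, np.ndarray] = {}
    end_sid: dict[int, int] = {}
    # deterministic directions: apical roots near +z, basal near -z
    golden = math.pi * (3.0 - math.sqrt(5.0))

    def _dir(parent_dir: np.ndarray, k: int) -> np.ndarray:
        """k-th child direction: tilt ~35 deg off the parent direction."""
        # build an orthonormal frame around parent_dir
        a = np.array([1.0, 0.0, 0.0])
        if abs(parent_dir @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(parent_dir, a)
        u /= np.linalg.norm(u)
        v = np.cross(parent_dir, u)
        phi = golden * (k + 1)
        tilt = 0.6  # rad
        d = math.cos(tilt) * parent_dir + math.sin(tilt) * (math.cos(phi) * u + math.sin(phi) * v)
        return d / np.linalg.norm(d)

    def _emit(sec: Section, origin: np.ndarray, direction: np.ndarray) -> None:
        nonlocal next_id
        L = sec.length
        chord = L * c
        end = origin + direction * chord
        # midpoint offset perpendicular to the chord so the two legs sum to L
        h = 0.5 * math.sqrt(max(L * L - chord * chord, 0.0))
        perp = np.cross(direction, np.array([0.0, 0.0, 1.0]))
        n = np.linalg.norm(perp)
        if n < 1e-12:
            perp = np.cross(direction, np.array([0.0, 1.0, 0.0]))
            n = np.linalg.norm(perp)
        perp /= n
        mid = origin + direction * (chord / 2.0) + perp * h
        typ = _SWC_APICAL if sec.arbor == "apical" else _SWC_BASAL
        r = sec.diameter / 2.0
        par_sid = end_sid.get(sec.parent_id, 1) if sec.parent_id is not None else 1
        mid_id, end_id = next_id, next_id + 1
        next_id += 2
        lines.append("%d %d %.9f %.9f %.9f %.9f %d" % (mid_id, typ, *mid, r, par_sid))
        lines.append("%d %d %.9f %.9f %.9f %.9f %d" % (end_id, typ, *end, r, mid_id))
        end_pos[sec.id] = end
        end_sid[sec.id] = end_id
        for k, child in enumerate(sorted(kids.get(sec.id, []), key=lambda s: s.id)):
            _emit(child, end, _dir(direction, k))

    roots = sorted(kids.get(None, []), key=lambda s: s.id)
    n_ap = sum(1 for s in roots if s.arbor == "apical")
    i_ap = i_ba = 0
    for sec in roots:
        if sec.arbor == "apical":
            d0 = np.array([math.sin(0.3 * i_ap), 0.0, math.cos(0.3 * i_ap)])
            i_ap += 1
        else:
            phi = golden * i_ba
            d0 = np.array([0.8 * math.cos(phi), 0.8 * math.sin(phi), -0.6])
            i_ba += 1
        d0 = d0 / np.linalg.norm(d0)
        # sections attach at the soma sample so the SWC path length from
        # the attachment point equals the section length exactly
        _emit(sec, np.zeros(3), d0)

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Discretization and spines
# ---------------------------------------------------------------------------

def compartmentalize(
    m: Morphology,
    max_len: float | Callable[[Section], float] = DEFAULT_MAX_COMPARTMENT_LEN_UM,
) -> list[Compartment]:
    """Cut every section into ceil(L/max_len) equal cylinders.

    ``max_len`` may be a scalar bound (um) or a callable giving a
    per-section bound (used e.g. to enforce an electrotonic spacing that
    depends on the local space constant).  Compartments are returned in
    depth-first order; ids index into the returned list.  Midpoint path
    distances accumulate along the tree from the soma surface.
    """
    out: list[Compartment] = []
    kids = m.children_map()
    last_comp_of_sec: dict[int, int] = {}

    def _bound(sec: Section) -> float:
        b = max_len(sec) if callable(max_len) else float(max_len)
        if b <= 0:
            raise ValueError("max_len must be positive")
        return b

    def _walk(sec: Section, start_dist: float) -> None:
        n = max(1, math.ceil(sec.length / _bound(sec) - 1e-12))
        lc = sec.length / n
        for i in range(n):
            cid = len(out)
            if i == 0:
                pid = last_comp_of_sec.get(sec.parent_id) if sec.parent_id is not None else None
            else:
                pid = cid - 1
            out.append(
                Compartment(
                    id=cid,
                    parent_id=pid,
                    section_id=sec.id,
                    length=lc,
                    diameter=sec.diameter,
                    arbor=sec.arbor,
                    midpoint_path_distance=start_dist + (i + 0.5) * lc,
                )
            )
        last_comp_of_sec[sec.id] = len(out) - 1
        for child in sorted(kids.get(sec.id, []), key=lambda s: s.id):
            _walk(child, start_dist + sec.length)

    for root in sorted(kids.get(None, []), key=lambda s: s.id):
        _walk(root, 0.0)
    return out


def fold_spines(
    c: Compartment,
    spine_density: float,
    spine_area: float = DEFAULT_SPINE_AREA_UM2,
) -> Compartment:
    """Fold spine membrane into a compartment.

    Sets ``A_s = density * length * spine_area`` so that the fold factor
    ``q = (A_s + A_d)/A_d`` scales membrane conductance and capacitance;
    geometry (length, diameter) is untouched.
    """
    if spine_density < 0:
        raise ValueError("spine density must be non-negative")
    if spine_area <= 0:
        raise ValueError("spine area must be positive")
    return replace(c, A_s=spine_density * c.length * spine_area)


def fold_spines_all(
    comps: Iterable[Compartment],
    spine_density: float,
    spine_area: float = DEFAULT_SPINE_AREA_UM2,
) -> list[Compartment]:
    """Apply :func:`fold_spines` to every compartment."""
    return [fold_spines(c, spine_density, spine_area) for c in comps]


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def morphometrics(
    m: Morphology,
    spine_density: float,
    spine_area: float = DEFAULT_SPINE_AREA_UM2,
    bin_width_um: float = 25.0,
) -> dict:
    """Summary morphometrics of one neuron.

    Returns per-arbor totals (length, smooth area, area including spines),
    apical bifurcation and oblique counts, mean diameter per order label,
    and binned distributions of dendritic length and spiny surface versus
    path distance from the soma (used for population-level distribution
    comparisons).
    """
    totals = {
        a: dict(length=0.0, area_smooth=0.0, area_incl_spines=0.0)
        for a in ("apical", "basal")
    }
    diam_samples: dict[str, list[tuple[float, float]]] = {}
    rows = []  # (arbor, mid_distance, length, area_incl)
    for s in m.sections:
        a_sm = s.lateral_area
        a_sp = a_sm + spine_density * s.length * spine_area
        t = totals[s.arbor]
        t["length"] += s.length
        t["area_smooth"] += a_sm
        t["area_incl_spines"] += a_sp
        diam_samples.setdefault(s.order_label, []).append((s.length, s.diameter))
        mid = m.path_distance_to_start(s.id) + s.length / 2.0
        rows.append((s.arbor, mid, s.length, a_sp))

    kids = m.children_map()
    n_bif = sum(
        1
        for s in m.sections
        if s.arbor == "apical" and len(kids.get(s.id, [])) >= 2
    )
    n_obl = sum(1 for s in m.sections if s.order_label == "OT1")

    diam_by_order = {
        lab: sum(L * d for L, d in pairs) / sum(L for L, _ in pairs)
        for lab, pairs in diam_samples.items()
    }

    # binned distance distributions
    max_d = max((r[1] for r in rows), default=0.0)
    nbins = max(1, math.ceil((max_d + 1e-9) / bin_width_um))
    edges = np.arange(nbins + 1) * bin_width_um
    hist: dict[str, dict[str, np.ndarray]] = {}
    for arbor in ("apical", "basal"):
        sel = [r for r in rows if r[0] == arbor]
        mids = np.array([r[1] for r in sel])
        length_w = np.array([r[2] for r in sel])
        area_w = np.array([r[3] for r in sel])
        hL, _ = np.histogram(mids, bins=edges, weights=length_w) if sel else (np.zeros(nbins), None)
        hA, _ = np.histogram(mids, bins=edges, weights=area_w) if sel else (np.zeros(nbins), None)
        hist[arbor] = dict(edges=edges, length=hL, area=hA)

    return dict(
        neuron_id=m.neuron_id,
        group=m.group.value,
        apical=totals["apical"],
        basal=totals["basal"],
        n_bifurcations_apical=n_bif,
        n_obliques=n_obl,
        diam_by_order=diam_by_order,
        distance_hist=hist,
    )
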