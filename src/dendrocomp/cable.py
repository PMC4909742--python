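"""Passive compartmental cable system: assembly, DC/AC solves, moments.

The electrical model is the standard compartmental discretization of the
passive cable.  Node 0 is the isopotential soma, nodes 1..n the dendritic
compartments.  Each node i carries an absolute membrane conductance

    g_i = q_i * A_i / Rm_i          (S, A_i in cm^2, Rm in Ohm*cm^2)

and capacitance  c_i = q_i * A_i * Cm * 1e-6  (F, Cm in uF/cm^2), where
q_i is the spine fold factor.  Adjacent compartments are coupled through
series half-cylinder axial resistances  Ra * (l/2) / (pi d^2/4).  The
resulting conductance matrix G is symmetric and, with positive membrane
leak everywhere, positive definite, so the DC system  G u = e_site  has a
unique solution; u is the vector of transfer resistances from the
injection site (V per injected A).

Delays are computed from the first two temporal moments of the impulse
response.  Writing V_j(t) for the voltage at node j after a current
impulse at the injection site, the zeroth moment integral of V_j is u_j
and the first moment w_j solves  G w = C u.  The centroid of V_j(t) is
w_j/u_j, so for an impulse (whose own centroid is zero) the local delay
at the site is w_site/u_site and the propagation delay to the soma is
w_soma/u_soma - w_site/u_site.  Both are exact for passive trees; a
Crank-Nicolson transient integrator is provided as an independent
brute-force check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import Compartment

__all__ = [
    "CompartmentalModel",
    "TransferSolution",
    "assemble",
    "dc_solve",
    "ac_solve",
    "input_resistance",
    "system_time_constant",
    "centroid_delays",
    "transient_oracle",
    "space_constant_um",
]

_UM2_TO_CM2 = 1e-8
_UM_TO_CM = 1e-4


def space_constant_um(diameter_um: float, rm_ohmcm2: float, ra_ohmcm: float,
                      q: float = 1.0) -> float:
    """Steady-state space constant lambda = sqrt(d * (Rm/q) / (4 Ra)), in um.

    Spine folding divides the effective specific resistance by q (spines
    add leak), shortening lambda on spiny dendrite.
    """
    d_cm = diameter_um * _UM_TO_CM
    lam_cm = math.sqrt(d_cm * (rm_ohmcm2 / q) / (4.0 * ra_ohmcm))
    return lam_cm / _UM_TO_CM


@dataclass
class CompartmentalModel:
    """Assembled passive electrical model of one neuron.

    Arrays are indexed by node: 0 = soma, i+1 = compartment i.
    """

    G: sp.csc_matrix  # S
    c: np.ndarray  # F, diagonal of the capacitance matrix
    g_membrane: np.ndarray  # S, membrane leak per node
    compartments: list[Compartment]
    soma_index: int = 0
    rm_soma: float = 0.0  # Ohm*cm^2, bookkeeping
    rm_dend: float = 0.0
    cm: float = 0.0  # uF/cm^2
    ra: float = 0.0  # Ohm*cm

    _lu: spla.SuperLU | None = None

    @property
    def n_nodes(self) -> int:
        return self.G.shape[0]

    def node_of_compartment(self, comp_id: int) -> int:
        return comp_id + 1

    def lu(self) -> spla.SuperLU:
        if self._lu is None:
            self._lu = spla.splu(self.G)
        return self._lu

    def space_constants_um(self) -> np.ndarray:
        """Per-compartment lambda (um), spine-folded."""
        return np.array(
            [
                space_constant_um(c.diameter, self.rm_dend, self.ra, c.q)
                for c in self.compartments
            ]
        )


@dataclass
class TransferSolution:
    """Moment solution for current injection at one node.

    ``u`` holds transfer resistances (zeroth moments, Ohm = V/A), ``w``
    first moments (V*s/A); ``v_complex`` is filled by AC solves.
    """

    site: int  # node index
    u: np.ndarray
    w: np.ndarray
    frequency_hz: float = 0.0
    v_complex: np.ndarray | None = None


def assemble(
    compartments: Sequence[Compartment],
    soma_area_um2: float,
    rm_soma_ohmcm2: float,
    rm_dend_ohmcm2: float,
    cm_uf_cm2: float,
    ra_ohmcm: float,
) -> CompartmentalModel:
    """Build conductance and capacitance matrices from folded compartments.

    Spine folding enters through each compartment's q: membrane
    conductance and capacitance scale by q while axial properties follow
    the smooth cylinder, so total membrane (shaft + spines) is conserved.
    """
    if rm_soma_ohmcm2 <= 0 or rm_dend_ohmcm2 <= 0 or cm_uf_cm2 <= 0 or ra_ohmcm <= 0:
        raise ValueError("membrane and axial parameters must be positive")
    n = len(compartments) + 1
    g_mem = np.zeros(n)
    c = np.zeros(n)
    a_soma = soma_area_um2 * _UM2_TO_CM2
    g_mem[0] = a_soma / rm_soma_ohmcm2
    c[0] = a_soma * cm_uf_cm2 * 1e-6
    for comp in compartments:
        i = comp.id + 1
        a_eff = comp.q * comp.A_d * _UM2_TO_CM2
        g_mem[i] = a_eff / rm_dend_ohmcm2
        c[i] = a_eff * cm_uf_cm2 * 1e-6

    # axial half-resistances (Ohm): soma is a point node, contributes none
    def _half_r(comp: Compartment) -> float:
        area = math.pi * (comp.diameter * _UM_TO_CM) ** 2 / 4.0
        return ra_ohmcm * (comp.length * _UM_TO_CM / 2.0) / area

    rows, cols, vals = [], [], []
    diag = g_mem.copy()
    for comp in compartments:
        i = comp.id + 1
        if comp.parent_id is None:
            r_ax = _half_r(comp)
            j = 0
        else:
            parent = compartments[comp.parent_id]
            r_ax = _half_r(comp) + _half_r(parent)
            j = parent.id + 1
        g_ax = 1.0 / r_ax
        rows += [i, j]
        cols += [j, i]
        vals += [-g_ax, -g_ax]
        diag[i] += g_ax
        diag[j] += g_ax

    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    G = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    # connectivity check: every node reachable from the soma
    nc, _ = sp.csgraph.connected_components(abs(G) > 0, directed=False)
    if nc != 1:
        raise ValueError("compartmental model is disconnected")

    return CompartmentalModel(
        G=G, c=c, g_membrane=g_mem, compartments=list(compartments),
        rm_soma=rm_soma_ohmcm2, rm_dend=rm_dend_ohmcm2,
        cm=cm_uf_cm2, ra=ra_ohmcm,
    )


def dc_solve(m: CompartmentalModel, site: int) -> TransferSolution:
    """Zeroth and first temporal moments for unit current injection at `site`.

    Solves G u = e_site and G w = C u.  u_j is the DC transfer resistance
    site->j; w_j/u_j the centroid of the impulse response at j.
    """
    if not (0 <= site < m.n_nodes):
        raise IndexError(f"site {site} out of range")
    e = np.zeros(m.n_nodes)
    e[site] = 1.0
    lu = m.lu()
    u = lu.solve(e)
    w = lu.solve(m.c * u)
    return TransferSolution(site=site, u=u, w=w)


def ac_solve(m: CompartmentalModel, site: int, f_hz: float) -> TransferSolution:
    """Complex steady-state potentials for sinusoidal injection at `site`.

    Solves (G + i 2 pi f C) V = e_site; at f = 0 this reduces to the DC
    solve.  The returned solution also carries the DC moments for
    convenience.
    """
    if f_hz < 0:
        raise ValueError("frequency must be non-negative")
    sol = dc_solve(m, site)
    if f_hz == 0.0:
        sol.v_complex = sol.u.astype(complex)
        return sol
    e = np.zeros(m.n_nodes, dtype=complex)
    e[site] = 1.0
    A = (m.G + 1j * 2.0 * math.pi * f_hz * sp.diags(m.c)).tocsc()
    sol.v_complex = spla.spsolve(A, e)
    sol.frequency_hz = f_hz
    return sol


def input_resistance(m: CompartmentalModel) -> float:
    """Somatic DC input resistance in MOhm (voltage at the soma per unit
    current injected there)."""
    sol = dc_solve(m, m.soma_index)
    return float(sol.u[m.soma_index]) / 1e6


def system_time_constant(m: CompartmentalModel) -> float:
    """Slowest passive time constant of the whole neuron, in ms.

    This is 1/lambda_min of the generalized eigenproblem G v = lambda C v,
    the decay constant of the final exponential tail of any step or
    impulse response (what an exponential peel of the somatic transient
    measures).  For spatially uniform membrane it equals Rm*Cm.
    """
    d = 1.0 / np.sqrt(m.c)
    A = (m.G.toarray() * d[None, :]) * d[:, None]
    A = 0.5 * (A + A.T)
    lam_min = scipy.linalg.eigvalsh(A, subset_by_index=[0, 0])[0]
    if lam_min <= 0:
        raise RuntimeError("non-positive eigenvalue: model is not passive")
    return 1e3 / lam_min


def centroid_delays(sol: TransferSolution, soma: int = 0) -> tuple[float, float]:
    """(local_delay_ms, propagation_delay_ms) from the moment solution.

    For an impulse input the input-current centroid is zero, so the local
    delay is the centroid of the local voltage transient, w/u at the site,
    and the propagation delay is the centroid difference soma - site.
    """
    t_site = sol.w[sol.site] / sol.u[sol.site]
    t_soma = sol.w[soma] / sol.u[soma]
    return 1e3 * float(t_site), 1e3 * float(t_soma - t_site)


def transient_oracle(
    m: CompartmentalModel,
    site: int,
    stimulus: Callable[[float], float],
    t_stop_s: float,
    dt_s: float = 0.025e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate C dV/dt + G V = I(t) e_site by Crank-Nicolson.

    Returns (times, V) with V of shape (n_steps+1, n_nodes).  Used in the
    test-suite as the brute-force oracle for transfers, delays and time
    constants; unconditionally stable, second-order accurate in dt.
    """
    if dt_s <= 0:
        raise ValueError("time step must be positive")
    n_steps = int(round(t_stop_s / dt_s))
    C = sp.diags(m.c).tocsc()
    A = (C / dt_s + m.G / 2.0).tocsc()
    B = (C / dt_s - m.G / 2.0).tocsc()
    lu = spla.splu(A)
    times = np.arange(n_steps + 1) * dt_s
    V = np.zeros((n_steps + 1, m.n_nodes))
    e = np.zeros(m.n_nodes)
    e[site] = 1.0
    for k in range(n_steps):
        i_mid = stimulus((times[k] + times[k + 1]) / 2.0)
        V[k + 1] = lu.solve(B @ V[k] + i_mid * e)
    return times, V
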