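"""Ice Ih boxes, proton disorder, stacked supercells, and LIL slabs.

Oxygens are placed on a lonsdaleite (hexagonal diamond) lattice in an
orthorhombic cell of 8 molecules, (a, sqrt(3) a, c); supercells hold
8 n1 n2 n3 molecules.  Hydrogens are assigned by orienting the
hydrogen-bond graph: an Eulerian circuit of the 4-regular O-O graph
gives every oxygen exactly two outgoing (donated) bonds, which is
precisely the Bernal-Fowler condition.  Closed directed loops of the
assignment are then reversed — a move that preserves the ice rules —
whenever they reduce the net cell dipole, yielding near-apolar,
seed-decorrelated proton-disorder replicas.

A liquid-ice-liquid (LIL) slab is built by adding a vacuum gap along z,
freezing the central half of the molecules, melting the two end regions
at an elevated temperature, and cooling back to the target temperature
in two stages (core still frozen, then everything mobile).  Melting is
verified with a tetrahedral order parameter rather than by eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import SITES_PER_MOL, SystemState, Topology
from .engine import RunConfig, initialize_velocities, rebuild_msites, run
from .errors import LatticeError, MeltFailureError
from .models import WaterModel, monomer_dipole

__all__ = ["IceBox", "LILSlab", "build_ice", "stack_ice", "equilibrate_cell",
           "make_lil_slab", "ice_rules_valid", "tetrahedral_order",
           "ICE_A", "ICE_C"]

# ice Ih lattice constants (Å) near the melting point; density ≈ 0.92 g/cm³
ICE_A = 4.518
ICE_C = 7.356

# lonsdaleite basis in the orthorhombic (a, sqrt(3) a, c) cell,
# fractional coordinates; two lattice offsets × four basis oxygens
_OFFSETS = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0]])
_BASIS = np.array([
    [0.0, 1.0 / 3.0, 0.0],
    [0.0, 1.0 / 3.0, 3.0 / 8.0],
    [0.5, 1.0 / 6.0, 0.5],
    [0.5, 1.0 / 6.0, 7.0 / 8.0],
])


@dataclass
class IceBox:
    """Proton-disordered ice Ih: oxygen lattice plus a directed H-bond graph.

    ``edges[k] = (i, j)`` is a hydrogen bond between oxygens i and j;
    ``donor[k]`` is 0 or 1 selecting which endpoint covalently holds the
    hydrogen on that bond.
    """

    o_positions: np.ndarray          # (N, 3) Å
    box: np.ndarray                  # (3,) Å
    edges: np.ndarray                # (2N, 2) int
    donor: np.ndarray                # (2N,) int in {0, 1}
    shifts: Optional[np.ndarray] = None  # (2N, 3) image shift of edge[k][1]
    seed: int = 0
    n_cells: tuple = (1, 1, 1)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shifts is None:
            self.shifts = np.zeros((len(self.edges), 3), dtype=int)

    @property
    def n_molecules(self) -> int:
        return len(self.o_positions)

    def bond_vectors(self) -> np.ndarray:
        """Unit vectors donor → acceptor for every hydrogen bond.

        Image shifts are stored per edge, so bonds that connect a
        molecule to a periodic image (including double edges in very
        small cells) keep their true geometry.
        """
        e = np.arange(len(self.edges))
        i = self.edges[e, self.donor]
        j = self.edges[e, 1 - self.donor]
        # shift applies to edges[k][1]; flip its sign when that endpoint
        # is the donor
        sign = np.where(self.donor == 0, 1.0, -1.0)[:, None]
        d = (self.o_positions[j] - self.o_positions[i]
             + sign * self.shifts * self.box[None, :])
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def donated_directions(self) -> np.ndarray:
        """(N, 2, 3) unit vectors of each oxygen's two donated bonds."""
        donors = self.edges[np.arange(len(self.edges)), self.donor]
        vecs = self.bond_vectors()
        out = np.zeros((self.n_molecules, 2, 3))
        count = np.zeros(self.n_molecules, dtype=int)
        for k, i in enumerate(donors):
            out[i, count[i]] = vecs[k]
            count[i] += 1
        if np.any(count != 2):
            raise LatticeError("hydrogen assignment violates the ice rules")
        return out

    def net_dipole_per_molecule(self, model: Optional[WaterModel] = None,
                                mu: float = 2.3,
                                theta: float = 104.5) -> float:
        """|Σ molecular dipoles| / N in Debye, from the bond directions."""
        if model is not None:
            mu = monomer_dipole(model)
            theta = model.model_geometry.theta_HOH
        dirs = self.donated_directions()
        bisector = dirs.sum(axis=1)    # per molecule, |u1+u2| = 2 cos(θ_t/2)
        net = bisector.sum(axis=0)
        scale = mu / (2.0 * math.cos(math.radians(theta) / 2.0))
        return scale * float(np.linalg.norm(net)) / self.n_molecules

    def to_state(self, model: WaterModel,
                 scale_to: Optional[np.ndarray] = None):
        """Materialize a (SystemState, Topology) with the model's geometry.

        Hydrogens are placed in the plane of the two donated bond
        directions, opened/closed symmetrically to the model's HOH
        angle.  ``scale_to`` rescales the cell (and O lattice) first.
        """
        geom = model.model_geometry
        opos = self.o_positions.copy()
        box = self.box.copy()
        if scale_to is not None:
            scale_to = np.asarray(scale_to, dtype=float)
            opos *= (scale_to / box)[None, :]
            box = scale_to
        dirs = self.donated_directions()
        b = dirs.sum(axis=1)
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        half = math.radians(geom.theta_HOH) / 2.0
        pos = np.zeros((self.n_molecules, SITES_PER_MOL, 3))
        pos[:, 0] = opos
        for h in (0, 1):
            p = dirs[:, h] - (dirs[:, h] * b).sum(axis=1, keepdims=True) * b
            norm = np.linalg.norm(p, axis=1, keepdims=True)
            p = np.divide(p, norm, out=np.zeros_like(p), where=norm > 1e-12)
            pos[:, 1 + h] = opos + geom.r_OH * (math.cos(half) * b
                                                + math.sin(half) * p)
        pos = pos.reshape(-1, 3)
        topo = Topology(model, self.n_molecules)
        rebuild_msites(pos, topo)
        state = SystemState(pos, np.zeros_like(pos), box)
        return state, topo


@dataclass
class LILSlab:
    """Liquid-ice-liquid slab with provenance of its staged construction."""

    state: SystemState
    topology: Topology
    core_indices: np.ndarray       # frozen-during-construction molecules
    end_indices: np.ndarray        # melted end molecules
    gap: float                     # vacuum added along z, Å
    stage_log: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

def _factor_cells(n_molecules: int):
    """Pick the most cubic (n1, n2, n3) supercell for n molecules."""
    if n_molecules % 8 != 0:
        valid = sorted({8 * k for k in range(1, max(2, n_molecules // 4))
                        if abs(8 * k - n_molecules) <= max(16, n_molecules // 4)})
        raise LatticeError(
            f"{n_molecules} molecules is incompatible with the 8-molecule "
            f"orthorhombic ice Ih cell; nearby valid counts: {valid}")
    m = n_molecules // 8
    best, best_cost = None, None
    for n1 in range(1, m + 1):
        if m % n1:
            continue
        for n2 in range(1, m // n1 + 1):
            if (m // n1) % n2:
                continue
            n3 = m // (n1 * n2)
            dims = np.array([n1 * ICE_A, n2 * math.sqrt(3.0) * ICE_A,
                             n3 * ICE_C])
            cost = dims.max() / dims.min()
            if best_cost is None or cost < best_cost:
                best, best_cost = (n1, n2, n3), cost
    return best


def _oxygen_lattice(n_cells):
    n1, n2, n3 = n_cells
    cell = np.array([ICE_A, math.sqrt(3.0) * ICE_A, ICE_C])
    frac = (_OFFSETS[:, None, :] + _BASIS[None, :, :]).reshape(-1, 3)
    pos = []
    for i in range(n1):
        for j in range(n2):
            for k in range(n3):
                pos.append((frac + np.array([i, j, k])) * cell)
    pos = np.concatenate(pos, axis=0)
    box = cell * np.array([n1, n2, n3])
    return pos, box


def _hbond_edges(opos: np.ndarray, box: np.ndarray):
    """The 4-regular O-O nearest-neighbor graph with image shifts.

    Edges are image-resolved — in a single unit cell one pair of
    oxygens can be bonded through two different periodic images, and
    those count as two distinct hydrogen bonds.  Returns
    (edges (2N, 2), shifts (2N, 3)) with shifts applying to edge[k][1].
    """
    n = len(opos)
    r_nn = 3.0 * ICE_C / 8.0           # bond length in the ideal lattice
    r_max = 1.15 * r_nn
    edges, shifts = [], []
    shift_grid = np.array([(a, b, c_)
                           for a in (-1, 0, 1) for b in (-1, 0, 1)
                           for c_ in (-1, 0, 1)])
    for s in shift_grid:
        disp = opos[None, :, :] + (s * box)[None, None, :] - opos[:, None, :]
        r2 = (disp**2).sum(axis=-1)
        ii, jj = np.where(r2 < r_max**2)
        for i, j in zip(ii, jj):
            # each physical edge appears as (i, j, s) and (j, i, -s);
            # keep one representative
            if i < j or (i == j and tuple(s) > (0, 0, 0)):
                edges.append((int(i), int(j)))
                shifts.append(s)
    edges = np.array(edges, dtype=int)
    shifts = np.array(shifts, dtype=int)
    counts = np.bincount(edges.ravel(), minlength=n)
    if not np.all(counts == 4):
        raise LatticeError("oxygen lattice is not 4-coordinated")
    return edges, shifts


def _euler_orientation(edges: np.ndarray, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Initial Bernal-Fowler-valid donor assignment via an Eulerian circuit.

    Every vertex of the H-bond graph has even degree 4, so an Eulerian
    circuit exists; orienting each edge along the traversal gives
    out-degree = in-degree = 2 everywhere.  Edge insertion order is
    shuffled so different seeds explore different circuits.
    """
    g = nx.MultiGraph()
    g.add_nodes_from(range(n))
    order = rng.permutation(len(edges))
    for k in order:
        i, j = edges[k]
        g.add_edge(int(i), int(j), key=int(k))
    donor = np.full(len(edges), -1, dtype=int)
    start = int(rng.integers(n))
    for u, v, key in nx.eulerian_circuit(g, source=start, keys=True):
        donor[key] = 0 if edges[key][0] == u else 1
    if np.any(donor < 0):
        raise LatticeError("hydrogen-bond graph is not connected")
    return donor


def _loop_reverse_minimize(icebox: IceBox, rng: np.random.Generator,
                           target_per_mol: float = 0.008,
                           decorrelate: int = 200,
                           max_moves: int = 20000) -> None:
    """Reverse random directed H-bond loops to shrink the net dipole.

    Reversing a closed loop of donated bonds keeps every oxygen's
    out-degree at 2, so the ice rules are preserved exactly.  A first
    phase accepts every loop reversal (decorrelating replicas built from
    similar circuits); a second phase accepts only reversals that reduce
    |Σ bond vectors|.
    """
    n = icebox.n_molecules
    edges, donor = icebox.edges, icebox.donor
    vecs = icebox.bond_vectors()          # donor→acceptor, current
    # outgoing edge lists per node
    out_edges = [[] for _ in range(n)]
    for k in range(len(edges)):
        out_edges[edges[k][donor[k]]].append(k)

    net = vecs.sum(axis=0)
    # |net| per molecule below which the molecular-dipole criterion holds
    # (bisector magnitude 2cos(θ/2) ≈ 1.22 relates bond and dipole sums)
    target = target_per_mol * n

    def reverse_loop(loop_edges):
        nonlocal net
        for k in loop_edges:
            d = edges[k][donor[k]]
            a = edges[k][1 - donor[k]]
            out_edges[d].remove(k)
            out_edges[a].append(k)
            donor[k] = 1 - donor[k]
            net -= 2.0 * vecs[k]
            vecs[k] = -vecs[k]

    for move in range(max_moves):
        greedy = move >= decorrelate
        if greedy and np.linalg.norm(net) < target:
            break
        # random walk along outgoing edges until a node repeats
        start = int(rng.integers(n))
        node = start
        path_nodes = {node: 0}
        path_edges = []
        while True:
            k = out_edges[node][int(rng.integers(2))]
            nxt = int(edges[k][1 - donor[k]])
            path_edges.append(k)
            if nxt in path_nodes:
                loop = path_edges[path_nodes[nxt]:]
                break
            path_nodes[nxt] = len(path_edges)
            node = nxt
        if not greedy:
            reverse_loop(loop)
            continue
        delta = -2.0 * vecs[loop].sum(axis=0)
        if np.linalg.norm(net + delta) < np.linalg.norm(net):
            reverse_loop(loop)


def build_ice(n_molecules: int, target_cell=None, seed: int = 0) -> IceBox:
    """Build a proton-disordered ice Ih box.

    ``n_molecules`` must be 8·n1·n2·n3; the most cubic supercell is
    chosen automatically.  Distinct seeds give distinct hydrogen
    assignments, each Bernal-Fowler valid with a per-molecule net dipole
    below 0.01 D.  ``target_cell`` rescales the cell lengths.
    """
    n_cells = _factor_cells(n_molecules)
    opos, box = _oxygen_lattice(n_cells)
    if target_cell is not None:
        target_cell = np.asarray(target_cell, dtype=float)
        opos = opos * (target_cell / box)[None, :]
        box = target_cell
    edges, shifts = _hbond_edges(opos, box)
    rng = np.random.default_rng(seed)
    donor = _euler_orientation(edges, n_molecules, rng)
    icebox = IceBox(o_positions=opos, box=box, edges=edges, donor=donor,
                    shifts=shifts, seed=seed, n_cells=n_cells)
    _loop_reverse_minimize(icebox, rng)
    if not ice_rules_valid(icebox):
        raise LatticeError("internal error: assignment lost ice-rule validity")
    return icebox


def ice_rules_valid(icebox: IceBox) -> bool:
    """Exhaustive Bernal-Fowler check of the directed H-bond graph.

    Every oxygen must donate exactly two hydrogens and every bond must
    carry exactly one (the latter holds structurally since each edge has
    a single donor flag; the out-degree is recomputed from scratch).
    """
    donors = icebox.edges[np.arange(len(icebox.edges)), icebox.donor]
    out_deg = np.bincount(donors, minlength=icebox.n_molecules)
    deg = np.bincount(icebox.edges.ravel(), minlength=icebox.n_molecules)
    return bool(np.all(out_deg == 2) and np.all(deg == 4))


def stack_ice(icebox: IceBox, n_z: int) -> IceBox:
    """Replicate the box ``n_z`` times along z, preserving the H network.

    The hydrogen-bond network is continuous across the replication seam
    because edges that crossed the old periodic boundary now connect
    adjacent copies (and the last copy wraps to the first).
    """
    if n_z == 1:
        return icebox
    n = icebox.n_molecules
    opos = np.concatenate([icebox.o_positions
                           + np.array([0.0, 0.0, kz * icebox.box[2]])
                           for kz in range(n_z)])
    box = icebox.box * np.array([1.0, 1.0, n_z])

    new_edges, new_donor, new_shifts = [], [], []
    for k, (i, j) in enumerate(icebox.edges):
        sx, sy, sz = icebox.shifts[k]
        for kz in range(n_z):
            # the bonded image of j sits in copy kz + sz of the old box
            jz = (kz + sz) % n_z
            wrap_z = (kz + sz - jz) // n_z     # ±1 when crossing the stack
            new_edges.append((kz * n + i, jz * n + j))
            new_shifts.append((sx, sy, wrap_z))
            new_donor.append(icebox.donor[k])
    out = IceBox(o_positions=opos, box=box,
                 edges=np.array(new_edges, dtype=int),
                 donor=np.array(new_donor, dtype=int),
                 shifts=np.array(new_shifts, dtype=int),
                 seed=icebox.seed,
                 n_cells=(icebox.n_cells[0], icebox.n_cells[1],
                          icebox.n_cells[2] * n_z),
                 meta=dict(icebox.meta, stacked=n_z))
    if not ice_rules_valid(out):
        raise LatticeError("stacking broke the hydrogen-bond network")
    return out


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------

def tetrahedral_order(o_positions: np.ndarray, box: np.ndarray,
                      r_cut: Optional[float] = None) -> np.ndarray:
    """Errington-Debenedetti tetrahedral order parameter per oxygen.

    q_i = 1 - 3/8 Σ_{j<k} (cos ψ_jik + 1/3)² over the four nearest
    oxygen neighbors; 1 for a perfect tetrahedral network, ≈ 0.5 for
    random dense packings.  With ``r_cut`` set, molecules with fewer
    than four neighbors inside that radius (surface molecules of a slab,
    gas-phase strays) get NaN instead of a misleading value.
    """
    n = len(o_positions)
    wrapped = np.mod(o_positions, box)
    tree = cKDTree(wrapped, boxsize=box)
    dist, idx = tree.query(wrapped, k=5)
    q = np.full(n, np.nan)
    for i in range(n):
        if r_cut is not None and dist[i, 4] > r_cut:
            continue
        nbrs = idx[i, 1:]
        d = o_positions[nbrs] - o_positions[i]
        d -= np.round(d / box) * box
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        s = 0.0
        for a in range(3):
            for b in range(a + 1, 4):
                s += (float(d[a] @ d[b]) + 1.0 / 3.0) ** 2
        q[i] = 1.0 - 3.0 / 8.0 * s
    return q


# ---------------------------------------------------------------------------
# staged protocols
# ---------------------------------------------------------------------------

def equilibrate_cell(icebox: IceBox, model: WaterModel, T: float,
                     P: float = 0.0, t_equil: float = 20000.0,
                     t_avg: float = 18000.0,
                     config: Optional[RunConfig] = None, seed: int = 0):
    """Anisotropic NPT relaxation of the ice cell; returns mean (a, b, c).

    The cell is equilibrated at (T, P) with per-axis weak coupling and
    the box lengths averaged over the trailing ``t_avg`` fs.
    """
    state, topo = icebox.to_state(model)
    if config is None:
        config = RunConfig()
    dt = 2.0 if model.is_rigid else 0.5
    cfg = RunConfig(timestep=dt, ensemble="NPT",
                    thermostat="stochastic_rescale", tau_t=200.0,
                    T_target=T, barostat_mode="anisotropic_orthorhombic",
                    tau_p=2000.0, P_target=P, cutoff=config.cutoff,
                    ewald_accuracy=config.ewald_accuracy,
                    tail_correction=config.tail_correction,
                    seed=seed, output_every=max(1, int(50.0 / dt)))
    initialize_velocities(state, topo, T, seed=seed)
    n_steps = max(1, int(round(t_equil / dt)))
    traj = run(state, topo, cfg, n_steps)
    t_start = traj.times[-1] - t_avg
    sel = traj.times >= t_start
    return traj.boxes[sel].mean(axis=0), traj


def make_lil_slab(icebox: IceBox, model: WaterModel, T_melt: float,
                  T_target: float, gap: float = 10.0,
                  config: Optional[RunConfig] = None,
                  melt_time: float = 200000.0, cool_time: float = 200000.0,
                  order_threshold: float = 0.8, seed: int = 0) -> LILSlab:
    """Build a liquid-ice-liquid slab by the staged melt/cool protocol.

    A vacuum of ``gap`` Å is added along z; the central half of the
    molecules (by z) is frozen while the two ends melt at ``T_melt``,
    then the slab is cooled to ``T_target`` in two equal stages — core
    still frozen, then all molecules mobile.  Stage durations are in fs
    (the full-scale protocol uses 200 ps for each of melt and cool;
    reduced-scale callers pass shorter times).  Raises
    :class:`MeltFailureError` if the end regions keep a crystalline
    tetrahedral order after the melt stage.
    """
    if config is None:
        config = RunConfig()
    state, topo = icebox.to_state(model)
    state.box = state.box + np.array([0.0, 0.0, gap])

    z = icebox.o_positions[:, 2]
    zc = 0.5 * (z.min() + z.max())
    half_core = (z.max() - z.min() + ICE_C / 4.0) / 4.0
    core = np.where(np.abs(z - zc) <= half_core)[0]
    ends = np.setdiff1d(np.arange(icebox.n_molecules), core)

    dt = 2.0 if model.is_rigid else 0.5
    stage_log = []

    def _stage(name, frozen_mask, T, duration, st, sd):
        topo_s = Topology(model, icebox.n_molecules, frozen=frozen_mask)
        cfg = RunConfig(timestep=dt, ensemble="NVT",
                        thermostat="stochastic_rescale", tau_t=100.0,
                        T_target=T, cutoff=config.cutoff,
                        ewald_accuracy=config.ewald_accuracy,
                        tail_correction=False, seed=sd,
                        output_every=max(1, int(duration / dt / 10)))
        initialize_velocities(st, topo_s, T, seed=sd)
        traj = run(st, topo_s, cfg, max(1, int(round(duration / dt))))
        stage_log.append({"stage": name, "T": T, "duration_fs": duration,
                          "n_steps": int(round(duration / dt))})
        return traj.final_state

    frozen_core = np.zeros(icebox.n_molecules, dtype=bool)
    frozen_core[core] = True

    core_before = state.positions.reshape(-1, SITES_PER_MOL, 3)[core].copy()
    state = _stage("melt", frozen_core, T_melt, melt_time, state, seed + 1)
    core_after = state.positions.reshape(-1, SITES_PER_MOL, 3)[core]
    if not np.allclose(core_before, core_after):
        raise MeltFailureError("frozen core moved during the melt stage")

    opos = state.positions.reshape(-1, SITES_PER_MOL, 3)[:, 0, :]
    # surface molecules (fewer than 4 neighbors within 3.5 Å) carry no
    # crystallinity information; judge the interior of the end regions
    q_end = tetrahedral_order(opos, state.box, r_cut=3.5)[ends]
    q_med = float(np.nanmedian(q_end)) if np.isfinite(q_end).any() \
        else 0.0
    if q_med > order_threshold:
        raise MeltFailureError(
            f"end regions still crystalline after the melt stage "
            f"(median q = {q_med:.2f} > {order_threshold}); "
            f"try a higher T_melt than {T_melt} K")

    state = _stage("cool-frozen-core", frozen_core, T_target,
                   cool_time / 2.0, state, seed + 2)
    state = _stage("cool-all", np.zeros(icebox.n_molecules, dtype=bool),
                   T_target, cool_time / 2.0, state, seed + 3)

    topo_final = Topology(model, icebox.n_molecules)
    return LILSlab(state=state, topology=topo_final,
                   core_indices=core, end_indices=ends, gap=gap,
                   stage_log=stage_log,
                   provenance={"T_melt": T_melt, "T_target": T_target,
                               "seed": seed, "ice_seed": icebox.seed})
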