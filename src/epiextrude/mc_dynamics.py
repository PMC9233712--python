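"""Stochastic vertex-move dynamics with Metropolis acceptance, T1
transitions and the per-iteration parameter ramps that define the two
extrusion protocols.

Dynamics
--------
One iteration moves one uniformly random vertex by a bounded random trial
displacement; the move is applied when it lowers the energy, and otherwise
with probability ``p_accept`` (default 0.05) so the tissue keeps thermal
fluctuations.  Every ``t1_check_interval`` iterations, internal junctions
shorter than ``d_min`` whose length has been shrinking are rewired by a T1
neighbour exchange when the rewiring itself passes the same Metropolis
rule.  One simulation time step (sts) is ``iterations_per_sts`` iterations.

Extrusion protocols (applied to the tracked cells only, from
``ramp_start_sts`` onward, once per iteration):

* ``contractility``:  Gamma <- Gamma * (1 + c)   (purse-string-like)
* ``resting_area``:   A0    <- A0 * (1 - r)      (shrinking target area)
* ``control``:        no parameter change
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import _engine
from ._engine import MAXF, MAXK, MAXN
from .vertex_core import (
    CellFace,
    MeshError,
    ModelParams,
    TissueMesh,
    circularity,
    validate_mesh,
)

__all__ = [
    "RateSchedule",
    "SimulationState",
    "SimulationResult",
    "metropolis_accept",
    "metropolis_step",
    "t1_transition",
    "apply_ramps",
    "run_simulation",
    "scale_rate",
]

CONDITIONS = ("control", "contractility", "resting_area")


@dataclass(frozen=True)
class RateSchedule:
    """An extrusion protocol: which condition, at what per-iteration rate,
    applied to which cells, over which window of simulation time steps."""

    condition: str = "control"
    rate: float = 0.0
    ramp_start_sts: int = 20
    total_sts: int = 50
    target_faces: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if not self.ramp_start_sts < self.total_sts:
            raise ValueError("ramp_start_sts must precede total_sts")

    def ramp_factors(self) -> Tuple[float, float]:
        """(contractility factor, resting-area factor) per iteration."""
        if self.condition == "contractility":
            return 1.0 + self.rate, 1.0
        if self.condition == "resting_area":
            return 1.0, 1.0 - self.rate
        return 1.0, 1.0


def scale_rate(rate: float, iterations_per_sts_from: int, iterations_per_sts_to: int) -> float:
    """Rescale a per-iteration ramp rate so the per-sts ramp factor is
    preserved: (1+r')^n' = (1+r)^n."""
    return math.expm1(
        math.log1p(rate) * iterations_per_sts_from / iterations_per_sts_to
    )


class SimulationAbort(RuntimeError):
    """Mesh invariants were violated mid-run; carries a diagnostic mesh."""

    def __init__(self, message: str, mesh: Optional[TissueMesh] = None):
        super().__init__(message)
        self.mesh = mesh


# ---------------------------------------------------------------------------
# Simulation state (flat-array mirror of a TissueMesh)
# ---------------------------------------------------------------------------


class SimulationState:
    """Mutable state of a running simulation.

    Holds the flat-array mirror of the mesh used by the jitted kernel,
    the iteration/sts counters, the move/T1 statistics and the running sum
    of accepted energy changes (the energy ledger).
    """

    def __init__(
        self,
        mesh: TissueMesh,
        params: ModelParams,
        schedule: Optional[RateSchedule] = None,
        seed: int = 0,
        t1_check_interval: int = 100,
        t1_new_length: Optional[float] = None,
        proposal_mode: str = "symmetric",
        t1_enabled: bool = True,
    ):
        if proposal_mode not in ("symmetric", "literal"):
            raise ValueError("proposal_mode must be 'symmetric' or 'literal'")
        self.params = params
        self.schedule = schedule or RateSchedule()
        self.seed = int(seed)
        self.t1_check_interval = int(t1_check_interval)
        self.t1_new_length = (
            1.05 * params.d_min if t1_new_length is None else float(t1_new_length)
        )
        self.proposal_literal = proposal_mode == "literal"
        self.t1_enabled = t1_enabled

        self.iteration = 0
        self.sts = 0
        self.accepted = 0
        self.rejected = 0
        self.t1_count = 0
        self.t1_skipped = 0
        self.energy_ledger = 0.0
        self._stats = np.zeros(3)
        self._rng_seeded = False
        # separate stream for T1 accept decisions
        self.rng = np.random.default_rng([self.seed, 0x7E1])

        self._build_arrays(mesh)
        self._edge_snapshot: Dict[Tuple[int, int], float] = {}
        self.snapshot_edge_lengths()

    # -- array construction / write-back -----------------------------------

    def _build_arrays(self, mesh: TissueMesh) -> None:
        nv = len(mesh.vertices)
        nf = len(mesh.faces)
        used = mesh.used_vertex_ids()
        if len(used) != nv:
            raise MeshError("mesh has vertices not referenced by any face")
        self.pos = np.array(mesh.vertices, dtype=float)
        self.fcount = np.zeros(nf, dtype=np.int32)
        self.fring = np.full((nf, MAXK), -1, dtype=np.int32)
        self.fa0 = np.zeros(nf)
        self.fgam = np.zeros(nf)
        self.tracked = np.zeros(nf, dtype=bool)
        for fi, face in enumerate(mesh.faces):
            k = len(face.vertex_ids)
            if k > MAXK:
                raise MeshError(f"face {fi} exceeds the ring capacity {MAXK}")
            self.fcount[fi] = k
            self.fring[fi, :k] = face.vertex_ids
            self.fa0[fi] = face.resting_area
            self.fgam[fi] = face.contractility
            self.tracked[fi] = face.tracked

        vf = mesh.vertex_faces()
        self.vnf = np.zeros(nv, dtype=np.int32)
        self.vfaces = np.full((nv, MAXF), -1, dtype=np.int32)
        for v, fs in vf.items():
            if len(fs) > MAXF:
                raise MeshError(f"vertex {v} exceeds the face capacity {MAXF}")
            self.vnf[v] = len(fs)
            self.vfaces[v, : len(fs)] = fs

        em = mesh.edge_map()
        nbrs: Dict[int, List[Tuple[int, float, int]]] = {v: [] for v in range(nv)}
        lam = self.params.line_tension_tilde
        lam_b = self.params.boundary_tension()
        for (u, v), fs in em.items():
            bnd = 1 if len(fs) == 1 else 0
            t = lam_b if bnd else lam
            nbrs[u].append((v, t, bnd))
            nbrs[v].append((u, t, bnd))
        self.vnn = np.zeros(nv, dtype=np.int32)
        self.vnbr = np.full((nv, MAXN), -1, dtype=np.int32)
        self.vlam = np.zeros((nv, MAXN))
        self.vbnd = np.zeros((nv, MAXN), dtype=np.uint8)
        for v, lst in nbrs.items():
            if len(lst) > MAXN:
                raise MeshError(f"vertex {v} exceeds the neighbour capacity {MAXN}")
            self.vnn[v] = len(lst)
            for k, (u, t, b) in enumerate(lst):
                self.vnbr[v, k] = u
                self.vlam[v, k] = t
                self.vbnd[v, k] = b

        self.farea = np.zeros(nf)
        self.fperim = np.zeros(nf)
        _engine.refresh_face_caches(self.pos, self.fring, self.fcount, self.farea, self.fperim)
        self._scan_u = np.zeros(4 * nv, dtype=np.int32)
        self._scan_v = np.zeros(4 * nv, dtype=np.int32)
        self._scan_l = np.zeros(4 * nv)

    @property
    def mesh(self) -> TissueMesh:
        return self.to_mesh()

    def to_mesh(self) -> TissueMesh:
        faces = [
            CellFace(
                [int(v) for v in self.fring[fi, : self.fcount[fi]]],
                resting_area=float(self.fa0[fi]),
                contractility=float(self.fgam[fi]),
                tracked=bool(self.tracked[fi]),
            )
            for fi in range(len(self.fcount))
        ]
        return TissueMesh(self.pos.copy(), faces)

    # -- observables --------------------------------------------------------

    def face_metrics(self, fi: int) -> Tuple[float, float]:
        ring = self.fring[fi, : self.fcount[fi]]
        coords = self.pos[ring]
        x, y = coords[:, 0], coords[:, 1]
        area = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        d = np.roll(coords, -1, axis=0) - coords
        return float(area), float(np.sum(np.hypot(d[:, 0], d[:, 1])))

    def tracked_observables(self) -> pd.DataFrame:
        rows = []
        for fi in np.flatnonzero(self.tracked):
            a, p = self.face_metrics(int(fi))
            rows.append(
                {
                    "sts": self.sts,
                    "cell_id": int(fi),
                    "perimeter": p,
                    "area": a,
                    "circularity": circularity(a, p),
                }
            )
        return pd.DataFrame(rows)

    def total_energy(self) -> float:
        """Total energy from the flat arrays (same formula as tissue_energy)."""
        E = 0.0
        for fi in range(len(self.fcount)):
            a, p = self.face_metrics(fi)
            E += _engine._elastic.py_func(a, self.fa0[fi], self.params.a0_min)
            E += 0.5 * self.fgam[fi] * p * p
        for v in range(len(self.vnn)):
            for k in range(self.vnn[v]):
                u = self.vnbr[v, k]
                if u > v:
                    E += self.vlam[v, k] * float(
                        np.hypot(*(self.pos[u] - self.pos[v]))
                    )
        return E

    # -- iteration ----------------------------------------------------------

    def _ensure_seeded(self) -> None:
        if not self._rng_seeded:
            _engine.seed_rng(self.seed % (2**31 - 1))
            self._rng_seeded = True

    def ramp_active(self) -> bool:
        return (
            self.schedule.condition != "control"
            and self.sts >= self.schedule.ramp_start_sts
        )

    def run_iterations(self, n_iter: int) -> None:
        """Advance ``n_iter`` iterations (kernel chunks + periodic T1 sweeps)."""
        self._ensure_seeded()
        gfac, afac = self.schedule.ramp_factors()
        targets = np.asarray(self.schedule.target_faces, dtype=np.int64)
        done = 0
        while done < n_iter:
            chunk = min(self.t1_check_interval, n_iter - done)
            _engine.run_chunk(
                self.pos,
                self.vnf,
                self.vfaces,
                self.vnn,
                self.vnbr,
                self.vlam,
                self.fcount,
                self.fring,
                self.fa0,
                self.fgam,
                self.farea,
                self.fperim,
                chunk,
                self.params.delta_max,
                self.params.p_accept,
                self.params.a0_min,
                self.proposal_literal,
                self.ramp_active(),
                targets,
                gfac,
                afac,
                self._stats,
            )
            done += chunk
            self.iteration += chunk
            if self.t1_enabled:
                self.t1_sweep()
        self.accepted = int(self._stats[0])
        self.rejected = int(self._stats[1])
        self.energy_ledger = float(self._stats[2]) + self._t1_ledger

    def run_sts(self, n_sts: int = 1) -> None:
        for _ in range(n_sts):
            self.run_iterations(self.params.iterations_per_sts)
            self.sts += 1
            self.snapshot_edge_lengths()
            if np.any(self.farea <= 0) or np.any(self.fcount < 3):
                raise SimulationAbort(
                    f"mesh invariant violated at sts {self.sts}", self.to_mesh()
                )

    # -- T1 machinery --------------------------------------------------------

    _t1_ledger: float = 0.0

    def snapshot_edge_lengths(self) -> None:
        n = _engine.all_edge_lengths(
            self.pos, self.vnn, self.vnbr, self._scan_u, self._scan_v, self._scan_l
        )
        self._edge_snapshot = {
            (int(self._scan_u[k]), int(self._scan_v[k])): float(self._scan_l[k])
            for k in range(n)
        }

    def t1_sweep(self) -> int:
        """Attempt a T1 on every eligible short, shrinking internal edge."""
        n = _engine.short_internal_edges(
            self.pos, self.vnn, self.vnbr, self.vbnd, self.params.d_min,
            self._scan_u, self._scan_v,
        )
        rewired = 0
        for k in range(n):
            i, j = int(self._scan_u[k]), int(self._scan_v[k])
            prev = self._edge_snapshot.get((i, j))
            cur = float(np.hypot(*(self.pos[j] - self.pos[i])))
            if prev is None or cur >= prev:
                continue  # not shrinking (or no history yet)
            if self._t1_attempt(i, j):
                rewired += 1
        return rewired

    def _vertex_edge_energy(self, pair_set) -> float:
        E = 0.0
        for (a, b) in pair_set:
            ka = list(self.vnbr[a, : self.vnn[a]]).index(b)
            E += self.vlam[a, ka] * float(np.hypot(*(self.pos[b] - self.pos[a])))
        return E

    def _faces_energy(self, faces) -> float:
        E = 0.0
        for f in faces:
            a, p = self.face_metrics(f)
            E += _engine._elastic.py_func(a, self.fa0[f], self.params.a0_min)
            E += 0.5 * self.fgam[f] * p * p
        return E

    def _ring(self, f: int) -> List[int]:
        return [int(v) for v in self.fring[f, : self.fcount[f]]]

    def _set_ring(self, f: int, ring: List[int]) -> None:
        self.fcount[f] = len(ring)
        self.fring[f, : len(ring)] = ring
        self.fring[f, len(ring):] = -1

    def _replace_entry(self, arr_count, arr, row: int, old: int, new: int) -> None:
        for k in range(arr_count[row]):
            if arr[row, k] == old:
                arr[row, k] = new
                return
        raise MeshError(f"entry {old} not found in row {row}")

    def _t1_attempt(self, i: int, j: int) -> bool:
        """Standard T1 neighbour exchange on internal edge (i, j).

        Eligibility: both endpoints interior and 3-valent, the four
        surrounding faces distinct, the two faces losing a vertex keep
        >= 3 vertices, and the rewired geometry stays simple.  The rewiring
        is kept when it lowers the energy, and otherwise with probability
        p_accept; skipped/rejected attempts leave the state untouched.
        """
        if self.vnf[i] != 3 or self.vnf[j] != 3 or self.vnn[i] != 3 or self.vnn[j] != 3:
            self.t1_skipped += 1
            return False
        fi_set = set(self.vfaces[i, : self.vnf[i]].tolist())
        fj_set = set(self.vfaces[j, : self.vnf[j]].tolist())
        shared = fi_set & fj_set
        if len(shared) != 2:
            self.t1_skipped += 1
            return False
        A, B = sorted(shared)
        C = (fi_set - shared).pop()
        D = (fj_set - shared).pop()
        if len({A, B, C, D}) != 4:
            self.t1_skipped += 1
            return False
        # orient A so that i -> j in ring order
        ringA = self._ring(A)
        ki = ringA.index(i)
        if ringA[(ki + 1) % len(ringA)] != j:
            A, B = B, A
            C, D = D, C
            # C/D swap: C must stay the off-edge face of i
            fi_set = set(self.vfaces[i, : self.vnf[i]].tolist())
            fj_set = set(self.vfaces[j, : self.vnf[j]].tolist())
            C = (fi_set - shared).pop()
            D = (fj_set - shared).pop()
            ringA = self._ring(A)
            ki = ringA.index(i)
            if ringA[(ki + 1) % len(ringA)] != j:
                self.t1_skipped += 1
                return False
        if self.fcount[A] < 4 or self.fcount[B] < 4:
            self.t1_skipped += 1
            return False
        if self.fcount[C] + 1 > MAXK or self.fcount[D] + 1 > MAXK:
            self.t1_skipped += 1
            return False
        kA = len(ringA)
        a1 = ringA[(ki - 1) % kA]
        a2 = ringA[(ki + 2) % kA]
        ringB = self._ring(B)
        kj = ringB.index(j)
        if ringB[(kj + 1) % len(ringB)] != i:
            self.t1_skipped += 1
            return False
        kB = len(ringB)
        b1 = ringB[(kj - 1) % kB]
        b2 = ringB[(kj + 2) % kB]

        touched_before = [(i, j), (i, a1), (i, b2), (j, a2), (j, b1)]
        touched_after = [(i, j), (i, a1), (i, a2), (j, b2), (j, b1)]
        E_before = self._faces_energy((A, B, C, D)) + self._vertex_edge_energy(
            touched_before
        )

        saved = (
            {f: self._ring(f) for f in (A, B, C, D)},
            self.pos[[i, j]].copy(),
            self.vfaces[[i, j]].copy(),
            {v: (self.vnbr[v].copy(), self.vlam[v].copy(), self.vbnd[v].copy())
             for v in (i, j, a2, b2)},
            {f: (self.farea[f], self.fperim[f]) for f in (A, B, C, D)},
        )

        # ring surgery
        newA = [v for v in ringA if v != j]
        newB = [v for v in ringB if v != i]
        ringC = self._ring(C)
        kc = ringC.index(i)
        if ringC[(kc - 1) % len(ringC)] == b2:
            ringC.insert(kc, j)  # between b2 and i
        elif ringC[(kc + 1) % len(ringC)] == b2:
            ringC.insert(kc + 1, j)
        else:
            self.t1_skipped += 1
            return False
        ringD = self._ring(D)
        kd = ringD.index(j)
        if ringD[(kd - 1) % len(ringD)] == a2:
            ringD.insert(kd, i)
        elif ringD[(kd + 1) % len(ringD)] == a2:
            ringD.insert(kd + 1, i)
        else:
            self.t1_skipped += 1
            return False
        self._set_ring(A, newA)
        self._set_ring(B, newB)
        self._set_ring(C, ringC)
        self._set_ring(D, ringD)

        # new vertex positions: rotate the junction about its midpoint
        mid = 0.5 * (self.pos[i] + self.pos[j])
        d = self.pos[j] - self.pos[i]
        norm = float(np.hypot(*d))
        if norm == 0:
            ortho = np.array([1.0, 0.0])
        else:
            ortho = np.array([-d[1], d[0]]) / norm
        # i stays in face A: put i on the side of A's centroid
        cenA = self.pos[newA].mean(axis=0)
        if float(np.dot(ortho, cenA - mid)) < 0:
            ortho = -ortho
        half = 0.5 * self.t1_new_length
        self.pos[i] = mid + half * ortho
        self.pos[j] = mid - half * ortho

        # adjacency surgery
        self._replace_entry(self.vnf, self.vfaces, i, B, D)
        self._replace_entry(self.vnf, self.vfaces, j, A, C)
        lam_int = self.params.line_tension_tilde
        for (row, old, new) in ((i, b2, a2), (j, a2, b2)):
            for k in range(self.vnn[row]):
                if self.vnbr[row, k] == old:
                    self.vnbr[row, k] = new
                    self.vlam[row, k] = lam_int
                    self.vbnd[row, k] = 0
                    break
        self._replace_entry(self.vnn, self.vnbr, a2, j, i)
        self._replace_entry(self.vnn, self.vnbr, b2, i, j)

        def _revert():
            rings, posij, vfij, nbrs, caches = saved
            for f, ring in rings.items():
                self._set_ring(f, ring)
            self.pos[[i, j]] = posij
            self.vfaces[[i, j]] = vfij
            for v, (nb, lm, bd) in nbrs.items():
                self.vnbr[v] = nb
                self.vlam[v] = lm
                self.vbnd[v] = bd
            for f, (a, p) in caches.items():
                self.farea[f] = a
                self.fperim[f] = p

        # geometric validity of the four rewired faces
        from .vertex_core import polygon_is_simple, signed_area

        for f in (A, B, C, D):
            coords = self.pos[self._ring(f)]
            if signed_area(coords) <= _engine.AREA_MIN or not polygon_is_simple(coords):
                _revert()
                self.t1_skipped += 1
                return False

        E_after = self._faces_energy((A, B, C, D)) + self._vertex_edge_energy(
            touched_after
        )
        dE = E_after - E_before
        if dE < 0 or self.rng.random() < self.params.p_accept:
            for f in (A, B, C, D):
                a, p = self.face_metrics(f)
                self.farea[f] = a
                self.fperim[f] = p
            self.t1_count += 1
            self._t1_ledger += dE
            self.energy_ledger = float(self._stats[2]) + self._t1_ledger
            return True
        _revert()
        return False


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------


def metropolis_accept(delta_e: float, p_accept: float, uniform_draw: float) -> bool:
    """The Metropolis-style decision: downhill moves always accepted,
    uphill moves accepted with probability ``p_accept``."""
    return delta_e < 0 or uniform_draw < p_accept


def metropolis_step(state: SimulationState, params: Optional[ModelParams] = None) -> bool:
    """One vertex-move iteration; returns whether the move was accepted."""
    if params is not None and params is not state.params:
        state.params = params
    before = state._stats[0]
    t1 = state.t1_enabled
    state.t1_enabled = False
    try:
        state.run_iterations(1)
    finally:
        state.t1_enabled = t1
    return state._stats[0] > before


def t1_transition(state: SimulationState, params: Optional[ModelParams] = None) -> int:
    """Run one T1 sweep over all short, shrinking internal edges; returns
    the number of rewirings performed."""
    if params is not None and params is not state.params:
        state.params = params
    return state.t1_sweep()


def apply_ramps(
    mesh: TissueMesh,
    schedule: RateSchedule,
    iteration: int,
    n_iterations: int = 1,
    params: Optional[ModelParams] = None,
) -> None:
    """Apply ``n_iterations`` multiplicative ramp updates to the target
    faces (closed form: Gamma * (1+c)^n, A0 * (1-r)^n).  No-op before the
    ramp onset or for the control condition."""
    params = params or ModelParams()
    start_iter = schedule.ramp_start_sts * params.iterations_per_sts
    if iteration < start_iter or schedule.condition == "control":
        return
    gfac, afac = schedule.ramp_factors()
    for fi in schedule.target_faces:
        face = mesh.faces[fi]
        face.contractility *= gfac**n_iterations
        face.resting_area *= afac**n_iterations


@dataclass
class SimulationResult:
    """Per-sts tracked-cell observables plus run metadata."""

    trajectory: pd.DataFrame  # sts, cell_id, perimeter, area, circularity
    summary: pd.DataFrame  # sts, mean_P, sem_P, mean_C, sem_C, mean_A
    final_mesh: TissueMesh
    stats: Dict = field(default_factory=dict)


def _summarise(trajectory: pd.DataFrame) -> pd.DataFrame:
    def sem(x):
        return x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0

    g = trajectory.groupby("sts")
    out = pd.DataFrame(
        {
            "mean_P": g["perimeter"].mean(),
            "sem_P": g["perimeter"].apply(sem),
            "mean_C": g["circularity"].mean(),
            "sem_C": g["circularity"].apply(sem),
            "mean_A": g["area"].mean(),
        }
    )
    return out.reset_index()


def run_simulation(
    mesh: TissueMesh,
    params: ModelParams,
    schedule: RateSchedule,
    seed: int,
    t1_check_interval: int = 100,
    t1_new_length: Optional[float] = None,
    proposal_mode: str = "symmetric",
    validate_final: bool = True,
) -> SimulationResult:
    """Run the full protocol and record tracked-cell shape observables
    once per sts (plus the initial state at sts 0).

    The input mesh is not modified.  Deterministic for a fixed seed.
    """
    work = mesh.copy()
    if not schedule.target_faces:
        targets = tuple(int(f) for f in np.flatnonzero([f.tracked for f in work.faces]))
        schedule = RateSchedule(
            schedule.condition,
            schedule.rate,
            schedule.ramp_start_sts,
            schedule.total_sts,
            targets,
        )
    state = SimulationState(
        work,
        params,
        schedule,
        seed=seed,
        t1_check_interval=t1_check_interval,
        t1_new_length=t1_new_length,
        proposal_mode=proposal_mode,
    )
    e0 = state.total_energy()
    frames = [state.tracked_observables()]
    for _ in range(schedule.total_sts):
        state.run_sts(1)
        frames.append(state.tracked_observables())
    final = state.to_mesh()
    if validate_final:
        report = validate_mesh(final)
        if not report.ok:
            raise SimulationAbort(
                "final mesh invalid: " + "; ".join(report.violations[:5]), final
            )
    trajectory = pd.concat(frames, ignore_index=True)
    n_moves = state.accepted + state.rejected
    stats = {
        "seed": seed,
        "condition": schedule.condition,
        "rate": schedule.rate,
        "iterations": state.iteration,
        "accepted": state.accepted,
        "rejected": state.rejected,
        "acceptance_rate": state.accepted / n_moves if n_moves else 0.0,
        "t1_count": state.t1_count,
        "t1_skipped": state.t1_skipped,
        "energy_initial": e0,
        "energy_final": state.total_energy(),
        "energy_ledger": state.energy_ledger,
    }
    return SimulationResult(trajectory, _summarise(trajectory), final, stats)
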