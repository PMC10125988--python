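"""Bipartite mossy-fiber/granule-cell connection models.

The model network has two node types: granule cells (GCs, each with a fixed
number of dendrites, by default 4) and glomeruli (mossy-fiber terminals).
Edges are GC dendrites.  GC ID numbers encode parallel-fiber depth order
(lower ID = deeper sublayer, i.e. earlier-born GC).  A *random* connection
places each GC's dendrites uniformly on distinct glomeruli; *preferential*
and *avoidance* connections are obtained from it by degree-preserving edge
swaps accepted according to a score function on dendrite-ID distances within
the two glomeruli involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

Mode = Literal["preferential", "avoidance"]

#: Rewiring-trial presets: severity level -> number of permutation trials.
PREFERENTIAL_TRIALS = {"mild": 2500, "moderate": 5000, "severe": 7500}
AVOIDANCE_TRIALS = {"mild": 1000, "moderate": 4000, "severe": 10000}

#: Default ensemble size (independent seeded configurations per model).
DEFAULT_N_CONFIGS = 50


class ImpossiblePlacementError(ValueError):
    """Raised when a GC needs more distinct glomeruli than exist."""


class ScoreUndefinedError(ValueError):
    """Raised when a swap score involves a degree-1 glomerulus."""


class InvalidPairError(ValueError):
    """Raised when the two picked dendrites cannot form a valid swap pair."""


@dataclass(frozen=True)
class BipartiteNetwork:
    """An MF-GC connection model.

    Attributes
    ----------
    n_gc, n_glom :
        Node counts for the two sides of the bipartite graph.
    dendrites_per_gc :
        Degree of every GC node.
    gc_ids, glom_ids :
        Parallel 1-based edge arrays of length ``n_gc * dendrites_per_gc``.
    seed :
        Master seed the network was generated from (for provenance).
    mode, trials :
        Rewiring provenance; ``mode`` is ``None`` for the random model.
    """

    n_gc: int
    n_glom: int
    dendrites_per_gc: int
    gc_ids: np.ndarray
    glom_ids: np.ndarray
    seed: int | None = None
    mode: str | None = None
    trials: int = 0

    def __post_init__(self) -> None:
        if self.gc_ids.shape != self.glom_ids.shape:
            raise ValueError("edge arrays must be parallel")

    @property
    def n_edges(self) -> int:
        return self.gc_ids.size

    @property
    def edges(self) -> list[tuple[int, int]]:
        """Edge list as (gc_id, glom_id) pairs."""
        return list(zip(self.gc_ids.tolist(), self.glom_ids.tolist()))

    def glomerulus_members(self) -> list[list[int]]:
        """Dendrite GC-ID lists per glomerulus, index 0 = glomerulus 1."""
        members: list[list[int]] = [[] for _ in range(self.n_glom)]
        for gc, gl in zip(self.gc_ids.tolist(), self.glom_ids.tolist()):
            members[gl - 1].append(gc)
        return members

    def glomerulus_degrees(self) -> np.ndarray:
        """Number of dendrites incident to each glomerulus (index 0 = id 1)."""
        return np.bincount(self.glom_ids, minlength=self.n_glom + 1)[1:]

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if self.n_edges != self.n_gc * self.dendrites_per_gc:
            raise ValueError("edge count != n_gc * dendrites_per_gc")
        gc_deg = np.bincount(self.gc_ids, minlength=self.n_gc + 1)[1:]
        if not np.all(gc_deg == self.dendrites_per_gc):
            raise ValueError("a GC node has the wrong degree")
        pairs = self.gc_ids.astype(np.int64) * (self.n_glom + 1) + self.glom_ids
        if np.unique(pairs).size != pairs.size:
            raise ValueError("duplicate GC-glomerulus contact")

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the edge list as TSV plus a JSON metadata sidecar."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("gc_id\tglom_id\n")
            for gc, gl in zip(self.gc_ids.tolist(), self.glom_ids.tolist()):
                fh.write(f"{gc}\t{gl}\n")
        if sidecar:
            meta = {
                "n_gc": self.n_gc,
                "n_glom": self.n_glom,
                "dendrites_per_gc": self.dendrites_per_gc,
                "mode": self.mode,
                "trials": self.trials,
                "seed": self.seed,
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=1)
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BipartiteNetwork":
        path = Path(path)
        data = np.loadtxt(path, skiprows=1, dtype=np.int64)
        gc_ids, glom_ids = data[:, 0], data[:, 1]
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            meta = json.loads(side.read_text())
        else:
            n_gc = int(gc_ids.max())
            deg = np.bincount(gc_ids)[1:]
            meta = {
                "n_gc": n_gc,
                "n_glom": int(glom_ids.max()),
                "dendrites_per_gc": int(deg.max()),
                "mode": None,
                "trials": 0,
                "seed": None,
            }
        return cls(
            n_gc=meta["n_gc"],
            n_glom=meta["n_glom"],
            dendrites_per_gc=meta["dendrites_per_gc"],
            gc_ids=gc_ids,
            glom_ids=glom_ids,
            seed=meta.get("seed"),
            mode=meta.get("mode"),
            trials=meta.get("trials", 0),
        )


@dataclass(frozen=True)
class ScoreEvaluation:
    """Outcome of scoring one hypothetical dendrite swap."""

    glom_x: int
    glom_y: int
    x_p: int
    y_q: int
    D_x: float
    D_y: float
    d_x: float
    d_y: float
    S0: float
    S: float
    executed: bool


@dataclass(frozen=True)
class ProximityResult:
    """Proximity index of one glomerulus."""

    glom_id: int
    mean_pairwise_distance: float | None
    pi: float | None

    @property
    def defined(self) -> bool:
        return self.pi is not None


def build_random_network(
    n_gc: int, n_glom: int, dendrites_per_gc: int, seed: int
) -> BipartiteNetwork:
    """Build the random connection model.

    Each GC's ``dendrites_per_gc`` dendrites are placed on glomeruli drawn
    uniformly *without replacement* (a GC never contacts the same glomerulus
    twice); glomerulus degrees are otherwise unconstrained and come out
    binomial with mean ``n_gc * dendrites_per_gc / n_glom``.
    """
    if dendrites_per_gc > n_glom:
        raise ImpossiblePlacementError(
            f"cannot place {dendrites_per_gc} dendrites on {n_glom} distinct glomeruli"
        )
    rng = np.random.default_rng(seed)
    # Uniform sample without replacement per GC, vectorised: the k smallest
    # entries of a row of iid uniforms form a uniform k-subset.
    keys = rng.random((n_gc, n_glom))
    chosen = np.argpartition(keys, dendrites_per_gc - 1, axis=1)[:, :dendrites_per_gc]
    gc_ids = np.repeat(np.arange(1, n_gc + 1), dendrites_per_gc)
    glom_ids = (chosen + 1).reshape(-1)
    return BipartiteNetwork(
        n_gc=n_gc,
        n_glom=n_glom,
        dendrites_per_gc=dendrites_per_gc,
        gc_ids=gc_ids.astype(np.int64),
        glom_ids=glom_ids.astype(np.int64),
        seed=seed,
    )


def _score_pair(
    members_x: Sequence[int],
    members_y: Sequence[int],
    x_p: int,
    y_q: int,
) -> tuple[float, float, float, float]:
    """Return (D_x, D_y, d_x, d_y) for a hypothetical swap.

    ``members_*`` include the picked dendrite itself; N and M are the
    glomerulus degrees and the averaging denominator is degree - 1.
    """
    n = len(members_x)
    m = len(members_y)
    D_x = sum(abs(x_p - x) for x in members_x) / (n - 1)
    D_y = sum(abs(y_q - y) for y in members_y) / (m - 1)
    d_x = (sum(abs(y_q - x) for x in members_x) - abs(y_q - x_p)) / (n - 1)
    d_y = (sum(abs(x_p - y) for y in members_y) - abs(x_p - y_q)) / (m - 1)
    return D_x, D_y, d_x, d_y


def evaluate_swap(
    network: BipartiteNetwork,
    edge_a: tuple[int, int],
    edge_b: tuple[int, int],
    mode: Mode,
) -> ScoreEvaluation:
    """Score the hypothetical swap of two dendrites between glomeruli.

    ``edge_a = (x_p, X)`` and ``edge_b = (y_q, Y)`` must lie on different
    glomeruli and carry different GC IDs.  The before-swap score ``S0`` is
    the sum of the mean absolute ID distances from each picked dendrite to
    the other dendrites of its own glomerulus; ``S`` is the same sum with
    the two picked IDs exchanged.  ``executed`` is True when the strict
    acceptance rule of ``mode`` holds (S < S0 preferential, S > S0
    avoidance).
    """
    x_p, glom_x = edge_a
    y_q, glom_y = edge_b
    if glom_x == glom_y:
        raise InvalidPairError("picked dendrites lie on the same glomerulus")
    if x_p == y_q:
        raise InvalidPairError("picked dendrites carry the same GC ID")
    members = network.glomerulus_members()
    members_x = members[glom_x - 1]
    members_y = members[glom_y - 1]
    if x_p not in members_x or y_q not in members_y:
        raise InvalidPairError("edge not present in network")
    if len(members_x) < 2 or len(members_y) < 2:
        raise ScoreUndefinedError("score undefined on a degree-1 glomerulus")
    D_x, D_y, d_x, d_y = _score_pair(members_x, members_y, x_p, y_q)
    S0 = D_x + D_y
    S = d_x + d_y
    executed = S < S0 if mode == "preferential" else S > S0
    return ScoreEvaluation(
        glom_x=glom_x,
        glom_y=glom_y,
        x_p=x_p,
        y_q=y_q,
        D_x=D_x,
        D_y=D_y,
        d_x=d_x,
        d_y=d_y,
        S0=S0,
        S=S,
        executed=executed,
    )


def rewire(
    network: BipartiteNetwork, mode: Mode, trials: int, seed: int
) -> BipartiteNetwork:
    """Rewire a connection model toward preferential or avoidance topology.

    Performs exactly ``trials`` pick-evaluate-maybe-swap iterations.  Each
    iteration picks two edges uniformly from the global edge list; picks that
    share a glomerulus, share a GC ID, touch a degree-1 glomerulus, or whose
    swap would duplicate an existing GC-glomerulus contact are rejected but
    still consume a trial, so trial counts are comparable across runs.
    Glomerulus and GC degree sequences are conserved exactly.
    """
    if trials < 0:
        raise ValueError("trials must be >= 0")
    if mode not in ("preferential", "avoidance"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    gc = network.gc_ids.copy()
    gl = network.glom_ids.copy()
    n_edges = gc.size
    # Mutable per-glomerulus member sets for O(degree) scoring + duplicate checks.
    members: list[set[int]] = [set() for _ in range(network.n_glom + 1)]
    for i in range(n_edges):
        members[gl[i]].add(int(gc[i]))

    picks = rng.integers(0, n_edges, size=(trials, 2))
    preferential = mode == "preferential"
    gc_l = gc.tolist()
    gl_l = gl.tolist()
    for t in range(trials):
        i, j = picks[t]
        glom_x = gl_l[i]
        glom_y = gl_l[j]
        if glom_x == glom_y:
            continue
        x_p = gc_l[i]
        y_q = gc_l[j]
        if x_p == y_q:
            continue
        mem_x = members[glom_x]
        mem_y = members[glom_y]
        if len(mem_x) < 2 or len(mem_y) < 2:
            continue
        if y_q in mem_x or x_p in mem_y:
            continue  # swap would duplicate a GC-glomerulus contact
        sum0_x = sum_s_x = 0
        for x in mem_x:
            sum0_x += abs(x_p - x)
            sum_s_x += abs(y_q - x)
        sum0_y = sum_s_y = 0
        for y in mem_y:
            sum0_y += abs(y_q - y)
            sum_s_y += abs(x_p - y)
        dxy = abs(y_q - x_p)
        inv_n = 1.0 / (len(mem_x) - 1)
        inv_m = 1.0 / (len(mem_y) - 1)
        S0 = sum0_x * inv_n + sum0_y * inv_m
        S = (sum_s_x - dxy) * inv_n + (sum_s_y - dxy) * inv_m
        if (S < S0) if preferential else (S > S0):
            gc_l[i], gc_l[j] = y_q, x_p
            mem_x.remove(x_p)
            mem_x.add(y_q)
            mem_y.remove(y_q)
            mem_y.add(x_p)

    return BipartiteNetwork(
        n_gc=network.n_gc,
        n_glom=network.n_glom,
        dendrites_per_gc=network.dendrites_per_gc,
        gc_ids=np.asarray(gc_l, dtype=np.int64),
        glom_ids=np.asarray(gl_l, dtype=np.int64),
        seed=network.seed,
        mode=mode,
        trials=network.trials + trials,
    )


def proximity_index(member_ids: Iterable[int]) -> ProximityResult | float:
    """Proximity index of one glomerulus: 1 / mean pairwise |ID difference|."""
    ids = np.asarray(sorted(member_ids), dtype=np.int64)
    n = ids.size
    if n < 2:
        raise ScoreUndefinedError("proximity index needs >= 2 dendrites")
    diffs = np.abs(ids[:, None] - ids[None, :])
    total = diffs.sum() / 2
    n_pairs = n * (n - 1) // 2
    return n_pairs / total


def glomerulus_proximity(network: BipartiteNetwork) -> list[ProximityResult]:
    """Per-glomerulus proximity indices; degree<2 glomeruli are flagged undefined."""
    out: list[ProximityResult] = []
    for gid, ids in enumerate(network.glomerulus_members(), start=1):
        if len(ids) < 2:
            out.append(ProximityResult(gid, None, None))
        else:
            pi = proximity_index(ids)
            out.append(ProximityResult(gid, 1.0 / pi, pi))
    return out


def mean_proximity_index(network: BipartiteNetwork) -> float:
    """Average proximity index over all glomeruli with >= 2 dendrites."""
    gl = network.glom_ids
    gc = network.gc_ids.astype(np.float64)
    order = np.argsort(gl, kind="stable")
    gl_s = gl[order]
    gc_s = gc[order]
    bounds = np.flatnonzero(np.diff(gl_s)) + 1
    groups = np.split(gc_s, bounds)
    pis = []
    for ids in groups:
        n = ids.size
        if n < 2:
            continue
        ids = np.sort(ids)
        # sum of pairwise |xi-xj| over sorted ids via prefix weights
        weights = 2 * np.arange(n) - (n - 1)
        total = float(np.dot(weights, ids))
        pis.append((n * (n - 1) / 2) / total)
    if not pis:
        raise ScoreUndefinedError("no glomerulus has >= 2 dendrites")
    return float(np.mean(pis))


def label_coverage_fraction(
    network: BipartiteNetwork, id_window: tuple[int, int] | None
) -> float:
    """Fraction of glomeruli containing >= 1 dendrite with GC ID in the window.

    ``id_window`` is an inclusive (lo, hi) ID interval; ``None`` or an empty
    interval gives 0 by definition.
    """
    if id_window is None:
        return 0.0
    lo, hi = id_window
    if hi < lo:
        return 0.0
    if lo < 1 or hi > network.n_gc:
        raise ValueError("window outside 1..n_gc")
    in_window = (network.gc_ids >= lo) & (network.gc_ids <= hi)
    covered = np.unique(network.glom_ids[in_window]).size
    return covered / network.n_glom
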