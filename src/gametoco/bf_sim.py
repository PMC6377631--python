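"""Beam-Film simulation of meiotic crossover patterning.

The Beam-Film (BF) model describes crossover (CO) designation along a
bivalent as a mechanical stress-and-stress-relief process.  A set of
recombination precursors is laid down along the bivalent (their number,
spacing, activity and sensitivity governed by parameters ``N, E, B, Y, A``);
under a global stress level ``Smax`` the most sensitive precursor fires
first and becomes an interfering class I CO, relieving stress in a
neighbourhood whose reach is the interference distance ``L``; designation
repeats until no precursor's potential exceeds the firing threshold.
Designated COs mature with probability ``M`` (maturation inefficiency when
``M < 1``), and leftover precursors may independently become non-interfering
class II COs with probability ``T2prob``.

Positions live on the unit interval of normalized genetic length.  Bivalent
CO sets are transformed to chromatid (single-gamete) level by random
assignment of each CO to one of the four chromatid pairs, so a sampled
chromatid carries each transmissible CO independently with probability 1/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BFParams",
    "PrecursorArray",
    "BivalentCOSet",
    "ChromatidCOSet",
    "CLASS_I_MATURE",
    "CLASS_I_IMMATURE",
    "CLASS_II",
    "place_precursors",
    "designate_class1",
    "apply_maturation",
    "sprinkle_class2",
    "simulate_bivalents",
    "to_chromatid",
]

CLASS_I_MATURE = "I_mature"
CLASS_I_IMMATURE = "I_immature"
CLASS_II = "II"
CO_CLASSES = (CLASS_I_MATURE, CLASS_I_IMMATURE, CLASS_II)

# stream tags for per-purpose derived RNG streams; each stream is consumed
# in bivalent order with fixed-size blocks so growing n_bivalents never
# reshuffles earlier bivalents
_STREAM_COUNT = 0
_STREAM_POS = 1
_STREAM_SENS = 2
_STREAM_ACTIVE = 3
_STREAM_MATURE = 4
_STREAM_T2 = 5
_STREAM_CHROMATID = 6

#: exponent of the stress-relief profile 1 - exp(-(d/L)^k).  A steep
#: shoulder keeps the suppression radius ~L regardless of the stress level,
#: which is what makes the interference distance identifiable from CoC
#: curves at a matched CO count.
RELIEF_SHAPE = 4.0


@dataclass(frozen=True)
class BFParams:
    """The nine Beam-Film parameters.

    N : mean precursor count per bivalent (> 0)
    E : precursor spacing evenness, 0 = i.i.d. uniform, 1 = even grid
    B : among-bivalent count dispersion, 0 = Poisson counts, 1 = fixed
    Y : probability a precursor is active (formed from a DSB)
    A : sensitivity-skew exponent; 1 = uniform sensitivities, > 1 skews
        precursors toward insensitivity
    Smax : starting stress level; designation requires Smax * s > 1
    L : interference spread distance, fraction of bivalent genetic length
    M : class I maturation probability (CMI when < 1)
    T2prob : per-precursor class II probability
    """

    N: float = 16.0
    E: float = 1.0
    B: float = 1.0
    Y: float = 1.0
    A: float = 1.0
    Smax: float = 3.5
    L: float = 0.3
    M: float = 1.0
    T2prob: float = 0.0

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError(f"N must be > 0, got {self.N}")
        if not self.Smax > 0:
            raise ValueError(f"Smax must be > 0, got {self.Smax}")
        if not 0 < self.L <= 1:
            raise ValueError(f"L must be in (0, 1], got {self.L}")
        if not self.A >= 1:
            raise ValueError(f"A must be >= 1, got {self.A}")
        for name in ("E", "B", "Y", "M", "T2prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BFParams":
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "BFParams":
        return cls.from_dict(json.loads(s))

    def replace(self, **kw) -> "BFParams":
        return replace(self, **kw)


@dataclass
class PrecursorArray:
    """Precursors on one bivalent: sorted positions, sensitivities, activity."""

    positions: np.ndarray
    sensitivities: np.ndarray
    active: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if not (len(self.positions) == len(self.sensitivities) == len(self.active)):
            raise ValueError("precursor field lengths differ")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("precursor positions must be sorted ascending")

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


@dataclass
class BivalentCOSet:
    """Per-bivalent CO records on normalized genetic coordinates [0, 1]."""

    positions: list  # list of float arrays, one per bivalent
    classes: list  # list of str arrays, matching positions
    params: BFParams | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.classes):
            raise ValueError("positions/classes length mismatch")
        if len(self.positions) < 1:
            raise ValueError("bivalent count must be >= 1")

    @property
    def n_bivalents(self) -> int:
        return len(self.positions)

    def counts(self, classes: Sequence[str] = CO_CLASSES) -> np.ndarray:
        """Per-bivalent CO counts restricted to the given class labels."""
        keep = set(classes)
        return np.array(
            [int(np.isin(c, list(keep)).sum()) for c in self.classes], dtype=int
        )

    def transmissible(self) -> "BivalentCOSet":
        """Drop immature class I records (not transmitted to chromatids)."""
        pos, cls = [], []
        for p, c in zip(self.positions, self.classes):
            keep = c != CLASS_I_IMMATURE
            pos.append(p[keep])
            cls.append(c[keep])
        return BivalentCOSet(pos, cls, self.params, self.seed)

    def position_lists(self) -> list:
        return [np.sort(p) for p in self.positions]


@dataclass
class ChromatidCOSet:
    """Per-chromatid CO positions sampled from a bivalent set."""

    positions: list  # list of float arrays, one per chromatid
    source: BivalentCOSet | None = None

    @property
    def n_chromatids(self) -> int:
        return len(self.positions)

    def counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.positions], dtype=int)

    def position_lists(self) -> list:
        return [np.sort(p) for p in self.positions]


def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), tag])))


def _kmax(params: BFParams) -> int:
    # fixed per-bivalent block size: generous Poisson upper tail
    return int(max(4, round(params.N) + 1 + np.ceil(8 * np.sqrt(params.N))))


def _raw_arrays(params: BFParams, n_bivalents: int, seed: int):
    """Vectorized precursor placement; returns (positions, sens, active, counts).

    Arrays have shape (n_bivalents, kmax); entries beyond each bivalent's
    count are masked inactive with position NaN.
    """
    kmax = _kmax(params)
    # counts: round(B*N + (1-B)*Poisson(N)), clipped to [0, kmax]
    pois = _stream(seed, _STREAM_COUNT).poisson(params.N, size=n_bivalents)
    counts = np.rint(params.B * params.N + (1.0 - params.B) * pois).astype(int)
    counts = np.clip(counts, 0, kmax)

    k = np.arange(kmax)
    valid = k[None, :] < counts[:, None]

    gen_pos = _stream(seed, _STREAM_POS)
    u_jit = gen_pos.uniform(-0.5, 0.5, size=(n_bivalents, kmax))
    # jitter half-width per grid stratum: 1/4 at E=1 (a jittered even grid,
    # never an exact lattice) growing to 1/2 (stratified-uniform) at E=0
    with np.errstate(divide="ignore", invalid="ignore"):
        grid = (k[None, :] + 0.5 + (1.0 - params.E / 2.0) * u_jit) / counts[:, None]
    if params.E == 0.0:
        # exact i.i.d. uniform law at E = 0
        positions = np.sort(np.where(valid, (u_jit + 0.5), np.inf), axis=1)
        positions[~np.isfinite(positions)] = np.nan
    else:
        positions = np.where(valid, grid, np.nan)

    u_sens = _stream(seed, _STREAM_SENS).uniform(0.0, 1.0, size=(n_bivalents, kmax))
    sens = u_sens**params.A
    sens = np.clip(sens, np.finfo(float).tiny, 1.0)

    u_act = _stream(seed, _STREAM_ACTIVE).uniform(0.0, 1.0, size=(n_bivalents, kmax))
    active = (u_act < params.Y) & valid

    return positions, sens, active, counts


def place_precursors(
    params: BFParams, n_bivalents: int, seed: int
) -> list[PrecursorArray]:
    """Lay down precursor arrays on ``n_bivalents`` bivalents.

    Counts have mean ``N`` with dispersion controlled by ``B``; each
    precursor is active with probability ``Y``; spacing evenness follows
    ``E`` and sensitivities are ``u**A`` for ``u ~ Uniform(0, 1)``.
    """
    if n_bivalents < 1:
        raise ValueError(f"n_bivalents must be >= 1, got {n_bivalents}")
    positions, sens, active, counts = _raw_arrays(params, n_bivalents, seed)
    out = []
    for i in range(n_bivalents):
        m = counts[i]
        p = positions[i, :m] if params.E != 0.0 else positions[i][~np.isnan(positions[i])]
        order = np.argsort(p, kind="stable")
        out.append(
            PrecursorArray(
                positions=np.asarray(p)[order],
                sensitivities=sens[i, :m][order] if params.E != 0.0 else sens[i, :m],
                active=active[i, :m][order] if params.E != 0.0 else active[i, :m],
            )
        )
    return out


def _designate_matrix(
    positions: np.ndarray,
    sens: np.ndarray,
    active: np.ndarray,
    Smax: float,
    L: float,
) -> np.ndarray:
    """Greedy stress-relief designation, vectorized across bivalents.

    Returns a boolean matrix of designated precursors.  Potentials start at
    ``Smax * s`` for active precursors; after each designation every
    remaining potential on that bivalent is multiplied by the relief factor
    ``1 - exp(-(d / L)**RELIEF_SHAPE)`` at its distance ``d`` from the new
    CO, so the interference signal suppresses designation almost completely
    within ``L`` and dies off quickly beyond it.  Iteration
    stops when no potential exceeds 1.  On exact ties the lowest index wins
    (argmax convention).
    """
    n, kmax = positions.shape
    potential = np.where(active, Smax * sens, -np.inf)
    designated = np.zeros((n, kmax), dtype=bool)
    rows = np.arange(n)
    live = np.ones(n, dtype=bool)
    while True:
        pot_live = potential[live]
        if pot_live.size == 0:
            break
        best = np.argmax(pot_live, axis=1)
        fire = pot_live[np.arange(pot_live.shape[0]), best] > 1.0
        if not np.any(fire):
            break
        live_rows = rows[live]
        fired_rows = live_rows[fire]
        fired_idx = best[fire]
        designated[fired_rows, fired_idx] = True
        d = np.abs(positions[fired_rows] - positions[fired_rows, fired_idx][:, None])
        relief = 1.0 - np.exp(-((d / L) ** RELIEF_SHAPE))
        potential[fired_rows] = potential[fired_rows] * relief
        potential[fired_rows, fired_idx] = -np.inf
        new_live = np.zeros(n, dtype=bool)
        new_live[fired_rows] = True
        live = new_live
    return designated


def designate_class1(
    precursors: list[PrecursorArray], Smax: float, L: float, seed: int = 0
) -> list[np.ndarray]:
    """Designate interfering class I COs on each bivalent.

    Returns per-bivalent integer index arrays into the precursor arrays,
    in designation order.  The procedure is deterministic given the
    precursor arrays (``seed`` is accepted for interface symmetry).
    """
    if not Smax > 0:
        raise ValueError("Smax must be > 0")
    if not L > 0:
        raise ValueError("L must be > 0")
    out = []
    for arr in precursors:
        k = len(arr.positions)
        if k == 0:
            out.append(np.array([], dtype=int))
            continue
        potential = np.where(arr.active, Smax * arr.sensitivities, -np.inf)
        order: list[int] = []
        while True:
            best = int(np.argmax(potential))  # lowest index wins ties
            if not potential[best] > 1.0:
                break
            order.append(best)
            relief = 1.0 - np.exp(-((np.abs(arr.positions - arr.positions[best]) / L) ** RELIEF_SHAPE))
            potential = potential * relief
            potential[best] = -np.inf
        out.append(np.array(order, dtype=int))
    return out


def apply_maturation(
    designations: list[np.ndarray], M: float, seed: int
) -> list[np.ndarray]:
    """Label each designated CO mature (prob. ``M``) or immature.

    Returns per-bivalent boolean arrays aligned with the designation index
    arrays: True = mature class I, False = immature (CMI casualty).
    """
    if not 0 <= M <= 1:
        raise ValueError("M must be in [0, 1]")
    gen = _stream(seed, _STREAM_MATURE)
    out = []
    for idx in designations:
        u = gen.uniform(0.0, 1.0, size=len(idx))
        out.append(u < M)
    return out


def sprinkle_class2(
    precursors: list[PrecursorArray],
    designations: list[np.ndarray],
    T2prob: float,
    seed: int,
) -> list[np.ndarray]:
    """Turn leftover active precursors into class II COs.

    Each active, non-designated precursor independently becomes a
    non-interfering class II CO with probability ``T2prob``.  Returns
    per-bivalent index arrays of class II precursors.
    """
    if not 0 <= T2prob <= 1:
        raise ValueError("T2prob must be in [0, 1]")
    gen = _stream(seed, _STREAM_T2)
    out = []
    for arr, des in zip(precursors, designations):
        k = len(arr.positions)
        u = gen.uniform(0.0, 1.0, size=k)
        eligible = arr.active.copy()
        eligible[des] = False
        out.append(np.flatnonzero(eligible & (u < T2prob)))
    return out


def _simulate_matrices(params: BFParams, n_bivalents: int, seed: int):
    """Full BF pipeline in matrix form.

    Returns (positions, mature, immature, class2): a (n_bivalents, kmax)
    float position matrix (invalid slots -1) and three boolean CO-class
    masks.  This is the computational core shared by ``simulate_bivalents``
    and the fitting fast path.
    """
    if n_bivalents < 1:
        raise ValueError(f"n_bivalents must be >= 1, got {n_bivalents}")
    positions, sens, active, counts = _raw_arrays(params, n_bivalents, seed)
    pos_filled = np.where(np.isnan(positions), -1.0, positions)
    designated = _designate_matrix(pos_filled, sens, active, params.Smax, params.L)

    gen_m = _stream(seed, _STREAM_MATURE)
    u_mat = gen_m.uniform(0.0, 1.0, size=designated.shape)
    mature = designated & (u_mat < params.M)
    immature = designated & ~mature

    gen_t2 = _stream(seed, _STREAM_T2)
    u_t2 = gen_t2.uniform(0.0, 1.0, size=designated.shape)
    class2 = active & ~designated & (u_t2 < params.T2prob)
    return pos_filled, mature, immature, class2


def simulate_bivalents(params: BFParams, n_bivalents: int, seed: int) -> BivalentCOSet:
    """Run the full BF pipeline: precursors -> designation -> maturation ->
    class II sprinkling.  Deterministic for identical (params, n, seed)."""
    pos_filled, mature, immature, class2 = _simulate_matrices(
        params, n_bivalents, seed
    )
    pos_list, cls_list = [], []
    for i in range(n_bivalents):
        idx_m = np.flatnonzero(mature[i])
        idx_i = np.flatnonzero(immature[i])
        idx_2 = np.flatnonzero(class2[i])
        p = np.concatenate(
            [pos_filled[i, idx_m], pos_filled[i, idx_i], pos_filled[i, idx_2]]
        )
        c = np.concatenate(
            [
                np.full(len(idx_m), CLASS_I_MATURE),
                np.full(len(idx_i), CLASS_I_IMMATURE),
                np.full(len(idx_2), CLASS_II),
            ]
        )
        order = np.argsort(p, kind="stable")
        pos_list.append(p[order])
        cls_list.append(c[order])
    return BivalentCOSet(pos_list, cls_list, params=params, seed=seed)


def to_chromatid(bivalent_set: BivalentCOSet, seed: int) -> ChromatidCOSet:
    """Sample one chromatid per bivalent.

    Each bivalent CO involves one of the four chromatid-pair combinations
    with probability 1/4, so a fixed single chromatid carries each
    transmissible CO (mature class I or class II) independently with
    probability 1/2.  Immature class I COs are never transmitted.
    """
    if bivalent_set.n_bivalents < 1:
        raise ValueError("empty bivalent set")
    gen = _stream(seed, _STREAM_CHROMATID)
    out = []
    for p, c in zip(bivalent_set.positions, bivalent_set.classes):
        keep_cls = c != CLASS_I_IMMATURE
        u = gen.uniform(0.0, 1.0, size=len(p))
        keep = keep_cls & (u < 0.5)
        out.append(np.sort(p[keep]))
    return ChromatidCOSet(out, source=bivalent_set)
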