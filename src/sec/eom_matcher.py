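"""Equilibrium Optimization Matching (EOM): the core block-classification stage.

The grayscale image is the search space and each keypoint-bearing B×B block is
a particle whose "concentration" is its pixel window. Per iteration:

1. every candidate's fitness is the mean squared difference between its block
   standard deviation and the standard deviations of the whole candidate
   population — similar (e.g. duplicated) blocks score low;
2. the four lowest-fitness candidates plus their element-wise average form the
   equilibrium pool;
3. each candidate draws random λ, r, r1, r2 ∈ [0, 1], computes the exponential
   term F and generation rate G, and updates its concentration toward the best
   pool member;
4. the updated concentration is classified: if it matches the pool at least as
   well as the worst pool member it is re-weighted toward white (window
   multiplied by the updated std), otherwise toward black (multiplied by the
   updated std divided by 100), clipped to [0, 255].

After the iteration budget the working image is thresholded: pixels at or
above the white/black threshold are the suspected (forged) region. The whole
run is deterministic given the seed; one shared RNG stream draws (λ, r, r1,
r2) per candidate per iteration, candidates in row-major block order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from sec.block_grid import Block, BlockGrid

__all__ = [
    "EomParams",
    "Concentration",
    "EquilibriumPool",
    "SuspicionMap",
    "fitness",
    "update_pool",
    "exponential_term",
    "generation_rate",
    "update_concentration",
    "classify_and_reweight",
    "run_eom",
]


@dataclass
class EomParams:
    """Free parameters of the equilibrium matcher.

    ``a1``, ``a2`` and ``gp`` are the method's stated defaults (2, 1, 0.5).
    ``f_variant`` selects the exponential-term form: ``"printed"`` is
    a1·sign(r−0.5)·exp(−λ·std) − a2; ``"canonical"`` is the classic
    equilibrium-optimizer form a1·sign(r−0.5)·(exp(−λ·std) − 1).
    """

    a1: float = 2.0
    a2: float = 1.0
    gp: float = 0.5
    max_iter: int = 20
    lambda_floor: float = 1e-6
    seed: int = 0
    white_black_threshold: float = 127.5
    f_variant: str = "printed"

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValueError("a1 must be positive")
        if not 0.0 <= self.gp <= 1.0:
            raise ValueError("gp must lie in [0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lambda_floor <= 0:
            raise ValueError("lambda_floor must be positive")
        if self.f_variant not in ("printed", "canonical"):
            raise ValueError(f"unknown f_variant {self.f_variant!r}")


@dataclass
class Concentration:
    """A particle: a block, its current pixel window, and its fitness."""

    block: Block | None
    values: np.ndarray
    fitness: float = float("nan")

    @property
    def std(self) -> float:
        return float(np.asarray(self.values, dtype=np.float64).std())


@dataclass
class EquilibriumPool:
    """The four best (lowest-fitness) concentrations plus their average."""

    c_eq1: Concentration
    c_eq2: Concentration
    c_eq3: Concentration
    c_eq4: Concentration
    c_avg: Concentration

    @property
    def members(self) -> tuple[Concentration, ...]:
        return (self.c_eq1, self.c_eq2, self.c_eq3, self.c_eq4)


@dataclass
class SuspicionMap:
    """Working image after re-weighting, plus its binarization."""

    working: np.ndarray
    threshold: float
    binarized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.binarized = self.working >= self.threshold


def _fitness_from_stds(current_std: float | np.ndarray, stds: np.ndarray) -> np.ndarray:
    """Mean squared std difference against the whole population (vectorized)."""
    current_std = np.asarray(current_std, dtype=np.float64)
    m1 = stds.mean()
    m2 = np.mean(stds**2)
    return current_std**2 - 2.0 * current_std * m1 + m2


def fitness(current: Concentration, population: Sequence[Concentration]) -> float:
    """Fitness of a concentration: (1/N)·Σᵢ (std_current − std_i)².

    Low fitness means the block's standard deviation sits close to those of
    the other candidates; zero when every candidate has the same std.
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    stds = np.array([c.std for c in population], dtype=np.float64)
    return float(np.mean((current.std - stds) ** 2))


def update_pool(population: Sequence[Concentration]) -> EquilibriumPool:
    """Select the equilibrium pool: four lowest-fitness members plus average.

    Ties are broken by position in the population sequence (row-major block
    order), which makes pool selection reproducible. Every member must have
    its ``fitness`` already evaluated.
    """
    if len(population) < 4:
        raise ValueError("population must contain at least 4 concentrations")
    fits = np.array([c.fitness for c in population], dtype=np.float64)
    if np.isnan(fits).any():
        raise ValueError("all population members must have evaluated fitness")
    order = np.argsort(fits, kind="stable")
    best = [population[i] for i in order[:4]]
    avg_values = np.mean([np.asarray(c.values, dtype=np.float64) for c in best], axis=0)
    stds = np.array([c.std for c in population], dtype=np.float64)
    c_avg = Concentration(
        block=None,
        values=avg_values,
        fitness=float(_fitness_from_stds(float(avg_values.std()), stds)),
    )
    return EquilibriumPool(*best, c_avg)


def exponential_term(r: float, lam: float, std: float, params: EomParams) -> float:
    """Exploration/exploitation factor F.

    Printed form: ``a1·sign(r − 0.5)·exp(−λ·std) − a2`` (with sign(0) = 0);
    canonical form: ``a1·sign(r − 0.5)·(exp(−λ·std) − 1)``.
    """
    s = np.sign(r - 0.5)
    if params.f_variant == "canonical":
        return float(params.a1 * s * (np.exp(-lam * std) - 1.0))
    return float(params.a1 * s * np.exp(-lam * std) - params.a2)


def generation_rate(
    r1: float,
    r2: float,
    lam: float,
    c_eq1_values: np.ndarray,
    block_values: np.ndarray,
    f: float,
    params: EomParams,
) -> np.ndarray:
    """Generation-rate grid G = GCP·(C_eq1 − λ·block)·F.

    The generation-rate control parameter GCP is 0.5·r1 when r2 ≥ GP and 0
    otherwise (the tie r2 = GP takes the active branch).
    """
    c_eq1_values = np.asarray(c_eq1_values, dtype=np.float64)
    block_values = np.asarray(block_values, dtype=np.float64)
    if c_eq1_values.shape != block_values.shape:
        raise ValueError("grid shape mismatch")
    gcp = 0.5 * r1 if r2 >= params.gp else 0.0
    g0 = gcp * (c_eq1_values - lam * block_values)
    return g0 * f


def update_concentration(
    block_values: np.ndarray,
    c_eq1_values: np.ndarray,
    f: float,
    g: np.ndarray,
    lam: float,
    params: EomParams,
) -> np.ndarray:
    """Concentration update: C' = C_eq1 + (C_eq1 − block)·F + (G/λ)·(1 − F).

    λ is floored at ``params.lambda_floor`` before the division.
    """
    block_values = np.asarray(block_values, dtype=np.float64)
    c_eq1_values = np.asarray(c_eq1_values, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if not (
        np.isfinite(block_values).all()
        and np.isfinite(c_eq1_values).all()
        and np.isfinite(g).all()
        and np.isfinite(f)
        and np.isfinite(lam)
    ):
        raise ValueError("non-finite inputs to concentration update")
    lam_eff = max(lam, params.lambda_floor)
    return c_eq1_values + (c_eq1_values - block_values) * f + (g / lam_eff) * (1.0 - f)


def classify_and_reweight(
    updated: Concentration,
    pool: EquilibriumPool,
    working: np.ndarray,
) -> bool:
    """Re-weight a block window of the working image; return pool membership.

    The updated concentration counts as a pool member iff its fitness is at
    most the fitness of the worst pool member. Members are pushed toward
    white (window scaled by the updated std), non-members toward black
    (scaled by std/100); the window is clipped to [0, 255] in place.
    """
    if updated.block is None:
        raise ValueError("updated concentration must reference a block")
    member = updated.fitness <= pool.c_eq4.fitness
    factor = updated.std if member else updated.std / 100.0
    r, c, b = updated.block.origin_row, updated.block.origin_col, updated.block.size
    window = working[r : r + b, c : c + b]
    np.clip(window * factor, 0.0, 255.0, out=window)
    return member


def run_eom(gray: np.ndarray, grid: BlockGrid, params: EomParams) -> SuspicionMap:
    """Run the full equilibrium matching loop and binarize the result.

    Candidate windows and their standard deviations are re-read from the
    mutated working image at the start of every iteration; re-weighting is
    applied sequentially in row-major candidate order within the iteration.
    Images with fewer than four candidate blocks are declared authentic
    (all-zero map) since the equilibrium pool needs four members.
    """
    gray = np.asarray(gray, dtype=np.float64)
    b = grid.block_size
    origins = grid.candidate_origins()
    n = origins.shape[0]
    if n < 4:
        return SuspicionMap(
            working=np.zeros_like(gray), threshold=params.white_black_threshold
        )
    rows = origins[:, 0]
    cols = origins[:, 1]
    working = gray.copy()
    rng = np.random.default_rng(params.seed)
    for _ in range(params.max_iter):
        windows = sliding_window_view(working, (b, b))[rows, cols].astype(
            np.float64, copy=True
        )  # (N, B, B) snapshot at iteration start
        stds = windows.std(axis=(1, 2))
        fits = _fitness_from_stds(stds, stds)
        order = np.argsort(fits, kind="stable")
        c_eq1 = windows[order[0]]
        fit_worst = fits[order[3]]
        # draws consumed in (λ, r, r1, r2) order per candidate
        draws = rng.random((n, 4))
        lam, r, r1, r2 = draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]
        if params.f_variant == "canonical":
            f = params.a1 * np.sign(r - 0.5) * (np.exp(-lam * stds) - 1.0)
        else:
            f = params.a1 * np.sign(r - 0.5) * np.exp(-lam * stds) - params.a2
        gcp = np.where(r2 >= params.gp, 0.5 * r1, 0.0)
        f3 = f[:, None, None]
        g = gcp[:, None, None] * (c_eq1[None] - lam[:, None, None] * windows) * f3
        lam_eff = np.maximum(lam, params.lambda_floor)
        updated = c_eq1[None] + (c_eq1[None] - windows) * f3 + (
            g / lam_eff[:, None, None]
        ) * (1.0 - f3)
        upd_stds = updated.std(axis=(1, 2))
        upd_fits = _fitness_from_stds(upd_stds, stds)
        member = upd_fits <= fit_worst
        factors = np.where(member, upd_stds, upd_stds / 100.0)
        for k in range(n):  # sequential: overlapping windows compound
            rk, ck = rows[k], cols[k]
            window = working[rk : rk + b, ck : ck + b]
            np.clip(window * factors[k], 0.0, 255.0, out=window)
    return SuspicionMap(working=working, threshold=params.white_black_threshold)
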