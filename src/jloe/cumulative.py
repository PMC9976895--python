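"""Cumulative-essentials curves, the synthetic-genome simulator, and the
RMSE grid fit for essential-gene count and per-screen FDR.

A pooled CRISPR screen in a saturating assay would show a cumulative count of
unique essential genes that flattens to zero slope as screens accumulate.
Real screens keep a positive tail slope: each additional screen contributes
false positives (and context-specific essentials) on top of the saturating
true positives. Two quantities parameterise this behaviour: ``n``, the number
of truly essential genes in the population, and the per-screen false
discovery rate ``fdr``.

The simulator draws screens from a synthetic genome of ``N`` genes with
``n`` essentials: each screen reports ``h`` hits, split as ``round(h*fdr)``
distinct nonessentials and ``h - round(h*fdr)`` distinct essentials drawn
uniformly without replacement within the screen and independently across
screens. Fitting the simulated mean cumulative curve to the observed one by
RMSE over a grid of (n, fdr) yields the best-fit essential-gene count and
screen FDR; the screen false negative rate follows as
``1 - mean_observed_hits / best_n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .screen_io import hit_matrix

__all__ = [
    "CumulativeCurve",
    "GenomeModelConfig",
    "GridFitResult",
    "cumulative_curve",
    "simulate_genome_screens",
    "fit_genome_model",
    "estimate_fnr",
    "default_n_grid",
    "default_fdr_grid",
]


@dataclass
class CumulativeCurve:
    """Mean/SD cumulative unique hits over screens 1..k, across iterations.

    ``mean_new`` is the expected number of newly discovered hits at each
    screen index (first differences of ``mean_cumulative``). For simulated
    curves the essential/nonessential components are tracked separately.
    """

    mean_cumulative: np.ndarray
    sd_cumulative: np.ndarray
    mean_new: np.ndarray
    mean_cumulative_essential: np.ndarray | None = None
    mean_cumulative_nonessential: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.mean_cumulative)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "screen_index": np.arange(1, self.k + 1),
                "mean_cumulative": self.mean_cumulative,
                "sd_cumulative": self.sd_cumulative,
                "mean_new": self.mean_new,
            }
        )
        if self.mean_cumulative_essential is not None:
            df["mean_cumulative_essential"] = self.mean_cumulative_essential
        if self.mean_cumulative_nonessential is not None:
            df["mean_cumulative_nonessential"] = self.mean_cumulative_nonessential
        return df


def _summarise(cumulative: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean/SD/new-hit summaries from an (iterations, k) cumulative array."""
    mean = cumulative.mean(axis=0)
    sd = cumulative.std(axis=0, ddof=0)
    new = np.diff(mean, prepend=0.0)
    return mean, sd, new


def cumulative_curve(
    matrix: pd.DataFrame,
    set_size: int = 20,
    hit_threshold: float = 10.0,
    iterations: int = 100,
    seed: int | None = None,
) -> CumulativeCurve:
    """Bootstrap cumulative-essentials curve from an observed BF matrix.

    Per iteration, ``set_size`` screens are sampled without replacement and
    the cumulative union of hit genes (BF >= ``hit_threshold``) is tracked
    across the ordered sample; mean and SD over iterations are returned.
    """
    n_screens = matrix.shape[1]
    if set_size > n_screens:
        raise ValueError(
            f"set_size {set_size} exceeds the {n_screens} available screens"
        )
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    hits = hit_matrix(matrix, hit_threshold).to_numpy()  # genes x screens
    out = np.empty((iterations, set_size))
    for it in range(iterations):
        order = rng.choice(n_screens, size=set_size, replace=False)
        seen = np.logical_or.accumulate(hits[:, order], axis=1)
        out[it] = seen.sum(axis=0)
    mean, sd, new = _summarise(out)
    return CumulativeCurve(mean, sd, new)


@dataclass(frozen=True)
class GenomeModelConfig:
    """Parameters of the synthetic-genome screen simulator.

    Defaults describe a genome-scale knockout library: ``N`` genes assayed,
    of which ``n`` are essential; each screen reports ``h`` hits at the
    strict BF threshold; ``k`` screens per replicate set; the whole draw is
    repeated ``iterations`` times.
    """

    n: int
    fdr: float
    N: int = 18111
    h: int = 1287
    k: int = 8
    iterations: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.n < self.N):
            raise ValueError(f"need 0 < n < N, got n={self.n}, N={self.N}")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0, 1], got {self.fdr}")
        if self.h > self.N:
            raise ValueError(f"h={self.h} exceeds genome size N={self.N}")
        fp, tp = self.split()
        if fp > self.N - self.n:
            raise ValueError(
                f"per-screen false positives {fp} exceed the {self.N - self.n} nonessentials"
            )
        if tp > self.n:
            raise ValueError(
                f"per-screen true positives {tp} exceed the {self.n} essentials"
            )

    def split(self) -> tuple[int, int]:
        """(nonessential, essential) hits per screen: round(h*fdr) and the rest."""
        fp = int(round(self.h * self.fdr))
        return fp, self.h - fp


def _cumulative_unique(
    rng: np.random.Generator, pop: int, draws: int, k: int, iterations: int
) -> np.ndarray:
    """Cumulative unique ids over k independent draws of ``draws`` distinct
    ids from a population of ``pop``, vectorised over iterations.

    Conditional on ``u`` ids already seen, the number of new uniques in the
    next screen is hypergeometric(pop - u good, u bad, draws sampled), so
    the cumulative count is simulated exactly without materialising ids.
    Returns an (iterations, k) integer array.
    """
    out = np.zeros((iterations, k), dtype=np.int64)
    if draws == 0 or pop == 0:
        return out
    u = np.zeros(iterations, dtype=np.int64)
    for j in range(k):
        u = u + rng.hypergeometric(pop - u, u, draws)
        out[:, j] = u
    return out


def simulate_genome_screens(config: GenomeModelConfig) -> CumulativeCurve:
    """Simulate cumulative unique hits over k screens of a synthetic genome.

    Each screen draws its essential and nonessential hits uniformly without
    replacement within the screen and independently across screens; the
    cumulative count of unique hit genes is tracked per screen index and
    averaged over iterations.
    """
    rng = np.random.default_rng(config.seed)
    fp, tp = config.split()
    ess = _cumulative_unique(rng, config.n, tp, config.k, config.iterations)
    non = _cumulative_unique(rng, config.N - config.n, fp, config.k, config.iterations)
    total = (ess + non).astype(float)
    mean, sd, new = _summarise(total)
    return CumulativeCurve(
        mean,
        sd,
        new,
        mean_cumulative_essential=ess.mean(axis=0),
        mean_cumulative_nonessential=non.mean(axis=0),
    )


def default_n_grid() -> np.ndarray:
    """Essential-gene-count grid: 1300 to 2000 in steps of 50."""
    return np.arange(1300, 2001, 50)


def default_fdr_grid() -> np.ndarray:
    """Per-screen FDR grid: 1% to 15% in 0.5% steps."""
    return np.round(np.arange(0.01, 0.1501, 0.005), 4)


@dataclass
class GridFitResult:
    """RMSE surface over (n, fdr) with the best-fit point.

    ``good_fit_region`` lists the grid points whose RMSE is below twice the
    minimum — the plateau of models statistically indistinguishable from the
    best fit.
    """

    rmse_surface: pd.DataFrame  # index: n, columns: fdr
    best_n: int
    best_fdr: float
    rmse_min: float
    good_fit_region: list[tuple[int, float]] = field(default_factory=list)

    def fnr(self, mean_observed_hits: float) -> float:
        return estimate_fnr(self.best_n, mean_observed_hits)


def fit_genome_model(
    reference: CumulativeCurve,
    n_grid: np.ndarray | None = None,
    fdr_grid: np.ndarray | None = None,
    *,
    N: int = 18111,
    h: int = 1287,
    iterations: int = 100,
    seed: int | None = None,
) -> GridFitResult:
    """Grid search over (n, fdr): RMSE of simulated vs reference curves.

    For each grid point a synthetic cumulative curve (mean over
    ``iterations`` replicate k-screen sets) is compared with the reference
    mean cumulative curve over its k points; the surface, its argmin and the
    RMSE < 2 x min region are returned. Grid points violating the simulator
    feasibility constraints are skipped with a warning.
    """
    n_grid = default_n_grid() if n_grid is None else np.asarray(n_grid)
    fdr_grid = default_fdr_grid() if fdr_grid is None else np.asarray(fdr_grid)
    if n_grid.size == 0 or fdr_grid.size == 0:
        raise ValueError("grids must be non-empty")
    k = reference.k
    ref = np.asarray(reference.mean_cumulative, dtype=float)
    rng = np.random.default_rng(seed)
    surface = np.full((n_grid.size, fdr_grid.size), np.nan)
    for i, n in enumerate(n_grid):
        for j, f in enumerate(fdr_grid):
            try:
                cfg = GenomeModelConfig(
                    n=int(n), fdr=float(f), N=N, h=h, k=k,
                    iterations=iterations,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except ValueError as err:
                warnings.warn(f"skipping grid point (n={n}, fdr={f}): {err}", stacklevel=2)
                continue
            sim = simulate_genome_screens(cfg)
            surface[i, j] = float(np.sqrt(np.mean((sim.mean_cumulative - ref) ** 2)))
    if np.isnan(surface).all():
        raise ValueError("no feasible grid point")
    flat = np.nanargmin(surface)
    bi, bj = np.unravel_index(flat, surface.shape)
    rmse_min = float(surface[bi, bj])
    good = [
        (int(n_grid[i]), float(fdr_grid[j]))
        for i in range(n_grid.size)
        for j in range(fdr_grid.size)
        if np.isfinite(surface[i, j]) and surface[i, j] < 2.0 * rmse_min
    ]
    return GridFitResult(
        rmse_surface=pd.DataFrame(surface, index=n_grid, columns=fdr_grid),
        best_n=int(n_grid[bi]),
        best_fdr=float(fdr_grid[bj]),
        rmse_min=rmse_min,
        good_fit_region=good,
    )


def estimate_fnr(best_n: float, mean_observed_hits: float) -> float:
    """Screen false negative rate: ``1 - mean_observed_hits / best_n``.

    Compares the fitted essential-gene count with the mean number of hits
    actually observed per screen; e.g. 1287 observed hits against a best-fit
    1600 essentials gives an FNR of ~20%.
    """
    if best_n <= 0:
        raise ValueError(f"best_n must be positive, got {best_n}")
    if not (0 < mean_observed_hits <= best_n):
        warnings.warn(
            f"mean observed hits {mean_observed_hits} outside (0, best_n={best_n}]; "
            "the FNR estimate may be meaningless",
            stacklevel=2,
        )
    return 1.0 - mean_observed_hits / best_n
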