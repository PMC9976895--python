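"""Synthetic gene x screen BF populations with a recorded truth table.

The generator emulates the statistical structure a BAGEL-style BF matrix
exhibits across a panel of tissue-annotated screens: a core population of
essential genes hit in (nearly) every screen, per-screen false-negative
dropout whose rate decreases with gene expression, a background
false-positive process among nonessentials, and subtype-restricted context
essentials within each tissue. Per (gene, screen) a latent state —
true-hit, false-negative, true-negative or false-positive — is drawn first
and recorded, then a BF is emitted from that state's location-scale
distribution. False negatives are emitted near BF 0 (not deeply negative),
matching the observed profile of essential genes in the screens that miss
them. A companion expression matrix is generated so that expression
increases with a gene's essentiality frequency and a stated fraction of
nonessentials is unexpressed (log2(TPM) < 1), which exercises the
low-expression false-positive proxy.

Everything is deterministic under the config seed, and the truth table makes
every pipeline stage testable without external screen data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cumulative import CumulativeCurve, cumulative_curve
from .screen_io import GeneSet, ScreenAnnotation

__all__ = ["SynthConfig", "TruthTable", "generate_population", "generate_reference_curve"]

STATE_TRUE_HIT = "true-hit"
STATE_FALSE_NEGATIVE = "false-negative"
STATE_TRUE_NEGATIVE = "true-negative"
STATE_FALSE_POSITIVE = "false-positive"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic screen population.

    The default scale (2000 genes, two tissues of 20 screens) keeps full
    pipeline runs fast while leaving every frequency bin populated. Default
    rates mirror a typical genome-wide knockout screen: a ~20% per-screen
    false-negative rate among essentials and a false-positive rate sized so
    that roughly a tenth of each screen's hits are spurious.

    BF emissions are location-scale (normal) draws per latent state. The
    dropout emission sits near BF 0 between the nonessential and
    essential-hit locations; ``expression_coupling`` sets how strongly a
    gene's dropout propensity decreases with its expression level.
    """

    n_genes: int = 2000
    screens_per_tissue: dict[str, int] = field(
        default_factory=lambda: {"colorectal": 20, "lung": 20}
    )
    n_core_essential: int = 300
    n_context_per_subtype: int = 40
    subtype_fractions: tuple[float, ...] = (0.5, 0.5)
    p_fn: float = 0.2
    p_fp: float = 0.015
    essential_hit_loc: float = 30.0
    essential_hit_scale: float = 6.0
    dropout_loc: float = 0.0
    dropout_scale: float = 1.5
    nonessential_loc: float = -10.0
    nonessential_scale: float = 6.0
    fp_loc: float = 15.0
    fp_scale: float = 2.0
    essential_expr_loc: float = 6.0
    essential_expr_scale: float = 1.0
    context_expr_loc: float = 5.0
    nonessential_expr_loc: float = 4.0
    nonessential_expr_scale: float = 1.5
    low_expression_fraction: float = 0.3
    expression_coupling: float = 0.8
    expression_noise: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_fn", "p_fp", "low_expression_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-9:
            raise ValueError("subtype_fractions must sum to 1")
        n_context = (
            len(self.screens_per_tissue)
            * len(self.subtype_fractions)
            * self.n_context_per_subtype
        )
        if self.n_core_essential + n_context > self.n_genes:
            raise ValueError(
                f"{self.n_core_essential} core + {n_context} context essentials "
                f"exceed n_genes={self.n_genes}"
            )
        if not (self.nonessential_loc < self.dropout_loc < self.essential_hit_loc):
            raise ValueError(
                "emission locations must be ordered nonessential < dropout < essential-hit"
            )

    @property
    def n_screens(self) -> int:
        return sum(self.screens_per_tissue.values())


@dataclass
class TruthTable:
    """Ground truth of a generated population.

    ``gene_class`` maps each gene to ``core-essential``,
    ``context-essential:<tissue>/<subtype>`` or ``nonessential``;
    ``states`` records the latent state behind every (gene, screen)
    emission; ``dropout_propensity`` is the realised per-gene per-screen
    false-negative probability (expression-coupled around the configured
    mean).
    """

    gene_class: pd.Series
    states: pd.DataFrame
    screen_tissue: pd.Series
    screen_subtype: pd.Series
    dropout_propensity: pd.Series

    @property
    def core_essentials(self) -> GeneSet:
        return GeneSet(
            "core_essential", self.gene_class.index[self.gene_class == "core-essential"]
        )

    @property
    def nonessentials(self) -> GeneSet:
        return GeneSet(
            "nonessential", self.gene_class.index[self.gene_class == "nonessential"]
        )

    def essential_in(self, screen: str) -> pd.Series:
        """Boolean per-gene truth of essentiality in one screen's background."""
        label = (
            "context-essential:"
            f"{self.screen_tissue[screen]}/{self.screen_subtype[screen]}"
        )
        return (self.gene_class == "core-essential") | (self.gene_class == label)

    def state_counts(self) -> pd.Series:
        return self.states.stack().value_counts()


def _truncated_normal(
    rng: np.random.Generator,
    loc: float,
    scale: float,
    size,
    lower: float | None = None,
    upper: float | None = None,
) -> np.ndarray:
    """Normal draws with out-of-bound values resampled (bounds are far tails,
    so rejection terminates in a handful of rounds)."""
    out = rng.normal(loc, scale, size)
    bad = np.zeros(np.shape(out), dtype=bool)
    for _ in range(1000):
        bad = np.zeros(np.shape(out), dtype=bool)
        if lower is not None:
            bad |= out < lower
        if upper is not None:
            bad |= out >= upper
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out[bad] = rng.normal(loc, scale, n_bad)
    raise RuntimeError("truncated emission bounds too tight for rejection sampling")


def _gene_expression(cfg: SynthConfig, gene_class: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Per-gene base expression level by class (before per-cell-line noise)."""
    base = np.empty(len(gene_class))
    is_core = (gene_class == "core-essential").to_numpy()
    is_context = gene_class.str.startswith("context-essential").to_numpy()
    is_non = ~(is_core | is_context)
    base[is_core] = rng.normal(cfg.essential_expr_loc, cfg.essential_expr_scale, is_core.sum())
    base[is_context] = rng.normal(cfg.context_expr_loc, cfg.essential_expr_scale, is_context.sum())
    n_non = int(is_non.sum())
    non_expr = rng.normal(cfg.nonessential_expr_loc, cfg.nonessential_expr_scale, n_non)
    low = rng.random(n_non) < cfg.low_expression_fraction
    non_expr[low] = np.clip(rng.normal(0.3, 0.4, int(low.sum())), 0.0, 0.99)
    base[is_non] = non_expr
    return pd.Series(base, index=gene_class.index, name="base_expression")


def generate_population(
    config: SynthConfig = SynthConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, ScreenAnnotation, TruthTable]:
    """Generate (BF matrix, expression matrix, annotation, truth table).

    Deterministic under ``config.seed``. Per screen, every gene that is
    essential in that screen's background (core, or context matching the
    screen's tissue/subtype) drops out with its gene-specific propensity
    (mean ``p_fn``) and otherwise emits a hit-scale BF; every other gene
    emits a false-positive BF with probability ``p_fp`` and a nonessential
    BF otherwise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    digits = max(4, len(str(cfg.n_genes)))
    genes = pd.Index([f"G{i:0{digits}d}" for i in range(cfg.n_genes)], name="gene")

    # screens and subtype assignment per tissue
    screen_ids, tissue_of, subtype_of = [], {}, {}
    subtype_names = [f"sub{j + 1}" for j in range(len(cfg.subtype_fractions))]
    for tissue, n_s in cfg.screens_per_tissue.items():
        counts = np.diff(np.round(np.cumsum((0.0,) + cfg.subtype_fractions) * n_s)).astype(int)
        labels = np.repeat(subtype_names, counts)
        for i in range(n_s):
            sid = f"{tissue}_{i + 1:02d}"
            screen_ids.append(sid)
            tissue_of[sid] = tissue
            subtype_of[sid] = labels[i]
    screens = pd.Index(screen_ids, name="screen")

    # gene classes: core block, then context blocks per tissue/subtype
    gene_class = pd.Series("nonessential", index=genes, name="class")
    cursor = cfg.n_core_essential
    gene_class.iloc[:cursor] = "core-essential"
    for tissue in cfg.screens_per_tissue:
        for sub in subtype_names:
            gene_class.iloc[cursor : cursor + cfg.n_context_per_subtype] = (
                f"context-essential:{tissue}/{sub}"
            )
            cursor += cfg.n_context_per_subtype

    base_expr = _gene_expression(cfg, gene_class, rng)

    # expression-coupled dropout propensity (essential classes only)
    is_ess = (gene_class != "nonessential").to_numpy()
    z = np.zeros(cfg.n_genes)
    z[is_ess] = (
        base_expr.to_numpy()[is_ess]
        - np.where(
            (gene_class == "core-essential").to_numpy()[is_ess],
            cfg.essential_expr_loc,
            cfg.context_expr_loc,
        )
    ) / cfg.essential_expr_scale
    propensity = np.clip(cfg.p_fn * (1.0 - cfg.expression_coupling * z), 0.0, 1.0)
    propensity[~is_ess] = np.nan

    # latent states, then emissions
    ess_mask = np.zeros((cfg.n_genes, cfg.n_screens), dtype=bool)
    for s_idx, sid in enumerate(screens):
        label = f"context-essential:{tissue_of[sid]}/{subtype_of[sid]}"
        ess_mask[:, s_idx] = (gene_class == "core-essential") | (gene_class == label)

    u = rng.random((cfg.n_genes, cfg.n_screens))
    dropout = ess_mask & (u < propensity[:, None])
    fp = ~ess_mask & (rng.random((cfg.n_genes, cfg.n_screens)) < cfg.p_fp)

    states = np.where(
        ess_mask,
        np.where(dropout, STATE_FALSE_NEGATIVE, STATE_TRUE_HIT),
        np.where(fp, STATE_FALSE_POSITIVE, STATE_TRUE_NEGATIVE),
    )

    # emissions: hit states are resampled above the hit threshold and miss
    # states below it, so the latent state exactly determines whether the
    # realised BF is a plain hit
    hit_thr = 10.0
    bf = _truncated_normal(
        rng, cfg.nonessential_loc, cfg.nonessential_scale,
        (cfg.n_genes, cfg.n_screens), upper=hit_thr,
    )
    for state, loc, scale, lo, hi in (
        (STATE_TRUE_HIT, cfg.essential_hit_loc, cfg.essential_hit_scale, hit_thr, None),
        (STATE_FALSE_NEGATIVE, cfg.dropout_loc, cfg.dropout_scale, None, hit_thr),
        (STATE_FALSE_POSITIVE, cfg.fp_loc, cfg.fp_scale, hit_thr, None),
    ):
        mask = states == state
        bf[mask] = _truncated_normal(
            rng, loc, scale, int(mask.sum()), lower=lo, upper=hi
        )

    expr = base_expr.to_numpy()[:, None] + rng.normal(
        0.0, cfg.expression_noise, (cfg.n_genes, cfg.n_screens)
    )
    expr = np.clip(expr, 0.0, None)

    bf_df = pd.DataFrame(bf, index=genes, columns=screens)
    expr_df = pd.DataFrame(expr, index=genes, columns=screens)
    annotation = ScreenAnnotation(
        pd.DataFrame(
            {
                "tissue": [tissue_of[s] for s in screens],
                "subtype": [subtype_of[s] for s in screens],
            },
            index=screens,
        )
    )
    truth = TruthTable(
        gene_class=gene_class,
        states=pd.DataFrame(states, index=genes, columns=screens),
        screen_tissue=pd.Series(tissue_of, name="tissue"),
        screen_subtype=pd.Series(subtype_of, name="subtype"),
        dropout_propensity=pd.Series(propensity, index=genes, name="dropout_propensity"),
    )
    return bf_df, expr_df, annotation, truth


def generate_reference_curve(
    config: SynthConfig = SynthConfig(),
    k: int = 8,
    iterations: int = 100,
    hit_threshold: float = 10.0,
    seed: int | None = None,
) -> CumulativeCurve:
    """Cumulative plain-threshold hit curve over k-screen sets of a generated
    population; feeds parameter-recovery tests of the genome-model fit."""
    bf, _, _, _ = generate_population(config)
    return cumulative_curve(
        bf,
        set_size=k,
        hit_threshold=hit_threshold,
        iterations=iterations,
        seed=config.seed if seed is None else seed,
    )


def config_dict(config: SynthConfig) -> dict:
    """JSON/YAML-serialisable echo of a config (tuples become lists)."""
    d = asdict(config)
    d["subtype_fractions"] = list(d["subtype_fractions"])
    return d
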