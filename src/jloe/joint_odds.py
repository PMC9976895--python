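"""Joint Log Odds of Essentiality (JLOE): sequential false-negative rescue.

A single screen misses a substantial fraction of truly essential genes, and
the missed genes tend to score in the intermediate BF range near zero rather
than deeply negative. JLOE shares evidence across a set of k screens of the
same tissue: for each gene, screens are ranked from highest to lowest BF and
evaluated sequentially. The top-ranked screen is judged with the flat,
uninformative prior (log2 odds -3) and called essential when its posterior
log2 odds (BF + prior) exceed the call threshold (7, ~99% posterior
probability). At every subsequent rank the prior is updated from the
bin-wise FDR estimated by saturation resampling, given the number of
essential calls already made among higher-ranked screens: a gene already
called essential in several screens receives strongly favourable prior odds
(capped at 9), so a marginal BF in the next screen can still clear the
threshold — rescuing a false negative — while a gene with no prior call
keeps the uninformative prior and is judged exactly as plain thresholding
would.

Tissue-level results are converted to per-cell-line scores by resampling
k-screen sets many times and normalising each cell line's call count by the
number of times it was sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import BayesParams, DEFAULT_PARAMS, PriorTable
from .saturation import FrequencyProfile
from .screen_io import GeneSet

__all__ = [
    "JLOEGeneTrace",
    "JLOESetResult",
    "JLOEResult",
    "jloe_single_set",
    "jloe_tissue",
    "classify_false_negatives",
    "jaccard",
    "low_expression_hit_count",
]


@dataclass
class JLOEGeneTrace:
    """Per-rank record of the sequential evaluation for one gene."""

    gene: str
    screens: list[str]  # ranked by descending BF, ties by screen id
    bf: np.ndarray
    prior: np.ndarray
    posterior: np.ndarray
    calls: np.ndarray

    @property
    def frequency(self) -> int:
        return int(self.calls.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.screens) + 1),
                "screen": self.screens,
                "bf": self.bf,
                "prior": self.prior,
                "posterior": self.posterior,
                "call": self.calls,
            }
        )


@dataclass
class JLOESetResult:
    """Vectorised traces for every gene over one k-screen set."""

    gene_ids: pd.Index
    screen_ids: pd.Index  # the k screens of the set, original order
    ranked_screen_pos: np.ndarray  # genes x k, positions into screen_ids
    bf: np.ndarray  # genes x k, in ranked order
    prior: np.ndarray
    posterior: np.ndarray
    calls: np.ndarray  # bool, genes x k, ranked order

    @property
    def k(self) -> int:
        return self.bf.shape[1]

    @property
    def frequency(self) -> pd.Series:
        """Number of essential calls per gene, out of k."""
        return pd.Series(self.calls.sum(axis=1), index=self.gene_ids, name="frequency")

    def calls_by_screen(self) -> pd.DataFrame:
        """Boolean gene x screen call matrix in the original screen order."""
        out = np.zeros_like(self.calls)
        rows = np.arange(len(self.gene_ids))[:, None]
        out[rows, self.ranked_screen_pos] = self.calls
        return pd.DataFrame(out, index=self.gene_ids, columns=self.screen_ids)

    def posterior_by_screen(self) -> pd.DataFrame:
        out = np.zeros_like(self.posterior)
        rows = np.arange(len(self.gene_ids))[:, None]
        out[rows, self.ranked_screen_pos] = self.posterior
        return pd.DataFrame(out, index=self.gene_ids, columns=self.screen_ids)

    def trace(self, gene: str) -> JLOEGeneTrace:
        g = self.gene_ids.get_loc(gene)
        screens = [str(self.screen_ids[p]) for p in self.ranked_screen_pos[g]]
        return JLOEGeneTrace(
            gene=gene,
            screens=screens,
            bf=self.bf[g].copy(),
            prior=self.prior[g].copy(),
            posterior=self.posterior[g].copy(),
            calls=self.calls[g].copy(),
        )


def jloe_single_set(
    bf_set: pd.DataFrame,
    priors: PriorTable,
    params: BayesParams = DEFAULT_PARAMS,
) -> JLOESetResult:
    """Run the sequential joint-log-odds evaluation on one gene x k BF set.

    Per gene, screens are ranked by descending BF (ties broken by screen
    id); rank 1 uses the uninformative prior, and rank j > 1 uses the
    prior-table entry for the number of essential calls made among ranks
    1..j-1 (falling back to the uninformative prior when that count is
    zero). A call is made when BF + prior strictly exceeds the call
    threshold.
    """
    if bf_set.shape[1] < 1:
        raise ValueError("bf_set must contain at least one screen")
    k = bf_set.shape[1]
    # column order sorted by id so that a stable descending-BF sort breaks
    # ties lexicographically
    ordered = bf_set[sorted(bf_set.columns, key=str)]
    values = ordered.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("bf_set contains non-finite values")
    order = np.argsort(-values, axis=1, kind="stable")
    rows = np.arange(values.shape[0])[:, None]
    ranked_bf = values[rows, order]

    # prior lookup by number of previous calls c = 0..k-1
    prior_by_count = np.empty(k)
    prior_by_count[0] = params.uninformative_log_prior
    for c in range(1, k):
        prior_by_count[c] = priors.log_prior_for(c)

    n_genes = values.shape[0]
    prior = np.empty_like(ranked_bf)
    posterior = np.empty_like(ranked_bf)
    calls = np.zeros((n_genes, k), dtype=bool)
    n_calls = np.zeros(n_genes, dtype=np.int64)
    for j in range(k):
        prior[:, j] = prior_by_count[n_calls]
        posterior[:, j] = ranked_bf[:, j] + prior[:, j]
        calls[:, j] = posterior[:, j] > params.call_threshold
        n_calls += calls[:, j]

    # map ranked positions back into the original column order of bf_set
    pos_in_original = np.array(
        [bf_set.columns.get_loc(c) for c in ordered.columns], dtype=np.int64
    )
    return JLOESetResult(
        gene_ids=bf_set.index,
        screen_ids=bf_set.columns,
        ranked_screen_pos=pos_in_original[order],
        bf=ranked_bf,
        prior=prior,
        posterior=posterior,
        calls=calls,
    )


@dataclass
class JLOEResult:
    """Aggregated JLOE output for one tissue.

    Cell-line-level scores are normalised by sampling exposure: the
    normalised binary call of gene g in cell line s is the number of
    iterations in which g was called essential in s divided by the number
    of iterations that sampled s (NaN if s was never sampled); posterior
    log odds are normalised by the same denominator.
    """

    gene_ids: pd.Index
    screen_ids: pd.Index
    k: int
    iterations: int
    call_counts: np.ndarray  # genes x screens
    posterior_sums: np.ndarray  # genes x screens
    times_sampled: np.ndarray  # screens
    call_freq: np.ndarray  # genes x iterations, calls out of k
    sampled_screens: np.ndarray  # iterations x k positions

    @property
    def normalized_calls(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(
                self.times_sampled > 0,
                self.call_counts / np.maximum(self.times_sampled, 1),
                np.nan,
            )
        return pd.DataFrame(norm, index=self.gene_ids, columns=self.screen_ids)

    @property
    def normalized_posterior(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(
                self.times_sampled > 0,
                self.posterior_sums / np.maximum(self.times_sampled, 1),
                np.nan,
            )
        return pd.DataFrame(norm, index=self.gene_ids, columns=self.screen_ids)

    @property
    def mean_frequency(self) -> pd.Series:
        """Mean JLOE call frequency out of k, per gene, over iterations."""
        return pd.Series(
            self.call_freq.mean(axis=1), index=self.gene_ids, name="mean_frequency"
        )

    def call_sets(self, min_normalized_call: float = 1.0) -> dict[str, GeneSet]:
        """Per cell line, the genes with normalised call >= the cutoff."""
        calls = self.normalized_calls
        out = {}
        for s in calls.columns:
            col = calls[s].dropna()
            out[str(s)] = GeneSet(str(s), col.index[col >= min_normalized_call - 1e-12])
        return out


def jloe_tissue(
    tissue_matrix: pd.DataFrame,
    priors: PriorTable,
    k: int = 8,
    iterations: int = 100,
    seed: int | None = None,
    params: BayesParams = DEFAULT_PARAMS,
) -> JLOEResult:
    """JLOE over repeated k-screen samples of one tissue's screens.

    Each iteration samples k screens without replacement, runs the
    sequential evaluation, and accumulates per-(gene, cell line) calls and
    posterior log odds, which are then normalised by how often each cell
    line was sampled.
    """
    n_screens = tissue_matrix.shape[1]
    if n_screens < k:
        raise ValueError(
            f"tissue has {n_screens} screens, fewer than the set size k={k}; "
            "use a smaller k (with a matching prior table)"
        )
    rng = np.random.default_rng(seed)
    n_genes = tissue_matrix.shape[0]
    call_counts = np.zeros((n_genes, n_screens), dtype=np.int64)
    posterior_sums = np.zeros((n_genes, n_screens))
    times_sampled = np.zeros(n_screens, dtype=np.int64)
    call_freq = np.zeros((n_genes, iterations), dtype=np.int64)
    sampled = np.zeros((iterations, k), dtype=np.int64)
    for it in range(iterations):
        pick = rng.choice(n_screens, size=k, replace=False)
        sampled[it] = pick
        times_sampled[pick] += 1
        res = jloe_single_set(tissue_matrix.iloc[:, pick], priors, params)
        rows = np.arange(n_genes)[:, None]
        # ranked positions index into the picked columns; map to full matrix
        full_pos = pick[res.ranked_screen_pos]
        np.add.at(call_counts, (rows, full_pos), res.calls)
        np.add.at(posterior_sums, (rows, full_pos), res.posterior)
        call_freq[:, it] = res.calls.sum(axis=1)
    return JLOEResult(
        gene_ids=tissue_matrix.index,
        screen_ids=tissue_matrix.columns,
        k=k,
        iterations=iterations,
        call_counts=call_counts,
        posterior_sums=posterior_sums,
        times_sampled=times_sampled,
        call_freq=call_freq,
        sampled_screens=sampled,
    )


def classify_false_negatives(
    sat_freq: FrequencyProfile | pd.Series,
    jloe_freq: pd.Series,
    k: int = 8,
    label: str = "false_negatives",
    tol: float = 1e-9,
) -> GeneSet:
    """Genes below saturation (mean hit frequency < k at the plain BF
    threshold) that JLOE calls essential in every screen (mean frequency k).

    These are the rescued false negatives: consistently essential under
    joint evidence, missed by at least one screen under plain thresholding.
    """
    sat = sat_freq.mean_frequency if isinstance(sat_freq, FrequencyProfile) else sat_freq
    sat, jloe = sat.align(jloe_freq, join="inner")
    mask = (sat < k - tol) & (jloe >= k - tol)
    return GeneSet(label, sat.index[mask])


def jaccard(a: GeneSet, b: GeneSet) -> float:
    """Jaccard coefficient |a & b| / |a | b|; 0 (with a warning) when both empty."""
    union = a.members | b.members
    if not union:
        warnings.warn("jaccard of two empty sets is 0 by convention", stacklevel=2)
        return 0.0
    return len(a.members & b.members) / len(union)


def low_expression_hit_count(
    calls: dict[str, GeneSet],
    expression: pd.DataFrame,
    tpm_cutoff: float = 1.0,
) -> tuple[pd.Series, pd.Series]:
    """Per cell line, count called genes expressed below ``tpm_cutoff``.

    Unexpressed hits (log2(TPM) strictly below the cutoff, default 1.0) are
    a proxy for false-positive calls when comparing calling strategies.
    Returns (counts, missing): genes absent from the expression matrix are
    tallied separately, not counted as low-expression.
    """
    counts, missing = {}, {}
    for cell_line, gene_set in calls.items():
        if cell_line not in expression.columns:
            counts[cell_line] = 0
            missing[cell_line] = len(gene_set)
            continue
        expr = expression[cell_line].reindex(sorted(gene_set.members))
        missing[cell_line] = int(expr.isna().sum())
        counts[cell_line] = int((expr.dropna() < tpm_cutoff).sum())
    return (
        pd.Series(counts, name="low_expression_hits"),
        pd.Series(missing, name="missing_from_expression"),
    )
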