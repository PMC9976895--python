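"""Saturation resampling: bin-wise FDR, high-confidence and context
essential gene sets, and expression / non-hit BF profiles per frequency bin.

Within a tissue with enough screens, a set of k "initial" screens is assumed
to approach saturation: nearly every essential gene of the lineage is a hit
in at least one of them. A disjoint set of k "subsequent" screens then
exposes the false-positive process — genes newly hit despite absence from
the saturated initial set. Binning genes by the number of screens in which
they are hit (1..k) and taking, per bin, the ratio of subsequent-set new
hits to initial-set hits yields a bin-wise false discovery rate: high for
genes seen in a single screen, negligible for frequent hits. The bin-wise
FDR drives the prior-updating table used by the sequential joint-log-odds
calling in :mod:`jloe.joint_odds`.

Genes hit in at least ``min_mean_freq`` (default 3) of k initial screens on
average across iterations form the high-confidence essential set of the
tissue; intersecting these sets across tissues separates common essentials
from context (tissue-restricted) essentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import BayesParams, DEFAULT_PARAMS, PriorTable
from .screen_io import GeneSet, hit_matrix

__all__ = [
    "BinProfile",
    "FrequencyProfile",
    "saturation_sample",
    "binwise_fdr",
    "high_confidence_set",
    "common_context_sets",
    "expression_by_bin",
    "nonhit_bf_by_bin",
]


@dataclass
class BinProfile:
    """Per-bin hit histograms from initial (TP) and subsequent (FP) screens.

    Index b runs 1..k; ``tp_mean[b]`` is the mean (over iterations) number
    of genes hit in exactly b initial screens, ``fp_mean[b]`` the mean
    number of new genes (zero initial hits) hit in exactly b subsequent
    screens.
    """

    k: int
    tp_mean: np.ndarray
    tp_sd: np.ndarray
    fp_mean: np.ndarray
    fp_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.k + 1),
                "tp_mean": self.tp_mean,
                "tp_sd": self.tp_sd,
                "fp_mean": self.fp_mean,
                "fp_sd": self.fp_sd,
            }
        )


@dataclass
class FrequencyProfile:
    """Per-gene hit frequencies in the initial screens, across iterations.

    ``counts`` holds the raw per-iteration initial-screen hit count of every
    gene (genes x iterations); ``initial_screens`` / ``subsequent_screens``
    record which screens each iteration sampled (iterations x k, column
    positions into ``screen_ids``).
    """

    k: int
    gene_ids: pd.Index
    screen_ids: pd.Index
    counts: np.ndarray
    initial_screens: np.ndarray
    subsequent_screens: np.ndarray

    @property
    def iterations(self) -> int:
        return self.counts.shape[1]

    @property
    def mean_frequency(self) -> pd.Series:
        return pd.Series(
            self.counts.mean(axis=1), index=self.gene_ids, name="mean_frequency"
        )


def saturation_sample(
    tissue_matrix: pd.DataFrame,
    k: int = 8,
    iterations: int = 100,
    hit_threshold: float = 10.0,
    seed: int | None = None,
    fp_binning: str = "subsequent_frequency",
    tissue: str = "",
) -> tuple[BinProfile, FrequencyProfile]:
    """Initial/subsequent resampling of one tissue's screens.

    Per iteration, k initial and k subsequent screens are drawn disjointly
    without replacement. Genes are binned by their hit frequency in the
    initial screens (TP histogram); genes with no initial hit but at least
    one subsequent hit enter the FP histogram at their subsequent-set
    frequency (``fp_binning="subsequent_frequency"``) or all in bin 1
    (``"flag_once"``). Histograms are averaged over iterations.
    """
    n_screens = tissue_matrix.shape[1]
    if n_screens < 2 * k:
        label = f" for tissue {tissue!r}" if tissue else ""
        raise ValueError(
            f"saturation resampling needs at least {2 * k} screens{label}, "
            f"got {n_screens}"
        )
    if fp_binning not in ("subsequent_frequency", "flag_once"):
        raise ValueError(f"unknown fp_binning mode {fp_binning!r}")
    rng = np.random.default_rng(seed)
    hits = hit_matrix(tissue_matrix, hit_threshold).to_numpy()
    n_genes = hits.shape[0]
    tp_hist = np.zeros((iterations, k))
    fp_hist = np.zeros((iterations, k))
    counts = np.zeros((n_genes, iterations), dtype=np.int64)
    init_rec = np.zeros((iterations, k), dtype=np.int64)
    subs_rec = np.zeros((iterations, k), dtype=np.int64)
    bins = np.arange(1, k + 2)  # histogram edges for counts 1..k
    for it in range(iterations):
        perm = rng.permutation(n_screens)
        init, subs = perm[:k], perm[k : 2 * k]
        init_rec[it], subs_rec[it] = init, subs
        init_freq = hits[:, init].sum(axis=1)
        subs_freq = hits[:, subs].sum(axis=1)
        counts[:, it] = init_freq
        tp_hist[it] = np.histogram(init_freq[init_freq > 0], bins=bins)[0]
        new = (init_freq == 0) & (subs_freq > 0)
        if fp_binning == "subsequent_frequency":
            fp_hist[it] = np.histogram(subs_freq[new], bins=bins)[0]
        else:
            fp_hist[it, 0] = int(new.sum())
    profile = BinProfile(
        k=k,
        tp_mean=tp_hist.mean(axis=0),
        tp_sd=tp_hist.std(axis=0, ddof=0),
        fp_mean=fp_hist.mean(axis=0),
        fp_sd=fp_hist.std(axis=0, ddof=0),
    )
    freq = FrequencyProfile(
        k=k,
        gene_ids=tissue_matrix.index,
        screen_ids=tissue_matrix.columns,
        counts=counts,
        initial_screens=init_rec,
        subsequent_screens=subs_rec,
    )
    return profile, freq


def binwise_fdr(
    profile: BinProfile,
    params: BayesParams = DEFAULT_PARAMS,
    max_bin: int | None = None,
) -> PriorTable:
    """Bin-wise FDR and prior-update table from a saturation bin profile.

    FDR in bin b is the ratio of subsequent-set new hits to initial-set hits
    in that bin, ``fp_mean[b] / tp_mean[b]``, clipped to [0, 1]. Bins with
    no initial hits inherit the FDR of the nearest populated lower bin (such
    bins arise only for very frequent hits where the FDR is negligible);
    with no populated lower bin the FDR is 0. The table covers bins
    1..k-1 by default — the possible counts of prior essential calls in a
    k-screen set.
    """
    top = profile.k - 1 if max_bin is None else max_bin
    if top < 1:
        raise ValueError("profile must cover at least two screens")
    fdr: dict[int, float] = {}
    last = 0.0
    for b in range(1, top + 1):
        tp = profile.tp_mean[b - 1]
        fp = profile.fp_mean[b - 1]
        if tp > 0:
            last = float(np.clip(fp / tp, 0.0, 1.0))
        fdr[b] = last
    return PriorTable.from_fdr(fdr, params=params, source="estimated")


def high_confidence_set(
    freq: FrequencyProfile,
    min_mean_freq: float = 3.0,
    label: str = "high_confidence",
) -> GeneSet:
    """Genes hit in at least ``min_mean_freq`` of k initial screens on average."""
    mean = freq.mean_frequency
    return GeneSet(label, mean.index[mean >= min_mean_freq])


def common_context_sets(
    per_tissue_sets: dict[str, GeneSet],
) -> tuple[GeneSet, dict[str, GeneSet], dict[str, GeneSet]]:
    """Split per-tissue essential sets into common, context and unique genes.

    ``common`` is the intersection over all tissues; ``context[t]`` the
    tissue's set minus the common genes; ``unique[t]`` the genes essential
    in tissue t and no other.
    """
    if len(per_tissue_sets) < 2:
        raise ValueError("need at least two tissues")
    tissues = list(per_tissue_sets)
    members = {t: per_tissue_sets[t].members for t in tissues}
    common = frozenset.intersection(*members.values())
    context = {
        t: GeneSet(f"{t}_context", members[t] - common) for t in tissues
    }
    unique = {}
    for t in tissues:
        others = set().union(*(members[o] for o in tissues if o != t))
        unique[t] = GeneSet(f"{t}_unique", members[t] - others)
    return GeneSet("common", common), context, unique


def expression_by_bin(
    freq: FrequencyProfile,
    tissue_matrix: pd.DataFrame,
    expression: pd.DataFrame,
    hit_threshold: float = 10.0,
) -> tuple[pd.Series, int]:
    """Mean log2(TPM) expression per initial-screen frequency bin.

    For every iteration and every gene hit in b >= 1 initial screens, the
    gene's expression is averaged over the cell lines in which it was a hit;
    these per-gene means are then averaged within each bin over genes and
    iterations. Returns the per-bin means (index 1..k) and the number of
    (gene, iteration) records dropped because the gene or cell line is
    missing from the expression matrix.
    """
    hits = hit_matrix(tissue_matrix, hit_threshold).to_numpy()
    expr = expression.reindex(
        index=tissue_matrix.index, columns=tissue_matrix.columns
    ).to_numpy()
    sums = np.zeros(freq.k)
    n_obs = np.zeros(freq.k)
    excluded = 0
    for it in range(freq.iterations):
        init = freq.initial_screens[it]
        sub_hits = hits[:, init]
        sub_expr = expr[:, init]
        b = sub_hits.sum(axis=1)
        valid = sub_hits & np.isfinite(sub_expr)
        n_valid = valid.sum(axis=1)
        gene_mean = np.where(
            n_valid > 0, np.where(valid, sub_expr, 0.0).sum(axis=1) / np.maximum(n_valid, 1), np.nan
        )
        for bin_b in range(1, freq.k + 1):
            sel = (b == bin_b) & np.isfinite(gene_mean)
            sums[bin_b - 1] += gene_mean[sel].sum()
            n_obs[bin_b - 1] += sel.sum()
            excluded += int(((b == bin_b) & ~np.isfinite(gene_mean)).sum())
    with np.errstate(invalid="ignore"):
        means = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), np.nan)
    return (
        pd.Series(means, index=pd.RangeIndex(1, freq.k + 1, name="bin"), name="mean_log2_tpm"),
        excluded,
    )


def nonhit_bf_by_bin(
    freq: FrequencyProfile,
    tissue_matrix: pd.DataFrame,
    hit_threshold: float = 10.0,
) -> pd.DataFrame:
    """Mean BF of each binned gene in the initial screens where it was NOT a hit.

    A truly context-restricted gene should score deeply negative where it is
    not essential; a false negative sits near BF 0. For every iteration and
    every gene with initial frequency 1 <= b < k, the mean BF over the
    initial screens with BF below the hit threshold is recorded. Genes hit
    in all k screens have no non-hit screens and are excluded. Returns a
    tidy frame with columns ``gene``, ``iteration``, ``bin``,
    ``mean_nonhit_bf``.
    """
    bf = tissue_matrix.to_numpy()
    hits = bf >= hit_threshold
    records: list[tuple[str, int, int, float]] = []
    genes = np.asarray(freq.gene_ids)
    for it in range(freq.iterations):
        init = freq.initial_screens[it]
        sub_bf = bf[:, init]
        sub_hits = hits[:, init]
        b = sub_hits.sum(axis=1)
        nonhit = ~sub_hits
        n_nonhit = nonhit.sum(axis=1)
        mean_nonhit = np.where(nonhit, sub_bf, 0.0).sum(axis=1) / np.maximum(n_nonhit, 1)
        sel = (b >= 1) & (b < freq.k)
        for g, bb, m in zip(genes[sel], b[sel], mean_nonhit[sel]):
            records.append((g, it, int(bb), float(m)))
    return pd.DataFrame(records, columns=["gene", "iteration", "bin", "mean_nonhit_bf"])
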