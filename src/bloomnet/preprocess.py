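"""Table-level preprocessing: rarefaction, prevalence filtering, relative
abundance and alpha diversity.

Rarefaction subsamples each sample's reads to a common depth *without*
replacement (multivariate hypergeometric draw), matching random resampling of
physical sequence reads.  Alpha diversity follows the classic amplicon
conventions: Shannon in nats, bias-corrected Chao1 richness, and Good's
coverage from the singleton fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OtuTable

__all__ = [
    "AlphaDiversityResult",
    "rarefy",
    "prevalence_filter",
    "alpha_diversity",
    "alpha_diversity_table",
    "relative_abundance",
    "clr_abundance",
]


@dataclass
class AlphaDiversityResult:
    shannon: float          # nats
    chao1: float            # estimated richness
    goods_coverage: float   # fraction of reads from non-singleton OTUs
    observed_otus: int


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Deterministic under ``seed``; samples shallower than ``depth`` raise.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    totals = table.sample_sums()
    for sample, total in zip(table.sample_ids, totals):
        if total < depth:
            raise ValueError(
                f"sample {sample!r} has {total} reads, fewer than depth {depth}"
            )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        if totals[j] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(table.otu_ids, table.sample_ids, out, table.taxonomy)


def prevalence_filter(table: OtuTable, min_samples: int) -> OtuTable:
    """Keep OTUs with nonzero counts in at least ``min_samples`` samples."""
    if not (0 <= min_samples <= table.n_samples):
        raise ValueError(
            f"min_samples must be in [0, {table.n_samples}], got {min_samples}"
        )
    prevalence = (table.counts > 0).sum(axis=1)
    keep = [o for o, p in zip(table.otu_ids, prevalence) if p >= min_samples]
    return table.select_otus(keep)


def alpha_diversity(sample_counts: np.ndarray) -> AlphaDiversityResult:
    """Shannon (nats), bias-corrected Chao1 and Good's coverage for one sample.

    shannon = -sum p_i ln p_i over nonzero proportions; chao1 = S_obs +
    n1(n1-1)/(2(n2+1)) with n1/n2 the singleton/doubleton counts; coverage =
    1 - n1/N.
    """
    x = np.asarray(sample_counts)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if np.any(x < 0) or (x.size and not np.all(np.equal(np.mod(x, 1), 0))):
        raise ValueError("counts must be non-negative integers")
    n = int(x.sum())
    if n == 0:
        raise ValueError("all-zero count vector")
    nz = x[x > 0].astype(float)
    p = nz / n
    shannon = float(-(p * np.log(p)).sum())
    s_obs = int(nz.size)
    n1 = int((nz == 1).sum())
    n2 = int((nz == 2).sum())
    chao1 = s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    coverage = 1.0 - n1 / n
    return AlphaDiversityResult(shannon, chao1, coverage, s_obs)


def alpha_diversity_table(table: OtuTable) -> dict[str, AlphaDiversityResult]:
    """Per-sample alpha diversity keyed by sample id."""
    return {
        s: alpha_diversity(table.counts[:, j])
        for j, s in enumerate(table.sample_ids)
    }


def clr_abundance(table: OtuTable, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of counts (per sample).

    clr(x)_i = log(x_i + pseudocount) - mean_j log(x_j + pseudocount).
    Removes the per-sample closure denominator, so correlations between
    transformed profiles are not distorted by a dominant taxon's swings.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logc = np.log(table.counts + pseudocount)
    return logc - logc.mean(axis=0, keepdims=True)


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Column-normalized proportions (each sample sums to 1)."""
    totals = table.sample_sums().astype(float)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"zero-total samples: {zero}")
    return table.counts / totals
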