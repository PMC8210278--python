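"""Expression-distribution-matched control gene sets.

Comparing a cancer gene set against all other genes confounds any signal
with expression level, since curated cancer genes are systematically more
expressed. The standard remedy is a control set sampled from the candidate
pool so that its expression distribution matches the test set's.

Matching bins ``log10(FPKM + 0.01)`` into equal-width bins over the pooled
range (the pseudocount keeps zero-expression genes in a dedicated lowest
bin) and samples candidates per bin proportionally to the target's bin
count. A single global feasibility ratio scales every bin so that none is
overdrawn, preserving the target's distribution shape; target bins with no
candidates at all are skipped and recorded in the diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

PSEUDOCOUNT = 0.01


@dataclass
class MatchedSet:
    """An expression-matched control set with its matching diagnostics."""

    target_ids: list[str]
    control_ids: list[str]
    bin_edges: np.ndarray
    target_bin_counts: np.ndarray
    control_bin_counts: np.ndarray
    ks_distance: float
    ks_distance_unmatched: float
    diagnostics: dict = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write("gene_id\trole\n")
            for g in self.target_ids:
                fh.write(f"{g}\ttarget\n")
            for g in self.control_ids:
                fh.write(f"{g}\tcontrol\n")


def _as_series(records: Mapping[str, float] | pd.DataFrame) -> pd.Series:
    if isinstance(records, pd.DataFrame):
        s = records.set_index("gene_id")["mean_fpkm"]
    else:
        s = pd.Series(records, dtype=float)
    if (s < 0).any():
        raise ValueError("mean_fpkm must be non-negative")
    return s


def match_distribution(
    target: Mapping[str, float] | pd.DataFrame,
    candidates: Mapping[str, float] | pd.DataFrame,
    n_bins: int = 20,
    rng_seed: int | None = None,
) -> MatchedSet:
    """Sample an expression-matched control set from ``candidates``.

    ``target`` and ``candidates`` give mean tumour FPKM per gene and must be
    disjoint. Returns the control IDs along with the achieved two-sample KS
    distance (and, for reference, the KS distance of the unmatched pool).
    """
    t = _as_series(target)
    c = _as_series(candidates)
    if len(c) == 0:
        raise ValueError("candidate pool is empty")
    overlap = t.index.intersection(c.index)
    if len(overlap):
        raise ValueError(f"candidates overlap targets: {list(overlap[:5])}")
    rng = np.random.default_rng(rng_seed)

    lt = np.log10(t.to_numpy() + PSEUDOCOUNT)
    lc = np.log10(c.to_numpy() + PSEUDOCOUNT)
    lo = min(lt.min(), lc.min())
    hi = max(lt.max(), lc.max())
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    t_bins = np.clip(np.digitize(lt, edges) - 1, 0, n_bins - 1)
    c_bins = np.clip(np.digitize(lc, edges) - 1, 0, n_bins - 1)
    t_counts = np.bincount(t_bins, minlength=n_bins)
    c_counts = np.bincount(c_bins, minlength=n_bins)

    feasible = (t_counts > 0) & (c_counts > 0)
    skipped = np.flatnonzero((t_counts > 0) & (c_counts == 0))
    if not feasible.any():
        raise ValueError("no bin contains both target and candidate genes")
    ratio = float(np.min(c_counts[feasible] / t_counts[feasible]))

    control_ids: list[str] = []
    drawn = np.zeros(n_bins, dtype=int)
    cand_ids = c.index.to_numpy()
    for b in np.flatnonzero(feasible):
        n_draw = min(int(round(ratio * t_counts[b])), int(c_counts[b]))
        if n_draw <= 0:
            continue
        pool = cand_ids[c_bins == b]
        take = rng.choice(pool, size=n_draw, replace=False)
        control_ids.extend(sorted(take))
        drawn[b] = n_draw

    ks_matched = float(ks_2samp(t.to_numpy(), c.loc[control_ids].to_numpy()).statistic) \
        if control_ids else float("nan")
    ks_unmatched = float(ks_2samp(t.to_numpy(), c.to_numpy()).statistic)
    return MatchedSet(
        target_ids=list(t.index),
        control_ids=control_ids,
        bin_edges=edges,
        target_bin_counts=t_counts,
        control_bin_counts=drawn,
        ks_distance=ks_matched,
        ks_distance_unmatched=ks_unmatched,
        diagnostics={
            "feasible_ratio": ratio,
            "skipped_bins": skipped.tolist(),
            "n_candidates": int(len(c)),
        },
    )
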