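"""Benchmark metrics for inferred regulators.

Three complementary metrics, all per target gene:

* out-of-sample MSE — how well the inferred TFs' expression predicts the
  TG's expression on held-out cells, through a small feed-forward network
  (widths: number of TFs, 20, 1);
* average TF distance — mean pairwise diffusion-state distance between the
  inferred TFs in the PPI network;
* F1_topk — agreement between the regions bindable by the top-k inferred
  TFs (Omega) and the promoter-interaction (PCHiC-style) linked regions
  (Lambda), with Delta their overlap: precision = |Delta|/|Omega|,
  recall = |Delta|/|Lambda|.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from grip.genomic import GenomicRegion
from grip.ppi import DSDMatrix


@dataclass
class PCHiCLinkSet:
    """Distal regions observed to interact with one TG's promoter."""

    tg: str
    linked_regions: list[GenomicRegion] = field(default_factory=list)


@dataclass
class EvalResult:
    tg: str
    oos_mse: float
    avg_tf_distance: float
    precision: float
    recall: float
    f1: float
    k_used: int


def oos_mse(expr: pd.DataFrame, tg: str, tf_ids: Sequence[str],
            split_frac: float = 0.9, seed: int = 0,
            hidden_units: int = 20, max_epochs: int = 200) -> float:
    """Held-out MSE of a feed-forward predictor of TG expression from TFs.

    Cells are split by a seeded shuffle into ``split_frac`` training and
    the rest testing. The predictor is a fully connected network with one
    tanh hidden layer of ``hidden_units`` neurons and a linear output,
    trained by full-batch L-BFGS for at most ``max_epochs`` iterations —
    deterministic for a fixed seed.
    """
    tf_ids = [str(t) for t in tf_ids]
    if not tf_ids:
        raise ValueError("tf_ids must be non-empty")
    if expr.shape[0] < 10:
        raise ValueError("need at least 10 cells")
    missing = [t for t in [tg, *tf_ids] if t not in expr.columns]
    if missing:
        raise KeyError(f"genes absent from expression table: {missing}")

    m = expr.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_train = int(round(split_frac * m))
    train, test = perm[:n_train], perm[n_train:]
    if test.size < 2:
        raise ValueError("fewer than 2 test cells after split")

    Xall = expr[tf_ids].to_numpy(dtype=float)
    yall = expr[tg].to_numpy(dtype=float)
    net = MLPRegressor(hidden_layer_sizes=(hidden_units,), activation="tanh",
                       solver="lbfgs", max_iter=max_epochs, alpha=1e-4,
                       random_state=int(seed) % (2 ** 31))
    with warnings.catch_warnings():
        # the epoch budget is a deliberate cap, not a convergence failure
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Xall[train], yall[train])
    pred = net.predict(Xall[test])
    return float(np.mean((yall[test] - pred) ** 2))


def average_tf_distance(tf_ids: Sequence[str], dsd: DSDMatrix) -> float:
    """Mean pairwise diffusion-state distance between inferred TFs."""
    tf_ids = [str(t) for t in tf_ids]
    if len(set(tf_ids)) != len(tf_ids):
        dup = sorted({t for t in tf_ids if tf_ids.count(t) > 1})
        raise ValueError(f"duplicate TF(s) in list: {dup}")
    present = [t for t in tf_ids if t in dsd]
    if len(present) < 2:
        raise ValueError("undefined for fewer than two TFs mappable to the "
                         "DSD matrix")
    vals = [dsd.loc(a, b) for a, b in itertools.combinations(present, 2)]
    return float(np.mean(vals))


def _harmonic(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)


def f1_topk(tg: str, ranked_tfs: Sequence[str], k: int,
            motif_hits: pd.DataFrame,
            candidate_regions: Sequence[GenomicRegion],
            links: PCHiCLinkSet) -> tuple[float, float, float]:
    """Precision/recall/F1 of the top-k TFs' bindable regions vs links.

    Omega is the set of unique candidate regions overlapped by a motif hit
    of any of the top-k ranked TFs; Delta keeps the Omega members that
    overlap some linked region in Lambda. A region bound by several top-k
    TFs counts once; region identity is interval overlap (>= 1 shared
    base), not exact coordinate equality.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lam = links.linked_regions
    if not lam:
        raise ValueError(f"TG {tg} has no promoter-interaction links")
    top = [str(t).strip().upper() for t in ranked_tfs[:k]]
    hits = motif_hits[motif_hits["tf_id"].astype(str).str.strip()
                      .str.upper().isin(top)]
    hit_regions = [GenomicRegion(str(r.chrom), int(r.start), int(r.end))
                   for r in hits.itertuples(index=False)]
    omega = {region for region in set(candidate_regions)
             if any(region.overlaps(h) for h in hit_regions)}
    delta = {w for w in omega if any(w.overlaps(l) for l in lam)}
    precision = len(delta) / len(omega) if omega else 0.0
    recall = len(delta) / len(lam)
    return precision, recall, _harmonic(precision, recall)


def evaluate_tg(tg: str, ranked_tfs: Sequence[str], expr: pd.DataFrame,
                dsd: DSDMatrix, motif_hits: pd.DataFrame,
                candidate_regions: Sequence[GenomicRegion],
                links: PCHiCLinkSet, topk: int = 3,
                seed: int = 0) -> EvalResult:
    """All three metrics for one TG's ranked regulator call."""
    p, r, f1 = f1_topk(tg, ranked_tfs, topk, motif_hits, candidate_regions,
                       links)
    return EvalResult(
        tg=tg,
        oos_mse=oos_mse(expr, tg, list(ranked_tfs), seed=seed),
        avg_tf_distance=average_tf_distance(list(ranked_tfs), dsd),
        precision=p, recall=r, f1=f1, k_used=min(topk, len(ranked_tfs)))


def paired_onesided_t(a: Sequence[float], b: Sequence[float]) -> float:
    """One-sided paired t-test p-value that mean(a) < mean(b)."""
    res = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float),
                          alternative="less")
    return float(res.pvalue)
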