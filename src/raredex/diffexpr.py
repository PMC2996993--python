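"""Per-gene inference and selection on a normalized ratio matrix.

Each gene's replicate log2 ratios are tested against zero with a one-sample
two-sided t-test; p-values are adjusted for multiple testing by the
Benjamini–Hochberg step-up (false discovery rate).  Effect sizes are
reported as signed fold changes on the symmetric FC* scale: FC = 2^mean(M),
and fold changes below 1 are mapped to FC* = −1/FC, so a halving is −2
rather than 0.5 and |FC| ≥ 1 always.  Selection takes genes with
|FC| ≥ fc_min (inclusive, default 1.5), optionally also requiring
q ≤ q_max.  Utilities classify the overlap of two comparisons into
concordant/discordant sign patterns and summarize selected genes by an
externally supplied GO-category annotation map.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import InsufficientDataError, RatioMatrix

__all__ = [
    "gene_statistics",
    "fdr_adjust",
    "fold_change",
    "select_de_genes",
    "intersect_comparisons",
    "summarize_go",
    "read_annotation",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NOT_SELECTED = "not_selected"


def gene_statistics(matrix: RatioMatrix, min_replicates: int = 2) -> pd.DataFrame:
    """One-sample t-test of each gene's replicate M values against 0.

    Returns a DataFrame indexed by gene with columns ``n, mean_M, t_stat,
    p``.  Genes with fewer than ``min_replicates`` observed replicates, or
    with zero variance across replicates, get NaN t/p (they are reported
    but can never be declared significant).
    """
    if min_replicates < 2:
        raise ValueError("min_replicates must be at least 2")
    M = matrix.M.to_numpy(float)
    if M.size == 0:
        raise InsufficientDataError("empty ratio matrix")
    finite = np.isfinite(M)
    n = finite.sum(axis=1)
    filled = np.where(finite, M, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=1) / n
        resid = np.where(finite, M - mean[:, None], 0.0)
        sd = np.sqrt((resid**2).sum(axis=1) / (n - 1))
    mean = np.where(n > 0, mean, np.nan)
    ok = (n >= min_replicates) & (sd > 0)
    t = np.full(len(mean), np.nan)
    p = np.full(len(mean), np.nan)
    se = np.where(ok, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    t[ok] = mean[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n[ok] - 1)
    return pd.DataFrame(
        {"n": n.astype(int), "mean_M": mean, "t_stat": t, "p": p},
        index=matrix.genes,
    )


def fdr_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_i = min_{j: p_(j) ≥ p_(i)} p_(j)·m/j`` capped at 1, where m counts
    the defined p-values; NaN entries pass through as NaN and do not count
    toward m.  Input order is preserved.
    """
    p = np.asarray(list(p), dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if not mask.any():
        return q
    vals = p[mask]
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q[mask], _, _ = multipletests(vals, alpha=0.05, method="fdr_bh")
    return q


def fold_change(mean_M):
    """Signed fold change on the FC* scale.

    FC = 2^mean_M; values below 1 are reported as −1/FC so that the scale
    is symmetric about ±1 (e.g. mean_M = −1 → −2.0).  mean_M = 0 maps to
    +1.0.  Accepts scalars or arrays; NaN propagates.
    """
    m = np.asarray(mean_M, dtype=float)
    fc = np.exp2(m)
    with np.errstate(divide="ignore"):
        signed = np.where(fc >= 1.0, fc, -1.0 / fc)
    signed = np.where(np.isnan(fc), np.nan, signed)
    if np.isscalar(mean_M) or np.ndim(mean_M) == 0:
        return float(signed)
    return signed


def select_de_genes(
    results: pd.DataFrame,
    fc_min: float = 1.5,
    q_max: float | None = None,
) -> pd.DataFrame:
    """Classify genes as up/down/not_selected.

    ``results`` is the output of :func:`gene_statistics`.  Adds columns
    ``q`` (BH-adjusted p), ``fc_signed`` and ``status``.  A gene is *up*
    when fc_signed ≥ +fc_min (inclusive boundary) and, if ``q_max`` is
    given, q ≤ q_max; *down* symmetrically.  Genes without a defined q can
    only be selected when no q threshold is requested.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be at least 1")
    out = results.copy()
    out["q"] = fdr_adjust(out["p"])
    out["fc_signed"] = fold_change(out["mean_M"].to_numpy())
    fc = out["fc_signed"].to_numpy()
    passes_fc_up = fc >= fc_min
    passes_fc_down = fc <= -fc_min
    if q_max is not None:
        qok = out["q"].to_numpy() <= q_max
        passes_fc_up &= qok
        passes_fc_down &= qok
    status = np.full(len(out), STATUS_NOT_SELECTED, dtype=object)
    status[passes_fc_up] = STATUS_UP
    status[passes_fc_down] = STATUS_DOWN
    out["status"] = status
    return out


def intersect_comparisons(results1: pd.DataFrame, results2: pd.DataFrame) -> pd.DataFrame:
    """Genes selected in both comparisons, split by sign pattern.

    Inputs are :func:`select_de_genes` outputs.  A shared gene is
    *concordant* when its two signed fold changes agree in sign (regulated
    the same way in both comparisons) and *discordant* otherwise.
    """
    sel1 = results1[results1["status"] != STATUS_NOT_SELECTED]
    sel2 = results2[results2["status"] != STATUS_NOT_SELECTED]
    common = sel1.index.intersection(sel2.index)
    fc1 = sel1.loc[common, "fc_signed"]
    fc2 = sel2.loc[common, "fc_signed"]
    pattern = np.where(np.sign(fc1) == np.sign(fc2), "concordant", "discordant")
    return pd.DataFrame(
        {"fc_comparison1": fc1, "fc_comparison2": fc2, "pattern": pattern},
        index=common,
    )


def read_annotation(source) -> dict[str, str]:
    """Tab-delimited ``gene<TAB>category`` map (header optional)."""
    df = pd.read_csv(source, sep="\t", dtype=str, header=None)
    if list(df.iloc[0]) == ["gene_id", "category"]:
        df = df.iloc[1:]
    return dict(zip(df[0], df[1]))


def summarize_go(
    genes: Iterable[str],
    annotation: Mapping[str, str],
    direction: str | None = None,
) -> pd.DataFrame:
    """Category counts and percentages for a gene list.

    Percentages are relative to the full input list; genes absent from the
    annotation map are tallied under ``"unknown"``.  ``direction`` is an
    optional label carried into the output (e.g. "up"/"down").
    """
    genes = list(genes)
    if not genes:
        return pd.DataFrame(columns=["category", "count", "percentage"])
    cats = pd.Series([annotation.get(g, "unknown") for g in genes])
    counts = cats.value_counts()
    out = pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.to_numpy(),
            "percentage": 100.0 * counts.to_numpy() / len(genes),
        }
    ).reset_index(drop=True)
    if direction is not None:
        out.insert(0, "direction", direction)
    return out
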