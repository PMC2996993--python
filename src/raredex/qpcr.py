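"""Relative quantification of qPCR data by the comparative Ct (ΔΔCt) method.

Each well measures a target gene and an endogenous reference (e.g.
ribosomal 18S) in the same sample.  Per replicate, ΔCt = Ct_target −
Ct_reference normalizes template input; per (group, gene), ΔΔCt is the
difference between the group's mean ΔCt and the calibrator group's, and
the relative quantity is RQ = 2^−ΔΔCt (one PCR cycle ≈ one doubling).
Dispersion is the SEM of per-replicate ΔCt mapped through the exponential
at the point estimate (delta method), and group differences are assessed
on per-replicate ΔCt values with one-way ANOVA and pairwise two-sample
t-tests.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import fold_change

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "relative_quantity",
    "group_comparison",
]

_LN2 = np.log(2.0)
_CT_COLUMNS = ("group", "gene", "replicate", "ct_target", "ct_reference")


def read_ct_table(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df


def write_ct_table(table: pd.DataFrame, sink) -> None:
    table.to_csv(sink, sep="\t", index=False, lineterminator="\n")


def _validate(table: pd.DataFrame) -> None:
    for col in _CT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    ct = table[["ct_target", "ct_reference"]].to_numpy(float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be positive and finite")


def relative_quantity(
    table: pd.DataFrame,
    calibrator: str,
    signed_fc: bool = False,
) -> pd.DataFrame:
    """ΔCt/ΔΔCt/2^−ΔΔCt per (group, gene) against a calibrator group.

    Returns one row per (group, gene) with columns ``n, delta_ct,
    delta_delta_ct, rq, sem`` — ``sem`` is the delta-method standard error
    of RQ (``rq·ln2·SEM(ΔCt)``); for a single replicate RQ is computed but
    the SEM is absent (a warning is emitted).  With ``signed_fc=True`` an
    ``fc_signed`` column maps RQ onto the symmetric signed fold-change
    scale used for the microarray results.  The calibrator group has
    ΔΔCt = 0 and RQ = 1 exactly.
    """
    _validate(table)
    if calibrator not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator!r} not present")
    dct = table.assign(dct=table["ct_target"] - table["ct_reference"])

    per_group = (
        dct.groupby(["group", "gene"], sort=True)["dct"]
        .agg(["mean", "std", "size"])
        .rename(columns={"mean": "delta_ct", "std": "sd", "size": "n"})
        .reset_index()
    )
    cal = per_group[per_group["group"] == calibrator].set_index("gene")["delta_ct"]
    missing = set(per_group["gene"]) - set(cal.index)
    if missing:
        raise ValueError(f"calibrator group lacks genes: {sorted(missing)}")

    ddct = per_group["delta_ct"] - per_group["gene"].map(cal).to_numpy()
    rq = np.exp2(-ddct)
    sem_dct = per_group["sd"] / np.sqrt(per_group["n"])
    if (per_group["n"] == 1).any():
        warnings.warn("single-replicate (group, gene) cells: SEM not available")
    out = pd.DataFrame(
        {
            "group": per_group["group"],
            "gene": per_group["gene"],
            "n": per_group["n"].astype(int),
            "delta_ct": per_group["delta_ct"],
            "delta_delta_ct": ddct,
            "rq": rq,
            "sem": rq * _LN2 * sem_dct,
        }
    )
    if signed_fc:
        out["fc_signed"] = fold_change(-ddct.to_numpy())
    return out


def group_comparison(
    table: pd.DataFrame,
    gene: str,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA and pairwise t-tests on per-replicate ΔCt for a gene.

    Returns ``{"anova_p": float|nan, "pairwise_t_p": {(g1, g2): p},
    "significant": bool|None}`` with significance at ``alpha`` on the ANOVA
    p.  Degenerate (zero-variance) data yield NaN p-values with a warning.
    Requires ≥2 groups with ≥2 replicates each.
    """
    _validate(table)
    sub = table[table["gene"] == gene]
    groups = sorted(sub["group"].unique())
    samples = {g: (sub.loc[sub["group"] == g, "ct_target"]
                   - sub.loc[sub["group"] == g, "ct_reference"]).to_numpy(float)
               for g in groups}
    if len(groups) < 2 or any(len(v) < 2 for v in samples.values()):
        from .preprocess import InsufficientDataError

        raise InsufficientDataError(
            f"gene {gene!r}: need ≥2 groups with ≥2 replicates each"
        )
    values = list(samples.values())
    if all(np.ptp(v) == 0 for v in values):
        warnings.warn(f"gene {gene!r}: zero variance in every group; p undefined")
        anova_p = float("nan")
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            anova_p = float(stats.f_oneway(*values).pvalue)
    pairwise = {}
    for g1, g2 in itertools.combinations(groups, 2):
        a, b = samples[g1], samples[g2]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            pairwise[(g1, g2)] = float("nan")
        else:
            pairwise[(g1, g2)] = float(stats.ttest_ind(a, b).pvalue)
    return {
        "anova_p": anova_p,
        "pairwise_t_p": pairwise,
        "significant": None if np.isnan(anova_p) else bool(anova_p < alpha),
    }
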