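"""From raw slides to normalized per-gene log2 ratios.

Pipeline per slide: quality filtering (flags, saturation at the scanner
ceiling, signal-to-background ratio), a data-driven decision whether to
subtract the local spot background, computation of the per-spot quantities
M = log2(treated/control) and A = mean log2 intensity, and removal of the
intensity-dependent dye bias by robust lowess of M on A.  Dye-swapped slide
pairs are then combined: averaging the sign-resolved ratios of a forward
and a swapped slide cancels any additive (in log2) dye bias shared by the
pair exactly.

The background-subtraction rule follows the correlation heuristic: local
background is subtracted only when, over retained spots, the log
foreground and log background medians of a channel are substantially
correlated (background then carries spot-specific signal contamination);
an uncorrelated background is left in place rather than injecting its
noise into every ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .gpr_io import (
    QC_EXCLUDED_FLAG,
    QC_EXCLUDED_SATURATED,
    QC_EXCLUDED_SB,
    QC_RETAINED,
    DesignError,
    DesignTable,
    SlideAssay,
)

__all__ = [
    "QcParams",
    "RatioMatrix",
    "InsufficientDataError",
    "apply_qc_mask",
    "background_policy",
    "compute_ma",
    "lowess_correct",
    "dye_swap_combine",
    "normalize_experiment",
]


class InsufficientDataError(ValueError):
    """Too few usable spots/replicates for the requested computation."""


@dataclass
class QcParams:
    """Filtering and normalization thresholds.

    ``sb_min``: spots with foreground/background below this in *either*
    channel are filtered (strictly below — a ratio of exactly ``sb_min`` is
    retained).  ``bg_correlation_threshold``: minimum Pearson correlation of
    log2 foreground vs log2 background at which local background is
    subtracted.  ``lowess_span``: fraction of spots in each local
    regression window.
    """

    saturation_level: int = 65535
    sb_min: float = 1.5
    bad_flag_codes: frozenset[int] = frozenset({-100, -75, -50})
    bg_correlation_threshold: float = 0.5
    lowess_span: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.sb_min <= 0:
            raise ValueError("sb_min must be positive")
        if not 0.0 < self.lowess_span <= 1.0:
            raise ValueError("lowess_span must lie in (0, 1]")
        self.bad_flag_codes = frozenset(self.bad_flag_codes)


@dataclass
class RatioMatrix:
    """Genes × replicates of normalized log2 ratios.

    ``M``/``A``/``n_spots_used`` are DataFrames indexed by gene with one
    column per replicate.  A replicate column is a sign-resolved slide by
    default; :func:`normalize_experiment` can instead emit one column per
    dye-swap pair (``collapse_pairs=True``), in which case the pair average
    is exactly dye-bias-free.  ``pair_of`` maps each column to its
    replicate-pair label.  M and A are NaN where no spot survived QC.
    """

    genes: pd.Index
    replicates: list[str]
    M: pd.DataFrame
    A: pd.DataFrame
    n_spots_used: pd.DataFrame
    pair_of: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def collapse_pairs(self) -> "RatioMatrix":
        """Average replicate columns pair-wise (dye-swap combination)."""
        if not self.pair_of:
            raise ValueError("no pair labels recorded")
        pairs = sorted(set(self.pair_of.values()))
        M = {}
        A = {}
        n = {}
        for p in pairs:
            cols = [c for c in self.replicates if self.pair_of[c] == p]
            M[p] = self.M[cols].mean(axis=1)
            A[p] = self.A[cols].mean(axis=1)
            n[p] = self.n_spots_used[cols].sum(axis=1)
        return RatioMatrix(
            genes=self.genes,
            replicates=pairs,
            M=pd.DataFrame(M),
            A=pd.DataFrame(A),
            n_spots_used=pd.DataFrame(n),
            pair_of={p: p for p in pairs},
            provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.M.add_prefix("M.")
        out = out.join(self.A.add_prefix("A."))
        out = out.join(self.n_spots_used.add_prefix("n."))
        out.index.name = "gene_id"
        return out

    def write(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", lineterminator="\n")

    @classmethod
    def read(cls, source) -> "RatioMatrix":
        df = pd.read_csv(source, sep="\t", index_col="gene_id")
        reps = [c[2:] for c in df.columns if c.startswith("M.")]
        return cls(
            genes=df.index,
            replicates=reps,
            M=df[[f"M.{r}" for r in reps]].rename(columns=lambda c: c[2:]),
            A=df[[f"A.{r}" for r in reps]].rename(columns=lambda c: c[2:]),
            n_spots_used=df[[f"n.{r}" for r in reps]].rename(columns=lambda c: c[2:]).astype(int),
        )


def apply_qc_mask(slide: SlideAssay, params: QcParams) -> SlideAssay:
    """Annotate each spot's qc_status; never drops rows.

    Exclusion reasons are assigned in priority order flag → saturated →
    signal/background.  A spot is saturated when either channel's
    foreground median equals the scanner ceiling; it fails S/B when either
    channel's foreground/background ratio is strictly below ``sb_min``
    (zero background with positive foreground counts as S/B = +∞).
    """
    spots = slide.spots.copy()
    f635 = spots["f635_median"].to_numpy(float)
    f532 = spots["f532_median"].to_numpy(float)
    b635 = spots["b635_median"].to_numpy(float)
    b532 = spots["b532_median"].to_numpy(float)

    flagged = spots["flag"].isin(list(params.bad_flag_codes)).to_numpy()
    saturated = (f635 >= params.saturation_level) | (f532 >= params.saturation_level)
    with np.errstate(divide="ignore", invalid="ignore"):
        sb635 = np.where(b635 > 0, f635 / np.where(b635 > 0, b635, 1), np.inf)
        sb532 = np.where(b532 > 0, f532 / np.where(b532 > 0, b532, 1), np.inf)
    low_sb = (sb635 < params.sb_min) | (sb532 < params.sb_min)

    status = np.full(len(spots), QC_RETAINED, dtype=object)
    status[low_sb] = QC_EXCLUDED_SB
    status[saturated] = QC_EXCLUDED_SATURATED
    status[flagged] = QC_EXCLUDED_FLAG
    spots["qc_status"] = status
    return SlideAssay(
        slide_id=slide.slide_id,
        orientation=slide.orientation,
        spots=spots,
        channel_meta=dict(slide.channel_meta),
    )


def background_policy(slide: SlideAssay, params: QcParams) -> dict[str, dict]:
    """Decide, per channel, whether to subtract local background.

    Returns ``{"635": {"subtract": bool, "correlation": float},
    "532": {...}}`` where the correlation is Pearson's r between
    log2(foreground median) and log2(background median) over retained
    spots (counts floored at 1 for the logarithm).  An undefined
    correlation (constant channel) yields ``subtract=False``.
    """
    retained = slide.retained()
    if len(retained) < 3:
        raise InsufficientDataError(
            f"slide {slide.slide_id!r}: {len(retained)} retained spots (<3)"
        )
    out: dict[str, dict] = {}
    for chan in ("635", "532"):
        f = np.log2(np.maximum(retained[f"f{chan}_median"].to_numpy(float), 1.0))
        b = np.log2(np.maximum(retained[f"b{chan}_median"].to_numpy(float), 1.0))
        if np.ptp(f) == 0 or np.ptp(b) == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(f, b)[0, 1])
        subtract = bool(corr >= params.bg_correlation_threshold) if np.isfinite(corr) else False
        out[chan] = {"subtract": subtract, "correlation": corr}
    return out


def compute_ma(slide: SlideAssay, policy: Mapping[str, Mapping] | None = None) -> pd.DataFrame:
    """Per-spot M and A over retained spots.

    ``signal = foreground − background`` for a channel whose policy says
    subtract, else the raw foreground; either way floored at 1 count (the
    ``clipped`` column marks spots hit by the floor).  M is sign-resolved to
    treated/control using the slide orientation: on a swapped slide the
    treated condition was labelled with the 532 dye, so M = −log2(F635/F532)
    in dye space.  A = ½·log2(signal_635 · signal_532) is orientation-free.
    """
    retained = slide.retained()
    policy = policy or {"635": {"subtract": False}, "532": {"subtract": False}}
    sig = {}
    clipped = np.zeros(len(retained), dtype=bool)
    for chan in ("635", "532"):
        f = retained[f"f{chan}_median"].to_numpy(float)
        if policy[chan]["subtract"]:
            s = f - retained[f"b{chan}_median"].to_numpy(float)
        else:
            s = f
        clipped |= s < 1
        sig[chan] = np.maximum(s, 1.0)
    sign = 1.0 if slide.orientation == "forward" else -1.0
    m = sign * (np.log2(sig["635"]) - np.log2(sig["532"]))
    a = 0.5 * (np.log2(sig["635"]) + np.log2(sig["532"]))
    return pd.DataFrame(
        {
            "spot_id": retained["spot_id"].to_numpy(),
            "gene_id": retained["gene_id"].to_numpy(),
            "M": m,
            "A": a,
            "clipped": clipped,
        }
    )


def lowess_correct(ma: pd.DataFrame, span: float = 2.0 / 3.0) -> pd.DataFrame:
    """Remove the intensity-dependent trend of M on A.

    Robust locally weighted regression (3 reweighting iterations) with the
    given smoother span; the fitted trend is subtracted from each spot's M.
    Requires at least 10 spots.
    """
    if len(ma) < 10:
        raise InsufficientDataError(f"{len(ma)} spots (<10) for lowess")
    a = ma["A"].to_numpy(float)
    m = ma["M"].to_numpy(float)
    delta = 0.005 * np.ptp(a) if len(a) > 2000 else 0.0
    fitted = _sm_lowess(
        m, a, frac=span, it=3, delta=delta, return_sorted=False
    )
    out = ma.copy()
    out["M"] = m - fitted
    return out


def _collapse_spots(ma: pd.DataFrame) -> pd.DataFrame:
    """Median-collapse duplicate spots of a gene within one slide."""
    g = ma.groupby("gene_id", sort=True)
    return pd.DataFrame(
        {"M": g["M"].median(), "A": g["A"].median(), "n_spots": g["M"].size()}
    )


def dye_swap_combine(forward: pd.DataFrame, swapped: pd.DataFrame) -> pd.DataFrame:
    """Combine a forward and a swapped slide into per-gene replicate values.

    Inputs are per-spot (gene_id, M, A) tables whose M is already
    sign-resolved to treated/control by :func:`compute_ma`.  Duplicate
    spots are median-collapsed within each slide, then the two per-slide
    gene values are averaged; because an additive log2 dye bias enters the
    two slides with opposite sign after sign resolution, the average is
    exactly bias-free.  Genes measured on only one slide keep that value
    (``single_slide`` marks them).
    """
    fw = _collapse_spots(forward)
    sw = _collapse_spots(swapped)
    if len(fw.index.intersection(sw.index)) == 0 and len(fw) and len(sw):
        raise DesignError("forward and swapped slides share no genes")
    joined = fw.join(sw, how="outer", lsuffix="_f", rsuffix="_s")
    m = joined[["M_f", "M_s"]].mean(axis=1)
    a = joined[["A_f", "A_s"]].mean(axis=1)
    n = joined[["n_spots_f", "n_spots_s"]].sum(axis=1).astype(int)
    single = joined["M_f"].isna() | joined["M_s"].isna()
    return pd.DataFrame(
        {"M": m, "A": a, "n_spots": n, "single_slide": single}
    )


def normalize_experiment(
    slides: Sequence[SlideAssay],
    design: DesignTable,
    params: QcParams | None = None,
    comparison: str | None = None,
    collapse_pairs: bool = False,
    lowess: bool = True,
) -> RatioMatrix:
    """Run QC → background policy → M/A → lowess per slide, then assemble.

    By default the matrix has one sign-resolved replicate column per slide
    (the unit used for per-gene inference); with ``collapse_pairs=True``
    each dye-swap pair is averaged into a single column.  Per-slide
    decisions and exclusion counts are recorded in ``provenance``.
    """
    params = params or QcParams()
    by_id = {s.slide_id: s for s in slides}
    design.validate(by_id)
    if comparison is None:
        if len(design.comparisons) != 1:
            raise DesignError("multiple comparisons in design; specify one")
        comparison = design.comparisons[0][0]
    pairs = design.pairs_for(comparison)
    if not pairs:
        raise DesignError(f"no replicate pairs for comparison {comparison!r}")

    per_slide: dict[str, pd.DataFrame] = {}
    pair_of: dict[str, str] = {}
    prov: dict = {"comparison": comparison, "slides": {}, "params": params.__dict__.copy()}
    for k, (fwd, swp) in enumerate(pairs, start=1):
        for sid in (fwd, swp):
            slide = apply_qc_mask(by_id[sid], params)
            counts = slide.spots["qc_status"].value_counts().to_dict()
            policy = background_policy(slide, params)
            ma = compute_ma(slide, policy)
            if lowess:
                ma = lowess_correct(ma, span=params.lowess_span)
            per_slide[sid] = ma
            pair_of[sid] = f"pair{k}"
            prov["slides"][sid] = {
                "qc_counts": counts,
                "background_policy": policy,
                "n_spots_used": int(len(ma)),
            }

    if collapse_pairs:
        columns = {}
        for k, (fwd, swp) in enumerate(pairs, start=1):
            columns[f"pair{k}"] = dye_swap_combine(per_slide[fwd], per_slide[swp])
        pair_map = {c: c for c in columns}
    else:
        columns = {sid: _collapse_spots(per_slide[sid]) for sid in per_slide}
        pair_map = pair_of

    genes = pd.Index(sorted(set().union(*(c.index for c in columns.values()))), name="gene_id")
    reps = list(columns)
    M = pd.DataFrame({r: columns[r]["M"].reindex(genes) for r in reps})
    A = pd.DataFrame({r: columns[r]["A"].reindex(genes) for r in reps})
    n = pd.DataFrame(
        {r: columns[r]["n_spots"].reindex(genes).fillna(0).astype(int) for r in reps}
    )
    return RatioMatrix(
        genes=genes,
        replicates=reps,
        M=M,
        A=A,
        n_spots_used=n,
        pair_of=pair_map,
        provenance=prov,
    )
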