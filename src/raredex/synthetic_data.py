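"""Synthetic experiments with known ground truth.

Three generators emulate the data the analysis pipeline consumes:

* a spot-level two-colour microarray experiment — dye-swapped replicate
  slide pairs with planted log2 fold changes, an intensity-dependent dye
  bias, additive local background, scanner saturation at a hard ceiling and
  a fraction of flagged (bad) spots;
* an aligned promoter pair with planted direct-repeat half-site motifs and
  a tunable inter-species substitution rate;
* a qPCR Ct table (target + reference gene, replicate wells) with known
  true fold changes between a treated group and a calibrator group.

Each generator returns, alongside the data, a :class:`SyntheticTruth`
recording what was planted, so recovery can be measured exactly.  Equal
seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gpr_io import DesignTable, SlideAssay

__all__ = [
    "ArraySimParams",
    "SyntheticTruth",
    "simulate_two_color_experiment",
    "simulate_promoter_pair",
    "simulate_qpcr_experiment",
    "HALF_SITE_CHOICES",
]

#: expansions of the PuG(G/T)TCA half-site consensus (Pu = A/G)
HALF_SITE_CHOICES = tuple(
    p + "G" + m + "TCA" for p in "AG" for m in "GT"
)

_BAD_FLAG = -100  # GenePix convention for a manually failed spot


@dataclass
class ArraySimParams:
    """Conditions of a simulated two-colour experiment.

    The defaults model a genome-scale spotted oligo array scanned on a
    16-bit scanner: one spot per gene, per-gene baseline log2 intensity
    N(11, 1.2) (median foreground ≈ 2000 counts), additive log-normal local
    background of mean 150 counts, saturation at 65535 counts, 2% of spots
    flagged bad, and a smooth quadratic dye bias in average intensity A
    whose amplitude (≈0.2–0.4 in M) is typical of unnormalised Cy-dye data.

    ``noise_sd`` is the standard deviation of the per-spot log2 ratio M
    contributed by measurement noise (split evenly between the channels).
    ``dye_bias_coeffs`` are ascending polynomial coefficients evaluated at
    the latent A.  ``gene_dye_bias`` optionally adds an arbitrary per-gene
    dye bias (same sign in dye space on both slides of a pair), which the
    dye-swap average cancels exactly.
    """

    n_genes: int = 1000
    spots_per_gene: int = 1
    n_replicate_pairs: int = 3
    de_fraction: float = 0.1
    true_log2fc_magnitude: float = 1.0
    noise_sd: float = 0.3
    dye_bias_coeffs: Sequence[float] = (2.8, -0.46, 0.02)
    background_mean: float = 150.0
    background_sd: float = 50.0
    saturation_level: int = 65535
    flag_fraction: float = 0.02
    seed: int = 0
    # secondary knobs, fixed unless a study varies them
    base_log2_mean: float = 11.0
    base_log2_sd: float = 1.2
    bg_foreground_slope: float = 0.0  # >0 couples log-background to log-foreground
    gene_dye_bias: Sequence[float] | None = None
    round_counts: bool = True  # False keeps exact float medians (algebraic oracles)
    comparison: tuple[str, str, str] = ("treated_vs_control", "treated", "control")

    def validate(self) -> None:
        if self.n_genes < 1 or self.spots_per_gene < 1 or self.n_replicate_pairs < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.flag_fraction <= 1.0:
            raise ValueError("flag_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.saturation_level <= self.background_mean:
            raise ValueError("saturation_level must exceed background_mean")
        if self.gene_dye_bias is not None and len(self.gene_dye_bias) != self.n_genes:
            raise ValueError("gene_dye_bias must have one entry per gene")


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to generated data."""

    de_genes: dict[str, float] = field(default_factory=dict)
    planted_motifs: list[tuple[str, int, str, int]] = field(default_factory=list)
    qpcr_truth: dict[str, float] = field(default_factory=dict)

    def de_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.de_genes), "true_log2fc": list(self.de_genes.values())}
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment-match a log-normal to the requested count-space mean/sd;
    # mean 0 means "no background", sd 0 a constant background
    if mean <= 0:
        return -np.inf, 0.0
    var = sd * sd
    sigma2 = np.log1p(var / (mean * mean))
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_two_color_experiment(
    params: ArraySimParams,
) -> tuple[list[SlideAssay], DesignTable, SyntheticTruth]:
    """Simulate dye-swapped replicate slide pairs with planted fold changes.

    Per spot, each channel's latent log2 intensity is the gene baseline
    ± half the true log2 ratio, ± half the dye bias (a polynomial in the
    latent A, plus any per-gene term), plus Gaussian noise of sd
    ``noise_sd/√2`` per channel; foreground counts are ``2**latent`` plus an
    additive local background draw, rounded and clipped at
    ``saturation_level``.  The measured background median for each channel
    is the same local draw that contaminated the foreground.  On a swapped
    slide the treated condition sits in the 532 channel, so the raw dye-space
    ratio is sign-flipped while the dye bias is not.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    G, S, P = params.n_genes, params.spots_per_gene, params.n_replicate_pairs

    genes = np.array([f"g{i + 1:05d}" for i in range(G)])
    n_de = int(round(params.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    true_m = np.zeros(G)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        true_m[de_idx] = signs * params.true_log2fc_magnitude
    base = rng.normal(params.base_log2_mean, params.base_log2_sd, size=G)

    bias_poly = np.polynomial.polynomial.polyval(base, np.asarray(params.dye_bias_coeffs, float))
    if params.gene_dye_bias is not None:
        bias_poly = bias_poly + np.asarray(params.gene_dye_bias, float)

    mu_bg, sigma_bg = _lognormal_params(params.background_mean, params.background_sd)
    chan_sd = params.noise_sd / np.sqrt(2.0)

    spot_gene = np.repeat(np.arange(G), S)  # gene index per spot
    n_spots = G * S
    spot_ids = np.array([f"s{i + 1:06d}" for i in range(n_spots)])

    slides: list[SlideAssay] = []
    pairs: list[tuple[str, str, str]] = []
    comp_name = params.comparison[0]
    for p in range(P):
        pair_ids = []
        for orientation in ("forward", "swapped"):
            sid = f"slide{p + 1:02d}{'f' if orientation == 'forward' else 's'}"
            pair_ids.append(sid)
            sign = 1.0 if orientation == "forward" else -1.0
            m_dye = sign * true_m[spot_gene] + bias_poly[spot_gene]
            b = base[spot_gene]
            eps635 = rng.normal(0.0, chan_sd, size=n_spots) if params.noise_sd else 0.0
            eps532 = rng.normal(0.0, chan_sd, size=n_spots) if params.noise_sd else 0.0
            log_f635 = b + m_dye / 2.0 + eps635
            log_f532 = b - m_dye / 2.0 + eps532
            bg_logn = rng.normal(0.0, 1.0, size=(n_spots, 2))
            bg635 = np.exp(mu_bg + sigma_bg * bg_logn[:, 0] + params.bg_foreground_slope * (log_f635 - np.mean(log_f635)))
            bg532 = np.exp(mu_bg + sigma_bg * bg_logn[:, 1] + params.bg_foreground_slope * (log_f532 - np.mean(log_f532)))
            sat = params.saturation_level
            f635 = np.minimum(np.exp2(log_f635) + bg635, sat)
            f532 = np.minimum(np.exp2(log_f532) + bg532, sat)
            if params.round_counts:
                f635 = np.round(f635).astype(int)
                f532 = np.round(f532).astype(int)
            flags = np.zeros(n_spots, dtype=int)
            if params.flag_fraction > 0:
                n_flag = int(round(params.flag_fraction * n_spots))
                flags[rng.choice(n_spots, size=n_flag, replace=False)] = _BAD_FLAG
            spots = pd.DataFrame(
                {
                    "spot_id": spot_ids,
                    "gene_id": genes[spot_gene],
                    "f635_median": f635,
                    "b635_median": np.round(bg635).astype(int) if params.round_counts else bg635,
                    "f532_median": f532,
                    "b532_median": np.round(bg532).astype(int) if params.round_counts else bg532,
                    "flag": flags,
                    "qc_status": "retained",
                }
            )
            slides.append(
                SlideAssay(
                    slide_id=sid,
                    orientation=orientation,
                    spots=spots,
                    channel_meta={},
                )
            )
        pairs.append((pair_ids[0], pair_ids[1], comp_name))

    design = DesignTable(comparisons=[params.comparison], replicate_pairs=pairs)
    truth = SyntheticTruth(
        de_genes={genes[i]: float(true_m[i]) for i in sorted(de_idx)}
    )
    return slides, design, truth


# ---------------------------------------------------------------------------
# promoter pairs


def simulate_promoter_pair(
    length: int,
    planted: Sequence[tuple[int, str, int]],
    substitution_rate: float,
    seed: int,
    species: tuple[str, str] = ("mouse", "human"),
):
    """Random promoter pair with planted direct repeats.

    ``planted`` lists (offset, strand, spacer): the offset is the 1-based
    distance upstream of the anchor of the repeat's 5′-most base on the +
    strand, reported negative (−1 = base immediately before the anchor).
    Half-sites are drawn from the PuG(G/T)TCA consensus; for a ``-`` strand
    plant the repeat is built on the reverse complement and mapped back.
    The second species is a copy of the first mutated at
    ``substitution_rate`` per base outside planted footprints, so planted
    motifs stay perfectly conserved.  Returns ``(PromoterPair, SyntheticTruth)``
    with an identity (gap-free) alignment attached.
    """
    from .rare_scan import PromoterPair, reverse_complement

    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)

    footprints: list[tuple[int, int]] = []
    for offset, strand, spacer in planted:
        if strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if spacer < 0:
            raise ValueError("spacer must be non-negative")
        if not (-length <= offset <= -1):
            raise ValueError(f"offset {offset} outside [-{length}, -1]")
        start = length + offset  # 0-based start of the footprint
        width = 12 + spacer
        if start + width > length:
            raise ValueError(f"plant at offset {offset} exceeds the region")
        for s0, s1 in footprints:
            if start < s1 and s0 < start + width:
                raise ValueError("planted motif footprints overlap")
        footprints.append((start, start + width))
        half1 = HALF_SITE_CHOICES[rng.integers(len(HALF_SITE_CHOICES))]
        half2 = HALF_SITE_CHOICES[rng.integers(len(HALF_SITE_CHOICES))]
        gap = "".join(rng.choice(list("ACGT"), size=spacer))
        motif = half1 + gap + half2
        if strand == "-":
            motif = reverse_complement(motif)
        seq[start : start + width] = list(motif)

    seq_a = "".join(seq)
    seq_b = np.array(seq, copy=True)
    if substitution_rate > 0:
        protected = np.zeros(length, dtype=bool)
        for s0, s1 in footprints:
            protected[s0:s1] = True
        mutate = (rng.random(length) < substitution_rate) & ~protected
        idx = np.nonzero(mutate)[0]
        alphabet = np.array(list("ACGT"))
        for i in idx:
            options = alphabet[alphabet != seq_b[i]]
            seq_b[i] = options[rng.integers(3)]
    seq_b = "".join(seq_b)

    pair = PromoterPair(
        species_a=species[0],
        species_b=species[1],
        seq_a=seq_a,
        seq_b=seq_b,
        aligned_a=seq_a,
        aligned_b=seq_b,
        anchor="TSS",
        region_length=length,
    )
    truth = SyntheticTruth(
        planted_motifs=[(species[0], off, strand, spacer) for off, strand, spacer in planted]
    )
    return pair, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr_experiment(
    genes: Sequence[str],
    true_fc: Mapping[str, float],
    ct_noise_sd: float,
    n_replicates: int,
    seed: int,
    groups: tuple[str, str] = ("control", "treated"),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Ct table for a calibrator group and a treated group.

    The target gene's Ct in the treated group is lowered by log2(true fold
    change) relative to the calibrator baseline (one PCR cycle per doubling
    of template); the reference gene's Ct does not depend on the group.
    Gaussian noise of sd ``ct_noise_sd`` is added per well.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    for g in genes:
        if g not in true_fc or not true_fc[g] > 0:
            raise ValueError(f"true fold change for {g!r} must be positive")
    rng = np.random.default_rng(seed)
    calibrator, treated = groups
    rows = []
    for gi, gene in enumerate(genes):
        target_baseline = 22.0 + 6.0 * rng.random()
        ref_baseline = 10.0 + 2.0 * rng.random()
        for group in groups:
            shift = -np.log2(true_fc[gene]) if group == treated else 0.0
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd, size=2) if ct_noise_sd else (0.0, 0.0)
                rows.append(
                    {
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct_target": target_baseline + shift + noise[0],
                        "ct_reference": ref_baseline + noise[1],
                    }
                )
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(qpcr_truth={g: float(true_fc[g]) for g in genes})
    return table, truth
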