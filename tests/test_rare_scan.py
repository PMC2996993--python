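"""Half-site and direct-repeat scanning, alignment, conserved blocks, and
the scan orchestration — checked against brute-force oracles."""

import io

import numpy as np
import pytest

from raredex.rare_scan import (
    IUPAC,
    ConservedBlock,
    MotifParams,
    PromoterPair,
    align_promoters,
    conserved_blocks,
    find_direct_repeats,
    find_half_sites,
    read_promoter_pair,
    reverse_complement,
    scan_promoter_pair,
    write_promoter_pair,
)
from raredex.synthetic_data import simulate_promoter_pair


# --- brute-force oracles (independent of the implementation) ----------------


def mm_count(window, consensus):
    return sum(ch not in IUPAC[c] for ch, c in zip(window, consensus))


def oracle_half_sites(seq, consensus="RGKTCA", maxmm=0, strands="both"):
    out = set()
    w = len(consensus)
    for i in range(len(seq) - w + 1):
        if mm_count(seq[i : i + w], consensus) <= maxmm:
            out.add((i + 1, "+"))
    if strands == "both":
        rc = reverse_complement(seq)
        n = len(seq)
        for j in range(len(rc) - w + 1):
            if mm_count(rc[j : j + w], consensus) <= maxmm:
                out.add((n - j - w + 1, "-"))
    return out


def oracle_repeats(seq, spacers, consensus="RGKTCA", maxmm=0, strands="both"):
    out = set()
    w = len(consensus)
    n = len(seq)
    strands_seqs = [("+", seq)] + ([("-", reverse_complement(seq))] if strands == "both" else [])
    for strand, s in strands_seqs:
        for sp in spacers:
            width = 2 * w + sp
            for i in range(n - width + 1):
                if (
                    mm_count(s[i : i + w], consensus) <= maxmm
                    and mm_count(s[i + w + sp : i + width], consensus) <= maxmm
                ):
                    start = i if strand == "+" else n - i - width
                    out.add((start - n, strand, sp))
    return out


# --- half sites -------------------------------------------------------------


@pytest.mark.parametrize("seq", ["AGGTCA", "GGTTCA", "AGTTCA", "GGGTCA"])
def test_consensus_expansions_hit(seq):
    hits = find_half_sites(seq)
    plus = [h for h in hits if h[1] == "+"]
    assert len(plus) == 1
    assert plus[0][0] == 1 and plus[0][3] == 0


def test_non_consensus_misses():
    assert all(h[1] != "+" for h in find_half_sites("ACGTCA"))  # C at G/T slot? pos2 must be G
    assert find_half_sites("TTTTTT") == []


def test_minus_strand_reported_at_plus_position():
    seq = "TT" + reverse_complement("AGGTCA") + "TT"
    hits = [h for h in find_half_sites(seq) if h[1] == "-"]
    assert len(hits) == 1
    assert hits[0][0] == 3
    assert hits[0][2] == "AGGTCA"


def test_n_never_matches():
    assert find_half_sites("NGGTCA") == []


def test_invalid_characters_located():
    with pytest.raises(ValueError, match="positions"):
        find_half_sites("AGGXCA")


def test_half_sites_match_oracle(rng):
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        got = {(h[0], h[1]) for h in find_half_sites(seq)}
        assert got == oracle_half_sites(seq)


# --- direct repeats ---------------------------------------------------------


def test_dr2_plus_strand():
    hits = find_direct_repeats("AGGTCAGTAGGTCA", MotifParams(spacers=frozenset({2})))
    assert len(hits) == 1
    h = hits[0]
    assert (h.strand, h.dr_class, h.offset) == ("+", "DR2", -14)
    assert h.half_site_1 == "AGGTCA" and h.half_site_2 == "AGGTCA"


def test_lone_half_site_is_not_a_repeat():
    assert find_direct_repeats("AGGTCA") == []


def test_chained_repeats_yield_every_ordered_pair():
    # three DR0 half-sites in a row: two qualifying ordered pairs
    seq = "AGGTCA" * 3
    hits = find_direct_repeats(seq, MotifParams(spacers=frozenset({0}), strands="forward"))
    assert len(hits) == 2


def test_spacer_set_monotonicity(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    small = find_direct_repeats(seq, MotifParams(spacers=frozenset({2})))
    large = find_direct_repeats(seq, MotifParams(spacers=frozenset({1, 2, 5})))
    small_keys = {(h.offset, h.strand, h.spacer) for h in small}
    large_keys = {(h.offset, h.strand, h.spacer) for h in large}
    assert small_keys <= large_keys


def test_mismatch_budget_monotonicity(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    strict = find_direct_repeats(seq, MotifParams())
    loose = find_direct_repeats(seq, MotifParams(max_mismatches_per_half_site=1))
    strict_keys = {(h.offset, h.strand, h.spacer) for h in strict}
    loose_keys = {(h.offset, h.strand, h.spacer) for h in loose}
    assert strict_keys <= loose_keys


def test_repeats_match_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(200, 1200))
        seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.3, 0.2]))
        got = {(h.offset, h.strand, h.spacer) for h in find_direct_repeats(seq)}
        assert got == oracle_repeats(seq, {1, 2, 5})


def test_strand_symmetry(rng):
    # minus-strand hits of seq = mirrored forward hits of its reverse complement
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    n = len(seq)
    both = find_direct_repeats(seq)
    fwd_rc = find_direct_repeats(
        reverse_complement(seq), MotifParams(strands="forward")
    )
    minus = {(n + h.offset, h.spacer) for h in both if h.strand == "-"}
    mirrored = {(n - (n + h.offset) - h.footprint, h.spacer) for h in fwd_rc}
    assert minus == mirrored


# --- alignment --------------------------------------------------------------


def test_identical_sequences_align_gap_free():
    pair = PromoterPair("a", "b", "ACGTACGT", "ACGTACGT")
    out = align_promoters(pair)
    assert out.aligned_a == out.aligned_b == "ACGTACGT"
    blocks = conserved_blocks(out, window=8, min_identity=1.0)
    assert len(blocks) == 1 and blocks[0].identity == 1.0


def test_single_gap_score():
    from Bio import Align

    pair = PromoterPair("a", "b", "ACGT", "ACT")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    assert aligner.score("ACGT", "ACT") == 3 * 1 + (-5)
    out = align_promoters(pair)
    assert out.aligned_b.count("-") == 1
    assert len(out.aligned_a) == 4


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_promoters(PromoterPair("a", "b", "", "ACGT"))


def test_substitution_only_pair_aligns_without_gaps():
    pair, _ = simulate_promoter_pair(600, [], 0.1, seed=3)
    bare = PromoterPair(pair.species_a, pair.species_b, pair.seq_a, pair.seq_b)
    out = align_promoters(bare)
    assert "-" not in out.aligned_a and "-" not in out.aligned_b
    ident = np.mean([a == b for a, b in zip(out.aligned_a, out.aligned_b)])
    assert ident >= 0.85


# --- conserved blocks -------------------------------------------------------


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_conserved_core_with_divergent_flanks(rng):
    def mutate(seq, rate):
        out = []
        for ch in seq:
            if rng.random() < rate:
                out.append(rng.choice([c for c in "ACGT" if c != ch]))
            else:
                out.append(ch)
        return "".join(out)

    flank1, core, flank2 = _random_seq(rng, 400), _random_seq(rng, 500), _random_seq(rng, 400)
    # flanks diverged well below threshold so no flank window qualifies by
    # chance (identity ~0.5, threshold 0.7, window sd ~0.05)
    a = flank1 + core + flank2
    b = mutate(flank1, 0.5) + mutate(core, 0.05) + mutate(flank2, 0.5)
    pair = PromoterPair("m", "h", a, b, aligned_a=a, aligned_b=b)
    window = 100
    blocks = conserved_blocks(pair, window=window, min_identity=0.7)
    assert len(blocks) == 1
    blk = blocks[0]
    # block covers the core, with at most window-1 columns of slack each side
    assert blk.start_col >= 400 - (window - 1) and blk.start_col <= 401
    assert blk.end_col <= 900 + (window - 1) and blk.end_col >= 900
    assert blk.identity >= 0.7


def test_all_gap_partner_yields_no_blocks():
    pair = PromoterPair("m", "h", "ACGTACGTACGT", "", aligned_a="ACGTACGTACGT",
                        aligned_b="-" * 12)
    assert conserved_blocks(pair, window=4, min_identity=0.5) == []


def test_window_larger_than_alignment_rejected():
    pair = PromoterPair("m", "h", "ACGT", "ACGT", aligned_a="ACGT", aligned_b="ACGT")
    with pytest.raises(ValueError, match="window"):
        conserved_blocks(pair, window=10)


# --- full scan --------------------------------------------------------------


def test_planted_dr2_found_conserved_at_offset():
    pair, _ = simulate_promoter_pair(2500, [(-2177, "+", 2)], 0.05, seed=42)
    report = scan_promoter_pair(pair)
    dr2 = [h for h in report.hits_a if h.dr_class == "DR2" and h.conserved]
    assert len(dr2) == 1
    assert dr2[0].offset == -2177
    assert dr2[0].aligned_partner_offset == -2177  # identity alignment


def test_minus_strand_dr5_at_planted_offset():
    pair, _ = simulate_promoter_pair(1500, [(-700, "-", 5)], 0.0, seed=8)
    report = scan_promoter_pair(pair)
    dr5 = [h for h in report.hits_a if h.dr_class == "DR5"]
    assert any(h.offset == -700 and h.strand == "-" for h in dr5)


def test_high_divergence_destroys_conservation_not_hit():
    planted = [(-900, "+", 2)]
    pair, _ = simulate_promoter_pair(1200, planted, 0.5, seed=13)
    report = scan_promoter_pair(pair)
    hits = [h for h in report.hits_a if h.offset == -900 and h.dr_class == "DR2"]
    assert len(hits) == 1
    assert hits[0].conserved is False


def test_planted_recovery_all_classes_and_strands():
    planted = [(-4500, "+", 1), (-3600, "-", 1), (-2700, "+", 2),
               (-1800, "-", 2), (-1000, "+", 5), (-400, "-", 5)]
    pair, truth = simulate_promoter_pair(5000, planted, 0.0, seed=21)
    report = scan_promoter_pair(pair)
    found = {(h.offset, h.strand, h.spacer) for h in report.hits_a}
    for _, off, strand, sp in truth.planted_motifs:
        assert (off, strand, sp) in found


def test_report_frame_and_bed_consistent():
    pair, _ = simulate_promoter_pair(800, [(-500, "+", 2)], 0.0, seed=2)
    report = scan_promoter_pair(pair)
    df = report.to_frame()
    bed = report.to_bed()
    assert len(df) == len(bed) == len(report.hits)
    row = df[df["offset"] == -500].iloc[0]
    assert row["dr_class"] == "DR2" and bool(row["conserved"])
    brow = bed.iloc[df.index[df["offset"] == -500][0]]
    assert brow["end"] - brow["start"] == 14


def test_fasta_round_trip(tmp_path):
    pair, _ = simulate_promoter_pair(300, [(-200, "+", 2)], 0.1, seed=5)
    path = tmp_path / "pair.fasta"
    write_promoter_pair(pair, str(path), aligned=False)
    back = read_promoter_pair(str(path))
    assert back.seq_a == pair.seq_a and back.seq_b == pair.seq_b
    assert not back.aligned  # plain FASTA carries no alignment


def test_gapped_fasta_parsed_as_alignment():
    text = ">m\nACG-TACGT\n>h\nACGTTA-GT\n"
    back = read_promoter_pair(io.StringIO(text))
    assert back.aligned
    assert back.seq_a == "ACGTACGT"
    assert back.aligned_b == "ACGTTA-GT"
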