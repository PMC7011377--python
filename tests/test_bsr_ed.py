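"""ED⁵ bulked-segregant statistic: depth screen, ED arithmetic, top-1%
threshold and region calling, each against an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from digenic_mapper.bsr_ed import (
    CandidateRegion,
    call_regions,
    ed_statistic,
    run_bsr,
    screen_differential,
    significance_threshold,
)


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "ref_count_G", "alt_count_G", "ref_count_Y", "alt_count_Y",
        ],
    )


def test_depth_screen_requires_min_depth_in_each_pool():
    table = _table(
        [
            ("A01", 100, "A", "G", 5, 5, 5, 5),  # kept: 10x / 10x
            ("A01", 200, "A", "G", 2, 1, 25, 25),  # dropped: G-pool 3x
            ("A01", 300, "A", "G", 2, 2, 2, 1),  # dropped: Y-pool 3x
            ("A01", 400, "A", "G", 2, 2, 2, 2),  # kept: exactly 4x
        ]
    )
    kept = screen_differential(table)
    assert list(kept["pos"]) == [100, 400]
    assert screen_differential(_table([])).empty


@pytest.mark.parametrize(
    "counts_g, counts_y, ed, ed5",
    [
        ((5, 5), (5, 5), 0.0, 0.0),  # equal frequencies
        ((10, 0), (0, 10), math.sqrt(2), 2 ** 2.5),  # fixed opposite alleles
        ((8, 7), (0, 10), math.sqrt(2) * 8 / 15, (math.sqrt(2) * 8 / 15) ** 5),
    ],
)
def test_ed_closed_forms(counts_g, counts_y, ed, ed5):
    """Includes the expected causal-locus configuration: G-pool 7/15,
    Y-pool fixed, giving ED = sqrt(2)*8/15."""
    table = _table([("A09", 1, "A", "G", *counts_g, *counts_y)])
    rec = ed_statistic(table).iloc[0]
    assert rec["ed"] == pytest.approx(ed, abs=1e-12)
    assert rec["ed5"] == pytest.approx(ed5, abs=1e-12)


def test_ed_rejects_zero_depth():
    with pytest.raises(ValueError, match="screen"):
        ed_statistic(_table([("A01", 1, "A", "G", 0, 0, 5, 5)]))


@given(
    fg=st.integers(0, 40),
    fy=st.integers(0, 40),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_ed_matches_two_coordinate_euclidean_oracle(fg, fy):
    """ED equals the brute-force Euclidean distance between the two pools'
    (f, 1-f) allele-frequency vectors, and is symmetric in the pools and
    under ref/alt relabelling."""
    depth = 40
    table = _table([("A01", 1, "A", "G", depth - fg, fg, depth - fy, fy)])
    rec = ed_statistic(table).iloc[0]
    pg, py = fg / depth, fy / depth
    oracle = math.dist((pg, 1 - pg), (py, 1 - py))
    assert rec["ed"] == pytest.approx(oracle, abs=1e-12)
    swapped_pools = _table([("A01", 1, "A", "G", depth - fy, fy, depth - fg, fg)])
    assert ed_statistic(swapped_pools).iloc[0]["ed"] == pytest.approx(rec["ed"])
    swapped_alleles = _table([("A01", 1, "G", "A", fg, depth - fg, fy, depth - fy)])
    assert ed_statistic(swapped_alleles).iloc[0]["ed"] == pytest.approx(rec["ed"])


def test_ed5_monotone_in_frequency_difference():
    diffs = np.linspace(0, 1, 21)
    depth = 100
    table = _table(
        [
            ("A01", i + 1, "A", "G", depth, 0, depth - int(d * depth), int(d * depth))
            for i, d in enumerate(diffs)
        ]
    )
    ed5 = ed_statistic(table)["ed5"].to_numpy()
    assert (np.diff(ed5) > 0).all()


def test_top_fraction_threshold_against_sort_oracle(rng):
    values = rng.permutation(np.linspace(0.001, 5.0, 1000))
    threshold, flags = significance_threshold(values, 0.01)
    assert flags.sum() == 10
    # oracle: the 10 largest values by full sort
    assert set(values[flags]) == set(np.sort(values)[-10:])
    assert threshold == np.sort(values)[-10]


def test_threshold_tie_and_degenerate_rules():
    _, flags = significance_threshold(np.full(50, 2.5), 0.01)
    assert flags.all()  # all tied at the threshold -> all flagged
    threshold, flags = significance_threshold(np.array([1.3]), 0.01)
    assert flags.tolist() == [True] and threshold == 1.3
    with pytest.raises(ValueError):
        significance_threshold(np.array([1.0]), 0.0)
    with pytest.raises(ValueError):
        significance_threshold(np.array([]), 0.01)


def _bruteforce_regions(loci, max_gap, min_loci):
    """Quadratic clustering oracle."""
    out = []
    for chrom in dict.fromkeys(c for c, _ in loci):
        pos = sorted(p for c, p in loci if c == chrom)
        cluster = [pos[0]]
        for a, b in zip(pos, pos[1:]):
            if b - a <= max_gap:
                cluster.append(b)
            else:
                if len(cluster) >= min_loci:
                    out.append((chrom, cluster[0], cluster[-1], len(cluster)))
                cluster = [b]
        if len(cluster) >= min_loci:
            out.append((chrom, cluster[0], cluster[-1], len(cluster)))
    return out


def test_region_calling_table_geometry():
    """A run of 19 close loci produces one region whose length is the
    span of its first and last member (1,626,909 bp here)."""
    positions = np.linspace(9_207_067, 10_833_976, 19).round().astype(int)
    positions[0], positions[-1] = 9_207_067, 10_833_976
    flagged = pd.DataFrame({"chrom": "A07", "pos": positions})
    regions = call_regions(flagged, max_gap_bp=2_000_000, min_loci=2)
    assert len(regions) == 1
    row = regions.iloc[0]
    assert (row["start"], row["end"], row["n_loci"]) == (9_207_067, 10_833_976, 19)
    assert row["length"] == 1_626_909


def test_isolated_locus_is_not_a_region():
    flagged = pd.DataFrame({"chrom": ["A01"], "pos": [500]})
    assert call_regions(flagged, 1000, min_loci=2).empty


@given(st.data())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_region_calling_against_bruteforce_oracle(data):
    n = data.draw(st.integers(1, 60))
    chroms = data.draw(
        st.lists(st.sampled_from(["A01", "A02", "A03"]), min_size=n, max_size=n)
    )
    pos = data.draw(
        st.lists(st.integers(1, 10_000_000), min_size=n, max_size=n, unique=True)
    )
    max_gap = data.draw(st.integers(1, 3_000_000))
    loci = sorted(zip(chroms, pos))
    flagged = pd.DataFrame(loci, columns=["chrom", "pos"])
    got = call_regions(flagged, max_gap, min_loci=2)
    want = _bruteforce_regions(loci, max_gap, 2)
    assert sorted(map(tuple, got[["chrom", "start", "end", "n_loci"]].values)) == sorted(want)


def test_merging_under_larger_gap_grows_regions():
    flagged = pd.DataFrame(
        {"chrom": "A01", "pos": [100, 200, 5_000_000, 5_000_100]}
    )
    two = call_regions(flagged, max_gap_bp=1_000, min_loci=2)
    one = call_regions(flagged, max_gap_bp=10_000_000, min_loci=2)
    assert len(two) == 2 and len(one) == 1
    assert one.iloc[0]["length"] >= two["length"].max()


def test_candidate_region_validation():
    with pytest.raises(ValueError):
        CandidateRegion("A01", 10, 5, 2)
    with pytest.raises(ValueError):
        CandidateRegion("A01", 1, 5, 0)


def test_null_calibration_flags_top_fraction_and_rarely_forms_regions(rng):
    """With both pools drawn from identical frequencies the flagged
    fraction equals the top-1% rule exactly, flagged loci scatter across
    chromosomes, and no signal-like cluster appears."""
    n_per_chrom, depth = 100, 30
    rows = []
    for c in range(10):
        pos = np.arange(n_per_chrom) * 300_000 + 150_000
        for x in pos:
            fg = rng.binomial(depth, 0.5)
            fy = rng.binomial(depth, 0.5)
            rows.append((f"A{c + 1:02d}", int(x), "A", "G", depth - fg, fg, depth - fy, fy))
    track, regions, threshold = run_bsr(_table(rows))
    # ceil(0.01 * 1000) = 10 flagged, plus any ties at the threshold
    assert int(track["significant"].sum()) >= 10
    assert int((track["ed5"] > threshold).sum()) < 10
    assert track.loc[track["significant"], "chrom"].nunique() >= 3
    # null regions are small accidents, never signal-like clusters
    if not regions.empty:
        assert regions["n_loci"].max() <= 3
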