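"""Concordance and interval-overlap tests against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from isletepi import (
    IntervalTrack,
    concordant_sites,
    multi_track_membership,
    overlap_sites_track,
    sites_in_gene_windows,
)


def _ewas_like(probe_ids, qs, coefs):
    return pd.DataFrame(
        {"probe_id": probe_ids, "q_value": qs, "coefficient_m": coefs}
    )


# ---------------------------------------------------------------- concordance

def test_concordant_site_same_sign_included():
    a = _ewas_like(["s1"], [0.01], [0.2])
    b = _ewas_like(["s1"], [0.01], [0.5])
    res = concordant_sites(a, b, 0.05)
    assert res.both == ["s1"]
    assert res.quadrant_counts == {"up_up": 1, "down_down": 0}


def test_discordant_sign_excluded_and_listed():
    a = _ewas_like(["s1"], [0.01], [0.2])
    b = _ewas_like(["s1"], [0.01], [-0.5])
    res = concordant_sites(a, b, 0.05)
    assert res.both == []
    assert res.discordant == ["s1"]


def test_concordance_hand_enumeration():
    """Eight-site toy universe with hand-assigned q values and signs."""
    ids = [f"s{i}" for i in range(8)]
    qa = [0.01, 0.01, 0.01, 0.20, 0.01, 0.20, 0.20, 0.01]
    qb = [0.01, 0.01, 0.20, 0.01, 0.01, 0.20, 0.01, 0.20]
    ca = [+1.0, -1.0, +1.0, +1.0, +1.0, -1.0, +1.0, -1.0]
    cb = [+1.0, -1.0, +1.0, +1.0, -1.0, -1.0, +1.0, -1.0]
    res = concordant_sites(_ewas_like(ids, qa, ca), _ewas_like(ids, qb, cb), 0.05)
    # by hand: s0 up/up, s1 down/down, s4 doubly significant but discordant,
    # s2 and s7 A-only, s3 and s6 B-only, s5 neither
    assert sorted(res.both) == ["s0", "s1"]
    assert res.discordant == ["s4"]
    assert sorted(res.a_only) == ["s2", "s7"]
    assert sorted(res.b_only) == ["s3", "s6"]
    assert res.quadrant_counts == {"up_up": 1, "down_down": 1}


def test_concordance_monotone_in_threshold():
    rng = np.random.default_rng(0)
    ids = [f"s{i}" for i in range(200)]
    a = _ewas_like(ids, rng.random(200), rng.normal(size=200))
    b = _ewas_like(ids, rng.random(200), rng.normal(size=200))
    sizes = [
        len(concordant_sites(a, b, thr).both) for thr in (0.5, 0.2, 0.05, 0.01)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_concordance_rejects_disjoint_universes():
    a = _ewas_like(["s1"], [0.01], [0.2])
    b = _ewas_like(["s2"], [0.01], [0.2])
    with pytest.raises(ValueError):
        concordant_sites(a, b, 0.05)


# ---------------------------------------------------------------- overlap

def _track(features, name="t"):
    return IntervalTrack(
        name,
        pd.DataFrame(features, columns=["chromosome", "start", "end", "label"]),
    )


def _sites(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "pos0"])


def test_overlap_half_open_boundaries():
    track = _track([("chr1", 100, 200, None)])
    sites = _sites([("a", "chr1", 100), ("b", "chr1", 199), ("c", "chr1", 200),
                    ("d", "chr1", 99), ("e", "chr2", 150)])
    flags, count = overlap_sites_track(sites, track)
    assert list(flags) == [True, True, False, False, False]
    assert count == 2


def test_overlap_matches_brute_force(rng):
    sites = _sites(
        [(f"s{i}", rng.choice(["chr1", "chr2"]), int(rng.integers(0, 5000)))
         for i in range(1000)]
    )
    starts = rng.integers(0, 4900, 50)
    track = _track(
        [(str(rng.choice(["chr1", "chr2"])), int(s), int(s + rng.integers(1, 300)), None)
         for s in starts]
    )
    flags, _ = overlap_sites_track(sites, track)
    for i, row in sites.iterrows():
        expected = any(
            f.chromosome == row["chromosome"] and f.start <= row["pos0"] < f.end
            for f in track.features.itertuples(index=False)
        )
        assert flags[i] == expected


def test_overlap_invariant_to_order_and_splitting(rng):
    sites = _sites([(f"s{i}", "chr1", int(rng.integers(0, 1000))) for i in range(200)])
    track = _track([("chr1", 100, 400, None), ("chr1", 600, 900, None)])
    shuffled = _track([("chr1", 600, 900, None), ("chr1", 100, 400, None)])
    split = _track([("chr1", 100, 250, None), ("chr1", 250, 400, None),
                    ("chr1", 600, 900, None)])
    base, _ = overlap_sites_track(sites, track)
    assert list(base) == list(overlap_sites_track(sites, shuffled)[0])
    assert list(base) == list(overlap_sites_track(sites, split)[0])


# ---------------------------------------------------------------- gene windows

def test_gene_window_boundaries():
    genes = pd.DataFrame(
        {"gene_id": ["g"], "chromosome": ["chr1"], "start": [50_000],
         "end": [60_000], "strand": ["+"]}
    )
    sites = _sites([("in", "chr1", 40_000), ("out", "chr1", 70_000),
                    ("last", "chr1", 69_999)])
    mapping, counts = sites_in_gene_windows(sites, genes, flank=10_000)
    assert set(mapping["probe_id"]) == {"in", "last"}
    assert counts["g"] == 2


def test_gene_window_negative_flank_errors():
    genes = pd.DataFrame(
        {"gene_id": ["g"], "chromosome": ["chr1"], "start": [0], "end": [10],
         "strand": ["+"]}
    )
    with pytest.raises(ValueError):
        sites_in_gene_windows(_sites([("a", "chr1", 5)]), genes, flank=-1)


def test_gene_window_matches_brute_force(rng):
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(30)],
            "chromosome": rng.choice(["chr1", "chr2"], 30),
            "start": rng.integers(0, 80_000, 30),
            "strand": rng.choice(["+", "-"], 30),
        }
    )
    genes["end"] = genes["start"] + rng.integers(1_000, 20_000, 30)
    sites = _sites(
        [(f"s{i}", rng.choice(["chr1", "chr2"]), int(rng.integers(0, 100_000)))
         for i in range(300)]
    )
    mapping, _ = sites_in_gene_windows(sites, genes, flank=10_000)
    got = set(map(tuple, mapping.to_numpy()))
    expected = set()
    for s in sites.itertuples(index=False):
        for g in genes.itertuples(index=False):
            lo = max(g.start - 10_000, 0)
            hi = g.end + 10_000
            if g.chromosome == s.chromosome and lo <= s.pos0 < hi:
                expected.add((s.probe_id, g.gene_id))
    assert got == expected


def test_gene_window_tss_anchor_strand_aware():
    genes = pd.DataFrame(
        {"gene_id": ["plus", "minus"], "chromosome": ["chr1", "chr1"],
         "start": [50_000, 50_000], "end": [60_000, 60_000],
         "strand": ["+", "-"]}
    )
    # TSS of "plus" is 50,000; of "minus" is 59,999
    sites = _sites([("near_plus_tss", "chr1", 41_000),
                    ("near_minus_tss", "chr1", 69_000)])
    mapping, _ = sites_in_gene_windows(sites, genes, flank=10_000, anchor="tss")
    got = set(map(tuple, mapping.to_numpy()))
    assert ("near_plus_tss", "plus") in got
    assert ("near_plus_tss", "minus") not in got
    assert ("near_minus_tss", "minus") in got


# ---------------------------------------------------------------- multi-track

def test_multi_track_saturation_and_empty():
    sites = _sites([(f"s{i}", "chr1", 10 + i) for i in range(5)])
    full = [_track([("chr1", 0, 1000, None)], name=f"TF{k}") for k in range(5)]
    member, tally, venn = multi_track_membership(sites, full)
    assert (member["cardinality"] == 5).all()
    assert tally[5] == 5 and tally[0] == 0
    assert venn[frozenset(f"TF{k}" for k in range(5))] == 5

    empty = [_track([], name=f"TF{k}") for k in range(3)]
    member2, tally2, _ = multi_track_membership(sites, empty)
    assert (member2["cardinality"] == 0).all()
    assert tally2[0] == 5


def test_multi_track_rejects_duplicate_names():
    t = _track([("chr1", 0, 10, None)], name="A")
    with pytest.raises(ValueError):
        multi_track_membership(_sites([("s", "chr1", 5)]), [t, t])


def test_multi_track_venn_matches_brute_force(rng):
    sites = _sites([(f"s{i}", "chr1", int(rng.integers(0, 2000))) for i in range(200)])
    tracks = []
    for k in range(5):
        starts = rng.integers(0, 1900, 8)
        tracks.append(
            _track([("chr1", int(s), int(s + rng.integers(1, 200)), None)
                    for s in starts], name=f"TF{k}")
        )
    _, _, venn = multi_track_membership(sites, tracks)
    brute = {}
    for s in sites.itertuples(index=False):
        cell = frozenset(
            t.name for t in tracks
            if any(f.start <= s.pos0 < f.end
                   for f in t.features.itertuples(index=False))
        )
        brute[cell] = brute.get(cell, 0) + 1
    assert venn == brute


def test_enrichment_of_planted_sites_in_tracks(small_cohort):
    """Tracks planted over true sites are enriched among significant sites."""
    from isletepi import run_ewas, simulate_annotation_tracks

    cfg, (mat, samples, manifest, _, truth) = small_cohort
    tracks = simulate_annotation_tracks(manifest, cfg, truth)
    ocr = next(t for t in tracks if t.name == "OCR")
    res = run_ewas(mat, samples, "binary")
    tab = res.table.set_index("probe_id")
    man = manifest.set_index("probe_id").loc[tab.index].reset_index()
    sites = man[["probe_id", "chromosome", "pos0"]]
    flags, _ = overlap_sites_track(sites, ocr)
    sig = (tab["q_value"] < 0.05).to_numpy()
    rate_sig = flags.to_numpy()[sig].mean()
    rate_null = flags.to_numpy()[~sig].mean()
    assert rate_sig > rate_null
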