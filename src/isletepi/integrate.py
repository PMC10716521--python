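"""Cross-phenotype concordance and genomic integration of EWAS hits.

CpG sites are treated as 1-bp points (the interrogated cytosine) and all
interval work is 0-based half-open and strand-blind: a site at position p
lies inside a feature [s, e) iff s <= p < e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .arrayio import IntervalTrack


@dataclass
class ConcordanceResult:
    """Intersection of two EWAS scans with sign-concordance bookkeeping.

    ``both`` holds sites significant in both scans with agreeing effect
    sign; doubly-significant sites with opposite signs are reported in
    ``discordant`` and excluded from ``both``.
    """

    a_only: list
    b_only: list
    both: list
    discordant: list
    quadrant_counts: dict     # {"up_up": int, "down_down": int}
    q_threshold: float

    @property
    def n_both(self) -> int:
        return len(self.both)


def concordant_sites(ewas_a, ewas_b, q_threshold: float = 0.05) -> ConcordanceResult:
    """Intersect two EWAS tables at a q threshold with sign concordance.

    Both tables must cover the same probe universe.  A site enters
    ``both`` iff q < threshold in each table and the phenotype
    coefficients share a sign; quadrant counts split ``both`` into
    up/up and down/down.
    """
    ta = ewas_a.table if hasattr(ewas_a, "table") else ewas_a
    tb = ewas_b.table if hasattr(ewas_b, "table") else ewas_b
    a = ta.set_index("probe_id")
    b = tb.set_index("probe_id")
    if set(a.index) != set(b.index):
        raise ValueError("EWAS tables cover different probe universes")
    b = b.loc[a.index]

    sig_a = (a["q_value"] < q_threshold).fillna(False).to_numpy()
    sig_b = (b["q_value"] < q_threshold).fillna(False).to_numpy()
    sign_a = np.sign(a["coefficient_m"].to_numpy())
    sign_b = np.sign(b["coefficient_m"].to_numpy())

    ids = a.index.to_numpy()
    both_mask = sig_a & sig_b & (sign_a == sign_b) & (sign_a != 0)
    disc_mask = sig_a & sig_b & ~both_mask
    a_only = ids[sig_a & ~sig_b].tolist()
    b_only = ids[sig_b & ~sig_a].tolist()
    both = ids[both_mask].tolist()
    discordant = ids[disc_mask].tolist()
    quadrants = {
        "up_up": int((both_mask & (sign_a > 0)).sum()),
        "down_down": int((both_mask & (sign_a < 0)).sum()),
    }
    return ConcordanceResult(
        a_only=a_only,
        b_only=b_only,
        both=both,
        discordant=discordant,
        quadrant_counts=quadrants,
        q_threshold=q_threshold,
    )


def _trees_by_chrom(features: pd.DataFrame) -> dict:
    trees = {}
    for row in features.itertuples(index=False):
        trees.setdefault(row.chromosome, IntervalTree()).addi(
            int(row.start), int(row.end), row.label
        )
    return trees


def _require_site_columns(sites: pd.DataFrame) -> pd.DataFrame:
    need = {"probe_id", "chromosome", "pos0"}
    missing = need - set(sites.columns)
    if missing:
        raise ValueError(f"site table lacks column(s) {sorted(missing)}")
    return sites


def overlap_sites_track(sites: pd.DataFrame, track: IntervalTrack):
    """Flag sites inside a track's features.

    Parameters
    ----------
    sites
        Table with probe_id, chromosome, pos0 (0-based position).
    track
        Interval features, 0-based half-open.

    Returns
    -------
    (membership, count)
        Boolean Series aligned to ``sites`` rows and the number of member
        sites.
    """
    sites = _require_site_columns(sites)
    trees = _trees_by_chrom(track.features)
    member = np.zeros(len(sites), dtype=bool)
    for i, row in enumerate(sites.itertuples(index=False)):
        tree = trees.get(row.chromosome)
        if tree is not None and tree.overlaps_point(int(row.pos0)):
            member[i] = True
    flags = pd.Series(member, index=sites.index, name=track.name)
    return flags, int(member.sum())


def site_regulome_states(sites: pd.DataFrame, regulome: IntervalTrack) -> pd.Series:
    """Per-site sorted list of chromatin-state labels covering the site."""
    sites = _require_site_columns(sites)
    trees = _trees_by_chrom(regulome.features)
    states = []
    for row in sites.itertuples(index=False):
        tree = trees.get(row.chromosome)
        hits = tree[int(row.pos0)] if tree is not None else set()
        states.append(sorted({h.data for h in hits if h.data is not None}))
    return pd.Series(states, index=sites.index, name="regulome_states")


def sites_in_gene_windows(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 10_000,
    anchor: str = "body",
):
    """Map sites to genes whose +-flank window contains them.

    A site at 0-based position p maps to gene g iff
    max(0, anchor_start - flank) <= p < anchor_end + flank, where the
    anchor is the gene body [start, end) by default, or the 1-bp TSS when
    ``anchor="tss"`` (strand-aware: end for '-' genes).

    Returns
    -------
    (mapping, per_gene_counts)
        mapping: DataFrame with probe_id/gene_id rows (many-to-many);
        per_gene_counts: Series of distinct-site counts per gene.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if anchor not in ("body", "tss"):
        raise ValueError("anchor must be 'body' or 'tss'")
    sites = _require_site_columns(sites)
    feats = genes.copy()
    if anchor == "tss":
        strand = feats["strand"] if "strand" in feats else pd.Series("+", index=feats.index)
        tss = np.where(strand == "-", feats["end"] - 1, feats["start"])
        feats["start"], feats["end"] = tss, tss + 1
    feats["wstart"] = np.maximum(feats["start"] - flank, 0)
    feats["wend"] = feats["end"] + flank

    trees = {}
    for row in feats.itertuples(index=False):
        trees.setdefault(row.chromosome, IntervalTree()).addi(
            int(row.wstart), int(row.wend), row.gene_id
        )
    pairs = []
    for row in sites.itertuples(index=False):
        tree = trees.get(row.chromosome)
        if tree is None:
            continue
        for hit in tree[int(row.pos0)]:
            pairs.append((row.probe_id, hit.data))
    mapping = pd.DataFrame(pairs, columns=["probe_id", "gene_id"])
    counts = mapping.groupby("gene_id")["probe_id"].nunique()
    counts = counts.reindex(genes["gene_id"], fill_value=0)
    return mapping, counts


def multi_track_membership(sites: pd.DataFrame, tf_tracks):
    """Per-site membership across several (e.g. TF-binding) tracks.

    Returns
    -------
    (membership, cardinality_tally, venn)
        membership: DataFrame with one boolean column per track plus a
        ``cardinality`` column; cardinality_tally: Series counting sites
        by membership cardinality 0..n; venn: dict mapping frozenset of
        track names (the exact Venn cell) to site count, empty cell
        frozenset() included.
    """
    names = [t.name for t in tf_tracks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate track names")
    if not tf_tracks:
        raise ValueError("at least one track required")
    sites = _require_site_columns(sites)
    member = pd.DataFrame(index=sites.index)
    for track in tf_tracks:
        flags, _ = overlap_sites_track(sites, track)
        member[track.name] = flags
    card = member[names].sum(axis=1).astype(int)
    member["cardinality"] = card
    tally = card.value_counts().reindex(range(len(names) + 1), fill_value=0)
    venn = {}
    for _, row in member.iterrows():
        cell = frozenset(n for n in names if row[n])
        venn[cell] = venn.get(cell, 0) + 1
    return member, tally, venn


def annotate_sites(
    sites: pd.DataFrame,
    ocr: IntervalTrack | None = None,
    tf_tracks=(),
    regulome: IntervalTrack | None = None,
    genes: pd.DataFrame | None = None,
    flank: int = 10_000,
) -> pd.DataFrame:
    """One-stop annotation: OCR flag, TF subset, regulome states, genes."""
    sites = _require_site_columns(sites).reset_index(drop=True)
    out = sites[["probe_id", "chromosome", "pos0"]].copy()
    if ocr is not None:
        flags, _ = overlap_sites_track(out, ocr)
        out["in_ocr"] = flags
    if tf_tracks:
        member, _, _ = multi_track_membership(out, tf_tracks)
        names = [t.name for t in tf_tracks]
        out["tf_set"] = [
            ",".join(n for n in names if row[n]) for _, row in member.iterrows()
        ]
        out["tf_count"] = member["cardinality"].to_numpy()
    if regulome is not None:
        out["regulome_states"] = [
            ",".join(s) for s in site_regulome_states(out, regulome)
        ]
    if genes is not None:
        mapping, _ = sites_in_gene_windows(out, genes, flank=flank)
        per_site = mapping.groupby("probe_id")["gene_id"].apply(
            lambda g: ",".join(sorted(g))
        )
        out["genes_within_window"] = (
            out["probe_id"].map(per_site).fillna("")
        )
    return out
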