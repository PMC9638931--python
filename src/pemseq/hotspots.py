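"""Hotspot calling, normalization and clonal-expansion statistics.

Samples are first normalized to the same number of editing events (seeded
uniform subsampling without replacement to the smallest sample), so junction
counts are comparable across libraries of different depth. Translocation
hotspots are then called on a per-nucleotide junction-count track with
bdgpeakcall threshold semantics: maximal runs of consecutive positions whose
count reaches the cutoff (default 5), of length at least the minimum
(default 1 bp). Calling is a fixed-count threshold, not a statistical test,
and the track is built from deduplicated molecules binned at 1 bp with
strands pooled; orientation is annotated on the call, not a calling
dimension.

Expansion statistics quantify the clonality signature: copies per junction
site, barcode diversity, and strand-orientation uniformity (a clonally
expanded site carries every junction at the same nucleotide in the same
orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import GeneModel, ReferenceBundle

__all__ = [
    "HotspotParams",
    "NormalizedCohort",
    "normalize_to_editing_events",
    "junction_track",
    "call_hotspots",
    "annotate_hotspot_genes",
    "hotspots_from_molecules",
    "expansion_stats",
    "shared_sites",
    "viral_profile",
    "category_proportions",
]


@dataclass(frozen=True)
class HotspotParams:
    cutoff: int = 5        # bdgpeakcall -c
    min_length: int = 1    # bdgpeakcall -l
    bin: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.min_length < 1 or self.bin < 1:
            raise ValueError("cutoff > 0, min_length >= 1 and bin >= 1 required")


@dataclass
class NormalizedCohort:
    samples: list[pd.DataFrame]
    target_event_count: int
    seed: int


def normalize_to_editing_events(
    samples: list[pd.DataFrame], seed: int = 0
) -> NormalizedCohort:
    """Subsample every sample's editing events to the smallest sample.

    Input tables must carry an ``event_class`` column; perfect events are
    excluded before normalization (the paper's junction counts are quoted
    per editing event). Subsampling is uniform without replacement and
    seeded per sample, so translocation counts scale hypergeometrically.
    """
    if not samples:
        raise ValueError("need at least one sample")
    editing = [s[s["event_class"] != "perfect"] for s in samples]
    if any(len(e) == 0 for e in editing):
        raise ValueError("all samples must contain editing events")
    target = min(len(e) for e in editing)
    out = []
    for i, e in enumerate(editing):
        if len(e) == target:
            out.append(e.reset_index(drop=True))
            continue
        rng = np.random.default_rng([seed, i])
        idx = np.sort(rng.choice(len(e), size=target, replace=False))
        out.append(e.iloc[idx].reset_index(drop=True))
    return NormalizedCohort(samples=out, target_event_count=target, seed=seed)


def junction_track(
    molecules: pd.DataFrame, *, bin: int = 1
) -> pd.DataFrame:
    """Per-position junction counts (strand-pooled): columns ref, pos, count.

    ``pos`` is the bin start (prey position floored to the bin width)."""
    if molecules.empty:
        return pd.DataFrame(columns=["ref", "pos", "count"])
    pos = (molecules["prey_pos"] // bin) * bin
    tr = (
        molecules.assign(pos=pos)
        .groupby(["prey_ref", "pos"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"prey_ref": "ref"})
        .sort_values(["ref", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return tr


def call_hotspots(track: pd.DataFrame, params: HotspotParams = HotspotParams()) -> pd.DataFrame:
    """bdgpeakcall-style threshold peaks on a sparse count track.

    Emits maximal runs of consecutive bins with count >= cutoff whose length
    reaches min_length, with the summed junction count. Positions absent
    from the track count zero and break runs.
    """
    calls = []
    if not track.empty:
        above = track[track["count"] >= params.cutoff]
        for ref, sub in above.groupby("ref", observed=True, sort=True):
            pos = sub["pos"].to_numpy()
            cnt = sub["count"].to_numpy()
            if len(pos) == 0:
                continue
            breaks = np.flatnonzero(np.diff(pos) != params.bin)
            starts = np.r_[0, breaks + 1]
            ends = np.r_[breaks, len(pos) - 1]
            for s, e in zip(starts, ends):
                length = pos[e] + params.bin - pos[s]
                if length >= params.min_length:
                    calls.append((ref, int(pos[s]), int(pos[e] + params.bin),
                                  int(cnt[s : e + 1].sum())))
    return pd.DataFrame(calls, columns=["ref", "start", "end", "normalized_junctions"])


def annotate_hotspot_genes(calls: pd.DataFrame, genes: GeneModel) -> pd.DataFrame:
    """Flag calls intersecting any gene body; adds in_gene and gene columns."""
    out = calls.copy()
    in_gene, names = [], []
    for row in out.itertuples(index=False):
        hits = genes.overlapping_genes(row.ref, row.start, row.end)
        in_gene.append(bool(hits))
        names.append(",".join(hits))
    out["in_gene"] = in_gene
    out["gene"] = names
    return out


def hotspots_from_molecules(
    molecules: pd.DataFrame,
    params: HotspotParams = HotspotParams(),
    genes: GeneModel | None = None,
) -> pd.DataFrame:
    """Call hotspots from a molecule table and annotate orientation fractions
    (and genes, when a model is given)."""
    track = junction_track(molecules, bin=params.bin)
    calls = call_hotspots(track, params)
    plus_frac = []
    for row in calls.itertuples(index=False):
        sub = molecules[
            (molecules["prey_ref"] == row.ref)
            & (molecules["prey_pos"] >= row.start)
            & (molecules["prey_pos"] < row.end)
        ]
        n_plus = int((sub["prey_strand"] == "+").sum())
        plus_frac.append(n_plus / len(sub) if len(sub) else 0.0)
    calls["plus_fraction"] = plus_frac
    calls["orientation_uniformity"] = [max(p, 1 - p) for p in plus_frac]
    if genes is not None:
        calls = annotate_hotspot_genes(calls, genes)
    return calls


def expansion_stats(molecules: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-junction-site clonality records and a cohort summary.

    Sites are prey positions at 1-bp resolution, strand-pooled for grouping;
    orientation_uniformity is max(plus, minus)/total at the site. The
    summary reports junctions per site (mean copies) — the quantity whose
    cross-cohort fold change indicates expansion.
    """
    if molecules.empty:
        return (
            pd.DataFrame(columns=["ref", "pos", "copies", "n_distinct_rmbs",
                                  "plus_fraction", "orientation_uniformity"]),
            {"n_sites": 0, "mean_copies_per_site": 0.0},
        )
    g = molecules.groupby(["prey_ref", "prey_pos"], observed=True, sort=True)
    out = g.agg(
        copies=("rmb", "size"),
        n_distinct_rmbs=("rmb", "nunique"),
        plus_count=("prey_strand", lambda s: int((s == "+").sum())),
    ).reset_index().rename(columns={"prey_ref": "ref", "prey_pos": "pos"})
    out["plus_fraction"] = out["plus_count"] / out["copies"]
    out["orientation_uniformity"] = np.maximum(out["plus_fraction"],
                                               1 - out["plus_fraction"])
    out = out.drop(columns="plus_count")
    summary = {
        "n_sites": int(len(out)),
        "mean_copies_per_site": float(out["copies"].mean()),
    }
    return out, summary


def expansion_fold_change(summary_a: dict, summary_b: dict) -> float:
    """Fold change of mean junctions per site between two cohorts (b over a)."""
    if summary_a["mean_copies_per_site"] == 0:
        raise ValueError("reference cohort has no sites")
    return summary_b["mean_copies_per_site"] / summary_a["mean_copies_per_site"]


def shared_sites(
    site_lists: list[pd.DataFrame | list[tuple]], *, bin: int = 1
) -> tuple[int, int, float]:
    """Cross-sample site sharing.

    Each element is a sample's site list — (ref, pos) tuples or a DataFrame
    with ref/pos (or prey_ref/prey_pos) columns. Sites are pooled at ``bin``
    resolution; a site present in >= 2 samples is shared. Returns
    (n_total_distinct, n_shared, percentage).
    """
    if len(site_lists) < 2:
        raise ValueError("site sharing requires at least two samples")
    per_sample: list[set] = []
    for s in site_lists:
        if isinstance(s, pd.DataFrame):
            cols = s.columns
            ref_c = "ref" if "ref" in cols else "prey_ref"
            pos_c = "pos" if "pos" in cols else "prey_pos"
            pairs = zip(s[ref_c], s[pos_c])
        else:
            pairs = iter(s)
        per_sample.append({(r, int(p) // bin * bin) for r, p in pairs})
    from collections import Counter

    counter = Counter()
    for sites in per_sample:
        counter.update(sites)
    total = len(counter)
    shared = sum(1 for v in counter.values() if v >= 2)
    pct = 100.0 * shared / total if total else 0.0
    return total, shared, pct


def viral_profile(
    molecules: pd.DataFrame, ref: ReferenceBundle
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Junction distribution over the vector genome.

    Returns (per-position counts, per-element totals, per-unique-junction
    proportion table). Junction extraction reports alignments lying wholly
    inside an LTR under the canonical 5' copy, so positions in the 5'LTR are
    flagged ``ambiguous_ltr`` here (counts under the 3' copy would mirror
    them exactly); a position still inside the 3'LTR was disambiguated by
    sequence extending beyond the repeat.
    """
    elements = {el: 0 for el in ("5LTR", "payload", "3LTR")}
    if molecules.empty:
        track = pd.DataFrame(columns=["pos", "strand", "count", "ambiguous_ltr"])
        props = pd.DataFrame(columns=["pos", "strand", "count", "fraction",
                                      "ambiguous_ltr"])
        return track, elements, props
    s5, e5 = ref.elements["5LTR"]
    track = (
        molecules.rename(columns={"prey_pos": "pos"})
        .groupby(["pos", "prey_strand"], observed=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"prey_strand": "strand"})
        .sort_values(["pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    track["ambiguous_ltr"] = (track["pos"] >= s5) & (track["pos"] < e5)
    for p, c in zip(track["pos"], track["count"]):
        elements[ref.element_of(int(p))] += int(c)
    props = track.copy()
    props["fraction"] = props["count"] / props["count"].sum()
    props = props.sort_values(["count", "pos", "strand"],
                              ascending=[False, True, True],
                              kind="mergesort").reset_index(drop=True)
    return track, elements, props


def category_proportions(
    molecules: pd.DataFrame,
    key: list[str] = ("prey_ref", "prey_pos", "prey_strand", "bait_end", "insertion"),
) -> pd.DataFrame:
    """Per-unique-junction proportions within one outcome class (the treemap
    table): count and fraction of the class total, sorted descending with a
    lexicographic tie-break. Fractions sum to 1."""
    if molecules.empty:
        return pd.DataFrame(columns=[*key, "count", "fraction"])
    key = list(key)
    tab = (
        molecules.groupby(key, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    tab["fraction"] = tab["count"] / tab["count"].sum()
    tab = tab.sort_values(["count", *key], ascending=[False] + [True] * len(key),
                          kind="mergesort").reset_index(drop=True)
    return tab
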