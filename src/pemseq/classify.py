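"""Editing-outcome classification and per-sample profiling.

Each deduplicated molecule is assigned exactly one outcome class relative
to the Cas9 cut:

* ``viral_integration`` — prey maps to the vector genome;
* ``translocation`` — prey on another chromosome, beyond the ±bound
  (500 kb by default) of the cut, or in the orientation inconsistent with
  simple rejoining (inversion-like junctions have no bin of their own and
  are counted here, flagged);
* ``small_deletion`` / ``large_deletion`` — same-chromosome sense junction
  resuming 1–100 bp, respectively 100 bp–500 kb, downstream of the bait end;
* ``insertion`` — zero-deletion junction with untemplated bases, or a
  small tandem-duplication junction (prey resuming up to 100 bp *behind*
  the bait end — the alignment-canonical form of an insertion that copies
  adjacent reference);
* ``perfect`` — identity with the reference around the cut.

Editing efficiency is the fraction of molecules that are not perfect;
per-class frequencies are quoted among editing events (perfect excluded
from the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import GeneModel, TargetSite

__all__ = [
    "ClassificationThresholds",
    "classify_event",
    "classify_events",
    "sample_profile",
    "top_alleles",
    "coding_impact",
    "EVENT_CLASSES",
]

EVENT_CLASSES = (
    "perfect",
    "insertion",
    "small_deletion",
    "large_deletion",
    "translocation",
    "viral_integration",
)

EDITING_CLASSES = tuple(c for c in EVENT_CLASSES if c != "perfect")


@dataclass(frozen=True)
class ClassificationThresholds:
    small_deletion_max: int = 100
    large_deletion_max: int = 500_000
    translocation_bound: int = 500_000

    def __post_init__(self) -> None:
        if not 0 < self.small_deletion_max < self.large_deletion_max:
            raise ValueError("need 0 < small_deletion_max < large_deletion_max")
        if self.translocation_bound != self.large_deletion_max:
            raise ValueError(
                "translocation_bound and large_deletion_max form a single "
                "boundary and must be equal"
            )


def classify_event(
    molecule,
    target: TargetSite,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    *,
    viral_name: str = "RV",
) -> dict:
    """Classify a single molecule (any object with the signature fields).

    Returns a dict with ``event_class``, ``deletion_length`` (signed prey
    offset from the bait end on sense same-chromosome junctions, else None),
    ``distance_from_cut`` and ``deletion_span``.
    """
    cut = target.cut_position
    prey_ref = molecule.prey_ref
    prey_pos = int(molecule.prey_pos)
    prey_strand = molecule.prey_strand
    bait_end = int(molecule.bait_end)
    ins = molecule.insertion or ""
    is_perfect = bool(getattr(molecule, "is_perfect", False))

    out = {
        "event_class": None,
        "deletion_length": None,
        "distance_from_cut": None,
        "deletion_span": None,
        "inversion_like": False,
    }
    if is_perfect:
        out["event_class"] = "perfect"
        return out
    if prey_ref == viral_name:
        out["event_class"] = "viral_integration"
        return out
    if prey_ref != target.chromosome:
        out["event_class"] = "translocation"
        return out
    out["distance_from_cut"] = abs(prey_pos - cut)
    if prey_strand != target.bait_orientation:
        out["event_class"] = "translocation"
        out["inversion_like"] = True
        return out
    if abs(prey_pos - cut) > thresholds.translocation_bound:
        out["event_class"] = "translocation"
        return out
    d = prey_pos - bait_end
    out["deletion_length"] = d
    if d >= 1:
        out["deletion_span"] = (bait_end, prey_pos)
        out["event_class"] = (
            "small_deletion" if d <= thresholds.small_deletion_max else "large_deletion"
        )
    elif d == 0:
        out["event_class"] = "insertion" if ins else "perfect"
    else:  # tandem-duplication form; see module docstring
        if -d <= thresholds.small_deletion_max:
            out["event_class"] = "insertion"
        else:
            out["event_class"] = "translocation"
    return out


def classify_events(
    molecules: pd.DataFrame,
    target: TargetSite,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    *,
    viral_name: str = "RV",
) -> pd.DataFrame:
    """Vectorised classification of a molecule table.

    Adds ``event_class``, ``deletion_length``, ``distance_from_cut`` and
    ``inversion_like`` columns; asserts the partition property (every
    molecule gets exactly one class).
    """
    df = molecules.copy()
    if df.empty:
        for c in ("event_class", "deletion_length", "distance_from_cut",
                  "inversion_like"):
            df[c] = []
        return df
    cut = target.cut_position
    prey_ref = df["prey_ref"].to_numpy()
    prey_pos = df["prey_pos"].to_numpy(dtype=np.int64)
    strand = df["prey_strand"].to_numpy()
    bait_end = df["bait_end"].to_numpy(dtype=np.int64)
    ins_len = df["insertion"].fillna("").str.len().to_numpy()
    perfect_flag = (
        df["is_perfect"].to_numpy(dtype=bool)
        if "is_perfect" in df.columns
        else np.zeros(len(df), dtype=bool)
    )

    same_chrom = prey_ref == target.chromosome
    viral = prey_ref == viral_name
    dist = np.abs(prey_pos - cut)
    sense = strand == target.bait_orientation
    d = prey_pos - bait_end

    conditions = [
        perfect_flag,
        viral,
        ~same_chrom & ~viral,
        same_chrom & ~sense,
        same_chrom & sense & (dist > thresholds.translocation_bound),
        same_chrom & sense & (d >= 1) & (d <= thresholds.small_deletion_max),
        same_chrom & sense & (d > thresholds.small_deletion_max),
        same_chrom & sense & (d == 0) & (ins_len > 0),
        same_chrom & sense & (d == 0) & (ins_len == 0),
        same_chrom & sense & (d < 0) & (-d <= thresholds.small_deletion_max),
        same_chrom & sense & (d < 0),
    ]
    choices = [
        "perfect",
        "viral_integration",
        "translocation",
        "translocation",
        "translocation",
        "small_deletion",
        "large_deletion",
        "insertion",
        "perfect",
        "insertion",
        "translocation",
    ]
    cls = np.select(conditions, choices, default="")
    assert (cls != "").all(), "classification rule table is not a partition"
    df["event_class"] = cls
    df["deletion_length"] = np.where(same_chrom & sense, d, 0)
    df["distance_from_cut"] = np.where(same_chrom, dist, -1)
    df["inversion_like"] = same_chrom & ~sense
    return df


def sample_profile(events: pd.DataFrame) -> dict:
    """Per-sample editing profile.

    ``editing_efficiency`` = 1 − perfect/total; class frequencies are among
    editing events. An all-perfect sample reports zero frequencies with a
    ``no_editing_events`` flag rather than NaNs.
    """
    if events.empty:
        raise ValueError("sample_profile requires a nonempty event table")
    total = int(len(events))
    counts = {c: int((events["event_class"] == c).sum()) for c in EVENT_CLASSES}
    editing = total - counts["perfect"]
    profile = {
        "total_events": total,
        "editing_events": editing,
        "editing_efficiency": editing / total,
        "class_counts": counts,
        "class_frequencies": {
            c: (counts[c] / editing if editing else 0.0) for c in EDITING_CLASSES
        },
        "no_editing_events": editing == 0,
    }
    assert sum(counts[c] for c in EDITING_CLASSES) == editing
    return profile


def allele_signature(row) -> str:
    """Human-readable allele key: prey locus, signed offset and insertion."""
    if getattr(row, "is_perfect", False) or row.event_class == "perfect":
        return "perfect"
    base = f"{row.prey_ref}:{row.prey_pos}:{row.prey_strand}|bait_end={row.bait_end}"
    ins = row.insertion or ""
    if ins:
        base += f"|ins={ins}"
    return base


def top_alleles(events: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Most frequent editing products.

    Events are grouped by junction signature (deletion span, prey locus,
    inserted sequence); frequencies are among editing events. Ties break
    lexicographically on the signature for determinism.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    editing = events[events["event_class"] != "perfect"]
    if editing.empty:
        return pd.DataFrame(columns=["signature", "event_class", "count", "frequency"])
    sig = (
        editing["prey_ref"].astype(str)
        + ":" + editing["prey_pos"].astype(str)
        + ":" + editing["prey_strand"].astype(str)
        + "|bait_end=" + editing["bait_end"].astype(str)
        + np.where(editing["insertion"].fillna("") != "",
                   "|ins=" + editing["insertion"].fillna(""), "")
    )
    tab = (
        editing.assign(signature=sig)
        .groupby(["signature", "event_class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    tab["frequency"] = tab["count"] / len(editing)
    tab = tab.sort_values(["count", "signature"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return tab.head(n)


def coding_impact(
    events: pd.DataFrame, genes: GeneModel, target: TargetSite
) -> float:
    """Fraction of editing events that do NOT intersect any exon.

    Deletions impact coding when their span overlaps an exon; insertions and
    vector integrations are point disruptions at the cut; translocations are
    scored on the bait-side allele only — from the cut to the prey when the
    prey is on the target chromosome, otherwise as a point disruption at the
    cut (the partner locus is not counted).
    """
    editing = events[events["event_class"] != "perfect"]
    if editing.empty:
        return 1.0
    cut = target.cut_position
    chrom = target.chromosome
    n_impact = 0
    for row in editing.itertuples(index=False):
        if row.event_class in ("small_deletion", "large_deletion"):
            lo, hi = int(row.bait_end), int(row.prey_pos)
        elif row.event_class == "translocation" and row.prey_ref == chrom:
            lo, hi = sorted((cut, int(row.prey_pos)))
            hi += 1
        else:
            lo, hi = cut, cut + 1
        if genes.overlaps_exon(chrom, lo, hi):
            n_impact += 1
    return 1.0 - n_impact / len(editing)
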