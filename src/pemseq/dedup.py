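"""Molecular-barcode deduplication and expansion/PCR diagnostics.

PEM-seq separates biological copies of a junction from PCR duplicates with
two independent features: the random molecular barcode (RMB) ligated after
one-round primer extension, and the sonication fragment end. Reads sharing
the junction signature, fragment length and (up to a small edit tolerance)
the RMB collapse to one molecule; a site whose molecules carry many distinct
RMBs and fragment lengths is a biological expansion, while many reads with a
single RMB are a PCR artifact.

The RMB merge is a directional network in the UMI-tools sense — a barcode
absorbs a neighbour within the mismatch tolerance only when its read count
is at least twice the neighbour's minus one — iterated to a fixpoint so
deduplication is idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SIGNATURE_COLUMNS",
    "deduplicate",
    "site_duplicate_diagnostics",
]

SIGNATURE_COLUMNS = [
    "bait_chrom",
    "bait_end",
    "prey_ref",
    "prey_pos",
    "prey_strand",
    "insertion",
]

MOLECULE_COLUMNS = SIGNATURE_COLUMNS + [
    "rmb",
    "fragment_length",
    "read_support",
    "is_perfect",
    "microhomology",
]


def _merge_rmb_group(
    rmbs: list[str], counts: list[int], tolerance: int
) -> list[tuple[str, int]]:
    """Directional-network merge of one (signature, fragment length) group.

    Passes run until no absorption happens, so re-running on the output is a
    no-op. Order of processing is (count desc, barcode asc), which makes the
    result deterministic.
    """
    if tolerance <= 0 or len(rmbs) == 1:
        return sorted(zip(rmbs, counts))
    mat = np.frombuffer("".join(rmbs).encode(), dtype=np.uint8).reshape(len(rmbs), -1)
    items: list[list] = sorted(
        ([r, c, i] for i, (r, c) in enumerate(zip(rmbs, counts))),
        key=lambda it: (-it[1], it[0]),
    )
    alive = [True] * len(items)
    changed = True
    while changed:
        changed = False
        items.sort(key=lambda it: (-it[1], it[0]))
        for a in range(len(items)):
            if not alive[a]:
                continue
            for b in range(len(items)):
                if a == b or not alive[b]:
                    continue
                if items[a][1] < 2 * items[b][1] - 1:
                    continue
                dist = int((mat[items[a][2]] != mat[items[b][2]]).sum())
                if dist <= tolerance:
                    items[a][1] += items[b][1]
                    alive[b] = False
                    changed = True
        items = [it for k, it in enumerate(items) if alive[k]]
        alive = [True] * len(items)
    return sorted((r, c) for r, c, _ in items)


def deduplicate(
    junctions: pd.DataFrame,
    *,
    rmb_mismatch_tolerance: int = 1,
    key_on_fragment_length: bool = True,
) -> pd.DataFrame:
    """Collapse junction records (one row per read) into molecules.

    The collapse key is the junction signature (bait end, prey locus with
    strand, inserted sequence) plus — by default — the sonication fragment
    length; within a key, RMBs within the mismatch tolerance merge
    directionally. A ``read_support`` column, if present, is honoured as a
    per-row read count, so deduplicating an already-deduplicated table is a
    no-op. Output is sorted by prey site then RMB.
    """
    if junctions.empty:
        return pd.DataFrame(columns=MOLECULE_COLUMNS)
    if junctions["rmb"].str.len().nunique() > 1:
        raise ValueError("mixed RMB lengths in input")
    df = junctions.copy()
    if "read_support" not in df.columns:
        df["read_support"] = 1
    if "is_perfect" not in df.columns:
        df["is_perfect"] = False
    if "microhomology" not in df.columns:
        df["microhomology"] = 0
    key_cols = SIGNATURE_COLUMNS + (["fragment_length"] if key_on_fragment_length else [])

    counts = (
        df.groupby(key_cols + ["rmb"], sort=True, observed=True)
        .agg(
            n=("read_support", "sum"),
            is_perfect=("is_perfect", "first"),
            microhomology=("microhomology", "min"),
            fragment_length_rep=("fragment_length", "min"),
        )
        .reset_index()
    )
    if key_on_fragment_length:
        counts["fragment_length_rep"] = counts["fragment_length"]
    n_in_key = counts.groupby(key_cols, observed=True)["rmb"].transform("size")

    single = counts[n_in_key == 1]
    rows: list[tuple] = list(
        single[SIGNATURE_COLUMNS + ["rmb", "fragment_length_rep", "n",
                                    "is_perfect", "microhomology"]]
        .itertuples(index=False, name=None)
    )
    multi = counts[n_in_key > 1]
    for key, sub in multi.groupby(key_cols, sort=True, observed=True):
        merged = _merge_rmb_group(
            sub["rmb"].tolist(), sub["n"].tolist(), rmb_mismatch_tolerance
        )
        sig = key[: len(SIGNATURE_COLUMNS)]
        frag_by_rmb = dict(zip(sub["rmb"], sub["fragment_length_rep"]))
        perfect = bool(sub["is_perfect"].iloc[0])
        mh = int(sub["microhomology"].min())
        for rmb, n in merged:
            rows.append((*sig, rmb, frag_by_rmb[rmb], n, perfect, mh))
    out = pd.DataFrame(rows, columns=MOLECULE_COLUMNS)
    out = out.sort_values(
        ["prey_ref", "prey_pos", "prey_strand", "bait_end", "insertion", "rmb",
         "fragment_length"],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def site_duplicate_diagnostics(
    molecules: pd.DataFrame,
    *,
    min_copies_expanded: int = 5,
    min_diversity_fraction: float = 0.9,
) -> pd.DataFrame:
    """Per prey-site (1-bp resolution, stranded) expansion diagnostics.

    ``expanded``: at least ``min_copies_expanded`` molecules whose RMB
    diversity (distinct RMBs / molecules) reaches ``min_diversity_fraction``
    — many biological copies with independent barcodes. ``pcr_artifact``:
    a read pileup carried by a single RMB. Everything else: ``singleton``.
    """
    cols = ["prey_ref", "prey_pos", "prey_strand"]
    if molecules.empty:
        return pd.DataFrame(
            columns=cols + ["n_reads", "n_molecules", "n_distinct_rmbs",
                            "n_distinct_fragment_lengths", "verdict"]
        )
    g = molecules.groupby(cols, sort=True, observed=True)
    out = g.agg(
        n_reads=("read_support", "sum"),
        n_molecules=("read_support", "size"),
        n_distinct_rmbs=("rmb", "nunique"),
        n_distinct_fragment_lengths=("fragment_length", "nunique"),
    ).reset_index()
    diversity = out["n_distinct_rmbs"] / out["n_molecules"]
    expanded = (out["n_molecules"] >= min_copies_expanded) & (
        diversity >= min_diversity_fraction
    )
    artifact = (~expanded) & (out["n_reads"] >= min_copies_expanded) & (
        out["n_distinct_rmbs"] == 1
    )
    out["verdict"] = np.where(expanded, "expanded",
                              np.where(artifact, "pcr_artifact", "singleton"))
    return out
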