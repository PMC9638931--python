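"""Synthetic PEM-seq library generator with per-molecule truth tracking.

The generator emulates the statistical structure a PEM-seq analysis relies
on: a configurable mixture of editing outcomes at a fixed Cas9 cut site
(perfect rejoin, insertions dominated by the +1 T product, geometric small
deletions, log-uniform large deletions, genome-wide translocations outside
the ±bound, retroviral-vector integrations with LTR enrichment), clonal
amplification of selected founder junctions (identical junction signature,
fresh molecular barcodes and sonication fragment lengths per biological
copy), and PCR duplication (extra read pairs that share barcode *and*
fragment end).

Reads follow the library chemistry: R1 starts at the bait primer and runs
through the bait into the prey; R2 starts with the random molecular barcode
(RMB) and continues with the reverse complement of the sonication fragment
end. Sequences are error-free by default, with an optional uniform
substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reference import (
    ReferenceBundle,
    TargetSite,
    oriented_avail,
    oriented_slice,
    revcomp,
)

__all__ = [
    "OUTCOME_CLASSES",
    "TRUTH_COLUMNS",
    "SimulationConfig",
    "preset_cohort",
    "simulate_molecules",
    "emit_reads",
    "molecules_from_truth",
    "canonical_junctions",
    "read_truth",
    "write_truth",
]

OUTCOME_CLASSES = (
    "perfect",
    "insertion",
    "small_deletion",
    "large_deletion",
    "translocation",
    "viral_integration",
)

TRUTH_COLUMNS = [
    "molecule_id",
    "clone_id",
    "class",
    "bait_chrom",
    "bait_pos",
    "bait_strand",
    "prey_ref",
    "prey_pos",
    "prey_strand",
    "insertion",
    "rmb",
    "fragment_length",
    "n_pcr_copies",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_mix() -> dict[str, float]:
    # activated-T-cell-like outcome mixture: ~95% editing, ~1% translocation,
    # ~4% vector integration, insertions >20% of events
    return {
        "perfect": 0.05,
        "insertion": 0.20,
        "small_deletion": 0.55,
        "large_deletion": 0.15,
        "translocation": 0.01,
        "viral_integration": 0.04,
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines its output."""

    n_molecules: int = 10_000
    seed: int = 0
    outcome_mix: dict[str, float] = field(default_factory=_default_mix)

    # insertion law: 1-bp T with fixed weight, remainder geometric 2-20 bp
    t_insertion_weight: float = 0.73
    insertion_geom_p: float = 0.35
    max_insertion_length: int = 20

    # deletion laws
    small_deletion_geom_p: float = 0.03
    small_deletion_max: int = 100
    large_deletion_max: int = 500_000  # log-uniform over (small_max, this]

    # translocations: uniform over the genome excluding the ±bound window
    translocation_exclusion: int = 500_000
    edge_margin: int = 800  # keep prey + fragment inside chromosomes

    # viral integrations
    ltr_weight: float = 3.0
    viral_margin: int = 70  # min readable prey inside the vector

    # clonal expansion
    n_expanded_clones: int = 0
    expansion_count_range: tuple[int, int] | None = None  # inclusive, overrides
    expansion_class_mix: dict[str, float] = field(
        default_factory=lambda: {"translocation": 1.0}
    )
    expansion_logseries_p: float = 0.98
    expansion_min_copies: int = 5
    expansion_max_copies: int = 1_000

    # library chemistry
    pcr_duplication_rate: float = 1.0  # mean extra reads per molecule
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    fragment_min: int = 300
    fragment_max: int = 700
    rmb_length: int = 14
    read_length: int = 150
    error_rate: float = 0.0

    def validate(self) -> None:
        if abs(sum(self.outcome_mix.values()) - 1.0) > 1e-9:
            raise ValueError("outcome_mix probabilities must sum to 1")
        if set(self.outcome_mix) - set(OUTCOME_CLASSES):
            raise ValueError(f"unknown outcome classes in mix: {self.outcome_mix}")
        if any(p < 0 for p in self.outcome_mix.values()):
            raise ValueError("outcome_mix probabilities must be non-negative")
        if self.n_molecules < 0 or self.n_expanded_clones < 0:
            raise ValueError("counts must be >= 0")
        if self.expansion_class_mix:
            if abs(sum(self.expansion_class_mix.values()) - 1.0) > 1e-9:
                raise ValueError("expansion_class_mix must sum to 1")
            if "perfect" in self.expansion_class_mix:
                raise ValueError("expanded clones must come from edited classes")
        if not 0 < self.small_deletion_max < self.large_deletion_max:
            raise ValueError("need 0 < small_deletion_max < large_deletion_max")


_PRESETS = ("activated", "inflammatory")


def preset_cohort(name: str, *, seed: int = 0, **overrides) -> SimulationConfig:
    """Named study-condition presets.

    ``activated``: ex-vivo activated T cells — ~150k molecules, ~95% edited,
    ~1% translocations, 4% vector integrations, no clonal expansion.
    ``inflammatory``: gut-derived T cells after infusion — the same library
    chemistry with 12–17 expanded translocation founder clones (heavy-tailed
    copy numbers, ≥5 copies each) and a halved background translocation rate.
    """
    if name == "activated":
        cfg = SimulationConfig(n_molecules=150_000, seed=seed)
    elif name == "inflammatory":
        cfg = SimulationConfig(
            n_molecules=150_000,
            seed=seed,
            outcome_mix={
                "perfect": 0.05,
                "insertion": 0.20,
                "small_deletion": 0.555,
                "large_deletion": 0.15,
                "translocation": 0.005,
                "viral_integration": 0.04,
            },
            expansion_count_range=(12, 17),
            n_expanded_clones=15,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; known presets: {_PRESETS}")
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# molecule simulation
# ---------------------------------------------------------------------------

def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n == 0:
        return []
    mat = _BASES[rng.integers(0, 4, size=(n, length))]
    return [bytes(row).decode("ascii") for row in mat]


def _draw_insertions(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> list[str]:
    out: list[str] = []
    is_t = rng.random(n) < cfg.t_insertion_weight
    n_other = int((~is_t).sum())
    lengths = np.clip(rng.geometric(cfg.insertion_geom_p, n_other) + 1, 2,
                      cfg.max_insertion_length)
    other_iter = iter(
        [s[:l] for s, l in zip(_random_seqs(rng, n_other, cfg.max_insertion_length),
                               lengths)]
    )
    for t in is_t:
        out.append("T" if t else next(other_iter))
    return out


def _translocation_regions(
    ref: ReferenceBundle, target: TargetSite, cfg: SimulationConfig
) -> list[tuple[str, int, int]]:
    """Allowed (chrom, lo, hi) intervals for translocation prey positions."""
    regions = []
    m = cfg.edge_margin
    lo_x = target.cut_position - cfg.translocation_exclusion
    hi_x = target.cut_position + cfg.translocation_exclusion
    for name, seq in sorted(ref.chromosomes.items()):
        L = len(seq)
        if name == target.chromosome:
            if m < lo_x:
                regions.append((name, m, min(lo_x, L - m)))
            if hi_x < L - m:
                regions.append((name, max(hi_x + 1, m), L - m))
        else:
            if m < L - m:
                regions.append((name, m, L - m))
    if not regions:
        raise ValueError("no genomic region available for translocation prey")
    return regions


def _draw_translocations(
    rng: np.random.Generator, n: int, ref: ReferenceBundle,
    target: TargetSite, cfg: SimulationConfig,
) -> tuple[list[str], np.ndarray, list[str]]:
    regions = _translocation_regions(ref, target, cfg)
    sizes = np.array([hi - lo for _, lo, hi in regions], dtype=float)
    idx = rng.choice(len(regions), size=n, p=sizes / sizes.sum())
    offs = rng.random(n)
    chroms, poss = [], np.empty(n, dtype=int)
    for i, (k, u) in enumerate(zip(idx, offs)):
        name, lo, hi = regions[k]
        chroms.append(name)
        poss[i] = lo + int(u * (hi - lo))
    strands = ["+" if s else "-" for s in rng.integers(0, 2, n)]
    return chroms, poss, strands


def _viral_position_weights(ref: ReferenceBundle, cfg: SimulationConfig, strand: str) -> np.ndarray:
    L = len(ref.viral_seq)
    w = np.ones(L)
    for el in ("5LTR", "3LTR"):
        s, e = ref.elements[el]
        w[s:e] = cfg.ltr_weight
    # keep at least viral_margin readable prey bases inside the vector
    if strand == "+":
        w[L - cfg.viral_margin + 1 :] = 0.0
    else:
        w[: cfg.viral_margin - 1] = 0.0
    return w / w.sum()


def _draw_viral(
    rng: np.random.Generator, n: int, ref: ReferenceBundle, cfg: SimulationConfig
) -> tuple[np.ndarray, list[str]]:
    strands = ["+" if s else "-" for s in rng.integers(0, 2, n)]
    pos = np.empty(n, dtype=int)
    for strand in "+-":
        mask = np.array([s == strand for s in strands])
        k = int(mask.sum())
        if k:
            w = _viral_position_weights(ref, cfg, strand)
            pos[mask] = rng.choice(len(w), size=k, p=w)
    return pos, strands


def _draw_junctions(
    rng: np.random.Generator,
    classes: list[str],
    ref: ReferenceBundle,
    target: TargetSite,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    """Per-molecule junction fields for an array of outcome classes."""
    n = len(classes)
    cut = target.cut_position
    chrom = target.chromosome
    prey_ref = np.array([chrom] * n, dtype=object)
    prey_pos = np.full(n, cut, dtype=int)
    prey_strand = np.array(["+"] * n, dtype=object)
    insertion = np.array([""] * n, dtype=object)

    cls = np.asarray(classes, dtype=object)

    m_ins = cls == "insertion"
    if m_ins.any():
        insertion[m_ins] = _draw_insertions(rng, int(m_ins.sum()), cfg)

    m_sd = cls == "small_deletion"
    if m_sd.any():
        d = np.clip(rng.geometric(cfg.small_deletion_geom_p, int(m_sd.sum())),
                    1, cfg.small_deletion_max)
        prey_pos[m_sd] = cut + d

    m_ld = cls == "large_deletion"
    if m_ld.any():
        lo, hi = np.log(cfg.small_deletion_max + 1), np.log(cfg.large_deletion_max)
        d = np.exp(rng.uniform(lo, hi, int(m_ld.sum()))).round().astype(int)
        d = np.clip(d, cfg.small_deletion_max + 1, cfg.large_deletion_max)
        prey_pos[m_ld] = cut + d

    m_tr = cls == "translocation"
    if m_tr.any():
        c, p, s = _draw_translocations(rng, int(m_tr.sum()), ref, target, cfg)
        prey_ref[m_tr] = c
        prey_pos[m_tr] = p
        prey_strand[m_tr] = s

    m_vi = cls == "viral_integration"
    if m_vi.any():
        p, s = _draw_viral(rng, int(m_vi.sum()), ref, cfg)
        prey_ref[m_vi] = ref.viral_name
        prey_pos[m_vi] = p
        prey_strand[m_vi] = s

    return pd.DataFrame(
        {
            "class": cls,
            "bait_chrom": chrom,
            "bait_pos": cut,
            "bait_strand": "+",
            "prey_ref": prey_ref,
            "prey_pos": prey_pos,
            "prey_strand": prey_strand,
            "insertion": insertion,
        }
    )


def _draw_copy_numbers(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Log-series copy numbers conditioned on the detectable range."""
    out: list[int] = []
    guard = 0
    while len(out) < n:
        draw = rng.logseries(cfg.expansion_logseries_p, size=max(4 * n, 64))
        keep = draw[(draw >= cfg.expansion_min_copies) & (draw <= cfg.expansion_max_copies)]
        out.extend(int(x) for x in keep)
        guard += 1
        if guard > 1000:
            raise RuntimeError("copy-number rejection sampling failed to converge")
    return np.array(out[:n], dtype=int)


def _fragment_lengths(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    a = (cfg.fragment_min - cfg.fragment_mean) / cfg.fragment_sd
    b = (cfg.fragment_max - cfg.fragment_mean) / cfg.fragment_sd
    fl = stats.truncnorm.rvs(a, b, loc=cfg.fragment_mean, scale=cfg.fragment_sd,
                             size=n, random_state=rng)
    return fl.round().astype(int)


def simulate_molecules(
    config: SimulationConfig, ref: ReferenceBundle, target: TargetSite
) -> pd.DataFrame:
    """Draw the truth table: background molecules i.i.d. from the outcome mix
    plus expanded clones replicated to their drawn copy numbers.

    Every row is one biological molecule; ``n_pcr_copies`` is the number of
    read pairs it will emit. Copies of one clone share the junction signature
    and insertion but carry fresh RMBs and fragment lengths.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = list(config.outcome_mix)
    probs = np.array([config.outcome_mix[c] for c in names])
    cls_idx = rng.choice(len(names), size=config.n_molecules, p=probs)
    bg_classes = [names[i] for i in cls_idx]
    frames = [_draw_junctions(rng, bg_classes, ref, target, config)]
    clone_ids = ["."] * config.n_molecules

    n_exp = config.n_expanded_clones
    if config.expansion_count_range is not None:
        lo, hi = config.expansion_count_range
        n_exp = int(rng.integers(lo, hi + 1))
    if n_exp:
        enames = list(config.expansion_class_mix)
        eprobs = np.array([config.expansion_class_mix[c] for c in enames])
        fidx = rng.choice(len(enames), size=n_exp, p=eprobs)
        fclasses = [enames[i] for i in fidx]
        founders = _draw_junctions(rng, fclasses, ref, target, config)
        copies = _draw_copy_numbers(rng, n_exp, config)
        expanded = founders.loc[founders.index.repeat(copies)].reset_index(drop=True)
        frames.append(expanded)
        for k, c in enumerate(copies):
            clone_ids.extend([f"clone{k:03d}"] * int(c))

    truth = pd.concat(frames, ignore_index=True)
    n = len(truth)
    truth.insert(0, "molecule_id", [f"m{i:07d}" for i in range(n)])
    truth.insert(1, "clone_id", clone_ids)
    truth["rmb"] = _random_seqs(rng, n, config.rmb_length)

    # sonication fragment length, truncated where the prey runs off the
    # reference (the fragment physically cannot extend past the vector or
    # chromosome end)
    fl = _fragment_lengths(rng, n, config)
    bait_len = target.cut_position - target.bait_primer_start
    avail = np.array(
        [
            oriented_avail(len(ref.get(r)), p, s)
            for r, p, s in zip(truth["prey_ref"], truth["prey_pos"], truth["prey_strand"])
        ]
    )
    ins_len = truth["insertion"].str.len().to_numpy()
    truth["fragment_length"] = np.minimum(fl, bait_len + ins_len + avail)
    truth["n_pcr_copies"] = 1 + rng.poisson(config.pcr_duplication_rate, n)
    return truth[TRUTH_COLUMNS]


def molecules_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Truth records in deduplicated-molecule schema (the idealised output of
    extraction + dedup on error-free reads), for read-free analyses."""
    out = truth.rename(columns={"bait_pos": "bait_end", "n_pcr_copies": "read_support"})
    out = out[
        [
            "bait_chrom",
            "bait_end",
            "prey_ref",
            "prey_pos",
            "prey_strand",
            "insertion",
            "rmb",
            "fragment_length",
            "read_support",
        ]
    ].copy()
    out["microhomology"] = 0
    return out


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def _core_sequence(
    row, ref: ReferenceBundle, target: TargetSite, bait_len: int
) -> str:
    """The full fragment sequence: bait (primer→cut) + insertion + prey."""
    cseq = ref.chromosomes[target.chromosome]
    ps = target.bait_primer_start
    bait = cseq[ps : ps + bait_len]
    ins = row.insertion
    prey_needed = int(row.fragment_length) - bait_len - len(ins)
    prey = oriented_slice(ref.get(row.prey_ref), int(row.prey_pos), row.prey_strand,
                          prey_needed)
    return bait + ins + prey


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit) == 0:
        return seq
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return bytes(arr).decode("ascii")


def emit_reads(
    truth: pd.DataFrame,
    ref: ReferenceBundle,
    target: TargetSite,
    config: SimulationConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> int:
    """Write paired FASTQ (Phred-33, constant quality) for the truth table.

    Per molecule, ``n_pcr_copies`` read pairs are emitted: PCR duplicates are
    byte-identical apart from independent sequencing errors. Returns the
    number of read pairs written.
    """
    rng = np.random.default_rng([config.seed, 7])
    bait_len = target.cut_position - target.bait_primer_start
    rl = config.read_length
    n_pairs = 0
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for row in truth.itertuples(index=False):
            core = _core_sequence(row, ref, target, bait_len)
            r1 = core[:rl]
            r2 = row.rmb + revcomp(core)[: rl - len(row.rmb)]
            for i in range(int(row.n_pcr_copies)):
                name = f"{row.molecule_id}:{i}"
                s1 = _mutate(r1, rng, config.error_rate)
                s2 = _mutate(r2, rng, config.error_rate)
                f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")
                n_pairs += 1
    return n_pairs


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"insertion": str, "rmb": str},
                     keep_default_na=False)
    df["insertion"] = df["insertion"].fillna("")
    return df


# ---------------------------------------------------------------------------
# canonical junction convention (the extraction oracle)
# ---------------------------------------------------------------------------

def canonical_junctions(
    truth: pd.DataFrame,
    ref: ReferenceBundle,
    target: TargetSite,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Truth records rewritten under the breakpoint-resolution convention.

    Junction coordinates as drawn are not unique: bases shared by bait and
    prey (microhomology) or insertions resembling adjacent reference slide
    the apparent breakpoint. This applies the extractor's own convention —
    maximal bait extension, maximal leftward prey extension, the shared
    scored gap resolution, and mirroring of prey alignments lying wholly
    within an LTR onto the 5' copy — to the error-free read each truth
    record would emit. Extraction output on error-free reads equals this
    table exactly.
    """
    from .extract import (
        _extend_left_exact,
        _extend_right,
        _frame_pos,
        _make_frame,
        resolve_junction,
    )

    cseq = ref.chromosomes[target.chromosome]
    ps = target.bait_primer_start
    cut = target.cut_position
    bait_len = cut - ps
    rl = config.read_length
    s5, e5 = ref.elements["5LTR"]
    s3, e3 = ref.elements["3LTR"]
    L_chrom = len(cseq)

    def bait_frame(x: int):
        g = ps + x
        return cseq[g] if 0 <= g < L_chrom else None

    rows = []
    for row in truth.itertuples(index=False):
        core = _core_sequence(row, ref, target, bait_len)[:rl]
        e_bait, _ = _extend_right(core, 0, bait_frame, 12)
        if e_bait == len(core):
            rows.append(
                (row.molecule_id, True, ps + e_bait, row.bait_chrom, cut, "+", "", 0, False)
            )
            continue
        pseq = ref.get(row.prey_ref)
        j0 = bait_len + len(row.insertion)
        frame = _make_frame(pseq, int(row.prey_pos), j0, row.prey_strand)
        s_prey = _extend_left_exact(core, j0, frame)
        res = resolve_junction(core, bait_frame, frame, e_bait, s_prey)
        prey_out = _frame_pos(int(row.prey_pos), j0, row.prey_strand, res["prey_off"])
        ambiguous = False
        if ref.is_viral(row.prey_ref):
            g_lo = _frame_pos(int(row.prey_pos), j0, row.prey_strand, res["aln_start"])
            g_hi = _frame_pos(int(row.prey_pos), j0, row.prey_strand, len(core) - 1)
            lo, hi = min(g_lo, g_hi), max(g_lo, g_hi) + 1
            if s3 <= lo and hi <= e3:
                prey_out = prey_out - s3 + s5
                ambiguous = True
            elif s5 <= lo and hi <= e5:
                ambiguous = True
        rows.append(
            (
                row.molecule_id,
                False,
                ps + res["bait_end_off"],
                row.prey_ref,
                prey_out,
                row.prey_strand,
                res["insertion"],
                res["microhomology"],
                ambiguous,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id",
            "is_perfect",
            "bait_end",
            "prey_ref",
            "prey_pos",
            "prey_strand",
            "insertion",
            "microhomology",
            "ambiguous_ltr",
        ],
    )
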