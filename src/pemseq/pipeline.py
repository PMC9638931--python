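"""Pipeline orchestration, configuration and report emission.

One YAML config fully determines a run: reference construction, per-sample
simulation (or read input), extraction, dedup, classification, hotspot
calling and report writing, in that fixed stage order. Reruns with the same
config are byte-identical except for the log (the only place timestamps
appear). All numeric report output uses 6 significant digits.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import dedup as _dedup
from . import extract as _extract
from . import hotspots as _hotspots
from . import simulate as _simulate
from .reference import GeneModel, ReferenceBundle, TargetSite, build_toy_reference

__all__ = [
    "PipelineConfig",
    "SampleSpec",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("pemseq")

_FMT = "%.6g"


def _fmt_float(x) -> str:
    return _FMT % x


@dataclass
class SampleSpec:
    name: str
    preset: str = "activated"
    overrides: dict = field(default_factory=dict)
    with_reads: bool = True
    r1: str | None = None  # pre-existing FASTQ input instead of simulation
    r2: str | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pemseq_out"
    reference: dict = field(default_factory=dict)  # build_toy_reference kwargs
    extract: dict = field(default_factory=dict)
    dedup: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    hotspots: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    samples: list[SampleSpec] = field(default_factory=list)
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(samples=samples, **raw)


def _setup_logging(outdir: Path, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers.clear()
    sh = logging.StreamHandler(sys.stderr)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (sh, fh):
        h.setFormatter(fmt)
        log.addHandler(h)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained with a FAILED
    marker naming the stage."""


def _stage(outdir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "FAILED").write_text(f"failed at stage: {name}\n{exc}\n")
                log.error("stage %s: FAILED (%s)", name, exc)
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# per-sample processing
# ---------------------------------------------------------------------------

def _sample_seed(cfg: PipelineConfig, i: int) -> int:
    return (cfg.seed * 1009 + i) % (2**31 - 1)


def _process_sample(
    cfg: PipelineConfig,
    spec: SampleSpec,
    i: int,
    ref: ReferenceBundle,
    target: TargetSite,
    genes: GeneModel,
    index,
    outdir: Path,
) -> dict:
    sdir = outdir / spec.name
    sdir.mkdir(parents=True, exist_ok=True)
    thresholds = _classify.ClassificationThresholds(**cfg.classify)
    results: dict = {"name": spec.name}

    if spec.r1 is None:
        with _stage(outdir, f"simulate[{spec.name}]"):
            sim_cfg = _simulate.preset_cohort(
                spec.preset, seed=_sample_seed(cfg, i), **spec.overrides
            )
            truth = _simulate.simulate_molecules(sim_cfg, ref, target)
            _simulate.write_truth(truth, sdir / "truth.tsv")
            log.info("sample %s: %d truth molecules", spec.name, len(truth))
            results["truth"] = truth
        r1, r2 = sdir / "r1.fastq", sdir / "r2.fastq"
        if spec.with_reads:
            with _stage(outdir, f"emit_reads[{spec.name}]"):
                n_pairs = _simulate.emit_reads(truth, ref, target, sim_cfg, r1, r2)
                log.info("sample %s: %d read pairs", spec.name, n_pairs)
    else:
        r1, r2 = Path(spec.r1), Path(spec.r2)
        sim_cfg = None

    if spec.r1 is not None or spec.with_reads:
        with _stage(outdir, f"extract[{spec.name}]"):
            junctions, stats = _extract.extract_junctions(
                r1, r2, ref, target, index=index, **cfg.extract
            )
            if stats["pairs"] == 0:
                raise ValueError(f"no reads parsed from {r1}")
            log.info("sample %s: extraction stats %s", spec.name, stats)
            _write_tsv(junctions, sdir / "junctions.tsv")
            results["extract_stats"] = stats
        with _stage(outdir, f"dedup[{spec.name}]"):
            molecules = _dedup.deduplicate(junctions, **cfg.dedup)
            log.info(
                "sample %s: %d reads -> %d molecules",
                spec.name, len(junctions), len(molecules),
            )
    else:
        with _stage(outdir, f"dedup[{spec.name}]"):
            molecules = _simulate.molecules_from_truth(truth)
            molecules["is_perfect"] = (truth["class"] == "perfect").to_numpy()
            log.info("sample %s: %d molecules (truth-derived)", spec.name,
                     len(molecules))
    _write_tsv(molecules, sdir / "molecules.tsv")
    results["molecules"] = molecules

    with _stage(outdir, f"classify[{spec.name}]"):
        events = _classify.classify_events(
            molecules, target, thresholds, viral_name=ref.viral_name
        )
        profile = _classify.sample_profile(events)
        # conservation check: every molecule lands in exactly one class bin
        assert sum(profile["class_counts"].values()) == len(events)
        _write_tsv(events, sdir / "events.tsv")
        _write_json(profile, sdir / "profile.json")
        results["events"] = events
        results["profile"] = profile

    with _stage(outdir, f"reports[{spec.name}]"):
        alleles = _classify.top_alleles(events, n=5)
        _write_tsv(alleles, sdir / "alleles.tsv")
        _write_sample_histograms(events, sdir)
        diags = _dedup.site_duplicate_diagnostics(molecules, **cfg.diagnostics)
        _write_tsv(diags, sdir / "diagnostics.tsv")
        results["alleles"] = alleles
        results["diagnostics"] = diags
        results["coding_impact_clean_fraction"] = _classify.coding_impact(
            events, genes, target
        )
    return results


def _write_sample_histograms(events: pd.DataFrame, sdir: Path) -> None:
    dels = events[events["event_class"].isin(["small_deletion", "large_deletion"])]
    del_hist = (
        dels.groupby("prey_pos", observed=True).size().rename("count").reset_index()
        .rename(columns={"prey_pos": "deletion_endpoint"})
    )
    _write_tsv(del_hist, sdir / "deletion_histogram.tsv")
    ins = events[events["event_class"] == "insertion"]
    ins_len = ins["insertion"].fillna("").str.len()
    # tandem-duplication insertions carry their length in the signed offset
    dup = -(ins["prey_pos"] - ins["bait_end"]).clip(upper=0)
    ins_hist = (
        pd.Series(np.maximum(ins_len, dup), name="length", dtype=int)
        .value_counts()
        .sort_index()
        .rename("count")
        .reset_index()
        .rename(columns={"index": "length"})
    )
    _write_tsv(ins_hist, sdir / "insertion_histogram.tsv")
    assert len(dels) == int(del_hist["count"].sum()) if len(del_hist) else True


# ---------------------------------------------------------------------------
# cohort stage
# ---------------------------------------------------------------------------

def _cohort_stage(
    cfg: PipelineConfig,
    per_sample: list[dict],
    ref: ReferenceBundle,
    genes: GeneModel,
    outdir: Path,
) -> dict:
    params = _hotspots.HotspotParams(**cfg.hotspots)
    events_list = [r["events"] for r in per_sample]
    if len(events_list) > 1:
        cohort = _hotspots.normalize_to_editing_events(events_list, seed=cfg.seed)
        log.info("normalized %d samples to %d editing events",
                 len(events_list), cohort.target_event_count)
        norm = cohort.samples
    else:
        cohort = None
        norm = [events_list[0][events_list[0]["event_class"] != "perfect"]]

    all_calls = []
    shared_input = []
    for r, ev in zip(per_sample, norm):
        tr = ev[ev["event_class"] == "translocation"]
        calls = _hotspots.hotspots_from_molecules(tr, params, genes)
        calls.insert(0, "sample", r["name"])
        all_calls.append(calls)
        track = _hotspots.junction_track(tr, bin=params.bin)
        _write_bedgraph(track, outdir / f"{r['name']}.translocations.bedgraph")
        vir = ev[ev["event_class"] == "viral_integration"]
        shared_input.append(vir[["prey_ref", "prey_pos"]])
        r["normalized_events"] = ev
        r["hotspots"] = calls
        site_stats, summary = _hotspots.expansion_stats(tr)
        r["expansion_summary"] = summary
        _write_tsv(site_stats, outdir / f"{r['name']}.expansion.tsv")
    hotspot_df = pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame()
    _write_hotspot_bed(hotspot_df, outdir / "hotspots.bed")
    _write_links(per_sample, outdir / "links.tsv")

    out = {"hotspots": hotspot_df, "normalized": cohort}
    viral_all = pd.concat(
        [ev[ev["event_class"] == "viral_integration"] for ev in norm],
        ignore_index=True,
    )
    track, elements, props = _hotspots.viral_profile(viral_all, ref)
    _write_tsv(track, outdir / "viral_profile.tsv")
    _write_json({k: int(v) for k, v in elements.items()}, outdir / "viral_elements.json")
    _write_tsv(props.head(1000), outdir / "viral_proportions.tsv")
    out["viral_elements"] = elements
    if len(shared_input) >= 2:
        total, shared, pct = _hotspots.shared_sites(shared_input, bin=params.bin)
        share = {"n_total_distinct": total, "n_shared": shared, "percent_shared": pct}
        _write_json(share, outdir / "shared_sites.json")
        out["shared_sites"] = share
    return out


def _write_bedgraph(track: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.ref}\t{row.pos}\t{row.pos + 1}\t{row.count}\n")


def _write_hotspot_bed(calls: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tnormalized_junctions\t"
            "plus_fraction\tgene\n"
        )
        if calls.empty:
            return
        for i, row in enumerate(calls.itertuples(index=False)):
            name = f"{row.sample}_hs{i:03d}"
            fh.write(
                f"{row.ref}\t{row.start}\t{row.end}\t{name}\t0\t.\t"
                f"{row.normalized_junctions}\t{_fmt_float(row.plus_fraction)}\t"
                f"{getattr(row, 'gene', '')}\n"
            )


def _write_links(per_sample: list[dict], path: Path) -> None:
    rows = []
    for r in per_sample:
        ev = r.get("normalized_events")
        if ev is None:
            continue
        tr = ev[ev["event_class"] == "translocation"]
        g = tr.groupby(["bait_chrom", "bait_end", "prey_ref", "prey_pos"],
                       observed=True).size().rename("count").reset_index()
        g.insert(0, "sample", r["name"])
        rows.append(g)
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample", "bait_chrom", "bait_end", "prey_ref", "prey_pos", "count"]
    )
    _write_tsv(df, path)


def _write_report(per_sample: list[dict], cohort_out: dict, outdir: Path) -> None:
    lines = ["PEM-seq pipeline report", "======================", ""]
    for r in per_sample:
        p = r["profile"]
        lines.append(f"sample {r['name']}:")
        lines.append(f"  total events            {p['total_events']}")
        lines.append(f"  editing events          {p['editing_events']}")
        lines.append(
            f"  editing efficiency      {_fmt_float(100 * p['editing_efficiency'])}%"
        )
        for c, f in sorted(p["class_frequencies"].items()):
            lines.append(f"  {c:<22}  {_fmt_float(100 * f)}% of editing events")
        lines.append(
            "  coding-intact fraction  "
            f"{_fmt_float(100 * r['coding_impact_clean_fraction'])}%"
        )
        if "expansion_summary" in r:
            s = r["expansion_summary"]
            lines.append(
                f"  translocation sites     {s['n_sites']} "
                f"(mean copies {_fmt_float(s['mean_copies_per_site'])})"
            )
        if "hotspots" in r:
            lines.append(f"  hotspots called         {len(r['hotspots'])}")
        lines.append("")
    if "shared_sites" in cohort_out:
        s = cohort_out["shared_sites"]
        lines.append(
            f"viral integration sites shared in >=2 samples: {s['n_shared']} of "
            f"{s['n_total_distinct']} ({_fmt_float(s['percent_shared'])}%)"
        )
    lines.append("")
    (outdir / "report.txt").write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate → extract → dedup → classify → normalize → hotspots →
    reports for every configured sample; returns the in-memory results."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    _setup_logging(outdir, cfg.log_level)
    if not cfg.samples:
        raise ValueError("config lists no samples")

    with _stage(outdir, "reference"):
        ref, target, genes = build_toy_reference(**cfg.reference)
        log.info("reference %s: %d chromosomes + %s", ref.genome_id,
                 len(ref.chromosomes), ref.viral_name)
    needs_reads = any(s.with_reads or s.r1 for s in cfg.samples)
    index = _extract.SeedIndex(ref) if needs_reads else None

    per_sample = [
        _process_sample(cfg, spec, i, ref, target, genes, index, outdir)
        for i, spec in enumerate(cfg.samples)
    ]
    with _stage(outdir, "cohort"):
        cohort_out = _cohort_stage(cfg, per_sample, ref, genes, outdir)
    with _stage(outdir, "report"):
        _write_report(per_sample, cohort_out, outdir)
    return {"samples": per_sample, "cohort": cohort_out, "outdir": outdir}
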