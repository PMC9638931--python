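# pemseq

Quantifying CRISPR/Cas9 editing outcomes — and the structural variants they
leave behind — from PEM-seq libraries, at desk scale.

Primer-extension-mediated sequencing (PEM-seq) anchors a biotinylated primer
next to a fixed Cas9 cut site (the *bait*, here a site in the first intron
of *c-Myc*, sgRNA `GCGGTGAGTCGTGATCTGAG`) and captures every sequence fused
to it (the *prey*): perfect rejoins, small indels, large deletions,
chromosomal translocations and integrated viral vector DNA. Random
molecular barcodes (RMBs) ligated after one round of primer extension,
together with sonication fragment ends, let the assay distinguish
biological copies of one junction from PCR duplicates — the key to telling
*clonal expansion* of an edited T cell from amplification noise.

This package implements the complete analysis:

- **simulator** (`pemseq.simulate`) — truth-tracked PEM-seq libraries:
  configurable outcome mixture, +1 T-dominated insertions, geometric small
  deletions (≤100 bp), log-uniform large deletions (0.1–500 kb),
  genome-wide translocations outside ±500 kb, LTR-enriched vector
  integrations, heavy-tailed clonal expansion, PCR duplication, paired
  2×150 bp reads;
- **junction extraction** (`pemseq.extract`) — bait extension from the
  primer, seed-and-extend prey mapping against genome + vector on both
  strands, microhomology/insertion resolution at the breakpoint, fragment
  length from R2;
- **deduplication** (`pemseq.dedup`) — directional RMB network merge keyed
  on junction signature and fragment length, plus per-site
  expansion/PCR-artifact diagnostics;
- **classification** (`pemseq.classify`) — the outcome taxonomy
  (perfect / insertion / small deletion ≤100 bp / large deletion ≤500 kb /
  translocation beyond ±500 kb or orientation-inconsistent / viral
  integration), editing efficiency, top alleles, coding impact;
- **hotspots & expansion** (`pemseq.hotspots`) — normalization to equal
  editing events, bdgpeakcall-style threshold peaks (cutoff 5, min length
  1 bp), orientation uniformity, cross-sample site sharing, vector-genome
  profiles, per-junction proportion tables;
- **pipeline & CLI** (`pemseq.pipeline`, `pemseq` command) — one YAML
  config drives simulate → extract → dedup → classify → normalize →
  hotspots → reports, byte-deterministically.

Everything runs against a built-in toy reference (two 2 Mb chromosomes with
the cut centred on chr1, a 2.8 kb vector with identical 400 bp LTRs), so
the real 500 kb classification bound is exercised verbatim without any
download.

## Worked example

```python
import pemseq
from pemseq.simulate import molecules_from_truth

ref, target, genes = pemseq.build_toy_reference()
cfg = pemseq.preset_cohort("inflammatory", seed=7, n_molecules=20_000)
truth = pemseq.simulate_molecules(cfg, ref, target)

molecules = molecules_from_truth(truth)          # or FASTQ → extract → dedup
events = pemseq.classify_events(molecules, target, viral_name=ref.viral_name)
profile = pemseq.sample_profile(events)
print(f"editing efficiency: {100*profile['editing_efficiency']:.2f}%")
for c, f in sorted(profile["class_frequencies"].items()):
    print(f"  {c:<18} {100*f:6.2f}% of editing events")

tr = events[events["event_class"] == "translocation"]
calls = pemseq.hotspots_from_molecules(tr, genes=genes)
print(f"translocation hotspots: {len(calls)}")
```

prints

```
editing efficiency: 95.22%
  insertion           20.77% of editing events
  large_deletion      16.18% of editing events
  small_deletion      57.61% of editing events
  translocation        1.39% of editing events
  viral_integration    4.05% of editing events
translocation hotspots: 12
```

The `inflammatory` preset models T cells recovered from an inflamed gut:
the library carries 12–17 expanded translocation founder clones, and each
surfaces as a ≥5-junction hotspot at a single nucleotide with orientation
uniformity 1.0 — the clonal-expansion signature. The `activated` preset
(pre-infusion cells, no expansion) yields zero hotspots at the same depth.
The 95% editing efficiency and the ~1% / ~4% translocation / vector
integration rates are the preset study conditions being recovered by the
classifier.

The same analysis from reads:

```bash
pemseq simulate --preset inflammatory --seed 7 --n-molecules 20000 --outdir lib/
pemseq run-all --config run.yaml     # full pipeline from a config file
```

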