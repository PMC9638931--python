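"""Toy reference model for PEM-seq analysis.

A PEM-seq library is anchored at a single Cas9 cut site (the *bait* locus);
every downstream operation — junction extraction, outcome classification,
hotspot calling — is expressed in coordinates relative to that cut. This
module holds the reference bundle (genomic chromosomes plus the retroviral
vector genome with its 5'LTR / payload / 3'LTR elements), the target-site
description, and a BED-backed gene/exon model, together with a deterministic
builder for a desk-scale toy genome in which the real ±500 kb translocation
bound is exercisable verbatim.

Coordinates are 0-based half-open throughout; 1-based closed coordinates
appear only in human-readable report text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceBundle",
    "TargetSite",
    "GeneModel",
    "ReferenceError",
    "load_reference",
    "save_reference",
    "locate_target",
    "build_toy_reference",
    "revcomp",
    "oriented_slice",
    "TOY_GRNA",
    "VIRAL_ELEMENT_NAMES",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: the SpCas9 guide used throughout: targets the first intron of c-Myc.
TOY_GRNA = "GCGGTGAGTCGTGATCTGAG"

VIRAL_ELEMENT_NAMES = ("5LTR", "payload", "3LTR")


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference input."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def oriented_slice(seq: str, pos: int, strand: str, length: int) -> str:
    """Sequence read off a reference starting at ``pos`` in ``strand``
    orientation.

    ``'+'`` walks rightward on the forward strand; ``'-'`` walks leftward
    returning the reverse complement (i.e. the sequence a read would carry
    after fusing to the minus strand at ``pos``). Truncates at reference
    boundaries.
    """
    if strand == "+":
        return seq[pos : pos + length]
    lo = max(0, pos - length + 1)
    return revcomp(seq[lo : pos + 1])


def oriented_avail(seq_len: int, pos: int, strand: str) -> int:
    """Bases available from ``pos`` (inclusive) to the reference edge in
    ``strand`` orientation."""
    return seq_len - pos if strand == "+" else pos + 1


@dataclass
class ReferenceBundle:
    """Genome chromosomes plus the retroviral vector genome.

    ``elements`` maps ``5LTR`` / ``payload`` / ``3LTR`` to half-open
    intervals on the viral sequence. The two LTR copies are identical by
    construction (retroviral direct repeats), which is what makes junctions
    falling wholly inside an LTR intrinsically ambiguous.
    """

    chromosomes: dict[str, str]
    viral_name: str
    viral_seq: str
    elements: dict[str, tuple[int, int]]
    genome_id: str = "toy"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self, allow_n: bool = False) -> None:
        alphabet = set("ACGTN" if allow_n else "ACGT")
        for name, seq in self.all_references().items():
            bad = set(seq) - alphabet
            if bad:
                raise ReferenceError(
                    f"sequence {name!r} contains non-ACGT characters: {sorted(bad)}"
                )
        for el in VIRAL_ELEMENT_NAMES:
            if el not in self.elements:
                raise ReferenceError(f"viral element {el!r} missing")
            s, e = self.elements[el]
            if not (0 <= s < e <= len(self.viral_seq)):
                raise ReferenceError(
                    f"viral element {el!r} interval ({s}, {e}) outside the "
                    f"{len(self.viral_seq)} bp viral genome"
                )
        if self.ltr5_seq() != self.ltr3_seq():
            raise ReferenceError("5'LTR and 3'LTR sequences are not identical copies")

    def all_references(self) -> dict[str, str]:
        refs = dict(self.chromosomes)
        refs[self.viral_name] = self.viral_seq
        return refs

    def get(self, name: str) -> str:
        if name == self.viral_name:
            return self.viral_seq
        return self.chromosomes[name]

    def is_viral(self, name: str) -> bool:
        return name == self.viral_name

    def ltr5_seq(self) -> str:
        s, e = self.elements["5LTR"]
        return self.viral_seq[s:e]

    def ltr3_seq(self) -> str:
        s, e = self.elements["3LTR"]
        return self.viral_seq[s:e]

    def element_of(self, pos: int) -> str:
        """Name of the viral element containing viral position ``pos``."""
        for el in VIRAL_ELEMENT_NAMES:
            s, e = self.elements[el]
            if s <= pos < e:
                return el
        return "flank"

    def mirror_ltr_position(self, pos: int) -> int:
        """Map a 3'LTR position onto the equivalent 5'LTR position
        (identity elsewhere)."""
        s3, e3 = self.elements["3LTR"]
        s5, _ = self.elements["5LTR"]
        if s3 <= pos < e3:
            return pos - s3 + s5
        return pos

    def truncated_chromosomes(self, large_deletion_bound: int) -> list[str]:
        """Chromosomes too short to exercise the ±bound classification rule.

        A chromosome must span at least twice the large-deletion /
        translocation bound for junctions on both sides of the boundary to
        exist; shorter chromosomes are flagged (classification still runs,
        but the far side of the rule is unreachable there).
        """
        return [
            name
            for name, seq in sorted(self.chromosomes.items())
            if len(seq) < 2 * large_deletion_bound
        ]


@dataclass(frozen=True)
class TargetSite:
    """The Cas9 cut locus and bait-primer geometry.

    ``cut_position`` is the 0-based offset of the blunt-cut phosphodiester
    bond (SpCas9 cuts 3 bp 5' of the PAM on the protospacer strand), i.e.
    the first base 3' of the cut on the forward strand. The bait primer
    interval is half-open; ``bait_orientation`` is the direction of primer
    extension toward the cut (this package places the bait on the lower-
    coordinate side, extending ``'+'``).
    """

    chromosome: str
    cut_position: int
    grna_sequence: str
    pam: str
    bait_primer_start: int
    bait_primer_end: int
    bait_orientation: str = "+"
    protospacer_strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.grna_sequence) != 20:
            raise ReferenceError("gRNA must be a 20-mer")
        if not (self.bait_primer_start < self.bait_primer_end):
            raise ReferenceError("bait primer interval is degenerate")
        if self.bait_primer_start <= self.cut_position < self.bait_primer_end:
            raise ReferenceError("bait primer interval must not span the cut")


@dataclass
class GeneModel:
    """Genes and exons as BED6-style half-open intervals."""

    genes: pd.DataFrame  # columns: chrom, start, end, name, strand
    exons: pd.DataFrame  # columns: chrom, start, end, gene, strand

    def __post_init__(self) -> None:
        for df, label in ((self.genes, "gene"), (self.exons, "exon")):
            if ((df["end"] <= df["start"]).any()):
                raise ReferenceError(f"degenerate {label} interval (end <= start)")
        gene_iv = {
            r.name: (r.chrom, r.start, r.end)
            for r in self.genes.itertuples(index=False)
        }
        for r in self.exons.itertuples(index=False):
            if r.gene not in gene_iv:
                raise ReferenceError(f"exon references unknown gene {r.gene!r}")
            c, s, e = gene_iv[r.gene]
            if r.chrom != c or r.start < s or r.end > e:
                raise ReferenceError(f"exon of {r.gene!r} lies outside its gene")

    def _overlaps(self, df: pd.DataFrame, chrom: str, start: int, end: int) -> bool:
        sub = df[df["chrom"] == chrom]
        return bool(((sub["start"] < end) & (sub["end"] > start)).any())

    def overlaps_exon(self, chrom: str, start: int, end: int) -> bool:
        return self._overlaps(self.exons, chrom, start, end)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[str]:
        sub = self.genes[self.genes["chrom"] == chrom]
        hit = sub[(sub["start"] < end) & (sub["end"] > start)]
        return sorted(hit["name"].tolist())

    # -- BED I/O ---------------------------------------------------------
    @staticmethod
    def _read_bed6(path: str | Path) -> pd.DataFrame:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(6),
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        return df

    @classmethod
    def from_bed(cls, genes_bed: str | Path, exons_bed: str | Path) -> "GeneModel":
        g = cls._read_bed6(genes_bed).drop(columns="score")
        e = cls._read_bed6(exons_bed).drop(columns="score")
        e = e.rename(columns={"name": "gene"})
        return cls(genes=g, exons=e)

    def to_bed(self, genes_bed: str | Path, exons_bed: str | Path) -> None:
        g = self.genes.assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]]
        e = self.exons.assign(score=0)[["chrom", "start", "end", "gene", "score", "strand"]]
        g.to_csv(genes_bed, sep="\t", header=False, index=False)
        e.to_csv(exons_bed, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA / BED round trip
# ---------------------------------------------------------------------------

def _read_fasta(path: str | Path, allow_n: bool) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN" if allow_n else "ACGT")
        if bad:
            raise ReferenceError(
                f"FASTA record {rec.id!r} in {path} contains invalid "
                f"characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise ReferenceError(f"no FASTA records parsed from {path}")
    return records


def load_reference(
    genome_path: str | Path,
    viral_path: str | Path,
    elements_path: str | Path,
    *,
    allow_n: bool = False,
    large_deletion_bound: int | None = 500_000,
    genome_id: str = "toy",
) -> ReferenceBundle:
    """Load genome + viral FASTA and the viral element BED into a bundle.

    Warns (and records nothing fatal) when a chromosome is too short to
    exercise the configured ±``large_deletion_bound`` classification rule.
    """
    chromosomes = _read_fasta(genome_path, allow_n)
    viral = _read_fasta(viral_path, allow_n)
    if len(viral) != 1:
        raise ReferenceError(
            f"viral FASTA {viral_path} must hold exactly one record, got {len(viral)}"
        )
    (viral_name, viral_seq), = viral.items()
    bed = pd.read_csv(
        elements_path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name"],
        usecols=range(4),
    )
    elements: dict[str, tuple[int, int]] = {}
    for r in bed.itertuples(index=False):
        if r.chrom != viral_name:
            raise ReferenceError(
                f"element {r.name!r} annotated on {r.chrom!r}, expected "
                f"viral sequence {viral_name!r}"
            )
        elements[r.name] = (int(r.start), int(r.end))
    bundle = ReferenceBundle(
        chromosomes=chromosomes,
        viral_name=viral_name,
        viral_seq=viral_seq,
        elements=elements,
        genome_id=genome_id,
    )
    if large_deletion_bound:
        short = bundle.truncated_chromosomes(large_deletion_bound)
        if short:
            warnings.warn(
                f"chromosomes {short} are shorter than 2x the large-deletion "
                f"bound ({large_deletion_bound} bp); the ±bound rule is "
                "truncated there",
                stacklevel=2,
            )
    return bundle


def save_reference(
    bundle: ReferenceBundle,
    genome_path: str | Path,
    viral_path: str | Path,
    elements_path: str | Path,
) -> None:
    genome_recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(bundle.chromosomes.items())
    ]
    SeqIO.write(genome_recs, str(genome_path), "fasta")
    SeqIO.write(
        [SeqRecord(Seq(bundle.viral_seq), id=bundle.viral_name, description="")],
        str(viral_path),
        "fasta",
    )
    rows = [
        (bundle.viral_name, s, e, name)
        for name, (s, e) in (
            (el, bundle.elements[el]) for el in VIRAL_ELEMENT_NAMES
        )
    ]
    pd.DataFrame(rows).to_csv(elements_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Target-site location
# ---------------------------------------------------------------------------

def _find_protospacers(seq: str, grna: str) -> list[tuple[int, str, int]]:
    """All protospacer+NGG matches on either strand of one chromosome.

    Returns (cut_position, strand, protospacer_start_on_forward).
    """
    hits: list[tuple[int, str, int]] = []
    # forward: grna at p, PAM = seq[p+20:p+23] matching NGG
    p = seq.find(grna)
    while p != -1:
        pam = seq[p + 20 : p + 23]
        if len(pam) == 3 and pam[1:] == "GG":
            hits.append((p + 17, "+", p))
        p = seq.find(grna, p + 1)
    # reverse: revcomp(grna) at q, PAM (revcomp) = CCN at q-3
    rc = revcomp(grna)
    q = seq.find(rc)
    while q != -1:
        pam_rc = seq[q - 3 : q]
        if len(pam_rc) == 3 and pam_rc[:2] == "CC":
            hits.append((q + 3, "-", q))
        q = seq.find(rc, q + 1)
    return hits


def locate_target(
    bundle: ReferenceBundle,
    grna: str,
    *,
    pam_rule: str = "NGG",
    bait_primer_length: int = 20,
    bait_primer_offset: int = 80,
) -> TargetSite:
    """Locate a unique SpCas9 protospacer (NGG PAM, either strand) and derive
    the cut coordinate, 3 bp 5' of the PAM on the protospacer strand.

    The bait primer is placed on the lower-coordinate side of the cut,
    ``bait_primer_offset`` bp upstream, extending ``'+'`` toward the cut —
    the geometry the simulator and extractor share.
    """
    if pam_rule != "NGG":
        raise ReferenceError("only the SpCas9 NGG PAM rule is supported")
    grna = grna.upper()
    if len(grna) != 20:
        raise ReferenceError("gRNA must be a 20-mer")
    all_hits: list[tuple[str, int, str, int]] = []
    for name, seq in sorted(bundle.chromosomes.items()):
        for cut, strand, p in _find_protospacers(seq, grna):
            all_hits.append((name, cut, strand, p))
    if len(all_hits) != 1:
        raise ReferenceError(
            f"expected exactly one protospacer+PAM match, found {len(all_hits)}"
        )
    chrom, cut, strand, p = all_hits[0]
    seq = bundle.chromosomes[chrom]
    pam = seq[p + 20 : p + 23] if strand == "+" else revcomp(seq[p - 3 : p])
    primer_end = cut - bait_primer_offset + bait_primer_length
    if cut - bait_primer_offset < 0 or primer_end > cut:
        raise ReferenceError("bait primer does not fit upstream of the cut")
    return TargetSite(
        chromosome=chrom,
        cut_position=cut,
        grna_sequence=grna,
        pam=pam,
        bait_primer_start=cut - bait_primer_offset,
        bait_primer_end=primer_end,
        bait_orientation="+",
        protospacer_strand=strand,
    )


# ---------------------------------------------------------------------------
# Toy reference builder
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytes(lut[rng.integers(0, 4, n)]).decode("ascii")


def _default_gene_model(chrom_length: int, cut_position: int) -> GeneModel:
    # A c-Myc-like three-exon gene straddling the cut (which sits in intron 1,
    # 500 bp downstream of exon 1), plus well-separated genes on both
    # chromosomes for hotspot annotation. Non-Myc genes sit at fixed fractions
    # of the chromosome so scaled-down toy genomes keep the same layout.
    L = chrom_length
    myc = ("chr1", cut_position - 5_000, cut_position + 15_000, "Myc", "+")
    fractional = [
        ("chr1", 0.05, 0.07, "GeneA1", "+"),
        ("chr1", 0.15, 0.18, "GeneA2", "-"),
        ("chr1", 0.30, 0.325, "GeneA3", "+"),
        ("chr1", 0.80, 0.84, "GeneA4", "-"),
        ("chr1", 0.90, 0.925, "GeneA5", "+"),
        ("chr2", 0.025, 0.06, "GeneB1", "+"),
        ("chr2", 0.20, 0.235, "GeneB2", "-"),
        ("chr2", 0.45, 0.48, "GeneB3", "+"),
        ("chr2", 0.60, 0.645, "GeneB4", "+"),
        ("chr2", 0.85, 0.88, "GeneB5", "-"),
    ]
    genes = [
        (c, int(f0 * L), int(f1 * L), name, strand)
        for c, f0, f1, name, strand in fractional
    ]
    genes.insert(3, myc)
    exons = []
    for chrom, s, e, name, strand in genes:
        if name == "Myc":
            exons += [
                (chrom, s, cut_position - 4_500, name, strand),
                (chrom, cut_position + 5_000, cut_position + 5_800, name, strand),
                (chrom, e - 1_000, e, name, strand),
            ]
        else:
            third = (e - s) // 3
            exons += [
                (chrom, s, s + third // 2, name, strand),
                (chrom, e - third // 2, e, name, strand),
            ]
    return GeneModel(
        genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "name", "strand"]),
        exons=pd.DataFrame(exons, columns=["chrom", "start", "end", "gene", "strand"]),
    )


def build_toy_reference(
    *,
    seed: int = 20,
    chrom_length: int = 2_000_000,
    n_chromosomes: int = 2,
    ltr_length: int = 400,
    payload_length: int = 2_000,
    cut_position: int = 1_000_000,
) -> tuple[ReferenceBundle, TargetSite, GeneModel]:
    """Deterministically build the desk-scale reference.

    Two 2 Mb chromosomes keep the paper's ±500 kb translocation bound usable
    verbatim with the cut centred on chr1. The retroviral vector is a
    fabricated 2.8 kb sequence with identical 400 bp LTRs flanking a 2 kb
    payload (the paper does not give the vector sequence; only the LTR
    direct-repeat structure matters to the analysis).
    """
    if not (20_000 <= cut_position <= chrom_length - 20_000):
        raise ReferenceError("cut must lie well inside the chromosome")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    chroms = {name: _random_seq(rng, chrom_length) for name in names}

    # embed the protospacer + AGG PAM so the blunt cut lands at cut_position
    proto_start = cut_position - 17
    site = TOY_GRNA + "AGG"
    s = chroms["chr1"]
    chroms["chr1"] = s[:proto_start] + site + s[proto_start + len(site) :]

    ltr = _random_seq(rng, ltr_length)
    payload = _random_seq(rng, payload_length)
    viral_seq = ltr + payload + ltr
    elements = {
        "5LTR": (0, ltr_length),
        "payload": (ltr_length, ltr_length + payload_length),
        "3LTR": (ltr_length + payload_length, len(viral_seq)),
    }
    bundle = ReferenceBundle(
        chromosomes=chroms,
        viral_name="RV",
        viral_seq=viral_seq,
        elements=elements,
        genome_id=f"toy-{seed}",
    )
    # the protospacer must be unique genome-wide for locate_target;
    # a random-sequence collision has probability ~L/4^20 and the fixed
    # builder seed is verified by the test suite
    target = locate_target(bundle, TOY_GRNA)
    if target.chromosome != "chr1" or target.cut_position != cut_position:
        raise ReferenceError("toy genome failed to place the target site")
    genes = _default_gene_model(chrom_length, cut_position)
    return bundle, target, genes
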