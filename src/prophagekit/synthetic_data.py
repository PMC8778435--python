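"""Synthetic genome cohorts with planted, machine-readable truth.

The generator emulates a cohort of closely related bacterial isolates the way
the analysis modules expect to see them: a shared chromosomal backbone with
core genes, accessory genes present in subsets of isolates, per-isolate
unique genes, tRNA loci whose 3' ends double as integration cores, planted
prophages (attL/attR direct repeats at tRNA genes, hallmark virion genes,
per-clade divergence), CRISPR repeat-spacer arrays whose spacers target the
planted prophages with controlled mismatch counts and optional 5'-TCC PAMs,
diversity-generating retroelements (RT gene plus a TR/VR repeat pair whose
differences are confined to defined variable sites), Rin shufflons
(rix-motif-delimited Rv cassettes next to a recombinase and an Rc gene), and
per-base depth profiles with elevated coverage over induced prophages.

Everything is deterministic under a fixed seed, and every truth interval can
be sliced back out of the emitted sequence.  Background sequence is
rejection-scrubbed so that rix motifs, att cores and the CRISPR repeat occur
only where they were planted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import (Feature, FeatureKind, GenomeRecord, reverse_complement,
                    write_fasta, write_gff)

# att core of the best-characterised clade-1-style element; the remaining
# clades receive randomly drawn cores of comparable length.
CLADE1_ATT_CORE = "CAACCCCATGGAGGTTCAAGTCCTCTCGCCCGCACCATCTGAA"

TRNA_ISOTYPES = ("Leu", "Ser", "Arg", "Ala")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

HALLMARK_PRODUCTS = (
    "terminase, large subunit",
    "portal protein",
    "major capsid protein",
)

_BACKBONE_PRODUCTS = (
    "DNA gyrase subunit A", "elongation factor Tu", "ribosomal protein L2",
    "ATP synthase subunit beta", "DNA-directed RNA polymerase subunit beta",
    "chaperonin GroEL", "recombinase RecA", "cell division protein FtsZ",
    "preprotein translocase SecY", "phosphoglycerate kinase",
)

_PHAGE_FILLER_PRODUCTS = (
    "hypothetical protein", "tail tape measure protein",
    "head-tail adaptor protein", "holin", "endolysin (amidase)",
    "Cro/C1-type transcriptional repressor", "ssDNA binding protein",
    "tail completion protein", "baseplate upper protein",
    "DNA replication protein",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions the analysis targets: ~0.635 host
    GC, prophages of 32-42 kb at GC 0.58-0.67 integrating at tRNA genes,
    130 bp template repeats with 10 variable sites, 34-nt spacers and the
    asymmetric 8-mer rix motif.  The genome length is a 300 kb scaled-down
    stand-in for the multi-megabase chromosomes so whole-pipeline runs stay
    desk-scale; all detection thresholds downstream are length-independent.
    The seed is mandatory: there is no silent nondeterminism.
    """

    seed: int
    n_genomes: int = 10
    genome_length: int = 300_000
    gc_content: float = 0.635
    prophage_size_range: tuple[int, int] = (32_000, 42_000)
    prophage_gc_range: tuple[float, float] = (0.58, 0.67)
    clade_sizes: tuple[int, ...] = (3, 2, 2, 2)
    clade_divergence: float = 0.015
    related_clade_pair: tuple[int, int] | None = (2, 3)
    related_divergence: float = 0.10
    tr_length: int = 130
    tr_length_embedded: int = 123
    n_variable_sites: int = 10
    n_rv_cassettes: int = 3
    rix_motif: str = "ttccgtat"
    spacer_length: int = 34
    repeat_length: int = 29
    n_core_genes: int = 25
    n_accessory_genes: int = 20
    n_unique_genes: int = 5
    n_decoy_spacers: int = 2
    base_depth: float = 50.0
    induction_range: tuple[float, float] = (1.1, 5.2)

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        lo, hi = self.prophage_size_range
        if not 0 < lo < hi:
            raise ValueError("prophage_size_range must be non-degenerate")
        if hi >= self.genome_length:
            raise ValueError("prophage size must be smaller than the genome")
        if not 120 <= self.tr_length <= 135:
            raise ValueError("tr_length must lie in [120, 135]")
        if self.n_variable_sites > 0.10 * min(self.tr_length,
                                              self.tr_length_embedded):
            raise ValueError(
                "variable sites incompatible with >90% TR/VR identity")
        if not 23 <= self.repeat_length <= 47:
            raise ValueError("repeat_length must lie in [23, 47]")
        if not 26 <= self.spacer_length <= 50:
            raise ValueError("spacer_length must lie in [26, 50]")
        glo, ghi = self.induction_range
        if glo < 1.0 or ghi < glo:
            raise ValueError("induction factors must be >= 1")
        if self.clade_sizes and self.n_genomes < 3:
            raise ValueError("prophage planting needs at least 3 genomes")
        if self.related_clade_pair is not None and self.clade_sizes:
            a, b = self.related_clade_pair
            if not (0 <= a < len(self.clade_sizes)
                    and 0 <= b < len(self.clade_sizes)) or a == b:
                raise ValueError("invalid related_clade_pair")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------

@dataclass
class DGRTruth:
    rt: tuple[int, int]
    mtd: tuple[int, int]
    avd: tuple[int, int] | None
    tr: tuple[int, int]
    vr: tuple[int, int]
    variable_sites: list[int]        # 0-based offsets within VR
    architecture: str                # TR_upstream_of_ert | TR_within_ert


@dataclass
class ShufflonTruth:
    rin: tuple[int, int]
    rc: tuple[int, int]
    rix_direct: list[int]
    rix_inverted: list[int]
    rv_segments: list[tuple[int, int]]


@dataclass
class ProphageTruth:
    prophage_id: str
    genome_id: str
    start: int
    end: int                          # region = interior + one att copy
    clade: int                        # 1-based clade label
    att_core: str | None
    attB_isotype: str | None
    attB_locus_tag: str | None
    induction_factor: float
    dgr: DGRTruth | None = None
    shufflon: ShufflonTruth | None = None


@dataclass
class SpacerTruth:
    spacer_id: str
    array_genome: str
    sequence: str
    prophage_id: str | None           # None for decoy spacers
    position: tuple[int, int] | None  # protospacer interval on host genome
    position_in_prophage: tuple[int, int] | None
    strand: str | None
    mismatches: int | None
    pam: bool


@dataclass
class ArrayTruth:
    genome_id: str
    start: int
    end: int
    repeat: str
    spacer_ids: list[str]


@dataclass
class SyntheticTruth:
    """Ground truth for one generated cohort; JSON round-trips losslessly."""

    prophages: list[ProphageTruth] = field(default_factory=list)
    arrays: list[ArrayTruth] = field(default_factory=list)
    spacers: list[SpacerTruth] = field(default_factory=list)

    def prophage(self, prophage_id: str) -> ProphageTruth:
        for p in self.prophages:
            if p.prophage_id == prophage_id:
                return p
        raise KeyError(prophage_id)

    def prophages_of(self, genome_id: str) -> list[ProphageTruth]:
        return [p for p in self.prophages if p.genome_id == genome_id]

    def to_json(self, path: str | Path | None = None) -> str:
        def _convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: _convert(v) for k, v in
                        dataclasses.asdict(obj).items()}
            return obj

        text = json.dumps(_convert(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)

        def _tup(x):
            return tuple(x) if x is not None else None

        prophages = []
        for p in data["prophages"]:
            dgr = p.get("dgr")
            if dgr is not None:
                dgr = DGRTruth(rt=_tup(dgr["rt"]), mtd=_tup(dgr["mtd"]),
                               avd=_tup(dgr["avd"]), tr=_tup(dgr["tr"]),
                               vr=_tup(dgr["vr"]),
                               variable_sites=list(dgr["variable_sites"]),
                               architecture=dgr["architecture"])
            shuf = p.get("shufflon")
            if shuf is not None:
                shuf = ShufflonTruth(
                    rin=_tup(shuf["rin"]), rc=_tup(shuf["rc"]),
                    rix_direct=list(shuf["rix_direct"]),
                    rix_inverted=list(shuf["rix_inverted"]),
                    rv_segments=[tuple(i) for i in shuf["rv_segments"]])
            prophages.append(ProphageTruth(
                prophage_id=p["prophage_id"], genome_id=p["genome_id"],
                start=p["start"], end=p["end"], clade=p["clade"],
                att_core=p["att_core"], attB_isotype=p["attB_isotype"],
                attB_locus_tag=p["attB_locus_tag"],
                induction_factor=p["induction_factor"], dgr=dgr,
                shufflon=shuf))
        arrays = [ArrayTruth(**a) for a in data["arrays"]]
        spacers = [SpacerTruth(
            spacer_id=s["spacer_id"], array_genome=s["array_genome"],
            sequence=s["sequence"], prophage_id=s["prophage_id"],
            position=_tup(s["position"]),
            position_in_prophage=_tup(s["position_in_prophage"]),
            strand=s["strand"], mismatches=s["mismatches"], pam=s["pam"])
            for s in data["spacers"]]
        return cls(prophages=prophages, arrays=arrays, spacers=spacers)


# ---------------------------------------------------------------------------
# sequence sampling primitives
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return rng.choice(_BASES, size=n, p=p).tobytes().decode("ascii")


_STOPS = {"TAA", "TAG", "TGA"}


def random_orf(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + GC-weighted stop-free codons + TAA; length = 3 * n_codons."""
    if n_codons < 3:
        raise ValueError("ORF needs at least 3 codons")
    body = list(random_dna(rng, 3 * (n_codons - 2), gc))
    for i in range(0, len(body), 3):
        if "".join(body[i:i + 3]) in _STOPS:
            body[i + 1] = "C"  # breaks every stop codon
    return "ATG" + "".join(body) + "TAA"


def mutate(seq: str, rate: float, rng: np.random.Generator,
           protected: Sequence[tuple[int, int]] = ()) -> str:
    """Per-base substitutions at the given rate, sparing protected intervals."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for s, e in protected:
        hit[s:e] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _overlaps(pos: int, length: int,
              intervals: Sequence[tuple[int, int]], margin: int = 0) -> bool:
    return any(pos < e + margin and s - margin < pos + length
               for s, e in intervals)


def scrub_motifs(seq: str, motifs: Sequence[str], rng: np.random.Generator,
                 protected: Sequence[tuple[int, int]] = ()) -> str:
    """Destroy accidental motif occurrences (both orientations) by point
    changes, leaving protected intervals untouched."""
    targets = set()
    for m in motifs:
        m = m.upper()
        targets.add(m)
        targets.add(reverse_complement(m))
    chars = list(seq)
    for _ in range(20):  # each pass destroys all current occurrences
        dirty = False
        text = "".join(chars)
        for motif in targets:
            start = 0
            while (pos := text.find(motif, start)) != -1:
                start = pos + 1
                if _overlaps(pos, len(motif), protected):
                    continue
                mid = pos + len(motif) // 2
                choices = [b for b in "ACGT" if b != chars[mid]]
                chars[mid] = choices[rng.integers(len(choices))]
                dirty = True
        if not dirty:
            return "".join(chars)
    raise RuntimeError("motif scrubbing did not converge")


# ---------------------------------------------------------------------------
# genome-level planting operations
# ---------------------------------------------------------------------------

def _shift_features(features: list[Feature], at: int, length: int) -> None:
    for f in features:
        if f.start >= at:
            f.start += length
            f.end += length


def plant_prophage(genome: GenomeRecord, interior: str, att_core: str,
                   trna: Feature,
                   interior_features: Sequence[Feature] = ()) -> tuple[GenomeRecord, tuple[int, int]]:
    """Insert a prophage immediately after a tRNA whose 3' end carries the
    att core, duplicating the core as flanking direct repeats (attL/attR).

    The reported interval is ``interior + attR`` (one att copy), so
    excision arithmetic is exact: removing the interval restores the host
    byte-for-byte.  Returns the new genome and the region interval.
    """
    att_core = att_core.upper()
    if not 20 <= len(att_core) <= 60:
        raise ValueError("att core length out of range")
    t_end = trna.end
    if genome.sequence[t_end - len(att_core):t_end] != att_core:
        raise ValueError(
            f"att core not found at the 3' end of the tRNA in {genome.id}")
    insert = interior + att_core
    new_seq = genome.sequence[:t_end] + insert + genome.sequence[t_end:]
    new_features = [Feature(kind=f.kind, start=f.start, end=f.end,
                            strand=f.strand, attributes=dict(f.attributes))
                    for f in genome.features]
    _shift_features(new_features, t_end, len(insert))
    for f in interior_features:
        new_features.append(Feature(kind=f.kind, start=f.start + t_end,
                                    end=f.end + t_end, strand=f.strand,
                                    attributes=dict(f.attributes)))
    region = (t_end, t_end + len(insert))
    return GenomeRecord(id=genome.id, sequence=new_seq,
                        features=new_features), region


def plant_crispr_array(genome: GenomeRecord, position: int, repeat: str,
                       spacers: Sequence[str]) -> tuple[GenomeRecord, tuple[int, int]]:
    """Insert a repeat-spacer-...-repeat array at the given position."""
    repeat = repeat.upper()
    if not 23 <= len(repeat) <= 47:
        raise ValueError("repeat length must lie in [23, 47]")
    if len(spacers) < 2:
        raise ValueError("an array needs >= 3 repeat copies (>= 2 spacers)")
    for sp in spacers:
        if not 26 <= len(sp) <= 50:
            raise ValueError("spacer lengths must lie in [26, 50]")
    body = repeat + "".join(sp.upper() + repeat for sp in spacers)
    new_seq = genome.sequence[:position] + body + genome.sequence[position:]
    new_features = [Feature(kind=f.kind, start=f.start, end=f.end,
                            strand=f.strand, attributes=dict(f.attributes))
                    for f in genome.features]
    _shift_features(new_features, position, len(body))
    interval = (position, position + len(body))
    new_features.append(Feature(
        kind=FeatureKind.CRISPR_array, start=interval[0], end=interval[1],
        attributes={"n_spacers": str(len(spacers))}))
    return GenomeRecord(id=genome.id, sequence=new_seq,
                        features=new_features), interval


def derive_spacer(protospacer: str, mismatches: int,
                  rng: np.random.Generator) -> str:
    """A spacer differing from its protospacer at exactly the given count."""
    if mismatches > len(protospacer):
        raise ValueError("more mismatches than spacer positions")
    chars = list(protospacer.upper())
    for i in rng.choice(len(chars), size=mismatches, replace=False):
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def simulate_depth(genome_length: int,
                   prophage_intervals: Sequence[tuple[int, int, float]],
                   base_depth: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-base Poisson depth; prophage intervals get base * factor.

    ``prophage_intervals`` is (start, end, induction_factor); factors < 1
    are rejected.
    """
    depth = rng.poisson(base_depth, size=genome_length)
    for start, end, factor in prophage_intervals:
        if factor < 1.0:
            raise ValueError("induction factor must be >= 1")
        depth[start:end] = rng.poisson(base_depth * factor, size=end - start)
    return depth.astype(np.int64)


def write_depth_tsv(path: str | Path,
                    profiles: dict[str, np.ndarray]) -> None:
    """BED-like depth track: chrom, 0-based position, depth."""
    with open(path, "w") as fh:
        for genome_id, depth in profiles.items():
            for pos, d in enumerate(depth):
                fh.write(f"{genome_id}\t{pos}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# prophage interior construction
# ---------------------------------------------------------------------------

@dataclass
class _Interior:
    sequence: str
    features: list[Feature]
    protected: list[tuple[int, int]]
    dgr: DGRTruth | None
    shufflon: ShufflonTruth | None
    gc: float


class _Builder:
    """Cursor-based sequence assembly with relative feature bookkeeping."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.cursor = 0
        self.features: list[Feature] = []
        self.protected: list[tuple[int, int]] = []

    def append(self, seq: str) -> tuple[int, int]:
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return (start, self.cursor)

    def append_gene(self, seq: str, product: str, strand: str = "+",
                    kind: FeatureKind = FeatureKind.gene) -> Feature:
        start, end = self.append(seq)
        feat = Feature(kind=kind, start=start, end=end, strand=strand,
                       attributes={"product": product})
        self.features.append(feat)
        return feat

    def protect(self, interval: tuple[int, int]) -> None:
        self.protected.append(interval)

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def plant_dgr(builder: _Builder, rng: np.random.Generator,
              cfg: SimulationConfig, embedded: bool) -> DGRTruth:
    """Append a DGR block: mtd carrying the VR, optional avd, TR and the
    RT (*ert*) gene; the TR either sits just upstream of ert or embedded
    within it.  The ancestral VR equals the TR; member-level substitutions
    at the variable sites are applied later."""
    gc = 0.62
    tr_len = cfg.tr_length_embedded if embedded else cfg.tr_length
    n_sites = cfg.n_variable_sites
    if n_sites > 0.10 * tr_len:
        raise ValueError("variable sites incompatible with >90% identity")

    # variable-site offsets leaving at least one exact run of >= 21 nt so
    # that seed-based repeat detection always fires
    while True:
        sites = sorted(int(x) for x in
                       rng.choice(tr_len - 4, size=n_sites, replace=False) + 2)
        gaps = np.diff([0] + sites + [tr_len])
        if n_sites == 0 or gaps.max() >= 21:
            break

    tr_content = random_orf(rng, tr_len // 3 + 2, gc)[3:3 + tr_len]

    if not embedded:
        # layout: mtd(VR at 3' end) .. avd .. TR .. ert
        mtd_codons = int(rng.integers(150, 190))
        mtd = random_orf(rng, mtd_codons, gc)
        vr_off = len(mtd) - 3 - tr_len
        mtd = mtd[:vr_off] + tr_content + mtd[vr_off + tr_len:]
        mtd_feat = builder.append_gene(mtd, "major tropism determinant (mtd)")
        vr = (mtd_feat.start + vr_off, mtd_feat.start + vr_off + tr_len)
        builder.append(random_dna(rng, 40, gc))
        avd_feat = builder.append_gene(
            random_orf(rng, 85, gc), "accessory variability determinant (avd)")
        avd = avd_feat.interval
        builder.append(random_dna(rng, 60, gc))
        tr = builder.append(tr_content)
        builder.append(random_dna(rng, 45, gc))
        rt_feat = builder.append_gene(
            random_orf(rng, int(rng.integers(280, 330)), gc),
            "reverse transcriptase (ert)")
        architecture = "TR_upstream_of_ert"
    else:
        # layout: mtd(VR at 5' end) .. ert with the TR inside the gene
        mtd_codons = int(rng.integers(150, 190))
        mtd = random_orf(rng, mtd_codons, gc)
        vr_off = 6
        mtd = mtd[:vr_off] + tr_content + mtd[vr_off + tr_len:]
        mtd_feat = builder.append_gene(mtd, "major tropism determinant (mtd)")
        vr = (mtd_feat.start + vr_off, mtd_feat.start + vr_off + tr_len)
        avd = None
        builder.append(random_dna(rng, 80, gc))
        ert = random_orf(rng, int(rng.integers(300, 340)), gc)
        tr_off = 3 * int(rng.integers(40, 60))
        ert = ert[:tr_off] + tr_content + ert[tr_off + tr_len:]
        rt_feat = builder.append_gene(ert, "reverse transcriptase (ert)")
        tr = (rt_feat.start + tr_off, rt_feat.start + tr_off + tr_len)
        architecture = "TR_within_ert"

    builder.protect((tr[0] - 2, tr[1] + 2))
    builder.protect((vr[0] - 2, vr[1] + 2))
    return DGRTruth(rt=rt_feat.interval, mtd=mtd_feat.interval, avd=avd,
                    tr=tr, vr=vr, variable_sites=sites,
                    architecture=architecture)


def plant_shufflon(builder: _Builder, rng: np.random.Generator,
                   cfg: SimulationConfig) -> ShufflonTruth:
    """Append a Rin shufflon: recombinase, n_rv rix-delimited Rv cassettes
    (direct rix orientation), then the Rc gene with one inverted rix inside
    the gene and one just downstream of its stop codon.  Rv 3' segments are
    diverged copies of the Rc C-terminus."""
    if cfg.n_rv_cassettes < 1:
        raise ValueError("shufflon needs at least one Rv cassette")
    gc = 0.62
    motif = cfg.rix_motif.upper()
    rix_inv = reverse_complement(motif)

    rin_feat = builder.append_gene(
        random_orf(rng, 190, gc),
        "site-specific DNA invertase (Rin shufflon recombinase)")
    builder.append(random_dna(rng, 55, gc))

    # Rc built first so Rv cassettes can borrow its C-terminus
    rc_codons = 320
    rc = random_orf(rng, rc_codons, gc)
    c_term = rc[len(rc) - 3 - 120:len(rc) - 3]

    rix_direct: list[int] = []
    rv_segments: list[tuple[int, int]] = []
    for _ in range(cfg.n_rv_cassettes):
        pos = builder.append(motif)
        builder.protect(pos)
        rix_direct.append(pos[0])
        unique = random_dna(rng, int(rng.integers(70, 110)), gc)
        homolog = mutate(c_term, 0.38, rng)
        rv = builder.append(unique + homolog)
        rv_segments.append(rv)
    pos = builder.append(motif)
    builder.protect(pos)
    rix_direct.append(pos[0])

    builder.append(random_dna(rng, 30, gc))
    # inverted rix embedded within Rc, upstream of its C-terminal segment
    inside_off = 3 * 60
    rc = rc[:inside_off] + rix_inv + rc[inside_off + len(motif):]
    rc_feat = builder.append_gene(rc, "receptor-binding protein (Rc)")
    rix_inverted = [rc_feat.start + inside_off]
    builder.protect((rix_inverted[0], rix_inverted[0] + len(motif)))
    pos = builder.append(rix_inv)  # just after the Rc stop codon
    builder.protect(pos)
    rix_inverted.append(pos[0])
    return ShufflonTruth(rin=rin_feat.interval, rc=rc_feat.interval,
                         rix_direct=rix_direct, rix_inverted=rix_inverted,
                         rv_segments=rv_segments)


def _build_interior(rng: np.random.Generator, cfg: SimulationConfig,
                    style: str, att_len: int) -> _Interior:
    """Ancestral prophage interior: integrase, hallmark virion genes, the
    optional DGR/shufflon block and filler genes up to the target size."""
    gc = float(rng.uniform(*cfg.prophage_gc_range))
    lo, hi = cfg.prophage_size_range
    target = int(rng.integers(lo, hi)) - att_len

    b = _Builder()
    b.append(random_dna(rng, 120, gc))
    b.append_gene(random_orf(rng, 200, gc), "integrase (tyrosine recombinase)")
    b.append(random_dna(rng, 150, gc))

    dgr = shufflon = None
    if style == "shufflon":
        shufflon = plant_shufflon(b, rng, cfg)
    elif style in {"dgr_upstream", "dgr_embedded"}:
        dgr = plant_dgr(b, rng, cfg, embedded=(style == "dgr_embedded"))
    b.append(random_dna(rng, 150, gc))
    for product in HALLMARK_PRODUCTS:
        b.append_gene(random_orf(rng, int(rng.integers(180, 260)), gc),
                      product)
        b.append(random_dna(rng, int(rng.integers(80, 160)), gc))
    while b.cursor < target - 1200:
        product = _PHAGE_FILLER_PRODUCTS[
            int(rng.integers(len(_PHAGE_FILLER_PRODUCTS)))]
        b.append_gene(random_orf(rng, int(rng.integers(110, 280)), gc),
                      product)
        b.append(random_dna(rng, int(rng.integers(60, 180)), gc))
    b.append(random_dna(rng, max(0, target - b.cursor), gc))
    seq = b.sequence
    if dgr is not None:
        # the two columns flanking TR and VR on each side must disagree,
        # otherwise the planted repeat pair could extend by chance agreement
        chars = list(seq)
        for t_edge, v_edge in ((dgr.tr[0] - 1, dgr.vr[0] - 1),
                               (dgr.tr[0] - 2, dgr.vr[0] - 2),
                               (dgr.tr[1], dgr.vr[1]),
                               (dgr.tr[1] + 1, dgr.vr[1] + 1)):
            if chars[t_edge] == chars[v_edge]:
                chars[v_edge] = next(x for x in "ACGT"
                                     if x != chars[t_edge])
        seq = "".join(chars)
    return _Interior(sequence=seq, features=b.features,
                     protected=b.protected, dgr=dgr, shufflon=shufflon, gc=gc)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class _MemberPlan:
    prophage_id: str
    genome_id: str
    clade: int                     # 1-based
    isotype: str
    att_core: str
    interior: str
    features: list[Feature]
    protected: list[tuple[int, int]]
    dgr: DGRTruth | None
    shufflon: ShufflonTruth | None
    protospacers: list[dict] = field(default_factory=list)


def _relabel(truth, offset: int):
    """Shift a relative DGR/Shufflon truth record by a genome offset."""
    if truth is None:
        return None
    if isinstance(truth, DGRTruth):
        sh = lambda t: (t[0] + offset, t[1] + offset)  # noqa: E731
        return DGRTruth(rt=sh(truth.rt), mtd=sh(truth.mtd),
                        avd=sh(truth.avd) if truth.avd else None,
                        tr=sh(truth.tr), vr=sh(truth.vr),
                        variable_sites=list(truth.variable_sites),
                        architecture=truth.architecture)
    sh = lambda t: (t[0] + offset, t[1] + offset)  # noqa: E731
    return ShufflonTruth(rin=sh(truth.rin), rc=sh(truth.rc),
                         rix_direct=[p + offset for p in truth.rix_direct],
                         rix_inverted=[p + offset for p in truth.rix_inverted],
                         rv_segments=[sh(t) for t in truth.rv_segments])


def generate_cohort(cfg: SimulationConfig) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate the cohort and its truth table.

    Deterministic given ``cfg.seed``; every planted interval matches its
    genome slice.  Genome 0 carries no prophage and serves as the
    prophage-free delineation reference.
    """
    rng = np.random.default_rng(cfg.seed)
    gc = cfg.gc_content

    # --- clade models -----------------------------------------------------
    styles = ["shufflon", "dgr_embedded", "dgr_upstream", "plain"]
    att_cores: list[str] = []
    n_clades = len(cfg.clade_sizes)
    for c in range(n_clades):
        if c == 0:
            att_cores.append(CLADE1_ATT_CORE)
        else:
            att_cores.append(random_dna(rng, int(rng.integers(42, 46)), 0.55))
    crispr_repeat = random_dna(rng, cfg.repeat_length, 0.5)
    rix = cfg.rix_motif.upper()
    forbidden = [rix, crispr_repeat] + att_cores

    ancestors: list[_Interior] = []
    for c in range(n_clades):
        style = styles[c % len(styles)]
        related = (cfg.related_clade_pair is not None
                   and c == cfg.related_clade_pair[1])
        if related:
            src = ancestors[cfg.related_clade_pair[0]]
            seq = mutate(src.sequence, cfg.related_divergence, rng,
                         protected=src.protected)
            seq = scrub_motifs(seq, forbidden, rng, protected=src.protected)
            feats = [Feature(kind=f.kind, start=f.start, end=f.end,
                             strand=f.strand, attributes=dict(f.attributes))
                     for f in src.features]
            ancestors.append(_Interior(
                sequence=seq, features=feats, protected=list(src.protected),
                dgr=src.dgr, shufflon=src.shufflon, gc=src.gc))
        else:
            interior = _build_interior(rng, cfg, style,
                                       att_len=len(att_cores[c]))
            interior.sequence = scrub_motifs(
                interior.sequence, forbidden, rng,
                protected=interior.protected)
            ancestors.append(interior)

    # --- member derivation and genome assignment --------------------------
    members: list[_MemberPlan] = []
    occupancy: dict[str, set[str]] = {}
    host_cycle = 0
    for c, size in enumerate(cfg.clade_sizes):
        isotype = TRNA_ISOTYPES[c % len(TRNA_ISOTYPES)]
        anc = ancestors[c]
        for m in range(size):
            # next host genome (1..n-1) whose isotype slot is free
            for _ in range(cfg.n_genomes):
                gid = f"G{1 + host_cycle % (cfg.n_genomes - 1):02d}"
                host_cycle += 1
                if isotype not in occupancy.setdefault(gid, set()):
                    occupancy[gid].add(isotype)
                    break
            else:
                raise ValueError("could not place all prophage members")
            seq = mutate(anc.sequence, cfg.clade_divergence, rng,
                         protected=anc.protected)
            dgr = anc.dgr
            if dgr is not None and dgr.variable_sites:
                chars = list(seq)
                vr0 = dgr.vr[0]
                for off in dgr.variable_sites:
                    current = chars[vr0 + off]
                    choices = [x for x in "ACGT" if x != current]
                    chars[vr0 + off] = choices[rng.integers(len(choices))]
                seq = "".join(chars)
            seq = scrub_motifs(seq, forbidden, rng, protected=anc.protected)
            members.append(_MemberPlan(
                prophage_id=f"{gid}phi{c + 1}", genome_id=gid, clade=c + 1,
                isotype=isotype, att_core=att_cores[c], interior=seq,
                features=[Feature(kind=f.kind, start=f.start, end=f.end,
                                  strand=f.strand,
                                  attributes=dict(f.attributes))
                          for f in anc.features],
                protected=list(anc.protected), dgr=anc.dgr,
                shufflon=anc.shufflon))

    # --- CRISPR spacer planning -------------------------------------------
    spacer_specs: list[dict] = []   # per array-genome spec dicts
    if members and cfg.n_genomes >= 4:
        array_hosts = [f"G{cfg.n_genomes - 1:02d}"]
        clade1_hosts = [m.genome_id for m in members if m.clade == 1]
        if clade1_hosts:
            array_hosts.append(clade1_hosts[0])      # self-targeting array
        lysogens = sorted({m.genome_id for m in members})
        for gid in lysogens:
            if gid not in array_hosts:
                array_hosts.append(gid)
                break
        first_of_clade = {}
        for m in members:
            first_of_clade.setdefault(m.clade, m)
        targets = list(first_of_clade.values())
        mm_cycle = [0, 1, 2, 3]
        strands = ["+", "+", "-", "+"]
        pams = [True, False, False, True]
        for i, tgt in enumerate(targets):
            spacer_specs.append(dict(
                array_genome=array_hosts[0], member=tgt,
                mismatches=mm_cycle[i % 4], strand=strands[i % 4],
                pam=pams[i % 4]))
        # one spacer beyond the recovery rule (4 mismatches)
        spacer_specs.append(dict(
            array_genome=array_hosts[0], member=targets[-1],
            mismatches=4, strand="+", pam=False))
        if len(array_hosts) > 1:
            host = array_hosts[1]
            own = next(m for m in members
                       if m.genome_id == host and m.clade == 1)
            spacer_specs.append(dict(array_genome=host, member=own,
                                     mismatches=0, strand="+", pam=True))
            other = next((m for m in members if m.genome_id != host),
                         None)
            if other is not None:
                spacer_specs.append(dict(array_genome=host, member=other,
                                         mismatches=3, strand="+", pam=False))
        if len(array_hosts) > 2:
            tgt = members[-1]
            spacer_specs.append(dict(array_genome=array_hosts[2], member=tgt,
                                     mismatches=1, strand="-", pam=False))
    else:
        array_hosts = []

    # choose protospacer sites inside member interiors, write PAMs
    sp_len = cfg.spacer_length
    for spec in spacer_specs:
        member = spec["member"]
        taken = [d["rel"] for d in member.protospacers]
        for _ in range(200):
            pos = int(rng.integers(60, len(member.interior) - sp_len - 60))
            rel = (pos, pos + sp_len)
            if _overlaps(pos, sp_len, member.protected, margin=12):
                continue
            if _overlaps(pos, sp_len, taken, margin=12):
                continue
            chars = list(member.interior)
            if spec["pam"]:
                if spec["strand"] == "+":
                    chars[pos - 3:pos] = "TCC"
                else:
                    chars[pos + sp_len:pos + sp_len + 3] = "GGA"
            candidate = "".join(chars)
            window = candidate[max(0, pos - 20):pos + sp_len + 20]
            if any(f in window or reverse_complement(f) in window
                   for f in forbidden):
                continue
            member.interior = candidate
            proto = member.interior[pos:pos + sp_len]
            if spec["strand"] == "-":
                proto = reverse_complement(proto)
            spec["protospacer"] = proto
            spec["rel"] = rel
            member.protospacers.append(dict(rel=rel))
            break
        else:
            raise RuntimeError("could not place a protospacer")
        spec["spacer"] = derive_spacer(spec["protospacer"],
                                       spec["mismatches"], rng)

    # --- backbone layout (shared across genomes) --------------------------
    layout: list[tuple] = []
    fixed_len = 0

    def add(kind: str, *payload, length: int = 0):
        nonlocal fixed_len
        layout.append((kind, *payload))
        fixed_len += length

    gene_len = lambda s: len(s)  # noqa: E731
    add("filler", length=0)
    core_products = [_BACKBONE_PRODUCTS[i % len(_BACKBONE_PRODUCTS)]
                     + f" {i // len(_BACKBONE_PRODUCTS) + 1}"
                     for i in range(cfg.n_core_genes)]
    core_genes = [random_orf(rng, int(rng.integers(130, 260)), gc)
                  for _ in range(cfg.n_core_genes)]
    accessory_genes = [random_orf(rng, int(rng.integers(130, 260)), gc)
                       for _ in range(cfg.n_accessory_genes)]
    accessory_presence = []
    for _ in range(cfg.n_accessory_genes):
        k = int(rng.integers(2, max(3, cfg.n_genomes)))
        present = set(rng.choice(cfg.n_genomes, size=min(k, cfg.n_genomes),
                                 replace=False).tolist())
        accessory_presence.append(present)
    unique_genes = {
        g: [random_orf(rng, int(rng.integers(120, 220)), gc)
            for _ in range(cfg.n_unique_genes)]
        for g in range(cfg.n_genomes)
    }

    trna_slots = list(TRNA_ISOTYPES)
    trna_seqs = {}
    for c, isotype in enumerate(trna_slots):
        core = att_cores[c] if c < len(att_cores) else \
            random_dna(rng, 43, 0.55)
        trna_seqs[isotype] = random_dna(rng, 42, 0.55) + core

    # interleave genes, tRNA loci and the array slot between filler blocks
    core_iter = list(zip(core_genes, core_products))
    acc_iter = list(zip(accessory_genes, accessory_presence))
    n_sections = len(trna_slots) + 2
    per_section_core = max(1, len(core_iter) // n_sections)
    per_section_acc = max(1, len(acc_iter) // n_sections)
    ci = ai = 0
    for sec in range(n_sections):
        for _ in range(per_section_core):
            if ci < len(core_iter):
                seq, prod = core_iter[ci]
                strand = "-" if ci % 7 == 3 else "+"
                add("core", seq, prod, strand, length=gene_len(seq) + 120)
                ci += 1
        for _ in range(per_section_acc):
            if ai < len(acc_iter):
                seq, present = acc_iter[ai]
                add("accessory", seq, f"accessory protein A{ai + 1:03d}",
                    present, length=gene_len(seq) + 120)
                ai += 1
        if sec < len(trna_slots):
            add("trna", trna_slots[sec], length=len(trna_seqs[trna_slots[sec]]) + 2400)
        elif sec == len(trna_slots):
            add("unique_slot", length=cfg.n_unique_genes * 800)
            add("array_slot", length=0)
        add("filler", length=0)
    while ci < len(core_iter):
        seq, prod = core_iter[ci]
        add("core", seq, prod, "+", length=gene_len(seq) + 120)
        ci += 1
    while ai < len(acc_iter):
        seq, present = acc_iter[ai]
        add("accessory", seq, f"accessory protein A{ai + 1:03d}",
            accessory_presence[ai], length=gene_len(seq) + 120)
        ai += 1

    n_fillers = sum(1 for el in layout if el[0] == "filler")
    filler_total = max(0, cfg.genome_length - fixed_len)
    filler_len = filler_total // n_fillers
    filler_seqs = [scrub_motifs(random_dna(rng, filler_len, gc), forbidden,
                                rng) for _ in range(n_fillers)]
    intergenic = scrub_motifs(random_dna(rng, 120, gc), forbidden, rng)
    trna_flank = {iso: (scrub_motifs(random_dna(rng, 1200, gc), forbidden, rng),
                        scrub_motifs(random_dna(rng, 1200, gc), forbidden, rng))
                  for iso in trna_slots}

    # make the att direct repeat maximal: the base entering the interior
    # must differ from the base entering the right flank (and likewise just
    # upstream of attL/attR), otherwise the repeat would extend ambiguously
    for m in members:
        after = trna_flank[m.isotype][1][0]
        before = trna_seqs[m.isotype][-len(m.att_core) - 1]
        interior = list(m.interior)
        if interior[0] == after:
            interior[0] = next(b for b in "ACGT" if b != after)
        if interior[-1] == before:
            interior[-1] = next(b for b in "ACGT" if b != before)
        m.interior = "".join(interior)

    member_by_site = {(m.genome_id, m.isotype): m for m in members}
    array_specs_by_host: dict[str, list[dict]] = {}
    for spec in spacer_specs:
        array_specs_by_host.setdefault(spec["array_genome"], []).append(spec)

    induction = {m.prophage_id: round(float(rng.uniform(*cfg.induction_range)), 2)
                 for m in members}

    # --- per-genome assembly ----------------------------------------------
    genomes: list[GenomeRecord] = []
    truth = SyntheticTruth()
    decoys_needed = {h: cfg.n_decoy_spacers for h in array_hosts}
    for g in range(cfg.n_genomes):
        gid = f"G{g:02d}"
        b = _Builder()
        tag_counter = 0

        def next_tag() -> str:
            nonlocal tag_counter
            tag_counter += 1
            return f"{gid}_{tag_counter:05d}"

        filler_i = 0
        for el in layout:
            kind = el[0]
            if kind == "filler":
                b.append(filler_seqs[filler_i])
                filler_i += 1
            elif kind == "core":
                _, seq, prod, strand = el
                stored = reverse_complement(seq) if strand == "-" else seq
                feat = b.append_gene(stored, prod, strand=strand)
                feat.attributes["locus_tag"] = next_tag()
                b.append(intergenic)
            elif kind == "accessory":
                _, seq, prod, present = el
                if g in present:
                    feat = b.append_gene(seq, prod)
                    feat.attributes["locus_tag"] = next_tag()
                    b.append(intergenic)
            elif kind == "unique_slot":
                for useq in unique_genes[g]:
                    feat = b.append_gene(useq,
                                         "hypothetical protein (strain specific)")
                    feat.attributes["locus_tag"] = next_tag()
                    b.append(intergenic)
            elif kind == "trna":
                isotype = el[1]
                left, right = trna_flank[isotype]
                b.append(left)
                tseq = trna_seqs[isotype]
                tstart, tend = b.append(tseq)
                trna_feat = Feature(
                    kind=FeatureKind.tRNA, start=tstart, end=tend,
                    attributes={"product": f"tRNA-{isotype}",
                                "isotype": isotype,
                                "locus_tag": next_tag()})
                b.features.append(trna_feat)
                member = member_by_site.get((gid, isotype))
                if member is not None:
                    region_start = b.cursor
                    offset = b.cursor
                    b.append(member.interior)
                    b.append(member.att_core)
                    region_end = b.cursor
                    for f in member.features:
                        nf = Feature(kind=f.kind, start=f.start + offset,
                                     end=f.end + offset, strand=f.strand,
                                     attributes=dict(f.attributes))
                        nf.attributes.setdefault("locus_tag", next_tag())
                        b.features.append(nf)
                    truth.prophages.append(ProphageTruth(
                        prophage_id=member.prophage_id, genome_id=gid,
                        start=region_start, end=region_end,
                        clade=member.clade, att_core=member.att_core,
                        attB_isotype=member.isotype,
                        attB_locus_tag=trna_feat.attributes["locus_tag"],
                        induction_factor=induction[member.prophage_id],
                        dgr=_relabel(member.dgr, offset),
                        shufflon=_relabel(member.shufflon, offset)))
                    for d in member.protospacers:
                        d["abs"] = (d["rel"][0] + offset,
                                    d["rel"][1] + offset)
                        d["region_start"] = region_start
                b.append(right)
            elif kind == "array_slot":
                specs = array_specs_by_host.get(gid, [])
                if specs or gid in decoys_needed:
                    spacers = [s["spacer"] for s in specs]
                    ids = []
                    for i, s in enumerate(specs):
                        ids.append(f"{gid}_sp{i + 1:03d}")
                        s["spacer_id"] = ids[-1]
                    for j in range(decoys_needed.get(gid, 0)):
                        decoy = scrub_motifs(
                            random_dna(rng, sp_len, 0.5), forbidden, rng)
                        spacers.append(decoy)
                        sid = f"{gid}_sp{len(spacers):03d}"
                        ids.append(sid)
                        truth.spacers.append(SpacerTruth(
                            spacer_id=sid, array_genome=gid, sequence=decoy,
                            prophage_id=None, position=None,
                            position_in_prophage=None, strand=None,
                            mismatches=None, pam=False))
                    if spacers:
                        astart, aend = b.append(
                            crispr_repeat
                            + "".join(sp + crispr_repeat for sp in spacers))
                        b.features.append(Feature(
                            kind=FeatureKind.CRISPR_array, start=astart,
                            end=aend,
                            attributes={"n_spacers": str(len(spacers))}))
                        truth.arrays.append(ArrayTruth(
                            genome_id=gid, start=astart, end=aend,
                            repeat=crispr_repeat, spacer_ids=ids))
        genomes.append(GenomeRecord(id=gid, sequence=b.sequence,
                                    features=b.features))

    # finalise spacer truths now that absolute coordinates exist
    for spec in spacer_specs:
        member = spec["member"]
        proto_abs = next(d for d in member.protospacers
                         if d["rel"] == spec["rel"])
        truth.spacers.append(SpacerTruth(
            spacer_id=spec["spacer_id"], array_genome=spec["array_genome"],
            sequence=spec["spacer"], prophage_id=member.prophage_id,
            position=proto_abs["abs"],
            position_in_prophage=spec["rel"],
            strand=spec["strand"], mismatches=spec["mismatches"],
            pam=spec["pam"]))

    truth.spacers.sort(key=lambda s: s.spacer_id)
    return genomes, truth


def simulate_cohort_depth(genomes: Sequence[GenomeRecord],
                          truth: SyntheticTruth, cfg: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> dict[str, np.ndarray]:
    """Depth profiles for every genome using the truth induction factors."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    profiles = {}
    for g in genomes:
        intervals = [(p.start, p.end, p.induction_factor)
                     for p in truth.prophages_of(g.id)]
        profiles[g.id] = simulate_depth(len(g), intervals, cfg.base_depth,
                                        rng)
    return profiles


def write_cohort(genomes: Sequence[GenomeRecord], truth: SyntheticTruth,
                 cfg: SimulationConfig, outdir: str | Path,
                 with_depth: bool = True) -> None:
    """Emit genomes.fasta, features.gff3, truth.json and (optionally)
    depth.tsv into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genomes, outdir / "genomes.fasta")
    write_gff(genomes, outdir / "features.gff3")
    truth.to_json(outdir / "truth.json")
    if with_depth:
        profiles = simulate_cohort_depth(genomes, truth, cfg)
        write_depth_tsv(outdir / "depth.tsv", profiles)
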