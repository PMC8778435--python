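"""Sequence/feature data model and FASTA/GFF3 I/O.

Every other module works on :class:`GenomeRecord` objects; nothing downstream
parses files directly.  Internal coordinates are 0-based half-open on the
forward strand everywhere; GFF3's 1-based closed convention is converted at
the boundary.  The alphabet is restricted to ``{A, C, G, T, N}`` — ``N`` is
carried through but never counts as a match in downstream identity
computations.
"""

from __future__ import annotations

import enum
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FeatureKind(str, enum.Enum):
    gene = "gene"
    tRNA = "tRNA"
    CRISPR_array = "CRISPR_array"
    prophage = "prophage"
    repeat = "repeat"
    other = "other"


@dataclass
class Feature:
    """A located genome feature (0-based half-open interval, forward strand).

    ``attributes`` is a free key->string map; the keys ``product`` and
    ``locus_tag`` are preserved verbatim through GFF round-trips.  tRNA
    features carry an ``isotype`` attribute (e.g. ``Leu``, ``Arg``) derived
    from their product string when not given explicitly.
    """

    kind: FeatureKind
    start: int
    end: int
    strand: str = "+"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def product(self) -> str:
        return self.attributes.get("product", "")

    @property
    def locus_tag(self) -> str:
        return self.attributes.get("locus_tag", "")


@dataclass
class GenomeRecord:
    """A named nucleotide sequence plus typed features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id!r}: invalid characters {sorted(bad)}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"genome {self.id!r}: feature [{f.start}, {f.end}) "
                    f"exceeds sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def add_feature(self, feature: Feature) -> None:
        if feature.end > len(self.sequence):
            raise ValueError(
                f"genome {self.id!r}: feature [{feature.start}, {feature.end})"
                f" exceeds sequence length {len(self.sequence)}"
            )
        self.features.append(feature)

    def feature_sequence(self, feature: Feature) -> str:
        """Extract a feature's sequence, reverse-complemented for '-' strand."""
        seg = self.sequence[feature.start:feature.end]
        return reverse_complement(seg) if feature.strand == "-" else seg

    def features_of_kind(self, kind: FeatureKind | str) -> list[Feature]:
        kind = FeatureKind(kind)
        return [f for f in self.features if f.kind == kind]


# ---------------------------------------------------------------------------
# elementary sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution (rc(rc(s)) == s)."""
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for reverse_complement: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    The first codon is translated as-is (no start-codon special-casing);
    internal stops are encoded as ``*`` and a terminal stop is stripped.
    """
    s = cds.upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for translate: {sorted(bad)}")
    protein = str(Seq(s).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); Ns are excluded from the denominator.

    Raises ValueError on an all-N (or empty) input.
    """
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (s.count("G") + s.count("C")) / acgt


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a multi-record FASTA into GenomeRecords.

    Sequences are uppercased, U is mapped to T, whitespace is stripped.
    Characters outside {A,C,G,T,N} and duplicate record IDs are rejected.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path,
                line_width: int = 70) -> None:
    """Write records as FASTA; round-trips losslessly with :func:`read_fasta`."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty record list")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_KIND_MAP = {
    "gene": FeatureKind.gene,
    "cds": FeatureKind.gene,
    "trna": FeatureKind.tRNA,
    "repeat_region": FeatureKind.repeat,
    "direct_repeat": FeatureKind.repeat,
    "crispr": FeatureKind.CRISPR_array,
    "crispr_array": FeatureKind.CRISPR_array,
    "prophage": FeatureKind.prophage,
}

_KIND_GFF_MAP = {
    FeatureKind.gene: "gene",
    FeatureKind.tRNA: "tRNA",
    FeatureKind.repeat: "repeat_region",
    FeatureKind.CRISPR_array: "CRISPR_array",
    FeatureKind.prophage: "prophage",
    FeatureKind.other: "region",
}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[urllib.parse.unquote(key.strip())] = urllib.parse.unquote(value)
    return attrs


def _format_gff_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    quote = lambda s: urllib.parse.quote(s, safe=" :,_-/().'")  # noqa: E731
    return ";".join(f"{quote(k)}={quote(v)}" for k, v in attrs.items())


def read_gff(path: str | Path, genomes: Iterable[GenomeRecord]) -> list[GenomeRecord]:
    """Attach GFF3 features to genomes (matched by seqid).

    GFF 1-based closed coordinates become internal 0-based half-open.
    tRNA features gain an ``isotype`` attribute parsed from a ``tRNA-Xxx``
    product when not present.  Unknown seqids and end < start are errors.
    """
    genomes = list(genomes)
    by_id = {g.id: g for g in genomes}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if seqid not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown seqid {seqid!r}")
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            attrs = _parse_gff_attributes(attr_s)
            kind = _GFF_KIND_MAP.get(ftype.lower(), FeatureKind.other)
            if kind == FeatureKind.tRNA and "isotype" not in attrs:
                product = attrs.get("product", "")
                if product.startswith("tRNA-"):
                    attrs["isotype"] = product.split("-", 1)[1].split()[0]
            if strand not in {"+", "-"}:
                strand = "+"
            by_id[seqid].add_feature(
                Feature(kind=kind, start=start - 1, end=end, strand=strand,
                        attributes=attrs)
            )
    return genomes


def write_gff(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write features as GFF3; round-trips losslessly with :func:`read_gff`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            for f in sorted(g.features, key=lambda x: (x.start, x.end)):
                fh.write("\t".join([
                    g.id, "prophagekit", _KIND_GFF_MAP[f.kind],
                    str(f.start + 1), str(f.end), ".", f.strand, ".",
                    _format_gff_attributes(f.attributes),
                ]) + "\n")
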