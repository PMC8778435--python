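"""Prophage discovery, boundary delineation and att-site prediction.

Candidate loci are flagged by hallmark virion genes (terminase, major
capsid/head, portal).  Boundaries are delineated by comparing the lysogen
against a prophage-free reference genome with unique exact anchors and
per-base extension: the prophage is the maximal lysogen segment absent from
the reference that contains the candidate.  att sites are predicted as the
longest direct repeat flanking the two boundaries; the attB locus is the
tRNA gene whose sequence carries the att core (directly or as a reverse
complement).

Coordinate convention: a complete region is reported as *interior plus the
right att copy* (one att core), with attL sitting immediately upstream of
the region start.  Removing the region therefore restores the prophage-free
chromosome exactly, which keeps the excision arithmetic in
:mod:`activity_evidence` exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from difflib import SequenceMatcher

import pandas as pd

from .seqio import Feature, FeatureKind, GenomeRecord, gc_fraction, \
    reverse_complement

HALLMARK_KEYWORDS: dict[str, tuple[str, ...]] = {
    "terminase": ("terminase",),
    "capsid": ("major capsid", "major head", "capsid protein"),
    "portal": ("portal",),
}

COMPLETE_SIZE_RANGE = (25_000, 60_000)


@dataclass
class ProphageRegion:
    host_id: str
    start: int
    end: int
    complete: bool
    gc: float = math.nan
    att_core: str | None = None
    attB_isotype: str | None = None
    attB_locus_tag: str | None = None
    clade: int | None = None

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def sequence(self, genome: GenomeRecord) -> str:
        return genome.sequence[self.start:self.end]


# ---------------------------------------------------------------------------
# hallmark screening
# ---------------------------------------------------------------------------

def _hallmark_class(product: str,
                    keywords: dict[str, tuple[str, ...]]) -> str | None:
    text = product.lower()
    for cls, words in keywords.items():
        if any(w in text for w in words):
            return cls
    return None


def screen_hallmarks(genome: GenomeRecord,
                     keywords: dict[str, tuple[str, ...]] | None = None,
                     min_classes: int = 2, max_span: int = 60_000,
                     cluster_gap: int = 30_000) -> list[tuple[int, int]]:
    """Candidate prophage loci: clusters of hallmark genes.

    A candidate is a maximal run of hallmark-carrying genes (consecutive
    hallmarks no further than ``cluster_gap`` apart) that spans at most
    ``max_span`` and contains at least ``min_classes`` distinct hallmark
    classes — a lone integrase or a single stray terminase never qualifies.
    """
    keywords = keywords or HALLMARK_KEYWORDS
    marks = []
    for f in genome.features:
        if f.kind != FeatureKind.gene:
            continue
        cls = _hallmark_class(f.product, keywords)
        if cls is not None:
            marks.append((f.start, f.end, cls))
    marks.sort()
    candidates: list[tuple[int, int]] = []
    cluster: list[tuple[int, int, str]] = []

    def flush():
        if not cluster:
            return
        classes = {c for _, _, c in cluster}
        span = (cluster[0][0], cluster[-1][1])
        if len(classes) >= min_classes and span[1] - span[0] <= max_span:
            candidates.append(span)

    for mark in marks:
        if cluster and mark[0] - cluster[-1][1] > cluster_gap:
            flush()
            cluster = []
        cluster.append(mark)
    flush()
    return candidates


# ---------------------------------------------------------------------------
# boundary delineation against a prophage-free reference
# ---------------------------------------------------------------------------

def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if w in dup:
            continue
        if w in seen:
            del seen[w]
            dup.add(w)
        else:
            seen[w] = i
    return seen


def delineate_boundaries(lysogen: GenomeRecord, reference: GenomeRecord,
                         candidate: tuple[int, int],
                         anchor_k: int = 20) -> ProphageRegion:
    """Delineate the insertion interval around a candidate locus.

    Anchors are exact ``anchor_k``-mers unique in both genomes; the nearest
    anchors flanking the candidate are extended base-by-base toward it, and
    the interval between the extension break-points is the inserted
    segment.  A side with no anchored flank leaves that terminus open at
    the contig end and marks the region incomplete.
    """
    cand_start, cand_end = candidate
    lys, ref = lysogen.sequence, reference.sequence
    lys_unique = _unique_kmer_positions(lys, anchor_k)
    ref_unique = _unique_kmer_positions(ref, anchor_k)
    shared = [(lp, ref_unique[w]) for w, lp in lys_unique.items()
              if w in ref_unique]
    left = [(lp, rp) for lp, rp in shared if lp + anchor_k <= cand_start]
    right = [(lp, rp) for lp, rp in shared if lp >= cand_end]

    start, end = 0, len(lys)
    left_ok = right_ok = False
    if left:
        lp, rp = max(left)
        i, j = lp + anchor_k, rp + anchor_k
        while i < len(lys) and j < len(ref) and lys[i] == ref[j]:
            i += 1
            j += 1
        if i <= cand_start:
            start, left_ok = i, True
    if right:
        lp, rp = min(right)
        i, j = lp, rp
        while i > 0 and j > 0 and lys[i - 1] == ref[j - 1]:
            i -= 1
            j -= 1
        if i >= cand_end:
            end, right_ok = i, True
    region = ProphageRegion(host_id=lysogen.id, start=start, end=end,
                            complete=left_ok and right_ok)
    region.gc = region_gc(region, lysogen)
    return region


# ---------------------------------------------------------------------------
# att-site prediction
# ---------------------------------------------------------------------------

def predict_att(region: ProphageRegion, genome: GenomeRecord,
                window: int = 500, min_repeat: int = 15
                ) -> tuple[str | None, Feature | None]:
    """Predict the att core as the longest direct repeat flanking the two
    boundaries, then snap the region so it runs from the end of attL to the
    end of attR (interior + one att copy).

    Each boundary contributes a ``window``-wide search window centred on
    it; the repeat must be at least ``min_repeat`` nt long and occur exactly
    once per window.  The attB locus is any tRNA feature of the host whose
    sequence contains the core directly or reverse-complemented.  Returns
    ``(None, None)`` — and leaves the region untouched — when no qualifying
    repeat exists.
    """
    if not region.complete:
        return None, None
    half = window // 2
    seq = genome.sequence
    l_lo = max(0, region.start - half)
    wl = seq[l_lo:region.start + half]
    r_lo = max(0, region.end - half)
    wr = seq[r_lo:region.end + half]
    match = SequenceMatcher(None, wl, wr, autojunk=False) \
        .find_longest_match(0, len(wl), 0, len(wr))
    if match.size < min_repeat:
        return None, None
    core = wl[match.a:match.a + match.size]
    if wl.count(core) != 1 or wr.count(core) != 1:
        return None, None
    att_l = l_lo + match.a
    att_r = r_lo + match.b
    if att_r <= att_l:
        return None, None
    # snap: region = ]attL .. attR], flanked by the direct repeat
    region.start = att_l + match.size
    region.end = att_r + match.size
    region.att_core = core
    region.gc = region_gc(region, genome)
    assert seq[region.start - match.size:region.start] == core
    assert seq[region.end - match.size:region.end] == core

    attB = None
    rc_core = reverse_complement(core)
    for f in genome.features_of_kind(FeatureKind.tRNA):
        t_seq = seq[f.start:f.end]
        if core in t_seq or rc_core in t_seq:
            attB = f
            break
    if attB is not None:
        region.attB_isotype = attB.attributes.get("isotype")
        region.attB_locus_tag = attB.locus_tag
    return core, attB


def region_gc(region: ProphageRegion, genome: GenomeRecord) -> float:
    """GC fraction of the region; NaN (flagged) when undefined (all-N)."""
    try:
        return gc_fraction(genome.sequence[region.start:region.end])
    except ValueError:
        return math.nan


# ---------------------------------------------------------------------------
# orchestration / export
# ---------------------------------------------------------------------------

def find_prophages(lysogen: GenomeRecord, reference: GenomeRecord,
                   **screen_kwargs) -> list[ProphageRegion]:
    """Screen hallmarks, delineate each candidate and predict att sites."""
    regions = []
    for candidate in screen_hallmarks(lysogen, **screen_kwargs):
        region = delineate_boundaries(lysogen, reference, candidate)
        predict_att(region, lysogen)
        regions.append(region)
    return regions


def regions_to_frame(regions: list[ProphageRegion]) -> pd.DataFrame:
    rows = [{
        "host": r.host_id, "left": r.start, "right": r.end,
        "size_bp": len(r), "gc_percent": round(100 * r.gc, 1),
        "integration_locus": (f"tRNA-{r.attB_isotype} ({r.attB_locus_tag})"
                              if r.attB_isotype else "unknown"),
        "att_core": r.att_core or "",
        "clade": r.clade if r.clade is not None else "",
        "complete": r.complete,
    } for r in regions]
    return pd.DataFrame(rows, columns=["host", "left", "right", "size_bp",
                                       "gc_percent", "integration_locus",
                                       "att_core", "clade", "complete"])
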