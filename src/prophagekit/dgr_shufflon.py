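"""Diversity-generating retroelements (DGRs) and Rin shufflons.

A DGR is anchored on a reverse-transcriptase (*ert*) gene plus a pair of
near-identical same-orientation repeats: the template repeat (TR) sits next
to — or inside — *ert*, while the variable repeat (VR) sits inside a target
gene (the *mtd* candidate, typically a tail-fibre/receptor-binding
protein).  Retrohoming copies the TR over the VR with substitutions
restricted to defined variable sites, so VR/TR identity stays above 90%
while the target protein diversifies.

A Rin shufflon is a site-specific invertase (Rin) next to a battery of
small Rv cassettes delimited by a short asymmetric crossover motif (rix,
5'-ttccgtat-3' here) in direct orientation, followed by a large Rc gene
carrying inverted rix copies (one inside the gene, one just after its
stop); inversion shuffles Rv 3' segments onto the Rc C-terminus.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .seqio import Feature, FeatureKind, GenomeRecord, reverse_complement

RT_KEYWORDS = ("reverse transcriptase", "rna-dependent dna polymerase")
RIN_KEYWORDS = ("invertase", "shufflon recombinase")
DEFAULT_RIX_MOTIF = "ttccgtat"


@dataclass
class DGRElement:
    rt_gene: tuple[int, int]
    mtd_gene: tuple[int, int]
    avd_gene: tuple[int, int] | None
    tr: tuple[int, int]
    vr: tuple[int, int]
    tr_vr_identity: float
    architecture: str                   # TR_upstream_of_ert | TR_within_ert
    variable_sites: list[int] = field(default_factory=list)


@dataclass
class ShufflonLocus:
    rin_gene: tuple[int, int]
    rc_gene: tuple[int, int]
    rix_sites: list[tuple[int, str]]    # (position, direct | inverted)
    rv_segments: list[tuple[int, int]]
    rv_rc_identity: list[float]


def features_in_interval(genome: GenomeRecord, start: int,
                         end: int) -> list[Feature]:
    """Features fully inside [start, end), re-based to interval coordinates."""
    out = []
    for f in genome.features:
        if f.start >= start and f.end <= end:
            out.append(Feature(kind=f.kind, start=f.start - start,
                               end=f.end - start, strand=f.strand,
                               attributes=dict(f.attributes)))
    return out


# ---------------------------------------------------------------------------
# repeat-pair discovery
# ---------------------------------------------------------------------------

def _best_window(match: np.ndarray, lo: int, hi: int, min_len: int,
                 max_len: int, min_identity: float
                 ) -> tuple[int, int, float] | None:
    """Best (start, length, identity) window of match[lo:hi] with length in
    range and identity >= min_identity.

    The window maximises match +1 / mismatch -3 (ungapped blastn-style
    scoring), so flanking junk (expected ~25% chance agreement) is firmly
    rejected while genuinely matching edge columns are retained; ties
    prefer the shorter window (the minimal maximal-scoring segment, so
    zero-sum tails are never absorbed).
    """
    region = match[lo:hi].astype(np.int32)
    if len(region) < min_len:
        return None
    cum = np.concatenate([[0], np.cumsum(region)])
    best = None
    for length in range(min_len, min(max_len, len(region)) + 1):
        window_matches = cum[length:] - cum[:-length]
        scores = 4 * window_matches - 3 * length
        s = int(np.argmax(scores))
        matches = int(window_matches[s])
        identity = matches / length
        if identity < min_identity:
            continue
        score = int(scores[s])
        if best is None or score > best[3]:
            best = (lo + s, length, identity, score)
    if best is None:
        return None
    return best[0], best[1], best[2]


def find_repeat_pairs(sequence: str, min_len: int = 100, max_len: int = 150,
                      min_identity: float = 0.90, seed_k: int = 20,
                      offsets: list[int] | None = None
                      ) -> list[tuple[tuple[int, int], tuple[int, int], float]]:
    """Same-orientation, non-overlapping repeat pairs in one sequence.

    Candidate copy offsets come from exact ``seed_k``-mer recurrences (or
    an explicit offset list, which makes the search exhaustive for oracle
    comparisons); each offset's match profile is scanned for the best
    window with length in [min_len, max_len] and Hamming identity at least
    ``min_identity``.  Overlapping candidates are reduced to the best
    non-redundant set.
    """
    n = len(sequence)
    if n < 2 * min_len:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    seed_span: dict[int, tuple[int, int]] = {}
    if offsets is None:
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(n - seed_k + 1):
            index[sequence[i:i + seed_k]].append(i)
        for positions in index.values():
            if len(positions) < 2:
                continue
            for a in positions:
                for b in positions:
                    d = b - a
                    if d < min_len:
                        continue
                    lo, hi = seed_span.get(d, (a, a + seed_k))
                    seed_span[d] = (min(lo, a), max(hi, a + seed_k))
    else:
        seed_span = {d: (0, n - d) for d in offsets if min_len <= d < n}

    candidates = []
    is_n = arr == ord("N")
    for d, (span_lo, span_hi) in sorted(seed_span.items()):
        match = (arr[:-d] == arr[d:]) & ~is_n[:-d] & ~is_n[d:]
        lo = max(0, span_lo - max_len)
        hi = min(len(match), span_hi + max_len)
        found = _best_window(match, lo, hi, min_len, min(max_len, d),
                             min_identity)
        if found is None:
            continue
        s, length, identity = found
        candidates.append(((s, s + length), (s + d, s + d + length),
                           identity))
    candidates.sort(key=lambda c: (-(c[2] * (c[0][1] - c[0][0])), c[0]))
    kept: list[tuple[tuple[int, int], tuple[int, int], float]] = []

    def overlaps(x, y):
        return x[0] < y[1] and y[0] < x[1]

    for cand in candidates:
        if any(overlaps(cand[0], k[0]) and overlaps(cand[1], k[1])
               for k in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: c[0])
    return kept


# ---------------------------------------------------------------------------
# DGR assembly
# ---------------------------------------------------------------------------

def _interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


def assemble_dgr(prophage_seq: str, features: list[Feature],
                 repeat_pairs=None,
                 rt_keywords: tuple[str, ...] = RT_KEYWORDS
                 ) -> DGRElement | None:
    """Assemble a DGR from gene annotations and repeat pairs.

    Requires a reverse-transcriptase gene; among repeat pairs, the member
    nearer to (or inside) the RT gene is the TR and the other is the VR,
    and the VR must fall inside a gene (the mtd candidate).  Returns None
    when the RT gene is missing or no pair qualifies.
    """
    genes = [f for f in features if f.kind == FeatureKind.gene]
    rt = next((f for f in genes
               if any(k in f.product.lower() for k in rt_keywords)), None)
    if rt is None:
        return None
    if repeat_pairs is None:
        repeat_pairs = find_repeat_pairs(prophage_seq)
    best: DGRElement | None = None
    for iv_a, iv_b, identity in repeat_pairs:
        da = _interval_distance(iv_a, rt.interval)
        db = _interval_distance(iv_b, rt.interval)
        tr, vr = (iv_a, iv_b) if da <= db else (iv_b, iv_a)
        mtd = next((g for g in genes
                    if g.start <= vr[0] and vr[1] <= g.end and g is not rt),
                   None)
        if mtd is None:
            continue
        inside_rt = rt.start <= tr[0] and tr[1] <= rt.end
        architecture = "TR_within_ert" if inside_rt else "TR_upstream_of_ert"
        lo, hi = min(tr[1], mtd.end), max(tr[0], mtd.start)
        avd = next((g for g in genes
                    if lo <= g.start and g.end <= hi and len(g) <= 600),
                   None)
        element = DGRElement(rt_gene=rt.interval, mtd_gene=mtd.interval,
                             avd_gene=avd.interval if avd else None,
                             tr=tr, vr=vr, tr_vr_identity=identity,
                             architecture=architecture)
        if best is None or identity > best.tr_vr_identity:
            best = element
    return best


def call_variable_sites(vr_sequences: list[str], tr_reference: str
                        ) -> list[int]:
    """Offsets (0-based within the VR) where >= 2 distinct bases are
    observed across the TR reference and the VR isolates.

    All sequences must share the TR length (anchored upstream); the result
    is invariant under isolate input order.  Ns are ignored.
    """
    if len(vr_sequences) < 1:
        raise ValueError("need at least one VR observation")
    length = len(tr_reference)
    for vr in vr_sequences:
        if len(vr) != length:
            raise ValueError("VR/TR length mismatch after anchoring")
    sites = []
    rows = [tr_reference.upper()] + [v.upper() for v in vr_sequences]
    for i in range(length):
        observed = {row[i] for row in rows} - {"N"}
        if len(observed) >= 2:
            sites.append(i)
    return sites


def variant_space(n_sites: int) -> int:
    """Size of the VR sequence space: 4^n (each site can carry any base)."""
    if n_sites < 0:
        raise ValueError("site count must be non-negative")
    return 4 ** n_sites


def ungapped_homology(a: str, b: str, min_overlap: int = 60) -> float:
    """Best ungapped-offset identity between two sequences.

    Slides one sequence along the other and reports the maximal
    matches/overlap over all offsets with at least ``min_overlap`` aligned
    columns.  Unlike local-alignment identity — which saturates near 1 on
    any short exact run — this reflects the average divergence of the
    homologous region, so a pair of sequences 30% diverged reports ~0.70
    and unrelated sequences stay near the 0.25 background.
    """
    if len(a) < min_overlap or len(b) < min_overlap:
        return 0.0
    arr_a = np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)
    best = 0.0
    for d in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        a_lo, b_lo = max(0, d), max(0, -d)
        overlap = min(len(a) - a_lo, len(b) - b_lo)
        if overlap < min_overlap:
            continue
        seg_a = arr_a[a_lo:a_lo + overlap]
        seg_b = arr_b[b_lo:b_lo + overlap]
        matches = int(((seg_a == seg_b)
                       & (seg_a != ord("N"))).sum())
        best = max(best, matches / overlap)
    return best


# ---------------------------------------------------------------------------
# shufflon
# ---------------------------------------------------------------------------

def find_rix_sites(sequence: str, motif: str = DEFAULT_RIX_MOTIF
                   ) -> list[tuple[int, str]]:
    """All exact occurrences of the rix motif (direct) and of its reverse
    complement (inverted); case-insensitive, overlaps allowed."""
    if len(motif) < 6:
        raise ValueError("rix motif must be at least 6 nt")
    seq = sequence.upper()
    fwd = motif.upper()
    rev = reverse_complement(fwd)
    sites = []
    for orientation, probe in (("direct", fwd), ("inverted", rev)):
        if orientation == "inverted" and rev == fwd:
            continue  # palindromic motif: direct scan already covers it
        start = 0
        while (pos := seq.find(probe, start)) != -1:
            sites.append((pos, orientation))
            start = pos + 1
    sites.sort()
    return sites


def assemble_shufflon(prophage_seq: str, features: list[Feature],
                      rix_sites: list[tuple[int, str]] | None = None,
                      motif: str = DEFAULT_RIX_MOTIF,
                      rin_keywords: tuple[str, ...] = RIN_KEYWORDS,
                      max_cassette: int = 1000,
                      rc_min_len: int = 600,
                      rc_rix_window: int = 200,
                      rc_cterm_window: int = 120) -> ShufflonLocus | None:
    """Assemble a Rin shufflon locus.

    Rv segments are the intervals between consecutive direct rix sites
    downstream of the recombinase (consecutive means separated by at most
    ``max_cassette``); the Rc gene is the first large gene after the last
    Rv with an inverted rix within ``rc_rix_window`` of its stop codon.
    Reports the ungapped-offset identity of each Rv segment against the
    Rc C-terminus.  Returns None when the recombinase, the cassettes or
    the Rc gene cannot be found.
    """
    genes = [f for f in features if f.kind == FeatureKind.gene]
    rin = next((f for f in genes
                if any(k in f.product.lower() for k in rin_keywords)
                and "integrase" not in f.product.lower()), None)
    if rin is None:
        return None
    if rix_sites is None:
        rix_sites = find_rix_sites(prophage_seq, motif)
    direct = [p for p, o in rix_sites if o == "direct" and p >= rin.end]
    inverted = [p for p, o in rix_sites if o == "inverted"]
    if len(direct) < 2:
        return None
    m = len(motif)
    rv_segments = []
    for a, b in zip(direct, direct[1:]):
        if b - (a + m) > max_cassette:
            break
        rv_segments.append((a + m, b))
    if not rv_segments:
        return None
    last_rix_end = rv_segments[-1][1] + m
    rc = next((g for g in sorted(genes, key=lambda f: f.start)
               if g.start >= last_rix_end and len(g) >= rc_min_len
               and any(g.end - m <= p <= g.end + rc_rix_window
                       for p in inverted)), None)
    if rc is None:
        return None
    c_term = prophage_seq[max(rc.start,
                                   rc.end - 3 - rc_cterm_window):rc.end - 3]
    identities = [ungapped_homology(prophage_seq[s:e], c_term)
                  for s, e in rv_segments]
    used = [(p, o) for p, o in rix_sites
            if (o == "direct" and rin.end <= p <= last_rix_end)
            or (o == "inverted" and rc.start <= p <= rc.end + rc_rix_window)]
    return ShufflonLocus(rin_gene=rin.interval, rc_gene=rc.interval,
                         rix_sites=used, rv_segments=rv_segments,
                         rv_rc_identity=identities)
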