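"""CRISPR array detection, spacer extraction and protospacer matching.

Arrays are detected CRT-style: at least three tandem copies of a repeat
(23-47 nt, exact or one mismatch per copy) separated by spacer-sized
(26-50 nt) non-repeat gaps.  Spacers are matched to prophage sequences as
full-length ungapped alignments on either strand with at most three
mismatches AND an ungapped blastn bit score of at least 44.1 — both filters
are applied, and both are individually necessary (a 26-nt spacer with three
mismatches clears the mismatch rule but not the bit-score rule).

The bit score uses the ungapped Karlin-Altschul statistics of the blastn
+1/-3 scoring system (lambda = 1.374, K = 0.711); at the median 34-nt
spacer length, three mismatches give a raw score of 22 and a bit score of
exactly 44.1, which is what pins this interpretation of the cutoff.

Candidate positions come from pigeonhole seeding (the spacer is split into
``max_mismatches + 1`` chunks, one of which must match exactly), so the hit
set is identical to a naive all-positions Hamming scan.  ``N`` never counts
as a match.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .align import SeedIndex, hamming_n
from .seqio import GenomeRecord, reverse_complement

LAMBDA_UNGAPPED = 1.374   # ungapped blastn, reward +1 / penalty -3
K_UNGAPPED = 0.711
MAX_MISMATCHES = 3
MIN_BITSCORE = 44.1

REPEAT_LENGTH_RANGE = (23, 47)
SPACER_LENGTH_RANGE = (26, 50)


@dataclass
class SpacerArray:
    genome_id: str
    start: int
    end: int
    repeat_consensus: str
    spacers: list[str]

    @property
    def n_repeats(self) -> int:
        return len(self.spacers) + 1


@dataclass
class ProtospacerHit:
    spacer_id: str
    prophage_id: str
    start: int
    end: int
    strand: str              # strand of the protospacer on the prophage
    mismatches: int
    bitscore: float
    pam_tcc: bool = False
    pam_edge: bool = False
    self_targeting: bool = False


# ---------------------------------------------------------------------------
# array detection
# ---------------------------------------------------------------------------

def _majority_consensus(copies: list[str]) -> str:
    cols = zip(*copies)
    return "".join(max("ACGT", key=lambda b: col.count(b)) for col in cols)


def detect_arrays(genome: GenomeRecord,
                  repeat_range: tuple[int, int] = REPEAT_LENGTH_RANGE,
                  spacer_range: tuple[int, int] = SPACER_LENGTH_RANGE,
                  min_copies: int = 3, copy_mismatch: int = 1,
                  seed_k: int = 16) -> list[SpacerArray]:
    """Scan one genome for repeat-spacer arrays.

    Two exact seed-sharing repeat copies at spacer-compatible distance
    nucleate a candidate; the repeat is maximised by exact extension and
    the array is then grown greedily in both directions, allowing
    ``copy_mismatch`` mismatches per additional copy.
    """
    seq = genome.sequence
    n = len(seq)
    if n < 200:
        return []
    min_rep, max_rep = repeat_range
    min_sp, max_sp = spacer_range
    min_period = min_rep + min_sp
    max_period = max_rep + max_sp

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - seed_k + 1):
        index[seq[i:i + seed_k]].append(i)

    claimed: list[tuple[int, int]] = []
    arrays: list[SpacerArray] = []
    for word in sorted(index):
        positions = index[word]
        if len(positions) < 2:
            continue
        for p, q in zip(positions, positions[1:]):
            d = q - p
            if not min_period <= d <= max_period:
                continue
            if any(s <= p < e for s, e in claimed):
                continue
            # maximal exact extension of the two copies
            rs, re = p, p + seed_k
            while rs > 0 and rs + d + (re - rs) <= n and \
                    seq[rs - 1] == seq[rs + d - 1]:
                rs -= 1
            while re + d <= n and re - rs < max_rep + 1 and \
                    seq[re] == seq[re + d]:
                re += 1
            rep_len = re - rs
            if not min_rep <= rep_len <= max_rep:
                continue
            if not min_sp <= d - rep_len <= max_sp:
                continue
            repeat = seq[rs:re]
            copies = [rs, rs + d]
            # grow right
            while True:
                last = copies[-1]
                nxt = _next_copy(seq, repeat, last + rep_len + min_sp,
                                 last + rep_len + max_sp, copy_mismatch)
                if nxt is None:
                    break
                copies.append(nxt)
            # grow left
            while True:
                first = copies[0]
                prev = _prev_copy(seq, repeat, first - max_sp - rep_len,
                                  first - min_sp - rep_len, copy_mismatch)
                if prev is None:
                    break
                copies.insert(0, prev)
            if len(copies) < min_copies:
                continue
            # refine boundaries across ALL copies: a column that is not
            # unanimous is flanking sequence dragged in by a coincidental
            # two-copy extension, not repeat
            while rep_len > min_rep and \
                    len({seq[c] for c in copies}) > 1:
                copies = [c + 1 for c in copies]
                rep_len -= 1
            while rep_len > min_rep and \
                    len({seq[c + rep_len - 1] for c in copies}) > 1:
                rep_len -= 1
            repeat = seq[copies[0]:copies[0] + rep_len]
            spacers = [seq[copies[i] + rep_len:copies[i + 1]]
                       for i in range(len(copies) - 1)]
            consensus = _majority_consensus(
                [seq[c:c + rep_len] for c in copies])
            start, end = copies[0], copies[-1] + rep_len
            if any(start < e and s < end for s, e in claimed):
                continue
            arrays.append(SpacerArray(genome_id=genome.id, start=start,
                                      end=end, repeat_consensus=consensus,
                                      spacers=spacers))
            claimed.append((start, end))
    arrays.sort(key=lambda a: a.start)
    return arrays


def _next_copy(seq: str, repeat: str, lo: int, hi: int,
               max_mm: int) -> int | None:
    best = None
    for s in range(lo, min(hi, len(seq) - len(repeat)) + 1):
        if hamming_n(repeat, seq[s:s + len(repeat)]) <= max_mm:
            if best is None or s < best:
                best = s
    return best


def _prev_copy(seq: str, repeat: str, lo: int, hi: int,
               max_mm: int) -> int | None:
    best = None
    for s in range(max(lo, 0), hi + 1):
        if s + len(repeat) > len(seq):
            continue
        if hamming_n(repeat, seq[s:s + len(repeat)]) <= max_mm:
            best = s  # keep the rightmost (nearest) previous copy
    return best


# ---------------------------------------------------------------------------
# spacer dedup and scoring
# ---------------------------------------------------------------------------

def dedup_spacers(arrays: list[SpacerArray]
                  ) -> tuple[dict[str, str], dict[str, list[str]], int]:
    """Exact-string dedup across all arrays.

    Returns (unique spacers: id -> sequence, carriers: id -> genomes
    carrying the spacer, total spacer count).  Ids are assigned from the
    first carrier in array order.
    """
    unique: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    carriers: dict[str, list[str]] = {}
    total = 0
    counter = 0
    for arr in arrays:
        for sp in arr.spacers:
            total += 1
            if sp not in by_seq:
                counter += 1
                sid = f"sp{counter:04d}"
                by_seq[sp] = sid
                unique[sid] = sp
                carriers[sid] = []
            sid = by_seq[sp]
            if arr.genome_id not in carriers[sid]:
                carriers[sid].append(arr.genome_id)
    return unique, carriers, total


def spacer_bitscore(spacer_len: int, mismatches: int) -> float:
    """Ungapped blastn bit score of a full-length spacer alignment.

    Raw score S = (len - m) * 1 + m * (-3) = len - 4m; bits =
    (lambda * S - ln K) / ln 2 with the ungapped +1/-3 constants.
    """
    if mismatches > spacer_len:
        raise ValueError("more mismatches than positions")
    raw = spacer_len - 4 * mismatches
    return (LAMBDA_UNGAPPED * raw - math.log(K_UNGAPPED)) / math.log(2.0)


def find_protospacers(spacers: dict[str, str], prophages: dict[str, str],
                      max_mismatches: int = MAX_MISMATCHES,
                      min_bitscore: float = MIN_BITSCORE
                      ) -> list[ProtospacerHit]:
    """Full-length ungapped matches of each spacer on both strands of each
    prophage, filtered by the mismatch AND bit-score rules."""
    hits: list[ProtospacerHit] = []
    if not spacers or not prophages:
        return hits
    chunk = min(len(s) for s in spacers.values()) // (max_mismatches + 1)
    k = max(4, min(11, chunk))
    for prophage_id in sorted(prophages):
        seq = prophages[prophage_id].upper()
        index = SeedIndex(seq, k=k)
        for sid in sorted(spacers):
            sp = spacers[sid].upper()
            for strand, probe in (("+", sp), ("-", reverse_complement(sp))):
                for pos, mm in index.find_hamming(probe, max_mismatches):
                    bits = spacer_bitscore(len(sp), mm)
                    if bits < min_bitscore:
                        continue
                    hit = ProtospacerHit(
                        spacer_id=sid, prophage_id=prophage_id,
                        start=pos, end=pos + len(sp), strand=strand,
                        mismatches=mm, bitscore=bits)
                    check_pam(hit, seq)
                    hits.append(hit)
    return hits


def check_pam(hit: ProtospacerHit, prophage_seq: str,
              pam: str = "TCC") -> bool:
    """True iff the 3 nt immediately 5' of the protospacer, read on the
    protospacer's strand, equal the PAM.  A protospacer flush with the
    sequence edge cannot be evaluated: False with the edge flag set."""
    if hit.strand == "+":
        if hit.start < len(pam):
            hit.pam_tcc, hit.pam_edge = False, True
            return False
        context = prophage_seq[hit.start - len(pam):hit.start]
    else:
        if hit.end + len(pam) > len(prophage_seq):
            hit.pam_tcc, hit.pam_edge = False, True
            return False
        context = reverse_complement(prophage_seq[hit.end:hit.end + len(pam)])
    hit.pam_tcc = context == pam
    hit.pam_edge = False
    return hit.pam_tcc


# ---------------------------------------------------------------------------
# targeting matrix
# ---------------------------------------------------------------------------

def targeting_matrix(hits: list[ProtospacerHit],
                     clade_of: dict[str, int],
                     spacer_carriers: dict[str, list[str]],
                     hosts: list[str],
                     prophage_host: dict[str, str] | None = None,
                     n_unique_spacers: int | None = None) -> dict:
    """Host x clade spacer-count matrix plus the targeting summaries.

    A (host, clade) cell counts the distinct spacers carried by the host
    with at least one hit in that clade.  Self-targeting rows (a host's
    spacer hitting a prophage resident in the same host) are flagged with
    their PAM status.  PAM status does not gate the counts.
    """
    clades = sorted(set(clade_of.values()))
    matrix = pd.DataFrame(0, index=list(hosts), columns=clades)
    spacer_clades: dict[tuple[str, int], set[str]] = defaultdict(set)
    self_rows = []
    for hit in hits:
        clade = clade_of.get(hit.prophage_id)
        if clade is None:
            continue
        for host in spacer_carriers.get(hit.spacer_id, []):
            if host in matrix.index:
                spacer_clades[(host, clade)].add(hit.spacer_id)
            if prophage_host is not None and \
                    prophage_host.get(hit.prophage_id) == host:
                hit.self_targeting = True
                self_rows.append({"host": host, "spacer": hit.spacer_id,
                                  "prophage": hit.prophage_id,
                                  "pam_tcc": hit.pam_tcc})
    for (host, clade), ids in spacer_clades.items():
        matrix.loc[host, clade] = len(ids)
    clades_per_host = (matrix > 0).sum(axis=1)
    breadth = clades_per_host[clades_per_host > 0].value_counts().to_dict()
    targeting_ids = {h.spacer_id for h in hits}
    summary = {
        "matrix": matrix,
        "hosts_by_n_clades_targeted": {int(k): int(v)
                                       for k, v in breadth.items()},
        "n_targeting_unique_spacers": len(targeting_ids),
        "self_targeting": self_rows,
    }
    if n_unique_spacers:
        summary["unique_spacer_fraction"] = unique_targeting_fraction(
            len(targeting_ids), n_unique_spacers)
    return summary


def unique_targeting_fraction(n_targeting: int, n_unique: int) -> float:
    """Fraction of unique spacers that target a prophage."""
    if n_unique <= 0:
        raise ValueError("need a positive unique-spacer count")
    return n_targeting / n_unique


def hits_to_frame(hits: list[ProtospacerHit]) -> pd.DataFrame:
    rows = [{
        "spacer": h.spacer_id, "prophage": h.prophage_id, "start": h.start,
        "end": h.end, "strand": h.strand, "mismatches": h.mismatches,
        "bitscore": round(h.bitscore, 1), "pam_tcc": h.pam_tcc,
        "self_targeting": h.self_targeting,
    } for h in hits]
    return pd.DataFrame(rows, columns=["spacer", "prophage", "start", "end",
                                       "strand", "mismatches", "bitscore",
                                       "pam_tcc", "self_targeting"])
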