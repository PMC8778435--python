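"""Shared pairwise-alignment and seeded-matching engine.

One scoring engine backs the fragmented-identity clade heatmap, ortholog
clustering, CRISPR protospacer matching and the Rv/Rc homology reports, so a
single oracle validates all of them.

Scoring conventions
-------------------
* Nucleotide local alignment uses blastn-style scores: match +1,
  mismatch -3, gap opening -5 plus -2 per gapped base (i.e. a length-1 gap
  costs 7).  ``N`` never scores as a match against anything, itself included.
* Protein local alignment uses BLOSUM62 with gap open 11 / extend 1.

Exact Smith-Waterman is delegated to Biopython's :class:`PairwiseAligner`
(C implementation); for long subjects a seed-and-window heuristic restricts
the DP to diagonals sharing an exact seed word.
"""

from __future__ import annotations

from collections import defaultdict
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

NT_MATCH = 1.0
NT_MISMATCH = -3.0
NT_GAP_OPEN = -5.0
NT_GAP_EXTEND = -2.0


def _nt_matrix():
    """5x5 substitution matrix over ACGTN with N scoring as a mismatch."""
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if a == b and a != "N":
                mat[a, b] = NT_MATCH
            else:
                mat[a, b] = NT_MISMATCH
    return mat


@lru_cache(maxsize=1)
def nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _nt_matrix()
    # PairwiseAligner charges open_gap_score for the first gapped base, so
    # the blastn convention (open 5 + extend 2 per base) maps to -7 / -2.
    aligner.open_gap_score = NT_GAP_OPEN + NT_GAP_EXTEND
    aligner.extend_gap_score = NT_GAP_EXTEND
    return aligner


@lru_cache(maxsize=1)
def protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_nt_score(query: str, subject: str) -> float:
    """Exact best local alignment score (blastn scoring) of query vs subject."""
    if not query or not subject:
        return 0.0
    return float(nucleotide_aligner().score(query, subject))


def local_nt_identity(a: str, b: str) -> float:
    """Identity (matches / aligned columns) of the best local nt alignment.

    Returns 0.0 when no positive-scoring local alignment exists.
    """
    aligner = nucleotide_aligner()
    if not a or not b or aligner.score(a, b) <= 0:
        return 0.0
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def protein_identity_coverage(a: str, b: str) -> tuple[float, float]:
    """Local-alignment identity and shorter-sequence coverage of two proteins.

    identity = matches / aligned columns (gapped columns included);
    coverage = aligned span on the shorter sequence / its length.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = protein_aligner()
    if aligner.score(a, b) <= 0:
        return 0.0, 0.0
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    # aligned span on the shorter of the two sequences
    shorter_axis = 0 if len(a) <= len(b) else 1
    ranges = aln.aligned[shorter_axis]
    if len(ranges) == 0:
        return identity, 0.0
    span = int(ranges[-1][1] - ranges[0][0])
    coverage = span / min(len(a), len(b))
    return identity, coverage


def hamming_n(a: str, b: str) -> int:
    """Hamming distance where N never matches (N vs anything is a mismatch)."""
    if len(a) != len(b):
        raise ValueError("hamming_n requires equal-length strings")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


class SeedIndex:
    """Exact k-mer index over one subject sequence.

    Supports seeded Hamming search (pigeonhole chunking, guaranteed complete
    for ``max_mm`` mismatches when the query splits into ``max_mm + 1``
    chunks of at least the index k) and diagonal-window retrieval for local
    alignment heuristics.
    """

    def __init__(self, subject: str, k: int = 11):
        if k < 4:
            raise ValueError("seed size must be >= 4")
        self.subject = subject
        self.k = k
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(subject) - k + 1):
            word = subject[i:i + k]
            if "N" not in word:
                index[word].append(i)
        self._index = dict(index)

    def seed_positions(self, word: str) -> list[int]:
        return self._index.get(word, [])

    def find_hamming(self, query: str, max_mm: int) -> list[tuple[int, int]]:
        """All subject positions where query matches with <= max_mm mismatches.

        Complete (identical to a naive all-positions scan) whenever
        ``len(query) // (max_mm + 1) >= k``; shorter queries fall back to the
        naive scan so completeness always holds.
        """
        n, m = len(self.subject), len(query)
        if m > n:
            return []
        chunk = m // (max_mm + 1)
        if chunk < self.k:
            return [
                (i, d) for i in range(n - m + 1)
                if (d := hamming_n(query, self.subject[i:i + m])) <= max_mm
            ]
        candidates: set[int] = set()
        for c in range(max_mm + 1):
            off = c * chunk
            word = query[off:off + self.k]
            if "N" in word:
                continue
            for pos in self.seed_positions(word):
                start = pos - off
                if 0 <= start <= n - m:
                    candidates.add(start)
        hits = []
        for start in sorted(candidates):
            d = hamming_n(query, self.subject[start:start + m])
            if d <= max_mm:
                hits.append((start, d))
        return hits


class LocalScorer:
    """Best local-alignment score of many short queries against one subject.

    Exact DP on the full subject when it is small; otherwise seeds (exact
    k-words) vote for diagonal bands and the DP runs only on the padded
    band windows.  A query with no seed hit scores 0.
    """

    EXACT_CELL_LIMIT = 2_000_000  # full-DP cutoff in matrix cells

    def __init__(self, subject: str, seed_k: int = 12, pad: int = 60,
                 max_bands: int = 4, band_width: int = 32):
        self.subject = subject
        self.seed_k = seed_k
        self.pad = pad
        self.max_bands = max_bands
        self.band_width = band_width
        self._index: SeedIndex | None = None

    def _ensure_index(self) -> SeedIndex:
        if self._index is None:
            self._index = SeedIndex(self.subject, k=self.seed_k)
        return self._index

    def score(self, query: str) -> float:
        if not query:
            return 0.0
        if len(query) * len(self.subject) <= self.EXACT_CELL_LIMIT:
            return local_nt_score(query, self.subject)
        index = self._ensure_index()
        votes: dict[int, int] = defaultdict(int)
        k = self.seed_k
        for qpos in range(0, len(query) - k + 1):
            word = query[qpos:qpos + k]
            if "N" in word:
                continue
            for spos in index.seed_positions(word):
                votes[(spos - qpos) // self.band_width] += 1
        if not votes:
            return 0.0
        bands = sorted(votes, key=lambda b: -votes[b])[: self.max_bands]
        best = 0.0
        for band in bands:
            diag = band * self.band_width
            lo = max(0, diag - self.pad)
            hi = min(len(self.subject),
                     diag + self.band_width + len(query) + self.pad)
            best = max(best, local_nt_score(query, self.subject[lo:hi]))
        return best
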