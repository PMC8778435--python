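"""Fragmented nucleotide similarity and clade clustering of prophages.

The similarity statistic mirrors the fragmented all-vs-all BLASTn approach
used for phage heatmaps: the query is tiled into fragments (200 bp at
100 bp stride by default), each fragment is locally aligned against the
whole subject with blastn scoring, the best fragment score is normalised by
the fragment's self-score, and the percent similarity is the mean over
fragments (threshold 0%: no fragment filtering).  The statistic is
deliberately asymmetric — the query side is tiled — so the full ordered
matrix is computed.

Clades are single-linkage components over pairs whose symmetrised (mean of
the two directions) similarity exceeds the within-clade threshold (60% by
default); between-clade pairs above a reporting threshold (40%) are
recorded as inter-clade relations without merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .align import LocalScorer, NT_MATCH


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray          # percent, asymmetric, diagonal = 100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def symmetrised(self) -> np.ndarray:
        return (self.values + self.values.T) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class CladeAssignment:
    clade_of: dict[str, int]                      # prophage id -> clade no.
    relations: list[tuple[int, int, float]] = field(default_factory=list)

    def members(self, clade: int) -> list[str]:
        return sorted(p for p, c in self.clade_of.items() if c == clade)

    @property
    def n_clades(self) -> int:
        return len(set(self.clade_of.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"prophage": p, "clade": c}
                for p, c in sorted(self.clade_of.items())]
        return pd.DataFrame(rows, columns=["prophage", "clade"])


def fragmented_similarity(query: str, subject: str, frag: int = 200,
                          step: int = 100,
                          scorer: LocalScorer | None = None) -> float:
    """Mean best-fragment normalised local-alignment score, in percent.

    A query shorter than one fragment is treated as a single whole-sequence
    fragment.  Identical sequences score exactly 100.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if scorer is None:
        scorer = LocalScorer(subject)
    if len(query) < frag:
        starts: list[int] = [0]
        frag = len(query)
    else:
        starts = list(range(0, len(query) - frag + 1, step))
    total = 0.0
    for s in starts:
        piece = query[s:s + frag]
        score = scorer.score(piece)
        total += min(max(score / (len(piece) * NT_MATCH), 0.0), 1.0)
    return 100.0 * total / len(starts)


def similarity_matrix(sequences: dict[str, str], frag: int = 200,
                      step: int = 100) -> SimilarityMatrix:
    """All ordered pairs; the diagonal is 100 by the self-identity
    invariant.  One seed index per subject is shared across queries."""
    ids = list(sequences)
    if not ids:
        raise ValueError("no sequences")
    n = len(ids)
    values = np.full((n, n), 100.0)
    scorers = {i: LocalScorer(sequences[i]) for i in ids}
    for j, subject_id in enumerate(ids):
        scorer = scorers[subject_id]
        for i, query_id in enumerate(ids):
            if i == j:
                continue
            values[i, j] = fragmented_similarity(
                sequences[query_id], sequences[subject_id],
                frag=frag, step=step, scorer=scorer)
    return SimilarityMatrix(ids=ids, values=values)


def cluster_clades(matrix: SimilarityMatrix, within: float = 60.0,
                   report_threshold: float = 40.0) -> CladeAssignment:
    """Single-linkage clades over symmetrised similarity > ``within``.

    Clades are numbered by descending size, then by first appearance in the
    matrix id order.  Between-clade pairs whose best symmetrised similarity
    exceeds ``report_threshold`` are reported as inter-clade relations.
    """
    sym = matrix.symmetrised()
    ids = matrix.ids
    graph = nx.Graph()
    graph.add_nodes_from(range(len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if sym[i, j] > within:
                graph.add_edge(i, j)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    clade_of = {}
    for number, comp in enumerate(components, start=1):
        for i in comp:
            clade_of[ids[i]] = number
    relations = []
    for a in range(len(components)):
        for b in range(a + 1, len(components)):
            best = max(sym[i, j] for i in components[a]
                       for j in components[b])
            if best > report_threshold:
                relations.append((a + 1, b + 1, float(best)))
    return CladeAssignment(clade_of=clade_of, relations=relations)
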