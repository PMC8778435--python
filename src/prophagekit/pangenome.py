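"""Ortholog clustering, core/accessory/unique classification and Heap's-law
openness of a genome cohort.

Proteins from different genomes are joined by reciprocal best hits (local
BLOSUM62 alignment, identity >= 30% and coverage >= 70% of the shorter
sequence by default) and orthologous groups (OGs) are the connected
components of that graph.  OG categories follow the usual pangenome
partition: *core* OGs span every genome, *unique* OGs sit in exactly one,
everything else is *accessory*.  Pan/core accumulation curves over random
genome orderings feed a power-law fit y = A x^B + C; an exponent B strictly
between 0 and 1 is read, per Heap's law, as an open pangenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.optimize import curve_fit

from .align import protein_identity_coverage
from .seqio import FeatureKind, GenomeRecord, translate

Proteomes = dict[str, dict[str, str]]   # genome_id -> gene_id -> protein


@dataclass
class OrthologGroup:
    og_id: str
    members: set[tuple[str, str]]       # (genome_id, gene_id)
    category: str | None = None         # core | accessory | unique

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class PangenomeModel:
    A_pan: float
    B_pan: float
    C_pan: float
    open: bool
    converged: bool = True


def proteome_from_genome(genome: GenomeRecord) -> dict[str, str]:
    """Translate every gene feature; gene ids are locus tags (or synthesised
    from coordinates when absent)."""
    proteome = {}
    for f in genome.features:
        if f.kind != FeatureKind.gene:
            continue
        if len(f) % 3 != 0:
            continue
        gene_id = f.locus_tag or f"{genome.id}:{f.start}-{f.end}"
        proteome[gene_id] = translate(genome.feature_sequence(f))
    return proteome


def pairwise_protein_similarity(a: str, b: str) -> tuple[float, float]:
    """Local-alignment identity and shorter-sequence coverage (see align)."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    return protein_identity_coverage(a, b)


def _kmer_set(protein: str, k: int = 5) -> set[str]:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def _best_hits(source: dict[str, str], target: dict[str, str],
               min_identity: float, min_coverage: float,
               cache: dict) -> dict[str, str]:
    """Best qualifying hit in `target` for each protein of `source`.

    Candidate pairs are restricted to proteins sharing at least one exact
    amino-acid 5-mer (a lossless-in-practice prefilter at the 30% identity
    / 70% coverage thresholds on realistic protein lengths).  Ties break by
    higher identity, then lexicographic gene id.
    """
    target_kmers: dict[str, set[str]] = {}
    kmer_index: dict[str, set[str]] = {}
    for gid, prot in target.items():
        ks = _kmer_set(prot)
        target_kmers[gid] = ks
        for km in ks:
            kmer_index.setdefault(km, set()).add(gid)
    best: dict[str, str] = {}
    for sid in sorted(source):
        sprot = source[sid]
        candidates: set[str] = set()
        for km in _kmer_set(sprot):
            candidates |= kmer_index.get(km, set())
        best_key = None
        best_tid = None
        for tid in sorted(candidates):
            pair = (sprot, target[tid]) if sprot <= target[tid] \
                else (target[tid], sprot)
            if pair not in cache:
                cache[pair] = pairwise_protein_similarity(*pair)
            identity, coverage = cache[pair]
            if identity < min_identity or coverage < min_coverage:
                continue
            # candidates scanned in lexicographic order, so a strict
            # comparison implements the (identity, gene id) tie-break
            if best_key is None or identity > best_key:
                best_key, best_tid = identity, tid
        if best_tid is not None:
            best[sid] = best_tid
    return best


def cluster_orthologs(proteomes: Proteomes, min_identity: float = 0.30,
                      min_coverage: float = 0.70) -> list[OrthologGroup]:
    """Reciprocal-best-hit graph + connected components.

    An edge joins proteins of two different genomes iff both alignment
    thresholds hold and each is the other's best hit in the counterpart
    genome.  The partition is invariant under genome input order.  A genome
    with an empty proteome is tolerated (it simply contributes no nodes).
    """
    if len(proteomes) < 2:
        raise ValueError("ortholog clustering needs at least 2 genomes")
    genome_ids = sorted(proteomes)
    graph = nx.Graph()
    for g in genome_ids:
        for gene in proteomes[g]:
            graph.add_node((g, gene))
    cache: dict = {}
    for i, gi in enumerate(genome_ids):
        for gj in genome_ids[i + 1:]:
            fwd = _best_hits(proteomes[gi], proteomes[gj],
                             min_identity, min_coverage, cache)
            rev = _best_hits(proteomes[gj], proteomes[gi],
                             min_identity, min_coverage, cache)
            for a, b in fwd.items():
                if rev.get(b) == a:
                    graph.add_edge((gi, a), (gj, b))
    components = sorted(nx.connected_components(graph),
                        key=lambda comp: sorted(comp))
    return [OrthologGroup(og_id=f"OG{i + 1:05d}", members=set(comp))
            for i, comp in enumerate(components)]


def classify(ogs: list[OrthologGroup], n_genomes: int,
             proteome_sizes: dict[str, int] | None = None) -> dict:
    """Assign core/accessory/unique categories and summarise.

    The summary reports pan/core/accessory/unique counts, per-genome unique
    counts and, when proteome sizes are supplied, the fraction of an
    average-sized genome represented by the core
    (``core_count / mean proteome size``).
    """
    per_genome_unique: dict[str, int] = {}
    counts = {"core": 0, "accessory": 0, "unique": 0}
    for og in ogs:
        spanned = og.genomes
        if len(spanned) == n_genomes:
            og.category = "core"
        elif len(spanned) == 1:
            og.category = "unique"
            g = next(iter(spanned))
            per_genome_unique[g] = per_genome_unique.get(g, 0) + 1
        else:
            og.category = "accessory"
        counts[og.category] += 1
    summary = {
        "pan_size": len(ogs),
        "core_size": counts["core"],
        "accessory_size": counts["accessory"],
        "unique_size": counts["unique"],
        "per_genome_unique": per_genome_unique,
    }
    if proteome_sizes:
        summary["mean_proteome_size"] = float(np.mean(list(proteome_sizes.values())))
        summary["core_fraction_of_average_genome"] = core_genome_fraction(
            counts["core"], summary["mean_proteome_size"])
    return summary


def core_genome_fraction(core_count: int, mean_proteome_size: float) -> float:
    """Core OGs as a fraction of the average genome's gene complement."""
    if mean_proteome_size <= 0:
        raise ValueError("mean proteome size must be positive")
    return core_count / mean_proteome_size


def accumulation_curves(ogs: list[OrthologGroup], genome_ids: list[str],
                        n_permutations: int = 100,
                        rng: np.random.Generator | int | None = None
                        ) -> pd.DataFrame:
    """Pan (cumulative union) and core (cumulative intersection) sizes over
    random genome orderings; mean and quartiles per x."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    genome_ids = list(genome_ids)
    n = len(genome_ids)
    membership = [frozenset(og.genomes) for og in ogs]
    pan = np.zeros((n_permutations, n), dtype=int)
    core = np.zeros((n_permutations, n), dtype=int)
    for p in range(n_permutations):
        order = [genome_ids[i] for i in rng.permutation(n)]
        for x in range(1, n + 1):
            seen = set(order[:x])
            pan[p, x - 1] = sum(1 for m in membership if m & seen)
            core[p, x - 1] = sum(1 for m in membership if seen <= m)
    rows = {
        "x": np.arange(1, n + 1),
        "pan_mean": pan.mean(axis=0),
        "pan_q25": np.quantile(pan, 0.25, axis=0),
        "pan_q75": np.quantile(pan, 0.75, axis=0),
        "core_mean": core.mean(axis=0),
        "core_q25": np.quantile(core, 0.25, axis=0),
        "core_q75": np.quantile(core, 0.75, axis=0),
    }
    return pd.DataFrame(rows)


def fit_heaps(curve: pd.DataFrame | tuple) -> PangenomeModel:
    """Nonlinear least squares of y = A x^B + C to the mean pan curve.

    Initialised at A = y(1), B = 0.5, C = 0.  Openness is read strictly:
    open iff 0 < B < 1.  A numerically constant curve short-circuits to
    B = 0 (closed); non-convergence returns a flagged model instead of
    raising.
    """
    if isinstance(curve, pd.DataFrame):
        x = curve["x"].to_numpy(dtype=float)
        y = curve["pan_mean"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    if len(x) < 4:
        raise ValueError("Heap's-law fit needs at least 4 points")
    if np.ptp(y) < 1e-9:
        return PangenomeModel(A_pan=0.0, B_pan=0.0, C_pan=float(y[0]),
                              open=False)

    def model(xv, a, b, c):
        return a * np.power(xv, b) + c

    try:
        popt, _ = curve_fit(model, x, y, p0=(y[0], 0.5, 0.0), maxfev=20000)
    except RuntimeError:
        return PangenomeModel(A_pan=float("nan"), B_pan=float("nan"),
                              C_pan=float("nan"), open=False,
                              converged=False)
    a, b, c = (float(v) for v in popt)
    return PangenomeModel(A_pan=a, B_pan=b, C_pan=c, open=0.0 < b < 1.0)


def ogs_to_frame(ogs: list[OrthologGroup]) -> pd.DataFrame:
    """Flat (og_id, genome, gene, category) table for TSV export."""
    rows = [
        {"og_id": og.og_id, "genome": g, "gene": gene,
         "category": og.category or ""}
        for og in ogs for g, gene in sorted(og.members)
    ]
    return pd.DataFrame(rows, columns=["og_id", "genome", "gene", "category"])
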