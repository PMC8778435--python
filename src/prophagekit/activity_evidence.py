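"""Evidence that prophages are active rather than domesticated.

Two lines of evidence are quantified:

* **Coverage ratio** — mean read depth over the prophage divided by mean
  depth over the host background (all prophage intervals excluded from the
  background by default).  Induced or replicating prophages show ratios
  above 1; a virion-enriched library shows large ratios.
* **Excision** — in-silico reversal of integration.  A prophage flanked by
  attL/attR direct repeats is excised: the host chromosome is restored
  with a single att copy (attB) and the prophage circularises carrying the
  other copy (attP).  Junction-spanning primer pairs amplify only from the
  circular form, which is the discriminating readout of the corresponding
  PCR assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .prophage_finder import ProphageRegion
from .seqio import Feature, GenomeRecord, reverse_complement


@dataclass
class CoverageProfile:
    genome_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")


@dataclass
class ExcisionResult:
    prophage_id: str
    circular_sequence: str
    restored_host: GenomeRecord
    attP_junction: str


def read_depth_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read a (chrom, 0-based position, depth) TSV into per-genome arrays."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["chrom", "pos", "depth"])
    profiles = {}
    for chrom, grp in frame.groupby("chrom", sort=False):
        arr = np.zeros(int(grp["pos"].max()) + 1, dtype=np.int64)
        arr[grp["pos"].to_numpy()] = grp["depth"].to_numpy()
        profiles[str(chrom)] = arr
    return profiles


def coverage_ratio(depth: np.ndarray, prophage: tuple[int, int],
                   all_prophages: Sequence[tuple[int, int]] | None = None,
                   exclude_prophages: bool = True,
                   stat: str = "mean") -> float:
    """Mean (or median) depth inside the prophage over mean depth outside.

    The host background excludes every prophage interval by default, so
    one induced prophage does not deflate the contrast for another.
    Returns NaN (flagged) when the host background has zero depth.
    """
    depth = np.asarray(depth, dtype=float)
    s, e = prophage
    if not 0 <= s < e <= len(depth):
        raise ValueError("prophage interval outside the depth profile")
    mask = np.ones(len(depth), dtype=bool)
    intervals = list(all_prophages) if (all_prophages is not None
                                        and exclude_prophages) else [prophage]
    for a, b in intervals:
        mask[a:b] = False
    agg = np.mean if stat == "mean" else np.median
    inside = float(agg(depth[s:e]))
    host = depth[mask]
    if host.size == 0 or float(np.mean(host)) == 0.0:
        return math.nan
    return inside / float(agg(host))


def excise(lysogen: GenomeRecord, region: ProphageRegion,
           junction_width: int = 100) -> ExcisionResult:
    """Excise a prophage region (interior + attR) from its host.

    Verifies the att direct-repeat geometry, returns the restored host
    (attB regenerated from the attL copy), the circularised prophage
    (one attP copy) and the junction sequence a circularisation amplicon
    would read (``junction_width`` nt centred on the att core across the
    circle's origin).
    """
    if region.att_core is None:
        raise ValueError(
            "region has no att core; run prophage_finder.predict_att first")
    core = region.att_core
    seq = lysogen.sequence
    la = len(core)
    if seq[region.start - la:region.start] != core or \
            seq[region.end - la:region.end] != core:
        raise ValueError("attL/attR direct repeats absent at the boundaries")
    circular = seq[region.start:region.end]
    restored_seq = seq[:region.start] + seq[region.end:]
    shift = region.end - region.start
    features = []
    for f in lysogen.features:
        if f.end <= region.start:
            features.append(Feature(kind=f.kind, start=f.start, end=f.end,
                                    strand=f.strand,
                                    attributes=dict(f.attributes)))
        elif f.start >= region.end:
            features.append(Feature(kind=f.kind, start=f.start - shift,
                                    end=f.end - shift, strand=f.strand,
                                    attributes=dict(f.attributes)))
    restored = GenomeRecord(id=lysogen.id, sequence=restored_seq,
                            features=features)
    half = junction_width // 2
    doubled = circular + circular
    centre = len(circular) - la + la // 2
    junction = doubled[max(0, centre - half):centre - half + junction_width]
    return ExcisionResult(
        prophage_id=f"{lysogen.id}:{region.start}-{region.end}",
        circular_sequence=circular, restored_host=restored,
        attP_junction=junction)


def insilico_pcr(template: str, fwd_primer: str, rev_primer: str,
                 circular: bool = False, max_product: int = 3000
                 ) -> list[str]:
    """Exact-match PCR emulation.

    The forward primer binds the + strand, the reverse primer binds the
    - strand (its reverse complement is searched on the + strand); products
    are convergent primer pairs spanning at most ``max_product``.  Circular
    templates are searched across the origin.  Returns the product
    sequences (possibly empty: no amplification).
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be at least 15 nt")
    template = template.upper()
    fwd = fwd_primer.upper()
    rev_rc = reverse_complement(rev_primer.upper())
    n = len(template)
    search = template + template if circular else template
    limit = min(max_product, n) if circular else max_product

    def occurrences(probe: str, text: str) -> list[int]:
        out, start = [], 0
        while (pos := text.find(probe, start)) != -1:
            out.append(pos)
            start = pos + 1
        return out

    f_sites = [p for p in occurrences(fwd, search) if p < n]
    r_sites = occurrences(rev_rc, search)
    products = set()
    for f in f_sites:
        for r in r_sites:
            end = r + len(rev_rc)
            length = end - f
            if f < end and 0 < length <= limit:
                products.add(search[f:end])
    return sorted(products)


def activity_table(profiles: dict[str, np.ndarray],
                   regions: Sequence[ProphageRegion]) -> pd.DataFrame:
    """Coverage fold per prophage region (host background excludes all
    regions of the same host)."""
    by_host: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_host.setdefault(r.host_id, []).append(r.interval)
    rows = []
    for r in regions:
        depth = profiles.get(r.host_id)
        fold = math.nan
        if depth is not None:
            fold = coverage_ratio(depth, r.interval,
                                  all_prophages=by_host[r.host_id])
        rows.append({"host": r.host_id, "left": r.start, "right": r.end,
                     "fold": round(fold, 2) if not math.isnan(fold)
                     else math.nan})
    return pd.DataFrame(rows, columns=["host", "left", "right", "fold"])
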