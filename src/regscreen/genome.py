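"""Detection of genomic regions enriched in co-regulated genes.

Two rules operate on the start-sorted gene order of each scaffold:

* windowed rule — three or more members of one expression cluster within a
  window of nine neighboring genes, with successive members at most five
  gene ranks apart. A region is the maximal gap-limited chain of same-cluster
  genes triggered by >= ``min_members`` inside some window of ``window``
  consecutive genes (the window predicate is monotone in the member set, so
  the maximal chains are well defined).
* adjacency rule — maximal runs of three or more rank-consecutive genes
  sharing one cluster ("adjacent patches").

Strand is ignored: co-regulated regions mix strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import ClusterAssignment
from .data import GeneLocus

DEFAULT_WINDOW = 9
DEFAULT_MIN_MEMBERS = 3
DEFAULT_MAX_GAP = 5
DEFAULT_MIN_RUN = 3


@dataclass(frozen=True)
class RegionCall:
    """One detected co-regulated region."""

    scaffold: str
    cluster_id: int
    member_gene_ids: tuple[str, ...]
    rank_span: tuple[int, int]  # first..last member rank (inclusive)
    bp_span: tuple[int, int]  # min start .. max end (1-based inclusive)
    kind: str  # "windowed" | "adjacent_patch"


def order_genes(loci: list[GeneLocus]) -> list[GeneLocus]:
    """Assign per-scaffold ranks by start coordinate (0-based, consecutive)."""
    seen: set[str] = set()
    for locus in loci:
        if locus.gene_id in seen:
            raise ValueError(f"duplicate gene id {locus.gene_id!r}")
        seen.add(locus.gene_id)
    ordered: list[GeneLocus] = []
    by_scaffold: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold, []).append(locus)
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(genes):
            ordered.append(
                GeneLocus(
                    gene_id=g.gene_id,
                    scaffold=g.scaffold,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    rank=rank,
                )
            )
    return ordered


def _scaffold_tracks(
    loci: list[GeneLocus], assignment: ClusterAssignment
) -> dict[str, list[tuple[int, str, int, GeneLocus]]]:
    """scaffold -> [(rank, gene_id, cluster, locus)], rank-sorted.

    Genes without a cluster assignment (or with a negative label) are kept in
    the rank order — they count as window neighbors and as gaps — but are
    never region members.
    """
    labels = assignment.labels
    locus_ids = {locus.gene_id for locus in loci}
    missing = [g for g in labels.index if g not in locus_ids]
    if missing:
        raise ValueError(f"assigned genes without loci: {missing[:5]}")
    tracks: dict[str, list] = {}
    for locus in loci:
        if locus.rank < 0:
            raise ValueError(
                f"locus {locus.gene_id} has no rank; call order_genes first"
            )
        cluster = int(labels.get(locus.gene_id, -1))
        tracks.setdefault(locus.scaffold, []).append(
            (locus.rank, locus.gene_id, cluster, locus)
        )
    for scaffold in tracks:
        tracks[scaffold].sort()
    return tracks


def _make_region(members: list[tuple[int, str, int, GeneLocus]], cluster: int,
                 scaffold: str, kind: str) -> RegionCall:
    return RegionCall(
        scaffold=scaffold,
        cluster_id=cluster,
        member_gene_ids=tuple(m[1] for m in members),
        rank_span=(members[0][0], members[-1][0]),
        bp_span=(
            min(m[3].start for m in members),
            max(m[3].end for m in members),
        ),
        kind=kind,
    )


def find_coregulated_regions(
    loci: list[GeneLocus],
    assignment: ClusterAssignment,
    window: int = DEFAULT_WINDOW,
    min_members: int = DEFAULT_MIN_MEMBERS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[RegionCall]:
    """Windowed co-regulation scan (defaults: window 9, >=3 members, gap <=5).

    Per scaffold and cluster, member ranks are grown left-to-right into
    maximal chains with successive-member rank gaps <= ``max_gap``; a chain
    is emitted when some stretch of ``window`` consecutive genes contains
    >= ``min_members`` of it. Output is sorted by (scaffold, first rank,
    cluster).
    """
    if window < min_members:
        raise ValueError(f"window ({window}) must be >= min_members ({min_members})")
    tracks = _scaffold_tracks(loci, assignment)
    calls: list[RegionCall] = []
    for scaffold, track in tracks.items():
        clusters = sorted({c for _, _, c, _ in track if c >= 0})
        for cluster in clusters:
            members = [t for t in track if t[2] == cluster]
            # maximal chains under the gap rule
            chains: list[list] = []
            for t in members:
                if chains and t[0] - chains[-1][-1][0] <= max_gap:
                    chains[-1].append(t)
                else:
                    chains.append([t])
            for chain in chains:
                if len(chain) < min_members:
                    continue
                ranks = [t[0] for t in chain]
                # window trigger: some `window` consecutive ranks hold
                # >= min_members chain members
                triggered = any(
                    ranks[i + min_members - 1] - ranks[i] <= window - 1
                    for i in range(len(ranks) - min_members + 1)
                )
                if triggered:
                    calls.append(_make_region(chain, cluster, scaffold, "windowed"))
    calls.sort(key=lambda r: (r.scaffold, r.rank_span[0], r.cluster_id))
    return calls


def find_adjacent_patches(
    loci: list[GeneLocus],
    assignment: ClusterAssignment,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[RegionCall]:
    """Maximal runs of >= ``min_run`` rank-consecutive same-cluster genes."""
    tracks = _scaffold_tracks(loci, assignment)
    calls: list[RegionCall] = []
    for scaffold, track in tracks.items():
        run: list = []
        for t in track + [(-1, "", -10**9, None)]:  # sentinel flushes the last run
            if run and t[2] == run[-1][2] and t[0] == run[-1][0] + 1 and t[2] >= 0:
                run.append(t)
                continue
            if len(run) >= min_run and run[0][2] >= 0:
                calls.append(
                    _make_region(run, run[0][2], scaffold, "adjacent_patch")
                )
            run = [t] if t[3] is not None else []
    calls.sort(key=lambda r: (r.scaffold, r.rank_span[0], r.cluster_id))
    return calls


def regions_to_frame(regions: list[RegionCall]) -> pd.DataFrame:
    """Tabular view of region calls (one row per region)."""
    return pd.DataFrame(
        [
            {
                "scaffold": r.scaffold,
                "cluster": r.cluster_id,
                "kind": r.kind,
                "first_rank": r.rank_span[0],
                "last_rank": r.rank_span[1],
                "start": r.bp_span[0],
                "end": r.bp_span[1],
                "n_members": len(r.member_gene_ids),
                "member_gene_ids": ",".join(r.member_gene_ids),
            }
            for r in regions
        ],
        columns=[
            "scaffold", "cluster", "kind", "first_rank", "last_rank",
            "start", "end", "n_members", "member_gene_ids",
        ],
    )


def region_gene_ids(regions: list[RegionCall]) -> set[str]:
    return {g for r in regions for g in r.member_gene_ids}


def annotate_neighbors(
    regions: list[RegionCall],
    candidate_ids: list[str],
    roles: pd.Series,
    loci: list[GeneLocus],
    flank: int = 1,
) -> pd.DataFrame:
    """Roles of the genes flanking each candidate, plus region context.

    For each candidate, reports every gene within ``flank`` ranks on the same
    scaffold with its role (CAZy / transporter / regulator / other), whether
    the candidate lies inside a detected region and whether a CAZy or
    transporter gene is a direct neighbor.
    """
    by_pos: dict[tuple[str, int], GeneLocus] = {}
    locus_of: dict[str, GeneLocus] = {}
    for locus in loci:
        by_pos[(locus.scaffold, locus.rank)] = locus
        locus_of[locus.gene_id] = locus
    in_region = region_gene_ids(regions)
    rows = []
    for gid in candidate_ids:
        locus = locus_of.get(gid)
        if locus is None:
            raise ValueError(f"candidate {gid!r} has no locus")
        if gid not in roles.index:
            raise ValueError(f"no role defined for candidate {gid!r}")
        neighbors = []
        for off in range(-flank, flank + 1):
            if off == 0:
                continue
            other = by_pos.get((locus.scaffold, locus.rank + off))
            if other is None:
                continue
            if other.gene_id not in roles.index:
                raise ValueError(f"no role defined for neighbor {other.gene_id!r}")
            neighbors.append((other.gene_id, str(roles[other.gene_id]), abs(off)))
        rows.append(
            {
                "gene_id": gid,
                "scaffold": locus.scaffold,
                "rank": locus.rank,
                "in_region": gid in in_region,
                "near_cazy_or_transporter": any(
                    role in ("CAZy", "transporter") for _, role, _ in neighbors
                ),
                "neighbors": ";".join(
                    f"{g}:{role}:{d}" for g, role, d in neighbors
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "scaffold", "rank", "in_region",
            "near_cazy_or_transporter", "neighbors",
        ],
    )
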