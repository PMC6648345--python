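"""Scanning and comparison workflows built on the aligner.

Horizontal scanning tiles one epigenome into fixed-size regions, aligns
every region against every other, and standardizes each region's best hit
against a permutation null ("horizontal alignment score").  Vertical
alignment compares the same region's sequences across epigenomes, with a
one-sided Wilcoxon rank-sum test contrasting within-group and between-group
scores.  A naive proportion-based score, region-similarity clustering, and
epigenome-level clustering round out the toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .aligner import ScoreParams, align_score
from .randomization import TAU, RngLike, _as_rng, normalized_score, randomize_sequence
from .segmentation_io import (
    GenomicRegion,
    SegmentationTrack,
    extract_region,
    tile_genome,
)
from .state_model import CompressedSequence, StateAlphabet

__all__ = [
    "HorizontalScanResult",
    "GroupComparisonResult",
    "horizontal_scan",
    "naive_horizontal_scan",
    "top_regions",
    "vertical_align",
    "group_compare",
    "group_compare_regions",
    "naive_score",
    "region_similarity",
    "epigenome_cluster",
]


@dataclass
class HorizontalScanResult:
    """Per-region best hits and horizontal alignment scores.

    ``table`` columns: chrom, start, end, name, best_name, raw_score,
    horizontal_score, provenance.  Empty regions are skipped and listed in
    ``skipped``.
    """

    table: pd.DataFrame
    regions: list[GenomicRegion]
    skipped: list[GenomicRegion] = field(default_factory=list)


def _region_sequences(
    track: SegmentationTrack, bin_size: int
) -> tuple[list[GenomicRegion], list[CompressedSequence], list[GenomicRegion]]:
    usable_regions, seqs, skipped = [], [], []
    for region in tile_genome(track, bin_size=bin_size):
        seq = extract_region(track, region)
        if len(seq) == 0:
            skipped.append(region)
        else:
            usable_regions.append(region)
            seqs.append(seq)
    return usable_regions, seqs, skipped


def _pairwise_scores(seqs: Sequence[CompressedSequence], params: ScoreParams):
    m = len(seqs)
    scores = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            scores[i, j] = scores[j, i] = align_score(seqs[i], seqs[j], params)
    return scores


def horizontal_scan(
    track: SegmentationTrack,
    params: Optional[ScoreParams] = None,
    bin_size: int = 500_000,
    B: int = 100,
    rng: RngLike = None,
) -> HorizontalScanResult:
    """Best-hit-except-self scan of one epigenome.

    Each tiled region is aligned (raw score) against every other region;
    the best hit is the region with the highest raw score (ties broken by
    genome order).  The best-hit score is then standardized against its
    permutation null: in each of B replicates every other region's sequence
    is segment-permuted and the query's best hit against that randomized
    database is recorded.  The horizontal score is the z-score of the real
    best hit against those B null best hits, so a query with no non-random
    sequential affinity to any other region scores near 0 no matter how
    many regions compete.
    """
    params = params or ScoreParams()
    rng = _as_rng(rng)
    regions, seqs, skipped = _region_sequences(track, bin_size)
    m = len(regions)
    if m < 2:
        raise ValueError("horizontal scan needs at least 2 non-empty regions")
    if B < 2:
        raise ValueError("need B >= 2 null replicates")
    scores = _pairwise_scores(seqs, params)
    np.fill_diagonal(scores, -np.inf)
    null = np.empty((B, m))
    for b in range(B):
        perms = [randomize_sequence(s, rng) for s in seqs]
        null_scores = np.full((m, m), -np.inf)
        for i in range(m):
            for j in range(m):
                if i != j:
                    null_scores[i, j] = align_score(seqs[i], perms[j], params)
        null[b] = null_scores.max(axis=1)
    null_mean = null.mean(axis=0)
    null_sd = np.maximum(null.std(axis=0, ddof=1), TAU)
    rows = []
    prov = track.provenance or {}
    for i, region in enumerate(regions):
        j = int(np.argmax(scores[i]))  # ties -> first in genome order
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "name": region.display_name,
                "best_name": regions[j].display_name,
                "raw_score": scores[i, j],
                "horizontal_score": (scores[i, j] - null_mean[i]) / null_sd[i],
                "provenance": prov.get(region.display_name, ""),
            }
        )
    return HorizontalScanResult(pd.DataFrame(rows), regions, skipped)


def naive_horizontal_scan(
    track: SegmentationTrack,
    bin_size: int = 500_000,
    basis: str = "compressed_occurrences",
) -> HorizontalScanResult:
    """Proportion-based baseline scan: best hit by the naive score.

    Same region universe as :func:`horizontal_scan`; the per-region score is
    its best-hit-except-self naive score (no permutation normalization --
    the naive score does not depend on sequential order, so the null is
    degenerate by construction).
    """
    regions, seqs, skipped = _region_sequences(track, bin_size)
    if len(regions) < 2:
        raise ValueError("horizontal scan needs at least 2 non-empty regions")
    alphabet = track.alphabet
    m = len(regions)
    scores = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            scores[i, j] = scores[j, i] = naive_score(
                seqs[i], seqs[j], alphabet, basis=basis
            )
    np.fill_diagonal(scores, -np.inf)
    prov = track.provenance or {}
    rows = []
    for i, region in enumerate(regions):
        j = int(np.argmax(scores[i]))
        rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "name": region.display_name,
                "best_name": regions[j].display_name,
                "raw_score": scores[i, j],
                "horizontal_score": scores[i, j],
                "provenance": prov.get(region.display_name, ""),
            }
        )
    return HorizontalScanResult(pd.DataFrame(rows), regions, skipped)


def top_regions(result: HorizontalScanResult, k: int = 500) -> pd.DataFrame:
    """The k regions with the highest horizontal scores (ties: genome order)."""
    df = result.table
    if k > len(df):
        import warnings

        warnings.warn(
            f"requested top {k} of only {len(df)} regions; returning all",
            stacklevel=2,
        )
        k = len(df)
    order = np.lexsort((np.arange(len(df)), -df["horizontal_score"].to_numpy()))
    return df.iloc[order[:k]].reset_index(drop=True)


def vertical_align(
    tracks: Sequence[SegmentationTrack],
    regions: Sequence[GenomicRegion],
    params: Optional[ScoreParams] = None,
    track_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Raw alignment scores of each region across every unordered track pair.

    Returns a long-form frame with columns (region, track_i, track_j,
    score); a region empty in either track yields NaN for that pair.
    """
    params = params or ScoreParams()
    if len(tracks) < 2:
        raise ValueError("vertical alignment needs at least 2 tracks")
    names = list(track_names) if track_names else [f"track{i}" for i in range(len(tracks))]
    common = set(tracks[0].chroms)
    for t in tracks[1:]:
        common &= set(t.chroms)
    if not common:
        raise ValueError("tracks share no chromosomes")
    rows = []
    for region in regions:
        seqs = [
            extract_region(t, region) if region.chrom in t.intervals else None
            for t in tracks
        ]
        for i in range(len(tracks)):
            for j in range(i + 1, len(tracks)):
                si, sj = seqs[i], seqs[j]
                if si is None or sj is None or len(si) == 0 or len(sj) == 0:
                    score = np.nan
                else:
                    score = align_score(si, sj, params)
                rows.append(
                    {
                        "region": region.display_name,
                        "track_i": names[i],
                        "track_j": names[j],
                        "score": score,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparisonResult:
    """One-sided rank-sum comparison of within- vs between-group scores."""

    p_value: float
    statistic: float
    n_within: int
    n_between: int
    method: str  # "exact" or "asymptotic"
    direction: str = "within > between"


def group_compare(
    scores_within: Sequence[float], scores_between: Sequence[float]
) -> GroupComparisonResult:
    """Two-sample one-sided Wilcoxon rank-sum test.

    Tests H1: within-group scores are stochastically larger than
    between-group scores.  The exact null distribution is enumerated when
    the combined sample size is at most 20 and there are no ties; otherwise
    the normal approximation with tie correction is used.
    """
    within = np.asarray(scores_within, dtype=float)
    between = np.asarray(scores_between, dtype=float)
    if within.size == 0 or between.size == 0:
        raise ValueError("both score lists must be non-empty")
    combined = np.concatenate([within, between])
    ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        within,
        between,
        alternative="greater",
        method="exact" if method == "exact" else "asymptotic",
    )
    return GroupComparisonResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        n_within=int(within.size),
        n_between=int(between.size),
        method=method,
    )


def group_compare_regions(
    scores: pd.DataFrame, groups: dict[str, str], focal_group: Optional[str] = None
) -> pd.DataFrame:
    """Per-region within- vs between-group comparison of vertical scores.

    ``scores`` is the long-form output of :func:`vertical_align`; ``groups``
    maps track name -> group label.  Within-group scores are pairs whose two
    tracks share a label (restricted to ``focal_group`` when given, mirroring
    e.g. a male-vs-male against male-vs-female contrast); between-group
    scores are pairs with differing labels.  Returns one row per region,
    sorted by p-value.
    """
    rows = []
    for region, sub in scores.groupby("region", sort=False):
        gi = sub["track_i"].map(groups)
        gj = sub["track_j"].map(groups)
        valid = sub["score"].notna()
        same = (gi == gj) & valid
        if focal_group is not None:
            same &= gi == focal_group
        diff = (gi != gj) & valid
        if focal_group is not None:
            diff &= (gi == focal_group) | (gj == focal_group)
        if not same.any() or not diff.any():
            continue
        res = group_compare(sub.loc[same, "score"], sub.loc[diff, "score"])
        rows.append(
            {
                "region": region,
                "p_value": res.p_value,
                "n_within": res.n_within,
                "n_between": res.n_between,
                "method": res.method,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    )


def naive_score(
    s1: CompressedSequence,
    s2: CompressedSequence,
    alphabet: Optional[StateAlphabet] = None,
    basis: str = "compressed_occurrences",
) -> float:
    """Proportion-based baseline: minus squared distance of state proportions.

    M_naive = -sum_q (p_1q - p_2q)^2 over the Q states, with proportions
    computed over compressed occurrences (default) or raw bins.  Always in
    [-2, 0]; 0 iff the proportion vectors coincide.
    """
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("naive score requires non-empty sequences")
    alphabet = alphabet or s1.alphabet or s2.alphabet
    q = alphabet.size if alphabet else int(max(s1.states.max(), s2.states.max()))

    def proportions(seq: CompressedSequence) -> np.ndarray:
        w = seq.run_lengths if basis == "raw_bins" else np.ones(len(seq))
        p = np.bincount(seq.states, weights=w, minlength=q + 1)[1:]
        return p / p.sum()

    d = proportions(s1) - proportions(s2)
    return float(-(d @ d))


def region_similarity(
    seqs: Sequence[CompressedSequence],
    params: Optional[ScoreParams] = None,
    alpha: float = 1.1,
    n_clusters: Optional[int] = 4,
):
    """Pairwise similarity matrix of regions and its average-linkage clustering.

    Off-diagonal similarities are raw alignment scores scaled by alpha times
    the maximum off-diagonal score, so A_ii = 1 and 0 < A_ij < 1 whenever
    all pairwise scores are positive; the distance D = 1 - A feeds
    average-linkage agglomerative clustering.  With ``n_clusters=None`` the
    cut is placed at the largest merge-height gap.

    Returns ``(A, labels, linkage)``.
    """
    params = params or ScoreParams()
    m = len(seqs)
    if m < 2:
        raise ValueError("need at least 2 regions")
    if any(len(s) == 0 for s in seqs):
        raise ValueError("all regions must be non-empty")
    scores = _pairwise_scores(seqs, params)
    iu = np.triu_indices(m, k=1)
    max_off = scores[iu].max()
    if max_off <= 0:
        raise ValueError("degenerate similarity matrix: all pairwise scores <= 0")
    a = scores / (alpha * max_off)
    np.fill_diagonal(a, 1.0)
    d = 1.0 - a
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    if n_clusters is None:
        heights = z[:, 2]
        gaps = np.diff(heights)
        n_clusters = m - (int(np.argmax(gaps)) + 1) if gaps.size else 1
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return a, labels, z


def epigenome_cluster(score_vectors: pd.DataFrame):
    """Cluster epigenomes by their horizontal-score vectors.

    ``score_vectors`` is an epigenome x region frame; regions with a missing
    value in any epigenome are dropped listwise.  Pairwise Pearson
    correlations define the distance 1 - r, clustered with average linkage.

    Returns ``(correlations, linkage, leaf_order)`` with correlations as a
    labeled DataFrame and leaf_order a list of epigenome names.
    """
    df = score_vectors.dropna(axis=1)
    if len(df) < 2:
        raise ValueError("need at least 2 epigenomes")
    mat = df.to_numpy(dtype=float)
    sds = mat.std(axis=1)
    if np.any(sds == 0):
        bad = df.index[int(np.argmax(sds == 0))]
        raise ValueError(f"epigenome {bad!r} has a zero-variance score vector")
    r = np.corrcoef(mat)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # guard float asymmetry
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    order = [df.index[i] for i in hierarchy.leaves_list(z)]
    corr = pd.DataFrame(r, index=df.index, columns=df.index)
    return corr, z, order
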