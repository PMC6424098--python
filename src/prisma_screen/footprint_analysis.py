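"""Interaction footprints and per-spot accumulation over filtered profiles.

A protein's footprint is the set of parent-protein residue intervals implied
by its surviving tiles: maximal runs of consecutive tiles map to intervals
from the first residue of the run's first tile to the last residue of its
last tile (overlapping intervals from nearby runs are merged). Per-spot
accumulated intensity sums normalized profile values over a protein set —
over all core interactors it gives the screen-wide binding landscape, over a
complex's members the complex footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from prisma_screen.core_pipeline import BindingProfile
from prisma_screen.matrix_design import TilingPeptide


@dataclass(frozen=True)
class Footprint:
    uniprot_id: str
    intervals: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted, disjoint
    spot_runs: tuple[tuple[int, int], ...]  # contributing tile_index runs


@dataclass
class SpotAccumulation:
    """Per-spot sum of normalized intensities plus contributing protein counts."""

    spots: list[str]
    total: np.ndarray
    protein_count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": self.spots,
                "accumulated_intensity": self.total,
                "protein_count": self.protein_count,
            }
        )


def accumulated_spot_intensity(
    profiles: Sequence[BindingProfile], spots: Sequence[str]
) -> SpotAccumulation:
    """Sum normalized profile values per spot over a protein set."""
    states = {p.normalized for p in profiles}
    if len(states) > 1:
        raise ValueError("profiles mix normalized and raw values")
    total = np.zeros(len(spots))
    count = np.zeros(len(spots), dtype=int)
    for p in profiles:
        v = np.asarray(p.values)
        if len(v) != len(spots):
            raise ValueError(f"profile {p.uniprot_id!r} does not match spot count")
        total += v
        count += (v > 0).astype(int)
    return SpotAccumulation(list(spots), total, count)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return tuple(merged)


def protein_footprint(
    profile: BindingProfile, design: Sequence[TilingPeptide]
) -> Footprint:
    """Residue intervals implied by a filtered profile's surviving tiles.

    Only unmodified tiles define the intervals (PTM-variant spots occupy
    identical coordinates and collapse to their parent tile).
    """
    marked: set[int] = {
        t.tile_index for t, v in zip(design, profile.values) if v > 0
    }
    runs: list[tuple[int, int]] = []
    for idx in sorted(marked):
        if runs and idx == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], idx)
        else:
            runs.append((idx, idx))
    by_index = {t.tile_index: t for t in design if not t.is_modified}
    intervals = _merge_intervals(
        (by_index[first].start, by_index[last].end) for first, last in runs
    )
    return Footprint(profile.uniprot_id, intervals, tuple(runs))


def complex_footprint(
    member_ids: Iterable[str],
    profiles: Sequence[BindingProfile],
    spots: Sequence[str],
) -> SpotAccumulation:
    """Per-spot accumulation over a complex's members found in the screen.

    Members absent from the screen contribute zero (logged); an empty match
    yields an all-zero accumulation with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    by_id = {p.uniprot_id: p for p in profiles}
    found = [by_id[m] for m in member_ids if m in by_id]
    missing = sorted(set(member_ids) - set(by_id))
    if missing:
        logger.info("complex members absent from screen: %s", ", ".join(missing))
    if not found:
        logger.warning("no complex members found in screen")
    return accumulated_spot_intensity(found, spots)


def cluster_heatmap_matrix(
    profiles: Sequence[BindingProfile],
    spots: Sequence[str],
    method: str = "average",
    metric: str = "euclidean",
) -> tuple[list[str], pd.DataFrame]:
    """Row order and matrix for a clustered binding heatmap.

    Agglomerative hierarchical clustering (default average linkage on
    Euclidean distances between normalized profiles). Input rows are sorted
    by id before clustering, so the leaf order is deterministic and invariant
    to input permutation up to the id tie-break. A single profile is returned
    as-is.
    """
    ordered = sorted(profiles, key=lambda p: p.uniprot_id)
    matrix = pd.DataFrame(
        [np.asarray(p.values) for p in ordered],
        index=[p.uniprot_id for p in ordered],
        columns=list(spots),
    )
    if len(ordered) < 2:
        return list(matrix.index), matrix
    z = linkage(matrix.to_numpy(), method=method, metric=metric)
    order = leaves_list(z)
    row_order = [matrix.index[i] for i in order]
    return row_order, matrix.loc[row_order]


def footprints_to_frame(footprints: Sequence[Footprint]) -> pd.DataFrame:
    """BED-like table of footprint intervals (1-based inclusive coordinates)."""
    rows = [
        {"uniprot_id": f.uniprot_id, "start": s, "end": e}
        for f in footprints
        for s, e in f.intervals
    ]
    return pd.DataFrame(rows, columns=["uniprot_id", "start", "end"])


def plot_heatmap(matrix: pd.DataFrame, path: str) -> None:
    """Static heatmap of a clustered binding matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, max(3, 0.02 * len(matrix))))
    ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xlabel("matrix spot")
    ax.set_ylabel("protein")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
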