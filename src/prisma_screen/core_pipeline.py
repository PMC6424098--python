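"""Replicate integration, normalization, filtering, and interactor sets.

The pipeline order is fixed: integrate the two replicates, normalize each
protein's profile to [0, 1] across all spots, remove sub-threshold signal
with a per-protein 90th-percentile outlier filter, then require binding on
at least ``min_run`` consecutive tiles (the consecutive-binding criterion,
which exploits the overlap between neighbouring tiling peptides: a genuine
linear-motif interaction shows up on adjacent spots, a spurious hit does
not). Proteins detected in both replicates that pass the consecutive
criterion form the core interactor set.

Each stage records its state on the profile (``normalized``,
``outlier_filtered``) and re-running a stage on its own output is a no-op.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from prisma_screen.matrix_design import (
    TilingPeptide,
    peptide_gravy,
    peptide_isoelectric_point,
)
from prisma_screen.screen_io import IntensityTable

ABSENT, SINGLE, DOUBLE = "absent", "single", "double"


@dataclass
class BindingProfile:
    """Per-protein intensity vector over all matrix spots.

    ``confidence`` labels each spot ``double`` (detected in both replicates),
    ``single`` (one replicate) or ``absent``. ``detected`` is False for
    all-zero profiles.
    """

    uniprot_id: str
    values: np.ndarray
    confidence: np.ndarray
    normalized: bool = False
    outlier_filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError(f"{self.uniprot_id}: negative intensities")
        if self.normalized and self.values.max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError(f"{self.uniprot_id}: normalized values must be <= 1")

    @property
    def detected(self) -> bool:
        return bool((self.values > 0).any())


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable filter parameters.

    ``outlier_quantile``: per-protein quantile below which signal is removed
    (nearest-rank over detected values). ``min_run``: minimum number of
    adjacent tiles with surviving signal for the consecutive criterion.
    """

    outlier_quantile: float = 0.90
    min_run: int = 2
    quantile_method: str = "nearest_rank"
    keep_rule: str = "geq_threshold"
    integration: str = "mean_of_detected"

    def __post_init__(self) -> None:
        if not (0.0 < self.outlier_quantile < 1.0):
            raise ValueError("outlier_quantile must be in (0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass
class InteractorSets:
    """Replicate, intersection and core interactor sets with provenance."""

    set1: frozenset[str]
    set2: frozenset[str]
    both: frozenset[str]
    core: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.core <= self.both <= self.set1 and self.both <= self.set2):
            raise ValueError("set nesting violated: core ⊆ both ⊆ set1, set2")

    @property
    def union(self) -> frozenset[str]:
        return self.set1 | self.set2


def integrate_replicates(
    rep1: IntensityTable, rep2: IntensityTable
) -> list[BindingProfile]:
    """Merge two replicate tables into per-protein raw profiles.

    Per (protein, spot): value = mean of the detected (nonzero) replicate
    values; confidence ``double`` if detected in both, ``single`` if in one,
    ``absent`` otherwise. Proteins present in either replicate appear in the
    output (sorted by id).
    """
    if list(rep1.values.columns) != list(rep2.values.columns):
        raise ValueError("replicates have mismatched spot sets")
    proteins = sorted(set(rep1.values.index) | set(rep2.values.index))
    spots = rep1.values.columns
    v1 = rep1.values.reindex(index=proteins, fill_value=0.0).to_numpy()
    v2 = rep2.values.reindex(index=proteins, fill_value=0.0).to_numpy()
    d1, d2 = v1 > 0, v2 > 0
    n_detected = d1.astype(int) + d2.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_detected > 0, (v1 + v2) / np.maximum(n_detected, 1), 0.0)
    conf = np.full(v1.shape, ABSENT, dtype=object)
    conf[n_detected == 1] = SINGLE
    conf[n_detected == 2] = DOUBLE
    return [
        BindingProfile(pid, mean[i], conf[i]) for i, pid in enumerate(proteins)
    ]


def normalize_profile(profile: BindingProfile) -> BindingProfile:
    """Scale a raw profile to [0, 1] by its maximum across all spots.

    All-zero profiles stay all-zero (``detected`` is False). No-op on an
    already-normalized profile.
    """
    if profile.normalized:
        return profile
    peak = profile.values.max(initial=0.0)
    values = profile.values / peak if peak > 0 else profile.values.copy()
    return replace(profile, values=values, normalized=True)


def _nearest_rank_threshold(detected: np.ndarray, q: float) -> float:
    """Nearest-rank q-quantile: the ⌈q·k⌉-th smallest of k detected values."""
    k = len(detected)
    rank = math.ceil(q * k)  # 1-based
    return float(np.sort(detected)[rank - 1])


def outlier_filter(profile: BindingProfile, cfg: PipelineConfig) -> BindingProfile:
    """Remove a protein's sub-threshold signal (promiscuous background binding).

    The threshold is the nearest-rank ``outlier_quantile`` of the protein's
    detected (nonzero) values; values below it are zeroed, values at or above
    it kept. All-zero profiles pass through. No-op on an already-filtered
    profile.
    """
    if not profile.normalized:
        raise ValueError("outlier_filter expects a normalized profile")
    if profile.outlier_filtered:
        return profile
    detected = profile.values[profile.values > 0]
    if len(detected) == 0:
        return replace(profile, outlier_filtered=True)
    threshold = _nearest_rank_threshold(detected, cfg.outlier_quantile)
    values = np.where(profile.values >= threshold, profile.values, 0.0)
    return replace(profile, values=values, outlier_filtered=True)


def consecutive_filter(
    profile: BindingProfile,
    design: Sequence[TilingPeptide],
    cfg: PipelineConfig,
) -> tuple[bool, list[tuple[int, int]]]:
    """Consecutive-binding criterion on the unmodified tile order.

    Spots collapse to their parent tile (a surviving PTM-variant signal marks
    its parent's ``tile_index``). The protein passes iff some run of at least
    ``min_run`` consecutive tile indices all carry surviving signal. Returns
    ``(passes, maximal_runs)`` with runs as inclusive ``(first, last)`` tile
    indices.
    """
    if len(design) != len(profile.values):
        raise ValueError(
            f"design has {len(design)} spots but profile {profile.uniprot_id!r} "
            f"has {len(profile.values)}"
        )
    marked: set[int] = {
        t.tile_index for t, v in zip(design, profile.values) if v > 0
    }
    runs: list[tuple[int, int]] = []
    for idx in sorted(marked):
        if runs and idx == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], idx)
        else:
            runs.append((idx, idx))
    passes = any(last - first + 1 >= cfg.min_run for first, last in runs)
    return passes, runs


def run_profile_pipeline(
    rep1: IntensityTable,
    rep2: IntensityTable,
    cfg: PipelineConfig | None = None,
) -> list[BindingProfile]:
    """Integrate, normalize and outlier-filter; returns filtered profiles."""
    cfg = cfg or PipelineConfig()
    return [
        outlier_filter(normalize_profile(p), cfg)
        for p in integrate_replicates(rep1, rep2)
    ]


def derive_interactor_sets(
    rep1: IntensityTable,
    rep2: IntensityTable,
    design: Sequence[TilingPeptide],
    cfg: PipelineConfig | None = None,
) -> InteractorSets:
    """Full set derivation: replicate sets, intersection and core.

    ``set1``/``set2`` are raw detection per replicate (>= 1 nonzero spot,
    after id merging); ``both`` their intersection; ``core`` the members of
    ``both`` whose integrated, normalized, outlier-filtered profile passes
    the consecutive-binding criterion.
    """
    cfg = cfg or PipelineConfig()
    set1 = frozenset(rep1.detected_proteins())
    set2 = frozenset(rep2.detected_proteins())
    both = set1 & set2
    core = set()
    for profile in run_profile_pipeline(rep1, rep2, cfg):
        if profile.uniprot_id in both:
            passes, _ = consecutive_filter(profile, design, cfg)
            if passes:
                core.add(profile.uniprot_id)
    provenance = {
        "outlier_quantile": cfg.outlier_quantile,
        "min_run": cfg.min_run,
        "quantile_method": cfg.quantile_method,
        "quantile_over": "detected_nonzero_values",
        "keep_rule": cfg.keep_rule,
        "integration": cfg.integration,
        "replicate_1": rep1.replicate_id,
        "replicate_2": rep2.replicate_id,
    }
    return InteractorSets(set1, set2, both, frozenset(core), provenance)


def bias_check(
    profiles: Sequence[BindingProfile],
    design: Sequence[TilingPeptide],
    pka_table: str = "EMBOSS",
) -> dict:
    """Physicochemical bias report for the screen.

    Spearman rank correlations (with two-sided p-values) between the per-spot
    accumulated intensity over unmodified spots and (a) peptide GRAVY and
    (b) peptide isoelectric point, plus the abundance span in orders of
    magnitude, log10(max/min) over positive accumulated values. A strong
    correlation would indicate that binding tracks peptide physicochemistry
    rather than sequence-specific recognition.
    """
    unmodified = [(i, t) for i, t in enumerate(design) if not t.is_modified]
    if len(unmodified) < 3:
        raise ValueError("bias_check needs at least 3 unmodified spots")
    idx = [i for i, _ in unmodified]
    accumulated = np.zeros(len(idx))
    for p in profiles:
        accumulated += np.asarray(p.values)[idx]
    gravy = np.array([peptide_gravy(t.sequence) for _, t in unmodified])
    pi = np.array(
        [peptide_isoelectric_point(t.sequence, pka_table) for _, t in unmodified]
    )

    def spearman(x: np.ndarray) -> dict:
        if np.allclose(x, x[0]) or np.allclose(accumulated, accumulated[0]):
            return {"rho": None, "p_value": None, "applicable": False}
        rho, p = stats.spearmanr(x, accumulated)
        return {"rho": float(rho), "p_value": float(p), "applicable": True}

    positive = accumulated[accumulated > 0]
    span = (
        float(np.log10(positive.max() / positive.min())) if len(positive) else None
    )
    return {
        "gravy": spearman(gravy),
        "isoelectric_point": spearman(pi),
        "pka_table": pka_table,
        "abundance_span_orders": span,
        "n_spots": len(idx),
    }
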