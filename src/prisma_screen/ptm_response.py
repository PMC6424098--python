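"""PTM-dependent binding: ratios against the unmodified spot, 4 categories.

For every (protein, peptide group) pair — a group being one unmodified spot
plus its PTM-variant spots at identical coordinates — the binding signal at
each variant is divided by the signal at the unmodified parent. With a fold
threshold δ (default 2), the detected ratios classify the pair into one of
four responses:

* ``repressed``   — every detected ratio ≤ 1/δ (any PTM weakens binding)
* ``independent`` — every detected ratio strictly inside (1/δ, δ)
* ``enhanced``    — every detected ratio ≥ δ (any PTM strengthens binding)
* ``regulated``   — anything else, i.e. PTM-specific: some variants beyond
  the band while others are not

Ratios are computed on integrated raw (replicate-averaged) intensities
before 0-1 normalization, since within-group normalization would distort
them. A variant detected where the parent is not gets a capped ratio
(flagged), keeping downstream clustering well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from prisma_screen.core_pipeline import BindingProfile
from prisma_screen.matrix_design import TilingPeptide

CATEGORIES = ("repressed", "independent", "regulated", "enhanced")
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class PTMConfig:
    """Fold threshold δ, cap for zero-parent ratios, minimum detected variants."""

    fold_threshold: float = 2.0
    cap_value: float = 64.0
    min_detected_variants: int = 1

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.cap_value <= self.fold_threshold:
            raise ValueError("cap_value must exceed fold_threshold")


@dataclass
class PTMComparison:
    """Ratios of one protein's variant signals to the unmodified parent signal."""

    uniprot_id: str
    parent_spot_id: str
    variant_spot_ids: list[str]
    ratios: np.ndarray  # NaN = variant not detected (both parent and variant 0)
    capped: np.ndarray  # True where parent 0 but variant > 0 (ratio capped)
    category: str = NOT_EVALUABLE

    @property
    def detected_ratios(self) -> np.ndarray:
        return self.ratios[~np.isnan(self.ratios)]


def peptide_groups(
    design: Sequence[TilingPeptide],
) -> list[tuple[TilingPeptide, list[TilingPeptide]]]:
    """(parent spot, variant spots) pairs for every parent with >= 1 variant."""
    parents = {t.spot_id: t for t in design if not t.is_modified}
    variants: dict[str, list[TilingPeptide]] = {}
    for t in design:
        if t.is_modified:
            variants.setdefault(t.parent_spot_id, []).append(t)
    return [
        (parents[pid], sorted(vs, key=lambda t: t.spot_id))
        for pid, vs in sorted(variants.items())
        if pid in parents
    ]


def ptm_ratio(
    profile: BindingProfile,
    parent: TilingPeptide,
    variants: Sequence[TilingPeptide],
    spot_index: dict[str, int],
    cfg: PTMConfig | None = None,
) -> PTMComparison:
    """Ratios of modified-spot to unmodified-spot signal for one group.

    ratio = I_variant / I_parent; if the parent is undetected but the variant
    is, the ratio is set to ``cap_value`` and flagged; if both are zero the
    variant is marked not-detected (NaN).
    """
    cfg = cfg or PTMConfig()
    for v in variants:
        if v.parent_spot_id != parent.spot_id:
            raise ValueError(
                f"spot {v.spot_id!r} does not belong to group {parent.spot_id!r}"
            )
    values = np.asarray(profile.values)
    i_parent = values[spot_index[parent.spot_id]]
    ratios = np.empty(len(variants))
    capped = np.zeros(len(variants), dtype=bool)
    for j, v in enumerate(variants):
        i_v = values[spot_index[v.spot_id]]
        if i_parent > 0:
            ratios[j] = i_v / i_parent
        elif i_v > 0:
            ratios[j] = cfg.cap_value
            capped[j] = True
        else:
            ratios[j] = np.nan
    return PTMComparison(
        uniprot_id=profile.uniprot_id,
        parent_spot_id=parent.spot_id,
        variant_spot_ids=[v.spot_id for v in variants],
        ratios=ratios,
        capped=capped,
    )


def classify_response(comparison: PTMComparison, cfg: PTMConfig | None = None) -> str:
    """Assign one of the four PTM-response categories (or not-evaluable)."""
    cfg = cfg or PTMConfig()
    detected = comparison.detected_ratios
    if len(detected) < cfg.min_detected_variants:
        return NOT_EVALUABLE
    delta = cfg.fold_threshold
    if (detected <= 1.0 / delta).all():
        return "repressed"
    if (detected >= delta).all():
        return "enhanced"
    if ((detected > 1.0 / delta) & (detected < delta)).all():
        return "independent"
    return "regulated"


def ptm_response_matrix(
    profiles: Sequence[BindingProfile],
    design: Sequence[TilingPeptide],
    cfg: PTMConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int], list[tuple[str, str]]]:
    """Classify every (protein, peptide group) pair.

    Returns the long-format comparison table (one row per variant), counts of
    evaluable pairs per category, and a deterministic clustered ordering of
    the evaluable (protein, group) ratio vectors (hierarchically clustered on
    log2 ratios, NaN treated as 0 = unchanged; ties broken by id).
    """
    cfg = cfg or PTMConfig()
    groups = peptide_groups(design)
    spot_index = {t.spot_id: i for i, t in enumerate(design)}
    rows = []
    counts = dict.fromkeys(CATEGORIES, 0)
    vectors: list[tuple[tuple[str, str], np.ndarray]] = []
    for profile in sorted(profiles, key=lambda p: p.uniprot_id):
        values = np.asarray(profile.values)
        for parent, variants in groups:
            group_idx = [spot_index[parent.spot_id]] + [
                spot_index[v.spot_id] for v in variants
            ]
            if not (values[group_idx] > 0).any():
                continue  # protein not detected on this group at all
            comp = ptm_ratio(profile, parent, variants, spot_index, cfg)
            comp.category = classify_response(comp, cfg)
            if comp.category in counts:
                counts[comp.category] += 1
                with np.errstate(divide="ignore"):
                    logr = np.log2(np.where(np.isnan(comp.ratios), 1.0, comp.ratios))
                logr[np.isneginf(logr)] = -np.log2(cfg.cap_value)
                vectors.append(((profile.uniprot_id, parent.spot_id), logr))
            for j, vid in enumerate(comp.variant_spot_ids):
                rows.append(
                    {
                        "uniprot_id": profile.uniprot_id,
                        "parent_spot_id": parent.spot_id,
                        "variant_spot_id": vid,
                        "ratio": comp.ratios[j],
                        "capped": bool(comp.capped[j]),
                        "category": comp.category,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "uniprot_id",
            "parent_spot_id",
            "variant_spot_id",
            "ratio",
            "capped",
            "category",
        ],
    )
    order = _cluster_order(vectors)
    return table, counts, order


def _cluster_order(
    vectors: list[tuple[tuple[str, str], np.ndarray]]
) -> list[tuple[str, str]]:
    if len(vectors) < 2:
        return [key for key, _ in vectors]
    # fixed-length embedding: groups differ in variant count, so cluster on
    # summary features of each ratio vector rather than ragged vectors
    feats = np.array(
        [
            [v.min(initial=0.0), v.max(initial=0.0), v.mean() if len(v) else 0.0]
            for _, v in vectors
        ]
    )
    z = linkage(feats, method="average", metric="euclidean")
    return [vectors[i][0] for i in leaves_list(z)]
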