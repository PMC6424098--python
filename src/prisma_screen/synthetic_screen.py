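"""Synthetic screens with planted ground truth for end-to-end validation.

The generator emulates the structure of a tiled peptide-matrix interaction
screen read out by label-free MS:

* **True binders** recognize a short linear motif. A motif fully contained in
  several consecutive tiles gives a plateau of maximal signal on those tiles
  (>= 2 tiles at the peptide offset used here) with attenuated signal on the
  flanking tiles where the motif is truncated (factors 0.5 and 0.2).
* **Background binders** stick to one isolated spot at low intensity.
* Peak intensities are log-normal over several orders of magnitude, echoing
  the wide abundance range of nuclear-extract proteins.
* Each replicate observes truth x multiplicative log-normal noise
  (``noise_cv``), with per-spot **dropout** (a detected signal missed in one
  replicate), the dominant source of replicate disagreement in sparse MS data.
* PTM-variant spots carry the parent-tile signal times a planted per-category
  multiplier: repressed x0.1 on all variants, independent x1, enhanced x8 on
  all variants, regulated x8 on one variant and x1 on the rest.

``generate_screen`` returns the two replicate tables plus a truth report;
``score_recovery`` compares pipeline output against the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from prisma_screen.matrix_design import TilingPeptide, default_design
from prisma_screen.screen_io import IntensityTable, ReferenceSet

#: flank attenuation beyond the plateau: +-1 tile, +-2 tiles
FLANK_FACTORS = (0.5, 0.2)

#: planted per-category multipliers applied to PTM-variant spots
CATEGORY_MULTIPLIERS = {
    "repressed": 0.1,
    "independent": 1.0,
    "enhanced": 8.0,
    "regulated": (8.0, 1.0),  # one variant off-band, the rest unchanged
}


@dataclass(frozen=True)
class TruthSpec:
    """Generator conditions: what is planted and how it is observed."""

    n_true_binders: int = 500
    n_background_binders: int = 1500
    plateau_min: int = 2  # tiles at full motif signal (>= consecutive min_run)
    plateau_max: int = 4
    dropout: float = 0.1  # per replicate, per detected spot
    noise_cv: float = 0.3  # multiplicative log-normal coefficient of variation
    log10_peak_mean: float = 7.0
    log10_peak_sd: float = 1.0  # ~6 orders of magnitude across binders
    log10_background_mean: float = 4.0
    log10_background_sd: float = 0.5
    ptm_effects: Mapping[str, float] | None = None  # category -> fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.plateau_min < 2 or self.plateau_max < self.plateau_min:
            raise ValueError("need plateau_max >= plateau_min >= 2")
        if self.ptm_effects is not None:
            total = sum(self.ptm_effects.values())
            if total > 1.0 + 1e-9 or any(v < 0 for v in self.ptm_effects.values()):
                raise ValueError("ptm_effects fractions must be >= 0 and sum <= 1")


#: balanced PTM plant used when a spec asks for PTM effects without fractions
BALANCED_PTM_EFFECTS = {
    "repressed": 0.25,
    "independent": 0.25,
    "regulated": 0.25,
    "enhanced": 0.25,
}


@dataclass
class TruthReport:
    """Planted labels: per-protein binder table and per-group PTM categories."""

    binders: pd.DataFrame  # uniprot_id, kind, plateau_start, plateau_end, peak
    ptm: pd.DataFrame  # uniprot_id, parent_spot_id, category

    def true_binder_ids(self) -> frozenset[str]:
        mask = self.binders["kind"] == "true"
        return frozenset(self.binders.loc[mask, "uniprot_id"])


def generate_screen(
    spec: TruthSpec, design: Sequence[TilingPeptide] | None = None
) -> tuple[IntensityTable, IntensityTable, TruthReport]:
    """Generate two replicate intensity tables plus the truth report."""
    if design is None:
        _, design = default_design()
    rng = np.random.default_rng(spec.seed)
    spot_ids = [t.spot_id for t in design]
    spot_index = {s: i for i, s in enumerate(spot_ids)}
    unmod = [t for t in design if not t.is_modified]
    n_tiles = len(unmod)
    tile_spot = {t.tile_index: t.spot_id for t in unmod}
    variants_by_parent: dict[str, list[TilingPeptide]] = {}
    for t in design:
        if t.is_modified:
            variants_by_parent.setdefault(t.parent_spot_id, []).append(t)
    for vs in variants_by_parent.values():
        vs.sort(key=lambda t: t.spot_id)

    if spec.plateau_max + 2 * len(FLANK_FACTORS) > n_tiles:
        raise ValueError("footprint span exceeds the number of tiles")

    ids = [f"TP{i:05d}" for i in range(spec.n_true_binders)] + [
        f"BG{i:05d}" for i in range(spec.n_background_binders)
    ]
    kinds = ["true"] * spec.n_true_binders + ["background"] * spec.n_background_binders
    values = np.zeros((len(ids), len(spot_ids)))
    binder_rows = []
    ptm_rows = []

    for row, (pid, kind) in enumerate(zip(ids, kinds)):
        if kind == "true":
            peak = 10.0 ** rng.normal(spec.log10_peak_mean, spec.log10_peak_sd)
            plateau_len = int(rng.integers(spec.plateau_min, spec.plateau_max + 1))
            start = int(rng.integers(0, n_tiles - plateau_len + 1))
            tile_factor: dict[int, float] = {
                start + j: 1.0 for j in range(plateau_len)
            }
            for dist, factor in enumerate(FLANK_FACTORS, start=1):
                for tile in (start - dist, start + plateau_len - 1 + dist):
                    if 0 <= tile < n_tiles:
                        tile_factor[tile] = factor
            for tile, factor in tile_factor.items():
                values[row, spot_index[tile_spot[tile]]] = peak * factor
            binder_rows.append(
                {
                    "uniprot_id": pid,
                    "kind": kind,
                    "plateau_start": start,
                    "plateau_end": start + plateau_len - 1,
                    "peak_intensity": peak,
                }
            )
            # PTM-variant spots: parent-tile signal times a planted multiplier
            for parent_id, vs in variants_by_parent.items():
                parent_value = values[row, spot_index[parent_id]]
                if parent_value <= 0:
                    continue
                category = _draw_category(spec, rng, n_variants=len(vs))
                mults = _category_multipliers(category, len(vs), rng)
                for v, m in zip(vs, mults):
                    values[row, spot_index[v.spot_id]] = parent_value * m
                if category is not None:
                    ptm_rows.append(
                        {
                            "uniprot_id": pid,
                            "parent_spot_id": parent_id,
                            "category": category,
                        }
                    )
        else:
            level = 10.0 ** rng.normal(
                spec.log10_background_mean, spec.log10_background_sd
            )
            tile = int(rng.integers(0, n_tiles))
            values[row, spot_index[tile_spot[tile]]] = level
            binder_rows.append(
                {
                    "uniprot_id": pid,
                    "kind": kind,
                    "plateau_start": tile,
                    "plateau_end": tile,
                    "peak_intensity": level,
                }
            )

    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))

    def observe() -> np.ndarray:
        obs = values.copy()
        if sigma > 0:
            obs *= np.exp(rng.normal(0.0, sigma, size=obs.shape))
        if spec.dropout > 0:
            obs[(obs > 0) & (rng.random(obs.shape) < spec.dropout)] = 0.0
        return obs

    def table(obs: np.ndarray, name: str) -> IntensityTable:
        frame = pd.DataFrame(obs, index=pd.Index(ids, name="uniprot_id"),
                             columns=spot_ids)
        genes = pd.Series(ids, index=frame.index, name="gene_name")
        return IntensityTable(name, frame, genes)

    rep1 = table(observe(), "rep1")
    rep2 = table(observe(), "rep2")
    truth = TruthReport(
        binders=pd.DataFrame(binder_rows),
        ptm=pd.DataFrame(ptm_rows, columns=["uniprot_id", "parent_spot_id", "category"]),
    )
    return rep1, rep2, truth


def _draw_category(
    spec: TruthSpec, rng: np.random.Generator, n_variants: int
) -> str | None:
    if spec.ptm_effects is None:
        return None
    cats = sorted(spec.ptm_effects)
    probs = np.array([spec.ptm_effects[c] for c in cats] + [0.0])
    probs[-1] = max(1.0 - probs.sum(), 0.0)
    choices = cats + [None]
    category = choices[int(rng.choice(len(choices), p=probs / probs.sum()))]
    if category == "regulated" and n_variants < 2:
        return "independent"  # regulated needs >= 2 variants to be expressible
    return category


def _category_multipliers(
    category: str | None, n_variants: int, rng: np.random.Generator
) -> list[float]:
    if category is None or category == "independent":
        return [1.0] * n_variants
    if category == "regulated":
        off_band, in_band = CATEGORY_MULTIPLIERS["regulated"]
        which = int(rng.integers(0, n_variants))
        return [off_band if j == which else in_band for j in range(n_variants)]
    return [CATEGORY_MULTIPLIERS[category]] * n_variants


def truth_reference_sets(truth: TruthReport) -> ReferenceSet:
    """Planted true binders as a reference set."""
    return ReferenceSet("planted_true", frozenset(truth.true_binder_ids()))


def score_recovery(
    sets,
    truth: TruthReport,
    ptm_table: pd.DataFrame | None = None,
) -> dict:
    """Precision/recall of the core set and (optionally) the PTM confusion.

    Core precision counts any planted true binder as a true positive; recall
    is measured against the planted binders detected in both replicates (a
    binder dropped out of one replicate is unrecoverable by design). With a
    classification table, the per-(protein, group) confusion matrix of
    planted vs assigned categories is added.
    """
    true_ids = truth.true_binder_ids()
    known = set(truth.binders["uniprot_id"])
    if not (set(sets.core) <= known):
        raise ValueError("core set contains ids unknown to the truth report")
    eligible = true_ids & sets.both
    tp = len(sets.core & true_ids)
    out: dict = {
        "core_size": len(sets.core),
        "n_true_planted": len(true_ids),
        "n_true_in_both": len(eligible),
        "core_precision": tp / len(sets.core) if sets.core else None,
        "core_recall": len(sets.core & eligible) / len(eligible) if eligible else None,
    }
    if ptm_table is not None and len(truth.ptm):
        predicted = (
            ptm_table[["uniprot_id", "parent_spot_id", "category"]]
            .drop_duplicates()
            .rename(columns={"category": "predicted"})
        )
        merged = truth.ptm.merge(predicted, on=["uniprot_id", "parent_spot_id"])
        confusion = (
            merged.groupby(["category", "predicted"]).size().unstack(fill_value=0)
        )
        evaluable = merged[merged["predicted"] != "not_evaluable"]
        correct = (evaluable["category"] == evaluable["predicted"]).sum()
        out["ptm_confusion"] = confusion
        out["ptm_pairs_evaluable"] = int(len(evaluable))
        out["ptm_recovery"] = (
            float(correct / len(evaluable)) if len(evaluable) else None
        )
    return out


def simulate_replicate_overlap(
    planted_fdr: float,
    n_true: int = 1000,
    sensitivity: float = 0.8,
    n_background: int = 5000,
    r_size: int = 200,
    seed: int = 0,
) -> tuple[ReferenceSet, ReferenceSet, ReferenceSet, float]:
    """Simulate two interaction screens with planted false positives.

    Each screen detects every true interactor with probability ``sensitivity``
    and adds false positives drawn independently from a disjoint background
    pool (false positives do not replicate); the number of false positives is
    chosen so the expected FDR per screen equals ``planted_fdr``. The
    reference R is a random sample of the true interactors. Returns
    (A, B, R, realized FDR of A).
    """
    if not (0.0 <= planted_fdr < 1.0):
        raise ValueError("planted_fdr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true_ids = np.array([f"T{i:05d}" for i in range(n_true)])
    bg_ids = np.array([f"F{i:05d}" for i in range(n_background)])
    n_false = int(round(planted_fdr / (1.0 - planted_fdr) * n_true * sensitivity))

    def screen(name: str) -> tuple[ReferenceSet, int]:
        hits = true_ids[rng.random(n_true) < sensitivity]
        false = rng.choice(bg_ids, size=n_false, replace=False)
        members = frozenset(hits) | frozenset(false)
        return ReferenceSet(name, members), len(false)

    a, n_false_a = screen("screen_A")
    b, _ = screen("screen_B")
    r = ReferenceSet(
        "reference", frozenset(rng.choice(true_ids, size=r_size, replace=False))
    )
    realized_fdr = n_false_a / len(a.members)
    return a, b, r, realized_fdr
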