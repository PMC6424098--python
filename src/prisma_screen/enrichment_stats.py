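"""Overlap statistics, intersection-based interaction FDR, enrichment, ranking.

Four statistical pieces sit here:

* directional overlap reports between interactor sets;
* a capture-recapture FDR estimator for interaction screens, built on the
  assumption that true interactions replicate between independent datasets
  while false positives do not: with screens A and B and a high-precision
  reference R, the sensitivity of B is s_B = |B∩R| / |R|, the true positives
  in A are approximately |A∩B| / s_B, and FDR_A = 1 − |A∩B|·|R| / (|A|·|B∩R|);
* exact upper-tail hypergeometric enrichment with Benjamini-Hochberg step-up
  control (integer arithmetic, no floating-point tail summation);
* complex ranking against a CORUM-style catalog: complexes are kept if they
  share ≥ ``min_prisma`` members with the screen set and ≥ ``min_combined``
  with the union of screen and IP sets, then ranked by the mean of their rank
  by screen coverage (descending) and their rank by Fisher-combined
  hypergeometric p-value (ascending).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from prisma_screen.screen_io import ComplexCatalog, ReferenceSet


@dataclass(frozen=True)
class OverlapReport:
    query_name: str
    reference_name: str
    query_size: int
    reference_size: int
    intersection: int
    coverage_of_reference: float  # percent
    coverage_of_query: float  # percent


@dataclass(frozen=True)
class FDREstimate:
    dataset_name: str
    fdr: float | None  # fraction in [0, 1]; None when not evaluable
    size_a: int
    intersection_ab: int
    size_r: int
    intersection_br: int
    estimator: str = "capture_recapture"

    @property
    def evaluable(self) -> bool:
        return self.fdr is not None


def overlap_stats(query: ReferenceSet, reference: ReferenceSet) -> OverlapReport:
    """Exact intersection with both directional coverages (percent)."""
    if not reference.members:
        raise ValueError("empty reference set")
    inter = len(query.members & reference.members)
    return OverlapReport(
        query_name=query.name,
        reference_name=reference.name,
        query_size=len(query.members),
        reference_size=len(reference.members),
        intersection=inter,
        coverage_of_reference=100.0 * inter / len(reference.members),
        coverage_of_query=100.0 * inter / len(query.members) if query.members else 0.0,
    )


def estimate_interaction_fdr(
    a: ReferenceSet, b: ReferenceSet, r: ReferenceSet
) -> FDREstimate:
    """Capture-recapture FDR of screen A given co-screen B and reference R.

    FDR_A = 1 − |A∩B|·|R| / (|A|·|B∩R|), clipped to [0, 1]. Undefined
    (not evaluable) when B and R do not overlap.
    """
    ab = len(a.members & b.members)
    br = len(b.members & r.members)
    if br == 0 or not a.members:
        return FDREstimate(a.name, None, len(a.members), ab, len(r.members), br)
    fdr = 1.0 - ab * len(r.members) / (len(a.members) * br)
    return FDREstimate(
        a.name, float(min(1.0, max(0.0, fdr))), len(a.members), ab, len(r.members), br
    )


def hypergeometric_test(k: int, n: int, big_k: int, big_n: int) -> float:
    """Exact upper-tail hypergeometric p-value P(X >= k).

    Drawing ``n`` items from a background of ``big_n`` containing ``big_k``
    category members, the probability of observing at least ``k`` category
    members. Computed with exact integer binomials.
    """
    if not (0 <= k <= min(n, big_k) and big_k <= big_n and n <= big_n):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={big_k}, N={big_n}"
        )
    if k == 0:
        return 1.0
    denom = math.comb(big_n, n)
    numer = sum(
        math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
        for i in range(k, min(n, big_k) + 1)
    )
    return numer / denom


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_(i) is multiplied by m/i in the sorted order, then a running minimum
    from the largest p downward enforces monotonicity; results capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted.tolist()


def annotation_enrichment(
    query: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a query set, BH-controlled.

    ``annotations`` maps term -> member ids; terms with no background members
    are skipped (warned). Output sorted by adjusted p then descending count.
    """
    import logging

    logger = logging.getLogger(__name__)
    bg = set(background)
    q = set(query) & bg
    if set(query) - bg:
        raise ValueError("query must be a subset of the background")
    rows = []
    for term in sorted(annotations):
        members = set(annotations[term]) & bg
        if not members:
            logger.warning("term %r has no background members, skipped", term)
            continue
        k = len(q & members)
        rows.append(
            {
                "term": term,
                "count": k,
                "term_size": len(members),
                "p_value": hypergeometric_test(k, len(q), len(members), len(bg)),
            }
        )
    frame = pd.DataFrame(rows, columns=["term", "count", "term_size", "p_value"])
    if len(frame):
        frame["adjusted_p"] = bh_adjust(frame["p_value"].tolist())
        frame["significant"] = frame["adjusted_p"] <= alpha
        frame = frame.sort_values(
            ["adjusted_p", "count"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    else:
        frame["adjusted_p"] = []
        frame["significant"] = []
    return frame


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's method for two p-values: chi-square with 4 df on −2Σln p."""
    p1 = max(p1, 1e-300)
    p2 = max(p2, 1e-300)
    statistic = -2.0 * (math.log(p1) + math.log(p2))
    return float(stats.chi2.sf(statistic, df=4))


def rank_complexes(
    prisma_set: ReferenceSet,
    ip_set: ReferenceSet,
    catalog: ComplexCatalog,
    min_prisma: int = 1,
    min_combined: int = 3,
    combined_mode: str = "union",
) -> pd.DataFrame:
    """Rank catalog complexes by screen coverage and deviation from randomness.

    Screen (PRISMA) and IP sets are intersected with the catalog background
    before testing. A complex is retained when it shares >= ``min_prisma``
    members with the screen set and — under the default ``union`` mode — has
    >= ``min_combined`` members in the union of screen and IP sets (``each``
    mode requires the threshold per set). Per retained complex, coverage by
    the screen set (percent) and hypergeometric p-values against the catalog
    background for both sets are computed; the final rank is the mean of the
    rank by descending coverage and the rank by ascending Fisher-combined
    p-value, ties broken by descending complex size then complex id. The
    upper quartile is ranks 1..floor(n/4).
    """
    if len(catalog) == 0:
        raise ValueError("empty complex catalog")
    if combined_mode not in ("union", "each"):
        raise ValueError(f"unknown combined_mode {combined_mode!r}")
    background = catalog.background
    prisma = prisma_set.members & background
    ip = ip_set.members & background
    n_bg = len(background)
    rows = []
    for cid, name, members in catalog.complexes:
        ov_prisma = len(members & prisma)
        ov_ip = len(members & ip)
        ov_union = len(members & (prisma | ip))
        combined_ok = (
            ov_union >= min_combined
            if combined_mode == "union"
            else ov_prisma >= min_combined and ov_ip >= min_combined
        )
        retained = ov_prisma >= min_prisma and combined_ok
        p_prisma = hypergeometric_test(ov_prisma, len(prisma), len(members), n_bg)
        p_ip = hypergeometric_test(ov_ip, len(ip), len(members), n_bg)
        rows.append(
            {
                "complex_id": cid,
                "complex_name": name,
                "size": len(members),
                "overlap_prisma": ov_prisma,
                "overlap_ip": ov_ip,
                "overlap_combined": ov_union,
                "coverage_prisma": 100.0 * ov_prisma / len(members),
                "p_prisma": p_prisma,
                "p_ip": p_ip,
                "combined_p": fisher_combine(p_prisma, p_ip),
                "retained": retained,
            }
        )
    frame = pd.DataFrame(rows)
    retained = frame[frame["retained"]].copy()
    if len(retained):
        retained["rank_coverage"] = (
            retained["coverage_prisma"].rank(ascending=False, method="average")
        )
        retained["rank_p"] = retained["combined_p"].rank(ascending=True, method="average")
        retained["mean_rank"] = 0.5 * (retained["rank_coverage"] + retained["rank_p"])
        retained = retained.sort_values(
            ["mean_rank", "size", "complex_id"],
            ascending=[True, False, True],
            kind="stable",
        )
        retained["rank"] = np.arange(1, len(retained) + 1)
        n_quartile = len(retained) // 4
        retained["upper_quartile"] = retained["rank"] <= n_quartile
        frame = frame.merge(
            retained[
                ["complex_id", "rank_coverage", "rank_p", "mean_rank", "rank",
                 "upper_quartile"]
            ],
            on="complex_id",
            how="left",
        )
    else:
        for col in ("rank_coverage", "rank_p", "mean_rank", "rank"):
            frame[col] = np.nan
        frame["upper_quartile"] = False
    frame = frame.sort_values(
        ["retained", "rank"], ascending=[False, True], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return frame
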