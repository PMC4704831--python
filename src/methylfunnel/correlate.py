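"""Rank funnel survivors by correlation with cognitive scores.

For each candidate locus the module computes Spearman's rho between its beta
values and MMSE, and separately FAB, over the scored patients (aMCI + AD; NC
subjects carry no scores by design).  Missing scores are dropped pairwise,
which is why the FAB n can be smaller than the MMSE n.  The top candidate is
the locus significant on both scores whose weaker correlation is strongest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleRecord
from .stats import spearman

logger = logging.getLogger(__name__)


@dataclass
class LocusCorrelation:
    locus_id: str
    rho_mmse: float
    p_mmse: float
    n_mmse: int
    rho_fab: float
    p_fab: float
    n_fab: int


@dataclass
class CandidateRanking:
    """Per-locus score correlations plus the selected top candidate."""

    rows: list[LocusCorrelation]
    selected: str | None = None
    rationale: str = ""

    def __post_init__(self) -> None:
        for r in self.rows:
            for rho in (r.rho_mmse, r.rho_fab):
                if not (math.isnan(rho) or -1.0 <= rho <= 1.0):
                    raise ValueError(f"rho {rho} outside [-1, 1] at {r.locus_id}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        return df.set_index("locus_id").sort_index()


def _scored_patients(cohort: list[SampleRecord], sample_ids: list[str],
                     score: str) -> tuple[list[int], np.ndarray]:
    """Column indices and score values of aMCI/AD subjects carrying a score."""
    by_id = {r.sample_id: r for r in cohort}
    idx, values = [], []
    for j, sid in enumerate(sample_ids):
        rec = by_id.get(sid)
        if rec is None or rec.group == "NC":
            continue
        val = getattr(rec, score)
        if val is not None:
            idx.append(j)
            values.append(float(val))
    return idx, np.asarray(values, dtype=float)


def score_correlations(beta: BetaMatrix, cohort: list[SampleRecord],
                       loci: set[str] | list[str],
                       exact: bool = False) -> CandidateRanking:
    """Spearman correlations of candidate betas with MMSE and FAB.

    ``exact`` requests the exact permutation p-value (only valid for n <= 9,
    the regime of the small discovery groups).  Loci with constant betas over
    the scored subjects — zero rank variance — are flagged with NaN entries
    rather than fabricated values.
    """
    loci = sorted(loci)
    if not loci:
        raise ValueError("no candidate loci to correlate")
    idx_m, mmse = _scored_patients(cohort, beta.sample_ids, "mmse")
    idx_f, fab = _scored_patients(cohort, beta.sample_ids, "fab")
    rows: list[LocusCorrelation] = []
    for locus in loci:
        values = beta.row(locus)
        out: dict[str, float | int] = {}
        for tag, idx, scores in (("mmse", idx_m, mmse), ("fab", idx_f, fab)):
            b = values[idx]
            ok = np.isfinite(b)
            b, s = b[ok], scores[ok]
            n = len(b)
            if n < 3:
                logger.warning("locus %s: only %d complete %s pairs; flagged",
                               locus, n, tag.upper())
                out[f"rho_{tag}"], out[f"p_{tag}"], out[f"n_{tag}"] = (
                    math.nan, math.nan, n)
                continue
            try:
                res = spearman(b, s, exact=exact and n <= 9)
            except ValueError:
                logger.warning("locus %s: zero rank variance vs %s; flagged",
                               locus, tag.upper())
                out[f"rho_{tag}"], out[f"p_{tag}"], out[f"n_{tag}"] = (
                    math.nan, math.nan, n)
                continue
            out[f"rho_{tag}"], out[f"p_{tag}"], out[f"n_{tag}"] = (
                res.statistic, res.p_value, n)
        rows.append(LocusCorrelation(locus_id=locus, **out))  # type: ignore[arg-type]
    return CandidateRanking(rows=rows)


def select_top(ranking: CandidateRanking, alpha: float = 0.05) -> str:
    """Pick the top candidate: strongest weaker correlation among loci
    significant on both scores.

    Among loci with p_mmse < alpha and p_fab < alpha, maximises
    ``min(|rho_mmse|, |rho_fab|)``; ties broken by smaller
    ``max(p_mmse, p_fab)``, then lexicographic locus id.  If no locus passes
    both score thresholds, falls back to the MMSE-only criterion with a
    warning.  The selection and its rationale are recorded on ``ranking``.
    """
    if not ranking.rows:
        raise ValueError("empty ranking")

    def both_ok(r: LocusCorrelation) -> bool:
        return (not math.isnan(r.p_mmse) and r.p_mmse < alpha
                and not math.isnan(r.p_fab) and r.p_fab < alpha)

    eligible = [r for r in ranking.rows if both_ok(r)]
    if eligible:
        key = lambda r: (-min(abs(r.rho_mmse), abs(r.rho_fab)),
                         max(r.p_mmse, r.p_fab), r.locus_id)
        best = min(eligible, key=key)
        ranking.selected = best.locus_id
        ranking.rationale = (
            f"significant on both scores at alpha={alpha}; strongest weaker "
            f"correlation min(|rho|)={min(abs(best.rho_mmse), abs(best.rho_fab)):.3f}"
        )
        return best.locus_id

    mmse_only = [r for r in ranking.rows
                 if not math.isnan(r.p_mmse) and r.p_mmse < alpha]
    if not mmse_only:
        raise ValueError(f"no locus significant at alpha={alpha} on MMSE")
    logger.warning("no locus significant on both scores; falling back to MMSE only")
    best = min(mmse_only, key=lambda r: (-abs(r.rho_mmse), r.p_mmse, r.locus_id))
    ranking.selected = best.locus_id
    ranking.rationale = (
        f"fallback: no locus significant on both scores at alpha={alpha}; "
        f"strongest |rho_mmse|={abs(best.rho_mmse):.3f}"
    )
    return best.locus_id
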