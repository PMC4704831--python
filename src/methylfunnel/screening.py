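"""The genome-wide candidate funnel.

Stages, applied in order to the CpG loci of the array:

1. per-locus unpaired t-tests for each of the three group pairs
   (NC-aMCI, NC-AD, aMCI-AD); a locus is significant for a pair at p < alpha,
   and the stage-1 set is the triple intersection;
2. monotone-progression filter: group means strictly ordered along disease
   progression NC -> aMCI -> AD, in either direction;
3. annotation filters: (a) at least one transcript accession, (b) at least
   one promoter-proximal RefGene group (TSS1500/TSS200/5'UTR/1stExon, on
   any-transcript semantics), (c) located in a CpG island.

The pairwise tests run vectorised across loci; tests assert equivalence with
per-locus calls to :func:`methylfunnel.stats.t_test_unpaired`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _dist
from scipy.stats import false_discovery_control

from .io import (
    GROUPS,
    BetaMatrix,
    LocusAnnotation,
    SampleRecord,
    manifest_index,
)

logger = logging.getLogger(__name__)

PAIRS: tuple[tuple[str, str], ...] = (("NC", "aMCI"), ("NC", "AD"), ("aMCI", "AD"))


@dataclass
class PairwiseScreen:
    """Per-pair significance sets plus the per-locus p-values behind them."""

    alpha: float
    sets: dict[tuple[str, str], set[str]]
    p_values: dict[tuple[str, str], dict[str, float]]
    skipped: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def venn_counts(self) -> dict[str, int]:
        """Sizes of the 7 exclusive regions of the three-set Venn diagram."""
        a, b, c = (self.sets[p] for p in PAIRS)
        regions = {
            "NC-aMCI only": a - b - c,
            "NC-AD only": b - a - c,
            "aMCI-AD only": c - a - b,
            "NC-aMCI & NC-AD": (a & b) - c,
            "NC-aMCI & aMCI-AD": (a & c) - b,
            "NC-AD & aMCI-AD": (b & c) - a,
            "all three": a & b & c,
        }
        return {k: len(v) for k, v in regions.items()}


@dataclass
class FunnelResult:
    """Nested stage sets of the candidate funnel with per-stage counts."""

    alpha: float
    n_total: int
    cpg_set: set[str]
    screen: PairwiseScreen
    stage1_common: set[str]
    stage2_monotone: set[str]
    directions: dict[str, str]  # stage2 locus -> 'decreasing' | 'increasing'
    stage3_accession: set[str]
    stage4_promoter: set[str]
    stage5_island: set[str]

    def __post_init__(self) -> None:
        chain = [self.stage5_island, self.stage4_promoter, self.stage3_accession,
                 self.stage2_monotone, self.stage1_common, self.cpg_set]
        for inner, outer in zip(chain, chain[1:]):
            if not inner <= outer:
                raise ValueError("funnel stages are not nested")
        if len(self.cpg_set) > self.n_total:
            raise ValueError("more CpG loci than total loci")

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "total": self.n_total,
            "cpg": len(self.cpg_set),
            "stage1_common": len(self.stage1_common),
            "stage2_monotone": len(self.stage2_monotone),
            "stage3_accession": len(self.stage3_accession),
            "stage4_promoter": len(self.stage4_promoter),
            "stage5_island": len(self.stage5_island),
        }

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "stage_counts": self.stage_counts,
            "venn_counts": self.screen.venn_counts,
            "stage1_common": sorted(self.stage1_common),
            "stage2_monotone": sorted(self.stage2_monotone),
            "directions": {k: self.directions[k] for k in sorted(self.directions)},
            "stage3_accession": sorted(self.stage3_accession),
            "stage4_promoter": sorted(self.stage4_promoter),
            "stage5_island": sorted(self.stage5_island),
        }


def _group_columns(beta: BetaMatrix, cohort: list[SampleRecord]) -> dict[str, np.ndarray]:
    by_id = {r.sample_id: r for r in cohort}
    missing = [s for s in beta.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples in beta matrix but not in cohort: {missing[:5]}")
    cols: dict[str, list[int]] = {g: [] for g in GROUPS}
    for j, s in enumerate(beta.sample_ids):
        cols[by_id[s].group].append(j)
    return {g: np.asarray(idx, dtype=int) for g, idx in cols.items()}


def _pooled_t_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Student t-test: x, y are (n_loci, n_x) and (n_loci, n_y)."""
    nx, ny = x.shape[1], y.shape[1]
    df = nx + ny - 2
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    p = np.where(np.isfinite(t), 2.0 * _dist.t.sf(np.abs(t), df), 0.0)
    return t, np.minimum(p, 1.0)


def pairwise_screen(beta: BetaMatrix, cohort: list[SampleRecord],
                    alpha: float = 0.05, fdr: bool = False) -> PairwiseScreen:
    """Unpaired t-tests per locus for each group pair.

    A locus enters a pair's significance set iff its two-sided p < alpha
    (or its Benjamini-Hochberg adjusted p < alpha with ``fdr``).  Loci with
    any missing value in a pair's groups are skipped for that pair and
    logged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    cols = _group_columns(beta, cohort)
    for g, idx in cols.items():
        if len(idx) < 2:
            raise ValueError(f"group {g} has {len(idx)} samples; need >= 2")
    loci = np.asarray(beta.locus_ids)
    sets: dict[tuple[str, str], set[str]] = {}
    p_values: dict[tuple[str, str], dict[str, float]] = {}
    skipped: dict[tuple[str, str], set[str]] = {}
    for pair in PAIRS:
        x = beta.values[:, cols[pair[0]]]
        y = beta.values[:, cols[pair[1]]]
        complete = np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1)
        skip = set(loci[~complete])
        if skip:
            logger.info("pair %s: skipped %d loci with missing values", pair, len(skip))
        t, p = _pooled_t_rows(x[complete], y[complete])
        pc = p.copy()
        if fdr and len(pc):
            pc = false_discovery_control(pc, method="bh")
        sig = loci[complete][pc < alpha]
        sets[pair] = set(sig)
        p_values[pair] = dict(zip(loci[complete], p))
        skipped[pair] = skip
    return PairwiseScreen(alpha=alpha, sets=sets, p_values=p_values, skipped=skipped)


def intersect_common(screen: PairwiseScreen) -> set[str]:
    """Loci significant in all three pairwise comparisons."""
    a, b, c = (screen.sets[p] for p in PAIRS)
    return a & b & c


def monotone_filter(beta: BetaMatrix, cohort: list[SampleRecord],
                    loci: set[str]) -> dict[str, str]:
    """Keep loci whose group means are strictly monotone along NC -> aMCI -> AD.

    Returns the surviving loci mapped to their direction.  Exact ties in
    group means fail strict monotonicity.
    """
    cols = _group_columns(beta, cohort)
    out: dict[str, str] = {}
    for locus in loci:
        row = beta.row(locus)
        means = []
        for g in GROUPS:
            vals = row[cols[g]]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                means = None
                break
            means.append(float(vals.mean()))
        if means is None:
            continue
        nc, amci, ad = means
        if nc > amci > ad:
            out[locus] = "decreasing"
        elif nc < amci < ad:
            out[locus] = "increasing"
    return out


def annotation_filters(loci: set[str],
                       manifest: list[LocusAnnotation] | dict[str, LocusAnnotation],
                       ) -> tuple[set[str], set[str], set[str]]:
    """Apply the three nested annotation filters.

    stage3: >= 1 transcript accession; stage4: additionally >= 1 RefGene group
    in {TSS1500, TSS200, 5'UTR, 1stExon} on any transcript; stage5:
    additionally located in a CpG island.
    """
    index = manifest if isinstance(manifest, dict) else manifest_index(manifest)
    missing = [l for l in loci if l not in index]
    if missing:
        raise KeyError(f"locus {missing[0]!r} not present in the manifest")
    stage3 = {l for l in loci if index[l].has_accession}
    stage4 = {l for l in stage3 if index[l].in_promoter}
    stage5 = {l for l in stage4 if index[l].in_island}
    return stage3, stage4, stage5


def run_funnel(beta: BetaMatrix, cohort: list[SampleRecord],
               manifest: list[LocusAnnotation], alpha: float = 0.05,
               fdr: bool = False) -> FunnelResult:
    """Run the complete candidate funnel on CpG loci of the beta matrix."""
    index = manifest_index(manifest)
    missing = [l for l in beta.locus_ids if l not in index]
    if missing:
        raise KeyError(f"locus {missing[0]!r} not present in the manifest")
    cpg_ids = [l for l in beta.locus_ids if index[l].is_cpg]
    cpg_beta = beta.subset_loci(cpg_ids)
    screen = pairwise_screen(cpg_beta, cohort, alpha=alpha, fdr=fdr)
    stage1 = intersect_common(screen)
    directions = monotone_filter(cpg_beta, cohort, stage1)
    stage2 = set(directions)
    stage3, stage4, stage5 = annotation_filters(stage2, index)
    return FunnelResult(
        alpha=alpha,
        n_total=len(beta.locus_ids),
        cpg_set=set(cpg_ids),
        screen=screen,
        stage1_common=stage1,
        stage2_monotone=stage2,
        directions=directions,
        stage3_accession=stage3,
        stage4_promoter=stage4,
        stage5_island=stage5,
    )
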