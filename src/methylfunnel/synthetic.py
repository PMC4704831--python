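"""Synthetic cohorts, manifests, beta matrices and pyrosequencing replicates.

The generator emulates the statistical structure the two-stage analysis
assumes: three diagnostic groups (NC / aMCI / AD, default sizes 30/28/30)
with realistic clinical covariate marginals, a 450K-like locus annotation
manifest at reduced scale, array beta values with logit-normal noise and
group-dependent monotone effects at planted loci, and a pyrosequencing
replicate of one locus with platform noise and optional orientation
inversion (the inverted mode reproduces negative cross-platform
correlations).

Everything is deterministic under a fixed seed: each generator draws from
its own :class:`numpy.random.Generator` stream spawned from the config seed,
so regenerating one artifact never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .io import (
    GROUPS,
    ISLAND_RELATIONS,
    REFGENE_GROUPS,
    BetaMatrix,
    LocusAnnotation,
    PyroTable,
    SampleRecord,
)

# ---------------------------------------------------------------------------
# Cohort marginals (study conditions; mean +/- SEM scale)
# ---------------------------------------------------------------------------

#: Per-group clinical marginals: age mean/SEM, female fraction, score means/SEMs,
#: disease duration, and APOE allele frequencies (e2, e3, e4).
COHORT_MARGINALS = {
    "NC": dict(
        age=(70.5, 1.0), female=0.600, mmse=None, fab=None, duration=None,
        apoe=(3 / 60, 46 / 60, 11 / 60),
    ),
    "aMCI": dict(
        age=(72.0, 0.9), female=0.536, mmse=(27.2, 0.4), fab=(14.8, 0.4),
        duration=(26.5, 4.4), apoe=(1 / 56, 43 / 56, 12 / 56),
    ),
    "AD": dict(
        age=(71.8, 0.9), female=0.533, mmse=(18.5, 1.0), fab=(12.0, 0.7),
        duration=(28.2, 3.5), apoe=(0.0, 35 / 60, 25 / 60),
    ),
}

#: Fraction of AD subjects with a missing FAB score (23 of 30 scored).
FAB_MISSING_AD = 7 / 30

AGE_RANGE = (55.0, 90.0)

#: Genome-wide CpG fraction of the 450K array (482,421 of 485,777 loci).
CPG_FRACTION_450K = 482421 / 485777


@dataclass
class AnnotationFractions:
    """Category probabilities for the synthetic manifest."""

    is_cpg: float = CPG_FRACTION_450K
    accession: float = 0.75  # fraction of loci annotated to >= 1 transcript
    refgene_probs: dict = field(default_factory=lambda: {
        "TSS1500": 0.17, "TSS200": 0.12, "5'UTR": 0.12,
        "1stExon": 0.08, "Body": 0.43, "3'UTR": 0.08,
    })
    island_probs: dict = field(default_factory=lambda: {
        "Island": 0.31, "N_Shore": 0.12, "S_Shore": 0.10,
        "N_Shelf": 0.05, "S_Shelf": 0.05, "OpenSea": 0.37,
    })

    def __post_init__(self) -> None:
        for p in (self.is_cpg, self.accession):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for probs, keys in ((self.refgene_probs, REFGENE_GROUPS),
                            (self.island_probs, ISLAND_RELATIONS)):
            if set(probs) - set(keys):
                raise ValueError(f"unknown categories {set(probs) - set(keys)}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category probabilities sum to {total}, not 1")


@dataclass
class CovariateModel:
    """Optional link from the score-linked planted locus to MMSE/FAB.

    When ``link`` is set, patient scores are re-drawn as the group centre
    plus ``slope`` points per percentage point of methylation above the
    group's planted mean at the first planted locus, plus independent noise.
    With the default decreasing effect profile this makes cognition and
    methylation fall together with disease severity — between-group and
    within-group components aligned — so the linked locus shows the
    strongest rank correlation (by magnitude) with both scores, the
    structure the candidate-selection rule keys on.
    """

    link: bool = False
    mmse_slope: float = 0.8   # MMSE points per % methylation deviation
    mmse_noise: float = 0.5
    fab_slope: float = 0.7
    fab_noise: float = 0.4


@dataclass
class Platform:
    """Pyrosequencing platform model: additive percent-scale noise and an
    optional orientation inversion (percent = 100 - 100*beta + noise)."""

    pyro_sd: float = 3.0   # percent points
    inverted: bool = False
    n_cpgs: int = 4


@dataclass
class SimulationConfig:
    group_sizes: tuple[int, int, int] = (30, 28, 30)
    n_loci: int = 10_000
    n_planted: int = 20
    effect_profile: tuple[float, float, float] = (0.8, 0.6, 0.4)
    validation_profile: tuple[float, float, float] = (0.60, 0.40, 0.45)
    noise_sd: float = 0.2  # logit-scale; ~0.05 on the beta scale near 0.5
    fab_missing_ad: float = FAB_MISSING_AD
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    annotation_fractions: AnnotationFractions = field(default_factory=AnnotationFractions)
    platform: Platform = field(default_factory=Platform)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes):
            raise ValueError(f"negative group size in {self.group_sizes}")
        if not 0 <= self.n_planted <= self.n_loci:
            raise ValueError("need 0 <= n_planted <= n_loci")
        for prof in (self.effect_profile, self.validation_profile):
            if len(prof) != 3 or any(not 0.0 < m < 1.0 for m in prof):
                raise ValueError(f"effect profile {prof} must be 3 means in (0, 1)")
        if self.noise_sd < 0 or self.platform.pyro_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "covariate_model" in d and isinstance(d["covariate_model"], dict):
            d["covariate_model"] = CovariateModel(**d["covariate_model"])
        if "annotation_fractions" in d and isinstance(d["annotation_fractions"], dict):
            d["annotation_fractions"] = AnnotationFractions(**d["annotation_fractions"])
        if "platform" in d and isinstance(d["platform"], dict):
            d["platform"] = Platform(**d["platform"])
        for key in ("group_sizes", "effect_profile", "validation_profile"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests: which loci carry group effects."""

    locus_ids: list[str]
    effect_profiles: list[tuple[float, float, float]]
    direction: str  # 'decreasing' or 'increasing'
    score_linked_locus: str | None = None


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# dedicated stream indices, so each artifact regenerates independently
_STREAM_COHORT, _STREAM_MANIFEST, _STREAM_BETA, _STREAM_PYRO, _STREAM_VALID = range(5)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # redraw, not clip: preserves the mean
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> list[SampleRecord]:
    """Simulate the three-group cohort with the study's covariate marginals.

    SEM-scale marginals are converted to subject-level SDs (sd = SEM * sqrt(n)
    at the published group size); ages are truncated to a plausible clinical
    range by redraw.  MMSE/FAB are present only for aMCI/AD, with a
    configurable fraction of AD subjects missing FAB.  Onset age is derived
    as age minus disease duration.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_COHORT)
    published_n = dict(zip(GROUPS, (30, 28, 30)))
    records: list[SampleRecord] = []
    for group, n in zip(GROUPS, config.group_sizes):
        marg = COHORT_MARGINALS[group]
        n_pub = published_n[group]
        age_mean, age_sem = marg["age"]
        ages = _truncated_normal(rng, age_mean, age_sem * np.sqrt(n_pub),
                                 *AGE_RANGE, size=n)
        female = rng.random(n) < marg["female"]
        apoe = np.asarray(marg["apoe"], dtype=float)
        apoe = apoe / apoe.sum()
        alleles = rng.choice(["e2", "e3", "e4"], size=(n, 2), p=apoe)
        if marg["mmse"] is not None:
            m_mean, m_sem = marg["mmse"]
            mmse = np.clip(np.round(rng.normal(m_mean, m_sem * np.sqrt(n_pub), n)),
                           0, 30).astype(int)
            f_mean, f_sem = marg["fab"]
            n_fab_pub = 23 if group == "AD" else n_pub
            fab = np.clip(np.round(rng.normal(f_mean, f_sem * np.sqrt(n_fab_pub), n)),
                          0, 18).astype(int)
            fab_missing = (rng.random(n) < config.fab_missing_ad) if group == "AD" \
                else np.zeros(n, dtype=bool)
            d_mean, d_sem = marg["duration"]
            duration = _truncated_normal(rng, d_mean, d_sem * np.sqrt(n_pub),
                                         1.0, 120.0, size=n)
        else:
            mmse = fab = duration = None
            fab_missing = np.zeros(n, dtype=bool)
        for i in range(n):
            records.append(SampleRecord(
                sample_id=f"{group}{i + 1:03d}",
                group=group,
                age=round(float(ages[i]), 2),
                sex="F" if female[i] else "M",
                mmse=None if mmse is None else int(mmse[i]),
                fab=None if fab is None or fab_missing[i] else int(fab[i]),
                apoe_alleles=tuple(sorted(alleles[i])),
                duration_months=None if duration is None else round(float(duration[i]), 2),
                onset_age=None if duration is None
                else round(float(ages[i] - duration[i] / 12.0), 2),
            ))
    return records


def discovery_subset(cohort: list[SampleRecord], k: int = 4) -> list[SampleRecord]:
    """The small age-matched discovery groups: the k youngest per group.

    Mirrors the two-stage design in which genome-wide screening used small
    groups nested inside the validation cohort.
    """
    if k < 2:
        raise ValueError("discovery subset needs k >= 2 per group")
    out: list[SampleRecord] = []
    for group in GROUPS:
        members = sorted((r for r in cohort if r.group == group),
                         key=lambda r: (r.age, r.sample_id))
        if len(members) < k:
            raise ValueError(f"group {group} has {len(members)} < k={k} subjects")
        out.extend(members[:k])
    return out


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_GENE_SYLLABLES = ["AL", "BR", "CO", "DU", "EX", "FI", "GA", "HO", "IN", "JU",
                   "KA", "LO", "MI", "NE", "OR", "PA", "QU", "RO", "SA", "TU"]


def _fake_gene_name(rng: np.random.Generator) -> str:
    parts = rng.choice(_GENE_SYLLABLES, size=3)
    return "".join(parts) + str(rng.integers(1, 10))


def generate_manifest(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[LocusAnnotation]:
    """Simulate a reduced-scale 450K-style manifest.

    Category indicators are drawn independently per the configured fractions.
    The first ``n_planted`` loci are forced to satisfy all four funnel
    annotation predicates (CpG locus, accession present, promoter-proximal
    RefGene group, CpG island), matching the contract with
    :func:`generate_beta`, which plants its effects at those same loci.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_MANIFEST)
    fr = config.annotation_fractions
    rg_names = list(fr.refgene_probs)
    rg_probs = np.array([fr.refgene_probs[g] for g in rg_names])
    is_names = list(fr.island_probs)
    is_probs = np.array([fr.island_probs[g] for g in is_names])
    promoter = ["TSS1500", "TSS200", "5'UTR", "1stExon"]

    out: list[LocusAnnotation] = []
    for i in range(config.n_loci):
        target_id = f"cg{i:08d}"
        forced = i < config.n_planted
        is_cpg = True if forced else bool(rng.random() < fr.is_cpg)
        annotated = True if forced else bool(rng.random() < fr.accession)
        if annotated:
            n_tx = int(rng.integers(1, 4))
            gene = _fake_gene_name(rng)
            genes = [gene] * n_tx
            accs = [f"NM_{rng.integers(1, 999999):06d}" for _ in range(n_tx)]
            groups = [str(g) for g in rng.choice(rg_names, size=n_tx, p=rg_probs)]
            if forced and not any(g in promoter for g in groups):
                groups[0] = str(rng.choice(promoter))
        else:
            genes, accs, groups = [], [], []
        island = "Island" if forced else str(rng.choice(is_names, p=is_probs))
        out.append(LocusAnnotation(
            target_id=target_id,
            is_cpg=is_cpg,
            gene_names=genes,
            accessions=accs,
            refgene_groups=groups,
            island_relation=island,
            chromosome=f"chr{int(rng.integers(1, 23))}",
            position=int(rng.integers(1, 2**27)),
        ))
    return out


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


def _logit_normal(rng, mean_beta, noise_sd, size):
    if noise_sd == 0.0:
        return np.full(size, mean_beta, dtype=float)
    return expit(logit(mean_beta) + rng.normal(0.0, noise_sd, size=size))


def generate_beta(cohort: list[SampleRecord],
                  manifest: list[LocusAnnotation],
                  config: SimulationConfig,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[BetaMatrix, PlantedTruth]:
    """Simulate the loci x samples beta matrix with planted monotone effects.

    Null loci draw a per-locus baseline in (0.05, 0.95) and add logit-scale
    Gaussian noise per subject — no group effect.  The first ``n_planted``
    manifest loci instead follow ``effect_profile`` per group (default
    strictly decreasing NC > aMCI > AD).  If the covariate model links scores
    to methylation, patient MMSE/FAB are re-drawn in place around the group
    centre with a negative dependence on the first planted locus.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_BETA)
    n_samples = len(cohort)
    n_loci = len(manifest)
    if config.n_planted > n_loci:
        raise ValueError("more planted loci than manifest rows")
    group_idx = np.array([GROUPS.index(r.group) for r in cohort])
    values = np.empty((n_loci, n_samples), dtype=float)

    cm = config.covariate_model
    profile = np.asarray(config.effect_profile, dtype=float)
    locus_profiles = [profile] * config.n_planted
    for i in range(config.n_planted):
        means = locus_profiles[i][group_idx]
        values[i] = expit(logit(means) + rng.normal(0.0, config.noise_sd, n_samples)) \
            if config.noise_sd > 0 else means

    n_null = n_loci - config.n_planted
    if n_null:
        baselines = rng.uniform(0.05, 0.95, size=n_null)
        noise = rng.normal(0.0, config.noise_sd, size=(n_null, n_samples)) \
            if config.noise_sd > 0 else 0.0
        values[config.n_planted:] = expit(logit(baselines)[:, None] + noise)

    locus_ids = [a.target_id for a in manifest]
    sample_ids = [r.sample_id for r in cohort]
    planted_ids = locus_ids[: config.n_planted]
    diffs = np.diff(profile)
    direction = "decreasing" if np.all(diffs < 0) else (
        "increasing" if np.all(diffs > 0) else "non-monotone")
    truth = PlantedTruth(
        locus_ids=planted_ids,
        effect_profiles=[tuple(p) for p in locus_profiles],
        direction=direction,
        score_linked_locus=planted_ids[0] if cm.link and planted_ids else None,
    )

    if cm.link and config.n_planted:
        link_beta = values[0]
        link_profile = locus_profiles[0]
        for j, rec in enumerate(cohort):
            if rec.group == "NC":
                continue
            g = GROUPS.index(rec.group)
            dev = 100.0 * (link_beta[j] - link_profile[g])  # % points above centre
            m_mean, _ = COHORT_MARGINALS[rec.group]["mmse"]
            f_mean, _ = COHORT_MARGINALS[rec.group]["fab"]
            rec.mmse = int(np.clip(round(
                m_mean + cm.mmse_slope * dev + rng.normal(0.0, cm.mmse_noise)), 0, 30))
            if rec.fab is not None:
                rec.fab = int(np.clip(round(
                    f_mean + cm.fab_slope * dev + rng.normal(0.0, cm.fab_noise)), 0, 18))

    return BetaMatrix(locus_ids, sample_ids, values), truth


def generate_locus_beta(cohort: list[SampleRecord],
                        profile: tuple[float, float, float],
                        noise_sd: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-subject beta at a single locus following a per-group mean profile."""
    profile = np.asarray(profile, dtype=float)
    means = profile[[GROUPS.index(r.group) for r in cohort]]
    if noise_sd == 0.0:
        return means
    return expit(logit(means) + rng.normal(0.0, noise_sd, size=len(cohort)))


def coupled_validation_beta(cohort: list[SampleRecord],
                            array_beta: np.ndarray,
                            profile: tuple[float, float, float],
                            rng: np.random.Generator,
                            residual_sd: float = 0.1) -> np.ndarray:
    """Validation-stage latent methylation coupled to the array measurement.

    The same blood sample underlies both platforms, so subject-level
    deviations are shared: each subject's logit-scale deviation from their
    group's array mean is carried over onto the validation-shaped group
    profile, plus independent platform/handling noise.  Group-level means may
    still differ between stages (``profile``), emulating a validation cohort
    whose ordering departs from the discovery ordering.
    """
    profile = np.asarray(profile, dtype=float)
    group_idx = np.array([GROUPS.index(r.group) for r in cohort])
    array_beta = np.clip(np.asarray(array_beta, dtype=float), 1e-6, 1 - 1e-6)
    lg = logit(array_beta)
    centers = np.array([lg[group_idx == g].mean() if np.any(group_idx == g) else 0.0
                        for g in range(len(GROUPS))])
    dev = lg - centers[group_idx]
    noise = rng.normal(0.0, residual_sd, size=len(cohort)) if residual_sd > 0 else 0.0
    return expit(logit(profile[group_idx]) + dev + noise)


# ---------------------------------------------------------------------------
# Pyrosequencing replicate
# ---------------------------------------------------------------------------


def generate_pyro(beta_row: np.ndarray,
                  sample_ids: list[str],
                  config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> PyroTable:
    """Simulate a pyrosequencing measurement of one locus.

    Per subject and CpG: ``percent = clamp(100*(o + s*beta) + noise, 0, 100)``
    with orientation ``(o, s) = (0, +1)`` for a same-scale platform and
    ``(1, -1)`` when the assay reads the inverted scale.
    """
    if rng is None:
        rng = _rng(config.seed, _STREAM_PYRO)
    beta_row = np.asarray(beta_row, dtype=float)
    if beta_row.shape != (len(sample_ids),):
        raise ValueError("beta_row length must match sample_ids")
    o, s = (1.0, -1.0) if config.platform.inverted else (0.0, 1.0)
    K = config.platform.n_cpgs
    rows = []
    for k in range(1, K + 1):
        noise = rng.normal(0.0, config.platform.pyro_sd, size=len(sample_ids)) \
            if config.platform.pyro_sd > 0 else 0.0
        pct = np.clip(100.0 * (o + s * beta_row) + noise, 0.0, 100.0)
        for sid, v in zip(sample_ids, pct):
            rows.append((sid, k, float(v)))
    df = pd.DataFrame(rows, columns=["sample_id", "cpg_index", "percent_methylation"])
    return PyroTable(df)


# ---------------------------------------------------------------------------
# Intensity -> beta helper
# ---------------------------------------------------------------------------


def intensities_to_beta(methylated_signal: float,
                        unmethylated_signal: float,
                        offset: float = 100.0) -> float:
    """Infinium beta value: M / (M + U + offset)."""
    if methylated_signal < 0 or unmethylated_signal < 0 or offset < 0:
        raise ValueError("signals and offset must be nonnegative")
    denom = methylated_signal + unmethylated_signal + offset
    if denom == 0.0:
        raise ValueError("beta undefined: M + U + offset == 0")
    return methylated_signal / denom
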