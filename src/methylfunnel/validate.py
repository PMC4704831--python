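"""Confirmation-stage statistics on the full cohort.

Given per-CpG pyrosequencing percent-methylation for the selected candidate
region, this module computes, per CpG site:

* age-adjusted three-group comparison (ANCOVA with age as the covariate)
  with pairwise contrasts of adjusted means,
* Spearman correlations with MMSE and FAB (scored patients), with age (all
  subjects), and with disease duration and onset age (patients only),
* a sex-difference t-test,
* cross-platform Pearson correlation against array betas for the subjects
  measured on both platforms, and
* an APOE epsilon-4 carrier vs non-carrier t-test.

Also provides the cohort characteristics table (group means +/- SEM with
the tests used for the subject-characteristics summary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GROUPS, PyroTable, SampleRecord
from .stats import (
    AncovaResult,
    TestResult,
    ancova_group_age,
    chi_square_independence,
    one_way_anova,
    pearson,
    spearman,
    t_test_unpaired,
)

SIGNIFICANCE_LEVELS = ((0.0001, "****"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in SIGNIFICANCE_LEVELS:
        if p < level:
            return stars
    return ""


def carrier_status(record: SampleRecord) -> bool:
    """True iff the subject carries at least one APOE epsilon-4 allele."""
    return "e4" in record.apoe_alleles


@dataclass
class CpgValidation:
    """All confirmation statistics for one CpG site of the assay."""

    cpg_index: int
    ancova: AncovaResult
    vs_mmse: TestResult | None
    vs_fab: TestResult | None
    vs_age: TestResult | None
    vs_duration: TestResult | None
    vs_onset: TestResult | None
    sex_diff: TestResult | None
    cross_platform: TestResult | None
    apoe_carrier: TestResult | None


@dataclass
class ValidationReport:
    per_cpg: dict[int, CpgValidation] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def tr(t: TestResult | None) -> dict | None:
            if t is None:
                return None
            df = list(t.df) if isinstance(t.df, tuple) else t.df
            return {"statistic": t.statistic, "df": df,
                    "p_value": t.p_value, "estimate": t.estimate}

        out: dict = {}
        for k in sorted(self.per_cpg):
            v = self.per_cpg[k]
            a = v.ancova
            out[str(k)] = {
                "ancova": {
                    "adjusted_group_means": a.adjusted_group_means,
                    "covariate_slope": a.covariate_slope,
                    "group_F": a.group_F,
                    "group_df": list(a.group_df),
                    "group_p": a.group_p,
                    "contrasts": {
                        f"{g1}-{g2}": {"diff": d, "t": t, "p": p,
                                       "stars": significance_stars(p)}
                        for (g1, g2), (d, t, p) in a.contrasts.items()
                    },
                },
                "spearman_mmse": tr(v.vs_mmse),
                "spearman_fab": tr(v.vs_fab),
                "spearman_age": tr(v.vs_age),
                "spearman_duration": tr(v.vs_duration),
                "spearman_onset": tr(v.vs_onset),
                "sex_t_test": tr(v.sex_diff),
                "cross_platform_pearson": tr(v.cross_platform),
                "apoe_carrier_t_test": tr(v.apoe_carrier),
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.per_cpg):
            v = self.per_cpg[k]
            row: dict = {"cpg_index": k,
                         "ancova_F": v.ancova.group_F,
                         "ancova_p": v.ancova.group_p}
            for g, m in v.ancova.adjusted_group_means.items():
                row[f"adj_mean_{g}"] = m
            for (g1, g2), (_, _, p) in v.ancova.contrasts.items():
                row[f"p_{g1}_vs_{g2}"] = p
            for tag, t in (("mmse", v.vs_mmse), ("fab", v.vs_fab),
                           ("age", v.vs_age), ("duration", v.vs_duration),
                           ("onset", v.vs_onset)):
                row[f"rho_{tag}"] = math.nan if t is None else t.statistic
                row[f"p_{tag}"] = math.nan if t is None else t.p_value
            row["r_cross_platform"] = (math.nan if v.cross_platform is None
                                       else v.cross_platform.statistic)
            row["p_cross_platform"] = (math.nan if v.cross_platform is None
                                       else v.cross_platform.p_value)
            row["p_sex"] = math.nan if v.sex_diff is None else v.sex_diff.p_value
            row["p_apoe"] = (math.nan if v.apoe_carrier is None
                             else v.apoe_carrier.p_value)
            rows.append(row)
        return pd.DataFrame(rows).set_index("cpg_index")


def _try(func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except ValueError:
        return None


def validate_candidate(pyro: PyroTable, cohort: list[SampleRecord],
                       array_beta_for_locus: dict[str, float] | None = None,
                       ) -> ValidationReport:
    """Run all confirmation statistics per CpG site.

    ``array_beta_for_locus`` maps sample_id -> array beta at the candidate
    locus for the subjects measured on both platforms; when given, a per-CpG
    cross-platform Pearson correlation is computed on those subjects.
    Age is a mandatory covariate: a subject with pyro data but no age aborts.
    """
    by_id = {r.sample_id: r for r in cohort}
    unknown = set(pyro.data["sample_id"]) - set(by_id)
    if unknown:
        raise ValueError(f"pyro samples not in cohort: {sorted(unknown)[:5]}")

    report = ValidationReport()
    for k in pyro.cpg_indices:
        series = pyro.for_cpg(k)
        recs = [by_id[s] for s in series.index]
        values = series.to_numpy(dtype=float)
        groups = [r.group for r in recs]
        ages = np.array([math.nan if r.age is None else r.age for r in recs])
        if not np.all(np.isfinite(ages)):
            raise ValueError(f"CpG {k}: missing age; the covariate is mandatory")
        for g in GROUPS:
            if groups.count(g) < 3:
                raise ValueError(f"CpG {k}: group {g} has < 3 pyro subjects")

        anc = ancova_group_age(values, groups, ages, group_order=list(GROUPS))

        def paired(attr: str, subset) -> tuple[np.ndarray, np.ndarray]:
            xs, ys = [], []
            for r, v in zip(recs, values):
                if not subset(r):
                    continue
                s = getattr(r, attr)
                if s is not None:
                    xs.append(v)
                    ys.append(float(s))
            return np.asarray(xs), np.asarray(ys)

        is_patient = lambda r: r.group != "NC"
        everyone = lambda r: True
        vs_mmse = _try(spearman, *paired("mmse", is_patient))
        vs_fab = _try(spearman, *paired("fab", is_patient))
        vs_age = _try(spearman, *paired("age", everyone))
        vs_dur = _try(spearman, *paired("duration_months", is_patient))
        vs_onset = _try(spearman, *paired("onset_age", is_patient))

        f_vals = [v for r, v in zip(recs, values) if r.sex == "F"]
        m_vals = [v for r, v in zip(recs, values) if r.sex == "M"]
        sex_diff = _try(t_test_unpaired, f_vals, m_vals)

        cross = None
        if array_beta_for_locus:
            xs = [array_beta_for_locus[s] for s in series.index
                  if s in array_beta_for_locus]
            ys = [series[s] for s in series.index if s in array_beta_for_locus]
            cross = _try(pearson, np.asarray(xs), np.asarray(ys))

        carriers = [v for r, v in zip(recs, values) if carrier_status(r)]
        non_carriers = [v for r, v in zip(recs, values) if not carrier_status(r)]
        apoe = _try(t_test_unpaired, carriers, non_carriers)

        report.per_cpg[k] = CpgValidation(
            cpg_index=k, ancova=anc, vs_mmse=vs_mmse, vs_fab=vs_fab,
            vs_age=vs_age, vs_duration=vs_dur, vs_onset=vs_onset,
            sex_diff=sex_diff, cross_platform=cross, apoe_carrier=apoe,
        )
    return report


# ---------------------------------------------------------------------------
# Cohort characteristics table
# ---------------------------------------------------------------------------


def _mean_sem(values: list[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 0:
        return math.nan, math.nan, 0
    sem = arr.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
    return float(arr.mean()), float(sem), n


def cohort_table(cohort: list[SampleRecord]) -> dict:
    """Subject-characteristics summary: per-group means +/- SEM and the
    between-group tests (ANOVA for age, chi-square for sex and each APOE
    allele vs the rest, unpaired t-tests for the aMCI-vs-AD comparisons)."""
    if not cohort:
        raise ValueError("empty cohort")
    by_group = {g: [r for r in cohort if r.group == g] for g in GROUPS}
    present = [g for g in GROUPS if by_group[g]]

    table: dict = {"group_sizes": {g: len(by_group[g]) for g in GROUPS}}

    def column(group: str, attr: str) -> list[float]:
        return [float(getattr(r, attr)) for r in by_group[group]
                if getattr(r, attr) is not None]

    for attr, label in (("age", "age"), ("duration_months", "duration_months"),
                        ("onset_age", "onset_age"), ("mmse", "mmse"), ("fab", "fab")):
        table[label] = {}
        for g in GROUPS:
            mean, sem, n = _mean_sem(column(g, attr))
            table[label][g] = {"mean": mean, "sem": sem, "n": n}

    table["sex"] = {g: {"F": sum(r.sex == "F" for r in by_group[g]),
                        "M": sum(r.sex == "M" for r in by_group[g])}
                    for g in GROUPS}
    table["apoe_counts"] = {}
    for g in GROUPS:
        counts = {a: 0 for a in ("e2", "e3", "e4")}
        for r in by_group[g]:
            for a in r.apoe_alleles:
                counts[a] += 1
        table["apoe_counts"][g] = counts

    tests: dict = {}
    if len(present) >= 2:
        age_samples = [column(g, "age") for g in present]
        if all(len(s) >= 2 for s in age_samples):
            tests["age_anova_p"] = one_way_anova(age_samples).p_value
        sex_table = [[table["sex"][g]["F"], table["sex"][g]["M"]] for g in present]
        chi = _try(chi_square_independence, sex_table)
        tests["sex_chi2_p"] = None if chi is None else chi.p_value
        # per-allele chi-square: allele-vs-rest counts by group
        for allele in ("e2", "e3", "e4"):
            rows = []
            for g in present:
                c = table["apoe_counts"][g]
                total = sum(c.values())
                rows.append([c[allele], total - c[allele]])
            chi = _try(chi_square_independence, rows)
            tests[f"apoe_{allele}_chi2_p"] = None if chi is None else chi.p_value
    else:
        tests["age_anova_p"] = None
        tests["sex_chi2_p"] = None

    for attr in ("mmse", "fab", "duration_months", "onset_age"):
        a, b = column("aMCI", attr), column("AD", attr)
        if len(a) >= 2 and len(b) >= 2:
            tests[f"{attr}_t_p"] = t_test_unpaired(a, b).p_value
        else:
            tests[f"{attr}_t_p"] = None
    table["tests"] = tests
    return table
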