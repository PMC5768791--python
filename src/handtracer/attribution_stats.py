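"""Cohort statistics over per-palm attribution estimates.

Per-sample mixing proportions are collapsed to body-site sums (forehead /
stool / tongue / unknown) and to relation sums (self / family / unrelated,
by comparing each source's host and family to the palm owner's).  A
one-sample t-test on the attribution mean and SD decides whether a palm's
fecal or oral signal sits above sampler noise.  Enrichment of self/family
assignment against a "reads land on any sample with equal chance"
permutation null is tested with a Cochran-Mantel-Haenszel-style stratified
statistic, one stratum per palm; group contrasts use the Mann-Whitney U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AgeClass, SampleMetadata
from .st_core import MixingEstimate

__all__ = [
    "AttributionSummary",
    "NullDistribution",
    "CohortReport",
    "summarize_palm",
    "signal_above_noise",
    "permute_null",
    "cmh_enrichment",
    "compare_groups",
    "summarize_cohort",
    "SITES",
    "RELATIONS",
]

logger = logging.getLogger(__name__)

SITES = ("forehead", "stool", "tongue", "unknown")
RELATIONS = ("self", "family", "unrelated")


@dataclass
class AttributionSummary:
    """One palm's attribution collapsed to sites and relations.

    ``by_site`` sums to 1; ``by_relation`` covers attributed (non-unknown)
    mass only, so relations + unknown also sum to 1.
    """

    palm_id: str
    by_site: dict[str, float]
    by_relation: dict[str, float]
    by_site_relation: dict[tuple[str, str], float]
    above_noise: dict[str, bool]

    def __post_init__(self):
        if abs(sum(self.by_site.values()) - 1) > 1e-9:
            raise ValueError("by_site must sum to 1")
        tot = sum(self.by_relation.values()) + self.by_site["unknown"]
        if abs(tot - 1) > 1e-9:
            raise ValueError("relations + unknown must sum to 1")

    @property
    def by_relation_renormalized(self) -> dict[str, float]:
        """Relation shares of the attributed mass (unknown excluded)."""
        attributed = sum(self.by_relation.values())
        if attributed <= 0:
            return {r: float("nan") for r in RELATIONS}
        return {r: v / attributed for r, v in self.by_relation.items()}


def signal_above_noise(mean: float, sd: float, n_draws: int,
                       alpha: float = 0.05) -> bool:
    """One-sided one-sample t-test of H0: proportion = 0 against > 0.

    Uses t = mean/(sd/sqrt(n_draws)) with n_draws - 1 degrees of freedom,
    the attribution SD across recorded Gibbs draws standing in for the
    sampling SD.
    """
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    if mean <= 0:
        return False
    if sd == 0:
        return True
    t = mean / (sd / np.sqrt(n_draws))
    return bool(stats.t.sf(t, df=n_draws - 1) < alpha)


def summarize_palm(estimate: MixingEstimate, metadata: SampleMetadata,
                   alpha: float = 0.05) -> AttributionSummary:
    """Collapse one palm's per-sample proportions to site/relation sums.

    Site-level noise testing uses draw-level site sums when the estimate
    retains its raw draws (preserving covariance between sources of the
    same site); otherwise variances are summed as a fallback.
    """
    missing = [s for s in estimate.source_ids if s not in metadata]
    if missing:
        raise KeyError(f"sources missing from metadata: {missing[:5]}")
    by_site = {s: 0.0 for s in SITES}
    by_relation = {r: 0.0 for r in RELATIONS}
    by_sr = {(s, r): 0.0 for s in SITES[:3] for r in RELATIONS}
    site_of, rel_of = [], []
    for sid, p in zip(estimate.source_ids, estimate.proportions_mean[:-1]):
        site = metadata.body_site(sid)
        rel = metadata.relation(sid, estimate.sink_id)
        site_of.append(site)
        rel_of.append(rel)
        by_site[site] += float(p)
        by_relation[rel] += float(p)
        by_sr[(site, rel)] += float(p)
    by_site["unknown"] = float(estimate.proportions_mean[-1])

    above = {}
    for site in ("stool", "tongue"):
        if estimate.draw_proportions is not None:
            mask = np.array([s == site for s in site_of] + [False])
            sums = estimate.draw_proportions[:, mask].sum(axis=1)
            m, sd = float(sums.mean()), float(sums.std(ddof=1))
        else:
            idx = [i for i, s in enumerate(site_of) if s == site]
            m = by_site[site]
            sd = float(np.sqrt(np.sum(estimate.proportions_sd[idx] ** 2)))
        above[site] = signal_above_noise(m, sd, estimate.n_draws, alpha)
    return AttributionSummary(estimate.sink_id, by_site, by_relation, by_sr,
                              above)


@dataclass
class NullDistribution:
    """Uniform-assignment null over source samples, per palm.

    ``per_palm_null_counts`` has shape (n_palms, n_perm, 3) over the
    relation categories; every permutation preserves each palm's total
    attributed read count.  ``summary_mean``/``summary_se`` are cohort
    relation fractions across permutations.
    """

    palm_ids: list[str]
    n_perm: int
    per_palm_null_counts: np.ndarray = field(repr=False)
    summary_mean: np.ndarray
    summary_se: np.ndarray

    def expected_counts(self, palm_id: str) -> np.ndarray:
        """Permutation-mean relation counts for one palm."""
        i = self.palm_ids.index(palm_id)
        return self.per_palm_null_counts[i].mean(axis=0)


def permute_null(estimates: list[MixingEstimate], metadata: SampleMetadata,
                 n_perm: int = 25, seed: int = 0) -> NullDistribution:
    """Reassign each palm's attributed reads uniformly over source samples.

    Read counts are reconstructed as mean proportions x sink depth (per-read
    labels are not persisted).  Under the null every read lands on any
    source sample with equal chance, so a palm's relation counts are
    multinomial with probabilities proportional to the number of samples
    per relation.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations for an SE")
    if not estimates:
        raise ValueError("no estimates supplied")
    rng = np.random.default_rng(seed)
    palm_ids = [e.sink_id for e in estimates]
    counts = np.zeros((len(estimates), n_perm, 3), dtype=np.int64)
    for i, e in enumerate(estimates):
        rels = np.array([RELATIONS.index(metadata.relation(s, e.sink_id))
                         for s in e.source_ids])
        probs = np.bincount(rels, minlength=3) / len(rels)
        n_attributed = int(round(float(e.assignment_counts[:-1].sum())))
        counts[i] = rng.multinomial(n_attributed, probs, size=n_perm)
    per_perm_frac = counts.sum(axis=0) / counts.sum(axis=(0, 2), keepdims=False)[:, None]
    return NullDistribution(palm_ids, n_perm, counts,
                            per_perm_frac.mean(axis=0),
                            per_perm_frac.std(axis=0, ddof=1) / np.sqrt(n_perm))


def observed_relation_counts(estimates: list[MixingEstimate],
                             metadata: SampleMetadata) -> dict[str, np.ndarray]:
    """Per-palm observed (self, family, unrelated) read counts.

    Relation proportions are scaled to the palm's attributed (non-unknown)
    read count and rounded, mirroring the reconstruction used for the
    permutation null.
    """
    out = {}
    for e in estimates:
        s = summarize_palm(e, metadata)
        attributed = float(e.assignment_counts[:-1].sum())
        denom = sum(s.by_relation.values())
        scale = attributed / denom if denom > 0 else 0.0
        out[e.sink_id] = np.rint(
            [s.by_relation[r] * scale for r in RELATIONS])
    return out


def _cmh_tables(observed: dict[str, np.ndarray],
                null: NullDistribution) -> list[np.ndarray]:
    tables = []
    for palm, obs in observed.items():
        obs = np.asarray(obs, dtype=float)
        exp = np.rint(null.expected_counts(palm))
        tab = np.stack([obs, exp])
        if tab.sum() == 0:
            logger.warning("palm %s dropped from CMH: zero total", palm)
            continue
        tables.append(tab)
    return tables


def cmh_enrichment(observed: dict[str, np.ndarray],
                   null: NullDistribution) -> tuple[float, float]:
    """Stratified observed-vs-null test over relation categories.

    Each palm is an independent stratum holding a 2x3 table: observed
    self/family/unrelated read counts against the permutation-null expected
    counts.  The generalized score statistic sums (O - E) and its
    covariance over strata; the covariance uses the multinomial (n^3)
    normalisation, so a single stratum reduces exactly to the Pearson
    chi-square of its table.  Returns (statistic, p) with 2 df.
    """
    tables = _cmh_tables(observed, null)
    if not tables:
        raise ValueError("no usable strata")
    d = np.zeros(2)
    V = np.zeros((2, 2))
    for tab in tables:
        n = tab.sum()
        R1 = tab[0].sum()
        R2 = tab[1].sum()
        C = tab.sum(axis=0)
        O = tab[0, :2]
        E = R1 * C[:2] / n
        d += O - E
        V += R1 * R2 * (n * np.diag(C[:2]) - np.outer(C[:2], C[:2])) / n**3
    T = float(d @ np.linalg.solve(V, d))
    return T, float(stats.chi2.sf(T, df=2))


def compare_groups(values, labels) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between the two label groups.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise (SciPy's automatic policy).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("a group is empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

GROUPINGS = ("age_class", "gender", "is_parent", "hand_side", "has_dog")


@dataclass
class CohortReport:
    """Cohort-level statistics across palms."""

    palm_table: pd.DataFrame = field(repr=False)
    site_summary: pd.DataFrame
    above_noise_fractions: pd.DataFrame
    frac_palms_stool_over_25: float
    group_means: pd.DataFrame
    tests: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.palm_table.to_csv(out / "palm_summaries.tsv", sep="\t")
        self.tests.to_csv(out / "cohort_report.tsv", sep="\t", index=False)
        self.group_means.to_csv(out / "group_means.tsv", sep="\t")
        self.site_summary.to_csv(out / "site_summary.tsv", sep="\t")


def _palm_frame(summaries: list[AttributionSummary],
                metadata: SampleMetadata) -> pd.DataFrame:
    rows = []
    for s in summaries:
        md = metadata.frame.loc[s.palm_id]
        ac = metadata.age_class(s.palm_id)
        row = {"palm_id": s.palm_id, "host_id": md["host_id"],
               "family_id": md["family_id"],
               "age_class": ac.value if ac is not None else pd.NA,
               "gender": md["gender"], "is_parent": md["is_parent"],
               "hand_side": md["hand_side"], "has_dog": md["has_dog"]}
        for site in SITES:
            row[f"site_{site}"] = s.by_site[site]
        for rel in RELATIONS:
            row[f"rel_{rel}"] = s.by_relation[rel]
        for (site, rel), v in s.by_site_relation.items():
            row[f"sr_{site}_{rel}"] = v
        for site, flag in s.above_noise.items():
            row[f"above_noise_{site}"] = flag
        rows.append(row)
    return pd.DataFrame(rows).set_index("palm_id")


def summarize_cohort(summaries: list[AttributionSummary],
                     metadata: SampleMetadata) -> CohortReport:
    """The cohort report: site medians/ranges, above-noise prevalence by
    palm and by individual, high-stool prevalence, and group contrasts
    (age class, gender, parent status, hand side, dog ownership) tested
    pairwise with Mann-Whitney U on every site and relation column.
    """
    if not summaries:
        raise ValueError("no palm summaries")
    df = _palm_frame(summaries, metadata)

    site_summary = pd.DataFrame(
        {"median": [df[f"site_{s}"].median() for s in SITES],
         "min": [df[f"site_{s}"].min() for s in SITES],
         "max": [df[f"site_{s}"].max() for s in SITES]},
        index=list(SITES))

    noise_rows = []
    for site in ("stool", "tongue"):
        col = df[f"above_noise_{site}"]
        by_host = df.groupby("host_id")[f"above_noise_{site}"].any()
        noise_rows.append({"site": site,
                           "frac_palms": float(col.mean()),
                           "frac_individuals": float(by_host.mean())})
    above_noise = pd.DataFrame(noise_rows).set_index("site")

    frac_stool25 = float((df["site_stool"] > 0.25).mean())

    value_cols = ([f"site_{s}" for s in SITES]
                  + [f"rel_{r}" for r in RELATIONS])
    means, tests = [], []
    for grouping in GROUPINGS:
        sub = df[df[grouping].notna()]
        levels = sorted(sub[grouping].dropna().unique(), key=str)
        if len(levels) < 2:
            logger.warning("grouping %s skipped: <2 levels present", grouping)
            continue
        gm = sub.groupby(grouping, observed=True)[value_cols].mean()
        gm.insert(0, "n", sub.groupby(grouping, observed=True).size())
        gm.index = pd.MultiIndex.from_product([[grouping], gm.index.astype(str)],
                                              names=["grouping", "level"])
        means.append(gm)
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                pair = sub[sub[grouping].isin([a, b])]
                for col in value_cols:
                    vals = pair[col].to_numpy(float)
                    labs = pair[grouping].to_numpy()
                    na, nb = int((labs == a).sum()), int((labs == b).sum())
                    U, p = compare_groups(vals, labs)
                    tests.append({"grouping": grouping, "variable": col,
                                  "group1": str(a), "group2": str(b),
                                  "n1": na, "n2": nb, "U": U, "p": p})
    group_means = pd.concat(means) if means else pd.DataFrame()
    tests_df = pd.DataFrame(tests)
    return CohortReport(df, site_summary, above_noise, frac_stool25,
                        group_means, tests_df)


def write_null_distribution(null: NullDistribution, path) -> None:
    """Write null_distribution.tsv (one row per palm x permutation)."""
    rows = []
    for i, palm in enumerate(null.palm_ids):
        for p in range(null.n_perm):
            c = null.per_palm_null_counts[i, p]
            rows.append({"palm_id": palm, "permutation": p,
                         "self": int(c[0]), "family": int(c[1]),
                         "unrelated": int(c[2])})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
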