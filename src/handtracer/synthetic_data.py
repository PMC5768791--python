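"""Synthetic family-structured multi-body-site cohorts with known truth.

A Dirichlet-multinomial hierarchy produces the three statistical features
the attribution pipeline relies on: body-site separation (each site draws
from a partially overlapping taxon pool), interpersonal distinctness
(individual profiles are Dirichlet draws around the site base, with a
tunable concentration — lower means more distinct people), and family
similarity (member profiles are pulled toward a family-level profile by a
mixing coefficient).  Palms are emitted as labelled mixtures of the
owner's/family's/population's site profiles plus an environmental
"unknown" profile over taxa disjoint from every source pool, and each
palm's true mixture is recorded so parameter-recovery tests have ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_tables import OtuTable, SampleMetadata
import pandas as pd

__all__ = [
    "MemberSpec",
    "PopulationSpec",
    "TruthRecord",
    "SyntheticCohort",
    "generate_population",
    "generate_palm",
    "default_spec",
    "high_distinctness_spec",
    "DEFAULT_FAMILY",
]

SOURCE_SITES = ("forehead", "stool", "tongue")


@dataclass(frozen=True)
class MemberSpec:
    """One family member: role drives age, demographic fields and the palm
    truth-mixture preset."""

    role: str  # infant | child | adult_female | adult_male

    def __post_init__(self):
        if self.role not in ("infant", "child", "adult_female", "adult_male"):
            raise ValueError(f"unknown role {self.role!r}")


DEFAULT_FAMILY = (MemberSpec("adult_female"), MemberSpec("adult_male"),
                  MemberSpec("child"))

# Role-dependent truth mixtures over (site, relation) components, before the
# unknown weight is folded in.  Infant palms are tongue-self-heavy and adult
# palms forehead-self-heavy, with smaller own/family stool components, so
# cohort-level age and relation contrasts have known directional truth.
ROLE_MIXTURES: dict[str, dict[tuple[str, str], float]] = {
    "infant": {("tongue", "self"): 0.55, ("forehead", "self"): 0.15,
               ("stool", "family"): 0.20, ("stool", "self"): 0.10},
    "child": {("forehead", "self"): 0.45, ("tongue", "self"): 0.25,
              ("stool", "family"): 0.20, ("stool", "self"): 0.10},
    "adult_female": {("forehead", "self"): 0.60, ("tongue", "self"): 0.15,
                     ("stool", "family"): 0.15, ("stool", "self"): 0.10},
    "adult_male": {("forehead", "self"): 0.60, ("tongue", "self"): 0.15,
                   ("stool", "family"): 0.15, ("stool", "self"): 0.10},
}

SELF_HEAVY_MIXTURE = {("forehead", "self"): 0.40, ("tongue", "self"): 0.30,
                      ("stool", "self"): 0.30}

# site weights used by the "population" preset (mass spread evenly over ALL
# samples of the site, so self/family mass equals the chance level)
POPULATION_SITE_WEIGHTS = {"forehead": 0.5, "tongue": 0.3, "stool": 0.2}

ROLE_AGE_RANGES = {"infant": (0.5, 1.9), "child": (3.0, 12.0),
                   "adult_female": (25.0, 45.0), "adult_male": (25.0, 45.0)}


@dataclass
class PopulationSpec:
    """Tunable description of a synthetic cohort.

    ``interpersonal_concentration`` is the Dirichlet concentration of
    individual profiles around the (family-blended) site base: 50 gives a
    realistically modest interpersonal variation, small values (~5) give
    highly distinct individuals.  ``family_coefficient`` in [0,1] pulls
    member profiles toward a family mean; 0 removes family structure.
    ``unknown_profile_weight`` is the truth-mixture weight of the
    environmental profile on every palm.
    """

    n_families: int = 8
    members_per_family: tuple[MemberSpec, ...] = DEFAULT_FAMILY
    n_taxa: int = 300
    site_pool_overlap: float = 0.2
    interpersonal_concentration: float = 50.0
    family_coefficient: float = 0.3
    depth: int = 1500
    unknown_profile_weight: float = 0.2
    truth_preset: str = "role_default"  # role_default | self_heavy | population
    clean_palm_hosts: int = 0  # first N hosts get pure-forehead (clean) palms
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.site_pool_overlap <= 1):
            raise ValueError("site_pool_overlap must be in [0,1]")
        if not (0 <= self.family_coefficient <= 1):
            raise ValueError("family_coefficient must be in [0,1]")
        if self.interpersonal_concentration <= 0:
            raise ValueError("interpersonal_concentration must be positive")
        if self.unknown_profile_weight < 0 or self.unknown_profile_weight >= 1:
            raise ValueError("unknown_profile_weight must be in [0,1)")
        if self.truth_preset not in ("role_default", "self_heavy", "population"):
            raise ValueError(f"unknown truth_preset {self.truth_preset!r}")
        n_env = max(6, round(0.1 * self.n_taxa))
        pool = int((self.n_taxa - n_env) // (3 - 2 * self.site_pool_overlap))
        if pool < 3:
            raise ValueError("n_taxa too small for three site pools")


@dataclass
class TruthRecord:
    """A palm's true mixing proportions over source sample IDs + 'unknown'."""

    palm_id: str
    mixture: dict[str, float]

    def __post_init__(self):
        s = sum(self.mixture.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"truth mixture sums to {s}")


@dataclass
class SyntheticCohort:
    """Generated table + metadata + truth, plus the latent per-sample
    profiles (over all taxa) used to draw reads."""

    table: OtuTable
    metadata: SampleMetadata
    truths: list[TruthRecord]
    profiles: dict[str, np.ndarray] = field(repr=False, default=None)
    unknown_profile: np.ndarray = field(repr=False, default=None)

    def __iter__(self):  # allows table, metadata, truths = generate_population(...)
        return iter((self.table, self.metadata, self.truths))


def default_spec(**overrides) -> PopulationSpec:
    """The standard cohort preset used throughout the tests."""
    return replace(PopulationSpec(), **overrides) if overrides else PopulationSpec()


def high_distinctness_spec(**overrides) -> PopulationSpec:
    """Highly distinct individuals (low Dirichlet concentration, little pool
    overlap) and a handful of clean forehead-only palms — the regime for
    spike-in validation."""
    spec = PopulationSpec(interpersonal_concentration=5.0, site_pool_overlap=0.1,
                          clean_palm_hosts=3)
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------

def _site_pools(spec: PopulationSpec) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Partition the taxon axis into three partially overlapping site pools
    and a disjoint environmental pool."""
    n_env = max(6, round(0.1 * spec.n_taxa))
    avail = spec.n_taxa - n_env
    pool = int(avail // (3 - 2 * spec.site_pool_overlap))
    shared = round(spec.site_pool_overlap * pool)
    excl = pool - shared
    idx = np.arange(spec.n_taxa)
    shared_taxa = idx[:shared]
    pools = {}
    start = shared
    for site in SOURCE_SITES:
        pools[site] = np.concatenate([shared_taxa, idx[start:start + excl]])
        start += excl
    env_taxa = idx[spec.n_taxa - n_env:]
    return pools, env_taxa


def _dirichlet_around(rng: np.random.Generator, mean: np.ndarray,
                      concentration: float) -> np.ndarray:
    # draw only on the mean's support so site pools stay disjoint from the
    # environmental taxa
    support = mean > 0
    out = np.zeros_like(mean)
    out[support] = rng.dirichlet(np.maximum(mean[support] * concentration,
                                            1e-6))
    return out


def generate_palm(owner: str, mixture: dict[str, float],
                  profiles: dict[str, np.ndarray], depth: int,
                  seed: int) -> np.ndarray:
    """Draw one palm sample: ``depth`` reads from the convex combination of
    the referenced source profiles ('unknown' keys must already be resolved
    to a profile under the key 'unknown')."""
    keys = list(mixture)
    missing = [k for k in keys if k not in profiles]
    if missing:
        raise KeyError(f"mixture references unknown profiles: {missing}")
    combo = np.zeros(len(next(iter(profiles.values()))))
    for k, w in mixture.items():
        combo += w * profiles[k]
    combo = combo / combo.sum()
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, combo).astype(np.int64)


def _resolve_truth_mixture(spec, rng, host, role, fam_hosts, all_site_samples):
    """Turn a (site, relation) preset into a mixture over sample IDs."""
    uw = spec.unknown_profile_weight
    mixture: dict[str, float] = {}
    if spec.truth_preset == "population":
        comps = POPULATION_SITE_WEIGHTS
        for site, w in comps.items():
            ids = all_site_samples[site]
            for sid in ids:
                mixture[sid] = mixture.get(sid, 0.0) + w * (1 - uw) / len(ids)
    else:
        comps = SELF_HEAVY_MIXTURE if spec.truth_preset == "self_heavy" \
            else ROLE_MIXTURES[role]
        others = [h for h in fam_hosts if h != host]
        for (site, rel), w in comps.items():
            if rel == "self" or not others:
                sid = f"{host}.{site}"
            else:
                sid = f"{rng.choice(others)}.{site}"
            mixture[sid] = mixture.get(sid, 0.0) + w * (1 - uw)
    if uw > 0:
        mixture["unknown"] = uw
    total = sum(mixture.values())
    return {k: v / total for k, v in mixture.items()}


def generate_population(spec: PopulationSpec) -> SyntheticCohort:
    """Generate a full cohort: one stool/tongue/forehead sample per member
    plus left/right palm samples with recorded truth mixtures.

    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pools, env_taxa = _site_pools(spec)

    # (1) site base profiles over their pools
    base = {}
    for site in SOURCE_SITES:
        p = np.zeros(spec.n_taxa)
        p[pools[site]] = rng.dirichlet(np.full(len(pools[site]), 0.8))
        base[site] = p

    unknown_profile = np.zeros(spec.n_taxa)
    unknown_profile[env_taxa] = rng.dirichlet(np.full(len(env_taxa), 0.8))

    profiles: dict[str, np.ndarray] = {"unknown": unknown_profile}
    rows = []  # metadata rows
    host_roles: dict[str, str] = {}
    families: list[list[str]] = []

    # (2)-(4): family and individual profiles, source samples
    for f in range(spec.n_families):
        fam_id = f"fam{f:02d}"
        has_dog = bool(rng.random() < 0.5)
        fam_hosts = []
        fam_profile = {site: _dirichlet_around(rng, base[site],
                                               spec.interpersonal_concentration)
                       for site in SOURCE_SITES}
        has_minor = any(m.role in ("infant", "child")
                        for m in spec.members_per_family)
        for k, member in enumerate(spec.members_per_family):
            host = f"{fam_id}.h{k}"
            fam_hosts.append(host)
            host_roles[host] = member.role
            lo, hi = ROLE_AGE_RANGES[member.role]
            age = float(rng.uniform(lo, hi))
            gender = ("female" if member.role == "adult_female"
                      else "male" if member.role == "adult_male"
                      else ("female" if rng.random() < 0.5 else "male"))
            is_parent = member.role.startswith("adult") and has_minor
            for site in SOURCE_SITES:
                mean = (spec.family_coefficient * fam_profile[site]
                        + (1 - spec.family_coefficient) * base[site])
                prof = _dirichlet_around(rng, mean,
                                         spec.interpersonal_concentration)
                sid = f"{host}.{site}"
                profiles[sid] = prof
                rows.append(dict(sample_id=sid, host_id=host, family_id=fam_id,
                                 body_site=site, hand_side=pd.NA,
                                 age_years=age, gender=gender,
                                 is_parent=is_parent, has_dog=has_dog))
            rows.append(dict(sample_id=None, host_id=host, family_id=fam_id,
                             body_site="palm", hand_side=None, age_years=age,
                             gender=gender, is_parent=is_parent,
                             has_dog=has_dog))  # placeholder expanded below
        families.append(fam_hosts)

    # expand palm placeholder rows into left/right entries
    palm_rows = []
    src_rows = []
    for r in rows:
        if r["body_site"] == "palm":
            for side in ("left", "right"):
                rr = dict(r)
                rr["sample_id"] = f"{r['host_id']}.palm.{side}"
                rr["hand_side"] = side
                palm_rows.append(rr)
        else:
            src_rows.append(r)

    all_site_samples = {site: [r["sample_id"] for r in src_rows
                               if r["body_site"] == site]
                        for site in SOURCE_SITES}

    # (5) palms from role-dependent truth mixtures + environmental component
    truths: list[TruthRecord] = []
    clean_hosts = set()
    if spec.clean_palm_hosts:
        hosts_in_order = [h for fam in families for h in fam]
        clean_hosts = set(hosts_in_order[:spec.clean_palm_hosts])

    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    for r in src_rows:
        sid = r["sample_id"]
        sample_ids.append(sid)
        columns.append(rng.multinomial(spec.depth, profiles[sid]))

    for r in palm_rows:
        host = r["host_id"]
        fam_hosts = next(f for f in families if host in f)
        if host in clean_hosts:
            uw = spec.unknown_profile_weight
            mixture = {f"{host}.forehead": 1 - uw}
            if uw > 0:
                mixture["unknown"] = uw
        else:
            mixture = _resolve_truth_mixture(spec, rng, host, host_roles[host],
                                             fam_hosts, all_site_samples)
        pid = r["sample_id"]
        counts = generate_palm(host, mixture, profiles, spec.depth,
                               seed=int(rng.integers(2**31 - 1)))
        sample_ids.append(pid)
        columns.append(counts)
        truths.append(TruthRecord(pid, mixture))

    taxon_ids = [f"OTU{i:04d}" for i in range(spec.n_taxa)]
    table = OtuTable(taxon_ids, sample_ids,
                     np.stack(columns, axis=1).astype(np.int64))
    meta_rows = src_rows + palm_rows
    frame = pd.DataFrame(meta_rows).set_index("sample_id")
    frame = frame.loc[sample_ids]
    metadata = SampleMetadata(frame)
    return SyntheticCohort(table, metadata, truths, profiles, unknown_profile)
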