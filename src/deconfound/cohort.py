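"""Synthetic repeated-measures multi-omics cohorts with a known
confounding graph.

The generator emulates a small hospital cohort: uninfected controls plus
patients with mild or severe disease, each sampled at several
timepoints, with clinical covariates (antibiotics, days hospitalized,
comorbidity burden) whose dependence on severity is controlled.  Feature
panels for four omics spaces (gut taxa, oropharyngeal taxa, plasma
metabolites, cytokines) are drawn around a latent Gaussian signal on
which effects are *planted*:

* ``direct``     -- the feature responds to the disease label itself;
* ``confounded`` -- the feature responds ONLY to a clinical covariate
                    that is itself coupled to severity;
* ``mediated``   -- the feature responds ONLY to the realized value of
                    an upstream feature (e.g. taxon -> metabolite);
* ``null``       -- pure noise.

Binary-driver effect sizes are specified on the Cliff's-delta scale and
calibrated through the closed-form relation for two equal-variance
normal groups, delta = 2*Phi(shift / (sqrt(2)*sigma)) - 1; continuous
and mediated effects are specified on the Spearman scale and calibrated
through rho_pearson = 2*sin(pi*rho_s/6).  Within-subject correlation
comes from a subject-level random intercept (SD = half the residual SD
by default).  The :class:`PlantedTruth` ledger records every plan so the
recovery of the downstream classification can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .random import substream
from .tables import FeatureTable

OMICS_SPACES = ("gut_taxa", "op_taxa", "metabolite", "cytokine")
EFFECT_CLASSES = ("null", "direct", "confounded", "mediated")
STATUS_LEVELS = ("control", "mild", "severe")

#: rarefaction target depths the taxa library sizes are drawn around
DEFAULT_DEPTHS = {"gut_taxa": 10_000, "op_taxa": 600}


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class CovariateSpec:
    """One clinical covariate and how strongly it tracks severity.

    ``strength`` in [-1, 1] controls the dependence on the disease
    group: for a binary covariate the prevalence moves from
    ``base*(1-strength)`` in controls through ``base`` in mild up to
    ``base + strength*(1-base)`` in severe; at strength 0 the covariate
    is independent of group.  Continuous covariates are Gaussian with a
    per-group location shift of ``strength*scale``.  ``zero_in_controls``
    forces the covariate to exactly zero for controls (antibiotics,
    hospitalization days).
    """

    name: str
    kind: str  # "binary" | "continuous"
    strength: float = 0.0
    base: float = 0.2
    scale: float = 1.0
    zero_in_controls: bool = False
    nonnegative: bool = False
    #: binary only: assign exactly round(p*n) positives per group instead of
    #: Bernoulli draws, pinning the covariate-severity coupling by design
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if not -1.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [-1, 1]")


def default_covariates() -> list[CovariateSpec]:
    """Clinical panel of the reference cohort: antibiotic use strongly
    enriched in severe disease, longer hospitalization and higher
    comorbidity burden with severity; controls antibiotic-free and never
    hospitalized."""
    return [
        CovariateSpec("antibiotics", "binary", strength=0.55, base=0.2,
                      zero_in_controls=True),
        CovariateSpec("hospital_days", "continuous", strength=0.7, base=9.0,
                      scale=7.0, zero_in_controls=True, nonnegative=True),
        CovariateSpec("comorbidity_index", "continuous", strength=0.35,
                      base=2.0, scale=1.8, nonnegative=True),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Sizes and design of one synthetic cohort."""

    n_controls: int = 15
    n_mild: int = 22
    n_severe: int = 8
    timepoints_per_subject: int = 2
    covariates: tuple[CovariateSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_mild", "n_severe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.timepoints_per_subject < 1:
            raise ValueError("timepoints_per_subject must be >= 1")
        if not self.covariates:
            object.__setattr__(self, "covariates", tuple(default_covariates()))
        else:
            covs = tuple(c if isinstance(c, CovariateSpec) else CovariateSpec(*c)
                         for c in self.covariates)
            object.__setattr__(self, "covariates", covs)


@dataclass(frozen=True)
class EffectPlan:
    """Ground-truth plan for one generated feature."""

    feature_id: str
    omics_space: str
    effect_class: str = "null"
    driver: str | None = None  # status label, covariate, or upstream feature
    target_effect_size: float = 0.0

    def __post_init__(self) -> None:
        if self.omics_space not in OMICS_SPACES:
            raise ValueError(f"unknown omics space {self.omics_space!r}")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if self.effect_class != "null" and self.driver is None:
            raise ValueError(f"{self.effect_class} effect needs a driver")
        if not -1.0 <= self.target_effect_size <= 1.0:
            raise ValueError("target effect size must lie in [-1, 1]")


@dataclass
class PlantedTruth:
    """Ledger of what was planted, for the recovery scorer."""

    plans: dict[str, EffectPlan]
    realized_correlations: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature_id": p.feature_id, "omics_space": p.omics_space,
                 "effect_class": p.effect_class, "driver": p.driver or "",
                 "target_effect_size": p.target_effect_size}
                for p in self.plans.values()]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metadata


def generate_metadata(spec: CohortSpec) -> pd.DataFrame:
    """One row per (subject, timepoint) with status and clinical covariates.

    Covariates are subject-level (constant across a subject's repeated
    samples).  Deterministic given ``spec.seed``.
    """
    rng = substream(spec.seed, "metadata")
    groups = (["control"] * spec.n_controls + ["mild"] * spec.n_mild
              + ["severe"] * spec.n_severe)
    widths = {"control": max(2, len(str(max(spec.n_controls, 1)))),
              "mild": max(2, len(str(max(spec.n_mild, 1)))),
              "severe": max(2, len(str(max(spec.n_severe, 1))))}
    prefix = {"control": "C", "mild": "M", "severe": "S"}
    counters = {g: 0 for g in STATUS_LEVELS}
    subjects, statuses = [], []
    for g in groups:
        counters[g] += 1
        subjects.append(f"{prefix[g]}{counters[g]:0{widths[g]}d}")
        statuses.append(g)
    n_subj = len(subjects)
    gcode = np.array([STATUS_LEVELS.index(s) for s in statuses])

    cov_values: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        s = cov.strength
        if cov.kind == "binary":
            p = np.empty(n_subj)
            p[gcode == 0] = min(1.0, max(0.0, cov.base * (1.0 - max(s, 0.0))))
            p[gcode == 1] = cov.base
            if s >= 0:
                p_sev = cov.base + s * (1.0 - cov.base)
            else:
                p_sev = cov.base * (1.0 + s)
            p[gcode == 2] = min(1.0, max(0.0, p_sev))
            if cov.exact_counts:
                vals = np.zeros(n_subj)
                for g in range(3):
                    idx = np.flatnonzero(gcode == g)
                    if idx.size:
                        k = int(round(p[idx[0]] * idx.size))
                        vals[rng.permutation(idx)[:k]] = 1.0
            else:
                vals = (rng.random(n_subj) < p).astype(float)
        else:
            loc = cov.base + s * cov.scale * (gcode - 1)
            vals = rng.normal(loc, cov.scale)
            if cov.nonnegative:
                vals = np.clip(vals, 0.0, None)
        if cov.zero_in_controls:
            vals[gcode == 0] = 0.0
        cov_values[cov.name] = vals

    rows = []
    for j in range(n_subj):
        for t in range(1, spec.timepoints_per_subject + 1):
            row = {"sample_id": f"{subjects[j]}_t{t}",
                   "subject_id": subjects[j],
                   "timepoint": t,
                   "status": statuses[j]}
            for name, vals in cov_values.items():
                row[name] = vals[j]
            rows.append(row)
    columns = (["sample_id", "subject_id", "timepoint", "status"]
               + [c.name for c in spec.covariates])
    meta = pd.DataFrame(rows, columns=columns)
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# feature generation


def _binary_shift(delta: float, sigma_total: float) -> float:
    """Location shift between two normal groups of common SD
    ``sigma_total`` that yields population Cliff's delta ``delta``."""
    if abs(delta) >= 1.0:
        return math.copysign(12.0 * sigma_total, delta)  # complete separation
    return math.sqrt(2.0) * sigma_total * float(ndtri((delta + 1.0) / 2.0))


def _spearman_loading(rho_s: float, sigma_total: float) -> float:
    """Loading ``a`` such that latent = a*z + noise(sigma_total) has
    Spearman correlation ``rho_s`` with the standard-normal score z."""
    if abs(rho_s) >= 1.0:
        return math.copysign(1e6, rho_s)
    rho = 2.0 * math.sin(math.pi * rho_s / 6.0)  # bivariate-normal inverse
    return rho * sigma_total / math.sqrt(1.0 - rho * rho)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (Blom) scores; ties share a score."""
    from scipy.stats import rankdata
    r = rankdata(x, method="average")
    return ndtri((r - 0.375) / (x.size + 0.25))


def _driver_vector(driver: str, metadata: pd.DataFrame,
                   realized: dict[str, np.ndarray]) -> tuple[np.ndarray, str]:
    """Resolve a driver name to a per-observation vector and its type."""
    status = metadata["status"].to_numpy()
    if driver == "status":
        return (status != "control").astype(float), "binary"
    if driver == "severity":
        return (status == "severe").astype(float), "binary"
    if driver in metadata.columns:
        vals = metadata[driver].to_numpy(dtype=float)
        kind = "binary" if set(np.unique(vals)) <= {0.0, 1.0} else "continuous"
        return vals, kind
    if driver in realized:
        return realized[driver], "feature"
    raise KeyError(f"driver {driver!r} is neither a label, covariate, "
                   "nor an already-generated feature")


def _toposort(plans: list[EffectPlan]) -> list[EffectPlan]:
    """Order plans so mediated features follow their upstream feature;
    raise on a cyclic mediation chain."""
    by_id = {p.feature_id: p for p in plans}
    order: list[EffectPlan] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(p: EffectPlan, stack: tuple[str, ...]) -> None:
        if state.get(p.feature_id) == 1:
            return
        if p.feature_id in stack:
            raise ValueError(f"cyclic mediation chain through {p.feature_id!r}")
        if p.effect_class == "mediated" and p.driver in by_id:
            visit(by_id[p.driver], stack + (p.feature_id,))
        if state.get(p.feature_id) != 1:
            state[p.feature_id] = 1
            order.append(p)

    for p in plans:
        visit(p, ())
    return order


def generate_features(metadata: pd.DataFrame,
                      plans: list[EffectPlan],
                      seed: int,
                      sigma_u: float = 0.5,
                      depths: dict[str, int] | None = None,
                      diversity_effects: dict[str, tuple[str, float]] | None = None,
                      low_depth_fraction: float = 0.05,
                      ) -> tuple[dict[str, FeatureTable], PlantedTruth]:
    """Draw one feature table per omics space according to ``plans``.

    Taxa spaces produce zero-inflated counts on a log-normal per-sample
    library size (around 5x the space's rarefaction depth); metabolite
    and cytokine panels are strictly positive log-normal, monotone in
    the latent signal so rank statistics see the planted effect exactly.
    ``diversity_effects`` optionally maps a taxa space to a
    ``(driver, strength)`` pair that modulates per-sample community
    evenness (and hence Shannon diversity): positive strength lowers the
    diversity of samples with high driver values.  Deterministic given
    ``seed``.
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    depths = {**DEFAULT_DEPTHS, **(depths or {})}
    diversity_effects = diversity_effects or {}
    n_obs = len(metadata)
    subjects = metadata["subject_id"].to_numpy()
    subj_ids, subj_inverse = np.unique(subjects, return_inverse=True)
    sigma_total = math.sqrt(1.0 + sigma_u ** 2)

    ids = [p.feature_id for p in plans]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature ids: {dupes}")
    ordered = _toposort(list(plans))

    latents: dict[str, np.ndarray] = {}
    by_space: dict[str, list[EffectPlan]] = {s: [] for s in OMICS_SPACES}
    rngs = {s: substream(seed, f"features:{s}") for s in OMICS_SPACES}
    for p in ordered:
        by_space[p.omics_space].append(p)
        rng = rngs[p.omics_space]
        u = rng.normal(0.0, sigma_u, size=len(subj_ids))[subj_inverse]
        eps = rng.normal(0.0, 1.0, size=n_obs)
        noise = u + eps
        if p.effect_class == "null":
            signal = np.zeros(n_obs)
        else:
            x, kind = _driver_vector(p.driver, metadata, latents)
            if kind == "binary":
                signal = _binary_shift(p.target_effect_size, sigma_total) * x
            else:
                z = _normal_scores(x) if kind == "continuous" else \
                    (x - x.mean()) / (x.std() or 1.0)
                signal = _spearman_loading(p.target_effect_size, sigma_total) * z
        latents[p.feature_id] = signal + noise

    tables: dict[str, FeatureTable] = {}
    extra_plans: list[EffectPlan] = []
    for space in OMICS_SPACES:
        sp_plans = by_space[space]
        if not sp_plans:
            continue
        rng = substream(seed, f"observe:{space}")
        feat_ids = [p.feature_id for p in sp_plans]
        lat = np.column_stack([latents[f] for f in feat_ids])
        if space in ("gut_taxa", "op_taxa"):
            tables[space], block_ids = _observe_taxa(
                lat, feat_ids, metadata, rng, space, depths[space],
                diversity_effects.get(space), low_depth_fraction, latents,
                effect_classes=[p.effect_class for p in sp_plans])
            if block_ids:
                driver = diversity_effects[space][0]
                cls = "direct" if driver in ("status", "severity") \
                    else "confounded"
                # structural diversity carriers: driver-responsive with an
                # unspecified per-feature magnitude (target recorded as 0)
                extra_plans += [EffectPlan(b, space, cls, driver, 0.0)
                                for b in block_ids]
        else:
            base = rng.normal(math.log(100.0), 1.0, size=len(feat_ids))
            values = np.exp(base[None, :] + 0.5 * lat)
            df = pd.DataFrame(values, index=metadata.index, columns=feat_ids)
            tables[space] = FeatureTable(df, space=space, state="concentration")

    truth = PlantedTruth({p.feature_id: p for p in ordered + extra_plans})
    sev = (metadata["status"] == "severe").astype(float)
    patients = metadata["status"] != "control"
    for cov in metadata.columns:
        if cov in ("subject_id", "timepoint", "status"):
            continue
        v = metadata.loc[patients, cov].astype(float)
        s = sev[patients]
        if v.std() > 0 and s.std() > 0:
            truth.realized_correlations[cov] = float(np.corrcoef(v, s)[0, 1])
    return tables, truth


def _observe_taxa(lat: np.ndarray, feat_ids: list[str], metadata: pd.DataFrame,
                  rng: np.random.Generator, space: str, depth: int,
                  diversity_effect: tuple[str, float] | None,
                  low_depth_fraction: float,
                  realized: dict[str, np.ndarray],
                  effect_classes: list[str] | None = None,
                  n_divblock: int = 12) -> tuple[FeatureTable, list[str]]:
    """Zero-inflated compositional counts from the latent signals.

    A diversity effect is carried by a dedicated *structural block* of
    ``n_divblock`` extra taxa holding a fixed half of each sample's
    mass: the driver modulates how evenly that mass is spread within
    the block (per-sample temperature on fixed random loadings), which
    moves Shannon entropy without touching the relative abundances of
    the planned features -- planted nulls stay null.
    """
    n_obs, n_feat = lat.shape
    mu = rng.normal(0.0, 1.5, size=n_feat)           # base log abundance
    pi = rng.uniform(0.1, 0.6, size=n_feat)          # structural-zero rate
    if effect_classes is not None:
        # effect-carrying taxa are prevalent ones (they must clear the
        # prevalence filter to be studied); nulls span the full spectrum
        planted = np.array([c != "null" for c in effect_classes])
        pi[planted] = rng.uniform(0.1, 0.25, size=int(planted.sum()))

    zero_mask = rng.random((n_obs, n_feat)) < pi[None, :]
    log_a = mu[None, :] + 0.8 * lat
    a = np.exp(log_a)
    a[zero_mask] = 0.0
    # guard: a fully zeroed sample keeps its most abundant latent feature
    dead = a.sum(axis=1) == 0
    if dead.any():
        top = np.argmax(log_a[dead], axis=1)
        a[np.flatnonzero(dead), top] = np.exp(log_a[dead, top])

    block_ids: list[str] = []
    if diversity_effect is not None:
        driver, strength = diversity_effect
        x, kind = _driver_vector(driver, metadata, realized)
        if kind != "binary":
            x = (x - x.mean()) / (x.std() or 1.0)
        temperature = np.exp(strength * x)           # >1 = more uneven
        # fixed, evenly spread loadings (normal quantiles) so the entropy
        # response to the temperature is stable across cohorts
        loadings = ndtri((np.arange(n_divblock) + 0.5) / n_divblock) * 1.2
        logw = temperature[:, None] * loadings[None, :] \
            + rng.normal(0.0, 0.6, size=(n_obs, n_divblock))
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        block = w * a.sum(axis=1, keepdims=True)     # half of sample mass
        a = np.concatenate([a, block], axis=1)
        block_ids = [f"{space}_divblock_{i:02d}" for i in range(n_divblock)]

    libsize = rng.lognormal(math.log(5.0 * depth), 0.35, size=n_obs)
    shallow = rng.random(n_obs) < low_depth_fraction
    libsize[shallow] = rng.uniform(0.1 * depth, 0.9 * depth,
                                   size=int(shallow.sum()))
    p = a / a.sum(axis=1, keepdims=True)
    counts = rng.poisson(libsize[:, None] * p)
    df = pd.DataFrame(counts, index=metadata.index,
                      columns=feat_ids + block_ids)
    table = FeatureTable(df, space=space, state="counts",
                         meta={"depth": depth, "divblock": block_ids})
    return table, block_ids


# ---------------------------------------------------------------------------
# default study design


def default_effect_plans(n_null_per_space: int = 30) -> list[EffectPlan]:
    """Reference planted design: direct severity effects in the gut and
    cytokine panels, antibiotic-confounded features in the oropharyngeal
    space, and one taxon -> metabolite -> cytokine mediation chain."""
    plans: list[EffectPlan] = []
    plans += [EffectPlan(f"gut_direct_{i}", "gut_taxa", "direct", "severity",
                         0.7) for i in range(4)]
    plans += [EffectPlan(f"gut_status_{i}", "gut_taxa", "direct", "status",
                         -0.6) for i in range(4)]
    plans += [EffectPlan(f"op_conf_{i}", "op_taxa", "confounded",
                         "antibiotics", 0.8) for i in range(5)]
    plans += [EffectPlan("met_mediator", "metabolite", "mediated",
                         "gut_direct_0", 0.75),
              EffectPlan("cyt_downstream", "cytokine", "mediated",
                         "met_mediator", 0.75)]
    plans += [EffectPlan(f"met_direct_{i}", "metabolite", "direct",
                         "severity", 0.8 if i % 2 == 0 else -0.8)
              for i in range(4)]
    plans += [EffectPlan(f"cyt_direct_{i}", "cytokine", "direct", "severity",
                         0.75) for i in range(2)]
    plans += [EffectPlan(f"met_hosp_{i}", "metabolite", "confounded",
                         "hospital_days", 0.5) for i in range(2)]
    for space, stem in (("gut_taxa", "gut_null"), ("op_taxa", "op_null"),
                        ("metabolite", "met_null"), ("cytokine", "cyt_null")):
        n = n_null_per_space if space != "cytokine" else max(5, n_null_per_space // 3)
        plans += [EffectPlan(f"{stem}_{i}", space) for i in range(n)]
    return plans


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryReport:
    sensitivity: float                 # robust fraction of direct features
    confounder_detection_rate: float   # confounded features naming true driver
    false_robust_rate: float           # null features classified robust
    confusion: pd.DataFrame            # effect_class x status counts

    def to_dict(self) -> dict:
        return {"sensitivity": self.sensitivity,
                "confounder_detection_rate": self.confounder_detection_rate,
                "false_robust_rate": self.false_robust_rate}


def _status_class(status: str) -> str:
    if status == "D":
        return "robust"
    if status.startswith("confounded"):
        return "confounded"
    return status  # "ambiguous" | "NS"


def evaluate_recovery(truth: PlantedTruth, records: pd.DataFrame,
                      contrast_label: str = "severity") -> RecoveryReport:
    """Score final association records against the planted ground truth.

    Only records whose independent variable is ``contrast_label`` are
    scored.  Undefined rates (e.g. sensitivity with no direct features)
    are reported as NaN.
    """
    rec = records[records["X_ind.var"] == contrast_label]
    unknown = set(rec["Y_dep.var"]) - set(truth.plans)
    if unknown:
        raise KeyError(f"records reference features absent from the truth "
                       f"ledger: {sorted(unknown)[:5]}")
    status_by_feat = dict(zip(rec["Y_dep.var"], rec["AssocStatus"]))

    counts: dict[tuple[str, str], int] = {}
    robust_direct = n_direct = 0
    named = n_confounded = 0
    false_robust = n_null = 0
    for fid, plan in truth.plans.items():
        status = status_by_feat.get(fid, "NS")
        cls = _status_class(status)
        counts[(plan.effect_class, cls)] = counts.get((plan.effect_class, cls), 0) + 1
        # features with target 0 (structural diversity carriers) have an
        # unspecified magnitude and are excluded from the rates
        if (plan.effect_class == "direct" and plan.driver == contrast_label
                and plan.target_effect_size != 0):
            n_direct += 1
            robust_direct += cls == "robust"
        elif plan.effect_class == "confounded" and plan.target_effect_size != 0:
            n_confounded += 1
            named += cls == "confounded" and plan.driver in status
        elif plan.effect_class == "null":
            n_null += 1
            false_robust += cls == "robust"

    confusion = pd.Series(counts).unstack(fill_value=0) if counts \
        else pd.DataFrame()
    return RecoveryReport(
        sensitivity=robust_direct / n_direct if n_direct else float("nan"),
        confounder_detection_rate=named / n_confounded if n_confounded
        else float("nan"),
        false_robust_rate=false_robust / n_null if n_null else 0.0,
        confusion=confusion,
    )
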