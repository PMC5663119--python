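"""Synthetic paired expression studies with planted mixture structure.

Each feature's tumor-normal difference (on the log2(1+x) scale) is drawn
from a four-component mixture: an exact-zero point mass (non-expression in
both tissues), a continuous null spread around zero, and negative and
positive effect modes.  A designated "driver" factor may switch the
mixture weights between its levels; mode locations are shared, only the
masses shift.  Factor levels are drawn first and then masked missing at a
per-factor rate; per-sample multiplicative scale factors exercise the
normalization step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dysregdir.classify import Color, Label, color_for
from dysregdir.core import DEFAULT_SITES, PairedExpressionStudy

__all__ = [
    "MixtureSpec",
    "FactorSpec",
    "FeaturePlan",
    "Scenario",
    "SyntheticTruth",
    "generate_study",
    "default_scenarios",
]

#: |pi_down - pi_up| at or below this margin implies a "no direction" level
IMPLIED_NS_MARGIN = 0.05


@dataclass(frozen=True)
class MixtureSpec:
    """Mixture weights and shape parameters of a difference distribution."""

    pi_zero: float
    pi_null: float
    pi_down: float
    pi_up: float
    mu: float = 2.0
    sigma_null: float = 0.5
    sigma_mode: float = 0.5

    def __post_init__(self) -> None:
        w = (self.pi_zero, self.pi_null, self.pi_down, self.pi_up)
        if any(x < 0 for x in w):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1 (got {sum(w)})")
        if self.mu <= 0 or self.sigma_null <= 0 or self.sigma_mode <= 0:
            raise ValueError("mu and sigmas must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.pi_zero, self.pi_null, self.pi_down, self.pi_up])

    def implied_label(self, margin: float = IMPLIED_NS_MARGIN) -> Label:
        """Direction implied by the weight imbalance of the effect modes."""
        delta = self.pi_down - self.pi_up
        if delta > margin:
            return Label.DOWN
        if delta < -margin:
            return Label.UP
        return Label.NS

    def pooled(self, other: "MixtureSpec", w_self: float, w_other: float) -> "MixtureSpec":
        """Weight-average of two specs (shared mode locations)."""
        tot = w_self + w_other
        a, b = w_self / tot, w_other / tot
        return MixtureSpec(
            pi_zero=a * self.pi_zero + b * other.pi_zero,
            pi_null=a * self.pi_null + b * other.pi_null,
            pi_down=a * self.pi_down + b * other.pi_down,
            pi_up=a * self.pi_up + b * other.pi_up,
            mu=self.mu, sigma_null=self.sigma_null, sigma_mode=self.sigma_mode,
        )


@dataclass(frozen=True)
class FactorSpec:
    """A binary subject factor: prevalence of level 1 and missingness."""

    name: str
    p_level1: float = 0.5
    missing_rate: float = 0.1
    #: draw exactly round(p_level1 * n) level-1 subjects per site (a
    #: randomized-block design) instead of independent Bernoulli draws
    balanced: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_level1 < 1.0):
            raise ValueError("p_level1 must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class FeaturePlan:
    """Mixture specs for one feature at the two driver-factor levels.

    With ``driver=None`` the feature ignores all factors and uses ``spec0``
    for every subject.
    """

    spec0: MixtureSpec
    spec1: MixtureSpec | None = None
    driver: str | None = None
    #: overrides the scenario-wide baseline; keeping dysregulated features
    #: below the per-sample 75th percentile avoids perturbing the scale
    #: normalization of the (mostly null) panel
    baseline_log2_mean: float | None = None

    def __post_init__(self) -> None:
        if (self.driver is None) != (self.spec1 is None):
            raise ValueError("spec1 must be given exactly when driver is set")


@dataclass
class Scenario:
    """A named truth assignment for study generation."""

    name: str
    factors: list[FactorSpec]
    features: dict[str, FeaturePlan]
    n_subjects_per_site: dict[str, int]
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    scale_sd: float = 0.15  # log-sd of per-sample true scale factors; 0 disables
    #: color the pipeline is expected to assign to driver-driven features.
    #: For weight-driven colors this equals the implied color; for purple it
    #: is produced by subsetting (power loss), not by the weights.
    expected_color: str | None = None


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated study."""

    scenario: str
    plans: dict[str, FeaturePlan]
    factor_specs: dict[str, FactorSpec]
    true_levels: pd.DataFrame  # subjects x factors, pre-masking, 0/1
    sample_scale: pd.DataFrame  # sample name -> true scale factor
    implied: pd.DataFrame  # feature -> implied labels and color
    expected_color: str | None = None

    def planted_features(self) -> list[str]:
        """Features with a driver factor (carriers of the planted pattern)."""
        return [f for f, plan in self.plans.items() if plan.driver is not None]

    def write(self, path, sep: str = "\t") -> None:
        self.implied.to_csv(path, sep=sep)


def _implied_frame(plans: dict[str, FeaturePlan],
                   factors: dict[str, FactorSpec]) -> pd.DataFrame:
    rows = {}
    for name, plan in plans.items():
        if plan.driver is None:
            lab = plan.spec0.implied_label()
            rows[name] = {
                "driver": "", "overall": lab.value,
                "level0": lab.value, "level1": lab.value,
                "color": Color.NONE.value,
            }
        else:
            p1 = factors[plan.driver].p_level1
            overall = plan.spec0.pooled(plan.spec1, 1.0 - p1, p1).implied_label()
            l0 = plan.spec0.implied_label()
            l1 = plan.spec1.implied_label()
            rows[name] = {
                "driver": plan.driver, "overall": overall.value,
                "level0": l0.value, "level1": l1.value,
                "color": color_for(overall, l0, l1).value,
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "feature"
    return df


def generate_study(scenario: Scenario, seed: int = 0) -> tuple[PairedExpressionStudy, SyntheticTruth]:
    """Generate a paired study and its ground truth from a scenario.

    Reproducible given ``seed``.  The tumor signal is constructed so that
    the log2(1+x) tumor-normal difference equals the sampled mixture draw
    before per-sample scaling is applied.
    """
    rng = np.random.default_rng(seed)
    sites: list[str] = []
    subjects: list[str] = []
    for site, n in scenario.n_subjects_per_site.items():
        if n <= 0:
            raise ValueError(f"non-positive subject count for site {site!r}")
        for k in range(n):
            subjects.append(f"{site[:3]}{k:04d}")
            sites.append(site)
    n_subj = len(subjects)
    feature_names = list(scenario.features)
    n_feat = len(feature_names)

    factor_specs = {f.name: f for f in scenario.factors}
    site_arr = np.array(sites, dtype=object)
    levels = {}
    for f in scenario.factors:
        if f.balanced:
            col = np.zeros(n_subj)
            for site in scenario.n_subjects_per_site:
                idx = np.flatnonzero(site_arr == site)
                k = int(round(f.p_level1 * idx.size))
                col[rng.permutation(idx)[:k]] = 1.0
            levels[f.name] = col
        else:
            levels[f.name] = rng.binomial(1, f.p_level1, n_subj).astype(float)
    true_levels = pd.DataFrame(levels, index=subjects, dtype=float)
    observed = true_levels.copy()
    for f in scenario.factors:
        mask = rng.random(n_subj) < f.missing_rate
        observed.loc[mask, f.name] = np.nan

    tumor = np.empty((n_feat, n_subj))
    normal = np.empty((n_feat, n_subj))
    for i, name in enumerate(feature_names):
        plan = scenario.features[name]
        if plan.driver is None:
            w = np.tile(plan.spec0.weights, (n_subj, 1))
            spec = plan.spec0
        else:
            lev = true_levels[plan.driver].to_numpy()
            w = np.where(lev[:, None] == 1.0, plan.spec1.weights, plan.spec0.weights)
            spec = plan.spec0  # mode locations shared between levels
        u = rng.random(n_subj)
        comp = (u[:, None] >= np.cumsum(w, axis=1)).sum(axis=1)  # 0:zero 1:null 2:down 3:up
        d = np.zeros(n_subj)
        d[comp == 1] = rng.normal(0.0, spec.sigma_null, (comp == 1).sum())
        d[comp == 2] = rng.normal(-spec.mu, spec.sigma_mode, (comp == 2).sum())
        d[comp == 3] = rng.normal(spec.mu, spec.sigma_mode, (comp == 3).sum())
        base_mean = (plan.baseline_log2_mean if plan.baseline_log2_mean is not None
                     else scenario.baseline_log2_mean)
        base = np.clip(
            rng.normal(base_mean, scenario.baseline_log2_sd, n_subj),
            0.0, None,
        )
        # split the difference symmetrically so tumor and normal columns
        # have identical marginal spread (keeps per-sample 75th percentiles
        # exchangeable, which the scale normalization relies on)
        tumor_t = np.clip(base + d / 2.0, 0.0, None)
        normal_t = np.clip(base - d / 2.0, 0.0, None)
        tumor[i] = np.exp2(tumor_t) - 1.0
        normal[i] = np.exp2(normal_t) - 1.0
        zero = comp == 0
        tumor[i, zero] = 0.0
        normal[i, zero] = 0.0

    if scenario.scale_sd > 0:
        scale_t = np.exp(rng.normal(0.0, scenario.scale_sd, n_subj))
        scale_n = np.exp(rng.normal(0.0, scenario.scale_sd, n_subj))
    else:
        scale_t = np.ones(n_subj)
        scale_n = np.ones(n_subj)
    tumor *= scale_t[None, :]
    normal *= scale_n[None, :]

    study = PairedExpressionStudy(
        features=feature_names,
        subjects=subjects,
        tumor_signal=tumor,
        normal_signal=normal,
        site=np.array(sites, dtype=object),
        factors=observed,
        allowed_sites=None,
    )
    sample_scale = pd.DataFrame(
        {
            "sample": [f"{s}_T" for s in subjects] + [f"{s}_N" for s in subjects],
            "scale": np.concatenate([scale_t, scale_n]),
        }
    ).set_index("sample")
    truth = SyntheticTruth(
        scenario=scenario.name,
        plans=dict(scenario.features),
        factor_specs=factor_specs,
        true_levels=true_levels,
        sample_scale=sample_scale,
        implied=_implied_frame(scenario.features, factor_specs),
        expected_color=scenario.expected_color,
    )
    return study, truth


# ---------------------------------------------------------------------------
# Default scenarios


def _spec(z: float, nul: float, down: float, up: float, **kw) -> MixtureSpec:
    return MixtureSpec(pi_zero=z, pi_null=nul, pi_down=down, pi_up=up, **kw)


NULL_SPEC = _spec(0.10, 0.90, 0.0, 0.0)
BALANCED_SPEC = _spec(0.10, 0.20, 0.35, 0.35)


def default_scenarios(
    n_subjects_per_site: int = 500,
    sites: tuple[str, ...] = DEFAULT_SITES,
    n_planted: int = 8,
    n_balanced: int = 24,
    n_null: int = 600,
    missing_rate: float = 0.1,
    scale_sd: float = 0.15,
    dys_baseline: float = 5.5,
) -> dict[str, Scenario]:
    """Named truth assignments: one scenario per color plus two null designs.

    ``null`` is fully unimodal (for screen FWER assessment); ``balanced``
    is symmetrically bimodal with no direction (for directional-FDR
    assessment).  Each color scenario also carries balanced and unimodal
    null features so adjustment families are realistically diluted.
    """
    sizes = {s: n_subjects_per_site for s in sites}

    def factors(missing: float, p_driver: float = 0.5) -> list[FactorSpec]:
        return [
            FactorSpec("DRIVER", p_driver, missing, balanced=True),
            FactorSpec("NOISE1", 0.5, missing),
            FactorSpec("NOISE2", 0.3, missing),
        ]

    def background(n_bal: int, n_nul: int) -> dict[str, FeaturePlan]:
        feats: dict[str, FeaturePlan] = {}
        for i in range(n_bal):
            feats[f"bal{i:03d}"] = FeaturePlan(spec0=BALANCED_SPEC,
                                               baseline_log2_mean=dys_baseline)
        for i in range(n_nul):
            feats[f"null{i:03d}"] = FeaturePlan(spec0=NULL_SPEC)
        return feats

    def planted(spec0: MixtureSpec, spec1: MixtureSpec) -> dict[str, FeaturePlan]:
        return {
            f"plant{i:03d}": FeaturePlan(spec0=spec0, spec1=spec1, driver="DRIVER",
                                         baseline_log2_mean=dys_baseline)
            for i in range(n_planted)
        }

    scenarios: dict[str, Scenario] = {}
    scenarios["null"] = Scenario(
        name="null", factors=factors(missing_rate),
        features={f"null{i:03d}": FeaturePlan(spec0=NULL_SPEC) for i in range(n_null)},
        n_subjects_per_site=dict(sizes), scale_sd=scale_sd,
    )
    scenarios["balanced"] = Scenario(
        name="balanced", factors=factors(missing_rate),
        features={f"bal{i:03d}": FeaturePlan(spec0=BALANCED_SPEC) for i in range(n_balanced)},
        n_subjects_per_site=dict(sizes), scale_sd=scale_sd,
    )

    # blue: effect confined to level 0, level 1 directionless
    scenarios["blue"] = Scenario(
        name="blue", expected_color="blue", factors=factors(missing_rate),
        features={**planted(_spec(0.10, 0.15, 0.70, 0.05), BALANCED_SPEC),
                  **background(n_balanced, n_null)},
        n_subjects_per_site=dict(sizes), scale_sd=scale_sd,
    )
    # green: rare level 1 with a strong effect, level 0 leaning just enough
    # the other way that the pooled margin vanishes
    p1 = 0.04
    d1, u1 = 0.85, 0.0
    lean = p1 * (d1 - u1) / (1.0 - p1)  # pooled cancellation
    scenarios["green"] = Scenario(
        name="green", expected_color="green", factors=factors(missing_rate, p_driver=p1),
        features={**planted(
            _spec(0.10, 0.20, round(0.35 - lean / 2, 6), round(0.35 + lean / 2, 6)),
            _spec(0.05, 0.10, d1, u1)),
            **background(n_balanced, n_null)},
        n_subjects_per_site=dict(sizes), scale_sd=scale_sd,
    )
    # orange: mirrored strong effects cancelling exactly overall
    scenarios["orange"] = Scenario(
        name="orange", expected_color="orange", factors=factors(missing_rate),
        features={**planted(_spec(0.10, 0.20, 0.55, 0.15), _spec(0.10, 0.20, 0.15, 0.55)),
                  **background(n_balanced, n_null)},
        n_subjects_per_site=dict(sizes), scale_sd=scale_sd,
    )
    # purple: modest overall effect; heavy missingness starves both level
    # tests of subjects (the "subsetting" mechanism)
    scenarios["purple"] = Scenario(
        name="purple", expected_color="purple", factors=factors(0.9),
        features={**planted(_spec(0.10, 0.20, 0.44, 0.26), _spec(0.10, 0.20, 0.44, 0.26)),
                  **background(n_balanced, n_null)},
        n_subjects_per_site=dict(sizes), scale_sd=scale_sd,
    )
    # yellow: up-dominant at level 0, down-dominant at level 1, pooled
    # margin still up
    scenarios["yellow"] = Scenario(
        name="yellow", expected_color="yellow", factors=factors(missing_rate, p_driver=0.3),
        features={**planted(_spec(0.10, 0.15, 0.05, 0.70), _spec(0.10, 0.15, 0.70, 0.05)),
                  **background(n_balanced, n_null)},
        n_subjects_per_site=dict(sizes), scale_sd=scale_sd,
    )
    return scenarios
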