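"""Per-site orchestration: screen -> tests -> adjustment -> classification.

For each site, the pipeline computes tumor-normal differences, screens
features for multimodality, runs the overall signed-rank test on every
selected feature, and (for every factor whose two levels both reach the
minimum sample size among non-missing subjects at the site) the
within-level tests.  One-sided FDR adjustment is applied per site and per
test arm (overall / level 0 / level 1), labels and colors are assigned,
and results are exported as a flat CSV plus cross-tabulations.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from dysregdir.classify import (
    Color,
    ColorCrosstab,
    Label,
    Thresholds,
    classify_outcome,
    color_for,
    crosstab_colors,
)
from dysregdir.core import (
    PairedExpressionStudy,
    compute_differences,
    expression_filter,
)
from dysregdir.dip import MultimodalScreen, screen_multimodal
from dysregdir.multiplicity import adjust_one_sided
from dysregdir.normalization import ScaleFactors, scale_normalize
from dysregdir.signed_rank import NotTestableError, signed_rank, test_subset

logger = logging.getLogger("dysregdir")

__all__ = [
    "RunConfig",
    "OutcomeRecord",
    "StudyResults",
    "normalize_study",
    "run_site",
    "run_study",
    "write_results",
    "read_results",
    "plot_triptych",
]


@dataclass
class RunConfig:
    """All tunables of a pipeline run; persisted verbatim into the output."""

    transform: str = "log2p1"
    normalize: bool = True
    min_nonzero_fraction: float = 0.0
    dip_B: int = 10000
    seed: int = 0
    fwer_alpha: float = 0.05
    fdr_alpha: float = 0.05
    band: float = 0.15
    min_n: int = 10
    exact_cutoff: int = 20
    continuity_correction: bool = True
    family_mode: str = "pooled"  # or "per_factor"

    def __post_init__(self) -> None:
        if self.family_mode not in ("pooled", "per_factor"):
            raise ValueError("family_mode must be 'pooled' or 'per_factor'")
        if not (0.0 < self.fwer_alpha < 1.0):
            raise ValueError("fwer_alpha must be in (0, 1)")
        self.thresholds = Thresholds(alpha=self.fdr_alpha, band=self.band)
        if not (0.0 <= self.min_nonzero_fraction <= 1.0):
            raise ValueError("min_nonzero_fraction must be in [0, 1]")
        if self.min_n < 1 or self.dip_B < 1 or self.exact_cutoff < 0:
            raise ValueError("min_n, dip_B must be >= 1 and exact_cutoff >= 0")

    def to_yaml(self, path=None) -> str:
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        if hasattr(path_or_text, "read"):
            payload = yaml.safe_load(path_or_text)
        else:
            try:
                with open(path_or_text) as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, TypeError):
                payload = yaml.safe_load(str(path_or_text))
        payload = payload or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class OutcomeRecord:
    """One (site, factor, feature) outcome row."""

    site: str
    factor: str
    feature: str
    n_overall: int
    n_eff_overall: int
    p_overall_adj: float
    label_overall: Label
    n_level0: int
    n_eff_level0: int
    p_level0_adj: float
    label_level0: Label
    n_level1: int
    n_eff_level1: int
    p_level1_adj: float
    label_level1: Label
    color: Color


@dataclass
class StudyResults:
    """Concatenated per-site records plus screens, cross-tabs and config."""

    records: list[OutcomeRecord]
    screens: dict[str, MultimodalScreen]
    config: RunConfig
    scale_factors: ScaleFactors | None = None

    def records_frame(self) -> pd.DataFrame:
        return _records_to_frame(self.records)

    def screened_counts(self) -> dict[str, int]:
        return {site: len(s.selected) for site, s in self.screens.items()}

    def crosstab(self, site: str | None = None) -> ColorCrosstab:
        recs = self.records if site is None else [r for r in self.records if r.site == site]
        return crosstab_colors(
            (r.label_overall, r.label_level0, r.label_level1) for r in recs
        )

    def color_totals(self) -> dict[Color, int]:
        return self.crosstab().color_totals()


def normalize_study(study: PairedExpressionStudy) -> tuple[PairedExpressionStudy, ScaleFactors]:
    """Scale-normalize tumor and normal signal with a pooled sample set."""
    names = [f"{s}_T" for s in study.subjects] + [f"{s}_N" for s in study.subjects]
    pooled = np.hstack([study.tumor_signal, study.normal_signal])
    normalized, sf = scale_normalize(pooled, sample_names=names)
    ns = study.n_subjects
    return study.with_signals(normalized[:, :ns], normalized[:, ns:]), sf


def _level_masks(study: PairedExpressionStudy, site_mask: np.ndarray, factor: str):
    """Masks (relative to the site's subjects) for factor levels 0 and 1."""
    vals = study.factors[factor].to_numpy(dtype=float)[site_mask]
    return vals == 0.0, vals == 1.0


def run_site(study: PairedExpressionStudy, site: str,
             config: RunConfig | None = None) -> list[OutcomeRecord]:
    """Run the full analysis for one site; see the module docstring."""
    config = config or RunConfig()
    if not study.subjects_at(site).any():
        raise ValueError(f"site {site!r} absent from study")
    if config.normalize:
        study, _ = normalize_study(study)
    records, _screen = _run_site_prepared(study, site, config)
    return records


def _run_site_prepared(
    study: PairedExpressionStudy, site: str, config: RunConfig
) -> tuple[list[OutcomeRecord], MultimodalScreen]:
    keep = expression_filter(study, config.min_nonzero_fraction)
    dropped = study.n_features - len(keep)
    if dropped:
        logger.info(
            "%s: expression filter (min nonzero fraction %.3g) dropped %d of %d features",
            site, config.min_nonzero_fraction, dropped, study.n_features,
        )
    diffs = compute_differences(study, site, transform=config.transform)
    keep_idx = [i for i, f in enumerate(diffs.features) if f in set(keep)]
    diffs.features = [diffs.features[i] for i in keep_idx]
    diffs.diffs = diffs.diffs[keep_idx]

    screen = screen_multimodal(diffs, B=config.dip_B, alpha=config.fwer_alpha,
                               seed=config.seed)
    selected = screen.selected
    logger.info("%s: %d of %d features pass the multimodality screen",
                site, len(selected), len(diffs.features))
    if not selected:
        return [], screen
    feat_index = {f: i for i, f in enumerate(diffs.features)}
    site_mask = study.subjects_at(site)
    n_site = int(site_mask.sum())

    # -- overall arm: one test per selected feature --------------------------
    overall_raw: dict[str, object] = {}
    for f in selected:
        try:
            overall_raw[f] = signed_rank(
                diffs.diffs[feat_index[f]],
                exact_cutoff=config.exact_cutoff,
                continuity_correction=config.continuity_correction,
            )
        except NotTestableError:
            logger.info("%s/%s: overall test skipped (all differences zero)", site, f)
            overall_raw[f] = None
    tested = [f for f in selected if overall_raw[f] is not None]
    overall_adj: dict[str, object] = {}
    if tested:
        adj = adjust_one_sided(
            [(overall_raw[f].p_less, overall_raw[f].p_greater) for f in tested],
            family_id=f"{site}/overall",
        )
        overall_adj = dict(zip(tested, adj))

    # -- level arms ----------------------------------------------------------
    level_raw: dict[int, dict[tuple[str, str], object]] = {0: {}, 1: {}}
    level_n: dict[str, tuple[int, int]] = {}
    skipped_minn: set[str] = set()
    for factor in study.factor_names:
        m0, m1 = _level_masks(study, site_mask, factor)
        n0, n1 = int(m0.sum()), int(m1.sum())
        level_n[factor] = (n0, n1)
        if min(n0, n1) < config.min_n:
            skipped_minn.add(factor)
            logger.info("%s/%s: level tests skipped (level sizes %d/%d < min_n=%d)",
                        site, factor, n0, n1, config.min_n)
            continue
        for lev, mask in ((0, m0), (1, m1)):
            for f in selected:
                try:
                    level_raw[lev][(factor, f)] = test_subset(
                        diffs.diffs[feat_index[f]], mask,
                        exact_cutoff=config.exact_cutoff,
                        continuity_correction=config.continuity_correction,
                    )
                except NotTestableError:
                    logger.info("%s/%s/%s level %d: skipped (no nonzero differences)",
                                site, factor, f, lev)
                    level_raw[lev][(factor, f)] = None

    level_adj: dict[int, dict[tuple[str, str], object]] = {0: {}, 1: {}}
    for lev in (0, 1):
        entries = level_raw[lev]
        if config.family_mode == "pooled":
            keys = [k for k, r in entries.items() if r is not None]
            if keys:
                adj = adjust_one_sided(
                    [(entries[k].p_less, entries[k].p_greater) for k in keys],
                    family_id=f"{site}/level{lev}",
                )
                level_adj[lev] = dict(zip(keys, adj))
        else:  # per-factor families
            for factor in study.factor_names:
                keys = [k for k, r in entries.items()
                        if k[0] == factor and r is not None]
                if keys:
                    adj = adjust_one_sided(
                        [(entries[k].p_less, entries[k].p_greater) for k in keys],
                        family_id=f"{site}/level{lev}/{factor}",
                    )
                    level_adj[lev].update(dict(zip(keys, adj)))

    # -- assemble records ----------------------------------------------------
    records: list[OutcomeRecord] = []
    for factor in study.factor_names:
        n0, n1 = level_n[factor]
        for f in selected:
            raw_o = overall_raw[f]
            if raw_o is None:
                lab_o, p_o, neff_o = Label.NT, np.nan, 0
            else:
                one = overall_adj[f]
                lab_o = classify_outcome(one.p_one_adj, config.thresholds)
                p_o, neff_o = one.p_one_adj, raw_o.n_effective

            per_level = []
            for lev, n_lev in ((0, n0), (1, n1)):
                raw_l = level_raw[lev].get((factor, f))
                if factor in skipped_minn or raw_l is None:
                    per_level.append((Label.NT, np.nan, 0))
                else:
                    one = level_adj[lev][(factor, f)]
                    per_level.append(
                        (classify_outcome(one.p_one_adj, config.thresholds),
                         one.p_one_adj, raw_l.n_effective)
                    )
            (lab0, p0, neff0), (lab1, p1, neff1) = per_level
            color = color_for(lab_o, lab0, lab1)
            if (lab_o in (Label.DOWN, Label.UP) and {lab0, lab1} ==
                    {Label.NS, Label.DOWN if lab_o is Label.UP else Label.UP}):
                logger.info("%s/%s/%s: unnamed triple (%s, %s, %s) -> none",
                            site, factor, f, lab_o, lab0, lab1)
            records.append(OutcomeRecord(
                site=site, factor=factor, feature=f,
                n_overall=n_site, n_eff_overall=neff_o,
                p_overall_adj=p_o, label_overall=lab_o,
                n_level0=n0, n_eff_level0=neff0, p_level0_adj=p0, label_level0=lab0,
                n_level1=n1, n_eff_level1=neff1, p_level1_adj=p1, label_level1=lab1,
                color=color,
            ))
    return records, screen


def run_study(study: PairedExpressionStudy, config: RunConfig | None = None,
              sites: list[str] | None = None) -> StudyResults:
    """Run every site of a study and collect records, screens and cross-tabs."""
    config = config or RunConfig()
    if sites is None:
        seen = set()
        sites = [s for s in study.site if not (s in seen or seen.add(s))]
    sf = None
    if config.normalize:
        study, sf = normalize_study(study)
    records: list[OutcomeRecord] = []
    screens: dict[str, MultimodalScreen] = {}
    for site in sites:
        site_records, screens[site] = _run_site_prepared(study, site, config)
        records.extend(site_records)
    return StudyResults(records=records, screens=screens, config=config,
                        scale_factors=sf)


# ---------------------------------------------------------------------------
# Results I/O

_RESULT_COLUMNS = [
    "site", "factor", "feature",
    "n_overall", "n_eff_overall", "p_overall_adj", "label_overall",
    "n_level0", "n_eff_level0", "p_level0_adj", "label_level0",
    "n_level1", "n_eff_level1", "p_level1_adj", "label_level1",
    "color",
]


def _records_to_frame(records: list[OutcomeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["label_overall"] = r.label_overall.value
        d["label_level0"] = r.label_level0.value
        d["label_level1"] = r.label_level1.value
        d["color"] = r.color.value
        rows.append(d)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(records: list[OutcomeRecord], path, colors_only: bool = False) -> None:
    """Write outcome records as CSV (stable column order, lossless)."""
    if colors_only:
        records = [r for r in records if r.color is not Color.NONE]
    _records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> list[OutcomeRecord]:
    """Re-read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={"site": str, "factor": str, "feature": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(OutcomeRecord(
            site=row.site, factor=row.factor, feature=row.feature,
            n_overall=int(row.n_overall), n_eff_overall=int(row.n_eff_overall),
            p_overall_adj=float(row.p_overall_adj),
            label_overall=Label(row.label_overall),
            n_level0=int(row.n_level0), n_eff_level0=int(row.n_eff_level0),
            p_level0_adj=float(row.p_level0_adj), label_level0=Label(row.label_level0),
            n_level1=int(row.n_level1), n_eff_level1=int(row.n_eff_level1),
            p_level1_adj=float(row.p_level1_adj), label_level1=Label(row.label_level1),
            color=Color(row.color),
        ))
    return records


def plot_triptych(diffs_overall, diffs_level0, diffs_level1, titles, path,
                  bins: int = 40) -> list[np.ndarray]:
    """Three-panel histogram (overall / level 0 / level 1) of differences.

    ``titles`` is a sequence of three title strings (typically feature,
    sample size and adjusted p per panel).  Empty panels are annotated as
    not tested.  Returns the per-panel histogram bin counts (shared bin
    edges across panels).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [np.asarray(d, dtype=float).ravel() if d is not None else np.array([])
              for d in (diffs_overall, diffs_level0, diffs_level1)]
    finite = np.concatenate([p for p in panels if p.size]) if any(p.size for p in panels) else None
    edges = None
    if finite is not None and finite.size:
        lo, hi = float(finite.min()), float(finite.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    counts: list[np.ndarray] = []
    for ax, data, title in zip(axes, panels, titles):
        if data.size:
            n, _, _ = ax.hist(data, bins=edges if edges is not None else bins,
                              color="0.6", edgecolor="0.3")
            counts.append(np.asarray(n))
        else:
            ax.text(0.5, 0.5, "not tested", ha="center", va="center",
                    transform=ax.transAxes)
            counts.append(np.array([]))
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("tumor - normal difference")
    axes[0].set_ylabel("subjects")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return counts
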