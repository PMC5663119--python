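"""Data model and I/O for paired tumor/normal expression studies.

An expression file is delimited text with one row per feature and two
columns per subject (``<subject>_T`` and ``<subject>_N``).  A metadata file
has one row per subject with a ``site`` column and one column per binary
factor; blank cells are missing factor values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SITES = ("proximal", "distal", "rectal")

#: Signal transforms applied before differencing.  Both map 0 -> 0 so the
#: spike of exact-zero differences (non-expression in both tissues) is
#: preserved.
TRANSFORMS = {
    "identity": lambda x: np.asarray(x, dtype=float),
    "log2p1": lambda x: np.log2(1.0 + np.asarray(x, dtype=float)),
}


class StudyValidationError(ValueError):
    """Raised when study inputs violate the data-model invariants."""


@dataclass
class PairedExpressionStudy:
    """Per-subject tumor and normal signal over features, with metadata.

    Parameters
    ----------
    features, subjects
        Identifier lists; rows and columns of the signal matrices.
    tumor_signal, normal_signal
        Non-negative matrices of shape ``(n_features, n_subjects)``.
    site
        Per-subject site label.
    factors
        DataFrame indexed by subject, one column per binary factor.  Values
        are 0.0, 1.0 or NaN (missing).
    """

    features: list[str]
    subjects: list[str]
    tumor_signal: np.ndarray
    normal_signal: np.ndarray
    site: np.ndarray
    factors: pd.DataFrame
    allowed_sites: tuple[str, ...] = field(default=DEFAULT_SITES, repr=False)

    def __post_init__(self) -> None:
        self.tumor_signal = np.asarray(self.tumor_signal, dtype=float)
        self.normal_signal = np.asarray(self.normal_signal, dtype=float)
        self.site = np.asarray(self.site, dtype=object)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        nf, ns = len(self.features), len(self.subjects)
        if self.tumor_signal.shape != (nf, ns):
            raise StudyValidationError(
                f"tumor_signal shape {self.tumor_signal.shape} != ({nf}, {ns})"
            )
        if self.normal_signal.shape != self.tumor_signal.shape:
            raise StudyValidationError("tumor and normal signal shapes differ")
        if np.any(self.tumor_signal < 0) or np.any(self.normal_signal < 0):
            raise StudyValidationError("negative signal values are not allowed")
        if self.site.shape != (ns,):
            raise StudyValidationError("site must have one label per subject")
        if self.allowed_sites is not None:
            bad = sorted(set(self.site) - set(self.allowed_sites))
            if bad:
                raise StudyValidationError(f"unknown site labels: {bad}")
        if list(self.factors.index) != list(self.subjects):
            raise StudyValidationError("factor table index must equal the subject list")
        vals = self.factors.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad_cols = [c for i, c in enumerate(self.factors.columns) if not ok[:, i].all()]
            raise StudyValidationError(
                f"factor values must be 0, 1 or missing; offending factors: {bad_cols}"
            )

    # -- conveniences ----------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)

    def subjects_at(self, site: str) -> np.ndarray:
        """Boolean mask over subjects belonging to ``site``."""
        return self.site == site

    def with_signals(
        self, tumor: np.ndarray, normal: np.ndarray
    ) -> "PairedExpressionStudy":
        """A copy of this study with replaced signal matrices."""
        return PairedExpressionStudy(
            features=list(self.features),
            subjects=list(self.subjects),
            tumor_signal=tumor,
            normal_signal=normal,
            site=self.site.copy(),
            factors=self.factors.copy(),
            allowed_sites=self.allowed_sites,
        )


@dataclass
class DiffMatrix:
    """Per-site matrix of per-subject tumor-normal differences."""

    site: str
    features: list[str]
    subjects: list[str]
    diffs: np.ndarray  # (n_features, n_subjects_at_site)
    transform_tag: str

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        if self.diffs.shape != (len(self.features), len(self.subjects)):
            raise StudyValidationError("diffs shape inconsistent with labels")


# ---------------------------------------------------------------------------
# I/O


def load_study(
    expression_path,
    metadata_path,
    sep: str = "\t",
    allowed_sites: tuple[str, ...] | None = DEFAULT_SITES,
) -> PairedExpressionStudy:
    """Load a study from an expression table and a subject metadata table.

    Raises
    ------
    StudyValidationError
        On mismatched subject sets (the offending identifiers are named),
        negative signal, unknown site labels, or factor entries outside
        {0, 1, blank}.
    """
    expr = pd.read_csv(expression_path, sep=sep, index_col=0)
    meta = pd.read_csv(metadata_path, sep=sep, index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)

    tumor_cols = [c for c in expr.columns if c.endswith("_T")]
    normal_cols = [c for c in expr.columns if c.endswith("_N")]
    subj_t = [c[:-2] for c in tumor_cols]
    subj_n = [c[:-2] for c in normal_cols]
    if subj_t != subj_n:
        raise StudyValidationError(
            "tumor/normal column pairs do not match: "
            f"{sorted(set(subj_t) ^ set(subj_n))}"
        )
    subjects = subj_t
    meta_subjects = list(meta.index)
    if set(subjects) != set(meta_subjects):
        missing_in_meta = sorted(set(subjects) - set(meta_subjects))
        missing_in_expr = sorted(set(meta_subjects) - set(subjects))
        raise StudyValidationError(
            "subject sets differ between expression and metadata files; "
            f"absent from metadata: {missing_in_meta}; "
            f"absent from expression: {missing_in_expr}"
        )
    meta = meta.loc[subjects]

    if "site" not in meta.columns:
        raise StudyValidationError("metadata file must have a 'site' column")
    factor_cols = [c for c in meta.columns if c != "site"]
    factors = meta[factor_cols].apply(pd.to_numeric, errors="coerce")
    # pd.to_numeric maps non-numeric garbage to NaN silently; re-check the
    # raw strings so e.g. "x" is rejected rather than treated as missing.
    raw = meta[factor_cols].astype(object)
    for c in factor_cols:
        for subj, cell in raw[c].items():
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            s = str(cell).strip()
            if s in ("", "nan"):
                continue
            try:
                v = float(s)
            except ValueError:
                raise StudyValidationError(
                    f"factor {c!r} has non-numeric entry {cell!r} for subject {subj}"
                ) from None
            if v not in (0.0, 1.0):
                raise StudyValidationError(
                    f"factor {c!r} has entry {cell!r} outside {{0, 1, blank}} "
                    f"for subject {subj}"
                )

    return PairedExpressionStudy(
        features=[str(f) for f in expr.index],
        subjects=subjects,
        tumor_signal=expr[tumor_cols].to_numpy(dtype=float),
        normal_signal=expr[normal_cols].to_numpy(dtype=float),
        site=meta["site"].to_numpy(dtype=object),
        factors=factors.set_axis(subjects, axis=0),
        allowed_sites=allowed_sites,
    )


def write_study(study: PairedExpressionStudy, expression_path, metadata_path,
                sep: str = "\t") -> None:
    """Write a study to the expression/metadata file formats (lossless)."""
    cols: dict[str, np.ndarray] = {}
    for j, subj in enumerate(study.subjects):
        cols[f"{subj}_T"] = study.tumor_signal[:, j]
        cols[f"{subj}_N"] = study.normal_signal[:, j]
    expr = pd.DataFrame(cols, index=pd.Index(study.features, name="feature"))
    expr.to_csv(expression_path, sep=sep, float_format="%.17g")

    meta = study.factors.copy()
    meta.insert(0, "site", study.site)
    meta.index.name = "subject"
    meta.to_csv(metadata_path, sep=sep)


# ---------------------------------------------------------------------------
# Differences and filtering


def compute_differences(
    study: PairedExpressionStudy, site: str, transform: str = "log2p1"
) -> DiffMatrix:
    """Tumor minus normal differences for all subjects at ``site``.

    ``transform`` is applied to both signals before differencing; both
    available transforms fix 0, so a pair that is zero in both tissues
    yields an exact-zero difference.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    mask = study.subjects_at(site)
    if not mask.any():
        raise StudyValidationError(f"no subjects at site {site!r}")
    t = TRANSFORMS[transform]
    diffs = t(study.tumor_signal[:, mask]) - t(study.normal_signal[:, mask])
    return DiffMatrix(
        site=site,
        features=list(study.features),
        subjects=[s for s, m in zip(study.subjects, mask) if m],
        diffs=diffs,
        transform_tag=transform,
    )


def expression_filter(
    study: PairedExpressionStudy, min_nonzero_fraction: float = 0.0
) -> list[str]:
    """Features whose fraction of subjects with nonzero signal in tumor or
    normal is at least ``min_nonzero_fraction`` (inclusive threshold)."""
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise ValueError("min_nonzero_fraction must be in [0, 1]")
    nonzero = (study.tumor_signal > 0) | (study.normal_signal > 0)
    frac = nonzero.mean(axis=1)
    keep = frac >= min_nonzero_fraction
    return [f for f, k in zip(study.features, keep) if k]
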