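"""Reliability analysis: ICC(2,1) with 95% CI, MAD, simulated examiners.

Agreement between repeated Cobb measurements is quantified with the
two-way random-effects, absolute-agreement, single-measurement
intraclass correlation coefficient ICC(2,1), computed from the two-way
ANOVA mean squares, with the 95% confidence interval from the standard
F-distribution formulation.  The mean absolute difference (MAD) of two
measurement series complements it on the degree scale.

Human examiners are replaced by a simulated observer whose only source
of variability is where they click: each nominal vertebra center is
perturbed by isotropic Gaussian click noise before measurement, exactly
the variability profile of a system in which the user only assigns the
patches.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

from .cobb import measure
from .dnn import DNNParameters
from .exceptions import ValidationError
from .patches import PATCH_SIZE

logger = logging.getLogger(__name__)

ICC_VARIANT = "ICC(2,1): two-way random effects, absolute agreement, single measure"


@dataclass(frozen=True)
class MeasurementTable:
    """n_subjects x k_raters grid of Cobb angles (degrees)."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    rater_ids: tuple[str, ...]

    def validate(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError("measurement table must be 2-D")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValidationError(
                f"need at least 2 subjects and 2 raters, got {n}x{k}"
            )
        if np.isnan(v).any():
            raise ValidationError("measurement table has missing cells")
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValidationError("id labels do not match the table shape")


@dataclass(frozen=True)
class ReliabilityReport:
    """ICC with 95% CI and MAD for one agreement study."""

    icc: float
    ci_low: float
    ci_high: float
    mad: float
    icc_variant: str = ICC_VARIANT
    n_subjects: int = 0
    k_raters: int = 0
    defined: bool = True
    table: MeasurementTable | None = None

    def to_dict(self) -> dict:
        return {
            "icc": self.icc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "mad": self.mad, "icc_variant": self.icc_variant,
            "n_subjects": self.n_subjects, "k_raters": self.k_raters,
            "defined": self.defined,
        }


def _anova_mean_squares(v: np.ndarray):
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((v - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse, ss_total


def icc_absolute_agreement(
    table: MeasurementTable, alpha: float = 0.05
) -> tuple[float, float, float]:
    """ICC(2,1) with a (1 - alpha) confidence interval.

    Computed from the two-way ANOVA mean squares (subjects x raters,
    single score per cell); the CI uses the F-distribution with
    Satterthwaite degrees of freedom.  When the between-subject variance
    is zero the coefficient is undefined and (nan, nan, nan) is
    returned — never a spurious 0.
    """
    table.validate()
    v = np.asarray(table.values, dtype=float)
    n, k = v.shape
    msr, msc, mse, ss_total = _anova_mean_squares(v)
    scale = max(ss_total / (n * k - 1), 1e-30)
    if msr <= 1e-12 * scale or ss_total <= 0:
        return (float("nan"),) * 3

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    if mse <= 1e-12 * scale and msc <= 1e-12 * scale:
        # perfect agreement: degenerate F statistics, CI collapses
        return 1.0, 1.0, 1.0

    fj = msc / mse if mse > 0 else np.inf
    a = n * (1.0 + (k - 1) * icc) - k * icc
    vn = (k - 1) * (n - 1) * (k * icc * fj + a) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + a**2
    v_df = max(vn / vd, 1.0)
    f2u = f_dist.ppf(1 - alpha / 2, n - 1, v_df)
    f2l = f_dist.ppf(1 - alpha / 2, v_df, n - 1)
    lb = n * (msr - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ub = n * (f2l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msr
    )
    return float(icc), float(lb), float(ub)


def mean_absolute_difference(a, b) -> float:
    """Mean of |a_i - b_i| over paired measurements (degrees)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError(
            f"need two equal-length 1-D series, got {a.shape} and {b.shape}"
        )
    return float(np.mean(np.abs(a - b)))


def simulate_examiner_session(
    radiographs,
    model: DNNParameters,
    click_noise_sd: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """One simulated measurement session: for every phantom radiograph,
    perturb each true vertebra center by isotropic Gaussian click noise,
    run the Cobb measurement, and return one angle per radiograph.

    Clicks pushed outside the valid patch margin are clamped to it (and
    logged).  A session is fully determined by its seed.
    """
    rng = np.random.default_rng(seed)
    half = PATCH_SIZE // 2
    angles = []
    n_clamped = 0
    for rad in radiographs:
        h, w = rad.image.shape
        centers = rad.truth.centers
        clicks = centers + rng.normal(0.0, click_noise_sd, size=centers.shape)
        lo = np.array([half, half])
        hi = np.array([w - half, h - half])
        clamped = np.clip(clicks, lo, hi)
        n_clamped += int(np.any(clamped != clicks, axis=1).sum())
        rec = measure(rad.image, clamped, model)
        angles.append(rec.cobb_angle)
    if n_clamped:
        logger.warning("clamped %d out-of-margin clicks", n_clamped)
    return np.asarray(angles)


def reliability_study(
    radiographs,
    model: DNNParameters,
    design: str = "intraobserver",
    sessions: int = 2,
    click_noise_sd: float | tuple = 5.0,
    seed: int = 0,
) -> ReliabilityReport:
    """Simulated agreement study over repeated measurement sessions.

    ``design='intraobserver'`` repeats sessions of one simulated examiner
    (one click-noise sd); ``design='interobserver'`` lets each session
    belong to a different examiner, so ``click_noise_sd`` may be a
    per-session sequence (experience differences are modeled purely as
    different click scatter).  Sessions use independent sub-seeds spawned
    from ``seed``; the report carries the full measurement table.
    """
    if design not in ("intraobserver", "interobserver"):
        raise ValidationError(
            f"design must be 'intraobserver' or 'interobserver', got {design!r}"
        )
    if sessions < 2:
        raise ValidationError("need at least 2 sessions")
    if np.isscalar(click_noise_sd):
        sds = [float(click_noise_sd)] * sessions
    else:
        sds = [float(s) for s in click_noise_sd]
        if design == "intraobserver" and len(set(sds)) > 1:
            raise ValidationError(
                "intraobserver design requires a single click-noise sd"
            )
        if len(sds) != sessions:
            raise ValidationError("one click_noise_sd per session required")
    children = np.random.SeedSequence(seed).spawn(sessions)
    cols = [
        simulate_examiner_session(
            radiographs, model, click_noise_sd=sd,
            seed=int(child.generate_state(1)[0] % np.uint64(2**31)),
        )
        for sd, child in zip(sds, children)
    ]
    values = np.column_stack(cols)
    prefix = "session" if design == "intraobserver" else "examiner"
    table = MeasurementTable(
        values=values,
        subject_ids=tuple(f"phantom-{i:04d}" for i in range(values.shape[0])),
        rater_ids=tuple(f"{prefix}-{j + 1}" for j in range(sessions)),
    )
    icc, lo, hi = icc_absolute_agreement(table)
    mads = [
        mean_absolute_difference(values[:, i], values[:, j])
        for i, j in itertools.combinations(range(sessions), 2)
    ]
    return ReliabilityReport(
        icc=icc, ci_low=lo, ci_high=hi, mad=float(np.mean(mads)),
        n_subjects=values.shape[0], k_raters=sessions,
        defined=not np.isnan(icc), table=table,
    )
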