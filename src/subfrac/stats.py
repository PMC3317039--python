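"""Dose-response statistics: mixed ANOVA, Tukey HSD, ANCOVA, blot arithmetic.

The experimental design is a split plot: dose is a between-subject factor
(each animal receives one dose), while hemicord side (injected vs
contralateral vehicle) and rostrocaudal distance from the injection center
are within-subject factors.  Neurons are aggregated to subject-level cell
means before inference — the subject is the experimental unit.

``mixed_anova`` computes the classical balanced split-plot F-table stratum
by stratum: the between stratum on subject means (dose tested against
subject-within-dose), and each within-factor stratum on subject×factor cell
means (the factor and its dose interaction tested against the
factor×subject-within-dose error).  For balanced designs this is equivalent
to a mixed model with a subject random intercept; unbalanced cell structures
trigger a warning and an unweighted-means approximation.

``ancova`` adjusts a synaptic measure for the total receptor signal, the
step that separates trafficking (pool redistribution) from synthesis
(wholesale protein increase).

The western-blot helpers implement loading-control normalization, the
antibody linear-range check, and median-based lane background correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class CohortRecord:
    """One neuron's measurements joined to its design factors."""

    subject_id: str
    dose_um: float
    side: str
    distance_um: float
    neuropil_total_px: float
    neuropil_synaptic_px: float
    membrane_synaptic_px: float
    membrane_extrasynaptic_px: float
    truth_synaptic: float | None = None
    truth_extrasynaptic: float | None = None
    truth_intracellular: float | None = None


def records_to_frame(records) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of :class:`CohortRecord`."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


@dataclass
class BlotMeasurement:
    """One lane of a quantitative fluorescence western blot."""

    lane_id: str
    condition: str  # "TNFa" or "albumin"
    receptor_band_intensity: float
    loading_control_intensity: float

    def __post_init__(self) -> None:
        if self.receptor_band_intensity <= 0 or self.loading_control_intensity <= 0:
            raise ValidationError("band intensities must be positive")

    @property
    def normalized_ratio(self) -> float:
        return self.receptor_band_intensity / self.loading_control_intensity


# -- split-plot ANOVA ----------------------------------------------------------

def _f_and_p(ss_effect: float, df_effect: int, ss_error: float,
             df_error: int) -> tuple[float, float]:
    """F ratio and p-value, with degenerate (zero-variance) inputs handled."""
    if df_error <= 0:
        return float("nan"), float("nan")
    ms_error = ss_error / df_error
    ms_effect = ss_effect / df_effect if df_effect > 0 else 0.0
    if ms_error <= 0:
        if ms_effect <= 0:
            return 0.0, 1.0  # all values identical: no evidence either way
        return float("inf"), 0.0
    f = ms_effect / ms_error
    return float(f), float(sps.f.sf(f, df_effect, df_error))


def _between_stratum(cells: pd.DataFrame, value: str, subject: str,
                     between: str) -> dict:
    """Dose tested against subject-within-dose, on subject means."""
    subj = cells.groupby([subject, between], observed=True)[value].mean().reset_index()
    grand = subj[value].mean()
    groups = subj.groupby(between, observed=True)[value]
    group_means = groups.mean()
    group_sizes = groups.size()
    ss_between = float((group_sizes * (group_means - grand) ** 2).sum())
    ss_within = float(((subj[value]
                        - subj[between].map(group_means)) ** 2).sum())
    a = len(group_means)
    n_total = len(subj)
    return {
        "factor": between,
        "df": a - 1,
        "df_error": n_total - a,
        **dict(zip(("F", "p"), _f_and_p(ss_between, a - 1, ss_within,
                                        n_total - a))),
    }


def _within_stratum(cells: pd.DataFrame, value: str, subject: str,
                    between: str, within: str) -> list[dict]:
    """One within factor and its dose interaction, on subject×factor means.

    Error term: within×subject-within-dose interaction.
    """
    tab = (cells.groupby([subject, between, within], observed=True)[value]
           .mean().reset_index())
    w_levels = tab[within].nunique()
    subj_means = tab.groupby(subject, observed=True)[value].transform("mean")
    w_means = tab.groupby(within, observed=True)[value].transform("mean")
    bw_means = tab.groupby([between, within], observed=True)[value].transform("mean")
    b_means = tab.groupby(between, observed=True)[value].transform("mean")
    grand = tab[value].mean()

    n_subjects = tab[subject].nunique()
    a = tab[between].nunique()
    # Sums over the subject×within table (each subject appears once per level).
    ss_w = float(((w_means - grand) ** 2).sum())
    ss_bw = float(((bw_means - b_means - w_means + grand) ** 2).sum())
    residual = tab[value] - subj_means - bw_means + b_means
    ss_err = float((residual ** 2).sum())
    df_w = w_levels - 1
    df_bw = (a - 1) * (w_levels - 1)
    df_err = (n_subjects - a) * (w_levels - 1)
    rows = [
        {"factor": within, "df": df_w, "df_error": df_err,
         **dict(zip(("F", "p"), _f_and_p(ss_w, df_w, ss_err, df_err)))},
        {"factor": f"{between}:{within}", "df": df_bw, "df_error": df_err,
         **dict(zip(("F", "p"), _f_and_p(ss_bw, df_bw, ss_err, df_err)))},
    ]
    return rows


def _check_design(df: pd.DataFrame, subject: str, between: str,
                  within: tuple[str, ...]) -> None:
    if df[between].nunique() < 2:
        raise ValidationError("need at least 2 dose levels")
    sides = df.groupby(subject, observed=True)["side"].nunique()
    if "side" in within and (sides < 2).any():
        raise ValidationError("every subject must contribute both sides")
    doses_per_subject = df.groupby(subject, observed=True)[between].nunique()
    if (doses_per_subject > 1).any():
        raise ValidationError(f"{between} must be constant within subject")


def mixed_anova(
    records,
    outcome: str,
    between: str = "dose_um",
    within: tuple[str, ...] = ("side", "distance_um"),
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Split-plot ANOVA table for one outcome.

    Returns rows for the between factor (dose), each within factor's main
    effect and its dose interaction, each with ``df``, ``df_error``, ``F``
    and ``p``.  Neurons are averaged to subject-level cells first.
    """
    df = records_to_frame(records)
    within = tuple(w for w in within if w in df.columns
                   and df[w].nunique() > 1)
    _check_design(df, subject, between, within)

    cell_keys = [subject, between, *within]
    cells = df.groupby(cell_keys, observed=True)[outcome].mean().reset_index()
    expected = df[subject].nunique() * int(np.prod(
        [df[w].nunique() for w in within] or [1]))
    if len(cells) != expected:
        warnings.warn(
            "unbalanced design: missing subject×condition cells; "
            "stratum tests use unweighted cell means (type-III-like)",
            stacklevel=2,
        )

    rows = [_between_stratum(cells, outcome, subject, between)]
    for w in within:
        rows.extend(_within_stratum(cells, outcome, subject, between, w))
    return pd.DataFrame(rows, columns=["factor", "df", "df_error", "F", "p"])


def tukey_posthoc(
    records,
    outcome: str,
    factor: str = "dose_um",
    subject: str = "subject_id",
) -> pd.DataFrame:
    """Tukey HSD over all pairwise levels of ``factor`` on subject means."""
    df = records_to_frame(records)
    if df[factor].nunique() < 3:
        raise ValidationError("Tukey post hoc needs at least 3 factor levels")
    subj = df.groupby([subject, factor], observed=True)[outcome].mean().reset_index()
    if subj.groupby(factor, observed=True).size().min() < 2:
        raise ValidationError("Tukey post hoc needs >= 2 subjects per level")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    res = pairwise_tukeyhsd(subj[outcome].to_numpy(),
                            subj[factor].astype(str).to_numpy())
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    out = pd.DataFrame({
        "pair": [f"{a} vs {b}" for a, b in zip(frame["group1"], frame["group2"])],
        "level_a": frame["group1"],
        "level_b": frame["group2"],
        "difference": frame["meandiff"].astype(float),
        "p_adj": frame["p-adj"].astype(float),
    })
    return out


def ancova(
    records,
    outcome: str,
    covariate: str,
    between: str = "dose_um",
    side: str = "side",
    subject: str = "subject_id",
    include_interaction: bool = False,
) -> dict:
    """ANCOVA: dose effect on ``outcome`` adjusted for ``covariate``.

    Aggregates to subject×side cell means, then fits
    ``outcome ~ C(dose, Sum) + C(side, Sum) + covariate`` (plus dose×side on
    request) by OLS with type-III sums of squares.  Returns the ANOVA table
    and the covariate slope.
    """
    df = records_to_frame(records)
    if df[covariate].nunique() < 2:
        raise ValidationError("covariate must vary")
    if df[between].nunique() < 2:
        raise ValidationError("need at least 2 dose levels")
    cells = (df.groupby([subject, between, side], observed=True)
             [[outcome, covariate]].mean().reset_index())
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    data = cells.rename(columns={outcome: "_y", covariate: "_x",
                                 between: "_dose", side: "_side"})
    terms = "C(_dose, Sum) + C(_side, Sum) + _x"
    if include_interaction:
        terms += " + C(_dose, Sum):C(_side, Sum)"
    model = smf.ols(f"_y ~ {terms}", data=data).fit()
    table = anova_lm(model, typ=3)
    rename = {"C(_dose, Sum)": between, "C(_side, Sum)": side, "_x": covariate,
              "C(_dose, Sum):C(_side, Sum)": f"{between}:{side}"}
    table = table.rename(index=rename)
    return {
        "table": table,
        "slope": float(model.params["_x"]),
        "dose_F": float(table.loc[between, "F"]),
        "dose_p": float(table.loc[between, "PR(>F)"]),
        "model": model,
    }


# -- western-blot arithmetic ---------------------------------------------------

def normalize_blot(receptor_intensity: float,
                   control_intensity: float) -> float:
    """Loading-control normalization: receptor / control intensity."""
    if control_intensity <= 0:
        raise ValidationError("control intensity must be positive")
    return receptor_intensity / control_intensity


def average_runs(ratio_runs: "list[list[float]]") -> np.ndarray:
    """Average per-lane normalized ratios across replicate blot runs."""
    arr = np.asarray(ratio_runs, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("expected runs × lanes ratios")
    return arr.mean(axis=0)


def linear_range_r2(loadings, intensities) -> float:
    """OLS R² of band intensity on loaded protein amount (≥3 points)."""
    loadings = np.asarray(loadings, dtype=np.float64)
    intensities = np.asarray(intensities, dtype=np.float64)
    if loadings.size < 3 or loadings.size != intensities.size:
        raise ValidationError("need >= 3 paired points")
    res = sps.linregress(loadings, intensities)
    return float(res.rvalue ** 2)


def band_background_correct(lane_profile, band_interval) -> float:
    """Background-corrected band intensity from a 1D lane profile.

    Background is the mean of the median profile values above and below the
    band; the corrected intensity is the band sum minus band_width times
    that background.
    """
    profile = np.asarray(lane_profile, dtype=np.float64)
    start, end = band_interval
    if profile.ndim != 1:
        raise ValidationError("lane profile must be 1-D")
    if not (0 < start < end < len(profile)):
        raise ValidationError("band interval must lie strictly inside the profile")
    above = profile[:start]
    below = profile[end:]
    background = (np.median(above) + np.median(below)) / 2
    band = profile[start:end]
    return float(band.sum() - len(band) * background)
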