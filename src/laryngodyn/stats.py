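"""Group comparisons, rank correlations and random-intercept mixed models.

The inference layer mirrors a typical movement-disorder imaging analysis:

* Wilcoxon rank-sum tests compare each per-participant summary measure
  between PD and control groups (exact null distribution for small untied
  samples, tie-corrected normal approximation otherwise).
* Spearman rank correlations relate the positional measures to disease
  duration (months) and severity (UPDRS part-III score).
* Linear mixed models are fit to the *per-frame* measures with disease
  duration or UPDRS, age and sex as fixed effects and a participant-level
  random intercept absorbing inter-individual variability. GA and IAI are
  non-linearly transformed (log by default) before modelling to linearise
  their relation to the predictors. Within each predictor, the model with
  the highest marginal R-squared is preferred for interpretation.

Degrees of freedom for the mixed-model t statistics use the
between-participant convention: n_participants - (participant-level fixed
effects) - 1, i.e. n - 4 for predictor + age + sex.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .measures import MeasureSummary
from .records import ParticipantRecord

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: measure -> (transform kind, offset); measures not listed are identity
DEFAULT_TRANSFORMS: dict[str, tuple[str, float]] = {
    "ga": ("log", 1.0),
    "iai": ("log", 1.0),
}
_EXACT_MAX_N = 10
_N_PARTICIPANT_FIXED_EFFECTS = 3  # predictor + age + sex


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    median_pd: float
    median_control: float
    statistic: float          # rank-sum W of the PD group (mid-ranks)
    p: float
    n_pd: int
    n_control: int
    method: str               # "exact" or "normal-approx"
    q: float | None = None    # Benjamini-Hochberg q, annotated post hoc


@dataclass(frozen=True)
class CorrelationResult:
    measure: str
    predictor: str            # "duration" or "updrs3"
    rho: float
    p: float
    n: int
    q: float | None = None


@dataclass(frozen=True)
class ModelFit:
    response: str             # measure name
    transform: str            # e.g. "identity" or "log(x + 1)"
    predictor: str
    b: float
    se_b: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    r2_marginal: float
    r2_conditional: float
    n_participants: int
    n_frames: int
    converged: bool
    singular: bool
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.converged and np.isfinite(self.b)


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    measure: str = "",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two independent samples.

    ``group_a`` is reported as the PD group. Uses the exact null distribution
    when both samples have <= 10 values and there are no ties, otherwise the
    tie-corrected normal approximation (with continuity correction).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one finite value")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_a = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of separation
        p = 1.0
        method = "degenerate"
    elif a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N and not has_ties:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue)
        method = "exact"
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue)
        method = "normal-approx"
    return GroupComparison(
        measure=measure,
        median_pd=float(np.median(a)),
        median_control=float(np.median(b)),
        statistic=w_a,
        p=min(p, 1.0),
        n_pd=int(a.size),
        n_control=int(b.size),
        method=method,
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    measure: str = "",
    predictor: str = "",
) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.spearmanr(x, y)
    return CorrelationResult(
        measure=measure,
        predictor=predictor,
        rho=float(res.statistic),
        p=float(res.pvalue),
        n=int(x.size),
    )


def transform_measure(
    values: Sequence[float],
    measure: str,
    transforms: dict[str, tuple[str, float]] | None = None,
) -> tuple[np.ndarray, str]:
    """Apply the configured linearising transformation for ``measure``.

    Returns the transformed values and a label recording what was applied
    (``"identity"`` or e.g. ``"log(x + 1)"``). GA and IAI default to a
    natural-log transform with a small offset since both can be exactly 0.
    """
    v = np.asarray(values, dtype=float)
    cfg = DEFAULT_TRANSFORMS if transforms is None else transforms
    kind, offset = cfg.get(measure, ("identity", 0.0))
    if kind == "identity":
        return v.copy(), "identity"
    if kind == "log":
        shifted = v + offset
        if np.any(shifted[np.isfinite(shifted)] <= 0):
            raise ValueError(
                f"log transform domain error for {measure}: "
                f"min(value + {offset}) <= 0"
            )
        label = f"log(x + {offset:g})" if offset else "log(x)"
        return np.log(shifted), label
    raise ValueError(f"unknown transform kind {kind!r}")


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH q-values (supplementary annotation; decisions stay at raw alpha)."""
    p = np.asarray(pvals, dtype=float)
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _records_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "participant_id": r.participant_id,
                "condition": r.condition,
                "age_years": r.age_years,
                "sex": r.sex,
                "duration": np.nan if r.duration_months is None else r.duration_months,
                "updrs3": r.updrs3,
            }
        )
    return pd.DataFrame(rows)


def fit_lmm(
    frames_table: pd.DataFrame,
    response: str,
    predictor: str,
    records: Iterable[ParticipantRecord],
    transforms: dict[str, tuple[str, float]] | None = None,
    pd_only: bool | None = None,
) -> ModelFit:
    """Fit ``response ~ predictor + age + sex`` with random intercepts.

    ``frames_table`` is the tidy per-frame table (one row per participant x
    frame) from :func:`laryngodyn.measures.frames_long_table`. The response is
    transformed according to ``transforms`` before fitting. REML estimates are
    reported. By default duration models use PD participants only (controls
    have no disease duration) while UPDRS models use everyone.

    A failed or degenerate fit is reported via the ``converged`` /
    ``singular`` flags rather than an exception.
    """
    if predictor not in ("duration", "updrs3"):
        raise ValueError("predictor must be 'duration' or 'updrs3'")
    if pd_only is None:
        pd_only = predictor == "duration"

    rec = _records_frame(records)
    df = frames_table.merge(rec, on="participant_id", how="inner")
    if pd_only:
        df = df[df["condition"] == "PD"]
    df = df.dropna(subset=[response, predictor, "age_years", "sex"]).copy()

    values, label = transform_measure(df[response].to_numpy(), response, transforms)
    df["_y"] = values
    df["sex_male"] = (df["sex"] == "M").astype(float)

    n_participants = df["participant_id"].nunique()
    n_frames = len(df)
    dof = n_participants - _N_PARTICIPANT_FIXED_EFFECTS - 1

    def _failed(msg: str) -> ModelFit:
        nan = float("nan")
        return ModelFit(
            response=response, transform=label, predictor=predictor,
            b=nan, se_b=nan, ci95=(nan, nan), t=nan, df=max(dof, 0), p=nan,
            r2_marginal=nan, r2_conditional=nan,
            n_participants=n_participants, n_frames=n_frames,
            converged=False, singular=False, message=msg,
        )

    if n_participants < 3 or dof < 1:
        return _failed(
            f"unfittable: {n_participants} participant(s), df={dof}"
        )
    if df.groupby("participant_id").size().max() < 2:
        return _failed("unfittable: no participant has >= 2 frames")

    formula = f"_y ~ {predictor} + age_years + sex_male"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(formula, df, groups=df["participant_id"])
            # lbfgs tends to stall on a var_re=0 boundary here; bfgs is robust
            result = model.fit(reml=True, method=["bfgs", "powell", "nm"])
        messages = "; ".join(str(w.message) for w in caught)
    except Exception as exc:  # singular design, no variation, ...
        return _failed(f"fit failed: {exc}")

    b = float(result.fe_params[predictor])
    se = float(result.bse_fe[predictor])
    t_stat = b / se if se > 0 else float("nan")
    p = float(2 * sps.t.sf(abs(t_stat), dof)) if np.isfinite(t_stat) else float("nan")
    t_crit = float(sps.t.ppf(0.975, dof))
    ci = (b - t_crit * se, b + t_crit * se)

    # variance-partition R^2: fixed / random / residual components
    exog = result.model.exog
    var_f = float(np.var(exog @ result.fe_params))
    var_re = float(np.asarray(result.cov_re)[0, 0])
    var_resid = float(result.scale)
    total = var_f + var_re + var_resid
    r2m = var_f / total if total > 0 else float("nan")
    r2c = (var_f + var_re) / total if total > 0 else float("nan")

    singular = (
        var_re <= 1e-8 * max(var_re + var_resid, 1e-30)
        or "singular" in messages.lower()
        or "boundary" in messages.lower()
    )
    converged = bool(getattr(result, "converged", True))
    if singular:
        messages = (messages + "; " if messages else "") + \
            "singular fit: between-participant variance ~ 0"
        logger.warning("%s ~ %s: %s", response, predictor, messages)
    return ModelFit(
        response=response, transform=label, predictor=predictor,
        b=b, se_b=se, ci95=ci, t=float(t_stat), df=dof, p=p,
        r2_marginal=r2m, r2_conditional=r2c,
        n_participants=n_participants, n_frames=n_frames,
        converged=converged, singular=singular, message=messages,
    )


@dataclass
class AnalysisConfig:
    """Switches for the full-analysis report."""

    alpha: float = DEFAULT_ALPHA
    #: include velocity measures in correlations only when their group
    #: comparison is significant ("conditional"), or "always" / "never"
    velocity_correlations: str = "conditional"
    #: duration correlations/models on PD participants only
    duration_pd_only: bool = True
    #: UPDRS correlations/models include controls (UPDRS recorded as 0)
    updrs_pd_only: bool = False
    transforms: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFORMS)
    )
    lmm_responses: tuple[str, ...] = ("iad", "ga", "iai")


@dataclass
class AnalysisReport:
    """Machine-readable result of the full inference stage."""

    comparisons: list[GroupComparison]
    correlations: list[CorrelationResult]
    models: list[ModelFit]
    preferred_models: dict[str, str]   # predictor -> "response [transform]"
    errors: list[dict]
    config: AnalysisConfig

    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, float) and not np.isfinite(obj):
                return None
            if isinstance(obj, tuple):
                return [_clean(v) for v in obj]
            if isinstance(obj, list):
                return [_clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            return obj

        return {
            "schema_version": 1,
            "comparisons": [_clean(asdict(c)) for c in self.comparisons],
            "correlations": [_clean(asdict(c)) for c in self.correlations],
            "models": [_clean(asdict(m)) for m in self.models],
            "preferred_models": dict(self.preferred_models),
            "errors": list(self.errors),
            "config": _clean(asdict(self.config)),
        }

    def render_text(self) -> str:
        lines = ["Laryngeal dynamics analysis report", ""]
        lines.append("Group comparisons (PD vs control, Wilcoxon rank-sum):")
        for c in self.comparisons:
            star = " *" if c.p < self.config.alpha else ""
            lines.append(
                f"  {c.measure:<12} Mdn {c.median_pd:8.3g} vs "
                f"{c.median_control:8.3g}  W={c.statistic:.1f}  "
                f"p={c.p:.4g}{star}"
            )
        lines.append("")
        lines.append("Spearman correlations:")
        for r in self.correlations:
            star = " *" if r.p < self.config.alpha else ""
            lines.append(
                f"  {r.measure:<12} vs {r.predictor:<8} "
                f"rho={r.rho:+.3f}  p={r.p:.4g}  n={r.n}{star}"
            )
        lines.append("")
        lines.append("Linear mixed models (random intercept per participant):")
        for m in self.models:
            if not m.ok:
                lines.append(
                    f"  {m.response:<6}[{m.transform}] ~ {m.predictor:<8} "
                    f"UNFITTABLE ({m.message})"
                )
                continue
            flag = " [singular]" if m.singular else ""
            lines.append(
                f"  {m.response:<6}[{m.transform}] ~ {m.predictor:<8} "
                f"b={m.b:+.4g}  SE={m.se_b:.3g}  "
                f"95% CI [{m.ci95[0]:+.4g}, {m.ci95[1]:+.4g}]  "
                f"t({m.df})={m.t:.2f}  p={m.p:.4g}  "
                f"R2m={m.r2_marginal:.3f}  R2c={m.r2_conditional:.3f}{flag}"
            )
        lines.append("")
        for predictor, label in self.preferred_models.items():
            lines.append(f"Preferred model for {predictor}: {label}")
        if self.errors:
            lines.append("")
            lines.append("Stage errors:")
            for e in self.errors:
                lines.append(f"  {e}")
        return "\n".join(lines) + "\n"


def run_full_analysis(
    summaries: Iterable[MeasureSummary],
    frames: pd.DataFrame,
    records: Iterable[ParticipantRecord],
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the complete inference stage.

    (i) Wilcoxon comparisons of all ten summary measures; (ii) Spearman
    correlations of the positional measures (velocities included only when
    their group comparison is significant) against duration and UPDRS-III;
    (iii) six mixed models ({IAD, transformed GA, transformed IAI} x
    {duration, UPDRS-III}); (iv) the preferred model per predictor by highest
    marginal R-squared. Item-level failures are recorded in the report rather
    than raised. Deterministic: two runs on the same inputs are identical.
    """
    cfg = AnalysisConfig() if config is None else config
    records = list(records)
    summaries = list(summaries)
    errors: list[dict] = []

    rec = _records_frame(records)
    sm_df = pd.DataFrame([asdict(s) for s in summaries]).merge(
        rec, on="participant_id", how="inner"
    )
    pd_df = sm_df[sm_df["condition"] == "PD"]
    ct_df = sm_df[sm_df["condition"] == "control"]

    comparisons: list[GroupComparison] = []
    for measure in MeasureSummary.MEASURES:
        try:
            comparisons.append(
                wilcoxon_rank_sum(
                    pd_df[measure].to_numpy(), ct_df[measure].to_numpy(), measure
                )
            )
        except ValueError as exc:
            errors.append({"stage": "comparison", "item": measure, "error": str(exc)})
    if comparisons:
        qs = benjamini_hochberg([c.p for c in comparisons])
        comparisons = [
            GroupComparison(**{**asdict(c), "q": float(q)})
            for c, q in zip(comparisons, qs)
        ]

    sig = {c.measure: c.p < cfg.alpha for c in comparisons}
    corr_measures = list(MeasureSummary.POSITIONAL_MEASURES)
    if cfg.velocity_correlations == "always":
        corr_measures += list(MeasureSummary.VELOCITY_MEASURES)
    elif cfg.velocity_correlations == "conditional":
        corr_measures += [
            m for m in MeasureSummary.VELOCITY_MEASURES if sig.get(m, False)
        ]

    correlations: list[CorrelationResult] = []
    for predictor, pd_only in (
        ("duration", cfg.duration_pd_only),
        ("updrs3", cfg.updrs_pd_only),
    ):
        base = pd_df if pd_only else sm_df
        for measure in corr_measures:
            try:
                correlations.append(
                    spearman(
                        base[predictor].to_numpy(), base[measure].to_numpy(),
                        measure, predictor,
                    )
                )
            except ValueError as exc:
                errors.append(
                    {"stage": "correlation", "item": f"{measure}~{predictor}",
                     "error": str(exc)}
                )
    if correlations:
        qs = benjamini_hochberg([r.p for r in correlations])
        correlations = [
            CorrelationResult(**{**asdict(r), "q": float(q)})
            for r, q in zip(correlations, qs)
        ]

    models: list[ModelFit] = []
    for predictor, pd_only in (
        ("duration", cfg.duration_pd_only),
        ("updrs3", cfg.updrs_pd_only),
    ):
        for response in cfg.lmm_responses:
            models.append(
                fit_lmm(
                    frames, response, predictor, records,
                    transforms=cfg.transforms, pd_only=pd_only,
                )
            )

    preferred: dict[str, str] = {}
    for predictor in ("duration", "updrs3"):
        fits = [
            m for m in models
            if m.predictor == predictor and m.ok and np.isfinite(m.r2_marginal)
        ]
        if fits:
            best = max(fits, key=lambda m: m.r2_marginal)
            preferred[predictor] = f"{best.response} [{best.transform}]"

    return AnalysisReport(
        comparisons=comparisons,
        correlations=correlations,
        models=models,
        preferred_models=preferred,
        errors=errors,
        config=cfg,
    )
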