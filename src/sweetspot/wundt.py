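"""Per-participant inverted-U curve fitting and preferred-complexity peaks.

Each participant's liking ratings are regressed on the excerpts'
complexity scores with an ordinary least-squares quadratic,

    liking = b0 + b1 * x + b2 * x**2 + e,

where ``x`` is the raw complexity score (no centering or scaling: the
quadratic term is literally the squared complexity, so the conventional
-0.1 cutoff on ``b2`` keeps its meaning).  Participants with
``b2 <= -0.1`` show a Wundt curve — an inverted U whose apex is their
preferred level of complexity.  For concave fits the preferred level is
the vertex ``-b1 / (2 * b2)``, clipped to the stimulus complexity range;
for non-concave fits a bounded maximum over the range (necessarily an
endpoint) is reported instead.

:class:`WundtModel` bundles the per-participant fits with a group-level
random-intercept confirmation of the Wundt effect, statsmodels-style:
build the model from data, call :meth:`WundtModel.fit`, inspect the
returned :class:`WundtResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import LikingMatrix, StimulusTable

__all__ = [
    "WundtFit",
    "GroupCurve",
    "WundtModel",
    "WundtResults",
    "fit_participant_curve",
    "classify_wundt",
    "preferred_level",
    "fit_group_curve",
    "screen_response_quality",
    "liking_variance",
    "peak_summary",
]

WUNDT_THRESHOLD = -0.1


@dataclass(frozen=True)
class WundtFit:
    """Quadratic fit of one participant's liking against complexity."""

    b0: float
    b1: float
    b2: float
    r2: float
    n_obs: int

    @property
    def vertex(self) -> float:
        """Unconstrained parabola vertex -b1/(2*b2); NaN when b2 == 0."""
        if self.b2 == 0:
            return float("nan")
        return -self.b1 / (2 * self.b2)


def _ols_quadratic(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each row of ``Y`` on (1, x, x**2); returns (coefs, r2)."""
    X = np.column_stack([np.ones_like(x), x, x * x])
    coefs, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ coefs).T
    resid = Y - fitted
    ss_res = np.sum(resid**2, axis=-1)
    ss_tot = np.sum((Y - Y.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1 - ss_res / ss_tot, 0.0)
    return coefs.T, r2


def fit_participant_curve(
    complexities: Sequence[float], ratings: Sequence[float]
) -> WundtFit:
    """Quadratic OLS of one participant's ratings on raw complexity.

    Missing pairs are dropped; at least 4 complete pairs over at least 3
    distinct complexity values are required for the three coefficients
    to be identified with a residual degree of freedom.
    """
    x = np.asarray(complexities, float)
    y = np.asarray(ratings, float)
    if x.shape != y.shape:
        raise ValueError("complexities and ratings differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct complexity values (design is rank-deficient)")
    coefs, r2 = _ols_quadratic(x, y[None, :])
    b0, b1, b2 = (float(c) for c in coefs[0])
    return WundtFit(b0=b0, b1=b1, b2=b2, r2=float(r2[0]), n_obs=int(x.size))


def classify_wundt(fit: WundtFit | float, threshold: float = WUNDT_THRESHOLD) -> str:
    """Classify a fit as ``"wundt"`` iff its quadratic component <= threshold.

    The exclusion rule drops quadratic components strictly larger than
    the cutoff, so a component exactly at -0.1 is retained.
    """
    b2 = fit.b2 if isinstance(fit, WundtFit) else float(fit)
    return "wundt" if b2 <= threshold else "non_wundt"


def preferred_level(
    fit: WundtFit, range_: tuple[float, float]
) -> tuple[float, str]:
    """Preferred complexity within the stimulus range, with its provenance.

    Returns ``(peak, peak_type)`` where ``peak_type`` is
    ``interior_vertex`` (concave fit, vertex inside the range),
    ``clipped_vertex`` (concave fit, vertex clipped to the nearest
    endpoint), ``bounded_maximum`` (non-concave fit: the larger fitted
    value of the two endpoints) or ``undefined`` (flat fit, b1 = b2 = 0;
    such participants are excluded from association analyses).
    """
    lo, hi = range_
    if lo >= hi:
        raise ValueError("range must satisfy min < max")
    if fit.b2 < 0:
        v = fit.vertex
        if lo <= v <= hi:
            return float(v), "interior_vertex"
        return (lo, "clipped_vertex") if v < lo else (hi, "clipped_vertex")
    if fit.b2 == 0 and fit.b1 == 0:
        return float("nan"), "undefined"
    f = lambda x: fit.b0 + fit.b1 * x + fit.b2 * x * x
    return (lo, "bounded_maximum") if f(lo) >= f(hi) else (hi, "bounded_maximum")


@dataclass(frozen=True)
class GroupCurve:
    """Fixed effects of the group-level random-intercept Wundt model."""

    beta_lin: float
    beta_quad: float
    se_lin: float
    se_quad: float
    p_lin: float
    p_quad: float
    converged: bool
    n_participants: int
    n_obs: int
    random_intercepts: pd.Series
    result: object = field(repr=False, compare=False)


def fit_group_curve(
    matrix: LikingMatrix,
    table: StimulusTable,
    *,
    reml: bool = True,
    predictor: str = "complexity",
) -> GroupCurve:
    """Random-intercept mixed model of liking on complexity and its square.

    Confirms the Wundt effect at the group level: a positive linear and a
    negative quadratic fixed effect.  On balanced complete data the fixed
    effects coincide with the pooled OLS coefficients.
    """
    if len(matrix) < 2:
        raise ValueError("group curve requires >= 2 participants")
    xs = _predictor_series(table, predictor)
    long = (
        matrix.df.loc[:, xs.index]
        .stack()
        .rename("rating")
        .reset_index()
        .set_axis(["participant", "excerpt", "rating"], axis=1)
    )
    long["x"] = xs.loc[long["excerpt"]].to_numpy()
    if long["x"].nunique() < 3:
        raise ValueError("group curve requires >= 3 distinct complexity values")
    exog = sm.add_constant(np.column_stack([long["x"], long["x"] ** 2]))
    model = sm.MixedLM(long["rating"].to_numpy(), exog, groups=long["participant"])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(reml=reml)
    re = pd.Series(
        {k: float(v.iloc[0]) for k, v in res.random_effects.items()},
        name="random_intercept",
    )
    return GroupCurve(
        beta_lin=float(res.fe_params[1]),
        beta_quad=float(res.fe_params[2]),
        se_lin=float(res.bse_fe[1]),
        se_quad=float(res.bse_fe[2]),
        p_lin=float(res.pvalues[1]),
        p_quad=float(res.pvalues[2]),
        converged=bool(res.converged),
        n_participants=int(long["participant"].nunique()),
        n_obs=int(len(long)),
        random_intercepts=re,
        result=res,
    )


def screen_response_quality(
    matrix: LikingMatrix,
    *,
    midpoint_band: tuple[float, float] = (45.0, 55.0),
    max_fraction: float = 0.5,
) -> pd.DataFrame:
    """Flag participants who gave a midpoint rating to most excerpts.

    A participant is flagged when the share of their non-missing ratings
    falling inside ``midpoint_band`` exceeds ``max_fraction``.  Returns a
    report with one row per flagged participant (participant, rule,
    statistic).
    """
    lo, hi = midpoint_band
    vals = matrix.values
    n_rated = np.sum(~np.isnan(vals), axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.nansum((vals >= lo) & (vals <= hi), axis=1) / np.maximum(n_rated, 1)
    flagged = (frac > max_fraction) & (n_rated > 0)
    return pd.DataFrame(
        {
            "participant_id": np.asarray(matrix.participant_ids)[flagged],
            "rule": "midpoint_majority",
            "statistic": frac[flagged],
        }
    )


def liking_variance(matrix: LikingMatrix) -> pd.Series:
    """Sample variance (n-1 denominator) of each participant's ratings.

    Participants with fewer than two ratings get NaN.
    """
    df = matrix.df
    n = df.notna().sum(axis=1)
    var = df.var(axis=1, ddof=1)
    var[n < 2] = np.nan
    return var.rename("liking_variance")


def peak_summary(peaks: Sequence[float]) -> dict[str, float]:
    """Location, spread and shape summaries of a peak distribution."""
    s = pd.Series(np.asarray(peaks, float)).dropna()
    return {
        "n": int(len(s)),
        "mean": float(s.mean()),
        "median": float(s.median()),
        "sd": float(s.std(ddof=1)),
        "skew": float(s.skew()),
        "kurtosis": float(s.kurt()),
    }


def _predictor_series(table: StimulusTable, predictor: str) -> pd.Series:
    if predictor == "complexity":
        return table.complexity
    nw = table.non_warmup
    if predictor not in nw.columns:
        raise ValueError(f"stimulus table has no {predictor!r} column")
    s = pd.Series(nw[predictor].to_numpy(float), index=nw["excerpt_id"], name=predictor)
    if s.isna().any():
        raise ValueError(f"predictor {predictor!r} has missing values")
    return s


class WundtModel:
    """Per-participant Wundt-curve model for a liking matrix.

    Parameters
    ----------
    matrix : LikingMatrix
        Participants x excerpts ratings.
    stimuli : StimulusTable
        Supplies the predictor (complexity by default; pass
        ``predictor="entropy"`` to rerun the analysis on an objective
        Wiener-entropy score stored in the table).
    threshold : float
        Quadratic-component cutoff for the Wundt classification.
    clip_vertices : bool
        Clip out-of-range vertices to the nearest endpoint of the
        stimulus range (the unclipped vertex is kept in ``peak_raw``).
    """

    def __init__(
        self,
        matrix: LikingMatrix,
        stimuli: StimulusTable,
        *,
        threshold: float = WUNDT_THRESHOLD,
        clip_vertices: bool = True,
        predictor: str = "complexity",
    ) -> None:
        self.matrix = matrix
        self.stimuli = stimuli
        self.threshold = float(threshold)
        self.clip_vertices = bool(clip_vertices)
        self.predictor = predictor
        self._xs = _predictor_series(stimuli, predictor)
        missing = [c for c in matrix.df.columns if c not in self._xs.index]
        if missing:
            raise ValueError(f"excerpt {missing[0]!r} missing from stimulus table")

    @classmethod
    def from_files(cls, liking_path, stimuli_path, **kwargs) -> "WundtModel":
        from .io import read_liking_matrix, read_stimulus_table

        stimuli = read_stimulus_table(stimuli_path)
        return cls(read_liking_matrix(liking_path, stimuli), stimuli, **kwargs)

    def fit(self, *, group_curve: bool = True, reml: bool = True) -> "WundtResults":
        """Fit every participant's quadratic; optionally the group curve."""
        cols = [c for c in self.matrix.df.columns]
        x = self._xs.loc[cols].to_numpy()
        Y = self.matrix.df.loc[:, cols].to_numpy(float)
        rng_ = (float(np.min(x)), float(np.max(x)))
        complete = ~np.isnan(Y).any()
        rows = []
        if complete:  # single batched solve; identical to row-by-row OLS
            coefs, r2 = _ols_quadratic(x, Y)
            fits = [
                WundtFit(float(b0), float(b1), float(b2), float(r), Y.shape[1])
                for (b0, b1, b2), r in zip(coefs, r2)
            ]
        else:
            fits = [
                fit_participant_curve(x, Y[i]) for i in range(Y.shape[0])
            ]
        for pid, f in zip(self.matrix.participant_ids, fits):
            peak, ptype = preferred_level(f, rng_)
            if not self.clip_vertices and ptype == "clipped_vertex":
                peak, ptype = f.vertex, "interior_vertex"
            rows.append(
                {
                    "participant_id": pid,
                    "b0": f.b0,
                    "b1": f.b1,
                    "b2": f.b2,
                    "r2": f.r2,
                    "n_obs": f.n_obs,
                    "classification": classify_wundt(f, self.threshold),
                    "peak_raw": f.vertex,
                    "peak": peak,
                    "peak_type": ptype,
                }
            )
        fits_df = pd.DataFrame(rows).set_index("participant_id")
        group = None
        if group_curve and len(self.matrix) >= 2:
            group = fit_group_curve(
                self.matrix, self.stimuli, reml=reml, predictor=self.predictor
            )
        return WundtResults(self, fits_df, group)


class WundtResults:
    """Fitted per-participant curves, classifications and peaks."""

    def __init__(
        self, model: WundtModel, fits: pd.DataFrame, group: GroupCurve | None
    ) -> None:
        self.model = model
        self.fits = fits
        self.group = group

    @property
    def wundt_mask(self) -> pd.Series:
        return self.fits["classification"] == "wundt"

    @property
    def n_wundt(self) -> int:
        return int(self.wundt_mask.sum())

    @property
    def peaks(self) -> pd.Series:
        """Preferred complexity of Wundt responders (defined peaks only)."""
        return self.fits.loc[self.wundt_mask, "peak"].dropna()

    @property
    def all_peaks(self) -> pd.Series:
        """Peaks of every participant with a defined preferred level."""
        return self.fits.loc[self.fits["peak_type"] != "undefined", "peak"].dropna()

    def peak_summary(self) -> dict[str, float]:
        return peak_summary(self.peaks)

    def to_csv(self, path) -> None:
        self.fits.to_csv(path, index_label="participant_id")

    def summary(self) -> str:
        ps = self.peak_summary()
        lines = [
            "Wundt curve analysis",
            "=" * 52,
            f"participants          {len(self.fits):>8d}",
            f"wundt responders      {self.n_wundt:>8d}"
            f"  (threshold b2 <= {self.model.threshold:g})",
            f"non-wundt             {len(self.fits) - self.n_wundt:>8d}",
            f"predictor             {self.model.predictor:>8s}",
            "",
            "preferred complexity (wundt responders)",
            f"  mean {ps['mean']:.2f}  median {ps['median']:.2f}  "
            f"sd {ps['sd']:.3f}  skew {ps['skew']:.2f}  kurtosis {ps['kurtosis']:.2f}"
            if ps["n"] else "  (no wundt responders)",
        ]
        if self.group is not None:
            g = self.group
            lines += [
                "",
                "group curve (random intercepts)",
                f"  linear    beta = {g.beta_lin:8.3f}  (se {g.se_lin:.3f}, p = {g.p_lin:.3g})",
                f"  quadratic beta = {g.beta_quad:8.3f}  (se {g.se_quad:.3f}, p = {g.p_quad:.3g})",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<WundtResults: {len(self.fits)} participants, "
            f"{self.n_wundt} wundt>"
        )
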