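"""Random-intercept linear mixed models for richness and abundance.

The model is

    y_ij = beta_0 + beta_c 1[condition_i = c] + u_j + e_ij,
    u_j ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma^2),

with one random intercept per block (experimental design) or site
(observational design), fitted by REML.  Fixed-effect contrasts are
reported against a designated reference condition with Wald-type p-values
on a residual-degrees-of-freedom t approximation.  Estimation is delegated
to statsmodels' ``MixedLM``; this module owns the contract (REML, random
intercept only, reference-level contrasts) and the degenerate-input
handling, not the optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_io import ValidationError


@dataclass
class FixedEffect:
    level: str
    estimate: float     # Delta vs reference
    se: float
    p: float


@dataclass
class LMEResult:
    response: str
    reference: str
    fixed_effects: dict             # condition level -> FixedEffect (reference: estimate 0)
    intercept: float
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int
    df_resid: int                   # residual-df approximation used for p-values
    fit_method: str = "REML"
    boundary: bool = False          # random-intercept variance at/near zero
    degenerate: bool = False        # constant response; trivial fit

    def effects_frame(self) -> pd.DataFrame:
        rows = [
            {"level": fe.level, "estimate": fe.estimate, "se": fe.se, "p": fe.p}
            for fe in self.fixed_effects.values()
        ]
        return pd.DataFrame(rows)


def fit_lme(
    y,
    condition,
    grouping,
    reference: str,
    response_name: str = "richness",
) -> LMEResult:
    """Fit the random-intercept model and contrast each condition level
    against ``reference``.

    Degenerate inputs are handled explicitly: a constant response yields a
    zero-variance result with all contrasts 0 (``degenerate``); a fit whose
    random-intercept variance collapses to the boundary is returned with
    ``boundary=True`` rather than an error.
    """
    y = np.asarray(y, dtype=float)
    condition = np.asarray(condition).astype(str)
    grouping = np.asarray(grouping).astype(str)
    if not (len(y) == len(condition) == len(grouping)):
        raise ValidationError("y, condition and grouping must have equal length")
    levels = sorted(set(condition))
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} not among condition levels")
    if len(levels) < 2:
        raise ValidationError("need at least 2 condition levels")
    groups_uniq = sorted(set(grouping))
    if len(groups_uniq) < 2:
        raise ValidationError("need at least 2 grouping units for a random intercept")

    others = [l for l in levels if l != reference]
    n, p_fixed = len(y), 1 + len(others)
    df_resid = max(n - p_fixed - len(groups_uniq) + 1, 1)

    fixed = {reference: FixedEffect(level=reference, estimate=0.0, se=0.0, p=np.nan)}

    if np.ptp(y) == 0.0:
        for l in others:
            fixed[l] = FixedEffect(level=l, estimate=0.0, se=0.0, p=np.nan)
        return LMEResult(
            response=response_name, reference=reference, fixed_effects=fixed,
            intercept=float(y[0]) if n else 0.0,
            random_intercept_sd=0.0, residual_sd=0.0,
            n_obs=n, n_groups=len(groups_uniq), df_resid=df_resid,
            boundary=True, degenerate=True,
        )

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    X = np.column_stack([np.ones(n)] + [(condition == l).astype(float) for l in others])
    boundary = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = sm.MixedLM(y, X, groups=grouping)
        try:
            fit = model.fit(reml=True, method=["lbfgs", "cg"])
        except (np.linalg.LinAlgError, ValueError):
            fit = model.fit(reml=True, method="powell")

    params = np.asarray(fit.fe_params)
    bse = np.asarray(fit.bse_fe)
    var_b = float(np.squeeze(fit.cov_re)) if fit.cov_re.size else 0.0
    if var_b < 1e-8 * max(float(fit.scale), 1e-300):
        boundary = True

    for j, l in enumerate(others, start=1):
        t = params[j] / bse[j] if bse[j] > 0 else np.inf * np.sign(params[j])
        p_val = 2.0 * stats.t.sf(abs(t), df=df_resid)
        fixed[l] = FixedEffect(level=l, estimate=float(params[j]), se=float(bse[j]), p=float(p_val))

    return LMEResult(
        response=response_name, reference=reference, fixed_effects=fixed,
        intercept=float(params[0]),
        random_intercept_sd=float(np.sqrt(max(var_b, 0.0))),
        residual_sd=float(np.sqrt(max(float(fit.scale), 0.0))),
        n_obs=n, n_groups=len(groups_uniq), df_resid=df_resid,
        boundary=boundary, degenerate=False,
    )
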