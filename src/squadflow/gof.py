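"""Chi-square goodness-of-fit test with free-parameter correction.

Under the null hypothesis that model-data deviations are pure white noise,
each weighted residual (x - x~)/sigma is standard normal, so the total
chi-square is chi-square-distributed.  Because every fitted parameter lets
the model absorb one direction of noise, the degrees of freedom are the
number of data points minus the number of free parameters.  The p-value is
the upper-tail probability of that distribution at the observed chi-square;
if it falls below the significance level we reject the hypothesis that the
model explains the data.  With dof <= 0 (more free parameters than data
points) the test is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import DataError


@dataclass
class GofResult:
    chi2_observed: float
    n_data: int
    n_free: int
    dof: int
    p_value: float | None
    level: float
    verdict: str
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.p_value is not None


def chi2_test(chi2_observed: float, n_data: int, n_free: int,
              level: float = 0.05) -> GofResult:
    """Upper-tail chi-square test at ``n_data - n_free`` degrees of freedom.

    Verdict is "cannot reject" iff p >= level; "undefined" when dof <= 0
    (too few data points relative to the free parameters).
    """
    if chi2_observed < 0:
        raise DataError(f"chi-square must be non-negative, got {chi2_observed}")
    if n_data < 0 or n_free < 0:
        raise DataError("n_data and n_free must be non-negative")
    if not 0.0 < level < 1.0:
        raise DataError(f"significance level must lie in (0, 1), got {level}")
    dof = n_data - n_free
    if dof <= 0:
        return GofResult(chi2_observed, n_data, n_free, dof, None, level,
                         verdict="undefined",
                         reason="insufficient data points: dof = "
                                f"{n_data} - {n_free} = {dof} <= 0")
    p = float(stats.chi2.sf(chi2_observed, dof))
    verdict = "cannot reject" if p >= level else "reject"
    return GofResult(chi2_observed, n_data, n_free, dof, p, level, verdict)
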