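"""Method-agreement analysis between CT and gravimetric wear measurements.

Linear regression (gravimetric on x, CT on y), Bland-Altman bias and 95 %
limits of agreement, Shapiro-Wilk normality of the differences, and
per-specimen percentage differences.  The difference convention is fixed
to CT minus gravimetric throughout and enforced by :class:`MethodPair`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethodPair",
    "AgreementReport",
    "linear_fit",
    "bland_altman",
    "shapiro_wilk",
    "percent_differences",
    "analyze_pairs",
    "pairs_from_dataframe",
]


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class MethodPair:
    """One specimen measured by both methods (masses in mg)."""

    specimen_id: str
    ct_mass: float
    grav_mass: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ct_mass) and np.isfinite(self.grav_mass)):
            raise AgreementError(f"non-finite mass for {self.specimen_id}")

    @property
    def difference(self) -> float:
        """CT minus gravimetric (mg) — the fixed sign convention."""
        return self.ct_mass - self.grav_mass

    @property
    def mean(self) -> float:
        return 0.5 * (self.ct_mass + self.grav_mass)


def _arrays(pairs: list[MethodPair]) -> tuple[np.ndarray, np.ndarray]:
    ct = np.array([p.ct_mass for p in pairs], dtype=float)
    gv = np.array([p.grav_mass for p in pairs], dtype=float)
    return ct, gv


def linear_fit(pairs: list[MethodPair]) -> tuple[float, float, float]:
    """OLS of CT (y) on gravimetric (x); returns (slope, intercept, R^2).

    R^2 is the squared Pearson correlation, the coefficient of
    determination quoted for method-comparison scatter plots.
    """
    if len(pairs) < 3:
        raise AgreementError("need at least 3 pairs for regression")
    ct, gv = _arrays(pairs)
    if np.ptp(gv) == 0:
        raise AgreementError("zero variance in gravimetric masses")
    res = stats.linregress(gv, ct)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(pairs: list[MethodPair], k: float = 1.96):
    """Bland-Altman bias and limits of agreement.

    bias = mean(CT - grav); sd is the sample standard deviation (n-1);
    limits of agreement = bias +/- k*sd (k = 1.96 for the 95 % limits).
    Returns ``(bias, sd_diff, loa_upper, loa_lower, coords)`` where
    ``coords`` are the (mean, difference) points for plotting.
    """
    if len(pairs) < 2:
        raise AgreementError("need at least 2 pairs")
    d = np.array([p.difference for p in pairs])
    m = np.array([p.mean for p in pairs])
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias + k * sd, bias - k * sd, np.column_stack([m, d])


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's approximation), 3 <= n <= 5000."""
    values = np.asarray(values, dtype=float)
    if not (3 <= len(values) <= 5000):
        raise AgreementError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(values)}")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def percent_differences(pairs: list[MethodPair]):
    """Per-pair percentage difference 100*(CT - grav)/grav.

    Returns ``(per_pair, mean_signed, max_abs, max_abs_specimen)`` where
    ``per_pair`` maps specimen_id -> signed percent.
    """
    for p in pairs:
        if p.grav_mass == 0:
            raise AgreementError(f"zero gravimetric mass for {p.specimen_id}")
    per = {p.specimen_id: 100.0 * p.difference / p.grav_mass for p in pairs}
    vals = np.array(list(per.values()))
    ids = list(per.keys())
    imax = int(np.argmax(np.abs(vals)))
    return per, float(vals.mean()), float(np.abs(vals[imax])), ids[imax]


@dataclass
class AgreementReport:
    """All agreement statistics for a set of CT/gravimetric pairs (mg)."""

    n_pairs: int
    slope: float
    intercept: float
    r_squared: float
    bias_mg: float
    sd_diff_mg: float
    loa_upper_mg: float
    loa_lower_mg: float
    loa_k: float
    shapiro_W: float
    shapiro_p: float
    percent_by_specimen: dict = field(default_factory=dict)
    mean_signed_percent: float = 0.0
    max_abs_percent: float = 0.0
    max_abs_percent_specimen: str = ""

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)

    def summary(self) -> str:
        return (
            f"n = {self.n_pairs} pairs\n"
            f"regression  CT = {self.slope:.3f} * grav + {self.intercept:.2f} mg, "
            f"R^2 = {self.r_squared:.4f}\n"
            f"Bland-Altman  bias = {self.bias_mg:.2f} mg, "
            f"LoA (+{self.loa_k:g} SD) = {self.loa_upper_mg:.1f} mg, "
            f"LoA (-{self.loa_k:g} SD) = {self.loa_lower_mg:.1f} mg\n"
            f"Shapiro-Wilk  W = {self.shapiro_W:.3f}, p = {self.shapiro_p:.2f}\n"
            f"percent difference  mean signed = {self.mean_signed_percent:.1f} %, "
            f"max |%| = {self.max_abs_percent:.1f} % "
            f"({self.max_abs_percent_specimen})"
        )


def analyze_pairs(pairs: list[MethodPair], k: float = 1.96) -> AgreementReport:
    """Full agreement analysis: regression + Bland-Altman + normality + %."""
    slope, intercept, r2 = linear_fit(pairs)
    bias, sd, upper, lower, _ = bland_altman(pairs, k=k)
    w, p = shapiro_wilk([pr.difference for pr in pairs])
    per, mean_pct, max_pct, max_id = percent_differences(pairs)
    return AgreementReport(
        n_pairs=len(pairs),
        slope=slope, intercept=intercept, r_squared=r2,
        bias_mg=bias, sd_diff_mg=sd,
        loa_upper_mg=upper, loa_lower_mg=lower, loa_k=k,
        shapiro_W=w, shapiro_p=p,
        percent_by_specimen=per,
        mean_signed_percent=mean_pct,
        max_abs_percent=max_pct,
        max_abs_percent_specimen=max_id,
    )


def pairs_from_dataframe(df: pd.DataFrame) -> list[MethodPair]:
    """Build pairs from a frame with specimen_id, ct_mass_mg, grav_mass_mg."""
    needed = {"specimen_id", "ct_mass_mg", "grav_mass_mg"}
    missing = needed - set(df.columns)
    if missing:
        raise AgreementError(f"missing columns: {sorted(missing)}")
    return [
        MethodPair(str(r.specimen_id), float(r.ct_mass_mg), float(r.grav_mass_mg))
        for r in df.itertuples(index=False)
    ]


def plot_agreement(pairs: list[MethodPair], report: AgreementReport, path) -> None:
    """Scatter + Bland-Altman figure (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ct, gv = _arrays(pairs)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.2))
    ax1.scatter(gv, ct, color="tab:blue")
    xs = np.linspace(gv.min(), gv.max(), 2)
    ax1.plot(xs, report.slope * xs + report.intercept, "k-", lw=1,
             label=f"$R^2$ = {report.r_squared:.4f}")
    ax1.set_xlabel("gravimetric mass loss (mg)")
    ax1.set_ylabel("CT mass loss (mg)")
    ax1.legend()
    means = 0.5 * (ct + gv)
    diffs = ct - gv
    ax2.scatter(means, diffs, color="tab:blue")
    for y, style in ((report.bias_mg, "k-"), (report.loa_upper_mg, "k--"),
                     (report.loa_lower_mg, "k--")):
        ax2.axhline(y, ls=style[1:], color="k", lw=1)
    ax2.set_xlabel("mean of methods (mg)")
    ax2.set_ylabel("CT - gravimetric (mg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
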